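"""Univariate group comparisons and feature-correlation structure.

Each of the 18 network features is compared between groups with an
independent two-sample Student t-test (pooled variance, two-sided, no
multiplicity adjustment by default — an optional Holm correction is
available).  The Pearson correlation matrix across features summarizes how
much non-redundant information the multivariable model has to draw on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graphmetrics import FEATURE_NAMES
from .model_validation import CohortDataset

__all__ = [
    "FeatureComparison",
    "per_feature_ttest",
    "feature_correlation",
    "comparisons_to_dataframe",
    "correlation_heatmap",
]


@dataclass(frozen=True)
class FeatureComparison:
    """Per-feature two-group comparison (case group listed first)."""

    feature: str
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    t: float
    p: float  # NaN when the pooled variance is zero
    degenerate: bool = False


def per_feature_ttest(
    data: CohortDataset, holm: bool = False
) -> list[FeatureComparison]:
    """Pooled-variance Student t-test per feature, two-sided.

    The t statistic is (mean_case - mean_control) / SE_pooled.  Features
    with zero pooled variance are flagged degenerate with p = NaN.  With
    ``holm=True`` p-values are Holm step-down adjusted (off by default).
    """
    X, y = data.X, data.y
    case = X[y == 1]
    ctrl = X[y == 0]
    out = []
    for j, name in enumerate(FEATURE_NAMES):
        a, b = case[:, j], ctrl[:, j]
        pooled_var = (
            (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
        ) / (a.size + b.size - 2)
        if pooled_var == 0:
            out.append(
                FeatureComparison(
                    name, float(a.mean()), float(b.mean()),
                    float(a.std(ddof=1)), float(b.std(ddof=1)),
                    t=0.0 if a.mean() == b.mean() else math.inf,
                    p=math.nan, degenerate=True,
                )
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        out.append(
            FeatureComparison(
                name, float(a.mean()), float(b.mean()),
                float(a.std(ddof=1)), float(b.std(ddof=1)),
                t=float(t), p=float(p),
            )
        )
    if holm:
        ps = np.array([c.p for c in out])
        valid = ~np.isnan(ps)
        order = np.argsort(ps[valid])
        m = valid.sum()
        adj = np.empty(m)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, (m - rank) * ps[valid][k])
            adj[k] = min(1.0, running)
        it = iter(adj)
        out = [
            FeatureComparison(
                c.feature, c.mean_case, c.mean_control, c.sd_case,
                c.sd_control, c.t, float(next(it)), c.degenerate,
            )
            if not np.isnan(c.p) else c
            for c in out
        ]
    return out


def feature_correlation(data: CohortDataset) -> pd.DataFrame:
    """18x18 Pearson correlation matrix of the network features.

    Symmetric with unit diagonal; a constant feature yields NaN in its row
    and column (flagged missing rather than zero).  Requires >= 3 subjects.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    df = pd.DataFrame(data.X, columns=list(FEATURE_NAMES))
    corr = df.corr()
    constant = df.std(ddof=1) == 0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    np.fill_diagonal(corr.values, np.where(constant, np.nan, 1.0))
    return corr


def comparisons_to_dataframe(comparisons: list[FeatureComparison]) -> pd.DataFrame:
    """Tabulate t-test results, one row per feature (CSV-ready)."""
    return pd.DataFrame([vars(c) for c in comparisons])


def correlation_heatmap(corr: pd.DataFrame, path: str) -> None:
    """Render the feature-correlation matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
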