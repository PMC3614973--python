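"""Random-forest diagnostic model with bootstrap internal validation.

Small diagnostic cohorts make apparent (same-data) performance optimistic.
Validation here is bootstrap-corrected: the forest is refit on ``B``
group-stratified resamples drawn with replacement, and each replicate is
scored only on its out-of-bag subjects (those the resample never drew).
Replicate ROC curves are vertically averaged on a fixed false-positive-rate
grid; point estimates are replicate means and 95% confidence intervals the
2.5th/97.5th percentiles.  A Harrell-style optimism-correction mode is
available as an alternative.

Sensitivity/specificity (and PPV/NPV) are reported at the operating point
maximizing Youden's J = sensitivity + specificity - 1 on the scored set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .graphmetrics import FEATURE_NAMES, NetworkFeatureVector
from .preprocess import FrequencyBand

__all__ = [
    "SubjectRecord",
    "CohortDataset",
    "ForestModel",
    "fit_forest",
    "roc_and_auc",
    "threshold_metrics",
    "ThresholdMetrics",
    "bootstrap_validate",
    "ValidationReport",
]

GROUP_LABELS = ("control", "case")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    features: NetworkFeatureVector
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}")


@dataclass
class CohortDataset:
    """Labelled feature vectors of a two-group cohort."""

    subjects: list[SubjectRecord]
    band: FrequencyBand | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for g in GROUP_LABELS:
            if sum(s.group == g for s in self.subjects) < 2:
                raise ValueError(f"need at least 2 subjects in group {g!r}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def X(self) -> np.ndarray:
        return np.vstack([s.features.as_array() for s in self.subjects])

    @property
    def y(self) -> np.ndarray:
        """1 for cases, 0 for controls."""
        return np.array([1 if s.group == "case" else 0 for s in self.subjects])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group": s.group}
            row.update(s.features.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df, band: FrequencyBand | None = None) -> "CohortDataset":
        subjects = [
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                features=NetworkFeatureVector(
                    **{name: float(row[name]) for name in FEATURE_NAMES}
                ),
                group=str(row["group"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(subjects, band=band)


class ForestModel:
    """Random forest over the 18 network features, scoring case probability.

    Each tree is grown on a bootstrap resample of the training subjects with
    ``mtry`` randomly selected candidate features per split; the model score
    is the fraction of trees voting "case" (trees are grown to purity, so the
    averaged leaf probabilities coincide with vote fractions).
    """

    def __init__(self, mtry: int = 5, n_trees: int = 500, seed: int | None = None):
        if not 1 <= mtry <= len(FEATURE_NAMES):
            raise ValueError(f"mtry must be in 1..{len(FEATURE_NAMES)}")
        self.mtry = mtry
        self.n_trees = n_trees
        self.seed = seed
        self._clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry,
            bootstrap=True,
            random_state=seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ForestModel":
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        self._clf.fit(X, y)
        return self

    def predict_proba_case(self, X: np.ndarray) -> np.ndarray:
        idx = list(self._clf.classes_).index(1)
        return self._clf.predict_proba(X)[:, idx]


def fit_forest(
    train: CohortDataset,
    mtry: int = 5,
    n_trees: int = 500,
    seed: int | None = None,
) -> ForestModel:
    """Fit the diagnostic random forest on a labelled cohort."""
    return ForestModel(mtry=mtry, n_trees=n_trees, seed=seed).fit(train.X, train.y)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = np.array([1 if v == "case" else 0 for v in y])
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be case/control or 0/1")
    return y


def roc_and_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Empirical ROC points and trapezoidal AUC.

    The trapezoidal area under the empirical ROC equals the Mann-Whitney U
    statistic divided by n_case * n_control (ties between a case and a
    control score count one half).  Constant scores yield the diagonal and
    AUC 0.5.
    """
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


@dataclass(frozen=True)
class ThresholdMetrics:
    """2x2-table metrics at the Youden-optimal threshold.

    PPV/NPV are NaN when their denominator is empty (no positive or no
    negative predictions); ``degenerate`` flags score sets where no
    threshold separates anything (all scores identical).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    degenerate: bool = False


def threshold_metrics(scores, labels) -> ThresholdMetrics:
    """Sensitivity, specificity, PPV, NPV at the max-Youden-J threshold.

    Candidate thresholds are the distinct observed scores; a subject is
    called positive when its score is >= the threshold.
    """
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)

    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / n_pos
        spec = (n_neg - fp) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, tp, fp)
    j, thr, tp, fp = best
    fn = n_pos - tp
    tn = n_neg - fp
    ppv = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    npv = tn / (tn + fn) if (tn + fn) > 0 else math.nan
    return ThresholdMetrics(
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        ppv=ppv,
        npv=npv,
        threshold=float(thr),
        degenerate=bool(np.unique(scores).size == 1),
    )


@dataclass
class ValidationReport:
    """Bootstrap-corrected validation summary.

    Point estimates are replicate means; ``*_ci`` are percentile 95%
    intervals; ``roc_points`` is the vertically averaged ROC sampled on a
    fixed FPR grid.
    """

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    roc_points: np.ndarray
    n_bootstrap: int
    n_skipped: int
    seed: int | None
    settings: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv, "ppv_ci": list(self.ppv_ci),
            "npv": self.npv, "npv_ci": list(self.npv_ci),
            "roc_points": self.roc_points.tolist(),
            "n_bootstrap": self.n_bootstrap,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
            "settings": self.settings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path: str) -> "ValidationReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            auc=d["auc"], auc_ci=tuple(d["auc_ci"]),
            sensitivity=d["sensitivity"],
            sensitivity_ci=tuple(d["sensitivity_ci"]),
            specificity=d["specificity"],
            specificity_ci=tuple(d["specificity_ci"]),
            ppv=d["ppv"], ppv_ci=tuple(d["ppv_ci"]),
            npv=d["npv"], npv_ci=tuple(d["npv_ci"]),
            roc_points=np.asarray(d["roc_points"]),
            n_bootstrap=d["n_bootstrap"], n_skipped=d["n_skipped"],
            seed=d["seed"], settings=d.get("settings", {}),
        )

    def plot_roc(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1], lw=2,
                label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _interp_tpr(points: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, points[:, 0], points[:, 1])


def bootstrap_validate(
    data: CohortDataset,
    B: int = 1000,
    mtry: int = 5,
    n_trees: int = 500,
    seed: int | None = None,
    fpr_grid_points: int = 101,
    method: str = "oob",
) -> ValidationReport:
    """Bootstrap-corrected internal validation of the forest model.

    For each of ``B`` replicates, subjects are resampled with replacement
    stratified by group (preserving the group sizes), the forest is refit on
    the resample, and ROC/AUC plus Youden-threshold metrics are computed on
    the out-of-bag subjects.  Replicates whose out-of-bag set misses a group
    are skipped; more than 20% skipped raises.  ``method="optimism"``
    instead applies Harrell's optimism correction to the AUC (threshold
    metrics still from OOB scoring).
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    if method not in ("oob", "optimism"):
        raise ValueError("method must be 'oob' or 'optimism'")
    X, y = data.X, data.y
    idx_case = np.where(y == 1)[0]
    idx_ctrl = np.where(y == 0)[0]
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, fpr_grid_points)

    aucs, senss, specs, ppvs, npvs, tprs = [], [], [], [], [], []
    optimisms = []
    n_skipped = 0
    if method == "optimism":
        full_model = fit_forest(data, mtry, n_trees,
                                seed=int(rng.integers(2**31)))
        _, apparent_auc = roc_and_auc(full_model.predict_proba_case(X), y)

    for _ in range(B):
        boot = np.concatenate([
            rng.choice(idx_case, size=idx_case.size, replace=True),
            rng.choice(idx_ctrl, size=idx_ctrl.size, replace=True),
        ])
        oob = np.setdiff1d(np.arange(len(y)), boot)
        if len(np.unique(y[oob])) < 2:
            n_skipped += 1
            continue
        model = ForestModel(
            mtry=mtry, n_trees=n_trees, seed=int(rng.integers(2**31))
        ).fit(X[boot], y[boot])
        scores = model.predict_proba_case(X[oob])
        points, auc = roc_and_auc(scores, y[oob])
        tm = threshold_metrics(scores, y[oob])
        aucs.append(auc)
        senss.append(tm.sensitivity)
        specs.append(tm.specificity)
        ppvs.append(tm.ppv)
        npvs.append(tm.npv)
        tprs.append(_interp_tpr(points, grid))
        if method == "optimism":
            _, auc_boot = roc_and_auc(model.predict_proba_case(X[boot]), y[boot])
            _, auc_full = roc_and_auc(model.predict_proba_case(X), y)
            optimisms.append(auc_boot - auc_full)

    if n_skipped > 0.2 * B:
        raise ValueError(
            f"{n_skipped}/{B} bootstrap replicates lacked out-of-bag subjects "
            "in one group"
        )

    def _est(values) -> tuple[float, tuple[float, float]]:
        arr = np.asarray(values, dtype=float)
        point = float(np.nanmean(arr))
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        return point, (float(lo), float(hi))

    auc_pt, auc_ci = _est(aucs)
    if method == "optimism":
        auc_pt = float(apparent_auc - np.mean(optimisms))
        auc_ci = (
            float(apparent_auc - np.percentile(optimisms, 97.5)),
            float(apparent_auc - np.percentile(optimisms, 2.5)),
        )
    sens_pt, sens_ci = _est(senss)
    spec_pt, spec_ci = _est(specs)
    ppv_pt, ppv_ci = _est(ppvs)
    npv_pt, npv_ci = _est(npvs)

    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr = np.maximum.accumulate(mean_tpr)  # guard monotonicity
    roc_points = np.column_stack([grid, mean_tpr])

    return ValidationReport(
        auc=auc_pt, auc_ci=auc_ci,
        sensitivity=sens_pt, sensitivity_ci=sens_ci,
        specificity=spec_pt, specificity_ci=spec_ci,
        ppv=ppv_pt, ppv_ci=ppv_ci,
        npv=npv_pt, npv_ci=npv_ci,
        roc_points=roc_points,
        n_bootstrap=B - n_skipped,
        n_skipped=n_skipped,
        seed=seed,
        settings={"B": B, "mtry": mtry, "n_trees": n_trees, "method": method},
    )
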