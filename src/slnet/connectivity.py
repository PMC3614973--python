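"""Synchronization likelihood (SL) functional connectivity.

SL quantifies generalized (linear and nonlinear) synchronization between two
time series as a value in [0, 1].  Both channels are delay-embedded into
state vectors.  For every reference time ``i`` a channel-specific critical
distance is calibrated so that a fixed fraction ``p_ref`` of the eligible
comparison times ``j`` (those with ``w1 < |i - j| <= w2``; the Theiler window
``w1`` excludes autocorrelated neighbours) are *recurrent*, i.e. closer than
the critical distance in embedding space.  SL(x, y) is then the probability
that channel y is recurrent at a time pair (i, j) given that channel x is,
averaged over all eligible pairs, symmetrized over the two directions.
Independent channels give SL ≈ p_ref; identical channels give SL = 1.

Default embedding parameters follow the frequency-adaptive prescription of
the software lineage this measure comes from: for an analysis band
``[f_lo, f_hi]`` at sampling rate ``fs``,

    lag = round(fs / (3 f_hi)),  m = round(3 f_hi / f_lo) + 1 (capped at 16),
    w1 = 2 lag (m - 1),          w2 = w1 + floor(10 / p_ref),  p_ref = 0.05.

All parameters are overridable per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import FrequencyBand
from .recording import EpochedRecording

__all__ = [
    "SLParams",
    "ConnectivityMatrix",
    "default_sl_params",
    "embed",
    "critical_distance",
    "sl_matrix",
    "subject_connectivity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SLParams:
    """Embedding and recurrence parameters for synchronization likelihood.

    ``lag`` (samples) and ``embed_dim`` define the delay embedding; ``w1`` is
    the Theiler exclusion window, ``w2`` the outer comparison window (both in
    samples); ``p_ref`` the target recurrence probability.
    """

    lag: int
    embed_dim: int
    w1: int
    w2: int
    p_ref: float = 0.05

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if not 0 < self.p_ref < 1:
            raise ValueError("p_ref must be in (0, 1)")
        if self.w1 < 2 * self.lag * (self.embed_dim - 1):
            raise ValueError("w1 must be >= 2*lag*(embed_dim-1)")
        if self.w2 <= self.w1:
            raise ValueError("w2 must exceed w1")

    def n_embedded(self, n_samples: int) -> int:
        return n_samples - (self.embed_dim - 1) * self.lag

    def validate_for_length(self, n_samples: int) -> None:
        n_emb = self.n_embedded(n_samples)
        if n_emb < self.w2:
            raise ValueError(
                f"epoch of {n_samples} samples yields {n_emb} embedded vectors; "
                f"need at least w2={self.w2}"
            )


def default_sl_params(
    band: FrequencyBand, fs: float, p_ref: float = 0.05, m_cap: int = 16
) -> SLParams:
    """Frequency-adaptive SL parameters for a band at sampling rate ``fs``."""
    lag = max(1, round(fs / (3.0 * band.f_hi)))
    m = min(m_cap, round(3.0 * band.f_hi / band.f_lo) + 1)
    m = max(2, m)
    w1 = 2 * lag * (m - 1)
    w2 = w1 + int(np.floor(10.0 / p_ref))
    return SLParams(lag=lag, embed_dim=m, w1=w1, w2=w2, p_ref=p_ref)


def embed(series: np.ndarray, m: int, lag: int) -> np.ndarray:
    """Delay-embed a 1-D series into m-dimensional state vectors.

    Vector ``t`` has components ``series[t + k*lag]`` for ``k = 0..m-1``;
    the result has ``len(series) - (m-1)*lag`` rows.  ``m = 1`` returns the
    samples themselves as column vectors.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if m < 1 or lag < 1:
        raise ValueError("m and lag must be >= 1")
    n_emb = series.size - (m - 1) * lag
    if n_emb < 1:
        raise ValueError(
            f"series too short: need more than {(m - 1) * lag} samples "
            f"for m={m}, lag={lag}"
        )
    cols = [series[k * lag : k * lag + n_emb] for k in range(m)]
    return np.column_stack(cols)


def _offset_sq_distances(
    embedded: np.ndarray, w1: int, w2: int
) -> np.ndarray:
    """Squared distances from each reference to its eligible neighbours.

    Returns ``(n_emb, 2*(w2-w1))`` with column block 0 holding offsets
    ``+(w1+1)..+w2`` and block 1 the mirrored negative offsets; entries whose
    neighbour index falls outside the series are +inf.
    """
    n = embedded.shape[0]
    n_off = w2 - w1
    D = np.full((n, 2 * n_off), np.inf)
    for k, d in enumerate(range(w1 + 1, w2 + 1)):
        if d >= n:
            continue
        diff = embedded[d:] - embedded[:-d]
        sq = np.einsum("ij,ij->i", diff, diff)
        D[: n - d, k] = sq          # neighbour at i + d
        D[d:, n_off + k] = sq       # neighbour at i - d
    return D


def _row_kth_smallest(D: np.ndarray, p_ref: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-row k-th smallest finite entry, k = round(p_ref * n_eligible).

    Returns (values, n_eligible).  Rows are grouped by their k so the bulk of
    the matrix is handled by a single partition.
    """
    n_el = np.isfinite(D).sum(axis=1)
    if np.any(n_el < int(np.ceil(1.0 / p_ref))):
        raise ValueError(
            f"fewer than {int(np.ceil(1.0 / p_ref))} eligible neighbours for "
            "some reference times; increase epoch length or w2"
        )
    ks = np.maximum(1, np.rint(p_ref * n_el).astype(int))
    out = np.empty(D.shape[0])
    for k in np.unique(ks):
        rows = np.where(ks == k)[0]
        out[rows] = np.partition(D[rows], k - 1, axis=1)[:, k - 1]
    return out, n_el


def critical_distance(
    embedded: np.ndarray, p_ref: float, w1: int, w2: int
) -> np.ndarray:
    """Per-reference-time critical distance epsilon_i.

    epsilon_i is the distance at which the fraction of eligible neighbours
    (``w1 < |i-j| <= w2``) within epsilon_i of reference ``i`` is the nearest
    achievable to ``p_ref``.  For a zero-variance (constant) series all
    embedded vectors coincide and epsilon_i is 0 (saturated recurrence).
    """
    embedded = np.asarray(embedded, dtype=float)
    D = _offset_sq_distances(embedded, w1, w2)
    eps_sq, _ = _row_kth_smallest(D, p_ref)
    return np.sqrt(eps_sq)


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of pairwise SL values in [0, 1], zero diagonal."""

    values: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("values must be square")
        if len(self.channel_labels) != n:
            raise ValueError("one label per channel required")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("values must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("SL values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str) -> None:
        """Labelled square CSV (header row and index column = labels)."""
        import pandas as pd

        pd.DataFrame(
            self.values, index=self.channel_labels, columns=self.channel_labels
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str) -> "ConnectivityMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns))


def sl_matrix(
    epoch: np.ndarray,
    params: SLParams,
    channel_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Synchronization-likelihood matrix of one (channels x samples) epoch.

    For each ordered channel pair, SL(x -> y) is the fraction of eligible
    time pairs (i, j) at which y is recurrent among those at which x is
    recurrent; the reported SL is the mean of the two directions, clipped to
    [0, 1] with a zero diagonal.  Recurrence thresholds include ties (points
    exactly at the critical distance count as recurrent).  Zero-variance
    channels saturate the recurrence definition; their SL against every other
    channel is defined as 0 and a warning is logged.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (channels x samples)")
    n_ch, n_samples = epoch.shape
    params.validate_for_length(n_samples)
    if channel_labels is None:
        channel_labels = [f"ch{c}" for c in range(n_ch)]

    n_emb = params.n_embedded(n_samples)
    n_cols = 2 * (params.w2 - params.w1)
    saturated = np.array([np.ptp(epoch[c]) == 0 for c in range(n_ch)])
    if saturated.any():
        logger.warning(
            "zero-variance channel(s) %s: SL against them defined as 0",
            [channel_labels[c] for c in np.where(saturated)[0]],
        )

    # Recurrence indicators, one flattened (n_emb * n_cols) row per channel.
    R = np.zeros((n_ch, n_emb * n_cols), dtype=np.float32)
    for c in range(n_ch):
        E = embed(epoch[c], params.embed_dim, params.lag)
        D = _offset_sq_distances(E, params.w1, params.w2)
        eps_sq, _ = _row_kth_smallest(D, params.p_ref)
        # padded +inf entries compare False automatically
        R[c] = np.less_equal(D, eps_sq[:, None]).ravel()

    # joint[x, y] = number of (i, j) pairs recurrent in both channels; the
    # diagonal holds each channel's own recurrence count.  Counts are integers
    # below 2**24, exact in float32.
    joint = (R @ R.T).astype(float)
    own = np.diag(joint).copy()
    own[own == 0] = 1.0  # cannot occur for non-degenerate rows; guards 0/0
    directed = joint / own[:, None]
    S = 0.5 * (directed + directed.T)
    np.fill_diagonal(S, 0.0)
    S = np.clip(S, 0.0, 1.0)
    if saturated.any():
        S[saturated, :] = 0.0
        S[:, saturated] = 0.0
    return ConnectivityMatrix(S, list(channel_labels))


def subject_connectivity(
    recording: EpochedRecording, params: SLParams
) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch SL matrices for one subject."""
    if not recording.epochs:
        raise ValueError("recording has no epochs")
    acc = None
    for epoch in recording.epochs:
        m = sl_matrix(epoch, params, recording.channel_labels)
        acc = m.values if acc is None else acc + m.values
    return ConnectivityMatrix(acc / recording.n_epochs, recording.channel_labels)
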