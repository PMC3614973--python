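"""Weighted network characteristics of an SL connectivity graph.

The subject-level SL matrix defines a weighted complete graph on the EEG
channels.  Seven characteristic families are computed: strength (weighted
degree), average shortest path length, closeness, betweenness and eigenvector
centrality, weighted clustering, and the power-law scaling index of the
strength distribution.  Path-based metrics use edge length ``1/w`` — a high
synchronization index is a short functional distance.  Per-node values are
summarized as min/mean/max (mean/max only for betweenness) to form an
18-dimensional feature vector per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "strength",
    "weighted_shortest_paths",
    "closeness",
    "betweenness",
    "eigenvector_centrality",
    "weighted_clustering",
    "powerlaw_fit",
    "PowerLawFit",
    "NetworkFeatureVector",
    "feature_vector",
    "FEATURE_NAMES",
]

#: Tie tolerance when deciding whether a node lies on a shortest path.
PATH_TIE_TOL = 1e-12


def _weights(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.values
    return np.asarray(W, dtype=float)


def _summary(x: np.ndarray) -> dict[str, float]:
    return {"min": float(x.min()), "mean": float(x.mean()), "max": float(x.max())}


def strength(W: ConnectivityMatrix | np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    """Weighted degree centrality s_i = sum_j w_ij, with min/mean/max."""
    w = _weights(W)
    s = w.sum(axis=1)
    return s, _summary(s)


def _length_matrix(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(w[off] <= 0):
        raise ValueError(
            "zero or negative off-diagonal weight: edge length 1/w undefined "
            "(graph would be disconnected)"
        )
    lengths = np.zeros_like(w)
    lengths[off] = 1.0 / w[off]
    return lengths


def weighted_shortest_paths(
    W: ConnectivityMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """All-pairs shortest path distances under edge length 1/w.

    Returns ``(distance_matrix, L, summary)`` where ``L_i`` is the mean
    distance from node i to all other nodes.  Requires strictly positive
    off-diagonal weights (complete SL graph; no disconnected nodes).
    """
    w = _weights(W)
    n = w.shape[0]
    lengths = _length_matrix(w)
    dist = _csgraph_shortest_path(lengths, method="D", directed=False)
    L = dist.sum(axis=1) / (n - 1)
    return dist, L, _summary(L)


def closeness(dist: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    """Closeness centrality cc_i = (N-1) / sum_j d_ij from a distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix must be finite")
    n = dist.shape[0]
    cc = (n - 1) / dist.sum(axis=1)
    return cc, _summary(cc)


def _shortest_path_counts(lengths: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s-t paths, ties within PATH_TIE_TOL."""
    n = lengths.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(dist[s], kind="stable")
        sigma[s, s] = 1.0
        for t in order:
            if t == s:
                continue
            # predecessors u of t on a shortest s-t path
            pred = np.abs(dist[s] + lengths[:, t] - dist[s, t]) <= PATH_TIE_TOL
            pred[t] = False
            sigma[s, t] = sigma[s, pred].sum()
    return sigma


def betweenness(
    W: ConnectivityMatrix | np.ndarray,
) -> tuple[np.ndarray, dict[str, float]]:
    """Weighted betweenness: shortest-path (1/w lengths) transit counts.

    bc_i sums sigma_st(i)/sigma_st over ordered source-target pairs with
    s != t != i, endpoints excluded, unnormalized.  Floating-point ties in
    path length are compared with an absolute tolerance of 1e-12 so that
    genuinely degenerate shortest paths share credit.
    """
    w = _weights(W)
    n = w.shape[0]
    lengths = _length_matrix(w)
    dist = _csgraph_shortest_path(lengths, method="D", directed=False)
    sigma = _shortest_path_counts(lengths, dist)
    bc = np.zeros(n)
    for i in range(n):
        for s in range(n):
            if s == i:
                continue
            on_path = np.abs(dist[s, i] + dist[i] - dist[s]) <= PATH_TIE_TOL
            for t in range(n):
                if t == i or t == s or not on_path[t]:
                    continue
                bc[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    summ = _summary(bc)
    return bc, {"mean": summ["mean"], "max": summ["max"]}


def eigenvector_centrality(
    W: ConnectivityMatrix | np.ndarray,
) -> tuple[np.ndarray, dict[str, float]]:
    """Principal eigenvector of W, oriented nonnegative, unit Euclidean norm.

    For a symmetric nonnegative irreducible weight matrix this is the Perron
    vector; it satisfies ``W ec = lambda ec`` to within 1e-10.
    """
    w = _weights(W)
    vals, vecs = np.linalg.eigh(w)
    lam = vals[-1]
    ec = vecs[:, -1]
    if ec[np.argmax(np.abs(ec))] < 0:
        ec = -ec
    if ec.min() < -1e-8:
        raise ValueError("principal eigenvector not nonnegative; W irreducible?")
    ec = np.clip(ec, 0.0, None)
    ec = ec / np.linalg.norm(ec)
    if np.linalg.norm(w @ ec - lam * ec) > 1e-10 * max(1.0, abs(lam)):
        raise ValueError("eigenvector residual exceeds tolerance")
    return ec, _summary(ec)


def weighted_clustering(
    W: ConnectivityMatrix | np.ndarray, method: str = "onnela"
) -> tuple[np.ndarray, dict[str, float]]:
    """Weighted clustering coefficient per node.

    The default (geometric-mean) form rescales weights by the graph maximum,
    ``ŵ = w / max(w)``, and averages the cube-root triangle intensity::

        C_i = (1 / (k_i (k_i - 1))) * sum_{j != h} (ŵ_ij ŵ_jh ŵ_hi)^{1/3}

    with k_i the number of nonzero-weight neighbours.  Edges of zero weight
    contribute nothing.  ``method="saramaki"`` uses the alternative form that
    averages sqrt(ŵ_ij ŵ_ih) over neighbour pairs closed by any triangle
    edge.  C_i lies in [0, 1] either way.
    """
    w = _weights(W)
    n = w.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n), _summary(np.zeros(n))
    what = w / wmax
    k = (w > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    if method == "onnela":
        A = np.cbrt(what)
        num = np.diag(A @ A @ A)
    elif method == "saramaki":
        closed = (w > 0).astype(float)
        B = np.sqrt(what)
        # diagonals of B and closed are zero, so i/j/h coincidences drop out
        num = np.einsum("ij,jh,hi->i", B, closed, B)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    C = np.divide(num, denom, out=np.zeros(n), where=denom > 0)
    return C, _summary(C)


@dataclass(frozen=True)
class PowerLawFit:
    """Continuous maximum-likelihood power-law fit of a strength sample.

    ``alpha`` is the scaling index of p(d) ~ d^-alpha for d >= d_min;
    ``n_tail`` the number of observations at or above the cutoff.
    """

    alpha: float
    d_min: float
    n_tail: int


def powerlaw_fit(
    strengths: np.ndarray, d_min: float | None = None, scan_xmin: bool = False
) -> PowerLawFit:
    """Fit the power-law scaling index by continuous maximum likelihood.

    alpha = 1 + n / sum(ln(d_i / d_min)) over the tail d_i >= d_min.  By
    default d_min is the smallest strength (with only ~17 nodes per network a
    cutoff scan is unstable); ``scan_xmin=True`` instead selects d_min by
    minimizing the Kolmogorov-Smirnov distance between the tail and the
    fitted law.  All strengths must be positive; an all-equal sample has an
    undefined index and raises a dedicated error.
    """
    d = np.asarray(strengths, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 strengths")
    if np.any(d <= 0):
        raise ValueError("strengths must be strictly positive")
    if np.ptp(d) == 0:
        raise ValueError("all strengths equal: power-law index undefined")

    def _fit_at(dm: float) -> PowerLawFit | None:
        tail = d[d >= dm]
        if tail.size < 2:
            return None
        log_sum = np.log(tail / dm).sum()
        if log_sum <= 0:
            return None
        return PowerLawFit(1.0 + tail.size / log_sum, float(dm), int(tail.size))

    if d_min is not None:
        fit = _fit_at(float(d_min))
        if fit is None:
            raise ValueError("fewer than 2 observations above d_min")
        return fit

    if not scan_xmin:
        fit = _fit_at(float(d.min()))
        if fit is None:
            raise ValueError("degenerate strength sample")
        return fit

    best, best_ks = None, np.inf
    for dm in np.unique(d)[:-1]:
        fit = _fit_at(dm)
        if fit is None:
            continue
        tail = np.sort(d[d >= dm])
        emp = np.arange(1, tail.size + 1) / tail.size
        model = 1.0 - (tail / dm) ** (1.0 - fit.alpha)
        ks = np.max(np.abs(emp - model))
        if ks < best_ks:
            best, best_ks = fit, ks
    if best is None:
        raise ValueError("degenerate strength sample")
    return best


FEATURE_NAMES = (
    "strength_min", "strength_mean", "strength_max",
    "path_min", "path_mean", "path_max",
    "closeness_min", "closeness_mean", "closeness_max",
    "betweenness_mean", "betweenness_max",
    "eigenvector_min", "eigenvector_mean", "eigenvector_max",
    "clustering_min", "clustering_mean", "clustering_max",
    "powerlaw_alpha",
)


@dataclass(frozen=True)
class NetworkFeatureVector:
    """The 18 named scalar network features of one subject, fixed order."""

    strength_min: float
    strength_mean: float
    strength_max: float
    path_min: float
    path_mean: float
    path_max: float
    closeness_min: float
    closeness_mean: float
    closeness_max: float
    betweenness_mean: float
    betweenness_max: float
    eigenvector_min: float
    eigenvector_mean: float
    eigenvector_max: float
    clustering_min: float
    clustering_mean: float
    clustering_max: float
    powerlaw_alpha: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("all features must be finite")
        for fam in ("strength", "path", "closeness", "eigenvector", "clustering"):
            lo = getattr(self, f"{fam}_min")
            mid = getattr(self, f"{fam}_mean")
            hi = getattr(self, f"{fam}_max")
            if not (lo <= mid + 1e-12 and mid <= hi + 1e-12):
                raise ValueError(f"{fam}: min <= mean <= max violated")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def feature_vector(W: ConnectivityMatrix | np.ndarray) -> NetworkFeatureVector:
    """Assemble the 18-feature vector from one subject's SL matrix."""
    s, s_sum = strength(W)
    dist, _L, L_sum = weighted_shortest_paths(W)
    _cc, cc_sum = closeness(dist)
    _bc, bc_sum = betweenness(W)
    _ec, ec_sum = eigenvector_centrality(W)
    _C, C_sum = weighted_clustering(W)
    alpha = powerlaw_fit(s).alpha
    return NetworkFeatureVector(
        strength_min=s_sum["min"], strength_mean=s_sum["mean"],
        strength_max=s_sum["max"],
        path_min=L_sum["min"], path_mean=L_sum["mean"], path_max=L_sum["max"],
        closeness_min=cc_sum["min"], closeness_mean=cc_sum["mean"],
        closeness_max=cc_sum["max"],
        betweenness_mean=bc_sum["mean"], betweenness_max=bc_sum["max"],
        eigenvector_min=ec_sum["min"], eigenvector_mean=ec_sum["mean"],
        eigenvector_max=ec_sum["max"],
        clustering_min=C_sum["min"], clustering_mean=C_sum["mean"],
        clustering_max=C_sum["max"],
        powerlaw_alpha=alpha,
    )
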