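"""Multivariate dynamic-connectome features per subject and band.

Temporal features: fractional occupancy (FO, 1 x K), transition probability
(TP, K x K row-stochastic) and mean dwell time, all computed on the hard
Viterbi path by default (posterior-weighted FO available in soft mode).
Spatial features: Newman modularity of each state's FC matrix under a fixed
intrinsic-connectivity-network (ICN) partition, mean FC within a data-driven
edge cluster per state, and exploratory within/between-ICN block means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IcnPartition",
    "ICN_LABELS",
    "fractional_occupancy",
    "transition_probability",
    "subject_state_fc",
    "state_fc_from_model",
    "modularity_fixed_partition",
    "cluster_fc",
    "icn_pair_fc",
    "extract_subject_features",
    "feature_vector",
]

#: The seven canonical intrinsic connectivity networks.
ICN_LABELS: tuple[str, ...] = (
    "default mode",
    "frontoparietal",
    "dorsal attention",
    "salience/cingulo-opercular",
    "sensory-motor",
    "visual",
    "limbic",
)


@dataclass(frozen=True)
class IcnPartition:
    """Region -> network assignment as a length-R array of network indices."""

    labels: tuple[str, ...]
    assignment: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(a < 0 or a >= len(self.labels) for a in self.assignment):
            raise ValueError("assignment indices must reference partition labels")

    @property
    def n_regions(self) -> int:
        return len(self.assignment)

    @property
    def n_networks(self) -> int:
        return len(self.labels)

    @classmethod
    def from_mapping(cls, mapping: dict, region_order: list) -> "IcnPartition":
        """Build from {region: network-label} for a given region order."""
        missing = [r for r in region_order if r not in mapping]
        if missing:
            raise ValueError(f"partition missing region(s): {missing}")
        labels = tuple(dict.fromkeys(mapping[r] for r in region_order))
        idx = {lab: i for i, lab in enumerate(labels)}
        return cls(labels, tuple(idx[mapping[r]] for r in region_order))

    @classmethod
    def balanced(cls, n_regions: int, n_networks: int = 7) -> "IcnPartition":
        """Round-robin partition of n_regions into the canonical 7 networks."""
        labels = ICN_LABELS[:n_networks]
        return cls(labels, tuple(i % n_networks for i in range(n_regions)))


# ---------------------------------------------------------------------------
# Temporal features
# ---------------------------------------------------------------------------

def fractional_occupancy(path_or_posteriors: np.ndarray, K: int) -> np.ndarray:
    """Proportion of time each state is active.

    Hard mode (1-D integer path): count_k / T.  Soft mode (2-D posterior
    matrix): column means of the posteriors.
    """
    x = np.asarray(path_or_posteriors)
    if x.ndim == 2:
        if x.shape[1] != K:
            raise ValueError("posterior matrix must have K columns")
        return x.mean(axis=0)
    return np.bincount(x.astype(int), minlength=K) / x.size


def transition_probability(path: np.ndarray, K: int) -> np.ndarray:
    """K x K matrix of transition probabilities between consecutive samples.

    tp[i, j] = (# transitions i -> j) / (# departures from i), diagonal
    included.  Rows for states never departed from are set to uniform 1/K so
    the matrix stays row-stochastic (needed for multivariate distances).
    """
    path = np.asarray(path, dtype=int)
    counts = np.zeros((K, K))
    if path.size >= 2:
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
    totals = counts.sum(axis=1)
    tp = np.full((K, K), 1.0 / K)
    visited = totals > 0
    tp[visited] = counts[visited] / totals[visited, None]
    return tp


# ---------------------------------------------------------------------------
# State-wise functional connectivity
# ---------------------------------------------------------------------------

def subject_state_fc(
    envelope, posteriors: np.ndarray, min_weight: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted Pearson correlation per state.

    For state k with weights w = posteriors[:, k], the weighted covariance is
    sum_t w_t (x_t - m)(y_t - m') / sum_t w_t, normalized to a correlation.
    States whose total weight falls below ``min_weight`` effective samples are
    flagged missing (matrix of NaN).

    Returns (fcs: K x R x R, valid: length-K boolean mask).
    """
    x = np.asarray(getattr(envelope, "data", envelope), dtype=float)
    gamma = np.atleast_2d(np.asarray(posteriors, dtype=float))
    if gamma.shape[0] != x.shape[0]:
        raise ValueError("posteriors and envelope must have equal length")
    K = gamma.shape[1]
    R = x.shape[1]
    fcs = np.full((K, R, R), np.nan)
    valid = np.zeros(K, dtype=bool)
    for k in range(K):
        w = gamma[:, k]
        sw = w.sum()
        if sw < min_weight:
            continue
        m = (w @ x) / sw
        d = x - m
        cov = (d.T * w) @ d / sw
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0):
            continue
        fc = cov / np.outer(sd, sd)
        np.fill_diagonal(fc, 1.0)
        fcs[k] = 0.5 * (fc + fc.T)
        valid[k] = True
    return fcs, valid


def state_fc_from_model(model) -> np.ndarray:
    """Correlation matrices implied by each state's covariance."""
    covs = np.asarray(model.covariances if hasattr(model, "covariances") else model)
    K = covs.shape[0]
    fcs = np.empty_like(covs)
    for k in range(K):
        sd = np.sqrt(np.diag(covs[k]))
        fcs[k] = covs[k] / np.outer(sd, sd)
    return fcs


# ---------------------------------------------------------------------------
# Spatial features
# ---------------------------------------------------------------------------

def modularity_fixed_partition(
    fc: np.ndarray, partition: IcnPartition, signed: bool = False
) -> float:
    """Newman modularity Q of a weighted FC graph for a fixed partition.

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j) on the
    non-negative weighted graph with self-loops excluded.  Classic Q is
    defined for non-negative weights, so negative FC edges are zeroed by
    default; ``signed=True`` instead computes Q+ - Q- over the positive and
    negative subgraphs weighted by their strengths.
    """
    a = np.asarray(fc, dtype=float).copy()
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("fc must be a symmetric square matrix")
    if partition.n_regions != a.shape[0]:
        raise ValueError("partition size must match fc")
    np.fill_diagonal(a, 0.0)
    ci = np.asarray(partition.assignment)
    same = ci[:, None] == ci[None, :]

    def _q(w: np.ndarray) -> float:
        two_m = w.sum()
        if two_m == 0:
            return 0.0
        k = w.sum(axis=1)
        return float(((w - np.outer(k, k) / two_m) * same).sum() / two_m)

    pos = np.clip(a, 0.0, None)
    if not signed:
        return _q(pos)
    neg = np.clip(-a, 0.0, None)
    vp, vn = pos.sum(), neg.sum()
    if vp + vn == 0:
        return 0.0
    return float(vp / (vp + vn) * _q(pos) - vn / (vp + vn) * _q(neg))


def cluster_fc(state_fcs: np.ndarray, cluster_mask: np.ndarray) -> np.ndarray:
    """Mean FC over the masked off-diagonal edges, per state (1 x K)."""
    fcs = np.asarray(state_fcs, dtype=float)
    mask = np.asarray(cluster_mask, dtype=bool).copy()
    np.fill_diagonal(mask, False)
    mask |= mask.T
    if not mask.any():
        raise ValueError("cluster mask selects no edges")
    return np.array([fc[mask].mean() for fc in fcs])


def icn_pair_fc(
    state_fcs: np.ndarray, partition: IcnPartition
) -> dict[tuple[str, str], np.ndarray]:
    """Block-mean FC for every ICN pair: within (off-diagonal) and between.

    For 7 networks this yields 21 between-network + 7 within-network entries,
    each a length-K vector of state-wise block means.
    """
    fcs = np.asarray(state_fcs, dtype=float)
    ci = np.asarray(partition.assignment)
    out: dict[tuple[str, str], np.ndarray] = {}
    n = partition.n_networks
    for i in range(n):
        for j in range(i, n):
            sel_i = np.flatnonzero(ci == i)
            sel_j = np.flatnonzero(ci == j)
            mask = np.zeros(fcs.shape[1:], dtype=bool)
            mask[np.ix_(sel_i, sel_j)] = True
            mask[np.ix_(sel_j, sel_i)] = True
            np.fill_diagonal(mask, False)
            key = (partition.labels[i], partition.labels[j])
            if not mask.any():
                out[key] = np.full(fcs.shape[0], np.nan)
            else:
                out[key] = np.array([fc[mask].mean() for fc in fcs])
    return out


def extract_subject_features(
    stcs,
    envelopes,
    K: int,
    partition: IcnPartition | None = None,
    cluster_mask: np.ndarray | None = None,
    mode: str = "hard",
) -> dict[str, np.ndarray]:
    """Per-subject multivariate phenotypes for a fitted, ordered model.

    Returns a dict with keys among 'fo' (n x K), 'tp' (n x K^2),
    'modularity' (n x K) and 'cluster_fc' (n x K); the spatial features are
    only produced when a partition / cluster mask is supplied.  States that a
    subject effectively never visits fall back to the subject's static FC for
    the spatial features.

    ``mode='hard'`` uses the Viterbi path for FO/TP (the default; transitions
    are well-defined on a hard path); ``mode='soft'`` uses posterior-weighted
    fractional occupancy instead.
    """
    if mode not in ("hard", "soft"):
        raise ValueError("mode must be 'hard' or 'soft'")
    n = len(stcs)
    fo = np.empty((n, K))
    tp = np.empty((n, K * K))
    for i, stc in enumerate(stcs):
        src = stc.posteriors if mode == "soft" else stc.path
        fo[i] = fractional_occupancy(src, K)
        tp[i] = transition_probability(stc.path, K).ravel()
    out = {"fo": fo, "tp": tp}

    if partition is None and cluster_mask is None:
        return out
    want_q = partition is not None
    if want_q:
        q = np.empty((n, K))
    if cluster_mask is not None:
        cfc = np.empty((n, K))
    for i, (stc, env) in enumerate(zip(stcs, envelopes)):
        fcs, valid = subject_state_fc(env, stc.posteriors)
        if not valid.all():
            x = np.asarray(getattr(env, "data", env), dtype=float)
            static = np.corrcoef(x.T)
            for k in np.flatnonzero(~valid):
                fcs[k] = static
        if want_q:
            q[i] = [modularity_fixed_partition(fcs[k], partition) for k in range(K)]
        if cluster_mask is not None:
            cfc[i] = cluster_fc(fcs, cluster_mask)
    if want_q:
        out["modularity"] = q
    if cluster_mask is not None:
        out["cluster_fc"] = cfc
    return out


def feature_vector(
    fo: np.ndarray | None = None,
    tp: np.ndarray | None = None,
    modularity: np.ndarray | None = None,
    cfc: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Assemble the per-subject multivariate phenotypes.

    FO is 1 x K; TP enters as the full flattened K^2 vector (diagonal
    included); modularity and cluster-FC are 1 x K each.
    """
    out = {}
    if fo is not None:
        out["fo"] = np.asarray(fo, dtype=float).ravel()
    if tp is not None:
        out["tp"] = np.asarray(tp, dtype=float).ravel()
    if modularity is not None:
        out["modularity"] = np.asarray(modularity, dtype=float).ravel()
    if cfc is not None:
        out["cluster_fc"] = np.asarray(cfc, dtype=float).ravel()
    return out
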