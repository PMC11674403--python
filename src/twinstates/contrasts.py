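"""Cross-state contrasts: edgewise ANCOVAs, density thresholding and NBS.

Connections whose FC differs across states are found by mass-univariate
F tests (factor state, covariates age and sex) on pooled subject x state
observations, thresholded at a target connection density, and corrected for
family-wise error with the network-based statistic (NBS): the null
distribution of the largest connected suprathreshold component under
within-subject permutation of state labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.stats

__all__ = [
    "EdgeStats",
    "NbsResult",
    "FTestResult",
    "edgewise_state_ancova",
    "threshold_by_density",
    "nbs",
    "state_feature_ancova",
]


@dataclass
class EdgeStats:
    """Symmetric matrix of per-edge ANCOVA F statistics for the state factor."""

    f_values: np.ndarray  # R x R, zero diagonal
    df: tuple[int, int]


@dataclass
class FTestResult:
    """One ANCOVA F test with effect size."""

    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float


@dataclass
class NbsResult:
    clusters: list[list[tuple[int, int]]]
    fwer_p: np.ndarray
    n_perm: int
    density: float
    adjacency: np.ndarray = field(repr=False)
    edge_stats: EdgeStats = field(repr=False)
    null_max_size: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Design matrices and pooled F tests
# ---------------------------------------------------------------------------

def _pooled_design(
    n_subjects: int, K: int, ages: np.ndarray, sexes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Full and reduced design matrices on subject x state rows.

    Rows are ordered subject-major (subject 0 states 0..K-1, then subject 1,
    ...).  Full: intercept + K-1 state dummies + centered age + sex indicator;
    reduced drops the state dummies.
    """
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    sex_num = (
        sexes.astype(float)
        if np.issubdtype(sexes.dtype, np.number)
        else (sexes == sexes[0]).astype(float)
    )
    age_c = np.repeat(ages - ages.mean(), K)
    sex_r = np.repeat(sex_num, K)
    n_obs = n_subjects * K
    state = np.tile(np.arange(K), n_subjects)
    dummies = np.zeros((n_obs, K - 1))
    for k in range(1, K):
        dummies[state == k, k - 1] = 1.0
    ones = np.ones(n_obs)
    x_full = np.column_stack([ones, dummies, age_c, sex_r])
    x_red = np.column_stack([ones, age_c, sex_r])
    return x_full, x_red


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of least-squares fit, per column of y."""
    q, _ = np.linalg.qr(x)
    resid = y - q @ (q.T @ y)
    return np.einsum("ij,ij->j", resid, resid)


def _state_f(
    y: np.ndarray, x_full: np.ndarray, x_red: np.ndarray, K: int
) -> tuple[np.ndarray, tuple[int, int], np.ndarray, np.ndarray]:
    """Extra-sum-of-squares F for the state factor, vectorized over columns."""
    n_obs, p_full = x_full.shape
    df1 = K - 1
    df2 = n_obs - p_full
    rss_full = _rss(x_full, y)
    rss_red = _rss(x_red, y)
    ss_state = np.maximum(rss_red - rss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_state / df1) / (rss_full / df2)
    f = np.where(rss_full <= 0, 0.0, f)
    return f, (df1, df2), ss_state, rss_full


def _edge_indices(R: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(R, k=1)


def edgewise_state_ancova(
    subject_state_fc: np.ndarray, ages: np.ndarray, sexes: np.ndarray
) -> EdgeStats:
    """Per-edge ANCOVA of factor state adjusted for age and sex.

    ``subject_state_fc`` has shape (n_subjects, K, R, R); each subject x state
    FC matrix contributes one pooled observation per edge.
    """
    fc = np.asarray(subject_state_fc, dtype=float)
    n_subjects, K, R, _ = fc.shape
    iu, ju = _edge_indices(R)
    y = fc[:, :, iu, ju].reshape(n_subjects * K, -1)
    x_full, x_red = _pooled_design(n_subjects, K, ages, sexes)
    f, df, _, _ = _state_f(y, x_full, x_red, K)
    f_mat = np.zeros((R, R))
    f_mat[iu, ju] = f
    f_mat += f_mat.T
    return EdgeStats(f_mat, df)


def threshold_by_density(f_values: np.ndarray, density: float) -> np.ndarray:
    """Binary adjacency keeping the top round(density * E) edges by F.

    E = R(R-1)/2 over the upper triangle; ties broken deterministically by
    edge index (earlier edges kept first).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    f = np.asarray(f_values, dtype=float)
    R = f.shape[0]
    iu, ju = _edge_indices(R)
    vals = f[iu, ju]
    n_keep = int(round(density * vals.size))
    order = np.lexsort((np.arange(vals.size), -vals))
    keep = order[:n_keep]
    adj = np.zeros((R, R), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    return adj | adj.T


def _components(adj: np.ndarray) -> list[list[tuple[int, int]]]:
    """Connected components of the suprathreshold graph, as edge lists."""
    g = nx.from_numpy_array(np.triu(adj, k=1))
    g.remove_nodes_from(list(nx.isolates(g)))
    comps = []
    for nodes in nx.connected_components(g):
        edges = sorted(tuple(sorted(e)) for e in g.subgraph(nodes).edges)
        comps.append([tuple(map(int, e)) for e in edges])
    comps.sort(key=len, reverse=True)
    return comps


def nbs(
    subject_state_fc: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    density: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> NbsResult:
    """Network-based statistic on cross-state FC differences.

    Observed clusters are connected components of the density-thresholded
    suprathreshold F graph; their family-wise error corrected p values come
    from the permutation null of the maximum component size (in edges), with
    state labels permuted within subject and covariates untouched.
    p = (1 + #{perm max >= observed size}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    fc = np.asarray(subject_state_fc, dtype=float)
    n_subjects, K, R, _ = fc.shape
    iu, ju = _edge_indices(R)
    y = fc[:, :, iu, ju].reshape(n_subjects * K, -1)
    x_full, x_red = _pooled_design(n_subjects, K, ages, sexes)

    f_obs, df, _, _ = _state_f(y, x_full, x_red, K)
    f_mat = np.zeros((R, R))
    f_mat[iu, ju] = f_obs
    f_mat += f_mat.T
    adj = threshold_by_density(f_mat, density)
    clusters = _components(adj)
    sizes = np.array([len(c) for c in clusters], dtype=int)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    y3 = y.reshape(n_subjects, K, -1)
    for b in range(n_perm):
        perm_rows = np.stack([rng.permutation(K) for _ in range(n_subjects)])
        y_perm = np.take_along_axis(y3, perm_rows[:, :, None], axis=1).reshape(
            n_subjects * K, -1
        )
        f_p, _, _, _ = _state_f(y_perm, x_full, x_red, K)
        fp_mat = np.zeros((R, R))
        fp_mat[iu, ju] = f_p
        fp_mat += fp_mat.T
        comps = _components(threshold_by_density(fp_mat, density))
        null_max[b] = len(comps[0]) if comps else 0

    fwer_p = np.array(
        [(1 + np.sum(null_max >= s)) / (1 + n_perm) for s in sizes], dtype=float
    )
    return NbsResult(clusters, fwer_p, n_perm, density, adj, EdgeStats(f_mat, df), null_max)


def state_feature_ancova(
    values: np.ndarray, ages: np.ndarray, sexes: np.ndarray
) -> FTestResult:
    """One-way ANCOVA of factor state on a scalar feature (e.g. Q or FO).

    ``values`` has shape (n_subjects, K); rows pool into subject x state
    observations with covariates age and sex.  Partial eta-squared is
    SS_state / (SS_state + SS_error).
    """
    v = np.asarray(values, dtype=float)
    n_subjects, K = v.shape
    x_full, x_red = _pooled_design(n_subjects, K, ages, sexes)
    f, (df1, df2), ss_state, ss_err = _state_f(v.reshape(-1, 1), x_full, x_red, K)
    f = float(f[0])
    ss_state = float(ss_state[0])
    ss_err = float(ss_err[0])
    p = float(scipy.stats.f.sf(f, df1, df2))
    eta = ss_state / (ss_state + ss_err) if (ss_state + ss_err) > 0 else 0.0
    return FTestResult(f, df1, df2, p, eta, ss_state, ss_err)
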