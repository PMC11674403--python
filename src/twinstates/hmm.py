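"""K-state Gaussian-observation hidden Markov model of connectome states.

Each state is characterized by a mean activation vector and a full
amplitude-coupling covariance over regions.  Band-specific envelopes are
z-scored per subject and concatenated over subjects; chains restart at
subject boundaries so transitions never cross subjects.  Inference is
expectation-maximization (Baum-Welch) with scaled forward-backward, with
k-means initialization and multiple restarts; decoding is Viterbi.

State labels from any single fit are arbitrary, so fitted models are
re-ordered canonically by descending group fractional occupancy before
features are extracted (``order_states``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GaussianHMM",
    "StateTimeCourse",
    "standardize_concatenate",
    "fit_hmm",
    "forward_backward",
    "viterbi",
    "order_states",
    "dwell_times",
]

_RIDGE_FRAC = 1e-6  # covariance ridge: _RIDGE_FRAC * trace/R on conditioning failure


@dataclass
class GaussianHMM:
    """Gaussian-emission HMM: per-state mean, covariance, transitions, initial."""

    means: np.ndarray  # K x R
    covariances: np.ndarray  # K x R x R
    transition: np.ndarray  # K x K, row-stochastic
    initial: np.ndarray  # K

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.initial = np.asarray(self.initial, dtype=float)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_regions(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        K, R = self.means.shape
        if self.covariances.shape != (K, R, R):
            raise ValueError("covariances must be K x R x R")
        if self.transition.shape != (K, K):
            raise ValueError("transition must be K x K")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.transition < 0):
            raise ValueError("transition entries must be non-negative")
        if abs(self.initial.sum() - 1.0) > 1e-10 or np.any(self.initial < 0):
            raise ValueError("initial must be a probability vector")
        for k in range(K):
            cov = self.covariances[k]
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"covariance {k} not symmetric")
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ValueError(f"covariance {k} not positive-definite")

    def permuted(self, perm: np.ndarray) -> "GaussianHMM":
        """Relabel states by permutation: new state i is old state perm[i]."""
        perm = np.asarray(perm)
        return GaussianHMM(
            means=self.means[perm],
            covariances=self.covariances[perm],
            transition=self.transition[np.ix_(perm, perm)],
            initial=self.initial[perm],
        )


@dataclass
class StateTimeCourse:
    """Posterior state probabilities and decoded path for one subject."""

    posteriors: np.ndarray  # T x K
    path: np.ndarray  # T, values in 0..K-1
    loglik: float

    def permuted(self, perm: np.ndarray) -> "StateTimeCourse":
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return StateTimeCourse(self.posteriors[:, perm], inv[self.path], self.loglik)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def standardize_concatenate(envelopes) -> tuple[np.ndarray, list[int]]:
    """Z-score each subject's each region, then stack over subjects.

    Returns the stacked matrix and the boundary index list
    [0, T1, T1+T2, ...]; chains restart at each boundary.
    """
    mats = []
    boundaries = [0]
    n_regions = None
    for env in envelopes:
        x = np.asarray(getattr(env, "data", env), dtype=float)
        if n_regions is None:
            n_regions = x.shape[1]
        elif x.shape[1] != n_regions:
            raise ValueError("all subjects must share the same region count")
        sd = x.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)
            raise ValueError(f"zero-variance region(s) {bad.tolist()}: cannot z-score")
        mats.append((x - x.mean(axis=0)) / sd)
        boundaries.append(boundaries[-1] + x.shape[0])
    return np.vstack(mats), boundaries


# ---------------------------------------------------------------------------
# Emission log-densities
# ---------------------------------------------------------------------------

def _log_emissions(model: GaussianHMM, x: np.ndarray) -> np.ndarray:
    """T x K matrix of per-state Gaussian log-densities."""
    T = x.shape[0]
    K, R = model.means.shape
    logb = np.empty((T, K))
    for k in range(K):
        cov = model.covariances[k]
        chol = np.linalg.cholesky(cov)
        diff = x - model.means[k]
        sol = np.linalg.solve(chol, diff.T)
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        logb[:, k] = -0.5 * (maha + logdet + R * np.log(2.0 * np.pi))
    return logb


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _forward_backward_logb(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """Scaled forward-backward given emission log-densities.

    Returns (gamma, loglik, xi_sum) where xi_sum[i, j] is the expected count
    of i -> j transitions.
    """
    T, K = logb.shape
    offset = logb.max(axis=1)
    b = np.exp(logb - offset[:, None])

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = initial * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.sum(np.log(c)) + np.sum(offset))

    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (transition @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * transition
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, loglik, xi_sum


def _forward_backward_batch(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward for a batch of equal-length chains.

    ``logb`` has shape (S, T, K); the time recursion is vectorized across the
    S independent chains.  Returns (gamma (S,T,K), loglik (S,), xi_sum (K,K)
    summed over all chains).
    """
    S, T, K = logb.shape
    offset = logb.max(axis=2)
    b = np.exp(logb - offset[:, :, None])

    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = initial[None, :] * b[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ transition) * b[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    loglik = np.log(c).sum(axis=1) + offset.sum(axis=1)

    beta = np.ones((S, K))
    gamma = np.empty((S, T, K))
    gamma[:, -1] = alpha[:, -1]
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = b[:, t + 1] * beta
        xi_sum += (alpha[:, t].T @ (bb / c[:, t + 1, None])) * transition
        beta = (bb @ transition.T) / c[:, t + 1, None]
        g = alpha[:, t] * beta
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)
    return gamma, loglik, xi_sum


def _viterbi_batch(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> np.ndarray:
    """Log-domain Viterbi for a batch of equal-length chains: (S, T) paths."""
    S, T, K = logb.shape
    with np.errstate(divide="ignore"):
        logp = np.log(transition)
        logpi = np.log(initial)
    delta = logpi[None, :] + logb[:, 0]
    back = np.empty((S, T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, :, None] + logp[None, :, :]
        back[:, t] = np.argmax(cand, axis=1)
        delta = np.take_along_axis(cand, back[:, t][:, None, :], axis=1)[:, 0, :] + logb[:, t]
    paths = np.empty((S, T), dtype=np.intp)
    paths[:, -1] = np.argmax(delta, axis=1)
    rows = np.arange(S)
    for t in range(T - 2, -1, -1):
        paths[:, t] = back[rows, t + 1, paths[:, t + 1]]
    return paths


def forward_backward(model: GaussianHMM, series: np.ndarray) -> StateTimeCourse:
    """Posterior state probabilities, Viterbi path and exact log-likelihood."""
    x = np.atleast_2d(np.asarray(series, dtype=float))
    if x.shape[1] != model.n_regions:
        raise ValueError("series column count must equal the model's region count")
    logb = _log_emissions(model, x)
    gamma, loglik, _ = _forward_backward_logb(logb, model.transition, model.initial)
    path = _viterbi_logb(logb, model.transition, model.initial)
    return StateTimeCourse(gamma, path, loglik)


def _viterbi_logb(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> np.ndarray:
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        logp = np.log(transition)
        logpi = np.log(initial)
    delta = logpi + logb[0]
    back = np.empty((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + logp
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def viterbi(model: GaussianHMM, series: np.ndarray) -> np.ndarray:
    """Most probable state path (log-domain max-product decoding)."""
    x = np.atleast_2d(np.asarray(series, dtype=float))
    logb = _log_emissions(model, x)
    return _viterbi_logb(logb, model.transition, model.initial)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _kmeans_init(
    x: np.ndarray, K: int, rng: np.random.Generator, subsample: int = 20_000
) -> GaussianHMM:
    from sklearn.cluster import KMeans

    T, R = x.shape
    idx = rng.permutation(T)[: min(T, subsample)]
    km = KMeans(
        n_clusters=K,
        n_init=3,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(x[idx])
    means = km.cluster_centers_
    covs = np.empty((K, R, R))
    global_cov = np.cov(x[idx].T).reshape(R, R)
    for k in range(K):
        sel = x[idx][km.labels_ == k]
        if len(sel) > R + 1:
            covs[k] = np.cov(sel.T).reshape(R, R)
        else:
            covs[k] = global_cov.copy()
        covs[k] += _RIDGE_FRAC * np.trace(covs[k]) / R * np.eye(R) + 1e-8 * np.eye(R)
    transition = np.full((K, K), 0.2 / max(K - 1, 1)) + np.eye(K) * (0.8 - 0.2 / max(K - 1, 1))
    transition /= transition.sum(axis=1, keepdims=True)
    return GaussianHMM(means, covs, transition, np.full(K, 1.0 / K))


def _regularize_cov(cov: np.ndarray) -> np.ndarray:
    R = cov.shape[0]
    cov = 0.5 * (cov + cov.T)
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        pass
    cov = cov + _RIDGE_FRAC * max(np.trace(cov), 1.0) / R * np.eye(R)
    for _ in range(8):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            cov = cov + 10 * _RIDGE_FRAC * max(np.trace(cov), 1.0) / R * np.eye(R)
    raise np.linalg.LinAlgError("covariance remained singular after ridge regularization")


def _em_once(
    x: np.ndarray,
    boundaries: list[int],
    init: GaussianHMM,
    tol: float,
    max_iter: int,
) -> tuple[GaussianHMM, float, list[float]]:
    model = init
    K, R = init.means.shape
    prev_ll = -np.inf
    history: list[float] = []
    segs = list(zip(boundaries[:-1], boundaries[1:]))
    lengths = {e - s for s, e in segs}
    equal_len = len(lengths) == 1
    for _ in range(max_iter):
        logb_all = _log_emissions(model, x)
        if equal_len:
            T_seg = lengths and next(iter(lengths))
            logb3 = logb_all.reshape(len(segs), T_seg, K)
            gamma3, lls, xi_sum = _forward_backward_batch(
                logb3, model.transition, model.initial
            )
            gamma_all = gamma3.reshape(-1, K)
            init_sum = gamma3[:, 0, :].sum(axis=0)
            ll = float(lls.sum())
        else:
            gamma_all = np.empty((x.shape[0], K))
            xi_sum = np.zeros((K, K))
            init_sum = np.zeros(K)
            ll = 0.0
            for s, e in segs:
                gamma, l, xi = _forward_backward_logb(
                    logb_all[s:e], model.transition, model.initial
                )
                gamma_all[s:e] = gamma
                xi_sum += xi
                init_sum += gamma[0]
                ll += l
        # M-step
        w = gamma_all.sum(axis=0)
        means = (gamma_all.T @ x) / w[:, None]
        covs = np.empty((K, R, R))
        for k in range(K):
            diff = x - means[k]
            covs[k] = _regularize_cov((diff.T * gamma_all[:, k]) @ diff / w[k])
        transition = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        zero_rows = xi_sum.sum(axis=1) == 0
        transition[zero_rows] = 1.0 / K
        initial = init_sum / init_sum.sum()
        model = GaussianHMM(means, covs, transition, initial)
        history.append(ll)
        if np.isfinite(prev_ll) and ll - prev_ll < tol * max(abs(prev_ll), 1.0):
            prev_ll = ll
            break
        prev_ll = ll
    return model, prev_ll, history


def fit_hmm(
    stacked: np.ndarray,
    boundaries: list[int],
    K: int,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[GaussianHMM, list[StateTimeCourse]]:
    """Fit by EM with restarts; return the canonically ordered best model.

    The best of ``n_restarts`` runs (by final log-likelihood) is kept, states
    are re-ordered by descending group fractional occupancy, and per-subject
    state time courses are decoded under the final model.
    """
    x = np.asarray(stacked, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("stacked data must be finite")
    if boundaries[0] != 0 or boundaries[-1] != x.shape[0]:
        raise ValueError("boundaries must start at 0 and end at the total length")

    if K == 1:
        R = x.shape[1]
        cov = _regularize_cov(np.cov(x.T).reshape(R, R))
        model = GaussianHMM(
            x.mean(axis=0)[None, :], cov[None], np.ones((1, 1)), np.ones(1)
        )
        stcs = [
            forward_backward(model, x[s:e])
            for s, e in zip(boundaries[:-1], boundaries[1:])
        ]
        return model, stcs

    ss = np.random.SeedSequence(seed)
    best_model, best_ll = None, -np.inf
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        init = _kmeans_init(x, K, rng)
        model, ll, _ = _em_once(x, boundaries, init, tol, max_iter)
        if ll > best_ll:
            best_model, best_ll = model, ll

    stcs = _decode_segments(best_model, x, boundaries)
    best_model, stcs, _ = order_states(best_model, stcs)
    return best_model, stcs


def _decode_segments(
    model: GaussianHMM, x: np.ndarray, boundaries: list[int]
) -> list[StateTimeCourse]:
    segs = list(zip(boundaries[:-1], boundaries[1:]))
    lengths = {e - s for s, e in segs}
    if len(lengths) == 1:
        T_seg = next(iter(lengths))
        K = model.n_states
        logb3 = _log_emissions(model, x).reshape(len(segs), T_seg, K)
        gamma3, lls, _ = _forward_backward_batch(logb3, model.transition, model.initial)
        paths = _viterbi_batch(logb3, model.transition, model.initial)
        return [
            StateTimeCourse(gamma3[i], paths[i], float(lls[i]))
            for i in range(len(segs))
        ]
    return [forward_backward(model, x[s:e]) for s, e in segs]


# ---------------------------------------------------------------------------
# Canonical state ordering and dwell times
# ---------------------------------------------------------------------------

def order_states(
    model: GaussianHMM, stcs: list[StateTimeCourse]
) -> tuple[GaussianHMM, list[StateTimeCourse], np.ndarray]:
    """Relabel states by descending group fractional occupancy.

    Ties are broken by earliest first activation (first time the state is the
    posterior argmax over the concatenated recording).  Returns the permuted
    model, permuted state time courses, and the permutation applied
    (new label i corresponds to old label perm[i]).
    """
    gamma = np.vstack([s.posteriors for s in stcs])
    fo = gamma.mean(axis=0)
    argmax = gamma.argmax(axis=1)
    K = model.n_states
    first = np.full(K, gamma.shape[0], dtype=float)
    for k in range(K):
        hits = np.flatnonzero(argmax == k)
        if hits.size:
            first[k] = hits[0]
    perm = np.lexsort((first, -fo))
    return model.permuted(perm), [s.permuted(perm) for s in stcs], perm


def dwell_times(path: np.ndarray, fs: float, K: int) -> np.ndarray:
    """Mean dwell time per state in milliseconds (NaN for unvisited states).

    A dwell is one maximal run of consecutive samples in the same state.
    """
    path = np.asarray(path)
    out = np.full(K, np.nan)
    if path.size == 0:
        return out
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [path.size]))
    lengths = ends - starts
    labels = path[starts]
    for k in range(K):
        sel = lengths[labels == k]
        if sel.size:
            out[k] = sel.mean() * 1000.0 / fs
    return out
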