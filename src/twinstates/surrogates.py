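"""Dynamics-free surrogate data and the null origin of each feature space.

Surrogates preserve each subject's static (time-averaged) mean and
covariance while destroying temporal state structure: they are i.i.d.
Gaussian draws of the same length as the empirical series.  Refitting the
HMM on each surrogate dataset and re-extracting the dynamic features gives
samples of where a dynamics-free dataset lands in feature space; their mean
is the null origin against which empirical subjects' multivariate
phenotypes are referenced (as Euclidean distances) for variance-component
modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import IcnPartition, extract_subject_features
from .hmm import fit_hmm, standardize_concatenate
from .preprocess import EnvelopeTimeSeries

__all__ = ["NullOrigin", "generate_surrogate", "compute_null_origin"]

logger = logging.getLogger(__name__)


@dataclass
class NullOrigin:
    """Mean feature vector over surrogate datasets, per feature."""

    feature: str
    band: str
    origin: np.ndarray
    n_surrogates: int


def generate_surrogate(
    envelopes: dict[str, EnvelopeTimeSeries], seed: int
) -> dict[str, EnvelopeTimeSeries]:
    """Static-moment-preserving, dynamics-free surrogate envelopes.

    Per subject: i.i.d. Gaussian samples with the subject's empirical mean
    vector and covariance matrix, of the same length as the original series
    (clipped at zero to stay in envelope space).
    """
    ss = np.random.SeedSequence(seed)
    out: dict[str, EnvelopeTimeSeries] = {}
    for child, (sid, env) in zip(ss.spawn(len(envelopes)), sorted(envelopes.items())):
        rng = np.random.default_rng(child)
        x = env.data
        mean = x.mean(axis=0)
        cov = np.cov(x.T).reshape(x.shape[1], x.shape[1])
        sur = rng.multivariate_normal(mean, cov, size=x.shape[0], method="cholesky")
        out[sid] = EnvelopeTimeSeries(sid, env.band, np.clip(sur, 0.0, None), env.fs)
    return out


def compute_null_origin(
    envelopes: dict[str, EnvelopeTimeSeries],
    K: int,
    n_surrogates: int = 50,
    seed: int = 0,
    partition: IcnPartition | None = None,
    cluster_mask: np.ndarray | None = None,
    subject_level: bool = False,
    n_restarts: int = 2,
    max_iter: int = 100,
    mode: str = "hard",
) -> dict[str, NullOrigin]:
    """Null origin of each feature space from repeated surrogate refits.

    For each of ``n_surrogates`` replicates: generate surrogate envelopes for
    every subject, refit the K-state HMM (states canonically ordered),
    extract per-subject features, and average over subjects to one group
    feature vector.  The origin is the mean of these group vectors over
    surrogates (``subject_level=True`` instead stacks subject-level vectors
    before averaging, which yields the same mean but is exposed for
    completeness of convention).

    A replicate whose HMM fit fails is dropped with a logged warning; the
    origin averages the remainder.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    band = next(iter(envelopes.values())).band.name
    ss = np.random.SeedSequence([seed, 0x5094])
    reps: dict[str, list[np.ndarray]] = {}
    n_ok = 0
    for r, child in enumerate(ss.spawn(n_surrogates)):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        sur = generate_surrogate(envelopes, seed=child_seed)
        order = sorted(sur)
        try:
            stacked, bounds = standardize_concatenate([sur[s] for s in order])
            model, stcs = fit_hmm(
                stacked,
                bounds,
                K,
                n_restarts=n_restarts,
                seed=child_seed,
                max_iter=max_iter,
            )
            feats = extract_subject_features(
                stcs,
                [sur[s] for s in order],
                K,
                partition=partition,
                cluster_mask=cluster_mask,
                mode=mode,
            )
        except Exception as exc:  # noqa: BLE001 - any failed refit is dropped
            logger.warning("surrogate %d dropped: %s", r, exc)
            continue
        n_ok += 1
        for name, mat in feats.items():
            vec = mat if subject_level else mat.mean(axis=0, keepdims=True)
            reps.setdefault(name, []).append(vec)
    if n_ok == 0:
        raise RuntimeError("all surrogate HMM fits failed")
    return {
        name: NullOrigin(name, band, np.vstack(vs).mean(axis=0), n_ok)
        for name, vs in reps.items()
    }
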