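"""Synthetic twin cohorts of state-switching envelope data with known truth.

The generator emulates the study design that the downstream pipeline targets:
R ~ 54 regions, K recurrent connectome states (each a mean-activation vector
plus an amplitude-coupling covariance), subject-specific Markov switching at
subsecond dwell times, and MZ / DZ / unrelated pairs whose state-dynamics
parameters carry a specified additive-genetic / shared-environment (or
dominance) / unique-environment decomposition.

Heritability enters through a latent phenotype per subject (one latent per
transition-matrix row) built from A/C/D/E components with the classic twin
correlations (A: 1 MZ, 0.5 DZ, 0 unrelated; D: 1, 0.25, 0; C: 1, 1, 0).
Latents perturb the base transition logits, so transition probabilities (and
hence fractional occupancy) are heritable while the spatial state parameters
are shared across subjects by default.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import GaussianHMM
from .preprocess import CANONICAL_BANDS, BandDefinition, EnvelopeTimeSeries

__all__ = [
    "AceSpec",
    "CohortConfig",
    "GroundTruth",
    "ZYGOSITY_CORRELATIONS",
    "sample_ace_latents",
    "phenotype_to_dynamics",
    "simulate_subject",
    "generate_cohort",
    "default_base_model",
]

#: (rA, rC, rD) within-pair correlations of the A, C and D components.
ZYGOSITY_CORRELATIONS: dict[str, tuple[float, float, float]] = {
    "MZ": (1.0, 1.0, 1.0),
    "DZ": (0.5, 1.0, 0.25),
    "UR": (0.0, 0.0, 0.0),
}

#: Constant added to Gaussian draws so simulated envelopes are non-negative.
ENVELOPE_OFFSET = 8.0


@dataclass(frozen=True)
class AceSpec:
    """Variance fractions of the latent phenotype: A + C (or D) + E = 1."""

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "d2", "e2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.a2 + self.c2 + self.d2 + self.e2 - 1.0) > 1e-8:
            raise ValueError("variance fractions must sum to 1")
        if self.c2 > 0 and self.d2 > 0:
            raise ValueError("C and D cannot both be non-zero (ACE or ADE, never both)")

    def pair_correlation(self, zygosity: str) -> float:
        """Expected within-pair correlation of the latent for a zygosity class."""
        ra, rc, rd = ZYGOSITY_CORRELATIONS[zygosity]
        return self.a2 * ra + self.c2 * rc + self.d2 * rd


@dataclass
class CohortConfig:
    """Sizes, sampling rate and duration of a simulated twin cohort.

    Defaults mirror the target study design: 206 MZ + 112 DZ + 145 unrelated
    sex-matched pairs, 54 regions, 6 states, envelopes at 40 samples/s.
    """

    n_mz_pairs: int = 206
    n_dz_pairs: int = 112
    n_ur_pairs: int = 145
    n_regions: int = 54
    n_states: int = 6
    fs: float = 40.0
    duration_s: float = 150.0
    bands: tuple[BandDefinition, ...] = (CANONICAL_BANDS[2],)  # alpha
    seed: int = 0
    effect_scale: float = 1.0
    spatial_heritable: bool = False
    spatial_effect_scale: float = 0.0
    age_mismatch_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_ur_pairs", "n_regions", "n_states"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s * self.fs < 10 * self.n_states:
            raise ValueError("duration too short: need duration_s * fs >= 10 * n_states")

    @property
    def n_pairs(self) -> int:
        return self.n_mz_pairs + self.n_dz_pairs + self.n_ur_pairs

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_pairs

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    """Simulation truth kept alongside a generated cohort for recovery tests."""

    base_model: GaussianHMM
    subject_transitions: dict[str, np.ndarray]
    true_paths: dict[str, dict[str, np.ndarray]]  # band -> subject -> path
    latent_phenotypes: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Latent heritable phenotypes
# ---------------------------------------------------------------------------

def sample_ace_latents(
    spec: AceSpec,
    pair_counts: tuple[int, int, int],
    n_latents: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-subject latent vectors with twin-structured correlations.

    Each latent dimension is an independent sum of A, C, D and E components
    weighted by the square roots of the variance fractions; components are
    shared within a pair according to the zygosity correlations, so each
    latent has unit variance and within-pair correlation
    a2*rA + c2*rC + d2*rD.

    Returns (latents, zygosity) where latents has shape
    (n_pairs, 2, n_latents) and zygosity is a length n_pairs array of
    'MZ' / 'DZ' / 'UR' labels (MZ first, then DZ, then UR).
    """
    n_mz, n_dz, n_ur = pair_counts
    rng = np.random.default_rng(seed)
    zygosity = np.repeat(["MZ", "DZ", "UR"], [n_mz, n_dz, n_ur])
    n_pairs = len(zygosity)
    latents = np.empty((n_pairs, 2, n_latents))
    weights = np.sqrt([spec.a2, spec.c2, spec.d2])
    e_weight = np.sqrt(spec.e2)
    for p, zyg in enumerate(zygosity):
        rs = ZYGOSITY_CORRELATIONS[zyg]
        pair = np.zeros((2, n_latents))
        for w, r in zip(weights, rs):
            if w == 0:
                continue
            shared = rng.standard_normal(n_latents)
            unique = rng.standard_normal((2, n_latents))
            pair += w * (np.sqrt(r) * shared + np.sqrt(1.0 - r) * unique)
        pair += e_weight * rng.standard_normal((2, n_latents))
        latents[p] = pair
    return latents, zygosity


def _row_directions(K: int) -> np.ndarray:
    """Fixed zero-sum unit direction per transition-matrix row.

    Row k pushes probability toward state (k+1) mod K and away from the
    rest; deterministic so that identical latents give identical dynamics.
    """
    dirs = np.full((K, K), -1.0 / max(K - 1, 1))
    for k in range(K):
        dirs[k, (k + 1) % K] = 1.0
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs


def phenotype_to_dynamics(
    latent: np.ndarray, base_model: GaussianHMM, effect_scale: float
) -> np.ndarray:
    """Map a length-K latent vector to a subject-specific transition matrix.

    Row k of the base transition logits is perturbed by
    effect_scale * latent[k] * u_k for a fixed zero-sum direction u_k, then
    passed through a row-wise softmax.  Each u_k is normalized by the local
    softmax Jacobian at the base row, so one unit of latent moves every row
    by roughly effect_scale in transition-probability space regardless of
    how sticky that row is.  effect_scale = 0 reproduces the base transition
    matrix exactly.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be >= 0")
    base_model.validate()
    K = base_model.n_states
    latent = np.asarray(latent, dtype=float)
    if latent.shape != (K,):
        raise ValueError(f"latent must have shape ({K},)")
    with np.errstate(divide="ignore"):
        logits = np.log(np.maximum(base_model.transition, 1e-300))
    dirs = _row_directions(K)
    if K > 1:
        p = base_model.transition
        # per-row probability-space gain of the logit direction
        jac_gain = np.array(
            [
                np.linalg.norm((np.diag(p[k]) - np.outer(p[k], p[k])) @ dirs[k])
                for k in range(K)
            ]
        )
        dirs = dirs / np.maximum(jac_gain, 1e-12)[:, None]
    logits = logits + effect_scale * latent[:, None] * dirs
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _sample_markov_path(
    transition: np.ndarray, T: int, rng: np.random.Generator, start_state: int | None,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    K = transition.shape[0]
    cum = np.cumsum(transition, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=np.intp)
    if start_state is not None:
        path[0] = start_state
    else:
        pi = np.full(K, 1.0 / K) if initial is None else initial
        path[0] = np.searchsorted(np.cumsum(pi), u[0], side="right")
    for t in range(1, T):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t], side="right")
    np.clip(path, 0, K - 1, out=path)
    return path


def simulate_subject(
    transition: np.ndarray,
    model: GaussianHMM,
    T: int,
    seed: int | np.random.SeedSequence,
    start_state: int | None = None,
    subject_id: str = "sim",
    band: BandDefinition = CANONICAL_BANDS[2],
    fs: float = 40.0,
    offset: float = ENVELOPE_OFFSET,
) -> tuple[EnvelopeTimeSeries, np.ndarray]:
    """Simulate one subject: Markov state path + state-conditional Gaussian draws.

    Envelopes are generated directly in envelope space: Gaussian draws under
    the state's mean/covariance, shifted by a constant so values are
    non-negative (any residual negatives are clipped; z-scoring downstream
    removes the shift).
    """
    transition = np.asarray(transition, dtype=float)
    if np.any(transition < 0) or np.any(np.abs(transition.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("transition rows must be non-negative and sum to 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    path = _sample_markov_path(transition, T, rng, start_state, model.initial)
    R = model.n_regions
    obs = np.empty((T, R))
    z = rng.standard_normal((T, R))
    for k in range(model.n_states):
        sel = path == k
        if not np.any(sel):
            continue
        chol = np.linalg.cholesky(model.covariances[k])
        obs[sel] = model.means[k] + z[sel] @ chol.T
    env = np.clip(obs + offset, 0.0, None)
    return EnvelopeTimeSeries(subject_id, band, env, fs=fs), path


def default_base_model(
    K: int = 6,
    R: int = 54,
    seed: int = 0,
    stickiness: float = 0.9,
    mean_scale: float = 2.0,
) -> GaussianHMM:
    """A well-separated K-state base model for simulation.

    State means are random unit directions scaled by ``mean_scale``;
    covariances are distinct random SPD matrices with unit-order variances;
    the transition matrix is sticky with self-probability ``stickiness``
    (0.9 at 40 samples/s gives a 250 ms mean dwell, i.e. subsecond dynamics).
    """
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((K, R))
    means *= mean_scale / np.linalg.norm(means, axis=1, keepdims=True) * np.sqrt(R)
    covs = np.empty((K, R, R))
    for k in range(K):
        w = rng.standard_normal((R, R + 4)) / np.sqrt(R + 4)
        c = w @ w.T
        d = np.sqrt(np.diag(c))
        covs[k] = c / np.outer(d, d) + 0.05 * np.eye(R)
    transition = np.full((K, K), (1.0 - stickiness) / max(K - 1, 1))
    np.fill_diagonal(transition, stickiness if K > 1 else 1.0)
    transition /= transition.sum(axis=1, keepdims=True)
    return GaussianHMM(means, covs, transition, np.full(K, 1.0 / K))


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _subject_seed(global_seed: int, subject_id: str, band: str) -> np.random.SeedSequence:
    """Stable per-subject substream independent of iteration order."""
    h = zlib.crc32(f"{subject_id}/{band}".encode())
    return np.random.SeedSequence([global_seed, h])


def generate_cohort(
    config: CohortConfig,
    spec: AceSpec,
    base_model: GaussianHMM | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, EnvelopeTimeSeries]], GroundTruth]:
    """Generate a full twin cohort with known ground truth.

    Returns (manifest, envelopes, truth):

    - manifest: one row per subject with subject_id, pair_id, zygosity, sex,
      age; pairs are sex-matched and (by default) age-matched within 1 year.
    - envelopes: band name -> subject_id -> EnvelopeTimeSeries.
    - truth: base model, per-subject transition matrices, true state paths
      and latent phenotypes.
    """
    if base_model is None:
        base_model = default_base_model(config.n_states, config.n_regions, seed=config.seed)
    base_model.validate()
    K = config.n_states
    if base_model.n_states != K or base_model.n_regions != config.n_regions:
        raise ValueError("base_model shape does not match config")

    latents, zygosity = sample_ace_latents(
        spec,
        (config.n_mz_pairs, config.n_dz_pairs, config.n_ur_pairs),
        n_latents=K,
        seed=config.seed,
    )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))
    rows = []
    subject_ids: list[tuple[str, np.ndarray]] = []
    for p in range(config.n_pairs):
        pair_id = f"P{p + 1:04d}"
        sex = "F" if rng.random() < 0.5 else "M"
        base_age = rng.uniform(23.0, 39.0)
        ages = base_age + rng.uniform(0.0, 1.0, size=2)
        if rng.random() < config.age_mismatch_fraction:
            ages[1] = rng.uniform(23.0, 40.0)
        for m in range(2):
            sid = f"{pair_id}{'ab'[m]}"
            rows.append(
                {
                    "subject_id": sid,
                    "pair_id": pair_id,
                    "zygosity": zygosity[p],
                    "sex": sex,
                    "age": round(float(ages[m]), 2),
                }
            )
            subject_ids.append((sid, latents[p, m]))
    manifest = pd.DataFrame(rows)

    transitions: dict[str, np.ndarray] = {}
    latent_map: dict[str, np.ndarray] = {}
    spatial_dirs = None
    if config.spatial_heritable and config.spatial_effect_scale > 0:
        dir_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
        spatial_dirs = dir_rng.standard_normal((K, config.n_regions))
        spatial_dirs /= np.linalg.norm(spatial_dirs, axis=1, keepdims=True)

    envelopes: dict[str, dict[str, EnvelopeTimeSeries]] = {b.name: {} for b in config.bands}
    true_paths: dict[str, dict[str, np.ndarray]] = {b.name: {} for b in config.bands}
    T = config.n_samples
    for sid, latent in subject_ids:
        transitions[sid] = phenotype_to_dynamics(latent, base_model, config.effect_scale)
        latent_map[sid] = latent
        subj_model = base_model
        if spatial_dirs is not None:
            means = base_model.means + config.spatial_effect_scale * latent[:, None] * spatial_dirs
            subj_model = GaussianHMM(
                means, base_model.covariances, base_model.transition, base_model.initial
            )
        for band in config.bands:
            env, path = simulate_subject(
                transitions[sid],
                subj_model,
                T,
                seed=_subject_seed(config.seed, sid, band.name),
                subject_id=sid,
                band=band,
                fs=config.fs,
            )
            envelopes[band.name][sid] = env
            true_paths[band.name][sid] = path

    truth = GroundTruth(base_model, transitions, true_paths, latent_map)
    return manifest, envelopes, truth
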