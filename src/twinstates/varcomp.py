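"""Maximum-likelihood twin variance-component (ACE/ADE) models.

The phenotype is a per-subject scalar (here: Euclidean distance of the
multivariate dynamic-connectome feature from its null origin), residualized
for age and sex and standardized.  Each pair contributes a bivariate-normal
likelihood whose within-pair covariance is structured by zygosity:

    cov = sigma2_A * rA + sigma2_C * rC + sigma2_D * rD

with (rA, rC, rD) = (1, 1, 1) for MZ, (0.5, 1, 0.25) for DZ and (0, 0, 0)
for unrelated pairs (reared in different families).  Full models are ACE or
ADE (never both C and D); nested AE / CE / DE models are compared by
likelihood-ratio tests and AIC.  Narrow-sense heritability
h2 = sigma2_A / total; broad-sense H2 = (sigma2_A + sigma2_D) / total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

__all__ = [
    "VarianceComponentFit",
    "LrtResult",
    "ModelSelection",
    "residualize",
    "fit_twin_model",
    "lrt",
    "model_selection",
    "twin_correlations",
]

#: (rA, rC, rD) genetic/environmental correlations by zygosity.
_RELATEDNESS = {"MZ": (1.0, 1.0, 1.0), "DZ": (0.5, 1.0, 0.25), "UR": (0.0, 0.0, 0.0)}

#: Which variance components each model structure estimates.
_STRUCTURES: dict[str, tuple[str, ...]] = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "DE": ("d", "e"),
    "E": ("e",),
}


@dataclass
class VarianceComponentFit:
    structure: str
    var_a: float
    var_c: float
    var_d: float
    var_e: float
    h2: float
    H2: float
    ci: dict[str, tuple[float, float]]
    minus2ll: float
    aic: float
    n_params: int
    raw_variances: dict[str, float] = field(default_factory=dict)

    @property
    def heritability(self) -> float:
        """h2 for ACE-family structures, H2 for ADE-family ones."""
        return self.H2 if "d" in _STRUCTURES[self.structure] else self.h2

    @property
    def heritability_ci(self) -> tuple[float, float]:
        key = "H2" if "d" in _STRUCTURES[self.structure] else "h2"
        return self.ci[key]


@dataclass
class LrtResult:
    chi: float
    delta_df: int
    p: float


@dataclass
class ModelSelection:
    family: str  # "ACE" or "ADE"
    full: VarianceComponentFit
    nested: dict[str, VarianceComponentFit]
    lrts: dict[str, LrtResult]
    chosen: VarianceComponentFit
    r_mz: float
    r_dz: float


def residualize(phenotype: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Residuals of the phenotype on age and sex, scaled to unit variance."""
    y = np.asarray(phenotype, dtype=float)
    sex = np.asarray(sex)
    sex_num = (
        sex.astype(float)
        if np.issubdtype(sex.dtype, np.number)
        else (sex == sex.flat[0]).astype(float)
    )
    x = np.column_stack([np.ones_like(y), np.asarray(age, float), sex_num])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * max(y.std(ddof=1), 1e-300):
        raise ValueError("phenotype has zero residual variance after adjustment")
    return resid / sd


# ---------------------------------------------------------------------------
# Pair likelihood
# ---------------------------------------------------------------------------

def _group_arrays(pairs) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    groups: dict[str, list[tuple[float, float]]] = {}
    for y_a, y_b, zyg in pairs:
        if zyg not in _RELATEDNESS:
            raise ValueError(f"unknown zygosity {zyg!r}")
        groups.setdefault(zyg, []).append((float(y_a), float(y_b)))
    return {
        z: (np.array([t[0] for t in v]), np.array([t[1] for t in v]))
        for z, v in groups.items()
    }


def _minus2ll(
    mu: float,
    variances: dict[str, float],
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
) -> float:
    va = variances.get("a", 0.0)
    vc = variances.get("c", 0.0)
    vd = variances.get("d", 0.0)
    ve = variances.get("e", 0.0)
    total = va + vc + vd + ve
    out = 0.0
    for zyg, (ya, yb) in groups.items():
        ra, rc, rd = _RELATEDNESS[zyg]
        cov = va * ra + vc * rc + vd * rd
        det = total * total - cov * cov
        if det <= 0 or total <= 0:
            # large finite penalty keeps quasi-Newton line searches usable
            return 1e12 * (1.0 + abs(det) + max(0.0, -total))
        da, db = ya - mu, yb - mu
        quad = (total * (da * da + db * db) - 2.0 * cov * da * db) / det
        out += np.sum(quad) + len(ya) * (np.log(det) + 2.0 * np.log(2.0 * np.pi))
    return float(out)


def fit_twin_model(
    pairs,
    structure: str = "ACE",
    n_restarts: int = 10,
    seed: int = 0,
    ci_method: str = "delta",
    n_boot: int = 1000,
) -> VarianceComponentFit:
    """Constrained ML fit of one variance-component structure.

    ``pairs`` is an iterable of (y_a, y_b, zygosity).  Variances are bounded
    at zero; the mean is free.  Confidence intervals for the variance
    fractions and heritability use the delta method on the unconstrained
    variance parameterization by default, so lower bounds may fall below
    zero even though point estimates are constrained;
    ``ci_method="bootstrap"`` instead resamples pairs with replacement
    (``n_boot`` resamples, percentile intervals).
    """
    if ci_method not in ("delta", "bootstrap"):
        raise ValueError("ci_method must be 'delta' or 'bootstrap'")
    if structure not in _STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    comp_names = _STRUCTURES[structure]
    groups = _group_arrays(pairs)
    informative = "MZ" in groups and ("DZ" in groups or "UR" in groups)
    if len(comp_names) > 1 and not informative:
        raise ValueError(
            "need MZ pairs plus DZ and/or unrelated pairs to separate components"
        )
    y_all = np.concatenate([np.concatenate(v) for v in groups.values()])
    v0 = y_all.var(ddof=1)
    mu0 = y_all.mean()

    def objective(theta: np.ndarray) -> float:
        variances = dict(zip(comp_names, theta[:-1]))
        return _minus2ll(theta[-1], variances, groups)

    rng = np.random.default_rng(seed)
    bounds = [(0.0, None)] * len(comp_names) + [(None, None)]
    best = None
    for r in range(n_restarts):
        if r == 0:
            split = np.full(len(comp_names), v0 / len(comp_names))
        else:
            w = rng.dirichlet(np.ones(len(comp_names)))
            split = w * v0 * rng.uniform(0.5, 1.5)
        x0 = np.concatenate([split, [mu0 + (0 if r == 0 else rng.normal(0, 0.1))]])
        res = scipy.optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("twin-model optimization failed to converge")

    theta = best.x
    variances = dict(zip(comp_names, theta[:-1]))
    va = variances.get("a", 0.0)
    vc = variances.get("c", 0.0)
    vd = variances.get("d", 0.0)
    ve = variances.get("e", 0.0)
    total = va + vc + vd + ve
    fr = {k: v / total for k, v in (("a", va), ("c", vc), ("d", vd), ("e", ve))}
    h2 = fr["a"]
    H2 = fr["a"] + fr["d"]
    n_params = len(comp_names) + 1  # variances + mean
    m2ll = float(best.fun)
    if ci_method == "bootstrap":
        ci = _bootstrap_cis(list(pairs), structure, n_boot, seed, n_restarts)
    else:
        ci = _delta_method_cis(theta, comp_names, objective)
    return VarianceComponentFit(
        structure=structure,
        var_a=fr["a"],
        var_c=fr["c"],
        var_d=fr["d"],
        var_e=fr["e"],
        h2=h2,
        H2=H2,
        ci=ci,
        minus2ll=m2ll,
        aic=m2ll + 2 * n_params,
        n_params=n_params,
        raw_variances=dict(zip(comp_names, theta[:-1])),
    )


def _delta_method_cis(theta, comp_names, objective) -> dict[str, tuple[float, float]]:
    """95% CIs for variance fractions and heritability via the delta method.

    The Hessian of -2LL is evaluated by central finite differences on the
    unconstrained parameterization; parameter covariance is 2 * H^{-1}.
    """
    n = len(theta)
    h = np.maximum(1e-4, 1e-3 * np.abs(theta))
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = objective(theta + ei + ej)
            fpm = objective(theta + ei - ej)
            fmp = objective(theta - ei + ej)
            fmm = objective(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.pinv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((n, n), np.nan)

    idx = {name: i for i, name in enumerate(comp_names)}
    var_of = lambda name: theta[idx[name]] if name in idx else 0.0
    total = sum(var_of(c) for c in "acde")

    def fraction_ci(numer_names: tuple[str, ...]) -> tuple[float, float]:
        numer = sum(var_of(c) for c in numer_names)
        grad = np.zeros(n)
        for name, i in idx.items():
            in_num = 1.0 if name in numer_names else 0.0
            grad[i] = (in_num * total - numer) / total**2
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        g = numer / total
        return (g - 1.96 * se, g + 1.96 * se)

    ci = {name: fraction_ci((name,)) for name in comp_names}
    ci["h2"] = fraction_ci(("a",))
    ci["H2"] = fraction_ci(("a", "d"))
    return ci


def _bootstrap_cis(
    pairs: list, structure: str, n_boot: int, seed: int, n_restarts: int
) -> dict[str, tuple[float, float]]:
    """Percentile CIs from resampling pairs with replacement."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    comp_names = _STRUCTURES[structure]
    stats: dict[str, list[float]] = {n: [] for n in (*comp_names, "h2", "H2")}
    n = len(pairs)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = [pairs[i] for i in idx]
        try:
            fit = fit_twin_model(
                resampled, structure, n_restarts=max(2, n_restarts // 3), seed=seed + b
            )
        except (ValueError, RuntimeError):
            continue
        for name in comp_names:
            stats[name].append(getattr(fit, f"var_{name}"))
        stats["h2"].append(fit.h2)
        stats["H2"].append(fit.H2)
    return {
        name: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for name, v in stats.items()
        if v
    }


def lrt(full: VarianceComponentFit, nested: VarianceComponentFit) -> LrtResult:
    """Likelihood-ratio test of a nested structure against the full model.

    chi = -2LL_nested - (-2LL_full), referred to a plain chi-squared with
    delta_df degrees of freedom (no boundary mixture; the conventional 3.84
    criterion at delta_df = 1).
    """
    chi = nested.minus2ll - full.minus2ll
    if chi < -1e-6:
        raise ValueError("nested model cannot fit better than the full model")
    chi = max(chi, 0.0)
    delta_df = full.n_params - nested.n_params
    p = float(scipy.stats.chi2.sf(chi, delta_df)) if delta_df > 0 else 1.0
    return LrtResult(float(chi), delta_df, p)


def twin_correlations(pairs) -> dict[str, float]:
    """Double-entered within-pair Pearson correlation per zygosity."""
    groups = _group_arrays(pairs)
    out = {}
    for z, (ya, yb) in groups.items():
        x1 = np.concatenate([ya, yb])
        x2 = np.concatenate([yb, ya])
        out[z] = float(np.corrcoef(x1, x2)[0, 1]) if len(ya) > 1 else np.nan
    return out


def model_selection(pairs, seed: int = 0) -> ModelSelection:
    """Fit the appropriate full model and its nested reductions.

    The full family is ADE when the DZ correlation is less than half the MZ
    correlation (dominance pattern), else ACE.  Nested models (AE plus CE or
    DE) are reported with likelihood-ratio tests and AIC; the full model is
    retained as the chosen model when no nested model fits significantly
    better, mirroring standard twin-model practice.
    """
    corr = twin_correlations(pairs)
    r_mz = corr.get("MZ", np.nan)
    r_dz = corr.get("DZ", np.nan)
    family = "ADE" if (np.isfinite(r_dz) and np.isfinite(r_mz) and r_dz < 0.5 * r_mz) else "ACE"
    full = fit_twin_model(pairs, family, seed=seed)
    nested_names = ("AE", "DE") if family == "ADE" else ("AE", "CE")
    nested = {nm: fit_twin_model(pairs, nm, seed=seed) for nm in nested_names}
    lrts = {nm: lrt(full, fit) for nm, fit in nested.items()}
    chosen = full
    return ModelSelection(family, full, nested, lrts, chosen, r_mz, r_dz)
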