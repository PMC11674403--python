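"""ANCOVA heritability screen on pairwise feature similarity.

The similarity of a multivariate dynamic-connectome phenotype within a
subject pair is its Euclidean distance; a genetic effect shows as MZ pairs
being more similar than DZ pairs, which in turn are more similar than
unrelated pairs.  The screen is a one-way ANCOVA of sibling status
(MZ / DZ / UR) on pair distances, adjusted for within-pair age difference
and pair sex, with partial eta-squared effect sizes, Bonferroni correction
over the fixed 20-test family (4 features x 5 bands), BIC-approximated
Bayes factors, and power / minimum-detectable-effect analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "TwinPairRecord",
    "AncovaResult",
    "BONFERRONI_FAMILY",
    "pairs_from_manifest",
    "pair_distance",
    "subject_origin_distance",
    "sibling_ancova",
    "componentwise_twoway_ancova",
    "bf01_bic",
    "ancova_power",
    "min_detectable_f",
    "eta2_to_f",
]

#: Fixed multiple-comparison family: 4 multivariate features x 5 bands.
BONFERRONI_FAMILY = 20

_ZYGOSITIES = ("MZ", "DZ", "UR")


@dataclass(frozen=True)
class TwinPairRecord:
    """One analysed pair: two subjects, zygosity class, pair sex, age gap."""

    pair_id: str
    subject_a: str
    subject_b: str
    zygosity: str
    pair_sex: str
    age_diff: float

    def __post_init__(self) -> None:
        if self.zygosity not in _ZYGOSITIES:
            raise ValueError(
                f"zygosity must be one of {_ZYGOSITIES}, got {self.zygosity!r}"
            )


@dataclass
class AncovaResult:
    F: float
    df: tuple[int, int]
    p: float
    p_bonf: float
    eta_p2: float
    bf01: float
    group_means: dict[str, float]


def pairs_from_manifest(manifest: pd.DataFrame) -> list[TwinPairRecord]:
    """Build pair records from a subject manifest (two rows per pair_id)."""
    records = []
    for pair_id, grp in manifest.groupby("pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"pair {pair_id} has {len(grp)} subjects, expected 2")
        a, b = grp.iloc[0], grp.iloc[1]
        if a["zygosity"] != b["zygosity"] or a["sex"] != b["sex"]:
            raise ValueError(f"pair {pair_id} members disagree on zygosity/sex")
        records.append(
            TwinPairRecord(
                pair_id=str(pair_id),
                subject_a=str(a["subject_id"]),
                subject_b=str(b["subject_id"]),
                zygosity=str(a["zygosity"]),
                pair_sex=str(a["sex"]),
                age_diff=abs(float(a["age"]) - float(b["age"])),
            )
        )
    return records


def pair_distance(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Euclidean distance between two subjects' feature vectors."""
    return float(np.linalg.norm(np.asarray(x_a, float) - np.asarray(x_b, float)))


def subject_origin_distance(x: np.ndarray, origin) -> float:
    """Euclidean distance of a subject's feature vector from the null origin.

    This scalar is the univariate phenotype entering variance-component
    modeling.
    """
    o = np.asarray(getattr(origin, "origin", origin), dtype=float)
    return float(np.linalg.norm(np.asarray(x, float) - o))


def _pair_frame(distances: np.ndarray, pairs: list[TwinPairRecord]) -> pd.DataFrame:
    distances = np.asarray(distances, dtype=float)
    if distances.shape[0] != len(pairs):
        raise ValueError("one distance per pair required")
    return pd.DataFrame(
        {
            "y": distances,
            "zygosity": pd.Categorical(
                [p.zygosity for p in pairs], categories=_ZYGOSITIES
            ),
            "age_diff": [p.age_diff for p in pairs],
            "pair_sex": [1.0 if p.pair_sex == "F" else 0.0 for p in pairs],
        }
    )


def sibling_ancova(
    distances: np.ndarray,
    pairs: list[TwinPairRecord],
    n_tests: int = BONFERRONI_FAMILY,
) -> AncovaResult:
    """One-way ANCOVA of sibling status on pair distances.

    Factor: zygosity (MZ / DZ / UR); covariates: within-pair age difference
    and pair sex.  F has df (2, n_pairs - 5).  Bonferroni correction uses the
    fixed family of ``n_tests``; BF01 is the BIC-approximated Bayes factor in
    favour of no sibling-status effect.
    """
    df = _pair_frame(distances, pairs)
    full = smf.ols("y ~ C(zygosity) + age_diff + pair_sex", df).fit()
    red = smf.ols("y ~ age_diff + pair_sex", df).fit()
    df1 = int(red.df_resid - full.df_resid)
    df2 = int(full.df_resid)
    ss_effect = red.ssr - full.ssr
    F = (ss_effect / df1) / (full.ssr / df2)
    p = float(scipy.stats.f.sf(F, df1, df2))
    eta = ss_effect / (ss_effect + full.ssr)
    bf01 = float(np.exp((full.bic - red.bic) / 2.0))
    means = {z: float(df.loc[df.zygosity == z, "y"].mean()) for z in _ZYGOSITIES}
    return AncovaResult(
        float(F), (df1, df2), p, min(1.0, n_tests * p), float(eta), bf01, means
    )


def componentwise_twoway_ancova(
    component_diffs: np.ndarray,
    pairs: list[TwinPairRecord],
    component_labels: list[str] | None = None,
) -> dict[str, "dict"]:
    """Two-way ANCOVA of sibling status x component on componentwise similarity.

    ``component_diffs`` is (n_pairs, m): the absolute within-pair difference
    of each scalar component (states for FO/Q/cluster-FC, off-diagonal state
    pairs for TP).  Returns F tests for the two main effects and their
    interaction, by extra sum of squares on pooled pair x component rows.
    """
    d = np.atleast_2d(np.asarray(component_diffs, dtype=float))
    n_pairs, m = d.shape
    if component_labels is None:
        component_labels = [f"c{i + 1}" for i in range(m)]
    long = pd.DataFrame(
        {
            "y": d.ravel(),
            "zygosity": pd.Categorical(
                np.repeat([p.zygosity for p in pairs], m), categories=_ZYGOSITIES
            ),
            "component": pd.Categorical(np.tile(component_labels, n_pairs)),
            "age_diff": np.repeat([p.age_diff for p in pairs], m),
            "pair_sex": np.repeat(
                [1.0 if p.pair_sex == "F" else 0.0 for p in pairs], m
            ),
        }
    )
    covs = "age_diff + pair_sex"
    fits = {
        "full": smf.ols(f"y ~ C(zygosity) * C(component) + {covs}", long).fit(),
        "additive": smf.ols(f"y ~ C(zygosity) + C(component) + {covs}", long).fit(),
        "no_zyg": smf.ols(f"y ~ C(component) + {covs}", long).fit(),
        "no_comp": smf.ols(f"y ~ C(zygosity) + {covs}", long).fit(),
    }

    def _ftest(reduced, full):
        df1 = int(reduced.df_resid - full.df_resid)
        df2 = int(full.df_resid)
        F = ((reduced.ssr - full.ssr) / df1) / (full.ssr / df2)
        return {
            "F": float(F),
            "df": (df1, df2),
            "p": float(scipy.stats.f.sf(F, df1, df2)),
        }

    return {
        "sibling_status": _ftest(fits["no_zyg"], fits["additive"]),
        "component": _ftest(fits["no_comp"], fits["additive"]),
        "interaction": _ftest(fits["additive"], fits["full"]),
    }


def bf01_bic(distances: np.ndarray, pairs: list[TwinPairRecord]) -> float:
    """BIC-approximated Bayes factor BF01 for no sibling-status effect.

    BF01 ~ exp((BIC_H1 - BIC_H0) / 2) comparing the covariates-only model
    (H0) against covariates + sibling status (H1); values > 1 favour H0.
    """
    df = _pair_frame(distances, pairs)
    h1 = smf.ols("y ~ C(zygosity) + age_diff + pair_sex", df).fit()
    h0 = smf.ols("y ~ age_diff + pair_sex", df).fit()
    return float(np.exp((h1.bic - h0.bic) / 2.0))


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

def eta2_to_f(eta2: float) -> float:
    """Cohen's f from (partial) eta-squared: f = sqrt(eta2 / (1 - eta2))."""
    if not 0 <= eta2 < 1:
        raise ValueError("eta2 must be in [0, 1)")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def ancova_power(
    f: float,
    n_total: int,
    k_groups: int = 3,
    n_covariates: int = 2,
    alpha: float = 0.05,
) -> float:
    """Power of the k-group ANCOVA F test at effect size Cohen's f.

    Noncentral F with df (k-1, n-k-n_cov) and noncentrality f^2 * n.
    """
    df1 = k_groups - 1
    df2 = n_total - k_groups - n_covariates
    crit = scipy.stats.f.isf(alpha, df1, df2)
    return float(scipy.stats.ncf.sf(crit, df1, df2, f**2 * n_total))


def min_detectable_f(
    n_total: int,
    k_groups: int = 3,
    n_covariates: int = 2,
    alpha: float = 0.05,
    power: float = 0.80,
) -> float:
    """Smallest Cohen's f detectable at the target power (bisection)."""
    lo, hi = 1e-6, 5.0
    if ancova_power(hi, n_total, k_groups, n_covariates, alpha) < power:
        raise ValueError("target power unreachable at f = 5")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ancova_power(mid, n_total, k_groups, n_covariates, alpha) < power:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-8:
            break
    return float(0.5 * (lo + hi))
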