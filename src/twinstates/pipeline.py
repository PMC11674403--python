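"""End-to-end orchestration: simulate -> fit -> contrasts -> features -> null
origin -> heritability screen -> variance components.

A run lives in one output directory; every stage reads the previous stage's
files from it and writes its own, so stages can be re-run individually from
the CLI.  A single top-level seed fans out to all stochastic stages.  The
configuration is serialized verbatim into the run directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .contrasts import nbs
from .features import IcnPartition, extract_subject_features
from .heritability import (
    pair_distance,
    pairs_from_manifest,
    sibling_ancova,
    subject_origin_distance,
)
from .hmm import fit_hmm, standardize_concatenate
from .preprocess import CANONICAL_BANDS, BandDefinition
from .surrogates import compute_null_origin
from .synth import AceSpec, CohortConfig, generate_cohort
from .varcomp import model_selection, residualize

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("twinstates")

_BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    seed: int = 0
    bands: list[str] = field(default_factory=lambda: ["alpha"])
    n_states: int = 6
    n_restarts: int = 3
    n_surrogates: int = 5
    nbs_density: float = 0.05
    nbs_n_perm: int = 200
    fo_mode: str = "hard"
    max_iter: int = 200
    # either simulate a cohort ...
    simulate: dict | None = None
    # ... or point at existing inputs
    manifest_path: str | None = None
    envelope_path: str | None = None
    partition_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config YAML must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config missing required field 'out_dir'")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None and (
            self.manifest_path is None or self.envelope_path is None
        ):
            raise ValueError(
                "config must provide either a 'simulate' block or both "
                "'manifest_path' and 'envelope_path'"
            )
        for b in self.bands:
            if b not in _BAND_BY_NAME:
                raise ValueError(f"unknown band {b!r}; known: {sorted(_BAND_BY_NAME)}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %-12s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, out: Path):
    sim = dict(cfg.simulate)
    spec = AceSpec(**sim.pop("ace", {"a2": 0.5, "e2": 0.5}))
    bands = tuple(_BAND_BY_NAME[b] for b in cfg.bands)
    cohort = CohortConfig(
        bands=bands, n_states=cfg.n_states, seed=cfg.seed, **sim
    )
    manifest, envelopes, truth = generate_cohort(cohort, spec)
    tio.write_manifest(manifest, out / "manifest.tsv")
    tio.write_envelopes(envelopes, out / "envelopes.h5")
    with h5py.File(out / "ground_truth.h5", "w") as f:
        for band, paths in truth.true_paths.items():
            g = f.create_group(f"paths/{band}")
            for sid, p in paths.items():
                g.create_dataset(sid, data=np.asarray(p, dtype=np.int64))
        g = f.create_group("transitions")
        for sid, tm in truth.subject_transitions.items():
            g.create_dataset(sid, data=tm)
    return manifest, envelopes


@_stage("fit-hmm")
def _fit_band(cfg: RunConfig, envs: dict, band: str, out: Path):
    order = sorted(envs)
    stacked, bounds = standardize_concatenate([envs[s] for s in order])
    model, stcs = fit_hmm(
        stacked,
        bounds,
        cfg.n_states,
        n_restarts=cfg.n_restarts,
        seed=cfg.seed,
        max_iter=cfg.max_iter,
    )
    tio.write_model(model, out / f"model_{band}.h5", band=band)
    with h5py.File(out / f"stc_{band}.h5", "w") as f:
        for sid, stc in zip(order, stcs):
            g = f.create_group(sid)
            g.create_dataset("posteriors", data=stc.posteriors)
            g.create_dataset("path", data=stc.path.astype(np.int64))
            g.attrs["loglik"] = stc.loglik
    return order, model, stcs


@_stage("contrasts")
def _contrasts(cfg: RunConfig, manifest, order, stcs, envs, band: str, out: Path):
    from .features import subject_state_fc

    ages = manifest.set_index("subject_id").loc[order, "age"].to_numpy(float)
    sexes = manifest.set_index("subject_id").loc[order, "sex"].to_numpy()
    K = cfg.n_states
    fc_stack = []
    for sid, stc in zip(order, stcs):
        fcs, valid = subject_state_fc(envs[sid], stc.posteriors)
        if not valid.all():
            static = np.corrcoef(np.asarray(envs[sid].data).T)
            for k in np.flatnonzero(~valid):
                fcs[k] = static
        fc_stack.append(fcs)
    fc_stack = np.asarray(fc_stack)
    result = nbs(
        fc_stack,
        ages,
        sexes,
        density=cfg.nbs_density,
        n_perm=cfg.nbs_n_perm,
        seed=cfg.seed + 1,
    )
    sig = [c for c, p in zip(result.clusters, result.fwer_p) if p < 0.05]
    mask = np.zeros(fc_stack.shape[-2:], dtype=bool)
    edges = [e for c in (sig if sig else result.clusters) for e in c]
    for i, j in edges:
        mask[i, j] = mask[j, i] = True
    rows = [
        {"region_i": i + 1, "region_j": j + 1, "F": result.edge_stats.f_values[i, j]}
        for i, j in edges
    ]
    pd.DataFrame(rows, columns=["region_i", "region_j", "F"]).to_csv(
        out / f"cluster_edges_{band}.tsv", sep="\t", index=False
    )
    return fc_stack, mask, result, ages, sexes


@_stage("features")
def _features(cfg: RunConfig, order, stcs, envs, partition, mask, band: str, out: Path):
    feats = extract_subject_features(
        stcs,
        [envs[s] for s in order],
        cfg.n_states,
        partition=partition,
        cluster_mask=mask if mask.any() else None,
        mode=cfg.fo_mode,
    )
    K = cfg.n_states
    cols: dict[str, np.ndarray] = {}
    for k in range(K):
        cols[f"fo_{k + 1}"] = feats["fo"][:, k]
    for i in range(K):
        for j in range(K):
            cols[f"tp_{i + 1}_{j + 1}"] = feats["tp"][:, i * K + j]
    if "modularity" in feats:
        for k in range(K):
            cols[f"q_{k + 1}"] = feats["modularity"][:, k]
    if "cluster_fc" in feats:
        for k in range(K):
            cols[f"cfc_{k + 1}"] = feats["cluster_fc"][:, k]
    table = pd.DataFrame(cols, index=pd.Index(order, name="subject_id"))
    # full precision so a stage re-run from the TSV reproduces results exactly
    table.to_csv(out / f"features_{band}.tsv", sep="\t", float_format="%.17g")
    return feats


@_stage("null-origin")
def _null(cfg: RunConfig, envs, partition, mask, band: str, out: Path):
    origins = compute_null_origin(
        envs,
        cfg.n_states,
        n_surrogates=cfg.n_surrogates,
        seed=cfg.seed + 2,
        partition=partition,
        cluster_mask=mask if mask.any() else None,
        n_restarts=max(1, cfg.n_restarts - 1),
        max_iter=min(cfg.max_iter, 100),
        mode=cfg.fo_mode,
    )
    payload = {
        name: {"origin": o.origin.tolist(), "n_surrogates": o.n_surrogates}
        for name, o in origins.items()
    }
    (out / f"origins_{band}.json").write_text(json.dumps(payload, indent=1))
    return origins


@_stage("heritability")
def _herit(cfg, manifest, order, feats, origins, band: str, out: Path):
    pairs = pairs_from_manifest(manifest)
    idx = {sid: i for i, sid in enumerate(order)}
    rows = []
    herit_tables = {}
    for name, mat in feats.items():
        dists = np.array(
            [pair_distance(mat[idx[p.subject_a]], mat[idx[p.subject_b]]) for p in pairs]
        )
        res = sibling_ancova(dists, pairs)
        rows.append(
            {
                "band": band,
                "feature": name,
                "F": res.F,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
                "p_bonf": res.p_bonf,
                "eta_p2": res.eta_p2,
                "bf01": res.bf01,
                "mean_dist_MZ": res.group_means["MZ"],
                "mean_dist_DZ": res.group_means["DZ"],
                "mean_dist_UR": res.group_means["UR"],
            }
        )
        herit_tables[name] = res
    pd.DataFrame(rows).to_csv(out / f"herit_{band}.tsv", sep="\t", index=False)
    return herit_tables


@_stage("varcomp")
def _varcomp(cfg, manifest, order, feats, origins, band: str, out: Path):
    pairs = pairs_from_manifest(manifest)
    meta = manifest.set_index("subject_id")
    rows = []
    selections = {}
    for name, mat in feats.items():
        if name not in origins:
            continue
        pheno = np.array(
            [subject_origin_distance(mat[i], origins[name]) for i in range(len(order))]
        )
        ages = meta.loc[list(order), "age"].to_numpy(float)
        sexes = meta.loc[list(order), "sex"].to_numpy()
        adj = residualize(pheno, ages, sexes)
        adj_by_sid = dict(zip(order, adj))
        trip = [
            (adj_by_sid[p.subject_a], adj_by_sid[p.subject_b], p.zygosity)
            for p in pairs
        ]
        sel = model_selection(trip, seed=cfg.seed + 3)
        selections[name] = sel
        for label, fit in [(sel.full.structure, sel.full)] + list(sel.nested.items()):
            l = sel.lrts.get(label)
            rows.append(
                {
                    "band": band,
                    "phenotype": name,
                    "model": label,
                    "h2": fit.heritability,
                    "ci_lo": fit.heritability_ci[0],
                    "ci_hi": fit.heritability_ci[1],
                    "A": fit.var_a,
                    "C_or_D": fit.var_c + fit.var_d,
                    "E": fit.var_e,
                    "minus2ll": fit.minus2ll,
                    "aic": fit.aic,
                    "chi": l.chi if l else np.nan,
                    "delta_df": l.delta_df if l else 0,
                    "p_chi": l.p if l else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(out / f"varcomp_{band}.tsv", sep="\t", index=False)
    return selections


# ---------------------------------------------------------------------------
# Re-loading stage artifacts so individual stages can be re-run from the CLI
# ---------------------------------------------------------------------------

def _read_stcs(out: Path, band: str):
    from .hmm import StateTimeCourse

    order, stcs = [], []
    with h5py.File(out / f"stc_{band}.h5", "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            order.append(sid)
            stcs.append(
                StateTimeCourse(
                    g["posteriors"][()], g["path"][()], float(g.attrs["loglik"])
                )
            )
    return order, stcs


def _read_mask(out: Path, band: str, n_regions: int) -> np.ndarray:
    mask = np.zeros((n_regions, n_regions), dtype=bool)
    path = out / f"cluster_edges_{band}.tsv"
    if path.exists():
        edges = pd.read_csv(path, sep="\t")
        for _, row in edges.iterrows():
            i, j = int(row["region_i"]) - 1, int(row["region_j"]) - 1
            mask[i, j] = mask[j, i] = True
    return mask


def _read_features_table(out: Path, band: str) -> tuple[list[str], dict[str, np.ndarray]]:
    table = pd.read_csv(
        out / f"features_{band}.tsv",
        sep="\t",
        index_col="subject_id",
        float_precision="round_trip",
    )
    order = [str(s) for s in table.index]
    feats: dict[str, np.ndarray] = {}
    for name, prefix in [
        ("fo", "fo_"),
        ("tp", "tp_"),
        ("modularity", "q_"),
        ("cluster_fc", "cfc_"),
    ]:
        cols = [c for c in table.columns if c.startswith(prefix)]
        if cols:
            feats[name] = table[cols].to_numpy(float)
    return order, feats


def _read_origins(out: Path, band: str):
    from .surrogates import NullOrigin

    payload = json.loads((out / f"origins_{band}.json").read_text())
    return {
        name: NullOrigin(name, band, np.asarray(d["origin"]), int(d["n_surrogates"]))
        for name, d in payload.items()
    }


def _band_partition(config: RunConfig, n_regions: int) -> IcnPartition:
    if config.partition_path:
        mapping = tio.read_partition(config.partition_path)
        return IcnPartition.from_mapping(mapping, [str(r) for r in range(n_regions)])
    return IcnPartition.balanced(n_regions)


def run_stage(config: RunConfig, stage: str, band: str | None = None) -> None:
    """Run one pipeline stage against an existing run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stage == "simulate":
        if config.simulate is None:
            raise ValueError("config has no 'simulate' block")
        _simulate(config, out)
        return
    bands = [band] if band else config.bands
    env_path = (
        Path(config.envelope_path) if config.envelope_path else out / "envelopes.h5"
    )
    man_path = (
        Path(config.manifest_path) if config.manifest_path else out / "manifest.tsv"
    )
    for b in bands:
        if stage == "fit-hmm":
            envs = tio.read_envelopes(env_path, bands=[b])[b]
            _fit_band(config, envs, b, out)
        elif stage == "contrasts":
            envs = tio.read_envelopes(env_path, bands=[b])[b]
            manifest = tio.read_manifest(man_path)
            order, stcs = _read_stcs(out, b)
            _contrasts(config, manifest, order, stcs, envs, b, out)
        elif stage == "features":
            envs = tio.read_envelopes(env_path, bands=[b])[b]
            order, stcs = _read_stcs(out, b)
            n_regions = next(iter(envs.values())).n_regions
            mask = _read_mask(out, b, n_regions)
            partition = _band_partition(config, n_regions)
            _features(config, order, stcs, envs, partition, mask, b, out)
        elif stage == "null":
            envs = tio.read_envelopes(env_path, bands=[b])[b]
            n_regions = next(iter(envs.values())).n_regions
            mask = _read_mask(out, b, n_regions)
            partition = _band_partition(config, n_regions)
            _null(config, envs, partition, mask, b, out)
        elif stage == "herit":
            manifest = tio.read_manifest(man_path)
            order, feats = _read_features_table(out, b)
            origins = _read_origins(out, b)
            _herit(config, manifest, order, feats, origins, b, out)
        elif stage == "varcomp":
            manifest = tio.read_manifest(man_path)
            order, feats = _read_features_table(out, b)
            origins = _read_origins(out, b)
            _varcomp(config, manifest, order, feats, origins, b, out)
        else:
            raise ValueError(f"unknown stage {stage!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the in-memory results keyed by band."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=False))

    if config.simulate is not None:
        manifest, envelopes = _simulate(config, out)
    else:
        manifest = tio.read_manifest(config.manifest_path)
        envelopes = tio.read_envelopes(config.envelope_path, bands=config.bands)

    partition_map = (
        tio.read_partition(config.partition_path) if config.partition_path else None
    )

    results: dict[str, dict] = {}
    for band in config.bands:
        envs = envelopes[band]
        order, model, stcs = _fit_band(config, envs, band, out)
        n_regions = model.n_regions
        if partition_map is not None:
            partition = IcnPartition.from_mapping(
                partition_map, [str(r) for r in range(n_regions)]
            )
        else:
            partition = IcnPartition.balanced(n_regions)
        fc_stack, mask, nbs_result, ages, sexes = _contrasts(
            config, manifest, order, stcs, envs, band, out
        )
        feats = _features(config, order, stcs, envs, partition, mask, band, out)
        origins = _null(config, envs, partition, mask, band, out)
        herit = _herit(config, manifest, order, feats, origins, band, out)
        vc = _varcomp(config, manifest, order, feats, origins, band, out)
        results[band] = {
            "order": order,
            "model": model,
            "stcs": stcs,
            "nbs": nbs_result,
            "features": feats,
            "origins": origins,
            "heritability": herit,
            "varcomp": vc,
        }
    return results
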