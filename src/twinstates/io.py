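"""File formats: manifest TSV, partition JSON, envelope/model HDF5, results TSV.

All numeric payloads round-trip losslessly (float64 end to end).  The
envelope store keeps one dataset per band per subject at
``/<band>/<subject_id>`` (time x region) with sampling-rate and band-edge
attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .hmm import GaussianHMM
from .preprocess import BandDefinition, EnvelopeTimeSeries

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_partition",
    "write_partition",
    "read_envelopes",
    "write_envelopes",
    "read_model",
    "write_model",
]

_ZYGOSITIES = ("MZ", "DZ", "UR")
_MANIFEST_COLUMNS = ("subject_id", "pair_id", "zygosity", "sex", "age")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "pair_id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    bad = sorted(set(df["zygosity"]) - set(_ZYGOSITIES))
    if bad:
        raise ValueError(
            f"invalid zygosity label(s) {bad}; allowed values are {list(_ZYGOSITIES)}"
        )
    return df


def write_partition(mapping: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(json.dumps(mapping, indent=1, sort_keys=True))


def read_partition(path: str | Path) -> dict[str, str]:
    mapping = json.loads(Path(path).read_text())
    if not isinstance(mapping, dict):
        raise ValueError("partition JSON must map region -> network label")
    return {str(k): str(v) for k, v in mapping.items()}


def write_envelopes(
    envelopes: dict[str, dict[str, EnvelopeTimeSeries]], path: str | Path
) -> None:
    """Write band -> subject -> envelope to an HDF5 store."""
    with h5py.File(path, "w") as f:
        for band_name, subjects in envelopes.items():
            grp = f.create_group(band_name)
            for sid in sorted(subjects):
                env = subjects[sid]
                ds = grp.create_dataset(sid, data=env.data.astype(np.float64))
                ds.attrs["fs"] = float(env.fs)
                ds.attrs["band_low_hz"] = float(env.band.low_hz)
                ds.attrs["band_high_hz"] = float(env.band.high_hz)


def read_envelopes(
    path: str | Path, bands: list[str] | None = None
) -> dict[str, dict[str, EnvelopeTimeSeries]]:
    out: dict[str, dict[str, EnvelopeTimeSeries]] = {}
    with h5py.File(path, "r") as f:
        for band_name in bands if bands is not None else sorted(f.keys()):
            if band_name not in f:
                raise KeyError(f"band {band_name!r} not present in envelope store")
            grp = f[band_name]
            out[band_name] = {}
            for sid in sorted(grp.keys()):
                ds = grp[sid]
                band = BandDefinition(
                    band_name, float(ds.attrs["band_low_hz"]), float(ds.attrs["band_high_hz"])
                )
                out[band_name][sid] = EnvelopeTimeSeries(
                    sid, band, ds[()], float(ds.attrs["fs"])
                )
    return out


def write_model(model: GaussianHMM, path: str | Path, band: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("means", data=model.means)
        f.create_dataset("covariances", data=model.covariances)
        f.create_dataset("transition", data=model.transition)
        f.create_dataset("initial", data=model.initial)
        f.attrs["K"] = model.n_states
        f.attrs["R"] = model.n_regions
        f.attrs["band"] = band


def read_model(path: str | Path) -> GaussianHMM:
    with h5py.File(path, "r") as f:
        return GaussianHMM(
            f["means"][()], f["covariances"][()], f["transition"][()], f["initial"][()]
        )
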