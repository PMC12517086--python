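"""Reading and writing of cohort tables and signal containers.

Feature-level cohorts use BIDS-style TSV conventions: a ``participants.tsv``
(participant_id, site, age, pain_intensity, diagnosis) and a
``features.tsv`` keyed by participant_id.  Signal-level cohorts are stored
as an HDF5 container (one dataset of epochs per participant) with a JSON
sidecar carrying sampling rate, channel names, epoch length, and overlap.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import LeadField, SensorEpochs

__all__ = [
    "write_feature_cohort", "read_feature_cohort",
    "write_signal_cohort", "read_signal_cohort",
    "write_leadfield", "read_leadfield",
]


def write_feature_cohort(outdir: str | Path, features: pd.DataFrame,
                         meta: pd.DataFrame) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta.to_csv(outdir / "participants.tsv", sep="\t")
    features.to_csv(outdir / "features.tsv", sep="\t")


def read_feature_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "participants.tsv", sep="\t", index_col="participant_id")
    features = pd.read_csv(indir / "features.tsv", sep="\t", index_col="participant_id")
    return features, meta


def write_signal_cohort(path: str | Path, recordings: dict[str, SensorEpochs]) -> None:
    path = Path(path)
    sidecar: dict = {"participants": {}}
    with h5py.File(path, "w") as f:
        for pid, rec in recordings.items():
            g = f.create_group(pid)
            g.create_dataset("epochs", data=rec.data, compression="gzip")
            g.create_dataset("clean_flags", data=rec.clean_flags)
            sidecar["participants"][pid] = {
                "fs": rec.fs,
                "channels": rec.channel_names,
                "epoch_len_s": rec.epoch_len_s,
                "overlap": rec.overlap,
            }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_signal_cohort(path: str | Path) -> dict[str, SensorEpochs]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    out = {}
    with h5py.File(path, "r") as f:
        for pid, info in sidecar["participants"].items():
            out[pid] = SensorEpochs(
                data=f[pid]["epochs"][()],
                fs=info["fs"],
                channel_names=list(info["channels"]),
                clean_flags=f[pid]["clean_flags"][()],
                epoch_len_s=info["epoch_len_s"],
                overlap=info["overlap"],
            )
    return out


def write_leadfield(path: str | Path, lf: LeadField) -> None:
    path = Path(path)
    np.savetxt(path, lf.matrix.reshape(lf.n_parcels, -1), delimiter="\t")
    sidecar = {
        "n_parcels": lf.n_parcels,
        "n_sensors": lf.n_sensors,
        "orientation_multiplicity": 3 if lf.free_orientation else 1,
        "network_labels": lf.network_labels.tolist(),
        "network_names": list(lf.network_names) if lf.network_names else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_leadfield(path: str | Path) -> LeadField:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    mat = np.loadtxt(path, delimiter="\t")
    if sidecar["orientation_multiplicity"] == 3:
        mat = mat.reshape(sidecar["n_parcels"], sidecar["n_sensors"], 3)
    return LeadField(
        matrix=mat,
        network_labels=np.asarray(sidecar["network_labels"], dtype=int),
        network_names=tuple(sidecar["network_names"]) if sidecar["network_names"] else None,
    )
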