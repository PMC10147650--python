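"""File interfaces: HDF5 recording containers, CSV manifests, feature and
label tables.

One HDF5 group per recording holds the ``signals`` dataset (channels x
samples, float) with acquisition metadata as attributes; the manifest CSV
has one row per recording. All tables use canonical column names so they
round-trip bit-identically.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .recording import FEATURE_NAMES, MEARecording
from .synth import StudyBundle

REC_ATTRS = (
    "fs",
    "tissue",
    "drug_id",
    "dose",
    "phase",
    "repeat",
    "grid_rows",
    "grid_cols",
    "pitch_um",
)


def recording_key(drug_id, dose_rank, tissue, repeat, phase) -> str:
    return f"{drug_id}__d{int(dose_rank)}__{tissue}__r{int(repeat)}__{phase}"


def write_recording(h5: h5py.File, key: str, rec: MEARecording) -> None:
    grp = h5.create_group(key)
    grp.create_dataset("signals", data=rec.signals)
    for attr in REC_ATTRS:
        grp.attrs[attr] = getattr(rec, attr)


def read_recording(h5: h5py.File, key: str) -> MEARecording:
    grp = h5[key]
    attrs = {a: grp.attrs[a] for a in REC_ATTRS}
    return MEARecording(
        signals=np.asarray(grp["signals"]),
        fs=float(attrs["fs"]),
        grid_rows=int(attrs["grid_rows"]),
        grid_cols=int(attrs["grid_cols"]),
        pitch_um=float(attrs["pitch_um"]),
        tissue=str(attrs["tissue"]),
        drug_id=str(attrs["drug_id"]),
        dose=float(attrs["dose"]),
        phase=str(attrs["phase"]),
        repeat=int(attrs["repeat"]),
    )


def write_study(bundle: StudyBundle, h5_path, manifest_csv=None, labels_csv=None) -> pd.DataFrame:
    """Write every recording of a study to one HDF5 container.

    Returns (and optionally writes) the per-recording manifest: one row per
    recording with its metadata and HDF5 group path.
    """
    rows = []
    with h5py.File(h5_path, "w") as h5:
        for row, base, post in bundle.iter_recordings():
            for rec in (base, post):
                key = recording_key(
                    rec.drug_id, row.dose_rank, rec.tissue, rec.repeat, rec.phase
                )
                write_recording(h5, key, rec)
                rows.append(
                    dict(
                        path=key,
                        drug_id=rec.drug_id,
                        dose=rec.dose,
                        dose_rank=int(row.dose_rank),
                        tissue=rec.tissue,
                        repeat=int(rec.repeat),
                        phase=rec.phase,
                        fs=rec.fs,
                        grid_rows=rec.grid_rows,
                        grid_cols=rec.grid_cols,
                        pitch_um=rec.pitch_um,
                    )
                )
    manifest = pd.DataFrame(rows)
    if manifest_csv is not None:
        manifest.to_csv(manifest_csv, index=False)
    if labels_csv is not None:
        bundle.raw_label_rows.to_csv(labels_csv, index=False)
    return manifest


def read_study(h5_path, manifest: pd.DataFrame):
    """Yield (manifest_row, MEARecording) for every recording listed."""
    with h5py.File(h5_path, "r") as h5:
        for _, row in manifest.iterrows():
            yield row, read_recording(h5, row["path"])


EF_META_COLUMNS = ("recording_id", "drug_id", "dose", "dose_rank", "tissue", "repeat", "phase")


def write_ef_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in EF_META_COLUMNS if c in df.columns] + list(FEATURE_NAMES)
    df[cols].to_csv(path, index=False)


def read_ef_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_label_rows(df: pd.DataFrame, path) -> None:
    df[["drug_id", "ae_name", "role"]].to_csv(path, index=False)


def read_label_rows(path) -> pd.DataFrame:
    return pd.read_csv(path)
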