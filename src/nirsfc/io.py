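"""Readers and writers for recordings and result tables.

Two interchangeable recording containers are supported pipeline-wide:

* a SNIRF-style HDF5 file (continuous-wave subset of the SNIRF layout:
  ``/nirs/data1/dataTimeSeries`` + measurement list + probe wavelengths);
* a plain per-subject TSV (time x channel-wavelength columns) with a JSON
  sidecar carrying sampling rate, wavelengths and group label.

Cohorts are tied together by a tab-separated manifest
``subject_id  group  file``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .simulate import RawRecording


# ---------------------------------------------------------------- TSV + JSON

def write_recording_tsv(rec: RawRecording, directory: str | Path) -> Path:
    """Write one recording as ``<subject>.tsv`` + ``<subject>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_ch, n_wl, n_t = rec.intensity.shape
    cols = {}
    for c in range(n_ch):
        for w in range(n_wl):
            cols[f"ch{c + 1}_wl{int(rec.wavelengths[w])}"] = rec.intensity[c, w]
    path = directory / f"{rec.subject_id}.tsv"
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "wavelengths": list(rec.wavelengths),
        "n_channels": n_ch,
    }
    (directory / f"{rec.subject_id}.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_tsv(path: str | Path) -> RawRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t")
    n_ch = meta["n_channels"]
    wavelengths = tuple(float(w) for w in meta["wavelengths"])
    intensity = np.empty((n_ch, len(wavelengths), len(df)))
    for c in range(n_ch):
        for w, wl in enumerate(wavelengths):
            intensity[c, w] = df[f"ch{c + 1}_wl{int(wl)}"].to_numpy()
    return RawRecording(
        subject_id=meta["subject_id"], group=meta["group"],
        intensity=intensity, fs=float(meta["fs"]), wavelengths=wavelengths,
    )


# ---------------------------------------------------------------------- SNIRF

def write_recording_snirf(rec: RawRecording, path: str | Path) -> Path:
    """Continuous-wave SNIRF-style container (HDF5)."""
    path = Path(path)
    n_ch, n_wl, n_t = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("Group", data=rec.group)
        data = nirs.create_group("data1")
        flat = rec.intensity.reshape(n_ch * n_wl, n_t).T   # time x measurement
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n_t) / rec.fs)
        for m in range(n_ch * n_wl):
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=m // n_wl + 1)
            ml.create_dataset("detectorIndex", data=m // n_wl + 1)
            ml.create_dataset("wavelengthIndex", data=m % n_wl + 1)
            ml.create_dataset("dataType", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(rec.wavelengths))
    return path


def read_recording_snirf(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        flat = np.asarray(data["dataTimeSeries"]).T
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = tuple(float(w) for w in f["nirs/probe/wavelengths"][()])
        n_wl = len(wavelengths)
        n_ch = flat.shape[0] // n_wl
        meta = f["nirs/metaDataTags"]
        subject = _h5str(meta["SubjectID"][()])
        group = _h5str(meta["Group"][()]) if "Group" in meta else ""
    return RawRecording(
        subject_id=subject, group=group,
        intensity=flat.reshape(n_ch, n_wl, -1), fs=fs, wavelengths=wavelengths,
    )


def _h5str(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    if path.suffix in {".snirf", ".h5", ".hdf5"}:
        return read_recording_snirf(path)
    return read_recording_tsv(path)


# -------------------------------------------------------------------- cohort

def write_cohort(recordings, directory: str | Path, fmt: str = "tsv") -> Path:
    """Write all recordings plus the ``subject_id  group  file`` manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        if fmt == "snirf":
            p = write_recording_snirf(rec, directory / f"{rec.subject_id}.snirf")
        elif fmt == "tsv":
            p = write_recording_tsv(rec, directory)
        else:
            raise ValueError("fmt must be 'tsv' or 'snirf'")
        rows.append((rec.subject_id, rec.group, p.name))
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows, columns=["subject_id", "group", "file"]).to_csv(
        manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest: str | Path):
    """Yield recordings listed in a cohort manifest."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    for row in table.itertuples():
        yield read_recording(manifest.parent / row.file)


# -------------------------------------------------------------------- tables

def write_matrix(cm: ConnectivityMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def read_matrix(path: str | Path, level: str, subject_id: str = "",
                group: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(level=level, labels=tuple(df.columns),
                              z=df.to_numpy(float), subject_id=subject_id,
                              group=group)
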