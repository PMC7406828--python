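"""HDF5 subject containers and CSV event tables.

One container per subject: ``/data`` (regions x samples, 32-bit float),
``/region_labels``, ``/fs``, with later stages adding ``/imfs/<region>``,
``/bands/<band>/<component>``, ``/expmse`` (+ column order metadata) and
``/crops/<kind>/{data,labels,trial_id}``.  The event table travels as a
CSV file next to the container.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decompose import BandComponents
from .entropy import ComplexityTensor
from .errors import ContainerError
from .features import CropSet
from .simulate import Recording

FORMAT_VERSION = "1"

EVENT_COLUMNS = ["session", "task", "trial",
                 "rest_onset", "task_onset", "task_offset"]


def events_path(container: str | Path) -> Path:
    p = Path(container)
    return p.with_name(p.stem + "_events.csv")


def write_subject(path: str | Path, recording: Recording,
                  events: pd.DataFrame | None = None) -> Path:
    """Create (or overwrite) a subject container; events go to CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["subject"] = recording.subject
        f.create_dataset("data", data=recording.data.astype(np.float32))
        f.create_dataset(
            "region_labels",
            data=np.array(recording.region_labels, dtype="S64"))
        f.create_dataset("fs", data=float(recording.fs))
    if events is not None:
        events[EVENT_COLUMNS].to_csv(events_path(path), index=False)
    return path


def _check_version(f: h5py.File, path) -> None:
    version = f.attrs.get("version")
    if version != FORMAT_VERSION:
        raise ContainerError(
            f"{path}: unknown container version {version!r} "
            f"(expected {FORMAT_VERSION!r})")


def read_subject(path: str | Path) -> tuple[Recording, pd.DataFrame | None]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        for name in ("data", "region_labels", "fs"):
            if name not in f:
                raise ContainerError(f"{path}: missing dataset /{name}")
        labels = tuple(s.decode() for s in f["region_labels"][()])
        rec = Recording(
            data=f["data"][()].astype(np.float64),
            fs=float(f["fs"][()]),
            region_labels=labels,
            subject=int(f.attrs.get("subject", 0)),
        )
    ev_path = events_path(path)
    events = pd.read_csv(ev_path) if ev_path.exists() else None
    return rec, events


def write_bands(path: str | Path, comps: BandComponents) -> None:
    with h5py.File(path, "a") as f:
        _check_version(f, path)
        if "bands" in f:
            del f["bands"]
        grp = f.create_group("bands")
        grp.attrs["edge_fraction"] = comps.edge_fraction
        for band in comps.amplitude:
            bg = grp.create_group(band)
            bg.create_dataset(
                "amplitude", data=comps.amplitude[band].astype(np.float32))
            bg.create_dataset(
                "phase", data=comps.phase[band].astype(np.float32))
            bg.create_dataset(
                "cos_phase", data=comps.cos_phase[band].astype(np.float32))


def read_bands(path: str | Path) -> BandComponents:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        if "bands" not in f:
            raise ContainerError(f"{path}: missing /bands group")
        labels = tuple(s.decode() for s in f["region_labels"][()])
        comps = BandComponents(
            fs=float(f["fs"][()]), region_labels=labels,
            edge_fraction=float(f["bands"].attrs["edge_fraction"]))
        for band in f["bands"]:
            bg = f["bands"][band]
            comps.amplitude[band] = bg["amplitude"][()].astype(np.float64)
            comps.phase[band] = bg["phase"][()].astype(np.float64)
            comps.cos_phase[band] = bg["cos_phase"][()].astype(np.float64)
        return comps


def write_imfs(path: str | Path, imfs_per_region: list[np.ndarray]) -> None:
    with h5py.File(path, "a") as f:
        _check_version(f, path)
        if "imfs" in f:
            del f["imfs"]
        labels = [s.decode() for s in f["region_labels"][()]]
        grp = f.create_group("imfs")
        for label, imfs in zip(labels, imfs_per_region):
            grp.create_dataset(label, data=imfs.astype(np.float32))


def write_expmse(path: str | Path, tensor: ComplexityTensor) -> None:
    with h5py.File(path, "a") as f:
        _check_version(f, path)
        if "expmse" in f:
            del f["expmse"]
        ds = f.create_dataset("expmse",
                              data=tensor.values.astype(np.float32))
        ds.attrs["columns"] = np.array(tensor.columns, dtype="S32")
        ds.attrs["bin_s"] = tensor.bin_s


def read_expmse(path: str | Path) -> ComplexityTensor:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        if "expmse" not in f:
            raise ContainerError(f"{path}: missing /expmse dataset")
        ds = f["expmse"]
        labels = tuple(s.decode() for s in f["region_labels"][()])
        return ComplexityTensor(
            values=ds[()].astype(np.float64),
            columns=tuple(s.decode() for s in ds.attrs["columns"]),
            region_labels=labels, bin_s=float(ds.attrs["bin_s"]))


def write_crops(path: str | Path, crop_set: CropSet) -> None:
    with h5py.File(path, "a") as f:
        _check_version(f, path)
        name = f"crops/{crop_set.kind}"
        if name in f:
            del f[name]
        grp = f.create_group(name)
        grp.create_dataset("data", data=crop_set.data.astype(np.float32))
        grp.create_dataset("labels",
                           data=np.array(crop_set.labels, dtype="S32"))
        grp.create_dataset("trial_id", data=crop_set.trial_ids)
        meta = crop_set.trial_meta
        for col in meta.columns:
            vals = meta[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S32")
            grp.create_dataset(f"meta_{col}", data=vals)


def read_crops(path: str | Path, kind: str) -> CropSet:
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        name = f"crops/{kind}"
        if name not in f:
            raise ContainerError(f"{path}: missing /{name}")
        grp = f[name]
        meta_cols = {}
        for key in grp:
            if key.startswith("meta_"):
                vals = grp[key][()]
                if vals.dtype.kind == "S":
                    vals = np.array([v.decode() for v in vals])
                meta_cols[key[5:]] = vals
        return CropSet(
            kind=kind, data=grp["data"][()].astype(np.float64),
            labels=np.array([s.decode() for s in grp["labels"][()]]),
            trial_ids=grp["trial_id"][()].astype(np.int64),
            trial_meta=pd.DataFrame(meta_cols))


__all__ = [
    "FORMAT_VERSION", "events_path", "write_subject", "read_subject",
    "write_bands", "read_bands", "write_imfs", "write_expmse",
    "read_expmse", "write_crops", "read_crops",
]
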