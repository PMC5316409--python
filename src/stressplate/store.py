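"""Persistence: HDF5 per-cell feature store, image frames, label masks.

The HDF5 layout is self-describing:

    /schema_version          (root attribute, integer)
    /plates/<plate>/wells/<well>/cells        per-cell records, fixed column order
    /plates/<plate>/wells/<well>/cells_columns  column names (attribute)

Write-then-read is an identity for the record tables; a store written by a
newer schema version is refused with an explicit message rather than
misread.  Image frames go to per-frame single-channel TIFFs named
``<plate>_<well>_t<index>_<channel>.tif``; label maps to 16-bit PNGs.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .quantify import WellFrameSet

SCHEMA_VERSION = 1

#: Columns persisted per cell record, in fixed order.
STORE_COLUMNS = [
    "frame",
    "time_h",
    "label",
    "track_id",
    "nucleus_area_px",
    "cell_area_px",
    "cytosol_area_px",
    "nuclear_mean_gfp",
    "cytosol_integrated_gfp",
    "cytosol_mean_gfp",
    "nuclear_foci_count",
    "cytosolic_foci_count",
    "is_dead",
]


class StoreError(IOError):
    """Raised on schema or integrity problems of a feature store."""


def write_feature_store(path: str | Path, records: dict[tuple[str, str], pd.DataFrame]) -> None:
    """Write per-(plate, well) cell-record tables to an HDF5 store."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_group("plates")
        for (plate, well), table in records.items():
            grp = f.require_group(f"plates/{plate}/wells/{well}")
            cols = [c for c in STORE_COLUMNS if c in table.columns]
            data = table[cols].copy()
            if "is_dead" in data.columns:
                # tri-state: -1 missing (pre-final frames), 0 alive, 1 dead
                data["is_dead"] = (
                    data["is_dead"].map({True: 1, False: 0}).fillna(-1).astype(np.int8)
                )
            arr = data.to_numpy(dtype=float)
            ds = grp.create_dataset("cells", data=arr)
            ds.attrs["columns"] = np.array(cols, dtype=h5py.string_dtype())


def read_feature_store(path: str | Path) -> dict[tuple[str, str], pd.DataFrame]:
    """Read a feature store back into per-(plate, well) tables."""
    out: dict[tuple[str, str], pd.DataFrame] = {}
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version > SCHEMA_VERSION:
            raise StoreError(
                f"store {path} was written by schema version {version}; this build "
                f"reads up to version {SCHEMA_VERSION}"
            )
        if version < 0:
            raise StoreError(f"store {path} carries no schema_version attribute")
        if "plates" not in f:
            raise StoreError(f"store {path}: missing group /plates")
        for plate in f["plates"]:
            wells_grp = f[f"plates/{plate}"]
            if "wells" not in wells_grp:
                raise StoreError(f"store {path}: missing group /plates/{plate}/wells")
            for well in wells_grp["wells"]:
                ds = wells_grp[f"wells/{well}/cells"]
                cols = [c for c in np.asarray(ds.attrs["columns"]).astype(str)]
                table = pd.DataFrame(np.asarray(ds), columns=cols)
                for c in ("frame", "label", "track_id", "nucleus_area_px", "cell_area_px",
                          "cytosol_area_px", "nuclear_foci_count", "cytosolic_foci_count"):
                    if c in table.columns:
                        table[c] = table[c].astype(int)
                if "is_dead" in table.columns:
                    table["is_dead"] = table["is_dead"].astype(int).map(
                        {1: True, 0: False, -1: pd.NA}
                    )
                out[(plate, well)] = table
    return out


def write_well_frames(directory: str | Path, wfs: WellFrameSet) -> list[Path]:
    """Write a well's frames as per-frame single-channel TIFFs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for t, frame in enumerate(wfs.frames):
        channels = {"nuclei": frame.nuclei, "gfp": frame.gfp}
        if frame.pi is not None:
            channels["pi"] = frame.pi
        for channel, img in channels.items():
            p = directory / f"{wfs.plate_id}_{wfs.well_id}_t{t:02d}_{channel}.tif"
            tifffile.imwrite(p, np.asarray(img))
            written.append(p)
    return written


def read_well_frames(directory: str | Path, plate: str, well: str) -> WellFrameSet:
    """Reassemble a WellFrameSet from per-frame TIFFs written by this module.

    Acquisition times are not stored in the TIFF names; frame indices are
    used as hour stand-ins unless a ``<plate>_<well>_times.tsv`` sidecar
    (columns frame, time_h) is present.
    """
    from .quantify import Frame

    directory = Path(directory)
    frames = []
    times = {}
    sidecar = directory / f"{plate}_{well}_times.tsv"
    if sidecar.exists():
        tdf = pd.read_csv(sidecar, sep="\t")
        times = dict(zip(tdf["frame"].astype(int), tdf["time_h"].astype(float)))
    t = 0
    while True:
        nuc = directory / f"{plate}_{well}_t{t:02d}_nuclei.tif"
        if not nuc.exists():
            break
        gfp = directory / f"{plate}_{well}_t{t:02d}_gfp.tif"
        pi = directory / f"{plate}_{well}_t{t:02d}_pi.tif"
        frames.append(
            Frame(
                time_h=times.get(t, float(t)),
                nuclei=tifffile.imread(nuc),
                gfp=tifffile.imread(gfp),
                pi=tifffile.imread(pi) if pi.exists() else None,
            )
        )
        t += 1
    if not frames:
        raise StoreError(f"no frames found for {plate}/{well} under {directory}")
    return WellFrameSet(plate_id=plate, well_id=well, frames=frames)


def write_times_sidecar(directory: str | Path, wfs: WellFrameSet) -> Path:
    p = Path(directory) / f"{wfs.plate_id}_{wfs.well_id}_times.tsv"
    pd.DataFrame(
        {"frame": range(len(wfs.frames)), "time_h": [f.time_h for f in wfs.frames]}
    ).to_csv(p, sep="\t", index=False)
    return p


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    """Store a label map as a 16-bit PNG for quality control."""
    lab = np.asarray(labels)
    if lab.max(initial=0) > np.iinfo(np.uint16).max:
        raise StoreError("label map exceeds the 16-bit PNG range")
    iio.imwrite(Path(path), lab.astype(np.uint16), extension=".png")


def read_label_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.int32)
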