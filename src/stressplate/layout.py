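"""Plate layouts: which well holds which reporter, treatment and replicate.

A layout is a tidy :class:`pandas.DataFrame` with one row per well and the
columns in :data:`LAYOUT_COLUMNS`.  Concentrations carry an explicit unit
string so that layouts written to disk stay self-describing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

LAYOUT_COLUMNS = [
    "plate",
    "well",
    "reporter",
    "treatment",
    "concentration",
    "conc_unit",
    "replicate",
    "is_dmso",
]

#: Treatment name used for vehicle-control wells throughout the package.
DMSO = "DMSO"


class LayoutError(ValueError):
    """Raised when a plate layout violates its invariants."""


def make_layout(
    plate: str,
    reporters: list[str],
    treatments: list[str],
    n_replicates: int = 3,
    concentration: float = 10.0,
    conc_unit: str = "uM",
    include_dmso: bool = True,
) -> pd.DataFrame:
    """Build a simple full-factorial layout for one plate.

    Wells are labelled ``A01``-style, row per reporter block, column per
    treatment × replicate.  DMSO control wells (concentration 0) are added
    for every reporter unless ``include_dmso`` is False.
    """
    rows = []
    all_treatments = ([DMSO] if include_dmso else []) + [t for t in treatments if t != DMSO]
    idx = 0
    for rp in reporters:
        for tr in all_treatments:
            for repl in range(1, n_replicates + 1):
                well = f"{chr(ord('A') + idx // 24)}{idx % 24 + 1:02d}"
                idx += 1
                is_dmso = tr == DMSO
                rows.append(
                    {
                        "plate": plate,
                        "well": well,
                        "reporter": rp,
                        "treatment": tr,
                        "concentration": 0.0 if is_dmso else concentration,
                        "conc_unit": conc_unit,
                        "replicate": repl,
                        "is_dmso": is_dmso,
                    }
                )
    if idx > 384:
        raise LayoutError(f"layout for plate {plate!r} needs {idx} wells; a plate has 384")
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def validate_layout(layout: pd.DataFrame, require_dmso: bool = True) -> pd.DataFrame:
    """Check layout invariants; returns the layout for chaining.

    Invariants: the required columns exist, (plate, well) pairs are unique,
    and — unless ``require_dmso`` is False — every plate × reporter group
    contains at least two DMSO control wells (the statistics stage needs
    replicate controls).
    """
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise LayoutError(f"layout is missing columns: {missing}")
    dup = layout.duplicated(subset=["plate", "well"])
    if dup.any():
        bad = layout.loc[dup, ["plate", "well"]].iloc[0]
        raise LayoutError(f"duplicate well {bad['well']!r} on plate {bad['plate']!r}")
    if require_dmso:
        for (plate, rp), grp in layout.groupby(["plate", "reporter"]):
            n_ctrl = int(grp["is_dmso"].sum())
            if n_ctrl < 2:
                raise LayoutError(
                    f"plate {plate!r} reporter {rp!r} has {n_ctrl} DMSO control wells; "
                    "at least 2 are required"
                )
    return layout


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited layout file and validate it."""
    df = pd.read_csv(path, sep="\t")
    if "is_dmso" in df.columns:
        df["is_dmso"] = df["is_dmso"].astype(bool)
    return validate_layout(df)


def write_layout(layout: pd.DataFrame, path: str | Path) -> None:
    """Write a layout as tab-delimited text with a header."""
    layout.to_csv(path, sep="\t", index=False)
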