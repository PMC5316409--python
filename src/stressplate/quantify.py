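"""Image quantification: nuclei, cells, foci, tracks, death calls, well curves.

The stage mirrors a classic high-content screening readout for closely
packed HepG2 nuclei:

1. watershed-masked nuclear segmentation — a watershed on the smoothed
   nuclear-stain image partitions the field into single-cell regions, then
   pixels inside each region are classified fore/background with a
   per-region Otsu threshold;
2. seeded cell/cytosol identification — an adaptive minimum-cross-entropy
   (Li) foreground mask on the GFP channel, with foreground pixels
   propagated to the nearest nuclear seed;
3. foci detection — prominence-based local maxima assigned to the parent
   region (nucleus for DNA-damage foci, cytosol for autophagosomal foci);
4. overlap-based tracking across frames;
5. intensity/area measurement and the propidium-iodide death call at the
   final time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_li, threshold_otsu
from skimage.segmentation import expand_labels, watershed

logger = logging.getLogger(__name__)

#: Per-cell measurement columns, in the fixed order used by the HDF5 store.
CELL_COLUMNS = [
    "label",
    "nucleus_area_px",
    "cell_area_px",
    "cytosol_area_px",
    "nuclear_mean_gfp",
    "cytosol_integrated_gfp",
    "cytosol_mean_gfp",
    "nuclear_foci_count",
    "cytosolic_foci_count",
]

#: Feature names summarize_well accepts (beyond the per-frame cell count).
WELL_FEATURES = [c for c in CELL_COLUMNS if c != "label"]


class QuantifyError(ValueError):
    """Raised on inconsistent inputs to the quantification stage."""


@dataclass
class Frame:
    """One acquisition time point of a well: channels share one pixel grid."""

    time_h: float
    nuclei: np.ndarray
    gfp: np.ndarray
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nuclei.ndim != 2 or self.gfp.shape != self.nuclei.shape:
            raise QuantifyError("nuclei and GFP images must be 2D and share a shape")
        if self.pi is not None and self.pi.shape != self.nuclei.shape:
            raise QuantifyError("PI image shape differs from the nuclei channel")


@dataclass
class WellFrameSet:
    """Ordered multi-channel frames of one well.

    The PI channel is optional except in the final frame, where the death
    call is made.
    """

    plate_id: str
    well_id: str
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [f.time_h for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise QuantifyError(
                f"well {self.well_id}: acquisition times must be strictly increasing"
            )
        shapes = {f.nuclei.shape for f in self.frames}
        if len(shapes) > 1:
            raise QuantifyError(f"well {self.well_id}: frames differ in image shape")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_h for f in self.frames], dtype=float)


# ---------------------------------------------------------------------------
# segmentation


def segment_nuclei(
    image: np.ndarray,
    smoothing_sigma: float = 1.5,
    min_area_px: int = 30,
    connectivity: int = 1,
    min_peak_distance: int = 6,
) -> np.ndarray:
    """Watershed-masked segmentation of a nuclear-stain image.

    Stage 1: a watershed on the smoothed image, seeded at local intensity
    maxima above the global Otsu level, partitions the field into
    single-nucleus regions (this is what separates touching nuclei).
    Stage 2: within each region, pixels are classified fore/background by a
    per-region Otsu threshold.  Objects below ``min_area_px`` are dropped
    and the survivors are relabelled 1..n in scan order.

    An empty or constant image yields an all-zero label map, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise QuantifyError("segment_nuclei expects a single-channel 2D image")
    if img.size == 0 or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)

    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    global_thr = threshold_otsu(smoothed)
    peaks = peak_local_max(
        smoothed,
        min_distance=min_peak_distance,
        threshold_abs=global_thr,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    regions = watershed(-smoothed, markers=markers, connectivity=connectivity)

    labels = np.zeros(img.shape, dtype=np.int32)
    for lab in range(1, len(peaks) + 1):
        mask = regions == lab
        vals = smoothed[mask]
        if np.ptp(vals) == 0:
            continue  # flat region: nothing to classify as foreground
        thr = threshold_otsu(vals)
        fg = mask & (smoothed > thr)
        if fg.sum() >= min_area_px:
            labels[fg] = lab
    return relabel_sequential_scan_order(labels)


def relabel_sequential_scan_order(labels: np.ndarray) -> np.ndarray:
    """Relabel objects 1..n ordered by first pixel in row-major scan order."""
    flat = labels.ravel()
    if not (flat > 0).any():
        return np.zeros_like(labels, dtype=np.int32)
    first_idx = {int(lab): int(np.argmax(flat == lab)) for lab in np.unique(flat) if lab > 0}
    ordered = sorted(first_idx, key=first_idx.get)
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    for new, old in enumerate(ordered, start=1):
        lut[old] = new
    return lut[labels]


# ---------------------------------------------------------------------------
# cell propagation


def adaptive_foreground(image: np.ndarray, window_px: int = 20) -> np.ndarray:
    """Adaptive minimum-cross-entropy foreground mask.

    Li (minimum cross entropy) thresholds are computed on a grid of
    ``window_px``-sized tiles; tiles whose contrast falls below 5 % of the
    image contrast fall back to the global Li threshold so that large
    uniform areas (all background, or the flat interior of a bright cell)
    are classified consistently.  A constant image has no foreground.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    global_thr = threshold_li(img)
    contrast_floor = 0.05 * np.ptp(img)
    thr_map = np.empty(img.shape, dtype=float)
    h, w = img.shape
    step = max(int(window_px), 4)
    for i0 in range(0, h, step):
        for j0 in range(0, w, step):
            tile = img[i0 : i0 + step, j0 : j0 + step]
            if np.ptp(tile) < contrast_floor:
                thr = global_thr
            else:
                thr = threshold_li(tile)
            thr_map[i0 : i0 + step, j0 : j0 + step] = thr
    return img > thr_map


def _nearest_seed_assignment(nuclei: np.ndarray) -> np.ndarray:
    """Assign every pixel to the Euclidean-nearest seed; ties to lower label."""
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    assign = np.zeros(nuclei.shape, dtype=np.int32)
    best = np.full(nuclei.shape, np.inf)
    for lab in labels:  # ascending: strict '<' keeps ties at the lower label
        d = ndi.distance_transform_edt(nuclei != lab)
        closer = d < best
        assign[closer] = lab
        best[closer] = d[closer]
    return assign


def propagate_cells(
    nuclei: np.ndarray,
    gfp_image: np.ndarray,
    window_px: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow cell regions from nuclear seeds over the GFP foreground.

    Returns ``(cell_labels, cytosol_labels)``.  Every cell is a superset of
    its nucleus (a cell with no GFP foreground equals its nucleus and has an
    empty cytosol).  Foreground pixels are assigned to the nearest seed;
    equidistant pixels go to the lower label, which keeps the output
    deterministic.
    """
    nuclei = np.asarray(nuclei)
    gfp = np.asarray(gfp_image, dtype=float)
    if gfp.shape != nuclei.shape:
        raise QuantifyError("GFP image shape differs from the nuclei label map")
    fg = adaptive_foreground(gfp, window_px=window_px) | (nuclei > 0)
    assign = _nearest_seed_assignment(nuclei)
    cell = np.where(fg, assign, 0).astype(np.int32)
    cell[nuclei > 0] = nuclei[nuclei > 0]
    nuc_labels = set(np.unique(nuclei[nuclei > 0]).tolist())
    cell_labels = set(np.unique(cell[cell > 0]).tolist())
    if not nuc_labels <= cell_labels:
        raise QuantifyError(
            f"internal consistency error: nuclei {sorted(nuc_labels - cell_labels)} "
            "absent from the cell map"
        )
    cytosol = np.where(nuclei == 0, cell, 0).astype(np.int32)
    return cell, cytosol


# ---------------------------------------------------------------------------
# foci


def detect_foci(
    gfp_image: np.ndarray,
    parent: np.ndarray,
    min_prominence: float,
    min_focus_px: int = 1,
    background_size: int = 11,
) -> pd.DataFrame:
    """Detect punctate foci and assign each to the parent region of its peak.

    The local background is the grey-scale morphological opening of the
    image with a ``background_size`` square (removing structures smaller
    than the window); a focus is a connected region of
    ``residual >= min_prominence / 2`` whose peak residual reaches
    ``min_prominence`` and whose area reaches ``min_focus_px``.  Foci whose
    peak pixel lies outside every parent region keep ``parent_label`` 0 and
    are excluded from per-cell counts downstream.
    """
    img = np.asarray(gfp_image, dtype=float)
    parent = np.asarray(parent)
    if parent.shape != img.shape:
        raise QuantifyError("parent label map shape differs from the image")
    cols = ["row", "col", "parent_label", "prominence", "area_px"]
    if img.size == 0 or np.ptp(img) == 0:
        return pd.DataFrame(columns=cols)
    background = ndi.grey_opening(img, size=background_size)
    resid = img - background
    candidates, n = ndi.label(resid >= min_prominence / 2.0)
    rows = []
    for lab in range(1, n + 1):
        mask = candidates == lab
        area = int(mask.sum())
        peak_flat = np.argmax(np.where(mask, resid, -np.inf))
        r, c = np.unravel_index(peak_flat, img.shape)
        prom = float(resid[r, c])
        if prom < min_prominence or area < min_focus_px:
            continue
        rows.append(
            {
                "row": int(r),
                "col": int(c),
                "parent_label": int(parent[r, c]),
                "prominence": prom,
                "area_px": area,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def foci_counts_per_parent(foci: pd.DataFrame) -> pd.Series:
    """Foci per parent label, discarding background foci (parent 0)."""
    inside = foci[foci["parent_label"] > 0]
    return inside.groupby("parent_label").size()


# ---------------------------------------------------------------------------
# tracking


def track_overlap(label_maps: list[np.ndarray]) -> pd.DataFrame:
    """Greedy maximum-pixel-overlap tracking of labels across frames.

    Consecutive frames are matched pair-by-pair: candidate (previous,
    current) label pairs are ranked by overlapping pixel count, ties broken
    toward the larger previous object and then the lower labels.  Unmatched
    current objects start new tracks; unmatched previous tracks terminate.

    Returns a DataFrame with columns ``frame``, ``label``, ``track_id``.
    """
    if len(label_maps) == 0:
        raise QuantifyError("track_overlap needs at least one frame")
    records: list[dict] = []
    next_track = 1
    prev_tracks: dict[int, int] = {}
    for t, lm in enumerate(label_maps):
        labels_here = np.unique(lm[lm > 0]).astype(int)
        tracks_here: dict[int, int] = {}
        if t > 0:
            prev = label_maps[t - 1]
            both = (prev > 0) & (lm > 0)
            pairs, counts = np.unique(
                np.stack([prev[both], lm[both]]), axis=1, return_counts=True
            )
            prev_areas = {
                int(lab): int((prev == lab).sum()) for lab in np.unique(prev[prev > 0])
            }
            order = sorted(
                range(pairs.shape[1]),
                key=lambda k: (
                    -counts[k],
                    -prev_areas[int(pairs[0, k])],
                    int(pairs[0, k]),
                    int(pairs[1, k]),
                ),
            )
            used_prev: set[int] = set()
            for k in order:
                p, c = int(pairs[0, k]), int(pairs[1, k])
                if p in used_prev or c in tracks_here or p not in prev_tracks:
                    continue
                tracks_here[c] = prev_tracks[p]
                used_prev.add(p)
        for lab in labels_here:
            if int(lab) not in tracks_here:
                tracks_here[int(lab)] = next_track
                next_track += 1
        for lab in labels_here:
            records.append({"frame": t, "label": int(lab), "track_id": tracks_here[int(lab)]})
        prev_tracks = tracks_here
    return pd.DataFrame(records, columns=["frame", "label", "track_id"])


# ---------------------------------------------------------------------------
# measurement


def measure_cells(
    nuclei: np.ndarray,
    cell: np.ndarray,
    cytosol: np.ndarray,
    gfp_image: np.ndarray,
    nuclear_foci: pd.DataFrame | None = None,
    cytosolic_foci: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell areas, GFP intensities and foci counts.

    nuclear_mean_gfp is the mean GFP over nucleus pixels;
    cytosol_integrated_gfp the sum over cytosol pixels (0 for an empty
    cytosol).  Foci tables, when given, must come from :func:`detect_foci`
    run with the matching parent maps.
    """
    gfp = np.asarray(gfp_image, dtype=float)
    for name, lm in (("nuclei", nuclei), ("cell", cell), ("cytosol", cytosol)):
        if np.asarray(lm).shape != gfp.shape:
            raise QuantifyError(f"{name} label map shape differs from the GFP image")
    labels = np.unique(cell[cell > 0]).astype(int)
    if labels.size == 0:
        return pd.DataFrame(columns=CELL_COLUMNS)
    n_max = int(labels.max())
    nuc_area = np.bincount(nuclei.ravel(), minlength=n_max + 1)
    cell_area = np.bincount(cell.ravel(), minlength=n_max + 1)
    cyt_area = np.bincount(cytosol.ravel(), minlength=n_max + 1)
    nuc_sum = np.bincount(nuclei.ravel(), weights=gfp.ravel(), minlength=n_max + 1)
    cyt_sum = np.bincount(cytosol.ravel(), weights=gfp.ravel(), minlength=n_max + 1)
    nfc = foci_counts_per_parent(nuclear_foci).to_dict() if nuclear_foci is not None else {}
    cfc = foci_counts_per_parent(cytosolic_foci).to_dict() if cytosolic_foci is not None else {}
    rows = []
    for lab in labels:
        na, ca, cya = int(nuc_area[lab]), int(cell_area[lab]), int(cyt_area[lab])
        rows.append(
            {
                "label": int(lab),
                "nucleus_area_px": na,
                "cell_area_px": ca,
                "cytosol_area_px": cya,
                "nuclear_mean_gfp": float(nuc_sum[lab] / na) if na else 0.0,
                "cytosol_integrated_gfp": float(cyt_sum[lab]),
                "cytosol_mean_gfp": float(cyt_sum[lab] / cya) if cya else 0.0,
                "nuclear_foci_count": int(nfc.get(lab, 0)),
                "cytosolic_foci_count": int(cfc.get(lab, 0)),
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


# ---------------------------------------------------------------------------
# death call


def flag_death(
    nuclei: np.ndarray,
    pi_image: np.ndarray,
    dilate_px: int = 2,
    area_ratio_min: float = 0.10,
    denominator: str = "dilated_nucleus",
    cell: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Propidium-iodide death call at the final time point.

    The PI foreground (per-image Otsu) is masked by each nucleus dilated by
    ``dilate_px`` pixels; the death-stain-to-area ratio is the masked PI
    pixel count divided by the dilated-nucleus area (or the full cell area
    with ``denominator='cell'``, which requires ``cell``).  A cell is dead
    iff the ratio is at least ``area_ratio_min`` (boundary inclusive).

    Returns a per-cell table and the dead fraction — ``None`` (missing, not
    0) when the frame holds no cells.
    """
    pi = np.asarray(pi_image, dtype=float)
    if pi.shape != np.asarray(nuclei).shape:
        raise QuantifyError("PI image shape differs from the nuclei label map")
    if denominator not in ("dilated_nucleus", "cell"):
        raise QuantifyError("denominator must be 'dilated_nucleus' or 'cell'")
    if denominator == "cell" and cell is None:
        raise QuantifyError("denominator='cell' requires the cell label map")
    labels = np.unique(nuclei[nuclei > 0]).astype(int)
    if labels.size == 0:
        return pd.DataFrame(columns=["label", "pi_ratio", "is_dead"]), None
    pi_fg = np.zeros(pi.shape, dtype=bool) if np.ptp(pi) == 0 else pi > threshold_otsu(pi)
    dilated = expand_labels(np.asarray(nuclei), distance=dilate_px)
    denom_map = dilated if denominator == "dilated_nucleus" else np.asarray(cell)
    n_max = int(labels.max())
    denom_area = np.bincount(denom_map.ravel(), minlength=n_max + 1)
    pi_in = np.bincount(
        np.where(pi_fg, dilated, 0).ravel(), minlength=n_max + 1
    )
    rows = []
    for lab in labels:
        denom = int(denom_area[lab])
        ratio = float(pi_in[lab] / denom) if denom else 0.0
        rows.append({"label": int(lab), "pi_ratio": ratio, "is_dead": ratio >= area_ratio_min})
    table = pd.DataFrame(rows, columns=["label", "pi_ratio", "is_dead"])
    return table, float(table["is_dead"].mean())


# ---------------------------------------------------------------------------
# well-level driver


@dataclass
class QuantifyParams:
    """Tunable knobs of the quantification stage (pixel units)."""

    smoothing_sigma: float = 1.5
    min_area_px: int = 30
    min_peak_distance: int = 6
    connectivity: int = 1
    window_px: int = 20
    foci_min_prominence: float = 2000.0
    foci_min_px: int = 1
    dilate_px: int = 2
    area_ratio_min: float = 0.10


def quantify_well(wfs: WellFrameSet, params: QuantifyParams | None = None) -> pd.DataFrame:
    """Run the full per-well quantification: one row per cell per frame.

    Adds ``frame``, ``time_h``, ``track_id`` and (final frame only)
    ``is_dead`` to the measurement columns.
    """
    params = params or QuantifyParams()
    if not wfs.frames:
        raise QuantifyError(f"well {wfs.well_id}: no frames")
    nuclei_maps = [
        segment_nuclei(
            f.nuclei,
            smoothing_sigma=params.smoothing_sigma,
            min_area_px=params.min_area_px,
            connectivity=params.connectivity,
            min_peak_distance=params.min_peak_distance,
        )
        for f in wfs.frames
    ]
    tracks = track_overlap(nuclei_maps)
    per_frame = []
    final = len(wfs.frames) - 1
    for t, (frame, nuc) in enumerate(zip(wfs.frames, nuclei_maps)):
        cell, cytosol = propagate_cells(nuc, frame.gfp, window_px=params.window_px)
        nuclear_foci = detect_foci(
            frame.gfp, nuc, params.foci_min_prominence, params.foci_min_px
        )
        cytosolic_foci = detect_foci(
            frame.gfp, cytosol, params.foci_min_prominence, params.foci_min_px
        )
        rec = measure_cells(nuc, cell, cytosol, frame.gfp, nuclear_foci, cytosolic_foci)
        rec.insert(0, "frame", t)
        rec.insert(1, "time_h", frame.time_h)
        rec = rec.merge(
            tracks[tracks["frame"] == t][["label", "track_id"]], on="label", how="left"
        )
        if t == final:
            if frame.pi is None:
                raise QuantifyError(
                    f"well {wfs.well_id}: final frame lacks the PI channel needed "
                    "for the death call"
                )
            death, _ = flag_death(
                nuc,
                frame.pi,
                dilate_px=params.dilate_px,
                area_ratio_min=params.area_ratio_min,
            )
            rec = rec.merge(death[["label", "is_dead"]], on="label", how="left")
        else:
            rec["is_dead"] = pd.NA
        per_frame.append(rec)
    out = pd.concat(per_frame, ignore_index=True)
    logger.info("well %s: %d cell records over %d frames", wfs.well_id, len(out), len(wfs.frames))
    return out


def summarize_well(records: pd.DataFrame, feature_name: str, times: np.ndarray) -> pd.DataFrame:
    """Per-frame mean of one feature over all cells: the well curve.

    Frames with no cells yield missing values that are kept in place so the
    time grid survives. ``feature_name`` may also be ``n_cells``.
    """
    valid = WELL_FEATURES + ["n_cells"]
    if feature_name not in valid:
        raise QuantifyError(
            f"unknown feature {feature_name!r}; valid features: {', '.join(valid)}"
        )
    if records.empty:
        raise QuantifyError("summarize_well needs at least one cell in at least one frame")
    times = np.asarray(times, dtype=float)
    values = np.full(len(times), np.nan)
    for t in range(len(times)):
        sub = records[records["frame"] == t]
        if len(sub) == 0:
            continue
        values[t] = float(len(sub)) if feature_name == "n_cells" else float(
            sub[feature_name].mean()
        )
    return pd.DataFrame({"time_h": times, "value": values})
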