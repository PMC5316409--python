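"""Synthetic stress-reporter plates with planted ground truth.

Emulates 384-well live-cell imaging plates of GFP pathway reporters, either
as raw three-channel image time-lapses (:func:`generate_plate_images`) or
directly as pre-quantified per-well feature curves
(:func:`generate_feature_curves`).

The generative model per well is

    value(t) = shift + scale * profile(t) * lognormal_noise

where ``profile`` is a piecewise log-linear fold-change template anchored at
onset/peak/decay times (a transient nuclear reporter such as Nrf2 rises
from ~2 h and returns to baseline; sustained cytosolic reporters such as
Srxn1 plateau; foci formers accumulate puncta; the null class is flat),
``shift``/``scale`` are plate-level batch effects, and the multiplicative
lognormal noise has unit mean and a configurable coefficient of variation.
Acquisition time grids are irregular and may differ between plates, as they
do between live-imaging sessions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .layout import DMSO, validate_layout
from .quantify import Frame, WellFrameSet

#: Tidy schema shared by raw and normalized curve tables.
CURVE_COLUMNS = [
    "plate",
    "well",
    "reporter",
    "treatment",
    "concentration",
    "replicate",
    "feature",
    "time_h",
    "value",
]

CLASS_NAMES = ("transient_nuclear", "sustained_cytosolic", "foci_forming", "null")

#: Default readout feature per reporter; unknown reporters fall back to
#: ``gfp_signal`` in curve mode.
DEFAULT_READOUTS = {
    "Nrf2": "nuclear_mean_gfp",
    "p53": "nuclear_mean_gfp",
    "p21": "nuclear_mean_gfp",
    "Xbp1": "nuclear_mean_gfp",
    "Atf4": "nuclear_mean_gfp",
    "Chop": "nuclear_mean_gfp",
    "Srxn1": "cytosol_integrated_gfp",
    "BiP": "cytosol_integrated_gfp",
    "Btg2": "cytosol_integrated_gfp",
    "Keap1": "cytosolic_foci_count",
    "53bp1": "nuclear_foci_count",
}


class SimulationError(ValueError):
    """Raised on invalid simulator configuration."""


@dataclass(frozen=True)
class DynamicClassSpec:
    """Fold-change template of one reporter dynamics class.

    ``amplitude`` is the peak fold-change over baseline (1 for the null
    class); ``noise_cv`` the coefficient of variation of the multiplicative
    lognormal noise.  The template rises log-linearly from 1 at ``onset_h``
    to ``amplitude`` at ``peak_h``; a transient class decays log-linearly
    back to 1 at ``decay_h`` while sustained and foci classes plateau.
    """

    class_name: str
    onset_h: float = 2.0
    peak_h: float = 8.0
    decay_h: float = 15.0
    amplitude: float = 4.0
    noise_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise SimulationError(
                f"unknown dynamics class {self.class_name!r}; choose from {CLASS_NAMES}"
            )
        if self.onset_h > self.peak_h:
            raise SimulationError("onset_h must not exceed peak_h")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be non-negative")
        if self.class_name == "null":
            if self.amplitude != 1:
                raise SimulationError("the null class has amplitude 1 by definition")
        elif self.amplitude < 1:
            raise SimulationError("amplitude must be >= 1 for responsive classes")
        if self.class_name == "transient_nuclear" and self.decay_h < self.peak_h:
            raise SimulationError("decay_h must not precede peak_h for a transient class")

    def profile(self, time_h: np.ndarray) -> np.ndarray:
        """Noiseless fold-change over baseline at the given times."""
        t = np.asarray(time_h, dtype=float)
        if self.class_name == "null" or self.amplitude == 1:
            return np.ones_like(t)
        log_a = np.log(self.amplitude)
        out = np.zeros_like(t)
        rise = (t > self.onset_h) & (t < self.peak_h)
        if self.peak_h > self.onset_h:
            out[rise] = log_a * (t[rise] - self.onset_h) / (self.peak_h - self.onset_h)
        out[t >= self.peak_h] = log_a
        if self.class_name == "transient_nuclear":
            fall = (t > self.peak_h) & (t < self.decay_h)
            if self.decay_h > self.peak_h:
                out[fall] = log_a * (self.decay_h - t[fall]) / (self.decay_h - self.peak_h)
            out[t >= self.decay_h] = 0.0
        return np.exp(out)


def default_time_grid(total_duration_h: float = 24.0) -> np.ndarray:
    """Irregular 13-point acquisition grid typical of an overnight session."""
    frac = np.array(
        [0, 0.02, 0.05, 0.085, 0.125, 0.19, 0.25, 0.33, 0.42, 0.54, 0.67, 0.83, 1.0]
    )
    return frac * total_duration_h


@dataclass(frozen=True)
class PlateEffect:
    """Plate-level batch effect and acquisition schedule.

    ``intensity_scale``/``intensity_shift`` act multiplicatively/additively
    on every well value of the plate; ``time_grid`` is the strictly
    increasing acquisition schedule spanning [0, total_duration_h].
    """

    intensity_scale: float = 1.0
    intensity_shift: float = 0.0
    time_grid: np.ndarray = field(default_factory=default_time_grid)
    total_duration_h: float = 24.0

    def __post_init__(self) -> None:
        if self.intensity_scale <= 0:
            raise SimulationError("intensity_scale must be positive")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise SimulationError("time_grid must be strictly increasing")
        if grid[0] < 0 or grid[-1] > self.total_duration_h:
            raise SimulationError("time_grid must lie within [0, total_duration_h]")
        object.__setattr__(self, "time_grid", grid)


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated plate set."""

    class_assignment: dict[str, DynamicClassSpec]
    expected_curves: pd.DataFrame
    nuclei_centers: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    foci_positions: pd.DataFrame | None = None
    death_labels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def death_fraction(self, plate: str, well: str) -> float | None:
        lab = self.death_labels.get((plate, well))
        if lab is None or len(lab) == 0:
            return None
        return float(np.mean(lab))


def child_seed(root_seed: int, plate: str, well: str) -> int:
    """Stable per-well seed: hash of (root seed, plate, well), < 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{plate}:{well}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _resolve_specs(layout: pd.DataFrame, specs: dict[str, DynamicClassSpec]) -> dict:
    resolved = dict(specs)
    if DMSO not in resolved:
        resolved[DMSO] = DynamicClassSpec("null", amplitude=1.0, noise_cv=0.2)
    missing = sorted(set(layout["treatment"]) - set(resolved))
    if missing:
        raise SimulationError(f"no DynamicClassSpec given for treatments {missing}")
    return resolved


# ---------------------------------------------------------------------------
# curve mode


def generate_feature_curves(
    layout: pd.DataFrame,
    specs: dict[str, DynamicClassSpec],
    effects: dict[str, PlateEffect],
    seed: int,
    readouts: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate pre-quantified per-well feature curves for all layout wells.

    Each well draws independent per-time-point lognormal noise from a seed
    hashed from (root seed, plate, well), so the noise stream depends on
    the well identity but not on the plate effect — rescaling a plate
    rescales its curves exactly.  Returns the tidy curve table and a
    :class:`GroundTruth` holding the noiseless expected curves.
    """
    validate_layout(layout)
    specs = _resolve_specs(layout, specs)
    readouts = {**DEFAULT_READOUTS, **(readouts or {})}
    missing_eff = sorted(set(layout["plate"]) - set(effects))
    if missing_eff:
        raise SimulationError(f"no PlateEffect given for plates {missing_eff}")
    rows: list[pd.DataFrame] = []
    expected: list[pd.DataFrame] = []
    for rec in layout.itertuples(index=False):
        eff = effects[rec.plate]
        spec = specs[rec.treatment]
        t = eff.time_grid
        base = spec.profile(t)
        rng = np.random.default_rng(child_seed(seed, rec.plate, rec.well))
        noise = _lognormal_factors(rng, spec.noise_cv, len(t))
        value = eff.intensity_shift + eff.intensity_scale * base * noise
        truth = eff.intensity_shift + eff.intensity_scale * base
        feature = readouts.get(rec.reporter, "gfp_signal")
        meta = {
            "plate": rec.plate,
            "well": rec.well,
            "reporter": rec.reporter,
            "treatment": rec.treatment,
            "concentration": rec.concentration,
            "replicate": rec.replicate,
            "feature": feature,
        }
        rows.append(pd.DataFrame({**meta, "time_h": t, "value": value}))
        expected.append(pd.DataFrame({**meta, "time_h": t, "value": truth}))
    curves = pd.concat(rows, ignore_index=True)[CURVE_COLUMNS]
    truth = GroundTruth(
        class_assignment=specs,
        expected_curves=pd.concat(expected, ignore_index=True)[CURVE_COLUMNS],
    )
    return curves, truth


# ---------------------------------------------------------------------------
# image mode


@dataclass(frozen=True)
class RenderParams:
    """Pixel-level rendering conventions (16-bit intensity range).

    Nuclei are Gaussian-blurred discs; the GFP channel renders uniform
    compartment fills (so mean compartment intensities equal the planted
    values exactly) plus square puncta for foci classes; the PI channel
    marks planted-dead cells with a blob covering their nucleus in the
    final frame only.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 25
    nucleus_radius_px: int = 8
    cell_radius_px: int = 14
    nuclei_intensity: float = 3000.0
    nuclei_background: float = 100.0
    blur_sigma: float = 1.5
    read_noise_sd: float = 5.0
    gfp_base: float = 1000.0
    gfp_background: float = 50.0
    foci_amplitude: float = 4000.0
    foci_half_size: int = 1
    max_foci: int = 5
    pi_intensity: float = 3000.0
    pi_background: float = 50.0


def _disc_mask(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_centers(
    shape: tuple[int, int],
    n: int,
    min_dist: float,
    margin: int,
    rng: np.random.Generator,
    well: str,
    max_tries_per_center: int = 400,
) -> np.ndarray:
    """Rejection-sample non-overlapping centers; too dense -> error."""
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries_per_center * n:
            raise SimulationError(
                f"well {well}: cannot place {n} nuclei at min distance "
                f"{min_dist:.0f}px in a {shape[0]}x{shape[1]} image — density too high"
            )
        r = int(rng.integers(margin, shape[0] - margin))
        c = int(rng.integers(margin, shape[1] - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist**2 for r0, c0 in centers):
            centers.append((r, c))
    return np.array(centers, dtype=int)


def _render_class(spec: DynamicClassSpec, readout: str) -> str:
    """Compartment to render: the class decides, null follows the reporter."""
    if spec.class_name != "null":
        return spec.class_name
    if "foci" in readout:
        return "foci_forming"
    if "cytosol" in readout:
        return "sustained_cytosolic"
    return "transient_nuclear"


def _planted_foci_count(spec: DynamicClassSpec, t: float, max_foci: int) -> int:
    if spec.amplitude <= 1:
        return 0
    frac = (spec.profile(np.array([t]))[0] - 1.0) / (spec.amplitude - 1.0)
    return int(round(frac * max_foci))


def generate_plate_images(
    layout: pd.DataFrame,
    specs: dict[str, DynamicClassSpec],
    effect: PlateEffect,
    seed: int,
    render: RenderParams | None = None,
    death_fraction: float = 0.0,
    readouts: dict[str, str] | None = None,
) -> tuple[dict[str, WellFrameSet], GroundTruth]:
    """Render three-channel time-lapses for every well of one plate.

    Returns ``(wells, truth)`` where ``wells`` maps well id to a
    :class:`~stressplate.quantify.WellFrameSet` and ``truth`` carries the
    planted nuclei centers, foci positions, death labels and the noiseless
    expected feature curves (compartment mean intensities and foci counts,
    which the renderer realizes exactly up to pixel noise).
    """
    validate_layout(layout)
    if (layout["plate"].nunique()) != 1:
        raise SimulationError("generate_plate_images renders one plate at a time")
    specs = _resolve_specs(layout, specs)
    readouts = {**DEFAULT_READOUTS, **(readouts or {})}
    render = render or RenderParams()
    if not 0.0 <= death_fraction <= 1.0:
        raise SimulationError("death_fraction must lie in [0, 1]")
    wells: dict[str, WellFrameSet] = {}
    expected: list[pd.DataFrame] = []
    foci_rows: list[dict] = []
    truth = GroundTruth(class_assignment=specs, expected_curves=pd.DataFrame())
    t_grid = effect.time_grid
    for rec in layout.itertuples(index=False):
        spec = specs[rec.treatment]
        readout = readouts.get(rec.reporter, "nuclear_mean_gfp")
        mode = _render_class(spec, readout)
        rng = np.random.default_rng(child_seed(seed, rec.plate, rec.well))
        if mode == "transient_nuclear":
            min_dist = 2 * (render.nucleus_radius_px + 2) + 2
            margin = render.nucleus_radius_px + 4
        else:
            min_dist = 2 * render.cell_radius_px + 2
            margin = render.cell_radius_px + 2
        centers = _place_centers(
            render.image_shape, render.n_cells, min_dist, margin, rng, rec.well
        )
        cell_factors = _lognormal_factors(rng, spec.noise_cv, len(centers))
        n_dead = int(round(death_fraction * len(centers)))
        dead = np.zeros(len(centers), dtype=bool)
        if n_dead:
            dead[rng.choice(len(centers), size=n_dead, replace=False)] = True
        truth.nuclei_centers[(rec.plate, rec.well)] = centers
        truth.death_labels[(rec.plate, rec.well)] = dead

        nuc_mask_img = np.zeros(render.image_shape, dtype=float)
        for r, c in centers:
            nuc_mask_img[_disc_mask(render.image_shape, (r, c), render.nucleus_radius_px)] = 1.0
        nuc_blur = ndi.gaussian_filter(nuc_mask_img, render.blur_sigma)

        profile = spec.profile(t_grid)
        frames: list[Frame] = []
        exp_vals = np.empty(len(t_grid))
        for ti, (t, fold) in enumerate(zip(t_grid, profile)):
            nuclei = (
                render.nuclei_background
                + render.nuclei_intensity * nuc_blur
                + rng.normal(0.0, render.read_noise_sd, render.image_shape)
            )
            gfp = np.full(render.image_shape, render.gfp_background, dtype=float)
            level = effect.intensity_shift + effect.intensity_scale * render.gfp_base * fold
            if mode == "transient_nuclear":
                for k, (r, c) in enumerate(centers):
                    m = _disc_mask(
                        render.image_shape, (r, c), render.nucleus_radius_px + 2
                    )
                    gfp[m] = level * cell_factors[k]
                exp_vals[ti] = level
                feature = "nuclear_mean_gfp"
            elif mode == "sustained_cytosolic":
                for k, (r, c) in enumerate(centers):
                    m = _disc_mask(render.image_shape, (r, c), render.cell_radius_px)
                    gfp[m] = level * cell_factors[k]
                exp_vals[ti] = level
                feature = "cytosol_mean_gfp"
            else:  # foci_forming
                for r, c in centers:
                    m = _disc_mask(render.image_shape, (r, c), render.cell_radius_px)
                    gfp[m] = render.gfp_base
                k_foci = _planted_foci_count(spec, t, render.max_foci)
                hs = render.foci_half_size
                for idx, (r, c) in enumerate(centers):
                    for j in range(k_foci):
                        ang = 2 * np.pi * j / max(render.max_foci, 1)
                        rad = render.nucleus_radius_px + 3
                        fr = int(round(r + rad * np.sin(ang)))
                        fc = int(round(c + rad * np.cos(ang)))
                        gfp[fr - hs : fr + hs + 1, fc - hs : fc + hs + 1] += (
                            render.foci_amplitude
                        )
                        foci_rows.append(
                            {
                                "plate": rec.plate,
                                "well": rec.well,
                                "frame": ti,
                                "row": fr,
                                "col": fc,
                                "parent_index": idx,
                            }
                        )
                exp_vals[ti] = k_foci
                feature = "cytosolic_foci_count"
            pi = None
            if ti == len(t_grid) - 1:
                pi = np.full(render.image_shape, render.pi_background, dtype=float)
                for k, (r, c) in enumerate(centers):
                    if dead[k]:
                        pi[
                            _disc_mask(render.image_shape, (r, c), render.nucleus_radius_px)
                        ] = render.pi_intensity
                pi = np.clip(pi, 0, 65535).astype(np.uint16)
            frames.append(
                Frame(
                    time_h=float(t),
                    nuclei=np.clip(nuclei, 0, 65535).astype(np.uint16),
                    gfp=np.clip(gfp, 0, 65535).astype(np.uint16),
                    pi=pi,
                )
            )
        wells[rec.well] = WellFrameSet(plate_id=rec.plate, well_id=rec.well, frames=frames)
        expected.append(
            pd.DataFrame(
                {
                    "plate": rec.plate,
                    "well": rec.well,
                    "reporter": rec.reporter,
                    "treatment": rec.treatment,
                    "concentration": rec.concentration,
                    "replicate": rec.replicate,
                    "feature": feature,
                    "time_h": t_grid,
                    "value": exp_vals,
                }
            )
        )
    truth.expected_curves = pd.concat(expected, ignore_index=True)[CURVE_COLUMNS]
    truth.foci_positions = pd.DataFrame(
        foci_rows, columns=["plate", "well", "frame", "row", "col", "parent_index"]
    )
    return wells, truth
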