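"""End-to-end pipeline: simulate → quantify → normalize → stats → cluster.

Every stage writes tab-delimited artifacts into the run directory and the
run ends with a ``manifest.json`` carrying the config hash, seed, package
version and per-stage row counts, so a rerun with the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import cubic_cluster, curve_distance_cube, endpoint_cluster
from .config import RunConfig
from .layout import DMSO, make_layout, write_layout
from .normalize import normalize_curves
from .quantify import QuantifyParams, quantify_well, summarize_well
from .stats import stat_table
from .store import write_feature_store, write_times_sidecar, write_well_frames
from .synthetic import (
    CURVE_COLUMNS,
    DEFAULT_READOUTS,
    DynamicClassSpec,
    PlateEffect,
    RenderParams,
    default_time_grid,
    generate_feature_curves,
    generate_plate_images,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _specs_from_config(cfg: RunConfig) -> dict[str, DynamicClassSpec]:
    specs = {
        name: DynamicClassSpec(
            class_name=tc.class_name,
            onset_h=tc.onset_h,
            peak_h=tc.peak_h,
            decay_h=tc.decay_h,
            amplitude=tc.amplitude,
            noise_cv=tc.noise_cv,
        )
        for name, tc in cfg.simulate.treatments.items()
    }
    return specs


def _layout_and_effects(cfg: RunConfig):
    layouts = []
    effects = {}
    for pc in cfg.simulate.plates:
        layouts.append(
            make_layout(
                pc.plate_id,
                reporters=cfg.simulate.reporters,
                treatments=list(cfg.simulate.treatments),
                n_replicates=cfg.simulate.n_replicates,
                concentration=cfg.simulate.concentration,
            )
        )
        effects[pc.plate_id] = PlateEffect(
            intensity_scale=pc.intensity_scale,
            intensity_shift=pc.intensity_shift,
            time_grid=default_time_grid(pc.total_duration_h),
            total_duration_h=pc.total_duration_h,
        )
    return pd.concat(layouts, ignore_index=True), effects


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    layout, effects = _layout_and_effects(cfg)
    specs = _specs_from_config(cfg)
    curves = None

    if "simulate" in cfg.stages:
        try:
            write_layout(layout, outdir / "layout.tsv")
            if cfg.simulate.mode == "curves":
                curves, truth = generate_feature_curves(layout, specs, effects, cfg.seed)
                _write_tsv(curves, outdir / "curves.tsv")
                _write_tsv(truth.expected_curves, outdir / "expected_curves.tsv")
                counts["simulate"] = len(curves)
            else:
                render = RenderParams(n_cells=cfg.simulate.n_cells)
                img_dir = outdir / "images"
                truth_curves = []
                for pc in cfg.simulate.plates:
                    sub = layout[layout["plate"] == pc.plate_id]
                    wells, truth = generate_plate_images(
                        sub,
                        specs,
                        effects[pc.plate_id],
                        cfg.seed,
                        render=render,
                        death_fraction=cfg.simulate.death_fraction,
                    )
                    for wfs in wells.values():
                        write_well_frames(img_dir, wfs)
                        write_times_sidecar(img_dir, wfs)
                    truth_curves.append(truth.expected_curves)
                expected = pd.concat(truth_curves, ignore_index=True)
                _write_tsv(expected, outdir / "expected_curves.tsv")
                counts["simulate"] = len(expected)
        except Exception as err:  # noqa: BLE001 — re-raised with the stage name
            raise StageError("simulate", err) from err

    if "quantify" in cfg.stages or (
        "simulate" in cfg.stages and cfg.simulate.mode == "images"
    ):
        try:
            from .store import read_well_frames

            img_dir = outdir / "images"
            params = QuantifyParams()
            records = {}
            curve_rows = []
            for rec in layout.drop_duplicates(["plate", "well"]).itertuples(index=False):
                wfs = read_well_frames(img_dir, rec.plate, rec.well)
                table = quantify_well(wfs, params)
                records[(rec.plate, rec.well)] = table
                feature = DEFAULT_READOUTS.get(rec.reporter, "nuclear_mean_gfp")
                curve = summarize_well(table, feature, wfs.times)
                curve_rows.append(
                    curve.assign(
                        plate=rec.plate,
                        well=rec.well,
                        reporter=rec.reporter,
                        treatment=rec.treatment,
                        concentration=rec.concentration,
                        replicate=rec.replicate,
                        feature=feature,
                    )[CURVE_COLUMNS]
                )
            write_feature_store(outdir / "features.h5", records)
            curves = pd.concat(curve_rows, ignore_index=True)
            _write_tsv(curves, outdir / "curves.tsv")
            counts["quantify"] = sum(len(t) for t in records.values())
        except Exception as err:  # noqa: BLE001
            raise StageError("quantify", err) from err

    normalized = fit_info = None
    if "normalize" in cfg.stages:
        try:
            if curves is None:
                curves = pd.read_csv(outdir / "curves.tsv", sep="\t")
            normalized, fit_info = normalize_curves(
                curves,
                df=cfg.normalize.df,
                n_out=cfg.normalize.n_out,
                scaling=cfg.normalize.scaling,
                quantile=cfg.normalize.quantile,
            )
            _write_tsv(normalized, outdir / "normalized_curves.tsv")
            _write_tsv(fit_info, outdir / "fit_info.tsv")
            counts["normalize"] = len(normalized)
        except Exception as err:  # noqa: BLE001
            raise StageError("normalize", err) from err

    stats_out = None
    if "stats" in cfg.stages:
        try:
            if normalized is None:
                normalized = pd.read_csv(outdir / "normalized_curves.tsv", sep="\t")
                fit_info = pd.read_csv(outdir / "fit_info.tsv", sep="\t")
            stats_out = stat_table(
                normalized,
                fit_info,
                variant=cfg.stats.variant,
                df_tp=cfg.normalize.n_out,
                meandiff_on=cfg.stats.meandiff_on,
            )
            _write_tsv(stats_out, outdir / "stats.tsv")
            counts["stats"] = len(stats_out)
        except Exception as err:  # noqa: BLE001
            raise StageError("stats", err) from err

    if "cluster" in cfg.stages:
        try:
            if normalized is None:
                normalized = pd.read_csv(outdir / "normalized_curves.tsv", sep="\t")
            treated = normalized[normalized["treatment"] != DMSO]
            cube = curve_distance_cube(
                treated, compare_axis=cfg.cluster.compare_axis, metric=cfg.cluster.metric
            )
            mean_df = pd.DataFrame(
                cube.mean_matrix, index=cube.entities, columns=cube.entities
            )
            mean_df.index.name = cfg.cluster.compare_axis
            mean_df.reset_index().to_csv(
                outdir / "mean_distances.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            result, flat = cubic_cluster(
                cube, linkage=cfg.cluster.linkage, n_clusters=cfg.cluster.n_clusters
            )
            link_df = pd.DataFrame(
                result.linkage, columns=["child_a", "child_b", "height", "n_members"]
            )
            _write_tsv(link_df, outdir / "linkage.tsv")
            (outdir / "dendrogram.nwk").write_text(result.to_newick() + "\n")
            if flat is not None:
                flat.rename_axis(cfg.cluster.compare_axis).reset_index().to_csv(
                    outdir / "clusters.tsv", sep="\t", index=False
                )
            if stats_out is not None and not stats_out.empty:
                endpoint = stats_out.assign(
                    meanDiff=stats_out[
                        [c for c in stats_out.columns if c.startswith("meanDiff_r")]
                    ].mean(axis=1)
                ).pivot_table(
                    index="treatment", columns="reporter", values="meanDiff", sort=True
                )
                ep = endpoint_cluster(
                    endpoint, metric=cfg.cluster.metric, linkage=cfg.cluster.linkage
                )
                (outdir / "endpoint_dendrogram.nwk").write_text(ep.to_newick() + "\n")
            counts["cluster"] = len(cube.entities)
        except Exception as err:  # noqa: BLE001
            raise StageError("cluster", err) from err

    manifest = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "stages": cfg.stages,
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    cfg.to_yaml(outdir / "config.yaml")
    logger.info("pipeline complete: %s", counts)
    return manifest
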