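"""Stage driver tying simulation, segmentation, quantification and screening.

Each stage writes plain-text/TIFF artifacts into an output directory; every
CSV carries a header comment with the package version and a hash of the
generating config, so any table can be traced back to its run. All
randomness flows from the single config seed, and re-running with the same
config reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .containers import FieldImage
from .errors import ConfigurationError
from .plate import write_plate_map
from .quantify import classify_sg_positive, measure_cells, normalize_to_control, summarize_well
from .screen import CascadeParams, control_noise_floor, run_cascade
from .segmentation import segment_field
from .synthetic import generate_field, generate_screen, make_library

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "quantify", "screen", "all")

__all__ = ["run_pipeline", "screen_well_table", "write_csv", "STAGES"]


def write_csv(df: pd.DataFrame, path: str | Path, meta: str) -> None:
    """Write a CSV with a provenance header comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# sgscreen {__version__} {meta}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def screen_well_table(
    wells: pd.DataFrame,
    p: CascadeParams | None = None,
    readout: str = "count",
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Normalize a per-well readout table plate-by-plate and run the cascade.

    ``wells`` needs columns ``plate_id, well_id, role, compound_id, dose_um``
    plus the readout columns (``cell_count``, ``fus_granules_per_cell`` /
    ``venus_cyto_intensity_mean``, ``g3bp1_granules_per_cell`` /
    ``mcherry_cyto_intensity_mean``). The FUS/G3BP1 screen readout is the
    per-cell granule count by default (``readout="count"``) or the summed
    cytosolic vesicle intensity per cell (``readout="intensity"``).

    Returns (per-compound results, funnel counts, normalized well table).
    """
    p = p or CascadeParams()
    if readout == "count":
        fus_col, g3_col = "fus_granules_per_cell", "g3bp1_granules_per_cell"
    elif readout == "intensity":
        fus_col, g3_col = "venus_cyto_intensity_mean", "mcherry_cyto_intensity_mean"
    else:
        raise ConfigurationError(f"unknown readout {readout!r}")

    norm_frames = []
    for plate_id, grp in wells.groupby("plate_id", sort=False):
        ctrl = grp.loc[grp["role"] == "control", "well_id"].tolist()
        if not ctrl:
            raise ConfigurationError(f"plate {plate_id}: no control wells")
        norm_frames.append(
            normalize_to_control(grp, ctrl, readouts=["cell_count", fus_col, g3_col])
        )
    norm = pd.concat(norm_frames, ignore_index=True)
    norm = norm.rename(
        columns={
            "cell_count_pct": "viability_pct",
            f"{fus_col}_pct": "fus_pct",
            f"{g3_col}_pct": "g3bp1_pct",
        }
    )

    cmp_rows = norm[norm["role"] == "compound"]
    primary = cmp_rows[np.isclose(cmp_rows["dose_um"], p.primary_dose)]
    primary = primary[["compound_id", "viability_pct", "fus_pct", "g3bp1_pct"]]
    dose_data = cmp_rows[["compound_id", "dose_um", "viability_pct", "fus_pct", "g3bp1_pct"]]
    have_doses = {round(float(d), 9) for d in cmp_rows["dose_um"]}
    full_series = {round(float(d), 9) for d in p.doses} <= have_doses
    ctrl_inhib = 100.0 - norm.loc[norm["role"] == "control", "fus_pct"].to_numpy()
    floor = max(control_noise_floor(ctrl_inhib), p.min_fit_quality)
    results, funnel = run_cascade(
        primary, dose_data if full_series else None, p, noise_floor=floor
    )
    return results, funnel, norm


def run_pipeline(cfg: PipelineConfig, stage: str, out_dir: str | Path) -> dict:
    """Run one stage (or ``all``) of the pipeline, writing artifacts to disk.

    Returns a small dict of the main counts produced (for logging/tests).
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = f"config={config_hash(cfg)} seed={cfg.seed}"
    info: dict = {}

    if stage in ("segment", "quantify") and cfg.tier != "image":
        raise ConfigurationError(f"stage {stage!r} requires tier: image")
    if stage in ("simulate", "all"):
        info.update(_stage_simulate(cfg, out, meta))
    if cfg.tier == "image" and stage in ("segment", "quantify", "all"):
        info.update(_stage_segment_quantify(cfg, out, meta, quantify=stage != "segment"))
    if stage == "screen" or (stage == "all" and cfg.tier == "tabular"):
        info.update(_stage_screen(cfg, out, meta))
    return info


def _stage_simulate(cfg: PipelineConfig, out: Path, meta: str) -> dict:
    cond = cfg.condition_spec()
    if cfg.tier == "image":
        ss = np.random.SeedSequence(cfg.seed)
        children = ss.spawn(cfg.n_fields)
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        cells_frames, gran_frames = [], []
        for i, child in enumerate(children):
            fid = f"f{i + 1}"
            fimg, gt = generate_field(cond, child, cfg.geometry, field_id=fid)
            fimg.to_tiff(img_dir / f"{fid}.tif")
            for frame, coll in ((gt.cells, cells_frames), (gt.granules, gran_frames)):
                frame = frame.copy()
                frame.insert(0, "field_id", fid)
                coll.append(frame)
        write_csv(pd.concat(cells_frames, ignore_index=True), out / "truth_cells.csv", meta)
        write_csv(pd.concat(gran_frames, ignore_index=True), out / "truth_granules.csv", meta)
        return {"n_fields": cfg.n_fields}

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    lib = make_library(
        rng,
        n_true_hit=cfg.library.n_true_hit,
        n_disruptor=cfg.library.n_disruptor,
        n_toxic=cfg.library.n_toxic,
        n_inactive=cfg.library.n_inactive,
    )
    cond = dataclasses.replace(cfg.condition_spec(), n_cells=cfg.cells_per_well)
    ds = generate_screen(
        lib, cond, doses=list(cfg.cascade.doses), seed=cfg.seed,
        n_controls=cfg.n_controls,
    )
    write_csv(ds.wells, out / "wells.csv", meta)
    write_csv(ds.truth, out / "screen_truth.csv", meta)
    write_plate_map(ds.layouts, out / "platemap.csv")
    return {"n_wells": len(ds.wells)}


def _stage_segment_quantify(cfg: PipelineConfig, out: Path, meta: str, quantify: bool) -> dict:
    img_dir = out / "images"
    paths = sorted(img_dir.glob("*.tif"))
    if not paths:
        raise ConfigurationError(f"no field TIFFs found under {img_dir}")
    label_dir = out / "labels"
    link_frames, cell_frames = [], []
    for path in paths:
        fid = path.stem
        fimg = FieldImage.from_tiff(path, field_id=fid)
        labels = segment_field(fimg, cfg.seg)
        labels.write_tiffs(label_dir, fid)
        link = labels.linkage.copy()
        link.insert(0, "field_id", fid)
        link_frames.append(link)
        if quantify:
            cells = classify_sg_positive(measure_cells(fimg, labels, cfg.seg))
            cells.insert(0, "field_id", fid)
            cell_frames.append(cells)
    write_csv(pd.concat(link_frames, ignore_index=True), out / "linkage.csv", meta)
    info = {"n_fields_segmented": len(paths)}
    if quantify:
        cells_df = pd.concat(cell_frames, ignore_index=True)
        write_csv(cells_df, out / "cells.csv", meta)
        wells = pd.DataFrame(
            [summarize_well(g, fid) for fid, g in cells_df.groupby("field_id")]
        )
        write_csv(wells, out / "field_summaries.csv", meta)
        info["n_cells"] = int(len(cells_df))
    return info


def _stage_screen(cfg: PipelineConfig, out: Path, meta: str) -> dict:
    wells_path = out / "wells.csv"
    if not wells_path.exists():
        raise ConfigurationError(f"missing input {wells_path}; run simulate first")
    wells = read_csv(wells_path)
    results, funnel, norm = screen_well_table(wells, cfg.cascade, cfg.readout)
    write_csv(results, out / "results.csv", meta)
    write_csv(norm, out / "wells_normalized.csv", meta)
    funnel_df = pd.DataFrame([funnel])
    write_csv(funnel_df, out / "funnel.csv", meta)
    return dict(funnel)
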