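"""Per-cell granule measurements, SG-positivity calls and well aggregation.

The central quantity is the *vesicle intensity per cell*: the integrated
(background-subtracted) intensity of every granule linked to a cell, split
into a nuclear and a cytosolic part by the decomposition

    cytosolic vesicle intensity = total vesicle intensity
                                  - nuclear vesicle intensity

which holds exactly, per cell and channel, by construction. Granule counts
are decomposed the same way. Well-level readouts are means and positive-cell
fractions, expressed as percent of the same-plate stimulus-control mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import REPORTER_CHANNELS, FieldImage, LabelSet
from .errors import NormalizationError
from .segmentation import SegParams, background_subtracted

__all__ = [
    "measure_cells",
    "classify_sg_positive",
    "colocalization_fraction",
    "summarize_well",
    "normalize_to_control",
    "CELL_COLUMNS",
]

#: per-cell measurement columns, per reporter channel
_PER_CHANNEL = [
    "total_intensity", "nuclear_intensity", "cytosolic_intensity",
    "cytosolic_granule_count", "nuclear_granule_count",
]
CELL_COLUMNS = ["cell_id"] + [
    f"{chan}_{m}" for chan in REPORTER_CHANNELS for m in _PER_CHANNEL
] + ["fus_sg_positive", "g3bp1_sg_positive"]


def measure_cells(
    field: FieldImage, labels: LabelSet, p: SegParams | None = None
) -> pd.DataFrame:
    """Per-cell vesicle intensities and granule counts (Step 4).

    For every cell and reporter channel, the total vesicle intensity is the
    sum of the integrated background-subtracted intensities of its linked
    granules; the nuclear part sums the granules whose pixel majority lies
    in the nucleus, and the cytosolic part is total minus nuclear, exactly.
    Cells without granules get zeros. Returns one row per cell (positivity
    flags are initialised to False; see :func:`classify_sg_positive`).
    """
    if labels.linkage is None:
        raise ValueError("LabelSet has no linkage table; run segmentation first")
    p = p or SegParams()
    cell_ids = np.unique(labels.cell)
    cell_ids = cell_ids[cell_ids > 0]
    out = pd.DataFrame({"cell_id": cell_ids.astype(int)})
    for col in CELL_COLUMNS[1:]:
        out[col] = 0.0
    out[["fus_sg_positive", "g3bp1_sg_positive"]] = False

    for chan in REPORTER_CHANNELS:
        if chan not in labels.granules:
            continue
        gmap = labels.granules[chan]
        dome = background_subtracted(field[chan], p)
        # integrated intensity of every granule = sum of the
        # background-subtracted image over its pixel mask
        sums = np.bincount(
            gmap.ravel(), weights=dome.ravel(), minlength=int(gmap.max()) + 1
        )
        link = labels.linkage
        link = link[(link["channel"] == chan) & (link["cell_id"] > 0)]
        total = np.zeros(len(out))
        nuclear = np.zeros(len(out))
        c_count = np.zeros(len(out))
        n_count = np.zeros(len(out))
        pos = {cid: i for i, cid in enumerate(out["cell_id"])}
        for rec in link.itertuples():
            i = pos.get(int(rec.cell_id))
            if i is None:
                continue
            inten = float(sums[int(rec.granule_id)])
            total[i] += inten
            if rec.in_nucleus:
                nuclear[i] += inten
                n_count[i] += 1
            else:
                c_count[i] += 1
        out[f"{chan}_total_intensity"] = total
        out[f"{chan}_nuclear_intensity"] = nuclear
        out[f"{chan}_cytosolic_intensity"] = total - nuclear
        out[f"{chan}_cytosolic_granule_count"] = c_count
        out[f"{chan}_nuclear_granule_count"] = n_count
    return out


def classify_sg_positive(
    cells: pd.DataFrame,
    min_cyto_granules: int = 1,
    min_cyto_intensity: float = 0.0,
) -> pd.DataFrame:
    """Flag cells containing cytosolic stress granules.

    A cell is FUS-SG positive iff its Venus-channel cytosolic granule count
    is >= ``min_cyto_granules`` and its cytosolic vesicle intensity is
    >= ``min_cyto_intensity``; G3BP1 positivity is the same rule on the
    mCherry channel. Returns a copy with the flags set.
    """
    if min_cyto_granules < 0 or min_cyto_intensity < 0:
        raise ValueError("thresholds must be >= 0")
    out = cells.copy()
    for chan, flag in (("venus", "fus_sg_positive"), ("mcherry", "g3bp1_sg_positive")):
        out[flag] = (
            (out[f"{chan}_cytosolic_granule_count"] >= min_cyto_granules)
            & (out[f"{chan}_cytosolic_intensity"] >= min_cyto_intensity)
        )
    return out


def colocalization_fraction(
    granules_a: np.ndarray, granules_b: np.ndarray, min_overlap: float = 0.5
) -> float:
    """Fraction of granules in ``a`` overlapping any granule in ``b``.

    A granule in ``a`` counts as colocalized when at least ``min_overlap``
    of its own pixels fall on foreground of ``b``. Returns NaN (with a
    warning) when ``a`` has no granules.
    """
    granules_a = np.asarray(granules_a)
    granules_b = np.asarray(granules_b)
    if granules_a.shape != granules_b.shape:
        raise ValueError("label maps must share shape")
    ids = np.unique(granules_a)
    ids = ids[ids > 0]
    if len(ids) == 0:
        warnings.warn("colocalization undefined: no granules in reference map")
        return float("nan")
    b_fg = granules_b > 0
    areas = np.bincount(granules_a.ravel(), minlength=ids.max() + 1)
    overlaps = np.bincount(
        granules_a.ravel(), weights=b_fg.ravel(), minlength=ids.max() + 1
    )
    frac = overlaps[ids] / areas[ids]
    return float(np.mean(frac >= min_overlap))


def summarize_well(cells: pd.DataFrame, well_id: str) -> dict:
    """Aggregate per-cell records to one well summary row.

    Zero-cell wells report ``cell_count`` 0 with NaN readouts and
    ``flagged_empty`` True so downstream viability filtering can fail them
    explicitly.
    """
    n = len(cells)
    row: dict = {"well_id": well_id, "cell_count": n, "flagged_empty": n == 0}
    readouts = {
        "fus_sg_fraction": "fus_sg_positive",
        "g3bp1_sg_fraction": "g3bp1_sg_positive",
        "fus_granules_per_cell": "venus_cytosolic_granule_count",
        "g3bp1_granules_per_cell": "mcherry_cytosolic_granule_count",
        "venus_cyto_intensity_mean": "venus_cytosolic_intensity",
        "venus_nuclear_intensity_mean": "venus_nuclear_intensity",
        "mcherry_cyto_intensity_mean": "mcherry_cytosolic_intensity",
    }
    for name, col in readouts.items():
        row[name] = float(cells[col].mean()) if n else float("nan")
    return row


def normalize_to_control(
    wells: pd.DataFrame,
    control_ids: list[str],
    readouts: list[str] | None = None,
    id_col: str = "well_id",
) -> pd.DataFrame:
    """Express well readouts as percent of the control-well mean.

    Adds a ``<readout>_pct`` column per readout; the mean over control wells
    maps to exactly 100 by construction. Controls with zero cells are
    excluded from the reference mean; if none remain a
    :class:`NormalizationError` is raised.
    """
    if readouts is None:
        readouts = [
            c for c in (
                "cell_count", "fus_sg_fraction", "g3bp1_sg_fraction",
                "fus_granules_per_cell", "g3bp1_granules_per_cell",
                "venus_cyto_intensity_mean", "mcherry_cyto_intensity_mean",
            ) if c in wells.columns
        ]
    ctrl = wells[wells[id_col].isin(control_ids) & (wells["cell_count"] > 0)]
    if ctrl.empty:
        raise NormalizationError("no control wells with cells > 0")
    out = wells.copy()
    for col in readouts:
        ref = float(ctrl[col].mean())
        if not np.isfinite(ref) or ref == 0:
            raise NormalizationError(f"control mean of {col!r} is {ref}")
        out[f"{col}_pct"] = 100.0 * out[col] / ref
    return out
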