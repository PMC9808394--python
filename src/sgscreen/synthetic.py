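"""Synthetic fluorescence fields and compound screens with known ground truth.

The generator emulates the experimental system the pipeline was built for:
adherent astrocytoma-like cells co-expressing a Venus-tagged FUS reporter and
an mCherry-tagged G3BP1 stress-granule marker, imaged in three channels
(Hoechst nuclear stain, Venus, mCherry) on 384-well plates. Under DNA-damage
stress (calicheamicin, "CLM") G3BP1 condenses into cytoplasmic stress
granules; when DNA-PK is additionally inhibited ("CLM+NU7441") the FUS
reporter joins those granules. Compounds may inhibit FUS recruitment,
dissolve stress granules generally, or kill cells; the screening cascade has
to separate these classes.

Two tiers are provided: an *image tier* that renders full fields (for
segmentation tests) and a *tabular tier* that simulates per-well true
readouts directly (for screen-cascade tests at library scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import FieldImage
from .errors import ConfigurationError, LayoutError
from .plate import PlateLayout

__all__ = [
    "ConditionSpec",
    "CompoundEffect",
    "FieldGeometry",
    "GroundTruth",
    "ScreenDataset",
    "CONDITIONS",
    "fractional_effect",
    "generate_field",
    "render_field",
    "generate_screen",
    "make_library",
]

# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class FieldGeometry:
    """Geometry of one rendered field.

    Defaults correspond to a 40x high-content acquisition: 1024 x 1024
    pixels at ~0.65 um/px on a 16-bit intensity scale. Cell and nucleus
    semi-axes are drawn uniformly from the given (lo, hi) ranges, in pixels.
    ``min_spacing_px`` is the minimum distance between cell centres; it is
    deliberately smaller than two cell radii so that neighbouring cells can
    touch and exercise clump breaking, while nuclei stay disjoint.
    """

    shape: tuple[int, int] = (1024, 1024)
    px_size: float = 0.65
    cell_a: tuple[float, float] = (19.0, 24.0)
    cell_b: tuple[float, float] = (15.0, 20.0)
    nucleus_a: tuple[float, float] = (7.5, 10.0)
    nucleus_b: tuple[float, float] = (6.0, 8.0)
    min_spacing_px: float = 36.0
    nucleus_jitter_px: float = 3.0
    border_clearance_px: float = 4.0


@dataclass
class ConditionSpec:
    """Biological condition of a field or well.

    ``cyto_fus_fraction`` is the fraction of diffuse reporter intensity in
    the cytoplasm (FUS is nuclear at rest; the P525L mutant is partially
    cytoplasmic). ``p_fus_sg`` / ``p_g3bp1_sg`` are the probabilities that a
    cell forms cytosolic FUS- / G3BP1-positive granules. Granule amplitude
    is the peak height of the rendered Gaussian profile above the local
    compartment level, in intensity units; granule radius is 2 sigma of
    that profile. ``coloc_rate`` is the probability that a cytosolic FUS
    granule is planted at the position of a G3BP1 granule of the same cell,
    reflecting that FUS is recruited into existing stress granules.
    """

    n_cells: int = 50
    cyto_fus_fraction: float = 0.05
    p_fus_sg: float = 0.0
    p_g3bp1_sg: float = 0.0
    granules_per_cell: float = 4.0
    granule_intensity: float = 150.0
    granule_radius_px: float = 2.5
    nuclear_granule_rate: float = 2.0
    noise_sd: float = 15.0
    background: float = 200.0
    coloc_rate: float = 0.9
    cyto_g3bp1_fraction: float = 0.6
    venus_level: float = 800.0
    mcherry_level: float = 600.0
    nuclear_stain_level: float = 3000.0

    def __post_init__(self) -> None:
        for name in ("cyto_fus_fraction", "p_fus_sg", "p_g3bp1_sg", "coloc_rate",
                     "cyto_g3bp1_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_cells", "granules_per_cell", "granule_intensity",
                     "granule_radius_px", "nuclear_granule_rate", "noise_sd",
                     "background", "venus_level", "mcherry_level",
                     "nuclear_stain_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.n_cells = int(self.n_cells)


#: named presets for the three reference conditions with a FUS P525L reporter:
#: unstressed control (FUS nuclear, no stress granules), CLM (DNA damage:
#: G3BP1 granules form, FUS only partially cytosolic), and CLM+NU7441
#: (DNA damage + DNA-PK inhibition: FUS joins the G3BP1 granules).
CONDITIONS: dict[str, ConditionSpec] = {
    "control": ConditionSpec(p_fus_sg=0.0, p_g3bp1_sg=0.0, cyto_fus_fraction=0.05),
    "CLM": ConditionSpec(p_fus_sg=0.25, p_g3bp1_sg=0.8, cyto_fus_fraction=0.15),
    "CLM+NU7441": ConditionSpec(p_fus_sg=0.7, p_g3bp1_sg=0.8, cyto_fus_fraction=0.3),
}

CLASS_LABELS = ("true_hit", "sg_disruptor", "toxic", "inactive")


def fractional_effect(ic50: float, hill: float, dose) -> float | np.ndarray:
    """Fractional Hill inhibition ``dose^h / (dose^h + ic50^h)``.

    ``ic50`` of ``inf`` means the compound is inactive on that readout and
    the effect is 0 at any dose; the effect is likewise 0 at dose 0.
    """
    if hill <= 0:
        raise ValueError(f"hill must be > 0, got {hill}")
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be >= 0")
    if not (ic50 > 0):  # also rejects nan
        raise ValueError(f"ic50 must be > 0 or inf, got {ic50}")
    if math.isinf(ic50):
        out = np.zeros_like(dose_arr)
    else:
        with np.errstate(divide="ignore"):
            dh = dose_arr**hill
            out = dh / (dh + ic50**hill)
    return float(out) if np.isscalar(dose) else out


@dataclass
class CompoundEffect:
    """Ground-truth pharmacology of one library compound.

    Potencies are in micromolar; ``inf`` disables the corresponding
    activity. The class label follows from the three potencies at the
    primary screening dose (3 uM by default): a compound is *toxic* if it
    kills at least half the cells, otherwise an *sg_disruptor* if it removes
    at least half the G3BP1 granules (it dissolves stress granules
    generally), otherwise a *true_hit* if it inhibits the FUS readout by at
    least 60% (the primary-filter strength), otherwise *inactive*.
    """

    compound_id: str
    fus_ic50: float = math.inf
    g3bp1_ic50: float = math.inf
    tox_lc50: float = math.inf
    hill: float = 1.0
    class_label: str = ""

    def __post_init__(self) -> None:
        for name in ("fus_ic50", "g3bp1_ic50", "tox_lc50"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0 or inf, got {v}")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        inferred = self.infer_class()
        if not self.class_label:
            self.class_label = inferred
        elif self.class_label != inferred:
            raise ValueError(
                f"{self.compound_id}: class_label {self.class_label!r} inconsistent "
                f"with potencies (inferred {inferred!r})"
            )

    def infer_class(self, primary_dose: float = 3.0) -> str:
        if fractional_effect(self.tox_lc50, self.hill, primary_dose) >= 0.5:
            return "toxic"
        if fractional_effect(self.g3bp1_ic50, self.hill, primary_dose) >= 0.5:
            return "sg_disruptor"
        if fractional_effect(self.fus_ic50, self.hill, primary_dose) >= 0.6:
            return "true_hit"
        return "inactive"


def make_library(
    rng: np.random.Generator,
    n_true_hit: int = 20,
    n_disruptor: int = 20,
    n_toxic: int = 20,
    n_inactive: int = 308,
) -> list[CompoundEffect]:
    """Draw a compound library with strong, well-separated class effects.

    True hits inhibit the FUS readout by >= 80% at 3 uM (IC50 log-uniform in
    [0.1, 0.75] uM) while leaving G3BP1 granules and viability untouched.
    Disruptors dissolve stress granules generally: both G3BP1 and FUS
    readouts are inhibited by >= 80% at 3 uM. Toxic compounds kill >= 60% of
    cells at 3 uM. Inactive compounds have no activity.
    """

    def logu(lo: float, hi: float, n: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    lib: list[CompoundEffect] = []
    for ic in logu(0.1, 0.75, n_true_hit):
        lib.append(CompoundEffect(f"HIT{len(lib):04d}", fus_ic50=float(ic)))
    for ic in logu(0.2, 0.75, n_disruptor):
        lib.append(
            CompoundEffect(
                f"DIS{len(lib):04d}", fus_ic50=float(ic), g3bp1_ic50=float(ic)
            )
        )
    for lc in logu(0.5, 2.0, n_toxic):
        lib.append(CompoundEffect(f"TOX{len(lib):04d}", tox_lc50=float(lc)))
    for _ in range(n_inactive):
        lib.append(CompoundEffect(f"INA{len(lib):04d}"))
    return lib


# ---------------------------------------------------------------------------
# field rendering


@dataclass
class GroundTruth:
    """Everything the generator knows about one rendered field.

    ``cells`` has one row per cell (centre, ellipse parameters of cell and
    nucleus, SG flags, granule counts); ``granules`` one row per planted
    granule (channel, parent cell, centre, sigma, peak amplitude and
    closed-form integrated intensity ``peak * 2 pi sigma^2``, compartment).
    ``nucleus_labels`` / ``cell_labels`` are the true compartment label maps
    consistent with the rendered image.
    """

    cells: pd.DataFrame
    granules: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    condition: ConditionSpec
    geometry: FieldGeometry

    @property
    def n_cells(self) -> int:
        return len(self.cells)


_CELL_COLUMNS = [
    "cell_id", "row", "col", "cell_a", "cell_b", "cell_theta",
    "nuc_row", "nuc_col", "nuc_a", "nuc_b", "nuc_theta",
    "brightness", "fus_sg", "g3bp1_sg",
]
_GRANULE_COLUMNS = [
    "granule_id", "channel", "cell_id", "row", "col",
    "sigma_px", "peak", "integrated", "compartment",
]


def _sample_centers(n: int, geom: FieldGeometry, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centres with a minimum pairwise spacing."""
    h, w = geom.shape
    margin = geom.cell_a[1] + geom.border_clearance_px
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise LayoutError(f"grid {geom.shape} too small for cell margin {margin:.0f}px")
    centers: list[tuple[float, float]] = []
    min_d2 = geom.min_spacing_px**2
    attempts = 0
    max_attempts = 500 * max(n, 1)
    while len(centers) < n:
        if attempts >= max_attempts:
            raise LayoutError(
                f"could not place {n} cells on {geom.shape} at spacing "
                f"{geom.min_spacing_px}px ({len(centers)} placed)"
            )
        attempts += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
            centers.append((r, c))
    return np.array(centers).reshape(n, 2)


def _ellipse_score(shape, center, a, b, theta):
    """Normalized squared ellipse radius on a bounding crop.

    Returns (row slice, col slice, score array); score <= 1 is inside.
    """
    h, w = shape
    ext = max(a, b)
    r0 = max(0, int(math.floor(center[0] - ext)))
    r1 = min(h, int(math.ceil(center[0] + ext)) + 1)
    c0 = max(0, int(math.floor(center[1] - ext)))
    c1 = min(w, int(math.ceil(center[1] + ext)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (dr * ct + dc * st) / a
    v = (-dr * st + dc * ct) / b
    return slice(r0, r1), slice(c0, c1), u * u + v * v


def _paint_labels(shape, params: pd.DataFrame, prefix: str) -> np.ndarray:
    """Rasterize ellipses into a label map; overlaps go to the ellipse in
    whose normalized coordinates the pixel lies deepest."""
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    for rec in params.itertuples():
        center = (getattr(rec, f"{prefix}row" if prefix else "row"),
                  getattr(rec, f"{prefix}col" if prefix else "col"))
        a = getattr(rec, f"{prefix}a" if prefix else "cell_a")
        b = getattr(rec, f"{prefix}b" if prefix else "cell_b")
        theta = getattr(rec, f"{prefix}theta" if prefix else "cell_theta")
        rs, cs, score = _ellipse_score(shape, center, a, b, theta)
        inside = (score <= 1.0) & (score < best[rs, cs])
        labels[rs, cs][inside] = rec.cell_id
        best[rs, cs][inside] = score[inside]
    return labels


def _sample_in_ellipse(rng, center, a, b, theta):
    """Uniform point in an ellipse (polar sampling)."""
    rad = math.sqrt(rng.uniform())
    ang = rng.uniform(0.0, 2.0 * math.pi)
    u, v = rad * math.cos(ang) * a, rad * math.sin(ang) * b
    ct, st = math.cos(theta), math.sin(theta)
    return center[0] + u * ct - v * st, center[1] + u * st + v * ct


def _norm_radius(p, center, a, b, theta) -> float:
    dr, dc = p[0] - center[0], p[1] - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (dr * ct + dc * st) / a
    v = (-dr * st + dc * ct) / b
    return u * u + v * v


def _place_granules(rng, rec, n, sigma, existing, compartment, min_sep):
    """Sample up to n granule centres in one compartment of one cell.

    Cytosolic granules live between the (inflated) nucleus ellipse and the
    (deflated) cell ellipse; nuclear granules inside the deflated nucleus.
    Centres keep ``min_sep`` from every already placed centre of the same
    channel (``existing`` spans the whole field) so each planted granule is
    individually resolvable; a granule that cannot be placed after 60
    attempts is dropped rather than planted on top of a neighbour, and the
    ground truth records only what was actually rendered.
    """
    margin = 2.0 * sigma + 1.0
    # cytosolic granules keep a wider berth from the nucleus: the nuclear
    # compartment is much brighter than the cytoplasm on the FUS channel and
    # a granule parked on that rim is not an individually resolvable punctum
    nuc_margin = 4.0 * sigma + 2.0
    cell_c = (rec.row, rec.col)
    nuc_c = (rec.nuc_row, rec.nuc_col)
    placed = []
    for _ in range(n):
        for _try in range(60):
            if compartment == "cyto":
                p = _sample_in_ellipse(
                    rng, cell_c, max(rec.cell_a - margin, 1.0),
                    max(rec.cell_b - margin, 1.0), rec.cell_theta)
                # reject inside nucleus inflated by the margin
                if _norm_radius(p, nuc_c, rec.nuc_a + nuc_margin,
                                rec.nuc_b + nuc_margin, rec.nuc_theta) <= 1.0:
                    continue
            else:
                a = rec.nuc_a - margin
                b = rec.nuc_b - margin
                if a <= 0.5 or b <= 0.5:
                    p = nuc_c
                else:
                    p = _sample_in_ellipse(rng, nuc_c, a, b, rec.nuc_theta)
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2
                   for q in existing + placed):
                placed.append(p)
                break
    return placed


def _zt_poisson(rng, lam: float) -> int:
    """Poisson count forced to be at least 1 (a flagged cell has granules)."""
    return max(1, int(rng.poisson(lam)))


def _add_granule(img, center, sigma, peak):
    h, w = img.shape
    ext = int(math.ceil(4.0 * sigma))
    r0, r1 = max(0, int(center[0]) - ext), min(h, int(center[0]) + ext + 1)
    c0, c1 = max(0, int(center[1]) - ext), min(w, int(center[1]) + ext + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += peak * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2)
    )


def generate_field(
    cond: ConditionSpec,
    seed: int | np.random.SeedSequence,
    geometry: FieldGeometry | None = None,
    well_id: str = "",
    field_id: str = "f1",
) -> tuple[FieldImage, GroundTruth]:
    """Render one 3-channel field under ``cond`` with full ground truth.

    The same (condition, geometry, seed) triple always produces bit-identical
    images and ground truth. Additive Gaussian noise is clipped at 4.5 sd so
    that no background pixel ever exceeds background + 5 noise_sd.
    """
    geom = geometry or FieldGeometry()
    rng = np.random.default_rng(seed)
    cells, granules = _plant_field(cond, geom, rng)
    return render_field(cells, granules, cond, geom, rng,
                        well_id=well_id, field_id=field_id)


def render_field(
    cells: pd.DataFrame,
    granules: pd.DataFrame,
    cond: ConditionSpec,
    geometry: FieldGeometry | None = None,
    rng: np.random.Generator | int | None = None,
    well_id: str = "",
    field_id: str = "f1",
) -> tuple[FieldImage, GroundTruth]:
    """Render explicit cell/granule tables into a field (no sampling).

    ``cells`` and ``granules`` follow the ground-truth table schema; the
    random generator is used only for the additive noise. This is the
    rendering backend of :func:`generate_field` and is public so that
    hand-built layouts (touching nuclei, border cells, ...) can be rendered
    directly.
    """
    geom = geometry or FieldGeometry()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nucleus_labels = (
        _paint_labels(geom.shape, cells, "nuc_") if len(cells) else np.zeros(geom.shape, np.int32)
    )
    cell_labels = (
        _paint_labels(geom.shape, cells, "") if len(cells) else np.zeros(geom.shape, np.int32)
    )
    if len(cells):
        # a nucleus always belongs to its own cell, even under heavy overlap
        for cid in cells["cell_id"]:
            cell_labels[nucleus_labels == cid] = cid

    bright = np.ones(int(cells["cell_id"].max()) + 1 if len(cells) else 1)
    if len(cells):
        bright[cells["cell_id"].to_numpy()] = cells["brightness"].to_numpy()
    in_nuc = nucleus_labels > 0
    in_cyto = (cell_labels > 0) & ~in_nuc

    def compartment_image(nuc_level: float, cyto_level: float) -> np.ndarray:
        img = np.zeros(geom.shape)
        img[in_nuc] = nuc_level * bright[nucleus_labels[in_nuc]]
        img[in_cyto] = cyto_level * bright[cell_labels[in_cyto]]
        return img

    clean = {
        "nuclei": compartment_image(cond.nuclear_stain_level, 0.0),
        "venus": compartment_image(
            cond.venus_level * (1.0 - cond.cyto_fus_fraction),
            cond.venus_level * cond.cyto_fus_fraction,
        ),
        "mcherry": compartment_image(
            cond.mcherry_level * (1.0 - cond.cyto_g3bp1_fraction),
            cond.mcherry_level * cond.cyto_g3bp1_fraction,
        ),
    }
    for g in granules.itertuples():
        _add_granule(clean[g.channel], (g.row, g.col), g.sigma_px, g.peak)

    channels = {}
    for name in ("nuclei", "venus", "mcherry"):
        noise = rng.normal(0.0, cond.noise_sd, size=geom.shape) if cond.noise_sd else 0.0
        if cond.noise_sd:
            noise = np.clip(noise, -4.5 * cond.noise_sd, 4.5 * cond.noise_sd)
        img = clean[name] + cond.background + noise
        channels[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    fimg = FieldImage(channels=channels, well_id=well_id, field_id=field_id,
                      px_size=geom.px_size)
    truth = GroundTruth(cells=cells, granules=granules,
                        nucleus_labels=nucleus_labels, cell_labels=cell_labels,
                        condition=cond, geometry=geom)
    return fimg, truth


def _plant_field(cond, geom, rng):
    """Draw cell geometry, SG flags and granule records for one field."""
    n = cond.n_cells
    if n == 0:
        return (pd.DataFrame(columns=_CELL_COLUMNS),
                pd.DataFrame(columns=_GRANULE_COLUMNS))
    centers = _sample_centers(n, geom, rng)
    jit = geom.nucleus_jitter_px
    rows = []
    for i in range(n):
        r, c = centers[i]
        rows.append({
            "cell_id": i + 1,
            "row": r, "col": c,
            "cell_a": rng.uniform(*geom.cell_a),
            "cell_b": rng.uniform(*geom.cell_b),
            "cell_theta": rng.uniform(0.0, math.pi),
            "nuc_row": r + rng.uniform(-jit, jit),
            "nuc_col": c + rng.uniform(-jit, jit),
            "nuc_a": rng.uniform(*geom.nucleus_a),
            "nuc_b": rng.uniform(*geom.nucleus_b),
            "nuc_theta": rng.uniform(0.0, math.pi),
            "brightness": rng.uniform(0.9, 1.1),
            "fus_sg": bool(rng.random() < cond.p_fus_sg),
            "g3bp1_sg": bool(rng.random() < cond.p_g3bp1_sg),
        })
    cells = pd.DataFrame(rows, columns=_CELL_COLUMNS)

    sigma = cond.granule_radius_px / 2.0
    min_sep = 3.0 * cond.granule_radius_px
    integ = cond.granule_intensity * 2.0 * math.pi * sigma**2
    grecs: list[dict] = []

    def record(channel, cid, p, compartment):
        grecs.append({
            "granule_id": len(grecs) + 1, "channel": channel, "cell_id": cid,
            "row": p[0], "col": p[1], "sigma_px": sigma,
            "peak": cond.granule_intensity, "integrated": integ,
            "compartment": compartment,
        })

    all_pts: dict[str, list] = {"venus": [], "mcherry": []}
    for rec in cells.itertuples():
        g3_pts: list = []
        if rec.g3bp1_sg:
            n_g3 = _zt_poisson(rng, cond.granules_per_cell)
            g3_pts = _place_granules(rng, rec, n_g3, sigma, all_pts["mcherry"],
                                     "cyto", min_sep)
            all_pts["mcherry"] += g3_pts
            for p in g3_pts:
                record("mcherry", rec.cell_id, p, "cyto")
        if rec.fus_sg:
            n_fus = _zt_poisson(rng, cond.granules_per_cell)
            fus_pts: list = []
            for k in range(n_fus):
                # FUS granules co-locate with existing G3BP1 granules
                if k < len(g3_pts) and rng.random() < cond.coloc_rate:
                    fus_pts.append(g3_pts[k])
            fresh = _place_granules(rng, rec, n_fus - len(fus_pts), sigma,
                                    all_pts["venus"] + fus_pts, "cyto", min_sep)
            all_pts["venus"] += fus_pts + fresh
            for p in fus_pts + fresh:
                record("venus", rec.cell_id, p, "cyto")
        n_nuc = int(rng.poisson(cond.nuclear_granule_rate))
        if n_nuc:
            pts = _place_granules(rng, rec, n_nuc, sigma, all_pts["venus"],
                                  "nuc", min_sep)
            all_pts["venus"] += pts
            for p in pts:
                record("venus", rec.cell_id, p, "nuc")

    granules = pd.DataFrame(grecs, columns=_GRANULE_COLUMNS)
    # flags reflect what was actually rendered: on rare infeasible
    # geometries a flagged cell ends up with no placeable granule
    cyto = granules[granules["compartment"] == "cyto"]
    has = {
        (ch, cid)
        for ch, cid in zip(cyto["channel"], cyto["cell_id"])
    }
    cells["fus_sg"] = [
        bool(f and ("venus", cid) in has)
        for f, cid in zip(cells["fus_sg"], cells["cell_id"])
    ]
    cells["g3bp1_sg"] = [
        bool(f and ("mcherry", cid) in has)
        for f, cid in zip(cells["g3bp1_sg"], cells["cell_id"])
    ]
    return cells, granules


# ---------------------------------------------------------------------------
# screen generation


@dataclass
class ScreenDataset:
    """A generated screen: per-well readouts/truth and optional images.

    ``wells`` carries the *true* per-well readouts of the tabular tier (or
    well metadata only, for the image tier); ``truth`` the planted per-well
    effect fractions and class labels; ``images`` maps
    ``(plate_id, well_id)`` to a rendered :class:`FieldImage` when the
    image tier was requested.
    """

    wells: pd.DataFrame
    truth: pd.DataFrame
    layouts: list[PlateLayout]
    images: dict[tuple[str, str], FieldImage] | None = None
    ground_truths: dict[tuple[str, str], GroundTruth] | None = None


WELL_READOUTS = [
    "cell_count",
    "fus_sg_fraction", "g3bp1_sg_fraction",
    "fus_granules_per_cell", "g3bp1_granules_per_cell",
    "venus_cyto_intensity_mean", "venus_nuclear_intensity_mean",
    "mcherry_cyto_intensity_mean",
]


def _simulate_well(cond: ConditionSpec, rng: np.random.Generator) -> dict:
    """Tabular-tier well: draw per-cell truth and aggregate, without rendering."""
    n = cond.n_cells
    out = {k: 0.0 for k in WELL_READOUTS}
    out["cell_count"] = n
    if n == 0:
        for k in WELL_READOUTS[1:]:
            out[k] = np.nan
        return out
    sigma = cond.granule_radius_px / 2.0
    integ = cond.granule_intensity * 2.0 * math.pi * sigma**2
    cv = 0.15

    def granule_sums(p_pos: float, lam: float):
        flags = rng.random(n) < p_pos
        counts = np.where(flags, np.maximum(rng.poisson(lam, n), 1), 0)
        inten = integ * (counts + cv * rng.standard_normal(n) * np.sqrt(counts))
        return flags, counts, np.maximum(inten, 0.0)

    fus_flags, fus_counts, fus_int = granule_sums(cond.p_fus_sg, cond.granules_per_cell)
    g3_flags, g3_counts, g3_int = granule_sums(cond.p_g3bp1_sg, cond.granules_per_cell)
    nuc_counts = rng.poisson(cond.nuclear_granule_rate, n)
    nuc_int = integ * (nuc_counts + cv * rng.standard_normal(n) * np.sqrt(nuc_counts))

    out.update({
        "fus_sg_fraction": float(fus_flags.mean()),
        "g3bp1_sg_fraction": float(g3_flags.mean()),
        "fus_granules_per_cell": float(fus_counts.mean()),
        "g3bp1_granules_per_cell": float(g3_counts.mean()),
        "venus_cyto_intensity_mean": float(fus_int.mean()),
        "venus_nuclear_intensity_mean": float(np.maximum(nuc_int, 0.0).mean()),
        "mcherry_cyto_intensity_mean": float(g3_int.mean()),
    })
    return out


def generate_screen(
    library: list[CompoundEffect],
    cond_base: ConditionSpec,
    doses: list[float] | None = None,
    layouts: list[PlateLayout] | None = None,
    seed: int | np.random.SeedSequence = 0,
    tier: str = "tabular",
    geometry: FieldGeometry | None = None,
    n_controls: int = 16,
) -> ScreenDataset:
    """Generate a full synthetic screen under the stimulated base condition.

    Each compound well applies the compound's Hill effects at its dose to
    the base condition: the FUS- and G3BP1-granule probabilities are scaled
    by ``1 - effect`` and the cell count is binomially thinned by the toxic
    effect. Control wells run the unmodified base condition. When ``layouts``
    is omitted, one 384-well plate per dose is built (compounds in fixed
    order, ``n_controls`` stimulus-control wells per plate).

    ``tier="tabular"`` simulates true per-well readouts directly;
    ``tier="image"`` additionally renders one field per well (desk-scale
    layouts only).
    """
    if tier not in ("tabular", "image"):
        raise ConfigurationError(f"unknown tier {tier!r}")
    ids = [c.compound_id for c in library]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate compound ids in library")
    by_id = {c.compound_id: c for c in library}

    if layouts is None:
        doses = list(doses) if doses is not None else [3.0]
        layouts = [
            PlateLayout.build(ids, d, plate_id=f"P{i + 1}", n_controls=n_controls)
            for i, d in enumerate(doses)
        ]
    for lay in layouts:
        if not lay.control_wells:  # PlateLayout already enforces this
            raise ConfigurationError(f"plate {lay.plate_id} has no control wells")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_wells = sum(len(l.wells) for l in layouts)
    children = ss.spawn(n_wells)

    rows, truth_rows = [], []
    images: dict[tuple[str, str], FieldImage] = {}
    gts: dict[tuple[str, str], GroundTruth] = {}
    k = 0
    for lay in layouts:
        for wrec in lay.wells.itertuples():
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            dose = float(wrec.concentration_um)
            if wrec.role == "control":
                f_fus = f_g3 = f_tox = 0.0
                label = "control"
            else:
                eff = by_id.get(wrec.compound_id)
                if eff is None:
                    raise ConfigurationError(
                        f"plate {lay.plate_id} well {wrec.well_id}: unknown compound "
                        f"{wrec.compound_id!r}"
                    )
                f_fus = fractional_effect(eff.fus_ic50, eff.hill, dose)
                f_g3 = fractional_effect(eff.g3bp1_ic50, eff.hill, dose)
                f_tox = fractional_effect(eff.tox_lc50, eff.hill, dose)
                label = eff.class_label
            n_surv = int(rng.binomial(cond_base.n_cells, 1.0 - f_tox))
            cond_well = replace(
                cond_base,
                n_cells=n_surv,
                p_fus_sg=cond_base.p_fus_sg * (1.0 - f_fus),
                p_g3bp1_sg=cond_base.p_g3bp1_sg * (1.0 - f_g3),
            )
            meta = {
                "plate_id": lay.plate_id, "well_id": wrec.well_id,
                "role": wrec.role, "compound_id": wrec.compound_id,
                "dose_um": dose,
            }
            truth_rows.append({
                **meta, "class_label": label,
                "f_fus": f_fus, "f_g3bp1": f_g3, "f_tox": f_tox,
                "p_fus_eff": cond_well.p_fus_sg, "p_g3bp1_eff": cond_well.p_g3bp1_sg,
                "n_cells_true": n_surv,
            })
            if tier == "tabular":
                rows.append({**meta, **_simulate_well(cond_well, rng)})
            else:
                fimg, gt = generate_field(cond_well, child, geometry,
                                          well_id=wrec.well_id)
                images[(lay.plate_id, wrec.well_id)] = fimg
                gts[(lay.plate_id, wrec.well_id)] = gt
                rows.append(meta)

    return ScreenDataset(
        wells=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        layouts=layouts,
        images=images or None,
        ground_truths=gts or None,
    )


def write_ground_truth(truth: GroundTruth, cells_path, granules_path) -> None:
    """Write the per-cell and per-granule ground-truth tables as CSV."""
    truth.cells.to_csv(cells_path, index=False)
    truth.granules.to_csv(granules_path, index=False)
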