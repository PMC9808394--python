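"""Two-stage compound-screen hit calling with dose-response confirmation.

Stage 1 (primary screen, one dose): a compound well passes when

* viability (cell count, % of control) >= ``viability_min`` — toxicity
  filter;
* the FUS-granule readout falls to <= ``fus_max`` % of control — the
  desired inhibition of FUS-containing stress granules;
* the G3BP1-granule readout stays >= ``g3bp1_min`` % of control — the
  counter-screen that rejects compounds dissolving stress granules
  generally.

Stage 2 (confirmation, four doses): candidates must show concentration
dependence — a convergent four-parameter logistic (4PL) fit of the FUS
inhibition with a span above the noise floor and responses monotone in dose
within tolerance — while the viability and G3BP1 filters keep holding at
every dose where FUS inhibition passes. The reported potency is the fitted
IC50 of the FUS-granule readout, in micromolar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "CascadeParams",
    "DoseResponseFit",
    "apply_primary_filters",
    "call_primary_hits",
    "fit_dose_response",
    "assess_concentration_dependence",
    "call_confirmed_hits",
    "run_cascade",
]


@dataclass(frozen=True)
class CascadeParams:
    """Thresholds of the screening cascade, in percent of control.

    ``viability_min`` (70): minimum surviving-cell percentage.
    ``fus_max`` (40): maximum remaining FUS-granule readout — i.e. at least
    60% inhibition. ``g3bp1_min`` (50): minimum remaining G3BP1 readout.
    ``doses`` is the confirmation grid in uM (descending);
    ``primary_dose`` the single-dose primary screen concentration.
    ``min_fit_quality`` is the minimum fitted span (top - bottom, in
    inhibition %) accepted as real when no control noise floor is supplied;
    ``monotonicity_alpha`` the tolerated backward step (in inhibition
    percentage points) before a dose series counts as non-monotone.
    """

    viability_min: float = 70.0
    fus_max: float = 40.0
    g3bp1_min: float = 50.0
    doses: tuple[float, ...] = (10.0, 3.0, 0.3, 0.03)
    primary_dose: float = 3.0
    min_fit_quality: float = 20.0
    monotonicity_alpha: float = 10.0

    def __post_init__(self) -> None:
        for name in ("viability_min", "fus_max", "g3bp1_min"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name}={v} outside (0, 100)")
        d = tuple(float(x) for x in self.doses)
        if any(x <= 0 for x in d) or list(d) != sorted(d, reverse=True):
            raise ValueError("doses must be positive and sorted descending")
        object.__setattr__(self, "doses", d)


def apply_primary_filters(
    viability_pct: float,
    fus_pct: float,
    g3bp1_pct: float,
    p: CascadeParams,
) -> tuple[bool, bool, bool]:
    """Evaluate the three primary filters on one well's normalized readouts.

    All three flags are computed even when an upstream filter fails (the
    hit call combines them in cascade order); a missing viability readout
    (zero-cell well) is an automatic viability fail.
    """
    pass_viability = bool(np.isfinite(viability_pct) and viability_pct >= p.viability_min)
    pass_fus = bool(np.isfinite(fus_pct) and fus_pct <= p.fus_max)
    pass_g3bp1 = bool(np.isfinite(g3bp1_pct) and g3bp1_pct >= p.g3bp1_min)
    return pass_viability, pass_fus, pass_g3bp1


def call_primary_hits(screen: pd.DataFrame, p: CascadeParams) -> pd.DataFrame:
    """Apply the primary cascade to one readout triple per compound.

    ``screen`` needs columns ``compound_id, viability_pct, fus_pct,
    g3bp1_pct``. Returns a copy with the three pass flags and
    ``primary_hit``, preserving input order. Duplicate compound ids are an
    error.
    """
    dup = screen["compound_id"][screen["compound_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate compound id {dup.iloc[0]!r} in primary screen")
    out = screen.copy()
    if out.empty:
        for col in ("pass_viability", "pass_fus", "pass_g3bp1", "primary_hit"):
            out[col] = pd.Series(dtype=bool)
        return out
    flags = [
        apply_primary_filters(r.viability_pct, r.fus_pct, r.g3bp1_pct, p)
        for r in out.itertuples()
    ]
    out[["pass_viability", "pass_fus", "pass_g3bp1"]] = pd.DataFrame(
        flags, index=out.index
    )
    out["primary_hit"] = out["pass_viability"] & out["pass_fus"] & out["pass_g3bp1"]
    return out


@dataclass
class DoseResponseFit:
    """Result of a four-parameter logistic fit in log-dose.

    The model is ``y(d) = bottom + (top - bottom) / (1 + (ic50 / d)^hill)``
    with ``y`` the inhibition in percent. ``converged`` is False for
    degenerate (flat) responses, in which case ``ic50`` is NaN.
    """

    top: float = float("nan")
    bottom: float = float("nan")
    ic50: float = float("nan")
    hill: float = float("nan")
    residual_sse: float = float("nan")
    converged: bool = False
    doses: tuple[float, ...] = field(default_factory=tuple)
    responses: tuple[float, ...] = field(default_factory=tuple)

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return _four_pl(d, self.bottom, self.top, self.ic50, self.hill)

    def summary(self) -> str:
        if not self.converged:
            return "4PL fit: not converged (degenerate or flat response)"
        return (
            "4PL dose-response fit\n"
            f"  IC50   : {self.ic50:8.4g} uM\n"
            f"  hill   : {self.hill:8.3g}\n"
            f"  top    : {self.top:8.3g} %\n"
            f"  bottom : {self.bottom:8.3g} %\n"
            f"  SSE    : {self.residual_sse:8.3g}"
        )


def _four_pl(d, bottom, top, ic50, hill):
    with np.errstate(divide="ignore", over="ignore"):
        return bottom + (top - bottom) / (1.0 + (ic50 / np.maximum(d, 1e-12)) ** hill)


def fit_dose_response(doses, responses) -> DoseResponseFit:
    """Bounded least-squares 4PL fit of percent inhibition vs dose.

    Requires >= 4 distinct doses. Bounds: bottom in [0, 100], top in
    [0, 120] (slack above 100 for noise), IC50 within
    [min dose / 10, max dose * 10], hill in [0.2, 5]. Several IC50 starting
    points are tried and the best solution kept. A response series with no
    spread returns ``converged=False``.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(doses) < 4:
        raise ValueError("need at least 4 (dose, response) pairs")
    if len(np.unique(doses)) != len(doses):
        raise ValueError("doses must be distinct")
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    out = DoseResponseFit(doses=tuple(doses), responses=tuple(responses))
    if float(np.ptp(responses)) < 1e-9:
        return out

    order = np.argsort(doses)
    d, y = doses[order], responses[order]
    lo = np.array([0.0, 0.0, np.log10(d.min() / 10.0), 0.2])
    hi = np.array([100.0, 120.0, np.log10(d.max() * 10.0), 5.0])

    def resid(theta):
        bottom, top, lic50, hill = theta
        return _four_pl(d, bottom, top, 10.0**lic50, hill) - y

    best = None
    for lic0 in np.linspace(lo[2] + 0.3, hi[2] - 0.3, 5):
        x0 = np.clip(
            np.array([max(y.min(), 0.0), min(max(y.max(), 1.0), 120.0), lic0, 1.0]),
            lo, hi,
        )
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except ValueError:  # pragma: no cover - defensive
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return out
    bottom, top, lic50, hill = best.x
    span = top - bottom
    if span < 1e-6:
        return out
    out.bottom, out.top = float(bottom), float(top)
    out.ic50, out.hill = float(10.0**lic50), float(hill)
    out.residual_sse = float(2.0 * best.cost)
    out.converged = True
    return out


def assess_concentration_dependence(
    fit: DoseResponseFit,
    responses,
    doses,
    p: CascadeParams,
    noise_floor: float | None = None,
) -> bool:
    """Decide whether a dose series shows genuine concentration dependence.

    True iff the 4PL fit converged, its span exceeds the noise floor
    (control-well dispersion when supplied, else ``p.min_fit_quality``),
    and inhibition is non-decreasing with dose up to
    ``p.monotonicity_alpha`` percentage points. Single-dose spikes and flat
    series fail.
    """
    if not fit.converged:
        return False
    floor = p.min_fit_quality if noise_floor is None else max(noise_floor, 1e-9)
    if fit.span < floor:
        return False
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)[np.argsort(d)]
    return bool(np.all(np.diff(y) >= -p.monotonicity_alpha))


def control_noise_floor(control_inhibition: np.ndarray, z: float = 4.0) -> float:
    """Noise floor for the fitted span, from control-well dispersion.

    Control wells carry no compound, so their apparent inhibition scatters
    around zero; a real dose-response span must exceed ``z`` times that
    standard deviation.
    """
    arr = np.asarray(control_inhibition, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 2:
        return 0.0
    return z * float(np.std(arr, ddof=1))


def call_confirmed_hits(
    dose_data: pd.DataFrame,
    p: CascadeParams,
    noise_floor: float | None = None,
) -> pd.DataFrame:
    """Confirm primary candidates on their four-dose series.

    ``dose_data`` has one row per (compound, dose) with columns
    ``compound_id, dose_um, viability_pct, fus_pct, g3bp1_pct``. A compound
    is confirmed iff its FUS inhibition (100 - fus_pct) is concentration
    dependent and the full primary-filter logic (viability and G3BP1
    preservation) holds at every dose where the FUS filter passes, with at
    least one such dose. Compounds missing doses are flagged unevaluable
    and excluded with a warning. Returns one row per compound with flags,
    per-dose readouts and the fitted IC50 (uM).
    """
    rows = []
    for cid, grp in dose_data.groupby("compound_id", sort=False):
        grp = grp.sort_values("dose_um", ascending=False)
        have = set(np.round(grp["dose_um"].to_numpy(), 9))
        need = set(np.round(np.asarray(p.doses), 9))
        row: dict = {"compound_id": cid}
        if not need <= have:
            warnings.warn(f"compound {cid!r}: missing dose rows, excluded as unevaluable")
            row.update(evaluable=False, dose_dependent=False,
                       confirmed_hit=False, ic50=float("nan"))
            rows.append(row)
            continue
        grp = grp[np.isin(np.round(grp["dose_um"], 9), list(need))]
        d = grp["dose_um"].to_numpy(float)
        fus = grp["fus_pct"].to_numpy(float)
        via = grp["viability_pct"].to_numpy(float)
        g3 = grp["g3bp1_pct"].to_numpy(float)
        inhibition = 100.0 - fus
        fit = fit_dose_response(d, inhibition)
        dose_dep = assess_concentration_dependence(fit, inhibition, d, p, noise_floor)
        fus_pass = np.isfinite(fus) & (fus <= p.fus_max)
        guard_ok = bool(
            fus_pass.any()
            and np.all(
                (np.isfinite(via[fus_pass]) & (via[fus_pass] >= p.viability_min))
                & (np.isfinite(g3[fus_pass]) & (g3[fus_pass] >= p.g3bp1_min))
            )
        )
        row.update(
            evaluable=True,
            dose_dependent=bool(dose_dep),
            confirmed_hit=bool(dose_dep and guard_ok),
            ic50=fit.ic50 if fit.converged else float("nan"),
            fit_converged=fit.converged,
            fit_span=fit.span if fit.converged else float("nan"),
        )
        for dose, v_, f_, g_ in zip(d, via, fus, g3):
            row[f"viability_pct_{dose:g}"] = v_
            row[f"fus_pct_{dose:g}"] = f_
            row[f"g3bp1_pct_{dose:g}"] = g_
        rows.append(row)
    return pd.DataFrame(rows)


def run_cascade(
    primary: pd.DataFrame,
    dose_data: pd.DataFrame | None,
    p: CascadeParams | None = None,
    noise_floor: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full funnel: primary filters, then dose confirmation.

    ``primary`` is the single-dose screen table (see
    :func:`call_primary_hits`); ``dose_data`` the dose-series table for the
    candidates (compounds absent from it are unevaluable). Returns the
    per-compound result table and a funnel summary with the counts
    surviving each stage.
    """
    p = p or CascadeParams()
    res = call_primary_hits(primary, p)
    funnel = {
        "tested": int(len(res)),
        "pass_viability": int(res["pass_viability"].sum()),
        "pass_fus": int((res["pass_viability"] & res["pass_fus"]).sum()),
        "primary_hits": int(res["primary_hit"].sum()),
    }
    res["confirmed_hit"] = False
    res["ic50"] = float("nan")
    res["dose_dependent"] = False
    if dose_data is not None and funnel["primary_hits"]:
        cand = res.loc[res["primary_hit"], "compound_id"]
        sub = dose_data[dose_data["compound_id"].isin(cand)]
        conf = call_confirmed_hits(sub, p, noise_floor)
        conf = conf.set_index("compound_id")
        idx = res["compound_id"].isin(conf.index) & res["primary_hit"]
        for col in ("confirmed_hit", "ic50", "dose_dependent"):
            res.loc[idx, col] = res.loc[idx, "compound_id"].map(conf[col]).values
    funnel["confirmed_hits"] = int(res["confirmed_hit"].sum())
    logger.info("screen funnel: %s", funnel)
    return res, funnel
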