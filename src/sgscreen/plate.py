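"""Plate layouts and plate-map CSV I/O.

A plate map assigns each well of a 384-well plate (rows A-P, columns 1-24)
either a compound at a concentration or a control role. Control wells
receive the stress stimulus plus vehicle (DMSO) only; every plate must
declare at least one, because all screen readouts are expressed as percent
of the same-plate control mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24

#: columns a plate-map CSV must carry
PLATE_MAP_COLUMNS = ["plate_id", "well_id", "role", "compound_id", "concentration_um", "condition"]

ROLES = {"control", "compound"}


def well_ids_384() -> list[str]:
    """All 384 well ids in row-major order (A01 ... P24)."""
    return [f"{r}{c:02d}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]


@dataclass
class PlateLayout:
    """Mapping from well id to (role, compound, concentration, condition).

    ``wells`` has one row per well with columns
    ``well_id, role, compound_id, concentration_um, condition``.
    ``role`` is ``"control"`` (stimulus + vehicle) or ``"compound"``.
    """

    plate_id: str
    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_MAP_COLUMNS[1:] if c not in self.wells.columns]
        if missing:
            raise ConfigurationError(f"plate {self.plate_id}: missing columns {missing}")
        dup = self.wells["well_id"][self.wells["well_id"].duplicated()]
        if len(dup):
            raise ConfigurationError(
                f"plate {self.plate_id}: duplicate well id {dup.iloc[0]!r}"
            )
        bad_roles = set(self.wells["role"]) - ROLES
        if bad_roles:
            raise ConfigurationError(f"plate {self.plate_id}: unknown roles {sorted(bad_roles)}")
        if not (self.wells["role"] == "control").any():
            raise ConfigurationError(f"plate {self.plate_id}: no control wells declared")
        self.wells = self.wells.reset_index(drop=True)

    @property
    def control_wells(self) -> list[str]:
        return list(self.wells.loc[self.wells["role"] == "control", "well_id"])

    @classmethod
    def build(
        cls,
        compounds: list[str],
        dose_um: float,
        plate_id: str = "P1",
        n_controls: int = 16,
        condition: str = "CLM+NU7441",
    ) -> "PlateLayout":
        """Lay out compounds at one dose plus stimulus-control wells.

        Controls occupy the first ``n_controls`` wells; compounds follow in
        row-major order. Raises if the plate overflows 384 wells.
        """
        ids = well_ids_384()
        if n_controls + len(compounds) > len(ids):
            raise ConfigurationError(
                f"{len(compounds)} compounds + {n_controls} controls exceed 384 wells"
            )
        rows = []
        it = iter(ids)
        for _ in range(n_controls):
            rows.append((next(it), "control", "DMSO", 0.0, condition))
        for cid in compounds:
            rows.append((next(it), "compound", cid, float(dose_um), condition))
        wells = pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS[1:])
        return cls(plate_id=plate_id, wells=wells)


def read_plate_map(path) -> list[PlateLayout]:
    """Read a plate-map CSV into one :class:`PlateLayout` per plate.

    The concentration column must parse as a plain number ("3" -> 3.0 uM);
    unit suffixes such as "10uM" are rejected.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"plate map {path}: missing required column(s) {missing}")
    try:
        conc = pd.to_numeric(df["concentration_um"])
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(
            f"plate map {path}: concentration_um must be strictly numeric ({exc})"
        ) from None
    df = df.assign(concentration_um=conc.astype(float))
    layouts = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        layouts.append(PlateLayout(plate_id=str(plate_id), wells=grp.drop(columns="plate_id")))
    return layouts


def write_plate_map(layouts: list[PlateLayout], path) -> None:
    frames = []
    for lay in layouts:
        frame = lay.wells.copy()
        frame.insert(0, "plate_id", lay.plate_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
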