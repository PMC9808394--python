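"""Shared fixtures: small rendered fields and their segmentations.

Fields are generated at reduced size (256/512 px) so the whole suite stays
fast; geometry and conditions are otherwise the generator defaults.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import sgscreen as sg
from sgscreen.synthetic import _CELL_COLUMNS, _GRANULE_COLUMNS

SMALL_GEOM = sg.FieldGeometry(shape=(256, 256))
FIELD_GEOM = sg.FieldGeometry(shape=(512, 512))


def make_cells(rows: list[dict]) -> pd.DataFrame:
    """Hand-built ground-truth cell table with defaults filled in."""
    defaults = dict(cell_a=20.0, cell_b=16.0, cell_theta=0.0,
                    nuc_a=9.0, nuc_b=7.0, nuc_theta=0.0,
                    brightness=1.0, fus_sg=False, g3bp1_sg=False)
    recs = []
    for i, row in enumerate(rows):
        rec = {**defaults, "cell_id": i + 1, **row}
        rec.setdefault("nuc_row", rec["row"])
        rec.setdefault("nuc_col", rec["col"])
        recs.append(rec)
    return pd.DataFrame(recs, columns=_CELL_COLUMNS)


def empty_granules() -> pd.DataFrame:
    return pd.DataFrame(columns=_GRANULE_COLUMNS)


@pytest.fixture(scope="session")
def stim_condition() -> sg.ConditionSpec:
    return sg.CONDITIONS["CLM+NU7441"]


@pytest.fixture(scope="session")
def small_field(stim_condition):
    """One 256x256 stimulated field with 12 cells, plus ground truth."""
    cond = dataclasses.replace(stim_condition, n_cells=12)
    return sg.generate_field(cond, seed=11, geometry=SMALL_GEOM)


@pytest.fixture(scope="session")
def segmented_small_field(small_field):
    field, truth = small_field
    return field, truth, sg.segment_field(field)


@pytest.fixture(scope="session")
def field_batch(stim_condition):
    """Twenty 512x512 default fields (50 cells each) with segmentations.

    Shared by the segmentation-recovery and measurement tests; generating
    and segmenting them once keeps the suite fast.
    """
    out = []
    for seed in range(20):
        field, truth = sg.generate_field(stim_condition, seed=seed, geometry=FIELD_GEOM)
        out.append((field, truth, sg.segment_field(field)))
    return out


def granule_centroids(label_map: np.ndarray) -> np.ndarray:
    import scipy.ndimage as ndi

    ids = np.unique(label_map)
    ids = ids[ids > 0]
    if not len(ids):
        return np.zeros((0, 2))
    return np.array(ndi.center_of_mass(label_map > 0, label_map, ids))


def match_centroids(detected: np.ndarray, truth: np.ndarray, tol: float = 2.0):
    """Greedy one-to-one matching of detected centroids to true centres."""
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for c in detected:
        if not len(truth):
            break
        d2 = np.sum((truth - c) ** 2, axis=1)
        j = int(np.argmin(d2))
        if d2[j] <= tol**2 and not used[j]:
            used[j] = True
            tp += 1
    return tp
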