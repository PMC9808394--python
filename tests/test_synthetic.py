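"""Generator contracts: Hill effects, field rendering, screen synthesis."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sgscreen as sg
from sgscreen.errors import ConfigurationError, LayoutError
from sgscreen.synthetic import _simulate_well

from conftest import SMALL_GEOM, empty_granules, make_cells


class TestFractionalEffect:
    @pytest.mark.parametrize(
        "ic50,hill,dose,expected",
        [
            (3.0, 1.0, 3.0, 0.5),      # dose at IC50 gives half effect
            (3.0, 1.0, 0.0, 0.0),      # no dose, no effect
            (1.0, 1.0, 3.0, 0.75),     # 3/(3+1)
            (math.inf, 1.0, 10.0, 0.0),  # inactive compound
        ],
    )
    def test_hill_values(self, ic50, hill, dose, expected):
        assert sg.fractional_effect(ic50, hill, dose) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs", [dict(ic50=3, hill=0, dose=1), dict(ic50=3, hill=1, dose=-1),
                   dict(ic50=-2, hill=1, dose=1), dict(ic50=0, hill=1, dose=1)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sg.fractional_effect(kwargs["ic50"], kwargs["hill"], kwargs["dose"])

    @given(
        ic50=st.floats(0.01, 100),
        hill=st.floats(0.2, 5),
        d1=st.floats(0, 100),
        d2=st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_dose_and_bounded(self, ic50, hill, d1, d2):
        lo, hi = sorted([d1, d2])
        f_lo = sg.fractional_effect(ic50, hill, lo)
        f_hi = sg.fractional_effect(ic50, hill, hi)
        assert 0.0 <= f_lo <= f_hi <= 1.0


class TestGenerateField:
    def test_empty_field_is_background_and_noise(self):
        cond = dataclasses.replace(sg.CONDITIONS["control"], n_cells=0)
        field, truth = sg.generate_field(cond, seed=0, geometry=SMALL_GEOM)
        assert truth.n_cells == 0 and len(truth.granules) == 0
        for chan in field.channels.values():
            arr = chan.astype(float)
            assert abs(arr.mean() - cond.background) < 2.0
            assert arr.max() <= cond.background + 5 * cond.noise_sd + 1

    def test_control_condition_has_no_cytosolic_fus_granules(self):
        cond = dataclasses.replace(sg.CONDITIONS["control"], n_cells=10)
        _, truth = sg.generate_field(cond, seed=1, geometry=SMALL_GEOM)
        venus_cyto = truth.granules.query("channel == 'venus' and compartment == 'cyto'")
        assert len(venus_cyto) == 0

    def test_planted_count_matches_ground_truth_enumeration(self):
        cond = dataclasses.replace(
            sg.CONDITIONS["CLM+NU7441"], n_cells=20, p_fus_sg=1.0, p_g3bp1_sg=0.0,
            nuclear_granule_rate=0.0,
        )
        geom = sg.FieldGeometry(shape=(512, 512))
        _, truth = sg.generate_field(cond, seed=2, geometry=geom)
        # oracle: brute-force enumeration of the ground-truth granule list
        by_cell = {}
        for rec in truth.granules.itertuples():
            assert rec.channel == "venus" and rec.compartment == "cyto"
            by_cell[rec.cell_id] = by_cell.get(rec.cell_id, 0) + 1
        assert sum(by_cell.values()) == len(truth.granules)
        flagged = set(truth.cells.loc[truth.cells.fus_sg, "cell_id"])
        assert set(by_cell) == flagged  # every flagged cell has granules

    def test_same_seed_bit_identical(self, stim_condition):
        cond = dataclasses.replace(stim_condition, n_cells=8)
        f1, t1 = sg.generate_field(cond, seed=9, geometry=SMALL_GEOM)
        f2, t2 = sg.generate_field(cond, seed=9, geometry=SMALL_GEOM)
        for name in f1.channels:
            assert np.array_equal(f1[name], f2[name])
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        pd.testing.assert_frame_equal(t1.granules, t2.granules)

    def test_nuclear_channel_confined_to_nuclei(self, small_field):
        field, truth = small_field
        cond = truth.condition
        outside = truth.nucleus_labels == 0
        limit = cond.background + 5 * cond.noise_sd
        assert field["nuclei"].astype(float)[outside].max() <= limit + 1

    def test_rendered_granule_intensity_matches_planted(self, stim_condition):
        """Mean rendered integrated intensity within 5% of closed form."""
        cond = dataclasses.replace(stim_condition, n_cells=40, noise_sd=0.0,
                                   p_fus_sg=1.0)
        vals = []
        planted = None
        for seed in (3, 4, 5, 6):
            field, truth = sg.generate_field(
                cond, seed=seed, geometry=sg.FieldGeometry(shape=(512, 512))
            )
            gr = truth.granules
            planted = gr["integrated"].iloc[0]
            # oracle: difference against the identical field rendered without
            # granules isolates the granule layer exactly
            blank, _ = sg.render_field(truth.cells, gr.iloc[0:0], cond,
                                       truth.geometry, 0)
            layer = field["venus"].astype(float) - blank["venus"].astype(float)
            venus = gr[gr.channel == "venus"]
            pts = venus[["row", "col"]].to_numpy()
            w = 6
            for i, rec in enumerate(venus.itertuples()):
                d2 = np.sum((pts - pts[i]) ** 2, axis=1)
                d2[i] = np.inf
                if d2.min() < (2 * w + 2) ** 2:  # neighbour inside the window
                    continue
                r, c = int(round(rec.row)), int(round(rec.col))
                vals.append(layer[r - w:r + w + 1, c - w:c + w + 1].sum())
        assert len(vals) >= 100
        assert np.mean(vals) == pytest.approx(planted, rel=0.05)

    def test_infeasible_layout_raises(self):
        cond = dataclasses.replace(sg.CONDITIONS["control"], n_cells=500)
        with pytest.raises(LayoutError):
            sg.generate_field(cond, seed=0, geometry=SMALL_GEOM)

    def test_dose_monotonicity_of_effective_probability(self, stim_condition):
        """Increasing dose never increases the effective SG probability."""
        eff = sg.CompoundEffect("X", fus_ic50=0.5)
        doses = [0.03, 0.3, 3.0, 10.0]
        p_eff = [
            stim_condition.p_fus_sg * (1 - sg.fractional_effect(eff.fus_ic50, eff.hill, d))
            for d in doses
        ]
        assert all(a >= b for a, b in zip(p_eff, p_eff[1:]))


class TestConditionSpec:
    @pytest.mark.parametrize("field,value", [
        ("p_fus_sg", 1.5), ("cyto_fus_fraction", -0.1), ("noise_sd", -1),
        ("granules_per_cell", -2),
    ])
    def test_invariants_enforced(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(sg.CONDITIONS["control"], **{field: value})


class TestCompoundEffect:
    def test_class_inference_rules(self):
        assert sg.CompoundEffect("a", fus_ic50=0.5).class_label == "true_hit"
        assert sg.CompoundEffect("b", fus_ic50=0.5, g3bp1_ic50=0.5).class_label == "sg_disruptor"
        assert sg.CompoundEffect("c", tox_lc50=1.0).class_label == "toxic"
        assert sg.CompoundEffect("d").class_label == "inactive"

    def test_inconsistent_label_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sg.CompoundEffect("x", fus_ic50=0.5, class_label="inactive")

    def test_invalid_potency_rejected(self):
        with pytest.raises(ValueError):
            sg.CompoundEffect("x", fus_ic50=-1.0)


class TestGenerateScreen:
    def test_inactive_compound_matches_controls(self, stim_condition):
        """Wells of an inactive compound are statistically indistinguishable
        from stimulus-control wells (permutation test on the true FUS-SG
        fraction, alpha=0.01)."""
        cond = dataclasses.replace(stim_condition, n_cells=300)
        lib = [sg.CompoundEffect(f"INA{i}") for i in range(24)]
        ds = sg.generate_screen(lib, cond, doses=[3.0], seed=4, n_controls=24)
        ctrl = ds.wells.loc[ds.wells.role == "control", "fus_sg_fraction"].to_numpy()
        comp = ds.wells.loc[ds.wells.role == "compound", "fus_sg_fraction"].to_numpy()
        observed = abs(ctrl.mean() - comp.mean())
        rng = np.random.default_rng(0)
        pooled = np.concatenate([ctrl, comp])
        null = []
        for _ in range(2000):
            rng.shuffle(pooled)
            null.append(abs(pooled[:len(ctrl)].mean() - pooled[len(ctrl):].mean()))
        p_value = float(np.mean(np.asarray(null) >= observed))
        assert p_value > 0.01

    def test_toxic_compound_survival_fraction(self, stim_condition):
        """tox_lc50 = 1 uM at 10 uM kills 10/11 of cells (Hill arithmetic)."""
        cond = dataclasses.replace(stim_condition, n_cells=3000)
        lib = [sg.CompoundEffect(f"T{i}", tox_lc50=1.0) for i in range(20)]
        ds = sg.generate_screen(lib, cond, doses=[10.0], seed=5)
        surv = ds.truth.loc[ds.truth.role == "compound", "n_cells_true"].mean()
        assert surv / cond.n_cells == pytest.approx(1.0 / 11.0, rel=0.05)

    def test_effective_probabilities_recomputed_independently(self, stim_condition):
        """Per-well effective p values equal Hill-adjusted baseline values
        recomputed from the planted parameter table (oracle)."""
        cond = dataclasses.replace(stim_condition, n_cells=200)
        rng = np.random.default_rng(1)
        lib = sg.make_library(rng, 8, 8, 8, 72)
        ds = sg.generate_screen(lib, cond, doses=[10.0, 0.3], seed=6)
        by_id = {c.compound_id: c for c in lib}
        for rec in ds.truth[ds.truth.role == "compound"].itertuples():
            eff = by_id[rec.compound_id]
            f = sg.fractional_effect(eff.fus_ic50, eff.hill, rec.dose_um)
            assert rec.p_fus_eff == pytest.approx(cond.p_fus_sg * (1 - f))
            g = sg.fractional_effect(eff.g3bp1_ic50, eff.hill, rec.dose_um)
            assert rec.p_g3bp1_eff == pytest.approx(cond.p_g3bp1_sg * (1 - g))

    def test_duplicate_compound_ids_rejected(self, stim_condition):
        lib = [sg.CompoundEffect("A"), sg.CompoundEffect("A")]
        with pytest.raises(ConfigurationError, match="duplicate"):
            sg.generate_screen(lib, stim_condition, doses=[3.0], seed=0)

    def test_zero_cell_well_readouts_are_nan(self, stim_condition):
        cond = dataclasses.replace(stim_condition, n_cells=0)
        row = _simulate_well(cond, np.random.default_rng(0))
        assert row["cell_count"] == 0
        assert math.isnan(row["fus_sg_fraction"])

    def test_image_tier_renders_every_well(self, stim_condition):
        cond = dataclasses.replace(stim_condition, n_cells=6)
        lib = [sg.CompoundEffect("A", fus_ic50=0.3)]
        geom = sg.FieldGeometry(shape=(256, 256))
        ds = sg.generate_screen(lib, cond, doses=[3.0], seed=7, tier="image",
                                geometry=geom, n_controls=2)
        assert ds.images is not None and len(ds.images) == 3
        for key, field in ds.images.items():
            assert field.shape == (256, 256)


class TestRenderField:
    def test_rendering_hand_built_layout(self):
        cells = make_cells([{"row": 64.0, "col": 64.0}, {"row": 150.0, "col": 150.0}])
        field, truth = sg.render_field(
            cells, empty_granules(), sg.CONDITIONS["control"], SMALL_GEOM, 0
        )
        assert truth.n_cells == 2
        assert set(np.unique(truth.nucleus_labels)) == {0, 1, 2}
        # nucleus pixels always belong to their own cell
        for cid in (1, 2):
            own = truth.nucleus_labels == cid
            assert np.all(truth.cell_labels[own] == cid)
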