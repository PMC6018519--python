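"""Synthetic screen generator: design, tables, gradients, rendering, truth."""

import numpy as np
import pandas as pd
import pytest

from lc3screen import imaging_io, synthgen
from lc3screen.errors import ConsistencyError, DesignError, PlacementError
from lc3screen.synthgen import (
    PARAMETERS,
    EffectSpec,
    GradientSpec,
    RenderParams,
    evaluate_segmentation,
    inject_plate_gradient,
    make_screen_design,
    null_effect,
    render_field,
    simulate_screen_tables,
)


class TestEffectSpec:
    def test_null_compound(self):
        e = EffectSpec("c", {"nuclear_lc3_intensity": 1.0})
        assert e.is_null

    def test_invalid_multiplier(self):
        with pytest.raises(DesignError):
            EffectSpec("c", {"nuclear_lc3_intensity": 0.0})

    def test_invalid_toxicity(self):
        with pytest.raises(DesignError):
            EffectSpec("c", {}, toxicity=1.5)

    def test_dose_slope_overrides_flat_multiplier(self):
        e = EffectSpec("c", {"nuclear_area": 1.5}, dose_slopes={"nuclear_area": 0.05})
        assert e.multiplier_for("nuclear_area", dose_uM=10.0) == pytest.approx(1.5)
        assert e.multiplier_for("nuclear_area", dose_uM=20.0) == pytest.approx(2.0)
        assert e.multiplier_for("nuclear_area") == pytest.approx(1.5)


class TestScreenDesign:
    def test_full_plate_layout(self):
        layouts, effects = make_screen_design(60, 2, seed=0)
        assert len(layouts) == 2
        for layout in layouts:
            counts = layout.role_counts()
            assert counts["vehicle"] == 36
            assert counts["compound"] == 60
            for w in imaging_io.border_wells():
                assert layout.wells[w].role == "vehicle"
        assert len(effects) == 60

    def test_empty_screen(self):
        layouts, effects = make_screen_design(0, 2, seed=0)
        assert layouts[0].role_counts()["vehicle"] == 36
        assert layouts[0].role_counts().get("compound", 0) == 0
        assert effects.empty

    def test_replicates_share_placement(self):
        layouts, _ = make_screen_design(30, 4, seed=5)
        ref = {w: i.compound_id for w, i in layouts[0].compound_wells().items()}
        for other in layouts[1:]:
            assert {w: i.compound_id for w, i in other.compound_wells().items()} == ref

    def test_determinism(self):
        a = make_screen_design(20, 3, seed=9)
        b = make_screen_design(20, 3, seed=9)
        assert [l.to_frame().equals(m.to_frame()) for l, m in zip(a[0], b[0])]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_screening_dose_default(self):
        layouts, _ = make_screen_design(5, 2, seed=0)
        doses = {i.dose_uM for i in layouts[0].compound_wells().values()}
        assert doses == {8.89}

    @pytest.mark.parametrize("n_comp,n_rep", [(61, 2), (10, 1), (10, 5)])
    def test_invalid_design_rejected(self, n_comp, n_rep):
        with pytest.raises(DesignError):
            make_screen_design(n_comp, n_rep, seed=0)


class TestSimulateTables:
    def test_noise_free_null_equals_baseline(self):
        design = make_screen_design(10, 2, seed=0)
        table = simulate_screen_tables(design, well_cv=0.0, seed=0)
        base = synthgen.WellBaselines().as_dict()
        for p in PARAMETERS:
            assert np.allclose(table[p], base[p])

    def test_noise_free_multiplier_exact(self):
        effects = [EffectSpec("C001", {"nuclear_lc3_intensity": 1.25})] + [
            null_effect(f"C{i:03d}") for i in range(2, 11)
        ]
        design = make_screen_design(10, 2, effects=effects, seed=0)
        table = simulate_screen_tables(design, well_cv=0.0, seed=0)
        base = synthgen.WellBaselines().nuclear_lc3_intensity
        target = table[table["compound_id"] == "C001"]["nuclear_lc3_intensity"]
        assert np.allclose(target, 1.25 * base)

    def test_toxicity_scales_density(self):
        effects = [EffectSpec("C001", {}, toxicity=0.4)]
        design = make_screen_design(1, 2, effects=effects, seed=0)
        table = simulate_screen_tables(design, well_cv=0.0, seed=0)
        dens = table[table["compound_id"] == "C001"]["cell_density"]
        assert np.allclose(dens, synthgen.WellBaselines().cell_density * 0.6)

    def test_effect_identifiability_closed_form(self):
        """With well_cv=0 and no gradient, the normalized value of a compound
        equals its multiplier divided by the plate mean multiplier."""
        from lc3screen import plate_qc

        m = 1.4
        effects = [EffectSpec("C001", {"nuclear_lc3_intensity": m})] + [
            null_effect(f"C{i:03d}") for i in range(2, 21)
        ]
        design = make_screen_design(20, 2, effects=effects, seed=0)
        table = simulate_screen_tables(design, well_cv=0.0, seed=0)
        norm = plate_qc.normalize_screen(table, ["nuclear_lc3_intensity"])
        plate_mean_mult = (36 * 1.0 + 19 * 1.0 + m) / 56
        got = norm[norm["compound_id"] == "C001"]["nuclear_lc3_intensity"].iloc[0]
        assert got == pytest.approx(m / plate_mean_mult, abs=1e-12)

    def test_mean_normalized_effect_matches_brute_force(self):
        """Averaged over many stochastic screens, the recovered normalized
        effect of a planted multiplier matches a brute-force replication of
        the full plate simulation + normalization within 2%."""
        from lc3screen import plate_qc

        m, cv, n_sims = 1.25, 0.05, 1000
        effects = [EffectSpec("C001", {"nuclear_lc3_intensity": m})] + [
            null_effect(f"C{i:03d}") for i in range(2, 61)
        ]
        design = make_screen_design(60, 2, effects=effects, seed=0)
        # oracle expectation by the vectorized fast path (independent draw)
        sim = synthgen.simulate_normalized_replicates(
            n_screens=4000, multiplier=m, well_cv=cv, n_replicates=2, seed=999
        )
        oracle = sim.replicate_values.mean()
        vals = []
        for s in range(n_sims // 10):  # 100 screens x 2 plates = 200 draws
            table = simulate_screen_tables(design, well_cv=cv, seed=1000 + s)
            norm = plate_qc.normalize_screen(table, ["nuclear_lc3_intensity"])
            vals.extend(norm[norm["compound_id"] == "C001"]["nuclear_lc3_intensity"])
        assert np.mean(vals) == pytest.approx(oracle, rel=0.02)

    def test_determinism(self):
        design = make_screen_design(10, 2, seed=0)
        a = simulate_screen_tables(design, 0.1, seed=3)
        b = simulate_screen_tables(design, 0.1, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_cv_rejected(self):
        design = make_screen_design(2, 2, seed=0)
        with pytest.raises(DesignError):
            simulate_screen_tables(design, well_cv=-0.1, seed=0)


class TestGradient:
    @pytest.mark.parametrize("orientation", GradientSpec.ORIENTATIONS)
    def test_factor_grid_invariants(self, orientation):
        g = GradientSpec(orientation, 0.2)
        f = g.factors()
        assert f.shape == (8, 12)
        assert f.mean() == pytest.approx(1.0, abs=1e-12)
        assert (f > 0).all()

    def test_amplitude_zero_is_identity(self):
        design = make_screen_design(60, 2, seed=0)  # full 8x12 grid
        table = simulate_screen_tables(design, 0.05, seed=1)
        out = inject_plate_gradient(table, GradientSpec("left-right", 0.0))
        pd.testing.assert_frame_equal(out, table)

    def test_left_right_orientation(self):
        f = GradientSpec("left-right", 0.1).factors()
        assert f[0, 0] < f[0, 11]
        assert np.allclose(f[0], f[7])  # constant down rows

    def test_unknown_orientation_rejected(self):
        with pytest.raises(DesignError, match="orientation"):
            GradientSpec("diagonal", 0.1)

    def test_partial_grid_rejected(self):
        design = make_screen_design(10, 2, seed=0)
        table = simulate_screen_tables(design, 0.0, seed=0)
        partial = table[table["role"] == "compound"]
        with pytest.raises(DesignError, match="full 8x12"):
            inject_plate_gradient(partial, GradientSpec("radial", 0.1))

    def test_wells_multiplied_by_their_factor(self):
        design = make_screen_design(60, 2, seed=0)  # full 8x12 grid
        table = simulate_screen_tables(design, 0.0, seed=0)
        g = GradientSpec("top-bottom", 0.15)
        out = inject_plate_gradient(table, g)
        for _, row in out.head(20).iterrows():
            raw = table[
                (table.plate_id == row.plate_id) & (table.well_id == row.well_id)
            ].iloc[0]
            assert row["nuclear_area"] == pytest.approx(
                raw["nuclear_area"] * g.factor_for_well(row.well_id)
            )


class TestRenderField:
    def test_zero_cells_background_only(self):
        fi, truth = render_field(n_cells=0, seed=0)
        assert truth.n_nuclei == 0 and not truth.puncta
        assert truth.labels.max() == 0
        # DNA channel is pure background
        assert np.unique(fi.dna).size == 1

    def test_determinism_bit_identical(self):
        a, ta = render_field(n_cells=8, seed=42, noise_level=10.0)
        b, tb = render_field(n_cells=8, seed=42, noise_level=10.0)
        np.testing.assert_array_equal(a.dna, b.dna)
        np.testing.assert_array_equal(a.lc3, b.lc3)
        np.testing.assert_array_equal(ta.labels, tb.labels)

    def test_intensity_range(self, noisy_field_snr5):
        fi, _ = noisy_field_snr5
        assert fi.dna.dtype == np.uint16 and fi.lc3.dtype == np.uint16

    def test_truth_consistency_puncta_compartments(self, noiseless_field):
        _, truth = noiseless_field
        for pt in truth.puncta:
            lab = truth.labels[pt.center]
            if pt.compartment == "nuclear":
                assert lab == pt.owner
            else:
                assert lab == 0

    def test_hole_pixels_are_recoverably_dark(self, noiseless_field):
        """On a noiseless render the DNA mean inside a true hole sits below
        the hole-detection threshold fraction of the nuclear median."""
        from scipy.ndimage import gaussian_filter

        fi, truth = noiseless_field
        smooth = gaussian_filter(fi.dna.astype(float), 1.0)
        for n in truth.nuclei:
            mask = truth.labels == n.label
            median = np.median(smooth[mask])
            for hy, hx in n.hole_centers:
                assert smooth[int(round(hy)), int(round(hx))] < 0.5 * median

    def test_overcrowded_field_raises_placement_error(self):
        with pytest.raises(PlacementError, match="non-overlapping"):
            render_field(n_cells=200, image_size=128, seed=0)

    def test_small_image_rejected(self):
        with pytest.raises(DesignError, match="128"):
            render_field(n_cells=1, image_size=64, seed=0)

    def test_nuclear_area_multiplier_scales_truth_masks(self):
        _, small = render_field(n_cells=5, seed=7)
        _, big = render_field(
            well_truth=EffectSpec("c", {"nuclear_area": 1.5}), n_cells=5, seed=7
        )
        a_small = (small.labels > 0).sum() / small.n_nuclei
        a_big = (big.labels > 0).sum() / big.n_nuclei
        assert a_big / a_small == pytest.approx(1.5, rel=0.1)


def _brute_force_matching(pred, truth_labels, thr):
    """All-pairs IoU + greedy matching oracle (set arithmetic, no masks reused)."""
    pred_ids = [int(l) for l in np.unique(pred) if l > 0]
    true_ids = [int(l) for l in np.unique(truth_labels) if l > 0]
    cand = []
    for pl in pred_ids:
        pset = set(zip(*np.nonzero(pred == pl)))
        for tl in true_ids:
            tset = set(zip(*np.nonzero(truth_labels == tl)))
            inter = len(pset & tset)
            if inter:
                iou = inter / len(pset | tset)
                if iou >= thr:
                    cand.append((iou, pl, tl))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_t, matches = set(), set(), []
    for iou, pl, tl in cand:
        if pl in used_p or tl in used_t:
            continue
        used_p.add(pl)
        used_t.add(tl)
        matches.append((pl, tl, iou))
    prec = 1.0 if not pred_ids else len(matches) / len(pred_ids)
    rec = 1.0 if not true_ids else len(matches) / len(true_ids)
    return prec, rec, matches


class TestEvaluateSegmentation:
    def test_perfect_prediction(self, noiseless_field):
        _, truth = noiseless_field
        prec, rec, matches = evaluate_segmentation(truth.labels, truth, 0.5)
        assert prec == 1.0 and rec == 1.0
        assert len(matches) == truth.n_nuclei
        assert all(iou == 1.0 for _, _, iou in matches)

    def test_empty_prediction_convention(self, noiseless_field):
        _, truth = noiseless_field
        prec, rec, _ = evaluate_segmentation(np.zeros_like(truth.labels), truth, 0.5)
        assert prec == 1.0  # vacuous: no predictions, none wrong
        assert rec == 0.0

    def test_shape_mismatch_rejected(self, noiseless_field):
        _, truth = noiseless_field
        with pytest.raises(ConsistencyError, match="shape"):
            evaluate_segmentation(np.zeros((10, 10), dtype=int), truth, 0.5)

    def test_jittered_masks_match_brute_force_oracle(self):
        """Shifted copies straddling IoU 0.5 agree with an all-pairs oracle."""
        rng = np.random.default_rng(3)
        truth = np.zeros((80, 80), dtype=int)
        pred = np.zeros((80, 80), dtype=int)
        for i, (cy, cx) in enumerate([(15, 15), (15, 55), (55, 15), (55, 55)], start=1):
            yy, xx = np.mgrid[0:80, 0:80]
            truth[(yy - cy) ** 2 + (xx - cx) ** 2 <= 64] = i
            shift = int(rng.integers(0, 9))  # IoU from 1.0 down past 0.5
            pred[(yy - cy - shift) ** 2 + (xx - cx) ** 2 <= 64] = i
        for thr in (0.3, 0.5, 0.7):
            got = evaluate_segmentation(pred, truth, thr)
            want = _brute_force_matching(pred, truth, thr)
            assert got[0] == want[0] and got[1] == want[1]
            assert sorted(got[2]) == pytest.approx(sorted(want[2]))
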