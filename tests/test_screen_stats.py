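"""Hit testing, waterfall ranking, dose-response OLS and BH correction."""

import numpy as np
import pandas as pd
import pytest

from lc3screen import screen_stats, synthgen
from lc3screen.errors import StatsError
from lc3screen.screen_stats import test_compound as compound_test
from lc3screen.screen_stats import (  # noqa: F401
    bh_adjust,
    dose_response_table,
    fit_dose_response,
    screen_compound_tests,
    select_hits,
    waterfall_rank,
)


class TestTestCompound:
    def test_replicates_at_null_give_p_one(self):
        res = compound_test([1.0, 1.0, 1.0])
        assert res.p_value == 1.0 and res.t_statistic == 0.0

    def test_degenerate_variance_off_null(self):
        res = compound_test([1.2, 1.2, 1.2])
        assert res.p_value == 0.0 and res.degenerate

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(StatsError):
            compound_test([1.0])

    def test_permutation_invariance_and_reflection(self):
        vals = [0.9, 1.3, 1.1]
        a = compound_test(vals)
        b = compound_test(vals[::-1])
        assert a.p_value == b.p_value
        reflected = compound_test([2.0 - v for v in vals])
        assert reflected.p_value == pytest.approx(a.p_value)
        assert {a.direction, reflected.direction} == {"up", "down"}

    def test_matches_scipy_one_sample(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        vals = rng.normal(1.1, 0.1, 4)
        res = compound_test(vals)
        ref = stats.ttest_1samp(vals, 1.0)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_null_calibration_monte_carlo(self):
        """10,000 simulated null compounds (lognormal replicate means around
        1, n=3): rejection frequency at alpha=0.001 is near nominal."""
        rng = np.random.default_rng(12345)
        sigma = np.sqrt(np.log(1 + 0.05**2))
        vals = rng.lognormal(-sigma**2 / 2, sigma, size=(10000, 3))
        from scipy import stats

        p = stats.ttest_1samp(vals, 1.0, axis=1).pvalue
        rate = (p < 0.001).mean()
        assert 0.0002 <= rate <= 0.003

    def test_referenced_variant_power(self):
        """A +25% planted effect at 5% well CV is detected at alpha=0.001 in
        >= 90% of trials with the vehicle-referenced test, n=3."""
        sim = synthgen.simulate_normalized_replicates(
            n_screens=1000, multiplier=1.25, well_cv=0.05, n_replicates=3, seed=77
        )
        detected = 0
        for i in range(1000):
            res = compound_test(
                sim.replicate_values[i],
                null_value=1.0,
                null_sd=float(sim.vehicle_sd[i]),
                null_df=sim.vehicle_df,
                null_n=3 * 36,
            )
            detected += res.p_value < 0.001
        assert detected / 1000 >= 0.90


class TestScreenTests:
    def _screen(self, seed=0, mult=1.5, n_rep=3, cv=0.02):
        from lc3screen import plate_qc

        effects = [synthgen.EffectSpec("C001", {"nuclear_lc3_intensity": mult})] + [
            synthgen.null_effect(f"C{i:03d}") for i in range(2, 31)
        ]
        design = synthgen.make_screen_design(30, n_rep, effects=effects, seed=seed)
        table = synthgen.simulate_screen_tables(design, well_cv=cv, seed=seed)
        return plate_qc.normalize_screen(table, synthgen.PARAMETERS)

    def test_planted_effect_found_nulls_not(self):
        norm = self._screen()
        tests = screen_compound_tests(norm, synthgen.PARAMETERS)
        t = tests[tests.parameter == "nuclear_lc3_intensity"].set_index("compound_id")
        assert t.loc["C001", "p_value"] < 1e-6
        assert t.loc["C001", "direction"] == "up"
        assert (t.drop("C001")["p_value"] > 0.001).mean() > 0.9

    def test_replicate_count_recorded(self):
        norm = self._screen(n_rep=4)
        tests = screen_compound_tests(norm, ["nuclear_lc3_intensity"])
        assert (tests.n_replicates == 4).all()

    def test_one_sample_reference_mode(self):
        norm = self._screen()
        tests = screen_compound_tests(norm, ["nuclear_lc3_intensity"], reference="one_sample")
        assert (tests.dof == 2).all()  # n-1 for n=3


class TestSelectHits:
    def _results(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "compound_id", "parameter", "mean_of_means", "p_value", "direction",
            ],
        )

    def test_significant_viable_compound_is_hit(self):
        rows = [
            ("A", "nuclear_lc3_intensity", 1.5, 1e-5, "up"),
            ("A", "cell_density", 1.0, 0.5, "up"),
            ("B", "nuclear_lc3_intensity", 1.0, 0.9, "up"),
            ("B", "cell_density", 1.0, 0.6, "down"),
        ]
        hits = select_hits(self._results(rows)).set_index("compound_id")
        assert hits.loc["A", "hit"] and not hits.loc["B", "hit"]

    def test_toxic_compound_excluded(self):
        rows = [
            ("A", "nuclear_lc3_intensity", 1.5, 1e-5, "up"),
            ("A", "cell_density", 0.4, 1e-6, "down"),
            ("B", "nuclear_lc3_intensity", 1.5, 1e-5, "up"),
            ("B", "cell_density", 1.0, 0.5, "up"),
        ]
        hits = select_hits(self._results(rows)).set_index("compound_id")
        assert hits.loc["A", "viability_flagged"] and not hits.loc["A", "hit"]
        assert hits.loc["B", "hit"]

    def test_sd_band_variant(self):
        rows = []
        for i in range(20):
            dens = 1.0 if i else 0.5  # one far-below-band compound
            rows += [
                (f"C{i:02d}", "nuclear_lc3_intensity", 1.0, 0.5, "up"),
                (f"C{i:02d}", "cell_density", dens, 0.5, "down"),
            ]
        hits = select_hits(
            self._results(rows), viability_rule="sd_band"
        ).set_index("compound_id")
        assert hits.loc["C00", "viability_flagged"]
        assert not hits.loc["C01", "viability_flagged"]

    def test_missing_density_rows_rejected(self):
        rows = [("A", "nuclear_lc3_intensity", 1.5, 1e-5, "up")]
        with pytest.raises(StatsError, match="cell_density"):
            select_hits(self._results(rows))


class TestWaterfall:
    def _results(self, means, sds=None, ids=None):
        ids = ids or [f"compound{i+1}" for i in range(len(means))]
        return pd.DataFrame(
            {
                "compound_id": ids,
                "parameter": "nuclear_lc3_intensity",
                "mean_of_means": means,
                "sd_of_means": sds or [0.1] * len(means),
                "n_replicates": 3,
            }
        )

    def test_sorted_ascending_by_mean(self):
        out = waterfall_rank(self._results([3.0, 1.0, 2.0]), "nuclear_lc3_intensity")
        assert list(out.compound_id) == ["compound2", "compound3", "compound1"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_ties_break_lexicographically(self):
        out = waterfall_rank(
            self._results([1.0, 1.0, 1.0], ids=["zz", "aa", "mm"]),
            "nuclear_lc3_intensity",
        )
        assert list(out.compound_id) == ["aa", "mm", "zz"]

    def test_agrees_with_independent_sort(self):
        rng = np.random.default_rng(0)
        means = list(rng.normal(1, 0.3, 50))
        res = self._results(means)
        out = waterfall_rank(res, "nuclear_lc3_intensity")
        oracle = sorted(zip(means, res.compound_id))
        assert list(out.compound_id) == [cid for _, cid in oracle]


def _ols_oracle(x, y):
    """Textbook closed-form simple regression: slope, p, F, r2, dof."""
    from scipy import stats as sps

    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    dof = n - 2
    s2 = (resid**2).sum() / dof
    se = np.sqrt(s2 / sxx)
    t = slope / se
    p = 2 * sps.t.sf(abs(t), dof)
    r2 = 1 - (resid**2).sum() / syy
    return slope, intercept, p, t * t, r2, dof


class TestDoseResponse:
    def test_matches_closed_form_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 20, 10)
            y = 1 + 0.05 * x + rng.normal(0, 0.1, 10)
            fit = fit_dose_response(x, y)
            slope, intercept, p, F, r2, dof = _ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)
            assert fit.p_value == pytest.approx(p, abs=1e-9)
            assert fit.F_statistic == pytest.approx(F, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2, abs=1e-9)
            assert fit.dof == dof == 8

    def test_too_few_points_rejected(self):
        with pytest.raises(StatsError, match=">= 3"):
            fit_dose_response([1.0, 2.0], [1.0, 2.0])

    def test_constant_dose_rejected(self):
        with pytest.raises(StatsError, match="dose"):
            fit_dose_response([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_constant_response_flagged(self):
        fit = fit_dose_response([1.25, 2.5, 5.0, 10.0, 20.0], [1.0] * 5)
        assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.constant_response

    def test_point_order_invariance(self):
        x = [1.25, 2.5, 5.0, 10.0, 20.0]
        y = [1.0, 1.1, 1.3, 1.2, 1.6]
        a = fit_dose_response(x, y)
        b = fit_dose_response(x[::-1], y[::-1])
        assert a.p_value == pytest.approx(b.p_value)
        assert a.slope == pytest.approx(b.slope)

    def test_dose_rescaling_rescales_slope_only(self):
        x = np.array([1.25, 2.5, 5.0, 10.0, 20.0])
        y = np.array([1.0, 1.1, 1.3, 1.2, 1.6])
        a = fit_dose_response(x, y)
        b = fit_dose_response(x * 1000.0, y)  # uM -> nM
        assert b.slope == pytest.approx(a.slope / 1000.0)
        for attr in ("p_value", "F_statistic", "r_squared", "dof"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr))

    def test_direction_follows_slope_sign(self):
        up = fit_dose_response([1, 2, 4, 8], [1.0, 1.1, 1.3, 1.5])
        down = fit_dose_response([1, 2, 4, 8], [1.5, 1.3, 1.1, 1.0])
        assert up.direction == "up" and down.direction == "down"


def _bh_oracle(p, q):
    """Literal step-up: sort, adjusted_i = min_{j>=i} p_(j)*m/j, clip at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0, 1)
    return adj, adj <= q


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adj, flags = bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03) and flags[0]

    def test_equal_ps_unchanged(self):
        adj, _ = bh_adjust([0.02] * 7)
        assert np.allclose(adj, 0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            adj, flags = bh_adjust(p, q=0.05)
            oadj, oflags = _bh_oracle(p, 0.05)
            np.testing.assert_allclose(adj, oadj, atol=1e-12)
            np.testing.assert_array_equal(flags, oflags)

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        adj, _ = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_realized_fdr_under_null(self):
        """All-null simulation: realized FDR stays near the nominal q."""
        rng = np.random.default_rng(2)
        fdrs = []
        for _ in range(200)[:50]:  # 50 reps suffice for the unit check
            p = rng.uniform(0, 1, 2000)
            _, flags = bh_adjust(p, q=0.05)
            fdrs.append(1.0 if flags.any() else 0.0)
        assert np.mean(fdrs) <= 0.12  # ~ q + binomial slack at 50 reps


class TestDoseResponseTable:
    def test_bh_family_is_per_parameter(self):
        rows = []
        doses = [1.25, 2.5, 5.0, 10.0, 20.0]
        rng = np.random.default_rng(0)
        for cid, slope in [("A", 0.05), ("B", 0.0), ("C", 0.0)]:
            for d in doses:
                for rep in range(2):
                    rows.append(
                        {
                            "compound_id": cid,
                            "role": "compound",
                            "dose_uM": d,
                            "nuclear_lc3_intensity": 1 + slope * d + rng.normal(0, 0.01),
                        }
                    )
        table = dose_response_table(pd.DataFrame(rows), ["nuclear_lc3_intensity"])
        assert len(table) == 3
        t = table.set_index("compound_id")
        assert t.loc["A", "bh_significant"]
        # adjusted values equal the oracle applied within the family
        oadj, _ = _bh_oracle(table["p_value"].to_numpy(), 0.05)
        np.testing.assert_allclose(table["p_adjusted"], oadj, atol=1e-12)
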