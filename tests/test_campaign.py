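"""Campaign design bookkeeping, grids, summaries, ANOVA and drift checks."""

import numpy as np
import pytest
from scipy import stats

from dielspec import (
    AnovaResult,
    CampaignPlan,
    DegenerateInputError,
    FrequencyGrid,
    MeasurementLocation,
    MeasurementRecord,
    PermittivitySpectrum,
    TissuePart,
    build_default_plan,
    build_log_grid,
    drift_diagnostic,
    filter_min_frequency,
    group_summary,
    mean_spectrum,
    one_way_anova,
    vna1_grid,
    vna2_grid,
)


def make_record(
    heart="A1",
    part=TissuePart.MYOCARDIUM,
    label="myocardium_septum",
    repeat=1,
    t=300.0,
    eps=50.0,
    sig=1.8,
    grid=None,
):
    grid = grid or FrequencyGrid(np.logspace(8.7, 10.3, 5))
    n = len(grid)
    return MeasurementRecord(
        heart_id=heart,
        location=MeasurementLocation(label, part),
        repeat_index=repeat,
        time_from_excision_min=t,
        temperature_c=24.0,
        instrument="VNA1",
        spectrum=PermittivitySpectrum(grid, np.full(n, float(eps)), np.full(n, float(sig))),
    )


class TestGrids:
    def test_three_point_decade_grid(self):
        g = build_log_grid(1.0, 100.0, 3)
        np.testing.assert_allclose(g.frequencies, [1.0, 10.0, 100.0], rtol=1e-12)

    def test_grid_is_geometric_with_exact_endpoints(self):
        g = build_log_grid(200e6, 20e9, 101)
        assert len(g) == 101
        assert g.f_min == 200e6 and g.f_max == 20e9
        ratios = g.frequencies[1:] / g.frequencies[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_instrument_grids_after_probe_cutoff(self):
        assert len(vna1_grid()) == 81
        assert vna1_grid().f_min >= 500e6
        # 101 log points on 200 MHz-8.5 GHz keep 76 at >= 500 MHz
        assert len(vna2_grid()) == 76

    def test_filter_below_minimum_is_identity(self):
        g = build_log_grid(1e9, 1e10, 11)
        assert filter_min_frequency(g, 1e6) == g

    def test_filter_is_idempotent(self):
        g = build_log_grid(200e6, 20e9, 101)
        once = filter_min_frequency(g, 500e6)
        assert filter_min_frequency(once, 500e6) == once

    def test_filter_count_matches_brute_force_scan(self):
        g = build_log_grid(200e6, 8.5e9, 101)
        kept = filter_min_frequency(g, 500e6)
        assert len(kept) == sum(1 for f in g.frequencies if f >= 500e6)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            build_log_grid(1e9, 1e8, 10)
        with pytest.raises(ValueError):
            build_log_grid(1e8, 1e9, 1)


class TestPlan:
    def test_default_plan_totals(self):
        plan = build_default_plan()
        assert plan.n_records == 1020
        assert len(plan.locations) == 17
        assert plan.repeats_per_location == 15

    def test_part_location_counts(self):
        plan = build_default_plan()
        counts = {part: len(plan.locations_for_part(part)) for part in TissuePart}
        assert counts[TissuePart.ENDOCARDIUM] == 4
        assert counts[TissuePart.MYOCARDIUM] == 1
        assert counts[TissuePart.GREAT_VESSELS] == 4
        assert counts[TissuePart.EPICARDIUM] == 6
        assert counts[TissuePart.APPENDAGE_INTERIOR] == 1
        assert counts[TissuePart.APPENDAGE_EXTERIOR] == 1
        assert sum(counts.values()) == 17

    def test_per_heart_group_sizes(self):
        """Endocardium and vessels contribute 60 records per heart, septum 15."""
        plan = build_default_plan()
        r = plan.repeats_per_location
        assert len(plan.locations_for_part(TissuePart.ENDOCARDIUM)) * r == 60
        assert len(plan.locations_for_part(TissuePart.GREAT_VESSELS)) * r == 60
        assert len(plan.locations_for_part(TissuePart.MYOCARDIUM)) * r == 15

    def test_missing_instrument_rejected(self):
        with pytest.raises(ValueError, match="instrument"):
            CampaignPlan(hearts=("A9",))


class TestGroupSummary:
    def test_identical_records_have_zero_sd(self):
        records = [make_record(repeat=i) for i in range(1, 4)]
        (s,) = group_summary(records, 2.4e9)
        assert s.n == 3
        assert s.mean_eps_r == pytest.approx(50.0)
        assert s.sd_eps_r == 0.0 and s.sd_sigma == 0.0

    def test_matches_hand_computed_means_and_sds(self):
        """8 hand-written records; means/SDs computed spreadsheet-style.

        A1 myocardium eps: (50, 52, 54, 56) -> mean 53, sample SD
        sqrt(((3^2+1^2+1^2+3^2)/3)) = sqrt(20/3).  A2 epicardium eps:
        (40, 44, 48, 52) -> mean 46, SD sqrt((36+4+4+36)/3).
        """
        recs = [
            make_record("A1", TissuePart.MYOCARDIUM, eps=e, sig=s, repeat=i)
            for i, (e, s) in enumerate([(50, 1.6), (52, 1.8), (54, 2.0), (56, 2.2)], 1)
        ] + [
            make_record("A2", TissuePart.EPICARDIUM, "epicardium_apex", eps=e, sig=1.5, repeat=i)
            for i, e in enumerate([40, 44, 48, 52], 1)
        ]
        s1, s2 = group_summary(recs, 2.4e9)
        assert (s1.heart_id, s1.part) == ("A1", TissuePart.MYOCARDIUM)
        assert s1.mean_eps_r == pytest.approx(53.0)
        assert s1.sd_eps_r == pytest.approx(np.sqrt(20.0 / 3.0))
        assert s1.mean_sigma == pytest.approx(1.9)
        assert s1.sd_sigma == pytest.approx(np.sqrt((0.09 + 0.01 + 0.01 + 0.09) / 3))
        assert s2.mean_eps_r == pytest.approx(46.0)
        assert s2.sd_eps_r == pytest.approx(np.sqrt((36 + 4 + 4 + 36) / 3))
        assert s2.sd_sigma == 0.0


class TestMeanSpectrum:
    def test_two_records_average_to_midpoint(self):
        grid = FrequencyGrid(np.logspace(9, 10, 4))
        r1 = make_record(eps=40, sig=1.0, grid=grid)
        r2 = make_record(eps=60, sig=2.0, grid=grid, repeat=2)
        mean, sd = mean_spectrum([r1, r2])
        np.testing.assert_allclose(mean.eps_r, 50.0)
        np.testing.assert_allclose(mean.sigma, 1.5)
        np.testing.assert_allclose(sd.eps_r, np.sqrt(200.0))  # sample SD of (40, 60)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        grid = FrequencyGrid(np.logspace(9, 10, 6))
        recs = [
            make_record(
                eps=1.0, sig=1.0, grid=grid, repeat=i
            )
            for i in range(1, 11)
        ]
        # replace spectra with random ones (same grid)
        recs = [
            MeasurementRecord(
                r.heart_id, r.location, r.repeat_index, r.time_from_excision_min,
                r.temperature_c, r.instrument,
                PermittivitySpectrum(grid, rng.uniform(30, 70, 6), rng.uniform(0.5, 3, 6)),
            )
            for r in recs
        ]
        mean, sd = mean_spectrum(recs)
        for j in range(6):
            vals_e = [r.spectrum.eps_r[j] for r in recs]
            vals_s = [r.spectrum.sigma[j] for r in recs]
            assert mean.eps_r[j] == pytest.approx(sum(vals_e) / 10, rel=1e-12)
            assert sd.sigma[j] == pytest.approx(np.std(vals_s, ddof=1), rel=1e-12)

    def test_mixed_grids_rejected(self):
        r1 = make_record(grid=FrequencyGrid(np.logspace(9, 10, 4)))
        r2 = make_record(grid=FrequencyGrid(np.logspace(9, 10, 5)), repeat=2)
        with pytest.raises(ValueError):
            mean_spectrum([r1, r2])


class TestOneWayAnova:
    def test_equal_group_means_give_zero_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_longhand_sums_of_squares_example(self):
        """Three groups of four, worked longhand.

        Groups (1,2,3,4), (2,3,4,5), (4,5,6,7): means 2.5, 3.5, 5.5, grand
        mean 23/6.  SS_between = 4*(16/9 + 1/9 + 25/9) * ... = 56/3, with
        SS_within = 15, df = (2, 9), so F = (28/3) / (5/3) = 5.6 exactly.
        """
        res = one_way_anova([[1, 2, 3, 4], [2, 3, 4, 5], [4, 5, 6, 7]])
        assert res.F == pytest.approx(5.6000, abs=5e-5)
        assert (res.df_between, res.df_within) == (2, 9)
        assert res.p == pytest.approx(stats.f.sf(5.6, 2, 9), rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(DegenerateInputError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_result_invariants(self):
        res = one_way_anova([[1.0, 2.0, 2.5], [4.0, 5.0, 5.5]])
        assert isinstance(res, AnovaResult)
        assert res.F >= 0 and 0 <= res.p <= 1


class TestAnovaBattery:
    @staticmethod
    def _records():
        recs = []
        for heart, base in [("A1", 50.0), ("A2", 55.0)]:
            for part, offset in [
                (TissuePart.MYOCARDIUM, 0.0),
                (TissuePart.ENDOCARDIUM, 6.0),
            ]:
                for i in range(3):
                    recs.append(
                        make_record(
                            heart, part, f"{part.value}_site", repeat=i + 1,
                            eps=base + offset + 0.5 * i, sig=1.5 + 0.01 * i,
                        )
                    )
        return recs

    def test_parts_within_heart_mode_keys_and_separation(self):
        results = anova_battery_helper(self._records(), mode="parts_within_heart")
        assert set(results) == {(h, q) for h in ("A1", "A2") for q in ("eps_r", "sigma")}
        assert results[("A1", "eps_r")].p < 0.001  # 6-unit part offset dominates

    def test_hearts_within_part_mode_keys(self):
        results = anova_battery_helper(self._records(), mode="hearts_within_part")
        assert set(results) == {
            (p, q)
            for p in ("myocardium", "endocardium")
            for q in ("eps_r", "sigma")
        }
        assert results[("myocardium", "eps_r")].p < 0.001  # 5-unit heart offset

    def test_unknown_mode_rejected(self):
        from dielspec import anova_battery

        with pytest.raises(ValueError, match="mode"):
            anova_battery(self._records(), 2.4e9, mode="nope")


def anova_battery_helper(records, mode):
    from dielspec import anova_battery

    return anova_battery(records, 2.4e9, mode=mode)


class TestDriftDiagnostic:
    def test_time_constant_signal_has_zero_slope(self):
        recs = [make_record(t=200 + 10 * i, eps=50.0, repeat=i) for i in range(1, 6)]
        slope, r = drift_diagnostic(recs, 2.4e9)
        assert slope == 0.0

    def test_exact_line_recovered(self):
        recs = [
            make_record(t=t, eps=50.0 - 0.01 * t, repeat=i)
            for i, t in enumerate([240.0, 300.0, 360.0, 420.0], 1)
        ]
        slope, r = drift_diagnostic(recs, 2.4e9)
        assert slope == pytest.approx(-0.01, rel=1e-9)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_constant_times_rejected(self):
        recs = [make_record(t=300.0, eps=50.0 + i, repeat=i) for i in range(1, 4)]
        with pytest.raises(DegenerateInputError):
            drift_diagnostic(recs, 2.4e9)

    def test_no_drift_slope_within_three_standard_errors(self):
        """Zero-drift noisy data: |slope| < 3*SE in >= 95% of 200 seeded runs."""
        n = 255
        covered = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            t = np.linspace(240.0, 510.0, n)
            y = 50.0 + 1.5 * rng.standard_normal(n)
            res = stats.linregress(t, y)
            # package result agrees with the oracle regression
            recs = None
            if seed == 0:
                recs = [
                    make_record(t=float(ti), eps=float(yi), repeat=1)
                    for ti, yi in zip(t, y)
                ]
                slope, r = drift_diagnostic(recs, 2.4e9)
                assert slope == pytest.approx(res.slope, rel=1e-9)
                assert r == pytest.approx(res.rvalue, rel=1e-9)
            if abs(res.slope) < 3 * res.stderr:
                covered += 1
        assert covered >= 190
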