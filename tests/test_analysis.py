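"""Analysis stack: window summaries, SASA filter, Hill fits, averaging."""

import numpy as np
import pytest

from phtmd import fixtures
from phtmd.analysis import (
    TitrationFit,
    average_replicates,
    combine_ramps,
    fit_hill,
    hysteresis,
    net_charge_curve,
    sasa_filter,
    summarize_windows,
)
from phtmd.samplers import ProtonationTrace, Schedule, run_phtmd
from phtmd.titration_model import analytic_hill_curve, exact_mean_charge
from phtmd.trajectory_io import WindowSummary


def trace_from(samples, ph=7.0, index=0):
    arr = np.asarray(samples, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr[:, None]
    return ProtonationTrace(window_index=index, ph=ph, samples=arr, final_state=arr[-1])


def noiseless_summaries(pka, n, grid, site_id="s", n_samples=1000):
    return [
        WindowSummary(ph=float(p), site_id=site_id, f_deprot=float(analytic_hill_curve(pka, n, p)),
                      n_transitions=1, n_samples=n_samples)
        for p in grid
    ]


class TestSummarizeWindows:
    def test_counting_example(self):
        tr = trace_from([0, 0, 1, 1, 0])
        (s,) = summarize_windows([tr], ["s"])
        assert s.f_deprot == pytest.approx(0.4)
        assert s.n_transitions == 2
        assert s.n_samples == 5

    def test_constant_samples_have_no_transitions(self):
        (s,) = summarize_windows([trace_from([1, 1, 1, 1])], ["s"])
        assert s.n_transitions == 0 and s.f_deprot == 1.0

    def test_known_generator_table(self):
        """Fixture traces with prescribed samples give the exact expected table."""
        traces = [
            trace_from([0, 1, 0, 1], ph=5.0, index=0),
            trace_from([1, 1, 0, 0], ph=4.9, index=1),
        ]
        rows = summarize_windows(traces, ["glu"], sasa={"glu": [0.8, 0.2]})
        assert [(r.ph, r.f_deprot, r.n_transitions, r.sasa_frac) for r in rows] == [
            (5.0, 0.5, 3, 0.8),
            (4.9, 0.5, 1, 0.2),
        ]

    def test_equilibration_fraction_discards_leading_samples(self):
        tr = trace_from([1, 1, 0, 0])
        (s,) = summarize_windows([tr], ["s"], equilibration_fraction=0.5)
        assert s.f_deprot == 0.0 and s.n_samples == 2

    def test_per_frame_sasa_window_averaged(self):
        traces = [trace_from([0, 1], ph=5.0), trace_from([0, 1], ph=4.9, index=1)]
        rows = summarize_windows(traces, ["s"], sasa={"s": [0.2, 0.4, 0.6, 0.8]})
        assert [r.sasa_frac for r in rows] == [pytest.approx(0.3), pytest.approx(0.7)]

    def test_bad_sasa_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            summarize_windows([trace_from([0, 1])], ["s"], sasa={"s": [0.1, 0.2, 0.3]})


class TestSasaFilter:
    def test_threshold_is_strictly_less(self):
        rows = [
            WindowSummary(ph=4.0, site_id="s", f_deprot=0.5, n_transitions=1,
                          sasa_frac=v, n_samples=10)
            for v in (0.25, 0.30, None)
        ]
        out = sasa_filter(rows)
        assert [r.valid for r in out] == [False, True, True]
        # bookkeeping only: fractions unchanged
        assert [r.f_deprot for r in out] == [0.5, 0.5, 0.5]

    def test_already_invalid_points_stay_invalid(self):
        row = WindowSummary(ph=4.0, site_id="s", f_deprot=0.5, n_transitions=1,
                            sasa_frac=0.9, n_samples=10)
        row.valid = False
        assert sasa_filter([row])[0].valid is False

    def test_burial_filter_shifts_fit_toward_unburied_value(self):
        """Excluding buried windows moves the fitted pKa down, toward truth."""
        system, traces, sasa = fixtures.buried_site_scenario(burial_ph_below=4.0, seed=2)
        rows = summarize_windows(traces, system.site_ids, sasa=sasa)
        unfiltered = fit_hill(rows, "glu")
        filtered = fit_hill(sasa_filter(rows), "glu")
        assert filtered.converged and unfiltered.converged
        assert filtered.n_points_excluded_sasa > 0
        assert filtered.pka < unfiltered.pka
        assert abs(filtered.pka - 4.2) < abs(unfiltered.pka - 4.2)

    def test_no_burial_variant_filter_is_noop(self):
        system, traces, sasa = fixtures.buried_site_scenario(burial_ph_below=0.0, seed=2)
        rows = summarize_windows(traces, system.site_ids, sasa=sasa)
        assert all(r.valid for r in sasa_filter(rows))


class TestFitHill:
    def test_exact_recovery_on_noiseless_curve(self):
        grid = np.arange(5.5, 11.5 + 1e-9, 0.02)
        fit = fit_hill(noiseless_summaries(8.5, 1.0, grid))
        assert fit.converged
        assert fit.pka == pytest.approx(8.5, abs=1e-6)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-6)
        assert fit.residual_norm < 1e-8

    @pytest.mark.parametrize("pka,n", [(4.0, 1.0), (6.2, 0.8), (9.0, 1.7)])
    def test_unbiased_across_parameter_values(self, pka, n):
        grid = np.arange(pka - 3, pka + 3 + 1e-9, 0.05)
        fit = fit_hill(noiseless_summaries(pka, n, grid))
        assert fit.pka == pytest.approx(pka, abs=1e-6)
        assert fit.hill_n == pytest.approx(n, abs=1e-6)

    def test_refuses_non_titrating_site(self):
        # all fractions below 0.1: the buried-residue situation, no pKa reported
        rows = [
            WindowSummary(ph=p, site_id="s", f_deprot=0.05, n_transitions=0, n_samples=100)
            for p in np.linspace(2, 8, 30)
        ]
        fit = fit_hill(rows)
        assert not fit.converged and fit.pka is None
        assert "midpoint" in fit.reason

    def test_refuses_too_few_points(self):
        rows = noiseless_summaries(7.0, 1.0, [6.0, 7.0, 8.0])
        fit = fit_hill(rows)
        assert not fit.converged and "valid points" in fit.reason

    def test_binomial_noise_recovery(self):
        """Seed-averaged fit is unbiased under per-window counting noise."""
        grid = np.arange(4.0, 8.0 + 1e-9, 0.02)
        truth = analytic_hill_curve(6.0, 0.9, grid)
        pkas, ns = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = rng.binomial(200, truth) / 200
            rows = [
                WindowSummary(ph=float(p), site_id="s", f_deprot=float(fi),
                              n_transitions=1, n_samples=200)
                for p, fi in zip(grid, f)
            ]
            fit = fit_hill(rows)
            assert fit.converged
            pkas.append(fit.pka)
            ns.append(fit.hill_n)
        assert np.mean(pkas) == pytest.approx(6.0, abs=0.03)
        assert np.mean(ns) == pytest.approx(0.9, abs=0.05)

    def test_requires_site_id_for_mixed_summaries(self):
        rows = noiseless_summaries(7.0, 1.0, [6, 7, 8], site_id="a") + noiseless_summaries(
            7.0, 1.0, [6, 7, 8], site_id="b"
        )
        with pytest.raises(ValueError, match="multiple sites"):
            fit_hill(rows)


class TestCombineRamps:
    def test_merged_coverage_and_sorting(self):
        down = noiseless_summaries(5.0, 1.0, np.arange(7.0, 2.0 - 1e-9, -0.5))
        up = noiseless_summaries(5.0, 1.0, np.arange(7.0, 12.0 + 1e-9, 0.5))
        merged = combine_ramps(down, up)
        phs = [s.ph for s in merged]
        assert phs == sorted(phs)
        assert min(phs) == 2.0 and max(phs) == 12.0
        # shared start pH kept twice, fit treats them as replicates
        assert phs.count(7.0) == 2

    def test_empty_second_set_is_identity(self):
        a = noiseless_summaries(5.0, 1.0, [4.0, 5.0, 6.0])
        assert combine_ramps(a, []) == sorted(a, key=lambda s: (s.ph, s.site_id))

    def test_fit_of_combined_halves_equals_full_range_fit(self):
        full = noiseless_summaries(6.5, 1.1, np.arange(2.0, 12.0 + 1e-9, 0.1))
        lo = noiseless_summaries(6.5, 1.1, np.arange(2.0, 7.0 + 1e-9, 0.1))
        hi = noiseless_summaries(6.5, 1.1, np.arange(7.1, 12.0 + 1e-9, 0.1))
        f_full = fit_hill(full)
        f_merged = fit_hill(combine_ramps(lo, hi))
        assert f_merged.pka == pytest.approx(f_full.pka, abs=1e-8)
        assert f_merged.hill_n == pytest.approx(f_full.hill_n, abs=1e-8)


class TestAverageReplicates:
    def _fit(self, pka, converged=True):
        return TitrationFit(site_id="glu", pka=pka, hill_n=1.0 if converged else None,
                            n_points_used=10, converged=converged)

    def test_six_replicate_worked_example(self):
        values = [4.21, 3.85, 3.78, 3.52, 3.64, 4.05]
        summary = average_replicates([self._fit(v) for v in values])
        assert summary.rounded(2) == 3.84
        assert summary.n_converged == 6
        assert summary.sd_pka > 0

    def test_single_replicate(self):
        summary = average_replicates([self._fit(4.5)])
        assert summary.mean_pka == 4.5 and summary.sd_pka is None

    def test_nonconverged_excluded_from_mean(self):
        summary = average_replicates([self._fit(4.0), self._fit(None, False), self._fit(5.0)])
        assert summary.mean_pka == pytest.approx(4.5)
        assert summary.values == [4.0, None, 5.0]
        assert summary.n_converged == 2

    def test_permutation_invariance(self, rng):
        values = list(rng.uniform(3, 5, size=7))
        a = average_replicates([self._fit(v) for v in values])
        shuffled = list(values)
        rng.shuffle(shuffled)
        b = average_replicates([self._fit(v) for v in shuffled])
        assert a.mean_pka == pytest.approx(b.mean_pka, abs=1e-12)
        assert a.sd_pka == pytest.approx(b.sd_pka, abs=1e-12)


class TestHysteresis:
    def test_arithmetic(self):
        up = TitrationFit("c", 8.14, 1.0, 10, converged=True)
        down = TitrationFit("c", 8.20, 1.0, 10, converged=True)
        assert hysteresis(up, down) == pytest.approx(0.06)
        assert hysteresis(up, up) == 0.0

    def test_missing_when_either_fit_failed(self):
        ok = TitrationFit("c", 8.14, 1.0, 10, converged=True)
        bad = TitrationFit("c", None, None, 2, converged=False)
        assert hysteresis(ok, bad) is None


class TestNetChargeCurve:
    def test_fully_protonated_and_deprotonated_limits(self, acfca_system):
        prot = trace_from(np.zeros((5, 2)), ph=5.0)
        deprot = trace_from(np.ones((5, 2)), ph=12.0)
        curve = net_charge_curve([prot, deprot], acfca_system)
        static = acfca_system.static_charge_total()  # +1 - 1 = 0
        assert curve[0, 1] == pytest.approx(0.0 + static)
        assert curve[1, 1] == pytest.approx(-2.0 + static)

    def test_windowed_charge_tracks_enumeration_oracle(self, asp_system):
        sched = Schedule(ph_start=3.0, ph_end=5.0, rate=0.1, steps_per_window=4000, seed=4)
        traces = run_phtmd(asp_system, sched)
        curve = net_charge_curve(traces, asp_system)
        exact = exact_mean_charge(asp_system, curve[:, 0])
        se = 3 * np.sqrt(0.25 / 4000) + 0.01  # sampling + ramp-lag allowance
        assert np.abs(curve[:, 1] - exact).max() < 3 * se

    def test_all_acid_exact_charge_nonincreasing_in_ph(self):
        sys_ = fixtures.acfca_like()
        q = exact_mean_charge(sys_, np.linspace(6, 12, 31))
        assert (np.diff(q) <= 1e-12).all()
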