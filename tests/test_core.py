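"""Morse/descriptor fitting, cleavage detection, sigmoid entropy, steepness
tuning and barrier extraction, checked against independent oracles
(grid searches, bisection, dense-grid maximization)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barrierless import core
from barrierless.core import (
    CleavagePoint,
    DescriptorFit,
    EntropySigmoid,
    FitError,
    MorseFit,
    PipelineError,
    assemble_gibbs,
    cleavage_distance,
    entropy_sigmoid,
    find_barrier,
    fit_descriptor,
    fit_morse,
    normalize_descriptor,
    run_pipeline,
    tune_steepness,
)
from barrierless.scan_io import DescriptorSeries, DissociationScan
from barrierless.synthetic import SyntheticCase, gen_descriptor, gen_scan


def _morse(r, de, a, req):
    d = np.asarray(r) - req
    return de * (np.exp(-2 * a * d) - 2 * np.exp(-a * d))


def _sigmoid(r, amp, rc, k):
    return amp / (1.0 + np.exp(-k * (np.asarray(r) - rc)))


def _scan(de=20.0, a=2.0, req=1.95, r0=1.90, r1=6.0, step=0.05, noise=0.0,
          seed=0):
    r = r0 + step * np.arange(int(round((r1 - r0) / step)) + 1)
    e = _morse(r, de, a, req)
    if noise:
        e = e + np.random.default_rng(seed).normal(0, noise, r.size)
    return DissociationScan(r, e)


# ---------------------------------------------------------------------------
# Morse fit
# ---------------------------------------------------------------------------

class TestFitMorse:
    def test_noiseless_recovery_to_machine_precision(self):
        fit = fit_morse(_scan())
        assert fit.well_depth == pytest.approx(20.0, rel=1e-6)
        assert fit.decay == pytest.approx(2.0, rel=1e-6)
        assert fit.r_eq == pytest.approx(1.95, rel=1e-6)
        assert fit.rss < 1e-12

    def test_fixed_r_eq_mode(self):
        fit = fit_morse(_scan(), fix_r_eq=1.95)
        assert fit.r_eq == 1.95
        assert fit.well_depth == pytest.approx(20.0, rel=1e-8)

    def test_predicted_minimum_is_minus_well_depth(self):
        fit = fit_morse(_scan())
        assert fit.predict(fit.r_eq) == pytest.approx(-fit.well_depth, rel=1e-12)
        assert abs(fit.predict(50.0)) < 1e-12

    def test_noisy_fit_matches_grid_search_oracle(self):
        scan = _scan(noise=0.1, seed=123)
        fit = fit_morse(scan)

        # independent oracle: iterative 3-D grid refinement of the same SSE
        def sse(de, a, req):
            return np.sum((_morse(scan.distances, de, a, req)
                           - scan.energies) ** 2)

        best = (20.0, 2.0, 1.95)
        spans = np.array([5.0, 0.5, 0.1])
        for _ in range(6):
            de_g = np.linspace(best[0] - spans[0], best[0] + spans[0], 21)
            a_g = np.linspace(best[1] - spans[1], best[1] + spans[1], 21)
            r_g = np.linspace(best[2] - spans[2], best[2] + spans[2], 21)
            vals = [(sse(de, a, rq), (de, a, rq))
                    for de in de_g for a in a_g for rq in r_g]
            best = min(vals)[1]
            spans = spans * 0.12
        assert fit.well_depth == pytest.approx(best[0], abs=1e-3)
        assert fit.decay == pytest.approx(best[1], abs=1e-3)
        assert fit.r_eq == pytest.approx(best[2], abs=1e-3)
        assert sse(fit.well_depth, fit.decay, fit.r_eq) <= sse(*best) * (1 + 1e-9)

    def test_unbound_scan_is_rejected(self):
        r = np.linspace(2.0, 6.0, 40)
        with pytest.raises(FitError, match="no bound well"):
            fit_morse(DissociationScan(r, 10.0 * np.exp(-r)))

    def test_still_decreasing_scan_is_rejected(self):
        r = np.linspace(2.0, 6.0, 40)
        with pytest.raises(FitError, match="still decreasing"):
            fit_morse(DissociationScan(r, -np.exp(r / 3)))


# ---------------------------------------------------------------------------
# descriptor normalization and fit
# ---------------------------------------------------------------------------

class TestNormalizeDescriptor:
    def test_affine_map(self):
        s = DescriptorSeries("MBO", [1.0, 2.0, 3.0], [4.0, 2.0, 3.0])
        out = normalize_descriptor(s)
        np.testing.assert_allclose(out.normalized_values, [1.0, 0.0, 0.5])

    def test_already_unit_interval_series_is_unchanged(self):
        v = np.array([1.0, 0.6, 0.3, 0.0])
        s = DescriptorSeries("IBSI", [1.0, 2.0, 3.0, 4.0], v)
        np.testing.assert_allclose(normalize_descriptor(s).normalized_values, v)

    def test_monotone_series_stays_monotone(self):
        r = np.linspace(2.0, 6.0, 30)
        v = np.exp(-r)
        out = normalize_descriptor(DescriptorSeries("IBSI", r, v))
        assert np.all(np.diff(out.normalized_values) < 0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_descriptor(
                DescriptorSeries("bad", [1.0, 2.0, 3.0], [1.0, 1.0, 1.0]))


class TestFitDescriptor:
    def _series(self, d0=1.0, k=1.5, noise=0.0, seed=0):
        r = 1.95 + 0.05 * np.arange(82)
        v = d0 * np.exp(-k * r)
        if noise:
            v = v + np.random.default_rng(seed).normal(0, noise, r.size)
        return DescriptorSeries("IBSI", r, v, np.clip(v, 0.0, 1.0))

    def test_noiseless_recovery(self):
        fit = fit_descriptor(self._series())
        assert fit.d0 == pytest.approx(1.0, rel=1e-6)
        assert fit.k_desc == pytest.approx(1.5, rel=1e-6)

    def test_noisy_fit_matches_grid_search_oracle(self):
        s = self._series(noise=0.02, seed=11)
        fit = fit_descriptor(s)

        def sse(d0, k):
            return np.sum((d0 * np.exp(-k * s.distances)
                           - s.normalized_values) ** 2)

        best = (1.0, 1.5)
        spans = np.array([0.8, 0.8])
        shrunk = 0
        while shrunk < 7:
            d_g = np.linspace(best[0] - spans[0], best[0] + spans[0], 41)
            k_g = np.linspace(max(best[1] - spans[1], 1e-6),
                              best[1] + spans[1], 41)
            vals = [(sse(d0, k), (d0, k)) for d0 in d_g for k in k_g]
            best = min(vals)[1]
            interior = (d_g[0] < best[0] < d_g[-1]
                        and k_g[0] < best[1] < k_g[-1])
            if interior:
                spans = spans * 0.1
                shrunk += 1
        # the LSQ valley is flat along the (d0, k) correlation, so parameter
        # agreement is checked at the scale the objective resolves
        assert fit.d0 == pytest.approx(best[0], abs=1e-3)
        assert fit.k_desc == pytest.approx(best[1], abs=1e-3)
        assert sse(fit.d0, fit.k_desc) <= sse(*best) * (1 + 1e-9)

    def test_local_optimality_against_perturbed_decay(self):
        case = SyntheticCase()
        series = normalize_descriptor(gen_descriptor(case))
        fit = fit_descriptor(series)

        def rss(d0, k):
            return np.sum((d0 * np.exp(-k * series.distances)
                           - series.normalized_values) ** 2)

        for factor in (0.9, 1.1):
            assert fit.rss < rss(fit.d0, fit.k_desc * factor)

    def test_non_decaying_series_rejected(self):
        r = np.linspace(2.0, 6.0, 30)
        v = 1.0 - np.exp(-r)  # increasing
        vn = (v - v.min()) / (v.max() - v.min())
        with pytest.raises(FitError, match="unsuitable"):
            fit_descriptor(DescriptorSeries("bad", r, v, vn))

    def test_unnormalized_series_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            fit_descriptor(DescriptorSeries("IBSI", [1, 2, 3], [3, 2, 1]))


# ---------------------------------------------------------------------------
# cleavage distance
# ---------------------------------------------------------------------------

class TestCleavageDistance:
    def test_closed_form_example(self):
        point = cleavage_distance(DescriptorFit(1.0, 1.0), 0.05)
        assert point.r_cleave == pytest.approx(np.log(20.0), rel=1e-12)

    def test_closed_form_matches_bisection_oracle(self):
        fit = DescriptorFit(0.83, 1.37)
        for gamma in (0.001, 0.01, 0.02, 0.1):
            point = cleavage_distance(fit, gamma)
            # oracle: bisect |dD/dr| - gamma = k*d0*exp(-k*r) - gamma
            lo, hi = 0.0, 100.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if fit.k_desc * fit.d0 * np.exp(-fit.k_desc * mid) > gamma:
                    lo = mid
                else:
                    hi = mid
            assert point.r_cleave == pytest.approx(0.5 * (lo + hi), abs=1e-9)
            # defining inequality holds with equality
            slope = abs(-fit.k_desc * fit.d0
                        * np.exp(-fit.k_desc * point.r_cleave))
            assert slope == pytest.approx(gamma, abs=1e-9)

    @given(st.floats(0.2, 3.0), st.floats(0.5, 3.0),
           st.floats(0.001, 0.1), st.floats(0.001, 0.1))
    def test_higher_cutoff_gives_smaller_cleavage_distance(self, d0, k, g1, g2):
        fit = DescriptorFit(d0, k)
        if g1 == g2:
            return
        r1 = cleavage_distance(fit, g1).r_cleave
        r2 = cleavage_distance(fit, g2).r_cleave
        assert (r1 > r2) == (g1 < g2)

    def test_cleavage_before_scan_start_rejected(self):
        fit = DescriptorFit(1.0, 1.5)
        with pytest.raises(ValueError, match="already broken"):
            cleavage_distance(fit, 0.2, r_min=1.95)

    def test_non_positive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cleavage_distance(DescriptorFit(1.0, 1.0), 0.0)


# ---------------------------------------------------------------------------
# sigmoid entropy
# ---------------------------------------------------------------------------

class TestEntropySigmoid:
    @given(st.floats(-80.0, -1.0), st.floats(2.0, 5.0), st.floats(0.2, 12.0))
    def test_half_amplitude_at_cleavage_exactly(self, amp, rc, k):
        model = EntropySigmoid(amp, rc, k)
        assert entropy_sigmoid(rc, model) == amp / 2.0

    def test_saturation_far_from_cleavage(self):
        model = EntropySigmoid(-35.0, 3.0, 4.0)
        assert abs(entropy_sigmoid(3.0 - 20.0 / 4.0, model)) < 1e-8 * 35.0
        assert entropy_sigmoid(3.0 + 20.0 / 4.0, model) == pytest.approx(
            -35.0, abs=1e-8 * 35.0)

    def test_monotone_in_r(self):
        model = EntropySigmoid(-35.0, 3.0, 4.0)
        r = np.linspace(1.0, 6.0, 500)
        assert np.all(np.diff(entropy_sigmoid(r, model)) < 0)


# ---------------------------------------------------------------------------
# assembly and barrier
# ---------------------------------------------------------------------------

class TestAssembleGibbs:
    def test_zero_amplitude_reduces_to_morse(self):
        morse = MorseFit(20.0, 2.0, 1.95)
        grid = np.linspace(1.95, 6.0, 100)
        res = assemble_gibbs(morse, EntropySigmoid(0.0, 3.0, 4.0), grid)
        np.testing.assert_allclose(res.delta_g, morse.predict(grid), atol=1e-14)

    def test_large_r_limit_is_the_amplitude(self):
        morse = MorseFit(20.0, 2.0, 1.95)
        sig = EntropySigmoid(-35.0, 3.0, 4.0)
        grid = np.linspace(1.95, 30.0, 50)
        res = assemble_gibbs(morse, sig, grid)
        assert res.delta_g[-1] == pytest.approx(-35.0, abs=1e-6)

    def test_pointwise_sum_matches_independent_evaluation(self):
        morse = MorseFit(22.0, 2.3, 2.0)
        sig = EntropySigmoid(-30.0, 3.2, 5.0)
        grid = np.linspace(2.0, 7.0, 137)
        res = assemble_gibbs(morse, sig, grid)
        want = _morse(grid, 22.0, 2.3, 2.0) + _sigmoid(grid, -30.0, 3.2, 5.0)
        np.testing.assert_allclose(res.delta_g, want, atol=1e-12)

    def test_grid_missing_r_eq_rejected(self):
        with pytest.raises(ValueError, match="r_eq"):
            assemble_gibbs(MorseFit(20.0, 2.0, 1.95),
                           EntropySigmoid(-35.0, 3.0, 4.0),
                           np.linspace(2.5, 6.0, 10))


class TestFindBarrier:
    def _result(self, amp, rc, k, de=20.0, a=2.0, req=2.0):
        morse = MorseFit(de, a, req)
        sig = EntropySigmoid(amp, rc, k)
        grid = np.linspace(req, 8.0, 200)
        return find_barrier(assemble_gibbs(morse, sig, grid))

    def test_matches_dense_grid_oracle(self):
        res = self._result(-35.0, 3.0, 4.0)
        r = np.arange(2.0, 10.0, 1e-4)
        g = _morse(r, 20.0, 2.0, 2.0) + _sigmoid(r, -35.0, 3.0, 4.0)
        assert not res.no_barrier
        assert res.barrier_dissociation == pytest.approx(
            g.max() - g[0], abs=1e-4)
        assert res.r_ts == pytest.approx(r[np.argmax(g)], abs=1e-3)

    def test_association_minus_dissociation_identity(self):
        res = self._result(-35.0, 3.0, 4.0)
        g_req = res.morse.predict(2.0) + res.sigmoid.predict(2.0)
        assert (res.barrier_association - res.barrier_dissociation
                == pytest.approx(g_req - (-35.0), abs=1e-6))

    def test_monotone_curve_has_no_barrier(self):
        # entropy already saturated just past r_eq: the curve climbs
        # monotonically to the asymptote with no interior maximum
        res = self._result(-35.0, 1.8, 10.0)
        assert res.no_barrier
        assert res.barrier_dissociation is None
        assert res.barrier_association is None
        assert res.r_ts is None

    def test_grid_density_stability(self):
        coarse = self._result(-35.0, 3.0, 4.0)
        morse = MorseFit(20.0, 2.0, 2.0)
        sig = EntropySigmoid(-35.0, 3.0, 4.0)
        grid = np.linspace(2.0, 8.0, 200)
        fine = find_barrier(assemble_gibbs(morse, sig, grid), grid_step=5e-4)
        assert fine.barrier_dissociation == pytest.approx(
            coarse.barrier_dissociation, abs=1e-4)


class TestTuneSteepness:
    def test_no_op_when_start_steepness_is_clean(self):
        morse = MorseFit(20.0, 2.0, 1.95)
        sig, res = tune_steepness(morse, -35.0, 4.8, r_end_hint=6.0)
        assert sig.k_sig == 10.0
        assert not res.no_barrier

    def test_dip_case_shrinks_k_and_final_curve_is_clean(self):
        # steep Morse with nearby cleavage: k=10 gives a post-TS dip
        morse = MorseFit(45.0, 2.8, 1.95)
        sig, res = tune_steepness(morse, -30.0, 3.6, r_end_hint=6.0)
        assert sig.k_sig < 10.0
        r = np.arange(res.r_ts, 3.6 + 10.0 / sig.k_sig, 1e-3)
        g = morse.predict(r) + sig.predict(r)
        suffix = np.maximum.accumulate(g[::-1])[::-1]
        assert np.all((suffix - g)[:-1] <= 0.01 + 1e-9)

    def test_returned_k_is_maximal(self):
        morse = MorseFit(45.0, 2.8, 1.95)
        sig, res = tune_steepness(morse, -30.0, 3.6, r_end_hint=6.0)
        k_bigger = sig.k_sig / 0.9
        big = EntropySigmoid(-30.0, 3.6, k_bigger)
        r = np.arange(1.95, max(6.0, 3.6 + 10.0 / k_bigger), 1e-3)
        g = morse.predict(r) + big.predict(r)
        i_ts = np.argmax(g)
        tail = g[i_ts:]
        suffix = np.maximum.accumulate(tail[::-1])[::-1]
        assert np.any((suffix - tail)[:-1] > 0.01)

    def test_floor_breach_raises(self):
        morse = MorseFit(45.0, 2.8, 1.95)
        with pytest.raises(core.TuningError):
            tune_steepness(morse, -30.0, 3.6, k_floor=9.99, shrink=0.9,
                           r_end_hint=6.0)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class TestRunPipeline:
    def test_gamma_sweep_barrier_non_increasing(self):
        case = SyntheticCase()
        scan, desc = gen_scan(case), gen_descriptor(case)
        barriers = []
        for gamma in (0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1):
            res = run_pipeline(scan, desc, case.amplitude, gamma)
            barriers.append(-np.inf if res.no_barrier
                            else res.barrier_dissociation)
        assert all(b1 >= b2 - 1e-9 for b1, b2 in zip(barriers, barriers[1:]))

    def test_zero_amplitude_pure_attraction_has_no_barrier(self):
        case = SyntheticCase(amplitude=0.0)
        res = run_pipeline(gen_scan(case), gen_descriptor(case), 0.0, 0.02)
        assert res.no_barrier

    def test_report_carries_every_stage_parameter(self):
        case = SyntheticCase()
        res = run_pipeline(gen_scan(case), gen_descriptor(case),
                           case.amplitude, 0.02)
        assert res.morse.well_depth == pytest.approx(20.0, rel=1e-6)
        assert res.descriptor_fit is not None
        assert res.cleavage is not None
        assert res.metadata["gamma_cleave"] == 0.02
        assert "sigmoid_residual_at_r_eq" in res.metadata

    def test_offset_flag_zeroes_entropy_at_req_without_moving_barriers(self):
        case = SyntheticCase()
        scan, desc = gen_scan(case), gen_descriptor(case)
        plain = run_pipeline(scan, desc, case.amplitude, 0.02)
        shifted = run_pipeline(scan, desc, case.amplitude, 0.02,
                               offset_at_req=True)
        residual = plain.metadata["sigmoid_residual_at_r_eq"]
        assert residual != 0.0
        np.testing.assert_allclose(shifted.delta_g,
                                   plain.delta_g - residual, atol=1e-12)
        assert shifted.barrier_dissociation == plain.barrier_dissociation
        assert shifted.barrier_association == plain.barrier_association

    def test_stage_errors_are_tagged(self):
        case = SyntheticCase()
        desc = gen_descriptor(case)
        r = np.linspace(2.0, 6.0, 40)
        unbound = DissociationScan(r, 10.0 * np.exp(-r))
        with pytest.raises(PipelineError, match=r"\[fit_morse\]"):
            run_pipeline(unbound, desc, -35.0, 0.02)
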