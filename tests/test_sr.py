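import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrpipe.io import PSTH
from cmrpipe.sr import (SRProfile, bootstrap_significance, cell_sigma,
                        first_crossing, masking_release, pip_window_mean,
                        population_mean_sr, select_responsive, signal_response,
                        sr_snr_function, subpopulation_sensitivity, upsample)

EDGES = np.arange(0.0, 2.0 + 0.0025, 0.005)


def psth(rate, cell="a"):
    rate = np.asarray(rate, dtype=float)
    return PSTH(cell_id=cell, condition={}, bin_edges=EDGES[:len(rate) + 1],
                rate=rate, n_trials=10)


def profile(snr, values_in_window, sigma=1.0):
    """SRProfile whose pip-window bins hold the given constant value."""
    sr = np.zeros(400)
    sr[235:255] = values_in_window
    return SRProfile(cell_id="a", family="NB", snr_db=snr,
                     bin_edges=EDGES, sr=sr, sigma=sigma)


class TestCellSigma:
    def test_two_level_bins(self):
        p = psth([0.0, 10.0] * 100)
        assert cell_sigma([p]) == pytest.approx(5.0)  # population SD

    def test_zero_variance_excluded(self):
        with pytest.raises(ValueError):
            cell_sigma([psth(np.full(400, 4.0))])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.poisson(5, 400).astype(float), rng.poisson(9, 400).astype(float)
        assert cell_sigma([psth(a), psth(b)]) == pytest.approx(
            cell_sigma([psth(b), psth(a)]))


class TestSignalResponse:
    def test_identical_psths_zero(self):
        p = psth(np.arange(400, dtype=float))
        sr = signal_response(p, p, sigma=2.0)
        assert np.all(sr.sr == 0.0)

    def test_one_sigma_difference(self):
        n = psth(np.full(400, 10.0))
        s_rate = np.full(400, 10.0)
        s_rate[240] = 15.0
        sr = signal_response(psth(s_rate), n, sigma=5.0)
        assert sr.sr[240] == pytest.approx(1.0)

    def test_arithmetic(self):
        sr = signal_response(psth(np.full(400, 40.0)), psth(np.full(400, 30.0)),
                             sigma=5.0)
        assert np.all(sr.sr == pytest.approx(2.0))

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            signal_response(psth(np.zeros(400)), psth(np.zeros(300)), 1.0)

    def test_sr_linearity(self):
        # adding c*sigma per bin shifts SR by exactly c
        rng = np.random.default_rng(1)
        base = rng.poisson(20, 400).astype(float)
        n = psth(rng.poisson(20, 400).astype(float))
        sigma, c = 3.0, 1.7
        sr1 = signal_response(psth(base), n, sigma)
        sr2 = signal_response(psth(base + c * sigma), n, sigma)
        assert np.allclose(sr2.sr - sr1.sr, c)


class TestSRFunction:
    SNRS = [-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0]

    def test_flat_zero_no_threshold(self):
        fn = sr_snr_function([profile(s, 0.0) for s in self.SNRS])
        assert fn.threshold_db is None

    def test_interpolated_crossing(self):
        vals = {s: 0.0 for s in self.SNRS}
        vals[5.0] = 1.0
        vals[10.0] = 1.0
        vals[15.0] = 1.0
        vals[20.0] = 1.0
        fn = sr_snr_function([profile(s, vals[s]) for s in self.SNRS])
        assert fn.threshold_db == pytest.approx(2.5, abs=0.051)

    def test_exact_criterion_at_measured_snr(self):
        vals = {s: 0.0 for s in self.SNRS}
        for s in (10.0, 15.0, 20.0):
            vals[s] = 0.5
        fn = sr_snr_function([profile(s, vals[s]) for s in self.SNRS])
        assert fn.threshold_db == pytest.approx(10.0)

    def test_threshold_monotone_under_offset(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0.2, 0.3, len(self.SNRS))
        fn = sr_snr_function([profile(s, v) for s, v in zip(self.SNRS, vals)])
        fn_up = sr_snr_function([profile(s, v + 0.25)
                                 for s, v in zip(self.SNRS, vals)])
        if fn.threshold_db is not None:
            assert fn_up.threshold_db is not None
            assert fn_up.threshold_db <= fn.threshold_db

    def test_first_crossing_retained(self):
        # non-monotone function recrosses; the lowest crossing is kept
        vals = dict(zip(self.SNRS, [0.0, 0.8, 0.1, 0.8, 0.8, 0.8, 0.8]))
        fn = sr_snr_function([profile(s, vals[s]) for s in self.SNRS])
        assert fn.threshold_db < -5.0


class TestBootstrap:
    def test_disjoint_supports_significant(self):
        assert bootstrap_significance(np.zeros(30), np.full(30, 50.0), seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        a, b = rng.poisson(5, 30), rng.poisson(8, 30)
        assert (bootstrap_significance(a, b, seed=7)
                == bootstrap_significance(a, b, seed=7))

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            bootstrap_significance([1, 2], [3, 4], seed=0)

    def test_select_responsive(self):
        flags = {
            "a": {("CM_long", 20.0): True, ("NB", 20.0): False},
            "b": {("CM_long", 20.0): False, ("NB", 20.0): False},
            "c": {("NB", 5.0): True, ("CM_long", 5.0): True},
        }
        overall, per_fam = select_responsive(flags)
        assert overall == {"a", "c"}
        assert per_fam["CM_long"] == {"a", "c"}
        assert per_fam["NB"] == {"c"}


class TestPopulation:
    SNRS = [-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0]

    def test_identical_cells(self):
        prof = {c: [profile(s, 0.3) for s in self.SNRS] for c in "abc"}
        fn = population_mean_sr(prof)
        assert np.allclose(fn.values, 0.3)

    def test_mean_of_two(self):
        prof = {"a": [profile(s, 0.0) for s in self.SNRS],
                "b": [profile(s, 2.0) for s in self.SNRS]}
        fn = population_mean_sr(prof)
        assert np.allclose(fn.values, 1.0)

    def test_matches_independent_mean(self):
        rng = np.random.default_rng(4)
        prof = {c: [profile(s, rng.normal()) for s in self.SNRS]
                for c in range(20)}
        fn = population_mean_sr(prof)
        oracle = np.mean([[pip_window_mean(p) for p in profs]
                          for profs in prof.values()], axis=0)
        assert np.allclose(fn.values, oracle)

    def test_empty_set(self):
        with pytest.raises(ValueError):
            population_mean_sr({})


class TestSubpopulation:
    SNRS = np.array([-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0])

    def test_single_cell_bin(self):
        vals = np.array([[0.0, 0.0, 0.1, 0.3, 0.6, 0.8, 0.9]])
        sens = subpopulation_sensitivity(vals, self.SNRS, seed=0)
        grid, gv = upsample(self.SNRS, vals[0])
        assert sens == first_crossing(grid, gv, 0.25)

    def test_tuned_bin_more_sensitive(self):
        rng = np.random.default_rng(5)
        tuned = 0.9 / (1 + np.exp(-(self.SNRS - 0.0))) + rng.normal(0, 0.01, (40, 7))
        untuned = 0.9 / (1 + np.exp(-(self.SNRS - 10.0))) + rng.normal(0, 0.01, (40, 7))
        s_t = subpopulation_sensitivity(tuned, self.SNRS, seed=1)
        s_u = subpopulation_sensitivity(untuned, self.SNRS, seed=1)
        assert s_t < s_u

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0.2, 0.2, (30, 7))
        assert (subpopulation_sensitivity(vals, self.SNRS, seed=2)
                == subpopulation_sensitivity(vals, self.SNRS, seed=2))

    def test_empty_bin(self):
        with pytest.raises(ValueError):
            subpopulation_sensitivity(np.empty((0, 7)), self.SNRS)


class TestMaskingRelease:
    def test_equal_thresholds(self):
        assert masking_release(4.0, 4.0) == 0.0

    def test_subtraction(self):
        assert masking_release(8.0, 2.0) == pytest.approx(6.0)

    def test_missing_threshold(self):
        assert masking_release(None, 2.0) is None
        assert masking_release(3.0, None) is None


@given(st.lists(st.floats(min_value=-2, max_value=2), min_size=7, max_size=7),
       st.floats(min_value=0.01, max_value=1.0))
@settings(max_examples=50, deadline=None)
def test_threshold_never_increases_with_offset(vals, offset):
    snrs = np.array([-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0])
    grid, gv = upsample(snrs, vals)
    t1 = first_crossing(grid, gv, 0.5)
    grid2, gv2 = upsample(snrs, np.asarray(vals) + offset)
    t2 = first_crossing(grid2, gv2, 0.5)
    if t1 is not None:
        assert t2 is not None and t2 <= t1
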