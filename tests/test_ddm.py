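"""Wiener first-passage numerics against closed forms and the brute-force
Euler-Maruyama oracle."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gonogo_ddm import (Boundary, DDMParams, choice_probability,
                        mean_decision_time, sample_fpt, sample_trials,
                        trial_loglik, wfpt_density)
from gonogo_ddm.io import TrialRecord

P_SETS = [
    DDMParams(a=2.0, z=0.5, v_go=1.0, v_nogo=-1.0, ter=0.2),
    DDMParams(a=1.6, z=0.73, v_go=1.7, v_nogo=-1.4, ter=0.16),
    DDMParams(a=1.0, z=0.3, v_go=0.5, v_nogo=-0.5, ter=0.1),
    DDMParams(a=2.5, z=0.6, v_go=3.0, v_nogo=-2.0, ter=0.3),
    DDMParams(a=0.8, z=0.45, v_go=-0.8, v_nogo=0.8, ter=0.05),
]


class TestDensityBasics:
    def test_nonpositive_time_gives_zero(self):
        p = P_SETS[0]
        assert wfpt_density(-0.1, p, 1.0, Boundary.UPPER) == 0.0
        assert wfpt_density(0.0, p, 1.0, Boundary.LOWER) == 0.0

    def test_symmetry_at_zero_drift_centred_start(self):
        p = DDMParams(a=1.5, z=0.5, v_go=0.0, v_nogo=0.0, ter=0.1)
        ts = np.linspace(0.01, 3.0, 50)
        up = wfpt_density(ts, p, 0.0, Boundary.UPPER)
        lo = wfpt_density(ts, p, 0.0, Boundary.LOWER)
        np.testing.assert_allclose(up, lo, rtol=1e-10)

    @pytest.mark.parametrize("p", P_SETS)
    def test_densities_normalize_to_one(self, p):
        total = 0.0
        for b in (Boundary.UPPER, Boundary.LOWER):
            total += quad(lambda t: wfpt_density(t, p, p.v_go, b), 0, 60,
                          limit=300)[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("p", P_SETS)
    def test_density_integral_matches_choice_probability(self, p):
        mass = quad(lambda t: wfpt_density(t, p, p.v_go, Boundary.UPPER),
                    0, 60, limit=300)[0]
        assert mass == pytest.approx(
            choice_probability(p, p.v_go, Boundary.UPPER), abs=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(a=st.floats(0.3, 4.0), z=st.floats(0.05, 0.95),
           v=st.floats(-5.0, 5.0), t=st.floats(0.001, 5.0))
    def test_density_nonnegative_and_finite(self, a, z, v, t):
        p = DDMParams(a=a, z=z, v_go=v, v_nogo=-v, ter=0.1)
        d = wfpt_density(t, p, v, Boundary.UPPER)
        assert np.isfinite(d) and d >= 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(a=-1.0, z=0.5, v_go=1.0, v_nogo=-1.0, ter=0.1)
        with pytest.raises(ValueError):
            DDMParams(a=1.0, z=1.2, v_go=1.0, v_nogo=-1.0, ter=0.1)
        with pytest.raises(ValueError):
            DDMParams(a=1.0, z=0.5, v_go=1.0, v_nogo=-1.0, ter=-0.1)


class TestChoiceProbability:
    def test_zero_drift_equals_starting_point(self):
        for z in (0.2, 0.5, 0.73):
            p = DDMParams(a=1.5, z=z, v_go=0.0, v_nogo=0.0, ter=0.1)
            assert choice_probability(p, 0.0, Boundary.UPPER) == pytest.approx(z, abs=1e-12)

    @pytest.mark.parametrize("p", P_SETS)
    def test_probabilities_sum_to_one(self, p):
        for drift in (p.v_go, p.v_nogo, 0.0):
            s = (choice_probability(p, drift, Boundary.UPPER)
                 + choice_probability(p, drift, Boundary.LOWER))
            assert s == pytest.approx(1.0, abs=1e-14)

    def test_monotone_in_drift_and_start(self):
        drifts = np.linspace(-3, 3, 13)
        ps = [choice_probability(DDMParams(a=1.5, z=0.4, v_go=v, v_nogo=-v, ter=0.1),
                                 v, Boundary.UPPER) for v in drifts]
        assert np.all(np.diff(ps) > 0)
        zs = np.linspace(0.05, 0.95, 13)
        ps = [choice_probability(DDMParams(a=1.5, z=z, v_go=1.0, v_nogo=-1.0, ter=0.1),
                                 1.0, Boundary.UPPER) for z in zs]
        assert np.all(np.diff(ps) > 0)

    def test_scale_invariance(self):
        # multiplying a and s jointly (start level a*z scales with a)
        p1 = DDMParams(a=1.2, z=0.65, v_go=1.3, v_nogo=-1.3, ter=0.1, s=1.0)
        p2 = DDMParams(a=2.4, z=0.65, v_go=2.6, v_nogo=-2.6, ter=0.1, s=2.0)
        for b in (Boundary.UPPER, Boundary.LOWER):
            assert choice_probability(p1, p1.v_go, b) == pytest.approx(
                choice_probability(p2, p2.v_go, b), abs=1e-12)


class TestOracleAgreement:
    """Analytic forms against the Euler-Maruyama simulation oracle."""

    @pytest.mark.parametrize("p,drift", [(P_SETS[1], 1.7), (P_SETS[0], 1.0)])
    def test_choice_probability_within_three_binomial_se(self, p, drift):
        n = 120000
        _, up = sample_fpt(p, drift, n, seed=17, dt=2e-4)
        pa = choice_probability(p, drift, Boundary.UPPER)
        se = math.sqrt(pa * (1 - pa) / n)
        assert abs(up.mean() - pa) < 3 * se

    def test_density_matches_oracle_histogram(self):
        # binwise three-sigma check with a family-wise multiplicity
        # correction (two-sided 1e-4 per bin across ~40 populated bins)
        p, drift = P_SETS[1], 1.7
        n = 120000
        times, up = sample_fpt(p, drift, n, seed=23, dt=2e-4)
        bins = np.arange(0.0, 2.0001, 0.04)
        h, _ = np.histogram(times[up == 1], bins=bins)
        zs = []
        for b in range(len(bins) - 1):
            pa = quad(lambda t: wfpt_density(t, p, drift, Boundary.UPPER),
                      bins[b], bins[b + 1])[0]
            if pa * n >= 25:
                zs.append((h[b] / n - pa) / math.sqrt(pa * (1 - pa) / n))
        zs = np.asarray(zs)
        assert len(zs) >= 15
        assert np.abs(zs).max() < 3.89
        assert abs(np.mean(zs)) < 1.0

    def test_mean_latency_matches_analytic_mean(self):
        # strong positive drift: nearly all paths absorb above, so the mean
        # observed latency approximates ter + unconditional mean decision time
        p = DDMParams(a=2.0, z=0.5, v_go=3.0, v_nogo=-3.0, ter=0.2)
        trials = sample_trials(p, "GO", 20000, deadline_s=1e9, seed=29)
        lats = np.array([t.latency_ms / 1000.0 for t in trials if t.responded])
        assert len(lats) > 19800
        expected = p.ter + mean_decision_time(p, p.v_go)
        assert lats.mean() == pytest.approx(expected, abs=0.01)


class TestTrialLoglik:
    P = DDMParams(a=2.0, z=0.5, v_go=2.0, v_nogo=-2.0, ter=0.2)

    def test_responded_trial_is_shifted_upper_density(self):
        t = TrialRecord("P1", "PSP", "GO", True, 500.0)
        expected = math.log(wfpt_density(0.3, self.P, 2.0, Boundary.UPPER))
        assert trial_loglik(t, self.P) == pytest.approx(expected, abs=1e-12)

    def test_withheld_trial_is_lower_probability(self):
        t = TrialRecord("P1", "PSP", "NOGO", False, None)
        expected = math.log(choice_probability(self.P, -2.0, Boundary.LOWER))
        assert trial_loglik(t, self.P) == pytest.approx(expected, abs=1e-12)

    def test_certain_withholding_approaches_zero_loglik(self):
        p = DDMParams(a=2.0, z=0.3, v_go=2.0, v_nogo=-15.0, ter=0.2)
        t = TrialRecord("P1", "PSP", "NOGO", False, None)
        assert -1e-4 < trial_loglik(t, p) <= 0.0

    def test_latency_before_ter_gives_minus_inf_not_error(self):
        t = TrialRecord("P1", "PSP", "GO", True, 150.0)
        assert trial_loglik(t, self.P) == -math.inf


class TestSampleTrials:
    def test_same_seed_identical_trials(self):
        p = P_SETS[0]
        t1 = sample_trials(p, "GO", 200, 1.5, seed=5)
        t2 = sample_trials(p, "GO", 200, 1.5, seed=5)
        assert t1 == t2

    def test_zero_drift_centred_start_splits_evenly(self):
        p = DDMParams(a=1.0, z=0.5, v_go=0.0, v_nogo=0.0, ter=0.1)
        trials = sample_trials(p, "GO", 20000, deadline_s=1e9, seed=7)
        frac = np.mean([t.responded for t in trials])
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 20000)

    def test_deadline_censors_late_responses(self):
        p = DDMParams(a=3.0, z=0.5, v_go=0.5, v_nogo=-0.5, ter=0.3)
        open_dl = sample_trials(p, "GO", 3000, deadline_s=1e9, seed=9)
        tight = sample_trials(p, "GO", 3000, deadline_s=0.8, seed=9)
        n_open = sum(t.responded for t in open_dl)
        n_tight = sum(t.responded for t in tight)
        assert n_tight < n_open
        assert all(t.latency_ms <= 800.0 for t in tight if t.responded)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_trials(P_SETS[0], "GO", 0, 1.5, seed=1)
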