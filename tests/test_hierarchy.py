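"""MCMC machinery: convergence diagnostics, DIC bookkeeping, recovery and
reproducibility of the hierarchical sampler."""
import math
from dataclasses import replace as drep

import numpy as np
import pandas as pd
import pytest

from gonogo_ddm import (DDMParams, McmcConfig, ModelSpec, StudyDataset,
                        compute_dic, fit_hierarchical, geweke_check, geweke_z,
                        sample_trials)
from gonogo_ddm.hierarchy import (InitializationError, PosteriorFit,
                                  export_chains, sample_mu_prior)
from gonogo_ddm.io import TrialRecord


def _participant_dataset(params, n_go, n_nogo, pid="P1", group="PSP",
                         deadline=1.5, dt=2e-4, seed=5):
    trials = []
    for t in sample_trials(params, "GO", n_go, deadline, seed=seed, dt=dt):
        trials.append(drep(t, participant_id=pid, group=group))
    for t in sample_trials(params, "NOGO", n_nogo, deadline, seed=seed + 1, dt=dt):
        trials.append(drep(t, participant_id=pid, group=group))
    return StudyDataset(trials, [(pid, group)])


class TestMcmcConfig:
    def test_defaults_are_fifteen_thousand_with_five_thousand_burnin(self):
        cfg = McmcConfig()
        assert cfg.n_samples == 15000 and cfg.n_burnin == 5000

    def test_burnin_before_samples_enforced(self):
        with pytest.raises(ValueError):
            McmcConfig(n_samples=100, n_burnin=100)

    def test_retained_count_invariant(self, small_fit):
        assert small_fit.n_retained == small_fit.n_samples - small_fit.n_burnin
        assert all(c.size == small_fit.n_retained for c in small_fit.chains.values())


class TestGeweke:
    def test_iid_chains_calibrated_at_nominal_rate(self):
        rng = np.random.default_rng(1234)
        within = sum(abs(geweke_z(rng.standard_normal(10000))) < 2.0
                     for _ in range(100))
        assert within >= 95

    def test_strong_linear_trend_flagged(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(5000) + np.linspace(0, 5, 5000)
        assert abs(geweke_z(chain)) > 2.0

    def test_constant_chain_scores_zero(self):
        assert geweke_z(np.full(1000, 3.14)) == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.zeros(50))

    def test_fit_report_lists_all_quantities(self, small_fit):
        rep = geweke_check(small_fit)
        assert set(rep.scores) == set(small_fit.chains)
        assert 0.0 <= rep.fraction_flagged <= 1.0
        assert set(rep.to_frame().columns) == {"quantity", "z", "flagged"}


def _fake_fit(deviance, dhat):
    dev = np.asarray(deviance, dtype=float)
    return PosteriorFit(chains={}, n_samples=len(dev), n_burnin=0, deviance=dev,
                        deviance_by_group={}, dhat=dhat, dhat_by_group={},
                        participants=[], model=None, seed=0)


class TestDic:
    def test_algebraic_identity(self):
        fit = _fake_fit([10.0, 12.0, 11.0], dhat=9.5)
        dic, dbar, dhat, pd_ = compute_dic(fit)
        assert dbar == pytest.approx(11.0)
        assert pd_ == pytest.approx(dbar - dhat, abs=1e-12)
        assert dic == pytest.approx(2 * dbar - dhat, abs=1e-12)

    def test_larger_penalty_larger_dic_at_equal_fit(self):
        dic1, *_ = compute_dic(_fake_fit([100.0, 102.0], dhat=99.0))
        dic2, *_ = compute_dic(_fake_fit([100.0, 102.0], dhat=95.0))
        assert dic2 > dic1

    def test_negative_pd_warns_not_raises(self):
        with pytest.warns(RuntimeWarning):
            compute_dic(_fake_fit([10.0, 10.0], dhat=20.0))


class TestSingleParticipantRecovery:
    def test_posterior_concentrates_near_generating_parameters(self):
        # fast drifts keep deadline censoring negligible, so this checks the
        # likelihood against the generator directly
        truth = DDMParams(a=1.4, z=0.6, v_go=3.0, v_nogo=-2.5, ter=0.2)
        ds = _participant_dataset(truth, 2500, 2500, dt=1e-4)
        fit = fit_hierarchical(ds, ModelSpec.variant(4),
                               McmcConfig(n_samples=2500, n_burnin=1000), seed=2)
        for q, tv in (("a", truth.a), ("z", truth.z), ("v_go", truth.v_go),
                      ("v_nogo", truth.v_nogo), ("ter", truth.ter)):
            ch = fit.chains[f"{q}:P1"]
            assert abs(ch.mean() - tv) < 3 * ch.std(), q

    def test_censoring_asymmetry_bias_is_bounded(self):
        # the generator censors at the deadline while withheld-trial
        # likelihood uses the marginal lower-boundary probability; at a
        # strongly Go-biased parameter set this biases a and z slightly
        # downward -- bounded here
        truth = DDMParams(a=1.6, z=0.73, v_go=1.7, v_nogo=-1.4, ter=0.16)
        ds = _participant_dataset(truth, 2000, 2000, deadline=1.5, seed=11)
        fit = fit_hierarchical(ds, ModelSpec.variant(4),
                               McmcConfig(n_samples=2000, n_burnin=800), seed=4)
        est = {q: float(np.mean(fit.chains[f"{q}:P1"]))
               for q in ("a", "z", "v_go", "v_nogo", "ter")}
        assert abs(est["a"] - truth.a) < 0.25
        assert abs(est["z"] - truth.z) < 0.06
        assert abs(est["v_go"] - truth.v_go) < 0.35
        assert abs(est["v_nogo"] - truth.v_nogo) < 0.35
        assert abs(est["ter"] - truth.ter) < 0.01


class TestPriorOnlyFit:
    def test_posterior_matches_prior_without_data(self):
        ds = StudyDataset([], [("P1", "PSP")])
        fit = fit_hierarchical(ds, ModelSpec.variant(4),
                               McmcConfig(n_samples=9000, n_burnin=1000),
                               seed=8, allow_empty=True)
        rng = np.random.default_rng(99)
        from scipy.stats import ks_2samp
        for q in ("a", "v_go", "ter"):
            prior = sample_mu_prior(q, 20000, rng)
            stat = ks_2samp(fit.chains[f"mu:{q}:PSP"][::20], prior).statistic
            assert stat < 0.15, q


class TestReproducibilityAndExchangeability:
    def _tiny_cohort(self, order=("PSP", "PD", "CONTROL"), seed=21):
        rng = np.random.default_rng(seed)
        trials, roster = [], []
        base = {"PSP": DDMParams(1.6, 0.7, 1.8, -1.4, 0.16),
                "PD": DDMParams(1.6, 0.62, 2.3, -1.5, 0.17),
                "CONTROL": DDMParams(1.6, 0.57, 3.0, -2.0, 0.21)}
        for g in order:
            for k in range(3):
                pid = f"{g}{k}"
                roster.append((pid, g))
                p = DDMParams(base[g].a, base[g].z, base[g].v_go + 0.1 * k,
                              base[g].v_nogo, base[g].ter)
                for c, n in (("GO", 50), ("NOGO", 50)):
                    for t in sample_trials(p, c, n, 1.5,
                                           seed=int(rng.integers(2 ** 31))):
                        trials.append(drep(t, participant_id=pid, group=g))
        return StudyDataset(trials, roster)

    def test_same_seed_bit_identical_chains(self):
        ds = self._tiny_cohort()
        cfg = McmcConfig(n_samples=400, n_burnin=150)
        f1 = fit_hierarchical(ds, ModelSpec.variant(4), cfg, seed=6)
        f2 = fit_hierarchical(ds, ModelSpec.variant(4), cfg, seed=6)
        for name in f1.chains:
            np.testing.assert_array_equal(f1.chains[name], f2.chains[name])
        np.testing.assert_array_equal(f1.deviance, f2.deviance)

    def test_group_posterior_invariant_to_participant_relabelling(self):
        from gonogo_ddm.hierarchy import _mcmc_var
        ds = self._tiny_cohort()
        # reverse participant order (same trials, same labels)
        rev = StudyDataset(ds.trials, list(reversed(ds.participants)))
        cfg = McmcConfig(n_samples=1500, n_burnin=500)
        f1 = fit_hierarchical(ds, ModelSpec.variant(4), cfg, seed=6)
        f2 = fit_hierarchical(rev, ModelSpec.variant(4), cfg, seed=6)
        for q in ("v_go", "ter", "a"):
            for g in ("PSP", "CONTROL"):
                c1, c2 = f1.chains[f"mu:{q}:{g}"], f2.chains[f"mu:{q}:{g}"]
                se = math.sqrt(_mcmc_var(c1) / c1.size + _mcmc_var(c2) / c2.size)
                assert abs(c1.mean() - c2.mean()) < 5 * se, (q, g)


class TestErrorsAndExport:
    def test_impossible_latency_reports_participant(self):
        trials = [TrialRecord("BAD1", "PSP", "GO", True, 0.5),
                  TrialRecord("BAD1", "PSP", "NOGO", False, None)]
        ds = StudyDataset(trials, [("BAD1", "PSP")])
        with pytest.raises(InitializationError, match="BAD1"):
            fit_hierarchical(ds, ModelSpec.variant(4),
                             McmcConfig(n_samples=200, n_burnin=50), seed=0)

    def test_export_chains_tidy_csv(self, small_fit, tmp_path):
        out = tmp_path / "chains.csv"
        export_chains(small_fit, out)
        df = pd.read_csv(out)
        assert set(df.columns) == {"quantity", "unit", "iteration", "value"}
        assert df["quantity"].nunique() == len(small_fit.chains)

    def test_point_estimates_cover_all_participants(self, small_fit):
        pe = small_fit.point_estimates()
        assert len(pe) == len(small_fit.participants)
        assert {"a", "z", "v_go", "v_nogo", "ter"} <= set(pe.columns)
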