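import numpy as np
import pandas as pd
import pytest

from phasebind import (
    BurstSpec,
    PhaseOutcomeLogistic,
    SimConfig,
    bandpass_analytic,
    extrapolate_phase,
    fit_phase_outcome_model,
    joint_early_late_model,
    predict_timecourse,
    simulate_dataset,
    simulate_outcomes,
)
from helpers import grid_search_logit


class TestExtrapolation:
    def test_zero_lag_identity(self):
        assert extrapolate_phase(np.pi / 2, 4.0, -0.1, -0.1) == np.pi / 2

    def test_one_period_advance_returns_same_phase(self):
        # 2 pi * 4 Hz * 0.25 s = one full cycle
        assert np.isclose(extrapolate_phase(0.0, 4.0, -0.25, 0.0), 0.0,
                          atol=1e-12)

    def test_half_period_advance_adds_pi(self):
        assert np.isclose(extrapolate_phase(0.0, 4.0, -0.5, -0.375), np.pi)

    def test_backward_extrapolation(self):
        fwd = extrapolate_phase(0.3, 4.0, -0.5, -0.2)
        back = extrapolate_phase(fwd, 4.0, -0.2, -0.5)
        assert np.isclose(back, 0.3)

    def test_output_wrapped(self, rng):
        ph = extrapolate_phase(rng.uniform(-np.pi, np.pi, 100), 4.0,
                               -1.9, rng.uniform(-0.6, 0.6, 100))
        assert (ph > -np.pi).all() and (ph <= np.pi).all()


class TestPhaseOutcomeModel:
    def test_recovers_analytic_parameterization(self, rng):
        """kappa, phi_opt map to (beta1, beta2) = kappa*(sin, cos)(phi_opt)."""
        phi = rng.uniform(-np.pi, np.pi, size=5000)
        y = simulate_outcomes(phi, 1.1, 0.8, np.pi / 3, rng=rng)
        fit = fit_phase_outcome_model(phi, y)
        assert fit.converged
        expect = np.array([0.8 * np.sin(np.pi / 3), 0.8 * np.cos(np.pi / 3)])
        se = 3.0 / np.sqrt(5000)  # conservative 3-SE scale for logit coefs
        assert np.abs(fit.beta[1:] - expect).max() < 3 * se

    def test_agrees_with_grid_search_oracle(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=2000)
        y = simulate_outcomes(phi, 0.5, 0.6, -1.0, rng=rng)
        fit = fit_phase_outcome_model(phi, y)
        oracle = grid_search_logit(phi, y.astype(float))
        assert np.abs(fit.beta - oracle).max() < 1e-3

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm
        phi = rng.uniform(-np.pi, np.pi, size=1500)
        y = simulate_outcomes(phi, 1.0, 0.5, 0.4, rng=rng)
        fit = fit_phase_outcome_model(phi, y)
        X = np.column_stack([np.ones_like(phi), np.sin(phi), np.cos(phi)])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)

    def test_null_effect_is_small(self, rng):
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            phi = rng.uniform(-np.pi, np.pi, size=5000)
            y = rng.integers(0, 2, size=5000)
            fit = fit_phase_outcome_model(phi, y)
            hits += np.hypot(fit.beta[1], fit.beta[2]) < 0.1
        assert hits >= 0.9 * n_rep

    def test_separation_flagged_not_converged(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=200)
        y = (np.cos(phi) > 0).astype(int)
        fit = fit_phase_outcome_model(phi, y)
        assert not fit.converged

    def test_min_trials_rule(self, rng):
        phi = rng.uniform(-np.pi, np.pi, size=10)
        y = rng.integers(0, 2, size=10)
        fit = fit_phase_outcome_model(phi, y, min_trials=30)
        assert not fit.converged and fit.n_trials == 10

    def test_estimator_interface(self, rng):
        est = PhaseOutcomeLogistic(min_trials=20)
        assert est.get_params() == {"min_trials": 20}
        est.set_params(min_trials=25)
        phi = rng.uniform(-np.pi, np.pi, size=800)
        y = simulate_outcomes(phi, 0.0, 2.0, 0.0, rng=rng)
        est.fit(phi, y)
        assert est.converged_
        proba = est.predict_proba(np.array([0.0, np.pi]))
        assert proba.shape == (2, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert proba[0, 1] > proba[1, 1]  # success likelier at optimal phase
        assert est.predict(np.array([0.0]))[0] == 1


def _late_coupled_dataset(n_subjects=5, n_trials=250, seed=33):
    """Outcomes coupled to the phase of a late burst only; high SNR."""
    cfg = SimConfig(
        n_subjects=n_subjects, n_trials=n_trials, n_channels=3, fs=500.0,
        noise_amplitude=1.0, kappa=1.0, phi_opt=0.8,
        bursts=[BurstSpec(center=-0.05, width=0.25, amplitude=2.0)],
    )
    subjects = simulate_dataset(cfg, seed=seed)
    analytic = [bandpass_analytic(s["epochs"], window=(-1.9, 0.0))
                for s in subjects]
    tables = [s["trials"] for s in subjects]
    return cfg, analytic, tables


@pytest.fixture(scope="module")
def late_dataset():
    return _late_coupled_dataset()


class TestPredictTimecourse:
    def test_effect_localized_to_burst_epoch(self, late_dataset):
        _, analytic, tables = late_dataset
        times = np.arange(-1.8, 0.0 + 1e-9, 0.1)
        pm = predict_timecourse(analytic, tables, times=times)
        sig_t = pm.significant_times
        assert sig_t.size > 0
        assert sig_t.max() > -0.4                  # effect near movement onset
        assert -1.4 not in np.round(sig_t, 3)      # silent far from the burst
        # the detected effect is concentrated in the burst epoch
        assert np.mean(sig_t > -0.6) >= 0.5

    def test_forward_only_uses_fewer_trials(self, late_dataset):
        _, analytic, tables = late_dataset
        times = np.array([-0.3, -0.1])
        pm_all = predict_timecourse(analytic, tables, times=times)
        pm_fwd = predict_timecourse(analytic, tables, times=times,
                                    variant="forward_only", fdr_family="space")
        assert (pm_fwd.mean_trials < pm_all.mean_trials).all()
        # consistency at high SNR: forward-only PV within a few SE of all-trials
        i = 1
        diff = np.abs(pm_fwd.pv[:, i] - pm_all.pv[:, i])
        bound = 3 * (pm_fwd.se[:, i] + pm_all.se[:, i])
        assert (diff <= bound).all()

    def test_channel_relabeling_permutes_map(self, late_dataset):
        from phasebind.spectral import AnalyticEpochs
        _, analytic, tables = late_dataset
        times = np.array([-0.2, -0.05])
        perm = [2, 0, 1]
        permuted = [
            AnalyticEpochs(values=a.values[perm], fs_out=a.fs_out,
                           time=a.time, center_freq=a.center_freq,
                           band=a.band,
                           channel_labels=[a.channel_labels[i] for i in perm],
                           alignment=a.alignment)
            for a in analytic
        ]
        pm = predict_timecourse(analytic, tables, times=times)
        pm_perm = predict_timecourse(permuted, tables, times=times)
        np.testing.assert_allclose(pm_perm.pv, pm.pv[perm], rtol=1e-10)
        np.testing.assert_allclose(pm_perm.p, pm.p[perm], rtol=1e-10)

    def test_reproducible_map(self, late_dataset):
        _, analytic, tables = late_dataset
        times = np.array([-0.1])
        a = predict_timecourse(analytic, tables, times=times)
        b = predict_timecourse(analytic, tables, times=times)
        np.testing.assert_array_equal(a.pv, b.pv)

    def test_mismatched_trials_rejected(self, late_dataset):
        _, analytic, tables = late_dataset
        with pytest.raises(ValueError, match="do not match"):
            predict_timecourse(analytic, [t.iloc[:-3] for t in tables],
                               times=np.array([-0.1]))


class TestStimulusLockedAndSweep:
    def test_stimulus_locked_uses_phase_directly(self, rng):
        """With analytic phases equal to the outcome-generating phases at a
        sample, the stimulus-locked variant recovers the direct fit."""
        from phasebind.spectral import AnalyticEpochs
        n, n_subj = 400, 5
        analytic, tables = [], []
        betas_direct = []
        for s in range(n_subj):
            phi = rng.uniform(-np.pi, np.pi, size=n)
            y = simulate_outcomes(phi, 1.1, 0.8, 0.5, rng=rng)
            vals = np.exp(1j * phi)[None, None, :] * np.ones((2, 3, 1))
            analytic.append(AnalyticEpochs(
                values=vals, fs_out=40.0,
                time=np.array([-0.05, -0.025, 0.0]), center_freq=4.0,
                band=(3.0, 5.0), channel_labels=["a", "b"],
                alignment="stimulus"))
            tables.append(pd.DataFrame({
                "subject_id": f"s{s}", "trial_id": np.arange(n),
                "condition": "short", "t_move": 1.5,
                "t_stim": np.zeros(n), "outcome": y}))
            betas_direct.append(fit_phase_outcome_model(phi, y).beta)
        pm = predict_timecourse(analytic, tables,
                                times=np.array([-0.025]),
                                variant="stimulus_locked",
                                fdr_family="space")
        assert pm.significant.any()
        for s in range(n_subj):
            np.testing.assert_allclose(pm.betas[s, 0, 0], betas_direct[s],
                                       atol=1e-8)

    def test_frequency_sweep_peaks_at_carrier(self):
        from phasebind import predict_frequency_sweep
        cfg = SimConfig(n_subjects=5, n_trials=200, n_channels=2, fs=500.0,
                        noise_amplitude=1.0, kappa=1.2, phi_opt=0.3,
                        bursts=[BurstSpec(center=-0.05, width=0.3,
                                          amplitude=2.0)])
        subjects = simulate_dataset(cfg, seed=55)
        grid = [(3.0, (2.0, 4.0)), (4.0, (3.0, 5.0)), (10.0, (9.0, 11.0))]
        maps = predict_frequency_sweep(
            [s["epochs"] for s in subjects],
            [s["trials"] for s in subjects],
            grid=grid, times=np.array([-0.1, -0.05]))
        peak_pv = [np.nanmax(m.pv) for m in maps]
        assert maps[1].freq == 4.0
        assert peak_pv[1] > peak_pv[2]  # carrier band beats the 10 Hz band


class TestJointEarlyLate:
    def test_independent_phases_both_recovered(self, rng):
        n = 4000
        e = rng.uniform(-np.pi, np.pi, n)
        l = rng.uniform(-np.pi, np.pi, n)
        eta = 1.1 + 0.5 * np.cos(e - 0.5) + 0.5 * np.cos(l + 1.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        out = joint_early_late_model(e, l, y)
        assert out["converged"] and not out["collinear"]
        phi_e = np.arctan2(out["early"][0], out["early"][1])
        phi_l = np.arctan2(out["late"][0], out["late"][1])
        assert abs((phi_e - 0.5 + np.pi) % (2 * np.pi) - np.pi) < 0.3
        assert abs((phi_l + 1.0 + np.pi) % (2 * np.pi) - np.pi) < 0.3

    def test_perfect_coupling_flagged_collinear(self, rng):
        e = rng.uniform(-np.pi, np.pi, 500)
        l = e + 0.7
        y = simulate_outcomes(e, 1.0, 0.5, 0.0, rng=rng)
        out = joint_early_late_model(e, l, y)
        assert out["collinear"] and not out["converged"]
        # single-predictor fit on the same data remains valid
        single = fit_phase_outcome_model(e, y)
        assert single.converged

    def test_specificity_when_only_early_coupled(self, rng):
        from phasebind import hotelling_t2
        false_pos = 0
        n_rep = 15
        for _ in range(n_rep):
            betas_late = []
            for _ in range(10):
                e = rng.uniform(-np.pi, np.pi, 300)
                l = rng.uniform(-np.pi, np.pi, 300)
                y = simulate_outcomes(e, 1.1, 0.6, 0.3, rng=rng)
                out = joint_early_late_model(e, l, y)
                betas_late.append(out["late"])
            _, p = hotelling_t2(np.array(betas_late))
            false_pos += p < 0.05
        assert false_pos <= 3  # ~nominal rate over 15 replicates
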