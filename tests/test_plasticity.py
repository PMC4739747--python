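"""sdSP / R-sdSP tests: eligibility pieces, filters, gradient oracle, limits."""

import numpy as np
import pytest

from dendrisp.model import (
    InputPattern,
    NeuronParams,
    SynapticWeights,
    TrialRecord,
    compute_psps,
    psp_kernel,
    simulate_trial,
    somatic_rate,
)
from dendrisp.plasticity import (
    EligibilityState,
    PlasticityParams,
    _filter_gains,
    den_conv_psp,
    eligibility_sds,
    eligibility_ss,
    escape_correction,
    nmda_rate_derivative,
    reward_update,
    rho_without_d,
    sds_weight_curve,
    supervised_update,
    three_factor_limit,
    trial_eligibility,
    trial_eligibility_reference,
    update_eligibility,
)


class TestEscapeCorrection:
    def test_limit_is_one(self):
        neuron = NeuronParams(alpha=1e-9)
        assert escape_correction(neuron) == pytest.approx(1.0, abs=1e-6)

    def test_default_value(self, neuron):
        x = neuron.alpha * neuron.a * neuron.beta_s  # 1.8
        assert escape_correction(neuron) == pytest.approx((np.exp(x) - 1) / x)
        assert escape_correction(neuron) > 1

    def test_rho_without_d_shifts_and_scales(self, neuron):
        u = 2.1
        off = rho_without_d(u, 0, neuron)
        on = rho_without_d(u, 1, neuron)
        c = escape_correction(neuron)
        assert off == pytest.approx(c * somatic_rate(u, neuron))
        assert on == pytest.approx(
            c * somatic_rate(u - neuron.alpha * neuron.a, neuron)
        )
        assert on < off  # removing the plateau lowers the rate


class TestNmdaDerivative:
    def test_max_slope_at_threshold(self, neuron):
        assert nmda_rate_derivative(neuron.theta_D, neuron) == pytest.approx(
            neuron.beta_D * neuron.r_D / 4
        )

    def test_vanishes_at_saturation(self, neuron):
        assert nmda_rate_derivative(-1e3, neuron) == pytest.approx(0, abs=1e-9)
        assert nmda_rate_derivative(1e3, neuron) == pytest.approx(0, abs=1e-9)

    def test_matches_finite_differences(self, neuron):
        from dendrisp.model import nmda_rate

        rng = np.random.default_rng(0)
        h = 1e-6
        for u in rng.uniform(-1, 5, size=10):
            fd = (nmda_rate(u + h, neuron) - nmda_rate(u - h, neuron)) / (2 * h)
            assert nmda_rate_derivative(u, neuron) == pytest.approx(fd, rel=1e-6)


class TestEligibilityIncrements:
    def test_ss_signs(self):
        assert eligibility_ss(0.0, 0.0, 0.0) == 0
        assert eligibility_ss(0.0, 0.5, 1.0) < 0       # no spike, positive rate
        assert eligibility_ss(1.0, 0.5, 1.0) > 0       # spike bin, 1/dt > rho
        assert eligibility_ss(1.0, 0.5, 0.0) == 0      # zero PSP

    def test_sds_product_oracle(self):
        rng = np.random.default_rng(1)
        S = rng.choice([0.0, 1.0], size=50)
        rho = rng.uniform(0, 0.5, size=50)
        den = rng.normal(size=50)
        out = eligibility_sds(S, rho, den)
        assert out == pytest.approx((S - rho) * den)
        assert eligibility_sds(1.0, 0.2, 0.0) == 0


class TestEligibilityFilter:
    def test_zero_drive_decay(self):
        p = PlasticityParams(tau_E=100.0)
        s = EligibilityState(E=np.ones((1, 1)), sigma=np.zeros((1, 1)))
        s = update_eligibility(s, np.zeros((1, 1)), np.zeros((1, 1)), 1.0, p)
        assert s.E[0, 0] == pytest.approx(np.exp(-1 / 100))

    def test_constant_drive_fixed_point(self):
        p = PlasticityParams(tau_E=40.0, a_bar=3.0)
        s = EligibilityState.zeros(1, 1)
        k = 0.7
        for _ in range(3000):
            s = update_eligibility(s, np.full((1, 1), k), np.zeros((1, 1)), 1.0, p)
        assert s.E[0, 0] == pytest.approx(40.0 * k, rel=1e-6)

    def test_a_bar_scales_only_sds_stream(self):
        p = PlasticityParams(tau_E=40.0, a_bar=3.0)
        s = EligibilityState.zeros(1, 1)
        for _ in range(3000):
            s = update_eligibility(s, np.zeros((1, 1)), np.ones((1, 1)), 1.0, p)
        assert s.E[0, 0] == pytest.approx(40.0 * 3.0, rel=1e-6)

    def test_sigma_filter_constant_drive_closed_form(self, neuron):
        """sigma settles to delta_bar * rho_d' * p0 under constant drive."""
        p = PlasticityParams(delta_bar=25.0)
        n_bins = 600
        u_d = np.full((1, n_bins), 2.0)
        psp = np.full((1, n_bins), 0.3)
        trial = TrialRecord(
            t_grid=np.arange(n_bins, dtype=float),
            psp=psp,
            u_dend=u_d,
            nmda_on=np.zeros((1, n_bins), dtype=bool),
            nmda_triggers=[np.array([])],
            trigger_bin_of=np.full((1, n_bins), -1),
            u_soma=np.zeros(n_bins),
            soma_spikes=np.array([]),
            mode="free",
        )
        state = trial_eligibility_reference(trial, neuron, p)
        g = nmda_rate_derivative(2.0, neuron) * neuron.rate_to_per_ms
        assert state.sigma[0, 0] == pytest.approx(25.0 * g * 0.3, rel=1e-4)


class TestDenConvPsp:
    def test_outside_plateau_returns_sigma(self, neuron):
        p = PlasticityParams(mix=0.5)
        assert den_conv_psp(0.7, False, 0.2, 2.0, neuron, p) == 0.7

    def test_zero_psp_at_trigger_kills_upper(self, neuron):
        p = PlasticityParams(mix=0.5)
        out = den_conv_psp(0.4, True, 0.0, 2.0, neuron, p)
        assert out == pytest.approx(0.5 * 0.4)  # lower term only

    def test_mix_combination(self, neuron):
        p = PlasticityParams(mix=0.25)
        from dendrisp.model import nmda_rate

        u_t, psp_t, sigma = 2.2, 0.15, 0.4
        upper = (
            neuron.beta_D * (1 - nmda_rate(u_t, neuron) / neuron.r_D) * psp_t
        )
        out = den_conv_psp(sigma, True, psp_t, u_t, neuron, p)
        assert out == pytest.approx(0.25 * upper + 0.75 * sigma)


class TestWeightUpdates:
    def test_supervised_trivials(self, neuron):
        w = SynapticWeights(w=np.ones((2, 2)), mask=np.ones((2, 2), bool))
        w0 = w.w.copy()
        supervised_update(w, np.zeros((2, 2)), PlasticityParams(eta=1.0))
        assert np.array_equal(w.w, w0)
        supervised_update(w, np.ones((2, 2)), PlasticityParams(eta=0.0))
        assert np.array_equal(w.w, w0)
        supervised_update(w, np.ones((2, 2)), PlasticityParams(eta=2.0))
        assert w.w == pytest.approx(w0 + 2.0)

    def test_only_connected_synapses_change(self, neuron):
        mask = np.array([[True, False]])
        w = SynapticWeights(w=np.array([[1.0, 0.0]]), mask=mask)
        supervised_update(w, np.ones((1, 2)), PlasticityParams(eta=1.0))
        assert w.w[0, 1] == 0.0

    def test_reward_modulation(self, neuron):
        p = PlasticityParams(eta=1.0, R0=1.0)
        E = np.ones((1, 1))
        w = SynapticWeights(w=np.zeros((1, 1)), mask=np.ones((1, 1), bool))
        reward_update(w, E, R=1.0, params=p)
        assert w.w[0, 0] == 0.0               # R == R0: no change
        reward_update(w, E, R=-1.0, params=p)
        assert w.w[0, 0] == pytest.approx(-2.0)  # step (R - R0) eta E
        reward_update(w, -E, R=-1.0, params=p)
        assert w.w[0, 0] == pytest.approx(0.0)   # sign flips with E


class TestFastMatchesReference:
    @pytest.mark.parametrize("mode", ["free", "clamped"])
    @pytest.mark.parametrize(
        "variant",
        [{}, {"use_sds": False}, {"use_ss": False}, {"mix": 0.0}, {"mix": 1.0},
         {"u_lowpass_tau": 10.0}],
    )
    def test_closed_form_equals_recursion(self, small_neuron, pattern, mode,
                                          variant):
        rng = np.random.default_rng(4)
        w = SynapticWeights.initialize(
            small_neuron.replace(w0=60.0), pattern.n_channels, rng
        )
        trial = simulate_trial(
            small_neuron, w, pattern, mode=mode,
            clamp_spikes=[50.0, 130.0] if mode == "clamped" else None, rng=rng,
        )
        p = PlasticityParams.from_neuron(small_neuron, pattern.duration,
                                         **variant)
        E_fast = trial_eligibility(trial, small_neuron, p)
        E_ref = trial_eligibility_reference(trial, small_neuron, p).E
        assert E_fast == pytest.approx(E_ref, rel=1e-9, abs=1e-12)

    def test_ablation_streams_are_additive(self, trial, small_neuron):
        rec, _ = trial
        p = PlasticityParams.from_neuron(small_neuron, 200.0)
        full = trial_eligibility(rec, small_neuron, p)
        ss = trial_eligibility(rec, small_neuron, p.replace(use_sds=False))
        sds = trial_eligibility(rec, small_neuron, p.replace(use_ss=False))
        assert full == pytest.approx(ss + sds)


class TestGradientOracle:
    def test_ss_stream_is_loglikelihood_gradient(self):
        """Single-compartment limit: beta_s * E_ss(T) with tau_E -> inf equals
        the finite-difference gradient of log P(S | w) for a clamped train."""
        neuron = NeuronParams(n_branches=1, alpha=1.0, r_D=0.0, theta_s=0.5)
        T = 100.0
        pat = InputPattern(
            spikes=[np.array([5.0, 40.0, 80.0]), np.array([20.0, 60.0])],
            duration=T,
        )
        S_times = [30.0, 70.0]
        w = SynapticWeights(
            w=np.array([[0.8, 1.2]]), mask=np.ones((1, 2), dtype=bool)
        )
        p = PlasticityParams(tau_E=np.inf, use_sds=False)
        rng = np.random.default_rng(0)
        trial = simulate_trial(neuron, w, pat, mode="clamped",
                               clamp_spikes=S_times, rng=rng)
        E = trial_eligibility(trial, neuron, p)

        psp = compute_psps(pat, neuron)
        spike_bins = trial.soma_spike_bins
        from dendrisp.model import somatic_voltage

        # log-likelihood: sum_bins [S_n log(rho dt) - rho dt]
        def loglik(wvec):
            u_d = wvec[None, :] @ psp
            u = somatic_voltage(u_d, np.zeros_like(u_d, dtype=bool),
                                spike_bins, neuron)
            rho_dt = somatic_rate(u, neuron) * neuron.rate_to_per_ms * neuron.dt
            ll = -rho_dt.sum()
            for b in spike_bins:
                ll += np.log(rho_dt[b])
            return ll

        h = 1e-6
        for i in range(2):
            wp, wm = w.w[0].copy(), w.w[0].copy()
            wp[i] += h
            wm[i] -= h
            fd = (loglik(wp) - loglik(wm)) / (2 * h)
            assert neuron.beta_s * E[0, i] == pytest.approx(fd, rel=0.01)

    def test_reward_step_promotes_underproduced_spiking(self):
        """One-afferent bandit: when the neuron should spike but mostly stays
        silent, the average R-sdSP step on the weight is positive."""
        neuron = NeuronParams(n_branches=1, alpha=1.0, r_D=0.0, theta_s=1.2)
        T = 100.0
        pat = InputPattern(
            spikes=[np.linspace(5, 95, 8)], duration=T
        )
        w = SynapticWeights(w=np.array([[1.0]]), mask=np.ones((1, 1), bool))
        p = PlasticityParams(eta=1.0, R0=1.0, tau_E=T / 2, use_sds=False)
        rng = np.random.default_rng(12)
        steps, n_spiked = [], 0
        for _ in range(10_000):
            trial = simulate_trial(neuron, w, pat, mode="free", rng=rng)
            spiked = trial.soma_spikes.size >= 1
            n_spiked += spiked
            R = 1.0 if spiked else -1.0
            E = trial_eligibility(trial, neuron, p)
            steps.append((R - p.R0) * E[0, 0])
        assert n_spiked / 10_000 < 0.5       # spiking under-produced
        mean = np.mean(steps)
        assert mean > 0
        assert mean > 2 * np.std(steps) / np.sqrt(len(steps))


class TestThreeFactorLimit:
    def test_factorizes_over_ss(self, neuron):
        S, rho, u_d, psp = 1.0, 0.2, 2.1, 0.3
        e3 = three_factor_limit(S, rho, u_d, psp, neuron)
        assert e3 == pytest.approx(
            eligibility_ss(S, rho, psp)
            * nmda_rate_derivative(u_d, neuron) * neuron.rate_to_per_ms
        )
        assert three_factor_limit(S, rho, u_d, 0.0, neuron) == 0

    def test_sds_converges_to_three_factor_rule(self):
        """Scaling a -> lam a, delta -> lam delta, rho_d -> rho_d / lam^2:
        lam * e_sds (integral line) approaches (delta/2) * the 3-factor value,
        with monotonically shrinking error over lam = 1, 1/2, 1/4, 1/8."""
        neuron = NeuronParams(n_branches=1, dt=0.5, theta_s=0.8,
                              rate_unit="per_s")
        T = 120.0
        pat = InputPattern(spikes=[np.array([10.0, 30.0, 60.0])], duration=T)
        psp = compute_psps(pat, neuron)
        n_bins = psp.shape[1]
        w = 30.0
        u_d = w * psp
        S_bin = int(35 / neuron.dt)
        soma_spikes = np.array([35.0])
        u_s = u_d[0] * 0.2 + 0.5  # a fixed somatic trace for the readout

        # reference: integral of the 3-factor rule over the trial
        S_mass = np.zeros(n_bins)
        S_mass[S_bin] = 1.0 / neuron.dt
        rho_s_ms = somatic_rate(u_s, neuron) * neuron.rate_to_per_ms
        e3 = three_factor_limit(S_mass, rho_s_ms, u_d[0], psp[0], neuron)
        ref = (e3 * neuron.dt).sum() * (neuron.delta / 2.0)

        errs = []
        for lam in (1.0, 0.5, 0.25, 0.125):
            nl = neuron.replace(
                a=neuron.a * lam, delta=neuron.delta * lam,
                r_D=neuron.r_D / lam ** 2,
            )
            pl = PlasticityParams(
                tau_E=np.inf, delta_bar=nl.delta / 2.0, a_bar=1.0,
                mix=0.0, use_ss=False,
            )
            trial = TrialRecord(
                t_grid=np.arange(n_bins) * nl.dt,
                psp=psp,
                u_dend=u_d,
                nmda_on=np.zeros((1, n_bins), dtype=bool),  # spike-free regime
                nmda_triggers=[np.array([])],
                trigger_bin_of=np.full((1, n_bins), -1),
                u_soma=u_s,
                soma_spikes=soma_spikes,
                mode="free",
            )
            E = trial_eligibility(trial, nl, pl)[0, 0]
            errs.append(abs(lam * E - ref) / abs(ref))
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < errs[0] / 3


class TestSdsWeightCurve:
    def test_pre_dend_post_window_signs(self, neuron):
        """Potentiation throughout the plateau window (t_dend, t_dend + delta),
        depression for acausal post-before-pre timing."""
        grid = np.array([-40.0, -20.0, 10.0, 25.0, 40.0, 52.0])
        dw = sds_weight_curve(0.0, 5.0, grid, neuron)
        assert np.all(dw[:2] < 0)      # acausal: depression
        assert np.all(dw[2:] > 0)      # within plateau: potentiation

    def test_early_nmda_spike_potentiates_more(self, neuron):
        grid = np.arange(6.0, 54.0, 4.0)
        dw5 = sds_weight_curve(0.0, 5.0, grid + 5.0, neuron)
        dw15 = sds_weight_curve(0.0, 15.0, grid + 15.0, neuron)
        assert dw5.max() > dw15.max()
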