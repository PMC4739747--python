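"""Somato-dendritic synaptic plasticity (sdSP) and its reward-modulated form.

The rule decomposes the per-synapse weight change into a somato-synaptic (ss)
and a somato-dendro-synaptic (sds) stream:

    e_ss(t)  = (S(t) - rho_s(t)) * PSP_i(t)
    e_sds(t) = (S(t) - rho_sans_d(t)) * (Den_d * PSP_i)(t)

where ``rho_sans_d = c * rho_s(u_s - alpha * a * NMDA_d)`` is the somatic
escape rate with branch d's putative plateau contribution removed
(``c = (e^{alpha a beta_s} - 1) / (alpha a beta_s)``), and ``Den_d * PSP_i``
measures how much synapse i contributed to triggering the plateau: within a
plateau triggered at t_d it mixes a sampling term
``PSP_i(t_d) rho_d'(t_d)/rho_d(t_d)`` with the windowed integral of
``rho_d' PSP_i`` (approximated online by the low-pass ``sigma_di`` with time
constant ``delta_bar = delta/2``); outside a plateau only the integral term
remains.  Both streams are weighted and low-pass filtered into the
eligibility trace

    dE_di/dt = -E_di / tau_E + a_bar * e_sds + e_ss,    a_bar = a/2,

read out at the end of the stimulus (supervised: dw = eta E(T)) or at reward
delivery (R-sdSP: dw = eta (R - R0) E(t_rew)).

Two equivalent implementations are provided: a per-bin reference recursion
(`trial_eligibility_reference`, used by the unit tests and exportable for
debugging) and a closed-form vectorized path (`trial_eligibility`) used by
the training loops; both discretize the linear filters with exact
exponential integrators, so they agree to numerical precision.

Conventions: spike trains carry delta mass 1/dt in their bin; all rates
enter the eligibilities in events/ms so that (S - rho) integrates correctly
over the ms time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .model import (
    NeuronParams,
    SynapticWeights,
    TrialRecord,
    nmda_rate,
    somatic_rate,
)

__all__ = [
    "PlasticityParams",
    "EligibilityState",
    "escape_correction",
    "rho_without_d",
    "nmda_rate_derivative",
    "den_conv_psp",
    "eligibility_ss",
    "eligibility_sds",
    "update_eligibility",
    "supervised_update",
    "reward_update",
    "three_factor_limit",
    "sds_weight_curve",
    "trial_eligibility",
    "trial_eligibility_reference",
]


@dataclass
class PlasticityParams:
    """Tunable constants of sdSP / R-sdSP.

    ``tau_E`` defaults to half the stimulus duration (T/2 for T = 500 ms),
    ``delta_bar`` to half the plateau duration, ``a_bar`` to half the plateau
    amplitude.  ``mix`` weighs the sampling (upper) term against the
    windowed-integral (lower) term inside a plateau; equal weighting performs
    best.  ``use_ss`` / ``use_sds`` switch off one stream (ablations), and
    ``u_lowpass_tau`` optionally low-pass filters the somatic voltage entering
    the plasticity readout (robustness variant; 0 = off).
    """

    eta: float = 1.0            # learning rate
    R0: float = 1.0             # reward baseline for R-sdSP
    tau_E: float = 250.0        # eligibility filter constant (ms), T/2
    delta_bar: float = 25.0     # sigma filter constant (ms), delta/2
    a_bar: float = 3.0          # sds stream weighting, a/2
    mix: float = 0.5            # weight of the sampling term within plateaus
    use_ss: bool = True
    use_sds: bool = True
    u_lowpass_tau: float = 0.0  # low-pass on the somatic readout (ms), 0 = off

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.delta_bar <= 0:
            raise ValueError("tau_E and delta_bar must be positive")
        if not (0.0 <= self.mix <= 1.0):
            raise ValueError("mix must lie in [0, 1]")

    @classmethod
    def from_neuron(
        cls, neuron: NeuronParams, duration: float, **kwargs
    ) -> "PlasticityParams":
        """Defaults tied to the neuron and stimulus: tau_E=T/2, delta_bar=delta/2, a_bar=a/2."""
        kwargs.setdefault("tau_E", duration / 2.0)
        kwargs.setdefault("delta_bar", neuron.delta / 2.0)
        kwargs.setdefault("a_bar", neuron.a / 2.0)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "PlasticityParams":
        return replace(self, **kwargs)


@dataclass
class EligibilityState:
    """Per-synapse accumulators: eligibility E_di and the sigma_di low-pass."""

    E: np.ndarray       # (n_branches, n_channels)
    sigma: np.ndarray   # (n_branches, n_channels)

    @classmethod
    def zeros(cls, n_branches: int, n_channels: int) -> "EligibilityState":
        return cls(
            E=np.zeros((n_branches, n_channels)),
            sigma=np.zeros((n_branches, n_channels)),
        )


def escape_correction(neuron: NeuronParams) -> float:
    """c = (e^{alpha a beta_s} - 1) / (alpha a beta_s); -> 1 as the exponent -> 0."""
    x = neuron.alpha * neuron.a * neuron.beta_s
    if abs(x) < 1e-12:
        return 1.0
    return float(np.expm1(x) / x)


def rho_without_d(u_s, nmda_on_d, neuron: NeuronParams):
    """Somatic escape rate with branch d's plateau removed: c rho_s(u_s - alpha a NMDA_d)."""
    c = escape_correction(neuron)
    shift = neuron.alpha * neuron.a * np.asarray(nmda_on_d, dtype=float)
    return c * somatic_rate(np.asarray(u_s, dtype=float) - shift, neuron)


def nmda_rate_derivative(u, neuron: NeuronParams):
    """d rho_d / du = (beta_D / r_D) rho_d(u) (r_D - rho_d(u))."""
    if neuron.r_D == 0:  # NMDA generation suppressed
        return np.zeros_like(np.asarray(u, dtype=float))
    rho = nmda_rate(u, neuron)
    return (neuron.beta_D / neuron.r_D) * rho * (neuron.r_D - rho)


def eligibility_ss(S_bin, rho_s_ms, psp_i):
    """Somato-synaptic increment (S - rho_s) PSP_i; rates in events/ms,
    S_bin carrying delta mass 1/dt in spike bins."""
    return (np.asarray(S_bin, float) - np.asarray(rho_s_ms, float)) * psp_i


def eligibility_sds(S_bin, rho_wo_d_ms, denpsp):
    """Somato-dendro-synaptic increment (S - rho_sans_d) (Den_d * PSP_i)."""
    return (np.asarray(S_bin, float) - np.asarray(rho_wo_d_ms, float)) * denpsp


def _filter_gains(tau: float, dt: float) -> tuple[float, float]:
    """Exact exponential-integrator coefficients for dx/dt = -x/tau + drive.

    Returns (decay, gain) with x[n+1] = decay x[n] + gain drive[n];
    tau = inf yields plain integration (decay 1, gain dt).
    """
    if np.isinf(tau):
        return 1.0, dt
    lam = float(np.exp(-dt / tau))
    return lam, tau * (1.0 - lam)


def update_eligibility(
    state: EligibilityState,
    e_ss: np.ndarray,
    e_sds: np.ndarray,
    dt: float,
    params: PlasticityParams,
) -> EligibilityState:
    """One bin of dE/dt = -E/tau_E + a_bar e_sds + e_ss (exact integrator)."""
    lam, gain = _filter_gains(params.tau_E, dt)
    drive = 0.0
    if params.use_sds:
        drive = drive + params.a_bar * e_sds
    if params.use_ss:
        drive = drive + e_ss
    state.E = state.E * lam + gain * drive
    return state


def den_conv_psp(
    sigma_di,
    plateau_on,
    psp_at_trigger,
    u_d_at_trigger,
    neuron: NeuronParams,
    params: PlasticityParams,
):
    """Den_d * PSP_i at one bin.

    ``sigma_di`` is the causal low-pass of rho_d' PSP_i (the lower,
    windowed-integral line); within a plateau the sampling (upper) line
    U = PSP_i(t_d) rho_d'(t_d) / rho_d(t_d) is mixed in with weight ``mix``.
    The ratio rho_d'/rho_d = beta_D (1 - rho_d/r_D) is unit-free.
    """
    if not plateau_on:
        return sigma_di
    upper = (
        neuron.beta_D
        * (1.0 - nmda_rate(u_d_at_trigger, neuron) / neuron.r_D)
        * psp_at_trigger
    )
    return params.mix * upper + (1.0 - params.mix) * sigma_di


def supervised_update(
    weights: SynapticWeights, E_at_T: np.ndarray, params: PlasticityParams
) -> SynapticWeights:
    """sdSP step after a clamped stimulus: w += eta E(T) on connected synapses."""
    weights.w = weights.w + params.eta * E_at_T * weights.mask
    return weights

def reward_update(
    weights: SynapticWeights, E_at_rew: np.ndarray, R: float, params: PlasticityParams
) -> SynapticWeights:
    """R-sdSP step at reward delivery: w += eta (R - R0) E(t_rew)."""
    weights.w = weights.w + params.eta * (R - params.R0) * E_at_rew * weights.mask
    return weights


def three_factor_limit(S_bin, rho_s_ms, u_d, psp_i, neuron: NeuronParams):
    """Plateau-free limit of e_sds: (S - rho_s) rho_d'(u_d) PSP_i.

    Obtained by scaling a -> lam a, delta -> lam delta, rho_d -> rho_d/lam^2
    and letting lam -> 0 (rates in events/ms).
    """
    deriv_ms = nmda_rate_derivative(u_d, neuron) * neuron.rate_to_per_ms
    return (np.asarray(S_bin, float) - np.asarray(rho_s_ms, float)) * deriv_ms * psp_i


# ---------------------------------------------------------------------------
# per-trial eligibility: reference recursion and fast closed form
# ---------------------------------------------------------------------------

# cap on rho * dt inside the eligibilities, in events per bin.  A spike bin
# carries delta mass 1/dt, so once rho dt exceeds 1 the raw error (S - rho)
# turns negative even in bins that did spike; under reward modulation with
# R - R0 < 0 that sign flip converts punishment into potentiation and the
# weights run away.  Capping rho at one expected event per bin keeps the
# error consistent with the binned spike train (zero in a satisfied spike
# bin, bounded depression elsewhere) and is inactive in the small rho dt
# regime where the rule equals the continuous-time likelihood gradient.
RATE_CAP_PER_BIN = 1.0


def _capped(rho_ms, dt: float):
    return np.minimum(rho_ms, RATE_CAP_PER_BIN / dt)


def _readout_voltage(u_soma: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Optionally low-pass filter the somatic voltage entering the readout."""
    if tau <= 0:
        return u_soma
    lam, gain = _filter_gains(tau, dt)
    return lfilter([gain / tau], [1.0, -lam], u_soma)


def _spike_mass(trial: TrialRecord, dt: float) -> np.ndarray:
    S = np.zeros(trial.n_bins)
    for b in trial.soma_spike_bins:
        S[b] += 1.0 / dt
    return S


def trial_eligibility_reference(
    trial: TrialRecord,
    neuron: NeuronParams,
    params: PlasticityParams,
    state: EligibilityState | None = None,
    return_trace: bool = False,
):
    """Per-bin recursion over the trial; returns the final EligibilityState.

    Slow but transparent; the vectorized `trial_eligibility` must reproduce
    its E(T) to numerical precision.
    """
    dt = neuron.dt
    n_b, n_bins = trial.u_dend.shape
    n_ch = trial.psp.shape[0]
    if state is None:
        state = EligibilityState.zeros(n_b, n_ch)
    c = escape_correction(neuron)
    to_ms = neuron.rate_to_per_ms
    mu, gain_s = _filter_gains(params.delta_bar, dt)
    S = _spike_mass(trial, dt)
    u_read = _readout_voltage(trial.u_soma, dt, params.u_lowpass_tau)
    trace = np.zeros((n_bins, n_b, n_ch)) if return_trace else None

    for n in range(n_bins):
        psp_n = trial.psp[:, n]
        g_n = nmda_rate_derivative(trial.u_dend[:, n], neuron) * to_ms
        state.sigma = state.sigma * mu + gain_s * g_n[:, None] * psp_n[None, :]
        denpsp = state.sigma.copy()
        rho_s_n = _capped(somatic_rate(u_read[n], neuron) * to_ms, dt)
        rho_wo = _capped(
            c
            * somatic_rate(
                u_read[n]
                - neuron.alpha * neuron.a * trial.nmda_on[:, n].astype(float),
                neuron,
            )
            * to_ms,
            dt,
        )
        for d in range(n_b):
            if trial.nmda_on[d, n]:
                m = trial.trigger_bin_of[d, n]
                denpsp[d] = den_conv_psp(
                    state.sigma[d],
                    True,
                    trial.psp[:, m],
                    trial.u_dend[d, m],
                    neuron,
                    params,
                )
        e_ss = eligibility_ss(S[n], rho_s_n, psp_n)[None, :]
        e_sds = eligibility_sds(S[n], rho_wo[:, None], denpsp)
        state = update_eligibility(state, e_ss, e_sds, dt, params)
        if return_trace:
            trace[n] = state.E
    if return_trace:
        return state, trace
    return state


def trial_eligibility(
    trial: TrialRecord, neuron: NeuronParams, params: PlasticityParams
) -> np.ndarray:
    """E(T) for all synapses, closed form (identical discretization).

    Exploits linearity: E(T) is a weighted sum over bins of the eligibility
    drive, and the sigma low-pass is separable, so everything reduces to 1-D
    filters over (branch, time) arrays plus two matrix products with the PSP
    matrix; the sparse plateau sampling terms are added per trigger.
    """
    dt = neuron.dt
    n_b, n_bins = trial.u_dend.shape
    c = escape_correction(neuron)
    to_ms = neuron.rate_to_per_ms
    lam, gain_E = _filter_gains(params.tau_E, dt)
    mu, gain_s = _filter_gains(params.delta_bar, dt)

    S = _spike_mass(trial, dt)
    u_read = _readout_voltage(trial.u_soma, dt, params.u_lowpass_tau)
    # weight of bin n in E(T) under the exponential integrator
    if np.isinf(params.tau_E):
        W = np.full(n_bins, dt)
    else:
        W = gain_E * lam ** (n_bins - 1 - np.arange(n_bins))

    P = trial.psp
    E = np.zeros((n_b, P.shape[0]))

    if params.use_ss:
        rho_s = _capped(somatic_rate(u_read, neuron) * to_ms, dt)
        E += (P @ ((S - rho_s) * W))[None, :]

    if params.use_sds:
        on = trial.nmda_on.astype(float)
        rho_wo = _capped(
            c
            * somatic_rate(u_read[None, :] - neuron.alpha * neuron.a * on, neuron)
            * to_ms,
            dt,
        )
        B = params.a_bar * (S[None, :] - rho_wo) * W[None, :]
        # lower (integral) line carries weight 1 outside, (1 - mix) inside a plateau
        B_low = B * (1.0 - params.mix * on)
        # sum_n B_low[d,n] sigma[d,i,n] = sum_m g[d,m] P[i,m] gain_s C[d,m],
        # C[d,m] = sum_{n>=m} B_low[d,n] mu^(n-m)  (reverse exponential scan)
        C = lfilter([1.0], [1.0, -mu], B_low[:, ::-1], axis=1)[:, ::-1]
        g = nmda_rate_derivative(trial.u_dend, neuron) * to_ms
        E += (g * C * gain_s) @ P.T
        # sampling (upper) line: the governing trigger's PSP/rate-ratio value
        # weighs every plateau bin it governs; accumulate weights per trigger
        if params.mix > 0.0 and neuron.r_D > 0:
            B_up = B * (params.mix * on)
            ratio = neuron.beta_D * (1.0 - nmda_rate(trial.u_dend, neuron)
                                     / neuron.r_D)
            for d in range(n_b):
                sel = trial.nmda_on[d]
                if not sel.any():
                    continue
                coef = np.bincount(
                    trial.trigger_bin_of[d][sel],
                    weights=B_up[d][sel],
                    minlength=n_bins,
                )
                E[d] += P @ (coef * ratio[d])
    return E


# ---------------------------------------------------------------------------
# deterministic pre/dend/post weight-change curve
# ---------------------------------------------------------------------------

def sds_weight_curve(
    t_pre: float,
    t_dend: float,
    t_soma_grid,
    neuron: NeuronParams,
    params: PlasticityParams | None = None,
    w_syn: float = 30.0,
    pad: float = 60.0,
) -> np.ndarray:
    """dw_sds as a function of the somatic spike time (one synapse, one branch).

    Deterministic evaluation: a single presynaptic spike at ``t_pre``, one
    forced NMDA trigger at ``t_dend`` and one somatic spike swept over
    ``t_soma_grid`` (which may include acausal, negative times); the sds
    eligibility is integrated to the end of the window and scaled by
    eta a_bar.  Reproduces the pre-dend-post potentiation window and the
    acausal depression.
    """
    from .model import TrialRecord, psp_kernel

    if params is None:
        params = PlasticityParams(eta=1.0)
    t_soma_grid = np.asarray(t_soma_grid, dtype=float)
    dt = neuron.dt
    t0 = min(0.0, t_soma_grid.min()) - pad
    t1 = max(t_dend + neuron.delta, t_soma_grid.max()) + pad
    n_bins = int(round((t1 - t0) / dt))
    t_grid = np.arange(n_bins) * dt + t0

    psp = psp_kernel(t_grid - t_pre, neuron)[None, :]
    u_d = w_syn * psp
    trig_bin = int(round((t_dend - t0) / dt))
    nmda_on = np.zeros((1, n_bins), dtype=bool)
    nmda_on[0, trig_bin : trig_bin + neuron.delta_bins] = True
    trigger_bin_of = np.where(nmda_on, trig_bin, -1)

    decay = np.exp(-dt / neuron.tau_m)
    base = neuron.alpha * (u_d[0] + neuron.a * nmda_on[0])

    out = np.zeros(t_soma_grid.size)
    p_only = params.replace(use_ss=False, use_sds=True)
    for j, t_s in enumerate(t_soma_grid):
        sb = int(round((t_s - t0) / dt))
        reset = np.zeros(n_bins)
        if sb + 1 < n_bins:
            reset[sb + 1 :] = decay ** np.arange(1, n_bins - sb - 1 + 1)
        trial = TrialRecord(
            t_grid=t_grid,
            psp=psp,
            u_dend=u_d,
            nmda_on=nmda_on,
            nmda_triggers=[np.array([t_dend])],
            trigger_bin_of=trigger_bin_of,
            u_soma=base - reset,
            soma_spikes=np.array([]),  # bins set directly below
            mode="clamped",
        )
        S = np.zeros(n_bins)
        S[sb] = 1.0 / dt
        out[j] = params.eta * _eligibility_with_spike_mass(
            trial, S, neuron, p_only
        )[0, 0]
    return out


def _eligibility_with_spike_mass(trial, S, neuron, params):
    """trial_eligibility with an explicit spike-mass trace (internal)."""
    saved = trial.soma_spikes
    dt = neuron.dt
    bins = np.nonzero(S)[0]
    trial.soma_spikes = bins * dt
    try:
        return trial_eligibility(trial, neuron, params)
    finally:
        trial.soma_spikes = saved
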