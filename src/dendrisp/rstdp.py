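"""Reward-modulated STDP baseline (best-performing published variant).

Pair-based eligibility per synapse,

    e_stdp(t) = A_+ post(t) xbar_+(t) + A_- pre(t) postbar_-(t),

with xbar_+ the exponentially filtered presynaptic history (tau_+) and
postbar_- the filtered postsynaptic history (tau_-); the defaults A_+ = 1,
A_- = 0 keep only causal pre-before-post pairings.  The postsynaptic signal
is either the somatic spike train ('pre-som') or the branch-local dendritic
trigger train ('pre-den').  e_stdp is low-pass filtered with tau_E exactly
like the sdSP eligibility, and the weight update at reward time uses a
pattern-specific running-mean reward baseline,

    dw = eta (R - Rtilde(x)) E_stdp(t_rew),
    Rtilde(x) <- R/tau_p + (1 - 1/tau_p) Rtilde(x).

The default tau_+ = 10 ms follows the published baseline configuration (a
50 ms window matching the plateau duration is a config option).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .model import NeuronParams, SynapticWeights, TrialRecord
from .plasticity import _filter_gains

__all__ = [
    "RstdpParams",
    "stdp_eligibility",
    "trial_stdp_eligibility",
    "running_reward",
    "rstdp_update",
]


@dataclass
class RstdpParams:
    A_plus: float = 1.0
    A_minus: float = 0.0        # dormant by default (causal pairs only)
    tau_plus: float = 10.0      # ms
    tau_minus: float = 10.0     # ms
    tau_p: float = 5.0          # reward-history constant, in presentations
    post_source: str = "somatic"  # 'somatic' | 'dendritic'
    eta: float = 1.0
    tau_E: float = 250.0        # eligibility low-pass, as for sdSP

    def __post_init__(self) -> None:
        if self.tau_plus <= 0:
            raise ValueError("tau_plus must be positive")
        if self.tau_p < 1:
            raise ValueError("tau_p must be >= 1")
        if self.post_source not in ("somatic", "dendritic"):
            raise ValueError("post_source must be 'somatic' or 'dendritic'")

    def replace(self, **kwargs) -> "RstdpParams":
        return replace(self, **kwargs)


def _exp_history(ind: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Filtered spike history: h[n] = sum_{m<=n} e^(-(n-m) dt / tau) ind[m]."""
    lam = np.exp(-dt / tau)
    return lfilter([1.0], [1.0, -lam], ind, axis=-1)


def stdp_eligibility(
    pre_ind: np.ndarray,
    post_ind: np.ndarray,
    params: RstdpParams,
    dt: float,
) -> np.ndarray:
    """Instantaneous pair eligibility per bin from 0/1 spike indicators.

    ``pre_ind`` (n_pre, n_bins), ``post_ind`` (n_bins,) or (n_post, n_bins)
    broadcastable against pre.  Spike trains are delta trains: the outer
    train carries mass 1/dt per spike bin, the filtered history sums unit
    amplitudes.
    """
    xbar = _exp_history(pre_ind.astype(float), params.tau_plus, dt)
    post_mass = post_ind.astype(float) / dt
    e = params.A_plus * post_mass * xbar
    if params.A_minus != 0.0:
        postbar = _exp_history(post_ind.astype(float), params.tau_minus, dt)
        e = e + params.A_minus * (pre_ind.astype(float) / dt) * postbar
    return e


def trial_stdp_eligibility(
    trial: TrialRecord,
    pattern,
    weights: SynapticWeights,
    neuron: NeuronParams,
    params: RstdpParams,
) -> np.ndarray:
    """E_stdp(T) per synapse: pair eligibility low-pass filtered with tau_E."""
    dt = neuron.dt
    n_bins = trial.n_bins
    pre_ind = np.zeros((pattern.n_channels, n_bins))
    for i, times in enumerate(pattern.spikes):
        for b in np.minimum(np.floor(times / dt).astype(int), n_bins - 1):
            pre_ind[i, b] += 1.0

    lam, gain_E = _filter_gains(params.tau_E, dt)
    W = gain_E * lam ** (n_bins - 1 - np.arange(n_bins))

    if params.post_source == "somatic":
        post_ind = np.zeros(n_bins)
        for b in trial.soma_spike_bins:
            post_ind[b] += 1.0
        e = stdp_eligibility(pre_ind, post_ind[None, :], params, dt)
        E_ch = (e * W[None, :]).sum(axis=1)          # (n_pre,)
        return np.broadcast_to(E_ch, weights.w.shape).copy()
    # dendritic: post train = branch trigger train
    E = np.zeros(weights.w.shape)
    xbar = _exp_history(pre_ind, params.tau_plus, dt)
    for d in range(weights.n_branches):
        post_ind = np.zeros(n_bins)
        trig_bins = np.round(trial.nmda_triggers[d] / dt).astype(int)
        for b in trig_bins:
            post_ind[b] += 1.0
        e = params.A_plus * (post_ind / dt)[None, :] * xbar
        if params.A_minus != 0.0:
            postbar = _exp_history(post_ind, params.tau_minus, dt)
            e = e + params.A_minus * (pre_ind / dt) * postbar[None, :]
        E[d] = (e * W[None, :]).sum(axis=1)
    return E


def running_reward(R_tilde: float, R: float, params: RstdpParams) -> float:
    """Pattern-specific running mean: Rtilde <- R/tau_p + (1 - 1/tau_p) Rtilde."""
    return R / params.tau_p + (1.0 - 1.0 / params.tau_p) * R_tilde


def rstdp_update(
    weights: SynapticWeights,
    E_stdp: np.ndarray,
    R: float,
    R_tilde: float,
    eta: float,
) -> SynapticWeights:
    """dw = eta (R - Rtilde(x)) E_stdp at reward time."""
    weights.w = weights.w + eta * (R - R_tilde) * E_stdp * weights.mask
    return weights
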