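"""Experiment orchestration: training loops, learning-rate search, metrics.

Training protocols follow the experiments the model was designed for:

* supervised spike timing (``sdsp``): clamped presentations with the target
  somatic spikes imposed, weights updated at stimulus end, free-running test
  trials interleaved every ``test_every`` presentations (never updating);
* reward-modulated learning (``rsdsp``/``rstdp``): free-running
  presentations, weight update at reward delivery (stimulus end) with either
  the binary, graded, or navigation reward;
* navigation: episodes starting at a uniformly random circle position, one
  action (presentation) per step, running until the target is reached and
  held once.

Learning rates are optimized on a factor-1.5 ladder: eta0 is accepted when
it outperforms both adjacent values 1.5 eta0 and eta0/1.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import (
    InputPattern,
    NeuronParams,
    SynapticWeights,
    simulate_trial,
)
from .plasticity import (
    PlasticityParams,
    reward_update,
    supervised_update,
    trial_eligibility,
)
from .rstdp import RstdpParams, running_reward, rstdp_update, trial_stdp_eligibility
from .tasks import (
    NAV_N_POSITIONS,
    NavState,
    TaskConfig,
    apply_jitter,
    binary_reward,
    build_patterns,
    gen_direction_patterns,
    graded_reward,
    nav_decode_action,
    nav_step,
)

__all__ = [
    "ExperimentConfig",
    "TaskResult",
    "run_experiment",
    "run_many",
    "grid_search_eta",
    "precision_metric",
    "performance_index",
    "presentations_to_criterion",
    "evaluate_navigation",
    "navigation_episode_lengths",
]

DEFAULT_TARGETS = (100.0, 250.0, 400.0)


@dataclass
class ExperimentConfig:
    task: TaskConfig
    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams | RstdpParams = field(
        default_factory=PlasticityParams
    )
    rule: str = "rsdsp"          # 'sdsp' | 'rsdsp' | 'rstdp'
    n_presentations: int = 1000
    test_every: int = 10         # free test trials interleaved (sdsp)
    n_runs: int = 1
    seed: int = 0
    suppress_nmda: bool = False  # disable dendritic spike generation (r_D = 0)
    max_episode_len: int = 50    # navigation episode cap (actions)

    def __post_init__(self) -> None:
        if self.n_presentations < 1:
            raise ValueError("n_presentations must be >= 1")
        if self.rule not in ("sdsp", "rsdsp", "rstdp"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.rule == "sdsp" and self.task.task_id != "timing_supervised":
            raise ValueError("sdsp (supervised) applies only to timing_supervised")
        if self.rule != "sdsp" and self.task.task_id == "timing_supervised":
            raise ValueError("timing_supervised requires rule='sdsp'")
        if self.rule == "rstdp" and self.task.task_id in (
            "precise_timing",
            "navigation",
        ):
            raise ValueError("rstdp is defined for the classification tasks")


@dataclass
class TaskResult:
    rewards: list = field(default_factory=list)       # per presentation
    correct: list = field(default_factory=list)       # per presentation (bool)
    test_spikes: list = field(default_factory=list)   # spike arrays, test trials
    test_at: list = field(default_factory=list)       # presentation index of tests
    spike_trains: list = field(default_factory=list)  # training-trial spikes
    weights: SynapticWeights | None = None
    initial_weights: SynapticWeights | None = None
    metrics: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "rewards": [float(r) for r in self.rewards],
            "correct": [bool(c) for c in self.correct],
            "test_at": [int(i) for i in self.test_at],
            "test_spikes": [np.asarray(s).tolist() for s in self.test_spikes],
            "metrics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.metrics.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def precision_metric(test_spike_trains, targets) -> float:
    """SD (ms) of spike deviations from the nearest target time.

    Trials whose spike count differs from the number of targets are
    discarded; if no trial has the right count, all spikes are pooled as a
    fallback so a (large) precision is still reported.
    """
    targets = np.asarray(targets, dtype=float)
    trains = [np.asarray(s, dtype=float) for s in test_spike_trains]
    if not any(s.size for s in trains):
        raise ValueError("no spikes in any test trial")
    valid = [s for s in trains if s.size == targets.size]
    pool = valid if valid else [s for s in trains if s.size]
    devs = np.concatenate(
        [s - targets[np.abs(s[:, None] - targets[None, :]).argmin(axis=1)]
         for s in pool]
    )
    return float(np.std(devs))


def performance_index(rollout_rewards) -> float:
    """Fraction of single-action rollouts earning R = +1."""
    r = np.asarray(rollout_rewards)
    return float(np.mean(r == 1))


def presentations_to_criterion(correct, streak: int = 40):
    """First presentation index (0-based) at which a run of ``streak``
    consecutive correct responses begins; None if never reached."""
    run = 0
    for k, c in enumerate(correct):
        run = run + 1 if c else 0
        if run >= streak:
            return k - streak + 1
    return None


def grid_search_eta(objective, eta0: float, factor: float = 1.5,
                    max_steps: int = 12) -> float:
    """Hill-climb on the factor-1.5 learning-rate ladder.

    Returns eta such that objective(eta) >= objective(eta * factor) and
    >= objective(eta / factor); ties break toward the smaller eta, a flat
    triple returns the current eta, and a monotone curve raises after
    ``max_steps`` ladder moves.
    """
    cache: dict[int, float] = {}

    def f(n: int) -> float:
        if n not in cache:
            cache[n] = float(objective(eta0 * factor ** n))
        return cache[n]

    pos = 0
    for _ in range(max_steps):
        cand = [pos - 1, pos, pos + 1]
        scores = [f(n) for n in cand]
        if scores[0] == scores[1] == scores[2]:
            return eta0 * factor ** pos
        # tie toward the smallest eta among equal top scores
        top = max(scores)
        best = min(n for n, s in zip(cand, scores) if s == top)
        if best == pos:
            return eta0 * factor ** pos
        pos = best
    raise RuntimeError(
        "learning-rate ladder did not find a local maximum "
        f"within {max_steps} steps (monotone performance curve?)"
    )


# ---------------------------------------------------------------------------
# experiment loops
# ---------------------------------------------------------------------------

def _streams(seed):
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    init_s, trial_s, test_s = ss.spawn(3)
    return (
        np.random.default_rng(init_s),
        np.random.default_rng(trial_s),
        np.random.default_rng(test_s),
    )


def _neuron_for(config: ExperimentConfig) -> NeuronParams:
    if config.suppress_nmda:
        return config.neuron.replace(r_D=0.0)
    return config.neuron


def run_experiment(config: ExperimentConfig) -> TaskResult:
    """Execute one train/test run; deterministic given ``config.seed``."""
    task = config.task
    if task.task_id == "timing_supervised":
        return _run_supervised(config)
    if task.task_id == "navigation":
        return _run_navigation(config)
    if task.task_id == "precise_timing":
        return _run_precise_timing(config)
    return _run_classification(config)


def run_many(config: ExperimentConfig) -> list[TaskResult]:
    """Independent repetitions with seeds spawned from ``config.seed``."""
    from dataclasses import replace as _replace

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    results = []
    for s in seeds:
        results.append(run_experiment(_replace(config, seed=s, n_runs=1)))
    return results


def _run_supervised(config: ExperimentConfig) -> TaskResult:
    neuron = _neuron_for(config)
    plast = config.plasticity
    rng_w, rng_trial, rng_test = _streams(config.seed)
    pattern = build_patterns(config.task)[0]
    targets = tuple(config.task.targets) or DEFAULT_TARGETS
    weights = SynapticWeights.initialize(neuron, config.task.n_afferents, rng_w)
    res = TaskResult(initial_weights=weights.copy())

    for k in range(config.n_presentations):
        pat = (
            apply_jitter(pattern, config.task.jitter_sd_ms, rng_trial)
            if config.task.jitter_sd_ms > 0
            else pattern
        )
        trial = simulate_trial(
            neuron, weights, pat, mode="clamped", clamp_spikes=targets,
            rng=rng_trial,
        )
        E = trial_eligibility(trial, neuron, plast)
        supervised_update(weights, E, plast)
        if (k + 1) % config.test_every == 0:
            test = simulate_trial(neuron, weights, pattern, mode="free",
                                  rng=rng_test)
            res.test_spikes.append(test.soma_spikes)
            res.test_at.append(k)

    res.weights = weights
    tail = max(1, int(0.3 * len(res.test_spikes)))
    try:
        res.metrics["precision_ms"] = precision_metric(
            res.test_spikes[-tail:], targets
        )
    except ValueError:
        res.metrics["precision_ms"] = float("nan")
    res.metrics["targets"] = list(targets)
    return res


def _labeled_presentation(config, patterns, k, rng):
    """Pattern (id, InputPattern, wants_spike) for presentation k."""
    task = config.task
    if task.task_id == "direction":
        fwd, bwd = gen_direction_patterns(
            config.n_synapses_, task.T_ms, rng, perm=config.perm_
        )
        if k % 2 == 0:
            return 0, fwd, True    # left-to-right requires a spike
        return 1, bwd, False
    idx = k % len(patterns)
    pat, wants = patterns[idx]
    if task.jitter_sd_ms > 0:
        pat = apply_jitter(pat, task.jitter_sd_ms, rng)
    return idx, pat, wants


def _run_classification(config: ExperimentConfig) -> TaskResult:
    """spike/no-spike, XOR and direction tasks under rsdsp or rstdp."""
    neuron = _neuron_for(config)
    plast = config.plasticity
    rng_w, rng_trial, _ = _streams(config.seed)
    task = config.task

    if task.task_id == "direction":
        # one input channel per realized synaptic contact
        weights = SynapticWeights.initialize(
            neuron, task.n_afferents, rng_w, per_synapse=True
        )
        config.n_synapses_ = weights.n_channels
        config.perm_ = rng_w.permutation(weights.n_channels)
        patterns = []
    else:
        patterns = build_patterns(task)
        # the feature-binding task fixes its own channel layout (4 x 25)
        n_ch = patterns[0][0].n_channels
        weights = SynapticWeights.initialize(neuron, n_ch, rng_w)

    res = TaskResult(initial_weights=weights.copy())
    r_tilde = {}

    for k in range(config.n_presentations):
        idx, pat, wants = _labeled_presentation(config, patterns, k, rng_trial)
        trial = simulate_trial(neuron, weights, pat, mode="free", rng=rng_trial)
        R = binary_reward(trial.soma_spikes, wants)
        if config.rule == "rsdsp":
            E = trial_eligibility(trial, neuron, plast)
            reward_update(weights, E, R, plast)
        else:
            E = trial_stdp_eligibility(trial, pat, weights, neuron, plast)
            rt = r_tilde.get(idx, 0.0)
            rstdp_update(weights, E, R, rt, plast.eta)
            r_tilde[idx] = running_reward(rt, R, plast)
        res.rewards.append(R)
        res.correct.append(R > 0)

    res.weights = weights
    tail = max(1, config.n_presentations // 5)
    res.metrics["final_accuracy"] = float(np.mean(res.correct[-tail:]))
    crit = presentations_to_criterion(res.correct)
    res.metrics["presentations_to_criterion"] = crit
    return res


def _run_precise_timing(config: ExperimentConfig) -> TaskResult:
    neuron = _neuron_for(config)
    plast = config.plasticity
    rng_w, rng_trial, _ = _streams(config.seed)
    task = config.task
    pattern = build_patterns(task)[0]
    t_targ = task.targets[0] if task.targets else 250.0
    weights = SynapticWeights.initialize(neuron, task.n_afferents, rng_w)
    res = TaskResult(initial_weights=weights.copy())

    for _ in range(config.n_presentations):
        trial = simulate_trial(neuron, weights, pattern, mode="free",
                               rng=rng_trial)
        R = graded_reward(trial.soma_spikes, t_targ, task.T_ms)
        E = trial_eligibility(trial, neuron, plast)
        reward_update(weights, E, R, plast)
        res.rewards.append(R)
        res.spike_trains.append(trial.soma_spikes)

    res.weights = weights
    res.metrics["t_targ"] = t_targ
    tail = max(1, config.n_presentations // 4)
    pooled = (
        np.concatenate([s for s in res.spike_trains[-tail:]])
        if any(s.size for s in res.spike_trains[-tail:])
        else np.array([])
    )
    res.metrics["spike_time_sigma_ms"] = (
        gaussian_halfwidth(pooled, t_targ) if pooled.size >= 10 else float("nan")
    )
    return res


def gaussian_halfwidth(spike_times, t_targ: float, window: float = 100.0) -> float:
    """Gaussian half-width (sigma, ms) of the spike-time distribution around
    the target, estimated from spikes within +-window of it."""
    t = np.asarray(spike_times, dtype=float)
    t = t[np.abs(t - t_targ) <= window]
    if t.size < 2:
        return float("nan")
    return float(np.sqrt(np.mean((t - t.mean()) ** 2)))


# -- navigation -------------------------------------------------------------

def _nav_action(neuron, weights, pattern, rng):
    trial = simulate_trial(neuron, weights, pattern, mode="free", rng=rng)
    return nav_decode_action(trial.soma_spikes, pattern.duration), trial


def evaluate_navigation(
    neuron, weights, patterns, rng, n_rollouts: int = 20
) -> float:
    """Performance index: fraction of single actions earning R=+1 across all
    positions (direct jump to target / staying at target)."""
    rewards = []
    for pos in range(NAV_N_POSITIONS):
        for _ in range(n_rollouts):
            jump, _ = _nav_action(neuron, weights, patterns[pos], rng)
            _, R = nav_step(NavState(position=pos), jump)
            rewards.append(R)
    return performance_index(rewards)


def navigation_episode_lengths(
    neuron, weights, patterns, rng, n_episodes: int = 50, cap: int = 500
) -> list[int]:
    """Actions needed to first reach the target from a random non-target
    start (no learning); episodes are truncated at ``cap`` actions."""
    lengths = []
    for _ in range(n_episodes):
        state = NavState(position=int(rng.integers(1, NAV_N_POSITIONS)))
        n = 0
        while n < cap:
            jump, _ = _nav_action(neuron, weights, patterns[state.position], rng)
            state, _R = nav_step(state, jump)
            n += 1
            if state.position == 0:
                break
        lengths.append(n)
    return lengths


def _run_navigation(config: ExperimentConfig) -> TaskResult:
    neuron = _neuron_for(config)
    plast = config.plasticity
    rng_w, rng_trial, rng_eval = _streams(config.seed)
    task = config.task
    patterns = build_patterns(task)
    weights = SynapticWeights.initialize(neuron, task.n_afferents, rng_w)
    res = TaskResult(initial_weights=weights.copy())

    episode_lengths = []
    k = 0
    state = NavState(position=int(rng_trial.integers(NAV_N_POSITIONS)))
    ep_len = 0
    while k < config.n_presentations:
        pat = patterns[state.position]
        jump, trial = _nav_action(neuron, weights, pat, rng_trial)
        new_state, R = nav_step(state, jump)
        E = trial_eligibility(trial, neuron, plast)
        reward_update(weights, E, R, plast)
        res.rewards.append(R)
        res.correct.append(R > 0)
        k += 1
        ep_len += 1
        done = (state.position == 0 and jump == 0) or ep_len >= config.max_episode_len
        state = new_state
        if done:
            episode_lengths.append(ep_len)
            ep_len = 0
            state = NavState(position=int(rng_trial.integers(NAV_N_POSITIONS)))

    res.weights = weights
    res.extra["episode_lengths"] = episode_lengths
    res.metrics["performance_index"] = evaluate_navigation(
        neuron, weights, patterns, rng_eval
    )
    tail = max(1, config.n_presentations // 5)
    res.metrics["final_reward_rate"] = float(np.mean(res.correct[-tail:]))
    return res
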