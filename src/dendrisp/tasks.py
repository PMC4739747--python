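"""Input-pattern generators and reward functions for the five experiments.

All generators are seed-deterministic: regenerating with the stored seed
reproduces byte-identical patterns ("frozen" Poisson patterns).  The study
conditions are 100 afferents firing at 6 Hz for T = 500 ms, except for the
direction-selectivity task (one channel per synaptic contact, each activated
once per sweep) and the feature-binding (XOR) task (4 populations of 25
afferents coding feature presence/absence by 40/5 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import InputPattern

__all__ = [
    "TaskConfig",
    "NavState",
    "gen_frozen_poisson",
    "apply_jitter",
    "gen_direction_patterns",
    "gen_xor_patterns",
    "binary_reward",
    "graded_reward",
    "nav_decode_action",
    "nav_step",
    "NAV_N_POSITIONS",
    "NAV_JUMPS",
]

NAV_N_POSITIONS = 7
NAV_JUMPS = (0, 1, 2, 3, -1, -2, -3)

TASK_IDS = (
    "timing_supervised",
    "spike_nospike",
    "direction",
    "xor",
    "precise_timing",
    "navigation",
)


@dataclass
class TaskConfig:
    """Declarative description of one experiment's input/label structure."""

    task_id: str = "spike_nospike"
    n_afferents: int = 100
    rate_hz: float = 6.0
    T_ms: float = 500.0
    n_patterns: int = 4
    targets: tuple = ()          # target spike times (supervised / graded reward)
    jitter_sd_ms: float = 0.0    # Gaussian spike-time jitter (robustness variant)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task_id not in TASK_IDS:
            raise ValueError(f"unknown task_id {self.task_id!r}")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NavState:
    """Agent state on the 7-position circle (position arithmetic mod 7)."""

    position: int = 0
    step_count: int = 0

    def __post_init__(self) -> None:
        self.position %= NAV_N_POSITIONS


def gen_frozen_poisson(
    n_channels: int,
    rate_hz: float,
    T: float,
    seed,
    channel_mode: str = "per_afferent",
) -> InputPattern:
    """Homogeneous Poisson spike times per channel; identical for identical seed."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    lam = rate_hz * T / 1000.0
    spikes = []
    for _ in range(n_channels):
        n = rng.poisson(lam)
        t = np.unique(np.sort(rng.uniform(0.0, T, size=n)))
        spikes.append(t)
    return InputPattern(spikes=spikes, duration=T, channel_mode=channel_mode)


def apply_jitter(
    pattern: InputPattern, sd_ms: float, rng: np.random.Generator
) -> InputPattern:
    """Shift every spike by N(0, sd^2), clipped into [0, T); count preserved."""
    if sd_ms < 0:
        raise ValueError("sd must be >= 0")
    if sd_ms == 0:
        return InputPattern(
            spikes=[s.copy() for s in pattern.spikes],
            duration=pattern.duration,
            channel_mode=pattern.channel_mode,
        )
    eps = 1e-6
    out = []
    for s in pattern.spikes:
        t = s + rng.normal(0.0, sd_ms, size=s.size)
        t = np.clip(t, 0.0, pattern.duration - eps)
        t = np.sort(t)
        # break exact ties from clipping so times stay strictly sorted
        for k in range(1, t.size):
            if t[k] <= t[k - 1]:
                t[k] = np.nextafter(t[k - 1], np.inf)
        out.append(t)
    return InputPattern(
        spikes=out, duration=pattern.duration, channel_mode=pattern.channel_mode
    )


def gen_direction_patterns(
    n_synapses: int,
    T: float,
    rng: np.random.Generator,
    jitter_sd: float | None = None,
    perm: np.ndarray | None = None,
) -> tuple[InputPattern, InputPattern]:
    """Forward/backward ordered single activations of every synaptic contact.

    A fixed random enumeration ``perm`` of the contacts assigns contact with
    order k its slot (k + 1/2) T / N (forward) or the time-reversed slot
    (backward); each activation is jittered by N(0, jitter_sd^2) and clipped
    into [0, T).  Default jitter sd = 2.5 T / N (a few ms), regenerated per
    call so each presentation is a fresh stochastic sweep.
    """
    if perm is None:
        perm = rng.permutation(n_synapses)
    if jitter_sd is None:
        jitter_sd = 2.5 * T / n_synapses
    order = np.empty(n_synapses, dtype=int)
    order[perm] = np.arange(n_synapses)   # order[ch] = rank of channel ch
    slots_fwd = (order + 0.5) * T / n_synapses
    slots_bwd = T - slots_fwd
    eps = 1e-6

    def build(slots):
        if jitter_sd > 0:
            t = slots + rng.normal(0.0, jitter_sd, size=n_synapses)
        else:
            t = slots.copy()
        t = np.clip(t, 0.0, T - eps)
        return InputPattern(
            spikes=[np.array([ti]) for ti in t],
            duration=T,
            channel_mode="per_synapse",
        )

    return build(slots_fwd), build(slots_bwd)


XOR_FEATURES = ("black", "blue", "circle", "diamond")


def gen_xor_patterns(
    rng,
    n_per_feature: int = 25,
    rate_high: float = 40.0,
    rate_low: float = 5.0,
    T: float = 500.0,
) -> list[tuple[InputPattern, bool]]:
    """The 4 feature-binding patterns with their spike/no-spike labels.

    Channels: 4 groups of ``n_per_feature`` afferents coding the features
    black, blue, circle, diamond; each pattern activates one color and one
    shape group at the high rate, the other two at the low rate.  The label
    requires a somatic spike for black&circle and blue&diamond and silence
    for the cross combinations (the XOR structure).
    """
    ss = np.random.SeedSequence(
        rng if isinstance(rng, (int, np.integer)) else rng.integers(2 ** 31)
    )
    seeds = ss.spawn(4)
    combos = [("black", "circle"), ("blue", "diamond"),
              ("black", "diamond"), ("blue", "circle")]
    patterns = []
    for (color, shape), seed in zip(combos, seeds):
        r = np.random.default_rng(seed)
        spikes = []
        for feat in XOR_FEATURES:
            rate = rate_high if feat in (color, shape) else rate_low
            lam = rate * T / 1000.0
            for _ in range(n_per_feature):
                n = r.poisson(lam)
                spikes.append(np.unique(np.sort(r.uniform(0.0, T, size=n))))
        wants_spike = (color, shape) in (("black", "circle"), ("blue", "diamond"))
        patterns.append(
            (InputPattern(spikes=spikes, duration=T), wants_spike)
        )
    return patterns


def binary_reward(soma_spikes, label_wants_spike: bool) -> int:
    """+1 iff the spike/no-spike response matches the label, else -1."""
    spiked = np.asarray(soma_spikes).size >= 1
    return 1 if spiked == bool(label_wants_spike) else -1


def graded_reward(soma_spikes, t_targ: float, T: float) -> float:
    """R = 1 - sum_t g(t - t_targ), g(d) = 1 - exp(-|d| / (T/2)).

    An empty spike train contributes a single term at t = 0.
    """
    t = np.asarray(soma_spikes, dtype=float)
    if t.size == 0:
        t = np.array([0.0])
    g = 1.0 - np.exp(-np.abs(t - t_targ) / (T / 2.0))
    return float(1.0 - g.sum())


def nav_decode_action(soma_spikes, T: float) -> int:
    """First-spike time-bin decoder: 6 bins of T/6, counted outward from the
    center (|3|2|1||1|2|3|), left negative; no spike decodes a stay (0)."""
    t = np.asarray(soma_spikes, dtype=float)
    if t.size == 0:
        return 0
    first = t.min()
    b = min(int(first // (T / 6.0)), 5)
    return b - 3 if b < 3 else b - 2


def nav_step(state: NavState, jump: int) -> tuple[NavState, int]:
    """Apply a jump (mod 7); R=+1 only for a direct jump to the target or for
    staying at the target; else R=-1."""
    if jump not in NAV_JUMPS:
        raise ValueError(f"invalid jump {jump}")
    was = state.position
    new = (was + jump) % NAV_N_POSITIONS
    reward = 1 if ((was != 0 and new == 0) or (was == 0 and jump == 0)) else -1
    return NavState(position=new, step_count=state.step_count + 1), reward


# ---------------------------------------------------------------------------
# task builders used by the runner
# ---------------------------------------------------------------------------

def build_patterns(config: TaskConfig) -> list:
    """Frozen patterns (and labels where applicable) for a task config.

    Returns a list whose structure depends on the task:
      timing_supervised / precise_timing -> [InputPattern]
      spike_nospike -> [(InputPattern, wants_spike)], 2 spike / 2 silence
      xor           -> [(InputPattern, wants_spike)] (4 feature combinations)
      navigation    -> [InputPattern] * 7 (one per circle position)
      direction     -> [] (patterns are redrawn every presentation)
    """
    ss = np.random.SeedSequence(config.seed)
    if config.task_id in ("timing_supervised", "precise_timing"):
        return [
            gen_frozen_poisson(
                config.n_afferents, config.rate_hz, config.T_ms, ss.spawn(1)[0]
            )
        ]
    if config.task_id == "spike_nospike":
        seeds = ss.spawn(config.n_patterns)
        labels = [False, False, True, True]  # 2 silence-class, 2 spike-class
        return [
            (
                gen_frozen_poisson(
                    config.n_afferents, config.rate_hz, config.T_ms, s
                ),
                labels[k % 4],
            )
            for k, s in enumerate(seeds)
        ]
    if config.task_id == "xor":
        return gen_xor_patterns(
            np.random.default_rng(ss), T=config.T_ms
        )
    if config.task_id == "navigation":
        seeds = ss.spawn(NAV_N_POSITIONS)
        return [
            gen_frozen_poisson(config.n_afferents, config.rate_hz, config.T_ms, s)
            for s in seeds
        ]
    if config.task_id == "direction":
        return []
    raise ValueError(config.task_id)
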