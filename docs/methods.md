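# Methods

## The model

`dendrisp` simulates a multi-branch neuron in which each of `n_branches`
(default 20) dendritic branches receives a random half of the afferents
(connection probability `p_connect = 0.5`).  The subthreshold branch voltage
is a weighted sum of normalized PSP kernels,

    u_d(t) = sum_i w_di PSP_i(t),
    eps(t) = Theta(t) (e^(-t/tau_m) - e^(-t/tau_s)) / (tau_m - tau_s),

with tau_m = 10 ms, tau_s = 1.5 ms; eps has unit time-integral, so weights
are dimensionless multipliers.  Branches emit NMDA spikes stochastically at
the saturating rate rho_d(u) = r_D / (1 + e^(-beta_D (u - theta_D)))
(r_D = 5, beta_D = 5, theta_D = 2.4); each trigger produces a square plateau
of amplitude a = 6 for delta = 50 ms, and overlapping plateaus in a branch
extend in time without stacking in amplitude.  The soma attenuates each
branch by alpha = 0.06, sums, and subtracts a reset kernel
kappa0(t) = Theta(t) e^(-t/tau_m) per somatic spike:

    u_s(t) = sum_d alpha (u_d(t) + a NMDA_d(t)) - kappa(t).

Somatic spikes are either imposed (clamped mode, supervised learning) or
drawn from the exponential escape rate rho_s(u) = e^(beta_s (u - theta_s))
(beta_s = 5, theta_s = 2).

### Time discretization and rate units

Simulation uses an Euler grid of dt = 1 ms; every stochastic event is drawn
per bin with probability 1 - exp(-rho dt), so probabilities never exceed
one.  Plateau duration (50 bins) and the PSP rise (1.5 ms) are resolved at
this step.

The time base of the escape rates is not fixed by the rate functions
themselves, so it is a configuration field (`rate_unit`).  The package
default is **per millisecond**.  The alternative per-second reading caps the
dendritic trigger hazard so low (r_D = 5 Hz) that the probability of a
plateau covering any given instant can never exceed
1 - exp(-5 Hz * 50 ms) ~ 0.22, no matter how depolarized the branch is.
Under that reading plateaus stay unreliable forever, the supervised
spike-timing task stalls short of reproducing its three targets, and the
co-aligned, reliable NMDA spikes that the reinforcement tasks converge to
are unreachable.  With per-ms rates the trigger hazard saturates within a
bin and learning can make dendritic events effectively deterministic where
needed.

Initial weights are i.i.d. uniform on [0, w0] and unconstrained afterwards.
w0 is set once so that the naive neuron fires sparsely but not never
(~1-3 somatic spikes per 500 ms stimulus): w0 = 2.7 for per-ms rates
(8.5 under the per-second variant).  At that operating point a trial
carries a handful of NMDA triggers across the tree.

## The plasticity rule

The per-synapse eligibility has a somato-synaptic and a
somato-dendro-synaptic stream,

    e_ss  = (S - rho_s) PSP_i,
    e_sds = (S - rho_sans_d) (Den_d * PSP_i),

where S(t) is the somatic spike train (delta mass 1/dt in its bin),
rho_sans_d = c rho_s(u_s - alpha a NMDA_d) is the somatic rate with branch
d's plateau removed, c = (e^(alpha a beta_s) - 1)/(alpha a beta_s), and
Den_d * PSP_i credits synapse i for plateau initiation: inside a plateau
triggered at t_d it mixes the sampling term
PSP_i(t_d) rho_d'(t_d)/rho_d(t_d) with the windowed integral of
rho_d' PSP_i (approximated by a first-order filter sigma_di with constant
delta_bar = delta/2); outside a plateau only the integral term remains.
The mixing weight is 0.5/0.5 (best-performing equal weighting; `mix` is a
parameter).  Both streams feed a low-pass eligibility trace

    dE/dt = -E/tau_E + a_bar e_sds + e_ss,   a_bar = a/2, tau_E = T/2,

read out at stimulus end.  Supervised updates clamp the soma to the target
train and apply dw = eta E(T); reward-modulated updates run the soma freely
and apply dw = eta (R - R0) E(t_rew) with R0 = 1.

All linear filters (sigma, E, the optional somatic-readout low-pass) are
discretized with exact exponential integrators, so filter fixed points are
reproduced to machine precision at any dt.  Two implementations exist: a
per-bin reference recursion and a closed-form path that reduces the whole
trial to 1-D filters and two matrix products with the PSP matrix (the
low-pass of E is linear, and sigma is separable).  They agree to ~1e-15
relative and the fast path is what the training loops use (~2 ms per trial
at the default problem size).

### Numerical choices

* **Rate cap in the error terms.**  A spike bin carries delta mass 1/dt.
  If rho dt grows beyond 1 during a transiently over-depolarized phase, the
  raw error (S - rho) becomes negative even in bins that did spike; under
  reward modulation with R - R0 < 0 this sign flip turns punishment into
  potentiation and the weights run away (observed before the cap was
  introduced).  The rates entering the eligibilities are therefore capped at
  one expected event per bin (`RATE_CAP_PER_BIN = 1.0`).  The cap is
  inactive in the small-rho-dt regime, where the rule is exactly the
  continuous-time likelihood gradient (verified against a finite-difference
  oracle to <1%).
* **Overflow guard.**  The exponent of rho_s is clipped at 700; the per-bin
  hazard saturates at 1 long before the clip is reached.
* **Reset convention.**  The reset kernel of a spike in bin m acts from bin
  m+1 on; the spike decision in a bin uses the pre-reset voltage of that
  bin.  The same convention is used in clamped trials ("kappa sums over each
  somatic spike", imposed or free).
* **Trigger process during plateaus.**  The NMDA trigger process stays
  active at rate rho_d(u_d) while a plateau is on; new triggers extend the
  plateau ("add in time but not in amplitude") and become the governing
  trigger for the sampling term.
* **sigma update order.**  Within a bin, sigma is updated first and the
  post-update value is used in that bin's eligibility.

## Learning tasks (synthetic data)

All inputs are generated by the package; generators are seed-deterministic
(frozen patterns reproduce byte-identically from their seed).  The
generator defaults are the study conditions:

* **Supervised spike timing**: one frozen Poisson pattern, 100 afferents at
  6 Hz for T = 500 ms; three target somatic spike times (100, 250, 400 ms;
  the target times themselves are a free choice).  3000 clamped
  presentations with one free test trial every 10 (the interleaving period
  is a free choice).  Precision is the SD of spike-minus-nearest-target over
  test trials with the correct spike count.
* **Spike/no-spike classification**: four frozen patterns as above, two
  requiring at least one spike, two requiring silence; binary reward +-1;
  patterns presented round-robin.  "Sustained perfect classification" is 40
  consecutive correct presentations (10 sweeps of the 4 patterns), reported
  at the first presentation of the streak.
* **Direction selectivity**: every realized synaptic contact is its own
  channel and fires exactly once per sweep, in a fixed random enumeration,
  at slot (k + 1/2) T/N forward or its time reversal backward, jittered by
  N(0, (2.5 T/N)^2) fresh on every presentation (the activation noise is a
  free choice; selectivity must be robust to it).
* **Feature binding (XOR)**: 4 populations of 25 afferents code black/blue
  and circle/diamond at 40 Hz (present) or 5 Hz (absent); the two matched
  combinations require a spike, the crossed ones silence.
* **Precise timing with graded reward**: one frozen pattern; reward
  R = 1 - sum_t g(t - 250 ms) with g(d) = 1 - exp(-|d| / (T/2)) and a
  single penalty term at t = 0 when the train is empty.  The printed form
  of g in the source material is dimensionally inconsistent; this bounded
  reading (g(0) = 0, saturating with deviation) is adopted.
* **Navigation**: 7 circle positions, each a frozen pattern; the first
  somatic spike's 83-ms bin, counted outward from the center (|3|2|1||1|2|3|,
  left negative), encodes a jump of up to +-3; no spike means stay.  R = +1
  only for a direct jump to position 0 or for staying there.  Episodes start
  at a uniformly random position and end when the target is reached and held
  once (capped at 50 actions); reward is applied after every action.

What the generators do *not* emulate: trial-to-trial rate modulations,
correlations between afferents, realistic in-vivo background activity, or
conduction delays.  Passing tests therefore demonstrate properties of the
learning rules under frozen/stationary Poisson statistics, not robustness
to those real-data features (spike-time jitter and a low-pass-filtered
somatic readout are available as robustness variants).

## Learning rates

For each task and rule the learning rate is optimized on a factor-1.5
ladder: eta0 is accepted when its performance beats both adjacent values
1.5 eta0 and eta0/1.5 (ties toward the smaller eta; a monotone curve raises
an error after a bounded number of moves).  The defaults shipped in the CLI
were set by this search once per task and are not re-tuned at run time.

## Problem sizes

Default experiment sizes are chosen at desk scale: 3000 presentations for
the supervised task (averaged over 4 independent runs where a run average
is reported), up to 4000 for spike/no-spike classification (10 runs; the
sustained-perfect criterion is typically reached between ~600 and ~1800
presentations), 8000 for graded-reward timing (the spike-time distribution
keeps narrowing slowly afterwards; the half-width is reported as the median
over 5 runs because an occasional run has not concentrated its spiking by
then), and 8000 actions for navigation (8 runs), where the performance
index plateaus.

## Known limitations and observed deviations

* The supervised task converges to very tight near-target spike
  distributions (SD 1-2 ms) but with per-target reliability ~0.8-0.9 and a
  few percent stray spikes; the SD-based precision metric is dominated by
  those strays, so it reports a few ms more than the width of the central
  distribution.
* With per-second rates (`rate_unit='per_s'`) the plateau-reliability
  ceiling described above limits what any plasticity rule can achieve; the
  configuration is retained for comparison, not as a default.
* The reward tasks use R0 = 1, so correct trials never update weights;
  convergence depends on the error-driven drift crossing the spiking
  threshold, which makes presentation counts to criterion heavy-tailed
  across seeds.
* Navigation training plateaus at a performance index of ~0.65-0.75; the
  untrained first-spike policy is close to uniform over actions, so a
  random start reaches the target in ~8-9 actions on average.  The feature
  -binding (XOR) task is learned only partially (2-3 of 4 patterns in most
  runs) even at its ladder-optimal learning rate — failures under intrinsic
  stochasticity are expected for this task — while direction selectivity is
  learned reliably (>0.9 accuracy) at its much larger optimal learning
  rate.
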