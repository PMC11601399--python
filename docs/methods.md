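# Methods

This document specifies the models implemented in `chunkwm`, the
assumptions behind them, every free parameter and its default, and the
numerical and statistical choices in the analysis code.

## 1. Overview

`chunkwm` simulates a prefrontal-cortex / basal-ganglia (PFC-BG) working
memory circuit performing a continuous-report ("color wheel") task, and
asks how a *chunking* layer — a ring attractor that merges a new color
with a nearby maintained color — changes effective memory capacity.

Two model variants are compared throughout:

- **chunk model**: stripe 0 of the PFC is wired to the chunking ring;
  the remaining stripes see the sensory input directly;
- **no-chunk model**: every stripe sees the sensory input.

Both learn, by reinforcement alone, *when* to store into which stripe
(input gating) and *which* stripe to read out at recall (output gating).

## 2. Task

An episode presents `load` store trials followed by one recall probe.
Each store trial binds a continuous color angle (iid uniform on
[0, 2&pi;)) to a discrete orientation drawn without replacement from an
inventory of `n_orientations`. The probe shows one stored orientation;
the network must reproduce its color. During both training and
evaluation the load of each episode is drawn uniformly from
{1..set_size} (`variable_load`), so networks also experience light
episodes.

Colors are encoded as circular Gaussian bumps over a ring of
`ring_size = 20` units with evenly spaced preferred angles and tuning
width 0.7 rad; ~10 units sit above the participation floor of 0.1,
giving a coarse population code. Responses are decoded as the
activity-weighted circular mean; if no unit exceeds the floor the trial
is a **non-response**. Scoring uses the signed shortest-arc error in
degrees; reward is `1 - |error|/90`, clipped to [-1, 1], so a uniform
guesser is reward-neutral in expectation. A non-response is scored by
drawing the error uniformly (chance-level reward), which is what a
guesser would earn.

**Assumption (orientation inventory).** `n_orientations` defaults to
`set_size`: the inventory is exactly the set of roles the network must
learn to bind. Orientation-conditioned gating policies can then allocate
every item deterministically, which is the regime in which a 2-stripe
network can reach 100% dual-stripe occupancy at set size 2.

## 3. Neuron and layer dynamics (`dynamics.py`)

Rate-coded point neurons on a normalized potential scale:

- membrane integration: `C_m dV/dt = ge*gbar_e*(E_e - V) +
  gi*gbar_i*(E_i - V) + g_l*gbar_l*(E_l - V)`, explicit Euler;
- excitatory conductance of a unit = sum over incoming projections of
  `relative_scale * mean(x_i * w_i)` (mean over senders);
- threshold conductance `ge_theta = (gi*gbar_i*(E_i - theta) +
  g_l*gbar_l*(E_l - theta)) / ((theta - E_e)*gbar_e)` — the excitation
  that puts the membrane equilibrium exactly at the firing threshold
  (verified to 1e-9 by a cross-equation oracle in the test suite);
- rate code `y = 1 / (1 + 1/(gamma*[ge - ge_theta]+))`: zero at or below
  threshold, strictly increasing, asymptoting to 1;
- pooled lateral inhibition (FFFB): `gi = Gi*(ff + fb)` with
  feedforward `ff = [mean_net_input - 0.1]+` and feedback `fb`
  leaky-integrating the layer's mean activation with time constant 1.4
  cycles.

Defaults: `E_i = 0.25 < E_l = 0.3 < theta = 0.5 < E_e = 1.0`,
`gamma = 40`, `g_l = 0.1`, all `gbar = 1`, `Gi = 1.9`. Layers settle for
30 cycles with the excitatory drive held fixed; settling is
deterministic and idempotent at the fixed point.

## 4. Circuit (`circuit.py`)

**Stripes.** Each of `n_stripes` PFC stripes has a superficial layer
(transient mirror of its source) and a deep layer implemented as an
idealized latch: an opened input gate copies the source bump in
(renormalized to unit peak), a closed gate leaves the content exactly
unchanged (`maintenance_leak = 1.0`; values < 1 enable decay for
sensitivity analysis). A stripe is *occupied* if any deep unit exceeds
the 0.1 floor.

**Chunking ring.** Receives one-to-one topographic excitation from the
sensory ring (scale `input_scale = 1.0`) and from every occupied deep
stripe (scale `top_down_scale = 0.4` each), then settles under FFFB
inhibition. When a maintained item lies near the input color the
surviving bump is a merged compromise attracted toward it; when the
nearest item is far the ring simply mirrors the input. With the default
constants the attraction follows a rise-and-fall profile over
separation (peaking around 60-80 deg at roughly 15 deg of deviation,
collapsing beyond ~120 deg). These constants were calibrated against
that qualitative merge profile, not fitted to any behavioral target.

**Gating.** Per stripe and per channel (input at store, output at
recall), striatal Go and NoGo weight rows indexed by the discrete
orientation compete: the gate opens iff
`Go - NoGo + N(0, noise_sd=0.1) > 0`, independently per stripe. Opened
occupied stripes at recall are averaged into the response drive; if no
opened stripe is occupied the trial is a non-response. The reported
"output-gated stripes" count is the number of opened gates.

**Report pathways.** Two plastic ring-to-ring mappings: input -> output
(trained on store trials to reproduce the presented color) and
PFC-deep -> output (trained at recall against the true target bump).
Both use a supervised delta rule (`lr_sup = 0.05`), a deliberate
simplification of error-driven cortical learning.

## 5. Reinforcement learning (`learning.py`)

**Critic.** One reward expectation per probe orientation, delta rule
(`lr_v = 0.05`); the reward prediction error on a recall trial is
`delta = r - v[probe]`. The per-state baseline matters: rewards differ
systematically across orientations (merged-chunk recalls earn slightly
less; given-up orientations earn chance), and only a state-conditioned
baseline lets the prediction error vanish at equilibrium instead of
perpetually punishing correct but lower-reward policies.

**Dopamine.** `da = burst_gain*delta` for positive, `dip_gain*delta`
for negative prediction errors (defaults 0.6 / 0.6).

**Opponent eligibility tags.** Every gating competition tags the
*winning* pool of each stripe: the Go synapse (orientation -> stripe)
where the gate opened, the NoGo synapse where it stayed closed. Closed
decisions are tagged at `closed_tag_gain` of the open-decision
increment (rationale: tag strength follows pre x post pool activity,
and a phasically selected Go pool is more active than a tonically
suppressing NoGo pool). Tags decay by 0.7 per trial and reset at
episode boundaries, so input-gating decisions early in an episode carry
exponentially less credit.

**Three-factor update.** At recall, with signed tag `T = tag_Go -
tag_NoGo` per synapse: `dGo = lr_w * da * T`, `dNoGo = -lr_w * da * T`
(`lr_w = 0.2`), weights clipped to [0, w_max = 1]. Bursts reinforce whatever decision
was taken (opening *or* suppressing); dips punish it. Punishing closed
gates after failed recalls is what lets networks escape
"every-gate-closed" local minima, while `closed_tag_gain < 1` keeps
adaptive giving-up partially sticky at overload.

`closed_tag_gain` and `lr_w` were calibrated against two pre-declared
criteria only: (1) training converges at set size 2 within 500 epochs
for both variants (including robustness across seeds), (2) the
qualitative overload phenomena (non-responses and restrained output
gating at set size 4) are present. No behavioral target value was used
in calibration.

## 6. Training and evaluation protocol (`analysis.py`)

Training: 500 epochs x 100 trials by default; each epoch draws fresh
episodes with variable load. All randomness flows from one
`numpy.random.SeedSequence` root per run; identical seeds give
bit-identical runs, and no global state is shared between runs.

Evaluation freezes all weights (exploration noise stays on, as it is
part of the gating mechanism) and runs fresh episodes from a separate
seed.

## 7. Analyses

- **Guess rate**: maximum-likelihood fit of a uniform + von Mises
  mixture to signed errors (L-BFGS-B, multi-start over 9 initial
  points; guess weight bounded to [0,1], concentration to [0.5, 500]).
  Estimator recovery on synthetic mixtures is verified to +/-0.05.
- **Stripe usage / giving up**: per-stripe occupancy after the final
  store trial, measured on maximum-load episodes only; plus the
  proportion of episodes with at least one empty stripe.
- **Out-of-cluster variance (OCV)**: circular standard deviation (in
  degrees) of the non-probed items; errors are binned by OCV to test
  whether chunking helps exactly when the other items cluster.
- **Gating policy**: `alpha_j = [sum_Go_j - sum_NoGo_j]+ /
  (sum_Go_j + sum_NoGo_j)` per stripe, scale-invariant, 0 when both
  sums vanish.
- **Chance recall**: closed form `(n-1)^(N-1) / n^N` for a random
  gating policy with `n` stripes and `N` items (verified against brute
  force enumeration).
- **Dopamine gain sweep**: trains fresh networks on a burst x dip gain
  grid; divergent runs are recorded as NaN rather than dropped.
- **Recency**: mean absolute error by storage-to-probe lag.

## 8. Numerical choices

- Settling holds `ge` fixed (senders are clamped within a trial), so 30
  cycles suffice for the FFFB fixed point at these gains.
- `rate_activation` guards the reciprocal with a floor of 1e-300; the
  layer raises `FloatingPointError` on non-finite activations instead
  of propagating NaNs.
- Circular statistics use resultant-vector math throughout; signed
  errors live in [-180, 180) with +180 folded to -180.
- Weight snapshots are `.npz` archives holding only learned state plus
  the JSON-encoded config; architecture is rebuilt on load.

## 9. Generator realism and limitations

- The task generator is synthetic by design (the reference experiments
  are themselves simulations); colors are uniform and independent, so
  chunkable (close-color) episodes arise by chance rather than by
  design, as in the reference protocol.
- The deep-layer latch is idealized: no drift, no interference between
  stripes; capacity limits arise from gating policy and stripe count,
  not maintenance noise. Precision limits come from the coarse
  population code and the report mappings.
- The BG is reduced to Go/NoGo weight rows per orientation rather than
  a full striatal network; consequently the gating policy is exactly
  orientation-addressable and cannot exploit color similarity.
- The critic is a per-orientation delta rule, not a full PVLV system;
  no temporal-difference chaining across trials within an episode
  (credit for store decisions reaches them through eligibility tags
  instead).
- Scaled-down seed counts (4-8 per condition) are used in the test and
  acceptance protocols for runtime; the headline statistics therefore
  carry stochastic tolerances.
- At high load the model reproduces the qualitative phenomena
  (giving-up, restrained output gating, chunk-stripe preference), but
  point estimates of some published quantities can sit at the edge of
  their stated tolerances; see the acceptance report for measured
  values.
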