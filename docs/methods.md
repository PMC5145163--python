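# Methods

## The model

`symptomnet` treats a mental-disorder syndrome — the motivating case is
major depression with its 14 disaggregated DSM-III-R symptoms — as a
network of binary nodes. Symptom `i` at time `t` is `X_i(t) ∈ {0, 1}`.
The static parameters are a symmetric weight matrix `W` (zero diagonal:
no autocatalytic self-loops) and per-symptom thresholds `τ_i`, the
parameterisation of the Ising model for binary data: positive `w_ij`
makes symptoms `i` and `j` prefer the same state, and negative `τ_i`
makes symptom `i` prefer to stay off.

The dynamics are a stochastic two-stage update. First the **total
activation** each symptom receives:

    A_i(t) = c · Σ_j W_ij X_j(t−1) + S_i(t)

with `c > 0` a global connectivity multiplier (the model's vulnerability
parameter) and `S_i(t)` an external stress input. Then the **activation
probability**:

    P(X_i(t) = 1) = 1 / (1 + exp(b_i − A_i(t)))

and every symptom is resampled from an independent Bernoulli draw with
its own probability (synchronous update). The state readout is the
symptom count `D(t) = Σ_i X_i(t) ∈ [0, J]`.

### The `b` parameter

The simulator's default sets `b_i = |τ_i|` (`b_mode="abs"`). This is
the convention of the source model family this package follows, but it
is worth flagging: for a symptom with `τ_i < 0` (prefers off) it gives
the same activation barrier as a symptom with threshold `−τ_i`, which
inverts the preference direction relative to the standard Ising full
conditional. The conventional choice `b_i = −τ_i` is available as
`b_mode="identity"`; with it (and `c = 1`, no stress) the synchronous
chain's single-site probabilities equal the Ising full conditionals
that the estimator targets. Both modes are first-class; the default
reproduces the reference dynamics.

### Update scheme

The update is synchronous because the activation function indexes all
neighbours at `t−1` with no ordering among nodes. An asynchronous mode
(one uniformly chosen node resampled per step) is provided for
robustness checks; it induces different transient dynamics but the same
qualitative bistability. Bernoulli draws are consumed in fixed node
order 0…J−1 from a single seeded `numpy` generator, so traces are
reproducible bit-for-bit.

### Numerical notes

The logistic is evaluated as `expit(A − b)`, which saturates cleanly to
0.0 / 1.0 for |b − A| up to and beyond 10⁴ instead of overflowing. For
small systems (J ≤ 12) the exact 2^J × 2^J synchronous transition
matrix and its stationary vector are available
(`transition_matrix` / `stationary_distribution`) and serve as the
independent oracle against which long-run simulated frequencies are
checked (total-variation distance below 0.02 at 2×10⁵ steps in the
test suite).

## Network estimation (eLasso)

`estimate_network` implements the nodewise estimator for binary data:
each symptom is regressed on all others by L1-penalised logistic
regression over a descending grid of penalties, and the penalty is
selected per node by the extended BIC,

    EBIC(λ) = −2·loglik + k·log N + 2γ·k·log(J−1),

`k` being the number of nonzero coefficients. Defaults follow the
published implementation of this estimator: `γ = 0.25`, AND-rule
symmetrisation (an undirected edge survives only if both directed
regressions select it; its weight is the mean of the two coefficients),
intercepts unpenalised, and a 100-point log-spaced grid from the
data-driven `λ_max` (the smallest penalty with an all-zero solution,
`max_j |x_jᵀ(y − ȳ)|/N`) down to `0.001·λ_max`. EBIC ties resolve to
the sparser model. The intercept-only model is always included as a
selection candidate with its exact closed-form likelihood, so an empty
neighbourhood can never lose by virtue of being absent from the grid.
The inner convex solve is scikit-learn's liblinear L1 logistic
regression with a large `intercept_scaling` so the intercept penalty is
negligible; estimation needs `N ≥ 10·J` respondents and rejects
constant columns.

## Synthetic data

`random_network` draws networks with Bernoulli(edge density) edges,
uniform positive weights, and uniform thresholds. The defaults — J = 14,
edge density 0.5, weights U(0.3, 1.2), thresholds U(−4, −2) — were
chosen once so that the simulated population is mostly symptom-free
(low prevalence, as in general-population symptom surveys) and the
three reference connectivity regimes show the canonical phenomenology:

- **weak (c = 0.80)**: short symptom excursions (D rarely above 7)
  with frequent spontaneous returns to D = 0;
- **medium (c = 1.10)**: larger but still transient episodes;
- **strong (c = 2.00)**: the system tips into a self-sustaining
  fully-depressed state and stays there.

`sample_ising_exact` enumerates all 2^J configurations of
P(x) ∝ exp(τᵀx + Σ_{i<j} w_ij x_i x_j), normalises (with a max-shift
guard on the exponentials), and draws i.i.d. respondents — feasible up
to J = 20. `sample_ising_gibbs` is the single-site Gibbs alternative
for larger systems (defaults: burn-in 1000 sweeps, thinning 10); its
moments are validated against the exact sampler at small J. The exact
sampler uses `τ` itself, not `|τ|`: the estimation target is the
conventional Ising distribution, and the absolute-value convention is
confined to the simulator.

What the generator does **not** emulate: respondent clustering (e.g.
twin/family structure), item-level measurement error, negative edges
(real estimated networks occasionally have them), and any particular
empirical weight topology such as hubs. Passing recovery tests
therefore shows the estimator is correct under i.i.d. sampling from
its own model class, not that any particular empirical network is
recoverable.

## Stress protocol

The diathesis-stress experiment adds the same scalar stress to every
symptom's activation and sweeps it as a triangular wave: −15 → 15 →
−15 in steps of 0.01 (6000 steps per full cycle), with the network
state carried continuously across reversals. The per-direction
dose-response curve averages D within half-open stress bins of width
0.20 anchored at the sweep minimum; non-overlapping bins were chosen
(rather than overlapping ±0.20 windows) so every step contributes to
exactly one bin and counts conserve the trace length.

For the hysteresis analyses the package runs 8 full cycles (48 000
steps) rather than a single partial pass: the per-bin branch means are
then averages over ~80 visits per direction, which brings the sampling
noise in the area metric well below the coupling-driven signal. The
**hysteresis area** is Σ_bins |mean_D_up − mean_D_down| · bin width over
bins visited in both directions; because the absolute value is taken,
even a memoryless system has a positive expected area (the noise
floor), which is computable in closed form for zero coupling — each
branch mean is an independent average of Binomial-type variables with
per-step variance Σ_i p_i(1−p_i) — and the test suite checks the
measured zero-coupling area against exactly that bound.

The **forbidden zone** is the widest contiguous band of D levels, each
occupied for less than 0.5 % of steps, lying strictly between two
levels above that occupancy threshold. The 0.5 % dwell threshold is a
package default (no reference value exists); it cleanly separates the
bimodal strong-coupling occupancy (band of width ≈ 7–10 between the
healthy and depressed modes) from the unimodal zero-coupling sweep,
which has no interior gap.

## Early warnings

Critical slowing down is quantified as the lag-1 autocorrelation of D
in a sliding window (default 100 steps; the window must exceed the lag
by at least 2). Windows with zero variance — long stretches at D = 0 or
D = J — yield an undefined (NaN) indicator rather than zero.
Transitions are located as crossings of D = J/2 that persist for at
least 10 steps. The rise test compares the mean indicator in a
150-step window ending 5 steps before a transition against a plateau
baseline window (by convention 500–200 steps before the transition,
where fluctuations exist but the tip is not imminent); the window
sizes are package defaults, as no reference values exist. No
detrending is applied by default; a per-window linear detrend is not
currently implemented and variance/skewness indicators are out of
scope.

On the reference strong-connectivity stress runs the indicator rises
before both the up-switch and the down-switch in the large majority of
seeded runs, and the estimator recovers AR(1) autocorrelation
coefficients φ ∈ {0.2, 0.5, 0.8} within 0.05 at window 500 (both
checked in the test suite and recomputed by `scripts/acceptance.py`).

## Problem sizes and determinism

Default experiment sizes: 10 000 steps for unstressed runs, 48 000
steps (8 ramp cycles) for hysteresis measurements, 12 000 steps (2
cycles) for forbidden-zone and early-warning analyses, five seeds per
condition, N = 5000 respondents and J = 6 for estimator-recovery
studies. These are the sizes at which the reported quantities stabilise
to the precision discussed above. All randomness flows through seeded
`numpy` generators; identical configurations and seeds give
byte-identical outputs, including CLI files.

## Known limitations

- Thresholds are constant over time and identical stress hits every
  symptom; per-symptom stress vectors are accepted but untested against
  any reference behaviour.
- The hysteresis area depends on the ramp speed (slower ramps give the
  system more time to escape metastable states, shrinking the loop);
  areas are comparable only across runs with the same schedule.
- A formal cusp-catastrophe likelihood fit is not provided; the package
  quantifies discontinuity and path dependence directly.
- The estimator assumes i.i.d. rows; clustered respondents will make
  EBIC overconfident.
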