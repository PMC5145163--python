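# symptomnet

Symptom networks as stochastic dynamical systems: a simulator and
analysis toolkit for studying how the *connectivity* of a
mental-disorder symptom network shapes vulnerability, tipping points,
hysteresis and early-warning signals — with an eLasso estimator to fit
such networks from binary cross-sectional data.

## The model

A disorder (the motivating case is major depression with its 14
disaggregated DSM-III-R symptoms) is represented as `J` binary nodes
`X_i ∈ {0, 1}` coupled by a symmetric weight matrix `W` (zero diagonal)
with per-symptom thresholds `τ_i`. Each time step, every symptom
receives the **total activation**

    A_i(t) = c · Σ_j W_ij X_j(t−1) + S_i(t)

where `c > 0` scales all couplings (the network's vulnerability) and
`S` is external stress, and then switches on with logistic probability

    P(X_i(t) = 1) = 1 / (1 + e^{b_i − A_i(t)}),    b_i = |τ_i|,

all symptoms being resampled synchronously. The scalar readout is the
symptom count `D(t) = Σ_i X_i(t)`. Weakly connected networks wander
near `D = 0` with brief episodes that resolve spontaneously; strongly
connected networks are bistable — once tipped into the high-`D`
("depressed") state they stay there, and under a slowly ramped stress
they show hysteresis: far more stress relief is needed to leave the
depressed state than was needed to enter it.

Network parameters `(W, τ)` can be estimated from binary respondent ×
symptom data by nodewise L1-regularised logistic regression with EBIC
model selection (the eLasso approach), and the package's synthetic-data
module draws exact samples from a known Ising distribution so that
estimation and every simulation run end-to-end with no external data.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from symptomnet import (
    GeneratorSpec, ModelConfig, random_network, simulate,
    make_ramp_schedule, run_stress_experiment,
    bin_hysteresis_curve, hysteresis_area, forbidden_zone,
)

net = random_network(GeneratorSpec(seed=1))   # 14-symptom synthetic network

for c in (0.80, 1.10, 2.00):
    trace = simulate(net, ModelConfig(connectivity=c, seed=0, n_steps=10_000))
    print(f"c={c:.2f}  mean D={trace.D.mean():5.2f}  max D={trace.D.max():2d}  "
          f"time at D=0: {np.mean(trace.D == 0):.1%}")

schedule = make_ramp_schedule(n_steps=48_000)  # -15 -> 15 -> -15, step 0.01
trace = run_stress_experiment(net, ModelConfig(connectivity=2.0, seed=0,
                                               n_steps=48_000), schedule)
area = hysteresis_area(bin_hysteresis_curve(trace))
print(f"hysteresis area (c=2.00): {area:.2f}")
print(f"forbidden zone (c=2.00): {forbidden_zone(trace)}")
```

Output:

```
c=0.80  mean D= 1.12  max D= 6  time at D=0: 31.6%
c=1.10  mean D= 1.72  max D=10  time at D=0: 21.5%
c=2.00  mean D=12.92  max D=14  time at D=0: 0.0%
hysteresis area (c=2.00): 11.87
forbidden zone (c=2.00): (2, 10)
```

Reading this: under weak connectivity the system spends a third of its
time fully symptom-free and episodes never exceed 6 of 14 symptoms;
under strong connectivity it locks into a nearly fully active state.
The stress ramp on the strong network traces a wide hysteresis loop
(area ≈ 12 symptom·stress units between the ascending and descending
response curves), and symptom counts 2–10 form a "forbidden zone"
occupied less than 0.5 % of the time — the system jumps across them
rather than resting in them.

Estimating a network from data:

```python
from symptomnet import sample_ising_exact, estimate_network

data = sample_ising_exact(net, N=5000, seed=2)   # exact Ising sample
estimated = estimate_network(data)               # eLasso, EBIC gamma = 0.25
```

## Command line

The same workflows are available as subcommands, each writing CSV/JSON
outputs plus a run manifest:

```bash
symptomnet generate --j 14 --seed 1 --network-out net.json --data-out data.csv
symptomnet estimate data.csv --out estimated.json
symptomnet simulate --network net.json --c 0.8 --c 1.1 --c 2.0 --seed 0
symptomnet stress   --network net.json --c 2.0 --steps 48000 --seed 0
```

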