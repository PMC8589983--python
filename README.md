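# adaptconf

Simulation and analysis of a neural-circuit model in which **decision
confidence is computed online by adaptive neurons** monitoring an attractor
decision network.

## The scientific problem

In the random-dot-motion task, a subject reports which of two directions a
noisy stimulus favors, and — in many experiments — how confident they are.
Three behavioral regularities of confidence recur across species:

1. accuracy rises with reported confidence;
2. on correct trials confidence grows with evidence strength (motion
   coherence *c*), while on error trials it falls — the "folded X";
3. at fixed evidence, high-confidence trials are more accurate than
   low-confidence ones.

How a neural circuit could *compute* such a signal during the decision itself
is the question this package addresses.  The model couples the classical
two-pool mean-field attractor decision circuit to one pool of **confidence
neurons** with spike-frequency adaptation.  Decision pools A and B integrate
evidence through slow NMDA gating variables,

```
dS_i/dt = -S_i/τ_NMDA + (1 - S_i) γ r_i ,      r_i = φ(I_syn,i)
I_syn,i = J_ii S_i - J_ij S_j + I_0 + I_ext,i + J_fc r_C + I_noise,i
φ(I)    = (c_E I - I_th) / (1 - exp(-g_E (c_E I - I_th)))
```

with the biased stimulus `I_ext,i = J_ext μ0 (1 ± c/100)`.  A choice is made
when either pool's rate crosses θ = 25 Hz (reaction-time protocol: 200 ms of
spontaneous activity, 1 s of stimulus, trial ends at 1.5 s).

The confidence pool receives the *summed* decision rates and adapts:

```
τ_r dr_C/dt = φ_C(I_syn,C) - r_C          φ_C(I) = max(c_E I - I_th,C, 0.5)
I_syn,C = J_C S_C + J_dc (r_A + r_B) + I_0c - J_a a + I_noise,C
da/dt   = -a/τ_a + A_1 r_C + A_0
```

Because the adaptation current `a` lags the pool's own activity with a slow
time constant (τ_a = 250 ms), the pool effectively differentiates its input:
steep ramps (easy trials) outrun adaptation and leave the confidence rate
high at decision time; shallow ramps (hard trials) let adaptation catch up.
The mean rate over the 10 ms before threshold crossing, **rc**, is the
model's confidence report and reproduces signatures 1–3.  A variant replaces
spike-frequency adaptation with short-term synaptic depression of the
decision→confidence synapses (`dx/dt = (1-x)/τ_d − U_0 x r_in`), showing the
mechanism generalizes.  Noise enters as independent Ornstein–Uhlenbeck
currents per pool.

## Worked example

```python
from adaptconf import (ExperimentPlan, run_experiment,
                       mean_readout_by_coherence, relative_rc, coding_slope)

plan = ExperimentPlan(trials_per_session=120, n_sessions=2, master_seed=7)
table = run_experiment(plan)                      # one row per trial
decided = table[table.choice != "none"]
print(decided.groupby("coherence_pct")[["correct", "decision_time_s", "rc"]]
      .mean().round(3))
slope = coding_slope(relative_rc(mean_readout_by_coherence(table)))
print("coding slope:", round(slope, 3), "Hz per % coherence")
```

prints

```
               correct  decision_time_s      rc
coherence_pct
0.0              0.444            0.770  11.433
3.2              0.775            0.722  10.336
6.4              0.919            0.657  12.963
12.8             1.000            0.543  13.283
25.6             1.000            0.416  14.621
51.2             1.000            0.299  15.919
coding slope: 0.095 Hz per % coherence
```

Accuracy rises from chance at c = 0 toward 100 %, median decision time falls
from ~0.77 s to ~0.30 s, and the confidence readout rc increases with
coherence — the chronometric, psychometric and confidence patterns of the
task (at 240 trials the rc means still carry sampling noise; the default
10 × 500-trial experiment orders all six levels).  The coding slope is the
OLS slope of baseline-subtracted rc on coherence: the confidence pool gains
about 0.1 Hz per percent coherence.

The same interface is available from the shell:

```
adaptconf simulate --trials 500 --sessions 10 --seed 1 --out run/
adaptconf analyze  --input run/trials.csv --figure fig4b --readout rc --out run/
adaptconf sweep    --a0-grid 0.015,0.03,0.045 --a1-grid 0.025,0.05,0.075 \
                   --trials 96 --sessions 1 --seed 1 --out sweep/
```

`simulate` writes the trial table (CSV), a log, and the fully resolved
configuration; a run is reproducible from that file alone.  `analyze`
computes the accuracy-by-confidence, folded-X, or confidence-split
psychometric summaries for any of the four readouts (confidence-pool rate,
r_A + r_B, |r_A − r_B|, total decision input); `sweep` maps the coding slope
over the adaptation parameters (A_0, A_1).

## Layout

- `src/adaptconf/model.py` — the whole implementation, sectioned in the
  order the method runs (parameters → transfer functions → integrator →
  trial protocol → experiments/sweeps → statistics → config/persistence).
- `src/adaptconf/__main__.py` — the CLI.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  decisions, and known limitations.
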