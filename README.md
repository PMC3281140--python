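# balanced-coding

How sensitively does a cortical circuit encode a small modulatory input —
an attentional bias, a top-down signal — and what network operating point
makes that encoding best?  `balanced_coding` implements two models of a
stimulus-selective local circuit and the information-theoretic machinery to
answer that question, reproducing a central result of theoretical
neuroscience: **encoding sensitivity, measured by Fisher information, is
maximal when excitatory and inhibitory synaptic inputs balance**, and the
attention-like reduction of spike-count variability (Fano factor) peaks at
the same place.

The package is a library; its public face is the importable API plus the
narrative scripts in `examples/`.

## Models and measures

**Stochastic binary network** (`balanced_coding.binary`) — N competing
populations of binary neurons with logistic (Glauber) stochastic dynamics;
for symmetric couplings the stationary law is Boltzmann–Gibbs.  The package
provides exact enumeration (≤ 20 neurons), seeded Monte-Carlo sampling, the
mean-field fixed point

&nbsp;&nbsp;&nbsp;&nbsp;m_p = σ(β (w₊ m_p − w_I Σ_q m_q + λ_p)),

population moments (Fano factor 1 − m), the closed-form Fisher information
of the population-1 input

&nbsp;&nbsp;&nbsp;&nbsp;F = N β² m₁(1 − m₁),

exact Fisher information F = β² Var(n₁) on enumerable systems, and the
balance condition: F is maximal over the inhibition level w_I exactly where
the total population-1 input vanishes (m₁ = 1/2).

**Conductance-based spiking network** (`balanced_coding.spiking`) — a fully
connected integrate-and-fire attractor network (800 excitatory + 200
inhibitory at full scale) with AMPA/NMDA/GABA-A synapses, NMDA
magnesium-block voltage dependence, selective excitatory pools under biased
competition, and a fluctuating (Ornstein–Uhlenbeck) external Poisson
background.  Bit-for-bit reproducible given a seed; also the package's
synthetic-data generator (spike rasters, pool currents, trial-structured
counts).

**Fisher-information estimators** (`balanced_coding.estimator`) — the
empirical histogram/finite-difference estimator (centered difference at
bias ± 10 Hz), the Poisson-regime form slope²/mean and the Gaussian-regime
form slope²/variance, count-moment curves, Fano factors, and delimited-text
I/O so the estimator runs on real trial × count tables too.

**Experiments** (`balanced_coding.experiments`) — seed-controlled sweeps
over the inhibition level joining all of the above, with CSV/JSON outputs
and optional figures.

## Worked example

```
$ python examples/binary_balance_sweep.py

3 populations (beta=2, w+=0.5, lambda=1, bias=0.1):
  balance root w_I*        = 0.8333
  argmax Fisher information = 0.8263
  argmax Fano reduction     = 0.8116
  grid step                 = 0.0146

5 populations (beta=2, w+=0.5, lambda=1, bias=0.1):
  balance root w_I*        = 0.5000
  argmax Fisher information = 0.5040
  argmax Fano reduction     = 0.5187
  grid step                 = 0.0146
```

Reading: for 3 (resp. 5) competing populations the excitatory and
inhibitory inputs onto population 1 cancel at w_I* = 0.833 (resp. 0.500) —
the value (w₊/2 + λ)/(P/2) — and the analytic Fisher information of the
population-1 input attains its maximum at that same inhibition level to
within one step of the 100-point grid.  The Fano-factor reduction induced
by a 0.1 bias peaks within a few grid steps of the Fisher peak and
converges onto it as the bias shrinks.

Other walkthroughs: `examples/glauber_vs_enumeration.py` (sampler vs exact
Boltzmann ensemble and the β²·Var identity),
`examples/spiking_single_trial.py` (one simulated trial: rates, currents,
CSV export), `examples/empirical_fisher_from_counts.py` (estimator vs
closed forms on synthetic counts, via the CSV interchange format), and
`examples/spiking_balance_sweep.py` (reduced inhibition sweep of the
spiking model: Fisher peak at the current-balance zero crossing).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the pipeline end to end — the analytic binary sweep (balance root and
both argmaxima), a scaled spiking-network run producing spike counts at
three bias values, and the empirical Fisher estimator on those counts —
printing each stage's numbers and writing the results JSON.  All
randomness derives from `--seed`.
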