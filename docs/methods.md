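# Methods

`balanced_coding` studies one question in two models: how sensitively does a
recurrently connected, stimulus-selective neural population encode a small
modulatory ("top-down", attentional) input, and where — as a function of the
inhibitory coupling strength — is that sensitivity maximal?  The package's
central quantitative claim, verified by its test suite, is that the Fisher
information of the population activity with respect to the modulatory input
peaks where the population's excitatory and inhibitory inputs balance.

## 1. The stochastic binary network

### Model

`n_pops` populations of `pop_size` binary neurons; neuron states S in {0, 1}.
A neuron with total input h is active with the logistic probability

    P(S = 1) = 1 / (1 + exp(-beta * h)),

where beta is an inverse temperature.  Asynchronous (Glauber) single-neuron
updates with symmetric couplings make the stationary law the Boltzmann–Gibbs
distribution P(c) ∝ exp(-beta * E(c)) with

    E(c) = -sum_pairs J_ab S_a S_b - sum_a lambda_a S_a .

Couplings: +w₊/(N−1) between two neurons of the same population (the
"cohesion level", N = `pop_size`) and −w_I/N between any two coupled neurons
under inhibition (the "inhibition level").  The 1/count scaling
(`pair_scaling`) makes the population-level mean-field weights exactly w₊ and
w_I, independent of N.  Self-couplings are excluded.

**Inhibition topology.**  By default inhibition is *global*: it acts within a
population as well as across populations (`inhibit_within=True`), the way a
single shared inhibitory pool acts in the biophysical model.  This is a
genuine modelling decision: with across-population inhibition only, the
differential (winner-take-all) mode is amplified as
1/(1 − beta·m(1−m)·(w₊+w_I)), a symmetry-breaking bifurcation enters the
swept w_I range, and the smooth peak-at-balance structure is destroyed.  The
across-only variant remains available behind the switch.

### Mean field, moments, Fisher information

Factorizing neighbor states by their means gives the fixed-point equations

    m_p = sigma(beta * (w₊ m_p − w_I Σ_q m_q + lambda_p)),   sigma = logistic,

solved by damped fixed-point iteration (damping 0.5, tolerance 1e-10, at most
1e4 iterations; if the damped map oscillates — strong inhibition — the solver
retries deterministically with damping /5 and /25).  Initialization at the
decoupled solution selects the branch continuously connected to the
symmetric state in multistable (high-cohesion) regimes; `init` overrides.

Under the factorized ensemble the summed population activity n_p is a sum of
N conditionally independent Bernoulli(m_p) units:

    <n> = N m,   Var(n) = N m (1 − m),   Fano = 1 − m,

and the Fisher information of the network state with respect to the
population-1 input, evaluated at the fixed point, is

    F = N beta² m₁ (1 − m₁).

F is maximal over w_I exactly where m₁ = 1/2, i.e. where the total
population-1 input vanishes — excitation (recurrent + external) balancing
inhibition.  `balance_condition` finds that root by Brent's method on the
fixed-point input; a second stationary solution (dm₁/dw_I = 0) exists only at
high cohesion and is outside the package's regime.  The *exact* Fisher
information on enumerable systems is beta²·Var(n₁) under the full Boltzmann
ensemble (the energy is linear in lambda₁), and the mean-field formula is
validated against it at weak coupling.

The bias-induced Fano-factor *reduction*, Fano(0) − Fano(bias) = m₁(bias) −
m₁(0), is governed by the true susceptibility and therefore peaks *near* but
not exactly at the Fisher peak; the separation vanishes as the bias goes to
zero.  `verify_fano_fisher_coincidence` locates both maxima by bounded continuous
minimization and checks the separation (≤ 3 steps of a 100-point grid at
bias 0.1) and its shrinkage with bias.

### Default analytic regime

beta = 2, w₊ = 0.5 (low cohesion), lambda = 1 for every population, bias
0.1, populations of 100 neurons, and 3 or 5 populations.  These values are
a package choice (the published values are not recoverable from the source
text); with them the balance roots are (w₊/2 + lambda)/(P/2) = 0.833 (P = 3)
and 0.500 (P = 5), illustrating the predicted scaling with population count.

## 2. The conductance-based spiking network

Leaky integrate-and-fire neurons (800 excitatory, 200 inhibitory at full
scale) with conductance-based AMPA (external and recurrent), NMDA and GABA-A
synapses:

    C dV/dt = −g_L (V − V_L) − g_AMPA s (V − V_E)
              − g_NMDA s_N (V − V_E) / (1 + [Mg] e^{−0.062 V} / 3.57)
              − g_GABA s_G (V − V_I),

with first-order AMPA/GABA gating (decay 2 / 10 ms), second-order NMDA
kinetics (rise 2 ms, decay 100 ms, alpha = 0.5 /ms, saturating open fraction
≤ 1) and the standard magnesium-block factor (0.2801 = [Mg]/3.57 at 1 mM).
Cell parameters (capacitance 0.5/0.2 nF, leak 25/20 nS, rest −70 mV,
threshold −50 mV, reset −55 mV, refractory 1 ms) and peak conductances
follow the published table of this model family.

Architecture: fully connected; excitatory neurons form `n_selective_pools`
selective pools of 80 (default 2 pools — the canonical two-stimulus biased-
competition configuration) plus a non-selective remainder; one global
inhibitory population.  Weights: w₊ = 1.9 within a pool; the depressed
weight w₋ = 1 − f(w₊−1)/(1−f) (f = one pool's fraction of the excitatory
population) between pools and from non-selective onto selective neurons,
keeping the average excitatory efficacy constant; baseline 1 elsewhere;
inhibitory-to-excitatory weight w_I is the swept inhibition level.
Autapses are excluded.

External drive: one equivalent Poisson train per neuron at 2.4 kHz
(800 sources × 3 Hz), shared per pool as a mean-reverting Ornstein–Uhlenbeck
rate (sigma 50 Hz, tau 10 ms, rectified at zero, independent across pools),
plus 120 Hz to every selective pool during the 1000 ms stimulus period
(after 500 ms of stabilization) and a bias rate to pool 1 only.  The bias
may be negative (the centered finite difference at ±10 Hz around zero);
total rates are rectified.  Background, stimulus and OU magnitudes are
package choices where the source text is unreadable.

Integration: exponential Euler (dt default 0.05 ms, must be ≤ 0.1 ms), exact
exponential gating decays, NMDA advanced with its rise variable frozen
within the step, spike test after the full step, immediate reset, refractory
clamp.  The magnesium factor is linearly interpolated from a 0.05 mV table
and small-argument exponentials use a cubic Taylor branch (relative error
< 3e-7); both are deterministic.  A single integer seed drives the OU
process and all Poisson arrivals, making trials bit-for-bit reproducible.
Single-neuron validation routes a constant injected current through the same
kernel and matches the closed-form LIF rate
1/(t_ref + tau_m ln((V_inf−V_r)/(V_inf−V_thr))) to well under 1%.

**Scaling.**  `scale` s < 1 multiplies neuron counts by s and recurrent peak
conductances by 1/s, preserving mean synaptic drive; fluctuations grow as
1/sqrt(s), so a scaled network is noisier than the full one.  Desk-scale
runs use s = 0.25 (250 neurons, selective pools of 20).

### What the generator emulates, and what it does not

The simulator produces trial-structured spike counts and synaptic-current
records of a local circuit under biased competition — the raw material of
the estimator module.  A green test on these data establishes that the
analysis pipeline recovers the model's encoding structure; it does not
establish anything about real recordings (no cell-type diversity, no
conduction delays, no synaptic plasticity, all-to-all connectivity, and a
reduced network whose relative fluctuations exceed the full-scale model's).

## 3. Fisher-information estimation from counts

The observable is the pool-summed spike count n over a 500 ms window of the
stimulus period, over trials.  Estimators:

* **Empirical (the definition).**  Histograms of n at bias ±delta
  (delta = 10 Hz), coarsened to ≤ 30 bins and regularized with a 0.5
  pseudo-count per bin; the score is the centered difference of the two
  log-histograms over 2*delta; F is the expectation of its square under the
  *normalized geometric mean* of the two histograms.  The geometric mean is
  the log-space midpoint — the exact center distribution for
  exponential-family counts.  (The arithmetic mixture, available as
  `reference="midpoint"`, is broader than the center distribution by
  (slope·delta)² and overestimates F by the factor
  1 + (slope·delta)²/variance — +25% already for slope 1 count/Hz,
  sigma 20 counts; this is measurable, not cosmetic.)  Binning matters for
  the same reason in the opposite direction: the plug-in estimator's noise
  bias grows with occupied bins, and unbinned 200-trial histograms over
  several hundred counts were dominated by it.  A trial-resampling bootstrap
  (default 200 replicates) supplies standard errors.
* **Poisson form** slope²/mean and **Gaussian form** slope²/variance, the
  closed forms for the subthreshold (irregular, Poisson-like) and
  suprathreshold (mean-driven, Gaussian-like) regimes; structurally one
  formula, coinciding whenever variance = mean.  Slopes come from the
  centered difference of the mean count over the same ±delta grid.

Counts enter either from the simulator or from delimited text
(trial, count, bias_hz).

## 4. The inhibition-level sweeps

`run_binary_sweep` (fully analytic) tabulates balance residual, Fano factor,
Fano reduction and Fisher information over a w_I grid.  `run_fisher_current_sweep` /
`run_moment_fit_sweep` (spiking) simulate, at every grid point, 200 trials at each bias
in {−10, 0, +10} Hz, and report the empirical Fisher information (with
bootstrap SE), the count moment curve, the two closed forms, and the pool-1
current balance: time-averaged mean synaptic current minus the *threshold
current* g_L (V_thr − V_L) = 0.5 nA — the constant current holding a
leak-only neuron at threshold, an operational definition isolated in
`mean_current_vs_threshold`.  All per-point randomness derives from the
master seed through documented `SeedSequence` spawn keys, so any grid point
reruns identically in isolation.

The desk-scale acceptance grid is 7 points, 0.65–1.55 in steps of 0.15,
chosen once from a coarse pre-scan to center the sweep on the
current-balance transition and to span the high-activity plateau on the left
and network silence on the right; sweeps run at dt = 0.1 ms.  Peak
co-location tolerances are package constants: one grid step for peak
alignment (`PEAK_TOL_STEPS`), three steps of a 100-point grid for the
Fano/Fisher coincidence (`FANO_FISHER_TOL_STEPS`), a 2-SE band and 80%
coverage for the analytic-fit check (`FIT_BAND_SE`, `FIT_FRACTION`).

### Known limitations

* At scale 0.25 the competition transition is abrupt; immediately past it
  the shared background fluctuations are amplified and counts are
  over-dispersed (Fano 2–4), so the Poisson regime is reached only deep in
  the subthreshold range.  The regime checks therefore use the highest grid
  point, and the count distribution at the transition point itself is
  bimodal (attractor switching) — the one place the Gaussian fit is allowed
  to miss.
* The empirical Fisher estimator retains an O(bins/(trials·delta²)) noise
  bias (~5e-4 Hz⁻² at 200 trials); it cancels in peak-location comparisons
  but inflates absolute values in near-silent regimes.
* Mean-field formulas for the binary model are exact only as couplings → 0;
  enumeration comparisons use |w| ≤ ~0.01 for 1e-3 agreement and 5% for
  moderate couplings.
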