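# Methods

`synalign` simulates how multiplicative synaptic normalization, acting
together with temporally local Hebbian plasticity, aligns the strengths
of *parallel synapses* — multiple contacts from the same axonal branch
onto the same dendritic branch. Three models of increasing realism share
one metrics layer. This note records the models, their assumptions, the
parameter choices, and the numerical decisions a maintainer would need.

## Model 1 — the pair-difference (Kesten) process (`synalign.kesten`)

A target neuron receives `n_pairs` (default 100) presynaptic sources,
each making two contacts with real-valued efficacies X¹ᵢ, X²ᵢ,
initialized independently uniform on [0, 1]. Per step:

1. A *potential change* Cᵢ is drawn uniformly on [−c, +c]
   (c = 0.005); positive entries are multiplied by the LTP bias
   (2 for the potentiation-biased condition, 0.5 for the
   depression-biased one). Both members of a pair share the same Cᵢ —
   the contacts are so close that the arriving currents are identical.
2. Each contact transmits independently with probability 1 − f
   (failure probability f = 0.2 by default). The Hebbian change is
   Pʲᵢ = Cᵢ Fʲᵢ: a failed synapse experiences no plasticity.
3. A multiplicative normalization change Sʲᵢ = η(t) Xʲᵢ is applied.
   Under **detailed balance** η(t) = −Σ(P¹+P²)/Σ(X¹+X²), cancelling the
   step's total Hebbian change exactly (the total efficacy is conserved
   to machine precision over the whole run). Under **global balance**
   η(t) ~ Normal(−0.002, 0.001) independent of the step — the empirical
   detailed-balance distribution at bias 2, f = 0.2 (our own runs
   reproduce mean ≈ −0.0020, sd ≈ 0.0007–0.001 without tuning).

The pair difference D = X¹ − X² then obeys the Kesten recursion
D(t+1) = (1 + η)D + C(F¹ − F²), which admits a limiting distribution iff
E[ln(1 + η)] < 0 — to first order, iff E[η] < 0, i.e. iff potentiation
dominates. `limiting_condition` estimates both quantities from a run's
own η samples, so the diagnostic is self-consistent with the process it
judges.

Numerical choices:

* Efficacies are deliberately **not** truncated at zero — this idealized
  model lives on all of ℝ; truncation belongs to Models 2 and 3.
* `n_steps` defaults to 10,000. The contraction rate is |η| ≈ 0.002 per
  step, so the stationary state is reached after a few thousand steps;
  a 10× longer run changes the final distance only within noise.
* The reported "final mean absolute distance" averages the per-step
  ensemble mean of |D| over the last 1% of steps: the process is
  stationary, and a single endpoint is one noisy sample.
* The plateau flag compares consecutive 500-step window means at a 10%
  tolerance. The pair difference decorrelates over ~1/|η| ≈ 500 steps,
  so a 500-step window mean carries on the order of one effective
  sample and fluctuates by a few percent at stationarity; a tolerance
  below that noise floor would never report convergence, while the
  divergent (LTD-biased) regime grows by orders of magnitude and never
  passes.
* Variance of the final distribution is reported both across pairs at
  the last step and across time over the tail window; the two answer
  slightly different questions and neither is privileged.
* One seeded `numpy.random.Generator` (PCG64) per run; draws are
  ordered C → F¹ → F² → η each step, so runs are reproducible and the
  generator is named in every output manifest.

## Model 2 — one neuron, 2000 model synapses (`synalign.single_neuron`)

1000 synapse pairs converge on one neuron. The two members of a pair
share a presynaptic Poisson train (1 Hz); the postsynaptic train is an
*independent* 1 Hz Poisson source. This independence is the point: with
no pre/post correlations, the sign of the plasticity bias is set purely
by the STDP window amplitudes rather than by network effects.

* **STDP**: exponential windows, τ₊ = τ₋ = 20 ms, A₊ = 0.001,
  A₋ = 0.00075 (potentiation-biased) or 0.00125 (depression-biased),
  nearest-neighbor pairing: a postsynaptic spike potentiates each
  synapse against its most recent *transmitted* presynaptic spike; a
  transmitted presynaptic spike depresses against the most recent
  postsynaptic spike. A failed presynaptic spike (probability 0.2)
  causes no plasticity and leaves no eligibility trace. Coincident
  (same-timestep) pairings are skipped — the window is undefined at 0.
* **Units**: weights are kept in volts. Initial weights are uniform on
  [0, 5 mV] and the normalization target is
  W_total = 2 · 1000 · 5 mV · 0.5 = 5 V; the window amplitude
  A₊ = 0.001 is then 1 mV on the same scale. This is the only reading
  under which the stated W_total is dimensionally consistent, and it
  produces alignment on a few-thousand-second timescale.
* **Normalization**: after every timestep in which any plasticity was
  applied, wⱼ ← wⱼ(1 + η_SN(W_total/Σw − 1)) with η_SN = 1
  (instantaneous), pinning Σw = W_total to machine precision. Weights
  are truncated at zero (Dale's law), so the process is only
  approximately a Kesten recursion.
* **Variants** (supplementary mechanisms, behind explicit
  configuration, with defaults chosen as the field-standard forms):
  soft-bound multiplicative STDP (potentiation × (1 − w/w_max),
  depression × w/w_max, w_max = 5 mV); subtractive normalization
  (common additive offset, then truncation); weight-dependent failure
  f(w) = f₀(1 − w/w_max) clipped to [0.05, 0.95] — stronger synapses
  more reliable — with the map injectable.
* **Spike generation**: binned Bernoulli at dt = 0.1 ms, sampled
  exactly through geometric gaps; at 1 Hz the distinction from exact
  Poisson is negligible (p = 10⁻⁴ per bin).
* **Sampling**: summary statistics (mean |Δw|, mean/median pair CV,
  standard errors) default to 10 s intervals; the interval is
  configurable down to the 10 ms used for raw trajectories, at
  proportional cost.
* **Durations**: the default is 10,000 s. The packaged direction-of-
  effect checks use 100 pairs × 6000 s: the depression-biased run has
  an initial transient in which the uniformly initialized weights relax
  toward the stationary weight distribution, transiently lowering the
  mean CV until roughly 3000 s; windows shorter than that can
  misreport the non-convergent regime as converging. Final values are
  averaged over the last 20% of samples.

## Model 3 — paired-synapse recurrent network (`synalign.sorn`)

A self-organizing recurrent network of N_E = 200 excitatory and
N_I = 40 inhibitory binary threshold units, synchronously updated with
Gaussian noise (σ² = 0.05), with *two* parallel excitatory matrices W1,
W2 over the same initial support (fraction p_EE = 0.1 of ordered pairs,
weights uniform, each row of W1+W2 jointly scaled to total 1).
Thresholds start uniform on [0, 1] (excitatory) and [0, 0.5]
(inhibitory); initial activity is Bernoulli at the target rate. Per
step, in order:

1. **State update** x(t+1) = Θ(masked EE drive − W^EI y − T^E + ξ),
   then y(t+1) = Θ(W^IE x(t+1) − T^I + ξ); Θ is strict (> 0). Every
   realized excitatory synapse fails independently with p_fail
   (default 0.2) and is masked out of the drive.
2. **STDP** ΔW = η_STDP(β^½ x(t+1)x(t)ᵀ − β^−½ x(t)x(t+1)ᵀ) applied to
   both matrices independently, restricted to existing synapses whose
   failure draw transmitted this step. β = 1.25 is the
   potentiation-biased condition, β = 1/1.25 the depression-biased one.
   η_STDP = 0.004 and η_inhib = 0.001 are the standard values of the
   model family this network belongs to; they are configurable and
   logged.
3. **iSTDP** ΔW^EI = −η_inhib y(t)(1 − x(t+1)(1 + 1/H_IP)), floored at
   zero: an unanswered inhibitory spike weakens the connection by
   η_inhib, an answered one strengthens it by η_inhib/H_IP. The rule is
   applied to all entries as written; in practice this regrows
   inhibitory connections from zero, and the W^EI support densifies
   over long runs (the model family's original form initializes
   inhibitory connectivity densely, so this is the intended regime).
4. **Joint normalization**: both matrices are rescaled row-wise by
   their combined total, returning every nonempty joint row of W1+W2
   to exactly 1 at η_sn = 1.
5. **Pruning**: entries at or below zero leave the support. With
   additive STDP, one depression (η_STDP β^−½ ≈ 0.0036–0.0045) exceeds
   the structural-plasticity seed weight w_sp = 0.001, so a new synapse
   survives only if potentiated before it is first depressed — this
   interaction sets the effective synapse birth rate.
6. **Structural plasticity**: with probability p_struct = 0.1 per
   matrix per step, one uniformly chosen absent off-diagonal entry is
   created at w_sp = 0.001. The two supports therefore drift apart from
   the initial pairing; pair statistics are computed only where both
   matrices hold a synapse, and the unpaired count is reported.
7. **Intrinsic plasticity** T^E ← T^E + η_IP(x − H_IP), η_IP = 0.01,
   driving every excitatory unit to the target rate H_IP = 0.1.

Failure-mask bookkeeping: each synapse receives at most one failure
draw per step, shared between the activity update and both STDP terms.
Draws cover the presynaptic columns active at t (activity +
potentiation eligibility) and additionally the columns active at t+1
(depression eligibility).

**Connection fraction** is the number of nonzero off-diagonal entries
of the reference matrix W1 over N_E(N_E − 1). Counting a neuron pair as
connected if *either* parallel matrix holds a synapse gives a value
roughly 1.2× larger at equilibrium; this sensitivity measure is exposed
as `final_connection_fraction_union`.

**Engines.** `run_model3` has two interchangeable implementations: the
pure-numpy step functions (the reference, unit-tested directly) and a
numba-compiled kernel an order of magnitude faster (~45 µs/step at
N_E = 200). Both are deterministic given the seed but use different
random streams (PCG64 vs the compiled legacy stream), so they agree
statistically, not trajectory-for-trajectory; a test pins their
agreement on rates, connectivity and pair CV. When normalization is
instantaneous, only rows touched since the last rescale are
renormalized — untouched rows already sum to 1 — which is exact and
keeps the kernel fast; for η_sn < 1 every row is rescaled every step.

**Run lengths.** Connectivity follows the three-phase course of fast
pruning, slow regrowth, and equilibrium between pruning and structural
birth. At the default parameters the connection fraction plateaus by
roughly 2 × 10⁶ steps, and the packaged checks use 2 × 10⁶ steps with
an equilibrium (slope-flatness) flag; the acceptance script uses
5 × 10⁶ for the headline p_fail = 0.2 run and 3 × 10⁶ for the
failure-probability sweep, where the pair CV — which equilibrates much
earlier than the connection fraction — is the reported quantity. At
equilibrium (p_fail = 0.2, potentiation-biased) we find a connection
fraction near 4% and a median pair CV near 0.05; the depression-biased
condition reaches a similar CV with a somewhat sparser connectivity
(near 2.5%), both ending potentiation-dominated (net-positive STDP
change) as the circuit-level mechanism predicts.

## Metrics (`synalign.metrics`)

The pair CV is σ/μ of the two-element sample. With the population σ
(divisor n = 2) this closes to |w1 − w2|/(w1 + w2), is scale-invariant
and bounded by 1; the sample-σ convention (divisor 1) differs by √2 and
is exposed as an option because comparisons against the experimental
0.083 depend on it. Population σ is the default — it is the convention
under which a fully segregated pair has CV exactly 1. Pairs with zero
combined weight are excluded and counted. The CV-vs-size relation is
fitted by ordinary least squares in log-log space (a descriptive fit,
not a maximum-likelihood power-law estimate); constant-CV input is a
degenerate case reported as slope 0, r = 0, p = 1.

## What the simulations do and do not show

All inputs are synthetic by design — the study *is* its simulations,
and every experiment regenerates from printed parameters and a seed.
The models idealize aggressively: identical potential changes within a
pair, failure independent of efficacy (except in the explicit
weight-dependent variant), Poisson activity (Model 2), binary neurons
and discrete time (Model 3). Passing checks therefore demonstrate
properties of the mechanism — that multiplicative normalization plus
potentiation-dominated Hebbian learning aligns parallel synapses — not
quantitative predictions for any particular biological circuit.
Alignment precision under additional biological noise sources
(release-site heterogeneity, receptor counting noise, dendritic
nonlinearity) is outside the models' scope.

## Interface conventions

Every CLI run writes a `manifest.json` (all parameters, seed, generator
name, package version) sufficient to re-run the experiment, next to
tidy CSV summaries. Replicated runs use consecutive seeds and report
mean ± sd time series; a single replicate reports no sd rather than a
fabricated zero. The figure-level conditions map to presets
(`fig1c/fig1d/fig2a/fig2b`, `fig3_ltp/fig3_ltd`, `fig4/fig5/fig6`,
`sm3/sm4/sm5/sm6`) frozen in `synalign.presets`.
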