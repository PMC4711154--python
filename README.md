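# synalign

Simulators and metrics for **parallel-synapse efficacy alignment** —
the observation that multiple synaptic contacts from the same axonal
branch onto the same dendritic branch end up with almost identical
strengths. `synalign` implements the hypothesis that no slow
spine-local averaging is needed for this: the combination of temporally
local Hebbian plasticity (STDP) with **multiplicative synaptic
normalization** aligns parallel synapses whenever learning is
potentiation-dominated.

The package is aimed at computational neuroscientists studying the
interaction of Hebbian and homeostatic plasticity. It contains three
models of increasing realism plus a shared statistics layer:

| module | model |
|---|---|
| `synalign.kesten` | Idealized stochastic process for a pair of efficacies X¹, X². Each step both receive the same potential change C (uniform on [−0.005, 0.005], positive values scaled by an LTP bias), gated by independent transmission failures F ∈ {0,1} (P = C·F), and a multiplicative normalization term S = η·X that balances total Hebbian change either exactly ("detailed balance") or on average ("global balance", η ~ N(−0.002, 0.001)). The pair difference D = X¹ − X² follows a Kesten recursion D(t+1) = (1+η)D(t) + C(F¹−F²), which has a limiting distribution — i.e. the pair aligns — iff E[ln(1+η)] < 0, to first order iff E[η] < 0: **potentiation must dominate**. |
| `synalign.single_neuron` | One neuron, 1000 synapse pairs, independent 1 Hz Poisson pre/post spike trains, exponential nearest-neighbor STDP (τ± = 20 ms, A₊ = 1 mV, A₋ = 0.75 or 1.25 mV), 20% transmission failure, and multiplicative normalization of the summed input to 5 V. Weights are truncated at zero. Alignment (falling pair CV) appears only for the potentiation-biased window. |
| `synalign.sorn` | Self-organizing recurrent network of 200 excitatory + 40 inhibitory binary units with *two* parallel excitatory weight matrices, biased STDP (ratio β), joint row normalization, inhibitory STDP, intrinsic plasticity (target rate 0.1), structural plasticity and synaptic failure. Here recurrent correlations make learning potentiation-dominated in **both** bias directions, so parallel synapses align either way — with median pair CV below the experimentally measured 0.083. |
| `synalign.metrics` | Pair statistics: CV = σ/μ of a weight pair (population-σ convention: \|w1−w2\|/(w1+w2), bounded by 1), alignment summaries, CV-vs-size power-law fits, STDP event counts. |

## Worked example

The reference condition of the stochastic model — 100 pairs, detailed
balance, potentiation twice as strong as depression, 20% failure:

```console
$ synalign kesten --preset fig2a --seed 1 --out runs/ltp
final mean |X1-X2| = 0.0342568 (converged: True, E[ln(1+eta)] = -1.973e-03)
```

The pairs start with a mean absolute distance around 0.5 and contract
to a stationary distance of ≈ 0.034: E[ln(1+η)] < 0, so the Kesten
recursion has a limiting distribution and the pairs align to within a
few percent of their ≈ 1.0 efficacy scale. Reversing the bias
(depression twice as strong) flips the sign of the criterion and the
distance grows without bound:

```console
$ synalign kesten --preset fig2b --seed 1 --n-steps 10000 --out runs/ltd
final mean |X1-X2| = 5596.54 (converged: False, E[ln(1+eta)] = 9.817e-04)
```

The same library calls are available directly:

```python
from synalign import kesten
res = kesten.run(kesten.KestenConfig(ltp_bias=2.0, failure_prob=0.2, seed=1))
res.final_mean_abs_distance        # 0.0342...
kesten.limiting_condition(res.eta) # has_limit=True, estimate=-1.97e-3
```

Other entry points: `synalign neuron --bias ltp|ltd` (single-neuron
model; variants `--stdp multiplicative`, `--norm subtractive`,
`--failure weight_dependent`, `--norm-rate 0.1`), and `synalign sorn
--bias ltp|ltd --pfail 0.2 --steps N --replicates 5` (recurrent
network; presets `fig4`, `fig5`, `fig6`). Every run directory contains
`summary.csv`, final-state tables and a `manifest.json` that fully
specifies the run (parameters, seed, generator); `synalign report DIR`
prints it.

Note that short network runs are far from connectivity equilibrium —
the connection fraction first collapses and then regrows over millions
of steps (see `docs/methods.md` for run-length guidance).

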