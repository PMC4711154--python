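"""Single postsynaptic neuron with parallel synapse pairs (Model 2).

One neuron receives ``n_pairs`` pairs of synapses (2000 by default). The
two members of a pair share one presynaptic Poisson spike train (1 Hz);
the postsynaptic train is an additional independent 1 Hz Poisson source,
which deliberately removes pre/post correlations so that the direction
of the plasticity bias is set purely by the STDP window amplitudes.

Mechanisms per synapse:

* exponential STDP with the nearest-neighbor pairing convention — each
  postsynaptic spike potentiates against the most recent *transmitted*
  presynaptic spike, each transmitted presynaptic spike depresses
  against the most recent postsynaptic spike;
* stochastic transmission failure — a failed presynaptic spike causes
  no plasticity and leaves no eligibility trace;
* multiplicative synaptic normalization of the whole afferent
  population toward a fixed total input ``W_total`` after every
  timestep in which plasticity occurred (instantaneous at rate 1).

Weights are in volts (initial weights uniform on [0, 5 mV]; the window
amplitudes A+ = 1 mV, A- = 0.75 or 1.25 mV) and truncated at zero.
Subtractive normalization, soft-bound multiplicative STDP and
weight-dependent failure are available as variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .metrics import AlignmentSummary

__all__ = [
    "STDPParams",
    "NormalizationParams",
    "FailureModel",
    "SynapseArray",
    "SpikeTrainSet",
    "SpikeEvent",
    "Model2Config",
    "Model2Result",
    "generate_poisson_trains",
    "stdp_increment",
    "process_spike",
    "normalize",
    "run_model2",
]


@dataclass
class STDPParams:
    """Exponential STDP window.

    ``a_plus`` and ``a_minus`` are magnitudes (volts); the depression
    sign is applied by the window itself. ``mode='multiplicative'``
    scales potentiation by (1 - w/w_max) and depression by w/w_max
    (soft bounds).
    """

    a_plus: float = 0.001
    a_minus: float = 0.00075
    tau_plus: float = 20.0  # ms
    tau_minus: float = 20.0  # ms
    mode: str = "additive"

    def __post_init__(self):
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError("mode must be 'additive' or 'multiplicative'")


@dataclass
class NormalizationParams:
    """Homeostatic rescaling of the total afferent weight.

    Multiplicative mode: w <- w * (1 + eta_sn * (W_total/sum(w) - 1));
    at eta_sn = 1 the total returns to W_total exactly. Subtractive
    mode adds a common offset eta_sn*(W_total - sum(w))/n to every
    weight and truncates at zero.
    """

    w_total: float = 5.0  # volts: 2 * 1000 pairs * 5 mV * 0.5
    eta_sn: float = 1.0
    mode: str = "multiplicative"

    def __post_init__(self):
        if self.w_total <= 0:
            raise ValueError("w_total must be positive")
        if not 0.0 < self.eta_sn <= 1.0:
            raise ValueError("eta_sn must lie in (0, 1]")
        if self.mode not in ("multiplicative", "subtractive"):
            raise ValueError("mode must be 'multiplicative' or 'subtractive'")


@dataclass
class FailureModel:
    """Per-spike transmission failure.

    Constant mode fails with fixed probability ``f``. Weight-dependent
    mode maps the current weight to a failure probability; the default
    map f0*(1 - w/w_max), clipped to [0.05, 0.95], makes strong
    synapses more reliable. A custom callable (weights, w_max) ->
    probabilities may be injected.
    """

    mode: str = "constant"
    f: float = 0.2
    weight_dependence: Callable[[np.ndarray, float], np.ndarray] | None = None

    def __post_init__(self):
        if self.mode not in ("constant", "weight_dependent"):
            raise ValueError("mode must be 'constant' or 'weight_dependent'")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")

    def probabilities(self, weights: np.ndarray, w_max: float) -> np.ndarray:
        if self.mode == "constant":
            return np.full_like(weights, self.f, dtype=float)
        fn = self.weight_dependence or _default_weight_dependent_failure
        p = np.asarray(fn(weights, w_max), dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("failure map produced probabilities outside [0, 1]")
        return p


def _default_weight_dependent_failure(weights: np.ndarray, w_max: float) -> np.ndarray:
    return np.clip(0.2 * (1.0 - weights / w_max), 0.05, 0.95)


@dataclass
class SynapseArray:
    """Weights and last-spike bookkeeping for the 2*n_pairs synapses.

    Synapses 2i and 2i+1 form pair i and share presynaptic source i.
    ``last_pre`` records the time (ms) of the last *transmitted*
    presynaptic spike per synapse; ``last_post`` is the single
    postsynaptic train's last spike time. -inf marks "none yet".
    """

    weights: np.ndarray
    last_pre: np.ndarray
    last_post: float = -np.inf

    @classmethod
    def create(cls, n_pairs: int, w_init_max: float, rng: np.random.Generator) -> "SynapseArray":
        n = 2 * n_pairs
        return cls(
            weights=rng.uniform(0.0, w_init_max, n),
            last_pre=np.full(n, -np.inf),
        )

    @property
    def n_pairs(self) -> int:
        return self.weights.size // 2

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self.weights[0::2], self.weights[1::2]


@dataclass
class SpikeTrainSet:
    """Poisson spike trains on the simulation grid (times in ms)."""

    pre_trains: list[np.ndarray]
    post_train: np.ndarray
    duration_s: float
    dt_ms: float


@dataclass(frozen=True)
class SpikeEvent:
    time_ms: float
    kind: str  # "pre" or "post"
    source: int = 0  # presynaptic source index; ignored for post events


def generate_poisson_trains(
    rate_hz: float,
    duration_s: float,
    n_sources: int,
    dt_ms: float,
    rng: np.random.Generator,
) -> SpikeTrainSet:
    """Independent Poisson trains discretized to the simulation grid.

    Each grid bin spikes independently with probability rate*dt
    (binned Bernoulli, sampled exactly via geometric gaps), so at most
    one spike per bin per train.
    """
    if rate_hz < 0:
        raise ValueError("rate must be nonnegative")
    p = rate_hz * dt_ms / 1000.0
    if p > 1.0:
        raise ValueError("rate * dt exceeds one spike per bin")
    n_bins = int(round(duration_s * 1000.0 / dt_ms))
    pre = [_bernoulli_train_bins(p, n_bins, rng) * dt_ms for _ in range(n_sources)]
    post = _bernoulli_train_bins(p, n_bins, rng) * dt_ms
    return SpikeTrainSet(pre_trains=pre, post_train=post, duration_s=duration_s, dt_ms=dt_ms)


def _bernoulli_train_bins(p: float, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Bin indices of a Bernoulli(p) process over n_bins, via geometric gaps."""
    if p == 0.0 or n_bins == 0:
        return np.array([], dtype=np.int64)
    bins: list[np.ndarray] = []
    pos = -1
    # expected count p*n_bins; draw gap batches until past the end
    batch = max(16, int(p * n_bins * 1.2) + 10)
    while pos < n_bins - 1:
        gaps = rng.geometric(p, size=batch)
        idx = pos + np.cumsum(gaps)
        bins.append(idx)
        pos = int(idx[-1])
    all_bins = np.concatenate(bins)
    return all_bins[all_bins < n_bins]


def stdp_increment(
    dt_pair: float,
    params: STDPParams,
    w: float = 0.0,
    w_max: float = 0.005,
) -> float:
    """Weight change for a pre/post spike pairing.

    ``dt_pair`` = t_post - t_pre (ms, nonzero): positive lags
    potentiate with amplitude A+ e^(-dt/tau+), negative lags depress
    with -A- e^(dt/tau-). The multiplicative (soft-bound) variant
    additionally scales potentiation by (1 - w/w_max) and depression by
    w/w_max.
    """
    if dt_pair == 0:
        raise ValueError("dt_pair must be nonzero (coincident spikes are skipped)")
    if dt_pair > 0:
        dw = params.a_plus * np.exp(-dt_pair / params.tau_plus)
        if params.mode == "multiplicative":
            dw *= max(0.0, 1.0 - w / w_max)
    else:
        dw = -params.a_minus * np.exp(dt_pair / params.tau_minus)
        if params.mode == "multiplicative":
            dw *= min(1.0, w / w_max)
    return float(dw)


def process_spike(
    event: SpikeEvent,
    synapses: SynapseArray,
    params: STDPParams,
    failure: FailureModel,
    rng: np.random.Generator,
    w_max: float = 0.005,
) -> np.ndarray:
    """Apply one spike event in time order; returns applied increments.

    A transmitted presynaptic spike (independent failure draw per pair
    member) depresses against the most recent postsynaptic spike and
    updates its eligibility trace; a failed spike does neither. A
    postsynaptic spike potentiates every synapse against its most
    recent transmitted presynaptic spike. Coincident (same-time)
    pairings are skipped. Weights are truncated at zero.
    """
    w = synapses.weights
    applied: list[float] = []
    if event.kind == "pre":
        j0 = 2 * event.source
        for j in (j0, j0 + 1):
            p_fail = failure.probabilities(w[j : j + 1], w_max)[0]
            if rng.random() < p_fail:
                continue  # no plasticity, no trace update
            if np.isfinite(synapses.last_post) and synapses.last_post != event.time_ms:
                dw = stdp_increment(
                    synapses.last_post - event.time_ms, params, w[j], w_max
                )
                w[j] = max(0.0, w[j] + dw)
                applied.append(dw)
            synapses.last_pre[j] = event.time_ms
    elif event.kind == "post":
        eligible = np.isfinite(synapses.last_pre) & (synapses.last_pre != event.time_ms)
        if eligible.any():
            lag = event.time_ms - synapses.last_pre[eligible]
            dw = params.a_plus * np.exp(-lag / params.tau_plus)
            if params.mode == "multiplicative":
                dw *= np.clip(1.0 - w[eligible] / w_max, 0.0, None)
            w[eligible] += dw
            applied.extend(dw.tolist())
        synapses.last_post = event.time_ms
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return np.asarray(applied)


def normalize(synapses: SynapseArray, params: NormalizationParams) -> None:
    """Drive the total afferent weight toward ``w_total`` in place."""
    w = synapses.weights
    total = w.sum()
    if total == 0.0:
        raise RuntimeError("total weight is zero; normalization undefined")
    if params.mode == "multiplicative":
        w *= 1.0 + params.eta_sn * (params.w_total / total - 1.0)
    else:
        w += params.eta_sn * (params.w_total - total) / w.size
        np.maximum(w, 0.0, out=w)


@dataclass
class Model2Config:
    """Full configuration of the single-neuron simulation."""

    n_pairs: int = 1000
    rate_hz: float = 1.0
    duration_s: float = 10_000.0
    dt_ms: float = 0.1
    w_init_max: float = 0.005  # volts (5 mV)
    w_max: float = 0.005
    stdp: STDPParams = field(default_factory=STDPParams)
    normalization: NormalizationParams | None = None
    failure: FailureModel = field(default_factory=FailureModel)
    sample_interval_s: float = 10.0
    seed: int = 0
    store_weights: bool = False

    def __post_init__(self):
        if self.normalization is None:
            # target total: [2 per pair] x [n_pairs] x [max init weight] x 0.5
            self.normalization = NormalizationParams(
                w_total=2 * self.n_pairs * self.w_init_max * 0.5
            )


@dataclass
class Model2Result:
    config: Model2Config
    times_s: np.ndarray
    mean_abs_diff: np.ndarray
    sem_abs_diff: np.ndarray
    mean_cv: np.ndarray
    sem_cv: np.ndarray
    median_cv: np.ndarray
    synapses: SynapseArray
    weight_samples: np.ndarray | None = None
    generator: str = "numpy.random.Generator(PCG64)"

    def final_summary(self) -> AlignmentSummary:
        w1, w2 = self.synapses.pairs()
        return AlignmentSummary.from_pairs(w1, w2, time=float(self.times_s[-1]))


def run_model2(config: Model2Config) -> Model2Result:
    """Simulate the single-neuron model; deterministic given the seed.

    Spike trains are generated up front; events are then replayed in
    time order (presynaptic before postsynaptic within a timestep —
    coincident pairings are skipped either way). Normalization runs
    after every timestep in which any plasticity was applied.
    """
    rng = np.random.default_rng(config.seed)
    syn = SynapseArray.create(config.n_pairs, config.w_init_max, rng)
    normalize(syn, config.normalization)
    trains = generate_poisson_trains(
        config.rate_hz, config.duration_s, config.n_pairs, config.dt_ms, rng
    )

    # flatten to a sorted event table: (time, kind 0=pre/1=post, source)
    times = [t for t in trains.pre_trains] + [trains.post_train]
    kinds = [np.zeros(t.size, dtype=np.int8) for t in trains.pre_trains] + [
        np.ones(trains.post_train.size, dtype=np.int8)
    ]
    srcs = [np.full(t.size, i, dtype=np.int64) for i, t in enumerate(trains.pre_trains)] + [
        np.zeros(trains.post_train.size, dtype=np.int64)
    ]
    ev_t = np.concatenate(times)
    ev_k = np.concatenate(kinds)
    ev_s = np.concatenate(srcs)
    order = np.lexsort((ev_s, ev_k, ev_t))
    ev_t, ev_k, ev_s = ev_t[order], ev_k[order], ev_s[order]

    sample_ms = config.sample_interval_s * 1000.0
    n_samples = int(config.duration_s * 1000.0 / sample_ms) + 1
    times_s = np.empty(n_samples)
    mean_ad = np.empty(n_samples)
    sem_ad = np.empty(n_samples)
    mean_cv = np.empty(n_samples)
    sem_cv = np.empty(n_samples)
    med_cv = np.empty(n_samples)
    snaps = np.empty((n_samples, syn.weights.size)) if config.store_weights else None

    def record(i: int, t_ms: float) -> None:
        w1, w2 = syn.pairs()
        s = AlignmentSummary.from_pairs(w1, w2)
        times_s[i] = t_ms / 1000.0
        mean_ad[i] = s.mean_abs_diff
        sem_ad[i] = s.sem_abs_diff
        mean_cv[i] = s.mean_cv
        sem_cv[i] = s.sem_cv
        med_cv[i] = s.median_cv
        if snaps is not None:
            snaps[i] = syn.weights

    record(0, 0.0)
    next_sample = 1
    i = 0
    n_events = ev_t.size
    while i < n_events:
        t = ev_t[i]
        while next_sample < n_samples and next_sample * sample_ms <= t:
            record(next_sample, next_sample * sample_ms)
            next_sample += 1
        # process all events in this timestep, then normalize once if any
        # plasticity occurred
        changed = False
        while i < n_events and ev_t[i] == t:
            ev = SpikeEvent(
                time_ms=float(t),
                kind="pre" if ev_k[i] == 0 else "post",
                source=int(ev_s[i]),
            )
            inc = process_spike(ev, syn, config.stdp, config.failure, rng, config.w_max)
            changed = changed or inc.size > 0
            i += 1
        if changed:
            normalize(syn, config.normalization)
    while next_sample < n_samples:
        record(next_sample, next_sample * sample_ms)
        next_sample += 1

    return Model2Result(
        config=config,
        times_s=times_s,
        mean_abs_diff=mean_ad,
        sem_abs_diff=sem_ad,
        mean_cv=mean_cv,
        sem_cv=sem_cv,
        median_cv=med_cv,
        synapses=syn,
        weight_samples=snaps,
    )
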