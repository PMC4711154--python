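"""Stochastic pair-difference model of STDP interacting with normalization.

A single neuron receives N presynaptic sources, each making two parallel
contacts with efficacies X^1_i, X^2_i (real-valued; this idealized model
does not truncate at zero). Each step,

* a potential change C_i is drawn uniformly on [-c, +c] per source, and
  all positive entries are multiplied by an LTP bias,
* each contact independently transmits (F=1) or fails (F=0) with failure
  probability f; the Hebbian change is P = C * F,
* a multiplicative normalization term S = eta(t) * X balances the total
  Hebbian change, either exactly each step ("detailed" balance, eta
  computed from the step's own P and X) or on average ("global" balance,
  eta drawn from a matched normal distribution).

The pair difference D_i = X^1_i - X^2_i then follows the Kesten recursion

    D(t+1) = (1 + eta(t)) D(t) + C (F^1 - F^2),

which admits a limiting distribution iff E[ln(1 + eta)] < 0 — to first
order, iff potentiation dominates so that E[eta] < 0. Alignment of the
parallel contacts is convergence of |D| to a narrow stationary
distribution; depression-dominated regimes make |D| grow without bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import AlignmentSummary

__all__ = [
    "KestenConfig",
    "PairEnsemble",
    "KestenStepRecord",
    "KestenResult",
    "LimitingCondition",
    "DegenerateStateError",
    "draw_potential_changes",
    "draw_failures",
    "eta_detailed",
    "eta_global",
    "step",
    "run",
    "limiting_condition",
]


class DegenerateStateError(RuntimeError):
    """Raised when the total efficacy is zero and eta is undefined."""


@dataclass
class KestenConfig:
    """Parameters of the pair-difference simulation.

    Defaults are the reference condition: 100 pairs, 20% failure,
    potentiation twice as strong as depression, potential changes drawn
    uniformly on [-0.005, +0.005], exact (detailed) balance. The global
    balance alternative draws eta ~ Normal(-0.002, 0.001), the empirical
    distribution of the detailed-balance eta in the reference condition.
    """

    n_pairs: int = 100
    failure_prob: float = 0.2
    ltp_bias: float = 2.0
    c_halfwidth: float = 0.005
    balance_mode: str = "detailed"
    global_eta_mean: float = -0.002
    global_eta_sd: float = 0.001
    n_steps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValueError("failure_prob must lie in [0, 1]")
        if self.ltp_bias <= 0:
            raise ValueError("ltp_bias must be positive")
        if self.c_halfwidth <= 0:
            raise ValueError("c_halfwidth must be positive")
        if self.n_pairs < 1 or self.n_steps < 1:
            raise ValueError("n_pairs and n_steps must be >= 1")
        if self.balance_mode not in ("detailed", "global"):
            raise ValueError("balance_mode must be 'detailed' or 'global'")


@dataclass
class PairEnsemble:
    """State of the N parallel efficacy pairs at step t."""

    X1: np.ndarray
    X2: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        if self.X1.shape != self.X2.shape or self.X1.ndim != 1:
            raise ValueError("X1 and X2 must be 1-d arrays of equal length")
        if not (np.isfinite(self.X1).all() and np.isfinite(self.X2).all()):
            raise ValueError("efficacies must be finite")

    @property
    def pair_distance(self) -> np.ndarray:
        return self.X1 - self.X2

    @property
    def total(self) -> float:
        return float(self.X1.sum() + self.X2.sum())


@dataclass
class KestenStepRecord:
    """Everything drawn or derived in one update step.

    The Kesten coefficients are a(t) = 1 + eta and b(t) = C*(F1 - F2);
    P = C*F is the Hebbian change and S = eta*X the normalization change.
    """

    C: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    eta: float
    S1: np.ndarray
    S2: np.ndarray
    total_T: float


def draw_potential_changes(config: KestenConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-source potential changes: uniform on [-c, +c], positive entries
    scaled by the LTP bias."""
    c = rng.uniform(-config.c_halfwidth, config.c_halfwidth, size=config.n_pairs)
    c[c > 0] *= config.ltp_bias
    return c


def draw_failures(f: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Transmission indicators: 1 = transmitted, 0 = failed (prob f)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("failure probability must lie in [0, 1]")
    return (rng.random(n) >= f).astype(np.int8)


def eta_detailed(P1, P2, X1, X2) -> float:
    """Normalization factor that exactly cancels the step's total Hebbian
    change: eta = -sum(P1 + P2) / sum(X1 + X2)."""
    denom = float(np.sum(X1) + np.sum(X2))
    if denom == 0.0:
        raise DegenerateStateError("total efficacy is zero; eta undefined")
    return -float(np.sum(P1) + np.sum(P2)) / denom


def eta_global(config: KestenConfig, rng: np.random.Generator) -> float:
    """Normalization factor drawn independently of the current step."""
    return float(rng.normal(config.global_eta_mean, config.global_eta_sd))


def step(
    ensemble: PairEnsemble, config: KestenConfig, rng: np.random.Generator
) -> tuple[PairEnsemble, KestenStepRecord]:
    """One update X^j <- X^j + P^j + eta*X^j.

    Both members of a pair receive the same C but independent failure
    draws. Draw order is fixed (C, F1, F2, then eta for global balance)
    so runs are bit-reproducible given the seed.
    """
    C = draw_potential_changes(config, rng)
    F1 = draw_failures(config.failure_prob, config.n_pairs, rng)
    F2 = draw_failures(config.failure_prob, config.n_pairs, rng)
    P1 = C * F1
    P2 = C * F2
    if config.balance_mode == "detailed":
        eta = eta_detailed(P1, P2, ensemble.X1, ensemble.X2)
    else:
        eta = eta_global(config, rng)
    S1 = eta * ensemble.X1
    S2 = eta * ensemble.X2
    record = KestenStepRecord(
        C=C, F1=F1, F2=F2, P1=P1, P2=P2, eta=eta, S1=S1, S2=S2,
        total_T=ensemble.total,
    )
    new = PairEnsemble(
        X1=ensemble.X1 + P1 + S1,
        X2=ensemble.X2 + P2 + S2,
        t=ensemble.t + 1,
    )
    return new, record


@dataclass
class KestenResult:
    """Trajectory summaries of one run.

    ``final_mean_abs_distance`` averages the per-step ensemble mean of
    |X1 - X2| over the last 1% of steps (a single noisy endpoint would
    misrepresent a stationary process). Variance of the final pair
    distribution is reported both across pairs at the last step and
    across time over the same tail window.
    """

    config: KestenConfig
    mean_abs_distance: np.ndarray
    eta: np.ndarray
    total_T: np.ndarray
    ensemble: PairEnsemble
    final_mean_abs_distance: float
    final_variance_across_pairs: float
    final_variance_across_time: float
    converged: bool
    generator: str = "numpy.random.Generator(PCG64)"

    def summary(self) -> AlignmentSummary:
        return AlignmentSummary.from_pairs(
            self.ensemble.X1, self.ensemble.X2, time=self.ensemble.t
        )


def _initial_ensemble(config: KestenConfig, rng: np.random.Generator) -> PairEnsemble:
    return PairEnsemble(
        X1=rng.uniform(0.0, 1.0, config.n_pairs),
        X2=rng.uniform(0.0, 1.0, config.n_pairs),
    )


def run(config: KestenConfig, initial: PairEnsemble | None = None) -> KestenResult:
    """Simulate the full pair ensemble for ``config.n_steps`` steps.

    Pairs are independently initialized uniformly on [0, 1] unless an
    initial ensemble is supplied. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ens = initial if initial is not None else _initial_ensemble(config, rng)
    n = config.n_steps
    mean_abs = np.empty(n)
    etas = np.empty(n)
    totals = np.empty(n)
    for i in range(n):
        ens, rec = step(ens, config, rng)
        mean_abs[i] = np.mean(np.abs(ens.pair_distance))
        etas[i] = rec.eta
        totals[i] = ens.total
    tail = max(1, n // 100)
    final_mean = float(mean_abs[-tail:].mean())
    d_final = ens.pair_distance
    return KestenResult(
        config=config,
        mean_abs_distance=mean_abs,
        eta=etas,
        total_T=totals,
        ensemble=ens,
        final_mean_abs_distance=final_mean,
        final_variance_across_pairs=float(np.var(d_final)),
        final_variance_across_time=float(np.var(mean_abs[-tail:])),
        converged=_has_plateaued(mean_abs),
    )


def _has_plateaued(series: np.ndarray, window: int = 500, rel_tol: float = 0.10) -> bool:
    """Relative change of the trailing moving average below tolerance.

    The pair difference decorrelates over ~1/|eta| steps (about 500 in
    the reference condition), so a 500-step window mean carries on the
    order of one effective sample and fluctuates by a few percent at
    stationarity; the tolerance must sit above that noise floor.
    """
    if series.size < 2 * window:
        return False
    recent = series[-window:].mean()
    previous = series[-2 * window : -window].mean()
    if previous == 0.0:
        return recent == 0.0
    return abs(recent - previous) / abs(previous) < rel_tol


@dataclass
class LimitingCondition:
    """Empirical convergence diagnostic for the Kesten recursion."""

    has_limit: bool
    estimate: float  # sample mean of ln(1 + eta)
    first_order: float  # sample mean of eta


def limiting_condition(eta_samples) -> LimitingCondition:
    """Estimate E[ln(1 + eta)] from a run's own eta samples.

    The recursion has a limiting distribution iff this expectation is
    negative; to first order the condition reads E[eta] < 0.
    """
    eta = np.asarray(eta_samples, dtype=float)
    if eta.size < 1:
        raise ValueError("need at least one eta sample")
    if np.any(eta <= -1.0):
        raise ValueError("ln(1 + eta) undefined for eta <= -1")
    estimate = float(np.mean(np.log1p(eta)))
    return LimitingCondition(
        has_limit=estimate < 0.0,
        estimate=estimate,
        first_order=float(eta.mean()),
    )
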