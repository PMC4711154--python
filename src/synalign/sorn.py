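"""Paired-synapse self-organizing recurrent network (Model 3).

A binary-threshold network of N_E excitatory and N_I = 0.2 N_E
inhibitory units. Every connected excitatory pair is linked by *two*
parallel synapses (matrices W1, W2 over the same initial support), and
each excitatory synapse fails independently each step with probability
``p_fail`` — a failed synapse neither contributes to the postsynaptic
drive nor takes part in that step's STDP.

Per step, in order: state update (threshold units with Gaussian noise),
biased STDP on both excitatory matrices (potentiation beta times as
strong as depression), inhibitory STDP balancing E/I drive, joint
multiplicative normalization of each row of W1+W2 to total 1, pruning
of non-positive weights, structural plasticity (random new synapses at
weight w_sp), and intrinsic plasticity driving every excitatory unit's
rate to H_IP.

Unlike the feed-forward models, network correlations feed back on the
plasticity: pruning of post-before-pre synapses plus potentiation of
sequentially firing pairs makes the surviving circuit
potentiation-dominated even when the STDP window favors depression, so
parallel synapses align in both bias conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import AlignmentSummary

__all__ = [
    "SornConfig",
    "SornState",
    "SornWeights",
    "StepFailures",
    "SornResult",
    "initialize",
    "state_update",
    "stdp_update",
    "normalize_paired",
    "istdp_update",
    "structural_plasticity",
    "ip_update",
    "prune",
    "run_model3",
]


@dataclass
class SornConfig:
    """Network and plasticity parameters.

    ``beta`` > 1 biases STDP toward potentiation (potentiation scaled
    by beta^1/2, depression by beta^-1/2, so their ratio is beta); the
    depression-biased condition uses beta = 1/1.25. ``eta_stdp`` and
    ``eta_inhib`` follow the standard SORN values 0.004 and 0.001.
    """

    n_e: int = 200
    n_i: int = 40
    p_ee: float = 0.1
    p_ei: float = 0.2
    noise_var: float = 0.05
    beta: float = 1.25
    eta_stdp: float = 0.004
    eta_sn: float = 1.0
    eta_inhib: float = 0.001
    h_ip: float = 0.1
    eta_ip: float = 0.01
    p_struct: float = 0.1
    w_sp: float = 0.001
    p_fail: float = 0.2
    n_steps: int = 1_000_000
    seed: int = 0
    record_every: int = 1000

    def __post_init__(self):
        for name in ("p_ee", "p_ei", "p_struct", "p_fail", "h_ip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("eta_stdp", "eta_sn", "eta_inhib", "eta_ip", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_var < 0:
            raise ValueError("noise_var must be nonnegative")


@dataclass
class SornState:
    """Binary activities and thresholds at step t."""

    x: np.ndarray  # excitatory activity, shape (n_e,), values {0, 1}
    y: np.ndarray  # inhibitory activity, shape (n_i,)
    T_E: np.ndarray  # plastic excitatory thresholds
    T_I: np.ndarray  # fixed inhibitory thresholds
    t: int = 0


@dataclass
class SornWeights:
    """Dense weight matrices with explicit boolean supports.

    ``W[i, j]`` is the synapse from presynaptic unit j to postsynaptic
    unit i (drive = W @ x). W1/W2 are the parallel excitatory matrices;
    S1/S2 mark their realized synapses. W_EI is inhibitory-to-
    excitatory (plastic via iSTDP), W_IE excitatory-to-inhibitory
    (fixed after initial row scaling).
    """

    W1: np.ndarray
    W2: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray


class StepFailures:
    """One transmission-failure realization per synapse per step.

    Masks are drawn lazily per presynaptic column (a synapse whose
    source is silent transmits nothing and has no STDP event, so its
    draw is never needed) but each synapse gets at most one draw per
    step, shared between the activity update and the STDP eligibility.
    """

    def __init__(self, rng: np.random.Generator, n_e: int, p_fail: float):
        self._rng = rng
        self._n_e = n_e
        self._p = p_fail
        self._col_index = np.full(n_e, -1, dtype=np.int64)
        self._m1 = np.empty((n_e, n_e), dtype=bool)
        self._m2 = np.empty((n_e, n_e), dtype=bool)
        self._n_drawn = 0

    def masks(self, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Transmission masks (True = transmitted) for the given
        presynaptic columns, shape (n_e, len(cols)), one per matrix."""
        idx = self._col_index[cols]
        missing = cols[idx < 0]
        if missing.size:
            k = missing.size
            base = self._n_drawn
            self._m1[:, base : base + k] = self._rng.random((self._n_e, k)) >= self._p
            self._m2[:, base : base + k] = self._rng.random((self._n_e, k)) >= self._p
            self._col_index[missing] = np.arange(base, base + k)
            self._n_drawn = base + k
            idx = self._col_index[cols]
        return self._m1[:, idx], self._m2[:, idx]


def initialize(config: SornConfig, rng: np.random.Generator) -> tuple[SornState, SornWeights]:
    """Random initial state.

    Both excitatory matrices share one random support (fraction p_ee of
    off-diagonal entries) but have independent uniform weights; each
    row of W1+W2 is then jointly scaled to sum 1 so the maximal
    excitatory activation is 1. W_EI (fraction p_ei) and the dense
    W_IE are likewise row-scaled to 1. Thresholds are uniform on [0, 1]
    (excitatory) and [0, 0.5] (inhibitory); initial activity is
    Bernoulli at the target rate H_IP.
    """
    n_e, n_i = config.n_e, config.n_i
    off_diag = ~np.eye(n_e, dtype=bool)
    support = (rng.random((n_e, n_e)) < config.p_ee) & off_diag
    W1 = np.where(support, rng.random((n_e, n_e)), 0.0)
    W2 = np.where(support, rng.random((n_e, n_e)), 0.0)
    _joint_row_scale(W1, W2)

    sup_ei = rng.random((n_e, n_i)) < config.p_ei
    W_EI = np.where(sup_ei, rng.random((n_e, n_i)), 0.0)
    _row_scale(W_EI)
    W_IE = rng.random((n_i, n_e))
    _row_scale(W_IE)

    state = SornState(
        x=(rng.random(n_e) < config.h_ip).astype(np.float64),
        y=np.zeros(n_i),
        T_E=rng.uniform(0.0, 1.0, n_e),
        T_I=rng.uniform(0.0, 0.5, n_i),
    )
    weights = SornWeights(
        W1=W1, W2=W2, S1=support.copy(), S2=support.copy(), W_EI=W_EI, W_IE=W_IE
    )
    return state, weights


def _joint_row_scale(W1: np.ndarray, W2: np.ndarray) -> None:
    rowsum = W1.sum(axis=1) + W2.sum(axis=1)
    nz = rowsum > 0
    W1[nz] /= rowsum[nz, None]
    W2[nz] /= rowsum[nz, None]


def _row_scale(W: np.ndarray) -> None:
    rowsum = W.sum(axis=1)
    nz = rowsum > 0
    W[nz] /= rowsum[nz, None]


def state_update(
    state: SornState,
    weights: SornWeights,
    config: SornConfig,
    rng: np.random.Generator,
) -> tuple[SornState, StepFailures]:
    """Threshold update of both populations with fresh failure masks.

    x(t+1) = Theta(masked EE drive - W_EI y(t) - T_E + noise), then
    y(t+1) = Theta(W_IE x(t+1) - T_I + noise); Theta is strict (> 0).
    Returns the new state and the step's failure draws for reuse by
    the STDP rule.
    """
    fails = StepFailures(rng, config.n_e, config.p_fail)
    active = np.flatnonzero(state.x)
    sigma = float(np.sqrt(config.noise_var))
    drive = np.zeros(config.n_e)
    if active.size:
        m1, m2 = fails.masks(active)
        drive = (weights.W1[:, active] * m1).sum(axis=1) + (
            weights.W2[:, active] * m2
        ).sum(axis=1)
    noise_e = rng.normal(0.0, sigma, config.n_e) if sigma > 0 else 0.0
    arg_e = drive - weights.W_EI @ state.y - state.T_E + noise_e
    x_new = (arg_e > 0).astype(np.float64)
    noise_i = rng.normal(0.0, sigma, config.n_i) if sigma > 0 else 0.0
    arg_i = weights.W_IE @ x_new - state.T_I + noise_i
    y_new = (arg_i > 0).astype(np.float64)
    new_state = SornState(x=x_new, y=y_new, T_E=state.T_E, T_I=state.T_I, t=state.t + 1)
    return new_state, fails


def stdp_update(
    weights: SornWeights,
    x_prev: np.ndarray,
    x_new: np.ndarray,
    fails: StepFailures,
    config: SornConfig,
) -> tuple[int, int, float]:
    """Biased additive STDP on both excitatory matrices.

    dW = eta_stdp * (beta^1/2 x(t+1) x(t)^T - beta^-1/2 x(t) x(t+1)^T),
    applied only to existing synapses whose failure draw transmitted
    this step. Returns (n_potentiating, n_depressing, net weight
    change) over both matrices.
    """
    eta = config.eta_stdp
    sb = float(np.sqrt(config.beta))
    pre_p = np.flatnonzero(x_prev)  # presynaptic fired at t
    post_p = np.flatnonzero(x_new)  # postsynaptic fired at t+1
    n_pot = n_dep = 0
    if pre_p.size and post_p.size:
        m1, m2 = fails.masks(pre_p)
        # potentiation: post fired at t+1, pre at t
        rows = post_p[:, None]
        for W, S, m in ((weights.W1, weights.S1, m1), (weights.W2, weights.S2, m2)):
            elig = S[rows, pre_p] & m[post_p, :]
            W[rows, pre_p] += eta * sb * elig
            n_pot += int(elig.sum())
        # depression: post fired at t, pre at t+1 — same step's draws
        m1d, m2d = fails.masks(post_p)
        rowsd = pre_p[:, None]
        for W, S, m in ((weights.W1, weights.S1, m1d), (weights.W2, weights.S2, m2d)):
            elig = S[rowsd, post_p] & m[pre_p, :]
            W[rowsd, post_p] -= (eta / sb) * elig
            n_dep += int(elig.sum())
    net = eta * (sb * n_pot - n_dep / sb)
    return n_pot, n_dep, float(net)


def normalize_paired(weights: SornWeights, eta_sn: float = 1.0, rows=None) -> None:
    """Scale both excitatory matrices by their joint row totals.

    W_m[i, :] <- W_m[i, :] * (1 + eta_sn * (1/rowsum_i - 1)) with
    rowsum_i = sum_k (W1[i, k] + W2[i, k]); at eta_sn = 1 every
    nonempty joint row returns to total 1 exactly. Empty rows are
    skipped. ``rows`` restricts the rescaling to the given row indices
    (valid at eta_sn = 1, where untouched rows already sum to 1).
    """
    if rows is None:
        rowsum = weights.W1.sum(axis=1) + weights.W2.sum(axis=1)
        factor = np.ones_like(rowsum)
        nz = rowsum != 0
        factor[nz] = 1.0 + eta_sn * (1.0 / rowsum[nz] - 1.0)
        weights.W1 *= factor[:, None]
        weights.W2 *= factor[:, None]
        return
    if rows.size == 0:
        return
    b1 = weights.W1[rows]
    b2 = weights.W2[rows]
    rowsum = b1.sum(axis=1) + b2.sum(axis=1)
    factor = np.ones_like(rowsum)
    nz = rowsum != 0
    factor[nz] = 1.0 + eta_sn * (1.0 / rowsum[nz] - 1.0)
    weights.W1[rows] = b1 * factor[:, None]
    weights.W2[rows] = b2 * factor[:, None]


def istdp_update(
    W_EI: np.ndarray, y_prev: np.ndarray, x_new: np.ndarray, config: SornConfig
) -> None:
    """Inhibitory STDP balancing excitatory and inhibitory drive.

    dW_EI[i, j] = -eta_inhib * y_j(t-1) * (1 - x_i(t) (1 + 1/h_ip)):
    an inhibitory spike not followed by an excitatory one weakens the
    connection by eta_inhib; one that is followed strengthens it by
    eta_inhib / h_ip. Weights are floored at zero.
    """
    yact = np.flatnonzero(y_prev)
    if yact.size == 0:
        return
    delta = -config.eta_inhib * (1.0 - x_new * (1.0 + 1.0 / config.h_ip))
    block = W_EI[:, yact]
    block += delta[:, None]
    np.maximum(block, 0.0, out=block)
    W_EI[:, yact] = block


def structural_plasticity(
    weights: SornWeights, config: SornConfig, rng: np.random.Generator
) -> None:
    """Random synapse creation, each matrix treated independently.

    With probability p_struct per matrix per step, one uniformly chosen
    absent off-diagonal entry is created at weight w_sp. The two
    supports may therefore drift apart from the initial pairing.
    Returns the (matrix, post, pre) coordinates of added synapses.
    """
    n = config.n_e
    added = []
    for m, (W, S) in enumerate(((weights.W1, weights.S1), (weights.W2, weights.S2))):
        if rng.random() >= config.p_struct:
            continue
        if S.sum() >= n * (n - 1):
            continue  # fully connected
        while True:
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            if i != j and not S[i, j]:
                break
        S[i, j] = True
        W[i, j] = config.w_sp
        added.append((m, i, j))
    return added


def ip_update(T_E: np.ndarray, x_new: np.ndarray, config: SornConfig) -> None:
    """Intrinsic plasticity: T_E <- T_E + eta_ip * (x - h_ip), driving
    each excitatory unit's mean rate to h_ip."""
    T_E += config.eta_ip * (x_new - config.h_ip)


def prune(weights: SornWeights, candidates=None) -> int:
    """Remove excitatory synapses with non-positive weight.

    ``candidates`` may restrict the scan to (rows, cols) index blocks
    known to have been depressed this step (only depression can push a
    weight below zero). Returns the number of synapses removed.
    """
    removed = 0
    for k, (W, S) in enumerate(((weights.W1, weights.S1), (weights.W2, weights.S2))):
        if candidates is None:
            dead = S & (W <= 0)
            n = int(dead.sum())
            if n:
                S[dead] = False
                W[dead] = 0.0
            removed += n
        else:
            rows, cols = candidates
            if rows.size == 0 or cols.size == 0:
                continue
            r = rows[:, None]
            sub_w = W[r, cols]
            dead = S[r, cols] & (sub_w <= 0)
            n = int(dead.sum())
            if n:
                sub_s = S[r, cols]
                sub_s[dead] = False
                sub_w[dead] = 0.0
                S[r, cols] = sub_s
                W[r, cols] = sub_w
            removed += n
    return removed


@dataclass
class SornResult:
    """Recorded trajectory and final state of one network run."""

    config: SornConfig
    record_steps: np.ndarray  # steps at which block records close
    connection_fraction: np.ndarray  # of W1 support, per record block
    mean_rate: np.ndarray  # mean excitatory activity per record block
    n_pot: np.ndarray  # per-step potentiating event counts
    n_dep: np.ndarray  # per-step depressing event counts
    net_dw: np.ndarray  # per-step net STDP weight change
    state: SornState
    weights: SornWeights
    generator: str = "numpy.random.Generator(PCG64)"

    def pair_table(self) -> dict[str, np.ndarray]:
        """Parallel-weight pairs where both matrices have a synapse.

        Structurally unpaired synapses (present in only one matrix) are
        excluded; their count is reported under ``n_unpaired``.
        """
        both = self.weights.S1 & self.weights.S2
        i, j = np.nonzero(both)
        w1 = self.weights.W1[i, j]
        w2 = self.weights.W2[i, j]
        denom = w1 + w2
        cv = np.abs(w1 - w2) / denom
        n_unpaired = int((self.weights.S1 ^ self.weights.S2).sum())
        return {
            "post": i,
            "pre": j,
            "w1": w1,
            "w2": w2,
            "mean": denom / 2.0,
            "cv": cv,
            "n_unpaired": n_unpaired,
        }

    def final_summary(self) -> AlignmentSummary:
        table = self.pair_table()
        return AlignmentSummary.from_pairs(table["w1"], table["w2"], time=self.state.t)

    def median_pair_cv(self) -> float:
        cv = self.pair_table()["cv"]
        return float(np.median(cv)) if cv.size else float("nan")

    def final_connection_fraction_union(self) -> float:
        """Connection fraction counting a neuron pair as connected if
        *either* parallel matrix holds a synapse (the recorded
        ``connection_fraction`` uses the reference matrix W1 only;
        this sensitivity measure is always at least as large)."""
        n = self.config.n_e
        return float((self.weights.S1 | self.weights.S2).sum() / (n * (n - 1)))

    def equilibrated(self, window: int | None = None, tol: float = 0.10) -> bool:
        """Connection-fraction drift over the trailing window below
        ``tol`` relative to its mean (slope-flatness check)."""
        cf = self.connection_fraction
        if window is None:
            window = max(2, cf.size // 10)
        if cf.size < 2 * window:
            return False
        recent = cf[-window:].mean()
        previous = cf[-2 * window : -window].mean()
        if previous == 0:
            return recent == 0
        return abs(recent - previous) / abs(previous) < tol


def run_model3(config: SornConfig, engine: str = "auto") -> SornResult:
    """Simulate the full network; deterministic given the seed.

    Per-step order: state update -> STDP -> iSTDP -> joint
    normalization -> pruning -> structural plasticity -> intrinsic
    plasticity. Connection fraction (nonzero off-diagonal entries of
    the reference matrix W1 over n_e*(n_e-1)) and mean excitatory rate
    are recorded every ``record_every`` steps; STDP event counts every
    step.

    ``engine`` selects the implementation: "numpy" runs the step
    functions above; "numba" runs the compiled kernel in
    :mod:`synalign._engine` (same schedule and semantics, different
    random stream, roughly an order of magnitude faster). "auto"
    prefers the compiled kernel when numba is available. Either way the
    run is deterministic given the seed and engine.
    """
    from . import _engine

    if engine == "auto":
        engine = "numba" if _engine.HAVE_NUMBA else "numpy"
    if engine == "numba":
        return _run_model3_compiled(config)
    if engine != "numpy":
        raise ValueError("engine must be 'auto', 'numba' or 'numpy'")
    rng = np.random.default_rng(config.seed)
    state, weights = initialize(config, rng)
    n = config.n_steps
    n_pot = np.zeros(n, dtype=np.int32)
    n_dep = np.zeros(n, dtype=np.int32)
    net_dw = np.zeros(n)
    n_blocks = (n + config.record_every - 1) // config.record_every
    record_steps = np.empty(n_blocks, dtype=np.int64)
    conn_frac = np.empty(n_blocks)
    mean_rate = np.empty(n_blocks)
    denom = config.n_e * (config.n_e - 1)
    rate_acc = 0.0
    block = 0
    instant = config.eta_sn == 1.0
    # rows whose joint sum may differ from 1 (pruned or grown after the
    # last normalization); at eta_sn = 1 only these need rescaling
    row_dirty = np.ones(config.n_e, dtype=bool)
    for t in range(n):
        new_state, fails = state_update(state, weights, config, rng)
        p, d, net = stdp_update(weights, state.x, new_state.x, fails, config)
        n_pot[t], n_dep[t], net_dw[t] = p, d, net
        pre_p = np.flatnonzero(state.x)
        post_p = np.flatnonzero(new_state.x)
        istdp_update(weights.W_EI, state.y, new_state.x, config)
        if instant:
            row_dirty[pre_p] = True
            row_dirty[post_p] = True
            normalize_paired(weights, config.eta_sn, rows=np.flatnonzero(row_dirty))
            row_dirty[:] = False
        else:
            normalize_paired(weights, config.eta_sn)
        removed = prune(weights, candidates=(pre_p, post_p))
        if removed:
            row_dirty[pre_p] = True
        for _, i, _ in structural_plasticity(weights, config, rng):
            row_dirty[i] = True
        ip_update(new_state.T_E, new_state.x, config)
        rate_acc += float(new_state.x.mean())
        state = new_state
        if (t + 1) % config.record_every == 0 or t == n - 1:
            record_steps[block] = t + 1
            conn_frac[block] = weights.S1.sum() / denom
            steps_in_block = config.record_every if (t + 1) % config.record_every == 0 else (t + 1) % config.record_every
            mean_rate[block] = rate_acc / steps_in_block
            rate_acc = 0.0
            block += 1
    return SornResult(
        config=config,
        record_steps=record_steps[:block],
        connection_fraction=conn_frac[:block],
        mean_rate=mean_rate[:block],
        n_pot=n_pot,
        n_dep=n_dep,
        net_dw=net_dw,
        state=state,
        weights=weights,
    )


def _run_model3_compiled(config: SornConfig) -> SornResult:
    """Run via the numba kernel; initialization is shared with the
    numpy engine, the loop RNG is numba's legacy stream."""
    from ._engine import sorn_kernel

    rng = np.random.default_rng(config.seed)
    state, weights = initialize(config, rng)
    n = config.n_steps
    n_pot = np.zeros(n, dtype=np.int32)
    n_dep = np.zeros(n, dtype=np.int32)
    net_dw = np.zeros(n)
    n_blocks = (n + config.record_every - 1) // config.record_every
    record_steps = np.zeros(n_blocks, dtype=np.int64)
    conn_frac = np.zeros(n_blocks)
    mean_rate = np.zeros(n_blocks)
    block, x, y = sorn_kernel(
        weights.W1,
        weights.W2,
        weights.S1,
        weights.S2,
        weights.W_EI,
        weights.W_IE,
        state.T_E,
        state.T_I,
        state.x.astype(np.uint8),
        state.y.astype(np.uint8),
        float(config.beta),
        float(config.eta_stdp),
        float(config.eta_sn),
        float(config.eta_inhib),
        float(config.h_ip),
        float(config.eta_ip),
        float(config.p_struct),
        float(config.w_sp),
        float(config.p_fail),
        float(config.noise_var),
        int(n),
        int(config.record_every),
        int(config.seed) % (2**31),
        n_pot,
        n_dep,
        net_dw,
        record_steps,
        conn_frac,
        mean_rate,
    )
    final_state = SornState(
        x=x.astype(np.float64),
        y=y.astype(np.float64),
        T_E=state.T_E,
        T_I=state.T_I,
        t=n,
    )
    return SornResult(
        config=config,
        record_steps=record_steps[:block],
        connection_fraction=conn_frac[:block],
        mean_rate=mean_rate[:block],
        n_pot=n_pot,
        n_dep=n_dep,
        net_dw=net_dw,
        state=final_state,
        weights=weights,
        generator="numba legacy np.random (compiled engine)",
    )
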