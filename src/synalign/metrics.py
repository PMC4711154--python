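"""Alignment statistics shared by all simulators.

The central quantity is the divergence of a *pair* of parallel synapses —
two contacts from the same presynaptic source onto the same target. Two
conventions exist for the coefficient of variation of a two-element sample
{w1, w2}:

* population sigma (divisor n=2):  CV = |w1 - w2| / (w1 + w2), bounded by 1
* sample sigma (divisor n-1=1):    CV = sqrt(2) |w1 - w2| / (w1 + w2)

The population convention is the default; it is the one under which a
fully segregated pair (w, 0) has CV exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "pair_cv",
    "AlignmentSummary",
    "PowerLawFit",
    "cv_size_fit",
    "stdp_event_counts",
]

_SQRT2 = float(np.sqrt(2.0))


def pair_cv(w1, w2, *, sample: bool = False):
    """Coefficient of variation sigma/mu of a pair of weights.

    Parameters
    ----------
    w1, w2 : float or array
        The two members of each pair. Must satisfy ``w1 + w2 > 0``
        (pairs with zero mean carry no CV; exclude them upstream).
    sample : bool
        Use the sample-sigma convention (divisor n-1) instead of the
        default population sigma (divisor n). The two differ by sqrt(2).

    Returns
    -------
    float or ndarray, scale-invariant and in [0, 1] (population) or
    [0, sqrt(2)] (sample).
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    denom = w1 + w2
    if np.any(denom <= 0):
        raise ValueError("pair_cv requires w1 + w2 > 0 for every pair")
    cv = np.abs(w1 - w2) / denom
    if sample:
        cv = _SQRT2 * cv
    if cv.ndim == 0:
        return float(cv)
    return cv


@dataclass
class AlignmentSummary:
    """Per-pair alignment statistics at one point in time.

    Pairs whose combined weight is zero are excluded from the CV
    statistics (their CV is undefined) and reported in ``n_excluded``.
    """

    per_pair_abs_diff: np.ndarray
    per_pair_cv: np.ndarray
    mean_abs_diff: float
    sem_abs_diff: float
    mean_cv: float
    sem_cv: float
    median_cv: float
    n_pairs: int
    n_excluded: int
    time: float | None = None

    @classmethod
    def from_pairs(
        cls,
        w1,
        w2,
        *,
        time: float | None = None,
        sample: bool = False,
    ) -> "AlignmentSummary":
        w1 = np.asarray(w1, dtype=float)
        w2 = np.asarray(w2, dtype=float)
        if w1.shape != w2.shape:
            raise ValueError("w1 and w2 must have the same shape")
        abs_diff = np.abs(w1 - w2)
        ok = (w1 + w2) > 0
        cv = pair_cv(w1[ok], w2[ok], sample=sample) if ok.any() else np.array([])
        cv = np.atleast_1d(cv)
        return cls(
            per_pair_abs_diff=abs_diff,
            per_pair_cv=cv,
            mean_abs_diff=float(abs_diff.mean()) if abs_diff.size else float("nan"),
            sem_abs_diff=_sem(abs_diff),
            mean_cv=float(cv.mean()) if cv.size else float("nan"),
            sem_cv=_sem(cv),
            median_cv=float(np.median(cv)) if cv.size else float("nan"),
            n_pairs=int(w1.size),
            n_excluded=int((~ok).sum()),
            time=time,
        )


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


@dataclass
class PowerLawFit:
    """Descriptive power law cv = prefactor * size**exponent.

    Fitted by ordinary least squares on log-log transformed data;
    ``correlation_r`` and ``p_value`` refer to the Pearson correlation of
    the transformed variables.
    """

    exponent: float
    prefactor: float
    correlation_r: float
    p_value: float
    n_pairs: int
    n_excluded: int = 0


def cv_size_fit(mean_sizes, cvs) -> PowerLawFit:
    """Fit the dependence of pair CV on pair mean weight.

    Nonpositive sizes or CVs cannot enter the log-log fit; they are
    dropped and counted. At least 3 usable pairs are required.
    """
    sizes = np.asarray(mean_sizes, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if sizes.shape != cvs.shape:
        raise ValueError("mean_sizes and cvs must have the same shape")
    ok = (sizes > 0) & (cvs > 0)
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("need at least 3 pairs with positive size and CV")
    lx, ly = np.log(sizes[ok]), np.log(cvs[ok])
    if np.ptp(ly) == 0.0:
        # constant CV: slope and association are identically zero
        return PowerLawFit(
            exponent=0.0,
            prefactor=float(np.exp(ly[0])),
            correlation_r=0.0,
            p_value=1.0,
            n_pairs=int(ok.sum()),
            n_excluded=n_excluded,
        )
    res = stats.linregress(lx, ly)
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        correlation_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_pairs=int(ok.sum()),
        n_excluded=n_excluded,
    )


def stdp_event_counts(increments_per_step):
    """Tally plasticity events from logged per-step increment arrays.

    Parameters
    ----------
    increments_per_step : iterable of arrays
        For each simulation step, the applied weight increments.

    Returns
    -------
    (n_pot, n_dep, net_change) : three ndarrays over steps — counts of
    strictly positive and strictly negative increments and their sum.
    """
    n_pot, n_dep, net = [], [], []
    for inc in increments_per_step:
        inc = np.asarray(inc, dtype=float)
        n_pot.append(int((inc > 0).sum()))
        n_dep.append(int((inc < 0).sum()))
        net.append(float(inc.sum()) if inc.size else 0.0)
    return np.array(n_pot), np.array(n_dep), np.array(net)
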