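"""Distances and divergences between finite discrete distributions.

All measures operate on :class:`ProbabilityVector` pairs defined on a common
finite sample space ``{0, ..., T}`` and return a :class:`DistanceResult`
carrying the value together with light diagnostics (achieving set, worst
cell).  Conventions for the log-based divergences follow the usual
measure-theoretic limits: ``0 * log(0/x) = 0`` and ``x * log(x/0) = +inf``
for ``x > 0``; infinity is a legitimate return value, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ProbabilityVector",
    "CountVector",
    "DistanceResult",
    "total_variation",
    "tv_set_supremum",
    "hellinger_sq",
    "affinity",
    "matusita",
    "kl_divergence",
    "likelihood_distance",
    "j_divergence",
    "pearson_chisq",
    "symmetric_chisq",
]

_SUM_TOL = 1e-12
_SUBSET_CAP = 20  # 2**20 subsets is the largest enumeration we allow


@dataclass(frozen=True)
class ProbabilityVector:
    """A probability mass function on the finite support ``{0, ..., T}``.

    Entries must be nonnegative and sum to one within ``1e-12``.  Silent
    renormalization is deliberately avoided: pass ``normalize=True`` or use
    :meth:`CountVector.normalize` to normalize explicitly.
    """

    probs: np.ndarray

    def __init__(self, probs, *, normalize: bool = False):
        p = np.asarray(probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probability vector must be a nonempty 1-d array")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        total = p.sum()
        if normalize:
            if total <= 0:
                raise ValueError("cannot normalize a zero vector")
            p = p / total
        elif abs(total - 1.0) > _SUM_TOL:
            raise ValueError(
                f"probabilities sum to {total!r}, not 1 (tolerance {_SUM_TOL})"
            )
        object.__setattr__(self, "probs", p)
        self.probs.setflags(write=False)

    @property
    def support_size(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.probs.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)


@dataclass(frozen=True)
class CountVector:
    """Observed cell counts ``n(t)`` on the finite support ``{0, ..., T}``."""

    counts: np.ndarray

    def __init__(self, counts):
        c = np.asarray(counts)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("count vector must be a nonempty 1-d array")
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be nonnegative integers")
        if c.sum() <= 0:
            raise ValueError("total count must be positive")
        object.__setattr__(self, "counts", c.astype(np.int64))
        self.counts.setflags(write=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalize(self) -> ProbabilityVector:
        """Relative frequencies ``d(t) = n(t) / n``."""
        return ProbabilityVector(self.counts / self.total, normalize=True)


@dataclass
class DistanceResult:
    """A named distance value with optional diagnostics."""

    name: str
    value: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


def _pair(tau, m) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(tau, dtype=float)
    p = np.asarray(m, dtype=float)
    if t.shape != p.shape:
        raise ValueError(
            f"support sizes differ: {t.shape[0]} vs {p.shape[0]}"
        )
    return t, p


def total_variation(tau, m) -> DistanceResult:
    """Total variation distance ``V = 0.5 * sum_t |tau(t) - m(t)|``.

    ``V`` lies in ``[0, 1]`` and equals the largest discrepancy in
    probability assigned to any event; the achieving event
    ``{t : tau(t) > m(t)}`` is reported in ``meta``.
    """
    t, p = _pair(tau, m)
    diff = t - p
    value = 0.5 * np.abs(diff).sum()
    achieving = np.flatnonzero(diff > 0)
    return DistanceResult("tv", float(value), {"achieving_set": achieving})


def tv_set_supremum(tau, m) -> DistanceResult:
    """Brute-force ``sup_A |P_tau(A) - P_m(A)]`` over all subsets of the support.

    Enumerates all ``2**(T+1)`` subsets, so the support is capped at
    20 points; this is an independent oracle for :func:`total_variation`,
    not a production routine.
    """
    t, p = _pair(tau, m)
    k = t.size
    if k > _SUBSET_CAP:
        raise ValueError(f"subset enumeration capped at support {_SUBSET_CAP}")
    diff = t - p
    best = 0.0
    best_set: tuple[int, ...] = ()
    # enumerate subsets in chunks of bitmasks to bound memory
    chunk = 1 << 16
    masks = np.arange(1 << k, dtype=np.uint32)
    bits = np.arange(k, dtype=np.uint32)
    for start in range(0, masks.size, chunk):
        sub = masks[start : start + chunk]
        member = ((sub[:, None] >> bits[None, :]) & 1).astype(float)
        vals = np.abs(member @ diff)
        i = int(np.argmax(vals))
        if vals[i] > best:
            best = float(vals[i])
            best_set = tuple(np.flatnonzero(member[i]).tolist())
    return DistanceResult("tv_set_supremum", best, {"achieving_set": best_set})


def hellinger_sq(tau, m) -> DistanceResult:
    """Squared Hellinger distance ``H^2 = 0.5 * sum (sqrt(tau) - sqrt(m))^2``."""
    t, p = _pair(tau, m)
    value = 0.5 * np.square(np.sqrt(t) - np.sqrt(p)).sum()
    return DistanceResult("hellinger_sq", float(value))


def affinity(tau, m) -> DistanceResult:
    """Affinity ``rho = sum sqrt(tau * m)``; equals ``1 - H^2``."""
    t, p = _pair(tau, m)
    value = np.sqrt(t * p).sum()
    return DistanceResult("affinity", float(value))


def matusita(tau, m) -> DistanceResult:
    """Matusita's distance ``[sum (sqrt(tau) - sqrt(m))^2]^(1/2) = sqrt(2 H^2)``."""
    value = np.sqrt(2.0 * hellinger_sq(tau, m).value)
    return DistanceResult("matusita", float(value))


def _kl_core(front: np.ndarray, back: np.ndarray) -> tuple[float, int | None]:
    """``sum front * log(front / back)`` with measure-theoretic conventions.

    Returns the value and, when finite, the index of the largest term.
    """
    pos = front > 0
    if np.any(back[pos] == 0):
        return np.inf, None
    terms = np.zeros_like(front)
    terms[pos] = front[pos] * np.log(front[pos] / back[pos])
    return float(terms.sum()), int(np.argmax(terms))


def kl_divergence(tau, m) -> DistanceResult:
    """Kullback-Leibler distance ``K2(tau, m) = sum_t m(t) log(m(t) / tau(t))``.

    Note the argument order: the model density sits inside the logarithm's
    numerator.  Cells with ``m(t) = 0`` contribute zero; a cell with
    ``m(t) > 0`` and ``tau(t) = 0`` makes the distance ``+inf``.
    """
    t, p = _pair(tau, m)
    value, worst = _kl_core(p, t)
    return DistanceResult("kl", value, {"worst_cell": worst})


def likelihood_distance(tau, m) -> DistanceResult:
    """Likelihood distance ``lambda2(tau, m) = sum_t tau(t) log(tau(t) / m(t))``.

    This is the Kullback-Leibler distance with its arguments reversed:
    ``lambda2(tau, m) == kl_divergence(m, tau)``.
    """
    t, p = _pair(tau, m)
    value, worst = _kl_core(t, p)
    return DistanceResult("likelihood", value, {"worst_cell": worst})


def j_divergence(tau, m) -> DistanceResult:
    """Symmetric Kullback-Leibler (J) divergence ``K2 + lambda2``."""
    value = kl_divergence(tau, m).value + likelihood_distance(tau, m).value
    return DistanceResult("j", float(value))


def pearson_chisq(tau, m) -> DistanceResult:
    """Pearson chi-squared ``P2(tau, m) = sum_t m(t) (tau(t)/m(t) - 1)^2``.

    Data in a cell with model probability zero makes the distance infinite.
    """
    t, p = _pair(tau, m)
    zero_m = p == 0
    if np.any(t[zero_m] > 0):
        return DistanceResult("pearson_chisq", np.inf, {"worst_cell": None})
    terms = np.zeros_like(t)
    pos = ~zero_m
    terms[pos] = np.square(t[pos] - p[pos]) / p[pos]
    return DistanceResult(
        "pearson_chisq", float(terms.sum()), {"worst_cell": int(np.argmax(terms))}
    )


def symmetric_chisq(tau, m) -> DistanceResult:
    """Symmetric chi-squared ``S2 = sum (tau - m)^2 / (tau/2 + m/2)``.

    Cells where both masses vanish contribute zero (the two distributions
    agree there).
    """
    t, p = _pair(tau, m)
    denom = 0.5 * (t + p)
    pos = denom > 0
    terms = np.zeros_like(t)
    terms[pos] = np.square(t[pos] - p[pos]) / denom[pos]
    return DistanceResult(
        "symmetric_chisq", float(terms.sum()), {"worst_cell": int(np.argmax(terms))}
    )


# registry used by the command-line surface and the self-check suite
MEASURES = {
    "tv": total_variation,
    "hellinger": hellinger_sq,
    "affinity": affinity,
    "matusita": matusita,
    "kl": kl_divergence,
    "lik": likelihood_distance,
    "j": j_divergence,
    "pearson": pearson_chisq,
    "s2": symmetric_chisq,
}
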