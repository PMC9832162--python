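"""Degree distributions and their probability generating functions.

A contact layer is statistically described by the distribution ``P(k)`` of the
number of layer contacts a randomly chosen individual has.  All downstream
machinery (excess-degree distributions, reproduction matrices, percolation
fixed points, mean-field ODEs) consumes only the generating function

    G(x) = sum_k P(k) x^k

and its first two derivatives, so this module is the numerical foundation of
the package.  Each distribution is stored as a finite pmf over ``0..K`` with
``K`` chosen so that the neglected tail mass is below ``tail_tol``; closed
forms are used for the classic families where available and cross-checked
against the truncated sums in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DegreeDistribution",
    "make_degree_distribution",
    "mean_degree",
    "eval_pgf",
]

_FAMILIES = ("regular", "poisson", "geometric", "powerlaw", "empirical")

DEFAULT_TAIL_TOL = 1e-10


class ParameterError(ValueError):
    """Invalid family parameters."""


class ValidationError(ValueError):
    """A supplied pmf violates its invariants."""


@dataclass(frozen=True)
class DegreeDistribution:
    """A degree distribution truncated to a finite support ``0..truncation_K``.

    Attributes
    ----------
    family:
        One of ``regular``, ``poisson``, ``geometric``, ``powerlaw``,
        ``empirical``.
    params:
        Family-specific parameters (e.g. ``{"k": 3}`` or ``{"mean": 2.0}``).
    pmf:
        Probabilities over degrees ``0..truncation_K``; sums to 1 up to the
        recorded ``tail_mass``.
    truncation_K:
        Largest degree retained.
    tail_mass:
        Probability mass discarded by truncation (< ``tail_tol`` requested at
        construction).
    """

    family: str
    params: dict = field(repr=True)
    pmf: np.ndarray = field(repr=False)
    truncation_K: int = 0
    tail_mass: float = 0.0

    def __post_init__(self):
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        if np.any(pmf < 0):
            raise ValidationError("pmf entries must be nonnegative")
        if not (0.0 <= self.tail_mass):
            raise ValidationError("tail_mass must be nonnegative")

    # -- moments ---------------------------------------------------------
    @property
    def mean(self) -> float:
        k = np.arange(self.pmf.size)
        return float(np.dot(k, self.pmf))

    def factorial_moment(self, order: int) -> float:
        """E[k(k-1)...(k-order+1)] from the truncated pmf."""
        k = np.arange(self.pmf.size, dtype=float)
        w = np.ones_like(k)
        for j in range(order):
            w *= k - j
        return float(np.dot(np.clip(w, 0.0, None), self.pmf))

    # -- generating function --------------------------------------------
    def pgf(self, x: float, order: int = 0) -> float:
        """Value or derivative (order <= 2) of G at ``x`` in [0, 1].

        Closed forms are used for regular, Poisson and geometric layers;
        other families differentiate the truncated polynomial.
        """
        if order not in (0, 1, 2):
            raise ValueError("pgf derivatives supported up to order 2 only")
        if self.family == "regular":
            k = int(self.params["k"])
            if order == 0:
                return float(x**k)
            if order == 1:
                return float(k * x ** (k - 1)) if k >= 1 else 0.0
            return float(k * (k - 1) * x ** (k - 2)) if k >= 2 else 0.0
        if self.family == "poisson":
            lam = float(self.params["mean"])
            return float(lam**order * np.exp(-lam * (1.0 - x)))
        if self.family == "geometric":
            # P(k) = (1-a) a^k, k >= 0  =>  G(x) = (1-a)/(1-a x)
            a = float(self.params["a"])
            num = (1.0 - a) * a**order * (2.0 if order == 2 else 1.0)
            return float(num / (1.0 - a * x) ** (order + 1))
        return self._poly_pgf(x, order)

    def _poly_pgf(self, x: float, order: int) -> float:
        p = np.polynomial.Polynomial(self.pmf)
        return float(p.deriv(order)(x)) if order else float(p(x))


def _truncate_by_tail(pmf_fn, cdf_fn, tail_tol: float, k_start: int) -> int:
    """Smallest K with tail mass beyond K below tail_tol."""
    K = max(k_start, 1)
    while 1.0 - cdf_fn(K) >= tail_tol:
        K = int(K * 2)
        if K > 10_000_000:  # pragma: no cover - guards runaway tails
            raise ParameterError("cannot truncate distribution: tail too heavy")
    # binary refine
    lo, hi = k_start, K
    while lo < hi:
        mid = (lo + hi) // 2
        if 1.0 - cdf_fn(mid) < tail_tol:
            hi = mid
        else:
            lo = mid + 1
    return lo


def make_degree_distribution(
    family: str, tail_tol: float = DEFAULT_TAIL_TOL, **params
) -> DegreeDistribution:
    """Construct a truncated degree distribution.

    Parameters
    ----------
    family:
        ``regular`` (param ``k``), ``poisson`` (param ``mean``), ``geometric``
        (param ``a``, pmf ``(1-a) a^k``), ``powerlaw`` (params ``alpha`` and
        hard cutoff ``kmax``, pmf proportional to ``k^-alpha`` on
        ``kmin..kmax``), or ``empirical`` (param ``pmf``).
    tail_tol:
        Largest acceptable truncated tail mass, in ``(0, 1e-4]``.
    """
    if family not in _FAMILIES:
        raise ParameterError(f"unknown family {family!r}; choose from {_FAMILIES}")
    if not (0.0 < tail_tol <= 1e-4):
        raise ParameterError("tail_tol must lie in (0, 1e-4]")

    if family == "regular":
        k = params.get("k")
        if k is None or int(k) != k or k < 0:
            raise ParameterError("regular family needs a nonnegative integer 'k'")
        k = int(k)
        pmf = np.zeros(k + 1)
        pmf[k] = 1.0
        return DegreeDistribution(family, {"k": k}, pmf, k, 0.0)

    if family == "poisson":
        lam = params.get("mean")
        if lam is None or lam <= 0:
            raise ParameterError("poisson family needs 'mean' > 0")
        lam = float(lam)
        dist = stats.poisson(lam)
        K = _truncate_by_tail(dist.pmf, dist.cdf, tail_tol, int(np.ceil(lam)))
        pmf = dist.pmf(np.arange(K + 1))
        return DegreeDistribution(family, {"mean": lam}, pmf, K, float(1.0 - pmf.sum()))

    if family == "geometric":
        a = params.get("a")
        if a is None or not (0.0 < a < 1.0):
            raise ParameterError("geometric family needs 'a' in (0, 1)")
        a = float(a)
        K = int(np.ceil(np.log(tail_tol) / np.log(a))) + 1
        k = np.arange(K + 1)
        pmf = (1.0 - a) * a**k
        return DegreeDistribution(family, {"a": a}, pmf, K, float(1.0 - pmf.sum()))

    if family == "powerlaw":
        alpha = params.get("alpha")
        kmax = params.get("kmax")
        kmin = int(params.get("kmin", 1))
        if alpha is None or alpha <= 1.0:
            raise ParameterError("powerlaw family needs 'alpha' > 1")
        if kmax is None or int(kmax) < kmin:
            raise ParameterError("powerlaw family needs integer 'kmax' >= kmin")
        kmax = int(kmax)
        pmf = np.zeros(kmax + 1)
        k = np.arange(kmin, kmax + 1, dtype=float)
        pmf[kmin:] = k ** (-float(alpha))
        pmf /= pmf.sum()
        return DegreeDistribution(
            family, {"alpha": float(alpha), "kmin": kmin, "kmax": kmax}, pmf, kmax, 0.0
        )

    # empirical
    raw = params.get("pmf")
    if raw is None:
        raise ParameterError("empirical family needs 'pmf'")
    pmf = np.asarray(raw, dtype=float)
    if pmf.ndim != 1 or pmf.size == 0 or np.any(pmf < 0):
        raise ValidationError("empirical pmf must be a nonempty nonnegative vector")
    total = pmf.sum()
    if not (1.0 - tail_tol <= total <= 1.0 + tail_tol):
        raise ValidationError(
            f"empirical pmf sums to {total:.6g}, outside [1-tail_tol, 1+tail_tol]"
        )
    pmf = pmf / total
    K = int(np.max(np.nonzero(pmf)[0])) if np.any(pmf > 0) else 0
    pmf = pmf[: K + 1]
    return DegreeDistribution("empirical", {}, pmf, K, 0.0)


def mean_degree(d: DegreeDistribution) -> float:
    """Average degree G'(1) of a layer."""
    return d.mean


def eval_pgf(d: DegreeDistribution, x: float, order: int = 0) -> float:
    """Order-th derivative (0, 1 or 2) of the layer pgf at ``x`` in [0, 1]."""
    if not (0.0 <= x <= 1.0):
        raise ValueError("pgf evaluation requires x in [0, 1]")
    return d.pgf(x, order)
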