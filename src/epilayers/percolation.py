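"""Late-stage outbreak model: multitype bond percolation on the ensemble.

``q_i`` is the probability that a given layer-``i`` contact never infects the
focal vertex.  Either the edge fails to transmit (prob ``1 - T_i``) or it
would transmit but the contact itself escaped infection, which, conditioning
on the contact's excess degree, averages to ``Gt_i(q)``.  Hence the coupled
fixed-point system

    q_i = 1 - T_i + T_i * Gt_i(q_1, ..., q_n),   i = 1..n,

always solved here by monotone iteration from ``q = 0`` so the *least* fixed
point is selected deterministically.  The probability that a random vertex
escapes the outbreak entirely is then ``P = G(q)``.  The outbreak transition
occurs where the spectral radius of the reproduction matrix crosses 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .gf_core import (
    NetworkEnsemble,
    eval_tilde_G_i,
    excess_joint_pmf,
    r0_layer,
    r_matrix,
)

__all__ = [
    "PercolationSolution",
    "TransitionScanResult",
    "solve_percolation",
    "escape_probability",
    "outbreak_condition",
    "scan_transition",
    "near_critical_slope",
]

NO_OUTBREAK_TOL = 1e-8


class ConvergenceError(RuntimeError):
    def __init__(self, msg, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


class DegenerateExpansionError(ValueError):
    """The near-critical expansion degenerates (vanishing curvature)."""


@dataclass(frozen=True)
class PercolationSolution:
    """Converged fixed point of the escape-probability system."""

    q: np.ndarray = field(repr=True)
    epsilon: np.ndarray = field(repr=False)  # q_i = 1 - T_i * eps_i
    escape_probability: float = 1.0
    converged: bool = True
    iterations: int = 0
    residual: float = 0.0

    @property
    def no_outbreak(self) -> bool:
        return bool(np.max(1.0 - self.q) < NO_OUTBREAK_TOL)


@dataclass(frozen=True)
class TransitionScanResult:
    """Leading-eigenvalue curve along a parametrised path, with crossing."""

    t_grid: np.ndarray = field(repr=False)
    lam: np.ndarray = field(repr=False)
    t_star: float | None = None
    bracket_width: float = 0.0


def _fixed_point_map(e: NetworkEnsemble, q: np.ndarray) -> np.ndarray:
    T = np.asarray(e.T)
    G = np.array([eval_tilde_G_i(e, i, q) for i in range(e.n)])
    return 1.0 - T + T * G


def solve_percolation(
    e: NetworkEnsemble,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    damping: float = 1.0,
) -> PercolationSolution:
    """Iterate the escape-probability system from ``q = 0``.

    The map is componentwise monotone and maps the unit box into itself, so
    iterates from 0 increase to the least fixed point.  ``damping`` < 1
    relaxes the update (automatically applied on detected oscillation, which
    can occur near criticality at finite precision).
    """
    if not (0.0 < tol <= 1e-6):
        raise ValueError("tol must lie in (0, 1e-6]")
    q = np.zeros(e.n)
    alpha = damping
    last_res = np.inf
    for it in range(1, max_iter + 1):
        nxt = _fixed_point_map(e, q)
        res = float(np.max(np.abs(nxt - q)))
        q = (1.0 - alpha) * q + alpha * nxt
        if res < tol:
            T = np.asarray(e.T)
            eps = np.where(T > 0, (1.0 - q) / np.where(T > 0, T, 1.0), 0.0)
            return PercolationSolution(
                q=q,
                epsilon=eps,
                escape_probability=escape_probability(e, q),
                converged=True,
                iterations=it,
                residual=res,
            )
        if res > last_res * (1.0 + 1e-12):
            alpha = max(0.5 * alpha, 0.5)
        last_res = res
    raise ConvergenceError(
        f"percolation fixed point not converged in {max_iter} iterations "
        f"(residual {last_res:.3e})",
        last_iterate=q,
    )


def escape_probability(
    e: NetworkEnsemble,
    q: Sequence[float],
    per_degree: Sequence[int] | None = None,
) -> float:
    """Probability a random vertex (or one of given joint degree) escapes.

    ``P = G(q)``; conditioned on joint degree ``k`` it is ``prod q_i^{k_i}``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("q must lie in [0, 1]^n")
    if per_degree is not None:
        k = np.asarray(per_degree)
        return float(np.prod(q**k))
    return e.eval_G(q)


def outbreak_condition(e: NetworkEnsemble) -> tuple[bool, np.ndarray]:
    """Sufficient condition for a nontrivial fixed point: every layer
    reproduction number exceeds 1."""
    r = np.array([r0_layer(e, i) for i in range(e.n)])
    return bool(np.all(r > 1.0)), r


def scan_transition(
    e_of_t: Callable[[float], NetworkEnsemble],
    t_grid: Sequence[float],
    bracket_tol: float = 1e-6,
) -> TransitionScanResult:
    """Locate where the reproduction-matrix spectral radius crosses 1.

    Evaluates the leading eigenvalue on ``t_grid``; if ``lam - 1`` changes
    sign between neighbours the crossing is bisected to ``bracket_tol``.
    Absence of a crossing is reported, not raised.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a sorted 1-d grid")

    def lam_of(t: float) -> float:
        return r_matrix(e_of_t(t)).leading_eigenvalue

    lam = np.array([lam_of(t) for t in t_grid])
    sign = np.sign(lam - 1.0)
    t_star = None
    width = 0.0
    for a, b, sa, sb in zip(t_grid[:-1], t_grid[1:], sign[:-1], sign[1:]):
        if sa == 0.0:
            t_star, width = float(a), 0.0
            break
        if sa * sb < 0:
            t_star = float(
                optimize.brentq(lambda t: lam_of(t) - 1.0, a, b, xtol=bracket_tol)
            )
            width = bracket_tol
            break
    return TransitionScanResult(t_grid=t_grid, lam=lam, t_star=t_star, bracket_width=width)


def near_critical_slope(e: NetworkEnsemble) -> float:
    """Linear coefficient ``c`` in ``1 - P ~ c (T - T_c)`` just above threshold.

    Single layer only.  With ``T_c = 1 / Gt'(1)`` the expansion of the fixed
    point gives ``c = 2 G'(1) / (Gt''(1) T_c^2)``; the curvature ``Gt''(1)``
    is the second factorial moment of the excess-degree pmf.
    """
    if e.n != 1:
        raise ValueError("near-critical slope implemented for single-layer only")
    d = e.distributions[0]
    excess = excess_joint_pmf(e)
    marg = excess.marginal(0)
    k = np.arange(marg.size, dtype=float)
    gt1 = float(np.dot(k, marg))  # Gt'(1)
    gt2 = float(np.dot(k * (k - 1.0), marg))  # Gt''(1)
    if gt2 <= 0:
        raise DegenerateExpansionError("excess pgf has vanishing curvature at 1")
    Tc = 1.0 / gt1
    return 2.0 * d.mean / (gt2 * Tc**2)
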