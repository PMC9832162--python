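"""Degree-based mean-field SIR and its exact n-dimensional reduction.

Grouping vertices by joint degree ``k = (k_1..k_n)`` and closing moments at
the degree-class level gives the full system

    ds_k/dt = - sum_i beta_i k_i v_i s_k
    dx_k/dt = - gamma x_k + sum_i beta_i k_i v_i s_k
    dr_k/dt = gamma x_k,

where ``v_i`` is the probability that the far end of a random layer-i edge
is infected.  With ``w_i`` the corresponding removed fraction and
``w_i(0) = 0`` the whole hierarchy collapses *exactly* onto n equations

    dw_i/dt = gamma * (1 - w_i - Ht_i(u_1, ..., u_n)),
    u_i = exp(-(beta_i/gamma) w_i),

with the susceptibility-weighted excess pgf ``Ht_i``.  Degree-class
compartments are reconstructed from ``w`` via
``s_k(t) = s_k(0) prod u_i^{k_i}``.  Equilibria solve the fixed-point system
``w_i = 1 - Ht_i(u(w))``; early growth is governed by the ``Ht``-kernel
reproduction matrix built at transmissibilities ``beta_i / gamma``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .gf_core import (
    InitialSusceptibility,
    NetworkEnsemble,
    eval_tilde_H_i,
    layer_excess_pmf,
    r_matrix,
)
from .network_sir import ConvergenceError, DynamicParams

__all__ = [
    "DegreeMFTrajectory",
    "integrate_reduced",
    "mf_equilibrium",
    "early_growth",
    "full_degree_system",
]


class NotDiagonalizableError(np.linalg.LinAlgError):
    def __init__(self, msg, eigenvalues=None):
        super().__init__(msg)
        self.eigenvalues = eigenvalues


class GridTooLargeError(ValueError):
    """Joint-degree reconstruction grid beyond the configured cap."""


@dataclass(frozen=True)
class DegreeMFTrajectory:
    """Time series of the reduced state ``(w, u, v)``.

    ``w[t, i]`` is the removed fraction at the far end of a random layer-i
    edge, nondecreasing in time; ``u = exp(-(beta/gamma) w)`` and
    ``v = 1 - w - Ht(u)`` is the corresponding infected fraction.
    """

    t: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.w.shape[1]

    def final_w(self) -> np.ndarray:
        return self.w[-1]


def _ht_vector(
    e: NetworkEnsemble, s0: InitialSusceptibility, u: np.ndarray
) -> np.ndarray:
    return np.array([eval_tilde_H_i(e, s0, i, u) for i in range(e.n)])


def _w_rhs(e, p, s0):
    beta = np.asarray(p.beta)
    gamma = p.gamma

    def rhs(_t, w):
        w = np.clip(w, 0.0, 1.0)
        u = np.minimum(np.exp(-(beta / gamma) * w), 1.0)
        return gamma * (1.0 - w - _ht_vector(e, s0, u))

    return rhs


def integrate_reduced(
    e: NetworkEnsemble,
    p: DynamicParams,
    s0: InitialSusceptibility,
    t_end: float,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    n_eval: int = 401,
) -> DegreeMFTrajectory:
    """Integrate the n-dimensional ``w`` system from ``w(0) = 0``.

    The ``w`` coordinates avoid the logarithmic singularity of the
    equivalent ``u`` system at ``u -> 0+``; ``u`` and ``v`` are derived.
    """
    if p.n != e.n:
        raise ValueError("params and ensemble disagree on number of layers")
    rhs = _w_rhs(e, p, s0)
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(e.n), method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise ConvergenceError(f"reduced mean-field integration failed: {sol.message}")
    w = np.clip(sol.y.T, 0.0, 1.0)
    beta = np.asarray(p.beta)
    u = np.exp(-(beta / p.gamma) * w)
    v = np.empty_like(w)
    for row in range(w.shape[0]):
        v[row] = 1.0 - w[row] - _ht_vector(e, s0, u[row])
    return DegreeMFTrajectory(t=sol.t, w=w, u=u, v=np.clip(v, 0.0, None))


def mf_equilibrium(
    e: NetworkEnsemble,
    p: DynamicParams,
    s0: InitialSusceptibility,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    interior_eps: float = 1e-6,
) -> np.ndarray:
    """Solve the equilibrium fixed point ``w = g(w) = 1 - Ht(u(w))``.

    Monotone iteration from ``w = 0``.  When the population starts fully
    susceptible, ``w = 0`` is itself a fixed point; if the ``Ht``-kernel
    reproduction matrix is supercritical the iteration is restarted from a
    small interior point so the nontrivial least fixed point is reached.
    For a single layer the map is increasing and concave, so the nontrivial
    root is unique.
    """
    beta = np.asarray(p.beta)
    gamma = p.gamma

    def g(w):
        u = np.minimum(np.exp(-(beta / gamma) * w), 1.0)
        return np.clip(1.0 - _ht_vector(e, s0, u), 0.0, 1.0)

    def iterate(w):
        for it in range(max_iter):
            nxt = g(w)
            if float(np.max(np.abs(nxt - w))) < tol:
                return nxt
            w = nxt
        raise ConvergenceError("mean-field equilibrium iteration did not converge", w)

    w = iterate(np.zeros(e.n))
    if np.max(w) < 10 * tol:
        R = r_matrix(e, kernel="Htilde", s0=s0, T=beta / gamma)
        if R.leading_eigenvalue > 1.0:
            w = iterate(np.full(e.n, interior_eps))
    return w


def equilibrium_susceptibles(
    e: NetworkEnsemble,
    p: DynamicParams,
    s0: InitialSusceptibility,
    w_eq: np.ndarray,
    grid: Sequence[Sequence[int]] | None = None,
) -> dict[tuple[int, ...], float]:
    """Per-joint-degree equilibrium susceptible fractions
    ``s_k(0) exp(-sum_i (beta_i/gamma) k_i w_i)``."""
    ratio = np.asarray(p.beta) / p.gamma
    if grid is None:
        grid = [range(d.pmf.size) for d in e.distributions]
    out = {}
    for k in itertools.product(*grid):
        kk = np.asarray(k, dtype=float)
        out[tuple(k)] = s0.value(tuple(k)) * float(np.exp(-np.dot(ratio * kk, w_eq)))
    return out


def early_growth(
    e: NetworkEnsemble, p: DynamicParams, s0: InitialSusceptibility
):
    """Linearised short-time behaviour of the reduced system.

    Expanding around ``w = 0`` gives
    ``dw/dt = gamma [ c + (R - I) w ]`` with forcing
    ``c_i = 1 - Ht_i(1)`` (one minus the mean initial susceptibility on
    layer-i edges) and ``R`` the ``Ht``-kernel reproduction matrix at
    transmissibilities ``beta/gamma``.  Returns the per-mode rates
    ``gamma (lambda_l - 1)``, a closed-form evaluator for the linearised
    ``w(t)``, and the outbreak-growth flag ``lambda_max > 1``.
    """
    beta = np.asarray(p.beta)
    gamma = p.gamma
    R = r_matrix(e, kernel="Htilde", s0=s0, T=beta / gamma)
    vals, vecs = np.linalg.eig(R.entries)
    if np.linalg.matrix_rank(vecs) < e.n:
        raise NotDiagonalizableError(
            "Ht-kernel reproduction matrix is defective", eigenvalues=vals
        )
    vals = np.real_if_close(vals)
    order = np.argsort(np.real(vals))
    vals, vecs = vals[order], vecs[:, order]
    c = np.array([1.0 - eval_tilde_H_i(e, s0, i, np.ones(e.n)) for i in range(e.n)])
    coeff = np.linalg.solve(vecs, c.astype(complex))

    rates = gamma * (np.real(vals) - 1.0)

    def w_lin(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((t.size, e.n), dtype=complex)
        for l in range(e.n):
            lam = vals[l]
            if abs(lam - 1.0) < 1e-12:
                mode = gamma * t  # degenerate rate: linear-in-time mode
            else:
                mode = (np.exp(gamma * (lam - 1.0) * t) - 1.0) / (lam - 1.0)
            out += np.outer(coeff[l] * mode, vecs[:, l])
        return np.real(out) if t.size > 1 else np.real(out[0])

    return rates, w_lin, bool(np.max(np.real(vals)) > 1.0)


def full_degree_system(
    e: NetworkEnsemble,
    p: DynamicParams,
    s0: InitialSusceptibility,
    t_end: float,
    K_grid: Sequence[int] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    grid_cap: int = 100_000,
    n_eval: int = 401,
):
    """Integrate the full joint-degree system directly on a truncated grid.

    Exists as the direct counterpart of :func:`integrate_reduced`: the
    reduction is algebraically exact given ``w(0) = 0``, so both must agree
    to integrator tolerance.  Returns ``(t, grid_degrees, s_k, x_k, r_k)``
    with compartments of shape ``(T, n_cells)``.
    """
    if K_grid is None:
        K_grid = [d.pmf.size - 1 for d in e.distributions]
    sizes = [int(K) + 1 for K in K_grid]
    n_cells = int(np.prod(sizes))
    if n_cells > grid_cap:
        raise GridTooLargeError(
            f"joint-degree grid has {n_cells} cells (cap {grid_cap}); "
            "use the reduced system instead"
        )
    degrees = np.array(list(itertools.product(*(range(s) for s in sizes))))
    beta = np.asarray(p.beta)
    gamma = p.gamma
    n = e.n

    # Pt_i arrays aligned with the grid for computing v_i = sum Pt_i(k) x_{k+e_i}
    pt = [layer_excess_pmf(e, i).probs for i in range(n)]
    s_init = np.array([s0.value(tuple(k)) for k in degrees])
    x_init = 1.0 - s_init

    shape = tuple(sizes)

    def v_of_x(x_grid):
        v = np.zeros(n)
        for i in range(n):
            # x at k + e_i: shift grid by one along axis i
            shifted = np.roll(x_grid, -1, axis=i)
            idx = [slice(None)] * n
            idx[i] = -1
            shifted[tuple(idx)] = 0.0
            block = shifted[tuple(slice(0, s) for s in pt[i].shape)]
            v[i] = float(np.sum(pt[i] * block))
        return v

    def rhs(_t, y):
        s = y[:n_cells].reshape(shape)
        x = y[n_cells:].reshape(shape)
        v = v_of_x(x)
        force = (degrees @ (beta * v)).reshape(shape)
        gain = force * s
        return np.concatenate([(-gain).ravel(), (gain - gamma * x).ravel()])

    y0 = np.concatenate([s_init, x_init])
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise ConvergenceError(f"full degree-system integration failed: {sol.message}")
    s = sol.y[:n_cells].T
    x = sol.y[n_cells:].T
    r = 1.0 - s - x
    return sol.t, degrees, s, x, r


def reconstruct_compartments(
    e: NetworkEnsemble,
    p: DynamicParams,
    s0: InitialSusceptibility,
    traj: DegreeMFTrajectory,
    degrees: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-11,
):
    """Degree-class compartments from a reduced trajectory.

    ``s_k`` follows in closed form from ``u``; ``x_k`` integrates the scalar
    linear balance driven by the reduced ``w`` (re-integrated jointly so no
    interpolation error enters — the coupling is strictly one-way), and
    ``r_k`` closes the sum to 1.  Returns arrays shaped like the
    full-system output, evaluated at ``traj.t``.
    """
    beta = np.asarray(p.beta)
    gamma = p.gamma
    n = e.n
    degrees = np.asarray(degrees)
    kf = degrees.astype(float)
    s0_vals = np.array([s0.value(tuple(k)) for k in degrees])

    # closed-form s_k(t) from the reduced trajectory
    logu = np.log(traj.u)  # (T, n)
    s_k = s0_vals[None, :] * np.exp(logu @ kf.T)

    w_rhs = _w_rhs(e, p, s0)

    def rhs(t, y):
        w = np.clip(y[:n], 0.0, 1.0)
        x = y[n:]
        dw = w_rhs(t, w)
        v = np.clip(dw / gamma, 0.0, None)
        u = np.exp(-(beta / gamma) * w)
        s_now = s0_vals * np.exp(kf @ np.log(u))
        force = kf @ (beta * v)
        return np.concatenate([dw, -gamma * x + force * s_now])

    y0 = np.concatenate([np.zeros(n), 1.0 - s0_vals])
    sol = solve_ivp(rhs, (traj.t[0], traj.t[-1]), y0, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=traj.t)
    if not sol.success:
        raise ConvergenceError(f"compartment reconstruction failed: {sol.message}")
    x_k = sol.y[n:].T
    r_k = 1.0 - s_k - x_k
    return s_k, x_k, r_k
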