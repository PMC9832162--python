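"""Multivariate generating functions and reproduction matrices.

A network with ``n`` edge types (layers) of transmissibilities ``T_1..T_n``
is summarised by one degree distribution per layer, assumed independent
across layers, so the joint degree pgf factorises:

    G(x_1, ..., x_n) = prod_i G_i(x_i).

Following a uniformly random edge of layer ``i`` leads to a vertex whose
*excess* joint degree (remaining edges, arrival edge excluded) has pgf

    Gt_i(x) = G_i'(x_i) / G_i'(1) * prod_{j != i} G_j(x_j),

and following a uniformly random edge of any layer gives the mixture
``Gt = sum_l E(k_l) Gt_l / E(k)``.  The epidemic-threshold object is the
n-by-n reproduction matrix with entries

    R_ij = T_j * dGt_i/dx_j  at x = 1,

whose spectral radius crossing 1 marks the outbreak transition.  The
``Ht``-kernel variant weights each term of ``Gt_i`` by the initial
susceptibility of the reached vertex and carries one extra power of ``x_i``
(the reached vertex itself); with susceptibility identically 1 it reduces to
``x_i * Gt_i`` so its reproduction matrix is ``diag(T) + R``.

Orientation note: entry (i, j) of the reproduction matrix couples arrival
layer ``i`` (row) to onward layer ``j`` (column).  Spectral quantities are
invariant under transposition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .distributions import DegreeDistribution

__all__ = [
    "NetworkEnsemble",
    "JointPMF",
    "InitialSusceptibility",
    "RMatrix",
    "excess_joint_pmf",
    "layer_excess_pmf",
    "eval_tilde_G",
    "eval_tilde_G_i",
    "eval_tilde_H_i",
    "secondary_infection_pgf",
    "r0",
    "r0_layer",
    "r_matrix",
    "leading_eigen",
]


class DegenerateEnsembleError(ValueError):
    """All layers have zero mean degree."""


class DegenerateLayerError(ValueError):
    """The requested layer has zero mean degree."""


class IncompleteTableError(KeyError):
    """A per-degree susceptibility table is missing required joint degrees."""


@dataclass(frozen=True)
class NetworkEnsemble:
    """``n`` independent layers, each a degree distribution + transmissibility.

    Layer order is significant and fixed; ``T[i]`` is the probability that a
    layer-``i`` edge ever transmits from an infected endpoint.
    """

    distributions: tuple[DegreeDistribution, ...]
    T: tuple[float, ...]

    def __init__(self, layers: Iterable[tuple[DegreeDistribution, float]]):
        layers = list(layers)
        if not layers:
            raise ValueError("ensemble needs at least one layer")
        dists, Ts = zip(*layers)
        for t in Ts:
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"transmissibility {t} outside [0, 1]")
        object.__setattr__(self, "distributions", tuple(dists))
        object.__setattr__(self, "T", tuple(float(t) for t in Ts))

    @property
    def n(self) -> int:
        return len(self.distributions)

    @property
    def layers(self) -> tuple[tuple[DegreeDistribution, float], ...]:
        return tuple(zip(self.distributions, self.T))

    def mean_degrees(self) -> np.ndarray:
        return np.array([d.mean for d in self.distributions])

    def total_mean_degree(self) -> float:
        return float(self.mean_degrees().sum())

    # joint pgf G(x) = prod G_i(x_i)
    def eval_G(self, x: Sequence[float]) -> float:
        x = np.asarray(x, dtype=float)
        if x.size != self.n:
            raise ValueError("x must have one coordinate per layer")
        return float(np.prod([d.pgf(xi) for d, xi in zip(self.distributions, x)]))


@dataclass(frozen=True)
class JointPMF:
    """A finite joint pmf over degrees ``(k_1, ..., k_n)``.

    Stored densely: ``probs[k_1, ..., k_n]``.
    """

    probs: np.ndarray = field(repr=False)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0):
            raise ValueError("joint pmf entries must be nonnegative")
        object.__setattr__(self, "probs", p)

    @property
    def n(self) -> int:
        return self.probs.ndim

    def total(self) -> float:
        return float(self.probs.sum())

    def marginal(self, axis: int) -> np.ndarray:
        axes = tuple(a for a in range(self.probs.ndim) if a != axis)
        return self.probs.sum(axis=axes)

    def mean(self) -> np.ndarray:
        return np.array(
            [np.dot(np.arange(m.size), m) for m in (self.marginal(a) for a in range(self.n))]
        )

    def pgf(self, x: Sequence[float]) -> float:
        """Power-sum evaluation sum_k p(k) prod x_i^{k_i}."""
        x = np.asarray(x, dtype=float)
        out = self.probs
        for axis in range(self.n - 1, -1, -1):
            powers = x[axis] ** np.arange(out.shape[axis])
            out = np.tensordot(out, powers, axes=([axis], [0]))
        return float(out)


@dataclass(frozen=True)
class InitialSusceptibility:
    """Initial susceptible fraction, constant or resolved per joint degree."""

    mode: str = "constant"
    s0: float = 1.0
    table: Mapping[tuple[int, ...], float] | None = None

    def __post_init__(self):
        if self.mode not in ("constant", "per_degree"):
            raise ValueError("mode must be 'constant' or 'per_degree'")
        if self.mode == "constant":
            if not (0.0 <= self.s0 <= 1.0):
                raise ValueError("constant s0 must lie in [0, 1]")
        else:
            if self.table is None:
                raise ValueError("per_degree mode needs a table")
            for k, v in self.table.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"s0 value {v} at degree {k} outside [0, 1]")

    def value(self, joint_degree: tuple[int, ...]) -> float:
        if self.mode == "constant":
            return self.s0
        try:
            return float(self.table[tuple(joint_degree)])
        except KeyError as exc:
            raise IncompleteTableError(
                f"s0 table missing joint degree {tuple(joint_degree)}"
            ) from exc


@dataclass(frozen=True)
class RMatrix:
    """Reproduction matrix with its Perron data.

    ``kernel`` records whether entries differentiate the excess-degree pgf
    (``Gtilde``) or its susceptibility-weighted variant (``Htilde``).  Entry
    (i, j) couples arrival layer i to onward layer j; parts of the
    literature use the transposed convention, which leaves all spectral
    output unchanged.
    """

    kernel: str
    entries: np.ndarray = field(repr=False)
    leading_eigenvalue: float = 0.0
    leading_eigenvector: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if entries.shape[0] != entries.shape[1]:
            raise ValueError("reproduction matrix must be square")
        if np.any(entries < -1e-12):
            raise ValueError("reproduction matrix entries must be nonnegative")
        object.__setattr__(self, "entries", entries)
        lam, vec = _perron(entries)
        object.__setattr__(self, "leading_eigenvalue", lam)
        object.__setattr__(self, "leading_eigenvector", vec)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)


# ---------------------------------------------------------------------------
# excess joint pmfs
# ---------------------------------------------------------------------------


def _product_support(e: NetworkEnsemble) -> list[np.ndarray]:
    return [d.pmf for d in e.distributions]


def excess_joint_pmf(e: NetworkEnsemble) -> JointPMF:
    """Joint excess-degree pmf after following a uniformly random edge.

    ``Pt(k) = sum_l (k_l + 1) P_l(k_l + 1) prod_{i != l} P_i(k_i) / E(k)``.
    """
    Ek = e.total_mean_degree()
    if Ek <= 0:
        raise DegenerateEnsembleError("all layers have zero mean degree")
    mix = None
    for l in range(e.n):
        if e.distributions[l].mean <= 0:
            continue
        part = layer_excess_pmf(e, l).probs * e.distributions[l].mean
        if mix is None:
            mix = part
        else:
            mix, part = _broadcast_pair(mix, part)
            mix = mix + part
    return JointPMF(mix / Ek)


def layer_excess_pmf(e: NetworkEnsemble, i: int) -> JointPMF:
    """Joint excess-degree pmf after following a random layer-``i`` edge.

    Size-biases the layer-``i`` degree; other layers keep their ordinary
    degree distribution (independence across layers).
    """
    di = e.distributions[i]
    if di.mean <= 0:
        raise DegenerateLayerError(f"layer {i} has zero mean degree")
    factors = []
    for j, d in enumerate(e.distributions):
        if j == i:
            k = np.arange(1, d.pmf.size, dtype=float)
            excess = k * d.pmf[1:] / d.mean  # support 0..K-1
            factors.append(excess if excess.size else np.array([1.0]))
        else:
            factors.append(d.pmf)
    out = factors[0]
    for f in factors[1:]:
        out = np.multiply.outer(out, f)
    return JointPMF(np.atleast_1d(out))


def _broadcast_pair(a: np.ndarray, b: np.ndarray):
    """Zero-pad two dense joint pmfs to a common shape."""
    shape = tuple(max(sa, sb) for sa, sb in zip(a.shape, b.shape))
    out_a = np.zeros(shape)
    out_b = np.zeros(shape)
    out_a[tuple(slice(0, s) for s in a.shape)] = a
    out_b[tuple(slice(0, s) for s in b.shape)] = b
    return out_a, out_b


# ---------------------------------------------------------------------------
# generating-function evaluation
# ---------------------------------------------------------------------------


def _check_x(e: NetworkEnsemble, x) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size != e.n:
        raise ValueError("x must have one coordinate per layer")
    if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError("generating functions are evaluated on [0, 1]^n")
    return np.clip(x, 0.0, 1.0)


def eval_tilde_G(e: NetworkEnsemble, x, grad: bool = False):
    """Value (or gradient) of the mixed excess-degree pgf Gt at ``x``."""
    x = _check_x(e, x)
    if e.total_mean_degree() <= 0:
        raise DegenerateEnsembleError("all layers have zero mean degree")
    # normalize with the same pgf evaluations used for the numerator, so the
    # all-ones point maps to exactly 1 regardless of truncation error
    Ek = float(sum(d.pgf(1.0, 1) for d in e.distributions))
    G = np.array([d.pgf(xi, 0) for d, xi in zip(e.distributions, x)])
    G1 = np.array([d.pgf(xi, 1) for d, xi in zip(e.distributions, x)])
    if not grad:
        val = sum(G1[l] * np.prod(np.delete(G, l)) for l in range(e.n))
        return float(val / Ek)
    G2 = np.array([d.pgf(xi, 2) for d, xi in zip(e.distributions, x)])
    out = np.zeros(e.n)
    for j in range(e.n):
        # d/dx_j of sum_l G_l'(x_l) prod_{i != l} G_i(x_i)
        term = G2[j] * np.prod(np.delete(G, j))
        for l in range(e.n):
            if l == j:
                continue
            rest = np.prod([G[i] for i in range(e.n) if i not in (l, j)])
            term += G1[l] * G1[j] * rest
        out[j] = term / Ek
    return out


def eval_tilde_G_i(e: NetworkEnsemble, i: int, x, grad: bool = False):
    """Value (or gradient) of the layer-i excess-degree pgf Gt_i at ``x``."""
    x = _check_x(e, x)
    di = e.distributions[i]
    if di.mean <= 0:
        raise DegenerateLayerError(f"layer {i} has zero mean degree")
    norm = di.pgf(1.0, 1)  # closed-form G_i'(1), consistent with the numerator
    G = np.array([d.pgf(xi, 0) for d, xi in zip(e.distributions, x)])
    G1 = np.array([d.pgf(xi, 1) for d, xi in zip(e.distributions, x)])
    rest = np.prod(np.delete(G, i))
    if not grad:
        return float(G1[i] / norm * rest)
    G2 = np.array([d.pgf(xi, 2) for d, xi in zip(e.distributions, x)])
    out = np.zeros(e.n)
    for j in range(e.n):
        if j == i:
            out[j] = G2[i] / norm * rest
        else:
            others = np.prod([G[l] for l in range(e.n) if l not in (i, j)])
            out[j] = G1[i] / norm * G1[j] * others
    return out


def eval_tilde_H_i(
    e: NetworkEnsemble,
    s0: InitialSusceptibility,
    i: int,
    x,
    grad: bool = False,
):
    """Susceptibility-weighted excess pgf Ht_i at ``x``.

    ``Ht_i(x) = sum_k Pt_i(k) s0(k + e_i) x^k * x_i`` — the extra ``x_i``
    accounts for the reached vertex itself.  With constant ``s0 = c`` this is
    ``c * x_i * Gt_i(x)``; ``Ht_i(1)`` equals the mean initial susceptibility
    of layer-i edge ends.
    """
    x = _check_x(e, x)
    if s0.mode == "constant":
        c = s0.s0
        if not grad:
            return float(c * x[i] * eval_tilde_G_i(e, i, x))
        g = eval_tilde_G_i(e, i, x, grad=True)
        val = eval_tilde_G_i(e, i, x)
        out = c * x[i] * g
        out[i] += c * val
        return out
    # per-degree: explicit truncated sum over the layer-i excess grid
    pt = layer_excess_pmf(e, i).probs
    n = e.n
    shape = pt.shape
    if not grad:
        total = 0.0
        for k in itertools.product(*(range(s) for s in shape)):
            p = pt[k]
            if p == 0.0:
                continue
            kk = list(k)
            kk[i] += 1
            s = s0.value(tuple(kk))
            total += p * s * np.prod([x[j] ** kk[j] for j in range(n)])
        return float(total)
    out = np.zeros(n)
    for k in itertools.product(*(range(s) for s in shape)):
        p = pt[k]
        if p == 0.0:
            continue
        kk = list(k)
        kk[i] += 1
        s = s0.value(tuple(kk))
        base = p * s
        for j in range(n):
            if kk[j] == 0:
                continue
            term = base * kk[j] * x[j] ** (kk[j] - 1)
            for l in range(n):
                if l != j:
                    term *= x[l] ** kk[l]
            out[j] += term
    return out


def secondary_infection_pgf(e: NetworkEnsemble, x: float) -> float:
    """Pgf of the number of onward infections caused by a typical infected.

    Each of the ``k_i`` excess layer-i edges independently transmits with
    probability ``T_i``, giving ``Gt(1 + T_1 (x-1), ..., 1 + T_n (x-1))``.
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError("x must lie in [0, 1]")
    args = [1.0 + t * (x - 1.0) for t in e.T]
    return eval_tilde_G(e, args)


def r0(e: NetworkEnsemble) -> float:
    """Basic reproduction number: sum_j T_j dGt/dx_j at the all-ones point."""
    g = eval_tilde_G(e, np.ones(e.n), grad=True)
    return float(np.dot(e.T, g))


def r0_layer(e: NetworkEnsemble, i: int) -> float:
    """Mean onward infections caused by someone infected via a layer-i edge."""
    g = eval_tilde_G_i(e, i, np.ones(e.n), grad=True)
    return float(np.dot(e.T, g))


def r_matrix(
    e: NetworkEnsemble,
    kernel: str = "Gtilde",
    s0: InitialSusceptibility | None = None,
    T: Sequence[float] | None = None,
) -> RMatrix:
    """Reproduction matrix with entries ``T_j * dK_i/dx_j`` at all-ones.

    ``kernel`` selects the excess pgf (``Gtilde``) or its susceptibility
    weighted variant (``Htilde``, requires ``s0``).  ``T`` overrides the
    ensemble transmissibilities — used by the dynamic models where the
    effective per-edge ratio ``beta/gamma`` may exceed 1.
    """
    if kernel not in ("Gtilde", "Htilde"):
        raise ValueError("kernel must be 'Gtilde' or 'Htilde'")
    Tvec = np.asarray(e.T if T is None else T, dtype=float)
    if Tvec.size != e.n or np.any(Tvec < 0):
        raise ValueError("T must be a nonnegative n-vector")
    ones = np.ones(e.n)
    entries = np.zeros((e.n, e.n))
    for i in range(e.n):
        if kernel == "Gtilde":
            g = eval_tilde_G_i(e, i, ones, grad=True)
        else:
            if s0 is None:
                raise ValueError("Htilde kernel requires an InitialSusceptibility")
            g = eval_tilde_H_i(e, s0, i, ones, grad=True)
        entries[i, :] = Tvec * g
    return RMatrix(kernel=kernel, entries=entries)


def _perron(entries: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eig(entries)
    idx = int(np.argmax(np.abs(vals)))
    lam = float(np.real(vals[idx]))
    vec = np.real(vecs[:, idx])
    # Perron vector of a nonnegative matrix can be taken nonnegative
    if vec.sum() < 0:
        vec = -vec
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return lam, vec


def leading_eigen(R: RMatrix | np.ndarray) -> tuple[float, np.ndarray]:
    """Spectral radius and a nonnegative (Perron) eigenvector."""
    entries = R.entries if isinstance(R, RMatrix) else np.atleast_2d(np.asarray(R, float))
    return _perron(entries)
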