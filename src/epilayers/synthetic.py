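"""Stochastic oracles: configuration-model graphs, bond percolation, Gillespie SIR.

The mean-field modules describe an ensemble of networks; this module
realises members of that ensemble and simulates epidemics on them exactly,
providing independent checks:

* :func:`sample_multilayer_graph` — per-layer configuration-model sampling
  (i.i.d. degrees from the layer pmf, stub matching with rejection of
  self-loops / multi-edges, bounded retries then erasure).
* :func:`bond_percolation` — each layer-``i`` edge open independently with
  probability ``T_i``; infection = reachability from the seed set.  Monte
  Carlo, or exhaustive enumeration of all ``2^E`` occupancy states on tiny
  graphs.
* :func:`gillespie_sir` — exact event-driven continuous-time SIR with
  per-layer infection rates ``beta_i`` and recovery rate ``gamma``.

All randomness flows through one seeded generator; replicate streams are
derived by seed splitting so results are reproducible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order

from .gf_core import NetworkEnsemble
from .network_sir import DynamicParams, MultilayerGraph

__all__ = [
    "SimulationResult",
    "sample_multilayer_graph",
    "bond_percolation",
    "gillespie_sir",
]

EXHAUSTIVE_EDGE_CAP = 20


class SamplingError(RuntimeError):
    """Stub matching failed within the retry budget and erasure is disabled."""


@dataclass(frozen=True)
class SimulationResult:
    """Replicate-level summary of a stochastic simulation."""

    vertex_probability: np.ndarray = field(repr=False)
    final_size_fraction: float = 0.0
    final_sizes: np.ndarray = field(repr=False, default=None)
    replicates: int = 0
    seed: int | None = None
    standard_error: float = 0.0
    vertex_standard_error: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# configuration-model sampling
# ---------------------------------------------------------------------------


def _sample_degrees(pmf: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    support = np.arange(pmf.size)
    p = pmf / pmf.sum()
    deg = rng.choice(support, size=N, p=p)
    # parity fix: redraw one vertex's degree until the stub count is even
    while deg.sum() % 2:
        v = rng.integers(N)
        deg[v] = rng.choice(support, p=p)
    return deg


def _match_stubs(
    deg: np.ndarray,
    rng: np.random.Generator,
    max_retries: int,
    erase: bool,
) -> set[tuple[int, int]]:
    stubs = np.repeat(np.arange(deg.size), deg)
    for _attempt in range(max_retries):
        rng.shuffle(stubs)
        pairs = stubs.reshape(-1, 2)
        u = np.minimum(pairs[:, 0], pairs[:, 1])
        v = np.maximum(pairs[:, 0], pairs[:, 1])
        ok = u != v
        edges = set(zip(u[ok].tolist(), v[ok].tolist()))
        if ok.all() and len(edges) == pairs.shape[0]:
            return edges
    if not erase:
        raise SamplingError(
            f"no simple stub matching found within {max_retries} retries"
        )
    dropped = int(pairs.shape[0] - len(edges))
    if dropped:
        warnings.warn(
            f"configuration model: erased {dropped} self-loop/multi-edge pairs",
            stacklevel=3,
        )
    return edges


def sample_multilayer_graph(
    e: NetworkEnsemble,
    N: int,
    seed: int | np.random.Generator,
    max_retries: int = 50,
    erase: bool = True,
) -> MultilayerGraph:
    """Sample one multilayer configuration-model graph on ``N`` vertices.

    Per layer, degrees are drawn i.i.d. from the layer pmf (with a parity
    fix), then stubs are matched uniformly.  Matchings containing self-loops
    or multi-edges are retried up to ``max_retries`` times; failing that the
    offending pairs are erased with a warning (``erase=False`` raises
    instead).  The empirical degree distribution converges to the target as
    ``N`` grows; erasure perturbs it by ``O(1/N)``.
    """
    if N < 2:
        raise ValueError("need at least 2 vertices")
    rng = np.random.default_rng(seed)
    layers = []
    for d in e.distributions:
        deg = _sample_degrees(d.pmf, N, rng)
        edges = _match_stubs(deg, rng, max_retries, erase)
        layers.append(tuple(sorted(edges)))
    return MultilayerGraph(N=N, edges=tuple(layers))


# ---------------------------------------------------------------------------
# bond percolation
# ---------------------------------------------------------------------------


def _reachable(N: int, open_edges: Iterable[tuple[int, int]], seeds: Sequence[int]) -> np.ndarray:
    mask = np.zeros(N, dtype=bool)
    mask[list(seeds)] = True
    edges = list(open_edges)
    if not edges:
        return mask
    rows = [u for u, v in edges] + [v for u, v in edges]
    cols = [v for u, v in edges] + [u for u, v in edges]
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(N, N))
    for s in seeds:
        order = breadth_first_order(adj, int(s), directed=False, return_predecessors=False)
        mask[order] = True
    return mask


def bond_percolation(
    g: MultilayerGraph,
    T: Sequence[float],
    seeds: Sequence[int],
    reps: int = 1000,
    mode: str = "mc",
    seed: int | np.random.Generator | None = None,
) -> SimulationResult:
    """Multitype bond percolation from a seed set.

    ``mc``: each replicate opens layer-``i`` edges independently with
    probability ``T_i`` and marks vertices reachable from the seeds.
    ``exhaustive``: sums reachability over all ``2^E`` occupancy states
    weighted by their exact probabilities (total edges capped at
    ``EXHAUSTIVE_EDGE_CAP``).
    """
    T = np.asarray(T, dtype=float)
    if T.size != g.n_layers or np.any(T < 0) or np.any(T > 1):
        raise ValueError("T must be an n-vector in [0, 1]")
    seeds = list(int(s) for s in seeds)
    all_edges = [(i, u, v) for i in range(g.n_layers) for (u, v) in g.edges[i]]

    if mode == "exhaustive":
        if len(all_edges) > EXHAUSTIVE_EDGE_CAP:
            raise ValueError(
                f"exhaustive mode capped at {EXHAUSTIVE_EDGE_CAP} edges "
                f"(graph has {len(all_edges)})"
            )
        prob = np.zeros(g.N)
        for state in itertools.product((False, True), repeat=len(all_edges)):
            p = 1.0
            open_edges = []
            for (i, u, v), is_open in zip(all_edges, state):
                p *= T[i] if is_open else 1.0 - T[i]
                if is_open:
                    open_edges.append((u, v))
            if p == 0.0:
                continue
            prob += p * _reachable(g.N, open_edges, seeds)
        fs = float(prob.mean())
        return SimulationResult(
            vertex_probability=prob,
            final_size_fraction=fs,
            final_sizes=None,
            replicates=0,
            seed=None,
            standard_error=0.0,
        )

    if mode != "mc":
        raise ValueError("mode must be 'mc' or 'exhaustive'")
    rng = np.random.default_rng(seed)
    edge_T = np.array([T[i] for i, _, _ in all_edges])
    counts = np.zeros(g.N)
    sizes = np.empty(reps)
    for r in range(reps):
        is_open = rng.random(len(all_edges)) < edge_T
        open_edges = [(u, v) for (i, u, v), o in zip(all_edges, is_open) if o]
        mask = _reachable(g.N, open_edges, seeds)
        counts += mask
        sizes[r] = mask.mean()
    prob = counts / reps
    se_v = np.sqrt(prob * (1.0 - prob) / reps)
    return SimulationResult(
        vertex_probability=prob,
        final_size_fraction=float(sizes.mean()),
        final_sizes=sizes,
        replicates=reps,
        seed=seed if isinstance(seed, int) else None,
        standard_error=float(sizes.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        vertex_standard_error=se_v,
    )


# ---------------------------------------------------------------------------
# Gillespie SIR
# ---------------------------------------------------------------------------


def _gillespie_once(
    adj: list[list[tuple[int, int]]],
    beta: np.ndarray,
    gamma: float,
    initial: Sequence[int],
    rng: np.random.Generator,
    N: int,
) -> np.ndarray:
    """One exact SIR realisation; returns the ever-infected indicator."""
    S, I, R = 0, 1, 2
    state = np.zeros(N, dtype=np.int8)
    pressure = np.zeros(N)  # infection rate on susceptibles
    infected = []
    for v in initial:
        state[v] = I
        infected.append(v)
    for v in initial:
        for i, w in adj[v]:
            if state[w] == S:
                pressure[w] += beta[i]
    n_inf = len(infected)
    while n_inf:
        total_inf_rate = float(pressure.sum())
        total = gamma * n_inf + total_inf_rate
        u = rng.random() * total
        if u < gamma * n_inf:
            # recovery of a uniformly chosen infected
            idx = rng.integers(n_inf)
            v = infected[idx]
            infected[idx] = infected[-1]
            infected.pop()
            n_inf -= 1
            state[v] = R
            for i, w in adj[v]:
                if state[w] == S:
                    pressure[w] -= beta[i]
        else:
            # infection: susceptible chosen proportionally to its pressure
            target = u - gamma * n_inf
            cum = np.cumsum(pressure)
            v = int(np.searchsorted(cum, target, side="right"))
            v = min(v, N - 1)
            if state[v] != S:  # fp-roundoff guard: snap to a pressured susceptible
                candidates = np.nonzero((pressure > 0) & (state == S))[0]
                if candidates.size == 0:
                    break
                v = int(candidates[np.argmin(np.abs(cum[candidates] - target))])
            state[v] = I
            pressure[v] = 0.0
            infected.append(v)
            n_inf += 1
            for i, w in adj[v]:
                if state[w] == S:
                    pressure[w] += beta[i]
    return state == R


def gillespie_sir(
    g: MultilayerGraph,
    p: DynamicParams,
    initial_infected: Sequence[int],
    seed: int | np.random.Generator | None = None,
    reps: int = 100,
) -> SimulationResult:
    """Exact event-driven SIR on the explicit graph.

    Susceptible ``v`` is infected at rate ``sum_i beta_i * (#infected
    layer-i neighbours)``; infected vertices recover at rate ``gamma``.  In
    isolation a single infectious neighbour transmits across a layer-i edge
    with probability ``beta_i / (beta_i + gamma)`` — note this differs from
    the whole-period transmissibility ``beta_i / gamma`` used by the
    percolation framework.
    """
    if p.n != g.n_layers:
        raise ValueError("params and graph disagree on number of layers")
    rng = np.random.default_rng(seed)
    beta = np.asarray(p.beta)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(g.N)]
    for i in range(g.n_layers):
        for u, v in g.edges[i]:
            adj[u].append((i, v))
            adj[v].append((i, u))
    counts = np.zeros(g.N)
    sizes = np.empty(reps)
    for r in range(reps):
        ever = _gillespie_once(adj, beta, p.gamma, list(initial_infected), rng, g.N)
        ever[list(initial_infected)] = True  # seeds count as infected
        counts += ever
        sizes[r] = ever.mean()
    prob = counts / reps
    return SimulationResult(
        vertex_probability=prob,
        final_size_fraction=float(sizes.mean()),
        final_sizes=sizes,
        replicates=reps,
        seed=seed if isinstance(seed, int) else None,
        standard_error=float(sizes.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        vertex_standard_error=np.sqrt(prob * (1.0 - prob) / reps),
    )
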