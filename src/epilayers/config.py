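"""Run configuration schema, validation, and result serialization.

A run config declares the layer ensemble and solver settings:

.. code-block:: yaml

    layers:
      - {family: poisson, params: {mean: 50}, T: 0.1}
      - {family: poisson, params: {mean: 2},  T: 0.6}
    tail_tol: 1.0e-10
    gamma: 1.0         # only for dynamic commands (layers then carry beta)
    s0: 1.0
    seed: 1

Each layer carries exactly one of ``T`` (whole-period transmissibility, for
percolation commands) or ``beta`` (rate per unit time, requires ``gamma``).
Unknown keys are rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .distributions import make_degree_distribution
from .gf_core import InitialSusceptibility, NetworkEnsemble

__all__ = ["RunConfig", "load_config", "write_results", "ConfigError"]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


_TOP_KEYS = {"layers", "gamma", "tail_tol", "s0", "solver", "seed", "output"}
_LAYER_KEYS = {"family", "params", "T", "beta"}
_SOLVER_KEYS = {"tol", "max_iter", "rtol", "atol", "t_end"}

_SOLVER_DEFAULTS = {
    "tol": 1e-12,
    "max_iter": 100_000,
    "rtol": 1e-9,
    "atol": 1e-11,
    "t_end": 50.0,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with defaults filled in."""

    layers: tuple[dict, ...]
    gamma: float | None
    tail_tol: float
    s0: float
    solver: dict
    seed: int | None
    output: str | None
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.layers)

    @property
    def has_T(self) -> bool:
        return all("T" in layer for layer in self.layers)

    @property
    def has_beta(self) -> bool:
        return all("beta" in layer for layer in self.layers)

    def ensemble(self, as_percolation: bool = False) -> NetworkEnsemble:
        """Build the ensemble; percolation commands require ``T`` per layer.

        ``as_percolation`` converts rates via ``T = beta / gamma`` when the
        config carries rates instead (explicit opt-in).
        """
        layers = []
        for layer in self.layers:
            d = make_degree_distribution(
                layer["family"], tail_tol=self.tail_tol, **layer.get("params", {})
            )
            if "T" in layer:
                t = layer["T"]
            elif as_percolation:
                t = layer["beta"] / self.gamma
                if t > 1.0:
                    raise ConfigError(
                        f"beta/gamma = {t:.3g} exceeds 1; not a valid transmissibility"
                    )
            else:
                raise ConfigError(
                    "percolation command requires per-layer T "
                    "(or pass --as-percolation to convert beta/gamma)"
                )
            layers.append((d, t))
        return NetworkEnsemble(layers)

    def betas(self) -> list[float]:
        if not self.has_beta:
            raise ConfigError("dynamic command requires per-layer beta plus gamma")
        return [float(layer["beta"]) for layer in self.layers]

    def susceptibility(self) -> InitialSusceptibility:
        return InitialSusceptibility(mode="constant", s0=self.s0)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate_keys(d: dict, allowed: set, where: str):
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _validate_keys(data, _TOP_KEYS, "config")
    layers = data.get("layers")
    if not isinstance(layers, list) or not layers:
        raise ConfigError("config needs a nonempty 'layers' list")
    gamma = data.get("gamma")
    if gamma is not None and not gamma > 0:
        raise ConfigError("gamma must be positive")
    for idx, layer in enumerate(layers):
        if not isinstance(layer, dict):
            raise ConfigError(f"layer {idx} must be a mapping")
        _validate_keys(layer, _LAYER_KEYS, f"layer {idx}")
        if "family" not in layer:
            raise ConfigError(f"layer {idx} missing 'family'")
        has_T, has_b = "T" in layer, "beta" in layer
        if has_T == has_b:
            raise ConfigError(
                f"layer {idx}: exactly one of 'T' or 'beta' must be given"
            )
        if has_T and not (0.0 <= layer["T"] <= 1.0):
            raise ConfigError(f"layer {idx}: T={layer['T']} outside [0, 1]")
        if has_b:
            if layer["beta"] < 0:
                raise ConfigError(f"layer {idx}: beta must be nonnegative")
            if gamma is None:
                raise ConfigError("'beta' layers require a top-level 'gamma'")
    tail_tol = float(data.get("tail_tol", 1e-10))
    if not (0.0 < tail_tol <= 1e-4):
        raise ConfigError("tail_tol must lie in (0, 1e-4]")
    s0 = float(data.get("s0", 1.0))
    if not (0.0 <= s0 <= 1.0):
        raise ConfigError("s0 must lie in [0, 1]")
    solver = dict(_SOLVER_DEFAULTS)
    user_solver = data.get("solver", {}) or {}
    _validate_keys(user_solver, _SOLVER_KEYS, "solver")
    solver.update(user_solver)
    for k in ("tol", "rtol", "atol"):
        if not solver[k] > 0:
            raise ConfigError(f"solver.{k} must be positive")
    seed = data.get("seed")
    return RunConfig(
        layers=tuple(dict(layer) for layer in layers),
        gamma=float(gamma) if gamma is not None else None,
        tail_tol=tail_tol,
        s0=s0,
        solver=solver,
        seed=int(seed) if seed is not None else None,
        output=data.get("output"),
        raw=data,
    )


def _format_float(x: float) -> float:
    """Round to 12 significant digits for deterministic output."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.12g}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(obj[k]) for k in obj}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return _format_float(float(obj))
    if isinstance(obj, (np.integer, int, str, bool)) or obj is None:
        return obj if not isinstance(obj, np.integer) else int(obj)
    return str(obj)


def write_results(result: dict, path, fmt: str = "json", metadata: dict | None = None):
    """Serialize a result mapping with deterministic field order.

    JSON output carries a metadata block (package version plus any config
    hash / seed the caller supplies); CSV expects ``result['columns']`` and
    ``result['rows']``.
    """
    path = Path(path)
    if fmt == "json":
        payload = {"metadata": {"version": __version__, **(metadata or {})}}
        payload.update(_jsonable(result))
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif fmt == "csv":
        cols = result["columns"]
        rows = result["rows"]
        lines = [",".join(cols)]
        for row in rows:
            lines.append(",".join(f"{_format_float(float(v)):.12g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("fmt must be 'json' or 'csv'")
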