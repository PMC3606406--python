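"""Config parsing, result writers and synthetic initial-state generation.

All floats are written with 17 significant digits so that runs are
reproducible across platforms to the last bit the numerics allow; no
operation anywhere in the package reads the ambient clock or the global
random state — randomness always flows from explicit seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dynamics import FieldState, NetworkState, SimulationResult
from .exceptions import ConfigError, OrderingError
from .fields import VelocityField
from .splay import SplayStateFiniteN, field_fixed_point, splay_finite

__all__ = [
    "InitialStateSpec",
    "make_initial_state",
    "read_config",
    "write_config",
    "write_raster",
    "write_spectrum",
    "read_spectrum",
    "write_splay_state",
    "write_json",
]

FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class InitialStateSpec:
    """How to build an initial network state.

    ``mode`` is one of ``splay_exact`` (the fixed point itself),
    ``splay_jittered`` (fixed point plus uniform noise of the given
    amplitude, re-sorted) or ``random_uniform`` (N-1 potentials drawn in
    (0,1), sorted, with the reset neuron appended).
    """

    mode: str = "splay_exact"
    jitter: float = 0.0
    seed: int = 0


def make_initial_state(spec: InitialStateSpec, field: VelocityField, g: float,
                       alpha: float, N: int) -> NetworkState:
    """Build a valid :class:`NetworkState` from a declarative spec."""
    if spec.mode in ("splay_exact", "splay_jittered"):
        st = splay_finite(field, g, alpha, N)
        u = st.u.copy()
        if spec.mode == "splay_jittered" and spec.jitter > 0.0:
            rng = np.random.default_rng(spec.seed)
            u[:-1] += spec.jitter * rng.uniform(-1.0, 1.0, N - 1)
            u[:-1] = np.sort(np.clip(u[:-1], 0.0, 1.0 - 1e-12))[::-1]
            if np.any(np.diff(u) >= 0):
                raise OrderingError(
                    f"jitter {spec.jitter} collapses the potential ordering at N={N}")
        state = NetworkState(u, st.fields)
    elif spec.mode == "random_uniform":
        rng = np.random.default_rng(spec.seed)
        body = np.sort(rng.uniform(0.0, 1.0, N - 1))[::-1]
        u = np.concatenate([body, [0.0]])
        state = NetworkState(u, FieldState(0.0, alpha**2 / N))
    else:
        raise ConfigError(f"unknown initial-state mode {spec.mode!r}")
    state.validate()
    return state


# ----------------------------------------------------------------------
# configs
# ----------------------------------------------------------------------

_REQUIRED = ("field", "g", "alpha")


def read_config(path, required: tuple = _REQUIRED) -> dict:
    """Read a YAML or JSON experiment config, checking required keys."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:
        raise ConfigError(f"unknown config format {path.suffix!r} (use .yaml/.yml/.json)")
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key in required:
        if key not in cfg:
            raise ConfigError(f"missing required key {key!r} in {path}")
    if "field" in cfg:
        fspec = cfg["field"]
        if not isinstance(fspec, dict) or "type" not in fspec:
            raise ConfigError("missing required key 'field.type'")
    return cfg


def write_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))


# ----------------------------------------------------------------------
# result writers
# ----------------------------------------------------------------------

def write_raster(result: SimulationResult, path) -> None:
    """TSV raster: one ``time<TAB>neuron_id`` line per spike."""
    with open(path, "w") as fh:
        fh.write("time\tneuron_id\n")
        for t, i in zip(result.times, result.neuron_ids):
            fh.write(f"{t:.17g}\t{i}\n")


def write_spectrum(table: pd.DataFrame, path) -> None:
    """CSV spectrum table with 17-significant-digit floats."""
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_spectrum(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_splay_state(st: SplayStateFiniteN, csv_path, json_path: Optional[str] = None) -> None:
    """Dump a splay state: CSV of (j, u_j) plus a JSON header."""
    pd.DataFrame({"j": np.arange(1, st.N + 1), "u_j": st.u}).to_csv(
        csv_path, index=False, float_format=FLOAT_FMT)
    if json_path is not None:
        write_json(dict(N=st.N, tau=st.tau, T=st.T, E=st.E, P=st.P,
                        residual=st.residual), json_path)


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
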