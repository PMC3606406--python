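"""Single-neuron velocity fields.

A neuron is described by a phase-like membrane potential ``u`` on [0, 1]
driven by a velocity field ``F(u) > 0`` (supra-threshold condition): the
neuron fires when ``u`` reaches the threshold ``u_th = 1`` and is reset to
``u_R = 0``.  Because threshold and reset can be identified, ``u`` behaves
like a phase and a field with ``F(1) != F(0)`` is called *discontinuous*;
this jump at the boundary is what controls splay-state stability.

Time is measured in units of the membrane time constant, so for the leaky
integrate-and-fire (LIF) neuron ``F(u) = a - u`` with supra-threshold bias
``a > 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["VelocityField", "lif_field", "custom_field", "effective_rate"]

_FD_STEP = 1e-5  # centred finite-difference step for automatic derivatives


@dataclass(frozen=True)
class VelocityField:
    """Velocity field ``F(u)`` of an isolated neuron on ``u in [0, 1]``.

    Parameters
    ----------
    evaluate
        Callable mapping ``u`` (scalar or array) to ``F(u)``, in units of
        potential per membrane time constant.
    derivatives
        Optional tuple of callables ``(F', F'', F''')``.  When absent,
        derivatives are approximated by centred finite differences of
        ``evaluate`` (step ``1e-5``); they enter only validation paths and
        the truncated series maps, never the core numerics.
    label
        Free-text description.
    lif_a
        Bias of the LIF field when this instance is ``F(u) = a - u``;
        ``None`` for any other field.  Enables the exact closed-form code
        paths throughout the package.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    derivatives: Optional[tuple] = None
    label: str = "custom"
    lif_a: Optional[float] = None

    def __call__(self, u):
        return self.evaluate(u)

    def derivative(self, m: int, u):
        """m-th derivative ``F^(m)(u)`` for ``m in {1, 2, 3}``."""
        if m not in (1, 2, 3):
            raise ValueError(f"derivative order must be 1, 2 or 3, got {m}")
        if self.derivatives is not None:
            return self.derivatives[m - 1](u)
        return _finite_difference(self.evaluate, u, m)

    @property
    def F_at_reset(self) -> float:
        """One-sided limit of F as u -> 0+ (value seen by a freshly reset neuron)."""
        return float(self.evaluate(0.0))

    @property
    def F_at_threshold(self) -> float:
        """One-sided limit of F as u -> 1- (value at the firing threshold)."""
        return float(self.evaluate(1.0))

    @property
    def is_discontinuous(self) -> bool:
        """True when F(1) != F(0), i.e. the field jumps at the reset/threshold point."""
        return not np.isclose(self.F_at_reset, self.F_at_threshold, rtol=0.0, atol=1e-12)

    @property
    def boundary_jump(self) -> float:
        """F(1) - F(0); its sign (together with g) decides splay stability."""
        return self.F_at_threshold - self.F_at_reset

    @property
    def is_lif(self) -> bool:
        return self.lif_a is not None


def _finite_difference(f, u, m: int, h: float = _FD_STEP):
    """Centred finite-difference derivative of order m, staying inside [0, 1]."""
    u = np.asarray(u, dtype=float)
    # shift evaluation points so the stencil never leaves the domain
    half_width = h * (2 if m == 3 else 1)
    uc = np.clip(u, half_width, 1.0 - half_width)
    if m == 1:
        return (f(uc + h) - f(uc - h)) / (2 * h)
    if m == 2:
        return (f(uc + h) - 2 * f(uc) + f(uc - h)) / h**2
    return (f(uc + 2 * h) - 2 * f(uc + h) + 2 * f(uc - h) - f(uc - 2 * h)) / (2 * h**3)


def lif_field(a: float) -> VelocityField:
    """Leaky integrate-and-fire field ``F(u) = a - u`` with ``a > 1``.

    The jump at the boundary is ``F(1) - F(0) = -1`` for every ``a``, so LIF
    networks are the canonical discontinuous-field example.
    """
    if a <= 1:
        raise ValueError(f"LIF neuron must be supra-threshold: a > 1 required, got a={a}")
    a = float(a)
    return VelocityField(
        evaluate=lambda u: a - np.asarray(u, dtype=float),
        derivatives=(
            lambda u: np.full_like(np.asarray(u, dtype=float), -1.0),
            lambda u: np.zeros_like(np.asarray(u, dtype=float)),
            lambda u: np.zeros_like(np.asarray(u, dtype=float)),
        ),
        label=f"LIF(a={a})",
        lif_a=a,
    )


def custom_field(
    evaluate: Callable,
    derivatives: Optional[tuple] = None,
    label: str = "custom",
) -> VelocityField:
    """Wrap a user-supplied callable into a :class:`VelocityField`.

    The callable must be positive on [0, 1] (checked on a coarse grid) and
    vectorised over numpy arrays.  Derivatives up to order 3 may be supplied;
    otherwise centred finite differences are used.
    """
    probe = np.asarray(evaluate(np.linspace(0.0, 1.0, 33)), dtype=float)
    if np.any(probe <= 0):
        raise ValueError("velocity field must be strictly positive on [0, 1] (supra-threshold)")
    return VelocityField(evaluate=evaluate, derivatives=derivatives, label=label)


def effective_rate(field: VelocityField, g: float, E: float, u) -> float:
    """Total drive of a coupled neuron: ``F(u) + g E``.

    A negative value is legal output but signals loss of the splay-existence
    condition (the total drive must stay positive for the network to keep
    firing).
    """
    return field.evaluate(u) + g * E


def field_from_spec(spec: dict) -> VelocityField:
    """Build a field from a config mapping, e.g. ``{"type": "lif", "a": 1.3}``."""
    kind = spec.get("type")
    if kind == "lif":
        if "a" not in spec:
            raise KeyError("LIF field spec requires key 'a'")
        return lif_field(float(spec["a"]))
    if kind == "custom":
        import importlib

        path = spec.get("module_path")
        if path is None:
            raise KeyError("custom field spec requires key 'module_path'")
        mod_name, _, attr = path.rpartition(":")
        obj = getattr(importlib.import_module(mod_name), attr)
        return obj if isinstance(obj, VelocityField) else custom_field(obj)
    raise ValueError(f"unknown field type {kind!r}")
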