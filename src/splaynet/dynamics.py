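"""Event-driven map of the pulse-coupled network.

Between two successive network spikes every membrane potential obeys

    du_j/dt = F(u_j) + g E(t),

where the common synaptic field is the superposition of alpha-pulses
``alpha^2 t e^{-alpha t} / N`` emitted at past firing times.  Introducing
``P := alpha E + dE/dt`` turns the field dynamics between spikes into a
closed form, so the whole network can be advanced exactly from spike to
spike: this module implements that event-driven map (field update, membrane
update, interspike-time solution and the comoving index shift) together
with a forward simulator.

Ordering convention: immediately after a spike the potentials are sorted in
decreasing order, ``1 > u_1 > ... > u_N = 0``; the neuron at slot 1 is the
next to fire and the just-reset neuron sits at slot N.  At every spike the
indices shift by one (comoving frame), which makes the splay state a fixed
point of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .exceptions import NotFiringError, OrderingError
from .fields import VelocityField

__all__ = [
    "FieldState",
    "NetworkState",
    "pulse_shape",
    "field_map",
    "lif_chi",
    "interspike_time",
    "step",
    "potential_update_series",
    "simulate",
    "SimulationResult",
]

#: residual tolerance for the interspike-time root
_ISI_TOL = 1e-13
#: integration tolerances for the generic-field path; the stability analysis
#: finite-differences through this map, so ~4 clean digits must survive the
#: differencing
_ODE_RTOL = 1e-11
_ODE_ATOL = 1e-13


class FieldState(NamedTuple):
    """Synaptic field pair at a spike time: ``E`` and ``P = alpha E + dE/dt``."""

    E: float
    P: float

    @property
    def Edot(self):
        raise AttributeError("use edot(alpha)")

    def edot(self, alpha: float) -> float:
        """dE/dt immediately after the spike."""
        return self.P - alpha * self.E


@dataclass
class NetworkState:
    """Network configuration immediately after a spike.

    ``u`` holds the N ordered membrane potentials (descending, ``u[-1] = 0``),
    ``fields`` the synaptic pair, ``t`` the accumulated time and ``ids`` the
    original neuron label sitting at each slot (needed for raster plots,
    since the comoving frame relabels neurons at every spike).
    """

    u: np.ndarray
    fields: FieldState
    t: float = 0.0
    spike_count: int = 0
    ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.ids is None:
            self.ids = np.arange(1, self.u.size + 1)

    @property
    def N(self) -> int:
        return self.u.size

    def validate(self) -> None:
        u = self.u
        if u[0] >= 1.0:
            raise OrderingError(f"u_1 = {u[0]} must be below threshold 1")
        if not np.all(np.diff(u) < 0):
            bad = int(np.argmax(np.diff(u) >= 0)) + 1
            raise OrderingError(f"potentials not strictly decreasing at slots {bad},{bad + 1}")
        if u[-1] != 0.0:
            raise OrderingError(f"just-reset neuron must have u_N = 0, got {u[-1]}")

    def copy(self) -> "NetworkState":
        return NetworkState(self.u.copy(), self.fields, self.t, self.spike_count, self.ids.copy())


def pulse_shape(t, alpha: float, N: int):
    """Single alpha-pulse ``alpha^2 t e^{-alpha t} / N`` emitted at t = 0.

    The 1/N normalisation matches the per-spike source term ``alpha^2/N`` of
    the field equation, so that a full splay period (N spikes) injects unit
    area into E.  Peak at ``t = 1/alpha`` with value ``alpha e^{-1}/N``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("pulse time must be non-negative")
    if alpha <= 0:
        raise ValueError("pulse rate alpha must be positive")
    if N < 1:
        raise ValueError("network size N must be >= 1")
    out = alpha**2 * t * np.exp(-alpha * t) / N
    return out if out.ndim else float(out)


def field_map(fs: FieldState, tau: float, alpha: float, N: int) -> FieldState:
    """Exact spike-to-spike update of the synaptic pair.

    ``E' = (E + tau P) e^{-alpha tau}``, ``P' = P e^{-alpha tau} + alpha^2/N``;
    the kick accounts for the spike emitted at the end of the interval.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    decay = np.exp(-alpha * tau)
    return FieldState((fs.E + tau * fs.P) * decay, fs.P * decay + alpha**2 / N)


def field_between(fs: FieldState, t, alpha: float):
    """Field value E(t) within an interspike interval (t measured from the last spike)."""
    return (fs.E + t * fs.P) * np.exp(-alpha * t)


# ----------------------------------------------------------------------
# LIF closed form
# ----------------------------------------------------------------------

def lif_chi(tau: float, fs: FieldState, a: float, g: float, alpha: float) -> float:
    """Inhomogeneous part of the exact LIF membrane update over an interval tau.

    Variation of constants for ``du/dt = a - u + g E(t)`` with
    ``E(t) = (E + t P) e^{-alpha t}`` gives ``u(tau) = e^{-tau} u(0) + chi`` with

        chi = a (1 - e^{-tau})
              + g (e^{-tau} - e^{-alpha tau})/(alpha - 1) * (E + P/(alpha - 1))
              - g tau e^{-alpha tau} P / (alpha - 1).

    ``alpha = 1`` is a removable singularity of this form and is rejected;
    the generic numeric path still covers it.
    """
    if alpha == 1.0:
        raise ValueError("alpha = 1 is a removable singularity of the closed form; "
                         "use the generic numeric path for this pulse rate")
    return _chi_partials(tau, fs.E, fs.P, a, g, alpha)[0]


def _chi_partials(tau, E, P, a, g, alpha):
    """chi and its partial derivatives (d/dE, d/dP, d/dtau)."""
    em, ea = np.exp(-tau), np.exp(-alpha * tau)
    am1 = alpha - 1.0
    s = (em - ea) / am1
    sprime = (-em + alpha * ea) / am1
    chi = a * (-np.expm1(-tau)) + g * s * (E + P / am1) - g * tau * ea * P / am1
    chi_E = g * s
    chi_P = g * s / am1 - g * tau * ea / am1
    chi_tau = a * em + g * sprime * (E + P / am1) - g * ea * (1 - alpha * tau) * P / am1
    return chi, chi_E, chi_P, chi_tau


def _free_period(field: VelocityField) -> float:
    """Period of an isolated neuron, used only as a time-scale cap."""
    if field.is_lif:
        a = field.lif_a
        return float(np.log(a / (a - 1)))
    val, _ = quad(lambda u: 1.0 / field.evaluate(u), 0.0, 1.0, limit=200)
    return float(val)


def interspike_time(state: NetworkState, field: VelocityField, g: float, alpha: float) -> float:
    """Smallest tau > 0 at which neuron 1 reaches threshold.

    LIF: safeguarded bracketing on ``e^{-tau} u_1 + chi(tau) - 1``.
    Generic: event detection on the integrated single-neuron ODE.
    Raises :class:`NotFiringError` if no crossing occurs within ten free
    periods (total drive non-positive, or coupling too inhibitory).
    """
    u1 = float(state.u[0])
    if u1 >= 1.0:
        return 0.0
    cap = 10.0 * _free_period(field)
    E0, P0 = state.fields

    if field.is_lif:
        a = field.lif_a

        def resid(tau):
            return np.exp(-tau) * u1 + _chi_partials(tau, E0, P0, a, g, alpha)[0] - 1.0

        # bracket by doubling from a crude free-flight guess
        lo = 0.0
        hi = max((1.0 - u1) / max(field.evaluate(u1) + g * E0, 0.05), 1e-8)
        while resid(hi) < 0.0:
            lo, hi = hi, 2.0 * hi
            if hi > cap:
                raise NotFiringError(
                    f"neuron 1 (u={u1}) never reaches threshold within {cap:.3g} "
                    "time units: total drive is non-positive or g too negative")
        tau = brentq(resid, lo, hi, xtol=1e-15, rtol=4 * np.finfo(float).eps)
        if abs(resid(tau)) > _ISI_TOL:
            raise NotFiringError(f"threshold residual {resid(tau):.3e} exceeds {_ISI_TOL}")
        return float(tau)

    def rhs(t, y):
        return [field.evaluate(y[0]) + g * field_between(state.fields, t, alpha)]

    def hit(t, y):
        return y[0] - 1.0

    hit.terminal = True
    hit.direction = 1
    sol = solve_ivp(rhs, (0.0, cap), [u1], method="DOP853",
                    rtol=_ODE_RTOL, atol=_ODE_ATOL, events=hit, dense_output=False)
    if not sol.t_events[0].size:
        raise NotFiringError(
            f"neuron 1 (u={u1}) never reaches threshold within {cap:.3g} time units")
    return float(sol.t_events[0][0])


def advance_potentials(u: np.ndarray, fs: FieldState, tau: float,
                       field: VelocityField, g: float, alpha: float) -> np.ndarray:
    """Advance a vector of potentials over a time tau under the frozen field pair.

    LIF uses the closed form ``u' = e^{-tau} u + chi``; generic fields
    integrate all neurons simultaneously with a high-order adaptive scheme.
    """
    if field.is_lif:
        chi = lif_chi(tau, fs, field.lif_a, g, alpha)
        return np.exp(-tau) * u + chi
    if tau == 0.0:
        return u.copy()

    def rhs(t, y):
        return field.evaluate(y) + g * field_between(fs, t, alpha)

    sol = solve_ivp(rhs, (0.0, tau), np.asarray(u, dtype=float), method="DOP853",
                    rtol=_ODE_RTOL, atol=_ODE_ATOL)
    return sol.y[:, -1]


def step(state: NetworkState, field: VelocityField, g: float, alpha: float) -> NetworkState:
    """One application of the event-driven map (exactly one network spike).

    Solves the interspike time, advances every potential, applies the
    comoving shift (neuron 1 exits at threshold, the firing neuron re-enters
    at slot N with u = 0) and updates the field pair with the new-spike kick.
    """
    N = state.N
    tau = interspike_time(state, field, g, alpha)
    u_adv = advance_potentials(state.u, state.fields, tau, field, g, alpha)
    u_new = np.empty(N)
    u_new[: N - 1] = u_adv[1:]
    u_new[N - 1] = 0.0
    if np.any(np.diff(u_new[: N - 1]) >= 0) or (N > 1 and u_new[0] >= 1.0):
        d = np.diff(np.concatenate([[1.0], u_new[: N - 1]]))
        bad = int(np.argmax(d >= 0))
        raise OrderingError(
            f"neuron overtaking after step {state.spike_count}: slots {bad},{bad + 1}")
    fs_new = field_map(state.fields, tau, alpha, N)
    ids_new = np.roll(state.ids, -1)
    return NetworkState(u_new, fs_new, state.t + tau, state.spike_count + 1, ids_new)


def potential_update_series(u, fs: FieldState, tau: float,
                            field: VelocityField, g: float, alpha: float):
    """Truncated (fourth-order in tau) membrane update; validation path only.

    Taylor-expands the exact interval update in powers of tau, with the
    total drive ``Ftot = F(u) + g E`` and the field slope ``Edot = P - alpha E``
    entering the higher orders.  The defect relative to the exact update is
    O(tau^5).
    """
    u = np.asarray(u, dtype=float)
    E, P = fs
    Edot = P - alpha * E
    F = field.evaluate(u)
    F1 = field.derivative(1, u)
    F2 = field.derivative(2, u)
    F3 = field.derivative(3, u)
    Ftot = F + g * E
    c1 = Ftot
    c2 = g * Edot + F1 * Ftot
    c3 = F1 * (F1 * Ftot + g * Edot) + F2 * Ftot**2 - g * alpha * (P + Edot)
    c4 = (-g * alpha * (Edot + P) * F1
          + 4 * F1 * F2 * Ftot**2 + F1**3 * Ftot + F3 * Ftot**3
          + g * ((3 * F2 * Ftot + F1**2) * Edot + alpha**2 * (Edot + 2 * P)))
    return u + c1 * tau + c2 * tau**2 / 2 + c3 * tau**3 / 6 + c4 * tau**4 / 24


@dataclass
class SimulationResult:
    """Raster and trajectory summary of an event-driven run."""

    times: np.ndarray          # firing times
    neuron_ids: np.ndarray     # original label of the neuron firing at each time
    taus: np.ndarray           # interspike intervals
    final_state: NetworkState
    snapshots: list = dc_field(default_factory=list)  # optional (spike_index, u) pairs


def simulate(state0: NetworkState, field: VelocityField, g: float, alpha: float,
             n_spikes: int, record_potentials: bool = False,
             snapshot_every: int = 1) -> SimulationResult:
    """Iterate the event-driven map for ``n_spikes`` network spikes."""
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    state = state0.copy()
    times = np.empty(n_spikes)
    ids = np.empty(n_spikes, dtype=int)
    taus = np.empty(n_spikes)
    snaps = []
    for n in range(n_spikes):
        firing = state.ids[0]
        t_prev = state.t
        try:
            state = step(state, field, g, alpha)
        except (NotFiringError, OrderingError) as exc:
            raise type(exc)(f"at spike {n}: {exc}") from exc
        times[n] = state.t
        ids[n] = firing
        taus[n] = state.t - t_prev
        if record_potentials and n % snapshot_every == 0:
            snaps.append((n, state.u.copy()))
    return SimulationResult(times, ids, taus, state, snaps)
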