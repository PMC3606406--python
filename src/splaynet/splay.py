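"""Splay-state construction.

A splay state is the periodic regime in which all N neurons traverse the
same orbit with phases evenly staggered by T/N: the network fires at the
constant interspike interval ``tau = T/N`` and, in the comoving frame, the
state is a fixed point of the event-driven map.

This module provides

* the infinite-N period ``T0`` and potential profile ``U(x)``, ``x = j/N``;
* the tau-periodic fixed point of the field map;
* the finite-N fixed point, by generic shooting or exactly for LIF;
* the analytic O(1/N^4) finite-size period correction for LIF, whose
  lower orders (1/N, 1/N^2, 1/N^3) all vanish.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .dynamics import FieldState, _chi_partials, advance_potentials, field_map
from .exceptions import ExistenceError
from .fields import VelocityField

__all__ = [
    "SplayStateFiniteN",
    "SplayProfileInfinite",
    "field_fixed_point",
    "period_infinite",
    "profile_infinite",
    "conserved_quantity",
    "splay_finite",
    "lif_splay_exact",
    "K_alpha",
    "lif_delta_T",
]

_TAU_TOL = 1e-14      # tau accuracy needed to resolve 1/N^4 corrections at N=64
_SHOOT_TOL = 1e-12


@dataclass
class SplayStateFiniteN:
    """Finite-N splay fixed point of the event-driven map."""

    N: int
    tau: float                 # interspike interval
    u: np.ndarray              # potentials u_1 > ... > u_N = 0 (length N)
    E: float                   # tau-periodic field value
    P: float
    residual: float            # |u_0 - 1| achieved by the solver

    @property
    def T(self) -> float:
        """Single-neuron period N * tau."""
        return self.N * self.tau

    @property
    def fields(self) -> FieldState:
        return FieldState(self.E, self.P)

    def to_network_state(self):
        from .dynamics import NetworkState

        return NetworkState(self.u.copy(), self.fields)


@dataclass
class SplayProfileInfinite:
    """Thermodynamic-limit splay profile.

    ``U(x)`` is the decreasing potential profile with ``U(0) = 1`` and
    ``U(1) = 0``; ``H(x)`` is the cumulative field-slope integral
    ``int_0^x F'(U(y)) dy`` that appears in the Floquet eigenvectors.
    """

    T0: float
    U: Callable[[float], float]
    H: Callable[[float], float]
    grid: np.ndarray
    U_grid: np.ndarray
    H_grid: np.ndarray


def field_fixed_point(tau: float, alpha: float, N: int) -> FieldState:
    """Unique tau-periodic point of the field map.

    ``P = (alpha^2/N) / (1 - e^{-alpha tau})`` and
    ``E = tau P e^{-alpha tau} / (1 - e^{-alpha tau})``; both written with
    expm1 so large ``alpha tau`` cannot overflow.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    den = -np.expm1(-alpha * tau)  # 1 - e^{-alpha tau}
    P = (alpha**2 / N) / den
    E = tau * P * np.exp(-alpha * tau) / den
    return FieldState(float(E), float(P))


def period_infinite(field: VelocityField, g: float) -> float:
    """Infinite-N splay period ``T0``.

    Unique positive root of ``G(T) = int_0^1 du / (g + T F(u)) - 1``; the
    constraint ``g < 1`` is the existence condition (at T = 0 the one-period
    potential gain reduces to g).  LIF uses the equivalent transcendental
    form ``(a + g/T)(1 - e^{-T}) = 1``.
    """
    if g >= 1.0:
        raise ExistenceError(f"no splay state for g = {g} >= 1")
    # G is increasing in T with G(0+) = g - 1 < 0, so the root is unique
    if field.is_lif:
        a = field.lif_a

        def G(T):
            return (a + g / T) * (-np.expm1(-T)) - 1.0
    else:
        def G(T):
            # the one-period potential gain minus 1; g + T F(u) must stay positive
            val, _ = quad(lambda u: 1.0 / (g + T * field.evaluate(u)), 0.0, 1.0,
                          limit=200)
            return 1.0 - val

    # lower end of the admissible T range: g + T min(F) > 0
    if g < 0.0:
        fmin = float(np.min(field.evaluate(np.linspace(0.0, 1.0, 201))))
        T_lo = -g / fmin * (1.0 + 1e-10)
    else:
        T_lo = 1e-12
    T_hi = max(1.0, 2.0 * T_lo)
    while G(T_hi) < 0.0:
        T_hi *= 2.0
        if T_hi > 1e6:
            raise ExistenceError("period bracketing failed: no threshold crossing")
    if G(T_lo) > 0.0:
        raise ExistenceError("period bracketing failed at the lower end")
    return float(brentq(G, T_lo, T_hi, xtol=1e-15, rtol=4 * np.finfo(float).eps))


def profile_infinite(field: VelocityField, g: float, T0: Optional[float] = None,
                     grid: Optional[np.ndarray] = None) -> SplayProfileInfinite:
    """Thermodynamic-limit potential profile U(x) and slope integral H(x).

    U solves ``1 - x = int_0^U dv / (g + T0 F(v))`` (monotone root per grid
    point) and H is obtained by the change of variables y -> U(y):
    ``H(x) = int_{U(x)}^{1} F'(v) / (g + T0 F(v)) dv``.
    """
    if T0 is None:
        T0 = period_infinite(field, g)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)

    def cum(Uv):
        val, _ = quad(lambda v: 1.0 / (g + T0 * field.evaluate(v)), 0.0, Uv, limit=200)
        return val

    def U_of_x(x):
        if x <= 0.0:
            return 1.0
        if x >= 1.0:
            return 0.0
        return brentq(lambda Uv: cum(Uv) - (1.0 - x), 0.0, 1.0,
                      xtol=1e-15, rtol=4 * np.finfo(float).eps)

    def H_of_x(x):
        Ux = U_of_x(x)
        val, _ = quad(lambda v: field.derivative(1, v) / (g + T0 * field.evaluate(v)),
                      Ux, 1.0, limit=200)
        return val

    U_grid = np.array([U_of_x(x) for x in grid])
    H_grid = np.array([H_of_x(x) for x in grid])
    return SplayProfileInfinite(T0=float(T0), U=U_of_x, H=H_of_x,
                                grid=grid, U_grid=U_grid, H_grid=H_grid)


def conserved_quantity(profile: SplayProfileInfinite, field: VelocityField,
                       g: float, x: float) -> float:
    """Invariant ``C(x) = e^{T0 H(x)} (F(U(x)) + g/T0)`` of the splay profile.

    Constant in x; at x = 0 it reduces to the effective drive at threshold
    since H(0) = 0.
    """
    T0 = profile.T0
    return float(np.exp(T0 * profile.H(x)) * (field.evaluate(profile.U(x)) + g / T0))


# ----------------------------------------------------------------------
# finite N
# ----------------------------------------------------------------------

def _lif_u0_minus_1(tau, a, g, alpha, N):
    """Shooting residual for the exact LIF fixed point.

    Summing the geometric recursion u_{j-1} = e^{-tau} u_j + chi from
    u_N = 0 gives u_j = chi (1 - e^{(j-N) tau})/(1 - e^{-tau}); the period
    condition is u_0 = 1.
    """
    E, P = field_fixed_point(tau, alpha, N)
    chi = _chi_partials(tau, E, P, a, g, alpha)[0]
    return chi * (-np.expm1(-N * tau)) / (-np.expm1(-tau)) - 1.0


def _bracket_tau(resid, tau_guess, tau_max):
    """Locate a sign change of the shooting residual around a guess."""
    lo, hi = 0.2 * tau_guess, min(5.0 * tau_guess, tau_max)
    flo, fhi = resid(lo), resid(hi)
    tries = 0
    while flo * fhi > 0.0 and tries < 60:
        if abs(flo) < abs(fhi):
            lo *= 0.5
            flo = resid(lo)
        else:
            hi = min(2.0 * hi, tau_max)
            fhi = resid(hi)
            if hi == tau_max and flo * fhi > 0.0:
                break
        tries += 1
    if flo * fhi > 0.0:
        return None
    return lo, hi


def lif_splay_exact(a: float, g: float, alpha: float, N: int) -> SplayStateFiniteN:
    """Exact finite-N LIF splay state via the closed-form geometric sum."""
    if g >= 1.0:
        raise ExistenceError(f"no splay state for g = {g} >= 1")
    if N < 2:
        raise ValueError("N must be >= 2")
    lif = VelocityField(lambda u: a - np.asarray(u, float), label="lif", lif_a=a)
    T0 = period_infinite(lif, g)

    def resid(tau):
        return _lif_u0_minus_1(tau, a, g, alpha, N)

    br = _bracket_tau(resid, T0 / N, 50.0 / N)
    if br is None:
        raise ExistenceError(
            f"splay shooting not bracketed for LIF(a={a}), g={g}: boundary jump "
            f"{-1.0}, check g < 1")
    tau = brentq(resid, *br, xtol=_TAU_TOL, rtol=4 * np.finfo(float).eps)
    E, P = field_fixed_point(tau, alpha, N)
    chi = _chi_partials(tau, E, P, a, g, alpha)[0]
    j = np.arange(1, N + 1)
    u = chi * (1.0 - np.exp((j - N) * tau)) / (-np.expm1(-tau))
    u[-1] = 0.0
    return SplayStateFiniteN(N=N, tau=float(tau), u=u, E=E, P=P,
                             residual=abs(resid(tau)))


def splay_finite(field: VelocityField, g: float, alpha: float, N: int) -> SplayStateFiniteN:
    """Finite-N splay fixed point by shooting on the interspike interval.

    For a trial tau the field pair is set to its tau-periodic value and the
    one-interval membrane update is applied N times starting from u = 0; the
    residual is the terminal potential minus 1.  LIF delegates to the exact
    closed form.
    """
    if field.is_lif:
        return lif_splay_exact(field.lif_a, g, alpha, N)
    if g >= 1.0:
        raise ExistenceError(f"no splay state for g = {g} >= 1")
    if N < 2:
        raise ValueError("N must be >= 2")
    T0 = period_infinite(field, g)

    def march(tau):
        fs = field_fixed_point(tau, alpha, N)
        traj = np.empty(N + 1)
        traj[0] = 0.0
        u = np.array([0.0])
        for i in range(N):
            u = advance_potentials(u, fs, tau, field, g, alpha)
            traj[i + 1] = u[0]
        return traj

    def resid(tau):
        return march(tau)[-1] - 1.0

    br = _bracket_tau(resid, T0 / N, 50.0 / N)
    if br is None:
        raise ExistenceError(
            f"splay shooting not bracketed for {field.label}, g={g} "
            f"(boundary jump {field.boundary_jump})")
    tau = brentq(resid, *br, xtol=_TAU_TOL, rtol=4 * np.finfo(float).eps)
    traj = march(tau)
    # traj[i] = u_{N-i}; potentials u_1..u_N are traj[N-1], ..., traj[0]
    u = traj[:N][::-1].copy()
    u[-1] = 0.0
    E, P = field_fixed_point(tau, alpha, N)
    return SplayStateFiniteN(N=N, tau=float(tau), u=u, E=E, P=P,
                             residual=abs(traj[-1] - 1.0))


# ----------------------------------------------------------------------
# LIF finite-size period correction
# ----------------------------------------------------------------------

def K_alpha(alpha: float) -> float:
    """Pulse-shape constant of the fifth-order term of the LIF update.

    Expanding the exact interval gain chi(tau) (with the tau-periodic field
    values substituted) in powers of tau yields

        chi = (a + g/T)[tau - tau^2/2 + tau^3/6 - tau^4/24]
              + a tau^5/120 + (g/T) K(alpha) tau^5/720 + ...

    with ``K(alpha) = 6 - alpha^2 - 2 alpha^3``, a polynomial despite the
    (alpha - 1) denominators of chi (the singularity is removable).
    """
    return 6.0 - alpha**2 - 2.0 * alpha**3


def lif_delta_T(a: float, g: float, alpha: float, T0: float) -> float:
    """Coefficient ``T4`` of the leading LIF period correction T(N) = T0 + T4/N^4.

    ``T4 = -zeta(T0)/xi(T0)`` with

        zeta(T) = g T^3 (1 - e^{-T}) (K(alpha) - 6) / 720,
        xi(T)   = (a + g/T) e^{-T} - (g/T^2)(1 - e^{-T}),

    xi being the derivative of the period condition ``(a + g/T)(1 - e^{-T})``.
    The 1/N, 1/N^2 and 1/N^3 corrections vanish identically.
    """
    one_me = -np.expm1(-T0)
    zeta = g * T0**3 * one_me * (K_alpha(alpha) - 6.0) / 720.0
    xi = (a + g / T0) * np.exp(-T0) - (g / T0**2) * one_me
    if xi == 0.0:
        raise ZeroDivisionError("degenerate period equation: xi(T0) = 0")
    return float(-zeta / xi)


def verify_fixed_point(splay: SplayStateFiniteN, alpha: float) -> float:
    """Max field-pair defect after one tau-interval of the field map."""
    fs = splay.fields
    fs2 = field_map(fs, splay.tau, alpha, splay.N)
    return max(abs(fs2.E - fs.E), abs(fs2.P - fs.P))
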