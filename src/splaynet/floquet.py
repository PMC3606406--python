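"""Floquet stability analysis of the splay state.

The splay state is a fixed point of the event-driven map in the comoving
frame, so its Floquet multipliers are the eigenvalues of the one-step
Jacobian in the (N+1)-dimensional state ``(u_1, ..., u_{N-1}, E, P)``
(``u_N = 0`` is pinned by the reset).  Each multiplier is parametrised as

    mu_k = e^{i phi_k} e^{(lambda_k + i omega_k) tau},   phi_k = 2 pi k / N,

so lambda_k is a decay rate per unit time.  Two of the N+1 multipliers
belong to the field pair (both near ``e^{-alpha tau}``); the remaining
N-1 form the membrane branch, whose short-wavelength (SW) part — finite
phase phi_k — admits the closed form

    lambda_k = (g alpha^2 / 12) (F(1) - F(0)) / (Ftot(1) Ftot(0))
               * (6/(1 - cos phi_k) - 1) / N^2,

with ``Ftot(v) = F(v) + g/T0`` the effective drive.  The spectrum thus
scales as 1/N^2 and its sign is fixed by ``g (F(1) - F(0))``: an excitatory
network is stable whenever the drive at reset exceeds the drive at
threshold.  In the crossover regime ``1 << k << N`` the exponents become
N-independent and proportional to 1/k^2.

Three routes to the Jacobian are provided: exact closed-form derivatives
for LIF (preferred), centred finite differences of the full event-driven
step for generic fields, and a truncated (third-order in tau) tangent map
assembled from the series expansion of the interval update, used as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import NetworkState, _chi_partials, step
from .exceptions import SpectrumError
from .fields import VelocityField
from .splay import SplayStateFiniteN

__all__ = [
    "FloquetSpectrum",
    "jacobian_numeric",
    "jacobian_lif_analytic",
    "tangent_map_series",
    "multipliers_to_exponents",
    "spectrum",
    "analytic_sw",
    "lif_gamma3",
    "analytic_crossover",
    "stability_verdict",
]


@dataclass
class FloquetSpectrum:
    """Per-mode Floquet records of a size-N splay state.

    The membrane branch carries mode indices k = 1..N-1 with zeroth-order
    phases phi_k = 2 pi k/N; ``branch`` distinguishes the two field modes
    ("field") from the membrane modes ("SW" for phi_k in the interior,
    "crossover" for k or N-k of order one).
    """

    k: np.ndarray
    phi: np.ndarray
    multipliers: np.ndarray    # complex mu_k, membrane branch
    lam: np.ndarray            # Re Floquet exponent per unit time
    omega: np.ndarray          # Im Floquet exponent per unit time
    field_multipliers: np.ndarray  # the two field-branch multipliers
    N: int
    T: float

    @property
    def tau(self) -> float:
        return self.T / self.N

    def branch(self, sw_frac: float = 0.1) -> np.ndarray:
        """Label modes 'SW' or 'crossover' by the fraction k/N."""
        frac = self.k / self.N
        return np.where((frac >= sw_frac) & (frac <= 1 - sw_frac), "SW", "crossover")

    def sw_mask(self, sw_frac: float = 0.1) -> np.ndarray:
        frac = self.k / self.N
        return (frac >= sw_frac) & (frac <= 1 - sw_frac)

    @property
    def max_lam(self) -> float:
        """Leading (least stable) membrane exponent."""
        return float(np.max(self.lam))


# ----------------------------------------------------------------------
# Jacobians
# ----------------------------------------------------------------------

def _pack(state: NetworkState) -> np.ndarray:
    return np.concatenate([state.u[:-1], [state.fields.E, state.fields.P]])


def _unpack(y: np.ndarray, N: int) -> NetworkState:
    from .dynamics import FieldState

    u = np.concatenate([y[: N - 1], [0.0]])
    return NetworkState(u, FieldState(y[N - 1], y[N]))


def one_step_map(y: np.ndarray, field: VelocityField, g: float, alpha: float,
                 N: int) -> np.ndarray:
    """Event-driven step as a plain vector map on (u_1..u_{N-1}, E, P)."""
    return _pack(step(_unpack(y, N), field, g, alpha))


def jacobian_numeric(splay: SplayStateFiniteN, field: VelocityField, g: float,
                     alpha: float, h: float = 1e-6,
                     richardson: bool = False) -> np.ndarray:
    """Centred finite-difference Jacobian of the event-driven step.

    The interspike time is a dependent quantity (re-solved from the
    threshold condition at every perturbed evaluation), so the differenced
    map is exactly the return map whose eigenvalues are the Floquet
    multipliers.  ``richardson=True`` combines steps h and h/2 for two
    extra orders of accuracy.
    """
    if splay.residual > 1e-11:
        raise ValueError(f"splay residual {splay.residual:.2e} too large for a clean Jacobian")
    y0 = _pack(splay.to_network_state())
    n = y0.size

    def jac_at(hh):
        J = np.empty((n, n))
        for i in range(n):
            hi = hh * max(1.0, abs(y0[i]))
            yp, ym = y0.copy(), y0.copy()
            yp[i] += hi
            ym[i] -= hi
            try:
                fp = one_step_map(yp, field, g, alpha, splay.N)
                fm = one_step_map(ym, field, g, alpha, splay.N)
            except Exception as exc:
                raise RuntimeError(f"perturbed step failed at coordinate {i}: {exc}") from exc
            J[:, i] = (fp - fm) / (2 * hi)
        return J

    J = jac_at(h)
    if richardson:
        J = (4.0 * jac_at(h / 2) - J) / 3.0
    return J


def jacobian_lif_analytic(splay: SplayStateFiniteN, a: float, g: float,
                          alpha: float) -> np.ndarray:
    """Exact one-step Jacobian for the LIF closed-form map.

    Differentiates ``u'_{j-1} = e^{-tau} u_j + chi(tau, E, P)`` and the field
    map, with ``d tau`` eliminated through the threshold identity
    ``e^{-tau} u_1 + chi = 1``; the common divisor is the velocity of the
    firing neuron at threshold.
    """
    N, tau = splay.N, splay.tau
    E, P = splay.E, splay.P
    chi, chi_E, chi_P, chi_tau = _chi_partials(tau, E, P, a, g, alpha)
    em = np.exp(-tau)
    u = splay.u
    # d(threshold)/dtau = velocity of neuron 1 when it hits u = 1
    D = -em * u[0] + chi_tau
    dt_du1, dt_dE, dt_dP = -em / D, -chi_E / D, -chi_P / D

    M = np.zeros((N + 1, N + 1))
    # rows 0..N-2: images u'_{j-1} for j = 2..N; u_N = 0 so its row has no u-dependence
    for r, j in enumerate(range(2, N + 1)):
        uj = u[j - 1]
        dd = -em * uj + chi_tau          # d u'_{j-1} / d tau
        if j <= N - 1:
            M[r, j - 1] = em
        M[r, 0] += dd * dt_du1
        M[r, N - 1] = chi_E + dd * dt_dE
        M[r, N] = chi_P + dd * dt_dP
    ea = np.exp(-alpha * tau)
    dE_dtau = (P - alpha * (E + tau * P)) * ea
    dP_dtau = -alpha * P * ea
    M[N - 1, 0] = dE_dtau * dt_du1
    M[N - 1, N - 1] = ea + dE_dtau * dt_dE
    M[N - 1, N] = tau * ea + dE_dtau * dt_dP
    M[N, 0] = dP_dtau * dt_du1
    M[N, N - 1] = dP_dtau * dt_dE
    M[N, N] = ea + dP_dtau * dt_dP
    return M


def tangent_map_series(splay: SplayStateFiniteN, field: VelocityField, g: float,
                       alpha: float) -> np.ndarray:
    """Third-order (in tau) truncated tangent map; cross-validation path.

    Differentiates the series interval update around the splay fixed point.
    The per-slot coefficients multiply (du_j, dE, dEdot, dtau) with
    dEdot = dP - alpha dE; dtau is eliminated via the pinned image
    ``u'_0 = 1`` of the firing neuron.  Its spectrum converges to the exact
    one as N grows (relative defect O(1/N^2)).
    """
    N, tau = splay.N, splay.tau
    E, P = splay.E, splay.P
    Edot = P - alpha * E
    u = splay.u
    # coefficients evaluated at every slot j = 1..N (index j-1)
    F = field.evaluate(u)
    F1 = field.derivative(1, u)
    F2 = field.derivative(2, u)
    F3 = field.derivative(3, u)
    Ft = F + g * E

    W1 = 1.0 + F1 * tau + (F2 * Ft + F1**2) * tau**2 / 2 \
        + (F3 * Ft**2 + F2 * (4 * F1 * Ft + g * Edot) + F1**3) * tau**3 / 6
    W2 = g * tau + g * F1 * tau**2 / 2 + g * (2 * F2 * Ft + F1**2) * tau**3 / 6
    W3 = g * tau**2 / 2 + g * (F1 - alpha) * tau**3 / 6
    W4 = Ft + (g * Edot + F1 * Ft) * tau \
        + (F2 * Ft**2 + F1**2 * Ft + F1 * g * Edot - g * alpha * (Edot + P)) * tau**2 / 2 \
        + (-g * alpha * (Edot + P) * F1 + 4 * F1 * F2 * Ft**2 + F1**3 * Ft
           + g * ((3 * F2 * Ft + F1**2) * Edot + alpha**2 * (Edot + 2 * P))
           + F3 * Ft**3) * tau**3 / 6

    # truncated field-map coefficients
    at = alpha * tau
    Z1 = 1 - at + at**2 / 2 - at**3 / 6 + at**4 / 24
    Z2 = alpha * (-1 + at - at**2 / 2 + at**3 / 6)
    Z3 = tau * (1 - at + at**2 / 2 - at**3 / 6)
    Z4 = 1 - 2 * at + 1.5 * at**2 - (2.0 / 3.0) * at**3 + (5.0 / 24.0) * at**4

    # dtau from the pinned firing-neuron image (slot 1, index 0)
    cu, cE, cD = W1[0] / W4[0], W2[0] / W4[0], W3[0] / W4[0]
    # dtau = -(cu du_1 + cE dE + cD dEdot); dEdot = dP - alpha dE
    t_u1, t_E, t_P = -cu, -(cE - alpha * cD), -cD

    M = np.zeros((N + 1, N + 1))
    for r, j in enumerate(range(2, N + 1)):
        i = j - 1  # coefficient index for slot j
        if j <= N - 1:
            M[r, j - 1] = W1[i]
        M[r, 0] += W4[i] * t_u1
        M[r, N - 1] = W2[i] - alpha * W3[i] + W4[i] * t_E
        M[r, N] = W3[i] + W4[i] * t_P
    cE_field = P * Z4 - alpha * E * Z1
    M[N - 1, 0] = cE_field * t_u1
    M[N - 1, N - 1] = Z1 + cE_field * t_E
    M[N - 1, N] = Z3 + cE_field * t_P
    M[N, 0] = P * Z2 * t_u1
    M[N, N - 1] = P * Z2 * t_E
    M[N, N] = Z1 + P * Z2 * t_P
    return M


# ----------------------------------------------------------------------
# multipliers -> exponents
# ----------------------------------------------------------------------

def multipliers_to_exponents(mus, T: float, N: int) -> FloquetSpectrum:
    """Sort N+1 multipliers into field and membrane branches and extract exponents.

    The two field multipliers are the pair nearest ``e^{-alpha T_step}`` —
    identified simply as the pair farthest inside the unit disk, since the
    membrane branch hugs the unit circle.  Each remaining multiplier is
    assigned the mode k whose phase 2 pi k/N is nearest its argument;
    ``lambda_k = (N/T) ln|mu_k|`` and ``omega_k`` is the residual phase per
    unit time, wrapped to (-pi/tau, pi/tau].
    """
    mus = np.asarray(mus, dtype=complex)
    if mus.size < 3:
        raise ValueError("need at least N+1 = 3 multipliers")
    n_total = mus.size
    N_eff = n_total - 1
    if N_eff != N:
        raise ValueError(f"expected {N + 1} multipliers for N={N}, got {n_total}")
    tau = T / N
    # field branch: the two smallest |mu| (membrane modes have |mu| ~ 1)
    order = np.argsort(np.abs(mus))
    field_mus = mus[order[:2]]
    rest = mus[order[2:]]
    ang = np.angle(rest)
    ang = np.where(ang < np.pi / N, ang + 2 * np.pi, ang)  # map to (pi/N, 2 pi + ...)
    ks = np.rint(ang * N / (2 * np.pi)).astype(int)
    vals, counts = np.unique(ks, return_counts=True)
    if np.any(counts > 1):
        dup = int(vals[counts > 1][0])
        raise SpectrumError(
            f"two multipliers map to the same mode k={dup}: N too small or "
            "splay state not converged")
    srt = np.argsort(ks)
    ks, rest = ks[srt], rest[srt]
    phi = 2 * np.pi * ks / N
    lam = np.log(np.abs(rest)) / tau
    omega = np.angle(rest * np.exp(-1j * phi)) / tau
    return FloquetSpectrum(k=ks, phi=phi, multipliers=rest, lam=lam, omega=omega,
                           field_multipliers=field_mus, N=N, T=T)


def spectrum(splay: SplayStateFiniteN, field: VelocityField, g: float, alpha: float,
             method: str = "auto") -> FloquetSpectrum:
    """Full numerical Floquet spectrum of a splay state.

    ``method``: "analytic" (exact LIF Jacobian), "numeric" (finite
    differences through the event-driven step), "series" (truncated tangent
    map) or "auto" (analytic for LIF, numeric otherwise).
    """
    if method == "auto":
        method = "analytic" if field.is_lif else "numeric"
    if method == "analytic":
        if not field.is_lif:
            raise ValueError("analytic Jacobian is available only for the LIF field")
        J = jacobian_lif_analytic(splay, field.lif_a, g, alpha)
    elif method == "numeric":
        J = jacobian_numeric(splay, field, g, alpha,
                             richardson=not field.is_lif)
    elif method == "series":
        J = tangent_map_series(splay, field, g, alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    mus = np.linalg.eigvals(J)
    return multipliers_to_exponents(mus, splay.T, splay.N)


# ----------------------------------------------------------------------
# analytic spectra
# ----------------------------------------------------------------------

def analytic_sw(F_at_threshold: float, F_at_reset: float, g: float, alpha: float,
                T0: float, N: int, k, denominator: str = "effective"):
    """Leading short-wavelength Floquet exponent.

    ``lambda_k = (g alpha^2/12) (F(1)-F(0)) / (D(1) D(0)) (6/(1-cos phi_k) - 1) / N^2``
    where D is the effective drive ``F + g/T0`` by default (``denominator=
    "effective"``); ``"bare"`` uses the uncoupled F values instead.  The
    imaginary part vanishes at this order.
    """
    k = np.asarray(k)
    if np.any((k < 1) | (k > N - 1)):
        raise ValueError("mode index k must lie in 1..N-1")
    phi = 2 * np.pi * k / N
    if denominator == "effective":
        den = (F_at_threshold + g / T0) * (F_at_reset + g / T0)
    elif denominator == "bare":
        den = F_at_threshold * F_at_reset
    else:
        raise ValueError("denominator must be 'effective' or 'bare'")
    out = (g * alpha**2 / 12.0) * (F_at_threshold - F_at_reset) / den \
        * (6.0 / (1.0 - np.cos(phi)) - 1.0) / N**2
    return out if out.ndim else float(out)


def lif_gamma3(a: float, g: float, alpha: float, T0: float, k, N: int):
    """Third-order LIF spectral coefficient Gamma3 (lambda_k = Gamma3/(T0 N^2)).

    ``Gamma3 = (g alpha^2 T0/12)(2 - e^{T0} - e^{-T0})(6/(1 - cos phi_k) - 1)``;
    uses the LIF identity ``1/(Ftot(1) Ftot(0)) = e^{T0} + e^{-T0} - 2`` that
    follows from the period condition, together with F(1) - F(0) = -1.
    """
    k = np.asarray(k)
    phi = 2 * np.pi * k / N
    out = (g * alpha**2 * T0 / 12.0) * (2.0 - np.exp(T0) - np.exp(-T0)) \
        * (6.0 / (1.0 - np.cos(phi)) - 1.0)
    return out if out.ndim else float(out)


def analytic_crossover(F_at_threshold: float, F_at_reset: float, g: float,
                       alpha: float, T0: float, k,
                       denominator: str = "effective"):
    """N-independent crossover exponent, valid for 1 << k << N.

    Small-phase limit of the SW formula: ``lambda_k = g alpha^2/(4 pi^2 k^2)
    * (F(1)-F(0)) / (D(1) D(0))``.
    """
    k = np.asarray(k)
    if np.any(k < 1):
        raise ValueError("mode index k must be >= 1")
    if denominator == "effective":
        den = (F_at_threshold + g / T0) * (F_at_reset + g / T0)
    elif denominator == "bare":
        den = F_at_threshold * F_at_reset
    else:
        raise ValueError("denominator must be 'effective' or 'bare'")
    out = g * alpha**2 / (4 * np.pi**2 * k**2) * (F_at_threshold - F_at_reset) / den
    return out if out.ndim else float(out)


def stability_verdict(field: VelocityField, g: float) -> str:
    """Sign rule for the SW branch: stable iff ``g (F(1) - F(0)) < 0``.

    Excitatory networks (g > 0) are stable when the drive at reset exceeds
    the drive at threshold; inhibitory networks when it is the other way
    round.  A continuous field (or g = 0) is marginal.  Long-wavelength
    instabilities are outside the scope of this rule.
    """
    s = g * field.boundary_jump
    if s < 0:
        return "stable"
    if s > 0:
        return "unstable"
    return "marginal"
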