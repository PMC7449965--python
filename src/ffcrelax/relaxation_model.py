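"""Relaxation model for tissue ¹H dispersion profiles.

The total spin–lattice relaxation rate is split into two dipolar
contributions,

    R₁(ν_H) = R₁ᴴᴴ(ν_H) + R₁ᴴᴺ(ν_H),

where R₁ᴴᴴ is a "model-free" sum of three Lorentzian spectral-density
terms (slow / intermediate / fast molecular motions, each with a dipolar
constant C and a correlation time τ) plus a frequency-independent offset
A, and R₁ᴴᴺ is the ¹H–¹⁴N quadrupole relaxation enhancement (QRE): six
Lorentzians centred at the ¹⁴N quadrupole transition frequencies ±ν₋,
±ν₊, ±ν₀, producing the "quadrupole peaks" seen near 2–3 MHz in protein-
rich tissues.

Conventions
-----------
All public interfaces take *linear* frequency ν in Hz; the angular
frequency ω = 2πν is internal and applied uniformly, including to the
quadrupole transition frequencies (ω± = 2πν±).  Distances cross the
interface in Å, quadrupole amplitudes a_Q = e²qQ/h in Hz, angles in
degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysConstants",
    "CONSTANTS",
    "HHParams",
    "QREParams",
    "RelaxationParams",
    "TransitionFrequencies",
    "lorentzian_pair",
    "r1_hh",
    "dipolar_constant",
    "transition_frequencies",
    "angular_weights",
    "r1_hn",
    "r1_total",
]

_ANGSTROM = 1e-10


@dataclass(frozen=True)
class PhysConstants:
    """CODATA physical constants used in the dipolar prefactors.

    ``gamma_n`` is the ¹⁴N gyromagnetic ratio; it is positive (unlike ¹⁵N)
    and in any case only |γ_N| matters here because γ_N enters squared.
    """

    gamma_h: float = 2.6752218744e8  # rad s⁻¹ T⁻¹, ¹H
    gamma_n: float = 1.9337792e7  # rad s⁻¹ T⁻¹, ¹⁴N
    mu0: float = 1.25663706212e-6  # N A⁻²
    hbar: float = 1.054571817e-34  # J s


CONSTANTS = PhysConstants()


@dataclass(frozen=True)
class HHParams:
    """Parameters of the three-process ¹H–¹H model-free term.

    ``c_s``, ``c_i``, ``c_f`` are dipolar relaxation constants (s⁻²) of the
    slow/intermediate/fast processes, ``tau_s > tau_i > tau_f`` their
    correlation times (s), and ``a`` the frequency-independent offset
    (s⁻¹) gathering dynamics on the ns scale or faster.
    """

    c_s: float
    c_i: float
    c_f: float
    tau_s: float
    tau_i: float
    tau_f: float
    a: float

    def __post_init__(self) -> None:
        for name in ("c_s", "c_i", "c_f", "tau_s", "tau_i", "tau_f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"HHParams.{name} must be > 0")
        if not self.a >= 0:
            raise ValueError("HHParams.a must be >= 0")
        if not (self.tau_s > self.tau_i > self.tau_f):
            raise ValueError(
                "correlation times must satisfy tau_s > tau_i > tau_f, got "
                f"{self.tau_s:g} / {self.tau_i:g} / {self.tau_f:g}"
            )


@dataclass(frozen=True)
class QREParams:
    """Parameters of the ¹H–¹⁴N quadrupole relaxation enhancement term.

    ``a_q`` (Hz) and ``eta`` (dimensionless, [0, 1]) are the amplitude
    e²qQ/h and asymmetry of the ¹⁴N quadrupole coupling; ``tau_q`` (s) is
    the correlation time of the ¹H–¹⁴N coupling fluctuations; ``theta``
    and ``phi`` (degrees) orient the ¹H–¹⁴N axis in the electric-field-
    gradient frame; ``r_hn`` (Å) is the effective ¹H–¹⁴N distance.
    """

    a_q: float
    eta: float
    tau_q: float
    theta: float
    phi: float
    r_hn: float

    def __post_init__(self) -> None:
        if not self.a_q > 0:
            raise ValueError("QREParams.a_q must be > 0")
        if not 0 <= self.eta <= 1:
            raise ValueError("QREParams.eta must be in [0, 1]")
        if not self.tau_q > 0:
            raise ValueError("QREParams.tau_q must be > 0")
        if not self.r_hn > 0:
            raise ValueError("QREParams.r_hn must be > 0")
        if not 0 <= self.theta <= 180:
            raise ValueError("QREParams.theta must be in [0, 180] degrees")
        if not 0 <= self.phi <= 360:
            raise ValueError("QREParams.phi must be in [0, 360] degrees")


@dataclass(frozen=True)
class RelaxationParams:
    """Full parameter vector: HH term plus optional QRE term.

    ``qre`` is ``None`` for tissues without quadrupole peaks (adipose
    tissue in practice), in which case R₁ = R₁ᴴᴴ exactly.
    """

    hh: HHParams
    qre: QREParams | None = None


@dataclass(frozen=True)
class TransitionFrequencies:
    """¹⁴N quadrupole energy levels (frequency units) and transitions."""

    nu_minus: float
    nu_plus: float
    nu_zero: float
    e1: float
    e2: float
    e3: float


def lorentzian_pair(omega, tau: float):
    """Spectral-density pair  τ/(1+ω²τ²) + 4τ/(1+4ω²τ²).

    ``omega`` is angular frequency in rad/s (scalar or array); at ω = 0
    the value is 5τ.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    omega = np.asarray(omega, dtype=float)
    wt2 = (omega * tau) ** 2
    return tau / (1.0 + wt2) + 4.0 * tau / (1.0 + 4.0 * wt2)


def r1_hh(nu_h, p: HHParams):
    """¹H–¹H model-free relaxation rate at proton Larmor frequency ν_H (Hz).

    Strictly decreasing in ν_H; tends to 5(C_sτ_s + C_iτ_i + C_fτ_f) + A
    at zero field and to A at infinite field.
    """
    omega = 2.0 * np.pi * np.asarray(nu_h, dtype=float)
    return (
        p.c_s * lorentzian_pair(omega, p.tau_s)
        + p.c_i * lorentzian_pair(omega, p.tau_i)
        + p.c_f * lorentzian_pair(omega, p.tau_f)
        + p.a
    )


def dipolar_constant(r_hh: float, constants: PhysConstants = CONSTANTS) -> float:
    """Dipolar constant Cᴴᴴ = (3/10)·(μ₀/4π · γ_H²ħ / r³)² for r in Å.

    ``r_hh`` is the effective inter-proton distance accounting for
    dipole–dipole interactions over several proton pairs; Cᴴᴴ falls as r⁻⁶.
    """
    if not r_hh > 0:
        raise ValueError("r_hh must be > 0")
    r = r_hh * _ANGSTROM
    k = (constants.mu0 / (4 * math.pi)) * constants.gamma_h**2 * constants.hbar / r**3
    return 0.3 * k**2


def transition_frequencies(a_q: float, eta: float) -> TransitionFrequencies:
    """¹⁴N quadrupole transition frequencies for amplitude a_Q (Hz), asymmetry η.

    Energy levels (frequency units): E₁ = ¼a_Q(1−η), E₂ = −½a_Q,
    E₃ = ¼a_Q(1+η); transitions ν₋ = ¾a_Q(1−η/3), ν₊ = ¾a_Q(1+η/3),
    ν₀ = ν₊ − ν₋ = ½ηa_Q.
    """
    if not a_q > 0:
        raise ValueError("a_q must be > 0")
    if not 0 <= eta <= 1:
        raise ValueError("eta must be in [0, 1]")
    e1 = 0.25 * a_q * (1.0 - eta)
    e2 = -0.5 * a_q
    e3 = 0.25 * a_q * (1.0 + eta)
    nu_minus = e1 - e2  # = 3/4 a_q (1 - eta/3)
    nu_plus = e3 - e2  # = 3/4 a_q (1 + eta/3)
    nu_zero = nu_plus - nu_minus  # = 1/2 eta a_q
    return TransitionFrequencies(nu_minus, nu_plus, nu_zero, e1, e2, e3)


def angular_weights(theta: float, phi: float) -> tuple[float, float, float]:
    """Geometric weights of the ν₋, ν₊, ν₀ lines; they always sum to 2.

    ``theta``/``phi`` in degrees orient the ¹H–¹⁴N dipole–dipole axis in
    the principal axis system of the electric field gradient at ¹⁴N.
    """
    t = math.radians(theta)
    f = math.radians(phi)
    w_minus = 1.0 / 3.0 + math.sin(t) ** 2 * math.cos(f) ** 2
    w_plus = 1.0 / 3.0 + math.sin(t) ** 2 * math.sin(f) ** 2
    w_zero = 1.0 / 3.0 + math.cos(t) ** 2
    return w_minus, w_plus, w_zero


def r1_hn(nu_h, q: QREParams, constants: PhysConstants = CONSTANTS):
    """¹H–¹⁴N QRE relaxation rate at ν_H (Hz).

    Six Lorentzians of width 1/τ_Q centred at ±ω₋, ±ω₊, ±ω₀ with the
    angular weights from :func:`angular_weights`; local maxima sit near
    ν₋ and ν₊ (the quadrupole peaks).  Non-negative everywhere and → 0 as
    r_HN → ∞ or τ_Q → 0.
    """
    tf = transition_frequencies(q.a_q, q.eta)
    w_minus, w_plus, w_zero = angular_weights(q.theta, q.phi)
    omega = 2.0 * np.pi * np.asarray(nu_h, dtype=float)
    r = q.r_hn * _ANGSTROM
    pref = (
        (constants.mu0 / (4 * math.pi))
        * constants.gamma_h
        * constants.gamma_n
        * constants.hbar
        / r**3
    )
    pref = (2.0 / 3.0) * pref**2
    tq = q.tau_q

    def pair(nu_line: float):
        wl = 2.0 * np.pi * nu_line
        return tq / (1.0 + (omega - wl) ** 2 * tq**2) + tq / (
            1.0 + (omega + wl) ** 2 * tq**2
        )

    bracket = (
        w_minus * pair(tf.nu_minus) + w_plus * pair(tf.nu_plus) + w_zero * pair(tf.nu_zero)
    )
    return pref * bracket


def r1_total(nu_h, p: RelaxationParams):
    """Total rate R₁ = R₁ᴴᴴ + R₁ᴴᴺ (QRE term omitted when ``p.qre`` is None)."""
    out = r1_hh(nu_h, p.hh)
    if p.qre is not None:
        out = out + r1_hn(nu_h, p.qre)
    return out
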