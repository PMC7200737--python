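"""Theoretical backbone amide 15N relaxation rates.

Rates for an isolated 1H-15N spin pair with an axially symmetric 15N CSA
tensor, evaluated on a Lipari-Szabo (model-free) spectral density in the
tau_e -> 0 limit,

    J(omega) = (2/5) S^2 tau_c / (1 + (omega tau_c)^2).

The six rates are the longitudinal 15N rate R1(Nz), the in-phase and
anti-phase transverse rates R2(N+) and R2(N+Hz), the selective proton
longitudinal rate R1,sel(Hz) (dipolar interactions of the amide proton with
its neighbours at an effective distance r_HH), the transverse
dipole/15N-CSA cross-correlation rate eta, and the TROSY rate of the narrow
15N doublet component,

    R2(N+Hbeta, TROSY) = (R2(N+) + R2(N+Hz) + R1,sel(Hz)) / 2 - eta.

Prefactors follow the standard Abragam convention with the dipolar coupling
d = (mu0/4pi) hbar gammaH gammaN / r_NH^3 and the CSA coupling
c = |gammaN| B0 dsigma / sqrt(3).  gammaN is negative; magnitudes are used
throughout and eta carries the sign convention under which a positive eta
(theta below the magic angle) narrows the TROSY line.

Public API units: Angstrom, ns, ppm, MHz, Tesla, s^-1.  SI internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger("gpcrdyn")

# ---------------------------------------------------------------------------
# Physical constants (CODATA 2018)
# ---------------------------------------------------------------------------

GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7126180e7    # 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
MU_0 = 1.25663706212e-6   # vacuum permeability, N A^-2
H_PLANCK = 6.62607015e-34  # Planck constant, J s
HBAR = H_PLANCK / (2.0 * math.pi)
K_BOLTZMANN = 1.380649e-23  # J K^-1
N_AVOGADRO = 6.02214076e23  # mol^-1

MAGIC_ANGLE_DEG = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356...

#: Search bracket for tau_c root finding, restricted to the slow-tumbling
#: branch where the rate expressions are monotonic in tau_c.
TAUC_BRACKET_NS = (5.0, 200.0)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinParams:
    """Model parameters of one backbone amide spin system.

    Parameters
    ----------
    tau_c : float
        Isotropic rotational correlation time in ns.
    r_nh : float
        N-H bond length in Angstrom.
    r_hh : float
        Effective H-H distance in Angstrom lumping the dipolar interactions
        of the amide proton with all adjacent protons in helical structure.
    s2 : float
        Lipari-Szabo order parameter (dimensionless).
    delta_sigma_n : float
        15N chemical-shift anisotropy in ppm.
    delta_sigma_hn : float
        1H CSA in ppm. Carried for completeness; it enters none of the six
        rate expressions implemented here.
    theta : float
        Angle between the unique axes of the 15N CSA and N-H dipolar
        tensors, in degrees.
    """

    tau_c: float
    r_nh: float = 1.02
    r_hh: float = 2.05
    s2: float = 0.85
    delta_sigma_n: float = 170.0
    delta_sigma_hn: float = 15.0
    theta: float = 20.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.tau_c, self.r_nh, self.r_hh,
                                       self.s2, self.delta_sigma_n,
                                       self.delta_sigma_hn, self.theta))):
            raise ValueError("SpinParams fields must be finite")
        if self.tau_c <= 0:
            raise ValueError(f"tau_c must be > 0 ns, got {self.tau_c}")
        if self.r_nh <= 0 or self.r_hh <= 0:
            raise ValueError("bond lengths must be > 0 Angstrom")
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError(f"S2 must lie in [0, 1], got {self.s2}")
        if not 0.0 <= self.theta <= 90.0:
            raise ValueError(f"theta must lie in [0, 90] deg, got {self.theta}")

    def with_tau_c(self, tau_c: float) -> "SpinParams":
        return replace(self, tau_c=tau_c)


@dataclass(frozen=True)
class FieldConditions:
    """Static field and derived Larmor frequencies.

    nu_h and nu_n are 1H and 15N Larmor frequencies in MHz (magnitudes),
    derived from B0 when not given.
    """

    b0: float
    nu_h: float = field(default=None)  # type: ignore[assignment]
    nu_n: float = field(default=None)  # type: ignore[assignment]
    temperature: float = 304.0

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError(f"B0 must be > 0 T, got {self.b0}")
        nu_h = GAMMA_H * self.b0 / (2e6 * math.pi)
        nu_n = abs(GAMMA_N) * self.b0 / (2e6 * math.pi)
        if self.nu_h is None:
            object.__setattr__(self, "nu_h", nu_h)
        elif abs(self.nu_h / nu_h - 1.0) > 1e-3:
            raise ValueError(
                f"nu_h={self.nu_h} MHz inconsistent with B0={self.b0} T "
                f"(expected {nu_h:.2f} MHz)")
        if self.nu_n is None:
            object.__setattr__(self, "nu_n", nu_n)
        elif abs(self.nu_n / nu_n - 1.0) > 1e-3:
            raise ValueError(
                f"nu_n={self.nu_n} MHz inconsistent with B0={self.b0} T "
                f"(expected {nu_n:.2f} MHz)")

    @classmethod
    def from_nu_h(cls, nu_h_mhz: float, temperature: float = 304.0
                  ) -> "FieldConditions":
        """Construct from the nominal 1H frequency in MHz (600/800/900...)."""
        b0 = 2e6 * math.pi * nu_h_mhz / GAMMA_H
        return cls(b0=b0, temperature=temperature)

    @property
    def omega_h(self) -> float:
        """1H angular Larmor frequency magnitude, rad/s."""
        return 2e6 * math.pi * self.nu_h

    @property
    def omega_n(self) -> float:
        """15N angular Larmor frequency magnitude, rad/s."""
        return 2e6 * math.pi * self.nu_n


@dataclass(frozen=True)
class RateSet:
    """The six theoretical rates at one field, all in s^-1."""

    R1: float
    R2_inphase: float
    R2_antiphase: float
    R1sel_H: float
    eta: float
    R2_trosy: float

    def identity_residual(self) -> float:
        """Residual of the TROSY combination identity (zero by construction)."""
        return self.R2_trosy - (
            (self.R2_inphase + self.R2_antiphase + self.R1sel_H) / 2.0
            - self.eta)


# ---------------------------------------------------------------------------
# Spectral density and coupling constants
# ---------------------------------------------------------------------------

def spectral_density(omega: float, tau_c: float, s2: float) -> float:
    """Lipari-Szabo spectral density J(omega) in s (tau_e -> 0 limit).

    Parameters are angular frequency in rad/s, correlation time in s and
    the order parameter S^2.
    """
    omega = np.asarray(omega, dtype=float)
    if not (np.all(np.isfinite(omega)) and math.isfinite(tau_c)
            and math.isfinite(s2)):
        raise ValueError("non-finite input to spectral_density")
    if tau_c <= 0:
        raise ValueError("tau_c must be > 0")
    j = 0.4 * s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    return float(j) if j.ndim == 0 else j


def _dipolar_coupling(gamma_a: float, gamma_b: float, r_angstrom: float
                      ) -> float:
    """d = (mu0/4pi) hbar gamma_a gamma_b / r^3 in rad/s (magnitudes)."""
    r = r_angstrom * 1e-10
    return MU_0 / (4.0 * math.pi) * HBAR * abs(gamma_a) * abs(gamma_b) / r ** 3


def _csa_coupling(b0: float, delta_sigma_ppm: float) -> float:
    """c = |gammaN| B0 dsigma / sqrt(3) in rad/s."""
    return abs(GAMMA_N) * b0 * delta_sigma_ppm * 1e-6 / math.sqrt(3.0)


def _j(p: SpinParams, omega: float) -> float:
    return spectral_density(omega, p.tau_c * 1e-9, p.s2)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def rate_R1(p: SpinParams, f: FieldConditions) -> float:
    """Longitudinal 15N rate R1(Nz) in s^-1 (N-H dipolar + 15N CSA)."""
    d2 = _dipolar_coupling(GAMMA_H, GAMMA_N, p.r_nh) ** 2
    c2 = _csa_coupling(f.b0, p.delta_sigma_n) ** 2
    wh, wn = f.omega_h, f.omega_n
    dip = d2 / 4.0 * (_j(p, wh - wn) + 3.0 * _j(p, wn)
                      + 6.0 * _j(p, wh + wn))
    csa = c2 * _j(p, wn)
    return dip + csa


def rate_R2_inphase(p: SpinParams, f: FieldConditions) -> float:
    """In-phase transverse 15N rate R2(N+) in s^-1."""
    d2 = _dipolar_coupling(GAMMA_H, GAMMA_N, p.r_nh) ** 2
    c2 = _csa_coupling(f.b0, p.delta_sigma_n) ** 2
    wh, wn = f.omega_h, f.omega_n
    dip = d2 / 8.0 * (4.0 * _j(p, 0.0) + _j(p, wh - wn) + 3.0 * _j(p, wn)
                      + 6.0 * _j(p, wh) + 6.0 * _j(p, wh + wn))
    csa = c2 / 6.0 * (4.0 * _j(p, 0.0) + 3.0 * _j(p, wn))
    return dip + csa


def rate_R2_antiphase(p: SpinParams, f: FieldConditions) -> float:
    """Anti-phase transverse rate R2(N+Hz) in s^-1.

    Identical to the in-phase rate except that the proton-flip 6J(omega_H)
    dipolar term is absent; dipolar contributions of neighbouring protons
    are accounted for separately through R1,sel(Hz) in the TROSY
    combination.
    """
    d2 = _dipolar_coupling(GAMMA_H, GAMMA_N, p.r_nh) ** 2
    return rate_R2_inphase(p, f) - d2 / 8.0 * 6.0 * _j(p, f.omega_h)


def rate_R1sel_H(p: SpinParams, f: FieldConditions) -> float:
    """Selective proton longitudinal rate R1,sel(Hz) in s^-1.

    Dipolar relaxation of the amide proton by neighbouring protons at the
    effective distance r_HH.
    """
    d2 = _dipolar_coupling(GAMMA_H, GAMMA_H, p.r_hh) ** 2
    wh = f.omega_h
    return d2 / 4.0 * (_j(p, 0.0) + 3.0 * _j(p, wh) + 6.0 * _j(p, 2.0 * wh))


def rate_eta(p: SpinParams, f: FieldConditions) -> float:
    """Transverse N-H dipole / 15N CSA cross-correlation rate eta in s^-1.

    Positive for theta below the magic angle, under the sign convention in
    which eta narrows the TROSY component.  Proportional to B0 and, in the
    slow-tumbling J(0)-dominated regime, approximately proportional to
    tau_c.
    """
    d = _dipolar_coupling(GAMMA_H, GAMMA_N, p.r_nh)
    c = _csa_coupling(f.b0, p.delta_sigma_n)
    p2 = 0.5 * (3.0 * math.cos(math.radians(p.theta)) ** 2 - 1.0)
    wn = f.omega_n
    return d * c / (2.0 * math.sqrt(3.0)) * p2 * (
        4.0 * _j(p, 0.0) + 3.0 * _j(p, wn))


def rate_set(p: SpinParams, f: FieldConditions) -> RateSet:
    """All six rates; the TROSY rate is built from the other five."""
    r2i = rate_R2_inphase(p, f)
    r2a = rate_R2_antiphase(p, f)
    r1s = rate_R1sel_H(p, f)
    eta = rate_eta(p, f)
    trosy = (r2i + r2a + r1s) / 2.0 - eta
    return RateSet(R1=rate_R1(p, f), R2_inphase=r2i, R2_antiphase=r2a,
                   R1sel_H=r1s, eta=eta, R2_trosy=trosy)


def rate_R2_trosy(p: SpinParams, f: FieldConditions) -> float:
    """TROSY rate R2(N+Hbeta) of the narrow doublet component, s^-1."""
    return rate_set(p, f).R2_trosy


# ---------------------------------------------------------------------------
# tau_c inversion
# ---------------------------------------------------------------------------

def _invert(rate_fn, target: float, p: SpinParams, f: FieldConditions,
            bracket_ns=TAUC_BRACKET_NS, xtol_ns: float = 0.01) -> float:
    lo, hi = bracket_ns
    f_lo = rate_fn(p.with_tau_c(lo), f) - target
    f_hi = rate_fn(p.with_tau_c(hi), f) - target
    if f_lo * f_hi > 0:
        r_lo = rate_fn(p.with_tau_c(lo), f)
        r_hi = rate_fn(p.with_tau_c(hi), f)
        achievable = (min(r_lo, r_hi), max(r_lo, r_hi))
        raise ValueError(
            f"measured rate {target:.4g} s^-1 has no root for tau_c in "
            f"[{lo}, {hi}] ns; achievable interval is "
            f"[{achievable[0]:.4g}, {achievable[1]:.4g}] s^-1")
    return brentq(lambda t: rate_fn(p.with_tau_c(t), f) - target,
                  lo, hi, xtol=xtol_ns)


def invert_tauc_from_R1(r1_meas: float, p: SpinParams, f: FieldConditions
                        ) -> float:
    """tau_c (ns) such that the theoretical R1(Nz) matches a measured rate.

    Root finding is restricted to the slow-tumbling branch (5-200 ns) on
    which R1 is strictly decreasing, guaranteeing a unique root.
    """
    if not (math.isfinite(r1_meas) and r1_meas > 0):
        raise ValueError("measured R1 must be positive and finite")
    return _invert(rate_R1, r1_meas, p, f)


def invert_tauc_from_eta(eta_meas: float, p: SpinParams, f: FieldConditions
                         ) -> float:
    """tau_c (ns) such that the theoretical eta matches a measured rate.

    eta is strictly increasing in tau_c, so the root is unique on the
    bracket.
    """
    if not (math.isfinite(eta_meas) and eta_meas > 0):
        raise ValueError("measured eta must be positive and finite")
    return _invert(rate_eta, eta_meas, p, f)


# ---------------------------------------------------------------------------
# Config support
# ---------------------------------------------------------------------------

def spin_params_from_config(path=None, **overrides) -> SpinParams:
    """Build SpinParams from a flat YAML key-value file plus overrides.

    Recognized keys match SpinParams field names.  All effective values are
    logged, so a run's parameterization is always recoverable from the log.
    """
    values: dict = {}
    if path is not None:
        import yaml
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        known = set(SpinParams.__dataclass_fields__)
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    params = SpinParams(**values)
    logger.info("SpinParams: %s", params)
    return params
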