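"""Chemical-exchange analysis of apparent 15N relaxation rates.

Micro- to millisecond interconversion between receptor conformations adds an
exchange term Rex to the measured transverse rate on top of the
exchange-free rate R2,0 predicted by the tumbling model:

    Rex = R2,observed - R2,0.

A CPMG pulse train with refocusing frequency nu_CP partially quenches Rex
when nu_CP is comparable to the exchange rate kex; comparing free-precession
and spin-echo Rex therefore brackets kex by an order of magnitude.  Slowly
exchanging states appear as resolved resonance pairs whose intensity ratio
gives the minor-state population and whose frequency separation lower-bounds
the state lifetime.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .relaxation import (FieldConditions, SpinParams, rate_R2_inphase,
                         rate_R2_trosy)

logger = logging.getLogger("gpcrdyn")

RATE_TYPES = ("inphase", "trosy")


@dataclass(frozen=True)
class ExchangeRecord:
    """Apparent rate, model exchange-free rate and their difference."""

    residue: str
    R2_app: float
    R2_0: float
    Rex_app: float
    field_tesla: float
    rate_type: str
    flagged_negative: bool = False


@dataclass(frozen=True)
class KexBand:
    """Order-of-magnitude bracket for the exchange rate, s^-1."""

    kex_low: float
    kex_high: float
    regime: str           # 'intermediate', 'fast', or 'slow' vs nu_CP
    kex_point: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kex_low > self.kex_high:
            raise ValueError("band endpoints out of order")


def rex_apparent(r2_app: float, p: SpinParams, f: FieldConditions,
                 rate_type: str = "trosy", residue: str = "",
                 mc_sd: float | None = None) -> ExchangeRecord:
    """Rex = R2,app - R2,0 with R2,0 from the relaxation model.

    rate_type selects the exchange-free reference: 'trosy' for rates from
    TROSY line-shape fitting, 'inphase' for spin-echo R2(Nx).  Negative Rex
    is retained, and flagged when it is below -2 MC SDs of the measurement.
    """
    if rate_type not in RATE_TYPES:
        raise ValueError(f"rate_type must be one of {RATE_TYPES}")
    r2_0 = (rate_R2_trosy if rate_type == "trosy" else rate_R2_inphase)(p, f)
    rex = r2_app - r2_0
    flagged = bool(mc_sd is not None and rex < -2.0 * mc_sd)
    if flagged:
        logger.warning("residue %s: Rex=%.2f s^-1 below -2 SD", residue, rex)
    return ExchangeRecord(residue=residue, R2_app=r2_app, R2_0=r2_0,
                          Rex_app=rex, field_tesla=f.b0, rate_type=rate_type,
                          flagged_negative=flagged)


def _quench_fraction(kex: float, nu_cp: float) -> float:
    """Fraction of Rex removed by a CPMG train, Luz-Meiboom fast exchange.

    nu_CP = 1/tau_cp (inverse 180-pulse spacing):
    Rex(nu_CP)/Rex(0) = (2 nu_CP / kex) tanh(kex / (2 nu_CP)), so the
    quenched fraction is 1 minus that, increasing from 0 (kex >> nu_CP)
    toward 1 (kex << nu_CP).
    """
    x = kex / (2.0 * nu_cp)
    if x < 1e-8:
        return x * x / 3.0  # series limit of 1 - tanh(x)/x
    return 1.0 - math.tanh(x) / x


def kex_band_from_quenching(rex_free: float, rex_cpmg: float, nu_cp: float,
                            sigma_free: float = 0.0, sigma_cpmg: float = 0.0
                            ) -> KexBand:
    """Order-of-magnitude kex bracket from CPMG quenching of Rex.

    rex_free is the free-precession (e.g. TROSY line-shape) exchange
    contribution, rex_cpmg the residual under a CPMG train of refocusing
    frequency nu_cp (Hz, = inverse 180-pulse spacing).  The observed quench
    fraction q = 1 - rex_cpmg/rex_free is inverted through the fast-exchange
    Luz-Meiboom profile to a point kex, reported as the decade bracket
    containing it; optional rate uncertainties widen the bracket.  Limits:
    no quenching implies kex >> nu_CP (unbounded above, with a warning),
    full quenching implies kex below nu_CP.
    """
    if nu_cp <= 0:
        raise ValueError("nu_cp must be > 0 Hz")
    if rex_cpmg < 0 or rex_free <= 0 or rex_free < rex_cpmg:
        raise ValueError("need Rex_free > Rex_cpmg >= 0 with Rex_free > 0")
    q = 1.0 - rex_cpmg / rex_free
    dq = 0.0
    if sigma_free or sigma_cpmg:
        dq = (rex_cpmg / rex_free) * math.hypot(
            sigma_cpmg / max(rex_cpmg, 1e-12), sigma_free / rex_free)

    def kex_of(qval: float) -> float:
        # invert the monotonic quench profile by bracketed root finding
        lo, hi = 1e-3 * nu_cp, 1e6 * nu_cp
        return brentq(lambda k: _quench_fraction(k, nu_cp) - qval, lo, hi,
                      rtol=1e-10)

    eps = 1e-6
    if q <= eps:
        warnings.warn("no CPMG quenching observed: kex >> nu_CP, band "
                      "unbounded above", stacklevel=2)
        return KexBand(kex_low=2.0 * nu_cp, kex_high=math.inf, regime="fast")
    if q >= 1.0 - eps:
        return KexBand(kex_low=0.0, kex_high=nu_cp, regime="slow")
    q_lo = max(q - dq, eps)
    q_hi = min(q + dq, 1.0 - eps)
    kex_point = kex_of(q)
    k_lo, k_hi = kex_of(q_lo), kex_of(q_hi)
    band_lo = 10.0 ** math.floor(math.log10(k_lo))
    band_hi = 10.0 ** math.ceil(math.log10(k_hi))
    if band_lo == band_hi:  # point landed exactly on a decade
        band_hi *= 10.0
    return KexBand(kex_low=band_lo, kex_high=band_hi,
                   regime="intermediate", kex_point=kex_point)


def population_from_intensities(i_minor: float, i_major: float) -> float:
    """Minor-state population p = I_minor / (I_minor + I_major)."""
    if i_minor < 0 or i_major < 0:
        raise ValueError("intensities must be >= 0")
    total = i_minor + i_major
    if total == 0:
        raise ValueError("both intensities are zero")
    return i_minor / total


def slow_exchange_lifetime_bound(delta_delta_ppm: float, nucleus: str,
                                 f: FieldConditions) -> float:
    """Minimum state lifetime (ms) for two resolved resonances.

    Two lines separated by dnu (Hz) coalesce at the exchange rate
    k = pi dnu / sqrt(2); observing them resolved therefore requires
    exchange slower than that, i.e. a lifetime above 1/k.  The bound
    decreases monotonically as the shift separation grows.
    """
    if delta_delta_ppm <= 0:
        raise ValueError("shift separation must be > 0 ppm")
    nucleus = nucleus.upper().lstrip("1 5")
    if nucleus in ("H", "1H"):
        nu_mhz = f.nu_h
    elif nucleus in ("N", "15N"):
        nu_mhz = f.nu_n
    else:
        raise ValueError(f"unknown nucleus {nucleus!r}")
    delta_nu_hz = delta_delta_ppm * nu_mhz
    k_coalesce = math.pi * delta_nu_hz / math.sqrt(2.0)
    return 1e3 / k_coalesce


def correlate(x, y, permutation_p: bool = False,
              n_perm: int = 10000, seed: int | None = None) -> tuple:
    """Pearson r, optionally with a permutation p-value.

    The permutation test on |r| is exhaustive for n <= 7 (at most 5040
    orderings) and seeded Monte-Carlo with n_perm draws otherwise.
    Returns (r, p) where p is None unless requested.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")

    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    r = pearson(x, y)
    if not permutation_p:
        return r, None
    if x.size <= 7:
        rs = [abs(pearson(x, np.asarray(p))) for p in permutations(y)]
        p_val = float(np.mean(np.asarray(rs) >= abs(r) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        hits = sum(abs(pearson(x, rng.permutation(y))) >= abs(r) - 1e-12
                   for _ in range(n_perm))
        p_val = (hits + 1) / (n_perm + 1)
    return r, p_val
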