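"""Unit constants and conversions used across the package.

All dose-rate physics funnels through :func:`dose_rate_gy_per_s` so that unit
conversions live in exactly one place.  Field-facing units are the ones the
beamline community uses: beam current in nA, LET in keV/µm, field area in mm²,
density in g/cm³, dose rate in Gy/s.  Volumes are computed in mm³ and reported
in µl (1 mm³ ≡ 1 µl).
"""

from __future__ import annotations

import math

#: Elementary charge in coulomb (2019 SI exact value).
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: Electron-volt in joule.
EV_J = ELEMENTARY_CHARGE_C

SECONDS_PER_MINUTE = 60.0


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


def protons_per_second(current_na: float) -> float:
    """Particle rate of a singly charged beam carrying ``current_na`` nanoampere."""
    if current_na < 0:
        raise InvalidParameterError(f"beam current must be >= 0 nA, got {current_na}")
    return current_na * 1e-9 / ELEMENTARY_CHARGE_C


def dose_rate_gy_per_s(
    current_na: float,
    let_kev_um: float,
    area_mm2: float,
    density_g_cm3: float = 1.0,
) -> float:
    """Absorbed dose rate of a broad proton beam from current and LET.

    The beam deposits ``LET`` per proton per unit path length into a slab of
    mass-per-path-length ``area × density``, so

        dose rate = (current / e) × LET / (area × density)

    with everything converted to SI internally.  Linear in current and LET,
    inverse-linear in area and density.
    """
    if let_kev_um <= 0:
        raise InvalidParameterError(f"LET must be > 0 keV/µm, got {let_kev_um}")
    if area_mm2 <= 0:
        raise InvalidParameterError(f"field area must be > 0 mm², got {area_mm2}")
    if density_g_cm3 <= 0:
        raise InvalidParameterError(f"density must be > 0 g/cm³, got {density_g_cm3}")
    rate_per_s = protons_per_second(current_na)
    let_j_per_m = let_kev_um * 1e3 * EV_J / 1e-6  # keV/µm -> J/m
    mass_per_length_kg_m = area_mm2 * 1e-6 * density_g_cm3 * 1e3  # mm²·g/cm³ -> kg/m
    return rate_per_s * let_j_per_m / mass_per_length_kg_m


def round_sig(value: float, sig: int) -> float:
    """Round ``value`` to ``sig`` significant digits (printed-precision compare)."""
    if sig < 1:
        raise InvalidParameterError(f"significant digits must be >= 1, got {sig}")
    if value == 0 or not math.isfinite(value):
        return value
    ndigits = sig - 1 - math.floor(math.log10(abs(value)))
    return round(value, ndigits)
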