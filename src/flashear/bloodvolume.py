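"""Irradiated-blood-volume model for a trans-illuminated mouse ear.

The blood exposed during one irradiation splits into a *static* volume — the
blood held in the vessels inside the field, modelled as cylinders in three
diameter classes (thick / middle / thin) — and a *flow* volume exchanged
through the veins entering the field while the beam is on:

    V_static = Σ_class π d_class²/4 × Σ lengths,
    V_flow   = Σ_veins π d_i²/4 × v × t,
    V_irr    = V_static + V_flow.

Because the blood present for only part of the irradiation receives a
correspondingly smaller dose, the mean dose to the irradiated blood is diluted
by the volume ratio: D_blood = D × V_static / V_irr.

All volumes are computed in mm³ and reported in µl (1 mm³ ≡ 1 µl); lengths and
diameters in mm, times in s, speeds in mm/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import InvalidParameterError


class DataFormatError(ValueError):
    """An input table row violates the expected schema or vocabulary."""


SIZE_CLASSES = ("thick", "middle", "thin")


@dataclass(frozen=True)
class DiameterTable:
    """Mean vessel diameters (mm) for the three by-eye thickness classes."""

    d_thick: float = 0.09
    d_middle: float = 0.05
    d_thin: float = 0.04

    def __post_init__(self) -> None:
        if not self.d_thick >= self.d_middle >= self.d_thin > 0:
            raise InvalidParameterError(
                f"need d_thick >= d_middle >= d_thin > 0, got {self.d_thick}/{self.d_middle}/{self.d_thin}"
            )

    def diameter(self, size_class: str) -> float:
        try:
            return {"thick": self.d_thick, "middle": self.d_middle, "thin": self.d_thin}[size_class]
        except KeyError:
            raise DataFormatError(f"unknown vessel size class {size_class!r}; expected one of {SIZE_CLASSES}")


@dataclass(frozen=True)
class VesselSegment:
    """One traced vessel inside the field: a thickness class and a length."""

    vessel_id: str
    size_class: str
    length_mm: float
    diameter_mm: float | None = None  # explicit override of the class diameter

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise DataFormatError(
                f"vessel {self.vessel_id}: unknown size class {self.size_class!r}; "
                f"expected one of {SIZE_CLASSES}"
            )
        if self.length_mm < 0:
            raise InvalidParameterError(f"vessel {self.vessel_id}: length must be >= 0 mm")
        if self.diameter_mm is not None and self.diameter_mm <= 0:
            raise InvalidParameterError(f"vessel {self.vessel_id}: diameter must be > 0 mm")


@dataclass(frozen=True)
class EntryVein:
    """A vein crossing the field boundary, through which blood is exchanged."""

    vein_id: str
    diameter_mm: float
    size_class: str = "thick"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise InvalidParameterError(f"vein {self.vein_id}: diameter must be > 0 mm")


@dataclass(frozen=True)
class FlowParameters:
    """Venous blood flow speed and the time the beam is on."""

    flow_speed_mm_s: float = 2.0
    irradiation_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.flow_speed_mm_s < 0 or self.irradiation_time_s < 0:
            raise InvalidParameterError("flow speed and irradiation time must be >= 0")


@dataclass(frozen=True)
class BloodVolumeEstimate:
    static_volume_ul: float
    flow_volume_ul: float
    irradiated_volume_ul: float
    blood_fraction_pct: float | None = None
    mean_blood_dose_gy: float | None = None


def _cross_section_mm2(diameter_mm: float) -> float:
    return math.pi * diameter_mm**2 / 4.0


def polyline_lengths(polylines: Iterable[Sequence[Sequence[float]]]) -> list[float]:
    """Length of each traced polyline (mm): sum of consecutive Euclidean steps."""
    lengths = []
    for i, line in enumerate(polylines):
        pts = np.asarray(line, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise InvalidParameterError(f"polyline {i}: need at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise InvalidParameterError(f"polyline {i}: non-finite coordinates")
        lengths.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
    return lengths


def static_volume(
    segments: Iterable[VesselSegment],
    diameters: DiameterTable | None = None,
) -> float:
    """Static blood volume (µl) of classed cylindrical vessel segments.

    Per-segment explicit diameters override the class diameter when present.
    """
    diameters = diameters or DiameterTable()
    total = 0.0
    for seg in segments:
        d = seg.diameter_mm if seg.diameter_mm is not None else diameters.diameter(seg.size_class)
        total += _cross_section_mm2(d) * seg.length_mm
    return total


def flow_volume(entry_veins: Iterable[EntryVein], flow: FlowParameters) -> float:
    """Blood volume (µl) exchanged through the entry veins during irradiation."""
    veins = list(entry_veins)
    thin = [v.vein_id for v in veins if v.size_class == "thin"]
    if thin:
        warnings.warn(
            f"entry veins {thin} are classed 'thin'; only thick and middle vessels "
            "are normally counted as entry veins",
            stacklevel=2,
        )
    area = sum(_cross_section_mm2(v.diameter_mm) for v in veins)
    return area * flow.flow_speed_mm_s * flow.irradiation_time_s


def irradiated_volume(static_ul: float, flow_ul: float) -> float:
    """Total irradiated blood volume (µl): static + flow."""
    if static_ul < 0 or flow_ul < 0:
        raise InvalidParameterError("volumes must be >= 0")
    return static_ul + flow_ul


def total_blood_volume(body_weight_g: float, per_weight_ml_100g: float = 10.35) -> float:
    """Total blood volume (ml) of a mouse from its body weight."""
    if body_weight_g < 0:
        raise InvalidParameterError("body weight must be >= 0")
    if per_weight_ml_100g <= 0:
        raise InvalidParameterError("blood per weight must be > 0")
    return body_weight_g * per_weight_ml_100g / 100.0


def blood_fraction(irradiated_ul: float, total_blood_ml: float) -> float:
    """Irradiated fraction of the total blood volume, in percent."""
    if total_blood_ml <= 0:
        raise InvalidParameterError("total blood volume must be > 0 ml")
    if irradiated_ul < 0:
        raise InvalidParameterError("irradiated volume must be >= 0")
    return 100.0 * irradiated_ul / (total_blood_ml * 1e3)


def mean_blood_dose(total_dose_gy: float, static_ul: float, irradiated_ul: float) -> float:
    """Mean dose (Gy) to the irradiated blood, diluted by exchange.

    Each blood parcel resides in the field for a fraction V_static/V_irr of
    the irradiation on average, so D_blood = D × V_static / V_irr.  Equals the
    full dose when no blood is exchanged and never exceeds it.
    """
    if not 0 < static_ul <= irradiated_ul:
        raise InvalidParameterError(
            f"need irradiated >= static > 0 µl, got static={static_ul}, irradiated={irradiated_ul}"
        )
    if total_dose_gy < 0:
        raise InvalidParameterError("total dose must be >= 0")
    return total_dose_gy * static_ul / irradiated_ul


def estimate(
    segments: Iterable[VesselSegment],
    entry_veins: Iterable[EntryVein],
    flow: FlowParameters,
    diameters: DiameterTable | None = None,
    total_dose_gy: float | None = None,
    total_blood_ml: float | None = None,
) -> BloodVolumeEstimate:
    """Full chain: V_static, V_flow, V_irr, blood fraction and mean blood dose."""
    vs = static_volume(segments, diameters)
    vf = flow_volume(entry_veins, flow)
    virr = irradiated_volume(vs, vf)
    frac = blood_fraction(virr, total_blood_ml) if total_blood_ml else None
    dose = (
        mean_blood_dose(total_dose_gy, vs, virr)
        if total_dose_gy is not None and vs > 0
        else None
    )
    return BloodVolumeEstimate(vs, vf, virr, frac, dose)


# ---------------------------------------------------------------------------
# Replicate statistics and first-order uncertainty propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sd: float | None  # None when n < 2
    sem: float | None
    n: int


def replicate_stats(values: Sequence[float]) -> ReplicateStats:
    """Across-replicate mean, SD and SEM; SD/SEM undefined (None) for n < 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("need at least one replicate")
    if arr.size == 1:
        return ReplicateStats(float(arr[0]), None, None, 1)
    sd = float(np.std(arr, ddof=1))
    return ReplicateStats(float(arr.mean()), sd, sd / math.sqrt(arr.size), int(arr.size))


def ratio_uncertainty(
    num_mean: float, num_sd: float, den_mean: float, den_sd: float
) -> float:
    """First-order SD of a ratio of independent quantities num/den."""
    if den_mean == 0:
        raise InvalidParameterError("denominator mean must be nonzero")
    if num_mean == 0:
        return abs(num_sd / den_mean)
    r = num_mean / den_mean
    return abs(r) * math.sqrt((num_sd / num_mean) ** 2 + (den_sd / den_mean) ** 2)


def propagate_estimates(
    per_replicate: Sequence[BloodVolumeEstimate],
    total_blood_ml: float | None = None,
) -> dict[str, ReplicateStats]:
    """Across-ear replicate statistics of the volume chain (n >= 2 for SDs)."""
    if len(per_replicate) == 0:
        raise InvalidParameterError("need at least one replicate estimate")
    out = {
        "static_volume_ul": replicate_stats([e.static_volume_ul for e in per_replicate]),
        "flow_volume_ul": replicate_stats([e.flow_volume_ul for e in per_replicate]),
        "irradiated_volume_ul": replicate_stats([e.irradiated_volume_ul for e in per_replicate]),
    }
    if total_blood_ml:
        out["blood_fraction_pct"] = replicate_stats(
            [blood_fraction(e.irradiated_volume_ul, total_blood_ml) for e in per_replicate]
        )
    return out
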