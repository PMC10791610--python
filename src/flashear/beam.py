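"""Pulsed proton-beam timing and dose-rate model.

A chopper in front of the accelerator passes every ``partition``-th pulse of a
base-frequency pulse train.  Within a pulse the beam delivers the *peak* dose
rate set by the peak current; averaged over the pulse train the *mean* dose
rate is the peak rate scaled by the duty cycle (pulse width / pulse period).
The irradiation duration for a prescribed dose follows from the mean rate.

Default configurations reproduce the three irradiation modes of a 20 MeV
proton mouse-ear FLASH experiment: a continuous 930 Gy/s mode, a pulsed
9.3 Gy/s mode (128 ns pulses every 12.8 µs) and a pulsed conventional
0.06 Gy/s mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .units import InvalidParameterError, dose_rate_gy_per_s


class BeamMode(str, Enum):
    CONTINUOUS = "continuous"
    PULSED = "pulsed"


@dataclass(frozen=True)
class BeamConfig:
    """Beamline settings sufficient to derive dose rates and durations.

    Parameters
    ----------
    peak_current_na:
        Beam current within a pulse (or the DC current in continuous mode), nA.
    let_kev_um:
        Linear energy transfer of the particles in the target, keV/µm.
    field_area_mm2:
        Irradiated field area, mm².
    density_g_cm3:
        Mass density of the target medium; water-equivalent tissue by default.
    particle_energy_mev:
        Informational only; not used in the dose conversion.
    pulse_width_ns, pulse_period_us:
        Chopper pulse structure (pulsed mode only).
    """

    peak_current_na: float
    let_kev_um: float = 2.6
    field_area_mm2: float = 42.25
    density_g_cm3: float = 1.0
    mode: BeamMode = BeamMode.CONTINUOUS
    pulse_width_ns: float | None = None
    pulse_period_us: float | None = None
    particle_energy_mev: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.peak_current_na < 0:
            raise InvalidParameterError("peak_current_na must be >= 0")
        for name in ("let_kev_um", "field_area_mm2", "density_g_cm3"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.mode is BeamMode.PULSED:
            if self.pulse_width_ns is None or self.pulse_period_us is None:
                raise InvalidParameterError("pulsed mode requires pulse_width_ns and pulse_period_us")
            if not 0 < self.pulse_width_ns <= self.pulse_period_us * 1e3:
                raise InvalidParameterError(
                    f"need 0 < pulse_width <= pulse_period, got {self.pulse_width_ns} ns / {self.pulse_period_us} µs"
                )

    @property
    def duty_cycle(self) -> float:
        if self.mode is BeamMode.CONTINUOUS:
            return 1.0
        assert self.pulse_width_ns is not None and self.pulse_period_us is not None
        return self.pulse_width_ns / (self.pulse_period_us * 1e3)


@dataclass(frozen=True)
class IrradiationPlan:
    """Derived quantities for delivering ``total_dose_gy`` with a given beam."""

    total_dose_gy: float
    peak_dose_rate_gy_s: float
    mean_dose_rate_gy_s: float
    duration_s: float
    duty_cycle: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mean_dose_rate_gy_s > self.peak_dose_rate_gy_s * (1 + 1e-12):
            raise InvalidParameterError("mean dose rate cannot exceed peak dose rate")
        if not 0 < self.duty_cycle <= 1:
            raise InvalidParameterError("duty cycle must lie in (0, 1]")

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


def dose_rate_from_current(
    current_na: float,
    let_kev_um: float,
    area_mm2: float,
    density_g_cm3: float = 1.0,
) -> float:
    """Dose rate (Gy/s) of a broad beam: ``(current/e) × LET / (area × density)``."""
    return dose_rate_gy_per_s(current_na, let_kev_um, area_mm2, density_g_cm3)


def chopper_period(base_frequency_mhz: float, frequency_partition: int) -> float:
    """Pulse-to-pulse distance (µs) when passing every ``partition``-th pulse.

    A 5 MHz chopper at partition 2**6 yields 12.8 µs.
    """
    if base_frequency_mhz <= 0:
        raise InvalidParameterError("base frequency must be > 0 MHz")
    if frequency_partition < 1:
        raise InvalidParameterError(f"frequency partition must be >= 1, got {frequency_partition}")
    return frequency_partition / base_frequency_mhz


def mean_dose_rate(peak_rate_gy_s: float, pulse_width_ns: float, pulse_period_us: float) -> float:
    """Mean dose rate of a pulsed beam: peak rate × duty cycle."""
    if peak_rate_gy_s < 0:
        raise InvalidParameterError("peak rate must be >= 0")
    period_ns = pulse_period_us * 1e3
    if not 0 < pulse_width_ns <= period_ns:
        raise InvalidParameterError(
            f"need 0 < pulse_width <= pulse_period, got {pulse_width_ns} ns / {pulse_period_us} µs"
        )
    return peak_rate_gy_s * (pulse_width_ns / period_ns)


def duration_for_dose(total_dose_gy: float, mean_rate_gy_s: float) -> float:
    """Time (s) needed to deliver ``total_dose_gy`` at ``mean_rate_gy_s``."""
    if total_dose_gy < 0:
        raise InvalidParameterError("total dose must be >= 0")
    if mean_rate_gy_s <= 0:
        raise InvalidParameterError("mean dose rate must be > 0")
    return total_dose_gy / mean_rate_gy_s


def plan_irradiation(config: BeamConfig, total_dose_gy: float) -> IrradiationPlan:
    """Derive peak/mean dose rates, duty cycle and duration for one beam mode."""
    peak = dose_rate_from_current(
        config.peak_current_na, config.let_kev_um, config.field_area_mm2, config.density_g_cm3
    )
    duty = config.duty_cycle
    mean = peak * duty
    return IrradiationPlan(
        total_dose_gy=total_dose_gy,
        peak_dose_rate_gy_s=peak,
        mean_dose_rate_gy_s=mean,
        duration_s=duration_for_dose(total_dose_gy, mean) if total_dose_gy > 0 else 0.0,
        duty_cycle=duty,
        label=config.label,
    )


# The three study modes: continuous 15 nA; 15 nA chopped to 128 ns / 12.8 µs
# (5 MHz, partition 2^6); 0.4 nA chopped to 128 ns / 51.2 µs (partition 2^8).
DEFAULT_BEAM_CONFIGS: Mapping[str, BeamConfig] = {
    "Flash930": BeamConfig(
        peak_current_na=15.0, let_kev_um=2.6, field_area_mm2=42.0,
        mode=BeamMode.CONTINUOUS, particle_energy_mev=20.5, label="Flash930",
    ),
    "Flash9": BeamConfig(
        peak_current_na=15.0, let_kev_um=2.6, field_area_mm2=42.0,
        mode=BeamMode.PULSED, pulse_width_ns=128.0,
        pulse_period_us=chopper_period(5.0, 2 ** 6),
        particle_energy_mev=20.5, label="Flash9",
    ),
    "Conv": BeamConfig(
        peak_current_na=0.4, let_kev_um=2.6, field_area_mm2=42.0,
        mode=BeamMode.PULSED, pulse_width_ns=128.0,
        pulse_period_us=chopper_period(5.0, 2 ** 8),
        particle_energy_mev=20.5, label="Conv",
    ),
}

#: Nominal (printed) mean dose rates of the three modes, Gy/s.
NOMINAL_MEAN_DOSE_RATES: Mapping[str, float] = {
    "Flash930": 930.0,
    "Flash9": 9.3,
    "Conv": 0.06,
}
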