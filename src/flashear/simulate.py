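"""Synthetic cohorts, vessel traces and qPCR plates with known ground truth.

The generators emulate the statistical structure the analysis chain assumes —
they are not biophysical simulations.  A cohort is a set of mice observed
every 2–7 days over 180 days whose ear thickness follows

    ET(day) = baseline + A_group · g(day) + ε,   ε ~ N(0, σ²),

with g a smooth unimodal gamma-shaped response (onset near day 12, peak at
day 23, back to ~0 by day 61) normalised to 1 at its peak, A_group the
group's true peak swelling and σ = 25 µm measurement noise.  Ordinal skin
grades are emitted by thresholding the *noiseless* swelling.  Vessel traces
are random polylines whose class-wise total lengths are exact, so the true
static volume is known in closed form.  qPCR plates inject a chosen true
log2 fold change by shifting the gene Ct relative to housekeeping.

Every generator draws from its own child stream of the master seed (fixed
spawn keys), so adding one generator never perturbs another's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bloodvolume import DiameterTable, EntryVein, VesselSegment
from .cohort import MouseRecord
from .units import InvalidParameterError

# child-stream spawn keys, fixed forever
_STREAM_COHORT = 0
_STREAM_VESSELS = 1
_STREAM_QPCR = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------

#: (dose Gy, dose-rate label, n mice): the study's group plan.
DEFAULT_GROUPS: tuple[tuple[float, str, int], ...] = (
    (23.0, "Conv", 7),
    (33.0, "Conv", 7),
    (23.0, "Flash9", 9),
    (33.0, "Flash9", 3),
    (23.0, "Flash930", 7),
    (33.0, "Flash930", 9),
    (0.0, "Sham", 7),
)

#: True peak swelling amplitude (µm) per (dose, label).  The 33 Gy FLASH
#: amplitudes encode true reductions of 57% (Flash9) and 40% (Flash930)
#: relative to the conventional 155 µm peak; the 23 Gy amplitudes match the
#: observed group maxima.
DEFAULT_AMPLITUDES: Mapping[tuple[float, str], float] = {
    (33.0, "Conv"): 155.0,
    (33.0, "Flash9"): 155.0 * (1 - 0.57),
    (33.0, "Flash930"): 155.0 * (1 - 0.40),
    (23.0, "Conv"): 49.0,
    (23.0, "Flash9"): 40.0,
    (23.0, "Flash930"): 30.0,
    (0.0, "Sham"): 0.0,
}

#: Swelling (µm) cut points above which each ordinal grade is emitted,
#: applied to the noiseless group response.  Chosen so a 155 µm peak scores
#: 2.5 (Definite erythema + Dry desquamation) and the 23 Gy groups stay
#: below a score of 1.
DEFAULT_ERYTHEMA_CUTS: tuple[tuple[float, str], ...] = (
    (200.0, "Severe"), (120.0, "Definite"), (40.0, "Mild"),
)
DEFAULT_DESQUAMATION_CUTS: tuple[tuple[float, str], ...] = (
    (220.0, "Moist"), (160.0, "Crust formation"), (100.0, "Dry"),
)

QPCR_GENES = ("TGF-b1", "TNF-a", "IL1a", "IL1b")
QPCR_HOUSEKEEPING = ("B2M", "GAPDH")
QPCR_DAYS = (7, 21, 28, 180)
#: Plausible baseline Ct offsets of each cytokine above housekeeping (cycles).
QPCR_BASELINE_DELTA_CT: Mapping[str, float] = {
    "TGF-b1": 4.0, "TNF-a": 6.5, "IL1a": 7.0, "IL1b": 5.5,
}
QPCR_HK_BASE_CT: Mapping[str, float] = {"B2M": 18.0, "GAPDH": 19.0}


@dataclass(frozen=True)
class VesselSpec:
    """Per-class total lengths (mm) and the entry-vein layout.

    Defaults give a true static volume of ~0.20 µl in a 6.5 × 6.5 mm field
    and four thick entry veins, which together reproduce the study's printed
    irradiated volumes for all three timing modes.
    """

    total_length_thick_mm: float = 16.0
    total_length_middle_mm: float = 26.0
    total_length_thin_mm: float = 38.0
    n_thick: int = 4
    n_middle: int = 6
    n_thin: int = 10
    entry_vein_diameters_mm: tuple[float, ...] = (0.09, 0.09, 0.09, 0.09)
    field_size_mm: float = 6.5
    diameters: DiameterTable = field(default_factory=DiameterTable)


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth for one simulated experiment."""

    groups: tuple[tuple[float, str, int], ...] = DEFAULT_GROUPS
    baseline_thickness_um: float = 230.0
    thickness_noise_sd_um: float = 25.0
    amplitudes_um: Mapping[tuple[float, str], float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    onset_day: float = 12.0
    peak_day: float = 23.0
    response_shape: float = 3.0  # gamma-like sharpness; ~0 beyond day 61
    followup_days: int = 180
    min_gap_days: int = 2
    max_gap_days: int = 7
    erythema_cuts: tuple[tuple[float, str], ...] = DEFAULT_ERYTHEMA_CUTS
    desquamation_cuts: tuple[tuple[float, str], ...] = DEFAULT_DESQUAMATION_CUTS
    vessels: VesselSpec = field(default_factory=VesselSpec)
    qpcr_true_log2fc: Mapping[tuple[str, str, int], float] = field(default_factory=dict)
    qpcr_ct_noise_sd: float = 0.2
    qpcr_n_per_group: Mapping[str, int] | None = None
    qpcr_groups: tuple[str, ...] = ("Sham", "Conv", "Flash9", "Flash930")

    def __post_init__(self) -> None:
        for dose, label, n in self.groups:
            if n < 1:
                raise InvalidParameterError(f"group ({dose}, {label}) needs n >= 1")
        if self.thickness_noise_sd_um < 0 or self.qpcr_ct_noise_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if not 0 < self.peak_day <= self.followup_days:
            raise InvalidParameterError("peak day must lie within the follow-up period")
        if not 0 < self.min_gap_days <= self.max_gap_days:
            raise InvalidParameterError("need 0 < min_gap_days <= max_gap_days")

    def amplitude(self, dose: float, label: str) -> float:
        if label.lower() == "sham":
            return 0.0
        try:
            return self.amplitudes_um[(dose, label)]
        except KeyError:
            raise InvalidParameterError(f"no amplitude configured for group ({dose} Gy, {label})")

    def true_reductions(self, dose: float = 33.0, reference: str = "Conv") -> dict[str, float]:
        """Injected percent reductions of each test group vs the reference."""
        a_ref = self.amplitude(dose, reference)
        return {
            label: 100.0 * (1 - self.amplitude(dose, label) / a_ref)
            for _, label, _ in self.groups
            if label not in (reference, "Sham") and (dose, label) in self.amplitudes_um
        }


def response_curve(days: np.ndarray, scenario: SyntheticScenario) -> np.ndarray:
    """Unimodal gamma-shaped response g(day), normalised to 1 at the peak day."""
    days = np.asarray(days, dtype=float)
    t0, tp, a = scenario.onset_day, scenario.peak_day, scenario.response_shape
    x = np.clip((days - t0) / (tp - t0), 0.0, None)
    with np.errstate(over="ignore"):
        g = x**a * np.exp(a * (1.0 - x))
    return np.where(days <= t0, 0.0, g)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def _grade(swelling: float, cuts: Sequence[tuple[float, str]]) -> str:
    for threshold, label in cuts:  # descending thresholds
        if swelling >= threshold:
            return label
    return "No"


def generate_cohort(scenario: SyntheticScenario, seed: int) -> list[MouseRecord]:
    """Simulate per-mouse longitudinal thickness and skin-grade series."""
    rng = _rng(seed, _STREAM_COHORT)
    records: list[MouseRecord] = []
    idx = 1
    for dose, label, n in scenario.groups:
        amp = scenario.amplitude(dose, label)
        for _ in range(n):
            days = [0]
            while days[-1] < scenario.followup_days:
                days.append(
                    days[-1]
                    + int(rng.integers(scenario.min_gap_days, scenario.max_gap_days + 1))
                )
            days = np.asarray(days[:-1] if days[-1] > scenario.followup_days else days, dtype=float)
            clean = amp * response_curve(days, scenario)
            thickness = (
                scenario.baseline_thickness_um
                + clean
                + rng.normal(0.0, scenario.thickness_noise_sd_um, size=days.size)
            )
            thickness = np.clip(thickness, 1.0, None)
            records.append(
                MouseRecord(
                    mouse_id=f"m{idx:03d}",
                    dose_gy=dose,
                    dose_rate_label=label,
                    days=days,
                    ear_thickness_um=thickness,
                    erythema=[_grade(s, scenario.erythema_cuts) for s in clean],
                    desquamation=[_grade(s, scenario.desquamation_cuts) for s in clean],
                )
            )
            idx += 1
    return records


# ---------------------------------------------------------------------------
# Vessel-trace generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselTraceTruth:
    static_volume_ul: float
    total_lengths_mm: Mapping[str, float]


def _random_polyline(rng: np.random.Generator, length: float, field_size: float,
                     n_points: int = 6) -> np.ndarray:
    """A jagged polyline of exact total length inside the square field."""
    # random walk, then rescale steps to the requested total length
    start = rng.uniform(0.15 * field_size, 0.85 * field_size, size=2)
    steps = rng.normal(size=(n_points - 1, 2))
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    steps = steps / norms
    seg_lengths = rng.uniform(0.5, 1.5, size=n_points - 1)
    seg_lengths *= length / seg_lengths.sum()
    pts = np.vstack([start, start + np.cumsum(steps * seg_lengths[:, None], axis=0)])
    # fold back into the field so traces stay inside the irradiated area
    pts = np.abs(pts)
    period = 2 * field_size
    pts = pts % period
    pts = np.where(pts > field_size, period - pts, pts)
    return pts


def generate_vessel_trace(
    scenario: SyntheticScenario, seed: int
) -> tuple[list[VesselSegment], dict[str, np.ndarray], list[EntryVein], VesselTraceTruth]:
    """Random vessel polylines with exactly known class lengths and V_static.

    Returns (segments, polylines-by-vessel-id, entry veins, truth).  Segment
    lengths are taken from the generated polylines, so re-measuring the
    polylines reproduces the truth exactly.
    """
    rng = _rng(seed, _STREAM_VESSELS)
    spec = scenario.vessels
    segments: list[VesselSegment] = []
    polylines: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    plan = (
        ("thick", spec.n_thick, spec.total_length_thick_mm),
        ("middle", spec.n_middle, spec.total_length_middle_mm),
        ("thin", spec.n_thin, spec.total_length_thin_mm),
    )
    for size_class, count, total in plan:
        totals[size_class] = total
        if count == 0 or total == 0:
            totals[size_class] = 0.0
            continue
        parts = rng.dirichlet(np.full(count, 5.0)) * total
        for i, length in enumerate(parts):
            vid = f"{size_class}{i + 1:02d}"
            poly = _random_polyline(rng, float(length), spec.field_size_mm)
            # folding at the boundary preserves step lengths exactly only for
            # interior reflections; recompute the authoritative length
            true_len = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
            segments.append(VesselSegment(vid, size_class, true_len))
            polylines[vid] = poly
        totals[size_class] = sum(s.length_mm for s in segments if s.size_class == size_class)
    d = spec.diameters
    v_static = sum(
        math.pi * d.diameter(c) ** 2 / 4.0 * totals[c] for c in ("thick", "middle", "thin")
    )
    veins = [
        EntryVein(f"v{i + 1:02d}", diam) for i, diam in enumerate(spec.entry_vein_diameters_mm)
    ]
    return segments, polylines, veins, VesselTraceTruth(v_static, totals)


# ---------------------------------------------------------------------------
# qPCR plate generator
# ---------------------------------------------------------------------------

def generate_qpcr(scenario: SyntheticScenario, seed: int) -> pd.DataFrame:
    """Simulate a triplicate Ct table for the cytokine panel.

    Per sample, housekeeping wells fluctuate around their base Ct plus a
    shared per-sample RNA-loading shift; each cytokine's Ct sits a baseline
    ΔCt above housekeeping minus the injected true log2 FC (sham group: 0 by
    definition).  Triplicate wells add independent N(0, σ_Ct) noise.
    """
    for (gene, group, day) in scenario.qpcr_true_log2fc:
        if gene not in QPCR_GENES:
            raise InvalidParameterError(f"unknown gene in qPCR spec: {gene!r}")
        if group not in scenario.qpcr_groups:
            raise InvalidParameterError(f"unknown group in qPCR spec: {group!r}")
        if day not in QPCR_DAYS:
            raise InvalidParameterError(f"unknown sampling day in qPCR spec: {day}")
    rng = _rng(seed, _STREAM_QPCR)
    sd = scenario.qpcr_ct_noise_sd
    default_n = {label: n for _, label, n in scenario.groups if label in scenario.qpcr_groups}
    n_per_group = dict(scenario.qpcr_n_per_group or {})
    rows = []
    for group in scenario.qpcr_groups:
        n = n_per_group.get(group, default_n.get(group, 7))
        for mouse in range(1, n + 1):
            mouse_id = f"{group.lower()}-{mouse:02d}"
            for day in QPCR_DAYS:
                sample_id = f"{mouse_id}-d{day}"
                loading = rng.normal(0.0, 0.5)  # cancels in ΔCt
                hk_true = {}
                for hk in QPCR_HOUSEKEEPING:
                    hk_true[hk] = QPCR_HK_BASE_CT[hk] + loading
                    rows.append(_well_row(sample_id, mouse_id, group, day, hk,
                                          hk_true[hk], sd, rng))
                hk_mean = float(np.mean(list(hk_true.values())))
                for gene in QPCR_GENES:
                    true_l2fc = 0.0
                    if group != "Sham":
                        true_l2fc = scenario.qpcr_true_log2fc.get((gene, group, day), 0.0)
                    ct = hk_mean + QPCR_BASELINE_DELTA_CT[gene] - true_l2fc
                    rows.append(_well_row(sample_id, mouse_id, group, day, gene, ct, sd, rng))
    return pd.DataFrame(rows)


def _well_row(sample_id, mouse_id, group, day, gene, true_ct, sd, rng):
    reps = true_ct + rng.normal(0.0, sd, size=3)
    return {
        "sample_id": sample_id, "mouse_id": mouse_id, "group": group, "day": day,
        "gene": gene, "ct_rep1": reps[0], "ct_rep2": reps[1], "ct_rep3": reps[2],
    }
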