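"""Longitudinal ear-swelling and inflammation-score statistics.

Each mouse contributes a time series of ear thickness (µm) and two ordinal
skin gradings, erythema and desquamation.  Swelling is thickness relative to
the sham-group mean at the same time point; the inflammation score is the sum
of the two ordinal grades (range 0–6).  Group curves are per-day mean ± SEM;
the maximum reaction of each group is compared against a reference group as a
percent reduction with first-order error propagation, and group differences
are tested with a two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .units import InvalidParameterError


class DataFormatError(ValueError):
    pass


class MissingReferenceError(ValueError):
    """No sham/reference data available where required."""


# Ordinal grade vocabularies and their scores (sum of the two = inflammation score).
ERYTHEMA_SCORES: Mapping[str, float] = {"no": 0.0, "mild": 0.5, "definite": 1.5, "severe": 3.0}
DESQUAMATION_SCORES: Mapping[str, float] = {"no": 0.0, "dry": 1.0, "crust formation": 2.0, "moist": 3.0}


@dataclass(frozen=True)
class ScoreTable:
    erythema: Mapping[str, float] = field(default_factory=lambda: dict(ERYTHEMA_SCORES))
    desquamation: Mapping[str, float] = field(default_factory=lambda: dict(DESQUAMATION_SCORES))

    def _lookup(self, table: Mapping[str, float], level, kind: str) -> float:
        if isinstance(level, (int, float)) and not isinstance(level, bool):
            if float(level) in set(table.values()):
                return float(level)
            raise DataFormatError(f"numeric {kind} score {level} not in {sorted(set(table.values()))}")
        key = str(level).strip().lower()
        if key not in table:
            raise DataFormatError(f"unknown {kind} level {level!r}; expected one of {sorted(table)}")
        return table[key]

    def erythema_score(self, level) -> float:
        return self._lookup(self.erythema, level, "erythema")

    def desquamation_score(self, level) -> float:
        return self._lookup(self.desquamation, level, "desquamation")


DEFAULT_SCORE_TABLE = ScoreTable()


@dataclass
class MouseRecord:
    """Longitudinal observations of one mouse's irradiated ear."""

    mouse_id: str
    dose_gy: float
    dose_rate_label: str  # Conv, Flash9, Flash930, or Sham
    days: np.ndarray
    ear_thickness_um: np.ndarray
    erythema: list
    desquamation: list

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.ear_thickness_um = np.asarray(self.ear_thickness_um, dtype=float)
        if self.days.size == 0:
            raise DataFormatError(f"mouse {self.mouse_id}: no observations")
        if not np.all(np.diff(self.days) > 0):
            raise DataFormatError(f"mouse {self.mouse_id}: days must be strictly increasing")
        if np.any(self.ear_thickness_um <= 0):
            raise DataFormatError(f"mouse {self.mouse_id}: ear thickness must be > 0 µm")
        if not (len(self.erythema) == len(self.desquamation) == self.days.size):
            raise DataFormatError(f"mouse {self.mouse_id}: ragged observation arrays")

    @property
    def group(self) -> tuple[float, str]:
        return (self.dose_gy, self.dose_rate_label)

    def scores(self, table: ScoreTable = DEFAULT_SCORE_TABLE) -> np.ndarray:
        return np.array(
            [
                inflammation_score(e, d, table)
                for e, d in zip(self.erythema, self.desquamation)
            ]
        )


def ear_swelling(ear_thickness_um: float, sham_mean_um: float) -> float:
    """Swelling (µm) of one ear relative to the sham-group mean thickness."""
    return ear_thickness_um - sham_mean_um


def inflammation_score(erythema_level, desquamation_level, table: ScoreTable = DEFAULT_SCORE_TABLE) -> float:
    """Sum of the erythema and desquamation grades; range [0, 6]."""
    return table.erythema_score(erythema_level) + table.desquamation_score(desquamation_level)


class ShamReference:
    """Mean sham ear thickness as a function of day.

    Each sham mouse's series is linearly interpolated (clamped to its own
    observed day range, never extrapolated) onto the query day; the reference
    is the mean over sham mice.  Evaluated at a sham mouse's own measurement
    day this reproduces its measured thickness exactly, so sham-centred
    swelling averages to zero identically.
    """

    def __init__(self, sham_records: Sequence[MouseRecord]):
        if len(sham_records) == 0:
            raise MissingReferenceError("no sham mice available for the swelling reference")
        self._records = list(sham_records)

    def mean_thickness(self, days) -> np.ndarray:
        days = np.atleast_1d(np.asarray(days, dtype=float))
        per_mouse = np.stack(
            [np.interp(days, r.days, r.ear_thickness_um) for r in self._records]
        )
        return per_mouse.mean(axis=0)

    def sem_thickness(self, days) -> np.ndarray:
        """Standard error of the sham mean itself; it is an estimate, and its
        sampling error propagates into every sham-referenced swelling mean."""
        days = np.atleast_1d(np.asarray(days, dtype=float))
        per_mouse = np.stack(
            [np.interp(days, r.days, r.ear_thickness_um) for r in self._records]
        )
        if per_mouse.shape[0] < 2:
            return np.full(days.shape, np.nan)
        return per_mouse.std(axis=0, ddof=1) / math.sqrt(per_mouse.shape[0])

    def __call__(self, days) -> np.ndarray:
        return self.mean_thickness(days)


def swelling_series(record: MouseRecord, sham: ShamReference) -> np.ndarray:
    """Per-observation swelling of one mouse: ET_i(t) − mean sham ET(t)."""
    return record.ear_thickness_um - sham.mean_thickness(record.days)


Quantity = Literal["swelling", "score", "thickness"]


def _mouse_values(record: MouseRecord, quantity: Quantity, sham: ShamReference | None,
                  table: ScoreTable) -> np.ndarray:
    if quantity == "swelling":
        if sham is None:
            raise MissingReferenceError("swelling requires a sham reference")
        return swelling_series(record, sham)
    if quantity == "score":
        return record.scores(table)
    if quantity == "thickness":
        return record.ear_thickness_um.copy()
    raise InvalidParameterError(f"unknown quantity {quantity!r}")


def group_curve(
    records: Sequence[MouseRecord],
    quantity: Quantity = "swelling",
    sham: ShamReference | None = None,
    align: Literal["interpolate", "observed"] = "interpolate",
    table: ScoreTable = DEFAULT_SCORE_TABLE,
) -> pd.DataFrame:
    """Per-day group mean ± SEM of swelling, score, or raw thickness.

    ``align='interpolate'`` (default): every mouse's series is linearly
    interpolated onto an integer-day grid restricted to its own observed
    range; per-day statistics run over the mice covering that day.
    ``align='observed'``: only mice measured exactly on a day contribute.
    SEM is NaN where n == 1.
    """
    if len(records) == 0:
        raise DataFormatError("empty group: no mice to aggregate")
    rows = []
    if align == "interpolate":
        d0 = int(min(r.days.min() for r in records))
        d1 = int(max(r.days.max() for r in records))
        grid = np.arange(d0, d1 + 1, dtype=float)
        for rec in records:
            mask = (grid >= rec.days.min()) & (grid <= rec.days.max())
            if quantity == "swelling":
                if sham is None:
                    raise MissingReferenceError("swelling requires a sham reference")
                # interpolate thickness, then subtract the sham mean at the
                # grid day itself — this keeps the sham-centring identity
                # exact even between the sham mice's own measurement days
                interp = (
                    np.interp(grid[mask], rec.days, rec.ear_thickness_um)
                    - sham.mean_thickness(grid[mask])
                )
            else:
                vals = _mouse_values(rec, quantity, sham, table)
                interp = np.interp(grid[mask], rec.days, vals)
            rows.append(pd.DataFrame({"day": grid[mask], "value": interp, "mouse_id": rec.mouse_id}))
    elif align == "observed":
        for rec in records:
            vals = _mouse_values(rec, quantity, sham, table)
            rows.append(pd.DataFrame({"day": rec.days, "value": vals, "mouse_id": rec.mouse_id}))
    else:
        raise InvalidParameterError(f"unknown alignment {align!r}")
    long = pd.concat(rows, ignore_index=True)
    g = long.groupby("day")["value"]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, ["sd", "sem"]] = np.nan
    return out.reset_index()[["day", "mean", "sem", "sd", "n"]]


def peak_reaction(
    curve: pd.DataFrame, window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """(day, mean, sem) of the maximal group mean; ties break to the earliest day."""
    sub = curve
    if window is not None:
        lo, hi = window
        sub = curve[(curve["day"] >= lo) & (curve["day"] <= hi)]
    sub = sub.dropna(subset=["mean"])
    if len(sub) == 0:
        raise MissingReferenceError("no data in the requested day window")
    idx = int(np.argmax(sub["mean"].to_numpy()))  # argmax returns the first maximum
    row = sub.iloc[idx]
    return float(row["day"]), float(row["mean"]), float(row["sem"])


def percent_reduction(
    ref: tuple[float, float], test: tuple[float, float]
) -> tuple[float, float]:
    """Percent reduction of the test peak relative to the reference peak.

    R = 100 (1 − m_t/m_r);  σ_R = 100 sqrt((σ_t/m_r)² + (m_t σ_r / m_r²)²).
    """
    m_r, s_r = ref
    m_t, s_t = test
    if m_r <= 0:
        raise InvalidParameterError("reference mean must be > 0 for a percent reduction")
    r = 100.0 * (1.0 - m_t / m_r)
    sem = 100.0 * math.sqrt((s_t / m_r) ** 2 + (m_t * s_r / m_r**2) ** 2)
    return r, sem


def two_sample_ttest(a: Sequence[float], b: Sequence[float], equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each sample needs at least 2 observations")
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        # degenerate: zero pooled variance
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass(frozen=True)
class ReductionResult:
    """Peak-reaction comparison of one test group against the reference group."""

    reference: str
    test: str
    quantity: str
    peak_day_ref: float
    peak_day_test: float
    peak_ref: float
    peak_ref_sem: float
    peak_test: float
    peak_test_sem: float
    reduction_percent: float
    reduction_sem: float
    t_statistic: float
    p_value: float


def _per_mouse_at_day(records: Sequence[MouseRecord], day: float, quantity: Quantity,
                      sham: ShamReference | None, table: ScoreTable) -> np.ndarray:
    vals = []
    for rec in records:
        if rec.days.min() <= day <= rec.days.max():
            if quantity == "swelling":
                assert sham is not None
                v = float(np.interp(day, rec.days, rec.ear_thickness_um)) - float(
                    sham.mean_thickness(day)[0]
                )
            else:
                v = float(np.interp(day, rec.days, _mouse_values(rec, quantity, sham, table)))
            vals.append(v)
    return np.asarray(vals)


def reduction_analysis(
    records: Sequence[MouseRecord],
    dose_gy: float = 33.0,
    reference_label: str = "Conv",
    test_labels: Sequence[str] = ("Flash9", "Flash930"),
    quantity: Quantity = "swelling",
    window: tuple[float, float] | None = None,
    peak_mode: Literal["own", "common"] = "own",
    equal_var: bool = True,
    table: ScoreTable = DEFAULT_SCORE_TABLE,
) -> list[ReductionResult]:
    """Percent reduction of each test group's maximum reaction vs the reference.

    Peaks are each group's own maximum of the mean curve (``peak_mode='own'``);
    with ``'common'`` the test groups are evaluated at the reference peak day.
    Peak search is restricted to the fully covered span of each group curve
    (days where every mouse of the group contributes), so trailing days
    represented by a single animal cannot masquerade as the maximum reaction.
    The t-test compares per-mouse values interpolated at the peak days.
    """
    sham_records = [r for r in records if r.dose_rate_label.lower() == "sham"]
    sham = ShamReference(sham_records) if quantity == "swelling" else None
    if quantity == "swelling" and not sham_records:
        raise MissingReferenceError("swelling analysis requires sham mice")

    def group(label: str) -> list[MouseRecord]:
        recs = [r for r in records if r.dose_rate_label == label and r.dose_gy == dose_gy]
        if not recs:
            raise DataFormatError(f"no mice in group ({dose_gy} Gy, {label})")
        return recs

    def full_coverage(curve: pd.DataFrame) -> pd.DataFrame:
        return curve[curve["n"] == curve["n"].max()]

    def peak_sem(sem: float, day: float) -> float:
        # the subtracted sham mean is itself estimated; its standard error
        # adds in quadrature to the group SEM of sham-referenced swelling
        if quantity == "swelling" and sham is not None:
            return math.sqrt(sem**2 + float(sham.sem_thickness(day)[0]) ** 2)
        return sem

    ref_recs = group(reference_label)
    ref_curve = full_coverage(group_curve(ref_recs, quantity, sham, table=table))
    ref_day, ref_mean, ref_sem = peak_reaction(ref_curve, window)
    ref_sem = peak_sem(ref_sem, ref_day)
    ref_vals = _per_mouse_at_day(ref_recs, ref_day, quantity, sham, table)

    results = []
    for label in test_labels:
        test_recs = group(label)
        test_curve = full_coverage(group_curve(test_recs, quantity, sham, table=table))
        if peak_mode == "own":
            t_day, t_mean, t_sem = peak_reaction(test_curve, window)
        else:
            row = test_curve.loc[test_curve["day"] == ref_day]
            if row.empty:
                raise MissingReferenceError(f"group {label} has no data at day {ref_day}")
            t_day, t_mean, t_sem = ref_day, float(row["mean"].iloc[0]), float(row["sem"].iloc[0])
        t_sem = peak_sem(t_sem, t_day)
        red, red_sem = percent_reduction((ref_mean, ref_sem), (t_mean, t_sem))
        test_vals = _per_mouse_at_day(test_recs, t_day, quantity, sham, table)
        t_stat, p = two_sample_ttest(ref_vals, test_vals, equal_var=equal_var)
        results.append(
            ReductionResult(
                reference=reference_label, test=label, quantity=quantity,
                peak_day_ref=ref_day, peak_day_test=t_day,
                peak_ref=ref_mean, peak_ref_sem=ref_sem,
                peak_test=t_mean, peak_test_sem=t_sem,
                reduction_percent=red, reduction_sem=red_sem,
                t_statistic=t_stat, p_value=p,
            )
        )
    return results
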