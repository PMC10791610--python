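"""CSV/YAML readers and writers with schema validation.

All tables are comma-separated UTF-8 with a header row and '.' decimal
separator; European comma decimals (``0,001``) are normalised on read with a
warning.  Errors name the offending row and column.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .beam import BeamConfig, BeamMode
from .bloodvolume import DiameterTable, EntryVein, VesselSegment
from .cohort import DEFAULT_SCORE_TABLE, MouseRecord, ScoreTable
from .units import InvalidParameterError


class DataFormatError(ValueError):
    pass


_COMMA_DECIMAL = re.compile(r"^-?\d+,\d+$")


def _numeric(series: pd.Series, column: str, path) -> pd.Series:
    """Parse a numeric column, normalising comma decimals with a warning."""
    s = series.copy()
    if s.dtype == object:
        mask = s.astype(str).str.match(_COMMA_DECIMAL)
        if mask.any():
            warnings.warn(
                f"{path}: column {column!r} uses comma decimal separators; normalising",
                stacklevel=3,
            )
            s = s.astype(str).str.replace(",", ".", regex=False)
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based + header
        raise DataFormatError(f"{path}: unparseable number in column {column!r}, row {row}")
    return out


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required columns {missing}")


MEASUREMENT_COLUMNS = (
    "mouse_id", "dose_Gy", "dose_rate_label", "day", "ear_thickness_um",
    "erythema", "desquamation",
)


def read_measurements(path, score_table: ScoreTable = DEFAULT_SCORE_TABLE) -> list[MouseRecord]:
    """Read a longitudinal measurement table into validated mouse records."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    for col in ("dose_Gy", "day", "ear_thickness_um"):
        df[col] = _numeric(df[col], col, path)
    dup = df.duplicated(subset=["mouse_id", "day"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise DataFormatError(f"{path}: duplicate mouse_id/day observation at row {row}")
    for col, check in (("erythema", score_table.erythema_score),
                       ("desquamation", score_table.desquamation_score)):
        for i, level in enumerate(df[col]):
            try:
                check(level)
            except ValueError as exc:
                raise DataFormatError(f"{path}: row {i + 2}, column {col!r}: {exc}") from exc
    records = []
    for mouse_id, sub in df.groupby("mouse_id", sort=False):
        sub = sub.sort_values("day")
        doses = sub["dose_Gy"].unique()
        labels = sub["dose_rate_label"].unique()
        if len(doses) > 1 or len(labels) > 1:
            raise DataFormatError(f"{path}: mouse {mouse_id} appears in multiple groups")
        records.append(
            MouseRecord(
                mouse_id=str(mouse_id), dose_gy=float(doses[0]), dose_rate_label=str(labels[0]),
                days=sub["day"].to_numpy(), ear_thickness_um=sub["ear_thickness_um"].to_numpy(),
                erythema=list(sub["erythema"]), desquamation=list(sub["desquamation"]),
            )
        )
    return records


def write_measurements(records: Sequence[MouseRecord], path) -> None:
    rows = []
    for rec in records:
        for i in range(rec.days.size):
            rows.append({
                "mouse_id": rec.mouse_id, "dose_Gy": rec.dose_gy,
                "dose_rate_label": rec.dose_rate_label, "day": int(rec.days[i]),
                "ear_thickness_um": rec.ear_thickness_um[i],
                "erythema": rec.erythema[i], "desquamation": rec.desquamation[i],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vessel_trace(path, polyline_path=None) -> list[VesselSegment]:
    """Read vessel segments; lengths from the table or a companion polyline CSV."""
    from .bloodvolume import polyline_lengths

    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("vessel_id", "size_class"), path)
    lengths: dict[str, float] = {}
    if "length_mm" in df.columns:
        df["length_mm"] = _numeric(df["length_mm"], "length_mm", path)
        lengths = dict(zip(df["vessel_id"].astype(str), df["length_mm"]))
    elif polyline_path is None:
        raise DataFormatError(f"{path}: needs a length_mm column or a companion polyline CSV")
    if polyline_path is not None:
        pdf = pd.read_csv(polyline_path)
        _require_columns(pdf, ("vessel_id", "point_index", "x_mm", "y_mm"), polyline_path)
        for col in ("point_index", "x_mm", "y_mm"):
            pdf[col] = _numeric(pdf[col], col, polyline_path)
        for vid, sub in pdf.groupby("vessel_id", sort=False):
            pts = sub.sort_values("point_index")[["x_mm", "y_mm"]].to_numpy()
            lengths[str(vid)] = polyline_lengths([pts])[0]
    segments = []
    for i, row in df.iterrows():
        vid = str(row["vessel_id"])
        if vid not in lengths:
            raise DataFormatError(f"{path}: row {i + 2}: no length or polyline for vessel {vid!r}")
        try:
            segments.append(VesselSegment(vid, str(row["size_class"]).strip().lower(), lengths[vid]))
        except ValueError as exc:
            raise DataFormatError(f"{path}: row {i + 2}: {exc}") from exc
    return segments


def write_vessel_trace(segments: Sequence[VesselSegment], path,
                       polylines: dict[str, np.ndarray] | None = None,
                       polyline_path=None) -> None:
    pd.DataFrame(
        [{"vessel_id": s.vessel_id, "size_class": s.size_class, "length_mm": s.length_mm}
         for s in segments]
    ).to_csv(path, index=False)
    if polylines is not None and polyline_path is not None:
        rows = []
        for vid, pts in polylines.items():
            for i, (x, y) in enumerate(np.asarray(pts)):
                rows.append({"vessel_id": vid, "point_index": i, "x_mm": x, "y_mm": y})
        pd.DataFrame(rows).to_csv(polyline_path, index=False)


def read_entry_veins(path) -> list[EntryVein]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("vein_id", "diameter_mm"), path)
    df["diameter_mm"] = _numeric(df["diameter_mm"], "diameter_mm", path)
    veins = []
    for i, row in df.iterrows():
        try:
            veins.append(
                EntryVein(str(row["vein_id"]), float(row["diameter_mm"]),
                          str(row.get("size_class", "thick")).strip().lower()
                          if "size_class" in df.columns else "thick")
            )
        except ValueError as exc:
            raise DataFormatError(f"{path}: row {i + 2}: {exc}") from exc
    return veins


def write_entry_veins(veins: Sequence[EntryVein], path) -> None:
    pd.DataFrame(
        [{"vein_id": v.vein_id, "diameter_mm": v.diameter_mm, "size_class": v.size_class}
         for v in veins]
    ).to_csv(path, index=False)


def read_qpcr(path) -> pd.DataFrame:
    """Read a Ct table (wide triplicate columns or long format with a ct column)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("sample_id", "mouse_id", "group", "day", "gene"), path)
    df["day"] = _numeric(df["day"], "day", path).astype(int)
    rep_cols = [c for c in df.columns if c.startswith("ct_rep")] or (
        ["ct"] if "ct" in df.columns else []
    )
    if not rep_cols:
        raise DataFormatError(f"{path}: needs ct_rep* columns or a long-format 'ct' column")
    for col in rep_cols:
        df[col] = _numeric(df[col], col, path)
    return df


def read_beam_config(path) -> BeamConfig:
    """Load a beam configuration from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DataFormatError(f"{path}: expected a mapping of beam-config fields")
    try:
        return BeamConfig(
            peak_current_na=float(raw["peak_current_na"]),
            let_kev_um=float(raw.get("let_kev_um", 2.6)),
            field_area_mm2=float(raw.get("field_area_mm2", 42.25)),
            density_g_cm3=float(raw.get("density_g_cm3", 1.0)),
            mode=BeamMode(raw.get("mode", "continuous")),
            pulse_width_ns=(float(raw["pulse_width_ns"]) if "pulse_width_ns" in raw else None),
            pulse_period_us=(float(raw["pulse_period_us"]) if "pulse_period_us" in raw else None),
            particle_energy_mev=(float(raw["particle_energy_mev"])
                                 if "particle_energy_mev" in raw else None),
            label=str(raw.get("label", path.stem)),
        )
    except KeyError as exc:
        raise DataFormatError(f"{path}: missing beam-config field {exc}") from exc
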