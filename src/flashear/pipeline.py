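"""End-to-end pipeline orchestration: simulate or load inputs, run every
analysis stage, and write a machine-readable report bundle."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .beam import DEFAULT_BEAM_CONFIGS, NOMINAL_MEAN_DOSE_RATES, duration_for_dose, plan_irradiation
from .bloodvolume import FlowParameters, estimate, total_blood_volume
from .cohort import reduction_analysis
from .io import read_entry_veins, read_measurements, read_qpcr, read_vessel_trace
from .qpcr import analyze_plate, group_log2fc_summary


@dataclass
class RunConfig:
    """Inputs and analysis flags for one pipeline run."""

    measurements_csv: str | None = None
    vessels_csv: str | None = None
    polylines_csv: str | None = None
    veins_csv: str | None = None
    qpcr_csv: str | None = None
    out_dir: str = "."
    seed: int = 0
    total_dose_gy: float = 33.0
    flow_speed_mm_s: float = 2.0
    body_weight_g: float = 19.2
    reference_group: str = "Conv"
    housekeeping: tuple[str, ...] = ("B2M", "GAPDH")
    qpcr_reference_group: str = "Sham"
    peak_mode: str = "own"
    equal_var: bool = True

    def validate(self) -> None:
        if all(p is None for p in (self.measurements_csv, self.vessels_csv, self.qpcr_csv)):
            raise ValueError("empty config: no input tables given; nothing to analyse")
        for p in (self.measurements_csv, self.vessels_csv, self.polylines_csv,
                  self.veins_csv, self.qpcr_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # where the report lands does not change its content
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def beam_report(total_dose_gy: float = 33.0) -> list[dict]:
    """One row per irradiation mode: currents, dose rates, duty cycle, durations."""
    rows = []
    for label, cfg in DEFAULT_BEAM_CONFIGS.items():
        plan = plan_irradiation(cfg, total_dose_gy)
        rows.append({
            "mode": label,
            "field_area_mm2": cfg.field_area_mm2,
            "peak_current_nA": cfg.peak_current_na,
            "mean_current_nA": cfg.peak_current_na * cfg.duty_cycle,
            "peak_dose_rate_Gy_s": plan.peak_dose_rate_gy_s,
            "mean_dose_rate_Gy_s": plan.mean_dose_rate_gy_s,
            "duty_cycle": plan.duty_cycle,
            "duration_s": plan.duration_s,
            "duration_s_nominal_rate": duration_for_dose(
                total_dose_gy, NOMINAL_MEAN_DOSE_RATES[label]
            ),
        })
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write report.json plus tidy CSVs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "meta": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "notes": "p-values are raw (no multiple-testing correction applied)",
        }
    }

    report["beam"] = beam_report(config.total_dose_gy)

    if config.vessels_csv:
        segments = read_vessel_trace(config.vessels_csv, config.polylines_csv)
        veins = read_entry_veins(config.veins_csv) if config.veins_csv else []
        blood_ml = total_blood_volume(config.body_weight_g)
        blood = {}
        for mode in ("Flash930", "Flash9", "Conv"):
            t = duration_for_dose(config.total_dose_gy, NOMINAL_MEAN_DOSE_RATES[mode])
            est = estimate(
                segments, veins, FlowParameters(config.flow_speed_mm_s, t),
                total_dose_gy=config.total_dose_gy, total_blood_ml=blood_ml,
            )
            blood[mode] = {
                "irradiation_time_s": t,
                "static_volume_ul": est.static_volume_ul,
                "flow_volume_ul": est.flow_volume_ul,
                "irradiated_volume_ul": est.irradiated_volume_ul,
                "blood_fraction_pct": est.blood_fraction_pct,
                "mean_blood_dose_Gy": est.mean_blood_dose_gy,
            }
        report["blood_volume"] = {"total_blood_ml": blood_ml, "modes": blood}

    if config.measurements_csv:
        records = read_measurements(config.measurements_csv)
        labels = sorted(
            {r.dose_rate_label for r in records}
            - {config.reference_group, "Sham"}
        )
        reductions = []
        for quantity in ("swelling", "score"):
            for res in reduction_analysis(
                records, dose_gy=config.total_dose_gy,
                reference_label=config.reference_group, test_labels=labels,
                quantity=quantity, peak_mode=config.peak_mode,  # type: ignore[arg-type]
                equal_var=config.equal_var,
            ):
                reductions.append(dataclasses.asdict(res))
        report["reductions"] = reductions

    if config.qpcr_csv:
        plate = read_qpcr(config.qpcr_csv)
        results = analyze_plate(
            plate, housekeeping=config.housekeeping,
            reference_group=config.qpcr_reference_group,
        )
        results.to_csv(out / "qpcr_fold_changes.csv", index=False)
        summary = group_log2fc_summary(results)
        summary.to_csv(out / "qpcr_summary.csv", index=False)
        report["qpcr"] = {
            "n_samples": int(results["sample_id"].nunique()),
            "max_abs_mean_log2fc": float(summary["mean_log2_fc"].abs().max()),
            "summary_csv": "qpcr_summary.csv",
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    pd.DataFrame(report["beam"]).to_csv(out / "beam_table.csv", index=False)
    return report
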