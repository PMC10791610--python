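"""ΔΔCt fold-change analysis of qPCR cytokine panels.

Relative expression follows the comparative-Ct method: for each sample,
ΔCt = Ct(gene of interest) − Ct(housekeeping); referenced to the sham group's
mean ΔCt for the same gene and day, ΔΔCt = ΔCt − mean ΔCt(sham); and

    FC = 2^(−ΔΔCt),        log2 FC = log₂(FC) = −ΔΔCt.

Replicate Ct wells are averaged arithmetically; undetermined (NaN) wells are
dropped with a warning, never imputed.  Two housekeeping genes may be
combined by averaging their per-sample Ct means (equivalent to normalising by
their geometric-mean expression) or a single gene can be selected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .units import InvalidParameterError


class MissingDataError(ValueError):
    pass


class MissingReferenceError(ValueError):
    pass


GENES_OF_INTEREST = ("TGF-b1", "TNF-a", "IL1a", "IL1b")
HOUSEKEEPING_GENES = ("B2M", "GAPDH")

#: Replicate spread (cycles) above which a QC warning is emitted.
QC_MAX_SPREAD_CYCLES = 0.5


def ct_mean(ct_values: Sequence[float], qc_warn: bool = False) -> float:
    """Arithmetic mean of the replicate Ct wells of one sample/gene.

    NaN wells (undetermined) are dropped with a warning.  With ``qc_warn``,
    a replicate spread larger than ``QC_MAX_SPREAD_CYCLES`` also warns.
    """
    arr = np.asarray(ct_values, dtype=float)
    if arr.size == 0:
        raise MissingDataError("no Ct replicates")
    finite = arr[np.isfinite(arr)]
    if finite.size < arr.size:
        warnings.warn(f"dropping {arr.size - finite.size} undetermined Ct well(s)", stacklevel=2)
    if finite.size == 0:
        raise MissingDataError("all Ct replicates undetermined")
    if np.any(finite <= 0):
        raise InvalidParameterError(f"Ct values must be > 0 cycles, got {finite.min()}")
    if qc_warn and finite.size > 1 and float(finite.max() - finite.min()) > QC_MAX_SPREAD_CYCLES:
        warnings.warn(
            f"Ct replicate spread {finite.max() - finite.min():.2f} cycles exceeds "
            f"{QC_MAX_SPREAD_CYCLES}", stacklevel=2,
        )
    return float(finite.mean())


def delta_delta_ct(ct_gene: float, ct_housekeeping: float, reference_delta_ct: float) -> float:
    """ΔΔCt = (Ct_gene − Ct_housekeeping) − mean ΔCt of the reference group."""
    for name, v in (("ct_gene", ct_gene), ("ct_housekeeping", ct_housekeeping),
                    ("reference_delta_ct", reference_delta_ct)):
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite, got {v}")
    return (ct_gene - ct_housekeeping) - reference_delta_ct


def fold_change(ddct: float) -> float:
    """FC = 2^(−ΔΔCt); strictly positive."""
    if not math.isfinite(ddct):
        raise InvalidParameterError(f"ΔΔCt must be finite, got {ddct}")
    return 2.0 ** (-ddct)


def log2_fold_change(fc: float) -> float:
    """log₂ of a fold change; composition with :func:`fold_change` gives −ΔΔCt."""
    if not (fc > 0 and math.isfinite(fc)):
        raise InvalidParameterError(f"fold change must be finite and > 0, got {fc}")
    return math.log2(fc)


@dataclass(frozen=True)
class FoldChangeResult:
    sample_id: str
    mouse_id: str
    group: str
    day: int
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    log2_fc: float


def _sample_ct_table(plate: pd.DataFrame, qc_warn: bool) -> pd.DataFrame:
    """Collapse replicate wells to one mean Ct per sample × gene."""
    required = {"sample_id", "mouse_id", "group", "day", "gene"}
    missing = required - set(plate.columns)
    if missing:
        raise MissingDataError(f"Ct table missing columns: {sorted(missing)}")
    rep_cols = [c for c in plate.columns if c.startswith("ct_rep")]
    if rep_cols:
        long = plate.melt(
            id_vars=["sample_id", "mouse_id", "group", "day", "gene"],
            value_vars=rep_cols, value_name="ct",
        ).drop(columns="variable")
    elif "ct" in plate.columns:
        long = plate[["sample_id", "mouse_id", "group", "day", "gene", "ct"]].copy()
    else:
        raise MissingDataError("Ct table needs ct_rep* columns or a long-format 'ct' column")
    rows = []
    for (sid, mid, grp, day, gene), sub in long.groupby(
        ["sample_id", "mouse_id", "group", "day", "gene"], sort=False
    ):
        rows.append(
            {"sample_id": sid, "mouse_id": mid, "group": grp, "day": int(day),
             "gene": gene, "ct": ct_mean(sub["ct"].to_numpy(), qc_warn=qc_warn)}
        )
    return pd.DataFrame(rows)


def analyze_plate(
    plate: pd.DataFrame,
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
    reference_group: str = "Sham",
    qc_warn: bool = False,
) -> pd.DataFrame:
    """Per-sample ΔCt/ΔΔCt/FC/log2FC for every gene of interest on a plate.

    ``plate`` is a table with columns ``sample_id, mouse_id, group, day, gene``
    and either triplicate columns ``ct_rep1..3`` or a long-format ``ct``
    column.  Housekeeping is the mean Ct of the listed genes (one or two).
    The sham reference ΔCt is the mean over ``reference_group`` samples at the
    same day, per gene.
    """
    if len(housekeeping) == 0:
        raise InvalidParameterError("need at least one housekeeping gene")
    cts = _sample_ct_table(plate, qc_warn)
    hk = cts[cts["gene"].isin(housekeeping)]
    if hk.empty:
        raise MissingReferenceError(f"no housekeeping Ct values for {tuple(housekeeping)}")
    hk_by_sample = hk.groupby("sample_id")["ct"].mean()

    goi = cts[~cts["gene"].isin(housekeeping)].copy()
    goi["ct_hk"] = goi["sample_id"].map(hk_by_sample)
    if goi["ct_hk"].isna().any():
        bad = goi.loc[goi["ct_hk"].isna(), "sample_id"].unique()
        raise MissingReferenceError(f"samples without housekeeping Ct: {list(bad)}")
    goi["delta_ct"] = goi["ct"] - goi["ct_hk"]

    ref = goi[goi["group"] == reference_group]
    if ref.empty:
        raise MissingReferenceError(f"no samples in reference group {reference_group!r}")
    ref_dct = ref.groupby(["gene", "day"])["delta_ct"].mean()

    def _ref(row):
        try:
            return ref_dct.loc[(row["gene"], row["day"])]
        except KeyError:
            raise MissingReferenceError(
                f"no {reference_group} reference ΔCt for gene {row['gene']} day {row['day']}"
            )

    goi["delta_delta_ct"] = goi.apply(lambda r: r["delta_ct"] - _ref(r), axis=1)
    goi["fold_change"] = 2.0 ** (-goi["delta_delta_ct"])
    goi["log2_fc"] = -goi["delta_delta_ct"]
    return goi[
        ["sample_id", "mouse_id", "group", "day", "gene",
         "delta_ct", "delta_delta_ct", "fold_change", "log2_fc"]
    ].reset_index(drop=True)


def group_log2fc_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (ddof=1) of log2 FC per gene × day × group; SD NaN for n=1."""
    if results.empty:
        raise MissingDataError("no fold-change results to summarise")
    g = results.groupby(["gene", "day", "group"])["log2_fc"]
    out = pd.DataFrame({"mean_log2_fc": g.mean(), "sd_log2_fc": g.std(ddof=1), "n": g.size()})
    return out.reset_index()
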