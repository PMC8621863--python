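"""Deterministic risk characterisation: PNEC, risk quotient, risk bands.

The predicted no-effect concentration is the acute EC/LC50 divided by an
assessment factor (1000 for a base set of acute data); the risk quotient is
the measured environmental concentration over the PNEC.  RQ bands follow
the standard screening scheme with left-closed edges:

    [0, 1)    no significant risk
    [1, 10)   small adverse effects
    [10, 100) significant adverse effects
    [100, ∞)  potential adverse effects

Two unit modes are provided because release-medium concentration tables in
the source literature are sometimes internally inconsistent: ``si_strict``
honours each record's printed unit and converts everything to µg/L before
division, while ``paper_numeric`` treats table numerals as µg/L regardless
of the printed header (reproducing narrative RQ bands computed that way).
Rows whose band reaches "potential adverse" under ``paper_numeric`` can
only move up under ``si_strict`` for mg/L records, since the RQ grows by
the conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .units import AnalyteConcentration, convert

__all__ = [
    "RiskBand",
    "UnitMode",
    "RiskResult",
    "pnec",
    "band_of",
    "risk_quotient",
    "risk_table",
]

DEFAULT_ASSESSMENT_FACTOR = 1000  # acute base-set assessment factor


class RiskBand(str, Enum):
    no_significant_risk = "no_significant_risk"
    small_adverse = "small_adverse"
    significant_adverse = "significant_adverse"
    potential_adverse = "potential_adverse"


class UnitMode(str, Enum):
    si_strict = "si_strict"
    paper_numeric = "paper_numeric"


@dataclass(frozen=True)
class RiskResult:
    """One risk characterisation: PNEC, MEC, RQ and band, with provenance."""

    product: str
    analyte: str
    condition: str
    organism: str | None
    duration_h: int | None
    ec50_ugL: float
    af: int
    pnec_ugL: float
    mec_ugL: float
    rq: float
    band: RiskBand
    unit_mode: UnitMode

    @property
    def pnec_ngL(self) -> float:
        return convert(self.pnec_ugL, "ug_per_L", "ng_per_L")


def pnec(ec50: float, af: int = DEFAULT_ASSESSMENT_FACTOR) -> float:
    """Predicted no-effect concentration ``ec50 / af`` (unit preserved)."""
    if not ec50 > 0:
        raise ValueError("ec50 must be positive")
    if not (isinstance(af, (int, np.integer)) and af >= 1):
        raise ValueError("assessment factor must be an integer >= 1")
    return float(ec50) / float(af)


def band_of(rq: float) -> RiskBand:
    """Assign the screening risk band for a risk quotient (left-closed)."""
    rq = float(rq)
    if rq < 0 or not np.isfinite(rq):
        raise ValueError(f"risk quotient must be finite and >= 0, got {rq!r}")
    if rq < 1.0:
        return RiskBand.no_significant_risk
    if rq < 10.0:
        return RiskBand.small_adverse
    if rq < 100.0:
        return RiskBand.significant_adverse
    return RiskBand.potential_adverse


def risk_quotient(
    mec: AnalyteConcentration,
    pnec_value: float,
    pnec_unit: str = "ug_per_L",
    unit_mode: UnitMode | str = UnitMode.si_strict,
    ec50_ugL: float = float("nan"),
    af: int = DEFAULT_ASSESSMENT_FACTOR,
    organism: str | None = None,
    duration_h: int | None = None,
) -> RiskResult:
    """Risk quotient MEC/PNEC with band assignment.

    ``si_strict`` converts the MEC to µg/L using its printed unit;
    ``paper_numeric`` takes the MEC numeral as µg/L regardless of unit.
    The PNEC is always interpreted in ``pnec_unit`` and converted to µg/L.
    """
    unit_mode = UnitMode(unit_mode)
    if not pnec_value > 0:
        raise ValueError("pnec must be positive")
    pnec_ugL = convert(float(pnec_value), pnec_unit, "ug_per_L")
    if unit_mode is UnitMode.si_strict:
        mec_ugL = mec.in_unit("ug_per_L")
    else:
        mec_ugL = float(mec.value)
    rq = mec_ugL / pnec_ugL
    return RiskResult(
        product=mec.product,
        analyte=mec.analyte.value,
        condition=mec.condition.value,
        organism=organism,
        duration_h=duration_h,
        ec50_ugL=float(ec50_ugL),
        af=int(af),
        pnec_ugL=pnec_ugL,
        mec_ugL=mec_ugL,
        rq=rq,
        band=band_of(rq),
        unit_mode=unit_mode,
    )


_EC50_COLS = {"product", "analyte", "condition", "organism", "duration_h", "ec50_ugL"}
_MEC_COLS = {"product", "analyte", "condition", "value", "unit"}


def risk_table(
    ec50_table: pd.DataFrame,
    mec_table: pd.DataFrame,
    af: int = DEFAULT_ASSESSMENT_FACTOR,
    unit_mode: UnitMode | str = UnitMode.paper_numeric,
) -> pd.DataFrame:
    """Cross EC/LC50 records with measured concentrations into a risk table.

    Joins on (product, analyte, condition).  Unmatched rows from either
    side are kept with status ``unmatched_mec`` / ``unmatched_ec50``; EC50s
    recorded as not determined (NaN) yield status ``not_determined`` with
    no RQ.  Returns columns: product, analyte, condition, organism,
    duration_h, ec50_ugL, af, pnec_ngL, mec_ugL, rq, band, unit_mode,
    status.
    """
    unit_mode = UnitMode(unit_mode)
    for cols, df, name in ((_EC50_COLS, ec50_table, "ec50_table"),
                           (_MEC_COLS, mec_table, "mec_table")):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} missing columns {sorted(missing)}")
    if mec_table.empty:
        import warnings

        warnings.warn("empty MEC table: no risk rows produced", stacklevel=2)
    merged = ec50_table.merge(
        mec_table,
        on=["product", "analyte", "condition"],
        how="outer",
        indicator=True,
    )
    rows = []
    for _, rec in merged.iterrows():
        row = {
            "product": rec["product"],
            "analyte": rec["analyte"],
            "condition": rec["condition"],
            "organism": rec.get("organism"),
            "duration_h": rec.get("duration_h"),
            "ec50_ugL": rec.get("ec50_ugL", np.nan),
            "af": af,
            "pnec_ngL": np.nan,
            "mec_ugL": np.nan,
            "rq": np.nan,
            "band": None,
            "unit_mode": unit_mode.value,
        }
        if rec["_merge"] == "left_only":
            row["status"] = "unmatched_mec"
        elif rec["_merge"] == "right_only":
            row["status"] = "unmatched_ec50"
        elif pd.isna(rec["ec50_ugL"]):
            row["status"] = "not_determined"
        else:
            mec = AnalyteConcentration(
                product=rec["product"],
                analyte=rec["analyte"],
                condition=rec["condition"],
                value=float(rec["value"]),
                unit=rec["unit"],
            )
            res = risk_quotient(
                mec,
                pnec(float(rec["ec50_ugL"]), af),
                pnec_unit="ug_per_L",
                unit_mode=unit_mode,
                ec50_ugL=float(rec["ec50_ugL"]),
                af=af,
                organism=rec.get("organism"),
                duration_h=rec.get("duration_h"),
            )
            row.update(
                pnec_ngL=res.pnec_ngL,
                mec_ugL=res.mec_ugL,
                rq=res.rq,
                band=res.band.value,
                status="ok",
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["product", "analyte", "condition", "organism", "duration_h"],
        na_position="last",
    ).reset_index(drop=True)
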