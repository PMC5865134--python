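"""Human-readable outputs: SIR tables, risk-change percentages, case-mix
summaries and choropleth-ready GeoJSON exports.

Display conventions follow epidemiological reporting practice: SIRs to two
decimals, percentages to one; the underlying files always keep full
precision (shortest round-trip decimal printing), so re-importing an export
reproduces the numbers bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping


def percent_risk_change(sir: float) -> float:
    """Signed percent risk change implied by a SIR: (sir - 1) * 100.

    A SIR of 0.70 is a 30% reduced risk; 2.02 is a 102% increase. The exact
    value is returned; round only for display.
    """
    if sir <= 0:
        raise ValueError("SIR must be positive")
    return (sir - 1.0) * 100.0


@dataclass(frozen=True)
class CaseMixSummary:
    """Descriptive case mix: totals, type and gender splits, age spread."""

    total: int
    by_type: pd.DataFrame    # count, pct per emergency type
    by_gender: pd.DataFrame  # count, pct per gender
    age_median: float
    age_iqr: tuple[float, float]


def _share_table(series: pd.Series, total: int) -> pd.DataFrame:
    filled = series.fillna("unknown").astype(str)
    counts = filled.value_counts()
    return pd.DataFrame(
        {
            "count": counts,
            "pct": (100.0 * counts / total).round(1),
        }
    )


def case_mix_summary(records: pd.DataFrame) -> CaseMixSummary:
    """Counts and percentages by emergency type and gender, median [IQR] age.

    ``records`` has one row per case with columns type, gender, age. Missing
    type/gender values land in an explicit "unknown" bucket; ages use
    linear-interpolation percentiles.
    """
    if len(records) == 0:
        raise ValueError("no case records")
    total = len(records)
    ages = records["age"].dropna().to_numpy(dtype=float)
    if ages.size == 0:
        raise ValueError("no non-missing ages")
    q25, q50, q75 = np.percentile(ages, [25, 50, 75])
    return CaseMixSummary(
        total=total,
        by_type=_share_table(records["type"], total),
        by_gender=_share_table(records["gender"], total),
        age_median=float(q50),
        age_iqr=(float(q25), float(q75)),
    )


def export_sir_geojson(geometries: dict, summary: pd.DataFrame, path: str | Path) -> dict:
    """Write a FeatureCollection carrying smoothed SIRs as feature properties.

    ``geometries`` maps region_id -> shapely geometry (or GeoJSON geometry
    dict); every region in ``summary`` must have one. Properties carried:
    region_id, sir, lower, upper, elevated, at full precision.
    """
    missing = [r for r in summary["region_id"] if r not in geometries]
    if missing:
        raise ValueError(f"no geometry for regions: {missing}")
    feats = []
    for row in summary.itertuples(index=False):
        geom = geometries[row.region_id]
        gj = geom if isinstance(geom, dict) else mapping(geom)
        feats.append(
            {
                "type": "Feature",
                "geometry": gj,
                "properties": {
                    "region_id": row.region_id,
                    "sir": float(row.sir),
                    "lower": float(row.lower),
                    "upper": float(row.upper),
                    "elevated": bool(row.elevated),
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(fc))
    return fc


#: Fixed column order of the per-region SIR report.
SIR_TABLE_COLUMNS = [
    "region_id", "observed", "case_rate_per_10000", "expected",
    "crude_sir", "smoothed_sir", "lower", "upper", "elevated",
]


def sir_table(crude: pd.DataFrame, smoothed: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """Combined per-region report: observed, rate, expected, crude and
    smoothed SIR with CrI and elevated flag; optionally written as CSV.

    ``crude`` comes from the standardisation step (region_id, observed,
    expected, erp, crude_sir, case_rate_per_10000), ``smoothed`` from
    :func:`carmap.car_model.summarize_posterior`.
    """
    if list(crude["region_id"]) != list(smoothed["region_id"]):
        raise ValueError("crude and smoothed tables list different regions")
    out = pd.DataFrame(
        {
            "region_id": crude["region_id"].to_numpy(),
            "observed": crude["observed"].to_numpy(),
            "case_rate_per_10000": crude["case_rate_per_10000"].to_numpy(),
            "expected": crude["expected"].to_numpy(),
            "crude_sir": crude["crude_sir"].to_numpy(),
            "smoothed_sir": smoothed["sir"].to_numpy(),
            "lower": smoothed["lower"].to_numpy(),
            "upper": smoothed["upper"].to_numpy(),
            "elevated": smoothed["elevated"].to_numpy(),
        }
    )[SIR_TABLE_COLUMNS]
    if path is not None:
        out.to_csv(path, index=False)
    return out


def format_sir(sir: float) -> str:
    """Display form: SIR to 2 decimals."""
    return f"{sir:.2f}"


def format_pct(pct: float) -> str:
    """Display form: percentage to 1 decimal."""
    return f"{pct:.1f}"
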