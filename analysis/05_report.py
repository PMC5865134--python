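#!/usr/bin/env python
"""Descriptive reporting: case mix and risk-change percentages.

Expands the stratum-level counts into per-case records (ages within band,
emergency type split ~70/30 hypo/hyper), summarises the case mix, and
translates the final model's top-quintile SIR ratio into a percent risk
change. Writes results/analysis/case_mix.json.
"""

import json
from pathlib import Path

import pandas as pd

from carmap import case_mix_summary, case_records, percent_risk_change

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    stratum_cases = pd.read_csv(
        ROOT / "synthetic" / "stratum_cases.csv", index_col="region_id"
    )
    records = case_records(stratum_cases, seed=SEED)
    mix = case_mix_summary(records)
    print(
        f"{mix.total} cases: "
        f"{mix.by_type.loc['hypoglycaemia', 'pct']}% hypoglycaemia, "
        f"{mix.by_type.loc['hyperglycaemia', 'pct']}% hyperglycaemia; "
        f"{mix.by_gender.loc['male', 'pct']}% male; "
        f"median [IQR] age {mix.age_median:.0f} [{mix.age_iqr[0]:.0f}, {mix.age_iqr[1]:.0f}]"
    )

    multi = ROOT / "analysis" / "multivariable.csv"
    lines = {}
    if multi.exists():
        table = pd.read_csv(multi)
        for cov, grp in table.groupby("covariate"):
            top = grp.iloc[-1]
            pct = percent_risk_change(top.ratio)
            direction = "increased" if pct > 0 else "reduced"
            lines[cov] = (
                f"top quintile of {cov}: {abs(round(pct))}% {direction} risk "
                f"(SIR {top.ratio:.2f}, 95% CrI [{top.lower:.2f}, {top.upper:.2f}])"
            )
            print(lines[cov])

    (ROOT / "analysis" / "case_mix.json").write_text(
        json.dumps(
            {
                "total": mix.total,
                "by_type": mix.by_type.to_dict(),
                "by_gender": mix.by_gender.to_dict(),
                "age_median": mix.age_median,
                "age_iqr": mix.age_iqr,
                "risk_statements": lines,
            }
        )
    )


if __name__ == "__main__":
    main()
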