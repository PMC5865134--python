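#!/usr/bin/env python
"""Indirect age-gender standardisation of the synthetic caseload.

State-wide per-stratum rates are applied to each region's stratified
population to get expected caseloads, then crude SIRs and case rates per
10,000 residents. Writes results/analysis/region_table.csv.
"""

from pathlib import Path

import pandas as pd

from carmap import indirect_standardise

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cases = pd.read_csv(ROOT / "synthetic" / "stratum_cases.csv", index_col="region_id")
    pop = pd.read_csv(ROOT / "synthetic" / "population.csv", index_col="region_id")
    table = indirect_standardise(cases, pop)
    out = ROOT / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "region_table.csv", index=False)
    total_o, total_e = table.observed.sum(), table.expected.sum()
    print(
        f"standardised {len(table)} regions: total observed {int(total_o)}, "
        f"total expected {total_e:.2f} (conservation error {abs(total_o - total_e):.2e})"
    )
    print(
        f"case rates span {table.case_rate_per_10000.min():.2f}-"
        f"{table.case_rate_per_10000.max():.2f} per 10,000; "
        f"crude SIR {table.crude_sir.min():.2f}-{table.crude_sir.max():.2f}"
    )


if __name__ == "__main__":
    main()
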