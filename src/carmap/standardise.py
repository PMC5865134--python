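"""Indirect age-gender standardisation.

Standard rates are the state-wide per-stratum case rates; an area's expected
caseload applies those rates to its own stratified population. The
standardised incidence ratio (SIR) O/E then compares each area against the
state as a whole, free of age-gender composition effects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def compute_standard_rates(
    state_cases: pd.Series, state_population: pd.Series
) -> pd.Series:
    """Per-stratum standard rate sr_g = state cases_g / state population_g.

    Both inputs are indexed by stratum label and must cover the same strata;
    a stratum with zero population and non-zero cases is contradictory.
    """
    missing = set(state_cases.index) ^ set(state_population.index)
    if missing:
        raise ValueError(f"strata mismatch between cases and population: {sorted(missing)}")
    pop = state_population.reindex(state_cases.index).astype(float)
    cases = state_cases.astype(float)
    bad = (pop <= 0) & (cases > 0)
    if bad.any():
        raise ValueError(
            f"zero population with non-zero cases in strata: {list(cases.index[bad])}"
        )
    if (pop <= 0).any():
        raise ValueError(f"non-positive population in strata: {list(pop.index[pop <= 0])}")
    sr = cases / pop
    sr.name = "sr"
    return sr


def compute_expected(region_pop: pd.DataFrame, rates: pd.Series) -> pd.Series:
    """Expected caseload E_i = sum_g pop[i, g] * sr_g per region."""
    if set(region_pop.columns) != set(rates.index):
        raise ValueError("population strata do not match rate table strata")
    r = rates.reindex(region_pop.columns).to_numpy(dtype=float)
    e = pd.Series(region_pop.to_numpy(dtype=float) @ r, index=region_pop.index)
    e.name = "expected"
    return e


def compute_crude_sir(table: pd.DataFrame) -> pd.DataFrame:
    """Crude SIR = observed/expected per region.

    A region with E = 0 and O = 0 has an undefined SIR: it is flagged (NaN
    ratio, ``undefined`` True) rather than silently set to zero. E = 0 with
    O > 0 is inconsistent standardisation and raises.
    """
    obs = table["observed"].to_numpy(dtype=float)
    exp_ = table["expected"].to_numpy(dtype=float)
    bad = (exp_ == 0) & (obs > 0)
    if bad.any():
        ids = table.loc[bad, "region_id"].tolist() if "region_id" in table else list(np.where(bad)[0])
        raise ValueError(f"observed cases with zero expected caseload in regions: {ids}")
    undefined = exp_ == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} region(s) have undefined crude SIR (O = E = 0); "
            "they are flagged and should be excluded from modelling",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        sir = np.where(undefined, np.nan, obs / np.where(undefined, 1.0, exp_))
    out = table.copy()
    out["crude_sir"] = sir
    out["undefined"] = undefined
    return out


def compute_case_rate(table: pd.DataFrame) -> pd.Series:
    """Observed case rate per 10,000 residents: 10000 * O_i / ERP_i."""
    erp = table["erp"].to_numpy(dtype=float)
    if (erp <= 0).any():
        raise ValueError("estimated residential population must be > 0 for all regions")
    rate = pd.Series(
        1e4 * table["observed"].to_numpy(dtype=float) / erp,
        index=table.index,
        name="case_rate_per_10000",
    )
    return rate


def indirect_standardise(
    stratum_cases: pd.DataFrame, region_pop: pd.DataFrame
) -> pd.DataFrame:
    """End-to-end indirect standardisation from region x stratum tables.

    Aggregates the region x stratum case matrix to state totals, derives
    standard rates against the aggregated population, and returns the region
    case table (region_id, observed, expected, erp, crude_sir, undefined,
    case_rate_per_10000). Because the regions partition the standard
    population, sum(E_i) equals the state caseload exactly.
    """
    if not stratum_cases.index.equals(region_pop.index):
        raise ValueError("case and population tables list different regions")
    sr = compute_standard_rates(stratum_cases.sum(axis=0), region_pop.sum(axis=0))
    expected = compute_expected(region_pop, sr)
    table = pd.DataFrame(
        {
            "region_id": region_pop.index,
            "observed": stratum_cases.sum(axis=1).to_numpy(),
            "expected": expected.to_numpy(),
            "erp": region_pop.sum(axis=1).to_numpy(),
        }
    ).reset_index(drop=True)
    table = compute_crude_sir(table)
    table["case_rate_per_10000"] = compute_case_rate(table).to_numpy()
    return table
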