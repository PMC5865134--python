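"""Replicated simulation studies over the full pipeline.

Each study generates synthetic data with known ground truth, runs the
standardisation + BYM machinery end to end, and measures frequency
properties (interval coverage, bias, selection rates). The default problem
sizes — an 8x10 lattice of ~80 regions with populations of 20,000-60,000,
ICAR/noise precisions of 10 and desk-scale chains (2 x 5,000 burn-in x
20,000 iterations, thinned by 2) — are the package's standard validation
conditions; screening fits inside the stepwise study use shorter chains
(2,000 / 8,000) since only block significance is read off them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .car_model import (
    MCMCConfig,
    compute_dic,
    convergence_diagnostics,
    fit_bym,
    summarize_posterior,
)
from .covariates import (
    BYMModelSpec,
    precategorised,
    quintile_categorise,
    stepwise_multivariable,
    univariable_screen,
)
from .standardise import indirect_standardise
from .synthetic import (
    SimulationTruth,
    generate_covariates,
    generate_lattice,
    generate_population,
    simulate_counts,
    simulate_spatial_effects,
)

DEFAULT_ROWS, DEFAULT_COLS = 8, 10
DEFAULT_POP_RANGE = (20_000, 60_000)


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class StudyData:
    """One synthetic dataset ready for modelling."""

    lattice: object
    neighbors: object
    population: pd.DataFrame
    cases: pd.DataFrame          # standardised region table (E from the data)
    truth: SimulationTruth
    design: pd.DataFrame | None


def make_dataset(
    seed: int,
    beta: dict[str, np.ndarray] | None = None,
    tau_u: float = 10.0,
    tau_v: float = 10.0,
    null_effects: bool = False,
    n_rows: int = DEFAULT_ROWS,
    n_cols: int = DEFAULT_COLS,
    pop_range: tuple[int, int] = DEFAULT_POP_RANGE,
) -> StudyData:
    """Simulate one dataset and push it through indirect standardisation.

    ``beta`` maps covariate name -> per-category log risks (ref = 0); the
    design assigns each region a category uniformly at random. With
    ``null_effects`` both random effects are zeroed (pure Poisson noise).
    """
    s_pop, s_eff, s_cnt, s_des = _seeds(seed, 4)
    lattice = generate_lattice(n_rows, n_cols)
    ns = lattice.queen_neighbors()
    population = generate_population(lattice, pop_range, s_pop)
    if null_effects:
        u = np.zeros(lattice.n_regions)
        v = np.zeros(lattice.n_regions)
    else:
        u, v = simulate_spatial_effects(ns, tau_u, tau_v, s_eff)
    beta = beta or {}
    design = None
    if beta:
        rng = np.random.default_rng(s_des)
        design = pd.DataFrame(
            {
                name: rng.integers(0, len(b), size=lattice.n_regions)
                for name, b in beta.items()
            },
            index=list(lattice.region_ids),
        )
    truth = SimulationTruth(tau_u=tau_u, tau_v=tau_v, u=u, v=v, beta=dict(beta))
    sim = simulate_counts(population, truth, design, s_cnt)
    cases = indirect_standardise(sim.stratum_cases, population)
    return StudyData(
        lattice=lattice, neighbors=ns, population=population,
        cases=cases, truth=truth, design=design,
    )


def recovery_study(
    n_reps: int,
    seed: int,
    beta_true: float = 0.7,
    config: MCMCConfig | None = None,
) -> dict:
    """Can the model recover a known category effect?

    Each replicate carries one two-category covariate with log risk
    ``beta_true`` in the exposed category, on top of ICAR + iid effects
    (tau_u = tau_v = 10). Reports 95% CrI coverage of beta and the relative
    bias of the posterior-median risk ratio exp(beta).
    """
    cfg = config or MCMCConfig.desk()
    covered = 0
    ratios = []
    for rep, s in enumerate(_seeds(seed, n_reps)):
        data = make_dataset(s, beta={"exposure": np.array([0.0, beta_true])})
        x = (data.design["exposure"] == 1).astype(float)
        design = pd.DataFrame({"exposure=cat2": x.to_numpy()}, index=list(data.cases["region_id"]))
        cfg_rep = MCMCConfig(
            n_chains=cfg.n_chains, burn_in=cfg.burn_in, iterations=cfg.iterations,
            thin=cfg.thin, seed=cfg.seed + rep, adapt_every=cfg.adapt_every,
        )
        chains = fit_bym(data.cases, data.neighbors, BYMModelSpec(design=design), cfg_rep)
        b = chains.pooled("exposure=cat2")
        lo, med, hi = np.percentile(b, [2.5, 50.0, 97.5])
        if lo <= beta_true <= hi:
            covered += 1
        ratios.append(np.exp(med))
    median_ratio = float(np.median(ratios))
    return {
        "n_reps": n_reps,
        "coverage_pct": 100.0 * covered / n_reps,
        "median_exp_beta": median_ratio,
        "exp_beta_rel_bias_pct": 100.0 * (median_ratio - np.exp(beta_true)) / np.exp(beta_true),
    }


def null_calibration_study(seed: int, config: MCMCConfig | None = None) -> dict:
    """Null data (no covariates, u = v = 0): smoothed-SIR CrIs should cover 1
    almost everywhere and the chains should pass the convergence criteria
    (R-hat < 1.1, MC error < 5% of posterior SD)."""
    cfg = config or MCMCConfig.desk(seed=seed)
    data = make_dataset(seed, null_effects=True)
    chains = fit_bym(data.cases, data.neighbors, None, cfg)
    summary = summarize_posterior(chains)
    contains_one = (summary["lower"] <= 1.0) & (summary["upper"] >= 1.0)
    diag = convergence_diagnostics(chains)
    dic = compute_dic(chains, data.cases)
    return {
        "n_regions": len(summary),
        "cri_covers_one_pct": 100.0 * float(contains_one.mean()),
        "max_rhat": float(diag["rhat"].max()),
        "max_mc_error_sd_pct": 100.0 * float(diag["mc_error_sd_ratio"].max()),
        "dic": dic.dic,
        "pd": dic.pd,
    }


def stepwise_study(
    n_reps: int,
    seed: int,
    beta_true: float = 0.7,
    config: MCMCConfig | None = None,
) -> dict:
    """Selection operating characteristics of the DIC-ordered stepwise.

    Each replicate has one truly predictive covariate (quintile-categorised
    continuous value whose top categories raise risk up to ``beta_true``)
    and one null covariate. Reports how often the true covariate is retained
    and the null one excluded.
    """
    cfg = config or MCMCConfig.desk(burn_in=2_000, iterations=8_000)
    kept_true = 0
    dropped_null = 0
    both = 0
    for rep, s in enumerate(_seeds(seed, n_reps)):
        s_cov, s_data = _seeds(s, 2)
        lattice = generate_lattice(DEFAULT_ROWS, DEFAULT_COLS)
        covs = generate_covariates(lattice, 2, spatial_corr=0.3, seed=s_cov)
        cat_true = quintile_categorise(covs["x1"], "predictive")
        cat_null = quintile_categorise(covs["x2"], "noise")
        # monotone dose-response over the predictive covariate's quintiles
        beta_steps = np.array([0.0, 0.25, 0.5, 0.75, 1.0]) * beta_true
        design = pd.DataFrame(
            {"predictive": cat_true.categories.to_numpy() - 1},
            index=list(lattice.region_ids),
        )
        s_pop, s_eff, s_cnt = _seeds(s_data, 3)
        population = generate_population(lattice, DEFAULT_POP_RANGE, s_pop)
        ns = lattice.queen_neighbors()
        u, v = simulate_spatial_effects(ns, 10.0, 10.0, s_eff)
        truth = SimulationTruth(tau_u=10.0, tau_v=10.0, u=u, v=v,
                                beta={"predictive": beta_steps})
        sim = simulate_counts(population, truth, design, s_cnt)
        cases = indirect_standardise(sim.stratum_cases, population)
        cfg_rep = MCMCConfig(
            n_chains=cfg.n_chains, burn_in=cfg.burn_in, iterations=cfg.iterations,
            thin=cfg.thin, seed=cfg.seed + 17 * rep, adapt_every=cfg.adapt_every,
        )
        screened = univariable_screen(cases, ns, [cat_true, cat_null], cfg_rep)
        ranked = [cat_true if f.name == "predictive" else cat_null for f in screened]
        result = stepwise_multivariable(cases, ns, ranked, cfg_rep)
        t = "predictive" in result.retained
        n = "noise" not in result.retained
        kept_true += t
        dropped_null += n
        both += t and n
    return {
        "n_reps": n_reps,
        "true_retained_pct": 100.0 * kept_true / n_reps,
        "null_excluded_pct": 100.0 * dropped_null / n_reps,
        "both_correct_pct": 100.0 * both / n_reps,
    }


def conservation_check(seed: int) -> dict:
    """Indirect-standardisation identity: regions partition the standard
    population, so the expected caseloads must sum to the state caseload."""
    data = make_dataset(seed, null_effects=True)
    total_expected = float(data.cases["expected"].sum())
    total_observed = float(data.cases["observed"].sum())
    return {
        "total_expected": total_expected,
        "total_observed": total_observed,
        "rel_err": abs(total_expected - total_observed) / total_observed,
    }
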