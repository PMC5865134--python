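"""Quintile categorisation and DIC-ordered stepwise spatial regression.

Continuous area covariates are cut into five categories at their 20/40/60/80
percentiles (externally categorised covariates, e.g. a six-class remoteness
index, are accepted as-is). Each covariate first enters a univariable BYM
fit; covariates are then added to a multivariable model in ascending order
of univariable DIC and retained when at least one of their category
coefficients has a 95% credible interval excluding zero on the log scale
(equivalently, a SIR ratio interval excluding 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjacency import NeighborStructure
from .car_model import BYMModelSpec, MCMCConfig, PosteriorChains, compute_dic, fit_bym


@dataclass
class QuintileCategorisation:
    """A covariate cut into ordered categories 1..n_categories.

    ``boundaries`` are the strictly increasing interior cut-points; a value
    below the first boundary falls in category 1 and a value equal to a
    boundary belongs to the upper category (the ">= cut-point" convention).
    """

    name: str
    boundaries: np.ndarray
    categories: pd.Series
    direction: str = ""

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if len(self.boundaries) and not (np.diff(self.boundaries) > 0).all():
            raise ValueError("boundaries must be strictly increasing")
        cats = self.categories.astype(int)
        if cats.min() < 1 or cats.max() > self.n_categories:
            raise ValueError("categories out of range")
        self.categories = cats

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + 1


def quintile_categorise(
    values: pd.Series, name: str, n_categories: int = 5, direction: str = ""
) -> QuintileCategorisation:
    """Cut per-region values at equally spaced percentiles.

    Boundaries sit at the 100*k/n_categories percentiles (linear
    interpolation); assignment is left-closed: value < boundary -> lower
    category, value >= boundary -> upper.
    """
    x = values.astype(float)
    if x.nunique() < n_categories:
        raise ValueError(
            f"{name}: need >= {n_categories} distinct values, got {x.nunique()}"
        )
    qs = [100.0 * k / n_categories for k in range(1, n_categories)]
    boundaries = np.percentile(x.to_numpy(), qs)
    cats = assign_categories(x, boundaries)
    return QuintileCategorisation(name, boundaries, cats, direction)


def assign_categories(values: pd.Series, boundaries: np.ndarray) -> pd.Series:
    """Category 1..len(boundaries)+1 per value; ties go to the upper category."""
    cats = np.searchsorted(np.asarray(boundaries, dtype=float),
                           values.to_numpy(dtype=float), side="right") + 1
    return pd.Series(cats, index=values.index, name="category")


def precategorised(
    name: str, categories: pd.Series, direction: str = ""
) -> QuintileCategorisation:
    """Wrap an externally defined categorisation (e.g. 6 remoteness classes)."""
    cats = categories.astype(int)
    n_cat = int(cats.max())
    if cats.min() < 1:
        raise ValueError("categories must start at 1")
    return QuintileCategorisation(name, np.arange(1, n_cat) + 0.5, cats, direction)


def design_matrix(
    categorisations: list[QuintileCategorisation], region_ids: list[str]
) -> pd.DataFrame:
    """Reference-cell dummy design: one column per non-reference category."""
    cols = {}
    for cat in categorisations:
        series = cat.categories.reindex(region_ids)
        if series.isna().any():
            missing = [r for r in region_ids if pd.isna(cat.categories.reindex([r]).iloc[0])]
            raise ValueError(f"{cat.name}: no category for regions {missing[:5]}")
        for k in range(2, cat.n_categories + 1):
            cols[f"{cat.name}=cat{k}"] = (series == k).astype(float).to_numpy()
    return pd.DataFrame(cols, index=region_ids)


@dataclass
class CovariateFit:
    """Per-category SIR ratios vs category 1 for one covariate in one model."""

    name: str
    table: pd.DataFrame  # category, ratio, lower, upper, significant
    dic: float
    error: str | None = None

    @property
    def any_significant(self) -> bool:
        return bool(self.table["significant"].any())


def _fit_table(chains: PosteriorChains, cat: QuintileCategorisation) -> pd.DataFrame:
    rows = [
        {"category": 1, "ratio": 1.0, "lower": np.nan, "upper": np.nan, "significant": False}
    ]
    for k in range(2, cat.n_categories + 1):
        col = f"{cat.name}=cat{k}"
        b = chains.pooled(col)
        lo, med, hi = np.percentile(b, [2.5, 50.0, 97.5])
        rows.append(
            {
                "category": k,
                "ratio": float(np.exp(med)),
                "lower": float(np.exp(lo)),
                "upper": float(np.exp(hi)),
                # CrI excludes zero on the log scale == ratio CrI excludes 1
                "significant": bool(lo > 0.0 or hi < 0.0),
            }
        )
    return pd.DataFrame(rows)


def fit_covariate_model(
    cases: pd.DataFrame,
    neighbors: NeighborStructure,
    categorisations: list[QuintileCategorisation],
    config: MCMCConfig,
    spec_kwargs: dict | None = None,
) -> tuple[list[CovariateFit], float, PosteriorChains]:
    """One BYM fit containing all given covariates; per-covariate tables + DIC."""
    ids = list(cases["region_id"])
    design = design_matrix(categorisations, ids)
    spec = BYMModelSpec(design=design, **(spec_kwargs or {}))
    chains = fit_bym(cases, neighbors, spec, config)
    dic = compute_dic(chains, cases).dic
    fits = [CovariateFit(c.name, _fit_table(chains, c), dic) for c in categorisations]
    return fits, dic, chains


def univariable_screen(
    cases: pd.DataFrame,
    neighbors: NeighborStructure,
    categorisations: list[QuintileCategorisation],
    config: MCMCConfig,
    spec_kwargs: dict | None = None,
) -> list[CovariateFit]:
    """One unadjusted BYM fit per covariate, ranked by ascending DIC.

    A covariate whose fit fails is reported with ``error`` set (sorted last)
    rather than aborting the whole screen.
    """
    results: list[CovariateFit] = []
    for k, cat in enumerate(categorisations):
        cfg_k = MCMCConfig(
            n_chains=config.n_chains, burn_in=config.burn_in,
            iterations=config.iterations, thin=config.thin,
            seed=config.seed + k, adapt_every=config.adapt_every,
        )
        try:
            fits, _, _ = fit_covariate_model(cases, neighbors, [cat], cfg_k, spec_kwargs)
            results.append(fits[0])
        except Exception as exc:  # propagate per-covariate, keep screening
            warnings.warn(f"univariable fit failed for {cat.name}: {exc}", stacklevel=2)
            results.append(
                CovariateFit(cat.name, pd.DataFrame(), float("inf"), error=str(exc))
            )
    return sorted(results, key=lambda f: f.dic)


@dataclass
class StepwiseResult:
    """Outcome of the forward DIC-ordered selection."""

    retained: list[str]
    fits: list[CovariateFit]
    dic: float
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    intercept_only: bool = False


def stepwise_multivariable(
    cases: pd.DataFrame,
    neighbors: NeighborStructure,
    ranked: list[QuintileCategorisation],
    config: MCMCConfig,
    spec_kwargs: dict | None = None,
) -> StepwiseResult:
    """Forward stepwise selection in the supplied (univariable-DIC) order.

    Each candidate joins the current model; it is retained when any of its
    category coefficients is significant (95% CrI excluding 0) in that joint
    fit, otherwise dropped and never revisited. Previously retained
    covariates stay in the model (forward-only). Categorical covariates
    enter and leave as whole blocks.
    """
    if not ranked:
        raise ValueError("ranked covariate list is empty")
    retained: list[QuintileCategorisation] = []
    trace_rows = []
    final_fits: list[CovariateFit] = []
    final_dic = float("nan")
    for step, cand in enumerate(ranked):
        cfg = MCMCConfig(
            n_chains=config.n_chains, burn_in=config.burn_in,
            iterations=config.iterations, thin=config.thin,
            seed=config.seed + 1000 + step, adapt_every=config.adapt_every,
        )
        fits, dic, _ = fit_covariate_model(
            cases, neighbors, retained + [cand], cfg, spec_kwargs
        )
        keep = fits[-1].any_significant
        trace_rows.append({"covariate": cand.name, "dic": dic, "retained": keep})
        if keep:
            retained.append(cand)
            final_fits = fits
            final_dic = dic
    if not retained:
        warnings.warn("no covariate retained: final model is intercept-only", stacklevel=2)
        return StepwiseResult(
            retained=[], fits=[], dic=float("nan"),
            trace=pd.DataFrame(trace_rows), intercept_only=True,
        )
    return StepwiseResult(
        retained=[c.name for c in retained],
        fits=final_fits,
        dic=final_dic,
        trace=pd.DataFrame(trace_rows),
    )


def select_seifa_representative(family: list[str], choice: str) -> str:
    """Pick the single index representing a correlated covariate family.

    Mirrors choosing one socioeconomic index (e.g. IRSD) out of the four
    SEIFA indices before multivariable modelling.
    """
    if choice not in family:
        raise ValueError(f"{choice!r} is not a member of the family {family}")
    return choice


def fits_to_table(fits: list[CovariateFit], dic: float | None = None) -> pd.DataFrame:
    """Long-format results table (covariate, category, SIR ratio, CrI, flag, DIC)."""
    frames = []
    for f in fits:
        t = f.table.copy()
        t.insert(0, "covariate", f.name)
        t["dic"] = f.dic if dic is None else dic
        frames.append(t)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
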