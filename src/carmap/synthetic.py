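"""Synthetic area-level data with known ground truth.

Emulates the inputs of an ecological study of EMS-attended diabetic
emergencies: a lattice of administrative regions (standing in for the 79
Victorian Local Government Areas), per-region populations stratified into 18
age-gender groups, spatially structured area covariates, and Poisson case
counts driven by a log-linear model with category effects plus spatially
structured (intrinsic CAR) and unstructured Gaussian random effects.

Every generator takes an explicit integer seed; there is no global random
state. Counts are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from .adjacency import NeighborStructure, queen_adjacency

AGE_BANDS: tuple[str, ...] = (
    "0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+",
)
SEXES: tuple[str, ...] = ("male", "female")

#: The 18 age-gender strata used for indirect standardisation, male bands first.
STRATA: tuple[str, ...] = tuple(f"{sex}_{band}" for sex in SEXES for band in AGE_BANDS)

# Adult-skewed age pyramid (share of the population per 10-year band).
_AGE_SHARE = np.array(
    [0.121, 0.121, 0.138, 0.145, 0.140, 0.126, 0.106, 0.064, 0.039]
)
_MALE_FRACTION = 0.49

#: Default stratum shares used to split a region total into the 18 strata.
DEFAULT_PYRAMID: pd.Series = pd.Series(
    np.concatenate([_AGE_SHARE * _MALE_FRACTION, _AGE_SHARE * (1.0 - _MALE_FRACTION)]),
    index=list(STRATA),
    name="share",
)

# Per-person case rates over the whole study window, rising steeply with age;
# males carry a higher rate, matching the observed male excess in caseload.
_AGE_RATE = np.array(
    [0.0010, 0.0030, 0.0050, 0.0050, 0.0060, 0.0080, 0.0105, 0.0140, 0.0200]
)

#: Default per-stratum baseline case rates (cases per person per study
#: window); the male/female multipliers put ~55% of cases in males.
DEFAULT_BASELINE_RATES: pd.Series = pd.Series(
    np.concatenate([_AGE_RATE * 1.14, _AGE_RATE * 0.88]),
    index=list(STRATA),
    name="rate",
)


@dataclass(frozen=True)
class RegionLattice:
    """A rectangular grid of unit-square regions in arbitrary planar units."""

    region_ids: tuple[str, ...]
    polygons: tuple[Polygon, ...]
    grid_row: np.ndarray
    grid_col: np.ndarray
    n_rows: int
    n_cols: int

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_geojson(self) -> dict:
        """FeatureCollection of the cell polygons with region_id properties."""
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "region_id": rid,
                    "grid_row": int(r),
                    "grid_col": int(c),
                },
            }
            for rid, poly, r, c in zip(
                self.region_ids, self.polygons, self.grid_row, self.grid_col
            )
        ]
        return {"type": "FeatureCollection", "features": feats}

    def queen_neighbors(self) -> NeighborStructure:
        return queen_adjacency(list(self.region_ids), list(self.polygons))


@dataclass
class SimulationTruth:
    """Ground-truth generative parameters behind a synthetic case table.

    ``beta`` maps covariate name -> per-category log risk (index 0 is the
    reference category and must be 0). ``u`` is the spatially structured
    effect (sums to zero within each connected component of the adjacency
    graph), ``v`` the unstructured effect.
    """

    tau_u: float
    tau_v: float
    u: np.ndarray
    v: np.ndarray
    baseline_rates: pd.Series = field(default_factory=lambda: DEFAULT_BASELINE_RATES.copy())
    beta: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("precisions tau_u and tau_v must be > 0")
        if (np.asarray(self.baseline_rates) < 0).any():
            raise ValueError("baseline rates must be non-negative")
        for name, b in self.beta.items():
            b = np.asarray(b, dtype=float)
            if b[0] != 0.0:
                raise ValueError(f"beta[{name!r}]: reference category must be 0")
            self.beta[name] = b


@dataclass
class SyntheticCounts:
    """Output of :func:`simulate_counts`.

    ``region_table`` has one row per region (observed, expected, erp);
    ``stratum_cases`` is the region x stratum case matrix and ``state_cases``
    its column sums — the state-wide stratum caseload a downstream analyst
    needs to re-derive standard rates.
    """

    region_table: pd.DataFrame
    stratum_cases: pd.DataFrame
    state_cases: pd.Series


def generate_lattice(n_rows: int, n_cols: int) -> RegionLattice:
    """Deterministic grid of unit squares; ``n_rows * n_cols`` regions (>= 4)."""
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    if n_rows * n_cols < 4:
        raise ValueError("lattice must contain at least 4 regions")
    ids, polys, rows, cols = [], [], [], []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            ids.append(f"R{k:03d}")
            polys.append(Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)]))
            rows.append(r)
            cols.append(c)
            k += 1
    return RegionLattice(
        region_ids=tuple(ids),
        polygons=tuple(polys),
        grid_row=np.array(rows),
        grid_col=np.array(cols),
        n_rows=n_rows,
        n_cols=n_cols,
    )


def generate_population(
    lattice: RegionLattice,
    total_range: tuple[int, int],
    seed: int,
    pyramid: pd.Series | None = None,
) -> pd.DataFrame:
    """Stratified population table (region x 18 strata of integer counts).

    Per-region totals are drawn uniformly in ``total_range`` (inclusive) and
    split across strata by a multinomial draw with fixed pyramid shares, so
    stratum counts sum exactly to the region total.
    """
    if lattice.n_regions == 0:
        raise ValueError("empty lattice")
    lo, hi = int(total_range[0]), int(total_range[1])
    if lo < 18:
        raise ValueError("total_range minimum must be >= 18 (one person per stratum)")
    if hi < lo:
        raise ValueError("total_range must be (min, max) with max >= min")
    if pyramid is None:
        pyramid = DEFAULT_PYRAMID
    p = np.asarray(pyramid.reindex(list(STRATA)), dtype=float)
    if np.isnan(p).any():
        raise ValueError("pyramid must cover all 18 strata")
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    totals = rng.integers(lo, hi + 1, size=lattice.n_regions)
    counts = np.vstack([rng.multinomial(t, p) for t in totals])
    return pd.DataFrame(counts, index=list(lattice.region_ids), columns=list(STRATA))


def generate_covariates(
    lattice: RegionLattice,
    n_covariates: int,
    spatial_corr: float,
    seed: int,
) -> pd.DataFrame:
    """Continuous area covariates, optionally smoothed over the Queen graph.

    For ``spatial_corr = rho > 0`` each covariate is a simultaneous-autoregressive
    field ``x = (I - rho * W_row)^{-1} z`` with iid standard-normal ``z`` and
    row-normalised Queen weights ``W_row``, then standardised; neighbouring
    regions are positively correlated for large ``rho``.
    """
    if n_covariates < 1:
        raise ValueError("n_covariates must be >= 1")
    if not (0.0 <= spatial_corr < 1.0):
        raise ValueError("spatial_corr must lie in [0, 1)")
    ns = lattice.queen_neighbors()
    n = ns.n
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, n_covariates))
    if spatial_corr > 0.0:
        w = np.zeros((n, n))
        for i, nbrs in enumerate(ns.neighbors):
            if len(nbrs):
                w[i, nbrs] = 1.0 / len(nbrs)
        x = np.linalg.solve(np.eye(n) - spatial_corr * w, z)
    else:
        x = z
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    cols = [f"x{j + 1}" for j in range(n_covariates)]
    return pd.DataFrame(x, index=list(lattice.region_ids), columns=cols)


def simulate_spatial_effects(
    neighbors: NeighborStructure,
    tau_u: float,
    tau_v: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (u, v): an intrinsic-CAR field and iid Gaussian noise.

    ``u`` is sampled exactly from the intrinsic CAR distribution with precision
    ``tau_u * (D - W)`` via the eigen-decomposition pseudo-inverse, then centred
    to zero mean within every connected component (the ICAR identifiability
    constraint). ``v`` is iid Normal(0, 1/tau_v).
    """
    if neighbors.n == 0:
        raise ValueError("neighbour structure has zero regions")
    if tau_u <= 0 or tau_v <= 0:
        raise ValueError("precisions must be > 0")
    neighbors.validate()
    n = neighbors.n
    rng = np.random.default_rng(seed)
    lap = neighbors.laplacian()
    w, vecs = np.linalg.eigh(lap)
    tol = 1e-10 * max(w.max(), 1.0)
    pos = w > tol
    z = rng.standard_normal(pos.sum())
    u = vecs[:, pos] @ (z / np.sqrt(tau_u * w[pos]))
    comp = neighbors.component_labels()
    for c in np.unique(comp):
        m = comp == c
        u[m] -= u[m].mean()
    v = rng.normal(0.0, 1.0 / np.sqrt(tau_v), size=n)
    return u, v


def simulate_counts(
    population: pd.DataFrame,
    truth: SimulationTruth,
    design: pd.DataFrame | None,
    seed: int,
) -> SyntheticCounts:
    """Poisson case counts at stratum level, aggregated both ways.

    The stratum-level intensity is ``pop[i, g] * rate[g] * r_i`` with region
    relative risk ``r_i = exp(sum_c beta[c][design[i, c]] + u_i + v_i)``.
    Expected counts use the baseline rates only: ``E_i = sum_g pop[i,g]*rate[g]``,
    so ``O_i / E_i`` is centred on ``r_i``.

    ``design`` holds one integer category column per named covariate
    (0-based, 0 = reference); pass ``None`` for a covariate-free simulation.
    """
    rates = truth.baseline_rates.reindex(population.columns)
    if rates.isna().any():
        raise ValueError("baseline rates do not cover all population strata")
    if (rates < 0).any():
        raise ValueError("baseline rates must be non-negative")
    n = len(population)
    if len(truth.u) != n or len(truth.v) != n:
        raise ValueError("u/v length does not match number of regions")
    log_r = truth.u + truth.v
    if design is not None and len(design.columns):
        design = design.reindex(population.index)
        if design.isna().any().any():
            raise ValueError("design does not cover all regions")
        for name in design.columns:
            if name not in truth.beta:
                raise ValueError(f"no beta coefficients for covariate {name!r}")
            cats = design[name].to_numpy(dtype=int)
            b = truth.beta[name]
            if cats.min() < 0 or cats.max() >= len(b):
                raise ValueError(f"design categories out of range for {name!r}")
            log_r = log_r + b[cats]
    rr = np.exp(log_r)
    pop = population.to_numpy(dtype=float)
    lam = pop * rates.to_numpy()[None, :] * rr[:, None]
    rng = np.random.default_rng(seed)
    cases = rng.poisson(lam)
    stratum_cases = pd.DataFrame(cases, index=population.index, columns=population.columns)
    expected = pop @ rates.to_numpy()
    region_table = pd.DataFrame(
        {
            "region_id": population.index,
            "observed": cases.sum(axis=1),
            "expected": expected,
            "erp": pop.sum(axis=1).astype(int),
        }
    ).reset_index(drop=True)
    state_cases = stratum_cases.sum(axis=0)
    state_cases.name = "cases"
    return SyntheticCounts(
        region_table=region_table,
        stratum_cases=stratum_cases,
        state_cases=state_cases,
    )


def case_records(
    stratum_cases: pd.DataFrame,
    seed: int,
    hypo_share: float = 0.699,
) -> pd.DataFrame:
    """Expand a region x stratum case matrix into per-case records.

    Each case gets its region, gender, an age drawn uniformly within its
    10-year band (80+ spans 80-99) and an emergency type drawn Bernoulli
    with probability ``hypo_share`` of hypoglycaemia. Used for case-mix
    summaries; the generative model itself is count-level.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, int, str]] = []
    for rid, counts in stratum_cases.iterrows():
        for stratum, k in counts.items():
            k = int(k)
            if k == 0:
                continue
            sex, band = stratum.split("_")
            lo = 80 if band == "80+" else int(band.split("-")[0])
            hi = 99 if band == "80+" else int(band.split("-")[1])
            ages = rng.integers(lo, hi + 1, size=k)
            types = np.where(
                rng.random(k) < hypo_share, "hypoglycaemia", "hyperglycaemia"
            )
            rows.extend((rid, sex, int(a), t) for a, t in zip(ages, types))
    return pd.DataFrame(rows, columns=["region_id", "gender", "age", "type"])
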