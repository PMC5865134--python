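"""Besag-York-Mollié (BYM) Poisson disease mapping fitted by MCMC.

Model, for region i with observed count O_i and expected count E_i:

    O_i ~ Poisson(mu_i)
    log mu_i = log(E_i) + alpha + x_i' beta + u_i + v_i

``u`` carries an intrinsic conditional-autoregressive (ICAR) prior over the
Queen-contiguity graph — each u_i, given the rest, is normal around the mean
of its neighbours with precision tau_u * n_i — constrained to sum to zero
within every connected component; ``v`` is exchangeable N(0, 1/tau_v) noise.
Precisions carry Gamma hyperpriors, the intercept and coefficients diffuse
normal priors. The smoothed standardised incidence ratio of region i is
mu_i / E_i.

The sampler is Metropolis-within-Gibbs (see :mod:`carmap._sampler`);
diagnostics are the Gelman-Rubin statistic with its Brooks-Gelman-Rubin
trajectory, batch-means Monte Carlo error, and the deviance information
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._sampler import run_chain
from .adjacency import NeighborStructure


@dataclass
class BYMModelSpec:
    """Priors and (optional) covariate design for a BYM fit.

    ``design`` holds reference-cell dummy columns (category 1 of every
    covariate omitted); ``None`` fits the intercept + random-effects model.
    Default hyperpriors are Gamma(0.5, 0.0005) on both precisions and
    Normal(0, precision 1e-6) on the intercept and coefficients — the
    conventional "uninformative" choices for this model family.
    """

    design: pd.DataFrame | None = None
    prior_tau_u: tuple[float, float] = (0.5, 0.0005)
    prior_tau_v: tuple[float, float] = (0.5, 0.0005)
    prior_beta_precision: float = 1e-6
    prior_intercept_precision: float = 1e-6

    def __post_init__(self) -> None:
        for name, (a, b) in (("tau_u", self.prior_tau_u), ("tau_v", self.prior_tau_v)):
            if a <= 0 or b <= 0:
                raise ValueError(f"Gamma hyperparameters for {name} must be > 0")
        if self.prior_beta_precision <= 0 or self.prior_intercept_precision <= 0:
            raise ValueError("prior precisions must be > 0")
        if self.design is not None and len(self.design.columns):
            x = self.design.to_numpy(dtype=float)
            if np.linalg.matrix_rank(x) < x.shape[1]:
                raise ValueError("design columns are linearly dependent")

    @property
    def has_covariates(self) -> bool:
        return self.design is not None and len(self.design.columns) > 0


@dataclass
class MCMCConfig:
    """Chain settings. Defaults mirror a long production run (2 chains,
    100k burn-in, 500k iterations, keep every other draw); use
    :meth:`desk` for the scaled-down settings used throughout the test
    simulations."""

    n_chains: int = 2
    burn_in: int = 100_000
    iterations: int = 500_000
    thin: int = 2
    seed: int = 0
    adapt_every: int = 100

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in < 0 or self.iterations < self.thin:
            raise ValueError("bad chain lengths")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "MCMCConfig":
        kw.setdefault("burn_in", 5_000)
        kw.setdefault("iterations", 20_000)
        return cls(seed=seed, **kw)


@dataclass
class PosteriorChains:
    """Post burn-in, thinned MCMC draws across chains.

    Arrays are indexed (chain, draw) or (chain, draw, region/column).
    ``mu`` is the derived fitted mean E_i * exp(eta_i).
    """

    region_ids: list[str]
    beta_names: list[str]
    expected: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: np.ndarray
    tau_v: np.ndarray
    mu: np.ndarray
    component_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of a scalar parameter pooled across chains."""
        arr = self.scalar_draws(name)
        return arr.reshape(-1)

    def scalar_draws(self, name: str) -> np.ndarray:
        """(chain, draw) array for 'intercept', 'tau_u', 'tau_v' or a beta name."""
        if name == "intercept":
            return self.alpha
        if name == "tau_u":
            return self.tau_u
        if name == "tau_v":
            return self.tau_v
        if name in self.beta_names:
            return self.beta[:, :, self.beta_names.index(name)]
        raise KeyError(name)

    def monitored(self) -> list[str]:
        return ["intercept", *self.beta_names, "tau_u", "tau_v"]


def fit_bym(
    cases: pd.DataFrame,
    neighbors: NeighborStructure,
    spec: BYMModelSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorChains:
    """Fit the BYM model by MCMC; reproducible for a fixed config seed.

    ``cases`` needs columns region_id, observed, expected with E_i > 0 for
    every region; region order must match ``neighbors.region_ids``.
    """
    spec = spec or BYMModelSpec()
    config = config or MCMCConfig()
    ids = list(cases["region_id"])
    if ids != list(neighbors.region_ids):
        raise ValueError("case table and neighbour structure list different regions")
    neighbors.validate()
    O = cases["observed"].to_numpy(dtype=float)
    E = cases["expected"].to_numpy(dtype=float)
    if (O < 0).any() or not np.allclose(O, np.round(O)):
        raise ValueError("observed counts must be non-negative integers")
    if (E <= 0).any():
        raise ValueError(
            "expected counts must be > 0 for all modelled regions "
            "(drop undefined-SIR regions before fitting)"
        )
    n = len(ids)
    if spec.has_covariates:
        design = spec.design.reindex(ids)
        if design.isna().any().any():
            raise ValueError("design does not cover all regions")
        X = np.ascontiguousarray(design.to_numpy(dtype=float))
        beta_names = list(design.columns)
    else:
        X = np.zeros((n, 0))
        beta_names = []
    p = X.shape[1]
    col_indptr = np.zeros(p + 1, dtype=np.int64)
    col_rows_list = []
    for j in range(p):
        rows = np.nonzero(X[:, j] != 0.0)[0]
        col_rows_list.append(rows)
        col_indptr[j + 1] = col_indptr[j] + len(rows)
    col_rows = (
        np.concatenate(col_rows_list).astype(np.int64)
        if p and col_indptr[-1]
        else np.zeros(0, dtype=np.int64)
    )

    adj_indptr, adj_indices = neighbors.to_csr()
    comp = neighbors.component_labels()
    n_comp = int(comp.max()) + 1
    icar_rank = n - n_comp
    island = neighbors.degrees() == 0

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.n_chains)]

    logE = np.log(E)
    per_chain = []
    for cs in chain_seeds:
        draws = run_chain(
            O, logE, X, col_indptr, col_rows,
            adj_indptr, adj_indices, comp.astype(np.int64), n_comp, float(icar_rank),
            island,
            float(spec.prior_tau_u[0]), float(spec.prior_tau_u[1]),
            float(spec.prior_tau_v[0]), float(spec.prior_tau_v[1]),
            float(spec.prior_beta_precision), float(spec.prior_intercept_precision),
            int(config.burn_in), int(config.iterations), int(config.thin),
            cs, int(config.adapt_every),
        )
        per_chain.append(draws)

    alpha = np.stack([d[0] for d in per_chain])
    beta = np.stack([d[1] for d in per_chain])
    u = np.stack([d[2] for d in per_chain])
    v = np.stack([d[3] for d in per_chain])
    tau_u = np.stack([d[4] for d in per_chain])
    tau_v = np.stack([d[5] for d in per_chain])
    eta = alpha[:, :, None] + (beta @ X.T if p else 0.0) + u + v
    mu = E[None, None, :] * np.exp(eta)
    for name, arr in (("alpha", alpha), ("beta", beta), ("u", u), ("v", v),
                      ("tau_u", tau_u), ("tau_v", tau_v), ("mu", mu)):
        if not np.isfinite(arr).all():
            raise RuntimeError(
                f"non-finite posterior draws in {name}; state summary: "
                f"min={np.nanmin(arr)}, max={np.nanmax(arr)}, "
                f"seed={config.seed}, n={n}, p={p}"
            )
    return PosteriorChains(
        region_ids=ids,
        beta_names=beta_names,
        expected=E,
        alpha=alpha, beta=beta, u=u, v=v, tau_u=tau_u, tau_v=tau_v, mu=mu,
        component_labels=comp,
    )


def icar_full_conditional(
    u: np.ndarray, i: int, neighbors: NeighborStructure, tau_u: float
) -> tuple[float, float]:
    """Mean and variance of u_i given the rest under the ICAR prior.

    mean = average of the neighbours' values, variance = 1 / (tau_u * n_i).
    Islands (degree 0) have no ICAR conditional and must be handled by the
    caller (their u is pinned at zero in the sampler).
    """
    nbrs = neighbors.neighbors[i]
    if len(nbrs) == 0:
        raise ValueError(f"region {neighbors.region_ids[i]} is an island: no ICAR conditional")
    if tau_u <= 0:
        raise ValueError("tau_u must be > 0")
    return float(np.mean(u[nbrs])), 1.0 / (tau_u * len(nbrs))


def poisson_log_likelihood(O: np.ndarray, mu: np.ndarray) -> float:
    """Total Poisson log-likelihood sum_i [O_i log mu_i - mu_i - log O_i!]."""
    O = np.asarray(O, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if (mu <= 0).any():
        raise ValueError("mu must be positive")
    return float(np.sum(O * np.log(mu) - mu - gammaln(O + 1.0)))


def summarize_posterior(
    chains: PosteriorChains, expected: np.ndarray | None = None
) -> pd.DataFrame:
    """Smoothed SIR per region: posterior median and equal-tailed 95% CrI.

    SIR draws are mu_i / E_i; ``elevated`` is True when the CrI lower bound
    strictly exceeds 1.
    """
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    E = chains.expected if expected is None else np.asarray(expected, dtype=float)
    sir = chains.mu.reshape(-1, chains.mu.shape[-1]) / E[None, :]
    med = np.percentile(sir, 50, axis=0)
    lo = np.percentile(sir, 2.5, axis=0)
    hi = np.percentile(sir, 97.5, axis=0)
    return pd.DataFrame(
        {
            "region_id": chains.region_ids,
            "sir": med,
            "lower": lo,
            "upper": hi,
            "elevated": lo > 1.0,
        }
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``chains`` is (n_chains, n_draws). R-hat = sqrt(((n-1)/n W + B/n) / W)
    with W the mean within-chain variance and B the between-chain variance
    of the chain means scaled by n.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    c, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for R-hat")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0
    v_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(v_hat / w))


def bgr_trajectory(chains: np.ndarray, n_points: int = 20) -> pd.DataFrame:
    """Brooks-Gelman-Rubin diagnostic: R-hat on growing chain prefixes."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    n = chains.shape[1]
    lengths = np.unique(np.linspace(max(10, n // n_points), n, n_points).astype(int))
    rows = [(int(m), gelman_rubin(chains[:, :m])) for m in lengths if m >= 10]
    return pd.DataFrame(rows, columns=["n_draws", "rhat"])


def mc_error(draws: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means Monte Carlo standard error of the posterior mean.

    Splits the (pooled) draws into ``n_batches`` equal batches (trailing
    remainder dropped) and returns SD(batch means) / sqrt(n_batches).
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size < 100:
        raise ValueError("need >= 100 draws for a batch-means error estimate")
    m = draws.size // n_batches
    batches = draws[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def convergence_diagnostics(chains: PosteriorChains) -> pd.DataFrame:
    """Per-monitored-parameter R-hat, MC error and MC-error/SD ratio."""
    rows = []
    for name in chains.monitored():
        arr = chains.scalar_draws(name)
        pooled = arr.reshape(-1)
        sd = pooled.std(ddof=1)
        mce = mc_error(pooled)
        rows.append(
            {
                "parameter": name,
                "rhat": gelman_rubin(arr),
                "mc_error": mce,
                "sd": sd,
                "mc_error_sd_ratio": mce / sd if sd > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def parameter_summary(chains: PosteriorChains) -> pd.DataFrame:
    """Posterior mean/SD/median/95% CrI/MC error for monitored parameters."""
    rows = []
    for name in chains.monitored():
        x = chains.pooled(name)
        rows.append(
            {
                "parameter": name,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "median": np.percentile(x, 50),
                "lower": np.percentile(x, 2.5),
                "upper": np.percentile(x, 97.5),
                "mc_error": mc_error(x),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion decomposition.

    dbar: posterior mean deviance; d_hat: deviance at the posterior mean of
    mu; pd = dbar - d_hat (effective parameters); dic = dbar + pd.
    """

    dbar: float
    d_hat: float
    pd: float
    dic: float


def compute_dic(chains: PosteriorChains, cases: pd.DataFrame) -> DICResult:
    """DIC from stored mu draws against the observed counts."""
    O = cases["observed"].to_numpy(dtype=float)
    mu = chains.mu.reshape(-1, chains.mu.shape[-1])
    if (mu <= 0).any():
        raise ValueError("non-positive fitted mean in posterior draws")
    const = gammaln(O + 1.0).sum()
    dev = -2.0 * ((O[None, :] * np.log(mu) - mu).sum(axis=1) - const)
    dbar = float(dev.mean())
    mu_bar = mu.mean(axis=0)
    d_hat = float(-2.0 * ((O * np.log(mu_bar) - mu_bar).sum() - const))
    pd_ = dbar - d_hat
    return DICResult(dbar=dbar, d_hat=d_hat, pd=pd_, dic=dbar + pd_)
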