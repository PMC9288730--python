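"""Synthetic clustered household expenditure surveys with known elasticities.

Emulates the structure of Indian consumer-expenditure microdata (NSS-style):
households nested in clusters (villages / urban blocks), each cluster facing a
single market price per beverage, households reporting 30-day quantities and
expenditures for aerated/sugar-sweetened beverages (ASB), fruit juice, milk
and tea.  The generator samples directly from the two-equation demand system

    ln v_hc = a1 + b1 ln x_hc + g1' z_hc + sum_H psi[G,H] ln pi_Hc + u1_hc
    w_hc    = a0 + b0 ln x_hc + g0' z_hc + sum_H theta[G,H] ln pi_Hc + f_c + u0_hc

where ``v`` is the unit value (expenditure / quantity), ``w`` the budget
share, ``x`` total household expenditure, ``pi_Hc`` the cluster-level price
of good H, ``f_c`` a cluster effect and ``u0, u1`` household noise that also
stands in for measurement error.  Purchase incidence is an independent
Bernoulli gate with income-tertile-specific probabilities, reproducing the
strong prevalence gradient (about 1% of low-income to 10% of high-income
households buying ASBs) seen in the real surveys.

Because the survey is drawn from the very model the two-stage estimator
assumes, any failure to recover the configured elasticities is attributable
to the estimator, not to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SeriesConfig",
    "InvalidConfigError",
    "DegenerateShareError",
    "config_from_elasticities",
    "default_config",
    "generate_cluster_prices",
    "generate_households",
    "true_elasticities",
    "generate_price_gdp_series",
    "flat_cpi_table",
    "TERTILES",
]

TERTILES = ("low", "middle", "high")

#: share of clipped share draws above which the truth object carries a warning
CLIP_WARN_FRACTION = 0.05


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


class DegenerateShareError(ValueError):
    """Raised when a mean budget share is zero (elasticities undefined)."""


def _asarray(x, n, name) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.shape != (n,):
        raise InvalidConfigError(f"{name} must have shape ({n},), got {a.shape}")
    return a


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the survey data-generating process.

    Matrices are ordered like ``goods``: ``psi[G, H]`` (resp. ``theta[G, H]``)
    is the response of good G's log unit value (resp. budget share) to good
    H's log cluster price.  ``gamma0``/``gamma1`` are goods x covariates
    coefficient matrices on (log household size, number of children, mean
    education years).
    """

    goods: tuple[str, ...]
    n_clusters: int
    households_per_cluster: int | tuple[int, int]
    mean_log_price: np.ndarray          # per good, level of ln pi
    price_sd_between: np.ndarray        # per good, between-cluster SD of ln pi
    psi: np.ndarray                     # G x G unit-value / price response
    theta: np.ndarray                   # G x G share / price response
    beta0: np.ndarray                   # per good, share eq. ln x coefficient
    beta1: np.ndarray                   # per good, unit-value eq. ln x coefficient
    gamma0: np.ndarray                  # G x K covariate coefficients, share eq.
    gamma1: np.ndarray                  # G x K covariate coefficients, unit-value eq.
    mean_share: np.ndarray              # per good, population mean budget share
    mean_log_unit_value: np.ndarray     # per good, population mean ln v
    sigma_u0: np.ndarray                # per good, within-cluster share noise SD
    sigma_u1: np.ndarray                # per good, within-cluster unit-value noise SD
    sigma_f: float                      # SD of the cluster effect in the share eq.
    prevalence_by_tertile: np.ndarray   # G x 3 purchase probabilities (low, middle, high)
    log_expenditure_mean_sd: tuple[float, float] = (9.3, 0.6)
    theta_by_tertile: Mapping[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self):
        g = len(self.goods)
        if g == 0:
            raise InvalidConfigError("goods list must be non-empty")
        if self.n_clusters <= 0:
            raise InvalidConfigError("n_clusters must be positive")
        for name in ("mean_log_price", "price_sd_between", "beta0", "beta1",
                     "mean_share", "mean_log_unit_value", "sigma_u0", "sigma_u1"):
            object.__setattr__(self, name, _asarray(getattr(self, name), g, name))
        for name in ("psi", "theta"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (g, g):
                raise InvalidConfigError(f"{name} must be {g}x{g}, got {a.shape}")
            object.__setattr__(self, name, a)
        for name in ("gamma0", "gamma1"):
            a = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if a.shape[0] != g:
                raise InvalidConfigError(f"{name} must have {g} rows")
            object.__setattr__(self, name, a)
        prev = np.asarray(self.prevalence_by_tertile, dtype=float)
        if prev.shape != (g, 3):
            raise InvalidConfigError(f"prevalence_by_tertile must be {g}x3")
        object.__setattr__(self, "prevalence_by_tertile", prev)
        if np.any(self.price_sd_between < 0) or np.any(self.sigma_u0 < 0) \
                or np.any(self.sigma_u1 < 0) or self.sigma_f < 0:
            raise InvalidConfigError("all noise SDs must be >= 0")
        if np.any(self.mean_share <= 0) or np.any(self.mean_share >= 1) \
                or self.mean_share.sum() >= 1:
            raise InvalidConfigError("mean shares must lie in (0,1) and sum below 1")
        if np.any(prev < 0) or np.any(prev > 1):
            raise InvalidConfigError("prevalence values must lie in [0,1]")
        if self.theta_by_tertile is not None:
            for t in TERTILES:
                if t not in self.theta_by_tertile:
                    raise InvalidConfigError(f"theta_by_tertile missing tertile {t!r}")
                a = np.asarray(self.theta_by_tertile[t], dtype=float)
                if a.shape != (g, g):
                    raise InvalidConfigError("theta_by_tertile matrices must be GxG")
            object.__setattr__(
                self, "theta_by_tertile",
                {t: np.asarray(self.theta_by_tertile[t], dtype=float) for t in TERTILES},
            )

    @property
    def n_goods(self) -> int:
        return len(self.goods)

    def with_(self, **kw) -> "SyntheticConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth implied by a :class:`SyntheticConfig`.

    ``true_price_elasticity`` is oriented like the estimator's output: entry
    (i, j) is the elasticity of good-i quantity with respect to good-j price.
    """

    cluster_log_prices: pd.DataFrame
    true_price_elasticity: pd.DataFrame
    true_expenditure_elasticity: pd.Series
    true_quality_elasticity: pd.Series
    config_echo: SyntheticConfig
    group_price_elasticity: dict[str, pd.DataFrame] | None = None
    group_mean_share: dict[str, np.ndarray] | None = None
    clip_fraction: float = 0.0
    clip_warning: bool = False


# ---------------------------------------------------------------------------
# elasticity algebra (kept self-contained: this is the generator's own oracle,
# independent of the estimation code path)
# ---------------------------------------------------------------------------

def _expenditure_quality(beta0, beta1, mean_share):
    """Expenditure elasticity eps_x = 1 + b0/w - b1 and quality elasticity
    zeta = b1/eps_x implied by the two equations."""
    if np.any(mean_share == 0):
        raise DegenerateShareError("zero mean budget share")
    eps_x = 1.0 + beta0 / mean_share - beta1
    zeta = beta1 / eps_x
    return eps_x, zeta


def _price_elasticity(theta, psi, mean_share, zeta) -> np.ndarray:
    """Solve the quality-shading system for the price-elasticity matrix E.

    With B = theta @ inv(psi) (share response to log unit values purged of
    measurement error), the system  theta = diag(w)(I + E),
    psi = I + diag(zeta) E  gives
        E = (I - diag(w)^-1 B diag(zeta))^-1 (diag(w)^-1 B - I).
    When zeta = 0 this is exactly diag(w)^-1 B - I.
    """
    g = len(mean_share)
    if np.any(mean_share == 0):
        raise DegenerateShareError("zero mean budget share")
    b = theta @ np.linalg.inv(psi)
    winv_b = b / mean_share[:, None]
    eye = np.eye(g)
    return np.linalg.solve(eye - winv_b * zeta[None, :], winv_b - eye)


def true_elasticities(config: SyntheticConfig) -> np.ndarray:
    """Price-elasticity matrix implied by (theta, psi, mean shares, betas).

    This is the closed form the estimator should converge to on noiseless,
    infinite data generated from ``config``.
    """
    _, zeta = _expenditure_quality(config.beta0, config.beta1, config.mean_share)
    return _price_elasticity(config.theta, config.psi, config.mean_share, zeta)


def config_from_elasticities(
    elasticity: np.ndarray,
    mean_share: Sequence[float],
    beta0: Sequence[float],
    beta1: Sequence[float],
    goods: Sequence[str] = ("ASB", "juice", "milk", "tea"),
    **kw,
) -> SyntheticConfig:
    """Build a quality-consistent config whose true elasticity matrix is given.

    Derives theta = diag(w)(I + E) and psi = I + diag(zeta) E with zeta
    implied by the expenditure coefficients, so the unit-value and share
    equations describe the same underlying demand (unit values genuinely vary
    less than prices when quality shading is on, i.e. beta1 > 0).  Remaining
    DGP settings are taken from ``default_config`` unless overridden via
    keyword arguments.
    """
    goods = tuple(goods)
    g = len(goods)
    e = np.asarray(elasticity, dtype=float).reshape(g, g)
    w = _asarray(mean_share, g, "mean_share")
    b0 = _asarray(beta0, g, "beta0")
    b1 = _asarray(beta1, g, "beta1")
    _, zeta = _expenditure_quality(b0, b1, w)
    theta = w[:, None] * (np.eye(g) + e)
    psi = np.eye(g) + zeta[:, None] * e
    base = _default_kwargs(goods)
    base.update(kw)
    return SyntheticConfig(goods=goods, mean_share=w, beta0=b0, beta1=b1,
                           theta=theta, psi=psi, **base)


def config_with_group_elasticities(
    elasticity_by_tertile: Mapping[str, np.ndarray],
    mean_share: Sequence[float],
    goods: Sequence[str] = ("ASB", "juice", "milk", "tea"),
    **kw,
) -> SyntheticConfig:
    """Config whose true price-elasticity matrix differs by income tertile.

    Sets theta_by_tertile = diag(w)(I + E_t) with no expenditure effects
    (beta0 = beta1 = 0, hence no quality shading, psi = I) and log prices
    centred at zero, so each tertile's population mean share equals the
    configured ``mean_share`` and its true elasticity matrix is exactly the
    one supplied.  Used by the group-recovery test harness.
    """
    goods = tuple(goods)
    g = len(goods)
    w = _asarray(mean_share, g, "mean_share")
    thetas = {}
    theta_sum = np.zeros((g, g))
    for t in TERTILES:
        e_t = np.asarray(elasticity_by_tertile[t], dtype=float).reshape(g, g)
        thetas[t] = w[:, None] * (np.eye(g) + e_t)
        theta_sum += thetas[t]
    base = _default_kwargs(goods)
    base.update(kw)
    base["mean_log_price"] = np.zeros(g)
    return SyntheticConfig(goods=goods, mean_share=w,
                           beta0=np.zeros(g), beta1=np.zeros(g),
                           theta=theta_sum / 3.0, psi=np.eye(g),
                           theta_by_tertile=thetas, **base)


def _default_kwargs(goods: tuple[str, ...]) -> dict:
    g = len(goods)
    # Levels anchored on the pooled-survey magnitudes: unit values ~45 INR/L
    # for ASBs, ~69 for juice, ~27 for milk, ~4.4 per cup of tea; monthly
    # total expenditure ~11,000 INR.  Between-cluster log-price SD 0.20 with
    # within-cluster unit-value noise 0.134 puts ~69% of unit-value variance
    # between clusters, the share observed in the real data.
    uv = {"ASB": 45.3, "juice": 69.4, "milk": 27.0, "tea": 4.4}
    prev = {
        "ASB": (0.01, 0.03, 0.10),
        "juice": (0.008, 0.02, 0.075),
        "milk": (0.65, 0.87, 0.94),
        "tea": (0.35, 0.43, 0.49),
    }
    return dict(
        n_clusters=2000,
        households_per_cluster=8,
        mean_log_price=np.array([np.log(uv.get(x, 20.0)) for x in goods]),
        price_sd_between=np.full(g, 0.20),
        gamma0=np.tile(np.array([0.002, -0.0005, 0.0001]), (g, 1)),
        gamma1=np.tile(np.array([0.05, -0.01, 0.005]), (g, 1)),
        mean_log_unit_value=np.array([np.log(uv.get(x, 20.0)) for x in goods]),
        sigma_u0=np.full(g, 0.005),
        sigma_u1=np.full(g, 0.134),
        sigma_f=0.002,
        prevalence_by_tertile=np.array([prev.get(x, (0.5, 0.5, 0.5)) for x in goods]),
        log_expenditure_mean_sd=(9.3, 0.6),
        seed=0,
    )


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-condition defaults: four beverages, pooled-survey elasticity
    matrix, budget shares and prevalence gradient of the Indian consumer
    expenditure rounds."""
    e = np.array([
        [-0.944, 0.206, -1.807, 0.271],   # ASB row: own -0.94, milk complement
        [1.533, -0.550, -0.130, -0.164],
        [-0.339, -0.001, -0.389, 0.208],
        [0.541, -0.041, 2.250, -0.989],
    ])
    cfg = config_from_elasticities(
        e,
        mean_share=[0.017, 0.019, 0.090, 0.028],
        beta0=[-0.004, -0.004, -0.005, -0.006],
        beta1=[0.05, 0.05, 0.04, 0.05],
        seed=seed,
    )
    return cfg


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def generate_cluster_prices(config: SyntheticConfig,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the clusters x goods matrix of log prices ln pi_Gc.

    One value per cluster-good: every household in a cluster faces the same
    price, the identifying assumption of the between-cluster estimator.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    return (config.mean_log_price[None, :]
            + rng.standard_normal((config.n_clusters, config.n_goods))
            * config.price_sd_between[None, :])


def _cluster_sizes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    hpc = config.households_per_cluster
    if isinstance(hpc, int):
        if hpc <= 0:
            raise InvalidConfigError("households_per_cluster must be positive")
        return np.full(config.n_clusters, hpc, dtype=int)
    lo, hi = hpc
    if lo <= 0 or hi < lo:
        raise InvalidConfigError("invalid households_per_cluster range")
    return rng.integers(lo, hi + 1, size=config.n_clusters)


def _poisson_log1p_mean(lam: float, tol: float = 1e-12) -> float:
    """E[ln(1 + K)] for K ~ Poisson(lam), by series summation."""
    k = np.arange(0, int(lam + 12 * np.sqrt(lam) + 30))
    p = stats.poisson.pmf(k, lam)
    return float(np.sum(p * np.log1p(k)))


_HH_SIZE_LAMBDA = 3.0      # household size = 1 + Poisson(3)  (mean ~4 members)
_CHILDREN_LAMBDA = 1.0
_EDU_MEAN, _EDU_SD = 7.0, 3.0

_CATEGORIES = {
    "head_gender": (("male", "female"), (0.85, 0.15)),
    "social_group": (("SC", "ST", "OBC", "other"), (0.18, 0.09, 0.42, 0.31)),
    "religion": (("hindu", "muslim", "christian", "other"), (0.80, 0.13, 0.03, 0.04)),
    "household_type": (("self_employed", "regular_wage", "casual_labour", "other"),
                       (0.38, 0.22, 0.28, 0.12)),
}


def _covariate_means() -> np.ndarray:
    return np.array([_poisson_log1p_mean(_HH_SIZE_LAMBDA), _CHILDREN_LAMBDA, _EDU_MEAN])


def _tertile_mean_logx(config: SyntheticConfig) -> np.ndarray:
    """Population mean of ln x within each expenditure tercile of a normal."""
    m, s = config.log_expenditure_mean_sd
    q = stats.norm.ppf([1 / 3, 2 / 3])
    d_low = -stats.norm.pdf(q[0]) / (1 / 3)
    d_high = stats.norm.pdf(q[1]) / (1 / 3)
    return m + s * np.array([d_low, 0.0, d_high])


def _group_truth(config: SyntheticConfig):
    """Per-tertile mean shares and elasticity matrices (analytic)."""
    thetas = config.theta_by_tertile
    if thetas is None:
        return None, None
    theta_bar = sum(np.asarray(thetas[t]) for t in TERTILES) / 3.0
    mean_lx = _tertile_mean_logx(config)
    m = config.log_expenditure_mean_sd[0]
    shares, elas = {}, {}
    for t, lx in zip(TERTILES, mean_lx):
        w_t = (config.mean_share + config.beta0 * (lx - m)
               + (np.asarray(thetas[t]) - theta_bar) @ config.mean_log_price)
        _, zeta_t = _expenditure_quality(config.beta0, config.beta1, w_t)
        e_t = _price_elasticity(np.asarray(thetas[t]), config.psi, w_t, zeta_t)
        shares[t] = w_t
        elas[t] = pd.DataFrame(e_t, index=list(config.goods), columns=list(config.goods))
    return shares, elas


def generate_households(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Sample a full survey table and its ground truth.

    Returns one row per household in the wide survey schema used throughout
    the package (``quantity_<good>`` / ``expenditure_<good>`` columns, 30-day
    reference period).  Expenditure and quantity are back-computed from the
    drawn share and unit value, so expenditure = quantity x unit value and
    share = expenditure / total expenditure hold exactly.
    """
    goods = config.goods
    g = config.n_goods
    ss = np.random.SeedSequence(config.seed).spawn(3)
    price_rng = np.random.default_rng(ss[0])
    hh_rng = np.random.default_rng(ss[1])
    cat_rng = np.random.default_rng(ss[2])

    log_prices = generate_cluster_prices(config, price_rng)
    sizes = _cluster_sizes(config, hh_rng)
    n = int(sizes.sum())
    cluster_idx = np.repeat(np.arange(config.n_clusters), sizes)

    m, s = config.log_expenditure_mean_sd
    lnx = m + s * hh_rng.standard_normal(n)
    thr = m + s * stats.norm.ppf([1 / 3, 2 / 3])
    tert_idx = np.digitize(lnx, thr)          # 0 low, 1 middle, 2 high

    hh_size = 1 + hh_rng.poisson(_HH_SIZE_LAMBDA, size=n)
    n_children = hh_rng.poisson(_CHILDREN_LAMBDA, size=n)
    education = _EDU_MEAN + _EDU_SD * hh_rng.standard_normal(n)
    z = np.column_stack([np.log(hh_size), n_children.astype(float), education])

    f_c = config.sigma_f * hh_rng.standard_normal((config.n_clusters, g))
    u0 = hh_rng.standard_normal((n, g)) * config.sigma_u0[None, :]
    u1 = hh_rng.standard_normal((n, g)) * config.sigma_u1[None, :]

    ez = _covariate_means()
    mu_pi = config.mean_log_price
    alpha1 = (config.mean_log_unit_value - config.beta1 * m
              - config.gamma1 @ ez - config.psi @ mu_pi)
    if config.theta_by_tertile is None:
        theta_bar = config.theta
        theta_by_t = [config.theta] * 3
    else:
        theta_by_t = [np.asarray(config.theta_by_tertile[t]) for t in TERTILES]
        theta_bar = sum(theta_by_t) / 3.0
    alpha0 = (config.mean_share - config.beta0 * m
              - config.gamma0 @ ez - theta_bar @ mu_pi)

    lp_h = log_prices[cluster_idx]            # n x g cluster prices per household
    lnv = (alpha1[None, :] + np.outer(lnx, config.beta1) + z @ config.gamma1.T
           + lp_h @ config.psi.T + u1)
    price_term = np.empty((n, g))
    for t in range(3):
        mask = tert_idx == t
        price_term[mask] = lp_h[mask] @ theta_by_t[t].T
    w = (alpha0[None, :] + np.outer(lnx, config.beta0) + z @ config.gamma0.T
         + price_term + f_c[cluster_idx] + u0)

    prev = config.prevalence_by_tertile[:, tert_idx].T     # n x g
    buys = hh_rng.random((n, g)) < prev

    eps = 1e-9
    clipped = buys & ((w <= 0) | (w >= 1))
    w_clipped = np.clip(w, eps, 1 - eps)
    clip_fraction = float(clipped.sum() / max(buys.sum(), 1))

    x = np.exp(lnx)
    expenditure = np.where(buys, w_clipped * x[:, None], 0.0)
    unit_value = np.exp(lnv)
    quantity = np.where(buys, expenditure / unit_value, 0.0)

    df = pd.DataFrame({
        "household_id": np.arange(n),
        "cluster_id": cluster_idx,
        "round_label": np.where(cluster_idx < config.n_clusters // 2, "66", "68"),
        "subround": (cluster_idx % 4) + 1,
        "sector": np.where(cluster_idx % 2 == 0, "rural", "urban"),
        "weight": 1.0,
        "total_expenditure": x,
        "household_size": hh_size,
        "n_children": n_children,
        "education_years_mean": education,
    })
    for col, (cats, p) in _CATEGORIES.items():
        df[col] = cat_rng.choice(cats, size=n, p=p)
    for j, good in enumerate(goods):
        df[f"quantity_{good}"] = quantity[:, j]
        df[f"expenditure_{good}"] = expenditure[:, j]

    eps_x, zeta = _expenditure_quality(config.beta0, config.beta1, config.mean_share)
    e = true_elasticities(config)
    group_shares, group_elas = _group_truth(config)
    truth = SyntheticTruth(
        cluster_log_prices=pd.DataFrame(log_prices, columns=list(goods)),
        true_price_elasticity=pd.DataFrame(e, index=list(goods), columns=list(goods)),
        true_expenditure_elasticity=pd.Series(eps_x, index=list(goods)),
        true_quality_elasticity=pd.Series(zeta, index=list(goods)),
        config_echo=config,
        group_price_elasticity=group_elas,
        group_mean_share=group_shares,
        clip_fraction=clip_fraction,
        clip_warning=clip_fraction > CLIP_WARN_FRACTION,
    )
    return df, truth


def flat_cpi_table(rounds: Sequence[str] = ("66", "68"),
                   subrounds: Sequence[int] = (1, 2, 3, 4),
                   index: float = 100.0) -> pd.DataFrame:
    """CPI deflator table with a constant index (identity deflation), matching
    the generator's output which is already expressed at base-period prices."""
    rows = [(r, sr, index) for r in rounds for sr in subrounds]
    return pd.DataFrame(rows, columns=["round_label", "subround", "cpi_index"])


# ---------------------------------------------------------------------------
# annual price / income series for the affordability module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesConfig:
    """Deterministic annual retail-price and per-capita-GDP series.

    Nominal magnitudes compound at inflation times the respective real growth
    rate; the CPI compounds at inflation alone, so deflating by it recovers
    the configured real paths exactly.
    """

    start_year: int = 2006
    n_years: int = 13
    initial_nominal_price: float = 25.0      # INR per litre
    real_price_annual_change: float = 0.0    # fraction per year
    inflation_rate: float = 0.05             # fraction per year
    initial_gdp_pc: float = 50_000.0         # INR per year
    real_gdp_growth: float = 0.049           # fraction per year
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 2:
            raise InvalidConfigError("n_years must be >= 2")
        if self.initial_nominal_price <= 0 or self.initial_gdp_pc <= 0:
            raise InvalidConfigError("prices and GDP must be positive")


def generate_price_gdp_series(config: SeriesConfig) -> pd.DataFrame:
    """Annual table (year, nominal_price, cpi_index, nominal_gdp_pc)."""
    t = np.arange(config.n_years)
    infl = (1 + config.inflation_rate) ** t
    price = config.initial_nominal_price * infl * (1 + config.real_price_annual_change) ** t
    gdp = config.initial_gdp_pc * infl * (1 + config.real_gdp_growth) ** t
    years = [f"{y}/{(y + 1) % 100:02d}" for y in range(config.start_year,
                                                       config.start_year + config.n_years)]
    return pd.DataFrame({
        "year": years,
        "nominal_price": price,
        "cpi_index": 100.0 * infl,
        "nominal_gdp_pc": gdp,
    })
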