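"""Two-stage between-cluster estimation of price elasticities from unit values.

Household surveys report expenditures and quantities, so prices are only
observed through unit values (expenditure / quantity).  Unit values are a
contaminated price signal: households respond to price partly by shading
quality (so unit values move less than prices), and reporting error in either
quantity or expenditure propagates into them.  The estimator implemented here
addresses both, following the classic two-stage design:

Stage 1 (within clusters).  Budget shares and log unit values are regressed
on log total expenditure and household covariates with cluster fixed effects
(within-cluster demeaning).  Prices are constant within a cluster, so these
regressions identify the expenditure and covariate coefficients and the
within-cluster residual covariances, which measure quality-plus-measurement
noise.

Stage 2 (between clusters).  Cluster averages of shares and log unit values,
purged of expenditure and covariate effects, vary across clusters because
prices do.  The share response to unit values is estimated by an
errors-in-variables regression across clusters, subtracting from the
between-cluster moment matrices the sampling noise implied by the stage-1
residual covariances and cluster purchaser counts.

The corrected response matrix is mapped to price elasticities through the
quality-shading system: with mean shares w, expenditure elasticities
eps_x = 1 + b0/w - b1 and quality elasticities zeta = b1/eps_x,

    theta = diag(w)(I + E),   psi = I + diag(zeta) E,   B = theta psi^-1,

which solves to E = (I - diag(w)^-1 B diag(zeta))^-1 (diag(w)^-1 B - I); with
zeta = 0 this reduces exactly to diag(w)^-1 B - I.

Standard errors come from a cluster bootstrap of the second stage: clusters
are resampled with replacement, the between-cluster regression and the
elasticity transform are recomputed per draw with stage-1 coefficients held
fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import PreparedSurvey
from .synthetic import TERTILES

__all__ = [
    "Stage1Results",
    "ClusterMoments",
    "ElasticityEstimate",
    "RankDeficiencyError",
    "InsufficientVariationError",
    "CorrectionOvershootError",
    "QualitySingularityError",
    "UnstableBootstrapError",
    "stage1_within",
    "cluster_purged_means",
    "stage2_eiv",
    "elasticity_transform",
    "bootstrap_se",
    "estimate_elasticities",
    "estimate_by_group",
    "unitvalue_variance_decomposition",
]

logger = logging.getLogger(__name__)


class RankDeficiencyError(ValueError):
    """Collinear covariates in a stage-1 regression."""


class InsufficientVariationError(ValueError):
    """Too few clusters with defined moments for a good pair."""


class CorrectionOvershootError(ValueError):
    """The measurement-error-corrected moment matrix is not positive definite
    (correction exceeds the observed between-cluster variation)."""


class QualitySingularityError(ValueError):
    """The quality-shading solve is singular."""


class UnstableBootstrapError(RuntimeError):
    """More than the tolerated fraction of bootstrap draws failed."""


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

@dataclass
class Stage1Results:
    """Within-cluster (fixed-effects) coefficients and residual moments."""

    goods: tuple[str, ...]
    covariates: tuple[str, ...]
    alpha0: np.ndarray            # share-eq level incl. average price term
    alpha1: np.ndarray
    beta0: np.ndarray             # per good, share-eq ln x coefficient
    beta1: np.ndarray             # per good, unit-value-eq ln x coefficient
    gamma0: np.ndarray            # G x K
    gamma1: np.ndarray            # G x K
    sigma00: np.ndarray           # G x G within residual covariances
    sigma01: np.ndarray           # sigma01[G, H] = cov(u0_G, u1_H)
    sigma11: np.ndarray
    mean_share: np.ndarray
    resid0: np.ndarray            # n x G within residuals, share eq
    resid1: np.ndarray            # n x G, NaN for non-purchasers
    cluster_ids: np.ndarray       # n, integer codes
    n_clusters: int


def _demean_within(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Subtract group means along axis 0 (NaNs ignored and preserved)."""
    v = np.asarray(values, dtype=float)
    flat = v.reshape(len(v), -1)
    valid = ~np.isnan(flat)
    filled = np.where(valid, flat, 0.0)
    sums = np.zeros((n_groups, flat.shape[1]))
    cnts = np.zeros((n_groups, flat.shape[1]))
    np.add.at(sums, codes, filled)
    np.add.at(cnts, codes, valid.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / cnts
    out = flat - means[codes]
    out[~valid] = np.nan
    return out.reshape(v.shape)


def _within_ols(y: np.ndarray, x: np.ndarray, codes: np.ndarray, n_groups: int,
                names: tuple[str, ...]):
    """Fixed-effects OLS by within-demeaning of one column y on columns x,
    restricted to rows where y is defined.  Returns (coefs, residuals) with
    residuals NaN outside the sample."""
    mask = ~np.isnan(y)
    ym = y[mask]
    xm = x[mask]
    cm = codes[mask]
    yd = _demean_within(ym, cm, n_groups)
    xd = _demean_within(xm, cm, n_groups)
    coef, _, rank, _ = np.linalg.lstsq(xd, yd, rcond=None)
    if rank < x.shape[1]:
        raise RankDeficiencyError(
            f"rank {rank} < {x.shape[1]} regressors; check columns {names}")
    resid = np.full_like(y, np.nan)
    resid[mask] = yd - xd @ coef
    return coef, resid


def _resid_cov(a: np.ndarray, b: np.ndarray, n_cells: np.ndarray, k: int) -> np.ndarray:
    """Pairwise residual covariance sum(a_G b_H) / (N - C - k) over the
    overlap sample; C is the number of demeaning cells of the narrower
    residual (degrees of freedom absorbed by the fixed effects)."""
    ga, gb = a.shape[1], b.shape[1]
    out = np.zeros((ga, gb))
    for i in range(ga):
        for j in range(gb):
            prod = a[:, i] * b[:, j]
            m = ~np.isnan(prod)
            n = int(m.sum())
            dof = max(n - int(n_cells[i, j]) - k, 1)
            out[i, j] = np.nansum(prod[m]) / dof
    return out


def stage1_within(prepared: PreparedSurvey) -> Stage1Results:
    """Estimate both household-level equations with cluster fixed effects.

    The share equation runs over every retained household; the unit-value
    equation for each good runs over its purchasers.  Goods with no
    purchasers at all are dropped with a warning.  Residual covariances are
    taken over pairwise-overlap samples with the fixed-effect and regressor
    degrees of freedom removed.
    """
    data = prepared.data
    goods = [g for g in prepared.goods if (data[f"quantity_{g}"] > 0).any()]
    dropped = set(prepared.goods) - set(goods)
    if dropped:
        logger.warning("dropping good(s) with zero purchasers: %s", sorted(dropped))
    codes, _ = pd.factorize(data["cluster_id"], sort=True)
    n_clusters = codes.max() + 1
    if n_clusters < 2:
        raise InsufficientVariationError("need at least 2 clusters")
    x = np.column_stack([data["log_total_expenditure"].to_numpy(dtype=float)]
                        + [data[c].to_numpy(dtype=float) for c in prepared.covariates])
    names = ("log_total_expenditure",) + tuple(prepared.covariates)
    k = x.shape[1]
    n = len(data)
    g = len(goods)

    beta0 = np.zeros(g)
    beta1 = np.zeros(g)
    gamma0 = np.zeros((g, k - 1))
    gamma1 = np.zeros((g, k - 1))
    alpha0 = np.zeros(g)
    alpha1 = np.zeros(g)
    resid0 = np.full((n, g), np.nan)
    resid1 = np.full((n, g), np.nan)
    mean_share = np.zeros(g)
    # per-cluster cell counts for dof bookkeeping
    cells_all = n_clusters
    cells_uv = np.zeros(g)

    for j, good in enumerate(goods):
        w = data[f"share_{good}"].to_numpy(dtype=float)
        lnv = data[f"log_unit_value_{good}"].to_numpy(dtype=float)
        c0, r0 = _within_ols(w, x, codes, n_clusters, names)
        c1, r1 = _within_ols(lnv, x, codes, n_clusters, names)
        beta0[j], gamma0[j] = c0[0], c0[1:]
        beta1[j], gamma1[j] = c1[0], c1[1:]
        resid0[:, j], resid1[:, j] = r0, r1
        mean_share[j] = w.mean()
        mask = ~np.isnan(lnv)
        alpha0[j] = w.mean() - x.mean(axis=0) @ c0
        alpha1[j] = lnv[mask].mean() - x[mask].mean(axis=0) @ c1
        cells_uv[j] = len(np.unique(codes[mask]))

    cells00 = np.full((g, g), cells_all)
    cells11 = np.minimum.outer(cells_uv, cells_uv)
    cells01 = np.tile(cells_uv, (g, 1))          # overlap limited by the uv sample
    sigma00 = _resid_cov(resid0, resid0, cells00, k)
    sigma11 = _resid_cov(resid1, resid1, cells11, k)
    sigma01 = _resid_cov(resid0, resid1, cells01, k)

    return Stage1Results(
        goods=tuple(goods), covariates=prepared.covariates,
        alpha0=alpha0, alpha1=alpha1, beta0=beta0, beta1=beta1,
        gamma0=gamma0, gamma1=gamma1,
        sigma00=sigma00, sigma01=sigma01, sigma11=sigma11,
        mean_share=mean_share, resid0=resid0, resid1=resid1,
        cluster_ids=codes, n_clusters=n_clusters,
    )


# ---------------------------------------------------------------------------
# stage 2 moments
# ---------------------------------------------------------------------------

@dataclass
class ClusterMoments:
    """Cluster-level purged averages and between-cluster moment matrices.

    ``y0`` are cluster means over all households of shares net of expenditure
    and covariate effects (the cluster effect and the price response remain);
    ``y1`` are cluster means over purchasers of purged log unit values (the
    noisy price signal), NaN where a cluster has no purchasers.
    """

    goods: tuple[str, ...]
    y0: np.ndarray                 # clusters x G
    y1: np.ndarray                 # clusters x G, NaN allowed
    n_households: np.ndarray       # per cluster, share-side household count
    n_purchasers: np.ndarray       # clusters x G, unit-value-side purchasers
    n_overlap: np.ndarray          # clusters x G x G pairwise purchaser overlap
    n_share_overlap: np.ndarray    # clusters x G share-side households buying G
    sigma01: np.ndarray
    sigma11: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.y0)

    def subset(self, idx: np.ndarray) -> "ClusterMoments":
        return ClusterMoments(self.goods, self.y0[idx], self.y1[idx],
                              self.n_households[idx], self.n_purchasers[idx],
                              self.n_overlap[idx], self.n_share_overlap[idx],
                              self.sigma01, self.sigma11)


def _cluster_mean(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    flat = np.asarray(values, dtype=float)
    valid = ~np.isnan(flat)
    filled = np.where(valid, flat, 0.0)
    sums = np.zeros((n_groups, flat.shape[1]))
    cnts = np.zeros((n_groups, flat.shape[1]))
    np.add.at(sums, codes, filled)
    np.add.at(cnts, codes, valid.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / cnts, cnts


def cluster_purged_means(stage1: Stage1Results, prepared: PreparedSurvey,
                         share_data: pd.DataFrame | None = None,
                         share_stage1: Stage1Results | None = None,
                         ) -> ClusterMoments:
    """Cluster averages of shares and log unit values purged of household
    effects.

    ``share_data`` / ``share_stage1`` allow the share side (y0) to come from
    a subgroup of households with its own stage-1 coefficients while the
    unit-value side (y1) is always computed from the full ``prepared`` table
    — the shared-cluster-price design used for income-group estimation.
    """
    if share_data is None:
        share_data = prepared.data
    if share_stage1 is None:
        share_stage1 = stage1
    data = prepared.data
    goods = stage1.goods
    g = len(goods)
    codes, uniques = pd.factorize(data["cluster_id"], sort=True)
    n_clusters = len(uniques)

    x_all = np.column_stack([data["log_total_expenditure"].to_numpy(dtype=float)]
                            + [data[c].to_numpy(dtype=float) for c in prepared.covariates])
    lnv = np.column_stack([data[f"log_unit_value_{good}"].to_numpy(dtype=float)
                           for good in goods])
    purged1 = lnv - x_all @ np.vstack([stage1.beta1, stage1.gamma1.T])
    y1, n_plus = _cluster_mean(purged1, codes, n_clusters)
    y1[n_plus == 0] = np.nan

    codes_s = pd.Categorical(share_data["cluster_id"], categories=uniques).codes
    if np.any(codes_s < 0):
        raise InsufficientVariationError("share households outside the cluster index")
    x_s = np.column_stack([share_data["log_total_expenditure"].to_numpy(dtype=float)]
                          + [share_data[c].to_numpy(dtype=float)
                             for c in prepared.covariates])
    w = np.column_stack([share_data[f"share_{good}"].to_numpy(dtype=float)
                         for good in goods])
    purged0 = w - x_s @ np.vstack([share_stage1.beta0, share_stage1.gamma0.T])
    y0, n_hh = _cluster_mean(purged0, codes_s, n_clusters)
    y0[n_hh == 0] = np.nan

    buys = ~np.isnan(lnv)
    n_overlap = np.zeros((n_clusters, g, g))
    pair = (buys[:, :, None] & buys[:, None, :]).astype(float)
    np.add.at(n_overlap, codes, pair)

    buys_s = np.column_stack([(share_data[f"quantity_{good}"] > 0).to_numpy()
                              for good in goods]).astype(float)
    n_share_overlap = np.zeros((n_clusters, g))
    np.add.at(n_share_overlap, codes_s, buys_s)

    return ClusterMoments(goods=goods, y0=y0, y1=y1,
                          n_households=n_hh[:, 0], n_purchasers=n_plus,
                          n_overlap=n_overlap, n_share_overlap=n_share_overlap,
                          sigma01=share_stage1.sigma01, sigma11=stage1.sigma11)


def _pairwise_cov(a: np.ndarray, b: np.ndarray, min_clusters: int = 3):
    """cov[i, j] = covariance across clusters of a[:, i] with b[:, j] on
    pairwise-complete rows."""
    ga, gb = a.shape[1], b.shape[1]
    out = np.zeros((ga, gb))
    for i in range(ga):
        for j in range(gb):
            m = ~np.isnan(a[:, i]) & ~np.isnan(b[:, j])
            n = int(m.sum())
            if n < min_clusters:
                raise InsufficientVariationError(
                    f"only {n} clusters with defined moments for pair ({i}, {j})")
            ai, bj = a[m, i], b[m, j]
            out[i, j] = np.dot(ai - ai.mean(), bj - bj.mean()) / (n - 1)
    return out


def _correction_matrices(m: ClusterMoments):
    """Average attenuation corrections.

    M11[G, H] = sigma11[G, H] * mean_c n+_GH / (n+_G n+_H): sampling noise of
    the cluster-average unit values.  M01[H, G] = sigma01[G, H] * mean_c
    n0+_H / (n_c n+_H): covariance between noise in the cluster-average unit
    value of H and the cluster-average share residual of G, where n0+_H
    counts share-side households that purchase H (equal to n+_H, hence the
    familiar mean 1/n_c, when the share and unit-value samples coincide).
    """
    g = len(m.goods)
    npl = m.n_purchasers
    m11 = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            ok = (npl[:, i] > 0) & (npl[:, j] > 0)
            ratio = m.n_overlap[ok, i, j] / (npl[ok, i] * npl[ok, j])
            m11[i, j] = m.sigma11[i, j] * ratio.mean()
    m01 = np.zeros((g, g))
    for j in range(g):
        ok = (m.n_households > 0) & (npl[:, j] > 0)
        ratio = m.n_share_overlap[ok, j] / (m.n_households[ok] * npl[ok, j])
        m01[j, :] = m.sigma01[:, j] * ratio.mean()
    return m11, m01


def stage2_eiv(moments: ClusterMoments, ridge: float = 0.0) -> np.ndarray:
    """Errors-in-variables between-cluster regression of purged shares on
    purged unit values.

    Returns B with entry (G, H) the response of good-G's share to good-H's
    log unit value, purged of the attenuation caused by sampling noise in
    cluster-average unit values:  B^T = (R - M11)^-1 (S - M01)  with R the
    between-cluster covariance of y1, S[H, G] = cov(y1_H, y0_G).  An optional
    ridge term stabilises a non-positive-definite corrected matrix; it is off
    by default and its use is logged loudly.
    """
    r = _pairwise_cov(moments.y1, moments.y1)
    s = _pairwise_cov(moments.y1, moments.y0)
    m11, m01 = _correction_matrices(moments)
    a = r - m11
    a = (a + a.T) / 2.0
    if ridge:
        logger.warning("stage2_eiv: applying ridge %.3g to the corrected "
                       "unit-value moment matrix", ridge)
        a = a + ridge * np.eye(len(a))
    eigmin = np.linalg.eigvalsh(a).min()
    if eigmin <= 0:
        raise CorrectionOvershootError(
            f"corrected between-cluster moment matrix not positive definite "
            f"(min eigenvalue {eigmin:.3g}); use more clusters or enable ridge")
    bt = np.linalg.solve(a, s - m01)
    return bt.T


# ---------------------------------------------------------------------------
# elasticity transform
# ---------------------------------------------------------------------------

@dataclass
class ElasticityEstimate:
    """Price-elasticity matrix with companion quantities.

    ``elasticity`` entry (i, j) is the elasticity of good-i quantity with
    respect to good-j price.
    """

    elasticity: pd.DataFrame
    expenditure_elasticity: pd.Series
    quality_elasticity: pd.Series
    b_matrix: pd.DataFrame
    mean_share: pd.Series
    group: str = "full"
    se: pd.DataFrame | None = None
    n_draws: int = 0
    seed: int | None = None
    n_failed_draws: int = 0


def _transform_matrices(b: np.ndarray, mean_share: np.ndarray, zeta: np.ndarray,
                        ) -> np.ndarray:
    g = len(mean_share)
    winv_b = b / mean_share[:, None]
    eye = np.eye(g)
    lhs = eye - winv_b * zeta[None, :]
    cond = np.linalg.cond(lhs)
    if not np.isfinite(cond) or cond > 1e12:
        raise QualitySingularityError(
            f"quality-shading solve ill-conditioned (cond={cond:.3g})")
    return np.linalg.solve(lhs, winv_b - eye)


def elasticity_transform(b: np.ndarray, stage1: Stage1Results,
                         mean_share: np.ndarray | None = None,
                         group: str = "full") -> ElasticityEstimate:
    """Map the corrected share-response matrix B to price elasticities.

    eps_x = 1 + b0/w - b1,  zeta = b1/eps_x, and E solves
    theta = diag(w)(I + E), psi = I + diag(zeta) E, B = theta psi^-1, i.e.
    E = (I - diag(w)^-1 B diag(zeta))^-1 (diag(w)^-1 B - I); the zeta = 0
    limit is exactly diag(w)^-1 B - I (no quality shading).
    """
    goods = list(stage1.goods)
    w = stage1.mean_share if mean_share is None else np.asarray(mean_share, float)
    if np.any(w <= 0):
        raise QualitySingularityError("non-positive mean share")
    eps_x = 1.0 + stage1.beta0 / w - stage1.beta1
    zeta = stage1.beta1 / eps_x
    e = _transform_matrices(np.asarray(b, dtype=float), w, zeta)
    return ElasticityEstimate(
        elasticity=pd.DataFrame(e, index=goods, columns=goods),
        expenditure_elasticity=pd.Series(eps_x, index=goods),
        quality_elasticity=pd.Series(zeta, index=goods),
        b_matrix=pd.DataFrame(np.asarray(b, float), index=goods, columns=goods),
        mean_share=pd.Series(w, index=goods),
        group=group,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_se(moments: ClusterMoments, stage1: Stage1Results,
                 n_draws: int = 1000, seed: int = 0,
                 mean_share: np.ndarray | None = None,
                 max_failed_fraction: float = 0.10,
                 strict: bool = False,
                 return_draws: bool = False):
    """Cluster-bootstrap standard errors of the elasticity matrix.

    Clusters are resampled with replacement; the second-stage moments, the
    EIV correction and the elasticity transform are recomputed per draw with
    the stage-1 coefficients held fixed.  Draws where the corrected moment
    matrix is singular are dropped and counted; more than
    ``max_failed_fraction`` failures raises (``strict=True``) or warns.
    Returns (se DataFrame, n_failed[, draws array]).
    """
    goods = list(moments.goods)
    g = len(goods)
    rng = np.random.default_rng(seed)
    nc = moments.n_clusters
    draws = np.full((n_draws, g, g), np.nan)
    failed = 0
    for d in range(n_draws):
        idx = rng.integers(0, nc, size=nc)
        try:
            b = stage2_eiv(moments.subset(idx))
            est = elasticity_transform(b, stage1, mean_share=mean_share)
            draws[d] = est.elasticity.to_numpy()
        except (CorrectionOvershootError, QualitySingularityError,
                InsufficientVariationError, np.linalg.LinAlgError):
            failed += 1
    if failed > max_failed_fraction * n_draws:
        msg = f"{failed}/{n_draws} bootstrap draws failed"
        if strict:
            raise UnstableBootstrapError(msg)
        logger.warning("unstable bootstrap: %s", msg)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN slices (every draw failed) legitimately yield NaN SEs
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(draws, axis=0, ddof=1)
    se_df = pd.DataFrame(se, index=goods, columns=goods)
    if return_draws:
        return se_df, failed, draws
    return se_df, failed


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def estimate_elasticities(prepared: PreparedSurvey, n_draws: int = 1000,
                          seed: int = 0, group: str = "full",
                          ridge: float = 0.0) -> ElasticityEstimate:
    """Full-sample pipeline: stage 1, purged cluster means, corrected stage 2,
    elasticity transform, cluster-bootstrap SEs."""
    s1 = stage1_within(prepared)
    moments = cluster_purged_means(s1, prepared)
    b = stage2_eiv(moments, ridge=ridge)
    est = elasticity_transform(b, s1, group=group)
    if n_draws:
        est.se, est.n_failed_draws = bootstrap_se(moments, s1, n_draws=n_draws,
                                                  seed=seed)
        est.n_draws = n_draws
        est.seed = seed
    return est


def estimate_by_group(prepared: PreparedSurvey, grouping: str = "income_tertile",
                      n_draws: int = 1000, seed: int = 0,
                      min_clusters: int = 30) -> dict[str, ElasticityEstimate]:
    """Stratified estimation with shared cluster prices.

    For income tertiles: the price signal y1 is computed once from all
    households in a cluster pooled across groups (households in the same
    cluster face the same price whatever their income), while the share side
    — stage-1 share coefficients, purged share means, mean shares — is
    group-specific.  For ``grouping='sector'`` clusters split cleanly by
    rural/urban, so the full pipeline simply runs per sector.  Groups with
    fewer than ``min_clusters`` clusters are skipped with a warning.
    """
    if grouping == "sector":
        out = {}
        for sec in ("rural", "urban"):
            sub = prepared.data[prepared.data["sector"] == sec]
            if sub["cluster_id"].nunique() < min_clusters:
                logger.warning("skipping sector %s: too few clusters", sec)
                continue
            ps = PreparedSurvey(sub, prepared.goods, prepared.covariates,
                                dict(prepared.meta))
            out[sec] = estimate_elasticities(ps, n_draws=n_draws, seed=seed,
                                             group=sec)
        return out
    if grouping != "income_tertile":
        raise ValueError("grouping must be 'income_tertile' or 'sector'")
    if "income_tertile" not in prepared.data.columns:
        raise KeyError("assign_income_tertiles must run before group estimation")

    pooled_s1 = stage1_within(prepared)
    out: dict[str, ElasticityEstimate] = {}
    for i, tert in enumerate(TERTILES):
        sub = prepared.data[prepared.data["income_tertile"] == tert]
        if sub["cluster_id"].nunique() < min_clusters:
            logger.warning("skipping tertile %s: too few clusters", tert)
            continue
        sub_ps = PreparedSurvey(sub, prepared.goods, prepared.covariates)
        group_s1 = stage1_within(sub_ps)
        # align goods: group share equations for the pooled good list
        if group_s1.goods != pooled_s1.goods:
            raise InsufficientVariationError(
                f"tertile {tert} lost goods {set(pooled_s1.goods) - set(group_s1.goods)}")
        moments = cluster_purged_means(pooled_s1, prepared,
                                       share_data=sub, share_stage1=group_s1)
        # restrict to clusters where the group is present
        present = moments.n_households > 0
        moments = moments.subset(np.flatnonzero(present))
        b = stage2_eiv(moments)
        w_g = np.array([sub[f"share_{good}"].mean() for good in pooled_s1.goods])
        mixed = Stage1Results(
            goods=pooled_s1.goods, covariates=pooled_s1.covariates,
            alpha0=group_s1.alpha0, alpha1=pooled_s1.alpha1,
            beta0=group_s1.beta0, beta1=pooled_s1.beta1,
            gamma0=group_s1.gamma0, gamma1=pooled_s1.gamma1,
            sigma00=group_s1.sigma00, sigma01=group_s1.sigma01,
            sigma11=pooled_s1.sigma11, mean_share=w_g,
            resid0=group_s1.resid0, resid1=pooled_s1.resid1,
            cluster_ids=pooled_s1.cluster_ids, n_clusters=pooled_s1.n_clusters)
        est = elasticity_transform(b, mixed, mean_share=w_g, group=tert)
        if n_draws:
            est.se, est.n_failed_draws = bootstrap_se(
                moments, mixed, n_draws=n_draws, seed=seed + i,
                mean_share=w_g)
            est.n_draws = n_draws
            est.seed = seed + i
        out[tert] = est
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def unitvalue_variance_decomposition(prepared: PreparedSurvey,
                                     good: str = "ASB") -> float:
    """R-squared of log unit values on cluster indicators.

    Measures how much of the unit-value variation is between clusters —
    i.e. plausibly genuine price variation rather than within-cluster quality
    and measurement noise.
    """
    data = prepared.data
    lnv = data[f"log_unit_value_{good}"]
    sub = data.loc[lnv.notna(), ["cluster_id"]].assign(lnv=lnv.dropna())
    if sub["cluster_id"].nunique() < 2:
        raise InsufficientVariationError("need purchasers in at least 2 clusters")
    y = sub["lnv"].to_numpy()
    fitted = sub.groupby("cluster_id")["lnv"].transform("mean").to_numpy()
    sst = float(np.sum((y - y.mean()) ** 2))
    ssw = float(np.sum((y - fitted) ** 2))
    return 1.0 - ssw / sst
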