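"""Survey ingestion and preparation for unit-value demand estimation.

Takes household expenditure microdata (one row per household, wide per-good
``quantity_<good>`` / ``expenditure_<good>`` columns), deflates nominal values
with a (round, subround) CPI table, constructs budget shares and log unit
values, applies the estimation filters (drop non-purchasers of the focal
good, keep clusters with at least two purchasers), assigns income tertiles by
total household expenditure, and produces descriptive summary tables by
income group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import TERTILES

__all__ = [
    "PreparedSurvey",
    "SchemaError",
    "RowValidationError",
    "DeflationError",
    "TertileError",
    "EmptyFilterError",
    "read_survey",
    "write_survey",
    "deflate_unit_values",
    "compute_shares_unitvalues",
    "filter_for_estimation",
    "assign_income_tertiles",
    "summarize_survey",
    "goods_in",
    "DEFAULT_COVARIATES",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "household_id", "cluster_id", "round_label", "subround", "sector",
    "total_expenditure", "household_size", "n_children", "education_years_mean",
)

#: household covariates entering both equations (the z vector)
DEFAULT_COVARIATES = ("log_household_size", "n_children", "education_years_mean")


class SchemaError(ValueError):
    """A mandatory column is missing from the survey file."""


class RowValidationError(ValueError):
    """One or more rows violate the record invariants; offending rows listed."""


class DeflationError(KeyError):
    """A (round, subround) cell is missing from the CPI table."""


class TertileError(ValueError):
    """Too few households to form income tertiles."""


class EmptyFilterError(ValueError):
    """The estimation filter removed every household."""


def goods_in(records: pd.DataFrame) -> tuple[str, ...]:
    """Goods present in a survey table, in column order, from the paired
    ``quantity_<good>`` / ``expenditure_<good>`` columns."""
    goods = [c[len("quantity_"):] for c in records.columns if c.startswith("quantity_")]
    missing = [g for g in goods if f"expenditure_{g}" not in records.columns]
    if missing:
        raise SchemaError(f"goods missing an expenditure column: {missing}")
    if not goods:
        raise SchemaError("no quantity_<good> columns found")
    return tuple(goods)


def _validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    goods = goods_in(records)
    bad: dict[str, list] = {}
    for g in goods:
        q, e = records[f"quantity_{g}"], records[f"expenditure_{g}"]
        neg = records.index[(q < 0) | (e < 0)]
        mism = records.index[(e > 0) != (q > 0)]
        if len(neg):
            bad[f"negative quantity/expenditure for {g}"] = list(neg[:20])
        if len(mism):
            bad[f"expenditure/quantity sign mismatch for {g}"] = list(mism[:20])
    if (records["total_expenditure"] <= 0).any():
        bad["non-positive total_expenditure"] = list(
            records.index[records["total_expenditure"] <= 0][:20])
    if bad:
        raise RowValidationError(f"invalid rows: {bad}")


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read and validate a survey CSV; returns one row per household."""
    records = pd.read_csv(path, dtype={"round_label": str})
    _validate_records(records)
    logger.info("read %d household records from %s", len(records), path)
    return records


def write_survey(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# deflation
# ---------------------------------------------------------------------------

def deflate_unit_values(records: pd.DataFrame, cpi_table: pd.DataFrame,
                        base_index: float) -> pd.DataFrame:
    """Deflate all currency columns to the base period.

    Each row is scaled by ``base_index / cpi_index(round, subround)``.  Both
    per-good expenditures and total expenditure are deflated (so budget
    shares are unchanged, while unit values are expressed in base-period
    currency); quantities are untouched.
    """
    cpi = cpi_table.copy()
    cpi["round_label"] = cpi["round_label"].astype(str)
    idx = cpi.set_index(["round_label", "subround"])["cpi_index"]
    key = pd.MultiIndex.from_frame(records[["round_label", "subround"]])
    cells = idx.reindex(key)
    if cells.isna().any():
        missing = sorted(set(key[np.asarray(cells.isna())]))
        raise DeflationError(f"missing CPI cell(s) for (round, subround): {missing}")
    factor = base_index / cells.to_numpy()
    out = records.copy()
    money_cols = ["total_expenditure"] + [c for c in records.columns
                                          if c.startswith("expenditure_")]
    for c in money_cols:
        out[c] = records[c].to_numpy() * factor
    return out


# ---------------------------------------------------------------------------
# prepared survey
# ---------------------------------------------------------------------------

@dataclass
class PreparedSurvey:
    """Estimation-ready survey: shares, log unit values, covariates, clusters.

    ``data`` holds one row per household with per-good ``share_<good>`` and
    ``log_unit_value_<good>`` columns (NaN where the household did not
    purchase), the log of total expenditure, the covariate columns, and —
    once assigned — an ``income_tertile`` label.
    """

    data: pd.DataFrame
    goods: tuple[str, ...]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    meta: dict = field(default_factory=dict)

    @property
    def n_households(self) -> int:
        return len(self.data)

    @property
    def n_clusters(self) -> int:
        return self.data["cluster_id"].nunique()

    def purchasers(self, good: str) -> pd.Series:
        return self.data[f"quantity_{good}"] > 0

    def cluster_counts(self) -> pd.DataFrame:
        """Per cluster: household count and purchaser count per good."""
        g = self.data.groupby("cluster_id")
        out = g.size().to_frame("n_households")
        for good in self.goods:
            out[f"n_purchasers_{good}"] = (
                (self.data[f"quantity_{good}"] > 0).groupby(self.data["cluster_id"]).sum())
        return out


def compute_shares_unitvalues(records: pd.DataFrame,
                              covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                              ) -> PreparedSurvey:
    """Budget shares (expenditure over total, zero when no purchase) and log
    unit values (expenditure over quantity, defined only for purchasers)."""
    _validate_records(records)
    goods = goods_in(records)
    data = records.copy()
    total = data["total_expenditure"].to_numpy(dtype=float)
    data["log_total_expenditure"] = np.log(total)
    if "log_household_size" in covariates and "log_household_size" not in data:
        data["log_household_size"] = np.log(data["household_size"].astype(float))
    for g in goods:
        e = data[f"expenditure_{g}"].to_numpy(dtype=float)
        q = data[f"quantity_{g}"].to_numpy(dtype=float)
        data[f"share_{g}"] = e / total
        with np.errstate(divide="ignore", invalid="ignore"):
            uv = np.where(q > 0, e / np.where(q > 0, q, 1.0), np.nan)
        data[f"log_unit_value_{g}"] = np.log(uv, out=np.full_like(uv, np.nan),
                                             where=q > 0)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise SchemaError(f"covariate column(s) not in survey: {missing}")
    return PreparedSurvey(data=data, goods=goods, covariates=tuple(covariates))


def filter_for_estimation(prepared: PreparedSurvey, focal_good: str = "ASB",
                          min_consumers: int = 2) -> PreparedSurvey:
    """Apply the estimation-sample filter.

    Drops households not purchasing the focal good, then drops clusters left
    with fewer than ``min_consumers`` purchasers.  Counts of dropped
    households and clusters are recorded in ``meta`` and logged.
    """
    if focal_good not in prepared.goods:
        raise KeyError(f"{focal_good!r} not among goods {prepared.goods}")
    data = prepared.data
    buyers = data[data[f"quantity_{focal_good}"] > 0]
    sizes = buyers.groupby("cluster_id").size()
    keep_clusters = sizes.index[sizes >= min_consumers]
    out = buyers[buyers["cluster_id"].isin(keep_clusters)].copy()
    if out.empty:
        raise EmptyFilterError(
            f"no households remain after the {focal_good} consumer filter")
    meta = dict(prepared.meta)
    meta.update(
        focal_good=focal_good, min_consumers=min_consumers,
        n_dropped_households=len(data) - len(out),
        n_dropped_clusters=data["cluster_id"].nunique() - out["cluster_id"].nunique(),
    )
    logger.info("estimation filter: kept %d/%d households in %d/%d clusters",
                len(out), len(data), out["cluster_id"].nunique(),
                data["cluster_id"].nunique())
    return PreparedSurvey(out, prepared.goods, prepared.covariates, meta)


def _tertile_labels(total_expenditure: pd.Series, household_id: pd.Series) -> pd.Series:
    n = len(total_expenditure)
    if n < 3:
        raise TertileError(f"need at least 3 households to form tertiles, got {n}")
    order = pd.DataFrame({"x": total_expenditure.to_numpy(),
                          "hid": household_id.to_numpy()}).sort_values(
        ["x", "hid"], kind="mergesort").index
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]  # extras to lower tertiles
    labels = np.repeat(list(TERTILES), sizes)
    out = pd.Series(index=total_expenditure.index[order], data=labels, dtype=object)
    return out.reindex(total_expenditure.index)


def assign_income_tertiles(prepared: PreparedSurvey) -> PreparedSurvey:
    """Label households low / middle / high by total-expenditure rank.

    Boundaries are computed on the sample given (post-filter when called
    after :func:`filter_for_estimation`).  Ties are broken by household id so
    the split is deterministic; tertile sizes differ by at most one, with
    remainders assigned to the lower tertiles.
    """
    data = prepared.data.copy()
    data["income_tertile"] = _tertile_labels(data["total_expenditure"],
                                             data["household_id"])
    return PreparedSurvey(data, prepared.goods, prepared.covariates,
                          dict(prepared.meta))


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

_SUMMARY_MEASURES = ("pct_purchasing", "mean_quantity", "mean_expenditure",
                     "mean_unit_value", "mean_budget_share")


def _summary_block(records: pd.DataFrame, goods, weights: np.ndarray) -> pd.DataFrame:
    total = records["total_expenditure"].to_numpy(dtype=float)
    rows = {}
    wsum = weights.sum()
    for g in goods:
        q = records[f"quantity_{g}"].to_numpy(dtype=float)
        e = records[f"expenditure_{g}"].to_numpy(dtype=float)
        buy = q > 0
        wbuy = weights[buy]
        denom = wbuy.sum()
        if denom > 0:
            mq = float(np.average(q[buy], weights=wbuy))
            me = float(np.average(e[buy], weights=wbuy))
            muv = float(np.average(e[buy] / q[buy], weights=wbuy))
            msh = float(np.average(e[buy] / total[buy], weights=wbuy))
        else:
            mq = me = muv = msh = np.nan
        rows[g] = [float(weights[buy].sum() / wsum), mq, me, muv, msh]
    return pd.DataFrame(rows, index=list(_SUMMARY_MEASURES)).T


def summarize_survey(records: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """Descriptive table per good x income group on the full sample.

    For each good and group (full sample plus expenditure tertiles):
    fraction of households purchasing, and conditional-on-purchase means of
    monthly quantity, expenditure, unit value and budget share.  With
    ``weighted=True`` the survey multipliers in the ``weight`` column are
    used; the default is unweighted.
    """
    goods = goods_in(records)
    weights = (records["weight"].to_numpy(dtype=float) if weighted
               else np.ones(len(records)))
    tert = _tertile_labels(records["total_expenditure"], records["household_id"])
    blocks = {"full": _summary_block(records, goods, weights)}
    for t in TERTILES:
        m = (tert == t).to_numpy()
        blocks[t] = _summary_block(records[m], goods, weights[m])
    out = pd.concat(blocks, names=["group", "good"])
    return out
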