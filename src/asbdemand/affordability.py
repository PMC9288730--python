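"""Affordability of a beverage via the relative income price (RIP).

RIP is the percentage of annual per-capita GDP needed to buy a fixed 100 L of
the beverage in a year; a falling RIP means the drink is becoming more
affordable.  The annual change in RIP is decomposed into a real-price effect
and an income effect: the percentage change in the CPI-deflated price is
subtracted from the percentage change in RIP, attributing the remainder to
income growth.  The two effects sum to the total RIP change by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_rip", "decompose_rip_change", "mean_growth",
           "pool_brand_prices", "REFERENCE_LITRES"]

#: fixed purchase volume defining the RIP numerator
REFERENCE_LITRES = 100.0


def pool_brand_prices(series: pd.DataFrame, weight_by_count: bool = True,
                      ) -> pd.DataFrame:
    """Collapse a multi-brand price table to one nominal price per year.

    Expects columns ``year``, ``nominal_price`` and optionally ``brand`` and
    ``n_observations``.  Brand prices within a year are averaged, weighted by
    observation counts when available (the default), so heavily sampled
    brands dominate the annual mean.  Non-price columns (``cpi_index``,
    ``nominal_gdp_pc``) are carried through and must be constant within year.
    """
    if "brand" not in series.columns:
        return series.copy()
    weights = (series["n_observations"].astype(float)
               if (weight_by_count and "n_observations" in series.columns)
               else pd.Series(1.0, index=series.index))
    s = series.assign(_w=weights)
    def agg(grp):
        out = {"nominal_price": np.average(grp["nominal_price"], weights=grp["_w"])}
        for c in ("cpi_index", "nominal_gdp_pc"):
            if c in grp.columns:
                vals = grp[c].unique()
                if len(vals) > 1:
                    raise ValueError(f"{c} not constant within year {grp.name}")
                out[c] = vals[0]
        return pd.Series(out)
    return s.groupby("year", sort=False).apply(agg, include_groups=False).reset_index()


def compute_rip(series: pd.DataFrame) -> pd.DataFrame:
    """RIP series from an annual table of nominal prices and per-capita GDP.

    ``rip = 100 * (nominal_price * 100 L) / nominal_gdp_pc`` (percent of a
    year's per-capita GDP).  Price and GDP must share the nominal basis;
    scaling both by a common factor leaves RIP unchanged.  When a
    ``cpi_index`` column is present a ``real_price`` column (base = first
    year) is added for the decomposition.
    """
    out = pool_brand_prices(series)
    if (out["nominal_gdp_pc"] <= 0).any():
        raise ValueError("non-positive per-capita GDP")
    out = out.copy()
    out["rip"] = (100.0 * out["nominal_price"] * REFERENCE_LITRES
                  / out["nominal_gdp_pc"])
    if "cpi_index" in out.columns:
        base = out["cpi_index"].iloc[0]
        out["real_price"] = out["nominal_price"] * base / out["cpi_index"]
    return out


def decompose_rip_change(rows: pd.DataFrame, log_exact: bool = False,
                         ) -> pd.DataFrame:
    """Split each year's RIP change into price and income effects.

    ``price_effect_pct`` is the year-over-year percentage change in the real
    price; ``income_effect_pct`` is the RIP change minus the price effect, so
    the two always sum to ``rip_change_pct`` exactly.  Percentage changes are
    simple arithmetic changes by default; ``log_exact=True`` uses log
    differences (x100), under which the price effect equals the real-price
    log change and the income effect equals minus the real-income log change
    exactly.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 years to decompose")
    if "real_price" not in rows.columns:
        raise KeyError("rows must carry a real_price column (see compute_rip)")
    out = rows.copy()

    def pct(x):
        x = x.astype(float)
        if log_exact:
            return 100.0 * np.log(x / x.shift(1))
        return 100.0 * (x / x.shift(1) - 1.0)

    out["rip_change_pct"] = pct(out["rip"])
    out["price_effect_pct"] = pct(out["real_price"])
    out["income_effect_pct"] = out["rip_change_pct"] - out["price_effect_pct"]
    return out


def mean_growth(values) -> float:
    """Geometric mean annual growth rate of a positive annual series:
    (last/first)^(1/(n-1)) - 1."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    return float((v[-1] / v[0]) ** (1.0 / (len(v) - 1)) - 1.0)
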