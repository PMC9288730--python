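"""GST / compensation-cess simulation for sugar-sweetened beverages.

India taxes aerated drinks with a statutory (exclusive) 28% GST plus a 12%
compensation cess, both levied on the net-of-tax price, so the tax burden —
tax as a share of the tax-inclusive retail price — is 0.40/1.40 = 28.6%.
Given an own-price elasticity, the simulator finds the retail price that
delivers a target consumption cut, translates it into the required tax
increase under a pass-through assumption (the fraction of a tax rise that
reaches the shelf price), and back-computes the compensation cess that would
implement it with the GST rate unchanged.

All arithmetic is carried at full precision; :func:`table_report` rounds to
presentation precision separately, so rounded tables never feed back into the
computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaxBaseline",
    "TaxSimResult",
    "InfeasibleScenarioError",
    "burden_from_statutory",
    "price_target_for_reduction",
    "simulate_scenario",
    "simulate_scenarios",
    "group_impacts",
    "group_consumption_shares",
    "table_report",
    "INDIA_GST_BASELINE",
]


class InfeasibleScenarioError(ValueError):
    """The implied tax meets or exceeds the retail price."""


def burden_from_statutory(gst: float, cess: float) -> float:
    """Tax burden (tax / tax-inclusive retail price) implied by exclusive
    statutory rates: (gst + cess) / (1 + gst + cess)."""
    if gst < 0 or cess < 0:
        raise ValueError("statutory rates must be non-negative")
    total = gst + cess
    return total / (1.0 + total)


@dataclass(frozen=True)
class TaxBaseline:
    """Pre-reform market and tax state.

    ``tax_burden`` defaults to the burden implied by the statutory rates but
    may be set directly (e.g. to a published rounded figure) so that
    ``tax_per_litre = retail_price * tax_burden`` matches reported revenue.
    """

    retail_price: float                  # currency / litre (tax inclusive)
    consumption_volume: float            # million litres / year
    elasticity: float                    # own-price elasticity, < 0
    statutory_gst: float = 0.28
    statutory_cess: float = 0.12
    tax_burden: float | None = None
    demand_form: str = "constant-elasticity"   # or "linear"

    def __post_init__(self):
        if self.tax_burden is None:
            object.__setattr__(self, "tax_burden",
                               burden_from_statutory(self.statutory_gst,
                                                     self.statutory_cess))
        if not 0 < self.tax_burden < 1:
            raise ValueError("tax burden must lie in (0, 1)")
        if self.retail_price <= 0 or self.consumption_volume <= 0:
            raise ValueError("price and volume must be positive")
        if self.demand_form not in ("constant-elasticity", "linear"):
            raise ValueError(f"unknown demand form {self.demand_form!r}")

    @property
    def tax_per_litre(self) -> float:
        return self.retail_price * self.tax_burden

    @property
    def revenue(self) -> float:
        """Annual tax revenue, currency millions."""
        return self.tax_per_litre * self.consumption_volume


#: the published Indian baseline: 60 INR/L retail, 28.6% burden (the rounded
#: figure implied by 28% GST + 12% cess), 5,568 M litres sold, overall
#: own-price elasticity -0.94
INDIA_GST_BASELINE = TaxBaseline(retail_price=60.0, consumption_volume=5568.0,
                                 elasticity=-0.94, tax_burden=0.286)


def price_target_for_reduction(p0: float, elasticity: float, reduction: float,
                               demand_form: str = "constant-elasticity") -> float:
    """Retail price at which demand falls by ``reduction``.

    Constant-elasticity demand: p1 = p0 (1 - reduction)^(1/elasticity);
    linear approximation: p1 = p0 (1 + reduction/|elasticity|).
    """
    if elasticity >= 0:
        raise ValueError("elasticity must be negative")
    if not 0 <= reduction < 1:
        raise ValueError("reduction must lie in [0, 1)")
    if demand_form == "constant-elasticity":
        return p0 * (1.0 - reduction) ** (1.0 / elasticity)
    if demand_form == "linear":
        return p0 * (1.0 + reduction / abs(elasticity))
    raise ValueError(f"unknown demand form {demand_form!r}")


@dataclass(frozen=True)
class TaxSimResult:
    """One pass-through scenario, full precision."""

    passthrough: float
    new_retail_price: float
    new_tax_per_litre: float
    new_tax_burden: float
    new_volume: float
    baseline_revenue: float
    new_revenue: float
    pct_change_price: float
    pct_change_consumption: float
    pct_change_revenue: float
    pct_change_tax: float
    abs_tax_increase: float
    required_cess: float


def simulate_scenario(baseline: TaxBaseline, passthrough: float,
                      reduction: float = 0.10) -> TaxSimResult:
    """Required tax change for a target consumption cut at a pass-through.

    The price rise needed for the cut is read off the demand curve; the tax
    must rise by that amount divided by the pass-through.  The compensation
    cess implementing the new per-litre tax is backed out from the statutory
    structure (rates apply to the net-of-tax price):
    required_cess = T1/(p1 - T1) - gst.
    """
    if not 0 < passthrough <= 1.5:
        raise ValueError("passthrough must lie in (0, 1.5]")
    p0 = baseline.retail_price
    t0 = baseline.tax_per_litre
    p1 = price_target_for_reduction(p0, baseline.elasticity, reduction,
                                    baseline.demand_form)
    t1 = t0 + (p1 - p0) / passthrough
    if t1 >= p1:
        raise InfeasibleScenarioError(
            f"implied tax {t1:.2f} >= retail price {p1:.2f} at "
            f"passthrough {passthrough}")
    v1 = baseline.consumption_volume * (1.0 - reduction)
    rev0 = baseline.revenue
    rev1 = t1 * v1
    return TaxSimResult(
        passthrough=passthrough,
        new_retail_price=p1,
        new_tax_per_litre=t1,
        new_tax_burden=t1 / p1,
        new_volume=v1,
        baseline_revenue=rev0,
        new_revenue=rev1,
        pct_change_price=100.0 * (p1 / p0 - 1.0),
        pct_change_consumption=-100.0 * reduction,
        pct_change_revenue=100.0 * (rev1 / rev0 - 1.0),
        pct_change_tax=100.0 * (t1 / t0 - 1.0),
        abs_tax_increase=t1 - t0,
        required_cess=t1 / (p1 - t1) - baseline.statutory_gst,
    )


def simulate_scenarios(baseline: TaxBaseline,
                       passthroughs=(0.5, 0.75, 1.0),
                       reduction: float = 0.10) -> dict[float, TaxSimResult]:
    return {pt: simulate_scenario(baseline, pt, reduction) for pt in passthroughs}


def group_impacts(price_change_pct: float, group_elasticities,
                  group_consumption_shares) -> pd.Series:
    """Consumption change by income group for a common price rise.

    Under constant-elasticity demand each group's consumption changes by
    (1 + dp)^eps_g - 1; the overall change is the consumption-share-weighted
    sum.  ``price_change_pct`` is in percent; shares must sum to one.
    """
    eps = pd.Series(group_elasticities, dtype=float)
    shares = pd.Series(group_consumption_shares, dtype=float).reindex(eps.index)
    if np.any(eps.to_numpy() >= 0):
        raise ValueError("group elasticities must be negative")
    if np.any(shares.to_numpy() < 0) or abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("consumption shares must be non-negative and sum to 1")
    dp = price_change_pct / 100.0
    change = (1.0 + dp) ** eps.to_numpy() - 1.0
    out = pd.Series(100.0 * change, index=eps.index)
    out["overall"] = float(np.dot(shares.to_numpy(), 100.0 * change))
    return out


def group_consumption_shares(prepared, good: str = "ASB") -> pd.Series:
    """Income-group shares of total consumption of a good from a prepared
    survey with income tertiles assigned."""
    data = prepared.data
    if "income_tertile" not in data.columns:
        raise KeyError("assign_income_tertiles must run first")
    q = data.groupby("income_tertile", sort=False)[f"quantity_{good}"].sum()
    return (q / q.sum()).astype(float)


_ROW_ORDER = [
    ("Average retail price (INR/liter)", "new_retail_price", 1),
    ("Tax component in retail price (INR/liter)", "new_tax_per_litre", 1),
    ("Consumption volume (million liter)", "new_volume", 0),
    ("Estimated GST revenue (INR million)", "new_revenue", 0),
    ("Tax burden (% of retail price)", "new_tax_burden_pct", 1),
    ("Consumption change (%)", "pct_change_consumption", 0),
    ("Tax revenue change (%)", "pct_change_revenue", 0),
    ("Price change (%)", "pct_change_price", 0),
    ("Required tax increase (%)", "pct_change_tax", 0),
    ("Absolute tax increase (INR/liter)", "abs_tax_increase", 0),
    ("Required compensation cess rate (%)", "required_cess_pct", 0),
]


def table_report(baseline: TaxBaseline, results: dict[float, TaxSimResult],
                 rounded: bool = True) -> pd.DataFrame:
    """Presentation table: baseline column plus one column per pass-through
    scenario, optionally rounded to the customary reporting precision."""
    cols = {"baseline": {
        "Average retail price (INR/liter)": baseline.retail_price,
        "Tax component in retail price (INR/liter)": baseline.tax_per_litre,
        "Consumption volume (million liter)": baseline.consumption_volume,
        "Estimated GST revenue (INR million)": baseline.revenue,
        "Tax burden (% of retail price)": 100.0 * baseline.tax_burden,
        "Required compensation cess rate (%)": 100.0 * baseline.statutory_cess,
    }}
    for pt in sorted(results):
        r = results[pt]
        vals = {
            "new_tax_burden_pct": 100.0 * r.new_tax_burden,
            "required_cess_pct": 100.0 * r.required_cess,
        }
        col = {}
        for label, attr, nd in _ROW_ORDER:
            v = vals.get(attr, getattr(r, attr, np.nan))
            col[label] = round(v, nd) if rounded else v
        cols[f"{int(pt * 100)}%"] = col
    out = pd.DataFrame(cols).reindex([label for label, _, _ in _ROW_ORDER])
    if rounded:
        out["baseline"] = [round(v, nd) if pd.notna(v) else v
                           for (label, _, nd), v in
                           zip(_ROW_ORDER, out["baseline"])]
    return out
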