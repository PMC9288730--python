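"""Estimate a price-elasticity matrix from a synthetic survey.

Generates a survey in which every household purchases every good (so the
two-equation system holds exactly and the generator's elasticities are the
truth to recover), prepares it, and runs the two-stage estimator: cluster
fixed-effects regressions, errors-in-variables correction of the
between-cluster regression, quality-shading transform, cluster-bootstrap
standard errors.  Prints the estimated matrix next to the truth.
"""

import numpy as np

import asbdemand as ad

cfg = ad.default_config(seed=11).with_(
    n_clusters=2000, households_per_cluster=8,
    prevalence_by_tertile=np.ones((4, 3)))
survey, truth = ad.generate_households(cfg)

prepared = ad.filter_for_estimation(ad.compute_shares_unitvalues(survey))
est = ad.estimate_elasticities(prepared, n_draws=500, seed=2)

print("True price-elasticity matrix (row good's quantity vs column good's price):")
print(truth.true_price_elasticity.round(3).to_string())
print("\nEstimated (bootstrap SE in parentheses):")
for gi in est.elasticity.index:
    cells = [f"{est.elasticity.loc[gi, gj]: .3f} ({est.se.loc[gi, gj]:.3f})"
             for gj in est.elasticity.columns]
    print(f"  {gi:>6}  " + "  ".join(cells))
print(f"\nExpenditure elasticities: {est.expenditure_elasticity.round(3).to_dict()}")
print(f"Quality elasticities:     {est.quality_elasticity.round(3).to_dict()}")
print(f"Share of unit-value variance between clusters (R^2 on cluster "
      f"indicators): {ad.unitvalue_variance_decomposition(prepared):.2f}")
print("\nA negative own-price entry near -0.94 for ASB means a 10% price rise "
      "cuts consumption about 9.4%; off-diagonal signs indicate substitutes "
      "(positive) or complements (negative).")
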