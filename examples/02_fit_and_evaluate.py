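"""Fit the two reference survival models and score their predictions.

The logistic-hazard network discretises follow-up into bins and learns
per-bin conditional event probabilities; the Royston-Parmar spline
models the log cumulative odds of the event as a smooth function of log
time plus a linear covariate effect. Both emit survival curves from
which a point time (median survival) and a 12-month event probability
are read.
"""

from ttegast.experiments import net_point_predictor, spline_point_predictor
from ttegast.metrics import panel
from ttegast.schema import default_schema
from ttegast.simulate import preset, simulate_cohort

schema = default_schema()
cols = [s.name for s in schema]
tbl, truth = simulate_cohort(preset("interaction-heavy", n_patients=1200, seed=0))
df = truth[cols]  # complete covariates straight from the generator
train, test = df.index[:900], df.index[900:]
t, e = truth["t_obs"], truth["event"]

for name, maker in (("spline (odds, 2 knots)", spline_point_predictor),
                    ("logistic-hazard net", net_point_predictor)):
    predict, _ = maker(t[train], e[train], df.loc[train], schema)
    pt, p12 = predict(df.loc[test])
    p = panel(pt, p12, t[test].to_numpy(), e[test].to_numpy())
    print(f"{name:24s} MAE {p.mae_months:.2f} months | AUROC@12mo "
          f"{p.auroc_12mo:.3f} | concordance {p.concordance:.3f}")
print("lower MAE = better-calibrated times; AUROC/concordance = discrimination."
      "\nWith strong covariate interactions the network should lead on concordance.")
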