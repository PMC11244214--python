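"""Shrink the 220-predictor baseline to a parsimonious model.

Two routes are compared:

* Sobol global sensitivity analysis — sample the predictor box uniformly
  with a Saltelli design, estimate each predictor's first-order (FOS) and
  total-order (TOS) share of the prediction variance averaged over the
  ensemble, and keep predictors with mean FOS > 0.01;
* recursive feature elimination with cross-validation (RFECV) — keep
  features whose mean importance rank over Monte-Carlo runs is below 2.

Both should rediscover the three layers that actually drive the synthetic
field (PD_ha, LAI, DTV).
"""

from collections import Counter

from lurpm.ensemble import SplitSpec, split_table, train_ensemble
from lurpm.rfe import RankRecord, aggregate_ranks, rfecv_select
from lurpm.sobol import (
    aggregate_over_ensemble,
    build_parameter_space,
    round_categoricals,
    saltelli_sample,
    screen_features,
)
from lurpm.synthetic import default_scene
from lurpm.workflow import route_feature_table

scene = default_scene(seed=1)
table = route_feature_table(scene, max_rows=835)
train, _ = split_table(table, SplitSpec(seed=1))
rf = dict(n_estimators=20, max_features=0.33)

ensemble = train_ensemble(train, seeds=range(20), **rf)
space = build_parameter_space(table)
design = round_categoricals(saltelli_sample(space, N=128, seed=1), space)
result = aggregate_over_ensemble(ensemble, design,
                                 constants=space.constant_values)
print("top mean first-order indices:")
print(result.mean_fos.sort_values(ascending=False).head(6).round(4))

screen = screen_features(result, threshold=0.01)
by_layer = Counter(table.column_layer[c] for c in screen.parsimonious)
print(f"GSA keeps {len(screen.parsimonious)} columns from layers {dict(by_layer)}")

record = RankRecord()
for k in range(2):
    _, ranking, _ = rfecv_select(train, seed=k, folds=5, step=22, **rf)
    record.add(k, ranking)
selected = aggregate_ranks(record, threshold=2.0)
by_layer = Counter(table.column_layer[c] for c in selected)
print(f"RFECV (mean rank < 2) keeps {len(selected)} columns "
      f"from layers {dict(by_layer)}")
print("true active layers:", scene.truth.active_layers)
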