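"""Build the land-use-regression feature table.

The preprocessed rounds are interpolated onto the idealized route (mean
path of all rounds, 25 m spacing); every sample within 25 m of a route
point contributes to its local-PM statistics, and the per-point maximum
becomes the modelling target.  Each predictor layer is then summarised in
buffers of 25-1000 m radius: max/min/mean for continuous layers, most- and
least-frequent code for categorical ones, giving the 220-column baseline
table named `layer_statistic_buffer`.
"""

from lurpm.synthetic import default_scene
from lurpm.workflow import route_feature_table, route_point_set

scene = default_scene(seed=1)

points = route_point_set(scene)
obs = points.observed
print(f"route: {len(points)} points at {points.spacing:.0f} m spacing, "
      f"{len(obs)} with contributing samples")
print(f"target (max local PM2.5): {obs['pm_max'].min():.2f} to "
      f"{obs['pm_max'].max():.2f} ug/m3")

table = route_feature_table(scene, max_rows=835)
print(f"feature table: {len(table)} rows x {len(table.feature_names)} predictors")
print("first columns:", table.feature_names[:4], "...")
print("categorical codebook:", {k: v[:4] for k, v in list(table.codebook.items())[:2]})
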