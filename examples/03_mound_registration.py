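"""Register mound coordinates to raster cells.

Mounds with GPS fall straight into cells; mounds mapped only in the
historical meter-based site frame are registered with a least-squares
similarity transform fitted on the mounds that carry both coordinate
systems (here 70 of 80), then assigned to cells.
"""

import numpy as np

from moundscape.geolink import assign_mounds, fit_local_to_map_transform
from moundscape.synthetic_data import SimConfig, simulate_study

config = SimConfig(
    seed=11, n_years=1, scenes_per_year=6, grid_shape=(40, 34),
    n_mounds=80, n_anchor_mounds=70, n_females_per_year=20, n_males_per_year=12,
)
study = simulate_study(config)

anchors = study.mounds.dropna(subset=["gps_x"])
tf, rms = fit_local_to_map_transform(
    anchors[["local_x", "local_y"]].to_numpy(),
    anchors[["gps_x", "gps_y"]].to_numpy(),
)
print(f"similarity transform from {len(anchors)} anchors:")
print(f"  rotation {np.rad2deg(tf.rotation_rad):.3f} deg, scale {tf.scale:.6f}, "
      f"translation ({tf.translation[0]:.1f}, {tf.translation[1]:.1f}) m")
print(f"  RMS residual {rms:.2e} m (coordinates are noiseless here; "
      "field data would show meters)")

assignments = assign_mounds(study.mounds, config.grid)
print("\nassignment sources:", assignments["source"].value_counts().to_dict())
truth = study.truth.mound_cells.set_index("mound_id")
hits = sum(
    (r.row, r.col) == (truth.loc[r.mound_id, "row"], truth.loc[r.mound_id, "col"])
    for r in assignments.itertuples(index=False)
)
print(f"cells matching generator truth: {hits}/{len(assignments)}")
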