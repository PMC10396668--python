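"""Generate a synthetic study, write it to disk, and ingest it back.

The generator emits Landsat-5-TM-like DN scenes (multiband TIFF + world
file), a scene catalog, mound/capture/pedigree tables and a daily climate
series.  The ingest side filters the catalog to one WRS path and a date
window, rescales DNs to physical units, and reports what it read.
"""

import tempfile
from datetime import date
from pathlib import Path

from moundscape.pipeline import ingest_scenes
from moundscape.synthetic_data import SimConfig, simulate_study, write_study

config = SimConfig(
    seed=42, n_years=2, scenes_per_year=8, grid_shape=(40, 34),
    n_mounds=80, n_anchor_mounds=70, n_females_per_year=20, n_males_per_year=12,
)
study = simulate_study(config)

out = Path(tempfile.mkdtemp()) / "simdata"
write_study(study, out)
print(f"wrote {len(study.scenes)} scenes + tables to {out}")

y0 = config.first_scene_year
scenes, catalog = ingest_scenes(
    out / "scenes",
    out / "catalog.csv",
    wrs_path=35,
    date_window=(date(y0, 7, 1), date(y0 + config.n_years, 7, 1)),
)
first = scenes[0]
b4 = first.bands["b4"]
st = first.bands["st"]
print(f"ingested {len(scenes)} path-35 scenes of {first.shape[0]}x{first.shape[1]} cells")
print(f"first scene {first.scene_id} ({first.acquisition_date}):")
print(f"  band 4 reflectance range [{b4.min():.3f}, {b4.max():.3f}]  (plausible: [-0.2, 1.6])")
print(f"  surface temperature range [{st.min():.1f}, {st.max():.1f}] degC")
# Reflectances are unitless fractions; surface temperature is the thermal
# band converted from DN with the published scale factor and offset.
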