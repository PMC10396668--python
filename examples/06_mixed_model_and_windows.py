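"""Repeated measures and rainy-season windows.

Females observed in several years get a random intercept (NB mixed model);
the fit honestly reports boundary/identifiability trouble, which is the
expected outcome when most females are observed only once.  Rainy-season
windows (summer: Jul-Aug; winter: Dec-Mar, lag-aligned) provide the
sub-annual covariates.
"""

from moundscape import demography
from moundscape.geolink import assign_mounds
from moundscape.inference import fit_nb_mixed
from moundscape.pipeline import COVARIATES, female_covariate_table
from moundscape.scene_io import scale_scene
from moundscape.spectral_indices import build_index_stacks, normalize_stacks
from moundscape.synthetic_data import SimConfig, simulate_study
from moundscape.temporal_agg import LagWindow

config = SimConfig(seed=13)
study = simulate_study(config)
stacks = normalize_stacks(build_index_stacks([scale_scene(s) for s in study.scenes]))
assignments = assign_mounds(study.mounds, config.grid)
fy = demography.build_female_years(study.pedigree, study.captures)
fy = fy[fy["year"].isin(config.response_years)]

w = LagWindow(response_year=2000, window_kind="winter_rainy", response_kind="offspring")
print(f"winter rainy window predicting year-2000 offspring: "
      f"{w.start_date} .. {w.end_date}")

summer = female_covariate_table(
    stacks, fy, assignments, config.grid, window_kind="summer_rainy"
)
print(f"\nsummer-rainy covariate table: {len(summer)} female-years; "
      f"brightness mean {summer['brightness'].mean():+.2f} z-units")

annual = female_covariate_table(stacks, fy, assignments, config.grid)
data = annual.dropna(subset=["n_offspring", *COVARIATES])
obs_per_female = data.groupby("female_id").size()
print(f"\n{int((obs_per_female == 1).sum())} of {len(obs_per_female)} females "
      "observed in only 1 year")

mixed = fit_nb_mixed(
    data["n_offspring"].astype(int), data[list(COVARIATES)],
    data["female_id"].to_numpy(),
)
print("NB mixed model (random intercept per female):")
print(f"  converged={mixed.converged}  singular={mixed.singular}  "
      f"random-intercept SD={mixed.re_sd:.3f}  theta={mixed.theta:.2f}")
print(mixed.params.round(4))
# The generator has no female-level heterogeneity beyond the covariates, so
# the random-intercept SD should collapse toward zero and be flagged singular.
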