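"""Synthetic study generator with known ground truth.

Emulates the structure of the real study system so every pipeline stage is
testable without downloads: a 70 x 92-cell 30 m grid holding 214 mounds
(188 with GPS, the rest only in a meter-based site frame related to the map
by a similarity transform); ~13 scene-years of Landsat-5-TM-like scenes
(13 per Jul-Jun year, ≈167-169 total) whose reflectance bands invert the
Collection 2 scale factors exactly; a seasonal sinusoidal surface
temperature field; strongly correlated brightness/wetness fields (target
Pearson r = 0.9) and a weak greenness signal; a daily climate series with
a bimodal rainy-season precipitation regime (July-August carrying ~50% of
the annual total); and a female population whose per-year offspring counts
are drawn from the log-link NB2 model the inference module assumes, with
offspring surviving to the next year by a logistic rule.

All randomness flows from one seed; the same seed reproduces every table
and scene bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import demography
from .geolink import SimilarityTransform, neighborhood3x3
from .scene_io import (
    DEFAULT_BAND_LAYOUT,
    GridGeometry,
    REFLECTANCE_OFFSET,
    REFLECTANCE_SCALE,
    SceneRaster,
    TEMPERATURE_OFFSET,
    TEMPERATURE_SCALE,
    write_scene,
)
from .spectral_indices import IndexStack, z_transform
from .tc_coefficients import TASSELED_CAP_INDICES, coefficient_matrix
from .temporal_agg import LagWindow, summarize_unit

__all__ = ["SimConfig", "GroundTruth", "SimulatedStudy", "simulate_study",
           "generate_climate", "write_study"]

_PEAK_DOY = 187  # early July: seasonal maximum of surface temperature


@dataclass
class SimConfig:
    """Study-scale defaults: 13 Jul-Jun scene-years starting July 1993,
    13 scenes/year, a 70-column x 92-row 30 m grid, 214 mounds (188 with
    GPS), ≈37 adult females/year (≈476 female-years over 13 years), NB
    offspring counts with true brightness and surface-temperature effects
    matching the magnitudes the individual-fitness models estimate."""

    seed: int = 0
    first_scene_year: int = 1993  # scenes start July 1 of this year
    n_years: int = 13             # response years: first_scene_year+1 ...
    scenes_per_year: int = 13
    grid_shape: tuple[int, int] = (92, 70)  # (rows, cols)
    cell_size: float = 30.0
    x_west: float = 663000.0
    y_north: float = 3500000.0
    n_mounds: int = 214
    n_anchor_mounds: int = 188
    n_females_per_year: int = 37
    n_males_per_year: int = 30
    adult_survival: float = 0.55
    intercept: float = -0.72
    true_beta: dict = field(
        default_factory=lambda: {
            "brightness": 0.36,
            "greenness": 0.0,
            "wetness": 0.0,
            "surface_temperature": 0.04,
        }
    )
    true_theta: float = 2.0
    frailty_sd: float = 0.0  # >0: lognormal frailty misspecification switch
    survival_logit: dict = field(default_factory=lambda: {"intercept": -0.4})
    temp_annual_mean: float = 20.0
    temp_annual_amplitude: float = 15.0
    temp_scene_anomaly_sd: float = 1.2
    temp_spatial_sd: float = 0.8
    temp_pixel_noise_sd: float = 0.3
    bw_correlation: float = 0.9
    capture_prob_adult: float = 1.0   # 0.98 mirrors the field protocol
    capture_prob_juvenile: float = 1.0  # 0.93 mirrors the field protocol
    n_path34_scenes: int = 0
    path34_bias: float = 0.06  # raw index offset for the per-path diagnostic
    annual_precip_mm: float = 350.0

    def __post_init__(self) -> None:
        if not (0 < abs(self.bw_correlation) < 1):
            raise ValueError("|bw_correlation| must be in (0, 1)")
        if self.true_theta <= 0:
            raise ValueError("true_theta must be positive")
        for name, val in [
            ("n_years", self.n_years), ("scenes_per_year", self.scenes_per_year),
            ("n_mounds", self.n_mounds), ("n_females_per_year", self.n_females_per_year),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_anchor_mounds > self.n_mounds:
            raise ValueError("n_anchor_mounds cannot exceed n_mounds")

    @property
    def response_years(self) -> list[int]:
        start = self.first_scene_year + 1
        return list(range(start, start + self.n_years))

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(
            x_west=self.x_west,
            y_north=self.y_north,
            cell_size=self.cell_size,
            n_rows=self.grid_shape[0],
            n_cols=self.grid_shape[1],
        )


@dataclass
class GroundTruth:
    """Realized truth of one simulated study."""

    true_beta: dict
    true_theta: float
    intercept: float
    transform: SimilarityTransform
    index_stacks: dict[str, IndexStack]          # z-scored TC + physical st
    female_covariates: pd.DataFrame              # per female-year covariates/eta/mu
    mound_cells: pd.DataFrame                    # mound_id, row, col
    living_by_year: dict[int, int]


@dataclass
class SimulatedStudy:
    config: SimConfig
    scenes: list[SceneRaster]      # DN scenes (unscaled)
    catalog: pd.DataFrame
    mounds: pd.DataFrame           # mound_id, gps_x, gps_y, local_x, local_y
    captures: pd.DataFrame
    pedigree: pd.DataFrame
    climate: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


def _smooth_field(rng, shape, sigma=3.0) -> np.ndarray:
    """Unit-variance zero-mean smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def _scene_dates(config: SimConfig) -> list[Date]:
    dates = []
    for k in range(config.n_years):
        start = Date(config.first_scene_year + k, 7, 1)
        for i in range(config.scenes_per_year):
            dates.append(start + timedelta(days=int(i * 364 / config.scenes_per_year)))
    return dates


def _seasonal(doy: float, amplitude: float) -> float:
    return amplitude * np.cos(2 * np.pi * (doy - _PEAK_DOY) / 365.25)


def _component_field(rng, shape, weights) -> "function":
    """Latent field factory: static spatial + per-scene scalar + pixel noise,
    with variance weights (w_seasonal, w_static, w_scene, w_pixel) summing
    to 1 so the pooled variance is ~1."""
    w_seas, w_stat, w_scene, w_pix = weights
    static = _smooth_field(rng, shape) * np.sqrt(w_stat)

    def draw(seasonal_std: float):
        return (
            np.sqrt(w_seas) * seasonal_std
            + static
            + np.sqrt(w_scene) * rng.standard_normal()
            + np.sqrt(w_pix) * rng.standard_normal(shape)
        )

    return draw


def _generate_scene_fields(config: SimConfig, rng) -> tuple[list[Date], dict[str, np.ndarray]]:
    """Raw (physical-unit, pre-DN) index fields per scene date.

    brightness/wetness share a common latent component so their pooled
    Pearson correlation targets ``bw_correlation``; greenness is a weak
    independent signal; surface temperature is an annual sinusoid plus a
    persistent spatial field and noise.
    """
    shape = config.grid_shape
    dates = _scene_dates(config)
    rho = config.bw_correlation

    common = _component_field(rng, shape, (0.25, 0.25, 0.16, 0.34))
    ind1 = _component_field(rng, shape, (0.0, 0.35, 0.2, 0.45))
    ind2 = _component_field(rng, shape, (0.0, 0.35, 0.2, 0.45))
    green = _component_field(rng, shape, (0.04, 0.2, 0.16, 0.6))
    temp_static = _smooth_field(rng, shape)

    b_list, g_list, w_list, t_list = [], [], [], []
    for d in dates:
        doy = d.timetuple().tm_yday
        seas = _seasonal(doy, 1.0) / np.sqrt(0.5)  # standardized seasonal
        c = common(seas)
        b_lat = np.sqrt(rho) * c + np.sqrt(1 - rho) * ind1(0.0)
        w_lat = np.sqrt(rho) * c + np.sqrt(1 - rho) * ind2(0.0)
        g_lat = green(-seas)  # greener in the cool season, weakly
        b_list.append(0.55 + 0.06 * b_lat)
        w_list.append(-0.10 + 0.05 * w_lat)
        g_list.append(0.18 + 0.02 * g_lat)
        t = (
            config.temp_annual_mean
            + _seasonal(doy, config.temp_annual_amplitude)
            + config.temp_scene_anomaly_sd * rng.standard_normal()
            + config.temp_spatial_sd * temp_static   # persistent microhabitat
            + config.temp_pixel_noise_sd * rng.standard_normal(shape)
        )
        t_list.append(t)
    return dates, {
        "brightness": np.stack(b_list),
        "greenness": np.stack(g_list),
        "wetness": np.stack(w_list),
        "surface_temperature": np.stack(t_list),
    }


def _fields_to_dn(raw: dict[str, np.ndarray]) -> np.ndarray:
    """Invert Tasseled Cap + physical scaling into quantized DN bands.

    Returns a (n_scenes, 7, H, W) float array of integer-valued DNs in the
    canonical band order; reflectance bands are the least-norm band vector
    reproducing the target index values, so the ingest path recovers the
    generator's fields to 1 DN of quantization.
    """
    C = coefficient_matrix()                     # (3, 6)
    pinv = np.linalg.pinv(C).astype(np.float32)  # (6, 3)
    tc = np.stack(
        [raw[i] for i in TASSELED_CAP_INDICES], axis=1, dtype=np.float32
    )  # (T, 3, H, W)
    refl = np.einsum("bi,tihw->tbhw", pinv, tc)  # (T, 6, H, W)
    refl -= np.float32(REFLECTANCE_OFFSET)
    refl /= np.float32(REFLECTANCE_SCALE)
    dn_refl = np.rint(refl)
    kelvin = raw["surface_temperature"].astype(np.float32) + np.float32(273.15)
    kelvin -= np.float32(TEMPERATURE_OFFSET)
    kelvin /= np.float32(TEMPERATURE_SCALE)
    dn_st = np.rint(kelvin)
    dn = np.concatenate([dn_refl, dn_st[:, None]], axis=1)
    if dn.min() < 1 or dn.max() > 65535:
        raise ValueError("simulated DNs escape the uint16 range; check config")
    return dn


def _dn_scene(
    config: SimConfig, scene_id: str, date: Date, path: int, dn_k: np.ndarray
) -> SceneRaster:
    bands = {
        b: np.ma.asarray(dn_k[i]) for i, b in enumerate(DEFAULT_BAND_LAYOUT)
    }
    return SceneRaster(
        scene_id=scene_id, acquisition_date=date, wrs_path=path, wrs_row=38,
        grid=config.grid, bands=bands, scaled=False,
    )


def _truth_stacks(dates, raw) -> dict[str, IndexStack]:
    """z-scored TC stacks + physical temperature stack from the raw fields."""
    stacks = {}
    for name in TASSELED_CAP_INDICES:
        stacks[name] = z_transform(
            IndexStack(index_name=name, dates=list(dates),
                       grids=np.ma.asarray(raw[name]))
        )
    stacks["surface_temperature"] = IndexStack(
        index_name="surface_temperature", dates=list(dates),
        grids=np.ma.asarray(raw["surface_temperature"]),
    )
    return stacks


# ---------------------------------------------------------------------------
# mounds & population
# ---------------------------------------------------------------------------

_TRUE_TRANSFORM = SimilarityTransform(
    scale=1.0, rotation_rad=np.deg2rad(12.0), translation=(663350.0, 3496900.0)
)


def _generate_mounds(config: SimConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    grid = config.grid
    nr, nc = config.grid_shape
    interior = [(r, c) for r in range(2, nr - 2) for c in range(2, nc - 2)]
    idx = rng.choice(len(interior), size=config.n_mounds, replace=False)
    cells = [interior[i] for i in idx]
    tf = _TRUE_TRANSFORM
    inv_R = np.linalg.inv(tf.matrix)
    rows = []
    cell_rows = []
    for m, (r, c) in enumerate(cells):
        mound_id = f"M{m + 1:03d}"
        cx, cy = grid.cell_center(r, c)
        # jitter inside the cell so points are not exactly on centers
        x = cx + rng.uniform(-12, 12)
        y = cy + rng.uniform(-12, 12)
        local = inv_R @ (np.array([x, y]) - np.asarray(tf.translation))
        has_gps = m < config.n_anchor_mounds
        rows.append(
            {
                "mound_id": mound_id,
                "gps_x": x if has_gps else np.nan,
                "gps_y": y if has_gps else np.nan,
                "local_x": local[0],
                "local_y": local[1],
            }
        )
        cell_rows.append({"mound_id": mound_id, "row": r, "col": c})
    return pd.DataFrame(rows), pd.DataFrame(cell_rows)


class _CovariateLookup:
    """Annual offspring-window covariates per (mound, year), memoized."""

    def __init__(self, stacks, mound_cells: pd.DataFrame, grid):
        self.stacks = stacks
        self.grid = grid
        self.cell_of = {
            str(r.mound_id): (int(r.row), int(r.col))
            for r in mound_cells.itertuples(index=False)
        }
        self._cache: dict[tuple[str, int], dict[str, float]] = {}

    def __call__(self, mound_id: str, year: int) -> dict[str, float]:
        key = (mound_id, year)
        if key not in self._cache:
            cells = neighborhood3x3(self.cell_of[mound_id], self.grid)
            window = LagWindow(response_year=year, window_kind="annual",
                              response_kind="offspring")
            self._cache[key] = summarize_unit(self.stacks, cells, window).values
        return self._cache[key]


def _simulate_population(config: SimConfig, rng, stacks, mound_cells, grid):
    """Forward-simulate females, males, offspring, captures and pedigree."""
    years = config.response_years
    covariates = _CovariateLookup(stacks, mound_cells, grid)
    mound_ids = mound_cells["mound_id"].tolist()
    free = set(mound_ids)
    next_f = next_m = next_k = 1

    def new_id(prefix):
        nonlocal next_f, next_m, next_k
        if prefix == "F":
            v, next_f = next_f, next_f + 1
        elif prefix == "M":
            v, next_m = next_m, next_m + 1
        else:
            v, next_k = next_k, next_k + 1
        return f"{prefix}{v:04d}"

    def claim_mound():
        m = sorted(free)[rng.integers(len(free))]
        free.discard(m)
        return m

    females: dict[str, str] = {}  # id -> mound
    males: dict[str, str] = {}
    for _ in range(config.n_females_per_year):
        females[new_id("F")] = claim_mound()
    for _ in range(config.n_males_per_year):
        males[new_id("M")] = claim_mound()

    captures, pedigree, cov_rows = [], [], []
    living_by_year: dict[int, int] = {}
    surviving_juveniles: list[tuple[str, str]] = []  # (id, sex) captured next year

    beta = config.true_beta
    for year in years:
        # survivors of last year's juveniles are captured (and settle) now
        for kid, sex in surviving_juveniles:
            m = claim_mound()
            if sex == "F":
                females[kid] = m
            else:
                males[kid] = m
            free.discard(m)
        surviving_juveniles = []
        n_adults = len(females) + len(males)

        # adult captures: two sessions per year
        for ind, mound, sex in (
            [(i, m, "F") for i, m in females.items()]
            + [(i, m, "M") for i, m in males.items()]
        ):
            for month, day in ((3, 15), (8, 15)):
                if rng.random() < config.capture_prob_adult:
                    captures.append(
                        (ind, sex, "adult", year, mound, Date(year, month, day))
                    )

        # reproduction: one NB draw per female from her home-range covariates
        for fid, mound in list(females.items()):
            cov = covariates(mound, year)
            eta = config.intercept + sum(
                beta.get(v, 0.0) * cov[v] for v in cov if not np.isnan(cov[v])
            )
            if config.frailty_sd > 0:
                eta += config.frailty_sd * rng.standard_normal()
            mu = float(np.exp(eta))
            th = config.true_theta
            n_off = int(rng.negative_binomial(th, th / (th + mu)))
            cov_rows.append(
                {"female_id": fid, "year": year, **cov, "eta": eta, "mu": mu,
                 "n_offspring": n_off}
            )
            p_surv = 1.0 / (1.0 + np.exp(-config.survival_logit["intercept"]))
            for _ in range(n_off):
                kid = new_id("K")
                sex = "F" if rng.random() < 0.5 else "M"
                pedigree.append((kid, fid, year))
                if rng.random() < config.capture_prob_juvenile:
                    captures.append(
                        (kid, sex, "juvenile", year, mound, Date(year, 9, 15))
                    )
                if rng.random() < p_surv:
                    surviving_juveniles.append((kid, sex))

        n_juveniles = sum(
            r["n_offspring"] for r in cov_rows if r["year"] == year
        )
        living_by_year[year] = n_adults + n_juveniles

        # adult turnover into next year
        for pool in (females, males):
            for ind in list(pool):
                if rng.random() > config.adult_survival:
                    free.add(pool.pop(ind))
        # top up toward a stochastic annual target (environmental variation
        # in recruitment), counting next year's settling survivors
        target_f = max(3, int(rng.poisson(config.n_females_per_year)))
        target_m = max(2, int(rng.poisson(config.n_males_per_year)))
        while len(females) + sum(
            1 for _, s in surviving_juveniles if s == "F"
        ) < target_f:
            females[new_id("F")] = claim_mound()
        while len(males) + sum(
            1 for _, s in surviving_juveniles if s == "M"
        ) < target_m:
            males[new_id("M")] = claim_mound()

    # capture surviving juveniles of the final year in year+1 so survival
    # counts are measurable for every response year
    final_plus = years[-1] + 1
    for kid, sex in surviving_juveniles:
        m = claim_mound()
        captures.append((kid, sex, "adult", final_plus, m, Date(final_plus, 3, 15)))

    captures_df = pd.DataFrame(
        captures,
        columns=["individual_id", "sex", "age_class", "year", "mound_id", "date"],
    )
    pedigree_df = pd.DataFrame(
        pedigree, columns=["offspring_id", "dam_id", "birth_year"]
    )
    cov_df = pd.DataFrame(cov_rows)
    return captures_df, pedigree_df, cov_df, living_by_year


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------


def generate_climate(config: SimConfig, rng=None) -> pd.DataFrame:
    """Daily climate series (date, precip, tmin, tmean, tmax).

    Bimodal precipitation: July-August carries ~50% of the annual total,
    December-March ~30%, the rest ~20%; sinusoidal temperatures with
    tmin <= tmean <= tmax by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    start = Date(config.first_scene_year, 7, 1)
    end = Date(config.first_scene_year + config.n_years + 1, 6, 30)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()

    annual = config.annual_precip_mm
    mean_day = np.full(len(dates), 0.2 * annual / 182.0)
    mean_day[np.isin(month, (7, 8))] = 0.5 * annual / 62.0
    mean_day[np.isin(month, (12, 1, 2, 3))] = 0.3 * annual / 121.0
    wet_prob = np.where(np.isin(month, (7, 8)), 0.6,
                        np.where(np.isin(month, (12, 1, 2, 3)), 0.35, 0.2))
    shape_p = 1.2
    scale = mean_day / (wet_prob * shape_p)
    wet = rng.random(len(dates)) < wet_prob
    precip = np.where(wet, rng.gamma(shape_p, scale), 0.0)

    tmean = (
        17.0
        + 10.0 * np.cos(2 * np.pi * (doy - _PEAK_DOY) / 365.25)
        + 1.5 * rng.standard_normal(len(dates))
    )
    spread_lo = 6.0 + np.abs(rng.standard_normal(len(dates)))
    spread_hi = 6.0 + np.abs(rng.standard_normal(len(dates)))
    return pd.DataFrame(
        {
            "date": dates.date,
            "precip": precip,
            "tmin": tmean - spread_lo,
            "tmean": tmean,
            "tmax": tmean + spread_hi,
        }
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Generate one complete synthetic study from a single seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    grid = config.grid

    dates, raw = _generate_scene_fields(config, rng)
    dn = _fields_to_dn(raw)
    scenes = []
    catalog_rows = []
    for k, d in enumerate(dates):
        sid = f"LT35_{d.isoformat().replace('-', '')}"
        scenes.append(_dn_scene(config, sid, d, 35, dn[k]))
        catalog_rows.append((sid, d, 35, 38, False, ""))
    if config.n_path34_scenes > 0:
        biased = {
            n: raw[n] + config.path34_bias for n in TASSELED_CAP_INDICES
        }
        biased["surface_temperature"] = raw["surface_temperature"] + 1.5
        dn34 = _fields_to_dn(biased)
        step = max(1, len(dates) // config.n_path34_scenes)
        for k in list(range(0, len(dates), step))[: config.n_path34_scenes]:
            d = dates[k] + timedelta(days=8)
            sid = f"LT34_{d.isoformat().replace('-', '')}"
            scenes.append(_dn_scene(config, sid, d, 34, dn34[k]))
            catalog_rows.append((sid, d, 34, 38, False, ""))
    catalog = pd.DataFrame(
        catalog_rows,
        columns=["scene_id", "date", "path", "row", "excluded", "reason"],
    )

    stacks = _truth_stacks(dates, raw)
    mounds, mound_cells = _generate_mounds(config, rng)
    captures, pedigree, cov_df, living = _simulate_population(
        config, rng, stacks, mound_cells, grid
    )
    climate = generate_climate(config, np.random.default_rng(config.seed + 7))

    truth = GroundTruth(
        true_beta=dict(config.true_beta),
        true_theta=config.true_theta,
        intercept=config.intercept,
        transform=_TRUE_TRANSFORM,
        index_stacks=stacks,
        female_covariates=cov_df,
        mound_cells=mound_cells,
        living_by_year=living,
    )
    return SimulatedStudy(
        config=config,
        scenes=scenes,
        catalog=catalog,
        mounds=mounds,
        captures=captures,
        pedigree=pedigree,
        climate=climate,
        truth=truth,
    )


def write_study(study: SimulatedStudy, out_dir) -> Path:
    """Emit the exact file formats the ingest side consumes, plus the
    ground truth as JSON."""
    out = Path(out_dir)
    (out / "scenes").mkdir(parents=True, exist_ok=True)
    for scene in study.scenes:
        write_scene(scene, out / "scenes")
    study.catalog.to_csv(out / "catalog.csv", index=False)
    study.mounds.to_csv(out / "mounds.csv", index=False)
    study.captures.to_csv(out / "captures.csv", index=False)
    study.pedigree.to_csv(out / "pedigree.csv", index=False)
    study.climate.to_csv(out / "climate.csv", index=False)
    truth = study.truth
    payload = {
        "seed": study.config.seed,
        "true_beta": truth.true_beta,
        "true_theta": truth.true_theta,
        "intercept": truth.intercept,
        "transform": {
            "scale": truth.transform.scale,
            "rotation_rad": truth.transform.rotation_rad,
            "translation": list(truth.transform.translation),
        },
        "living_by_year": {str(k): v for k, v in truth.living_by_year.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    truth.female_covariates.to_csv(out / "female_covariates_truth.csv", index=False)
    truth.mound_cells.to_csv(out / "mound_cells_truth.csv", index=False)
    return out
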