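"""Tasseled Cap transform, z-normalization and correlation summaries."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moundscape.scene_io import scale_scene
from moundscape.spectral_indices import (
    DegenerateStackError,
    IndexStack,
    UndefinedCorrelationError,
    build_index_stacks,
    pearson_correlation,
    scene_mean_series,
    tasseled_cap,
    z_transform,
)
from moundscape.tc_coefficients import (
    CRIST_1985_TM_REFLECTANCE,
    TM_BANDS,
    coefficient_matrix,
)

from conftest import make_scene


def brute_force_tasseled_cap(scene):
    """Independent per-cell dot-product oracle."""
    H, W = scene.shape
    out = {k: np.zeros((H, W)) for k in CRIST_1985_TM_REFLECTANCE}
    for r in range(H):
        for c in range(W):
            vec = [float(scene.bands[b][r, c]) for b in TM_BANDS]
            for name, coefs in CRIST_1985_TM_REFLECTANCE.items():
                out[name][r, c] = sum(x * w for x, w in zip(vec, coefs))
    return out


class TestCoefficients:
    def test_sign_structure(self):
        b = CRIST_1985_TM_REFLECTANCE["brightness"]
        g = CRIST_1985_TM_REFLECTANCE["greenness"]
        w = CRIST_1985_TM_REFLECTANCE["wetness"]
        assert all(c > 0 for c in b)
        # visible bands (b1-b3) negative, near-infrared (b4) positive
        assert all(c < 0 for c in g[:3]) and g[3] > 0
        # wetness contrasts SWIR (b5, b7) against the rest
        assert w[4] < 0 and w[5] < 0

    def test_matrix_layout(self):
        M = coefficient_matrix()
        assert M.shape == (3, 6)
        np.testing.assert_array_equal(M[0], CRIST_1985_TM_REFLECTANCE["brightness"])


class TestTasseledCap:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            scene = make_scene(rng, shape=(5, 5), scaled=False)
            scene = scale_scene(scene)
            tc = tasseled_cap(scene)
            oracle = brute_force_tasseled_cap(scene)
            for name in oracle:
                np.testing.assert_array_equal(np.ma.getdata(tc[name]), oracle[name])

    def test_zero_reflectance_gives_zero_indices(self, small_scene):
        for b in TM_BANDS:
            small_scene.bands[b] = np.ma.zeros(small_scene.shape)
        small_scene.scaled = True
        tc = tasseled_cap(small_scene)
        for name in tc:
            np.testing.assert_array_equal(np.ma.getdata(tc[name]), 0.0)

    def test_unit_reflectance_gives_coefficient_sums(self, small_scene):
        for b in TM_BANDS:
            small_scene.bands[b] = np.ma.ones(small_scene.shape)
        small_scene.scaled = True
        tc = tasseled_cap(small_scene)
        for name, coefs in CRIST_1985_TM_REFLECTANCE.items():
            assert float(tc[name][0, 0]) == pytest.approx(sum(coefs), abs=1e-12)

    def test_linearity_doubling(self, rng):
        scene = scale_scene(make_scene(rng, shape=(4, 4)))
        tc1 = tasseled_cap(scene)
        for b in TM_BANDS:
            scene.bands[b] = scene.bands[b] * 2.0
        tc2 = tasseled_cap(scene)
        for name in tc1:
            np.testing.assert_allclose(
                np.ma.getdata(tc2[name]), 2 * np.ma.getdata(tc1[name]), rtol=1e-12
            )

    def test_unscaled_scene_rejected(self, small_scene):
        with pytest.raises(ValueError, match="unscaled"):
            tasseled_cap(small_scene)

    def test_masked_cells_stay_masked(self, rng):
        scene = scale_scene(make_scene(rng, shape=(4, 4)))
        scene.bands["b3"][1, 2] = np.ma.masked
        tc = tasseled_cap(scene)
        assert tc["wetness"].mask[1, 2]


def _stack(values, name="brightness", start=date(2000, 1, 1)):
    grids = np.ma.asarray(np.asarray(values, dtype=float))
    dates = [start + timedelta(days=30 * i) for i in range(grids.shape[0])]
    return IndexStack(index_name=name, dates=dates, grids=grids)


class TestZTransform:
    def test_three_values_hand_computed(self):
        stack = _stack([[[1.0]], [[2.0]], [[3.0]]])
        z = z_transform(stack)
        np.testing.assert_allclose(
            np.ma.getdata(z.grids).ravel(), [-1.0, 0.0, 1.0], atol=1e-12
        )
        assert z.norm_mean == pytest.approx(2.0)
        assert z.norm_sd == pytest.approx(1.0)  # sample sd, n-1 denominator

    def test_pooled_moments_zero_one(self, rng):
        stack = _stack(rng.normal(5.0, 2.0, (12, 6, 7)))
        z = z_transform(stack)
        vals = z.grids.compressed()
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_invertible(self, rng):
        stack = _stack(rng.normal(0.4, 0.07, (5, 4, 4)))
        z = z_transform(stack)
        back = np.ma.getdata(z.grids) * z.norm_sd + z.norm_mean
        np.testing.assert_allclose(back, np.ma.getdata(stack.grids), atol=1e-12)

    def test_constant_stack_degenerate(self):
        with pytest.raises(DegenerateStackError):
            z_transform(_stack(np.full((3, 2, 2), 1.7)))

    def test_double_normalization_rejected(self, rng):
        z = z_transform(_stack(rng.normal(size=(3, 2, 2))))
        with pytest.raises(ValueError, match="already"):
            z_transform(z)

    def test_surface_temperature_never_normalized(self, rng):
        stack = _stack(rng.normal(20, 5, (3, 2, 2)), name="surface_temperature")
        with pytest.raises(ValueError, match="physical units"):
            z_transform(stack)


class TestPearson:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.normal(size=50)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 5) == pytest.approx(-1.0)

    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-10, 10))
    @settings(deadline=None, max_examples=30)
    def test_affine_gives_sign_of_slope(self, a, b):
        x = np.linspace(0, 1, 20)
        assert pearson_correlation(x, a * x + b) == pytest.approx(np.sign(a))

    def test_bivariate_normal_monte_carlo(self):
        rng = np.random.default_rng(99)
        n = 10_000
        z1, z2 = rng.standard_normal((2, n))
        x = z1
        y = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
        assert pearson_correlation(x, y) == pytest.approx(0.9, abs=0.02)

    def test_invariant_under_z_transform(self, rng):
        x = rng.normal(3, 2, 200)
        y = 0.5 * x + rng.normal(size=200)
        zx = (x - x.mean()) / x.std(ddof=1)
        assert pearson_correlation(zx, y) == pytest.approx(
            pearson_correlation(x, y), abs=1e-12
        )

    def test_pairwise_complete_masking(self, rng):
        x = np.ma.asarray(rng.normal(size=30))
        y = np.ma.asarray(0.7 * np.ma.getdata(x) + rng.normal(size=30) * 0.1)
        full = pearson_correlation(x, y)
        x[3] = np.ma.masked
        y[17] = np.ma.masked
        partial = pearson_correlation(x, y)
        ok = np.ones(30, bool); ok[[3, 17]] = False
        expected = np.corrcoef(np.ma.getdata(x)[ok], np.ma.getdata(y)[ok])[0, 1]
        assert partial == pytest.approx(expected, abs=1e-12)
        assert partial != full

    def test_degenerate_inputs(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1.0, 1.0, 1.0], [3.0, 4.0, 5.0])


class TestSceneMeanSeries:
    def test_single_cell(self, rng):
        stack = _stack(rng.normal(size=(3, 4, 4)))
        out = scene_mean_series({"brightness": stack}, [(2, 3)])
        assert len(out) == 3
        for k in range(3):
            assert out.loc[k, "mean"] == pytest.approx(float(stack.grids[k, 2, 3]))
            assert out.loc[k, "sd"] == 0.0

    def test_hand_computed_means(self):
        stack = _stack([[[1.0, 2.0], [3.0, 4.0]], [[10.0, 20.0], [30.0, 40.0]]])
        out = scene_mean_series({"brightness": stack}, [(0, 0), (0, 1), (1, 0)])
        assert out.loc[0, "mean"] == pytest.approx((1 + 2 + 3) / 3)
        assert out.loc[1, "mean"] == pytest.approx((10 + 20 + 30) / 3)

    def test_per_path_series_reveal_bias(self, rng):
        # the per-path diagnostic: a biased second path shows higher means
        from moundscape.scene_io import scale_scene as _ss
        from moundscape.spectral_indices import build_index_stacks
        from moundscape.synthetic_data import SimConfig, simulate_study

        cfg = SimConfig(
            seed=21, n_years=1, scenes_per_year=6, grid_shape=(20, 18),
            n_mounds=20, n_anchor_mounds=18, n_females_per_year=5,
            n_males_per_year=3, n_path34_scenes=4,
        )
        study = simulate_study(cfg)
        cells = [(r, c) for r in range(5, 8) for c in range(5, 8)]
        means = {}
        for path in (34, 35):
            scenes = [
                _ss(s) for s in study.scenes if s.wrs_path == path
            ]
            stacks = build_index_stacks(scenes)
            series = scene_mean_series(stacks, cells)
            means[path] = series.loc[
                series["index"] == "brightness", "mean"
            ].mean()
        assert means[34] > means[35]


def test_build_index_stacks_shapes(small_study):
    scaled = [scale_scene(s) for s in small_study.scenes]
    stacks = build_index_stacks(scaled)
    assert set(stacks) == {
        "brightness", "greenness", "wetness", "surface_temperature"
    }
    n = len(small_study.scenes)
    for s in stacks.values():
        assert s.grids.shape == (n, *small_study.config.grid_shape)
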