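import numpy as np
import pytest

import specgwas as sg
from specgwas.spectral import (default_registry, default_wavelength_grid,
                               index_resolvable, load_registry, save_registry)


@pytest.fixture
def grid():
    return default_wavelength_grid()  # 150 bands, 386-1021 nm


class TestNearestBand:
    def test_nominal_target(self, grid):
        b = sg.nearest_band(grid, 800.0)
        assert abs(grid[b] - 800.0) <= np.diff(grid).max() / 2

    def test_exact_grid_point(self, grid):
        assert sg.nearest_band(grid, grid[42]) == 42

    def test_tie_picks_lower_band(self):
        wl = np.array([400.0, 410.0])
        assert sg.nearest_band(wl, 405.0) == 0

    def test_out_of_range_raises(self, grid):
        with pytest.raises(ValueError, match="outside"):
            sg.nearest_band(grid, 1510.0)


class TestMaskAndMean:
    def test_constant_leaf(self):
        cube, _ = sg.simulate_cube(np.full(12, 0.4), (10, 10),
                                   background_value=0.0)
        vec = sg.mask_and_mean(cube, threshold=0.2, threshold_band_nm=800)
        np.testing.assert_allclose(vec, 0.4)

    def test_empty_foreground_names_threshold(self):
        cube, _ = sg.simulate_cube(np.full(12, 0.4), (10, 10))
        with pytest.raises(ValueError, match="0.5"):
            sg.mask_and_mean(cube, threshold=0.5, threshold_band_nm=800)

    def test_invariant_to_background_level(self):
        refl = np.linspace(0.3, 0.6, 10)
        a, _ = sg.simulate_cube(refl, (12, 12), background_value=0.0)
        b, _ = sg.simulate_cube(refl, (12, 12), background_value=0.15)
        va = sg.mask_and_mean(a, 0.25, 900)
        vb = sg.mask_and_mean(b, 0.25, 900)
        np.testing.assert_allclose(va, vb)

    def test_noisy_mean_within_sem(self):
        refl = np.full(15, 0.4)
        cube, mask = sg.simulate_cube(refl, (200, 200), leaf_shape=(100, 100),
                                      noise_sd=0.01, seed=3)
        vec = sg.mask_and_mean(cube, 0.2, 800)
        assert np.all(np.abs(vec - 0.4) < 4.5e-4)  # 3 sem with margin


def _table(values, wl=None):
    values = np.atleast_2d(values)
    if wl is None:
        wl = default_wavelength_grid(values.shape[1])
    return sg.SpectraTable(plot_ids=np.array([f"p{i}" for i in
                                              range(values.shape[0])]),
                           values=values, wavelengths_nm=wl)


def _one(table, name, registry=None):
    df = sg.compute_indices(table, registry)
    return df.iloc[0][name]


class TestComputeIndices:
    def test_required_indices_present_with_sources(self):
        names = {d.name for d in default_registry()}
        required = {"NDNI", "NPQI", "EVI", "Chlg", "CRI1", "CRI2", "CRI3",
                    "CRI4", "Datt6", "GMI1", "PARS", "SR3", "D2", "RDVI",
                    "RARSb", "NDVI", "SD"}
        assert required <= names
        assert len(names) >= 20
        assert all(d.source for d in default_registry())

    def test_sd_index_key_avoids_trait_collision(self):
        sd = [d for d in default_registry() if d.name == "SD"][0]
        assert sd.key == "SD_index"

    def test_ndvi_arithmetic(self):
        wl = np.array([680.0, 800.0])
        reg = [d for d in default_registry() if d.name == "NDVI"]
        val = _one(_table([[0.1, 0.5]], wl), "NDVI", reg)
        assert val == pytest.approx(0.6667, abs=1e-4)

    def test_cri1_zero_when_bands_equal(self):
        wl = np.array([510.0, 550.0])
        reg = [d for d in default_registry() if d.name == "CRI1"]
        assert _one(_table([[0.2, 0.2]], wl), "CRI1", reg) == pytest.approx(0.0)

    def test_npqi_boundary(self):
        wl = np.array([415.0, 435.0])
        reg = [d for d in default_registry() if d.name == "NPQI"]
        assert _one(_table([[0.0, 0.2]], wl), "NPQI", reg) == pytest.approx(-1.0)

    def test_normalized_difference_bounded(self, rng):
        table = _table(rng.uniform(0.01, 0.99, size=(40, 150)))
        reg = [d for d in default_registry()
               if d.name in ("NDVI", "GNDVI", "NPQI", "PRI")]
        df = sg.compute_indices(table, reg)
        assert (df.abs() <= 1.0 + 1e-12).all().all()

    def test_constant_spectrum_gives_zero_nd_indices(self):
        table = _table(np.full((1, 150), 0.3))
        reg = [d for d in default_registry()
               if d.name in ("NDVI", "GNDVI", "NPQI", "PRI")]
        df = sg.compute_indices(table, reg)
        np.testing.assert_allclose(df.to_numpy(), 0.0)

    def test_division_by_zero_yields_nan(self):
        wl = np.array([510.0, 550.0])
        reg = [d for d in default_registry() if d.name == "CRI1"]
        assert np.isnan(_one(_table([[0.0, 0.2]], wl), "CRI1", reg))

    def test_unresolvable_ndni_is_nan_on_camera_grid(self, grid):
        table = _table(np.full((2, 150), 0.4), grid)
        reg = [d for d in default_registry() if d.name == "NDNI"]
        assert not index_resolvable(reg[0], grid)
        df = sg.compute_indices(table, reg)
        assert df["NDNI"].isna().all()
        with pytest.raises(ValueError, match="NDNI"):
            sg.compute_indices(table, reg, on_unresolvable="error")

    def test_derivative_index_on_linear_spectrum(self, grid):
        # linear spectrum: derivative constant, so D2 = D705/D722 = 1
        table = _table(np.linspace(0.1, 0.9, 150), grid)
        reg = [d for d in default_registry() if d.name == "D2"]
        assert _one(table, "D2", reg) == pytest.approx(1.0)

    def test_registry_yaml_roundtrip(self, tmp_path):
        reg = default_registry()
        save_registry(reg, tmp_path / "reg.yaml")
        back = load_registry(tmp_path / "reg.yaml")
        assert [d.name for d in back] == [d.name for d in reg]
        assert [d.formula for d in back] == [d.formula for d in reg]

    def test_formula_must_declare_wavelengths(self):
        with pytest.raises(ValueError, match="not declared"):
            sg.IndexDefinition(name="bad", formula="R700 / R550",
                               required_wavelengths_nm=[700])
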