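import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import normal_equations_unmix
from msotvasc.unmixing import (
    ChromophoreMaps,
    ConfigurationError,
    ExtinctionTable,
    build_design_matrix,
    compute_so2,
    load_default_extinction_table,
    mean_so2,
    noise_floor_mask,
    unmix_pseudo_inverse,
)


class TestExtinctionTable:
    def test_bundled_table_valid(self, extinction_table):
        assert extinction_table.range_nm == (650.0, 900.0)
        assert np.all(extinction_table.eps_hb > 0)
        assert np.all(extinction_table.eps_hbo2 > 0)

    def test_crossing_sign_flips_between_760_and_850(self, extinction_table):
        rows = extinction_table.interpolate([760.0, 850.0])
        d760 = rows[0, 0] - rows[0, 1]  # eps_hb - eps_hbo2
        d850 = rows[1, 0] - rows[1, 1]
        assert np.sign(d760) != np.sign(d850)

    def test_isosbestic_near_800(self, extinction_table):
        iso = extinction_table.isosbestic_wavelength()
        assert 780 <= iso <= 820
        row = extinction_table.interpolate([iso])[0]
        assert abs(row[0] - row[1]) / row[0] < 0.05

    def test_positive_coefficients_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            ExtinctionTable(
                np.array([700.0, 800.0]),
                np.array([1.0, -1.0]),
                np.array([1.0, 1.0]),
            )


class TestDesignMatrix:
    def test_tabulated_wavelengths_verbatim(self, extinction_table):
        design = build_design_matrix(extinction_table, [700.0, 850.0])
        i700 = np.where(extinction_table.wavelengths == 700.0)[0][0]
        i850 = np.where(extinction_table.wavelengths == 850.0)[0][0]
        assert design[0, 0] == extinction_table.eps_hb[i700]
        assert design[0, 1] == extinction_table.eps_hbo2[i700]
        assert design[1, 0] == extinction_table.eps_hb[i850]
        assert design[1, 1] == extinction_table.eps_hbo2[i850]

    def test_midpoint_is_mean_of_bracketing_rows(self, extinction_table):
        design = build_design_matrix(extinction_table, [705.0, 800.0])
        rows = extinction_table.interpolate([700.0, 710.0])
        assert design[0] == pytest.approx(rows.mean(axis=0))

    def test_out_of_range_wavelength(self, extinction_table):
        with pytest.raises(ConfigurationError, match="outside"):
            build_design_matrix(extinction_table, [600.0, 800.0])

    def test_fewer_than_two_wavelengths(self, extinction_table):
        with pytest.raises(ConfigurationError, match="at least 2"):
            build_design_matrix(extinction_table, [800.0])
        with pytest.raises(ConfigurationError, match="at least 2"):
            build_design_matrix(extinction_table, [800.0, 800.0])

    def test_full_column_rank(self, extinction_table):
        design = build_design_matrix(
            extinction_table, [700, 730, 760, 800, 850]
        )
        assert np.linalg.matrix_rank(design) == 2


class TestUnmixPseudoInverse:
    @pytest.fixture()
    def design(self, extinction_table):
        return build_design_matrix(extinction_table, [700, 730, 760, 800, 850])

    def test_exact_forward_recovery(self, design):
        spectrum = design @ np.array([2.0, 3.0])
        data = np.broadcast_to(spectrum, (2, 2, 2, 5)).copy()
        maps = unmix_pseudo_inverse(data, design)
        assert maps.hb == pytest.approx(np.full((2, 2, 2), 2.0))
        assert maps.hbo2 == pytest.approx(np.full((2, 2, 2), 3.0))
        assert maps.residual == pytest.approx(np.zeros((2, 2, 2)), abs=1e-10)

    def test_zero_spectrum(self, design):
        maps = unmix_pseudo_inverse(np.zeros((1, 1, 1, 5)), design)
        assert maps.hb[0, 0, 0] == 0.0
        assert maps.hbo2[0, 0, 0] == 0.0
        assert maps.residual[0, 0, 0] == 0.0

    def test_orthogonal_perturbation_goes_to_residual(self, design):
        # perturbation in the orthogonal complement of the column space
        base = design @ np.array([1.0, 1.0])
        rng = np.random.default_rng(7)
        noise = rng.normal(size=5)
        proj = design @ np.linalg.pinv(design) @ noise
        perp = noise - proj
        maps = unmix_pseudo_inverse(
            (base + perp).reshape(1, 1, 1, 5), design
        )
        assert maps.hb[0, 0, 0] == pytest.approx(1.0)
        assert maps.hbo2[0, 0, 0] == pytest.approx(1.0)
        assert maps.residual[0, 0, 0] == pytest.approx(np.linalg.norm(perp))

    def test_oracle_equivalence_random_voxels(self, design):
        rng = np.random.default_rng(42)
        spectra = rng.normal(size=(1000, 5)) * 100
        maps = unmix_pseudo_inverse(spectra.reshape(10, 10, 10, 5), design)
        coeffs, resid = normal_equations_unmix(spectra, design)
        got = np.stack(
            [maps.hb.ravel(), maps.hbo2.ravel()], axis=1
        )
        assert np.allclose(got, coeffs, rtol=1e-8, atol=1e-12)
        assert np.allclose(maps.residual.ravel(), resid, rtol=1e-8, atol=1e-9)

    def test_rank_deficient_design_named_error(self):
        design = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(ValueError, match="collinear"):
            unmix_pseudo_inverse(np.zeros((1, 1, 1, 3)), design)

    def test_wavelength_count_mismatch(self, design):
        with pytest.raises(ValueError, match="wavelengths"):
            unmix_pseudo_inverse(np.zeros((1, 1, 1, 4)), design)

    def test_scale_invariance(self, design):
        rng = np.random.default_rng(3)
        data = np.abs(rng.normal(size=(3, 3, 3, 5))) * 50
        m1 = unmix_pseudo_inverse(data, design)
        m2 = unmix_pseudo_inverse(7.5 * data, design)
        assert m2.hb == pytest.approx(7.5 * m1.hb)
        assert m2.hbo2 == pytest.approx(7.5 * m1.hbo2)
        s1 = compute_so2(m1, noise_floor_mask(m1, 0.0))
        s2 = compute_so2(m2, noise_floor_mask(m2, 0.0))
        assert np.array_equal(s1.valid_mask, s2.valid_mask)
        assert s1.so2[s1.valid_mask] == pytest.approx(s2.so2[s2.valid_mask])

    def test_wavelength_order_invariance(self, design):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(4, 4, 4, 5)) * 10
        perm = np.array([3, 0, 4, 1, 2])
        m1 = unmix_pseudo_inverse(data, design)
        m2 = unmix_pseudo_inverse(data[..., perm], design[perm])
        assert m2.hb == pytest.approx(m1.hb)
        assert m2.hbo2 == pytest.approx(m1.hbo2)
        assert m2.residual == pytest.approx(m1.residual)


class TestNoiseFloorMask:
    def _maps(self, total):
        total = np.asarray(total, float)
        return ChromophoreMaps(
            hb=total / 2, hbo2=total / 2, residual=np.zeros_like(total)
        )

    def test_zero_floor_keeps_any_signal(self):
        maps = self._maps([[1e-9, 0.5, 0.0]])
        assert noise_floor_mask(maps, 0.0).tolist() == [[True, True, False]]

    def test_saturating_floor_empty_mask(self):
        maps = self._maps([[0.3, 0.5]])
        assert not noise_floor_mask(maps, 10.0).any()

    def test_negative_floor_rejected(self):
        with pytest.raises(ConfigurationError):
            noise_floor_mask(self._maps([[1.0]]), -0.1)

    def test_floor_between_background_and_vessel_recovers_truth(
        self, noiseless_phantom, extinction_table
    ):
        spec, cube, truth = noiseless_phantom
        design = build_design_matrix(extinction_table, cube.wavelengths)
        maps = unmix_pseudo_inverse(cube, design)
        mask = noise_floor_mask(maps, 0.5)  # between 0 (bg) and 1 (vessel)
        assert np.array_equal(mask, truth.vessel_mask)


class TestComputeSo2:
    def _maps(self, hb, hbo2):
        hb = np.asarray(hb, float)
        return ChromophoreMaps(
            hb=hb, hbo2=np.asarray(hbo2, float), residual=np.zeros_like(hb)
        )

    def test_symmetry_half(self):
        omap = compute_so2(self._maps([[2.0]], [[2.0]]))
        assert omap.so2[0, 0] == 0.5

    def test_pure_chromophore_limits(self):
        omap = compute_so2(self._maps([[0.0, 3.0]], [[3.0, 0.0]]))
        assert omap.so2[0, 0] == 1.0
        assert omap.so2[0, 1] == 0.0

    def test_direct_arithmetic(self):
        omap = compute_so2(self._maps([[1.0]], [[3.0]]))
        assert omap.so2[0, 0] == 0.75

    def test_negative_clamped_and_zero_total_invalidated(self):
        omap = compute_so2(self._maps([[-1.0, -2.0]], [[2.0, -3.0]]))
        assert omap.so2[0, 0] == 1.0  # hb clamped to 0
        assert not omap.valid_mask[0, 1]  # both clamped to 0 -> removed
        assert np.isnan(omap.so2[0, 1])

    def test_so2_bounded_where_valid(self):
        rng = np.random.default_rng(5)
        maps = self._maps(rng.normal(size=(50, 1)), rng.normal(size=(50, 1)))
        omap = compute_so2(maps)
        vals = omap.so2[omap.valid_mask]
        assert np.all((vals >= 0) & (vals <= 1))


class TestMeanSo2:
    def _omap(self, values, valid=None):
        values = np.asarray(values, float)
        maps = ChromophoreMaps(
            hb=1 - values, hbo2=values, residual=np.zeros_like(values)
        )
        return compute_so2(maps, valid)

    def test_constant_field(self):
        assert mean_so2(self._omap([[0.38, 0.38]])) == pytest.approx(0.38)

    def test_two_level_mean(self):
        omap = self._omap([[0.3, 0.3, 0.5, 0.5]])
        assert mean_so2(omap) == pytest.approx(0.4)

    def test_empty_mask_is_error(self):
        omap = self._omap([[0.4]], valid=np.array([[False]]))
        with pytest.raises(ValueError, match="no valid voxels"):
            mean_so2(omap)

    def test_noiseless_phantom_recovery(self, extinction_table):
        # single vessel at true sO2 = 0.373, depth-dependent fluence on
        from conftest import axial_vessel
        from msotvasc.core import VoxelGeometry
        from msotvasc.phantom import PhantomSpec, make_finger_phantom

        geom = VoxelGeometry(80, 50, (24, 24, 16))
        vessel = axial_vessel(geom, radius_mm=0.3, hb=0.627, hbo2=0.373)
        spec = PhantomSpec(
            geometry=geom, vessels=(vessel,), fluence_decay_per_mm=0.3,
        )
        cube, truth = make_finger_phantom(spec)
        design = build_design_matrix(extinction_table, cube.wavelengths)
        maps = unmix_pseudo_inverse(cube, design)
        omap = compute_so2(maps, noise_floor_mask(maps, 1e-9))
        assert mean_so2(omap) == pytest.approx(0.373, abs=1e-6)


@settings(max_examples=25, deadline=None)
@given(
    hb=st.floats(0.0, 10.0),
    hbo2=st.floats(0.0, 10.0),
    scale=st.floats(0.1, 100.0),
)
def test_forward_inverse_consistency_property(hb, hbo2, scale):
    """Unmixing any noiseless forward spectrum recovers the concentrations."""
    if hb + hbo2 == 0:
        return
    table = load_default_extinction_table()
    design = build_design_matrix(table, [700, 730, 760, 800, 850])
    spectrum = scale * (design @ np.array([hb, hbo2]))
    maps = unmix_pseudo_inverse(spectrum.reshape(1, 1, 1, 5), design)
    assert maps.hb[0, 0, 0] == pytest.approx(scale * hb, abs=1e-8)
    assert maps.hbo2[0, 0, 0] == pytest.approx(scale * hbo2, abs=1e-8)
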