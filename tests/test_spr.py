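"""Dual-energy path: EAN->I mapping, SPR volumes, mass-density estimation."""

import numpy as np
import pandas as pd
import pytest

import sprkit as sk
from sprkit.materials import ElementData, MaterialComposition


def fake_elements(*rows):
    return {r[0]: ElementData(*r) for r in rows}


class TestIvalueMappingFit:
    def test_two_tissues_single_segment_exact_interpolation(self, lib):
        two = [lib["adipose_tissue"], lib["muscle_skeletal"]]
        mapping = sk.fit_ivalue_mapping(two, lib.elements, boundaries=(), water_anchor=False)
        for t in two:
            z = sk.effective_atomic_number(t, lib.elements, 3.3)
            assert mapping(z) == pytest.approx(sk.i_value_bragg(t, lib.elements), rel=1e-9)

    def test_constant_ivalue_gives_zero_slope(self):
        # Two elements with different Z but identical I-values.
        els = fake_elements(("A", 6, 12.0, 100.0), ("B", 10, 20.0, 100.0))
        mats = [
            MaterialComposition("a", {"A": 1.0}, 1.0, "reference_human_tissue"),
            MaterialComposition("b", {"B": 1.0}, 1.0, "reference_human_tissue"),
        ]
        mapping = sk.fit_ivalue_mapping(mats, els, boundaries=(), water_anchor=False)
        (_, _, slope, intercept) = mapping.segments[0]
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert np.exp(intercept) == pytest.approx(100.0)

    def test_segment_with_too_few_tissues_errors(self, lib):
        with pytest.raises(ValueError, match="need at least 2"):
            sk.fit_ivalue_mapping(
                [lib["adipose_tissue"], lib["muscle_skeletal"]], lib.elements,
                boundaries=(8.0,),
            )

    def test_packaged_tissues_recovered_within_15_percent(self, lib, tissues, ivalue_mapping):
        for t in tissues:
            z = sk.effective_atomic_number(t, lib.elements, 3.3)
            i_true = sk.i_value_bragg(t, lib.elements)
            assert ivalue_mapping(z) == pytest.approx(i_true, rel=0.15)

    def test_continuity_at_interior_boundary(self, ivalue_mapping):
        below = ivalue_mapping(8.0 - 1e-9)
        above = ivalue_mapping(8.0 + 1e-9)
        assert below == pytest.approx(above, rel=1e-6)

    def test_water_anchor_pins_convention_value(self, lib, tissues):
        z_w = sk.effective_atomic_number(sk.WATER, lib.elements, 3.3)
        anchored = sk.fit_ivalue_mapping(tissues, lib.elements, water_anchor=True)
        free = sk.fit_ivalue_mapping(tissues, lib.elements, water_anchor=False)
        assert anchored(z_w) == pytest.approx(78.73, abs=1e-9)
        assert free(z_w) != pytest.approx(78.73, abs=1e-6)

    def test_clamping_outside_fitted_range(self, ivalue_mapping):
        z_min, z_max = ivalue_mapping.clamp_range
        assert ivalue_mapping(z_min - 2.0) == pytest.approx(ivalue_mapping(z_min))
        assert ivalue_mapping(z_max + 5.0) == pytest.approx(ivalue_mapping(z_max))


class TestExactMapping:
    def test_interpolates_materials_exactly(self, lib, surrogates):
        mapping = sk.exact_ivalue_mapping(surrogates, lib.elements)
        for m in surrogates:
            z = sk.effective_atomic_number(m, lib.elements, 3.3)
            assert mapping(z) == pytest.approx(sk.i_value_bragg(m, lib.elements), rel=1e-12)

    def test_conflicting_ivalues_at_same_zeff_raise(self):
        els = fake_elements(("A", 8, 16.0, 90.0), ("B", 8, 16.0, 120.0))
        mats = [
            MaterialComposition("a", {"A": 1.0}, 1.0, "water"),
            MaterialComposition("b", {"B": 1.0}, 1.0, "water"),
        ]
        with pytest.raises(ValueError, match="share Z_eff"):
            sk.exact_ivalue_mapping(mats, els)


class TestPredictSprVolume:
    def grids(self, ed_val, ean_val, shape=(4, 4, 4)):
        ed = sk.ImageVolume(np.full(shape, ed_val), (1, 1, 1), semantic="ED")
        ean = sk.ImageVolume(np.full(shape, ean_val), (1, 1, 1), semantic="EAN")
        return ed, ean

    def test_water_identity_voxelwise(self, lib, ivalue_mapping):
        z_w = sk.effective_atomic_number(sk.WATER, lib.elements, 3.3)
        ed, ean = self.grids(1.0, z_w)
        spr = sk.predict_spr_volume(ed, ean, ivalue_mapping)
        np.testing.assert_allclose(spr.values, 1.0, atol=1e-9)
        assert spr.semantic == "SPR"

    def test_doubling_ed_doubles_spr(self, lib, ivalue_mapping):
        ed1, ean = self.grids(0.9, 7.6)
        ed2 = ed1.with_values(ed1.values * 2)
        s1 = sk.predict_spr_volume(ed1, ean, ivalue_mapping)
        s2 = sk.predict_spr_volume(ed2, ean, ivalue_mapping)
        np.testing.assert_allclose(s2.values, 2 * s1.values, rtol=1e-12)

    def test_monotone_nonincreasing_in_ean_over_soft_segment(self, ivalue_mapping):
        zs = np.linspace(6.5, 7.9, 30)
        ed = sk.ImageVolume(np.ones((1, 1, 30)), (1, 1, 1), semantic="ED")
        ean = sk.ImageVolume(zs.reshape(1, 1, 30), (1, 1, 1), semantic="EAN")
        spr = sk.predict_spr_volume(ed, ean, ivalue_mapping).values.ravel()
        assert np.all(np.diff(spr) <= 1e-12)

    def test_air_voxels_assigned_air_spr(self, ivalue_mapping):
        ed, ean = self.grids(0.001, 7.5)
        spr = sk.predict_spr_volume(ed, ean, ivalue_mapping)
        np.testing.assert_allclose(spr.values, 1e-3)

    def test_grid_mismatch_raises_with_details(self, ivalue_mapping):
        ed = sk.ImageVolume(np.ones((4, 4, 4)), (1, 1, 1), semantic="ED")
        ean = sk.ImageVolume(np.ones((4, 4, 4)), (1, 1, 2), semantic="EAN")
        with pytest.raises(ValueError, match="do not match"):
            sk.predict_spr_volume(ed, ean, ivalue_mapping)

    def test_zero_noise_phantom_recovered_exactly(self, lib, sc_coarse):
        # End-to-end identity: self-consistent mapping returns truth SPR < 1e-6.
        labels, truth = sc_coarse
        ed, ean = sk.render_dlct(labels, truth)
        insert_mats = [lib[n] for n in truth[truth["is_insert"]]["name"]]
        mapping = sk.exact_ivalue_mapping(insert_mats, lib.elements)
        spr = sk.predict_spr_volume(ed, ean, mapping)
        rois = sk.extract_roi_means(spr, truth)
        ref = truth[truth["is_insert"]].set_index("name")["spr"]
        for _, row in rois.iterrows():
            assert abs(row["mean"] / ref[row["name"]] - 1.0) < 1e-6
            assert row["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_robustness_of_roi_means(self, lib, tissues, sc_coarse, ivalue_mapping):
        # Realistic channel noise: mean overall residual stays below 1% and no
        # insert exceeds 2% (the per-insert spread the method shows in practice).
        labels, truth = sc_coarse
        noise = sk.NoiseModel(sigma_ed=0.01, sigma_ean=0.1, seed=11)
        ed, ean = sk.render_dlct(labels, truth, noise)
        spr = sk.predict_spr_volume(ed, ean, ivalue_mapping)
        rois = sk.extract_roi_means(spr, truth)
        ref = truth[truth["is_insert"]].set_index("name")["spr"]
        residuals = np.array(
            [100 * (row["mean"] / ref[row["name"]] - 1.0) for _, row in rois.iterrows()]
        )
        assert np.mean(np.abs(residuals)) < 1.0
        assert np.max(np.abs(residuals)) < 2.0


class TestDeedz:
    def test_null_signal_gives_zero_coefficients(self):
        ref = pd.DataFrame(
            {"rho_e": np.linspace(0.9, 1.7, 10),
             "z_eff": np.linspace(6.5, 13.0, 10)}
        )
        ref["rho"] = ref["rho_e"]  # rho == rho_e exactly
        c = sk.fit_deedz(ref, z_eff_w=7.4776)
        assert abs(c.e0) < 1e-12 and abs(c.e1) < 1e-12 and abs(c.e2) < 1e-12

    def test_exact_inverse_problem_recovery(self):
        z_w = 7.477553548
        gen = (0.012, 0.051, 0.019)
        z = np.linspace(6.3, 13.6, 20)
        rho_e = np.linspace(0.9, 1.7, 20)
        x = (z / z_w) ** 3.3 - 1.0
        rho = rho_e * (1 + gen[0] + gen[1] * x + gen[2] * x**2)
        c = sk.fit_deedz(pd.DataFrame({"rho_e": rho_e, "z_eff": z, "rho": rho}), z_eff_w=z_w)
        assert c.e0 == pytest.approx(gen[0], abs=1e-8)
        assert c.e1 == pytest.approx(gen[1], abs=1e-8)
        assert c.e2 == pytest.approx(gen[2], abs=1e-8)

    def test_packaged_fit_is_small_near_water(self, lib, tissues):
        ref = sk.deedz_reference_frame(tissues, lib.elements)
        c = sk.fit_deedz(ref, elements=lib.elements)
        # near x = 0 the correction rho = rho_e (1 + e0) must be percent-level
        assert abs(c.e0) < 0.05

    def test_rank_deficient_design_errors(self):
        ref = pd.DataFrame({"rho_e": [1.0, 1.1, 1.2], "z_eff": [7.5, 7.5, 7.5],
                            "rho": [1.0, 1.1, 1.2]})
        with pytest.raises(ValueError, match="rank"):
            sk.fit_deedz(ref, z_eff_w=7.4776)

    def test_mass_density_volume_identity_cases(self):
        ed = sk.ImageVolume(np.full((3, 3, 3), 1.3), (1, 1, 1), semantic="ED")
        ean = sk.ImageVolume(np.full((3, 3, 3), 9.0), (1, 1, 1), semantic="EAN")
        c0 = sk.DeedzCoefficients(0.0, 0.0, 0.0, z_eff_w=7.4776)
        rho = sk.mass_density_volume(ed, ean, c0)
        np.testing.assert_allclose(rho.values, ed.values)
        assert rho.semantic == "MASS_DENSITY"
        # z_eff = z_eff_w with e0 = 0 keeps rho = rho_e regardless of e1, e2
        ean_w = ean.with_values(np.full((3, 3, 3), 7.4776))
        c = sk.DeedzCoefficients(0.0, 0.4, -0.2, z_eff_w=7.4776)
        np.testing.assert_allclose(
            sk.mass_density_volume(ed, ean_w, c).values, ed.values, rtol=1e-12
        )

    def test_volume_roundtrip_recovery(self, sc_coarse, lib):
        # Densities generated voxelwise from known coefficients come back 1e-6.
        labels, truth = sc_coarse
        ed, ean = sk.render_dlct(labels, truth)
        c = sk.DeedzCoefficients(0.01, 0.05, 0.02, z_eff_w=7.477553548)
        rho = sk.mass_density_volume(ed, ean, c)
        expected = c.density(ed.values, ean.values)
        np.testing.assert_allclose(rho.values, expected, rtol=1e-12)
        rois = sk.extract_roi_means(rho, truth)
        for _, row in truth[truth["is_insert"]].iterrows():
            want = c.density(row["rho_e"], row["z_eff"])
            got = rois.loc[rois["name"] == row["name"], "mean"].iloc[0]
            assert got == pytest.approx(want, rel=1e-6)

    def test_serialization_round_trip(self, tmp_path):
        c = sk.DeedzCoefficients(0.01, -0.02, 0.003, m=3.3, z_eff_w=7.4776)
        path = tmp_path / "deedz.json"
        c.to_json(path)
        back = sk.DeedzCoefficients.from_json(path)
        assert back == c
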