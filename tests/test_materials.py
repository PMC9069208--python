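"""Composition physics: electron density, EAN, I-values, Bethe SPR, tables."""

import math

import numpy as np
import pytest

import sprkit as sk
from sprkit.materials import (
    MaterialComposition,
    PhysicsConstants,
    electron_weighted_power_mean,
    load_material_tables,
    stopping_number,
)


def comp(name, fractions, rho, category="tissue_surrogate"):
    return MaterialComposition(name, fractions, rho, category)


class TestElectronDensity:
    def test_water_normalization_identity(self, lib):
        assert sk.electron_density(sk.WATER, lib.elements) == pytest.approx(1.0, abs=1e-12)

    def test_linear_in_bulk_density(self, lib):
        heavy = comp("heavy_water_like", {"H": 0.1119, "O": 0.8881}, 2.0, "water")
        assert sk.electron_density(heavy, lib.elements) == pytest.approx(2.0, abs=1e-12)
        for rho in (0.3, 0.75, 1.5):
            m = comp("x", {"H": 0.1119, "O": 0.8881}, rho, "water")
            assert sk.electron_density(m, lib.elements) == pytest.approx(rho, rel=1e-12)

    def test_pmma_matches_hand_evaluation(self, lib):
        # Independent spreadsheet-style evaluation of sum(w_i Z_i / A_i).
        assert lib.properties("pmma").rho_e == pytest.approx(1.1562496277, abs=1e-8)

    def test_unknown_element_named_in_error(self, lib):
        bad = comp("mystery", {"Xx": 1.0}, 1.0)
        with pytest.raises(KeyError, match="Xx"):
            sk.electron_density(bad, lib.elements)


class TestEffectiveAtomicNumber:
    @pytest.mark.parametrize("exponent", [1.0, 1.86, 3.3, 3.62])
    def test_single_element_returns_its_z(self, lib, exponent):
        al = comp("al", {"Al": 1.0}, 2.699, "implant")
        assert sk.effective_atomic_number(al, lib.elements, exponent) == pytest.approx(13.0)

    def test_water_at_default_exponent(self, lib):
        # Brute-force evaluation of the two-term power sum, frozen.
        z = sk.effective_atomic_number(sk.WATER, lib.elements, 3.3)
        assert z == pytest.approx(7.477553548, abs=1e-6)

    def test_equal_z_mixture_degenerates(self, lib):
        # Two equal-Z components (here: the same element at any split) give that Z.
        m = comp("graphite_mix", {"C": 1.0}, 1.8)
        assert sk.effective_atomic_number(m, lib.elements, 3.3) == pytest.approx(6.0)

    def test_power_mean_between_min_and_max_z(self, lib):
        z = sk.effective_atomic_number(lib["cortical_bone"], lib.elements, 3.3)
        assert 1.0 < z < 20.0

    def test_non_positive_exponent_rejected(self, lib):
        with pytest.raises(ValueError):
            electron_weighted_power_mean(sk.WATER, lib.elements, 0.0)


class TestIvalueBragg:
    def test_pure_element_returns_tabulated_value(self, lib):
        c = comp("carbon", {"C": 1.0}, 2.0)
        assert sk.i_value_bragg(c, lib.elements) == pytest.approx(lib.elements["C"].I_elem)

    def test_water_raw_table_matches_hand_evaluation(self, raw_lib):
        # Log-weighted mean of H (19.2 eV) and O (95.0 eV), hand-evaluated.
        assert sk.i_value_bragg(sk.WATER, raw_lib.elements) == pytest.approx(69.00, abs=0.01)

    def test_water_anchored_table_returns_convention_value(self, lib):
        assert sk.i_value_bragg(sk.WATER, lib.elements) == pytest.approx(78.73, abs=1e-9)

    def test_equal_constituent_ivalues_collapse(self, lib):
        # P and Si share I = 173 eV in the raw table; anchoring preserves equality.
        m = comp("psi", {"P": 0.5, "Si": 0.5}, 1.0)
        i = sk.i_value_bragg(m, lib.elements)
        assert i == pytest.approx(lib.elements["P"].I_elem)
        assert i == pytest.approx(lib.elements["Si"].I_elem)

    def test_mixture_between_constituent_extremes(self, lib):
        i = sk.i_value_bragg(lib["muscle"], lib.elements)
        vals = [lib.elements[s].I_elem for s in lib["muscle"].fractions]
        assert min(vals) < i < max(vals)


class TestBetaSquared:
    def test_matches_relativistic_hand_computation(self):
        # 1 - (938.272 / 1038.272)^2, evaluated independently.
        assert sk.beta_squared(100.0, 938.272) == pytest.approx(0.1833513881, abs=1e-9)

    def test_low_energy_limit_vanishes(self):
        assert sk.beta_squared(1e-6) < 1e-8

    def test_monotone_to_ultrarelativistic_limit(self):
        ts = np.logspace(0, 6, 30)
        b2 = np.array([sk.beta_squared(t) for t in ts])
        assert np.all(np.diff(b2) > 0)
        assert b2[-1] < 1.0
        assert b2[-1] > 0.999

    def test_non_positive_energy_rejected(self):
        with pytest.raises(ValueError):
            sk.beta_squared(0.0)


class TestBetheSpr:
    def test_water_identity_across_therapeutic_energies(self):
        for t in (1.0, 10.0, 70.0, 100.0, 200.0, 1000.0):
            c = PhysicsConstants(T_per_u=t)
            assert sk.bethe_spr(1.0, c.I_water, c) == pytest.approx(1.0, abs=1e-14)

    def test_linear_in_electron_density(self):
        assert sk.bethe_spr(2.0, 78.73) == pytest.approx(2.0, abs=1e-12)
        assert sk.bethe_spr(0.5, 70.0) == pytest.approx(0.5 * sk.bethe_spr(1.0, 70.0))

    def test_against_direct_two_term_evaluation(self):
        # Independent evaluation of both stopping numbers at I = 75 eV, 100 MeV/u.
        assert sk.bethe_spr(1.0, 75.0) == pytest.approx(1.0062273036, abs=1e-9)

    def test_strictly_decreasing_in_ivalue(self):
        ivals = np.linspace(60.0, 120.0, 20)
        spr = sk.bethe_spr(np.ones_like(ivals), ivals)
        assert np.all(np.diff(spr) < 0)

    def test_unphysically_large_ivalue_raises_not_nan(self):
        with pytest.raises(ValueError, match="stopping number"):
            sk.bethe_spr(1.0, 1e9, PhysicsConstants(T_per_u=1.0))

    def test_energy_insensitivity_of_packaged_materials(self, lib, surrogates, tissues):
        # The working-energy choice barely matters in the therapeutic range.
        for m in surrogates + tissues:
            rho_e = sk.electron_density(m, lib.elements)
            i_val = sk.i_value_bragg(m, lib.elements)
            s70 = sk.bethe_spr(rho_e, i_val, PhysicsConstants(T_per_u=70.0))
            s100 = sk.bethe_spr(rho_e, i_val, PhysicsConstants(T_per_u=100.0))
            s200 = sk.bethe_spr(rho_e, i_val, PhysicsConstants(T_per_u=200.0))
            assert abs(s70 - s200) / s100 < 0.01

    def test_stopping_number_positive_at_working_energy(self, lib, surrogates):
        for m in surrogates:
            assert stopping_number(sk.i_value_bragg(m, lib.elements)) > 0


class TestBetheProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=60)
    @given(
        rho_e=st.floats(0.01, 3.0),
        i_value=st.floats(30.0, 300.0),
        factor=st.floats(0.1, 5.0),
    )
    def test_spr_scales_linearly_with_electron_density(self, rho_e, i_value, factor):
        base = sk.bethe_spr(rho_e, i_value)
        assert sk.bethe_spr(factor * rho_e, i_value) == pytest.approx(
            factor * base, rel=1e-12
        )

    @settings(derandomize=True, max_examples=60)
    @given(i_low=st.floats(30.0, 299.0), delta=st.floats(0.5, 100.0))
    def test_spr_monotone_decreasing_in_ivalue(self, i_low, delta):
        assert sk.bethe_spr(1.0, i_low) > sk.bethe_spr(1.0, i_low + delta)

    @settings(derandomize=True, max_examples=40)
    @given(rho=st.floats(0.05, 5.0))
    def test_electron_density_linear_in_rho(self, lib, rho):
        m = MaterialComposition("w", {"H": 0.1119, "O": 0.8881}, rho, "water")
        assert sk.electron_density(m, lib.elements) == pytest.approx(rho, rel=1e-12)


class TestMaterialTables:
    def test_packaged_census(self, lib):
        assert len(lib.by_category("tissue_surrogate")) == 13
        assert len(lib.by_category("implant")) == 8
        assert len(lib.by_category("reference_human_tissue")) >= 20
        for name in ("water", "air", "pmma"):
            assert name in lib.materials

    def test_fraction_sum_validation(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "name,category,rho_g_cm3,element,fraction\n"
            "halfwater,water,1.0,H,0.1\nhalfwater,water,1.0,O,0.8\n"
        )
        with pytest.raises(ValueError, match="halfwater"):
            load_material_tables(materials_path=bad)

    def test_duplicate_element_row_rejected(self, tmp_path):
        bad = tmp_path / "dup.csv"
        bad.write_text(
            "name,category,rho_g_cm3,element,fraction\n"
            "m,water,1.0,H,0.5\nm,water,1.0,H,0.5\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_material_tables(materials_path=bad)

    def test_all_materials_resolvable_and_physical(self, lib):
        for name in lib.materials:
            p = lib.properties(name)
            assert p.i_value > 0
            if lib[name].category != "air":
                assert p.rho_e > 0 and p.spr > 0

    def test_composition_invariants_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            MaterialComposition("m", {"H": 0.6, "O": 0.6}, 1.0, "water")
        with pytest.raises(ValueError, match="category"):
            MaterialComposition("m", {"H": 1.0}, 1.0, "mystery_goo")
        with pytest.raises(ValueError, match="empty"):
            MaterialComposition("m", {}, 1.0, "water")
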