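"""Unit tests for the theoretical ion grid and assignment rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligoms.constants import C13_C12_DELTA, H_MASS_MONO, PROTON_MASS
from oligoms.ion_grid import (
    OligomerIon,
    PeptideSpecies,
    assign_peaks,
    build_grid,
    composition_from_sequence,
    grid_to_frame,
    infer_charge,
    isotope_pattern,
    oligomer_mass,
    oligomer_mz,
    spacing_resolvable,
)


class TestComposition:
    def test_glycine_composition(self):
        # free glycine: C2H5NO2
        assert composition_from_sequence("G") == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_composition_is_additive_plus_water(self):
        gg = composition_from_sequence("GG")
        g = composition_from_sequence("G")
        # condensation removes one water per bond
        assert gg["C"] == 2 * g["C"]
        assert gg["H"] == 2 * g["H"] - 2
        assert gg["O"] == 2 * g["O"] - 1

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            composition_from_sequence("GGXG")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_from_sequence("")


class TestSpeciesMasses:
    def test_abeta40_monoisotopic_mass(self, abeta40):
        # canonical value for DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV
        assert abeta40.mono_mass == pytest.approx(4327.148, abs=0.01)

    def test_abeta40_average_mass(self, abeta40):
        assert abeta40.avg_mass == pytest.approx(4329.8, abs=0.1)

    def test_mono_below_average(self, abeta40, abeta42):
        assert abeta40.mono_mass < abeta40.avg_mass
        assert abeta42.mono_mass < abeta42.avg_mass

    def test_abeta42_heavier_by_ile_ala(self, abeta40, abeta42):
        # residue masses of I (113.084) + A (71.037)
        assert abeta42.mono_mass - abeta40.mono_mass == pytest.approx(
            184.121, abs=0.01
        )


class TestOligomerMass:
    def test_noncovalent_mass_is_n_times_monomer(self, abeta40):
        for n in range(1, 7):
            assert oligomer_mass(abeta40, n) == pytest.approx(
                n * abeta40.mono_mass, rel=1e-12
            )

    def test_crosslink_removes_two_h_per_bond(self, abeta40):
        for n in range(2, 7):
            delta = oligomer_mass(abeta40, n) - oligomer_mass(
                abeta40, n, crosslinked=True, n_bonds=n - 1
            )
            assert delta == pytest.approx(2 * (n - 1) * H_MASS_MONO, rel=1e-12)

    def test_extra_bonds_allowed_beyond_minimal(self, abeta40):
        ring = oligomer_mass(abeta40, 3, crosslinked=True, n_bonds=3)
        chain = oligomer_mass(abeta40, 3, crosslinked=True, n_bonds=2)
        assert chain - ring == pytest.approx(2 * H_MASS_MONO, rel=1e-12)

    def test_underconnected_crosslink_rejected(self, abeta40):
        with pytest.raises(ValueError, match="n-1 bonds"):
            oligomer_mass(abeta40, 3, crosslinked=True, n_bonds=1)

    def test_bonds_without_crosslink_rejected(self, abeta40):
        with pytest.raises(ValueError):
            oligomer_mass(abeta40, 2, n_bonds=1)

    def test_bad_mass_basis_rejected(self, abeta40):
        with pytest.raises(ValueError, match="mass_basis"):
            oligomer_mass(abeta40, 1, mass_basis="nominal")


class TestOligomerMz:
    def test_protonation_convention(self, abeta40):
        mz = oligomer_mz(abeta40, 1, 3)
        assert mz == pytest.approx(
            (abeta40.mono_mass + 3 * PROTON_MASS) / 3, rel=1e-12
        )

    def test_nz_degeneracy_exact_on_mono_basis(self, abeta40):
        # equal n/z => identical m/z for non-covalent oligomers
        ref = oligomer_mz(abeta40, 1, 2)
        for n, z in [(2, 4), (3, 6), (4, 8)]:
            assert oligomer_mz(abeta40, n, z) == pytest.approx(ref, rel=1e-12)

    def test_charge_must_be_positive(self, abeta40):
        with pytest.raises(ValueError):
            oligomer_mz(abeta40, 1, 0)


class TestOligomerIon:
    def test_create_fills_derived_fields(self, abeta40):
        ion = OligomerIon.create(abeta40, 2, 5)
        assert ion.mz_mono == pytest.approx(oligomer_mz(abeta40, 2, 5))
        assert ion.isotope_spacing == pytest.approx(C13_C12_DELTA / 5)
        assert ion.label == "Abeta40:D+5"

    def test_crosslinked_default_minimal_bonds(self, abeta40):
        ion = OligomerIon.create(abeta40, 4, 6, crosslinked=True)
        assert ion.n_bonds == 3

    def test_species_key_ignores_charge(self, abeta40):
        a = OligomerIon.create(abeta40, 2, 4)
        b = OligomerIon.create(abeta40, 2, 5)
        assert a.species_key == b.species_key


class TestGrid:
    def test_grid_size(self, abeta40):
        ions = build_grid(abeta40, max_order=6, charge_range=(1, 10))
        assert len(ions) == 60

    def test_grid_frame_columns(self, abeta40):
        df = grid_to_frame(build_grid(abeta40, max_order=2, charge_range=(1, 3)))
        assert set(df.columns) >= {"species", "n", "z", "mz_mono", "spacing"}
        assert len(df) == 6

    def test_crosslinked_grid_keeps_monomer_free(self, abeta40):
        ions = build_grid(abeta40, max_order=3, charge_range=(2, 2),
                          crosslinked=True)
        by_n = {i.order_n: i for i in ions}
        assert not by_n[1].crosslinked
        assert by_n[2].crosslinked and by_n[2].n_bonds == 1

    def test_multiple_species(self, abeta40, abeta42):
        ions = build_grid([abeta40, abeta42], max_order=1, charge_range=(1, 2))
        assert {i.species.id for i in ions} == {"Abeta40", "Abeta42"}


class TestIsotopePattern:
    def test_pattern_spacing_and_monotone_mz(self, abeta40):
        pat = isotope_pattern(abeta40.composition, charge_z=3)
        mzs = [p[0] for p in pat]
        diffs = np.diff(mzs)
        assert np.allclose(diffs, C13_C12_DELTA / 3, atol=1e-9)

    def test_base_peak_normalised_to_one(self, abeta40):
        pat = isotope_pattern(abeta40.composition)
        assert max(a for _, a in pat) == pytest.approx(1.0)

    def test_first_peak_is_monoisotopic(self, abeta40):
        pat = isotope_pattern(abeta40.composition, charge_z=2)
        assert pat[0][0] == pytest.approx(
            (abeta40.mono_mass + 2 * PROTON_MASS) / 2, abs=1e-6
        )

    def test_small_molecule_matches_binomial(self):
        # C10: P(k) follows Binomial(10, p13C)
        pat = isotope_pattern({"C": 10})
        rel = pat[1][1] / pat[0][1]
        p13 = 0.0107 / (1 - 0.0107)
        assert rel == pytest.approx(10 * p13, rel=0.02)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern({})

    def test_tail_truncated(self, abeta40):
        pat = isotope_pattern(abeta40.composition, min_abundance=1e-4)
        assert all(a >= 1e-4 for _, a in pat)


class TestSpacingResolvable:
    def test_threshold_behaviour(self):
        # spacing 1.003355/5 ~ 0.2007; peak width mz/R
        assert spacing_resolvable(2000.0, 5, 10000.0)
        assert not spacing_resolvable(2000.0, 5, 9000.0)


class TestInferCharge:
    def test_exact_spacings(self):
        for z in range(1, 21):
            assert infer_charge(C13_C12_DELTA / z) == z

    def test_implausible_spacing_rejected(self):
        # halfway between z=1 and z=2
        assert infer_charge(C13_C12_DELTA / 1.5) is None

    def test_nonpositive_spacing_rejected(self):
        assert infer_charge(0.0) is None
        assert infer_charge(-0.1) is None


class TestAssignPeaks:
    def test_spacing_rule_resolves_degenerate_channel(self, abeta40):
        grid = build_grid(abeta40, max_order=4, charge_range=(1, 10))
        mz = oligomer_mz(abeta40, 2, 4)  # degenerate with M+2, Tr+6, Te+8
        [a] = assign_peaks([(mz, 1.0, C13_C12_DELTA / 4)], grid)
        assert a.rule_used == "isotope_spacing"
        assert (a.accepted.order_n, a.accepted.charge_z) == (2, 4)

    def test_consecutive_charge_state_fallback(self, abeta40):
        grid = build_grid(abeta40, max_order=2, charge_range=(1, 10))
        peaks = [
            (oligomer_mz(abeta40, 2, 5), 1.0, None),
            (oligomer_mz(abeta40, 2, 6), 1.0, None),
        ]
        out = assign_peaks(peaks, grid)
        assert all(a.rule_used == "consecutive_charge_states" for a in out)
        assert {a.accepted.charge_z for a in out} == {5, 6}

    def test_single_charge_state_without_spacing_unassigned(self, abeta40):
        grid = build_grid(abeta40, max_order=2, charge_range=(1, 10))
        # D+5 alone, no spacing, no corroborating charge state
        [a] = assign_peaks([(oligomer_mz(abeta40, 2, 5), 1.0, None)], grid)
        assert a.accepted is None
        assert a.rule_used == "unassigned"

    def test_implausible_spacing_warns_and_falls_back(self, abeta40):
        grid = build_grid(abeta40, max_order=2, charge_range=(1, 10))
        mz = oligomer_mz(abeta40, 2, 5)
        # spacing 0.4 Th implies z ~ 2.5: no integer charge within the
        # plausibility window
        with pytest.warns(UserWarning, match="non-integer charge"):
            [a] = assign_peaks([(mz, 1.0, 0.4)], grid)
        assert a.accepted is None

    def test_candidates_listed_for_degenerate_peak(self, abeta40):
        grid = build_grid(abeta40, max_order=4, charge_range=(1, 10))
        mz = oligomer_mz(abeta40, 1, 2)
        [a] = assign_peaks([(mz, 1.0, None)], grid)
        pairs = {(c.order_n, c.charge_z) for c in a.candidates}
        assert {(1, 2), (2, 4), (3, 6), (4, 8)} <= pairs

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            assign_peaks([(1000.0, 1.0)], [])

    def test_nonmatching_peak_unassigned(self, abeta40):
        grid = build_grid(abeta40, max_order=2, charge_range=(1, 10))
        [a] = assign_peaks([(1234.5, 1.0, None)], grid)
        assert a.candidates == [] and a.accepted is None


@settings(max_examples=50, deadline=None, derandomize=True)
@given(n=st.integers(1, 8), z=st.integers(1, 12))
def test_mz_formula_property(n, z):
    sp = PeptideSpecies.from_sequence("pep", "GAVLIK")
    mz = oligomer_mz(sp, n, z)
    assert mz == pytest.approx((n * sp.mono_mass + z * PROTON_MASS) / z,
                               rel=1e-12)
    assert math.isfinite(mz) and mz > 0
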