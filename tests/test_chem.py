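"""Mass table, formula arithmetic, adducts, label shifts."""

import csv
from importlib import resources

import pytest
from hypothesis import given, strategies as st

from tracerscreen.chem import (
    ADDUCTS,
    DEUTERIUM_COMPUTED,
    DEUTERIUM_PRINTED,
    MONOISOTOPIC_MASS,
    SULFUR34,
    LabelShiftSpec,
    MolecularFormula,
    UnsupportedElementError,
    adduct_mz,
    label_delta,
    monoisotopic_mass,
    neutral_mass_from_mz,
    ppm_error,
)


class TestMonoisotopicMass:
    def test_water(self):
        # frozen from the embedded H and O monoisotopic masses
        assert monoisotopic_mass("H2O") == pytest.approx(18.010565, abs=1e-6)

    def test_gsh_deprotonated_matches_measured(self):
        mz = adduct_mz("C10H17N3O6S", "[M-H]-")
        assert ppm_error(mz, 306.0759, 306.0759) < 5

    def test_additivity(self):
        f1 = MolecularFormula.parse("C6H12O6")
        f2 = MolecularFormula.parse("C3H7NO2S")
        assert monoisotopic_mass(f1 + f2) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
        )

    def test_empty_formula_rejected(self):
        with pytest.raises(ValueError):
            MolecularFormula({})
        with pytest.raises(ValueError):
            MolecularFormula.parse("")

    def test_unsupported_element_named(self):
        with pytest.raises(UnsupportedElementError, match="Xe"):
            MolecularFormula.parse("C2Xe")

    def test_label_symbols(self):
        d5 = MolecularFormula.parse("C6H6D5NOS2")
        same = MolecularFormula.parse("C6H6[2H]5NOS2")
        assert d5.element_counts == same.element_counts
        shift = monoisotopic_mass(d5) - monoisotopic_mass("C6H11NOS2")
        assert shift == pytest.approx(5 * (MONOISOTOPIC_MASS["2H"] - MONOISOTOPIC_MASS["H"]))


class TestAdducts:
    @pytest.mark.parametrize("formula,adduct,printed", [
        ("C16H28N4O7S3", "[M+H]+", 485.1184),   # SFN-GSH
        ("C14H25N3O6S3", "[M+H]+", 428.0979),   # SFN-gammaEC
        ("C9H18N2O3S3", "[M+H]+", 299.0555),    # SFN-Cys
        ("C5H13NOS", "[M+H]+", 136.0797),       # 4MSB amine
        ("C4H5NO2S2", "[M-H]-", 161.9683),      # raphanusamic acid
        ("C10H17N3O6S", "[M-H]-", 306.0759),    # glutathione
    ])
    def test_theoretical_matches_measured_within_5ppm(self, formula, adduct, printed):
        assert ppm_error(adduct_mz(formula, adduct), printed, printed) <= 5

    def test_unknown_adduct(self):
        with pytest.raises(KeyError):
            adduct_mz("H2O", "[M+Na]+")

    @given(
        mass_formula=st.sampled_from(["H2O", "C10H17N3O6S", "C16H28N4O7S3", "C4H5NO2S2"]),
        adduct=st.sampled_from(sorted(ADDUCTS)),
    )
    def test_roundtrip_inversion(self, mass_formula, adduct):
        mz = adduct_mz(mass_formula, adduct)
        assert neutral_mass_from_mz(mz, adduct) == pytest.approx(
            monoisotopic_mass(mass_formula), abs=1e-9
        )

    def test_dimer(self):
        m = monoisotopic_mass("C10H17N3O6S")
        assert adduct_mz("C10H17N3O6S", "[2M+H]+") == pytest.approx(
            2 * m + 1.00727646, abs=1e-6
        )


class TestLabelDelta:
    def test_printed_table(self):
        assert label_delta(DEUTERIUM_PRINTED, 2) == 2.0126
        assert label_delta(DEUTERIUM_PRINTED, 3) == 3.0189
        assert label_delta(DEUTERIUM_PRINTED, 5) == 5.0314
        assert label_delta(DEUTERIUM_PRINTED, 10) == 10.0628

    def test_computed_five_deuteriums(self):
        per = MONOISOTOPIC_MASS["2H"] - MONOISOTOPIC_MASS["H"]
        assert label_delta(DEUTERIUM_COMPUTED, 5) == pytest.approx(5 * per)
        assert label_delta(DEUTERIUM_COMPUTED, 5) == pytest.approx(5.03138, abs=1e-5)

    def test_sulfur34_double_label_is_plus4(self):
        delta = label_delta(SULFUR34, 2)
        assert delta == pytest.approx(3.99159, abs=1e-5)
        assert round(delta) == 4

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_printed_and_computed_agree_within_20ppm_at_mz300(self, n):
        printed = label_delta(DEUTERIUM_PRINTED, n)
        computed = label_delta(DEUTERIUM_COMPUTED, n)
        assert ppm_error(printed, computed, 300.0) <= 20

    def test_disallowed_count(self):
        with pytest.raises(ValueError):
            label_delta(DEUTERIUM_PRINTED, 4)

    def test_printed_values_sanity_bound(self):
        with pytest.raises(ValueError):
            LabelShiftSpec("2H", per_atom_delta=1.00628, allowed_counts={2},
                           printed_deltas={2: 2.10})


class TestPpmError:
    @pytest.mark.parametrize("obs,exp,ref,want", [
        (5.0314, 5.0314, 500.0, 0.0),
        (5.0414, 5.0314, 500.0, 20.0),
    ])
    def test_forced_arithmetic(self, obs, exp, ref, want):
        assert ppm_error(obs, exp, ref) == pytest.approx(want, abs=1e-9)

    def test_small_error_on_is_mz(self):
        assert ppm_error(2.0125, 2.0126, 235.1805) < 1

    def test_requires_positive_reference(self):
        with pytest.raises(ValueError):
            ppm_error(1.0, 1.0, 0.0)


def test_bundled_library_matches_printed_mz_within_5ppm():
    """Every compound with a recorded measured m/z is explained by its
    formula's precursor adduct to instrument accuracy."""
    ref = resources.files("tracerscreen.data") / "compounds.csv"
    with ref.open() as fh:
        rows = [r for r in csv.DictReader(fh) if r["printed_mz"]]
    assert len(rows) == 6
    for row in rows:
        mz = adduct_mz(row["formula"], row["printed_adduct"])
        assert ppm_error(mz, float(row["printed_mz"]), float(row["printed_mz"])) <= 5, row["name"]
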