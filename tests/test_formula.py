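"""Molecular-formula parsing and mass/composition arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qcpost import constants as k
from qcpost.formula import (
    DEFAULT_TABLES,
    FormulaError,
    MolecularFormula,
    adduct_mass,
    average_molar_mass,
    elemental_percentages,
    energetic_descriptors,
    format_formula,
    monoisotopic_mass,
    nitrogen_percent,
    oxygen_balance,
    parse_formula,
    round_half_even,
)

# strategy: random small formulas over the common organic elements
formula_st = st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "Cl", "S", "Br", "F", "P"]),
    st.integers(min_value=1, max_value=60),
    min_size=1,
    max_size=6,
).map(MolecularFormula)


class TestParsing:
    @pytest.mark.parametrize(
        "text,counts",
        [
            ("C24H18Cl2N10O2", {"C": 24, "H": 18, "Cl": 2, "N": 10, "O": 2}),
            ("C", {"C": 1}),
            ("CH4", {"C": 1, "H": 4}),
            ("H2O", {"H": 2, "O": 1}),
            ("ClH", {"Cl": 1, "H": 1}),
        ],
    )
    def test_examples(self, text, counts):
        assert parse_formula(text).counts == counts

    @pytest.mark.parametrize("bad", ["", "   ", "Xx9", "C0", "c24", "C-2", "C2.5", "Qq"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_type_invariants(self):
        with pytest.raises(FormulaError):
            MolecularFormula({})
        with pytest.raises(FormulaError):
            MolecularFormula({"C": 0})
        with pytest.raises(FormulaError):
            MolecularFormula({"Zz": 1})

    @given(formula_st)
    def test_hill_roundtrip(self, f):
        assert parse_formula(format_formula(f)).counts == f.counts

    def test_hill_order(self):
        assert format_formula(parse_formula("O2N10Cl2H18C24")) == "C24H18Cl2N10O2"
        assert format_formula(parse_formula("OH2")) == "H2O"


class TestMasses:
    @pytest.mark.parametrize(
        "text,expected",
        [
            # printed HRMS calcd values match the neutral monoisotopic sum
            ("C30H32N10O2", 564.2710),
            ("C24H16N14O10", 660.1174),
            ("C24H18Cl2N10O2", 548.0991),
        ],
    )
    def test_hrms_calcd_values(self, text, expected):
        got = round_half_even(monoisotopic_mass(parse_formula(text)), 4)
        assert got == pytest.approx(expected, abs=5e-5)

    def test_single_carbon_is_exactly_twelve(self):
        assert monoisotopic_mass(parse_formula("C")) == 12.0

    @pytest.mark.parametrize(
        "text,expected,tol",
        [("C24H16N14O10", 660.48, 0.02), ("H2", 2.016, 1e-3), ("C24H18Cl2N10O2", 549.38, 0.02)],
    )
    def test_average_molar_mass(self, text, expected, tol):
        assert average_molar_mass(parse_formula(text)) == pytest.approx(expected, abs=tol)

    @given(st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "Cl"]),
        st.integers(min_value=1, max_value=60), min_size=1, max_size=5,
    ).map(MolecularFormula))
    def test_monoisotopic_below_average(self, f):
        assert monoisotopic_mass(f) < average_molar_mass(f)

    @given(formula_st)
    def test_per_atom_summation_oracle(self, f):
        """Masses agree with an independent atom-by-atom accumulation."""
        mono = avg = 0.0
        for sym, n in f.counts.items():
            for _ in range(n):
                mono += DEFAULT_TABLES.principal_isotope_mass[sym]
                avg += DEFAULT_TABLES.average_weight[sym]
        assert monoisotopic_mass(f) == pytest.approx(mono, abs=1e-6)
        assert average_molar_mass(f) == pytest.approx(avg, abs=1e-6)

    def test_rdkit_cross_check(self):
        """Independent oracle: rdkit's exact/average weights from SMILES."""
        from rdkit import Chem
        from rdkit.Chem.Descriptors import ExactMolWt, MolWt
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula

        smiles = [
            "O", "C", "CCO", "N", "c1ccccc1", "OC(=O)c1ccccc1",
            "NC(=O)c1ccccc1Cl", "O=[N+]([O-])c1ccccc1", "ClC(Cl)(Cl)Cl",
            "CC(N)C(=O)O", "c1ccc2[nH]cnc2c1", "FC(F)(F)c1ccccc1",
            "S=C=S", "OP(=O)(O)O", "BrCCBr", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
            "Nc1ncnc2[nH]cnc12", "OCC1OC(O)C(O)C(O)C1O", "CSC", "ICl",
        ]
        for smi in smiles:
            mol = Chem.AddHs(Chem.MolFromSmiles(smi))
            f = parse_formula(CalcMolFormula(mol))
            assert monoisotopic_mass(f) == pytest.approx(ExactMolWt(mol), abs=1e-4)
            # average weights differ at the last digit between table
            # vintages (e.g. Cl 35.45 conventional vs 35.453)
            assert average_molar_mass(f) == pytest.approx(MolWt(mol), abs=0.02)

    def test_missing_table_entry(self):
        from qcpost.formula import MassTables

        sparse = MassTables(average_weight={"C": 12.011}, principal_isotope_mass={"C": 12.0})
        with pytest.raises(FormulaError):
            monoisotopic_mass(parse_formula("CH4"), sparse)
        with pytest.raises(FormulaError):
            average_molar_mass(parse_formula("CH4"), sparse)


class TestAdducts:
    def test_neutral_equals_monoisotopic(self):
        f = parse_formula("C30H32N10O2")
        assert adduct_mass(f, "M") == monoisotopic_mass(f)
        assert round_half_even(adduct_mass(f, "M"), 4) == 564.2710

    def test_protonation_adds_proton_mass(self):
        f = parse_formula("H2O")
        delta = adduct_mass(f, "M+H") - adduct_mass(f, "M")
        assert delta == pytest.approx(1.00728, abs=1e-5)
        # deprotonation is symmetric
        assert adduct_mass(f, "M") - adduct_mass(f, "M-H") == pytest.approx(delta)

    def test_protonated_6d(self):
        got = adduct_mass(parse_formula("C24H16N14O10"), "M+H")
        assert got == pytest.approx(661.1247, abs=2e-4)

    def test_electron_correction_toggle(self):
        f = parse_formula("H2O")
        lax = adduct_mass(f, "M+H", electron_correction=False) - adduct_mass(f, "M")
        assert lax == pytest.approx(1.00782503, abs=1e-6)

    def test_unknown_adduct(self):
        with pytest.raises(FormulaError):
            adduct_mass(parse_formula("H2O"), "M+Na")


class TestComposition:
    def test_printed_anal_calcd_values(self):
        pct_6a = elemental_percentages(parse_formula("C24H18Cl2N10O2"))
        assert round_half_even(pct_6a["N"], 2) == 25.50
        pct_6d = elemental_percentages(parse_formula("C24H16N14O10"))
        assert round_half_even(pct_6d["C"], 2) == 43.64
        assert round_half_even(pct_6d["H"], 2) == 2.44

    @given(formula_st)
    def test_percentages_close_to_hundred(self, f):
        assert sum(elemental_percentages(f).values()) == pytest.approx(100.0, abs=1e-9)

    def test_nitrogen_percent(self):
        assert nitrogen_percent(parse_formula("C24H16N14O10")) == pytest.approx(29.69, abs=0.02)
        assert nitrogen_percent(parse_formula("CH4")) == 0.0
        assert nitrogen_percent(parse_formula("N2")) == pytest.approx(100.0)


class TestOxygenBalance:
    def test_co2_exactly_balanced(self):
        assert oxygen_balance(parse_formula("CO2")) == 0.0

    def test_balanced_stoichiometry_is_zero(self):
        # O = 2C + H/2 exactly: C2H4O6
        assert oxygen_balance(parse_formula("C2H4O6")) == pytest.approx(0.0, abs=1e-12)

    def test_6d_value(self):
        assert oxygen_balance(parse_formula("C24H16N14O10")) == pytest.approx(-111.4, abs=0.1)

    @given(formula_st.filter(lambda f: set(f.counts) <= {"C", "H", "N", "O", "Cl"}))
    def test_linearity_under_doubling(self, f):
        assert oxygen_balance(f.scaled(2)) == pytest.approx(oxygen_balance(f), rel=1e-12)

    def test_halogen_convention_changes_hydrogen_term(self):
        f = parse_formula("C24H18Cl2N10O2")
        classic = oxygen_balance(f, convention="CHNO-classic")
        hx = oxygen_balance(f, convention="halogen-HX")
        mw = average_molar_mass(f)
        assert hx - classic == pytest.approx(1600.0 * 1.0 / mw)  # nX/2 = 1

    def test_rejects_out_of_scope_elements(self):
        with pytest.raises(FormulaError):
            oxygen_balance(parse_formula("NaCl"))
        with pytest.raises(FormulaError):
            oxygen_balance(parse_formula("CO2"), convention="bogus")

    def test_descriptor_bundle_records_convention(self):
        d = energetic_descriptors(parse_formula("C24H16N14O10"))
        assert d.convention_tag == "CHNO-classic"
        assert 0 <= d.nitrogen_percent <= 100


class TestRounding:
    @pytest.mark.parametrize(
        "x,n,expected",
        [(0.49185, 4, 0.4918), (0.00005, 4, 0.0), (0.00015, 4, 0.0002), (2.675, 2, 2.68)],
    )
    def test_half_to_even(self, x, n, expected):
        assert round_half_even(x, n) == expected
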