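"""Mass arithmetic: formulas, adduct m/z, ppm deviations, enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycodyn.masses import (
    ADDUCTS,
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    ElementalFormula,
    FormulaConstraints,
    enumerate_formulas,
    monoisotopic_mass,
    ppm_deviation,
    theoretical_mz,
)


class TestElementalFormula:
    def test_parse_serialize_roundtrip(self):
        for text in ("C76H120O42", "H2O", "C30H46O6", "C10H15N3O5S", "CHNaO2"):
            assert str(ElementalFormula.parse(text)) == text

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "Na", "O", "S"]),
            st.integers(min_value=0, max_value=300),
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_property(self, counts):
        f = ElementalFormula(counts)
        assert ElementalFormula.parse(str(f)) == f

    def test_arithmetic(self):
        a = ElementalFormula.parse("C6H10O5")
        b = ElementalFormula.parse("H2O")
        assert str(a + b) == "C6H12O6"
        assert str((a + b) - b) == "C6H10O5"
        assert str(2 * b) == "H4O2"

    def test_subtraction_below_zero_errors(self):
        with pytest.raises(ValueError):
            ElementalFormula.parse("H2O") - ElementalFormula.parse("C")

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            ElementalFormula({"Xx": 1})
        with pytest.raises(ValueError):
            monoisotopic_mass("C2Si3")

    def test_empty_formula_mass_zero(self):
        assert monoisotopic_mass(ElementalFormula({})) == 0.0


class TestMonoisotopicMass:
    def test_against_hand_summed_oracle(self):
        # independent sums over the atomic constants
        assert monoisotopic_mass("C76H120O42") == pytest.approx(1704.725418, abs=1e-6)
        assert monoisotopic_mass("H2O") == pytest.approx(18.010565, abs=1e-6)

    def test_additivity(self):
        a, b = ElementalFormula.parse("C30H46O6"), ElementalFormula.parse("C6H8O6")
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-12
        )


class TestTheoreticalMz:
    def test_deprotonated_convention(self):
        assert theoretical_mz("C76H120O42", "[M-H]-") == pytest.approx(1703.718141, abs=1e-6)
        assert theoretical_mz("C30H46O6", "[M-H]-") == pytest.approx(501.322163, abs=1e-6)

    def test_proton_mass_identity(self):
        for text in ("C76H120O42", "C30H46O6", "C15H10O7"):
            assert theoretical_mz(text, "[M-H]-") + PROTON_MASS == pytest.approx(
                monoisotopic_mass(text), abs=1e-9
            )

    def test_anion_composition_includes_electron(self):
        mz = theoretical_mz("C30H45O6", "[M-H]-", composition="ion")
        assert mz == pytest.approx(monoisotopic_mass("C30H45O6") + ELECTRON_MASS, abs=1e-12)

    def test_zero_charge_rejected(self):
        from glycodyn.masses import AdductSpec

        neutral = AdductSpec("[M]", 1, {}, 0)
        with pytest.raises(ValueError):
            theoretical_mz("H2O", neutral)

    def test_doubly_charged(self):
        mz = theoretical_mz("C76H120O42", "[M-2H]2-")
        expect = (monoisotopic_mass("C76H120O42") - 2 * PROTON_MASS) / 2
        assert mz == pytest.approx(expect, abs=1e-9)


class TestPpmDeviation:
    def test_printed_precursor_row(self):
        theo = theoretical_mz("C76H120O42", "[M-H]-")
        assert ppm_deviation(1703.71838, theo) == pytest.approx(0.141, abs=0.005)

    def test_printed_sugar_chain_row(self):
        theo = theoretical_mz("C34H56O26", "[M-H]-")
        assert ppm_deviation(879.30701, theo) == pytest.approx(9.445, abs=0.005)

    def test_zero_at_equality(self):
        assert ppm_deviation(500.0, 500.0) == 0.0

    def test_antisymmetry(self):
        d = ppm_deviation(500.001, 500.0)
        # swapping observation and reference flips the sign of the difference
        assert ppm_deviation(500.0 - (500.001 - 500.0), 500.0) == pytest.approx(-d, rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ppm_deviation(100.0, 0.0)


# Table of printed fragment-ion deviations: (observed m/z, formula, printed
# ppm, composition convention resolved by minimising |ppm|).
PRINTED_DEVIATIONS = [
    (1703.71838, "C76H120O42", 0.141, "neutral"),
    (1381.62830, "C64H102O32", 0.113, "neutral"),
    (879.30701, "C34H56O26", 9.445, "neutral"),
    (823.41089, "C42H64O16", -1.541, "neutral"),
    (501.32275, "C30H45O6", 1.172, "ion"),
    (439.31934, "C29H44O3", -5.528, "neutral"),
]


@pytest.mark.parametrize("observed,formula,printed,composition", PRINTED_DEVIATIONS)
def test_printed_deviation_rows(observed, formula, printed, composition):
    theo = theoretical_mz(formula, "[M-H]-", composition=composition)
    assert ppm_deviation(observed, theo) == pytest.approx(printed, abs=0.01)


@pytest.mark.parametrize("observed,formula,printed,composition", PRINTED_DEVIATIONS)
def test_interpretation_resolved_by_min_ppm(observed, formula, printed, composition):
    """One of the two conventions reproduces each printed row; the winner is
    the |ppm|-minimising one."""
    devs = {
        c: ppm_deviation(observed, theoretical_mz(formula, "[M-H]-", composition=c))
        for c in ("neutral", "ion")
    }
    assert min(devs, key=lambda c: abs(devs[c])) == composition


class TestEnumerateFormulas:
    def test_vendor_box_reproduces_printed_count(self):
        hits = enumerate_formulas(
            1703.71838, "[M-H]-", 5.0, FormulaConstraints.vendor()
        )
        assert len(hits) == 19
        # the ion composition of the neutral C76H120O42
        assert any(str(f) == "C76H119O42" for f, _ in hits)

    def test_default_box_contains_true_formula_first(self):
        hits = enumerate_formulas(1703.71838, "[M-H]-", 5.0)
        assert str(hits[0][0]) == "C76H120O42"
        assert abs(hits[0][1]) < 0.2

    def test_water_only_in_narrow_window(self):
        mz = theoretical_mz("H2O", "[M-H]-")
        cons = FormulaConstraints(c_range=(0, 2), h_range=(0, 6), o_range=(0, 2))
        hits = enumerate_formulas(mz, "[M-H]-", 5.0, cons)
        assert [str(f) for f, _ in hits] == ["H2O"]

    def test_zero_tolerance_exact_hit(self):
        mz = theoretical_mz("C76H120O42", "[M-H]-")
        hits = enumerate_formulas(mz, "[M-H]-", 0.0)
        assert any(str(f) == "C76H120O42" for f, _ in hits)

    def test_sorted_by_abs_ppm(self):
        hits = enumerate_formulas(1703.71838, "[M-H]-", 5.0)
        devs = [abs(d) for _, d in hits]
        assert devs == sorted(devs)

    def test_matches_independent_triple_loop(self):
        """Set equality against a naive brute force on random targets."""
        rng = np.random.default_rng(12)
        cons = FormulaConstraints(c_range=(0, 40), h_range=(0, 80), o_range=(0, 20))
        mC, mH, mO = (MONOISOTOPIC_MASS[e] for e in ("C", "H", "O"))
        for _ in range(50):
            target = rng.uniform(100, 2000)
            expected = set()
            for c in range(41):
                for h in range(0, 81, 1):
                    if h % 2 or c - h / 2 + 1 < 0:
                        continue
                    for o in range(21):
                        mz = c * mC + h * mH + o * mO - PROTON_MASS
                        if abs(mz - target) <= 5e-6 * target:
                            expected.add((c, h, o))
            got = {
                (f["C"], f["H"], f["O"])
                for f, _ in enumerate_formulas(target, "[M-H]-", 5.0, cons)
            }
            assert got == expected

    def test_unbounded_constraints_rejected(self):
        with pytest.raises(ValueError):
            FormulaConstraints(c_range=(0, None))


def test_builtin_adduct_dialect_complete():
    for name in (
        "[M-H]-", "[M+H]+", "[M+Na]+", "[M+NH4]+", "[M-H+FA]-",
        "[M-H+NaFA]-", "[2M-H]-", "[2M+Na]+", "[M-2H]2-",
    ):
        assert name in ADDUCTS


def test_sodiated_multimer_against_printed_value():
    # herniariasaponin F: printed positive-mode sodium adduct
    mz = theoretical_mz("C59H94O28", "[M+Na]+")
    assert ppm_deviation(1273.58240, mz) == pytest.approx(0.0, abs=5.0)
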