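"""Formula arithmetic against independent hand-sum / convolution oracles."""

import itertools

import numpy as np
import pytest
from pyteomics import mass as pmass

from pfascreen.chem_core import (
    DEFAULT_ELEMENT_BOUNDS,
    ELECTRON_MASS_DA,
    Formula,
    FormulaError,
    adduct_mz,
    equivalent_carbon_number,
    isotope_m1_fraction,
    kaufmann_point,
    mass_defect,
    monoisotopic_mass,
    nominal_mass,
    predict_formula,
    rdbe,
)

# hand-summed IUPAC monoisotopic masses (independent of the implementation)
M_C, M_H, M_F, M_O = 12.0, 1.007825, 18.9984032, 15.9949146


class TestFormula:
    def test_parse_hill_round_trip(self):
        assert str(Formula.parse("C8HF15O2")) == "C8HF15O2"
        assert str(Formula.parse("F15O2C8H")) == "C8HF15O2"
        assert str(Formula.parse("CF2CF2O")) == "C2F4O"
        assert str(Formula.parse("H2O")) == "H2O"

    def test_unsupported_element_rejected(self):
        with pytest.raises(FormulaError):
            Formula.parse("C2Hg1")
        with pytest.raises(FormulaError):
            Formula.from_counts({"Xx": 1})

    def test_empty_rejected(self):
        with pytest.raises(FormulaError):
            Formula.from_counts({"C": 0})

    def test_arithmetic(self):
        cf2 = Formula.parse("CF2")
        assert str(cf2 + cf2) == "C2F4"
        assert str(3 * cf2) == "C3F6"


class TestMasses:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("CF2", M_C + 2 * M_F),              # 49.996806
            ("C8HF15O2", 8 * M_C + M_H + 15 * M_F + 2 * M_O),  # 413.973702 (PFOA)
            ("H", M_H),
        ],
    )
    def test_monoisotopic_hand_sum(self, formula, expected):
        assert monoisotopic_mass(Formula.parse(formula)) == pytest.approx(expected, abs=1e-5)

    def test_nominal(self):
        assert nominal_mass(Formula.parse("CF2")) == 50
        assert nominal_mass(Formula.parse("C8HF15O2")) == 414

    def test_adduct_mz_examples(self):
        pfoa = Formula.parse("C8HF15O2")
        assert adduct_mz(pfoa, "[M-H]-") == pytest.approx(412.966426, abs=1e-5)
        assert adduct_mz(pfoa, "[M-H-CO2]-") == pytest.approx(368.976597, abs=1e-5)

    def test_unknown_adduct_lists_vocabulary(self):
        with pytest.raises(KeyError, match=r"\[M-H\]-"):
            adduct_mz(Formula.parse("C2F4"), "[M+H]+")

    @pytest.mark.parametrize("formula", ["C8HF15O2", "C4HF7O2", "C10H2F16O2"])
    def test_co2_loss_constant_offset(self, formula):
        f = Formula.parse(formula)
        assert adduct_mz(f, "[M-H]-") - adduct_mz(f, "[M-H-CO2]-") == pytest.approx(
            43.989829, abs=1e-5
        )


class TestMassDefect:
    @pytest.mark.parametrize(
        "mz, expected",
        [(412.9664, -0.0336), (500.0, 0.0), (350.17, 0.17)],
    )
    def test_examples(self, mz, expected):
        assert mass_defect(mz) == pytest.approx(expected, abs=1e-9)

    def test_range(self):
        for mz in np.linspace(50.1, 1000.3, 211):
            assert -0.5 <= mass_defect(float(mz)) <= 0.5

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mass_defect(0.0)


def _convolution_m1_percent(formula: Formula) -> float:
    """Oracle: full multinomial isotope-pattern convolution over nominal bins."""
    dist = np.array([1.0])
    for el, n in formula.counts.items():
        isotopes = sorted(
            k for k in pmass.nist_mass[el] if k != 0 and pmass.nist_mass[el][k][1] > 0
        )
        base = isotopes[0]
        el_dist = np.zeros(isotopes[-1] - base + 1)
        for iso in isotopes:
            el_dist[iso - base] = pmass.nist_mass[el][iso][1]
        for _ in range(n):
            dist = np.convolve(dist, el_dist)
    return dist[1] / dist[0] * 100.0


class TestIsotopes:
    @pytest.mark.parametrize(
        "formula", ["C8HF15O2", "CF4", "H2O", "C60H80O20", "C10H2F16O2", "C8H2F17NSO2"]
    )
    def test_m1_against_convolution_oracle(self, formula):
        f = Formula.parse(formula)
        assert isotope_m1_fraction(f) == pytest.approx(
            _convolution_m1_percent(f), abs=0.1
        )

    def test_m1_magnitudes(self):
        assert isotope_m1_fraction(Formula.parse("C8HF15O2")) == pytest.approx(8.73, abs=0.05)
        assert isotope_m1_fraction(Formula.parse("CF4")) == pytest.approx(1.08, abs=0.01)
        assert isotope_m1_fraction(Formula.parse("H2O")) < 0.1

    def test_equivalent_carbon_number(self):
        assert equivalent_carbon_number(8.6528) == pytest.approx(8.0, abs=1e-9)
        assert equivalent_carbon_number(1.0816) == pytest.approx(1.0, abs=1e-9)
        assert equivalent_carbon_number(0.0) is None
        assert equivalent_carbon_number(-1.0) is None

    def test_kaufmann_point(self):
        kp = kaufmann_point(412.9664, 8.6528)
        assert kp.ecn == pytest.approx(8.0, abs=1e-6)
        assert kp.md_over_ecn == pytest.approx(-0.0042, abs=1e-4)
        assert kp.mz_over_ecn == pytest.approx(51.62, abs=0.01)
        assert kaufmann_point(412.9664, 0.0) is None


SMALL_BOUNDS = {"C": 10, "H": 6, "F": 17, "O": 4, "N": 1, "S": 1, "P": 0, "Cl": 1}


def _brute_force_candidates(mz, tol_ppm, bounds):
    """Oracle: exhaustive nested enumeration for [M-H]- with the same chemistry filters."""
    tol_da = mz * tol_ppm * 1e-6
    target = mz + 1.007825032 - ELECTRON_MASS_DA
    masses = {el: pmass.nist_mass[el][0][0] for el in bounds}
    hits = set()
    elements = sorted(bounds)
    for combo in itertools.product(*(range(bounds[el] + 1) for el in elements)):
        counts = {el: n for el, n in zip(elements, combo) if n}
        if not counts or counts.get("H", 0) < 1:
            continue
        total = sum(n * masses[el] for el, n in counts.items())
        if abs(total - target) > tol_da:
            continue
        r = rdbe(counts)
        if r < 0 or r != int(r):
            continue
        if counts.get("F", 0) > 2 * counts.get("C", 0) + 3:
            continue
        hits.add(str(Formula.from_counts(counts)))
    return hits


class TestPredictFormula:
    def test_recovers_pfoa(self):
        cands = predict_formula(412.9664, "[M-H]-", tol_ppm=5.0)
        assert "C8HF15O2" in {str(c.formula) for c in cands}
        assert abs(cands[0].ppm_error) <= 5.0

    @pytest.mark.parametrize("mz", [412.9664, 298.9430, 226.9949])
    def test_matches_brute_force_oracle(self, mz):
        ours = {
            str(c.formula)
            for c in predict_formula(mz, "[M-H]-", tol_ppm=20.0, element_bounds=SMALL_BOUNDS)
        }
        assert ours == _brute_force_candidates(mz, 20.0, SMALL_BOUNDS)

    def test_tightening_monotonic(self):
        wide = {str(c.formula) for c in predict_formula(412.9664, tol_ppm=10.0)}
        narrow = {str(c.formula) for c in predict_formula(412.9664, tol_ppm=1.0)}
        assert narrow <= wide
        # in a sparse element space an ultratight window keeps at most one hit
        tiny = predict_formula(412.9664, tol_ppm=0.01, element_bounds=SMALL_BOUNDS)
        assert len(tiny) <= 1

    def test_fluorine_bound_zero_excludes_pfas(self):
        cands = predict_formula(
            412.9664, tol_ppm=5.0, element_bounds={**DEFAULT_ELEMENT_BOUNDS, "F": 0}
        )
        assert all(c.formula["F"] == 0 for c in cands)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            predict_formula(412.9664, tol_ppm=0.0)
        with pytest.raises(ValueError):
            predict_formula(-1.0)
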