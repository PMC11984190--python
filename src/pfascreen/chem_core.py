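"""Elemental-formula arithmetic for negative-mode PFAS ion annotation.

Everything downstream of the feature table ultimately reduces to a handful
of mass computations: monoisotopic masses of neutral formulas, adduct m/z
values for the deprotonated species and common in-source neutral losses,
mass defects, first-order (M+1) isotope abundances, the equivalent carbon
number derived from them, and bounded molecular-formula prediction.

Monoisotopic masses come from the NIST table shipped with :mod:`pyteomics`
(identical to IUPAC values at the precision used here, >= 6 decimals).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from pyteomics import mass as _pmass
from pyteomics.auxiliary import PyteomicsError

__all__ = [
    "Formula",
    "FormulaError",
    "KaufmannPoint",
    "FormulaCandidate",
    "SUPPORTED_ELEMENTS",
    "ELECTRON_MASS_DA",
    "ADDUCTS",
    "register_adduct",
    "monoisotopic_mass",
    "nominal_mass",
    "adduct_mz",
    "mass_defect",
    "isotope_m1_fraction",
    "equivalent_carbon_number",
    "kaufmann_point",
    "predict_formula",
]

SUPPORTED_ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: CODATA electron rest mass in Da; matters at the 0.01-Da tolerance scale.
ELECTRON_MASS_DA = 0.000548579909

#: Monoisotopic (lightest-isotope) masses, Da.
MONOISOTOPIC: Mapping[str, float] = {
    el: _pmass.nist_mass[el][0][0] for el in SUPPORTED_ELEMENTS
}

#: Integer nominal masses, Da.
NOMINAL: Mapping[str, int] = {
    "C": 12, "H": 1, "N": 14, "O": 16, "S": 32,
    "P": 31, "F": 19, "Cl": 35, "Br": 79, "I": 127,
}

#: Per-atom M+1 contribution, percent of the monoisotopic peak.
#: Dominated by 13C (1.0816% per carbon); F, P and I are monoisotopic,
#: and the +2 isotopes of Cl/Br/S do not contribute to M+1.
M1_PERCENT_PER_ATOM: Mapping[str, float] = {
    "C": 1.0816, "H": 0.0115, "N": 0.3654, "O": 0.0381, "S": 0.8000,
}

#: 13C contribution per carbon, percent — the conversion factor between the
#: M+1 peak percentage and the equivalent carbon number.
C13_PERCENT_PER_CARBON = 1.0816


class FormulaError(ValueError):
    """Raised for unparseable formulas or unsupported elements."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition over the supported element set.

    Immutable and hashable; ``str()`` gives the canonical Hill-order
    string (C first, then H, then the rest alphabetically).
    """

    _items: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "Formula":
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {el!r} (supported: {', '.join(SUPPORTED_ELEMENTS)})")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}")
            if n:
                clean[el] = n
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        return cls(_hill_items(clean))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a plain formula string such as ``C8HF15O2`` or ``CF2CF2O``."""
        try:
            comp = _pmass.Composition(formula=str(text).strip())
        except PyteomicsError as exc:
            raise FormulaError(f"unparseable formula {text!r}: {exc}") from None
        return cls.from_counts(dict(comp))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._items)

    def __getitem__(self, element: str) -> int:
        return dict(self._items).get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = self.counts
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula.from_counts(merged)

    def __mul__(self, k: int) -> "Formula":
        return Formula.from_counts({el: n * k for el, n in self._items})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in self._items)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Formula({str(self)!r})"


def _hill_items(counts: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else []) + sorted(
            el for el in counts if el not in ("C", "H")
        )
    else:
        order = sorted(counts)
    return tuple((el, counts[el]) for el in order)


# ---------------------------------------------------------------------------
# adducts

@dataclass(frozen=True)
class AdductSpec:
    """Mass/charge bookkeeping for an ionized species relative to neutral M.

    ``delta`` gives atoms added (positive) or lost (negative); ``charge``
    is the signed ion charge (negative mode by default).
    """

    label: str
    delta: tuple[tuple[str, int], ...]
    charge: int = -1

    @property
    def delta_mass(self) -> float:
        return sum(n * MONOISOTOPIC[el] for el, n in self.delta)

    @property
    def n_electrons(self) -> int:
        return -self.charge


ADDUCTS: dict[str, AdductSpec] = {}


def register_adduct(label: str, delta: Mapping[str, int], charge: int = -1) -> AdductSpec:
    """Extend the adduct vocabulary with a (delta formula, charge) entry."""
    if charge == 0:
        raise ValueError("adduct charge must be nonzero")
    for el in delta:
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {el!r} in adduct delta")
    spec = AdductSpec(label, tuple(sorted(delta.items())), charge)
    ADDUCTS[label] = spec
    return spec


register_adduct("[M-H]-", {"H": -1})
register_adduct("[M-H-CO2]-", {"H": -1, "C": -1, "O": -2})
register_adduct("[M+formate]-", {"C": 1, "H": 1, "O": 2})


def _adduct(label: str) -> AdductSpec:
    try:
        return ADDUCTS[label]
    except KeyError:
        known = ", ".join(sorted(ADDUCTS))
        raise KeyError(f"unknown adduct label {label!r}; known labels: {known}") from None


# ---------------------------------------------------------------------------
# scalar mass functions

def monoisotopic_mass(formula: Formula) -> float:
    """Monoisotopic (lightest-isotope) mass of a neutral formula, Da."""
    return sum(n * MONOISOTOPIC[el] for el, n in formula.counts.items())


def nominal_mass(formula: Formula) -> int:
    """Integer nominal mass of a neutral formula, Da."""
    return sum(n * NOMINAL[el] for el, n in formula.counts.items())


def adduct_mz(formula: Formula, adduct_label: str = "[M-H]-") -> float:
    """m/z of an ionized species, electron mass included.

    m/z = (monoisotopic(M) + delta mass + n_electrons x m_e) / |z|.
    """
    spec = _adduct(adduct_label)
    m = monoisotopic_mass(formula) + spec.delta_mass + spec.n_electrons * ELECTRON_MASS_DA
    return m / abs(spec.charge)


def mass_defect(mz: float) -> float:
    """Mass defect: m/z minus the nearest integer (round-half-to-even)."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return float(mz - round(mz))


def isotope_m1_fraction(formula: Formula) -> float:
    """First-order M+1 relative abundance, percent of the monoisotopic peak.

    Linear in atom counts; exact to first order because an M+1 isotopologue
    carries exactly one heavy-isotope substitution.
    """
    return sum(
        n * M1_PERCENT_PER_ATOM.get(el, 0.0) for el, n in formula.counts.items()
    )


def equivalent_carbon_number(m1_percent: float) -> float | None:
    """Carbon count estimated from the M+1 peak percentage (None if <= 0)."""
    if m1_percent is None or m1_percent <= 0:
        return None
    return m1_percent / C13_PERCENT_PER_CARBON


@dataclass(frozen=True)
class KaufmannPoint:
    """Coordinates separating fluorinated from biological molecules.

    Fluorine is heavy but nearly invisible in the M+1 peak, so PFASs sit at
    high m/z-per-equivalent-carbon and low (usually negative) mass defect
    per equivalent carbon relative to CHNO biomolecules.
    """

    ecn: float
    md_over_ecn: float
    mz_over_ecn: float


def kaufmann_point(mz: float, m1_percent: float) -> KaufmannPoint | None:
    ecn = equivalent_carbon_number(m1_percent)
    if ecn is None or ecn <= 0:
        return None
    return KaufmannPoint(ecn=ecn, md_over_ecn=mass_defect(mz) / ecn, mz_over_ecn=mz / ecn)


# ---------------------------------------------------------------------------
# formula prediction

#: Default element bounds for formula enumeration, permissive for highly
#: fluorinated anions up to ~1200 Da.
DEFAULT_ELEMENT_BOUNDS: Mapping[str, int] = {
    "C": 60, "H": 80, "F": 80, "O": 20, "N": 5, "S": 4, "P": 3, "Cl": 4,
    "Br": 0, "I": 0,
}

# Enumeration order: heaviest first so mass pruning bites early; C second to
# last (solved under a tight window once H is the only remaining element),
# H solved in closed form.
_ENUM_ORDER: tuple[str, ...] = ("I", "Br", "Cl", "S", "P", "F", "O", "N", "C")


@dataclass(frozen=True)
class FormulaCandidate:
    formula: Formula
    mz_calc: float
    ppm_error: float
    m1_percent: float


def rdbe(counts: Mapping[str, int]) -> float:
    """Ring-plus-double-bond equivalents of a neutral formula."""
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    x = sum(counts.get(el, 0) for el in ("F", "Cl", "Br", "I"))
    n = counts.get("N", 0) + counts.get("P", 0)
    return c - (h + x) / 2.0 + n / 2.0 + 1.0


def predict_formula(
    mz: float,
    adduct_label: str = "[M-H]-",
    tol_ppm: float = 5.0,
    element_bounds: Mapping[str, int] | None = None,
    observed_m1_percent: float | None = None,
) -> list[FormulaCandidate]:
    """Enumerate neutral formulas whose adduct m/z falls within ``tol_ppm``.

    Candidates must have integer RDBE >= 0 (an even-electron deprotonated
    anion implies an integer-RDBE neutral), satisfy the fluorine sanity
    bound F <= 2C + 3, and contain the atoms removed by the adduct.
    Ranked by absolute ppm error, then by distance between theoretical and
    observed M+1 percentage when an observed value is given.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if mz <= 0:
        raise ValueError("m/z must be positive")
    spec = _adduct(adduct_label)
    bounds = dict(DEFAULT_ELEMENT_BOUNDS)
    if element_bounds:
        for el, b in element_bounds.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {el!r} in bounds")
            bounds[el] = int(b)

    target = mz * abs(spec.charge) - spec.delta_mass - spec.n_electrons * ELECTRON_MASS_DA
    tol_da = mz * tol_ppm * 1e-6 * abs(spec.charge)
    removed = {el: -n for el, n in spec.delta if n < 0}

    m_h = MONOISOTOPIC["H"]
    order = [el for el in _ENUM_ORDER if bounds.get(el, 0) > 0]
    # Max mass attainable by elements after position i (H included), for
    # lower-bound pruning of each count loop.
    suffix_max: list[float] = []
    acc = bounds.get("H", 0) * m_h
    for el in reversed(order):
        suffix_max.append(acc)
        acc += bounds[el] * MONOISOTOPIC[el]
    suffix_max.reverse()

    out: list[FormulaCandidate] = []
    counts: dict[str, int] = {}

    def emit(n_h: int, total: float) -> None:
        if not (0 <= n_h <= bounds.get("H", 0)):
            return
        if abs(total - target) > tol_da:
            return
        cand = {el: n for el, n in counts.items() if n}
        if n_h:
            cand["H"] = n_h
        if not cand:
            return
        for el, need in removed.items():
            if cand.get(el, 0) < need:
                return
        r = rdbe(cand)
        if r < 0 or r != int(r):
            return
        if cand.get("F", 0) > 2 * cand.get("C", 0) + 3:
            return
        formula = Formula.from_counts(cand)
        calc = adduct_mz(formula, adduct_label)
        ppm = (calc - mz) / mz * 1e6
        out.append(
            FormulaCandidate(formula, calc, ppm, isotope_m1_fraction(formula))
        )

    def rec(idx: int, remaining: float) -> None:
        if idx == len(order):
            base = round(remaining / m_h)
            for n_h in (base - 1, base, base + 1):
                emit(n_h, target - remaining + n_h * m_h)
            return
        el = order[idx]
        m = MONOISOTOPIC[el]
        hi = min(bounds[el], int((remaining + tol_da) // m))
        lo = max(0, -int(-(remaining - suffix_max[idx] - tol_da) // m))
        for n in range(lo, hi + 1):
            counts[el] = n
            rec(idx + 1, remaining - n * m)
        counts[el] = 0

    rec(0, target)

    def key(c: FormulaCandidate):
        tie = (
            abs(c.m1_percent - observed_m1_percent)
            if observed_m1_percent is not None
            else 0.0
        )
        return (abs(c.ppm_error), tie, str(c.formula))

    out.sort(key=key)
    return out
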