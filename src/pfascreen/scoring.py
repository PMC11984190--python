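"""Confidence grading of annotated features (A+ ... E) and PCL mapping.

Each feature receives exactly one grade from the strictly ordered rule
table below, combining exact-mass and CCS match evidence, optional MS/MS
evidence booleans supplied by an external fragmentation workflow,
homologous-series membership, and the mass-defect window.  The C tier is
contextual: it promotes series members on the strength of a confidently
identified sibling, so grading runs to a fixed point (two passes suffice
because A/B grades never depend on siblings).

Grades map onto PFAS Confidence Levels (PCL): A tier -> 2b, B tier -> 2c,
C+ -> 2c when the series holds an A-grade member (else 3d), C/C- -> 3d,
D tier and E -> 5.  A+ is reserved for standard-confirmed targeted
identifications and is never emitted by this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .chem_core import mass_defect

__all__ = [
    "GRADES",
    "EvidenceBundle",
    "grade_rank",
    "grade_at_least",
    "md_in_window",
    "assign_grade",
    "finalize_grades",
    "pcl_for",
]

#: Best to worst.
GRADES = ("A+", "A", "A-", "B+", "B", "B-", "C+", "C", "C-", "D+", "D", "D-", "E")

_RANK = {g: i for i, g in enumerate(GRADES)}

#: Sibling thresholds for the C tier.
A_GRADES = frozenset({"A+", "A", "A-"})
B_OR_BETTER = frozenset({"A+", "A", "A-", "B+", "B", "B-"})


def grade_rank(grade: str) -> int:
    """Position in the grade order (0 is best)."""
    return _RANK[grade]


def grade_at_least(grade: str | None, threshold: str) -> bool:
    return grade is not None and _RANK[grade] <= _RANK[threshold]


def md_in_window(mz: float, window: tuple[float, float] = (-0.11, 0.12)) -> bool:
    """True when the mass defect falls in [lo, hi] (both ends inclusive).

    Boundary comparisons carry a 1e-9 guard so a defect that is exactly on
    an endpoint up to float representation still counts as inside.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    eps = 1e-9
    return lo - eps <= mass_defect(mz) <= hi + eps


@dataclass(frozen=True)
class EvidenceBundle:
    """Everything grading needs to know about one feature.

    ``ccs_match`` means a single library entry matched in both mass and
    CCS; ``co2_loss_conflict`` means the only mass match is a CO2-loss
    entry whose CCS instead fits the sibling precursor entry.  The MS/MS
    booleans default to false when no fragmentation data is available.
    """

    mass_match: bool = False
    ccs_match: bool = False
    class_fragment: bool = False
    pfas_fragment: bool = False
    common_f_fragment: bool = False
    md_in_window: bool = False
    series_effective_size: int = 0
    best_sibling_grade: str | None = None
    co2_loss_conflict: bool = False


def assign_grade(ev: EvidenceBundle) -> str:
    """First matching rule in strict order decides the grade.

    A:  mass + (CCS or class fragment), 2+ effective in series
    A-: mass + (CCS or class fragment)
    B+: PFAS fragment + mass, 2+ in series
    B:  common F fragment + mass, 2+ in series
    B-: any PFAS/common-F fragment + mass
    C+: 2+ in series with an A-grade sibling, or a CO2-loss conflict
        inside a qualifying (2+) series
    C:  3+ in series with a B-grade-or-better sibling
    C-: 2+ in series with a B-grade-or-better sibling
    D+: (mass defect in window or mass match) and 3+ in series
    D:  3+ in series
    D-: mass defect in window or mass match
    E:  otherwise

    A CO2-loss conflict suppresses the A tier: the mass-matched entry's
    CCS did not match, so the evidence is series-level, not structural.
    """
    s = ev.series_effective_size
    sib = ev.best_sibling_grade
    if (
        ev.mass_match
        and (ev.ccs_match or ev.class_fragment)
        and not ev.co2_loss_conflict
    ):
        return "A" if s >= 2 else "A-"
    if ev.pfas_fragment and ev.mass_match and s >= 2:
        return "B+"
    if ev.common_f_fragment and ev.mass_match and s >= 2:
        return "B"
    if (ev.pfas_fragment or ev.common_f_fragment) and ev.mass_match:
        return "B-"
    if s >= 2 and (ev.co2_loss_conflict or (sib in A_GRADES if sib else False)):
        return "C+"
    if s >= 3 and sib in B_OR_BETTER:
        return "C"
    if s >= 2 and sib in B_OR_BETTER:
        return "C-"
    if (ev.md_in_window or ev.mass_match) and s >= 3:
        return "D+"
    if s >= 3:
        return "D"
    if ev.md_in_window or ev.mass_match:
        return "D-"
    return "E"


def finalize_grades(
    bundles: Mapping[str, EvidenceBundle],
    siblings: Mapping[str, set[str]],
) -> dict[str, str]:
    """Iterate grading to a fixed point over sibling dependencies.

    ``siblings`` maps each feature id to the other members of its series
    (flagged members included — they stay categorized in the series).
    Pass 1 grades everything without sibling context; subsequent passes
    feed each feature the best current grade among its siblings until no
    grade changes.  Terminates in <= 2 refinement passes because sibling
    thresholds only reference A/B grades, which are context-free.
    """
    grades = {fid: assign_grade(ev) for fid, ev in bundles.items()}
    for _ in range(4):
        changed = False
        for fid, ev in bundles.items():
            sibs = siblings.get(fid, set())
            best = None
            for other in sibs:
                g = grades.get(other)
                if g is not None and (best is None or _RANK[g] < _RANK[best]):
                    best = g
            new = assign_grade(replace(ev, best_sibling_grade=best))
            if new != grades[fid]:
                grades[fid] = new
                changed = True
        if not changed:
            break
    return grades


def pcl_for(grade: str, sibling_has_a: bool = False) -> str:
    """PFAS Confidence Level for a grade (Charbonnet scale sublevels)."""
    if grade in A_GRADES:
        return "2b"
    if grade in ("B+", "B", "B-"):
        return "2c"
    if grade == "C+":
        return "2c" if sibling_has_a else "3d"
    if grade in ("C", "C-"):
        return "3d"
    return "5"
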