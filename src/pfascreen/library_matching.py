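"""Accurate-mass and CCS matching against a reference library.

A feature matches a library entry when its m/z falls within an absolute
mass window (default 0.01 Da) of the entry's adduct m/z; the CCS is then
compared within a relative window (default 2%) with the library value as
the denominator.  Several entries can pass the mass window (isomers,
shared adduct masses); all are reported, ranked by mass then CCS error,
and flagged ambiguous.

In-source CO2 loss of perfluoroalkyl carboxylates decouples the fragment's
m/z from the precursor's CCS (fragmentation happens after the drift cell):
the m/z matches the ``[M-H-CO2]-`` entry while the measured CCS still
matches the sibling ``[M-H]-`` entry.  :func:`reconcile_co2_loss` detects
that pattern and flags it, so grading can treat it as series-level rather
than structure-level evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

from .io_tables import CcsLibraryEntry, FeatureRecord, SuspectEntry

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

__all__ = [
    "MatchEvidence",
    "match_feature",
    "reconcile_co2_loss",
    "match_suspect_list",
    "library_agreement",
]


@dataclass
class MatchEvidence:
    """One feature-vs-entry comparison that passed the mass window."""

    feature_id: str
    entry: CcsLibraryEntry
    mass_error_da: float
    mass_error_ppm: float
    ccs_error_pct: float
    mass_match: bool
    ccs_match: bool
    co2_loss_conflict: bool = False
    ambiguous: bool = False


def match_feature(
    feature: FeatureRecord,
    library: Sequence[CcsLibraryEntry],
    config: "RunConfig",
) -> list[MatchEvidence]:
    """All library entries within the mass window, best first.

    Sorted by (|ppm error|, |CCS error|); ties broken by library row
    order.  ``ambiguous`` is set on every evidence when two or more
    entries pass.
    """
    out: list[MatchEvidence] = []
    for idx, entry in enumerate(library):
        dm = feature.mz - entry.adduct_mz
        if abs(dm) > config.mz_tol_da:
            continue
        ccs_err = (feature.ccs - entry.ccs) / entry.ccs * 100.0
        out.append(
            MatchEvidence(
                feature_id=feature.feature_id,
                entry=entry,
                mass_error_da=dm,
                mass_error_ppm=dm / entry.adduct_mz * 1e6,
                ccs_error_pct=ccs_err,
                mass_match=True,
                ccs_match=abs(ccs_err) <= config.ccs_tol_pct,
            )
        )
    order = {id(ev): i for i, ev in enumerate(out)}
    out.sort(key=lambda ev: (abs(ev.mass_error_ppm), abs(ev.ccs_error_pct), order[id(ev)]))
    if len(out) >= 2:
        for ev in out:
            ev.ambiguous = True
    return out


def reconcile_co2_loss(
    feature: FeatureRecord,
    evidences: list[MatchEvidence],
    library: Sequence[CcsLibraryEntry],
    config: "RunConfig",
) -> list[MatchEvidence]:
    """Flag mass matches explained by post-mobility CO2 neutral loss.

    For every evidence on a ``[M-H-CO2]-`` entry whose CCS did not match,
    look up the same compound's ``[M-H]-`` entry; if the measured CCS is
    within tolerance of that sibling's CCS, set ``co2_loss_conflict``.
    Evidences are updated in place and returned.
    """
    siblings = {
        e.name: e for e in library if e.adduct_label == "[M-H]-"
    }
    for ev in evidences:
        if ev.entry.adduct_label != "[M-H-CO2]-" or ev.ccs_match:
            continue
        sib = siblings.get(ev.entry.name)
        if sib is None:
            continue
        sib_err = (feature.ccs - sib.ccs) / sib.ccs * 100.0
        if abs(sib_err) <= config.ccs_tol_pct:
            ev.co2_loss_conflict = True
    return evidences


def match_suspect_list(
    feature: FeatureRecord,
    suspects: Sequence[SuspectEntry],
    config: "RunConfig",
) -> list[SuspectEntry]:
    """Mass-only matches against a CCS-free suspect list.

    Deduplicated by canonical formula (mass-only entries are kept as-is).
    Suspect hits count as exact-mass evidence only and can never raise a
    grade above the D tier on their own.
    """
    out: list[SuspectEntry] = []
    seen: set[str] = set()
    for s in suspects:
        if abs(feature.mz - s.mz) > config.mz_tol_da:
            continue
        key = str(s.formula) if s.formula is not None else f"mz:{s.mz!r}:{s.name}"
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


def library_agreement(
    pairs: Iterable[tuple[float, float]], tol_pct: float = 2.0
) -> tuple[int, int, float]:
    """Fraction of external CCS values within ``tol_pct`` of library values.

    ``pairs`` iterates (library_ccs, external_ccs); returns
    (n_within, n_total, fraction).  Used to assess cross-platform CCS
    agreement for a library against literature measurements.
    """
    n_within = n_total = 0
    for lib, ext in pairs:
        if lib <= 0:
            raise ValueError("library CCS must be positive")
        n_total += 1
        if abs((ext - lib) / lib) * 100.0 <= tol_pct:
            n_within += 1
    frac = n_within / n_total if n_total else 0.0
    return n_within, n_total, frac
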