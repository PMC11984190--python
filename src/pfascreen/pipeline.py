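"""End-to-end annotation: match -> reconcile -> series -> flags -> grades.

This is the engine behind the ``annotate`` command: it consumes feature
records, a CCS library, the repeating-units table and a run
configuration, and produces one :class:`~pfascreen.io_tables.AnnotationRecord`
per feature plus the detected series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem_core import isotope_m1_fraction, kaufmann_point, mass_defect
from .config import RunConfig
from .homolog_series import SeriesAssignment, detect_series, flag_order
from .io_tables import (
    AnnotationRecord,
    CcsLibraryEntry,
    FeatureRecord,
    RepeatingUnit,
    SuspectEntry,
)
from .library_matching import (
    MatchEvidence,
    match_feature,
    match_suspect_list,
    reconcile_co2_loss,
)
from .scoring import (
    A_GRADES,
    EvidenceBundle,
    finalize_grades,
    md_in_window,
    pcl_for,
)

__all__ = ["AnnotationResult", "annotate"]

_TRUTHY = {"true", "yes", "1"}


@dataclass
class AnnotationResult:
    annotations: dict[str, AnnotationRecord]
    series: list[SeriesAssignment]
    evidences: dict[str, list[MatchEvidence]] = field(default_factory=dict)
    grades: dict[str, str] = field(default_factory=dict)

    def grade_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.grades.values():
            counts[g] = counts.get(g, 0) + 1
        return counts


def _extra_bool(feature: FeatureRecord, column: str | None) -> bool:
    if not column:
        return False
    return feature.extras.get(column, "").strip().lower() in _TRUTHY


def _extra_float(feature: FeatureRecord, column: str | None) -> float | None:
    if not column:
        return None
    cell = feature.extras.get(column, "").strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        return None


def annotate(
    features: Sequence[FeatureRecord],
    library: Sequence[CcsLibraryEntry],
    units: Sequence[RepeatingUnit],
    config: RunConfig,
    suspects: Sequence[SuspectEntry] = (),
) -> AnnotationResult:
    """Annotate every feature; each one receives exactly one grade."""
    by_id = {f.feature_id: f for f in features}

    # 1. library matching + CO2-loss reconciliation
    evidences: dict[str, list[MatchEvidence]] = {}
    for f in features:
        evs = match_feature(f, library, config)
        evidences[f.feature_id] = reconcile_co2_loss(f, evs, library, config)

    # 2. suspect-list cross-reference (mass-only)
    suspect_hits: dict[str, list[SuspectEntry]] = {}
    if suspects:
        for f in features:
            hits = match_suspect_list(f, suspects, config)
            if hits:
                suspect_hits[f.feature_id] = hits

    # 3. series detection and order flagging
    series = detect_series(features, units, config)
    series = flag_order(series, by_id, enabled=config.flag_order)

    membership: dict[str, list[SeriesAssignment]] = {}
    for s in series:
        for fid in s.member_ids:
            membership.setdefault(fid, []).append(s)

    # 4. evidence bundles
    bundles: dict[str, EvidenceBundle] = {}
    siblings: dict[str, set[str]] = {}
    for f in features:
        fid = f.feature_id
        evs = evidences[fid]
        full_match = any(ev.ccs_match for ev in evs)
        conflict = any(ev.co2_loss_conflict for ev in evs) and not full_match
        in_series = membership.get(fid, [])
        eff = max((s.effective_size for s in in_series), default=0)
        sibs: set[str] = set()
        for s in in_series:
            sibs.update(m for m in s.member_ids if m != fid)
        siblings[fid] = sibs
        bundles[fid] = EvidenceBundle(
            mass_match=bool(evs) or fid in suspect_hits,
            ccs_match=full_match,
            class_fragment=_extra_bool(f, config.columns.class_fragment),
            pfas_fragment=_extra_bool(f, config.columns.pfas_fragment),
            common_f_fragment=_extra_bool(f, config.columns.common_f_fragment),
            md_in_window=md_in_window(f.mz, config.md_window),
            series_effective_size=eff,
            co2_loss_conflict=conflict,
        )

    # 5. grades to fixed point, then PCL with sibling context
    grades = finalize_grades(bundles, siblings)

    annotations: dict[str, AnnotationRecord] = {}
    for f in features:
        fid = f.feature_id
        evs = evidences[fid]
        best = _best_evidence(evs)
        ann = AnnotationRecord(feature_id=fid)
        in_series = membership.get(fid, [])
        if in_series:
            primary = max(in_series, key=lambda s: (s.effective_size, -s.series_id))
            ann.series_id = primary.series_id
            ann.series_unit = primary.unit
            ann.n_in_series = primary.effective_size
            ann.rt_flag = any(s.rt_flags.get(fid, False) for s in in_series)
            ann.dt_flag = any(s.dt_flags.get(fid, False) for s in in_series)
        if best is not None:
            ann.match_name = best.entry.name
            ann.match_formula = str(best.entry.neutral_formula)
            ann.match_adduct = best.entry.adduct_label
            ann.mass_error_da = best.mass_error_da
            ann.mass_error_ppm = best.mass_error_ppm
            ann.ccs_error_pct = best.ccs_error_pct
        elif fid in suspect_hits:
            hit = suspect_hits[fid][0]
            ann.match_name = hit.name
            ann.match_formula = str(hit.formula) if hit.formula else ""
            ann.match_adduct = "mass-only"
            ann.mass_error_da = f.mz - hit.mz
            ann.mass_error_ppm = (f.mz - hit.mz) / hit.mz * 1e6
        ann.co2_loss_conflict = bundles[fid].co2_loss_conflict
        ann.md_flag = bundles[fid].md_in_window
        ann.mass_defect = mass_defect(f.mz)

        m1 = _extra_float(f, config.columns.m1_pct)
        if m1 is None and best is not None:
            m1 = isotope_m1_fraction(best.entry.neutral_formula)
        if m1 is not None:
            kp = kaufmann_point(f.mz, m1)
            if kp is not None:
                ann.ecn = kp.ecn
                ann.md_over_ecn = kp.md_over_ecn
                ann.mz_over_ecn = kp.mz_over_ecn

        ann.grade = grades[fid]
        sib_has_a = any(grades.get(s) in A_GRADES for s in siblings[fid])
        ann.pcl = pcl_for(ann.grade, sibling_has_a=sib_has_a)
        annotations[fid] = ann

    return AnnotationResult(
        annotations=annotations, series=series, evidences=evidences, grades=grades
    )


def _best_evidence(evs: Sequence[MatchEvidence]) -> MatchEvidence | None:
    if not evs:
        return None
    # Prefer a full (mass + CCS) match over the raw mass-error ordering.
    for ev in evs:
        if ev.ccs_match:
            return ev
    return evs[0]
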