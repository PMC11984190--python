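"""Nontarget filtering cascade for features without target annotations.

Stages run in a fixed order, and each feature is removed at exactly one
stage or kept:

1. ``blank_ratio``   — mean sample abundance must be >= ratio (default 5)
                       times the mean field-blank abundance;
2. ``background``    — features at the same order of magnitude across all
                       sample types (ratio of type means < 10, all types
                       detected) are background ions or in-source
                       fragments of spiked standards;
3. ``single_sample`` — features detected in fewer than two samples;
4. ``order_flag``    — series members flagged "RT not ordered" or
                       "DT not ordered";
5. ``e_score``       — features graded E (likely not PFAS);
6. ``trendline``     — CCS must lie on or below the PFAS ceiling
                       CCS = slope x m/z + intercept (defaults
                       0.1799 / 96.308).

The cascade is idempotent: re-running it on its own output removes
nothing further.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .io_tables import FeatureRecord

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

__all__ = [
    "STAGES",
    "FilterTrace",
    "blank_ratio_filter",
    "background_filter",
    "single_sample_filter",
    "trendline_filter",
    "fit_threshold_line",
    "apply_cascade",
]

STAGES = ("blank_ratio", "background", "single_sample", "order_flag", "e_score", "trendline")


@dataclass(frozen=True)
class FilterTrace:
    feature_id: str
    stage_removed: str  # one of STAGES or "kept"
    details: str = ""


def _role_columns(sample_roles: Mapping[str, str], role: str) -> list[str]:
    return [sid for sid, r in sample_roles.items() if r == role]


def _mean_over(feature: FeatureRecord, cols: Sequence[str]) -> float:
    if not cols:
        return 0.0
    return float(np.mean([feature.abundance(c) for c in cols]))


def blank_ratio_filter(
    features: Sequence[FeatureRecord],
    sample_roles: Mapping[str, str],
    ratio: float = 5.0,
) -> dict[str, bool]:
    """Keep iff mean sample abundance >= ratio x mean field-blank abundance.

    A zero blank mean keeps the feature: absence from blanks is the
    strongest evidence against contamination.  Without field-blank
    columns the filter is inapplicable and everything passes.
    """
    sample_cols = _role_columns(sample_roles, "sample")
    blank_cols = _role_columns(sample_roles, "field_blank")
    out = {}
    for f in features:
        if not blank_cols:
            out[f.feature_id] = True
            continue
        blank_mean = _mean_over(f, blank_cols)
        out[f.feature_id] = (
            True if blank_mean == 0 else _mean_over(f, sample_cols) >= ratio * blank_mean
        )
    return out


def background_filter(
    features: Sequence[FeatureRecord],
    sample_roles: Mapping[str, str],
    fold: float = 10.0,
) -> dict[str, bool]:
    """Remove features at the same order of magnitude in all sample types.

    Sample types are the distinct roles present in ``sample_roles``.  A
    feature is removed when it is detected in every type and the ratio of
    the largest to the smallest type mean is below ``fold``; a zero mean
    in any type means the feature is not ubiquitous and is kept.  With a
    single type the filter is inapplicable.
    """
    roles = sorted({r for r in sample_roles.values()})
    cols_by_role = {r: _role_columns(sample_roles, r) for r in roles}
    out = {}
    for f in features:
        if len(roles) < 2:
            out[f.feature_id] = True
            continue
        means = [_mean_over(f, cols_by_role[r]) for r in roles]
        if min(means) <= 0:
            out[f.feature_id] = True
            continue
        out[f.feature_id] = max(means) / min(means) >= fold
    return out


def single_sample_filter(
    features: Sequence[FeatureRecord],
    sample_roles: Mapping[str, str],
) -> dict[str, bool]:
    """Keep iff detected (abundance > 0) in at least two sample columns."""
    sample_cols = _role_columns(sample_roles, "sample")
    return {
        f.feature_id: sum(1 for c in sample_cols if f.abundance(c) > 0) >= 2
        for f in features
    }


def trendline_filter(
    features: Sequence[FeatureRecord],
    slope: float = 0.1799,
    intercept: float = 96.308,
) -> dict[str, bool]:
    """Keep iff CCS <= slope x m/z + intercept (on the line is kept)."""
    return {f.feature_id: f.ccs <= slope * f.mz + intercept for f in features}


def fit_threshold_line(
    confirmed: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Fit a maximum-CCS ceiling from confirmed (m/z, CCS) points.

    Ordinary least squares, with the intercept raised by the largest
    positive residual so every confirmed point lies on or below the line.
    """
    if len(confirmed) < 2:
        raise ValueError("need at least two confirmed (mz, ccs) points")
    mz = np.asarray([p[0] for p in confirmed], dtype=float)
    ccs = np.asarray([p[1] for p in confirmed], dtype=float)
    slope, intercept = np.polyfit(mz, ccs, 1)
    resid = ccs - (slope * mz + intercept)
    return float(slope), float(intercept + max(0.0, float(resid.max())))


def apply_cascade(
    features: Sequence[FeatureRecord],
    sample_roles: Mapping[str, str],
    config: "RunConfig",
    grades: Mapping[str, str] | None = None,
    order_flagged: Iterable[str] = (),
) -> list[FilterTrace]:
    """Run all six stages in order; one trace per feature.

    ``order_flagged`` lists feature ids carrying an RT/DT order flag in
    their series; ``grades`` supplies confidence grades for the E-score
    stage (stage skipped when absent).
    """
    flagged = set(order_flagged)
    keep_blank = blank_ratio_filter(features, sample_roles, config.blank_ratio)
    keep_bg = background_filter(features, sample_roles)
    keep_single = single_sample_filter(features, sample_roles)
    keep_trend = trendline_filter(
        features, config.trendline_slope, config.trendline_intercept
    )
    traces = []
    for f in features:
        fid = f.feature_id
        if not keep_blank[fid]:
            traces.append(FilterTrace(fid, "blank_ratio", "sample mean below ratio x field-blank mean"))
        elif not keep_bg[fid]:
            traces.append(FilterTrace(fid, "background", "same order of magnitude in all sample types"))
        elif not keep_single[fid]:
            traces.append(FilterTrace(fid, "single_sample", "detected in fewer than two samples"))
        elif fid in flagged:
            traces.append(FilterTrace(fid, "order_flag", "RT or DT not ordered within series"))
        elif grades is not None and grades.get(fid) == "E":
            traces.append(FilterTrace(fid, "e_score", "graded E (likely not PFAS)"))
        elif not keep_trend[fid]:
            traces.append(FilterTrace(fid, "trendline", "CCS above the PFAS m/z-CCS ceiling"))
        else:
            traces.append(FilterTrace(fid, "kept"))
    return traces
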