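"""Homologous-series detection via Kendrick mass defect normalization.

Rescaling m/z so a chosen repeat unit (CF2 by default) has integer mass
maps every homologue ladder onto a shared Kendrick mass defect (KMD).
Two features belong together when their KMDs agree within a tolerance AND
their m/z difference is an integer number (gaps allowed) of repeat-unit
exact masses within the mass window; series are the transitive closure of
that pair relation, with singletons discarded.

Members whose retention time or drift time does not increase with m/z are
flagged ("RT not ordered" / "DT not ordered"): under reverse-phase
chromatography and for a fixed subclass, heavier homologues elute later
and drift longer.  Flagged members stay listed in the series but do not
count toward its effective size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .io_tables import FeatureRecord, RepeatingUnit

if TYPE_CHECKING:  # pragma: no cover
    from .config import RunConfig

__all__ = [
    "SeriesAssignment",
    "kendrick_mass",
    "kendrick_mass_defect",
    "detect_series",
    "flag_order",
]


def kendrick_mass(mz: float, unit: RepeatingUnit) -> float:
    """Kendrick mass: m/z rescaled so the repeat unit has integer mass."""
    return mz * unit.nominal_mass / unit.exact_mass


def kendrick_mass_defect(mz: float, unit: RepeatingUnit) -> float:
    """KMD = round(KM) - KM; homologues of one ladder share this value."""
    km = kendrick_mass(mz, unit)
    return float(round(km) - km)


@dataclass
class SeriesAssignment:
    """A detected homologue ladder for one repeat unit."""

    series_id: int
    unit: str
    kmd: float
    member_ids: list[str]
    rt_flags: dict[str, bool] = field(default_factory=dict)
    dt_flags: dict[str, bool] = field(default_factory=dict)
    effective_size: int = 0

    def flagged(self, feature_id: str) -> bool:
        return self.rt_flags.get(feature_id, False) or self.dt_flags.get(feature_id, False)


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _pair_related(dmz: float, dkmd: float, unit: RepeatingUnit, mz_tol: float, kmd_tol: float) -> bool:
    if abs(dkmd) > kmd_tol:
        return False
    k = round(abs(dmz) / unit.exact_mass)
    if k < 1:
        return False
    return abs(abs(dmz) - k * unit.exact_mass) <= mz_tol


def detect_series(
    features: Sequence[FeatureRecord],
    units: Sequence[RepeatingUnit],
    config: "RunConfig",
) -> list[SeriesAssignment]:
    """Group features into homologue ladders per enabled repeat unit.

    Series ids are assigned 1..n in ascending order of the minimum member
    m/z (across units), so output is invariant to input row order up to
    renumbering.  A feature joins at most one series per unit.
    """
    groups: list[tuple[RepeatingUnit, list[FeatureRecord], float]] = []
    for unit in units:
        if not unit.enabled:
            continue
        n = len(features)
        if n < 2:
            continue
        mz = np.array([f.mz for f in features])
        kmd = np.array([kendrick_mass_defect(m, unit) for m in mz])
        order = np.argsort(kmd, kind="stable")
        ds = _DisjointSet(n)
        # Pairs must agree in KMD within kmd_tol: scan a sliding window
        # over the KMD-sorted order so only candidate pairs are examined.
        for a in range(n):
            i = order[a]
            for b in range(a + 1, n):
                j = order[b]
                if kmd[j] - kmd[i] > config.kmd_tol:
                    break
                if _pair_related(mz[j] - mz[i], kmd[j] - kmd[i], unit, config.mz_tol_da, config.kmd_tol):
                    ds.union(i, j)
        buckets: dict[int, list[int]] = {}
        for i in range(n):
            buckets.setdefault(ds.find(i), []).append(i)
        for members in buckets.values():
            if len(members) < 2:
                continue
            recs = sorted((features[i] for i in members), key=lambda f: f.mz)
            groups.append((unit, recs, min(f.mz for f in recs)))

    groups.sort(key=lambda g: (g[2], g[0].label))
    out = []
    for sid, (unit, recs, _) in enumerate(groups, start=1):
        ids = [f.feature_id for f in recs]
        out.append(
            SeriesAssignment(
                series_id=sid,
                unit=unit.label,
                kmd=float(np.mean([kendrick_mass_defect(f.mz, unit) for f in recs])),
                member_ids=ids,
                rt_flags={fid: False for fid in ids},
                dt_flags={fid: False for fid in ids},
                effective_size=len(ids),
            )
        )
    return out


def flag_order(
    series: Sequence[SeriesAssignment],
    features_by_id: Mapping[str, FeatureRecord],
    enabled: bool = True,
) -> list[SeriesAssignment]:
    """Flag members that break the increasing RT/DT-with-m/z order.

    Greedy sequential scan in ascending m/z: a member whose RT (DT) does
    not exceed the last unflagged member's RT (DT) gets the corresponding
    flag and does not advance the running values.  With flagging disabled
    every member counts toward the effective size.
    """
    out: list[SeriesAssignment] = []
    for s in series:
        rt_flags = {fid: False for fid in s.member_ids}
        dt_flags = {fid: False for fid in s.member_ids}
        if enabled:
            last_rt = last_dt = -np.inf
            for fid in s.member_ids:  # already ascending in m/z
                f = features_by_id[fid]
                rt_bad = f.rt <= last_rt
                dt_bad = f.dt <= last_dt
                rt_flags[fid] = rt_bad
                dt_flags[fid] = dt_bad
                if not (rt_bad or dt_bad):
                    last_rt, last_dt = f.rt, f.dt
        effective = sum(
            1 for fid in s.member_ids if not (rt_flags[fid] or dt_flags[fid])
        )
        out.append(
            replace(
                s,
                rt_flags=rt_flags,
                dt_flags=dt_flags,
                effective_size=effective,
            )
        )
    return out
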