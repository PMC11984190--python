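"""Kendrick normalization and series detection vs a brute-force oracle."""

import numpy as np
import pytest

from pfascreen.config import RunConfig
from pfascreen.homolog_series import (
    detect_series,
    flag_order,
    kendrick_mass_defect,
)
from pfascreen.io_tables import default_repeating_units, make_repeating_unit

from conftest import make_feature

CF2_EXACT = 49.996806


@pytest.fixture
def cfg():
    return RunConfig()


class TestKendrick:
    def test_pfoa_kmd(self, cf2):
        # 413 - 412.9664 * 50 / 49.996806
        assert kendrick_mass_defect(412.9664, cf2) == pytest.approx(0.0072, abs=1e-4)

    def test_homolog_invariance(self, cf2):
        base = kendrick_mass_defect(412.9664, cf2)
        for k in range(1, 8):
            assert kendrick_mass_defect(412.9664 + k * cf2.exact_mass, cf2) == pytest.approx(
                base, abs=1e-4
            )

    def test_exact_multiple_is_fixed_point(self, cf2):
        assert kendrick_mass_defect(4 * cf2.exact_mass, cf2) == pytest.approx(0.0, abs=1e-9)


def _brute_force_groups(features, unit, mz_tol, kmd_tol):
    """Oracle: O(n^2) pair relation + BFS transitive closure."""
    n = len(features)
    mz = np.array([f.mz for f in features])
    kmd = np.array([kendrick_mass_defect(m, unit) for m in mz])
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if abs(kmd[i] - kmd[j]) > kmd_tol:
                continue
            dmz = abs(mz[i] - mz[j])
            k = round(dmz / unit.exact_mass)
            if k >= 1 and abs(dmz - k * unit.exact_mass) <= mz_tol:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    groups = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        if len(comp) >= 2:
            groups.append(frozenset(features[u].feature_id for u in comp))
    return set(groups)


def _series_sets(series):
    return {frozenset(s.member_ids) for s in series}


class TestDetectSeries:
    def test_planted_ladder_among_decoys(self, cfg, cf2):
        rng = np.random.default_rng(42)
        feats = [
            make_feature(f"P{k}", 412.9664 + k * CF2_EXACT, rt=5 + k, dt=20 + k)
            for k in range(3)
        ]
        # decoys: random positive-defect masses off the CF2 lattice
        for i in range(50):
            feats.append(
                make_feature(
                    f"D{i}",
                    float(rng.integers(200, 900)) + float(rng.uniform(0.1, 0.45)),
                    rt=float(rng.uniform(1, 12)),
                    dt=float(rng.uniform(15, 45)),
                )
            )
        series = detect_series(feats, default_repeating_units(), cfg)
        oracle = _brute_force_groups(feats, cf2, cfg.mz_tol_da, cfg.kmd_tol)
        assert _series_sets(series) == oracle
        assert frozenset({"P0", "P1", "P2"}) in _series_sets(series)

    def test_off_ladder_spacing_rejected(self, cfg):
        feats = [make_feature("A", 400.0), make_feature("B", 450.5)]
        assert detect_series(feats, default_repeating_units(), cfg) == []

    def test_gap_in_ladder_allowed(self, cfg):
        feats = [
            make_feature("A", 412.9664),
            make_feature("B", 412.9664 + 3 * CF2_EXACT),
        ]
        series = detect_series(feats, default_repeating_units(), cfg)
        assert len(series) == 1

    def test_disabled_unit_detects_nothing(self, cfg):
        unit = make_repeating_unit("CF2CF2O", enabled=False)
        feats = [make_feature("A", 400.0), make_feature("B", 400.0 + unit.exact_mass)]
        assert detect_series(feats, [unit], cfg) == []

    def test_permutation_invariance(self, cfg):
        rng = np.random.default_rng(3)
        feats = [
            make_feature(f"P{k}", 312.97 + k * CF2_EXACT) for k in range(4)
        ] + [
            make_feature(f"D{i}", float(rng.uniform(200, 900)))
            for i in range(60)
        ]
        base = _series_sets(detect_series(feats, default_repeating_units(), cfg))
        for seed in (1, 2, 3):
            perm = list(feats)
            np.random.default_rng(seed).shuffle(perm)
            assert _series_sets(detect_series(perm, default_repeating_units(), cfg)) == base

    def test_all_members_share_kmd_posthoc(self, cfg, cf2):
        rng = np.random.default_rng(9)
        feats = [
            make_feature(f"F{i}", float(rng.uniform(200, 900))) for i in range(200)
        ]
        for s in detect_series(feats, default_repeating_units(), cfg):
            kmds = [
                kendrick_mass_defect(next(f.mz for f in feats if f.feature_id == fid), cf2)
                for fid in s.member_ids
            ]
            assert max(kmds) - min(kmds) <= cfg.kmd_tol + 1e-12

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_tables(self, cfg, cf2, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 200))
        feats = []
        # half pure noise, half noisy ladders
        for i in range(n // 2):
            feats.append(make_feature(f"N{i}", float(rng.uniform(200, 900))))
        base = float(rng.uniform(250, 400))
        for i in range(n - n // 2):
            feats.append(
                make_feature(
                    f"L{i}",
                    base
                    + float(rng.integers(0, 8)) * CF2_EXACT
                    + float(rng.normal(0, 0.004)),
                )
            )
        series = detect_series(feats, default_repeating_units(), cfg)
        assert _series_sets(series) == _brute_force_groups(
            feats, cf2, cfg.mz_tol_da, cfg.kmd_tol
        )

    def test_series_ids_ascend_with_min_mz(self, cfg):
        feats = [
            make_feature("A1", 500.0 - 0.0336),
            make_feature("A2", 500.0 - 0.0336 + CF2_EXACT),
            make_feature("B1", 300.0 - 0.05),
            make_feature("B2", 300.0 - 0.05 + CF2_EXACT),
        ]
        series = detect_series(feats, default_repeating_units(), cfg)
        assert [s.series_id for s in series] == [1, 2]
        assert series[0].member_ids[0] == "B1"


class TestFlagOrder:
    def _series(self, cfg, rts, dts):
        feats = [
            make_feature(f"M{k}", 312.97 + k * CF2_EXACT, rt=rts[k], dt=dts[k])
            for k in range(len(rts))
        ]
        series = detect_series(feats, default_repeating_units(), cfg)
        assert len(series) == 1
        by_id = {f.feature_id: f for f in feats}
        return flag_order(series, by_id, enabled=True)[0], by_id

    def test_rt_regression_flagged(self, cfg):
        s, _ = self._series(cfg, rts=[5.1, 6.0, 5.8], dts=[20, 21, 22])
        assert s.rt_flags == {"M0": False, "M1": False, "M2": True}
        assert s.effective_size == 2

    def test_monotone_unflagged(self, cfg):
        s, _ = self._series(cfg, rts=[5.1, 6.0, 6.8], dts=[20, 21, 22])
        assert not any(s.rt_flags.values()) and not any(s.dt_flags.values())
        assert s.effective_size == 3

    def test_flagged_member_does_not_advance_running_value(self, cfg):
        # M1 regresses; M2 must be compared against M0, not M1
        s, _ = self._series(cfg, rts=[5.0, 4.0, 5.5], dts=[20, 21, 22])
        assert s.rt_flags == {"M0": False, "M1": True, "M2": False}
        assert s.effective_size == 2

    def test_disabled_counts_everyone(self, cfg):
        feats = [
            make_feature(f"M{k}", 312.97 + k * CF2_EXACT, rt=10 - k, dt=20 + k)
            for k in range(3)
        ]
        series = detect_series(feats, default_repeating_units(), cfg)
        by_id = {f.feature_id: f for f in feats}
        s = flag_order(series, by_id, enabled=False)[0]
        assert s.effective_size == 3
        assert not any(s.rt_flags.values())

    def test_flagged_members_stay_in_series(self, cfg):
        s, _ = self._series(cfg, rts=[5.1, 6.0, 5.8], dts=[20, 21, 22])
        assert set(s.member_ids) == {"M0", "M1", "M2"}
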