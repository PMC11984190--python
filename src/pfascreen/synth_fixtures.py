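"""Seedable synthetic LC-IM-HRMS scenarios with ground truth.

The generator emulates the structure of a standard-mix / wastewater
experiment: a handful of PFAS subclasses planted as exact CF2 homologue
ladders with monotone retention and drift times and subclass-specific
CCS-vs-m/z trends sitting below the PFAS ceiling line, a matching CCS
library ([M-H]- entries, plus [M-H-CO2]- entries for carboxylate-like
subclasses), background decoys with biomolecule-like positive mass
defects and CCS above the ceiling, field-blank contaminants, and
optionally in-source CO2-loss fragment features whose m/z matches the
CO2-loss entry while their CCS still matches the precursor entry.

Identical :class:`ScenarioSpec` values produce byte-identical CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import Formula, adduct_mz, mass_defect
from .io_tables import (
    ColumnMapping,
    FeatureRecord,
    default_repeating_units,
    read_ccs_library,
    read_feature_table,
    write_repeating_units,
    write_sample_roles,
)

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "BenchmarkResult",
    "generate_scenario",
    "write_scenario",
    "benchmark",
]

CF2_EXACT = 49.996806  # monoisotopic CF2, Da

#: Homologue-class templates: name prefix and counts as a function of the
#: perfluorinated chain length n.  Consecutive n differ by exactly CF2.
_CLASS_TEMPLATES: tuple[tuple[str, bool, Callable[[int], dict[str, int]]], ...] = (
    ("PFCA", True, lambda n: {"C": n, "H": 1, "F": 2 * n - 1, "O": 2}),
    ("PFSA", False, lambda n: {"C": n, "H": 1, "F": 2 * n + 1, "S": 1, "O": 3}),
    ("FASA", False, lambda n: {"C": n, "H": 2, "F": 2 * n + 1, "N": 1, "S": 1, "O": 2}),
    ("PFECA", True, lambda n: {"C": n, "H": 1, "F": 2 * n - 1, "O": 3}),
    ("FTCA", False, lambda n: {"C": n, "H": 3, "F": 2 * n - 3, "O": 2}),
    ("FTS", False, lambda n: {"C": n, "H": 5, "F": 2 * n - 3, "S": 1, "O": 3}),
    ("MeFASA", False, lambda n: {"C": n, "H": 4, "F": 2 * n - 1, "N": 1, "S": 1, "O": 2}),
    ("PFdiCA", False, lambda n: {"C": n, "H": 2, "F": 2 * n - 2, "O": 4}),
    ("PFESA", False, lambda n: {"C": n, "H": 1, "F": 2 * n + 1, "S": 1, "O": 4}),
    ("FTs-O4", False, lambda n: {"C": n, "H": 4, "F": 2 * n - 3, "S": 1, "O": 4}),
)


@dataclass(frozen=True)
class ScenarioSpec:
    """All knobs of a synthetic scenario; identical spec => identical bytes.

    Noise defaults sit well inside the matching tolerances (1 ppm mass
    noise against a 0.01 Da window, 0.3% CCS noise against a 2% window)
    so that, with full library coverage, every planted feature is
    annotatable; decoy mass defects are drawn from a biomolecule-like
    positive band and decoy CCS sits above the PFAS ceiling line.
    """

    seed: int = 1
    n_series: int = 10
    series_len_range: tuple[int, int] = (4, 8)
    n_decoys: int = 500
    decoy_md_range: tuple[float, float] = (0.05, 0.45)
    decoy_mz_range: tuple[float, float] = (220.0, 1000.0)
    mz_noise_ppm: float = 1.0
    ccs_noise_pct: float = 0.3
    rt_jitter_min: float = 0.02
    dt_jitter_ms: float = 0.05
    blank_contamination: float = 0.10
    co2_loss_fraction: float = 0.0
    library_coverage: float = 1.0
    n_samples: int = 4
    n_field_blanks: int = 2
    n_lab_blanks: int = 1
    adversarial: int = 0  # count of on-ladder decoys to plant

    def __post_init__(self) -> None:
        lo, hi = self.series_len_range
        if not (2 <= lo <= hi):
            raise ValueError("series_len_range must satisfy 2 <= min <= max")
        if hi > 40:
            raise ValueError("series longer than the usable mass range")
        if not 0.0 <= self.library_coverage <= 1.0:
            raise ValueError("library_coverage must be in [0, 1]")
        if not 0.0 <= self.co2_loss_fraction <= 1.0:
            raise ValueError("co2_loss_fraction must be in [0, 1]")


@dataclass
class Scenario:
    features: pd.DataFrame
    library: pd.DataFrame
    truth: pd.DataFrame
    sample_roles: dict[str, str]
    spec: ScenarioSpec

    def feature_records(self) -> list[FeatureRecord]:
        recs = []
        for _, row in self.features.iterrows():
            recs.append(
                FeatureRecord(
                    feature_id=row["feature_id"],
                    mz=float(row["mz"]),
                    rt=float(row["rt"]),
                    dt=float(row["dt"]),
                    ccs=float(row["ccs"]),
                    abundances={
                        sid: float(row[sid]) for sid in self.sample_roles
                    },
                )
            )
        return recs


def _sample_columns(spec: ScenarioSpec) -> dict[str, str]:
    roles: dict[str, str] = {}
    for i in range(spec.n_samples):
        roles[f"S{i + 1}"] = "sample"
    for i in range(spec.n_field_blanks):
        roles[f"FB{i + 1}"] = "field_blank"
    for i in range(spec.n_lab_blanks):
        roles[f"LB{i + 1}"] = "lab_blank"
    return roles


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Build (feature table, CCS library, truth labels) for a spec."""
    rng = np.random.default_rng(spec.seed)
    roles = _sample_columns(spec)
    sample_cols = list(roles)
    dt_per_ccs = 0.17  # ms per A^2, fixed drift-time proxy

    feat_rows: list[dict] = []
    lib_rows: list[dict] = []
    truth_rows: list[dict] = []

    def add_feature(fid, mz_true, ccs_true, rt, dt, abund: Mapping[str, float]) -> None:
        mz = mz_true * (1.0 + rng.normal(0.0, spec.mz_noise_ppm) * 1e-6)
        ccs = ccs_true * (1.0 + rng.normal(0.0, spec.ccs_noise_pct) / 100.0)
        row = {
            "feature_id": fid,
            "mz": round(mz, 6),
            "rt": round(rt + rng.normal(0.0, spec.rt_jitter_min), 4),
            "dt": round(dt + rng.normal(0.0, spec.dt_jitter_ms), 4),
            "ccs": round(ccs, 3),
        }
        for sid in sample_cols:
            row[sid] = round(float(abund.get(sid, 0.0)), 1)
        feat_rows.append(row)

    # ---- planted homologue series -------------------------------------
    for s_idx in range(spec.n_series):
        cls_name, is_carboxylate, counts_fn = _CLASS_TEMPLATES[
            s_idx % len(_CLASS_TEMPLATES)
        ]
        label = f"{cls_name}" if s_idx < len(_CLASS_TEMPLATES) else f"{cls_name}b"
        n0 = int(rng.integers(4, 7))
        length = int(rng.integers(spec.series_len_range[0], spec.series_len_range[1] + 1))
        slope = rng.uniform(0.115, 0.155)
        intercept = rng.uniform(65.0, 90.0)
        rt0 = rng.uniform(2.0, 6.0)
        drt = rng.uniform(0.3, 0.6)
        covered = rng.random(length) < spec.library_coverage
        for k in range(length):
            n = n0 + k
            formula = Formula.from_counts(counts_fn(n))
            name = f"{label}-C{n}"
            mz_true = adduct_mz(formula, "[M-H]-")
            ccs_true = slope * mz_true + intercept
            rt = rt0 + k * drt
            dt = dt_per_ccs * ccs_true
            base = 10.0 ** rng.uniform(4.5, 6.0)
            abund = {
                sid: base * rng.lognormal(0.0, 0.15) for sid in sample_cols
                if roles[sid] == "sample"
            }
            fid = f"P{s_idx + 1}_{k + 1}"
            add_feature(fid, mz_true, ccs_true, rt, dt, abund)
            truth_rows.append(
                {
                    "feature_id": fid,
                    "is_pfas": True,
                    "compound": name,
                    "formula": str(formula),
                    "series_label": label,
                    "in_library": bool(covered[k]),
                    "expected_tier": "A" if covered[k] else "series",
                }
            )
            if covered[k]:
                lib_rows.append(
                    {
                        "name": name,
                        "formula": str(formula),
                        "adduct": "[M-H]-",
                        "adduct_mz": round(mz_true, 6),
                        "ccs": round(ccs_true, 3),
                    }
                )
                if is_carboxylate:
                    # the CO2-loss fragment's own (smaller) mobility-cell CCS
                    lib_rows.append(
                        {
                            "name": name,
                            "formula": str(formula),
                            "adduct": "[M-H-CO2]-",
                            "adduct_mz": round(adduct_mz(formula, "[M-H-CO2]-"), 6),
                            "ccs": round(ccs_true * 0.90, 3),
                        }
                    )
            # in-source CO2-loss duplicate: m/z of the fragment, CCS of the
            # precursor (fragmentation happens after the drift cell)
            if is_carboxylate and rng.random() < spec.co2_loss_fraction:
                frag_mz = adduct_mz(formula, "[M-H-CO2]-")
                add_feature(
                    f"P{s_idx + 1}_{k + 1}-CO2",
                    frag_mz,
                    ccs_true,
                    rt,
                    dt,
                    {sid: 0.4 * a for sid, a in abund.items()},
                )
                truth_rows.append(
                    {
                        "feature_id": f"P{s_idx + 1}_{k + 1}-CO2",
                        "is_pfas": True,
                        "compound": name,
                        "formula": str(formula),
                        "series_label": f"{label}-CO2loss",
                        "in_library": bool(covered[k]),
                        "expected_tier": "C+" if covered[k] else "series",
                    }
                )

    planted_mz = [r["mz"] for r in feat_rows]

    # ---- decoys --------------------------------------------------------
    ceiling = lambda mz: 0.1799 * mz + 96.308
    n_contaminants = int(round(spec.blank_contamination * spec.n_decoys))
    for d in range(spec.n_decoys):
        nominal = int(rng.integers(*[int(v) for v in spec.decoy_mz_range]))
        md = rng.uniform(*spec.decoy_md_range)
        mz_true = nominal + md
        ccs_true = ceiling(mz_true) + rng.uniform(5.0, 60.0)
        rt = rng.uniform(0.5, 14.0)
        dt = dt_per_ccs * ccs_true
        base = 10.0 ** rng.uniform(3.5, 5.5)
        contaminated = d < n_contaminants
        abund: dict[str, float] = {}
        if contaminated:
            # present everywhere at the same order of magnitude
            for sid in sample_cols:
                if roles[sid] == "sample":
                    abund[sid] = base * rng.uniform(0.8, 2.5)
                else:
                    abund[sid] = base * rng.lognormal(0.0, 0.05)
        else:
            n_present = int(rng.integers(1, spec.n_samples + 1))
            present = rng.choice(
                [s for s in sample_cols if roles[s] == "sample"],
                size=n_present,
                replace=False,
            )
            for sid in present:
                abund[sid] = base * rng.lognormal(0.0, 0.3)
        fid = f"D{d + 1}"
        add_feature(fid, mz_true, ccs_true, rt, dt, abund)
        truth_rows.append(
            {
                "feature_id": fid,
                "is_pfas": False,
                "compound": "",
                "formula": "",
                "series_label": "blank_contaminant" if contaminated else "",
                "in_library": False,
                "expected_tier": "decoy",
            }
        )

    # ---- adversarial on-ladder decoys ---------------------------------
    for a in range(spec.adversarial):
        anchor = feat_rows[int(rng.integers(0, len(planted_mz)))]
        k = int(rng.integers(1, 4))
        mz_true = float(anchor["mz"]) + k * CF2_EXACT
        ccs_true = ceiling(mz_true) + rng.uniform(5.0, 30.0)
        rt = float(anchor["rt"]) + 0.45 * k
        dt = float(anchor["dt"]) + 1.0 * k
        abund = {
            sid: 10.0 ** rng.uniform(4.0, 5.0)
            for sid in sample_cols
            if roles[sid] == "sample"
        }
        fid = f"X{a + 1}"
        add_feature(fid, mz_true, ccs_true, rt, dt, abund)
        truth_rows.append(
            {
                "feature_id": fid,
                "is_pfas": False,
                "compound": "",
                "formula": "",
                "series_label": "adversarial",
                "in_library": False,
                "expected_tier": "decoy",
            }
        )

    features = pd.DataFrame(feat_rows)
    library = pd.DataFrame(
        lib_rows, columns=["name", "formula", "adduct", "adduct_mz", "ccs"]
    ).drop_duplicates(subset=["name", "adduct"], keep="first")
    truth = pd.DataFrame(truth_rows)
    return Scenario(features=features, library=library, truth=truth, sample_roles=roles, spec=spec)


def write_scenario(scenario: Scenario, outdir) -> dict[str, Path]:
    """Write features/library/repeating-units/truth/roles CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.csv",
        "library": outdir / "library.csv",
        "units": outdir / "repeating_units.csv",
        "truth": outdir / "truth.csv",
        "roles": outdir / "sample_roles.csv",
    }
    scenario.features.to_csv(paths["features"], index=False)
    scenario.library.to_csv(paths["library"], index=False)
    write_repeating_units(default_repeating_units(), paths["units"])
    scenario.truth.to_csv(paths["truth"], index=False)
    write_sample_roles(scenario.sample_roles, paths["roles"])
    return paths


def load_scenario_inputs(scenario: Scenario):
    """Round-trip a scenario through its CSV form into pipeline inputs."""
    import io as _io

    fbuf = _io.StringIO()
    scenario.features.to_csv(fbuf, index=False)
    fbuf.seek(0)
    feats = read_feature_table(
        fbuf, scenario.sample_roles, ColumnMapping(feature_id="feature_id")
    )
    lbuf = _io.StringIO()
    scenario.library.to_csv(lbuf, index=False)
    lbuf.seek(0)
    library = read_ccs_library(lbuf)
    return feats, library


# ---------------------------------------------------------------------------
# benchmarking

CONFIDENT_GRADES = frozenset({"A", "A-", "C+"})
_TIER_OK = frozenset({"A+", "A", "A-", "B+", "B", "B-", "C+"})


@dataclass(frozen=True)
class BenchmarkResult:
    """False-positive / false-negative rates against ground truth.

    ``fp_rate_confident``: fraction of A/A-/C+ features that are decoys;
    ``fp_rate_all``: fraction of all name-annotated features that are
    decoys; ``fn_rate``: fraction of planted, library-covered features not
    graded C+ or better.  Empty denominators yield 0.0.
    """

    fp_rate_confident: float
    fp_rate_all: float
    fn_rate: float
    fn_rate_by_formula: float
    n_confident: int
    n_annotated: int
    n_planted_covered: int


def benchmark(
    truth: pd.DataFrame,
    grades: Mapping[str, str],
    annotated_names: Mapping[str, str] | None = None,
) -> BenchmarkResult:
    """Score pipeline output against scenario truth labels.

    ``grades`` maps feature_id -> grade; ``annotated_names`` (optional)
    maps feature_id -> matched compound name ("" when unmatched).
    """
    truth_ids = set(truth["feature_id"])
    missing = truth_ids.symmetric_difference(grades.keys())
    if missing:
        raise ValueError(f"feature-id mismatch between truth and output: {sorted(missing)[:5]}")

    is_decoy = dict(zip(truth["feature_id"], ~truth["is_pfas"].astype(bool)))
    confident = [fid for fid, g in grades.items() if g in CONFIDENT_GRADES]
    fp_conf = (
        sum(1 for fid in confident if is_decoy[fid]) / len(confident)
        if confident
        else 0.0
    )

    if annotated_names is not None:
        annotated = [fid for fid, name in annotated_names.items() if name]
    else:
        annotated = confident
    fp_all = (
        sum(1 for fid in annotated if is_decoy.get(fid, False)) / len(annotated)
        if annotated
        else 0.0
    )

    planted = truth[(truth["is_pfas"].astype(bool)) & (truth["in_library"].astype(bool))]
    n_planted = len(planted)
    misses = [
        fid for fid in planted["feature_id"] if grades[fid] not in _TIER_OK
    ]
    fn = len(misses) / n_planted if n_planted else 0.0

    by_formula_total = planted["formula"].nunique()
    hit_formulas = {
        row.formula
        for row in planted.itertuples()
        if grades[row.feature_id] in _TIER_OK
    }
    fn_formula = (
        1.0 - len(hit_formulas) / by_formula_total if by_formula_total else 0.0
    )

    return BenchmarkResult(
        fp_rate_confident=fp_conf,
        fp_rate_all=fp_all,
        fn_rate=fn,
        fn_rate_by_formula=fn_formula,
        n_confident=len(confident),
        n_annotated=len(annotated),
        n_planted_covered=n_planted,
    )
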