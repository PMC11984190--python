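# pfascreen

Nontargeted annotation of per- and polyfluoroalkyl substances (PFASs) in
LC-IM-HRMS feature tables.

Environmental samples carry thousands of chromatographic features, of
which only a handful are PFASs, often at trace levels too low for useful
MS/MS spectra. Ion mobility offers an orthogonal, highly reproducible
identifier: the collision cross section (CCS, Å²), comparable across
drift-tube instruments to within ~2%. `pfascreen` takes an aligned 4-D
feature table — m/z, retention time, drift time, CCS, and one abundance
column per sample — and annotates candidate PFASs by combining:

- **accurate-mass + CCS library matching** (|Δm/z| ≤ 0.01 Da,
  |ΔCCS/CCS| ≤ 2% by default), including reconciliation of in-source CO2
  loss of perfluoroalkyl carboxylates, where the fragment's m/z matches
  the `[M−H−CO2]⁻` entry while its CCS still matches the `[M−H]⁻`
  precursor;
- **Kendrick-mass-defect homologous-series detection**: with
  KM = m/z × 50 / 49.996806, homologues differing by CF2 units share
  KMD = round(KM) − KM; ladders are grouped by shared KMD (±0.005) and
  integer CF2 spacing (±0.01 Da), with members breaking the expected
  RT/DT-increase-with-m/z order flagged;
- **mass-defect flagging** (window [−0.11, 0.12]) and the CCS-vs-m/z
  ceiling CCS ≤ 0.1799 × m/z + 96.308 that separates PFASs from
  biomolecule space;
- a **confidence grading scheme** (A+…E, mapped onto PFAS Confidence
  Levels 2b/2c/3d/5) that promotes series members with confidently
  identified siblings and caps CO2-loss conflicts at C+;
- a **blank/background filtering cascade** for nontarget review
  (≥5× field blank, cross-type background, single-sample, order-flag,
  E-score, trendline);
- a **seedable synthetic-scenario generator** with ground truth, used to
  measure false positive / false negative rates of the whole pipeline.

Everything is plain CSV in and out; no vendor binaries. The annotated
output file name always ends in `_FIN.csv`, with the input columns
carried through verbatim and the annotation columns appended.

## Worked example

Generate a synthetic scenario (4 planted homologue series, 60 decoys),
annotate it, and score against ground truth:

```sh
pfascreen simulate --seed 1 --n-series 4 --n-decoys 60 --out demo
pfascreen annotate --features demo/features.csv --library demo/library.csv \
    --units demo/repeating_units.csv --roles demo/sample_roles.csv \
    --id-column feature_id --out demo/results.csv
pfascreen benchmark --truth demo/truth.csv --fin demo/results_FIN.csv
```

The annotate step writes `demo/results_FIN.csv` plus a JSON summary:

```json
{
  "grade_counts": {"A": 27, "D-": 8, "E": 52},
  "n_features": 87,
  "n_library_entries": 38,
  "n_series": 6
}
```

All 27 planted, library-covered features are graded A (exact mass + CCS
match + 2 or more effective members in a CF2 series); the remaining
features are decoys graded D−/E (mass defect only, or nothing). Six
ladders were detected: the four planted series plus two chance decoy
pairings. The benchmark prints

```json
{
  "fn_rate": 0.0,
  "fp_rate_confident": 0.0,
  "n_confident": 27,
  "n_planted_covered": 27
}
```

i.e. no planted compound was missed (false negative rate 0%) and no
decoy reached a confident grade (A/A−/C+ false positive rate 0%).

Plots (`pfascreen plot --kind kmd|rt_mz|dt_mz|rt_dt|3d|kaufmann`) render
the classic nontarget views — KMD vs m/z, RT/DT vs m/z, and Kaufmann
space — colored by series or grade, with grade/series/range filters.

## Layout

- `src/pfascreen/chem_core.py` — formulas, masses, adducts, isotopes,
  Kaufmann coordinates, bounded formula prediction
- `src/pfascreen/io_tables.py` — CSV readers/writers and the FIN contract
- `src/pfascreen/library_matching.py` — mass/CCS matching, CO2-loss
  reconciliation, suspect lists
- `src/pfascreen/homolog_series.py` — KMD series detection and order flags
- `src/pfascreen/scoring.py` — grade rules and PCL mapping
- `src/pfascreen/nta_filters.py` — the nontarget filtering cascade
- `src/pfascreen/synth_fixtures.py` — scenario generator and benchmark
- `src/pfascreen/pipeline.py`, `cli_app.py`, `config.py` — orchestration,
  CLI, run configuration

See `docs/methods.md` for the underlying models, parameter defaults, and
known limitations.
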