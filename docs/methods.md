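# Methods

`pfascreen` annotates aligned 4-D LC-IM-HRMS features (m/z, retention
time, drift time, CCS, per-sample abundance) as candidate per- and
polyfluoroalkyl substances (PFASs). This note records the models and
procedures it implements, the parameters that matter, what the synthetic
data generator does and does not emulate, and the numerical choices made
where the design was open.

## Annotation model

**Library matching.** A feature matches a CCS-library entry when its m/z
lies within an absolute mass window of the entry's adduct m/z (default
0.01 Da); ppm error is reported for information only. The CCS comparison
is relative, `(measured − library) / library × 100`, matched within a
default 2% window — the reproducibility of drift-tube CCS values across
instruments. All entries passing the mass window are reported (isomers
and shared adduct masses are common), ranked by |ppm| then |CCS error|,
ties broken by library row order, and flagged ambiguous when two or more
pass. There is no winner-takes-all suppression: duplicate annotations of
one formula across features are all kept and graded.

**In-source CO2 loss.** Perfluoroalkyl carboxylates readily lose CO2
after the mobility cell, so the fragment ion's m/z is decoupled from the
precursor's CCS. When a feature mass-matches a `[M-H-CO2]-` entry, fails
its CCS window, but fits the same compound's `[M-H]-` CCS within
tolerance, the evidence is flagged as a CO2-loss conflict. Such features
never reach the A tier (the mass-matched entry's CCS did not match); in a
qualifying homologous series they grade C+ — the conflict itself ties the
feature to a confidently identified compound.

**Homologous series.** For each enabled repeat unit (CF2 by default,
nominal 50 Da, monoisotopic 49.996806 Da) the Kendrick mass is
`KM = m/z × nominal / exact` and the Kendrick mass defect is
`KMD = round(KM) − KM`; homologues of a ladder share KMD. Two features
are related when |ΔKMD| ≤ 0.005 and their m/z difference is within
0.01 Da of k × unit mass for some integer k ≥ 1 (gaps allowed). Series
are the transitive closure of this relation; singletons are discarded;
ids ascend with the minimum member m/z. Transitive closure means one bad
bridge can merge two ladders; this is accepted as the semantics of
KMD-bin grouping. The 0.005 KMD tolerance is half the mass window
expressed in defect units at the working mass range.

**Order flagging.** Within a subclass, heavier homologues elute later
(reverse phase) and drift longer. Members are scanned in ascending m/z
with a greedy keep-first rule: a member whose RT (DT) does not exceed the
last unflagged member's RT (DT) is flagged and does not advance the
running values. Flagged members stay in the series but do not count
toward its *effective size*. Greedy scanning (rather than a longest
increasing subsequence) is deterministic, cheap, and matches the
flag-then-keep behavior users of this workflow expect.

**Grading.** Each feature gets exactly one grade from a strictly ordered
rule table (see `scoring.assign_grade`): the A tier needs exact mass plus
structural evidence (CCS or class fragmentation), the B tier fragment
evidence (only available when an external MS/MS workflow supplies the
boolean columns), the C tier series membership plus a confident sibling,
the D tier series membership and/or mass-defect/exact-mass evidence, and
E none of the above. "2+ in series" counts the feature itself among the
effective members. Sibling thresholds are {A, A−} for C+ and any B or
better for C/C−. Because C grades depend on sibling grades, grading
iterates to a fixed point; two refinement passes suffice since A/B grades
are context-free. A+ is reserved for standard-confirmed targeted work
and is never emitted. Grades map to PFAS Confidence Levels: A → 2b,
B → 2c, C+ → 2c with an A sibling else 3d, C/C− → 3d, D/E → 5.

**Mass-defect window.** The flag window is [−0.11, 0.12] inclusive,
covering the large majority of curated PFAS structures; comparisons
carry a 1e-9 guard so endpoint values are inside regardless of binary
rounding. `round` is half-to-even for determinism on degenerate inputs.

**Kaufmann coordinates.** The equivalent carbon number is the M+1
isotope percentage divided by 1.0816 (the per-carbon ¹³C contribution,
in percent); the coordinates (mass defect / ECN, m/z / ECN) separate
fluorinated from CHNO biological space because fluorine adds mass but
almost nothing to M+1. The observed M+1 percentage is taken from a
mapped input column when present, else from the matched formula's
theoretical value (first-order: 1.0816 C + 0.0115 H + 0.3654 N +
0.0381 O + 0.8000 S, percent per atom — exact for the M+1 bin).

**Formula prediction.** Bounded exhaustive enumeration (defaults C≤60,
H≤80, F≤80, O≤20, N≤5, S≤4, P≤3, Cl≤4) of neutral formulas whose adduct
m/z lies within a ppm tolerance, pruned by suffix mass bounds. Filters:
integer ring-plus-double-bond equivalents ≥ 0 (an even-electron
deprotonated anion implies an integer-RDBE neutral), the permissive
fluorine sanity bound F ≤ 2C + 3, and presence of the atoms the adduct
removes. Ranked by |ppm|, then |ΔM+1%| when an observed value is given.
The electron mass (0.000549 Da) is included in all adduct m/z values; it
matters at the 0.01 Da scale.

## Nontarget filtering cascade

Fixed stage order; each feature is removed at exactly one stage or kept:

1. **blank_ratio** — mean abundance across `sample` columns must be
   ≥ 5× the mean across `field_blank` columns. A zero blank mean keeps
   the feature (absence from blanks is the strongest keep signal).
2. **background** — a feature detected in *every* sample type whose type
   means all lie within one order of magnitude (max/min < 10) is treated
   as a background ion or an in-source fragment of spiked standards.
   "Same order of magnitude" is formalized as max/min < 10; a zero mean
   in any type keeps the feature.
3. **single_sample** — detected in fewer than two sample columns.
4. **order_flag** — carries an RT/DT order flag in its series.
5. **e_score** — graded E.
6. **trendline** — CCS must lie on or below the PFAS ceiling
   CCS = 0.1799 × m/z + 96.308 (on the line is kept).
   `fit_threshold_line` re-derives such a ceiling from a user's confirmed
   (m/z, CCS) set: OLS, intercept raised by the largest positive residual.

The cascade is idempotent, and raising the blank ratio or lowering the
ceiling never re-admits a removed feature.

## Synthetic scenarios

The generator plants `n_series` CF2 homologue ladders drawn from ten
PFAS-like subclass templates (carboxylates, sulfonates, sulfonamides,
ether acids, fluorotelomer acids/sulfonates, ...), each with an exact
49.996806 Da m/z spacing, monotone RT (0.3–0.6 min per CF2) and DT
(proportional to CCS), and a subclass CCS trend (slope 0.115–0.155 Å²/Th,
intercept 65–90 Å²) below the PFAS ceiling. The library holds `[M-H]-`
entries for covered compounds and `[M-H-CO2]-` entries for
carboxylate-like classes (fragment CCS set to 0.90× the precursor, so a
precursor-CCS measurement fails its window by ~11%). Decoys carry
biomolecule-like mass defects (0.05–0.45) and CCS 5–60 Å² above the
ceiling: both properties place them structurally outside every planted
ladder's KMD band and outside the library mass windows, so confident
false positives are impossible by construction unless the adversarial
toggle plants on-ladder decoys. Blank contaminants appear in all sample
types at one order of magnitude. Default noise — 1 ppm mass, 0.3% CCS,
0.02 min RT, 0.05 ms DT — sits 6–20 sigma inside the matching windows:
these are the study conditions for the validation mirror, under which
the confident-grade false positive rate and covered-feature false
negative rate are 0% on every seed.

What the generator does **not** emulate: chromatographic peak shapes,
raw spectra, isotope envelopes beyond M+1, correlated (systematic) mass
or CCS drift, matrix-dependent ionization suppression, and real isomer
co-elution. Passing tests therefore demonstrate the correctness of the
annotation logic under its stated tolerances, not field performance on
vendor data.

Problem sizes used by the test suite and the acceptance script — 20
scenarios of ~560 features, 50 random tables of ≤300 features for the
brute-force series oracle, and ≥1000 property cases — were chosen as the
smallest sizes at which every structural claim above is exercised with
comfortable statistical margin.

## Known limitations

- Negative mode only by default; the adduct vocabulary
  (`[M-H]-`, `[M-H-CO2]-`, `[M+formate]-`) is user-extensible via
  `register_adduct`, but |z| > 1 is out of scope.
- No in-silico CCS prediction and no RT-based matching.
- B-tier grades require externally supplied fragment-evidence booleans;
  without MS/MS data the pipeline emits A, A−, C+, D+, D, D−, E only.
- The appended FIN column names are this package's own; other tools in
  this space do not publish a column contract.
- Multi-unit joint series are reported per unit, never merged.
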