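# Methods

## Data model and study design

The unit of analysis is an aligned feature table: one row per LC–MS
feature (id, m/z in Da, retention time in minutes, ion mode), one
column per sample, intensities as area-under-curve in arbitrary
counts. The experimental design assigns each sample a treatment —
`control` (solvent), `unlabeled_tracer`, `labeled_tracer` — a time
point, a replicate and a batch. The default layout is 3 treatments ×
4 time points (3, 9, 24, 48 h) × 3 replicates = 36 samples, with
positive- and negative-mode features held in one table and all screens
operating per ion mode.

Missing intensities are represented as missing (NaN), not zero, until
the flooring step materializes them to the noise floor. This keeps the
raw/processed distinction auditable; the table carries `floored` and
`normalized` flags and the pipeline refuses to normalize twice.

## Preprocessing

* **Noise flooring.** Every intensity below the floor, and every
  missing cell, is set to exactly the floor (default 500 counts for
  untargeted matrices; 10 for targeted ones). Idempotent by
  construction.
* **Internal-standard (IS) normalization.** Each ion mode's features
  are divided, per sample, by that sample's IS intensity in the same
  mode. The IS feature is located by m/z (±0.01 Da; lidocaine
  235.1805 for positive, 10-camphorsulfonic acid 231.0697 for
  negative); ties resolve to the highest total intensity and are
  logged. The IS row normalizes to 1 everywhere; an IS at the floor in
  some sample triggers a warning.

The intensity criterion of the screens (below) is evaluated on the
floored, pre-normalization table by default, because the noise level
is stated in raw counts and a 2× multiple of it is only meaningful on
that scale. A `screen_on_normalized` switch runs the screens on
normalized intensities for sensitivity analysis.

## Mass arithmetic

Atomic monoisotopic masses are embedded constants (8 decimals; light
isotopes from CODATA 2018, ²H and ³⁴S from AME2020), so results do not
depend on an external mass-table package or platform. Heavy labels are
distinct formula symbols (`D`/`[2H]`, `[34S]`). Three singly charged
adducts are built in — [M+H]⁺, [M−H]⁻, [2M+H]⁺ — with m/z =
multimer × M ± 1.00727646; users can define others.

The deuterium shift table used by the pair screen defaults to the
reported values {2: 2.0126, 3: 3.0189, 5: 5.0314, 10: 10.0628} Da
rather than recomputed products of the per-atom mass difference
(1.00628 Da), so that screens bit-match runs made with those printed
constants; a computed mode is available by config. The two modes agree
within 20 ppm at m/z 300 for 2, 5 and 10 atoms; the 3-atom printed
value (3.0189) differs from 3 × 1.00628 = 3.01883 in the fourth
decimal — the printed value is used verbatim, since the rounding
convention behind it is not recoverable. A ³⁴S spec (1.99580 Da per
atom; +2/+4 Da for one/two atoms) is provided for sulfur-tracer work.

## The screens

**Pair screen (criteria 1–4).** Candidate pairs are generated per ion
mode by a sorted-m/z window search per allowed shift; each candidate
is then tested:

1. *Intensity*: max over (treatment, time)-group means strictly
   greater than 2 × floor, for **both** members (the criterion is a
   record-level filter preceding pairing).
2. *Mass shift*: |Δm/z − shift(n)| ≤ 20 ppm × the **query** m/z,
   where the query is the lighter (unlabeled) member — the screen asks
   each unlabeled record for a heavier partner. The smallest matching
   n is reported.
3. *Co-elution*: |ΔRT| ≤ 0.05 min, boundary inclusive.
4. *Treatment maxima*: the unique argmax of the lighter member's
   group means lies in an unlabeled-tracer group and that of the
   heavier member in a labeled-tracer group. Ties disqualify —
   floored/flat profiles are noise, and a non-unique maximum carries
   no treatment information. A per-sample-max variant is available by
   config.

A feature may participate in several pairs; de-duplication belongs to
consolidation. Output order is deterministic (mode, unlabeled m/z,
labeled m/z) and per-criterion rejection tallies are logged so a count
discrepancy can be traced to a single criterion.

**Co-behavior screen (criteria 1, 5, 6).** Criterion 5 requires the
unique global maximum *or* minimum of the group means to lie in a
tracer group (same tie rule as criterion 4). Criterion 6 computes
Spearman rank correlations on replicate-level vectors matched across
treatments by (time, replicate) — 12 points in the default design —
requiring ρ(U, L) > 0.4 (strict) and both ρ(C, U), ρ(C, L) ≤ 0.2
(inclusive). Replicate-level vectors were chosen because 4-point
group-mean vectors make Spearman take only coarse values (steps of
0.2), which interacts badly with thresholds at 0.4/0.2; the group-mean
mode remains available by config. The replicate pairing is arbitrary
in principle (replicates are exchangeable across treatments); this is
a declared convention, not an inference. Constant vectors (e.g. a
feature at the floor throughout a treatment) make the correlation
undefined; such features are rejected rather than assigned a number.

**Consolidation.** Entries are linked when any of their neutral-mass
hypotheses (positive mode: [M+H]⁺ and [2M+H]⁺; negative: [M−H]⁻)
agree within 0.01 Da *and* RTs agree within 0.05 min; merged groups
are the connected components of this graph — the only
order-independent reading of "organize into one record". The
representative is the member with the highest maximal intensity; ties
break to lower m/z, then lexicographic id (logged). For pairs, linkage
is evaluated on the unlabeled member and the labeled members' mutual
consistency is checked, with a warning on mismatch. The 0.01 Da merge
tolerance reuses the annotation tolerance, since no separate
consolidation tolerance is documented; RT gating applies across ion
modes (both modes come from the same chromatographic run). Both are
config-exposed.

**Annotation.** |measured − theoretical adduct m/z| ≤ 0.01 Da against
the mode's precursor adduct, hits sorted by absolute error. The
bundled library holds the isothiocyanate-processing intermediates
(SFN–GSH, SFN–γEC, SFN–Cys, 4MSB-amine, raphanusamic acid,
glutathione, sulforaphane, procysteine) and 24 glucosinolate species
with formulas; it is a curated starting point, not a database — any
CSV with `name,formula` columns substitutes.

## Isotope-budget arithmetic

`labeled_fraction(i_mono, i_heavy) = i_heavy / (i_mono + i_heavy)` on
the designated fragment-ion channel pair, with no natural-abundance
correction (the implemented convention; enrichment values are
therefore slight overestimates at natural ³⁴S abundance ~4.2%).
`dose_per_plant` uses μM × mL = nmol; `recovery_percent` is
100 × Σ retained / dose.

## Synthetic data generator

The generator emulates the study's statistical structure at its actual
scale (1,200 positive + 800 negative features, 36 samples) with
log-normal multiplicative noise and a 500-count floor, and returns a
ground-truth ledger. Its guiding principle: **planted truths are
recoverable by construction, decoys unrecoverable by construction**,
so recovery tests are exact rather than probabilistic.

* *Planted pairs* (default 13 positive + 7 negative) draw their m/z
  gap uniformly within ±half the 20-ppm tolerance of an allowed shift
  and their RT offset within ±40% of the 0.05-min tolerance;
  deuterated partners co-elute with their unlabeled forms (deuterium
  RT shifts are ignored — a documented simplification). Peak
  amplitudes are 10^3.8–10^4.7 with time profiles shaped like the
  observed intermediates (maximum at 24 h, late accumulation,
  monotone rise); off-target treatments sit below the floor, so after
  flooring those vectors are constant and the co-behavior screen
  rejects pair members via the undefined-correlation rule.
* *Decoy pairs* (default 80 + 60 + 60) violate exactly one criterion
  by 2–4× its tolerance: mass-gap near-misses, RT misses, or a
  labeled member peaking in the control. A config whose decoy offset
  does not exceed the tolerance is rejected as contradictory.
* *Co-behaving features* (default 15, of which 2 × 3 form
  adduct-consistent triplets of one neutral mass — [M+H]⁺, [2M+H]⁺,
  [M−H]⁻ — to exercise consolidation) share a time profile across both
  tracer treatments with flat controls. Control noise is resampled
  (seeded, bounded attempts) until the planted feature clears the
  screen thresholds with margin (tracer ρ ≥ 0.5, control ρ ≤ 0.15):
  a construction guarantee, not a tuned threshold.
* *Background features* share one (time, replicate) profile across
  all three treatments (structure sd 0.3 dex ≫ treatment noise 0.02
  dex), emulating alignment-order/biological structure; their control
  correlations are therefore high and the co-behavior screen rejects
  them deterministically. ~2% of background cells are missing.
* Two *audits* close the residual probability mass: a sweep nudges
  the m/z of any accidental shift/RT coincidence between features not
  planted as a pair (guard band 2× each tolerance, preserving planted
  gaps, never moving internal standards or triplet members), and a
  final pass runs both screens and flattens any remaining non-planted
  positive by copying its control profile across treatments. Both are
  deterministic under the seed.

What the generator does **not** emulate: correlated chromatographic
drift, inter-batch effects, isotope-envelope satellites, in-source
fragments beyond the three adduct forms, heteroscedastic
detector saturation, and RT shifts of deuterated species. Passing
recovery tests therefore demonstrates the correctness of the
screening logic under the declared statistical model, not performance
on raw instrument data — on real data the same thresholds apply but
recovery depends on instrument mass accuracy and alignment quality.

## Numerical and interface choices

* Spearman's ρ via `scipy.stats.spearmanr` (Pearson on average ranks);
  an independent rank-then-Pearson oracle cross-checks tie handling in
  the tests.
* Connected components via `scipy.sparse.csgraph` on an explicit
  pairwise linkage graph (consolidation inputs are tens of records, so
  the O(n²) edge scan is immaterial).
* All stage outputs are deterministic given inputs and config; the
  only randomness in the package is the generator's seeded RNG.
* CSV dialects: matrix = `id,mz,rt,ion_mode,<sample…>`, design =
  `sample_id,treatment,time_h,replicate,batch`; empty cell = missing.
  Readers accept a column mapping for differently named metadata
  columns; writers round-trip bit-stably.
* Config: TOML sections per stage; unknown keys are rejected so typos
  cannot silently revert to defaults.

## Problem sizes in the test suite

Unit tests run a reduced layout (150 + 100 features, 6 pairs, 7
co-behavers, 20 decoys); the acceptance tests run the full default
scale (2,000 features, 20 pairs, 15 co-behavers, 200 decoys) once per
session and compare both screens against O(n²) brute-force reference
enumerations. These sizes were chosen to exercise the windowed pair
search and vectorized group statistics well past any special-casing
while keeping a full run in tens of seconds.

## Known limitations

* Only singly charged species; no charge-state deconvolution, isotope
  fine structure or natural-abundance envelope modeling.
* One label type per screen pass (no simultaneous ²H + ³⁴S).
* Annotation is exact-mass only — no MS/MS spectral matching or RT
  libraries; hits are candidates, not identifications.
* The consolidation merge tolerance and the cross-mode RT gate are
  declared conventions (see above), not values recovered from a
  reference implementation.
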