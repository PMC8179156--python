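# tracerscreen

Screening of untargeted LC–MS feature tables from stable-isotope
tracer-feeding experiments, for discovering the processing
intermediates of a fed compound.

## The problem

Feed plants (or any organism) a tracer in two forms — unlabeled and
isotope-labeled (e.g. a glucosinolate carrying five deuterium atoms on
its side chain) — plus a solvent control, and record untargeted
LC–QTOF/MS feature tables over a time course. Every metabolite derived
from the tracer then appears **twice**: as an unlabeled feature that
accumulates only under the unlabeled tracer, and as a co-eluting
feature shifted by the label mass that accumulates only under the
labeled tracer. Metabolites *affected* by the treatment without
incorporating the label (a depleted conjugation substrate such as
glutathione, or an accumulating terminal product such as raphanusamic
acid) instead respond identically under both tracer forms.

`tracerscreen` implements both screens over an aligned feature matrix
(features × samples, with m/z, retention time and ion mode per
feature, and a treatment × time × replicate design):

1. **Isotopologue-pair screen** (criteria 1–4): a feature's highest
   (treatment, time)-group mean exceeds 2× the noise floor (strict);
   two same-mode features differ by the mass of *n* ∈ {2, 3, 5, 10}
   deuterium atoms (Δ = 2.0126, 3.0189, 5.0314, 10.0628 Da) within
   ±20 ppm of the query m/z; they co-elute within ±0.05 min; and the
   lighter/heavier member peaks under the unlabeled/labeled tracer
   respectively.
2. **Co-behavior screen** (criteria 1, 5, 6): the global extremum of
   the group means lies in a tracer group, and Spearman's
   ρ(unlabeled-tracer, labeled-tracer) > 0.4 while both
   ρ(control, tracer) ≤ 0.2, on replicate-matched 12-point intensity
   vectors.
3. **Consolidation**: records explained by one neutral mass across
   adduct forms ([M+H]⁺, [2M+H]⁺, [M−H]⁻) and co-eluting within
   tolerance are merged into one record led by the most intense member.
4. **Annotation**: exact-mass lookup of screened records against a
   compound library via the mode's precursor adduct, |Δm| ≤ 0.01 Da.

Supporting pieces: noise flooring (< 500 → 500; missing → 500) and
internal-standard normalization (lidocaine m/z 235.1805 for positive
ions, 10-camphorsulfonic acid m/z 231.0697 for negative ions);
monoisotopic mass/adduct arithmetic from an embedded atomic mass
table; isotope-budget helpers (labeled fraction, per-plant dose,
percent recovery); and a seeded synthetic-data generator that emulates
the study design with a ground-truth ledger, so the whole pipeline is
testable without any instrument data.

## Worked example

```python
from tracerscreen import *
from tracerscreen.simulate import SimulationConfig, generate
from tracerscreen.pipeline import PipelineConfig, run_pipeline

table, truth = generate(SimulationConfig(seed=7))   # 1,200 + 800 features
result = run_pipeline(table, PipelineConfig())
print(result.summary)
```

prints (abbreviated)

```
n_features:                {positive: 1200, negative: 800}
n_pairs:                   {positive: 13, negative: 7}
n_consolidated_pairs:      20
n_cobehavior:              {positive: 9, negative: 6}
n_consolidated_cobehavior: 11
rejections:                {criterion3: 179, criterion4: 60, criterion1: 52}
```

— the screen found the 20 planted isotopologue pairs (13 positive, 7
negative mode) and none of the 200 decoy pairs, and the 15 planted
co-behaving features, which consolidate to 11 records because two
planted metabolites each appear as three adduct features. The
`rejections` tally says why candidate pairs that matched a mass shift
were discarded (co-elution failure, wrong treatment maximum, intensity
below threshold). A single pair record carries the evidence:

```python
result.pairs[0]
# PairCandidate(unlabeled_id='P0008', labeled_id='P0009', n_label=10,
#               observed_delta=10.0627, delta_ppm_error=0.70,
#               rt_diff=0.015, ion_mode='positive')
```

Mass arithmetic and the tracer budget:

```python
adduct_mz("C16H28N4O7S3", "[M+H]+")        # 485.1193 (SFN-GSH conjugate)
label_delta(DEUTERIUM_PRINTED, 5)          # 5.0314 Da
dose_per_plant(TracerDose(150, 2, 10))     # 30.0 nmol per plant
recovery_percent([0.076, 0.150], 30.0)     # 0.75 % of the dose retained
```

The same stages are available from a shell:

```bash
tracerscreen simulate --seed 7 --out sim/
tracerscreen run-all --matrix sim/matrix.csv --design sim/design.csv --out-dir results/
tracerscreen annotate --mz 485.1184 --ion-mode positive
tracerscreen budget --concentration 150 --volume 2 --n-plants 10 \
    --retained 0.076 --retained 0.150
```

Every threshold (noise floor, ppm and RT tolerances, shift table,
correlation thresholds, annotation tolerance) can be overridden in a
TOML config passed with `--config`; unknown keys are rejected.

## Layout

```
src/tracerscreen/
  chem.py           mass tables, formulas, adducts, label shifts, ppm
  feature_table.py  data model + CSV readers/writers, group means
  preprocess.py     noise flooring, internal-standard normalization
  pair_screen.py    criteria 1–4 (isotopologue pairs)
  cobehavior.py     criteria 1, 5, 6 (tracer co-behavior)
  consolidate.py    cross-adduct/-mode record merging
  annotate.py       exact-mass annotation + bundled compound library
  enrichment.py     labeled fraction, dose, recovery
  simulate.py       seeded synthetic data generator with ground truth
  pipeline.py       stage wiring + funnel summary
  cli.py            command-line interface
docs/methods.md     model, parameters, numerical choices, limitations
```
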