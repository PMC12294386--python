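# Methods

## Scope and assumptions

`hydropep` covers the in-silico stages of a hydrolysate peptidomics
workflow. Everything upstream — extraction, molecular-weight fractionation,
digestion, LC-MS/MS acquisition and the spectrum-to-peptide search — is out
of scope; the pipeline begins at the search engine's identification export
and at a Skyline-style light/heavy peak-area report. Consequences of that
boundary:

- **FDR is consumed, not computed.** Peptide-level false-discovery control
  belongs to the search engine; identification rows carry a boolean
  `fdr_pass` flag and the pipeline filters on it.
- **Peak areas are consumed as given.** No chromatogram integration is
  performed.
- **Sequences are plain.** Modification annotations in parentheses or
  brackets (e.g. `M(+15.99)`) are stripped on load, because all matching,
  scoring and mass arithmetic operates on unmodified sequences. Isoleucine
  and leucine are kept distinct; reference databases list literal sequences
  and collapsing I/L would manufacture matches.
- **Coordinates** are 0-based, half-open everywhere; the convention is
  stated once and never converted internally.

## Identification filtering and pooling

Records are retained when 4 ≤ length ≤ 65 (inclusive on both ends — the
bounds are attainable) and `fdr_pass` is true. A peptide belongs to a
product if identified in at least one of the product's batches; batch
provenance is kept per peptide, and a `min_batches` knob allows the stricter
"seen in k batches" reading. Fraction labels (<3 kDa, 3–10 kDa, >10 kDa)
are metadata only: identifications are pooled per product, and no
fraction-specific scoring exists.

## Annotation

Parent mapping reports every occurrence of a peptide in every parent
protein, ordered by (accession, start); hydrolysates genuinely contain
peptides attributable to several proteoforms, so all parents are retained
and reports list them comma-separated. Cross-referencing searches three
relations per (peptide, entry) pair — exact equality, peptide-in-entry, and
entry-in-peptide — with a minimum contained-sequence length of 4 (matching
the identification minimum) for the two proper-containment relations, to
suppress spurious short matches; the threshold is configurable. Matching is
case-insensitive and modification-blind by construction.

Consolidation emits one record per (peptide, activity): a peptide matching
entries of different activities is multifunctional and yields one record per
activity. The parent accession comes from direct parent hits when present,
else from the matched entry's catalogued parent. Peptides with database
evidence but no product membership are kept and flagged rather than
dropped.

## Motif-frequency (BF) scoring

For peptide length N and an activity's motif set, BF = a/N where `a` counts
total motif occurrences: overlapping occurrences count, each start position
of each motif counts once, and distinct motifs at the same position each
count. This per-position, per-motif convention is the one under which the
bundled snapshot reproduces the reference scores carried in the acceptance
suite; the counting rule and the snapshot are validated jointly, so a
drifted motif list is diagnosable as a golden-value failure that reports the
implied versus the counted `a`.

The bundled snapshot (`data/motifs_synthetic.tsv`) is a synthetic, pinned
excerpt in the style of the public ACE-inhibitor and DPP-IV-inhibitor
fragment tables; live motif databases change between access dates, so a
fixed snapshot with a `snapshot_id` echoed into every report is the only way
to make scores reproducible. Banding: BF ≥ 0.5 HIGH, 0.2 ≤ BF < 0.5
MODERATE, BF < 0.2 LOW. The textual gap between 0.49 and 0.5 in common
usage is closed at 0.5, reading "0.2–0.49" as presentational rounding.
Reported BF values are rounded to 4 decimals (round-half-even); full
precision is kept internally. The potency-weighted (B-type) index and
enzyme-action prediction are not implemented.

## Absolute quantification

L = (area_light / area_heavy) × H, with H the heavy spike in pmol. The
heavy label shifts mass enough to separate chromatogram channels but cancels
out of the arithmetic, so it is not modelled. Composition amounts are
pg peptide per µg total peptide: L·M/m_total with M the **monoisotopic**
mass of the unlabelled peptide (the targeted-proteomics norm; average mass
is available by flag) computed from the standard residue table plus one
water. `total_peptide_ug` defaults to 10 µg on column and is a visible,
required configuration value — never silently assumed in reports. Batch
replicates are combined by arithmetic mean with the contributing batch count
reported.

## Activity classifiers

Feature vector (26 features; 400 optional dipeptide fractions by flag):
amino-acid composition (fractions summing to 1), length (residues),
monoisotopic mass (Da), net charge at pH 7 by Henderson–Hasselbalch over
standard sidechain and terminal pKa values, mean Kyte–Doolittle hydropathy,
aromaticity (F/W/Y fraction) and cysteine fraction. These are the
community-standard descriptors for short-peptide activity prediction and
are fully specified here for reproducibility.

Forest defaults: 500 trees, √p feature subsampling, no depth cap, fixed
seed; stratified 80/20 train/validation split; probability is the forest
vote fraction; calls use a 0.5 threshold with ties called positive (the tie
rule must be explicit for determinism). Training is bit-reproducible for a
fixed seed and input order. Gram-positive/negative sub-typing and deep
models are out of scope.

## Synthetic data generator

The generator emulates the study design the pipeline targets, and its
defaults are the study conditions:

- two products (`PHP`, `P62`) × three batches each, with realistic batch
  identifiers;
- peptides of 4–65 residues; unspecific cleavage by default (random
  substrings, 25 per protein), Lys-C (cut after K) and trypsin (cut after
  K/R except before P, 0 missed cleavages by default) as alternatives;
- background proteins drawn from release-average Swiss-Prot amino-acid
  frequencies (renormalised to sum exactly to 1), lengths 80–300;
- six planted bioactive peptides present in every batch of both products,
  with fixed per-product true amounts (0.0054–8.05 pg/µg) and heavy-spike
  levels of 0.34–1.2 pmol;
- light areas generated as heavy_area × (L_true/H) × mean-one lognormal
  noise with coefficient of variation `noise_cv` (default 0.1; 0 gives
  exact ratios); heavy areas are lognormal around 10⁶ — only ratios matter
  downstream;
- per-batch presence of background peptides with probability 0.7, plus
  deliberately failing rows (too short, FDR fail) so acceptance filtering
  has work to do.

Background peptides are drawn only from background proteins: the planted
parents sit in the proteome for mapping, but their peptide content is
controlled exclusively by the planted list, so the truth ledger is exact and
the full-pipeline round trip (planted table in → same table out; exact
amounts at zero noise) holds by construction.

Labelled classifier sets are class-balanced (200 positives + 200 negatives
per class by default). Positives are sampled from a background tilted
towards class-typical residues — cationic (K/R) plus a hydropathy shift for
antimicrobial, aromatic/cationic (R/W/F) for antiviral, radical-scavenging
(W/Y/C/H/M) for antioxidant — with log-linear strength `ml_effect`. The
default `ml_effect = 3.0` defines the *separable regime*: positive
compositions are strongly biased (e.g. roughly half cationic residues for
antimicrobial positives, as in strongly cationic natural antimicrobial
peptides), which the classifiers must resolve at ≥ 0.9
accuracy/sensitivity/specificity. At `ml_effect = 0` positive and negative
sampling distributions coincide exactly and performance collapses to
chance — the generator's null control.

**What passing does and does not show.** The generator plants composition-
level signal and the classifiers recover it; real activity data carry
positional motifs, structure and database redundancy that the generator
does not emulate (nor does it simulate spectra, retention times or
acquisition bias). Classifier metrics on synthetic data therefore validate
the machinery, not real-world predictive performance; published accuracies
from differently trained corpora are not comparable and are not targets.
Likewise the total peptide counts of a real study depend on raw spectra and
a commercial search engine and are covered here only by the synthetic
round-trip property.

## Numerical choices

- BF arithmetic is exact integer-over-integer; only report formatting
  rounds (4 decimals, round-half-even).
- Quantification validates heavy_area > 0, H > 0, total µg > 0 at record
  construction, so divisions cannot fault downstream.
- Mass tolerance in tests against the independent residue table is 2×10⁻³ Da,
  reflecting transcription precision of the table, not algorithmic error.
- Every generator draws from an independent, named substream of the
  configured seed, so adding one generator never perturbs another's output.
- Problem sizes in the test and acceptance runs (e.g. 100 quantification
  replicates, 400-peptide training sets, 20-seed null checks with
  100-tree forests) were chosen to keep the full suite under a minute of
  compute while leaving comfortable statistical margins.

## Known limitations

- The motif snapshot is a pinned synthetic excerpt, not a live database
  export; scores are reproducible but not exhaustive over all catalogued
  motifs or activities beyond the two bundled ones.
- Reference fixtures (parent FASTA, bioactive entries) are synthetic
  stand-ins shipped for testing; production runs should point the pipeline
  at curated local copies of the real databases.
- No ortholog resolution: peptides are mapped against whatever parent
  sequences are supplied, and cross-species accession ambiguity is left to
  the user.
- The identification-export dialect varies by search engine and version;
  the column-mapping configuration exists precisely because no universal
  schema can be assumed.
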