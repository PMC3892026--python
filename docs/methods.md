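# Methods

## The classification model

AACDS is a deterministic rule system, not a probabilistic score.  Each
homozygous missense substitution is reduced to four booleans — documented
causal, prediction consensus (≥ 3 of 6 programs), disease-gene
association, trait-gene association — and mapped to the eight categories.
Two semantic commitments matter:

1. **Multi-label counting.**  Labels 1, 2A, 2B, 3A, 3B overlap (a variant
   in a gene with both disease and trait associations that reaches the
   consensus carries 2A, 2B, 3A and 3B simultaneously), while 4, 5, 6 are
   exclusive residual classes.  This is the only reading under which a
   per-category count table reconciles with per-genome unique variant
   totals; the identities `unique = |2A∪3A| + n(4) + n(6)` and
   `n(5) = |2A∪3A| − |2B∪3B|` are enforced as invariants and verified on
   every generated cohort.  Cohort summaries expose both **label-sum**
   statistics (a 2B∩3B variant counts once per label) and **deduplicated**
   variant counts, clearly named, because headline arithmetic such as
   "35 = 14 + 21" follows the label-sum convention.
2. **Category 1 is strict.**  Only a record with status
   `disease_causing` yields category 1; `probable` records never do.
   When curated sources conflict for one substitution, the loader keeps
   all records and warns; the classifier uses the most severe status but
   never promotes one.  A documented-causal variant with no other
   evidence yields the bare label set {1} (and {1, 4} when deleterious);
   such variants sit outside the 4/5/6 residual partition and are logged.

The reported label is the "/"-joined intersection with {1, 2B, 3B} when
non-empty (e.g. `1/2B/3B`), otherwise the single residual class.  The
priority tier for sorting follows 1 > 2B > 3B > 4 > 2A > 3A > 5 > 6.

## Inputs and the variant filter

The analysis set is **homozygous-alternate** missense variants with
quality ≥ 20 (when a quality is present; annotation-table inputs carry
none) and matched-population 1000 Genomes MAF strictly below 0.10.
A variant absent from the frequency panel has never been observed there
and is retained.  The matched-population default (Caucasian → EUR,
African → AFR) is deliberate: exome-panel African frequencies can exceed
10% for variants that clearly passed the original filter, so the ESP
columns are never used for filtering — only for reporting, where they are
normalized from percent to fractions at load.  `any`/`all` population
modes are available for unmatched ethnicities.  Known vs private status
is decided by rsID membership in the local dbSNP snapshot (positional
lookup when the rsID is absent).  Hemizygous single-allele alternate
calls (male X) are treated as homozygous-alternate and logged.
Multi-allelic VCF records are decomposed before genotype interpretation.

## Scores, cutoffs and defaults

Raw scores are re-scaled to [0, 1] with 1 = most deleterious: SIFT is
flipped (1 − raw), MutationAssessor is min–max scaled over its published
[−5.545, 5.975] range, and the probability-scaled programs pass through.
A categorical source label, when present, decides the call by default
(`prefer_categorical`); a score-only mode is a switch away, and the
generator plants scores consistent under both.

| cutoff | default | provenance |
|---|---|---|
| MutationAssessor raw | > 3.5 (strict) | stated by the source method |
| LRT (rescaled) | ≥ 0.999 | stated |
| SIFT (rescaled) | ≥ 0.95 (raw ≤ 0.05) | package default (SIFT's conventional 0.05) |
| PolyPhen2 (both, rescaled) | ≥ 0.5, or label D/P | package default |
| MutationTaster | label A/D, or rescaled ≥ 0.5 | package default |
| GERP++ RS | ≥ 2.0 | package default |
| phyloP | ≥ 1.6 | package default |
| SiPhy | ≥ 12.0 | package default |

All cutoffs are configuration entries and are echoed into every report
header.  Missing entries count as non-damaging in the consensus (a
variant scored by fewer than six programs can still reach ≥ 3) and are
reported as `missing`, never silently `tolerated`.  The conservation
cutoffs are uncalibrated against any external count data — per-site
conservation counts are reproducible only for fixtures that plant them.

**Grantham distance.**  The embedded 190-entry integer matrix is the
rounded output of the weighted-Euclidean formula over the 1974 property
triples with ρ fixed by the mean-distance-100 normalization
(ρ ≈ 50.79).  This reproduces every pair value quoted in the
prioritization literature and the published extremes (5, 215); a few
entries of the historical typeset table differ by one unit from exact
recomputation (e.g. Ala–Arg 112 vs 111), a rounding artifact of the
original typesetting that we do not reproduce.  The test suite
regenerates the full matrix from an independent copy of the property
triples.

**Stability.**  ΔΔG values are ingested, never computed.  Sign is
normalized to positive = destabilizing at load (a per-column declared
convention).  |ΔΔG| < 0.5 kcal/mol is neutral, |ΔΔG| ≥ 2 kcal/mol strong,
in between weak.

## Structure flags

Cα B-factor uses a strict > 60 Å² disorder flag; multi-model (NMR) files
use the first model.  Ligand proximity is the minimum heavy-atom distance
from the variant residue to any hetero group, excluding water and a
configurable list of buffer/cryoprotectant components, flagged at
≤ 5.0 Å — a documented package default, as no canonical distance exists
for "in or near a binding pocket".  Residue numbering is canonical
(UniProt-style); a per-structure offset maps to author numbering.
External structure-server outputs (surface patches, stability centers,
flexibility classes) are ingested as optional columns.  No flag is ever
emitted `True` when its evidence source is missing — ablating any input
leaves the corresponding flags `None`.

## Cohort statistics

The ethnicity comparison is **Student's pooled-variance** two-sample
t-test (two-tailed, n₁+n₂−2 df): on the packaged per-genome counts it
gives p = 0.181, matching the reference analysis, where Welch's variant
gives 0.209 — hence the pooled flavor is the package convention, recorded
in the report.  On the per-genome top-category (1/2B/3B) counts the same
pooled test gives p ≈ 0.14; the reference analysis quotes 0.21 for that
comparison, which neither pooled nor Welch reproduces from the published
count table, so the package reports its computed value and notes the
mismatch here rather than adjusting to it.  (A related inconsistency: the
top-category per-genome range is 0–7 by the count-table arithmetic the
package reproduces, though 0–8 appears in one summary sentence of the
reference analysis.)  ECDFs are standard empirical CDFs with shared steps
at ties.  Population-bias grouping uses a strict ±5-percentage-point
EA−AA difference per SNP, lifted to genes as EA-only / AA-only / both /
neither.  Printed percentages round half away from zero.

## The synthetic-data generator

The generator is the package's test bed and emulates the *shape* of a
small whole-genome cohort study: per subject, planted counts for each
exclusive class (deleterious+associated with its 2B/3B overlap, the
neutral associated classes with their 2A/3A overlap, deleterious-only,
neutral-only, private), one gene per variant in a reserved SYN*
namespace, prediction scores drawn inside safe margins of the cutoffs so
intended calls always hold, conservation scores likewise, and
matched-population MAFs drawn from Beta distributions scaled into
[0, 0.0999) — lower-mean shapes (0.6, 16) for deleterious-associated
variants than for the rest (2.0, 10), emulating the observed downward
frequency shift of deleterious variants.  All draws come from one seeded
generator; identical plans produce byte-identical tables.

The packaged 12-subject plan reproduces the study's category matrix
cell-for-cell — the per-subject label overlaps are the unique solution of
the reconciliation identities — with 4 African and 8 Caucasian genomes
and the published private-variant counts (29 total).  Documented-causal
marks are placed greedily on each subject's disease-gene variants
(deleterious ones first), one of several placements consistent with the
matrix.

What the generator does **not** emulate: linkage between variants, shared
genes across subjects (each synthetic variant gets its own gene, so
gene-level sharing statistics are out of scope), realistic score
correlations between predictors, genotype error, or real sequence
context.  Passing tests therefore demonstrate the correctness of the
classification and summary logic, not predictive performance on real
genomes; cohort-scale quantities that would require the original genomes
(e.g. the 88-variant consensus subset, real score ECDFs) are mirrored by
fixture-based equivalents with the same totals.

## Problem sizes and determinism

Generated cohorts are small (the packaged plan: 826 variants across 12
pseudo-genomes; property tests use 2–4 subjects at scales of 4–12
variants per class), chosen so the full suite and the acceptance script
run in seconds.  Every stochastic path takes an explicit seed; the
acceptance script threads its `--seed` into the cohort generation and
keeps derived seeds below 2³¹.

## Known limitations

* Conflicting curated statuses are surfaced, not resolved; the most
  severe wins downstream.
* The consensus depends on ingested pre-computed scores; no predictor is
  executed.
* Frequency filtering assumes biallelic SNVs; indels and structural
  variants are out of scope.
* The per-variant report reconstructs a reasonable superset of the
  original online tool's fields; the exact historical field list is not
  fully documented anywhere.
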