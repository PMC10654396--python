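# Methods

This note records the models, conventions and design choices behind
`lmexome`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, and
where the genuinely open choices were resolved.

## Variant representation and merge identity

A somatic variant is identified by (chromosome, position, ref, alt) after
indel normalization: shared trailing bases are trimmed, then shared
leading bases down to the single VCF anchor base, advancing the position.
This is the minimal unambiguous merge key across callers; caller-specific
representations of the same indel collapse to one record.

Substitutions are always expressed on the pyrimidine strand (COSMIC
convention): a G>A call becomes C>T with its trinucleotide context
reverse-complemented. One convention serves two purposes — the
FFPE-artifact VAF thresholds target "C>T and G>A" as a single folded
class, and the 96-context catalogs are built from the same labels, so the
two can never disagree.

Caller dialects are configuration data, not code. A dialect names the
tumour/normal sample columns and the allele-depth tag, or declares the
caller INFO-based (depth + allele fraction, no normal column). The
LoFreq-style dialect has no normal column, so its records carry
"germline unavailable", which downstream waives the germline-read filter
for variants only such callers report.

## Filter cascade

Defaults: ≥ 2 callers; ≥ 5 tumour alt reads; ≤ 2 germline alt reads;
≥ 10× depth; per-sample overrides replace the three read thresholds in
their stated order (the study used 3/1/7 for three low-coverage CSF
samples). Minimum VAF by purity stratum — high (p > 0.5) 0.05, low
(p ≤ 0.2) 0.01, intermediate 0.03 — raised to 0.07/0.03/0.05 respectively
for folded-C>T variants in FFPE samples only; non-artifact-class variants
in FFPE samples use the standard threshold, and the VAF comparison is
inclusive (a floor). Read counts across callers are reconciled by maximum
(the most permissive consistent choice), with VAF recomputed from the
reconciled counts.

Cross-sample rescue is taken literally as an exemption from the whole
cascade: a variant called in sample S that fails any filter there, but
passes in another sample of the same patient, enters S's final set
flagged `rescued`. Rescue runs after the full cascade; variants never
called in S are not invented. Synonymous exonic variants pass the cascade
(they are exonic) and are excluded only from the non-silent analyses
downstream; signature catalogs use SNVs only.

TMB divides the final set size by the configured panel footprint (60 Mb),
flagging > 10 mutations/Mb as high.

## Purity and ploidy

Three curation triggers replace the model estimate: cfDNA model-vs-ulpWGS
purity difference > 0.15 (strict), model ploidy outside [1.5, 3.5], and
tissue purity ≤ 0.35. Curated purity is the clonal-heterozygous-diploid
inversion p = min(1, 2·median VAF); this deterministic rule stands in for
the study's human review, which is not implementable, while keeping the
fired triggers as audit flags. Curated ploidy retains the model value if
it was in range, else 2 — the choice was open; diploid is the least
informative prior. A sample with no somatic variants would invert to
p = 0, so curated purity is floored at 0.01 with an extra flag, keeping
purity in (0, 1].

Segment adjustment is the standard two-population mixture inversion,
n = (2ʳ·(pψ + 2(1−p)) − 2(1−p))/p clamped at 0, re-expressed as
log2(max(n, ε)/2) with ε = 0.01 so homozygous deletions stay finite. It
is the exact inverse of the simulator's forward model, which is what
makes the noise-free round trip a testable identity.

## Gene-level copy number

Gene ratios are overlap-length-weighted means of adjusted segment ratios;
genes in uncovered gaps are absent rather than imputed. Standardization
divides by the sample SD (n−1 denominator) without centering: ploidy
adjustment already places neutral at 0, and centering would shift neutral
in aneuploid genomes. Standardization is applied to gene-level ratios
(whether the original analysis standardized before or after aggregation
is unstated; for arm-level segments the two differ only through overlap
weights).

State thresholds: amplification z > 2.0; gain 1.0 < z ≤ 2.0; neutral
−1.5 ≤ z ≤ 1.0; loss −2.5 ≤ z < −1.5; deletion z < −2.5. The loss band is
the sign-corrected reading of a printed "loss < −1.5 to ≤ 2.5": any other
reading overlaps the gain or neutral bands, while this one makes the five
states a partition of the line, monotone in z.

Between-group frequency tests use the two-sided chi-square test of equal
proportions with continuity correction (the default of R's `prop.test`),
falling back to Fisher's exact test when any expected count is below 5;
volcano selection requires |Δ proportion| ≥ 0.20 and −log10 p ≥ 1.5.

## Signatures

Catalogs are refit by NNLS on raw counts (not relative frequencies)
against a column-normalized reference matrix; exposures are reported raw
and as contributions summing to 1, with the cosine similarity of the
reconstruction. NNLS is the standard refit of the COSMIC framework and is
cross-checked in the tests against an independent grid-search oracle. The
chemotherapy-related set {SBS11, SBS17b, SBS28, SBS31, SBS35, SBS86} is
aggregated on contributions. Group comparisons use the two-tailed
Mann-Whitney test, exact (full null enumeration) when both groups have
≤ 8 tie-free samples, tie-corrected normal approximation otherwise.

The packaged reference matrix is a deterministic synthetic stand-in in
COSMIC v3.2 layout (nine signatures including the six chemotherapy
labels); the profiles are sparse-random, not the COSMIC profiles, so the
package is fully testable offline. Analyses of real data should supply a
genuine COSMIC TSV by path.

## Cohort statistics

Pair partitions use the union of the two samples' non-silent variants as
denominator (the three fractions then sum to 1); cohort summaries report
medians and linearly interpolated quartiles. Alteration matrices count a
gene as altered on non-silent mutation, amplification or deep deletion —
gain and shallow loss never qualify. Driver selection takes curated
cancer genes altered in ≥ 4 samples and breast-cancer driver genes in
≥ 3. The external-cohort comparison consumes a per-gene rate table
(gene, altered, total) rather than raw calls.

Mutual exclusivity uses the two-sided Fisher exact test under the
minimum-likelihood summation convention (the R convention): the p-value
sums the probabilities of all tables at fixed margins no more likely than
the observed one. This convention is required to reproduce the published
CDH1/CTNNA1 value: the zero-overlap table (0, 11, 4, 6) in 21 samples has
exact p = 210/5985 ≈ 0.0351, which the study prints as 0.0352 — a
fourth-decimal discrepancy that is noted, not resolved. Degenerate
margins return p = 1 with a warning.

Overrepresentation is one-sided Fisher (enrichment), per the cited
tool's convention, with Benjamini-Hochberg adjustment across tested sets;
retention requires set size ≥ 10 within the background, −log10 p ≥ 3.0
and q < 0.05. Enriched-gene lists use absolute count thresholds (≥ 4/21
CSF or ≥ 3/11 plasma focal samples, ≤ 2 tissue samples).

## Synthetic cohort generator

The generator defines the study conditions for every recovery benchmark;
its defaults are fixed, not tuning knobs:

- **Cohort**: 20 patients; CSF and plasma cfDNA plus FFPE primary per
  patient, FFPE metastasis for 40% of patients (the study sequenced 8
  metastases in 21 patients); purity 0.5 and mean depth 100× at every
  site; ploidy 2.
- **Clones**: 50 founder variants present at every site and 20
  site-private variants per sample (the study's median filtered SNV
  burden is ≈ 96 per sample), private subclones at cellular prevalence
  0.6; 5% indels. Expected VAF is p·f·m/(p·ψ + 2(1−p)).
- **Reads**: per-locus depth Poisson around the site mean; alt reads
  binomial; germline alt reads binomial at 10⁻³; each caller detects
  independently with logistic sensitivity of midpoint 4 alt reads (so the
  5-read filter and the 2-caller consensus interact), reporting counts
  with ±1 jitter; caller-private false positives (Poisson mean 8 per
  caller) carry 1–4 alt reads.
- **FFPE artifacts**: Poisson mean 40 per FFPE sample, folded-C>T only,
  VAF ~ Beta(1, 50) (mean ≈ 0.02) so artifacts straddle the 0.03–0.07
  thresholds and the threshold tests are informative.
- **Signatures**: trinucleotide contexts drawn from per-site mixtures
  over the synthetic reference; plasma (and metastasis) mixtures carry
  more chemotherapy-signature weight than CSF, planting the
  sanctuary-site contrast.
- **Copy number**: one integer state per chromosome arm (16 arms of a
  synthetic 8-chromosome genome, 15 genes per arm), drawn from
  {2: 0.75, 3: 0.07, 1: 0.06, 4: 0.04, 5: 0.04, 0: 0.02, 6: 0.02} — a
  breast-cancer-like aberration load; observed ratios add Gaussian noise
  (SD 0.1 by default) to the forward mixture model.

All randomness descends from one mandatory seed via hierarchical
`SeedSequence` splitting per patient, sample and stage, so any subset of
the cohort is reproducible in isolation and emitted files are
byte-identical across runs.

What the generator deliberately does not emulate: read-level errors and
mapping artifacts, germline variation, structural variants, locus-level
copy-number/multiplicity coupling to VAF, subclonal phylogenies deeper
than founder + one private clone per site, and caller-specific error
profiles beyond sensitivity/false-positive rates. Recovery results on
synthetic cohorts therefore demonstrate the correctness of the filtering,
inversion and statistical machinery under the stated generative
assumptions — not performance on real sequencing data.

## Numerical choices and degenerate inputs

Reference signature columns are renormalized on read (tolerance 1e-6);
zero catalogs refit to zero exposures with cosine defined as 0 and a
warning; zero vectors likewise in cosine similarity. Zero SD in
standardization yields all-zero z with a warning. Ties in the
Mann-Whitney exact path fall back to the tie-corrected approximation.
Proportion tests with an empty event column return p = 1. Benchmark
problem sizes (20-patient cohorts, 200 refit replicates, 4-patient grids
per purity level) were chosen as the smallest sizes at which the measured
rates are stable to the second decimal across seeds.

## Known limitations

The functional class of a variant is read from an annotation tag or
table, never computed from transcripts. Manual purity curation is
approximated by a deterministic rule. Allele-specific copy number,
panel-of-normals construction and subclonal reconstruction are out of
scope. The cohort-level headline medians of the original study (CSF-unique
variant fractions, enriched-gene list sizes) require its per-patient
variant tables, which are not redistributable; the corresponding checks in
the acceptance suite therefore fail with an explanatory message unless
those tables are supplied under `data/external/`.
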