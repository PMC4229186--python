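# Methods

This note records the statistical model, the conventions and numerical
choices behind `extremevar`, and what the synthetic-data generator does
and does not emulate.

## Cohort representation and coordinates

Genotypes are stored as a dense sample x variant matrix of diploid
alternate-allele counts with an explicit no-call state; a genotype is
either fully called (0/1/2) or uncalled, and half-calls (`0/.`) are
conservatively treated as no-calls. Reading a no-call's allele count
raises, so missing data can never silently become homozygous reference.
Each genotype additionally carries a binary quality tier driven by one
configurable FORMAT key and threshold; platform-specific quality scores
do not port between sequencing vendors, so one tier is all the pipeline
assumes. By default low-quality calls are masked to no-call everywhere;
setting `use_low_quality` reproduces a sensitivity re-run that admits
them.

Coordinates are VCF 1-based externally and 0-based half-open
internally; the conversion happens only in the I/O and consequence
modules. Multi-allelic records are decomposed into biallelic keys with
per-allele counts recomputed. Keys are normalized by trimming shared
prefix/suffix padding (keeping at least one base per allele); full
left-alignment against the reference is not attempted, so homopolymer
indels must be consistently represented across inputs — the praxis for
the TSV/VCF fixtures this pipeline consumes.

A variant absent from the frequency panel is treated as novel
(frequency 0 over the panel's full allele count), matching the
convention that novel variants count as rare. Because a sites-only
panel has no genotypes, panel *carriers* are approximated by the
alternate-allele count capped at the panel size; for the rare variants
this test is applied to, alternate alleles are overwhelmingly
heterozygous and the approximation is exact in the regime that matters
(zero or near-zero panel carriers).

## Consequence classification

One transcript per gene model; a gene's protein-altering status is the
OR over the transcripts provided. Categories: missense, frameshift,
non-frameshift indel, stop-gain, stop-loss, splice-site, else
non-protein-altering. Splice sites are exactly the two intronic bases
flanking each coding exon (canonical GT donor / AG acceptor on the
coding strand). Precedence, where a variant could satisfy two rules:

* coding indels are called by `(|REF| - |ALT|) mod 3` even when they
  also touch splice bases — the frame effect is the stronger claim;
* a codon becoming a stop is stop-gain, never missense; a stop codon
  becoming coding is stop-loss;
* start-codon SNVs that do not create a stop are missense (start-loss
  is not a separate category here).

Single-base coding SNVs are classified from the affected codon alone;
equal-length multi-base substitutions compare the full reference and
mutated CDS translations and report the first differing residue. The
unit suite checks both paths against a brute-force oracle that mutates
the genome sequence and translates with biopython.

## Filtering cascade

Three stages with per-variant audit traces; the trace records the first
stage that removed each variant, so retained + removed always
partitions the input and the retained set is independent of stage order
(each stage is a per-variant predicate).

* `platform_nocall`: remove when the no-call fraction among
  platform-matched control genomes strictly exceeds 0.5. The strict
  inequality matters at the boundary: 27 of 54 is retained, 28 of 54
  removed.
* `known_variant`: allele-aware membership in a public known-variant
  set; used on the single-variant path, where "rare" means "not
  previously catalogued".
* `maf`: retain when panel MAF < 0.015 AND empirical MAF < 0.10 (both
  strict); used on the gene-burden path. The empirical denominator is
  called alleles over cases plus genotype-level controls combined —
  platform controls are excluded; a switch narrows it to cases only.
  A variant with no called alleles is retained by the panel rule alone
  and flagged.

Sensitivity re-runs (5% instead of 1.5% panel cutoff; admitting
low-quality calls) are pure configuration changes.

## Association statistics

**Fisher exact test.** Implemented directly from the hypergeometric
log-pmf over the full support (log-gamma binomials), because exhaustive
verification sweeps need ~10^6 calls. One-sided (`one_greater`) is the
upper tail; two-sided sums all tables at fixed margins whose point
probability is at most the observed one, with a 1e-9 relative tie
tolerance. Degenerate margins return 1. The test suite verifies
equality with integer enumeration for every 2x2 table with total <= 60
and cross-checks scipy on random tables.

**RVT1 burden test.** Logistic regression of case status on
x_i = r_i/n_i (rare sites carried over rare sites called; samples
called nowhere in the gene get x_i = 0 and are flagged), scored by the
LRT against the intercept-only fit, chi-square with 1 df. With a
handful of cases the interesting genes *separate*: every carrier is a
case. The maximum-likelihood coefficient then diverges, but the
likelihood supremum is finite; it is reached by a step function whose
perfectly-predicted samples contribute zero and whose samples tied at
the threshold value are fitted at their group proportion. Separation is
detected structurally (the controls' maximum x vs the cases' minimum x,
and the mirrored direction) before any iterative fit; the boundary LRT
is then computed in closed form. This is scale-invariant in x — a
capped iterative fit is not, because x values of order 1/n_sites need
coefficients far beyond any fixed cap. Non-separated fits use
statsmodels with a convergence/magnitude guard (100 iterations,
|coefficient| <= 30 on the logit scale) whose fallback re-derives the
best boundary. p = 1 exactly when the predictor is constant.

**Recessive scan.** Per gene, samples whose summed alternate-allele
count over the gene's rare sites is >= 2 (two het sites or one
homozygous site; no-calls contribute 0; phase is ignored — without
phasing, two hets are only *consistent with* compound heterozygosity).
Fisher exact on >=2 status, one-sided toward cases by default with the
two-sided variant exposed, since the sidedness of the original analysis
is not documented.

**Follow-up allele test.** Two-sided Fisher on carrier alleles vs
cohort allele totals, i.e. the table [[k1, N1], [k2, N2]] rather than
[[k1, N1-k1], [k2, N2-k2]]. The carriers-vs-totals table is the
convention under which the published follow-up comparison
(8/198 vs 213/8600 -> P = 0.17) reproduces; with non-carrier columns
the same counts give 0.164. For frequencies this small the two differ
only in the third decimal. The packaged follow-up variant table and its
reference-cohort allele summary live in `src/extremevar/data/`.

**Multiple testing.** Bonferroni with n = tests actually performed in
the scan at hand (retained variants; genes with >= 1 rare
protein-altering site), reported alongside every result table. Ranked
outputs sort by ascending p with ties broken lexicographically by gene
symbol, so reports are deterministic.

**Power calculators.** Invert the two tests: the smallest k such that k
case carriers (zero panel/control carriers; one distinct site per
carrier at the gene level) reaches a given threshold. For 13 cases,
379 panel individuals and 34 controls these give 4 (variant level, at
0.05/13,892) and 7 (gene level, at 0.05/10,508). The gene-level
statement is conditional on no control carriers — one control carrier
breaks separation and the p-value rises by three orders of magnitude.

## Incidental-findings screen

No rarity filtering: the screen sees every variant. A carrier is
reported when the variant is catalogued pathogenic by at least one
source, or is a LoF consequence (frameshift, stop-gain, stop-loss,
splice-site) in one of the genes flagged LoF-actionable. A benign
classification in any source vetoes reporting regardless of other
evidence; "uncertain" entries neither trigger nor veto. Zygosity is
reported but never used as a criterion. The 56-gene list (45
LoF-actionable) ships as an editable TSV because gene lists and
classifications version over time; the actionable flags in the packaged
fixture are a curated mechanism-based approximation.

## Synthetic-data generator

The generator emulates the study conditions as defaults: 13 cases, 34
genotype-level controls, 54 platform controls, a 379-individual
frequency panel, ~50%-no-call bad sites, and a 30% false-call rate
among apparent rare protein-altering candidates. Randomness flows from
one master seed through named substreams (CRC-keyed
`SeedSequence.spawn_key`), so enlarging one component does not perturb
draws elsewhere; identical configurations produce byte-identical
output files.

* **Genome**: two chromosomes of spaced, all-coding multi-exon genes
  (ATG...TAA, GT/AG introns, CDS length divisible by 3, alternating
  strands), each with planted truth-labelled variants spanning every
  consequence category.
* **Panel**: per segregating site, a fraction (default 0.20) is made
  common (uniform MAF 0.02-0.30) and a member of the known set; the
  rest draw from Beta(0.2, 50) — a rare-skewed spectrum with ~95% of
  mass below the 1.5% cutoff — with 30% left novel. No published
  site-frequency spectrum exists for such a cohort; the Beta shape is a
  modeling choice, exposed in the configuration.
* **Genotypes**: binomial(2, panel frequency) per sample per site,
  independent across samples — no linkage, no population structure.
* **Spikes**: a spiked gene's background genotypes are overridden:
  exactly the requested distinct case/control carriers, one alternate
  allele each at dedicated novel sites kept out of the panel pool. This
  realizes the conditional scenario the gene-level power statement
  describes.
* **No-calls**: a configured fraction of sites (default 5%) is "bad";
  platform controls are uncalled there with probability 0.55, so the
  >50% filter removes each bad site with probability
  P(Binom(54, 0.55) > 27) ~= 0.57 — verified against the binomial tail.
* **Errors**: false calls are injected as singleton alternate alleles
  in one case sample at otherwise-monomorphic novel coding sites —
  the form real sequencing errors take after screening for rare
  protein-altering variants — at a count that makes the expected error
  fraction among candidates equal the configured rate.

What passing on synthetic data does **not** show: robustness to linkage
disequilibrium, population stratification, relatedness, batch effects
between case and control platforms, or mis-specified gene models. Those
require real cohorts and the upstream QC (ancestry PCA, relatedness
screening) that is out of scope here.

## Pipeline and problem sizes

The pipeline keeps plain files between stages (multi-sample VCF, BED12,
FASTA, TSV) so each stage is a pure function of its inputs and can be
re-run alone; re-running an identical configuration reproduces every
output byte for byte, and the report carries a configuration hash.

The shipped verification runs use desk-scale inputs (the printed
contingency tables and carrier counts) plus synthetic cohorts of 60-200
genes and ~300-1,000 coding sites — sizes at which every statistic is
exercised, separation and null behaviour both occur, and the whole
suite completes in a few minutes on one CPU. The genome-scale counts of
a real study (tens of thousands of variants) enter only as the
divisors of the Bonferroni thresholds, which is how they are reported.
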