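# extremevar

Rare-variant enrichment analysis for extreme-phenotype case/control
cohorts.

## The problem

Extreme phenotypes — for instance, survival past 110 years — are so rare
that any strongly contributing genetic variant must itself be rare. A
whole-genome study of such a cohort therefore asks three questions:

1. Is any single rare protein-altering variant shared by more cases than
   chance allows, relative to a large reference population?
2. Is any *gene* enriched for rare protein-altering variants — different
   variants in different cases — under a dominant (burden) or recessive
   (two-hit) model?
3. Independent of the phenotype, do the genomes carry reportable
   pathogenic variants in medically actionable genes?

With a dozen cases, honest statistics hinge on exact tests, explicit
power arithmetic, and aggressive filtering of platform artefacts and
sequencing errors. `extremevar` implements that pipeline end to end, and
ships a synthetic-cohort generator that reproduces the statistical
structure of such a study (rare site-frequency spectrum, spiked genes,
platform no-call patterns, false rare calls) so every stage can be
validated without any cohort data.

## Methods at a glance

**Consequence annotation.** Variants are classified per transcript into
missense, frameshift, non-frameshift indel, stop-gain, stop-loss,
splice-site disruption (the two intronic bases flanking a coding exon,
GT donor / AG acceptor), or non-protein-altering. Coding SNVs are
classified by codon translation; coding indels by length mod 3.

**Filtering cascade.** Variants with a no-call fraction > 50% in
platform-matched control genomes are removed; the single-variant path
then removes variants present in a public known-variant set, while the
gene-burden path keeps only variants with reference-panel
MAF < 1.5% and empirical MAF < 10%. Every variant receives an audit
trace naming the first stage that removed it.

**Variant-level test.** For each rare protein-altering variant, a
one-sided Fisher exact test compares case carriers (k of n_cases)
against panel carriers, with Bonferroni correction over the variants
actually tested. With 13 cases and a 379-individual panel,

&nbsp;&nbsp;&nbsp;&nbsp;P(4 carriers, 0 in panel) = C(13,4)/C(392,4) = 7.4x10^-7,

below 0.05/13,892 = 3.6x10^-6 — i.e. the design detects a variant
shared by four cases.

**RVT1 burden test.** Per gene, case/control status is regressed
(logistic) on x_i = r_i / n_i, the proportion of the gene's rare sites
at which genome i carries an alternate allele. Significance comes from
a likelihood-ratio test against the intercept-only model (chi-square,
1 df). When carriers are all cases the likelihood separates; the LRT is
then computed analytically at the boundary from group-wise fitted
probabilities, which keeps the statistic finite and reproduces the
design's power: a gene altered in seven of 13 cases and no control is
detectable at 0.05/10,508.

**Recessive scan.** Per gene, a Fisher exact test on the number of cases
vs controls carrying two or more rare alleles (two heterozygous sites or
one homozygous; phase is not used).

**Incidental screen.** All genomes, unfiltered for rarity, are screened
against a 56-gene actionable list: catalogued-pathogenic variants (with
benign-in-any-source veto) are reported, as are novel loss-of-function
variants in the 45 genes where LoF is expected pathogenic.

## Worked example

```python
from extremevar import (SimulationConfig, generate_genome, simulate_panel,
                        simulate_cohort, burden_scan, annotate_cohort,
                        min_detectable_carriers_gene)
from extremevar.consequence import protein_altering_by_gene
from extremevar.filters import FilterConfig, run_cascade, BURDEN_TEST_STAGES

cfg = SimulationConfig(seed=1, n_genes=100, spike=(("GENE0042", 7, 0),))
genome = generate_genome(cfg)
panel, known, site_truth = simulate_panel(cfg, genome)
cohort, truth = simulate_cohort(cfg, panel, genome, site_truth)

calls = annotate_cohort(cohort, genome.models, genome.sequences)
by_gene = protein_altering_by_gene(calls)
platform = cohort.subset_samples(cohort.samples_with_label("platform_control"))
rare, traces = run_cascade(sorted({v for vs in by_gene.values() for v in vs}),
                           cohort, panel, known, platform, FilterConfig(),
                           stages=BURDEN_TEST_STAGES)
rare = set(rare)
results = burden_scan(cohort, {g: sorted(vs & rare)
                               for g, vs in by_gene.items() if vs & rare})
print(f"powered for {min_detectable_carriers_gene(13, 34, 0.05/10508)} case carriers")
for r in results[:3]:
    print(f"{r.gene_symbol}  carriers {r.carriers_cases}/13 vs "
          f"{r.carriers_controls}/34  LRT {r.lrt_statistic:.2f}  p {r.p_value:.2e}")
```

Output:

```
powered for 7 case carriers
GENE0042  carriers 7/13 vs 0/34  LRT 21.62  p 3.33e-06
GENE0005  carriers 3/13 vs 0/34  LRT 8.27  p 4.03e-03
GENE0001  carriers 2/13 vs 0/34  LRT 5.38  p 2.04e-02
```

The spiked gene (seven case carriers, no controls) separates the
logistic fit; its boundary LRT of 21.62 gives p = 3.3x10^-6, below the
genome-wide threshold 4.8x10^-6, exactly as the power calculator
predicts. The runner-up null genes sit orders of magnitude above it.

The same analysis is available as a command-line pipeline over standard
formats (multi-sample VCF, BED12 gene models, FASTA, TSV panels):

```bash
extremevar simulate --seed 1 --out demo/
extremevar run --config run.yaml --override filter.panel_maf_cutoff=0.05
```

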