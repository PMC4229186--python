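"""Shared fixtures: a hand-built toy gene and a seeded synthetic bundle."""

import numpy as np
import pytest

from extremevar.cohort_io import (CASE, CONTROL, PLATFORM_CONTROL, CohortGenotypes,
                                  VariantKey)
from extremevar.consequence import GeneModel
from extremevar.synthetic_data import (SimulationConfig, generate_genome,
                                       simulate_cohort, simulate_panel)


@pytest.fixture(scope="session")
def sim_bundle():
    """A seeded study-shaped simulation with one spiked gene, shared by
    filter / association / synthetic-data tests (never mutated)."""
    cfg = SimulationConfig(seed=7, n_genes=60, spike=(("GENE0010", 7, 0),))
    genome = generate_genome(cfg)
    panel, known, site_truth = simulate_panel(cfg, genome)
    cohort, truth = simulate_cohort(cfg, panel, genome, site_truth)
    return dict(config=cfg, genome=genome, panel=panel, known=known,
                site_truth=site_truth, cohort=cohort, truth=truth)


def make_cohort(case_cols, control_cols, platform_cols=None, variants=None,
                low_quality=None):
    """Build a small cohort from per-group genotype columns.

    Each *_cols argument is an array-like (n_samples, n_variants) of
    allele counts with -1 for no-call.
    """
    blocks, samples, labels = [], [], {}
    for prefix, label, block in (("S", CASE, case_cols),
                                 ("C", CONTROL, control_cols),
                                 ("P", PLATFORM_CONTROL, platform_cols)):
        if block is None:
            continue
        block = np.asarray(block, dtype=np.int8)
        for i in range(block.shape[0]):
            name = f"{prefix}{len(samples):03d}"
            samples.append(name)
            labels[name] = label
        blocks.append(block)
    counts = np.vstack(blocks)
    if variants is None:
        variants = [VariantKey("chr1", 100 + 10 * j, "A", "G")
                    for j in range(counts.shape[1])]
    return CohortGenotypes(variants=list(variants), samples=samples, labels=labels,
                           counts=counts, low_quality=low_quality)


def make_single_exon_gene(codons, chrom="chrT", offset=10, strand="+",
                          symbol="TOY"):
    """A one-exon gene from a list of codons, plus the genome dict."""
    cds = "".join(codons)
    seq = "T" * offset + cds + "T" * 20
    if strand == "-":
        from extremevar.consequence import reverse_complement
        seq = "T" * offset + reverse_complement(cds) + "T" * 20
    model = GeneModel(gene_symbol=symbol, chromosome=chrom, strand=strand,
                      exons=((offset, offset + len(cds)),),
                      cds_start=offset, cds_end=offset + len(cds),
                      transcript_id=f"{symbol}.t1")
    return {chrom: seq}, model
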