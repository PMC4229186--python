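"""Variant consequence classification against transcript models.

A variant is classified, per transcript, into one of six protein-altering
categories — missense, frameshift, non-frameshift indel, stop-gain,
stop-loss, splice-site disruption — or ``non_protein_altering``.  Coding
SNVs are classified by codon translation with the standard genetic code;
coding indels by length mod 3; splice-site calls cover exactly the two
intronic bases flanking each coding exon (the canonical GT donor / AG
acceptor dinucleotides on the coding strand).

Precedence rules: an indel touching both CDS and splice bases is called
by its frame effect; stop-gain beats missense when a codon becomes a
stop; a lost stop codon is stop-loss.  SNVs in the start codon that do
not create a stop are missense (start-loss is not a category here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .cohort_io import CohortGenotypes, VariantKey

PROTEIN_ALTERING_CATEGORIES = frozenset({
    "missense", "frameshift", "nonframeshift_indel",
    "stopgain", "stoploss", "splice_site",
})
LOF_CATEGORIES = frozenset({"frameshift", "stopgain", "stoploss", "splice_site"})

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


class ReferenceMismatchError(ValueError):
    """The variant's REF allele does not match the reference sequence."""


def fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference bases [start, end) 0-based from a dict of strings
    or any object with a pysam-style ``fetch`` method."""
    if hasattr(reference, "fetch"):
        return reference.fetch(chrom, start, end).upper()
    return reference[chrom][start:end].upper()


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model with genomic 0-based half-open exons."""

    gene_symbol: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        for (s, e) in exons:
            if s >= e:
                raise ValueError(f"empty exon ({s},{e}) in {self.gene_symbol}")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 >= s2:
                raise ValueError(f"exons overlap or unsorted in {self.gene_symbol}")
        object.__setattr__(self, "exons", exons)
        if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise ValueError(f"CDS outside exon span in {self.gene_symbol}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} not divisible by 3 in {self.gene_symbol}")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def coding_exons(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.coding_exons)

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in translation order."""
        pos = [p for s, e in self.coding_exons for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, reference) -> str:
        chunks = [fetch(reference, self.chromosome, s, e) for s, e in self.coding_exons]
        seq = "".join(chunks)
        return reverse_complement(seq) if self.strand == "-" else seq

    def splice_regions(self) -> list[tuple[int, int]]:
        """Two-base intronic intervals flanking each coding exon."""
        coding = [(s, e) for s, e in self.exons
                  if max(s, self.cds_start) < min(e, self.cds_end)]
        regions = []
        for i, (s, e) in enumerate(self.exons):
            if (s, e) not in coding:
                continue
            if i > 0:  # intronic bases upstream of this exon
                regions.append((s - 2, s))
            if i < len(self.exons) - 1:  # intronic bases downstream
                regions.append((e, e + 2))
        return regions


@dataclass(frozen=True)
class ConsequenceCall:
    variant: VariantKey
    gene_symbol: str
    category: str
    transcript_id: str = ""
    aa_position: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    @property
    def protein_altering(self) -> bool:
        return self.category in PROTEIN_ALTERING_CATEGORIES


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def classify_variant(variant: VariantKey, model: GeneModel,
                     reference) -> ConsequenceCall:
    """Classify one biallelic variant against one transcript model."""
    if variant.chrom != model.chromosome:
        raise ValueError(f"{variant} is not on {model.chromosome}")
    start = variant.pos - 1
    end = start + len(variant.ref)
    if not _overlaps(start, end, model.tx_start - 2, model.tx_end + 2):
        raise ValueError(f"{variant} outside transcript span of {model.gene_symbol}")
    observed = fetch(reference, variant.chrom, start, end)
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"reference is {observed!r} at {variant.chrom}:{variant.pos}, "
            f"variant REF is {variant.ref!r}")

    def call(category, **aa):
        return ConsequenceCall(variant=variant, gene_symbol=model.gene_symbol,
                               transcript_id=model.transcript_id,
                               category=category, **aa)

    in_cds = any(_overlaps(start, end, s, e) for s, e in model.coding_exons)
    in_splice = any(_overlaps(start, end, s, e) for s, e in model.splice_regions())

    if variant.is_indel:
        # frame effect wins over splice disruption when an indel spans both
        if in_cds:
            shift = (len(variant.ref) - len(variant.alt)) % 3
            return call("frameshift" if shift else "nonframeshift_indel")
        if in_splice:
            return call("splice_site")
        return call("non_protein_altering")

    # equal-length substitution
    if in_splice and not in_cds:
        return call("splice_site")
    if not in_cds:
        return call("non_protein_altering")

    cds_pos = model.cds_positions()
    index_of = {p: i for i, p in enumerate(cds_pos)}
    cds_ref = model.cds_sequence(reference)
    cds_alt = list(cds_ref)
    touched = []
    for offset in range(len(variant.ref)):
        g = start + offset
        i = index_of.get(g)
        if i is None:
            continue
        base = variant.alt[offset]
        cds_alt[i] = base.translate(_COMPLEMENT) if model.strand == "-" else base
        touched.append(i)
    if not touched:
        # substitution overlaps a coding exon boundary but no coding base
        return call("splice_site") if in_splice else call("non_protein_altering")
    cds_alt = "".join(cds_alt)

    if len(variant.ref) == 1:
        # single-base: classify from the affected codon alone
        i = touched[0]
        ci = i // 3
        ref_codon = cds_ref[3 * ci: 3 * ci + 3]
        alt_codon = cds_alt[3 * ci: 3 * ci + 3]
        aa_ref, aa_alt = translate_codon(ref_codon), translate_codon(alt_codon)
        return _aa_call(call, ci + 1, aa_ref, aa_alt)

    # multi-base substitution: compare the full translations
    for ci in range(len(cds_ref) // 3):
        aa_ref = translate_codon(cds_ref[3 * ci: 3 * ci + 3])
        aa_alt = translate_codon(cds_alt[3 * ci: 3 * ci + 3])
        if aa_ref != aa_alt:
            return _aa_call(call, ci + 1, aa_ref, aa_alt)
    return call("non_protein_altering")


def _aa_call(call, aa_position: int, aa_ref: str, aa_alt: str) -> ConsequenceCall:
    if aa_ref == aa_alt:
        return call("non_protein_altering")
    aa = dict(aa_position=aa_position, aa_ref=aa_ref, aa_alt=aa_alt)
    if aa_ref != "*" and aa_alt == "*":
        return call("stopgain", **aa)
    if aa_ref == "*" and aa_alt != "*":
        return call("stoploss", **aa)
    return call("missense", **aa)


def annotate_cohort(cohort: CohortGenotypes, models: Sequence[GeneModel],
                    reference) -> list[ConsequenceCall]:
    """One call per variant x overlapping transcript (span +/- 2 bp)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    calls: list[ConsequenceCall] = []
    for v in cohort.variants:
        start, end = v.pos - 1, v.pos - 1 + len(v.ref)
        for m in by_chrom.get(v.chrom, ()):
            if _overlaps(start, end, m.tx_start - 2, m.tx_end + 2):
                calls.append(classify_variant(v, m, reference))
    return calls


def protein_altering_by_gene(calls: Iterable[ConsequenceCall]) -> dict[str, set[VariantKey]]:
    """Gene -> set of variants protein-altering on any transcript."""
    out: dict[str, set[VariantKey]] = {}
    for c in calls:
        if c.protein_altering:
            out.setdefault(c.gene_symbol, set()).add(c.variant)
    return out


def protein_altering_variants(calls: Iterable[ConsequenceCall]) -> set[VariantKey]:
    return {c.variant for c in calls if c.protein_altering}


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Read single-transcript gene models from a BED12 file.

    The BED name field is ``gene_symbol`` or ``gene_symbol|transcript_id``.
    """
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"malformed BED12 blocks for {name}")
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            if exons[-1][1] != end:
                raise ValueError(f"blocks do not reach chromEnd for {name}")
            gene, _, tx = name.partition("|")
            models.append(GeneModel(gene_symbol=gene, chromosome=chrom, strand=strand,
                                    exons=exons, cds_start=thick_start,
                                    cds_end=thick_end, transcript_id=tx or name))
    return models


def write_gene_models_bed12(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chromosome, m.tx_start)):
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - m.tx_start) for s, e in m.exons)
            name = f"{m.gene_symbol}|{m.transcript_id}" if m.transcript_id else m.gene_symbol
            fh.write("\t".join(map(str, [
                m.chromosome, m.tx_start, m.tx_end, name, 0, m.strand,
                m.cds_start, m.cds_end, 0, len(m.exons), sizes, starts,
            ])) + "\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    """Write a reference FASTA deterministically (sorted contig names)."""
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
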