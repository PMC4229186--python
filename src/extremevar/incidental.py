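"""Incidental (secondary) pathogenic-findings screen.

Every genome is screened — with no rarity filtering — for reportable
variants in a list of medically actionable genes.  A variant is
reportable for a carrier when it is classified pathogenic by at least
one catalogue source with no benign classification in any source, or
when it is a loss-of-function consequence (frameshift, stop-gain,
stop-loss, splice-site) in a gene where novel LoF is expected
pathogenic.  A benign classification in any source vetoes reporting
regardless of other evidence; "uncertain" entries neither trigger nor
veto.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort_io import NOCALL, CohortGenotypes, VariantKey
from .consequence import LOF_CATEGORIES, ConsequenceCall

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("pathogenic", "benign", "uncertain")


@dataclass(frozen=True)
class AcmgGene:
    gene_symbol: str
    lof_actionable: bool


@dataclass(frozen=True)
class CatalogueEntry:
    variant: VariantKey
    classification: str
    source: str
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"classification must be one of {CLASSIFICATIONS}, "
                             f"got {self.classification!r}")


@dataclass(frozen=True)
class IncidentalFinding:
    sample: str
    variant: VariantKey
    gene_symbol: str
    basis: str  # catalogue_pathogenic | novel_lof
    consequence: str
    evidence: tuple[CatalogueEntry, ...] = ()
    allele_count: int = 1  # zygosity, reported but not a criterion


def screen_incidental(cohort: CohortGenotypes,
                      annotations: Sequence[ConsequenceCall],
                      acmg: Sequence[AcmgGene],
                      catalogue: Sequence[CatalogueEntry],
                      ) -> list[IncidentalFinding]:
    """Screen all samples for reportable variants in the listed genes."""
    acmg_by_symbol = {g.gene_symbol: g for g in acmg}
    calls_by_variant: dict[VariantKey, list[ConsequenceCall]] = {}
    for c in annotations:
        calls_by_variant.setdefault(c.variant, []).append(c)
    cat_by_variant: dict[VariantKey, list[CatalogueEntry]] = {}
    for e in catalogue:
        cat_by_variant.setdefault(e.variant, []).append(e)

    for v, entries in cat_by_variant.items():
        genes = {c.gene_symbol for c in calls_by_variant.get(v, [])}
        if not (genes & set(acmg_by_symbol)):
            logger.warning("catalogue entry at %s is outside every screened gene; "
                           "ignored", v)

    findings: list[IncidentalFinding] = []
    for v in cohort.variants:
        acmg_calls = [c for c in calls_by_variant.get(v, [])
                      if c.gene_symbol in acmg_by_symbol]
        if not acmg_calls:
            continue
        entries = cat_by_variant.get(v, [])
        if any(e.classification == "benign" for e in entries):
            continue  # benign anywhere vetoes
        pathogenic = tuple(e for e in entries if e.classification == "pathogenic")
        basis = None
        call = None
        if pathogenic:
            basis = "catalogue_pathogenic"
            altering = [c for c in acmg_calls if c.protein_altering]
            call = altering[0] if altering else acmg_calls[0]
        else:
            for c in acmg_calls:
                if (c.category in LOF_CATEGORIES
                        and acmg_by_symbol[c.gene_symbol].lof_actionable):
                    basis, call = "novel_lof", c
                    break
        if basis is None:
            continue
        j = cohort.variant_index(v)
        for i, sample in enumerate(cohort.samples):
            count = int(cohort.counts[i, j])
            if count != NOCALL and count >= 1:
                findings.append(IncidentalFinding(
                    sample=sample, variant=v, gene_symbol=call.gene_symbol,
                    basis=basis, consequence=call.category,
                    evidence=pathogenic, allele_count=count))
    findings.sort(key=lambda f: (f.sample, f.variant))
    return findings


# ---------------------------------------------------------------------------
# fixtures and I/O
# ---------------------------------------------------------------------------

def read_acmg_genes(path: str | Path) -> list[AcmgGene]:
    """Read a gene list TSV (gene_symbol, lof_actionable as 0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_symbol", "lof_actionable"])
    return [AcmgGene(str(r.gene_symbol), bool(int(r.lof_actionable)))
            for r in df.itertuples(index=False)]


def load_default_acmg_genes() -> list[AcmgGene]:
    """The packaged 56-gene incidental-findings list (45 LoF-actionable)."""
    with resources.as_file(resources.files("extremevar.data") / "acmg56.tsv") as p:
        return read_acmg_genes(p)


def write_acmg_genes(genes: Sequence[AcmgGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_symbol\tlof_actionable\n")
        for g in genes:
            fh.write(f"{g.gene_symbol}\t{int(g.lof_actionable)}\n")


def read_catalogue(path: str | Path) -> list[CatalogueEntry]:
    """Read a variant catalogue TSV
    (chrom, pos, ref, alt, classification, source, identifier)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                     names=["chrom", "pos", "ref", "alt", "classification",
                            "source", "identifier"])
    out = []
    for r in df.itertuples(index=False):
        key = VariantKey.normalized(str(r.chrom), int(r.pos), r.ref, r.alt)
        ident = "" if pd.isna(r.identifier) else str(r.identifier)
        out.append(CatalogueEntry(key, str(r.classification), str(r.source), ident))
    return out


def write_catalogue(entries: Sequence[CatalogueEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tclassification\tsource\tidentifier\n")
        for e in sorted(entries, key=lambda e: (e.variant, e.source)):
            v = e.variant
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{e.classification}\t"
                     f"{e.source}\t{e.identifier}\n")


def format_finding(f: IncidentalFinding) -> str:
    """Human-readable one-paragraph report block for a finding."""
    lines = [
        f"Sample {f.sample}: {f.variant} in {f.gene_symbol}",
        f"  consequence: {f.consequence}; alleles: {f.allele_count}",
        f"  basis: {f.basis}",
    ]
    for e in f.evidence:
        ident = f" ({e.identifier})" if e.identifier else ""
        lines.append(f"  evidence: {e.source} classifies as {e.classification}{ident}")
    return "\n".join(lines)


def write_findings(findings: Sequence[IncidentalFinding], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tchrom\tpos\tref\talt\tgene\tbasis\tconsequence\t"
                 "allele_count\tevidence\n")
        for f in findings:
            v = f.variant
            ev = ";".join(f"{e.source}:{e.classification}:{e.identifier}"
                          for e in f.evidence)
            fh.write(f"{f.sample}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                     f"{f.gene_symbol}\t{f.basis}\t{f.consequence}\t"
                     f"{f.allele_count}\t{ev}\n")
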