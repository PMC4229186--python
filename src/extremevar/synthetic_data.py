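"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study conditions end to end: a small diploid
reference with valid single-transcript gene models (ATG...stop, GT/AG
introns), a pool of segregating coding sites with a rare-skewed
Beta site-frequency spectrum, a sites-only reference frequency panel, a
known-variant set covering the common sites, case/control/platform-
control genotypes drawn binomially from the panel frequencies, gene
spike-ins with a prescribed number of case and control carriers,
platform no-call injection at a subset of bad sites, and a sequencing-
error process in which a configured fraction of apparent rare
protein-altering calls are false singletons.

Randomness flows from one master seed through named substreams, one per
operation, so extending one part of the configuration does not perturb
draws elsewhere.  Identical configurations produce byte-identical
output files.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_io import (NOCALL, CASE, CONTROL, PLATFORM_CONTROL, CohortGenotypes,
                        FrequencyPanel, KnownVariantSet, VariantKey,
                        write_cohort_vcf, write_frequency_panel, write_known_variants)
from .consequence import (GeneModel, PROTEIN_ALTERING_CATEGORIES, reverse_complement,
                          translate_codon, write_fasta, write_gene_models_bed12)
from .incidental import AcmgGene, CatalogueEntry, write_acmg_genes, write_catalogue

_SENSE_CODONS = sorted(
    c for c in ("".join(b) for b in itertools.product("ACGT", repeat=3))
    if translate_codon(c) != "*" and c != "ATG"
)
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 13 cases, 34 genotype-level controls, 54
    platform controls, a 379-individual frequency panel, ~30% of
    candidate rare calls injected as errors, and >50%-no-call bad sites."""

    seed: int = 0
    n_cases: int = 13
    n_controls: int = 34
    n_platform_controls: int = 54
    panel_individuals: int = 379
    n_genes: int = 60
    mean_sites_per_gene: float = 5.0
    sfs_alpha: float = 0.2
    sfs_beta: float = 50.0
    spike: tuple[tuple[str, int, int], ...] = ()
    nocall_site_fraction: float = 0.05
    nocall_rate_at_bad_sites: float = 0.55
    false_rare_call_rate: float = 0.30
    common_known_fraction: float = 0.20
    novel_rare_fraction: float = 0.30
    nonaltering_site_fraction: float = 0.20

    def __post_init__(self) -> None:
        for name in ("nocall_site_fraction", "nocall_rate_at_bad_sites",
                     "false_rare_call_rate", "common_known_fraction",
                     "novel_rare_fraction", "nonaltering_site_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_cases", "n_controls", "n_platform_controls",
                     "panel_individuals", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        self.spike = tuple((str(g), int(a), int(b)) for g, a, b in self.spike)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream keyed by the master seed."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["spike"] = [list(s) for s in self.spike]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["spike"] = tuple(tuple(s) for s in d.get("spike", []))
        return cls(**d)


@dataclass(frozen=True)
class PlantedVariant:
    variant: VariantKey
    gene: str
    category: str  # truth consequence category


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    models: list[GeneModel]
    truth_variants: list[PlantedVariant]      # category spectrum per gene
    segregating_sites: list[PlantedVariant]   # cohort site pool
    error_pool: list[PlantedVariant]          # reserved for false-call injection
    spike_sites: dict[str, list[PlantedVariant]] = field(default_factory=dict)

    def model(self, gene: str) -> GeneModel:
        return next(m for m in self.models if m.gene_symbol == gene)

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.sequences, path)

    def write_bed12(self, path: str | Path) -> None:
        write_gene_models_bed12(self.models, path)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _build_gene(rng: np.random.Generator, symbol: str, chrom: str,
                offset: int, strand: str) -> tuple[str, GeneModel]:
    """One all-coding multi-exon gene; returns (region sequence, model)."""
    n_exons = int(rng.integers(2, 5))
    codons_per_exon = rng.integers(15, 41, size=n_exons)
    total_codons = int(codons_per_exon.sum())
    codons = (["ATG"]
              + [str(rng.choice(_SENSE_CODONS)) for _ in range(total_codons - 2)]
              + ["TAA"])
    cds = "".join(codons)
    exon_seqs, start = [], 0
    for nc in codons_per_exon:
        exon_seqs.append(cds[start:start + 3 * int(nc)])
        start += 3 * int(nc)
    intron_seqs = ["GT" + _random_seq(rng, int(rng.integers(26, 77))) + "AG"
                   for _ in range(n_exons - 1)]
    region_parts, exon_bounds, pos = [], [], 0
    for i, ex in enumerate(exon_seqs):
        region_parts.append(ex)
        exon_bounds.append((pos, pos + len(ex)))
        pos += len(ex)
        if i < len(intron_seqs):
            region_parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    region = "".join(region_parts)
    if strand == "-":
        length = len(region)
        region = reverse_complement(region)
        exon_bounds = [(length - e, length - s) for s, e in reversed(exon_bounds)]
    exons = tuple((offset + s, offset + e) for s, e in exon_bounds)
    model = GeneModel(gene_symbol=symbol, chromosome=chrom, strand=strand,
                      exons=exons, cds_start=exons[0][0], cds_end=exons[-1][1],
                      transcript_id=f"{symbol}.t1")
    return region, model


def _substitute(rng: np.random.Generator, base: str) -> str:
    return str(rng.choice([b for b in _BASES if b != base]))


class _Planter:
    """Plants variants of known truth category against one gene model."""

    def __init__(self, genome: dict[str, str], model: GeneModel,
                 rng: np.random.Generator, used: set[int]):
        self.seq = genome[model.chromosome]
        self.model = model
        self.rng = rng
        self.used = used  # genomic positions already carrying a plant
        self.cds_pos = model.cds_positions()
        self.cds_seq = model.cds_sequence(genome)

    def _genomic_snv(self, cds_index: int, sense_alt: str) -> VariantKey:
        g = self.cds_pos[cds_index]
        ref = self.seq[g]
        alt = (reverse_complement(sense_alt) if self.model.strand == "-"
               else sense_alt)
        return VariantKey(self.model.chromosome, g + 1, ref, alt)

    def _free(self, *positions: int) -> bool:
        return not any(p in self.used for p in positions)

    def _claim(self, *positions: int) -> None:
        self.used.update(positions)

    def _codon_sub(self, want: str) -> PlantedVariant | None:
        """Search codons for a single substitution with the wanted effect:
        'missense', 'synonymous', or 'stopgain'."""
        n_codons = len(self.cds_seq) // 3
        order = self.rng.permutation(n_codons - 2) + 1  # skip start and stop
        for ci in order:
            codon = self.cds_seq[3 * ci:3 * ci + 3]
            aa = translate_codon(codon)
            for off in self.rng.permutation(3):
                g = self.cds_pos[3 * ci + off]
                if not self._free(g):
                    continue
                for b in _BASES:
                    if b == codon[off]:
                        continue
                    alt_codon = codon[:off] + b + codon[off + 1:]
                    aa2 = translate_codon(alt_codon)
                    ok = {"missense": aa2 != aa and aa2 != "*" and aa != "*",
                          "synonymous": aa2 == aa,
                          "stopgain": aa != "*" and aa2 == "*"}[want]
                    if ok:
                        self._claim(g)
                        category = ("non_protein_altering" if want == "synonymous"
                                    else want)
                        return PlantedVariant(self._genomic_snv(3 * ci + off, b),
                                              self.model.gene_symbol, category)
        return None

    def missense(self):
        return self._codon_sub("missense")

    def synonymous(self):
        return self._codon_sub("synonymous")

    def stopgain(self):
        return self._codon_sub("stopgain")

    def stoploss(self) -> PlantedVariant | None:
        i = len(self.cds_seq) - 3  # first base of the TAA stop codon
        g = self.cds_pos[i]
        if not self._free(g):
            return None
        self._claim(g)
        return PlantedVariant(self._genomic_snv(i, "C"),  # TAA -> CAA (Gln)
                              self.model.gene_symbol, "stoploss")

    def _deletion(self, ndel: int, category: str) -> PlantedVariant | None:
        for s, e in self.rng.permutation(np.array(self.model.coding_exons)):
            s, e = int(s), int(e)
            if e - s < ndel + 4:
                continue
            for p in self.rng.permutation(np.arange(s + 1, e - ndel - 1)):
                p = int(p)
                span = range(p, p + ndel + 1)
                if self._free(*span):
                    self._claim(*span)
                    ref = self.seq[p:p + ndel + 1]
                    return PlantedVariant(
                        VariantKey(self.model.chromosome, p + 1, ref, ref[0]),
                        self.model.gene_symbol, category)
        return None

    def frameshift(self):
        return self._deletion(1, "frameshift")

    def nonframeshift_indel(self):
        return self._deletion(3, "nonframeshift_indel")

    def splice_site(self) -> PlantedVariant | None:
        regions = self.model.splice_regions()
        for ri in self.rng.permutation(len(regions)):
            s, _ = regions[int(ri)]
            for p in (s, s + 1):
                if self._free(p):
                    self._claim(p)
                    ref = self.seq[p]
                    return PlantedVariant(
                        VariantKey(self.model.chromosome, p + 1, ref,
                                   _substitute(self.rng, ref)),
                        self.model.gene_symbol, "splice_site")
        return None

    def intronic(self) -> PlantedVariant | None:
        exons = self.model.exons
        for i in self.rng.permutation(len(exons) - 1):
            i = int(i)
            lo, hi = exons[i][1] + 2, exons[i + 1][0] - 2
            if hi - lo < 3:
                continue
            for p in self.rng.permutation(np.arange(lo, hi)):
                p = int(p)
                if self._free(p):
                    self._claim(p)
                    ref = self.seq[p]
                    return PlantedVariant(
                        VariantKey(self.model.chromosome, p + 1, ref,
                                   _substitute(self.rng, ref)),
                        self.model.gene_symbol, "non_protein_altering")
        return None


_SPECTRUM_KINDS = ("missense", "stopgain", "stoploss", "frameshift",
                   "nonframeshift_indel", "splice_site", "synonymous", "intronic")


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Two-chromosome reference with valid gene models and planted
    truth-labelled variants spanning every consequence category."""
    rng = config.rng("genome")
    half = (config.n_genes + 1) // 2
    chrom_seqs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    chrom_len = {"chr1": 0, "chr2": 0}
    models: list[GeneModel] = []
    truth: list[PlantedVariant] = []
    sites: list[PlantedVariant] = []
    errors: list[PlantedVariant] = []

    for gi in range(config.n_genes):
        chrom = "chr1" if gi < half else "chr2"
        spacer = _random_seq(rng, 100)
        chrom_seqs[chrom].append(spacer)
        offset = chrom_len[chrom] + len(spacer)
        strand = "+" if gi % 2 == 0 else "-"
        region, model = _build_gene(rng, f"GENE{gi:04d}", chrom, offset, strand)
        chrom_seqs[chrom].append(region)
        chrom_len[chrom] = offset + len(region)
        models.append(model)
    for chrom in chrom_seqs:
        chrom_seqs[chrom].append(_random_seq(rng, 100))
    sequences = {c: "".join(parts) for c, parts in chrom_seqs.items()}

    spike_need = {gene: kc + kk for gene, kc, kk in config.spike}
    spike_sites: dict[str, list[PlantedVariant]] = {}
    for model in models:
        used: set[int] = set()
        planter = _Planter(sequences, model, rng, used)
        # dedicated novel sites for spike-ins, kept out of the panel pool
        need = spike_need.get(model.gene_symbol, 0)
        if need:
            planted = [planter.missense() for _ in range(need)]
            if any(pv is None for pv in planted):
                raise ValueError(f"cannot plant {need} spike sites in "
                                 f"{model.gene_symbol}")
            spike_sites[model.gene_symbol] = planted
        # one variant of every category per gene, truth-labelled
        for kind in _SPECTRUM_KINDS:
            pv = getattr(planter, kind)()
            if pv is not None:
                truth.append(pv)
        # segregating-site pool for the cohort simulation
        n_sites = max(1, int(rng.poisson(config.mean_sites_per_gene)))
        for _ in range(n_sites):
            if rng.random() < config.nonaltering_site_fraction:
                pv = planter.synonymous() or planter.intronic()
            else:
                pv = planter.missense()
            if pv is not None:
                sites.append(pv)
        for _ in range(2):  # reserve for error injection
            pv = planter.missense()
            if pv is not None:
                errors.append(pv)

    missing = set(spike_need) - {m.gene_symbol for m in models}
    if missing:
        raise ValueError(f"spiked genes not in genome: {sorted(missing)}")
    return SyntheticGenome(sequences=sequences, models=models,
                           truth_variants=truth, segregating_sites=sites,
                           error_pool=errors, spike_sites=spike_sites)


# ---------------------------------------------------------------------------
# panel, cohort, catalogue
# ---------------------------------------------------------------------------

def simulate_panel(config: SimulationConfig, genome: SyntheticGenome,
                   ) -> tuple[FrequencyPanel, KnownVariantSet, pd.DataFrame]:
    """Reference-panel frequencies for the segregating-site pool.

    A configured fraction of sites is made common (MAF >= 1.5%) and a
    member of the known-variant set; the rest draw from the rare Beta
    spectrum, with a fraction left novel (absent from the panel).
    """
    rng = config.rng("panel")
    an = 2 * config.panel_individuals
    entries: dict[VariantKey, tuple[int, int]] = {}
    known: set[VariantKey] = set()
    rows = []
    for pv in genome.segregating_sites:
        if rng.random() < config.common_known_fraction:
            freq = float(rng.uniform(0.02, 0.30))
            common = True
        elif rng.random() < config.novel_rare_fraction:
            freq, common = 0.0, False
        else:
            freq = float(rng.beta(config.sfs_alpha, config.sfs_beta))
            common = False
        if freq > 0:
            ac = max(1, int(round(freq * an)))
            entries[pv.variant] = (ac, an)
            freq = ac / an
        if common:
            known.add(pv.variant)
        rows.append({"chrom": pv.variant.chrom, "pos": pv.variant.pos,
                     "ref": pv.variant.ref, "alt": pv.variant.alt,
                     "gene": pv.gene, "category": pv.category,
                     "panel_freq": freq, "is_common_known": common})
    return (FrequencyPanel(entries, config.panel_individuals),
            KnownVariantSet(known), pd.DataFrame(rows))


@dataclass
class TruthSet:
    """Ground truth serialized alongside the simulated outputs."""

    sites: pd.DataFrame  # per-site status incl. spikes, errors, bad sites
    spiked: dict[str, dict]  # gene -> {case_samples, control_samples, sites}
    findings: list[tuple[str, VariantKey, str]] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(self.sites.columns) + "\n")
            self.sites.to_csv(fh, sep="\t", header=False, index=False)


def simulate_cohort(config: SimulationConfig, panel: FrequencyPanel,
                    genome: SyntheticGenome,
                    site_truth: pd.DataFrame | None = None,
                    ) -> tuple[CohortGenotypes, TruthSet]:
    """Draw case/control/platform-control genotypes from the panel
    frequencies, then apply spikes, bad-site no-calls and false calls."""
    rng = config.rng("cohort")
    cases = [f"SC{i:02d}" for i in range(config.n_cases)]
    controls = [f"PGP{i:02d}" for i in range(config.n_controls)]
    platform = [f"HAP{i:02d}" for i in range(config.n_platform_controls)]
    samples = cases + controls + platform
    labels = {**{s: CASE for s in cases}, **{s: CONTROL for s in controls},
              **{s: PLATFORM_CONTROL for s in platform}}

    sites = list(genome.segregating_sites)
    n_base = len(sites)
    freqs = np.array([panel.frequency(pv.variant) for pv in sites])
    counts = rng.binomial(2, freqs[None, :],
                          size=(len(samples), len(sites))).astype(np.int8)

    if site_truth is None:
        _, _, site_truth = simulate_panel(config, genome)
    truth = site_truth.copy()
    truth["is_spiked"] = False
    truth["is_error"] = False
    truth["is_bad_site"] = False
    truth["spike_carrier"] = ""

    # --- gene spike-ins: dedicated novel sites, exactly k distinct carriers.
    # A spiked gene's genotypes are overridden: background draws at its
    # segregating sites are cleared so the gene carries exactly the
    # planted alleles (the gene-level power statement is conditional on
    # no other carriers in the gene).
    spiked_genes = {gene for gene, _, _ in config.spike}
    for j, pv in enumerate(sites):
        if pv.gene in spiked_genes:
            counts[:, j] = 0
    spiked_meta: dict[str, dict] = {}
    spike_rows = []
    spike_cols = []
    spike_pvs: list[PlantedVariant] = []
    for gene, k_case, k_ctrl in config.spike:
        if k_case > config.n_cases or k_ctrl > config.n_controls:
            raise ValueError(f"spike for {gene} exceeds cohort size")
        planted = genome.spike_sites.get(gene, [])
        need = k_case + k_ctrl
        if len(planted) < need:
            raise ValueError(f"genome has {len(planted)} spike sites for {gene}, "
                             f"need {need}; regenerate with matching config")
        case_idx = rng.choice(config.n_cases, size=k_case, replace=False)
        ctrl_idx = rng.choice(config.n_controls, size=k_ctrl, replace=False)
        carriers_case = [cases[i] for i in sorted(case_idx)]
        carriers_ctrl = [controls[i] for i in sorted(ctrl_idx)]
        for sample, pv in zip(carriers_case + carriers_ctrl, planted):
            col = np.zeros(len(samples), dtype=np.int8)
            col[samples.index(sample)] = 1
            spike_cols.append(col)
            spike_pvs.append(pv)
            spike_rows.append({"chrom": pv.variant.chrom, "pos": pv.variant.pos,
                               "ref": pv.variant.ref, "alt": pv.variant.alt,
                               "gene": pv.gene, "category": pv.category,
                               "panel_freq": 0.0, "is_common_known": False,
                               "is_spiked": True, "is_error": False,
                               "is_bad_site": False, "spike_carrier": sample})
        spiked_meta[gene] = {
            "case_samples": carriers_case, "control_samples": carriers_ctrl,
            "sites": [pv.variant for pv in planted[:need]]}
    if spike_cols:
        sites = sites + spike_pvs
        counts = np.hstack([counts, np.stack(spike_cols, axis=1)])
        truth = pd.concat([truth, pd.DataFrame(spike_rows)], ignore_index=True)

    # --- platform no-call injection at bad sites (segregating pool only) --
    n_bad = int(round(config.nocall_site_fraction * n_base))
    bad_pool = np.arange(n_base)
    if n_bad and len(bad_pool):
        bad = rng.choice(bad_pool, size=min(n_bad, len(bad_pool)), replace=False)
        bad = np.sort(bad)
        p0 = len(cases) + len(controls)
        mask = rng.random((len(platform), len(bad))) < config.nocall_rate_at_bad_sites
        block = counts[p0:, bad]
        block[mask] = NOCALL
        counts[p0:, bad] = block
        truth.loc[bad, "is_bad_site"] = True

    # --- sequencing-error injection ---------------------------------------
    case_rows = np.arange(len(cases))
    real_rare = 0
    for j, pv in enumerate(sites):
        if (pv.category in PROTEIN_ALTERING_CATEGORIES
                and not truth.loc[j, "is_common_known"]
                and (counts[case_rows, j] > 0).any()):
            real_rare += 1
    f = config.false_rare_call_rate
    err_pool = [pv for pv in genome.error_pool if pv.gene not in spiked_genes]
    n_err = int(round(f / (1.0 - f) * real_rare)) if f < 1.0 else len(err_pool)
    if n_err > len(err_pool):
        n_err = len(err_pool)
    err_rows = []
    if n_err:
        err_sites = err_pool[:n_err]
        err_counts = np.zeros((len(samples), n_err), dtype=np.int8)
        victims = rng.integers(0, len(cases), size=n_err)
        for k, pv in enumerate(err_sites):
            err_counts[victims[k], k] = 1
            err_rows.append({"chrom": pv.variant.chrom, "pos": pv.variant.pos,
                             "ref": pv.variant.ref, "alt": pv.variant.alt,
                             "gene": pv.gene, "category": pv.category,
                             "panel_freq": 0.0, "is_common_known": False,
                             "is_spiked": False, "is_error": True,
                             "is_bad_site": False,
                             "spike_carrier": samples[victims[k]]})
        sites = sites + list(err_sites)
        counts = np.hstack([counts, err_counts])
    if err_rows:
        truth = pd.concat([truth, pd.DataFrame(err_rows)], ignore_index=True)

    cohort = CohortGenotypes(variants=[pv.variant for pv in sites],
                             samples=samples, labels=labels, counts=counts)
    return cohort, TruthSet(sites=truth, spiked=spiked_meta)


def simulate_catalogue(config: SimulationConfig, genome: SyntheticGenome,
                       cohort: CohortGenotypes,
                       ) -> tuple[list[AcmgGene], list[CatalogueEntry],
                                  CohortGenotypes, TruthSet]:
    """Screened-gene list, variant catalogue and planted carriers.

    Uses the first 56 genes of the genome (45 LoF-actionable) and plants
    a catalogued-pathogenic carrier, a benign-vetoed carrier, a novel
    LoF carrier in an actionable gene, a LoF carrier in a
    non-actionable gene, and an uncertain-only carrier.  Only the first
    and third are reportable; the truth records exactly those.
    """
    if len(genome.models) < 56:
        raise ValueError("catalogue simulation needs at least 56 gene models")
    rng = config.rng("catalogue")
    symbols = [m.gene_symbol for m in genome.models[:56]]
    acmg = [AcmgGene(s, lof_actionable=(i < 45)) for i, s in enumerate(symbols)]

    def pick(gene: str, category: str) -> PlantedVariant:
        for pv in genome.truth_variants:
            if pv.gene == gene and pv.category == category:
                return pv
        raise ValueError(f"no planted {category} variant in {gene}")

    cases = cohort.samples_with_label(CASE)
    carriers = [cases[int(i)] for i in rng.integers(0, len(cases), size=5)]
    plants = [
        ("catalogue_pathogenic", pick(symbols[0], "missense"), carriers[0]),
        ("benign_vetoed", pick(symbols[1], "missense"), carriers[1]),
        ("novel_lof", pick(symbols[2], "frameshift"), carriers[2]),
        ("lof_not_actionable", pick(symbols[50], "splice_site"), carriers[3]),
        ("uncertain_only", pick(symbols[3], "missense"), carriers[4]),
    ]
    catalogue = [
        CatalogueEntry(plants[0][1].variant, "pathogenic", "ClinVar", "rs900001"),
        CatalogueEntry(plants[1][1].variant, "pathogenic", "HGMD", "CM900002"),
        CatalogueEntry(plants[1][1].variant, "benign", "ClinVar", "rs900002"),
        CatalogueEntry(plants[4][1].variant, "uncertain", "LSDB", "lsdb:900005"),
    ]
    new_keys, cols = [], []
    for _, pv, sample in plants:
        col = np.zeros((cohort.n_samples, 1), dtype=np.int8)
        col[cohort.samples.index(sample), 0] = 1
        new_keys.append(pv.variant)
        cols.append(col)
    cohort2 = cohort.with_variants(new_keys, np.hstack(cols))
    findings = [(plants[0][2], plants[0][1].variant, "catalogue_pathogenic"),
                (plants[2][2], plants[2][1].variant, "novel_lof")]
    truth = TruthSet(sites=pd.DataFrame(), spiked={}, findings=findings)
    return acmg, catalogue, cohort2, truth


# ---------------------------------------------------------------------------
# one-call dataset writer
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path,
                 with_catalogue: bool = True) -> dict[str, Path]:
    """Generate a complete synthetic dataset as standard-format files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    panel, known, site_truth = simulate_panel(config, genome)
    cohort, truth = simulate_cohort(config, panel, genome, site_truth)
    paths = {
        "reference": outdir / "reference.fa",
        "gene_models": outdir / "genes.bed",
        "cohort_vcf": outdir / "cohort.vcf",
        "panel": outdir / "panel.tsv",
        "known": outdir / "known.tsv",
        "labels": outdir / "labels.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "config": outdir / "config.yaml",
    }
    if with_catalogue:
        acmg, catalogue, cohort, cat_truth = simulate_catalogue(config, genome, cohort)
        paths["acmg_genes"] = outdir / "acmg_genes.tsv"
        paths["catalogue"] = outdir / "catalogue.tsv"
        paths["truth_findings"] = outdir / "truth_findings.tsv"
        write_acmg_genes(acmg, paths["acmg_genes"])
        write_catalogue(catalogue, paths["catalogue"])
        with open(paths["truth_findings"], "w") as fh:
            fh.write("#sample\tchrom\tpos\tref\talt\tbasis\n")
            for sample, v, basis in cat_truth.findings:
                fh.write(f"{sample}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{basis}\n")
    genome.write_fasta(paths["reference"])
    genome.write_bed12(paths["gene_models"])
    write_cohort_vcf(cohort, paths["cohort_vcf"])
    write_frequency_panel(panel, paths["panel"], fmt="tsv")
    write_known_variants(known, paths["known"])
    with open(paths["labels"], "w") as fh:
        fh.write("#sample\tlabel\n")
        for s in cohort.samples:
            fh.write(f"{s}\t{cohort.labels[s]}\n")
    truth.write_tsv(paths["truth_sites"])
    config.to_yaml(paths["config"])
    return paths
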