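"""Cohort, frequency-panel and known-variant I/O.

The pipeline's in-memory cohort is a dense sample x variant matrix of
diploid alternate-allele counts with an explicit no-call state, plus a
per-genotype quality tier.  Coordinates are VCF 1-based externally and
0-based half-open internally; the conversion happens only in this module
and in :mod:`extremevar.consequence`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a no-call genotype in the allele-count matrix
NOCALL = -1

_VALID_BASES = frozenset("ACGT")

CASE = "case"
CONTROL = "control"
PLATFORM_CONTROL = "platform_control"
LABELS = (CASE, CONTROL, PLATFORM_CONTROL)


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping >= 1 base each.

    This makes membership tests against the known set and the frequency
    panel invariant to the padding VCF writers add around indels.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """Biallelic variant identity: chromosome, 1-based position, REF, ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(
                    f"alleles must be non-empty A/C/G/T strings, got "
                    f"{self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos}"
                )
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a key with shared prefix/suffix padding trimmed off."""
        pos, ref, alt = _trim_alleles(pos, ref.upper(), alt.upper())
        return cls(chrom, pos, ref, alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class Genotype:
    """A single diploid genotype: allele count, called flag, quality tier.

    ``allele_count`` is undefined (raises) for a no-call, so downstream
    code cannot silently treat missing genotypes as homozygous reference.
    """

    __slots__ = ("_count", "called", "quality_tier")

    def __init__(self, allele_count: int | None = None, called: bool = True,
                 quality_tier: str = "high"):
        if called:
            if allele_count not in (0, 1, 2):
                raise ValueError(f"allele_count must be 0/1/2, got {allele_count}")
        if quality_tier not in ("high", "low"):
            raise ValueError(f"quality_tier must be 'high' or 'low', got {quality_tier}")
        self._count = allele_count if called else None
        self.called = called
        self.quality_tier = quality_tier

    @classmethod
    def no_call(cls, quality_tier: str = "high") -> "Genotype":
        return cls(called=False, quality_tier=quality_tier)

    @property
    def allele_count(self) -> int:
        if not self.called:
            raise ValueError("allele_count is undefined for a no-call genotype")
        return self._count

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return (self.called, self._count, self.quality_tier) == (
            other.called, other._count, other.quality_tier)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = "./." if not self.called else str(self._count)
        return f"Genotype({body}, {self.quality_tier})"


@dataclass
class CohortGenotypes:
    """Dense genotype matrix over an ordered variant and sample list.

    ``counts`` holds alternate-allele counts (int8), with :data:`NOCALL`
    marking uncalled genotypes; ``low_quality`` flags genotypes below the
    configured quality threshold.
    """

    variants: list[VariantKey]
    samples: list[str]
    labels: dict[str, str]
    counts: np.ndarray  # (n_samples, n_variants) int8, NOCALL = no-call
    low_quality: np.ndarray = field(default=None)  # same shape, bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.low_quality is None:
            self.low_quality = np.zeros_like(self.counts, dtype=bool)
        self.low_quality = np.asarray(self.low_quality, dtype=bool)
        ns, nv = len(self.samples), len(self.variants)
        if self.counts.shape != (ns, nv):
            raise ValueError(
                f"counts shape {self.counts.shape} != (samples={ns}, variants={nv})")
        if self.low_quality.shape != self.counts.shape:
            raise ValueError("low_quality shape mismatch")
        if len(set(self.samples)) != ns:
            raise ValueError("sample identifiers must be unique")
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a label: {missing}")
        bad = {l for l in self.labels.values()} - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}; expected one of {LABELS}")
        self._index = {v: i for i, v in enumerate(self.variants)}

    # -- basic accessors ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, key: VariantKey) -> int:
        return self._index[key]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index

    def genotype(self, sample: str, variant: VariantKey) -> Genotype:
        i, j = self.samples.index(sample), self.variant_index(variant)
        c = int(self.counts[i, j])
        tier = "low" if self.low_quality[i, j] else "high"
        if c == NOCALL:
            return Genotype.no_call(tier)
        return Genotype(c, quality_tier=tier)

    def samples_with_label(self, *labels: str) -> list[str]:
        want = set(labels)
        return [s for s in self.samples if self.labels[s] in want]

    def sample_indices(self, *labels: str) -> np.ndarray:
        want = set(labels)
        return np.array([i for i, s in enumerate(self.samples)
                         if self.labels[s] in want], dtype=int)

    # -- derived views --------------------------------------------------
    def effective_counts(self, include_low_quality: bool = True) -> np.ndarray:
        """Allele-count matrix with low-quality calls masked to no-call
        when ``include_low_quality`` is false."""
        if include_low_quality:
            return self.counts.copy()
        out = self.counts.copy()
        out[self.low_quality] = NOCALL
        return out

    def nocall_fraction(self, variant: VariantKey | int,
                        sample_idx: np.ndarray | None = None) -> float:
        j = variant if isinstance(variant, (int, np.integer)) else self.variant_index(variant)
        col = self.counts[:, j] if sample_idx is None else self.counts[sample_idx, j]
        return float(np.mean(col == NOCALL))

    def subset_samples(self, samples: Sequence[str]) -> "CohortGenotypes":
        idx = [self.samples.index(s) for s in samples]
        return CohortGenotypes(
            variants=list(self.variants),
            samples=list(samples),
            labels={s: self.labels[s] for s in samples},
            counts=self.counts[idx, :].copy(),
            low_quality=self.low_quality[idx, :].copy(),
        )

    def subset_variants(self, keys: Sequence[VariantKey]) -> "CohortGenotypes":
        idx = [self.variant_index(k) for k in keys]
        return CohortGenotypes(
            variants=list(keys),
            samples=list(self.samples),
            labels=dict(self.labels),
            counts=self.counts[:, idx].copy(),
            low_quality=self.low_quality[:, idx].copy(),
        )

    def with_variants(self, keys: Sequence[VariantKey], counts: np.ndarray,
                      low_quality: np.ndarray | None = None) -> "CohortGenotypes":
        """Return a new cohort with extra variant columns appended."""
        counts = np.asarray(counts, dtype=np.int8)
        if low_quality is None:
            low_quality = np.zeros_like(counts, dtype=bool)
        return CohortGenotypes(
            variants=list(self.variants) + list(keys),
            samples=list(self.samples),
            labels=dict(self.labels),
            counts=np.hstack([self.counts, counts]),
            low_quality=np.hstack([self.low_quality, low_quality]),
        )


class FrequencyPanel:
    """Sites-only allele frequencies from a reference population.

    A variant absent from the panel is treated as novel: counts
    ``(0, 2 * n_individuals)``.
    """

    def __init__(self, entries: Mapping[VariantKey, tuple[int, int]],
                 n_individuals: int):
        if n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        for key, (ac, an) in entries.items():
            if not (0 <= ac <= an):
                raise ValueError(f"need 0 <= AC <= AN, got AC={ac} AN={an} at {key}")
            if an > 2 * n_individuals:
                raise ValueError(
                    f"AN={an} exceeds 2 x n_individuals={2*n_individuals} at {key}")
        self.entries = dict(entries)
        self.n_individuals = n_individuals

    def counts(self, key: VariantKey) -> tuple[int, int]:
        return self.entries.get(key, (0, 2 * self.n_individuals))

    def frequency(self, key: VariantKey) -> float:
        ac, an = self.counts(key)
        return ac / an if an else 0.0

    def carriers(self, key: VariantKey) -> int:
        """Lower-bound carrier count implied by the allele count.

        Individual genotypes are unknown for a sites-only panel; rare
        alternate alleles are overwhelmingly heterozygous, so the allele
        count (capped at the panel size) stands in for carriers.
        """
        ac, _ = self.counts(key)
        return min(ac, self.n_individuals)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


class KnownVariantSet:
    """Allele-aware membership set emulating a public variant database."""

    def __init__(self, keys: Iterable[VariantKey] = ()):
        self._keys = set(keys)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def add(self, key: VariantKey) -> None:
        self._keys.add(key)

    def __iter__(self):
        return iter(sorted(self._keys))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _is_vcf(path: str | Path) -> bool:
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return True
    try:
        import gzip
        opener = gzip.open if path.name.endswith(".gz") else open
        with opener(path, "rt") as fh:
            return fh.readline().startswith("##fileformat=VCF")
    except OSError:
        return False


def read_cohort_vcf(path: str | Path, label_map: Mapping[str, str],
                    quality_key: str | None = None,
                    quality_threshold: float | None = None) -> CohortGenotypes:
    """Read a multi-sample VCF into a :class:`CohortGenotypes`.

    Multi-allelic records are decomposed into one biallelic key per ALT
    with per-allele counts recomputed; ``./.`` and half-calls become
    no-calls; records with symbolic alleles are skipped with a warning.
    When ``quality_key`` names a FORMAT field, genotypes whose value
    falls below ``quality_threshold`` are tiered low.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    missing = sorted(set(label_map) - set(header_samples))
    if missing:
        raise ValueError(f"samples in label_map absent from VCF header: {missing}")
    keep = [s for s in header_samples if s in label_map]
    dropped = [s for s in header_samples if s not in label_map]
    if dropped:
        logger.warning("dropping %d unlabelled VCF samples: %s", len(dropped), dropped)
    keep_idx = [header_samples.index(s) for s in keep]

    variants: list[VariantKey] = []
    cols: list[np.ndarray] = []
    lq_cols: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT or []
        if any(("<" in a) or (">" in a) or a in ("*", ".") or
               not set(a) <= _VALID_BASES for a in alts):
            logger.warning("skipping record with symbolic/non-ACGT ALT at %s:%s",
                           rec.CHROM, rec.POS)
            continue
        gts = rec.genotypes  # list of [a1, a2, ..., phased]
        lowq = np.zeros(len(keep), dtype=bool)
        if quality_key is not None:
            fmt = rec.format(quality_key)
            if fmt is not None:
                vals = np.asarray(fmt, dtype=float).reshape(len(header_samples), -1)[:, 0]
                lowq = vals[keep_idx] < float(quality_threshold)
        for ai, alt in enumerate(alts):
            key = VariantKey.normalized(rec.CHROM, rec.POS, rec.REF, alt)
            col = np.empty(len(keep), dtype=np.int8)
            for out_i, si in enumerate(keep_idx):
                g = gts[si]
                alleles = g[:-1]
                if len(alleles) != 2 or any(a < 0 for a in alleles):
                    col[out_i] = NOCALL  # ./., half-calls, non-diploid
                else:
                    col[out_i] = sum(1 for a in alleles if a == ai + 1)
            variants.append(key)
            cols.append(col)
            lq_cols.append(lowq.copy())

    counts = (np.stack(cols, axis=1) if cols
              else np.zeros((len(keep), 0), dtype=np.int8))
    lq = (np.stack(lq_cols, axis=1) if lq_cols
          else np.zeros((len(keep), 0), dtype=bool))
    return CohortGenotypes(variants=variants, samples=keep,
                           labels={s: label_map[s] for s in keep},
                           counts=counts, low_quality=lq)


def write_cohort_vcf(cohort: CohortGenotypes, path: str | Path,
                     quality_key: str = "GQ",
                     low_gq: int = 10, high_gq: int = 99) -> None:
    """Write the cohort back to a deterministic plain-text VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({v.chrom for v in cohort.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f'##FORMAT=<ID={quality_key},Number=1,Type=Integer,'
                 'Description="Genotype quality tier surrogate">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.samples) + "\n")
        order = sorted(range(cohort.n_variants),
                       key=lambda j: (cohort.variants[j].chrom, cohort.variants[j].pos,
                                      cohort.variants[j].ref, cohort.variants[j].alt))
        gt_text = {0: "0/0", 1: "0/1", 2: "1/1", NOCALL: "./."}
        for j in order:
            v = cohort.variants[j]
            fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".",
                      f"GT:{quality_key}"]
            for i in range(cohort.n_samples):
                gq = low_gq if cohort.low_quality[i, j] else high_gq
                fields.append(f"{gt_text[int(cohort.counts[i, j])]}:{gq}")
            fh.write("\t".join(fields) + "\n")


def read_frequency_panel(path: str | Path, n_individuals: int) -> FrequencyPanel:
    """Read a sites-only VCF (AC/AN INFO) or 5-column TSV frequency panel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: dict[VariantKey, tuple[int, int]] = {}
    if _is_vcf(path):
        from cyvcf2 import VCF
        for rec in VCF(str(path)):
            acs = rec.INFO.get("AC")
            an = rec.INFO.get("AN")
            if acs is None or an is None:
                raise ValueError(f"panel VCF record without AC/AN at {rec.CHROM}:{rec.POS}")
            if not isinstance(acs, tuple):
                acs = (acs,)
            for alt, ac in zip(rec.ALT, acs):
                key = VariantKey.normalized(rec.CHROM, rec.POS, rec.REF, alt)
                entries[key] = (int(ac), int(an))
    else:
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["chrom", "pos", "ref", "alt", "maf"], dtype={"chrom": str})
        an = 2 * n_individuals
        for row in df.itertuples(index=False):
            key = VariantKey.normalized(str(row.chrom), int(row.pos), row.ref, row.alt)
            ac = int(round(float(row.maf) * an))
            entries[key] = (ac, an)
    return FrequencyPanel(entries, n_individuals)


def write_frequency_panel(panel: FrequencyPanel, path: str | Path,
                          fmt: str = "tsv") -> None:
    """Write the panel as a TSV (chrom, pos, ref, alt, maf) or sites VCF."""
    keys = sorted(panel.entries)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tmaf\n")
            for k in keys:
                ac, an = panel.entries[k]
                fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{ac/an:.10g}\n")
    elif fmt == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in sorted({k.chrom for k in keys}):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n')
            fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for k in keys:
                ac, an = panel.entries[k]
                fh.write(f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t"
                         f"AC={ac};AN={an}\n")
    else:
        raise ValueError(f"unknown panel format {fmt!r}")


def read_known_variants(path: str | Path) -> KnownVariantSet:
    """Read a known-variant set from a sites-only VCF or a 4-column TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    keys: set[VariantKey] = set()
    if _is_vcf(path):
        from cyvcf2 import VCF
        for rec in VCF(str(path)):
            for alt in rec.ALT or []:
                keys.add(VariantKey.normalized(rec.CHROM, rec.POS, rec.REF, alt))
    else:
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["chrom", "pos", "ref", "alt"], dtype={"chrom": str},
                         usecols=[0, 1, 2, 3])
        for row in df.itertuples(index=False):
            keys.add(VariantKey.normalized(str(row.chrom), int(row.pos), row.ref, row.alt))
    return KnownVariantSet(keys)


def write_known_variants(known: KnownVariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for k in known:
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0", 1: "1", 2: "2", NOCALL: "."}
_GT_DECODE = {"0": 0, "1": 1, "2": 2, ".": NOCALL}


def encode_genotype(count: int, low_quality: bool = False) -> str:
    code = _GT_CODE[int(count)]
    return code + "L" if low_quality else code


def decode_genotype(text: str) -> tuple[int, bool]:
    low = text.endswith("L")
    return _GT_DECODE[text.rstrip("L")], low


def variant_table(cohort: CohortGenotypes, calls=None,
                  panel: FrequencyPanel | None = None,
                  traces=None) -> pd.DataFrame:
    """Assemble the per-variant report table: one row per variant x
    consequence, with key columns, per-sample genotype codes, panel MAF
    and the filter-trace outcome."""
    call_map: dict[VariantKey, list] = {}
    for c in calls or []:
        call_map.setdefault(c.variant, []).append(c)
    trace_map = {t.variant: t for t in traces or []}
    rows = []
    for j, v in enumerate(cohort.variants):
        gts = {s: encode_genotype(cohort.counts[i, j], cohort.low_quality[i, j])
               for i, s in enumerate(cohort.samples)}
        vcalls = call_map.get(v) or [None]
        for c in vcalls:
            row = {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": c.gene_symbol if c else ".",
                "consequence": c.category if c else ".",
                "panel_maf": panel.frequency(v) if panel is not None else float("nan"),
                "removed_by": trace_map[v].removed_by if v in trace_map else ".",
            }
            row.update(gts)
            rows.append(row)
    cols = (["chrom", "pos", "ref", "alt", "gene", "consequence", "panel_maf",
             "removed_by"] + list(cohort.samples))
    return pd.DataFrame(rows, columns=cols)


def write_variant_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(table.columns) + "\n")
        table.to_csv(fh, sep="\t", header=False, index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=header,
                           dtype={"chrom": str, "gene": str, "consequence": str,
                                  "removed_by": str})
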