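"""End-to-end pipeline: annotate -> filter -> scans -> incidental screen.

Plain files between stages: every stage is a pure function of its input
files, so stages can be re-run independently (e.g. re-filter at a 5%
panel MAF cutoff without re-annotating).  All outputs are deterministic
TSVs; re-running an identical configuration reproduces them byte for
byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_io import (CASE, CONTROL, PLATFORM_CONTROL, CohortGenotypes,
                        read_cohort_vcf, read_frequency_panel, read_known_variants,
                        variant_table, write_variant_table)
from .consequence import (annotate_cohort, protein_altering_by_gene,
                          protein_altering_variants, read_gene_models_bed12)
from .filters import (BURDEN_TEST_STAGES, VARIANT_TEST_STAGES, FilterConfig,
                      run_cascade, write_filter_traces)
from .association import (MultipleTestingConfig, burden_scan, recessive_scan,
                          variant_enrichment_scan)
from .incidental import read_acmg_genes, read_catalogue, screen_incidental, \
    write_findings

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    cohort_vcf: str
    labels: str           # TSV sample -> label
    reference: str
    gene_models: str
    panel: str
    panel_individuals: int
    known: str | None = None
    acmg_genes: str | None = None
    catalogue: str | None = None
    output_dir: str = "extremevar_out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    variant_scan: bool = True
    burden_scan: bool = True
    recessive_scan: bool = True
    incidental_screen: bool = True
    quality_key: str | None = None
    quality_threshold: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path,
                  overrides: dict | None = None) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key, value in (overrides or {}).items():
            head, _, rest = key.partition(".")
            if rest:
                d.setdefault(head, {})[rest] = value
            else:
                d[key] = value
        if isinstance(d.get("filter"), dict):
            d["filter"] = FilterConfig(**d["filter"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    version: str
    config_hash: str
    counts: dict
    n_tests: dict
    thresholds: dict
    top_burden: list
    top_variants: list
    findings: list
    outputs: dict

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", names=["sample", "label"])
    return dict(zip(df["sample"].astype(str), df["label"].astype(str)))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("extremevar")
    root.addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> RunReport:
    import pysam

    counts: dict[str, int] = {}
    n_tests: dict[str, int] = {}
    thresholds: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("load")
        labels = read_labels(config.labels)
        cohort = read_cohort_vcf(config.cohort_vcf, labels,
                                 quality_key=config.quality_key,
                                 quality_threshold=config.quality_threshold)
        reference = pysam.FastaFile(str(config.reference))
        models = read_gene_models_bed12(config.gene_models)
        panel = read_frequency_panel(config.panel, config.panel_individuals)
        from .cohort_io import KnownVariantSet
        known = (read_known_variants(config.known) if config.known
                 else KnownVariantSet())
        counts["variants_input"] = cohort.n_variants
        counts["samples"] = cohort.n_samples
    except Exception as e:  # noqa: BLE001
        raise StageError("load", e)

    try:
        stage("annotate")
        calls = annotate_cohort(cohort, models, reference)
        pa_variants = sorted(protein_altering_variants(calls))
        gene_index = protein_altering_by_gene(calls)
        counts["protein_altering_variants"] = len(pa_variants)
        table = variant_table(cohort, calls, panel)
        outputs["variant_table"] = str(outdir / "variants.tsv")
        write_variant_table(table, outputs["variant_table"])
    except Exception as e:  # noqa: BLE001
        raise StageError("annotate", e)

    platform = cohort.subset_samples(cohort.samples_with_label(PLATFORM_CONTROL)) \
        if cohort.samples_with_label(PLATFORM_CONTROL) else None
    analysis = cohort  # case+control view is selected inside the stats

    report_top_variants: list = []
    report_top_burden: list = []
    findings_out: list = []

    if config.variant_scan:
        try:
            stage("filter_variant_path")
            stages = VARIANT_TEST_STAGES if platform is not None else ("known_variant",)
            retained_v, traces_v = run_cascade(
                pa_variants, analysis, panel, known, platform, config.filter,
                stages=stages)
            counts["variant_path_retained"] = len(retained_v)
            outputs["variant_filter_trace"] = str(outdir / "filter_trace_variant.tsv")
            write_filter_traces(traces_v, outputs["variant_filter_trace"])

            stage("variant_scan")
            results = variant_enrichment_scan(retained_v, analysis, panel,
                                              alpha=config.alpha,
                                              include_low_quality=config.filter.use_low_quality)
            n_tests["variant_scan"] = len(results)
            if results:
                thresholds["variant_scan"] = MultipleTestingConfig(
                    config.alpha, len(results)).threshold
            outputs["variant_scan"] = str(outdir / "variant_scan.tsv")
            with open(outputs["variant_scan"], "w") as fh:
                fh.write("#chrom\tpos\tref\talt\tcase_carriers\tn_cases\t"
                         "panel_carriers\tn_panel\tp_value\tsignificant\n")
                for r in results:
                    v = r.variant
                    fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                             f"{r.case_carriers}\t{r.n_cases}\t{r.panel_carriers}\t"
                             f"{r.n_panel}\t{r.p_value:.6e}\t{int(r.significant)}\n")
            report_top_variants = [
                {"variant": str(r.variant), "p_value": float(r.p_value),
                 "case_carriers": r.case_carriers, "significant": bool(r.significant)}
                for r in results[:10]]
        except Exception as e:  # noqa: BLE001
            raise StageError("variant_scan", e)

    retained_g: list = []
    if config.burden_scan or config.recessive_scan:
        try:
            stage("filter_burden_path")
            stages = BURDEN_TEST_STAGES if platform is not None else ("maf",)
            retained_g, traces_g = run_cascade(
                pa_variants, analysis, panel, known, platform, config.filter,
                stages=stages)
            counts["burden_path_retained"] = len(retained_g)
            outputs["burden_filter_trace"] = str(outdir / "filter_trace_burden.tsv")
            write_filter_traces(traces_g, outputs["burden_filter_trace"])
        except Exception as e:  # noqa: BLE001
            raise StageError("filter_burden_path", e)

    if config.burden_scan:
        try:
            stage("burden_scan")
            retained_set = set(retained_g)
            gene_sites = {g: sorted(vs & retained_set)
                          for g, vs in gene_index.items() if vs & retained_set}
            results = burden_scan(analysis, gene_sites, alpha=config.alpha,
                                  include_low_quality=config.filter.use_low_quality)
            n_tests["burden_scan"] = len(results)
            if results:
                thresholds["burden_scan"] = MultipleTestingConfig(
                    config.alpha, len(results)).threshold
            outputs["burden_scan"] = str(outdir / "burden_scan.tsv")
            with open(outputs["burden_scan"], "w") as fh:
                fh.write("#gene\tn_rare_sites\tcarriers_cases\tcarriers_controls\t"
                         "lrt\tp_value\tseparation\tsignificant\n")
                for r in results:
                    fh.write(f"{r.gene_symbol}\t{r.n_rare_sites}\t{r.carriers_cases}\t"
                             f"{r.carriers_controls}\t{r.lrt_statistic:.6g}\t"
                             f"{r.p_value:.6e}\t{int(r.separation)}\t"
                             f"{int(r.significant)}\n")
            report_top_burden = [
                {"gene": r.gene_symbol, "p_value": float(r.p_value),
                 "carriers_cases": r.carriers_cases,
                 "significant": bool(r.significant)}
                for r in results[:10]]
        except Exception as e:  # noqa: BLE001
            raise StageError("burden_scan", e)

    if config.recessive_scan:
        try:
            stage("recessive_scan")
            retained_set = set(retained_g)
            gene_sites = {g: sorted(vs & retained_set)
                          for g, vs in gene_index.items() if vs & retained_set}
            results = recessive_scan(analysis, gene_sites, alpha=config.alpha,
                                     include_low_quality=config.filter.use_low_quality)
            n_tests["recessive_scan"] = len(results)
            if results:
                thresholds["recessive_scan"] = MultipleTestingConfig(
                    config.alpha, len(results)).threshold
            outputs["recessive_scan"] = str(outdir / "recessive_scan.tsv")
            with open(outputs["recessive_scan"], "w") as fh:
                fh.write("#gene\tcases_two_plus\tcontrols_two_plus\tp_value\t"
                         "significant\n")
                for r in results:
                    fh.write(f"{r.gene_symbol}\t{r.cases_with_two_plus}\t"
                             f"{r.controls_with_two_plus}\t{r.p_value:.6e}\t"
                             f"{int(r.significant)}\n")
        except Exception as e:  # noqa: BLE001
            raise StageError("recessive_scan", e)

    if config.incidental_screen and config.acmg_genes:
        try:
            stage("incidental_screen")
            acmg = read_acmg_genes(config.acmg_genes)
            catalogue = read_catalogue(config.catalogue) if config.catalogue else []
            findings = screen_incidental(cohort, calls, acmg, catalogue)
            counts["incidental_findings"] = len(findings)
            outputs["findings"] = str(outdir / "incidental_findings.tsv")
            write_findings(findings, outputs["findings"])
            findings_out = [
                {"sample": f.sample, "variant": str(f.variant),
                 "gene": f.gene_symbol, "basis": f.basis} for f in findings]
        except Exception as e:  # noqa: BLE001
            raise StageError("incidental_screen", e)

    report = RunReport(version=__version__, config_hash=config.config_hash(),
                       counts=counts, n_tests=n_tests, thresholds=thresholds,
                       top_burden=report_top_burden,
                       top_variants=report_top_variants,
                       findings=findings_out, outputs=outputs)
    report.to_yaml(outdir / "report.yaml")
    return report
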