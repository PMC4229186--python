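"""Rare-variant filtering cascade with a per-variant audit trail.

Three stages, applied in order with per-path toggles:

1. ``platform_nocall`` — drop variants with a no-call fraction strictly
   above the threshold (default 0.5) in platform-matched control genomes,
   removing platform-specific artefact sites.
2. ``known_variant`` — drop variants present in a public known-variant
   set (allele-aware membership); used on the single-variant test path.
3. ``maf`` — keep only variants with reference-panel MAF strictly below
   the panel cutoff (default 1.5%) AND empirical MAF (alt alleles over
   called alleles in cases+controls) strictly below the empirical cutoff
   (default 10%); used on the gene-burden path.

Every input variant receives a :class:`FilterTrace` recording the first
stage that removed it (or ``none``), so retained + removed always
partitions the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort_io import (NOCALL, CASE, CONTROL, CohortGenotypes, FrequencyPanel,
                        KnownVariantSet, VariantKey)

logger = logging.getLogger(__name__)

STAGES = ("low_quality", "platform_nocall", "known_variant", "maf")
DEFAULT_STAGES = ("platform_nocall", "known_variant", "maf")
#: stage sets for the two analysis paths
VARIANT_TEST_STAGES = ("platform_nocall", "known_variant")
BURDEN_TEST_STAGES = ("platform_nocall", "maf")


@dataclass
class FilterConfig:
    nocall_rate_threshold: float = 0.5
    panel_maf_cutoff: float = 0.015
    empirical_maf_cutoff: float = 0.10
    use_low_quality: bool = False
    known_set_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("nocall_rate_threshold", "panel_maf_cutoff", "empirical_maf_cutoff"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class FilterTrace:
    variant: VariantKey
    removed_by: str  # one of STAGES, or "none"
    observed_value: float | None = None


def platform_nocall_filter(variants: Sequence[VariantKey],
                           platform_controls: CohortGenotypes,
                           config: FilterConfig) -> tuple[list[VariantKey], list[FilterTrace]]:
    """Remove variants whose no-call fraction in platform controls
    strictly exceeds ``nocall_rate_threshold``."""
    if platform_controls.n_samples == 0:
        raise ValueError("platform control set is empty")
    counts = platform_controls.effective_counts(config.use_low_quality)
    retained, traces = [], []
    for v in variants:
        if v in platform_controls:
            col = counts[:, platform_controls.variant_index(v)]
            frac = float(np.mean(col == NOCALL))
        else:
            frac = 0.0  # site unobserved on the platform panel: no evidence against
        if frac > config.nocall_rate_threshold:
            traces.append(FilterTrace(v, "platform_nocall", frac))
        else:
            retained.append(v)
            traces.append(FilterTrace(v, "none", frac))
    return retained, traces


def known_variant_filter(variants: Sequence[VariantKey],
                         known: KnownVariantSet) -> tuple[list[VariantKey], list[FilterTrace]]:
    retained, traces = [], []
    for v in variants:
        if v in known:
            traces.append(FilterTrace(v, "known_variant", None))
        else:
            retained.append(v)
            traces.append(FilterTrace(v, "none", None))
    return retained, traces


def empirical_maf(variant: VariantKey, cohort: CohortGenotypes,
                  include_low_quality: bool = False) -> float | None:
    """Alt alleles over called alleles across case + control samples;
    ``None`` when no allele is called."""
    idx = cohort.sample_indices(CASE, CONTROL)
    counts = cohort.effective_counts(include_low_quality)
    col = counts[idx, cohort.variant_index(variant)]
    called = col != NOCALL
    n_alleles = 2 * int(called.sum())
    if n_alleles == 0:
        return None
    return float(col[called].sum()) / n_alleles


def maf_filter(variants: Sequence[VariantKey], panel: FrequencyPanel,
               cohort: CohortGenotypes,
               config: FilterConfig) -> tuple[list[VariantKey], list[FilterTrace]]:
    """Retain variants rare both in the reference panel and empirically."""
    retained, traces = [], []
    for v in variants:
        pf = panel.frequency(v)
        if pf >= config.panel_maf_cutoff:
            traces.append(FilterTrace(v, "maf", pf))
            continue
        emp = empirical_maf(v, cohort, config.use_low_quality)
        if emp is None:
            logger.warning("no called alleles for %s; retained by panel rule alone", v)
            retained.append(v)
            traces.append(FilterTrace(v, "none", None))
        elif emp >= config.empirical_maf_cutoff:
            traces.append(FilterTrace(v, "maf", emp))
        else:
            retained.append(v)
            traces.append(FilterTrace(v, "none", emp))
    return retained, traces


def low_quality_filter(variants: Sequence[VariantKey], cohort: CohortGenotypes,
                       config: FilterConfig) -> tuple[list[VariantKey], list[FilterTrace]]:
    """When low-quality calls are excluded, drop variants whose only alt
    evidence in cases+controls is low-quality."""
    if config.use_low_quality:
        return list(variants), [FilterTrace(v, "none", None) for v in variants]
    idx = cohort.sample_indices(CASE, CONTROL)
    hi = cohort.effective_counts(include_low_quality=False)
    retained, traces = [], []
    for v in variants:
        col = hi[idx, cohort.variant_index(v)]
        alt = int(col[col != NOCALL].sum())
        if alt == 0:
            traces.append(FilterTrace(v, "low_quality", 0.0))
        else:
            retained.append(v)
            traces.append(FilterTrace(v, "none", None))
    return retained, traces


def run_cascade(variants: Sequence[VariantKey], cohort: CohortGenotypes,
                panel: FrequencyPanel | None, known: KnownVariantSet | None,
                platform_controls: CohortGenotypes | None,
                config: FilterConfig,
                stages: Sequence[str] = DEFAULT_STAGES,
                ) -> tuple[list[VariantKey], list[FilterTrace]]:
    """Apply the selected stages in order; the trace records the first
    removing stage per variant.  ``known_variant`` is additionally gated
    by ``config.known_set_enabled``."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; choose from {STAGES}")
    final_trace: dict[VariantKey, FilterTrace] = {}
    current = list(variants)
    counts_log = []
    for stage in stages:
        if stage == "known_variant" and not config.known_set_enabled:
            continue
        n_in = len(current)
        if stage == "platform_nocall":
            current, traces = platform_nocall_filter(current, platform_controls, config)
        elif stage == "known_variant":
            current, traces = known_variant_filter(current, known)
        elif stage == "maf":
            current, traces = maf_filter(current, panel, cohort, config)
        elif stage == "low_quality":
            current, traces = low_quality_filter(current, cohort, config)
        for t in traces:
            if t.removed_by != "none":
                final_trace[t.variant] = t
        counts_log.append((stage, n_in, len(current)))
        logger.info("stage %-16s %d -> %d variants", stage, n_in, len(current))
    retained_set = set(current)
    out_traces = [FilterTrace(v, "none", None) if v in retained_set else final_trace[v]
                  for v in variants]
    return current, out_traces


def write_filter_traces(traces: Sequence[FilterTrace], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tremoved_by\tobserved_value\n")
        for t in traces:
            v = t.variant
            obs = "" if t.observed_value is None else f"{t.observed_value:.6g}"
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{t.removed_by}\t{obs}\n")
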