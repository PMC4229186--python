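"""Packaged reference tables used by the follow-up analyses."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .association import allele_burden_test

_COLUMNS = ["chrom", "pos", "ref", "alt", "aa_pos", "aa_ref", "aa_alt",
            "supercentenarian_carriers", "centenarian_carriers",
            "nonagenarian_carriers", "panel_maf"]


def _data_path(name: str):
    return resources.as_file(resources.files("extremevar.data") / name)


def load_tshz3_followup() -> tuple[pd.DataFrame, dict[str, int]]:
    """The TSHZ3 follow-up variant table and its cohort-level metadata.

    Returns the per-variant table (``panel_maf`` is NaN for novel
    variants) and a metadata dict with ``n_longlived``,
    ``control_carrier_alleles`` and ``control_total_alleles``.
    """
    with _data_path("tshz3_followup.tsv") as path:
        meta: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("#meta "):
                key, _, value = line[len("#meta "):].partition("=")
                meta[key.strip()] = int(value)
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=_COLUMNS, dtype={"chrom": str})
    return df, meta


def tshz3_followup_summary(panel_maf_cutoff: float = 0.015) -> dict:
    """Allele-frequency enrichment test for the TSHZ3 follow-up cohort.

    Variants are kept when rare in the reference panel (novel, or MAF
    strictly below the cutoff); carrier alleles are summed over the
    centenarian and nonagenarian carriers of the long-lived cohort and
    compared with the reference cohort by a two-sided Fisher test.
    """
    df, meta = load_tshz3_followup()
    maf = df["panel_maf"].fillna(0.0)
    rare = df[maf < panel_maf_cutoff]
    carriers = int(rare["centenarian_carriers"].sum()
                   + rare["nonagenarian_carriers"].sum())
    total = 2 * meta["n_longlived"]
    p = allele_burden_test(carriers, total,
                           meta["control_carrier_alleles"],
                           meta["control_total_alleles"])
    return {
        "n_rare_variants": len(rare),
        "carrier_alleles": carriers,
        "total_alleles": total,
        "cohort_frequency": carriers / total,
        "control_frequency": (meta["control_carrier_alleles"]
                              / meta["control_total_alleles"]),
        "p_value": p,
    }
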