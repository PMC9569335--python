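"""Filtering of GWAS summary statistics and distance-based clumping.

Lead (independently significant) variants are identified conservatively
without LD information: filter to well-observed variants (minor allele
count >= 10, panel MAF > 0.01), restrict to genome-wide significance
(P < 5e-8) outside the MHC region, then greedily select the
smallest-p variant as a lead and discard all remaining significant variants
within +/-500 kb on the same chromosome, repeating until none remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epienrich.annotations import MHC_GRCH38, exclude_region
from epienrich.synthetic import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class LeadVariantSet:
    """Clumped lead variants for one disorder, with filter provenance."""

    disorder: str
    leads: pd.DataFrame  # columns SNP, CHR, BP, P
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.leads)


def filter_mac(stats: pd.DataFrame, min_mac: int = 10) -> pd.DataFrame:
    """Drop variants with minor allele count below ``min_mac``.

    Uses the MAC column when present, otherwise derives
    ``round(2 * N * min(FRQ, 1 - FRQ))``.  Variants with MAC exactly at the
    threshold are retained.
    """
    if "MAC" in stats.columns:
        mac = stats["MAC"].to_numpy(dtype=np.float64)
    elif {"FRQ", "N"}.issubset(stats.columns):
        frq = stats["FRQ"].to_numpy(dtype=np.float64)
        mac = np.round(2.0 * stats["N"].to_numpy() * np.minimum(frq, 1 - frq))
    else:
        raise ValueError(
            "cannot filter on minor allele count: need a MAC column "
            "or FRQ and N columns"
        )
    keep = mac >= min_mac
    logger.info("MAC filter removed %d of %d variants",
                int((~keep).sum()), len(stats))
    return stats.loc[keep].reset_index(drop=True)


def filter_maf_panel(
    stats: pd.DataFrame, panel: GenotypePanel, min_maf: float = 0.01
) -> pd.DataFrame:
    """Keep variants present in the reference panel with MAF > ``min_maf``."""
    maf = pd.Series(panel.maf, index=panel.variant_map["SNP"].to_numpy())
    panel_maf = stats["SNP"].map(maf)
    keep = (panel_maf > min_maf).fillna(False).to_numpy()
    logger.info("panel MAF filter removed %d of %d variants",
                int((~keep).sum()), len(stats))
    return stats.loc[keep].reset_index(drop=True)


def clump(
    stats: pd.DataFrame,
    p_threshold: float = 5e-8,
    distance_bp: int = 500_000,
    mhc: tuple[str, int, int] = MHC_GRCH38,
    disorder: str = "trait",
) -> LeadVariantSet:
    """Distance-based greedy clumping of genome-wide-significant variants.

    Restricts to ``P < p_threshold`` outside the MHC region, then repeatedly
    promotes the smallest-p remaining variant to lead status and discards
    every remaining significant variant within ``distance_bp`` on the same
    chromosome (a variant exactly at the distance is clumped; retained leads
    are separated by strictly more than ``distance_bp``).  Ties on p break
    by (chromosome, position), making the result independent of input row
    order.
    """
    n_input = len(stats)
    sig = stats.loc[stats["P"].to_numpy() < p_threshold].copy()
    n_sig = len(sig)
    if mhc is not None and n_sig:
        keep = exclude_region(sig["CHR"], sig["BP"], mhc)
        sig = sig.loc[keep]
    n_after_mhc = len(sig)

    sig = sig.sort_values(
        ["P", "CHR", "BP"], kind="mergesort"
    ).reset_index(drop=True)
    chrom = sig["CHR"].to_numpy(dtype=object)
    bp = sig["BP"].to_numpy(dtype=np.int64)
    alive = np.ones(len(sig), dtype=bool)
    lead_rows = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        lead_rows.append(i)
        clumped = alive & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= distance_bp)
        alive[clumped] = False

    leads = sig.iloc[lead_rows][["SNP", "CHR", "BP", "P"]]
    leads = leads.sort_values(["CHR", "BP"]).reset_index(drop=True)
    if leads.empty:
        logger.info("no genome-wide-significant variants for %s", disorder)
    prov = {
        "n_input": n_input,
        "n_significant": n_sig,
        "n_after_mhc": n_after_mhc,
        "n_leads": len(leads),
        "p_threshold": p_threshold,
        "distance_bp": distance_bp,
        "mhc": list(mhc) if mhc is not None else None,
    }
    return LeadVariantSet(disorder, leads, prov)


def check_min_loci(leads: LeadVariantSet, min_loci: int = 3) -> bool:
    """Eligibility for downstream specificity-rank analysis.

    Disorders with fewer independent genome-wide-significant loci than
    ``min_loci`` are flagged ineligible (too few loci for a meaningful
    overlap statistic).
    """
    ok = len(leads) >= min_loci
    if not ok:
        logger.info(
            "%s has %d lead loci (< %d): ineligible for enrichment analysis",
            leads.disorder, len(leads), min_loci,
        )
    return ok


def write_leads(leads: LeadVariantSet, tsv_path, bed_path=None) -> None:
    df = leads.leads.copy()
    df.insert(0, "DISORDER", leads.disorder)
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for _, r in leads.leads.iterrows():
                fh.write(f"{r.CHR}\t{r.BP - 1}\t{r.BP}\t{r.SNP}\n")
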