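"""Peak-to-gene assignment and gene-set over-representation analysis.

Cell-selective peaks overlapped by risk variants are mapped to genes (gene
bodies or promoters overlapping the peak, else the nearest TSS within a
distance cap), and the resulting gene list is tested for over-representation
in curated gene sets with a one-sided (upper-tail) hypergeometric test and
Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epienrich.cheers import PeakSpecificityMatrix
from epienrich.comparisons import selective_peaks

logger = logging.getLogger(__name__)

#: Promoter half-window around the TSS, in bp.
DEFAULT_PROMOTER_BP = 3000


def select_test_peaks(
    psm: PeakSpecificityMatrix,
    overlaps: pd.DataFrame,
    states: Sequence[str],
    specificity_threshold: float = 0.9,
) -> np.ndarray:
    """Peaks both highly state-specific and overlapped by risk variants.

    Selects peak indices with normalized specificity rank strictly greater
    than the threshold in at least one designated state AND present in the
    variant-overlap table.  An empty result is valid (downstream ORA is
    simply skipped).
    """
    sel = set(selective_peaks(psm, states, specificity_threshold))
    hit = set(overlaps["peak_index"]) if len(overlaps) else set()
    return np.array(sorted(sel & hit), dtype=np.int64)


def peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    max_tss_distance: int = 10_000,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> list[str]:
    """Assign genes to peaks; deduplicated union across peaks.

    Per peak: genes whose body overlaps the peak, union genes whose promoter
    (TSS +/- ``promoter_bp``) overlaps the peak; if that union is empty, the
    single gene with the nearest TSS, provided it is within
    ``max_tss_distance`` bp (ties break by gene id), else no gene.
    """
    out: set[str] = set()
    tss0 = genes["tss"].to_numpy(dtype=np.int64) - 1  # 0-based TSS base
    gstart = genes["start"].to_numpy(dtype=np.int64)
    gend = genes["end"].to_numpy(dtype=np.int64)
    gchrom = genes["CHR"].to_numpy(dtype=object)
    gid = genes["gene_id"].to_numpy(dtype=object)
    pstart = peaks["start"].to_numpy(dtype=np.int64)
    pend = peaks["end"].to_numpy(dtype=np.int64)
    pchrom = peaks["CHR"].to_numpy(dtype=object)

    for i in range(len(peaks)):
        on_chrom = gchrom == pchrom[i]
        body = on_chrom & (gstart < pend[i]) & (gend > pstart[i])
        prom = on_chrom & (tss0 - promoter_bp < pend[i]) & (
            tss0 + promoter_bp + 1 > pstart[i]
        )
        hits = body | prom
        if hits.any():
            out.update(gid[hits])
            continue
        cand = np.flatnonzero(on_chrom)
        if len(cand) == 0:
            continue
        # gap distance from peak to TSS (0 when TSS inside the peak)
        d = np.maximum(0, np.maximum(pstart[i] - tss0[cand],
                                     tss0[cand] - (pend[i] - 1)))
        best = d.min()
        if best <= max_tss_distance:
            nearest = cand[d == best]
            out.add(sorted(gid[nearest])[0])
    return sorted(out)


def ora(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation across gene sets.

    For each set (intersected with the universe), with M universe genes,
    K set genes, n test genes, and k overlap, the p-value is the upper tail
    P(X >= k) of Hypergeometric(M, K, n); BH adjustment is applied across
    sets and results are sorted by p.  ``gene_ratio`` is k / n.
    """
    universe = set(universe)
    test = set(gene_list)
    stray = test - universe
    if stray:
        logger.warning("dropping %d test gene(s) outside the universe",
                       len(stray))
        test &= universe
    M, n = len(universe), len(test)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            logger.info("gene set %r has no genes in the universe; skipped",
                        name)
            continue
        K = len(members)
        overlap = sorted(test & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({
            "gene_set": name, "k": k, "K": K, "n": n, "M": M, "p": p,
            "gene_ratio": k / n if n else 0.0,
            "genes": ",".join(overlap),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "gene_set"]).reset_index(drop=True)
    return out


def bh_adjust(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# GMT and gene-model I/O

def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_model(path) -> pd.DataFrame:
    """Gene model TSV with columns gene_id, CHR, start, end, strand[, tss]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})
    if "tss" not in df.columns:
        df["tss"] = np.where(df["strand"] == "+", df["start"] + 1, df["end"])
    return df
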