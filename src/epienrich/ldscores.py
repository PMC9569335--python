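"""LD computation: pairwise r-squared, partitioned LD scores, LD expansion.

The partitioned LD score of variant j with respect to annotation C is
``l(j, C) = sum_{k in C, |pos_k - pos_j| <= window} r2(j, k)`` where r2 is
the squared Pearson correlation of allele counts in a reference panel.  A
variant that is itself a member contributes its self term (r2 = 1), so
``l(j, C) >= 1`` whenever j is in C.  Disjoint annotations are exactly
additive: ``l(j, C1 | C2) = l(j, C1) + l(j, C2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from epienrich.annotations import AnnotationSet, annotate_variants
from epienrich.synthetic import GenotypePanel


def _standardize(genotypes: np.ndarray) -> np.ndarray:
    g = genotypes.astype(np.float64)
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant: correlation undefined")
    return (g - mu) / sd


def pairwise_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation between two variants' allele counts."""
    x = panel.genotypes[:, i].astype(np.float64)
    y = panel.genotypes[:, j].astype(np.float64)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("monomorphic variant: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _as_membership(
    panel: GenotypePanel,
    annotations: Mapping[str, AnnotationSet | np.ndarray] | Sequence[AnnotationSet],
) -> dict[str, np.ndarray]:
    if not isinstance(annotations, Mapping):
        annotations = {a.name: a for a in annotations}
    out = {}
    for name, ann in annotations.items():
        if isinstance(ann, AnnotationSet):
            vec = annotate_variants(
                panel.variant_map["CHR"], panel.variant_map["BP"], ann
            )
        else:
            vec = np.asarray(ann, dtype=bool)
        out[name] = vec
    return out


def partitioned_ld_scores(
    panel: GenotypePanel,
    annotations: Mapping[str, AnnotationSet | np.ndarray] | Sequence[AnnotationSet],
    window_bp: int = 1_000_000,
    adjusted: bool = False,
    chunk_size: int = 512,
) -> pd.DataFrame:
    """Per-variant LD scores for each annotation within a base-pair window.

    Returns a DataFrame indexed by variant id with one column per annotation.
    ``adjusted=True`` applies the finite-sample bias correction
    ``r2_adj = r2 - (1 - r2)/(n - 2)`` to each pairwise term (the plain
    estimator is the default).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    member = _as_membership(panel, annotations)
    for name, vec in member.items():
        if not vec.any():
            warnings.warn(f"annotation {name!r} has no member variants",
                          stacklevel=2)
    names = list(member)
    n, m = panel.genotypes.shape
    scores = {name: np.zeros(m) for name in names}

    chroms = panel.variant_map["CHR"].to_numpy()
    pos = panel.variant_map["BP"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
        z = _standardize(panel.genotypes[:, idx])
        lo = np.searchsorted(p, p - window_bp, side="left")
        hi = np.searchsorted(p, p + window_bp, side="right")
        mloc = len(idx)
        memb_loc = {name: member[name][idx] for name in names}
        for a in range(0, mloc, chunk_size):
            b = min(a + chunk_size, mloc)
            span_lo, span_hi = int(lo[a]), int(hi[b - 1])
            r = z[:, a:b].T @ z[:, span_lo:span_hi] / n
            r2 = r * r
            if adjusted:
                r2 = r2 - (1.0 - r2) / (n - 2)
            cols = np.arange(span_lo, span_hi)
            in_win = (cols[None, :] >= lo[a:b, None]) & (
                cols[None, :] < hi[a:b, None]
            )
            r2 = np.where(in_win, r2, 0.0)
            for name in names:
                vec = memb_loc[name][span_lo:span_hi].astype(np.float64)
                scores[name][idx[a:b]] += r2 @ vec

    out = pd.DataFrame(scores, index=panel.variant_map["SNP"].to_numpy())
    out.index.name = "SNP"
    return out


@dataclass
class LdNeighborhood:
    """A lead variant plus all panel variants in strong LD with it."""

    lead: str
    members: list[str]
    r2_threshold: float
    expanded: bool = True  # False when the lead was absent from the panel


def expand_leads(
    panel: GenotypePanel,
    leads: Iterable[str],
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
) -> list[LdNeighborhood]:
    """LD-expand lead variants: members with r2 strictly above the threshold.

    The lead itself is always included (self r2 = 1).  Leads absent from the
    panel are returned unexpanded (lead-only neighborhood) with a warning.
    """
    snp_idx = {s: i for i, s in enumerate(panel.variant_map["SNP"])}
    pos = panel.variant_map["BP"].to_numpy()
    chroms = panel.variant_map["CHR"].to_numpy()
    snps = panel.variant_map["SNP"].to_numpy()
    z = _standardize(panel.genotypes)
    n = panel.n_individuals

    out = []
    for lead in leads:
        i = snp_idx.get(lead)
        if i is None:
            warnings.warn(f"lead {lead!r} absent from panel; not expanded",
                          stacklevel=2)
            out.append(LdNeighborhood(lead, [lead], r2_threshold, False))
            continue
        near = np.flatnonzero(
            (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window_bp)
        )
        r = z[:, near].T @ z[:, i] / n
        keep = near[(r * r) > r2_threshold]
        members = set(snps[keep]) | {lead}
        out.append(LdNeighborhood(lead, sorted(members), r2_threshold, True))
    return out


def neighborhood_variants(
    neighborhoods: Iterable[LdNeighborhood], panel: GenotypePanel
) -> pd.DataFrame:
    """Flatten neighborhoods into a variant table (SNP, CHR, BP, LEAD)."""
    vm = panel.variant_map.set_index("SNP")
    rows = []
    for nb in neighborhoods:
        for snp in nb.members:
            if snp in vm.index:
                rows.append(
                    {
                        "SNP": snp,
                        "CHR": vm.loc[snp, "CHR"],
                        "BP": int(vm.loc[snp, "BP"]),
                        "LEAD": nb.lead,
                    }
                )
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "LEAD"])


def write_ld_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", float_format="%.6g")


def read_ld_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="SNP")
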