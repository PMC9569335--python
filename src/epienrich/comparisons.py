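"""Cross-disorder and cross-condition comparison statistics.

Covers: Venn/upset-style sharing of variant-overlapped peaks between
disorders; discordant cell-selective peaks (overlapped by one disorder but
not another) with regulatory-element classes and paired association
statistics; Spearman rank correlation with exact small-n p-values and
seeded percentile-bootstrap confidence intervals (used for the relationship
between GWAS heritability Z-scores and enrichment Z-scores across
disorders).
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epienrich.annotations import AnnotationSet
from epienrich.cheers import PeakSpecificityMatrix


def sharing_counts(overlaps: Mapping[str, Iterable]) -> pd.DataFrame:
    """Disjoint intersection-cell counts of overlapped peaks per disorder.

    Each peak is counted once (even if overlapped by several variants) in
    exactly one cell of the disorder power set, so cell counts sum to the
    number of distinct overlapped peaks.  Returns a table with one row per
    non-empty cell: the '+'-joined member disorders and the peak count.
    """
    sets = {d: set(v) for d, v in overlaps.items()}
    disorders = sorted(sets)
    cells: dict[tuple[str, ...], set] = {}
    all_peaks = set().union(*sets.values()) if sets else set()
    for peak in all_peaks:
        key = tuple(d for d in disorders if peak in sets[d])
        cells.setdefault(key, set()).add(peak)
    rows = [
        {"disorders": "+".join(key), "n_members": len(key),
         "n_peaks": len(v), "peaks": ",".join(sorted(map(str, v)))}
        for key, v in sorted(cells.items())
    ]
    return pd.DataFrame(rows,
                        columns=["disorders", "n_members", "n_peaks", "peaks"])


@dataclass
class DiscordanceReport:
    """Cell-selective peaks overlapped by disorder A but not B (and B not A)."""

    disorder_a: str
    disorder_b: str
    a_not_b: pd.DataFrame
    b_not_a: pd.DataFrame
    specificity_threshold: float
    states: tuple[str, ...] = ()


def selective_peaks(
    psm: PeakSpecificityMatrix,
    states: Sequence[str],
    threshold: float = 0.9,
) -> np.ndarray:
    """Indices of peaks with normalized specificity rank strictly above the
    threshold in at least one of the designated states."""
    cols = [psm.state_index(s) for s in states]
    mask = (psm.norm_ranks[:, cols] > threshold).any(axis=1)
    return np.flatnonzero(mask)


def discordant_peaks(
    psm: PeakSpecificityMatrix,
    overlaps_a: pd.DataFrame,
    overlaps_b: pd.DataFrame,
    states: Sequence[str],
    specificity_threshold: float = 0.9,
    disorder_a: str = "A",
    disorder_b: str = "B",
    peak_classes: pd.Series | None = None,
    stats_a: pd.DataFrame | None = None,
    stats_b: pd.DataFrame | None = None,
) -> DiscordanceReport:
    """Cell-selective peaks implicated by one disorder but not the other.

    ``overlaps_a/b`` are variant-peak overlap tables (from
    :func:`epienrich.cheers.overlap_variants`).  Peaks must be selective
    (rank > threshold in >= 1 designated state) to enter either discordant
    set; the two sets are disjoint by construction.  Optional per-peak
    element classes and per-disorder summary statistics are attached to the
    supporting variants so the discordance can be inspected at the level of
    association sign and strength.
    """
    sel = set(selective_peaks(psm, states, specificity_threshold))
    set_a = set(overlaps_a["peak_index"]) & sel
    set_b = set(overlaps_b["peak_index"]) & sel

    def _report(only: set, overlaps: pd.DataFrame) -> pd.DataFrame:
        if not only:
            return pd.DataFrame(columns=["peak_index", "peak_id", "SNP"])
        out = overlaps[overlaps["peak_index"].isin(only)].copy()
        if peak_classes is not None:
            out["element_class"] = out["peak_index"].map(peak_classes)
        for label, tbl in (("a", stats_a), ("b", stats_b)):
            if tbl is not None:
                sub = tbl.set_index("SNP")
                for col in ("BETA", "P"):
                    if col in sub.columns:
                        out[f"{col}_{label}"] = out["SNP"].map(sub[col])
        return out.reset_index(drop=True)

    return DiscordanceReport(
        disorder_a=disorder_a, disorder_b=disorder_b,
        a_not_b=_report(set_a - set_b, overlaps_a),
        b_not_a=_report(set_b - set_a, overlaps_b),
        specificity_threshold=specificity_threshold,
        states=tuple(states),
    )


def classify_peak_elements(
    peaks: pd.DataFrame,
    class_annotation_sets: Mapping[str, AnnotationSet],
) -> list[frozenset[str]]:
    """Regulatory-element class labels for each peak (multi-label).

    A class is attached when any of its intervals shares at least one base
    pair with the peak.  Returns one frozenset of labels per peak row; a
    single-label priority collapse (promoter > genic_enhancer > enhancer)
    is available via :func:`collapse_classes`.
    """
    labels: list[set[str]] = [set() for _ in range(len(peaks))]
    for cls, ann in class_annotation_sets.items():
        for chrom, arr in ann.intervals.items():
            if arr.size == 0:
                continue
            sel = peaks["CHR"] == chrom
            if not sel.any():
                continue
            starts = peaks.loc[sel, "start"].to_numpy(dtype=np.int64)
            ends = peaks.loc[sel, "end"].to_numpy(dtype=np.int64)
            rows = np.flatnonzero(sel.to_numpy())
            # overlap iff some interval has start < peak_end and end > peak_start
            j = np.searchsorted(arr[:, 0], ends, side="left") - 1
            ok = j >= 0
            ok[ok] &= arr[j[ok], 1] > starts[ok]
            for r in rows[ok]:
                labels[r].add(cls)
    return [frozenset(s) for s in labels]


_CLASS_PRIORITY = ("promoter", "genic_enhancer", "enhancer")


def collapse_classes(labels: Iterable[frozenset[str]],
                     priority: Sequence[str] = _CLASS_PRIORITY) -> list[str]:
    """Collapse multi-label element classes to one label by priority."""
    out = []
    for lab in labels:
        for cls in priority:
            if cls in lab:
                out.append(cls)
                break
        else:
            out.append("none" if not lab else sorted(lab)[0])
    return out


@dataclass
class CorrelationResult:
    """Spearman correlation with exact p and bootstrap CI."""

    n: int
    s_statistic: float
    rho: float
    p: float
    p_method: str
    ci_low: float
    ci_high: float
    n_boot: int
    ties: bool = False


def spearman_rho_from_s(s: float, n: int) -> float:
    """Closed-form rho = 1 - 6 S / (n (n^2 - 1)) for tie-free ranks."""
    return 1.0 - 6.0 * s / (n * (n * n - 1.0))


@functools.lru_cache(maxsize=8)
def _null_s_distribution(n: int) -> np.ndarray:
    """Null distribution of S = sum d_i^2 over all n! rank permutations."""
    base = np.arange(1, n + 1, dtype=np.int64)
    perms = np.array(list(itertools.permutations(range(1, n + 1))),
                     dtype=np.int64)
    return ((perms - base) ** 2).sum(axis=1)


def _exact_spearman_p(s_obs: float, rho: float, n: int) -> float:
    """Two-sided exact p from full enumeration of the n! rank permutations.

    Convention: twice the smaller tail of the null distribution of S,
    capped at 1 (p = 1 when rho = 0).
    """
    s_null = _null_s_distribution(n)
    total = math.factorial(n)
    if rho > 0:
        p = 2.0 * (s_null <= s_obs).sum() / total
    elif rho < 0:
        p = 2.0 * (s_null >= s_obs).sum() / total
    else:
        p = 1.0
    return min(1.0, float(p))


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else np.nan


def spearman_exact(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    exact_max_n: int = 10,
) -> CorrelationResult:
    """Spearman correlation with exact small-n p and percentile-bootstrap CI.

    Without ties, ``S = sum d_i^2`` over rank differences and
    ``rho = 1 - 6 S / (n (n^2 - 1))``; the two-sided p-value enumerates all
    n! rank permutations for n <= ``exact_max_n`` and falls back to the
    t-approximation otherwise.  With ties, the general rank-correlation
    (Pearson on mid-ranks) is used with a warning and exact enumeration is
    disabled.  The 95% CI is a seeded percentile bootstrap over pairs.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ties = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
    if ties:
        warnings.warn("ties present: using general rank correlation; "
                      "exact enumeration disabled", stacklevel=2)
        rho = _rank_corr(x, y)
        s = float(((rx - ry) ** 2).sum())
        t = rho * np.sqrt((n - 2) / max(1e-12, 1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        method = "t-approx (ties)"
    else:
        s = float(((rx - ry) ** 2).sum())
        rho = spearman_rho_from_s(s, n)
        if n <= exact_max_n:
            p = _exact_spearman_p(s, rho, n)
            method = "exact permutation"
        else:
            t = rho * np.sqrt((n - 2) / max(1e-12, 1.0 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
            method = "t-approx"

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    rxb = stats.rankdata(x[idx], axis=1)
    ryb = stats.rankdata(y[idx], axis=1)
    rxb = rxb - rxb.mean(axis=1, keepdims=True)
    ryb = ryb - ryb.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxb * rxb).sum(axis=1) * (ryb * ryb).sum(axis=1))
    with np.errstate(invalid="ignore"):
        boots = (rxb * ryb).sum(axis=1) / denom
    boots = boots[~np.isnan(boots)]
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(
        n=n, s_statistic=s, rho=float(rho), p=p, p_method=method,
        ci_low=float(ci_low), ci_high=float(ci_high),
        n_boot=n_boot, ties=ties,
    )
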