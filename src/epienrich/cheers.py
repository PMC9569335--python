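"""Specificity-rank enrichment of risk variants in cell-state peaks.

Given a peak-by-cell-state signal matrix (e.g. H3K27ac read counts), each
peak's specificity score in a state is its signal divided by the Euclidean
norm of that peak's row, after quantile normalization of states and removal
of the weakest peaks.  Within each state, peaks are ranked by specificity
(1 = least specific, N = most specific) and the rank is normalized to
(0, 1].  The enrichment statistic for a state is the mean normalized rank
x-bar of the peaks overlapped by LD-expanded risk variants (each peak
counted once even if several variants fall in it); under the null that
overlapped peaks are an i.i.d. draw from the discrete uniform distribution
of ranks, x-bar has mean (N+1)/(2N) and standard error
sqrt((N^2 - 1) / (12 N^2 n)), giving a one-sided normal p-value.  An exact
enumerated null and a Monte-Carlo null are available for validation at
small n * N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epienrich.synthetic import PeakMatrix


@dataclass
class PeakSpecificityMatrix:
    """Peaks with per-state specificity scores and normalized ranks.

    ``peaks`` (rows aligned with all matrices) has columns peak_id, CHR,
    start, end.  ``ranks`` per state is a permutation of 1..N;
    ``norm_ranks`` = ranks / N.
    """

    peaks: pd.DataFrame
    states: list[str]
    normalized: np.ndarray
    scores: np.ndarray
    ranks: np.ndarray
    norm_ranks: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown cell state {state!r}") from None


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Map each column onto the mean of the column-sorted values."""
    order = np.argsort(x, axis=0, kind="stable")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=np.float64)
    for j in range(x.shape[1]):
        out[order[:, j], j] = target
    return out


def specificity_scores(
    raw: np.ndarray | PeakMatrix,
    peaks: pd.DataFrame | None = None,
    states: Sequence[str] | None = None,
    quantile_normalize: bool = True,
    drop_bottom_fraction: float = 0.1,
) -> PeakSpecificityMatrix:
    """Normalize a signal matrix and compute specificity scores and ranks.

    Processing chain (each step switchable): quantile-normalize cell-state
    columns; drop the bottom ``drop_bottom_fraction`` of peaks by mean
    signal; scale each peak row by its Euclidean norm (so per-peak squared
    scores sum to 1); rank peaks within each state by score, breaking ties
    by peak order, and normalize ranks by the number of retained peaks.
    All-zero rows are dropped with a warning.
    """
    if isinstance(raw, PeakMatrix):
        peaks = raw.peaks if peaks is None else peaks
        states = raw.states if states is None else states
        raw = raw.signal
    raw = np.asarray(raw, dtype=np.float64)
    n, s = raw.shape
    if s < 2 or n < 2:
        raise ValueError("need at least 2 peaks and 2 cell states")
    if states is None:
        states = [f"state_{i + 1}" for i in range(s)]
    if peaks is None:
        peaks = pd.DataFrame({
            "peak_id": [f"peak_{i + 1}" for i in range(n)],
            "CHR": "1",
            "start": np.arange(n) * 2,
            "end": np.arange(n) * 2 + 1,
        })
    peaks = peaks.reset_index(drop=True)

    keep = ~np.all(raw == 0, axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-zero peak row(s)",
                      stacklevel=2)
        raw = raw[keep]
        peaks = peaks.loc[keep].reset_index(drop=True)

    norm = _quantile_normalize(raw) if quantile_normalize else raw.copy()

    if drop_bottom_fraction > 0:
        n_now = norm.shape[0]
        n_drop = int(np.floor(drop_bottom_fraction * n_now))
        if n_drop:
            order = np.argsort(norm.mean(axis=1), kind="stable")
            keep_idx = np.sort(order[n_drop:])
            norm = norm[keep_idx]
            peaks = peaks.iloc[keep_idx].reset_index(drop=True)

    row_norm = np.linalg.norm(norm, axis=1)
    row_norm[row_norm == 0] = 1.0
    scores = norm / row_norm[:, None]

    n_final = scores.shape[0]
    ranks = np.empty_like(scores, dtype=np.int64)
    for j in range(scores.shape[1]):
        order = np.argsort(scores[:, j], kind="stable")
        ranks[order, j] = np.arange(1, n_final + 1)
    norm_ranks = ranks / n_final
    return PeakSpecificityMatrix(
        peaks=peaks, states=list(states), normalized=norm,
        scores=scores, ranks=ranks, norm_ranks=norm_ranks,
    )


def overlap_variants(
    psm: PeakSpecificityMatrix, variants: pd.DataFrame
) -> pd.DataFrame:
    """Variant-peak overlaps; peaks are deduplicated downstream.

    ``variants`` needs SNP, CHR, BP (1-based positions).  A variant overlaps
    a peak when its 0-based position lies in the half-open peak interval.
    Returns a table (peak_index, peak_id, SNP); a peak overlapped by several
    variants appears once per supporting variant but counts once in the
    enrichment statistic.
    """
    rows = []
    pk = psm.peaks
    for chrom in pd.unique(variants["CHR"]):
        sel = pk["CHR"] == chrom
        if not sel.any():
            continue
        starts = pk.loc[sel, "start"].to_numpy()
        ends = pk.loc[sel, "end"].to_numpy()
        pidx = np.flatnonzero(sel.to_numpy())
        order = np.argsort(starts)
        starts_s, ends_s, pidx_s = starts[order], ends[order], pidx[order]
        vsel = variants["CHR"] == chrom
        pos0 = variants.loc[vsel, "BP"].to_numpy(dtype=np.int64) - 1
        snps = variants.loc[vsel, "SNP"].to_numpy()
        j = np.searchsorted(starts_s, pos0, side="right") - 1
        ok = (j >= 0)
        ok[ok] &= pos0[ok] < ends_s[j[ok]]
        for v in np.flatnonzero(ok):
            pi = int(pidx_s[j[v]])
            rows.append({
                "peak_index": pi,
                "peak_id": pk["peak_id"].iloc[pi],
                "SNP": snps[v],
            })
    return pd.DataFrame(rows, columns=["peak_index", "peak_id", "SNP"])


@dataclass
class CheersResult:
    """Enrichment of one cell state: mean specificity rank vs uniform null."""

    state: str
    n_peaks_overlapped: int
    n_peaks_total: int
    mean_rank: float
    null_mean: float
    null_se: float
    z: float
    p: float
    p_exact: float | None = None
    p_bonferroni: float | None = None
    overlaps: pd.DataFrame | None = field(default=None, repr=False)


def _exact_mean_rank_tail(n: int, N: int, total_rank: int) -> float:
    """P(sum of n i.i.d. uniform{1..N} ranks >= total_rank), by convolution."""
    pmf = np.full(N, 1.0 / N)
    dist = pmf.copy()
    for _ in range(n - 1):
        dist = np.convolve(dist, pmf)
    support = np.arange(n, n * N + 1)
    return float(dist[support >= total_rank].sum())


def enrichment_test(
    psm: PeakSpecificityMatrix,
    overlapped_peaks: Iterable[int],
    state: str,
    exact: bool = False,
    mc_replicates: int = 0,
    rng: np.random.Generator | None = None,
) -> CheersResult:
    """Test one state's mean specificity rank against the uniform null.

    ``overlapped_peaks`` are row indices into the matrix (deduplicated
    internally).  ``exact=True`` additionally enumerates the null of the
    rank sum (feasible for small n * N); ``mc_replicates`` adds a
    Monte-Carlo p instead when set.
    """
    idx = np.unique(np.fromiter(overlapped_peaks, dtype=np.int64))
    n = len(idx)
    N = psm.n_peaks
    if n == 0:
        raise ValueError("no overlapped peaks: result untestable")
    j = psm.state_index(state)
    xbar = float(psm.norm_ranks[idx, j].mean())
    mu = (N + 1) / (2 * N)
    se = np.sqrt((N * N - 1) / (12.0 * N * N * n))
    z = (xbar - mu) / se if se > 0 else 0.0
    p = float(stats.norm.sf(z))
    p_exact = None
    if exact:
        total = int(psm.ranks[idx, j].sum())
        p_exact = _exact_mean_rank_tail(n, N, total)
    elif mc_replicates:
        if rng is None:
            rng = np.random.default_rng(0)
        draws = rng.integers(1, N + 1, size=(mc_replicates, n)).mean(axis=1) / N
        p_exact = float((draws >= xbar).mean())
    return CheersResult(
        state=state, n_peaks_overlapped=n, n_peaks_total=N,
        mean_rank=xbar, null_mean=mu, null_se=float(se),
        z=float(z), p=p, p_exact=p_exact,
    )


def cheers_test(
    psm: PeakSpecificityMatrix,
    variants: pd.DataFrame,
    exact: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the enrichment test for every cell state.

    Returns (per-state results with Bonferroni-adjusted p, variant-peak
    overlap table with per-state normalized ranks).  The Bonferroni family
    is the number of states tested.
    """
    overlaps = overlap_variants(psm, variants)
    if overlaps.empty:
        res = pd.DataFrame(columns=["state", "n_peaks", "mean_rank", "z",
                                    "p", "p_bonferroni"])
        return res, overlaps
    idx = overlaps["peak_index"].to_numpy()
    rows = []
    for st in psm.states:
        r = enrichment_test(psm, idx, st, exact=exact)
        rows.append({
            "state": st, "n_peaks": r.n_peaks_overlapped,
            "mean_rank": r.mean_rank, "z": r.z, "p": r.p,
            "p_exact": r.p_exact,
        })
    res = pd.DataFrame(rows)
    res["p_bonferroni"] = bonferroni(res["p"].to_numpy(), len(psm.states))
    if not exact:
        res = res.drop(columns=["p_exact"])
    # attach per-state normalized ranks of each overlapped peak
    uniq = np.unique(idx)
    rank_tbl = pd.DataFrame(psm.norm_ranks[uniq], columns=psm.states)
    rank_tbl.insert(0, "peak_id", psm.peaks["peak_id"].iloc[uniq].to_numpy())
    overlaps = overlaps.merge(rank_tbl, on="peak_id", how="left")
    return res, overlaps


def stimulation_contrast(
    result_stim: CheersResult, result_unstim: CheersResult
) -> tuple[float, float]:
    """One-sided Z-test comparing stimulated vs unstimulated enrichment.

    ``Z = (x1 - x2) / sqrt(2 SE^2)`` with the common standard error of the
    mean rank (peaks are called across the dataset as a whole, so SE depends
    only on N and n, which must match between the two results).
    """
    if (result_stim.n_peaks_total != result_unstim.n_peaks_total
            or result_stim.n_peaks_overlapped != result_unstim.n_peaks_overlapped):
        raise ValueError(
            "results are not comparable: peak universe or overlap count differ"
        )
    se = result_stim.null_se
    z = (result_stim.mean_rank - result_unstim.mean_rank) / (se * np.sqrt(2.0))
    return float(z), float(stats.norm.sf(z))


def bonferroni(pvalues: np.ndarray | Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) with family size m."""
    p = np.asarray(pvalues, dtype=np.float64)
    if m < len(p):
        raise ValueError(f"family size {m} smaller than number of tests {len(p)}")
    return np.minimum(1.0, p * m)
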