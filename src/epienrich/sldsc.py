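"""Stratified LD-score regression.

Under a polygenic model where annotation C contributes tau_C to per-SNP
heritability, the expected GWAS chi-square of variant j is

    E[chi2_j] = 1 + N * sum_C tau_C * l(j, C)

with N the GWAS sample size and l(j, C) the partitioned LD score.  The
engine regresses observed chi-square statistics on {N * l(j, C)} with a free
intercept, estimating tau per annotation with delete-one-block jackknife
standard errors over contiguous genome-ordered variant blocks.  Enrichment
p-values are one-sided tests of tau_C > 0.  Conditional models add
potentially confounding annotations as extra regression terms; a
two-sample Z-test compares an annotation's coefficient between two fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegressionResult:
    """Per-annotation tau estimates from one stratified regression."""

    annotations: list[str]
    tau: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    intercept: float
    intercept_se: float
    n_variants: int
    n_blocks: int
    #: delete-one-block coefficient estimates, shape (n_blocks, n_terms);
    #: last column is the intercept.  Kept for downstream jackknives.
    jackknife_estimates: np.ndarray = field(repr=False, default=None)
    target: str | None = None
    p_adjusted: np.ndarray | None = None

    def coefficient(self, annotation: str) -> tuple[float, float]:
        """(tau, se) for one annotation."""
        try:
            i = self.annotations.index(annotation)
        except ValueError:
            raise KeyError(
                f"annotation {annotation!r} not in model {self.annotations}"
            ) from None
        return float(self.tau[i]), float(self.se[i])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "annotation": self.annotations,
                "tau": self.tau,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )
        if self.p_adjusted is not None:
            out["p_adjusted"] = self.p_adjusted
        return out


@dataclass
class HeritabilitySummary:
    """Total SNP heritability, its jackknife SE, and the Z-score."""

    h2: float
    se: float
    z: float


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # QR diagnoses which columns are (nearly) linearly dependent
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * diag.max()
    if bad.any():
        offending = [names[i] for i in np.flatnonzero(bad) if i < len(names)]
        raise ValueError(
            f"collinear LD-score columns; offending annotations: {offending}"
        )


def fit_sldsc(
    chisq: np.ndarray | pd.Series,
    n_gwas: float,
    ld_scores: pd.DataFrame,
    model_annotations: Sequence[str],
    n_blocks: int = 200,
    use_weights: bool = True,
    weight_ld: np.ndarray | None = None,
) -> RegressionResult:
    """Estimate per-annotation tau from chi-square statistics and LD scores.

    Variants must be aligned (same order) between ``chisq`` and
    ``ld_scores`` and in genome order, since jackknife blocks are contiguous
    index ranges.  With ``use_weights`` (default), a single reweighting pass
    applies heteroskedasticity weights ``1 / (2 (1 + N tau_bar l_tot(j))^2)``
    where ``tau_bar`` is a crude first-pass heritability slope and ``l_tot``
    is ``weight_ld`` (defaults to the row-sum of model LD-score columns,
    floored at 1).  Weighting affects efficiency only; plain OLS
    (``use_weights=False``) must recover the same tau in expectation.
    """
    model_annotations = list(model_annotations)
    y = np.asarray(chisq, dtype=np.float64)
    m = len(y)
    missing = [a for a in model_annotations if a not in ld_scores.columns]
    if missing:
        raise KeyError(f"no LD-score column for annotations: {missing}")
    L = ld_scores[model_annotations].to_numpy(dtype=np.float64)
    if L.shape[0] != m:
        raise ValueError("chisq and ld_scores are not aligned")

    if m < 2 * n_blocks:
        new_blocks = max(2, m // 2)
        warnings.warn(
            f"only {m} variants: reducing jackknife blocks "
            f"{n_blocks} -> {new_blocks}",
            stacklevel=2,
        )
        n_blocks = new_blocks

    X = np.column_stack([n_gwas * L, np.ones(m)])
    names = model_annotations + ["intercept"]
    _check_rank(X, names)

    if use_weights:
        if weight_ld is None:
            weight_ld = np.maximum(L.sum(axis=1), 1.0)
        weight_ld = np.asarray(weight_ld, dtype=np.float64)
        denom = n_gwas * weight_ld.mean()
        tau_bar = max(0.0, (y.mean() - 1.0) / denom) if denom > 0 else 0.0
        w = 1.0 / (2.0 * (1.0 + n_gwas * tau_bar * weight_ld) ** 2)
    else:
        w = np.ones(m)

    Xw = X * w[:, None]
    xtx = X.T @ Xw
    xty = X.T @ (w * y)
    theta = np.linalg.solve(xtx, xty)

    bounds = _block_bounds(m, n_blocks)
    n_terms = X.shape[1]
    block_xtx = np.empty((n_blocks, n_terms, n_terms))
    block_xty = np.empty((n_blocks, n_terms))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        Xb = X[sl]
        wb = w[sl]
        block_xtx[b] = Xb.T @ (Xb * wb[:, None])
        block_xty[b] = Xb.T @ (wb * y[sl])

    jack = np.empty((n_blocks, n_terms))
    for b in range(n_blocks):
        jack[b] = np.linalg.solve(xtx - block_xtx[b], xty - block_xty[b])
    jbar = jack.mean(axis=0)
    jvar = (n_blocks - 1) / n_blocks * ((jack - jbar) ** 2).sum(axis=0)
    se = np.sqrt(jvar)

    tau = theta[:-1]
    tau_se = se[:-1]
    z = np.divide(tau, tau_se, out=np.zeros_like(tau), where=tau_se > 0)
    p = stats.norm.sf(z)
    return RegressionResult(
        annotations=model_annotations,
        tau=tau,
        se=tau_se,
        z=z,
        p=p,
        intercept=float(theta[-1]),
        intercept_se=float(se[-1]),
        n_variants=m,
        n_blocks=n_blocks,
        jackknife_estimates=jack,
    )


def fit_conditional(
    chisq: np.ndarray | pd.Series,
    n_gwas: float,
    ld_scores: pd.DataFrame,
    target_annotation: str,
    conditioning_annotations: Sequence[str],
    n_blocks: int = 200,
    **kwargs,
) -> RegressionResult:
    """Fit the target annotation jointly with confounder annotations.

    Same engine as :func:`fit_sldsc` with model terms
    ``[target] + conditioning``; the returned result carries the target flag.
    With an empty conditioning set this reduces exactly to the unconditional
    fit.
    """
    conditioning = list(conditioning_annotations)
    if target_annotation in conditioning:
        raise ValueError("target annotation must not be in the conditioning set")
    res = fit_sldsc(
        chisq, n_gwas, ld_scores,
        [target_annotation] + conditioning,
        n_blocks=n_blocks, **kwargs,
    )
    res.target = target_annotation
    return res


def coefficient_difference_test(
    result1: RegressionResult, result2: RegressionResult, annotation: str
) -> tuple[float, float]:
    """One-sided two-sample Z-test comparing one annotation's coefficient.

    ``Z = (beta1 - beta2) / sqrt(SE1^2 + SE2^2)``; the one-sided p-value
    tests whether the coefficient dropped from fit 1 to fit 2 (e.g. after
    conditioning on confounding annotations).
    """
    b1, s1 = result1.coefficient(annotation)
    b2, s2 = result2.coefficient(annotation)
    z = (b1 - b2) / np.sqrt(s1 * s1 + s2 * s2)
    return float(z), float(stats.norm.sf(z))


def heritability_summary(
    result: RegressionResult, annotation_sizes: Mapping[str, int]
) -> HeritabilitySummary:
    """Total SNP heritability ``h2 = sum_C tau_C |C|`` with jackknife SE.

    ``annotation_sizes`` maps each model annotation to its variant count
    |C|.  The SE reuses the stored delete-one-block coefficient estimates,
    so h2 and its uncertainty come from the same jackknife.
    """
    missing = [a for a in result.annotations if a not in annotation_sizes]
    if missing:
        raise KeyError(f"sizes missing for annotations: {missing}")
    sizes = np.array([annotation_sizes[a] for a in result.annotations],
                     dtype=np.float64)
    h2 = float(sizes @ result.tau)
    jack_h2 = result.jackknife_estimates[:, :-1] @ sizes
    B = result.n_blocks
    var = (B - 1) / B * ((jack_h2 - jack_h2.mean()) ** 2).sum()
    se = float(np.sqrt(var))
    z = h2 / se if se > 0 else np.inf if h2 > 0 else 0.0
    return HeritabilitySummary(h2=h2, se=se, z=float(z))


def bh_adjust_results(results: Mapping[str, RegressionResult],
                      annotation_per_result: Mapping[str, str] | None = None
                      ) -> pd.DataFrame:
    """Benjamini-Hochberg across a family of per-tissue enrichment tests.

    Each entry contributes the one-sided p of its annotation of interest
    (the target if flagged, else the first model term).
    """
    from epienrich.pathways import bh_adjust

    rows = []
    for name, res in results.items():
        ann = (annotation_per_result or {}).get(name) or res.target \
            or res.annotations[0]
        tau, se = res.coefficient(ann)
        i = res.annotations.index(ann)
        rows.append({"test": name, "annotation": ann, "tau": tau, "se": se,
                     "z": res.z[i], "p": res.p[i]})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out
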