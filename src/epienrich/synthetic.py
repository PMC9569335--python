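"""Synthetic inputs with planted signal for the enrichment pipeline.

Everything the pipeline consumes can be generated here with the statistical
structure the methods assume: an LD-block-structured genotype panel, GWAS
summary statistics whose expected chi-square follows the additive
per-annotation heritability model, a chromatin-state segmentation with
IDEAS-style labels, a peak-by-cell-state signal matrix with planted
cell-type specificity, and risk-variant positions planted inside
state-specific peaks.  Planted parameters (tau coefficients, enrichment
probability pi) are recorded so downstream estimators can be validated
against ground truth.

Seeds propagate hierarchically: one master seed spawns an independent stream
per stage, so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epienrich.annotations import AnnotationSet, GenomicInterval, annotate_variants

# fixed stage keys for hierarchical seeding
_STAGE_KEYS = {
    "genotypes": 1,
    "sumstats": 2,
    "peaks": 3,
    "leads": 4,
    "segmentation": 5,
    "genes": 6,
    "genesets": 7,
}

#: IDEAS-style state vocabulary used for synthetic segmentations.  The six
#: active promoter/enhancer states come first; the rest are inactive filler.
SEGMENTATION_STATES = (
    "10_TssA", "8_TssAFlnk", "14_TssWk", "4_Enh", "6_EnhG", "17_EnhGA",
    "1_Quies", "2_ReprPC", "3_Het", "5_Tx",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_KEYS[stage]]))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    LD is AR-1 within fixed-size blocks of variants and independent across
    blocks; ``rho_ld`` is the latent-Gaussian autocorrelation.  ``planted_tau``
    maps annotation names to per-SNP heritability coefficients tau_C >= 0 (the
    quantities the regression engine must recover).  ``planted_enrichment_pi``
    is the probability that a planted risk variant lands inside a peak
    specific to the target cell state.
    """

    seed: int = 0
    n_individuals: int = 500
    n_variants: int = 2000
    block_size: int = 20
    rho_ld: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    variant_spacing_bp: int = 1000
    gwas_sample_size: int = 50_000
    planted_tau: dict[str, float] = field(default_factory=dict)
    n_peaks: int = 1000
    n_cell_states: int = 6
    specificity_fraction: float = 0.05
    specificity_boost: float = 6.0
    peak_width_bp: int = 500
    peak_gap_bp: int = 500
    planted_enrichment_pi: float = 0.8
    n_lead_variants: int = 50

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_variants": self.n_variants,
            "block_size": self.block_size,
            "variant_spacing_bp": self.variant_spacing_bp,
            "n_peaks": self.n_peaks,
            "n_cell_states": self.n_cell_states,
            "peak_width_bp": self.peak_width_bp,
            "n_lead_variants": self.n_lead_variants,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        # N = 0 is allowed as the no-association limit of the analytic mode
        if self.gwas_sample_size < 0:
            raise ValueError("gwas_sample_size must be non-negative")
        if not (0.0 <= self.rho_ld < 1.0):
            raise ValueError("rho_ld must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name, p in (
            ("specificity_fraction", self.specificity_fraction),
            ("planted_enrichment_pi", self.planted_enrichment_pi),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if any(t < 0 for t in self.planted_tau.values()):
            raise ValueError("planted tau coefficients must be >= 0")
        if self.block_size > self.n_variants:
            raise ValueError("block_size exceeds n_variants")
        if self.n_peaks < self.n_cell_states:
            raise ValueError("n_peaks must be >= n_cell_states")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "planted_tau" in d and d["planted_tau"] is not None:
            d["planted_tau"] = {k: float(v) for k, v in d["planted_tau"].items()}
        return cls(**d)


@dataclass
class GenotypePanel:
    """Reference genotypes: individuals x variants allele counts in {0,1,2}.

    ``variant_map`` has columns SNP, CHR, BP (1-based positions, strictly
    increasing within a chromosome).  ``blocks`` lists half-open variant-index
    ranges of the independent LD blocks.
    """

    variant_map: pd.DataFrame
    genotypes: np.ndarray
    blocks: list[tuple[int, int]]
    rho_ld: float

    def __post_init__(self) -> None:
        if self.genotypes.shape[1] != len(self.variant_map):
            raise ValueError("genotype matrix / variant map size mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per variant."""
        return self.genotypes.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    def standardized(self) -> np.ndarray:
        """Genotypes centred and scaled to unit variance per variant."""
        g = self.genotypes.astype(np.float64)
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        return (g - mu) / sd


@dataclass
class SummaryStats:
    """GWAS summary statistics plus simulation ground truth.

    ``table`` carries SNP, CHR, BP, A1, A2, BETA, SE, P, CHISQ, N, FRQ.
    ``true_tau`` is the planted per-annotation heritability coefficient
    mapping; ``mode`` records the generating process.
    """

    table: pd.DataFrame
    n_gwas: int
    true_tau: dict[str, float]
    mode: str
    seed: int
    #: realized variance of the genetic component (phenotype mode only)
    realized_h2: float | None = None


def simulate_genotype_panel(config: SimulationConfig) -> GenotypePanel:
    """Generate an LD-block-structured diploid genotype panel.

    Each haplotype is a latent AR-1 Gaussian within a block (independent
    across blocks), thresholded at the normal quantile of the target allele
    frequency; genotype = sum of two independent haplotypes.  Monomorphic
    columns (possible at small n) are repaired by flipping one individual so
    every variant has MAF > 0.
    """
    rng = stage_rng(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_variants
    rho = config.rho_ld
    blocks = [
        (s, min(s + config.block_size, m))
        for s in range(0, m, config.block_size)
    ]
    # target MAF is drawn per LD block: variants in strong LD share allele
    # frequencies, and mismatched frequencies would cap attainable r2 far
    # below the latent correlation
    mafs = np.empty(m)
    for lo, hi in blocks:
        mafs[lo:hi] = rng.uniform(*config.maf_range)
    thresholds = stats.norm.ppf(mafs)
    geno = np.empty((n, m), dtype=np.int8)
    for lo, hi in blocks:
        w = hi - lo
        # two haplotypes per individual, AR-1 along variants
        z = rng.standard_normal((2 * n, w))
        if rho > 0:
            scale = np.sqrt(1.0 - rho * rho)
            for j in range(1, w):
                z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
        hap = (z < thresholds[lo:hi]).astype(np.int8)
        geno[:, lo:hi] = hap[:n] + hap[n:]

    # repair monomorphic columns
    colsum = geno.sum(axis=0)
    for j in np.flatnonzero((colsum == 0) | (colsum == 2 * n)):
        i = int(rng.integers(n))
        geno[i, j] = 1

    positions = (np.arange(m, dtype=np.int64) + 1) * config.variant_spacing_bp
    vmap = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "CHR": "1",
            "BP": positions,
        }
    )
    return GenotypePanel(vmap, geno, blocks, rho)


def _membership_matrix(
    panel: GenotypePanel,
    annotations: Mapping[str, AnnotationSet | np.ndarray],
) -> dict[str, np.ndarray]:
    out = {}
    for name, ann in annotations.items():
        if isinstance(ann, AnnotationSet):
            out[name] = annotate_variants(
                panel.variant_map["CHR"], panel.variant_map["BP"], ann
            )
        else:
            vec = np.asarray(ann, dtype=bool)
            if vec.shape != (panel.n_variants,):
                raise ValueError(f"membership vector for {name!r} has wrong length")
            out[name] = vec
    return out


def simulate_summary_stats(
    panel: GenotypePanel,
    annotations: Mapping[str, AnnotationSet | np.ndarray],
    config: SimulationConfig,
    mode: Literal["analytic", "phenotype"] = "analytic",
    ld_scores: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> SummaryStats:
    """Simulate GWAS summary statistics under planted per-annotation tau.

    ``analytic`` mode draws chi-square statistics with expectation
    ``1 + N * sum_C tau_C * l(j, C)`` directly from the model the regression
    engine assumes (LD scores computed from the panel unless supplied).
    ``phenotype`` mode draws per-variant effects with variance
    ``sum_C tau_C a_jC`` on standardized genotypes, builds a unit-variance
    phenotype on the panel individuals, and runs per-variant marginal
    regressions; there N equals the panel size.
    """
    member = _membership_matrix(panel, annotations)
    tau = {k: float(config.planted_tau.get(k, 0.0)) for k in member}
    extra = set(config.planted_tau) - set(member)
    if extra:
        raise ValueError(f"planted_tau names without annotations: {sorted(extra)}")
    h2 = sum(tau[k] * member[k].sum() for k in member)
    if h2 > 1.0:
        raise ValueError(f"planted tau implies total heritability {h2:.3f} > 1")

    if rng is None:
        rng = stage_rng(config.seed, "sumstats")
    m = panel.n_variants
    per_snp_var = np.zeros(m)
    for k in member:
        per_snp_var += tau[k] * member[k]

    if mode == "analytic":
        n_gwas = config.gwas_sample_size
        if ld_scores is None:
            from epienrich.ldscores import partitioned_ld_scores

            ld_scores = partitioned_ld_scores(panel, member, window_bp=1_000_000)
        lam = np.ones(m)
        for k in member:
            lam += n_gwas * tau[k] * ld_scores[k].to_numpy()
        chisq = lam * rng.chisquare(1, size=m)
        z = np.sqrt(chisq) * rng.choice([-1.0, 1.0], size=m)
        se = np.full(m, 1.0 / np.sqrt(n_gwas) if n_gwas > 0 else np.nan)
        realized_h2 = None
    elif mode == "phenotype":
        n_gwas = panel.n_individuals
        zg = panel.standardized()
        beta = rng.standard_normal(m) * np.sqrt(per_snp_var)
        g = zg @ beta
        realized_h2 = float(g.var())
        env_var = max(1e-8, 1.0 - h2)
        y = g + rng.standard_normal(panel.n_individuals) * np.sqrt(env_var)
        yc = (y - y.mean()) / y.std()
        r = (zg * yc[:, None]).mean(axis=0)
        chisq = n_gwas * r * r
        z = np.sqrt(n_gwas) * r
        se = np.full(m, 1.0 / np.sqrt(n_gwas))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pvals = stats.chi2.sf(chisq, df=1)
    frq = panel.allele_freq
    table = panel.variant_map.copy()
    table["A1"] = "A"
    table["A2"] = "G"
    table["BETA"] = z * se
    table["SE"] = se
    table["P"] = pvals
    table["CHISQ"] = chisq
    table["N"] = n_gwas
    table["FRQ"] = frq
    return SummaryStats(table, n_gwas, tau, mode, config.seed, realized_h2)


def simulate_segmentation(
    config: SimulationConfig,
    mean_segment_bp: int = 5000,
    active_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """Tile the synthetic genome with IDEAS-style labelled segments.

    Segment lengths are geometric with the given mean; each segment draws an
    active promoter/enhancer state with probability ``active_fraction``
    (uniform over the six active labels), otherwise an inactive label.
    """
    if rng is None:
        rng = stage_rng(config.seed, "segmentation")
    genome_end = (config.n_variants + 1) * config.variant_spacing_bp
    active = SEGMENTATION_STATES[:6]
    inactive = SEGMENTATION_STATES[6:]
    out: list[GenomicInterval] = []
    pos = 0
    while pos < genome_end:
        length = max(200, int(rng.geometric(1.0 / mean_segment_bp)))
        end = min(pos + length, genome_end)
        if rng.uniform() < active_fraction:
            state = active[int(rng.integers(len(active)))]
        else:
            state = inactive[int(rng.integers(len(inactive)))]
        out.append(GenomicInterval("1", pos, end, state))
        pos = end
    return out


@dataclass
class PeakMatrix:
    """Peak intervals plus raw peak-by-cell-state signal and planted truth.

    ``peaks`` has columns peak_id, CHR, start, end (BED coordinates);
    ``signal`` is peaks x states; ``planted_specific`` maps each state to the
    indices of peaks given a specificity boost in that state only.
    """

    peaks: pd.DataFrame
    signal: np.ndarray
    states: list[str]
    planted_specific: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_peak_matrix(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PeakMatrix:
    """Simulate non-overlapping peaks with planted cell-state specificity.

    Background signal is log-normal and shared across states; for each state
    a disjoint subset (``specificity_fraction`` of peaks) receives a
    multiplicative boost in that state only, making those peaks highly
    specific to it.
    """
    if rng is None:
        rng = stage_rng(config.seed, "peaks")
    n_peaks, n_states = config.n_peaks, config.n_cell_states
    states = [f"state_{i + 1}" for i in range(n_states)]

    pitch = config.peak_width_bp + config.peak_gap_bp
    starts = np.arange(n_peaks, dtype=np.int64) * pitch + config.peak_gap_bp
    ends = starts + config.peak_width_bp
    peaks = pd.DataFrame(
        {
            "peak_id": [f"peak_{i + 1}" for i in range(n_peaks)],
            "CHR": "1",
            "start": starts,
            "end": ends,
        }
    )

    base = rng.lognormal(mean=3.0, sigma=0.5, size=n_peaks)
    noise = rng.lognormal(mean=0.0, sigma=0.2, size=(n_peaks, n_states))
    signal = base[:, None] * noise

    n_spec = int(round(config.specificity_fraction * n_peaks))
    planted: dict[str, np.ndarray] = {}
    if n_spec > 0:
        if n_spec * n_states > n_peaks:
            raise ValueError(
                "specificity_fraction too large for disjoint per-state sets"
            )
        pool = rng.permutation(n_peaks)
        for i, st in enumerate(states):
            idx = np.sort(pool[i * n_spec:(i + 1) * n_spec])
            signal[idx, i] *= config.specificity_boost
            planted[st] = idx
    else:
        planted = {st: np.empty(0, dtype=np.int64) for st in states}
    return PeakMatrix(peaks, signal, states, planted)


def plant_risk_variants(
    peaks: PeakMatrix,
    target_state: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Place lead risk variants, enriched in target-state-specific peaks.

    With probability ``planted_enrichment_pi`` a lead falls uniformly inside
    a peak planted as specific to ``target_state``; otherwise uniformly on
    the genome.  Returns a table of SNP, CHR, BP (1-based).
    """
    if target_state not in peaks.states:
        raise KeyError(f"unknown cell state {target_state!r}")
    specific = peaks.planted_specific.get(target_state)
    pi = config.planted_enrichment_pi
    if pi > 0 and (specific is None or len(specific) == 0):
        raise ValueError(
            f"no peaks specific to {target_state!r}; cannot plant enrichment"
        )
    if rng is None:
        rng = stage_rng(config.seed, "leads")
    genome_end = int(peaks.peaks["end"].max()) + config.peak_gap_bp
    rows = []
    for i in range(config.n_lead_variants):
        if pi > 0 and rng.uniform() < pi:
            j = int(specific[int(rng.integers(len(specific)))])
            start = int(peaks.peaks["start"].iloc[j])
            end = int(peaks.peaks["end"].iloc[j])
            pos0 = int(rng.integers(start, end))
        else:
            pos0 = int(rng.integers(0, genome_end))
        rows.append({"SNP": f"lead_{i + 1}", "CHR": "1", "BP": pos0 + 1})
    return pd.DataFrame(rows)


def simulate_gene_model(
    config: SimulationConfig,
    gene_length_bp: int = 2000,
    gene_gap_bp: int = 3000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tile the genome with genes of alternating strand.

    Returns columns gene_id, CHR, start, end, strand, tss (1-based TSS at the
    gene-body start on + strand, end on - strand).
    """
    if rng is None:
        rng = stage_rng(config.seed, "genes")
    genome_end = (config.n_variants + 1) * config.variant_spacing_bp
    pitch = gene_length_bp + gene_gap_bp
    n_genes = max(1, genome_end // pitch)
    rows = []
    for i in range(n_genes):
        start = i * pitch + gene_gap_bp // 2
        end = start + gene_length_bp
        strand = "+" if rng.uniform() < 0.5 else "-"
        tss = start + 1 if strand == "+" else end
        rows.append(
            {
                "gene_id": f"gene_{i + 1}",
                "CHR": "1",
                "start": start,
                "end": end,
                "strand": strand,
                "tss": tss,
            }
        )
    return pd.DataFrame(rows)


def simulate_gene_sets(
    genes: pd.DataFrame,
    config: SimulationConfig,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    enriched_genes: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Random gene sets, plus one set seeded with ``enriched_genes`` if given."""
    if rng is None:
        rng = stage_rng(config.seed, "genesets")
    ids = genes["gene_id"].tolist()
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        size = min(size, len(ids))
        pick = rng.choice(len(ids), size=size, replace=False)
        sets[f"pathway_{i + 1}"] = sorted(ids[j] for j in pick)
    if enriched_genes:
        extra = [g for g in ids if g not in set(enriched_genes)]
        pad = rng.choice(len(extra), size=min(10, len(extra)), replace=False)
        sets["pathway_planted"] = sorted(
            set(enriched_genes) | {extra[j] for j in pad}
        )
    return sets


# ---------------------------------------------------------------------------
# Plain-text writers (TSV / BED); every file starts with a seed comment so
# outputs are traceable to their configuration.

def _header(fh, config: SimulationConfig) -> None:
    fh.write(f"# seed={config.seed}\n")


def write_panel(panel: GenotypePanel, config: SimulationConfig,
                map_path, matrix_path) -> None:
    with open(map_path, "w") as fh:
        _header(fh, config)
        panel.variant_map.to_csv(fh, sep="\t", index=False)
    with open(matrix_path, "w") as fh:
        _header(fh, config)
        np.savetxt(fh, panel.genotypes, fmt="%d", delimiter="\t")


def read_panel(map_path, matrix_path, blocks=None, rho_ld=0.0) -> GenotypePanel:
    vmap = pd.read_csv(map_path, sep="\t", comment="#",
                       dtype={"CHR": str})
    geno = np.loadtxt(matrix_path, dtype=np.int8, delimiter="\t", comments="#")
    geno = np.atleast_2d(geno)
    if blocks is None:
        blocks = [(0, geno.shape[1])]
    return GenotypePanel(vmap, geno, blocks, rho_ld)


def write_sumstats(ss: SummaryStats, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={ss.seed} mode={ss.mode} N={ss.n_gwas}\n")
        ss.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})


def write_peak_matrix(pm: PeakMatrix, config: SimulationConfig,
                      bed_path, signal_path) -> None:
    with open(bed_path, "w") as fh:
        for _, r in pm.peaks.iterrows():
            fh.write(f"{r.CHR}\t{r.start}\t{r.end}\t{r.peak_id}\n")
    sig = pd.DataFrame(pm.signal, columns=pm.states)
    sig.insert(0, "peak_id", pm.peaks["peak_id"].to_numpy())
    with open(signal_path, "w") as fh:
        _header(fh, config)
        sig.to_csv(fh, sep="\t", index=False, float_format="%.6g")
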