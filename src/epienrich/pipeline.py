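"""End-to-end orchestration of the enrichment pipeline on one config.

Stages run in dependency order:

    simulate -> annotate -> ldscore -> sldsc -> clump -> cheers
             -> compare -> pathways

Each stage reads only declared inputs from the output directory and writes
plain-text outputs (TSV/BED/JSON); a run manifest records the config
snapshot, seed, per-stage output digests and record counts.  Re-running
with an unchanged config skips stages whose outputs already exist with
matching digests, and deterministic stages reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from epienrich import __version__, annotations as ann, cheers, clumping
from epienrich import comparisons, ldscores, pathways, sldsc, synthetic

logger = logging.getLogger(__name__)

STAGES = ["simulate", "annotate", "ldscore", "sldsc", "clump",
          "cheers", "compare", "pathways"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)

    def record(self, stage: str, files: dict[str, Path],
               counts: dict[str, int], cfg_digest: str) -> None:
        self.stages[stage] = {
            "config_digest": cfg_digest,
            "files": {k: {"path": str(p), "sha256": _digest(p)}
                      for k, p in files.items()},
            "counts": counts,
            "finished": time.time(),
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "seed": self.seed,
                 "version": self.version, "stages": self.stages,
                 "started": self.started},
                fh, indent=1, default=str,
            )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _cfg_digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    unknown = set(cfg) - {"simulation", "ldscore", "sldsc", "clump",
                          "cheers", "compare", "pathways"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def default_config() -> dict:
    from importlib.resources import files

    return yaml.safe_load(
        files("epienrich").joinpath("data/demo_config.yaml").read_text()
    )


def _stage_fresh(manifest_path: Path, stage: str, cfg_digest: str) -> bool:
    """True when a previous run of this stage is on disk with intact outputs."""
    if not manifest_path.exists():
        return False
    try:
        prev = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    rec = prev.get("stages", {}).get(stage)
    if rec is None or rec.get("config_digest") != cfg_digest:
        return False
    for entry in rec["files"].values():
        p = Path(entry["path"])
        if not p.exists() or _digest(p) != entry["sha256"]:
            return False
    return True


def run_pipeline(
    config: dict,
    out_dir,
    seed: int | None = None,
    stages: list[str] | None = None,
    resume: bool = True,
) -> RunManifest:
    """Run (a subset of) the pipeline stages; returns the run manifest.

    ``seed`` overrides ``config["simulation"]["seed"]``.  Stage names are
    validated before any computation; requesting a later stage assumes its
    upstream outputs exist in ``out_dir``.
    """
    requested = stages or STAGES
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
    requested = [s for s in STAGES if s in requested]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg_dict = dict(config.get("simulation", {}))
    if seed is not None:
        sim_cfg_dict["seed"] = seed
    sim_cfg = synthetic.SimulationConfig.from_dict(sim_cfg_dict)

    manifest_path = out / "manifest.json"
    manifest = RunManifest(config=config, seed=sim_cfg.seed)

    ctx: dict = {"sim_cfg": sim_cfg, "out": out}
    for stage in requested:
        stage_cfg = {"simulation": sim_cfg_dict,
                     stage: config.get(stage, {})}
        cdg = _cfg_digest(stage_cfg)
        if resume and _stage_fresh(manifest_path, stage, cdg):
            logger.info("stage %s up to date; skipping", stage)
            prev = json.loads(manifest_path.read_text())
            manifest.stages[stage] = prev["stages"][stage]
            continue
        logger.info("running stage %s", stage)
        files, counts = _STAGE_FUNCS[stage](config, ctx)
        manifest.record(stage, files, counts, cdg)
        manifest.write(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stage implementations.  Each takes (config, ctx) and returns
# ({name: path}, {name: record count}); intermediate objects needed by later
# stages are reloaded from disk so stages stay isolated.


def _load_panel(out: Path) -> synthetic.GenotypePanel:
    return synthetic.read_panel(out / "variant_map.tsv", out / "genotypes.tsv")


def _stage_simulate(config, ctx):
    cfg: synthetic.SimulationConfig = ctx["sim_cfg"]
    out: Path = ctx["out"]
    panel = synthetic.simulate_genotype_panel(cfg)
    synthetic.write_panel(panel, cfg, out / "variant_map.tsv",
                          out / "genotypes.tsv")
    seg = synthetic.simulate_segmentation(cfg)
    ann.write_bed(out / "segmentation.bed", seg)

    active = ann.merge_active_states(seg)
    member = {"active": ann.annotate_variants(
        panel.variant_map["CHR"], panel.variant_map["BP"], active)}
    ld_window = config.get("ldscore", {}).get("window_bp", 1_000_000)
    ld = ldscores.partitioned_ld_scores(panel, member, window_bp=ld_window)
    ss_a = synthetic.simulate_summary_stats(panel, member, cfg,
                                            mode="analytic", ld_scores=ld)
    synthetic.write_sumstats(ss_a, out / "sumstats_disorderA.tsv")
    null_cfg = synthetic.SimulationConfig.from_dict(
        {**cfg.__dict__, "planted_tau": {}, "seed": cfg.seed + 1,
         "maf_range": tuple(cfg.maf_range)})
    ss_b = synthetic.simulate_summary_stats(panel, member, null_cfg,
                                            mode="analytic", ld_scores=ld)
    synthetic.write_sumstats(ss_b, out / "sumstats_disorderB.tsv")

    pm = synthetic.simulate_peak_matrix(cfg)
    synthetic.write_peak_matrix(pm, cfg, out / "peaks.bed",
                                out / "peak_signal.tsv")
    target = config.get("cheers", {}).get("target_state", "state_1")
    leads_a = synthetic.plant_risk_variants(pm, target, cfg)
    null_cfg2 = synthetic.SimulationConfig.from_dict(
        {**cfg.__dict__, "planted_enrichment_pi": 0.0, "seed": cfg.seed + 2,
         "maf_range": tuple(cfg.maf_range), "planted_tau": dict(cfg.planted_tau)})
    leads_b = synthetic.plant_risk_variants(pm, target, null_cfg2)
    leads_a.to_csv(out / "planted_leads_disorderA.tsv", sep="\t", index=False)
    leads_b.to_csv(out / "planted_leads_disorderB.tsv", sep="\t", index=False)

    genes = synthetic.simulate_gene_model(cfg)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)

    truth = {"planted_tau": cfg.planted_tau, "target_state": target,
             "planted_enrichment_pi": cfg.planted_enrichment_pi,
             "seed": cfg.seed}
    (out / "truth.json").write_text(json.dumps(truth, indent=1))

    files = {n: out / f for n, f in [
        ("variant_map", "variant_map.tsv"), ("genotypes", "genotypes.tsv"),
        ("segmentation", "segmentation.bed"),
        ("sumstats_a", "sumstats_disorderA.tsv"),
        ("sumstats_b", "sumstats_disorderB.tsv"),
        ("peaks", "peaks.bed"), ("peak_signal", "peak_signal.tsv"),
        ("leads_a", "planted_leads_disorderA.tsv"),
        ("leads_b", "planted_leads_disorderB.tsv"),
        ("genes", "genes.tsv"), ("truth", "truth.json")]}
    counts = {"variants": panel.n_variants, "segments": len(seg),
              "peaks": cfg.n_peaks, "genes": len(genes)}
    return files, counts


def _stage_annotate(config, ctx):
    out: Path = ctx["out"]
    seg = ann.read_bed(out / "segmentation.bed")
    active = ann.merge_active_states(seg)
    classes = ann.class_annotations(seg)
    ann.write_bed(out / "active.bed", active)
    for cls, a in classes.items():
        ann.write_bed(out / f"{cls}.bed", a)

    panel = _load_panel(out)
    member = pd.DataFrame({"SNP": panel.variant_map["SNP"]})
    sizes = {}
    for name, a in {"active": active, **classes}.items():
        vec = ann.annotate_variants(panel.variant_map["CHR"],
                                    panel.variant_map["BP"], a)
        member[name] = vec.astype(int)
        sizes[name] = int(vec.sum())
    member["all"] = 1
    sizes["all"] = panel.n_variants
    member.to_csv(out / "membership.tsv", sep="\t", index=False)
    (out / "annotation_sizes.json").write_text(json.dumps(sizes, indent=1))

    files = {"active": out / "active.bed",
             "membership": out / "membership.tsv",
             "sizes": out / "annotation_sizes.json"}
    files.update({cls: out / f"{cls}.bed" for cls in classes})
    counts = {"active_bases": active.total_length, **sizes}
    return files, counts


def _stage_ldscore(config, ctx):
    out: Path = ctx["out"]
    lcfg = config.get("ldscore", {})
    panel = _load_panel(out)
    member = pd.read_csv(out / "membership.tsv", sep="\t")
    annots = {c: member[c].to_numpy(dtype=bool)
              for c in member.columns if c != "SNP"}
    ld = ldscores.partitioned_ld_scores(
        panel, annots,
        window_bp=lcfg.get("window_bp", 1_000_000),
        adjusted=lcfg.get("adjusted", False),
    )
    ldscores.write_ld_scores(ld, out / "ld_scores.tsv")
    return ({"ld_scores": out / "ld_scores.tsv"},
            {"variants": len(ld), "annotations": ld.shape[1]})


def _stage_sldsc(config, ctx):
    out: Path = ctx["out"]
    scfg = config.get("sldsc", {})
    ld = ldscores.read_ld_scores(out / "ld_scores.tsv")
    sizes = json.loads((out / "annotation_sizes.json").read_text())
    n_blocks = scfg.get("n_blocks", 200)
    use_weights = scfg.get("use_weights", True)

    results = {}
    herit_rows = []
    for d in ("disorderA", "disorderB"):
        ss = synthetic.read_sumstats(out / f"sumstats_{d}.tsv")
        res = sldsc.fit_sldsc(
            ss["CHISQ"].to_numpy(), float(ss["N"].iloc[0]), ld,
            ["active", "all"], n_blocks=n_blocks, use_weights=use_weights,
        )
        res.target = "active"
        results[d] = res
        h = sldsc.heritability_summary(res, sizes)
        herit_rows.append({"disorder": d, "h2": h.h2, "se": h.se, "z": h.z})

    family = sldsc.bh_adjust_results(results)
    family.rename(columns={"test": "disorder"}, inplace=True)
    family.to_csv(out / "sldsc_results.tsv", sep="\t", index=False,
                  float_format="%.6g")
    pd.DataFrame(herit_rows).to_csv(out / "heritability.tsv", sep="\t",
                                    index=False, float_format="%.6g")

    # conditional example: is the enhancer class enriched beyond the full
    # active annotation it is part of?
    ss = synthetic.read_sumstats(out / "sumstats_disorderA.tsv")
    n = float(ss["N"].iloc[0])
    chisq = ss["CHISQ"].to_numpy()
    uncond = sldsc.fit_sldsc(chisq, n, ld, ["enhancer", "all"],
                             n_blocks=n_blocks, use_weights=use_weights)
    cond = sldsc.fit_conditional(chisq, n, ld, "enhancer", ["active", "all"],
                                 n_blocks=n_blocks, use_weights=use_weights)
    z, p = sldsc.coefficient_difference_test(uncond, cond, "enhancer")
    cond_tbl = pd.DataFrame([
        {"model": "unconditional", **_coef_row(uncond, "enhancer")},
        {"model": "conditional_on_active", **_coef_row(cond, "enhancer")},
        {"model": "difference", "tau": np.nan, "se": np.nan, "z": z, "p": p},
    ])
    cond_tbl.to_csv(out / "conditional_results.tsv", sep="\t", index=False,
                    float_format="%.6g")
    files = {"sldsc": out / "sldsc_results.tsv",
             "heritability": out / "heritability.tsv",
             "conditional": out / "conditional_results.tsv"}
    return files, {"disorders": len(results)}


def _coef_row(res: sldsc.RegressionResult, annotation: str) -> dict:
    i = res.annotations.index(annotation)
    return {"tau": res.tau[i], "se": res.se[i], "z": res.z[i], "p": res.p[i]}


def _stage_clump(config, ctx):
    out: Path = ctx["out"]
    ccfg = config.get("clump", {})
    panel = _load_panel(out)
    files, counts = {}, {}
    for d in ("disorderA", "disorderB"):
        ss = synthetic.read_sumstats(out / f"sumstats_{d}.tsv")
        ss = clumping.filter_mac(ss, ccfg.get("min_mac", 10))
        ss = clumping.filter_maf_panel(ss, panel, ccfg.get("min_maf", 0.01))
        mhc = ccfg.get("mhc", None)
        leads = clumping.clump(
            ss,
            p_threshold=ccfg.get("p_threshold", 5e-8),
            distance_bp=ccfg.get("distance_bp", 500_000),
            mhc=tuple(mhc) if mhc else None,
            disorder=d,
        )
        eligible = clumping.check_min_loci(leads, ccfg.get("min_loci", 3))
        leads.provenance["eligible"] = bool(eligible)
        clumping.write_leads(leads, out / f"leads_{d}.tsv",
                             out / f"leads_{d}.bed")
        (out / f"leads_{d}_provenance.json").write_text(
            json.dumps(leads.provenance, indent=1))
        files[f"leads_{d}"] = out / f"leads_{d}.tsv"
        files[f"leads_{d}_bed"] = out / f"leads_{d}.bed"
        files[f"prov_{d}"] = out / f"leads_{d}_provenance.json"
        counts[f"n_leads_{d}"] = len(leads)
    return files, counts


def _load_psm(out: Path):
    sig = pd.read_csv(out / "peak_signal.tsv", sep="\t", comment="#")
    states = [c for c in sig.columns if c != "peak_id"]
    bed = pd.read_csv(out / "peaks.bed", sep="\t",
                      names=["CHR", "start", "end", "peak_id"],
                      dtype={"CHR": str})
    bed = bed[["peak_id", "CHR", "start", "end"]]
    return cheers.specificity_scores(sig[states].to_numpy(), bed, states)


def _stage_cheers(config, ctx):
    out: Path = ctx["out"]
    psm = _load_psm(out)
    files, counts = {}, {}
    for d in ("disorderA", "disorderB"):
        variants = pd.read_csv(out / f"planted_leads_{d}.tsv", sep="\t",
                               dtype={"CHR": str})
        res, overlaps = cheers.cheers_test(psm, variants)
        res.to_csv(out / f"cheers_results_{d}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        overlaps.to_csv(out / f"cheers_overlaps_{d}.tsv", sep="\t",
                        index=False, float_format="%.6g")
        files[f"cheers_{d}"] = out / f"cheers_results_{d}.tsv"
        files[f"overlaps_{d}"] = out / f"cheers_overlaps_{d}.tsv"
        counts[f"n_overlapped_peaks_{d}"] = overlaps["peak_id"].nunique()
    return files, counts


def _stage_compare(config, ctx):
    out: Path = ctx["out"]
    ccfg = config.get("compare", {})
    psm = _load_psm(out)
    overlaps = {
        d: pd.read_csv(out / f"cheers_overlaps_{d}.tsv", sep="\t")
        for d in ("disorderA", "disorderB")
    }
    share = comparisons.sharing_counts(
        {d: o["peak_id"] for d, o in overlaps.items()})
    share.to_csv(out / "sharing.tsv", sep="\t", index=False)

    seg = ann.read_bed(out / "segmentation.bed")
    classes = ann.class_annotations(seg)
    labels = comparisons.classify_peak_elements(psm.peaks, classes)
    cls = pd.Series(comparisons.collapse_classes(labels))
    target = config.get("cheers", {}).get("target_state", "state_1")
    report = comparisons.discordant_peaks(
        psm, overlaps["disorderA"], overlaps["disorderB"],
        states=[target],
        specificity_threshold=ccfg.get("specificity_threshold", 0.9),
        disorder_a="disorderA", disorder_b="disorderB",
        peak_classes=cls,
    )
    report.a_not_b.to_csv(out / "discordant_a_not_b.tsv", sep="\t",
                          index=False, float_format="%.6g")
    report.b_not_a.to_csv(out / "discordant_b_not_a.tsv", sep="\t",
                          index=False, float_format="%.6g")

    ra = pd.read_csv(out / "cheers_results_disorderA.tsv", sep="\t")
    rb = pd.read_csv(out / "cheers_results_disorderB.tsv", sep="\t")
    corr = comparisons.spearman_exact(
        ra["z"].to_numpy(), rb["z"].to_numpy(),
        n_boot=ccfg.get("n_boot", 10_000),
        seed=ctx["sim_cfg"].seed,
    )
    (out / "correlation.json").write_text(json.dumps({
        "n": corr.n, "S": corr.s_statistic, "rho": round(corr.rho, 10),
        "p": round(corr.p, 10), "method": corr.p_method,
        "ci95": [round(corr.ci_low, 10), round(corr.ci_high, 10)],
    }, indent=1))
    files = {"sharing": out / "sharing.tsv",
             "discordant_ab": out / "discordant_a_not_b.tsv",
             "discordant_ba": out / "discordant_b_not_a.tsv",
             "correlation": out / "correlation.json"}
    return files, {"sharing_cells": len(share)}


def _stage_pathways(config, ctx):
    out: Path = ctx["out"]
    pcfg = config.get("pathways", {})
    psm = _load_psm(out)
    overlaps = pd.read_csv(out / "cheers_overlaps_disorderA.tsv", sep="\t")
    target = config.get("cheers", {}).get("target_state", "state_1")
    idx = pathways.select_test_peaks(
        psm, overlaps, states=[target],
        specificity_threshold=pcfg.get("specificity_threshold", 0.9))
    genes = pathways.read_gene_model(out / "genes.tsv")
    gene_list = pathways.peaks_to_genes(
        psm.peaks.iloc[idx], genes,
        max_tss_distance=pcfg.get("max_tss_distance", 10_000))
    sets = synthetic.simulate_gene_sets(genes, ctx["sim_cfg"],
                                        enriched_genes=gene_list)
    pathways.write_gmt(sets, out / "gene_sets.gmt")
    tbl = pathways.ora(gene_list, sets, genes["gene_id"])
    tbl.to_csv(out / "ora_results.tsv", sep="\t", index=False,
               float_format="%.6g")
    files = {"ora": out / "ora_results.tsv",
             "gene_sets": out / "gene_sets.gmt"}
    return files, {"test_peaks": len(idx), "test_genes": len(gene_list),
                   "gene_sets": len(sets)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "ldscore": _stage_ldscore,
    "sldsc": _stage_sldsc,
    "clump": _stage_clump,
    "cheers": _stage_cheers,
    "compare": _stage_compare,
    "pathways": _stage_pathways,
}


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
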