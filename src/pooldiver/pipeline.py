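"""End-to-end orchestration: simulate -> select -> call -> test ->
annotate -> concord -> design, with a JSON manifest of every stage.

Each stage writes its outputs under the run directory before the next
starts; a failure aborts with the stage name while earlier outputs are
preserved. Reruns with the same configuration reproduce all outputs
byte-identically (every stochastic step draws from a stream derived from
the single global seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, calling, cohort, concordance, design
from . import difftest, io, simulate
from .errors import PoolDiverError

log = logging.getLogger("pooldiver")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (serialisable to/from YAML)."""

    seed: int = 0
    out_dir: str = "pooldiver_run"
    # simulation
    n_genes: int = 6
    n_loci: int = 2000
    n_per_group: int = 75
    mean_depth_low: float = 56.0
    mean_depth_high: float = 32.0
    depth_dispersion: float = 0.3
    seq_error_rate: float = 0.001
    frac_differential: float = 0.15
    differential_effect: float = 0.35
    # cohort selection
    n_candidates: int = 698
    n_sires: int = 60
    group_size: int = 75
    w_ebv: float = 0.6
    w_rel: float = 0.4
    # calling / testing
    min_alt_reads: int = 4
    alpha_pools: float = 0.01
    top_k: int = 20
    top_min_distance: int = 10_000_000
    # validation
    alpha_concord: float = 0.1
    n_concord_snps: int = 43
    fnr_tiers: tuple = (4, 10, 30)
    # logging
    log_level: str = "INFO"

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            seed=self.seed, n_per_group=self.n_per_group,
            n_loci=self.n_loci, mean_depth_low=self.mean_depth_low,
            mean_depth_high=self.mean_depth_high,
            depth_dispersion=self.depth_dispersion,
            seq_error_rate=self.seq_error_rate,
            frac_differential=self.frac_differential,
            differential_effect=self.differential_effect)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["fnr_tiers"] = list(self.fnr_tiers)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "fnr_tiers" in d:
            d["fnr_tiers"] = tuple(d["fnr_tiers"])
        return cls(**d)


@dataclass
class _Manifest:
    version: str
    seed: int
    config: dict
    stages: list = field(default_factory=list)

    def add(self, name: str, outputs: list[str], counts: dict) -> None:
        self.stages.append(
            {"stage": name, "outputs": outputs, "row_counts": counts,
             "status": "complete"})

    def write(self, path) -> None:
        d = asdict(self)
        d["config"]["fnr_tiers"] = list(d["config"]["fnr_tiers"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True)
                              + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run all seven stages; returns the manifest as a dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(version=__version__, seed=config.seed,
                         config=asdict(config))
    manifest_path = out / "manifest.json"
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate), ("select", _stage_select),
        ("call", _stage_call), ("test", _stage_test),
        ("annotate", _stage_annotate), ("concord", _stage_concord),
        ("design", _stage_design),
    ]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            outputs, counts = fn(config, out, state)
        except Exception as exc:
            manifest.stages.append({"stage": name, "status": "failed",
                                    "error": str(exc)})
            manifest.write(manifest_path)
            raise PoolDiverError(f"stage {name!r} failed: {exc}") from exc
        manifest.add(name, outputs, counts)
    manifest.write(manifest_path)
    config.to_yaml(out / "config.yaml")
    return asdict(manifest)


def _stage_simulate(cfg: RunConfig, out: Path, st: dict):
    sim = cfg.sim_config()
    genome = simulate.simulate_toy_genome(cfg.n_genes, seed=cfg.seed)
    truth = simulate.simulate_truth(sim, genome=genome)
    counts = simulate.simulate_pool_counts(truth, sim)
    ped = simulate.simulate_pedigree(cfg.n_candidates, cfg.n_sires,
                                     seed=cfg.seed)
    st.update(genome=genome, truth=truth, counts=counts, ped=ped, sim=sim)
    io.write_fasta(genome.sequences, out / "reference.fa")
    io.write_gtf(genome.models, out / "genes.gtf")
    io.write_truth_vcf(truth, out / "truth.vcf")
    io.write_truth_vcf(genome.variants, out / "planted.vcf")
    io.write_counts_tsv(counts, out / "counts.tsv")
    io.write_pedigree_tsv(ped, out / "pedigree.tsv")
    return (["reference.fa", "genes.gtf", "truth.vcf", "planted.vcf",
             "counts.tsv", "pedigree.tsv"],
            {"loci": len(truth), "planted_variants": len(genome.variants),
             "animals": len(ped)})


def _stage_select(cfg: RunConfig, out: Path, st: dict):
    ped = st["ped"]
    A = cohort.numerator_relationship_matrix(ped)
    weights = cohort.IndexWeights(cfg.w_ebv, cfg.w_rel)
    res = cohort.select_divergent_groups(ped, A, cfg.group_size, weights)
    summary = cohort.group_summary(res, A, ped)
    st.update(selection=res, A=A)
    groups = pd.DataFrame(
        {"id": res.low_group + res.high_group,
         "group": ["low"] * len(res.low_group)
         + ["high"] * len(res.high_group)})
    groups.to_csv(out / "groups.tsv", sep="\t", index=False)
    summary.to_csv(out / "group_summary.tsv", sep="\t", index=False)
    res.trace.to_csv(out / "selection_trace.tsv", sep="\t", index=False)
    return (["groups.tsv", "group_summary.tsv", "selection_trace.tsv"],
            {"selected": len(groups)})


def _stage_call(cfg: RunConfig, out: Path, st: dict):
    calls = calling.call_variants(st["counts"], cfg.min_alt_reads)
    st["calls"] = calls
    io.write_variants_vcf(calls, out / "calls.vcf")
    io.write_variants_tsv(calls, out / "calls.tsv")
    stats = calling.capture_summary(
        calls["depth_low"].to_numpy(), calls["depth_high"].to_numpy())
    frame = stats.to_frame().reset_index()
    frame.to_csv(out / "capture_stats.tsv", sep="\t", index=False)
    return (["calls.vcf", "calls.tsv", "capture_stats.tsv"],
            {"sites": len(calls), "called": int(calls["called"].sum())})


def _stage_test(cfg: RunConfig, out: Path, st: dict):
    results = difftest.compare_pools(st["calls"], cfg.alpha_pools)
    st["results"] = results
    results.to_csv(out / "differential.tsv", sep="\t", index=False,
                   na_rep=io.NA)
    dist = difftest.differential_distribution(results)
    dist["histogram"].to_csv(out / "differential_hist.tsv", sep="\t",
                             index=False)
    dist["qq"].to_csv(out / "differential_qq.tsv", sep="\t", index=False)
    top = difftest.top_k_spaced(results, cfg.top_k, cfg.top_min_distance)
    top.to_csv(out / "top_snps.tsv", sep="\t", index=False)
    return (["differential.tsv", "differential_hist.tsv",
             "differential_qq.tsv", "top_snps.tsv"],
            {"tested": len(results),
             "significant": int(results["significant"].sum())})


def _stage_annotate(cfg: RunConfig, out: Path, st: dict):
    genome = st["genome"]
    called = st["calls"][st["calls"]["called"]].reset_index(drop=True)
    ann = annotate.annotate_variants(called, genome.models,
                                     genome.sequences)
    st["annotations"] = ann
    ann.to_csv(out / "annotations.tsv", sep="\t", index=False,
               na_rep=io.NA)
    summary = annotate.summarize_categories(ann, called)
    summary.to_csv(out / "category_summary.tsv", sep="\t", index=False)
    annotate.table2_view(summary).to_csv(
        out / "category_summary_merged.tsv", sep="\t", index=False)
    return (["annotations.tsv", "category_summary.tsv",
             "category_summary_merged.tsv"],
            {"annotated": len(ann)})


def _stage_concord(cfg: RunConfig, out: Path, st: dict):
    sim, truth, calls = st["sim"], st["truth"], st["calls"]
    geno = simulate.simulate_genotypes(truth, sim)
    keyed = calls.set_index(
        calls["chrom"].astype(str) + ":" + calls["pos"].astype(str))
    called_ids = keyed.index[keyed["called"]]
    pick = list(called_ids[:cfg.n_concord_snps])
    rows = []
    for pool in ("low", "high"):
        g = geno[pool].loc[pick]
        alt_copies = g.sum(axis=1)
        total = 2 * g.notna().sum(axis=1)
        est_alt = keyed.loc[pick, f"alt_{pool}"]
        est_depth = keyed.loc[pick, f"depth_{pool}"]
        for sid in pick:
            rows.append({
                "snp_id": sid, "pool": pool,
                "actual_alt": int(alt_copies[sid]),
                "actual_total": int(total[sid]),
                "est_alt": int(est_alt[sid]),
                "est_depth": int(est_depth[sid])})
    conc = concordance.concordance_test(pd.DataFrame(rows),
                                        cfg.alpha_concord)
    conc.to_csv(out / "concordance.tsv", sep="\t", index=False,
                na_rep=io.NA)
    truth_ids = truth["chrom"].astype(str) + ":" + truth["pos"].astype(str)
    combined_depth = keyed["depth_low"] + keyed["depth_high"]
    reference = pd.DataFrame({
        "chrom": truth["chrom"], "pos": truth["pos"],
        "depth": combined_depth.reindex(truth_ids).to_numpy(),
    })
    fnr = concordance.false_negative_report(reference, calls,
                                            cfg.fnr_tiers)
    fnr.tiers.to_csv(out / "fnr.tsv", sep="\t", index=False)
    fnr.depth_quartiles.to_csv(out / "fnr_depth_quartiles.tsv", sep="\t",
                               index=False)
    st["concordance"] = conc
    st["fnr"] = fnr
    return (["concordance.tsv", "fnr.tsv", "fnr_depth_quartiles.tsv"],
            {"tests": len(conc),
             "concordant": int(conc["concordant"].sum())})


def _stage_design(cfg: RunConfig, out: Path, st: dict):
    table = design.design_table(
        int(cfg.mean_depth_low), int(cfg.mean_depth_high),
        cfg.min_alt_reads, cfg.seq_error_rate)
    table.to_csv(out / "design.tsv", sep="\t", index=False)
    mdm = table.attrs["min_detectable_maf"]
    power, se = design.fisher_power(
        0.1, 0.1 + cfg.differential_effect,
        int(cfg.mean_depth_low), int(cfg.mean_depth_high),
        cfg.alpha_pools, n_reps=1000, seed=cfg.seed)
    summary = pd.DataFrame([{
        "min_detectable_maf": mdm,
        "min_detectable_maf_pct": round(100 * mdm, 1),
        "power_at_planted_effect": power,
        "power_mc_se": se,
    }])
    summary.to_csv(out / "design_summary.tsv", sep="\t", index=False)
    return (["design.tsv", "design_summary.tsv"],
            {"grid_points": len(table)})
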