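"""End-to-end orchestration: simulate -> cluster -> repartition -> correlate -> tree-compare.

One configured, seeded run produces the cluster table, the abundance matrix and
top-cluster selection with superfamily composition, the 4-clade Venn
repartition, the species correlation dendrogram with its grouping report, the
plastome NJ tree with conflict metrics, and a machine-readable run report.
When the inputs come from the simulator the truth tables additionally yield a
scorecard (ARI against truth families, grouping-pattern and
plastid-paraphyly/asymmetry flags).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from .simulate import (Scenario, SimulationResult, default_scenario,
                       null_scenario, seq_to_str, without_fractionation)
from .simulate import simulate as run_simulation
from . import clustering as clu
from . import repartition as rep
from . import correlation as cor
from . import phylogeny as phy

log = logging.getLogger("ssapipe")

CLADES = rep.CLADES


def coverage(L: float, N: float, G: float) -> float:
    """Sequencing coverage C = L*N/G."""
    if G <= 0:
        raise ValueError("G must be > 0")
    if L < 0 or N < 0:
        raise ValueError("L and N must be >= 0")
    return L * N / G


@dataclass
class PipelineConfig:
    """All knobs of a run; ``seed`` is mandatory and drives every random stream."""

    seed: int
    scenario: str = "default"            # "default", "null", or a scenario YAML path
    output_dir: str | None = None
    write_reads: bool = False
    # clustering
    min_read_length: int = 45
    identity_threshold: float = clu.IDENTITY_THRESHOLD
    min_overlap_frac: float = clu.MIN_OVERLAP_FRAC
    kmer_size: int = clu.KMER_SIZE
    min_shared_kmers: int = clu.MIN_SHARED_KMERS
    min_cluster_size: int = clu.MIN_CLUSTER_SIZE
    max_reads_per_species: int | None = 1000   # clustering subsample cap
    # repartition
    top_fraction: float = 0.5
    min_reads: int = 1
    min_species: int = 1
    # correlation
    transform: str = "log1p_normalized"
    linkage_method: str = "average"
    # plastome tree
    distance_model: str = "jc69"
    bootstrap_replicates: int = 0
    outgroup: str = "Out1"
    # scenario scaling (the defaults are the study conditions)
    species_per_clade: int = 4
    size_scale: float = 1.0

    def validate(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold out of range")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction out of range")
        if not (0 <= self.min_overlap_frac <= 1):
            raise ValueError("min_overlap_frac out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything a run computed, recomputable from the emitted TSVs."""

    report: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


@dataclass
class RunResult:
    config: PipelineConfig
    simulation: SimulationResult
    cluster_table: "clu.ClusterTable"
    matrix: "rep.AbundanceMatrix"
    top: list
    partition: "rep.CladePartition"
    corr: "cor.CorrelationMatrix"
    dendro: "cor.Dendrogram"
    grouping: dict
    plastome_tree: "object"
    report: RunReport


def _load_scenario(cfg: PipelineConfig) -> Scenario:
    if cfg.scenario == "default":
        return default_scenario(cfg.species_per_clade, cfg.size_scale)
    if cfg.scenario in ("null", "no_hybridization"):
        return null_scenario(max(2, cfg.species_per_clade - 1), cfg.size_scale)
    if cfg.scenario == "no_fractionation":
        return without_fractionation(
            default_scenario(cfg.species_per_clade, cfg.size_scale))
    return Scenario.from_yaml(cfg.scenario)


class _stage:
    """Names the failing stage in errors and logs stage timing; partial outputs
    written before the failure are retained on disk."""

    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            log.error("stage %s failed: %s", self.name, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", self.name, time.time() - self.t0)
        return False


def run(cfg: PipelineConfig) -> RunResult:
    """Execute all stages; identical (config, seed) gives identical reports."""
    cfg.validate()
    outdir = cfg.output_dir
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    with _stage("simulate"):
        scenario = _load_scenario(cfg)
        simulation = run_simulation(scenario, cfg.seed)
        if outdir:
            scenario.to_yaml(os.path.join(outdir, "scenario.yaml"))
            simulation.write_outputs(outdir, write_reads=cfg.write_reads)

    # ---- clustering -------------------------------------------------------
    with _stage("cluster"):
        pooled: list[tuple[str, str]] = []
        for sp in sorted(simulation.reads):
            rs = simulation.reads[sp]
            cap = cfg.max_reads_per_species or len(rs)
            pooled.extend(zip(rs.read_ids[:cap], rs.sequences[:cap]))
        pooled = clu.filter_reads(pooled, cfg.min_read_length)
        graph = clu.build_similarity_graph(
            pooled, identity_threshold=cfg.identity_threshold,
            min_overlap_frac=cfg.min_overlap_frac, k=cfg.kmer_size,
            min_shared_kmers=cfg.min_shared_kmers)
        table = clu.cluster_reads(graph, min_cluster_size=cfg.min_cluster_size)
        seqs_by_id = dict(pooled)
        index = clu.LibraryIndex(simulation.library)
        table = clu.classify_clusters(table, seqs_by_id, index)
    if outdir:
        table.write_tsv(os.path.join(outdir, "cluster_table.tsv"))
        table.summary().to_csv(os.path.join(outdir, "cluster_summary.tsv"),
                               sep="\t", index=False)

    # ---- repartition ------------------------------------------------------
    with _stage("repartition"):
        matrix = rep.abundance_matrix(table)
        top = rep.select_top_clusters(matrix, cfg.top_fraction)
        focal_species = sorted(sp for sp, cl in scenario.clade_map.items()
                               if cl in CLADES)
        presence = rep.clade_presence(matrix, scenario.clade_map, top,
                                      min_reads=cfg.min_reads,
                                      min_species=cfg.min_species)
        partition = rep.venn_partition(presence)
        superfamily_counts: dict[str, int] = {}
        for cid in top:
            label = table.superfamilies.get(int(cid), "unknown")
            superfamily_counts[label] = superfamily_counts.get(label, 0) + 1
    if outdir:
        matrix.write_tsv(os.path.join(outdir, "abundance.tsv"))
        partition.write_tsv(os.path.join(outdir, "venn.tsv"))

    # ---- correlation dendrogram ------------------------------------------
    with _stage("correlate"):
        corr = cor.correlation_matrix(matrix, top, transform=cfg.transform,
                                      species=[s for s in focal_species
                                               if s in matrix.counts.columns])
        dendro = cor.hierarchical_cluster(corr, method=cfg.linkage_method)
        grouping = cor.grouping_check(dendro, scenario.clade_map)
        newick = cor.dendrogram_to_newick(dendro)
    if outdir:
        corr.write_tsv(os.path.join(outdir, "correlation.tsv"))
        with open(os.path.join(outdir, "repeat_dendrogram.nwk"), "w") as fh:
            fh.write(newick + "\n")

    # ---- plastome tree and conflict --------------------------------------
    with _stage("plastree"):
        aln = {spp: seq_to_str(p) for spp, p in simulation.plastomes.items()}
        if cfg.bootstrap_replicates > 0:
            ptree = phy.bootstrap_support(aln, B=cfg.bootstrap_replicates,
                                          seed=cfg.seed, model=cfg.distance_model)
        else:
            ptree = phy.neighbor_joining(
                phy.plastome_distances(aln, model=cfg.distance_model))
        conflict = _conflict_report(ptree, newick, scenario, cfg)
    if outdir:
        with open(os.path.join(outdir, "plastome_tree.nwk"), "w") as fh:
            fh.write(ptree.as_string(schema="newick"))

    # ---- report -----------------------------------------------------------
    n_reads_total = int(sum(len(r) for r in simulation.reads.values()))
    report = RunReport({
        "provenance": {
            "seed": cfg.seed,
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "scenario": cfg.scenario,
        },
        "reads": {
            "total_simulated": n_reads_total,
            "clustered_input": len(pooled),
            "clustered": int(len(table.assignments)),
            "unclustered": len(table.unclustered),
        },
        "clusters": {
            "n_clusters": int(table.n_clusters),
            "top_count": len(top),
            "top_fraction_requested": cfg.top_fraction,
            "top_fraction_attained": float(
                matrix.cluster_totals().loc[top].sum() / matrix.grand_total),
            "superfamily_composition_top": dict(sorted(superfamily_counts.items())),
        },
        "venn": partition.to_dict(),
        "grouping": {
            "clade_coherence": grouping["clade_coherence"],
            "deep_split_pairs": grouping["deep_split_pairs"],
            "all_coherent": grouping["all_coherent"],
        },
        "conflict": conflict,
    })
    scorecard = verify_report(report.report, simulation, table)
    report.report["scorecard"] = scorecard
    if outdir:
        report.write(os.path.join(outdir, "report.json"))
    return RunResult(cfg, simulation, table, matrix, top, partition, corr,
                     dendro, grouping, ptree, report)


def _conflict_report(ptree, repeat_newick: str, scenario, cfg: PipelineConfig) -> dict:
    import dendropy

    clade_map = scenario.clade_map
    leaves = {lf.taxon.label for lf in ptree.leaf_node_iter()}
    by_clade = {c: [sp for sp in leaves if clade_map.get(sp) == c] for c in CLADES}
    og = cfg.outgroup if cfg.outgroup in leaves else None
    bambuseae_oly = by_clade["Olyreae"] + by_clade["NWB"] + by_clade["PWB"]
    woody = by_clade["Arundinarieae"] + by_clade["NWB"] + by_clade["PWB"]
    out: dict = {
        "plastid_olyreae_bambuseae_monophyletic": bool(
            phy.is_monophyletic(ptree, bambuseae_oly, outgroup=og)),
        "plastid_woody_monophyletic": bool(
            phy.is_monophyletic(ptree, woody, outgroup=og)),
    }
    out["plastid_paraphyly_of_woody"] = (
        out["plastid_olyreae_bambuseae_monophyletic"]
        and not out["plastid_woody_monophyletic"])
    ptree_c = phy.clade_collapsed_tree(ptree, clade_map, CLADES)
    rtree = dendropy.Tree.get(data=repeat_newick, schema="newick")
    rtree_c = phy.clade_collapsed_tree(rtree, clade_map, CLADES)
    if ptree_c is None or rtree_c is None:
        out["rf_clade_collapsed"] = None
    else:
        out["rf_clade_collapsed"] = int(phy.robinson_foulds(ptree_c, rtree_c))
    return out


def verify_report(report: dict, simulation, table) -> dict:
    """Scorecard tying the run to the simulation truth: ARI of clusters vs truth
    families (clustered reads only), grouping-pattern match, plastid paraphyly,
    and the Venn asymmetry ordering of exclusive pairwise shared-cluster counts."""
    truth = {}
    for sp, rs in simulation.reads.items():
        for rid, fid in zip(rs.read_ids, rs.family_ids):
            truth[rid] = fid
    assigned = table.assignments
    t_labels = [truth[r] for r in assigned["read_id"]]
    # family recovery is scored on reads that belong to a truth family;
    # clustered background reads (homologous low-copy loci) are counted but
    # cannot meaningfully agree with any family partition
    fam_mask = [t != "background" for t in t_labels]
    fam_truth = [t for t, m in zip(t_labels, fam_mask) if m]
    fam_cluster = [c for c, m in zip(assigned["cluster_id"], fam_mask) if m]
    ari = float(adjusted_rand_score(fam_truth, fam_cluster)) if fam_truth else float("nan")
    ari_with_bg = float(adjusted_rand_score(t_labels, assigned["cluster_id"].tolist())) \
        if len(assigned) else float("nan")

    pairs = report["grouping"]["deep_split_pairs"]
    grouping_match = (
        report["grouping"]["all_coherent"]
        and sorted(map(sorted, pairs)) == sorted(map(sorted, [
            ["NWB", "Olyreae"], ["Arundinarieae", "PWB"]]))
    )
    regions = report["venn"]["regions"]

    def excl(a, b):
        return regions.get("+".join(sorted((a, b), key=CLADES.index)), 0)

    oly_nwb = excl("Olyreae", "NWB")
    oly_aru = excl("Olyreae", "Arundinarieae")
    oly_pwb = excl("Olyreae", "PWB")
    aru_pwb = excl("Arundinarieae", "PWB")
    aru_nwb = excl("Arundinarieae", "NWB")
    nwb_pwb = excl("NWB", "PWB")
    venn_flags = {
        "oly_nwb_gt_oly_aru": oly_nwb > oly_aru,
        "aru_pwb_gt_aru_nwb": aru_pwb > aru_nwb,
        "oly_pwb_minimal": oly_pwb <= min(oly_nwb, oly_aru, aru_pwb, aru_nwb, nwb_pwb),
        "totals_conserved": all(
            report["venn"]["per_clade_totals"][c]
            == sum(n for reg, n in regions.items() if c in reg.split("+"))
            for c in CLADES),
    }
    return {
        "ari_vs_truth": ari,
        "ari_including_background": ari_with_bg,
        "background_reads_clustered": int(len(fam_mask) - sum(fam_mask)),
        "grouping_pattern_match": bool(grouping_match),
        "plastid_paraphyly": bool(report["conflict"]["plastid_paraphyly_of_woody"]),
        "venn_asymmetry": venn_flags,
        "exclusive_pairs": {
            "Olyreae+NWB": oly_nwb, "Olyreae+Arundinarieae": oly_aru,
            "Olyreae+PWB": oly_pwb, "Arundinarieae+PWB": aru_pwb,
            "Arundinarieae+NWB": aru_nwb, "NWB+PWB": nwb_pwb,
        },
    }
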