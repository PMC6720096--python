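"""End-to-end orchestration of one disease-network study.

One run takes a background network, a seed list and two validated
miRNA→target tables (either from files or from the synthetic generator),
and executes every stage in dependency order:

build triple → degree/hub analysis of the background → null-calibrated
clustering and small-worldness of the expanded network → per-node Z-scores →
communities and backbone → miRNA intersection, bipartite projection, pattern
counts, coverage/core selection → simplified core-regulator network.

Every stage writes a plain-text artifact (edge list, TSV, JSON report) into
the run directory, and a deterministic ``manifest.json`` records the
configuration, seed, package version and stage outputs.  Wall-clock timings
go to ``run.log`` only, so a rerun with an identical configuration is
byte-identical outside that log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__, build, io, mirna, synthetic, topology

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "netregmir_run"
    # either a synthetic study ...
    synthetic: synthetic.SyntheticConfig | None = None
    # ... or user-supplied files
    background_path: str | None = None
    seeds_path: str | None = None
    regulations_a_path: str | None = None
    regulations_b_path: str | None = None

    n_null: int = 1000
    null_mode: str = "degree"          # "degree" or "size"
    hub_tol: float = 0.05
    coverage_threshold: float = 0.9
    key_mirna_count: int = 20
    backbone_percentile: float = 90.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None:
            for name in ("background_path", "seeds_path",
                         "regulations_a_path", "regulations_b_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when no synthetic config given")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file: {p}")


@dataclass
class SimplifiedNetwork:
    """Core regulators, key (backbone) proteins and the links among them."""

    core_mirnas: list[str]
    key_proteins: list[str]
    regulation_links: list[tuple[str, str]]
    protein_edges: list[tuple[str, str]]
    annotation: dict[str, str]          # directly-regulated | indirectly-regulated | unregulated


def simplified_network_report(backbone: topology.BackboneReport,
                              core: list[str],
                              bip: mirna.BipartiteRegulation,
                              net: nx.Graph) -> SimplifiedNetwork:
    """Assemble the core-miRNA × key-protein network with per-protein status.

    A key protein is *directly-regulated* iff some core miRNA targets it;
    *indirectly-regulated* iff it is not targeted but is the untargeted
    middle of a pattern-C path of some core miRNA; otherwise *unregulated*.
    """
    if not backbone.backbone:
        raise ValueError("empty backbone")
    key = list(backbone.backbone)
    key_set = set(key)
    direct: set[str] = set()
    indirect: set[str] = set()
    links = []
    for m in sorted(core):
        targets = bip.targets_of(m)
        direct |= targets & key_set
        links.extend((m, p) for p in sorted(targets & key_set))
        indirect |= mirna._indirect_middles(net, targets) & key_set
    annotation = {}
    for p in key:
        if p in direct:
            annotation[p] = "directly-regulated"
        elif p in indirect:
            annotation[p] = "indirectly-regulated"
        else:
            annotation[p] = "unregulated"
    edges = sorted(tuple(sorted(e)) for e in net.subgraph(key_set).edges)
    return SimplifiedNetwork(core_mirnas=sorted(core), key_proteins=sorted(key),
                             regulation_links=sorted(links),
                             protein_edges=edges, annotation=annotation)


def _load_inputs(config: RunConfig, out: Path):
    if config.synthetic is not None:
        study = synthetic.generate(config.synthetic)
        io.write_network(study.background, out / "background.tsv")
        (out / "seeds.txt").write_text("".join(s + "\n" for s in study.seeds))
        io.write_regulations(study.table_a, out / "regulations_a.tsv")
        io.write_regulations(study.table_b, out / "regulations_b.tsv")
        io.write_report(study.truth, out / "ground_truth.json")
        return study.background, study.seeds, study.table_a, study.table_b, study.truth
    background = io.read_edge_list(config.background_path)
    seeds = [ln.strip() for ln in Path(config.seeds_path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    table_a = io.read_regulations(config.regulations_a_path)
    table_b = io.read_regulations(config.regulations_b_path)
    return background, seeds, table_a, table_b, None


def run_full(config: RunConfig) -> Path:
    """Execute the whole study; returns the run directory.

    Any stage failure aborts the run with the stage name and cause.  The run
    is a pure function of the configuration (including ``rng_seed``): rerun
    output is byte-identical apart from ``run.log``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest_stages: list[dict] = []
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        dt = time.perf_counter() - t0
        log_lines.append(f"{name}: OK ({dt:.2f}s)")
        manifest_stages.append({"stage": name, "status": "OK",
                                "outputs": sorted(outputs)})

    def s_inputs():
        (state["background"], state["seeds"], state["table_a"],
         state["table_b"], state["truth"]) = _load_inputs(config, out)
        return (["background.tsv", "seeds.txt", "regulations_a.tsv",
                 "regulations_b.tsv", "ground_truth.json"]
                if config.synthetic is not None else [])

    def s_build():
        triple = build.build_triple(state["background"], state["seeds"])
        state["triple"] = triple
        io.write_network(triple.basic, out / "basic.tsv")
        io.write_network(triple.expanded, out / "expanded.tsv")
        io.write_report({
            "background_nodes": triple.background.number_of_nodes(),
            "background_edges": triple.background.number_of_edges(),
            "basic_nodes": triple.basic.number_of_nodes(),
            "basic_edges": triple.basic.number_of_edges(),
            "basic_isolates": sum(1 for _ in nx.isolates(triple.basic)),
            "expanded_nodes": triple.expanded.number_of_nodes(),
            "expanded_edges": triple.expanded.number_of_edges(),
            "missing_seeds": triple.missing_seeds,
        }, out / "build_report.json")
        return ["basic.tsv", "expanded.tsv", "build_report.json"]

    def s_hubs():
        bg = state["background"]
        ranking = topology.rank_by_degree(bg)
        curve = topology.connectivity_curve(bg, ranking)
        hubs = topology.identify_hubs(curve, tol=config.hub_tol)
        state["hubs"] = hubs
        dist = topology.degree_distribution(bg)
        pd.DataFrame({"k": curve.k, "r": curve.r}).to_csv(
            out / "connectivity_curve.tsv", sep="\t", index=False)
        io.write_report({"cutoff_k": hubs.cutoff_k, "hubs": hubs.hubs,
                         "stabilization_tol": hubs.stabilization_tol,
                         "r_full": curve.r_full,
                         "degree_loglog_slope": dist.loglog_slope},
                        out / "hub_report.json")
        return ["connectivity_curve.tsv", "hub_report.json"]

    def s_null_stats():
        bg, expanded = state["background"], state["triple"].expanded
        nulls = topology.sample_degree_matched_null(
            bg, expanded, config.n_null, config.rng_seed, mode=config.null_mode)
        c_obs = topology.transitivity(expanded)
        c_null = [topology.transitivity(g) for g in nulls]
        percentile, ks_p = topology.compare_to_null(c_obs, c_null)
        sw = topology.small_worldness(expanded, nulls)
        state["smallworld"] = sw
        io.write_report({"clustering_observed": c_obs,
                         "clustering_null_mean": float(pd.Series(c_null).mean()),
                         "empirical_percentile": percentile, "ks_p": ks_p,
                         "n_null": config.n_null, "null_mode": config.null_mode,
                         "small_worldness": sw}, out / "null_report.json")
        return ["null_report.json"]

    def s_zscores():
        records = topology.z_scores_for_network(state["triple"].expanded,
                                                state["background"])
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            out / "zscores.tsv", sep="\t", index=False)
        return ["zscores.tsv"]

    def s_communities():
        expanded = state["triple"].expanded
        part = topology.detect_communities(expanded)
        backbone = topology.extract_backbone(
            expanded, part, state["hubs"],
            degree_percentile=config.backbone_percentile)
        state["partition"], state["backbone"] = part, backbone
        io.write_report({"modularity_q": part.modularity_q,
                         "n_communities": len(part.communities()),
                         "community_sizes": [len(c) for c in part.communities()]},
                        out / "community_report.json")
        io.write_report({"community_hubs": backbone.community_hubs,
                         "backbone": backbone.backbone,
                         "covered": sorted(backbone.covered),
                         "uncovered": sorted(backbone.uncovered)},
                        out / "backbone_report.json")
        return ["community_report.json", "backbone_report.json"]

    def s_mirna():
        expanded = state["triple"].expanded
        inter = mirna.intersect_regulations(state["table_a"], state["table_b"])
        bip = mirna.build_bipartite(inter, expanded)
        state["bip"] = bip
        counts = mirna.count_patterns(bip, expanded)
        frac = mirna.coregulated_edge_fraction(counts, expanded)
        core = mirna.select_core(bip, expanded,
                                 threshold=config.coverage_threshold)
        state["core"] = core
        k = min(config.key_mirna_count, len(bip.mirnas))
        key_mirnas, key_cov = mirna.rank_key_mirnas(bip, expanded, k)
        rows = pd.DataFrame({
            "mirna": sorted(bip.mirnas),
            "n_targets": [len(bip.targets_of(m)) for m in sorted(bip.mirnas)],
            "pattern_a": [counts.count_a[m] for m in sorted(bip.mirnas)],
            "pattern_b": [counts.count_b[m] for m in sorted(bip.mirnas)],
            "pattern_c": [counts.count_c[m] for m in sorted(bip.mirnas)],
        })
        rows.to_csv(out / "pattern_counts.tsv", sep="\t", index=False)
        io.write_report({
            "intersected_records": len(inter),
            "bipartite_mirnas": len(bip.mirnas),
            "bipartite_proteins": len(bip.proteins),
            "bipartite_links": len(bip.links),
            "pattern_totals": counts.totals(),
            "coregulated_edge_fraction": frac,
            "key_mirnas": key_mirnas, "key_mirna_coverage": key_cov,
            "core_direct": {"size": len(core["direct"].core_set),
                            "mirnas": core["direct"].core_set,
                            "reached": core["direct"].reached},
            "core_all_patterns": {"size": len(core["direct+indirect"].core_set),
                                  "mirnas": core["direct+indirect"].core_set,
                                  "reached": core["direct+indirect"].reached},
            "coverage_threshold": config.coverage_threshold,
            "universe_size": core["direct"].universe_size,
        }, out / "mirna_report.json")
        return ["pattern_counts.tsv", "mirna_report.json"]

    def s_simplified():
        simple = simplified_network_report(
            state["backbone"], state["core"]["direct+indirect"].core_set,
            state["bip"], state["triple"].expanded)
        io.write_report(simple, out / "simplified_network.json")
        return ["simplified_network.json"]

    stage("inputs", s_inputs)
    stage("build", s_build)
    stage("hubs", s_hubs)
    stage("null_stats", s_null_stats)
    stage("zscores", s_zscores)
    stage("communities", s_communities)
    stage("mirna", s_mirna)
    stage("simplified", s_simplified)

    manifest = {
        "tool": "netregmir", "version": __version__,
        "rng_seed": config.rng_seed,
        "config": io._jsonable(config),
        "stages": manifest_stages,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "run.log").write_text("".join(ln + "\n" for ln in log_lines))
    return out
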