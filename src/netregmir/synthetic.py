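"""Synthetic study systems with planted ground truth.

The generator emulates the statistical structure a disease-network analysis
assumes, at desk scale:

* a scale-free background grown by preferential attachment (single-edge
  seed, ``attach_m`` stubs per new node);
* a planted disease module — a node subset densified with uniform internal
  edges until a target internal density — standing in for the empirical
  tendency of disease proteins to interact;
* planted hubs whose mutual links are suppressed: each receives extra stubs
  to uniformly chosen non-hub nodes and any hub–hub edge is removed,
  reproducing the connectivity signature that relative-subgraph-connectivity
  hub detection exploits;
* seed lists mixing module members with off-module "isolate" seeds;
* two overlapping, noisy miRNA→target tables whose per-miRNA target sets
  grow along network neighborhoods (targets of one regulator tend to
  interact), with a few planted core regulators holding target sets an order
  of magnitude larger.

Everything is a pure function of the configuration's ``rng_seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .mirna import RegulationTable

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic instance.

    Defaults describe a 2,000-protein background with a 60-protein module,
    five suppressed-link hubs, a 60-seed list with 40% off-module seeds, and
    120 miRNAs (5 of them core) averaging 8 validated targets each, reported
    by two databases with expected Jaccard overlap 0.8.
    """

    n_background: int = 2000
    attach_m: int = 2
    module_size: int = 60
    module_density: float = 0.25
    hub_count: int = 5
    hub_degree_boost: int = 150
    seed_count: int = 60
    seed_isolate_fraction: float = 0.4
    n_mirnas: int = 120
    targets_per_mirna: float = 8.0
    neighbor_bias: float = 0.5
    table_overlap: float = 0.8
    core_mirna_count: int = 5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.module_size >= self.n_background:
            raise ValueError("module_size must be smaller than n_background")
        for name in ("module_density", "seed_isolate_fraction",
                     "neighbor_bias", "table_overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.module_size and not 0 < self.module_density <= 1:
            raise ValueError("module_density must lie in (0, 1]")


@dataclass
class GroundTruth:
    module_members: set[str] = field(default_factory=set)
    planted_hubs: set[str] = field(default_factory=set)
    core_mirnas: set[str] = field(default_factory=set)


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def _mirna_id(i: int) -> str:
    return f"mir-{i:04d}"


def _stage_rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, stage)))


def generate_background(cfg: SyntheticConfig) -> tuple[nx.Graph, GroundTruth]:
    """Grow the background and plant module and hubs.

    Growth is preferential attachment from a single edge; each new node
    attaches ``attach_m`` stubs to distinct existing nodes drawn with
    probability proportional to degree, so an n-node instance has
    1 + attach_m·(n−2) edges (fewer stubs while the graph is smaller than
    attach_m).  Hubs are chosen after growth (their identity is independent
    of attachment luck), stripped of any mutual edge, and boosted with
    ``hub_degree_boost`` stubs to uniform non-hub nodes.  The module is a
    hub-disjoint node subset densified with uniform internal edges until its
    internal density reaches ``module_density``.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 0)
    n = cfg.n_background
    if n < 2:
        raise ValueError("need at least 2 background nodes")

    # --- preferential attachment over integer labels -----------------------
    stubs = [0, 1]                      # node index repeated once per degree
    edges: set[tuple[int, int]] = {(0, 1)}
    for new in range(2, n):
        m = min(cfg.attach_m, new)
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(stubs[int(rng.integers(len(stubs)))])
        for u in sorted(chosen):
            edges.add((u, new) if u < new else (new, u))
            stubs.append(u)
        stubs.extend([new] * m)

    net = nx.Graph(name="background")
    net.add_nodes_from(_protein_id(i) for i in range(n))
    net.add_edges_from((_protein_id(a), _protein_id(b)) for a, b in sorted(edges))

    # --- plant module then hubs (disjoint sets) ----------------------------
    module_idx = sorted(rng.choice(n, size=cfg.module_size, replace=False).tolist()) \
        if cfg.module_size else []
    module = [_protein_id(i) for i in module_idx]
    non_module = sorted(set(range(n)) - set(module_idx))
    if cfg.hub_count > len(non_module):
        raise ValueError("hub_count exceeds available non-module nodes")
    hub_idx = sorted(rng.choice(len(non_module), size=cfg.hub_count,
                                replace=False).tolist()) if cfg.hub_count else []
    hubs = [_protein_id(non_module[i]) for i in hub_idx]
    hub_set = set(hubs)

    # suppressed hub-hub links: drop any mutual edge, then boost degrees
    net.remove_edges_from([(u, v) for u, v in net.edges
                           if u in hub_set and v in hub_set])
    others = sorted(set(net.nodes) - hub_set)
    for h in hubs:
        attached = 0
        forbidden = set(net.neighbors(h))
        while attached < cfg.hub_degree_boost:
            tgt = others[int(rng.integers(len(others)))]
            if tgt in forbidden or tgt == h:
                continue
            net.add_edge(h, tgt)
            forbidden.add(tgt)
            attached += 1

    # densify the module to the target internal density
    if module:
        if cfg.module_density > 1:
            raise ValueError("module_density above 1 is infeasible")
        pairs = [(module[i], module[j])
                 for i in range(len(module)) for j in range(i + 1, len(module))]
        needed = math.ceil(cfg.module_density * len(pairs))
        internal = sum(1 for u, v in pairs if net.has_edge(u, v))
        free = [p for p in pairs if not net.has_edge(*p)]
        order = rng.permutation(len(free))
        for k in order:
            if internal >= needed:
                break
            net.add_edge(*free[int(k)])
            internal += 1

    truth = GroundTruth(module_members=set(module), planted_hubs=hub_set)
    logger.info("generate_background: %d nodes, %d edges, %d module members, "
                "%d planted hubs", net.number_of_nodes(), net.number_of_edges(),
                len(module), len(hubs))
    return net, truth


def sample_seed_list(net: nx.Graph, truth: GroundTruth,
                     cfg: SyntheticConfig) -> list[str]:
    """Seed list mixing module members and off-module nodes.

    ⌈seed_count·(1−seed_isolate_fraction)⌉ seeds come from the planted
    module, the remainder uniformly from non-module nodes; no duplicates.
    """
    cfg.validate()
    if cfg.seed_count > net.number_of_nodes():
        raise ValueError("seed_count exceeds network size")
    rng = _stage_rng(cfg, 1)
    n_module = math.ceil(cfg.seed_count * (1.0 - cfg.seed_isolate_fraction))
    module = sorted(truth.module_members)
    if n_module > len(module):
        raise ValueError(f"module has {len(module)} members, "
                         f"{n_module} module seeds requested")
    outside = sorted(set(net.nodes) - truth.module_members)
    n_out = cfg.seed_count - n_module
    if n_out > len(outside):
        raise ValueError("not enough non-module nodes for isolate seeds")
    seeds = [module[i] for i in rng.choice(len(module), size=n_module, replace=False)]
    seeds += [outside[i] for i in rng.choice(len(outside), size=n_out, replace=False)]
    return sorted(seeds)


def _grow_target_set(net: nx.Graph, nodes: list[str], size: int,
                     bias: float, rng: np.random.Generator) -> set[str]:
    """One miRNA's target set: neighborhood growth with escape probability."""
    targets: set[str] = set()
    first = nodes[int(rng.integers(len(nodes)))]
    targets.add(first)
    while len(targets) < size:
        frontier = sorted(set().union(*(set(net.neighbors(t)) for t in targets))
                          - targets)
        if rng.random() < bias:
            if not frontier:
                break                  # bias=1 keeps the induced subgraph connected
            targets.add(frontier[int(rng.integers(len(frontier)))])
        else:
            pool = sorted(set(nodes) - targets)
            if not pool:
                break
            targets.add(pool[int(rng.integers(len(pool)))])
    return targets


def generate_regulations(net: nx.Graph, cfg: SyntheticConfig
                         ) -> tuple[RegulationTable, RegulationTable, GroundTruth]:
    """Two overlapping validated-target tables plus the core-miRNA truth.

    Target-set sizes are Poisson around ``targets_per_mirna`` (truncated at
    1); core miRNAs draw around 10× that mean.  Table B is table A with each
    record kept with probability q = 2J/(1+J) and every dropped record
    replaced by a fresh random pair, which gives expected Jaccard J =
    ``table_overlap`` between the tables.
    """
    cfg.validate()
    if cfg.n_mirnas <= 0:
        raise ValueError("n_mirnas must be positive")
    if cfg.core_mirna_count > cfg.n_mirnas:
        raise ValueError("core_mirna_count exceeds n_mirnas")
    rng = _stage_rng(cfg, 2)
    nodes = sorted(net.nodes)
    mirnas = [_mirna_id(i) for i in range(cfg.n_mirnas)]
    core = set(mirnas[i] for i in rng.choice(cfg.n_mirnas, size=cfg.core_mirna_count,
                                             replace=False))
    table_a = RegulationTable()
    for m in mirnas:
        mean = cfg.targets_per_mirna * (10.0 if m in core else 1.0)
        size = max(1, int(rng.poisson(mean)))
        size = min(size, len(nodes))
        for t in sorted(_grow_target_set(net, nodes, size, cfg.neighbor_bias, rng)):
            table_a.add(m, t, "dbA")

    j = cfg.table_overlap
    q = 1.0 if j >= 1 else 2.0 * j / (1.0 + j)
    table_b = RegulationTable()
    dropped = 0
    for m, t in sorted(table_a.pairs):
        if rng.random() < q:
            table_b.add(m, t, "dbB")
        else:
            dropped += 1
    taken = table_a.pairs | table_b.pairs
    while dropped > 0:
        m = mirnas[int(rng.integers(len(mirnas)))]
        t = nodes[int(rng.integers(len(nodes)))]
        if (m, t) in taken:
            continue
        table_b.add(m, t, "dbB")
        taken.add((m, t))
        dropped -= 1
    return table_a, table_b, GroundTruth(core_mirnas=core)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    background: nx.Graph
    seeds: list[str]
    table_a: RegulationTable
    table_b: RegulationTable
    truth: GroundTruth


def generate(cfg: SyntheticConfig) -> SyntheticStudy:
    """Generate one full synthetic study instance under ``cfg.rng_seed``."""
    net, truth = generate_background(cfg)
    seeds = sample_seed_list(net, truth, cfg)
    table_a, table_b, reg_truth = generate_regulations(net, cfg)
    truth.core_mirnas = reg_truth.core_mirnas
    return SyntheticStudy(config=cfg, background=net, seeds=seeds,
                          table_a=table_a, table_b=table_b, truth=truth)
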