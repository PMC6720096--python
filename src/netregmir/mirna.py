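"""miRNA regulation layer over a protein interaction network.

A validated miRNA→target table is intersected across two source databases,
projected onto a disease network as a bipartite regulation graph, and then
analysed for three elementary regulation motifs on the protein network:

* **pattern A** (co-regulation): one miRNA targets both endpoints of a PPI
  edge;
* **pattern B** (full mediation): one miRNA targets all three proteins of a
  length-2 interaction path u–w–v;
* **pattern C** (indirect mediation): one miRNA targets the two endpoints
  u, v of a length-2 path but not the middle protein w, which is thereby
  indirectly reachable by the regulator.

Length-2 paths are unordered (u–w–v ≡ v–w–u, u ≠ v); whether u and v are
themselves adjacent does not affect the classification, so a triangle
contributes three distinct paths.  Key/core regulators are selected by greedy
set cover of the regulated-protein universe, the standard reproducible
surrogate for the NP-hard exact cover.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)


class RegulationTable:
    """A set of validated (miRNA, target) records with optional source tags.

    The unordered record identity is the (mirna, target) pair; duplicate rows
    collapse, merging their source tags.
    """

    def __init__(self, pairs=(), sources: dict | None = None):
        self.pairs: set[tuple[str, str]] = set(pairs)
        self.sources: dict[tuple[str, str], frozenset[str]] = dict(sources or {})

    def add(self, mirna: str, target: str, source: str | None = None) -> None:
        key = (mirna, target)
        self.pairs.add(key)
        if source:
            self.sources[key] = self.sources.get(key, frozenset()) | {source}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def __eq__(self, other) -> bool:
        return isinstance(other, RegulationTable) and self.pairs == other.pairs

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}

    def targets_of(self, mirna: str) -> set[str]:
        return {t for m, t in self.pairs if m == mirna}


@dataclass
class BipartiteRegulation:
    """Bipartite miRNA→protein regulation restricted to one protein network."""

    mirnas: set[str]
    proteins: set[str]
    links: set[tuple[str, str]]

    def targets_of(self, mirna: str) -> set[str]:
        return {p for m, p in self.links if m == mirna}

    def regulators_of(self, protein: str) -> set[str]:
        return {m for m, p in self.links if p == protein}

    def target_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {m: set() for m in self.mirnas}
        for m, p in self.links:
            out[m].add(p)
        return out


@dataclass
class PatternCounts:
    """Per-miRNA motif counts, plus the aggregate co-regulated edge set."""

    count_a: dict[str, int]
    count_b: dict[str, int]
    count_c: dict[str, int]
    coregulated_edges: set[tuple[str, str]]
    listings: dict[str, dict] | None = None

    def totals(self) -> dict[str, int]:
        return {"A": sum(self.count_a.values()),
                "B": sum(self.count_b.values()),
                "C": sum(self.count_c.values())}


@dataclass
class CoverageCurve:
    """Greedy regulator-selection curve over a protein universe."""

    order: list[str]
    fractions: list[float]
    mode: str
    threshold: float
    core_set: list[str]
    reached: bool
    universe_size: int
    covered: set[str] = field(default_factory=set)


def intersect_regulations(table_a: RegulationTable,
                          table_b: RegulationTable) -> RegulationTable:
    """Records whose (miRNA, target) pair occurs in both tables; sources merged."""
    pairs = table_a.pairs & table_b.pairs
    sources = {}
    for key in pairs:
        merged = table_a.sources.get(key, frozenset()) | table_b.sources.get(key, frozenset())
        if merged:
            sources[key] = merged
    if not pairs:
        logger.warning("intersect_regulations: empty intersection")
    return RegulationTable(pairs, sources)


def build_bipartite(regs: RegulationTable, net: nx.Graph) -> BipartiteRegulation:
    """Project a regulation table onto a protein network.

    Links whose target is absent from ``net`` are dropped, as are miRNAs left
    with no surviving link; both counts are logged.
    """
    nodes = set(net.nodes)
    links = {(m, t) for m, t in regs.pairs if t in nodes}
    mirnas = {m for m, _ in links}
    dropped_links = len(regs.pairs) - len(links)
    dropped_mirnas = len(regs.mirnas) - len(mirnas)
    if dropped_links:
        logger.info("build_bipartite: dropped %d links (target not in network), "
                    "%d miRNAs left without targets", dropped_links, dropped_mirnas)
    if not links:
        logger.warning("build_bipartite: no regulation link maps into the network")
    return BipartiteRegulation(mirnas=mirnas,
                               proteins={t for _, t in links},
                               links=links)


def _indirect_middles(net: nx.Graph, targets: set[str]) -> set[str]:
    """Untargeted middle proteins of pattern-C paths for one target set."""
    middles = set()
    candidates = set()
    for t in targets:
        if t in net:
            candidates.update(net.neighbors(t))
    for w in candidates - targets:
        hits = 0
        for u in net.neighbors(w):
            if u in targets:
                hits += 1
                if hits >= 2:
                    middles.add(w)
                    break
    return middles


def count_patterns(bip: BipartiteRegulation, net: nx.Graph,
                   listings: bool = False) -> PatternCounts:
    """Enumerate the three regulation motifs for every miRNA.

    For a miRNA with target set T: pattern A counts the network edges with
    both endpoints in T; every unordered length-2 path u–w–v (u ≠ v) counts
    toward pattern B iff u, v, w ∈ T, and toward pattern C iff u, v ∈ T and
    w ∉ T.  A path's middle-node targeting state makes B and C mutually
    exclusive per (miRNA, path).

    With ``listings=True`` the explicit pair/triple listings per miRNA are
    attached (triples as (u, w, v) with the middle node second).
    """
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    count_c: dict[str, int] = {}
    coreg: set[tuple[str, str]] = set()
    listing: dict[str, dict] = {}

    for mirna in sorted(bip.mirnas):
        targets = bip.targets_of(mirna)
        a = b = c = 0
        pairs_a = []
        triples_b = []
        triples_c = []
        # pattern A: edges inside the target set
        for u in sorted(targets):
            if u not in net:
                continue
            for v in net.neighbors(u):
                if v in targets and u < v:
                    a += 1
                    coreg.add((u, v))
                    if listings:
                        pairs_a.append((u, v))
        # patterns B/C: for each candidate middle w, pairs of targeted neighbors
        candidates = set()
        for t in targets:
            if t in net:
                candidates.add(t)
                candidates.update(net.neighbors(t))
        for w in sorted(candidates):
            hit = sorted(u for u in net.neighbors(w) if u in targets and u != w)
            n_pairs = len(hit) * (len(hit) - 1) // 2
            if n_pairs == 0:
                continue
            if w in targets:
                b += n_pairs
                if listings:
                    triples_b.extend((hit[i], w, hit[j])
                                     for i in range(len(hit))
                                     for j in range(i + 1, len(hit)))
            else:
                c += n_pairs
                if listings:
                    triples_c.extend((hit[i], w, hit[j])
                                     for i in range(len(hit))
                                     for j in range(i + 1, len(hit)))
        count_a[mirna] = a
        count_b[mirna] = b
        count_c[mirna] = c
        if listings:
            listing[mirna] = {"pairs_a": pairs_a, "triples_b": triples_b,
                              "triples_c": triples_c}
    return PatternCounts(count_a, count_b, count_c, coreg,
                         listing if listings else None)


def coregulated_edge_fraction(counts: PatternCounts, net: nx.Graph) -> float:
    """Fraction of network edges co-regulated (pattern A) by ≥1 miRNA."""
    m = net.number_of_edges()
    if m == 0:
        logger.warning("coregulated_edge_fraction: edgeless network, undefined")
        return math.nan
    return len(counts.coregulated_edges) / m


def _cover_sets(bip: BipartiteRegulation, net: nx.Graph, mode: str,
                universe: set[str]) -> dict[str, set[str]]:
    if mode not in ("direct", "direct+indirect"):
        raise ValueError(f"unknown coverage mode: {mode!r}")
    covers = {}
    for mirna in sorted(bip.mirnas):
        targets = bip.targets_of(mirna)
        cov = set(targets)
        if mode == "direct+indirect":
            cov |= _indirect_middles(net, targets)
        covers[mirna] = cov & universe
    return covers


def coverage_curve(bip: BipartiteRegulation, net: nx.Graph,
                   mode: str = "direct", threshold: float = 0.9,
                   universe: str = "regulated") -> CoverageCurve:
    """Greedy miRNA selection until a fraction ``threshold`` of proteins is covered.

    A miRNA covers a protein directly iff it targets it; in mode
    ``direct+indirect`` additionally iff the protein is the untargeted middle
    of one of its pattern-C paths.  Each pick maximises the number of
    yet-uncovered proteins (ties broken lexicographically).  The universe is
    the regulated protein side of the bipartite object by default
    (``universe="network"`` uses every network node instead); the achieved
    denominator is always reported.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    uni = set(net.nodes) if universe == "network" else set(bip.proteins)
    covers = _cover_sets(bip, net, mode, uni)
    if not uni:
        return CoverageCurve([], [], mode, threshold, [], False, 0)

    covered: set[str] = set()
    order: list[str] = []
    fractions: list[float] = []
    remaining = dict(covers)
    while remaining:
        gains = {m: len(s - covered) for m, s in remaining.items()}
        gain = max(gains.values())
        if gain == 0:
            break
        # lexicographic tie-break: smallest ID among maximal-gain miRNAs
        best = min(m for m, g in gains.items() if g == gain)
        covered |= remaining.pop(best)
        order.append(best)
        fractions.append(len(covered) / len(uni))
        if fractions[-1] >= threshold:
            break
    reached = bool(fractions) and fractions[-1] >= threshold
    if not reached:
        logger.warning("coverage_curve: threshold %.3f unreached (%.3f after %d picks)",
                       threshold, fractions[-1] if fractions else 0.0, len(order))
    return CoverageCurve(order=order, fractions=fractions, mode=mode,
                         threshold=threshold, core_set=list(order),
                         reached=reached, universe_size=len(uni), covered=covered)


def select_core(bip: BipartiteRegulation, net: nx.Graph,
                threshold: float = 0.9, universe: str = "regulated") -> dict:
    """Core-regulator comparison: greedy cover size under direct-only
    regulation versus all three patterns, at the same coverage threshold."""
    direct = coverage_curve(bip, net, "direct", threshold, universe)
    full = coverage_curve(bip, net, "direct+indirect", threshold, universe)
    return {"direct": direct, "direct+indirect": full}


def rank_key_mirnas(bip: BipartiteRegulation, net: nx.Graph,
                    k: int, universe: str = "regulated") -> tuple[list[str], float]:
    """First ``k`` miRNAs of the greedy direct-coverage order and their joint
    coverage fraction."""
    if k < 0 or k > len(bip.mirnas):
        raise ValueError(f"k={k} outside [0, {len(bip.mirnas)}]")
    if k == 0:
        return [], 0.0
    curve = coverage_curve(bip, net, "direct", threshold=1.0, universe=universe)
    top = curve.order[:k]
    if not top:
        return [], 0.0
    fraction = curve.fractions[min(k, len(curve.fractions)) - 1]
    return top, fraction
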