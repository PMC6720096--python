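"""Single-network topology statistics.

Hub detection follows the relative-subgraph-connectivity procedure: nodes are
ranked by decreasing degree, subgraphs are induced on successive prefixes of
the ranking, and the relative connectivity r(k) — largest-component size over
prefix size — is tracked.  Because links between hubs are systematically
suppressed in biological networks, prefixes made of hubs only are poorly
connected; the hub set is the shortest prefix after which r(k) has stabilised
at the whole-network value.

Null models are degree-matched induced subgraphs of a background network: for
each node of a template network, a distinct background node of the same
background degree is drawn without replacement, and the null network is the
background subgraph induced on the draw.  These nulls calibrate the global
clustering coefficient and the small-world coefficient

    S^Δ = (C / C_rand) / (L / L_rand),

where C is the triangle-based transitivity and L the characteristic path
length over the largest component; S^Δ > 1 indicates a small world.

A node's preference for the focal network A over a reference network B is the
binomial-proportion Z-score

    z = (a/c − b/d) / sqrt[(b/d)(1 − b/d) / d],

with a, b its link counts and c, d the total link counts in A and B.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse.csgraph as csgraph
import scipy.stats

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# degree ranking and relative subgraph connectivity
# --------------------------------------------------------------------------

@dataclass
class DegreeRanking:
    nodes: list[str]          # descending degree
    degrees: list[int]
    tie_rule: str = "lexicographic"


@dataclass
class ConnectivityCurve:
    k: np.ndarray             # prefix sizes 1..N
    r: np.ndarray             # relative connectivity per prefix
    r_full: float             # relative connectivity of the whole network
    nodes: list[str]          # the ranked order the prefixes are drawn from


@dataclass
class HubReport:
    cutoff_k: int
    hubs: list[str]
    stabilization_tol: float


def rank_by_degree(net: nx.Graph) -> DegreeRanking:
    """Rank all nodes by decreasing degree; ties break lexicographically."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty network")
    order = sorted(net.nodes, key=lambda v: (-net.degree[v], v))
    return DegreeRanking(nodes=order, degrees=[net.degree[v] for v in order])


def connectivity_curve(net: nx.Graph, ranking: DegreeRanking) -> ConnectivityCurve:
    """Relative connectivity r(k) of the induced subgraph on each ranking prefix.

    Incremental union-find: adding the k-th ranked node unions it with its
    already-present neighbors, so the whole curve costs O((N+E) α(N)).
    """
    order = ranking.nodes
    if set(order) != set(net.nodes):
        raise ValueError("ranking is not a permutation of the network's nodes")
    n = len(order)
    pos = {v: i for i, v in enumerate(order)}
    parent = list(range(n))
    size = [1] * n

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    r = np.empty(n)
    largest = 1
    for i, v in enumerate(order):
        for u in net.neighbors(v):
            j = pos[u]
            if j < i:
                ra, rb = find(i), find(j)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
                    largest = max(largest, size[ra])
        r[i] = largest / (i + 1)
    return ConnectivityCurve(k=np.arange(1, n + 1), r=r, r_full=float(r[-1]),
                             nodes=list(order))


def identify_hubs(curve: ConnectivityCurve, tol: float = 0.05) -> HubReport:
    """Shortest ranking prefix after which r(k) stays within ``tol``·r_full.

    cutoff_k is the smallest k such that |r(k′) − r_full| ≤ tol·r_full for
    every k′ ≥ k; the hubs are the first cutoff_k ranked nodes.  The suffix
    condition always holds at k = N since r(N) = r_full.
    """
    if not 0 < tol < 1:
        raise ValueError("tol must be in (0, 1)")
    r = curve.r
    band = tol * curve.r_full
    cutoff = len(r)
    for k in range(len(r), 0, -1):
        if abs(r[k - 1] - curve.r_full) <= band:
            cutoff = k
        else:
            break
    if cutoff == len(r) and len(r) > 1 and abs(r[-2] - curve.r_full) > band:
        logger.warning("identify_hubs: curve only stabilises at the full network")
    return HubReport(cutoff_k=cutoff, hubs=curve.nodes[:cutoff],
                     stabilization_tol=tol)


# --------------------------------------------------------------------------
# clustering, path length, null ensembles
# --------------------------------------------------------------------------

def transitivity(net: nx.Graph) -> float:
    """Global (triangle-based) clustering coefficient: 3·triangles / triples.

    Returns NaN with a warning when the network has no length-2 path.
    """
    if max((d for _, d in net.degree), default=0) < 2:
        logger.warning("transitivity: no length-2 path, coefficient undefined")
        return math.nan
    return nx.transitivity(net)


def characteristic_path_length(net: nx.Graph) -> float:
    """Mean shortest-path length over the largest connected component."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comp = max(nx.connected_components(net), key=lambda c: (len(c), sorted(c)[0]))
    if len(comp) < 2:
        raise ValueError("largest component has fewer than 2 nodes")
    sub = net.subgraph(comp)
    adj = nx.to_scipy_sparse_array(sub, nodelist=sorted(comp), format="csr")
    dist = csgraph.shortest_path(adj, method="D", unweighted=True)
    n = len(comp)
    return float(dist.sum() / (n * (n - 1)))


def sample_degree_matched_null(background: nx.Graph, template: nx.Graph,
                               n_samples: int, rng_seed: int,
                               mode: str = "degree") -> list[nx.Graph]:
    """Draw null networks as induced background subgraphs.

    mode="degree" (default): for each template node, draw without replacement
    a distinct background node with the same *background* degree, falling back
    to the nearest available degree (ties toward the smaller degree, node ties
    lexicographic) when a degree pool is exhausted; every fallback is logged.
    mode="size": draw |template| background nodes uniformly, matching size only.

    The null network is the background subgraph induced on the drawn node set.
    Fully deterministic under ``rng_seed``.
    """
    if template.number_of_nodes() > background.number_of_nodes():
        raise ValueError("background smaller than template")
    missing = set(template.nodes) - set(background.nodes)
    if mode == "degree" and missing:
        raise ValueError(f"template nodes absent from background: {sorted(missing)[:5]}")
    rng = np.random.default_rng(rng_seed)
    bg_nodes = sorted(background.nodes)
    n_template = template.number_of_nodes()

    if mode == "size":
        samples = []
        for _ in range(n_samples):
            picked = rng.choice(len(bg_nodes), size=n_template, replace=False)
            chosen = [bg_nodes[i] for i in sorted(picked)]
            samples.append(_induced(background, chosen))
        return samples
    if mode != "degree":
        raise ValueError(f"unknown null mode: {mode!r}")

    pools: dict[int, list[str]] = {}
    for v in bg_nodes:
        pools.setdefault(background.degree[v], []).append(v)
    demand: dict[int, int] = {}
    for v in template.nodes:
        d = background.degree[v]
        demand[d] = demand.get(d, 0) + 1

    samples = []
    n_fallbacks = 0
    for _ in range(n_samples):
        avail = {d: list(nodes) for d, nodes in pools.items()}
        chosen: list[str] = []
        sample_fallbacks = 0
        for d in sorted(demand):
            for _ in range(demand[d]):
                use = d
                if not avail.get(d):
                    near = [dd for dd, ns in avail.items() if ns]
                    if not near:
                        raise ValueError("background exhausted during null sampling")
                    use = min(near, key=lambda dd: (abs(dd - d), dd))
                    sample_fallbacks += 1
                pool = avail[use]
                idx = int(rng.integers(len(pool)))
                chosen.append(pool.pop(idx))
        sub = _induced(background, chosen)
        sub.graph["n_fallbacks"] = sample_fallbacks
        n_fallbacks += sample_fallbacks
        samples.append(sub)
    if n_fallbacks:
        logger.info("sample_degree_matched_null: %d nearest-degree fallbacks "
                    "over %d samples", n_fallbacks, n_samples)
    return samples


def _induced(background: nx.Graph, nodes: list[str]) -> nx.Graph:
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(background.subgraph(nodes).edges)
    return sub


def compare_to_null(observed: float, null_values) -> tuple[float, float]:
    """Locate an observed statistic in a null distribution.

    Returns ``(empirical_percentile, ks_p)``: the fraction of null values
    strictly below the observed one, and the one-sample two-sided KS p-value
    of the null sample against the point mass at the observed value.  The
    percentile is the recommended summary; the KS variant mirrors a common
    reporting style for clustering-coefficient calibrations.
    """
    nulls = np.asarray(list(null_values), dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null sample")
    percentile = float(np.mean(nulls < observed))
    degenerate_cdf = lambda x: (np.asarray(x) >= observed).astype(float)
    ks_p = float(scipy.stats.kstest(nulls, degenerate_cdf).pvalue)
    return percentile, ks_p


# --------------------------------------------------------------------------
# binomial-proportion Z-score
# --------------------------------------------------------------------------

@dataclass
class ZScoreRecord:
    node: str
    a: int     # node's link count in the focal network
    c: int     # focal network's total link count
    b: int     # node's link count in the reference network
    d: int     # reference network's total link count
    z: float
    defined: bool = True


def z_score(a: int, c: int, b: int, d: int) -> float:
    """Binomial-proportion Z: (a/c − b/d) / sqrt[(b/d)(1 − b/d)/d].

    Positive z means the node holds proportionally more of the focal
    network's links.  Undefined (NaN) when b = 0 or b = d, which zeroes the
    denominator; the caller decides policy for those records.
    """
    if c <= 0 or d <= 0:
        raise ValueError("total link counts must be positive")
    if not 0 <= a <= c or not 0 <= b <= d:
        raise ValueError("per-node link counts must lie within their totals")
    p_ref = b / d
    if b == 0 or b == d:
        return math.nan
    return (a / c - p_ref) / math.sqrt(p_ref * (1.0 - p_ref) / d)


def z_scores_for_network(focal: nx.Graph, reference: nx.Graph) -> list[ZScoreRecord]:
    """Per-node Z-scores of a focal network against a reference it sits inside."""
    missing = set(focal.nodes) - set(reference.nodes)
    if missing:
        raise ValueError(f"focal nodes absent from reference: {sorted(missing)[:5]}")
    c = focal.number_of_edges()
    d = reference.number_of_edges()
    records = []
    for v in sorted(focal.nodes):
        a, b = focal.degree[v], reference.degree[v]
        z = z_score(a, c, b, d)
        records.append(ZScoreRecord(node=v, a=a, c=c, b=b, d=d, z=z,
                                    defined=not math.isnan(z)))
    n_undef = sum(not r.defined for r in records)
    if n_undef:
        logger.info("z_scores_for_network: %d nodes with undefined z flagged", n_undef)
    return records


# --------------------------------------------------------------------------
# small-worldness
# --------------------------------------------------------------------------

@dataclass
class SmallWorldReport:
    C: float
    C_rand: float
    L: float
    L_rand: float
    s_delta: float


def small_worldness(net: nx.Graph, nulls: list[nx.Graph]) -> SmallWorldReport:
    """Small-world coefficient S^Δ = (C/C_rand)/(L/L_rand) against an ensemble.

    C is triangle-based transitivity, L the characteristic path length of the
    largest component; C_rand and L_rand are ensemble means computed the same
    way.  S^Δ > 1 marks a small-world topology.
    """
    if not nulls:
        raise ValueError("need at least one null network")
    C = transitivity(net)
    L = characteristic_path_length(net)
    c_vals = [transitivity(g) for g in nulls]
    l_vals = [characteristic_path_length(g) for g in nulls]
    C_rand = float(np.mean(c_vals))
    L_rand = float(np.mean(l_vals))
    if not C_rand > 0:
        raise ValueError("null ensemble has zero mean transitivity; "
                         "enlarge the ensemble or the null networks")
    s = (C / C_rand) / (L / L_rand)
    return SmallWorldReport(C=C, C_rand=C_rand, L=L, L_rand=L_rand, s_delta=s)


# --------------------------------------------------------------------------
# communities and backbone
# --------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    labels: dict[str, int]
    modularity_q: float

    def communities(self) -> list[list[str]]:
        groups: dict[int, list[str]] = {}
        for v, lab in self.labels.items():
            groups.setdefault(lab, []).append(v)
        return [sorted(groups[lab]) for lab in sorted(groups)]


def detect_communities(net: nx.Graph) -> CommunityPartition:
    """Deterministic greedy modularity agglomeration (CNM-style).

    The graph is canonicalised (sorted nodes and edges) before agglomeration
    so equal networks always yield the identical partition; community labels
    are assigned by each community's lexicographically smallest member.
    An edgeless network yields singleton communities with Q = 0 by convention.
    """
    if net.number_of_edges() == 0:
        labels = {v: i for i, v in enumerate(sorted(net.nodes))}
        return CommunityPartition(labels=labels, modularity_q=0.0)
    canon = nx.Graph()
    canon.add_nodes_from(sorted(net.nodes))
    canon.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
    comms = nx.community.greedy_modularity_communities(canon)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    q = nx.community.modularity(canon, comms)
    labels = {v: i for i, members in enumerate(comms) for v in members}
    return CommunityPartition(labels=labels, modularity_q=float(q))


@dataclass
class BackboneReport:
    community_hubs: dict[int, list[str]]
    backbone: list[str]
    backbone_network: nx.Graph
    covered: set[str]
    uncovered: set[str]


def extract_backbone(net: nx.Graph, partition: CommunityPartition,
                     global_hubs: HubReport | None = None,
                     degree_percentile: float = 90.0,
                     top_k: int | None = None) -> BackboneReport:
    """Per-community hubs, their induced subgraph, and its direct reach.

    Within each community the hubs are the members whose *full-network*
    degree reaches the community's ``degree_percentile`` (at least one node;
    top degree, lexicographic ties) — or, when ``top_k`` is given, exactly
    the top ``top_k`` members by degree — plus any global hubs that fall in
    the community.  ``covered`` is every non-backbone node adjacent to the
    backbone; the rest is ``uncovered``.
    """
    if set(partition.labels) != set(net.nodes):
        raise ValueError("partition does not cover the network")
    hub_pool = set(global_hubs.hubs) if global_hubs is not None else set()
    community_hubs: dict[int, list[str]] = {}
    for label, members in enumerate(partition.communities()):
        if not members:
            logger.warning("extract_backbone: empty community %d skipped", label)
            continue
        if top_k is not None:
            picked = set(sorted(members, key=lambda v: (-net.degree[v], v))[:top_k])
        else:
            degs = np.array([net.degree[v] for v in members])
            cut = np.percentile(degs, degree_percentile)
            picked = {v for v in members if net.degree[v] >= cut}
            if not picked:
                picked = {min(members, key=lambda v: (-net.degree[v], v))}
        picked |= hub_pool & set(members)
        community_hubs[label] = sorted(picked)
    backbone = sorted(set().union(*community_hubs.values()))
    backbone_network = _induced(net, backbone)
    rest = set(net.nodes) - set(backbone)
    covered = {v for v in rest if any(u in backbone_network for u in net.neighbors(v))}
    return BackboneReport(community_hubs=community_hubs, backbone=backbone,
                          backbone_network=backbone_network,
                          covered=covered, uncovered=rest - covered)


# --------------------------------------------------------------------------
# degree distribution
# --------------------------------------------------------------------------

@dataclass
class DegreeDistribution:
    histogram: dict[int, int]
    loglog_slope: float        # CCDF slope; NaN when undefined


def degree_distribution(net: nx.Graph) -> DegreeDistribution:
    """Degree histogram and least-squares log-log slope of the CCDF.

    The slope is fitted to log(#nodes with degree ≥ d) against log d over the
    distinct degrees d ≥ 1; a power-law degree distribution shows up as a
    slope around −(γ−1) for exponent γ.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = np.array([d for _, d in net.degree])
    hist: dict[int, int] = {}
    for d in degrees:
        hist[int(d)] = hist.get(int(d), 0) + 1
    pos = np.sort(np.unique(degrees[degrees >= 1]))
    if pos.size < 2:
        return DegreeDistribution(histogram=hist, loglog_slope=math.nan)
    ccdf = np.array([(degrees >= d).sum() for d in pos], dtype=float)
    slope = float(np.polyfit(np.log(pos), np.log(ccdf), 1)[0])
    return DegreeDistribution(histogram=hist, loglog_slope=slope)
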