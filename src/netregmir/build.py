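"""Three-step disease-network construction.

Starting from a background PPI network and a list of disease-associated seed
proteins: (1) the *basic* network is the background subgraph induced on the
seeds, retaining seeds with no intra-seed interaction as isolated nodes;
(2) the *expanded* network adds every direct background neighbor of a seed
and induces the full subgraph on the enlarged node set (guilt by
association), so it also contains the neighbor–neighbor edges that any
clustering analysis of the disease module needs.  Seeds absent from the
background are dropped with a warning and reported, never silently invented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class NetworkTriple:
    background: nx.Graph
    basic: nx.Graph
    expanded: nx.Graph
    seeds: set[str]
    missing_seeds: set[str]


def _present_seeds(background: nx.Graph, seeds) -> tuple[set[str], set[str]]:
    seeds = set(seeds)
    if not seeds:
        raise ValueError("empty seed list")
    present = seeds & set(background.nodes)
    missing = seeds - present
    if missing:
        logger.warning("%d seed(s) absent from background, dropped: %s%s",
                       len(missing), sorted(missing)[:5],
                       "..." if len(missing) > 5 else "")
    if not present:
        raise ValueError("no seed is present in the background network")
    return present, missing


def build_basic(background: nx.Graph, seeds) -> nx.Graph:
    """Background subgraph induced on the seeds (isolated seeds retained)."""
    present, _ = _present_seeds(background, seeds)
    basic = nx.Graph(name="basic")
    basic.add_nodes_from(sorted(present))
    basic.add_edges_from(background.subgraph(present).edges)
    return basic


def build_expanded(background: nx.Graph, seeds) -> nx.Graph:
    """Background subgraph induced on seeds plus their direct neighbors."""
    present, _ = _present_seeds(background, seeds)
    nodes = set(present)
    for s in present:
        nodes.update(background.neighbors(s))
    expanded = nx.Graph(name="expanded")
    expanded.add_nodes_from(sorted(nodes))
    expanded.add_edges_from(background.subgraph(nodes).edges)
    return expanded


def build_triple(background: nx.Graph, seeds) -> NetworkTriple:
    """Run both construction steps and bundle the result with bookkeeping."""
    present, missing = _present_seeds(background, seeds)
    return NetworkTriple(background=background,
                         basic=build_basic(background, present),
                         expanded=build_expanded(background, present),
                         seeds=present, missing_seeds=missing)
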