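"""Query-centered subnetwork extraction at a confidence level.

A layer-0 network keeps only interactions among the query proteins; a
layer-1 network also admits interactions reaching out to one non-query
partner. Either can be thresholded on the confidence score (score >=
min_score is kept) and filtered on PSI-MI interaction-type annotation.
Repeated layer-1 expansion grows a neighborhood around a seed set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .model import ScoredNetwork

logger = logging.getLogger(__name__)

#: Refuse neighborhood expansions deeper than this by default; beyond a few
#: layers the result approaches the whole connected component.
DEFAULT_LAYER_CAP = 3


@dataclass(frozen=True)
class SubnetworkQuery:
    proteins: frozenset[str]
    layer: int = 0
    min_score: float = 0.0
    interaction_type_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("query protein set must be non-empty")
        if self.layer not in (0, 1):
            raise ValueError(f"layer must be 0 or 1, got {self.layer}")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError(f"min_score must be in [0, 1], got {self.min_score}")


def extract_subnetwork(net: ScoredNetwork, q: SubnetworkQuery) -> ScoredNetwork:
    """Interactions incident to the query at the requested layer.

    Layer 0 requires both endpoints in the query set, layer 1 at least one.
    Interactions below min_score are dropped; with an interaction-type
    filter active, only interactions annotated with one of the requested
    PSI-MI codes survive — untyped interactions are dropped, which on
    sparsely annotated inputs can remove most of the network.
    """
    known = net.proteins()
    unknown = q.proteins - known
    if unknown:
        logger.warning("ignoring %d query identifier(s) not in the network, e.g. %s",
                       len(unknown), sorted(unknown)[0])
    effective = q.proteins & known
    if not effective:
        logger.warning("no query identifier matched the network; empty result")
        return ScoredNetwork([])
    out = []
    for si in net:
        a, b = si.key
        in_query = (a in effective) + (b in effective)
        if q.layer == 0 and in_query < 2:
            continue
        if q.layer == 1 and in_query < 1:
            continue
        if si.score < q.min_score:
            continue
        if q.interaction_type_filter is not None and not (
            si.evidence.interaction_types & q.interaction_type_filter
        ):
            continue
        out.append(si)
    return ScoredNetwork(out).sorted()


def neighborhood_expand(
    net: ScoredNetwork,
    seed: frozenset[str] | set[str],
    layers: int = 1,
    min_score: float = 0.0,
    layer_cap: int = DEFAULT_LAYER_CAP,
) -> ScoredNetwork:
    """Iterated layer-1 expansion around a seed set.

    Each round extracts the layer-1 network of the current protein set at
    the threshold and adds the new partners to the set. A seed already
    closed under interaction is a fixed point. Deeper expansions than
    ``layer_cap`` are refused: each layer can multiply the protein set by
    the typical degree, so the result quickly stops being a neighborhood.
    """
    if layers < 1:
        raise ValueError(f"layers must be >= 1, got {layers}")
    if layers > layer_cap:
        raise ValueError(
            f"refusing {layers}-layer expansion (cap {layer_cap}); raise "
            "layer_cap explicitly if the combinatorial growth is intended"
        )
    current = set(seed)
    edges = {}
    for _ in range(layers):
        sub = extract_subnetwork(
            net, SubnetworkQuery(frozenset(current), layer=1, min_score=min_score)
        )
        if not len(sub):
            break
        before = set(current)
        for si in sub:
            edges[si.key] = si
            current.update(si.key)
        if current == before and all(k in edges for k in (si.key for si in sub)):
            break  # fixed point
    return ScoredNetwork([edges[k] for k in sorted(edges)])


def to_networkx(net: ScoredNetwork) -> nx.Graph:
    """Undirected graph with score and evidence summaries as edge data."""
    g = nx.Graph()
    for si in net:
        a, b = si.key
        ev = si.evidence
        g.add_edge(
            a,
            b,
            score=si.score,
            n_studies=len(ev.studies),
            n_organisms=len(ev.organisms),
            techniques=",".join(sorted(ev.techniques)),
            sources=",".join(sorted(ev.sources)),
        )
    return g


def write_edge_list(net: ScoredNetwork, path) -> None:
    """Three-column edge list: protein_a, protein_b, score (2 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        for si in net.sorted():
            fh.write(f"{si.key[0]}\t{si.key[1]}\t{si.score:.2f}\n")


def write_graphml(net: ScoredNetwork, path) -> None:
    """GraphML export for visualization tools."""
    nx.write_graphml(to_networkx(net), path)
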