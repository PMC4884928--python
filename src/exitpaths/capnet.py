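"""CAP-Net: common pathway inference by shortest-path network intersection.

For each drug, the shortest paths on a confidence-filtered protein
interaction network between the drug's targets and its differentially
expressed genes (DEGs) form that drug's shortest-path network (SPNet): the
union of the edges of *all* tied shortest paths over every connected
(target, DEG) pair, on an unweighted hop-count metric. Intersecting SPNets
across drugs — keeping edges supported by at least ``min_support`` drugs
(default 2) — yields the Commonly Affected Paths Network (CAP-Net):
interaction edges that multiple, possibly chemically unrelated, drugs
perturb en route from their targets to their transcriptional endpoints.

Edge significance comes from an empirical null: draw random connected node
pairs from the same filtered network, take each draw's all-shortest-paths
edge set, and score how often it contains the CAP-Net edge.

Tied shortest paths are handled without path enumeration: an edge (u, v)
lies on some shortest s-t path iff dist(s,u) + 1 + dist(v,t) = dist(s,t)
in either orientation, so two breadth-first sweeps per pair suffice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ControlErrorModel, ExpressionDataset, GroundTruth

MIN_EDGE_CONFIDENCE = 0.8
FOLD_CHANGE = 1.5
MIN_SUPPORT = 2

Edge = tuple[str, str]


def _edge(u, v) -> Edge:
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# DEG selection
# ---------------------------------------------------------------------------

def select_degs(
    data: ExpressionDataset,
    model: ControlErrorModel,
    drug: str,
    day: int,
    fold: float = FOLD_CHANGE,
    log_base: float = 2.0,
) -> set[str]:
    """Genes >= ``fold``-fold up-/down-regulated vs the control mean.

    Expression is assumed on a log scale with the given base, so the rule is
    |x - x0_mean| >= log_base(fold), inclusive at the boundary.
    """
    if fold <= 1.0:
        raise ValueError("fold must exceed 1")
    col = data.sample_for(drug, day)
    delta = (data.values[col] - model.mean).abs()
    thr = math.log(fold, log_base)
    return set(delta.index[delta >= thr])


# ---------------------------------------------------------------------------
# SPNet construction
# ---------------------------------------------------------------------------

def filter_network(net: nx.Graph, min_conf: float = MIN_EDGE_CONFIDENCE) -> nx.Graph:
    """Subgraph of edges at or above the confidence threshold (nodes kept)."""
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        if u == v:
            continue
        if d.get("confidence", 1.0) >= min_conf:
            out.add_edge(u, v, **d)
    return out


def all_shortest_path_edges(graph: nx.Graph, source: str, sink: str) -> set[Edge] | None:
    """Edge union of every shortest source-sink path; None if disconnected.

    Uses the two-sided BFS distance criterion rather than enumerating paths,
    so tied paths cost nothing extra.
    """
    try:
        ds = nx.single_source_shortest_path_length(graph, source)
    except nx.NodeNotFound:
        raise KeyError(f"node {source!r} not in graph")
    if sink not in graph:
        raise KeyError(f"node {sink!r} not in graph")
    if sink not in ds:
        return None
    dt = nx.single_source_shortest_path_length(graph, sink)
    total = ds[sink]
    edges = set()
    for u, v in graph.edges():
        du, dv = ds.get(u), ds.get(v)
        eu, ev = dt.get(u), dt.get(v)
        if du is None or dv is None or eu is None or ev is None:
            continue
        if du + 1 + ev == total or dv + 1 + eu == total:
            edges.add(_edge(u, v))
    return edges


@dataclass
class SPNet:
    """One drug's shortest-path network with per-edge provenance."""

    drug: str
    edges: dict[Edge, set[tuple[str, str]]]   # edge -> (target, DEG) pairs using it
    distances: dict[tuple[str, str], int]     # connected (target, DEG) -> hops
    unreachable: list[tuple[str, str]]
    unmapped_targets: list[str]
    unmapped_degs: list[str]

    @property
    def edge_set(self) -> frozenset:
        return frozenset(self.edges)


def build_spnet(
    net: nx.Graph,
    targets,
    degs,
    min_conf: float = MIN_EDGE_CONFIDENCE,
    drug: str = "",
) -> SPNet:
    """Union of all shortest paths between each (target, DEG) pair.

    The network is confidence-filtered first. Targets or DEGs missing from
    the network are recorded and skipped; empty input sets are an error.
    """
    targets = list(dict.fromkeys(targets))
    degs = list(dict.fromkeys(degs))
    if not targets:
        raise ValueError(f"empty target set for drug {drug!r}")
    if not degs:
        raise ValueError(f"empty DEG set for drug {drug!r}")
    g = filter_network(net, min_conf)
    unmapped_t = [t for t in targets if t not in g]
    unmapped_g = [d for d in degs if d not in g]
    targets = [t for t in targets if t in g]
    degs = [d for d in degs if d in g]
    if not targets:
        raise ValueError(f"no targets mapped onto the network for drug {drug!r}")
    if not degs:
        raise ValueError(f"no DEGs mapped onto the network for drug {drug!r}")

    edges: dict[Edge, set[tuple[str, str]]] = {}
    distances: dict[tuple[str, str], int] = {}
    unreachable: list[tuple[str, str]] = []
    for t in targets:
        ds = nx.single_source_shortest_path_length(g, t)
        for deg in degs:
            if deg == t:
                continue
            if deg not in ds:
                unreachable.append((t, deg))
                continue
            pair_edges = all_shortest_path_edges(g, t, deg)
            distances[(t, deg)] = ds[deg]
            for e in pair_edges:
                edges.setdefault(e, set()).add((t, deg))
    return SPNet(
        drug=drug,
        edges=edges,
        distances=distances,
        unreachable=unreachable,
        unmapped_targets=unmapped_t,
        unmapped_degs=unmapped_g,
    )


# ---------------------------------------------------------------------------
# intersection and significance
# ---------------------------------------------------------------------------

@dataclass
class CAPNet:
    """Edges supported by multiple drugs' SPNets, with optional p-values."""

    edges: dict[Edge, frozenset]              # edge -> supporting drug ids
    min_support: int
    pvalues: dict[Edge, float] = field(default_factory=dict)
    node_annotations: pd.DataFrame | None = None

    @property
    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def support(self, edge: Edge) -> int:
        return len(self.edges[edge])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_a": e[0],
                "node_b": e[1],
                "support": len(drugs),
                "drugs": ",".join(sorted(drugs)),
                "p_value": self.pvalues.get(e, np.nan),
            }
            for e, drugs in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "support", "drugs", "p_value"]
        )


def intersect_spnets(spnets: list[SPNet], min_support: int = MIN_SUPPORT) -> CAPNet:
    """Keep edges present in at least ``min_support`` drugs' SPNets."""
    if len(spnets) < 2:
        raise ValueError("need >= 2 SPNets to intersect")
    support: dict[Edge, set] = {}
    for sp in spnets:
        for e in sp.edges:
            support.setdefault(e, set()).add(sp.drug)
    kept = {
        e: frozenset(drugs) for e, drugs in support.items() if len(drugs) >= min_support
    }
    return CAPNet(edges=kept, min_support=min_support)


def capnet_pvalues(
    cap: CAPNet,
    net: nx.Graph,
    n_null: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_conf: float = MIN_EDGE_CONFIDENCE,
) -> dict[Edge, float]:
    """Empirical per-edge p-values against random shortest-path draws.

    Each draw picks a connected node pair uniformly (over all connected
    pairs of the filtered network) and computes its all-shortest-paths edge
    set; p(edge) = (1 + hits) / (n_null + 1). Stores the result on ``cap``
    and returns it.
    """
    g = filter_network(net, min_conf)
    if g.number_of_nodes() < 2:
        raise ValueError("network must have >= 2 nodes")
    for e in cap.edges:
        if not g.has_edge(*e):
            raise ValueError(f"CAP edge {e} absent from the filtered network")
    if rng is None:
        rng = np.random.default_rng(seed)

    comps = [list(c) for c in nx.connected_components(g) if len(c) >= 2]
    if not comps:
        raise ValueError("no connected pairs in the filtered network")
    weights = np.array([len(c) * (len(c) - 1) / 2 for c in comps], dtype=float)
    weights /= weights.sum()

    hits = {e: 0 for e in cap.edges}
    comp_idx = rng.choice(len(comps), size=n_null, p=weights)
    for ci in comp_idx:
        nodes = comps[ci]
        i, j = rng.choice(len(nodes), size=2, replace=False)
        draw = all_shortest_path_edges(g, nodes[i], nodes[j])
        for e in hits:
            if e in draw:
                hits[e] += 1
    pvals = {e: (1 + h) / (n_null + 1) for e, h in hits.items()}
    cap.pvalues = pvals
    return pvals


def annotate_nodes(
    cap: CAPNet,
    targets_by_drug: dict[str, tuple] | None = None,
    expression_change: pd.Series | None = None,
) -> pd.DataFrame:
    """Node table: which drugs target each CAP node, mean expression change."""
    nodes = sorted({n for e in cap.edges for n in e})
    rows = []
    for n in nodes:
        targeting = (
            sorted(d for d, ts in targets_by_drug.items() if n in ts)
            if targets_by_drug
            else []
        )
        change = (
            float(expression_change[n])
            if expression_change is not None and n in expression_change.index
            else np.nan
        )
        rows.append({"node": n, "is_target_of": ",".join(targeting),
                     "mean_expression_change": change})
    frame = pd.DataFrame(rows, columns=["node", "is_target_of", "mean_expression_change"])
    cap.node_annotations = frame
    return frame


def recover_planted(cap: CAPNet, truth: GroundTruth) -> dict:
    """Precision/recall of CAP-Net edges against the planted backbone."""
    true_edges = {tuple(sorted(e)) for e in truth.backbone_edges}
    found = set(cap.edge_set)
    tp = len(found & true_edges)
    degenerate = len(found) == 0
    precision = 0.0 if degenerate else tp / len(found)
    recall = tp / len(true_edges) if true_edges else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "n_cap_edges": len(found),
        "n_true_edges": len(true_edges),
        "degenerate": degenerate,
    }


# ---------------------------------------------------------------------------
# brute-force oracle (small graphs only; used for validation)
# ---------------------------------------------------------------------------

def spnet_edges_bruteforce(
    net: nx.Graph, targets, degs, min_conf: float = MIN_EDGE_CONFIDENCE
) -> frozenset:
    """Edge union via explicit enumeration of every shortest path.

    Exponential in the worst case — intended as an independent oracle on
    small graphs, not for analysis use.
    """
    g = filter_network(net, min_conf)
    edges = set()
    for t in targets:
        for deg in degs:
            if t == deg or t not in g or deg not in g:
                continue
            paths = list(nx.all_simple_paths(g, t, deg))
            if not paths:
                continue
            best = min(len(p) for p in paths)
            for path in paths:
                if len(path) == best:
                    for u, v in itertools.pairwise(path):
                        edges.add(_edge(u, v))
    return frozenset(edges)
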