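"""Retrieval of OrthNets by copy-number pattern or network topology.

Topology matching canonicalizes each OrthNet as a colored directed
multigraph (node color = genome, edge label = property + reciprocity, with
``td`` undirected).  Canonical labeling uses iterated color refinement
followed by exhaustive search over the remaining symmetry, which is cheap
because OrthNets are small.  Two OrthNets are topologically identical iff
their canonical signatures are equal.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import networkx as nx

from .onfinder import OrthNet

__all__ = [
    "PatternQuery",
    "parse_pattern",
    "search_by_pattern",
    "topology_signature",
    "search_by_topology",
]

_MAX_EXACT_NODES = 30
_MAX_SYMMETRY = 2_000_000


@dataclass
class PatternQuery:
    """Declarative OrthNet filter.

    copy_constraints: genome -> (op, k) with op one of ``==  >=  <=``;
        genomes not listed are unconstrained.
    edges_required / edges_forbidden: (genome_a, genome_b, property,
        reciprocity) tuples; reciprocal and ``td`` constraints match either
        orientation, unidirectional ones the a -> b direction.
    extra_copies_only_uni_tr: genomes whose surplus copies (all but one
        node) may carry only unidirectional ``tr`` inter-genome out-edges
        — the copy-number fingerprint of a transposition-duplication.
    """

    copy_constraints: dict[str, tuple[str, int]] = field(default_factory=dict)
    edges_required: set[tuple[str, str, str, str]] = field(default_factory=set)
    edges_forbidden: set[tuple[str, str, str, str]] = field(default_factory=set)
    extra_copies_only_uni_tr: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (
            self.copy_constraints
            or self.edges_required
            or self.edges_forbidden
            or self.extra_copies_only_uni_tr
        ):
            # the tautological pattern is explicitly allowed
            pass

    def matches(self, orthnet: OrthNet) -> bool:
        copies = orthnet.copy_number
        for genome, (op, k) in self.copy_constraints.items():
            c = copies.get(genome, 0)
            if op == "==" and c != k:
                return False
            if op == ">=" and c < k:
                return False
            if op == "<=" and c > k:
                return False
        if self.edges_required or self.edges_forbidden:
            present = _edge_triples(orthnet)
            for t in self.edges_required:
                if not _triple_present(present, t):
                    return False
            for t in self.edges_forbidden:
                if _triple_present(present, t):
                    return False
        for genome in self.extra_copies_only_uni_tr:
            nodes = orthnet.genome_nodes(genome)
            if len(nodes) < 2:
                return False
            n_tr_only = sum(
                1 for n in nodes if _only_uni_tr_out(orthnet.graph, n)
            )
            if n_tr_only < len(nodes) - 1:
                return False
        return True


def _only_uni_tr_out(graph: nx.DiGraph, node: str) -> bool:
    """True when every inter-genome out-edge of ``node`` is unidirectional tr."""
    genome = graph.nodes[node]["genome"]
    for _, v, data in graph.out_edges(node, data=True):
        if data["property"] == "td" or graph.nodes[v]["genome"] == genome:
            continue
        if not (data["property"] == "tr" and data["reciprocity"] == "uni"):
            return False
    return True


def _edge_triples(orthnet: OrthNet) -> set[tuple[str, str, str, str]]:
    triples = set()
    for u, v, data in orthnet.graph.edges(data=True):
        gu = orthnet.graph.nodes[u]["genome"]
        gv = orthnet.graph.nodes[v]["genome"]
        triples.add((gu, gv, data["property"], data["reciprocity"]))
    return triples


def _triple_present(
    present: set[tuple[str, str, str, str]], t: tuple[str, str, str, str]
) -> bool:
    a, b, prop, rec = t
    if rec in ("rc", "und"):
        return (a, b, prop, rec) in present or (b, a, prop, rec) in present
    return (a, b, prop, rec) in present


_PATTERN_RE = re.compile(r"^\s*(\w+)\s*(==|>=|<=)\s*(\d+)\s*$")


def parse_pattern(expr: str) -> PatternQuery:
    """Parse a copy-number expression like ``"Spa>=2,Aly==1,Ath<=1"``.

    A trailing ``;trd=<genome>`` clause adds the surplus-copies-are-
    unidirectional-tr constraint for that genome.
    """
    query = PatternQuery()
    expr = expr.strip()
    if not expr:
        return query
    main, _, trd = expr.partition(";")
    for term in filter(None, (t.strip() for t in main.split(","))):
        m = _PATTERN_RE.match(term)
        if not m:
            raise ValueError(f"cannot parse pattern term {term!r}")
        genome, op, k = m.groups()
        query.copy_constraints[genome] = (op, int(k))
    if trd:
        key, _, val = trd.partition("=")
        if key.strip() != "trd" or not val.strip():
            raise ValueError(f"cannot parse pattern clause {trd!r}")
        query.extra_copies_only_uni_tr.add(val.strip())
    return query


def search_by_pattern(
    orthnets: list[OrthNet], pattern: PatternQuery
) -> list[str]:
    """Ids of all OrthNets satisfying every constraint, in id order."""
    return sorted(n.orthnet_id for n in orthnets if pattern.matches(n))


# ---------------------------------------------------------------------------
# topology signatures


def _edge_labels(graph: nx.DiGraph) -> dict[tuple[str, str], tuple[str, ...]]:
    """Directed (u, v) -> sorted labels; td appears in both directions."""
    labels: dict[tuple[str, str], list[str]] = {}
    for u, v, data in graph.edges(data=True):
        if data["property"] == "td":
            labels.setdefault((u, v), []).append("td")
            labels.setdefault((v, u), []).append("td")
        else:
            lab = f"{data['property']}_{data['reciprocity']}"
            labels.setdefault((u, v), []).append(lab)
    return {k: tuple(sorted(v)) for k, v in labels.items()}


def _refine_colors(
    nodes: list[str],
    colors: dict[str, str],
    labels: dict[tuple[str, str], tuple[str, ...]],
) -> dict[str, str]:
    """Iterated neighbourhood color refinement (1-WL with edge labels)."""
    while True:
        new: dict[str, str] = {}
        for n in nodes:
            signature = sorted(
                (("out",) + labels[(n, v)] + (colors[v],))
                for v in nodes
                if (n, v) in labels
            ) + sorted(
                (("in",) + labels[(v, n)] + (colors[v],))
                for v in nodes
                if (v, n) in labels
            )
            new[n] = repr((colors[n], signature))
        if len(set(new.values())) == len(set(colors.values())):
            # no class split further; normalize names and stop
            mapping = {c: f"c{i}" for i, c in enumerate(sorted(set(new.values())))}
            return {n: mapping[new[n]] for n in nodes}
        colors = new


def _canonical_encoding(
    nodes: list[str],
    colors: dict[str, str],
    labels: dict[tuple[str, str], tuple[str, ...]],
    base_color: dict[str, str],
) -> tuple:
    """Lexicographically minimal encoding over the residual symmetry."""
    classes: dict[str, list[str]] = {}
    for n in nodes:
        classes.setdefault(colors[n], []).append(n)
    class_keys = sorted(classes)
    sym = math.prod(math.factorial(len(classes[k])) for k in class_keys)
    if sym > _MAX_SYMMETRY:
        raise ValueError(
            f"too much residual symmetry ({sym} orderings); refuse exact match"
        )
    best: tuple | None = None
    perm_sets = [
        list(itertools.permutations(sorted(classes[k]))) for k in class_keys
    ]
    for combo in itertools.product(*perm_sets):
        order = [n for group in combo for n in group]
        index = {n: i for i, n in enumerate(order)}
        enc_nodes = tuple(base_color[n] for n in order)
        enc_edges = tuple(
            sorted(
                (index[u], index[v], labels[(u, v)])
                for (u, v) in labels
            )
        )
        enc = (enc_nodes, enc_edges)
        if best is None or enc < best:
            best = enc
    assert best is not None
    return best


def topology_signature(orthnet: OrthNet, mode: str = "exact") -> str:
    """Canonical string of the colored directed multigraph.

    ``exact``: node color = (genome, truncation flag).
    ``similar``: truncation flags dropped and same-genome nodes with
    identical non-td edge signatures collapsed into one (so one-copy and
    many-copy versions of the same event match).
    """
    graph = orthnet.graph
    if mode == "similar":
        graph = _collapse_duplicates(graph)
    elif mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    nodes = sorted(graph.nodes)
    if mode == "exact":
        base_color = {
            n: f"{graph.nodes[n]['genome']}~{graph.nodes[n].get('truncation', 'none')}"
            for n in nodes
        }
    else:
        base_color = {n: graph.nodes[n]["genome"] for n in nodes}
    labels = _edge_labels(graph)
    colors = _refine_colors(nodes, dict(base_color), labels)
    enc = _canonical_encoding(nodes, colors, labels, base_color)
    return repr(enc)


def _collapse_duplicates(graph: nx.DiGraph) -> nx.DiGraph:
    """Quotient graph merging same-genome nodes with identical non-td
    edge signatures; td edges inside a merged group vanish."""
    signature: dict[str, tuple] = {}
    for n in graph.nodes:
        outs = sorted(
            (f"{d['property']}_{d['reciprocity']}", v)
            for _, v, d in graph.out_edges(n, data=True)
            if d["property"] != "td"
        )
        ins = sorted(
            (f"{d['property']}_{d['reciprocity']}", u)
            for u, _, d in graph.in_edges(n, data=True)
            if d["property"] != "td"
        )
        signature[n] = (graph.nodes[n]["genome"], tuple(outs), tuple(ins))
    rep: dict[tuple, str] = {}
    merge_to: dict[str, str] = {}
    for n in sorted(graph.nodes):
        key = signature[n]
        if key in rep:
            merge_to[n] = rep[key]
        else:
            rep[key] = n
            merge_to[n] = n
    out = nx.DiGraph()
    for n in sorted(set(merge_to.values())):
        out.add_node(n, genome=graph.nodes[n]["genome"], truncation="none",
                     orf_length=graph.nodes[n].get("orf_length", 0))
    for u, v, data in graph.edges(data=True):
        mu, mv = merge_to[u], merge_to[v]
        if mu == mv:
            continue
        if not out.has_edge(mu, mv):
            out.add_edge(mu, mv, **data)
    return out


def search_by_topology(
    orthnets: list[OrthNet], query: OrthNet, mode: str = "exact"
) -> list[str]:
    """Ids of OrthNets whose topology matches the query's.

    ``exact`` requires identical canonical signatures (including truncation
    flags); ``similar`` matches after collapsing same-genome duplicate
    nodes and dropping truncation flags.  Exact mode refuses queries with
    more than 30 nodes.
    """
    if mode == "exact" and len(query) > _MAX_EXACT_NODES:
        raise ValueError(
            f"query has {len(query)} nodes > {_MAX_EXACT_NODES}; "
            "exact matching refused"
        )
    want = topology_signature(query, mode=mode)
    hits = []
    for net in orthnets:
        if mode == "exact" and len(net) > _MAX_EXACT_NODES:
            continue
        try:
            if topology_signature(net, mode=mode) == want:
                hits.append(net.orthnet_id)
        except ValueError:
            continue
    return sorted(hits)
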