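"""Orthologue-network (OrthNet) construction from pairwise co-linearity calls.

Each locus of every genome becomes a node; each locus is joined to its
best-hit in every other genome by a directed edge carrying the co-linearity
label as its property (``cl``, ``tr`` or ``nd``; ``cl_end`` folds into
``cl``).  Tandem-duplicated paralogues are joined by undirected ``td``
edges.  Connected components are then refined in three steps:

1. best-hit repair — a unidirectional edge A->B is made reciprocal when A
   appears anywhere in B's 10-candidate list (unless B already forms a
   reciprocal pair in A's genome);
2. Markov clustering with property-dependent edge weights, separating
   aggregates of out-paralogues;
3. rewiring — edges crossing cluster boundaries are replaced by the
   highest-ranked candidate inside the cluster, when one exists.

The resulting OrthNets each represent the descendants of (ideally) a single
ancestral locus, with the evolutionary history encoded in the topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

import networkx as nx
import numpy as np
import pandas as pd

from .clfinder import (
    CLParams,
    CLRelation,
    Projection,
    TdGroup,
    classify_locus,
    classify_projection,
    detect_tandem_duplicates,
    effective_projection,
)
from .mcl import mcl_partition
from .types import BestHitTable, GenomeTable, ParalogClusters

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeWeightScheme",
    "OrthNet",
    "OnfinderContext",
    "node_key",
    "split_key",
    "build_raw_network",
    "repair_best_hit_pairs",
    "component_weight_matrix",
    "cluster_graph",
    "rewire_after_mcl",
    "flag_truncated_orfs",
    "build_orthnets",
    "write_sif",
    "read_sif",
    "orthnet_annotation",
]


def node_key(genome_id: str, gene_id: str) -> str:
    return f"{genome_id}|{gene_id}"


def split_key(key: str) -> tuple[str, str]:
    genome_id, gene_id = key.split("|", 1)
    return genome_id, gene_id


@dataclass(frozen=True)
class EdgeWeightScheme:
    """MCL edge weights by property and reciprocity, plus inflation.

    Defaults favour keeping tandem duplicates and reciprocal co-linear
    orthologues together while letting weak unidirectional transposition
    edges break, so that out-paralogue aggregates split apart.
    ``nd`` edges weigh the same as unidirectional ``tr``.
    """

    w_td: float = 1.5
    w_cl_reciprocal: float = 1.2
    w_cl_unidirectional: float = 0.6
    w_tr_reciprocal: float = 0.5
    w_tr_unidirectional: float = 0.25
    inflation: float = 1.2

    def weight(self, prop: str, reciprocity: str) -> float:
        if prop == "td":
            return self.w_td
        if prop == "nd":
            return self.w_tr_unidirectional
        if prop == "cl":
            return self.w_cl_reciprocal if reciprocity == "rc" else self.w_cl_unidirectional
        if prop == "tr":
            return self.w_tr_reciprocal if reciprocity == "rc" else self.w_tr_unidirectional
        raise ValueError(f"unknown edge property {prop!r}")


@dataclass
class OrthNet:
    """One final orthologue network.

    ``graph`` is a directed graph over node keys ``genome|gene``; ``td``
    edges are stored once with reciprocity ``und`` and are treated as
    undirected everywhere.
    """

    orthnet_id: str
    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def copy_number(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for n, data in self.graph.nodes(data=True):
            counts[data["genome"]] = counts.get(data["genome"], 0) + 1
        return counts

    def genome_nodes(self, genome_id: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["genome"] == genome_id
        )

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class OnfinderContext:
    """Everything needed to (re-)classify an edge with an imposed best-hit."""

    genomes: dict[str, GenomeTable]
    besthits: dict[tuple[str, str], BestHitTable]
    projections: dict[tuple[str, str], Projection]
    td_groups: dict[str, list[TdGroup]]
    params: CLParams = field(default_factory=CLParams)

    def classify_imposed(
        self, query_genome: str, gene_id: str, target_genome: str, imposed_hit: str
    ) -> str:
        """Edge property after imposing ``imposed_hit`` as the best-hit."""
        proj = self.projections[(query_genome, target_genome)]
        pos_gene = gene_id
        if pos_gene not in proj.index_of:
            pos_gene = proj.rep_of.get(gene_id, gene_id)
        if pos_gene not in proj.index_of or imposed_hit not in proj.target_eff:
            # no chain context (the locus was lineage-specific here)
            scaffold = self.genomes[query_genome][gene_id].scaffold_id
            short = proj.raw_counts.get(scaffold, 0) < self.params.W
            return "nd" if short else "tr"
        rel = classify_locus(pos_gene, proj, self.params, imposed_hit=imposed_hit)
        return _fold(rel.label)


def _fold(label: str) -> str:
    if label in ("cl", "cl_end"):
        return "cl"
    if label in ("tr", "nd"):
        return label
    raise ValueError(f"cannot place label {label!r} on a network edge")


def build_raw_network(
    relations: dict[tuple[str, str], dict[str, CLRelation]],
    genomes: dict[str, GenomeTable],
    td_groups: dict[str, list[TdGroup]] | None = None,
) -> nx.DiGraph:
    """Directed best-hit graph over all loci of all genomes.

    One edge per (query locus -> best-hit); mutual same-property edges are
    marked reciprocal.  Tandem groups contribute undirected ``td`` edges
    between rank-consecutive members.
    """
    graph = nx.DiGraph()
    for genome_id, table in genomes.items():
        for locus in table:
            graph.add_node(
                node_key(genome_id, locus.gene_id),
                genome=genome_id,
                gene=locus.gene_id,
                orf_length=locus.orf_length,
                scaffold=locus.scaffold_id,
                rank=locus.rank,
                truncation="none",
            )
    for (q, t), rels in relations.items():
        for rel in rels.values():
            if rel.best_hit is None:
                continue
            u = node_key(q, rel.query)
            v = node_key(t, rel.best_hit)
            if v not in graph:
                continue
            graph.add_edge(
                u, v, property=_fold(rel.label), reciprocity="uni", candidate_rank=1
            )
    for genome_id, groups in (td_groups or {}).items():
        for grp in groups:
            for a, b in zip(grp.members, grp.members[1:]):
                u, v = sorted((node_key(genome_id, a), node_key(genome_id, b)))
                graph.add_edge(u, v, property="td", reciprocity="und", candidate_rank=0)
    _mark_reciprocity(graph)
    return graph


def _mark_reciprocity(graph: nx.DiGraph) -> None:
    for u, v, data in graph.edges(data=True):
        if data["property"] == "td":
            continue
        back = graph.get_edge_data(v, u)
        if back and back["property"] != "td" and back["property"] == data["property"]:
            data["reciprocity"] = "rc"
        else:
            data["reciprocity"] = "uni"


def repair_best_hit_pairs(graph: nx.DiGraph, ctx: OnfinderContext) -> nx.DiGraph:
    """Resolve non-reciprocal best-hit edges from the 10-candidate lists.

    For each node B and genome g: if B's outgoing edge into g is not part
    of a mutual best-hit pair, and some node A of genome g with an edge
    A->B lists B so that A appears in B's candidate list, redirect B's
    edge to the best-ranked such A.  Existing mutual pairs are never
    broken.  The operation is idempotent.
    """
    for b in sorted(graph.nodes):
        g_b, gene_b = split_key(b)
        # incoming unidirectional best-hit edges grouped by source genome
        incoming: dict[str, list[str]] = {}
        for a, _, data in graph.in_edges(b, data=True):
            if data["property"] == "td":
                continue
            if not graph.has_edge(b, a):
                incoming.setdefault(graph.nodes[a]["genome"], []).append(a)
        for g_a, sources in sorted(incoming.items()):
            table = ctx.besthits.get((g_b, g_a))
            if table is None:
                continue
            current = _out_edge_into(graph, b, g_a)
            if current is not None and graph.has_edge(current, b):
                continue  # mutual pair already; never break it
            ranked = [
                (table.candidate_rank(gene_b, split_key(a)[1]), a)
                for a in sources
            ]
            ranked = sorted((r, a) for r, a in ranked if r is not None)
            if not ranked:
                continue
            rank, a = ranked[0]
            if current is not None:
                if current == a:
                    continue
                graph.remove_edge(b, current)
            prop = ctx.classify_imposed(g_b, gene_b, g_a, split_key(a)[1])
            graph.add_edge(b, a, property=prop, reciprocity="uni", candidate_rank=rank)
    _mark_reciprocity(graph)
    return graph


def _out_edge_into(graph: nx.DiGraph, node: str, genome_id: str) -> str | None:
    for _, v, data in graph.out_edges(node, data=True):
        if data["property"] != "td" and graph.nodes[v]["genome"] == genome_id:
            return v
    return None


def component_weight_matrix(
    graph: nx.DiGraph, nodes: list[str], scheme: EdgeWeightScheme
) -> np.ndarray:
    """Symmetric MCL weight matrix for one component.

    A reciprocal pair contributes its weight once; antiparallel
    unidirectional edges sum; ``td`` contributes w_td.
    """
    index = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    done_rc: set[frozenset] = set()
    for u, v, data in graph.edges(data=True):
        if u not in index or v not in index:
            continue
        i, j = index[u], index[v]
        w = scheme.weight(data["property"], data["reciprocity"])
        if data["property"] == "td":
            W[i, j] = W[j, i] = max(W[i, j], scheme.w_td)
        elif data["reciprocity"] == "rc":
            pair = frozenset((u, v))
            if pair not in done_rc:
                done_rc.add(pair)
                W[i, j] += w
                W[j, i] += w
        else:
            W[i, j] += w
            W[j, i] += w
    return W


def cluster_graph(
    graph: nx.DiGraph, scheme: EdgeWeightScheme = EdgeWeightScheme()
) -> list[set[str]]:
    """MCL partition of the whole best-hit graph, component by component."""
    partition: list[set[str]] = []
    for comp in nx.weakly_connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            partition.append(set(nodes))
            continue
        W = component_weight_matrix(graph, nodes, scheme)
        for cluster in mcl_partition(W, inflation=scheme.inflation):
            partition.append({nodes[i] for i in cluster})
    return partition


def rewire_after_mcl(
    graph: nx.DiGraph,
    partition: list[set[str]],
    ctx: OnfinderContext,
) -> list[OrthNet]:
    """Drop cross-cluster edges, rewire inside clusters, emit OrthNets.

    For each dropped best-hit edge from node X into genome g, the
    highest-ranked candidate of X inside X's cluster (if any) replaces it.
    Clusters disconnected after rewiring split into their connected
    components; final OrthNets get stable ids ordered by minimum node key.
    """
    cluster_of: dict[str, int] = {}
    for ci, cluster in enumerate(partition):
        for n in cluster:
            cluster_of[n] = ci
    work = graph.copy()
    dropped: list[tuple[str, str]] = []
    for u, v, data in list(work.edges(data=True)):
        if cluster_of[u] != cluster_of[v]:
            work.remove_edge(u, v)
            if data["property"] != "td":
                dropped.append((u, work.nodes[v]["genome"]))
    for x, g in sorted(set(dropped)):
        g_x, gene_x = split_key(x)
        table = ctx.besthits.get((g_x, g))
        if table is None:
            continue
        if _out_edge_into(work, x, g) is not None:
            continue
        for rank, cand in enumerate(table.candidates(gene_x), start=1):
            cand_key = node_key(g, cand)
            if cand_key in cluster_of and cluster_of[cand_key] == cluster_of[x]:
                prop = ctx.classify_imposed(g_x, gene_x, g, cand)
                work.add_edge(
                    x, cand_key, property=prop, reciprocity="uni", candidate_rank=rank
                )
                break
    _mark_reciprocity(work)

    pieces: list[nx.DiGraph] = []
    for cluster in partition:
        sub = work.subgraph(cluster)
        for comp in nx.weakly_connected_components(sub):
            pieces.append(nx.DiGraph(work.subgraph(comp)))
    pieces.sort(key=lambda g: min(g.nodes))
    width = max(4, len(str(len(pieces))))
    orthnets = [
        OrthNet(orthnet_id=f"ON_{i:0{width}d}", graph=piece)
        for i, piece in enumerate(pieces)
    ]
    for net in orthnets:
        flag_truncated_orfs(net)
    return orthnets


def flag_truncated_orfs(
    orthnet: OrthNet, low: float = 0.4, high: float = 0.8
) -> OrthNet:
    """Flag nodes whose ORF is short relative to their network neighbours.

    m = median ORF length of all nodes connected to the node by any edge
    type (excluding itself); flags: ``lt40`` if orf < low*m, ``lt80`` if
    orf < high*m, else ``none``.  Isolated nodes stay ``none``.
    """
    und = orthnet.graph.to_undirected(as_view=True)
    for n in orthnet.graph.nodes:
        neighbours = [v for v in und.neighbors(n) if v != n]
        if not neighbours:
            orthnet.graph.nodes[n]["truncation"] = "none"
            continue
        m = median(orthnet.graph.nodes[v]["orf_length"] for v in neighbours)
        orf = orthnet.graph.nodes[n]["orf_length"]
        if orf < low * m:
            flag = "lt40"
        elif orf < high * m:
            flag = "lt80"
        else:
            flag = "none"
        orthnet.graph.nodes[n]["truncation"] = flag
    return orthnet


def build_orthnets(
    genomes: dict[str, GenomeTable],
    besthits: dict[tuple[str, str], BestHitTable],
    clusters: dict[str, ParalogClusters] | None = None,
    params: CLParams = CLParams(),
    scheme: EdgeWeightScheme = EdgeWeightScheme(),
) -> tuple[list[OrthNet], dict[tuple[str, str], dict[str, CLRelation]], OnfinderContext]:
    """Run the full pipeline: pairwise classification through final OrthNets."""
    clusters = clusters or {}
    empty = {g: ParalogClusters(genome_id=g, clusters={}) for g in genomes}
    td_groups = {
        g: detect_tandem_duplicates(genomes[g], clusters.get(g, empty[g]), params.T)
        for g in genomes
    }
    projections: dict[tuple[str, str], Projection] = {}
    relations: dict[tuple[str, str], dict[str, CLRelation]] = {}
    for q in sorted(genomes):
        for t in sorted(genomes):
            if q == t or (q, t) not in besthits:
                continue
            proj = effective_projection(
                genomes[q], genomes[t], besthits[(q, t)], td_groups[q], td_groups[t]
            )
            projections[(q, t)] = proj
            relations[(q, t)] = classify_projection(proj, genomes[q], params)
    ctx = OnfinderContext(
        genomes=genomes,
        besthits=besthits,
        projections=projections,
        td_groups=td_groups,
        params=params,
    )
    graph = build_raw_network(relations, genomes, td_groups)
    repair_best_hit_pairs(graph, ctx)
    partition = cluster_graph(graph, scheme)
    orthnets = rewire_after_mcl(graph, partition, ctx)
    return orthnets, relations, ctx


# ---------------------------------------------------------------------------
# SIF export / import

def write_sif(orthnet: OrthNet, path: str | Path) -> None:
    """Write one OrthNet as a Simple Interaction File.

    Reciprocal pairs appear once as ``u <prop>_rc v`` (lexicographically
    smaller node first); unidirectional edges as ``u <prop>_uni v``;
    tandem edges as ``u td v``.
    """
    lines = []
    seen_rc: set[frozenset] = set()
    for u, v, data in sorted(orthnet.graph.edges(data=True)):
        if data["property"] == "td":
            lines.append(f"{u}\ttd\t{v}")
        elif data["reciprocity"] == "rc":
            pair = frozenset((u, v))
            if pair not in seen_rc:
                seen_rc.add(pair)
                a, b = sorted((u, v))
                lines.append(f"{a}\t{data['property']}_rc\t{b}")
        else:
            lines.append(f"{u}\t{data['property']}_uni\t{v}")
    Path(path).write_text("\n".join(sorted(lines)) + "\n")


def read_sif(path: str | Path, orthnet_id: str | None = None) -> OrthNet:
    """Read a SIF file back into an OrthNet (topology only).

    Node attributes not stored in SIF (ORF length, rank) default to 0; the
    genome is recovered from the ``genome|gene`` node naming.
    """
    graph = nx.DiGraph()

    def ensure(n: str) -> None:
        if n not in graph:
            genome_id, gene_id = split_key(n)
            graph.add_node(
                n, genome=genome_id, gene=gene_id, orf_length=0,
                scaffold="", rank=0, truncation="none",
            )

    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        u, etype, v = line.split("\t")
        ensure(u)
        ensure(v)
        if etype == "td":
            graph.add_edge(u, v, property="td", reciprocity="und", candidate_rank=0)
        else:
            prop, rec = etype.rsplit("_", 1)
            graph.add_edge(u, v, property=prop, reciprocity=rec, candidate_rank=1)
            if rec == "rc":
                graph.add_edge(v, u, property=prop, reciprocity=rec, candidate_rank=1)
    return OrthNet(orthnet_id=orthnet_id or Path(path).stem, graph=graph)


def orthnet_annotation(orthnets: list[OrthNet]) -> pd.DataFrame:
    """Per-locus network annotation for the combined TSV.

    Indexed by node key; columns: orthnet_id, per-genome copy numbers
    (``copies.<genome>``) and the locus's outgoing edge types.
    """
    rows = {}
    for net in orthnets:
        copies = net.copy_number
        for n in net.graph.nodes:
            out_types = sorted(
                f"{d['property']}_{d['reciprocity']}"
                for _, _, d in net.graph.out_edges(n, data=True)
            )
            row = {"orthnet_id": net.orthnet_id,
                   "out_edges": ",".join(out_types),
                   "truncation": net.graph.nodes[n]["truncation"]}
            for g, c in copies.items():
                row[f"copies.{g}"] = c
            rows[n] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    copy_cols = [c for c in frame.columns if c.startswith("copies.")]
    frame[copy_cols] = frame[copy_cols].fillna(0).astype(int)
    return frame
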