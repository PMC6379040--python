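"""Per-locus co-linearity classification between genome pairs.

For every ordered (query, target) genome pair, each query locus is labelled

* ``cl``     — co-linear: its best-hit sits inside a conserved gene-order
  chain with support on both sides,
* ``cl_end`` — at the end of a co-linear segment (chain support on one side
  only; inversion / indel / segmental-rearrangement breakpoints),
* ``tr``     — transposed: a best-hit exists but no chain support,
* ``ls``     — lineage-specific: no best-hit in the target genome,
* ``nd``     — not determined: the query scaffold is too short (< W loci)
  to support the scan, and the locus would otherwise be ``tr``.

The scan walks outward from the query locus, up to ``W`` effective loci in
each direction.  A neighbour joins the chain when its best-hit lies on the
same target scaffold as, and within ``G`` effective target ranks of, the
best-hit of the nearest already-chained locus on that side (the query's own
best-hit until a neighbour chains).  Lineage-specific loci are skipped and
tandem-duplicated paralogues (same cluster, separated by at most ``T``
intervening loci) collapse to a single effective position before scanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BestHitTable, GenomeTable, ParalogClusters

logger = logging.getLogger(__name__)

__all__ = [
    "CLParams",
    "CLRelation",
    "TdGroup",
    "Projection",
    "detect_tandem_duplicates",
    "effective_projection",
    "classify_locus",
    "clfinder_pairwise",
    "summarize_all_pairs",
    "erosion_profile",
    "chain_counts_arrays",
    "labels_from_counts",
]

LABELS = ("cl", "cl_end", "tr", "ls", "nd")


@dataclass(frozen=True)
class CLParams:
    """Tuning parameters of the co-linearity scan.

    W : window size, loci scanned on each side of the query locus.
    N : loci-in-chain threshold (includes the query locus itself).
    G : maximum effective-rank gap between consecutive loci-in-chain,
        measured on the target genome.
    T : maximum number of intervening loci between tandem duplicates,
        measured on the query genome.
    """

    W: int = 20
    N: int = 3
    G: int = 20
    T: int = 4

    def __post_init__(self) -> None:
        if self.W <= 0 or self.N <= 0 or self.G < 0 or self.T < 0:
            raise ValueError("require W > 0, N > 0, G >= 0, T >= 0")
        if self.N > 2 * self.W:
            raise ValueError("N must not exceed 2*W")


@dataclass
class CLRelation:
    """Classification of one query locus against one target genome."""

    query: str
    target_genome: str
    best_hit: str | None
    label: str
    n_chain_up: int = 0
    n_chain_down: int = 0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "ls") != (self.best_hit is None):
            raise ValueError("label 'ls' iff best_hit is absent")


@dataclass
class TdGroup:
    """A maximal run of tandem-duplicated paralogues on one scaffold."""

    genome_id: str
    scaffold_id: str
    cluster_id: str
    members: list[str]  # ordered by rank
    representative: str


def detect_tandem_duplicates(
    genome: GenomeTable, clusters: ParalogClusters, T: int = 4
) -> list[TdGroup]:
    """Chain same-cluster paralogues separated by <= T intervening loci.

    Chaining is transitive within a (scaffold, cluster) pair: members whose
    successive rank gaps are all <= T+1 form one maximal group.  Groups of
    size >= 2 are reported; the representative is the member with the
    longest ORF (ties: lowest rank).
    """
    groups: list[TdGroup] = []
    by_key: dict[tuple[str, str], list] = {}
    for locus in genome:
        cid = clusters.cluster_of(locus.gene_id)
        if cid is not None:
            by_key.setdefault((locus.scaffold_id, cid), []).append(locus)
    for (scaffold_id, cid) in sorted(by_key):
        members = sorted(by_key[(scaffold_id, cid)], key=lambda g: g.rank)
        run = [members[0]]
        for locus in members[1:]:
            if locus.rank - run[-1].rank <= T + 1:
                run.append(locus)
            else:
                if len(run) >= 2:
                    groups.append(_make_group(genome.genome_id, scaffold_id, cid, run))
                run = [locus]
        if len(run) >= 2:
            groups.append(_make_group(genome.genome_id, scaffold_id, cid, run))
    return groups


def _make_group(genome_id, scaffold_id, cid, run) -> TdGroup:
    rep = max(run, key=lambda g: (g.orf_length, -g.rank))
    return TdGroup(
        genome_id=genome_id,
        scaffold_id=scaffold_id,
        cluster_id=cid,
        members=[g.gene_id for g in run],
        representative=rep.gene_id,
    )


@dataclass
class Projection:
    """Effective coordinates of one (query, target) genome pair.

    Query loci with no best-hit are dropped and tandem groups collapse to a
    single effective position (the representative's).  Target ranks are the
    target genome's ranks with its tandem groups collapsed.
    """

    query_genome: str
    target_genome: str
    # per query scaffold, in effective-rank order:
    positions: dict[str, list[str]]  # scaffold -> retained gene ids
    th_scaf: dict[str, np.ndarray]  # scaffold -> target scaffold index of best-hit
    th_rank: dict[str, np.ndarray]  # scaffold -> target effective rank of best-hit
    raw_counts: dict[str, int]  # query scaffold -> raw locus count
    rep_of: dict[str, str]  # gene -> its td-group representative (or itself)
    group_members: dict[str, list[str]]  # representative -> all members
    best_hit_of: dict[str, str]  # retained gene -> best-hit gene id
    target_eff: dict[str, tuple[int, int]]  # target gene -> (scaf idx, eff rank)
    index_of: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index_of:
            self.index_of = {
                g: (scaf, i)
                for scaf, genes in self.positions.items()
                for i, g in enumerate(genes)
            }


def _collapse_target_ranks(
    target: GenomeTable, target_td: list[TdGroup]
) -> dict[str, tuple[int, int]]:
    """Map each target gene to (scaffold index, effective rank)."""
    group_of: dict[str, TdGroup] = {}
    for grp in target_td:
        for m in grp.members:
            group_of[m] = grp
    eff: dict[str, tuple[int, int]] = {}
    for si, scaffold_id in enumerate(target.scaffolds):
        next_rank = 0
        group_rank: dict[int, int] = {}
        for locus in target.scaffolds[scaffold_id]:
            grp = group_of.get(locus.gene_id)
            if grp is not None:
                key = id(grp)
                if key not in group_rank:
                    group_rank[key] = next_rank
                    next_rank += 1
                eff[locus.gene_id] = (si, group_rank[key])
            else:
                eff[locus.gene_id] = (si, next_rank)
                next_rank += 1
    return eff


def effective_projection(
    query: GenomeTable,
    target: GenomeTable,
    besthits: BestHitTable,
    query_td: list[TdGroup] | None = None,
    target_td: list[TdGroup] | None = None,
) -> Projection:
    """Project query loci onto collapsed target coordinates.

    Unresolvable best-hit ids (absent from the target table) are treated as
    missing hits and logged.
    """
    query_td = query_td or []
    target_td = target_td or []
    target_eff = _collapse_target_ranks(target, target_td)

    rep_of: dict[str, str] = {}
    group_members: dict[str, list[str]] = {}
    for grp in query_td:
        group_members[grp.representative] = list(grp.members)
        for m in grp.members:
            rep_of[m] = grp.representative

    positions: dict[str, list[str]] = {}
    th_scaf: dict[str, np.ndarray] = {}
    th_rank: dict[str, np.ndarray] = {}
    raw_counts: dict[str, int] = {}
    best_hit_of: dict[str, str] = {}
    n_unresolved = 0
    for scaffold_id, loci in query.scaffolds.items():
        raw_counts[scaffold_id] = len(loci)
        genes: list[str] = []
        scafs: list[int] = []
        ranks: list[int] = []
        for locus in loci:
            rep = rep_of.get(locus.gene_id, locus.gene_id)
            if rep != locus.gene_id:
                continue  # collapsed into its representative's position
            hit = besthits.best_hit(locus.gene_id)
            if hit is None:
                continue  # lineage-specific: skipped by the scan
            if hit not in target_eff:
                n_unresolved += 1
                continue
            si, er = target_eff[hit]
            genes.append(locus.gene_id)
            scafs.append(si)
            ranks.append(er)
            best_hit_of[locus.gene_id] = hit
        positions[scaffold_id] = genes
        th_scaf[scaffold_id] = np.asarray(scafs, dtype=np.int64)
        th_rank[scaffold_id] = np.asarray(ranks, dtype=np.int64)
    if n_unresolved:
        logger.warning(
            "%s->%s: dropped %d best-hits not present in the target table",
            query.genome_id, target.genome_id, n_unresolved,
        )
    return Projection(
        query_genome=query.genome_id,
        target_genome=target.genome_id,
        positions=positions,
        th_scaf=th_scaf,
        th_rank=th_rank,
        raw_counts=raw_counts,
        rep_of=rep_of,
        group_members=group_members,
        best_hit_of=best_hit_of,
        target_eff=target_eff,
    )


def chain_counts_arrays(
    th_scaf: np.ndarray, th_rank: np.ndarray, W: int, G: int
) -> tuple[np.ndarray, np.ndarray]:
    """Chained-neighbour counts for every position of one query scaffold.

    Vectorized over positions: for each side, the anchor starts at the
    query's own best-hit and advances to each neighbour that chains; a
    neighbour chains when its best-hit shares the anchor's target scaffold
    and lies within G effective ranks of it.  The window is truncated at the
    scaffold boundaries.
    """
    n = len(th_rank)
    up = np.zeros(n, dtype=np.int32)
    down = np.zeros(n, dtype=np.int32)
    if n == 0:
        return up, down
    base = np.arange(n)
    for side, cnt in ((-1, up), (1, down)):
        anchor_r = th_rank.copy()
        anchor_s = th_scaf.copy()
        for k in range(1, W + 1):
            idx = base + side * k
            valid = (idx >= 0) & (idx < n)
            safe = np.clip(idx, 0, n - 1)
            cand_r = th_rank[safe]
            cand_s = th_scaf[safe]
            ok = valid & (cand_s == anchor_s) & (
                np.abs(cand_r - anchor_r) <= G
            )
            cnt += ok
            anchor_r = np.where(ok, cand_r, anchor_r)
            anchor_s = np.where(ok, cand_s, anchor_s)
    return up, down


def labels_from_counts(
    up: np.ndarray, down: np.ndarray, N: int
) -> np.ndarray:
    """Map chained-neighbour counts to cl / cl_end / tr labels."""
    total = 1 + up + down
    both = (up > 0) & (down > 0)
    one = (up > 0) ^ (down > 0)
    labels = np.full(len(up), "tr", dtype=object)
    labels[(total >= N) & both] = "cl"
    labels[(total >= N) & one] = "cl_end"
    return labels


def _scan_one(
    th_scaf: np.ndarray,
    th_rank: np.ndarray,
    i: int,
    W: int,
    G: int,
    override: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Chained-neighbour counts for a single position (loop form).

    ``override`` imposes a (target scaffold, effective rank) best-hit at
    position i, used when re-classifying a repaired best-hit pair.
    """
    n = len(th_rank)
    own = override if override is not None else (th_scaf[i], th_rank[i])
    counts = []
    for side in (-1, 1):
        anchor_s, anchor_r = own
        c = 0
        for k in range(1, W + 1):
            j = i + side * k
            if j < 0 or j >= n:
                break
            if th_scaf[j] == anchor_s and abs(int(th_rank[j]) - int(anchor_r)) <= G:
                c += 1
                anchor_s, anchor_r = th_scaf[j], th_rank[j]
        counts.append(c)
    return counts[0], counts[1]


def classify_locus(
    gene_id: str,
    projection: Projection,
    params: CLParams,
    imposed_hit: str | None = None,
) -> CLRelation:
    """Classify one query locus; optionally impose an alternative best-hit.

    The locus must be a retained (non-ls, representative) position of the
    projection unless a hit is imposed on a previously lineage-specific
    locus, which is unsupported and raises KeyError.
    """
    scaffold_id, i = projection.index_of[gene_id]
    override = None
    hit = projection.best_hit_of[gene_id]
    if imposed_hit is not None:
        override = projection.target_eff[imposed_hit]
        hit = imposed_hit
    up, down = _scan_one(
        projection.th_scaf[scaffold_id],
        projection.th_rank[scaffold_id],
        i,
        params.W,
        params.G,
        override=override,
    )
    label = str(labels_from_counts(np.array([up]), np.array([down]), params.N)[0])
    if label == "tr" and projection.raw_counts[scaffold_id] < params.W:
        label = "nd"
    return CLRelation(
        query=gene_id,
        target_genome=projection.target_genome,
        best_hit=hit,
        label=label,
        n_chain_up=up,
        n_chain_down=down,
    )


def clfinder_pairwise(
    query: GenomeTable,
    target: GenomeTable,
    besthits: BestHitTable,
    query_clusters: ParalogClusters | None = None,
    target_clusters: ParalogClusters | None = None,
    params: CLParams = CLParams(),
) -> dict[str, CLRelation]:
    """Label every query locus against one target genome.

    Tandem-group members inherit the label computed for their group
    representative; loci without a best-hit are ``ls``; would-be ``tr``
    loci on scaffolds shorter than W loci become ``nd``.
    """
    empty = ParalogClusters(genome_id="", clusters={})
    query_td = detect_tandem_duplicates(query, query_clusters or empty, params.T)
    target_td = detect_tandem_duplicates(target, target_clusters or empty, params.T)
    proj = effective_projection(query, target, besthits, query_td, target_td)
    return classify_projection(proj, query, params)


def classify_projection(
    proj: Projection, query: GenomeTable, params: CLParams
) -> dict[str, CLRelation]:
    """Vectorized classification of all retained positions of a projection,
    expanded back to every locus of the query genome."""
    rep_result: dict[str, tuple[str, str, int, int]] = {}
    for scaffold_id, genes in proj.positions.items():
        up, down = chain_counts_arrays(
            proj.th_scaf[scaffold_id], proj.th_rank[scaffold_id], params.W, params.G
        )
        labels = labels_from_counts(up, down, params.N)
        short = proj.raw_counts[scaffold_id] < params.W
        for i, g in enumerate(genes):
            label = labels[i]
            if label == "tr" and short:
                label = "nd"
            rep_result[g] = (label, proj.best_hit_of[g], int(up[i]), int(down[i]))

    out: dict[str, CLRelation] = {}
    for locus in query:
        gene = locus.gene_id
        rep = proj.rep_of.get(gene, gene)
        if rep in rep_result:
            label, hit, cu, cd = rep_result[rep]
            out[gene] = CLRelation(
                query=gene,
                target_genome=proj.target_genome,
                best_hit=hit,
                label=label,
                n_chain_up=cu,
                n_chain_down=cd,
            )
        else:
            out[gene] = CLRelation(
                query=gene,
                target_genome=proj.target_genome,
                best_hit=None,
                label="ls",
            )
    return out


def summarize_all_pairs(
    tables: dict[tuple[str, str], dict[str, CLRelation]],
    genomes: dict[str, GenomeTable],
    td_groups: dict[str, list[TdGroup]] | None = None,
) -> pd.DataFrame:
    """Pairwise label counts plus per-genome tandem-duplication totals.

    ``cl_end`` is merged into ``cl``.  Every ordered pair of genomes must be
    present; for each pair the four counts sum to the query genome's locus
    count.
    """
    ids = sorted(genomes)
    missing = [
        (q, t) for q in ids for t in ids if q != t and (q, t) not in tables
    ]
    if missing:
        raise ValueError(f"missing pairwise tables: {missing}")
    rows = []
    for q in ids:
        td = (td_groups or {}).get(q, [])
        for t in ids:
            if q == t:
                continue
            rels = tables[(q, t)]
            counts = {"cl": 0, "tr": 0, "ls": 0, "nd": 0}
            for rel in rels.values():
                counts["cl" if rel.label == "cl_end" else rel.label] += 1
            total = sum(counts.values())
            if total != genomes[q].n_loci:
                raise AssertionError(
                    f"{q}->{t}: labels cover {total} loci, expected {genomes[q].n_loci}"
                )
            rows.append(
                {
                    "query": q,
                    "target": t,
                    "n_loci": genomes[q].n_loci,
                    **counts,
                    "td_events": len(td),
                    "td_genes": sum(len(g.members) for g in td),
                }
            )
    return pd.DataFrame(rows)


def erosion_profile(
    query: GenomeTable, target: GenomeTable, besthits: BestHitTable
) -> dict[str, int]:
    """Histogram of target-rank displacement between best-hits of
    immediately neighbouring query loci.

    For each query locus n whose successor n+1 (same scaffold) also has a
    best-hit, d = |target rank difference| of the two best-hits; bins:
    ``d<=1``, ``2-20``, ``>20``, ``diff_scaffold``.
    """
    bins = {"d<=1": 0, "2-20": 0, ">20": 0, "diff_scaffold": 0}
    for scaffold_id, loci in query.scaffolds.items():
        for a, b in zip(loci, loci[1:]):
            ha, hb = besthits.best_hit(a.gene_id), besthits.best_hit(b.gene_id)
            if ha is None or hb is None:
                continue
            la, lb = target.get(ha), target.get(hb)
            if la is None or lb is None:
                continue
            if la.scaffold_id != lb.scaffold_id:
                bins["diff_scaffold"] += 1
                continue
            d = abs(la.rank - lb.rank)
            if d <= 1:
                bins["d<=1"] += 1
            elif d <= 20:
                bins["2-20"] += 1
            else:
                bins[">20"] += 1
    return bins
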