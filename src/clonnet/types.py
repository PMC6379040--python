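"""Core in-memory containers shared by all pipeline stages.

A genome is represented as an ordered table of primary protein-coding gene
models (:class:`GeneLocus`), ranked along each scaffold.  Homology between a
pair of genomes enters the pipeline as a ranked best-hit list per query locus
(:class:`BestHitTable`), and within-genome paralogy as precomputed clusters
(:class:`ParalogClusters`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GeneLocus",
    "GenomeTable",
    "BestHitTable",
    "ParalogClusters",
]


@dataclass
class GeneLocus:
    """One primary protein-coding gene model.

    Coordinates are 1-based inclusive genomic bp, as read from GTF/GFF.
    ``rank`` is the ordinal position of the locus on its scaffold, ordered by
    ascending start (ties: ascending end, then gene_id), starting at 0.
    ``orf_length`` is the total CDS length of the primary transcript; for
    spliced genes it is typically much smaller than ``end - start + 1`` and
    no ordering between the two is assumed.
    """

    gene_id: str
    genome_id: str
    scaffold_id: str
    strand: str
    start: int
    end: int
    orf_length: int
    rank: int = -1
    paralog_cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.orf_length < 3:
            raise ValueError(f"{self.gene_id}: orf_length {self.orf_length} < 3")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


class GenomeTable:
    """All loci of one genome, grouped by scaffold and ranked.

    Ranks within a scaffold are consecutive integers starting at 0.
    """

    def __init__(self, genome_id: str, loci: Iterable[GeneLocus]):
        self.genome_id = genome_id
        self._by_id: dict[str, GeneLocus] = {}
        by_scaffold: dict[str, list[GeneLocus]] = {}
        for locus in loci:
            if locus.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {locus.gene_id!r}")
            if locus.genome_id != genome_id:
                raise ValueError(
                    f"{locus.gene_id}: genome_id {locus.genome_id!r} != {genome_id!r}"
                )
            self._by_id[locus.gene_id] = locus
            by_scaffold.setdefault(locus.scaffold_id, []).append(locus)
        self.scaffolds: dict[str, list[GeneLocus]] = {}
        for scaffold_id in sorted(by_scaffold):
            ordered = sorted(
                by_scaffold[scaffold_id],
                key=lambda g: (g.start, g.end, g.gene_id),
            )
            for rank, locus in enumerate(ordered):
                locus.rank = rank
            self.scaffolds[scaffold_id] = ordered

    @property
    def n_loci(self) -> int:
        return len(self._by_id)

    def __len__(self) -> int:
        return self.n_loci

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> GeneLocus | None:
        return self._by_id.get(gene_id)

    def __iter__(self) -> Iterator[GeneLocus]:
        for scaffold_id in self.scaffolds:
            yield from self.scaffolds[scaffold_id]

    def gene_ids(self) -> list[str]:
        return [locus.gene_id for locus in self]


class BestHitTable:
    """Ranked candidate homologues per query locus, in one target genome.

    ``entries`` maps query gene_id to a list of ``(target_gene_id, score)``
    pairs, best first, at most 10 long.  The first entry is the best-hit.
    """

    MAX_CANDIDATES = 10

    def __init__(
        self,
        query_genome: str,
        target_genome: str,
        entries: dict[str, list[tuple[str, float]]] | None = None,
    ):
        if query_genome == target_genome:
            raise ValueError("query and target genome must differ")
        self.query_genome = query_genome
        self.target_genome = target_genome
        self.entries: dict[str, list[tuple[str, float]]] = {}
        if entries:
            for query, hits in entries.items():
                self.add(query, hits)

    def add(self, query: str, hits: list[tuple[str, float]]) -> None:
        seen: dict[str, float] = {}
        order: list[str] = []
        for target, score in hits:
            if target not in seen:
                seen[target] = score
                order.append(target)
            elif score > seen[target]:
                seen[target] = score
        ranked = sorted(order, key=lambda t: -seen[t])
        self.entries[query] = [
            (t, seen[t]) for t in ranked[: self.MAX_CANDIDATES]
        ]

    def best_hit(self, query: str) -> str | None:
        hits = self.entries.get(query)
        return hits[0][0] if hits else None

    def candidates(self, query: str) -> list[str]:
        return [t for t, _ in self.entries.get(query, [])]

    def candidate_rank(self, query: str, target: str) -> int | None:
        """1-based rank of ``target`` in the candidate list, or None."""
        for i, (t, _) in enumerate(self.entries.get(query, []), start=1):
            if t == target:
                return i
        return None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ParalogClusters:
    """Within-genome paralogue clusters (OrthoMCL-style groups).

    A gene belongs to at most one cluster; singleton clusters are dropped at
    load time.
    """

    genome_id: str
    clusters: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cluster_id, members in self.clusters.items():
            for gene_id in members:
                if gene_id in seen:
                    raise ValueError(
                        f"gene {gene_id!r} in clusters "
                        f"{seen[gene_id]!r} and {cluster_id!r}"
                    )
                seen[gene_id] = cluster_id
        self._cluster_of = seen

    def cluster_of(self, gene_id: str) -> str | None:
        return self._cluster_of.get(gene_id)

    def __len__(self) -> int:
        return len(self.clusters)
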