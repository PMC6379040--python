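"""Shared fixtures: compact builders for genomes, best-hit maps and graphs."""

from __future__ import annotations

import pytest

from clonnet.types import BestHitTable, GeneLocus, GenomeTable, ParalogClusters


def make_genome(
    genome_id: str,
    scaffolds: dict[str, list[str]],
    orf: int | dict[str, int] = 900,
) -> GenomeTable:
    """Genome with the given gene order per scaffold; 1 kb locus spacing."""
    loci = []
    for scaffold_id, genes in scaffolds.items():
        for i, gene_id in enumerate(genes):
            length = orf[gene_id] if isinstance(orf, dict) else orf
            loci.append(
                GeneLocus(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    scaffold_id=scaffold_id,
                    strand="+",
                    start=i * 1000 + 1,
                    end=i * 1000 + length + 50,
                    orf_length=length,
                )
            )
    return GenomeTable(genome_id, loci)


def make_hits(
    query_genome: str,
    target_genome: str,
    mapping: dict[str, list[str] | str],
    score: float = 100.0,
) -> BestHitTable:
    """Best-hit table from a {query: best..worst candidates} mapping."""
    table = BestHitTable(query_genome, target_genome)
    for query, targets in mapping.items():
        if isinstance(targets, str):
            targets = [targets]
        table.add(query, [(t, score - i) for i, t in enumerate(targets)])
    return table


def identity_pair(
    n: int, qg: str = "GA", tg: str = "GB"
) -> tuple[GenomeTable, GenomeTable, BestHitTable, BestHitTable]:
    """Two identical single-scaffold genomes with mutual identity hits."""
    q_names = [f"{qg.lower()}{i:03d}" for i in range(n)]
    t_names = [f"{tg.lower()}{i:03d}" for i in range(n)]
    query = make_genome(qg, {"s1": q_names})
    target = make_genome(tg, {"s1": t_names})
    fwd = make_hits(qg, tg, dict(zip(q_names, t_names)))
    rev = make_hits(tg, qg, dict(zip(t_names, q_names)))
    return query, target, fwd, rev


@pytest.fixture
def empty_clusters():
    def _make(genome_id: str) -> ParalogClusters:
        return ParalogClusters(genome_id=genome_id, clusters={})

    return _make
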