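"""Synthetic data with known ground truth.

Three generators feed development and testing:

* shuffled genome pairs — two genomes with a one-to-one best-hit bijection
  and independently randomized gene orders; the false-positive calibration
  of the co-linearity scan (no common ancestry, so every co-linear call is
  a false positive);
* evolved genome sets — an ancestral gene list evolves along a species
  tree with per-branch tandem-duplication, transposition,
  transposition-duplication and deletion events, emitting the annotation /
  best-hit / paralogue-cluster inputs of the pipeline together with the
  planted truth;
* synthetic window sequences with a planted duplicated segment, for the
  homologous-genome-segment aligner.

All outputs are reproducible bit-for-bit given (config, seed); internal
randomness is derived per-operation from the master seed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo

from .clfinder import CLParams, chain_counts_arrays, clfinder_pairwise, labels_from_counts
from .onfinder import node_key
from .types import BestHitTable, GeneLocus, GenomeTable, ParalogClusters

__all__ = [
    "SimConfig",
    "PlantedEvent",
    "GroundTruth",
    "FalsePositiveResult",
    "simulate_shuffled_pair",
    "false_positive_simulation",
    "evolve_genomes",
    "synth_sequences_for_trd",
]


@dataclass(frozen=True)
class SimConfig:
    """Conditions of an evolved-genome simulation.

    Event rates are per locus per branch.  ORF lengths are drawn from a
    log-normal roughly matching plant protein-coding genes (median about
    1.2 kb) and rounded to codon multiples.
    """

    n_loci: int = 27_000
    p_td: float = 0.01
    p_tr: float = 0.01
    p_trd: float = 0.01
    p_del: float = 0.005
    orf_log_mean: float = 7.09  # exp(7.09) ~ 1200 bp
    orf_log_sd: float = 0.45
    p_trd_truncation: float = 0.5
    # transposed copies must land at least this many loci away from their
    # source, so that a planted transposition actually leaves the syntenic
    # neighbourhood instead of degenerating into a tandem duplication
    min_move: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.p_td, self.p_tr, self.p_trd, self.p_del):
            if not 0.0 <= r <= 1.0:
                raise ValueError("event rates must be in [0, 1]")


@dataclass
class PlantedEvent:
    event_type: str  # td | tr | trd | del
    genomes: frozenset[str]  # leaves below the branch carrying the event
    ancestral_locus: int
    source_copy: int
    new_copy: int | None
    truncated: bool = False


@dataclass
class GroundTruth:
    """Expected outcome of an evolved-genome simulation."""

    events: list[PlantedEvent] = field(default_factory=list)
    # ancestral locus -> expected OrthNet node keys across all leaf genomes
    orthnet_nodes: dict[int, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shuffled pairs and the false-positive calibration


def simulate_shuffled_pair(
    n_loci: int, seed: int
) -> tuple[GenomeTable, GenomeTable, BestHitTable]:
    """Two single-scaffold genomes with a bijective best-hit map and an
    independently uniformly permuted target gene order."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_loci)  # target rank of query locus i
    width = len(str(n_loci))
    q_loci = [
        GeneLocus(
            gene_id=f"qa{i:0{width}d}", genome_id="simQ", scaffold_id="chr1",
            strand="+", start=i * 1000 + 1, end=i * 1000 + 901, orf_length=900,
        )
        for i in range(n_loci)
    ]
    t_loci = [
        GeneLocus(
            gene_id=f"tb{i:0{width}d}", genome_id="simT", scaffold_id="chr1",
            strand="+", start=int(perm[i]) * 1000 + 1,
            end=int(perm[i]) * 1000 + 901, orf_length=900,
        )
        for i in range(n_loci)
    ]
    query = GenomeTable("simQ", q_loci)
    target = GenomeTable("simT", t_loci)
    hits = BestHitTable("simQ", "simT")
    for i in range(n_loci):
        hits.add(f"qa{i:0{width}d}", [(f"tb{i:0{width}d}", 100.0)])
    return query, target, hits


@dataclass
class FalsePositiveResult:
    counts: np.ndarray  # per-iteration false-positive cl + cl_end counts
    mean: float
    sd: float
    pct_mean: float
    pct_sd: float
    n_loci: int
    n_iter: int


def false_positive_simulation(
    n_iter: int,
    n_loci: int = 27_000,
    params: CLParams = CLParams(),
    seed: int = 0,
    fast: bool = True,
) -> FalsePositiveResult:
    """Count loci falsely labelled co-linear between shuffled genome pairs.

    The fast path feeds the permutation directly to the vectorized chain
    scanner (equivalent to the full pipeline on these inputs, which have a
    single scaffold, no ls loci and no tandem groups — asserted by tests);
    ``fast=False`` runs the full per-pair classification.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_iter, dtype=np.int64)
    for it in range(n_iter):
        if fast:
            perm = rng.permutation(n_loci)
            scaf = np.zeros(n_loci, dtype=np.int64)
            up, down = chain_counts_arrays(scaf, perm, params.W, params.G)
            labels = labels_from_counts(up, down, params.N)
            counts[it] = int(np.sum((labels == "cl") | (labels == "cl_end")))
        else:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            q, t, hits = simulate_shuffled_pair(n_loci, sub_seed)
            rels = clfinder_pairwise(q, t, hits, params=params)
            counts[it] = sum(
                1 for r in rels.values() if r.label in ("cl", "cl_end")
            )
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_iter > 1 else 0.0
    return FalsePositiveResult(
        counts=counts,
        mean=mean,
        sd=sd,
        pct_mean=100.0 * mean / n_loci,
        pct_sd=100.0 * sd / n_loci,
        n_loci=n_loci,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# evolved genomes


@dataclass
class _Gene:
    """One gene copy during the simulated evolution."""

    ancestral_locus: int
    copy_id: int
    orf_length: int
    # genealogy: one token per divergence-relevant event since the root
    hist: tuple[int, ...]


def evolve_genomes(
    config: SimConfig,
    tree_newick: str,
) -> tuple[
    dict[str, GenomeTable],
    dict[tuple[str, str], BestHitTable],
    dict[str, ParalogClusters],
    GroundTruth,
]:
    """Evolve an ancestral gene list along a newick species tree.

    Per branch, each locus independently undergoes tandem duplication
    (copy inserted immediately downstream), transposition (moved to a
    random position), transposition-duplication (copy inserted at a random
    position, optionally with a truncated ORF) or deletion.  Best-hit
    candidate lists are derived from the gene genealogy: the score decays
    with the genealogical distance between two copies, so original
    orthologue pairs are reciprocal best-hits while younger duplicates
    rank below them.
    """
    tree = Phylo.read(_io.StringIO(tree_newick), "newick")
    leaves = [cl.name for cl in tree.get_terminals()]
    if len(set(leaves)) != len(leaves) or any(n is None for n in leaves):
        raise ValueError("tree must have unique named leaves")
    master = np.random.SeedSequence(config.seed)
    ss_orf, ss_evo = master.spawn(2)
    rng_orf = np.random.default_rng(ss_orf)
    orfs = np.exp(
        rng_orf.normal(config.orf_log_mean, config.orf_log_sd, config.n_loci)
    )
    orfs = (np.maximum(orfs, 300.0) // 3).astype(int) * 3

    truth = GroundTruth()
    counter = {"copy": config.n_loci, "token": 0}
    ancestral = [
        _Gene(ancestral_locus=i, copy_id=i, orf_length=int(orfs[i]), hist=())
        for i in range(config.n_loci)
    ]

    genomes_state: dict[str, list[_Gene]] = {}

    def leaves_below(clade) -> frozenset[str]:
        return frozenset(t.name for t in clade.get_terminals())

    def descend(clade, state: list[_Gene], rng: np.random.Generator) -> None:
        for child in clade.clades:
            child_rng = np.random.default_rng(
                rng.integers(0, 2**31 - 1)
            )
            counter["token"] += 1
            branch_token = counter["token"]
            new_state = [
                _Gene(g.ancestral_locus, g.copy_id, g.orf_length,
                      g.hist + (branch_token,))
                for g in state
            ]
            new_state = _apply_branch_events(
                new_state, config, child_rng, leaves_below(child), truth, counter
            )
            if child.is_terminal():
                genomes_state[child.name] = new_state
            else:
                descend(child, new_state, child_rng)

    descend(tree.root, ancestral, np.random.default_rng(ss_evo))

    genomes: dict[str, GenomeTable] = {}
    gene_objects: dict[str, dict[str, _Gene]] = {}
    for name in sorted(genomes_state):
        state = genomes_state[name]
        loci = []
        objs: dict[str, _Gene] = {}
        for pos, g in enumerate(state):
            gene_id = f"{name}_g{g.copy_id:06d}"
            objs[gene_id] = g
            loci.append(
                GeneLocus(
                    gene_id=gene_id, genome_id=name, scaffold_id="chr1",
                    strand="+", start=pos * 2000 + 1,
                    end=pos * 2000 + g.orf_length + 200,
                    orf_length=g.orf_length,
                )
            )
            truth.orthnet_nodes.setdefault(g.ancestral_locus, set()).add(
                node_key(name, gene_id)
            )
        genomes[name] = GenomeTable(name, loci)
        gene_objects[name] = objs

    clusters = {
        name: _paralog_clusters(name, gene_objects[name]) for name in genomes
    }
    besthits = _derive_besthits(genomes, gene_objects)
    return genomes, besthits, clusters, truth


def _apply_branch_events(
    state: list[_Gene],
    config: SimConfig,
    rng: np.random.Generator,
    below: frozenset[str],
    truth: GroundTruth,
    counter: dict[str, int],
) -> list[_Gene]:
    n = len(state)
    draws = rng.random((n, 4))
    trunc_draws = rng.random(n)
    out: list[_Gene] = []
    # (type, new gene, source gene for distance constraints, insert hint)
    pending: list[tuple[str, _Gene, _Gene, int]] = []
    for i, g in enumerate(state):
        p_del, p_td, p_tr, p_trd = draws[i]
        if p_del < config.p_del:
            truth.events.append(
                PlantedEvent("del", below, g.ancestral_locus, g.copy_id, None)
            )
            continue
        out.append(g)
        if p_td < config.p_td:
            new = _copy_gene(g, counter)
            truth.events.append(
                PlantedEvent("td", below, g.ancestral_locus, g.copy_id, new.copy_id)
            )
            pending.append(("td", new, g, len(out)))
        if p_tr < config.p_tr:
            truth.events.append(
                PlantedEvent("tr", below, g.ancestral_locus, g.copy_id, g.copy_id)
            )
            pending.append(("tr", out.pop(), g, -1))
        if p_trd < config.p_trd:
            new = _copy_gene(g, counter)
            truncated = trunc_draws[i] < config.p_trd_truncation
            if truncated:
                frac = 0.3 + 0.4 * rng.random()
                new.orf_length = max(300, int(new.orf_length * frac) // 3 * 3)
            truth.events.append(
                PlantedEvent(
                    "trd", below, g.ancestral_locus, g.copy_id, new.copy_id,
                    truncated=truncated,
                )
            )
            pending.append(("trd", new, g, -1))
    # tandem copies go right after their source; tr/trd copies relocate to
    # a random position at least min_move loci away from the source
    for kind, gene, source, hint in pending:
        if kind == "td" and 0 <= hint <= len(out):
            out.insert(min(hint, len(out)), gene)
        else:
            try:
                src_idx = out.index(source)
            except ValueError:  # source itself transposed or deleted
                src_idx = None
            choices = [
                p for p in range(len(out) + 1)
                if src_idx is None or abs(p - src_idx) >= config.min_move
            ] or list(range(len(out) + 1))
            out.insert(choices[int(rng.integers(0, len(choices)))], gene)
    return out


def _copy_gene(g: _Gene, counter: dict[str, int]) -> _Gene:
    counter["copy"] += 1
    counter["token"] += 1
    return _Gene(
        ancestral_locus=g.ancestral_locus,
        copy_id=counter["copy"],
        orf_length=g.orf_length,
        hist=g.hist + (counter["token"],),
    )


def _paralog_clusters(name: str, objs: dict[str, _Gene]) -> ParalogClusters:
    by_locus: dict[int, list[str]] = {}
    for gene_id, g in objs.items():
        by_locus.setdefault(g.ancestral_locus, []).append(gene_id)
    clusters = {
        f"CL{locus}": set(members)
        for locus, members in by_locus.items()
        if len(members) >= 2
    }
    return ParalogClusters(genome_id=name, clusters=clusters)


def _genealogy_distance(a: _Gene, b: _Gene) -> int:
    common = 0
    for x, y in zip(a.hist, b.hist):
        if x != y:
            break
        common += 1
    return len(a.hist) + len(b.hist) - 2 * common


def _derive_besthits(
    genomes: dict[str, GenomeTable],
    gene_objects: dict[str, dict[str, _Gene]],
) -> dict[tuple[str, str], BestHitTable]:
    by_locus: dict[str, dict[int, list[str]]] = {}
    for name, objs in gene_objects.items():
        loc: dict[int, list[str]] = {}
        for gene_id, g in objs.items():
            loc.setdefault(g.ancestral_locus, []).append(gene_id)
        by_locus[name] = loc
    tables: dict[tuple[str, str], BestHitTable] = {}
    for q in sorted(genomes):
        for t in sorted(genomes):
            if q == t:
                continue
            table = BestHitTable(q, t)
            for gene_id, g in gene_objects[q].items():
                cands = by_locus[t].get(g.ancestral_locus, [])
                scored = sorted(
                    (
                        (
                            100.0
                            - 5.0 * _genealogy_distance(g, gene_objects[t][c]),
                            c,
                        )
                        for c in cands
                    ),
                    key=lambda sc: (-sc[0], sc[1]),
                )
                if scored:
                    table.add(gene_id, [(c, s) for s, c in scored])
            tables[(q, t)] = table
    return tables


# ---------------------------------------------------------------------------
# synthetic sequences for HGS detection


def synth_sequences_for_trd(
    gene_length: int,
    flank: int = 5_000,
    duplicated_span: tuple[int, int] | None = None,
    identity: float = 1.0,
    seed: int = 0,
) -> tuple[str, str, dict[str, tuple[int, int]]]:
    """A CL window, a Tr window with a planted duplicated segment, and the
    true segment intervals.

    The CL window is random sequence with the gene occupying its centre
    ``[flank, flank + gene_length)``.  ``duplicated_span`` (CL-window
    coordinates; default: the gene body) is copied into the centre of an
    independent random Tr window with per-base substitutions bringing it
    to the requested identity.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    win_len = gene_length + 2 * flank
    cl = rng.choice(bases, size=win_len)
    tr = rng.choice(bases, size=win_len)
    if duplicated_span is None:
        duplicated_span = (flank, flank + gene_length)
    ds, de = duplicated_span
    if not (0 <= ds < de <= win_len):
        raise ValueError("duplicated_span outside the CL window")
    span = cl[ds:de].copy()
    sub = rng.random(len(span)) >= identity
    if sub.any():
        shift = rng.integers(1, 4, size=int(sub.sum()))
        base_idx = np.searchsorted(bases, span[sub])
        span[sub] = bases[(base_idx + shift) % 4]
    ins = (win_len - len(span)) // 2
    tr[ins : ins + len(span)] = span
    truth = {
        "gene": (flank, flank + gene_length),
        "cl_segment": (ds, de),
        "tr_segment": (ins, ins + len(span)),
    }
    return "".join(cl), "".join(tr), truth
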