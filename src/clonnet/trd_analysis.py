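"""Detection and characterization of transposition-duplication (tr-d) events.

A tr-d event duplicates a gene into a genomic context where synteny is
lost.  Inside an OrthNet the donor ("CL copy") is the duplicated-genome
node with the most co-linear edges to other genomes; the acceptor
("Tr copies") are the remaining copies whose edges to the co-linear
orthologues are all unidirectional ``tr``.  The duplicated genomic segment
(Homologous Genome Segment, HGS) is recovered by a seed-extend-chain local
aligner run on the gene +/- 5 kb windows of the two copies, and events are
classed

* ``incomplete`` — the HGS covers only part of the CL-copy gene,
* ``complete``   — the HGS contains the whole gene,
* ``gene_only``  — complete, with the HGS barely exceeding the coding
  region (< 120% of its length): no intergenic conservation survives.

A randomization test (shuffling observed HGS lengths over random positions
near the CL-copy genes) gives the expected occurrence of complete and
gene-only events under chance, and pairwise substitution rates at 4-fold
degenerate codon sites provide a relative age for each duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy import stats

from .onfinder import OrthNet, split_key

logger = logging.getLogger(__name__)

__all__ = [
    "TrdRoles",
    "HGS",
    "TrdEvent",
    "ShuffleResult",
    "FourDRate",
    "identify_trd_roles",
    "detect_hgs",
    "classify_trd",
    "classify_tr_orf",
    "shuffle_expected_occurrence",
    "fourfold_degenerate_rate",
    "categorize_shared_trd",
    "collect_trd_events",
    "events_to_frame",
]

WINDOW_FLANK = 5_000  # bp of intergenic context on each side of a gene


@dataclass
class TrdRoles:
    """CL/Tr role assignment for one genome inside one OrthNet."""

    genome_id: str
    cl_copies: list[str]  # node keys, incl. tandem copies of the donor
    representative: str | None  # longest-ORF CL copy
    tr_copies: list[str]
    excluded: list[str]  # same-genome nodes fitting neither role


@dataclass
class HGS:
    """One homologous genome segment between a CL and a Tr window.

    Intervals are 0-based half-open within their windows; ``strand`` is the
    orientation of the Tr-side interval relative to the CL side.
    """

    cl_start: int
    cl_end: int
    tr_start: int
    tr_end: int
    strand: str
    identity: float
    score: float

    @property
    def length(self) -> int:
        return self.cl_end - self.cl_start


@dataclass
class TrdEvent:
    """One transposition-duplication event (one Tr copy)."""

    orthnet_id: str
    genome_id: str
    cl_copy: str
    tr_copy: str
    hgs: list[HGS] = field(default_factory=list)
    trd_class: str | None = None  # incomplete | complete | gene_only
    tr_orf_status: str | None = None  # complete | truncated
    sharing: str = "lineage_specific"  # lineage_specific | ind_parallel | tr_cl


@dataclass
class ShuffleResult:
    """Randomization null for the occurrence count of one tr-d class."""

    observed_count: int | None
    expected_mean: float
    expected_sd: float
    p_value: float | None
    n_iter: int
    min_overlap: int


@dataclass
class FourDRate:
    """Substitution rate at 4-fold degenerate third codon positions."""

    n_4d_sites: int
    n_diff: int
    raw_p: float
    jc_rate: float  # NaN when saturated (raw_p >= 0.75)
    low_confidence: bool = False
    saturated: bool = False


# ---------------------------------------------------------------------------
# roles


def identify_trd_roles(orthnet: OrthNet) -> dict[str, TrdRoles]:
    """Assign CL-copy / Tr-copy roles per genome holding >= 2 nodes.

    The CL copy has the most genomes connected by a ``cl`` edge (ties:
    most reciprocal cl, longest ORF, lowest id); its tandem (``td``-linked)
    partners are CL copies too, represented by the longest ORF among them.
    Remaining nodes are Tr copies when their edges to the single-copy /
    CL-copy orthologues are all unidirectional ``tr``; edges to other
    genomes' surplus copies are not held against them (Tr copies of a
    shared event may be co-linear to each other).
    """
    graph = orthnet.graph
    by_genome: dict[str, list[str]] = {}
    for n, d in graph.nodes(data=True):
        by_genome.setdefault(d["genome"], []).append(n)

    def cl_partner_count(n: str, reciprocal_only: bool) -> int:
        genomes = set()
        for u, v, d in list(graph.out_edges(n, data=True)) + list(
            graph.in_edges(n, data=True)
        ):
            other = v if u == n else u
            if d["property"] != "cl" or graph.nodes[other]["genome"] == graph.nodes[n]["genome"]:
                continue
            if reciprocal_only and d["reciprocity"] != "rc":
                continue
            genomes.add(graph.nodes[other]["genome"])
        return len(genomes)

    # provisional CL copy per genome (needed to define the ortholog core)
    provisional: dict[str, str] = {}
    for genome, nodes in by_genome.items():
        provisional[genome] = max(
            nodes,
            key=lambda n: (
                cl_partner_count(n, False),
                cl_partner_count(n, True),
                graph.nodes[n]["orf_length"],
                _neg_id(n),
            ),
        )
    core = set(provisional.values())

    roles: dict[str, TrdRoles] = {}
    for genome, nodes in sorted(by_genome.items()):
        if len(nodes) < 2:
            continue
        cl_copy = provisional[genome]
        cl_copies = sorted(_td_component(graph, cl_copy))
        rep = max(
            cl_copies, key=lambda n: (graph.nodes[n]["orf_length"], _neg_id(n))
        )
        tr_copies: list[str] = []
        excluded: list[str] = []
        remaining = [n for n in nodes if n not in cl_copies]
        tr_like: set[str] = set()
        for n in remaining:
            ok = True
            for u, v, d in list(graph.out_edges(n, data=True)) + list(
                graph.in_edges(n, data=True)
            ):
                other = v if u == n else u
                if d["property"] == "td" or other not in core or other == n:
                    continue
                if not (d["property"] == "tr" and d["reciprocity"] == "uni"):
                    ok = False
                    break
            has_inter = any(
                d["property"] != "td"
                for _, _, d in list(graph.out_edges(n, data=True))
                + list(graph.in_edges(n, data=True))
            )
            if ok and has_inter:
                tr_like.add(n)
        for n in remaining:
            if n in tr_like:
                tr_copies.append(n)
            elif _td_component(graph, n) & tr_like:
                tr_copies.append(n)  # tandem satellite of a Tr copy
            else:
                excluded.append(n)
        if excluded:
            logger.debug(
                "%s/%s: nodes fitting neither role: %s",
                orthnet.orthnet_id, genome, excluded,
            )
        roles[genome] = TrdRoles(
            genome_id=genome,
            cl_copies=cl_copies,
            representative=rep,
            tr_copies=sorted(tr_copies),
            excluded=sorted(excluded),
        )
    return roles


class _neg_id(str):
    """Reverses string comparison so max() prefers the smallest id."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _td_component(graph, node: str) -> set[str]:
    comp = {node}
    frontier = [node]
    while frontier:
        n = frontier.pop()
        for u, v, d in list(graph.out_edges(n, data=True)) + list(
            graph.in_edges(n, data=True)
        ):
            if d["property"] != "td":
                continue
            other = v if u == n else u
            if other not in comp:
                comp.add(other)
                frontier.append(other)
    return comp


# ---------------------------------------------------------------------------
# HGS detection: seed - ungapped extend - co-linear chain

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class _Segment:
    cs: int
    ce: int
    ts: int
    te: int
    matches: int

    @property
    def score(self) -> float:
        return 2 * self.matches - (self.ce - self.cs)  # +1 match, -1 mismatch


def detect_hgs(
    cl_window: str,
    tr_window: str,
    seed_k: int = 16,
    min_identity: float = 0.7,
    xdrop: int = 20,
    chain_gap: int = 200,
    max_seed_hits: int = 25,
) -> list[HGS]:
    """Find homologous segments between two gene +/- 5 kb windows.

    Exact ``seed_k``-mer seeds are extended ungapped with an X-drop
    criterion and chained co-linearly (gaps below ``chain_gap`` bp on both
    sequences).  Both strands of the Tr window are searched.  Chains are
    reported as HGS intervals, best score first — the first element is the
    primary HGS; segments below ``min_identity`` are discarded.
    """
    results: list[HGS] = []
    cl = cl_window.upper()
    for strand in "+-":
        tr = tr_window.upper() if strand == "+" else _revcomp(tr_window.upper())
        segments = _extend_seeds(cl, tr, seed_k, xdrop, max_seed_hits)
        for chain in _chain_segments(segments, chain_gap):
            cs = min(s.cs for s in chain)
            ce = max(s.ce for s in chain)
            ts = min(s.ts for s in chain)
            te = max(s.te for s in chain)
            aligned = sum(s.ce - s.cs for s in chain)
            matches = sum(s.matches for s in chain)
            identity = matches / aligned if aligned else 0.0
            if identity < min_identity:
                continue
            if strand == "-":
                ts, te = len(tr_window) - te, len(tr_window) - ts
            results.append(
                HGS(
                    cl_start=cs, cl_end=ce, tr_start=ts, tr_end=te,
                    strand=strand, identity=identity,
                    score=sum(s.score for s in chain),
                )
            )
    results.sort(key=lambda h: -h.score)
    return results


def _extend_seeds(
    cl: str, tr: str, k: int, xdrop: int, max_seed_hits: int
) -> list[_Segment]:
    if len(cl) < k or len(tr) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(cl) - k + 1):
        index.setdefault(cl[i : i + k], []).append(i)
    covered: set[tuple[int, int]] = set()  # (diagonal, tr pos) already inside a segment
    segments: list[_Segment] = []
    for j in range(len(tr) - k + 1):
        hits = index.get(tr[j : j + k])
        if not hits or len(hits) > max_seed_hits:
            continue
        for i in hits:
            diag = i - j
            if (diag, j) in covered:
                continue
            seg = _xdrop_extend(cl, tr, i, j, k, xdrop)
            segments.append(seg)
            for t in range(seg.ts, seg.te - k + 1):
                covered.add((diag, t))
    return segments


def _xdrop_extend(cl: str, tr: str, i: int, j: int, k: int, xdrop: int) -> _Segment:
    # seed is an exact match of length k at cl[i:], tr[j:]
    best_right = 0
    score = 0
    best = 0
    r = 0
    while i + k + r < len(cl) and j + k + r < len(tr):
        score += 1 if cl[i + k + r] == tr[j + k + r] else -1
        if score > best:
            best, best_right = score, r + 1
        if best - score > xdrop:
            break
        r += 1
    best_left = 0
    score = 0
    best = 0
    l = 0
    while i - 1 - l >= 0 and j - 1 - l >= 0:
        score += 1 if cl[i - 1 - l] == tr[j - 1 - l] else -1
        if score > best:
            best, best_left = score, l + 1
        if best - score > xdrop:
            break
        l += 1
    cs, ce = i - best_left, i + k + best_right
    ts, te = j - best_left, j + k + best_right
    matches = sum(1 for a, b in zip(cl[cs:ce], tr[ts:te]) if a == b)
    return _Segment(cs=cs, ce=ce, ts=ts, te=te, matches=matches)


def _chain_segments(segments: list[_Segment], chain_gap: int) -> list[list[_Segment]]:
    """Greedy best-chain decomposition via co-linear DP.

    Chains require non-decreasing positions on both sequences with gaps
    (and overlaps) smaller than ``chain_gap``; each round extracts the
    maximum-score chain of the remaining segments.
    """
    chains: list[list[_Segment]] = []
    pool = sorted(segments, key=lambda s: (s.cs, s.ts))
    while pool:
        n = len(pool)
        dp = [s.score for s in pool]
        back = [-1] * n
        for jdx in range(n):
            for idx in range(jdx):
                a, b = pool[idx], pool[jdx]
                gap_c = b.cs - a.ce
                gap_t = b.ts - a.te
                if gap_c < -chain_gap or gap_t < -chain_gap:
                    continue
                if gap_c >= chain_gap or gap_t >= chain_gap:
                    continue
                penalty = 0.01 * max(gap_c, gap_t, 0)
                cand = dp[idx] + pool[jdx].score - penalty
                if cand > dp[jdx]:
                    dp[jdx] = cand
                    back[jdx] = idx
        jbest = max(range(n), key=lambda x: dp[x])
        chain = []
        x = jbest
        while x != -1:
            chain.append(pool[x])
            x = back[x]
        chain.reverse()
        used = set(map(id, chain))
        chains.append(chain)
        pool = [s for s in pool if id(s) not in used]
    return chains


# ---------------------------------------------------------------------------
# event classification


def classify_trd(
    primary_hgs: HGS,
    gene_interval: tuple[int, int],
    coding_length: int | None = None,
) -> str:
    """Class of one tr-d event from its primary HGS (CL-window coords).

    complete  : the HGS contains the whole CL-copy gene;
    gene_only : complete and HGS length < 1.2 x the coding-region length;
    incomplete otherwise.
    """
    gs, ge = gene_interval
    if coding_length is None:
        coding_length = ge - gs
    complete = primary_hgs.cl_start <= gs and primary_hgs.cl_end >= ge
    if not complete:
        return "incomplete"
    if primary_hgs.length < 1.2 * coding_length:
        return "gene_only"
    return "complete"


def classify_tr_orf(tr_orf: int, cl_orf: int) -> str:
    """``complete`` when the Tr-copy ORF is within +/-20% of the CL copy's
    (inclusive bounds), else ``truncated``."""
    if cl_orf <= 0:
        raise ValueError("CL-copy ORF length must be positive")
    ratio = tr_orf / cl_orf
    return "complete" if 0.8 <= ratio <= 1.2 else "truncated"


# ---------------------------------------------------------------------------
# shuffling null for complete / gene-only occurrence


def shuffle_expected_occurrence(
    hgs_lengths: list[int],
    cl_genes: list[tuple[int, int]],
    n_iter: int = 10_000,
    min_overlap: int = 60,
    seed: int | None = None,
    observed: dict[str, int] | None = None,
) -> dict[str, ShuffleResult]:
    """Expected chance occurrence of complete and gene-only tr-d events.

    Each iteration places, for every CL gene (given as ``(gene_length,
    window_length)`` with the gene centred in its window), one HGS of a
    length drawn uniformly from the observed distribution at a start drawn
    uniformly among all window positions yielding at least ``min_overlap``
    bp of overlap with the gene.  Draws that cannot overlap validly
    (length below ``min_overlap`` or exceeding the window) are resampled.
    Per-iteration counts of complete / gene-only placements are fitted to
    a normal distribution (method of moments); p-values are the upper-tail
    probability at the observed counts.
    """
    if not hgs_lengths or not cl_genes:
        raise ValueError("need at least one HGS length and one gene")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(hgs_lengths, dtype=np.int64)
    n_genes = len(cl_genes)
    gene_len = np.asarray([g for g, _ in cl_genes], dtype=np.int64)
    window = np.asarray([w for _, w in cl_genes], dtype=np.int64)
    if np.any(gene_len > window):
        raise ValueError("gene longer than its window")
    gs = (window - gene_len) // 2
    ge = gs + gene_len
    if np.any(gene_len < min_overlap):
        raise ValueError(
            f"gene shorter than min_overlap={min_overlap}: no valid placement"
        )

    # feasible lengths per gene: can be placed inside the window with the
    # required overlap
    feasible_any = (lengths >= min_overlap)[None, :] & (
        lengths[None, :] <= window[:, None]
    )
    if not feasible_any.any(axis=1).all():
        raise ValueError("some gene admits no valid HGS placement at all")
    if (~feasible_any).any():
        logger.warning(
            "some HGS lengths can never overlap validly; they are resampled"
        )

    complete_counts = np.zeros(n_iter, dtype=np.int64)
    gene_only_counts = np.zeros(n_iter, dtype=np.int64)
    for it in range(n_iter):
        L = np.empty(n_genes, dtype=np.int64)
        todo = np.arange(n_genes)
        for _ in range(200):
            draw = rng.choice(lengths, size=len(todo))
            ok = (draw >= min_overlap) & (draw <= window[todo])
            L[todo[ok]] = draw[ok]
            todo = todo[~ok]
            if len(todo) == 0:
                break
        else:  # pragma: no cover - guarded by feasibility check above
            raise RuntimeError("resampling failed to find feasible lengths")
        lo = np.maximum(0, gs - L + min_overlap)
        hi = np.minimum(window - L, ge - min_overlap)
        s = lo + (rng.random(n_genes) * (hi - lo + 1)).astype(np.int64)
        complete = (s <= gs) & (s + L >= ge)
        complete_counts[it] = int(complete.sum())
        gene_only_counts[it] = int((complete & (L < 1.2 * gene_len)).sum())

    out: dict[str, ShuffleResult] = {}
    for name, counts in (("complete", complete_counts), ("gene_only", gene_only_counts)):
        mean = float(counts.mean())
        sd = float(counts.std(ddof=1)) if n_iter > 1 else 0.0
        obs = (observed or {}).get(name)
        if obs is None:
            p = None
        elif sd == 0.0:
            p = 1.0 if obs <= mean else 0.0
        else:
            p = float(stats.norm.sf(obs, loc=mean, scale=sd))
        out[name] = ShuffleResult(
            observed_count=obs,
            expected_mean=mean,
            expected_sd=sd,
            p_value=p,
            n_iter=n_iter,
            min_overlap=min_overlap,
        )
    return out


# ---------------------------------------------------------------------------
# 4d substitution rate

# codon prefixes whose third position is four-fold degenerate
_FOURFOLD_PREFIXES = {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}
_STOPS = {"TAA", "TAG", "TGA"}


def fourfold_degenerate_rate(cl_orf: str, tr_orf: str) -> FourDRate:
    """Pairwise substitution rate at 4-fold degenerate sites.

    The two complete ORFs are aligned codon-aware (global protein
    alignment projected back to codons).  A site is 4d when both codons
    share a prefix from a 4-fold degenerate family and the first two
    positions are identical.  raw_p = differences / sites; the
    Jukes-Cantor correction is -(3/4) ln(1 - (4/3) raw_p), undefined
    (saturated) at raw_p >= 0.75.
    """
    cl = _check_orf(cl_orf, "cl")
    tr = _check_orf(tr_orf, "tr")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    prot_cl = str(Seq(cl).translate())
    prot_tr = str(Seq(tr).translate())
    alignment = aligner.align(prot_cl, prot_tr)[0]
    n_sites = 0
    n_diff = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for off in range(a1 - a0):
            ca = cl[3 * (a0 + off) : 3 * (a0 + off) + 3]
            cb = tr[3 * (b0 + off) : 3 * (b0 + off) + 3]
            if ca[:2] == cb[:2] and ca[:2] in _FOURFOLD_PREFIXES:
                n_sites += 1
                if ca[2] != cb[2]:
                    n_diff += 1
    raw_p = n_diff / n_sites if n_sites else 0.0
    saturated = raw_p >= 0.75
    jc = float("nan") if saturated else -0.75 * np.log1p(-4.0 * raw_p / 3.0)
    return FourDRate(
        n_4d_sites=n_sites,
        n_diff=n_diff,
        raw_p=raw_p,
        jc_rate=float(jc),
        low_confidence=n_sites < 10,
        saturated=saturated,
    )


def _check_orf(orf: str, which: str) -> str:
    orf = orf.upper().replace("U", "T")
    if len(orf) % 3:
        raise ValueError(f"{which} ORF length {len(orf)} not divisible by 3")
    codons = [orf[i : i + 3] for i in range(0, len(orf) - 3, 3)]
    if any(c in _STOPS for c in codons):
        raise ValueError(f"{which} ORF contains an internal stop codon")
    return orf


# ---------------------------------------------------------------------------
# shared events


def categorize_shared_trd(
    orthnets: list[OrthNet], genome_pair: tuple[str, str]
) -> dict[str, str]:
    """Label OrthNets with Tr copies in both genomes of a pair.

    ``tr_cl`` when any cross-genome Tr-copy pair is joined by a ``cl``
    edge (reciprocal or repaired-unidirectional); ``ind_parallel``
    otherwise — two transpositions that happened independently.
    """
    g1, g2 = genome_pair
    out: dict[str, str] = {}
    for net in orthnets:
        roles = identify_trd_roles(net)
        tr1 = set(roles[g1].tr_copies) if g1 in roles else set()
        tr2 = set(roles[g2].tr_copies) if g2 in roles else set()
        if not tr1 or not tr2:
            continue
        linked = any(
            (net.graph.has_edge(a, b) and net.graph[a][b]["property"] == "cl")
            or (net.graph.has_edge(b, a) and net.graph[b][a]["property"] == "cl")
            for a in tr1
            for b in tr2
        )
        out[net.orthnet_id] = "tr_cl" if linked else "ind_parallel"
    return out


# ---------------------------------------------------------------------------
# event tables


def collect_trd_events(orthnets: list[OrthNet]) -> list[TrdEvent]:
    """One TrdEvent per (OrthNet, genome, Tr copy).

    ORF-completeness is derived from the node ORF lengths; the sharing
    category is ``tr_cl`` / ``ind_parallel`` when another genome in the
    same OrthNet also carries Tr copies, ``lineage_specific`` otherwise.
    HGS-dependent fields stay unset — they require sequence windows.
    """
    events: list[TrdEvent] = []
    for net in orthnets:
        roles = identify_trd_roles(net)
        with_tr = [g for g, r in roles.items() if r.tr_copies]
        for genome in with_tr:
            role = roles[genome]
            rep = role.representative
            cl_orf = net.graph.nodes[rep]["orf_length"] if rep else 0
            sharing = "lineage_specific"
            if len(with_tr) > 1:
                pair_cats = {
                    categorize_shared_trd([net], (genome, other)).get(
                        net.orthnet_id
                    )
                    for other in with_tr
                    if other != genome
                }
                sharing = "tr_cl" if "tr_cl" in pair_cats else "ind_parallel"
            for tr in role.tr_copies:
                tr_orf = net.graph.nodes[tr]["orf_length"]
                events.append(
                    TrdEvent(
                        orthnet_id=net.orthnet_id,
                        genome_id=genome,
                        cl_copy=rep,
                        tr_copy=tr,
                        tr_orf_status=(
                            classify_tr_orf(tr_orf, cl_orf) if cl_orf else None
                        ),
                        sharing=sharing,
                    )
                )
    return events


def events_to_frame(
    events: list[TrdEvent],
    expression: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Flatten events to a table, one row per event.

    ``expression`` maps Tr-copy gene ids (bare, without the genome prefix)
    to detected-yes/no and joins on as an ``expressed`` column.
    """
    rows = []
    for e in events:
        row = {
            "orthnet_id": e.orthnet_id,
            "genome_id": e.genome_id,
            "cl_copy": e.cl_copy,
            "tr_copy": e.tr_copy,
            "trd_class": e.trd_class or "",
            "tr_orf_status": e.tr_orf_status or "",
            "sharing": e.sharing,
            "n_hgs": len(e.hgs),
            "primary_hgs_length": e.hgs[0].length if e.hgs else 0,
        }
        if expression is not None:
            gene = split_key(e.tr_copy)[1]
            row["expressed"] = bool(expression.get(gene, False))
        rows.append(row)
    return pd.DataFrame(rows)
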