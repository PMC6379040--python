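"""Readers and writers for the pipeline's external formats.

Annotations (GTF or GFF3) are parsed into :class:`~clonnet.types.GenomeTable`
using one primary transcript per gene — the transcript with the longest
total CDS (ties broken by lexicographic transcript id).  Ranked homology
hits come in as 12-column BLAST tabular (outfmt 6) files and within-genome
paralogue clusters as OrthoMCL-style group files.  The combined per-locus
table (one row per locus, one column block per target genome) is the
pipeline's flat output format.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd

from .clfinder import CLRelation
from .types import BestHitTable, GeneLocus, GenomeTable, ParalogClusters

logger = logging.getLogger(__name__)

__all__ = [
    "parse_annotation",
    "load_besthits",
    "load_paralog_clusters",
    "write_locus_table",
    "read_locus_table",
]

BLAST6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_annotation(path: str | Path, genome_id: str) -> GenomeTable:
    """Parse a GTF/GFF3 annotation into a ranked genome table.

    Both the GTF dialect (``gene_id``/``transcript_id`` attributes on CDS
    lines) and GFF3 (``ID``/``Parent``) are accepted.  The primary
    transcript of a gene is the one with the longest summed CDS; its CDS
    length becomes the locus ``orf_length`` and the locus interval spans
    all CDS of that transcript.  Malformed lines are skipped with a
    warning; a file yielding zero usable genes is an error.
    """
    path = Path(path)
    good_lines: list[str] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                n_bad += 1
                continue
            good_lines.append(line)
    if n_bad:
        logger.warning("%s: skipped %d malformed lines", path, n_bad)
    if not good_lines:
        raise ValueError(f"{path}: no usable annotation lines")
    db = gffutils.create_db(
        "".join(good_lines),
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )

    # transcript -> gene map for GFF3 (CDS Parent is the transcript)
    tx_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent") or feat.attributes.get("gene_id")
            tid = (feat.attributes.get("ID") or feat.attributes.get("transcript_id") or [feat.id])[0]
            if parents:
                tx_gene[tid] = parents[0]

    # (gene, transcript) -> accumulated CDS segments
    per_tx: dict[tuple[str, str], list[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        attrs = cds.attributes
        if "transcript_id" in attrs:  # GTF dialect
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0] if "gene_id" in attrs else tx_gene.get(tid, tid)
        elif "Parent" in attrs:  # GFF3
            tid = attrs["Parent"][0]
            gid = tx_gene.get(tid, tid)
        else:
            n_bad += 1
            continue
        per_tx.setdefault((gid, tid), []).append(cds)

    # longest-CDS primary transcript per gene
    best: dict[str, tuple[int, str, list[gffutils.Feature]]] = {}
    for (gid, tid), segs in per_tx.items():
        cds_len = sum(f.end - f.start + 1 for f in segs)
        cur = best.get(gid)
        if cur is None or cds_len > cur[0] or (cds_len == cur[0] and tid < cur[1]):
            best[gid] = (cds_len, tid, segs)

    loci = []
    for gid, (cds_len, _tid, segs) in best.items():
        if cds_len < 3:
            logger.warning("%s: gene %s has CDS < 3 bp, skipped", path, gid)
            continue
        loci.append(
            GeneLocus(
                gene_id=gid,
                genome_id=genome_id,
                scaffold_id=segs[0].seqid,
                strand=segs[0].strand if segs[0].strand in "+-" else "+",
                start=min(f.start for f in segs),
                end=max(f.end for f in segs),
                orf_length=cds_len,
            )
        )
    if not loci:
        raise ValueError(f"{path}: no usable protein-coding genes")
    return GenomeTable(genome_id, loci)


def load_besthits(
    path: str | Path,
    query_genome: str,
    target_genome: str,
    e_max: float = 1e-5,
    query_table: GenomeTable | None = None,
    target_table: GenomeTable | None = None,
) -> BestHitTable:
    """Load a 12-column BLAST tabular file into a ranked best-hit table.

    Rows with e-value >= ``e_max`` are discarded; per query, hits are
    deduplicated by subject (keeping the best bitscore), sorted by
    descending bitscore and truncated to 10 candidates.  Ids that do not
    resolve in the supplied genome tables are dropped with a warning.
    """
    path = Path(path)
    raw: dict[str, list[tuple[str, float]]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            evalue, bitscore = float(fields[10]), float(fields[11])
            n_rows += 1
            if evalue >= e_max:
                continue
            raw.setdefault(query, []).append((subject, bitscore))
    if n_rows == 0:
        logger.warning("%s: empty best-hit file", path)
    table = BestHitTable(query_genome, target_genome)
    n_dropped = 0
    for query, hits in raw.items():
        if query_table is not None and query not in query_table:
            n_dropped += len(hits)
            continue
        if target_table is not None:
            kept = [(t, s) for t, s in hits if t in target_table]
            n_dropped += len(hits) - len(kept)
            hits = kept
        if hits:
            table.add(query, hits)
    if n_dropped:
        logger.warning("%s: dropped %d hits with unresolvable ids", path, n_dropped)
    return table


def load_paralog_clusters(
    path: str | Path,
    genome_id: str,
    genome_table: GenomeTable | None = None,
) -> ParalogClusters:
    """Load an OrthoMCL-style group file (``cluster_id: member ...``).

    Members absent from ``genome_table`` are dropped, after which singleton
    clusters are removed.  A member listed in two clusters is an error.
    """
    path = Path(path)
    raw: dict[str, list[str]] = {}
    membership: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'cluster_id: members'")
            cid, members_str = line.split(":", 1)
            cid = cid.strip()
            members = members_str.split()
            for m in members:
                if m in membership and membership[m] != cid:
                    raise ValueError(
                        f"{path}:{lineno}: member {m!r} appears in clusters "
                        f"{membership[m]!r} and {cid!r}"
                    )
                membership[m] = cid
            raw.setdefault(cid, []).extend(members)
    clusters: dict[str, set[str]] = {}
    for cid, members in raw.items():
        kept = {
            m for m in members
            if genome_table is None or m in genome_table
        }
        if len(kept) >= 2:
            clusters[cid] = kept
    return ParalogClusters(genome_id=genome_id, clusters=clusters)


def write_locus_table(
    path: str | Path,
    genomes: dict[str, GenomeTable],
    relations: dict[tuple[str, str], dict[str, CLRelation]] | None = None,
    clusters: dict[str, ParalogClusters] | None = None,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write the combined per-locus TSV.

    One row per locus with its coordinates and rank, followed by one column
    block (label and best-hit) per target genome when pairwise relations
    are supplied.  ``extra`` (indexed by ``genome_id|gene_id``) appends
    network-level annotation columns.
    """
    rows = []
    genome_ids = sorted(genomes)
    for gid in genome_ids:
        for locus in genomes[gid]:
            row = {
                "genome_id": gid,
                "gene_id": locus.gene_id,
                "scaffold_id": locus.scaffold_id,
                "strand": locus.strand,
                "start": locus.start,
                "end": locus.end,
                "orf_length": locus.orf_length,
                "rank": locus.rank,
                "paralog_cluster_id": (
                    (clusters or {}).get(gid) and clusters[gid].cluster_of(locus.gene_id)
                ) or "",
            }
            if relations is not None:
                for tgt in genome_ids:
                    if tgt == gid:
                        continue
                    rel = relations.get((gid, tgt), {}).get(locus.gene_id)
                    row[f"{tgt}.label"] = rel.label if rel else ""
                    row[f"{tgt}.best_hit"] = (rel.best_hit or "") if rel else ""
            rows.append(row)
    frame = pd.DataFrame(rows)
    if extra is not None:
        key = frame["genome_id"] + "|" + frame["gene_id"]
        frame = frame.join(extra.reindex(key).set_axis(frame.index))
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_locus_table(path: str | Path) -> tuple[dict[str, GenomeTable], pd.DataFrame]:
    """Read a combined per-locus TSV back into genome tables.

    Round-trips gene ids, coordinates, ORF lengths and ranks exactly.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "genome_id": str},
                        keep_default_na=False)
    genomes: dict[str, GenomeTable] = {}
    for gid, sub in frame.groupby("genome_id"):
        loci = [
            GeneLocus(
                gene_id=r.gene_id,
                genome_id=gid,
                scaffold_id=r.scaffold_id,
                strand=r.strand,
                start=int(r.start),
                end=int(r.end),
                orf_length=int(r.orf_length),
                paralog_cluster_id=r.paralog_cluster_id or None,
            )
            for r in sub.itertuples()
        ]
        table = GenomeTable(gid, loci)
        for r in sub.itertuples():
            if table[r.gene_id].rank != int(r.rank):
                raise ValueError(
                    f"{path}: rank mismatch for {r.gene_id} "
                    f"(file {r.rank}, recomputed {table[r.gene_id].rank})"
                )
        genomes[gid] = table
    return genomes, frame
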