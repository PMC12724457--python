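"""Transcript models, GTF I/O, polyA-site clustering and exon context.

Internal coordinates are 0-based half-open throughout; GTF I/O converts
the 1-based inclusive convention at the boundary. The transcript end site
(TES) is the 3' terminus in transcription direction: the last exon's end
on the + strand, the first exon's start on the - strand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "PolyASiteCluster",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "cluster_polya_sites",
    "annotate_exon_context",
    "most_abundant_transcript",
    "clusters_to_frame",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF rows, with the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start must precede end: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One isoform: ordered exons, strand, optional ORF span and its TES."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    strand: str
    cds_span: GenomicInterval | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if self.cds_span is not None:
            lo = self.exons[0].start
            hi = self.exons[-1].end
            if not (lo <= self.cds_span.start and self.cds_span.end <= hi):
                raise ValueError(
                    f"cds_span outside exon span for {self.transcript_id}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def tes(self) -> int:
        """Transcript end site: the 3' terminus in transcription direction."""
        if self.strand == "+":
            return self.exons[-1].end
        return self.exons[0].start

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Intron coordinates (donor end, acceptor start) in genomic order."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    def exon_lengths(self) -> list[int]:
        return [len(e) for e in self.exons]

    def transcript_length(self) -> int:
        return sum(self.exon_lengths())

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic boundary position to a 5'-anchored transcript offset.

        `pos` is interpreted as a 0-based half-open boundary; the result is
        the number of mature-transcript nucleotides 5' of that boundary.
        """
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        offset = 0
        for exon in exons:
            if self.strand == "+":
                if pos <= exon.start:
                    return offset
                if pos <= exon.end:
                    return offset + (pos - exon.start)
            else:
                if pos >= exon.end:
                    return offset
                if pos >= exon.start:
                    return offset + (exon.end - pos)
            offset += len(exon)
        return offset


@dataclass
class PolyASiteCluster:
    """A group of transcript end sites within the clustering window."""

    gene_id: str
    cluster_id: str
    member_tes: list[int]
    member_transcripts: list[str]
    representative: int
    proximal_rank: int = 0


def _parse_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(" ", 1)
        if len(parts) != 2:
            raise GtfParseError(
                f"malformed attribute {chunk!r} on GTF line {lineno}"
            )
        key, value = parts
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str) -> list[TranscriptModel]:
    """Read transcript models from a GENCODE-dialect GTF file.

    Exon rows are mandatory; CDS rows, when present, are merged into a
    single genomic span per transcript. GTF 1-based inclusive coordinates
    are converted to 0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"expected 9 columns on GTF line {lineno}")
            chrom, _, feature, start, end, _, strand, _, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_attributes(attr, lineno)
            try:
                tid = attrs["transcript_id"]
                gid = attrs["gene_id"]
            except KeyError as exc:
                raise GtfParseError(
                    f"missing {exc.args[0]} attribute on GTF line {lineno}"
                ) from None
            s0, e0 = int(start) - 1, int(end)
            meta[tid] = (gid, chrom, strand)
            if feature == "exon":
                exons[tid].append(GenomicInterval(chrom, s0, e0, strand))
            else:
                cds[tid].append((s0, e0))
    models = []
    for tid, (gid, chrom, strand) in meta.items():
        if tid not in exons:
            continue
        span = None
        if tid in cds:
            lo = min(s for s, _ in cds[tid])
            hi = max(e for _, e in cds[tid])
            span = GenomicInterval(chrom, lo, hi, strand)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                exons=exons[tid],
                strand=strand,
                cds_span=span,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str) -> None:
    """Write models as GENCODE-dialect GTF (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for exon in m.exons:
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            "isocoord",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            m.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
            if m.cds_span is not None:
                for exon in m.exons:
                    lo = max(exon.start, m.cds_span.start)
                    hi = min(exon.end, m.cds_span.end)
                    if lo < hi:
                        fh.write(
                            "\t".join(
                                [
                                    m.chrom,
                                    "isocoord",
                                    "CDS",
                                    str(lo + 1),
                                    str(hi),
                                    ".",
                                    m.strand,
                                    ".",
                                    attrs,
                                ]
                            )
                            + "\n"
                        )


def cluster_polya_sites(
    models: Sequence[TranscriptModel], window: int = 24
) -> dict[str, list[PolyASiteCluster]]:
    """Single-linkage clustering of transcript end sites, per gene.

    Two end sites join the same cluster when they lie within `window`
    nucleotides of each other, with chaining (single linkage). Cluster
    representatives are the modal member position, ties resolved to the
    most distal member in transcription direction. ``proximal_rank`` is 1
    for the cluster closest to the gene's 5' end in transcription
    direction.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    per_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in models:
        per_gene[m.gene_id].append(m)
    out: dict[str, list[PolyASiteCluster]] = {}
    for gene_id, gene_models in per_gene.items():
        strand = gene_models[0].strand
        pairs = sorted((m.tes, m.transcript_id) for m in gene_models)
        groups: list[list[tuple[int, str]]] = [[pairs[0]]]
        for prev, cur in zip(pairs, pairs[1:]):
            if cur[0] - prev[0] <= window:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        clusters = []
        for group in groups:
            positions = [p for p, _ in group]
            counts = Counter(positions)
            top = max(counts.values())
            modal = [p for p, c in counts.items() if c == top]
            # most distal in transcription direction breaks representative ties
            rep = max(modal) if strand == "+" else min(modal)
            clusters.append(
                PolyASiteCluster(
                    gene_id=gene_id,
                    cluster_id="",
                    member_tes=positions,
                    member_transcripts=[t for _, t in group],
                    representative=rep,
                )
            )
        clusters.sort(
            key=lambda c: c.representative, reverse=(strand == "-")
        )
        for rank, cluster in enumerate(clusters, start=1):
            cluster.proximal_rank = rank
            cluster.cluster_id = f"{gene_id}:pA{rank}"
        out[gene_id] = clusters
    return out


def cluster_assignment(
    clusters: Mapping[str, list[PolyASiteCluster]]
) -> dict[str, str]:
    """Map transcript_id -> cluster_id over all genes."""
    assign: dict[str, str] = {}
    for gene_clusters in clusters.values():
        for cluster in gene_clusters:
            for tid in cluster.member_transcripts:
                assign[tid] = cluster.cluster_id
    return assign


def clusters_to_frame(
    clusters: Mapping[str, list[PolyASiteCluster]]
) -> pd.DataFrame:
    rows = []
    for gene_clusters in clusters.values():
        for c in gene_clusters:
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "cluster_id": c.cluster_id,
                    "representative": c.representative,
                    "members": ",".join(str(p) for p in c.member_tes),
                    "proximal_rank": c.proximal_rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "cluster_id", "representative", "members", "proximal_rank"],
    )


def annotate_exon_context(exon: GenomicInterval, model: TranscriptModel) -> str:
    """Classify an exon as 5UTR / ORF / 3UTR or a straddling combination.

    Segments are defined on the mature transcript relative to the ORF span,
    strand-aware: the 5'UTR is upstream of the CDS start in transcription
    direction, the 3'UTR downstream of the CDS end.
    """
    if model.cds_span is None:
        raise ValueError(
            f"transcript {model.transcript_id} has no CDS span; "
            "exon context unavailable"
        )
    cds = model.cds_span
    in_orf = exon.start < cds.end and cds.start < exon.end
    if model.strand == "+":
        has_five = exon.start < cds.start
        has_three = exon.end > cds.end
    else:
        has_five = exon.end > cds.end
        has_three = exon.start < cds.start
    if in_orf and has_five and has_three:
        raise ValueError("exon spans the entire ORF; context label undefined")
    if in_orf and has_five:
        return "5UTR+ORF"
    if in_orf and has_three:
        return "ORF+3UTR"
    if in_orf:
        return "ORF"
    if has_five:
        return "5UTR"
    return "3UTR"


def most_abundant_transcript(
    gene_id: str,
    counts: pd.DataFrame,
    gene_of: Mapping[str, str],
) -> str:
    """Representative isoform: the transcript with the largest summed count.

    `counts` is transcript-by-sample; `gene_of` maps transcript_id to
    gene_id. Ties break lexicographically on transcript_id.
    """
    tids = sorted(t for t in counts.index if gene_of.get(t) == gene_id)
    if not tids:
        raise ValueError(f"no transcripts with counts for gene {gene_id}")
    totals = counts.loc[tids].sum(axis=1)
    if totals.max() <= 0:
        raise ValueError(f"gene {gene_id} has zero total count")
    best = totals.max()
    return min(t for t in tids if totals[t] == best)
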