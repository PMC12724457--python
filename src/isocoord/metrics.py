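"""Characterization of significant coordination events.

For each event the distance and exon-count metrics are measured on the
gene's most abundant (representative) isoform: the genomic distance runs
from the 5' position of the exon immediately downstream of the
coordinated exon to the most proximal polyA site, and the intervening
exon count covers exons strictly after the coordinated exon up to and
including the exon holding that proximal site. Gene-set enrichment is a
one-sided Fisher exact test over an explicit background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .events import SkippedExonEvent
from .genome import PolyASiteCluster, TranscriptModel, annotate_exon_context

__all__ = [
    "CoordinationAnnotation",
    "genomic_distance",
    "intervening_exons",
    "geneset_enrichment",
    "annotate_events",
]


@dataclass
class CoordinationAnnotation:
    event_id: str
    gene_id: str
    distance_nt: int
    intervening_exons: int
    context: str


def _proximal_cluster(clusters: Sequence[PolyASiteCluster]) -> PolyASiteCluster:
    return min(clusters, key=lambda c: c.proximal_rank)


def _find_exon_index(model: TranscriptModel, start: int, end: int) -> int:
    for i, exon in enumerate(model.exons):
        if exon.start == start and exon.end == end:
            return i
    raise ValueError(
        f"representative {model.transcript_id} does not contain exon "
        f"{start}-{end}"
    )


def genomic_distance(
    event: SkippedExonEvent,
    clusters: Sequence[PolyASiteCluster],
    representative: TranscriptModel,
) -> int:
    """Distance from the next exon's 5' position to the proximal polyA site.

    "Next" means the exon immediately downstream of the coordinated exon in
    transcription direction on the representative isoform; the proximal
    site is the retained cluster with the smallest proximal rank, taken at
    its representative position.
    """
    idx = _find_exon_index(representative, event.as_exon.start, event.as_exon.end)
    if representative.strand == "+":
        if idx == len(representative.exons) - 1:
            raise ValueError("coordinated exon is the last exon; no downstream exon")
        five_prime = representative.exons[idx + 1].start
    else:
        if idx == 0:
            raise ValueError("coordinated exon is the last exon; no downstream exon")
        five_prime = representative.exons[idx - 1].end
    proximal = _proximal_cluster(clusters)
    return abs(five_prime - proximal.representative)


def intervening_exons(
    event: SkippedExonEvent,
    clusters: Sequence[PolyASiteCluster],
    representative: TranscriptModel,
) -> int:
    """Exons between the coordinated exon (exclusive) and the proximal
    polyA site (inclusive of the exon containing it)."""
    idx = _find_exon_index(representative, event.as_exon.start, event.as_exon.end)
    proximal = _proximal_cluster(clusters)
    pos = proximal.representative
    if representative.strand == "+":
        downstream = representative.exons[idx + 1 :]
    else:
        downstream = list(reversed(representative.exons[:idx]))
    count = 0
    for exon in downstream:
        count += 1
        if exon.start <= pos <= exon.end:
            return count
    raise ValueError(
        "proximal polyA site lies within no downstream exon of the "
        f"representative {representative.transcript_id}"
    )


def geneset_enrichment(
    candidates: set[str], target: set[str], background: set[str]
) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test of candidate/target overlap.

    Returns (odds_ratio, p). Candidates must be drawn from the background;
    the target set is intersected with the background.
    """
    if not background:
        raise ValueError("background gene set is empty")
    if not candidates <= background:
        raise ValueError("candidate genes must be a subset of the background")
    target = target & background
    a = len(candidates & target)
    b = len(candidates - target)
    c = len(target - candidates)
    d = len(background - candidates - target)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def annotate_events(
    events: Sequence[SkippedExonEvent],
    clusters_by_event: Mapping[str, Sequence[PolyASiteCluster]],
    representatives: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """Distance / exon-count / context annotations for significant events.

    `clusters_by_event` holds each event's retained polyA clusters;
    `representatives` maps gene_id to its most abundant isoform. Events
    whose representative lacks the coordinated exon (or a downstream exon)
    are skipped.
    """
    rows = []
    for event in events:
        rep = representatives.get(event.gene_id)
        clusters = clusters_by_event.get(event.event_id)
        if rep is None or not clusters:
            continue
        try:
            dist = genomic_distance(event, clusters, rep)
            n_exons = intervening_exons(event, clusters, rep)
            context = annotate_exon_context(event.as_exon, rep)
        except ValueError:
            continue
        rows.append(
            {
                "event_id": event.event_id,
                "gene_id": event.gene_id,
                "distance_nt": dist,
                "intervening_exons": n_exons,
                "context": context,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "distance_nt", "intervening_exons", "context"],
    )
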