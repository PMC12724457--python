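"""Skipped-exon event extraction, transcript flags, and event count tables.

A skipped-exon (SE) event requires an inclusion form with junctions
U->E and E->D around the alternative exon E and a skipping form with the
direct junction U->D, where U is the upstream anchor (3' end of the
upstream exon) and D the downstream anchor (5' start of the downstream
exon). Transcripts carrying neither junction pattern are irrelevant to
the event and contribute to neither count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import GenomicInterval, TranscriptModel

__all__ = [
    "SkippedExonEvent",
    "EventCountTable",
    "TranscriptFlags",
    "MICROEXON_MAX_NT",
    "PTC_JUNCTION_DISTANCE_NT",
    "extract_skipped_exons",
    "flag_microexon",
    "detect_ptc",
    "detect_intron_retention",
    "transcript_flags",
    "classify_transcripts",
    "build_event_counts",
    "filter_events",
]

logger = logging.getLogger("isocoord")

#: Skipped exons shorter than this many nucleotides are microexons.
MICROEXON_MAX_NT = 28
#: A stop codon at least this far upstream of the final junction is a PTC.
PTC_JUNCTION_DISTANCE_NT = 50


@dataclass(frozen=True)
class SkippedExonEvent:
    event_id: str
    gene_id: str
    as_exon: GenomicInterval
    upstream_anchor: int  # genomic 3' end of the shared upstream exon
    downstream_anchor: int  # genomic 5' start of the shared downstream exon
    is_microexon: bool = False


@dataclass
class TranscriptFlags:
    transcript_id: str
    has_ptc: bool
    has_retained_intron: bool
    microexon_lengths: list[int] = field(default_factory=list)


@dataclass
class EventCountTable:
    """Long-format inclusion/skipping counts per (event, polyA site, sample).

    ``data`` columns: event_id, gene_id, cluster_id, sample_id,
    inclusion_count, skipping_count. Counts are raw (no pseudocount); the
    pseudocount of 1 is applied at model/PSI time so raw counts stay
    auditable. ``sample_timepoint`` maps each sample to its ordered
    timepoint label.
    """

    data: pd.DataFrame
    sample_timepoint: dict[str, str]

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for tp in self.sample_timepoint.values():
            if tp not in seen:
                seen.append(tp)
        return sorted(seen)

    def event_ids(self) -> list[str]:
        return list(pd.unique(self.data["event_id"]))

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, sample_map_path: str) -> "EventCountTable":
        data = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        sm = pd.read_csv(sample_map_path, sep="\t", dtype=str)
        mapping = dict(zip(sm["sample_id"], sm["timepoint"]))
        return cls(data=data, sample_timepoint=mapping)


def extract_skipped_exons(
    models: Sequence[TranscriptModel],
) -> list[SkippedExonEvent]:
    """Enumerate skipped-exon events among one gene's transcripts.

    Deduplicated on (alternative exon, anchors); output order follows
    genomic position so results are invariant to input order.
    """
    junction_sets = {m.transcript_id: set(m.junctions) for m in models}
    all_junctions = set().union(*junction_sets.values()) if models else set()
    events: dict[tuple, SkippedExonEvent] = {}
    for m in models:
        for i in range(1, len(m.exons) - 1):
            exon = m.exons[i]
            upstream = m.exons[i - 1].end
            downstream = m.exons[i + 1].start
            if (upstream, downstream) not in all_junctions:
                continue
            key = (exon.start, exon.end, upstream, downstream)
            if key in events:
                continue
            event_id = (
                f"{m.gene_id}:SE:{m.chrom}:{upstream}-{exon.start}:"
                f"{exon.end}-{downstream}:{m.strand}"
            )
            events[key] = SkippedExonEvent(
                event_id=event_id,
                gene_id=m.gene_id,
                as_exon=exon,
                upstream_anchor=upstream,
                downstream_anchor=downstream,
                is_microexon=len(exon) < MICROEXON_MAX_NT,
            )
    return [events[k] for k in sorted(events)]


def flag_microexon(event: SkippedExonEvent) -> bool:
    """True when the alternative exon is shorter than 28 nt."""
    return len(event.as_exon) < MICROEXON_MAX_NT


def detect_ptc(model: TranscriptModel) -> bool:
    """Premature termination codon: stop >=50 nt upstream of the last junction.

    The stop position is the 3' boundary of the ORF span mapped into
    mature-transcript coordinates; mono-exonic transcripts have no junction
    and can never carry a PTC.
    """
    if model.cds_span is None:
        raise ValueError(
            f"transcript {model.transcript_id} has no CDS span; PTC undefined"
        )
    if len(model.exons) < 2:
        return False
    if model.strand == "+":
        stop_t = model.genomic_to_transcript(model.cds_span.end)
        last_junction_t = model.transcript_length() - len(model.exons[-1])
    else:
        stop_t = model.genomic_to_transcript(model.cds_span.start)
        last_junction_t = model.transcript_length() - len(model.exons[0])
    return last_junction_t - stop_t >= PTC_JUNCTION_DISTANCE_NT


def detect_intron_retention(
    model: TranscriptModel, others: Iterable[TranscriptModel]
) -> bool:
    """True when an exon of `model` spans >= 1 intron of another isoform.

    The containing exon's ends must match the outer boundaries of the
    flanking exons around the contained intron run in the other
    transcript, so a single retained exon may cover several consecutive
    introns.
    """
    exon_spans = {(e.start, e.end) for e in model.exons}
    for other in others:
        if other.transcript_id == model.transcript_id:
            continue
        for i, left in enumerate(other.exons):
            for right in other.exons[i + 1 :]:
                if (left.start, right.end) in exon_spans:
                    return True
    return False


def transcript_flags(
    models: Sequence[TranscriptModel],
) -> list[TranscriptFlags]:
    """PTC / intron-retention / microexon flags for every isoform of a gene."""
    events = extract_skipped_exons(models)
    out = []
    for m in models:
        exon_spans = {(e.start, e.end) for e in m.exons}
        micro = sorted(
            len(ev.as_exon)
            for ev in events
            if ev.is_microexon and (ev.as_exon.start, ev.as_exon.end) in exon_spans
        )
        out.append(
            TranscriptFlags(
                transcript_id=m.transcript_id,
                has_ptc=(detect_ptc(m) if m.cds_span is not None else False),
                has_retained_intron=detect_intron_retention(m, models),
                microexon_lengths=micro,
            )
        )
    return out


def classify_transcripts(
    event: SkippedExonEvent, models: Sequence[TranscriptModel]
) -> dict[str, str]:
    """Label each transcript inclusion / skipping / irrelevant for an event."""
    labels = {}
    u, d = event.upstream_anchor, event.downstream_anchor
    inc = {(u, event.as_exon.start), (event.as_exon.end, d)}
    for m in models:
        junctions = set(m.junctions)
        if inc <= junctions:
            labels[m.transcript_id] = "inclusion"
        elif (u, d) in junctions:
            labels[m.transcript_id] = "skipping"
        else:
            labels[m.transcript_id] = "irrelevant"
    return labels


def build_event_counts(
    events: Sequence[SkippedExonEvent],
    models: Sequence[TranscriptModel],
    assignment: Mapping[str, str],
    counts: pd.DataFrame,
    sample_timepoint: Mapping[str, str],
) -> EventCountTable:
    """Aggregate transcript counts into per-(event, polyA site, sample) cells.

    `assignment` maps transcript_id -> polyA cluster_id; `counts` is the
    transcript-by-sample matrix. Each (event, cluster) pair that has at
    least one inclusion or skipping transcript is zero-filled across every
    sample.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    samples = list(counts.columns)
    rows = []
    for event in events:
        gene_models = by_gene.get(event.gene_id, [])
        labels = classify_transcripts(event, gene_models)
        members: dict[str, dict[str, list[str]]] = {}
        for tid, label in labels.items():
            if label == "irrelevant" or tid not in counts.index:
                continue
            if tid not in assignment:
                raise RuntimeError(
                    f"transcript {tid} mapped to no polyA cluster"
                )
            cl = assignment[tid]
            members.setdefault(cl, {"inclusion": [], "skipping": []})
            members[cl][label].append(tid)
        for cluster_id in sorted(members):
            inc_ids = members[cluster_id]["inclusion"]
            skp_ids = members[cluster_id]["skipping"]
            inc = (
                counts.loc[inc_ids, samples].sum(axis=0)
                if inc_ids
                else pd.Series(0, index=samples)
            )
            skp = (
                counts.loc[skp_ids, samples].sum(axis=0)
                if skp_ids
                else pd.Series(0, index=samples)
            )
            for sample in samples:
                rows.append(
                    {
                        "event_id": event.event_id,
                        "gene_id": event.gene_id,
                        "cluster_id": cluster_id,
                        "sample_id": sample,
                        "inclusion_count": int(inc[sample]),
                        "skipping_count": int(skp[sample]),
                    }
                )
    data = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "cluster_id",
            "sample_id",
            "inclusion_count",
            "skipping_count",
        ],
    )
    return EventCountTable(data=data, sample_timepoint=dict(sample_timepoint))


def filter_events(
    table: EventCountTable,
    min_site_total: int = 50,
    min_samples: int = 5,
    min_per_sample: int = 10,
    min_sites: int = 2,
    site_rule: str = "sum",
) -> EventCountTable:
    """Apply the read-support filter to polyA sites and events.

    A site is retained when at least `min_samples` samples each carry an
    inclusion+skipping total of `min_per_sample` or more, and (under the
    default ``site_rule='sum'``) those qualifying samples together carry at
    least `min_site_total` reads. ``site_rule='per_sample'`` instead
    requires `min_samples` samples each reaching `min_site_total` on their
    own. Events keep only surviving sites and are dropped below
    `min_sites` sites.
    """
    if site_rule not in ("sum", "per_sample"):
        raise ValueError(f"unknown site_rule {site_rule!r}")
    df = table.data.copy()
    if df.empty:
        return EventCountTable(df, dict(table.sample_timepoint))
    df["total"] = df["inclusion_count"] + df["skipping_count"]

    def site_ok(group: pd.DataFrame) -> bool:
        qualifying = group["total"] >= min_per_sample
        if site_rule == "per_sample":
            return int((group["total"] >= min_site_total).sum()) >= min_samples
        return (
            int(qualifying.sum()) >= min_samples
            and group.loc[qualifying, "total"].sum() >= min_site_total
        )

    keys = ["event_id", "cluster_id"]
    ok = df.groupby(keys, sort=False).apply(site_ok, include_groups=False)
    kept_sites = set(ok[ok].index)
    mask = df.set_index(keys).index.isin(kept_sites)
    kept = df[mask].drop(columns="total")
    n_sites = kept.groupby("event_id")["cluster_id"].nunique()
    kept_events = set(n_sites[n_sites >= min_sites].index)
    dropped = set(df["event_id"]) - kept_events
    if dropped:
        logger.info(
            "filter_events: %d of %d events dropped (insufficient site support)",
            len(dropped),
            df["event_id"].nunique(),
        )
    kept = kept[kept["event_id"].isin(kept_events)].reset_index(drop=True)
    return EventCountTable(kept, dict(table.sample_timepoint))
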