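"""PolyA-site usage quantification: PAU, PPAU, delta-PPAU and calls.

PolyA-site Usage (PAU) is the percentage of a unit's (gene's or
CDS-identical cluster's) expression assigned to one polyA site, computed
per sample from CPM values and summarized per timepoint as the median
across that timepoint's samples. PPAU is the PAU of the unit's most
proximal site; delta-PPAU = PPAU(early) - PPAU(late), with > 20 called a
3'UTR lengthening event and < -20 a shortening event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PolyASiteCluster, TranscriptModel, cluster_polya_sites

__all__ = [
    "DELTA_PPAU_LENGTHENING",
    "DELTA_PPAU_SHORTENING",
    "compute_cpm",
    "compute_pau",
    "classify_delta_ppau",
    "pau_table",
    "correlate_usage_expression",
    "cds_identical_clusters",
]

logger = logging.getLogger("isocoord")

DELTA_PPAU_LENGTHENING = 20.0
DELTA_PPAU_SHORTENING = -20.0
MIN_UNIT_CPM = 1.0


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million with library size = column sum of retained rows."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size in samples: {bad}")
    return counts * 1e6 / libsize


def compute_pau(
    site_cpm: pd.DataFrame,
    sample_timepoint: Mapping[str, str],
) -> pd.DataFrame:
    """Per-timepoint median PAU from per-sample site CPM values of one unit.

    `site_cpm` is site-by-sample for a single unit. Per sample,
    PAU = 100 * site CPM / unit CPM (so PAUs sum to 100 per sample);
    the per-timepoint value is the median across the timepoint's samples.
    """
    unit_cpm = site_cpm.sum(axis=0)
    if (unit_cpm <= 0).any():
        raise ValueError("unit CPM is zero in some sample; unit must be excluded")
    pau = 100.0 * site_cpm / unit_cpm
    tps = pd.Series({s: sample_timepoint[s] for s in site_cpm.columns})
    return pau.T.groupby(tps).median().T.sort_index(axis=1)


def classify_delta_ppau(ppau_early: float, ppau_late: float) -> tuple[float, str]:
    """delta-PPAU = early - late; > 20 lengthening, < -20 shortening."""
    delta = ppau_early - ppau_late
    if delta > DELTA_PPAU_LENGTHENING:
        call = "lengthening"
    elif delta < DELTA_PPAU_SHORTENING:
        call = "shortening"
    else:
        call = "unchanged"
    return delta, call


def pau_table(
    site_counts: pd.DataFrame,
    sample_timepoint: Mapping[str, str],
    proximal_site: Mapping[str, str],
    min_unit_cpm: float = MIN_UNIT_CPM,
    expression_stat: str = "mean",
) -> pd.DataFrame:
    """PAU/PPAU/delta-PPAU table across units.

    `site_counts` carries a (unit_id, site_id) MultiIndex over sample
    columns; CPM normalization uses the full matrix as the library.
    Units need more than `min_unit_cpm` CPM at every timepoint
    (`expression_stat` picks mean or median across samples) and at least
    two sites; others are excluded with a logged reason. delta-PPAU is
    computed between the first and last timepoint in sorted label order.
    """
    if expression_stat not in ("mean", "median"):
        raise ValueError(f"unknown expression_stat {expression_stat!r}")
    cpm = compute_cpm(site_counts)
    tps = pd.Series({s: sample_timepoint[s] for s in cpm.columns})
    ordered_tps = sorted(tps.unique())
    rows = []
    for unit_id, unit_cpm in cpm.groupby(level=0):
        unit_cpm = unit_cpm.droplevel(0)
        if len(unit_cpm) < 2:
            logger.info("unit %s excluded: fewer than 2 polyA sites", unit_id)
            continue
        totals = unit_cpm.sum(axis=0)
        if (totals <= 0).any():
            logger.info("unit %s excluded: zero CPM in some sample", unit_id)
            continue
        agg = getattr(totals.groupby(tps), expression_stat)()
        if not (agg > min_unit_cpm).all():
            logger.info(
                "unit %s excluded: %s CPM <= %g at some timepoint",
                unit_id,
                expression_stat,
                min_unit_cpm,
            )
            continue
        pau = compute_pau(unit_cpm, sample_timepoint)
        prox = proximal_site[unit_id]
        ppau_early = float(pau.loc[prox, ordered_tps[0]])
        ppau_late = float(pau.loc[prox, ordered_tps[-1]])
        delta, call = classify_delta_ppau(ppau_early, ppau_late)
        for site_id in pau.index:
            row = {
                "unit_id": unit_id,
                "site_id": site_id,
                "is_proximal": site_id == prox,
                "delta_ppau": delta,
                "call": call,
            }
            for tp in ordered_tps:
                row[f"pau_{tp}"] = float(pau.loc[site_id, tp])
            rows.append(row)
    return pd.DataFrame(rows)


def correlate_usage_expression(
    delta_ppau: Sequence[float], log2fc: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of per-unit delta-PPAU with expression log2FC."""
    x = np.asarray(delta_ppau, dtype=float)
    y = np.asarray(log2fc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("delta_ppau and log2fc must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _structure_key(model: TranscriptModel) -> tuple | None:
    """Exon structure up to the 3'UTR start (the ORF's 3' boundary),
    strand-aware; None when the transcript lacks a CDS."""
    if model.cds_span is None:
        return None
    if model.strand == "+":
        utr_start = model.cds_span.end
        parts = []
        for exon in model.exons:
            if exon.end <= utr_start:
                parts.append((exon.start, exon.end))
            elif exon.start < utr_start:
                parts.append((exon.start, utr_start))
        return (model.chrom, model.strand, tuple(parts))
    utr_start = model.cds_span.start
    parts = []
    for exon in reversed(model.exons):
        if exon.start >= utr_start:
            parts.append((exon.start, exon.end))
        elif exon.end > utr_start:
            parts.append((utr_start, exon.end))
    return (model.chrom, model.strand, tuple(parts))


def cds_identical_clusters(
    models: Sequence[TranscriptModel], window: int = 24
) -> tuple[dict[str, list[str]], dict[str, list[PolyASiteCluster]]]:
    """Group transcripts sharing identical structure up to the 3'UTR start.

    Each group becomes an independent APA unit whose end sites are
    re-clustered with the usual 24-nt single-linkage rule, isolating 3'UTR
    choice from upstream structural differences. Transcripts without a CDS
    are excluded (logged). Returns (unit -> member transcripts,
    unit -> polyA clusters).
    """
    groups: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        key = _structure_key(m)
        if key is None:
            logger.info(
                "transcript %s excluded from CDS clustering: no CDS span",
                m.transcript_id,
            )
            continue
        groups.setdefault(key, []).append(m)
    units: dict[str, list[str]] = {}
    unit_clusters: dict[str, list[PolyASiteCluster]] = {}
    for i, key in enumerate(sorted(groups), start=1):
        members = groups[key]
        gene = members[0].gene_id
        unit_id = f"{gene}:cds{i}"
        units[unit_id] = sorted(m.transcript_id for m in members)
        renamed = [
            TranscriptModel(
                transcript_id=m.transcript_id,
                gene_id=unit_id,
                exons=list(m.exons),
                strand=m.strand,
                cds_span=m.cds_span,
            )
            for m in members
        ]
        unit_clusters[unit_id] = cluster_polya_sites(renamed, window)[unit_id]
    return units, unit_clusters
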