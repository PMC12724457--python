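"""Fisher contingency-table baseline for splicing / polyA coordination.

The baseline pools counts across samples per event into an n-sites x 2
(inclusion, exclusion) matrix, then tests each polyA site against the
pooled remainder with a two-sided Fisher exact test. It deliberately
discards sample-to-sample variance — that is the methodological gap the
nested quasi-binomial models close — and serves as the comparison
method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import EventCountTable

__all__ = [
    "FisherSiteResult",
    "ContingencyRejection",
    "build_contingency",
    "per_site_fisher",
    "run_fisher_baseline",
    "compare_methods",
]

#: Sites below this pooled inclusion+exclusion total are removed.
MIN_SITE_TOTAL = 100
#: Events need at least this many pooled reads of each isoform class.
MIN_CLASS_TOTAL = 100
#: Guard constant added to the odds ratio before taking its log.
LOG_OR_GUARD = 1e-13

FDR_THRESHOLD = 0.05
LOG_OR_THRESHOLD = 1.0


@dataclass(frozen=True)
class ContingencyRejection:
    """Typed outcome for events that fail the contingency-table filters."""

    event_id: str
    reason: str


@dataclass
class FisherSiteResult:
    event_id: str
    site_id: str
    odds_ratio: float
    log_or: float
    p_value: float
    fdr: float = float("nan")
    significant: bool = False


def build_contingency(
    rows: pd.DataFrame, event_id: str | None = None
) -> pd.DataFrame | ContingencyRejection:
    """Pool an event's counts across samples into an n x 2 site matrix.

    Sites with fewer than 100 pooled reads are removed first; the event is
    rejected when the surviving pooled inclusion or exclusion total falls
    below 100, or when fewer than two sites remain. A pseudocount of 1 is
    added to every retained cell.
    """
    if event_id is None:
        event_id = str(rows["event_id"].iloc[0])
    pooled = rows.groupby("cluster_id")[["inclusion_count", "skipping_count"]].sum()
    pooled.columns = ["inclusion", "exclusion"]
    totals = pooled.sum(axis=1)
    pooled = pooled[totals >= MIN_SITE_TOTAL]
    if pooled["inclusion"].sum() < MIN_CLASS_TOTAL:
        return ContingencyRejection(event_id, "inclusion total < 100")
    if pooled["exclusion"].sum() < MIN_CLASS_TOTAL:
        return ContingencyRejection(event_id, "exclusion total < 100")
    if len(pooled) < 2:
        return ContingencyRejection(event_id, "fewer than 2 sites after filter")
    return (pooled + 1).sort_index()


def per_site_fisher(
    matrix: pd.DataFrame,
    event_id: str,
    or_estimator: str = "sample",
) -> list[FisherSiteResult]:
    """Test each polyA site's 2x2 table against the pooled remaining sites.

    The default odds-ratio estimator is the sample (cross-product) ratio
    a*d / (b*c); ``or_estimator='conditional'`` switches to the
    conditional maximum-likelihood estimate of the noncentral
    hypergeometric model. FDR fields are filled later, across the whole
    run.
    """
    if or_estimator not in ("sample", "conditional"):
        raise ValueError(f"unknown or_estimator {or_estimator!r}")
    if len(matrix) < 2:
        raise ValueError("per-site tests need at least two sites")
    results = []
    col_totals = matrix.sum(axis=0)
    for site_id, row in matrix.iterrows():
        a, b = float(row["inclusion"]), float(row["exclusion"])
        c = float(col_totals["inclusion"] - a)
        d = float(col_totals["exclusion"] - b)
        table = np.array([[a, b], [c, d]])
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        if or_estimator == "sample":
            odds = (a * d) / (b * c) if b * c > 0 else math.inf
        else:
            odds = float(stats.contingency.odds_ratio(table.astype(int)).statistic)
        log_or = math.log(odds + LOG_OR_GUARD)
        results.append(
            FisherSiteResult(
                event_id=event_id,
                site_id=str(site_id),
                odds_ratio=odds,
                log_or=log_or,
                p_value=p,
            )
        )
    return results


def run_fisher_baseline(
    table: EventCountTable,
    or_estimator: str = "sample",
    fdr_threshold: float = FDR_THRESHOLD,
    log_or_threshold: float = LOG_OR_THRESHOLD,
) -> tuple[pd.DataFrame, list[ContingencyRejection]]:
    """Fisher baseline over every event; BH across all site tests at once.

    Returns the per-site result table (with ``significant`` requiring both
    FDR < 0.05 and |logOR| >= 1) and the list of rejected events.
    """
    all_results: list[FisherSiteResult] = []
    rejections: list[ContingencyRejection] = []
    for event_id, rows in table.data.groupby("event_id", sort=True):
        outcome = build_contingency(rows, str(event_id))
        if isinstance(outcome, ContingencyRejection):
            rejections.append(outcome)
            continue
        all_results.extend(per_site_fisher(outcome, str(event_id), or_estimator))
    if all_results:
        fdrs = multipletests([r.p_value for r in all_results], method="fdr_bh")[1]
        for r, fdr in zip(all_results, fdrs):
            r.fdr = float(fdr)
            r.significant = bool(
                r.fdr < fdr_threshold and abs(r.log_or) >= log_or_threshold
            )
    frame = pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "site_id": r.site_id,
                "odds_ratio": r.odds_ratio,
                "log_or": r.log_or,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in all_results
        ],
        columns=[
            "event_id",
            "site_id",
            "odds_ratio",
            "log_or",
            "p_value",
            "fdr",
            "significant",
        ],
    )
    return frame, rejections


def compare_methods(
    glm_results: pd.DataFrame, fisher_results: pd.DataFrame
) -> dict:
    """Overlap of significant GLM-global and Fisher events, on shared events.

    Restricted to events tested by both methods; the overlap fraction is
    |significant in both| / |significant in either|, reported as NaN when
    neither method called any shared event significant (or no events are
    shared).
    """
    glm_events = set(glm_results["event_id"])
    fisher_events = set(fisher_results["event_id"])
    shared = glm_events & fisher_events
    glm_sig = set(
        glm_results.loc[glm_results["passes_global"], "event_id"]
    ) & shared
    fisher_sig = (
        set(
            fisher_results.loc[fisher_results["significant"], "event_id"]
        )
        & shared
    )
    union = glm_sig | fisher_sig
    both = glm_sig & fisher_sig
    return {
        "n_shared_events": len(shared),
        "n_glm_significant": len(glm_sig),
        "n_fisher_significant": len(fisher_sig),
        "n_union": len(union),
        "n_overlap": len(both),
        "overlap_fraction": (len(both) / len(union)) if union else float("nan"),
    }
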