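"""Expression-trajectory codes, direction-bias tests, enrichment, and TE.

Gene (or protein) dynamics over two consecutive intervals are coded with
two characters from {U, D, -}: 'U' for log2FC > 1 with FDR < 0.05, 'D'
for log2FC < -1 with FDR < 0.05, '-' otherwise, giving nine possible
trajectories. Direction bias among switch consequences (e.g. exon
skipping vs inclusion) uses a two-sided exact binomial test against 0.5.
Translational efficiency (TE) is the ribosome-protected fragment count
over the matched input RNA count, pseudocounted by 0.5, averaged across
replicates and then log2-transformed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import geneset_enrichment

__all__ = [
    "TrajectoryCode",
    "BiasTestResult",
    "TEResult",
    "classify_trajectory",
    "classify_trajectories",
    "direction_bias_test",
    "direction_bias_tests",
    "geneset_enrichment_bonferroni",
    "translational_efficiency",
]

logger = logging.getLogger("isocoord")

LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05
TE_PSEUDOCOUNT = 0.5
TE_MIN_INPUT_READS = 6

#: The nine possible two-interval trajectory codes.
TRAJECTORY_CODES = tuple(a + b for a in "UD-" for b in "UD-")


@dataclass(frozen=True)
class TrajectoryCode:
    unit_id: str
    code: str


@dataclass
class BiasTestResult:
    category: str
    n_gain: int
    n_loss: int
    fraction: float
    p: float
    fdr: float = float("nan")


@dataclass(frozen=True)
class TEResult:
    region_id: str
    te_log2: float
    te_class: str


def _interval_symbol(lfc: float, fdr: float | None) -> str:
    if fdr is None or not np.isfinite(fdr):
        if abs(lfc) > LFC_THRESHOLD:
            logger.warning(
                "missing FDR with |log2FC| > 1; classifying interval as '-'"
            )
        return "-"
    if lfc > LFC_THRESHOLD and fdr < FDR_THRESHOLD:
        return "U"
    if lfc < -LFC_THRESHOLD and fdr < FDR_THRESHOLD:
        return "D"
    return "-"


def classify_trajectory(
    lfc1: float, fdr1: float | None, lfc2: float, fdr2: float | None
) -> str:
    """Two-character trajectory code for the two timepoint intervals.

    Boundary values (|log2FC| = 1 or FDR = 0.05) fall to '-' — both
    inequalities are strict. A large fold change whose FDR is missing is
    also coded '-' with a warning.
    """
    return _interval_symbol(lfc1, fdr1) + _interval_symbol(lfc2, fdr2)


def classify_trajectories(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized trajectory coding of a unit table.

    `table` needs columns unit_id, lfc1, fdr1, lfc2, fdr2; returns
    unit_id + code.
    """
    codes = [
        classify_trajectory(r.lfc1, r.fdr1, r.lfc2, r.fdr2)
        for r in table.itertuples()
    ]
    return pd.DataFrame({"unit_id": table["unit_id"], "code": codes})


def direction_bias_test(n_gain: int, n_loss: int, category: str = "") -> BiasTestResult:
    """Two-sided exact binomial test of gain/loss counts against 0.5.

    The two-sided p sums all outcomes whose point probability does not
    exceed the observed one (minimum-likelihood method).
    """
    n = n_gain + n_loss
    if n < 1:
        raise ValueError("need at least one observation")
    p = float(stats.binomtest(n_gain, n, 0.5, alternative="two-sided").pvalue)
    return BiasTestResult(
        category=category,
        n_gain=n_gain,
        n_loss=n_loss,
        fraction=n_gain / n,
        p=p,
    )


def direction_bias_tests(
    counts: Mapping[str, tuple[int, int]]
) -> list[BiasTestResult]:
    """Bias test per category with BH correction across the run's categories."""
    results = [
        direction_bias_test(gain, loss, category)
        for category, (gain, loss) in counts.items()
    ]
    if results:
        fdrs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
    return results


def geneset_enrichment_bonferroni(
    category_candidates: Mapping[str, set[str]],
    target: set[str],
    background: set[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment per category, Bonferroni-corrected.

    The Bonferroni multiplier is the number of non-empty categories in
    this comparison; corrected p-values cap at 1. Empty categories are
    skipped with a log message.
    """
    rows = []
    tested = {k: v for k, v in category_candidates.items() if v}
    for name, skipped in category_candidates.items():
        if not skipped:
            logger.info("enrichment category %s skipped: empty gene set", name)
    m = len(tested)
    for name, candidates in tested.items():
        odds, p = geneset_enrichment(candidates, target, background)
        rows.append(
            {
                "category": name,
                "odds_ratio": odds,
                "p": p,
                "p_bonf": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows, columns=["category", "odds_ratio", "p", "p_bonf"])


def translational_efficiency(
    rpf_counts: Sequence[float],
    input_counts: Sequence[float],
    region_id: str = "",
    te_class: str = "",
) -> TEResult | None:
    """log2 mean TE across replicates, or None when the region fails the
    input filter (every matched input library needs >= 6 reads).

    TE per replicate = (RPF + 0.5) / (input + 0.5); replicate TEs are
    averaged first and the mean is then log2-transformed.
    """
    rpf = np.asarray(rpf_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    if rpf.shape != inp.shape or rpf.ndim != 1 or len(rpf) == 0:
        raise ValueError("rpf and input counts must be equal-length vectors")
    if (inp < TE_MIN_INPUT_READS).any():
        return None
    te = (rpf + TE_PSEUDOCOUNT) / (inp + TE_PSEUDOCOUNT)
    return TEResult(
        region_id=region_id,
        te_log2=float(math.log2(te.mean())),
        te_class=te_class,
    )
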