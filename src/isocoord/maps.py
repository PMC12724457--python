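"""Mutability-Adjusted Proportion of Singletons (MAPS) and burden tests.

MAPS measures purifying selection on a variant class as the excess of
singleton variants beyond a neutral expectation calibrated on synonymous
variants: the per-context singleton proportion of synonymous variants is
regressed on the trinucleotide-specific mutation rate, the fit predicts
each class's expected singleton proportion from its context composition,
and MAPS = observed - expected. Confidence intervals come from a
nonparametric bootstrap over variants; significance versus the
synonymous class uses a chi-squared test on the 2x2 singleton-by-class
table, BH-corrected across classes. The de novo burden comparison is a
Fisher exact test on carrier counts in cases versus sibling controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MutabilityBaseline",
    "MapsResult",
    "fit_mutability_baseline",
    "compute_maps",
    "maps_table",
    "burden_fisher",
]

logger = logging.getLogger("isocoord")

BOOTSTRAP_SAMPLES = 1000
SYNONYMOUS = "synonymous"

#: Variant table columns consumed by this module.
VARIANT_COLUMNS = ("variant_id", "context", "variant_class", "is_singleton", "mu")


@dataclass
class MutabilityBaseline:
    """Singleton proportion as a linear function of context mutability."""

    slope: float
    intercept: float
    log_mu: bool = False
    contexts: tuple[str, ...] = ()

    def predict(self, mu: np.ndarray) -> np.ndarray:
        x = np.log(mu) if self.log_mu else np.asarray(mu, dtype=float)
        return self.intercept + self.slope * x


@dataclass
class MapsResult:
    variant_class: str
    n_variants: int
    ps_observed: float
    ps_expected: float
    maps: float
    ci_low: float
    ci_high: float
    p_vs_synonymous: float = float("nan")
    fdr: float = float("nan")


def fit_mutability_baseline(
    variants: pd.DataFrame, log_mu: bool = False
) -> MutabilityBaseline:
    """Weighted regression of synonymous singleton proportion on mutability.

    `variants` is the synonymous set (columns context, is_singleton, mu);
    per-context singleton proportions are fit against mu (or log mu) by
    weighted least squares with the context variant counts as weights.
    """
    grouped = variants.groupby("context").agg(
        ps=("is_singleton", "mean"),
        n=("is_singleton", "size"),
        mu=("mu", "first"),
    )
    if len(grouped) < 2:
        raise ValueError("baseline regression needs >= 2 distinct contexts")
    x = np.log(grouped["mu"].to_numpy()) if log_mu else grouped["mu"].to_numpy()
    slope, intercept = np.polyfit(
        x, grouped["ps"].to_numpy(), 1, w=np.sqrt(grouped["n"].to_numpy())
    )
    return MutabilityBaseline(
        slope=float(slope),
        intercept=float(intercept),
        log_mu=log_mu,
        contexts=tuple(grouped.index),
    )


def compute_maps(
    class_variants: pd.DataFrame,
    baseline: MutabilityBaseline,
    seed: int = 0,
    n_bootstrap: int = BOOTSTRAP_SAMPLES,
) -> MapsResult:
    """MAPS for one variant class with a bootstrap confidence interval.

    The expected singleton proportion is the mean baseline prediction over
    the class's variants (equivalently, the count-weighted mean over its
    contexts); MAPS is observed minus expected. The 95% CI is the
    percentile interval of MAPS over `n_bootstrap` resamples of the
    class's variants.
    """
    if class_variants.empty:
        raise ValueError("variant class is empty")
    unseen = set(class_variants["context"]) - set(baseline.contexts)
    if unseen:
        warnings.warn(
            f"contexts absent from the baseline, extrapolating: {sorted(unseen)}",
            stacklevel=2,
        )
    s = class_variants["is_singleton"].to_numpy(dtype=float)
    e = baseline.predict(class_variants["mu"].to_numpy())
    d = s - e
    maps = float(d.mean())
    rng = np.random.default_rng(seed)
    n = len(d)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boots[b] = d[rng.integers(0, n, n)].mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    name = str(class_variants["variant_class"].iloc[0])
    return MapsResult(
        variant_class=name,
        n_variants=n,
        ps_observed=float(s.mean()),
        ps_expected=float(e.mean()),
        maps=maps,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def maps_table(
    variants: pd.DataFrame,
    seed: int = 0,
    n_bootstrap: int = BOOTSTRAP_SAMPLES,
    log_mu: bool = False,
) -> pd.DataFrame:
    """MAPS across all classes of a variant table, tested vs synonymous.

    The baseline is trained on the table's synonymous variants. Each
    class's 2x2 (singleton x class-vs-synonymous) chi-squared p-value is
    BH-adjusted across the non-synonymous classes.
    """
    if SYNONYMOUS not in set(variants["variant_class"]):
        raise ValueError("variant table needs a synonymous class for training")
    syn = variants[variants["variant_class"] == SYNONYMOUS]
    baseline = fit_mutability_baseline(syn, log_mu=log_mu)
    syn_singletons = int(syn["is_singleton"].sum())
    syn_total = len(syn)
    results = []
    for i, (name, group) in enumerate(
        variants.groupby("variant_class", sort=True)
    ):
        res = compute_maps(group, baseline, seed=seed + i, n_bootstrap=n_bootstrap)
        if name != SYNONYMOUS:
            k = int(group["is_singleton"].sum())
            table = np.array(
                [
                    [k, len(group) - k],
                    [syn_singletons, syn_total - syn_singletons],
                ]
            )
            res.p_vs_synonymous = float(
                stats.chi2_contingency(table, correction=False)[1]
            )
        results.append(res)
    tested = [r for r in results if r.variant_class != SYNONYMOUS]
    if tested:
        fdrs = multipletests([r.p_vs_synonymous for r in tested], method="fdr_bh")[1]
        for r, fdr in zip(tested, fdrs):
            r.fdr = float(fdr)
    return pd.DataFrame(
        [
            {
                "variant_class": r.variant_class,
                "n_variants": r.n_variants,
                "ps_observed": r.ps_observed,
                "ps_expected": r.ps_expected,
                "maps": r.maps,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_vs_synonymous": r.p_vs_synonymous,
                "fdr": r.fdr,
            }
            for r in results
        ]
    )


def burden_fisher(
    n_carriers_case: int,
    n_case: int,
    n_carriers_control: int,
    n_control: int,
) -> tuple[float, float]:
    """Fisher exact test of carrier proportions, cases vs controls.

    Returns (sample odds ratio, two-sided p). The odds ratio is NaN when
    a margin is zero.
    """
    if n_carriers_case > n_case or n_carriers_control > n_control:
        raise ValueError("carrier counts cannot exceed cohort sizes")
    a, b = n_carriers_case, n_case - n_carriers_case
    c, d = n_carriers_control, n_control - n_carriers_control
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    return odds, p
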