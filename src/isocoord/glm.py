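"""Quasi-binomial nested GLMs for splicing / polyA-site coordination.

Per splicing event, inclusion is modelled on the logit scale against the
sample timepoint and the polyA site of each read's transcript, through
three nested models fit to (inclusion, skipping) counts per
(site, sample) cell:

    Inclusion ~ Time                (reduced)
    Inclusion ~ Time + Site         (global)
    Inclusion ~ Time x Site         (interaction)

Fits use binomial-logit IRLS with treatment coding; overdispersion is
absorbed by a quasi-likelihood dispersion estimated from Pearson
residuals, and nested models are compared with F-tests on the analysis
of deviance. Significant events must also clear percent-spliced-in
(PSI) effect-size thresholds computed from pseudocounted observed
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import EventCountTable

__all__ = [
    "GlmFit",
    "CoordinationResult",
    "fit_quasibinomial",
    "anova_f_test",
    "compute_observed_psi",
    "effect_size_filters",
    "marginal_means",
    "run_coordination",
    "results_to_frame",
]

logger = logging.getLogger("isocoord")

#: IRLS stops when the absolute deviance change falls below this.
IRLS_TOL = 1e-8
#: IRLS iteration cap; hitting it marks the fit non-convergent.
IRLS_MAX_ITER = 100
#: |coefficient| beyond this on the logit scale is treated as separation.
SEPARATION_LOGIT = 15.0
#: Default FDR and effect-size thresholds for calling coordination.
FDR_THRESHOLD = 0.05
DELTA_PSI_THRESHOLD = 0.1

FORMULAS = ("time", "time+site", "time*site")


@dataclass
class GlmFit:
    """A fitted binomial-logit model with quasi-likelihood dispersion."""

    formula: str
    coefficients: pd.Series  # logit scale, treatment coding
    cov_unscaled: np.ndarray  # (X'WX)^-1; multiply by dispersion for cov
    residual_deviance: float
    residual_df: int
    pearson_dispersion: float
    converged: bool
    time_levels: list[str]
    site_levels: list[str]

    @property
    def covariance(self) -> np.ndarray:
        phi = self.pearson_dispersion if self.residual_df > 0 else 1.0
        return self.cov_unscaled * phi


@dataclass
class CoordinationResult:
    event_id: str
    gene_id: str
    p_global: float
    p_interaction: float
    fdr_global: float
    fdr_interaction: float
    psi: pd.DataFrame  # sites x timepoints, pseudocounted observed PSI
    delta_psi_global: float
    passes_global: bool
    passes_interaction: bool
    marginal_means: pd.DataFrame


def _design_columns(
    time: np.ndarray,
    site: np.ndarray,
    formula: str,
    time_levels: list[str],
    site_levels: list[str],
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix for one of the three nested formulas."""
    cols = [np.ones(len(time))]
    names = ["(Intercept)"]
    t_dummies = {}
    s_dummies = {}
    for lv in time_levels[1:]:
        t_dummies[lv] = (time == lv).astype(float)
    for lv in site_levels[1:]:
        s_dummies[lv] = (site == lv).astype(float)
    for lv, col in t_dummies.items():
        cols.append(col)
        names.append(f"time[{lv}]")
    if formula in ("time+site", "time*site"):
        for lv, col in s_dummies.items():
            cols.append(col)
            names.append(f"site[{lv}]")
    if formula == "time*site":
        for tl, tc in t_dummies.items():
            for sl, sc in s_dummies.items():
                cols.append(tc * sc)
                names.append(f"time[{tl}]:site[{sl}]")
    return np.column_stack(cols), names


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, n: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(n * (t1 + t2)))


def fit_quasibinomial(design: pd.DataFrame, formula: str) -> GlmFit:
    """IRLS fit of a binomial-logit model on (inclusion, skipping) cells.

    `design` needs columns ``time``, ``site``, ``inclusion``, ``skipping``
    (counts already pseudocounted by the caller). `formula` is one of
    ``time``, ``time+site``, ``time*site``; factors use treatment coding
    with the first (sorted) level as reference. Non-convergence — IRLS not
    settling within the iteration cap, or a coefficient escaping to
    |logit| > 15 (separation) — is reported via ``converged=False`` rather
    than raised.
    """
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}, got {formula!r}")
    time = design["time"].astype(str).to_numpy()
    site = design["site"].astype(str).to_numpy()
    time_levels = sorted(pd.unique(time))
    site_levels = sorted(pd.unique(site))
    inc = design["inclusion"].to_numpy(dtype=float)
    skp = design["skipping"].to_numpy(dtype=float)
    n = inc + skp
    if np.any(n <= 0):
        raise ValueError("every cell needs a positive inclusion+skipping total")
    y = inc / n
    X, names = _design_columns(time, site, formula, time_levels, site_levels)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by testing each against the preceding span
        aliased = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(
                X[:, :j]
            ):
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    mu = (inc + 0.5) / (n + 1.0)
    eta = np.log(mu / (1 - mu))
    beta = np.zeros(X.shape[1])
    deviance = _binomial_deviance(y, mu, n)
    converged = False
    xtwx = np.eye(X.shape[1])
    for _ in range(IRLS_MAX_ITER):
        w = n * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        xtwx = X.T @ (X * w[:, None])
        xtwz = X.T @ (w * z)
        beta = np.linalg.solve(xtwx, xtwz)
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        new_dev = _binomial_deviance(y, mu, n)
        if abs(new_dev - deviance) < IRLS_TOL:
            deviance = new_dev
            converged = True
            break
        deviance = new_dev
    if np.any(np.abs(beta) > SEPARATION_LOGIT):
        converged = False
    df_resid = X.shape[0] - X.shape[1]
    if df_resid > 0:
        pearson = float(np.sum(n * (y - mu) ** 2 / (mu * (1 - mu))))
        dispersion = pearson / df_resid
    else:
        dispersion = float("nan")
    return GlmFit(
        formula=formula,
        coefficients=pd.Series(beta, index=names),
        cov_unscaled=np.linalg.inv(xtwx),
        residual_deviance=deviance,
        residual_df=df_resid,
        pearson_dispersion=dispersion,
        converged=converged,
        time_levels=time_levels,
        site_levels=site_levels,
    )


def anova_f_test(
    reduced: GlmFit, full: GlmFit, dispersion: float | None = None
) -> float:
    """Analysis-of-deviance F-test p-value for nested quasi-binomial fits.

    F = ((D_reduced - D_full)/ddf) / dispersion with the dispersion taken
    from the fuller model's Pearson estimate unless overridden; the
    p-value is the upper tail of F(ddf, full residual df). Forcing
    ``dispersion=1`` recovers the plain binomial likelihood-ratio scale
    (F * ddf equals the LRT statistic).
    """
    ddf = reduced.residual_df - full.residual_df
    if ddf <= 0:
        raise ValueError("full model must have more parameters than reduced")
    if full.residual_df <= 0:
        raise ValueError("full model has no residual degrees of freedom")
    phi = full.pearson_dispersion if dispersion is None else dispersion
    if not np.isfinite(phi) or phi <= 0:
        raise ValueError(f"dispersion must be positive, got {phi}")
    f_stat = max((reduced.residual_deviance - full.residual_deviance) / ddf, 0.0) / phi
    return float(stats.f.sf(f_stat, ddf, full.residual_df))


def compute_observed_psi(
    rows: pd.DataFrame,
    sample_timepoint: dict[str, str],
    method: str = "pooled",
) -> pd.DataFrame:
    """Observed PSI per (polyA site x timepoint) from raw counts.

    ``pooled`` (default) sums pseudocounted counts across a timepoint's
    samples: PSI = sum(inclusion+1) / sum(inclusion+skipping+2).
    ``mean`` instead averages per-sample pseudocounted PSI values.
    """
    if method not in ("pooled", "mean"):
        raise ValueError(f"unknown PSI method {method!r}")
    df = rows.copy()
    df["timepoint"] = df["sample_id"].map(sample_timepoint)
    df["inc1"] = df["inclusion_count"] + 1
    df["tot2"] = df["inclusion_count"] + df["skipping_count"] + 2
    if method == "pooled":
        grouped = df.groupby(["cluster_id", "timepoint"])[["inc1", "tot2"]].sum()
        psi = grouped["inc1"] / grouped["tot2"]
    else:
        df["psi"] = df["inc1"] / df["tot2"]
        psi = df.groupby(["cluster_id", "timepoint"])["psi"].mean()
    out = psi.unstack("timepoint")
    return out.reindex(sorted(out.index), columns=sorted(out.columns))


def effect_size_filters(
    psi: pd.DataFrame,
    threshold: float = DELTA_PSI_THRESHOLD,
    global_order: str = "avg_then_delta",
) -> tuple[bool, bool, float]:
    """Evaluate the global and interaction PSI effect-size conditions.

    Global: the spread (max - min) across sites of time-averaged PSI must
    reach `threshold` (``global_order='delta_then_avg'`` instead averages
    the per-timepoint spread). Interaction: some site must move by
    >= `threshold` across time AND some timepoint must separate sites by
    >= `threshold`. Returns (passes_global, passes_interaction,
    delta_psi_global).
    """
    if global_order not in ("avg_then_delta", "delta_then_avg"):
        raise ValueError(f"unknown global_order {global_order!r}")
    if global_order == "avg_then_delta":
        site_avg = psi.mean(axis=1)
        delta_global = float(site_avg.max() - site_avg.min())
    else:
        per_time = psi.max(axis=0) - psi.min(axis=0)
        delta_global = float(per_time.mean())
    passes_global = delta_global >= threshold
    time_spread = psi.max(axis=1) - psi.min(axis=1)  # per site, across time
    site_spread = psi.max(axis=0) - psi.min(axis=0)  # per time, across sites
    passes_interaction = bool(
        (time_spread >= threshold).any() and (site_spread >= threshold).any()
    )
    return passes_global, passes_interaction, delta_global


def marginal_means(fit: GlmFit, z: float = 1.96) -> pd.DataFrame:
    """Estimated marginal means per (site, time) cell on the probability scale.

    Each cell's linear predictor and delta-method standard error come from
    the fitted coefficients and dispersion-scaled covariance; the
    confidence interval is inverse-logit(eta +/- z * SE).
    """
    if not fit.converged:
        raise ValueError("marginal means require a converged fit")
    names = list(fit.coefficients.index)
    cov = fit.covariance
    beta = fit.coefficients.to_numpy()
    rows = []
    for site in fit.site_levels:
        for tp in fit.time_levels:
            x = np.zeros(len(names))
            for j, name in enumerate(names):
                if name == "(Intercept)":
                    x[j] = 1.0
                elif name == f"time[{tp}]":
                    x[j] = 1.0
                elif name == f"site[{site}]":
                    x[j] = 1.0
                elif name == f"time[{tp}]:site[{site}]":
                    x[j] = 1.0
            eta = float(x @ beta)
            se = float(np.sqrt(x @ cov @ x))
            rows.append(
                {
                    "site": site,
                    "timepoint": tp,
                    "estimate": 1 / (1 + np.exp(-eta)),
                    "ci_low": 1 / (1 + np.exp(-(eta - z * se))),
                    "ci_high": 1 / (1 + np.exp(-(eta + z * se))),
                }
            )
    return pd.DataFrame(rows)


def _event_design(
    rows: pd.DataFrame, sample_timepoint: dict[str, str], pseudocount: int = 1
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": rows["sample_id"].map(sample_timepoint),
            "site": rows["cluster_id"],
            "inclusion": rows["inclusion_count"] + pseudocount,
            "skipping": rows["skipping_count"] + pseudocount,
        }
    )


def run_coordination(
    table: EventCountTable,
    fdr_threshold: float = FDR_THRESHOLD,
    delta_psi_threshold: float = DELTA_PSI_THRESHOLD,
    psi_method: str = "pooled",
    global_order: str = "avg_then_delta",
) -> list[CoordinationResult]:
    """Fit the three nested models per event and call coordination.

    Events whose models fail to converge are removed (and logged).
    Benjamini-Hochberg adjustment runs across events, separately for the
    global and the interaction p-value families; flags additionally
    require the PSI effect-size filters.
    """
    results: list[CoordinationResult] = []
    if table.data.empty:
        return results
    kept: list[dict] = []
    for event_id, rows in table.data.groupby("event_id", sort=True):
        design = _event_design(rows, table.sample_timepoint)
        fits = {}
        failed = None
        for formula in FORMULAS:
            fit = fit_quasibinomial(design, formula)
            if not fit.converged:
                failed = formula
                break
            fits[formula] = fit
        if failed is not None:
            logger.info(
                "event %s removed: %s model did not converge", event_id, failed
            )
            continue
        try:
            p_global = anova_f_test(fits["time"], fits["time+site"])
        except ValueError as exc:
            logger.info("event %s removed: %s", event_id, exc)
            continue
        if fits["time*site"].residual_df < fits["time+site"].residual_df:
            p_inter = anova_f_test(fits["time+site"], fits["time*site"])
        else:
            # single factor level: the interaction adds no parameters
            p_inter = float("nan")
        psi = compute_observed_psi(rows, table.sample_timepoint, psi_method)
        kept.append(
            {
                "event_id": event_id,
                "gene_id": rows["gene_id"].iloc[0],
                "p_global": p_global,
                "p_interaction": p_inter,
                "psi": psi,
                "emm": marginal_means(fits["time*site"]),
            }
        )
    if not kept:
        return results
    def bh(pvals: list[float]) -> np.ndarray:
        arr = np.asarray(pvals, dtype=float)
        out = np.full_like(arr, np.nan)
        mask = np.isfinite(arr)
        if mask.any():
            out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
        return out

    fdr_g = bh([k["p_global"] for k in kept])
    fdr_i = bh([k["p_interaction"] for k in kept])
    for k, fg, fi in zip(kept, fdr_g, fdr_i):
        ok_g, ok_i, delta = effect_size_filters(
            k["psi"], delta_psi_threshold, global_order
        )
        results.append(
            CoordinationResult(
                event_id=k["event_id"],
                gene_id=k["gene_id"],
                p_global=k["p_global"],
                p_interaction=k["p_interaction"],
                fdr_global=float(fg),
                fdr_interaction=float(fi),
                psi=k["psi"],
                delta_psi_global=delta,
                passes_global=bool(fg < fdr_threshold and ok_g),
                passes_interaction=bool(fi < fdr_threshold and ok_i),
                marginal_means=k["emm"],
            )
        )
    return results


def results_to_frame(results: list[CoordinationResult]) -> pd.DataFrame:
    """Flatten coordination results into the per-event summary table."""
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "gene_id": r.gene_id,
                "p_global": r.p_global,
                "fdr_global": r.fdr_global,
                "p_interaction": r.p_interaction,
                "fdr_interaction": r.fdr_interaction,
                "delta_psi": r.delta_psi_global,
                "passes_global": r.passes_global,
                "passes_interaction": r.passes_interaction,
            }
            for r in results
        ],
        columns=[
            "event_id",
            "gene_id",
            "p_global",
            "fdr_global",
            "p_interaction",
            "fdr_interaction",
            "delta_psi",
            "passes_global",
            "passes_interaction",
        ],
    )
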