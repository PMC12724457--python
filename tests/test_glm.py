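"""Quasi-binomial fits, nested F-tests, PSI arithmetic, marginal means."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from isocoord.events import EventCountTable
from isocoord.glm import (
    GlmFit,
    anova_f_test,
    compute_observed_psi,
    effect_size_filters,
    fit_quasibinomial,
    marginal_means,
    run_coordination,
)


def design_frame(cells):
    """cells: list of (time, site, inclusion, skipping) tuples."""
    return pd.DataFrame(cells, columns=["time", "site", "inclusion", "skipping"])


def sm_fit(design, formula):
    """statsmodels reference fit of the same model."""
    X = pd.DataFrame({"const": np.ones(len(design))})
    t_levels = sorted(design["time"].unique())
    s_levels = sorted(design["site"].unique())
    for lv in t_levels[1:]:
        X[f"t_{lv}"] = (design["time"] == lv).astype(float)
    if formula in ("time+site", "time*site"):
        for lv in s_levels[1:]:
            X[f"s_{lv}"] = (design["site"] == lv).astype(float)
    if formula == "time*site":
        for tl in t_levels[1:]:
            for sl in s_levels[1:]:
                X[f"ts_{tl}_{sl}"] = (
                    (design["time"] == tl) & (design["site"] == sl)
                ).astype(float)
    endog = design[["inclusion", "skipping"]].to_numpy(dtype=float)
    return sm.GLM(endog, X, family=sm.families.Binomial()).fit()


class TestFitQuasibinomial:
    def test_homogeneous_data_gives_zero_coefficients(self):
        cells = [(t, s, 50, 50) for t in ("t00", "t04") for s in ("a", "b")]
        fit = fit_quasibinomial(design_frame(cells), "time*site")
        assert fit.converged
        assert np.allclose(fit.coefficients.to_numpy(), 0.0, atol=1e-9)

    def test_saturated_model_reproduces_cell_proportions(self):
        cells = [
            ("t00", "a", 30, 10),
            ("t00", "b", 5, 45),
            ("t04", "a", 22, 18),
            ("t04", "b", 40, 2),
        ]
        fit = fit_quasibinomial(design_frame(cells), "time*site")
        assert fit.residual_deviance == pytest.approx(0.0, abs=1e-8)
        assert fit.residual_df == 0
        emm = marginal_means(fit)
        obs = {
            (s, t): inc / (inc + skp) for t, s, inc, skp in cells
        }
        for row in emm.itertuples():
            assert row.estimate == pytest.approx(obs[(row.site, row.timepoint)], abs=1e-7)

    def test_site_coefficient_closed_form(self):
        # pseudocounted cells: reference site (10,90)+1, other (90,10)+1
        cells = [
            ("t00", "a", 11, 91),
            ("t00", "b", 91, 11),
            ("t04", "a", 11, 91),
            ("t04", "b", 91, 11),
        ]
        fit = fit_quasibinomial(design_frame(cells), "time+site")
        expected = np.log(91 / 11) - np.log(11 / 91)
        assert fit.coefficients["site[b]"] == pytest.approx(expected, rel=1e-6)

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(7)
        cells = [
            (t, s, int(rng.integers(3, 80)), int(rng.integers(3, 80)))
            for t in ("t00", "t04", "t30")
            for s in ("a", "b")
            for _ in range(3)
        ]
        design = design_frame(cells)
        for formula in ("time", "time+site", "time*site"):
            mine = fit_quasibinomial(design, formula)
            ref = sm_fit(design, formula)
            assert np.allclose(
                mine.coefficients.to_numpy(), ref.params.to_numpy(), atol=1e-8
            )
            assert mine.residual_deviance == pytest.approx(ref.deviance, abs=1e-8)
            assert mine.pearson_dispersion == pytest.approx(
                ref.pearson_chi2 / ref.df_resid, rel=1e-8
            )

    def test_rank_deficient_design_names_aliased_terms(self):
        # site perfectly confounded with time
        cells = [("t00", "a", 10, 10), ("t04", "b", 10, 10)]
        with pytest.raises(ValueError, match="aliased.*site"):
            fit_quasibinomial(design_frame(cells), "time+site")

    def test_separation_marks_non_convergent(self):
        cells = [
            ("t00", "a", 500, 0),
            ("t00", "b", 0, 500),
            ("t04", "a", 500, 0),
            ("t04", "b", 0, 500),
        ]
        fit = fit_quasibinomial(design_frame(cells), "time+site")
        assert not fit.converged


class TestAnovaFTest:
    def test_null_nesting_gives_p_near_one(self):
        rng = np.random.default_rng(3)
        cells = [
            (t, s, int(rng.binomial(100, 0.4)), 0)
            for t in ("t00", "t04", "t30")
            for s in ("a", "b")
            for _ in range(3)
        ]
        cells = [(t, s, i, 100 - i) for t, s, i, _ in cells]
        design = design_frame(cells)
        reduced = fit_quasibinomial(design, "time")
        full = fit_quasibinomial(design, "time+site")
        p = anova_f_test(reduced, full)
        assert p > 0.05

    def test_f_distribution_oracle(self):
        reduced = GlmFit(
            formula="time", coefficients=pd.Series(dtype=float),
            cov_unscaled=np.eye(1), residual_deviance=30.0, residual_df=9,
            pearson_dispersion=1.2, converged=True, time_levels=[], site_levels=[],
        )
        full = GlmFit(
            formula="time+site", coefficients=pd.Series(dtype=float),
            cov_unscaled=np.eye(2), residual_deviance=18.0, residual_df=8,
            pearson_dispersion=1.0, converged=True, time_levels=[], site_levels=[],
        )
        p = anova_f_test(reduced, full)
        assert p == pytest.approx(stats.f.sf(12.0, 1, 8), rel=1e-12)

    def test_forced_unit_dispersion_recovers_binomial_lrt(self):
        rng = np.random.default_rng(11)
        design = design_frame(
            [
                (t, s, int(rng.integers(5, 50)), int(rng.integers(5, 50)))
                for t in ("t00", "t04")
                for s in ("a", "b")
                for _ in range(3)
            ]
        )
        reduced = fit_quasibinomial(design, "time")
        full = fit_quasibinomial(design, "time+site")
        ddf = reduced.residual_df - full.residual_df
        p = anova_f_test(reduced, full, dispersion=1.0)
        f_stat = stats.f.isf(p, ddf, full.residual_df)
        lrt = sm_fit(design, "time").deviance - sm_fit(design, "time+site").deviance
        assert f_stat * ddf == pytest.approx(lrt, rel=1e-6)

    def test_strong_site_effect_is_extreme(self):
        rng = np.random.default_rng(2)
        cells = []
        for t in ("t00", "t04", "t30"):
            for s, p in (("a", 0.2), ("b", 0.65)):
                for _ in range(3):
                    inc = int(rng.binomial(2000, p))
                    cells.append((t, s, inc, 2000 - inc))
        design = design_frame(cells)
        p = anova_f_test(
            fit_quasibinomial(design, "time"),
            fit_quasibinomial(design, "time+site"),
        )
        assert p < 1e-6

    def test_bad_nesting_errors(self):
        fit = GlmFit(
            formula="time", coefficients=pd.Series(dtype=float),
            cov_unscaled=np.eye(1), residual_deviance=1.0, residual_df=5,
            pearson_dispersion=1.0, converged=True, time_levels=[], site_levels=[],
        )
        with pytest.raises(ValueError):
            anova_f_test(fit, fit)


def rows_frame(entries):
    return pd.DataFrame(
        entries,
        columns=["cluster_id", "sample_id", "inclusion_count", "skipping_count"],
    )


class TestObservedPsi:
    def test_single_sample_pseudocount_arithmetic(self):
        rows = rows_frame([("pA1", "s1", 49, 49)])
        psi = compute_observed_psi(rows, {"s1": "t00"})
        assert psi.loc["pA1", "t00"] == pytest.approx(50 / 100)
        rows0 = rows_frame([("pA1", "s1", 0, 100)])
        psi0 = compute_observed_psi(rows0, {"s1": "t00"})
        assert psi0.loc["pA1", "t00"] == pytest.approx(1 / 102)

    def test_pooling_across_samples(self):
        rows = rows_frame([("pA1", "s1", 10, 0), ("pA1", "s2", 0, 10)])
        psi = compute_observed_psi(rows, {"s1": "t00", "s2": "t00"})
        assert psi.loc["pA1", "t00"] == pytest.approx(12 / 24)

    def test_mean_method_differs_by_averaging_order(self):
        rows = rows_frame([("pA1", "s1", 10, 0), ("pA1", "s2", 0, 10)])
        psi = compute_observed_psi(rows, {"s1": "t00", "s2": "t00"}, method="mean")
        assert psi.loc["pA1", "t00"] == pytest.approx((11 / 12 + 1 / 12) / 2)


class TestEffectSizeFilters:
    def test_constant_psi_passes_nothing(self):
        psi = pd.DataFrame(0.5, index=["pA1", "pA2"], columns=["t00", "t04"])
        ok_g, ok_i, delta = effect_size_filters(psi)
        assert (ok_g, ok_i) == (False, False)
        assert delta == 0.0

    def test_global_threshold_on_time_averaged_spread(self):
        psi = pd.DataFrame(
            {"t00": [0.28, 0.47], "t04": [0.32, 0.43]}, index=["pA1", "pA2"]
        )
        ok_g, _, delta = effect_size_filters(psi)
        assert ok_g and delta == pytest.approx(0.15)

    def test_interaction_requires_both_conditions(self):
        # one site moves 0.20 -> 0.35 while sites differ by 0.12 at t30
        psi = pd.DataFrame(
            {"t00": [0.20, 0.23], "t30": [0.35, 0.23]}, index=["pA1", "pA2"]
        )
        _, ok_i, _ = effect_size_filters(psi)
        assert ok_i
        # time movement without any per-time site separation
        psi2 = pd.DataFrame(
            {"t00": [0.20, 0.21], "t30": [0.35, 0.36]}, index=["pA1", "pA2"]
        )
        _, ok_i2, _ = effect_size_filters(psi2)
        assert not ok_i2

    def test_delta_then_avg_order_flag(self):
        psi = pd.DataFrame(
            {"t00": [0.2, 0.5], "t04": [0.4, 0.4]}, index=["pA1", "pA2"]
        )
        _, _, d1 = effect_size_filters(psi, global_order="avg_then_delta")
        _, _, d2 = effect_size_filters(psi, global_order="delta_then_avg")
        assert d1 == pytest.approx(0.15)
        assert d2 == pytest.approx(0.15)  # (0.3 + 0.0) / 2


class TestMarginalMeans:
    def test_ci_shrinks_with_depth(self):
        def fit_at(scale):
            cells = [
                (t, s, int(scale * inc) + jitter, int(scale * skp) - jitter)
                for (t, s, inc, skp) in [
                    ("t00", "a", 30, 10), ("t00", "b", 12, 28),
                    ("t04", "a", 25, 15), ("t04", "b", 18, 22),
                ]
                for jitter in (0, 3)
            ]
            return fit_quasibinomial(design_frame(cells), "time*site")

        lo = marginal_means(fit_at(1))
        hi = marginal_means(fit_at(10))
        width_lo = (lo["ci_high"] - lo["ci_low"]).to_numpy()
        width_hi = (hi["ci_high"] - hi["ci_low"]).to_numpy()
        assert (width_hi < width_lo).all()

    def test_standard_errors_match_statsmodels_delta_method(self):
        rng = np.random.default_rng(5)
        cells = [
            (t, s, int(rng.integers(5, 60)), int(rng.integers(5, 60)))
            for t in ("t00", "t04")
            for s in ("a", "b")
            for _ in range(3)
        ]
        design = design_frame(cells)
        fit = fit_quasibinomial(design, "time*site")
        ref = sm_fit(design, "time*site")
        phi = ref.pearson_chi2 / ref.df_resid
        cov = ref.cov_params().to_numpy() / ref.scale * phi
        emm = marginal_means(fit)
        cols = list(ref.params.index)
        for row in emm.itertuples():
            x = np.zeros(len(cols))
            x[cols.index("const")] = 1
            if f"t_{row.timepoint}" in cols:
                x[cols.index(f"t_{row.timepoint}")] = 1
            if f"s_{row.site}" in cols:
                x[cols.index(f"s_{row.site}")] = 1
            if f"ts_{row.timepoint}_{row.site}" in cols:
                x[cols.index(f"ts_{row.timepoint}_{row.site}")] = 1
            eta = float(x @ ref.params.to_numpy())
            se = float(np.sqrt(x @ cov @ x))
            assert row.ci_low == pytest.approx(
                1 / (1 + np.exp(-(eta - 1.96 * se))), abs=1e-5
            )
            assert row.ci_high == pytest.approx(
                1 / (1 + np.exp(-(eta + 1.96 * se))), abs=1e-5
            )


class TestRunCoordination:
    def test_single_timepoint_degenerate_design(self):
        rows = []
        for s, (inc, skp) in (("pA1", (60, 40)), ("pA2", (20, 80))):
            for r in range(3):
                rows.append(
                    {
                        "event_id": "E1",
                        "gene_id": "G1",
                        "cluster_id": s,
                        "sample_id": f"s{r}",
                        "inclusion_count": inc + 2 * r,
                        "skipping_count": skp - 2 * r,
                    }
                )
        table = EventCountTable(pd.DataFrame(rows), {f"s{r}": "t00" for r in range(3)})
        results = run_coordination(table)
        assert len(results) == 1
        assert results[0].p_global < 0.01
        assert results[0].passes_global
        assert np.isnan(results[0].p_interaction)
        assert not results[0].passes_interaction

    def test_empty_table_empty_result(self):
        table = EventCountTable(pd.DataFrame(), {})
        assert run_coordination(table) == []

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(13)
        rows = []
        for e in range(10):
            for s in ("pA1", "pA2"):
                for t in ("t00", "t04"):
                    for r in range(2):
                        inc = int(rng.binomial(80, 0.4))
                        rows.append(
                            {
                                "event_id": f"E{e}",
                                "gene_id": f"G{e}",
                                "cluster_id": f"G{e}:{s}",
                                "sample_id": f"{t}_r{r}",
                                "inclusion_count": inc,
                                "skipping_count": 80 - inc,
                            }
                        )
        table = EventCountTable(
            pd.DataFrame(rows),
            {f"{t}_r{r}": t for t in ("t00", "t04") for r in range(2)},
        )
        results = run_coordination(table)
        assert len(results) == 10
        for res in results:
            assert res.fdr_global >= res.p_global - 1e-15
            assert res.fdr_interaction >= res.p_interaction - 1e-15
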