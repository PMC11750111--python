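import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from phosflow.diff_model import (DesignSpec, ModerationParams, apply_contrasts,
                                 bh_adjust, classify_sites, cluster_profiles,
                                 corrected_contrasts, ebayes_moderate,
                                 fit_groups, moderated_F, posterior_variance,
                                 run_pipeline, stepwise_contrasts)
from phosflow.synthetic_data import fusion_config, mating_config, simulate_experiment
from phosflow.tables_io import median_center_by_replicate
from .conftest import make_table


def design_matrix(cell_idx, n_cells):
    X = np.zeros((len(cell_idx), n_cells))
    X[np.arange(len(cell_idx)), cell_idx] = 1.0
    return X


class TestFitGroups:
    def test_cell_mean_and_residual_ss(self):
        cols = ["control_0min_R1", "control_0min_R2", "control_0min_R3",
                "control_45min_R1", "control_45min_R2", "control_45min_R3"]
        t = make_table([[1.0, 1.2, 0.8, 0.0, 0.0, 0.0]], cols)
        fit = fit_groups(t)
        assert fit.cell_means.iloc[0, 0] == pytest.approx(1.0)
        # residual SS for the first cell is 0.08; second cell contributes 0
        assert fit.s2.iloc[0] * fit.df.iloc[0] == pytest.approx(0.08)
        assert fit.df.iloc[0] == 4  # 6 obs - 2 cells

    def test_noiseless_data_zero_residual_variance(self):
        cfg = mating_config(n_sites=30, noise_sd=0.0, batch_sd=0.0, missing_rate=0.0,
                            replicate_dropout_rate=0.0, redundancy_rate=0.0,
                            coupled_fraction=0.0, seed=1)
        _, phospho, _ = simulate_experiment(cfg)
        fit = fit_groups(phospho)
        assert np.allclose(fit.s2.to_numpy(), 0.0)

    def test_ols_equality_with_normal_equations_oracle(self, mating_columns):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(50, 30))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        t = make_table(vals, mating_columns)
        design = DesignSpec.from_table(t)
        fit = fit_groups(t, design)
        cell_idx = design.cell_of_sample(t).to_numpy()
        for i in range(50):
            y = vals[i]
            obs = ~np.isnan(y)
            X = design_matrix(cell_idx[obs], len(design.cells))
            used = X.sum(axis=0) > 0
            beta = np.linalg.solve(X[:, used].T @ X[:, used], X[:, used].T @ y[obs])
            mine = fit.cell_means.iloc[i].to_numpy()[used]
            assert np.allclose(mine, beta, atol=1e-10)
            resid = y[obs] - X[:, used] @ beta
            df = obs.sum() - used.sum()
            if df > 0:
                assert fit.s2.iloc[i] == pytest.approx(resid @ resid / df)


class TestContrasts:
    def test_contrast_vectors_sum_to_zero(self, mating_columns):
        t = make_table(np.zeros((1, 30)), mating_columns)
        design = DesignSpec.from_table(t)
        for cset in (stepwise_contrasts(design, "control"), corrected_contrasts(design)):
            assert np.allclose(cset.matrix.sum(axis=1), 0.0)

    def test_diff_contrast_arithmetic(self):
        # Diff_45-0 = (Mating.45-Mating.0) - (Ctrl.45-Ctrl.0) = (1.2-0.0)-(0.4-0.1)
        cols = [f"{c}_{t}min_R1" for c in ("control", "mating") for t in (0, 45)]
        t = make_table([[0.1, 0.4, 0.0, 1.2]], cols)
        design = DesignSpec.from_table(t)
        cfit = apply_contrasts(fit_groups(t, design), corrected_contrasts(design))
        assert cfit.estimates.loc[t.feature_ids[0], "Diff_45-0"] == pytest.approx(0.9)

    def test_identical_profiles_cancel(self, mating_columns):
        profile = np.tile(np.array([0.0, 1.0, 2.0, 3.0, 4.0]), 6)  # same in all cond/reps
        t = make_table(profile[None, :], mating_columns)
        design = DesignSpec.from_table(t)
        fit = fit_groups(t, design)
        diff = apply_contrasts(fit, corrected_contrasts(design))
        assert np.allclose(diff.estimates.to_numpy(), 0.0)
        ctrl = apply_contrasts(fit, stepwise_contrasts(design, "control"))
        assert np.allclose(ctrl.estimates.to_numpy(), 1.0)  # equal-slope change

    def test_undefined_contrast_when_cell_missing(self, mating_columns):
        vals = np.random.default_rng(0).normal(size=(1, 30))
        # blank out every mating_180 sample
        cols = [i for i, c in enumerate(mating_columns) if c.startswith("mating_180")]
        vals[0, cols] = np.nan
        t = make_table(vals, mating_columns)
        design = DesignSpec.from_table(t)
        cfit = apply_contrasts(fit_groups(t, design), corrected_contrasts(design))
        assert not cfit.defined.loc[t.feature_ids[0], "Diff_180-135"]
        assert cfit.defined.loc[t.feature_ids[0], "Diff_45-0"]


class TestModeration:
    def test_posterior_variance_plugin(self):
        assert posterior_variance(3.0, 4.0, ModerationParams(4.0, 1.0)) == pytest.approx(2.0)

    def test_infinite_prior_df_returns_prior_variance(self):
        # equal sample variances force evar <= 0 and an infinite d0
        s2 = pd.Series(np.full(100, 0.5))
        df = pd.Series(np.full(100, 10.0))
        params, post = ebayes_moderate(s2, df)
        assert np.isinf(params.d0)
        assert np.allclose(post.to_numpy(), params.s02)

    def test_prior_variance_recovered_on_simulated_data(self):
        # 5,000 features with common true variance: s0^2 within 10%
        rng = np.random.default_rng(11)
        true_var, df = 0.0625, 20
        s2 = pd.Series(true_var * rng.chisquare(df, size=5000) / df)
        params, _ = ebayes_moderate(s2, pd.Series(np.full(5000, float(df))))
        assert abs(params.s02 / true_var - 1.0) < 0.10

    def test_noiseless_input_rejected(self):
        s2 = pd.Series(np.zeros(100))
        df = pd.Series(np.full(100, 10.0))
        with pytest.raises(ValueError, match="noiseless"):
            ebayes_moderate(s2, df)

    def test_matches_limma_on_complete_data(self, tmp_path):
        """Cross-check d0, s0^2, moderated F and p against Bioconductor limma."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        cfg = mating_config(n_sites=300, missing_rate=0.0, replicate_dropout_rate=0.0,
                            redundancy_rate=0.0, coupled_fraction=0.0, seed=21)
        _, phospho, _ = simulate_experiment(cfg)
        t = median_center_by_replicate(phospho)
        design = DesignSpec.from_table(t)
        fit = fit_groups(t, design)
        params, s2p = ebayes_moderate(fit.s2, fit.df)
        stat = moderated_F(apply_contrasts(fit, corrected_contrasts(design)), s2p, params, fit.df)

        t.values.to_csv(tmp_path / "vals.tsv", sep="\t")
        t.sample_frame().reset_index().rename(columns={"index": "sample"}).to_csv(
            tmp_path / "meta.tsv", sep="\t", index=False)
        rscript = tmp_path / "check.R"
        rscript.write_text("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            vals <- read.delim(args[1], row.names=1, check.names=FALSE)
            meta <- read.delim(args[2])
            cell <- factor(paste0(meta$condition, ".", meta$time_min))
            design <- model.matrix(~0+cell); colnames(design) <- levels(cell)
            fit <- lmFit(as.matrix(vals), design)
            cm <- makeContrasts(
              d1=(mating.45-mating.0)-(control.45-control.0),
              d2=(mating.90-mating.45)-(control.90-control.45),
              d3=(mating.135-mating.90)-(control.135-control.90),
              d4=(mating.180-mating.135)-(control.180-control.135), levels=design)
            fit2 <- eBayes(contrasts.fit(fit, cm))
            out <- data.frame(feature_id=rownames(vals), F=fit2$F, p=fit2$F.p.value)
            out$d0 <- fit2$df.prior; out$s02 <- fit2$s2.prior
            write.table(out, args[3], sep="\\t", row.names=FALSE, quote=FALSE)
        """)
        subprocess.run(["Rscript", str(rscript), str(tmp_path / "vals.tsv"),
                        str(tmp_path / "meta.tsv"), str(tmp_path / "out.tsv")], check=True)
        lim = pd.read_csv(tmp_path / "out.tsv", sep="\t").set_index("feature_id")
        assert params.d0 == pytest.approx(float(lim["d0"].iloc[0]), rel=1e-6)
        assert params.s02 == pytest.approx(float(lim["s02"].iloc[0]), rel=1e-6)
        assert np.allclose(stat["F"].to_numpy(), lim["F"].to_numpy(), rtol=1e-8)
        assert np.allclose(stat["p"].to_numpy(), lim["p"].to_numpy(), rtol=1e-6, atol=1e-300)


class TestModeratedF:
    def _fit(self, vals, columns):
        t = make_table(vals, columns)
        design = DesignSpec.from_table(t)
        fit = fit_groups(t, design)
        return t, design, fit

    def test_zero_contrasts_give_F_zero_p_one(self, mating_columns):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(50, 30))
        vals[0] = np.tile(np.arange(10, dtype=float), 3)  # same cells in both... replaced below
        t, design, fit = self._fit(rng.normal(size=(50, 30)), mating_columns)
        params, s2p = ebayes_moderate(fit.s2, fit.df)
        cfit = apply_contrasts(fit, corrected_contrasts(design))
        cfit.estimates.iloc[0] = 0.0  # force exact null estimates
        stat = moderated_F(cfit, s2p, params, fit.df)
        assert stat["F"].iloc[0] == pytest.approx(0.0)
        assert stat["p"].iloc[0] == pytest.approx(1.0)

    def test_single_contrast_equals_squared_moderated_t(self, mating_columns):
        rng = np.random.default_rng(4)
        t, design, fit = self._fit(rng.normal(size=(60, 30)), mating_columns)
        params, s2p = ebayes_moderate(fit.s2, fit.df)
        full = corrected_contrasts(design)
        single = type(full)(full.name, full.contrast_names[:1], full.matrix[:1], full.cells)
        stat = moderated_F(apply_contrasts(fit, single), s2p, params, fit.df)
        # moderated t by hand: est / sqrt(s2_post * l' D l)
        L = full.matrix[0]
        n = fit.cell_counts.iloc[0].to_numpy(dtype=float)
        unscaled = float((L ** 2 / n).sum())
        est = apply_contrasts(fit, single).estimates.iloc[:, 0].to_numpy()
        tstat = est / np.sqrt(s2p.to_numpy() * unscaled)
        assert np.allclose(stat["F"].to_numpy(), tstat ** 2, rtol=1e-10)

    def test_agrees_with_gls_oracle(self, mating_columns):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 30))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        t, design, fit = self._fit(vals, mating_columns)
        params, s2p = ebayes_moderate(fit.s2, fit.df)
        cset = corrected_contrasts(design)
        cfit = apply_contrasts(fit, cset)
        stat = moderated_F(cfit, s2p, params, fit.df)
        cell_idx = design.cell_of_sample(t).to_numpy()
        for i in range(20):
            y = vals[i]
            obs = ~np.isnan(y)
            X = design_matrix(cell_idx[obs], len(design.cells))
            XtXi = np.linalg.pinv(X.T @ X)
            beta = XtXi @ X.T @ y[obs]
            dmask = cfit.defined.iloc[i].to_numpy()
            if not dmask.any():
                continue
            L = cset.matrix[dmask]
            C = L @ XtXi @ L.T
            b = L @ beta
            F_oracle = b @ np.linalg.solve(C, b) / (dmask.sum() * s2p.iloc[i])
            assert stat["F"].iloc[i] == pytest.approx(F_oracle, rel=1e-6)


class TestBH:
    def test_worked_example(self):
        out = bh_adjust(np.array([0.01, 0.04, 0.03, 0.002]))
        assert np.allclose(out, [0.02, 0.04, 0.04, 0.008])

    def test_degenerate_inputs(self):
        assert np.allclose(bh_adjust(np.array([1.0, 1.0, 1.0])), 1.0)
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        with pytest.raises(ValueError, match="p-values"):
            bh_adjust(np.array([1.5]))

    def test_nan_excluded_from_m(self):
        out = bh_adjust(pd.Series([0.01, np.nan, 0.02]))
        assert np.isnan(out.iloc[1])
        assert np.allclose(out.dropna(), [0.02, 0.02])

    def test_order_independence_and_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for n in (1, 2, 3, 5, 8, 50):
            for _ in range(20):
                p = rng.integers(0, 101, size=n) / 100.0
                mine = bh_adjust(p)
                ref = multipletests(p, method="fdr_bh")[1]
                assert np.allclose(mine, ref, atol=1e-12)
                perm = rng.permutation(n)
                assert np.allclose(bh_adjust(p[perm]), mine[perm], atol=1e-12)

    def test_exhaustive_small_grids(self):
        """All p-vectors of length <= 2 on the 0.01 grid and length 3 on a
        coarser grid, against the independent step-up oracle."""
        from statsmodels.stats.multitest import multipletests
        grid = np.arange(0, 101) / 100.0
        for a in grid:
            assert bh_adjust(np.array([a]))[0] == pytest.approx(a)
        pairs = np.array(np.meshgrid(grid, grid)).T.reshape(-1, 2)
        mine = np.array([bh_adjust(p) for p in pairs])
        ref = np.array([multipletests(p, method="fdr_bh")[1] for p in pairs])
        assert np.allclose(mine, ref, atol=1e-12)
        coarse = np.arange(0, 11) / 10.0
        triples = np.array(np.meshgrid(coarse, coarse, coarse)).T.reshape(-1, 3)
        mine3 = np.array([bh_adjust(p) for p in triples])
        ref3 = np.array([multipletests(p, method="fdr_bh")[1] for p in triples])
        assert np.allclose(mine3, ref3, atol=1e-12)


class TestClassification:
    def test_class_assignment_rules(self):
        idx = pd.Index(list("ABCD"), name="feature_id")
        mating = pd.Series([0.01, 0.01, 0.5, 0.5], index=idx)
        starv = pd.Series([0.5, 0.01, 0.01, 0.5], index=idx)
        out = classify_sites(mating, starv, 0.05, 0.05)
        assert out.tolist() == ["mating_specific", "both_different", "starvation_only", "ns"]

    def test_universe_mismatch_errors(self):
        a = pd.Series([0.1], index=pd.Index(["A"]))
        b = pd.Series([0.1], index=pd.Index(["B"]))
        with pytest.raises(ValueError, match="universe"):
            classify_sites(a, b)

    def test_no_significant_sites(self):
        idx = pd.Index(["A", "B"])
        out = classify_sites(pd.Series([0.9, 0.9], index=idx), pd.Series([0.9, 0.9], index=idx))
        assert (out == "ns").all()


class TestClustering:
    @pytest.mark.parametrize("profile,k,expected", [
        ([0, 1, 2, 3, 4], 2, "increase"),
        ([0, -1, -2, -2, -3], 2, "decrease"),
        ([0, 0, 0, 0, 0], 2, "increase"),  # exact tie goes to increase
        ([0, 2, 3, 3.5, 4], 3, "early_increase"),
        ([0, 0, 0, 2, 3], 3, "late_increase"),
        ([0, -1, -2, -2, -3], 3, "decrease"),
    ])
    def test_rules(self, profile, k, expected):
        prof = pd.DataFrame([profile], index=pd.Index(["A"]),
                            columns=[f"{t}min" for t in (0, 45, 90, 135, 180)])
        assert cluster_profiles(prof, k=k).iloc[0] == expected

    def test_invalid_k(self):
        prof = pd.DataFrame([[0, 1]], columns=["0min", "45min"])
        with pytest.raises(ValueError, match="k"):
            cluster_profiles(prof, k=4)


class TestPipeline:
    def test_difference_fitting_equivalence_on_complete_data(self, mating_columns):
        """Fitting per-replicate consecutive differences (mating minus
        control) averages to the same estimates as contrasts on cell means."""
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(40, 30))
        t = make_table(vals, mating_columns)
        design = DesignSpec.from_table(t)
        cfit = apply_contrasts(fit_groups(t, design), corrected_contrasts(design))
        sf = t.sample_frame()
        times = sorted(sf["time_min"].unique())
        for i, fid in enumerate(t.feature_ids):
            deltas = []
            for r in sorted(sf["replicate"].unique()):
                get = lambda cond, tt: vals[i, sf.index.get_loc(f"{cond}_{tt}min_R{r}")]
                deltas.append([
                    (get("mating", times[j + 1]) - get("mating", times[j]))
                    - (get("control", times[j + 1]) - get("control", times[j]))
                    for j in range(4)
                ])
            assert np.allclose(cfit.estimates.loc[fid].to_numpy(), np.mean(deltas, axis=0))

    def test_all_null_noiseless_raises_noiseless_error(self):
        cfg = mating_config(n_sites=50, class_proportions={"null": 1.0}, noise_sd=0.0,
                            batch_sd=0.0, coupled_fraction=0.0, redundancy_rate=0.0, seed=1)
        _, phospho, _ = simulate_experiment(cfg)
        with pytest.raises(ValueError, match="noiseless"):
            run_pipeline(phospho, preset="mating")

    def test_all_null_noisy_simulation_yields_no_calls(self):
        cfg = mating_config(n_sites=2000, class_proportions={"null": 1.0},
                            coupled_fraction=0.0, redundancy_rate=0.0, seed=0)
        _, phospho, _ = simulate_experiment(cfg)
        res, summary = run_pipeline(phospho, preset="mating")
        assert summary["class_counts"].get("mating_specific", 0) == 0
        assert summary["class_counts"].get("both_different", 0) == 0

    def test_label_invariance_to_feature_order(self, small_experiment):
        _, _, phospho, _ = small_experiment
        res1, _ = run_pipeline(phospho, preset="mating")
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(phospho.feature_ids))
        shuffled = phospho.subset(phospho.feature_ids[perm])
        res2, _ = run_pipeline(shuffled, preset="mating")
        common = res1.index
        assert (res1["class"] == res2["class"].reindex(common)).all()

    def test_recovery_of_planted_classes(self, small_experiment):
        _, _, phospho, truth = small_experiment
        res, _ = run_pipeline(phospho, preset="mating")
        called = res["class"].isin(["mating_specific", "both_different"])
        truly_diff = truth.differential_in_condition_pair("mating", "control").reindex(res.index)
        tp = int((called & truly_diff).sum())
        fp = int((called & ~truly_diff).sum())
        assert tp > 0.7 * int(truly_diff.sum())
        assert fp / max(tp + fp, 1) < 0.10

    def test_fusion_preset_runs_with_three_clusters(self):
        cfg = fusion_config(n_sites=600, seed=2)
        _, phospho, _ = simulate_experiment(cfg)
        res, summary = run_pipeline(phospho, preset="fusion")
        assert summary["alpha"] == 0.001
        sig = res["class"] == "fusion_significant"
        assert sig.sum() > 0
        assert set(res.loc[sig, "cluster"].unique()) <= {"decrease", "early_increase", "late_increase"}

    def test_redundant_duplicates_share_statistics(self, small_experiment):
        _, _, phospho, truth = small_experiment
        res, _ = run_pipeline(phospho, preset="mating")
        groups = truth.redundancy_group.dropna()
        filtered = groups[groups.index.isin(res.index)]
        for gid, members in filtered.groupby(filtered).groups.items():
            if len(members) < 2:
                continue
            vals = res.loc[members, "adj_p_mating"]
            assert vals.nunique(dropna=False) == 1
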