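"""Moderated linear model: design, OLS, variance prior, moderated t, BH."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from valveproteome import (
    DesignSpec,
    EBPrior,
    IntensityMatrix,
    SynthConfig,
    adjust_bh,
    build_design,
    estimate_variance_prior,
    fit_linear_model,
    generate_cohort,
    moderated_statistics,
    two_group_design,
)
from valveproteome.linear_model import trigamma_inverse

from conftest import make_meta


def toy_fit(two_group_matrix):
    matrix, meta = two_group_matrix
    design = two_group_design(meta, "AS", "CON")
    return fit_linear_model(matrix, design), design


class TestDesign:
    def test_condition_contrast_averages_sexes_equally(self, small_cohort):
        _, meta, _ = small_cohort
        design = build_design(meta)
        np.testing.assert_allclose(
            design.contrast("AS_vs_CON"), [0.5, 0.5, 0, 0, -0.5, -0.5]
        )
        np.testing.assert_allclose(
            design.contrast("ASf_vs_CONf"), [1, 0, 0, 0, -1, 0]
        )

    def test_cell_means_design_full_rank(self, small_cohort):
        _, meta, _ = small_cohort
        design = build_design(meta)
        X = design.matrix.to_numpy()
        assert np.linalg.matrix_rank(X) == 6
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_size_weighting_option(self, small_cohort):
        _, meta, _ = small_cohort
        design = build_design(meta, sex_weighting="size")
        vec = design.contrast("AS_vs_CON")
        np.testing.assert_allclose(vec[0], 21 / 41)
        np.testing.assert_allclose(vec[5], -9 / 17)

    def test_empty_cell_rejected(self):
        meta = make_meta(
            {
                "AS": {"female": 3},
                "MR": {"female": 2, "male": 2},
                "CON": {"female": 2, "male": 2},
            }
        )
        with pytest.raises(ValueError, match="empty design cells"):
            build_design(meta)

    def test_unknown_contrast_name(self, small_cohort):
        _, meta, _ = small_cohort
        design = build_design(meta)
        with pytest.raises(KeyError):
            design.contrast("no_such")


class TestOLSFit:
    def test_hand_computed_two_group_toy(self, two_group_matrix):
        fit, design = toy_fit(two_group_matrix)
        # group means 2 and 5; pooled residual variance 1; df = 6 - 2 = 4
        est = fit.coef.to_numpy() @ design.contrast("AS_vs_CON")
        assert est[0] == pytest.approx(-3.0)
        assert fit.s2.iloc[0] == pytest.approx(1.0)
        assert fit.df_resid == 4
        assert fit.amean.iloc[0] == pytest.approx(3.5)

    def test_constant_row_zero_variance(self, small_cohort):
        _, meta, _ = small_cohort
        values = pd.DataFrame(
            [[20.0] * len(meta.samples)], index=["P1"], columns=meta.samples
        )
        fit = fit_linear_model(IntensityMatrix(values), build_design(meta))
        assert fit.s2.iloc[0] == 0.0
        assert fit.amean.iloc[0] == 20.0
        for name in ("AS_vs_CON", "MR_vs_CON", "AS_vs_MR"):
            est = fit.coef.to_numpy() @ fit.design.contrast(name)
            assert est[0] == pytest.approx(0.0)

    def test_incomplete_matrix_rejected(self, censored_cohort):
        censored, meta, _, _ = censored_cohort
        with pytest.raises(ValueError, match="complete"):
            fit_linear_model(censored, build_design(meta))


class TestVariancePrior:
    def test_recovers_simulated_prior(self):
        """Moment estimator recovers (d0, s0) from scaled-F simulated s2."""
        rng = np.random.default_rng(12)
        d0_true, s0_true, d = 10.0, 0.05, 4
        n = 5000
        s2 = (
            s0_true
            * (rng.chisquare(d, n) / d)
            / (rng.chisquare(d0_true, n) / d0_true)
        )
        fit = _fit_from_s2(s2, d)
        prior = estimate_variance_prior(fit, trend=False)
        assert 7 <= prior.d0 <= 14
        assert abs(prior.s0_scalar - s0_true) / s0_true < 0.10

    def test_identical_variances_give_infinite_d0(self):
        fit = _fit_from_s2(np.full(100, 0.3), 4)
        with pytest.warns(UserWarning, match="identical"):
            prior = estimate_variance_prior(fit, trend=False)
        assert np.isinf(prior.d0)

    def test_trend_off_constant_s0(self):
        rng = np.random.default_rng(3)
        fit = _fit_from_s2(rng.chisquare(4, 200) / 4, 4)
        prior = estimate_variance_prior(fit, trend=False)
        s0 = prior.s0_of(np.array([20.0, 25.0, 30.0]))
        assert np.all(s0 == s0[0])

    def test_trend_follows_mean_variance_relation(self):
        rng = np.random.default_rng(4)
        n, d = 2000, 10
        amean = rng.uniform(20, 30, n)
        true_var = np.exp(0.3 * (amean - 25))  # variance increasing with A
        s2 = true_var * rng.chisquare(d, n) / d
        fit = _fit_from_s2(s2, d, amean=amean)
        prior = estimate_variance_prior(fit, trend=True)
        s0 = prior.s0_of(np.array([21.0, 29.0]))
        assert s0[1] > s0[0] * 3

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (0.01, 0.5, 2.0, 50.0):
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


def _fit_from_s2(s2, d, amean=None):
    """Minimal LinearFit carrying given residual variances."""
    from valveproteome.linear_model import LinearFit

    n = len(s2)
    idx = pd.Index([f"P{i}" for i in range(n)])
    X = pd.DataFrame({"g": [1.0] * (d + 1)}, index=[f"s{i}" for i in range(d + 1)])
    design = DesignSpec(matrix=X, contrasts={"c": np.array([1.0])})
    return LinearFit(
        coef=pd.DataFrame({"g": np.zeros(n)}, index=idx),
        s2=pd.Series(np.asarray(s2, dtype=float), index=idx),
        df_resid=float(d),
        xtx_inv=np.array([[1.0 / (d + 1)]]),
        amean=pd.Series(
            amean if amean is not None else np.full(n, 25.0), index=idx
        ),
        design=design,
    )


class TestModeratedStatistics:
    def test_d0_zero_equals_ordinary_t(self, two_group_matrix):
        fit, _ = toy_fit(two_group_matrix)
        prior = EBPrior(d0=0.0, s0_scalar=1.0)
        res = moderated_statistics(fit, prior, "AS_vs_CON")
        t_ref, p_ref = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert res.table["t"].iloc[0] == pytest.approx(t_ref)
        assert res.table["p"].iloc[0] == pytest.approx(p_ref)

    def test_d0_infinite_uses_prior_variance(self, two_group_matrix):
        fit, _ = toy_fit(two_group_matrix)
        prior = EBPrior(d0=np.inf, s0_scalar=4.0)
        res = moderated_statistics(fit, prior, "AS_vs_CON")
        # t = -3 / (sqrt(2/3) * 2), normal reference
        expected_t = -3.0 / (np.sqrt(2.0 / 3.0) * 2.0)
        assert res.table["t"].iloc[0] == pytest.approx(expected_t)
        assert res.table["p"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(abs(expected_t))
        )

    def test_hand_evaluated_posterior_variance(self, two_group_matrix):
        # d0=4, s0=1, s2=1 -> posterior variance 1; t = 3/sqrt(2/3); df = 8
        fit, _ = toy_fit(two_group_matrix)
        prior = EBPrior(d0=4.0, s0_scalar=1.0)
        res = moderated_statistics(fit, prior, "AS_vs_CON")
        expected_t = -3.0 / np.sqrt(2.0 / 3.0)
        assert res.table["t"].iloc[0] == pytest.approx(expected_t, abs=1e-9)
        assert abs(res.table["t"].iloc[0]) == pytest.approx(3.674, abs=1e-3)
        assert res.table["p"].iloc[0] == pytest.approx(
            2 * stats.t.sf(abs(expected_t), 8)
        )

    def test_oracle_equivalence_small_matrix(self):
        """With d0 = 0 the pipeline reproduces per-protein ordinary t-tests."""
        rng = np.random.default_rng(8)
        values = pd.DataFrame(
            rng.normal(25, 1, size=(20, 12)),
            index=[f"P{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(12)],
        )
        meta = make_meta({"AS": {"female": 6}, "CON": {"female": 6}})
        values.columns = meta.samples
        design = two_group_design(meta, "AS", "CON")
        fit = fit_linear_model(IntensityMatrix(values), design)
        res = moderated_statistics(fit, EBPrior(0.0, 1.0), "AS_vs_CON")
        x = values.iloc[:, :6].to_numpy()
        y = values.iloc[:, 6:].to_numpy()
        t_ref, p_ref = stats.ttest_ind(x, y, axis=1)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, atol=1e-10)


class TestLimmaCrossCheck:
    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: R limma's eBayes on a heteroscedastic matrix."""
        rng = np.random.default_rng(7)
        n_prot, n = 150, 12
        true_var = 0.25 * 8 / rng.chisquare(8, n_prot)
        Y = rng.normal(0, 1, (n_prot, n)) * np.sqrt(true_var)[:, None] + 25
        df = pd.DataFrame(
            Y,
            index=[f"P{i}" for i in range(n_prot)],
            columns=[f"s{j}" for j in range(n)],
        )
        mat = tmp_path / "mat.tsv"
        out = tmp_path / "limma.tsv"
        df.to_csv(mat, sep="\t")
        script = tmp_path / "run.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'Y <- as.matrix(read.delim("{mat}", row.names=1))\n'
            'design <- model.matrix(~0 + factor(rep(c("A","B"), each=6)))\n'
            'colnames(design) <- c("A","B")\n'
            "fit <- lmFit(Y, design)\n"
            'fit <- contrasts.fit(fit, makeContrasts(A-B, levels=design))\n'
            "fit <- eBayes(fit, trend=FALSE)\n"
            "out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],"
            " d0=fit$df.prior, s0=fit$s2.prior)\n"
            f'write.table(out, "{out}", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        lim = pd.read_csv(out, sep="\t")

        meta = make_meta({"AS": {"female": 6}, "CON": {"female": 6}})
        values = df.copy()
        values.columns = meta.samples
        design = two_group_design(meta, "AS", "CON")
        fit = fit_linear_model(IntensityMatrix(values), design)
        prior = estimate_variance_prior(fit, trend=False)
        res = moderated_statistics(fit, prior, "AS_vs_CON")
        assert prior.d0 == pytest.approx(lim["d0"].iloc[0], rel=1e-9)
        assert prior.s0_scalar == pytest.approx(lim["s0"].iloc[0], rel=1e-9)
        np.testing.assert_allclose(res.table["t"], lim["t"], atol=1e-9)
        np.testing.assert_allclose(res.table["p"], lim["p"], atol=1e-9)


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_ceiling(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)
        assert np.all(adjust_bh([1.0, 1.0, 1.0]) == 1.0)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = adjust_bh(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.1, 1.5])


class TestNullCalibration:
    def test_raw_p_uniform_on_null_cohort(self):
        """Moderated raw p-values are uniform when nothing is planted."""
        cfg = SynthConfig(n_proteins=2000, frac_effect=0.0, seed=21)
        matrix, meta, _ = generate_cohort(cfg)
        design = build_design(meta)
        fit = fit_linear_model(matrix, design)
        prior = estimate_variance_prior(fit, trend=True)
        res = moderated_statistics(fit, prior, "AS_vs_CON")
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01
        assert int((res.table["adj_p"] < 0.05).sum()) <= 0.02 * 2000
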