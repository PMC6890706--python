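import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import immstrat as im
from immstrat.io import ExpressionMatrix, ImmstratError
from immstrat.lasso import _path_fit, kkt_residual, lambda_max


def _centered_matrix(X, genes=None, samples=None):
    """samples x genes array -> mean-centered genes x samples ExpressionMatrix."""
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    samples = samples or [f"s{i}" for i in range(X.shape[0])]
    df = pd.DataFrame(X.T, index=genes, columns=samples)
    return im.mean_center(ExpressionMatrix(df))


def _toy_problem(rng, n=120, p=25, informative=3, shift=2.0):
    y = rng.random(n) < 0.5
    X = rng.normal(size=(n, p))
    X[:, :informative] += shift * y[:, None]
    X = X - X.mean(axis=0)
    return X, y


class TestSolver:
    def test_all_zero_at_and_above_lambda_max(self, rng):
        X, y = _toy_problem(rng)
        lmax = lambda_max(X, y.astype(float))
        for lam in (lmax, lmax * 1.3):
            _, b0, beta = next(iter(_path_fit(X, y.astype(float), [lam])))
            assert np.all(beta == 0.0)
            assert kkt_residual(X, y.astype(float), b0, beta, lam) < 1e-6

    def test_kkt_conditions_hold_along_path(self, rng):
        X, y = _toy_problem(rng)
        lmax = lambda_max(X, y.astype(float))
        path = lmax * np.array([0.5, 0.1, 0.02])
        for lam, b0, beta in _path_fit(X, y.astype(float), path):
            assert kkt_residual(X, y.astype(float), b0, beta, lam) < 1e-4

    def test_perfectly_separating_gene_dominates(self, rng):
        n = 80
        y = np.repeat([False, True], n // 2)
        X = rng.normal(size=(n, 10)) * 0.3
        X[:, 4] = np.where(y, 2.0, -2.0) + rng.normal(0, 0.05, n)
        matrix = _centered_matrix(X)
        w = im.fit_l1_logistic(matrix, pd.Series(y, index=matrix.samples), seed=0)
        coef = w.coefficients.reindex(matrix.genes).fillna(0.0)
        assert coef.abs().idxmax() == "g4"

    def test_permuted_labels_give_chance_auc(self, rng):
        aucs = []
        for rep in range(5):
            X, y = _toy_problem(rng, n=300, p=40)
            y_perm = rng.permutation(y)
            matrix = _centered_matrix(X)
            w = im.fit_l1_logistic(
                matrix, pd.Series(y_perm, index=matrix.samples), seed=rep, n_lambda=15
            )
            Xte = rng.normal(size=(400, 40))
            te = _centered_matrix(Xte, samples=[f"t{i}" for i in range(400)])
            yte = pd.Series(rng.random(400) < 0.5, index=te.samples)
            if w.n_targets == 0:
                aucs.append(0.5)  # empty model: index constant, AUC 1/2 by ties
            else:
                aucs.append(im.roc_auc(im.index_score(te, w).index, yte))
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_single_class_labels_error(self, rng):
        X, _ = _toy_problem(rng, n=40)
        matrix = _centered_matrix(X)
        with pytest.raises(ImmstratError):
            im.fit_l1_logistic(matrix, pd.Series(True, index=matrix.samples))

    def test_uncentered_matrix_rejected(self, rng):
        X, y = _toy_problem(rng, n=40)
        df = pd.DataFrame(X.T + 5.0, index=[f"g{i}" for i in range(X.shape[1])],
                          columns=[f"s{i}" for i in range(40)])
        with pytest.raises(ImmstratError, match="mean-centered"):
            im.fit_l1_logistic(ExpressionMatrix(df), pd.Series(y, index=df.columns))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_glmnet_at_fixed_lambda(tmp_path, rng):
    """Independent oracle: R glmnet solves the same penalized objective."""
    n, p = 60, 8
    X, y = _toy_problem(rng, n=n, p=p, informative=2, shift=1.5)
    lam = 0.05
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", y.astype(int), delimiter=",")
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent("""
        suppressMessages(library(glmnet))
        X <- as.matrix(read.csv("X.csv", header=FALSE))
        y <- scan("y.csv", quiet=TRUE)
        fit <- glmnet(X, y, family="binomial", lambda=0.05,
                      standardize=FALSE, intercept=TRUE, thresh=1e-14)
        cat(as.numeric(coef(fit)), sep="\\n")
    """))
    res = subprocess.run(
        ["Rscript", "fit.R"], cwd=tmp_path, capture_output=True, text=True, timeout=300
    )
    assert res.returncode == 0, res.stderr
    r_coef = np.array([float(v) for v in res.stdout.split()])
    _, b0, beta = next(iter(_path_fit(X, y.astype(float), [lam])))
    np.testing.assert_allclose(b0, r_coef[0], atol=2e-4)
    np.testing.assert_allclose(beta, r_coef[1:], atol=2e-4)


class TestIndexScore:
    def test_published_threshold_arithmetic(self):
        # beta = (0.5, -0.25) on X = (4, 2): index 1.5 exceeds the
        # published intercept 1.206538657, so the sample is Cluster B
        w = im.SignatureWeights(
            coefficients=pd.Series({"g1": 0.5, "g2": -0.25}), intercept=1.206538657
        )
        m = ExpressionMatrix(pd.DataFrame({"s0": [4.0, 2.0]}, index=["g1", "g2"]))
        out = im.index_score(m, w)
        assert out.index["s0"] == pytest.approx(1.5, abs=1e-12)
        assert bool(out.is_cluster_b["s0"]) is True

    def test_all_zero_coefficients_give_index_zero_not_b(self):
        w = im.SignatureWeights(
            coefficients=pd.Series({"g1": 0.0, "g2": 0.0}), intercept=1.206538657
        )
        m = ExpressionMatrix(pd.DataFrame({"s0": [4.0, 2.0]}, index=["g1", "g2"]))
        out = im.index_score(m, w)
        assert out.index["s0"] == 0.0
        assert bool(out.is_cluster_b["s0"]) is False

    def test_doubling_weights_doubles_index(self, rng):
        genes = [f"g{i}" for i in range(5)]
        m = ExpressionMatrix(pd.DataFrame(rng.normal(size=(5, 3)), index=genes,
                                          columns=["a", "b", "c"]))
        w1 = im.SignatureWeights(coefficients=pd.Series(rng.normal(size=5), index=genes),
                                 intercept=0.0)
        w2 = im.SignatureWeights(coefficients=2.0 * w1.coefficients, intercept=0.0)
        np.testing.assert_allclose(
            im.index_score(m, w2).index, 2.0 * im.index_score(m, w1).index, atol=1e-12
        )

    def test_index_invariant_to_absent_genes(self, rng):
        genes = [f"g{i}" for i in range(4)]
        m = ExpressionMatrix(pd.DataFrame(rng.normal(size=(4, 2)), index=genes, columns=["a", "b"]))
        w = im.SignatureWeights(coefficients=pd.Series({"g0": 1.0, "g2": -2.0}), intercept=0.0)
        w_extra = im.SignatureWeights(
            coefficients=pd.Series({"g0": 1.0, "g2": -2.0, "missing": 9.9}), intercept=0.0
        )
        np.testing.assert_allclose(im.index_score(m, w).index, im.index_score(m, w_extra).index)

    def test_no_weight_genes_found_errors(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["g"]))
        w = im.SignatureWeights(coefficients=pd.Series({"zz": 1.0}), intercept=0.0)
        with pytest.raises(ImmstratError):
            im.index_score(m, w)

    def test_roundtrip_weight_files(self, tmp_path):
        w = im.SignatureWeights(
            coefficients=pd.Series({"g1": 0.5, "g2": -0.25}),
            intercept=1.206538657,
            meta={"lambda": 0.1},
        )
        w.to_files(str(tmp_path / "w.tsv"))
        back = im.SignatureWeights.from_files(str(tmp_path / "w.tsv"))
        pd.testing.assert_series_equal(back.coefficients, w.coefficients, check_names=False)
        assert back.intercept == w.intercept


class TestPredictThreeClusters:
    def _weights(self, gene, coef, intercept):
        return im.SignatureWeights(coefficients=pd.Series({gene: coef}), intercept=intercept)

    def test_b_precedence_over_second_stage(self):
        m = ExpressionMatrix(pd.DataFrame({"s0": [10.0, 10.0]}, index=["g1", "g2"]))
        out = im.predict_three_clusters(
            m, self._weights("g1", 1.0, 0.0), self._weights("g2", 1.0, 0.0)
        )
        assert out.labels["s0"] == "B"

    def test_ac_only_when_no_b_exceeds(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s0": [-5.0, 3.0], "s1": [-5.0, -3.0]}, index=["g1", "g2"])
        )
        out = im.predict_three_clusters(
            m, self._weights("g1", 1.0, 0.0), self._weights("g2", 1.0, 0.0)
        )
        assert list(out.labels) == ["C", "A"]
        assert out.source == "predicted"


class TestRocAuc:
    def test_perfect_separation(self):
        s = pd.Series([0.1, 0.2, 0.9, 0.8], index=list("abcd"))
        y = pd.Series([False, False, True, True], index=list("abcd"))
        assert im.roc_auc(s, y) == 1.0

    def test_random_scores_near_half(self, rng):
        s = pd.Series(rng.normal(size=2000), index=[f"s{i}" for i in range(2000)])
        y = pd.Series(rng.random(2000) < 0.5, index=s.index)
        assert abs(im.roc_auc(s, y) - 0.5) < 0.03

    def test_tie_handling_matches_pair_counting(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        y = pd.Series([False, False, True, True], index=list("abcd"))
        # pairs (pos, neg): (c,a)=1, (c,b)=0.5 tie, (d,a)=1, (d,b)=1 -> 3.5/4
        assert im.roc_auc(s, y) == pytest.approx(3.5 / 4.0, abs=1e-12)

    def test_single_class_errors(self):
        s = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ImmstratError):
            im.roc_auc(s, pd.Series([True, True], index=list("ab")))
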