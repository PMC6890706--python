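import numpy as np
import pandas as pd
import pytest
from scipy import stats

import immstrat as im
from immstrat.cluster import ClusterAssignment
from immstrat.io import ExpressionMatrix, GeneSetCollection, ImmstratError
from immstrat.microenv import CellTypeProportions, GeneSetScores
from immstrat.simulate import CellTypeSignatureMatrix


def _signature(rng, n_genes=24, n_types=3):
    genes = [f"g{i}" for i in range(n_genes)]
    types = [f"t{i}" for i in range(n_types)]
    data = rng.lognormal(3.0, 0.5, size=(n_genes, n_types))
    markers = {}
    per = n_genes // n_types
    for k, t in enumerate(types):
        block = slice(k * per, k * per + per)
        data[block, :] *= 0.05
        data[block, k] *= 100.0
        markers[t] = genes[block][:1]
    return CellTypeSignatureMatrix(data=pd.DataFrame(data, index=genes, columns=types),
                                   markers=markers)


def _bulk_from(sig, W):
    lin = sig.data.to_numpy() @ W.T
    df = pd.DataFrame(np.log2(lin + 1.0), index=sig.genes,
                      columns=[f"s{i}" for i in range(W.shape[0])])
    return ExpressionMatrix(df)


class TestDeconvolve:
    def test_noiseless_two_type_mixture_recovered(self, rng):
        sig = _signature(rng, n_types=2, n_genes=16)
        W = np.array([[0.3, 0.7], [0.5, 0.5]])
        out = im.deconvolve(_bulk_from(sig, W), sig)
        np.testing.assert_allclose(out.relative.to_numpy(), W, atol=1e-6)

    def test_single_signature_column_gets_fraction_one(self, rng):
        sig = _signature(rng)
        W = np.zeros((1, 3))
        W[0, 1] = 1.0
        out = im.deconvolve(_bulk_from(sig, W), sig)
        assert out.relative.iloc[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_residual_never_increases_with_true_type_added(self, rng):
        sig = _signature(rng)
        W = rng.dirichlet(np.ones(3), size=5)
        bulk = _bulk_from(sig, W)
        sub = CellTypeSignatureMatrix(
            data=sig.data.iloc[:, :2], markers={t: sig.markers[t] for t in sig.data.columns[:2]}
        )

        def _residual(signature):
            S = signature.data.to_numpy()
            sd = S.std(axis=1)
            Sz = S / sd[:, None]
            B = np.maximum(2.0 ** bulk.values - 1.0, 0.0) / sd[:, None]
            from scipy.optimize import nnls

            return [nnls(Sz, B[:, i])[1] for i in range(B.shape[1])]

        r_full = _residual(sig)
        r_sub = _residual(sub)
        assert all(f <= s + 1e-9 for f, s in zip(r_full, r_sub))

    def test_too_few_signature_genes_errors(self, rng):
        sig = _signature(rng)
        small = ExpressionMatrix(
            pd.DataFrame(np.ones((3, 2)), index=sig.genes[:3], columns=["a", "b"])
        )
        with pytest.raises(ImmstratError, match="signature genes"):
            im.deconvolve(small, sig)

    def test_noisy_recovery_matches_generator_truth(self, rng):
        sig = im.generate_signature_matrix(im.SyntheticConfig())
        W = rng.dirichlet(np.ones(8), size=60)
        lin = sig.data.to_numpy() @ W.T
        logged = np.log2(lin + 1.0) + rng.normal(0, 0.5, lin.shape)
        bulk = ExpressionMatrix(pd.DataFrame(logged, index=sig.genes,
                                             columns=[f"s{i}" for i in range(60)]))
        out = im.deconvolve(bulk, sig)
        assert np.abs(out.relative.to_numpy() - W).mean() < 0.05


class TestGenesetScore:
    def test_single_gene_set_is_z_score(self, rng):
        vals = rng.normal(size=(3, 6))
        m = ExpressionMatrix(pd.DataFrame(vals, index=["a", "b", "c"],
                                          columns=[f"s{i}" for i in range(6)]))
        out = im.geneset_score(m, GeneSetCollection(sets={"one": ["b"]}))
        z = (vals[1] - vals[1].mean()) / vals[1].std()
        np.testing.assert_allclose(out.scores["one"], z, atol=1e-12)

    def test_all_genes_set_is_mean_z(self, rng):
        vals = rng.normal(size=(4, 5))
        m = ExpressionMatrix(pd.DataFrame(vals, index=list("abcd"),
                                          columns=[f"s{i}" for i in range(5)]))
        out = im.geneset_score(m, GeneSetCollection(sets={"all": list("abcd")}))
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        np.testing.assert_allclose(out.scores["all"], z.mean(axis=0), atol=1e-12)

    def test_invariant_under_per_gene_affine_transform(self, rng):
        vals = rng.normal(size=(5, 8))
        m1 = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(5)],
                                           columns=[f"s{i}" for i in range(8)]))
        a = rng.uniform(0.5, 2.0, size=(5, 1))
        b = rng.normal(size=(5, 1))
        m2 = ExpressionMatrix(pd.DataFrame(vals * a + b, index=m1.genes, columns=m1.samples))
        sets = GeneSetCollection(sets={"s": ["g0", "g2", "g4"]})
        np.testing.assert_allclose(
            im.geneset_score(m1, sets).scores, im.geneset_score(m2, sets).scores, atol=1e-10
        )

    def test_unmeasured_set_flagged_not_zero(self, rng):
        m = ExpressionMatrix(pd.DataFrame(rng.normal(size=(2, 4)), index=["a", "b"],
                                          columns=[f"s{i}" for i in range(4)]))
        out = im.geneset_score(m, GeneSetCollection(sets={"ghost": ["zz"]}))
        assert out.scores["ghost"].isna().all()
        assert "ghost" in out.flagged

    def test_emt_score_higher_in_b_emt_than_a(self, default_cohort):
        tr = default_cohort.truth.table
        gs = im.geneset_score(default_cohort.expression, default_cohort.gene_sets)
        b_emt = tr.index[(tr.true_cluster == "B") & (tr.true_phenotype == "EMT")]
        a = tr.index[tr.true_cluster == "A"]
        assert gs.scores.loc[b_emt, "emt_program"].median() > gs.scores.loc[a, "emt_program"].median()


class TestCelltypeMedianMap:
    def _props(self, vals, samples):
        df = pd.DataFrame(vals, index=samples, columns=["t0", "t1"])
        rel = df.div(df.sum(axis=1), axis=0)
        return CellTypeProportions(absolute=df, relative=rel)

    def test_hand_computed_medians(self):
        samples = [f"s{i}" for i in range(9)]
        vals = np.arange(18.0).reshape(9, 2)
        props = self._props(vals, samples)
        labels = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=samples)
        assignment = ClusterAssignment(labels=labels, k=3)
        table, _, _ = im.celltype_median_map(props, assignment)
        assert table.loc["cohort|A", "t0"] == 2.0
        assert table.loc["cohort|B", "t1"] == 9.0

    def test_invariant_to_sample_order(self, rng):
        samples = [f"s{i}" for i in range(12)]
        vals = rng.uniform(0.1, 2.0, size=(12, 2))
        labels = pd.Series(list("ABC") * 4, index=samples)
        a1 = ClusterAssignment(labels=labels, k=3)
        t1, _, _ = im.celltype_median_map(self._props(vals, samples), a1)
        perm = rng.permutation(12)
        t2, _, _ = im.celltype_median_map(
            self._props(vals[perm], [samples[i] for i in perm]),
            ClusterAssignment(labels=labels.iloc[perm], k=3),
        )
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_protumor_types_enriched_in_b_vs_c(self, default_cohort):
        props = im.deconvolve(default_cohort.expression, default_cohort.signature)
        tr = default_cohort.truth.table["true_cluster"]
        for t in ("macrophage_m2", "mast_resting", "t_memory_resting"):
            med_b = props.relative.loc[tr == "B", t].median()
            med_c = props.relative.loc[tr == "C", t].median()
            assert med_b > med_c


class TestLogisticExplainers:
    def test_binary_feature_matches_log_odds_ratio(self, rng):
        n = 400
        x = rng.random(n) < 0.5
        p = np.where(x, 0.7, 0.3)
        y = rng.random(n) < p
        feats = pd.DataFrame({"f": x.astype(float)}, index=[f"s{i}" for i in range(n)])
        target = pd.Series(y, index=feats.index)
        out = im.logistic_explainers(feats, target, mode="univariate")
        tab = pd.crosstab(x, y)
        lor = np.log(tab.loc[True, True] * tab.loc[False, False]
                     / (tab.loc[True, False] * tab.loc[False, True]))
        # feature was standardized internally; unscale the coefficient
        est = out.table["estimate"].iloc[0] / feats["f"].std(ddof=0)
        assert est == pytest.approx(lor, abs=1e-6)

    def test_null_features_rarely_significant(self, rng):
        hits, reps = 0, 10
        for _ in range(reps):
            n = 2000
            y = pd.Series(rng.random(n) < 0.5, index=range(n))
            feats = pd.DataFrame({"f": rng.normal(size=n)}, index=range(n))
            out = im.logistic_explainers(feats, y, mode="univariate")
            row = out.table.iloc[0]
            if abs(row["estimate"]) < 0.15 and row["fdr_p"] > 0.05:
                hits += 1
        assert hits >= 0.9 * reps

    def test_duplicated_feature_column_errors(self, rng):
        n = 100
        f = rng.normal(size=n)
        feats = pd.DataFrame({"a": f, "b": f}, index=range(n))
        y = pd.Series(rng.random(n) < 0.5, index=range(n))
        with pytest.raises(ImmstratError, match="rank"):
            im.logistic_explainers(feats, y, mode="multivariable")


class TestCorrelateScoresProportions:
    def _fixture(self, rng, n=30):
        samples = [f"s{i}" for i in range(n)]
        props = pd.DataFrame(rng.uniform(0.1, 1.0, size=(n, 2)), index=samples,
                             columns=["t0", "t1"])
        scores = pd.DataFrame({"setA": props["t0"], "setB": rng.normal(size=n)},
                              index=samples)
        return (GeneSetScores(scores=scores),
                CellTypeProportions(absolute=props,
                                    relative=props.div(props.sum(axis=1), axis=0)))

    def test_identical_columns_give_rho_one(self, rng):
        scores, props = self._fixture(rng)
        rho, fdr, mask = im.correlate_scores_proportions(scores, props)
        assert rho.loc["setA", "t0"] == pytest.approx(1.0, abs=1e-12)
        assert bool(mask.loc["setA", "t0"])

    def test_matches_bruteforce_rank_pearson(self, rng):
        scores, props = self._fixture(rng, n=10)
        rho, _, _ = im.correlate_scores_proportions(scores, props)
        for s in scores.scores.columns:
            for t in props.absolute.columns:
                expected = np.corrcoef(
                    stats.rankdata(scores.scores[s]), stats.rankdata(props.absolute[t])
                )[0, 1]
                assert rho.loc[s, t] == pytest.approx(expected, abs=1e-10)

    def test_null_false_discoveries_controlled(self, rng):
        total_fd = 0
        reps = 5
        for _ in range(reps):
            n = 500
            samples = [f"s{i}" for i in range(n)]
            props = pd.DataFrame(rng.uniform(size=(n, 5)), index=samples,
                                 columns=[f"t{i}" for i in range(5)])
            scores = pd.DataFrame(rng.normal(size=(n, 10)), index=samples,
                                  columns=[f"set{i}" for i in range(10)])
            _, _, mask = im.correlate_scores_proportions(
                GeneSetScores(scores=scores),
                CellTypeProportions(absolute=props,
                                    relative=props.div(props.sum(axis=1), axis=0)),
            )
            total_fd += int(mask.to_numpy().sum())
        assert total_fd / reps <= 2.5 + 1.0
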