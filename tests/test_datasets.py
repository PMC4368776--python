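import logging

import numpy as np
import pandas as pd
import pytest

from disis import (
    FeatureBlock,
    assemble,
    default_block_sizes,
    generate_synthetic,
    load_feature_block,
    pearson_corr,
    sigma_for_r2,
    write_feature_block,
)

from conftest import weak_family


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


class TestLoadFeatureBlock:
    def test_genes_by_samples_is_transposed(self, tmp_path):
        path = _write(tmp_path, "expr.tsv", "gene\tA\tB\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        block = load_feature_block(path, "expression", "genes_by_samples")
        assert block.values.shape == (2, 3)
        assert block.sample_ids == ["A", "B"]
        np.testing.assert_array_equal(block.values, [[1, 3, 5], [2, 4, 6]])

    def test_orientations_agree_after_normalisation(self, tmp_path):
        p1 = _write(tmp_path, "a.tsv", "gene\tA\tB\ng1\t1\t2\ng2\t3\t4\n")
        p2 = _write(tmp_path, "b.tsv", "cell\tg1\tg2\nA\t1\t3\nB\t2\t4\n")
        b1 = load_feature_block(p1, "expression", "genes_by_samples")
        b2 = load_feature_block(p2, "expression", "samples_by_genes")
        np.testing.assert_array_equal(b1.values, b2.values)
        assert b1.feature_ids == b2.feature_ids

    def test_duplicate_gene_row_named_in_error(self, tmp_path):
        path = _write(tmp_path, "dup.tsv", "gene\tA\tB\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ValueError, match="g1"):
            load_feature_block(path, "expression")

    def test_mutation_value_outside_binary_domain(self, tmp_path):
        path = _write(tmp_path, "mut.tsv", "gene\tA\tB\ng1\t0\t1\ng2\t2\t0\n")
        with pytest.raises(ValueError, match="g2"):
            load_feature_block(path, "mutation")

    def test_non_numeric_cell_located(self, tmp_path):
        path = _write(tmp_path, "bad.tsv", "gene\tA\tB\ng1\t1\tx\ng2\t3\t4\n")
        with pytest.raises(ValueError, match="'x'"):
            load_feature_block(path, "expression")

    def test_missing_value_errors_unless_imputed(self, tmp_path):
        path = _write(tmp_path, "na.tsv", "gene\tA\tB\tC\ng1\t1\t\t3\ng2\t4\t5\t6\n")
        with pytest.raises(ValueError, match="missing"):
            load_feature_block(path, "expression")
        block = load_feature_block(path, "expression", impute_mean=True)
        assert block.values[1, 0] == 2.0  # mean of 1 and 3

    def test_round_trip_exact(self, tmp_path, rng):
        block = FeatureBlock(
            kind="copynumber",
            feature_ids=[f"g{j}" for j in range(4)],
            sample_ids=["A", "B", "C"],
            values=rng.standard_normal((3, 4)),
        )
        for orientation in ("genes_by_samples", "samples_by_genes"):
            path = str(tmp_path / f"{orientation}.tsv")
            write_feature_block(block, path, orientation)
            back = load_feature_block(path, "copynumber", orientation)
            np.testing.assert_array_equal(back.values, block.values)
            assert back.feature_ids == block.feature_ids


def _block(kind, genes, samples, values):
    return FeatureBlock(kind=kind, feature_ids=genes, sample_ids=samples, values=values)


class TestAssemble:
    def _response(self, samples, values, drug="drugX"):
        return pd.DataFrame({drug: values}, index=samples)

    def test_sample_intersection(self):
        b1 = _block("expression", ["g1"], ["A", "B", "C"], [[1.0], [2.0], [3.0]])
        b2 = _block("mutation", ["g2"], ["B", "C", "D"], [[0.0], [1.0], [0.0]])
        resp = self._response(["B", "C"], [1.0, 2.0])
        X, y = assemble([b1, b2], resp, "drugX")
        assert X.sample_ids == ["B", "C"]
        assert y.sample_ids == ["B", "C"]

    def test_namespaced_concatenation_order(self):
        vals = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        exp = _block("expression", ["g1", "g2", "g3"], ["A", "B"], vals)
        mut = _block("mutation", ["g4", "g5"], ["A", "B"], [[0.0, 1.0], [1.0, 0.0]])
        resp = self._response(["A", "B"], [0.5, 1.5])
        # block input order must not matter: canonical order is EXP, MUT, CNV
        X, _ = assemble([mut, exp], resp, "drugX")
        assert X.p == 5
        assert X.feature_ids == ["EXP:g1", "EXP:g2", "EXP:g3", "MUT:g4", "MUT:g5"]

    def test_missing_response_dropped_and_logged(self, caplog):
        b = _block("expression", ["g1"], ["A", "B", "C"], [[1.0], [2.0], [3.0]])
        resp = self._response(["A", "B", "C"], [1.0, 2.0, np.nan])
        with caplog.at_level(logging.WARNING, logger="disis.datasets"):
            X, y = assemble([b], resp, "drugX")
        assert X.sample_ids == ["A", "B"]
        assert "dropping 1" in caplog.text

    def test_permutation_invariance(self, rng):
        genes = [f"g{j}" for j in range(3)]
        samples = ["A", "B", "C", "D"]
        vals = rng.standard_normal((4, 3))
        resp = self._response(samples, [1.0, 2.0, 3.0, 4.0])
        X1, y1 = assemble([_block("expression", genes, samples, vals)], resp, "drugX")
        shuffled = [2, 0, 3, 1]
        X2, y2 = assemble(
            [_block("expression", genes, [samples[i] for i in shuffled], vals[shuffled])],
            resp.iloc[::-1],
            "drugX",
        )
        np.testing.assert_array_equal(X1.values, X2.values)
        np.testing.assert_array_equal(y1.values, y2.values)

    def test_empty_intersection_errors(self):
        b1 = _block("expression", ["g1"], ["A"], [[1.0]])
        b2 = _block("mutation", ["g2"], ["B"], [[0.0]])
        with pytest.raises(ValueError, match="intersection"):
            assemble([b1, b2], self._response(["A", "B"], [1.0, 2.0]), "drugX")

    def test_unknown_drug_lists_available(self):
        b = _block("expression", ["g1"], ["A", "B"], [[1.0], [2.0]])
        with pytest.raises(KeyError, match="drugX"):
            assemble([b], self._response(["A", "B"], [1.0, 2.0], drug="other"), "drugX")


class TestGenerateSynthetic:
    def test_weak_feature_marginal_correlation_vanishes(self):
        # near-noiseless: any residual correlation is purely sampling error
        X, y, truth = generate_synthetic(
            n=2000, p=200, s_strong=3, rho=0.5, sigma=1e-6, seed=5, expr_subblock=20
        )
        r = pearson_corr(X.values[:, truth.weak_feature], y.values)
        assert abs(r) < 0.1

    @pytest.mark.parametrize("n", [1000, 4000])
    def test_weak_marginal_shrinks_with_n(self, n):
        X, y, truth = generate_synthetic(n=n, p=200, seed=17, expr_subblock=20)
        r = pearson_corr(X.values[:, truth.weak_feature], y.values)
        assert abs(r) < 3 * 2 / np.sqrt(n)

    def test_strong_features_independent_at_rho_zero(self):
        X, _, truth = generate_synthetic(
            n=2000, p=200, s_strong=5, rho=0.0, seed=9, expr_subblock=15
        )
        strong = [j for j in truth.support if j != truth.weak_feature]
        cors = [
            abs(pearson_corr(X.values[:, a], X.values[:, b]))
            for i, a in enumerate(strong)
            for b in strong[i + 1:]
        ]
        assert np.mean(cors) < 0.1

    def test_expression_subblocks_correlated_at_rho(self):
        X, _, _ = generate_synthetic(n=4000, p=200, rho=0.6, seed=2, expr_subblock=20)
        # columns 1 and 2 sit in the same sub-block and are not support members
        r = pearson_corr(X.values[:, 1], X.values[:, 2])
        assert r == pytest.approx(0.6, abs=0.06)

    def test_seed_determinism_bit_identical(self):
        a = generate_synthetic(n=50, p=60, seed=3, expr_subblock=7)
        b = generate_synthetic(n=50, p=60, seed=3, expr_subblock=7)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        assert a[2].support == b[2].support

    def test_truth_contract(self):
        X, _, truth = weak_family(0)
        assert truth.weak_feature in truth.support
        assert X.feature_ids[truth.weak_feature].startswith("EXP:")
        assert truth.beta[truth.weak_feature] == pytest.approx(-0.75)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(sigma=0.0), "sigma"),
            (dict(block_sizes=(10, 10, 10)), "block_sizes"),
            (dict(s_strong=0), "s_strong"),
            (dict(rho=1.0), "rho"),
        ],
    )
    def test_invalid_parameters(self, kwargs, msg):
        args = dict(n=50, p=60, expr_subblock=10)
        args.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            generate_synthetic(**args)

    def test_block_size_split_sums_to_p(self):
        assert sum(default_block_sizes(1000)) == 1000
        assert sum(default_block_sizes(42953)) == 42953

    def test_sigma_for_r2_matches_empirical_variance(self):
        sigma = sigma_for_r2(3, 0.81)
        X, y, truth = generate_synthetic(
            n=20000, p=100, s_strong=3, sigma=sigma, seed=1, expr_subblock=10
        )
        r2 = 1 - sigma**2 / np.var(y.values)
        assert r2 == pytest.approx(0.81, abs=0.02)
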