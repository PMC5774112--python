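"""PCA pattern extraction, PC1 correlation and clustering order."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radioshift import generate_pattern_study
from radioshift.pattern import (correlate_with_pc1, extract_pattern,
                                hierarchical_order, partition_by_sign, run_pca)
from radioshift.preprocess import normalize_to_control_median, normalize_to_percentile

from conftest import make_matrix


def ratio_matrix(log2_values, groups=None, tps=None):
    log2_values = np.asarray(log2_values, dtype=float)
    n_arrays = log2_values.shape[1]
    groups = groups or ["RT_IgG"] * n_arrays
    tps = tps or ["18w"] * n_arrays
    return make_matrix(np.exp2(log2_values), groups, tps, scale="control_ratio")


def prepare_pattern_ratios(seed=0, **kw):
    m, truth = generate_pattern_study(seed=seed, **kw)
    chip = normalize_to_percentile(m)
    return normalize_to_control_median(chip, "noRT_IgG"), truth


class TestRunPCA:
    def test_rank_one_matrix_fully_explained(self):
        rng = np.random.default_rng(0)
        probe_amp = rng.normal(0, 1, 20)
        array_pat = rng.normal(0, 1, 6)
        X = np.outer(probe_amp, array_pat)
        m = ratio_matrix(X)
        res = run_pca(m, m.probe_ids)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)
        # PC1 recovers the array pattern up to sign/scale (after centering)
        pat = array_pat - array_pat.mean()
        pc1 = res.pc1.to_numpy()
        cos = abs(pat @ pc1) / np.linalg.norm(pat)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_variance_fractions_sum_to_one_and_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        m = ratio_matrix(rng.normal(0, 1, size=(30, 8)))
        res = run_pca(m, m.probe_ids)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        S = res.scores.to_numpy()
        np.testing.assert_allclose(S.T @ S, np.eye(S.shape[1]), atol=1e-10)

    def test_planted_variance_split_recovered(self):
        ratios, truth = prepare_pattern_ratios(seed=2)
        probes = truth.primary_probes + truth.secondary_probes
        res = run_pca(ratios, probes)
        assert res.variance_fractions[0] == pytest.approx(0.7, abs=0.05)

    def test_orientation_rule_restores_polarity(self):
        ratios, truth = prepare_pattern_ratios(seed=3)
        probes = truth.primary_probes + truth.secondary_probes
        res = run_pca(ratios, probes)
        rt18 = ratios.arrays_where(group="RT_IgG", timepoint="18w")
        assert res.pc1[rt18].mean() > 0
        # negating all inputs flips the raw sign but the rule restores it
        neg = ratios.with_values(1.0 / ratios.values, "control_ratio")
        res2 = run_pca(neg, probes)
        assert res2.pc1[rt18].mean() > 0

    def test_constant_matrix_errors(self):
        m = ratio_matrix(np.zeros((5, 4)))
        with pytest.raises(ValueError, match="constant"):
            run_pca(m, m.probe_ids)

    def test_matches_bruteforce_eigendecomposition(self):
        """SVD route agrees with explicit covariance eigendecomposition."""
        rng = np.random.default_rng(4)
        for n_arrays in (4, 7, 10):
            X = rng.normal(0, 1, size=(40, n_arrays))
            m = ratio_matrix(X, groups=["g"] * n_arrays, tps=["t"] * n_arrays)
            res = run_pca(m, m.probe_ids, orient_group="none")
            Xc = X - X.mean(axis=1, keepdims=True)
            cov = Xc.T @ Xc
            evals, evecs = np.linalg.eigh(cov)
            evals, evecs = evals[::-1], evecs[:, ::-1]
            np.testing.assert_allclose(res.variance_fractions,
                                       evals / evals.sum(), atol=1e-10)
            for k in range(n_arrays - 1):
                dot = abs(res.scores.iloc[:, k] @ evecs[:, k])
                assert dot == pytest.approx(1.0, abs=1e-8)


class TestCorrelateWithPC1:
    def test_profile_proportional_to_pc1_selected(self):
        rng = np.random.default_rng(5)
        pat = rng.normal(0, 1, 8)
        X = np.outer(rng.normal(1, 0.1, 30), pat)
        X[0] = 2.0 * pat             # exactly proportional
        m = ratio_matrix(X)
        res = run_pca(m, m.probe_ids)
        table, selected = correlate_with_pc1(m, m.probe_ids, res)
        assert abs(table.loc["p0", "r"]) == pytest.approx(1.0, abs=1e-9)
        assert table.loc["p0", "p"] == pytest.approx(0.0, abs=1e-12)
        assert "p0" in selected

    def test_orthogonal_profile_excluded(self):
        pat = np.array([1.0, -1.0, 1.0, -1.0])
        orth = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.vstack([np.outer(np.ones(10), pat), orth])
        m = ratio_matrix(X)
        res = run_pca(m, m.probe_ids)
        table, selected = correlate_with_pc1(m, m.probe_ids, res)
        assert table.loc["p10", "r"] == pytest.approx(0.0, abs=1e-9)
        assert "p10" not in selected

    def test_zero_variance_profile_excluded(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, size=(10, 5))
        X[3] = 0.7          # constant profile
        m = ratio_matrix(X)
        res = run_pca(m, m.probe_ids)
        table, _ = correlate_with_pc1(m, m.probe_ids, res)
        assert "p3" not in table.index

    def test_p_matches_t_transform(self):
        """p-values equal the analytic t transform at n = 5 arrays."""
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, size=(20, 5))
        m = ratio_matrix(X)
        res = run_pca(m, m.probe_ids)
        table, _ = correlate_with_pc1(m, m.probe_ids, res, p_max=1.1)
        pc1 = res.pc1.to_numpy()
        for probe in table.index:
            r_ref, p_ref = stats.pearsonr(X[int(probe[1:])], pc1)
            assert table.loc[probe, "r"] == pytest.approx(r_ref, abs=1e-10)
            assert table.loc[probe, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_planted_pattern_recall(self):
        ratios, truth = prepare_pattern_ratios(seed=8)
        probes = truth.primary_probes + truth.secondary_probes
        res = run_pca(ratios, probes)
        _, selected = correlate_with_pc1(ratios, probes, res)
        recall = len(set(selected) & set(truth.primary_probes)) / len(truth.primary_probes)
        assert recall >= 0.9


class TestPartition:
    def test_all_positive_r_gives_empty_diminished(self):
        per_probe = pd.DataFrame({"r": [0.9, 0.8], "p": [1e-5, 1e-5]},
                                 index=["a", "b"])
        elevated, diminished = partition_by_sign(["a", "b"], per_probe)
        assert elevated == ["a", "b"] and diminished == []

    def test_partition_is_exhaustive(self):
        ratios, truth = prepare_pattern_ratios(seed=9)
        probes = truth.primary_probes + truth.secondary_probes
        res = extract_pattern(ratios, probes)
        assert len(res.elevated) + len(res.diminished) == len(res.selected)
        assert not set(res.elevated) & set(res.diminished)

    def test_planted_signs_assigned_to_correct_side(self):
        ratios, truth = prepare_pattern_ratios(seed=10)
        probes = truth.primary_probes + truth.secondary_probes
        res = extract_pattern(ratios, probes)
        up = {p for p in truth.primary_probes if truth.primary_sign[p] > 0}
        dn = {p for p in truth.primary_probes if truth.primary_sign[p] < 0}
        correct = len(up & set(res.elevated)) + len(dn & set(res.diminished))
        assigned = len(set(truth.primary_probes) & set(res.elevated + res.diminished))
        assert assigned > 0
        assert correct / assigned >= 0.99


class TestHierarchicalOrder:
    def test_identical_probes_adjacent(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, size=(8, 6))
        X[5] = X[2]
        m = ratio_matrix(X)
        order, _ = hierarchical_order(m, m.probe_ids)
        assert abs(order.index("p2") - order.index("p5")) == 1

    def test_output_is_permutation(self):
        rng = np.random.default_rng(12)
        m = ratio_matrix(rng.normal(0, 1, size=(15, 6)))
        order, _ = hierarchical_order(m, m.probe_ids)
        assert sorted(order) == sorted(m.probe_ids)

    def test_separated_clusters_form_contiguous_blocks(self):
        rng = np.random.default_rng(13)
        pat1 = np.array([1.0, 1, 1, -1, -1, -1])
        pat2 = -pat1
        X = np.vstack([np.outer(np.abs(rng.normal(1, 0.05, 10)), pat1),
                       np.outer(np.abs(rng.normal(1, 0.05, 10)), pat2)])
        X += rng.normal(0, 0.01, X.shape)
        m = ratio_matrix(X)
        order, _ = hierarchical_order(m, m.probe_ids)
        cluster1 = {f"p{i}" for i in range(10)}
        positions = [i for i, p in enumerate(order) if p in cluster1]
        assert max(positions) - min(positions) == len(positions) - 1
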