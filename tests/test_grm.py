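"""GRM construction, GCTA binary interop, pruning and ancestry PCA."""

import numpy as np
import pandas as pd
import pytest

from covgreml.grm import (
    GRMatrix,
    build_grm,
    grm_pca,
    prune_related,
    read_grm_gcta,
    write_grm_gcta,
)
from covgreml.panel import GenotypePanel


def _panel(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": 1,
            "pos": np.arange(1, m + 1),
            "allele1": "A",
            "allele2": "G",
            "maf": np.nan,
            "info_r2": np.nan,
            "hwe_p": np.nan,
        }
    )
    return GenotypePanel([f"i{i}" for i in range(n)], snps, calls)


def _grm_reference(calls):
    """Direct elementwise evaluation of the relatedness formula."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    p = calls.mean(axis=0) / 2
    A = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            A[j, k] = np.mean(
                (calls[j] - 2 * p) * (calls[k] - 2 * p) / (2 * p * (1 - p))
            )
    return A


class TestBuildGRM:
    def test_matches_hand_formula_on_toy_panel(self):
        calls = [[0, 1], [1, 2], [2, 1], [1, 0]]
        grm = build_grm(_panel(calls))
        np.testing.assert_allclose(grm.values, _grm_reference(calls), atol=1e-12)
        assert (grm.pair_snp_counts == 2).all()

    def test_individual_at_mean_contributes_zero(self):
        # x = 2p exactly: the centred term vanishes for that individual
        calls = [[0], [1], [2], [1]]  # p = 0.5 -> 2p = 1
        grm = build_grm(_panel(calls))
        np.testing.assert_allclose(grm.values[1, :], 0.0, atol=1e-12)

    def test_exact_symmetry_and_snp_order_invariance(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        grm = build_grm(_panel(calls))
        assert np.array_equal(grm.values, grm.values.T)
        perm = rng.permutation(50)
        grm_perm = build_grm(_panel(calls[:, perm]))
        np.testing.assert_allclose(grm.values, grm_perm.values, atol=1e-10)

    def test_hwe_mean_diagonal_near_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.5, size=2000)
        calls = rng.binomial(2, p, size=(500, 2000)).astype(np.int8)
        grm = build_grm(_panel(calls))
        assert 0.95 <= np.mean(np.diag(grm.values)) <= 1.05

    def test_monomorphic_snp_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm(_panel([[2, 2], [2, 0], [2, 1]]))

    def test_missing_calls_use_pairwise_counts(self):
        calls = np.array([[0, 1, -1], [1, 2, 2], [2, -1, 0]], dtype=np.int8)
        grm = build_grm(_panel(calls))
        # i0 observes snps {0,1}, i2 observes {0,2}: one shared SNP
        assert grm.pair_snp_counts[0, 2] == 1
        assert grm.pair_snp_counts[0, 1] == 2
        assert grm.pair_snp_counts[1, 1] == 3


class TestGctaBinary:
    def test_round_trip_float32(self, tmp_path):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        grm = build_grm(_panel(calls))
        write_grm_gcta(grm, tmp_path / "g")
        back = read_grm_gcta(tmp_path / "g")
        assert np.abs(back.values - grm.values).max() <= 1e-6
        np.testing.assert_array_equal(back.pair_snp_counts, grm.pair_snp_counts)
        assert back.sample_ids == grm.sample_ids

    def test_file_length_is_lower_triangle(self, tmp_path):
        # n = 10 -> 55 float32 elements -> 220 bytes
        calls = np.random.default_rng(7).integers(0, 3, size=(10, 5)).astype(np.int8)
        write_grm_gcta(build_grm(_panel(calls)), tmp_path / "g")
        assert (tmp_path / "g.grm.bin").stat().st_size == 220

    def test_wrong_element_count_raises(self, tmp_path):
        calls = np.random.default_rng(8).integers(0, 3, size=(4, 5)).astype(np.int8)
        write_grm_gcta(build_grm(_panel(calls)), tmp_path / "g")
        data = (tmp_path / "g.grm.bin").read_bytes()
        (tmp_path / "g.grm.bin").write_bytes(data[:-4])
        with pytest.raises(ValueError, match="float32"):
            read_grm_gcta(tmp_path / "g")


def _grm_from_values(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return GRMatrix(
        [f"i{i}" for i in range(n)], values, np.full((n, n), 100, dtype=np.int64)
    )


class TestPruneRelated:
    def test_unrelated_panel_untouched(self):
        grm = _grm_from_values(np.eye(5))
        assert prune_related(grm) == [f"i{i}" for i in range(5)]

    def test_single_pair_drops_exactly_one(self):
        v = np.eye(4)
        v[1, 2] = v[2, 1] = 0.3
        retained = prune_related(_grm_from_values(v), seed=9)
        assert len(retained) == 3
        assert ("i1" in retained) != ("i2" in retained)

    def test_star_graph_removes_only_hub(self):
        # hub i0 related to i1..i5; spokes mutually unrelated -> greedy
        # degree rule = minimum vertex cover here: remove only the hub
        v = np.eye(6)
        v[0, 1:] = v[1:, 0] = 0.2
        retained = prune_related(_grm_from_values(v))
        assert retained == [f"i{i}" for i in range(1, 6)]

    def test_no_retained_pair_over_threshold(self):
        rng = np.random.default_rng(10)
        v = rng.normal(0, 0.05, size=(30, 30))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        grm = _grm_from_values(v)
        retained = prune_related(grm, threshold=0.05, seed=1)
        idx = [grm.sample_ids.index(s) for s in retained]
        sub = v[np.ix_(idx, idx)]
        off = sub[~np.eye(len(idx), dtype=bool)]
        assert (off <= 0.05).all()


class TestGrmPca:
    def test_identity_grm_equal_eigenvalues(self):
        pcs = grm_pca(_grm_from_values(np.eye(6)), k=3)
        np.testing.assert_allclose(pcs.eigenvalues, 1.0)

    def test_rank_one_recovers_direction(self):
        v = np.arange(1.0, 6.0)
        pcs = grm_pca(_grm_from_values(np.outer(v, v)), k=2)
        assert pcs.eigenvalues[0] == pytest.approx(v @ v)
        cos = abs(pcs.scores[:, 0] @ (v / np.linalg.norm(v)))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_orthogonality_and_reconstruction(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 3, size=(25, 60)).astype(np.int8)
        grm = build_grm(_panel(calls))
        pcs = grm_pca(grm, k=25)
        gram = pcs.scores.T @ pcs.scores
        np.testing.assert_allclose(gram, np.eye(25), atol=1e-8)
        recon = (pcs.scores * pcs.eigenvalues) @ pcs.scores.T
        np.testing.assert_allclose(recon, grm.values, atol=1e-8)

    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(12)
        m, n_half = 500, 60
        p1 = rng.uniform(0.1, 0.5, size=m)
        p2 = np.clip(p1 + rng.normal(0, 0.12, size=m), 0.02, 0.98)
        calls = np.vstack(
            [
                rng.binomial(2, p1, size=(n_half, m)),
                rng.binomial(2, p2, size=(n_half, m)),
            ]
        ).astype(np.int8)
        pcs = grm_pca(build_grm(_panel(calls)), k=2)
        group = np.repeat([0, 1], n_half)
        r = np.corrcoef(pcs.scores[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_k_exceeding_n_errors(self):
        with pytest.raises(ValueError):
            grm_pca(_grm_from_values(np.eye(3)), k=4)
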