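import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from anchorseek.anchor_discovery import (
    anchor_correlation,
    bh_adjust,
    conserved_intersection,
    discover_conserved,
    exact_ranksum_p,
    map_homologs,
    stress_de,
    top_k,
)
from anchorseek.preprocess import NormalizedMatrix, lognormalize, subset_cells

from tests.oracles import oracle_bh, oracle_spearman


def _norm_from_dense(dense, genes=None, barcodes=None):
    dense = np.asarray(dense, dtype=float)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(dense.shape[1])]
    return NormalizedMatrix(genes, barcodes, sp.csr_matrix(dense))


class TestAnchorCorrelation:
    def _table(self, dense, anchor="g0", **kw):
        norm = _norm_from_dense(dense)
        kw.setdefault("min_cells", 1)
        kw.setdefault("min_frac_expressing", 0.0)
        return anchor_correlation(norm, norm.barcodes, anchor, **kw)

    def test_self_similar_gene_rank_1(self):
        anchor = [1.0, 2, 3, 4, 5]
        dense = [anchor, anchor, [5, 3, 1, 2, 4]]
        tbl = self._table(dense)
        row = tbl[tbl["gene"] == "g1"].iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert row["rank"] == 1

    def test_worked_example_rho_08(self):
        """y = (2,1,4,3,5) vs x = (1,2,3,4,5): sum d^2 = 4 -> rho = 0.8."""
        dense = [[1.0, 2, 3, 4, 5], [2.0, 1, 4, 3, 5]]
        tbl = self._table(dense)
        assert tbl[tbl["gene"] == "g1"]["rho"].iloc[0] == pytest.approx(
            1 - 6 * 4 / (5 * (25 - 1)), abs=1e-12
        )

    def test_constant_gene_ineligible(self):
        dense = [[1.0, 2, 3, 4, 5], [7.0, 7, 7, 7, 7]]
        tbl = self._table(dense)
        row = tbl[tbl["gene"] == "g1"].iloc[0]
        assert not row["eligible"]
        assert np.isnan(row["rho"])
        assert np.isnan(row["rank"])

    def test_anchor_itself_ineligible(self):
        dense = [[1.0, 2, 3], [3.0, 2, 1]]
        tbl = self._table(dense)
        assert not tbl[tbl["gene"] == "g0"]["eligible"].iloc[0]

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(2, size=(20, 30)).astype(float)
        dense[0] += 1  # keep anchor expressed
        tbl = self._table(dense)
        ranks = tbl.loc[tbl["eligible"], "rank"].to_numpy()
        assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_low_frac_expressing_ineligible(self):
        dense = np.zeros((3, 100))
        dense[0] = np.arange(100)
        dense[1] = np.arange(100)
        dense[2, 0] = 5.0  # expressed in 1% only
        norm = _norm_from_dense(dense)
        tbl = anchor_correlation(norm, norm.barcodes, "g0",
                                 min_cells=1, min_frac_expressing=0.02)
        assert not tbl[tbl["gene"] == "g2"]["eligible"].iloc[0]

    def test_min_cells_enforced(self):
        dense = [[1.0, 2], [2.0, 1]]
        norm = _norm_from_dense(dense)
        with pytest.raises(ValueError, match="at least"):
            anchor_correlation(norm, norm.barcodes, "g0", min_cells=50)

    def test_all_zero_anchor_errors(self):
        dense = [[0.0, 0, 0], [1.0, 2, 3]]
        norm = _norm_from_dense(dense)
        with pytest.raises(ValueError, match="zero expression"):
            anchor_correlation(norm, norm.barcodes, "g0", min_cells=1)

    def test_oracle_equivalence_with_ties(self):
        """|rho - brute-force rank-then-Pearson oracle| <= 1e-12, 100 instances."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 51)
            g = rng.integers(2, 8)
            dense = rng.poisson(2.0, size=(g, n)).astype(float)  # plenty of ties
            dense[0, rng.integers(0, n)] += 1
            tbl = self._table(dense)
            for _, row in tbl.iterrows():
                if row["gene"] == "g0" or np.isnan(row["rho"]):
                    continue
                gi = int(row["gene"][1:])
                expect = oracle_spearman(dense[gi], dense[0])
                assert abs(row["rho"] - expect) <= 1e-12


class TestTopK:
    def _table(self, rhos, eligible=None):
        genes = [f"g{i}" for i in range(len(rhos))]
        eligible = eligible if eligible is not None else [True] * len(rhos)
        return pd.DataFrame({"gene": genes, "rho": rhos, "eligible": eligible})

    def test_k_larger_than_eligible(self):
        tbl = self._table([0.5, 0.2])
        assert top_k(tbl, 10) == ["g0", "g1"]

    def test_k_1(self):
        tbl = self._table([0.2, 0.9, 0.5])
        assert top_k(tbl, 1) == ["g1"]

    def test_boundary_tie_matches_sort_oracle(self):
        rhos = [0.9, 0.9, 0.8, 0.7, 0.7, 0.1]
        tbl = self._table(rhos)
        got = top_k(tbl, 4)
        oracle = [g for _, g in sorted(
            zip(rhos, tbl["gene"]), key=lambda t: (-t[0], t[1])
        )][:4]
        assert got == oracle == ["g0", "g1", "g2", "g3"]

    def test_k_nonpositive(self):
        with pytest.raises(ValueError):
            top_k(self._table([0.5]), 0)

    def test_no_eligible(self):
        with pytest.raises(ValueError, match="eligible"):
            top_k(self._table([0.5], eligible=[False]), 1)


class TestMapHomologs:
    def test_identity(self):
        tbl = pd.DataFrame({"gene_a": ["a", "b"], "gene_b": ["a", "b"]})
        mapped, n, unmapped = map_homologs(["a", "b"], tbl)
        assert mapped == {"a", "b"} and n == 2 and unmapped == []

    def test_empty_table(self):
        tbl = pd.DataFrame({"gene_a": [], "gene_b": []})
        mapped, n, unmapped = map_homologs(["a", "b"], tbl)
        assert mapped == set() and n == 0 and unmapped == ["a", "b"]

    def test_many_to_many_expansion(self):
        tbl = pd.DataFrame({"gene_a": ["a", "a", "c"], "gene_b": ["A1", "A2", "C"]})
        mapped, n, unmapped = map_homologs(["a", "b"], tbl)
        assert mapped == {"A1", "A2"} and n == 1 and unmapped == ["b"]

    def test_reverse_direction(self):
        tbl = pd.DataFrame({"gene_a": ["a"], "gene_b": ["A"]})
        mapped, n, _ = map_homologs(["A"], tbl, a_to_b=False)
        assert mapped == {"a"} and n == 1


class TestConservedIntersection:
    def test_identical_lists(self):
        out = conserved_intersection({"x", "y"}, ["x", "y"])
        assert list(out["gene"]) == ["x", "y"]

    def test_disjoint(self):
        assert len(conserved_intersection({"a"}, ["b", "c"])) == 0

    def test_ranks_annotated(self):
        out = conserved_intersection({"X", "Y", "Z"}, ["W", "X", "Y"])
        assert list(out["gene"]) == ["X", "Y"]
        assert list(out["rank_b"]) == [2, 3]


class TestExactRanksum:
    def test_separated_groups_p_01(self):
        assert exact_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_1(self):
        assert exact_ranksum_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = [1, 5, 2, 7], [3, 3, 8]
        assert exact_ranksum_p(a, b) == pytest.approx(exact_ranksum_p(b, a))


class TestStressDe:
    def _data(self, control, stressed):
        vals = np.array([control + stressed], dtype=float)
        n_c, n_s = len(control), len(stressed)
        barcodes = [f"c{i}" for i in range(n_c + n_s)]
        norm = _norm_from_dense(vals, genes=["g0"], barcodes=barcodes)
        meta = pd.DataFrame(
            {
                "barcode": barcodes,
                "species": "mouse",
                "cell_type": "CM",
                "condition": ["control"] * n_c + ["stressed"] * n_s,
                "sample": "s1",
            }
        )
        return norm, meta

    def test_exact_p_01(self):
        norm, meta = self._data([1, 2, 3], [4, 5, 6])
        tbl = stress_de(norm, meta, ["g0"])
        assert tbl["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_p_1(self):
        norm, meta = self._data([1, 2, 3], [1, 2, 3])
        tbl = stress_de(norm, meta, ["g0"])
        assert tbl["p"].iloc[0] == pytest.approx(1.0)

    def test_log2fc_sign(self):
        norm, meta = self._data([1, 1, 1], [4, 4, 4])
        tbl = stress_de(norm, meta, ["g0"])
        assert tbl["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_missing_condition_errors(self):
        norm, meta = self._data([1, 2, 3], [4, 5, 6])
        meta["condition"] = "control"
        with pytest.raises(ValueError):
            stress_de(norm, meta, ["g0"])


class TestBh:
    def test_hand_case(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_capped_at_1(self):
        assert bh_adjust([0.9, 0.95])[1] <= 1.0

    def test_against_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_against_hand_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 25))
            np.testing.assert_allclose(bh_adjust(p), oracle_bh(p), atol=1e-12)


class TestPipelineInvariants:
    def test_conserved_subset_and_anchor_excluded(self, small_pair):
        cfg, (ca, ma), (cb, mb), hom, truth = small_pair
        norm_a, norm_b = lognormalize(ca), lognormalize(cb)
        tbl_a = anchor_correlation(norm_a, subset_cells(ma, "CM"), truth.anchor["mouse"])
        tbl_b = anchor_correlation(norm_b, subset_cells(mb, "CM"), truth.anchor["human"])
        k = 50
        conserved = discover_conserved(tbl_a, tbl_b, hom, k=k)
        top_a, top_b = top_k(tbl_a, k), top_k(tbl_b, k)
        mapped, _, _ = map_homologs(top_a, hom)
        got = set(conserved["gene"])
        assert got <= mapped
        assert got <= set(top_b)
        for out in (top_a, got):
            assert truth.anchor["mouse"] not in out
            assert truth.anchor["human"] not in out

    def test_planted_recovery_small(self, small_pair):
        cfg, (ca, ma), (cb, mb), hom, truth = small_pair
        norm_a, norm_b = lognormalize(ca), lognormalize(cb)
        tbl_a = anchor_correlation(norm_a, subset_cells(ma, "CM"), truth.anchor["mouse"])
        tbl_b = anchor_correlation(norm_b, subset_cells(mb, "CM"), truth.anchor["human"])
        conserved = set(discover_conserved(tbl_a, tbl_b, hom, k=50)["gene"])
        planted_b = set(truth.planted_genes["human"])
        mappable_planted = {b for a, b in truth.homolog_pairs if b in planted_b}
        recall = len(conserved & mappable_planted) / max(len(mappable_planted), 1)
        assert recall >= 0.8
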