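"""Recovery-curve activity scores: worked cases, oracle equivalence, binarization."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from regulonkit import RegulonSet, ValidationError
from regulonkit.activity import (ActivityMatrix, binarize, explore_thresholds,
                                 ras_cell, ras_matrix)
from regulonkit.io_qc import LOGNORM_LAYER


def recovery_oracle(ranks: dict, set_genes, fraction: float) -> float:
    """Literal step-by-step recovery-curve enumeration."""
    G = len(ranks)
    k = math.ceil(fraction * G)
    m = len(set_genes)
    area = sum(sum(1 for g in set_genes if ranks[g] <= x) for x in range(1, k + 1))
    max_area = sum(min(x, m) for x in range(1, k + 1))
    return area / max_area


def adata_from_layer(values, gene_names=None):
    values = np.asarray(values, dtype=float)
    gene_names = gene_names or [f"g{j}" for j in range(values.shape[1])]
    adata = AnnData(X=sp.csr_matrix(values),
                    obs=pd.DataFrame(index=[f"c{i}" for i in range(values.shape[0])]),
                    var=pd.DataFrame(index=gene_names))
    adata.layers[LOGNORM_LAYER] = values
    return adata


def regset(**kwargs):
    return RegulonSet({tf: pd.DataFrame({"target": sorted(genes)})
                       for tf, genes in kwargs.items()})


class TestRasCell:
    RANKS = {f"g{r}": r for r in range(1, 11)}  # G = 10

    @pytest.mark.parametrize("genes,expected", [
        ({"g1", "g2"}, 1.0),        # both at the top
        ({"g9", "g10"}, 0.0),       # none within top k=5
        ({"g2", "g4"}, 6 / 9),      # (0+1+1+2+2)/(1+2+2+2+2)
    ])
    def test_worked_examples(self, genes, expected):
        assert ras_cell(self.RANKS, genes, 0.5) == pytest.approx(expected)

    def test_empty_regulon_rejected(self):
        with pytest.raises(ValidationError):
            ras_cell(self.RANKS, set(), 0.5)

    def test_absent_genes_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            value = ras_cell(self.RANKS, {"g1", "nope"}, 0.5)
        assert value == ras_cell(self.RANKS, {"g1"}, 0.5)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """50 random (ranking, regulon, fraction) draws at G <= 30, to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            G = int(rng.integers(5, 31))
            genes = [f"g{j}" for j in range(G)]
            perm = rng.permutation(G) + 1
            ranks = dict(zip(genes, perm.tolist()))
            m = int(rng.integers(1, G))
            regulon = set(rng.choice(genes, size=m, replace=False).tolist())
            fraction = float(rng.uniform(0.05, 1.0))
            assert ras_cell(ranks, regulon, fraction) == pytest.approx(
                recovery_oracle(ranks, regulon, fraction), abs=1e-12)

    def test_random_regulon_mean_matches_monte_carlo(self):
        """Implementation mean over 1,000 random rankings stays within 0.02
        of an independent Monte-Carlo estimate of the null expectation."""
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(2)
        G, m, fraction = 20, 5, 0.25
        genes = [f"g{j}" for j in range(G)]
        regulon = set(genes[:m])

        def mean_of(rng, fn):
            total = 0.0
            for _ in range(1000):
                ranks = dict(zip(genes, (rng.permutation(G) + 1).tolist()))
                total += fn(ranks)
            return total / 1000

        impl = mean_of(rng_a, lambda r: ras_cell(r, regulon, fraction))
        oracle = mean_of(rng_b, lambda r: recovery_oracle(r, regulon, fraction))
        assert impl == pytest.approx(oracle, abs=0.02)


class TestRasMatrix:
    def test_full_gene_regulon_scores_one_everywhere(self):
        rng = np.random.default_rng(3)
        adata = adata_from_layer(rng.normal(size=(5, 8)))
        act = ras_matrix(adata, regset(R=set(adata.var_names)), 0.25)
        np.testing.assert_allclose(act.ras.to_numpy(), 1.0)

    def test_single_cell_matrix(self):
        adata = adata_from_layer([[3.0, 2.0, 1.0, 0.5]])
        act = ras_matrix(adata, regset(R={"g0"}), 0.5)
        assert act.ras.shape == (1, 1)

    def test_agrees_with_per_cell_calls(self):
        """Matrix path equals independent ras_cell calls on 20 random draws."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            n_cells, G = int(rng.integers(2, 6)), int(rng.integers(6, 15))
            values = rng.normal(size=(n_cells, G))  # continuous: no ties
            adata = adata_from_layer(values)
            m = int(rng.integers(1, G // 2 + 1))
            genes = set(rng.choice(adata.var_names, size=m, replace=False).tolist())
            fraction = float(rng.uniform(0.2, 1.0))
            act = ras_matrix(adata, regset(R=genes), fraction)
            for c in range(n_cells):
                order = np.argsort(-values[c])
                ranks = {adata.var_names[j]: int(r + 1)
                         for r, j in enumerate(order)}
                assert act.ras.iloc[0, c] == pytest.approx(
                    ras_cell(ranks, genes, fraction), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(4, 10))
        a = ras_matrix(adata_from_layer(values), regset(R={"g0", "g3"}), 0.3)
        b = ras_matrix(adata_from_layer(np.exp(values)), regset(R={"g0", "g3"}), 0.3)
        pd.testing.assert_frame_equal(a.ras, b.ras)

    def test_scores_bounded(self, small_dataset, small_normalized):
        act = ras_matrix(small_normalized, small_dataset.planted_regulons, 0.05)
        assert float(act.ras.min().min()) >= 0.0
        assert float(act.ras.max().max()) <= 1.0


class TestExploreThresholds:
    def test_single_fraction_grid(self):
        adata = adata_from_layer(np.random.default_rng(0).normal(size=(6, 10)))
        clusters = pd.Series(["a", "a", "a", "b", "b", "b"], index=adata.obs_names)
        chosen, grid = explore_thresholds(adata, regset(R={"g1", "g2"}),
                                          fractions=(0.05,), clusters=clusters)
        assert (chosen == 0.05).all() and grid.shape == (1, 1)

    def test_constant_matrix_ties_choose_smallest_fraction(self):
        adata = adata_from_layer(np.ones((6, 10)))
        chosen, _ = explore_thresholds(adata, regset(R={"g1", "g2"}),
                                       criterion="max_variance")
        assert (chosen == 0.01).all()

    def test_cluster_specific_regulon_selects_best_rss_fraction(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(40, 30))
        values[:20, :3] += 4.0  # regulon genes high in cluster "a" only
        adata = adata_from_layer(values)
        clusters = pd.Series(["a"] * 20 + ["b"] * 20, index=adata.obs_names)
        regulon = regset(R={"g0", "g1", "g2"})
        chosen, grid = explore_thresholds(adata, regulon, clusters=clusters)
        assert chosen.loc["R"] == grid.loc["R"].idxmax()


class TestBinarize:
    def act(self, rows):
        ras = pd.DataFrame(rows, index=[f"R{i}" for i in range(len(rows))],
                           columns=[f"c{j}" for j in range(len(rows[0]))],
                           dtype=float)
        return ActivityMatrix(ras=ras, threshold_fraction=pd.Series(0.05,
                                                                    index=ras.index))

    def test_z_score_cutoff(self):
        out = binarize(self.act([[0, 0, 10]]), cutoff=0.15)
        assert out.binarized.iloc[0].tolist() == [0, 0, 1]

    def test_constant_activity_binarizes_to_zero(self):
        out = binarize(self.act([[0.4, 0.4, 0.4]]), cutoff=-1e9)
        assert out.binarized.iloc[0].tolist() == [0, 0, 0]

    def test_very_low_cutoff_turns_everything_on(self):
        out = binarize(self.act([[0.1, 0.2, 0.3]]), cutoff=-1e9)
        assert out.binarized.iloc[0].tolist() == [1, 1, 1]

    def test_per_regulon_cutoffs(self):
        cutoffs = pd.Series({"R0": 0.15, "R1": 10.0})
        out = binarize(self.act([[0, 0, 10], [0, 0, 10]]), cutoff=cutoffs)
        assert out.binarized.loc["R0"].tolist() == [0, 0, 1]
        assert out.binarized.loc["R1"].tolist() == [0, 0, 0]
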