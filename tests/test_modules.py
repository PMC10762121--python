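"""Pairwise correlation, connection specificity, and module detection."""

import numpy as np
import pandas as pd
import pytest

from regulonkit import ValidationError
from regulonkit.activity import ActivityMatrix
from regulonkit.modules import (cluster_relatedness, csi, detect_modules,
                                module_activity, regulon_pcc)


def csi_oracle(C: np.ndarray, variant: str, connective: str) -> np.ndarray:
    """Naive triple-loop evaluation of the pairwise counting rule."""
    N = C.shape[0]
    denom = (N - 2) if variant == "fraction" else (N - 2) ** 2
    out = np.zeros_like(C)
    for a in range(N):
        for b in range(N):
            if a == b:
                out[a, b] = (N - 2) / denom
                continue
            total = 0
            for i in range(N):
                if i in (a, b):
                    continue
                lo_a = C[a, i] < C[a, b]
                lo_b = C[b, i] < C[a, b]
                if (lo_a and lo_b) if connective == "and" else (lo_a or lo_b):
                    total += 1
            out[a, b] = total / denom
    return out


def activity(rows, cells=None):
    ras = pd.DataFrame(rows, index=[f"R{i}" for i in range(len(rows))],
                       columns=cells or [f"c{j}" for j in range(len(rows[0]))],
                       dtype=float)
    return ActivityMatrix(ras=ras, threshold_fraction=pd.Series(0.05, index=ras.index))


class TestRegulonPcc:
    def test_linear_and_anti_linear_profiles(self):
        act = activity([[1, 2, 3], [2, 4, 6], [3, 2, 1]])
        pcc = regulon_pcc(act)
        assert pcc.loc["R0", "R0"] == pytest.approx(1.0)
        assert pcc.loc["R0", "R1"] == pytest.approx(1.0)
        assert pcc.loc["R0", "R2"] == pytest.approx(-1.0)

    def test_zero_variance_regulon_warned_and_zeroed(self):
        act = activity([[1, 2, 3], [5, 5, 5]])
        with pytest.warns(UserWarning, match="zero-variance"):
            pcc = regulon_pcc(act)
        assert pcc.loc["R0", "R1"] == 0.0
        assert pcc.loc["R1", "R1"] == 1.0

    def test_too_small_inputs_rejected(self):
        with pytest.raises(ValidationError):
            regulon_pcc(activity([[1, 2, 3]]))


class TestCsi:
    def pcc3(self, pq, pi, qi):
        C = np.ones((3, 3))
        C[0, 1] = C[1, 0] = pq
        C[0, 2] = C[2, 0] = pi
        C[1, 2] = C[2, 1] = qi
        return pd.DataFrame(C, index=list("PQI"), columns=list("PQI"))

    def test_worked_case_counts_the_outsider(self):
        # PCC(P,i)=0.2 and PCC(Q,i)=0.3 both < 0.9 -> m_i = 1 under either
        # connective; with N=3 both denominators are 1
        for variant in ("fraction", "literal"):
            for connective in ("and", "or"):
                out = csi(self.pcc3(0.9, 0.2, 0.3), variant=variant,
                          connective=connective)
                assert out.loc["P", "Q"] == pytest.approx(1.0)

    def test_worked_case_outsider_more_correlated(self):
        for connective in ("and", "or"):
            out = csi(self.pcc3(0.9, 0.95, 0.96), connective=connective)
            assert out.loc["P", "Q"] == pytest.approx(0.0)

    @pytest.mark.parametrize("variant", ["fraction", "literal"])
    @pytest.mark.parametrize("connective", ["and", "or"])
    def test_matches_triple_loop_oracle(self, variant, connective):
        """20 random PCC matrices at N <= 20, equality to 1e-12."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            N = int(rng.integers(3, 21))
            C = rng.uniform(-1, 1, size=(N, N))
            C = (C + C.T) / 2
            np.fill_diagonal(C, 1.0)
            frame = pd.DataFrame(C, index=[f"R{i}" for i in range(N)],
                                 columns=[f"R{i}" for i in range(N)])
            got = csi(frame, variant=variant, connective=connective).to_numpy()
            expected = csi_oracle(C, variant, connective)
            np.testing.assert_allclose(got, expected, atol=1e-12)
            np.testing.assert_allclose(got, got.T, atol=0)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            csi(pd.DataFrame(np.eye(2)))


class TestDetectModules:
    def block_csi(self):
        names = [f"R{i}" for i in range(6)]
        C = np.zeros((6, 6))
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        return pd.DataFrame(C, index=names, columns=names)

    def test_two_blocks_recovered_exactly(self):
        labels = detect_modules(self.block_csi(), k=2)
        assert labels.nunique() == 2
        assert len(set(labels.iloc[:3])) == 1
        assert len(set(labels.iloc[3:])) == 1

    def test_k_extremes(self):
        assert detect_modules(self.block_csi(), k=1).nunique() == 1
        assert detect_modules(self.block_csi(), k=6).nunique() == 6
        with pytest.raises(ValidationError):
            detect_modules(self.block_csi(), k=7)

    def test_invariant_to_input_order(self):
        base = detect_modules(self.block_csi(), k=2)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = self.block_csi().iloc[perm, perm]
        relabeled = detect_modules(shuffled, k=2)
        pd.testing.assert_series_equal(base.sort_index(), relabeled.sort_index())


class TestModuleActivity:
    def test_single_regulon_module_matches_cluster_mean(self):
        act = activity([[0.2, 0.4, 0.6, 0.8]])
        clusters = pd.Series(["a", "a", "b", "b"],
                             index=[f"c{j}" for j in range(4)])
        modules = pd.Series({"R0": "M1"})
        out = module_activity(act, modules, clusters)
        assert out.loc["M1", "a"] == pytest.approx(0.3)
        assert out.loc["M1", "b"] == pytest.approx(0.7)

    def test_two_constant_regulons_average(self):
        act = activity([[0.2] * 4, [0.4] * 4])
        clusters = pd.Series(["a", "a", "b", "b"],
                             index=[f"c{j}" for j in range(4)])
        out = module_activity(act, pd.Series({"R0": "M1", "R1": "M1"}), clusters)
        assert out.loc["M1"].tolist() == pytest.approx([0.3, 0.3])

    def test_size_weighted_cluster_scores_recover_global_mean(self):
        rng = np.random.default_rng(2)
        act = activity(rng.random((3, 10)).tolist())
        labels = ["a"] * 7 + ["b"] * 3
        clusters = pd.Series(labels, index=[f"c{j}" for j in range(10)])
        modules = pd.Series({"R0": "M1", "R1": "M1", "R2": "M2"})
        out = module_activity(act, modules, clusters)
        weighted = (out["a"] * 7 + out["b"] * 3) / 10
        assert weighted.loc["M1"] == pytest.approx(
            act.ras.loc[["R0", "R1"]].to_numpy().mean())
        assert weighted.loc["M2"] == pytest.approx(act.ras.loc["R2"].mean())


class TestClusterRelatedness:
    def test_identical_profiles_connect(self):
        act = activity([[0.2, 0.2, 0.8, 0.8], [0.4, 0.4, 0.6, 0.6]])
        clusters = pd.Series(["a", "b", "c", "d"],
                             index=[f"c{j}" for j in range(4)])
        corr, edges = cluster_relatedness(act, clusters, edge_threshold=0.99)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert ("a", "b") in set(zip(edges["cluster_a"], edges["cluster_b"]))

    def test_anticorrelated_profiles_do_not_connect_at_zero(self):
        act = activity([[0.9, 0.1], [0.1, 0.9]])
        clusters = pd.Series(["a", "b"], index=["c0", "c1"])
        corr, edges = cluster_relatedness(act, clusters, edge_threshold=0.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert edges.empty


def test_planted_module_structure_recovered(small_dataset, small_normalized):
    """Home-cluster regulon groups come back as detected modules on the
    small fixture (planted regulons, generous rank cutoff)."""
    from sklearn.metrics import adjusted_rand_score

    from regulonkit.activity import ras_matrix

    act = ras_matrix(small_normalized, small_dataset.planted_regulons,
                     threshold_fraction=0.2, tie_seed=11)
    labels = detect_modules(csi(regulon_pcc(act)),
                            k=small_dataset.config.n_clusters)
    truth = [small_dataset.planted_modules[tf] for tf in labels.index]
    assert adjusted_rand_score(truth, labels.tolist()) >= 0.5
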