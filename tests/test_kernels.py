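"""Kernel construction: GRM, Kronecker SCA sub-matrix, expansions, Hadamard."""

import numpy as np
import pytest

from hybridpred import (
    HybridPedigree,
    MarkerMatrix,
    RelationshipKernel,
    compute_grm,
    expand_to_records,
    identity_kernel,
    interaction_kernel,
    sca_kernel,
)
from hybridpred.kernels import KernelError

from conftest import random_psd


def labelled(values, prefix="e"):
    return RelationshipKernel(
        [f"{prefix}{i}" for i in range(len(values))], np.asarray(values, float)
    )


class TestGRM:
    def test_three_line_worked_example(self):
        # dosages [[0,2],[2,0],[1,1]]: column means 1, population sd sqrt(2/3)
        m = MarkerMatrix(["L1", "L2", "L3"], ["m1", "m2"], [[0, 2], [2, 0], [1, 1]])
        G = compute_grm(m)
        expected = np.array([[1.5, -1.5, 0.0], [-1.5, 1.5, 0.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(G.values, expected, atol=1e-12)
        assert G.values.diagonal().mean() == pytest.approx(1.0, abs=1e-10)

    def test_identical_lines_share_all_entries(self):
        m = MarkerMatrix(["a", "b", "c"], ["m1", "m2"], [[0, 2], [0, 2], [2, 0]])
        G = compute_grm(m).values
        assert G[0, 0] == pytest.approx(G[0, 1])
        assert G[0, 0] == pytest.approx(G[1, 1])

    def test_monomorphic_column_rejected_by_name(self):
        m = MarkerMatrix(["a", "b"], ["ok", "flat"], [[0, 1], [2, 1]])
        with pytest.raises(KernelError, match="flat"):
            compute_grm(m)

    def test_missing_values_rejected(self):
        m = MarkerMatrix(["a", "b"], ["m1"], [[np.nan], [2.0]])
        with pytest.raises(KernelError, match="missing"):
            compute_grm(m)

    def test_invariant_to_column_order_and_allele_swap(self, rng):
        d = rng.integers(0, 3, size=(6, 10)).astype(float)
        d[0] = 0.0
        d[1] = 2.0  # keep columns polymorphic regardless of draw
        ids = [f"m{j}" for j in range(10)]
        m = MarkerMatrix([f"L{i}" for i in range(6)], ids, d)
        G = compute_grm(m).values
        perm = rng.permutation(10)
        G_perm = compute_grm(
            MarkerMatrix(m.line_ids, [ids[j] for j in perm], d[:, perm])
        ).values
        G_swap = compute_grm(MarkerMatrix(m.line_ids, ids, 2.0 - d)).values
        np.testing.assert_allclose(G_perm, G, atol=1e-10)
        np.testing.assert_allclose(G_swap, G, atol=1e-10)

    def test_mean_diagonal_is_one_for_any_matrix(self, rng):
        for n, p in [(5, 20), (12, 7), (30, 50)]:
            d = rng.integers(0, 3, size=(n, p)).astype(float)
            d[0], d[1] = 0.0, 2.0
            G = compute_grm(MarkerMatrix(
                [f"L{i}" for i in range(n)], [f"m{j}" for j in range(p)], d
            ))
            assert G.values.diagonal().mean() == pytest.approx(1.0, abs=1e-10)


class TestSCAKernel:
    def test_identity_factors_give_identity(self):
        G_M = identity_kernel(["m1", "m2"])
        G_F = identity_kernel(["f1", "f2"])
        ped = HybridPedigree(["h1", "h2"], ["m1", "m1"], ["f1", "f2"])
        H = sca_kernel(ped, G_M, G_F)
        np.testing.assert_allclose(H.values, np.eye(2))

    def test_entrywise_product_definition(self):
        G_M = RelationshipKernel(["m1"], [[1.2]])
        G_F = RelationshipKernel(["f1", "f2"], [[1.0, 0.5], [0.5, 1.0]])
        ped = HybridPedigree(["h1", "h2"], ["m1", "m1"], ["f1", "f2"])
        H = sca_kernel(ped, G_M, G_F)
        assert H.values[0, 1] == pytest.approx(0.6)

    def test_matches_full_kronecker_product(self, rng):
        n_m, n_f, n_h = 5, 8, 20
        G_M = labelled(random_psd(rng, n_m), "m")
        G_F = labelled(random_psd(rng, n_f), "f")
        males = rng.integers(0, n_m, n_h)
        females = rng.integers(0, n_f, n_h)
        ped = HybridPedigree(
            [f"h{i}" for i in range(n_h)],
            [f"m{i}" for i in males],
            [f"f{i}" for i in females],
        )
        H = sca_kernel(ped, G_M, G_F)
        full = np.kron(G_M.values, G_F.values)  # index (m, f) -> m * n_f + f
        idx = males * n_f + females
        np.testing.assert_allclose(H.values, full[np.ix_(idx, idx)], atol=1e-12)
        assert H.is_psd()

    def test_unknown_parent_listed(self):
        ped = HybridPedigree(["h1"], ["mX"], ["f1"])
        with pytest.raises(KernelError, match="mX"):
            sca_kernel(ped, identity_kernel(["m1"]), identity_kernel(["f1"]))


class TestExpansion:
    def test_repeated_entity_copies_entry(self):
        K = identity_kernel(["h1", "h2", "h3"])
        out = expand_to_records(K, ["h1", "h1"])
        np.testing.assert_allclose(out.values, np.ones((2, 2)))

    def test_one_record_per_entity_is_identity_map(self):
        K = labelled(random_psd(np.random.default_rng(0), 4), "h")
        out = expand_to_records(K, [f"h{i}" for i in range(4)])
        np.testing.assert_allclose(out.values, K.values)

    def test_matches_dense_incidence_product(self, rng):
        K = labelled(random_psd(rng, 5), "h")
        entities = [f"h{i}" for i in rng.integers(0, 5, 12)]
        out = expand_to_records(K, entities)
        Z = np.zeros((12, 5))
        for r, e in enumerate(entities):
            Z[r, int(e[1:])] = 1.0
        np.testing.assert_allclose(out.values, Z @ K.values @ Z.T, atol=1e-12)

    def test_unmapped_record_errors(self):
        with pytest.raises(KernelError, match="hX"):
            expand_to_records(identity_kernel(["h1"]), ["h1", "hX"])


class TestInteraction:
    def make_pair(self, rng, envs):
        n = len(envs)
        main = labelled(random_psd(rng, n), "r")
        env_k = expand_to_records(identity_kernel(sorted(set(envs))), envs)
        env_k = RelationshipKernel(main.entity_ids, env_k.values, "EXPANDED")
        return main, env_k

    def test_cross_environment_entries_vanish(self, rng):
        envs = ["e1", "e2"]
        main, env_k = self.make_pair(rng, envs)
        out = interaction_kernel(main, env_k)
        assert out.values[0, 1] == 0.0
        assert out.values[0, 0] == pytest.approx(main.values[0, 0])

    def test_same_environment_entry_equals_main(self, rng):
        envs = ["e1", "e1", "e2"]
        main, env_k = self.make_pair(rng, envs)
        out = interaction_kernel(main, env_k)
        assert out.values[0, 1] == pytest.approx(main.values[0, 1])

    def test_result_is_psd(self, rng):
        envs = [f"e{i % 3}" for i in range(15)]
        main, env_k = self.make_pair(rng, envs)
        out = interaction_kernel(main, env_k)
        assert out.is_psd()

    def test_label_mismatch_errors(self, rng):
        main, env_k = self.make_pair(rng, ["e1", "e2"])
        other = labelled(np.eye(2), "x")
        with pytest.raises(KernelError, match="identical record set"):
            interaction_kernel(main, other)
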