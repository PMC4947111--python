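"""Gene-level kernel builders against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metkern import (FeatureTable, KernelMatrix, MotifSet, SequenceSet,
                     assert_psd, feature_log_e_kernel, linear_kernel,
                     motif_kernel, normalize_kernel, rbf_kernel,
                     spectrum_kernel, transform_e_values)
from metkern.kernels import (KernelError, STANDARD_AA, median_bandwidth,
                             min_eig_ratio, motif_match_counts)

AA = STANDARD_AA


def brute_force_ngram_dot(s1: str, s2: str, n: int) -> int:
    """Independent oracle: explicit window counting over both sequences."""
    def counts(s):
        c = {}
        for i in range(len(s) - n + 1):
            g = s[i:i + n]
            if all(ch in AA for ch in g):
                c[g] = c.get(g, 0) + 1
        return c
    c1, c2 = counts(s1.upper()), counts(s2.upper())
    return sum(v * c2.get(g, 0) for g, v in c1.items())


class TestRbfKernel:
    def test_unit_diagonal_and_analytic_value(self):
        # two points at squared distance 2 sigma^2 -> K = exp(-1)
        x = np.zeros(10)
        y = np.zeros(10)
        y[0] = 2.0  # ||x-y||^2 = 4 = 2 sigma^2 with sigma = sqrt(2)
        table = FeatureTable(("a", "b"), np.vstack([x, y]), "expression")
        K = rbf_kernel(table, sigma=np.sqrt(2.0))
        assert K.values[0, 0] == 1.0 and K.values[1, 1] == 1.0
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_matches_entrywise_formula(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 10))
        table = FeatureTable(tuple("abcde"), X, "expression")
        K = rbf_kernel(table, sigma=1.0)
        for i in range(5):
            for j in range(5):
                expect = np.exp(-np.sum((X[i] - X[j]) ** 2) / 2.0)
                assert K.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_rejects_nonpositive_bandwidth(self):
        table = FeatureTable(("a", "b"), np.eye(2), "expression")
        with pytest.raises(KernelError):
            rbf_kernel(table, sigma=0.0)
        with pytest.raises(KernelError):
            rbf_kernel(table, sigma=-1.0)

    def test_median_heuristic_default_is_psd(self):
        rng = np.random.default_rng(1)
        table = FeatureTable(tuple(f"g{i}" for i in range(8)),
                             rng.standard_normal((8, 4)), "expression")
        assert median_bandwidth(table) > 0
        K = rbf_kernel(table)
        _, diag = assert_psd(K)
        assert diag == "psd"


class TestLinearKernel:
    def test_binary_overlap_and_orthogonality(self):
        X = np.array([[1, 0, 1], [1, 1, 1], [0, 1, 0]], dtype=float)
        K = linear_kernel(FeatureTable(("a", "b", "c"), X, "localization"))
        assert K.values[0, 1] == 2.0
        assert K.values[0, 2] == 0.0

    def test_matches_bruteforce_dot_products(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(6, 23)).astype(float)
        table = FeatureTable(tuple(f"g{i}" for i in range(6)), X, "localization")
        K = linear_kernel(table)
        for i in range(6):
            for j in range(6):
                assert K.values[i, j] == float(np.dot(X[i], X[j]))


class TestSpectrumKernel:
    @pytest.mark.parametrize("s1,s2,n,expected", [
        ("AAA", "AAA", 3, 1),
        ("AAAA", "AAA", 3, 2),      # AAA occurs twice in AAAA
        ("ACDEF", "GHIKL", 3, 0),   # disjoint trigram sets
        ("AXA", "AA", 1, 4),        # X never counted: 2 A's in each sequence
        ("AC", "AC", 3, 0),         # too short -> zero feature vector
    ])
    def test_known_values(self, s1, s2, n, expected):
        K = spectrum_kernel(SequenceSet(("a", "b"), (s1, s2)), n=n)
        assert K.values[0, 1] == expected

    def test_matches_bruteforce_oracle_many_random_pairs(self):
        rng = np.random.default_rng(3)
        letters = list(AA + "XBZ")
        for trial in range(50):
            n = int(rng.integers(1, 4))
            s1 = "".join(rng.choice(letters, size=rng.integers(3, 51)))
            s2 = "".join(rng.choice(letters, size=rng.integers(3, 51)))
            K = spectrum_kernel(SequenceSet(("a", "b"), (s1, s2)), n=n)
            assert K.values[0, 1] == brute_force_ngram_dot(s1, s2, n)
            assert K.values[0, 0] == brute_force_ngram_dot(s1, s1, n)

    def test_rejects_invalid_gram_length(self):
        with pytest.raises(KernelError):
            spectrum_kernel(SequenceSet(("a",), ("ACD",)), n=0)


class TestMotifKernel:
    def test_overlapping_matches_counted(self):
        seqs = SequenceSet(("a",), ("ACAC",))
        counts = motif_match_counts(seqs, MotifSet(("AC",)))
        assert counts[0, 0] == 2
        K = motif_kernel(seqs, MotifSet(("AC",)))
        assert K.values[0, 0] == 4.0

    def test_class_and_wildcard_syntax(self):
        seqs = SequenceSet(("a", "b"), ("GC", "TTTT"))
        counts = motif_match_counts(seqs, MotifSet(("[AG]C", "T.T")))
        assert counts[0, 0] == 1      # [AG]C matches GC
        assert counts[1, 1] == 2      # T.T matches TTTT at positions 0 and 1
        assert counts[1, 0] == 0

    def test_nonmatching_motif_contributes_zero(self):
        seqs = SequenceSet(("a", "b"), ("AAAA", "CCCC"))
        K = motif_kernel(seqs, MotifSet(("WWW",)))
        assert np.all(K.values == 0.0)

    def test_ambiguity_codes_never_match(self):
        seqs = SequenceSet(("a",), ("AXA",))
        counts = motif_match_counts(seqs, MotifSet(("A.A", "[AC]")))
        assert counts[0, 0] == 0  # '.' does not match X
        assert counts[0, 1] == 2  # only the two real A's
        with pytest.raises(KernelError):
            MotifSet(("[AX]",))   # ambiguity codes not allowed in classes

    @pytest.mark.parametrize("bad", ["", "A[", "[", "A]C", "a c", "[ax]"])
    def test_malformed_pattern_rejected_with_pattern_named(self, bad):
        with pytest.raises(KernelError, match="motif"):
            MotifSet((bad,))


class TestLogEKernel:
    def test_transform_maps_small_e_values_to_large_features(self):
        feats = transform_e_values(np.array([1e-10, 1.0, 100.0]))
        assert feats[0] == pytest.approx(10.0)
        assert feats[1] == 0.0 and feats[2] == 0.0

    def test_matches_bruteforce_dot_products(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 10, size=(4, 50))
        table = FeatureTable(tuple("abcd"), X, "log_e")
        K = feature_log_e_kernel(table)
        for i in range(4):
            for j in range(4):
                assert K.values[i, j] == pytest.approx(float(X[i] @ X[j]),
                                                       rel=1e-12)

    def test_zero_feature_gene_gives_zero_row(self):
        X = np.array([[1.0, 2.0], [0.0, 0.0]])
        K = feature_log_e_kernel(FeatureTable(("a", "b"), X, "log_e"))
        assert K.values[1, 0] == 0.0 and K.values[1, 1] == 0.0

    def test_rejects_wrong_kind_and_negative_features(self):
        with pytest.raises(KernelError):
            feature_log_e_kernel(FeatureTable(("a",), [[1.0]], "expression"))
        with pytest.raises(KernelError):
            feature_log_e_kernel(FeatureTable(("a",), [[-0.5]], "log_e"))


class TestNormalizeKernel:
    def test_worked_example(self):
        K = KernelMatrix(("a", "b"), np.array([[4.0, 2.0], [2.0, 1.0]]))
        Kn = normalize_kernel(K)
        assert np.allclose(Kn.values, 1.0)

    def test_idempotent_on_rbf(self):
        rng = np.random.default_rng(5)
        table = FeatureTable(tuple(f"g{i}" for i in range(6)),
                             rng.standard_normal((6, 3)), "expression")
        K = rbf_kernel(table, sigma=1.0)
        once = normalize_kernel(K)
        twice = normalize_kernel(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_entries_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((5, 7))
        K = KernelMatrix(tuple("abcde"), A @ A.T + 1e-6 * np.eye(5))
        Kn = normalize_kernel(K)
        assert np.abs(Kn.values).max() <= 1.0 + 1e-12
        assert np.allclose(np.diag(Kn.values), 1.0)

    def test_zero_diagonal_error_names_gene(self):
        K = KernelMatrix(("a", "zed"), np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(KernelError, match="zed"):
            normalize_kernel(K)


class TestAssertPsd:
    def test_identity_passes_unchanged(self):
        K = KernelMatrix(("a", "b"), np.eye(2))
        out, diag = assert_psd(K)
        assert diag == "psd"
        assert out.values is K.values

    def test_indefinite_matrix_repaired_by_eigenvalue_clipping(self):
        K = KernelMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))
        out, diag = assert_psd(K)
        assert diag == "repaired"
        # eigendecomposition oracle: clip (3, -1) -> keep 3 * v v^T
        v = np.array([1.0, 1.0]) / np.sqrt(2.0)
        assert np.allclose(out.values, 3.0 * np.outer(v, v), atol=1e-10)
        assert min_eig_ratio(out.values) >= -1e-8

    def test_asymmetric_input_rejected(self):
        with pytest.raises(KernelError, match="asymmetric"):
            KernelMatrix(("a", "b"), np.array([[1.0, 0.5], [0.0, 1.0]]))


@pytest.mark.parametrize("builder", [
    lambda t: rbf_kernel(t, sigma=1.2),
    linear_kernel,
])
def test_gene_order_invariance(builder):
    """Permuting input genes permutes kernel rows/columns identically."""
    rng = np.random.default_rng(6)
    X = rng.integers(0, 2, size=(7, 5)).astype(float)
    ids = tuple(f"g{i}" for i in range(7))
    K = builder(FeatureTable(ids, X, "localization"))
    perm = rng.permutation(7)
    Kp = builder(FeatureTable(tuple(ids[i] for i in perm), X[perm],
                              "localization"))
    assert np.allclose(Kp.values, K.values[np.ix_(perm, perm)], atol=1e-12)


def test_spectrum_gene_order_invariance():
    rng = np.random.default_rng(7)
    seqs = tuple("".join(rng.choice(list(AA), size=20)) for _ in range(6))
    ids = tuple(f"g{i}" for i in range(6))
    K = spectrum_kernel(SequenceSet(ids, seqs), n=2)
    perm = rng.permutation(6)
    Kp = spectrum_kernel(
        SequenceSet(tuple(ids[i] for i in perm),
                    tuple(seqs[i] for i in perm)), n=2)
    assert np.array_equal(Kp.values, K.values[np.ix_(perm, perm)])


@pytest.mark.parametrize("builder_name", ["rbf", "linear", "log_e", "spectrum"])
def test_builders_are_psd_without_repair(builder_name):
    rng = np.random.default_rng(8)
    ids = tuple(f"g{i}" for i in range(10))
    if builder_name == "rbf":
        K = rbf_kernel(FeatureTable(ids, rng.standard_normal((10, 6)),
                                    "expression"), sigma=1.0)
    elif builder_name == "linear":
        K = linear_kernel(FeatureTable(
            ids, rng.integers(0, 2, (10, 8)).astype(float), "localization"))
    elif builder_name == "log_e":
        K = feature_log_e_kernel(FeatureTable(
            ids, rng.uniform(0, 5, (10, 12)), "log_e"))
    else:
        seqs = tuple("".join(rng.choice(list(AA), size=30)) for _ in range(10))
        K = spectrum_kernel(SequenceSet(ids, seqs), n=3)
    assert min_eig_ratio(K.values) >= -1e-8
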