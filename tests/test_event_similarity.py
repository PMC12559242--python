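import numpy as np
import pytest
from scipy import stats

from splicewalk.event_similarity import (
    EventFeatureMatrix,
    RegulatoryCorrelation,
    build_event_similarity,
    combine_event_distances,
    compute_rbp_event_correlation,
    embed_features,
    extract_sequence_features,
    normalized_euclidean,
    omega,
    profile_correlation_pvalues,
)
from splicewalk.events import (
    EventDefinition,
    ExpressionMatrix,
    Junction,
    PsiMatrix,
)


class TestOmega:
    def test_endpoints_forced_by_constants(self):
        assert omega(0.0) == pytest.approx(1.0 / 10000, abs=1e-12)
        assert omega(0.5) == pytest.approx(0.5, abs=1e-12)
        assert omega(1.0) == pytest.approx(9999.0 / 10000, abs=1e-12)

    def test_complementarity(self):
        assert omega(0.0) + omega(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing(self):
        p = np.linspace(0, 1, 101)
        w = omega(p)
        assert np.all(np.diff(w) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            omega(np.array([1.5]))


class TestNormalizedEuclidean:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
        D = normalized_euclidean(X)
        assert D[0, 1] == 0.0

    def test_hand_value_sample_variance(self):
        # column (0, 2): sample variance 2 -> NED = sqrt(4/2) = sqrt(2)
        X = np.array([[0.0], [2.0]])
        D = normalized_euclidean(X)
        assert D[0, 1] == pytest.approx(np.sqrt(2))

    def test_equals_euclidean_after_standardization(self, rng):
        X = rng.normal(size=(10, 5)) * np.array([1.0, 4.0, 0.5, 2.0, 3.0])
        D = normalized_euclidean(X)
        Z = X / X.std(axis=0, ddof=1)
        from scipy.spatial.distance import pdist, squareform

        assert np.allclose(D, squareform(pdist(Z)), atol=1e-12)

    def test_zero_variance_columns_dropped(self, rng):
        X = np.hstack([rng.normal(size=(6, 3)), np.ones((6, 1))])
        D = normalized_euclidean(X)
        assert np.all(np.isfinite(D))

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            normalized_euclidean(np.ones((4, 3)))


class TestEmbedding:
    def make_features(self, values):
        values = np.asarray(values, float)
        return EventFeatureMatrix(
            values,
            [f"e{i}" for i in range(values.shape[0])],
            [f"f{i}" for i in range(values.shape[1])],
        )

    def test_low_rank_recovered_exactly(self, rng):
        base = rng.normal(size=(12, 2))
        X = base @ rng.normal(size=(2, 7))
        emb = embed_features(self.make_features(X), L=2)
        # rank-2 input: 2 components reconstruct the standardized matrix
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        assert np.allclose((U[:, :2] * s[:2]) @ Vt[:2], Z, atol=1e-8)
        assert emb.values.shape == (12, 2)

    def test_duplicate_events_identical_rows(self, rng):
        X = rng.normal(size=(5, 4))
        X[3] = X[1]
        emb = embed_features(self.make_features(X), L=3)
        assert np.allclose(emb.values[3], emb.values[1])

    def test_deterministic(self, rng):
        X = rng.normal(size=(8, 5))
        a = embed_features(self.make_features(X), L=3, seed=0)
        b = embed_features(self.make_features(X), L=3, seed=0)
        assert np.array_equal(a.values, b.values)

    def test_dimension_bound_enforced(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="L="):
            embed_features(self.make_features(X), L=5)


class TestRbpCorrelation:
    def make_psi(self, values, support=None):
        values = np.asarray(values, float)
        return PsiMatrix(
            values,
            [f"c{i}" for i in range(values.shape[0])],
            [f"e{i}" for i in range(values.shape[1])],
            support,
        )

    def make_expr(self, values):
        values = np.asarray(values, float)
        return ExpressionMatrix(
            values,
            [f"c{i}" for i in range(values.shape[0])],
            [f"r{i}" for i in range(values.shape[1])],
        )

    def test_identical_vectors_correlation_one(self):
        v = np.linspace(0.1, 0.9, 10)
        per = compute_rbp_event_correlation(self.make_psi(v[:, None]), self.make_expr(v[:, None]))
        assert per.values[0, 0] == pytest.approx(1.0)

    def test_reversed_vector_correlation_minus_one(self):
        v = np.linspace(0.1, 0.9, 10)
        per = compute_rbp_event_correlation(
            self.make_psi(v[:, None]), self.make_expr(v[::-1, None].copy())
        )
        assert per.values[0, 0] == pytest.approx(-1.0)

    def test_matches_scipy_pearson_oracle(self, rng):
        psi = rng.uniform(size=(50, 3))
        expr = rng.uniform(size=(50, 4))
        per = compute_rbp_event_correlation(self.make_psi(psi), self.make_expr(expr))
        for e in range(3):
            for b in range(4):
                r, p = stats.pearsonr(psi[:, e], expr[:, b])
                assert per.values[e, b] == pytest.approx(r, abs=1e-12)
                assert per.pvalues[e, b] == pytest.approx(p, abs=1e-12)

    def test_pairwise_exclusion_of_unsupported_cells(self, rng):
        psi = rng.uniform(size=(20, 1))
        support = np.ones((20, 1), dtype=bool)
        support[:10] = False
        expr = rng.uniform(size=(20, 1))
        per = compute_rbp_event_correlation(self.make_psi(psi, support), self.make_expr(expr))
        r, _ = stats.pearsonr(psi[10:, 0], expr[10:, 0])
        assert per.values[0, 0] == pytest.approx(r, abs=1e-12)

    def test_too_few_supported_cells_zeroed(self, rng):
        psi = rng.uniform(size=(5, 1))
        support = np.zeros((5, 1), dtype=bool)
        support[:2] = True
        per = compute_rbp_event_correlation(self.make_psi(psi, support),
                                            self.make_expr(rng.uniform(size=(5, 1))))
        assert per.values[0, 0] == 0.0
        assert per.pvalues[0, 0] == 1.0


class TestCombine:
    def make_per(self, values):
        values = np.asarray(values, float)
        return RegulatoryCorrelation(
            values,
            np.full(values.shape, 0.5),
            [f"e{i}" for i in range(values.shape[0])],
            [f"r{i}" for i in range(values.shape[1])],
        )

    def test_combined_distance_between_components(self, rng):
        n = 6
        per = self.make_per(rng.uniform(-1, 1, size=(n, 8)))
        d1 = np.abs(rng.normal(size=(n, n)))
        d2 = np.abs(rng.normal(size=(n, n)))
        np.fill_diagonal(d1, 0)
        np.fill_diagonal(d2, 0)
        out = combine_event_distances(d1, d2, per)
        lo = np.minimum(d1, d2)
        hi = np.maximum(d1, d2)
        assert np.all(out >= lo - 1e-12)
        assert np.all(out <= hi + 1e-12)

    def test_identical_profiles_weight_per_distance_down(self, rng):
        """Perfectly correlated regulation profiles have p ~ 0, so the fused
        distance sits at the embedding distance."""
        base = rng.uniform(-1, 1, size=8)
        per = self.make_per(np.vstack([base, base * 0.5 + 0.1]))
        d_emb = np.array([[0.0, 1.0], [1.0, 0.0]])
        d_per = np.array([[0.0, 5.0], [5.0, 0.0]])
        out = combine_event_distances(d_emb, d_per, per)
        w = omega(0.0)
        assert out[0, 1] == pytest.approx((1 - w) * 1.0 + w * 5.0, abs=1e-9)

    def test_profile_pvalues_match_pearson_oracle(self, rng):
        per = self.make_per(rng.uniform(-1, 1, size=(4, 12)))
        P = profile_correlation_pvalues(per)
        for i in range(4):
            for j in range(i + 1, 4):
                _, p = stats.pearsonr(per.values[i], per.values[j])
                assert P[i, j] == pytest.approx(p, abs=1e-10)


class TestEventKernel:
    def test_fixed_k_sigma_index(self, rng):
        """k_event = 10 -> bandwidth is the 5th smallest distance of the row."""
        n = 20
        X = rng.normal(size=(n, 3))
        from splicewalk.cell_similarity import pairwise_euclidean

        D = pairwise_euclidean(X)
        net = build_event_similarity(D, k_event=10)
        i = 0
        others = np.delete(D[i], i)
        sigma = np.sort(others)[4]  # ceil(10/3)+1 = 5th smallest, 0-based 4
        j = np.argsort(np.where(np.arange(n) == i, np.inf, D[i]))[0]
        pre = np.exp(-((D[i, j] / sigma) ** 2))
        # S + S' adds the transposed contribution; entry must be >= pre
        assert net.values[i, j] >= pre - 1e-12

    def test_k_event_bound(self, rng):
        D = np.abs(rng.normal(size=(5, 5)))
        with pytest.raises(ValueError):
            build_event_similarity(D, k_event=5)

    def test_symmetric_output(self, rng):
        X = rng.normal(size=(15, 4))
        from splicewalk.cell_similarity import pairwise_euclidean

        net = build_event_similarity(pairwise_euclidean(X), k_event=6)
        assert np.allclose(net.values, net.values.T)


class TestSequenceFeatures:
    @pytest.fixture()
    def genome(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        path = tmp_path / "genome.fa"
        path.write_text(">chr1\n" + "\n".join(seq[i : i + 60] for i in range(0, 3000, 60)) + "\n")
        return path, seq

    def event(self, strand="+"):
        incl = [Junction("chr1", 500, 700, strand), Junction("chr1", 800, 1000, strand)]
        excl = [Junction("chr1", 500, 1000, strand)]
        return EventDefinition("se_plus", "gA", "SE", incl, excl)

    def test_alt_region_length(self, genome):
        path, _ = genome
        feats = extract_sequence_features([self.event()], str(path), k=2)
        length = feats.values[0, feats.feature_ids.index("len_alt")]
        assert length == 100  # cassette exon [700, 800)

    def test_minus_strand_kmers_are_revcomp_permutation(self, genome):
        path, _ = genome
        plus = extract_sequence_features([self.event("+")], str(path), k=2)
        minus = extract_sequence_features([self.event("-")], str(path), k=2)
        kcols = [i for i, f in enumerate(plus.feature_ids) if f.startswith("kmer_")]
        # reverse-complement permutation of the k-mer alphabet
        import itertools

        kmers = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        comp = str.maketrans("ACGT", "TGCA")
        perm = [kmers.index(m.translate(comp)[::-1]) for m in kmers]
        plus_k = plus.values[0, kcols]
        minus_k = minus.values[0, kcols]
        assert np.allclose(minus_k, plus_k[perm], atol=1e-12)

    def test_identical_events_identical_rows(self, genome):
        path, _ = genome
        e1 = self.event()
        e2 = EventDefinition("copy", "gA", "SE",
                             e1.inclusion_junctions, e1.exclusion_junctions)
        feats = extract_sequence_features([e1, e2], str(path))
        assert np.array_equal(feats.values[0], feats.values[1])

    def test_out_of_contig_raises(self, genome):
        path, _ = genome
        incl = [Junction("chr1", 500, 5000)]
        excl = [Junction("chr1", 500, 6000)]
        bad = EventDefinition("bad", "gA", "SE", incl, excl)
        with pytest.raises(ValueError, match="bad"):
            extract_sequence_features([bad], str(path))
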