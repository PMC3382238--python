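"""Discretization, mutual information, MaxRel/mRMR, IFS, and analyses."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amylostretch.classify_eval import NearestNeighborClassifier, jackknife
from amylostretch.featurization import (FeatureMatrix, FeatureSchema,
                                        SchemaEntry)
from amylostretch.feature_selection import (category_enrichment, discretize,
                                            ifs_curve, maxrel_rank,
                                            mrmr_rank, mutual_information,
                                            position_contributions,
                                            write_ifs_tsv, write_ranking_tsv)


def make_matrix(values, labels, flank_j=0):
    values = np.asarray(values, dtype=float)
    entries = tuple(
        SchemaEntry(1, f"f{j}", "physicochemical") for j in range(values.shape[1])
    )
    return FeatureMatrix(
        values, FeatureSchema(entries, flank_j), np.asarray(labels),
        [("p", i + 1) for i in range(len(values))],
    )


class TestDiscretize:
    def test_three_point_spread(self):
        assert discretize(np.array([-10.0, 0.0, 10.0])).tolist() == [0, 1, 2]

    def test_constant_column_all_zero(self):
        assert discretize(np.full(5, 3.3)).tolist() == [0] * 5

    def test_binary_column_keeps_two_states(self):
        out = discretize(np.array([0.0, 1.0] * 10))
        assert sorted(set(out.tolist())) == [0, 2]

    def test_standard_normal_middle_bin_mass(self):
        x = np.random.default_rng(7).standard_normal(10000)
        frac_mid = np.mean(discretize(x) == 1)
        assert frac_mid == pytest.approx(0.6827, abs=0.02)


class TestMutualInformation:
    def test_identity_balanced_binary_is_one_bit(self):
        y = np.array([0, 1] * 50)
        assert mutual_information(y, y) == pytest.approx(1.0)

    def test_independent_product_design_is_zero(self):
        # exact product distribution -> plug-in MI is exactly 0
        x, y = zip(*itertools.product(range(3), range(2)))
        assert mutual_information(np.array(x), np.array(y)) == pytest.approx(0.0)

    @given(
        x=st.lists(st.integers(0, 3), min_size=2, max_size=30),
        y=st.lists(st.integers(0, 2), min_size=2, max_size=30),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetric_and_nonnegative(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        mi = mutual_information(x, y)
        assert mi >= 0
        assert mi == pytest.approx(mutual_information(y, x))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 1])


@pytest.fixture
def toy_matrix(rng):
    """A = label copy, B = duplicate of A, C = partially informative,
    D = noise, E = constant."""
    y = np.array([0, 1] * 30)
    a = y.astype(float)
    b = a.copy()
    c = y.astype(float)
    c[:8] = 1 - c[:8]  # flip a few -> informative but not redundant with noise
    d = rng.standard_normal(60)
    e = np.full(60, 2.0)
    return make_matrix(np.column_stack([a, b, c, d, e]), y)


class TestRankings:
    def test_label_copy_ranks_first_constant_last(self, toy_matrix):
        r = maxrel_rank(toy_matrix)
        assert r.order[0] == 0
        assert r.order[-1] == 4  # zero MI, largest index among the zeros
        assert r.relevance[0] == pytest.approx(1.0)

    def test_relevance_matches_per_column_mi(self, toy_matrix):
        r = maxrel_rank(toy_matrix)
        for j, rel in zip(r.order, r.relevance):
            col = discretize(toy_matrix.values[:, j])
            assert rel == pytest.approx(mutual_information(col, toy_matrix.labels))

    def test_maxrel_relevance_nonincreasing(self, toy_matrix):
        r = maxrel_rank(toy_matrix)
        assert all(x >= y for x, y in zip(r.relevance, r.relevance[1:]))

    def test_mrmr_first_equals_maxrel_first(self, toy_matrix):
        assert mrmr_rank(toy_matrix).order[0] == maxrel_rank(toy_matrix).order[0]

    def test_duplicate_demoted_after_complementary_feature(self):
        """B duplicates A, so the MID criterion must rank the complementary
        informative feature C ahead of B; the greedy second pick is verified
        against a brute-force evaluation of relevance minus mean redundancy."""
        y = np.array([0, 1] * 30)
        a = y.astype(float)
        a[[0, 2, 4, 5]] = 1 - a[[0, 2, 4, 5]]  # strong but imperfect
        b = a.copy()
        c = y.astype(float)
        c[[40, 42, 45, 47]] = 1 - c[[40, 42, 45, 47]]  # errs on other samples
        m = make_matrix(np.column_stack([a, b, c]), y)
        r = mrmr_rank(m)
        order = list(r.order)
        assert order.index(2) < order.index(1)
        # brute-force MID check of the second pick given the first
        first = order[0]
        D = {j: discretize(m.values[:, j]) for j in range(3)}
        scores = {
            j: mutual_information(D[j], y) - mutual_information(D[j], D[first])
            for j in range(3) if j != first
        }
        expected_second = max(sorted(scores), key=lambda j: scores[j])
        assert order[1] == expected_second

    def test_rankings_are_permutations(self, toy_matrix):
        for r in (maxrel_rank(toy_matrix), mrmr_rank(toy_matrix),
                  mrmr_rank(toy_matrix, top_k=2)):
            assert sorted(r.order) == list(range(5))

    def test_row_order_invariance(self, toy_matrix, rng):
        perm = rng.permutation(toy_matrix.n_samples)
        shuffled = FeatureMatrix(
            toy_matrix.values[perm], toy_matrix.schema, toy_matrix.labels[perm],
            [toy_matrix.sample_ids[i] for i in perm],
        )
        assert np.array_equal(mrmr_rank(toy_matrix).order, mrmr_rank(shuffled).order)
        assert np.array_equal(
            maxrel_rank(toy_matrix).order, maxrel_rank(shuffled).order
        )


class TestIFS:
    @pytest.fixture
    def separable_matrix(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        x0 = y.astype(float)
        noise = rng.standard_normal((60, 4))
        return make_matrix(np.column_stack([x0, noise]), y)

    def test_curve_covers_every_k(self, separable_matrix):
        r = maxrel_rank(separable_matrix)
        curve = ifs_curve(r, separable_matrix, NearestNeighborClassifier, jackknife)
        assert [p.k for p in curve.points] == [1, 2, 3, 4, 5]

    def test_label_feature_alone_is_perfect(self, separable_matrix):
        r = maxrel_rank(separable_matrix)
        curve = ifs_curve(r, separable_matrix, NearestNeighborClassifier, jackknife)
        assert curve.points[0].acc_overall == 100.0
        assert curve.best_k == 1  # smallest k on ties

    def test_k_total_equals_full_matrix_jackknife(self, separable_matrix):
        r = maxrel_rank(separable_matrix)
        curve = ifs_curve(r, separable_matrix, NearestNeighborClassifier, jackknife)
        full = jackknife(separable_matrix, NearestNeighborClassifier)
        assert curve.points[-1].acc_overall == full.acc_overall

    def test_recomputation_identical(self, separable_matrix):
        r = maxrel_rank(separable_matrix)
        c1 = ifs_curve(r, separable_matrix, NearestNeighborClassifier, jackknife)
        c2 = ifs_curve(r, separable_matrix, NearestNeighborClassifier, jackknife)
        assert c1 == c2

    def test_improving_ks_are_strict_increases(self, separable_matrix):
        r = maxrel_rank(separable_matrix)
        curve = ifs_curve(r, separable_matrix, NearestNeighborClassifier, jackknife)
        accs = {p.k: p.acc_overall for p in curve.points}
        for k in curve.improving_ks():
            assert accs[k] > (accs.get(k - 1, 0.0))


class TestAnalyses:
    def make_schema(self, n_positions, per_pos):
        entries = tuple(
            SchemaEntry(p, f"a{i}", "pssm" if i % 2 else "disorder")
            for p in range(1, n_positions + 1)
            for i in range(per_pos)
        )
        return FeatureSchema(entries, (n_positions - 1) // 2)

    def test_counts_partition_selection(self):
        schema = self.make_schema(27, 34)
        sel = list(range(0, 918, 2))
        counts, mean = position_contributions(sel, schema)
        assert sum(counts.values()) == len(sel)
        assert set(counts) == set(range(1, 28))
        assert mean == pytest.approx(len(sel) / 27)

    def test_empty_selection_all_zero(self):
        schema = self.make_schema(5, 2)
        counts, mean = position_contributions([], schema)
        assert all(v == 0 for v in counts.values())
        assert mean == 0.0

    def test_uniform_selection_mean_matches_ratio(self):
        # 446 features spread over 27 positions average 16.5 per position
        schema = self.make_schema(27, 34)
        counts, mean = position_contributions(range(446), schema)
        assert mean == pytest.approx(446 / 27, abs=0.01)
        assert round(mean, 1) == 16.5

    def test_full_selection_ratios_one(self):
        schema = self.make_schema(3, 4)
        enr = category_enrichment(range(12), schema, reference_ratio=0.5)
        assert all(e.ratio == 1.0 for e in enr.values())

    def test_reference_ratio_flags(self):
        schema = self.make_schema(27, 34)
        sel = [i for i, e in enumerate(schema.entries) if e.category == "disorder"]
        ref = len(sel) / len(schema)
        enr = category_enrichment(sel, schema, ref)
        assert enr["disorder"].enriched and enr["disorder"].ratio == 1.0
        assert not enr["pssm"].enriched and enr["pssm"].ratio == 0.0
        assert all(0 <= e.ratio <= 1 for e in enr.values())


def test_ranking_and_curve_exports(tmp_path, rng):
    y = np.array([0, 1] * 20)
    m = make_matrix(np.column_stack([y, rng.standard_normal(40)]), y)
    r = mrmr_rank(m)
    p1 = write_ranking_tsv(r, m.schema, tmp_path / "rank.tsv")
    lines = p1.read_text().splitlines()
    assert len(lines) == 3 and lines[0].startswith("rank\t")
    curve = ifs_curve(r, m, NearestNeighborClassifier, jackknife)
    p2 = write_ifs_tsv(curve, tmp_path / "ifs.tsv")
    assert len(p2.read_text().splitlines()) == 3
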