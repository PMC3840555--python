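"""Effective-number diversity: index correspondences, limits, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divprof import (
    Community,
    EmptyCommunityError,
    SimilarityMatrix,
    classical_indices,
    default_q_grid,
    diversity,
    diversity_profile,
    naive_profile,
    ordinariness,
    relative_abundances,
)


def hill_number(p, q):
    """Independent brute-force Hill number (Σ p_i^q)^(1/(1−q))."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if math.isinf(q):
        return 1.0 / p.max()
    if abs(q - 1.0) < 1e-12:
        return math.exp(-(p * np.log(p)).sum())
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


class TestRelativeAbundances:
    def test_equal_split(self):
        assert np.allclose(relative_abundances(Community(["h", "b"], [10, 10])), [0.5, 0.5])

    def test_scale_invariance(self):
        # halving every count leaves relative abundances unchanged
        before = relative_abundances(Community(["h", "b"], [10, 10]))
        after = relative_abundances(Community(["h", "b"], [5, 5]))
        assert np.array_equal(before, after)

    def test_zero_taxon_dropped(self):
        p = relative_abundances(Community(list("abcd"), [6, 3, 1, 0]))
        assert np.allclose(p, [0.6, 0.3, 0.1])

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyCommunityError):
            Community(["a", "b"], [0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            Community(["a", "b"], [1, -1])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            Community(["a", "a"], [1, 1])


class TestOrdinariness:
    def test_identity_returns_p(self):
        p = np.array([0.6, 0.3, 0.1])
        Z = SimilarityMatrix.identity(["a", "b", "c"])
        assert np.allclose(ordinariness(Z, p), p)

    def test_all_ones_returns_ones(self):
        Z = SimilarityMatrix(["a", "b", "c"], np.ones((3, 3)))
        assert np.allclose(ordinariness(Z, [0.6, 0.3, 0.1]), 1.0)

    def test_uniform_offdiagonal(self):
        Z = SimilarityMatrix(["a", "b", "c"], np.full((3, 3), 0.9) + 0.1 * np.eye(3))
        zp = ordinariness(Z, np.full(3, 1 / 3))
        assert np.allclose(zp, 1 / 3 + 2 * 0.9 / 3)

    def test_bounds(self, rng):
        for _ in range(20):
            s = int(rng.integers(2, 20))
            p = rng.dirichlet(np.ones(s))
            Z = rng.uniform(size=(s, s))
            np.fill_diagonal(Z, 1.0)
            zp = ordinariness(SimilarityMatrix([str(i) for i in range(s)], Z), p)
            assert np.all(zp >= p - 1e-12) and np.all(zp <= 1 + 1e-12)

    def test_dimension_mismatch(self):
        Z = SimilarityMatrix.identity(["a", "b"])
        with pytest.raises(ValueError):
            ordinariness(Z, np.array([0.5, 0.3, 0.2]))


class TestDiversity:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([0.5, 0.5], 0.0, 2.0),                       # richness
            ([0.6, 0.3, 0.1], 2.0, 1 / 0.46),             # inverse Simpson
            ([0.6, 0.3, 0.1], 1.0, math.exp(0.8979457248567797)),  # exp(Shannon H)
            ([0.6, 0.3, 0.1], math.inf, 1 / 0.6),         # 1 / Berger-Parker
        ],
    )
    def test_hill_correspondences(self, p, q, expected):
        assert diversity(np.array(p), None, q) == pytest.approx(expected, abs=1e-12)

    def test_all_ones_similarity_gives_one(self, rng):
        for _ in range(5):
            s = int(rng.integers(2, 10))
            p = rng.dirichlet(np.ones(s))
            Z = SimilarityMatrix([str(i) for i in range(s)], np.ones((s, s)))
            for q in (0.0, 1.0, 2.7, math.inf):
                assert diversity(p, Z, q) == pytest.approx(1.0, abs=1e-12)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            diversity(np.array([0.5, 0.5]), None, -0.5)

    def test_q1_limit_matches_generic_formula(self, rng):
        for _ in range(10):
            s = int(rng.integers(2, 30))
            p = rng.dirichlet(np.ones(s))
            lim = diversity(p, None, 1.0)
            for eps in (1e-6, -1e-6):
                # agreement to 1e-6 precision (relative for large D, where
                # the O(eps * D * var(ln p)) drift exceeds 1e-6 absolute)
                assert diversity(p, None, 1.0 + eps) == pytest.approx(
                    lim, rel=1e-6, abs=1e-6
                )

    def test_matches_brute_force_hill(self, communities):
        for comm in communities:
            p = relative_abundances(comm)
            for q in (0.0, 0.5, 1.0, 1.7, 2.0, 3.4, 5.0, math.inf):
                assert diversity(p, None, q) == pytest.approx(hill_number(p, q), abs=1e-10)

    def test_log_space_path_matches_direct(self, rng):
        # communities larger than the log-space threshold agree with the
        # plain formula evaluated on a subset-free small computation
        s = 1500
        p = rng.dirichlet(np.full(s, 0.3))
        for q in (0.0, 2.0, 5.0):
            direct = float((p[p > 0] ** q).sum() ** (1 / (1 - q))) if q != 1 else None
            assert diversity(p, None, q) == pytest.approx(hill_number(p, q), rel=1e-10)


class TestProfiles:
    def test_uniform_community_constant(self):
        prof = naive_profile(Community(list("abcd"), [1, 1, 1, 1]))
        assert np.allclose(prof.diversities, 4.0)
        assert prof.is_naive

    def test_known_values_on_grid(self):
        comm = Community(["a", "b", "c"], [6, 3, 1])
        prof = naive_profile(comm, q_grid=[0, 1, 2, math.inf])
        assert np.allclose(
            prof.diversities,
            [3.0, math.exp(0.8979457248567797), 1 / 0.46, 1 / 0.6],
            atol=1e-9,
        )

    def test_default_grid(self):
        grid = default_q_grid()
        assert grid[0] == 0.0 and grid[-1] == 5.0
        assert np.allclose(np.diff(grid), 0.05)
        # q = 1 is on the grid and evaluated by its limit form
        assert 1.0 in grid

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            naive_profile(Community(["a", "b"], [1, 1]), q_grid=[])

    def test_range_and_monotone(self, communities, rng):
        grid = default_q_grid()
        for comm in communities[:10]:
            s = comm.richness
            prof = naive_profile(comm, grid)
            assert np.all(prof.diversities >= 1 - 1e-9)
            assert np.all(prof.diversities <= s + 1e-9)
            assert np.all(np.diff(prof.diversities) <= 1e-9)

    def test_similarity_at_most_naive(self, communities, rng):
        grid = np.array([0.0, 0.5, 1.0, 2.0, 3.5, 5.0])
        for comm in communities[:10]:
            s = comm.richness
            Z = rng.uniform(size=(s, s))
            Z = (Z + Z.T) / 2
            np.fill_diagonal(Z, 1.0)
            Zm = SimilarityMatrix(comm.present().taxon_ids, Z)
            naive = naive_profile(comm.present(), grid).diversities
            sim = diversity_profile(comm.present(), Zm, grid).diversities
            assert np.all(sim <= naive + 1e-9)

    def test_doubling_with_dissimilar_copy(self, rng):
        # two completely dissimilar copies at half abundance double diversity
        for _ in range(5):
            s = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(s))
            Z0 = rng.uniform(0.2, 0.9, size=(s, s))
            Z0 = (Z0 + Z0.T) / 2
            np.fill_diagonal(Z0, 1.0)
            Z2 = np.block([[Z0, np.zeros((s, s))], [np.zeros((s, s)), Z0]])
            ids = [f"x{i}" for i in range(s)]
            Zm1 = SimilarityMatrix(ids, Z0)
            Zm2 = SimilarityMatrix(ids + [f"y{i}" for i in range(s)], Z2)
            p2 = np.concatenate([p, p]) / 2
            for q in (0.0, 1.0, 2.0, 3.7, math.inf):
                d1 = diversity(p, Zm1, q)
                d2 = diversity(p2, Zm2, q)
                assert d2 == pytest.approx(2 * d1, abs=1e-9)

    def test_dissimilar_trio_more_diverse_than_similar_trio(self):
        # one hawk + one hummingbird + one goose beats three near-identical
        # hummingbird species at equal abundance
        p = np.full(3, 1 / 3)
        ids = ["s1", "s2", "s3"]
        dissimilar = SimilarityMatrix.identity(ids)
        similar = SimilarityMatrix(ids, np.full((3, 3), 0.95) + 0.05 * np.eye(3))
        for q in (0.0, 1.0, 2.0, math.inf):
            assert diversity(p, dissimilar, q) > diversity(p, similar, q)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=2, max_size=25),
    st.floats(min_value=0, max_value=5),
)
def test_naive_diversity_bounds_property(abund, q):
    """1 ≤ D ≤ S for arbitrary positive abundance vectors and q."""
    comm = Community([f"t{i}" for i in range(len(abund))], abund)
    p = relative_abundances(comm)
    d = diversity(p, None, q)
    assert 1 - 1e-9 <= d <= len(abund) + 1e-9


class TestClassicalIndices:
    def test_even_pair(self):
        idx = classical_indices(Community(["a", "b"], [1, 1]))
        assert idx["richness"] == 2
        assert idx["shannon_H"] == pytest.approx(math.log(2))
        assert idx["simpson_D"] == pytest.approx(0.5)
        assert idx["berger_parker"] == pytest.approx(0.5)

    def test_single_taxon(self):
        idx = classical_indices(Community(["a", "b"], [3, 0]))
        assert idx == {"richness": 1, "shannon_H": 0.0, "simpson_D": 1.0,
                       "berger_parker": 1.0}

    def test_consistency_with_profile(self):
        comm = Community(["a", "b", "c"], [6, 3, 1])
        idx = classical_indices(comm)
        assert idx["simpson_D"] == pytest.approx(0.46)
        p = relative_abundances(comm)
        assert 1 / idx["simpson_D"] == pytest.approx(diversity(p, None, 2.0))
        assert math.exp(idx["shannon_H"]) == pytest.approx(diversity(p, None, 1.0))
        assert 1 / idx["berger_parker"] == pytest.approx(diversity(p, None, math.inf))
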