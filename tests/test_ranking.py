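"""Rank probabilities, SUCRA identities, and SUCRA-plane clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from migranet import NMAConfig, cluster_treatments, rank_samples, sucra
from migranet.nma import PosteriorSet
from migranet.ranking import RankMatrix, SUCRAScores
from migranet.trial_data import ENDPOINTS, ValidationError, treatment


def make_post(d_draws: np.ndarray, treatments, ep=4) -> PosteriorSet:
    """Posterior stub from explicit draws, shaped (n, K-1), 2 pseudo-chains."""
    n = d_draws.shape[0]
    half = n // 2
    d = np.stack([d_draws[:half], d_draws[half : 2 * half]])
    cfg = NMAConfig(chains=2, iterations=2, burnin=1, seed=0)
    return PosteriorSet(
        endpoint=ENDPOINTS[ep],
        treatments=[treatment(t) for t in treatments],
        study_ids=["S1"],
        d=d,
        mu=np.zeros((2, half, 1)),
        tau=np.full((2, half), 0.1),
        config=cfg,
    )


def test_sure_winner_has_rank_one_probability_one():
    # treatment B always beats A and C on a lower-is-better endpoint
    draws = np.column_stack([np.full(100, -5.0), np.full(100, 2.0)])
    post = make_post(draws, "ABC")
    rm = rank_samples(post)
    b = post.treatments.index(treatment("B"))
    assert rm.P[b, 0] == 1.0


def test_direction_flips_ranking():
    draws = np.column_stack([np.full(100, -5.0), np.full(100, 2.0)])
    post = make_post(draws, "ABC", ep=3)  # higher is better
    rm = rank_samples(post, direction="higher_is_better")
    c = post.treatments.index(treatment("C"))
    assert rm.P[c, 0] == 1.0


def test_symmetric_two_treatment_posterior_is_a_coin_flip():
    rng = np.random.default_rng(3)
    draws = rng.normal(0.0, 1.0, (100_000, 1))
    post = make_post(draws, "AB")
    rm = rank_samples(post)
    assert rm.P[0, 0] == pytest.approx(0.5, abs=0.01)


def test_rank_matrix_is_doubly_stochastic(triangle_post):
    rm = rank_samples(triangle_post)
    rm.validate()
    assert np.allclose(rm.P.sum(axis=0), 1.0, atol=1e-9)
    assert np.allclose(rm.P.sum(axis=1), 1.0, atol=1e-9)


def _matrix(P, treatments="ABC"):
    return RankMatrix(treatments=[treatment(t) for t in treatments], P=np.asarray(P, float))


class TestSUCRA:
    def test_uniform_matrix_gives_half(self):
        s = sucra(_matrix(np.full((3, 3), 1 / 3)))
        assert all(v == pytest.approx(0.5) for v in s.scores.values())

    def test_always_best_gives_one(self):
        P = [[1, 0, 0], [0, 0.5, 0.5], [0, 0.5, 0.5]]
        s = sucra(_matrix(P))
        assert s[treatment("A")] == pytest.approx(1.0)

    def test_formula_arithmetic(self):
        P = [[0.6, 0.3, 0.1], [0.3, 0.4, 0.3], [0.1, 0.3, 0.6]]
        s = sucra(_matrix(P))
        assert s[treatment("A")] == pytest.approx(0.75)

    def test_mean_sucra_is_half(self, triangle_post):
        s = sucra(rank_samples(triangle_post))
        assert np.mean(list(s.scores.values())) == pytest.approx(0.5, abs=1e-9)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValidationError):
            sucra(_matrix([[0.9, 0.3, 0.1], [0.3, 0.4, 0.3], [0.1, 0.3, 0.6]]))

    def test_two_treatments_reduces_to_p_best(self):
        P = [[0.7, 0.3], [0.3, 0.7]]
        s = sucra(_matrix(P, "AB"))
        assert s[treatment("A")] == pytest.approx(0.7)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(0, 1, (400, 2))
        post1 = make_post(draws, "ABC")
        post2 = make_post(np.vstack([draws, draws]), "ABC")
        s1 = sucra(rank_samples(post1))
        s2 = sucra(rank_samples(post2))
        for t in s1.scores:
            assert s1[t] == pytest.approx(s2[t], abs=1e-12)

    @given(shift=st.floats(0.05, 2.0))
    def test_monotone_in_uniform_shifts(self, shift):
        rng = np.random.default_rng(9)
        draws = rng.normal(0, 1, (500, 2))
        base = sucra(rank_samples(make_post(draws, "ABC")))
        better = draws.copy()
        better[:, 0] -= shift  # lower is better on endpoint 4
        shifted = sucra(rank_samples(make_post(better, "ABC")))
        assert shifted[treatment("B")] >= base[treatment("B")] - 1e-12

    def test_formula_matches_exhaustive_rank_counting(self):
        """Brute-force oracle: count ranks draw by draw for K <= 4."""
        rng = np.random.default_rng(5)
        for K in (2, 3, 4):
            draws = rng.normal(0, 1, (800, K - 1))
            post = make_post(draws, "ABCD"[:K])
            scores = sucra(rank_samples(post))
            full = np.column_stack([post.d_draws(t) for t in post.treatments])
            N = full.shape[0]
            mean_rank = np.zeros(K)
            for i in range(N):
                order = np.argsort(full[i], kind="stable")
                r = np.empty(K)
                r[order] = np.arange(1, K + 1)
                mean_rank += r
            mean_rank /= N
            # SUCRA = (K - mean rank) / (K - 1)
            for k, t in enumerate(post.treatments):
                expected = (K - mean_rank[k]) / (K - 1)
                assert scores[t] == pytest.approx(expected, abs=1e-9)


def _scores(vals, treatments="ABCDEFG"):
    ts = [treatment(t) for t in treatments[: len(vals)]]
    return SUCRAScores(treatments=ts, scores=dict(zip(ts, map(float, vals))))


class TestClustering:
    def test_separated_groups_recovered(self):
        x = _scores([0.10, 0.12, 0.08, 0.90, 0.92, 0.88])
        y = _scores([0.11, 0.09, 0.12, 0.91, 0.89, 0.90])
        ca = cluster_treatments(x, y, seed=0)
        assert ca.k == 2
        lab = ca.labels
        low = {lab[t] for t in list(lab)[:3]}
        high = {lab[t] for t in list(lab)[3:]}
        assert len(low) == 1 and len(high) == 1 and low != high

    def test_identical_points_degenerate(self):
        x = _scores([0.5] * 4)
        y = _scores([0.5] * 4)
        ca = cluster_treatments(x, y)
        assert ca.degenerate
        assert ca.silhouette == 0.0
        assert len(set(ca.labels.values())) == 1

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValidationError):
            cluster_treatments(_scores([0.1, 0.9]), _scores([0.1, 0.9, 0.5]))

    def test_permutation_invariance_up_to_relabel(self):
        vals_x = [0.1, 0.9, 0.15, 0.85, 0.12]
        vals_y = [0.2, 0.8, 0.25, 0.75, 0.18]
        a = cluster_treatments(_scores(vals_x), _scores(vals_y), k=2, seed=1)

        perm = [4, 2, 0, 3, 1]
        ts = "ABCDE"
        px = _scores([vals_x[i] for i in perm], "".join(ts[i] for i in perm))
        py = _scores([vals_y[i] for i in perm], "".join(ts[i] for i in perm))
        b = cluster_treatments(px, py, k=2, seed=1)
        # same partition of treatments, labels possibly renamed
        part_a = {}
        for t, l in a.labels.items():
            part_a.setdefault(l, set()).add(t)
        part_b = {}
        for t, l in b.labels.items():
            part_b.setdefault(l, set()).add(t)
        assert set(map(frozenset, part_a.values())) == set(map(frozenset, part_b.values()))

    def test_explicit_k_bounds(self):
        x = _scores([0.1, 0.5, 0.9])
        with pytest.raises(ValidationError):
            cluster_treatments(x, x, k=3)  # k must be < K
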