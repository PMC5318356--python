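"""Treatment ranking: rank probabilities, SUCRA, and SUCRA-plane clustering.

Rank 1 is best.  The endpoint's benefit direction decides the sort order:
for harm/tolerability outcomes a smaller effect ranks first, for the
responder outcome a larger one does.  SUCRA is the surface under the
cumulative ranking curve, SUCRA_k = sum_{j=1}^{K-1} cum_k(j) / (K-1),
a 0-1 summary of the rank distribution (1 = certainly best).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .nma import PosteriorSet
from .trial_data import Treatment, ValidationError

__all__ = [
    "RankMatrix",
    "SUCRAScores",
    "ClusterAssignment",
    "rank_samples",
    "sucra",
    "cluster_treatments",
]


@dataclass
class RankMatrix:
    """P[k, j] = probability that treatment k attains rank j+1 (0-indexed)."""

    treatments: list[Treatment]
    P: np.ndarray  # (K, K), doubly stochastic

    def __post_init__(self):
        K = len(self.treatments)
        assert self.P.shape == (K, K)

    def validate(self, tol: float = 1e-9) -> None:
        if not (
            np.allclose(self.P.sum(axis=0), 1.0, atol=tol)
            and np.allclose(self.P.sum(axis=1), 1.0, atol=tol)
            and (self.P >= -tol).all()
        ):
            raise ValidationError("rank matrix is not doubly stochastic")

    def to_rows(self) -> list[dict]:
        return [
            {"treatment": t.name, "rank": j + 1, "probability": float(self.P[k, j])}
            for k, t in enumerate(self.treatments)
            for j in range(len(self.treatments))
        ]


@dataclass
class SUCRAScores:
    treatments: list[Treatment]
    scores: dict  # Treatment -> float in [0, 1]

    def __getitem__(self, t: Treatment) -> float:
        return self.scores[t]

    def to_rows(self) -> list[dict]:
        return [
            {"treatment": t.name, "sucra": float(self.scores[t])}
            for t in self.treatments
        ]


@dataclass
class ClusterAssignment:
    treatments: list[Treatment]
    labels: dict  # Treatment -> int
    coords: dict  # Treatment -> (sucra_x, sucra_y)
    k: int
    silhouette: float
    degenerate: bool = False


def rank_samples(post: PosteriorSet, direction: str | None = None) -> RankMatrix:
    """Rank frequencies over posterior draws.

    Each draw sorts the treatments by effect with the better direction
    first; ties break by treatment code order (the draws are perturbed by
    position with an infinitesimal weight via stable argsort).
    """
    if direction is None:
        direction = post.endpoint.direction
    if direction not in ("higher_is_better", "lower_is_better"):
        raise ValidationError(f"bad direction {direction!r}")
    K = len(post.treatments)
    draws = np.column_stack([post.d_draws(t) for t in post.treatments])  # (N, K)
    key = -draws if direction == "higher_is_better" else draws
    # stable sort => ties resolved by column (treatment code) order
    order = np.argsort(key, axis=1, kind="stable")  # (N, K): order[n, j] = who is rank j+1
    N = draws.shape[0]
    P = np.zeros((K, K))
    for j in range(K):
        P[:, j] = np.bincount(order[:, j], minlength=K)
    P /= N
    return RankMatrix(treatments=list(post.treatments), P=P)


def sucra(ranks: RankMatrix) -> SUCRAScores:
    """Surface under the cumulative ranking curve for each treatment."""
    ranks.validate()
    K = len(ranks.treatments)
    if K < 2:
        raise ValidationError("SUCRA needs at least two treatments")
    cum = np.cumsum(ranks.P, axis=1)  # cum[k, j] = P(rank <= j+1)
    scores = cum[:, : K - 1].sum(axis=1) / (K - 1)
    return SUCRAScores(
        treatments=list(ranks.treatments),
        scores={t: float(s) for t, s in zip(ranks.treatments, scores)},
    )


def cluster_treatments(
    x: SUCRAScores,
    y: SUCRAScores,
    k: int | None = None,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterAssignment:
    """k-means grouping of treatments on the plane of two SUCRA scores.

    With ``k=None`` the cluster count is chosen among {2, 3, 4} by maximum
    mean silhouette.  If all points coincide the geometry is degenerate:
    everything lands in one effective cluster and the assignment is
    flagged.  Deterministic given ``seed``.
    """
    if set(x.scores) != set(y.scores):
        raise ValidationError("SUCRA inputs cover different treatment sets")
    treats = sorted(x.scores, key=lambda t: t.code)
    K = len(treats)
    pts = np.array([[x.scores[t], y.scores[t]] for t in treats])

    if np.allclose(pts, pts[0], atol=1e-12):
        return ClusterAssignment(
            treatments=treats,
            labels={t: 0 for t in treats},
            coords={t: tuple(map(float, p)) for t, p in zip(treats, pts)},
            k=2,
            silhouette=0.0,
            degenerate=True,
        )

    def fit(kk: int):
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(pts)
        if len(set(labels)) < 2 or kk >= K:
            return labels, -1.0
        return labels, float(silhouette_score(pts, labels))

    if k is not None:
        if not 2 <= k < K:
            raise ValidationError("cluster count must satisfy 2 <= k < K")
        labels, sil = fit(k)
        chosen = k
    else:
        if K < 3:
            raise ValidationError("automatic k needs at least 3 treatments")
        best = None
        for kk in (2, 3, 4):
            if kk >= K:
                break
            labels, sil = fit(kk)
            if best is None or sil > best[2]:
                best = (kk, labels, sil)
        chosen, labels, sil = best

    return ClusterAssignment(
        treatments=treats,
        labels={t: int(l) for t, l in zip(treats, labels)},
        coords={t: tuple(map(float, p)) for t, p in zip(treats, pts)},
        k=chosen,
        silhouette=max(sil, 0.0) if sil == -1.0 else sil,
        degenerate=False,
    )
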