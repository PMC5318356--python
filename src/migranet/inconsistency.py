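"""Inconsistency diagnostics and publication-bias data.

Two complementary routes are implemented deliberately:

* node-splitting re-fits the Bayesian NMA giving one comparison's direct
  evidence its own parameter, so direct and indirect estimates can be
  contrasted draw-wise (Bayesian, matching the main model);
* the net-heat construction works on a frequentist weighted-least-squares
  backbone over design-level contrasts, decomposing Cochran's Q into
  within-design heterogeneity and design-inconsistency and localising the
  latter by detaching one design at a time.

Funnel-plot data use comparison-adjusted centering (study effect minus the
direct pooled effect of its comparison) with Egger's regression as the
quantitative companion to visual inspection.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .nma import NMAConfig, fit_nma
from .pairwise import EffectEstimate, PooledResult, pool_dl
from .trial_data import (
    ArmRecord,
    Treatment,
    ValidationError,
    build_network,
    endpoint as resolve_endpoint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NodeSplitResult",
    "DesignLevel",
    "DesignContrasts",
    "NetHeatMatrix",
    "FunnelDatum",
    "NotSplittableError",
    "node_split",
    "splittable_comparisons",
    "design_contrasts",
    "wls_network_fit",
    "q_decomposition",
    "net_heat",
    "funnel_data",
]


class NotSplittableError(ValueError):
    """The comparison lacks direct evidence or an independent indirect path."""


@dataclass
class NodeSplitResult:
    comparison: tuple[Treatment, Treatment]
    direct: dict  # median / cr_low / cr_high on the additive scale
    indirect: dict
    difference: dict
    p_value: float

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0


def _summ(draws: np.ndarray) -> dict:
    med, lo, hi = np.quantile(draws, [0.5, 0.025, 0.975])
    return {"median": float(med), "cr_low": float(lo), "cr_high": float(hi)}


def splittable_comparisons(arms: Sequence[ArmRecord], ep) -> list[tuple[Treatment, Treatment]]:
    """Comparisons with two-arm direct evidence plus an indirect path."""
    net = build_network(arms, ep)
    out = []
    for pair in sorted(net.edges, key=lambda p: sorted(t.code for t in p)):
        a, b = sorted(pair)
        if _has_indirect_path(net, a, b):
            out.append((a, b))
    return out


def _has_indirect_path(net, a: Treatment, b: Treatment) -> bool:
    g = nx.Graph()
    g.add_nodes_from(net.treatments)
    for pair, sids in net.edges.items():
        x, y = sorted(pair)
        remaining = [
            s for s in sids if {r.treatment for r in net.studies[s]} != {a, b}
        ]
        if remaining:
            g.add_edge(x, y)
    return nx.has_path(g, a, b)


def node_split(
    arms: Sequence[ArmRecord],
    ep,
    comparison: tuple[Treatment, Treatment],
    config: NMAConfig = NMAConfig(),
) -> NodeSplitResult:
    """Direct-versus-indirect conflict test for one comparison.

    The NMA is refitted with the comparison's two-arm direct studies
    informing a separate parameter; the network's basic parameters then
    carry only the indirect evidence for that contrast.  The two-sided
    Bayesian p-value is 2 * min(P(diff > 0), P(diff < 0)) over draws of
    difference = direct - indirect.
    """
    ep = resolve_endpoint(ep)
    a, b = comparison
    net = build_network(arms, ep)
    if frozenset((a, b)) not in net.edges:
        raise NotSplittableError(f"no direct evidence for {a.name} vs {b.name}")
    if not _has_indirect_path(net, a, b):
        raise NotSplittableError(
            f"no indirect path between {a.name} and {b.name} after removing "
            f"direct studies"
        )
    post = fit_nma(arms, ep, config, split=(a, b))
    direct = post.omega.reshape(-1)
    indirect = post.contrast_draws(a, b)
    diff = direct - indirect
    p_gt = float(np.mean(diff > 0))
    p = 2.0 * min(p_gt, 1.0 - p_gt)
    return NodeSplitResult(
        comparison=(a, b),
        direct=_summ(direct),
        indirect=_summ(indirect),
        difference=_summ(diff),
        p_value=min(p, 1.0),
    )


# ---------------------------------------------------------------------------
# design-level frequentist backbone


@dataclass
class DesignLevel:
    """One design: a distinct treatment set, with its pooled direct contrasts.

    Contrasts are taken versus the design's internal baseline (lowest
    treatment code).  ``y`` is the fixed-effect pooled contrast vector over
    the design's studies, ``W`` its weight (inverse-covariance) matrix, and
    ``q_het`` the within-design heterogeneity contribution.
    """

    treatments: frozenset
    baseline: Treatment
    contrasts: list  # (baseline, alt) pairs, alt ordered by code
    y: np.ndarray
    W: np.ndarray
    studies: list
    q_het: float

    @property
    def label(self) -> str:
        return "-".join(sorted(t.code for t in self.treatments))


@dataclass
class DesignContrasts:
    """All designs of one endpoint network plus the basic-parameter order."""

    endpoint: object
    treatments: list  # reference first; basic parameters follow treatments[1:]
    designs: list


@dataclass
class NetHeatMatrix:
    designs: list  # labels
    contribution: np.ndarray  # rows sum to 1
    delta_inconsistency: np.ndarray  # >0: detaching the column lowers row's Q_inc
    Q_total: float
    Q_het: float
    Q_inc: float

    def __post_init__(self):
        assert self.Q_total >= -1e-12 and self.Q_het >= -1e-12 and self.Q_inc >= -1e-12


@dataclass(frozen=True)
class FunnelDatum:
    study_id: str
    comparison: tuple
    centered_effect: float
    se: float


def _study_contrast_cov(recs: list[ArmRecord], binary: bool, correction: float = 0.5):
    """Contrast vector vs the study baseline with its covariance matrix."""
    base, alts = recs[0], recs[1:]
    if binary:
        cells = []
        zero = any(r.events == 0 or r.events == r.n for r in recs)
        for r in recs:
            a = r.events + (correction if zero else 0.0)
            b = r.n - r.events + (correction if zero else 0.0)
            cells.append((a, b))
        lo = [math.log(a / b) for a, b in cells]
        var = [1.0 / a + 1.0 / b for a, b in cells]
        y = np.array([lo[j + 1] - lo[0] for j in range(len(alts))])
        V = np.full((len(alts), len(alts)), var[0])
        V[np.diag_indices(len(alts))] = [var[0] + var[j + 1] for j in range(len(alts))]
    else:
        y = np.array([r.mean - base.mean for r in alts])
        v0 = base.sd**2 / base.n
        V = np.full((len(alts), len(alts)), v0)
        V[np.diag_indices(len(alts))] = [
            v0 + r.sd**2 / r.n for r in alts
        ]
    return y, V


def design_contrasts(arms: Sequence[ArmRecord], ep, correction: float = 0.5) -> DesignContrasts:
    """Aggregate studies into designs with pooled contrasts and weights."""
    ep = resolve_endpoint(ep)
    net = build_network(arms, ep)
    treats = sorted(net.treatments)
    by_design: dict[frozenset, list[str]] = defaultdict(list)
    for sid, recs in sorted(net.studies.items()):
        by_design[frozenset(r.treatment for r in recs)].append(sid)

    designs = []
    for tset in sorted(by_design, key=lambda s: sorted(t.code for t in s)):
        sids = by_design[tset]
        members = sorted(tset)
        baseline = members[0]
        m = len(members) - 1
        Wsum = np.zeros((m, m))
        Wy = np.zeros(m)
        per_study = []
        for sid in sids:
            y_i, V_i = _study_contrast_cov(net.studies[sid], ep.is_binary, correction)
            W_i = np.linalg.inv(V_i)
            Wsum += W_i
            Wy += W_i @ y_i
            per_study.append((y_i, W_i))
        y_d = np.linalg.solve(Wsum, Wy)
        q_het = 0.0
        for y_i, W_i in per_study:
            r = y_i - y_d
            q_het += float(r @ W_i @ r)
        designs.append(
            DesignLevel(
                treatments=tset,
                baseline=baseline,
                contrasts=[(baseline, t) for t in members[1:]],
                y=y_d,
                W=Wsum,
                studies=sids,
                q_het=q_het,
            )
        )
    ordered = [t for t in treats]
    # place the global reference first if present
    return DesignContrasts(endpoint=ep, treatments=ordered, designs=designs)


def _stack(dc: DesignContrasts, detach: Optional[int] = None):
    """Flatten designs into (X, W, y) with optional detached design columns."""
    tindex = {t: i for i, t in enumerate(dc.treatments)}
    P = len(dc.treatments) - 1
    rows_X, blocks_W, ys, row_design = [], [], [], []
    extra = sum(len(d.contrasts) for i, d in enumerate(dc.designs) if detach == i)
    e_off = 0
    for i, d in enumerate(dc.designs):
        m = len(d.contrasts)
        Xd = np.zeros((m, P + extra))
        if detach == i:
            for j in range(m):
                Xd[j, P + e_off + j] = 1.0
            e_off += m
        else:
            for j, (b, t) in enumerate(d.contrasts):
                if tindex[t] > 0:
                    Xd[j, tindex[t] - 1] += 1.0
                if tindex[b] > 0:
                    Xd[j, tindex[b] - 1] -= 1.0
        rows_X.append(Xd)
        blocks_W.append(d.W)
        ys.append(d.y)
        row_design.extend([i] * m)
    X = np.vstack(rows_X)
    y = np.concatenate(ys)
    R = len(y)
    W = np.zeros((R, R))
    pos = 0
    for B in blocks_W:
        m = B.shape[0]
        W[pos : pos + m, pos : pos + m] = B
        pos += m
    return X, W, y, np.array(row_design)


def wls_network_fit(dc: DesignContrasts):
    """Weighted least squares of design contrasts on the basic parameters.

    Returns (estimates, H, fitted) where H = X (X'WX)^-1 X'W is the hat
    matrix over design-contrast rows.  A rank-deficient design matrix
    (disconnected design network) raises a ValidationError naming the
    components.
    """
    X, W, y, _ = _stack(dc)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        g = nx.Graph()
        g.add_nodes_from(dc.treatments)
        for d in dc.designs:
            for b, t in d.contrasts:
                g.add_edge(b, t)
        comps = [
            "{" + ",".join(sorted(t.code for t in c)) + "}"
            for c in nx.connected_components(g)
        ]
        raise ValidationError(
            f"design matrix is rank deficient; components: {'; '.join(comps)}"
        )
    A = X.T @ W @ X
    est = np.linalg.solve(A, X.T @ W @ y)
    H = X @ np.linalg.solve(A, X.T @ W)
    return est, H, X @ est


def q_decomposition(dc: DesignContrasts) -> tuple[float, float, float]:
    """Cochran Q split: Q_total = Q_het (within design) + Q_inc (between).

    Q_total sums study-level weighted squared deviations from the network
    (consistency) estimates; the within-design part uses deviations from
    each design's own pooled contrast, and the remainder is the
    design-by-treatment inconsistency.  The identity holds exactly because
    each design's pooled contrast is its weighted mean.
    """
    _, _, fitted = wls_network_fit(dc)
    q_het = sum(d.q_het for d in dc.designs)
    q_inc = 0.0
    pos = 0
    for d in dc.designs:
        m = len(d.contrasts)
        r = d.y - fitted[pos : pos + m]
        q_inc += float(r @ d.W @ r)
        pos += m
    return q_het + q_inc, q_het, q_inc


def _per_design_qinc(dc: DesignContrasts, detach: Optional[int] = None) -> np.ndarray:
    X, W, y, row_design = _stack(dc, detach=detach)
    A = X.T @ W @ X
    est, *_ = np.linalg.lstsq(X, y, rcond=None)  # placeholder if singular
    try:
        est = np.linalg.solve(A, X.T @ W @ y)
    except np.linalg.LinAlgError:
        est = np.linalg.pinv(A) @ (X.T @ W @ y)
    fitted = X @ est
    q = np.zeros(len(dc.designs))
    pos = 0
    for i, d in enumerate(dc.designs):
        m = len(d.contrasts)
        r = d.y - fitted[pos : pos + m]
        q[i] = float(r @ d.W @ r)
        pos += m
    return q


def net_heat(dc: DesignContrasts) -> NetHeatMatrix:
    """Design-by-design evidence-flow and inconsistency-localisation matrix.

    ``contribution[d, d']`` is the normalised absolute hat-matrix weight of
    design d' in design d's network estimate.  ``delta_inconsistency[d, d']``
    is design d's Q_inc contribution in the full fit minus its contribution
    after design d' is detached (granted its own parameters): positive
    entries mean detaching d' lowers the inconsistency seen at d (warm
    colours), negative entries mean it raises it.
    """
    if len(dc.designs) < 2:
        raise ValidationError("net heat requires at least two designs")
    _, H, _ = wls_network_fit(dc)
    _, _, _, row_design = _stack(dc)
    nD = len(dc.designs)
    contrib = np.zeros((nD, nD))
    absH = np.abs(H)
    for i in range(nD):
        ri = row_design == i
        for j in range(nD):
            contrib[i, j] = absH[np.ix_(ri, row_design == j)].sum()
    rows = contrib.sum(axis=1, keepdims=True)
    contrib = np.divide(contrib, rows, out=np.zeros_like(contrib), where=rows > 0)

    q_full = _per_design_qinc(dc)
    delta = np.zeros((nD, nD))
    for j in range(nD):
        q_det = _per_design_qinc(dc, detach=j)
        delta[:, j] = q_full - q_det
    q_total, q_het, q_inc = q_decomposition(dc)
    return NetHeatMatrix(
        designs=[d.label for d in dc.designs],
        contribution=contrib,
        delta_inconsistency=delta,
        Q_total=q_total,
        Q_het=q_het,
        Q_inc=q_inc,
    )


# ---------------------------------------------------------------------------
# funnel data


def funnel_data(
    effects: Sequence[EffectEstimate],
    pooled: Sequence[PooledResult],
) -> tuple[list[FunnelDatum], Optional[dict]]:
    """Comparison-adjusted funnel data plus Egger's asymmetry regression.

    Each study effect is centered on the direct pooled effect of its own
    comparison, so multi-comparison networks share one funnel.  Egger's
    test regresses (centered effect / se) on (1 / se); with fewer than
    three studies the regression is omitted and the data still returned.
    """
    pooled_by_comp = {p.comparison: p.pooled for p in pooled}
    data = []
    for e in effects:
        if e.comparison not in pooled_by_comp:
            single = pool_dl([e])
            pooled_by_comp[e.comparison] = single.pooled
        data.append(
            FunnelDatum(
                study_id=e.study_id,
                comparison=e.comparison,
                centered_effect=e.effect - pooled_by_comp[e.comparison],
                se=e.se,
            )
        )
    egger = None
    if len(data) >= 3:
        z = np.array([d.centered_effect / d.se for d in data])
        prec = np.array([1.0 / d.se for d in data])
        res = stats.linregress(prec, z)
        dfree = len(data) - 2
        tval = res.intercept / res.intercept_stderr if res.intercept_stderr > 0 else 0.0
        pval = 2.0 * stats.t.sf(abs(tval), dfree)
        egger = {
            "intercept": float(res.intercept),
            "se": float(res.intercept_stderr),
            "p": float(pval),
            "slope": float(res.slope),
            "n": len(data),
        }
    return data, egger
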