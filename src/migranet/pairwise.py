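"""Conventional random-effects pairwise meta-analysis.

Per-study effects are raw mean differences (continuous endpoints) or log
odds ratios (binary endpoints); pooling uses inverse-variance weights with
the DerSimonian-Laird moment estimator of the between-study variance tau^2
and Wald 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .trial_data import ArmRecord, EvidenceNetwork, Treatment, ValidationError, build_network

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEstimate",
    "PooledResult",
    "DegenerateTableError",
    "study_effect_binary",
    "study_effect_continuous",
    "study_effects",
    "pool_dl",
    "pairwise_table",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateTableError(ValueError):
    """A 2x2 table is uninformative even after continuity correction."""


@dataclass(frozen=True)
class EffectEstimate:
    """One study's contrast (alt minus ref) on the analysis scale."""

    study_id: str
    comparison: tuple[Treatment, Treatment]  # (ref, alt)
    effect: float  # MD or log-OR
    se: float
    scale: str  # "MD" | "logOR"

    def __post_init__(self):
        if not (self.se > 0 and math.isfinite(self.effect) and math.isfinite(self.se)):
            raise ValidationError(
                f"{self.study_id}: non-finite effect or non-positive se"
            )


@dataclass(frozen=True)
class PooledResult:
    comparison: tuple[Treatment, Treatment]
    k: int
    pooled: float
    ci_low: float
    ci_high: float
    Q: float
    tau2: float
    I2: float
    scale: str

    def __post_init__(self):
        assert self.ci_low <= self.pooled <= self.ci_high
        assert self.Q >= 0 and self.tau2 >= 0 and 0 <= self.I2 <= 100


def study_effect_binary(
    ref_arm: ArmRecord, alt_arm: ArmRecord, correction: float = 0.5
) -> EffectEstimate:
    """Log odds ratio of alt vs ref from one study's 2x2 table.

    A continuity correction (default 0.5) is added to all four cells only
    when any cell is zero.  Tables that remain degenerate (no events or all
    events in both arms) raise :class:`DegenerateTableError`.
    """
    if ref_arm.study_id != alt_arm.study_id:
        raise ValidationError("arms must come from the same study")
    if not ref_arm.endpoint.is_binary:
        raise ValidationError("binary effect requested for a continuous endpoint")
    if correction < 0:
        raise ValidationError("continuity correction must be >= 0")
    a = float(alt_arm.events)
    b = float(alt_arm.n - alt_arm.events)
    c = float(ref_arm.events)
    d = float(ref_arm.n - ref_arm.events)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = (x + correction for x in (a, b, c, d))
    if min(a, b, c, d) <= 0.0 or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise DegenerateTableError(
            f"{ref_arm.study_id}: degenerate 2x2 table for "
            f"{alt_arm.treatment.name} vs {ref_arm.treatment.name}"
        )
    y = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        study_id=ref_arm.study_id,
        comparison=(ref_arm.treatment, alt_arm.treatment),
        effect=y,
        se=se,
        scale="logOR",
    )


def study_effect_continuous(
    ref_arm: ArmRecord, alt_arm: ArmRecord, crossover_rho: float | None = None
) -> EffectEstimate:
    """Raw mean difference of alt vs ref with its large-sample SE.

    If ``crossover_rho`` is given and the study is a crossover trial, the SE
    is shrunk by sqrt(1 - rho) as a sensitivity analysis for within-subject
    correlation; by default crossover arms are pooled as if parallel.
    """
    if ref_arm.study_id != alt_arm.study_id:
        raise ValidationError("arms must come from the same study")
    if ref_arm.endpoint.is_binary:
        raise ValidationError("continuous effect requested for a binary endpoint")
    y = alt_arm.mean - ref_arm.mean
    se = math.sqrt(alt_arm.sd**2 / alt_arm.n + ref_arm.sd**2 / ref_arm.n)
    if crossover_rho is not None and ref_arm.design == "crossover":
        if not 0 <= crossover_rho < 1:
            raise ValidationError("crossover_rho must be in [0, 1)")
        se *= math.sqrt(1 - crossover_rho)
    return EffectEstimate(
        study_id=ref_arm.study_id,
        comparison=(ref_arm.treatment, alt_arm.treatment),
        effect=y,
        se=se,
        scale="MD",
    )


def study_effects(
    network: EvidenceNetwork,
    correction: float = 0.5,
    crossover_rho: float | None = None,
) -> list[EffectEstimate]:
    """All within-study contrasts of a network versus each study's first arm.

    Arms are ordered by treatment code, so the reference-most treatment of
    each study anchors its contrasts.  Degenerate binary tables are skipped
    with a logged warning.
    """
    out = []
    for sid in sorted(network.studies):
        recs = network.studies[sid]
        base = recs[0]
        for alt in recs[1:]:
            try:
                if network.endpoint.is_binary:
                    out.append(study_effect_binary(base, alt, correction=correction))
                else:
                    out.append(
                        study_effect_continuous(base, alt, crossover_rho=crossover_rho)
                    )
            except DegenerateTableError:
                logger.warning(
                    "skipping degenerate table in study %s (%s)", sid,
                    network.endpoint.name,
                )
    return out


def pool_dl(effects: list[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling of one comparison.

    Fixed weights w_i = 1/se_i^2 give Cochran's Q; the moment estimator
    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))) feeds random
    weights 1/(se_i^2 + tau^2).  With a single study the estimate passes
    through with Q = tau^2 = 0.
    """
    if not effects:
        raise ValidationError("cannot pool an empty list of effects")
    scales = {e.scale for e in effects}
    comps = {e.comparison for e in effects}
    if len(scales) > 1 or len(comps) > 1:
        raise ValidationError("all effects must share one comparison and scale")
    k = len(effects)
    y = np.array([e.effect for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    yw = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - yw) ** 2))
    if k == 1:
        tau2 = 0.0
        I2 = 0.0
    else:
        C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / C)
        I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    ws = 1.0 / (v + tau2)
    pooled = float(np.sum(ws * y) / np.sum(ws))
    se_pooled = float(1.0 / math.sqrt(np.sum(ws)))
    return PooledResult(
        comparison=effects[0].comparison,
        k=k,
        pooled=pooled,
        ci_low=pooled - Z95 * se_pooled,
        ci_high=pooled + Z95 * se_pooled,
        Q=Q,
        tau2=tau2,
        I2=I2,
        scale=effects[0].scale,
    )


def pairwise_table(
    arms,
    ep,
    correction: float = 0.5,
    crossover_rho: float | None = None,
) -> list[PooledResult]:
    """One pooled random-effects summary per direct comparison of an endpoint."""
    network = build_network(arms, ep)
    effects = study_effects(network, correction=correction, crossover_rho=crossover_rho)
    by_comp: dict[tuple, list[EffectEstimate]] = {}
    for e in effects:
        by_comp.setdefault(e.comparison, []).append(e)
    return [pool_dl(v) for _, v in sorted(by_comp.items(), key=lambda kv: (kv[0][0].code, kv[0][1].code))]
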