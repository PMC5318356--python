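"""Synthetic networks of randomized trials with known ground truth.

The generator emulates the data-generating process the analysis assumes:
logit-linear treatment effects on binomial arm events (binary endpoints),
normal arm means with a common within-arm standard deviation (continuous
endpoints), between-study heterogeneity tau on the trial-specific
contrasts, optional additive loop-inconsistency offsets on chosen edges,
parallel and crossover designs, and withdrawal endpoints driven by
independent per-arm binomial dropout.  Everything is reproducible from the
scenario seed, and the truth record travels with the simulated arm table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .nma import NMAConfig, fit_nma
from .trial_data import (
    ArmRecord,
    ENDPOINTS,
    REFERENCE,
    ValidationError,
    load_fixture,
    treatment as resolve_treatment,
    write_arm_table,
)

__all__ = [
    "SimulationScenario",
    "StudySpec",
    "SimulatedNetwork",
    "simulate_network",
    "make_evidence_base_scenario",
    "recovery_experiment",
    "nodesplit_calibration",
]


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class StudySpec:
    """An explicit study skeleton (used by the evidence-base-like scenario)."""

    study_id: str
    design: str
    treatments: tuple
    n_arms: tuple
    endpoints: tuple
    year: int = 2000
    blinding: str = "double"


@dataclass(frozen=True)
class SimulationScenario:
    """Ground truth and geometry of a simulated trial network.

    ``true_d`` maps treatment name to its true effect versus the reference
    on the endpoint's linear scale (log odds ratio or mean difference; the
    reference must map to 0).  ``inconsistency`` maps an unordered
    comparison (frozenset of names) to an additive offset applied to that
    edge's direct evidence.  ``n_per_arm`` is a fixed count or an inclusive
    (low, high) range.  Binary baselines are drawn per study on the logit
    scale around ``baseline_logit`` (default logit(0.3), a plausible
    adverse-event rate); withdrawal endpoints use logit(``dropout_rate``)
    instead.  Continuous baselines are drawn around ``baseline_mean`` with
    within-arm standard deviation ``within_sd``.
    """

    treatments: tuple = ("placebo", "topiramate", "propranolol")
    true_d: dict = field(default_factory=dict)
    #: optional per-endpoint override of true_d, keyed by endpoint code
    true_d_by_endpoint: dict = field(default_factory=dict)
    tau: float = 0.1
    inconsistency: dict = field(default_factory=dict)
    trials_per_comparison: dict = field(default_factory=dict)
    n_per_arm: object = 200
    endpoint: int = 4
    crossover_fraction: float = 0.0
    dropout_rate: float = 0.15
    baseline_logit: float = math.log(0.3 / 0.7)
    baseline_sd: float = 0.3
    baseline_mean: float = 6.0
    baseline_mean_sd: float = 1.0
    within_sd: float = 2.5
    seed: int = 0
    studies: Optional[tuple] = None  # explicit StudySpec skeletons

    def __post_init__(self):
        ref = self.treatments[0]
        if self.true_d.get(ref, 0.0) != 0.0 or any(
            m.get(ref, 0.0) != 0.0 for m in self.true_d_by_endpoint.values()
        ):
            raise ValidationError("reference treatment must have true_d = 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValidationError("crossover_fraction must be in [0, 1]")
        lo = self.n_per_arm if isinstance(self.n_per_arm, int) else min(self.n_per_arm)
        if lo < 2:
            raise ValidationError("n_per_arm must be >= 2")

    def effect(self, name: str, ep_code: Optional[int] = None) -> float:
        if ep_code is not None and ep_code in self.true_d_by_endpoint:
            return float(self.true_d_by_endpoint[ep_code].get(name, 0.0))
        return float(self.true_d.get(name, 0.0))


@dataclass
class SimulatedNetwork:
    arms: list
    truth: dict
    #: realised trial-specific contrasts, keyed (study_id, endpoint code)
    thetas: dict = field(default_factory=dict)

    def save(self, arms_path, truth_path) -> None:
        write_arm_table(self.arms, arms_path)
        Path(truth_path).parent.mkdir(parents=True, exist_ok=True)
        Path(truth_path).write_text(json.dumps(self.truth, indent=2, default=str))


def _study_skeletons(scn: SimulationScenario, rng: np.random.Generator) -> list[StudySpec]:
    if scn.studies is not None:
        return list(scn.studies)
    tpc = scn.trials_per_comparison or {
        pair: 5
        for pair in [
            (scn.treatments[0], t) for t in scn.treatments[1:]
        ]
    }
    specs = []
    idx = 0
    for comp in sorted(tpc, key=lambda c: tuple(sorted(c))):
        k = tpc[comp]
        comp_t = tuple(sorted(comp))
        for _ in range(k):
            idx += 1
            if isinstance(scn.n_per_arm, int):
                ns = tuple([scn.n_per_arm] * len(comp_t))
            else:
                lo, hi = scn.n_per_arm
                ns = tuple(int(rng.integers(lo, hi + 1)) for _ in comp_t)
            design = "crossover" if rng.random() < scn.crossover_fraction else "parallel"
            specs.append(
                StudySpec(
                    study_id=f"SIM{idx:03d}",
                    design=design,
                    treatments=comp_t,
                    n_arms=ns,
                    endpoints=(scn.endpoint,),
                )
            )
    return specs


def _check_connected(specs: Sequence[StudySpec]) -> None:
    g = nx.Graph()
    for s in specs:
        ts = list(s.treatments)
        g.add_nodes_from(ts)
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                g.add_edge(ts[i], ts[j])
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValidationError("simulated comparison graph is disconnected")


def simulate_network(scn: SimulationScenario) -> SimulatedNetwork:
    """Draw one network of trials under the scenario's ground truth.

    Per study on comparison (a, b) the trial-specific contrast is
    theta ~ Normal(true_d_b - true_d_a + offset_ab, tau^2); multi-arm
    trials use the exchangeable construction with between-arm covariance
    tau^2 / 2.  Binary arms then draw events ~ Binomial(n, expit(baseline))
    and Binomial(n, expit(baseline + theta)); continuous arms draw observed
    means and sample standard deviations at the stated n.
    """
    rng = np.random.default_rng(scn.seed)
    specs = _study_skeletons(scn, rng)
    _check_connected(specs)

    arms: list[ArmRecord] = []
    thetas: dict = {}
    for spec in specs:
        for ep_code in spec.endpoints:
            ep = ENDPOINTS[int(ep_code)]
            ts = spec.treatments
            means = []
            for t in ts[1:]:
                m = scn.effect(t, ep.code) - scn.effect(ts[0], ep.code)
                if len(ts) == 2:
                    m += float(scn.inconsistency.get(frozenset(ts), 0.0))
                means.append(m)
            half = scn.tau / math.sqrt(2.0)
            shared = rng.normal(0.0, half) if len(ts) > 2 else 0.0
            theta = [
                m + shared + rng.normal(0.0, half if len(ts) > 2 else scn.tau)
                for m in means
            ]
            thetas[(spec.study_id, ep.code)] = theta

            if ep.is_binary:
                base = (
                    math.log(scn.dropout_rate / (1 - scn.dropout_rate))
                    if ep.code in (8, 9)
                    else scn.baseline_logit
                )
                b_i = rng.normal(base, scn.baseline_sd)
                etas = [b_i] + [b_i + th for th in theta]
                for t, n, eta in zip(ts, spec.n_arms, etas):
                    arms.append(
                        ArmRecord(
                            study_id=spec.study_id,
                            year=spec.year,
                            design=spec.design,
                            blinding=spec.blinding,
                            endpoint=ep,
                            treatment=resolve_treatment(t),
                            n=int(n),
                            events=int(rng.binomial(int(n), _expit(eta))),
                        )
                    )
            else:
                b_i = rng.normal(scn.baseline_mean, scn.baseline_mean_sd)
                mus = [b_i] + [b_i + th for th in theta]
                for t, n, mu_arm in zip(ts, spec.n_arms, mus):
                    n = int(n)
                    obs_mean = rng.normal(mu_arm, scn.within_sd / math.sqrt(n))
                    obs_sd = scn.within_sd * math.sqrt(
                        rng.chisquare(n - 1) / (n - 1)
                    )
                    arms.append(
                        ArmRecord(
                            study_id=spec.study_id,
                            year=spec.year,
                            design=spec.design,
                            blinding=spec.blinding,
                            endpoint=ep,
                            treatment=resolve_treatment(t),
                            n=n,
                            mean=float(obs_mean),
                            sd=float(max(obs_sd, 1e-6)),
                        )
                    )

    truth = {
        "true_d": {t: scn.effect(t) for t in scn.treatments},
        "true_d_by_endpoint": {
            int(c): dict(m) for c, m in scn.true_d_by_endpoint.items()
        },
        "tau": scn.tau,
        "inconsistency": {
            "/".join(sorted(k)): v for k, v in scn.inconsistency.items()
        },
        "seed": scn.seed,
        "endpoint": scn.endpoint,
        "n_studies": len(specs),
    }
    return SimulatedNetwork(arms=arms, truth=truth, thetas=thetas)


def make_evidence_base_scenario(
    seed: int = 0,
    true_d: Optional[dict] = None,
    tau: float = 0.1,
    true_d_by_endpoint: Optional[dict] = None,
) -> SimulationScenario:
    """Scenario reproducing the packaged evidence base's geometry.

    Thirty-two studies over seven interventions with the fixture's
    per-study sizes (split evenly across the two arms), designs, and
    per-study endpoint sets; true effects default to zero.
    """
    fixture = load_fixture()
    specs = []
    for m in fixture:
        t1, t2 = m.interventions
        n1 = m.size // 2
        n2 = m.size - n1
        specs.append(
            StudySpec(
                study_id=m.study_id,
                design=m.design,
                treatments=(t2.name, t1.name) if t2.name == "placebo" else (
                    (t1.name, t2.name)
                    if t1.name == "placebo"
                    else tuple(sorted((t1.name, t2.name)))
                ),
                n_arms=(n1, n2),
                endpoints=tuple(sorted(m.endpoints_measured)),
                year=m.year,
                blinding=m.blinding,
            )
        )
    names = tuple(
        t.name
        for t in sorted(
            {REFERENCE}
            | {x for m in fixture for x in m.interventions},
            key=lambda t: (t != REFERENCE, t.code),
        )
    )
    return SimulationScenario(
        treatments=names,
        true_d=dict(true_d or {}),
        true_d_by_endpoint=dict(true_d_by_endpoint or {}),
        tau=tau,
        seed=seed,
        studies=tuple(specs),
    )


def recovery_experiment(
    scenario: SimulationScenario,
    config: NMAConfig,
    replicates: int = 1,
    split: Optional[tuple] = None,
    alpha: float = 0.05,
) -> dict:
    """Repeated simulate-and-refit parameter-recovery study.

    Per replicate: simulate, fit the NMA, compare posterior medians and 95%
    credible intervals of each basic parameter with the scenario's truth;
    optionally run a node split on one comparison and track its rejection
    rate at ``alpha``.  Reports mean bias, RMSE, and CrI coverage pooled
    over treatments and replicates.
    """
    from .inconsistency import node_split

    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    errors, covered, rejections = [], [], []
    for rep in range(replicates):
        scn = replace(scenario, seed=(scenario.seed + 1000 * rep) & 0x7FFFFFFF)
        sim = simulate_network(scn)
        cfg = replace(config, seed=(config.seed + 7919 * rep) & 0x7FFFFFFF)
        post = fit_nma(sim.arms, scn.endpoint, cfg)
        ref = post.treatments[0]
        for t in post.treatments[1:]:
            truth = scn.effect(t.name, scn.endpoint) - scn.effect(ref.name, scn.endpoint)
            draws = post.contrast_draws(ref, t)
            med = float(np.median(draws))
            lo, hi = np.quantile(draws, [0.025, 0.975])
            errors.append(med - truth)
            covered.append(lo <= truth <= hi)
        if split is not None:
            res = node_split(sim.arms, scn.endpoint, split, cfg)
            rejections.append(res.p_value < alpha)
    errors = np.asarray(errors)
    report = {
        "replicates": replicates,
        "bias": float(errors.mean()),
        "rmse": float(np.sqrt((errors**2).mean())),
        "coverage": float(np.mean(covered)),
        "n_contrasts": int(errors.size),
    }
    if split is not None:
        report["nodesplit_rejection_rate"] = float(np.mean(rejections))
    return report


def nodesplit_calibration(
    scenario: SimulationScenario,
    comparison: tuple,
    config: NMAConfig,
    replicates: int,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the node-split test over simulated replicates.

    Under a consistent scenario this estimates the type-I error at
    ``alpha``; with an inconsistency offset injected on ``comparison`` it
    estimates power.  Also reports the mean direct-minus-indirect gap.
    """
    from .inconsistency import node_split

    rejections, gaps, pvals = [], [], []
    for rep in range(replicates):
        scn = replace(scenario, seed=(scenario.seed + 1000 * rep) & 0x7FFFFFFF)
        sim = simulate_network(scn)
        cfg = replace(config, seed=(config.seed + 7919 * rep) & 0x7FFFFFFF)
        res = node_split(sim.arms, scn.endpoint, comparison, cfg)
        rejections.append(res.p_value < alpha)
        gaps.append(res.difference["median"])
        pvals.append(res.p_value)
    return {
        "replicates": replicates,
        "rejection_rate": float(np.mean(rejections)),
        "mean_gap": float(np.mean(gaps)),
        "p_values": pvals,
    }
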