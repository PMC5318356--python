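"""Bayesian random-effects network meta-analysis fitted by MCMC.

Model (arm-based hierarchical consistency formulation):

* binary endpoints:      r_ik ~ Binomial(n_ik, p_ik),  logit(p_ik) = mu_i + delta_ik
* continuous endpoints:  ybar_ik ~ Normal(mu_i + delta_ik, sd_ik^2 / n_ik)

with delta_i,baseline = 0, and for the non-baseline arms of study i the
trial-specific effects delta_i are multivariate normal around the
consistency means d_{t_ik} - d_{t_i1} with variance tau^2 and between-arm
covariance tau^2/2 (the exchangeable multi-arm construction).  Priors are
vague normals on the basic parameters d and study baselines mu, and a
uniform prior on tau.

The sampler is Metropolis-within-Gibbs: per-study random-walk block
updates of (mu_i, delta_i) accepted independently across studies, an
exact multivariate-normal Gibbs draw of the basic parameters given the
trial effects (their full conditional is Gaussian), and an exact Gibbs
draw of tau^2 from its truncated inverse-gamma full conditional under the
uniform prior on tau.  Random-walk proposal scales adapt towards 20-40%
acceptance during burn-in and are frozen afterwards.  All chains advance
in lock-step through vectorised numpy operations; each chain consumes its
own seeded random stream, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .trial_data import (
    ArmRecord,
    Endpoint,
    EvidenceNetwork,
    REFERENCE,
    Treatment,
    ValidationError,
    build_network,
    endpoint as resolve_endpoint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NMAConfig",
    "PosteriorSet",
    "LeagueTable",
    "ConvergenceReport",
    "fit_nma",
    "relative_effect",
    "league_table",
    "convergence",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class NMAConfig:
    """Sampler and prior settings.

    ``iterations`` counts total per-chain sweeps including ``burnin``; the
    retained draw count is chains * (iterations - burnin) / thin.
    ``tau_prior_upper`` defaults to 5 on the log-odds scale and 10 on the
    mean-difference scale when left as None.
    """

    prior_d_sd: float = 100.0
    prior_mu_sd: float = 100.0
    tau_prior_upper: Optional[float] = None
    chains: int = 4
    iterations: int = 50_000
    burnin: int = 10_000
    thin: int = 10
    seed: int = 0
    reference: Treatment = REFERENCE
    chain_seeds: Optional[Sequence[int]] = None  # defaults to 0..chains-1
    adapt: bool = True
    init_scale: float = 0.5

    def __post_init__(self):
        if self.iterations <= self.burnin:
            raise ValidationError("iterations must exceed burnin")
        if self.chains < 2:
            raise ValidationError("at least 2 chains are required")
        if self.thin < 1 or self.prior_d_sd <= 0 or self.prior_mu_sd <= 0:
            raise ValidationError("invalid sampler configuration")

    def tau_upper(self, ep: Endpoint) -> float:
        if self.tau_prior_upper is not None:
            return self.tau_prior_upper
        return 5.0 if ep.is_binary else 10.0


@dataclass
class PosteriorSet:
    """Posterior draws with per-chain structure retained.

    ``d`` has shape (chains, draws, K-1) in ``treatments[1:]`` order (the
    reference is pinned at zero), ``mu`` (chains, draws, n_studies) and
    ``tau`` (chains, draws).  ``omega`` holds the direct-evidence parameter
    of a node-split refit when one was requested.
    """

    endpoint: Endpoint
    treatments: list[Treatment]  # reference first
    study_ids: list[str]
    d: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    config: NMAConfig
    converged: bool = True
    rhat: dict = field(default_factory=dict)
    omega: Optional[np.ndarray] = None
    split: Optional[tuple[Treatment, Treatment]] = None

    @property
    def n_draws(self) -> int:
        return self.d.shape[0] * self.d.shape[1]

    def d_draws(self, t: Treatment) -> np.ndarray:
        """Flattened draws of the basic parameter for ``t`` (0 for reference)."""
        if t == self.treatments[0]:
            return np.zeros(self.n_draws)
        try:
            j = self.treatments.index(t) - 1
        except ValueError:
            raise ValidationError(f"treatment {t.name} not in network") from None
        return self.d[:, :, j].reshape(-1)

    def contrast_draws(self, a: Treatment, b: Treatment) -> np.ndarray:
        """Draws of d_b - d_a (the b-versus-a contrast, additive scale)."""
        return self.d_draws(b) - self.d_draws(a)


@dataclass
class LeagueTable:
    """All pairwise contrasts in the row-versus-column convention.

    ``cells[(r, c)]`` is (median, lo, hi, significant) for the r-vs-c
    contrast, exponentiated on odds-ratio endpoints; the diagonal is the
    identity and opposite cells are draw-wise reciprocals/negations.
    """

    endpoint: Endpoint
    treatments: list[Treatment]
    cells: dict

    def to_rows(self) -> list[dict]:
        rows = []
        for (r, c), (med, lo, hi, sig) in sorted(
            self.cells.items(), key=lambda kv: (kv[0][0].code, kv[0][1].code)
        ):
            rows.append(
                {
                    "row": r.name,
                    "col": c.name,
                    "median": med,
                    "cr_low": lo,
                    "cr_high": hi,
                    "significant": sig,
                }
            )
        return rows


@dataclass
class ConvergenceReport:
    rhat: dict
    ess: dict

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def ok(self) -> bool:
        return self.max_rhat < 1.05


# ---------------------------------------------------------------------------
# data flattening


class _FlatNetwork:
    """Arm-level arrays grouped contiguously by study, baseline arm first."""

    def __init__(self, net: EvidenceNetwork, reference: Treatment,
                 split: Optional[tuple[Treatment, Treatment]] = None):
        self.endpoint = net.endpoint
        self.study_ids = sorted(net.studies)
        treats = sorted(net.treatments)
        if reference in net.treatments:
            treats.remove(reference)
            treats.insert(0, reference)
        self.treatments = treats
        tindex = {t: i for i, t in enumerate(treats)}

        soa, darm_pos, sod = [], [], []
        r, n, ybar, var = [], [], [], []
        arm_treat = []
        offs_arm, offs_darm = [], []
        arms_per_study = []
        split_studies = []
        pos = 0
        dpos = 0
        for i, sid in enumerate(self.study_ids):
            recs = net.studies[sid]
            offs_arm.append(pos)
            offs_darm.append(dpos)
            arms_per_study.append(len(recs))
            if split is not None and len(recs) == 2:
                pair = {recs[0].treatment, recs[1].treatment}
                if pair == set(split):
                    split_studies.append(i)
            for j, rec in enumerate(recs):
                soa.append(i)
                arm_treat.append(tindex[rec.treatment])
                if net.endpoint.is_binary:
                    r.append(rec.events)
                    n.append(rec.n)
                else:
                    ybar.append(rec.mean)
                    var.append(rec.sd**2 / rec.n)
                if j > 0:
                    darm_pos.append(pos)
                    sod.append(i)
                    dpos += 1
                pos += 1

        self.S = len(self.study_ids)
        self.A = pos
        self.D = dpos
        self.soa = np.array(soa)
        self.darm_pos = np.array(darm_pos)
        self.sod = np.array(sod)
        self.offs_arm = np.array(offs_arm)
        self.offs_darm = np.array(offs_darm)
        self.a_s = np.array(arms_per_study, dtype=float)  # arms per study
        self.m_s = self.a_s - 1.0  # deltas per study
        self.is_binary = net.endpoint.is_binary
        if self.is_binary:
            self.r = np.array(r, dtype=float)
            self.n = np.array(n, dtype=float)
        else:
            self.ybar = np.array(ybar, dtype=float)
            self.var = np.array(var, dtype=float)

        # design matrix mapping basic parameters (and the optional split
        # parameter omega) to the prior mean of each delta
        self.split_studies = split_studies
        P = len(treats) - 1 + (1 if split is not None else 0)
        self.P = P
        M = np.zeros((self.D, P))
        arm_treat = np.array(arm_treat)
        base_treat_of_study = arm_treat[self.offs_arm]
        for dd in range(self.D):
            i = self.sod[dd]
            t = arm_treat[self.darm_pos[dd]]
            b = base_treat_of_study[i]
            if split is not None and i in split_studies:
                # direct evidence gets its own parameter; orientation is
                # split[0] -> split[1]
                sign = 1.0 if treats[t] == split[1] else -1.0
                M[dd, P - 1] = sign
                continue
            if t > 0:
                M[dd, t - 1] += 1.0
            if b > 0:
                M[dd, b - 1] -= 1.0
        self.M = M

    def loglik(self, eta: np.ndarray, idx=None) -> np.ndarray:
        """Per-arm log-likelihood (constants dropped) at linear predictor eta."""
        if self.is_binary:
            r = self.r if idx is None else self.r[idx]
            n = self.n if idx is None else self.n[idx]
            return r * eta - n * np.logaddexp(0.0, eta)
        y = self.ybar if idx is None else self.ybar[idx]
        v = self.var if idx is None else self.var[idx]
        return -0.5 * (y - eta) ** 2 / v

    def init_values(self):
        """Crude per-study starting values from the observed data."""
        if self.is_binary:
            p = (self.r + 0.5) / (self.n + 1.0)
            obs = np.log(p / (1 - p))
        else:
            obs = self.ybar
        mu0 = obs[self.offs_arm]
        delta0 = obs[self.darm_pos] - mu0[self.sod]
        return mu0, delta0


# ---------------------------------------------------------------------------
# the sampler


def fit_nma(
    arms: Sequence[ArmRecord],
    ep,
    config: NMAConfig = NMAConfig(),
    split: Optional[tuple[Treatment, Treatment]] = None,
) -> PosteriorSet:
    """Fit the hierarchical NMA model and return posterior draws.

    ``split`` gives the named comparison its own direct-evidence parameter
    (node-splitting); the network estimate of that contrast then flows only
    through the indirect paths.  Non-convergence (any split-chain R-hat
    above 1.05 on the basic parameters or tau) sets ``converged=False``
    with a logged warning rather than raising.
    """
    arms = list(arms)
    if not arms:
        raise ValidationError("empty arm list")
    ep = resolve_endpoint(ep)
    net = build_network(arms, ep)
    flat = _FlatNetwork(net, config.reference, split=split)
    if split is not None and not flat.split_studies:
        raise ValidationError(
            f"no two-arm study directly compares {split[0].name} and {split[1].name}"
        )

    C = config.chains
    S, A, D, P = flat.S, flat.A, flat.D, flat.P
    tau_hi = config.tau_upper(ep)
    chain_seeds = (
        list(config.chain_seeds)
        if config.chain_seeds is not None
        else list(range(C))
    )
    if len(chain_seeds) != C:
        raise ValidationError("chain_seeds length must equal chains")
    rngs = [np.random.default_rng([int(config.seed) & 0x7FFFFFFF, int(cs)]) for cs in chain_seeds]

    # state
    mu0, delta0 = flat.init_values()
    mu = np.tile(mu0, (C, 1))
    delta = np.tile(delta0, (C, 1))
    theta = np.zeros((C, P))
    tau = np.full(C, min(0.5, tau_hi / 2.0))
    for c, rng in enumerate(rngs):
        mu[c] += 0.1 * rng.standard_normal(S)
        delta[c] += 0.1 * rng.standard_normal(D)
        theta[c] = 0.1 * rng.standard_normal(P)
        tau[c] = min(0.5, tau_hi / 2.0) * (0.5 + rng.random())

    s_mu = np.full((C, S), config.init_scale)
    s_del = np.full((C, S), config.init_scale)
    s_tau = np.full(C, config.init_scale / 2.0)

    delta_full = np.zeros((C, A))
    delta_full[:, flat.darm_pos] = delta
    ll_arm = flat.loglik(mu[:, flat.soa] + delta_full)
    m = theta @ flat.M.T  # (C, D) prior means of delta

    inv_mu_var = 1.0 / config.prior_mu_sd**2
    inv_d_var = 1.0 / config.prior_d_sd**2

    # constant pieces of the Gaussian full conditional of theta:
    # M' Sigma^-1 M = (2/tau^2) (M'M - sum_s c_s c_s' / a_s) with c_s the
    # per-study column sums of M (from Sigma_s^-1 = (2/tau^2)(I - J/a_s))
    C_mat = np.add.reduceat(flat.M, flat.offs_darm, axis=0)  # (S, P)
    MtM_c = flat.M.T @ flat.M - (C_mat / flat.a_s[:, None]).T @ C_mat
    eyeP = np.eye(P)

    from scipy.special import gammaincc, gammainccinv

    ig_shape = (D - 1) / 2.0  # uniform prior on tau over (0, tau_hi)
    use_gibbs_tau = ig_shape > 0.05

    n_keep = (config.iterations - config.burnin) // config.thin
    d_store = np.empty((C, n_keep, P))
    mu_store = np.empty((C, n_keep, S))
    tau_store = np.empty((C, n_keep))

    adapt_every = 50
    target = 0.3
    acc_mu = np.zeros((C, S))
    acc_del = np.zeros((C, S))
    acc_tau = np.zeros(C)
    s_tnc = np.full(C, 0.3)  # log-scale step of the interweaved tau move
    acc_tnc = np.zeros(C)

    block = 250
    kept = 0
    it = 0
    sod, soa, darm_pos = flat.sod, flat.soa, flat.darm_pos
    while it < config.iterations:
        nb = min(block, config.iterations - it)
        # per-chain random streams, pre-generated per block
        zs = np.stack([rng.standard_normal((nb, S + D + P + 1)) for rng in rngs])
        us = np.stack([rng.random((nb, 2 * S + 2)) for rng in rngs])
        lus = np.log(us)
        for b in range(nb):
            z = zs[:, b]
            lu = lus[:, b]

            # -- study baselines mu (independent per study)
            mu_prop = mu + s_mu * z[:, :S]
            ll_prop = flat.loglik(mu_prop[:, soa] + delta_full)
            d_ll = np.add.reduceat(ll_prop - ll_arm, flat.offs_arm, axis=1)
            d_pr = 0.5 * inv_mu_var * (mu**2 - mu_prop**2)
            acc = lu[:, :S] < d_ll + d_pr
            mu = np.where(acc, mu_prop, mu)
            acc_arm = acc[:, soa]
            ll_arm = np.where(acc_arm, ll_prop, ll_arm)
            acc_mu += acc

            # -- trial effects delta (block per study, independent across studies)
            delta_prop = delta + s_del[:, sod] * z[:, S : S + D]
            eta_d = mu[:, soa[darm_pos]] + delta_prop
            ll_d_prop = flat.loglik(eta_d, idx=darm_pos)
            ll_d_old = ll_arm[:, darm_pos]
            d_ll = np.add.reduceat(ll_d_prop - ll_d_old, flat.offs_darm, axis=1)
            e_o = delta - m
            e_p = delta_prop - m
            t2 = tau[:, None] ** 2
            q_o = np.add.reduceat(e_o * e_o, flat.offs_darm, axis=1) - (
                np.add.reduceat(e_o, flat.offs_darm, axis=1) ** 2 / flat.a_s
            )
            q_p = np.add.reduceat(e_p * e_p, flat.offs_darm, axis=1) - (
                np.add.reduceat(e_p, flat.offs_darm, axis=1) ** 2 / flat.a_s
            )
            d_pr = (q_o - q_p) / t2
            acc = lu[:, S : 2 * S] < d_ll + d_pr
            acc_d = acc[:, sod]
            delta = np.where(acc_d, delta_prop, delta)
            ll_arm[:, darm_pos] = np.where(acc_d, ll_d_prop, ll_d_old)
            delta_full[:, darm_pos] = delta
            acc_del += acc

            # -- basic parameters: exact Gaussian full-conditional draw
            two_over_t2 = 2.0 / tau**2
            prec = two_over_t2[:, None, None] * MtM_c + inv_d_var * eyeP
            dsums = np.add.reduceat(delta, flat.offs_darm, axis=1)  # (C, S)
            bvec = two_over_t2[:, None] * (
                delta @ flat.M - (dsums / flat.a_s) @ C_mat
            )
            mean = np.linalg.solve(prec, bvec[:, :, None])[:, :, 0]
            L = np.linalg.cholesky(prec)
            noise = np.linalg.solve(
                np.transpose(L, (0, 2, 1)), z[:, S + D : S + D + P, None]
            )[:, :, 0]
            theta = mean + noise
            m = theta @ flat.M.T

            # -- heterogeneity tau
            if use_gibbs_tau:
                # tau^2 | delta ~ truncated InvGamma((D-1)/2, G)
                e = delta - m
                G = np.sum(
                    np.add.reduceat(e * e, flat.offs_darm, axis=1)
                    - np.add.reduceat(e, flat.offs_darm, axis=1) ** 2 / flat.a_s,
                    axis=1,
                )
                G = np.maximum(G, 1e-12)
                # F(x) = gammaincc(shape, G / x); invert on (0, tau_hi^2)
                hi_cdf = gammaincc(ig_shape, G / tau_hi**2)
                zq = gammainccinv(
                    ig_shape, np.maximum(us[:, b, 2 * S] * hi_cdf, 1e-300)
                )
                x = G / np.maximum(zq, 1e-300)
                tau = np.sqrt(np.clip(x, 1e-10, tau_hi**2))

                # interweaved (non-centered) tau move: rescale all residuals
                # delta = m + tau * eps jointly with tau, which decouples tau
                # from the random-walk speed of delta (funnel escape)
                eps = (delta - m) / tau[:, None]
                tau_nc = tau * np.exp(s_tnc * z[:, S + D + P])
                ok = tau_nc < tau_hi
                delta_nc = m + tau_nc[:, None] * eps
                eta_nc = mu[:, soa[darm_pos]] + delta_nc
                ll_nc = flat.loglik(eta_nc, idx=darm_pos)
                d_ll = np.sum(ll_nc - ll_arm[:, darm_pos], axis=1)
                # log-normal proposal Hastings correction: + log(tau'/tau)
                accept = ok & (lu[:, 2 * S + 1] < d_ll + np.log(tau_nc / tau))
                tau = np.where(accept, tau_nc, tau)
                accD = accept[:, None]
                delta = np.where(accD, delta_nc, delta)
                ll_arm[:, darm_pos] = np.where(accD, ll_nc, ll_arm[:, darm_pos])
                delta_full[:, darm_pos] = delta
                acc_tnc += accept
            else:
                # too few trial effects for the conjugate draw: random walk
                e = delta - m
                q_of = lambda tv: np.sum(  # noqa: E731
                    (2.0 / tv[:, None] ** 2)
                    * (
                        np.add.reduceat(e * e, flat.offs_darm, axis=1)
                        - np.add.reduceat(e, flat.offs_darm, axis=1) ** 2 / flat.a_s
                    )
                    + flat.m_s * np.log(tv[:, None] ** 2 / 2.0),
                    axis=1,
                )
                tau_prop = tau + s_tau * z[:, S + D + P]
                ok = (tau_prop > 0.0) & (tau_prop < tau_hi)
                safe = np.where(ok, tau_prop, tau)
                accept = ok & (lu[:, 2 * S] < -0.5 * (q_of(safe) - q_of(tau)))
                tau = np.where(accept, tau_prop, tau)
                acc_tau += accept

            it += 1
            if config.adapt and it <= config.burnin and it % adapt_every == 0:
                for scale, count in (
                    (s_mu, acc_mu),
                    (s_del, acc_del),
                    (s_tau, acc_tau),
                    (s_tnc, acc_tnc),
                ):
                    rate = count / adapt_every
                    np.multiply(scale, np.exp(rate - target), out=scale)
                    np.clip(scale, 1e-4, 50.0, out=scale)
                    count[...] = 0.0
            if it > config.burnin and (it - config.burnin) % config.thin == 0:
                d_store[:, kept] = theta
                mu_store[:, kept] = mu
                tau_store[:, kept] = tau
                kept += 1

    omega = None
    d_basic = d_store
    if split is not None:
        omega = d_store[:, :, P - 1]
        d_basic = d_store[:, :, : P - 1]

    post = PosteriorSet(
        endpoint=ep,
        treatments=flat.treatments,
        study_ids=flat.study_ids,
        d=d_basic,
        mu=mu_store,
        tau=tau_store,
        config=config,
        omega=omega,
        split=split,
    )
    post.rhat = _rhat_all(post)
    post.converged = all(v < 1.05 for v in post.rhat.values())
    if not post.converged:
        logger.warning(
            "NMA for %s did not converge: max R-hat = %.3f",
            ep.name,
            max(post.rhat.values()),
        )
    return post


def _rhat_all(post: PosteriorSet) -> dict:
    import arviz as az

    out = {}
    for j, t in enumerate(post.treatments[1:]):
        out[f"d_{t.name}"] = float(az.rhat(post.d[:, :, j]))
    out["tau"] = float(az.rhat(post.tau))
    if post.omega is not None:
        out["omega"] = float(az.rhat(post.omega))
    return out


def convergence(post: PosteriorSet) -> ConvergenceReport:
    """Split-chain R-hat and effective sample size for each d_k and tau."""
    import arviz as az

    if post.d.shape[0] < 2:
        raise ValidationError("convergence diagnostics require at least 2 chains")
    rhat, ess = {}, {}
    for j, t in enumerate(post.treatments[1:]):
        arr = post.d[:, :, j]
        rhat[f"d_{t.name}"] = float(az.rhat(arr))
        ess[f"d_{t.name}"] = float(az.ess(arr))
    rhat["tau"] = float(az.rhat(post.tau))
    ess["tau"] = float(az.ess(post.tau))
    return ConvergenceReport(rhat=rhat, ess=ess)


# ---------------------------------------------------------------------------
# posterior summaries


def _summary(draws: np.ndarray, exponentiate: bool) -> tuple[float, float, float]:
    med, lo, hi = np.quantile(draws, [0.5, 0.025, 0.975])
    if exponentiate:
        return float(np.exp(med)), float(np.exp(lo)), float(np.exp(hi))
    return float(med), float(lo), float(hi)


def relative_effect(post: PosteriorSet, a: Treatment, b: Treatment) -> dict:
    """Posterior median and 95% credible interval of the b-versus-a contrast.

    Odds-ratio endpoints are exponentiated; mean differences stay raw.
    """
    draws = post.contrast_draws(a, b)
    med, lo, hi = _summary(draws, post.endpoint.is_binary)
    return {"comparison": (a, b), "median": med, "cr_low": lo, "cr_high": hi}


def league_table(post: PosteriorSet) -> LeagueTable:
    """Square table of all pairwise contrasts (row versus column)."""
    exp = post.endpoint.is_binary
    null = 1.0 if exp else 0.0
    cells = {}
    for r in post.treatments:
        for c in post.treatments:
            if r == c:
                cells[(r, c)] = (null, null, null, False)
                continue
            med, lo, hi = _summary(post.contrast_draws(c, r), exp)
            sig = lo > null or hi < null
            cells[(r, c)] = (med, lo, hi, sig)
    return LeagueTable(endpoint=post.endpoint, treatments=post.treatments, cells=cells)
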