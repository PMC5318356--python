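"""Study-level effects and DerSimonian-Laird random-effects pooling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from migranet import SimulationScenario, pairwise_table, pool_dl, simulate_network
from migranet.pairwise import (
    DegenerateTableError,
    EffectEstimate,
    study_effect_binary,
    study_effect_continuous,
)
from migranet.trial_data import ValidationError, treatment
from conftest import make_arm


def _pair(ref_events, alt_events, n=20, ep=4):
    ref = make_arm("S1", "placebo", ep=ep, n=n, events=ref_events)
    alt = make_arm("S1", "topiramate", ep=ep, n=n, events=alt_events)
    return ref, alt


class TestBinaryEffect:
    def test_identical_arms_give_null_log_or(self):
        e = study_effect_binary(*_pair(10, 10))
        assert e.effect == pytest.approx(0.0)
        assert e.se == pytest.approx(math.sqrt(0.4))

    def test_hand_computed_2x2(self):
        e = study_effect_binary(*_pair(5, 15))
        assert e.effect == pytest.approx(math.log(9), abs=1e-12)
        assert e.se == pytest.approx(math.sqrt(1 / 15 + 1 / 5 + 1 / 5 + 1 / 15))

    def test_continuity_correction_on_zero_cell(self):
        ref = make_arm("S1", "placebo", n=10, events=5)
        alt = make_arm("S1", "topiramate", n=10, events=0)
        e = study_effect_binary(ref, alt)
        assert e.effect == pytest.approx(math.log(0.5 * 5.5 / (10.5 * 5.5)), abs=1e-9)
        assert e.se == pytest.approx(
            math.sqrt(1 / 0.5 + 1 / 10.5 + 1 / 5.5 + 1 / 5.5), abs=1e-9
        )

    def test_degenerate_table(self):
        ref = make_arm("S1", "placebo", n=10, events=0)
        alt = make_arm("S1", "topiramate", n=10, events=0)
        with pytest.raises(DegenerateTableError):
            study_effect_binary(ref, alt, correction=0.0)

    def test_different_studies_rejected(self):
        ref = make_arm("S1", "placebo", events=5)
        alt = make_arm("S2", "topiramate", events=5)
        with pytest.raises(ValidationError):
            study_effect_binary(ref, alt)


class TestContinuousEffect:
    def test_identical_arms(self):
        ref = make_arm("S1", "placebo", ep=1, n=50, mean=5.0, sd=2.0)
        alt = make_arm("S1", "topiramate", ep=1, n=50, mean=5.0, sd=2.0)
        e = study_effect_continuous(ref, alt)
        assert e.effect == 0.0
        assert e.se == pytest.approx(0.4)

    def test_hand_computed_md_and_antisymmetry(self):
        ref = make_arm("S1", "placebo", ep=1, n=36, mean=6.0, sd=3.0)
        alt = make_arm("S1", "topiramate", ep=1, n=36, mean=4.0, sd=3.0)
        e = study_effect_continuous(ref, alt)
        assert e.effect == pytest.approx(-2.0)
        assert e.se == pytest.approx(math.sqrt(0.5))
        flipped = study_effect_continuous(alt, ref)
        assert flipped.effect == pytest.approx(2.0)

    def test_crossover_rho_shrinks_se(self):
        ref = make_arm("S1", "placebo", ep=1, n=36, mean=6.0, sd=3.0, design="crossover")
        alt = make_arm("S1", "topiramate", ep=1, n=36, mean=4.0, sd=3.0, design="crossover")
        plain = study_effect_continuous(ref, alt)
        shrunk = study_effect_continuous(ref, alt, crossover_rho=0.5)
        assert shrunk.se == pytest.approx(plain.se * math.sqrt(0.5))


def _eff(y, se, comp=None, sid="S", scale="logOR"):
    comp = comp or (treatment("A"), treatment("B"))
    return EffectEstimate(study_id=sid, comparison=comp, effect=y, se=se, scale=scale)


class TestPoolDL:
    def test_homogeneous_duplicates(self):
        res = pool_dl([_eff(0.5, 0.2, sid="a"), _eff(0.5, 0.2, sid="b")])
        assert res.Q == pytest.approx(0.0)
        assert res.tau2 == 0.0
        assert res.pooled == pytest.approx(0.5)
        assert (res.ci_high - res.pooled) == pytest.approx(1.96 * 0.2 / math.sqrt(2), rel=1e-3)

    def test_single_study_passthrough(self):
        res = pool_dl([_eff(1.0, 0.3)])
        assert res.pooled == pytest.approx(1.0)
        assert res.tau2 == 0.0 and res.Q == 0.0
        assert res.ci_low == pytest.approx(0.412, abs=5e-4)
        assert res.ci_high == pytest.approx(1.588, abs=5e-4)

    def test_hand_computed_dl(self):
        """y=(0,1), se=(0.2,0.2): w=25, Q=12.5, C=25, tau2=0.46, w*=2."""
        res = pool_dl([_eff(0.0, 0.2, sid="a"), _eff(1.0, 0.2, sid="b")])
        assert res.Q == pytest.approx(12.5)
        assert res.tau2 == pytest.approx(0.46)
        assert res.pooled == pytest.approx(0.5)
        assert res.I2 == pytest.approx(92.0)
        assert (res.ci_high - res.pooled) == pytest.approx(1.96 * 0.5, rel=1e-3)

    def test_errors(self):
        with pytest.raises(ValidationError):
            pool_dl([])
        with pytest.raises(ValidationError):
            pool_dl([_eff(0, 0.2), _eff(0, 0.2, scale="MD")])

    def test_fixed_effect_reduction_when_tau_zero(self):
        """Homogeneous y -> DL equals an independent fixed-effect computation."""
        effs = [_eff(0.30, 0.25, sid="a"), _eff(0.32, 0.30, sid="b"),
                _eff(0.29, 0.20, sid="c")]
        res = pool_dl(effs)
        assert res.tau2 == 0.0
        w = np.array([1 / e.se**2 for e in effs])
        y = np.array([e.effect for e in effs])
        assert res.pooled == pytest.approx(float(np.sum(w * y) / np.sum(w)))

    @given(
        ys=st.lists(st.floats(-3, 3), min_size=1, max_size=8),
        ses=st.lists(st.floats(0.05, 2.0), min_size=8, max_size=8),
    )
    def test_pooled_is_convex_combination(self, ys, ses):
        effs = [_eff(y, s, sid=f"s{i}") for i, (y, s) in enumerate(zip(ys, ses))]
        res = pool_dl(effs)
        assert min(ys) - 1e-9 <= res.pooled <= max(ys) + 1e-9
        assert res.ci_low <= res.pooled <= res.ci_high
        assert 0 <= res.I2 <= 100

    def test_reversed_comparison_negates(self):
        effs = [_eff(0.4, 0.2, sid="a"), _eff(0.9, 0.3, sid="b")]
        rev = [
            _eff(-e.effect, e.se, comp=(e.comparison[1], e.comparison[0]), sid=e.study_id)
            for e in effs
        ]
        a, b = pool_dl(effs), pool_dl(rev)
        assert b.pooled == pytest.approx(-a.pooled)
        assert b.ci_low == pytest.approx(-a.ci_high)
        assert b.ci_high == pytest.approx(-a.ci_low)
        assert b.Q == pytest.approx(a.Q) and b.tau2 == pytest.approx(a.tau2)


def test_null_simulation_pooled_near_zero():
    """No true effects, no heterogeneity, big trials: every pooled |MD|,|logOR| small."""
    scn = SimulationScenario(
        trials_per_comparison={("placebo", "topiramate"): 10,
                               ("placebo", "propranolol"): 10},
        n_per_arm=1000, endpoint=4, tau=0.0, seed=7,
    )
    sim = simulate_network(scn)
    for res in pairwise_table(sim.arms, 4):
        assert abs(res.pooled) < 0.15


def test_pairwise_table_shapes(triangle_sim):
    rows = pairwise_table(triangle_sim.arms, 4)
    assert len(rows) == 3
    assert all(r.k == 10 for r in rows)


def test_ci_coverage_under_homogeneous_truth():
    """95% CI coverage of a true MD stays near nominal over replicates."""
    rng = np.random.default_rng(42)
    theta, k, n, sd = 0.4, 50, 500, 2.0
    hits = 0
    reps = 500
    for _ in range(reps):
        m_ref = rng.normal(0.0, sd / math.sqrt(n), k)
        m_alt = rng.normal(theta, sd / math.sqrt(n), k)
        sds = sd * np.sqrt(rng.chisquare(n - 1, (2, k)) / (n - 1))
        effs = [
            _eff(m_alt[i] - m_ref[i],
                 math.sqrt(sds[0, i] ** 2 / n + sds[1, i] ** 2 / n),
                 sid=f"s{i}", scale="MD")
            for i in range(k)
        ]
        res = pool_dl(effs)
        hits += res.ci_low <= theta <= res.ci_high
    assert 0.91 <= hits / reps <= 0.99
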