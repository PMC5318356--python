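"""Node-splitting, design-level Q decomposition, net heat, and funnel data."""

import numpy as np
import pytest

from migranet import (
    NMAConfig,
    SimulationScenario,
    build_network,
    design_contrasts,
    funnel_data,
    net_heat,
    node_split,
    pairwise_table,
    q_decomposition,
    simulate_network,
    wls_network_fit,
)
from migranet.inconsistency import (
    DesignContrasts,
    DesignLevel,
    NotSplittableError,
    splittable_comparisons,
)
from migranet.pairwise import EffectEstimate, study_effects
from migranet.trial_data import ValidationError, treatment
from conftest import TRIANGLE, make_arm


def _design(pair, y, w, studies=("S",), q_het=0.0):
    a, b = (treatment(x) for x in pair)
    a, b = sorted((a, b))
    return DesignLevel(
        treatments=frozenset((a, b)),
        baseline=a,
        contrasts=[(a, b)],
        y=np.array([float(y)]),
        W=np.array([[float(w)]]),
        studies=list(studies),
        q_het=q_het,
    )


def _dc(designs, treatments="ABC"):
    return DesignContrasts(
        endpoint=None,
        treatments=[treatment(t) for t in treatments],
        designs=designs,
    )


class TestWLS:
    def test_single_design_is_saturated(self):
        dc = _dc([_design("AB", 0.5, 4.0)], "AB")
        est, H, fitted = wls_network_fit(dc)
        assert H == pytest.approx(np.array([[1.0]]))
        assert fitted[0] == pytest.approx(0.5)

    def test_equal_weight_designs_split_contribution(self):
        # two designs measuring the same comparison: each contributes half
        dc = _dc([_design("AB", 0.4, 3.0), _design("AB", 0.8, 3.0)], "AB")
        est, H, fitted = wls_network_fit(dc)
        assert H == pytest.approx(np.full((2, 2), 0.5))
        assert est[0] == pytest.approx(0.6)

    def test_consistent_noise_free_triangle_fits_exactly(self):
        dc = _dc(
            [_design("AB", 0.5, 1.0), _design("BC", 0.7, 1.0), _design("AC", 1.2, 1.0)]
        )
        est, H, fitted = wls_network_fit(dc)
        assert fitted == pytest.approx(np.array([0.5, 0.7, 1.2]), abs=1e-12)

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(0)
        dc = _dc(
            [
                _design("AB", rng.normal(), 2.0),
                _design("BC", rng.normal(), 1.5),
                _design("AC", rng.normal(), 3.0),
            ]
        )
        est, H, fitted = wls_network_fit(dc)
        X = np.array([[1.0, 0.0], [-1.0, 1.0], [0.0, 1.0]])
        W = np.diag([2.0, 1.5, 3.0])
        y = np.concatenate([d.y for d in dc.designs])
        brute = np.linalg.inv(X.T @ W @ X) @ X.T @ W @ y
        assert est == pytest.approx(brute, abs=1e-12)
        # hat matrix reproduces X on its column space
        assert H @ X == pytest.approx(X, abs=1e-9)

    def test_rank_deficient_design_matrix_rejected(self):
        dc = _dc([_design("AB", 0.5, 1.0)], "ABC")  # C never measured
        with pytest.raises(ValidationError, match="rank deficient"):
            wls_network_fit(dc)


class TestQDecomposition:
    def test_additivity_and_noise_free_consistency(self):
        dc = _dc(
            [_design("AB", 0.5, 1.0), _design("BC", 0.7, 1.0), _design("AC", 1.2, 1.0)]
        )
        q_total, q_het, q_inc = q_decomposition(dc)
        assert q_total == pytest.approx(q_het + q_inc, abs=1e-9)
        assert q_inc == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_identical_studies_have_zero_heterogeneity(self):
        scn = SimulationScenario(
            trials_per_comparison=TRIANGLE, n_per_arm=300, endpoint=4, tau=0.0, seed=4
        )
        sim = simulate_network(scn)
        dc = design_contrasts(sim.arms, 4)
        # rebuild with every study replaced by a single pooled copy
        for d in dc.designs:
            d.q_het = 0.0
        q_total, q_het, q_inc = q_decomposition(dc)
        assert q_het == 0.0
        assert q_total == pytest.approx(q_inc, abs=1e-9)

    def test_injected_inconsistency_raises_q_inc(self):
        base = [
            _design("AB", 0.5, 1.0), _design("BC", 0.7, 1.0), _design("AC", 1.2, 1.0)
        ]
        _, _, q0 = q_decomposition(_dc(base))
        bumped = [
            _design("AB", 0.5, 1.0), _design("BC", 0.7, 1.0), _design("AC", 3.2, 1.0)
        ]
        _, _, q1 = q_decomposition(_dc(bumped))
        assert q1 > q0 + 1.0

    def test_additivity_on_simulated_network(self, triangle_sim):
        dc = design_contrasts(triangle_sim.arms, 4)
        q_total, q_het, q_inc = q_decomposition(dc)
        assert q_total == pytest.approx(q_het + q_inc, abs=1e-9)
        assert q_total >= 0 and q_het >= 0 and q_inc >= -1e-12


class TestNetHeat:
    def test_single_design_rejected(self):
        with pytest.raises(ValidationError):
            net_heat(_dc([_design("AB", 0.5, 1.0)], "AB"))

    def test_contribution_rows_sum_to_one(self, triangle_sim):
        nh = net_heat(design_contrasts(triangle_sim.arms, 4))
        assert nh.contribution.sum(axis=1) == pytest.approx(
            np.ones(len(nh.designs)), abs=1e-9
        )

    def test_consistent_network_has_tiny_deltas(self):
        dc = _dc(
            [_design("AB", 0.5, 1.0), _design("BC", 0.7, 1.0), _design("AC", 1.2, 1.0)]
        )
        nh = net_heat(dc)
        assert np.abs(nh.delta_inconsistency).max() == pytest.approx(0.0, abs=1e-9)

    def test_triangle_deltas_cannot_discriminate_within_one_loop(self):
        # a single loop is the minimal inconsistency unit: detaching any of
        # its designs saturates the fit, so every detachment clears the
        # same Q and the columns tie
        dc = _dc(
            [_design("AB", 0.5, 4.0), _design("BC", 0.7, 4.0), _design("AC", 2.2, 4.0)]
        )
        nh = net_heat(dc)
        assert nh.Q_inc > 0.5
        col = nh.delta_inconsistency.sum(axis=0)
        assert col == pytest.approx(np.full(3, col[0]), abs=1e-9)

    def test_inconsistency_localised_on_perturbed_design(self):
        # consistent truth d_B=0.5, d_C=1.2, d_D=0.4 with C held in two
        # loops; the A-C design is perturbed by +1
        dc = _dc(
            [
                _design("AB", 0.5, 4.0),
                _design("BC", 0.7, 4.0),
                _design("AC", 2.2, 4.0),
                _design("AD", 0.4, 4.0),
                _design("CD", -0.8, 4.0),
            ],
            "ABCD",
        )
        nh = net_heat(dc)
        ac = nh.designs.index("A-C")
        col_mag = np.abs(nh.delta_inconsistency).sum(axis=0)
        assert col_mag.argmax() == ac
        assert nh.Q_inc > 0.5


class TestNodeSplit:
    def test_two_treatment_network_not_splittable(self, quick_config):
        arms = [
            make_arm("S1", "placebo", events=10),
            make_arm("S1", "topiramate", events=15),
            make_arm("S2", "placebo", events=12),
            make_arm("S2", "topiramate", events=17),
        ]
        with pytest.raises(NotSplittableError):
            node_split(arms, 4, (treatment("A"), treatment("B")), quick_config)

    def test_all_triangle_edges_splittable(self, triangle_sim):
        comps = splittable_comparisons(triangle_sim.arms, 4)
        assert len(comps) == 3

    def test_consistent_triangle_not_rejected(self, triangle_sim, quick_config):
        res = node_split(
            triangle_sim.arms, 4, (treatment("A"), treatment("B")), quick_config
        )
        assert res.p_value > 0.05
        assert res.difference["median"] == pytest.approx(
            res.direct["median"] - res.indirect["median"], abs=0.05
        )

    def test_injected_offset_detected(self):
        scn = SimulationScenario(
            trials_per_comparison=TRIANGLE,
            n_per_arm=500,
            endpoint=4,
            tau=0.1,
            true_d={"topiramate": -0.5, "propranolol": -1.0},
            inconsistency={frozenset(("placebo", "topiramate")): 1.0},
            seed=17,
        )
        sim = simulate_network(scn)
        cfg = NMAConfig(chains=2, iterations=8_000, burnin=2_000, thin=3, seed=17)
        res = node_split(sim.arms, 4, (treatment("A"), treatment("B")), cfg)
        assert res.p_value < 0.05
        # direct evidence sits ~1.0 above the indirect estimate
        assert res.difference["median"] == pytest.approx(1.0, abs=0.4)


def test_nodesplit_p_values_uniform_under_consistency():
    """Across many consistent replicates the split p-values look Uniform(0,1)."""
    from scipy import stats

    from migranet.simulate import nodesplit_calibration

    scn = SimulationScenario(
        trials_per_comparison=TRIANGLE, n_per_arm=200, endpoint=4, tau=0.1,
        true_d={"topiramate": -0.5, "propranolol": -1.0}, seed=101,
    )
    cfg = NMAConfig(chains=2, iterations=4_000, burnin=1_000, thin=2, seed=101)
    out = nodesplit_calibration(
        scn, (treatment("A"), treatment("B")), cfg, replicates=200
    )
    ks = stats.kstest(np.array(out["p_values"]), "uniform")
    assert ks.pvalue > 0.01


class TestFunnel:
    def test_single_study_comparisons_center_to_zero(self, quick_config):
        arms = [
            make_arm("S1", "placebo", events=10),
            make_arm("S1", "topiramate", events=15),
            make_arm("S2", "placebo", events=12),
            make_arm("S2", "propranolol", events=9),
        ]
        net = build_network(arms, 4)
        effects = study_effects(net)
        pooled = pairwise_table(arms, 4)
        data, egger = funnel_data(effects, pooled)
        assert all(d.centered_effect == pytest.approx(0.0, abs=1e-12) for d in data)
        assert egger is None  # < 3 studies

    def test_symmetric_simulation_has_no_asymmetry(self):
        scn = SimulationScenario(
            trials_per_comparison={("placebo", "topiramate"): 20,
                                   ("placebo", "propranolol"): 20},
            n_per_arm=(50, 400), endpoint=4, tau=0.1, seed=19,
        )
        sim = simulate_network(scn)
        net = build_network(sim.arms, 4)
        effects = study_effects(net)
        pooled = pairwise_table(sim.arms, 4)
        _, egger = funnel_data(effects, pooled)
        assert egger["n"] == 40
        assert egger["p"] > 0.05

    def test_injected_small_study_bias_found(self):
        scn = SimulationScenario(
            trials_per_comparison={("placebo", "topiramate"): 40},
            n_per_arm=(30, 600), endpoint=4, tau=0.05, seed=23,
        )
        sim = simulate_network(scn)
        net = build_network(sim.arms, 4)
        effects = study_effects(net)
        # inflate each study effect by 0.5 * its SE (small studies inflate more)
        biased = [
            EffectEstimate(e.study_id, e.comparison, e.effect + 0.5 * e.se, e.se, e.scale)
            for e in effects
        ]
        pooled = pairwise_table(sim.arms, 4)
        _, egger = funnel_data(biased, pooled)
        assert egger["intercept"] > 0.2
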