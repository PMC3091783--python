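import itertools
import math

import numpy as np
import pytest

from dister import (
    DisTerModel,
    SimulationConfig,
    classify,
    estimate_prior_geometric,
    fit,
    posterior_stu,
    simulate_genome,
    training_pairs,
)
from dister.pairs import SAME_STRAND, AdjacentPair


def make_pair(bin_, term=False, conf=None, label="unlabeled"):
    return AdjacentPair(
        upstream="u",
        downstream="d",
        orientation=SAME_STRAND,
        distance=bin_ * 10,
        terminator_present=term,
        terminator_score_class=(
            "absent" if not term else ("low" if conf is None else
                                       ("low" if conf < 76 else "mid" if conf <= 90 else "high"))
        ),
        terminator_confidence=conf if term else None,
        label=label,
    )


@pytest.fixture
def eight_pair_set():
    """4 STU pairs at (bin 1, no terminator), 4 DTU pairs at (bin 1, terminator)."""
    return [make_pair(1, False, label="STU") for _ in range(4)] + [
        make_pair(1, True, conf=80.0, label="DTU") for _ in range(4)
    ]


class TestGeometricPrior:
    def test_paper_operating_point(self):
        # mean TU length ~2.13 genes gives prior 0.53
        assert round(estimate_prior_geometric(1 / (1 - 0.53)), 2) == 0.53

    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 0.53, 0.9])
    def test_inverse_relation_exact(self, p):
        assert estimate_prior_geometric(1.0 / (1.0 - p)) == pytest.approx(p, abs=1e-12)

    def test_monocistronic_boundary(self):
        assert estimate_prior_geometric(1.0) == 0.0

    def test_mean_below_one_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior_geometric(0.9)


class TestFit:
    def test_joint_table_add_one_smoothing(self, eight_pair_set):
        # grid is the single trained bin x {absent, present} = 2 cells;
        # (4 + 1)/(4 + 2) and (0 + 1)/(4 + 2)
        m = fit(eight_pair_set, config=2, smoothing_alpha=1.0,
                prior_mode="empirical")
        assert m.cond["STU"][(1, "absent")] == pytest.approx(5 / 6)
        assert m.cond["STU"][(1, "present")] == pytest.approx(1 / 6)
        assert m.cond["DTU"][(1, "absent")] == pytest.approx(1 / 6)
        assert m.cond["DTU"][(1, "present")] == pytest.approx(5 / 6)

    def test_independent_marginals_config_1(self, eight_pair_set):
        m = fit(eight_pair_set, config=1, smoothing_alpha=1.0,
                prior_mode="empirical")
        assert m.bin_marg["STU"][1] == pytest.approx(1.0)
        assert m.term_marg["STU"]["absent"] == pytest.approx(5 / 6)

    def test_single_class_unfittable(self):
        only_stu = [make_pair(1, label="STU")] * 3
        with pytest.raises(ValueError, match="DTU"):
            fit(only_stu, prior_mode="empirical")

    def test_negative_alpha_rejected(self, eight_pair_set):
        with pytest.raises(ValueError):
            fit(eight_pair_set, smoothing_alpha=-0.5, prior_mode="empirical")

    def test_geometric_mode_requires_mean(self, eight_pair_set):
        with pytest.raises(ValueError, match="mean_tu_length"):
            fit(eight_pair_set, prior_mode="geometric")

    def test_serialization_roundtrip_identical_posteriors(self, tmp_path, sim_medium):
        pairs = training_pairs(sim_medium.pairs)
        m = fit(pairs, config=3, prior_mode="empirical")
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = DisTerModel.from_json(path)
        rng = np.random.default_rng(1)
        for i in rng.integers(0, len(pairs), 100):
            p = pairs[int(i)]
            assert posterior_stu(m, p) == posterior_stu(m2, p)


class TestPosterior:
    def test_hand_bayes_on_eight_pairs(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, smoothing_alpha=1.0,
                prior_mode="empirical")  # prior = 0.5
        post = posterior_stu(m, make_pair(1, False))
        assert post == pytest.approx((0.5 * 5 / 6) / (0.5 * 5 / 6 + 0.5 * 1 / 6))
        assert post == pytest.approx(5 / 6)

    def test_uninformative_likelihood_returns_prior(self):
        tbl = {(0, "absent"): 0.5, (0, "present"): 0.5}
        m = DisTerModel(config=2, p_stu_prior=0.37, smoothing_alpha=1.0,
                        min_bin=0, max_bin=0, cond={"STU": tbl, "DTU": dict(tbl)})
        for term in (False, True):
            assert posterior_stu(m, make_pair(0, term, conf=80.0)) == pytest.approx(0.37)

    def test_posteriors_of_both_classes_sum_to_one(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, prior_mode="empirical")
        p_stu = posterior_stu(m, make_pair(1, True, conf=80.0))
        # DTU posterior by symmetry of Bayes' rule
        l_stu = m.cond["STU"][(1, "present")]
        l_dtu = m.cond["DTU"][(1, "present")]
        p_dtu = (0.5 * l_dtu) / (0.5 * l_stu + 0.5 * l_dtu)
        assert p_stu + p_dtu == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_bins_clamped(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, prior_mode="empirical")
        assert posterior_stu(m, make_pair(30, False)) == posterior_stu(
            m, make_pair(1, False)
        )

    def test_opposite_strand_pair_has_no_posterior(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, prior_mode="empirical")
        bad = AdjacentPair("u", "d", "convergent", 30)
        with pytest.raises(ValueError, match="same-strand"):
            posterior_stu(m, bad)

    def test_alpha_to_zero_pure_cell_posterior_to_one(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, smoothing_alpha=1e-9,
                prior_mode="empirical")
        assert posterior_stu(m, make_pair(1, False)) == pytest.approx(1.0, abs=1e-6)


class TestClassify:
    def test_above_threshold_is_stu(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, prior_mode="empirical")
        assert classify(m, make_pair(1, False), 0.5) == "STU"

    def test_tie_at_threshold_is_dtu(self):
        tbl = {(0, "absent"): 1.0, (0, "present"): 0.0}
        m = DisTerModel(config=2, p_stu_prior=0.5, smoothing_alpha=0.0,
                        min_bin=0, max_bin=0, cond={"STU": tbl, "DTU": dict(tbl)})
        assert posterior_stu(m, make_pair(0)) == 0.5
        assert classify(m, make_pair(0), 0.5) == "DTU"

    def test_threshold_one_makes_everything_dtu(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, prior_mode="empirical")
        for b, t in itertools.product([0, 1, 2], [False, True]):
            assert classify(m, make_pair(b, t, conf=80.0), 1.0) == "DTU"

    def test_threshold_outside_unit_interval_rejected(self, eight_pair_set):
        m = fit(eight_pair_set, config=2, prior_mode="empirical")
        with pytest.raises(ValueError):
            classify(m, make_pair(1), 1.5)


def brute_force_posterior(pairs, query_bin, query_state, alpha, prior, config):
    """Independent oracle: smoothed counts and Bayes' rule, enumerated directly."""
    bins = sorted({p.distance_bin for p in pairs})
    grid = list(range(min(bins), max(bins) + 1))
    states = ["absent", "low", "mid", "high"] if config == 3 else ["absent", "present"]

    def state_of(p):
        if config == 3:
            return p.terminator_score_class
        return "present" if p.terminator_present else "absent"

    qb = min(max(query_bin, grid[0]), grid[-1])
    lik = {}
    for c in ("STU", "DTU"):
        members = [p for p in pairs if p.label == c]
        if config == 1:
            nb = sum(1 for p in members if p.distance_bin == qb)
            ns = sum(1 for p in members if state_of(p) == query_state)
            lik[c] = ((nb + alpha) / (len(members) + alpha * len(grid))) * (
                (ns + alpha) / (len(members) + alpha * len(states))
            )
        else:
            ncell = sum(
                1
                for p in members
                if p.distance_bin == qb and state_of(p) == query_state
            )
            lik[c] = (ncell + alpha) / (len(members) + alpha * len(grid) * len(states))
    return prior * lik["STU"] / (prior * lik["STU"] + (1 - prior) * lik["DTU"])


@pytest.mark.parametrize("config", [1, 2, 3])
def test_oracle_equivalence_on_random_training_sets(config):
    """Fitted posteriors match an independent smoothed-count Bayes enumeration."""
    rng = np.random.default_rng(7)
    for trial in range(10):
        pairs = []
        for _ in range(30):
            label = "STU" if rng.random() < 0.6 else "DTU"
            b = int(rng.integers(-2, 6))
            term = bool(rng.random() < 0.4)
            conf = float(rng.uniform(50, 100)) if term else None
            pairs.append(make_pair(b, term, conf=conf, label=label))
        if len({p.label for p in pairs}) < 2:
            continue
        alpha = float(rng.uniform(0.2, 2.0))
        m = fit(pairs, config=config, smoothing_alpha=alpha, prior_mode="empirical")
        states = (
            ["absent", "low", "mid", "high"] if config == 3 else ["absent", "present"]
        )
        for qb in range(-4, 8):
            for qs in states:
                term = qs != "absent"
                conf = {"low": 60.0, "mid": 80.0, "high": 95.0}.get(qs)
                got = posterior_stu(m, make_pair(qb, term, conf=conf))
                want = brute_force_posterior(pairs, qb, qs, alpha, m.p_stu_prior, config)
                assert got == pytest.approx(want, abs=1e-12)


def test_config_2_and_3_coincide_with_single_score_class():
    """When every terminator confidence falls in one class, the four-level
    joint collapses (up to smoothing over the extra empty levels)."""
    rng = np.random.default_rng(11)
    pairs = []
    for _ in range(200):
        label = "STU" if rng.random() < 0.5 else "DTU"
        term = bool(rng.random() < (0.1 if label == "STU" else 0.7))
        pairs.append(
            make_pair(int(rng.integers(0, 4)), term, conf=95.0 if term else None,
                      label=label)
        )
    m2 = fit(pairs, config=2, smoothing_alpha=0.0, prior_mode="empirical")
    m3 = fit(pairs, config=3, smoothing_alpha=0.0, prior_mode="empirical")
    for b in range(0, 4):
        for term in (False, True):
            p2 = posterior_stu(m2, make_pair(b, term, conf=95.0 if term else None))
            p3 = posterior_stu(m3, make_pair(b, term, conf=95.0 if term else None))
            if not (math.isnan(p2) or math.isnan(p3)):
                assert p2 == pytest.approx(p3, abs=1e-12)


def test_parameter_recovery_improves_with_sample_size():
    """Total-variation distance of the fitted STU table to the generating
    distribution decreases as the training set grows."""
    cfg_template = SimulationConfig(p_stu=0.53)
    tvs = []
    for n, seed in [(200, 21), (2000, 22), (20000, 23)]:
        g = simulate_genome(SimulationConfig(n_genes=n, seed=seed))
        pairs = training_pairs(g.pairs)
        m = fit(pairs, config=2, smoothing_alpha=0.0, prior_mode="empirical")
        truth = {}
        for b, pb in cfg_template.stu_distance_model.items():
            feas = 0.0 if b < 0 else (0.9 if b == 0 else 1.0)
            pt = cfg_template.p_term_given_class["STU"]
            truth[(b, "present")] = pb * feas * pt
            truth[(b, "absent")] = pb * (1 - feas * pt)
        cells = set(truth) | set(m.cond["STU"])
        tv = 0.5 * sum(
            abs(truth.get(c, 0.0) - m.cond["STU"].get(c, 0.0)) for c in cells
        )
        tvs.append(tv)
    assert tvs[0] > tvs[1] > tvs[2]
    assert tvs[2] < 0.03
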