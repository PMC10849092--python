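"""Mk models and ancestral reconstruction: oracles, limits, invariances."""

import numpy as np
import pytest

import klebkit as kk
from _oracles import (
    enumeration_loglik,
    enumeration_marginals,
    random_mk_instance,
)
from klebkit.acsr import (
    SCHEMES,
    build_q,
    fit_mk,
    marginal_states,
    mk_loglik,
    mrca_leafset,
    n_free_rates,
    recode,
    stationary_distribution,
)
from klebkit.io_formats import TraitTable


class TestBuildQ:
    def test_er_two_state_definition(self):
        model = build_q(2, "ER", [1.0])
        assert np.allclose(model.Q, [[-1, 1], [1, -1]])

    def test_fixed_ratio_two_to_one(self):
        model = build_q(2, "FIXED_RATIO", [0.5], ratio=2.0, direction="01")
        assert model.Q[0, 1] == pytest.approx(1.0)
        assert model.Q[1, 0] == pytest.approx(0.5)
        reverse = build_q(2, "FIXED_RATIO", [0.5], ratio=2.0, direction="10")
        assert reverse.Q[0, 1] == pytest.approx(0.5)
        assert reverse.Q[1, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("scheme,k", [("ER", 3), ("SYM", 4), ("ARD", 3)])
    def test_rows_sum_to_zero_and_symmetry(self, scheme, k, rng):
        theta = rng.uniform(0.1, 2.0, size=n_free_rates(scheme, k))
        model = build_q(k, scheme, theta)
        assert np.allclose(model.Q.sum(axis=1), 0.0, atol=1e-12)
        if scheme == "SYM":
            assert np.allclose(model.Q, model.Q.T)

    def test_free_parameter_counts(self):
        assert n_free_rates("ER", 4) == 1
        assert n_free_rates("SYM", 4) == 6
        assert n_free_rates("ARD", 4) == 12
        assert n_free_rates("FIXED_RATIO", 2) == 1

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            build_q(2, "ER", [0.0])

    def test_stationary_prior_for_asymmetric_model(self):
        model = build_q(2, "FIXED_RATIO", [0.5], ratio=2.0, root_prior="stationary")
        pi = stationary_distribution(model.Q)
        # q01=2b pushes mass to state 1: pi = (1/3, 2/3)
        assert pi == pytest.approx([1 / 3, 2 / 3])
        assert model.root_prior == pytest.approx(pi)


class TestRecode:
    def test_parenchymatous_is_multicellular_sensu_lato(self):
        traits = TraitTable(states={"Chara": "parenchymatous", "Kleb": "filamentous"})
        coded, _ = recode(traits, "growth-2state")
        assert coded == {"Chara": 1, "Kleb": 1}

    def test_unicellular_is_state_zero_in_every_scheme(self):
        traits = TraitTable(states={"Meso": "unicellular"})
        for name in SCHEMES:
            if name.startswith("growth"):
                coded, _ = recode(traits, name)
                assert coded["Meso"] == 0

    def test_missing_marker_and_unknown_label(self):
        coded, _ = recode(TraitTable(states={"X": "?"}), "growth-2state")
        assert coded["X"] is None
        with pytest.raises(KeyError, match="colonial"):
            recode(TraitTable(states={"Y": "colonial"}), "growth-2state")

    def test_three_state_scheme_separates_sarcinoid(self):
        traits = TraitTable(
            states={"a": "sarcinoid", "b": "filamentous", "c": "parenchymatous"}
        )
        coded, _ = recode(traits, "growth-3state")
        assert coded == {"a": 1, "b": 2, "c": 2}


class TestLoglik:
    def test_matches_enumeration_on_quartet(self, four_leaf_tree):
        model = build_q(2, "ER", [1.0])
        tips = {"A": 0, "B": 0, "C": 1, "D": 1}
        ll = mk_loglik(four_leaf_tree, tips, model)
        oracle = enumeration_loglik(
            four_leaf_tree, tips, model.Q, model.root_prior
        )
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_vanishing_rate_limits(self, four_leaf_tree):
        slow = build_q(2, "ER", [1e-12])
        concordant = {"A": 0, "B": 0, "C": 0, "D": 0}
        assert mk_loglik(four_leaf_tree, concordant, slow) == pytest.approx(
            np.log(0.5), abs=1e-6
        )
        discordant = {"A": 0, "B": 1, "C": 0, "D": 1}
        assert mk_loglik(four_leaf_tree, discordant, slow) < np.log(0.5) - 10

    def test_missing_tips_are_marginalised(self, four_leaf_tree):
        model = build_q(2, "ER", [0.7])
        full = mk_loglik(four_leaf_tree, {"A": 0, "B": 0, "C": 1}, model)
        with_none = mk_loglik(
            four_leaf_tree, {"A": 0, "B": 0, "C": 1, "D": None}, model
        )
        assert full == pytest.approx(with_none, abs=1e-12)

    def test_unknown_taxon_in_states_is_error(self, four_leaf_tree):
        model = build_q(2, "ER", [1.0])
        with pytest.raises(ValueError, match="Zed"):
            mk_loglik(four_leaf_tree, {"Zed": 0}, model)

    def test_invariant_to_rerooting_for_reversible_models(self):
        rng = np.random.default_rng(3)
        tree, tips, Q, prior, k, scheme, theta = random_mk_instance(rng)
        # ER/SYM with a flat prior are reversible at stationarity; ARD is not
        theta = rng.uniform(0.1, 2.0, size=n_free_rates("SYM", k))
        model = build_q(k, "SYM", theta)
        base = mk_loglik(tree, tips, model)
        clone = tree.clone(depth=1)
        node = next(
            n for n in clone.postorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        )
        clone.reroot_at_node(node, update_bipartitions=False)
        assert mk_loglik(clone, tips, model) == pytest.approx(base, abs=1e-9)


class TestMarginals:
    def test_zero_branch_lengths_propagate_tip_state(self):
        tree = kk.tree_from_string("((A:0,B:0):0,(C:0,D:0):0);")
        model = build_q(2, "ER", [1.0])
        res = marginal_states(tree, {"A": 0, "B": 0, "C": 0, "D": 0}, model)
        for vec in res.node_probabilities.values():
            assert vec[0] == pytest.approx(1.0)

    def test_saturation_limit_returns_flat_prior(self, four_leaf_tree):
        model = build_q(2, "ER", [50.0])
        res = marginal_states(four_leaf_tree, {"A": 0, "B": 1, "C": 0, "D": 1}, model)
        root = res.node_probabilities[frozenset("ABCD")]
        assert root == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_matches_enumeration_on_five_tip_tree(self):
        tree = kk.tree_from_string(
            "(((A:0.4,B:0.7):0.3,C:0.9):0.2,(D:0.5,E:0.6):0.8);"
        )
        model = build_q(2, "ER", [1.0])
        tips = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0}
        res = marginal_states(tree, tips, model)
        oracle = enumeration_marginals(tree, tips, model.Q, model.root_prior)
        for key, expected in oracle.items():
            assert res.node_probabilities[key] == pytest.approx(expected, abs=1e-10)

    def test_vectors_sum_to_one(self):
        rng = np.random.default_rng(11)
        tree, tips, Q, prior, k, scheme, theta = random_mk_instance(rng)
        res = marginal_states(tree, tips, build_q(k, scheme, theta))
        for vec in res.node_probabilities.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)


class TestFit:
    def test_invariant_character_hits_lower_bound(self, four_leaf_tree):
        fit = fit_mk(
            four_leaf_tree, {"A": 0, "B": 0, "C": 0, "D": 0}, scheme="ER", k=2
        )
        assert fit.at_lower_bound()
        assert fit.loglik == pytest.approx(np.log(0.5), abs=1e-4)

    def test_model_nesting_ard_at_least_er(self):
        tree = kk.sim_tree(20, seed=41, depth=1.0)
        gen = build_q(2, "ER", [0.8])
        tips, _ = kk.sim_mk_characters(tree, gen, 50, seed=42)
        ll_er = fit_mk(tree, tips, scheme="ER", k=2).loglik
        ll_ard = fit_mk(tree, tips, scheme="ARD", k=2).loglik
        assert ll_ard >= ll_er - 1e-6

    def test_recovers_generating_rate(self):
        tree = kk.sim_tree(64, seed=11, depth=1.0)
        gen = build_q(2, "ER", [0.5])
        tips, _ = kk.sim_mk_characters(tree, gen, 1000, seed=21)
        fit = fit_mk(tree, tips, scheme="ER", k=2, n_starts=3)
        assert abs(fit.theta[0] - 0.5) / 0.5 < 0.10


class TestRunACSR:
    def test_focal_node_equal_to_root_marginal(self):
        tree = kk.sim_tree(10, seed=51, depth=1.0)
        gen = build_q(2, "SYM", [0.5])
        tips, _ = kk.sim_mk_characters(tree, gen, 1, seed=52)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        traits = TraitTable(
            states={t: ["unicellular", "filamentous"][int(v[0])] for t, v in tips.items()}
        )
        report = kk.run_acsr(
            tree, traits, "growth-2state", model="SYM",
            focal_nodes={"everything": labels}, n_starts=3,
        )
        res = report.results["SYM"]
        root_vec = res.node_probabilities[frozenset(labels)]
        focal_row = report.focal[report.focal["node"] == "everything"].iloc[0]
        assert focal_row["unicellular"] == pytest.approx(root_vec[0])
        assert mrca_leafset(tree, labels) == frozenset(labels)

    def test_fixed_ratio_emits_both_directions(self):
        tree = kk.sim_tree(8, seed=61, depth=1.0)
        gen = build_q(2, "ER", [0.5])
        tips, _ = kk.sim_mk_characters(tree, gen, 1, seed=62)
        traits = TraitTable(
            states={t: ["terrestrial", "aquatic"][int(v[0])] for t, v in tips.items()}
        )
        report = kk.run_acsr(
            tree, traits, "habitat", model="FIXED_RATIO", ratio=2.0, n_starts=2
        )
        assert len(report.results) == 2
        labels = sorted(report.results)
        assert any("01" in l for l in labels) and any("10" in l for l in labels)

    def test_taxa_without_traits_are_warned_and_treated_missing(self):
        tree = kk.tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        traits = TraitTable(states={"A": "unicellular", "B": "filamentous", "C": "unicellular"})
        with pytest.warns(UserWarning, match="missing"):
            report = kk.run_acsr(tree, traits, "growth-2state", model="ER", n_starts=2)
        tip_vec = report.results["ER"].node_probabilities[frozenset(["D"])]
        assert 0.0 < tip_vec[0] < 1.0  # not pinned to an observed state
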