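"""Likelihood engine, neutral fitting, acceleration tests, FDR, windowing."""

import itertools
import math

import numpy as np
import pytest

from acedhs.alignment import OrthologAlignment
from acedhs.hky import HKYModel, Tree, hky_rate_matrix, pruning_loglik
from acedhs.phylo import (
    acceleration_test,
    bh_fdr,
    call_accelerated,
    fit_neutral_model,
    sliding_sub_ares,
    AccelerationResult,
)
from acedhs.simulate import (
    DEFAULT_BASE_FREQS,
    DEFAULT_TREE,
    SimulationConfig,
    simulate_alignment,
)


def enumeration_loglik(aln, tree, model, branch_scales=None, tree_scale=1.0):
    """Sum over all joint ancestral-state assignments (exponential oracle)."""
    codes = aln.codes()
    order = aln.species
    n_nodes = tree.n_nodes
    leaf_of = {tree.leaf_names[s]: s for s in order if s in tree.leaf_names}
    mats = {}
    for i in range(n_nodes):
        if tree.parent[i] >= 0:
            t = tree.blen[i] * tree_scale
            if branch_scales:
                t *= branch_scales.get(i, 1.0)
            mats[i] = model.transition_matrix(t)
    length = aln.length
    total = 0.0
    for col in range(length):
        site = 0.0
        for states in itertools.product(range(4), repeat=n_nodes):
            ok = True
            for i, sp in leaf_of.items():
                obs = codes[sp][col]
                if obs < 4 and states[i] != obs:
                    ok = False
                    break
            if not ok:
                continue
            p = model.pi[states[tree.root]]
            for i in range(n_nodes):
                par = tree.parent[i]
                if par >= 0:
                    p *= mats[i][states[par], states[i]]
            site += p
        total += math.log(site)
    return total


class TestHKYModel:
    def test_rows_sum_to_one_and_p0_identity(self):
        m = HKYModel(3.0, np.array(DEFAULT_BASE_FREQS))
        for t in (0.0, 0.01, 0.3, 2.0):
            p = m.transition_matrix(t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(p >= -1e-12)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-12)

    def test_detailed_balance(self):
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        q = hky_rate_matrix(5.0, pi)
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)

    def test_unit_rate_normalisation(self):
        pi = np.array([0.3, 0.2, 0.2, 0.3])
        q = hky_rate_matrix(2.0, pi)
        assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0, abs=1e-12)

    def test_equilibrium_at_saturation(self):
        m = HKYModel(4.0, np.array(DEFAULT_BASE_FREQS))
        p = m.transition_matrix(50.0)
        assert np.allclose(p, np.tile(m.pi, (4, 1)), atol=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hky_rate_matrix(-1.0, np.full(4, 0.25))
        with pytest.raises(ValueError):
            hky_rate_matrix(2.0, np.array([0.5, 0.5, 0.2, 0.2]))
        m = HKYModel(2.0, np.full(4, 0.25))
        with pytest.raises(ValueError):
            m.transition_matrix(-0.1)


class TestPruningLikelihood:
    def test_zero_branches_identical_sequences(self):
        tree = Tree.from_newick("(a:0.0,b:0.0);")
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        model = HKYModel(2.0, pi)
        aln = OrthologAlignment("x", {"a": "ACGTG", "b": "ACGTG"})
        pat, cnt, order = aln.patterns()
        lnl = pruning_loglik(pat, cnt, order, tree, model)
        expected = sum(math.log(pi["ACGT".index(b)]) for b in "ACGTG")
        assert lnl == pytest.approx(expected, abs=1e-12)

    def test_jukes_cantor_closed_form(self):
        """Two taxa at kappa=1, uniform pi: per-site likelihoods match JC69."""
        pi = np.full(4, 0.25)
        model = HKYModel(1.0, pi)
        for t in (0.01, 0.05, 0.1, 0.5, 1.0, 2.0):
            tree = Tree.from_newick(f"(a:{t / 2},b:{t / 2});")
            match = OrthologAlignment("m", {"a": "A", "b": "A"})
            mis = OrthologAlignment("m", {"a": "A", "b": "C"})
            p_same = 0.25 * (0.25 + 0.75 * math.exp(-4.0 * t / 3.0))
            p_diff = 0.25 * (0.25 - 0.25 * math.exp(-4.0 * t / 3.0))
            for aln, expect in ((match, p_same), (mis, p_diff)):
                pat, cnt, order = aln.patterns()
                lnl = pruning_loglik(pat, cnt, order, tree, model)
                assert lnl == pytest.approx(math.log(expect), abs=1e-10)

    def test_matches_exhaustive_enumeration(self, default_tree):
        model = HKYModel(3.0, np.array(DEFAULT_BASE_FREQS))
        aln = simulate_alignment(
            SimulationConfig(seed=77, element_length=30), "small"
        )
        pat, cnt, order = aln.patterns()
        lnl = pruning_loglik(pat, cnt, order, default_tree, model)
        brute = enumeration_loglik(aln, default_tree, model)
        assert lnl == pytest.approx(brute, abs=1e-8)

    def test_enumeration_with_branch_scales(self, default_tree):
        model = HKYModel(2.0, np.full(4, 0.25))
        aln = simulate_alignment(
            SimulationConfig(seed=78, element_length=20), "small"
        )
        pat, cnt, order = aln.patterns()
        human = default_tree.terminal_branch("human")
        scales = {human: 3.0}
        lnl = pruning_loglik(
            pat, cnt, order, default_tree, model, scales, tree_scale=1.5
        )
        brute = enumeration_loglik(aln, default_tree, model, scales, 1.5)
        assert lnl == pytest.approx(brute, abs=1e-8)

    def test_leaf_order_invariance(self, default_tree):
        model = HKYModel(3.0, np.array(DEFAULT_BASE_FREQS))
        aln = simulate_alignment(SimulationConfig(seed=9, element_length=100), "x")
        pat, cnt, order = aln.patterns()
        ref = pruning_loglik(pat, cnt, order, default_tree, model)
        shuffled = OrthologAlignment(
            "x", {s: aln.sequences[s] for s in reversed(aln.species)}
        )
        pat2, cnt2, order2 = shuffled.patterns()
        assert pruning_loglik(pat2, cnt2, order2, default_tree, model) == pytest.approx(ref, abs=1e-9)

    def test_missing_species_pruned_equivalently(self, default_tree):
        """Scoring 3 of 5 species equals scoring on the pruned 3-taxon tree."""
        model = HKYModel(3.0, np.array(DEFAULT_BASE_FREQS))
        aln = simulate_alignment(SimulationConfig(seed=10, element_length=80), "x")
        sub = aln.subset(["human", "chimp", "macaque"])
        pat, cnt, order = sub.patterns()
        full = pruning_loglik(pat, cnt, order, default_tree, model)
        pruned = default_tree.pruned_to({"human", "chimp", "macaque"})
        via_pruned = pruning_loglik(pat, cnt, order, pruned, model)
        assert full == pytest.approx(via_pruned, abs=1e-9)

    def test_all_missing_columns_contribute_zero(self):
        tree = Tree.from_newick("(a:0.1,b:0.2);")
        model = HKYModel(2.0, np.full(4, 0.25))
        base = OrthologAlignment("x", {"a": "ACGT", "b": "ACCT"})
        padded = OrthologAlignment("x", {"a": "ACGT--NN", "b": "ACCTN-N-"})
        p1, c1, o1 = base.patterns()
        p2, c2, o2 = padded.patterns()
        assert pruning_loglik(p2, c2, o2, tree, model) == pytest.approx(
            pruning_loglik(p1, c1, o1, tree, model), abs=1e-12
        )

    def test_unknown_species_rejected(self, default_tree):
        aln = OrthologAlignment("x", {"human": "ACGT", "yeti": "ACGT"})
        pat, cnt, order = aln.patterns()
        with pytest.raises(KeyError):
            pruning_loglik(pat, cnt, order, default_tree, HKYModel(2.0, np.full(4, 0.25)))


class TestNeutralFit:
    def test_identical_sequences_zero_branches(self, default_tree):
        seq = "ACGT" * 50
        aln = OrthologAlignment(
            "flat", {s: seq for s in default_tree.leaf_names}
        )
        nm = fit_neutral_model(aln, default_tree)
        assert np.all(nm.tree.blen[nm.tree.free_branches()] <= 1e-4)

    def test_refit_at_optimum_is_fixed_point(self, default_tree, neutral_alignment):
        nm = fit_neutral_model(neutral_alignment, default_tree)
        nm2 = fit_neutral_model(
            neutral_alignment, nm.tree, init_kappa=nm.kappa
        )
        assert abs(nm2.loglik - nm.loglik) < 1e-5
        # stored parameters reproduce the stored likelihood
        from acedhs.phylo import _prepare
        pat, cnt, order, tree = _prepare(neutral_alignment, nm.tree)
        lnl = pruning_loglik(pat, cnt, order, nm.tree, nm.model())
        assert lnl == pytest.approx(nm.loglik, abs=1e-9)

    def test_all_gap_alignment_errors(self, default_tree):
        aln = OrthologAlignment(
            "gaps", {s: "----" for s in default_tree.leaf_names}
        )
        with pytest.raises(ValueError):
            fit_neutral_model(aln, default_tree)

    def test_parameter_recovery_at_modest_scale(self):
        """2 kb fit recovers branch lengths loosely (tight version is the
        dedicated recovery experiment on 10 kb alignments)."""
        tree = Tree.from_newick(DEFAULT_TREE)
        aln = simulate_alignment(SimulationConfig(seed=21, element_length=2000), "r")
        nm = fit_neutral_model(aln, tree)
        for sp in tree.leaf_names:
            t_true = tree.blen[tree.terminal_branch(sp)]
            t_hat = nm.tree.blen[nm.tree.terminal_branch(sp)]
            assert t_hat == pytest.approx(t_true, rel=0.5)
        assert nm.kappa == pytest.approx(4.0, rel=0.5)


@pytest.fixture(scope="module")
def neutral(default_tree, neutral_alignment):
    return fit_neutral_model(neutral_alignment, default_tree)


class TestAccelerationTest:

    def test_perfect_conservation_boundary(self, neutral, default_tree):
        seq = "ACGTTGCA" * 30
        aln = OrthologAlignment("c", {s: seq for s in default_tree.leaf_names})
        res = acceleration_test(aln, neutral)
        assert res.rho_a == 1.0 and res.lr_a == 0.0
        assert res.p_a == 1.0 and res.p_b == 1.0

    def test_strong_acceleration_detected(self, neutral):
        dhs = simulate_alignment(
            SimulationConfig(seed=31, element_length=1000, human_rate_multiplier=5.0),
            "fast",
        )
        res = acceleration_test(dhs, neutral)
        assert res.rho_a > 2.0
        assert res.p_a < 1e-3 and res.p_b < 1e-3

    def test_alternative_never_below_null(self, neutral):
        for seed in range(40, 52):
            dhs = simulate_alignment(
                SimulationConfig(seed=seed, element_length=300), f"n{seed}"
            )
            res = acceleration_test(dhs, neutral)
            assert res.lnl_alt_a >= res.lnl_null_a - 1e-6
            assert res.lnl_alt_b >= res.lnl_null_b - 1e-6
            assert 0 < res.p_a <= 1 and 0 < res.p_b <= 1

    def test_short_alignment_untestable(self, neutral, default_tree):
        aln = OrthologAlignment(
            "tiny", {s: "ACGT" * 10 for s in default_tree.leaf_names}
        )
        res = acceleration_test(aln, neutral)
        assert res.untestable

    def test_human_required(self, neutral):
        aln = OrthologAlignment("x", {"chimp": "ACGT" * 30, "gorilla": "ACGT" * 30})
        with pytest.raises(KeyError):
            acceleration_test(aln, neutral)


class TestSlidingWindows:
    def _are(self, human_len, species=("human", "chimp", "gorilla", "macaque")):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=human_len))
        return OrthologAlignment("are", {s: seq for s in species})

    def test_short_are_single_window(self):
        assert len(sliding_sub_ares(self._are(550), 300)) == 1

    def test_exactly_twice_is_single_window(self):
        # 600 is not *more than* twice 300
        assert len(sliding_sub_ares(self._are(600), 300)) == 1

    def test_window_count_arithmetic(self):
        wins = sliding_sub_ares(self._are(1000), 300)
        assert len(wins) == 24  # floor((1000-300)/30) + 1
        assert all(len(w.ungapped("human")) == 300 for w in wins)

    def test_windows_follow_human_coordinates_through_gaps(self):
        human = "AC-GT" * 100  # 400 human bases over 500 columns
        other = "ACCGT" * 100
        aln = OrthologAlignment("g", {"human": human, "chimp": other})
        wins = sliding_sub_ares(aln, 150)
        assert len(wins) == 1 + (400 - 150) // 15
        assert all(len(w.ungapped("human")) == 150 for w in wins)

    def test_below_minimum_width_rejected(self):
        with pytest.raises(ValueError):
            sliding_sub_ares(self._are(500), 80)


class TestBHFDR:
    def test_stepup_formula_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([]).size == 0

    def test_invalid_pvalues_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.1]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    def test_matches_statsmodels_exactly(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(1000):
            p = rng.uniform(1e-12, 1.0, size=int(rng.integers(1, 40)))
            ours = bh_fdr(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.array_equal(ours, theirs)


class TestCallAccelerated:
    def _result(self, eid, window, p):
        return AccelerationResult(
            element_id=eid, window=window, n_windows=0,
            p_a=p, p_b=p, lr_a=1.0, lr_b=1.0, rho_a=2.0, rho_b=2.0,
        )

    def test_strict_majority_rule(self):
        results = []
        # element A: 2 of 4 windows significant -> NOT accelerated
        for w, p in enumerate([1e-6, 1e-6, 0.9, 0.9]):
            results.append(self._result("A", w, p))
        # element B: 3 of 5 windows significant -> accelerated
        for w, p in enumerate([1e-6, 1e-6, 1e-6, 0.9, 0.9]):
            results.append(self._result("B", w, p))
        calls = call_accelerated(results, alpha=0.05)
        assert calls.accelerated_ids == ["B"]
        assert calls.votes["A"] == (2, 4) and calls.votes["B"] == (3, 5)

    def test_single_window_rule(self):
        calls = call_accelerated(
            [self._result("X", 0, 1e-8), self._result("Y", 0, 0.8)], alpha=0.05
        )
        assert calls.accelerated_ids == ["X"]

    def test_empty_input(self):
        calls = call_accelerated([], alpha=0.05)
        assert calls.accelerated_ids == []

    def test_untestable_excluded_from_fdr_pool(self):
        r1 = self._result("A", 0, 1e-8)
        r2 = AccelerationResult(element_id="B", untestable=True)
        calls = call_accelerated([r1, r2], alpha=0.05)
        assert calls.accelerated_ids == ["A"]
        assert math.isnan(r2.q_a)
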