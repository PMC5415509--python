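"""Unordered-parsimony reconstruction: exactness against brute force,
ACCTRAN/DELTRAN semantics, and missing-data handling."""

import numpy as np
import pytest

from morphotrace import (brute_force_min_steps, find_synapomorphies,
                         fitch_steps, mpr_sets, parse_newick, resolve)

from conftest import matrix_from, random_tree_newick


class TestFitchSteps:
    def test_single_clean_origin(self, quartet):
        m = matrix_from({"A": "0", "B": "0", "C": "1", "D": "1"})
        assert fitch_steps(quartet, m, 1) == 1

    def test_incongruent_character_needs_two_steps(self, quartet):
        # expected value established by exhaustive enumeration
        m = matrix_from({"A": "0", "B": "1", "C": "0", "D": "1"})
        assert brute_force_min_steps(quartet, m, 1) == 2
        assert fitch_steps(quartet, m, 1) == 2

    def test_star_tree_multistate(self):
        t = parse_newick("(A,B,C);")
        m = matrix_from({"A": "0", "B": "1", "C": "2"})
        assert brute_force_min_steps(t, m, 1) == 2
        assert fitch_steps(t, m, 1) == 2

    def test_all_missing_character_warns_and_counts_zero(self, quartet):
        m = matrix_from({"A": "?", "B": "?", "C": "-", "D": "?"})
        with pytest.warns(UserWarning, match="no observed states"):
            assert fitch_steps(quartet, m, 1) == 0

    def test_character_index_out_of_range(self, quartet):
        m = matrix_from({"A": "0", "B": "0", "C": "1", "D": "1"})
        with pytest.raises(IndexError):
            fitch_steps(quartet, m, 5)

    def test_missing_vs_inapplicable_equivalent(self):
        # relabelling any ? as - (or back) never changes the step count
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(20):
            t = parse_newick(random_tree_newick(rng, labels))
            syms = rng.choice(list("01?-"), size=8, p=[0.4, 0.4, 0.1, 0.1])
            m1 = matrix_from(dict(zip(labels, syms)))
            flipped = ["-" if s == "?" else ("?" if s == "-" else s)
                       for s in syms]
            m2 = matrix_from(dict(zip(labels, flipped)))
            assert fitch_steps(t, m1, 1) == fitch_steps(t, m2, 1)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(60):
            t = parse_newick(random_tree_newick(rng, labels))
            syms = rng.choice(list("0123?-"), size=6,
                              p=[0.3, 0.3, 0.1, 0.1, 0.1, 0.1])
            m = matrix_from(dict(zip(labels, syms)))
            assert fitch_steps(t, m, 1) == brute_force_min_steps(t, m, 1)

    def test_polytomy_never_beats_its_binary_resolutions(self):
        t_poly = parse_newick("((A,B,C),(D,E));")
        res1 = parse_newick("(((A,B),C),(D,E));")
        res2 = parse_newick("((A,(B,C)),(D,E));")
        m = matrix_from({"A": "0", "B": "1", "C": "0", "D": "1", "E": "1"})
        s_poly = fitch_steps(t_poly, m, 1)
        assert s_poly <= fitch_steps(res1, m, 1)
        assert s_poly <= fitch_steps(res2, m, 1)

    def test_within_restriction_ignores_outside_variation(self):
        t = parse_newick("((A,B),((C,D),E));")
        m = matrix_from({"A": "1", "B": "0", "C": "0", "D": "0", "E": "0"})
        assert fitch_steps(t, m, 1) == 1
        assert fitch_steps(t, m, 1, within=["C", "D", "E"]) == 0


class TestMprSets:
    def test_root_ambiguity(self, quartet):
        m = matrix_from({"A": "0", "B": "0", "C": "1", "D": "1"})
        rec = mpr_sets(quartet, m, 1)
        assert rec.state_sets[quartet.root.id] == frozenset({0, 1})

    def test_constant_character(self, quartet):
        m = matrix_from({"A": "2", "B": "2", "C": "2", "D": "2"})
        rec = mpr_sets(quartet, m, 1)
        assert rec.steps == 0
        assert all(s == frozenset({2}) for s in rec.state_sets.values())

    def test_missing_tip_inherits_constant_state(self, quartet):
        m = matrix_from({"A": "1", "B": "1", "C": "?", "D": "1"})
        rec = mpr_sets(quartet, m, 1)
        tip_c = quartet.tip("C")
        assert rec.state_sets[tip_c.id] == frozenset({1})


class TestResolve:
    def test_unique_mpr_both_modes_agree(self):
        t = parse_newick("(((A,B),C),D);")
        m = matrix_from({"A": "1", "B": "0", "C": "0", "D": "0"})
        for mode in ("ACCTRAN", "DELTRAN"):
            rec = resolve(t, m, 1, mode)
            assert rec.steps == 1
            assert [(c.node_label, c.from_state, c.to_state)
                    for c in rec.changes] == [("A", 0, 1)]

    def test_acctran_reversal_vs_deltran_parallelism(self):
        # two equally parsimonious histories: an early gain reversed in D,
        # or two parallel gains (in (A,B) and in C)
        t = parse_newick("(((A,B),(C,D)),E);")
        m = matrix_from({"A": "1", "B": "1", "C": "1", "D": "0", "E": "0"})
        acc = resolve(t, m, 1, "ACCTRAN")
        dlt = resolve(t, m, 1, "DELTRAN")
        assert acc.steps == dlt.steps == 2
        acc_moves = {(c.from_state, c.to_state) for c in acc.changes}
        dlt_moves = [(c.from_state, c.to_state) for c in dlt.changes]
        assert (1, 0) in acc_moves          # ACCTRAN reverses
        assert dlt_moves == [(0, 1), (0, 1)]  # DELTRAN gains in parallel

    def test_change_count_equals_steps_on_random_instances(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(7)]
        for _ in range(40):
            t = parse_newick(random_tree_newick(rng, labels))
            syms = rng.choice(list("012?"), size=7, p=[0.4, 0.3, 0.2, 0.1])
            m = matrix_from(dict(zip(labels, syms)))
            s = fitch_steps(t, m, 1)
            for mode in ("ACCTRAN", "DELTRAN"):
                rec = resolve(t, m, 1, mode)
                assert rec.steps == s == len(rec.changes)

    def test_tips_keep_observed_states(self):
        t = parse_newick("((A,B),(C,D));")
        m = matrix_from({"A": "0", "B": "1", "C": "2", "D": "0"})
        for mode in ("ACCTRAN", "DELTRAN"):
            rec = resolve(t, m, 1, mode)
            for lab, want in [("A", 0), ("B", 1), ("C", 2), ("D", 0)]:
                assert rec.states[t.tip(lab).id] == want


class TestSynapomorphies:
    def test_non_monophyletic_clade_names_intruders(self, quartet):
        m = matrix_from({"A": "0", "B": "0", "C": "1", "D": "1"})
        with pytest.raises(ValueError, match="\\bB\\b"):
            find_synapomorphies(quartet, m, ["A", "C", "D"])

    def test_clean_gain_detected(self):
        t = parse_newick("((A,B),((C,D),E));")
        m = matrix_from({"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"})
        rep = find_synapomorphies(t, m, ["C", "D"])
        assert rep.homoplasy_free_characters == [1]
        assert rep.entries[0].derived_state == 1

    def test_homoplasious_stem_change_flagged(self):
        # state 1 arises on the (C,D) stem but also independently in A
        t = parse_newick("((A,B),((C,D),E));")
        m = matrix_from({"A": "1", "B": "0", "C": "1", "D": "1", "E": "0"})
        rep = find_synapomorphies(t, m, ["C", "D"])
        assert rep.characters == [1]
        assert rep.homoplasy_free_characters == []


class TestBruteForce:
    def test_constant_character_is_free(self, quartet):
        m = matrix_from({"A": "3", "B": "3", "C": "3", "D": "3"})
        assert brute_force_min_steps(quartet, m, 1) == 0

    def test_refuses_large_instances(self):
        labels = [f"t{i}" for i in range(16)]
        nwk = random_tree_newick(np.random.default_rng(0), labels)
        t = parse_newick(nwk)
        m = matrix_from({lab: "0" if i % 2 else "1"
                         for i, lab in enumerate(labels)})
        with pytest.raises(ValueError, match="too large"):
            brute_force_min_steps(t, m, 1)
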