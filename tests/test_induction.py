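"""Initial grammar, operators, exact deltas, constraints, greedy search."""

import math
import random

import pytest

from mdlgram.grammar import (
    Corpus,
    CostWeights,
    GrammarError,
    InputError,
    total_cost,
)
from mdlgram.induction import (
    DEFAULT_BLOCKED_TAGS,
    InductionConfig,
    OperatorInstance,
    StaleCandidateError,
    apply_operator,
    build_initial_grammar,
    enumerate_combine_candidates,
    enumerate_merge_candidates,
    estimate_delta,
    induce,
    violates_constraints,
)
from mdlgram.parsing import is_recursive, language_up_to, viterbi_parse
from mdlgram.em import init_uniform

from conftest import oracle_total_cost, random_corpus, random_state


def rules(grammar):
    return sorted(str(p) for p in grammar)


# -- initial grammar -------------------------------------------------------


class TestBuildInitialGrammar:
    def test_two_sentence_example(self):
        state = build_initial_grammar(Corpus([("a", "b"), ("a", "c")]))
        assert rules(state.grammar) == [
            "A -> a", "B -> b", "C -> c", "S -> A B", "S -> A C"]
        assert state.grammar.sigma_size == 7

    def test_duplicates_share_grammar_but_not_derivations(self):
        one = build_initial_grammar(Corpus([("a", "b")]))
        two = build_initial_grammar(Corpus([("a", "b"), ("a", "b")]))
        assert rules(one.grammar) == rules(two.grammar)
        assert len(one.derivations) == 1
        assert len(two.derivations) == 2

    def test_single_token_sentence(self):
        state = build_initial_grammar(Corpus([("a",)]))
        assert rules(state.grammar) == ["A -> a", "S -> A"]
        assert total_cost(state.grammar, state.derivations,
                          CostWeights(0.0)) == 0.0

    def test_empty_corpus_rejected(self):
        with pytest.raises(InputError):
            build_initial_grammar(Corpus([]))

    def test_preterminals_shared_across_sentences(self):
        state = build_initial_grammar(
            Corpus([("a", "b"), ("b", "a"), ("a", "a")]))
        preterms = [p for p in state.grammar if len(p.rhs) == 1
                    and p.rhs[0].is_terminal]
        assert len(preterms) == 2  # one per unique terminal

    def test_start_name_dodges_terminal_collision(self):
        state = build_initial_grammar(Corpus([("S", "a")]))
        assert state.grammar.start.name != "S"
        state.check_consistency()

    def test_parses_exactly_the_unique_sentences(self):
        corpus = Corpus([("a", "b"), ("b",), ("a", "b")])
        state = build_initial_grammar(corpus)
        assert language_up_to(state.grammar, 4) == set(
            corpus.unique_sentences())


# -- candidate enumeration -------------------------------------------------


class TestEnumerateCombine:
    def test_bigram_and_trigram_counts(self):
        state = build_initial_grammar(Corpus([("a", "b", "c"), ("a", "b")]))
        got = {inst.operands: n
               for inst, n in enumerate_combine_candidates(state, 4)}
        assert got[("A", "B")] == 2
        assert got[("B", "C")] == 1
        assert got[("A", "B", "C")] == 1

    def test_non_overlapping_tiling(self):
        state = build_initial_grammar(Corpus([("a", "a", "a", "a")]))
        got = {inst.operands: n
               for inst, n in enumerate_combine_candidates(state, 4)}
        assert got[("A", "A")] == 2
        assert got[("A", "A", "A")] == 1

    def test_no_candidates_without_long_rhs(self):
        state = build_initial_grammar(Corpus([("a",), ("b",)]))
        assert enumerate_combine_candidates(state, 4) == []

    def test_max_n_caps_gram_length(self):
        state = build_initial_grammar(Corpus([("a", "b", "c", "d", "e")]))
        lengths = {len(inst.operands)
                   for inst, _ in enumerate_combine_candidates(state, 3)}
        assert lengths == {2, 3}


class TestEnumerateMerge:
    def test_start_symbol_excluded(self):
        state = build_initial_grammar(Corpus([("a", "b"), ("a", "c")]))
        pairs = {inst.operands for inst in enumerate_merge_candidates(state)}
        assert pairs == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_single_other_nonterminal_gives_nothing(self):
        state = build_initial_grammar(Corpus([("a",), ("a", "a")]))
        assert enumerate_merge_candidates(state) == []

    def test_pair_count_formula(self, rng):
        for _ in range(5):
            state = random_state(rng, warmup_ops=2)
            k = len(state.grammar.nonterminals) - 1
            assert len(enumerate_merge_candidates(state)) == k * (k - 1) // 2


# -- exact deltas ----------------------------------------------------------


class TestEstimateDelta:
    def test_merge_example_f1(self):
        state = build_initial_grammar(Corpus([("a", "b"), ("a", "c")]))
        inst = OperatorInstance("merge", ("B", "C"), "M1")
        delta = estimate_delta(state, inst, CostWeights(1.0))
        assert delta == pytest.approx(9 * math.log2(6) - 12 * math.log2(7),
                                      abs=1e-9)

    def test_merge_example_f0_choice_moves(self):
        state = build_initial_grammar(Corpus([("a", "b"), ("a", "c")]))
        inst = OperatorInstance("merge", ("B", "C"), "M1")
        assert estimate_delta(state, inst, CostWeights(0.0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_single_occurrence_combine_increases_grammar_cost(self):
        state = build_initial_grammar(Corpus([("a", "b", "c")]))
        inst = OperatorInstance("combine", ("A", "B"), "C1")
        assert estimate_delta(state, inst, CostWeights(1.0)) > 0

    def test_stale_candidate_raises(self):
        state = build_initial_grammar(Corpus([("a", "b"), ("a", "c")]))
        with pytest.raises(StaleCandidateError):
            estimate_delta(state, OperatorInstance("combine", ("B", "C"), "C1"),
                           CostWeights(0.5))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_apply_and_recompute(self, seed):
        rng = random.Random(900 + seed)
        state = random_state(rng, warmup_ops=3)
        f = rng.choice([0.0, 0.15, 0.5, 1.0])
        weights = CostWeights(f)
        before = oracle_total_cost(state.grammar, state.derivations, f)
        cands = [i for i, _ in enumerate_combine_candidates(state, 4)]
        cands += enumerate_merge_candidates(state)
        for inst in cands:
            delta = estimate_delta(state, inst, weights)
            trial = state.copy()
            apply_operator(trial, inst)
            after = oracle_total_cost(trial.grammar, trial.derivations, f)
            assert delta == pytest.approx(after - before, abs=1e-9), inst


# -- operator application --------------------------------------------------


class TestApplyCombine:
    def test_rewrites_all_occurrences(self):
        state = build_initial_grammar(
            Corpus([("d", "n", "v", "d", "n"), ("d", "n", "v")]))
        inst = OperatorInstance("combine", ("D", "N"), "C1")
        apply_operator(state, inst)
        assert "C1 -> D N" in rules(state.grammar)
        assert "S -> C1 V C1" in rules(state.grammar)
        assert "S -> C1 V" in rules(state.grammar)
        state.check_consistency()

    def test_language_preserved(self, rng):
        for _ in range(8):
            state = random_state(rng, warmup_ops=1)
            cands = enumerate_combine_candidates(state, 4)
            if not cands:
                continue
            before = language_up_to(state.grammar, 8)
            apply_operator(state, cands[0][0])
            state.check_consistency()
            assert language_up_to(state.grammar, 8) == before

    def test_derivations_gain_unit_steps(self):
        state = build_initial_grammar(Corpus([("a", "b")]))
        n_steps = len(state.derivations[0].steps)
        apply_operator(state, OperatorInstance("combine", ("A", "B"), "C1"))
        assert len(state.derivations[0].steps) == n_steps + 1
        state.check_consistency()


class TestApplyMerge:
    def test_collapses_duplicate_productions(self):
        state = build_initial_grammar(Corpus([("a", "b"), ("a", "c")]))
        apply_operator(state, OperatorInstance("merge", ("B", "C"), "M1"))
        assert rules(state.grammar) == ["A -> a", "M1 -> b", "M1 -> c",
                                        "S -> A M1"]
        assert state.grammar.sigma_size == 6
        state.check_consistency()

    def test_language_never_shrinks(self, rng):
        grown = 0
        for _ in range(8):
            state = random_state(rng, warmup_ops=1)
            cands = enumerate_merge_candidates(state)
            if not cands:
                continue
            inst = cands[rng.randrange(len(cands))]
            before = language_up_to(state.grammar, 6)
            trial = state.copy()
            apply_operator(trial, inst)
            if is_recursive(trial.grammar):
                continue
            after = language_up_to(trial.grammar, 6)
            assert before <= after
            grown += after > before
        # at least some merges genuinely generalize
        assert grown >= 1

    def test_merged_symbols_leave_inventory(self):
        state = build_initial_grammar(Corpus([("a", "b"), ("a", "c")]))
        apply_operator(state, OperatorInstance("merge", ("B", "C"), "M1"))
        assert not state.grammar.has_symbol("B")
        assert not state.grammar.has_symbol("C")
        assert state.grammar.has_symbol("M1")


# -- constraints -----------------------------------------------------------


def _cfg(**kw):
    base = dict(weights=CostWeights(0.5))
    base.update(kw)
    return InductionConfig(**base)


class TestViolatesConstraints:
    def test_merge_creating_cycle_blocked(self):
        # S -> A B, A -> a, B -> b; merging A with S is impossible (start),
        # but combining then merging C1 with A would nest A inside itself.
        state = build_initial_grammar(Corpus([("a", "b")]))
        apply_operator(state, OperatorInstance("combine", ("A", "B"), "C1"))
        bad, reason = violates_constraints(
            state, OperatorInstance("merge", ("A", "C1"), "M1"), _cfg())
        assert bad and "cycle" in reason

    def test_merge_cycle_allowed_when_recursion_permitted(self):
        state = build_initial_grammar(Corpus([("a", "b")]))
        apply_operator(state, OperatorInstance("combine", ("A", "B"), "C1"))
        bad, _ = violates_constraints(
            state, OperatorInstance("merge", ("A", "C1"), "M1"),
            _cfg(forbid_recursion=False))
        assert not bad

    def test_combine_with_blocked_tag_second(self):
        state = build_initial_grammar(Corpus([("det", "verb")]))
        bad, reason = violates_constraints(
            state, OperatorInstance("combine", ("DET", "VERB"), "C1"), _cfg())
        assert bad and "VERB" in reason

    def test_combine_with_blocked_tag_first_allowed(self):
        state = build_initial_grammar(Corpus([("verb", "noun")]))
        bad, _ = violates_constraints(
            state, OperatorInstance("combine", ("VERB", "NOUN"), "C1"), _cfg())
        assert not bad

    def test_blocklist_disabled(self):
        state = build_initial_grammar(Corpus([("det", "verb")]))
        bad, _ = violates_constraints(
            state, OperatorInstance("combine", ("DET", "VERB"), "C1"),
            _cfg(enforce_blocklist=False))
        assert not bad

    def test_blocked_status_is_derivable_not_literal(self):
        # C1 -> VERB NOUN makes C1 derive "verb"; C1 may not then sit at
        # position >= 2 of a later combine.
        state = build_initial_grammar(
            Corpus([("verb", "noun"), ("noun", "verb", "noun")]))
        apply_operator(state,
                       OperatorInstance("combine", ("VERB", "NOUN"), "C1"))
        bad, _ = violates_constraints(
            state, OperatorInstance("combine", ("NOUN", "C1"), "C2"), _cfg())
        assert bad

    def test_merge_pushing_blocked_symbol_into_tail_blocked(self):
        # A derives plain 'a'; W_verb is blocked.  A occurs at position 2
        # (in S -> B A), so merging A with W_verb would newly block that slot.
        state = build_initial_grammar(Corpus([("b", "a"), ("verb",)]))
        bad, reason = violates_constraints(
            state, OperatorInstance("merge", ("A", "VERB"), "M1"), _cfg())
        assert bad and "blocks" in reason

    def test_merge_of_two_blocked_symbols_allowed(self):
        state = build_initial_grammar(Corpus([("verb", "aux")]))
        bad, _ = violates_constraints(
            state, OperatorInstance("merge", ("VERB", "AUX"), "M1"), _cfg())
        assert not bad


# -- greedy search ---------------------------------------------------------


class TestInduce:
    def test_trace_strictly_decreasing(self, rng):
        for _ in range(6):
            corpus = random_corpus(rng, n_sentences=(8, 25), max_len=6)
            res = induce(corpus, _cfg(enforce_blocklist=False))
            totals = res.cost_trace
            assert all(b < a - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_parses_all_training_sentences(self, rng):
        for f in (0.0, 0.5, 1.0):
            corpus = random_corpus(rng, n_sentences=(10, 25))
            res = induce(corpus, _cfg(weights=CostWeights(f)))
            pcfg = init_uniform(res.grammar)
            for sent in corpus.unique_sentences():
                assert viterbi_parse(pcfg, sent).ok

    def test_f0_stays_most_specific(self, rng):
        for _ in range(4):
            corpus = random_corpus(rng, n_sentences=(8, 20))
            res = induce(corpus, _cfg(weights=CostWeights(0.0)))
            lang = language_up_to(res.grammar, 8)
            assert lang == set(corpus.unique_sentences())

    def test_f1_grammar_cost_descends_to_trace_minimum(self, rng):
        corpus = random_corpus(rng, n_sentences=(10, 25))
        res = induce(corpus, InductionConfig(
            weights=CostWeights(1.0), forbid_recursion=True,
            enforce_blocklist=False))
        cgs = [r.grammar_cost for r in res.trace]
        assert cgs[-1] == min(cgs)

    def test_no_recursion_in_result_when_banned(self, rng):
        for _ in range(4):
            corpus = random_corpus(rng, n_sentences=(8, 20))
            res = induce(corpus, _cfg(weights=CostWeights(0.9)))
            assert not is_recursive(res.grammar)

    def test_deterministic(self):
        corpus = Corpus([tuple("ab"), tuple("abab"), tuple("ab"),
                         tuple("ba"), tuple("abab")])
        r1 = induce(corpus, _cfg())
        r2 = induce(corpus, _cfg())
        assert [str(p) for p in r1.grammar] == [str(p) for p in r2.grammar]
        assert r1.cost_trace == r2.cost_trace

    def test_single_sentence_corpus(self):
        res = induce(Corpus([("a", "b", "a", "b")]),
                     _cfg(weights=CostWeights(0.0)))
        totals = res.cost_trace
        assert all(b <= a for a, b in zip(totals, totals[1:]))
        assert language_up_to(res.grammar, 6) == {("a", "b", "a", "b")}
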