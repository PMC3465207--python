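"""Shared fixtures and independent from-scratch oracles.

The oracle functions recompute encoding costs directly from the definitions
(symbol counts, per-LHS production counts) without going through the
package's cost functions, so equality tests are genuinely dual-route.
"""

from __future__ import annotations

import math
import random

import pytest

from mdlgram.grammar import Corpus, CostWeights, Grammar
from mdlgram.induction import (
    InductionState,
    apply_operator,
    build_initial_grammar,
    enumerate_combine_candidates,
    enumerate_merge_candidates,
)


# -- independent cost oracles ---------------------------------------------


def oracle_grammar_cost(grammar: Grammar) -> float:
    """From-scratch evaluation: sum over rules of (1+|rhs|)*log2(|Sigma|)."""
    sigma = len(grammar.inventory)
    total = 0.0
    for prod in grammar.productions:
        total += (1 + len(prod.rhs)) * math.log2(sigma)
    return total


def oracle_derivation_cost(derivations, grammar: Grammar) -> float:
    """From-scratch: per step, log2 of the number of rules sharing the LHS,
    counted by scanning the production list directly."""
    total = 0.0
    prods = grammar.productions
    for deriv in derivations:
        for lhs, _prod in deriv.steps:
            k = sum(1 for p in prods if p.lhs.name == lhs.name)
            total += math.log2(k)
    return total


def oracle_total_cost(grammar: Grammar, derivations, f: float) -> float:
    return (f * oracle_grammar_cost(grammar)
            + (1 - f) * oracle_derivation_cost(derivations, grammar))


# -- random corpora / states ----------------------------------------------


def random_corpus(rng: random.Random, *, max_alphabet: int = 5,
                  n_sentences: tuple[int, int] = (3, 10),
                  max_len: int = 6) -> Corpus:
    alphabet = list("abcde"[:rng.randint(2, max_alphabet)])
    n = rng.randint(*n_sentences)
    sents = [tuple(rng.choice(alphabet)
                   for _ in range(rng.randint(1, max_len)))
             for _ in range(n)]
    # encourage duplicates, the way clinical corpora repeat sentences
    for _ in range(n // 3):
        sents.append(sents[rng.randrange(len(sents))])
    return Corpus(sents)


def random_state(rng: random.Random, *, warmup_ops: int = 3,
                 **corpus_kw) -> InductionState:
    """An initial state diversified by a few random legal operators."""
    state = build_initial_grammar(random_corpus(rng, **corpus_kw))
    for _ in range(rng.randint(0, warmup_ops)):
        cands = [inst for inst, _ in enumerate_combine_candidates(state, 4)]
        cands += enumerate_merge_candidates(state)
        rng.shuffle(cands)
        applied = False
        for inst in cands[:8]:
            try:
                trial = state.copy()
                apply_operator(trial, inst)
                trial.check_consistency()
                state = trial
                applied = True
                break
            except Exception:
                continue
        if not applied:
            break
    return state


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
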