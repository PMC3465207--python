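"""Production-probability estimation by hard (Viterbi) EM.

Probabilities start uniform per LHS; each iteration parses every training
sentence, counts production usages in the best parse (or fractionally over
all parses), and renormalizes per LHS.  Five iterations are the default;
convergence is tracked through the corpus best-parse log-probability and
the largest per-production probability change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .grammar import Corpus, Grammar, GrammarError, Production
from .parsing import Pcfg, enumerate_parses, parse_probability, viterbi_parse


class EstimationDegenerateError(GrammarError):
    """No corpus sentence is parsable, so counts cannot be collected."""


@dataclass(frozen=True)
class EmConfig:
    iterations: int = 5
    mode: str = "viterbi"  # or "fractional"
    smoothing_alpha: float = 0.0
    enumeration_limit: int = 5000  # fractional mode only

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise GrammarError("iterations must be >= 0")
        if self.mode not in ("viterbi", "fractional"):
            raise GrammarError(f"unknown EM mode: {self.mode}")
        if self.smoothing_alpha < 0:
            raise GrammarError("smoothing_alpha must be >= 0")


@dataclass
class EmDiagnostics:
    """Per-iteration convergence record.

    ``log2_likelihood`` is the corpus best-parse log2 probability of the
    model *entering* the iteration (the one whose parses are counted);
    ``max_abs_change`` is the largest per-production probability change the
    iteration produced.
    """

    iteration: int
    log2_likelihood: float
    parsable: int
    max_abs_change: float


def init_uniform(grammar: Grammar) -> Pcfg:
    """Uniform probabilities: a nonterminal with k expansions gets 1/k each."""
    prob: dict = {}
    for nt in grammar.nonterminals:
        prods = grammar.expansions(nt)
        if not prods:
            raise GrammarError(f"nonterminal {nt.name} has no production")
        for p in prods:
            prob[p.key] = 1.0 / len(prods)
    return Pcfg(grammar=grammar, prob=prob)


def _viterbi_counts(pcfg: Pcfg, corpus: Corpus) -> tuple[dict, int, float]:
    """Counts from each sentence's single best parse; duplicates weighted."""
    counts: dict = {}
    parsable = 0
    loglik = 0.0
    cache: dict[tuple[str, ...], Optional[tuple[dict, float]]] = {}
    for sent in corpus:
        hit = cache.get(sent)
        if hit is None and sent not in cache:
            outcome = viterbi_parse(pcfg, sent)
            if outcome.ok:
                local: dict = {}
                for node in outcome.tree.iter_nodes():
                    k = node.production_key()
                    local[k] = local.get(k, 0.0) + 1.0
                hit = (local, outcome.log2_probability)
            else:
                hit = None
            cache[sent] = hit
        if hit is None:
            continue
        local, lp = hit
        parsable += 1
        loglik += lp
        for k, c in local.items():
            counts[k] = counts.get(k, 0.0) + c
    return counts, parsable, loglik


def _fractional_counts(pcfg: Pcfg, corpus: Corpus,
                       limit: int) -> tuple[dict, int, float]:
    """Counts from all parses, weighted by normalized parse probability."""
    counts: dict = {}
    parsable = 0
    loglik = 0.0
    cache: dict = {}
    for sent in corpus:
        if sent not in cache:
            forest = enumerate_parses(pcfg.grammar, sent, limit=limit)
            weighted = [(t, parse_probability(pcfg, t)) for t in forest]
            total = sum(w for _, w in weighted)
            if total <= 0.0:
                cache[sent] = None
            else:
                local: dict = {}
                best = 0.0
                for tree, w in weighted:
                    share = w / total
                    best = max(best, w)
                    for node in tree.iter_nodes():
                        k = node.production_key()
                        local[k] = local.get(k, 0.0) + share
                cache[sent] = (local, math.log2(best))
        hit = cache[sent]
        if hit is None:
            continue
        local, lp = hit
        parsable += 1
        loglik += lp
        for k, c in local.items():
            counts[k] = counts.get(k, 0.0) + c
    return counts, parsable, loglik


def em_step(pcfg: Pcfg, corpus: Corpus, config: EmConfig) -> Pcfg:
    """One estimation step: parse, count, renormalize per LHS.

    Unparsable sentences contribute nothing; an LHS never expanded in any
    counted parse keeps its previous distribution.  With smoothing alpha,
    probabilities are ``(usage + alpha) / (total + alpha * k)``.
    """
    new, _ = _em_step_with_diag(pcfg, corpus, config)
    return new


def _em_step_with_diag(pcfg: Pcfg, corpus: Corpus,
                       config: EmConfig) -> tuple[Pcfg, tuple[int, float]]:
    if config.mode == "viterbi":
        counts, parsable, loglik = _viterbi_counts(pcfg, corpus)
    else:
        counts, parsable, loglik = _fractional_counts(pcfg, corpus,
                                                      config.enumeration_limit)
    if parsable == 0:
        raise EstimationDegenerateError("no corpus sentence is parsable")

    grammar = pcfg.grammar
    alpha = config.smoothing_alpha
    prob = dict(pcfg.prob)
    for nt in grammar.nonterminals:
        prods = grammar.expansions(nt)
        if not prods:
            continue
        total = sum(counts.get(p.key, 0.0) for p in prods)
        if total <= 0.0 and alpha == 0.0:
            continue  # retain the previous distribution
        denom = total + alpha * len(prods)
        for p in prods:
            prob[p.key] = (counts.get(p.key, 0.0) + alpha) / denom
    return Pcfg(grammar=grammar, prob=prob), (parsable, loglik)


@dataclass
class EstimateResult:
    pcfg: Pcfg
    diagnostics: list[EmDiagnostics]


def estimate(grammar: Grammar, corpus: Corpus,
             config: EmConfig = EmConfig()) -> EstimateResult:
    """Uniform initialization followed by ``config.iterations`` EM steps.

    Diagnostics carry, for each iteration, the corpus best-parse log2
    likelihood of the model entering the iteration and the largest
    absolute probability change the iteration produced.
    """
    pcfg = init_uniform(grammar)
    diags: list[EmDiagnostics] = []
    for it in range(1, config.iterations + 1):
        new, (parsable, loglik) = _em_step_with_diag(pcfg, corpus, config)
        max_change = max(
            (abs(new.prob[k] - pcfg.prob[k]) for k in new.prob), default=0.0)
        diags.append(EmDiagnostics(iteration=it, log2_likelihood=loglik,
                                   parsable=parsable,
                                   max_abs_change=max_change))
        pcfg = new
    return EstimateResult(pcfg=pcfg, diagnostics=diags)
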