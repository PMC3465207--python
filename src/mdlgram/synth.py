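"""Synthetic tagged-sentence corpora with clinical-report-like statistics.

Real clinical-report tag corpora are access-restricted, so the pipeline is
exercised on corpora sampled from small bundled reference PCFGs: short
sentences over a mixed alphabet of POS-like and semantic-class tags, with
heavy sentence duplication (a Zipf weight over an i.i.d. sample pool makes
a minority of unique sentences account for most of the corpus).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .grammar import (
    NONTERMINAL,
    ORIGIN_SENTENCE,
    ORIGIN_START,
    TERMINAL,
    Corpus,
    Grammar,
    GrammarError,
    InputError,
    Production,
    Symbol,
)
from .parsing import ParseTree, Pcfg, is_recursive

PROFILES = ("tiny", "clinical_like")

_TINY_RULES = [
    ("S", ("X", "Y"), 0.7),
    ("S", ("X", "Y", "X"), 0.3),
    ("X", ("a",), 0.6),
    ("X", ("b",), 0.4),
    ("Y", ("c",), 0.5),
    ("Y", ("d",), 0.5),
]

# 15 POS-like tags + 8 semantic-class tags, ~6 nonterminals, RHS <= 3,
# acyclic, and (by construction) unambiguous: every generated sentence has
# exactly one parse, which keeps probability-recovery oracles exact.
_CLINICAL_RULES = [
    ("S", ("NP", "VP"), 0.40),
    ("S", ("pron", "VP"), 0.15),
    ("S", ("NP", "aux", "adj"), 0.15),
    ("S", ("NG", "conj", "NG"), 0.10),
    ("S", ("NP", "neg", "VP"), 0.10),
    ("S", ("adv", "NP", "VP"), 0.10),
    ("NP", ("NG",), 0.70),
    ("NP", ("NG", "PP"), 0.30),
    ("PP", ("prep", "NG"), 1.00),
    ("NG", ("HEAD",), 0.35),
    ("NG", ("det", "HEAD"), 0.25),
    ("NG", ("adj", "HEAD"), 0.10),
    ("NG", ("det", "adj", "HEAD"), 0.15),
    ("NG", ("num", "HEAD"), 0.10),
    ("NG", ("labvalue", "num"), 0.05),
    ("VP", ("verb",), 0.15),
    ("VP", ("verb", "NP"), 0.25),
    ("VP", ("aux", "vbn"), 0.15),
    ("VP", ("aux", "vbn", "PP"), 0.10),
    ("VP", ("verb", "adv"), 0.10),
    ("VP", ("modal", "verb"), 0.10),
    ("VP", ("verb", "part"), 0.05),
    ("VP", ("to", "verb"), 0.10),
    ("HEAD", ("noun",), 0.30),
    ("HEAD", ("finding",), 0.15),
    ("HEAD", ("disease",), 0.15),
    ("HEAD", ("bodypart",), 0.10),
    ("HEAD", ("device",), 0.10),
    ("HEAD", ("medication",), 0.10),
    ("HEAD", ("procedure",), 0.05),
    ("HEAD", ("symptom",), 0.05),
]


def _build_pcfg(rules: list[tuple[str, tuple[str, ...], float]]) -> Pcfg:
    lhs_names = {l for l, _, _ in rules}
    start_name = rules[0][0]
    symbols: dict[str, Symbol] = {}
    for lhs, rhs, _ in rules:
        for name in (lhs, *rhs):
            if name in symbols:
                continue
            if name in lhs_names:
                origin = ORIGIN_START if name == start_name else ORIGIN_SENTENCE
                symbols[name] = Symbol(name, NONTERMINAL, origin)
            else:
                symbols[name] = Symbol(name, TERMINAL)
    grammar = Grammar(symbols[start_name])
    for sym in symbols.values():
        grammar.add_symbol(sym)
    prob: dict = {}
    for lhs, rhs, p in rules:
        prod = grammar.add_production(
            Production(symbols[lhs], tuple(symbols[r] for r in rhs)))
        prob[prod.key] = p
    pcfg = Pcfg(grammar=grammar, prob=prob)
    pcfg.validate()
    if is_recursive(grammar):
        raise GrammarError("reference grammar must be acyclic")
    return pcfg


def reference_pcfg(name: str) -> Pcfg:
    """A fixed, versioned reference PCFG: ``tiny`` or ``clinical_like``."""
    if name == "tiny":
        return _build_pcfg(_TINY_RULES)
    if name == "clinical_like":
        return _build_pcfg(_CLINICAL_RULES)
    raise InputError(f"unknown profile {name!r}; choose from {PROFILES}")


@dataclass(frozen=True)
class CorpusProfile:
    """Sampling recipe: which reference PCFG, how many sentences, the
    sentence-length cap (enforced by rejection), the Zipf exponent of
    sentence reuse and the split size."""

    name: str = "clinical_like"
    n_sentences: int = 1000
    max_len: int = 10
    duplication: float = 1.2
    seed: int = 0
    test_fraction: float = 0.2
    max_rejects_per_sentence: int = 2000

    def pcfg(self) -> Pcfg:
        return reference_pcfg(self.name)


def sample_tree(pcfg: Pcfg, rng: random.Random, *,
                start: Optional[Symbol] = None, pos: int = 0) -> ParseTree:
    """Sample one derivation tree top-down; spans are laid out from ``pos``."""
    sym = start if start is not None else pcfg.grammar.start
    prods = pcfg.grammar.expansions(sym)
    weights = [pcfg.prob[p.key] for p in prods]
    prod = rng.choices(prods, weights=weights, k=1)[0]
    children: list = []
    cur = pos
    for s in prod.rhs:
        if s.is_terminal:
            children.append(s.name)
            cur += 1
        else:
            sub = sample_tree(pcfg, rng, start=s, pos=cur)
            children.append(sub)
            cur = sub.span[1]
    return ParseTree(label=sym, children=tuple(children), span=(pos, cur))


def _sample_bounded(pcfg: Pcfg, rng: random.Random, max_len: int,
                    cap: int) -> ParseTree:
    for _ in range(cap):
        tree = sample_tree(pcfg, rng)
        if tree.span[1] <= max_len:
            return tree
    raise InputError(
        f"could not sample a sentence of length <= {max_len} in {cap} tries; "
        f"max_len is too small for this grammar")


@dataclass
class SampledCorpus:
    train: Corpus
    test: Corpus
    gold_trees: list[ParseTree]  # parallel to test.sentences


def sample_corpus(profile: CorpusProfile) -> SampledCorpus:
    """Sample, duplicate, and split a corpus; fully reproducible per seed.

    An i.i.d. pool of derivation trees is drawn first; with a positive
    ``duplication`` exponent the corpus is resampled from the pool with
    Zipf weights (rank r gets weight r**-s), so few unique sentences
    dominate.  The train/test split is by sentence occurrence, mirroring a
    protocol where test sentences may duplicate training ones.
    """
    if profile.n_sentences < 2:
        raise InputError("need at least 2 sentences to split")
    pcfg = profile.pcfg()
    rng = random.Random(profile.seed)
    pool = [_sample_bounded(pcfg, rng, profile.max_len,
                            profile.max_rejects_per_sentence)
            for _ in range(profile.n_sentences)]
    if profile.duplication > 0.0:
        weights = [(r + 1) ** (-profile.duplication)
                   for r in range(len(pool))]
        trees = rng.choices(pool, weights=weights, k=profile.n_sentences)
    else:
        trees = pool
    order = list(range(len(trees)))
    rng.shuffle(order)
    n_test = max(1, int(round(profile.test_fraction * len(trees))))
    test_idx, train_idx = order[:n_test], order[n_test:]
    train = Corpus([trees[i].tokens() for i in train_idx])
    test = Corpus([trees[i].tokens() for i in test_idx])
    gold = [trees[i] for i in test_idx]
    return SampledCorpus(train=train, test=test, gold_trees=gold)
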