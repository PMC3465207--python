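"""Core symbolic types for grammars, derivations and corpora, plus encoding costs.

A grammar is scored by the number of bits needed to write it down
(``grammar_cost``) and by the number of bits needed to record, for every
corpus sentence, which production was chosen at each derivation step
(``corpus_derivation_cost``).  The weighted combination of the two is
``total_cost``; the weight ``f`` trades grammar size against derivation
size.  All logarithms are base 2 and all costs are reported in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

TERMINAL = "terminal"
NONTERMINAL = "nonterminal"

#: provenance tags for nonterminals created by the pipeline
ORIGIN_START = "start"
ORIGIN_PRETERMINAL = "preterminal"
ORIGIN_SENTENCE = "sentence"
ORIGIN_COMBINED = "combined"
ORIGIN_MERGED = "merged"

_ORIGINS = {ORIGIN_START, ORIGIN_PRETERMINAL, ORIGIN_SENTENCE,
            ORIGIN_COMBINED, ORIGIN_MERGED}


class GrammarError(ValueError):
    """A structural violation in a grammar or its components."""


class InvalidInventoryError(GrammarError):
    """The symbol inventory is too small for costs to be meaningful."""


class StaleDerivationError(GrammarError):
    """A derivation references a production absent from the grammar."""


class InputError(ValueError):
    """Malformed user-supplied input (corpus, sentence, file)."""


@dataclass(frozen=True)
class Symbol:
    """A terminal tag or a nonterminal.

    ``origin`` records how a nonterminal came to exist (start symbol,
    pre-terminal, per-sentence rule, combine or merge); terminals carry
    ``None``.
    """

    name: str
    kind: str
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise GrammarError(f"symbol name must be non-empty and whitespace-free: {self.name!r}")
        if self.kind not in (TERMINAL, NONTERMINAL):
            raise GrammarError(f"unknown symbol kind: {self.kind!r}")
        if self.origin is not None and self.origin not in _ORIGINS:
            raise GrammarError(f"unknown symbol origin: {self.origin!r}")
        if self.kind == TERMINAL and self.origin is not None:
            raise GrammarError("terminals carry no origin")

    @property
    def is_terminal(self) -> bool:
        return self.kind == TERMINAL

    @property
    def is_nonterminal(self) -> bool:
        return self.kind == NONTERMINAL

    def __repr__(self) -> str:  # compact, for test failure messages
        return self.name


@dataclass(frozen=True)
class Production:
    """A context-free rewrite rule ``lhs -> rhs`` with non-empty ``rhs``."""

    lhs: Symbol
    rhs: tuple[Symbol, ...]

    def __post_init__(self) -> None:
        if not self.lhs.is_nonterminal:
            raise GrammarError(f"production LHS must be a nonterminal: {self.lhs}")
        if len(self.rhs) < 1:
            raise GrammarError("production RHS must be non-empty")
        object.__setattr__(self, "rhs", tuple(self.rhs))

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        return (self.lhs.name, tuple(s.name for s in self.rhs))

    def __repr__(self) -> str:
        return f"{self.lhs.name} -> {' '.join(s.name for s in self.rhs)}"


class Grammar:
    """A CFG: start symbol, symbol inventory and an ordered production set.

    Production order is creation order and is used for deterministic
    tie-breaking everywhere downstream.  Duplicate productions (same LHS
    and RHS) are rejected.  ``sigma_size`` counts terminals *and*
    nonterminals.
    """

    def __init__(self, start: Symbol) -> None:
        if not start.is_nonterminal:
            raise GrammarError("start symbol must be a nonterminal")
        self.start = start
        self._symbols: dict[str, Symbol] = {start.name: start}
        self._productions: list[Production] = []
        self._index: dict[tuple[str, tuple[str, ...]], int] = {}
        self._by_lhs: dict[str, list[Production]] = {}

    # -- inventory ---------------------------------------------------------

    @property
    def inventory(self) -> dict[str, Symbol]:
        return dict(self._symbols)

    @property
    def sigma_size(self) -> int:
        return len(self._symbols)

    def symbol(self, name: str) -> Symbol:
        return self._symbols[name]

    def has_symbol(self, name: str) -> bool:
        return name in self._symbols

    def add_symbol(self, sym: Symbol) -> Symbol:
        prev = self._symbols.get(sym.name)
        if prev is not None:
            if prev != sym:
                raise GrammarError(f"conflicting redefinition of symbol {sym.name!r}")
            return prev
        self._symbols[sym.name] = sym
        return sym

    def remove_symbol(self, name: str) -> None:
        if name == self.start.name:
            raise GrammarError("cannot remove the start symbol")
        for p in self._productions:
            if p.lhs.name == name or any(s.name == name for s in p.rhs):
                raise GrammarError(f"symbol {name!r} still used by {p}")
        del self._symbols[name]

    @property
    def terminals(self) -> list[Symbol]:
        return [s for s in self._symbols.values() if s.is_terminal]

    @property
    def nonterminals(self) -> list[Symbol]:
        return [s for s in self._symbols.values() if s.is_nonterminal]

    # -- productions -------------------------------------------------------

    @property
    def productions(self) -> list[Production]:
        return list(self._productions)

    def __len__(self) -> int:
        return len(self._productions)

    def __iter__(self) -> Iterator[Production]:
        return iter(self._productions)

    def has_production(self, prod: Production) -> bool:
        return prod.key in self._index

    def creation_order(self, prod: Production) -> int:
        try:
            return self._index[prod.key]
        except KeyError:
            raise StaleDerivationError(f"production not in grammar: {prod}") from None

    def add_production(self, prod: Production) -> Production:
        if prod.key in self._index:
            raise GrammarError(f"duplicate production: {prod}")
        for sym in (prod.lhs, *prod.rhs):
            existing = self._symbols.get(sym.name)
            if existing is None:
                raise GrammarError(f"production uses unknown symbol {sym.name!r}: {prod}")
            if existing != sym:
                raise GrammarError(f"symbol {sym.name!r} conflicts with inventory entry")
        self._index[prod.key] = len(self._productions)
        self._productions.append(prod)
        self._by_lhs.setdefault(prod.lhs.name, []).append(prod)
        return prod

    def remove_production(self, prod: Production) -> None:
        if prod.key not in self._index:
            raise GrammarError(f"production not in grammar: {prod}")
        del self._index[prod.key]
        self._productions.remove(prod)
        self._by_lhs[prod.lhs.name].remove(prod)
        if not self._by_lhs[prod.lhs.name]:
            del self._by_lhs[prod.lhs.name]
        # renumber creation order to stay dense & deterministic
        self._index = {p.key: i for i, p in enumerate(self._productions)}

    def expansions(self, nonterminal: str | Symbol) -> list[Production]:
        """All productions whose LHS is the given nonterminal (``P(s)``)."""
        name = nonterminal.name if isinstance(nonterminal, Symbol) else nonterminal
        return list(self._by_lhs.get(name, []))

    def expansion_count(self, nonterminal: str | Symbol) -> int:
        name = nonterminal.name if isinstance(nonterminal, Symbol) else nonterminal
        return len(self._by_lhs.get(name, ()))

    # -- bookkeeping -------------------------------------------------------

    def copy(self) -> "Grammar":
        g = Grammar(self.start)
        for sym in self._symbols.values():
            g.add_symbol(sym)
        for prod in self._productions:
            g.add_production(prod)
        return g

    def validate(self) -> None:
        starts = [s for s in self._symbols.values() if s.origin == ORIGIN_START]
        if len(starts) != 1 or starts[0] != self.start:
            raise GrammarError("exactly one symbol must carry the start origin")
        for prod in self._productions:
            for sym in (prod.lhs, *prod.rhs):
                if self._symbols.get(sym.name) != sym:
                    raise GrammarError(f"{prod} uses symbol outside the inventory")
        for lhs, prods in self._by_lhs.items():
            expected = [p for p in self._productions if p.lhs.name == lhs]
            if prods != expected:
                raise GrammarError(f"expansion index inconsistent for {lhs}")

    def __repr__(self) -> str:
        return f"Grammar(|P|={len(self._productions)}, |Sigma|={self.sigma_size})"


@dataclass
class Derivation:
    """A leftmost derivation of one corpus sentence.

    ``steps`` lists ``(nonterminal, production)`` pairs in leftmost-expansion
    order; replaying them from the start symbol must reproduce the sentence.
    """

    sentence_index: int
    steps: list[tuple[Symbol, Production]]

    def replay(self, grammar: Grammar) -> tuple[str, ...]:
        """Re-run the steps and return the terminal string they yield."""
        stack: list[Symbol] = [grammar.start]
        out: list[str] = []
        it = iter(self.steps)
        while stack:
            sym = stack.pop(0)
            if sym.is_terminal:
                out.append(sym.name)
                continue
            try:
                lhs, prod = next(it)
            except StopIteration:
                raise StaleDerivationError("derivation ran out of steps") from None
            if lhs != sym or prod.lhs != sym:
                raise StaleDerivationError(f"step expands {lhs}, expected {sym}")
            if not grammar.has_production(prod):
                raise StaleDerivationError(f"production not in grammar: {prod}")
            stack[0:0] = list(prod.rhs)
        if next(it, None) is not None:
            raise StaleDerivationError("derivation has leftover steps")
        return tuple(out)


@dataclass
class Corpus:
    """An ordered list of tagged sentences; duplicates are kept."""

    sentences: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        clean = []
        for i, sent in enumerate(self.sentences):
            if len(sent) == 0:
                raise InputError(f"sentence {i} is empty")
            for tok in sent:
                if not tok or any(c.isspace() for c in tok):
                    raise InputError(f"bad token {tok!r} in sentence {i}")
            clean.append(tuple(sent))
        self.sentences = clean

    @property
    def q(self) -> int:
        """Number of sentences, duplicates included."""
        return len(self.sentences)

    def unique_sentences(self) -> list[tuple[str, ...]]:
        """Unique sentences in first-occurrence order."""
        seen: dict[tuple[str, ...], None] = {}
        for s in self.sentences:
            seen.setdefault(s, None)
        return list(seen)

    def terminal_alphabet(self) -> list[str]:
        """Unique tokens in first-occurrence order."""
        seen: dict[str, None] = {}
        for s in self.sentences:
            for t in s:
                seen.setdefault(t, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        return iter(self.sentences)


@dataclass(frozen=True)
class CostWeights:
    """The grammar-vs-derivation weight; ``f`` must lie in [0, 1]."""

    f: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise GrammarError(f"f must be in [0, 1], got {self.f}")


# -- encoding costs --------------------------------------------------------


def production_cost(production: Production, sigma_size: int) -> float:
    """Bits to encode one production: ``(1 + |rhs|) * log2(sigma_size)``."""
    if sigma_size < 2:
        raise InvalidInventoryError(
            f"need at least 2 symbols to assign per-symbol bits, got {sigma_size}")
    return (1 + len(production.rhs)) * math.log2(sigma_size)


def grammar_cost(grammar: Grammar) -> float:
    """Bits to encode the whole grammar at its current inventory size."""
    if len(grammar) == 0:
        return 0.0
    sigma = grammar.sigma_size
    return sum(production_cost(p, sigma) for p in grammar)


def derivation_cost(derivation: Derivation, grammar: Grammar) -> float:
    """Bits to encode one sentence's derivation: sum of log2 |P(s_k)|."""
    total = 0.0
    for lhs, prod in derivation.steps:
        if not grammar.has_production(prod):
            raise StaleDerivationError(f"production not in grammar: {prod}")
        total += math.log2(grammar.expansion_count(lhs))
    return total


def corpus_derivation_cost(derivations: Iterable[Derivation], grammar: Grammar) -> float:
    """Bits to encode every sentence's derivation, duplicates included."""
    return sum(derivation_cost(d, grammar) for d in derivations)


def total_cost(grammar: Grammar, derivations: Iterable[Derivation],
               weights: CostWeights) -> float:
    """``f * grammar_cost + (1 - f) * corpus_derivation_cost`` in bits."""
    return (weights.f * grammar_cost(grammar)
            + (1.0 - weights.f) * corpus_derivation_cost(derivations, grammar))
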