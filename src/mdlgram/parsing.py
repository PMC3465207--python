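"""Parsing with an induced (P)CFG.

The main entry point is :func:`viterbi_parse`, a probabilistic Earley parser
that handles arbitrary right-hand-side lengths without binarization.  Two
exhaustive oracles back the test-suite: :func:`enumerate_parses` lists every
parse tree of a sentence and :func:`language_up_to` enumerates the exact
language of an acyclic grammar up to a length bound.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .grammar import (
    Grammar,
    GrammarError,
    InputError,
    Production,
    Symbol,
)

Leaf = str
Child = Union["ParseTree", Leaf]


@dataclass(frozen=True)
class ParseTree:
    """A labeled constituency tree over a token span.

    ``children`` holds subtrees for nonterminal slots and plain token
    strings for terminal slots; ``span`` is 0-based half-open.
    """

    label: Symbol
    children: tuple[Child, ...]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))

    def tokens(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.children:
            if isinstance(c, ParseTree):
                out.extend(c.tokens())
            else:
                out.append(c)
        return tuple(out)

    def production_key(self) -> tuple[str, tuple[str, ...]]:
        rhs = tuple(c.label.name if isinstance(c, ParseTree) else c
                    for c in self.children)
        return (self.label.name, rhs)

    def iter_nodes(self) -> Iterable["ParseTree"]:
        yield self
        for c in self.children:
            if isinstance(c, ParseTree):
                yield from c.iter_nodes()

    def validate(self) -> None:
        i, j = self.span
        if j - i != len(self.tokens()):
            raise GrammarError("span width disagrees with leaf count")
        pos = i
        for c in self.children:
            if isinstance(c, ParseTree):
                if c.span[0] != pos:
                    raise GrammarError("child spans are not contiguous")
                c.validate()
                pos = c.span[1]
            else:
                pos += 1
        if pos != j:
            raise GrammarError("children do not cover the span")

    def to_sexpr(self) -> str:
        parts = [c.to_sexpr() if isinstance(c, ParseTree) else c
                 for c in self.children]
        return f"({self.label.name} {' '.join(parts)})"

    def __str__(self) -> str:
        return self.to_sexpr()


@dataclass
class Pcfg:
    """A grammar with per-production probabilities, normalized per LHS."""

    grammar: Grammar
    prob: dict[tuple[str, tuple[str, ...]], float]

    def probability(self, prod: Production) -> float:
        return self.prob[prod.key]

    def validate(self, tol: float = 1e-9) -> None:
        for nt in self.grammar.nonterminals:
            prods = self.grammar.expansions(nt)
            if not prods:
                continue
            total = sum(self.prob[p.key] for p in prods)
            if abs(total - 1.0) > tol:
                raise GrammarError(
                    f"probabilities for {nt.name} sum to {total}, not 1")
            for p in prods:
                if not (0.0 <= self.prob[p.key] <= 1.0 + tol):
                    raise GrammarError(f"probability out of range for {p}")


@dataclass
class ParseOutcome:
    """Result of parsing one sentence.

    ``status`` is ``ok``, ``no-parse`` or ``unknown-token``; on success
    ``tree`` and ``probability`` are set (probability is 1.0 in the
    unweighted first-parse mode).
    """

    status: str
    tree: Optional[ParseTree] = None
    probability: Optional[float] = None
    log2_probability: Optional[float] = None
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


# -- derives-relation helpers ---------------------------------------------


def derives_edges(grammar: Grammar) -> dict[str, set[str]]:
    """Adjacency of the derives relation restricted to nonterminals."""
    edges: dict[str, set[str]] = {nt.name: set() for nt in grammar.nonterminals}
    for p in grammar:
        for s in p.rhs:
            if s.is_nonterminal:
                edges[p.lhs.name].add(s.name)
    return edges


def is_recursive(grammar: Grammar) -> bool:
    """True iff some nonterminal derives itself (directly or indirectly)."""
    edges = derives_edges(grammar)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in edges}
    for root in edges:
        if color[root] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(root, iter(edges[root]))]
        color[root] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    return True
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(edges[nxt])))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return False


def _topological_nonterminals(grammar: Grammar) -> list[str]:
    """Nonterminals ordered so that every RHS nonterminal precedes its LHS."""
    edges = derives_edges(grammar)
    order: list[str] = []
    state: dict[str, int] = {}
    def visit(n: str) -> None:
        state[n] = 1
        for m in sorted(edges[n]):
            st = state.get(m)
            if st == 1:
                raise GrammarError("grammar is recursive; language may be infinite")
            if st is None:
                visit(m)
        state[n] = 2
        order.append(n)
    for n in sorted(edges):
        if n not in state:
            visit(n)
    return order


def language_up_to(grammar: Grammar, max_len: int) -> set[tuple[str, ...]]:
    """Exact set of terminal strings of length <= max_len derivable from start.

    Refuses recursive grammars, whose language may be infinite.
    """
    if max_len < 0:
        raise InputError("max_len must be non-negative")
    strings: dict[str, set[tuple[str, ...]]] = {}
    for nt in _topological_nonterminals(grammar):
        acc: set[tuple[str, ...]] = set()
        for prod in grammar.expansions(nt):
            partial: set[tuple[str, ...]] = {()}
            for sym in prod.rhs:
                pieces = ({(sym.name,)} if sym.is_terminal
                          else strings.get(sym.name, set()))
                partial = {a + b for a in partial for b in pieces
                           if len(a) + len(b) <= max_len}
                if not partial:
                    break
            acc |= partial
        strings[nt] = acc
    return strings.get(grammar.start.name, set())


# -- probabilistic Earley --------------------------------------------------


def _check_tokens(grammar: Grammar, sentence: Sequence[str]) -> Optional[str]:
    unknown = [t for t in sentence
               if not grammar.has_symbol(t) or not grammar.symbol(t).is_terminal]
    if unknown:
        return "unknown tokens: " + " ".join(dict.fromkeys(unknown))
    return None


def viterbi_parse(pcfg: Pcfg, sentence: Sequence[str], *,
                  mode: str = "viterbi") -> ParseOutcome:
    """Return a maximum-probability parse of ``sentence``, or a no-parse.

    In ``mode="first"`` every production scores 0 bits and the returned
    parse is the first one under the deterministic tie-break (the
    probability-free baseline).  Ties are broken by the lexicographically
    smallest sequence of production creation orders along the leftmost
    derivation, so parsing is invariant to chart-internal processing order.
    """
    if mode not in ("viterbi", "first"):
        raise InputError(f"unknown parse mode: {mode}")
    grammar = pcfg.grammar
    words = tuple(sentence)
    if len(words) == 0:
        raise InputError("cannot parse an empty sentence")
    reason = _check_tokens(grammar, words)
    if reason is not None:
        return ParseOutcome(status="unknown-token", reason=reason)

    prods = grammar.productions
    n = len(words)
    if mode == "viterbi":
        logp = []
        for p in prods:
            pr = pcfg.prob[p.key]
            logp.append(math.log2(pr) if pr > 0.0 else -math.inf)
    else:
        logp = [0.0] * len(prods)

    exp_idx: dict[str, list[int]] = {}
    for i, p in enumerate(prods):
        exp_idx.setdefault(p.lhs.name, []).append(i)

    # item = (pid, dot, origin); value = (score, key, kids)
    # key = production creation orders along the leftmost derivation so far;
    # kids = children built for rhs[:dot] (token str, or (tree, key) pairs)
    Item = tuple[int, int, int]
    Value = tuple[float, tuple, tuple]
    charts: list[dict[Item, Value]] = [{} for _ in range(n + 1)]
    expecting: list[dict[str, list[Item]]] = [{} for _ in range(n + 1)]
    best_full: Optional[tuple[ParseTree, tuple, float]] = None

    def better(new_score: float, new_key: tuple,
               old_score: float, old_key: tuple) -> bool:
        if new_score != old_score:
            return new_score > old_score
        return new_key < old_key

    for j in range(n + 1):
        chart = charts[j]
        agenda: deque[Item] = deque()

        def offer(item: Item, score: float, key: tuple, kids: tuple) -> None:
            old = chart.get(item)
            if old is None or better(score, key, old[0], old[1]):
                chart[item] = (score, key, kids)
                agenda.append(item)

        if j == 0:
            for pid in exp_idx.get(grammar.start.name, []):
                if logp[pid] > -math.inf:
                    offer((pid, 0, 0), logp[pid], (pid,), ())
        else:
            # scan the token between columns j-1 and j
            w = words[j - 1]
            for item, (score, key, kids) in charts[j - 1].items():
                pid, dot, org = item
                rhs = prods[pid].rhs
                if dot < len(rhs) and rhs[dot].is_terminal and rhs[dot].name == w:
                    offer((pid, dot + 1, org), score, key, kids + (w,))

        predicted: set[str] = set()
        while agenda:
            item = agenda.popleft()
            val = chart.get(item)
            if val is None:
                continue
            score, key, kids = val
            pid, dot, org = item
            rhs = prods[pid].rhs
            if dot < len(rhs):
                sym = rhs[dot]
                if sym.is_terminal:
                    continue  # the next column's scan picks this up
                waiters = expecting[j].setdefault(sym.name, [])
                if item not in waiters:
                    waiters.append(item)
                if sym.name not in predicted:
                    predicted.add(sym.name)
                    for qid in exp_idx.get(sym.name, []):
                        if logp[qid] > -math.inf:
                            offer((qid, 0, j), logp[qid], (qid,), ())
            else:
                # completion: prods[pid].lhs spans (org, j); org < j always
                # because there are no epsilon rules, so expecting[org] is
                # final by the time this runs.
                lhs = prods[pid].lhs
                tree = ParseTree(
                    label=lhs,
                    children=tuple(k[0] if isinstance(k, tuple) else k
                                   for k in kids),
                    span=(org, j))
                for parent in expecting[org].get(lhs.name, ()):
                    ppid, pdot, porg = parent
                    pscore, pkey, pkids = charts[org][parent]
                    offer((ppid, pdot + 1, porg), pscore + score,
                          pkey + key, pkids + ((tree, key),))
                if org == 0 and j == n and lhs.name == grammar.start.name:
                    if best_full is None or better(score, key,
                                                   best_full[2], best_full[1]):
                        best_full = (tree, key, score)

    if best_full is None:
        return ParseOutcome(status="no-parse", reason="no complete parse")
    tree, _key, score = best_full
    if mode == "first":
        return ParseOutcome(status="ok", tree=tree, probability=1.0,
                            log2_probability=0.0)
    return ParseOutcome(status="ok", tree=tree, probability=2.0 ** score,
                        log2_probability=score)


class ParseForest(list):
    """A list of parse trees with a flag marking truncated enumeration."""

    truncated: bool = False


def enumerate_parses(grammar: Grammar, sentence: Sequence[str],
                     limit: int = 10000) -> ParseForest:
    """All distinct parse trees of ``sentence``, up to ``limit``.

    This is the brute-force oracle the Earley parser is checked against.
    On a recursive grammar, unit-cycle re-entries are cut off and the
    result carries ``truncated=True``.
    """
    words = tuple(sentence)
    if len(words) == 0:
        raise InputError("cannot parse an empty sentence")
    forest = ParseForest()
    if _check_tokens(grammar, words) is not None:
        return forest

    on_stack: set[tuple[str, int, int]] = set()
    memo: dict[tuple[str, int, int], list[ParseTree]] = {}

    def seqs(rhs: tuple[Symbol, ...], i: int, j: int) -> list[tuple]:
        """All ways to realize rhs over words[i:j], as child tuples."""
        if not rhs:
            return [()] if i == j else []
        head, rest = rhs[0], rhs[1:]
        out: list[tuple] = []
        if head.is_terminal:
            if i < j and words[i] == head.name:
                for tail in seqs(rest, i + 1, j):
                    out.append((head.name,) + tail)
            return out
        min_rest = len(rest)  # every symbol spans >= 1 token
        for k in range(i + 1, j - min_rest + 1):
            for sub in parses(head.name, i, k):
                for tail in seqs(rest, k, j):
                    out.append((sub,) + tail)
        return out

    def parses(sym: str, i: int, j: int) -> list[ParseTree]:
        state = (sym, i, j)
        if state in memo:
            return memo[state]
        if state in on_stack:
            forest.truncated = True
            return []
        on_stack.add(state)
        trees: list[ParseTree] = []
        for prod in grammar.expansions(sym):
            for kids in seqs(prod.rhs, i, j):
                trees.append(ParseTree(label=prod.lhs, children=kids,
                                       span=(i, j)))
                if len(trees) > limit:
                    forest.truncated = True
        on_stack.discard(state)
        if not forest.truncated:
            memo[state] = trees
        return trees

    for t in parses(grammar.start.name, 0, len(words)):
        if len(forest) >= limit:
            forest.truncated = True
            break
        forest.append(t)
    return forest


def parse_probability(pcfg: Pcfg, tree: ParseTree) -> float:
    """Product of the probabilities of the productions used in ``tree``."""
    prob = 1.0
    for node in tree.iter_nodes():
        prob *= pcfg.prob[node.production_key()]
    return prob
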