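"""Greedy grammar induction by encoding-cost minimization.

Starting from a trivial grammar with one rule per unique training sentence,
the search repeatedly applies the cheapest *combine* (replace a recurring
nonterminal n-gram by a fresh symbol) or *merge* (collapse two nonterminals
into one) operator, each time strictly decreasing the f-weighted total
encoding cost, until no operator instance decreases it further.

Cost deltas are computed exactly — including the ripple of the inventory
size |Sigma| through every production's cost, production deduplication
after a merge, and the resulting changes to every |P(s)| term of the
derivation cost — and the unit tests check them against an
apply-then-recompute oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .grammar import (
    NONTERMINAL,
    ORIGIN_COMBINED,
    ORIGIN_MERGED,
    ORIGIN_PRETERMINAL,
    ORIGIN_START,
    TERMINAL,
    Corpus,
    CostWeights,
    Derivation,
    Grammar,
    GrammarError,
    InputError,
    Production,
    Symbol,
    corpus_derivation_cost,
    grammar_cost,
    total_cost,
)

DEFAULT_BLOCKED_TAGS = frozenset({"verb", "det", "prep", "aux", "conj"})

#: deltas closer to zero than this are treated as "no improvement"
_DELTA_EPS = 1e-9


class StaleCandidateError(GrammarError):
    """An operator instance no longer applies to the current state."""


@dataclass(frozen=True)
class OperatorInstance:
    """One applicable grammar transformation.

    For ``combine`` the operands are an ordered nonterminal n-gram; for
    ``merge`` an unordered (stored sorted) pair of nonterminals.  The new
    symbol name is assigned when the instance is created, from the owning
    state's C/M counters.
    """

    kind: str  # "combine" | "merge"
    operands: tuple[str, ...]
    new_symbol_name: str

    def __post_init__(self) -> None:
        if self.kind == "combine":
            if len(self.operands) < 2:
                raise GrammarError("combine needs at least 2 operands")
        elif self.kind == "merge":
            if len(self.operands) != 2 or self.operands[0] == self.operands[1]:
                raise GrammarError("merge needs two distinct operands")
        else:
            raise GrammarError(f"unknown operator kind: {self.kind}")


@dataclass(frozen=True)
class InductionConfig:
    weights: CostWeights = CostWeights(0.5)
    max_n: int = 4
    forbid_recursion: bool = True
    blocked_tags: frozenset[str] = DEFAULT_BLOCKED_TAGS
    enforce_blocklist: bool = True

    def __post_init__(self) -> None:
        if self.max_n < 2:
            raise GrammarError("max_n must be >= 2")
        object.__setattr__(self, "blocked_tags", frozenset(self.blocked_tags))


class _DNode:
    """A mutable derivation-tree node; ``kids`` parallels ``prod.rhs`` with
    ``None`` in terminal slots.  Duplicate corpus sentences share nodes, so
    one in-place rewrite updates every copy."""

    __slots__ = ("prod", "kids")

    def __init__(self, prod: Production, kids: list[Optional["_DNode"]]):
        self.prod = prod
        self.kids = kids

    def steps(self) -> list[tuple[Symbol, Production]]:
        """Leftmost-expansion (preorder) step sequence."""
        out = [(self.prod.lhs, self.prod)]
        for kid in self.kids:
            if kid is not None:
                out.extend(kid.steps())
        return out

    def copy(self, prod_map: dict) -> "_DNode":
        return _DNode(prod_map.get(self.prod.key, self.prod),
                      [k.copy(prod_map) if k is not None else None
                       for k in self.kids])


class InductionState:
    """Grammar plus one derivation tree per corpus sentence.

    ``trees`` holds one shared node per unique sentence; ``sentence_trees``
    maps corpus order (duplicates included) onto them.
    """

    def __init__(self, grammar: Grammar, corpus: Corpus,
                 sentence_trees: list[_DNode],
                 combine_counter: int = 0, merge_counter: int = 0):
        self.grammar = grammar
        self.corpus = corpus
        self.sentence_trees = sentence_trees
        self.combine_counter = combine_counter
        self.merge_counter = merge_counter

    # -- views -------------------------------------------------------------

    @property
    def derivations(self) -> list[Derivation]:
        return [Derivation(sentence_index=i, steps=t.steps())
                for i, t in enumerate(self.sentence_trees)]

    def unique_nodes(self) -> list[_DNode]:
        seen: dict[int, _DNode] = {}
        stack = []
        for t in self.sentence_trees:
            if id(t) not in seen:
                seen[id(t)] = t
                stack.append(t)
        out: list[_DNode] = []
        while stack:
            node = stack.pop()
            out.append(node)
            for kid in node.kids:
                if kid is not None and id(kid) not in seen:
                    seen[id(kid)] = kid
                    stack.append(kid)
        return out

    def occurrence_index(self) -> dict[str, set[tuple[Production, int]]]:
        """Nonterminal name -> set of (production, RHS position)."""
        idx: dict[str, set[tuple[Production, int]]] = {}
        for p in self.grammar:
            for pos, sym in enumerate(p.rhs):
                if sym.is_nonterminal:
                    idx.setdefault(sym.name, set()).add((p, pos))
        return idx

    def derivation_index(self) -> dict[tuple[str, tuple[str, ...]],
                                       set[tuple[int, int]]]:
        """Production key -> set of (sentence index, leftmost step index)."""
        idx: dict[tuple[str, tuple[str, ...]], set[tuple[int, int]]] = {}
        for si, tree in enumerate(self.sentence_trees):
            for step_i, (_, prod) in enumerate(tree.steps()):
                idx.setdefault(prod.key, set()).add((si, step_i))
        return idx

    def usage_counts(self) -> dict[str, int]:
        """Derivation uses per nonterminal, duplicates included."""
        # count uses once per unique tree, then weight by multiplicity
        tree_count: dict[int, int] = {}
        tree_by_id: dict[int, _DNode] = {}
        for t in self.sentence_trees:
            tree_count[id(t)] = tree_count.get(id(t), 0) + 1
            tree_by_id[id(t)] = t
        totals: dict[str, int] = {}
        for tid, mult in tree_count.items():
            stack = [tree_by_id[tid]]
            while stack:
                node = stack.pop()
                name = node.prod.lhs.name
                totals[name] = totals.get(name, 0) + mult
                for kid in node.kids:
                    if kid is not None:
                        stack.append(kid)
        return totals

    def check_consistency(self) -> None:
        self.grammar.validate()
        for i, deriv in enumerate(self.derivations):
            sent = deriv.replay(self.grammar)
            if sent != self.corpus.sentences[i]:
                raise GrammarError(f"derivation {i} yields {sent}")

    def copy(self) -> "InductionState":
        g = self.grammar.copy()
        node_map: dict[int, _DNode] = {}

        def cp(node: _DNode) -> _DNode:
            if id(node) in node_map:
                return node_map[id(node)]
            new = _DNode(node.prod,
                         [cp(k) if k is not None else None for k in node.kids])
            node_map[id(node)] = new
            return new

        return InductionState(g, self.corpus,
                              [cp(t) for t in self.sentence_trees],
                              self.combine_counter, self.merge_counter)

    def fresh_name(self, prefix: str, counter: int) -> tuple[str, int]:
        """Next unused C<i> / M<i> name, skipping inventory collisions."""
        while True:
            counter += 1
            name = f"{prefix}{counter}"
            if not self.grammar.has_symbol(name):
                return name, counter


# -- initial grammar -------------------------------------------------------


def _preterminal_name(token: str, taken: set[str]) -> str:
    candidates = []
    upper = token.upper()
    if upper != token:
        candidates.append(upper)
    candidates.append(f"W_{token}")
    i = 2
    for cand in candidates:
        if cand not in taken:
            return cand
    while f"W_{token}_{i}" in taken:
        i += 1
    return f"W_{token}_{i}"


def build_initial_grammar(corpus: Corpus) -> InductionState:
    """The trivial most-specific grammar: one rule per unique sentence.

    Each unique terminal gets one shared pre-terminal ``W -> w``; each
    unique sentence ``w1..wn`` gets ``S -> W1..Wn``.  Every corpus sentence
    (duplicates included) gets a derivation.
    """
    if corpus.q == 0:
        raise InputError("corpus is empty")
    alphabet = corpus.terminal_alphabet()
    taken = set(alphabet)
    start_name = "S"
    while start_name in taken:
        start_name += "_"
    start = Symbol(start_name, NONTERMINAL, ORIGIN_START)
    taken.add(start_name)

    grammar = Grammar(start)
    terms: dict[str, Symbol] = {}
    preterms: dict[str, Symbol] = {}
    preterm_prods: dict[str, Production] = {}
    for tok in alphabet:
        terms[tok] = grammar.add_symbol(Symbol(tok, TERMINAL))
    for tok in alphabet:
        name = _preterminal_name(tok, taken)
        taken.add(name)
        preterms[tok] = grammar.add_symbol(
            Symbol(name, NONTERMINAL, ORIGIN_PRETERMINAL))

    sentence_prods: dict[tuple[str, ...], Production] = {}
    for sent in corpus.unique_sentences():
        prod = Production(start, tuple(preterms[t] for t in sent))
        if not grammar.has_production(prod):
            grammar.add_production(prod)
        sentence_prods[sent] = prod
    for tok in alphabet:
        preterm_prods[tok] = grammar.add_production(
            Production(preterms[tok], (terms[tok],)))

    unique_tree: dict[tuple[str, ...], _DNode] = {}
    for sent in corpus.unique_sentences():
        kids: list[Optional[_DNode]] = [
            _DNode(preterm_prods[t], [None]) for t in sent]
        unique_tree[sent] = _DNode(sentence_prods[sent], kids)
    sentence_trees = [unique_tree[s] for s in corpus.sentences]
    return InductionState(grammar, corpus, sentence_trees)


# -- candidate enumeration -------------------------------------------------


def _ngram_counts(grammar: Grammar, max_n: int) -> dict[tuple[str, ...], int]:
    """Corpus-wide non-overlapping RHS occurrence counts of NT n-grams."""
    counts: dict[tuple[str, ...], int] = {}
    for prod in grammar:
        rhs = prod.rhs
        L = len(rhs)
        nt = [s.is_nonterminal for s in rhs]
        names = [s.name for s in rhs]
        # collect overlapping match positions per gram, then tile greedily
        positions: dict[tuple[str, ...], list[int]] = {}
        for n in range(2, max_n + 1):
            for i in range(L - n + 1):
                if all(nt[i:i + n]):
                    positions.setdefault(tuple(names[i:i + n]), []).append(i)
        for gram, pos_list in positions.items():
            n = len(gram)
            last_end = -1
            c = 0
            for p in pos_list:
                if p >= last_end:
                    c += 1
                    last_end = p + n
            counts[gram] = counts.get(gram, 0) + c
    return counts


def enumerate_combine_candidates(
        state: InductionState, max_n: int = 4
) -> list[tuple[OperatorInstance, int]]:
    """Every contiguous nonterminal n-gram (2 <= n <= max_n) on some RHS,
    with its corpus-wide left-to-right non-overlapping occurrence count."""
    name, _ = state.fresh_name("C", state.combine_counter)
    out = []
    for gram, count in _ngram_counts(state.grammar, max_n).items():
        inst = OperatorInstance("combine", gram, name)
        out.append((inst, count))
    out.sort(key=lambda ic: (-len(ic[0].operands), ic[0].operands))
    return out


def enumerate_merge_candidates(state: InductionState) -> list[OperatorInstance]:
    """All unordered pairs of distinct nonterminals, start symbol excluded."""
    name, _ = state.fresh_name("M", state.merge_counter)
    nts = sorted(nt.name for nt in state.grammar.nonterminals
                 if nt.name != state.grammar.start.name)
    out = []
    for i in range(len(nts)):
        for j in range(i + 1, len(nts)):
            out.append(OperatorInstance("merge", (nts[i], nts[j]), name))
    return out


# -- per-iteration context -------------------------------------------------


class _IterContext:
    """Shared per-iteration statistics for exact delta computation and
    constraint checking."""

    def __init__(self, state: InductionState,
                 config: Optional[InductionConfig] = None):
        g = state.grammar
        self.sigma = g.sigma_size
        self.prods = g.productions
        self.T = sum(1 + len(p.rhs) for p in self.prods)
        self.pcount: dict[str, int] = {}
        self.by_sym: dict[str, set[int]] = {}
        for i, p in enumerate(self.prods):
            self.pcount[p.lhs.name] = self.pcount.get(p.lhs.name, 0) + 1
            self.by_sym.setdefault(p.lhs.name, set()).add(i)
            for s in p.rhs:
                if s.is_nonterminal:
                    self.by_sym.setdefault(s.name, set()).add(i)
        self.usage = state.usage_counts()
        self.cd = sum(u * math.log2(self.pcount[s])
                      for s, u in self.usage.items() if s in self.pcount)
        self.cg = self.T * math.log2(self.sigma) if self.prods else 0.0

        # reachability bitmasks over nonterminals (derives relation)
        self.nt_names = sorted(n.name for n in g.nonterminals)
        self.nt_bit = {n: 1 << i for i, n in enumerate(self.nt_names)}
        edges: dict[str, set[str]] = {n: set() for n in self.nt_names}
        for p in self.prods:
            for s in p.rhs:
                if s.is_nonterminal:
                    edges[p.lhs.name].add(s.name)
        self.edges = edges
        self.reach = self._closure(edges)
        redges: dict[str, set[str]] = {n: set() for n in self.nt_names}
        for a, outs in edges.items():
            for b in outs:
                redges[b].add(a)
        self.ancestors = self._closure(redges)

        self.blocked_tags: frozenset[str] = (
            config.blocked_tags if config is not None else frozenset())
        blocked: set[str] = set()
        # fixpoint: NT is blocked iff some RHS holds a blocked terminal
        # or a blocked nonterminal
        changed = True
        direct = {p.lhs.name for p in self.prods
                  if any(s.is_terminal and s.name in self.blocked_tags
                         for s in p.rhs)}
        blocked |= direct
        while changed:
            changed = False
            for p in self.prods:
                if p.lhs.name not in blocked and any(
                        s.is_nonterminal and s.name in blocked for s in p.rhs):
                    blocked.add(p.lhs.name)
                    changed = True
        self.blocked = blocked
        # nonterminals occurring at RHS position >= 2 (1-based) anywhere
        self.tail_occupants: set[str] = set()
        for p in self.prods:
            for s in p.rhs[1:]:
                if s.is_nonterminal:
                    self.tail_occupants.add(s.name)

    def _closure(self, edges: dict[str, set[str]]) -> dict[str, int]:
        """Transitive (non-reflexive unless cyclic) closure as bitmasks."""
        masks: dict[str, int] = {}
        state: dict[str, int] = {}

        def visit(n: str) -> int:
            st = state.get(n)
            if st == 2:
                return masks[n]
            if st == 1:
                return masks.get(n, 0)  # cycle: partial mask, refined below
            state[n] = 1
            masks[n] = 0
            m = 0
            for child in edges[n]:
                m |= self.nt_bit[child] | visit(child)
            masks[n] = m
            state[n] = 2
            return m

        for n in self.nt_names:
            visit(n)
        # iterate to a fixpoint so cyclic graphs are handled too
        changed = True
        while changed:
            changed = False
            for n in self.nt_names:
                m = masks[n]
                for child in edges[n]:
                    m |= self.nt_bit[child] | masks[child]
                if m != masks[n]:
                    masks[n] = m
                    changed = True
        return masks

    def reaches(self, a: str, b: str) -> bool:
        return bool(self.reach[a] & self.nt_bit[b])


# -- constraints -----------------------------------------------------------


def violates_constraints(state: InductionState, instance: OperatorInstance,
                         config: InductionConfig,
                         _ctx: Optional[_IterContext] = None
                         ) -> tuple[bool, str]:
    """Would applying ``instance`` create a recursive production chain or
    put a blocked-tag-derived nonterminal at RHS position >= 2 where the
    pre-image symbol was not already blocked?

    Returns ``(violates, reason)``.
    """
    ctx = _ctx if _ctx is not None else _IterContext(state, config)
    if instance.kind == "combine":
        # a fresh symbol cannot close a cycle, so only the blocklist applies
        if config.enforce_blocklist:
            for name in instance.operands[1:]:
                if name in ctx.blocked:
                    return True, (f"{name} derives a blocked tag and would sit "
                                  f"at RHS position >= 2 of the new production")
        return False, ""

    x, y = instance.operands
    if x not in ctx.nt_bit or y not in ctx.nt_bit:
        raise StaleCandidateError(f"nonterminal gone: {instance.operands}")
    if config.forbid_recursion:
        if ctx.reaches(x, y) or ctx.reaches(y, x):
            return True, f"merging {x} and {y} creates a derives-cycle"
    if config.enforce_blocklist:
        xb, yb = x in ctx.blocked, y in ctx.blocked
        if xb != yb:
            unblocked = y if xb else x
            newly = [unblocked] + [
                n for n in ctx.nt_names
                if (ctx.ancestors[unblocked] & ctx.nt_bit[n])
                and n not in ctx.blocked]
            for n in newly:
                if n in ctx.tail_occupants:
                    return True, (
                        f"merging {x} and {y} newly blocks {n}, which sits at "
                        f"RHS position >= 2")
    return False, ""


# -- exact deltas ----------------------------------------------------------

_MERGE_SENTINEL = "\x00M"


def _combine_delta(ctx: _IterContext, gram: tuple[str, ...],
                   weights: CostWeights) -> float:
    n = len(gram)
    count = 0
    gram_l = list(gram)
    for i in ctx.by_sym.get(gram[0], ()):  # productions containing gram[0]
        rhs = ctx.prods[i].rhs
        L = len(rhs)
        j = 0
        while j <= L - n:
            if all(rhs[j + k].name == gram_l[k] and rhs[j + k].is_nonterminal
                   for k in range(n)):
                count += 1
                j += n
            else:
                j += 1
    if count == 0:
        raise StaleCandidateError(f"n-gram no longer occurs: {gram}")
    t_after = ctx.T - count * (n - 1) + (1 + n)
    d_cg = t_after * math.log2(ctx.sigma + 1) - ctx.cg
    # the new symbol has exactly one expansion, so derivation cost is
    # unchanged: its choice points cost log2(1) = 0 bits
    return weights.f * d_cg


def _merge_delta(ctx: _IterContext, x: str, y: str,
                 weights: CostWeights) -> float:
    if x not in ctx.by_sym and x not in ctx.pcount:
        raise StaleCandidateError(f"nonterminal gone: {x}")
    affected = sorted(ctx.by_sym.get(x, set()) | ctx.by_sym.get(y, set()))
    groups: dict[tuple[str, tuple[str, ...]], list[int]] = {}
    for i in affected:
        p = ctx.prods[i]
        lhs = _MERGE_SENTINEL if p.lhs.name in (x, y) else p.lhs.name
        rhs = tuple(_MERGE_SENTINEL if s.name in (x, y) else s.name
                    for s in p.rhs)
        groups.setdefault((lhs, rhs), []).append(i)

    delta_t = 0
    removed_by_lhs: dict[str, int] = {}
    for (lhs, rhs), members in groups.items():
        extra = len(members) - 1
        if extra:
            delta_t -= extra * (1 + len(rhs))
            removed_by_lhs[lhs] = removed_by_lhs.get(lhs, 0) + extra

    sigma_after = ctx.sigma - 1
    d_cg = (ctx.T + delta_t) * math.log2(sigma_after) - ctx.cg

    ux = ctx.usage.get(x, 0)
    uy = ctx.usage.get(y, 0)
    px = ctx.pcount.get(x, 0)
    py = ctx.pcount.get(y, 0)
    pm = px + py - removed_by_lhs.get(_MERGE_SENTINEL, 0)
    d_cd = 0.0
    if px:
        d_cd -= ux * math.log2(px)
    if py:
        d_cd -= uy * math.log2(py)
    if pm:
        d_cd += (ux + uy) * math.log2(pm)
    for lhs, removed in removed_by_lhs.items():
        if lhs == _MERGE_SENTINEL:
            continue
        before = ctx.pcount[lhs]
        after = before - removed
        d_cd += ctx.usage.get(lhs, 0) * (math.log2(after) - math.log2(before))
    return weights.f * d_cg + (1.0 - weights.f) * d_cd


def estimate_delta(state: InductionState, instance: OperatorInstance,
                   weights: CostWeights,
                   _ctx: Optional[_IterContext] = None) -> float:
    """Exact change in total cost if ``instance`` were applied.

    Equals ``total_cost(after) - total_cost(before)`` to within floating
    point; negative means improvement.
    """
    ctx = _ctx if _ctx is not None else _IterContext(state)
    if instance.kind == "combine":
        return _combine_delta(ctx, instance.operands, weights)
    return _merge_delta(ctx, instance.operands[0], instance.operands[1],
                        weights)


# -- operator application --------------------------------------------------


def _rewrite_combine(rhs: tuple[Symbol, ...], gram: tuple[str, ...],
                     new_sym: Symbol) -> tuple[tuple[Symbol, ...], list[int]]:
    """Replace left-to-right non-overlapping occurrences; also return the
    match start positions (in the OLD rhs coordinates)."""
    n = len(gram)
    out: list[Symbol] = []
    matches: list[int] = []
    j = 0
    L = len(rhs)
    while j < L:
        if (j <= L - n
                and all(rhs[j + k].name == gram[k] and rhs[j + k].is_nonterminal
                        for k in range(n))):
            out.append(new_sym)
            matches.append(j)
            j += n
        else:
            out.append(rhs[j])
            j += 1
    return tuple(out), matches


def apply_operator(state: InductionState,
                   instance: OperatorInstance) -> InductionState:
    """Apply a combine or merge in place; returns the same (mutated) state.

    Production creation order is preserved for surviving productions;
    combine appends its defining production at the end.  Derivation trees
    are rewired so that every corpus sentence keeps a valid derivation.
    """
    if instance.kind == "combine":
        return _apply_combine(state, instance)
    return _apply_merge(state, instance)


def _apply_combine(state: InductionState,
                   instance: OperatorInstance) -> InductionState:
    g = state.grammar
    gram = instance.operands
    n = len(gram)
    for name in gram:
        if not g.has_symbol(name) or not g.symbol(name).is_nonterminal:
            raise StaleCandidateError(f"operand gone: {name}")
    name, _ = state.fresh_name("C", state.combine_counter)
    if instance.new_symbol_name and not g.has_symbol(instance.new_symbol_name):
        name = instance.new_symbol_name
    new_sym = Symbol(name, NONTERMINAL, ORIGIN_COMBINED)

    rewrites: dict[tuple[str, tuple[str, ...]],
                   tuple[Production, list[int]]] = {}
    new_prods: list[Production] = []
    any_match = False
    for prod in g:
        new_rhs, matches = _rewrite_combine(prod.rhs, gram, new_sym)
        if matches:
            any_match = True
            new_prod = Production(prod.lhs, new_rhs)
            rewrites[prod.key] = (new_prod, matches)
            new_prods.append(new_prod)
        else:
            new_prods.append(prod)
    if not any_match:
        raise StaleCandidateError(f"n-gram no longer occurs: {gram}")
    defining = Production(new_sym, tuple(g.symbol(s) for s in gram))
    new_prods.append(defining)

    g2 = Grammar(g.start)
    for sym in g.inventory.values():
        g2.add_symbol(sym)
    g2.add_symbol(new_sym)
    seen: set[tuple[str, tuple[str, ...]]] = set()
    for p in new_prods:
        if p.key in seen:
            continue  # defensive; combine rewriting is injective
        seen.add(p.key)
        g2.add_production(p)

    # rewire derivation trees: group matched kid runs under a new node
    for node in state.unique_nodes():
        hit = rewrites.get(node.prod.key)
        if hit is None:
            continue
        new_prod, matches = hit
        old_kids = node.kids
        match_set = set(matches)
        kids: list[Optional[_DNode]] = []
        j = 0
        while j < len(old_kids):
            if j in match_set:
                sub = _DNode(defining, old_kids[j:j + n])
                kids.append(sub)
                j += n
            else:
                kids.append(old_kids[j])
                j += 1
        node.prod = new_prod
        node.kids = kids

    state.grammar = g2
    state.combine_counter = max(state.combine_counter, _suffix_int(name, "C"))
    return state


def _apply_merge(state: InductionState,
                 instance: OperatorInstance) -> InductionState:
    g = state.grammar
    x, y = instance.operands
    for nm in (x, y):
        if not g.has_symbol(nm) or not g.symbol(nm).is_nonterminal:
            raise StaleCandidateError(f"operand gone: {nm}")
        if nm == g.start.name:
            raise StaleCandidateError("cannot merge the start symbol")
    name, _counter = state.fresh_name("M", state.merge_counter)
    if instance.new_symbol_name and not g.has_symbol(instance.new_symbol_name):
        name = instance.new_symbol_name
    new_sym = Symbol(name, NONTERMINAL, ORIGIN_MERGED)

    def map_sym(s: Symbol) -> Symbol:
        return new_sym if s.name in (x, y) else s

    canonical: dict[tuple[str, tuple[str, ...]], Production] = {}
    prod_map: dict[tuple[str, tuple[str, ...]], Production] = {}
    ordered: list[Production] = []
    for prod in g:
        new_prod = Production(map_sym(prod.lhs),
                              tuple(map_sym(s) for s in prod.rhs))
        kept = canonical.get(new_prod.key)
        if kept is None:
            canonical[new_prod.key] = new_prod
            ordered.append(new_prod)
            kept = new_prod
        prod_map[prod.key] = kept

    g2 = Grammar(g.start)
    for sym in g.inventory.values():
        if sym.name not in (x, y):
            g2.add_symbol(sym)
    g2.add_symbol(new_sym)
    for p in ordered:
        g2.add_production(p)

    for node in state.unique_nodes():
        node.prod = prod_map[node.prod.key]

    state.grammar = g2
    state.merge_counter = max(state.merge_counter, _suffix_int(name, "M"))
    return state


def _suffix_int(name: str, prefix: str) -> int:
    try:
        return int(name[len(prefix):]) if name.startswith(prefix) else 0
    except ValueError:
        return 0


# -- greedy search ---------------------------------------------------------


@dataclass
class TraceRecord:
    step: int
    operator: str  # "init", "combine", "merge"
    operands: tuple[str, ...]
    new_symbol: str
    delta: float
    grammar_cost: float
    derivation_cost: float
    total: float


@dataclass
class InductionResult:
    grammar: Grammar
    state: InductionState
    trace: list[TraceRecord]

    @property
    def derivations(self) -> list[Derivation]:
        return self.state.derivations

    @property
    def cost_trace(self) -> list[float]:
        return [r.total for r in self.trace]


def induce(corpus: Corpus, config: InductionConfig) -> InductionResult:
    """Greedy minimum-cost search over combine/merge instances.

    Both operator families are evaluated in a single loop; the legal
    instance with the most negative exact delta is applied; the search
    stops when no instance strictly decreases the total cost.  Ties are
    broken deterministically: combine before merge, longer n-grams first,
    then lexicographic operand order.
    """
    state = build_initial_grammar(corpus)
    weights = config.weights
    cg = grammar_cost(state.grammar)
    cd = corpus_derivation_cost(state.derivations, state.grammar)
    total = weights.f * cg + (1 - weights.f) * cd
    trace = [TraceRecord(0, "init", (), "", 0.0, cg, cd, total)]

    step = 0
    while True:
        ctx = _IterContext(state, config)
        best: Optional[tuple[tuple, float, OperatorInstance]] = None

        for inst, _count in enumerate_combine_candidates(state, config.max_n):
            bad, _ = violates_constraints(state, inst, config, ctx)
            if bad:
                continue
            delta = _combine_delta(ctx, inst.operands, weights)
            if delta < -_DELTA_EPS:
                rank = (delta, 0, -len(inst.operands), inst.operands)
                if best is None or rank < best[0]:
                    best = (rank, delta, inst)

        for inst in enumerate_merge_candidates(state):
            bad, _ = violates_constraints(state, inst, config, ctx)
            if bad:
                continue
            delta = _merge_delta(ctx, inst.operands[0], inst.operands[1],
                                 weights)
            if delta < -_DELTA_EPS:
                rank = (delta, 1, -2, inst.operands)
                if best is None or rank < best[0]:
                    best = (rank, delta, inst)

        if best is None:
            break
        _, delta, inst = best
        apply_operator(state, inst)
        step += 1
        cg = grammar_cost(state.grammar)
        cd = corpus_derivation_cost(state.derivations, state.grammar)
        total = weights.f * cg + (1 - weights.f) * cd
        trace.append(TraceRecord(step, inst.kind, inst.operands,
                                 inst.new_symbol_name, delta, cg, cd, total))

    return InductionResult(state.grammar, state, trace)
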