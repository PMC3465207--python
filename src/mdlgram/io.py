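"""Text file formats: corpora, grammars/PCFGs, trees, reports, manifests.

Everything is plain UTF-8 text so runs are diffable.  The grammar format
round-trips symbol kinds and origins and (when present) per-production
probabilities at full precision:

    #start: S
    #symbol: S nonterminal start
    #symbol: det terminal -
    S -> DET NOUN <TAB> 0.5
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .grammar import (
    NONTERMINAL,
    TERMINAL,
    Corpus,
    Grammar,
    GrammarError,
    InputError,
    Production,
    Symbol,
)
from .parsing import ParseTree, Pcfg

PathLike = Union[str, Path]


# -- corpus ----------------------------------------------------------------


def read_corpus(path: PathLike) -> Corpus:
    """One sentence per non-blank line, tokens split on whitespace."""
    text = Path(path).read_text(encoding="utf-8")
    sentences = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        toks = line.split()
        if not toks:
            continue
        sentences.append(tuple(toks))
    if not sentences:
        raise InputError(f"{path}: no sentences found")
    return Corpus(sentences)


def write_corpus(path: PathLike, corpus: Corpus) -> None:
    Path(path).write_text(
        "".join(" ".join(s) + "\n" for s in corpus.sentences),
        encoding="utf-8")


# -- grammar / pcfg --------------------------------------------------------


def write_grammar(path: PathLike, grammar_or_pcfg: Union[Grammar, Pcfg]) -> None:
    if isinstance(grammar_or_pcfg, Pcfg):
        grammar, prob = grammar_or_pcfg.grammar, grammar_or_pcfg.prob
    else:
        grammar, prob = grammar_or_pcfg, None
    lines = [f"#start: {grammar.start.name}"]
    for sym in grammar.inventory.values():
        origin = sym.origin if sym.origin is not None else "-"
        lines.append(f"#symbol: {sym.name} {sym.kind} {origin}")
    for p in grammar:
        rule = f"{p.lhs.name} -> {' '.join(s.name for s in p.rhs)}"
        if prob is not None:
            rule += f"\t{prob[p.key]:.17g}"
        lines.append(rule)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_grammar(path: PathLike) -> Union[Grammar, Pcfg]:
    """Read a grammar file; returns a Pcfg when probabilities are present."""
    start_name: Optional[str] = None
    symbols: dict[str, Symbol] = {}
    rules: list[tuple[str, tuple[str, ...], Optional[float], int]] = []
    for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#start:"):
            start_name = line.split(":", 1)[1].strip()
            continue
        if line.startswith("#symbol:"):
            parts = line.split(":", 1)[1].split()
            if len(parts) != 3:
                raise InputError(f"{path}:{lineno}: bad symbol line")
            name, kind, origin = parts
            try:
                symbols[name] = Symbol(name, kind,
                                       None if origin == "-" else origin)
            except GrammarError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            continue
        if line.startswith("#"):
            continue
        prob: Optional[float] = None
        if "\t" in raw:
            rule_part, prob_part = raw.split("\t", 1)
            try:
                prob = float(prob_part.strip())
            except ValueError:
                raise InputError(f"{path}:{lineno}: bad probability") from None
        else:
            rule_part = raw
        if "->" not in rule_part:
            raise InputError(f"{path}:{lineno}: expected 'LHS -> RHS'")
        lhs_s, rhs_s = rule_part.split("->", 1)
        lhs, rhs = lhs_s.strip(), tuple(rhs_s.split())
        if not lhs or not rhs:
            raise InputError(f"{path}:{lineno}: empty LHS or RHS")
        rules.append((lhs, rhs, prob, lineno))
    if start_name is None:
        raise InputError(f"{path}: missing '#start:' line")

    if not symbols:
        # legacy header-less file: LHS names are nonterminals, rest terminals
        lhs_names = {l for l, _, _, _ in rules} | {start_name}
        for l, rhs, _, _ in rules:
            for name in (l, *rhs):
                if name not in symbols:
                    kind = NONTERMINAL if name in lhs_names else TERMINAL
                    origin = "start" if name == start_name else None
                    symbols[name] = Symbol(name, kind, origin)
    if start_name not in symbols:
        raise InputError(f"{path}: start symbol {start_name!r} undeclared")

    grammar = Grammar(symbols[start_name])
    for sym in symbols.values():
        grammar.add_symbol(sym)
    probs: dict = {}
    has_prob = any(p is not None for _, _, p, _ in rules)
    for lhs, rhs, prob, lineno in rules:
        try:
            prod = grammar.add_production(
                Production(symbols[lhs], tuple(symbols[r] for r in rhs)))
        except KeyError as exc:
            raise InputError(f"{path}:{lineno}: undeclared symbol {exc}") from exc
        except GrammarError as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from exc
        if has_prob:
            if prob is None:
                raise InputError(f"{path}:{lineno}: missing probability")
            probs[prod.key] = prob
    if has_prob:
        pcfg = Pcfg(grammar=grammar, prob=probs)
        pcfg.validate(tol=1e-6)
        return pcfg
    return grammar


# -- trees -----------------------------------------------------------------


def tree_to_line(tree: ParseTree) -> str:
    return tree.to_sexpr()


def parse_sexpr(line: str, start_pos: int = 0) -> ParseTree:
    """Parse one bracketed s-expression like ``(S (X a b) c)``."""
    tokens = line.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def node(at: int) -> tuple[Union[ParseTree, str], int]:
        nonlocal pos
        if tokens[pos] != "(":
            leaf = tokens[pos]
            pos += 1
            return leaf, at + 1
        pos += 1  # "("
        label = tokens[pos]
        pos += 1
        children: list = []
        cur = at
        while pos < len(tokens) and tokens[pos] != ")":
            child, cur = node(cur)
            children.append(child)
        if pos >= len(tokens):
            raise InputError(f"unbalanced parentheses: {line!r}")
        pos += 1  # ")"
        return ParseTree(label=Symbol(label, NONTERMINAL),
                         children=tuple(children), span=(at, cur)), cur

    try:
        tree, _ = node(start_pos)
    except IndexError:
        raise InputError(f"malformed tree line: {line!r}") from None
    if pos != len(tokens):
        raise InputError(f"trailing content in tree line: {line!r}")
    if not isinstance(tree, ParseTree):
        raise InputError(f"tree line is a bare token: {line!r}")
    return tree


def read_trees(path: PathLike) -> list[Optional[ParseTree]]:
    """One tree per line; ``NOPARSE``-prefixed lines become ``None``."""
    out: list[Optional[ParseTree]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line.startswith("NOPARSE"):
            out.append(None)
        else:
            out.append(parse_sexpr(line))
    return out


def write_trees(path: PathLike,
                trees: Sequence[Optional[tuple[ParseTree, str]]]) -> None:
    """Each entry is ``(tree, "")`` or ``(None, reason)``."""
    lines = []
    for entry in trees:
        tree, reason = entry
        lines.append(tree.to_sexpr() if tree is not None
                     else f"NOPARSE\t{reason}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- manifests -------------------------------------------------------------


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_path: PathLike, command: str, config: dict,
                   inputs: Sequence[PathLike] = ()) -> Path:
    """Write ``<out>.manifest.json`` recording config and input digests."""
    from . import __version__
    out_path = Path(out_path)
    manifest = {
        "command": command,
        "config": config,
        "version": __version__,
        "python": platform.python_version(),
        "inputs": {str(p): _digest(Path(p)) for p in inputs
                   if Path(p).exists()},
    }
    target = out_path.with_name(out_path.name + ".manifest.json")
    target.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                      encoding="utf-8")
    return target
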