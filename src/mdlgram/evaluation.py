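"""Unlabeled bracketing precision/recall/F and held-out coverage statistics.

Brackets of width one and the full-sentence bracket are excluded (they are
always correct); labels are ignored because induced grammars only carry
system-generated labels.  Corpus scores are micro-averaged; by default an
unparsed sentence contributes an empty predicted bracket set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .grammar import InputError
from .parsing import ParseOutcome, ParseTree, Pcfg, viterbi_parse


@dataclass(frozen=True)
class BracketSet:
    """Unlabeled spans of one sentence, 0-based half-open.

    Width-1 spans and the full-sentence span are dropped at construction.
    """

    sentence_length: int
    spans: frozenset[tuple[int, int]]

    def __init__(self, sentence_length: int,
                 spans: Iterable[tuple[int, int]] = ()):
        kept = set()
        for (a, b) in spans:
            if not (0 <= a < b <= sentence_length):
                raise InputError(
                    f"span ({a}, {b}) outside sentence of length {sentence_length}")
            if b - a == 1:
                continue
            if a == 0 and b == sentence_length:
                continue
            kept.add((a, b))
        object.__setattr__(self, "sentence_length", sentence_length)
        object.__setattr__(self, "spans", frozenset(kept))

    def __len__(self) -> int:
        return len(self.spans)


def extract_brackets(tree: ParseTree) -> BracketSet:
    """Spans of all internal nodes, exclusions applied, labels discarded."""
    length = tree.span[1] - tree.span[0]
    offset = tree.span[0]
    spans = [(n.span[0] - offset, n.span[1] - offset)
             for n in tree.iter_nodes()]
    return BracketSet(length, spans)


def _harmonic(p: float, r: float) -> float:
    return 0.0 if p + r == 0.0 else 2.0 * p * r / (p + r)


def prf(gold: BracketSet, predicted: BracketSet) -> tuple[float, float, float]:
    """Single-sentence precision/recall/F with the vacuous-1.0 convention."""
    if gold.sentence_length != predicted.sentence_length:
        raise InputError("gold and predicted bracket sets disagree on length")
    inter = len(gold.spans & predicted.spans)
    p = inter / len(predicted) if len(predicted) else 1.0
    r = inter / len(gold) if len(gold) else 1.0
    return p, r, _harmonic(p, r)


def micro_prf(pairs: Iterable[tuple[BracketSet, BracketSet]]
              ) -> tuple[float, float, float]:
    """Corpus-level scores: sum of intersections over sum of set sizes."""
    inter = n_gold = n_pred = 0
    for gold, pred in pairs:
        if gold.sentence_length != pred.sentence_length:
            raise InputError("gold and predicted bracket sets disagree on length")
        inter += len(gold.spans & pred.spans)
        n_gold += len(gold)
        n_pred += len(pred)
    p = inter / n_pred if n_pred else 1.0
    r = inter / n_gold if n_gold else 1.0
    return p, r, _harmonic(p, r)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_measure: float
    parsed_count: int
    noparse_count: int
    unknown_token_count: int
    novel_total: int
    novel_parsed: int
    novel_parse_rate: Optional[float]  # None when no novel sentence exists

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "parsed_count": self.parsed_count,
            "noparse_count": self.noparse_count,
            "unknown_token_count": self.unknown_token_count,
            "novel_total": self.novel_total,
            "novel_parsed": self.novel_parsed,
            "novel_parse_rate": self.novel_parse_rate,
        }


def evaluate(pcfg: Pcfg, sentences: Sequence[tuple[str, ...]],
             gold_brackets: dict[int, BracketSet],
             train_sentences: Iterable[tuple[str, ...]] = (),
             *, mode: str = "viterbi",
             skip_unparsed: bool = False) -> EvalReport:
    """Parse every test sentence, score brackets on the gold subset and
    report the novel-sentence parse rate.

    ``gold_brackets`` maps sentence indices to gold bracket sets; a
    sentence is *novel* iff its token string does not occur in
    ``train_sentences``.  With ``skip_unparsed`` unparsed gold sentences
    are dropped from the bracket scores instead of contributing empty
    predictions.
    """
    train_set = {tuple(s) for s in train_sentences}
    parsed = noparse = unknown = 0
    novel_total = novel_parsed = 0
    pairs: list[tuple[BracketSet, BracketSet]] = []
    for i, sent in enumerate(sentences):
        sent = tuple(sent)
        outcome = viterbi_parse(pcfg, sent, mode=mode)
        is_novel = sent not in train_set
        if is_novel:
            novel_total += 1
        if outcome.ok:
            parsed += 1
            if is_novel:
                novel_parsed += 1
        elif outcome.status == "unknown-token":
            unknown += 1
            noparse += 1
        else:
            noparse += 1
        gold = gold_brackets.get(i)
        if gold is None:
            continue
        if outcome.ok:
            pairs.append((gold, extract_brackets(outcome.tree)))
        elif not skip_unparsed:
            pairs.append((gold, BracketSet(gold.sentence_length)))
    p, r, f = micro_prf(pairs)
    rate = (novel_parsed / novel_total) if novel_total else None
    return EvalReport(precision=p, recall=r, f_measure=f,
                      parsed_count=parsed, noparse_count=noparse,
                      unknown_token_count=unknown,
                      novel_total=novel_total, novel_parsed=novel_parsed,
                      novel_parse_rate=rate)
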