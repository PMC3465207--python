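# mdlgram

Unsupervised grammar induction for tagged sublanguage corpora (e.g.
clinical-report sentences pre-tagged with part-of-speech and semantic-class
tags). The package:

- **induces** a context-free grammar from unannotated tag sequences by
  greedily minimizing an f-weighted encoding cost of the grammar plus all
  sentence derivations, using two transformation operators — *combine*
  (replace a recurring nonterminal n-gram by a fresh symbol; language
  preserving) and *merge* (collapse two nonterminals; language
  generalizing) — with exact cost deltas, an optional recursion ban and
  positional tag blocklist;
- **estimates** production probabilities from the same unannotated corpus
  by hard (Viterbi) EM, with a fractional all-parses variant;
- **parses** novel sentences with a probabilistic Earley parser that
  handles arbitrary right-hand-side lengths (no binarization);
- **evaluates** unlabeled bracketing precision/recall/F (width-1 and
  full-sentence brackets excluded, micro-averaged) and the novel-sentence
  parse rate;
- **simulates** clinical-like tagged corpora (short sentences, mixed
  POS/semantic tag alphabet, heavy sentence duplication) with gold trees,
  so the whole pipeline is testable without restricted data.

The cost model: a production `A -> β` costs `(1+|β|)·log2|Σ|` bits, the
grammar cost is the sum over productions, and a derivation costs
`Σ log2|P(s)|` bits over its choice points. The search minimizes
`f·C_G + (1−f)·C_D`: `f=0` yields the most specific grammar (one rule per
unique sentence), `f=1` the most general one; useful grammars live in
between.

## CLI

Every command writes a `<output>.manifest.json` with its configuration and
input digests.

```sh
# sample a synthetic tagged corpus with gold trees for the test split
mdlgram simulate --profile clinical_like --n 600 --max-len 10 --seed 7 \
    --out-train train.txt --out-test test.txt --out-gold gold.trees

# induce a grammar (f weighs grammar cost vs derivation cost)
mdlgram induce --corpus train.txt --f 0.7 --max-n 4 --no-recursion \
    --out grammar.txt --trace costs.csv

# estimate production probabilities by hard EM
mdlgram estimate --grammar grammar.txt --corpus train.txt \
    --iterations 5 --mode viterbi --out pcfg.txt --diagnostics em.csv

# parse (viterbi, or probability-free "first" baseline)
mdlgram parse --grammar pcfg.txt --corpus test.txt --mode viterbi \
    --out parses.trees

# score unlabeled bracketing + novel-sentence parse rate
mdlgram evaluate --pcfg pcfg.txt --test test.txt --gold gold.trees \
    --train train.txt --report report.json

# everything at once, with f- and EM-iteration sweeps
mdlgram pipeline --outdir run/ --n 600 --seed 7 \
    --f-values 0.05,0.3,0.7,0.95 --em-iterations 0,1,5
```

Corpora are plain text, one sentence per line, whitespace-separated tags.
Grammars are text files (`#start:`/`#symbol:` headers, one
`LHS -> SYM ...` rule per line, optional tab-separated probability); parse
trees are bracketed s-expressions, one per line.

## Package layout

```
src/mdlgram/
  grammar.py     symbols, productions, grammars, derivations, corpora,
                 encoding costs (bits)
  induction.py   initial grammar, combine/merge operators, exact deltas,
                 constraints, greedy search
  parsing.py     probabilistic Earley parser, parse enumeration oracle,
                 bounded language enumeration
  em.py          uniform init, hard-EM / fractional counting, diagnostics
  evaluation.py  unlabeled bracketing P/R/F, coverage statistics
  synth.py       reference PCFGs and corpus sampling (Zipf duplication)
  io.py          text formats: corpora, grammars/PCFGs, trees, manifests
  cli.py         click CLI: simulate / induce / estimate / parse /
                 evaluate / pipeline
```
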