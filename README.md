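# bbgru

Attention-based bidirectional GRU for extracting **Lives_In** events —
which bacterium lives in which habitat or geographical location — from
biomedical text annotated in the BioNLP-ST standoff format (Bacteria
Biotope task layout: entity types `Bacteria`, `Habitat`, `Geographical`,
one binary relation type `Lives_In`).

It is aimed at biomedical text-mining practitioners who want a compact,
dependency-path-based neural relation extractor whose every numerical
component (GRU cell, attention pooling, backpropagation, skip-gram
embedding trainer, scorer) is plain, inspectable numpy code. A bundled
synthetic-corpus generator produces standoff documents with consistent
dependency parses and a planted lexical cue, so the full pipeline trains
and evaluates without downloading any corpus.

## Model

Each intra-sentence (Bacteria, Habitat/Geographical) pair is a candidate.
The two mentions are replaced by `entity_1` / `entity_2` placeholders, and
the classifier sees only the tokens on the shortest undirected dependency
path between them (the linearized shortest-path-enclosed tree, SPT),
extended by the nearest governing verb (the dynamic extended tree, DET).

Token *i* is encoded as the concatenation of word, POS and distance
embeddings, x_i = [w_i ; p_i ; d1(ℓ1) ; d2(ℓ2)], where ℓ1, ℓ2 are the
signed token distances to the two placeholders and every component of a
fresh distance row for distance ℓ is initialized to tanh(ℓ/s), s being the
largest distance in the training corpus. The sequence runs through a
single-layer bidirectional GRU without bias terms,

    r_t = σ(W_r x_t + U_r h_{t−1})
    h̃_t = tanh(W x_t + U (r_t ⊙ h_{t−1}))
    z_t = σ(W_z x_t + U_z h_{t−1})
    h_t = z_t ⊙ h_{t−1} + (1 − z_t) ⊙ h̃_t

with the two directions merged by averaging, D_t = (h_t^f + h_t^b)/2.
Attention pooling scores each position with a trained vector p,

    H = tanh(D),  m̂ = pᵀH,  α = softmax(m̂),  r = Dα,  o = tanh(r),

and a 2-way softmax on o decides Lives_In vs. none. Training is
mini-batch Adam on the cross-entropy with inverted dropout on o
(defaults: 50-dim word/POS/distance embeddings, dropout 0.5, learning
rate 1e-3, batch size 5, 4 epochs). Word and POS tables may be
pre-trained with the included domain-oriented skip-gram trainer, whose
context units include each neighbour's surface form, stem, chunk tag,
entity tag and POS tag.

Evaluation uses the Bacteria-Biotope matching-similarity rule: a predicted
event counts iff both arguments are the same — or `Equiv`-equivalent —
entities as a gold event (1-to-1 matching); cross-sentence gold relations
count against an intra-sentence system as false negatives.

## Worked example

```bash
bbgru synth --seed 7 --out corpus --train-docs 30 --dev-docs 5 --test-docs 10
bbgru train --data corpus/train --model model.ckpt --seed 7
bbgru predict --data corpus/test --model model.ckpt --out preds
bbgru evaluate --gold corpus/test --pred preds
```

The synthetic corpus plants a cue verb (`inhabits`) on the dependency path
between gold-positive pairs with probability 0.95. Training logs the
per-epoch mean loss — here `0.6130, 0.0967, 0.0852, 0.0579` — and
evaluation prints per-document counts plus a global line:

```
doc_id  TP  FP  FN
SYN-test-0000   6   0   0
...
SYN-test-0009   3   0   0
TOTAL   P=100.00%   R=93.55%    F=96.67%
```

Recall stays below 100% by construction: a few positives lack the cue
(1 − p_cue) and a small rate of planted cross-sentence gold relations is
unreachable for any intra-sentence system. `predict` also exposes the
attention weights through the library API (`bbgru.predict(state, cand)`),
which on true positives concentrate on the cue verb.

## Data formats

* `doc.txt` — UTF-8 text; `doc.a1` — entity lines
  `Tn<TAB>Type start end<TAB>surface` (0-based half-open offsets,
  `;`-separated discontinuous spans); `doc.a2` — relation lines
  `Rn<TAB>Lives_In Bacterium:Tx Location:Ty` and equivalence lines
  `*<TAB>Equiv Tx Ty ...`.
* `doc.conll` — one token per line, TAB-separated columns
  `index surface stem pos chunk entity head deplabel` (1-based indices,
  head 0 = root), blank line between sentences; this is the
  GDep-compatible column order. Documents without a parse file fall back
  to whitespace tokenization with a chain parse.
* Embedding tables serialize to word2vec text format (`|V| k` header).

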