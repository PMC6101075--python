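# Methods

This note records the modelling assumptions, parameter choices and design
decisions behind `bbgru`, in the order the pipeline runs.

## Candidate generation

Only intra-sentence pairs are classified: every (Bacteria,
Habitat-or-Geographical) pair co-occurring in one sentence becomes a
candidate, and a candidate is gold-positive iff a gold `Lives_In` relation
links the pair directly or through `Equiv`-equivalent mentions. Bacteria
are paired with Geographical entities as well as Habitats, since both are
legal location arguments. Gold relations whose arguments sit in different
sentences cannot be reached by any candidate; they are surfaced separately
and scored as false negatives, matching the evaluation convention that
cross-sentence relations count against an intra-sentence submission.

Entity mentions are replaced by `entity_1` / `entity_2` placeholders. Two
granularities are supported (`replace: span|head`): the default collapses
the full annotated token run to a single placeholder, because that is
well-defined for arbitrary spans; `head` renames only the run's syntactic
head token (the token whose governor lies outside the run) and keeps the
other mention tokens, the behaviour suggested by head-word replacement in
the literature this architecture descends from. Both are tested; `span`
is the default because it never leaves fragments of a mention in the
input. Sentence segmentation and tokenization come from the parse file
(one CoNLL block per sentence); running a parser is deliberately out of
scope, and a whitespace splitter with a left-headed chain parse exists
only as a fallback for parse-less documents.

## Dependency-path input (SPT and DET)

The encoder input is the token subsequence on the shortest undirected
path between the two placeholders in the dependency graph, re-ordered by
sentence position (linearized SPT). The dynamic extension (DET) adds the
nearest governing verb: from the shallower path endpoint, head links are
walked upward until a `VB*`-tagged token is found. This "nearest
governing verb" rule is a reconstruction from the single published
example of the extension (which adds exactly the clause verb) rather than
a restatement of a full published definition, and is documented as such;
sentences with no verb ancestor return the SPT unchanged, and a
disconnected graph falls back to the whole sentence with a warning. Both
subsequences preserve sentence order and satisfy SPT ⊆ DET ⊆ sentence.

## Token encoding

Each token contributes a 150-dimensional row: 50-dim word embedding,
50-dim POS embedding, and a 50-dim distance block split 25/25 over the
two targets. The split resolves a genuine ambiguity — all three embedding
types are nominally 50-dimensional, but the distance embedding is defined
as the concatenation of two per-target vectors — by keeping the
concatenated block at 50. Distances use the convention ℓ = entity index −
token index, the only sign convention consistent with the reference
example (the token "at" one position after the bacterium and three before
the location has distances (−1, 3)). A fresh distance row for distance ℓ
has every component equal to tanh(ℓ/s); the normalizer s is the maximum
absolute distance in the training corpus, computed once and frozen, with
larger unseen distances clipped to ±s. All four tables (word, POS, two
distance tables) are trainable; out-of-vocabulary words map to a
dedicated trained row.

## Domain-oriented embedding pre-training

The optional pre-trainer is skip-gram with negative sampling (5 negatives,
unigram^0.75 noise, window 5, initial learning rate 0.025 with linear
decay) in which the context of a focus token includes, for each neighbour
in the window, five distinct units: surface, stem, chunk tag, entity tag
and POS tag. Focus units are each token's surface and POS tag; the word
table is read off surface units and the POS table off POS units. This is
a concrete reconstruction of "training on surrounding words plus their
parser-derived annotations": no objective was published for that idea, so
the closest standard formulation was chosen and is stated here as such.
Only the word and POS tables are emitted, because only those are consumed
downstream; stems, chunks and entity tags act purely as context. The
classifier trains fine from random tables — on the synthetic corpus the
cue signal is strong enough that pre-training is not needed for the
end-to-end checks — so pre-training is optional everywhere.

## Network

The GRU follows the gate equations exactly as used here, with no bias
terms anywhere (a config flag could add them, but the default matches the
bias-free formulation); the update gate multiplies the previous state, so
z → 1 retains memory and z → 0 hands over to the candidate. Hidden width
defaults to the input width d_w = 150 (the formulation types the hidden
matrix D as d_w × n, conflating the two; both are configurable). The two
directions have independent parameters and are merged by per-position
averaging, not concatenation. Attention pooling is H = tanh(D), scores
m̂ = pᵀH, max-stabilized softmax weights, r = Dα, o = tanh(r); the output
layer is a 2-class softmax with bias (the output layer is ordinary
plumbing, not part of the bias-free recurrent core).

Training minimizes mean cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999) at
learning rate 1e-3, batch size 5, 4 epochs by default (the useful range
on small relation corpora is 3–5), one layer. Inverted dropout at rate
0.5 is applied to the pooled vector o during training only, so inference
is deterministic. The optimizer was not named in the source formulation;
Adam at the stated learning rate is this package's choice. Likewise the
loss ("softmax output") is realized as 2-class cross-entropy rather than
a scalar sigmoid. Mini-batches are processed one instance at a time with
gradient averaging instead of padded/masked tensor batches: for a mean
loss the two are mathematically identical, and at dependency-path lengths
(typically 3–8 tokens) padding bookkeeping buys nothing. All gradients
are derived by hand and checked against central differences (relative
error < 1e-4 on every parameter group, in practice ~1e-6) in the test
suite. One integer seed drives parameter initialization, batch shuffling
and dropout masks; fixed-seed runs are bit-identical on one platform.

## Scorer

Matching similarity is binary: a prediction matches a gold event iff both
arguments agree up to `Equiv` equivalence. Arguments are canonicalized to
their equivalence-class representative (classes are closed transitively
at load time), duplicate predictions of one canonical pair are
deduplicated, and matching is 1-to-1 — because matching is pure pair
equality, greedy assignment attains the maximum matching, which the tests
verify against an exhaustive brute force on small random sets. P, R and F
use zero-valued conventions at empty denominators. The official online
service's tie-breaking is not published; 1-to-1 maximum matching is the
assumption made here.

## Synthetic corpus

The generator emulates the standoff + parse corpus layout with planted,
controllable signal. Each sentence is one clause with 1–3 conjoined
Bacteria subjects and 1–3 location objects (Geographical with probability
0.25, multi-word habitats like "tissue4 of host7" with probability 0.3);
a sentence is positive with probability 0.5, and positive sentences use
the cue verb `inhabits` with probability p_cue = 0.95 (otherwise a
neutral verb — label noise). The head assignment makes the clause verb
govern both entity heads, so the cue sits on the dependency path of every
positive pair: the signal lives on the SPT, not merely in the bag of
words, which is what makes path extraction measurably useful. Negative
sentences carry the cue as an off-path distractor (a relative clause
under a location) with probability 0.2. Equiv groups are planted as
parenthesized abbreviations (rate 0.1 per sentence), and cross-sentence
gold relations are planted at rate 0.05 per document purely to exercise
the scorer's false-negative rule. These rates were chosen once as a
plausible miniature of a relation-extraction corpus: roughly balanced
labels, mild label noise, and rare annotation quirks.

What the generator does *not* emulate: real PubMed prose, realistic parse
errors, the heavy class imbalance and lexical diversity of the real
Bacteria-Biotope corpora, coreference, or discontinuous entity spans.
Passing the end-to-end checks therefore shows that the architecture,
gradients, data plumbing and scorer are correct and that the model can
exploit path-planted lexical signal — it does not predict F-scores on
real corpora.

## Problem sizes in the checks

The end-to-end recovery check trains on 300 sentences (60 documents × 5)
and tests on 100, at the full default configuration (150-dim inputs,
hidden 150); this takes well under a minute on one CPU and is ample for
the planted-cue task, where a decision stump on the cue is already
perfect at p_cue = 1. The gradient check runs at reduced widths (input
14, hidden 5) because central differences cost two forward passes per
scalar parameter.

## Known limitations

* The DET verb-extension rule is reverse-engineered from one example.
* The skip-gram pre-trainer is a documented reconstruction, not a port.
* `Equiv` classes use a single representative; exotic overlapping-group
  annotations are merged transitively rather than rejected.
* No GPU path; everything is numpy on one CPU, sized for corpora in the
  thousands of sentences, not millions.
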