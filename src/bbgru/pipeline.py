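"""Directory-level glue: load standoff + parse corpora, build candidate
datasets, and run training / prediction / scoring over whole corpora."""

from __future__ import annotations

import logging
from pathlib import Path

from .candidates import (
    CandidateInstance,
    SentenceSpan,
    align_sentences,
    enumerate_candidates,
    segment_fallback,
)
from .evaluation import EvalCounts, evaluate_documents
from .model import ModelState, TrainConfig, predict_label, train_model
from .parse import read_conll
from .standoff import Document, RelationAnn, read_document, write_a2

logger = logging.getLogger(__name__)


def load_corpus_dir(corpus_dir, with_gold: bool = True) -> list[tuple[Document, list[SentenceSpan]]]:
    """Load every doc_id.{txt,a1,a2,conll} triple under *corpus_dir*.

    Documents without a .conll parse file fall back to whitespace
    tokenization with a chain parse.  ``with_gold=False`` ignores .a2
    files (prediction on unlabeled data).
    """
    corpus_dir = Path(corpus_dir)
    out = []
    for txt in sorted(corpus_dir.glob("*.txt")):
        stem = txt.with_suffix("")
        a1 = stem.with_suffix(".a1")
        a2 = stem.with_suffix(".a2") if with_gold else None
        doc = read_document(txt, a1, a2)
        conll = stem.with_suffix(".conll")
        if conll.exists():
            graphs = read_conll(conll)
        else:
            logger.warning("%s: no parse file, using whitespace fallback", doc.doc_id)
            graphs = segment_fallback(doc.text)
        out.append((doc, align_sentences(doc.text, graphs)))
    return out


def build_dataset(
    corpus, replace_mode: str = "span", use_det: bool = True
) -> tuple[list[CandidateInstance], dict[str, list[RelationAnn]]]:
    """Candidates for every document plus the unreachable gold relations."""
    instances: list[CandidateInstance] = []
    unreachable: dict[str, list[RelationAnn]] = {}
    for doc, sentences in corpus:
        cands, missed = enumerate_candidates(doc, sentences,
                                             replace_mode=replace_mode, use_det=use_det)
        instances.extend(cands)
        if missed:
            unreachable[doc.doc_id] = missed
    return instances, unreachable


def train_on_dir(
    corpus_dir, cfg: TrainConfig,
    word_tab=None, pos_tab=None,
    replace_mode: str = "span", use_det: bool = True,
) -> ModelState:
    corpus = load_corpus_dir(corpus_dir)
    instances, _ = build_dataset(corpus, replace_mode=replace_mode, use_det=use_det)
    logger.info("training on %d candidates (%d positive) from %d documents",
                len(instances), sum(i.label for i in instances), len(corpus))
    return train_model(instances, cfg, word_tab=word_tab, pos_tab=pos_tab)


def predict_corpus(
    state: ModelState, corpus, replace_mode: str = "span", use_det: bool = True
) -> dict[str, list[RelationAnn]]:
    """Predicted Lives_In relations per document id."""
    preds: dict[str, list[RelationAnn]] = {}
    for doc, sentences in corpus:
        cands, _ = enumerate_candidates(doc, sentences,
                                        replace_mode=replace_mode, use_det=use_det)
        rels = []
        for cand in cands:
            if predict_label(state, cand) == 1:
                rels.append(RelationAnn(id=f"R{len(rels) + 1}",
                                        bacterium=cand.e1.id, location=cand.e2.id))
        preds[doc.doc_id] = rels
    return preds


def write_predictions(preds: dict[str, list[RelationAnn]], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc_id, rels in preds.items():
        (out / f"{doc_id}.a2").write_text(write_a2(rels), encoding="utf-8")


def score_dirs(gold_dir, pred_dir) -> tuple[dict[str, EvalCounts], EvalCounts]:
    """Score predicted .a2 files in *pred_dir* against the gold corpus."""
    gold_docs: dict[str, Document] = {}
    preds: dict[str, list[RelationAnn]] = {}
    for doc, _sentences in load_corpus_dir(gold_dir):
        gold_docs[doc.doc_id] = doc
    for doc_id, doc in gold_docs.items():
        pred_a2 = Path(pred_dir) / f"{doc_id}.a2"
        if pred_a2.exists():
            pred_doc = read_document(Path(gold_dir) / f"{doc_id}.txt",
                                     Path(gold_dir) / f"{doc_id}.a1", pred_a2)
            preds[doc_id] = pred_doc.relations
    return evaluate_documents(gold_docs, preds)
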