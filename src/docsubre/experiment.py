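"""End-to-end driver: instance building, training, evaluation, ensembling.

The pipeline trains with a wide sliding window (default w=5, which harvests
more patterns) and predicts with a narrow one (default w=2, which limits
noise), aggregates instance predictions to document-level relation pairs
(the identity, since merging already left one instance per pair), and
reports micro P/R/F1 overall and split into intra- vs inter-sentence gold
relations.  Candidate pairs that never co-occur inside any window are
uncovered: they yield no instance and count against recall when gold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .corpus_io import (CHEMICAL, DISEASE, CorefLink, DocumentRecord, KBPair,
                        ParsedSentence, align_mentions)
from .doc_graph import (LEAN_EDGES, EdgeConfig, build_subgraph,
                        enumerate_windows)
from .errors import ConfigurationError, DocsubreError
from .path_encoder import EncoderConfig, WordTable
from .path_miner import (CID, NONE, CandidateInstance, Cooccurrence,
                         find_paths, merge_instances, minimal_span_filter,
                         select_top_k)
from .swcnn_model import ModelState, SwCNNConfig, predict, train

Key = tuple[str, str, str]  # (doc id, chemical concept, disease concept)

INTRA = "intra"
INTER = "inter"


@dataclass(frozen=True)
class ExperimentConfig:
    w_train: int = 5
    w_test: int = 2
    top_k: int = 3
    strategy: str = "shortest"
    md: int = 15
    kmax: int = 150
    edge_config: EdgeConfig = LEAN_EDGES
    encoder: EncoderConfig = field(default_factory=EncoderConfig.small)
    model: SwCNNConfig = field(default_factory=SwCNNConfig.small)
    train_frac: float = 0.7
    dev_frac: float = 0.1
    ensemble_runs: int = 20

    def __post_init__(self):
        for w in (self.w_train, self.w_test):
            if not (1 <= w <= 5):
                raise ConfigurationError(f"window size {w} outside [1,5]")


@dataclass
class SubReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def f1(self) -> float:
        p = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        r = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        return _round2(200.0 * p * r / (p + r)) if p + r else 0.0


def _pct(num: int, den: int) -> float:
    return _round2(100.0 * num / den) if den else 0.0


def _round2(x: float) -> float:
    """Two decimals, half-up, matching tabular presentation."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    overall: SubReport
    intra: SubReport
    inter: SubReport

    def as_dict(self) -> dict:
        return {name: {"tp": s.tp, "fp": s.fp, "fn": s.fn,
                       "precision": s.precision, "recall": s.recall, "f1": s.f1}
                for name, s in (("overall", self.overall), ("intra", self.intra),
                                ("inter", self.inter))}

    def as_tsv(self) -> str:
        lines = ["scope\ttp\tfp\tfn\tprecision\trecall\tf1"]
        for name, s in (("overall", self.overall), ("intra", self.intra),
                        ("inter", self.inter)):
            lines.append(f"{name}\t{s.tp}\t{s.fp}\t{s.fn}\t"
                         f"{s.precision}\t{s.recall}\t{s.f1}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Instance building
# ---------------------------------------------------------------------------

def build_instances(docs: list[DocumentRecord],
                    parses_by_doc: dict[str, list[ParsedSentence]],
                    w: int,
                    *,
                    top_k: int = 3,
                    strategy: str = "shortest",
                    md: int = 15,
                    kmax: int = 150,
                    edge_config: EdgeConfig = LEAN_EDGES,
                    coref_by_doc: dict[str, list[CorefLink]] | None = None,
                    kb_pairs: list[KBPair] = (),
                    ) -> list[CandidateInstance]:
    """One labeled CandidateInstance per document-level concept pair with at
    least one windowed co-occurrence; minimal-span filtering and instance
    merging applied; paths trimmed to the top-k."""
    instances: list[CandidateInstance] = []
    for doc in docs:
        parses = parses_by_doc[doc.doc_id]
        alignments = align_mentions(doc, parses)
        windows = enumerate_windows(doc.n_abstract_sentences, w)
        subgraphs = {}
        coref = (coref_by_doc or {}).get(doc.doc_id, [])

        chems: dict[str, list[int]] = {}
        diss: dict[str, list[int]] = {}
        for mi, m in enumerate(doc.mentions):
            (chems if m.etype == CHEMICAL else diss).setdefault(m.concept, []).append(mi)

        for c_concept, c_mentions in sorted(chems.items()):
            for d_concept, d_mentions in sorted(diss.items()):
                coocs: list[Cooccurrence] = []
                for win in windows:
                    inside = set(win.sentences)
                    for cm in c_mentions:
                        for dm in d_mentions:
                            cs = alignments[cm].sent_idx
                            ds = alignments[dm].sent_idx
                            if cs in inside and ds in inside:
                                span = (min(cs, ds), max(cs, ds))
                                coocs.append(Cooccurrence(cm, dm, win, span))
                if not coocs:
                    continue
                paths = []
                for co in minimal_span_filter(coocs):
                    win = co.window
                    if win not in subgraphs:
                        subgraphs[win] = build_subgraph(
                            doc, parses, win, coref, kb_pairs, edge_config,
                            alignments=alignments)
                    src = (alignments[co.chem_mention].sent_idx,
                           alignments[co.chem_mention].head)
                    tgt = (alignments[co.dis_mention].sent_idx,
                           alignments[co.dis_mention].head)
                    if src == tgt:
                        continue
                    paths.extend(find_paths(subgraphs[win], src, tgt, md, kmax))
                label = CID if (c_concept, d_concept) in doc.relations else NONE
                inst = merge_instances(doc.doc_id, c_concept, d_concept,
                                       paths, parses, label)
                instances.append(select_top_k(inst, top_k, strategy))
    return instances


def _mention_sentence(doc: DocumentRecord, begin: int) -> int:
    for si, (lo, hi) in enumerate(doc.sentence_spans):
        if lo <= begin < hi:
            return si
    raise DocsubreError(f"{doc.doc_id}: offset {begin} outside all sentences")


def classify_relation_locus(doc: DocumentRecord, chemical: str,
                            disease: str) -> str:
    """'intra' iff some single sentence (title included) mentions both
    concepts; 'inter' otherwise."""
    c_sents = {_mention_sentence(doc, m.begin) for m in doc.mentions
               if m.etype == CHEMICAL and m.concept == chemical}
    d_sents = {_mention_sentence(doc, m.begin) for m in doc.mentions
               if m.etype == DISEASE and m.concept == disease}
    if not c_sents or not d_sents:
        raise DocsubreError(
            f"{doc.doc_id}: pair ({chemical},{disease}) has no mentions")
    return INTRA if c_sents & d_sents else INTER


def gold_pairs(docs: list[DocumentRecord]) -> set[Key]:
    return {(d.doc_id, c, s) for d in docs for c, s in d.relations}


def locus_map(docs: list[DocumentRecord], keys) -> dict[Key, str]:
    by_id = {d.doc_id: d for d in docs}
    return {k: classify_relation_locus(by_id[k[0]], k[1], k[2]) for k in keys}


# ---------------------------------------------------------------------------
# Evaluation and ensembling
# ---------------------------------------------------------------------------

def evaluate(predictions: dict[Key, str], gold: set[Key],
             locus: dict[Key, str]) -> EvalReport:
    """Micro P/R/F1; uncovered gold pairs are automatic false negatives; the
    intra/inter sub-reports restrict gold and predictions to that locus."""
    predicted = {k for k, v in predictions.items() if v == CID}

    def sub(keys_filter) -> SubReport:
        p = {k for k in predicted if keys_filter(k)}
        g = {k for k in gold if keys_filter(k)}
        return SubReport(tp=len(p & g), fp=len(p - g), fn=len(g - p))

    return EvalReport(
        overall=sub(lambda k: True),
        intra=sub(lambda k: locus[k] == INTRA),
        inter=sub(lambda k: locus[k] == INTER))


def ensemble_vote(runs: list[dict[Key, str]]) -> dict[Key, str]:
    """Strict majority vote: CID iff more than half the runs say CID."""
    if not runs:
        raise DocsubreError("no runs to ensemble")
    keys = set(runs[0])
    for r in runs[1:]:
        if set(r) != keys:
            raise DocsubreError("ensemble runs cover different instance keys")
    n = len(runs)
    return {k: CID if sum(r[k] == CID for r in runs) * 2 > n else NONE
            for k in keys}


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    report: EvalReport
    predictions: dict[Key, str]
    history: list[dict]
    state: ModelState
    test_docs: list[DocumentRecord]
    config: ExperimentConfig
    splits: dict[str, list[str]]


def split_documents(docs: list[DocumentRecord], cfg: ExperimentConfig,
                    seed: int) -> tuple[list, list, list]:
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(docs)))
    n_train = int(len(docs) * cfg.train_frac)
    n_dev = int(len(docs) * cfg.dev_frac)
    pick = lambda idx: [docs[i] for i in idx]
    return (pick(order[:n_train]), pick(order[n_train:n_train + n_dev]),
            pick(order[n_train + n_dev:]))


def predict_and_evaluate(state: ModelState, docs, parses_by_doc,
                         cfg: ExperimentConfig,
                         edge_config: EdgeConfig | None = None,
                         ) -> tuple[EvalReport, dict[Key, str]]:
    """Build test instances at w_test (optionally with a modified edge
    configuration, e.g. for ablations) and evaluate a trained model."""
    edges = cfg.edge_config if edge_config is None else edge_config
    instances = build_instances(docs, parses_by_doc, cfg.w_test,
                                top_k=cfg.top_k, strategy=cfg.strategy,
                                md=cfg.md, kmax=cfg.kmax, edge_config=edges)
    predictions = predict(state, instances, parses_by_doc)
    gold = gold_pairs(docs)
    keys = gold | {k for k, v in predictions.items() if v == CID}
    report = evaluate(predictions, gold, locus_map(docs, keys))
    return report, predictions


def run_experiment(docs: list[DocumentRecord],
                   parses_by_doc: dict[str, list[ParsedSentence]],
                   word_table: WordTable,
                   cfg: ExperimentConfig,
                   seed: int,
                   extra_train_docs: list[DocumentRecord] = (),
                   extra_parses: dict[str, list[ParsedSentence]] | None = None,
                   ) -> ExperimentResult:
    """Split the corpus, train with w_train, evaluate with w_test.

    ``extra_train_docs`` (e.g. distantly supervised documents) join the
    training set with weight 1 through the identical pipeline.
    """
    train_docs, dev_docs, test_docs = split_documents(docs, cfg, seed)
    parses = dict(parses_by_doc)
    if extra_parses:
        parses.update(extra_parses)
    train_docs = list(train_docs) + list(extra_train_docs)

    mining = dict(top_k=cfg.top_k, strategy=cfg.strategy, md=cfg.md,
                  kmax=cfg.kmax, edge_config=cfg.edge_config)
    train_instances = build_instances(train_docs, parses, cfg.w_train, **mining)
    dev_instances = build_instances(dev_docs, parses, cfg.w_test, **mining)

    state, history = train(train_instances, dev_instances, parses,
                           word_table, cfg.encoder, cfg.model, seed)
    report, predictions = predict_and_evaluate(state, test_docs, parses, cfg)
    splits = {"train": [d.doc_id for d in train_docs],
              "dev": [d.doc_id for d in dev_docs],
              "test": [d.doc_id for d in test_docs]}
    return ExperimentResult(report, predictions, history, state, test_docs,
                            cfg, splits)


def run_edge_ablation(result: ExperimentResult, parses_by_doc,
                      family: str) -> EvalReport:
    """Re-evaluate the trained model on test instances built without one
    virtual-edge family (Table-style ablation grid on fixture data)."""
    edges = result.config.edge_config.without(family)
    report, _ = predict_and_evaluate(result.state, result.test_docs,
                                     parses_by_doc, result.config, edges)
    return report


def predictions_tsv(predictions: dict[Key, str]) -> str:
    lines = [f"{doc}\tCID\t{chem}\t{dis}"
             for (doc, chem, dis), label in sorted(predictions.items())
             if label == CID]
    return "\n".join(lines) + ("\n" if lines else "")
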