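"""Synthetic corpus generator: PubTator abstracts with matching parses.

The generator emulates the structure of document-level chemical-disease
annotation: each document is a short title plus a fixed skeleton of
template sentences with hand-built dependency trees.  A planted CID pair is
made learnable by placing a trigger verb ("induces"-class) on the
dependency route between the two mention heads, while negative pairs
co-occur only through trigger-free routes:

* intra positives put chemical, trigger and disease in one sentence;
* next-sentence inter positives put the chemical under a trigger root in
  the penultimate sentence and the disease in the last sentence, so the
  evidence crosses a NEXT-SENT edge;
* title-routed inter positives mention the chemical ONLY in the title and
  make the trigger the root of the penultimate sentence, so every path at
  window width >= 2 runs title -> TITLE edge -> trigger root -> NEXT-SENT
  -> disease.  With single-sentence windows the TITLE edge attaches
  directly to the disease sentence and the only available route is
  trigger-free — structurally identical to the negative decoy patterns —
  so single-sentence models have nothing to find.

Decoy chemical/disease mentions occupy the first three sentences with
neutral verbs drawn from the same pools as the positive-zone sentences,
giving each document a realistic surplus of negative candidate pairs
(roughly 1 positive : 3 negatives, in line with subgraph candidate
generation on real abstracts).  The intra/inter split of planted relations
defaults to 0.7/0.3, mirroring the reported share of relations that only
appear across sentence boundaries.

Deterministic: one seed fixes every byte of output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import (DocumentRecord, Mention, ParsedSentence, Token,
                        write_conllu, write_pubtator)
from .errors import ConfigurationError

# Template rows: (surface or slot, POS, head (1-based, 0 = root), deprel).
# Slots: {CHEM} {DIS} {ADJ} {TRIG}
TEMPLATES: dict[str, list[tuple[str, str, int, str]]] = {
    "title": [
        ("{CHEM}", "NN", 2, "compound"),
        ("study", "NN", 0, "root"),
    ],
    "chem_measure": [
        ("{CHEM}", "NN", 2, "compound"),
        ("levels", "NNS", 4, "nsubjpass"),
        ("were", "VBD", 4, "auxpass"),
        ("measured", "VBN", 0, "root"),
        (".", ".", 4, "punct"),
    ],
    "dis_observe": [
        ("{ADJ}", "JJ", 2, "amod"),
        ("{DIS}", "NN", 4, "nsubjpass"),
        ("was", "VBD", 4, "auxpass"),
        ("observed", "VBN", 0, "root"),
        (".", ".", 4, "punct"),
    ],
    "filler": [
        ("{NOUN}", "NNS", 3, "nsubjpass"),
        ("were", "VBD", 3, "auxpass"),
        ("{VERB}", "VBN", 0, "root"),
        (".", ".", 3, "punct"),
    ],
    "intra_pos": [
        ("{CHEM}", "NN", 2, "nsubj"),
        ("{TRIG}", "VBZ", 0, "root"),
        ("{ADJ}", "JJ", 4, "amod"),
        ("{DIS}", "NN", 2, "dobj"),
        (".", ".", 2, "punct"),
    ],
    "inter_chem": [
        ("{CHEM}", "NN", 2, "nsubj"),
        ("{TRIG}", "VBD", 0, "root"),
        ("complications", "NNS", 2, "dobj"),
        (".", ".", 2, "punct"),
    ],
    "inter_trigger": [
        ("it", "PRP", 2, "nsubj"),
        ("{TRIG}", "VBZ", 0, "root"),
        ("injury", "NN", 2, "dobj"),
        (".", ".", 2, "punct"),
    ],
}

TRIGGERS: tuple[tuple[str, str], ...] = (  # (present, past)
    ("induces", "induced"), ("causes", "caused"),
    ("provokes", "provoked"), ("aggravates", "aggravated"))
ADJECTIVES = ("mild", "severe", "transient", "marked")
FILLER_NOUNS = ("samples", "records", "profiles", "assays")
FILLER_VERBS = ("collected", "reviewed", "monitored", "analysed")


@dataclass(frozen=True)
class GeneratorSpec:
    n_docs: int = 500
    sentence_range: tuple[int, int] = (8, 10)  # abstract sentences, inclusive
    n_chemicals: int = 40
    n_diseases: int = 40
    positive_rate: float = 0.9
    intra_frac: float = 0.7
    title_routed_frac: float = 0.5  # share of inter positives routed via TITLE
    seed: int = 0

    def __post_init__(self):
        for f in (self.positive_rate, self.intra_frac, self.title_routed_frac):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError("fractions must lie in [0,1]")
        if self.n_chemicals < 3 or self.n_diseases < 3:
            raise ConfigurationError("concept inventories too small for a document")
        if self.sentence_range[0] < 8 or self.sentence_range[0] > self.sentence_range[1]:
            raise ConfigurationError("documents need at least 8 abstract sentences")


def chem_surface(i: int) -> str:
    return f"chemox{i}"


def dis_surface(i: int) -> str:
    return f"malitis{i}"


def chem_concept(i: int) -> str:
    return f"MESH:C{i:03d}"


def dis_concept(i: int) -> str:
    return f"MESH:D{i:03d}"


def generate_parse(template: str | list, bindings: dict[str, str]) -> ParsedSentence:
    """Instantiate a template tree; POS tags come from the template roles."""
    rows = TEMPLATES[template] if isinstance(template, str) else template
    tokens, arcs, root = [], [], None
    for i, (slot, pos, head, deprel) in enumerate(rows):
        surface = bindings.get(slot.strip("{}"), slot) if slot.startswith("{") else slot
        tokens.append(Token(surface, pos))
        if head == 0:
            root = i
        else:
            arcs.append((head - 1, i, deprel))
    sent = ParsedSentence(tokens, arcs, root)
    sent.validate()
    return sent


def _capitalize(sent: ParsedSentence) -> ParsedSentence:
    first = sent.tokens[0]
    cap = Token(first.surface[0].upper() + first.surface[1:], first.pos, first.span)
    return ParsedSentence([cap] + sent.tokens[1:], sent.arcs, sent.root)


@dataclass
class _DocPlan:
    doc_id: str
    sentences: list[ParsedSentence]  # index 0 = title, no spans yet
    mentions: list[tuple[int, int, str, str]]  # (sent, token, etype, concept)
    relations: set[tuple[str, str]]
    locus: str | None  # locus of the planted pair, None for negative docs


def _plan_document(spec: GeneratorSpec, rng: np.random.Generator,
                   doc_id: str) -> _DocPlan:
    n = int(rng.integers(spec.sentence_range[0], spec.sentence_range[1] + 1))
    chems = rng.choice(spec.n_chemicals, size=3, replace=False)
    dises = rng.choice(spec.n_diseases, size=3, replace=False)
    C, c2, c3 = (int(i) for i in chems)
    D, d2, d3 = (int(i) for i in dises)
    trig_present, trig_past = TRIGGERS[rng.integers(len(TRIGGERS))]
    adj = lambda: ADJECTIVES[rng.integers(len(ADJECTIVES))]

    positive = rng.random() < spec.positive_rate
    locus = None
    if positive:
        if rng.random() < spec.intra_frac:
            locus = "intra"
        else:
            locus = "inter-title" if rng.random() < spec.title_routed_frac else "inter-ns"

    sentences: list[ParsedSentence] = []
    mentions: list[tuple[int, int, str, str]] = []

    def add(template, bindings, ments=()):
        si = len(sentences)
        sent = generate_parse(template, bindings)
        if si > 0:
            sent = _capitalize(sent)
        sentences.append(sent)
        for tok_idx, etype, concept in ments:
            mentions.append((si, tok_idx, etype, concept))

    # The title's chemical is the gold chemical in positive documents (for
    # title-routed inter positives it is the ONLY mention of it); negative
    # documents get an unrelated decoy chemical.
    title_chem = C if positive else c3
    add("title", {"CHEM": chem_surface(title_chem)},
        [(0, "Chemical", chem_concept(title_chem))])
    add("chem_measure", {"CHEM": chem_surface(c2)},
        [(0, "Chemical", chem_concept(c2))])
    add("dis_observe", {"ADJ": adj(), "DIS": dis_surface(d2)},
        [(1, "Disease", dis_concept(d2))])
    add("dis_observe", {"ADJ": adj(), "DIS": dis_surface(d3)},
        [(1, "Disease", dis_concept(d3))])
    n_fillers = n - 5  # decoy zone (3) + positive zone (2)
    for _ in range(n_fillers):
        add("filler", {"NOUN": FILLER_NOUNS[rng.integers(len(FILLER_NOUNS))],
                       "VERB": FILLER_VERBS[rng.integers(len(FILLER_VERBS))]})

    relations: set[tuple[str, str]] = set()
    if not positive:
        for _ in range(2):
            add("filler", {"NOUN": FILLER_NOUNS[rng.integers(len(FILLER_NOUNS))],
                           "VERB": FILLER_VERBS[rng.integers(len(FILLER_VERBS))]})
    else:
        relations.add((chem_concept(C), dis_concept(D)))
        if locus == "intra":
            add("intra_pos", {"CHEM": chem_surface(C), "TRIG": trig_present,
                              "ADJ": adj(), "DIS": dis_surface(D)},
                [(0, "Chemical", chem_concept(C)), (3, "Disease", dis_concept(D))])
            add("filler", {"NOUN": FILLER_NOUNS[rng.integers(len(FILLER_NOUNS))],
                           "VERB": FILLER_VERBS[rng.integers(len(FILLER_VERBS))]})
        elif locus == "inter-ns":
            add("inter_chem", {"CHEM": chem_surface(C), "TRIG": trig_past},
                [(0, "Chemical", chem_concept(C))])
            add("dis_observe", {"ADJ": adj(), "DIS": dis_surface(D)},
                [(1, "Disease", dis_concept(D))])
        else:  # inter-title: chemical only in the title
            add("inter_trigger", {"TRIG": trig_present})
            add("dis_observe", {"ADJ": adj(), "DIS": dis_surface(D)},
                [(1, "Disease", dis_concept(D))])
    return _DocPlan(doc_id, sentences, mentions, relations,
                    "intra" if locus == "intra" else ("inter" if locus else None))


def _realize(plan: _DocPlan) -> tuple[DocumentRecord, list[ParsedSentence]]:
    """Lay the planned sentences out as text and attach absolute spans."""
    parses: list[ParsedSentence] = []
    pieces: list[str] = []
    cursor = 0
    mention_map: dict[tuple[int, int], tuple[int, int, str]] = {}
    for si, sent in enumerate(plan.sentences):
        if si > 0:
            cursor += 1  # single separator (after title) or inter-sentence space
        start = cursor
        toks = []
        for ti, tok in enumerate(sent.tokens):
            if ti > 0:
                cursor += 1
            span = (cursor, cursor + len(tok.surface))
            toks.append(Token(tok.surface, tok.pos, span))
            mention_map[(si, ti)] = (span[0], span[1], tok.surface)
            cursor = span[1]
        parses.append(ParsedSentence(toks, sent.arcs, sent.root))
        pieces.append(" ".join(t.surface for t in sent.tokens))
    title = pieces[0]
    abstract = " ".join(pieces[1:])
    mentions = []
    for si, ti, etype, concept in plan.mentions:
        b, e, surf = mention_map[(si, ti)]
        mentions.append(Mention(plan.doc_id, b, e, surf, etype, concept))
    rec = DocumentRecord(plan.doc_id, title, abstract, mentions, set(plan.relations))
    rec.sentence_spans = [(s.tokens[0].span[0], s.tokens[-1].span[1]) for s in parses]
    rec.validate()
    return rec, parses


def generate_documents(spec: GeneratorSpec
                       ) -> tuple[list[DocumentRecord],
                                  dict[str, list[ParsedSentence]],
                                  dict[tuple[str, str, str], str]]:
    """In-memory form: (documents, parses per doc, gold-pair locus map)."""
    rng = np.random.default_rng(spec.seed)
    docs, parses_by_doc, locus = [], {}, {}
    for i in range(spec.n_docs):
        plan = _plan_document(spec, rng, f"90{i:05d}")
        rec, parses = _realize(plan)
        docs.append(rec)
        parses_by_doc[rec.doc_id] = parses
        for chem, dis in rec.relations:
            locus[(rec.doc_id, chem, dis)] = plan.locus
    return docs, parses_by_doc, locus


def generate_corpus(spec: GeneratorSpec) -> tuple[str, str, dict]:
    """Serialized form: (PubTator stream, CoNLL-U stream, locus map).

    Identical seeds produce identical bytes.
    """
    docs, parses_by_doc, locus = generate_documents(spec)
    pubtator = write_pubtator(docs)
    blocks = []
    for doc in docs:
        blocks.append(f"# newdoc id = {doc.doc_id}\n"
                      + write_conllu(parses_by_doc[doc.doc_id]))
    return pubtator, "".join(blocks), locus


def vocabulary(spec: GeneratorSpec) -> list[str]:
    """Every lowercase word type the generator can emit."""
    words = {w for rows in TEMPLATES.values()
             for w, _, _, _ in rows if not w.startswith("{")}
    words |= set(ADJECTIVES) | set(FILLER_NOUNS) | set(FILLER_VERBS)
    words |= {w for pair in TRIGGERS for w in pair}
    words |= {chem_surface(i) for i in range(spec.n_chemicals)}
    words |= {dis_surface(i) for i in range(spec.n_diseases)}
    return sorted(words)


def word_vectors_text(spec: GeneratorSpec, dim: int, seed: int = 7) -> str:
    """A word2vec-text file of random vectors covering the generator
    vocabulary (synthetic stand-in for pre-trained embeddings)."""
    vocab = vocabulary(spec)
    rng = np.random.default_rng(seed)
    lines = [f"{len(vocab)} {dim}"]
    for w in vocab:
        vec = rng.uniform(-0.5, 0.5, size=dim)
        lines.append(w + " " + " ".join(f"{v:.5f}" for v in vec))
    return "\n".join(lines) + "\n"
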