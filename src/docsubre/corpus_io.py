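"""Readers, writers and mention alignment for the corpus formats.

The pipeline consumes PubTator-style annotated abstracts (title + abstract
text, character-offset entity mentions typed Chemical/Disease with MeSH-style
concept ids, and document-level CID relation pairs), per-sentence dependency
parses in CoNLL-U, and two optional tab-separated side tables: knowledge-base
chemical-disease pairs and coreference links.

Offsets are 0-based half-open over ``title + " " + abstract`` (a single
separator character, the PubTator convention).  The title is sentence index 0.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field

from .errors import AlignmentError, MalformedRecordError, ParseStructureError

logger = logging.getLogger(__name__)

CHEMICAL = "Chemical"
DISEASE = "Disease"
ENTITY_TYPES = frozenset({CHEMICAL, DISEASE})

UNK_LABEL = "<unk>"

# Dependency label inventory: 71 named labels + the reserved unknown row.
# Universal Dependencies core labels, common subtypes, and the legacy
# Stanford/clearNLP labels that biomedical parsers still emit.
DEP_LABELS: tuple[str, ...] = (
    "acl", "advcl", "advmod", "amod", "appos", "aux", "case", "cc", "ccomp",
    "clf", "compound", "conj", "cop", "csubj", "dep", "det", "discourse",
    "dislocated", "expl", "fixed", "flat", "goeswith", "iobj", "list", "mark",
    "nmod", "nsubj", "nummod", "obj", "obl", "orphan", "parataxis", "punct",
    "reparandum", "vocative", "xcomp",
    "acl:relcl", "aux:pass", "cc:preconj", "compound:prt", "csubj:pass",
    "det:predet", "expl:impers", "flat:foreign", "flat:name", "nmod:npmod",
    "nmod:poss", "nmod:tmod", "nsubj:pass", "obl:agent", "obl:npmod",
    "obl:tmod",
    "dobj", "nsubjpass", "csubjpass", "auxpass", "neg", "prep", "pobj",
    "pcomp", "attr", "oprd", "dative", "agent", "acomp", "quantmod",
    "npadvmod", "predet", "preconj", "prt", "meta",
    UNK_LABEL,
)
assert len(DEP_LABELS) == 72

# POS inventory: 56 OntoNotes / Penn Treebank tags + the reserved unknown row.
POS_TAGS: tuple[str, ...] = (
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD", "NN",
    "NNP", "NNPS", "NNS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR", "RBS",
    "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "WDT",
    "WP", "WP$", "WRB", ".", ",", ":", "''", "``", "-LRB-", "-RRB-", "HYPH",
    "NFP", "$", "#", "ADD", "AFX", "GW", "XX", "SP", "_SP", "NIL", "-NONE-",
    "X",
    UNK_LABEL,
)
assert len(POS_TAGS) == 57

# Character inventory: 84 characters + the reserved unknown row.
CHAR_INVENTORY: tuple[str, ...] = tuple(
    string.ascii_lowercase + string.ascii_uppercase + string.digits
    + ".,;:!?'\"()-[]{}/\\%+=<>"
) + (UNK_LABEL,)
assert len(CHAR_INVENTORY) == 85


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mention:
    doc_id: str
    begin: int
    end: int
    surface: str
    etype: str
    concept: str

    def __post_init__(self):
        if self.begin >= self.end:
            raise MalformedRecordError(
                f"{self.doc_id}: mention span [{self.begin},{self.end}) is empty")
        if self.etype not in ENTITY_TYPES:
            raise MalformedRecordError(
                f"{self.doc_id}: unknown entity type {self.etype!r}")


@dataclass
class DocumentRecord:
    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    relations: set[tuple[str, str]] = field(default_factory=set)
    sentence_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return self.title + " " + self.abstract

    @property
    def n_abstract_sentences(self) -> int:
        return len(self.sentence_spans) - 1

    def validate(self) -> None:
        text = self.full_text
        for m in self.mentions:
            if m.end > len(text):
                raise MalformedRecordError(
                    f"{self.doc_id}: mention offset {m.end} outside text")
            if text[m.begin:m.end] != m.surface:
                raise MalformedRecordError(
                    f"{self.doc_id}: mention surface {m.surface!r} does not match "
                    f"text {text[m.begin:m.end]!r} at [{m.begin},{m.end})")
        concepts = {m.concept for m in self.mentions}
        for chem, dis in self.relations:
            if chem not in concepts or dis not in concepts:
                raise MalformedRecordError(
                    f"{self.doc_id}: relation ({chem},{dis}) references a concept "
                    "with no mention")
        spans = self.sentence_spans
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 > b0:
                raise MalformedRecordError(f"{self.doc_id}: sentence spans overlap")


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str
    span: tuple[int, int] | None = None  # absolute offsets over the document


@dataclass
class ParsedSentence:
    tokens: list[Token]
    arcs: list[tuple[int, int, str]]  # (head index, dependent index, label)
    root: int

    def validate(self) -> None:
        n = len(self.tokens)
        heads = {}
        for h, d, _ in self.arcs:
            if d in heads:
                raise ParseStructureError(f"token {d} has two heads")
            if not (0 <= h < n and 0 <= d < n):
                raise ParseStructureError("arc endpoint outside sentence")
            heads[d] = h
        if self.root in heads or len(heads) != n - 1:
            raise ParseStructureError("sentence is not a single-rooted tree")
        # cycle check: walk up from every node
        for start in range(n):
            seen, cur = set(), start
            while cur in heads:
                if cur in seen:
                    raise ParseStructureError("dependency arcs form a cycle")
                seen.add(cur)
                cur = heads[cur]
            if cur != self.root:
                raise ParseStructureError("token not reachable from root")

    def children(self, idx: int) -> list[tuple[int, str]]:
        """Dependents of token ``idx`` with their incoming labels."""
        return [(d, lab) for h, d, lab in self.arcs if h == idx]

    def head_of(self, idx: int) -> int | None:
        for h, d, _ in self.arcs:
            if d == idx:
                return h
        return None


@dataclass(frozen=True)
class KBPair:
    chemical: str
    disease: str
    relation_code: str


@dataclass(frozen=True)
class CorefLink:
    """Token-index spans: (sentence index, first token, one-past-last token)."""
    anaphor: tuple[int, int, int]
    antecedent: tuple[int, int, int]


@dataclass(frozen=True)
class MentionAlignment:
    sent_idx: int
    token_ids: tuple[int, ...]
    head: int


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_BOUNDARY = re.compile(r"[.!?](?=\s+[A-Z])")


def split_sentences(text: str, offset: int = 0) -> list[tuple[int, int]]:
    """Deterministic splitter: sentence ends after . ! or ? followed by
    whitespace and an uppercase letter.  Returns absolute spans."""
    if not text:
        return []
    spans = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        spans.append((start, end))
        start = end
        while start < len(text) and text[start].isspace():
            start += 1
    if start < len(text):
        spans.append((start, len(text)))
    return [(s + offset, e + offset) for s, e in spans]


def compute_sentence_spans(title: str, abstract: str) -> list[tuple[int, int]]:
    spans = [(0, len(title))]
    spans.extend(split_sentences(abstract, offset=len(title) + 1))
    return spans


# ---------------------------------------------------------------------------
# PubTator
# ---------------------------------------------------------------------------

def read_pubtator(stream) -> list[DocumentRecord]:
    """Parse a PubTator stream (a file-like object or a string)."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    records: list[DocumentRecord] = []
    block: list[str] = []
    for line in lines + [""]:
        if line.strip() == "":
            if block:
                records.append(_parse_block(block))
                block = []
        else:
            block.append(line)
    return records


def _parse_block(block: list[str]) -> DocumentRecord:
    title = abstract = None
    pmid = None
    mentions: list[Mention] = []
    relations: set[tuple[str, str]] = set()
    for line in block:
        parts = line.split("|", 2)
        if len(parts) == 3 and parts[1] == "t":
            pmid, title = parts[0], parts[2]
            continue
        if len(parts) == 3 and parts[1] == "a":
            pmid, abstract = parts[0], parts[2]
            continue
        cols = line.split("\t")
        if len(cols) == 4 and cols[1] == "CID":
            relations.add((cols[2], cols[3]))
        elif len(cols) == 6:
            try:
                begin, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise MalformedRecordError(f"{cols[0]}: bad offsets in {line!r}") from exc
            mentions.append(Mention(cols[0], begin, end, cols[3], cols[4], cols[5]))
        else:
            raise MalformedRecordError(f"unrecognized PubTator line {line!r}")
    if title is None or abstract is None:
        raise MalformedRecordError(f"{pmid or '?'}: missing title or abstract line")
    rec = DocumentRecord(pmid, title, abstract, mentions, relations)
    rec.sentence_spans = compute_sentence_spans(title, abstract)
    rec.validate()
    return rec


def write_pubtator(records: list[DocumentRecord]) -> str:
    out = []
    for rec in records:
        rec.validate()
        lines = [f"{rec.doc_id}|t|{rec.title}", f"{rec.doc_id}|a|{rec.abstract}"]
        for m in sorted(rec.mentions, key=lambda m: (m.begin, m.end)):
            lines.append(
                f"{m.doc_id}\t{m.begin}\t{m.end}\t{m.surface}\t{m.etype}\t{m.concept}")
        for chem, dis in sorted(rec.relations):
            lines.append(f"{rec.doc_id}\tCID\t{chem}\t{dis}")
        out.append("\n".join(lines))
    return "\n\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

def read_conllu(stream, dep_labels: tuple[str, ...] = DEP_LABELS) -> list[ParsedSentence]:
    """Parse CoNLL-U blocks into dependency trees.

    HEAD/DEPREL must be populated; labels outside ``dep_labels`` are mapped to
    the reserved unknown label (and logged).  Token character spans are read
    from MISC ``start_char``/``end_char`` entries when present.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    known = set(dep_labels)
    sentences: list[ParsedSentence] = []
    rows: list[list[str]] = []
    for line in lines + [""]:
        if line.strip() == "":
            if rows:
                sentences.append(_build_sentence(rows, known))
                rows = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if "-" in cols[0] or "." in cols[0]:
            continue  # multiword / empty nodes are not tree tokens
        rows.append(cols)
    return sentences


def _build_sentence(rows: list[list[str]], known: set[str]) -> ParsedSentence:
    tokens: list[Token] = []
    arcs: list[tuple[int, int, str]] = []
    root = None
    for cols in rows:
        if len(cols) < 8:
            raise MalformedRecordError(f"short CoNLL-U row: {cols!r}")
        idx = int(cols[0]) - 1
        form = cols[1]
        xpos = cols[4] if len(cols) > 4 and cols[4] != "_" else cols[3]
        span = None
        if len(cols) >= 10 and cols[9] != "_":
            misc = dict(kv.split("=", 1) for kv in cols[9].split("|") if "=" in kv)
            if "start_char" in misc and "end_char" in misc:
                span = (int(misc["start_char"]), int(misc["end_char"]))
        tokens.append(Token(form, xpos, span))
        head = int(cols[6])
        label = cols[7]
        if head == 0:
            if root is not None:
                raise ParseStructureError("sentence has multiple roots")
            root = idx
        else:
            if label not in known:
                logger.warning("unknown dependency label %r mapped to %s", label, UNK_LABEL)
                label = UNK_LABEL
            arcs.append((head - 1, idx, label))
    if root is None:
        raise ParseStructureError("sentence has no root")
    sent = ParsedSentence(tokens, arcs, root)
    sent.validate()
    return sent


def read_conllu_corpus(stream) -> dict[str, list[ParsedSentence]]:
    """Multi-document CoNLL-U: ``# newdoc id = X`` comments group sentences
    by document; returns doc id -> parses (title first)."""
    if not isinstance(stream, str):
        stream = stream.read()
    docs: dict[str, list[ParsedSentence]] = {}
    current = None
    block: list[str] = []

    def flush():
        nonlocal block
        if block:
            if current is None:
                raise MalformedRecordError("sentence before any newdoc marker")
            docs[current].extend(read_conllu("\n".join(block) + "\n"))
            block = []

    for line in stream.splitlines() + [""]:
        m = re.match(r"#\s*newdoc id\s*=\s*(\S+)", line)
        if m:
            flush()
            current = m.group(1)
            docs.setdefault(current, [])
            continue
        if line.strip() == "":
            flush()
            continue
        block.append(line)
    flush()
    return docs


def write_conllu(parses: list[ParsedSentence]) -> str:
    blocks = []
    for si, sent in enumerate(parses):
        heads = {d: (h, lab) for h, d, lab in sent.arcs}
        lines = [f"# sent_id = {si}"]
        for ti, tok in enumerate(sent.tokens):
            if ti == sent.root:
                head, label = 0, "root"
            else:
                h, label = heads[ti]
                head = h + 1
            misc = "_"
            if tok.span is not None:
                misc = f"start_char={tok.span[0]}|end_char={tok.span[1]}"
            lines.append("\t".join([
                str(ti + 1), tok.surface, "_", "_", tok.pos, "_",
                str(head), label, "_", misc]))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# Side tables
# ---------------------------------------------------------------------------

def read_kb_pairs(stream, relation_code: str = "M") -> list[KBPair]:
    """`chemical_id<TAB>disease_id<TAB>relation_code`; keeps matching rows."""
    if not isinstance(stream, str):
        stream = stream.read()
    pairs = []
    for ln, line in enumerate(stream.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3 or not all(cols):
            raise MalformedRecordError(f"KB table line {ln}: malformed row {line!r}")
        if cols[2] == relation_code:
            pairs.append(KBPair(cols[0], cols[1], cols[2]))
    return pairs


def read_coref_links(stream, parses: list[ParsedSentence] | None = None) -> list[CorefLink]:
    """`sent<TAB>begin<TAB>end<TAB>ant_sent<TAB>ant_begin<TAB>ant_end`
    with token-index spans; validated against ``parses`` when given."""
    if not isinstance(stream, str):
        stream = stream.read()
    links = []
    for ln, line in enumerate(stream.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 6:
            raise MalformedRecordError(f"coref table line {ln}: malformed row {line!r}")
        try:
            s, b, e, as_, ab, ae = (int(c) for c in cols)
        except ValueError as exc:
            raise MalformedRecordError(f"coref table line {ln}: non-integer field") from exc
        link = CorefLink((s, b, e), (as_, ab, ae))
        if parses is not None:
            for sent_idx, lo, hi in (link.anaphor, link.antecedent):
                if not (0 <= sent_idx < len(parses)):
                    raise MalformedRecordError(
                        f"coref table line {ln}: sentence index {sent_idx} outside document")
                if not (0 <= lo < hi <= len(parses[sent_idx].tokens)):
                    raise MalformedRecordError(
                        f"coref table line {ln}: token span outside sentence")
        links.append(link)
    return links


# ---------------------------------------------------------------------------
# Mention alignment
# ---------------------------------------------------------------------------

def _token_spans(doc: DocumentRecord, sent_idx: int,
                 sent: ParsedSentence) -> list[tuple[int, int]]:
    if all(t.span is not None for t in sent.tokens):
        return [t.span for t in sent.tokens]
    lo, hi = doc.sentence_spans[sent_idx]
    text = doc.full_text
    spans, cursor = [], lo
    for tok in sent.tokens:
        pos = text.find(tok.surface, cursor, hi)
        if pos < 0:
            raise AlignmentError(
                f"{doc.doc_id}: token {tok.surface!r} not found in sentence {sent_idx}")
        spans.append((pos, pos + len(tok.surface)))
        cursor = pos + len(tok.surface)
    return spans


def align_mentions(doc: DocumentRecord,
                   parses: list[ParsedSentence]) -> dict[int, MentionAlignment]:
    """Map each mention (by index in ``doc.mentions``) to its sentence, the
    tokens its span overlaps, and its syntactic head token.

    The head is the mention token whose syntactic head lies outside the
    mention token set; ties or no such token fall back to the rightmost
    mention token.  Mentions crossing sentence boundaries are rejected.
    """
    if len(parses) != len(doc.sentence_spans):
        raise AlignmentError(
            f"{doc.doc_id}: {len(parses)} parses for {len(doc.sentence_spans)} sentences")
    all_spans = [_token_spans(doc, si, s) for si, s in enumerate(parses)]
    result: dict[int, MentionAlignment] = {}
    for mi, m in enumerate(doc.mentions):
        hits = []  # (sent_idx, token_idx)
        for si, spans in enumerate(all_spans):
            for ti, (b, e) in enumerate(spans):
                if b < m.end and m.begin < e:
                    hits.append((si, ti))
        if not hits:
            raise AlignmentError(f"{doc.doc_id}: mention {m.surface!r} overlaps no token")
        sents = {si for si, _ in hits}
        if len(sents) > 1:
            raise AlignmentError(
                f"{doc.doc_id}: mention {m.surface!r} crosses a sentence boundary")
        si = sents.pop()
        token_ids = tuple(sorted(ti for _, ti in hits))
        token_set = set(token_ids)
        sent = parses[si]
        outward = [ti for ti in token_ids
                   if ti == sent.root or sent.head_of(ti) not in token_set]
        head = outward[0] if len(outward) == 1 else token_ids[-1]
        result[mi] = MentionAlignment(si, token_ids, head)
    return result
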