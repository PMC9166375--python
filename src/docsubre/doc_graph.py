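"""Document subgraphs: merged dependency trees plus labeled virtual edges.

A document subgraph covers the title (always sentence 0) plus a sliding
window of consecutive abstract sentences.  Syntactic edges keep their
directed dependency labels; six families of undirected virtual edges can be
injected on top: NEXT-SENT between roots of consecutive window sentences,
TITLE between the title root and the first window sentence's root,
three coreference subtypes, and KB-CTD between head tokens of a
chemical/disease mention pair recorded in the knowledge base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .corpus_io import (CHEMICAL, DISEASE, CorefLink, DocumentRecord, KBPair,
                        MentionAlignment, ParsedSentence, align_mentions)
from .errors import ConfigurationError, DocsubreError

Node = tuple[int, int]  # (sentence index, token index)

MAX_WINDOW = 5

TITLE = "TITLE"
NEXT_SENT = "NEXT-SENT"
COREF_SENT = "COREF-sent"
COREF_TO_TITLE = "COREF-to-title"
COREF_FROM_TITLE = "COREF-from-title"
KB_CTD = "KB-CTD"
VIRTUAL_LABELS: tuple[str, ...] = (
    TITLE, NEXT_SENT, COREF_SENT, COREF_TO_TITLE, COREF_FROM_TITLE, KB_CTD)

SYNTACTIC = "syntactic"
VIRTUAL = "virtual"


@dataclass(frozen=True)
class WindowSpec:
    """``first`` is the document sentence index (>= 1) of the first window
    sentence; the title is implicitly part of every window."""
    first: int
    width: int

    def __post_init__(self):
        if not (1 <= self.width <= MAX_WINDOW):
            raise ConfigurationError(f"window width {self.width} outside [1,{MAX_WINDOW}]")
        if self.first < 1:
            raise ConfigurationError("window cannot start at the title")

    @property
    def sentences(self) -> tuple[int, ...]:
        """Window sentences including the title."""
        return (0,) + tuple(range(self.first, self.first + self.width))

    @property
    def body_sentences(self) -> tuple[int, ...]:
        return tuple(range(self.first, self.first + self.width))


@dataclass(frozen=True)
class EdgeConfig:
    """Independent toggles for each virtual-edge family (ablation switches)."""
    title: bool = True
    next_sent: bool = True
    coref_sent: bool = True
    coref_to_title: bool = True
    coref_from_title: bool = True
    kb_ctd: bool = True

    def without(self, family: str) -> "EdgeConfig":
        key = {TITLE: "title", NEXT_SENT: "next_sent", COREF_SENT: "coref_sent",
               COREF_TO_TITLE: "coref_to_title", COREF_FROM_TITLE: "coref_from_title",
               KB_CTD: "kb_ctd"}[family]
        return replace(self, **{key: False})


# Table-style default for the final system: only TITLE and NEXT-SENT.
LEAN_EDGES = EdgeConfig(coref_sent=False, coref_to_title=False,
                        coref_from_title=False, kb_ctd=False)


@dataclass(frozen=True)
class GraphEdge:
    u: Node
    v: Node
    category: str  # syntactic | virtual
    label: str
    directed: bool  # True: u is the head, v the dependent

    def key(self):
        if self.directed:
            return (self.u, self.v, self.category, self.label)
        a, b = sorted((self.u, self.v))
        return (a, b, self.category, self.label)


@dataclass
class DocumentSubgraph:
    window: WindowSpec
    nodes: set[Node]
    edges: list[GraphEdge]
    roots: dict[int, Node] = field(default_factory=dict)

    def adjacency(self) -> dict[Node, list[tuple[Node, str, str, str]]]:
        """node -> sorted [(neighbor, label, category, traversal direction)].

        Traversal direction is 'with'/'against' the arc for syntactic edges
        and 'fwd'/'rev' (traversal order w.r.t. the stored canonical endpoint
        order) for undirected virtual edges.
        """
        adj: dict[Node, list[tuple[Node, str, str, str]]] = {n: [] for n in self.nodes}
        for e in self.edges:
            if e.directed:
                adj[e.u].append((e.v, e.label, e.category, "with"))
                adj[e.v].append((e.u, e.label, e.category, "against"))
            else:
                a, b = sorted((e.u, e.v))
                adj[a].append((b, e.label, e.category, "fwd"))
                adj[b].append((a, e.label, e.category, "rev"))
        for lst in adj.values():
            lst.sort()
        return adj

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.u, e.v, category=e.category, label=e.label,
                       directed=e.directed)
        return g

    def to_edge_tsv(self) -> str:
        lines = []
        for e in sorted(self.edges, key=lambda e: e.key()):
            direction = "head->dep" if e.directed else "undirected"
            lines.append(f"{e.u[0]}:{e.u[1]}\t{e.v[0]}:{e.v[1]}\t"
                         f"{e.category}\t{e.label}\t{direction}")
        return "\n".join(lines) + ("\n" if lines else "")

    def to_graphml(self) -> str:
        g = nx.MultiGraph()
        g.add_nodes_from(f"{n[0]}:{n[1]}" for n in self.nodes)
        for e in self.edges:
            g.add_edge(f"{e.u[0]}:{e.u[1]}", f"{e.v[0]}:{e.v[1]}",
                       category=e.category, label=e.label,
                       directed="true" if e.directed else "false")
        return "\n".join(nx.generate_graphml(g))


def enumerate_windows(n_sentences: int, w: int) -> list[WindowSpec]:
    """All stride-1 windows of ``w`` consecutive abstract sentences.

    Documents shorter than ``w`` yield a single whole-document window (so
    short abstracts still emit instances).
    """
    if not (1 <= w <= MAX_WINDOW):
        raise ConfigurationError(f"window width {w} outside [1,{MAX_WINDOW}]")
    if n_sentences < 1:
        raise ConfigurationError("document has no abstract sentences")
    if n_sentences < w:
        return [WindowSpec(1, n_sentences)]
    return [WindowSpec(first, w) for first in range(1, n_sentences - w + 2)]


def _span_head(sent: ParsedSentence, lo: int, hi: int) -> int:
    """Head token of a token span: the token headed from outside the span."""
    span = set(range(lo, hi))
    outward = [t for t in span
               if t == sent.root or sent.head_of(t) not in span]
    return outward[0] if len(outward) == 1 else hi - 1


def build_subgraph(doc: DocumentRecord,
                   parses: list[ParsedSentence],
                   window: WindowSpec,
                   coref_links: list[CorefLink] = (),
                   kb_pairs: list[KBPair] = (),
                   edge_config: EdgeConfig = EdgeConfig(),
                   alignments: dict[int, MentionAlignment] | None = None,
                   ) -> DocumentSubgraph:
    """Merge the dependency trees of the title + window sentences and inject
    the enabled virtual-edge families.

    Coref/KB edges whose endpoints fall outside the window are skipped;
    endpoints outside the document raise.
    """
    sents = window.sentences
    if max(sents) >= len(parses):
        raise DocsubreError(
            f"{doc.doc_id}: window {window} references sentence without a parse")

    nodes: set[Node] = set()
    edges: list[GraphEdge] = []
    roots: dict[int, Node] = {}
    for s in sents:
        sent = parses[s]
        roots[s] = (s, sent.root)
        for t in range(len(sent.tokens)):
            nodes.add((s, t))
        for h, d, lab in sent.arcs:
            edges.append(GraphEdge((s, h), (s, d), SYNTACTIC, lab, directed=True))

    virtual: dict[tuple, GraphEdge] = {}

    def add_virtual(u: Node, v: Node, label: str):
        if u == v:
            return
        e = GraphEdge(u, v, VIRTUAL, label, directed=False)
        virtual.setdefault(e.key(), e)

    if edge_config.next_sent:
        body = window.body_sentences
        for a, b in zip(body, body[1:]):
            add_virtual(roots[a], roots[b], NEXT_SENT)
    if edge_config.title:
        add_virtual(roots[0], roots[window.first], TITLE)

    in_window = set(sents)
    for link in coref_links:
        for s, lo, hi in (link.anaphor, link.antecedent):
            if not (0 <= s < len(parses)) or not (0 <= lo < hi <= len(parses[s].tokens)):
                raise DocsubreError(f"{doc.doc_id}: coref endpoint outside document")
        (sa, la, ha), (sb, lb, hb) = link.anaphor, link.antecedent
        if sa not in in_window or sb not in in_window:
            continue
        if sa == 0:
            subtype, enabled = COREF_FROM_TITLE, edge_config.coref_from_title
        elif sb == 0:
            subtype, enabled = COREF_TO_TITLE, edge_config.coref_to_title
        else:
            subtype, enabled = COREF_SENT, edge_config.coref_sent
        if enabled:
            add_virtual((sa, _span_head(parses[sa], la, ha)),
                        (sb, _span_head(parses[sb], lb, hb)), subtype)

    if edge_config.kb_ctd and kb_pairs:
        if alignments is None:
            alignments = align_mentions(doc, parses)
        kb = {(p.chemical, p.disease) for p in kb_pairs}
        chems = [(m, alignments[i]) for i, m in enumerate(doc.mentions)
                 if m.etype == CHEMICAL and alignments[i].sent_idx in in_window]
        diss = [(m, alignments[i]) for i, m in enumerate(doc.mentions)
                if m.etype == DISEASE and alignments[i].sent_idx in in_window]
        for cm, ca in chems:
            for dm, da in diss:
                if (cm.concept, dm.concept) in kb:
                    add_virtual((ca.sent_idx, ca.head), (da.sent_idx, da.head), KB_CTD)

    edges.extend(virtual[k] for k in sorted(virtual))
    return DocumentSubgraph(window, nodes, edges, roots)
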