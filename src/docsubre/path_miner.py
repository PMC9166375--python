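"""Path mining between entity mention heads on document subgraphs.

Bounded breadth-first enumeration of simple paths, minimal-span filtering of
mention-pair co-occurrences, per-concept-pair instance merging with
surface-pattern deduplication, and top-k path selection.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

from .corpus_io import ParsedSentence
from .doc_graph import DocumentSubgraph, Node, WindowSpec
from .errors import ConfigurationError, DocsubreError

CID = "CID"
NONE = "NONE"

DEFAULT_MAX_DEPTH = 15
DEFAULT_MAX_PATHS = 150
DEFAULT_TOP_K = 3


@dataclass(frozen=True)
class TraversedEdge:
    label: str
    category: str  # syntactic | virtual
    direction: str  # with/against (syntactic), fwd/rev (virtual traversal order)


@dataclass(frozen=True)
class Path:
    """Alternating node/edge sequence between two mention head nodes."""
    nodes: tuple[Node, ...]
    edges: tuple[TraversedEdge, ...]

    def __post_init__(self):
        if len(self.nodes) != len(self.edges) + 1:
            raise DocsubreError("path must alternate nodes and edges")

    def __len__(self):
        return len(self.nodes)

    def sort_key(self):
        return (len(self.nodes), self.nodes,
                tuple((e.label, e.category, e.direction) for e in self.edges))


def path_signature(path: Path, parses: list[ParsedSentence]) -> tuple:
    """Dedup key: the lexical surface pattern of the path — per-token
    (surface, POS) interleaved with per-edge (label, direction) — so repeats
    of the same pattern at different document positions also collapse."""
    sig: list[tuple] = []
    for i, (s, t) in enumerate(path.nodes):
        tok = parses[s].tokens[t]
        sig.append((tok.surface, tok.pos))
        if i < len(path.edges):
            e = path.edges[i]
            sig.append((e.label, e.direction))
    return tuple(sig)


def find_paths(subgraph: DocumentSubgraph, source: Node, target: Node,
               md: int = DEFAULT_MAX_DEPTH, kmax: int = DEFAULT_MAX_PATHS,
               ) -> list[Path]:
    """Breadth-first enumeration of simple paths from source to target.

    Paths never revisit a node, contain at most ``md`` nodes, and collection
    stops after ``kmax`` paths.  Output order is nondecreasing node count
    with lexicographic tie-breaking on node coordinates (then edge labels),
    so runs are reproducible.
    """
    if source == target:
        raise DocsubreError("degenerate pair: source equals target")
    if source not in subgraph.nodes or target not in subgraph.nodes:
        raise DocsubreError("path endpoint not in subgraph")
    if md < 2:
        raise ConfigurationError("md must be >= 2")
    if kmax < 1:
        raise ConfigurationError("kmax must be >= 1")

    adj = subgraph.adjacency()
    out: list[Path] = []
    queue: deque[tuple[tuple[Node, ...], tuple[TraversedEdge, ...]]] = deque()
    queue.append(((source,), ()))
    while queue and len(out) < kmax:
        nodes, edges = queue.popleft()
        seen = set(nodes)
        for nbr, label, category, direction in adj[nodes[-1]]:
            te = TraversedEdge(label, category, direction)
            if nbr == target:
                if len(nodes) + 1 <= md:
                    out.append(Path(nodes + (nbr,), edges + (te,)))
                    if len(out) >= kmax:
                        break
            elif nbr not in seen and len(nodes) + 1 < md:
                queue.append((nodes + (nbr,), edges + (te,)))
    return out


@dataclass(frozen=True)
class Cooccurrence:
    """One chemical/disease mention pair inside one window."""
    chem_mention: int  # index into doc.mentions
    dis_mention: int
    window: WindowSpec
    span: tuple[int, int]  # [min, max] sentence index of the two mentions


def minimal_span_filter(coocs: list[Cooccurrence]) -> list[Cooccurrence]:
    """Drop a co-occurrence iff another co-occurrence of the same pair
    overlaps it with a strictly contained sentence span."""
    spans = {c.span for c in coocs}

    def dominated(span):
        lo, hi = span
        for olo, ohi in spans:
            if olo >= lo and ohi <= hi and (olo, ohi) != (lo, hi):
                if olo <= hi and lo <= ohi:  # overlap (implied, kept explicit)
                    return True
        return False

    return [c for c in coocs if not dominated(c.span)]


@dataclass
class CandidateInstance:
    """One (document, chemical concept, disease concept) pair with its merged
    deduplicated path set and gold label."""
    doc_id: str
    chemical: str
    disease: str
    paths: list[Path] = field(default_factory=list)
    multiplicities: list[int] = field(default_factory=list)
    label: str = NONE

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical, self.disease)


def merge_instances(doc_id: str, chemical: str, disease: str,
                    paths: list[Path], parses: list[ParsedSentence],
                    label: str = NONE) -> CandidateInstance:
    """Pool all windows' paths for one concept pair into a single instance,
    deduplicating by surface pattern and recording pre-dedup multiplicities.
    Merging is idempotent."""
    unique: dict[tuple, int] = {}
    keep: dict[tuple, Path] = {}
    for p in paths:
        sig = path_signature(p, parses)
        if sig in unique:
            unique[sig] += 1
            if p.sort_key() < keep[sig].sort_key():
                keep[sig] = p
        else:
            unique[sig] = 1
            keep[sig] = p
    ordered = sorted(keep.values(), key=Path.sort_key)
    mult = [unique[path_signature(p, parses)] for p in ordered]
    return CandidateInstance(doc_id, chemical, disease, ordered, mult, label)


def select_top_k(instance: CandidateInstance, k: int = DEFAULT_TOP_K,
                 strategy: str = "shortest") -> CandidateInstance:
    """Keep at most ``k`` paths: the shortest ones, or the ones with the
    highest pre-dedup repetition count (ties: shorter, then path order)."""
    if k < 1:
        raise ConfigurationError("top-k requires k >= 1")
    pairs = list(zip(instance.paths, instance.multiplicities))
    if strategy == "shortest":
        pairs.sort(key=lambda pm: (len(pm[0]), pm[0].sort_key()))
    elif strategy == "most_frequent":
        pairs.sort(key=lambda pm: (-pm[1], len(pm[0]), pm[0].sort_key()))
    else:
        raise ConfigurationError(f"unknown top-k strategy {strategy!r}")
    pairs = pairs[:k]
    return CandidateInstance(instance.doc_id, instance.chemical, instance.disease,
                             [p for p, _ in pairs], [m for _, m in pairs],
                             instance.label)


def dump_instances(instances: list[CandidateInstance],
                   parses_by_doc: dict[str, list[ParsedSentence]]) -> str:
    """JSON-lines dump of instances for inspection/debugging."""
    lines = []
    for inst in instances:
        parses = parses_by_doc[inst.doc_id]
        paths = []
        for p in inst.paths:
            elems = []
            for i, (s, t) in enumerate(p.nodes):
                tok = parses[s].tokens[t]
                elems.append({"kind": "token", "sent": s, "idx": t,
                              "surface": tok.surface, "pos": tok.pos})
                if i < len(p.edges):
                    e = p.edges[i]
                    elems.append({"kind": "edge", "label": e.label,
                                  "category": e.category, "direction": e.direction})
            paths.append(elems)
        lines.append(json.dumps({
            "doc_id": inst.doc_id, "chemical": inst.chemical,
            "disease": inst.disease, "label": inst.label,
            "paths": paths, "multiplicities": inst.multiplicities}))
    return "\n".join(lines) + ("\n" if lines else "")
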