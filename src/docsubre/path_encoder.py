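"""Path representation: from mined dependency paths to embedding matrices.

Each path alternates token vectors ``x_i`` and dependency-unit vectors
``d_i``.  A dependency unit embeds the relation type (separate lookup tables
for the 72-row syntactic and the 6-row virtual label inventories) together
with its traversal direction, passed through a tanh transform.  A token
embeds its word vector, POS tag, optionally a character-level biLSTM output
and a fixed auxiliary lexical vector, again through a tanh transform; it is
then augmented with attentive information gathered from its children on the
ORIGINAL sentence dependency tree (not the document subgraph): each child
context — child word/POS/incoming-label features concatenated with the
parent token vector and a signed-distance term ``d * w_dist`` — is gated by
a learned self-attention weight and by the distance heuristic
``sigmoid(beta * d^2)`` (beta < 0, so far children are damped), pushed
through K kernel filters with ReLU, and max-pooled filter-wise into the
augmentation vector ``a``.  The final token vector is
``x = tanh([t ++ a] W_x + b_x)``.

Two code paths compute the same function: transparent per-item operations
(plain numpy, used directly in tests and for inspection) and a vectorized
batched encoder on the autodiff graph (used for training).  A compositional
test holds them equal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .corpus_io import CHAR_INVENTORY, DEP_LABELS, POS_TAGS, UNK_LABEL, ParsedSentence
from .doc_graph import VIRTUAL_LABELS
from .errors import ConfigurationError
from .path_miner import CandidateInstance, Path

_POS_INDEX = {t: i for i, t in enumerate(POS_TAGS)}
_DEP_INDEX = {l: i for i, l in enumerate(DEP_LABELS)}
_VIRT_INDEX = {l: i for i, l in enumerate(VIRTUAL_LABELS)}
_CHAR_INDEX = {c: i for i, c in enumerate(CHAR_INVENTORY[:-1])}
_UNK_POS = _POS_INDEX[UNK_LABEL]
_UNK_DEP = _DEP_INDEX[UNK_LABEL]
_UNK_CHAR = len(CHAR_INVENTORY) - 1

# direction rows: arc traversed head->dependent (or virtual edge in canonical
# order) = 0; the reverse = 1
_DIR_INDEX = {"with": 0, "fwd": 0, "against": 1, "rev": 1}


def pos_index(tag: str) -> int:
    return _POS_INDEX.get(tag, _UNK_POS)


def dep_index(label: str) -> int:
    return _DEP_INDEX.get(label, _UNK_DEP)


def char_indices(word: str, max_len: int) -> list[int]:
    return [_CHAR_INDEX.get(c, _UNK_CHAR) for c in word[:max_len]]


# ---------------------------------------------------------------------------
# Configuration and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderConfig:
    """Dimensions of the path encoder.

    Defaults are the published-scale configuration: 300-dim word vectors,
    57x50 POS table, 72x150 dependency-type and 2x150 direction tables (the
    6 virtual labels get their own 6x150 table), an 85x50 character table
    with a 50-unit-per-direction biLSTM, a fixed 45-dim auxiliary lexical
    vector, a 32-dim base distance embedding, 100 kernel filters on the
    832-dim child context, and beta = -0.03 for the distance heuristic.
    """
    dim_word: int = 300
    dim_pos: int = 50
    dim_typ: int = 150
    dim_dir: int = 150
    dim_char: int = 50
    char_hidden: int = 50
    use_char: bool = True
    dim_aux: int = 45
    use_aux: bool = True
    dim_token: int = 300       # output of the token transform (t_i)
    dim_dep_unit: int = 150    # output of the dependency transform (d_i)
    dim_distance: int = 32     # base distance embedding w_dist
    n_kernels: int = 100       # K filters on the child context
    dim_x: int = 595           # final token representation x_i
    beta: float = -0.03
    child_cap: int = 6
    max_word_len: int = 16

    def __post_init__(self):
        dims = (self.dim_word, self.dim_pos, self.dim_typ, self.dim_dir,
                self.dim_token, self.dim_dep_unit, self.dim_distance,
                self.n_kernels, self.dim_x)
        if any(d <= 0 for d in dims):
            raise ConfigurationError("all encoder dimensions must be positive")
        if self.beta >= 0:
            raise ConfigurationError("beta must be negative")

    @property
    def token_input_dim(self) -> int:
        dim = self.dim_word + self.dim_pos
        if self.use_char:
            dim += 2 * self.char_hidden
        if self.use_aux:
            dim += self.dim_aux
        return dim

    @property
    def child_base_dim(self) -> int:
        # child word + POS + incoming dependency label; the character and
        # auxiliary features stay out of the child context by design, which
        # is what makes the default context land on 832 dims.
        return self.dim_word + self.dim_pos + self.dim_typ

    @property
    def child_context_dim(self) -> int:
        return self.child_base_dim + self.dim_token + self.dim_distance

    @classmethod
    def small(cls) -> "EncoderConfig":
        """Desk-scale preset for synthetic experiments."""
        return cls(dim_word=24, dim_pos=8, dim_typ=12, dim_dir=8,
                   use_char=False, use_aux=False, dim_token=16,
                   dim_dep_unit=12, dim_distance=4, n_kernels=12, dim_x=20,
                   child_cap=6, max_word_len=12)


class WordTable:
    """Fixed pre-trained word vectors with a lowercase, OOV-safe lookup."""

    def __init__(self, vectors: dict[str, np.ndarray], dim: int):
        self.dim = dim
        words = sorted(vectors)
        self.index = {w: i for i, w in enumerate(words)}
        mat = np.zeros((len(words) + 1, dim))
        for w, i in self.index.items():
            mat[i] = vectors[w]
        self.matrix = mat  # last row = OOV fallback (zeros)
        self.oov = len(words)

    def lookup(self, word: str) -> int:
        return self.index.get(word.lower(), self.oov)


def load_word_vectors(stream) -> WordTable:
    """word2vec text dialect: optional ``V D`` header, then ``word v1 ...``."""
    if not isinstance(stream, str):
        stream = stream.read()
    lines = [ln for ln in stream.splitlines() if ln.strip()]
    if not lines:
        raise ConfigurationError("empty word-vector file")
    start = 0
    head = lines[0].split()
    if len(head) == 2 and all(p.lstrip("-").isdigit() for p in head):
        start = 1
    vectors: dict[str, np.ndarray] = {}
    dim = None
    for ln in lines[start:]:
        parts = ln.split()
        vec = np.array([float(v) for v in parts[1:]])
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ConfigurationError("inconsistent word-vector dimensions")
        vectors[parts[0].lower()] = vec
    return WordTable(vectors, dim)


def aux_vector(word: str, dim: int) -> np.ndarray:
    """Fixed auxiliary lexical vector (synthetic stand-in): a deterministic
    per-word pseudo-random fingerprint seeded from a CRC of the surface."""
    seed = zlib.crc32(word.lower().encode("utf-8")) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.5, 0.5, size=dim)


@dataclass
class EncoderParams:
    """All encoder lookup tables and transforms (autodiff tensors)."""
    cfg: EncoderConfig
    words: WordTable
    tensors: dict[str, ad.Tensor] = field(default_factory=dict)

    @classmethod
    def create(cls, cfg: EncoderConfig, words: WordTable,
               rng: np.random.Generator) -> "EncoderParams":
        if words.dim != cfg.dim_word:
            raise ConfigurationError(
                f"word vectors are {words.dim}-dim, config wants {cfg.dim_word}")
        t: dict[str, ad.Tensor] = {}

        def table(name, rows, dim):
            t[name] = ad.parameter(rng.uniform(-0.1, 0.1, size=(rows, dim)), name)

        def transform(name, fan_in, fan_out):
            t["W_" + name] = ad.parameter(
                ad.glorot_uniform(rng, fan_in, fan_out), "W_" + name)
            t["b_" + name] = ad.parameter(np.zeros(fan_out), "b_" + name)

        table("pos", len(POS_TAGS), cfg.dim_pos)
        table("typ", len(DEP_LABELS), cfg.dim_typ)
        table("virt", len(VIRTUAL_LABELS), cfg.dim_typ)
        table("dir", 2, cfg.dim_dir)
        if cfg.use_char:
            table("char", len(CHAR_INVENTORY), cfg.dim_char)
            h, i = cfg.char_hidden, cfg.dim_char
            for d in ("fw", "bw"):
                t[f"lstm_{d}_Wi"] = ad.parameter(
                    ad.glorot_uniform(rng, i, 4 * h, (i, 4 * h)), f"lstm_{d}_Wi")
                t[f"lstm_{d}_Wh"] = ad.parameter(
                    ad.glorot_uniform(rng, h, 4 * h, (h, 4 * h)), f"lstm_{d}_Wh")
                t[f"lstm_{d}_b"] = ad.parameter(np.zeros(4 * h), f"lstm_{d}_b")
        transform("d", cfg.dim_typ + cfg.dim_dir, cfg.dim_dep_unit)
        transform("t", cfg.token_input_dim, cfg.dim_token)
        t["w_dist"] = ad.parameter(
            rng.uniform(-0.1, 0.1, size=cfg.dim_distance), "w_dist")
        transform("e", cfg.child_context_dim, 1)
        transform("f", cfg.child_context_dim, cfg.n_kernels)
        transform("x", cfg.dim_token + cfg.n_kernels, cfg.dim_x)
        return cls(cfg, words, t)

    def trainable(self) -> list[ad.Tensor]:
        return list(self.tensors.values())

    def __getitem__(self, name: str) -> ad.Tensor:
        return self.tensors[name]


# ---------------------------------------------------------------------------
# Per-item operations (plain numpy forward)
# ---------------------------------------------------------------------------

def _dep_type_row(label: str, params: EncoderParams) -> np.ndarray:
    if label in _VIRT_INDEX:
        return params["virt"].data[_VIRT_INDEX[label]]
    return params["typ"].data[dep_index(label)]


def encode_dependency(label: str, direction: str, params: EncoderParams) -> np.ndarray:
    """d = tanh([type ++ direction] W_d + b_d); components in (-1, 1)."""
    typ = _dep_type_row(label, params)
    d = params["dir"].data[_DIR_INDEX[direction]]
    return np.tanh(np.concatenate([typ, d]) @ params["W_d"].data + params["b_d"].data)


def _char_bilstm_single(word: str, params: EncoderParams) -> np.ndarray:
    cfg = params.cfg
    idx = char_indices(word, cfg.max_word_len) or [_UNK_CHAR]
    emb = params["char"].data[idx]
    h = cfg.char_hidden

    def run(seq, d):
        Wi, Wh = params[f"lstm_{d}_Wi"].data, params[f"lstm_{d}_Wh"].data
        b = params[f"lstm_{d}_b"].data
        hv = np.zeros(h)
        cv = np.zeros(h)
        for xt in seq:
            gates = xt @ Wi + hv @ Wh + b
            i_g = 1 / (1 + np.exp(-gates[:h]))
            f_g = 1 / (1 + np.exp(-gates[h:2 * h]))
            g_g = np.tanh(gates[2 * h:3 * h])
            o_g = 1 / (1 + np.exp(-gates[3 * h:]))
            cv = f_g * cv + i_g * g_g
            hv = o_g * np.tanh(cv)
        return hv

    return np.concatenate([run(emb, "fw"), run(emb[::-1], "bw")])


def _token_features(surface: str, pos: str, params: EncoderParams) -> np.ndarray:
    cfg = params.cfg
    parts = [params.words.matrix[params.words.lookup(surface)],
             params["pos"].data[pos_index(pos)]]
    if cfg.use_char:
        parts.append(_char_bilstm_single(surface, params))
    if cfg.use_aux:
        parts.append(aux_vector(surface, cfg.dim_aux))
    return np.concatenate(parts)


def encode_token(surface: str, pos: str, params: EncoderParams) -> np.ndarray:
    """t = tanh([word ++ POS (++ char ++ aux)] W_t + b_t)."""
    feat = _token_features(surface, pos, params)
    return np.tanh(feat @ params["W_t"].data + params["b_t"].data)


@dataclass(frozen=True)
class ChildContext:
    """One child of a token on the original sentence tree."""
    surface: str
    pos: str
    dep_label: str
    distance: int  # signed token offset child - parent; never 0

    def __post_init__(self):
        if self.distance == 0:
            raise ConfigurationError("child distance must be nonzero")


def child_attention(children: list[ChildContext], t_parent: np.ndarray,
                    params: EncoderParams) -> list[dict]:
    """Two gates per child on its full context vector: a learned
    self-attention weight and the distance heuristic sigmoid(beta d^2)."""
    cfg = params.cfg
    out = []
    for ch in children:
        base = np.concatenate([
            params.words.matrix[params.words.lookup(ch.surface)],
            params["pos"].data[pos_index(ch.pos)],
            params["typ"].data[dep_index(ch.dep_label)]])
        chi = np.concatenate([base, t_parent, ch.distance * params["w_dist"].data])
        e = float(chi @ params["W_e"].data[:, 0] + params["b_e"].data[0])
        alpha_s = 1 / (1 + np.exp(-e))
        alpha_h = 1 / (1 + np.exp(-cfg.beta * ch.distance ** 2))
        out.append({"context": chi, "alpha_s": alpha_s, "alpha_h": alpha_h,
                    "gated": alpha_h * alpha_s * chi})
    return out


def augment(attended: list[dict], params: EncoderParams) -> np.ndarray:
    """a_k = max over children of ReLU(c_h W_f + b_f)_k; leaves give a = 0."""
    if not attended:
        return np.zeros(params.cfg.n_kernels)
    feats = np.stack([
        np.maximum(a["gated"] @ params["W_f"].data + params["b_f"].data, 0.0)
        for a in attended])
    return feats.max(axis=0)


def finalize_token(t: np.ndarray, a: np.ndarray, params: EncoderParams) -> np.ndarray:
    """x = tanh([t ++ a] W_x + b_x)."""
    return np.tanh(np.concatenate([t, a]) @ params["W_x"].data + params["b_x"].data)


def _tree_children(parses: list[ParsedSentence], sent: int, tok: int,
                   cap: int) -> list[ChildContext]:
    sentence = parses[sent]
    out = []
    for d, lab in sorted(sentence.children(tok)):
        c = sentence.tokens[d]
        out.append(ChildContext(c.surface, c.pos, lab, d - tok))
    return out[:cap]


def token_representation(parses: list[ParsedSentence], sent: int, tok: int,
                         params: EncoderParams) -> np.ndarray:
    """Full x_i for a document token (path-independent by construction)."""
    t = encode_token(parses[sent].tokens[tok].surface,
                     parses[sent].tokens[tok].pos, params)
    children = _tree_children(parses, sent, tok, params.cfg.child_cap)
    a = augment(child_attention(children, t, params), params)
    return finalize_token(t, a, params)


@dataclass
class EncodedPath:
    """Alternating x/d vectors: [x_1, d_1, x_2, ..., x_n], length 2n-1."""
    vectors: list[np.ndarray]
    n_tokens: int


def encode_path(path: Path, parses: list[ParsedSentence],
                params: EncoderParams) -> EncodedPath:
    vectors: list[np.ndarray] = []
    for i, (s, t) in enumerate(path.nodes):
        vectors.append(token_representation(parses, s, t, params))
        if i < len(path.edges):
            e = path.edges[i]
            vectors.append(encode_dependency(e.label, e.direction, params))
    return EncodedPath(vectors, len(path.nodes))


# ---------------------------------------------------------------------------
# Batched dataset + autodiff forward
# ---------------------------------------------------------------------------

@dataclass
class PathDataset:
    """Index arrays for a set of instances, padded to [B, k, L]."""
    keys: list[tuple[str, str, str]]
    labels: np.ndarray          # [B] 0=CID, 1=NONE
    path_mask: np.ndarray       # [B,K]
    tok_word: np.ndarray        # [B,K,L]
    tok_pos: np.ndarray
    tok_mask: np.ndarray
    tok_char: np.ndarray | None  # [B,K,L,W]
    char_mask: np.ndarray | None
    tok_aux: np.ndarray | None   # [B,K,L,A] fixed features
    ch_word: np.ndarray         # [B,K,L,M]
    ch_pos: np.ndarray
    ch_dep: np.ndarray
    ch_dist: np.ndarray         # float
    ch_mask: np.ndarray
    edge_syn: np.ndarray        # [B,K,L-1]
    edge_virt: np.ndarray
    edge_is_virt: np.ndarray
    edge_dir: np.ndarray
    zero_path_keys: list[tuple[str, str, str]]

    def __len__(self):
        return len(self.keys)

    def subset(self, idx) -> "PathDataset":
        sl = np.asarray(idx)
        pick = lambda a: None if a is None else a[sl]
        return PathDataset(
            [self.keys[i] for i in sl], self.labels[sl], self.path_mask[sl],
            self.tok_word[sl], self.tok_pos[sl], self.tok_mask[sl],
            pick(self.tok_char), pick(self.char_mask), pick(self.tok_aux),
            self.ch_word[sl], self.ch_pos[sl], self.ch_dep[sl],
            self.ch_dist[sl], self.ch_mask[sl], self.edge_syn[sl],
            self.edge_virt[sl], self.edge_is_virt[sl], self.edge_dir[sl], [])


def build_dataset(instances: list[CandidateInstance],
                  parses_by_doc: dict[str, list[ParsedSentence]],
                  params: EncoderParams, k: int) -> PathDataset:
    """Turn mined instances into padded index arrays.

    Instances with zero paths are set aside (they are predicted NONE and are
    excluded from training)."""
    cfg = params.cfg
    usable = [i for i in instances if i.paths]
    zero = [i.key for i in instances if not i.paths]
    B = len(usable)
    L = max((len(p) for i in usable for p in i.paths[:k]), default=2)
    M = max(cfg.child_cap, 1)
    W = cfg.max_word_len

    labels = np.zeros(B, dtype=np.intp)
    path_mask = np.zeros((B, k))
    tok_word = np.full((B, k, L), params.words.oov, dtype=np.intp)
    tok_pos = np.full((B, k, L), _UNK_POS, dtype=np.intp)
    tok_mask = np.zeros((B, k, L))
    tok_char = np.full((B, k, L, W), _UNK_CHAR, dtype=np.intp) if cfg.use_char else None
    char_mask = np.zeros((B, k, L, W)) if cfg.use_char else None
    tok_aux = np.zeros((B, k, L, cfg.dim_aux)) if cfg.use_aux else None
    ch_word = np.full((B, k, L, M), params.words.oov, dtype=np.intp)
    ch_pos = np.full((B, k, L, M), _UNK_POS, dtype=np.intp)
    ch_dep = np.full((B, k, L, M), _UNK_DEP, dtype=np.intp)
    ch_dist = np.ones((B, k, L, M))
    ch_mask = np.zeros((B, k, L, M))
    Lm1 = max(L - 1, 1)
    edge_syn = np.full((B, k, Lm1), _UNK_DEP, dtype=np.intp)
    edge_virt = np.zeros((B, k, Lm1), dtype=np.intp)
    edge_is_virt = np.zeros((B, k, Lm1))
    edge_dir = np.zeros((B, k, Lm1), dtype=np.intp)

    for b, inst in enumerate(usable):
        parses = parses_by_doc[inst.doc_id]
        labels[b] = 0 if inst.label == "CID" else 1
        for pi, path in enumerate(inst.paths[:k]):
            path_mask[b, pi] = 1.0
            for ti, (s, t) in enumerate(path.nodes):
                tok = parses[s].tokens[t]
                tok_word[b, pi, ti] = params.words.lookup(tok.surface)
                tok_pos[b, pi, ti] = pos_index(tok.pos)
                tok_mask[b, pi, ti] = 1.0
                if cfg.use_char:
                    ci = char_indices(tok.surface, W)
                    tok_char[b, pi, ti, :len(ci)] = ci
                    char_mask[b, pi, ti, :len(ci)] = 1.0
                if cfg.use_aux:
                    tok_aux[b, pi, ti] = aux_vector(tok.surface, cfg.dim_aux)
                for mi, ch in enumerate(_tree_children(parses, s, t, cfg.child_cap)):
                    ch_word[b, pi, ti, mi] = params.words.lookup(ch.surface)
                    ch_pos[b, pi, ti, mi] = pos_index(ch.pos)
                    ch_dep[b, pi, ti, mi] = dep_index(ch.dep_label)
                    ch_dist[b, pi, ti, mi] = ch.distance
                    ch_mask[b, pi, ti, mi] = 1.0
            for ei, e in enumerate(path.edges):
                if e.label in _VIRT_INDEX:
                    edge_virt[b, pi, ei] = _VIRT_INDEX[e.label]
                    edge_is_virt[b, pi, ei] = 1.0
                else:
                    edge_syn[b, pi, ei] = dep_index(e.label)
                edge_dir[b, pi, ei] = _DIR_INDEX[e.direction]

    return PathDataset([i.key for i in usable], labels, path_mask, tok_word,
                       tok_pos, tok_mask, tok_char, char_mask, tok_aux,
                       ch_word, ch_pos, ch_dep, ch_dist, ch_mask, edge_syn,
                       edge_virt, edge_is_virt, edge_dir, zero)


def _char_bilstm_batch(ds: PathDataset, params: EncoderParams) -> ad.Tensor:
    cfg = params.cfg
    B, K, L, W = ds.tok_char.shape
    h = cfg.char_hidden
    flat_idx = ds.tok_char.reshape(-1, W)
    flat_mask = ds.char_mask.reshape(-1, W)
    emb = ad.take_rows(params["char"], flat_idx)  # [Q, W, dim_char]

    def run(direction, order):
        Wi, Wh = params[f"lstm_{direction}_Wi"], params[f"lstm_{direction}_Wh"]
        b = params[f"lstm_{direction}_b"]
        Q = flat_idx.shape[0]
        hv = ad.constant(np.zeros((Q, h)))
        cv = ad.constant(np.zeros((Q, h)))
        for t in order:
            xt = ad.slice_axis(emb, 1, t, t + 1)
            xt = ad.reduce_sum(xt, axes=(1,))  # squeeze the time axis
            gates = ad.add(ad.add(ad.matmul(xt, Wi), ad.matmul(hv, Wh)), b)
            i_g = ad.sigmoid(ad.slice_axis(gates, 1, 0, h))
            f_g = ad.sigmoid(ad.slice_axis(gates, 1, h, 2 * h))
            g_g = ad.tanh(ad.slice_axis(gates, 1, 2 * h, 3 * h))
            o_g = ad.sigmoid(ad.slice_axis(gates, 1, 3 * h, 4 * h))
            c_new = ad.add(ad.mul(f_g, cv), ad.mul(i_g, g_g))
            h_new = ad.mul(o_g, ad.tanh(c_new))
            m = flat_mask[:, t:t + 1]
            cv = ad.add(ad.mul(c_new, m), ad.mul(cv, 1.0 - m))
            hv = ad.add(ad.mul(h_new, m), ad.mul(hv, 1.0 - m))
        return hv

    fw = run("fw", range(W))
    bw = run("bw", range(W - 1, -1, -1))
    out = ad.concat([fw, bw], axis=-1)  # [Q, 2h]
    return ad.reshape(out, (B, K, L, 2 * h))


def _dropout(x: ad.Tensor, rate: float, rng: np.random.Generator) -> ad.Tensor:
    if rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return ad.mul(x, keep)


def encode_batch(ds: PathDataset, params: EncoderParams, *,
                 train: bool = False, rng: np.random.Generator | None = None,
                 noise_scale: float = 0.0, dropout: float = 0.0,
                 ) -> tuple[ad.Tensor, ad.Tensor]:
    """Vectorized encoder: returns (x [B,K,L,X], d [B,K,L-1,D]) tensors."""
    cfg = params.cfg
    B, K, L = ds.tok_word.shape

    parts = [ad.constant(params.words.matrix[ds.tok_word]),
             ad.take_rows(params["pos"], ds.tok_pos)]
    if cfg.use_char:
        parts.append(_char_bilstm_batch(ds, params))
    if cfg.use_aux:
        parts.append(ad.constant(ds.tok_aux))
    t_base = ad.concat(parts, axis=-1)
    t = ad.tanh(ad.add(ad.matmul(t_base, params["W_t"]), params["b_t"]))

    typ_syn = ad.take_rows(params["typ"], ds.edge_syn)
    typ_virt = ad.take_rows(params["virt"], ds.edge_virt)
    mv = ds.edge_is_virt[..., None]
    typ = ad.add(ad.mul(typ_syn, 1.0 - mv), ad.mul(typ_virt, mv))
    dirv = ad.take_rows(params["dir"], ds.edge_dir)
    d = ad.tanh(ad.add(ad.matmul(ad.concat([typ, dirv], axis=-1),
                                 params["W_d"]), params["b_d"]))

    c_base = ad.concat([ad.constant(params.words.matrix[ds.ch_word]),
                        ad.take_rows(params["pos"], ds.ch_pos),
                        ad.take_rows(params["typ"], ds.ch_dep)], axis=-1)
    M = ds.ch_word.shape[3]
    t_exp = ad.expand(t, 3, M)  # [B,K,L,M,T]
    dist_term = ad.mul(ad.constant(ds.ch_dist[..., None]), params["w_dist"])
    chi = ad.concat([c_base, t_exp, dist_term], axis=-1)
    alpha_s = ad.sigmoid(ad.add(ad.matmul(chi, params["W_e"]), params["b_e"]))
    alpha_h = 1.0 / (1.0 + np.exp(-cfg.beta * ds.ch_dist ** 2))
    gated = ad.mul(ad.mul(chi, alpha_s), alpha_h[..., None])
    F = ad.relu(ad.add(ad.matmul(gated, params["W_f"]), params["b_f"]))
    a = ad.masked_max(F, ds.ch_mask[..., None], axes=(3,), neutral=0.0)

    x = ad.tanh(ad.add(ad.matmul(ad.concat([t, a], axis=-1),
                                 params["W_x"]), params["b_x"]))

    if train and rng is not None:
        if noise_scale > 0.0:
            x = ad.add(x, rng.normal(0.0, noise_scale, size=x.data.shape))
            d = ad.add(d, rng.normal(0.0, noise_scale, size=d.data.shape))
        x = _dropout(x, dropout, rng)
        d = _dropout(d, dropout, rng)
    return x, d
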