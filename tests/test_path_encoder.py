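"""Closed-form checks of the encoder operations and batch/per-item equality."""

import numpy as np
import pytest

from docsubre.corpus_io import ParsedSentence, Token
from docsubre.errors import ConfigurationError
from docsubre.fixtures import GeneratorSpec, generate_documents, word_vectors_text
from docsubre.path_encoder import (ChildContext, EncoderConfig, EncoderParams,
                                   augment, build_dataset, child_attention,
                                   encode_batch, encode_dependency,
                                   encode_path, encode_token, finalize_token,
                                   load_word_vectors, token_representation)
from docsubre.experiment import build_instances


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def test_default_config_matches_published_dimensions():
    cfg = EncoderConfig()
    assert cfg.child_context_dim == 832
    assert cfg.token_input_dim == 300 + 50 + 100 + 45
    with pytest.raises(ConfigurationError):
        EncoderConfig(beta=0.01)
    with pytest.raises(ConfigurationError):
        EncoderConfig(dim_token=0)


def test_load_word_vectors_header_and_oov():
    table = load_word_vectors("2 3\nAlpha 1 2 3\nbeta 0 0 1\n")
    assert table.dim == 3
    assert np.allclose(table.matrix[table.lookup("ALPHA")], [1, 2, 3])
    assert table.lookup("gamma") == table.oov
    assert np.allclose(table.matrix[table.oov], 0.0)
    no_header = load_word_vectors("alpha 1 2\nbeta 3 4\n")
    assert no_header.dim == 2
    with pytest.raises(ConfigurationError):
        load_word_vectors("a 1 2\nb 1 2 3\n")


def test_encode_dependency_zero_weight_and_direction(small_params):
    p = small_params
    W, b = p["W_d"], p["b_d"]
    old = W.data.copy()
    W.data[...] = 0.0
    b.data[...] = np.linspace(-1, 1, b.data.size)
    for lab in ("nsubj", "TITLE", "never-seen-label"):
        assert np.allclose(encode_dependency(lab, "with", p), np.tanh(b.data))
    W.data[...] = old
    with_arc = encode_dependency("nsubj", "with", p)
    against = encode_dependency("nsubj", "against", p)
    assert not np.allclose(with_arc, against)
    assert np.all(np.abs(with_arc) < 1.0)


def test_encode_dependency_toy_closed_form(word_table):
    cfg = EncoderConfig(dim_word=24, dim_pos=2, dim_typ=2, dim_dir=2,
                        use_char=False, use_aux=False, dim_token=2,
                        dim_dep_unit=2, dim_distance=2, n_kernels=2, dim_x=2)
    p = EncoderParams.create(cfg, word_table, np.random.default_rng(3))
    typ = p["typ"].data[0]
    p.tensors["typ"].data[0] = [0.5, -0.5]
    p["dir"].data[0] = [0.25, 1.0]
    p["W_d"].data[...] = np.array([[1.0, 0], [0, 1], [1, 1], [0, 0]])
    p["b_d"].data[...] = [0.1, -0.2]
    from docsubre.corpus_io import DEP_LABELS
    lab = DEP_LABELS[0]
    expect = np.tanh(np.array([0.5 + 0.25, -0.5 + 0.25]) + np.array([0.1, -0.2]))
    assert np.allclose(encode_dependency(lab, "with", p), expect, atol=1e-6)


def test_encode_token_zero_weight_and_determinism(small_params):
    p = small_params
    old = p["W_t"].data.copy()
    p["W_t"].data[...] = 0.0
    assert np.allclose(encode_token("chemox1", "NN", p), np.tanh(p["b_t"].data))
    p["W_t"].data[...] = old
    a = encode_token("chemox1", "NN", p)
    b = encode_token("chemox1", "NN", p)
    assert np.array_equal(a, b)
    assert np.all(np.abs(a) < 1.0)


def test_child_attention_gates_and_distance_heuristic(small_params):
    t = np.zeros(small_params.cfg.dim_token)
    children = [ChildContext("mild", "JJ", "amod", d) for d in (1, 2, 5, -5, 9)]
    out = child_attention(children, t, small_params)
    # beta = -0.03: alpha_h(5) = sigmoid(-0.75)
    assert out[2]["alpha_h"] == pytest.approx(_sigmoid(-0.75), abs=1e-6)
    assert out[2]["alpha_h"] == pytest.approx(0.32082, abs=1e-4)
    assert out[2]["alpha_h"] == out[3]["alpha_h"]  # symmetric in |d|
    hs = [o["alpha_h"] for o in (out[0], out[1], out[2], out[4])]
    assert all(a > b for a, b in zip(hs, hs[1:]))  # strictly decreasing in |d|
    for o in out:
        assert 0.0 < o["alpha_s"] < 1.0 and 0.0 < o["alpha_h"] < 1.0
        assert np.allclose(o["gated"], o["alpha_h"] * o["alpha_s"] * o["context"])
    with pytest.raises(ConfigurationError):
        ChildContext("x", "NN", "dep", 0)


def test_augment_zero_weight_single_child_and_max_oracle(small_params):
    p = small_params
    K = p.cfg.n_kernels
    assert np.allclose(augment([], p), np.zeros(K))  # leaf -> zero vector
    t = np.zeros(p.cfg.dim_token)
    children = [ChildContext(s, "NN", "dobj", d)
                for s, d in (("mild", 1), ("severe", -2), ("marked", 3))]
    att = child_attention(children, t, p)
    old = p["W_f"].data.copy()
    p["W_f"].data[...] = 0.0
    p["b_f"].data[...] = np.linspace(-0.5, 0.5, K)
    assert np.allclose(augment(att, p), np.maximum(p["b_f"].data, 0.0))
    p["W_f"].data[...] = old
    single = augment(att[:1], p)
    assert np.allclose(single, np.maximum(
        att[0]["gated"] @ p["W_f"].data + p["b_f"].data, 0.0))
    # exhaustive per-component max over the three children
    feats = np.stack([np.maximum(a["gated"] @ p["W_f"].data + p["b_f"].data, 0.0)
                      for a in att])
    got = augment(att, p)
    assert np.allclose(got, feats.max(axis=0))
    assert np.all(got >= 0.0)


def test_finalize_token_zero_weight(small_params):
    p = small_params
    old = p["W_x"].data.copy()
    p["W_x"].data[...] = 0.0
    t = np.zeros(p.cfg.dim_token)
    a = np.zeros(p.cfg.n_kernels)
    assert np.allclose(finalize_token(t, a, p), np.tanh(p["b_x"].data))
    p["W_x"].data[...] = old


def test_encode_path_structure_and_path_independence(corpus, small_params):
    docs, parses_by_doc, _ = corpus
    instances = [i for i in build_instances(docs[:6], parses_by_doc, 2) if i.paths]
    inst = instances[0]
    parses = parses_by_doc[inst.doc_id]
    path = inst.paths[0]
    enc = encode_path(path, parses, small_params)
    assert len(enc.vectors) == 2 * len(path.nodes) - 1
    assert enc.vectors[0].size == small_params.cfg.dim_x
    assert enc.vectors[1].size == small_params.cfg.dim_dep_unit
    # a token's x vector does not depend on which path it sits in
    s, t = path.nodes[0]
    assert np.allclose(enc.vectors[0],
                       token_representation(parses, s, t, small_params))


def test_batch_encoder_matches_per_item_composition():
    """The vectorized training encoder and the transparent per-item pipeline
    compute the same function (character biLSTM and auxiliary vector on)."""
    spec = GeneratorSpec(n_docs=6, seed=9)
    docs, parses_by_doc, _ = generate_documents(spec)
    words = load_word_vectors(word_vectors_text(spec, 8))
    cfg = EncoderConfig(dim_word=8, dim_pos=4, dim_typ=6, dim_dir=4,
                        dim_char=5, char_hidden=4, use_char=True,
                        dim_aux=7, use_aux=True, dim_token=6,
                        dim_dep_unit=5, dim_distance=3, n_kernels=4,
                        dim_x=6, max_word_len=8)
    params = EncoderParams.create(cfg, words, np.random.default_rng(11))
    instances = [i for i in build_instances(docs, parses_by_doc, 2) if i.paths][:5]
    ds = build_dataset(instances, parses_by_doc, params, k=3)
    x, d = encode_batch(ds, params)
    for b, inst in enumerate(instances):
        parses = parses_by_doc[inst.doc_id]
        for pi, path in enumerate(inst.paths[:3]):
            enc = encode_path(path, parses, params)
            for ti in range(len(path.nodes)):
                assert np.allclose(x.data[b, pi, ti], enc.vectors[2 * ti], atol=1e-9)
            for ei in range(len(path.edges)):
                assert np.allclose(d.data[b, pi, ei], enc.vectors[2 * ei + 1], atol=1e-9)


def test_dataset_masks_and_zero_path_instances(corpus, small_params):
    docs, parses_by_doc, _ = corpus
    instances = build_instances(docs[:8], parses_by_doc, 2)
    ds = build_dataset(instances, parses_by_doc, small_params, k=3)
    assert ds.tok_mask.shape == ds.tok_word.shape
    # token count along each real path equals mask sum; edges = tokens - 1
    usable = [i for i in instances if i.paths]
    for b, inst in enumerate(usable):
        for pi, path in enumerate(inst.paths[:3]):
            assert ds.tok_mask[b, pi].sum() == len(path.nodes)
        assert ds.path_mask[b].sum() == min(len(inst.paths), 3)
    assert set(ds.zero_path_keys) == {i.key for i in instances if not i.paths}
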