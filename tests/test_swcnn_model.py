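"""Shared-weight convolution/pooling, classification, loss and training."""

from types import SimpleNamespace

import numpy as np
import pytest

from docsubre import autodiff as ad
from docsubre.errors import DocsubreError
from docsubre.experiment import build_instances
from docsubre.path_encoder import EncoderConfig, EncoderParams, build_dataset
from docsubre.path_miner import CID, NONE
from docsubre.swcnn_model import (ModelState, SwCNNConfig, batch_loss,
                                  classify, convolve_pool, count_parameters,
                                  example_loss, forward_logits, predict,
                                  predict_dataset, train)


def _toy_pool_inputs(rng, B=3, K=2, L=5, X=4, D=3):
    x = ad.constant(rng.normal(size=(B, K, L, X)))
    d = ad.constant(rng.normal(size=(B, K, L - 1, D)))
    lengths = rng.integers(2, L + 1, size=(B, K))
    tok_mask = np.zeros((B, K, L))
    for b in range(B):
        for k in range(K):
            tok_mask[b, k, :lengths[b, k]] = 1.0
    path_mask = np.ones((B, K))
    ds = SimpleNamespace(tok_word=np.zeros((B, K, L)), tok_mask=tok_mask,
                         path_mask=path_mask)
    return x, d, ds


def _state_for_pool(rng, X=4, D=3, n_filters=3):
    cfg = SwCNNConfig(n_filters=n_filters, dropout=0.0, noise_scale=0.0)
    state = ModelState.__new__(ModelState)
    state.cfg = cfg
    state.tensors = {}
    for r in cfg.region_sizes:
        fan = r * X + (r - 1) * D
        state.tensors[f"W_c{r}"] = ad.parameter(rng.normal(size=(fan, n_filters)))
        state.tensors[f"b_c{r}"] = ad.parameter(rng.normal(size=n_filters))
    return state


def _pool_oracle(x, d, ds, state):
    """Materialize every window of every path and take the per-filter max."""
    B, K, L, X = x.data.shape
    D = d.data.shape[-1]
    cfg = state.cfg
    out = np.zeros((B, len(cfg.region_sizes) * cfg.n_filters))
    for b in range(B):
        feats = []
        for r in cfg.region_sizes:
            W = state.tensors[f"W_c{r}"].data
            bias = state.tensors[f"b_c{r}"].data
            best = np.full(cfg.n_filters, -np.inf)
            for k in range(K):
                if not ds.path_mask[b, k]:
                    continue
                n = int(ds.tok_mask[b, k].sum())
                for j in range(n - r + 1):
                    win = []
                    for t in range(r):
                        win.append(x.data[b, k, j + t])
                        if t < r - 1:
                            win.append(d.data[b, k, j + t])
                    best = np.maximum(best, np.concatenate(win) @ W + bias)
            feats.append(np.where(np.isfinite(best), best, 0.0))
        out[b] = np.concatenate(feats)
    return out


def test_convolve_pool_matches_window_enumeration_oracle():
    rng = np.random.default_rng(21)
    for _ in range(30):
        x, d, ds = _toy_pool_inputs(rng)
        state = _state_for_pool(rng)
        got = convolve_pool(x, d, ds, state).data
        assert np.allclose(got, _pool_oracle(x, d, ds, state), atol=1e-10)


def test_convolve_pool_constant_filter_yields_its_bias():
    rng = np.random.default_rng(22)
    x, d, ds = _toy_pool_inputs(rng, B=1, K=1)
    state = _state_for_pool(rng, n_filters=1)
    for r in (1, 2, 3):
        state.tensors[f"W_c{r}"].data[...] = 0.0
        state.tensors[f"b_c{r}"].data[...] = -0.7  # negative: no ReLU in pooling
    f = convolve_pool(x, d, ds, state).data
    assert np.allclose(f, -0.7)


def test_convolve_pool_invariant_to_padding_and_path_order():
    rng = np.random.default_rng(23)
    x, d, ds = _toy_pool_inputs(rng, B=2, K=2)
    state = _state_for_pool(rng)
    base = convolve_pool(x, d, ds, state).data

    # append an all-padding third path
    pad = lambda a: np.concatenate([a, np.zeros_like(a[:, :1])], axis=1)
    x3 = ad.constant(np.concatenate([x.data, rng.normal(size=x.data[:, :1].shape)], axis=1))
    d3 = ad.constant(np.concatenate([d.data, rng.normal(size=d.data[:, :1].shape)], axis=1))
    ds3 = SimpleNamespace(tok_word=pad(ds.tok_word), tok_mask=pad(ds.tok_mask),
                          path_mask=np.concatenate(
                              [ds.path_mask, np.zeros((2, 1))], axis=1))
    assert np.allclose(convolve_pool(x3, d3, ds3, state).data, base)

    # swap the two paths
    perm = [1, 0]
    xs = ad.constant(x.data[:, perm])
    dsw = ad.constant(d.data[:, perm])
    ds_sw = SimpleNamespace(tok_word=ds.tok_word[:, perm],
                            tok_mask=ds.tok_mask[:, perm],
                            path_mask=ds.path_mask[:, perm])
    assert np.allclose(convolve_pool(xs, dsw, ds_sw, state).data, base)


def test_paths_shorter_than_region_size_contribute_nothing():
    rng = np.random.default_rng(24)
    x, d, ds = _toy_pool_inputs(rng, B=1, K=2, L=5)
    ds.tok_mask[0, 0, :] = 0
    ds.tok_mask[0, 0, :2] = 1.0  # 2-token path: no region-3 window
    state = _state_for_pool(rng)
    got = convolve_pool(x, d, ds, state).data
    assert np.allclose(got, _pool_oracle(x, d, ds, state))


def _tiny_state(word_table, rng_seed=0, n_filters=4):
    rng = np.random.default_rng(rng_seed)
    params = EncoderParams.create(EncoderConfig.small(), word_table, rng)
    cfg = SwCNNConfig(n_filters=n_filters, dropout=0.0, noise_scale=0.0)
    return ModelState.create(params, cfg, rng)


def test_classify_closed_forms(word_table):
    state = _tiny_state(word_table)
    state.tensors["W_y"].data[...] = 0.0
    state.tensors["b_y"].data[...] = 0.0
    f = np.ones(state.cfg.feature_dim)
    assert np.allclose(classify(f, state), [0.5, 0.5], atol=1e-9)
    state.tensors["b_y"].data[...] = [3.3, 3.3]  # softmax shift invariance
    assert np.allclose(classify(f, state), [0.5, 0.5], atol=1e-9)
    state.tensors["b_y"].data[...] = [1.0, 0.0]
    e = np.e
    assert np.allclose(classify(f, state), [e / (e + 1), 1 / (e + 1)], atol=1e-6)
    assert classify(f, state).sum() == pytest.approx(1.0, abs=1e-6)


def test_example_loss_weighting_and_regularization():
    cfg = SwCNNConfig()
    assert example_loss(np.array([1.0, 0.0]), CID, 0.0, cfg) == pytest.approx(0.0, abs=1e-9)
    cfg0 = SwCNNConfig(lambda_l2=0.0)
    assert example_loss(np.array([0.5, 0.5]), CID, 123.0, cfg0) == \
        pytest.approx(3.0 * np.log(2.0))
    assert example_loss(np.array([0.5, 0.5]), NONE, 0.0, cfg0) == \
        pytest.approx(np.log(2.0))
    cfg1 = SwCNNConfig(lambda_l2=0.25)
    assert example_loss(np.array([0.0, 1.0]), NONE, 8.0, cfg1) == pytest.approx(2.0)
    # numeric floor guards log(0)
    assert np.isfinite(example_loss(np.array([0.0, 1.0]), CID, 0.0, cfg0))


def test_count_parameters_published_components():
    counts = count_parameters(EncoderConfig(), SwCNNConfig())
    assert counts["dependency_type_lut"] == 10800
    assert counts["dependency_direction_lut"] == 300
    assert counts["character_lut"] == 4250
    assert counts["character_bilstm"] == 40400
    assert counts["pos_lut"] == 2850
    assert counts["distance_base"] == 32
    assert counts["attention_scorer"] == 833
    assert counts["kernel_filters"] == 83300
    assert counts["total"] == sum(v for k, v in counts.items() if k != "total")


def test_count_parameters_matches_allocated_model(word_table):
    # small configuration: the accounting and the actual arrays must agree
    enc_cfg = EncoderConfig.small()
    cfg = SwCNNConfig.small()
    rng = np.random.default_rng(1)
    wt = word_table
    params = EncoderParams.create(enc_cfg, wt, rng)
    state = ModelState.create(params, cfg, rng)
    assert state.parameter_count() == count_parameters(enc_cfg, cfg)["total"]


def _training_setup(corpus, word_table, n_docs=25):
    docs, parses_by_doc, _ = corpus
    docs = docs[:n_docs]
    tr = build_instances(docs[:18], parses_by_doc, 2)
    dv = build_instances(docs[18:22], parses_by_doc, 2)
    te = build_instances(docs[22:], parses_by_doc, 2)
    return docs, parses_by_doc, tr, dv, te


def test_training_descends_and_is_deterministic(corpus, word_table):
    docs, parses, tr, dv, te = _training_setup(corpus, word_table)
    cfg = SwCNNConfig(n_filters=8, max_epochs=6, patience=10)
    state1, hist1 = train(tr, dv, parses, word_table, EncoderConfig.small(), cfg, seed=3)
    assert hist1[1]["loss"] < hist1[0]["loss"]
    pred1 = predict(state1, te, parses)
    state2, hist2 = train(tr, dv, parses, word_table, EncoderConfig.small(), cfg, seed=3)
    assert hist1 == hist2
    assert predict(state2, te, parses) == pred1
    with pytest.raises(DocsubreError, match="empty"):
        train([], dv, parses, word_table, EncoderConfig.small(), cfg, seed=0)


def test_batch_and_single_instance_predictions_agree(corpus, word_table):
    docs, parses, tr, dv, te = _training_setup(corpus, word_table)
    cfg = SwCNNConfig(n_filters=8, max_epochs=2, patience=10)
    state, _ = train(tr, dv, parses, word_table, EncoderConfig.small(), cfg, seed=5)
    batch = predict(state, te, parses)
    singles = {}
    for inst in te:
        singles.update(predict(state, [inst], parses))
    assert singles == batch
    # zero-path instances are predicted NONE
    from docsubre.path_miner import CandidateInstance
    empty = CandidateInstance("90000000", "MESH:C999", "MESH:D999")
    assert predict(state, [empty], parses)["90000000", "MESH:C999", "MESH:D999"] == NONE


def test_raising_cid_logit_never_flips_cid_to_none(corpus, word_table):
    docs, parses, tr, dv, te = _training_setup(corpus, word_table)
    cfg = SwCNNConfig(n_filters=8, max_epochs=2, patience=10)
    state, _ = train(tr, dv, parses, word_table, EncoderConfig.small(), cfg, seed=7)
    before = predict(state, te, parses)
    state.tensors["b_y"].data[0] += 5.0  # push the CID logit up everywhere
    after = predict(state, te, parses)
    for key, lab in before.items():
        if lab == CID:
            assert after[key] == CID


def test_model_save_load_round_trip(tmp_path, corpus, word_table):
    docs, parses, tr, dv, te = _training_setup(corpus, word_table)
    cfg = SwCNNConfig(n_filters=8, max_epochs=2, patience=10)
    state, _ = train(tr, dv, parses, word_table, EncoderConfig.small(), cfg, seed=9)
    state.save(tmp_path / "model")
    loaded = ModelState.load(tmp_path / "model")
    assert predict(loaded, te, parses) == predict(state, te, parses)
    assert loaded.cfg == state.cfg and loaded.encoder.cfg == state.encoder.cfg


def test_gradient_check_on_tiny_dimensions(corpus, word_table):
    """Backpropagated gradients match finite differences to 1e-4."""
    docs, parses_by_doc, _ = corpus
    rng = np.random.default_rng(0)
    params = EncoderParams.create(EncoderConfig.small(), word_table, rng)
    cfg = SwCNNConfig(n_filters=3, dropout=0.0, noise_scale=0.0)
    state = ModelState.create(params, cfg, rng)
    insts = [i for i in build_instances(docs[:4], parses_by_doc, 2) if i.paths][:6]
    ds = build_dataset(insts, parses_by_doc, params, cfg.k)
    loss = batch_loss(ds, state)
    for p in state.trainable():
        p.grad = None
    loss.backward()
    crng = np.random.default_rng(1)
    for p in state.trainable():
        flat = p.data.reshape(-1)
        g = p.grad.reshape(-1) if p.grad is not None else np.zeros_like(flat)
        for idx in crng.choice(flat.size, size=min(2, flat.size), replace=False):
            eps = 1e-6
            old = flat[idx]
            flat[idx] = old + eps
            lp = float(batch_loss(ds, state).data)
            flat[idx] = old - eps
            lm = float(batch_loss(ds, state).data)
            flat[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - g[idx]) <= 1e-4 * max(1.0, abs(fd))
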