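"""Shared-weight CNN over multi-path instances.

One instance is a set of up to k encoded paths for a (chemical, disease)
concept pair.  A single bank of convolution filters (N filters per region
size r in {1,2,3}) slides over every path of the instance, advancing one
dependency unit at a time; a window of size r concatenates r token vectors
and the r-1 dependency vectors between them.  Filter-wise max pooling then
reduces each filter's responses across ALL paths and ALL positions to a
single feature, so the feature vector f has sum_r N components regardless
of how many paths the instance holds; padding paths and positions are
masked and can never win the max.  A softmax layer on f predicts
{CID, NONE}; training minimizes class-weighted cross-entropy (3:1 for
positive:negative) with an L2 penalty, using Adam, Glorot initialization,
dropout, small Gaussian input noise, a max-norm constraint and early
stopping on development F1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .errors import ConfigurationError, DocsubreError
from .path_encoder import (EncoderConfig, EncoderParams, PathDataset,
                           WordTable, build_dataset, encode_batch)

CID = "CID"
NONE = "NONE"
_CLASS_INDEX = {CID: 0, NONE: 1}


@dataclass(frozen=True)
class SwCNNConfig:
    k: int = 3                       # paths per instance
    n_filters: int = 128             # filters per region size
    region_sizes: tuple[int, ...] = (1, 2, 3)
    n_classes: int = 2
    class_weights: tuple[float, float] = (3.0, 1.0)  # (CID, NONE)
    lambda_l2: float = 1e-4
    dropout: float = 0.5
    noise_scale: float = 0.001
    batch_size: int = 128
    lr: float = 1e-3
    max_norm: float = 3.0
    patience: int = 5
    max_epochs: int = 50

    def __post_init__(self):
        if self.k < 1 or any(r < 1 for r in self.region_sizes):
            raise ConfigurationError("k and region sizes must be >= 1")
        if any(w <= 0 for w in self.class_weights):
            raise ConfigurationError("class weights must be positive")

    @property
    def feature_dim(self) -> int:
        return self.n_filters * len(self.region_sizes)

    @classmethod
    def small(cls) -> "SwCNNConfig":
        return cls(n_filters=16)


@dataclass
class ModelState:
    """Parameter tuple theta = (W, b): encoder + convolution + classifier."""
    encoder: EncoderParams
    cfg: SwCNNConfig
    tensors: dict[str, ad.Tensor] = field(default_factory=dict)
    epoch: int = 0
    best_dev_f1: float = 0.0

    @classmethod
    def create(cls, encoder: EncoderParams, cfg: SwCNNConfig,
               rng: np.random.Generator) -> "ModelState":
        X, D = encoder.cfg.dim_x, encoder.cfg.dim_dep_unit
        t: dict[str, ad.Tensor] = {}
        for r in cfg.region_sizes:
            fan_in = r * X + (r - 1) * D
            t[f"W_c{r}"] = ad.parameter(
                ad.glorot_uniform(rng, fan_in, cfg.n_filters), f"W_c{r}")
            t[f"b_c{r}"] = ad.parameter(np.zeros(cfg.n_filters), f"b_c{r}")
        t["W_y"] = ad.parameter(
            ad.glorot_uniform(rng, cfg.feature_dim, cfg.n_classes), "W_y")
        t["b_y"] = ad.parameter(np.zeros(cfg.n_classes), "b_y")
        return cls(encoder, cfg, t)

    def trainable(self) -> list[ad.Tensor]:
        return self.encoder.trainable() + list(self.tensors.values())

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.trainable())

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.trainable()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self.trainable(), snap):
            p.data[...] = d

    # -- serialization: a manifest plus one portable array container --------
    def save(self, directory) -> None:
        import os
        os.makedirs(directory, exist_ok=True)
        manifest = {"encoder_cfg": asdict(self.encoder.cfg),
                    "model_cfg": asdict(self.cfg),
                    "epoch": self.epoch, "best_dev_f1": self.best_dev_f1,
                    "vocab": sorted(self.encoder.words.index,
                                    key=self.encoder.words.index.get)}
        with open(f"{directory}/manifest.json", "w") as fh:
            json.dump(manifest, fh)
        arrays = {f"enc__{k}": v.data for k, v in self.encoder.tensors.items()}
        arrays.update({f"mod__{k}": v.data for k, v in self.tensors.items()})
        arrays["word_matrix"] = self.encoder.words.matrix
        np.savez(f"{directory}/weights.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "ModelState":
        with open(f"{directory}/manifest.json") as fh:
            manifest = json.load(fh)
        enc_cfg = EncoderConfig(**manifest["encoder_cfg"])
        mcfg = manifest["model_cfg"]
        mcfg["region_sizes"] = tuple(mcfg["region_sizes"])
        mcfg["class_weights"] = tuple(mcfg["class_weights"])
        cfg = SwCNNConfig(**mcfg)
        arrays = np.load(f"{directory}/weights.npz")
        words = WordTable.__new__(WordTable)
        words.matrix = arrays["word_matrix"]
        words.dim = words.matrix.shape[1]
        words.index = {w: i for i, w in enumerate(manifest["vocab"])}
        words.oov = words.matrix.shape[0] - 1
        enc = EncoderParams(enc_cfg, words,
                            {k[5:]: ad.parameter(arrays[k], k[5:])
                             for k in arrays.files if k.startswith("enc__")})
        state = cls(enc, cfg,
                    {k[5:]: ad.parameter(arrays[k], k[5:])
                     for k in arrays.files if k.startswith("mod__")})
        state.epoch = manifest["epoch"]
        state.best_dev_f1 = manifest["best_dev_f1"]
        return state


# ---------------------------------------------------------------------------
# Forward pieces
# ---------------------------------------------------------------------------

def convolve_pool(x: ad.Tensor, d: ad.Tensor, ds: PathDataset,
                  state: ModelState) -> ad.Tensor:
    """f_p = max over paths i and window positions j of [x_{i,j:j+r} W_c + b_c]_p,
    concatenated over region sizes.  Windows advance token-to-token; a path
    shorter than r simply contributes no window for that region size, and a
    region size with no valid window anywhere yields zeros."""
    cfg = state.cfg
    B, K, L = ds.tok_word.shape
    feats = []
    for r in cfg.region_sizes:
        P = L - r + 1
        if P < 1:
            feats.append(ad.constant(np.zeros((B, cfg.n_filters))))
            continue
        parts = []
        for t in range(r):
            parts.append(ad.slice_axis(x, 2, t, t + P))
            if t < r - 1:
                parts.append(ad.slice_axis(d, 2, t, t + P))
        win = ad.concat(parts, axis=-1)  # [B,K,P,rX+(r-1)D]
        z = ad.add(ad.matmul(win, state.tensors[f"W_c{r}"]),
                   state.tensors[f"b_c{r}"])
        mask = (ds.tok_mask[:, :, r - 1:] * ds.path_mask[:, :, None])[..., None]
        feats.append(ad.masked_max(z, mask, axes=(1, 2), neutral=0.0))
    return ad.concat(feats, axis=-1)  # [B, sum_r N]


def forward_logits(ds: PathDataset, state: ModelState, *, train: bool = False,
                   rng: np.random.Generator | None = None) -> ad.Tensor:
    cfg = state.cfg
    x, d = encode_batch(ds, state.encoder, train=train, rng=rng,
                        noise_scale=cfg.noise_scale if train else 0.0,
                        dropout=cfg.dropout if train else 0.0)
    f = convolve_pool(x, d, ds, state)
    if train and rng is not None and cfg.dropout > 0:
        keep = (rng.random(f.data.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
        f = ad.mul(f, keep)
    return ad.add(ad.matmul(f, state.tensors["W_y"]), state.tensors["b_y"])


def classify(f: np.ndarray, state: ModelState) -> np.ndarray:
    """softmax(f W_y + b_y) for a single pooled feature vector."""
    logits = f @ state.tensors["W_y"].data + state.tensors["b_y"].data
    return ad.softmax(logits)


def example_loss(y_hat: np.ndarray, gold: str, theta_sumsq: float,
                 cfg: SwCNNConfig, floor: float = 1e-12) -> float:
    """Class-weighted cross-entropy of one prediction plus lambda * ||theta||^2."""
    idx = _CLASS_INDEX[gold]
    w = cfg.class_weights[idx]
    return float(w * -np.log(max(y_hat[idx], floor)) + cfg.lambda_l2 * theta_sumsq)


def batch_loss(ds: PathDataset, state: ModelState, *, train: bool = False,
               rng: np.random.Generator | None = None) -> ad.Tensor:
    logits = forward_logits(ds, state, train=train, rng=rng)
    weights = np.asarray(state.cfg.class_weights)[ds.labels]
    ce = ad.weighted_softmax_cross_entropy(logits, ds.labels, weights)
    reg = ad.mul(ad.sum_squares(state.trainable()), state.cfg.lambda_l2)
    return ad.add(ce, reg)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def _instance_f1(pred: dict, gold_cid: set) -> float:
    tp = sum(1 for k, v in pred.items() if v == CID and k in gold_cid)
    fp = sum(1 for k, v in pred.items() if v == CID and k not in gold_cid)
    fn = len(gold_cid) - tp
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def predict_dataset(ds: PathDataset, state: ModelState,
                    chunk: int = 256) -> dict[tuple, str]:
    """Label every instance of a dataset; zero-path instances are NONE."""
    out: dict[tuple, str] = {k: NONE for k in ds.zero_path_keys}
    for lo in range(0, len(ds), chunk):
        sub = ds.subset(np.arange(lo, min(lo + chunk, len(ds))))
        logits = forward_logits(sub, state).data
        labels = np.argmax(logits, axis=1)
        for key, li in zip(sub.keys, labels):
            out[key] = CID if li == 0 else NONE
    return out


def train(train_instances, dev_instances, parses_by_doc,
          word_table: WordTable, enc_cfg: EncoderConfig, cfg: SwCNNConfig,
          seed: int) -> tuple[ModelState, list[dict]]:
    """Fit the model; returns the best-dev checkpoint and the epoch log.

    Deterministic given (instances, configs, seed).  Raises on an empty
    training set and aborts with a diagnostic if the loss diverges.
    """
    usable = [i for i in train_instances if i.paths]
    if not usable:
        raise DocsubreError("empty training set")
    rng = np.random.default_rng(seed)
    params = EncoderParams.create(enc_cfg, word_table, rng)
    state = ModelState.create(params, cfg, rng)
    train_ds = build_dataset(usable, parses_by_doc, params, cfg.k)
    dev_ds = build_dataset(dev_instances, parses_by_doc, params, cfg.k)
    dev_gold = {i.key for i in dev_instances if i.label == CID}

    opt = ad.Adam(state.trainable(), lr=cfg.lr, max_norm=cfg.max_norm)
    history: list[dict] = []
    best_f1, best_snap, best_epoch, stall = -1.0, state.snapshot(), 0, 0
    n = len(train_ds)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, cfg.batch_size):
            sub = train_ds.subset(order[lo:lo + cfg.batch_size])
            loss = batch_loss(sub, state, train=True, rng=rng)
            if not np.isfinite(loss.data):
                raise DocsubreError(f"loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sub)
        dev_pred = predict_dataset(dev_ds, state)
        dev_f1 = _instance_f1(dev_pred, dev_gold)
        history.append({"epoch": epoch, "loss": total / n, "dev_f1": dev_f1})
        if dev_f1 > best_f1:
            best_f1, best_snap, best_epoch, stall = dev_f1, state.snapshot(), epoch, 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    state.restore(best_snap)
    state.epoch = best_epoch
    state.best_dev_f1 = max(best_f1, 0.0)
    return state, history


def predict(state: ModelState, instances, parses_by_doc) -> dict[tuple, str]:
    """Label candidate instances; instances with zero paths are NONE."""
    ds = build_dataset(list(instances), parses_by_doc, state.encoder, state.cfg.k)
    return predict_dataset(ds, state)


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def count_parameters(enc_cfg: EncoderConfig,
                     cfg: SwCNNConfig) -> dict[str, int]:
    """Trainable parameter counts per named component.

    Fixed inputs (pre-trained word vectors, the auxiliary lexical vectors)
    carry no trainable parameters and are not counted.
    """
    from .corpus_io import CHAR_INVENTORY, DEP_LABELS, POS_TAGS
    from .doc_graph import VIRTUAL_LABELS
    c: dict[str, int] = {}
    c["dependency_type_lut"] = len(DEP_LABELS) * enc_cfg.dim_typ
    c["dependency_direction_lut"] = 2 * enc_cfg.dim_dir
    c["virtual_label_lut"] = len(VIRTUAL_LABELS) * enc_cfg.dim_typ
    c["pos_lut"] = len(POS_TAGS) * enc_cfg.dim_pos
    if enc_cfg.use_char:
        c["character_lut"] = len(CHAR_INVENTORY) * enc_cfg.dim_char
        h, i = enc_cfg.char_hidden, enc_cfg.dim_char
        c["character_bilstm"] = 2 * 4 * (h * (i + h) + h)
    c["distance_base"] = enc_cfg.dim_distance
    c["attention_scorer"] = enc_cfg.child_context_dim + 1
    c["kernel_filters"] = (enc_cfg.child_context_dim * enc_cfg.n_kernels
                           + enc_cfg.n_kernels)
    c["dependency_transform"] = ((enc_cfg.dim_typ + enc_cfg.dim_dir)
                                 * enc_cfg.dim_dep_unit + enc_cfg.dim_dep_unit)
    c["token_transform"] = (enc_cfg.token_input_dim * enc_cfg.dim_token
                            + enc_cfg.dim_token)
    c["token_final_transform"] = ((enc_cfg.dim_token + enc_cfg.n_kernels)
                                  * enc_cfg.dim_x + enc_cfg.dim_x)
    X, D = enc_cfg.dim_x, enc_cfg.dim_dep_unit
    c["swcnn_filters"] = sum((r * X + (r - 1) * D) * cfg.n_filters + cfg.n_filters
                             for r in cfg.region_sizes)
    c["softmax"] = cfg.feature_dim * cfg.n_classes + cfg.n_classes
    c["total"] = sum(v for k, v in c.items())
    return c
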