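"""Reduced U-Net for pixel regression / classification, training and triage.

The canonical 4-level U-Net (two 3x3 convolutions per level, feature
maps doubling from ``base_features``, 2x2 max pooling down and 2x2
up-convolutions with skip concatenation up) is reduced by shrinking
``base_features`` from 64 to 16, cutting trainable parameters about
15-fold while keeping the architecture intact.  Both output modes train
against an MSE loss with Adam at 1e-4: regression targets are
normalized fluorescence projections, classification targets their Otsu
masks.  Checkpointing keeps the best-validation weights and early
stopping halts on a validation-loss plateau.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import label as cc_label

from . import nn
from .prep import SamplePair, DatasetSplit, otsu_mask
from .qpi import PlaneStack

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PredictionImage",
    "TriageResult",
    "TrainingHistory",
    "UNet",
    "build_unet",
    "train_model",
    "predict",
    "prediction_mask",
    "triage_fov",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs for the virtual-staining U-Net."""

    in_planes: int = 8
    mode: str = "regression"
    base_features: int = 16
    depth: int = 4
    final_activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_planes not in (1, 2, 4, 8):
            raise ValueError("in_planes must be 1, 2, 4 or 8")
        if self.mode not in ("regression", "classification"):
            raise ValueError("mode must be 'regression' or 'classification'")
        if self.base_features < 1 or 64 % self.base_features:
            raise ValueError("base_features must divide 64")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.final_activation != "sigmoid":
            raise ValueError("only sigmoid output is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe: Adam at 1e-4 with MSE and early stopping."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    loss: str = "mse"
    batch_size: int = 4
    max_epochs: int = 30
    early_stop_patience: int = 5
    checkpoint: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer != "adam" or self.loss != "mse":
            raise ValueError("supported recipe is Adam + MSE")


@dataclass
class PredictionImage:
    """Network output in [0, 1] with provenance."""

    values: np.ndarray
    model_fingerprint: str = ""
    input_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("prediction must be 2-D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("prediction values must lie in [0, 1]")


@dataclass(frozen=True)
class TriageResult:
    """Consensus call for one scanned field of view."""

    fov_id: str
    per_model_votes: tuple[bool, ...]
    consensus: bool
    aggregate_count: int


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else float("nan")


class _DoubleConv:
    """Two 3x3 conv + ReLU stages, the U-Net level building block."""

    def __init__(self, in_ch, out_ch, rng):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.r2 = nn.ReLU()

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


class _UpBlock:
    """2x nearest upsampling followed by a 2x2 'up-convolution'."""

    def __init__(self, in_ch, out_ch, rng):
        self.up = nn.UpsampleNearest2()
        self.conv = nn.Conv2d(in_ch, out_ch, 2, rng)

    def parameters(self):
        return self.conv.parameters()

    def forward(self, x):
        return self.conv.forward(self.up.forward(x))

    def backward(self, dy):
        return self.up.backward(self.conv.backward(dy))


class UNet:
    """Encoder-decoder with skip connections; spatial shape is preserved."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b, d = config.base_features, config.depth
        self.enc = []
        ch = config.in_planes
        for i in range(d):
            out = b * 2 ** i
            self.enc.append(_DoubleConv(ch, out, rng))
            ch = out
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = _DoubleConv(ch, b * 2 ** d, rng)
        self.ups, self.dec = [], []
        ch = b * 2 ** d
        for i in reversed(range(d)):
            out = b * 2 ** i
            self.ups.append(_UpBlock(ch, out, rng))
            self.dec.append(_DoubleConv(2 * out, out, rng))
            ch = out
        self.final = nn.Conv2d(b, 1, 1, rng, init_scale=np.sqrt(1.0 / b))
        self.out_act = nn.Sigmoid()

    def parameters(self):
        ps = []
        for blk in self.enc:
            ps += blk.parameters()
        ps += self.bottleneck.parameters()
        for up, dec in zip(self.ups, self.dec):
            ps += up.parameters() + dec.parameters()
        ps += self.final.parameters()
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        h, w = x.shape[-2:]
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^depth={div}; pad the input")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x)
        return self.out_act.forward(self.final.forward(x))

    def backward(self, dy: np.ndarray) -> None:
        dy = self.final.backward(self.out_act.backward(dy))
        dskips = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            dx = dec.backward(dy)
            sk_ch = dx.shape[1] // 2
            dskips.append(dx[:, :sk_ch])
            dy = up.backward(dx[:, sk_ch:])
        dy = self.bottleneck.backward(dy)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            dy = blk.backward(dy + dskip)

    # -- weight (de)serialization ------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value = np.ascontiguousarray(w, dtype=nn.DTYPE)

    def fingerprint(self) -> str:
        h = hashlib.sha256(json.dumps(asdict(self.config), sort_keys=True).encode())
        for p in self.parameters():
            h.update(p.value.tobytes())
        return h.hexdigest()[:16]


def build_unet(config: ModelConfig):
    """Instantiate the U-Net and report its exact trainable-parameter count."""
    net = UNet(config)
    return net, net.n_parameters


def _pairs_to_arrays(pairs: list[SamplePair], mode: str):
    xs, ys = [], []
    for p in pairs:
        xs.append(p.input_stack.planes.astype(nn.DTYPE))
        target = p.label_mask.astype(nn.DTYPE) if mode == "classification" \
            else p.label_image.astype(nn.DTYPE)
        ys.append(target[None])
    return np.stack(xs), np.stack(ys)


def train_model(
    pairs: list[SamplePair],
    split: DatasetSplit,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
):
    """Train the U-Net on the split's train set, validating per epoch.

    Returns ``(model, history)`` where the model carries the
    best-validation weights (checkpoint contract) and the history the
    per-epoch train/validation losses.  Fully deterministic given the
    config seeds.
    """
    by_id = {p.acquisition_id: p for p in pairs}
    train_pairs = [by_id[i] for i in split.train_ids if i in by_id]
    val_pairs = [by_id[i] for i in split.val_ids if i in by_id]
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must both be non-empty")

    x_train, y_train = _pairs_to_arrays(train_pairs, mcfg.mode)
    x_val, y_val = _pairs_to_arrays(val_pairs, mcfg.mode)
    if x_train.shape[1] != mcfg.in_planes:
        raise ValueError(
            f"pairs have {x_train.shape[1]} input planes, model expects {mcfg.in_planes}")

    model = UNet(mcfg)
    # start the sigmoid output at the label mean: with sparse bright
    # targets an unbiased start collapses to a constant prediction
    # before any structure is learned
    m = float(np.clip(y_train.mean(), 1e-3, 1 - 1e-3))
    model.final.bias.value[:] = np.log(m / (1.0 - m))
    opt = nn.Adam(model.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            opt.zero_grad()
            pred = model.forward(x_train[idx])
            loss, grad = nn.mse_loss(pred, y_train[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / len(order))

        val_loss = evaluate_loss(model, x_val, y_val, tcfg.batch_size)
        history.val_loss.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            since_best = 0
            if tcfg.checkpoint:
                best_weights = model.get_weights()
        else:
            since_best += 1
            if since_best >= tcfg.early_stop_patience:
                history.stopped_early = True
                break

    if tcfg.checkpoint:
        model.set_weights(best_weights)
    return model, history


def evaluate_loss(model: UNet, x: np.ndarray, y: np.ndarray, batch_size: int = 8) -> float:
    total = 0.0
    for start in range(0, len(x), batch_size):
        pred = model.forward(x[start:start + batch_size])
        loss, _ = nn.mse_loss(pred, y[start:start + batch_size])
        total += loss * len(x[start:start + batch_size])
    return total / len(x)


def predict(model: UNet, input_stack: PlaneStack, input_id: str = "") -> PredictionImage:
    """Run inference on one normalized input stack."""
    if input_stack.n_planes != model.config.in_planes:
        raise ValueError(
            f"model expects {model.config.in_planes} input planes, "
            f"got {input_stack.n_planes}")
    out = model.forward(input_stack.planes[None])[0, 0]
    return PredictionImage(np.clip(np.asarray(out, dtype=float), 0.0, 1.0),
                           model_fingerprint=model.fingerprint(),
                           input_id=input_id)


def prediction_mask(pred: PredictionImage, method: str = "otsu",
                    level: float = 0.5) -> np.ndarray:
    """Binary mask from a prediction.

    ``otsu`` thresholds adaptively (regression outputs on
    aggregate-containing fields); ``fixed`` applies the classification
    0.5 cut, appropriate when the field may contain no aggregate at
    all.  A constant prediction yields an empty mask.
    """
    v = pred.values
    if method == "fixed":
        return v > level
    if method != "otsu":
        raise ValueError("method must be 'otsu' or 'fixed'")
    if v.min() == v.max():
        return np.zeros_like(v, dtype=bool)
    _, mask = otsu_mask(v)
    return mask


def triage_fov(
    predictions: list[PredictionImage],
    min_area_um2: float = 3.0,
    pixel_size_um: float = 0.111,
    fov_id: str = "",
) -> TriageResult:
    """Conservative multi-model consensus call on one field of view.

    Each model votes positive iff the Otsu mask of its prediction holds
    an 8-connected component of at least ``min_area_um2``; the FOV is
    flagged only if *every* model votes positive, trading false
    negatives for a minimal false-positive rate.  The aggregate count
    is taken on the intersection of the per-model masks.
    """
    if not predictions:
        raise ValueError("triage needs at least one prediction")
    min_px = min_area_um2 / pixel_size_um ** 2
    struct = np.ones((3, 3), dtype=int)

    votes = []
    masks = []
    for pred in predictions:
        mask = prediction_mask(pred, method="otsu")
        masks.append(mask)
        labels, n = cc_label(mask, structure=struct)
        if n == 0:
            votes.append(False)
            continue
        sizes = np.bincount(labels.ravel())[1:]
        votes.append(bool((sizes >= min_px).any()))

    consensus = all(votes)
    count = 0
    if consensus:
        inter = np.logical_and.reduce(masks)
        labels, n = cc_label(inter, structure=struct)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            count = int((sizes >= min_px).sum())
    return TriageResult(fov_id, tuple(votes), consensus, count)


def save_model(model: UNet, path) -> None:
    """Serialize weights (npz) plus a JSON-embedded config fingerprint."""
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    meta = json.dumps({"config": asdict(model.config),
                       "fingerprint": model.fingerprint()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    model = UNet(ModelConfig(**meta["config"]))
    model.set_weights(weights)
    if model.fingerprint() != meta["fingerprint"]:
        warnings.warn("fingerprint mismatch after loading weights", stacklevel=2)
    return model
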