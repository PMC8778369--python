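"""Motion classification: the 5-layer CNN and freeze-and-retrain transfer.

The classifier is a five-block convolutional network over grayscale ERDS
feature images (46 x W x 1): each block is a same-padded 3x3 convolution,
ReLU, and max pooling along the time axis only; a dropout layer and a
fully connected softmax head follow.  Training uses stochastic gradient
descent with momentum (SGDM), 10 epochs, shuffling every epoch, and
validation metrics every third iteration; validation data never update
the weights.

Transfer learning reuses a model pretrained on fused EEG+EMG images
(46 x 403): the first four convolutional blocks are frozen and the fifth
block plus the head are retrained at a small learning rate (3e-4) on
single-modality images padded into the fused layout.  A stricter mode
freezes all five blocks.

Two surfaces are provided: the functional operations
(:func:`build_network`, :func:`train`, :func:`grid_search_lr`,
:func:`transfer_learn`, :func:`predict`) and a model-object wrapper
(:class:`CNNClassifier` / :class:`CNNResults`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from neurofuse.images import ImageDataset
from neurofuse.nn import Network, cross_entropy, sgdm_update

__all__ = [
    "NetSpec",
    "TrainConfig",
    "ModelBundle",
    "build_network",
    "train",
    "grid_search_lr",
    "transfer_learn",
    "predict",
    "save_bundle",
    "load_bundle",
    "CNNClassifier",
    "CNNResults",
]


@dataclass(frozen=True)
class NetSpec:
    """Architecture of the five-block CNN.

    ``input_shape`` is (time, width, 1): 46 x 403 x 1 for fused or padded
    images, 46 x 279 / 46 x 124 for single-modality-native nets.  Pooling
    acts on the time axis only, so the frequency-column extent is
    preserved through the convolutional base.
    """

    input_shape: tuple[int, int, int]
    conv_filters: tuple[int, ...] = (8, 16, 32, 32, 64)
    kernel: tuple[int, int] = (3, 3)
    dropout_rate: float = 0.5
    n_classes: int = 3

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 5:
            raise ValueError("the architecture uses exactly 5 convolutional blocks")
        t = self.input_shape[0]
        if t < 1:
            raise ValueError(
                f"input time extent {t} cannot survive 5 pooling stages; "
                "a minimum extent of 1 is required")

    @staticmethod
    def for_width(width: int, **kw) -> "NetSpec":
        return NetSpec(input_shape=(46, width, 1), **kw)

    @staticmethod
    def small(width: int, **kw) -> "NetSpec":
        """A low-capacity preset (4/8/8/8/16 filters) for quick studies."""
        return NetSpec(input_shape=(46, width, 1),
                       conv_filters=(4, 8, 8, 8, 16), **kw)


@dataclass(frozen=True)
class TrainConfig:
    """SGDM optimization settings.

    ``validation_frequency`` counts optimizer iterations between
    validation-metric evaluations.  ``lr_grid`` is the log-scale search
    range used by :func:`grid_search_lr`.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 10
    batch_size: int = 16
    validation_frequency: int = 3
    shuffle: bool = True
    seed: int = 0
    lr_grid: tuple[float, ...] = (0.1, 0.01, 0.001)
    # global gradient-norm ceiling; guards SGDM's large early steps from
    # killing the ReLUs (loss otherwise parks at the uniform plateau)
    clip_grad_norm: float | None = 5.0

    def __post_init__(self) -> None:
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class ModelBundle:
    """A network's architecture, parameters, and training provenance.

    ``provenance`` is one of ``single_modal``, ``pretrained_multimodal``,
    ``transfer_learned`` (or ``untrained``); ``frozen`` flags layers whose
    parameters must stay bit-identical through further fitting.
    """

    spec: NetSpec
    parameters: list[dict[str, np.ndarray]]
    frozen: list[bool]
    history: dict[str, list]
    provenance: str = "untrained"
    source_id: str | None = None
    seed: int = 0

    def make_network(self) -> Network:
        net = Network(self.spec.input_shape, self.spec.conv_filters,
                      self.spec.kernel, self.spec.dropout_rate,
                      self.spec.n_classes, seed=self.seed)
        net.set_params(self.parameters)
        return net

    def copy(self) -> "ModelBundle":
        return ModelBundle(
            spec=self.spec,
            parameters=[{k: v.copy() for k, v in p.items()} for p in self.parameters],
            frozen=list(self.frozen),
            history={k: list(v) for k, v in self.history.items()},
            provenance=self.provenance,
            source_id=self.source_id,
            seed=self.seed,
        )


def build_network(spec: NetSpec, seed: int = 0) -> ModelBundle:
    """Seeded He initialization of the five-block network."""
    net = Network(spec.input_shape, spec.conv_filters, spec.kernel,
                  spec.dropout_rate, spec.n_classes, seed=seed)
    n_layers = len(net.layers())
    return ModelBundle(spec=spec, parameters=net.get_params(),
                       frozen=[False] * n_layers,
                       history={"iteration": [], "loss": [], "accuracy": [],
                                "val_iteration": [], "val_loss": [],
                                "val_accuracy": []},
                       seed=seed)


def _clip_global_norm(grads: list[dict], max_norm: float) -> None:
    total = 0.0
    for g in grads:
        for v in g.values():
            total += float((v.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / norm)
        for g in grads:
            for k in g:
                g[k] = g[k] * scale


def _check_images(images: np.ndarray, spec: NetSpec) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if np.isnan(images).any():
        raise ValueError("input images contain NaN")
    t, w, _ = spec.input_shape
    if images.shape[1:3] != (t, w):
        raise ValueError(
            f"images of shape {images.shape[1:3]} do not match the network "
            f"input {t} x {w}")
    return images


def train(bundle: ModelBundle, dataset: ImageDataset,
          cfg: TrainConfig) -> ModelBundle:
    """SGDM training honoring ``cfg``; returns a new bundle.

    The input bundle is untouched.  Validation metrics are recorded every
    ``cfg.validation_frequency`` iterations on the dataset's ``val`` split
    (if present); validation images never contribute gradients.  Frozen
    layers are skipped by the optimizer and keep bit-identical parameters.
    """
    out = bundle.copy()
    net = out.make_network()
    X_tr, y_tr = dataset.subset("train")
    if len(X_tr) == 0:
        raise ValueError("training split is empty")
    X_tr = _check_images(X_tr, out.spec)
    X_va, y_va = dataset.subset("val")
    has_val = len(X_va) > 0
    if has_val:
        X_va = _check_images(X_va, out.spec)

    rng = np.random.default_rng(cfg.seed)
    params = [l.params() for l in net.layers()]   # live references
    velocity = [dict() for _ in params]

    # a frozen prefix of conv blocks never changes, so its activations can
    # be computed once and training restricted to the layers above it
    n_pre = 0
    n_blocks = len(net.blocks)
    while n_pre < n_blocks and out.frozen[n_pre]:
        n_pre += 1
    if n_pre:
        X_tr = net.forward_features(X_tr, n_pre)
        if has_val:
            X_va = net.forward_features(X_va, n_pre)

    it = 0
    n = len(X_tr)
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = X_tr[sel], y_tr[sel]
            probs = net.forward(xb, train=True, rng=rng, start_block=n_pre)
            grads = net.backward(probs, yb, stop_block=n_pre)
            if cfg.clip_grad_norm is not None:
                _clip_global_norm(grads, cfg.clip_grad_norm)
            sgdm_update(params, grads, velocity, cfg.learning_rate,
                        cfg.momentum, out.frozen)
            it += 1
            out.history["iteration"].append(it)
            out.history["loss"].append(cross_entropy(probs, yb))
            out.history["accuracy"].append(float((probs.argmax(1) == yb).mean()))
            if has_val and it % cfg.validation_frequency == 0:
                pv = net.forward(X_va, train=False, start_block=n_pre)
                out.history["val_iteration"].append(it)
                out.history["val_loss"].append(cross_entropy(pv, y_va))
                out.history["val_accuracy"].append(
                    float((pv.argmax(1) == y_va).mean()))

    out.parameters = net.get_params()
    # restore bit-identical parameters on frozen layers
    for i, fr in enumerate(out.frozen):
        if fr:
            out.parameters[i] = {k: v.copy() for k, v in bundle.parameters[i].items()}
    if out.provenance == "untrained":
        out.provenance = ("pretrained_multimodal"
                          if dataset.layout_mode == "fused" else "single_modal")
    return out


def predict(bundle: ModelBundle, images: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax of softmax) and probabilities; deterministic."""
    images = _check_images(np.asarray(images), bundle.spec)
    net = bundle.make_network()
    probs = net.forward(images, train=False)
    return probs.argmax(axis=1), probs


def _val_accuracy(bundle: ModelBundle, dataset: ImageDataset) -> float:
    X, y = dataset.subset("val")
    if len(X) == 0:
        raise ValueError("grid search requires a validation split")
    pred, _ = predict(bundle, X)
    return float((pred == y).mean())


def _with_val(dataset: ImageDataset, frac: float, seed: int) -> ImageDataset:
    """Carve a validation subset out of the train split (map level)."""
    ds = copy.copy(dataset)
    split = dataset.split.copy()
    tr = np.where(split == "train")[0]
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(frac * len(tr))))
    val_ix = rng.choice(tr, size=n_val, replace=False)
    split[val_ix] = "val"
    ds.split = split
    return ds


def grid_search_lr(dataset: ImageDataset, cfg: TrainConfig,
                   spec: NetSpec | None = None, seed: int = 0) -> float:
    """Train one model per grid learning rate; select by validation
    accuracy, breaking ties toward the smaller rate."""
    if not cfg.lr_grid:
        raise ValueError("lr_grid is empty")
    if spec is None:
        spec = NetSpec.for_width(dataset.width)
    if not (dataset.split == "val").any():
        dataset = _with_val(dataset, 0.2, seed)
    best_lr, best_acc = None, -1.0
    for lr in sorted(cfg.lr_grid, reverse=True):  # ties -> smaller lr wins
        bundle = build_network(spec, seed=seed)
        fitted = train(bundle, dataset, cfg.replace(learning_rate=lr))
        acc = _val_accuracy(fitted, dataset)
        if acc >= best_acc:
            best_lr, best_acc = lr, acc
    return best_lr


def transfer_learn(pretrained: ModelBundle, dataset: ImageDataset,
                   cfg: TrainConfig | None = None,
                   freeze_all_conv: bool = False) -> ModelBundle:
    """Freeze the convolutional base and retrain the top on padded images.

    Blocks 1-4 are frozen (all five with ``freeze_all_conv``); block 5 and
    the fully connected head are retrained at the transfer learning rate,
    3e-4 by default.  Frozen parameters are bit-identical before and after.
    """
    if pretrained.provenance != "pretrained_multimodal":
        raise ValueError(
            f"transfer learning requires a pretrained_multimodal bundle, "
            f"got provenance {pretrained.provenance!r}")
    t, w, _ = pretrained.spec.input_shape
    if dataset.width != w:
        raise ValueError(
            f"dataset width {dataset.width} does not match the pretrained "
            f"input width {w}; pad the single modality into the fused layout")
    if cfg is None:
        cfg = TrainConfig(learning_rate=3e-4)
    bundle = pretrained.copy()
    n_frozen = 5 if freeze_all_conv else 4
    bundle.frozen = [i < n_frozen for i in range(len(bundle.frozen))]
    bundle.history = {k: [] for k in bundle.history}
    if cfg.max_epochs > 0:
        # the classification head is trained as a NEW layer: the pretrained
        # head weighs the other modality's (now blank) columns and would
        # otherwise anchor predictions to stale features
        fresh = build_network(bundle.spec, seed=cfg.seed)
        bundle.parameters[-1] = fresh.parameters[-1]
    fitted = train(bundle, dataset, cfg)
    fitted.provenance = "transfer_learned"
    fitted.source_id = pretrained.source_id or "pretrained_multimodal"
    return fitted


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a bundle to a portable ``.npz`` with a JSON manifest."""
    import json

    manifest = {
        "spec": {"input_shape": list(bundle.spec.input_shape),
                 "conv_filters": list(bundle.spec.conv_filters),
                 "kernel": list(bundle.spec.kernel),
                 "dropout_rate": bundle.spec.dropout_rate,
                 "n_classes": bundle.spec.n_classes},
        "frozen": bundle.frozen,
        "provenance": bundle.provenance,
        "source_id": bundle.source_id,
        "seed": bundle.seed,
        "history": bundle.history,
    }
    arrays = {f"layer{i}__{k}": v
              for i, p in enumerate(bundle.parameters) for k, v in p.items()}
    with open(path, "wb") as fh:  # honor the exact path, whatever its suffix
        np.savez_compressed(fh, manifest=np.asarray(json.dumps(manifest)),
                            n_layers=np.asarray(len(bundle.parameters)),
                            **arrays)


def load_bundle(path) -> ModelBundle:
    """Load a bundle written by :func:`save_bundle`."""
    import json

    with np.load(path, allow_pickle=False) as z:
        if "manifest" not in z.files:
            raise ValueError(f"{path} is not a model bundle (no manifest)")
        m = json.loads(str(z["manifest"]))
        n_layers = int(z["n_layers"])
        params: list[dict[str, np.ndarray]] = [dict() for _ in range(n_layers)]
        for name in z.files:
            if name.startswith("layer"):
                layer, key = name.split("__", 1)
                params[int(layer[5:])][key] = z[name]
    spec = NetSpec(input_shape=tuple(m["spec"]["input_shape"]),
                   conv_filters=tuple(m["spec"]["conv_filters"]),
                   kernel=tuple(m["spec"]["kernel"]),
                   dropout_rate=m["spec"]["dropout_rate"],
                   n_classes=m["spec"]["n_classes"])
    return ModelBundle(spec=spec, parameters=params, frozen=list(m["frozen"]),
                       history=m["history"], provenance=m["provenance"],
                       source_id=m["source_id"], seed=m["seed"])


# --------------------------------------------------------------------------
# model-object surface
# --------------------------------------------------------------------------

class CNNClassifier:
    """Model object over an :class:`ImageDataset`.

    ``CNNClassifier(dataset, spec).fit(cfg)`` returns :class:`CNNResults`
    holding the fitted bundle, its training history, and test metrics.
    """

    def __init__(self, dataset: ImageDataset, spec: NetSpec | None = None,
                 seed: int = 0):
        self.dataset = dataset
        self.spec = spec or NetSpec.for_width(dataset.width)
        self.seed = seed

    def fit(self, cfg: TrainConfig | None = None) -> "CNNResults":
        cfg = cfg or TrainConfig()
        bundle = build_network(self.spec, seed=self.seed)
        fitted = train(bundle, self.dataset, cfg)
        return CNNResults(self, fitted, cfg)

    def fit_transfer(self, pretrained: ModelBundle,
                     cfg: TrainConfig | None = None,
                     freeze_all_conv: bool = False) -> "CNNResults":
        fitted = transfer_learn(pretrained, self.dataset, cfg,
                                freeze_all_conv=freeze_all_conv)
        return CNNResults(self, fitted, cfg or TrainConfig(learning_rate=3e-4))


class CNNResults:
    """Fitted-model results: bundle, history, accuracies, summary table."""

    def __init__(self, model: CNNClassifier, bundle: ModelBundle,
                 cfg: TrainConfig):
        self.model = model
        self.bundle = bundle
        self.cfg = cfg

    def accuracy(self, which: str = "test") -> float:
        """Classification accuracy (%) on a split: correct / total x 100."""
        X, y = self.model.dataset.subset(which)
        if len(X) == 0:
            raise ValueError(f"split {which!r} is empty")
        pred, _ = predict(self.bundle, X)
        return float((pred == y).mean() * 100.0)

    def confusion(self, which: str = "test") -> np.ndarray:
        X, y = self.model.dataset.subset(which)
        pred, _ = predict(self.bundle, X)
        k = self.bundle.spec.n_classes
        cm = np.zeros((k, k), dtype=int)
        np.add.at(cm, (y, pred), 1)
        return cm

    def summary(self) -> str:
        b = self.bundle
        lines = [
            "CNN motion classifier results",
            "=============================",
            f"provenance:      {b.provenance}",
            f"input shape:     {b.spec.input_shape}",
            f"conv filters:    {b.spec.conv_filters}",
            f"learning rate:   {self.cfg.learning_rate:g}  (momentum {self.cfg.momentum:g})",
            f"epochs:          {self.cfg.max_epochs}",
            f"final train acc: {100 * b.history['accuracy'][-1]:.1f} %"
            if b.history["accuracy"] else "final train acc: n/a",
        ]
        for split in ("train", "test"):
            try:
                lines.append(f"{split} accuracy:   {self.accuracy(split):.2f} %")
            except ValueError:
                pass
        return "\n".join(lines)
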