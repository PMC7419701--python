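"""Densely connected 3D CNN for resting-state network classification.

The classifier maps a whole-brain Fisher-z correlation volume (one seed) to a
probability distribution over the K networks. Architecture: a stem
convolution, dense blocks whose layers each see the concatenation of all
previous features in the block (3- and 5-cubic convolutions alternating),
batch normalization, average pooling in the transitions, and a global average
pool before the K-way softmax head.

Layer accounting (the manifest's rule): learnable convolution and fully
connected layers are counted, i.e.

    total = 1 (stem) + sum(layers per block) + (n_blocks - 1) transitions + 1 (head)

so the reference configuration — 3 dense blocks of 15 layers — counts 49.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import (ConfigurationError, CoverageError, LabelDegeneracyError,
                     ParameterError)
from .nn import (Adam, AvgPool3d, BatchNorm3d, Conv3d, GlobalAvgPool3d, Linear,
                 ReLU, softmax, softmax_cross_entropy)


@dataclass(frozen=True)
class DenseNet3DConfig:
    """Architecture and training hyper-parameters.

    ``total_layers``, when given, is validated against the layer-accounting
    formula in the module docstring. Optimizer settings (Adam, fixed step) are
    free parameters exposed here.
    """

    n_dense_blocks: int = 2
    layers_per_block: tuple[int, ...] = (1, 2)
    kernel_edges: tuple[int, ...] = (3, 5)
    total_layers: int | None = None
    growth_rate: int = 6
    stem_channels: int = 8
    compression: float = 0.5
    use_batch_norm: bool = True
    pooling: str = "average"
    n_classes: int = 6
    patience_validations: int = 3
    split_fractions: tuple[float, float] = (0.7, 0.3)
    learning_rate: float = 3e-3
    batch_size: int = 16
    max_epochs: int = 80
    validate_every: int = 2

    def __post_init__(self):
        if self.n_dense_blocks < 1:
            raise ConfigurationError("need at least one dense block")
        if len(self.layers_per_block) != self.n_dense_blocks:
            raise ConfigurationError(
                f"layers_per_block {self.layers_per_block} does not match "
                f"{self.n_dense_blocks} blocks")
        for k in self.kernel_edges:
            if k % 2 == 0:
                raise ConfigurationError(f"kernel edges must be odd, got {k}")
        if self.pooling != "average":
            raise ConfigurationError("only average pooling is supported")
        expected = self.accounted_layers()
        if self.total_layers is not None and self.total_layers != expected:
            raise ConfigurationError(
                f"total_layers={self.total_layers} inconsistent with accounting "
                f"{self.accounting()} = {expected}")

    def accounted_layers(self) -> int:
        return 1 + sum(self.layers_per_block) + (self.n_dense_blocks - 1) + 1

    def accounting(self) -> str:
        return (f"1 stem + {'+'.join(map(str, self.layers_per_block))} block "
                f"conv layers + {self.n_dense_blocks - 1} transitions + 1 head")

    @classmethod
    def reference(cls, n_classes: int = 11) -> "DenseNet3DConfig":
        """The full-scale configuration: 49 layers, 3 dense blocks."""
        return cls(n_dense_blocks=3, layers_per_block=(15, 15, 15),
                   kernel_edges=(3, 5), total_layers=49, growth_rate=12,
                   stem_channels=16, n_classes=n_classes)

    @classmethod
    def desk_scale(cls, n_classes: int = 6) -> "DenseNet3DConfig":
        """Small configuration that trains in minutes on one CPU."""
        return cls(n_classes=n_classes)


@dataclass
class TrainingHistory:
    """Per-validation accuracy/loss trace and the stopping reason."""

    val_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    stop_reason: str = "max-epochs"
    best_accuracy: float = 0.0
    n_epochs: int = 0


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities over the K networks."""

    probs: np.ndarray              # (x, y, z, K)
    class_names: list[str]
    mask: np.ndarray

    def __post_init__(self):
        k = self.probs.shape[-1]
        if len(self.class_names) != k:
            raise ParameterError("one class name per probability channel")
        self.validate()

    def validate(self, tol: float = 1e-5) -> None:
        inside = self.probs[self.mask]
        if inside.size and not np.allclose(inside.sum(axis=-1), 1.0, atol=tol):
            raise ParameterError("in-mask probabilities must sum to 1")
        outside = self.probs[~self.mask]
        if outside.size and np.abs(outside).max() > 0:
            raise ParameterError("probabilities must be zero outside the mask")

    def class_map(self, name: str) -> np.ndarray:
        return self.probs[..., self.class_names.index(name)]


class DenseNet3D:
    """The network itself; built by :func:`build_model`."""

    def __init__(self, config: DenseNet3DConfig, input_shape: tuple[int, int, int],
                 seed: int = 0):
        if min(input_shape) < max(config.kernel_edges):
            raise ConfigurationError(
                f"input edge {min(input_shape)} smaller than largest kernel "
                f"{max(config.kernel_edges)}")
        self.config = config
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        self.manifest: list[dict] = []
        bn = config.use_batch_norm
        dims = list(input_shape)

        def can_pool(d):
            return all(v % 2 == 0 and v >= 4 for v in d)

        def record(kind, kernel, cin, cout):
            self.manifest.append({"index": len(self.manifest) + 1, "kind": kind,
                                  "kernel": kernel, "in_channels": cin,
                                  "out_channels": cout})

        # average pooling for dimensionality reduction: once before the stem
        # convolution (correlation volumes are spatially smooth, so the stem
        # loses little) and once after it, but only while the grid stays
        # coarse enough for the dense blocks to see parcel-scale structure
        self.input_pool = AvgPool3d(2) if can_pool(dims) and min(dims) >= 16 \
            else None
        if self.input_pool:
            dims = [d // 2 for d in dims]
        c = config.stem_channels
        self.stem_conv = Conv3d(1, c, 3, rng)
        record("stem-conv", 3, 1, c)
        self.stem_pool = AvgPool3d(2) if can_pool(dims) and min(dims) >= 12 \
            else None
        if self.stem_pool:
            dims = [d // 2 for d in dims]

        self.blocks: list[list[dict]] = []
        self.transitions: list[dict] = []
        for b, n_layers in enumerate(config.layers_per_block):
            block = []
            for i in range(n_layers):
                k = config.kernel_edges[i % len(config.kernel_edges)]
                layer = {"bn": BatchNorm3d(c) if bn else None, "relu": ReLU(),
                         "conv": Conv3d(c, config.growth_rate, k, rng)}
                record("dense-conv", k, c, config.growth_rate)
                block.append(layer)
                c += config.growth_rate
            self.blocks.append(block)
            if b < config.n_dense_blocks - 1:
                c_out = max(1, int(c * config.compression))
                tr = {"bn": BatchNorm3d(c) if bn else None, "relu": ReLU(),
                      "conv": Conv3d(c, c_out, 1, rng),
                      "pool": AvgPool3d(2) if can_pool(dims) else None}
                record("transition-conv", 1, c, c_out)
                self.transitions.append(tr)
                c = c_out
                if tr["pool"]:
                    dims = [d // 2 for d in dims]

        self.head_bn = BatchNorm3d(c) if bn else None
        self.head_relu = ReLU()
        self.head_pool = GlobalAvgPool3d()
        self.head_fc = Linear(c, config.n_classes, rng)
        record("head-fc", None, c, config.n_classes)
        assert len(self.manifest) == config.accounted_layers()

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.input_pool.forward(x, train) if self.input_pool else x
        h = self.stem_conv.forward(h, train)
        if self.stem_pool:
            h = self.stem_pool.forward(h, train)
        for b, block in enumerate(self.blocks):
            for layer in block:
                y = h
                if layer["bn"]:
                    y = layer["bn"].forward(y, train)
                y = layer["relu"].forward(y, train)
                y = layer["conv"].forward(y, train)
                h = np.concatenate([h, y], axis=1)
            if b < len(self.transitions):
                tr = self.transitions[b]
                if tr["bn"]:
                    h = tr["bn"].forward(h, train)
                h = tr["relu"].forward(h, train)
                h = tr["conv"].forward(h, train)
                if tr["pool"]:
                    h = tr["pool"].forward(h, train)
        if self.head_bn:
            h = self.head_bn.forward(h, train)
        h = self.head_relu.forward(h, train)
        h = self.head_pool.forward(h, train)
        return self.head_fc.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head_fc.backward(dlogits)
        d = self.head_pool.backward(d)
        d = self.head_relu.backward(d)
        if self.head_bn:
            d = self.head_bn.backward(d)
        g = self.config.growth_rate
        for b in range(len(self.blocks) - 1, -1, -1):
            if b < len(self.transitions):
                tr = self.transitions[b]
                if tr["pool"]:
                    d = tr["pool"].backward(d)
                d = tr["conv"].backward(d)
                d = tr["relu"].backward(d)
                if tr["bn"]:
                    d = tr["bn"].backward(d)
            for layer in reversed(self.blocks[b]):
                dy = d[:, -g:]
                d = np.ascontiguousarray(d[:, :-g])
                dx = layer["conv"].backward(dy)
                dx = layer["relu"].backward(dx)
                if layer["bn"]:
                    dx = layer["bn"].backward(dx)
                d = d + dx
        if self.stem_pool:
            d = self.stem_pool.backward(d)
        d = self.stem_conv.backward(d)
        if self.input_pool:
            self.input_pool.backward(d)

    # ---- parameters / state -------------------------------------------------

    def _layers(self):
        yield self.stem_conv
        for block in self.blocks:
            for layer in block:
                if layer["bn"]:
                    yield layer["bn"]
                yield layer["conv"]
        for tr in self.transitions:
            if tr["bn"]:
                yield tr["bn"]
            yield tr["conv"]
        if self.head_bn:
            yield self.head_bn
        yield self.head_fc

    def parameters(self):
        for layer in self._layers():
            yield from layer.params()

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._layers()):
            for j, (p, _) in enumerate(layer.params()):
                state[f"p{i}_{j}"] = p
            if isinstance(layer, BatchNorm3d):
                state[f"rm{i}"] = layer.running_mean
                state[f"rv{i}"] = layer.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for j, (p, _) in enumerate(layer.params()):
                p[...] = state[f"p{i}_{j}"]
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"rm{i}"]
                layer.running_var[...] = state[f"rv{i}"]

    def save(self, path: str) -> None:
        meta = {"config": asdict(self.config), "input_shape": self.input_shape,
                "manifest": self.manifest}
        np.savez(path, __meta__=json.dumps(meta),
                 **{k: v.copy() for k, v in self.state_arrays().items()})

    @classmethod
    def load(cls, path: str) -> "DenseNet3D":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            cfg = meta["config"]
            for key in ("layers_per_block", "kernel_edges", "split_fractions"):
                cfg[key] = tuple(cfg[key])
            model = cls(DenseNet3DConfig(**cfg), tuple(meta["input_shape"]))
            model.set_state({k: f[k] for k in f.files if k != "__meta__"})
        return model

    def predict_proba(self, volumes: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax probabilities for a stack of correlation volumes (N, x, y, z)."""
        out = []
        for start in range(0, len(volumes), batch_size):
            x = volumes[start:start + batch_size, None].astype(np.float32)
            out.append(softmax(self.forward(x, train=False)))
        return np.concatenate(out)


def build_model(config: DenseNet3DConfig, input_shape: tuple[int, int, int],
                seed: int = 0) -> tuple[DenseNet3D, list[dict]]:
    """Instantiate the network; returns (model, layer manifest)."""
    model = DenseNet3D(config, input_shape, seed=seed)
    return model, model.manifest


def train(model: DenseNet3D, example_set, config: DenseNet3DConfig | None = None,
          seed: int = 0, verbose: bool = False) -> TrainingHistory:
    """Optimize cross-entropy on the train partition with early stopping.

    Validation accuracy is evaluated every ``validate_every`` epochs; training
    stops once accuracy has not improved for ``patience_validations``
    consecutive evaluations, restoring the best-validation weights.
    """
    config = config or model.config
    labels = np.asarray(example_set.labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise LabelDegeneracyError("training set must contain >= 2 classes")
    if len(example_set.train_idx) == 0 or len(example_set.val_idx) == 0:
        raise LabelDegeneracyError("both partitions must be non-empty")
    y = labels - 1  # network ids 1..K -> 0-based
    vols = example_set.volumes
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    best_state = None
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(example_set.train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = vols[idx][:, None].astype(np.float32)
            logits = model.forward(x, train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.n_epochs = epoch
        if epoch % config.validate_every:
            continue
        probs = model.predict_proba(vols[example_set.val_idx])
        acc = float((probs.argmax(axis=1) == y[example_set.val_idx]).mean())
        history.val_accuracy.append(acc)
        history.train_loss.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch}: loss {np.mean(losses):.4f} val acc {acc:.4f}")
        if acc > history.best_accuracy:
            history.best_accuracy = acc
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience_validations:
                history.stop_reason = "early-stop"
                break
    if best_state is not None:
        model.set_state(best_state)
    return history


def predict_volume(model: DenseNet3D, stream, mask: np.ndarray,
                   class_names: list[str] | None = None) -> ProbabilityVolume:
    """Assemble per-voxel softmax probabilities from an inference stream.

    ``stream`` yields ``(positions, volumes, degenerate)`` in in-mask raster
    order (see :func:`langmap.features.iter_inference_examples`). Degenerate
    voxels receive uniform 1/K probabilities.
    """
    k = model.config.n_classes
    class_names = class_names or [f"network-{i + 1}" for i in range(k)]
    n_vox = int(mask.sum())
    flat = np.zeros((n_vox, k), dtype=np.float32)
    seen = np.zeros(n_vox, dtype=bool)
    for positions, volumes, degenerate in stream:
        p = model.predict_proba(volumes)
        p[degenerate] = 1.0 / k
        flat[positions] = p
        seen[positions] = True
    if not seen.all():
        raise CoverageError(f"stream covered {seen.sum()} of {n_vox} mask voxels")
    probs = np.zeros(mask.shape + (k,), dtype=np.float32)
    probs[mask] = flat
    return ProbabilityVolume(probs=probs, class_names=class_names, mask=mask)


# ---------------------------------------------------------------------------
# probability-map smoothing: stride-1 mode filter, then length-3 box filter
# ---------------------------------------------------------------------------

def _window_sum(x: np.ndarray, size: int) -> np.ndarray:
    return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * size ** 3


def smooth_probability(prob: ProbabilityVolume, mode_window: int = 3,
                       box_length: int = 3, apply_mode: bool = True,
                       apply_box: bool = True) -> ProbabilityVolume:
    """Two-stage spatial regularization of a probability volume.

    Stage 1 (mode filter, stride 1): the winner-take-all label volume is
    replaced by its modal label in a cubic window (ties -> lowest class
    index), and each voxel's probability vector becomes the mean over
    neighborhood voxels sharing that modal label. Stage 2 (box filter):
    separable length-``box_length`` moving average per class, restricted to
    the mask, then renormalized per voxel. Out-of-mask voxels never
    contribute.
    """
    if mode_window % 2 == 0 or box_length % 2 == 0:
        raise ParameterError("mode window and box length must be odd")
    mask = prob.mask
    maskf = mask.astype(float)
    k = prob.probs.shape[-1]
    p = prob.probs.astype(float)

    if apply_mode and mode_window > 1:
        labels = p.argmax(axis=-1)
        onehot = [(labels == c) & mask for c in range(k)]
        counts = np.stack([_window_sum(oh.astype(float), mode_window)
                           for oh in onehot], axis=-1)
        modal = counts.argmax(axis=-1)
        new_p = np.zeros_like(p)
        modal_count = np.take_along_axis(counts, modal[..., None], axis=-1)[..., 0]
        modal_count[modal_count == 0] = 1.0
        for c in range(k):
            sel_c = onehot[c].astype(float)
            member_sum = np.stack(
                [_window_sum(p[..., j] * sel_c, mode_window) for j in range(k)],
                axis=-1)
            use = modal == c
            new_p[use] = member_sum[use] / modal_count[use][:, None]
        p = new_p
        p[~mask] = 0.0

    if apply_box and box_length > 1:
        denom = _window_sum(maskf, box_length)
        denom[denom == 0] = 1.0
        for c in range(k):
            p[..., c] = _window_sum(p[..., c] * maskf, box_length) / denom
        p[~mask] = 0.0

    total = p.sum(axis=-1)
    total[total == 0] = 1.0
    p = p / total[..., None]
    p[~mask] = 0.0
    return ProbabilityVolume(probs=p, class_names=list(prob.class_names), mask=mask)
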