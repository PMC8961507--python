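"""Realize a :class:`~eunet.graphgen.LayerGraph` as a trainable network.

The realization compiles the graph into a flat, topologically ordered
program of primitive ops over named tensors; forward and reverse passes
run that program in a fixed order, so training is bitwise-reproducible
for a fixed seed under ``deterministic_mode``.

Training minimizes the soft Dice loss

    L = 1 − (2·Σ p·t + ε) / (Σ p + Σ t + ε)

with additive smoothing ε (default 1.0) in numerator and denominator,
the standard differentiable surrogate for the Dice coefficient on binary
masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import RealizationError
from .graphgen import LayerGraph, _walk_shapes
from .metrics import MetricReport, confusion, metric_report

__all__ = [
    "TrainingConfig", "ModelHandle", "TrainingResult",
    "realize", "dice_loss", "train", "predict", "evaluate_loss",
    "save_model", "load_weights",
]

F = np.float32


@dataclass
class TrainingConfig:
    seed: int = 0
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    base_filters: int = 64  # echoed into artifacts
    dice_smoothing: float = 1.0
    deterministic_mode: bool = True
    shuffle: bool = True
    #: optional early-stop threshold on the evaluation-mode training loss;
    #: ``epochs`` remains the hard cap.
    stop_at_train_loss: float | None = None
    track_metrics: bool = False

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0 \
                or self.dice_smoothing <= 0:
            raise ValueError("epochs/batch_size/learning_rate/dice_smoothing must be positive")
        if self.optimizer_name not in nn.OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}; "
                             f"choose from {sorted(nn.OPTIMIZERS)}")


@dataclass
class _Instr:
    op: nn.Op
    inputs: list[str]
    output: str


@dataclass
class ModelHandle:
    graph: LayerGraph
    program: list[_Instr]
    params: list[nn.Param]
    fingerprint: str
    parameter_count: int
    seed: int

    def batchnorms(self) -> list[nn.BatchNorm]:
        return [i.op for i in self.program if isinstance(i.op, nn.BatchNorm)]


@dataclass
class TrainingResult:
    """Per-epoch traces of a training run (what a loss-curve figure plots)."""

    train_loss: list[float]       # optimisation loss (train mode, batch mean)
    train_eval_loss: list[float]  # evaluation-mode Dice loss on the train set
    val_loss: list[float | None]
    metric_trace: list[MetricReport | None]
    config: TrainingConfig
    epochs_run: int

    def to_csv(self, path) -> None:
        lines = ["epoch,train_loss,train_eval_loss,val_loss"]
        for i in range(self.epochs_run):
            v = "" if self.val_loss[i] is None else f"{self.val_loss[i]:.6f}"
            lines.append(f"{i + 1},{self.train_loss[i]:.6f},"
                         f"{self.train_eval_loss[i]:.6f},{v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _compile(graph: LayerGraph, seed: int) -> tuple[list[_Instr], list[nn.Param]]:
    shapes = _walk_shapes(graph)
    program: list[_Instr] = []
    feat_var: dict[str, str] = {}
    out_var: dict[str, str] = {}
    conv_index = 0

    for nid in graph.topo_order():
        node = graph.nodes[nid]
        src = graph.main_input(nid)
        cur = out_var[src] if src is not None else "input"
        last_non_pool = cur
        for k, (op, inp, out) in enumerate(shapes[nid]["per_op"]):
            var = f"{nid}/{k}"
            name = f"{nid}.{k}"
            if op.kind == "conv":
                layer = nn.Conv2D(name, inp[2], op.channels_out, op.kernel, op.dilation)
                layer.init(np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(conv_index,))))
                conv_index += 1
                inputs = [cur]
            elif op.kind == "pool":
                layer, inputs = nn.MaxPool2(op.factor), [cur]
            elif op.kind == "upsample":
                layer, inputs = nn.Upsample2(op.factor), [cur]
            elif op.kind == "batchnorm":
                layer, inputs = nn.BatchNorm(name, inp[2]), [cur]
            elif op.kind == "activation":
                layer, inputs = nn.Activation(op.fn), [cur]
            elif op.kind == "dropout":
                layer, inputs = nn.Dropout(op.rate), [cur]
            elif op.kind == "concat":
                layer = nn.Concat()
                extras = [feat_var[s] for s in node.concat_sources]
                inputs = extras if node.role == "merge" else [cur] + extras
            else:
                raise RealizationError(f"unsupported op kind {op.kind!r} in {nid}")
            program.append(_Instr(layer, inputs, var))
            cur = var
            if op.kind != "pool":
                last_non_pool = var
        feat_var[nid] = last_non_pool
        out_var[nid] = cur

    params = [p for instr in program for p in instr.op.params()]
    return program, params


def realize(graph: LayerGraph, seed: int = 0) -> ModelHandle:
    """Instantiate the graph with seeded He-normal initialization.

    Every convolution draws from its own seed stream derived from
    ``seed`` and its position in the graph, so parallel branches are
    independently initialized while the whole model stays reproducible.
    """
    program, params = _compile(graph, seed)
    return ModelHandle(
        graph=graph, program=program, params=params,
        fingerprint=graph.fingerprint(),
        parameter_count=sum(p.value.size for p in params),
        seed=seed,
    )


def _forward(model: ModelHandle, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
    vals = {"input": x.astype(F)}
    for instr in model.program:
        vals[instr.output] = instr.op.forward(
            [vals[v] for v in instr.inputs], training, rng)
    model._vals = vals
    return vals[model.program[-1].output]


def _backward(model: ModelHandle, dy: np.ndarray) -> None:
    grads = {model.program[-1].output: dy}
    for instr in reversed(model.program):
        g = grads.pop(instr.output, None)
        if g is None:
            continue
        dxs = instr.op.backward(g)
        for v, dx in zip(instr.inputs, dxs):
            if v in grads:
                grads[v] = grads[v] + dx
            else:
                grads[v] = dx


def dice_loss(pred: np.ndarray, target: np.ndarray, smoothing: float = 1.0) -> float:
    """Soft Dice loss in [0, 1); 0 for perfect overlap."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum() + smoothing
    return float(1.0 - (2.0 * inter + smoothing) / denom)


def _dice_grad(pred: np.ndarray, target: np.ndarray, smoothing: float) -> np.ndarray:
    p = pred.astype(np.float64)
    t = target.astype(np.float64)
    a = 2.0 * (p * t).sum() + smoothing
    b = p.sum() + t.sum() + smoothing
    return (-(2.0 * t * b - a) / (b * b)).astype(F)


def _stack(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of SamplePair-like objects or an (images, masks) pair."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        images, masks = dataset
    else:
        images = [s.image for s in dataset]
        masks = [s.mask for s in dataset]
    x = np.stack([np.atleast_3d(np.asarray(im, dtype=F)) for im in images])
    y = np.stack([np.atleast_3d(np.asarray(m, dtype=F)) for m in masks])
    return x, y


def evaluate_loss(model: ModelHandle, dataset, smoothing: float = 1.0,
                  batch_size: int = 8) -> float:
    """Evaluation-mode (no dropout, running batch-norm stats) Dice loss,
    pooled over all pixels of the dataset."""
    x, y = _stack(dataset)
    preds = []
    for i in range(0, len(x), batch_size):
        preds.append(_forward(model, x[i:i + batch_size], training=False))
    return dice_loss(np.concatenate(preds), y, smoothing)


def train(model: ModelHandle, train_set, val_set=None,
          config: TrainingConfig | None = None) -> TrainingResult:
    """Train with the Dice loss; returns full per-epoch traces.

    With ``deterministic_mode`` on, identical (seed, data, config) reruns
    produce identical traces bit for bit.
    """
    config = config or TrainingConfig()
    x, y = _stack(train_set)
    n = len(x)
    opt = nn.OPTIMIZERS[config.optimizer_name](model.params, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xD5,)))
    drop_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xD6,)))

    train_loss, train_eval, val_loss, metric_trace = [], [], [], []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n) if config.shuffle else np.arange(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = _forward(model, x[idx], training=True, rng=drop_rng)
            loss = dice_loss(pred, y[idx], config.dice_smoothing)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, batch {start // config.batch_size + 1}")
            batch_losses.append(loss)
            opt.zero_grad()
            _backward(model, _dice_grad(pred, y[idx], config.dice_smoothing))
            opt.step()
        train_loss.append(float(np.mean(batch_losses)))
        te = evaluate_loss(model, (x, y), config.dice_smoothing)
        train_eval.append(te)
        if val_set is not None:
            xv, yv = _stack(val_set)
            val_loss.append(evaluate_loss(model, (xv, yv), config.dice_smoothing))
            if config.track_metrics:
                pv = np.concatenate([_forward(model, xv[i:i + 8], training=False)
                                     for i in range(0, len(xv), 8)])
                metric_trace.append(metric_report(
                    confusion((pv >= 0.5).astype(np.uint8), yv.astype(np.uint8))))
            else:
                metric_trace.append(None)
        else:
            val_loss.append(None)
            metric_trace.append(None)
        if config.stop_at_train_loss is not None and te <= config.stop_at_train_loss:
            break

    return TrainingResult(train_loss=train_loss, train_eval_loss=train_eval,
                          val_loss=val_loss, metric_trace=metric_trace,
                          config=config, epochs_run=len(train_loss))


def predict(model: ModelHandle, image: np.ndarray, pad: bool = True) -> np.ndarray:
    """Probability map in [0, 1] with the spatial size of the input.

    Inputs whose sides are not divisible by the pooling requirement are
    reflect-padded and the output cropped back (``pad=False`` raises
    instead).
    """
    from .data import pad_to_divisible

    img = np.asarray(image, dtype=F)
    squeeze_batch = img.ndim < 4
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim == 3:
        img = img[None]
    levels = 1 - min(n.elevation for n in model.graph.nodes.values())
    div = 2 ** (levels - 1)
    h, w = img.shape[1:3]
    record = None
    if h % div or w % div:
        if not pad:
            raise ValueError(
                f"input size {(h, w)} not divisible by {div}; pass pad=True")
        padded, record = pad_to_divisible(img[0] if squeeze_batch else img, levels)
        img = padded[None] if squeeze_batch else padded
    out = _forward(model, img, training=False)
    if record is not None:
        out = record.crop(out[0] if squeeze_batch else out)
        if squeeze_batch:
            out = out[None]
    out = out[..., 0]
    return out[0] if squeeze_batch else out


def save_model(model: ModelHandle, path, config: TrainingConfig | None = None) -> None:
    """Checkpoint: an .npz of parameters and batch-norm moments plus a JSON
    sidecar with the graph, seed and config."""
    path = Path(path)
    arrays = {f"param{i}": p.value for i, p in enumerate(model.params)}
    for i, bn in enumerate(model.batchnorms()):
        arrays[f"bn{i}.mean"] = bn.running_mean
        arrays[f"bn{i}.var"] = bn.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "fingerprint": model.fingerprint,
        "seed": model.seed,
        "parameter_count": model.parameter_count,
        "graph": model.graph.to_dict(),
        "config": asdict(config) if config else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_weights(model: ModelHandle, path) -> ModelHandle:
    data = np.load(Path(path).with_suffix(".npz"))
    for i, p in enumerate(model.params):
        p.value = data[f"param{i}"].astype(F)
    for i, bn in enumerate(model.batchnorms()):
        bn.running_mean = data[f"bn{i}.mean"].astype(F)
        bn.running_var = data[f"bn{i}.var"].astype(F)
    return model
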