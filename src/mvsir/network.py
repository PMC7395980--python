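"""The MV-SIR voxel classifier: six secondary-input residual (SIR) branches.

A single SIR submodel classifies one 30x30 patch.  Its stem is a 3x3
convolution (C1, 32 kernels) and a 2x2 stride-2 max pool (P2), giving a
15x15x32 map.  An identity residual block (1x1 valid -> 3x3 same -> 1x1
valid, skip added, ReLU) keeps that shape.  The *secondary input* re-injects
the original patch through one convolution + pool (EC1/EP2, 15x15x32) and is
channel-concatenated with the residual output (15x15x64).  A further pool
(P3, ceil mode: 15 -> 8), a 3x3 convolution to 128 channels (C4), a second
identity residual block, and a shape-preserving 2x2 stride-1 pool produce an
8x8x128 map, flattened into two 256-wide dense layers (F7, F8).

The full MV-SIR model runs six submodels — intensity (VH) and shape (SH)
patches from the axial, coronal and sagittal planes — concatenates the six
256-vectors, and maps them through a fusion dense layer to a single sigmoid
neuron: the probability that the centre voxel belongs to the nodule.

Ablation variants: ``MV-I-CNN`` drops the secondary-input path; ``MV-CNN``
additionally replaces each residual block with a single 3x3 same convolution
(a plain conv/pool stack of matched depth).

Training minimises mean binary cross-entropy with Adam; "weight decay" is an
L2 coefficient by default (a learning-rate-decay interpretation is available
via ``decay_mode='lr'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .nn import Adam, Conv2D, Dense, Flatten, Layer, MaxPool2D, Param, ReLU

VARIANTS = ("MV-SIR", "MV-I-CNN", "MV-CNN")

#: fixed ordering of the six input streams
STREAM_ORDER = (
    "axial-VH", "axial-SH",
    "coronal-VH", "coronal-SH",
    "sagittal-VH", "sagittal-SH",
)


@dataclass
class NetConfig:
    """Architecture hyper-parameters (defaults are the published model)."""

    patch_size: int = 30
    stem_channels: int = 32
    residual1_widths: tuple[int, int, int] = (32, 32, 32)
    residual2_widths: tuple[int, int, int] = (128, 128, 128)
    fc_width: int = 256
    fusion_width: int = 256
    variant: str = "MV-SIR"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.residual1_widths[-1] != self.stem_channels:
            raise ValueError("residual block 1 output width must equal its input "
                             f"({self.stem_channels}) for the identity skip")


@dataclass
class TrainConfig:
    """Optimisation settings (defaults are the published run)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    decay_mode: str = "l2"
    batch_size: int = 2000
    epochs: int = 100
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        for name in ("learning_rate", "weight_decay", "batch_size", "epochs"):
            if getattr(self, name) < 0 or getattr(self, name) == 0 and name != "weight_decay":
                raise ValueError(f"{name} must be positive")


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Logistic function 1 / (1 + exp(-z)), numerically stable both tails."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def bce_loss(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy -(1/n) sum[y log p + (1-y) log(1-p)].

    Predictions are clipped to (eps, 1-eps); values outside [0, 1] before
    clipping are rejected.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    if np.any((y_pred < 0) | (y_pred > 1)):
        raise ValueError("predictions must lie in [0, 1] before clipping")
    p = np.clip(y_pred, eps, 1.0 - eps)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


class ResidualBlock(Layer):
    """Identity residual block: 1x1 valid -> 3x3 same -> 1x1 valid, + skip, ReLU.

    Input and output channel counts must match so the skip is addable.
    """

    def __init__(self, c_in: int, widths: tuple[int, int, int], *,
                 rng: np.random.Generator, dtype=np.float32):
        if widths[-1] != c_in:
            raise ValueError(f"last width {widths[-1]} must equal input channels "
                             f"{c_in} for the identity skip")
        w1, w2, w3 = widths
        self.conv1 = Conv2D(c_in, w1, 1, "valid", rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(w1, w2, 3, "same", rng=rng, dtype=dtype)
        self.relu2 = ReLU()
        self.conv3 = Conv2D(w2, w3, 1, "valid", rng=rng, dtype=dtype)
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        return self.conv1.params() + self.conv2.params() + self.conv3.params()

    def main_path(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """The F(x) branch alone (pre-addition), caching for backward."""
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.relu2.forward(self.conv2.forward(h, train), train)
        return self.conv3.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.relu_out.forward(self.main_path(x, train) + x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dpre = self.relu_out.backward(dy)
        dh = self.conv3.backward(dpre)
        dh = self.conv2.backward(self.relu2.backward(dh))
        dx_main = self.conv1.backward(self.relu1.backward(dh))
        return dx_main + dpre


class _ConvRelu(Layer):
    """Convenience: convolution followed by ReLU."""

    def __init__(self, *args, **kwargs):
        self.conv = Conv2D(*args, **kwargs)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params()

    def forward(self, x, train: bool = True):
        return self.relu.forward(self.conv.forward(x, train), train)

    def backward(self, dy):
        return self.conv.backward(self.relu.backward(dy))


class SIRSubmodel:
    """One branch: (primary patch, secondary patch) -> fc_width embedding.

    In the full model the secondary patch is the same image as the primary;
    the forward contract keeps them as two arguments so the shared-input
    choice lives in the caller.
    """

    def __init__(self, cfg: NetConfig, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.cfg = cfg
        self.use_secondary = cfg.variant == "MV-SIR"
        self.use_residual = cfg.variant in ("MV-SIR", "MV-I-CNN")
        s, c = cfg.patch_size, cfg.stem_channels
        self.c1 = _ConvRelu(1, c, 3, "same", rng=rng, dtype=dtype)
        self.p2 = MaxPool2D(2, "ceil")
        if self.use_residual:
            self.block1: Layer = ResidualBlock(c, cfg.residual1_widths, rng=rng, dtype=dtype)
            self.block2: Layer = ResidualBlock(cfg.residual2_widths[-1],
                                               cfg.residual2_widths, rng=rng, dtype=dtype)
        else:
            self.block1 = _ConvRelu(c, c, 3, "same", rng=rng, dtype=dtype)
            self.block2 = _ConvRelu(cfg.residual2_widths[-1], cfg.residual2_widths[-1],
                                    3, "same", rng=rng, dtype=dtype)
        if self.use_secondary:
            self.ec1 = _ConvRelu(1, c, 3, "same", rng=rng, dtype=dtype)
            self.ep2 = MaxPool2D(2, "ceil")
        self.p3 = MaxPool2D(2, "ceil")
        mid_c = 2 * c if self.use_secondary else c
        self.c4 = _ConvRelu(mid_c, cfg.residual2_widths[-1], 3, "same", rng=rng, dtype=dtype)
        self.p5 = MaxPool2D(2, "same")
        self.flat = Flatten()
        # flatten width found by a dry run (depends on patch_size via two
        # ceil-mode pools)
        deep = -(-(-(-s // 2)) // 2)
        n_flat = deep * deep * cfg.residual2_widths[-1]
        self.f7 = Dense(n_flat, cfg.fc_width, rng=rng, dtype=dtype)
        self.relu7 = ReLU()
        self.f8 = Dense(cfg.fc_width, cfg.fc_width, rng=rng, dtype=dtype)
        self.relu8 = ReLU()
        self.stage_shapes_: dict[str, tuple] = {}

    def params(self) -> list[Param]:
        ps = self.c1.params() + self.block1.params()
        if self.use_secondary:
            ps += self.ec1.params()
        ps += self.c4.params() + self.block2.params()
        ps += self.f7.params() + self.f8.params()
        return ps

    def forward(self, primary: np.ndarray, secondary: np.ndarray,
                train: bool = True) -> np.ndarray:
        rec = self.stage_shapes_
        h = self.c1.forward(primary, train)
        rec["c1"] = h.shape[1:]
        h = self.p2.forward(h, train)
        rec["p2"] = h.shape[1:]
        h = self.block1.forward(h, train)
        rec["block1"] = h.shape[1:]
        if self.use_secondary:
            e = self.ep2.forward(self.ec1.forward(secondary, train), train)
            rec["secondary"] = e.shape[1:]
            h = np.concatenate([h, e], axis=-1)
            rec["concat"] = h.shape[1:]
        h = self.p3.forward(h, train)
        rec["p3"] = h.shape[1:]
        h = self.c4.forward(h, train)
        rec["c4"] = h.shape[1:]
        h = self.block2.forward(h, train)
        rec["block2"] = h.shape[1:]
        h = self.p5.forward(h, train)
        rec["p5"] = h.shape[1:]
        h = self.flat.forward(h, train)
        h = self.relu7.forward(self.f7.forward(h, train), train)
        rec["f7"] = h.shape[1:]
        h = self.relu8.forward(self.f8.forward(h, train), train)
        rec["f8"] = h.shape[1:]
        return h

    def backward(self, demb: np.ndarray) -> None:
        d = self.f8.backward(self.relu8.backward(demb))
        d = self.f7.backward(self.relu7.backward(d))
        d = self.flat.backward(d)
        d = self.p5.backward(d)
        d = self.block2.backward(d)
        d = self.c4.backward(d)
        d = self.p3.backward(d)
        if self.use_secondary:
            c = self.cfg.stem_channels
            d, de = d[..., :c], d[..., c:]
            self.ec1.backward(self.ep2.backward(de))
        d = self.block1.backward(d)
        d = self.p2.backward(d)
        self.c1.backward(d)


class MVSIRNetwork:
    """Six SIR submodels fused by a dense layer into one sigmoid neuron."""

    def __init__(self, cfg: NetConfig, *, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.submodels = [SIRSubmodel(cfg, rng=rng, dtype=dtype) for _ in STREAM_ORDER]
        self.fusion = Dense(6 * cfg.fc_width, cfg.fusion_width, rng=rng, dtype=dtype)
        self.relu_fusion = ReLU()
        self.head = Dense(cfg.fusion_width, 1, rng=rng, dtype=dtype)
        self.dtype = dtype

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for sm in self.submodels:
            ps += sm.params()
        return ps + self.fusion.params() + self.head.params()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (n, 6, s, s) in the fixed stream order -> logits (n,)."""
        if x.ndim != 4 or x.shape[1] != len(STREAM_ORDER):
            raise ValueError(f"expected input of shape (n, 6, s, s), got {x.shape}")
        embs = []
        for i, sm in enumerate(self.submodels):
            patch = np.ascontiguousarray(x[:, i, :, :, None], dtype=self.dtype)
            # the same patch enters both the primary and the secondary path
            embs.append(sm.forward(patch, patch, train))
        fused = np.concatenate(embs, axis=1)
        self._fusion_in_width = fused.shape[1]
        h = self.relu_fusion.forward(self.fusion.forward(fused, train), train)
        return self.head.forward(h, train)[:, 0]

    def backward_logits(self, dlogit: np.ndarray) -> None:
        d = self.head.backward(dlogit[:, None])
        d = self.fusion.backward(self.relu_fusion.backward(d))
        w = self.cfg.fc_width
        for i, sm in enumerate(self.submodels):
            sm.backward(np.ascontiguousarray(d[:, i * w:(i + 1) * w]))

    def predict_proba_raw(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = np.empty(len(x), dtype=np.float64)
        for lo in range(0, len(x), batch_size):
            out[lo:lo + batch_size] = sigmoid(
                self.forward_logits(x[lo:lo + batch_size], train=False))
        return out

    def stage_shapes(self) -> dict[str, tuple]:
        """Run a dummy forward and report every submodel stage shape."""
        s = self.cfg.patch_size
        x = np.zeros((1, len(STREAM_ORDER), s, s), dtype=self.dtype)
        self.forward_logits(x)
        shapes = dict(self.submodels[0].stage_shapes_)
        shapes["fusion_in"] = (self._fusion_in_width,)
        shapes["fusion"] = (self.cfg.fusion_width,)
        return shapes

    # --- persistence -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("checkpoint does not match this architecture")
            p.value[...] = a


def build_sir_submodel(cfg: NetConfig | None = None, *, seed: int = 0) -> SIRSubmodel:
    cfg = cfg or NetConfig()
    return SIRSubmodel(cfg, rng=np.random.default_rng(seed))


def build_mvsir(cfg: NetConfig | None = None, *, seed: int = 0) -> MVSIRNetwork:
    return MVSIRNetwork(cfg or NetConfig(), seed=seed)


class MVSIRClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator around the MV-SIR network.

    Parameters mirror :class:`NetConfig` and :class:`TrainConfig`.  ``X`` is
    a float array of shape ``(n_samples, 6, patch_size, patch_size)`` whose
    second axis follows :data:`STREAM_ORDER`; ``y`` is binary.

    Fitted attributes: ``network_`` (the trained :class:`MVSIRNetwork`),
    ``learning_curve_`` (per-epoch DataFrame with ``acc``, ``loss``,
    ``val_acc``, ``val_loss``), ``classes_``, ``n_parameters_``.
    """

    def __init__(self, variant: str = "MV-SIR", patch_size: int = 30,
                 stem_channels: int = 32, fc_width: int = 256,
                 fusion_width: int = 256, learning_rate: float = 1e-4,
                 weight_decay: float = 1e-2, decay_mode: str = "l2",
                 batch_size: int = 2000, epochs: int = 100,
                 validation_fraction: float = 0.10, random_state: int | None = None):
        self.variant = variant
        self.patch_size = patch_size
        self.stem_channels = stem_channels
        self.fc_width = fc_width
        self.fusion_width = fusion_width
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.decay_mode = decay_mode
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _net_config(self) -> NetConfig:
        c = self.stem_channels
        return NetConfig(patch_size=self.patch_size, stem_channels=c,
                         residual1_widths=(c, c, c),
                         residual2_widths=(4 * c, 4 * c, 4 * c),
                         fc_width=self.fc_width, fusion_width=self.fusion_width,
                         variant=self.variant)

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[1] != len(STREAM_ORDER) or \
                X.shape[2] != self.patch_size or X.shape[3] != self.patch_size:
            raise ValueError(
                f"X must have shape (n, 6, {self.patch_size}, {self.patch_size}),"
                f" got {X.shape}")
        return X.astype(np.float32, copy=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MVSIRClassifier":
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        if not np.isin(self.classes_, [0, 1]).all():
            raise ValueError("labels must be binary {0, 1}")
        yf = y.astype(np.float64)
        seed = 0 if self.random_state is None else int(self.random_state)
        Xtr, Xval, ytr, yval = train_test_split(
            X, yf, test_size=self.validation_fraction, stratify=yf,
            random_state=seed % (2 ** 32))
        net = MVSIRNetwork(self._net_config(), seed=seed)
        opt = Adam(net.params(), lr=self.learning_rate,
                   weight_decay=self.weight_decay, decay_mode=self.decay_mode)
        rng = np.random.default_rng(seed + 1)
        rows = []
        n = len(Xtr)
        bs = min(self.batch_size, n)
        for epoch in range(self.epochs):
            opt.epoch = epoch
            order = rng.permutation(n)
            tot_loss = tot_correct = tot = 0.0
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                xb, yb = Xtr[idx], ytr[idx]
                logits = net.forward_logits(xb)
                p = sigmoid(logits)
                tot_loss += bce_loss(yb, p) * len(idx)
                tot_correct += np.sum((p >= 0.5) == (yb >= 0.5))
                tot += len(idx)
                opt.zero_grad()
                net.backward_logits(((p - yb) / len(idx)).astype(np.float32))
                opt.step()
            pval = net.predict_proba_raw(Xval)
            rows.append({
                "epoch": epoch + 1,
                "acc": tot_correct / tot,
                "loss": tot_loss / tot,
                "val_acc": float(np.mean((pval >= 0.5) == (yval >= 0.5))),
                "val_loss": bce_loss(yval, pval),
            })
        self.network_ = net
        self.learning_curve_ = pd.DataFrame(rows)
        self.n_parameters_ = net.n_parameters()
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.network_.predict_proba_raw(self._validate_X(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # --- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Write weights (npz) plus a JSON architecture fingerprint."""
        import json
        from pathlib import Path
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.network_.state_arrays())}
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        fingerprint = {
            "params": self.get_params(),
            "stage_shapes": {k: list(v) for k, v in self.network_.stage_shapes().items()},
            "n_parameters": int(self.n_parameters_),
        }
        path.with_suffix(".json").write_text(json.dumps(fingerprint, indent=2))

    @classmethod
    def load(cls, path) -> "MVSIRClassifier":
        import json
        from pathlib import Path
        path = Path(path)
        fingerprint = json.loads(path.with_suffix(".json").read_text())
        est = cls(**fingerprint["params"])
        est.classes_ = np.array([0, 1])
        est.network_ = MVSIRNetwork(est._net_config(),
                                    seed=0 if est.random_state is None else est.random_state)
        with np.load(path.with_suffix(".npz")) as data:
            est.network_.load_state_arrays([data[f"p{i}"] for i in range(len(data.files))])
        est.n_parameters_ = est.network_.n_parameters()
        return est


def train(model: MVSIRClassifier | None, streams, tcfg: TrainConfig | None = None,
          **overrides) -> MVSIRClassifier:
    """Fit a classifier on a :class:`~mvsir.patches.PatchStreams` object."""
    tcfg = tcfg or TrainConfig()
    model = model or MVSIRClassifier()
    model.set_params(learning_rate=tcfg.learning_rate, weight_decay=tcfg.weight_decay,
                     decay_mode=tcfg.decay_mode, batch_size=tcfg.batch_size,
                     epochs=tcfg.epochs, validation_fraction=tcfg.validation_fraction,
                     random_state=tcfg.seed, **overrides)
    return model.fit(streams.as_array(), streams.labels)
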