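"""Supervised refinement network trained on pseudo-labels.

A compact fully-convolutional network distills the slow unsupervised pixel
labeler into a fast forward pass.  The architecture follows the three-stage
parallel-kernel design: each of three sequential subnetworks applies three
convolutional layers *in parallel* to its input (distinct receptive fields,
default 3/5/7), concatenates their feature maps along the channel axis and
applies a ReLU; a final 1x1 convolution with a logistic activation produces
one score per pixel.  Spatial dimensions are preserved throughout
(same-padding), so the network runs at any resolution.

Two training modes mirror the two uses of the output:

* ``boundary`` - mean absolute error against the binary pseudo-labels pushes
  every pixel toward exactly 0 or 1; thresholding at 0.5 then yields hard
  tumor boundaries.
* ``importance`` - binary cross-entropy leaves graded scores in (0, 1) that
  act as a per-pixel importance map (tumors darker/stronger than discs).

Everything - the convolutions, backpropagation and the RMSProp update - is
implemented on numpy (float32, BLAS matmuls).  The parallel branches of a
block are stored as one dense ``k_max x k_max`` kernel tensor under a fixed
structural mask that zeroes each branch outside its own support, so a block's
forward/backward pass is a single masked convolution.  Training with batch
size 1 (the default) performs one RMSProp update per image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class RefinerConfig:
    mode: str = "boundary"  # "boundary" (MAE) or "importance" (BCE)
    learning_rate: float = 1e-3
    batch_size: int = 1
    epochs: int = 10
    threshold: float = 0.5
    seed: int = 0
    input_height: int = 320
    input_width: int = 480
    channels_per_branch: int = 4
    kernel_sizes: tuple[int, int, int] = (3, 5, 7)
    patience: int = 3
    min_delta: float = 1e-4
    rho: float = 0.9  # RMSProp moving-average coefficient
    eps: float = 1e-7  # added inside the square root (Keras semantics)

    def __post_init__(self) -> None:
        if self.mode not in ("boundary", "importance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd (same-padding contract)")

    @property
    def loss_name(self) -> str:
        return "mae" if self.mode == "boundary" else "bce"


@dataclass(frozen=True)
class DatasetSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    eval_idx: np.ndarray


def split_dataset(n: int, seed: int) -> DatasetSplit:
    """Seeded shuffle, then 10% evaluation, 10% of the rest validation.

    With ``n = 3279`` this reproduces the 328-image evaluation pool and the
    81/9/10 percent train/val/eval proportions.
    """
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_eval = int(round(0.10 * n))
    n_val = int(round(0.10 * (n - n_eval)))
    return DatasetSplit(
        eval_idx=np.sort(order[:n_eval]),
        val_idx=np.sort(order[n_eval : n_eval + n_val]),
        train_idx=np.sort(order[n_eval + n_val :]),
    )


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------


def _branch_mask(kernel_sizes: tuple[int, ...], cpb: int, cin: int) -> np.ndarray:
    """Structural mask (cout, cin, kmax, kmax): branch b only sees its own
    centred ``k_b x k_b`` support."""
    kmax = max(kernel_sizes)
    cout = cpb * len(kernel_sizes)
    mask = np.zeros((cout, cin, kmax, kmax), dtype=np.float32)
    for b, k in enumerate(kernel_sizes):
        lo = (kmax - k) // 2
        mask[b * cpb : (b + 1) * cpb, :, lo : lo + k, lo : lo + k] = 1.0
    return mask


class _MaskedConv:
    """Same-padding convolution whose kernel tensor carries a structural mask.

    Weights live in a packed ``(cout, k*k*cin)`` layout so that, against the
    persistent shifted-input cache ``cols`` of shape ``(k*k*cin, H*W)``, the
    forward pass and the weight gradient are each a single BLAS gemm; only the
    input gradient walks the ``k*k`` shifts.  The canonical ``(cout, cin, k,
    k)`` tensor is exposed as the :attr:`W` property.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        kmax: int,
        mask: np.ndarray | None,
        rng: np.random.Generator,
    ):
        self.cin, self.cout, self.k = cin, cout, kmax
        self.mask = mask
        W = rng.normal(0.0, 1.0, size=(cout, cin, kmax, kmax)).astype(np.float32)
        if mask is not None:
            W *= mask
            fan = mask.sum(axis=(1, 2, 3), keepdims=True)
        else:
            fan = np.full((cout, 1, 1, 1), cin * kmax * kmax, dtype=np.float32)
        W *= np.sqrt(2.0 / fan).astype(np.float32)  # He init per actual fan-in
        self.Wb = self._pack(W)
        self.mask_b = self._pack(mask) if mask is not None else None
        self.b = np.zeros(cout, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None
        self._train_ready = False

    # packed layout: (cout, k, k, cin) flattened to (cout, k*k*cin), so the
    # row block for shift (dy, dx) is contiguous in cols
    def _pack(self, W: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(
            np.transpose(W, (0, 2, 3, 1)).reshape(self.cout, -1)
        )

    def _unpack(self, Wb: np.ndarray) -> np.ndarray:
        return np.transpose(
            Wb.reshape(self.cout, self.k, self.k, self.cin), (0, 3, 1, 2)
        )

    @property
    def W(self) -> np.ndarray:
        return self._unpack(self.Wb)

    @W.setter
    def W(self, value: np.ndarray) -> None:
        self.Wb = self._pack(np.asarray(value, dtype=np.float32))

    def n_params(self) -> int:
        active = int(self.mask.sum()) if self.mask is not None else self.Wb.size
        return active + self.b.size

    def _buffers(self, cin: int, H: int, W: int) -> np.ndarray:
        # persistent scratch: reallocating ~90 MB of shift slices per call
        # would otherwise dominate the iteration cost
        if self._shape != (cin, H, W):
            self._cols = np.empty((self.k * self.k * cin, H * W), dtype=np.float32)
            self._shape = (cin, H, W)
        return self._cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """x: (cin, H, W) -> (cout, H, W)."""
        cin, H, W = x.shape
        k, p = self.k, self.k // 2
        cols = self._buffers(cin, H, W)
        xpad = np.zeros((cin, H + 2 * p, W + 2 * p), dtype=np.float32)
        xpad[:, p : p + H, p : p + W] = x
        i = 0
        for dy in range(k):
            for dx in range(k):
                dst = cols[i * cin : (i + 1) * cin].reshape(cin, H, W)
                np.copyto(dst, xpad[:, dy : dy + H, dx : dx + W])
                i += 1
        y = self.Wb @ cols
        y += self.b[:, None]
        self._train_ready = train
        return y.reshape(self.cout, H, W)

    def backward(
        self, dy: np.ndarray, need_dx: bool
    ) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
        """dy: (cout, H, W) -> (dx, packed dW, db); uses the forward cache."""
        assert self._train_ready, "forward(train=True) must precede backward"
        cin, H, W = self._shape
        k, p = self.k, self.k // 2
        dyf = dy.reshape(self.cout, H * W)
        dWb = dyf @ self._cols.T
        if self.mask_b is not None:
            dWb *= self.mask_b
        db = dyf.sum(axis=1)
        dx = None
        if need_dx:
            dxpad = np.zeros((cin, H + 2 * p, W + 2 * p), dtype=np.float32)
            gtmp = np.empty((cin, H * W), dtype=np.float32)
            Wr = self.Wb.reshape(self.cout, k, k, cin)
            i = 0
            for ky in range(k):
                for kx in range(k):
                    np.matmul(
                        np.ascontiguousarray(Wr[:, ky, kx, :]).T, dyf, out=gtmp
                    )
                    dxpad[:, ky : ky + H, kx : kx + W] += gtmp.reshape(cin, H, W)
                    i += 1
            dx = dxpad[:, p : p + H, p : p + W]
        self._train_ready = False
        return dx, dWb, db


class RefinerNet:
    """Three parallel-kernel blocks plus a 1x1 logistic output head."""

    def __init__(self, cfg: RefinerConfig, input_channels: int = 1):
        self.cfg = cfg
        self.input_channels = input_channels
        rng = np.random.default_rng(cfg.seed)
        cpb = cfg.channels_per_branch
        kmax = max(cfg.kernel_sizes)
        cout = cpb * len(cfg.kernel_sizes)
        self.blocks: list[_MaskedConv] = []
        cin = input_channels
        for _ in range(3):
            mask = _branch_mask(cfg.kernel_sizes, cpb, cin)
            self.blocks.append(_MaskedConv(cin, cout, kmax, mask, rng))
            cin = cout
        self.head = _MaskedConv(cin, 1, 1, None, rng)
        n = self.parameter_count()
        if n >= 500_000:
            raise ValueError(f"parameter budget exceeded: {n}")
        logger.info("refiner built: %d trainable parameters", n)

    # -- inference ---------------------------------------------------------
    def parameter_count(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    @property
    def layers(self) -> list[_MaskedConv]:
        return [*self.blocks, self.head]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (cin, H, W) -> logistic scores (H, W) in (0, 1)."""
        self._relu_masks = []
        h = x.astype(np.float32)
        for block in self.blocks:
            h = block.forward(h, train)
            if train:
                self._relu_masks.append(h > 0)
            h = np.maximum(h, 0.0)
        z = self.head.forward(h, train)[0]
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dz: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """dz: gradient w.r.t. the pre-sigmoid logits; returns per-layer grads."""
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        dh, dW, db = self.head.backward(dz[None, :, :].astype(np.float32), need_dx=True)
        grads.append((dW, db))
        for i in reversed(range(len(self.blocks))):
            dh = dh * self._relu_masks[i]
            dh, dW, db = self.blocks[i].backward(dh, need_dx=(i > 0))
            grads.append((dW, db))
        return grads[::-1]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": asdict(self.cfg), "input_channels": self.input_channels}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RefinerNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = sidecar["config"]
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        net = cls(RefinerConfig(**cfg_dict), input_channels=sidecar["input_channels"])
        data = np.load(path.with_suffix(".npz"))
        for i, layer in enumerate(net.layers):
            layer.W = data[f"W{i}"]
            layer.b = data[f"b{i}"]
        return net


def build_refiner(cfg: RefinerConfig, input_channels: int = 1) -> RefinerNet:
    """Construct the (untrained) refinement network for the given config."""
    return RefinerNet(cfg, input_channels=input_channels)


# ---------------------------------------------------------------------------
# losses and training
# ---------------------------------------------------------------------------

_EPS = 1e-7


def _loss_and_dz(p: np.ndarray, y: np.ndarray, mode: str) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. the logits (sigmoid already applied)."""
    n = p.size
    if mode == "boundary":  # mean absolute error
        loss = float(np.abs(p - y).mean())
        dz = np.sign(p - y) * p * (1.0 - p) / n
    else:  # binary cross-entropy
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
        dz = (p - y) / n
    return loss, dz.astype(np.float32)


def _as_chw(image: np.ndarray) -> np.ndarray:
    """Channels-first float32 view, centered: [0,1] intensities map to
    [-0.5, 0.5] so first-layer features respond to contrast, not to the mean
    brightness shared by every fundus image."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {arr.shape}")
    return arr - np.float32(0.5)


def train_refiner(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    split: DatasetSplit,
    cfg: RefinerConfig,
) -> tuple[RefinerNet, list[dict]]:
    """Train on (image, pseudo-label) pairs with RMSProp at batch size 1.

    Returns the network (restored to its best-validation-loss weights) and a
    per-epoch history ``[{"epoch", "train_loss", "val_loss"}, ...]``.  Early
    stopping: training halts once the validation loss has not improved by at
    least ``cfg.min_delta`` for ``cfg.patience`` consecutive epochs.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks are not aligned")
    if len(split.train_idx) == 0:
        raise ValueError("empty training split")
    for m in masks:
        if not np.isin(np.asarray(m), (0, 1)).all():
            raise ValueError("training masks must be binary")

    xs = [_as_chw(img) for img in images]
    ys = [np.asarray(m, dtype=np.float32) for m in masks]
    net = build_refiner(cfg, input_channels=xs[0].shape[0])
    # prior initialization: start the output bias at the logit of the
    # training foreground rate so no epochs are spent learning the base rate
    fg = float(np.mean([ys[j].mean() for j in split.train_idx]))
    fg = min(max(fg, 1e-4), 1 - 1e-4)
    net.head.b[:] = np.log(fg / (1 - fg))
    sq_avg = [
        (np.zeros_like(layer.Wb), np.zeros_like(layer.b)) for layer in net.layers
    ]
    rng = np.random.default_rng(cfg.seed + 1)

    def apply_update(grads, scale):
        for i, layer in enumerate(net.layers):
            for g, param, avg_slot in (
                (grads[i][0] * scale, "Wb", 0),
                (grads[i][1] * scale, "b", 1),
            ):
                avg = sq_avg[i][avg_slot]
                avg *= cfg.rho
                avg += (1 - cfg.rho) * g * g
                # epsilon inside the sqrt: small-gradient updates stay
                # proportional instead of degenerating to +-lr sign steps
                step = cfg.learning_rate * g / np.sqrt(avg + cfg.eps)
                setattr(layer, param, getattr(layer, param) - step)

    def mean_loss(idx) -> float:
        total = 0.0
        for j in idx:
            p = net.forward(xs[j], train=False)
            loss, _ = _loss_and_dz(p, ys[j], cfg.mode)
            total += loss
        return total / max(len(idx), 1)

    history: list[dict] = []
    best_val = np.inf
    best_weights: list[tuple[np.ndarray, np.ndarray]] | None = None
    stall = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(split.train_idx)
        running = 0.0
        batch_grads = None
        in_batch = 0
        for j in order:
            p = net.forward(xs[j], train=True)
            loss, dz = _loss_and_dz(p, ys[j], cfg.mode)
            running += loss
            grads = net.backward(dz)
            if cfg.batch_size == 1:
                apply_update(grads, 1.0)
                continue
            if batch_grads is None:
                batch_grads = grads
            else:
                batch_grads = [
                    (bW + gW, bb + gb)
                    for (bW, bb), (gW, gb) in zip(batch_grads, grads)
                ]
            in_batch += 1
            if in_batch == cfg.batch_size:
                apply_update(batch_grads, 1.0 / in_batch)
                batch_grads, in_batch = None, 0
        if batch_grads is not None:
            apply_update(batch_grads, 1.0 / in_batch)
        train_loss = running / len(order)
        val_loss = mean_loss(split.val_idx) if len(split.val_idx) else train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info(
            "epoch %d: train %s=%.5f val=%.5f", epoch, cfg.loss_name, train_loss, val_loss
        )
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_weights = [(l.Wb.copy(), l.b.copy()) for l in net.layers]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                logger.info("early stopping after epoch %d", epoch)
                break
    if best_weights is not None:
        for layer, (Wb, bb) in zip(net.layers, best_weights):
            layer.Wb, layer.b = Wb, bb
    return net, history


def predict_soft(model: RefinerNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel scores in [0, 1] at the image's own resolution."""
    x = _as_chw(image)
    if x.shape[0] != model.input_channels:
        raise ValueError(
            f"model expects {model.input_channels} channel(s), got {x.shape[0]}"
        )
    return model.forward(x, train=False)


def predict_binary(model: RefinerNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Thresholded scores; values equal to the threshold map to 1."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (predict_soft(model, image) >= threshold).astype(np.uint8)


def simulate_disc_removal(
    pseudo_masks: list[np.ndarray],
    disc_masks: list[np.ndarray],
    margin: int = 0,
) -> list[np.ndarray]:
    """Erase known optic-disc pixels from pseudo-labels (``pseudo & ~disc``).

    Stands in for the expert's manual disc edits when the true disc supports
    are available (synthetic data).  ``margin`` dilates the disc mask by that
    many pixels first, mirroring how a human would wipe out the disc's blurred
    rim along with its core; returned masks stay binary uint8.
    """
    if len(pseudo_masks) != len(disc_masks):
        raise ValueError("mask lists are not aligned")
    out = []
    for p, d in zip(pseudo_masks, disc_masks):
        p = np.asarray(p)
        d = np.asarray(d).astype(bool)
        if p.shape != d.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {d.shape}")
        if margin > 0 and d.any():
            from scipy import ndimage

            d = ndimage.binary_dilation(d, iterations=margin)
        out.append((p.astype(bool) & ~d).astype(np.uint8))
    return out


def write_history_csv(history: list[dict], path: str | Path, loss_name: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", f"train_{loss_name}", f"val_{loss_name}"])
        for row in history:
            writer.writerow([row["epoch"], row["train_loss"], row["val_loss"]])
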