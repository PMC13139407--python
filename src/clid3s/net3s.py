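"""Hybrid supervised / self-supervised single-frame denoiser ("3Snet").

Training data come from ON/OFF switching acquisitions: averaging k ON
frames (k in {1, 2, 4, 8, 16}) produces images at five noise levels; at
each level two distinct averages form a noisy input/target pair (the
self-supervised, noise2noise-style signal), while the per-acquisition 3S
clear image is the supervised ground truth. The loss combines both:

    loss = ( ||x_hat - y||_2^2 + lambda ||x_hat - GT||_2^2 ) / (1 + lambda)

with lambda = 0 reducing to a purely self-supervised model and
lambda = inf (sentinel) to a purely supervised one. The lambda grid
{0, 1, 2, 4, 8, 16, inf} is scanned by test-set pSNR.

The network is a compact U-net-style convolutional encoder-decoder with a
global residual connection (the network predicts a correction to its
input), implemented directly in NumPy (im2col convolutions, manual
backpropagation, Adam). Inference is deterministic and fully
convolutional; large frames are processed in overlapping tiles with
linear blending.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from clid3s.denoise3s import ClearImage

# ---------------------------------------------------------------------------
# data organisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingSetSpec:
    """How one acquisition's ON stack becomes multi-noise-level image sets."""

    n_frames: int = 50
    k_levels: tuple[int, ...] = (1, 2, 4, 8, 16)
    selections_per_level: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        for k in self.k_levels:
            if k > self.n_frames:
                raise ValueError(f"averaging count k={k} exceeds n_frames={self.n_frames}")
            if self.selections_per_level > math.comb(self.n_frames, k):
                raise ValueError(
                    f"{self.selections_per_level} selections exceed C({self.n_frames},{k})"
                )


@dataclass(frozen=True)
class TrainingPair:
    """One self-supervised pair plus the supervised target."""

    x: np.ndarray
    y: np.ndarray
    gt: np.ndarray
    level: int

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape or self.x.shape != self.gt.shape:
            raise ValueError("x, y and gt must share one shape")


def build_noise_level_sets(
    on_stack: np.ndarray, spec: TrainingSetSpec
) -> dict[int, dict]:
    """For each k, ``selections_per_level`` means of distinct k-subsets.

    Returns {k: {"images": (S, H, W) array, "subsets": list of index
    tuples}}; the recorded subsets make every image reproducible.
    """
    on = np.asarray(on_stack, dtype=float)
    if on.ndim != 3 or on.shape[0] != spec.n_frames:
        raise ValueError(f"ON stack must have {spec.n_frames} frames")
    rng = np.random.default_rng(spec.seed)
    sets: dict[int, dict] = {}
    for k in spec.k_levels:
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < spec.selections_per_level:
            subset = tuple(sorted(rng.choice(spec.n_frames, size=k, replace=False).tolist()))
            chosen.add(subset)
        subsets = sorted(chosen)
        images = np.stack([on[list(s)].mean(axis=0) for s in subsets])
        sets[k] = {"images": images, "subsets": subsets}
    return sets


def sample_training_pair(
    sets: dict[int, dict],
    level: int,
    gt: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> TrainingPair:
    """Draw two distinct images of one noise level as (x, y)."""
    if level not in sets:
        raise ValueError(f"no noise level k={level}")
    images = sets[level]["images"]
    if images.shape[0] < 2:
        raise ValueError("need at least 2 images at a level to form a pair")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    i, j = rng.choice(images.shape[0], size=2, replace=False)
    return TrainingPair(images[i], images[j], np.asarray(gt, dtype=float), level)


def hybrid_loss(x_hat: np.ndarray, y: np.ndarray, gt: np.ndarray, lam: float) -> float:
    """Mean-squared hybrid loss; lam = inf evaluates the supervised term alone."""
    x_hat = np.asarray(x_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if x_hat.shape != y.shape or x_hat.shape != gt.shape:
        raise ValueError("shape mismatch")
    if lam < 0:
        raise ValueError("lambda must be >= 0 (or inf)")
    mse_self = float(np.mean((x_hat - y) ** 2))
    mse_sup = float(np.mean((x_hat - gt) ** 2))
    if np.isinf(lam):
        return mse_sup
    return (mse_self + lam * mse_sup) / (1.0 + lam)


# ---------------------------------------------------------------------------
# NumPy convolutional network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture knobs for the encoder-decoder."""

    base_channels: int = 12
    n_scales: int = 2  # encoder depth; each scale halves the resolution
    kernel: int = 3


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) with zero same-padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    B, C, H, W = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)


class _Conv:
    """3x3 (or 1x1) convolution, zero same-padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, scale: float = 1.0):
        std = scale * np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, std, (c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        self._col = _im2col(x, self.k)
        self._in_shape = x.shape
        Wmat = self.W.reshape(self.W.shape[0], -1).T  # (C*k*k, F)
        out = self._col @ Wmat + self.b
        return out.transpose(0, 2, 1).reshape(B, -1, H, Wd)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, F, H, Wd = dout.shape
        dflat = dout.reshape(B, F, H * Wd).transpose(0, 2, 1)  # (B, HW, F)
        d2 = np.ascontiguousarray(dflat).reshape(-1, F)
        c2 = self._col.reshape(-1, self._col.shape[-1])
        self.dW = (d2.T @ c2).reshape(self.W.shape)
        self.db = dflat.sum(axis=(0, 1))
        # dx = conv of dout with the transposed, 180deg-rotated kernels
        Wback = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, F, k, k)
        col = _im2col(dout, self.k)
        dx = col @ Wback.reshape(Wback.shape[0], -1).T
        return dx.transpose(0, 2, 1).reshape(self._in_shape)

    @property
    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    """Leaky rectifier (slope 0.1 below zero) — immune to dead units."""

    slope = 0.1

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


def _pool2(x):
    B, C, H, W = x.shape
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def _pool2_back(dout):
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_back(dout):
    B, C, H, W = dout.shape
    return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class UNet:
    """Residual encoder-decoder; predicts input + correction."""

    def __init__(self, spec: NetworkSpec, seed: int | None = None):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        k = spec.kernel
        self.enc = []  # per scale: (conv, relu, conv, relu)
        c_prev = 1
        for s in range(spec.n_scales):
            c_s = c * 2**s
            self.enc.append(
                (_Conv(c_prev, c_s, k, rng), _ReLU(), _Conv(c_s, c_s, k, rng), _ReLU())
            )
            c_prev = c_s
        c_b = c * 2**spec.n_scales
        self.bott = (_Conv(c_prev, c_b, k, rng), _ReLU(), _Conv(c_b, c_b, k, rng), _ReLU())
        self.dec = []  # per scale (finest last): (conv after concat, relu, conv, relu)
        c_up = c_b
        for s in reversed(range(spec.n_scales)):
            c_s = c * 2**s
            self.dec.append(
                (_Conv(c_up + c_s, c_s, k, rng), _ReLU(), _Conv(c_s, c_s, k, rng), _ReLU())
            )
            c_up = c_s
        self.final = _Conv(c, 1, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _convs(self):
        for block in (*self.enc, self.bott, *self.dec):
            yield block[0]
            yield block[2]
        yield self.final

    def get_params(self):
        return [p for conv in self._convs() for p in conv.params]

    def set_params(self, values):
        it = iter(values)
        for conv in self._convs():
            conv.W = next(it).reshape(conv.W.shape).copy()
            conv.b = next(it).reshape(conv.b.shape).copy()

    def get_grads(self):
        return [g for conv in self._convs() for g in conv.grads]

    # -- forward / backward ---------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, 1, H, W) with H, W divisible by 2**n_scales."""
        self._x_in = x
        skips = []
        h = x
        for conv1, r1, conv2, r2 in self.enc:
            h = r2.forward(conv2.forward(r1.forward(conv1.forward(h))))
            skips.append(h)
            h = _pool2(h)
        c1, r1, c2, r2 = self.bott
        h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        self._skip_channels = []
        for (conv1, r1, conv2, r2), skip in zip(self.dec, reversed(skips)):
            h = _up2(h)
            self._skip_channels.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h = r2.forward(conv2.forward(r1.forward(conv1.forward(h))))
        out = self.final.forward(h)
        return x + out

    def backward(self, dout: np.ndarray) -> None:
        dh = self.final.backward(dout)
        dskips = []
        for (conv1, r1, conv2, r2), (c_up, c_skip) in zip(
            reversed(self.dec), reversed(self._skip_channels)
        ):
            d = conv1.backward(r1.backward(conv2.backward(r2.backward(dh))))
            d_up, d_skip = d[:, :c_up], d[:, c_up:]
            dskips.append(d_skip)
            dh = _up2_back(d_up)
        c1, r1, c2, r2 = self.bott
        dh = c1.backward(r1.backward(c2.backward(r2.backward(dh))))
        for (conv1, r1, conv2, r2), d_skip in zip(reversed(self.enc), reversed(dskips)):
            dh = _pool2_back(dh) + d_skip
            dh = conv1.backward(r1.backward(conv2.backward(r2.backward(dh))))
        # gradient w.r.t. the residual input is dout + dh; not needed further


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# trained model container
# ---------------------------------------------------------------------------


@dataclass
class TrainedDenoiser:
    """Network weights plus the input/output normalization contract."""

    network: UNet
    normalization: dict = field(default_factory=lambda: {"scale": 255.0})
    training_record: dict = field(default_factory=dict)
    tile_size: int = 256
    tile_overlap: int = 32

    @property
    def min_input(self) -> int:
        return 2**self.network.spec.n_scales

    def _forward_whole(self, frame: np.ndarray) -> np.ndarray:
        mult = self.min_input
        H, W = frame.shape
        pad_h = (-H) % mult
        pad_w = (-W) % mult
        x = np.pad(frame, ((0, pad_h), (0, pad_w)), mode="reflect")
        out = self.network.forward(x[None, None].astype(np.float32))[0, 0]
        return out[:H, :W].astype(float)

    def denoise(self, frame: np.ndarray) -> np.ndarray:
        """Deterministic single-frame inference; nonnegative output."""
        frame = np.asarray(frame, dtype=float)
        if frame.ndim != 2:
            raise ValueError("frame must be 2-D")
        if min(frame.shape) < self.min_input:
            raise ValueError(
                f"frame smaller than the minimum tile ({self.min_input} px)"
            )
        scale = float(self.normalization.get("scale", 255.0))
        x = frame / scale
        T, ov = self.tile_size, self.tile_overlap
        H, W = x.shape
        if max(H, W) <= T:
            out = self._forward_whole(x)
        else:
            out = np.zeros_like(x)
            weight = np.zeros_like(x)
            step = T - ov
            ys = list(range(0, max(H - ov, 1), step))
            xs = list(range(0, max(W - ov, 1), step))
            for y0 in ys:
                for x0 in xs:
                    y1, x1 = min(y0 + T, H), min(x0 + T, W)
                    tile = self._forward_whole(x[y0:y1, x0:x1])
                    wy = _blend_profile(y1 - y0, y0 > 0, y1 < H, ov)
                    wx = _blend_profile(x1 - x0, x0 > 0, x1 < W, ov)
                    w = wy[:, None] * wx[None, :]
                    out[y0:y1, x0:x1] += tile * w
                    weight[y0:y1, x0:x1] += w
            out /= np.maximum(weight, 1e-12)
        return np.clip(out * scale, 0.0, None)

    __call__ = denoise

    def save(self, path: str) -> None:
        """Weights as .npz next to a JSON training record."""
        params = self.network.get_params()
        np.savez(
            path,
            *params,
            meta=json.dumps(
                {
                    "spec": {
                        "base_channels": self.network.spec.base_channels,
                        "n_scales": self.network.spec.n_scales,
                        "kernel": self.network.spec.kernel,
                    },
                    "normalization": self.normalization,
                    "training_record": _json_safe(self.training_record),
                }
            ),
        )

    @classmethod
    def load(cls, path: str) -> "TrainedDenoiser":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        spec = NetworkSpec(**meta["spec"])
        net = UNet(spec, seed=0)
        params = [data[f"arr_{i}"] for i in range(len(net.get_params()))]
        net.set_params(params)
        return cls(net, meta["normalization"], meta["training_record"])


def _blend_profile(n: int, fade_lo: bool, fade_hi: bool, ov: int) -> np.ndarray:
    w = np.ones(n)
    ramp = np.linspace(0.0, 1.0, min(ov, n), endpoint=False) + 0.5 / max(min(ov, n), 1)
    if fade_lo:
        w[: ramp.size] = ramp
    if fade_hi:
        w[-ramp.size :] = ramp[::-1]
    return w


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    return obj


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Acquisition:
    """One acquisition's noise-level sets plus its 3S clear ground truth."""

    sets: dict[int, dict]
    gt: np.ndarray


def make_acquisition(on_stack: np.ndarray, clear: ClearImage | np.ndarray, spec: TrainingSetSpec) -> Acquisition:
    gt = clear.pixels if isinstance(clear, ClearImage) else np.asarray(clear, dtype=float)
    return Acquisition(build_noise_level_sets(on_stack, spec), gt)


def train_denoiser(
    acquisitions: list[Acquisition],
    network_spec: NetworkSpec = NetworkSpec(),
    lam: float = 1.0,
    epochs: int = 10,
    seed: int | None = None,
    steps_per_epoch: int = 50,
    patch: int = 48,
    batch: int = 4,
    lr: float = 1e-3,
    scale: float = 255.0,
) -> TrainedDenoiser:
    """Minimize the hybrid loss over sampled pairs with Adam.

    Every training step draws ``batch`` (acquisition, noise level, pair,
    patch) samples; per-level pairs are mixed freely within a batch.
    ``epochs = 0`` returns the seeded initial network unchanged. Supervised
    weight lam > 0 requires ground truth, which every
    :class:`Acquisition` carries by construction.
    """
    if not acquisitions:
        raise ValueError("need at least one acquisition")
    if lam > 0 and any(a.gt is None for a in acquisitions):
        raise ValueError("supervised weight lambda > 0 requires ground-truth images")
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    rng = np.random.default_rng(seed)
    net = UNet(network_spec, seed=None if seed is None else seed + 1)
    model = TrainedDenoiser(
        net,
        {"scale": scale},
        {
            "lambda": lam,
            "epochs": epochs,
            "seed": seed,
            "steps_per_epoch": steps_per_epoch,
            "patch": patch,
            "batch": batch,
            "lr": lr,
            "loss_curve": [],
        },
    )
    if epochs == 0:
        return model
    opt = _Adam(net.get_params(), lr=lr)
    levels = sorted(acquisitions[0].sets.keys())
    curve = model.training_record["loss_curve"]
    warmup = max(2 * steps_per_epoch, 1)  # linear lr ramp stabilizes early steps
    step_count = 0
    for _epoch in range(epochs):
        epoch_loss = 0.0
        for _step in range(steps_per_epoch):
            step_count += 1
            opt.lr = lr * min(step_count / warmup, 1.0)
            xs, ys, gts = [], [], []
            for _ in range(batch):
                acq = acquisitions[rng.integers(len(acquisitions))]
                level = levels[rng.integers(len(levels))]
                pair = sample_training_pair(acq.sets, level, acq.gt, rng)
                H, W = pair.x.shape
                py = rng.integers(0, max(H - patch, 0) + 1)
                px = rng.integers(0, max(W - patch, 0) + 1)
                sl = (slice(py, py + patch), slice(px, px + patch))
                x_c, y_c, g_c = pair.x[sl], pair.y[sl], pair.gt[sl]
                if rng.random() < 0.5:  # horizontal flip augmentation
                    x_c, y_c, g_c = x_c[:, ::-1], y_c[:, ::-1], g_c[:, ::-1]
                xs.append(x_c)
                ys.append(y_c)
                gts.append(g_c)
            xb = (np.stack(xs)[:, None] / scale).astype(np.float32)
            yb = (np.stack(ys)[:, None] / scale).astype(np.float32)
            gb = (np.stack(gts)[:, None] / scale).astype(np.float32)
            out = net.forward(xb)
            n_el = out.size
            if np.isinf(lam):
                loss = float(np.mean((out - gb) ** 2))
                dout = 2.0 * (out - gb) / n_el
            else:
                loss = (
                    float(np.mean((out - yb) ** 2)) + lam * float(np.mean((out - gb) ** 2))
                ) / (1.0 + lam)
                dout = (2.0 * (out - yb) + lam * 2.0 * (out - gb)) / ((1.0 + lam) * n_el)
            net.backward(dout)
            opt.step(net.get_params(), net.get_grads())
            epoch_loss += loss
        curve.append(epoch_loss / steps_per_epoch)
    return model


def select_lambda(
    candidates: list[float],
    train_acquisitions: list[Acquisition],
    test_frames: list[tuple[np.ndarray, np.ndarray]],
    network_spec: NetworkSpec = NetworkSpec(),
    seed: int | None = None,
    peak: float = 255.0,
    evaluator=None,
    **train_kwargs,
) -> tuple[float, dict[float, float], TrainedDenoiser]:
    """Train one model per lambda candidate; pick the best test pSNR.

    ``test_frames`` is a list of (noisy frame, reference) pairs held out
    from training. Every candidate trains under identical seeds. The
    score is the mean test pSNR of the denoised frames (``evaluator``
    overrides the scoring: a callable (model, test_frames) -> float).
    Ties (to 1e-9 dB) go to the smallest lambda. Returns (lambda*, pSNR
    table, winning model).
    """
    from clid3s.metrics import psnr

    if not candidates:
        raise ValueError("empty candidate list")
    if evaluator is None:
        def evaluator(model, frames):
            return float(
                np.mean([psnr(model.denoise(noisy), ref, peak) for noisy, ref in frames])
            )

    table: dict[float, float] = {}
    models: dict[float, TrainedDenoiser] = {}
    for lam in candidates:
        model = train_denoiser(
            train_acquisitions, network_spec, lam=lam, seed=seed, **train_kwargs
        )
        table[lam] = float(evaluator(model, test_frames))
        models[lam] = model
    best = max(sorted(table), key=lambda l: (table[l], -l))
    # explicit smallest-lambda tie-break
    for lam in sorted(table):
        if abs(table[lam] - table[best]) < 1e-9:
            best = lam
            break
    return best, table, models[best]


def denoise_frame(model: TrainedDenoiser, frame: np.ndarray, pixel_nm: float = 65.0) -> ClearImage:
    """Single-frame inference wrapped as a :class:`ClearImage`."""
    out = model.denoise(frame)
    return ClearImage(
        out,
        pixel_nm,
        {"reducer": "3Snet", "lambda": model.training_record.get("lambda")},
    )
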