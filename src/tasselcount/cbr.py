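"""Counting tassels by local-count regression on density maps.

The counting-by-regression (CBR) approach never detects individual tassels.
Instead, each annotated tassel center contributes a unit-mass bivariate
Gaussian to a density map whose integral equals the image's count. The
image is decomposed into overlapping fixed-size sub-images (default 32×32,
stride 8); each sub-image's regression target is the density mass inside
its footprint; a small convolutional network is trained with an L1 loss to
predict that local count. At prediction time a sliding window scans the
image, each window's predicted count is redistributed uniformly over its
pixels, the per-pixel values are normalized by the number of windows that
visited each pixel, and the normalized map is summed to yield the image
count (it also serves as a localization heatmap).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core_io import PointAnnotation, RgbImage
from .errors import ValidationError
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Flatten,
    Linear,
    MaxPool2,
    ReLU,
    Sequential,
)

__all__ = [
    "DensityMap",
    "TrainingPatch",
    "CounterConfig",
    "CounterModel",
    "RedistributionAccumulator",
    "build_density_map",
    "extract_patches",
    "train_counter",
    "predict_count",
    "bootstrap_mae",
    "save_model",
    "load_model",
]


@dataclasses.dataclass
class DensityMap:
    """Gaussian-smoothed tassel density; total mass equals the point count."""

    values: np.ndarray
    bandwidth: float
    source_points: int


@dataclasses.dataclass
class TrainingPatch:
    """A 32×32×3 sub-image (values scaled to [0, 1]) and its local count target."""

    patch: np.ndarray
    target: float


@dataclasses.dataclass
class CounterConfig:
    """Hyperparameters of the CBR pipeline.

    Defaults follow the reference setting: 32×32 sub-images with stride 8,
    Gaussian bandwidth (σ) of 8 pixels, learning rate 1e-4, 50 epochs with
    early-stopping patience 5. ``widths`` are the four conv-block channel
    counts; they are free parameters of the architecture.
    """

    patch_size: int = 32
    stride: int = 8
    bandwidth: float = 8.0
    learning_rate: float = 1e-4
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 256
    validation_fraction: float = 0.1
    seed: int = 0
    widths: tuple[int, int, int, int] = (16, 32, 64, 128)
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if not self.patch_size >= self.stride >= 1:
            raise ValidationError("need patch_size >= stride >= 1")
        if self.patch_size % 8 != 0:
            raise ValidationError("patch_size must be divisible by 8 (three 2×2 pools)")
        if self.bandwidth <= 0:
            raise ValidationError("bandwidth must be > 0")
        if not 0 < self.validation_fraction < 1:
            raise ValidationError("validation_fraction must be in (0, 1)")


@dataclasses.dataclass
class RedistributionAccumulator:
    """Per-pixel redistributed count sum C(x,y) and visit counts P(x,y)."""

    count_sum: np.ndarray
    visit_count: np.ndarray


def build_density_map(
    pts: PointAnnotation, shape: tuple[int, int], bandwidth: float
) -> DensityMap:
    """Place a unit-mass Gaussian (σ = ``bandwidth``) at each annotated point.

    Kernels are evaluated on the integer pixel grid, truncated at ±4σ and at
    the image borders, then renormalized per point, so the total mass equals
    the number of points exactly (to float round-off).
    """
    h, w = shape
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    pts.validate_bounds(shape)
    dm = np.zeros((h, w), dtype=np.float64)
    radius = int(np.ceil(4.0 * bandwidth))
    for r, c in pts.points:
        r0, r1 = max(0, int(np.floor(r)) - radius), min(h, int(np.ceil(r)) + radius + 1)
        c0, c1 = max(0, int(np.floor(c)) - radius), min(w, int(np.ceil(c)) + radius + 1)
        rows = np.arange(r0, r1, dtype=np.float64)
        cols = np.arange(c0, c1, dtype=np.float64)
        kern = np.exp(
            -((rows[:, None] - r) ** 2 + (cols[None, :] - c) ** 2)
            / (2.0 * bandwidth**2)
        )
        dm[r0:r1, c0:c1] += kern / kern.sum()
    return DensityMap(dm, float(bandwidth), len(pts.points))


def _window_offsets(h: int, w: int, ps: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.arange(0, h - ps + 1, stride),
        np.arange(0, w - ps + 1, stride),
    )


def extract_patches(
    img: RgbImage, dm: DensityMap, cfg: CounterConfig
) -> list[TrainingPatch]:
    """Decompose an image into overlapping sub-images with local count targets.

    Windows sit at offsets ``(a·stride, b·stride)`` with the full window
    inside the image; each target is the density mass under the window.
    """
    h, w = img.shape
    if dm.values.shape != (h, w):
        raise ValidationError("image and density map shapes differ")
    ps, stride = cfg.patch_size, cfg.stride
    if h < ps or w < ps:
        raise ValidationError(f"image {h}×{w} smaller than patch size {ps}")
    # integral image makes each window's density sum an O(1) lookup
    integ = np.zeros((h + 1, w + 1), dtype=np.float64)
    integ[1:, 1:] = dm.values.cumsum(axis=0).cumsum(axis=1)
    scaled = img.pixels.astype(np.float32) / 255.0
    out = []
    row_offs, col_offs = _window_offsets(h, w, ps, stride)
    for r in row_offs:
        for c in col_offs:
            target = (
                integ[r + ps, c + ps]
                - integ[r, c + ps]
                - integ[r + ps, c]
                + integ[r, c]
            )
            out.append(TrainingPatch(scaled[r : r + ps, c : c + ps], float(target)))
    return out


def _build_network(cfg: CounterConfig, rng: np.random.Generator) -> Sequential:
    w1, w2, w3, w4 = cfg.widths
    layers = [
        Conv2d(3, w1, rng), BatchNorm2d(w1), ReLU(), MaxPool2(),
        Conv2d(w1, w2, rng), BatchNorm2d(w2), ReLU(), MaxPool2(),
        Conv2d(w2, w3, rng), BatchNorm2d(w3), ReLU(), MaxPool2(),
        Conv2d(w3, w4, rng), BatchNorm2d(w4), ReLU(),
        Dropout(cfg.dropout), Flatten(),
        Linear((cfg.patch_size // 8) ** 2 * w4, 1, rng),
    ]
    return Sequential(layers)


class CounterModel:
    """A trained patch-count regressor: maps a 32×32×3 patch to a scalar count.

    Predictions are clamped at 0 from below (counts are non-negative).
    ``training_log`` records per-epoch training and validation L1 loss.
    """

    def __init__(self, net: Sequential, cfg: CounterConfig):
        self.net = net
        self.cfg = cfg
        self.training_log: list[dict[str, float]] = []

    def predict_patches(self, x: np.ndarray) -> np.ndarray:
        """Predict counts for a batch of patches, shape (N, ps, ps, 3) in [0, 1]."""
        x = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32)
        preds = []
        for i in range(0, x.shape[0], 1024):
            out = self.net.forward(x[i : i + 1024], train=False)
            preds.append(out[:, 0])
        return np.clip(np.concatenate(preds), 0.0, None)


def _l1(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.abs(pred - target).mean())


def train_counter(train_patches: list[TrainingPatch], cfg: CounterConfig) -> CounterModel:
    """Train the regressor by minimizing mean absolute error on patch targets.

    A random ``validation_fraction`` of the patches is held out; training
    stops after ``patience`` epochs without validation improvement or at
    ``max_epochs``, and the parameters from the best validation epoch are
    returned.
    """
    if len(train_patches) < 2:
        raise ValidationError("need at least 2 training patches")
    rng = np.random.default_rng(cfg.seed)
    x = np.stack([p.patch for p in train_patches]).transpose(0, 3, 1, 2)
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.array([p.target for p in train_patches], dtype=np.float32)

    order = rng.permutation(len(y))
    n_val = max(1, int(round(cfg.validation_fraction * len(y))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValidationError("validation split leaves no training patches")
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    net = _build_network(cfg, rng)
    opt = Adam(net, lr=cfg.learning_rate)
    model = CounterModel(net, cfg)

    best_val = np.inf
    best_state = net.get_state()
    stall = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(yt))
        tr_losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            xb, yb = xt[idx], yt[idx]
            pred = net.forward(xb, train=True, rng=rng)[:, 0]
            tr_losses.append(_l1(pred, yb))
            dpred = np.sign(pred - yb).astype(np.float32) / len(yb)
            net.backward(dpred[:, None])
            opt.step()
        val_pred = np.concatenate(
            [
                net.forward(xv[i : i + 1024], train=False)[:, 0]
                for i in range(0, len(yv), 1024)
            ]
        )
        val_loss = _l1(val_pred, yv)
        model.training_log.append(
            {"epoch": epoch, "train_l1": float(np.mean(tr_losses)), "val_l1": val_loss}
        )
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = net.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    net.set_state(best_state)
    return model


def predict_count(
    model, img: RgbImage, cfg: CounterConfig
) -> tuple[float, np.ndarray, RedistributionAccumulator]:
    """Sliding-window prediction with uniform count redistribution.

    Each window's predicted count T̂j is spread uniformly over its footprint
    (T̂j / patch_size² per pixel) into ``count_sum`` while ``visit_count``
    tracks how often each pixel was covered. The image count is
    Σ count_sum/visit_count over visited pixels; the same normalized map is
    returned as a localization heatmap. ``model`` may be any object with a
    ``predict_patches`` method (a trained :class:`CounterModel` or a stub).
    """
    h, w = img.shape
    ps, stride = cfg.patch_size, cfg.stride
    if h < ps or w < ps:
        raise ValidationError(f"image {h}×{w} smaller than patch size {ps}")
    scaled = img.pixels.astype(np.float32) / 255.0
    row_offs, col_offs = _window_offsets(h, w, ps, stride)
    offsets = [(r, c) for r in row_offs for c in col_offs]
    batch = np.stack([scaled[r : r + ps, c : c + ps] for r, c in offsets])
    preds = np.clip(np.asarray(model.predict_patches(batch), dtype=np.float64), 0.0, None)

    count_sum = np.zeros((h, w), dtype=np.float64)
    visit = np.zeros((h, w), dtype=np.int64)
    area = float(ps * ps)
    for (r, c), p in zip(offsets, preds):
        count_sum[r : r + ps, c : c + ps] += p / area
        visit[r : r + ps, c : c + ps] += 1
    heatmap = np.divide(count_sum, visit, out=np.zeros_like(count_sum), where=visit > 0)
    count = float(heatmap.sum())
    return count, heatmap, RedistributionAccumulator(count_sum, visit)


def bootstrap_mae(
    train_patches: list[TrainingPatch],
    test_images: list[RgbImage],
    test_truth: list[int],
    cfg: CounterConfig,
    n_replicates: int = 100,
    replicate_size: int | None = None,
    resample: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap the test-set MAE over resampled training sets.

    Per replicate: draw ``replicate_size`` patches with replacement, train a
    fresh model, and score its MAE on the fixed holdout test set. Returns
    the mean MAE and the (2.5th, 97.5th) percentile interval. With
    ``resample=False`` every replicate trains on the identical full set
    with the identical seed (a degenerate mode whose interval has width 0).
    Fully determined by ``cfg.seed``.
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    if len(test_images) != len(test_truth):
        raise ValidationError("test_images and test_truth lengths differ")
    if replicate_size is None:
        replicate_size = len(train_patches)
    rng = np.random.default_rng([cfg.seed, 0xB007])
    maes = []
    for rep in range(n_replicates):
        if resample:
            idx = rng.integers(0, len(train_patches), size=replicate_size)
            subset = [train_patches[i] for i in idx]
            rep_seed = int(rng.integers(0, 2**31 - 1))
        else:
            subset = list(train_patches)
            rep_seed = cfg.seed
        rep_cfg = dataclasses.replace(cfg, seed=rep_seed)
        model = train_counter(subset, rep_cfg)
        errs = [
            abs(predict_count(model, img, cfg)[0] - truth)
            for img, truth in zip(test_images, test_truth)
        ]
        maes.append(float(np.mean(errs)))
    maes_arr = np.array(maes)
    lo, hi = np.percentile(maes_arr, [2.5, 97.5])
    return float(maes_arr.mean()), (float(lo), float(hi))


def save_model(model: CounterModel, path: str | Path) -> None:
    """Persist a model as a directory: JSON manifest + parameter arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(model.cfg),
        "training_log": model.training_log,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    state = model.net.get_state()
    np.savez(path / "params.npz", **{f"p{i}": a for i, a in enumerate(state)})


def load_model(path: str | Path) -> CounterModel:
    """Reload a persisted model bit-exactly."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg_d = manifest["config"]
    cfg_d["widths"] = tuple(cfg_d["widths"])
    cfg = CounterConfig(**cfg_d)
    net = _build_network(cfg, np.random.default_rng(cfg.seed))
    with np.load(path / "params.npz") as z:
        state = [z[f"p{i}"] for i in range(len(z.files))]
    net.set_state(state)
    model = CounterModel(net, cfg)
    model.training_log = manifest["training_log"]
    return model
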