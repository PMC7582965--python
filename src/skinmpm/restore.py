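"""Paired low/high-SNR image restoration.

The restoration protocol follows content-aware image restoration practice:
pairs of pixel-registered images are acquired (here: simulated) at low SNR
(7 or 15 accumulated frames) and high SNR (70 accumulated frames); patches
cut from the pairs train a small convolutional regressor that maps the noisy
input toward the high-SNR target; the trained model is applied to full images
by tiled inference.  Quality is tracked as MSE/MAE on percentile-normalized
intensities and as the structural similarity index (SSIM) against the
high-SNR ground truth.

Both input SNR levels are pooled into one model.  The ground truth is itself
a (70-accumulation) noisy acquisition rather than a noise-free field, so SSIM
against it saturates below 1 even for a perfect denoiser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from ._nn import Adam, UNet, mse_loss

__all__ = [
    "RestorationConfig",
    "RestorationMetrics",
    "Restorer",
    "extract_patches",
    "split_train_val",
    "normalize",
    "denormalize",
    "train_restorer",
    "restore_image",
    "evaluate",
    "ssim_pair",
]


@dataclass(frozen=True)
class RestorationConfig:
    """Training protocol parameters.

    The instrument-scale protocol uses 128-px patches (64 per 1024x1024
    image; 550 image pairs -> 35,200 patches, 10% validation), 100 epochs of
    30 steps.  The defaults here express that protocol; reduced-scale runs
    override ``patch_px``, ``epochs`` and the data volume, not the logic.
    """

    patch_px: int = 128
    input_accums: tuple[int, ...] = (7, 15)
    gt_accum: int = 70
    val_fraction: float = 0.10
    epochs: int = 100
    steps_per_epoch: int = 30
    batch_size: int = 16
    learning_rate: float = 3e-3
    norm_percentiles: tuple[float, float] = (0.1, 99.9)
    base_features: int = 16
    n_scales: int = 3
    input_transform: str = "sqrt"  # variance stabilization for Poisson inputs
    augment: bool = True           # D4 (flip/rotate) patch augmentation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_px not in (64, 128, 256):
            raise ValueError(
                f"patch_px must be one of 64/128/256 (patch-size study range), "
                f"got {self.patch_px}"
            )
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.input_transform not in ("sqrt", "linear"):
            raise ValueError("input_transform must be 'sqrt' or 'linear'")

    def transform_input(self, counts: np.ndarray) -> np.ndarray:
        """Apply the configured variance-stabilizing transform to raw counts
        (before percentile normalization).  Targets are never transformed."""
        if self.input_transform == "sqrt":
            return np.sqrt(np.clip(counts, 0.0, None))
        return np.asarray(counts, dtype=np.float64)


@dataclass(frozen=True)
class RestorationMetrics:
    """Mean +/- sd of each quality metric over an evaluation set."""

    mse: tuple[float, float]
    mae: tuple[float, float]
    ssim: tuple[float, float]

    def __post_init__(self) -> None:
        if self.mse[0] < 0 or self.mae[0] < 0:
            raise ValueError("mse/mae must be nonnegative")
        if not (-1.0 <= self.ssim[0] <= 1.0):
            raise ValueError("ssim must lie in [-1, 1]")


def extract_patches(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    patch_px: int,
    stride: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut registered patch pairs on a regular grid.

    Input and ground-truth patches are taken at identical coordinates, so
    registration survives.  With stride == patch size a 1024x1024 image yields
    an 8x8 grid of 64 patches.  The grid is deterministic; ``seed`` only
    shuffles the output order.
    """
    stride = stride or patch_px
    xs, ys = [], []
    for inp, gt in pairs:
        if inp.shape != gt.shape:
            raise ValueError("input/ground-truth shapes differ")
        h, w = inp.shape
        if h < patch_px or w < patch_px:
            raise ValueError(
                f"image {inp.shape} smaller than patch size {patch_px}"
            )
        for y in range(0, h - patch_px + 1, stride):
            for x in range(0, w - patch_px + 1, stride):
                xs.append(inp[y: y + patch_px, x: x + patch_px])
                ys.append(gt[y: y + patch_px, x: x + patch_px])
    xs_a, ys_a = np.stack(xs), np.stack(ys)
    order = np.random.default_rng(seed).permutation(len(xs_a))
    return xs_a[order], ys_a[order]


def split_train_val(
    patches: tuple[np.ndarray, np.ndarray] | np.ndarray,
    val_fraction: float = 0.10,
    seed: int = 0,
):
    """Seeded random partition; validation gets floor(val_fraction * N).

    35,200 patches at 10% split into 3,520 validation / 31,680 training.
    Accepts either a single array or an (inputs, targets) pair.
    """
    paired = isinstance(patches, tuple)
    n = len(patches[0]) if paired else len(patches)
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    n_val = int(np.floor(val_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if paired:
        tr = tuple(a[train_idx] for a in patches)
        va = tuple(a[val_idx] for a in patches)
        return tr, va
    return patches[train_idx], patches[val_idx]


def normalize(
    image: np.ndarray, p_low: float = 0.1, p_high: float = 99.9
) -> tuple[np.ndarray, tuple[float, float]]:
    """Percentile-affine normalization: p_low -> 0, p_high -> 1.

    Returns the normalized image and ``(offset, scale)`` such that
    ``image = normalized * scale + offset``.  A constant image cannot be
    scaled meaningfully; it triggers a warning and an identity transform.
    """
    lo, hi = np.percentile(image, [p_low, p_high])
    if hi <= lo:
        warnings.warn("constant image: returning identity normalization")
        return np.asarray(image, dtype=np.float64), (0.0, 1.0)
    return (image - lo) / (hi - lo), (float(lo), float(hi - lo))


def denormalize(image: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    offset, scale = params
    return image * scale + offset


@dataclass
class Restorer:
    """A trained restoration model plus the protocol it was trained under."""

    net: UNet
    config: RestorationConfig
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        from dataclasses import asdict
        import json

        state = self.net.state_dict()
        np.savez(
            path,
            **{k: v for k, v in state.items() if isinstance(v, np.ndarray)},
            base=state["base"],
            levels=state["levels"],
            seed=state["seed"],
            config=json.dumps(asdict(self.config)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Restorer":
        import json

        with np.load(path, allow_pickle=False) as z:
            state = {k: z[k] for k in z.files if k != "config"}
            cfg_dict = json.loads(str(z["config"]))
        for key in ("input_accums", "norm_percentiles"):
            cfg_dict[key] = tuple(cfg_dict[key])
        return cls(net=UNet.from_state(state), config=RestorationConfig(**cfg_dict))


def train_restorer(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: RestorationConfig | None = None,
) -> Restorer:
    """Train the encoder-decoder regressor on normalized patch pairs.

    ``train``/``val`` are (inputs, targets) stacks of patches already on the
    normalized intensity scale.  Optimization is Adam on the mean-square
    error, ``epochs x steps_per_epoch`` minibatches, deterministic for a
    fixed config seed.  Per-epoch validation MSE/MAE are recorded in the
    returned model's history; a NaN validation loss aborts with an error.
    """
    config = config or RestorationConfig()
    xt, yt = train
    xv, yv = val
    if len(xt) == 0 or len(xv) == 0:
        raise ValueError("training and validation sets must be nonempty")
    net = UNet(base=config.base_features, levels=config.n_scales, seed=config.seed)
    opt = Adam(net, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n_val_eval = min(len(xv), 64)
    decay_at = max(int(config.epochs * 2 / 3), 1)
    history: list[dict] = []
    for epoch in range(config.epochs):
        if epoch == decay_at:
            opt.lr = config.learning_rate / 3.0
        for _ in range(config.steps_per_epoch):
            idx = rng.integers(0, len(xt), size=min(config.batch_size, len(xt)))
            xb = xt[idx][:, None]
            yb = yt[idx][:, None]
            if config.augment:
                # per-sample D4 symmetry, applied identically to both arms
                ks = rng.integers(0, 4, size=len(idx))
                flips = rng.random(len(idx)) < 0.5
                xb, yb = xb.copy(), yb.copy()
                for s, (k, fl) in enumerate(zip(ks, flips)):
                    if k:
                        xb[s, 0] = np.rot90(xb[s, 0], k)
                        yb[s, 0] = np.rot90(yb[s, 0], k)
                    if fl:
                        xb[s, 0] = xb[s, 0][::-1]
                        yb[s, 0] = yb[s, 0][::-1]
            pred = net.forward(xb, train=True)
            _, grad = mse_loss(pred, yb)
            net.backward(grad)
            opt.step()
        pv = _predict_batched(net, xv[:n_val_eval])
        diff = pv - yv[:n_val_eval]
        val_mse = float(np.mean(diff**2))
        val_mae = float(np.mean(np.abs(diff)))
        if not np.isfinite(val_mse):
            raise RuntimeError(f"training diverged at epoch {epoch}: val MSE NaN")
        history.append({"epoch": epoch, "val_mse": val_mse, "val_mae": val_mae})
    return Restorer(net=net, config=config, history=history)


def _predict_batched(net: UNet, x: np.ndarray, batch: int = 16) -> np.ndarray:
    outs = [net.predict(x[i: i + batch][:, None]) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)[:, 0]


def restore_image(
    model: Restorer,
    image: np.ndarray,
    tile_px: int = 128,
    tile_overlap_px: int = 16,
    normalized: bool = False,
    tta: bool = False,
) -> np.ndarray:
    """Apply a trained restorer to an image of any size by tiled inference.

    The image is normalized by its own percentiles (unless ``normalized``),
    covered with overlapping tiles, each tile restored, and the tiles blended
    with linear feather weights that sum to one at every pixel; the result is
    mapped back to the input intensity scale.  Output shape equals input
    shape.  With ``tta`` the prediction is averaged over the eight
    flip/rotation symmetries, matching the augmentation used in training.
    """
    if model.net is None:
        raise ValueError("untrained model")
    img = np.asarray(image, dtype=np.float64)
    params = (0.0, 1.0)
    if not normalized:
        img, params = normalize(img, *model.config.norm_percentiles)
    if tta:
        acc = np.zeros_like(img)
        for k in range(4):
            for flip in (False, True):
                t = np.rot90(img, k)
                t = t[::-1] if flip else t
                r = restore_image(model, t, tile_px, tile_overlap_px,
                                  normalized=True)
                r = r[::-1] if flip else r
                acc += np.rot90(r, -k)
        out = acc / 8.0
        return denormalize(out, params) if not normalized else out
    h, w = img.shape
    t = min(tile_px, max(h, 2), max(w, 2))
    t = max(t - t % 2, 2)
    ov = min(tile_overlap_px, t // 2)
    ov -= ov % 2
    step = t - ov
    acc = np.zeros((h, w))
    wacc = np.zeros((h, w))

    def ramp(n, ov_lo, ov_hi):
        wgt = np.ones(n)
        if ov_lo:
            wgt[:ov_lo] = np.linspace(0, 1, ov_lo + 2)[1:-1]
        if ov_hi:
            wgt[-ov_hi:] = np.linspace(1, 0, ov_hi + 2)[1:-1]
        return wgt

    ys = list(range(0, max(h - t, 0) + 1, step))
    if ys[-1] + t < h:
        ys.append(h - t)
    xs = list(range(0, max(w - t, 0) + 1, step))
    if xs[-1] + t < w:
        xs.append(w - t)
    for y0 in ys:
        for x0 in xs:
            tile = img[y0: y0 + t, x0: x0 + t]
            th, tw = tile.shape
            pe_h, pe_w = th + th % 2, tw + tw % 2
            padded = np.pad(tile, ((0, pe_h - th), (0, pe_w - tw)), mode="edge")
            pred = model.net.predict(padded[None, None])[0, 0][:th, :tw]
            wy = ramp(th, ov if y0 > 0 else 0, ov if y0 + t < h else 0)
            wx = ramp(tw, ov if x0 > 0 else 0, ov if x0 + t < w else 0)
            w2 = wy[:, None] * wx[None, :]
            acc[y0: y0 + th, x0: x0 + tw] += pred * w2
            wacc[y0: y0 + th, x0: x0 + tw] += w2
    out = acc / np.where(wacc > 0, wacc, 1.0)
    return denormalize(out, params) if not normalized else out


def ssim_pair(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """SSIM with 7-px Gaussian-weighted windows (sigma 1.5).

    ``data_range`` defaults to the range of ``b`` (conventionally the ground
    truth).  Symmetric in its arguments when data_range is given.
    """
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(b.max() - b.min()) or 1.0
    return float(
        structural_similarity(
            a, b, win_size=7, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=data_range,
        )
    )


def _metrics(preds, gns, data_range, p_lo, p_hi, prenormalized) -> RestorationMetrics:
    mses, maes, ssims = [], [], []
    for p, gn in zip(preds, gns):
        pn = p if prenormalized else normalize(p, p_lo, p_hi)[0]
        diff = pn - gn
        mses.append(np.mean(diff**2))
        maes.append(np.mean(np.abs(diff)))
        ssims.append(ssim_pair(pn, gn, data_range=data_range))
    return RestorationMetrics(
        mse=(float(np.mean(mses)), float(np.std(mses))),
        mae=(float(np.mean(maes)), float(np.std(maes))),
        ssim=(float(np.mean(ssims)), float(np.std(ssims))),
    )


def evaluate(
    restored: list[np.ndarray],
    inputs: list[np.ndarray],
    gts: list[np.ndarray],
    norm_percentiles: tuple[float, float] = (0.1, 99.9),
    restored_normalized: bool = False,
) -> dict[str, RestorationMetrics]:
    """Score both arms (restored-vs-GT and raw-input-vs-GT) of a test set.

    Ground-truth and input images are each mapped to the normalized scale by
    their own percentiles (which puts the differently-scaled accumulation
    levels on one intensity scale); the SSIM data range is the pooled range
    of the normalized ground-truth set.  With ``restored_normalized`` the
    restored images are taken as already being on the target-normalized
    scale (the space the regressor predicts in), avoiding the bias of
    re-estimating percentile anchors from a denoised image.
    """
    if not (len(restored) == len(inputs) == len(gts)):
        raise ValueError("restored/inputs/gts must have equal lengths")
    for r, i, g in zip(restored, inputs, gts):
        if r.shape != g.shape or i.shape != g.shape:
            raise ValueError("evaluation triplets must be pixel-registered")
    p_lo, p_hi = norm_percentiles
    gns = [normalize(g, p_lo, p_hi)[0] for g in gts]
    data_range = float(
        max(g.max() for g in gns) - min(g.min() for g in gns)
    ) or 1.0
    return {
        "restored": _metrics(restored, gns, data_range, p_lo, p_hi,
                             restored_normalized),
        "input": _metrics(inputs, gns, data_range, p_lo, p_hi, False),
    }
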