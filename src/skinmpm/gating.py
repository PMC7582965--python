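"""Virtual-channel gating, corrected-red melanin discrimination, and 3-D
virtual staining.

Melanin's fluorescence lifetime is markedly shorter than the other endogenous
skin fluorophores, so photons gated into an early ("red") arrival window are
melanin-enriched while a late ("green") window collects long-lifetime signal.
The two windows deliberately share a bin; subtracting the green counts from
the red counts and zero-clipping the negatives (the *corrected red* channel)
yields a differential melanin signature.  Thresholding corrected red through
a z-stack produces a 3-D virtual melanin stain, scored here against phantom
ground truth by Dice overlap and ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .photonsim import TimeBinnedFrame
from .timetag import GateWindows, window_to_bins

__all__ = [
    "ChannelImage",
    "integrate_channels",
    "corrected_red",
    "compose_color",
    "melanin_stain_3d",
    "melanin_recovery_score",
]


@dataclass
class ChannelImage:
    """Gated channel images from one time-binned frame."""

    red: np.ndarray
    green: np.ndarray
    corrected_red: np.ndarray
    windows: GateWindows
    shg: np.ndarray | None = None
    source: dict | None = None

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape or self.red.shape != self.corrected_red.shape:
            raise ValueError("channel grids must share one shape")
        if np.any(self.corrected_red < 0) or np.any(self.corrected_red > self.red):
            raise ValueError("corrected_red must satisfy 0 <= corrected_red <= red")


def integrate_channels(
    frame: TimeBinnedFrame, windows: GateWindows | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sum counts over the red- and green-window bins of a time-binned frame."""
    windows = windows or GateWindows()
    red_bins = sorted(window_to_bins(windows.red, frame.pulse_cfg))
    green_bins = sorted(window_to_bins(windows.green, frame.pulse_cfg))
    if max(red_bins + green_bins) >= frame.n_bins:
        raise ValueError(
            f"gate windows address bins up to {max(red_bins + green_bins)} but the "
            f"frame has only {frame.n_bins} bins"
        )
    red = frame.counts[..., red_bins].sum(axis=-1)
    green = frame.counts[..., green_bins].sum(axis=-1)
    return red, green


def corrected_red(red: np.ndarray, green: np.ndarray) -> np.ndarray:
    """Melanin-selective channel: elementwise max(red - green, 0).

    Negative differences arise where long-lifetime signal dominates; they are
    clipped to zero after the per-image subtraction (never per bin).
    """
    red = np.asarray(red)
    green = np.asarray(green)
    if red.shape != green.shape:
        raise ValueError(f"shape mismatch: red {red.shape} vs green {green.shape}")
    return np.maximum(red - green, 0)


def gate_frame(
    frame: TimeBinnedFrame,
    windows: GateWindows | None = None,
    shg: np.ndarray | None = None,
) -> ChannelImage:
    """Full gating chain for one frame: integrate, subtract, clip."""
    windows = windows or GateWindows()
    red, green = integrate_channels(frame, windows)
    return ChannelImage(
        red=red,
        green=green,
        corrected_red=corrected_red(red, green),
        windows=windows,
        shg=shg,
        source=dict(frame.provenance, depth_um=frame.depth_um, n_accum=frame.n_accum),
    )


def _stretch(img: np.ndarray, p_low: float, p_high: float) -> np.ndarray:
    lo, hi = np.percentile(img, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float64)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def compose_color(
    channels: ChannelImage, p_low: float = 0.1, p_high: float = 99.9
) -> np.ndarray:
    """8-bit RGB composite: corrected red -> R, green -> G, SHG -> B.

    Each channel is independently contrast-stretched between its p_low/p_high
    percentiles, matching the display convention of short-lifetime (red),
    long-lifetime (green) and second-harmonic (blue) signals.
    """
    h, w = channels.red.shape
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    rgb[..., 0] = _stretch(channels.corrected_red.astype(np.float64), p_low, p_high)
    rgb[..., 1] = _stretch(channels.green.astype(np.float64), p_low, p_high)
    if channels.shg is not None:
        rgb[..., 2] = _stretch(channels.shg.astype(np.float64), p_low, p_high)
    return np.round(rgb * 255).astype(np.uint8)


def melanin_stain_3d(
    zstack: Sequence[ChannelImage],
    depths_um: Sequence[float],
    threshold: float | None = None,
    fallback_quantile: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, float]:
    """3-D virtual melanin stain from a z-stack of gated channel images.

    The default threshold policy is Otsu's method on the pooled nonzero
    corrected-red histogram of the whole stack (the subtraction itself zeroes
    most non-melanin pixels, so the nonzero values are the informative ones).
    Otsu presumes a bimodal pool (clipping noise vs true melanin); when its
    two classes are not separated (lower-class mean above 60% of the
    upper-class mean, i.e. an effectively unimodal pool of pure signal) every
    nonzero pixel is taken as stain-positive.  A degenerate nonzero
    population falls back to the ``fallback_quantile`` of all values; an
    explicit ``threshold`` overrides the policy entirely.

    Returns ``(mask, per_depth_fraction, threshold_used)`` where ``mask`` has
    shape (n_depths, H, W) and ``per_depth_fraction`` is the melanin-positive
    pixel fraction at each depth.
    """
    if len(zstack) == 0:
        raise ValueError("empty z-stack")
    depths = np.asarray(depths_um, dtype=float)
    if len(depths) != len(zstack) or np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing, one per slice")
    vol = np.stack([c.corrected_red for c in zstack]).astype(np.float64)
    if threshold is None:
        nz = vol[vol > 0]
        if nz.size >= 2 and nz.min() < nz.max():
            from skimage.filters import threshold_otsu

            threshold = float(threshold_otsu(nz))
            lo, hi = nz[nz <= threshold], nz[nz > threshold]
            if lo.size and hi.size and lo.mean() > 0.6 * hi.mean():
                threshold = 0.0  # unimodal pool: all nonzero is signal
        else:
            threshold = float(np.quantile(vol, fallback_quantile))
    mask = vol > threshold
    fractions = mask.reshape(len(zstack), -1).mean(axis=1)
    return mask, fractions, float(threshold)


def melanin_recovery_score(
    mask: np.ndarray,
    truth: np.ndarray,
    scores: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Dice coefficient of the stain mask and, optionally, ROC AUC.

    ``scores`` (typically the corrected-red values the mask was thresholded
    from) enable the threshold-free AUC; with an all-positive or all-negative
    truth the AUC is undefined and raised as an error.
    """
    mask = np.asarray(mask, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs truth {truth.shape}")
    inter = np.logical_and(mask, truth).sum()
    denom = mask.sum() + truth.sum()
    dice = 1.0 if denom == 0 else 2.0 * inter / denom
    auc = None
    if scores is not None:
        if scores.shape != truth.shape:
            raise ValueError("scores must share the truth's shape")
        if truth.all() or not truth.any():
            raise ValueError("ROC AUC undefined: truth labels are all one class")
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(truth.ravel(), scores.ravel()))
    return float(dice), auc
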