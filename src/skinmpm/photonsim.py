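"""Poisson photon-counting forward model and scan-timing arithmetic.

Turns noise-free phantom optical sections into time-binned photon-count
frames: expected per-pixel emission is brightness x dwell x depth attenuation,
distributed over arrival-time bins by each fluorophore's wrapped-decay
histogram, and realized as independent Poisson counts.  Frame accumulation
multiplies the expectation (the sum of n independent frames is Poisson with n
times the mean), which is how the instrument trades speed against SNR:
7/15-frame accumulations are the fast low-SNR inputs, 70 accumulations the
high-SNR ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import (
    DEFAULT_FLUOROPHORES,
    Fluorophore,
    GaussianPsf,
    SkinPhantom,
    ground_truth_image,
)
from .timetag import Irf, PulseTrainConfig, decay_bin_probs

__all__ = [
    "ScanTimingConfig",
    "TimeBinnedFrame",
    "expected_bin_rates",
    "expected_total_rate",
    "simulate_frame",
    "effective_dwell_us",
    "make_training_pairs",
]


@dataclass(frozen=True)
class ScanTimingConfig:
    """Resonant-galvo raster timing.

    A 4 kHz resonant mirror scanned bidirectionally yields an 8 kHz line rate,
    so a 1024-line frame takes 0.128 s; the per-pixel dwell follows by
    dividing the frame time uniformly over the raster.
    """

    resonant_freq: float = 4000.0
    bidirectional: bool = True
    lines_per_frame: int = 1024
    pixels_per_line: int = 1024

    def __post_init__(self) -> None:
        if self.resonant_freq <= 0 or self.lines_per_frame < 1 or self.pixels_per_line < 1:
            raise ValueError("invalid scan timing configuration")

    @property
    def line_rate(self) -> float:
        return self.resonant_freq * (2 if self.bidirectional else 1)

    @property
    def frame_time_s(self) -> float:
        return self.lines_per_frame / self.line_rate

    @property
    def dwell_us_per_frame(self) -> float:
        return self.frame_time_s * 1e6 / (self.lines_per_frame * self.pixels_per_line)


@dataclass
class TimeBinnedFrame:
    """H x W x n_bins integer photon counts with acquisition metadata."""

    counts: np.ndarray
    n_accum: int
    dwell_us_per_frame: float
    depth_um: float
    pulse_cfg: PulseTrainConfig
    provenance: dict

    def __post_init__(self) -> None:
        if self.n_accum < 1:
            raise ValueError(f"n_accum must be >= 1, got {self.n_accum}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[-1]

    @property
    def total(self) -> np.ndarray:
        """Time-integrated (intensity) image: counts summed over bins."""
        return self.counts.sum(axis=-1)


def effective_dwell_us(timing: ScanTimingConfig, n_accum: int) -> float:
    """Effective per-pixel dwell time in microseconds after accumulation.

    With the default 4 kHz bidirectional 1024x1024 raster, 70 accumulations
    give ~9 us and 15 give ~2 us.
    """
    if n_accum < 0:
        raise ValueError(f"n_accum must be >= 0, got {n_accum}")
    return n_accum * timing.frame_time_s * 1e6 / (
        timing.lines_per_frame * timing.pixels_per_line
    )


def expected_bin_rates(
    phantom: SkinPhantom,
    depth_um: float,
    psf: GaussianPsf | None = None,
    timing: ScanTimingConfig | None = None,
    pulse_cfg: PulseTrainConfig | None = None,
    irf: Irf | None = None,
    attenuation_length_um: float = 150.0,
    fluorophores: Sequence[Fluorophore] = DEFAULT_FLUOROPHORES,
    channel: str = "fluorescence",
    dark_rate_per_us: float = 0.0,
) -> np.ndarray:
    """Expected per-pixel per-bin counts for a single (non-accumulated) frame.

    For each fluorophore on the requested detection channel the expected
    emission is its noise-free section times the single-frame dwell times
    exp(-depth / attenuation_length); the wrapped-decay histogram distributes
    it over arrival-time bins.  SHG emitters live on the ``"shg"`` channel,
    which the instrument detects on a separate spectral arm, so the default
    excludes them from the time-binned fluorescence stack.

    ``irf=None`` models the sampling-limited regime (the 780 ps bin width
    dominates the sub-bin detector response, so the ideal prompt response is
    the default); pass an explicit :class:`~skinmpm.timetag.Irf` to include
    detector blur in the forward model.
    """
    if attenuation_length_um <= 0:
        raise ValueError("attenuation_length_um must be positive")
    timing = timing or ScanTimingConfig()
    pulse_cfg = pulse_cfg or PulseTrainConfig()
    psf = psf or GaussianPsf()
    dwell = timing.dwell_us_per_frame
    atten = float(np.exp(-depth_um / attenuation_length_um))

    selected = [f for f in fluorophores if f.display_channel == channel]
    shape = phantom.shape[1:]
    out = np.zeros(shape + (pulse_cfg.n_bins,), dtype=np.float64)
    for f in selected:
        if f.name not in phantom.concentration:
            continue
        img = ground_truth_image(phantom, depth_um, f, psf)
        if not np.any(img):
            continue
        probs = decay_bin_probs(
            list(f.lifetimes) if not f.prompt else None,
            irf,
            pulse_cfg,
            prompt=f.prompt,
        )
        out += (img * dwell * atten)[..., None] * probs
    if dark_rate_per_us > 0:
        out += dark_rate_per_us * dwell / pulse_cfg.n_bins
    return out


def expected_total_rate(
    phantom: SkinPhantom,
    depth_um: float,
    psf: GaussianPsf | None = None,
    timing: ScanTimingConfig | None = None,
    attenuation_length_um: float = 150.0,
    fluorophores: Sequence[Fluorophore] = DEFAULT_FLUOROPHORES,
    channel: str = "fluorescence",
) -> np.ndarray:
    """Expected time-integrated counts per pixel for one frame (no binning)."""
    timing = timing or ScanTimingConfig()
    psf = psf or GaussianPsf()
    dwell = timing.dwell_us_per_frame
    atten = float(np.exp(-depth_um / attenuation_length_um))
    out = np.zeros(phantom.shape[1:], dtype=np.float64)
    for f in fluorophores:
        if f.display_channel != channel or f.name not in phantom.concentration:
            continue
        out += ground_truth_image(phantom, depth_um, f, psf) * dwell * atten
    return out


def simulate_frame(
    expected: np.ndarray,
    n_accum: int,
    seed: int | np.random.Generator,
    depth_um: float = 0.0,
    pulse_cfg: PulseTrainConfig | None = None,
    timing: ScanTimingConfig | None = None,
    provenance: dict | None = None,
) -> TimeBinnedFrame:
    """Draw a Poisson realization of ``n_accum`` accumulated frames.

    Counts are independent Poisson with mean ``n_accum * expected`` per
    pixel-bin, which is exactly the distribution of the sum of ``n_accum``
    independent single frames.
    """
    if n_accum < 1:
        raise ValueError(f"n_accum must be >= 1, got {n_accum}")
    if np.any(expected < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    timing = timing or ScanTimingConfig()
    counts = rng.poisson(n_accum * np.asarray(expected, dtype=np.float64))
    return TimeBinnedFrame(
        counts=counts.astype(np.int64),
        n_accum=int(n_accum),
        dwell_us_per_frame=timing.dwell_us_per_frame,
        depth_um=depth_um,
        pulse_cfg=pulse_cfg or PulseTrainConfig(),
        provenance=provenance or {},
    )


def make_training_pairs(
    phantoms: Sequence[SkinPhantom],
    depths_um: Sequence[float],
    input_accums: Sequence[int] = (7, 15),
    gt_accum: int = 70,
    seed: int = 0,
    psf: GaussianPsf | None = None,
    timing: ScanTimingConfig | None = None,
    attenuation_length_um: float = 150.0,
) -> list[tuple[np.ndarray, np.ndarray, dict]]:
    """Paired low/high-SNR single-channel images for restoration training.

    For each phantom section the expected total-fluorescence rate is computed
    once; each (section, accumulation) pair then gets an input image and a
    ground-truth image as *independent* Poisson realizations at the input and
    ground-truth accumulation counts.  The ground truth is itself a noisy
    (70-accumulation) acquisition, not a noise-free field, mirroring the
    acquired-ground-truth training protocol.  Summing Poisson bins equals a
    Poisson draw of the summed mean, so the time-binned stack is bypassed.

    Returns a list of ``(input_image, gt_image, meta)`` with float counts.
    """
    if not phantoms or not len(depths_um):
        raise ValueError("need at least one phantom and one depth")
    pairs = []
    for pi, ph in enumerate(phantoms):
        for di, depth in enumerate(depths_um):
            rate = expected_total_rate(
                ph, depth, psf=psf, timing=timing,
                attenuation_length_um=attenuation_length_um,
            )
            for acc in input_accums:
                # streams keyed by (seed, section, accumulation): different
                # accumulations are independent, while input == ground-truth
                # accumulation degenerates to the identical image
                inp_rng = np.random.default_rng([seed, pi, di, int(acc)])
                gt_rng = np.random.default_rng([seed, pi, di, int(gt_accum)])
                inp = inp_rng.poisson(acc * rate).astype(np.float64)
                gt = gt_rng.poisson(gt_accum * rate).astype(np.float64)
                pairs.append(
                    (
                        inp,
                        gt,
                        {
                            "phantom_index": pi,
                            "phantom_seed": ph.seed,
                            "depth_um": float(depth),
                            "input_accum": int(acc),
                            "gt_accum": int(gt_accum),
                        },
                    )
                )
    return pairs
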