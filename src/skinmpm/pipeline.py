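"""End-to-end benchmark pipelines on synthetic tissue.

Two standard experiments bind the simulator and the analysis stages together:

* :func:`melanin_benchmark` — simulate a time-binned z-stack over the default
  phantom, gate it into red/green channels, build the corrected-red 3-D
  virtual melanin stain, and score it against the phantom's voxel ground
  truth (Dice, ROC AUC).

* :func:`restoration_benchmark` — simulate paired low/high-SNR acquisitions
  over a panel of phantoms, train the small restorer on patch pairs from a
  training split, and evaluate SSIM/MSE/MAE of raw and restored held-out
  sections against their 70-accumulation ground truth.

Both derive every stage seed from one master seed so a run is reproducible
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gating import gate_frame, melanin_recovery_score, melanin_stain_3d
from .mosaic import plan_zstack
from .phantom import GaussianPsf, generate_phantom
from .photonsim import (
    ScanTimingConfig,
    expected_bin_rates,
    make_training_pairs,
    simulate_frame,
)
from .restore import (
    RestorationConfig,
    evaluate,
    extract_patches,
    normalize,
    restore_image,
    split_train_val,
    train_restorer,
)

__all__ = [
    "stage_seed",
    "melanin_benchmark",
    "restoration_benchmark",
]

_STAGES = {"phantom": 0, "simulate": 1, "gate": 2, "stitch": 3,
           "zstack": 4, "train": 5, "restore": 6, "eval": 7}


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Fan one master seed out to per-stage streams via SeedSequence.

    Stages are numbered in a fixed documented order, so any stage can be
    rerun independently and still see the stream it saw in the full run.
    """
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}; one of {sorted(_STAGES)}")
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(_STAGES[stage], int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass(frozen=True)
class MelaninBenchmarkResult:
    dice: float
    auc: float
    per_depth_fraction: tuple[float, ...]
    threshold: float
    n_planes: int


def melanin_benchmark(
    seed: int = 0,
    shape: tuple[int, int, int] = (30, 256, 256),
    n_accum: int = 15,
    depth_range_um: float = 150.0,
    step_um: float = 5.0,
) -> MelaninBenchmarkResult:
    """Full discrimination chain: phantom -> z-stack -> gating -> stain -> score.

    A default phantom (z pitch 5 um) is imaged as a z-stack at the planner's
    depths, each plane a ``n_accum``-accumulation time-binned frame.  The
    stain volume is scored against the melanin ground truth resampled to the
    image grid: a plane's label takes every phantom slice inside the axial
    optical profile's half-maximum support, since an optical section gathers
    signal from that whole slab (plane depths falling on voxel boundaries
    weight the two adjacent slices equally).
    """
    ph = generate_phantom(stage_seed(seed, "phantom"), shape=shape,
                          pitch_um=(step_um, 0.9, 0.9))
    plan = plan_zstack(min(depth_range_um, ph.depth_extent_um), step_um)
    rng = np.random.default_rng(stage_seed(seed, "zstack"))
    psf = GaussianPsf()
    channels, truths = [], []
    nz = shape[0]
    zc = (np.arange(nz) + 0.5) * ph.voxel_pitch_um[0]
    for depth in plan.depths_um:
        d = min(depth, ph.depth_extent_um)
        expected = expected_bin_rates(ph, d)
        frame = simulate_frame(expected, n_accum, rng, depth_um=depth)
        channels.append(gate_frame(frame))
        w = np.exp(-0.5 * ((zc - d) / psf.axial_sigma_um) ** 2)
        support = w >= 0.5 * w.max()
        truths.append(ph.melanin_truth[support].any(axis=0))
    mask, fractions, thr = melanin_stain_3d(channels, plan.depths_um)
    truth = np.stack(truths)
    scores = np.stack([c.corrected_red for c in channels]).astype(float)
    dice, auc = melanin_recovery_score(mask, truth, scores=scores)
    return MelaninBenchmarkResult(
        dice=dice, auc=auc, per_depth_fraction=tuple(float(f) for f in fractions),
        threshold=thr, n_planes=plan.n_planes,
    )


@dataclass(frozen=True)
class RestorationBenchmarkResult:
    input_ssim: tuple[float, float]
    restored_ssim: tuple[float, float]
    input_mse: tuple[float, float]
    restored_mse: tuple[float, float]
    input_mae: tuple[float, float]
    restored_mae: tuple[float, float]
    paired_ssim_gain: tuple[float, ...]   # per held-out section
    n_train_patches: int
    n_heldout: int
    history: tuple[dict, ...]


def restoration_benchmark(
    seed: int = 0,
    n_train_phantoms: int = 8,
    n_test_phantoms: int = 5,
    depths_um: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0),
    section_shape: tuple[int, int, int] = (30, 256, 256),
    eval_accum: int = 15,
    patch_stride: int = 38,
    config: RestorationConfig | None = None,
) -> RestorationBenchmarkResult:
    """Reduced-scale paired-restoration experiment.

    Phantom panels are disjoint between training and held-out evaluation.
    Training pools both input accumulation levels (7 and 15 by default) into
    one model; inputs pass through the configured variance-stabilizing
    transform before percentile normalization, targets are normalized
    linearly.  Evaluation restores the held-out ``eval_accum``-accumulation
    sections (the model's native output lives on the target-normalized
    scale) and scores both arms against the 70-accumulation ground truth.
    The default geometry yields ~2,100 64-px patch pairs for training and 20
    held-out sections.
    """
    config = config or RestorationConfig(
        patch_px=64, epochs=60, steps_per_epoch=30, batch_size=16,
        base_features=12, n_scales=3, seed=stage_seed(seed, "train"),
    )
    psd = stage_seed(seed, "phantom")
    train_phantoms = [
        generate_phantom(psd + i, shape=section_shape)
        for i in range(n_train_phantoms)
    ]
    test_phantoms = [
        generate_phantom(psd + n_train_phantoms + i, shape=section_shape)
        for i in range(n_test_phantoms)
    ]

    sim_seed = stage_seed(seed, "simulate")
    train_pairs = make_training_pairs(
        train_phantoms, depths_um, input_accums=config.input_accums,
        gt_accum=config.gt_accum, seed=sim_seed,
    )
    norm_pairs = []
    for inp, gt, _ in train_pairs:
        ni, _ = normalize(config.transform_input(inp), *config.norm_percentiles)
        ng, _ = normalize(gt, *config.norm_percentiles)
        norm_pairs.append((ni.astype(np.float32), ng.astype(np.float32)))
    patches = extract_patches(norm_pairs, config.patch_px, stride=patch_stride,
                              seed=config.seed)
    train_set, val_set = split_train_val(patches, config.val_fraction,
                                         seed=config.seed)
    model = train_restorer(train_set, val_set, config)

    test_pairs = make_training_pairs(
        test_phantoms, depths_um, input_accums=(eval_accum,),
        gt_accum=config.gt_accum, seed=stage_seed(seed, "eval"),
    )
    inputs = [p[0] for p in test_pairs]
    gts = [p[1] for p in test_pairs]
    restored = [
        restore_image(
            model,
            normalize(config.transform_input(img), *config.norm_percentiles)[0],
            tile_px=256,
            normalized=True,
            tta=True,
        )
        for img in inputs
    ]
    metrics = evaluate(restored, inputs, gts, config.norm_percentiles,
                       restored_normalized=True)

    from .restore import ssim_pair

    gns = [normalize(g, *config.norm_percentiles)[0] for g in gts]
    dr = float(max(g.max() for g in gns) - min(g.min() for g in gns)) or 1.0
    gains = []
    for r, i, gn in zip(restored, inputs, gns):
        inn, _ = normalize(i, *config.norm_percentiles)
        gains.append(ssim_pair(r, gn, dr) - ssim_pair(inn, gn, dr))
    return RestorationBenchmarkResult(
        input_ssim=metrics["input"].ssim,
        restored_ssim=metrics["restored"].ssim,
        input_mse=metrics["input"].mse,
        restored_mse=metrics["restored"].mse,
        input_mae=metrics["input"].mae,
        restored_mae=metrics["restored"].mae,
        paired_ssim_gain=tuple(gains),
        n_train_patches=len(train_set[0]),
        n_heldout=len(test_pairs),
        history=tuple(model.history),
    )
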