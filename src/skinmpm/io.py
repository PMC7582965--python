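"""File formats and run configuration.

Conventions:

* time-binned photon-count stacks — plain multi-page TIFF, one 16-bit page
  per arrival-time bin, with a JSON sidecar (``<stem>.json``) carrying the
  acquisition metadata (accumulations, dwell, depth, pulse configuration,
  provenance);
* gated channel images and mosaics — OME-TIFF with physical pixel size;
* scan plans, metrics, resolved configs — JSON/YAML.

Every output directory written by the command-line layer receives a frozen
copy of the resolved run configuration plus the package version, so a run can
be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .phantom import PhantomParams
from .photonsim import ScanTimingConfig, TimeBinnedFrame
from .restore import RestorationConfig
from .timetag import GateWindows, PulseTrainConfig

__all__ = [
    "write_timebinned_tiff",
    "read_timebinned_tiff",
    "write_channel_ome_tiff",
    "RunConfig",
    "freeze_config",
]


def write_timebinned_tiff(path: str | Path, frame: TimeBinnedFrame) -> Path:
    """Write a frame as a 16-bit multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    counts = frame.counts
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed the 16-bit storage range")
    pages = np.moveaxis(counts.astype(np.uint16), -1, 0)  # bin-major pages
    tifffile.imwrite(path, pages)
    sidecar = {
        "n_accum": frame.n_accum,
        "dwell_us_per_frame": frame.dwell_us_per_frame,
        "depth_um": frame.depth_um,
        "pulse_cfg": dataclasses.asdict(frame.pulse_cfg),
        "provenance": frame.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_timebinned_tiff(
    path: str | Path, expect_bins: int | None = None
) -> TimeBinnedFrame:
    """Round-trip counterpart of :func:`write_timebinned_tiff`.

    A missing sidecar degrades to default metadata with a warning; a page
    count disagreeing with the expected bin count is a format error.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    counts = np.moveaxis(pages, 0, -1).astype(np.int64)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        pulse_cfg = PulseTrainConfig(**meta["pulse_cfg"])
    else:
        warnings.warn(f"missing sidecar {sidecar_path.name}; assuming defaults")
        meta = {"n_accum": 1, "dwell_us_per_frame":
                ScanTimingConfig().dwell_us_per_frame, "depth_um": 0.0,
                "provenance": {}}
        pulse_cfg = PulseTrainConfig()
    n_bins = expect_bins if expect_bins is not None else pulse_cfg.n_bins
    if counts.shape[-1] != n_bins:
        raise ValueError(
            f"{path.name}: {counts.shape[-1]} pages but {n_bins} time bins expected"
        )
    return TimeBinnedFrame(
        counts=counts,
        n_accum=int(meta["n_accum"]),
        dwell_us_per_frame=float(meta["dwell_us_per_frame"]),
        depth_um=float(meta["depth_um"]),
        pulse_cfg=pulse_cfg,
        provenance=meta.get("provenance", {}),
    )


def write_channel_ome_tiff(
    path: str | Path,
    channels: np.ndarray,
    pixel_size_um: float,
    channel_names: tuple[str, ...] = ("corrected_red", "green", "shg"),
) -> Path:
    """Write a (C, H, W) stack as OME-TIFF with physical pixel size."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(channels),
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(channel_names[: channels.shape[0]])},
            "PhysicalSizeX": pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )
    return path


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one end-to-end run.

    Defaults reproduce the instrument-mode values throughout: 16 bins at
    80 MHz, red/green gates of -0.4-1.2 and 0.4-12 ns, 0.75 mm strips under a
    13 mm travel limit, 0.9 mm tiles, 5 um z-steps over 150 um, 7/15
    accumulation inputs against 70-accumulation ground truth, 128-px patches
    with a 10% validation split.
    """

    seed: int = 0
    pulse: PulseTrainConfig = dataclasses.field(default_factory=PulseTrainConfig)
    windows: GateWindows = dataclasses.field(default_factory=GateWindows)
    timing: ScanTimingConfig = dataclasses.field(default_factory=ScanTimingConfig)
    phantom: PhantomParams = dataclasses.field(default_factory=PhantomParams)
    phantom_shape: tuple[int, int, int] = (30, 256, 256)
    phantom_pitch_um: tuple[float, float, float] = (5.0, 0.9, 0.9)
    restoration: RestorationConfig = dataclasses.field(
        default_factory=RestorationConfig
    )
    strip_width_mm: float = 0.75
    travel_limit_mm: float = 13.0
    tile_fov_mm: float = 0.9
    zstack_range_um: float = 150.0
    zstack_step_um: float = 5.0
    attenuation_length_um: float = 150.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("pulse", PulseTrainConfig),
            ("windows", GateWindows),
            ("timing", ScanTimingConfig),
            ("phantom", PhantomParams),
            ("restoration", RestorationConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                d[key] = sub(**sub_d)
        for key in ("phantom_shape", "phantom_pitch_um"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def freeze_config(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the resolved config (+ package version) into an output directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "config": config.to_dict()}
    target = out_dir / "run_config.json"
    target.write_text(json.dumps(payload, indent=2, default=str))
    return target
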