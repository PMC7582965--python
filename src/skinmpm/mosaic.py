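"""Multi-scale scan planning and mosaic assembly.

Three complementary acquisition geometries cover centimetre-to-cell scales:

* **strip mosaic** — the resonant mirror scans the fast axis while a linear
  stage travels the slow axis, producing long narrow swaths (default 10 mm x
  0.75 mm, serpentine order, stage travel capped at 13 mm) that abut into a
  single large field;
* **tile mosaic** — full optical fields (default 0.9 mm) acquired at stepped
  stage positions on a rows x cols grid, optionally overlapping;
* **z-stack** — en-face planes stepped axially (default 150 um range at 5 um,
  i.e. 30 planes).

This module plans those geometries, simulates strip acquisition from a
noise-free wide-field truth (with optional per-strip lateral jitter),
stitches strips and tiles back, rebins anisotropic rasters to square pixels
by bicubic interpolation, and estimates/removes the slowly varying field-
curvature gain shared by every tile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = [
    "StripScanPlan",
    "TileScanPlan",
    "ZStackPlan",
    "plan_strip_scan",
    "plan_tile_scan",
    "plan_zstack",
    "simulate_strips",
    "stitch_strips",
    "rebin_aspect",
    "stitch_tiles",
    "flat_field_correct",
    "split_mosaic_into_tiles",
]


@dataclass(frozen=True)
class StripScanPlan:
    """Serpentine strip-mosaic geometry; lengths in mm, pitches in um."""

    strip_length_mm: float
    strip_width_mm: float
    n_strips: int
    travel_limit_mm: float = 13.0
    offsets_mm: tuple[float, ...] = ()
    directions: tuple[int, ...] = ()
    pixel_pitch_along_um: float = 1.5
    pixel_pitch_across_um: float = 1.2

    def __post_init__(self) -> None:
        if self.n_strips < 1:
            raise ValueError("n_strips must be >= 1")
        if self.strip_length_mm > self.travel_limit_mm + 1e-12:
            raise ValueError(
                f"strip length {self.strip_length_mm} mm exceeds the stage travel "
                f"limit of {self.travel_limit_mm} mm"
            )

    @property
    def width_mm(self) -> float:
        return self.n_strips * self.strip_width_mm

    @property
    def strip_shape_px(self) -> tuple[int, int]:
        n_along = int(round(self.strip_length_mm * 1000 / self.pixel_pitch_along_um))
        n_across = int(round(self.strip_width_mm * 1000 / self.pixel_pitch_across_um))
        return n_along, n_across


@dataclass(frozen=True)
class TileScanPlan:
    tile_fov_mm: float = 0.9
    grid: tuple[int, int] = (1, 1)
    overlap_fraction: float = 0.0
    tile_pixels: tuple[int, int] = (1024, 1024)

    def __post_init__(self) -> None:
        if min(self.grid) < 1:
            raise ValueError("grid must be at least 1x1")
        if not (0.0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5)")

    @property
    def nominal_megapixels(self) -> int:
        """Tile count in units of one (1024x1024) megapixel frame."""
        return self.grid[0] * self.grid[1]


@dataclass(frozen=True)
class ZStackPlan:
    depth_range_um: float = 150.0
    step_um: float = 5.0
    n_planes: int = 30

    @property
    def depths_um(self) -> tuple[float, ...]:
        """Planes at step, 2*step, ..., n*step below the reference surface."""
        return tuple(self.step_um * (k + 1) for k in range(self.n_planes))


def plan_strip_scan(
    area_w_mm: float,
    area_h_mm: float,
    strip_width_mm: float = 0.75,
    travel_limit_mm: float = 13.0,
    pixel_pitch_along_um: float = 1.5,
    pixel_pitch_across_um: float = 1.2,
) -> StripScanPlan:
    """Cover an area with serpentine strips.

    Strips run along the stage-travel (height) axis; their count is the
    ceiling of the width over the strip width.  A 10 x 12 mm field at the
    default 0.75 mm strip width takes 16 strips.
    """
    if area_w_mm <= 0 or area_h_mm <= 0:
        raise ValueError("area dimensions must be positive")
    if area_h_mm > travel_limit_mm:
        raise ValueError(
            f"strip length {area_h_mm} mm exceeds the stage travel limit of "
            f"{travel_limit_mm} mm"
        )
    n = math.ceil(area_w_mm / strip_width_mm)
    return StripScanPlan(
        strip_length_mm=min(area_h_mm, travel_limit_mm),
        strip_width_mm=strip_width_mm,
        n_strips=n,
        travel_limit_mm=travel_limit_mm,
        offsets_mm=tuple(i * strip_width_mm for i in range(n)),
        directions=tuple(1 if i % 2 == 0 else -1 for i in range(n)),
        pixel_pitch_along_um=pixel_pitch_along_um,
        pixel_pitch_across_um=pixel_pitch_across_um,
    )


def plan_tile_scan(
    area_w_mm: float,
    area_h_mm: float,
    tile_fov_mm: float = 0.9,
    overlap_fraction: float = 0.0,
    tile_pixels: tuple[int, int] = (1024, 1024),
) -> TileScanPlan:
    """Cover an area with stage-stepped tiles.

    The effective step is ``tile_fov * (1 - overlap)``; rows/cols are the
    ceiling of the area over that step (4.5 mm at 0.9 mm tiles -> 5x5, the
    instrument's nominal 25 MPx; 6.3 mm -> 7x7, 49 MPx).
    """
    if area_w_mm <= 0 or area_h_mm <= 0:
        raise ValueError("area dimensions must be positive")
    if not (0.0 <= overlap_fraction < 0.5):
        raise ValueError("overlap_fraction must be in [0, 0.5)")
    step = tile_fov_mm * (1.0 - overlap_fraction)
    rows = max(math.ceil(round(area_h_mm / step, 9)), 1)
    cols = max(math.ceil(round(area_w_mm / step, 9)), 1)
    return TileScanPlan(
        tile_fov_mm=tile_fov_mm,
        grid=(rows, cols),
        overlap_fraction=overlap_fraction,
        tile_pixels=tile_pixels,
    )


def plan_zstack(depth_range_um: float = 150.0, step_um: float = 5.0) -> ZStackPlan:
    """Plan an axial stack: round(range / step) planes, one step apart.

    150 um at 5 um steps gives the instrument's standard 30 planes; a step
    exceeding the range degenerates to a single plane at the full range.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    if step_um > depth_range_um:
        return ZStackPlan(depth_range_um=depth_range_um, step_um=depth_range_um, n_planes=1)
    return ZStackPlan(
        depth_range_um=depth_range_um,
        step_um=step_um,
        n_planes=int(round(depth_range_um / step_um)),
    )


def simulate_strips(
    truth: np.ndarray,
    truth_pitch_um: tuple[float, float],
    plan: StripScanPlan,
    jitter_um: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Cut a wide-field truth image into serpentine strips.

    ``truth`` is (along, across) with pitches in um.  Each strip is cropped at
    its planned across-axis offset (plus seeded Gaussian lateral jitter,
    rounded to whole pixels), resampled to the plan's pitches when they differ
    from the truth's, and stored in its acquisition orientation: strips
    acquired on the return stroke are reversed along the travel axis.  Zero
    jitter with matching pitches partitions the truth exactly.
    """
    p_along, p_across = truth_pitch_um
    n_along = int(round(plan.strip_length_mm * 1000 / p_along))
    w_across = int(round(plan.strip_width_mm * 1000 / p_across))
    need_across = int(round(plan.width_mm * 1000 / p_across))
    if truth.shape[0] < n_along or truth.shape[1] < need_across:
        raise ValueError(
            f"truth image {truth.shape} smaller than planned area "
            f"({n_along}, {need_across}) px"
        )
    rng = np.random.default_rng(seed)
    strips = []
    for i, (off_mm, direction) in enumerate(zip(plan.offsets_mm, plan.directions)):
        jitter_px = (
            int(round(rng.normal(0.0, jitter_um) / p_across)) if jitter_um > 0 else 0
        )
        x0 = int(round(off_mm * 1000 / p_across)) + jitter_px
        x0 = min(max(x0, 0), truth.shape[1] - w_across)
        strip = truth[:n_along, x0: x0 + w_across]
        if direction < 0:
            strip = strip[::-1]
        tgt = (
            int(round(plan.strip_length_mm * 1000 / plan.pixel_pitch_along_um)),
            int(round(plan.strip_width_mm * 1000 / plan.pixel_pitch_across_um)),
        )
        if tgt != strip.shape:
            strip = resize(strip.astype(float), tgt, order=3, mode="edge",
                           anti_aliasing=False)
        strips.append(strip.copy())
    return strips


def stitch_strips(strips: list[np.ndarray], plan: StripScanPlan) -> np.ndarray:
    """Abut strips at their planned offsets, undoing serpentine reversal."""
    if len(strips) != plan.n_strips:
        raise ValueError(
            f"plan expects {plan.n_strips} strips, got {len(strips)}"
        )
    shapes = {s.shape for s in strips}
    if len(shapes) != 1:
        raise ValueError(f"strips disagree in shape: {shapes}")
    n_along, w = strips[0].shape
    out = np.zeros((n_along, w * plan.n_strips), dtype=strips[0].dtype)
    for i, (strip, direction) in enumerate(zip(strips, plan.directions)):
        if direction < 0:
            strip = strip[::-1]
        out[:, i * w: (i + 1) * w] = strip
    return out


def rebin_aspect(
    mosaic: np.ndarray, pitch_along_um: float, pitch_across_um: float
) -> np.ndarray:
    """Bicubic-resample the coarser-pitch axis so pixels become square.

    Axis 0 carries ``pitch_along_um``, axis 1 ``pitch_across_um``; the coarser
    axis is upsampled to the finer pitch, preserving physical extent.  With
    the standard 1.25 pitch ratio an 8000x8000 (64 MPx) raster becomes
    10000x8000 (80 MPx).  Equal pitches return the input unchanged.
    """
    if pitch_along_um <= 0 or pitch_across_um <= 0:
        raise ValueError("pitches must be positive")
    if pitch_along_um == pitch_across_um:
        return mosaic
    n0, n1 = mosaic.shape
    if pitch_along_um > pitch_across_um:
        shape = (int(round(n0 * pitch_along_um / pitch_across_um)), n1)
    else:
        shape = (n0, int(round(n1 * pitch_across_um / pitch_along_um)))
    return resize(
        mosaic.astype(float), shape, order=3, mode="edge", anti_aliasing=False
    )


def stitch_tiles(tiles: list[np.ndarray], plan: TileScanPlan) -> np.ndarray:
    """Assemble tiles row-major; overlaps are blended by linear feathering."""
    rows, cols = plan.grid
    if len(tiles) != rows * cols:
        raise ValueError(f"plan expects {rows * cols} tiles, got {len(tiles)}")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"tiles disagree in shape: {shapes}")
    th, tw = tiles[0].shape
    ov_y = int(round(plan.overlap_fraction * th))
    ov_x = int(round(plan.overlap_fraction * tw))
    step_y, step_x = th - ov_y, tw - ov_x
    H = step_y * (rows - 1) + th
    W = step_x * (cols - 1) + tw
    acc = np.zeros((H, W), dtype=np.float64)
    wacc = np.zeros((H, W), dtype=np.float64)

    def ramp(n, ov, first, last):
        w = np.ones(n)
        if ov > 0:
            r = np.linspace(0, 1, ov + 2)[1:-1]
            if not first:
                w[:ov] = r
            if not last:
                w[-ov:] = r[::-1]
        return w

    for r in range(rows):
        for c in range(cols):
            tile = np.asarray(tiles[r * cols + c], dtype=np.float64)
            wy = ramp(th, ov_y, r == 0, r == rows - 1)
            wx = ramp(tw, ov_x, c == 0, c == cols - 1)
            w2 = wy[:, None] * wx[None, :]
            y0, x0 = r * step_y, c * step_x
            acc[y0: y0 + th, x0: x0 + tw] += tile * w2
            wacc[y0: y0 + th, x0: x0 + tw] += w2
    out = acc / np.where(wacc > 0, wacc, 1.0)
    if all(np.issubdtype(t.dtype, np.integer) for t in tiles) and ov_y == ov_x == 0:
        out = out.astype(tiles[0].dtype)
    return out


def split_mosaic_into_tiles(mosaic: np.ndarray, tile_shape: tuple[int, int]):
    """Partition a mosaic into non-overlapping tiles (drops ragged edges)."""
    th, tw = tile_shape
    rows, cols = mosaic.shape[0] // th, mosaic.shape[1] // tw
    return np.stack(
        [
            mosaic[r * th: (r + 1) * th, c * tw: (c + 1) * tw]
            for r in range(rows)
            for c in range(cols)
        ]
    )


def flat_field_correct(
    tiles: np.ndarray, poly_order: int = 2, min_gain: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and remove the shared field-curvature gain from a tile set.

    Field curvature and vignetting impose the same smooth multiplicative
    pattern on every tile of a mosaic.  The pattern is estimated by averaging
    all tiles (content averages out; the gain does not) and fitting a
    low-order 2-D polynomial (``poly_order`` per axis) to the average by
    least squares.  The fit, normalized to unit mean, is the gain field; the
    corrected tiles are the input divided by it.  The estimate is invariant
    to global intensity scaling by construction.

    Parameters
    ----------
    tiles : ndarray, shape (n_tiles, H, W)
        At least 4 nonnegative tiles.

    Returns
    -------
    (corrected, gain) : corrected tiles (same shape) and the (H, W) gain.
    """
    tiles = np.asarray(tiles, dtype=np.float64)
    if tiles.ndim != 3 or tiles.shape[0] < 4:
        raise ValueError("need a (n>=4, H, W) tile stack for gain estimation")
    if np.any(tiles < 0):
        raise ValueError("tiles must be nonnegative")
    mean_tile = tiles.mean(axis=0)
    if not np.any(mean_tile):
        raise ValueError("degenerate all-zero input")
    h, w = mean_tile.shape
    y = (np.arange(h) - (h - 1) / 2) / max(h - 1, 1)
    x = (np.arange(w) - (w - 1) / 2) / max(w - 1, 1)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    terms = [
        (yy**i * xx**j).ravel()
        for i in range(poly_order + 1)
        for j in range(poly_order + 1)
    ]
    A = np.stack(terms, axis=1)
    coef, *_ = np.linalg.lstsq(A, mean_tile.ravel(), rcond=None)
    fit = (A @ coef).reshape(h, w)
    gain = fit / fit.mean()
    gain = np.clip(gain, min_gain, None)
    return tiles / gain, gain
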