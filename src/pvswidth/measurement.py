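"""PVS width measurement: endfoot selection, normal-ray casting, summaries.

For each vessel-perimeter pixel three rays are cast outward — one along the
outward normal and two at ±10° — and marched in sub-pixel steps.  If any ray
intersects a selected astrocytic-endfoot mask the pixel is a *facing edge*
and is assigned the Euclidean-distance-map value (µm) at the first endfoot
pixel hit, minimized over the three rays.  Per-vessel summaries record the
mean width over facing pixels and the means of the five quintiles of the
sorted width distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .contour import estimate_outward_normals, trace_perimeter  # re-exported
from .segmentation import SegmentedObject, VesselRegion

__all__ = [
    "DistanceMap",
    "EndfootRegion",
    "WidthProfile",
    "compute_vessel_distance_map",
    "estimate_outward_normals",
    "select_endfeet",
    "measure_pvs_width",
    "summarize_vessel",
    "render_distance_overlay",
]


@dataclass
class DistanceMap:
    """Euclidean distance (µm) to the nearest included vessel.

    Zero exactly on the union of vessel masks (wall plus lumen); elsewhere
    the exact Euclidean distance to the nearest vessel pixel, scaled by the
    pixel size.
    """

    values: np.ndarray
    pixel_size: float


@dataclass
class EndfootRegion:
    """A GFAP object annotated with its distance to the nearest vessel."""

    object: SegmentedObject
    nearest_vessel_distance_um: float
    selected: bool
    selection_source: str  # auto | manual


@dataclass
class WidthProfile:
    """Per-perimeter-pixel PVS widths and the per-vessel summary.

    ``widths_um[i]`` is NaN where perimeter pixel ``i`` has no facing edge
    (``facing[i]`` False).  ``quintile_means_um`` is None when fewer than 5
    facing pixels were found (vessel kept for mean-only analyses, flagged).
    """

    vessel_id: int
    widths_um: np.ndarray
    facing: np.ndarray
    mean_width_um: float
    quintile_means_um: np.ndarray | None
    n_facing: int
    n_perimeter: int


def compute_vessel_distance_map(
    vessel_regions: Sequence[VesselRegion],
    image_shape: tuple[int, int],
    pixel_size: float,
) -> DistanceMap:
    """Exact Euclidean distance transform of the union of vessel masks.

    Raises
    ------
    ValueError
        If no vessel region is supplied.
    """
    if len(vessel_regions) == 0:
        raise ValueError("need at least one included vessel")
    union = np.zeros(image_shape, dtype=bool)
    for v in vessel_regions:
        union |= v.filled_mask
    dist_px = ndimage.distance_transform_edt(~union)
    return DistanceMap(values=dist_px * pixel_size, pixel_size=pixel_size)


def select_endfeet(
    endfoot_objects: Sequence[SegmentedObject],
    distance_map: DistanceMap,
    auto_radius_um: float = 2.5,
    manual_ids: Sequence[int] = (),
) -> list[EndfootRegion]:
    """Select endfoot objects near a vessel, with manual inclusion beyond.

    Each object is annotated with the minimum distance-map value over its
    perimeter pixels.  Objects within ``auto_radius_um`` of a vessel
    perimeter are auto-selected; farther objects are selected only when
    listed in ``manual_ids`` (wide PVSs require explicit inclusion).

    Raises
    ------
    KeyError
        If a manual id does not match any endfoot object.
    """
    known = {o.object_id for o in endfoot_objects}
    missing = set(manual_ids) - known
    if missing:
        raise KeyError(f"manual endfoot id(s) not found: {sorted(missing)}")
    manual = set(manual_ids)
    out = []
    for obj in endfoot_objects:
        # perimeter pixels: object pixels with >= 1 background 8-neighbor
        eroded = ndimage.binary_erosion(obj.mask, structure=np.ones((3, 3)), border_value=0)
        boundary = obj.mask & ~eroded
        if not boundary.any():
            boundary = obj.mask
        nearest = float(distance_map.values[boundary].min())
        if nearest <= auto_radius_um:
            sel, src = True, "auto"
        elif obj.object_id in manual:
            sel, src = True, "manual"
        else:
            sel, src = False, "auto"
        out.append(
            EndfootRegion(
                object=obj,
                nearest_vessel_distance_um=nearest,
                selected=sel,
                selection_source=src,
            )
        )
    return out


def _bilinear(mask_f: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear lookup of a float raster at (x=col, y=row) positions."""
    return ndimage.map_coordinates(mask_f, [y.ravel(), x.ravel()], order=1, mode="constant").reshape(
        x.shape
    )


def measure_pvs_width(
    vessel: VesselRegion,
    endfeet: Sequence[EndfootRegion],
    distance_map: DistanceMap,
    half_angle_deg: float = 10.0,
    max_ray_um: float = 10.0,
    step_px: float = 0.5,
) -> WidthProfile:
    """Cast 3 rays per perimeter pixel and read widths off the distance map.

    Rays are the outward normal and its ±``half_angle_deg`` rotations,
    marched outward in ``step_px`` steps (bilinear mask interpolation,
    occupancy threshold 0.5) up to ``max_ray_um``.  A pixel facing a
    selected endfoot gets ``width_um`` = the distance-map value at the first
    endfoot pixel hit, minimized over the three rays; otherwise it carries
    no width.  Perimeter pixels with degenerate normals are excluded.
    """
    selected_masks = [e.object.mask for e in endfeet if e.selected]
    if not selected_masks:
        raise ValueError("no selected endfeet: nothing to measure against")
    endfoot_mask = np.zeros(vessel.filled_mask.shape, dtype=float)
    for m in selected_masks:
        endfoot_mask[m] = 1.0

    chain = vessel.perimeter
    n = len(chain)
    normals = vessel.normals
    valid = vessel.normals_valid.copy()

    px = distance_map.pixel_size
    n_steps = max(1, int(np.ceil((max_ray_um / px) / step_px)))
    steps = (np.arange(1, n_steps + 1) * step_px)  # in pixels

    theta = np.deg2rad(half_angle_deg)
    base = np.arctan2(normals[:, 1], normals[:, 0])  # (n,) may contain NaN
    angles = np.stack([base, base - theta, base + theta], axis=1)  # (n, 3)
    dirx, diry = np.cos(angles), np.sin(angles)

    xy = chain[:, ::-1].astype(float)  # (n, 2) as (x, y)
    # positions: (n, 3, n_steps)
    X = xy[:, 0, None, None] + dirx[:, :, None] * steps[None, None, :]
    Y = xy[:, 1, None, None] + diry[:, :, None] * steps[None, None, :]
    with np.errstate(invalid="ignore"):
        occ = _bilinear(endfoot_mask, np.nan_to_num(X), np.nan_to_num(Y)) >= 0.5

    widths = np.full(n, np.nan)
    facing = np.zeros(n, dtype=bool)
    h, w = endfoot_mask.shape
    hit_any = occ.any(axis=2)  # (n, 3)
    first = np.argmax(occ, axis=2)  # (n, 3) first True index (0 if none)
    for i in range(n):
        if not valid[i]:
            continue
        best = np.inf
        for r in range(3):
            if not hit_any[i, r]:
                continue
            s = first[i, r]
            hx, hy = X[i, r, s], Y[i, r, s]
            rr = int(np.clip(np.rint(hy), 0, h - 1))
            cc = int(np.clip(np.rint(hx), 0, w - 1))
            best = min(best, float(distance_map.values[rr, cc]))
        if np.isfinite(best):
            facing[i] = True
            widths[i] = best

    n_facing = int(facing.sum())
    if n_facing == 0:
        warnings.warn(
            f"vessel {vessel.vessel_id}: no facing perimeter pixels; empty width profile",
            stacklevel=2,
        )
        return WidthProfile(vessel.vessel_id, widths, facing, float("nan"), None, 0, n)
    mean, quintiles = summarize_vessel(widths[facing])
    return WidthProfile(
        vessel_id=vessel.vessel_id,
        widths_um=widths,
        facing=facing,
        mean_width_um=mean,
        quintile_means_um=quintiles,
        n_facing=n_facing,
        n_perimeter=n,
    )


def summarize_vessel(widths: np.ndarray) -> tuple[float, np.ndarray | None]:
    """Mean width and quintile means of a vessel's width samples.

    Widths are sorted ascending and sliced into five blocks with the
    floor-index rule (quintile ``k`` covers sorted indices
    ``[⌊(k−1)n/5⌋, ⌊kn/5⌋)``); the mean of each block is reported.  With
    fewer than 5 samples the quintile means are undefined and ``None`` is
    returned in their place (the vessel is kept for mean-only analyses).
    """
    widths = np.asarray(widths, dtype=float)
    widths = widths[np.isfinite(widths)]
    if widths.size == 0:
        return float("nan"), None
    mean = float(widths.mean())
    n = widths.size
    if n < 5:
        return mean, None
    s = np.sort(widths, kind="stable")
    bounds = [(k * n) // 5 for k in range(6)]
    q = np.array([s[bounds[k] : bounds[k + 1]].mean() for k in range(5)])
    return mean, q


def _width_to_rgb(width_um: np.ndarray, mid_anchor: float, max_anchor: float) -> np.ndarray:
    """Map widths to RGB: red at 0 → green at mid_anchor → blue at ≥ max_anchor."""
    w = np.asarray(width_um, dtype=float)
    rgb = np.zeros(w.shape + (3,))
    lower = np.clip(w / mid_anchor, 0.0, 1.0)
    upper = np.clip((w - mid_anchor) / (max_anchor - mid_anchor), 0.0, 1.0)
    in_lower = w <= mid_anchor
    rgb[..., 0] = np.where(in_lower, 1.0 - lower, 0.0)
    rgb[..., 1] = np.where(in_lower, lower, 1.0 - upper)
    rgb[..., 2] = np.where(in_lower, 0.0, upper)
    return rgb


def render_distance_overlay(
    vessel: VesselRegion,
    profile: WidthProfile,
    mid_anchor_um: float = 0.78,
    max_anchor_um: float = 1.56,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Render the perimeter color-coded by PVS width as an RGB float image.

    Width 0 µm maps to pure red, ``mid_anchor_um`` (default 0.78) to pure
    green, and widths ≥ ``max_anchor_um`` (default 1.56) clamp to pure blue;
    non-facing perimeter pixels are drawn grey.  ``background`` (a raw
    channel) is rendered dimly underneath when given.
    """
    shape = vessel.filled_mask.shape
    rgb = np.zeros(shape + (3,))
    if background is not None:
        bg = np.asarray(background, dtype=float)
        span = bg.max() - bg.min()
        if span > 0:
            rgb[...] = (0.4 * (bg - bg.min()) / span)[..., None]
    colors = _width_to_rgb(np.nan_to_num(profile.widths_um), mid_anchor_um, max_anchor_um)
    for i, (r, c) in enumerate(vessel.perimeter):
        rgb[r, c] = colors[i] if profile.facing[i] else (0.5, 0.5, 0.5)
    return rgb
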