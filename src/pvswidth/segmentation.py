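"""Ratio-of-Gaussians segmentation of locally bright objects.

A channel is divided by a more heavily blurred copy of itself
(``G(σ_small)∗I / G(σ_large)∗I``): the quotient is ≈1 over background,
>1 on locally bright structures (vessel walls, endfeet) and <1 on locally
dark ones.  A global threshold is then read off the ratio histogram — the
first bin right of the background peak whose count drops strictly below a
fixed fraction (default 77%) of the peak count.  Detected objects are
filtered on area, mean intensity and boundary contrast, with declarative
manual overrides applied last; putative vessel walls are closed with
morphological dilation/erosion until the perimeter forms a single closed
chain around the lumen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .contour import estimate_outward_normals, trace_perimeter

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class RatioImage:
    """Pixelwise quotient of a lightly vs heavily blurred channel.

    ``border_px`` marks the band (width 3·σ_large) adjacent to the image
    edge where reflective blurring makes the ratio unreliable; it is
    excluded from thresholding statistics.
    """

    values: np.ndarray
    source_channel: str = ""
    border_px: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio image contains non-finite values")

    def interior(self) -> np.ndarray:
        """Ratio values away from the unreliable border band (flattened)."""
        b = self.border_px
        if b == 0 or 2 * b >= min(self.values.shape):
            return self.values.ravel()
        return self.values[b:-b, b:-b].ravel()


@dataclass
class SegmentedObject:
    """One connected bright region with object-level descriptors."""

    object_id: int
    mask: np.ndarray  # boolean, full image frame
    area_px: int
    area_um2: float
    mean_intensity: float
    boundary_contrast: float
    selected: bool = True
    selection_source: str = "auto"  # auto | manual


@dataclass
class VesselRegion:
    """A closed vessel wall with ordered outer perimeter and outward normals."""

    object: SegmentedObject
    closed_mask: np.ndarray
    filled_mask: np.ndarray  # wall + lumen, defines "inside" for normals
    perimeter: np.ndarray  # (n, 2) ordered (row, col) chain
    normals: np.ndarray  # (n, 2) unit (x, y) vectors
    normals_valid: np.ndarray  # (n,) bool
    vessel_id: int = 0


@dataclass
class FilterConfig:
    """Object-level filter thresholds; ``None`` disables a criterion.

    Defaults keep only the area floor active — intensity and contrast
    cut-offs vary between stains and are meant to be set per image.
    """

    min_area_px: int | None = 20
    max_area_px: int | None = None
    min_mean_intensity: float | None = None
    min_boundary_contrast: float | None = None

    def __post_init__(self) -> None:
        if (
            self.min_area_px is not None
            and self.max_area_px is not None
            and self.min_area_px > self.max_area_px
        ):
            raise ValueError("min_area_px > max_area_px")


def compute_ratio_image(
    channel: np.ndarray,
    sigma_small: float = 1.0,
    sigma_large: float = 4.0,
    epsilon: float | None = None,
    source_channel: str = "",
) -> RatioImage:
    """Ratio of a σ_small-blurred to a σ_large-blurred copy of ``channel``.

    The denominator is floored at ``epsilon`` (default ``1e-6 ×`` the image
    maximum, which keeps the ratio exactly invariant to global
    multiplicative rescaling).  Blurring uses reflective boundary handling;
    the border band of width ``3·σ_large`` is flagged unreliable.

    Raises
    ------
    ValueError
        If the channel is all-zero (no foreground possible; the division
        would be degenerate) or ``sigma_small >= sigma_large``.
    """
    channel = np.asarray(channel, dtype=float)
    if np.any(channel < 0):
        raise ValueError("channel intensities must be non-negative")
    if not (sigma_small < sigma_large):
        raise ValueError(f"need sigma_small < sigma_large, got {sigma_small} >= {sigma_large}")
    peak = channel.max()
    if peak == 0:
        raise ValueError("all-zero image: ratio undefined")
    if epsilon is None:
        epsilon = 1e-6 * peak
    num = ndimage.gaussian_filter(channel, sigma_small, mode="reflect")
    den = ndimage.gaussian_filter(channel, sigma_large, mode="reflect")
    # floor (rather than shift) the denominator: background ratio stays
    # exactly 1 and the quotient is exactly invariant to global rescaling
    ratio = num / np.maximum(den, epsilon)
    return RatioImage(
        values=ratio,
        source_channel=source_channel,
        border_px=int(np.ceil(3 * sigma_large)),
    )


def threshold_from_histogram(
    counts: np.ndarray,
    bin_edges: np.ndarray,
    fraction: float = 0.77,
) -> float:
    """Apply the background-peak drop rule to a prepared histogram.

    The modal bin is taken as the background peak; scanning bins in
    increasing value order starting right of the peak, the threshold is the
    left edge of the first bin whose count is *strictly* below
    ``fraction × peak count``.

    Raises
    ------
    ValueError
        If no bin right of the peak drops below the fraction (e.g. a
        single-spike histogram) — a pathological image, never a fabricated
        threshold.
    """
    counts = np.asarray(counts, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) != len(counts) + 1:
        raise ValueError("bin_edges must have len(counts)+1 entries")
    peak_idx = int(np.argmax(counts))
    cutoff = fraction * counts[peak_idx]
    for i in range(peak_idx + 1, len(counts)):
        if counts[i] < cutoff:
            return float(bin_edges[i])
    raise ValueError(
        "no threshold found: no bin right of the background peak drops below "
        f"{fraction:.0%} of the peak count"
    )


def background_peak_threshold(
    ratio: RatioImage,
    fraction: float = 0.77,
    n_bins: int = 256,
    smooth: bool = True,
) -> float:
    """Histogram-peak threshold on a ratio image.

    The histogram uses ``n_bins`` equal-width bins over [min, max] of the
    interior ratio values and is smoothed with a 3-bin moving average before
    peak finding (stabilizes the modal bin against shot noise); the 77% drop
    rule then runs on the smoothed counts.
    """
    values = ratio.interior()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate ratio image: all interior values identical")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    counts = counts.astype(float)
    if smooth:
        counts = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    return threshold_from_histogram(counts, edges, fraction=fraction)


def segment_bright_objects(ratio: RatioImage, threshold: float) -> np.ndarray:
    """Label 8-connected components of ``{ratio >= threshold}``.

    Returns an integer label map (background 0, objects 1..K).  An empty
    result is legal (threshold above the global maximum).
    """
    fg = ratio.values >= threshold
    labels, _ = ndimage.label(fg, structure=_EIGHT)
    return labels


def _boundary_contrast(mask: np.ndarray, channel: np.ndarray) -> float:
    """Mean absolute intensity step across the object boundary.

    For every object pixel with ≥1 background 8-neighbor, average
    |I(p) − I(q)| over its background neighbors; then average over boundary
    pixels.
    """
    rows, cols = np.nonzero(mask)
    h, w = mask.shape
    total, n_boundary = 0.0, 0
    for r, c in zip(rows, cols):
        diffs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                    diffs.append(abs(float(channel[r, c]) - float(channel[rr, cc])))
                elif not (0 <= rr < h and 0 <= cc < w):
                    continue
        if diffs:
            total += float(np.mean(diffs))
            n_boundary += 1
    return total / n_boundary if n_boundary else 0.0


def filter_objects(
    label_map: np.ndarray,
    channel: np.ndarray,
    config: FilterConfig | None = None,
    pixel_size: float = 1.0,
    manual_overrides: Mapping[int, bool] | None = None,
) -> list[SegmentedObject]:
    """Annotate labelled objects and apply the selection filters.

    ``channel`` must be the raw (unratioed) intensity raster the objects
    were segmented from.  An object is auto-included iff it passes every
    configured threshold; ``manual_overrides`` (object_id → include) are
    applied last and always win, with ``selection_source`` set to
    ``"manual"``.

    Raises
    ------
    KeyError
        If a manual override references a nonexistent object id.
    """
    config = config or FilterConfig()
    manual_overrides = dict(manual_overrides or {})
    channel = np.asarray(channel, dtype=float)
    ids = [int(i) for i in np.unique(label_map) if i != 0]
    unknown = set(manual_overrides) - set(ids)
    if unknown:
        raise KeyError(f"manual override references nonexistent object id(s): {sorted(unknown)}")

    objects = []
    for oid in ids:
        mask = label_map == oid
        area_px = int(mask.sum())
        mean_intensity = float(channel[mask].mean())
        contrast = _boundary_contrast(mask, channel)
        ok = True
        if config.min_area_px is not None and area_px < config.min_area_px:
            ok = False
        if config.max_area_px is not None and area_px > config.max_area_px:
            ok = False
        if config.min_mean_intensity is not None and mean_intensity < config.min_mean_intensity:
            ok = False
        if config.min_boundary_contrast is not None and contrast < config.min_boundary_contrast:
            ok = False
        source = "auto"
        if oid in manual_overrides:
            ok = bool(manual_overrides[oid])
            source = "manual"
        objects.append(
            SegmentedObject(
                object_id=oid,
                mask=mask,
                area_px=area_px,
                area_um2=area_px * pixel_size**2,
                mean_intensity=mean_intensity,
                boundary_contrast=contrast,
                selected=ok,
                selection_source=source,
            )
        )
    return objects


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return x * x + y * y <= r * r


def _is_closed_ring(mask: np.ndarray) -> bool:
    """True if the mask is one component enclosing at least one lumen pixel."""
    n_fg = ndimage.label(mask, structure=_EIGHT)[1]
    if n_fg != 1:
        return False
    filled = ndimage.binary_fill_holes(mask)
    return bool((filled & ~mask).any())


def close_vessel_boundary(
    obj: SegmentedObject,
    closing_radius_px: int = 2,
    max_iterations: int = 5,
    vessel_id: int | None = None,
) -> VesselRegion:
    """Close staining gaps in a putative vessel wall and trace its perimeter.

    Morphological closing (dilation then erosion with a disk of
    ``closing_radius_px``) is applied repeatedly, up to ``max_iterations``
    times, until the wall forms a single connected ring enclosing a lumen.
    The ring filled with its lumen defines "inside" for orienting the
    outward normals.

    Raises
    ------
    ValueError
        If the wall is still not closable after ``max_iterations`` — the
        object is a candidate for manual exclusion.
    """
    if not obj.selected:
        raise ValueError(f"object {obj.object_id} is excluded; refusing to close")
    structure = _disk(closing_radius_px)
    mask = obj.mask.astype(bool)
    closed = mask
    # closing is idempotent, so escalate: attempt i uses i dilations followed
    # by i erosions (effective radius i × closing_radius_px)
    if not _is_closed_ring(closed):
        for i in range(1, max_iterations + 1):
            closed = ndimage.binary_closing(mask, structure=structure, iterations=i)
            if _is_closed_ring(closed):
                break
    if not _is_closed_ring(closed):
        raise ValueError(
            f"object {obj.object_id}: vessel wall not closable after "
            f"{max_iterations} closing iteration(s); consider manual exclusion"
        )
    filled = ndimage.binary_fill_holes(closed)
    perimeter = trace_perimeter(filled)
    normals, valid = estimate_outward_normals(perimeter, filled)
    return VesselRegion(
        object=obj,
        closed_mask=closed,
        filled_mask=filled,
        perimeter=perimeter,
        normals=normals,
        normals_valid=valid,
        vessel_id=vessel_id if vessel_id is not None else obj.object_id,
    )
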