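"""Tile-to-overview alignment and vessel distance to the syrinx / central canal.

High-resolution vessel fields are placed into the tiled overview by a pure
translation derived from stage metadata (coarse), optionally refined by a
manually supplied residual offset (the sample can shift on the stage
holder).  Each vessel's distance to the reference region — the syrinx
outline, or the central canal in controls — is the minimum distance from its
facing perimeter pixels to the reference polygon, in µm, with points on or
inside the polygon at distance zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from shapely.geometry import Point

from .io import MultiChannelSection, RoiPolygon
from .measurement import WidthProfile
from .segmentation import VesselRegion

#: reference ROI expected for each animal group
_GROUP_REFERENCE = {"syrinx": "syrinx", "control": "central_canal"}


@dataclass(frozen=True)
class AlignmentTransform:
    """Pure translation from tile frame to overview frame, in µm.

    ``residual_offset_um`` is a manual correction applied after the coarse
    stage-metadata translation; composition is simple vector addition.
    """

    translation_um: tuple[float, float]
    residual_offset_um: tuple[float, float] = (0.0, 0.0)
    source: str = "stage_metadata"  # stage_metadata | manual_refined

    @property
    def total_um(self) -> tuple[float, float]:
        return (
            self.translation_um[0] + self.residual_offset_um[0],
            self.translation_um[1] + self.residual_offset_um[1],
        )

    def tile_to_overview_um(self, xy_um: np.ndarray) -> np.ndarray:
        """Map (x, y) µm points from the tile frame to the overview frame."""
        return np.asarray(xy_um, dtype=float) + np.asarray(self.total_um)

    def overview_to_tile_um(self, xy_um: np.ndarray) -> np.ndarray:
        return np.asarray(xy_um, dtype=float) - np.asarray(self.total_um)


@dataclass
class ReferenceDistance:
    vessel_id: int
    reference_label: str  # syrinx | central_canal
    distance_um: float


def coarse_align(tile: MultiChannelSection, overview: MultiChannelSection) -> AlignmentTransform:
    """Coarse alignment of a tile into the overview from stage metadata.

    Raises
    ------
    ValueError
        If either image lacks stage metadata — manual alignment is then the
        only option.
    """
    if tile.stage_position is None or overview.stage_position is None:
        raise ValueError(
            "stage metadata missing on tile or overview; supply a manual alignment instead"
        )
    tx = tile.stage_position[0] - overview.stage_position[0]
    ty = tile.stage_position[1] - overview.stage_position[1]
    return AlignmentTransform(translation_um=(tx, ty), source="stage_metadata")


def refine_align(
    transform: AlignmentTransform, manual_offset_um: tuple[float, float]
) -> AlignmentTransform:
    """Add a manual residual offset (µm) to a coarse transform."""
    rx = transform.residual_offset_um[0] + float(manual_offset_um[0])
    ry = transform.residual_offset_um[1] + float(manual_offset_um[1])
    return replace(transform, residual_offset_um=(rx, ry), source="manual_refined")


def distance_to_reference(
    vessel: VesselRegion,
    profile: WidthProfile,
    roi: RoiPolygon,
    pixel_size: float,
    transform: AlignmentTransform | None = None,
    group: str | None = None,
) -> ReferenceDistance:
    """Closest distance (µm) from a vessel's PVS to the reference polygon.

    The vessel side of the distance is its set of facing perimeter pixels
    (falling back to all perimeter pixels when none face an endfoot),
    converted to overview-frame µm coordinates via ``transform``.  Points on
    or inside the polygon are at distance 0 (even-odd rule, boundary counts
    as inside).

    Raises
    ------
    ValueError
        If the ROI label does not match the animal group (a syrinx outline
        for a control animal, or a central canal for a syrinx animal).
    """
    if roi.label not in ("syrinx", "central_canal"):
        raise ValueError(f"reference ROI must be syrinx|central_canal, got {roi.label!r}")
    if group is not None:
        expected = _GROUP_REFERENCE.get(group)
        if expected != roi.label:
            raise ValueError(
                f"group {group!r} requires a {expected!r} reference ROI, got {roi.label!r}"
            )
    pix = vessel.perimeter[profile.facing] if profile.facing.any() else vessel.perimeter
    xy_um = pix[:, ::-1].astype(float) * pixel_size  # (x, y) µm in tile frame
    if transform is not None:
        xy_um = transform.tile_to_overview_um(xy_um)
    poly = roi.shapely()
    pts = shapely.points(xy_um[:, 0], xy_um[:, 1])
    # shapely distance is 0 for points inside or on the polygon boundary
    d = shapely.distance(pts, poly)
    return ReferenceDistance(
        vessel_id=vessel.vessel_id,
        reference_label=roi.label,
        distance_um=float(np.min(d)),
    )
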