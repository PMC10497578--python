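"""Image, ROI and table I/O shared by all pipeline stages.

Conventions enforced at every module boundary:

* Pixel coordinates are 0-based ``(row, col)``.
* Polygon vertices are ``(x, y)`` with ``x = col`` and ``y = row``.
* ``pixel_size`` is a single isotropic µm/pixel scalar; anisotropic
  calibration is rejected rather than approximated.

Images are TIFF / OME-TIFF (multi-page = channels); ROIs are GeoJSON
FeatureCollections with a ``label`` property per feature.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

GROUPS = ("control", "syrinx")
LEVELS = ("above", "at", "below")
ROI_LABELS = ("syrinx", "central_canal", "manual_include", "manual_exclude")

#: micron tolerance when comparing X/Y pixel sizes from metadata
_ANISOTROPY_RTOL = 1e-6


class ConfigurationError(ValueError):
    """Raised when inputs disagree with the declared configuration."""


@dataclass
class MultiChannelSection:
    """A registered stack of 2-D channel images with physical calibration.

    Parameters
    ----------
    channels
        Mapping of channel label (e.g. ``"SMA"``, ``"GFAP"``) to a 2-D
        non-negative intensity raster.  All rasters must share one shape.
    pixel_size
        Isotropic pixel pitch in µm/pixel, strictly positive.
    stage_position
        ``(x, y)`` stage coordinates of the image origin in µm, or ``None``
        when the acquisition metadata carried none.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    stage_position: tuple[float, float] | None = None
    section_id: str = ""
    animal_id: str = ""
    group: str | None = None
    level: str | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("section must contain at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {sorted(shapes)}")
        for label, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {label!r} is not 2-D")
            if np.any(np.asarray(ch) < 0):
                raise ValueError(f"channel {label!r} has negative intensities")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.level is not None and self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, label: str) -> np.ndarray:
        """Look up a channel by label, case-insensitively."""
        for key, raster in self.channels.items():
            if key.lower() == label.lower():
                return raster
        raise KeyError(f"no channel labelled {label!r}; have {list(self.channels)}")


@dataclass
class RoiPolygon:
    """A manually drawn polygon (syrinx outline, central canal, selection region).

    Vertices are ``(x, y)`` pairs in either image-pixel or stage-µm
    coordinates; the polygon must be simple (non-self-intersecting) with at
    least three vertices.
    """

    vertices: list[tuple[float, float]]
    label: str
    coordinate_frame: str = "image"
    name: str = ""

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"ROI label must be one of {ROI_LABELS}, got {self.label!r}")
        if self.coordinate_frame not in ("image", "stage"):
            raise ValueError(f"coordinate_frame must be image|stage, got {self.coordinate_frame!r}")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError(
                f"ROI {self.name or self.label!r} needs >= 3 vertices, got {len(self.vertices)}"
            )
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_simple or poly.area == 0:
            raise ValueError(f"ROI {self.name or self.label!r} is self-intersecting or degenerate")

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


def _parse_ome_calibration(tf: tifffile.TiffFile):
    """Extract (pixel_size, stage_position) from OME-XML, if present."""
    if not tf.is_ome or tf.ome_metadata is None:
        return None, None
    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0][1:]} if root.tag.startswith("{") else {"ome": ""}
    pixels = root.find(".//ome:Pixels", ns)
    pixel_size = None
    if pixels is not None:
        sx, sy = pixels.get("PhysicalSizeX"), pixels.get("PhysicalSizeY")
        if sx is not None and sy is not None:
            sx, sy = float(sx), float(sy)
            if abs(sx - sy) > _ANISOTROPY_RTOL * max(sx, sy):
                raise ValueError(
                    f"anisotropic pixels unsupported: PhysicalSizeX={sx} != PhysicalSizeY={sy}"
                )
            pixel_size = sx
        elif sx is not None:
            pixel_size = float(sx)
    plane = root.find(".//ome:Plane", ns)
    stage = None
    if plane is not None:
        px, py = plane.get("PositionX"), plane.get("PositionY")
        if px is not None and py is not None:
            stage = (float(px), float(py))
    return pixel_size, stage


def read_section(
    path: str | Path,
    channel_map: Mapping[int, str],
    pixel_size_override: float | None = None,
    **meta,
) -> MultiChannelSection:
    """Read a multi-page TIFF / OME-TIFF into a :class:`MultiChannelSection`.

    ``channel_map`` assigns a label to each plane index.  The pixel size is
    taken from OME metadata unless ``pixel_size_override`` is given; missing
    stage metadata yields ``stage_position=None`` rather than an error.
    Extra keyword arguments (``section_id``, ``group``, ...) are forwarded to
    the section.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_pixel_size, stage = _parse_ome_calibration(tf)
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    data = np.atleast_2d(np.asarray(data))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ConfigurationError(f"{path}: expected 2-D planes, got array of shape {data.shape}")
    n_planes = data.shape[0]
    if set(channel_map) != set(range(n_planes)):
        raise ConfigurationError(
            f"{path}: channel_map indices {sorted(channel_map)} do not match "
            f"the {n_planes} plane(s) in the file"
        )
    pixel_size = pixel_size_override if pixel_size_override is not None else meta_pixel_size
    if pixel_size is None:
        raise ConfigurationError(
            f"{path}: no pixel size in metadata and no override given; "
            "physical calibration is required"
        )
    channels = {channel_map[i]: data[i] for i in range(n_planes)}
    return MultiChannelSection(
        channels=channels, pixel_size=float(pixel_size), stage_position=stage, **meta
    )


def write_section(path: str | Path, section: MultiChannelSection) -> None:
    """Write a section as OME-TIFF with pixel size and stage metadata."""
    path = Path(path)
    labels = list(section.channels)
    stack = np.stack([section.channels[k] for k in labels])
    metadata = {
        "axes": "CYX",
        "PhysicalSizeX": section.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": section.pixel_size,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": labels},
    }
    if section.stage_position is not None:
        x, y = section.stage_position
        n = len(labels)
        metadata["Plane"] = {
            "PositionX": [float(x)] * n,
            "PositionY": [float(y)] * n,
            "PositionXUnit": ["µm"] * n,
            "PositionYUnit": ["µm"] * n,
        }
    tifffile.imwrite(path, stack, ome=True, metadata=metadata)


def read_rois(path: str | Path) -> list[RoiPolygon]:
    """Read ROI polygons from a GeoJSON FeatureCollection.

    Every feature must be a Polygon with a ``label`` property; polygons are
    validated against the :class:`RoiPolygon` invariants and a
    self-intersecting outline raises a :class:`ValueError` naming the ROI.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    rois = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"{path}: feature {i} is not a Polygon")
        ring = geom["coordinates"][0]
        # GeoJSON closes the ring by repeating the first vertex
        if len(ring) >= 2 and ring[0] == ring[-1]:
            ring = ring[:-1]
        props = feat.get("properties") or {}
        rois.append(
            RoiPolygon(
                vertices=[tuple(v) for v in ring],
                label=props.get("label", ""),
                coordinate_frame=props.get("coordinate_frame", "image"),
                name=props.get("name", f"feature-{i}"),
            )
        )
    return rois


def write_rois(path: str | Path, rois: Sequence[RoiPolygon]) -> None:
    """Write ROI polygons as a GeoJSON FeatureCollection (lossless round-trip)."""
    features = []
    for roi in rois:
        ring = [list(v) for v in roi.vertices] + [list(roi.vertices[0])]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "label": roi.label,
                    "coordinate_frame": roi.coordinate_frame,
                    "name": roi.name,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
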