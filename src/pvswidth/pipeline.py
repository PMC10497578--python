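"""End-to-end section processing: segmentation through width profiles.

This is the in-memory orchestration layer the CLI wraps: given a
:class:`~pvswidth.io.MultiChannelSection` and a parameter mapping it runs
ratio-image segmentation on the vessel-wall and endfoot channels, closes the
vessel perimeters, builds the distance map, selects endfeet, and measures
per-vessel width profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MultiChannelSection
from .measurement import (
    DistanceMap,
    EndfootRegion,
    WidthProfile,
    compute_vessel_distance_map,
    measure_pvs_width,
    select_endfeet,
)
from .segmentation import (
    FilterConfig,
    SegmentedObject,
    VesselRegion,
    background_peak_threshold,
    close_vessel_boundary,
    compute_ratio_image,
    filter_objects,
    segment_bright_objects,
)

#: default parameters; every key can be overridden from the run config
DEFAULT_PARAMS: dict = {
    "sigma_small": 1.0,
    "sigma_large": 4.0,
    "fraction": 0.77,
    "n_bins": 256,
    "auto_radius_um": 2.5,
    "half_angle_deg": 10.0,
    "max_ray_um": 10.0,
    "closing_radius_px": 2,
    "max_iterations": 5,
    "min_area_px": 20,
    "max_area_px": None,
    "min_mean_intensity": None,
    "min_boundary_contrast": None,
    "mid_anchor_um": 0.78,
    "max_anchor_um": 1.56,
    "vessel_channel": "SMA",
    "endfoot_channel": "GFAP",
}


@dataclass
class SectionResult:
    """All artefacts of processing one section."""

    section: MultiChannelSection
    vessel_objects: list[SegmentedObject]
    endfoot_objects: list[SegmentedObject]
    vessels: list[VesselRegion]
    endfeet: list[EndfootRegion]
    distance_map: DistanceMap
    profiles: list[WidthProfile]


def _params(overrides: Mapping | None) -> dict:
    p = dict(DEFAULT_PARAMS)
    if overrides:
        unknown = set(overrides) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        p.update(overrides)
    return p


def segment_channel(
    section: MultiChannelSection,
    channel_label: str,
    params: Mapping | None = None,
    manual_overrides: Mapping[int, bool] | None = None,
) -> list[SegmentedObject]:
    """Ratio → threshold → label → filter for one channel."""
    p = _params(params)
    raw = section.channel(channel_label)
    ratio = compute_ratio_image(
        raw, sigma_small=p["sigma_small"], sigma_large=p["sigma_large"],
        source_channel=channel_label,
    )
    thr = background_peak_threshold(ratio, fraction=p["fraction"], n_bins=p["n_bins"])
    labels = segment_bright_objects(ratio, thr)
    cfg = FilterConfig(
        min_area_px=p["min_area_px"],
        max_area_px=p["max_area_px"],
        min_mean_intensity=p["min_mean_intensity"],
        min_boundary_contrast=p["min_boundary_contrast"],
    )
    return filter_objects(
        labels, raw, config=cfg, pixel_size=section.pixel_size,
        manual_overrides=manual_overrides,
    )


def process_section(
    section: MultiChannelSection,
    params: Mapping | None = None,
    vessel_overrides: Mapping[int, bool] | None = None,
    endfoot_overrides: Mapping[int, bool] | None = None,
    manual_endfoot_ids: Sequence[int] = (),
) -> SectionResult:
    """Run the whole per-section pipeline and return every intermediate."""
    p = _params(params)
    vessel_objs = segment_channel(section, p["vessel_channel"], p, vessel_overrides)
    endfoot_objs = segment_channel(section, p["endfoot_channel"], p, endfoot_overrides)

    vessels = []
    for obj in vessel_objs:
        if not obj.selected:
            continue
        try:
            vessels.append(
                close_vessel_boundary(
                    obj, closing_radius_px=p["closing_radius_px"],
                    max_iterations=p["max_iterations"],
                )
            )
        except ValueError as exc:
            warnings.warn(f"PVW01 skipping unclosable vessel: {exc}", stacklevel=2)
    if not vessels:
        raise ValueError("no closable vessel wall found in section")

    dmap = compute_vessel_distance_map(vessels, section.shape, section.pixel_size)
    endfeet = select_endfeet(
        [o for o in endfoot_objs if o.selected],
        dmap,
        auto_radius_um=p["auto_radius_um"],
        manual_ids=manual_endfoot_ids,
    )
    profiles = [
        measure_pvs_width(
            v, endfeet, dmap,
            half_angle_deg=p["half_angle_deg"], max_ray_um=p["max_ray_um"],
        )
        for v in vessels
    ]
    return SectionResult(
        section=section,
        vessel_objects=vessel_objs,
        endfoot_objects=endfoot_objs,
        vessels=vessels,
        endfeet=endfeet,
        distance_map=dmap,
        profiles=profiles,
    )


def object_table(objects: Sequence[SegmentedObject], object_class: str) -> pd.DataFrame:
    """Object-level CSV schema (one row per segmented object)."""
    return pd.DataFrame(
        [
            dict(
                object_id=o.object_id,
                object_class=object_class,
                area_px=o.area_px,
                area_um2=o.area_um2,
                mean_intensity=o.mean_intensity,
                boundary_contrast=o.boundary_contrast,
                selected=o.selected,
                selection_source=o.selection_source,
            )
            for o in objects
        ]
    )


def per_pixel_table(result: SectionResult) -> pd.DataFrame:
    """Long-format per-perimeter-pixel widths (vessel, pixel, facing, width)."""
    rows = []
    for prof in result.profiles:
        for i in range(prof.n_perimeter):
            rows.append(
                dict(
                    vessel_id=prof.vessel_id,
                    pixel_index=i,
                    facing=bool(prof.facing[i]),
                    width_um=prof.widths_um[i] if prof.facing[i] else np.nan,
                )
            )
    return pd.DataFrame(rows)


def profile_table(result: SectionResult) -> pd.DataFrame:
    """Per-vessel width summary CSV schema."""
    rows = []
    for prof in result.profiles:
        q = prof.quintile_means_um
        rows.append(
            dict(
                vessel_id=prof.vessel_id,
                section_id=result.section.section_id,
                n_perimeter=prof.n_perimeter,
                n_facing=prof.n_facing,
                mean_width_um=prof.mean_width_um,
                q1_um=q[0] if q is not None else np.nan,
                q2_um=q[1] if q is not None else np.nan,
                q3_um=q[2] if q is not None else np.nan,
                q4_um=q[3] if q is not None else np.nan,
                q5_um=q[4] if q is not None else np.nan,
                flag_few_facing=prof.n_facing < 5,
            )
        )
    return pd.DataFrame(rows)
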