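"""Synthetic phantoms with known ground truth.

Two generators stand in for the (undeposited) confocal data:

* :func:`generate_section` renders a multi-channel section — annular
  vessel walls in the SMA channel, astrocytic-endfoot sheaths at a
  controlled radial gap in the GFAP channel, optional wall gap arcs, and
  Poisson + Gaussian noise — so the full image pipeline can be tested
  against the true gap widths.
* :func:`generate_cohort` draws per-vessel width samples from a two-level
  log-normal model (vessel-to-vessel and within-vessel variation) for the
  2-group × 3-level × 2-animal study design, with an optional
  multiplicative width effect injected in one group × level cell
  (optionally restricted to the upper quintiles), and emits the per-vessel
  record table the statistics layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GROUPS, LEVELS, MultiChannelSection
from .measurement import summarize_vessel


@dataclass
class VesselSpec:
    """An annular vessel wall: ring of ``wall_thickness_px`` ending at
    ``outer_radius_px`` around ``center_px`` (row, col)."""

    center_px: tuple[float, float]
    outer_radius_px: float
    wall_thickness_px: float = 3.0
    wall_intensity: float = 100.0


@dataclass
class EndfootSpec:
    """An endfoot sheath around one vessel at constant radial gap.

    ``gap_um`` is the true PVS width (wall outer edge to sheath inner
    edge); ``angular_coverage_deg`` < 360 leaves part of the perimeter
    without a facing endfoot.
    """

    parent_vessel: int
    gap_um: float
    sheath_thickness_px: float = 4.0
    angular_coverage_deg: float = 360.0
    start_angle_deg: float = 0.0
    intensity: float = 100.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic section; ``seed`` fixes all noise."""

    image_size_px: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.156
    vessels: list[VesselSpec] = field(default_factory=list)
    endfeet: list[EndfootSpec] = field(default_factory=list)
    #: (vessel_index, start_deg, extent_deg) arcs removed from the wall
    wall_gap_arcs: list[tuple[int, float, float]] = field(default_factory=list)
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0
    background_level: float = 10.0
    stage_position_um: tuple[float, float] | None = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for e in self.endfeet:
            if e.gap_um < 0:
                raise ValueError("gap_um must be >= 0")
            if not (0 < e.angular_coverage_deg <= 360):
                raise ValueError("angular_coverage_deg must be in (0, 360]")


@dataclass
class GroundTruth:
    """True geometry of a rendered section, per vessel."""

    gap_um: list[float]
    facing_fraction: list[float]
    wall_masks: list[np.ndarray]
    endfoot_masks: list[np.ndarray]


def _angle_in_arc(theta_deg: np.ndarray, start: float, extent: float) -> np.ndarray:
    rel = np.mod(theta_deg - start, 360.0)
    return rel < extent


def _vessel_extent_px(spec: PhantomSpec, i: int) -> float:
    """Outer radius of vessel i including its sheath, in pixels."""
    v = spec.vessels[i]
    ext = v.outer_radius_px
    for e in spec.endfeet:
        if e.parent_vessel == i:
            ext = max(ext, v.outer_radius_px + e.gap_um / spec.pixel_size_um + e.sheath_thickness_px)
    return ext


def generate_section(spec: PhantomSpec) -> tuple[MultiChannelSection, GroundTruth]:
    """Render a synthetic SMA/GFAP section with known gap widths.

    Deterministic given ``spec.seed``.  Raises ``ValueError`` when vessels
    (including their sheaths) would overlap or spill over the image border —
    either would make the ground truth ambiguous.
    """
    h, w = spec.image_size_px
    if not spec.vessels:
        raise ValueError("phantom needs at least one vessel")
    margin = 2.0
    for i, v in enumerate(spec.vessels):
        ext = _vessel_extent_px(spec, i)
        cy, cx = v.center_px
        if cy - ext < margin or cx - ext < margin or cy + ext > h - margin or cx + ext > w - margin:
            raise ValueError(f"vessel {i} (extent {ext:.1f} px) does not fit inside the image")
        for j in range(i):
            cj = spec.vessels[j].center_px
            d = np.hypot(cy - cj[0], cx - cj[1])
            if d < ext + _vessel_extent_px(spec, j) + margin:
                raise ValueError(f"vessels {j} and {i} overlap; ground truth would be ambiguous")

    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    sma = np.zeros((h, w))
    gfap = np.zeros((h, w))
    wall_masks, endfoot_masks, gaps, fracs = [], [], [], []

    for i, v in enumerate(spec.vessels):
        cy, cx = v.center_px
        r = np.hypot(rows - cy, cols - cx)
        theta = np.degrees(np.arctan2(rows - cy, cols - cx))
        # half-open annulus [R-t, R): pixel count equals the difference of
        # two disk counts, keeping discretization error at the few-% level
        wall = (r < v.outer_radius_px) & (r >= v.outer_radius_px - v.wall_thickness_px)
        for vi, start, extent in spec.wall_gap_arcs:
            if vi == i:
                wall &= ~_angle_in_arc(theta, start, extent)
        sma[wall] = np.maximum(sma[wall], v.wall_intensity)
        wall_masks.append(wall)

        ef_mask = np.zeros((h, w), dtype=bool)
        gap_um = np.nan
        coverage = 0.0
        for e in spec.endfeet:
            if e.parent_vessel != i:
                continue
            gap_px = e.gap_um / spec.pixel_size_um
            inner = v.outer_radius_px + gap_px
            sheath = (r >= inner) & (r < inner + e.sheath_thickness_px)
            if e.angular_coverage_deg < 360:
                sheath &= _angle_in_arc(theta, e.start_angle_deg, e.angular_coverage_deg)
            gfap[sheath] = np.maximum(gfap[sheath], e.intensity)
            ef_mask |= sheath
            gap_um = e.gap_um
            coverage += e.angular_coverage_deg
        endfoot_masks.append(ef_mask)
        gaps.append(float(gap_um))
        fracs.append(min(coverage, 360.0) / 360.0)

    rng = np.random.default_rng(spec.seed)
    channels = {}
    for name, img in (("SMA", sma), ("GFAP", gfap)):
        out = img + spec.background_level
        if spec.poisson_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * spec.poisson_scale) / spec.poisson_scale
        if spec.gaussian_sd > 0:
            out = out + rng.normal(0.0, spec.gaussian_sd, size=out.shape)
        channels[name] = np.clip(out, 0, None)

    section = MultiChannelSection(
        channels=channels,
        pixel_size=spec.pixel_size_um,
        stage_position=spec.stage_position_um,
        section_id=f"phantom-seed{spec.seed}",
    )
    truth = GroundTruth(
        gap_um=gaps, facing_fraction=fracs,
        wall_masks=wall_masks, endfoot_masks=endfoot_masks,
    )
    return section, truth


@dataclass
class CohortModel:
    """Two-level log-normal width model for a synthetic vessel cohort.

    Widths within a vessel are log-normal around a vessel-specific median,
    which is itself log-normal around the population median — chosen so the
    quintile spread (narrowest ≈ 0.2 µm, widest ≈ 2 µm around a ≈ 0.85 µm
    mean) resembles arteriolar PVS morphometry in cleared rodent spinal
    cord.  ``effect_multiplier`` scales widths in the
    ``effect_group`` × ``effect_level`` cell; ``effect_quintiles`` restricts
    the scaling to the listed quintiles (1..5) of each vessel's sorted
    widths.
    """

    animals_per_group: int = 2
    vessels_per_animal_level: int = 25
    samples_per_vessel: int = 100
    median_width_um: float = 0.57
    sigma_within: float = 0.9
    sigma_vessel: float = 0.35
    animal_sigma: float = 0.0
    effect_group: str = "syrinx"
    effect_level: str = "at"
    effect_multiplier: float = 1.0
    effect_quintiles: tuple[int, ...] | None = None


def generate_cohort(
    model: CohortModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic per-vessel record table with known effect sizes.

    Returns the record table (statistics-module schema) and a dict of the
    true generative parameters.
    """
    model = model or CohortModel()
    rng = np.random.default_rng(seed)
    rows = []
    vid = 0
    for group in GROUPS:
        for a in range(model.animals_per_group):
            animal_id = f"{group}-{a + 1}"
            animal_factor = float(np.exp(rng.normal(0.0, model.animal_sigma))) if model.animal_sigma > 0 else 1.0
            for level in LEVELS:
                for _ in range(model.vessels_per_animal_level):
                    vessel_median = (
                        model.median_width_um
                        * animal_factor
                        * float(np.exp(rng.normal(0.0, model.sigma_vessel)))
                    )
                    widths = vessel_median * np.exp(
                        rng.normal(0.0, model.sigma_within, size=model.samples_per_vessel)
                    )
                    if (
                        model.effect_multiplier != 1.0
                        and group == model.effect_group
                        and level == model.effect_level
                    ):
                        widths = _apply_effect(
                            widths, model.effect_multiplier, model.effect_quintiles
                        )
                    mean, q = summarize_vessel(widths)
                    rows.append(
                        dict(
                            vessel_id=vid,
                            animal_id=animal_id,
                            group=group,
                            level=level,
                            mean_width_um=mean,
                            q1_um=q[0], q2_um=q[1], q3_um=q[2], q4_um=q[3], q5_um=q[4],
                        )
                    )
                    vid += 1
    truth = {
        "effect_group": model.effect_group,
        "effect_level": model.effect_level,
        "effect_multiplier": model.effect_multiplier,
        "effect_quintiles": model.effect_quintiles,
        "median_width_um": model.median_width_um,
    }
    return pd.DataFrame(rows), truth


def _apply_effect(
    widths: np.ndarray, multiplier: float, quintiles: tuple[int, ...] | None
) -> np.ndarray:
    if quintiles is None:
        return widths * multiplier
    order = np.argsort(widths, kind="stable")
    n = len(widths)
    out = widths.copy()
    for k in quintiles:
        lo, hi = ((k - 1) * n) // 5, (k * n) // 5
        out[order[lo:hi]] *= multiplier
    return out
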