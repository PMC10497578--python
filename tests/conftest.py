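import numpy as np
import pytest

from pvswidth.phantom import EndfootSpec, PhantomSpec, VesselSpec, generate_section
from pvswidth.segmentation import SegmentedObject

#: per-image filter settings suited to the default phantom contrast
#: (wall/sheath intensity 100 on background 20, read noise sd 10)
PHANTOM_FILTERS = dict(min_area_px=50, min_mean_intensity=60.0)


def ring_mask(shape, center, outer_r, inner_r):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r = np.hypot(rows - center[0], cols - center[1])
    return (r <= outer_r) & (r > inner_r)


def disk_mask(shape, center, radius):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return np.hypot(rows - center[0], cols - center[1]) <= radius


def make_object(mask, object_id=1, **kw):
    defaults = dict(
        area_px=int(mask.sum()),
        area_um2=float(mask.sum()),
        mean_intensity=100.0,
        boundary_contrast=100.0,
        selected=True,
        selection_source="auto",
    )
    defaults.update(kw)
    return SegmentedObject(object_id=object_id, mask=mask, **defaults)


def phantom_spec(gap_um=1.0, coverage=360.0, seed=0, noisy=True, outer_radius_px=10.0):
    return PhantomSpec(
        image_size_px=(224, 224),
        pixel_size_um=0.156,
        vessels=[
            VesselSpec(
                center_px=(112, 112),
                outer_radius_px=outer_radius_px,
                wall_thickness_px=3.0,
                wall_intensity=100.0,
            )
        ],
        endfeet=[
            EndfootSpec(
                parent_vessel=0,
                gap_um=gap_um,
                sheath_thickness_px=4.0,
                angular_coverage_deg=coverage,
            )
        ],
        gaussian_sd=10.0 if noisy else 0.0,
        background_level=20.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def noisy_section():
    """One noisy full-ring phantom (gap 1 µm) reused across read-only tests."""
    return generate_section(phantom_spec(gap_um=1.0, seed=42))
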