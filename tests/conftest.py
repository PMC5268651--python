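import numpy as np
import pytest

from nucseg.core import CalibratedImage, NucleusContour
from nucseg.synth import BlebSpec, FieldSpec, NucleusSpec, render_field


def circle_contour(cx, cy, radius, n=128, nucleus_id=1, stage="initial"):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([cx + radius * np.cos(t), cy + radius * np.sin(t)])
    return NucleusContour(points=pts, stage=stage, nucleus_id=nucleus_id)


def square_contour(x0, y0, side, nucleus_id=1, stage="initial", n_per_side=16):
    t = np.linspace(0, side, n_per_side, endpoint=False)
    pts = np.concatenate([
        np.column_stack([x0 + t, np.full_like(t, y0)]),
        np.column_stack([np.full_like(t, x0 + side), y0 + t]),
        np.column_stack([x0 + side - t, np.full_like(t, y0 + side)]),
        np.column_stack([np.full_like(t, x0), y0 + side - t]),
    ])
    return NucleusContour(points=pts, stage=stage, nucleus_id=nucleus_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_image():
    """Bright disk (radius 20 px) on a dark background, no noise."""
    yy, xx = np.mgrid[0:96, 0:96]
    r = np.hypot(xx - 48, yy - 48)
    px = np.where(r <= 20, 200.0, 10.0)
    return CalibratedImage(pixels=px, pixel_size_um=0.5)


@pytest.fixture(scope="session")
def blebbed_field():
    """One nucleus with a dim bleb (30% body intensity), rendered with noise."""
    bleb = BlebSpec(neck_angle=0.5, neck_width_um=1.8, bleb_radius_um=2.0,
                    intensity_fraction=0.3)
    nuc = NucleusSpec(center_um=(14.0, 14.0), semi_axes_um=(5.5, 4.5),
                      blebs=(bleb,), class_label="dysmorphic")
    spec = FieldSpec(shape_px=(140, 140), nuclei=(nuc,), seed=3)
    img, mask, table = render_field(spec)
    return {"spec": spec, "image": img, "mask": mask, "table": table}
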