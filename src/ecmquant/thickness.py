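"""Cuticle-layer thickness from traced electron-microscopy layer borders.

Each cuticular layer border is a one-pixel-thick binary curve traced on a
transverse TEM section.  The thickness between two borders A and B is the mean
over every pixel of both curves of its shortest Euclidean distance to the
other curve, computed with an exact Euclidean distance transform.  Pixel
distances convert to micrometers via the scale-bar calibration
f = 25000 / (m * s), where m is the magnification, s the measured scale-bar
length in pixels, and 25000 um the printed 2.5 cm scale-bar length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, ShapeMismatchError

SCALE_BAR_UM = 25000.0  # printed scale bar is 2.5 cm


@dataclass
class LayerTrace:
    """One-pixel-thick binary curve marking one cuticle-layer border."""

    mask: np.ndarray
    layer_name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ShapeMismatchError("trace mask must be 2D")
        if self.mask.sum() < 2:
            raise EmptyMaskError(
                f"trace {self.layer_name!r} needs at least 2 pixels"
            )
        # thinness: no member pixel may have a full 3x3 member neighborhood
        filled = ndimage.minimum_filter(self.mask, size=3, mode="constant")
        if np.any(filled & self.mask):
            warnings.warn(
                f"trace {self.layer_name!r} is not 1 pixel thick (contains blobs)",
                stacklevel=2,
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CalibrationSpec:
    m: float
    s: float
    f: float = field(init=False)

    def __post_init__(self) -> None:
        if self.m <= 0 or self.s <= 0:
            raise ValueError("magnification and scale-bar length must be positive")
        self.f = SCALE_BAR_UM / (self.m * self.s)


@dataclass
class ThicknessResult:
    mean_px: float
    mean_um: float | None
    n_a: int
    n_b: int


def calibration_factor(m: float, s: float) -> CalibrationSpec:
    """Micrometer-per-pixel conversion factor f = 25000 / (m * s)."""
    return CalibrationSpec(m=m, s=s)


def curve_distance(
    a: LayerTrace, b: LayerTrace, cal: CalibrationSpec | None = None
) -> ThicknessResult:
    """Mean shortest Euclidean distance between two traced curves.

    For every pixel of B the nearest distance to A (read off the exact
    Euclidean distance transform of A), symmetrically for every pixel of A
    against B; the mean is taken over the concatenation of both distance
    vectors, so each pixel contributes once.
    """
    if a.mask.shape != b.mask.shape:
        raise ShapeMismatchError(
            f"trace shapes differ: {a.mask.shape} vs {b.mask.shape}"
        )
    # distance_transform_edt gives, for each background pixel, the exact
    # distance to the nearest foreground pixel
    a_dmap = ndimage.distance_transform_edt(~a.mask)
    b_dmap = ndimage.distance_transform_edt(~b.mask)
    dist_b_to_a = a_dmap[b.mask]
    dist_a_to_b = b_dmap[a.mask]
    mean_px = float(np.concatenate([dist_a_to_b, dist_b_to_a]).mean())
    mean_um = mean_px * cal.f if cal is not None else None
    return ThicknessResult(
        mean_px=mean_px, mean_um=mean_um, n_a=a.n_pixels, n_b=b.n_pixels
    )


def layer_report(traces, cal: CalibrationSpec) -> pd.DataFrame:
    """Adjacent-pair layer thicknesses plus the outermost-pair total (um)."""
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("layer report needs at least 2 traces")
    rows = []
    for t0, t1 in zip(traces[:-1], traces[1:]):
        res = curve_distance(t0, t1, cal)
        rows.append(
            {
                "layer_pair": f"{t0.layer_name}|{t1.layer_name}",
                "mean_px": res.mean_px,
                "f": cal.f,
                "mean_um": res.mean_um,
            }
        )
    total = curve_distance(traces[0], traces[-1], cal)
    rows.append(
        {
            "layer_pair": f"total:{traces[0].layer_name}|{traces[-1].layer_name}",
            "mean_px": total.mean_px,
            "f": cal.f,
            "mean_um": total.mean_um,
        }
    )
    return pd.DataFrame(rows)
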