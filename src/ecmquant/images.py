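"""Image and mask data model shared by every image-quantification stage.

Multi-channel fluorescence frames are stored as named 2D rasters that share a
shape; z-stacks are ordered sequences of such frames.  Regions of interest are
binary masks carrying a role tag (worm body, photoconverted stripe, flanking
regions, or a generic anatomical region).  Conventions: row-major rasters,
0-based indices, pixel centers at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import EmptyMaskError, MissingChannelError, ShapeMismatchError

ROI_ROLES = ("body", "photoconverted", "flank_left", "flank_right", "region")


@dataclass
class MultiChannelImage:
    """Named 2D channel rasters sharing one shape.

    Parameters
    ----------
    channels : mapping of str -> 2D ndarray
        Nonnegative intensities in arbitrary units.  All rasters must have
        identical shape.
    pixel_size : float, optional
        Physical edge length of one pixel in micrometers.
    bit_depth : int
        8 or 16; bounds the maximum representable intensity.
    """

    channels: dict
    pixel_size: float | None = None
    bit_depth: int = 16
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image must have at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"channel shapes differ: {sorted(shapes)}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}
        shape = next(iter(shapes))
        if len(shape) != 2:
            raise ShapeMismatchError(f"channels must be 2D, got shape {shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        for name, arr in self.channels.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class ZStack:
    """Ordered sequence of shape- and channel-compatible frames."""

    slices: Sequence[MultiChannelImage]
    z_step: float | None = None

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValueError("z-stack must contain at least one slice")
        first = self.slices[0]
        for i, sl in enumerate(self.slices):
            if sl.shape != first.shape:
                raise ShapeMismatchError(f"slice {i} shape {sl.shape} != {first.shape}")
            if set(sl.channels) != set(first.channels):
                raise ShapeMismatchError(f"slice {i} channel names differ")


@dataclass
class ROIMask:
    """Binary pixel-membership mask with a role tag."""

    mask: np.ndarray
    role: str = "region"
    label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(f"role must be one of {ROI_ROLES}, got {self.role!r}")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ShapeMismatchError("mask must be 2D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> "ROIMask":
        if self.n_pixels == 0:
            raise EmptyMaskError(f"mask role={self.role!r} label={self.label!r} is empty")
        return self


# ---------------------------------------------------------------------------
# I/O


def read_image(path, channel_map: Mapping | None = None) -> MultiChannelImage:
    """Read a TIFF as a multi-channel image.

    Grayscale files become a single channel; multi-plane files are mapped via
    ``channel_map`` (plane index or color name -> channel name); RGB files
    default to channels red/green/blue.  Intensities are preserved bit-exactly.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        name = "gray"
        if channel_map:
            name = next(iter(channel_map.values()))
        planes = {name: arr}
    elif arr.ndim == 3:
        # channel axis: last for RGB (size 3/4 uint8), else first
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            default = ["red", "green", "blue", "alpha"][: arr.shape[-1]]
            planes = {default[i]: arr[..., i] for i in range(arr.shape[-1])}
        else:
            n = arr.shape[0]
            if channel_map is None:
                raise ValueError(
                    f"{n}-plane TIFF requires a channel_map naming each plane"
                )
            names = _resolve_plane_names(channel_map, n)
            planes = {names[i]: arr[i] for i in range(n)}
        if channel_map and set(channel_map.values()) - set(planes):
            # rename default RGB planes per the map (e.g. {"red": "acceptor"})
            planes = {channel_map.get(k, k): v for k, v in planes.items()}
    else:
        raise ValueError(f"cannot interpret TIFF with shape {arr.shape} as 2D image")
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return MultiChannelImage(channels=planes, bit_depth=bit_depth)


def _resolve_plane_names(channel_map: Mapping, n: int) -> list:
    names = [None] * n
    for key, value in channel_map.items():
        if isinstance(key, str) and key.startswith("plane"):
            idx = int(key[5:])
        else:
            idx = int(key)
        if not 0 <= idx < n:
            raise ValueError(f"channel_map index {idx} out of range for {n} planes")
        names[idx] = value
    if any(v is None for v in names):
        raise ValueError(f"channel_map must name all {n} planes")
    return names


def write_image(path, img: MultiChannelImage, channel_order: Sequence | None = None) -> None:
    """Write channels as a multi-plane TIFF (plane order = ``channel_order``)."""
    order = list(channel_order) if channel_order is not None else sorted(img.channels)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    stack = np.stack([np.asarray(img.channels[name]).astype(dtype) for name in order])
    if stack.shape[0] == 1:
        tifffile.imwrite(str(path), stack[0])
    else:
        tifffile.imwrite(str(path), stack)


def read_mask(path, role: str = "region", label: str = "") -> ROIMask:
    """Read a single-plane TIFF/PNG mask; nonzero pixels are members.

    If a JSON sidecar ``<path>.json`` with keys role/label exists it overrides
    the arguments.
    """
    p = Path(path)
    if p.suffix.lower() == ".png":
        from imageio.v3 import imread as _imread

        arr = np.asarray(_imread(p))
        if arr.ndim == 3:
            arr = arr[..., 0]
    else:
        arr = tifffile.imread(str(p))
    sidecar = p.with_suffix(p.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        role = meta.get("role", role)
        label = meta.get("label", label)
    return ROIMask(mask=arr != 0, role=role, label=label)


def write_mask(path, roi: ROIMask) -> None:
    tifffile.imwrite(str(path), roi.mask.astype(np.uint8) * 255)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"role": roi.role, "label": roi.label}))


# ---------------------------------------------------------------------------
# Projections and flank-mask geometry


def max_project(stack: ZStack) -> MultiChannelImage:
    """Per-channel, per-pixel maximum over slices."""
    first = stack.slices[0]
    channels = {}
    for name in first.channels:
        channels[name] = np.maximum.reduce(
            [sl.channel(name) for sl in stack.slices]
        )
    return MultiChannelImage(
        channels=channels,
        pixel_size=first.pixel_size,
        bit_depth=first.bit_depth,
        metadata=dict(first.metadata),
    )


def build_flank_masks(
    roi: ROIMask,
    body: ROIMask,
    gap_px: int = 0,
    width_px: int | None = None,
) -> tuple:
    """Construct the two flanking masks on either side of a photoconverted region.

    The flank axis is the longer side of the roi bounding box (worms are imaged
    lengthwise).  Each flank is offset ``gap_px`` from the roi bounding box and
    extends ``width_px`` along the axis (default: the roi extent), spans the roi
    bounding box across the axis, and is intersected with the body and stripped
    of any roi pixels.
    """
    roi.require_nonempty()
    body.require_nonempty()
    if gap_px < 0:
        raise ValueError("gap_px must be >= 0")
    rows, cols = np.nonzero(roi.mask)
    r0, r1 = rows.min(), rows.max() + 1  # half-open
    c0, c1 = cols.min(), cols.max() + 1
    axis = 1 if (c1 - c0) >= (r1 - r0) else 0  # longer side of the bbox
    extent = (c1 - c0) if axis == 1 else (r1 - r0)
    if width_px is None:
        width_px = extent
    if width_px < 1:
        raise ValueError("width_px must be >= 1")

    shape = body.mask.shape
    if roi.mask.shape != shape:
        raise ShapeMismatchError("roi and body masks must share a shape")

    def _box(lo_axis, hi_axis):
        m = np.zeros(shape, dtype=bool)
        lo_axis = max(lo_axis, 0)
        hi_axis = max(hi_axis, 0)
        if axis == 1:
            m[r0:r1, lo_axis:hi_axis] = True
        else:
            m[lo_axis:hi_axis, c0:c1] = True
        return m & body.mask & ~roi.mask

    lo, hi = (c0, c1) if axis == 1 else (r0, r1)
    left = _box(lo - gap_px - width_px, lo - gap_px)
    right = _box(hi + gap_px, hi + gap_px + width_px)
    for side, m in (("left", left), ("right", right)):
        if not m.any():
            raise EmptyMaskError(
                f"{side} flank falls entirely outside the body mask"
            )
    return (
        ROIMask(mask=left, role="flank_left", label=roi.label),
        ROIMask(mask=right, role="flank_right", label=roi.label),
    )
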