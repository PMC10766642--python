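"""Per-pixel channel-arithmetic quantifications.

Three measurements operate on registered channel pairs inside a region of
interest:

* autofluorescence-corrected reporter intensity — gut autofluorescence appears
  in both the red and green channels, so subtracting red from green per pixel
  cancels it while leaving the green-only GFP reporter signal; pixels below a
  noise threshold are discarded;
* FRET ratio images — per-pixel acceptor/donor emission ratio after constant
  background subtraction, defined only where the donor is sufficiently bright;
* pixel colocalization — Pearson correlation of the (red, green) intensity
  pairs over the region, read as spatial co-occurrence of the two proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    EmptyMaskError,
    UndefinedStatisticError,
    ZeroVarianceError,
)
from .images import MultiChannelImage, ROIMask


@dataclass
class IntensityResult:
    """Corrected-intensity summary over one region of interest."""

    total: float
    pixel_count: int
    mean_per_pixel: float
    threshold: float


@dataclass
class RatioImage:
    """Acceptor/donor ratio raster with its validity mask."""

    ratio: np.ndarray
    valid: np.ndarray
    background: dict


@dataclass
class ColocResult:
    r: float
    n_pixels: int
    region_label: str = ""


def corrected_intensity(
    img: MultiChannelImage, roi: ROIMask, threshold: float = 0.0
) -> IntensityResult:
    """Autofluorescence-corrected green intensity inside ``roi``.

    Per pixel, corrected = max(green - red, 0); pixels whose corrected value
    falls below ``threshold`` are treated as background noise and contribute
    neither intensity nor count.  Returns the summed intensity, the number of
    contributing pixels, and their mean.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    roi.require_nonempty()
    green = np.asarray(img.channel("green"), dtype=float)
    red = np.asarray(img.channel("red"), dtype=float)
    corrected = np.clip(green - red, 0.0, None)[roi.mask]
    # "remaining" pixels carry signal: strictly positive corrected intensity
    # at or above the noise threshold
    keep = (corrected > 0) & (corrected >= threshold)
    vals = corrected[keep]
    total = float(vals.sum())
    count = int(keep.sum())
    mean = total / count if count else 0.0
    return IntensityResult(total=total, pixel_count=count, mean_per_pixel=mean, threshold=threshold)


def fret_ratio_image(
    img: MultiChannelImage,
    donor_threshold: float,
    background: dict | None = None,
    formula: str = "acceptor/donor",
) -> RatioImage:
    """Construct a per-pixel FRET ratio image.

    ratio = (acceptor - bg_acc) / (donor - bg_don) wherever the
    background-subtracted donor is at least ``donor_threshold``; elsewhere the
    ratio is undefined (NaN, excluded from the valid mask).  The alternative
    formula ``"acceptor/(donor+acceptor)"`` expresses the ratio as a
    transmission fraction.
    """
    if donor_threshold <= 0:
        raise ValueError("donor_threshold must be > 0")
    background = dict(background or {})
    bg_don = float(background.get("donor", 0.0))
    bg_acc = float(background.get("acceptor", 0.0))
    donor = np.asarray(img.channel("donor"), dtype=float) - bg_don
    acceptor = np.asarray(img.channel("acceptor"), dtype=float) - bg_acc
    valid = donor >= donor_threshold
    ratio = np.full(donor.shape, np.nan)
    if formula == "acceptor/donor":
        np.divide(acceptor, donor, out=ratio, where=valid)
    elif formula == "acceptor/(donor+acceptor)":
        denom = donor + acceptor
        ok = valid & (denom != 0)
        np.divide(acceptor, denom, out=ratio, where=ok)
        valid = ok
    else:
        raise ValueError(f"unknown FRET formula {formula!r}")
    return RatioImage(ratio=ratio, valid=valid, background={"donor": bg_don, "acceptor": bg_acc})


def fret_region_mean(ratio_img: RatioImage, roi: ROIMask | None = None) -> float:
    """Mean ratio over valid pixels (optionally restricted to a region)."""
    sel = ratio_img.valid
    label = "image"
    if roi is not None:
        sel = sel & roi.mask
        label = roi.label or roi.role
    if not sel.any():
        raise UndefinedStatisticError(
            f"FRET region mean undefined: no valid pixel in {label}"
        )
    return float(ratio_img.ratio[sel].mean())


def fret_group_compare(
    ratios_a, ratios_b, equal_var: bool = False
) -> tuple:
    """Difference of means and two-sided p-value between two animal groups.

    Welch's unequal-variance t-test by default (``equal_var=True`` pools).
    Degenerate zero-variance convention: both groups constant and equal
    means -> p = 1; constant with unequal means -> p = 0 (warned).
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 animals")
    delta = float(a.mean() - b.mean())
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if delta == 0 else 0.0
        warnings.warn(
            "both groups have zero variance; p-value set by degenerate convention",
            stacklevel=2,
        )
        return delta, p
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return delta, float(t.pvalue)


def pixel_colocalization(
    img: MultiChannelImage, roi: ROIMask, method: str = "pearson"
) -> ColocResult:
    """Correlation of per-pixel red and green intensities over the region.

    Pearson by default (an arbitrary linear relation between the two markers
    indicates spatial co-occurrence below the pixel scale); Spearman optional.
    """
    roi.require_nonempty()
    if roi.n_pixels < 3:
        raise EmptyMaskError("colocalization needs at least 3 roi pixels")
    red = np.asarray(img.channel("red"), dtype=float)[roi.mask]
    green = np.asarray(img.channel("green"), dtype=float)[roi.mask]
    for name, v in (("red", red), ("green", green)):
        if np.all(v == v[0]):
            raise ZeroVarianceError(f"channel {name!r} is constant within the roi")
    if method == "pearson":
        r = float(stats.pearsonr(red, green).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(red, green).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ColocResult(r=r, n_pixels=int(red.size), region_label=roi.label)
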