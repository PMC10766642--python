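"""Shared brute-force oracles, independent of the implementation paths they check."""

import numpy as np
import pytest


def corrected_intensity_oracle(green, red, mask, threshold):
    """Per-pixel Python loop: clamp(green-red), threshold, sum/count."""
    total = 0.0
    count = 0
    h, w = green.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            c = green[i, j] - red[i, j]
            if c < 0:
                c = 0.0
            if c > 0 and c >= threshold:
                total += c
                count += 1
    return total, count


def mask_ratio_oracle(red, green, mask):
    """Sum-of-red over sum-of-green via an explicit pixel loop."""
    sr = sg = 0.0
    h, w = red.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                sr += red[i, j]
                sg += green[i, j]
    return sr / sg


def pearson_oracle(x, y):
    """Textbook Pearson r from raw sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def curve_distance_oracle(mask_a, mask_b):
    """O(|A|*|B|) min pairwise Euclidean distance, mean over both directions."""
    pa = np.argwhere(mask_a).astype(float)
    pb = np.argwhere(mask_b).astype(float)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2)
    return float(np.concatenate([d.min(axis=1), d.min(axis=0)]).mean())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
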