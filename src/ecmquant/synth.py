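"""Seeded synthetic-data generators with planted ground truth.

Every generator emulates one input the quantification pipeline consumes —
worm-shaped fluorescence frames with correlated red+green gut
autofluorescence, photoconverted Dendra2 stripes, donor/acceptor FRET stacks,
channel pairs with a planted pixel correlation, traced cuticle-layer curves
with known separation, omics time courses with planted trends, screen plates
with planted hits, and Gompertz survival cohorts — and returns a
machine-readable truth dict recording every planted parameter.

Determinism: each generator draws from its own stream seeded from
(global seed, generator name), so outputs are bit-identical under a fixed
seed and adding generators never perturbs existing ones.

Image noise model: Poisson shot noise on the signal plus additive Gaussian
read noise, clipped to the bit depth — a standard microscopy stand-in.
"""

from __future__ import annotations

import zlib

import numpy as np
from .images import MultiChannelImage, ROIMask, ZStack
from .lifespan import SurvivalRecord
from .screen import ScoreRecord
from .thickness import LayerTrace


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _apply_noise(signal, rng, noise_sigma, shot_noise, max_value):
    out = np.asarray(signal, dtype=float)
    if shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(out, 0.0, max_value)


def _body_mask(shape, margin_frac=0.08):
    """Elongated elliptical worm body spanning most of the frame."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry = h * (0.5 - margin_frac) * 0.7
    rx = w * (0.5 - margin_frac)
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# Imaging phantoms


def gen_worm_image(
    seed: int = 0,
    shape=(96, 256),
    reporter_intensity: float = 100.0,
    autofl_intensity: float = 150.0,
    autofl_fraction: float = 0.35,
    noise_sigma: float = 2.0,
    shot_noise: bool = True,
    bit_depth: int = 16,
):
    """Worm frame with green-only cuticular reporter plus yellow (red~green)
    gut autofluorescence occupying a central band of the body.

    Returns (image, body mask, truth).  Truth records the noise-free reporter
    sum inside the body, which ``corrected_intensity`` recovers exactly in
    the noise-free limit.
    """
    rng = _rng(seed, "worm_image")
    body = _body_mask(shape)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    # gut band: central fraction of the body along the worm axis
    cx = (w - 1) / 2
    gut = body & (np.abs(cc - cx) <= autofl_fraction * w / 2)
    reporter = np.where(body, reporter_intensity, 0.0)
    autofl = np.where(gut, autofl_intensity, 0.0)
    max_value = 2**bit_depth - 1
    green = _apply_noise(reporter + autofl, rng, noise_sigma, shot_noise, max_value)
    red = _apply_noise(autofl, rng, noise_sigma, shot_noise, max_value)
    img = MultiChannelImage(channels={"green": green, "red": red}, bit_depth=bit_depth)
    truth = {
        "seed": seed,
        "reporter_intensity": reporter_intensity,
        "autofl_intensity": autofl_intensity,
        "reporter_total": float(reporter[body].sum()),
        "body_pixels": int(body.sum()),
        "gut_pixels": int(gut.sum()),
        "noise_sigma": noise_sigma,
        "shot_noise": shot_noise,
    }
    return img, ROIMask(mask=body, role="body", label="worm"), truth


def gen_photoconversion_pair(
    seed: int = 0,
    shape=(96, 256),
    phi: float = 0.3,
    converted_intensity: float = 200.0,
    baseline: float = 50.0,
    stripe_frac: float = 0.2,
    noise_sigma: float = 0.0,
    shot_noise: bool = False,
    bit_depth: int = 16,
):
    """Photoconverted stripe after a chase replacing fraction ``phi`` of the
    converted protein: stripe red = (1-phi)*I, stripe green = phi*I + baseline;
    flanking body is green-only at baseline.

    Returns (image, photoconverted roi, (left flank, right flank), truth).
    The truth carries the closed-form normalized turnover value
    (1-phi)*I / (phi*I + baseline), since the flank red/green ratio is zero.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    rng = _rng(seed, "photoconversion")
    body = _body_mask(shape)
    h, w = shape
    _, cc = np.mgrid[0:h, 0:w]
    cx = (w - 1) / 2
    half = stripe_frac * w / 2
    stripe = body & (np.abs(cc - cx) <= half)
    green = np.where(body, baseline, 0.0) + np.where(stripe, phi * converted_intensity, 0.0)
    red = np.where(stripe, (1.0 - phi) * converted_intensity, 0.0)
    max_value = 2**bit_depth - 1
    green = _apply_noise(green, rng, noise_sigma, shot_noise, max_value)
    red = _apply_noise(red, rng, noise_sigma, shot_noise, max_value)
    img = MultiChannelImage(channels={"green": green, "red": red}, bit_depth=bit_depth)
    roi = ROIMask(mask=stripe, role="photoconverted", label="stripe")
    gap = int(round(0.05 * w))
    width = int(round(2 * half))
    flank_cols_l = (cc >= cc[stripe].min() - gap - width) & (cc < cc[stripe].min() - gap)
    flank_cols_r = (cc > cc[stripe].max() + gap) & (cc <= cc[stripe].max() + gap + width)
    left = ROIMask(mask=body & flank_cols_l, role="flank_left", label="stripe")
    right = ROIMask(mask=body & flank_cols_r, role="flank_right", label="stripe")
    expected_in = (
        (1.0 - phi) * converted_intensity / (phi * converted_intensity + baseline)
    )
    truth = {
        "seed": seed,
        "phi": phi,
        "converted_intensity": converted_intensity,
        "baseline": baseline,
        "expected_ratio_in": expected_in,
        "expected_ratio_flank": 0.0,
        "expected_normalized": expected_in,
    }
    return img, roi, (left, right), truth


def gen_fret_stack(
    seed: int = 0,
    shape=(64, 128),
    region_ratios=(0.5, 2.0),
    donor_level: float = 200.0,
    background: float = 0.0,
    noise_sigma: float = 1.0,
    n_slices: int = 3,
    focus_profile=(0.6, 1.0, 0.6),
):
    """Donor/acceptor z-stack with planted acceptor/donor ratios per region.

    The frame is split into ``len(region_ratios)`` vertical regions; each
    carries donor ``donor_level`` and acceptor ``ratio * donor_level`` at the
    focus slice, attenuated off-focus, plus Gaussian noise.  Returns
    (stack, region masks, truth).
    """
    rng = _rng(seed, "fret_stack")
    h, w = shape
    n_regions = len(region_ratios)
    _, cc = np.mgrid[0:h, 0:w]
    bounds = np.linspace(0, w, n_regions + 1)
    masks = [
        ROIMask(mask=(cc >= bounds[i]) & (cc < bounds[i + 1]), role="region", label=f"region{i}")
        for i in range(n_regions)
    ]
    donor0 = np.full(shape, float(background))
    acceptor0 = np.full(shape, float(background))
    for m, ratio in zip(masks, region_ratios):
        donor0[m.mask] = donor_level + background
        acceptor0[m.mask] = ratio * donor_level + background
    slices = []
    for att in focus_profile[:n_slices]:
        don = donor0 * att + rng.normal(0, noise_sigma, shape) if noise_sigma else donor0 * att
        acc = acceptor0 * att + rng.normal(0, noise_sigma, shape) if noise_sigma else acceptor0 * att
        slices.append(
            MultiChannelImage(
                channels={"donor": np.clip(don, 0, None), "acceptor": np.clip(acc, 0, None)}
            )
        )
    truth = {
        "seed": seed,
        "region_ratios": list(region_ratios),
        "donor_level": donor_level,
        "background": background,
        "noise_sigma": noise_sigma,
    }
    return ZStack(slices=slices), masks, truth


def gen_coloc_pair(
    seed: int = 0,
    shape=(100, 100),
    rho: float = 0.6,
    mean: float = 100.0,
    sigma: float = 20.0,
):
    """Red/green channel pair whose pixel intensities are drawn from a
    bivariate normal with correlation ``rho`` (means well above zero so the
    nonnegativity clip is inactive in practice)."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = _rng(seed, "coloc_pair")
    n = int(np.prod(shape))
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    red = mean + sigma * z1
    green = mean + sigma * (rho * z1 + np.sqrt(1 - rho**2) * z2)
    img = MultiChannelImage(
        channels={
            "red": np.clip(red, 0, None).reshape(shape),
            "green": np.clip(green, 0, None).reshape(shape),
        }
    )
    roi = ROIMask(mask=np.ones(shape, dtype=bool), role="region", label="full")
    truth = {"seed": seed, "rho": rho, "mean": mean, "sigma": sigma, "n_pixels": n}
    return img, roi, truth


def gen_layer_traces(
    seed: int = 0,
    kind: str = "parallel",
    shape=(128, 128),
    separations=(10, 15),
    radii=(30, 40),
):
    """Traced layer-border curve fixtures with known geometry.

    ``kind="parallel"``: horizontal 1-px lines starting at row 10, spaced by
    ``separations``.  ``kind="concentric"``: circle perimeters at ``radii``
    around the frame center.  Returns (list of traces, truth).
    """
    if kind == "parallel":
        rows = np.concatenate([[10], 10 + np.cumsum(separations)])
        traces = []
        for i, r in enumerate(rows):
            m = np.zeros(shape, dtype=bool)
            m[int(r), 10:-10] = True
            traces.append(LayerTrace(mask=m, layer_name=f"layer{i}"))
        truth = {"kind": kind, "rows": [int(r) for r in rows], "separations": list(separations)}
    elif kind == "concentric":
        from skimage.draw import circle_perimeter

        cy, cx = shape[0] // 2, shape[1] // 2
        traces = []
        for i, rad in enumerate(radii):
            m = np.zeros(shape, dtype=bool)
            rr, cc = circle_perimeter(cy, cx, int(rad), shape=shape)
            m[rr, cc] = True
            traces.append(LayerTrace(mask=m, layer_name=f"ring{i}"))
        truth = {"kind": kind, "radii": list(radii)}
    else:
        raise ValueError(f"unknown trace kind {kind!r}")
    truth["seed"] = seed
    return traces, truth


def gen_random_trace(seed: int, shape=(96, 96)) -> LayerTrace:
    """Random smooth open curve rasterized 1 px thick (for oracle fuzzing)."""
    rng = _rng(seed, "random_trace")
    h, w = shape
    n = w - 16
    base = rng.uniform(h * 0.2, h * 0.8)
    amp = rng.uniform(2, h * 0.15)
    freq = rng.uniform(0.5, 2.0)
    phase = rng.uniform(0, 2 * np.pi)
    cols = np.arange(8, 8 + n)
    rows = np.clip(
        np.round(base + amp * np.sin(freq * cols / w * 2 * np.pi + phase)).astype(int),
        0,
        h - 1,
    )
    m = np.zeros(shape, dtype=bool)
    m[rows, cols] = True
    return LayerTrace(mask=m, layer_name=f"random{seed}")


# ---------------------------------------------------------------------------
# Omics, screen, and survival tables


def gen_omics_table(
    seed: int = 0,
    n_per_class: int = 500,
    ages=tuple(range(1, 9)),
    n_replicates: int = 3,
    slope: float = 1.0,
    noise_sigma: float = 0.3,
    baseline: float = 10.0,
    level: str = "mRNA",
):
    """Long-format omics time courses with planted down/unchanged/up trends.

    Down/up series carry linear slope -+``slope`` (value units per day, with
    the noise scale ``noise_sigma`` defining the SD unit); unchanged series are
    flat.  Returns (DataFrame with columns molecule_id, level, age_days,
    replicate, value; truth DataFrame molecule_id -> planted_class).
    """
    import pandas as pd

    rng = _rng(seed, "omics_table")
    rows = []
    truth_rows = []
    for cls, s in (("down", -slope), ("unchanged", 0.0), ("up", slope)):
        for i in range(n_per_class):
            mol = f"{cls}_{i:04d}"
            truth_rows.append({"molecule_id": mol, "planted_class": cls})
            for age in ages:
                for rep in range(n_replicates):
                    value = baseline + s * age + rng.normal(0.0, noise_sigma)
                    rows.append(
                        {
                            "molecule_id": mol,
                            "level": level,
                            "age_days": float(age),
                            "replicate": f"r{rep}",
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_synthesis_table(
    seed: int = 0,
    n_per_group: int = 100,
    group_offsets=(-2.0, 0.0, 2.0),
    within_sigma: float = 0.2,
    n_points: int = 4,
    grand_mean: float = 5.0,
    between_sigma: float = 1.0,
):
    """De-novo synthesis rates with three planted groups at -2/0/+2 SD around
    the grand mean (the between-molecule SD unit is ``between_sigma``)."""
    import pandas as pd

    rng = _rng(seed, "synthesis_table")
    labels = {-1: "down", 0: "unchanged", 1: "up"}
    rows, truth_rows = [], []
    for offset in group_offsets:
        cls = labels[int(np.sign(offset))]
        for i in range(n_per_group):
            mol = f"syn_{cls}_{i:04d}"
            center = grand_mean + offset * between_sigma + rng.normal(0, 0.05)
            truth_rows.append({"molecule_id": mol, "planted_class": cls})
            for j in range(n_points):
                rows.append(
                    {
                        "molecule_id": mol,
                        "level": "synthesis",
                        "age_days": float(j + 1),
                        "replicate": "r0",
                        "value": center + rng.normal(0, within_sigma),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_screen_plate(
    seed: int = 0,
    n_conditions: int = 1000,
    n_hits: int = 50,
    hit_delta: float = 1.0,
    control_mean: float = 1.0,
    n_replicates: int = 4,
    noise_steps: int = 1,
    grid_step: float = 0.5,
    grid_max: float = 3.0,
    control_name: str = "control-EV",
    day: float = 8.0,
):
    """Simulated screen plate: ``n_hits`` planted enhancer conditions at
    ``control_mean + hit_delta`` and the rest at the control level, each
    replicate jittered by up to ``noise_steps`` grid steps and snapped to the
    ordinal grid.  Returns (records, truth dict condition -> is_hit)."""
    rng = _rng(seed, "screen_plate")

    def _score(base):
        jitter = grid_step * rng.integers(-noise_steps, noise_steps + 1) if noise_steps else 0.0
        snapped = round((base + jitter) / grid_step) * grid_step
        return float(min(max(snapped, 0.0), grid_max))

    records = []
    truth = {}
    for rep in range(n_replicates):
        records.append(
            ScoreRecord(
                well_id=f"ctrl_r{rep}",
                condition=control_name,
                day=day,
                replicate=f"r{rep}",
                score=_score(control_mean),
            )
        )
    hit_idx = set(rng.choice(n_conditions, size=n_hits, replace=False).tolist())
    for i in range(n_conditions):
        cond = f"clone_{i:04d}"
        base = control_mean + (hit_delta if i in hit_idx else 0.0)
        truth[cond] = i in hit_idx
        for rep in range(n_replicates):
            records.append(
                ScoreRecord(
                    well_id=f"w{i:04d}_r{rep}",
                    condition=cond,
                    day=day,
                    replicate=f"r{rep}",
                    score=_score(base),
                )
            )
    return records, truth


def _gompertz_mean(a: float, b: float) -> float:
    # E[T] = (1/b) * exp(a/b) * E1(a/b) for hazard a*exp(b*t)
    from scipy.special import exp1

    return float(np.exp(a / b) * exp1(a / b) / b)


def gen_cohort(
    seed: int = 0,
    n: int = 1000,
    mean_lifespan_days: float = 17.0,
    gompertz_b: float = 0.3,
    effect_multiplier: float = 1.0,
    genotype: str = "N2",
    treatment: str = "control-EV",
    batch: str = "batch1",
    censor_fraction: float = 0.0,
):
    """Survival cohort drawn from a Gompertz law (baseline hazard a*exp(b*t)),
    time-rescaled so the expected mean lifespan is
    ``mean_lifespan_days * effect_multiplier``.  A fraction of animals can be
    right-censored at a uniform random day before death (lost/bagged)."""
    rng = _rng(seed, f"cohort:{genotype}:{treatment}:{batch}")
    # small baseline hazard gives a steep Gompertz (CV ~0.25, typical for
    # synchronized worm cohorts); the time rescale sets the mean exactly
    a = 0.001
    raw_mean = _gompertz_mean(a, gompertz_b)
    scale = mean_lifespan_days * effect_multiplier / raw_mean
    u = rng.uniform(size=n)
    t_raw = (1.0 / gompertz_b) * np.log1p(-(gompertz_b / a) * np.log(u))
    days = np.maximum(t_raw * scale, 0.5)
    records = []
    for i, d in enumerate(days):
        censored = bool(rng.uniform() < censor_fraction)
        event_day = float(d if not censored else max(0.5, d * rng.uniform(0.3, 0.9)))
        records.append(
            SurvivalRecord(
                animal_id=f"{genotype}_{treatment}_{batch}_{i:04d}",
                genotype=genotype,
                treatment=treatment,
                batch=batch,
                event_day=event_day,
                censored=censored,
            )
        )
    truth = {
        "seed": seed,
        "expected_mean": mean_lifespan_days * effect_multiplier,
        "gompertz_b": gompertz_b,
        "n": n,
    }
    return records, truth
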