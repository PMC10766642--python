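# Methods

## Scope and data model

The package quantifies ECM-aging readouts downstream of acquisition: it takes
registered multi-channel rasters, binary region masks, traced layer curves,
long-format omics tables, ordinal score tables, and individual-level survival
tables. It does not segment worms, draw ROIs, register channels, or process
raw sequencing/mass-spec data. Rasters are row-major with 0-based integer
pixel centers; masks are boolean with nonzero = member.

## Corrected reporter intensity

Gut autofluorescence is modeled as a signal present equally in the red and
green channels (yellow blend); the GFP reporter is green-only. Corrected
signal per pixel is `max(G − R, 0)`. Negative differences are clamped before
thresholding because negative corrected intensity has no physical meaning and
clamping removes autofluorescence without touching reporter-only pixels. A
pixel contributes (to total, count, and mean) when its corrected value is
strictly positive and at least the noise threshold; the threshold default is
0 a.u. and is supplied per experiment, since the appropriate cutoff depends
on detector offset and exposure. With threshold 0 on a red-free image the
total equals the plain green sum over the ROI exactly — a closure the tests
assert.

## Photoconversion turnover

"Total" signal is the sum over mask pixels, and the metric is a ratio of
sums, not a mean of per-pixel ratios — robust to dark pixels inside the
stripe. The two flank ratios are averaged unweighted before subtraction
(a pooled flank-union ratio is available as `flank_mode="pooled"`; on
symmetric flanks the two agree). A total-green floor (`min_total`, default
1 a.u.) guards division by zero and raises naming the offending mask. No
background subtraction is applied by default. Flank masks are placed along
the longer side of the photoconverted bounding box (worms are imaged
lengthwise), offset `gap_px` (default 0) and of width `width_px` (default:
the stripe extent), clipped to the body and stripped of stripe pixels; a
flank falling entirely outside the body is an explicit error naming the side.

## FRET ratio

`ratio = (A − bg_A)/(D − bg_D)` with per-channel constant backgrounds,
defined only where the background-subtracted donor is at least
`donor_threshold` (so dim pixels cannot blow up the ratio). The alternative
transmission form `A/(D+A)` is selectable. Region means are taken over
valid ∩ region pixels; an empty intersection is an explicit
undefined-statistic error rather than a silent NaN. Group comparison uses
Welch's unequal-variance two-tailed t-test by default (pooled optional).
Degenerate inputs where both groups are constant get `p = 1` for equal means
and `p = 0` otherwise, with a warning — the test statistic is undefined
there and the convention keeps batch pipelines running loudly.

## Pixel colocalization

Pearson correlation of (red, green) pairs over the ROI — a linear-relation
model of co-occurrence that is invariant to per-channel gain and offset, so
it does not require the two fluorophores to be scaled identically. Spearman
is available for monotone non-linear relations. Constant channels raise a
zero-variance error. At least 3 pixels are required.

## Cuticle thickness

Thickness between traces A and B is the mean of the concatenated distance
vectors (every pixel of A to nearest B, every pixel of B to nearest A) —
i.e. count-weighted when |A| ≠ |B|, since every pixel of both curves
contributes once. Distances are between pixel centers with no sub-pixel
interpolation; the Euclidean distance transform is exact, and the suite
checks exact agreement with an O(|A|·|B|) brute-force oracle. Traces that
are not one pixel thick trigger a warning, not an error. The calibration
constant 25000 µm (the 2.5 cm printed scale bar) is fixed. Users should
pre-trim distorted trace regions; no trimming or section-angle correction is
attempted.

## Trajectory classification

Replicates enter the correlation as individual (age, value) points, never
averaged first. Spearman ties get average ranks. The agreement threshold
τ defaults to 0.5 — both coefficients must exceed it in magnitude with the
same sign — and is a first-class knob because no canonical value exists for
this rule; a significance-based variant (both `p < α`, same sign) is
provided. "Mildly declining" mRNA is operationalized as down at τ/2
(default 0.25) but not at τ, which routes molecules with accumulating
protein to pattern III. The pattern rule is a pure function of the level
calls, exhaustively tested over all 48 call combinations. Synthesis rates
use k = 1 SD around the grand mean of per-molecule means.

## Screen scoring

The hit threshold is inclusive (≥ 0.5 grade, the lowest visible difference)
and symmetric: the same magnitude defines suppressors (negative delta, the
relevant direction in long-lived backgrounds). Controls are plate-matched.
Fewer than 3 replicates warns; the mean is still computed. The
hemidesmosome 0–5 category scale is the same machinery with a unit-step
grid. The day × condition time-course summary reports mean ± SEM per cell
and a two-way factorial ANOVA fitted by ordinary least squares.

## Lifespan

Mean (not median) lifespan over uncensored animals; censored animals
(lost/bagged) are excluded. Epistasis deltas require matching batches and
error on mismatch rather than pooling, because extension percentages are not
comparable across batches. Kaplan–Meier and log-rank are routine plumbing
(lifelines) behind the module surface; the log-rank p-value is checked
against a textbook chi-square oracle in the tests. The applied-pressure
helper computes `P = m·g/A` and formats to one decimal; the worked example
(0.05 kg on 0.04 m² → 12.3 Pa) uses the stated contact area as printed,
although a 2 cm × 2 cm chunk would be 4×10⁻⁴ m² — the package reproduces
the published arithmetic and flags the discrepancy here.

## Synthetic generators

Each generator owns a pseudo-random stream seeded from (global seed,
generator name), so outputs are bit-identical under a fixed seed and adding
generators never perturbs existing fixtures. Every fixture returns a truth
dict recording all planted parameters.

* **Worm frames**: elongated elliptical body, uniform green reporter, a
  central gut band with equal red/green autofluorescence. Noise is Poisson
  shot noise plus additive Gaussian read noise clipped to the bit depth — a
  standard microscopy stand-in; no point-spread function, vignetting, or
  anatomical texture is simulated, so passing tests demonstrate correctness
  of the arithmetic, not robustness to real-worm morphology.
* **Photoconversion pairs**: stripe red `(1−φ)I`, stripe green `φI + b`,
  flanks green-only at baseline `b` (I = 200, b = 50 a.u. defaults); the
  normalized turnover has the closed form `(1−φ)I/(φI+b)`, strictly
  decreasing in the replacement fraction φ.
* **FRET stacks**: two planted-ratio regions (defaults 0.5 and 2.0) at
  donor level 200 a.u. with σ = 1 a.u. Gaussian noise over 3 slices with an
  off-focus attenuation profile, exercising the max-projection path.
* **Colocalization pairs**: bivariate normal pixels at the requested ρ
  (mean 100, σ 20 a.u., so the nonnegativity clip is inactive).
* **Layer traces**: parallel lines at known separations, concentric-circle
  perimeters, and random smooth sinusoid curves for oracle fuzzing.
* **Omics tables**: linear trends of ±1 value-unit/day (down/up) or flat
  (unchanged) over 8 ages × 3 replicates with σ = 0.3 Gaussian noise;
  synthesis tables plant three groups at −2/0/+2 between-molecule SD.
* **Screen plates**: planted enhancers at +1.0 grade over a control level
  of 1.0, four replicates, each jittered by up to one 0.5-step and snapped
  to the grid.
* **Survival cohorts**: Gompertz law (hazard `a·e^{bt}`) with a small
  baseline hazard giving a coefficient of variation near 0.25, typical of
  synchronized worm cohorts, time-rescaled so the expected mean is exactly
  the configured 17 days times the treatment effect multiplier. Only the
  mean is asserted in tests.

## Problem sizes and numerical choices

The default suite runs brute-force pixel/pairwise oracles on 50–200 fixtures
per metric at 32×64 to 100×100 rasters, 500 series per trajectory class, a
1,000-condition screen plate, and cohorts of 200–1,000 animals — sizes at
which every stochastic assertion has comfortable margin while the whole
suite completes in well under a minute. Exactness claims (distance
transform, pixel-loop equality, ratio arithmetic) are asserted at 1e-9 to
1e-12; recovery claims at the generator's planted tolerances (±0.02 on ρ,
1e-2 on FRET ratios, ±5 points on lifespan extension, ≥95% class recovery).

## Known limitations

The published collagen pattern split (21/6/14 of 41 detected collagens)
requires the study's collagen trajectory tables; the classifier and its τ
calibration options are implemented and the acceptance test documents the
expected input (`data/collagen_trajectories.csv`), but the split cannot be
recomputed without that table. The FRET ratio arithmetic follows the
acceptor/donor convention with constant background; the original macro's
exact background/smoothing steps live in supplementary material and the
formula is therefore configurable. Flank geometry for turnover
normalization (gap, width, averaging) is a documented default, not a
published constant.
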