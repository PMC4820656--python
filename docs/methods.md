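# Methods

This note documents the models, defaults and design decisions behind
`nkscreen`: what the synthetic assay generator simulates, how each image
stage works, how killing statistics are estimated, and what passing the
test suite does and does not establish about real microscope data.

## 1. Chip and imaging geometry

The chip model (`layout.ChipLayout`) is a rectangular array of imaging
*subunits*, each a square block of wells; one microscope field covers
exactly one subunit. Defaults reproduce the reference chip: 20 × 20
subunits × 9 × 9 wells = 32,400 wells, 400 fields, 81 wells per field;
wells 50 µm × 50 µm and 300 µm deep (depth and glass thickness are
metadata only — rendering and analysis are strictly 2D).

Values the chip drawings do not pin down are configurable defaults chosen
once: pixel size 1.0 µm/px (plausible for a 10× objective), wall
thickness 20 µm between wells, inter-subunit gap equal to the wall, and a
12 px blank margin around each rendered tile. Coordinates are 0-based,
row-major; bounding boxes are half-open pixel rectangles. Each well has a
four-level index `(subunit_row, subunit_col, well_row, well_col)` in
bijection with a global row-major `well_id`.

## 2. Synthetic assay generator

The generator (`synthetic`) defines the study conditions under which the
pipeline is validated. Timeline: minutes relative to the first
post-mixing screen `T_0h`; the target-only prescreen `T_minusNK` sits at
−45 min (screening the chip takes about 45 min), `T_6h` = 360, `T_12h` =
720.

**Seeding.** Per-well target and NK counts are Poisson (cells sediment
independently); the NK mean is `mean_targets_per_well × et_ratio`.
Cells are placed on a jittered 3 × 3 lattice inside the well floor
(pitch ≈ 2.6 cell radii), which keeps the packing physically plausible —
up to ~9 cells of 11 µm in a 50 µm well — while bounding overlap;
occupancy is truncated at the placement capacity (8 targets, 2 NK). A
fraction `initial_dead_fraction = 0.06` of targets is dead before the
prescreen, matching the few-percent background of pre-dead targets such
assays show.

**Kill events.** Each NK draws an intended kill count from a preset
distribution, truncated by the live targets available in its well
(shared among the well's NK cells):

- `resting` (non-activated NK, E:T = 1:3, mean 3 targets/well):
  P(0..3) = (0.72, 0.20, 0.07, 0.01). The two anchors — 72% non-killers
  and ~1% serial killers — are published population values; the interior
  split is a calibration default.
- `serial_assay` (IL-2-activated NK, target density doubled to 6/well at
  unchanged NK density, prescreen acquired): P(0..6) = (0.30, 0.27,
  0.12, 0.14, 0.10, 0.05, 0.02), calibrated so that in expectation
  ≥3-killers commit 70% of kills and ≥5-killers ≈ 22%
  (E[K] = 1.70; 1.19/1.70 = 0.70; 0.37/1.70 = 0.218).
- `il2_activated` uses the serial distribution at standard density with a
  45-min unobserved pre-`T_0h` window.

Kill times are uniform between NK seeding and the last screen — uniform
is a default, not a claim; the data constrain only that most killing is
early. For the resting preset the assay is modelled as observed from
mixing (time-lapse), so no unobserved window exists and the scoring
baseline `T_0h` sees every kill; for the serial assay the prescreen
baseline plays that role.

**Spontaneous death.** Targets never NK-killed die independently with
probability 0.02 per 6-hour interval (rescaled by interval length).
Modelling choice: victims are drawn first and exempted from the
spontaneous hazard, so per well the observed deaths decompose exactly as
`D = K + Binomial(n − K, q)` — the identity the corrected estimator of
§5 inverts. Death is absorbing; per-well conservation
(live + dead = initial) holds at every screen by construction.

**Rendering.** Four float32 channels per tile (transmitted, orange,
green, DDAO). Walls render at 200, floors at 90 intensity units; live
targets as anti-aliased disks (radius 5.5 ± 0.45 µm) at green 150 /
DDAO 25; dead targets keep their position at green 15 (10% of live — the
classifier, not the renderer, must separate the classes) and DDAO 160;
NK cells are unions of a main disk (r = 4 µm) and two offset lobes at
orange 150. Per-cell dye-loading heterogeneity is lognormal with
σ = 0.10. Fluorophores bleach by 0.85 per screen, NK by a further 0.92
(the NK channel fades fastest, as observed); screens after the first
gain Poisson(0.3) small bright two-lobed debris objects per well in
green/DDAO; background 20, additive Gaussian noise σ = 5; each field
carries a random integer stage offset (±3 px) shared across its screens.
All randomness flows from one seeded generator; simulations are
bit-reproducible given the seed.

*What the generator does not emulate:* cell motility and conjugate
dynamics (wells are escape-proof), kill-time clustering, out-of-focus
light, illumination gradients, chip warp or rotation, and donor
variability. Pipeline accuracy measured on generator output is therefore
an upper bound for real micrographs; the goodness/QC machinery exists
precisely because real wells fail in ways synthetic wells rarely do.

## 3. Segmentation

**Grid.** The well lattice is known a priori, so localization is
template matching: a binary wall/floor template is cross-correlated
(normalized) with the transmitted channel; because the offset cannot
exceed the tile margin, a central sub-template (~3 pitches wide) is
matched over a small search window. The peak is refined to subpixel by
quadratic interpolation; a correlation below 0.2 raises "no grid found".
An optional small-angle rotation sweep (±2°) is available but off by
default — the generator, like a clamped chip, does not rotate. Fitting
is per tile; wells truncated by the border are excluded.

**Targets.** Both fluorescence channels are thresholded (per-tile
background median + 4 robust SD) and smoothed with a Gaussian of
σ = 2.75 px ≈ half the cell radius, then max-normalized and combined by
pixelwise maximum: the union evidence sees live cells through calcein
and dead cells through DDAO. A circular Hough transform over radii
4–9 px runs on the boundary of the union mask; candidate circles come
from non-maximum suppression of the radius-collapsed accumulator
(min separation 6 px, accumulator threshold 0.32) and must pass two
validations that kill accumulator artefacts: measured intensity of at
least 12 units in one channel, and above-threshold fill of ≥ 60% of the
fitted disk (this also rejects small bright debris, whose blobs cannot
fill a cell-sized disk). Mean intensities are measured on the original
background-subtracted channels inside a concentric disk of 0.75 r to
limit contamination from touching neighbours.

**NK cells.** Connected components of the thresholded orange channel
with area in [20, 130] px² count as one NK; larger components count as
`round(area / 75)` cells and raise the `large_contiguous` flag.

**Figure of goodness.** Per well, the product of four penalties in
(0, 1]: cell count beyond a soft cap of 10; merged (large contiguous)
objects; bright above-threshold area outside all detections (> 2% of the
well); overlap between detected disks (> 5% shared area). The score is
1.0 iff no penalty is active; wells under 0.5 are flagged
`manual_review` and excluded from selections — the automated analogue of
falling back to manual counting.

## 4. Viability classification

Each target's discriminant is `d = log((green + ε)/(DDAO + ε))` with
ε = 1 intensity unit; live ⇔ `d >` threshold. Thresholds are set per
screen (bleaching shifts intensities between screens) on the cells
pooled across the run's fields, either manually or automatically.

The automatic threshold scans the finite candidate set of midpoints
between consecutive sorted discriminants and scores each induced
live/dead split by the pairwise Euclidean distances between the groups
in per-channel-standardized (green, DDAO) space. Two literal readings of
"separation between the groups" fail on realistic populations: the
per-pair *mean* cross-distance is maximized by peeling a single extreme
cell off a tight cluster (a 94%-live population gets thresholded inside
its dead cluster), while the raw distance *sum* is maximized by cutting
the large cluster in half once dye-loading spread is realistic. The
implemented objective is the mean cross-pair distance weighted by
√(n_live·n_dead)/n — the geometric balance factor suppresses both
degeneracies (measured on a representative prescreen population:
true split 1.36 vs balanced cut 0.67 vs singleton split 0.14). Exact
ties break toward the candidate nearest the discriminant median.
Populations beyond 3,000 cells are thinned deterministically before the
O(n²) scan. Degenerate populations (all discriminants equal, or fewer
than two cells) raise an error; the pipeline falls back to threshold 0
(the balanced-channel boundary) with a warning.

## 5. Kill scoring and the spontaneous-death correction

Aligned per-well time courses are filtered by the selection criteria
(README §overview) — wells failing QC at any screen are excluded — and
scored: kills in an interval are `max(0, live_t − live_{t+1})`; totals
accumulate from the baseline (`T_0h`, or `T_minusNK` for the serial
assay so pre-`T_0h` kills are captured); in single-NK wells all kills
attribute to that NK. Decreasing dead counts flag a well inconsistent.
Live-count decreases are the primary evidence because late-screen debris
corrupts dead counts more than live ones.

Counting cannot distinguish an NK kill from a spontaneous death in the
same well, and with ~4 live targets over 12 h the spontaneous background
(~4% per target) inflates the observed death counts far beyond the
tolerance of the headline statistics. The correction uses the NK-free
wells of the same screens: the per-target spontaneous probability `q`
over the scoring window is their death fraction, and the observed
death-count distribution is deconvolved under the exact mixture
`P(D = d | n) = Σ_k P(K = k)·C(n−k, d−k)·q^{d−k}(1−q)^{n−d}` by EM over
the pooled `(n, D)` table. Because detection noise perturbs NK-free and
single-NK wells alike, `q` absorbs the symmetric part of the counting
error as well. On exact draws the estimator recovers the kill
distribution to < 1 pp at 40,000 wells; end to end (rendered images,
5,000 selected wells) it recovers the resting preset's zero-kill mass
within ~1 pp. Killing shares are computed from the corrected
distribution as `Σ_{k≥K} k·p_k / Σ_k k·p_k`.

## 6. Population statistics

Cytotoxic fractions are reported per group and pooled with Wilson 95%
intervals (an addition for usability, not part of the original analysis).
Significance between conditions uses the Yates continuity-corrected χ²
on 2 × 2 tables of (cytotoxic, non-cytotoxic) × condition, with the
correction clamped at |ad − bc| so the statistic is never negative, and
stars: p > 0.05 n.s.; * to 0.01; ** to 0.001; *** below. No
multiple-testing correction is applied — stars are per comparison.

## 7. Problem sizes and numerical choices

The acceptance runs simulate 2 × 2-subunit batches (324 wells) until
5,000 wells pass each selection (~25,000 wells per preset), a scale at
which the binomial standard error of the zero-kill mass is ~0.6 pp.
Batches draw independent child seeds from one `SeedSequence`, so results
are reproducible and order-independent. EM runs to a 1e−10 sup-norm
tolerance (≤ 500 iterations); the kill-support upper bound defaults to
the largest observed death count, so no preset knowledge leaks into the
estimator. Tie-breaks: Hough candidates are accepted in decreasing
accumulator order; NK multiplicities round half away from zero via
`round`; the viability tie-break is the discriminant median.

## 8. Known limitations

- Segmentation accuracy is quoted on generator output (§2 caveats); real
  images add failure modes the goodness score flags but cannot repair.
- The spontaneous-death correction assumes spontaneous hazard is
  identical in NK-containing and NK-free wells and independent of kills;
  bystander effects would bias it.
- Multi-NK wells are never scored per cell; they contribute only
  well-level death statistics.
- Kill-time placement within an interval is unidentifiable from screen
  data; only interval counts are reported (time-lapse mode treats every
  frame as a screen and inherits the same arithmetic).
- Donor-specific cytotoxic ranges and absolute experiment sizes are not
  reproducible from synthetic data; they appear only as calibration
  anchors of the presets.
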