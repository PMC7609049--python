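# Methods

This note records the models, parameter choices and numerical decisions
behind `orgscreen`, and what the synthetic validation does and does not
establish about real data.

## Analysis pipeline

### Aggregate identification

Each confocal plane of the channel-summed stack is smoothed (median
filter, width 5 px by default) and thresholded (Otsu by default; an
absolute-abu threshold is available for calibrated setups). The binary
boundary is cleaned by a dilation of 10 px followed by an erosion of
3 px. This pair is deliberately asymmetric and therefore grows the mask
by roughly 7 px; the grown mask is kept as the *clipping region* for
segmentation, while the size and brightness gates are evaluated on the
raw thresholded foreground inside each cleaned region. Measuring gates
on the raw foreground keeps a 100 px disc at its analytic area (π·100²
within a few %) and lets a 3000 µm² speck fail the 4000 µm² minimum,
while the grown clip region still captures nuclei at the sample rim.
The minimum-brightness gate (default 300 abu) applies to the region
*mean* intensity; a switch to integrated totals exists because the
convention is genuinely ambiguous in common HCS software.

When several regions pass all gates on one plane, the largest is used
(wells hold one aggregate by design) and the rest are examined by QC.
QC rejects wells for: `dust` (compact bright off-aggregate object),
`fiber` (roundness < 0.2 and extent > 50 µm), `incomplete` (aggregate
mask touching the image border on any plane), `missing` (no aggregate
anywhere). Failing wells are reported, never silently dropped.

### Background correction

Three anti-extensive corrections (output ≤ input, clipped at zero):

* **Gaussian high-pass** (`subtract_blur` / `gaussian_highpass`):
  raw − blur(raw, σ). Channel conventions for soma-scale markers:
  σ = 10 px for TH, 5 px for Map2.
* **Sliding parabola**: background = grayscale opening of the intensity
  surface with a paraboloid of height κ·r². The commercial "curvature"
  dial maps to κ = curvature/1000 abu/px²; κ is also exposed directly.
  Numeric equivalence with proprietary implementations is not claimed —
  the role (removing background flatter than the paraboloid while
  passing features sharper than it) is what is reproduced.

The opening is computed separably: the additive split
κ(s² + t²) = κs² + κt² makes a 1-D parabolic erosion per axis followed
by 1-D dilations exactly equal to the full 2-D operation, including at
borders (offsets shrink to valid positions; no padding). Offsets whose
penalty exceeds the data range are skipped, giving O(N·min(r_max, n))
per plane. The test suite verifies bit-exact agreement with a
brute-force 2-D opening, anti-extensivity, idempotence (to 1 ulp), and
that the residual is pointwise non-increasing in curvature — a sharper
paraboloid tracks the surface more closely and removes more.

Choosing κ is a matter of scale separation: κ must exceed the local
curvature of the background (haze domes of amplitude A over radius R
curve at ~A/R²) and stay far below the curvature of real objects
(a nucleus blob of peak A_n and σ px curves at A_n/σ² ≈ 100 abu/px²
here). For the synthetic scenes (A ≈ 150 abu, R ≈ 40–110 px) the
matched preset uses curvature 200 (κ = 0.2); every imaging campaign
needs its own setting of this kind.

### Segmentation and gating

Nuclei/cells are found by smoothing the corrected plane at the expected
object scale (σ = d/4), seeding at local maxima above an absolute
threshold, and growing seeds by watershed restricted to the aggregate
region and to pixels above half the seed threshold. Seeds are labelled
in (row, col) order so flooding ties resolve deterministically.
Equivalence with proprietary "find nuclei"/"find cells" routines is
claimed only at the level of gated counts on well-separated objects,
never pixel masks.

Brightness is measured on the raw channel (the corrected image steers
detection only) and reported as the footprint **sum** — the quantity
aggregated per well — with the mean alongside. Gate semantics follow
the strict wording "larger than / brighter than": minima are strict
(>), maxima reject strictly (>), so a value equal to a cap passes.
Gating is idempotent, order-preserving, and monotone under tightening.
Double-positive calling matches accepted objects across channels by
greedy closest-first pairing under a distance cap; on disjoint-or-
coincident scenes this equals optimal bipartite matching (tested).

### Quantification and plate analytics

Per well: accepted-object counts and summed raw brightness accumulate
over planes and fields; filamentous markers accumulate the per-plane
mean raw intensity within the aggregate sample mask (the integrated
total is a switch, since both conventions appear in practice); aggregate
area sums over planes. Totals always equal the per-plane breakdown.
Area normalization (metric ÷ summed area) is a flag, applied before
control normalization in dose–response work. Batch homogeneity uses
CV = sd/mean with the sample (n−1) standard deviation — batches are
small. The mature-cell fraction is 1 − N_marker/N_DAPI, clipped to
[0, 1]. Edge-effect reports compare interior wells against the
outermost ring ("edge" = first/last row or column; exactly 36 edge and
60 inside wells on a 96-well plate) via
(mean_inside − mean_edge)/mean_edge with a seeded percentile bootstrap
(10⁴ resamples) — a descriptive CI, chosen because no specific test is
canonical for this readout. Dose series are fitted with a 4PL in
log-dose (bounds: bottom ≥ 0, top ≤ 1.5, Hill in [0.2, 5]; seeded
multi-start least squares; dose 0 sits one decade below the lowest
nonzero dose, standard pseudo-log practice). Non-convergence and flat
(degenerate) series are reported as flags, never raised.

### Time-series readouts

ΔF/F₀ spike detection uses a rolling 10th-percentile baseline (30 s
window), a threshold of 3 robust SDs (1.4826·MAD) and 1 s event
merging; these four numbers are this package's choice — published
traces rarely state an algorithm. At SNR 5 the detector recovers
planted events at sample precision; occasional low-amplitude noise
crossings can appear and carry their (small) amplitudes, so downstream
consumers can filter on amplitude. Synchrony is the mean pairwise
Pearson correlation plus the fraction of cross-train event groups in
which every train participates. The MEA oscillation metric
Savitzky–Golay-smooths each 15 s segment (window 50 → 51 samples, since
the filter needs an odd window; polyorder 3), removes the segment mean
(otherwise DC offsets dominate an absolute sum), and returns
Σ|treated| / Σ|basal|; the 15 s window defaults to the segment start
with a configurable offset. Spectra use a Blackman taper and report
local maxima above 50× the median spectral power and above 10⁻⁶ of the
peak (so numerical leakage in noiseless signals never registers);
white noise passes this floor in <10 % of runs while planted tones
exceed it by orders of magnitude.

## Synthetic data model

The generator emulates what drives the analysis, not optics:

* **Geometry** — a sphere of radius R; nuclei placed by dart throwing
  with minimum center distance 1.5× the nucleus radius (configurable
  down to force overlaps for stress tests). The z-stack covers the
  sphere in equal slabs; **each nucleus renders once, as a 2-D Gaussian
  (σ = r/2) on its nearest plane**, idealising one optical section per
  slab. Consequences: per-plane counts follow the circle-of-latitude
  profile (maximal at the equator) and summing planes recovers the
  planted total — both tested.
* **Signal model** — peak amplitude `abu_per_fluorophore` (default
  300 abu) with 10 % per-nucleus jitter, attenuated by exp(−α·depth)
  (α = 0.002/µm default, the simplest monotone model of residual
  absorption after clearing); additive haze = a thickness-profile dome
  (smoothed by ~σ = min(haze_scale/2, 6) px, since scattering spreads
  haze beyond sharp sample borders) plus a random smooth field; additive
  Gaussian noise, clipped at zero.
* **Composition** — zone markers are Bernoulli draws with per-shell
  probabilities (three concentric shells by default, precursor markers
  enriched in the core). Tracker labelling for dilution series is
  Bernoulli per nucleus, so realized counts are binomial — that noise,
  not the imaging, limits R² at small aggregate sizes. Toxin-plate
  subpopulations (TH/Map2) are mutually exclusive with *exact* counts:
  these organoids are homogeneous in composition well-to-well, so only
  the spatial arrangement and the kill draw are random. Killed cells
  are removed from the scene entirely (dead cells are cleared from
  tissue).
* **Artifacts** — dust: a compact very bright blob planted ≥ 28 px off
  the aggregate rim (beyond the reach of the 10 px mask dilation);
  fiber: a long thin bright streak. Both serve as QC positive controls.
* **Time series** — synchronized spikes at a fixed period (instant
  rise, exponential decay, optional per-ROI private events, optional
  switch-off time for the channel-blocker scenario); field potentials
  are phase-locked sinusoid sums plus independent electrode noise.

Not modelled: light scattering, a realistic PSF, spectral cross-talk,
vignetting, or saturation. Passing tests therefore show the *analysis
logic* is correct and quantitative under a plausible image-formation
model; they do not certify performance on any particular microscope.

## Study conditions used by tests and the acceptance script

Scaled-down once, as this package's choice, and then fixed:

* Dilution series: fractions 1.25/2.5/5/10/20/40 %, 3 replicates, two
  sizes (1000 nuclei at R = 90 µm; 2000 at R = 115 µm), 8 planes,
  256² px at 1 µm/px, default attenuation/haze/noise. Expected R²
  from binomial counting statistics alone is ≈ 0.995 at the small
  size, so the ≥ 0.99 bar genuinely tests the imaging chain.
* Segmentation benchmark: 500 non-overlapping nuclei on one 640² plane,
  SNR 5.
* Edge-effect plates: full 96 wells, R = 40 µm, 4 planes, 128² px,
  filament density 60 abu with a −10 % interior effect (or 0 for
  nulls). The measured relative difference (≈ −7 to −9 %) sits below
  the planted 10 % because the raw in-mask readout includes
  marker-independent haze — the same dilution a real stained sample
  would show.
* Toxicity assay: doses 0/50/100/250/500 µM, 6 replicates, R = 60 µm
  organoids of 240 cells (20 % TH, 30 % Map2, soma radius 4 µm),
  6 planes, TH kill curve = logistic with EC50 100 µM, Hill 1.5, 90 %
  max kill; quantified with the cell finder (expected diameter 10 µm)
  after channel-specific high-pass.
* Time series: 10 Hz × 240 s calcium with 30 s period; 1 + 14 Hz field
  potentials at 200–1000 Hz sampling.

All generators and analyses are seed-deterministic; identical seeds
give byte-identical stacks and result tables.

## Known limitations

* Counting loses ~5–10 % of nuclei to in-plane fusion when slab
  projection puts neighbours within ~5 px laterally; summed brightness
  is robust to fusion (footprints merge, intensity sums), which is why
  dilution linearity regresses brightness, not counts.
* The edge-effect readout under-reports a planted multiplicative effect
  in the presence of additive haze (see above); the sign and CI are the
  reliable outputs.
* The paraboloid curvature and the detection threshold are per-campaign
  calibration parameters; the shipped presets match the synthetic
  scenes' gain and geometry only.
* 3-D object linking across planes is deliberately absent: the method
  counts per plane and sums, so a structure spanning several optical
  sections would count once per section. With slab-partition rendering
  this cannot occur in the synthetic data.
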