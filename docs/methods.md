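# Methods

## The detection model and its assumptions

The detector treats a synapse as a bright, compact, roughly elliptical
punctum riding on a darker surround, present on a short run of adjacent
z-planes. Nothing is learned from data: the rule system itself is the
definition of a detected synapse. The assumptions that make this work are
(i) puncta are diffraction-limited or nearly so in z (axial PSF FWHM
2.5 µm at 1 µm z-steps spreads even a thin structure over 2–4 planes);
(ii) in-plane puncta sizes fall in a known physiological band
(0.125–1.25 µm², i.e. 20–150 px at 0.096 µm pixels); (iii) background
structures are either much darker (vessels, somata — removed by the
exclusion mask) or much more extended in z (autofluorescence — removed by
the wide-average rule).

### Matched-template SNR

Each candidate is scored against every family member as
`SNR = (mean(fg) − mean(bg)) / σ`, where fg is the rasterised ellipse
interior, bg the surrounding 3-px ring, and σ the standard deviation of
the 65 × 65 defining window. The window convention keeps the denominator
noise-dominated at every contrast (foreground plus ring occupy at most
~8% of the window), so the SNR of a bright punctum keeps growing with
contrast and the slice-averaging rules below remain well conditioned.
Two alternatives are available through `DetectionConfig.snr_std_region`:
`"region"` (σ over fg ∪ bg) saturates at a pattern-geometry ceiling of
about 1.6 once the punctum is several times brighter than the noise, at
which point every SNR comparison degenerates into a coin flip — measured
on synthetic volumes this costs ~20% recall; `"bg"` (σ over the ring
alone) makes template selection run away to the largest family member,
because enlarging a template moves its ring off the object's slope and
shrinks the denominator. Both are retained for comparison, neither is
recommended.

### Slice-averaging rules

`snr3` is the SNR of the winning template on the pixelwise mean of planes
z−1…z+1 and `snr7` on the mean of planes z−3…z+3 (truncated at stack
ends). Acceptance requires `snr3 ≥ (2/3)·snr1` — a synapse's signal
persists on neighbouring planes while single-plane noise is diluted by
~1/√3 — and `snr7 ≤ snr3`. The second comparison is deliberately against
the 3-plane average, not the single plane: for an axially PSF-limited
punctum the matched SNR *peaks* at an averaging window matching its own
axial extent, and the 7-plane SNR sits almost exactly at the single-plane
SNR on the peak plane (axial profile mass 2.66 planes: 2.66/7·√7 ≈ 1.005)
and above it on the flanking planes. A `snr7 ≤ snr1` rule therefore
accepts only peak planes, which the 2–6-plane validity rule would then
discard wholesale; `snr7 ≤ snr3` expresses the intended "wider averaging
must not help" test. The single-plane baseline and a `snr3 ≥ snr1`
variant of the first rule remain available as configuration switches
(`snr7_baseline`, `snr3_rule`).

### The null threshold

The SNR cut is the 90th percentile of best-template SNRs at 300 random
null locations. Defining the null population needs care because the test
statistic is evaluated at *local maxima* of the blurred volume, which are
biased high relative to arbitrary voxels: a percentile of arbitrary-voxel
SNRs sits below the entire noise-maxima band and passes ~25% of them.
The default (`null_locations="snapped"`) therefore draws 300 voxels
uniformly in space (outside the exclusion mask) and snaps each to the
brightest blurred position within 2·σ_xy in-plane — a spatially uniform
sample of local maxima. Because puncta occupy a small fraction of *area*
at any realistic density, this null stays noise-dominated even when
puncta make up a quarter of the candidate list, where a null drawn from
the candidates themselves would land inside the synapse SNR band (and,
worse, would track global intensity changes, silently cancelling the very
potentiation effects the longitudinal statistics measure). `"candidates"`
and `"uniform"` sampling remain available.

### Parameters

All thresholds live in `DetectionConfig`; the defaults are the published
operating point of the rule system and are not meant to be tuned:

| parameter | default | meaning |
| --- | --- | --- |
| `sigma_xy`, `sigma_z` | 5, 1 px | candidate-finding blur |
| `min_candidate_dist` | 3 px | in-plane farthest-first pruning radius |
| `area_min_px`, `area_max_px` | 20, 150 | template foreground area band |
| `roundness_min/max`, `n_roundness` | 1–2.5, 4 | major/minor axis ratio grid |
| `n_angles` | 12 | orientations over [0, 2π) (duplicates removed) |
| `n_areas` | 12 | area grid (count unpublished; 12 keeps ~200 templates) |
| `window_radius`, `bg_width` | 32, 3 px | template window and background ring |
| `exclusion_z` | −1 | blurred z-score cutoff for dark regions |
| `n_null_locations`, `null_percentile` | 300, 90 | SNR null sample |
| `snr3_min_fraction` | 2/3 | 3-plane SNR retention |
| `z_span_min/max` | 2, 6 | valid synapse axial extent (planes) |
| `min_overlap_px` | 1 | XY overlap required to merge adjacent planes |

Numerical conventions: per-plane maxima use a strict 8-neighbour
comparison (plateaus are dropped; after floating-point blurring exact ties
have measure zero), and pixels within 1 px of the XY edge never qualify.
The farthest-first traversal starts at the brightest peak and breaks
max-min-distance ties by input order (brightest first). Template SNR ties
are broken towards smaller area, then smaller axis ratio, then smaller
angle, by pre-sorting the family. Windows at volume borders are
reflection-padded. Batch scoring uses float32 matrix products; the
scalar float64 path (`template_snr`) is the reference the tests compare
against. Every stage is deterministic given `rng_seed`, which is recorded
in the JSON sidecar/manifest of every output.

## The synthetic ground-truth generator

`generate_volume` emulates the imaging physics the detector assumes:
elliptical single-plane discs (area ~ U(0.125, 1.25) µm², axis ratio
~ U(1, 2.5), orientation ~ U(0, π)) placed with a minimum XY-projected
centre separation (default 1.5 µm) and clearance from vessels, made 3D by
a separable Gaussian PSF (FWHM 0.55/0.57/2.50 µm in X/Y/Z), on a constant
background with Gaussian read noise, optional Poisson shot noise, and
dark ellipsoidal vessel regions. Vessels attenuate the scene *before* the
PSF acts, so their edges are optically smooth. Structure (positions,
shapes, amplitudes, vessels) and noise draw from independent streams
spawned from one seed, so longitudinal replicates redraw noise alone;
regeneration is bit-exact.

Two definitional choices matter for interpreting results:

- **Amplitude is observed peak contrast.** A punctum's `amplitude` is its
  post-PSF peak intensity above background; the painted disc height is
  scaled by the punctum's own PSF attenuation (0.15–0.35 for these
  sizes). "Contrast 10" therefore means what a microscopist would
  measure on the image, independent of punctum size. The default
  conditions are `amp_median = 80`, log-normal spread 0.3,
  `sigma_read = 8` (contrast ≈ 10); validation suites that require
  uniformly high-contrast puncta set the spread to 0.
- **Truth footprints are per-plane half-max contours.** A plane carries a
  punctum when its in-plane peak reaches half the punctum's 3D peak
  (giving the 2–4-plane extent the validity rule expects); on each such
  plane the footprint is the half-maximum contour of that plane's own
  profile. The alternative — one 3D half-max isophote — shrinks off-peak
  footprints to ~0.45× the centre area even though the *image's* XY
  profile is identical on every plane (only dimmer), so no per-plane
  segmentation could match it to 50% voxel overlap even in principle;
  the per-plane definition makes voxel-overlap evaluation well
  conditioned in both directions.

What the generator does **not** emulate: vascular morphology (vessels are
ellipsoids), photobleaching or motion within a session, depth-dependent
scattering, sub-plane punctum z-positions, spatially varying background,
and extrasynaptic/dendritic-shaft fluorescence. Passing the synthetic
recovery suite therefore demonstrates that the rule system is implemented
faithfully and is self-consistent under its own physics — not that these
precision/recall figures transfer to real tissue, where agreement with
human annotators is the relevant benchmark.

## Longitudinal statistics

Sessions are aligned to the first by integer translation (zero-mean FFT
cross-correlation, ties to the smallest shift), detected independently,
and summarised by per-synapse summed raw intensity (background included —
the footprint sum of the native-scale voxels) and maximum single-plane
area. Intensities are divided by the pooled-baseline mean (mean, not
median, switchable), and each session is compared to the pooled baseline
with a two-sided Mann–Whitney U test: midrank tie handling, exact p by
full enumeration of the permutation null when the smaller sample has ≤ 8
values and the enumeration is tractable (≤ 2·10⁵ arrangements), otherwise
a tie-corrected normal approximation with continuity correction. Synapse
identity is *not* tracked across sessions; all statistics are
population-level, so the per-synapse size spread (σ of log intensity
≈ 0.5 under default conditions) enters the test as noise and sets the
sample sizes needed to resolve a given intensity shift: a uniform ×1.2
amplitude change surfaces as a ~6% shift in summed intensity and needs
on the order of 600–1000 synapses for p < 0.01.

Validation problem sizes (chosen once from this power analysis): detection
recovery uses ten 256×256×20 volumes with 40 puncta at contrast 10; the
noise-degradation sweep doubles `sigma_read` from 8 to 64; the
potentiation arm uses 750 puncta in 20×1024×1024 (1150 in 20×1280×1280 in
the reproduction script) with two baseline sessions and one ×1.2 session;
the null calibration runs 100 replicated-session pairs (25 puncta,
12×128×128) with intensities measured on the ground-truth footprints,
which isolates the statistic from detection variability.

## FRAP fitting

Traces are normalised by the per-timepoint mean of unbleached spines
(cancelling imaging drift) and scaled so the pre-bleach baseline is 1.
The recovery — expressed as the fluorescence increase after the bleach,
so Y0 ≈ 0 — is fitted over t ∈ [0, 30] min by bounded least squares on
`Y(t) = (Y0 − Plateau)·exp(−k·t) + Plateau` with 0 ≤ Y0, Plateau ≤ 2 and
k > 0, initialised at Y0 = first value, Plateau = last value, and k from
a log-linear regression of |Plateau − Y|. `tau = 1/k`;
`mobile_fraction = (Plateau − Y0)/(prebleach − Y0)`. A flat trace is
flagged degenerate (plateau = the constant, k = NaN) rather than forced.
The optional robust pass discards points with absolute studentized
residual > 3 and refits once — a documented, reproducible stand-in for
proprietary outlier-removal procedures, disabled by default. The late
second recovery phase (t > 30 min) is deliberately outside the model and
is reported descriptively if at all.

## Known limitations

- Closely z-abutting puncta (within the axial PSF) are unresolvable by
  construction; the 2–6-plane rule discards the resulting over-long
  merges rather than splitting them (no watershed).
- Detected footprints are template ellipses, not free-form boundaries:
  per-plane areas are quantised to the family grid and carry its
  orientation resolution (30°).
- Alignment is integer translation only; rotation and non-rigid motion
  are out of scope.
- The Mann–Whitney longitudinal comparison is unpaired; tracking synapse
  identity across sessions would greatly increase power but is not
  implemented.
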