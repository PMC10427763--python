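# Methods

This note documents the models, defaults and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## PIV engine

Displacement between consecutive frames is estimated per interrogation
window by circular FFT cross-correlation of zero-mean windows. Window mean
subtraction is the only normalization: it makes the estimate robust to
uniform illumination changes without the noise amplification of full
per-pixel normalization.

Multipass scheme: default passes of 64 px then 32 px windows at 50% overlap.
After each pass the grid field is bilinearly interpolated to a dense
per-pixel field (constant extrapolation outside the grid hull) and the
second frame is warped by it (bilinear image interpolation) before the next,
finer pass measures the residual. This "window deformation" extends the
dynamic range beyond the one-quarter-window rule and sharpens the
correlation peak under shear.

Subpixel peak: independent 3-point Gaussian fits along x and y, falling back
to a parabolic fit when any stencil value is non-positive (the Gaussian fit
needs positive correlation values for its logarithms). Windows with zero
correlation energy (constant intensity) are flagged invalid immediately.

Validation: the normalized median test (residual against the median of the 8
neighbours, normalized by the median absolute neighbour fluctuation + ε) with
ε = 0.1 and threshold 2.0, plus a hard magnitude cut at half the window
size. Invalid vectors are replaced by the mean of their valid 8-neighbours
and carry `valid=False, replaced=True` flags. The median test assumes
isolated outliers; a contiguous cluster of corrupted windows larger than the
neighbourhood can survive it (verified in the test suite by construction).

Tracking: a reference point (in practice a myonucleus, chosen because whole
myotubes contract heterogeneously) is advanced each interval by the
interpolated field at its current position. Displacement converts to µm only
at this boundary; everything upstream is px/frame. A trajectory leaving the
grid hull truncates the trace and flags it rather than extrapolating.

Coordinates are 0-based with origin at the top-left pixel center, x along
columns, y along rows.

## Twitch kinetics

Extrema detection runs on a Savitzky–Golay-smoothed copy of the trace
(window 5 samples, quadratic; disabled by `smooth_window=0`) so that
single-sample noise dips cannot masquerade as twitch boundaries; each
detected extremum is then snapped to the raw-trace extremum within the
smoothing radius, which removes the timing bias smoothing would otherwise
introduce at asymmetric peaks. Prominence is relative (default 10% of the
trace range) because absolute amplitudes vary by an order of magnitude
between cells. Alternation is enforced by keeping the more extreme of two
same-kind neighbours. The leading sample is admitted as an extremum
(traces start at rest); a trailing minimum is admitted only where the trace
demonstrably settles before the recording ends, so a truncated final cycle
yields no event.

Timing resolution: twitch phase durations are index differences, quantized
to the sample interval. At 20 ms sampling with 10% amplitude noise, the
median timing error is one sample at 5–10 Hz pacing and two to three samples
at 2 Hz, where the twitch valley is so shallow that adjacent samples differ
by less than the noise — an information floor of extremum-based timing, not
an estimator defect.

Dominant frequency: largest non-DC amplitude of the 4×-zero-padded FFT of
the mean-subtracted trace (bin width 0.125 Hz at 2 s / 20 ms). A peak must
exceed 5× the median spectral amplitude, otherwise 0 Hz is reported (no
periodic motion above the noise floor). The reported `period` is
1/frequency; this is the "wavelength" of the representative sine in the
temporal sense.

Contraction velocity: the mean of per-interval instantaneous speeds over the
first 2 s (the analysis window of the assay), computed from the tracked
position steps, not from field magnitudes averaged over the cell. For a
rectified wave of peak amplitude A at frequency f the analytic mean speed is
2·A·f (path 2A per period).

Fatigue: the pre-stimulation baseline (required, supplied as the first
`baseline_window` seconds of the trace) sets a threshold of 2× baseline RMS
velocity. Fatigue time is the first instant from which the RMS velocity over
the following 1 s (`sustain`) is below threshold; the RMS series is smoothed
with a centered moving average at the sustain scale first, because the first
crossing of an unsmoothed noisy series triggers on downward fluctuations and
biases the estimate early. Both the threshold factor and the sustain window
are statistical choices — the assay defines cessation only as "stopped
moving". A trace with zero motion throughout reports fatigue time 0.

## Morphometry

Preprocessing: max-intensity projection (if 3D), rolling-ball background
subtraction (default radius 50 px), Otsu threshold, minimum object area
64 px. The Otsu threshold is refined to the midpoint of the two class means
it induces (iterated to convergence); on well-behaved histograms this is a
no-op, but it keeps the threshold out of a background cluster that collapses
into a single histogram bin on low-noise images.

Average width: total foreground area divided by centerline length. The
centerline is the morphological skeleton with terminal branches shorter than
twice the local distance-transform radius removed (digitization spurs), and
the chain length (1 per 4-step, √2 per diagonal, corner shortcuts not double
counted) is extended by the local radius at each endpoint, because the
skeleton of a ribbon stops half a width short of its ends. On straight
ribbons of 8–40 px width the estimator is accurate to well under 10% and
monotone in the true width.

Myonuclei: 8-connected DAPI components above 9 px with ≥ 50% of their area
(boundary inclusive) on the actinin mask. Density normalizes the count by
the full image area in mm².

Spacing: nucleus centroids are projected to their arc-length position along
the tube centerline; neighbour distances are consecutive gaps after sorting,
summarized as mean and CoV = population SD / mean (`ddof` configurable;
straight-line consecutive distances available via `method="euclidean"`).
Arc-length projection was chosen because curved tubes make straight-line
distances underestimate separation.

Striation scoring is deliberately absent: in the source assay it was a
manual classification.

## Puncta scoring

BTX: the background is the center of the most populated of 64 histogram bins
spanning the observed range of per-nucleus mean intensities (ties take the
lower bin); a nucleus is AChR-positive iff its mean is strictly greater than
2× background. The strict inequality and the centroid-membership rule for
boundary-straddling spots (below) are deterministic tie-breaks. Fewer than
10 nuclei raise an error advising pooling images, since a mode over fewer
observations is meaningless.

Cluster shape: area, chain-perimeter, circularity 4πA/P², roundness
4A/(π·major²) with the major axis from the second-moment ellipse. Roundness
is clamped at 1.0 (digitization can push the ratio marginally past the
continuous bound). Components under 5 px are measured but flagged
unreliable.

Perinuclear regions: all tube-mask pixels whose arc-length projection lies
within ±50 µm of the nucleus projection. Bands truncate at tube ends (round
end caps project onto the terminal centerline point and are included when in
range). A nucleus farther than 25 µm from the centerline is rejected.

Spot counting: 8-connected components of the binarized smFISH channel with
pixel area within configurable [min, max] bounds (no evidence-based default
exists for the upper bound; both are exposed), counted if their centroid
lies in the region. Densities divide by a caller-supplied normalizer:
myotube-region area for receptor-subunit and filamin probes, myonucleus area
for myosin isoform probes, matching the two normalizations used for those
probe families.

## Statistics

ROUT (location-only model, the case arising for univariate group data): the
robust center is an iteratively reweighted mean with Lorentzian weights
1/(1 + (r/s)²); the robust SD of residuals (RSDR) is the 68.27th percentile
of |residuals| with an n/(n−1) correction. Each residual's two-tailed t-tail
probability (df = n−1) is tested from the most extreme inward against the
FDR ladder α_i = (Q/100)·i/n, stopping at the first failure. At Q = 1 this
flags a planted 10σ point in ≥ 99/100 trials while flagging ~0.03% of clean
normal samples. All-identical samples (RSDR 0) flag nothing.

t test: Student's pooled-variance two-tailed test by default (Welch via
flag). Zero pooled variance is handled explicitly: equal means → (0, 1);
unequal → (±∞, 0) with a warning.

Pearson: product-moment r, r² reported, p from the t transform, CI of r via
Fisher z (undefined-width cases fall back to a degenerate interval).

ΔΔCt: per-sample ΔCt against the housekeeping gene, group means, ΔΔCt =
treated − control, fold change 2^−ΔΔCt. Significance is |log2FC| strictly
greater than 0.5. By construction the statistic is invariant to per-sample
additive shifts of all Ct values. Outlier removal, when used in a pipeline,
is applied per group before testing (configurable).

## Synthetic data

Waveforms are rectified periodic pulses: each period rises over
`acceleration_fraction` of the period and relaxes over the remainder (both
half-cosine limbs); `sine` is the symmetric special case
0.5·A·(1 − cos 2πft). `fatigue_decay` multiplies the amplitude by
exp(−t/decay_time). An `onset` delay renders pre-stimulation quiescence for
fatigue analysis. Ground truth lists every complete twitch's true extrema
times, amplitude and phase durations.

Movies render each tube as a speckle texture (smoothed uniform noise, grain
3 px — coarse enough for correlation windows to lock onto) translated
rigidly along the tube axis by the waveform displacement, sampled at
subpixel offsets by bilinear interpolation, plus additive Gaussian sensor
noise. Rigid motion keeps every nucleus's ground-truth trace exact. The
default study conditions used by the validation runs are 2 s recordings at
20 ms/frame, 0.25 µm/px, 1 µm amplitude and image noise SD 2 intensity units
against ~30 units of texture contrast (SNR ≈ 15, typical of time-lapse
brightfield).

What the generator does **not** emulate: local strain along the tube
(contraction is rigid), photobleaching, defocus, sarcomere banding, nucleus
appearance changes, 3D stacks, or segmentation-confounding cell debris.
Passing tests therefore demonstrate the correctness of the measurement
chain, not robustness to every real-microscopy artifact.

Morphology scenes render tubes as constant-intensity ribbons, nuclei as
disks (BTX disks at background level or at 3× background for AChR-positive
nuclei), puncta as small disks, plus Gaussian noise. Scene validation
rejects geometry outside the frame and nuclei in one tube closer than the
sum of radii + 2 px, which would make counting ambiguous.

Ct tables are built so that the expected 2^−ΔΔCt equals 2^(true log2FC)
exactly at zero noise.

All randomness flows through one `numpy.random.Generator` seeded explicitly;
identical seeds give bit-identical outputs.

## Validation problem sizes

The acceptance script and test suite use: 192² px frames for shift-theorem
checks; 20 movies of 100 frames (128×256 px) for end-to-end kinetics; 50
seeded 25 s traces for fatigue (10 Hz pacing, where the threshold crossing
is well conditioned — at 2 Hz the crossing occurs so early that its
definition is ambiguous at the ±15% level); ribbons of 8–40 px width for the
width estimator; 50 rendered scenes of 10 nuclei for BTX classification;
10,000 draws for t-test null uniformity; 100 planted-outlier and 500 clean
trials for ROUT. These sizes were chosen to make the stochastic checks
stable across seeds.

## Known limitations

- Single-tube movies with one global waveform; heterogeneous or multi-tube
  motion fields are representable by the PIV engine but not generated.
- The tracker interpolates the displacement field rather than re-detecting
  the nucleus, so it inherits PIV bias near strong intensity edges.
- Skeleton-based centerlines assume an essentially unbranched tube after
  spur pruning; dense branched cultures need instance segmentation first,
  which is out of scope.
- ROUT is the location-only variant; regression ROUT (outliers from a fitted
  curve) is not implemented because no stage fits curves to grouped data.
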