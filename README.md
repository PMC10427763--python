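# twitchkit

Quantitative analysis of optogenetically paced skeletal-muscle cultures.
`twitchkit` turns the two standard readouts of an in-vitro "exercise" assay
into numbers:

1. **Contractility** — from time-lapse movies of ChR2-expressing myotubes
   twitching under blue-light stimulation, it computes particle image
   velocimetry (PIV) displacement fields, tracks a reference myonucleus
   through them, and extracts per-cell twitch kinetics: amplitude,
   acceleration and relaxation phase durations, dominant pacing frequency,
   contraction velocity, and the time to fatigue under continuous
   stimulation.
2. **Maturation** — from multi-channel fluorescence images (α-actinin, DAPI,
   α-bungarotoxin, smFISH), it measures myotube width, myonuclei density and
   spacing uniformity, the fraction of AChR-positive nuclei, receptor-cluster
   shape, and perinuclear mRNA densities.

A statistics module supplies the accompanying inference: ROUT outlier
removal (Q = 1%), two-tailed unpaired t tests, Pearson r² with confidence
intervals, and 2^−ΔΔCt relative expression from qPCR Ct tables.

A first-class synthetic-data module generates every input with known ground
truth — textured contracting tubes with prescribed waveforms, tube + nuclei +
puncta images with known geometry, Ct tables with known fold changes — so
the entire pipeline is testable without any microscopy data.

## The core algorithms

**PIV.** The displacement field between consecutive frames is estimated by
multipass FFT cross-correlation: interrogation windows of 64 px, then 32 px
(50% overlap), with the second pass warping the target frame by the
dense-interpolated first-pass field (window deformation). Each correlation
peak gets a 3-point Gaussian subpixel fit; vectors failing the normalized
median test (ε = 0.1, threshold 2.0) are replaced by the mean of their valid
neighbours and flagged. A nucleus at position **x**₀ is tracked by Lagrangian
integration, **x**ₜ₊₁ = **x**ₜ + **u**(**x**ₜ), and its displacement trace is
d(t) = ‖**x**ₜ − **x**₀‖ · pixel size.

**Twitch kinetics.** Local extrema of d(t) with prominence ≥ 10% of the
trace range are forced to alternate; each min → max → min triple is one
twitch with amplitude d(peak) − d(start), acceleration time
(peak − start)·Δt and relaxation time (end − peak)·Δt. The dominant
frequency is the largest non-DC peak of the 4×-zero-padded FFT of the
mean-subtracted trace. Fatigue time is the first instant at which the RMS
velocity over the following 1 s falls below 2× the pre-stimulation baseline
RMS.

**Morphometry.** Binarized α-actinin gives the myotube footprint; its
average width is total area / centerline-skeleton length (spur-pruned, with
end-cap correction). DAPI components with ≥ 50% overlap on the actinin mask
are myonuclei; per-tube spacing uniformity is the coefficient of variation
of consecutive arc-length gaps along the centerline.

**Puncta scoring.** The BTX background is the modal histogram bin of
per-nucleus mean intensities; a nucleus is AChR-positive when its mean is
strictly above 2× that background. smFISH spots are 8-connected components
counted inside the perinuclear band: all myotube pixels within ±50 µm arc
length of the nucleus.

## Worked example

```python
import numpy as np
from twitchkit import synthetic as syn, piv, kinetics

# a 2 s movie at 20 ms/frame: 5 Hz pacing, 1 µm twitch amplitude
spec = syn.WaveformSpec(kind="sine", frequency=5.0, amplitude=1.0,
                        duration=2.0, sample_interval=0.02)
scene = syn.make_tube_scene(noise_sd=2.0)
stack, truth = syn.generate_movie(spec, scene, seed=7)

fields = piv.movie_to_fields(stack)                    # 99 vector fields
nucleus = scene.nuclei[1]
start = (nucleus.center[0] / scene.pixel_size,
         nucleus.center[1] / scene.pixel_size)
trace = piv.track_point(fields, start, stack.pixel_size, stack.frame_interval)

summary = kinetics.summarize(trace, window=1.9)
print(f"dominant frequency : {summary.dominant_frequency:.3f} Hz")
print(f"contraction velocity: {summary.contraction_velocity:.2f} um/s")
print(f"twitches detected  : {summary.n_twitches}")
print(f"acceleration time  : {summary.mean_acceleration_time*1000:.0f} ms")
```

prints

```
dominant frequency : 5.000 Hz
contraction velocity: 9.67 um/s
twitches detected  : 9
acceleration time  : 100 ms
```

The recovered frequency is exact to the padded FFT bin (0.125 Hz); the
velocity approaches the analytic mean speed of the rectified 5 Hz, 1 µm wave
(2·A·f = 10 µm/s); the 9 complete twitches are symmetric (acceleration =
relaxation = half the 200 ms period), and the tenth cycle is dropped because
its closing minimum falls past the end of the recording.

The same pipelines are scriptable from the shell:

```bash
twitchkit simulate --kind sine --frequency 5 --out movie.tif
twitchkit piv --movie movie.tif --px-size 0.25 --dt 0.02 --point 128,64
twitchkit morpho --actinin a.tif --dapi d.tif --px-size 0.227
twitchkit stats --test ddct --data ct_table.csv
```

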