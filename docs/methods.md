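# Methods

`fovdisp` is an image-computable model of human binocular disparity
processing across the visual field, together with the psychophysical
machinery needed to run the model as a simulated observer.  This note
documents the model, its parameters, the numerical choices, and what the
synthetic stimuli and desk-scale protocols do and do not establish.

## Retino-cortical front end

The space-variant sampling of the human retina is modelled by the central
blind-spot log-polar transform

    xi  = log_a(rho / rho0),      eta = q * theta,

with `rho0` the radius of a discarded central disk (avoiding the log
singularity), `a = (rho_max/rho0)^(1/R)` the radial growth base and
`q = S/(2*pi)` the angular resolution.  Discretized on an `R x S`
(rings x sectors) grid this yields the cortical image.  Sector count
follows the isotropy rule `S = round(2*pi/(a-1))`, which equates the local
circular and radial sampling intervals and drives the log-polar pixel
aspect ratio to 1.  Derived descriptors:

* compression ratio `CR = Nc*Nr/(R*S)` — retina-to-cortex data reduction,
  the model's knob for the strength of cortical magnification;
* maximum receptive-field size `Wmax = rho0*a^R*(1-1/a)` — the scale at
  which the far periphery is processed;
* foveal fraction `chi` — the fraction of rings that oversample the image.

Each cortical node averages the Cartesian image under a circular Gaussian
receptive field centered on the inverse-mapped node position.  The
published model description calls only for overlapping circular Gaussian
receptive fields, without sizes, so the package sets the Gaussian sigma to
half the local log-polar pixel width `rho0*a^u*(a-1)/2`, floored at 0.5 px in the
oversampled fovea and truncated at 3 sigma.  This gives roughly two-fold
overlap and anti-aliases the undersampled periphery.  The forward and
backward transforms are precomputed sparse operators (Gaussian weights,
row-normalized; bilinear interpolation with circular wrap in `eta`), so
repeated transforms cost a sparse mat-vec.  The backward transform fills
the blind spot and the region beyond `rho_max` with a declared fill value
(the mean cortical activity by default); it is used for visualization and
for returning decoded disparity to retinal coordinates.

With the published full-scale geometry (`R = 318`, `rho0 = 9` px,
`CR = 6.4` on a square image, isotropic sectors) the field radius solves to
`rho_max ≈ 501` px; mapping the 21-degree stimulus field onto it makes the
preferred-disparity range of ±1.52 cortical px correspond to ±0.43 arcmin
at the foveal edge.  At the peripheral end the same computation gives
±24.2 arcmin; the model description this package follows reports ±25.
The ~3% gap is consistent with rounding in the published geometry (e.g.
integer sector counts) and is documented here rather than asserted by the
test-suite.

## Stimuli

Psychophysical stimuli are 1/f (pink) noise stereograms carrying an oblique
(45° or 135°) sinusoidal disparity corrugation, windowed to an annulus with
1-degree raised-cosine edges; the noise carrier itself is confined to the
annulus (mid-gray outside), as in dichoptic presentation on a gray
background.  The corrugation is rendered by resampling the carrier by ±d/2
horizontally in the two eyes (cubic interpolation), which keeps the
cyclopean geometry centered and leaves each eye's amplitude spectrum at the
1/f slope (no usable monocular artifact).  Field geometry is specified in
degrees and realized at a configurable `pixels_per_degree`; 23.86 px/deg
reproduces a 0.311-mm-dot-pitch display at 45 cm, on which the 21-degree
field radius spans ~501 px.

## Cortical population model

**V1.** Binocular simple cells follow the phase-shift model: left/right
receptive fields are complex Gabors (zero-mean, unit-energy) sharing a
center and differing in carrier phase by `delta_psi`; the response is the
sum of the monocular convolutions, with the quadrature partner from the
imaginary parts.  Convolutions mirror along rings and wrap along sectors
(the cortex is an annulus).  A channel's preferred cortical disparity is
`d = delta_psi/(2*pi*fs)`; the K = 5 channels sit at `{-D, -D/2, 0, +D/2,
+D}` with `D = 1.52` cortical px.  With `fs = 0.13` cycles/px this puts
`delta_psi` within ±71°.  Complex cells compute binocular energy
`R² + R_q²`, then a 0.5-power nonlinearity with divisive normalization
across the 12 orientations (floor `epsilon = 1e-6`) removes local-contrast
confounds.  Orientations sample the full circle (theta is the carrier
direction); a cell at `theta+pi` with channel `-d` duplicates `(theta, d)`,
a redundancy the cosine MT weights require.

The published relation between filter scale and bandwidth cannot reproduce
`sigma = 5.12` px at `fs = 0.13` as printed; this package derives it from
the one-standard-deviation amplitude-spectrum cutoff,
`sigma = (2^B+1)/((2^B-1)·2*pi*fs)`, treats `sigma = 5.12` as authoritative
and reports the implied bandwidth B ≈ 0.70 octaves.

**MT.** MT units pool V1 afferents with a Gaussian (`sigma_pool = 3.66`
cortical px, wrap along sectors), weight orientations by
`w_phi(theta) = cos(phi - theta)` for the two tuning directions
`phi ∈ {0, pi/2}` (sufficient for a full disparity vector), and pass the
result through `exp(lambda * s)` with `lambda = 0.65`.  The cosine
weighting makes the MT tuning over preferred disparity sigmoidal rather
than bell-shaped; direction and sign are explicit in the population peak
while magnitude is recovered by the decoder.

**Noise.** Neural noise is zero-mean uniform with half-width equal to a
fraction of the local average activity (34% at V1, 18% at MT), drawn fresh
per unit and trial and clipped so rates stay nonnegative.  At V1 "local
average activity" is the mean normalized response over the tuning
dimensions at each location, which is zero without texture.  At MT the
exponential output has spontaneous level F(0) = 1 everywhere, so the noise
reference is the local mean of the *driven* modulation |E_MT − 1|;
otherwise unstimulated cortex would be the noisiest part of the map,
contradicting the localized responses to annular stimuli that the model is
supposed to exhibit.

**Decoding.** The cortical disparity components are linear sums of MT
activity over the preferred-disparity channels,
`d_xi(p) = Σ_i d_i·E_MT(p, 0, d_i)` (and `phi = pi/2` for `d_eta`), the
two-direction case in which the direction-sampling normalization constant
is 1.  This read-out is exactly homogeneous (`decode(αE) = α·decode(E)`)
but its slope against true disparity depends on the population's
tuning-modulation depth.  The package measures that population gain once
per parameter set by probing the noiseless stack with textured images at
known sub-range shifts (`decoder_gain`); dividing by it yields calibrated
cortical pixels, with uniform vector shifts inside ±D recovered within one
channel spacing at essentially all textured nodes.  The scale-free raw
read-out is what the tilt decision consumes.  A population-average variant
(divide by the summed channel activity) exists behind a flag but is *not*
suitable for magnitude recovery here: the exponential MT nonlinearity is
shallow at these parameters, so the softmax-style average compresses
magnitudes by an order of magnitude.

Decoded cortical components return to retinal coordinates through the
inverse mapping's Jacobian: at a pixel with polar coordinates
`(rho, theta)` the retinal displacement is `rho·ln(a)·d_xi` radially and
`(rho/q)·d_eta` tangentially, rotated by `theta`, then scaled to arcmin.

## Tilt decision and cue combination

The simulated observer's 2AFC decision reads the position of the dominant
peak of the Fourier magnitude of the retinal (horizontal) disparity map.
Conditions are blocked, as for the human observers, so only two peak
positions are consistent with the stimulus: the oblique wave vectors at
-45 and +45 degrees.  Each annular MT population (foveal, mid- and
far-peripheral -- the cortex is partitioned at the 3/9/21-degree ring
boundaries) contributes signed *tilt evidence*: the difference of spectral
power in ~1.5-bin Gaussian neighbourhoods of the two candidate
(conjugate-pair) positions, normalized by the mean power of the
surrounding frequency ring, computed on that population's own back-mapped
disparity field.  Components that do not complete one full cycle across
the population's aperture (diameter 2 x outer radius) are discarded
first: a disparity modulation slower than the aperture is
indistinguishable from a uniform disparity pedestal and carries no tilt
information.  This aperture rule is the model expression of why a small
central field cannot represent the lowest corrugation frequencies;
without it, a template reader exploits sub-cycle disparity ramps that
human observers demonstrably cannot use, and the foveal low-frequency
falloff disappears.  Symmetrically, a population contributes nothing
above the high edge of its representable band -- the V1 passband mapped
through the local magnification at its best (innermost) eccentricity,
`(fs + 1/(2*pi*sigma)) * ppd / (rho_inner * ln a)` -- where its receptive
fields cannot encode the corrugation and its spectrum is pure noise.
Both band edges follow from the mapping and filter parameters, not from
data.

The decision is the sign of the summed evidence.  The ring normalization
puts each population's evidence on a roughly inverse-variance scale, so
the sum is a near-optimal combination of disparity information across the
visual field: for annular stimuli only the stimulated population carries
evidence, and for full-field stimuli the combination inherits the best
region at every frequency (the envelope property).  A plain spectral
read-out of the undifferentiated full-field map fails in exactly the way
this combination predicts: the peripheral populations' noise drowns the
foveal signal at high corrugation frequencies.  Axis-aligned and
sub-aperture spectral structure (the radially symmetric signature of the
annular window and of the mapping) is common to both tilts and is ignored
by construction.  When no task frequency is supplied (free viewing of an
arbitrary map), the decision falls back to the most significant oblique
quadrant asymmetry across ~1-cycle radial bands; ties and empty spectra
yield a seeded random guess.

## Psychophysics

* **Staircase.** Three-down one-up with multiplicative, symmetric up/down
  steps (×1.5 until two reversals, ×1.26 after), converging at the
  `(1/2)^(1/3) ≈ 79.4%` correct level.  Asymmetric final steps were
  considered and rejected: they shift the convergence point away from the
  79% the procedure is defined to produce.
* **Psychometric fit.** Cumulative normal in log disparity with the lower
  asymptote fixed at 0.5 (2AFC, no lapses), fit to per-level proportions by
  least squares weighted by the reciprocal binomial SD (continuity-
  corrected at 0/1); threshold = the 75% point.  Because multiplicative
  staircases visit many near-unique levels, levels are grouped into
  quarter-octave bins before fitting, which stabilizes the proportions the
  weighted fit consumes.  Degenerate data (all
  proportions on one side of 75%) are flagged non-converged with the
  threshold pinned at the nearest tested level; converged thresholds are
  reported within half a log-unit of the tested range, since extrapolation
  beyond the levels the staircases visited is not meaningful.
* **DSF.** Sensitivity (1/threshold) versus corrugation frequency is fit
  with the three-parameter log parabola (peak gain, peak frequency, octave
  bandwidth at half height) by least squares in log10 sensitivity with
  multi-start over the peak-frequency grid.
* **MLE combination.** The optimal full-field threshold from regional
  thresholds is `T_opt = (Σ_v 1/T_v²)^(-1/2)`; infinite (unmeasurable)
  regions drop out.
* **Agreement metrics.** Pearson r (and r²) between model and
  participant-mean sensitivities on a matched condition grid, with a noise
  ceiling from leave-one-out between-participant correlations,
  Fisher-z-averaged and bootstrapped (1000 resamples, percentile 95% CI,
  squared).

## Protocols and desk scaling

The full protocol is 4 field conditions (0–3, 3–9, 9–21, 0–21 deg) × 6
frequencies (0.04–1.41 c/deg) × 24 interleaved staircases × 75 trials.
Simulated runs scale this down: the staircase count shrinks linearly with
the scale factor and trials per staircase with its square root (scale 0.2:
5 × 34), so staircases still descend from the start level into the
threshold region.  Desk-scale runs start at 5 arcmin with a 60-arcmin
ceiling: at reduced resolution the mapping's disparity tuning range spans
fewer arcmin than at full scale, and levels deep in the phase-wrapping
regime produce a non-monotone psychometric function that a 3-down-1-up
rule cannot recover from once it has drifted above the visible range.

Model geometry for reduced runs is specified in degrees (blind-spot radius
0.377 deg, field radius 21 deg, CR 6.4) and realized at a chosen
resolution, solving the ring count from the CR constraint; the cortical
parameters (`fs`, `sigma`, `D`, `sigma_pool` in cortical px) are
resolution-invariant, so a reduced model is a geometrically self-similar
scale model.  The package uses 6 px/deg (cortex 81 × 124) for the main
protocol run and 4 px/deg for parameter sweeps.  What does *not* scale:
with ~16× fewer cortical units than the full-scale model, per-map noise is
integrated over fewer samples, so absolute sensitivities are lower and the
arcmin axis is stretched (the foveal tuning range is ±1.7 arcmin at
6 px/deg versus ±0.43 at full scale).  Ordering patterns across regions
and the directions of parameter effects are preserved; absolute human
sensitivities are not reproduced at desk scale, and the model-vs-human
agreement of the original study is not a test surface here (per-participant
sensitivities are not published as data tables; `agreement_metrics` accepts
a user-supplied CSV).

## Model variants

* `LP` — log-polar front end, single scale (default).
* `LP2S` — adds a second, half-resolution cortical pyramid level; decoded
  fields are merged coarse-to-fine by averaging (no warping refinement).
* `noLP` — replaces the log-polar stage by uniform downsampling at
  `sqrt(CR)` (matching the pixel-count compression), so processing is
  eccentricity-invariant.
* `noLP2S` — uniform sampling with the two-level pyramid.

Sweep axes: compression ratio (rebuilds the geometry at fixed blind-spot
and field radii), cortical receptive-field scale (scales Gabor sigma up
and `fs` down together, preserving octave bandwidth; the preferred-
disparity range follows `fs`), and noise (scales both noise fractions).

## Numerical choices and edge cases

* Gabor kernels: support `2*ceil(3σ)+1` (31 × 31 at default parameters);
  exact DC removal by envelope subtraction; unit L2 energy.
* The monocular convolution is computed once per orientation and eye; the
  K phase channels are complex rotations of the same responses.
* MT spatial pooling uses reflect/wrap boundary modes along rings/sectors.
* `epsilon` in the divisive normalization guards 0/0 in untextured
  regions; it is far below textured pool levels, so normalized responses
  saturate to their contrast-invariant values at any realistic contrast.
* Staircase levels are clipped to `[min_level, max_level]`; reversals are
  logged on direction changes and switch the step factor after two.
* All randomness flows through `numpy.random.Generator`s seeded from a
  single `SeedSequence`; identical seeds reproduce experiments bit-for-bit.

## Known limitations

* The decision stage is an idealized blocked-design reader of the decoded
  map; it is not a model of perceptual decision making, and its aperture
  cutoff is a geometric, not mechanistic, account of the foveal
  low-frequency falloff.
* Horizontal/vertical disparity anisotropies, crossed/uncrossed
  asymmetries, vergence-dependent geometry and coarse-to-fine warping
  refinement are out of scope.
* The MT d-tuning is sigmoidal under cosine orientation weighting (see
  above); analyses that assume bell-shaped MT tuning curves should use the
  decoded field instead.
* Desk-scale runs trade absolute sensitivity for runtime, as quantified
  above; conclusions from them are ordinal.
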