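# Methods

This note documents the models, estimators and numerical choices behind
`embryopulse`, and what the synthetic study does and does not establish.

## Particle image velocimetry

Velocity fields are extracted from consecutive frame pairs by two-pass
frequency-domain cross-correlation. Pass 1 correlates 20 µm interrogation
windows on a regular grid; pass 2 correlates 10 µm windows whose search
windows in the second frame are offset by the rounded, bilinearly
interpolated pass-1 displacement, so the residual displacement is small
where the first pass is right. Window means are subtracted before
correlation; windows with vanishing variance are flagged invalid. The
integer correlation peak is searched within ± window/4 of zero lag, after
dividing the correlation plane by the loss-of-pairs triangle
(1 − |d|/N per axis) — without this normalization the peak is biased
toward zero displacement whenever the texture autocorrelation is broad.
Sub-pixel refinement uses the three-point Gaussian estimator, falling back
to the parabolic fit when a log of a non-positive correlation value would
be needed. Vectors are validated with the normalized median test
(threshold 2, regularization 0.1 px) against their 3×3 neighbourhood and
replaced by the local median when rejected; replaced vectors stay flagged.

The pass-2 grid uses 54 % overlap (4.6 µm spacing), chosen so that a
70-µm embryo contains ≈180 in-mask vectors; the embryo mask is an Otsu
threshold on a temporally (5-frame) and spatially (2 px) smoothed stack,
keeping the largest connected component and filling holes. Displacements
convert to µm/s through the movie calibration only.

On synthetic rigid translations the implementation recovers integer
shifts exactly (against a brute-force argmax oracle) and sub-pixel shifts
to better than 0.05 px in the mean (0.2 px tolerance in the tests); on the
pulsating-disk movie the radially averaged cortical velocity tracks the
analytic dr/dt to ≈5 % RMS.

## Oscillation detection

Per embryo, each retained vector contributes the power spectra of its u
and v velocity time series (mean removed, rectangular window, DC bin
dropped); spectra are averaged across vectors and components rather than
transforming the mean velocity, so out-of-phase pulsations across the
cortex are preserved. The oscillation amplitude is the maximal power at
periods between 50 and 120 s, the background is the mean power of the
whole DC-excluded spectrum (band included), and the embryo is called
oscillating when amplitude/background ≥ 1.7, boundary inclusive. The call
is invariant to rescaling all velocities and to constant drift.

On a 10-min record sampled every 5 s the 80 s pulsation period falls
between the 85.7 s and 75 s grid periods; detection tests therefore accept
either straddling bin. PIV noise between consecutive pairs is
anti-correlated (adjacent pairs share a frame), making the null spectrum
rise toward short periods; this works against false positives in the
50–120 s band, and 200 seeded noise-only movies produce no oscillation
call at the 1.7× criterion in the test suite.

## Event logic

Cleavages within 30 min of another cleavage of the same embryo belong to
one wave. "Within 30 min of another" is applied transitively
(single-linkage chaining on sorted times, ≤ inclusive) — the only reading
that is independent of processing order; it is verified against a
brute-force pairwise-chaining oracle. Failed cytokineses count as wave
members but not toward the cell count; reverting cleavages subtract one
cell. The 8-cell-stage duration runs from the last third-wave division to
the first fourth-wave division, matching stage boundaries (end of one
wave to start of the next). Event times are normalized to the end of the
third cleavage. Lumen opening is the first time a fluid compartment
reaches 20 µm equivalent diameter (an explicit event in synthetic
timelines, a threshold crossing for annotated diameter series). The time
of maximal compaction is the earliest maximum of the lightly smoothed
angle series.

## Morphometrics

Contact angles are the interior angle at the vertex of three-point ROIs;
an automated closed-form route for two-circle geometries
(θ = 180° − γ, cos γ = (r1² + r2² − d²)/(2 r1 r2)) generates annotation
triplets for testing. Growth rates are ordinary least-squares slopes of
the hourly projected area over the 7 h window after lumen opening
(endpoint difference available as an alternative estimator); the
fractional increase uses the raw endpoint areas and the ≥35 % filter
applies to control embryos only. Zona pellucida shape is the aspect ratio
(≥1) of a direct least-squares ellipse fit (via scikit-image's conic
estimator, with an explicit collinearity rejection). Cohort growth curves
are synchronized to lumen opening and averaged pointwise over the
overlapping hourly span. Cellular volume is total minus blastocoel
volume, consumed as numbers from external 3D segmentation.

## Stain and expression quantification

N/C ratios divide mean intensities of two equal circular ROIs of 3.7 µm²
(radius ≈1.085 µm), one at the equatorial nuclear plane and one in
adjacent cytoplasm; the measure is invariant to multiplicative intensity
scaling but not to additive offsets, matching the raw-intensity protocol.
Per embryo, 5 ICM + 5 polar-TE + 5 mural-TE cells are sampled; an ICM
shortfall is topped up with TE cells, and embryos under 15 cells are
measured in full. Cells are outer iff they own pixels on the embryo
mask's outermost layer. Polarity line profiles average intensity across a
0.4 µm thickness along 15 µm from the cell-medium interface and min-max
normalize; a constant profile has no dynamic range and is returned as
zeros with a degeneracy flag. Reporter intensities subtract a 5-µm-circle
background mean from a 50-µm-circle embryo mean and normalize batches to
the zygote-stage mean. qPCR expression is 2^(−ΔCT) against the
housekeeping gene, replicates averaged on the CT scale, scaled to the
calibrator condition.

## Statistics

Welch's t (Satterthwaite df, two-tailed), Mann-Whitney U (exact when
min(n) ≤ 8 without ties, otherwise the tie-corrected normal approximation
with continuity correction), Pearson's χ² with Yates's correction (the
|O−E|−0.5 correction floored at zero), and Pearson correlation with
t-based p values, all through scipy behind this module's surface. Tests
verify each against an independent oracle: full enumeration of labelings
for Mann-Whitney, the 2×2 shortcut formula for χ², permutation-null
uniformity for Welch. p < 10⁻² is a reporting convention applied in
summary tables, never inside the estimators.

## Synthetic data: what it emulates

Movies are speckle-textured disks (band-pass-filtered Gaussian noise,
1 µm correlation length) whose radius follows R + A·sin(2πt/T); the
texture lives in material coordinates and is advected by the uniform
radial scaling ρ → ρ·r(t)/R, so a point at radius ρ moves at ρ·(dr/dt)/r
— trackable signal with an analytic velocity field. Defaults follow the
short-timescale acquisition (5 s interval, 120 frames, 0.5 µm/px,
35 µm embryo, 1 µm amplitude); the Nyquist constraint (period 0 or
> 2 × interval) and frame containment are enforced at construction.

Angle trajectories ramp logistically between per-embryo start and plateau
angles over the embryo's own 8-cell-stage duration (the published
compaction curves are sigmoidal; no functional form is stated, so the
logistic is a design choice), sampled at the four published stages with
i.i.d. measurement noise (default 2°). Timelines run five cleavage waves
from one cell; every cell attempts cytokinesis each wave and fails with
the preset probability, intra-wave attempts are jittered within 25 min so
the 30-min rule groups them correctly by construction, the third-to-fourth
wave gap is the genotype's 8-cell-stage duration, other gaps default to
10 ± 1 h, and all events are stamped on the 30-min observation grid
(ceiling to the next frame). Area series grow linearly from
≈3800 ± 300 µm² at the genotype rate with 50 µm² reading noise. Stain
stacks tile outer cells on a ring that fully covers the embryo
circumference (guaranteeing medium contact) with inner cells on a
sunflower layout strictly interior, assign pixels to the nearest cell
center, and paint nuclei at nc_ratio × cytoplasm intensity.

Genotype presets carry the published cohort means; per-embryo spreads are
back-computed from the published SEMs as sd = SEM·√n, since only
mean ± SEM is reported. The double-mutant division-failure probability
solves (2 − p)⁵ = 2.9, the published mean blastocyst cell count, giving
p ≈ 0.763; the mzMyh9 failure probability (0.2) and reversion rate (0.05)
are rough emulations of its reduced cell count and observed reverting
cleavages, not recovery targets. The mzMyh10 preset uses a 14 h
compaction ramp so its angle is ≈121° before the fourth cleavage yet
reaches ≈148° by the 16-cell stage, as published.

What passing tests show — and what they do not. Parameter recovery on
these cohorts demonstrates that the estimators are unbiased and correctly
calibrated against the generative model, and that the pipeline plumbing
(units, wave logic, band edges, thresholds) matches the published
protocol. It does not validate the generators as models of real embryos:
real movies have out-of-focus light, photobleaching, embryo rotation and
non-radial deformation modes; real compaction curves need not be
logistic; real division failure is not i.i.d. across attempts. In
particular, the i.i.d. branching model reproduces the published
double-mutant mean cell count exactly in expectation but has a wider
per-embryo spread (SD ≈1.85) than observed (≈1.41), so small-cohort means
scatter slightly more than the published SEM suggests.

## Problem sizes and determinism

All simulations run at desk scale: recovery cohorts use the published
sample sizes (n = 3–23), PIV tests use 128–192 px movies, and the
noise-only false-positive sweep uses 200 seeded 96-px movies. Every
generator and pipeline stage is deterministic given its seed; the
acceptance script derives independent child seeds (below 2³¹) from one
master seed via `numpy.random.SeedSequence`. Recovery tests average five
replicate cohorts (each at the published n) so the test statistic's
spread is well below the published-SEM tolerance while a systematic bias
of one SEM would still fail.
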