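# embryopulse

Multiscale quantification of mouse preimplantation development from
time-lapse and immunostain imaging: short-timescale periodic cortical
contractions, long-timescale morphogenesis (compaction, cleavage timing,
lumen-driven growth), and fate-marker readouts — together with a
synthetic-data generator so the entire pipeline runs, and is tested,
without any microscope data.

## Who this is for

Groups quantifying early-embryo contractility phenotypes (e.g. non-muscle
myosin II mutants) from nested time-lapse protocols: a long acquisition
(one frame every 30 min over ~50 h) capturing cleavages, compaction and
blastocoel growth, and short acquisitions (one frame every 5 s for 10 min)
capturing actomyosin pulsations at the 8-cell stage.

## What it computes

**Periodic contractions.** Two-pass cross-correlation PIV (20/10 µm
interrogation windows, ≈180 vectors per embryo, three-point Gaussian
sub-pixel peaks, normalized-median vector validation) gives per-frame-pair
velocity fields. Per embryo, the discrete-Fourier power spectra of every
vector's u and v time series are averaged into one spectrum; the embryo is
*oscillating* when the peak power at periods of 50–120 s reaches

```
amplitude / background ≥ 1.7,    background = mean spectral power
```

**Morphogenesis.** Compaction is the surface contact angle θ between
adjacent blastomeres from three-point ROIs (wild-type embryos ramp from
≈87° to ≈147° during the 8-cell stage). Cleavages within 30 min of one
another chain into waves; the 8-cell-stage duration is the interval from
the last third-wave to the first fourth-wave division. After a ≥20 µm
lumen appears, the projected area A(t) grows linearly; the growth rate is
the least-squares slope over 7 h (in µm²/min), with a ≥35 % minimal-growth
filter for control embryos. Cell counts follow +1 per division, 0 per
failed cytokinesis, −1 per reverting cleavage.

**Quantification.** Nuclear-to-cytoplasmic ratios from paired 3.7 µm²
circular ROIs under the 5 ICM + 5 polar-TE + 5 mural-TE sampling rule;
inner/outer classification by contact with the outside medium; 15-µm
min–max-normalized polarity line profiles; background-subtracted reporter
intensities; qPCR fold changes by 2^(−ΔCT); Welch's t, Mann-Whitney U,
Yates-corrected χ² and Pearson correlation with p < 10⁻² as the
significance convention.

**Synthetic data.** `embryopulse.synthetic` generates every input with
known ground truth: speckle-textured disks whose cortex pulses as
r(t) = R + A·sin(2πt/T) with texture advected by the deformation (so PIV
has trackable signal), logistic compaction-angle trajectories, stochastic
cleavage timelines with per-cytokinesis failure probability, post-lumen
growth curves, and two-compartment stain stacks. Genotype presets
(`src/embryopulse/data/presets.yaml`) encode the published cohort
parameters for WT, mzMyh9, mMyh9, mzMyh10, mMyh10 and mzMyh9;mzMyh10.

## Worked example

```python
from embryopulse import synthetic, piv, spectral

spec = synthetic.SyntheticMovieSpec(seed=1)   # 120 frames, 5 s, 80 s pulse
movie, truth = synthetic.make_movie(spec)
field = piv.piv_two_pass(movie)               # 20/10 µm windows
keep = piv.vectors_in_mask(field, piv.mask_embryo(movie))
call = spectral.call_oscillation(spectral.embryo_spectrum(field, keep=keep))
print(keep.sum(), call.is_oscillating, call.peak_period, round(call.ratio, 2))
```

prints

```
185 True 85.0 26.45
```

— 185 PIV vectors inside the embryo, the movie is called oscillating, and
the spectral peak lands at 85 s, the grid period closest to the true 80 s
pulsation on a 10-min record; the peak stands 26× above the mean spectral
power, far beyond the 1.7× criterion.

The full synthetic study is a sequence of drivers under `analysis/`
(simulate cohorts → contraction calls → morphogenesis summaries → stain
quantification → statistics), each writing tidy CSVs to `results/`. A
`embryo-pulse` CLI exposes the same stages (`simulate`, `piv`,
`oscillate`, `morpho`, `events`, `stats`, `all`).

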