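# Methods

## Spectral estimation

Signals are uniformly sampled traces (muscle length in tracking units, or
indicator fluorescence in arbitrary units). Each trace is demeaned —
nothing beyond mean subtraction, no detrending or filtering — before being
multiplied by K orthonormal discrete prolate spheroidal sequences (Slepian
tapers) computed by `scipy.signal.windows.dpss` with the symmetric
formulation, whose outputs are eigenvectors of the tridiagonal concentration
problem and therefore orthonormal to machine precision. Defaults are
NW = 5, K = 7; K ≤ 2·NW − 1 is recommended and violating it warns rather
than fails. Tapered copies are Fourier transformed on a grid zero-padded by
a factor of 4 (default), which interpolates the spectrum for smoother phase
readout without adding resolution; the Rayleigh resolution remains
fs/N.

**Normalization.** The taper-averaged power spectrum is rescaled so that
its trapezoidal integral over [0, Nyquist] equals the variance of the
demeaned trace exactly. This makes the Parseval property a contract of the
estimator rather than an asymptotic approximation; relative spectral shape
is unaffected. A constant trace has identically zero power.

**Dominant frequency** is the argmax of the reference trace's own
multitaper spectrum, excluding the DC bin, optionally restricted to a
frequency band; exact ties break toward the lowest frequency so the result
is deterministic. For crawling data a band of roughly 0.1–1 Hz brackets the
rhythm; the default is unrestricted because the simulated traces are
narrowband.

**Coherency** is the taper-averaged cross-spectrum normalized by the
geometric mean of the auto-spectra, with magnitude clipped into [0, 1]
against floating-point overshoot. The cross-spectrum is defined as
reference × conjugate(test), so a test signal that reaches the
corresponding waveform feature *later* than the reference has *positive*
phase; a transverse muscle contracting 42°/360 of a cycle after the
longitudinal reference reads +42°. Phase is stored in radians and reported
in degrees reduced to (−180, 180]. Unequal-length pairs are truncated to
the shorter length from the start; different sampling rates are an error.

**Significance** of coherence magnitude at a single frequency uses the
closed-form null quantile √(1 − α^{1/(K−1)}), the (1−α) point of the
Beta(1, K−1) distribution of squared coherence estimated from K independent
taper pairs (0.6269 for K = 7, α = 0.05). No jackknife confidence bands are
computed. Monte-Carlo calibration on independent white-noise pairs puts the
false-significance rate near the nominal α (very slightly conservative,
because the readout frequency is selected as the reference's power argmax).

## Circular statistics

Angles are degrees reduced to (−180, 180] at type boundaries. The circular
mean is atan2 of the mean sine and cosine; its 95% CI uses the
resultant-length-based chi-square formulas (one branch for mean resultant
length ≤ 0.9, one above), returned as undefined when the formulas'
square-root arguments leave their domain (sample too dispersed). A
resultant length numerically zero with n > 1 flags the mean itself as
undefined instead of raising.

**Paired Hotelling test.** Each animal contributes a rectangular difference
vector (cos a − cos b, sin a − sin b); a one-sample Hotelling T² tests the
mean vector against the origin, with (n−2)/(2(n−1))·T² referred to
F(2, n−2). All-identical pairs give a singular difference covariance; the
result is then p = 1 with a `degenerate` flag so multi-segment pipelines
continue. The statistic is exact for bivariate-normal difference vectors;
for von Mises angles at small n it is mildly **conservative** (empirical
type-I ≈ 0.03 at nominal 0.05 for n = 7 across concentrations κ = 1–30),
because one standardized component of the difference vector is a product of
two near-Gaussian variables and hence leptokurtic. Users should read its
p-values as upper-bound-honest: it does not reject more often than nominal.

**Watson-Williams test.** Classical F-type test for equality of mean
directions with the concentration correction 1 + 3/(8κ̂), κ̂ estimated from
the weighted mean resultant length by Fisher's piecewise approximation. The
conventional validity bound is flagged (not enforced) when that resultant
length is below 0.45. Empirical type-I error under von Mises nulls sits
inside the binomial band around the nominal level. No multiple-comparison
correction is applied anywhere; reports say so explicitly.

## Kinematics

Muscle length is the per-frame Euclidean distance between two tracked
attachment points (pixels or micrometers; lengths inherit the unit).
Coincident points are flagged frames, not errors. Length — not contraction
— feeds the coherency analysis so the phase-sign convention is defined on
waveforms whose troughs are contractions for every muscle. Optional
normalization divides by a resting length: by default the 95th percentile
of observed lengths (robust to tracking glitches; a few frames may exceed
1), alternatively the maximum.

## Synthetic data

The peristalsis generator emulates what the analyses assume about crawling:
a common segmental drive recurring at the wave frequency (default 0.3 Hz),
realized as a raised-cosine contraction pulse occupying a `contraction_duty`
fraction of each cycle (default 0.4) — smooth and spectrally compact, unlike
a square pulse. Muscle length is resting length × (1 − depth·pulse), depth
0.2 by default. One jittered cycle-boundary sequence per simulation is
shared by all traces (per-cycle periods T(1 + ε), ε Gaussian with sd 0.02 of
the period, clipped at ±3 sd); each trace evaluates that train at t − shift,
where the shift is s·intersegmental_delay for segment s plus lag/360·T for
the transverse muscle. Implementing lags as time shifts of a shared train
makes the programmed phase exact at the wave frequency even under jitter.
Gaussian length noise (sd 0.02 of resting length by default; 0.04 gives
signal-to-noise 5 relative to the 0.2 contraction depth) is drawn from a
per-trace stream split from the master seed by a CRC32 label hash, so output
is bitwise reproducible and independent of trace evaluation order.

Defaults the generator fixes as its study conditions: 120 s at 10 Hz,
3 segments, intrasegmental lag 42°, intersegmental delay 0.4 s (a 0.3 Hz
wave crossing the larva's ~8 segments in roughly one period). The calcium
variant convolves each neuron's pulse train with a peak-normalized
(1 − e^{−t/rise}) e^{−t/decay} kernel (rise 0.1 s, decay 0.4 s — fast
indicator dynamics), adds baseline and noise; both members of a segment
pair share the kernel, so relative phase at the wave frequency is
preserved, with a small bias (< 5°) for decays up to a quarter period.

The connectome generator builds two motor neurons with prescribed partner
counts and shared subset (defaults 55 + 54 with 34 shared, union 75).
Synapse counts are lognormal (log-mean 1.5, log-sd 0.8 — median ≈ 4.5
synapses); shared partners' count pairs are coupled by a Gaussian copula on
log-weights. The programmed `shared_weight_correlation` is interpreted on
the *count* scale — the scale on which such correlations are reported — and
the log-scale copula correlation is back-computed from the lognormal moment
formula ρ_log = ln(1 + r(e^{σ²} − 1))/σ²; infeasible combinations raise at
construction. Counts are rounded with a floor of one synapse, a slight
attenuation absorbed by the recovery tolerance (mean recovered r within
±0.05 of the programmed 0.76 over 200 replicates).

**What the generator does not emulate:** slow baseline drift and bleaching
in imaging data, non-stationary wave frequency, amplitude asymmetries
between segments, tracking dropouts, and any realistic degree-distribution
or community structure beyond the two-motor-neuron overlap motif. Passing
recovery tests therefore validates the estimators under the assumed model,
not robustness to those artifacts.

## Connectome metrics

Graphs hold one aggregated edge per ordered (pre, post) pair; duplicate
rows in edge-list CSVs are summed on load ("pre-aggregation" is the
loader's job). Shared-partner fractions use the **union** of the two
neurons' presynaptic partner sets as denominator (the Venn-diagram
reading); percentages round to the nearest integer for reporting while raw
fractions stay in machine output. The divergent fraction is 1 − the mean of
the two shared-synapse fractions, so shared + divergent = 1 per pair by
construction. The contribution correlation requires ≥ 3 shared partners
and nonzero variance on both sides; otherwise it is undefined (flagged, not
raised). Screening uses strict inequalities on both thresholds (a cell with
exactly 35 synapses fails), exclusion is categorical (a single synapse onto
the excluded pool disqualifies), candidates must be annotated as
interneurons, and left/right homologs are distinct nodes — pooling across
hemisegments is the caller's choice when defining pool sets.

## Numerical choices and degeneracies

- Phase wrap convention (−180, 180], with −180 mapped to +180.
- Dominant-frequency ties break toward the lowest frequency; DC always
  excluded.
- Coherency at frequencies where an auto-spectrum vanishes is defined as 0.
- Hotelling covariance treated as degenerate when its determinant is below
  1e−14 × trace²; Watson-Williams with all-identical within-group angles
  returns F = 0/∞ with a `degenerate` flag instead of dividing by zero.
- CSV loaders validate uniform sampling (interval deviation ≤ 1% of the
  mean) and report the first offending line of corrupt input.

## Problem sizes

Tests and the acceptance script run at the scale of the study conditions:
120 s × 10 Hz traces (N = 1200), 500-pair Monte-Carlo nulls at N = 1024,
2000-replicate circular-test calibrations at n = 7–10 animals, 200-replicate
generator-recovery runs, and random oracle graphs of ≤ 50 neurons. The full
suite and the acceptance script each complete in well under a minute of CPU.

## Known limitations

- No time-resolved (sliding-window) coherence, wavelet/Hilbert phase, or
  jackknife confidence bands; the per-pair estimate carries a single
  analytic threshold.
- Circular CIs across animals use the resultant-length formulas, which are
  undefined for very dispersed samples.
- The paired Hotelling test's conservatism at small n (above) is a property
  of the named procedure, not of this implementation.
- Screening denominators are whatever pool set the caller supplies; the
  per-segment vs whole-volume choice is not made for them.
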