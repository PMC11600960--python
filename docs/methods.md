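# Methods

`blasteeg` implements the quantitative chain used to characterise chronic
electrophysiological and histological consequences of mild blast traumatic
brain injury in a rodent model: spectral power and phase-lag connectivity
from 32-channel epicranial EEG in a 2x2 (injury x time) cohort design, the
permutation inference applied to them, and the layer-resolved cell-density
statistics for the accompanying immunohistochemistry. Because real
recordings of this kind cannot generally be shared, the package ships a
first-class synthetic-data generator with known ground truth; every claim
the pipeline makes is validated against that truth.

## Synthetic data model

**EEG.** Each channel is a sum of independent band-limited Gaussian
processes, one per canonical band (delta 1-4, theta 4-8, alpha 8-12, beta
12-25, gamma 25-80, HFO 80-200 Hz). Band-limited noise is synthesized
exactly in the frequency domain — white Gaussian noise is transformed,
out-of-band coefficients zeroed, and inverse-transformed — which is
zero-phase and leaves zero stop-band leakage, so the ground-truth band
power is exactly the squared requested RMS amplitude. (A zero-phase
Butterworth filter realisation was evaluated and rejected: at practical
orders it leaks several percent of a loud neighbouring band across the
shared edge, contaminating ground truth.) Default per-band RMS amplitudes
fall off with frequency (20, 15, 10, 8, 6, 4 uV) to mimic the 1/f-like
shape of cortical field potentials.

Phase coupling on a designated edge set is produced by giving both
endpoint channels a shared narrowband source carrying a stated fraction
`c` of the in-band variance, with the second endpoint's copy rotated by a
fixed phase lag via its analytic signal. At `c = 1` and a quarter-cycle
lag the debiased weighted phase lag index of the pair is 1 by
construction; at `c = 0` the channels are independent and the debiased
estimator averages to zero. A channel belonging to several coupled edges
splits the coupled variance budget `c` equally among them.

Line noise is added as sinusoids at 50 Hz and harmonics (amplitude
decaying as 1/k, common phase across channels); artifacts as 0.5-2 s
high-amplitude low-frequency transients (Hann-enveloped 1-3 Hz bursts at a
configurable multiple of channel RMS) on random channel subsets at a
configurable events/minute rate.

**Cohorts.** The chronic design defaults to the study's group sizes —
blast 1-month n=13, blast 3-months n=20, sham 1-month n=8, sham 3-months
n=9 — with per-band amplitude multipliers and a coupling specification
attached to the blast groups. Per-animal, per-run seeds derive
deterministically from the cohort seed through `numpy` seed sequences, so
cohorts are bit-reproducible without correlated streams. Animals
additionally receive a lognormal broadband amplitude factor (sigma = 0.15
on the log scale) as a simple model of stable individual differences;
runs within an animal are exchangeable, since nothing is known about
systematic inter-run structure.

**Histology.** Cell counts are drawn per slice (three slices per
stain/animal, later averaged) with mean `density x sampled area x
multiplier`, Poisson by default, optionally negative-binomial via a
gamma-Poisson mixture (variance = mean + dispersion x mean^2), or
noise-free for arithmetic checks. The default baseline is 120 cells/mm^2
over a 0.5 mm^2 sampling window, giving per-animal relative count noise of
a few percent — comparable to the tight error bars of real layer-density
panels. Time-point-specific multipliers per ROI x layer plant effects;
the values 0.7047 and 0.5427 reproduce the reported 29.53% and 45.73%
layer-5 reductions.

**What the generator does not emulate.** No volume conduction or head
model (channels are spatially independent unless explicitly coupled), no
1/f continuum within bands, no non-stationarity beyond artifacts, no
real electrode geometry beyond a generic grid-on-sphere layout, and no
spatial correlation in histology. Tests that pass on these data validate
the estimators and inference chain, not the biology; in particular the
interpolation-robustness checks use separately constructed spatially
smooth fields, because interpolating spatially independent noise is
meaningless.

## Preprocessing

The cleaning order is fixed: resample to 1 kHz (polyphase, anti-aliased,
downsampling only) -> line-noise suppression -> artifact rejection -> ICA
screening -> bad-channel interpolation. Every stage appends to a
provenance log carried by the recording.

*Line noise* is removed CleanLine-style: within consecutive 4 s windows a
sine/cosine pair at each target frequency is fitted by least squares and
subtracted — but only where the fitted tone is statistically significant
(F-test with a Bonferroni-strict gate over all window x channel x
frequency tests). The gate is what makes the operation safe: on tone-free
data blind subtraction would remove ~6 degrees of freedom per window
(several percent RMS), whereas the gated version changes clean records by
well under 0.5% while still achieving >20 dB suppression of genuine
tones, whose F statistics are orders of magnitude above threshold.

*Artifact rejection* is discard-only (no subspace reconstruction):
per-channel RMS in 1 s windows is z-scored against a robust calibration
(median and MAD across windows, i.e. the clean majority), and windows
exceeding z = 5 on any channel are excised. The retained data is carried
as disjoint half-open sample intervals; epochs and Welch windows never
straddle an excised gap. Cohort comparisons can truncate every animal to
the cohort-minimum retained duration to equalise signal-to-noise.

*ICA* uses extended infomax (via `mne`) after PCA whitening with rank
detection, so duplicated or silent channels yield a reduced-rank
decomposition instead of an error. Component screening is automated with
three auditable rules — 50 Hz-relative power, excess kurtosis, sub-1 Hz
drift fraction — each with conservative thresholds and a reason code per
flag, replacing manual screening with something a reviewer can override.

*Interpolation* implements the spherical spline on unit-sphere electrode
coordinates (Legendre-series kernel, order m=4, 30 terms, small ridge
regulariser) with an inverse-distance-squared alternative. Both reproduce
a constant field exactly and recover a held-out channel of a smooth field
to well under 5% RMS.

## Spectral power

Welch PSD per channel: 2 s Hann windows, 50% overlap, density scaling,
restricted to 1-200 Hz (0.5 Hz grid). Absolute band power is the mean of
PSD bins in each half-open band (the top band closed at 200 Hz, so each
bin counts exactly once); relative power divides each channel's PSD by
the sum of its bins over the analysed 1-200 Hz range — not the full
Nyquist range — before taking band means. Normalisation is per-channel
*before* any channel averaging, preserving per-electrode relative
topographies; global power is the unweighted mean over the full array,
and runs are averaged per animal. Estimator caveat: a spectrum with a
hard edge smears by about one bin through a 2 s Hann window, so band
means adjacent to a loud neighbouring band inherit a small positive bias;
ground-truth accounting in tests therefore uses direct FFT (Parseval)
integration where the generator's exactness matters.

## Phase connectivity

Recordings are epoched into 3 s segments (non-overlapping); each 1.5 s
Hann window with 50% overlap inside each epoch contributes one complex
cross-spectral observation per electrode pair. Observations are pooled
across windows and epochs (maximising the observation count; nothing
suggests a different pooling level). With `I_i` the imaginary
cross-spectrum at observation `i`:

    dwPLI = [(sum I_i)^2 - sum I_i^2] / [(sum |I_i|)^2 - sum I_i^2]

computed per frequency and averaged over band bins; global connectivity
averages the 496 unordered pairs of the 32-channel array. The one-pass
sums form is provably identical to the O(n^2) pairwise estimator
`sum_{i != l} I_i I_l / sum_{i != l} |I_i I_l|`, which is kept as a
reference and checked to 1e-10 on random inputs. A zero denominator (no
imaginary cross-spectral mass — identical or exactly zero-lag signals) is
defined as 0: no phase-lag evidence, no connectivity. Debiased values may
be slightly negative; that is a property of the estimator, not an error.

## Permutation inference

All permutation p-values use the add-one rule `p = (1 + #{null >= obs}) /
(1 + n_perm)`, which keeps them valid and strictly positive. Defaults are
10,000 permutations (50,000 for the edge-wise network test), with every
null distribution reproducible from a seed.

*Paired (acute) arm*: observed paired t with a sign-flip null on the
paired differences, two-sided, Bonferroni over the six bands.

*Factorial (chronic) arm*: Type-III sums of squares with sum-to-zero
coding on the unbalanced 2x2, giving the conventional F(1, N-4)
statistics (checked to 1e-8 against an independent OLS/ANOVA oracle); the
null permutes outcomes across all animals (Manly's unrestricted scheme),
which is exact under the global null being tested and is recomputed for
all three effects per permutation. Channel-level testing repeats the
model per electrode with a Bonferroni family of 32; significant
interactions are followed by pairwise Welch t-tests with permutation
nulls and a Bonferroni family of the declared pairs.

*Welch-Satterthwaite*: the unequal-variance t with
`nu = (s1^2/n1 + s2^2/n2)^2 / [(s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1)]`,
used analytically and as the edge-wise statistic.

*Network arm*: the two time points are pooled within injury group (33
blast vs 17 sham from the default design; two-sample df = N-2 = 48), each
of the 496 edges gets a one-sided (blast > sham) Welch t against a
label-permutation null that reuses the same permutations across edges —
preserving inter-edge dependence under the null — and edge p-values are
thresholded by Benjamini-Hochberg FDR at q = 0.05. This is the edge-wise
FDR mode of network-based-statistic practice rather than cluster-extent
inference, matching an analysis that reports an FDR-adjusted edge
threshold. Empirically the chain recovers a planted 10-edge gamma network
at full sensitivity with FDR near the nominal level; false positives
concentrate on edges incident to truly coupled channels, where group
variance heterogeneity mildly strains label exchangeability — a known
limitation of permutation t-tests rather than of the FDR step.

## Histology chain

Per-slice densities (count/area) are averaged over the three slices per
animal before any statistics. A hemisphere gate runs a two-way ANOVA
(time x hemisphere with interaction) per ROI x layer and collapses
hemispheres by averaging only when both hemisphere effects are
non-significant (alpha = 0.05); otherwise hemispheres stay separate and
the gate report says so. One-way ANOVAs over time post-injury (five
groups including the merged Naive/Sham control) yield F(k-1, N-k) with
analytic p; the FDR family is the set of layer-wise p-values within each
stain x ROI, corrected by the Benjamini-Krieger-Yekutieli two-stage
linear step-up at Q = 5% (stage 1: BH at Q/(1+Q); if neither nothing nor
everything is rejected, stage 2 reruns BH at level Q' m / m0_hat with
m0_hat = m - r1). The two-stage flags are checked against both an
exhaustive step-up oracle and an independent implementation. Post hoc
comparisons of each time point against control use Fisher-LSD-style t on
the pooled ANOVA mean square error with the omnibus error df, reported
raw alongside the omnibus FDR flag (comparisons under a non-significant
omnibus are computed but marked exploratory). Percent change is
`100 (mean_control - mean_timepoint) / mean_control`. Immunofluorescence
intensities are normalised per animal to a minimal-fluorescence reference
region before entering the same ANOVA machinery. The whole chain is
invariant to rescaling all sampled areas, and reproduces exactly the
arithmetic that a 40% loss of a 5% subpopulation moves total neuronal
density by 2%.

## Numerical and design choices

- Sample intervals are 0-based half-open `[start, end)` throughout.
- Band edges: half-open on the left, the top band closed at its upper
  edge; a band passed alone is treated as the top band.
- Permutation schemes, seeds and family sizes are recorded in every
  result object; statistics CSVs regenerate byte-identically from the
  same seed.
- Recordings are stored as raw little-endian float32 plus a JSON sidecar
  (rate, channel names, coordinates, retained segments, provenance log);
  no binary container format is required anywhere.
- The edge-wise permutation test reports p = 1 with t = 0 for an edge
  constant across all animals, and the paired test warns and returns
  p = 1 on zero-variance differences.

## Validation problem sizes

The validation battery (`blasteeg.validation`, driven by
`scripts/acceptance.py` and the acceptance tests) runs each arm at sizes
chosen to keep the full battery within minutes on one CPU while leaving
every estimate well-resolved: repetition loops use 30 s recordings at
500 Hz (band content to 200 Hz preserved; the generator's scientific
defaults of 300 s at 1 kHz are unchanged and used where one cohort
suffices), 1000 null cohorts at 200 permutations for type-I calibration,
8-10 cohort repetitions for detection/network recovery, and 150
repetitions at paper-scale group sizes for histology recovery.

## Known limitations

- The generator's spatial independence means scalp-map smoothness and
  volume-conduction effects are not represented; dwPLI's zero-lag
  immunity is validated by direct common-source injection instead.
- Automated ICA component rules are a screening aid, not a validated
  classifier of physiological artifacts.
- Manly permutation is exact only under the global null; restricted or
  residualised schemes (e.g. Freedman-Lane) are not implemented.
- The hemisphere gate, like any gated analysis, conditions later
  inference on an accept decision; its alpha is configurable but the
  conditioning is not corrected for.
- Cluster-extent network inference is not implemented; only the
  edge-wise FDR mode is provided.
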