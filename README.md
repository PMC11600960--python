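# blasteeg

Band power, phase-lag connectivity and cortical cell-density statistics
for rodent blast-TBI cohort designs, with a ground-truth synthetic data
generator.

## What this is for

Mild blast traumatic brain injury leaves a chronic electrophysiological
signature — broadband power changes and band-specific hyperconnectivity in
epicranial EEG — alongside layer-specific loss of inhibitory interneurons
(parvalbumin- and somatostatin-expressing cells) that shifts the cortical
excitation/inhibition balance. Quantifying those claims takes a fairly
long analysis chain: cleaning multichannel recordings, Welch band power
(absolute and normalised), debiased weighted phase-lag-index (dwPLI)
connectivity, permutation inference on an unbalanced 2x2 (injury x time)
cohort, edge-wise network statistics with FDR control, and layer-resolved
density ANOVAs with two-stage FDR and post hoc contrasts.

`blasteeg` implements that chain as a tested, reusable library for
electrophysiologists and analysts working with this class of design.
Because animal EEG of this kind is rarely shareable, the package also
ships a first-class synthetic-data generator that produces whole cohorts
with known ground truth (planted band-power effects, planted coupled edge
sets, planted density reductions), so every stage can be validated by
parameter recovery rather than by eye.

## The core quantities

- **Band power.** Welch PSD per channel (2 s Hann windows, 50% overlap,
  1-200 Hz), band means over delta/theta/alpha/beta/gamma/HFO, absolute
  and normalised to each channel's total power; global power averages the
  32-channel array.
- **dwPLI.** With `I_i` the imaginary part of the cross-spectrum of an
  electrode pair at observation `i` (1.5 s Welch windows inside 3 s
  epochs),

      dwPLI = [(Σ I_i)² − Σ I_i²] / [(Σ |I_i|)² − Σ I_i²]

  a debiased phase-synchronisation measure immune to zero-lag (volume
  conducted) coupling, averaged within bands and over the 496 pairs for
  global connectivity.
- **Inference.** Permutation paired t (sign-flip null) for the acute
  pre/post arm; permutation two-way ANOVA (Type-III SS, sum-to-zero
  coding, Manly's unrestricted scheme) with F(1, N−4) for the chronic
  2x2; Welch t with Satterthwaite ν; Bonferroni families over bands,
  channels or pairs; edge-wise one-sided permutation t with shared
  permutations and Benjamini-Hochberg FDR for the hyperconnected network;
  one-way density ANOVAs with Benjamini-Krieger-Yekutieli two-stage FDR
  (Q = 5%) and Fisher-LSD post hoc contrasts against control.

## Worked example

Generate a chronic cohort at the study's group sizes (blast 1-month
n=13, blast 3-months n=20, sham 1-month n=8, sham 3-months n=9) with a
1.5x broadband amplitude effect in the blast groups, compute per-animal
global gamma power, and fit the permutation factorial ANOVA:

```python
from blasteeg import RecordingSpec
from blasteeg.bands import BAND_NAMES
from blasteeg.synthetic import chronic_design
from blasteeg.pipeline import cohort_band_power, global_band_power_table
from blasteeg.permstats import TwoWayPermutationAnova

design = chronic_design(
    blast_band_multipliers={b: 1.5 for b in BAND_NAMES},
    recording=RecordingSpec(duration=30.0, sampling_rate=500.0,
                            line_noise_amplitude=0.0, artifact_rate=0.0),
    seed=42,
)
power = cohort_band_power(design)
gamma = global_band_power_table(power, "gamma", "absolute")
res = TwoWayPermutationAnova.from_dataframe(gamma, "value").fit(
    n_perm=10000, seed=0, family_size=6)
print(res.summary())
```

prints

```
Permutation two-way ANOVA (Type-III SS, Manly permutation)
N = 50, error df = 46, n_perm = 10000, seed = 0
effect                 F        df         p     p_adj
group            57.3882    (1,46)    0.0001    0.0006
time              1.2546    (1,46)    0.2638    1.0000
interaction      0.0000     (1,46)    0.9965    1.0000
```

The planted injury effect (amplitude x1.5 means power x2.25) shows up as
a large group main effect surviving Bonferroni correction over the six
bands (`p_adj` multiplies the permutation p by 6), while the time main
effect and interaction — which were not planted — stay null. The error
df of 46 is fixed by the four group sizes (N = 50 animals, 4 cells).

The same flow works from a shell: `blasteeg simulate | preprocess |
power | connectivity | stats | network | histo | report` chain the
stages on disk artifacts (raw float32 + JSON recordings, tidy CSVs) with
a JSON provenance record per stage.

## Layout

| module | contents |
|---|---|
| `blasteeg.synthetic` | recording/cohort/histology generators with ground truth |
| `blasteeg.recording` | the multichannel container + raw-binary IO |
| `blasteeg.preprocess` | resample, line-noise, artifact scan, ICA, interpolation, epoch |
| `blasteeg.spectral` | Welch PSD, absolute/relative band power, global/run averaging |
| `blasteeg.connectivity` | cross-spectra, dwPLI (one-pass + pairwise reference), band/global |
| `blasteeg.permstats` | paired/factorial permutation tests, Welch-Satterthwaite, families |
| `blasteeg.network` | pooling, edge-wise permutation t, BH FDR, significant network |
| `blasteeg.histology` | densities, hemisphere gate, ANOVA + BKY FDR, post hoc, percent change |
| `blasteeg.pipeline` | cohort-level orchestration into tidy animal-level tables |
| `blasteeg.validation` | the simulation battery behind tests and the acceptance script |
| `blasteeg.cli` | the `blasteeg` command-line chain |

See `docs/methods.md` for the full statistical specification and the
design decisions behind it.
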