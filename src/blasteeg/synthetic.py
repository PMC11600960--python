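"""Synthetic EEG cohorts and histology count tables with known ground truth.

The generator emulates the data the analysis pipeline expects: 5-minute
32-channel epicranial recordings per animal in a 2x2 (sham/blast x 1/3
months) design, with per-band amplitude multipliers for group effects,
phase-lagged narrowband coupling on a designated edge set, 50 Hz line noise
plus harmonics, and transient high-amplitude artifacts; and per-slice cell
count tables over ROI x layer x hemisphere with time-point-specific density
multipliers on a stable baseline.

Each channel is a sum of independent band-limited Gaussian noise processes,
one per frequency band, produced by zero-phase band-pass filtering of white
noise and rescaled to the requested RMS amplitude, so band power ground
truth is amplitude squared.  For a coupled edge, a stated fraction of each
endpoint's band-limited variance is replaced by a shared source injected
into both channels with a fixed phase lag (applied by rotating the analytic
signal), which gives the phase-lag index estimator a known target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .bands import DEFAULT_BANDS, validate_bands
from .recording import MultichannelRecording, default_electrode_coords

__all__ = [
    "RecordingSpec",
    "CouplingSpec",
    "GroupSpec",
    "CohortDesign",
    "HistoSpec",
    "generate_recording",
    "generate_cohort",
    "design_table",
    "generate_histology",
]

#: default per-band RMS amplitudes (microvolts), roughly 1/f-shaped
DEFAULT_BAND_AMPLITUDES = {
    "delta": 20.0,
    "theta": 15.0,
    "alpha": 10.0,
    "beta": 8.0,
    "gamma": 6.0,
    "hfo": 4.0,
}


@dataclass
class CouplingSpec:
    """Ground-truth phase coupling on a set of channel pairs.

    coupling_fraction is the fraction of each coupled channel's band-limited
    variance drawn from a shared source lagged by ``phase_lag`` radians.
    """

    edges: list[tuple[int, int]]
    band: str = "gamma"
    phase_lag: float = math.pi / 2
    coupling_fraction: float = 0.5

    def validate(self, n_channels: int, band_names: Iterable[str]) -> None:
        if self.band not in set(band_names):
            raise ValueError(f"coupling band {self.band!r} not in band set")
        if not (0.0 <= self.coupling_fraction <= 1.0):
            raise ValueError("coupling_fraction must be in [0, 1]")
        if not (-math.pi < self.phase_lag <= math.pi):
            raise ValueError("phase_lag must be in (-pi, pi]")
        for a, b in self.edges:
            if not (0 <= a < n_channels and 0 <= b < n_channels) or a == b:
                raise ValueError(f"edge ({a}, {b}) references invalid channels")


@dataclass
class RecordingSpec:
    n_channels: int = 32
    sampling_rate: float = 1000.0
    duration: float = 300.0
    electrode_coords: np.ndarray | None = None
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    line_noise_amplitude: float = 5.0
    line_freq: float = 50.0
    n_harmonics: int = 3  # 50, 100, 150 Hz
    artifact_rate: float = 0.0  # events per minute
    artifact_amplitude_factor: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be >= 0")
        if self.line_noise_amplitude < 0 or self.artifact_rate < 0:
            raise ValueError("amplitudes and rates must be >= 0")
        validate_bands(dict(self.bands))
        coords = self.get_coords()
        if len(np.unique(np.round(coords, 9), axis=0)) != self.n_channels:
            raise ValueError("electrode coordinates must be distinct")

    def get_coords(self) -> np.ndarray:
        if self.electrode_coords is not None:
            return np.asarray(self.electrode_coords, dtype=float)
        return default_electrode_coords(self.n_channels)


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, exact in the frequency domain.

    White Gaussian noise is transformed, components outside ``[lo, hi)``
    zeroed, and transformed back: zero-phase by construction with no
    stop-band leakage, so band-power ground truth is exact.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _rotate_phase(x: np.ndarray, phase: float) -> np.ndarray:
    """Shift every spectral component of a narrowband signal by ``phase`` rad."""
    analytic = signal.hilbert(x)
    return np.real(analytic * np.exp(-1j * phase))


def generate_recording(
    spec: RecordingSpec, coupling: CouplingSpec | None = None
) -> MultichannelRecording:
    """Generate one multichannel recording; reproducible per ``spec.seed``."""
    spec.validate()
    band_names = list(spec.bands)
    if coupling is not None:
        coupling.validate(spec.n_channels, band_names)

    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)
    data = np.zeros((n, spec.n_channels))

    # per-channel count of coupled edges, for variance budgeting
    edge_count = np.zeros(spec.n_channels, dtype=int)
    if coupling is not None:
        for a, b in coupling.edges:
            edge_count[a] += 1
            edge_count[b] += 1

    for name in band_names:
        lo, hi = spec.bands[name]
        amp = float(spec.band_amplitudes.get(name, 0.0))
        if amp == 0.0 and not (coupling is not None and coupling.band == name):
            continue
        coupled_band = coupling is not None and coupling.band == name
        own_frac = np.ones(spec.n_channels)
        if coupled_band:
            own_frac[edge_count > 0] = 1.0 - coupling.coupling_fraction
        for ch in range(spec.n_channels):
            if amp == 0.0:
                continue
            x = _band_noise(rng, n, lo, hi, fs)
            data[:, ch] += amp * np.sqrt(own_frac[ch]) * x
        if coupled_band and coupling.coupling_fraction > 0:
            for a, b in coupling.edges:
                s = _band_noise(rng, n, lo, hi, fs)
                s_lag = _rotate_phase(s, coupling.phase_lag)
                # a channel in k edges receives fraction c/k from each edge
                for ch, src in ((a, s), (b, s_lag)):
                    frac = coupling.coupling_fraction / edge_count[ch]
                    data[:, ch] += amp * np.sqrt(frac) * src

    t = np.arange(n) / fs
    if spec.line_noise_amplitude > 0:
        for k in range(1, spec.n_harmonics + 1):
            f = spec.line_freq * k
            if f >= fs / 2:
                break
            # harmonics decay as 1/k; random phase shared across channels
            phase = rng.uniform(0, 2 * math.pi)
            tone = (spec.line_noise_amplitude / k) * math.sqrt(2) * np.sin(
                2 * math.pi * f * t + phase
            )
            data += tone[:, None]

    if spec.artifact_rate > 0:
        n_events = rng.poisson(spec.artifact_rate * spec.duration / 60.0)
        ch_rms = np.sqrt(np.mean(data**2, axis=0))
        for _ in range(n_events):
            dur = rng.uniform(0.5, 2.0)
            width = int(dur * fs)
            start = rng.integers(0, max(1, n - width))
            chans = np.flatnonzero(rng.random(spec.n_channels) < 0.5)
            if chans.size == 0:
                chans = np.array([rng.integers(spec.n_channels)])
            env = np.hanning(width)
            f_art = rng.uniform(1.0, 3.0)
            wave = env * np.sin(2 * math.pi * f_art * np.arange(width) / fs + rng.uniform(0, 2 * math.pi))
            for ch in chans:
                data[start : start + width, ch] += (
                    spec.artifact_amplitude_factor * ch_rms[ch] * wave
                )

    return MultichannelRecording(
        data=data,
        sfreq=fs,
        ch_names=[f"ch{idx:02d}" for idx in range(spec.n_channels)],
        coords=spec.get_coords(),
        log=[f"synthetic:seed={spec.seed}"],
    )


@dataclass
class GroupSpec:
    """One cell of the cohort design."""

    injury: str  # "sham" or "blast"
    time: str  # "1-month" or "3-months"
    n_animals: int
    band_multipliers: Mapping[str, float] = field(default_factory=dict)
    coupling: CouplingSpec | None = None

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1 per group")
        if any(m <= 0 for m in self.band_multipliers.values()):
            raise ValueError("band multipliers must be > 0")


@dataclass
class CohortDesign:
    groups: list[GroupSpec]
    recording: RecordingSpec = field(default_factory=RecordingSpec)
    runs_per_animal: int = 1
    #: lognormal sigma of a per-animal broadband amplitude factor
    animal_jitter_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for g in self.groups:
            g.validate()
        if self.runs_per_animal < 1:
            raise ValueError("runs_per_animal must be >= 1")
        self.recording.validate()


def chronic_design(
    n_per_group: Mapping[tuple[str, str], int] | None = None,
    blast_band_multipliers: Mapping[str, float] | None = None,
    blast_coupling: CouplingSpec | None = None,
    recording: RecordingSpec | None = None,
    runs_per_animal: int = 1,
    seed: int = 0,
) -> CohortDesign:
    """The chronic 2x2 cohort: sham/blast x 1-month/3-months.

    Default group sizes match the study design: blast 1-month n=13, blast
    3-months n=20, sham 1-month n=8, sham 3-months n=9.
    """
    if n_per_group is None:
        n_per_group = {
            ("blast", "1-month"): 13,
            ("blast", "3-months"): 20,
            ("sham", "1-month"): 8,
            ("sham", "3-months"): 9,
        }
    groups = []
    for (injury, time), n in n_per_group.items():
        mult = dict(blast_band_multipliers or {}) if injury == "blast" else {}
        coup = blast_coupling if injury == "blast" else None
        groups.append(GroupSpec(injury, time, n, mult, coup))
    return CohortDesign(
        groups=groups,
        recording=recording or RecordingSpec(),
        runs_per_animal=runs_per_animal,
        seed=seed,
    )


def design_table(design: CohortDesign) -> pd.DataFrame:
    """Animal-level metadata table (one row per animal)."""
    rows = []
    for g in design.groups:
        for i in range(g.n_animals):
            rows.append(
                {
                    "animal_id": f"{g.injury}-{g.time}-{i:02d}",
                    "injury": g.injury,
                    "time": g.time,
                }
            )
    df = pd.DataFrame(rows)
    if df["animal_id"].duplicated().any():
        raise ValueError("duplicate animal ids in design")
    return df


def _animal_seed(cohort_seed: int, animal_index: int, run: int) -> int:
    """Deterministic per-animal, per-run seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), int(animal_index), int(run)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(design: CohortDesign):
    """Yield ``(recording, animal_id, injury, time, run)`` for every run.

    Per-animal seeds derive deterministically from the cohort seed; group
    band multipliers scale the base amplitudes; an optional lognormal
    per-animal broadband factor models individual differences.
    """
    design.validate()
    meta = design_table(design)  # validates id uniqueness
    base = design.recording
    idx = 0
    jitter_rng = np.random.default_rng(
        np.random.SeedSequence([int(design.seed), 987654321])
    )
    for g in design.groups:
        for i in range(g.n_animals):
            animal_id = f"{g.injury}-{g.time}-{i:02d}"
            jitter = (
                float(np.exp(jitter_rng.normal(0.0, design.animal_jitter_sigma)))
                if design.animal_jitter_sigma > 0
                else 1.0
            )
            amps = {
                name: base.band_amplitudes.get(name, 0.0)
                * g.band_multipliers.get(name, 1.0)
                * jitter
                for name in base.bands
            }
            for run in range(design.runs_per_animal):
                spec = RecordingSpec(
                    n_channels=base.n_channels,
                    sampling_rate=base.sampling_rate,
                    duration=base.duration,
                    electrode_coords=base.electrode_coords,
                    band_amplitudes=amps,
                    bands=base.bands,
                    line_noise_amplitude=base.line_noise_amplitude,
                    line_freq=base.line_freq,
                    n_harmonics=base.n_harmonics,
                    artifact_rate=base.artifact_rate,
                    artifact_amplitude_factor=base.artifact_amplitude_factor,
                    seed=_animal_seed(design.seed, idx, run),
                )
                yield generate_recording(spec, g.coupling), animal_id, g.injury, g.time, run
            idx += 1
    del meta


# ---------------------------------------------------------------------------
# histology
# ---------------------------------------------------------------------------

DEFAULT_TIMEPOINTS = ("Naive/Sham", "6-h", "7-days", "1-month", "3-months")
DEFAULT_ROIS = ("Au1", "V1", "RSC", "CC")
DEFAULT_LAYERS = ("L2/3", "L4", "L5", "L6")


@dataclass
class HistoSpec:
    """Ground truth for cell-count tables over ROI x layer x hemisphere.

    ``group_multipliers`` maps ``(roi, layer, timepoint) -> density
    multiplier`` (default 1 everywhere).  ``dispersion`` of 0 means Poisson
    counts; > 0 adds negative-binomial overdispersion (variance =
    mean + dispersion * mean^2); ``None`` disables count noise entirely.
    """

    rois: tuple[str, ...] = DEFAULT_ROIS
    layers: tuple[str, ...] = DEFAULT_LAYERS
    hemispheres: tuple[str, ...] = ("left", "right")
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    baseline_density: float | Mapping[tuple[str, str], float] = 120.0  # cells/mm^2
    region_area: float = 0.5  # mm^2 sampling window
    group_multipliers: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    dispersion: float | None = 0.0
    slices_per_animal: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.region_area <= 0:
            raise ValueError("region_area must be > 0")
        if self.slices_per_animal < 1:
            raise ValueError("slices_per_animal must be >= 1")
        if any(m <= 0 for m in self.group_multipliers.values()):
            raise ValueError("multipliers must be > 0")
        for roi in self.rois:
            for layer in self.layers:
                if self._base(roi, layer) <= 0:
                    raise ValueError("densities must be > 0")

    def _base(self, roi: str, layer: str) -> float:
        if isinstance(self.baseline_density, Mapping):
            return float(self.baseline_density[(roi, layer)])
        return float(self.baseline_density)


def generate_histology(spec: HistoSpec, n_per_group: Mapping[str, int]) -> pd.DataFrame:
    """Cell-count table: one row per animal x ROI x layer x hemisphere x slice.

    Counts are drawn per slice with mean ``density * area * multiplier``;
    downstream analysis averages the three slices per animal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for tp in spec.timepoints:
        n_animals = int(n_per_group.get(tp, 0))
        for i in range(n_animals):
            animal_id = f"{tp}-{i:02d}"
            for roi in spec.rois:
                for layer in spec.layers:
                    mult = spec.group_multipliers.get((roi, layer, tp), 1.0)
                    mean = spec._base(roi, layer) * spec.region_area * mult
                    for hemi in spec.hemispheres:
                        for sl in range(1, spec.slices_per_animal + 1):
                            if spec.dispersion is None:
                                count = mean
                            elif spec.dispersion == 0:
                                count = rng.poisson(mean)
                            else:
                                # NB via gamma-Poisson mixture
                                shape = 1.0 / spec.dispersion
                                lam = rng.gamma(shape, mean / shape)
                                count = rng.poisson(lam)
                            rows.append(
                                {
                                    "animal_id": animal_id,
                                    "timepoint": tp,
                                    "roi": roi,
                                    "layer": layer,
                                    "hemisphere": hemi,
                                    "slice": sl,
                                    "count": count,
                                    "area_mm2": spec.region_area,
                                }
                            )
    return pd.DataFrame(rows)
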