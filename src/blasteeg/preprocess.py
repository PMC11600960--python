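"""Preprocessing: resampling, line-noise removal, artifact rejection, ICA,
channel interpolation and epoching.

The pipeline order mirrors standard epicranial EEG practice: resample to
1 kHz, suppress 50 Hz line noise and harmonics by sliding-window sinusoid
regression, excise artifact-contaminated windows (discard-only; no subspace
reconstruction), decompose with infomax ICA and flag artifactual components
by auditable spectral/temporal rules, then interpolate bad channels on the
electrode sphere.  Each step appends to the recording's provenance log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal, stats
from scipy.special import eval_legendre

from .recording import MultichannelRecording

__all__ = [
    "resample",
    "remove_line_noise",
    "detect_artifact_segments",
    "reject_artifacts",
    "ICADecomposition",
    "ica_decompose",
    "ComponentRules",
    "flag_components",
    "remove_components",
    "interpolate_channels",
    "epoch",
    "preprocess_pipeline",
]


def resample(rec: MultichannelRecording, target_rate: float = 1000.0) -> MultichannelRecording:
    """Anti-alias filtered polyphase resampling to ``target_rate``.

    Only downsampling (or the identity) is supported; duration is preserved
    to within one sample.
    """
    if target_rate > rec.sfreq:
        raise ValueError("upsampling not supported: target rate above original")
    if target_rate == rec.sfreq:
        return rec.copy_with(log_extra=[f"resample:identity@{target_rate}"])
    frac = Fraction(target_rate / rec.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=0)
    new = replace(rec, data=out, sfreq=rec.sfreq * up / down, retained_segments=None)
    new.log = rec.log + [f"resample:{rec.sfreq}->{new.sfreq}"]
    return new


def remove_line_noise(
    rec: MultichannelRecording,
    base: float = 50.0,
    n_harmonics: int = 3,
    window_s: float = 4.0,
) -> MultichannelRecording:
    """Suppress line noise at ``base`` Hz and harmonics.

    Within consecutive windows, a sine/cosine pair at each target frequency
    is fitted by least squares per channel and subtracted, removing the
    locally stationary deterministic tone while leaving broadband content
    essentially untouched.
    """
    if base >= rec.sfreq / 2:
        raise ValueError("line frequency must be below Nyquist")
    data = rec.data.copy()
    n = rec.n_samples
    wlen = int(window_s * rec.sfreq)
    targets = [base * k for k in range(1, n_harmonics + 1) if base * k < rec.sfreq / 2]
    # subtract a fitted tone only where its regression is significant, so a
    # record with no line contamination passes through essentially unchanged;
    # the gate is Bonferroni-strict over all window/channel/frequency tests
    n_tests = max(1, (n // wlen) * len(targets) * rec.n_channels)
    p_gate = 1e-3 / n_tests
    for start in range(0, n, wlen):
        end = min(start + wlen, n)
        if end - start < int(rec.sfreq / base * 2):
            continue  # window too short to resolve the tone
        t = np.arange(start, end) / rec.sfreq
        seg = data[start:end]
        m = end - start
        for f in targets:
            X = np.column_stack(
                [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
            )
            beta, *_ = np.linalg.lstsq(X, seg, rcond=None)
            fitted = X @ beta
            ss_tone = (fitted**2).sum(axis=0)
            resid = seg - fitted
            ss_res = (resid**2).sum(axis=0)
            df2 = m - 2
            with np.errstate(divide="ignore", invalid="ignore"):
                fstat = (ss_tone / 2) / np.where(ss_res > 0, ss_res / df2, np.inf)
            pvals = stats.f.sf(fstat, 2, df2)
            keep = pvals < p_gate
            seg[:, keep] -= fitted[:, keep]
    new = replace(rec, data=data)
    new.log = rec.log + [f"remove_line_noise:{base}Hz x{len(targets)}"]
    return new


def detect_artifact_segments(
    rec: MultichannelRecording, z_threshold: float = 5.0, window_s: float = 1.0
) -> list[tuple[int, int]]:
    """Windowed-RMS artifact scan; returns the retained sample segments.

    Per channel, the RMS of consecutive windows is z-scored against a robust
    calibration (median and MAD over windows, i.e. the clean majority);
    windows exceeding the threshold on any channel are excised, and the
    remaining data is returned as disjoint half-open ``[start, end)``
    intervals.  Discard-only: nothing is reconstructed.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    wlen = int(window_s * rec.sfreq)
    n_win = rec.n_samples // wlen
    if n_win < 2:
        raise ValueError("recording too short for artifact scan")
    segs = rec.data[: n_win * wlen].reshape(n_win, wlen, rec.n_channels)
    rms = np.sqrt(np.mean(segs**2, axis=1))  # n_win x channels
    med = np.median(rms, axis=0)
    mad = stats.median_abs_deviation(rms, axis=0, scale="normal")
    mad = np.where(mad <= 0, 1e-12, mad)
    z = (rms - med) / mad
    bad_win = np.any(z > z_threshold, axis=1)
    # tail samples beyond the last full window follow the last window's verdict
    keep = ~bad_win
    if not keep.any():
        raise ValueError("all windows rejected: recording unusable")
    retained: list[tuple[int, int]] = []
    start = None
    for w in range(n_win):
        if keep[w] and start is None:
            start = w * wlen
        elif not keep[w] and start is not None:
            retained.append((start, w * wlen))
            start = None
    if start is not None:
        end = rec.n_samples if keep[n_win - 1] else n_win * wlen
        retained.append((start, end))
    return retained


def reject_artifacts(
    rec: MultichannelRecording, z_threshold: float = 5.0, window_s: float = 1.0
) -> MultichannelRecording:
    """Apply :func:`detect_artifact_segments` and record the result."""
    segments = detect_artifact_segments(rec, z_threshold, window_s)
    new = replace(rec, retained_segments=segments)
    kept = sum(e - s for s, e in segments)
    new.log = rec.log + [f"reject_artifacts:z={z_threshold},kept={kept}/{rec.n_samples}"]
    return new


@dataclass
class ICADecomposition:
    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray  # channels x components
    mean: np.ndarray  # per-channel mean removed before decomposition
    activations: np.ndarray  # samples x components
    ch_names: list[str]
    sfreq: float
    component_flags: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def reconstruct(self, exclude: set[int] | None = None) -> np.ndarray:
        """Channel data from components, optionally excluding some."""
        acts = self.activations
        if exclude:
            keep = [i for i in range(self.n_components) if i not in exclude]
            return acts[:, keep] @ self.mixing[:, keep].T + self.mean
        return acts @ self.mixing.T + self.mean


def ica_decompose(
    rec: MultichannelRecording, rank_tol: float = 1e-10, seed: int = 0
) -> ICADecomposition:
    """Infomax ICA of the retained data, with PCA rank reduction.

    Requires at least ``20 * n_channels**2`` retained samples for a stable
    estimate.  Rank-deficient inputs (duplicated or silent channels) yield a
    reduced-rank decomposition rather than an error.
    """
    from mne.preprocessing import infomax

    X = rec.retained_data()
    if X.shape[0] < 20 * rec.n_channels**2:
        raise ValueError(
            f"need >= {20 * rec.n_channels ** 2} retained samples for a "
            f"stable decomposition, got {X.shape[0]}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    # PCA whitening with rank detection
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    rank = int(np.sum(var > rank_tol * var[0]))
    s, Vt = s[:rank], Vt[:rank]
    whitened = U[:, :rank] * np.sqrt(X.shape[0] - 1)  # unit-variance scores
    W = infomax(whitened, random_state=seed, extended=True, verbose=False)
    # unmixing from channels to components
    whitener = (Vt.T / (s / np.sqrt(X.shape[0] - 1))).T  # rank x channels
    unmixing = W @ whitener
    mixing = np.linalg.pinv(unmixing)
    activations = Xc @ unmixing.T
    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        mean=mean,
        activations=activations,
        ch_names=list(rec.ch_names),
        sfreq=rec.sfreq,
    )


@dataclass
class ComponentRules:
    """Thresholds for automated component screening.

    Conservative defaults flag only blatant artifacts.  Set a threshold to
    ``None`` to disable that rule.
    """

    line_freq: float = 50.0
    line_ratio: float | None = 0.6  # fraction of PSD within +-1 Hz of line freq
    kurtosis: float | None = 20.0  # excess kurtosis of the activation
    drift_fraction: float | None = 0.6  # fraction of PSD below 1 Hz


def flag_components(decomp: ICADecomposition, rules: ComponentRules | None = None) -> dict[int, list[str]]:
    """Flag components by 50 Hz share, kurtosis, or sub-1 Hz drift share.

    An automated, auditable stand-in for manual screening; every flag
    carries a reason code so a reviewer can override.
    """
    if rules is None:
        rules = ComponentRules()
    flags: dict[int, list[str]] = {}
    nper = min(decomp.activations.shape[0], int(2 * decomp.sfreq))
    for comp in range(decomp.n_components):
        x = decomp.activations[:, comp]
        reasons = []
        freqs, psd = signal.welch(x, fs=decomp.sfreq, nperseg=nper)
        total = psd.sum()
        if total > 0:
            if rules.line_ratio is not None:
                m = np.abs(freqs - rules.line_freq) <= 1.0
                if psd[m].sum() / total > rules.line_ratio:
                    reasons.append("line")
            if rules.drift_fraction is not None:
                if psd[freqs < 1.0].sum() / total > rules.drift_fraction:
                    reasons.append("drift")
        if rules.kurtosis is not None and stats.kurtosis(x) > rules.kurtosis:
            reasons.append("kurtosis")
        if reasons:
            flags[comp] = reasons
    decomp.component_flags = flags
    return flags


def remove_components(
    rec: MultichannelRecording, decomp: ICADecomposition, exclude: set[int]
) -> MultichannelRecording:
    """Reconstruct the retained data without the excluded components."""
    clean = decomp.reconstruct(exclude=exclude)
    data = rec.data.copy()
    pos = 0
    for s, e in rec.retained_segments:
        data[s:e] = clean[pos : pos + (e - s)]
        pos += e - s
    new = replace(rec, data=data)
    new.log = rec.log + [f"remove_components:{sorted(exclude)}"]
    return new


def _spherical_g(cosang: np.ndarray, m: int = 4, n_terms: int = 30) -> np.ndarray:
    """Spherical spline kernel: Legendre series over degrees 1..n_terms."""
    out = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * eval_legendre(n, cosang)
    return out / (4 * np.pi)


def _spherical_weights(good: np.ndarray, bad: np.ndarray, reg: float = 1e-8) -> np.ndarray:
    """Interpolation matrix mapping good-channel values to bad channels."""
    G = _spherical_g(np.clip(good @ good.T, -1, 1))
    G = G + reg * np.eye(len(good))
    Gb = _spherical_g(np.clip(bad @ good.T, -1, 1))
    n = len(good)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    # solve for spline coefficients given data at good electrodes
    Ainv = np.linalg.pinv(A)
    # value at bad site = d + Gb @ c where [c; d] = Ainv @ [z; 0]
    return np.hstack([Gb, np.ones((len(bad), 1))]) @ Ainv[:, :n]


def interpolate_channels(
    rec: MultichannelRecording, bad: set[str], method: str = "spherical"
) -> MultichannelRecording:
    """Replace bad channels by spherical-spline or inverse-distance estimates.

    Good channels are untouched.  Spherical interpolation fits a spline on
    the unit-sphere electrode coordinates (all coordinates required).
    """
    if not bad:
        return rec.copy_with(log_extra=["interpolate:none"])
    if rec.coords is None:
        raise ValueError("electrode coordinates required for interpolation")
    if not bad <= set(rec.ch_names):
        raise ValueError("bad channels not in recording")
    bad_idx = np.array([rec.ch_names.index(c) for c in sorted(bad)])
    good_idx = np.array([i for i in range(rec.n_channels) if i not in set(bad_idx)])
    if method == "spherical" and len(bad_idx) >= rec.n_channels - 3:
        raise ValueError("too many bad channels for spherical interpolation")
    coords = rec.coords / np.linalg.norm(rec.coords, axis=1, keepdims=True)
    data = rec.data.copy()
    if method == "spherical":
        W = _spherical_weights(coords[good_idx], coords[bad_idx])
        data[:, bad_idx] = data[:, good_idx] @ W.T
    elif method == "inverse_distance":
        for bi in bad_idx:
            d = np.linalg.norm(coords[good_idx] - coords[bi], axis=1)
            w = 1.0 / np.maximum(d, 1e-12) ** 2
            w /= w.sum()
            data[:, bi] = data[:, good_idx] @ w
    else:
        raise ValueError(f"unknown method {method!r}")
    new = replace(rec, data=data, bad_channels=set())
    new.log = rec.log + [f"interpolate:{method}:{sorted(bad)}"]
    return new


def epoch(
    rec: MultichannelRecording, length_s: float, overlap_fraction: float = 0.0
) -> np.ndarray:
    """Cut the retained segments into equal-length epochs.

    Epochs never span excised gaps.  Returns an array of shape
    ``(n_epochs, length_samples, n_channels)``.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    wlen = int(round(length_s * rec.sfreq))
    step = max(1, int(round(wlen * (1 - overlap_fraction))))
    epochs = []
    for s, e in rec.retained_segments:
        start = s
        while start + wlen <= e:
            epochs.append(rec.data[start : start + wlen])
            start += step
    if not epochs:
        raise ValueError("no epoch fits in the retained segments")
    return np.stack(epochs)


def preprocess_pipeline(
    rec: MultichannelRecording,
    target_rate: float = 1000.0,
    line_freq: float = 50.0,
    n_harmonics: int = 3,
    z_threshold: float = 5.0,
    artifact_window_s: float = 1.0,
    run_ica: bool = False,
    component_rules: ComponentRules | None = None,
    interpolate: str | None = "spherical",
    ica_seed: int = 0,
) -> MultichannelRecording:
    """Full cleaning chain in the contract order:

    resample -> line-noise removal -> artifact scan -> (optional ICA with
    automated component rejection) -> bad-channel interpolation.
    """
    out = resample(rec, target_rate) if target_rate < rec.sfreq else rec
    out = remove_line_noise(out, base=line_freq, n_harmonics=n_harmonics)
    out = reject_artifacts(out, z_threshold=z_threshold, window_s=artifact_window_s)
    if run_ica:
        try:
            decomp = ica_decompose(out, seed=ica_seed)
            flags = flag_components(decomp, component_rules)
            if flags:
                out = remove_components(out, decomp, set(flags))
        except ValueError as err:
            warnings.warn(f"ICA skipped: {err}")
    if interpolate and out.bad_channels:
        out = interpolate_channels(out, out.bad_channels, method=interpolate)
    return out
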