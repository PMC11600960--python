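"""Debiased weighted phase-lag-index (dwPLI) connectivity.

Epochs (3 s by default) are cut into 1.5 s Hann windows with 50 % overlap;
each window's cross-spectrum for every unordered electrode pair is one
observation.  With ``I_i`` the imaginary part of the cross-spectrum at
observation ``i`` over ``n`` observations, the debiased estimator is

    dwPLI = [(sum I_i)^2 - sum I_i^2] / [(sum |I_i|)^2 - sum I_i^2]

computed per frequency bin; a zero denominator (no imaginary cross-spectral
mass, e.g. identical or exactly zero-lag signals) is defined as 0.  The
estimator is insensitive to zero-lag (volume-conducted) coupling because a
common instantaneous source contributes no imaginary cross-spectrum, and
the debiasing removes the positive small-sample bias of weighted PLI, so
independent channels average to ~0 (slightly negative values are an
estimator property, not an error).

Band summaries are means over the frequency bins inside each half-open
band; global connectivity is the mean over all unordered pairs of the
array.  Sums over observations are accumulated streaming, so memory does
not grow with recording length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import DEFAULT_BANDS, band_masks

__all__ = [
    "CrossSpectra",
    "cross_spectral_density",
    "dwpli",
    "dwpli_pairwise",
    "band_connectivity",
    "global_connectivity",
    "average_connectivity_runs",
    "edge_list",
]


@dataclass
class CrossSpectra:
    """Accumulated cross-spectral observations for all unordered pairs.

    ``sum_im``, ``sum_im2``, ``sum_absim`` are running sums over
    observations of Im X_jk, (Im X_jk)^2 and |Im X_jk|, each of shape
    ``(n_pairs, n_freqs)``.  ``values`` (observations x pairs x freqs,
    complex) is retained only when requested, for inspection and for
    brute-force cross-checks on small problems.
    """

    freqs: np.ndarray
    pairs: np.ndarray  # n_pairs x 2 channel indices, j < k
    n_channels: int
    n_observations: int
    sum_im: np.ndarray
    sum_im2: np.ndarray
    sum_absim: np.ndarray
    window_s: float
    overlap: float
    values: np.ndarray | None = None


def _pair_index(n_channels: int) -> np.ndarray:
    j, k = np.triu_indices(n_channels, k=1)
    return np.column_stack([j, k])


def cross_spectral_density(
    epochs: np.ndarray,
    sfreq: float,
    window_s: float = 1.5,
    overlap: float = 0.5,
    keep_observations: bool | None = None,
) -> CrossSpectra:
    """Welch cross-spectra of epoched data, pooled across windows and epochs.

    ``epochs`` has shape ``(n_epochs, n_samples, n_channels)``.  Every
    Hann-tapered window of every epoch contributes one complex
    cross-spectral observation per pair and frequency.  Pooling across
    sub-windows and epochs maximizes the observation count entering the
    phase-lag estimator.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_samples, n_channels)")
    n_epochs, n_samples, n_channels = epochs.shape
    if n_channels < 2:
        raise ValueError("need at least two channels")
    nper = int(round(window_s * sfreq))
    if n_samples < nper:
        raise ValueError("epoch shorter than the cross-spectral window")
    step = nper - int(round(nper * overlap))
    win = sps.get_window("hann", nper)
    scale = 1.0 / (sfreq * (win**2).sum())
    freqs = np.fft.rfftfreq(nper, d=1.0 / sfreq)
    pairs = _pair_index(n_channels)
    pj, pk = pairs[:, 0], pairs[:, 1]
    n_freqs = freqs.size

    starts = list(range(0, n_samples - nper + 1, step))
    n_obs = n_epochs * len(starts)
    if keep_observations is None:
        keep_observations = n_obs * len(pairs) * n_freqs * 16 < 50e6

    sum_im = np.zeros((len(pairs), n_freqs))
    sum_im2 = np.zeros_like(sum_im)
    sum_absim = np.zeros_like(sum_im)
    kept = [] if keep_observations else None
    for ep in range(n_epochs):
        for s in starts:
            seg = epochs[ep, s : s + nper] * win[:, None]
            F = np.fft.rfft(seg, axis=0)  # freqs x channels
            cross = F[:, pj] * np.conj(F[:, pk])  # freqs x pairs
            cross *= 2.0 * scale  # one-sided density scaling
            cross[0] *= 0.5
            if nper % 2 == 0:
                cross[-1] *= 0.5
            cross = cross.T  # pairs x freqs
            im = cross.imag
            sum_im += im
            sum_im2 += im**2
            sum_absim += np.abs(im)
            if kept is not None:
                kept.append(cross)
    return CrossSpectra(
        freqs=freqs,
        pairs=pairs,
        n_channels=n_channels,
        n_observations=n_obs,
        sum_im=sum_im,
        sum_im2=sum_im2,
        sum_absim=sum_absim,
        window_s=window_s,
        overlap=overlap,
        values=np.stack(kept) if kept is not None else None,
    )


def _debiased_ratio(sum_im, sum_im2, sum_absim):
    num = sum_im**2 - sum_im2
    den = sum_absim**2 - sum_im2
    out = np.zeros_like(num)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def dwpli(cs: CrossSpectra) -> np.ndarray:
    """Per-frequency dwPLI, shape ``(n_freqs, n_channels, n_channels)``.

    Symmetric with zero diagonal.  Uses the one-pass sums form; the
    equivalent O(n^2) pairwise estimator is :func:`dwpli_pairwise`.
    """
    if cs.n_observations < 2:
        raise ValueError("need at least 2 observations for dwPLI")
    vals = _debiased_ratio(cs.sum_im, cs.sum_im2, cs.sum_absim)  # pairs x freqs
    out = np.zeros((cs.freqs.size, cs.n_channels, cs.n_channels))
    pj, pk = cs.pairs[:, 0], cs.pairs[:, 1]
    out[:, pj, pk] = vals.T
    out[:, pk, pj] = vals.T
    return out


def dwpli_from_observations(imag_obs: np.ndarray) -> float:
    """One-pass dwPLI from a vector of Im X_jk observations."""
    I = np.asarray(imag_obs, dtype=float)
    if I.size < 2:
        raise ValueError("need at least 2 observations")
    return float(
        _debiased_ratio(
            np.array(I.sum()), np.array((I**2).sum()), np.array(np.abs(I).sum())
        )
    )


def dwpli_pairwise(imag_obs: np.ndarray) -> float:
    """Brute-force debiased WPLI over observations of Im X_jk.

    Averages products over all ordered pairs of distinct observations:
    ``sum_{i != l} I_i I_l / sum_{i != l} |I_i I_l|``.  O(n^2) reference
    estimator for cross-checking the one-pass form.
    """
    I = np.asarray(imag_obs, dtype=float)
    n = I.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    num = 0.0
    den = 0.0
    for i in range(n):
        for l in range(n):
            if i == l:
                continue
            num += I[i] * I[l]
            den += abs(I[i] * I[l])
    return num / den if den != 0 else 0.0


def band_connectivity(
    conn: np.ndarray, freqs: np.ndarray, bands=None
) -> dict[str, np.ndarray]:
    """Mean dwPLI over the frequency bins of each half-open band.

    ``conn`` is the per-frequency stack from :func:`dwpli`.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    masks = band_masks(freqs, bands)
    out = {}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"band {name!r} contains no frequency bins")
        out[name] = conn[mask].mean(axis=0)
    return out


def global_connectivity(band_matrices: dict[str, np.ndarray]) -> pd.Series:
    """Mean over all unordered channel pairs, per band."""
    out = {}
    for name, mat in band_matrices.items():
        n = mat.shape[0]
        iu = np.triu_indices(n, k=1)
        out[name] = float(mat[iu].mean())
    return pd.Series(out, name="dwpli")


def average_connectivity_runs(run_matrices: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Arithmetic mean of band connectivity matrices over runs."""
    if not run_matrices:
        raise ValueError("need at least one run")
    bands = list(run_matrices[0])
    for rm in run_matrices[1:]:
        if list(rm) != bands:
            raise ValueError("inconsistent band sets across runs")
    return {b: np.mean([rm[b] for rm in run_matrices], axis=0) for b in bands}


def edge_list(band_matrices: dict[str, np.ndarray], ch_names: list[str]) -> pd.DataFrame:
    """Tidy edge-list frame: chan_a, chan_b, band, dwpli."""
    rows = []
    for band, mat in band_matrices.items():
        iu = np.triu_indices(mat.shape[0], k=1)
        for a, b in zip(*iu):
            rows.append(
                {"chan_a": ch_names[a], "chan_b": ch_names[b], "band": band,
                 "dwpli": float(mat[a, b])}
            )
    return pd.DataFrame(rows)
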