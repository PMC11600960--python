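"""Welch power spectra and absolute/relative band power summaries.

Power spectral densities are computed per channel with Welch's method on
2 s Hann-tapered windows with 50 % overlap, giving a 0.5 Hz grid, and
restricted to the analysed 1--200 Hz range.  Band power is the mean of the
PSD bins inside each half-open band; relative (normalized) power divides
each channel's PSD by the sum of its bins over the analysed range before
taking band means, so each channel's relative spectrum integrates to one.
Global summaries average over the electrode array; multiple runs per animal
are averaged arithmetically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .bands import DEFAULT_BANDS, FMAX, FMIN, band_masks
from .recording import MultichannelRecording

__all__ = [
    "PowerSpectrum",
    "welch_psd",
    "band_power",
    "relative_power",
    "band_power_table",
    "global_power",
    "average_runs",
]


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz grid restricted to [fmin, fmax]
    psd: np.ndarray  # channels x freqs, uV^2/Hz
    ch_names: list[str]
    window_s: float
    overlap: float
    full_freqs: np.ndarray | None = None  # unrestricted grid (for Parseval)
    full_psd: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def welch_psd(
    rec: MultichannelRecording,
    window_s: float = 2.0,
    overlap: float = 0.5,
    fmin: float = FMIN,
    fmax: float = FMAX,
) -> PowerSpectrum:
    """Hann-tapered Welch PSD of the retained data, per channel.

    Welch segments are taken within each retained segment so estimates never
    straddle excised gaps.  The returned grid is restricted to
    ``[fmin, fmax]``; the full one-sided PSD is kept for Parseval checks.
    """
    nper = int(round(window_s * rec.sfreq))
    nover = int(round(nper * overlap))
    psd_sum = None
    total_windows = 0
    for s, e in rec.retained_segments:
        if e - s < nper:
            continue
        f, p = signal.welch(
            rec.data[s:e].T,
            fs=rec.sfreq,
            window="hann",
            nperseg=nper,
            noverlap=nover,
            detrend="constant",
            scaling="density",
        )
        n_win = (e - s - nover) // (nper - nover)
        psd_sum = p * n_win if psd_sum is None else psd_sum + p * n_win
        total_windows += n_win
    if psd_sum is None:
        raise ValueError("retained data shorter than one Welch window")
    psd = psd_sum / total_windows
    keep = (f >= fmin) & (f <= fmax)
    return PowerSpectrum(
        freqs=f[keep],
        psd=psd[:, keep],
        ch_names=list(rec.ch_names),
        window_s=window_s,
        overlap=overlap,
        full_freqs=f,
        full_psd=psd,
    )


def band_power(spectrum: PowerSpectrum, bands=None) -> pd.DataFrame:
    """Absolute band power: mean PSD value within each band, per channel.

    Returns a tidy frame with columns channel, band, power.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    masks = band_masks(spectrum.freqs, bands)
    rows = []
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"band {name!r} contains no frequency bins")
        vals = spectrum.psd[:, mask].mean(axis=1)
        for ch, v in zip(spectrum.ch_names, vals):
            rows.append({"channel": ch, "band": name, "power": float(v)})
    return pd.DataFrame(rows)


def relative_power(spectrum: PowerSpectrum, bands=None) -> pd.DataFrame:
    """Normalized band power: per-channel PSD divided by its summed bins
    over the analysed range, then band means as in :func:`band_power`."""
    totals = spectrum.psd.sum(axis=1)
    if np.any(totals <= 0):
        bad = [spectrum.ch_names[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"zero total power in channel(s): {bad}")
    norm = PowerSpectrum(
        freqs=spectrum.freqs,
        psd=spectrum.psd / totals[:, None],
        ch_names=spectrum.ch_names,
        window_s=spectrum.window_s,
        overlap=spectrum.overlap,
    )
    return band_power(norm, bands)


def band_power_table(spectrum: PowerSpectrum, bands=None) -> pd.DataFrame:
    """Absolute and relative band power in one tidy frame."""
    absolute = band_power(spectrum, bands).rename(columns={"power": "absolute"})
    rel = relative_power(spectrum, bands).rename(columns={"power": "relative"})
    return absolute.merge(rel, on=["channel", "band"])


def global_power(table: pd.DataFrame, n_channels: int | None = None) -> pd.Series:
    """Array-average band power: unweighted mean over channels per band.

    ``n_channels`` (when given) asserts the full array is present, e.g.
    after interpolation of rejected channels.
    """
    counts = table.groupby("band")["channel"].nunique()
    if n_channels is not None and (counts != n_channels).any():
        raise ValueError("missing channels in band power table")
    value_col = [c for c in table.columns if c not in ("channel", "band")]
    return table.groupby("band")[value_col].mean()


def average_runs(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean over runs of per-run band power tables.

    All runs must cover the same channel x band grid.
    """
    if not tables:
        raise ValueError("need at least one run")
    keys = ["channel", "band"]
    ref = tables[0][keys].sort_values(keys).reset_index(drop=True)
    for t in tables[1:]:
        cur = t[keys].sort_values(keys).reset_index(drop=True)
        if not ref.equals(cur):
            raise ValueError("inconsistent channel/band sets across runs")
    stacked = pd.concat(tables, ignore_index=True)
    return stacked.groupby(keys, as_index=False).mean(numeric_only=True)
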