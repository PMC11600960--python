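"""Canonical EEG frequency bands.

Bands are half-open on the left edge, ``[lo, hi)``, except the highest band
which is closed at its upper edge so that the union covers the full analysed
range 1--200 Hz with every frequency bin assigned exactly once.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

#: delta 1-4, theta 4-8, alpha 8-12, beta 12-25, gamma 25-80, HFO 80-200 Hz
DEFAULT_BANDS: "OrderedDict[str, tuple[float, float]]" = OrderedDict(
    [
        ("delta", (1.0, 4.0)),
        ("theta", (4.0, 8.0)),
        ("alpha", (8.0, 12.0)),
        ("beta", (12.0, 25.0)),
        ("gamma", (25.0, 80.0)),
        ("hfo", (80.0, 200.0)),
    ]
)

BAND_NAMES = tuple(DEFAULT_BANDS)

FMIN = 1.0
FMAX = 200.0


def validate_bands(bands: "OrderedDict[str, tuple[float, float]]") -> None:
    """Check that bands are non-overlapping, ordered and contiguous."""
    edges = list(bands.values())
    for (lo, hi) in edges:
        if not lo < hi:
            raise ValueError(f"band has non-positive width: ({lo}, {hi})")
    for (_, hi), (lo2, _) in zip(edges, edges[1:]):
        if lo2 < hi:
            raise ValueError("bands overlap")


def band_mask(freqs: np.ndarray, band: tuple[float, float], *, closed_top: bool = False) -> np.ndarray:
    """Boolean mask of frequency bins falling in a half-open band ``[lo, hi)``.

    ``closed_top`` includes the upper edge (used for the highest band so the
    200 Hz bin belongs to HFO).
    """
    lo, hi = band
    if closed_top:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def band_masks(freqs: np.ndarray, bands=None) -> "OrderedDict[str, np.ndarray]":
    """Masks for every band; the last band is closed at the top edge."""
    if bands is None:
        bands = DEFAULT_BANDS
    names = list(bands)
    out = OrderedDict()
    for i, name in enumerate(names):
        out[name] = band_mask(freqs, bands[name], closed_top=(i == len(names) - 1))
    return out
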