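"""In-memory container for multichannel electrophysiology and raw-binary IO.

A recording is a ``samples x channels`` float array in microvolts with its
sampling rate, channel names, 3-D electrode coordinates on the unit sphere,
a set of bad channels and a list of retained sample intervals (0-based,
half-open ``[start, end)``).  Every processing step appends to a provenance
log so cleaned files document how they were produced.

Files are written as raw little-endian float32 (C order, samples x channels)
with a JSON sidecar carrying rate, channel names and coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["MultichannelRecording", "default_electrode_coords", "read_raw", "write_raw"]


def default_electrode_coords(n_channels: int = 32) -> np.ndarray:
    """Electrode positions on the upper unit hemisphere.

    Arranged as a rectangular grid (as on an epicranial rodent array)
    projected onto the sphere: 4 columns x 8 rows for 32 channels, or the
    nearest grid for other counts.
    """
    n_cols = 4 if n_channels % 4 == 0 else max(1, int(np.floor(np.sqrt(n_channels))))
    n_rows = int(np.ceil(n_channels / n_cols))
    coords = []
    for idx in range(n_channels):
        r, c = divmod(idx, n_cols)
        # grid in the tangent plane, scaled to stay on the upper cap
        x = (c - (n_cols - 1) / 2) / max(n_cols, 1) * 1.2
        y = (r - (n_rows - 1) / 2) / max(n_rows, 1) * 1.6
        z2 = 1.0 - x * x - y * y
        z = np.sqrt(max(z2, 0.05))
        v = np.array([x, y, z])
        coords.append(v / np.linalg.norm(v))
    return np.asarray(coords)


@dataclass
class MultichannelRecording:
    data: np.ndarray  # samples x channels, microvolts
    sfreq: float
    ch_names: list[str]
    coords: np.ndarray  # channels x 3, unit sphere
    bad_channels: set[str] = field(default_factory=set)
    retained_segments: list[tuple[int, int]] | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be samples x channels")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel name count does not match data")
        if self.coords is not None and len(self.coords) != self.n_channels:
            raise ValueError("coordinate count does not match channels")
        if self.retained_segments is None:
            self.retained_segments = [(0, self.n_samples)]
        self._check_segments()
        if not self.bad_channels <= set(self.ch_names):
            raise ValueError("bad_channels must be a subset of channels")

    def _check_segments(self) -> None:
        prev_end = 0
        for start, end in self.retained_segments:
            if not (0 <= start < end <= self.n_samples):
                raise ValueError(f"segment ({start}, {end}) outside record")
            if start < prev_end:
                raise ValueError("retained segments overlap")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def retained_duration(self) -> float:
        return sum(e - s for s, e in self.retained_segments) / self.sfreq

    def copy_with(self, log_extra: list[str] | None = None, **kwargs) -> "MultichannelRecording":
        out = replace(self, **kwargs)
        out.log = list(self.log) + list(log_extra or [])
        return out

    def retained_data(self) -> np.ndarray:
        """Concatenated data from the retained segments (samples x channels)."""
        return np.concatenate([self.data[s:e] for s, e in self.retained_segments])

    def truncate_retained(self, n_samples: int) -> "MultichannelRecording":
        """Keep only the first ``n_samples`` retained samples.

        Used to enforce equal retained durations across a cohort before
        spectral or connectivity analysis.
        """
        if n_samples > sum(e - s for s, e in self.retained_segments):
            raise ValueError("cannot truncate beyond retained length")
        segs: list[tuple[int, int]] = []
        left = n_samples
        for s, e in self.retained_segments:
            take = min(e - s, left)
            if take > 0:
                segs.append((s, s + take))
                left -= take
            if left == 0:
                break
        out = replace(self, retained_segments=segs)
        out.log = self.log + [f"truncate_retained:{n_samples}"]
        return out


def write_raw(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write ``<path>.bin`` (float32) and ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    binpath = path.with_suffix(".bin")
    rec.data.astype("<f4").tofile(binpath)
    meta = {
        "sfreq": rec.sfreq,
        "ch_names": rec.ch_names,
        "coords": np.asarray(rec.coords).tolist(),
        "n_samples": rec.n_samples,
        "bad_channels": sorted(rec.bad_channels),
        "retained_segments": [list(s) for s in rec.retained_segments],
        "log": rec.log,
        "dtype": "<f4",
        "order": "samples_x_channels",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return binpath


def read_raw(path: str | Path) -> MultichannelRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".bin"), dtype=meta["dtype"])
    data = data.reshape(meta["n_samples"], len(meta["ch_names"])).astype(float)
    return MultichannelRecording(
        data=data,
        sfreq=meta["sfreq"],
        ch_names=list(meta["ch_names"]),
        coords=np.asarray(meta["coords"]),
        bad_channels=set(meta.get("bad_channels", [])),
        retained_segments=[tuple(s) for s in meta.get("retained_segments", [])] or None,
        log=list(meta.get("log", [])),
    )
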