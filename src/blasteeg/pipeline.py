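"""Cohort-level orchestration: recordings -> animal-level outcome tables.

Glues the stages together for whole cohorts: every run of every animal is
(optionally) preprocessed, spectra and connectivity are computed on the
retained data, runs are averaged per animal, and tidy animal-level tables
come out ready for the inferential modules.  Equal retained durations
across a cohort are enforced by truncating every recording to the cohort
minimum before spectral/connectivity analysis, keeping signal-to-noise
comparable between animals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS
from .connectivity import (
    average_connectivity_runs,
    band_connectivity,
    cross_spectral_density,
    dwpli,
    global_connectivity,
)
from .preprocess import epoch, preprocess_pipeline
from .recording import MultichannelRecording
from .spectral import average_runs, band_power_table, global_power, welch_psd
from .synthetic import CohortDesign, generate_cohort

__all__ = [
    "cohort_band_power",
    "cohort_connectivity",
    "enforce_equal_duration",
    "global_band_power_table",
]


def enforce_equal_duration(
    recordings: list[MultichannelRecording],
) -> list[MultichannelRecording]:
    """Truncate every recording's retained data to the cohort minimum."""
    n_min = min(
        sum(e - s for s, e in rec.retained_segments) for rec in recordings
    )
    return [rec.truncate_retained(n_min) for rec in recordings]


def _iter_animals(design: CohortDesign, preprocess: bool, **pp_kwargs):
    """Group the cohort generator's runs by animal."""
    current_id = None
    runs: list[MultichannelRecording] = []
    meta = None
    for rec, animal_id, injury, time, _run in generate_cohort(design):
        if preprocess:
            rec = preprocess_pipeline(rec, **pp_kwargs)
        if animal_id != current_id and current_id is not None:
            yield current_id, meta, runs
            runs = []
        current_id = animal_id
        meta = (injury, time)
        runs.append(rec)
    if current_id is not None:
        yield current_id, meta, runs


def cohort_band_power(
    design: CohortDesign,
    bands=None,
    preprocess: bool = False,
    **pp_kwargs,
) -> pd.DataFrame:
    """Per-animal global band power for a synthetic cohort.

    Returns a tidy frame: animal_id, injury, time, band, absolute,
    relative (run-averaged, channel-averaged).
    """
    bands = bands or DEFAULT_BANDS
    rows = []
    for animal_id, (injury, time), runs in _iter_animals(design, preprocess, **pp_kwargs):
        tables = [band_power_table(welch_psd(rec), bands) for rec in runs]
        per_animal = average_runs(tables)
        glob = global_power(per_animal, n_channels=design.recording.n_channels)
        for band in glob.index:
            rows.append(
                {
                    "animal_id": animal_id,
                    "injury": injury,
                    "time": time,
                    "band": band,
                    "absolute": float(glob.loc[band, "absolute"]),
                    "relative": float(glob.loc[band, "relative"]),
                }
            )
    return pd.DataFrame(rows)


def global_band_power_table(df: pd.DataFrame, band: str, value: str = "absolute") -> pd.DataFrame:
    """Slice one band out of the tidy cohort table for the 2x2 ANOVA."""
    sub = df[df["band"] == band].copy()
    sub["value"] = sub[value]
    return sub[["animal_id", "injury", "time", "value"]]


def cohort_connectivity(
    design: CohortDesign,
    band: str = "gamma",
    epoch_s: float = 3.0,
    csd_window_s: float = 1.5,
    csd_overlap: float = 0.5,
    preprocess: bool = False,
    **pp_kwargs,
):
    """Per-animal band dwPLI matrices and edge values for a cohort.

    Returns ``(edge_values, labels, pairs, ch_names, global_series)`` where
    ``edge_values`` is (animals x edges) run-averaged dwPLI in ``band``,
    ``labels`` the animal metadata frame, and ``global_series`` the
    pair-averaged global dwPLI per animal.
    """
    rows = []
    values = []
    pairs = None
    ch_names = None
    for animal_id, (injury, time), runs in _iter_animals(design, preprocess, **pp_kwargs):
        run_mats = []
        for rec in runs:
            eps = epoch(rec, epoch_s)
            cs = cross_spectral_density(
                eps, rec.sfreq, window_s=csd_window_s, overlap=csd_overlap,
                keep_observations=False,
            )
            conn = dwpli(cs)
            run_mats.append(band_connectivity(conn, cs.freqs))
            if pairs is None:
                pairs = cs.pairs
                ch_names = rec.ch_names
        mats = average_connectivity_runs(run_mats)
        mat = mats[band]
        values.append(mat[pairs[:, 0], pairs[:, 1]])
        rows.append(
            {
                "animal_id": animal_id,
                "injury": injury,
                "time": time,
                "global_dwpli": float(global_connectivity({band: mat})[band]),
            }
        )
    labels = pd.DataFrame(rows)
    return np.array(values), labels, pairs, ch_names, labels["global_dwpli"]
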