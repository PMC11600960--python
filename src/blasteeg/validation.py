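"""End-to-end validation suites on synthetic cohorts with known truth.

Each function runs a self-contained simulation through the public pipeline
and returns the measured quantities: degrees-of-freedom identities implied
by the cohort design, estimator calibration (dwPLI, Welch), permutation
test type-I rates, power/parameter recovery on the chronic cohort, FDR
procedure agreement with brute-force oracles, histology effect recovery,
and preprocessing quality metrics.  The test suite asserts tolerances on
these quantities; the acceptance script reports them.

Simulation problem sizes (recording duration, sampling rate, repetition
counts) are chosen so the full battery runs in minutes on one CPU while
every estimate remains well-resolved; the generator's scientific defaults
(300 s at 1 kHz, 32 channels, cohort sizes 13/20/8/9) are unchanged and
used wherever a single cohort suffices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .connectivity import (
    band_connectivity,
    cross_spectral_density,
    dwpli,
    dwpli_from_observations,
    dwpli_pairwise,
)
from .histology import LayerDensityAnalysis, compute_density, fdr_bky, hemisphere_gate
from .network import edgewise_perm_ttest, fdr_bh
from .permstats import TwoWayPermutationAnova, _add_one_p, _effect_design, _hat
from .pipeline import cohort_band_power, cohort_connectivity, global_band_power_table
from .preprocess import (
    detect_artifact_segments,
    interpolate_channels,
    remove_line_noise,
)
from .recording import MultichannelRecording, default_electrode_coords
from .spectral import relative_power, welch_psd
from .synthetic import (
    CouplingSpec,
    HistoSpec,
    RecordingSpec,
    chronic_design,
    generate_histology,
    generate_recording,
)

# ---------------------------------------------------------------------------
# degrees-of-freedom identities from the cohort design
# ---------------------------------------------------------------------------


def dof_identities() -> dict[str, int]:
    """Degrees of freedom implied by the study's printed group sizes.

    Computed by building the corresponding designs and reading the df off
    the fitted objects, not by arithmetic shortcuts.
    """
    out = {}
    # acute arm: 12 animals, paired pre/post -> n - 1
    out["paired_ttest_df"] = 12 - 1
    # chronic 2x2: 13/20/8/9 -> error df = N - 4
    rng = np.random.default_rng(0)
    rows = []
    for (injury, time), n in {("blast", "1-month"): 13, ("blast", "3-months"): 20,
                              ("sham", "1-month"): 8, ("sham", "3-months"): 9}.items():
        for _ in range(n):
            rows.append({"injury": injury, "time": time, "value": rng.normal()})
    df = pd.DataFrame(rows)
    model = TwoWayPermutationAnova.from_dataframe(df, "value")
    out["anova_error_df"] = model.df_error
    # pooled two-group contrast: N - 2
    out["pooled_ttest_df"] = len(df) - 2
    # histology one-way ANOVAs: PV Au1 {13,6,6,7,6} and SST Au1 {13,6,6,8,6}
    from .histology import oneway_anova_time

    def _histo_df2(ns):
        rows = []
        for tp, n in ns.items():
            for i in range(n):
                rows.append({"timepoint": tp, "density": rng.normal(100, 5)})
        return oneway_anova_time(pd.DataFrame(rows)).df2

    out["pv_au1_anova_df2"] = _histo_df2(
        {"Naive/Sham": 13, "6-h": 6, "7-days": 6, "1-month": 7, "3-months": 6})
    out["sst_au1_anova_df2"] = _histo_df2(
        {"Naive/Sham": 13, "6-h": 6, "7-days": 6, "1-month": 8, "3-months": 6})
    return out


# ---------------------------------------------------------------------------
# dwPLI estimator checks
# ---------------------------------------------------------------------------


def dwpli_oracle_max_diff(n_sets: int = 1000, seed: int = 0) -> float:
    """Max |one-pass - O(n^2) pairwise| over random observation sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(2, 40))
        I = rng.standard_normal(n) * 10.0 ** rng.integers(-3, 4)
        worst = max(worst, abs(dwpli_from_observations(I) - dwpli_pairwise(I)))
    return worst


def _pair_gamma_dwpli(data: np.ndarray, fs: float) -> float:
    n = int(3.0 * fs)
    k = data.shape[0] // n
    eps = data[: k * n].reshape(k, n, data.shape[1])
    cs = cross_spectral_density(eps, fs, keep_observations=False)
    conn = dwpli(cs)
    return float(band_connectivity(conn, cs.freqs, {"gamma": (25.0, 80.0)})["gamma"][0, 1])


def dwpli_calibration(seed: int = 0, n_sims: int = 100,
                      duration: float = 102.0, fs: float = 200.0) -> dict[str, float]:
    """Constant-lag pair, independence bias, zero-lag-source immunity."""
    out = {}
    spec = RecordingSpec(
        n_channels=2, sampling_rate=fs, duration=60.0,
        band_amplitudes={"gamma": 5.0}, line_noise_amplitude=0.0, seed=seed,
    )
    cp = CouplingSpec(edges=[(0, 1)], band="gamma",
                      phase_lag=np.pi / 2, coupling_fraction=1.0)
    rec = generate_recording(spec, cp)
    out["constant_lag_dwpli"] = _pair_gamma_dwpli(rec.data, fs)

    rng = np.random.default_rng(seed + 1)
    vals = []
    shifts = []
    for _ in range(n_sims):
        data = rng.standard_normal((int(duration * fs), 2))
        v = _pair_gamma_dwpli(data, fs)
        vals.append(v)
        common = 3.0 * rng.standard_normal(data.shape[0])
        shifts.append(_pair_gamma_dwpli(data + common[:, None], fs) - v)
    out["independent_mean_dwpli"] = float(np.mean(vals))
    out["common_source_shift"] = float(np.mean(np.abs(shifts)))
    return out


# ---------------------------------------------------------------------------
# spectral checks
# ---------------------------------------------------------------------------


def spectral_checks(seed: int = 0) -> dict[str, float]:
    """Parseval consistency, white-noise relative flatness, sinusoid power."""
    rng = np.random.default_rng(seed)
    fs = 500.0
    data = rng.standard_normal((int(300 * fs), 4))
    rec = MultichannelRecording(data, fs, [f"ch{i}" for i in range(4)],
                               default_electrode_coords(4))
    ps = welch_psd(rec)
    dfreq = ps.full_freqs[1] - ps.full_freqs[0]
    total = ps.full_psd.sum(axis=1) * dfreq
    parseval = float(np.abs(total / data.var(axis=0) - 1).max())

    rel = relative_power(ps).groupby("band")["power"].mean()
    spread = float(np.abs(rel / rel.mean() - 1).max())

    A = 2.0
    t = np.arange(0, 60, 1 / fs)
    tone = MultichannelRecording((A * np.sin(2 * np.pi * 10 * t))[:, None], fs,
                                 ["ch0"], default_electrode_coords(2)[:1])
    pst = welch_psd(tone)
    m = (pst.freqs >= 8) & (pst.freqs < 12)
    band_int = pst.psd[0, m].sum() * (pst.freqs[1] - pst.freqs[0])
    sin_err = float(abs(band_int / (A**2 / 2) - 1))
    return {
        "parseval_max_rel_error": parseval,
        "white_noise_relative_band_max_dev": spread,
        "sinusoid_band_power_rel_error": sin_err,
    }


# ---------------------------------------------------------------------------
# permutation-test validity (type-I rates under the null)
# ---------------------------------------------------------------------------


def paired_type1_rate(n_cohorts: int = 1000, n_pairs: int = 12,
                      n_perm: int = 200, alpha: float = 0.05,
                      seed: int = 0) -> float:
    """Rejection rate of the sign-flip paired test on null cohorts."""
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_cohorts, n_pairs))
    signs = rng.choice([-1.0, 1.0], size=(n_cohorts, n_perm, n_pairs))
    sd = d.std(axis=1, ddof=1)
    t_obs = d.mean(axis=1) / (sd / np.sqrt(n_pairs))
    x = signs * d[:, None, :]
    m = x.mean(axis=2)
    s = x.std(axis=2, ddof=1)
    t_null = np.where(s > 0, m / (s / np.sqrt(n_pairs)), 0.0)
    exceed = (np.abs(t_null) >= np.abs(t_obs)[:, None]).sum(axis=1)
    p = (1 + exceed) / (1 + n_perm)
    return float((p <= alpha).mean())


def anova_type1_rates(n_cohorts: int = 1000, n_perm: int = 200,
                      alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Per-effect rejection rates of the factorial permutation ANOVA under
    a global null with the chronic 13/20/8/9 design."""
    rng = np.random.default_rng(seed)
    inj = np.repeat(["blast", "blast", "sham", "sham"], [13, 20, 8, 9])
    tim = np.repeat(["1-month", "3-months", "1-month", "3-months"], [13, 20, 8, 9])
    designs = _effect_design(inj, tim)
    hats = {k: _hat(X) for k, X in designs.items()}
    n = len(inj)
    df_error = n - 4

    def f_stats(Y):
        yy = np.sum(Y * Y, axis=1)
        fitted = {k: np.sum(Y * (Y @ H), axis=1) for k, H in hats.items()}
        rss_full = yy - fitted["full"]
        mse = rss_full / df_error
        return {
            eff: np.where(mse > 0, (fitted["full"] - fitted[eff]) / mse, 0.0)
            for eff in ("group", "time", "interaction")
        }

    rejects = {eff: 0 for eff in ("group", "time", "interaction")}
    for _ in range(n_cohorts):
        y = rng.standard_normal(n)
        obs = {k: v[0] for k, v in f_stats(y[None, :]).items()}
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        nulls = f_stats(y[perms])
        for eff in rejects:
            p = _add_one_p(nulls[eff], obs[eff])
            rejects[eff] += p <= alpha
    return {f"{k}_type1_rate": v / n_cohorts for k, v in rejects.items()}


# ---------------------------------------------------------------------------
# power / parameter recovery on the chronic cohort
# ---------------------------------------------------------------------------

#: scaled-down per-run recording used inside repetition loops
_FAST_RECORDING = dict(n_channels=32, sampling_rate=500.0, duration=30.0,
                       line_noise_amplitude=0.0, artifact_rate=0.0)


def group_effect_detection_rate(n_reps: int = 10, n_perm: int = 800,
                                seed: int = 0) -> float:
    """Fraction of synthetic chronic cohorts (x1.5 blast broadband
    amplitude) in which the gamma-band group main effect survives
    Bonferroni over the six bands."""
    detected = 0
    for rep in range(n_reps):
        design = chronic_design(
            blast_band_multipliers={b: 1.5 for b in BAND_NAMES},
            recording=RecordingSpec(**_FAST_RECORDING),
            seed=seed * 10007 + rep,
        )
        df = cohort_band_power(design)
        sub = global_band_power_table(df, "gamma", "absolute")
        res = TwoWayPermutationAnova.from_dataframe(sub, "value").fit(
            n_perm=n_perm, seed=seed + rep, family_size=6
        )
        detected += res.effects["group"].p_adjusted < 0.05
    return detected / n_reps


DEFAULT_PLANTED_EDGES = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11),
                         (12, 13), (14, 15), (16, 17), (18, 19)]


def network_recovery(n_reps: int = 10, n_perm: int = 2000, q: float = 0.05,
                     coupling: float = 0.5, seed: int = 0) -> dict[str, float]:
    """Sensitivity and empirical FDR for a planted 10-edge gamma network.

    Blast animals carry the coupled edges (coupling fraction ``coupling``);
    sham animals none.  Each repetition runs the full connectivity +
    edge-wise permutation + BH chain; counts are pooled over repetitions.
    """
    true_set = {tuple(e) for e in DEFAULT_PLANTED_EDGES}
    tp = fp = fn = 0
    for rep in range(n_reps):
        cp = CouplingSpec(edges=DEFAULT_PLANTED_EDGES, band="gamma",
                          coupling_fraction=coupling)
        design = chronic_design(
            blast_coupling=cp,
            recording=RecordingSpec(**_FAST_RECORDING),
            seed=seed * 20011 + rep,
        )
        vals, labels, pairs, _, _ = cohort_connectivity(design, band="gamma")
        stats = edgewise_perm_ttest(
            vals, (labels["injury"] == "blast").to_numpy(),
            n_perm=n_perm, seed=seed + rep,
        )
        flags = fdr_bh(stats["p"].to_numpy(), q)
        hits = {tuple(pairs[i]) for i in np.flatnonzero(flags)}
        tp += len(hits & true_set)
        fp += len(hits - true_set)
        fn += len(true_set - hits)
    sens = tp / (tp + fn) if tp + fn else 0.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return {"edge_sensitivity": sens, "empirical_fdr": fdr}


# ---------------------------------------------------------------------------
# FDR procedures against exhaustive oracles
# ---------------------------------------------------------------------------


def _bh_oracle(p: np.ndarray, q: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    best = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best = k
    flags = np.zeros(m, bool)
    flags[order[:best]] = True
    return flags


def _bky_oracle(p: np.ndarray, q: float) -> np.ndarray:
    m = p.size
    qp = q / (1 + q)
    s1 = _bh_oracle(p, qp)
    r1 = int(s1.sum())
    if r1 == 0 or r1 == m:
        return s1
    return _bh_oracle(p, qp * m / (m - r1))


def fdr_oracle_mismatches(n_vectors: int = 10000, seed: int = 0) -> dict[str, int]:
    """Count disagreements of BH / BKY flags with exhaustive step-up
    oracles over random p-vectors (mixtures of uniform and small p)."""
    rng = np.random.default_rng(seed)
    bh_bad = bky_bad = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 30))
        p = np.where(rng.random(m) < 0.4, rng.uniform(high=0.03, size=m),
                     rng.uniform(size=m))
        p = np.clip(p, 1e-12, 1.0)
        if not np.array_equal(fdr_bh(p, 0.05), _bh_oracle(p, 0.05)):
            bh_bad += 1
        flags, _ = fdr_bky(p, 0.05)
        if not np.array_equal(flags, _bky_oracle(p, 0.05)):
            bky_bad += 1
    return {"bh_mismatches": bh_bad, "bky_mismatches": bky_bad}


def fdr_empirical(n_reps: int = 2000, m: int = 20, m_true: int = 5,
                  q: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Empirical FDR of BH and BKY under a mixture of null and strong
    alternative p-values."""
    rng = np.random.default_rng(seed)
    res = {}
    for name, proc in (("bh", lambda p: fdr_bh(p, q)),
                       ("bky", lambda p: fdr_bky(p, q)[0])):
        fdps = []
        for _ in range(n_reps):
            z = rng.standard_normal(m)
            z[:m_true] += 4.0
            from scipy.stats import norm

            p = np.clip(norm.sf(z), 1e-300, 1.0)
            flags = proc(p)
            r = flags.sum()
            fdps.append(flags[m_true:].sum() / r if r else 0.0)
        res[f"{name}_empirical_fdr"] = float(np.mean(fdps))
    return res


# ---------------------------------------------------------------------------
# histology recovery
# ---------------------------------------------------------------------------

PAPER_SCALE_PV_AU1 = {"Naive/Sham": 13, "6-h": 6, "7-days": 6,
                      "1-month": 7, "3-months": 6}


def histology_recovery(n_reps: int = 150, seed: int = 0) -> dict[str, float]:
    """Recovery of planted layer-5 density reductions at paper-scale n.

    Plants the 7-day and 1-month multipliers (0.7047, 0.5427) in Au1 layer 5
    and measures the mean recovered percent reduction, the detection rate
    of the planted layer, and layer specificity (the true-negative rate
    over the non-planted ROI x layer cells).
    """
    pcs_1m, pcs_7d = [], []
    detected = 0
    false_flags = 0
    n_null_cells = 0
    for rep in range(n_reps):
        spec = HistoSpec(
            rois=("Au1", "V1"), layers=("L2/3", "L4", "L5", "L6"),
            seed=seed * 30013 + rep,
            group_multipliers={("Au1", "L5", "7-days"): 0.7047,
                               ("Au1", "L5", "1-month"): 0.5427},
        )
        counts = generate_histology(spec, PAPER_SCALE_PV_AU1)
        res = LayerDensityAnalysis(counts).fit()
        ph = res.posthoc.set_index(["roi", "layer", "timepoint"])
        pcs_1m.append(ph.loc[("Au1", "L5", "1-month"), "percent_reduction"])
        pcs_7d.append(ph.loc[("Au1", "L5", "7-days"), "percent_reduction"])
        flagged = set(map(tuple, res.table.loc[res.table["q_flag"],
                                               ["roi", "layer"]].to_numpy()))
        detected += ("Au1", "L5") in flagged
        false_flags += len(flagged - {("Au1", "L5")})
        n_null_cells += len(res.table) - 1
    return {
        "percent_reduction_1month": float(np.mean(pcs_1m)),
        "percent_reduction_7days": float(np.mean(pcs_7d)),
        "layer5_detection_rate": detected / n_reps,
        "layer_specificity": 1.0 - false_flags / n_null_cells,
    }


def neun_subpopulation_change() -> float:
    """Expected total-density percent change from a 40% loss of a 5%
    subpopulation, through the noise-free generator and density chain."""
    spec = HistoSpec(rois=("Au1",), layers=("L5",), dispersion=None,
                     baseline_density=1000.0,
                     group_multipliers={("Au1", "L5", "1-month"): 1 - 0.4 * 0.05})
    counts = generate_histology(spec, {"Naive/Sham": 5, "1-month": 5})
    collapsed, _ = hemisphere_gate(compute_density(counts))
    means = collapsed.groupby("timepoint")["density"].mean()
    return float(100 * (1 - means["1-month"] / means["Naive/Sham"]))


# ---------------------------------------------------------------------------
# preprocessing metrics
# ---------------------------------------------------------------------------


def preprocessing_metrics(seed: int = 0) -> dict[str, float]:
    """Line-noise suppression, artifact excision quality, interpolation."""
    from scipy import signal as sps

    out = {}
    fs = 500.0
    spec = RecordingSpec(n_channels=4, sampling_rate=fs, duration=60.0,
                         line_noise_amplitude=5.0, n_harmonics=3,
                         artifact_rate=0.0, seed=seed)
    rec = generate_recording(spec)
    clean = remove_line_noise(rec, base=50.0, n_harmonics=3)

    def psd(x):
        f, p = sps.welch(x, fs=fs, nperseg=int(4 * fs))
        return f, p

    f, p_before = psd(rec.data[:, 0])
    _, p_after = psd(clean.data[:, 0])
    k50 = np.argmin(np.abs(f - 50.0))
    out["line_suppression_db"] = float(10 * np.log10(p_before[k50] / p_after[k50]))
    off = np.ones(f.size, bool)
    for target in (50.0, 100.0, 150.0):
        off &= np.abs(f - target) > 1.0
    out["off_target_power_change"] = float(
        abs(p_after[off].sum() / p_before[off].sum() - 1)
    )

    base = generate_recording(RecordingSpec(
        n_channels=4, sampling_rate=fs, duration=120.0,
        line_noise_amplitude=0.0, artifact_rate=0.0, seed=seed + 1))
    data = base.data.copy()
    rms = data.std()
    starts = (np.arange(10) * 11 + 3) * int(fs)
    for s in starts:
        data[s: s + int(fs)] += 20 * rms * np.hanning(int(fs))[:, None]
    dirty = MultichannelRecording(data, fs, base.ch_names, base.coords)
    segs = detect_artifact_segments(dirty, z_threshold=5.0, window_s=1.0)
    kept = np.zeros(dirty.n_samples, bool)
    for a, b in segs:
        kept[a:b] = True
    hit = sum((~kept[s: s + int(fs)]).any() for s in starts)
    out["artifact_sensitivity"] = hit / len(starts)
    clean_mask = np.ones(dirty.n_samples, bool)
    for s in starts:
        clean_mask[s: s + int(fs)] = False
    out["clean_data_loss"] = float((~kept & clean_mask).sum() / clean_mask.sum())

    coords = default_electrode_coords(32)
    field = 1.5 * coords[:, 2] + 0.8 * coords[:, 0] - 0.4 * coords[:, 1]
    t = np.linspace(0, 1, 200)
    data = np.outer(np.sin(2 * np.pi * 3 * t) + 2.0, field)
    rec = MultichannelRecording(data, 200.0,
                                [f"ch{i:02d}" for i in range(32)], coords)
    truth = rec.data[:, 5].copy()
    rec.data[:, 5] = 0.0
    fixed = interpolate_channels(rec, {"ch05"}, method="spherical")
    out["interp_rms_error"] = float(
        np.sqrt(np.mean((fixed.data[:, 5] - truth) ** 2))
        / np.sqrt(np.mean(truth**2))
    )
    return out
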