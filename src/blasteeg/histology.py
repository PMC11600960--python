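"""Cortical cell-density construction and the histology inference chain.

From per-slice cell counts and sampled areas, densities (cells/mm^2) are
computed per slice and averaged over the three slices per animal.  The
inference chain then follows standard practice for layer-resolved
immunohistochemistry cohorts:

1. hemisphere gate: a 2-way ANOVA (time post-injury x hemisphere with
   interaction); when hemisphere effects are non-significant the two
   hemispheres are averaged per animal;
2. one-way ANOVA with time post-injury as the factor, per ROI x layer,
   F(k-1, N-k) with analytic p;
3. the layer-wise p-values within a stain x ROI are corrected with the
   Benjamini-Krieger-Yekutieli two-stage linear step-up FDR at Q = 5 %;
4. significant omnibus tests are followed by pairwise post hoc comparisons
   of each time point against the Naive/Sham control (Fisher-LSD-style t on
   the pooled ANOVA mean-square error), with percent change relative to
   control;
5. immunofluorescence intensities (e.g. neurofilament light in the corpus
   callosum) are normalized to a reference region (periaqueductal grey)
   before entering the same ANOVA machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_density",
    "hemisphere_gate",
    "oneway_anova_time",
    "OneWayAnovaResult",
    "fdr_bky",
    "posthoc_vs_control",
    "percent_change",
    "normalize_intensity",
    "LayerDensityAnalysis",
    "LayerDensityResults",
    "CONTROL_GROUP",
]

CONTROL_GROUP = "Naive/Sham"


def compute_density(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-animal densities from a slice-level count table.

    Expects columns ``animal_id, timepoint, roi, layer, hemisphere, slice,
    count, area_mm2``.  Per-slice density = count / area; the per-animal
    value is the mean over slices, computed before any statistics.
    """
    required = {"animal_id", "timepoint", "roi", "layer", "hemisphere", "count", "area_mm2"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if counts["area_mm2"].isna().any() or (counts["area_mm2"] <= 0).any():
        raise ValueError("missing or non-positive sampled area")
    df = counts.copy()
    df["density"] = df["count"] / df["area_mm2"]
    keys = ["animal_id", "timepoint", "roi", "layer", "hemisphere"]
    return df.groupby(keys, as_index=False)["density"].mean()


def _two_way_f_p(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Type-III analytic p for factors a (k levels) and b (2 levels) + interaction."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "a": a, "b": b})
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    return {
        "factor_a": float(table.loc["C(a, Sum)", "PR(>F)"]),
        "factor_b": float(table.loc["C(b, Sum)", "PR(>F)"]),
        "interaction": float(table.loc["C(a, Sum):C(b, Sum)", "PR(>F)"]),
    }


def hemisphere_gate(
    density: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test hemisphere effects and collapse hemispheres where justified.

    Per ROI x layer, runs a 2-way ANOVA (time x hemisphere with
    interaction).  If both the hemisphere main effect and the interaction
    have p >= alpha, the hemispheres are averaged per animal; otherwise
    they are kept separate and the gate report says so.  Returns
    ``(collapsed_density, gate_report)``.
    """
    report_rows = []
    out_frames = []
    for (roi, layer), sub in density.groupby(["roi", "layer"]):
        hemis = sub["hemisphere"].unique()
        if len(hemis) < 2:
            collapsed = sub.groupby(
                ["animal_id", "timepoint", "roi", "layer"], as_index=False
            )["density"].mean()
            out_frames.append(collapsed)
            report_rows.append(
                {"roi": roi, "layer": layer, "p_hemisphere": np.nan,
                 "p_interaction": np.nan, "collapsed": True,
                 "note": "single hemisphere present"}
            )
            continue
        ps = _two_way_f_p(
            sub["density"].to_numpy(),
            sub["timepoint"].to_numpy(),
            sub["hemisphere"].to_numpy(),
        )
        collapse = ps["factor_b"] >= alpha and ps["interaction"] >= alpha
        if collapse:
            grp = sub.groupby(
                ["animal_id", "timepoint", "roi", "layer"], as_index=False
            )["density"].mean()
        else:
            grp = sub.copy()
        out_frames.append(grp)
        report_rows.append(
            {"roi": roi, "layer": layer, "p_hemisphere": ps["factor_b"],
             "p_interaction": ps["interaction"], "collapsed": collapse,
             "note": ""}
        )
    return pd.concat(out_frames, ignore_index=True), pd.DataFrame(report_rows)


@dataclass
class OneWayAnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    mse: float  # pooled within-group mean square, for LSD post hoc

    def __post_init__(self):
        k = len(self.group_means)
        n = sum(self.group_ns.values())
        if self.df1 != k - 1 or self.df2 != n - k:
            raise ValueError("inconsistent degrees of freedom")


def oneway_anova_time(
    density: pd.DataFrame, group_col: str = "timepoint", value_col: str = "density"
) -> OneWayAnovaResult:
    """Classical one-way ANOVA with time post-injury as the factor."""
    groups = {g: sub[value_col].to_numpy() for g, sub in density.groupby(group_col)}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(groups)
    n = sum(v.size for v in groups.values())
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return OneWayAnovaResult(
                0.0, df1, df2, 1.0,
                {g: float(v.mean()) for g, v in groups.items()},
                {g: int(v.size) for g, v in groups.items()}, 0.0,
            )
        raise ValueError("degenerate within-group variance")
    mse = ss_within / df2
    f = (ss_between / df1) / mse
    p = float(stats.f.sf(f, df1, df2))
    return OneWayAnovaResult(
        float(f), df1, df2, p,
        {g: float(v.mean()) for g, v in groups.items()},
        {g: int(v.size) for g, v in groups.items()},
        float(mse),
    )


def fdr_bky(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, dict]:
    """Benjamini-Krieger-Yekutieli two-stage linear step-up FDR.

    Stage 1: BH at Q' = Q / (1 + Q) giving r1 rejections.  If r1 = 0 stop
    (nothing rejected); if r1 = m stop (everything rejected).  Otherwise
    estimate m0_hat = m - r1 true nulls and rerun BH at level
    Q' * m / m0_hat.  Returns ``(flags, info)`` where info carries the
    stage parameters.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_flags(p, q1)
    r1 = int(stage1.sum())
    info = {"m": m, "q_prime": q1, "r1": r1}
    if r1 == 0:
        info["m0_hat"] = m
        return stage1, info
    if r1 == m:
        info["m0_hat"] = 0
        return stage1, info
    m0_hat = m - r1
    q2 = q1 * m / m0_hat
    info["m0_hat"] = m0_hat
    info["q_stage2"] = q2
    return _bh_flags(p, q2), info


def _bh_flags(p: np.ndarray, q: float) -> np.ndarray:
    """BH step-up: reject the k smallest p with p_(k) <= k q / m."""
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= thresh)
    flags = np.zeros(m, dtype=bool)
    if below.size:
        flags[order[: below[-1] + 1]] = True
    return flags


def posthoc_vs_control(
    result: OneWayAnovaResult, control: str = CONTROL_GROUP
) -> pd.DataFrame:
    """Fisher-LSD-style comparisons of each time point against control.

    t = (mean_c - mean_t) / sqrt(MSE (1/n_c + 1/n_t)) with the omnibus
    error df; analytic two-sided p.  Callers should gate interpretation on
    the FDR-corrected omnibus; results computed regardless are exploratory.
    """
    if control not in result.group_means:
        raise ValueError(f"control group {control!r} absent")
    mc = result.group_means[control]
    nc = result.group_ns[control]
    rows = []
    for g, mg in result.group_means.items():
        if g == control:
            continue
        ng = result.group_ns[g]
        se = np.sqrt(result.mse * (1.0 / nc + 1.0 / ng))
        t = (mc - mg) / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df=result.df2) if se > 0 else 1.0
        rows.append({"timepoint": g, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def percent_change(
    result: OneWayAnovaResult, control: str = CONTROL_GROUP
) -> pd.Series:
    """Percent reduction of each time point's mean relative to control.

    100 * (mean_control - mean_timepoint) / mean_control; positive values
    are reductions.
    """
    mc = result.group_means.get(control)
    if mc is None:
        raise ValueError(f"control group {control!r} absent")
    if mc == 0:
        raise ValueError("control mean is zero")
    out = {
        g: 100.0 * (mc - mg) / mc
        for g, mg in result.group_means.items()
        if g != control
    }
    return pd.Series(out, name="percent_reduction")


def normalize_intensity(intensities: pd.DataFrame) -> pd.DataFrame:
    """Normalize fluorescence intensity to the reference-region intensity.

    Expects columns ``animal_id, timepoint, intensity, reference``; the
    reference (periaqueductal grey, minimal-fluorescence internal control)
    must be positive.  Adds a ``ratio`` column; group comparison then uses
    the same one-way ANOVA machinery on the ratios.
    """
    if (intensities["reference"] <= 0).any():
        raise ValueError("reference intensity must be > 0")
    out = intensities.copy()
    out["ratio"] = out["intensity"] / out["reference"]
    return out


@dataclass
class LayerDensityResults:
    """Per ROI x layer omnibus, FDR flags, post hoc and percent changes."""

    table: pd.DataFrame  # roi, layer, F, df1, df2, p, q_flag
    posthoc: pd.DataFrame  # roi, layer, timepoint, t, p, percent_reduction
    gate_report: pd.DataFrame
    q: float
    fdr_info: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Layer density one-way ANOVAs, BKY two-stage FDR Q = {self.q:.0%}"]
        for _, r in self.table.iterrows():
            flag = "*" if r["q_flag"] else " "
            lines.append(
                f"{r['roi']:>4} {r['layer']:<5} F({r['df1']},{r['df2']}) = "
                f"{r['F']:.3f}, P = {r['p']:.4f} {flag}"
            )
        return "\n".join(lines)


class LayerDensityAnalysis:
    """Model: the full histology chain for one stain.

    Built from a slice-level count table; ``fit()`` runs density
    construction, the hemisphere gate, per-ROI x layer one-way ANOVAs with
    the BKY FDR family taken over layers within each ROI, post hoc
    comparisons against control and percent changes.
    """

    def __init__(self, counts: pd.DataFrame, control: str = CONTROL_GROUP):
        self.counts = counts
        self.control = control

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, control: str = CONTROL_GROUP):
        return cls(counts, control=control)

    def fit(self, q: float = 0.05, gate_alpha: float = 0.05) -> LayerDensityResults:
        density = compute_density(self.counts)
        collapsed, gate_report = hemisphere_gate(density, alpha=gate_alpha)
        rows = []
        posthoc_rows = []
        results: dict[tuple[str, str], OneWayAnovaResult] = {}
        for (roi, layer), sub in collapsed.groupby(["roi", "layer"]):
            res = oneway_anova_time(sub)
            results[(roi, layer)] = res
            rows.append(
                {"roi": roi, "layer": layer, "F": res.f, "df1": res.df1,
                 "df2": res.df2, "p": res.p}
            )
        table = pd.DataFrame(rows)
        # FDR family: layer-wise omnibus p within each ROI
        table["q_flag"] = False
        fdr_info = {}
        for roi, sub in table.groupby("roi"):
            flags, info = fdr_bky(sub["p"].to_numpy(), q=q)
            table.loc[sub.index, "q_flag"] = flags
            fdr_info[roi] = info
        for (roi, layer), res in results.items():
            ph = posthoc_vs_control(res, control=self.control)
            pc = percent_change(res, control=self.control)
            omni = bool(table.loc[(table.roi == roi) & (table.layer == layer), "q_flag"].iloc[0])
            for _, r in ph.iterrows():
                posthoc_rows.append(
                    {"roi": roi, "layer": layer, "timepoint": r["timepoint"],
                     "t": r["t"], "p": r["p"],
                     "percent_reduction": pc[r["timepoint"]],
                     "omnibus_significant": omni}
                )
        return LayerDensityResults(
            table=table,
            posthoc=pd.DataFrame(posthoc_rows),
            gate_report=gate_report,
            q=q,
            fdr_info=fdr_info,
        )
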