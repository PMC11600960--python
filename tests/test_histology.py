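"""Cell-density construction and the histology inference chain."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blasteeg.histology import (
    LayerDensityAnalysis,
    compute_density,
    fdr_bky,
    hemisphere_gate,
    normalize_intensity,
    oneway_anova_time,
    percent_change,
    posthoc_vs_control,
)
from blasteeg.synthetic import HistoSpec, generate_histology


def density_frame(group_values, seed=0, sd=1.0):
    """One ROI/layer density frame: {timepoint: (n, mean)}."""
    rng = np.random.default_rng(seed)
    rows = []
    for tp, (n, mu) in group_values.items():
        for i in range(n):
            rows.append({"animal_id": f"{tp}-{i}", "timepoint": tp,
                         "roi": "Au1", "layer": "L5",
                         "density": rng.normal(mu, sd)})
    return pd.DataFrame(rows)


def bky_oracle(p, q):
    """Exhaustive two-stage step-up, straight from its definition."""
    p = np.asarray(p)
    m = p.size
    qp = q / (1 + q)

    def bh(level):
        order = np.argsort(p, kind="stable")
        best = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * level / m:
                best = k
        flags = np.zeros(m, bool)
        flags[order[:best]] = True
        return flags

    s1 = bh(qp)
    r1 = s1.sum()
    if r1 == 0 or r1 == m:
        return s1
    return bh(qp * m / (m - r1))


class TestDensity:
    def test_count_over_area(self):
        counts = pd.DataFrame({
            "animal_id": ["a"], "timepoint": ["Naive/Sham"], "roi": ["Au1"],
            "layer": ["L5"], "hemisphere": ["left"], "slice": [1],
            "count": [100], "area_mm2": [0.5],
        })
        out = compute_density(counts)
        assert out["density"].iloc[0] == pytest.approx(200.0)

    def test_slice_average(self):
        counts = pd.DataFrame({
            "animal_id": ["a"] * 3, "timepoint": ["Naive/Sham"] * 3,
            "roi": ["Au1"] * 3, "layer": ["L5"] * 3, "hemisphere": ["left"] * 3,
            "slice": [1, 2, 3], "count": [100, 200, 300], "area_mm2": [1.0] * 3,
        })
        out = compute_density(counts)
        assert out["density"].iloc[0] == pytest.approx(200.0)

    def test_matches_per_slice_enumeration(self):
        spec = HistoSpec(rois=("Au1",), layers=("L5", "L6"), seed=3)
        counts = generate_histology(spec, {"Naive/Sham": 4, "6-h": 3})
        out = compute_density(counts).set_index(
            ["animal_id", "roi", "layer", "hemisphere"]
        )["density"]
        g = counts.groupby(["animal_id", "roi", "layer", "hemisphere"])
        for key, sub in g:
            brute = np.mean(sub["count"] / sub["area_mm2"])
            assert out[key] == pytest.approx(brute)

    def test_missing_area_rejected(self):
        counts = pd.DataFrame({
            "animal_id": ["a"], "timepoint": ["x"], "roi": ["Au1"],
            "layer": ["L5"], "hemisphere": ["left"], "slice": [1],
            "count": [10], "area_mm2": [np.nan],
        })
        with pytest.raises(ValueError, match="area"):
            compute_density(counts)

    def test_area_rescaling_leaves_statistics_invariant(self):
        """Rescaling all areas by c rescales densities by 1/c only."""
        spec = HistoSpec(rois=("Au1",), layers=("L5",), seed=4,
                         group_multipliers={("Au1", "L5", "1-month"): 0.6})
        counts = generate_histology(spec, {"Naive/Sham": 8, "1-month": 8})
        scaled = counts.assign(area_mm2=counts["area_mm2"] * 3.0)
        d1 = compute_density(counts)
        d2 = compute_density(scaled)
        r1 = oneway_anova_time(d1)
        r2 = oneway_anova_time(d2)
        assert r2.f == pytest.approx(r1.f)
        assert r2.p == pytest.approx(r1.p)
        pc1 = percent_change(r1)
        pc2 = percent_change(r2)
        assert pc2["1-month"] == pytest.approx(pc1["1-month"])


class TestHemisphereGate:
    def _two_hemi_frame(self, hemi_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for tp in ("Naive/Sham", "1-month"):
            for i in range(8):
                base = rng.normal(100, 5)
                for hemi, shift in (("left", 0.0), ("right", hemi_shift)):
                    rows.append({"animal_id": f"{tp}-{i}", "timepoint": tp,
                                 "roi": "Au1", "layer": "L5",
                                 "hemisphere": hemi,
                                 "density": base + shift + rng.normal(0, 2)})
        return pd.DataFrame(rows)

    def test_symmetric_data_collapsed(self):
        collapsed, report = hemisphere_gate(self._two_hemi_frame(0.0))
        assert report["collapsed"].all()
        assert "hemisphere" not in collapsed.columns

    def test_planted_hemisphere_effect_blocks_collapse(self):
        collapsed, report = hemisphere_gate(self._two_hemi_frame(30.0, seed=1))
        assert not report["collapsed"].any()
        assert "hemisphere" in collapsed.columns

    def test_identical_hemispheres_collapse_to_same_value(self):
        df = self._two_hemi_frame(0.0, seed=2)
        df["density"] = df.groupby("animal_id")["density"].transform("mean")
        collapsed, report = hemisphere_gate(df)
        assert report["collapsed"].all()
        merged = collapsed.merge(df.drop_duplicates("animal_id"), on="animal_id")
        assert np.allclose(merged["density_x"], merged["density_y"])


class TestOneWayAnova:
    def test_pv_au1_degrees_of_freedom(self):
        df = density_frame({"Naive/Sham": (13, 100), "6-h": (6, 100),
                            "7-days": (6, 100), "1-month": (7, 100),
                            "3-months": (6, 100)})
        res = oneway_anova_time(df)
        assert (res.df1, res.df2) == (4, 33)

    def test_sst_au1_degrees_of_freedom(self):
        df = density_frame({"Naive/Sham": (13, 100), "6-h": (6, 100),
                            "7-days": (6, 100), "1-month": (8, 100),
                            "3-months": (6, 100)})
        res = oneway_anova_time(df)
        assert (res.df1, res.df2) == (4, 34)

    def test_matches_scipy_f_oneway(self):
        df = density_frame({"a": (6, 10), "b": (8, 12), "c": (5, 9)}, seed=5)
        res = oneway_anova_time(df, group_col="timepoint")
        groups = [g["density"].to_numpy() for _, g in df.groupby("timepoint")]
        ref = stats.f_oneway(*groups)
        assert res.f == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_equal_groups_zero_noise(self):
        df = density_frame({"a": (4, 5), "b": (4, 5)}, sd=0.0)
        res = oneway_anova_time(df)
        assert res.f == 0.0 and res.p == 1.0

    def test_tiny_group_rejected(self):
        df = density_frame({"a": (1, 5), "b": (4, 5)})
        with pytest.raises(ValueError):
            oneway_anova_time(df)


class TestFdrBky:
    def test_all_ones_nothing_rejected(self):
        flags, info = fdr_bky(np.ones(10))
        assert not flags.any() and info["r1"] == 0

    def test_single_test_threshold(self):
        q = 0.05
        thresh = q / (1 + q)
        flags_lo, _ = fdr_bky(np.array([thresh * 0.99]), q)
        flags_hi, _ = fdr_bky(np.array([thresh * 1.01]), q)
        assert flags_lo.all() and not flags_hi.any()

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            m = rng.integers(1, 25)
            p = np.clip(np.concatenate([
                rng.uniform(size=m), rng.uniform(high=0.02, size=m),
            ])[:m], 1e-12, 1.0)
            flags, _ = fdr_bky(p, 0.05)
            assert np.array_equal(flags, bky_oracle(p, 0.05))

    def test_matches_statsmodels_tsbky(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(100):
            p = np.clip(rng.uniform(size=12) ** 2, 1e-12, 1.0)
            flags, _ = fdr_bky(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(flags, ref)


class TestPosthocPercent:
    def test_planted_reduction_flagged(self):
        df = density_frame({"Naive/Sham": (13, 100), "7-days": (6, 100),
                            "1-month": (7, 55), "3-months": (6, 100)},
                           seed=9, sd=8.0)
        res = oneway_anova_time(df)
        ph = posthoc_vs_control(res).set_index("timepoint")
        assert ph.loc["1-month", "p"] < 0.001
        assert ph.loc["7-days", "p"] > 0.05

    def test_percent_change_values(self):
        from blasteeg.histology import OneWayAnovaResult

        res = OneWayAnovaResult(
            f=3.0, df1=1, df2=8, p=0.1,
            group_means={"Naive/Sham": 10.0, "1-month": 5.0},
            group_ns={"Naive/Sham": 5, "1-month": 5}, mse=1.0,
        )
        assert percent_change(res)["1-month"] == pytest.approx(50.0)

    def test_missing_control_rejected(self):
        df = density_frame({"a": (4, 5), "b": (4, 6)})
        res = oneway_anova_time(df)
        with pytest.raises(ValueError, match="control"):
            percent_change(res, control="Naive/Sham")


class TestIntensity:
    def test_ratio(self):
        df = pd.DataFrame({"animal_id": ["a"], "timepoint": ["x"],
                           "intensity": [200.0], "reference": [100.0]})
        assert normalize_intensity(df)["ratio"].iloc[0] == pytest.approx(2.0)

    def test_uniform_scaling_invariant(self):
        df = pd.DataFrame({"animal_id": ["a", "b"], "timepoint": ["x", "x"],
                           "intensity": [200.0, 150.0], "reference": [100.0, 80.0]})
        r1 = normalize_intensity(df)["ratio"]
        df2 = df.assign(intensity=df["intensity"] * 3, reference=df["reference"] * 3)
        r2 = normalize_intensity(df2)["ratio"]
        assert np.allclose(r1, r2)

    def test_zero_reference_rejected(self):
        df = pd.DataFrame({"animal_id": ["a"], "timepoint": ["x"],
                           "intensity": [200.0], "reference": [0.0]})
        with pytest.raises(ValueError, match="reference"):
            normalize_intensity(df)


class TestFullChain:
    def test_planted_layer5_loss_detected_only_there(self):
        spec = HistoSpec(
            rois=("Au1", "V1"), layers=("L2/3", "L4", "L5", "L6"), seed=10,
            baseline_density=120.0,
            group_multipliers={("Au1", "L5", "7-days"): 0.7047,
                               ("Au1", "L5", "1-month"): 0.5427},
        )
        counts = generate_histology(
            spec, {"Naive/Sham": 13, "6-h": 6, "7-days": 6,
                   "1-month": 7, "3-months": 6})
        res = LayerDensityAnalysis(counts).fit()
        tab = res.table.set_index(["roi", "layer"])
        assert tab.loc[("Au1", "L5"), "q_flag"]
        assert not tab.drop(index=("Au1", "L5"))["q_flag"].any()
        ph = res.posthoc.set_index(["roi", "layer", "timepoint"])
        assert ph.loc[("Au1", "L5", "1-month"), "p"] < 0.01
        pc = ph.loc[("Au1", "L5", "1-month"), "percent_reduction"]
        assert pc == pytest.approx(45.73, abs=8)

    def test_neun_subpopulation_arithmetic(self):
        """40% loss of a 5% subpopulation shifts total density by ~2%."""
        spec = HistoSpec(rois=("Au1",), layers=("L5",), dispersion=None,
                         baseline_density=1000.0,
                         group_multipliers={("Au1", "L5", "1-month"): 1 - 0.4 * 0.05})
        counts = generate_histology(spec, {"Naive/Sham": 5, "1-month": 5})
        dens = compute_density(counts)
        collapsed, _ = hemisphere_gate(dens)
        means = collapsed.groupby("timepoint")["density"].mean()
        change = 100 * (1 - means["1-month"] / means["Naive/Sham"])
        assert change == pytest.approx(2.0, abs=1e-9)
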