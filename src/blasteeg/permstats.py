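"""Permutation inference for band- and channel-level group comparisons.

Implements the study's inferential toolkit: permutation paired t-tests
(sign-flip null), permutation two-way factorial ANOVA on the unbalanced
2x2 injury x time design (Type-III sums of squares, sum-to-zero coding,
Manly unrestricted permutation of outcomes), Welch's unequal-variance
t-test with Satterthwaite degrees of freedom, pairwise post hoc permutation
tests, and Bonferroni families over bands, channels or pairs.

All permutation p-values use the add-one rule p = (1 + #{null >= obs}) /
(1 + n_perm), so p is never exactly zero and the test is valid under the
null.  The factorial model follows the statsmodels Model -> fit() ->
Results convention; a results object carries observed statistics, null
distributions, p-values and a summary() table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationResult",
    "WelchTTestResult",
    "perm_paired_ttest",
    "welch_ttest",
    "TwoWayPermutationAnova",
    "TwoWayAnovaResults",
    "perm_two_way_anova",
    "perm_welch_ttest",
    "pairwise_posthoc",
    "channelwise_test",
    "bonferroni",
]


def bonferroni(p: float, family_size: int) -> float:
    return min(1.0, p * family_size)


@dataclass
class PermutationResult:
    observed_stat: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    family_size: int = 1
    effect: str = ""

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must be in (0, 1]")

    @property
    def p_adjusted(self) -> float:
        return bonferroni(self.p_value, self.family_size)


def _add_one_p(null_abs: np.ndarray, obs_abs: float) -> float:
    return (1 + int(np.sum(null_abs >= obs_abs))) / (1 + null_abs.size)


def perm_paired_ttest(
    pre: Sequence[float],
    post: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
    family_size: int = 1,
) -> PermutationResult:
    """Two-sided permutation paired t-test via random sign flips.

    The null exchanges each animal's pre/post labels independently, i.e.
    flips the sign of the paired difference.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("pre and post must be equal-length vectors, n >= 2")
    d = post - pre
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance paired differences; p = 1")
        return PermutationResult(0.0, np.zeros(n_perm), 1.0, n_perm, seed,
                                 family_size, "paired")
    t_obs = d.mean() / (sd / np.sqrt(n))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    x = signs * d
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(s > 0, m / (s / np.sqrt(n)), 0.0)
    p = _add_one_p(np.abs(t_null), abs(t_obs))
    return PermutationResult(float(t_obs), t_null, p, n_perm, seed, family_size, "paired")


@dataclass
class WelchTTestResult:
    t: float
    nu: float  # Satterthwaite degrees of freedom
    p: float  # analytic, two-sided
    n1: int
    n2: int

    def __post_init__(self):
        lo = min(self.n1, self.n2) - 1
        hi = self.n1 + self.n2 - 2
        if not (lo - 1e-9 <= self.nu <= hi + 1e-9):
            raise ValueError("Satterthwaite df outside valid range")


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> WelchTTestResult:
    """Unequal-variance two-sample t-test with Satterthwaite df.

    nu = (s1^2/n1 + s2^2/n2)^2 /
         [(s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1)]
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both groups")
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    nu = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df=nu)
    return WelchTTestResult(float(t), float(nu), float(p), n1, n2)


# ---------------------------------------------------------------------------
# factorial permutation ANOVA (Model -> fit -> Results)
# ---------------------------------------------------------------------------


def _effect_design(a_labels: np.ndarray, b_labels: np.ndarray) -> dict[str, np.ndarray]:
    """Sum-to-zero (effect-coded) design matrices for a 2x2 with interaction."""
    a_levels = np.unique(a_labels)
    b_levels = np.unique(b_labels)
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("factors must each have exactly two levels")
    a = np.where(a_labels == a_levels[0], 1.0, -1.0)
    b = np.where(b_labels == b_levels[0], 1.0, -1.0)
    ones = np.ones_like(a)
    full = np.column_stack([ones, a, b, a * b])
    return {
        "full": full,
        "group": np.column_stack([ones, b, a * b]),  # drop main effect A
        "time": np.column_stack([ones, a, a * b]),
        "interaction": np.column_stack([ones, a, b]),
    }


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


@dataclass
class TwoWayAnovaResults:
    """Results of a permutation two-way ANOVA; statsmodels-style container."""

    effects: dict[str, PermutationResult]
    f_observed: dict[str, float]
    df_effect: int
    df_error: int
    n: int
    n_perm: int
    seed: int
    family_size: int = 1

    def p_values(self) -> dict[str, float]:
        return {k: r.p_value for k, r in self.effects.items()}

    def p_adjusted(self) -> dict[str, float]:
        return {k: r.p_adjusted for k, r in self.effects.items()}

    def summary(self) -> str:
        lines = [
            "Permutation two-way ANOVA (Type-III SS, Manly permutation)",
            f"N = {self.n}, error df = {self.df_error}, "
            f"n_perm = {self.n_perm}, seed = {self.seed}",
            f"{'effect':<14}{'F':>10}{'df':>10}{'p':>10}{'p_adj':>10}",
        ]
        for name, res in self.effects.items():
            lines.append(
                f"{name:<14}{res.observed_stat:>10.4f}"
                f"{f'({self.df_effect},{self.df_error})':>10}"
                f"{res.p_value:>10.4f}{res.p_adjusted:>10.4f}"
            )
        return "\n".join(lines)


class TwoWayPermutationAnova:
    """Permutation 2x2 factorial ANOVA model (group x time, interaction).

    Observed F statistics use Type-III sums of squares with sum-to-zero
    coding, matching the F(1, N-4) convention of mainstream packages for
    unbalanced designs.  The null permutes outcome values across all
    animals (Manly's unrestricted scheme), recomputing all three F's per
    permutation.
    """

    def __init__(self, y: Sequence[float], group: Sequence, time: Sequence):
        self.y = np.asarray(y, dtype=float)
        self.group = np.asarray(group)
        self.time = np.asarray(time)
        if not (self.y.shape == self.group.shape == self.time.shape):
            raise ValueError("y, group, time must have equal length")
        cells = pd.crosstab(self.group, self.time)
        if cells.shape != (2, 2) or (cells.values == 0).any():
            raise ValueError("need a complete 2x2 design with non-empty cells")
        self.designs = _effect_design(self.group, self.time)
        self.n = self.y.size
        self.df_error = self.n - 4

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dv: str, group: str = "injury", time: str = "time"
    ) -> "TwoWayPermutationAnova":
        return cls(df[dv].to_numpy(), df[group].to_numpy(), df[time].to_numpy())

    def _f_stats(self, Y: np.ndarray, hats: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Type-III F for each effect; Y is (n_perm_or_1, N)."""
        yy = np.sum(Y * Y, axis=1)
        fitted = {k: np.sum(Y * (Y @ H), axis=1) for k, H in hats.items()}
        rss_full = yy - fitted["full"]
        mse = rss_full / self.df_error
        out = {}
        for eff in ("group", "time", "interaction"):
            ss = fitted["full"] - fitted[eff]
            with np.errstate(divide="ignore", invalid="ignore"):
                out[eff] = np.where(mse > 0, ss / mse, 0.0)
        return out

    def fit(
        self, n_perm: int = 10000, seed: int = 0, family_size: int = 1
    ) -> TwoWayAnovaResults:
        hats = {k: _hat(X) for k, X in self.designs.items()}
        obs = {k: float(v[0]) for k, v in self._f_stats(self.y[None, :], hats).items()}
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(self.n) for _ in range(n_perm)])
        nulls = self._f_stats(self.y[perms], hats)
        effects = {}
        for eff in ("group", "time", "interaction"):
            p = _add_one_p(nulls[eff], obs[eff])
            effects[eff] = PermutationResult(
                obs[eff], nulls[eff], p, n_perm, seed, family_size, eff
            )
        return TwoWayAnovaResults(
            effects=effects,
            f_observed=obs,
            df_effect=1,
            df_error=self.df_error,
            n=self.n,
            n_perm=n_perm,
            seed=seed,
            family_size=family_size,
        )


def perm_two_way_anova(
    design: pd.DataFrame,
    dv: str = "value",
    n_perm: int = 10000,
    seed: int = 0,
    family_size: int = 1,
) -> TwoWayAnovaResults:
    """Functional wrapper: columns ``injury``, ``time`` and the outcome."""
    return TwoWayPermutationAnova.from_dataframe(design, dv).fit(
        n_perm=n_perm, seed=seed, family_size=family_size
    )


def perm_welch_ttest(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
    family_size: int = 1,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Two-sample Welch t with a label-permutation null."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("need n >= 2 per group")
    obs = welch_ttest(a, b).t
    pooled = np.concatenate([a, b])
    n1 = a.size
    rng = np.random.default_rng(seed)
    t_null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        pa, pb = perm[:n1], perm[n1:]
        v1, v2 = pa.var(ddof=1), pb.var(ddof=1)
        se2 = v1 / n1 + v2 / (pooled.size - n1)
        t_null[i] = (pa.mean() - pb.mean()) / np.sqrt(se2) if se2 > 0 else 0.0
    if alternative == "two-sided":
        p = _add_one_p(np.abs(t_null), abs(obs))
    elif alternative == "greater":
        p = _add_one_p(t_null, obs)
    elif alternative == "less":
        p = _add_one_p(-t_null, -obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationResult(float(obs), t_null, p, n_perm, seed, family_size, "welch")


def pairwise_posthoc(
    design: pd.DataFrame,
    pairs: Sequence[tuple],
    dv: str = "value",
    cell_cols: tuple[str, str] = ("injury", "time"),
    n_perm: int = 10000,
    seed: int = 0,
) -> dict[tuple, PermutationResult]:
    """Pairwise permutation Welch t-tests between named design cells.

    Bonferroni family = the declared set of pairs (e.g. the 3 comparisons
    of interest after a significant interaction).
    """
    family = len(pairs)
    out = {}
    for i, (cell_a, cell_b) in enumerate(pairs):
        mask_a = np.ones(len(design), dtype=bool)
        mask_b = np.ones(len(design), dtype=bool)
        for col, va, vb in zip(cell_cols, cell_a, cell_b):
            mask_a &= design[col].to_numpy() == va
            mask_b &= design[col].to_numpy() == vb
        a = design.loc[mask_a, dv].to_numpy()
        b = design.loc[mask_b, dv].to_numpy()
        if min(a.size, b.size) < 2:
            raise ValueError(f"pair {cell_a} vs {cell_b} has a group with n < 2")
        out[(cell_a, cell_b)] = perm_welch_ttest(
            a, b, n_perm=n_perm, seed=seed + i, family_size=family
        )
    return out


def channelwise_test(
    per_channel: Mapping[str, tuple],
    test: Callable[..., PermutationResult],
    family: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply a permutation test per channel with a Bonferroni family.

    ``per_channel`` maps channel name to the positional arguments of
    ``test``; ``family`` defaults to the number of channels (e.g. 32).
    Returns a frame with the per-channel statistic, raw and adjusted p, and
    the significance flag at ``alpha`` on the adjusted p.
    """
    if family is None:
        family = len(per_channel)
    rows = []
    for ch, args in per_channel.items():
        res = test(*args)
        p_adj = bonferroni(res.p_value, family)
        rows.append(
            {
                "channel": ch,
                "stat": res.observed_stat,
                "p": res.p_value,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)
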