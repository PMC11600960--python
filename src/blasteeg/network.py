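"""Edge-level network statistics on connectivity matrices.

After pooling the two post-injury time points within each injury group,
every unordered electrode pair (496 edges for 32 channels) is tested with a
one-sided (blast > sham) Welch t statistic against a label-permutation null
that uses the *same* permutations for every edge, preserving the dependence
structure between edges under the null.  Edge-level p-values are then
controlled with Benjamini-Hochberg FDR, and the surviving edges form the
significant (hyperconnected) network.

Exposed both as functions and as the :class:`EdgewiseNetworkTest` model
whose ``fit()`` returns a results object with per-edge statistics and a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pool_groups",
    "edgewise_perm_ttest",
    "fdr_bh",
    "extract_network",
    "EdgewiseNetworkTest",
    "EdgewiseNetworkResults",
]


def pool_groups(design: pd.DataFrame, group_col: str = "injury") -> pd.DataFrame:
    """Collapse the time factor, leaving a two-group (blast vs sham) design.

    With the chronic cohort sizes 13/20/8/9 this yields blast n = 33 vs
    sham n = 17 and a two-sample df of N - 2 = 49.
    """
    out = design.copy()
    out["pooled_group"] = out[group_col]
    return out


def _welch_t_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized Welch t over columns of two (animals x edges) blocks."""
    n1, n2 = A.shape[0], B.shape[0]
    m1, m2 = A.mean(axis=0), B.mean(axis=0)
    v1, v2 = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (m1 - m2) / np.sqrt(se2), 0.0)
    return t


def edgewise_perm_ttest(
    values: np.ndarray,
    is_blast: np.ndarray,
    n_perm: int = 50000,
    seed: int = 0,
    one_sided: bool = True,
) -> pd.DataFrame:
    """Per-edge Welch t with a shared label-permutation null.

    ``values`` is (animals x edges) dwPLI; ``is_blast`` the boolean group
    label.  The same permutations are applied to every edge.  One-sided
    p-values (blast > sham) by the add-one rule.  Edges constant across all
    animals get p = 1 with t = 0.
    """
    values = np.asarray(values, dtype=float)
    is_blast = np.asarray(is_blast, dtype=bool)
    if values.ndim != 2 or values.shape[0] != is_blast.size:
        raise ValueError("values must be (animals x edges) matching labels")
    n1 = int(is_blast.sum())
    n2 = int((~is_blast).sum())
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 animals per group")
    order = np.concatenate([np.flatnonzero(is_blast), np.flatnonzero(~is_blast)])
    V = values[order]  # blast block first
    t_obs = _welch_t_matrix(V[:n1], V[n1:])

    rng = np.random.default_rng(seed)
    n_animals = V.shape[0]
    exceed = np.zeros(values.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_animals)
        t_null = _welch_t_matrix(V[perm[:n1]], V[perm[n1:]])
        if one_sided:
            exceed += t_null >= t_obs
        else:
            exceed += np.abs(t_null) >= np.abs(t_obs)
    p = (1 + exceed) / (1 + n_perm)

    constant = values.std(axis=0) == 0
    t_obs = np.where(constant, 0.0, t_obs)
    p = np.where(constant, 1.0, p)
    return pd.DataFrame({"t": t_obs, "p": p})


def fdr_bh(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def extract_network(
    edge_stats: pd.DataFrame,
    pairs: np.ndarray,
    ch_names: list[str],
    coords: np.ndarray | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Edges surviving FDR, as a tidy edge list with node coordinates.

    ``edge_stats`` must carry columns ``t`` and ``p`` aligned with
    ``pairs`` (n_edges x 2 channel indices).
    """
    flags = fdr_bh(edge_stats["p"].to_numpy(), q=q)
    rows = []
    for (a, b), t, p, sig in zip(
        pairs, edge_stats["t"], edge_stats["p"], flags
    ):
        if not sig:
            continue
        row = {
            "chan_a": ch_names[a],
            "chan_b": ch_names[b],
            "t": float(t),
            "p": float(p),
        }
        if coords is not None:
            row.update(
                xa=coords[a][0], ya=coords[a][1], za=coords[a][2],
                xb=coords[b][0], yb=coords[b][1], zb=coords[b][2],
            )
        rows.append(row)
    cols = ["chan_a", "chan_b", "t", "p"] + (
        ["xa", "ya", "za", "xb", "yb", "zb"] if coords is not None else []
    )
    return pd.DataFrame(rows, columns=cols)


@dataclass
class EdgewiseNetworkResults:
    edge_stats: pd.DataFrame  # t, p per edge
    pairs: np.ndarray
    ch_names: list[str]
    band: str
    q: float
    n_perm: int
    seed: int
    n_blast: int
    n_sham: int
    significant: pd.DataFrame = None  # set in __post_init__

    def __post_init__(self):
        self.significant = extract_network(
            self.edge_stats, self.pairs, self.ch_names, q=self.q
        )

    @property
    def df(self) -> int:
        """Two-sample degrees of freedom after pooling time points."""
        return self.n_blast + self.n_sham - 2

    def summary(self) -> str:
        return (
            f"Edge-wise one-sided permutation t-test (blast > sham), "
            f"band = {self.band}\n"
            f"n = {self.n_blast} blast vs {self.n_sham} sham "
            f"(t df = {self.df}), {len(self.pairs)} edges, "
            f"n_perm = {self.n_perm}, seed = {self.seed}\n"
            f"BH FDR q = {self.q}: {len(self.significant)} significant edges"
        )


class EdgewiseNetworkTest:
    """Model: per-edge group contrast of dwPLI with FDR-controlled output.

    ``values`` is (animals x edges); ``is_blast`` boolean labels after
    pooling time points; ``pairs`` the (n_edges x 2) channel index pairs.
    """

    def __init__(
        self,
        values: np.ndarray,
        is_blast: np.ndarray,
        pairs: np.ndarray,
        ch_names: list[str],
        band: str = "gamma",
    ):
        self.values = np.asarray(values, dtype=float)
        self.is_blast = np.asarray(is_blast, dtype=bool)
        self.pairs = np.asarray(pairs)
        self.ch_names = list(ch_names)
        self.band = band

    def fit(
        self, n_perm: int = 50000, seed: int = 0, q: float = 0.05,
        one_sided: bool = True,
    ) -> EdgewiseNetworkResults:
        stats = edgewise_perm_ttest(
            self.values, self.is_blast, n_perm=n_perm, seed=seed,
            one_sided=one_sided,
        )
        return EdgewiseNetworkResults(
            edge_stats=stats,
            pairs=self.pairs,
            ch_names=self.ch_names,
            band=self.band,
            q=q,
            n_perm=n_perm,
            seed=seed,
            n_blast=int(self.is_blast.sum()),
            n_sham=int((~self.is_blast).sum()),
        )
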