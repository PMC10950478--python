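"""Differential APA usage (APA marker) detection between cell groups.

For an ordered group pair (X, Y) every gene with enough covered cells in
both groups is tested with a two-sided Wilcoxon rank-sum test on the
per-cell RUD values.  P-values come from the exact null distribution of
the rank-sum statistic (dynamic-programming enumeration) when both groups
have <= EXACT_MAX_N cells and the pooled values are tie-free; otherwise
from the normal approximation with tie correction and continuity
correction.  Benjamini-Hochberg adjustment is applied within each pairwise
comparison.  Positive markers have significantly higher RUD in X than Y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ParameterError, UnknownIdError
from .metrics import RUDMatrix

EXACT_MAX_N = 25

MARKER_COLUMNS = ["gene_id", "group_x", "group_y", "delta_rud", "p_value",
                  "q_value", "direction", "n_x", "n_y"]


@dataclass
class MarkerTable:
    """Per-gene differential-APA results for one ordered group pair."""

    table: pd.DataFrame  # MARKER_COLUMNS, markers only (q <= alpha, |delta| >= min_delta)
    tested: pd.DataFrame  # same columns, all tested genes
    params: dict

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


# ---------------------------------------------------------------------------
# exact rank-sum null distribution
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _ranksum_counts(m: int, n: int) -> np.ndarray:
    """Number of m-subsets of ranks 1..m+n per rank-sum value.

    ``counts[w]`` is the number of ways to choose m of the m+n ranks with
    sum ``w + m(m+1)/2`` (i.e. indexed by the Mann-Whitney U statistic).
    Standard recurrence: c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u).
    """
    # dp[j][u]: ways to pick j ranks from the first i with U statistic u
    max_u = m * n
    dp = np.zeros((m + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, m + n + 1):
        for j in range(min(i, m), 0, -1):
            # taking rank i as the j-th chosen element adds (i - j) to U
            add = i - j
            if add > max_u:
                continue
            dp[j, add:] += dp[j - 1, : max_u + 1 - add]
    return dp[m]


def exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value for tie-free samples.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1, under the
    exact permutation null of the Mann-Whitney U statistic of ``x``.
    """
    m, n = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    counts = _ranksum_counts(m, n)
    total = counts.sum()
    u = int(round(u_obs))
    lower = counts[: u + 1].sum() / total
    upper = counts[u:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # degenerate: identical constant distributions
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(len(x), len(y)) <= EXACT_MAX_N:
        return exact_ranksum_pvalue(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# marker detection
# ---------------------------------------------------------------------------

def _group_values(rud: RUDMatrix, groups: pd.Series, label: str) -> pd.DataFrame:
    groups = groups.astype(str)
    if label not in set(groups):
        raise UnknownIdError(f"unknown group label '{label}'")
    obs = groups.index[groups == label]
    obs = [o for o in obs if o in rud.obs_index]
    return rud.values[obs]


def get_apa_markers(rud: RUDMatrix, groups: pd.Series, group_x: str, group_y: str,
                    min_cells: int = 10, alpha: float = 0.05,
                    min_delta: float = 0.1) -> MarkerTable:
    """Detect genes with differential RUD between ``group_x`` and ``group_y``.

    ``groups`` maps obs_id -> group label (e.g. ``pac.obs_meta["group"]``).
    Cells with missing RUD for a gene are excluded from that gene's test.
    Markers satisfy ``q_value <= alpha`` and ``|delta_rud| >= min_delta``;
    direction is positive iff mean RUD is higher in ``group_x``.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    if min_cells < 1:
        raise ParameterError("min_cells must be a positive integer")
    vx = _group_values(rud, groups, group_x)
    vy = _group_values(rud, groups, group_y)

    rows = []
    for gene in rud.gene_index:
        x = vx.loc[gene].dropna().to_numpy(dtype=float)
        y = vy.loc[gene].dropna().to_numpy(dtype=float)
        if len(x) < min_cells or len(y) < min_cells:
            continue
        delta = float(x.mean() - y.mean())
        p = _ranksum_pvalue(x, y)
        rows.append((gene, group_x, group_y, delta, p,
                     np.nan, "positive" if delta > 0 else "negative",
                     len(x), len(y)))
    tested = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if len(tested) == 0:
        warnings.warn(f"no testable gene for {group_x}~{group_y} "
                      f"(min_cells={min_cells})")
    else:
        tested["q_value"] = multipletests(tested["p_value"], method="fdr_bh")[1]
    keep = tested[(tested["q_value"] <= alpha)
                  & (tested["delta_rud"].abs() >= min_delta)].reset_index(drop=True)
    params = dict(group_x=group_x, group_y=group_y, min_cells=min_cells,
                  alpha=alpha, min_delta=min_delta)
    return MarkerTable(table=keep, tested=tested, params=params)


def count_markers_pairwise(rud: RUDMatrix, groups: pd.Series,
                           group_order: list[str] | None = None,
                           min_cells: int = 10, alpha: float = 0.05,
                           min_delta: float = 0.1) -> pd.DataFrame:
    """Marker counts for every unordered group pair (reported once, X~Y).

    Pairs follow ``group_order`` (default: first-appearance order of
    ``groups``); within a pair X precedes Y in that order.
    """
    if group_order is None:
        group_order = list(pd.unique(groups.astype(str)))
    if len(group_order) < 2:
        raise ParameterError("need at least two groups for pairwise marker counts")
    rows = []
    for gx, gy in combinations(group_order, 2):
        mt = get_apa_markers(rud, groups, gx, gy, min_cells=min_cells,
                             alpha=alpha, min_delta=min_delta)
        n_pos = int((mt.table["direction"] == "positive").sum())
        n_neg = int((mt.table["direction"] == "negative").sum())
        rows.append((gx, gy, n_pos, n_neg))
    return pd.DataFrame(rows, columns=["group_x", "group_y", "n_positive", "n_negative"])
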