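"""Small-sample statistics for the wet-lab validation assays.

Exact Wilcoxon rank-sum for tiny reporter-assay groups (full enumeration of
rank assignments when the combined sample is small and tie-free), the
2^(-ddCt) relative-quantification method for qPCR, and Fisher's least
significant difference with compact letter display for multi-group
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class WilcoxonResult:
    W: float  # rank sum of the first sample
    p: float
    exact: bool


def exact_wilcoxon(x, y) -> WilcoxonResult:
    """Two-sided two-sample Wilcoxon rank-sum test.

    Midranks for ties. When n_x + n_y <= 12 and there are no ties, the
    two-sided p comes from full enumeration of rank assignments:
    p = min(1, 2 * min(P(W <= w), P(W >= w))). Otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    n, m = x.size, y.size
    N = n + m
    ranks = stats.rankdata(combined)
    w = float(ranks[:n].sum())
    has_ties = np.unique(combined).size < N

    if N <= 12 and not has_ties:
        dist = _ranksum_distribution(n, N)
        total = comb(N, n)
        lower = sum(c for s, c in dist.items() if s <= w) / total
        upper = sum(c for s, c in dist.items() if s >= w) / total
        return WilcoxonResult(w, min(1.0, 2.0 * min(lower, upper)), exact=True)

    mean_w = n * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var_w = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_w <= 0:
        return WilcoxonResult(w, 1.0, exact=False)
    z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
    return WilcoxonResult(w, float(2.0 * stats.norm.sf(abs(z))), exact=False)


def _ranksum_distribution(n: int, N: int) -> dict[int, int]:
    """Counts of each possible rank sum for n ranks drawn from 1..N."""
    dist: dict[int, int] = {}
    for subset in combinations(range(1, N + 1), n):
        s = sum(subset)
        dist[s] = dist.get(s, 0) + 1
    return dist


# ---------------------------------------------------------------------------
# ddCt relative quantification


def ddct_fold_change(ct_table: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Relative expression by the 2^(-ddCt) method.

    ``ct_table`` needs columns ``treatment``, ``ct_target``, ``ct_reference``
    (one row per sample). dCt = Ct_target - Ct_reference; ddCt subtracts the
    calibrator-group mean dCt; relative expression = 2^(-ddCt). The
    calibrator group's mean relative expression is 1 by construction only on
    the dCt scale; its geometric mean is exactly 1.
    """
    required = {"treatment", "ct_target", "ct_reference"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(required)}")
    missing = ct_table[["ct_target", "ct_reference"]].isna().any(axis=1)
    if missing.any():
        raise ValueError(f"missing Ct for samples: {list(ct_table.index[missing])}")
    if calibrator_group not in set(ct_table["treatment"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    out = ct_table.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    cal_mean = out.loc[out["treatment"] == calibrator_group, "dct"].mean()
    out["ddct"] = out["dct"] - cal_mean
    out["rel_expr"] = np.exp2(-out["ddct"])
    return out


def ddct_group_summary(ddct: pd.DataFrame) -> pd.DataFrame:
    """Group means +/- SE of relative expression."""
    g = ddct.groupby("treatment")["rel_expr"]
    return pd.DataFrame(
        {"mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.count()), "n": g.count()}
    )


# ---------------------------------------------------------------------------
# Fisher's LSD with compact letter display


@dataclass
class LsdGrouping:
    means: pd.Series
    mse: float
    df: int
    pairwise_p: pd.DataFrame
    letters: dict[str, str]


def fisher_lsd(values_by_group: dict[str, list[float]], alpha: float = 0.05) -> LsdGrouping:
    """Unprotected Fisher's LSD pairwise tests with letter groupings.

    Pooled one-way-ANOVA MSE; pairwise t with the ANOVA residual df;
    letters via insert-and-absorb so that groups sharing a letter are not
    significantly different. Letter columns are ordered by descending group
    mean.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    n_total = sum(a.size for a in arrays.values())
    df_resid = n_total - len(groups)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    mse = sum(a.var(ddof=1) * (a.size - 1) for a in arrays.values()) / df_resid
    means = pd.Series({g: a.mean() for g, a in arrays.items()})

    pw = pd.DataFrame(1.0, index=groups, columns=groups)
    for g1, g2 in combinations(groups, 2):
        a1, a2 = arrays[g1], arrays[g2]
        se = np.sqrt(mse * (1.0 / a1.size + 1.0 / a2.size))
        t = abs(means[g1] - means[g2]) / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(t, df_resid))
        pw.loc[g1, g2] = pw.loc[g2, g1] = p

    letters = _letter_display(means, pw, alpha)
    return LsdGrouping(means.sort_values(ascending=False), float(mse), df_resid, pw, letters)


def _letter_display(
    means: pd.Series, pairwise_p: pd.DataFrame, alpha: float
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one column holding all groups; for each significant pair
    split every column containing both; absorb columns that become subsets.
    """
    ordered = list(means.sort_values(ascending=False).index)
    columns: list[set[str]] = [set(ordered)]
    sig_pairs = [
        (g1, g2)
        for g1, g2 in combinations(ordered, 2)
        if pairwise_p.loc[g1, g2] < alpha
    ]
    for g1, g2 in sig_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [
            c
            for i, c in enumerate(new_columns)
            if c and not any(i != j and c < other or (c == other and i > j)
                             for j, other in enumerate(new_columns))
        ]
    # order columns by the best (highest) mean they contain
    columns.sort(key=lambda c: min(ordered.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in ordered}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}
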