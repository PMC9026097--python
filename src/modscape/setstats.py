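"""Directional gene-set statistics and resampling nulls.

Given a per-gene fold-change table and a directional signature (e.g. genes
up-regulated by NRF2 activation), these operations quantify concordance:
the up/down split of expressed signature members against the detectable
background (Fisher's exact test, with an exact binomial-vs-50% variant),
a signed cumulative-overlap area statistic over the FC-ranked gene list
(rank-sum p), plain hypergeometric annotation enrichment, aggregation of
disease-gene sources into evidence tiers, a random-gene-set |log2FC| null,
FC-vector correlations across studies, and top-k overlap tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import SignatureSet


@dataclass
class DirectionTestResult:
    signature: str
    n_expressed: int
    n_up: int
    n_down: int
    n_zero: int
    frac_up: float
    frac_down: float
    odds_ratio: float
    fisher_p: float
    binom_p: float


@dataclass
class AreaStatResult:
    signature: str
    area: float
    wilcoxon_p: float
    n_members: int


def _detectable(de: pd.DataFrame) -> pd.DataFrame:
    if "detected" in de:
        return de.loc[de["detected"].astype(bool)]
    return de


def direction_fisher(de: pd.DataFrame, sig: SignatureSet) -> DirectionTestResult:
    """Up/down concordance of expressed signature members vs the background.

    2x2 table {signature, background} x {log2fc > 0, log2fc < 0} with exact
    zeros dropped (but counted); two-sided Fisher's exact test. An exact
    binomial test of the member up-fraction against 0.5 is reported
    alongside, since the published test's exact table is ambiguous.
    """
    det = _detectable(de)
    members = det.index.intersection(pd.Index(sig.members))
    if len(members) == 0:
        raise ValueError(f"signature {sig.name!r} has no expressed members")
    fc = det["log2fc"]
    in_sig = det.index.isin(set(members))
    up = fc.to_numpy() > 0
    down = fc.to_numpy() < 0
    a = int((in_sig & up).sum())
    b = int((in_sig & down).sum())
    c = int((~in_sig & up).sum())
    d = int((~in_sig & down).sum())
    n_zero = int(len(members) - a - b)
    if a + b == 0:
        raise ValueError(f"all expressed members of {sig.name!r} have log2fc == 0")
    odds, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    binom_p = stats.binomtest(a, a + b, 0.5).pvalue
    return DirectionTestResult(
        signature=sig.name,
        n_expressed=int(len(members)),
        n_up=a,
        n_down=b,
        n_zero=n_zero,
        frac_up=a / (a + b),
        frac_down=b / (a + b),
        odds_ratio=float(odds) if np.isfinite(odds) else float("inf"),
        fisher_p=float(fisher_p),
        binom_p=float(binom_p),
    )


def cumulative_overlap_area(de: pd.DataFrame, sig: SignatureSet) -> AreaStatResult:
    """Signed cumulative-overlap area over the FC-ranked gene list.

    All detectable genes are ranked by log2FC descending (gene-ID
    tie-break); the running curve C(k) = (members among top k)/m - k/N is
    averaged over k. Positive area means members concentrate among
    increased genes. The p-value is a two-sided rank-sum test of member
    log2FCs vs non-members.
    """
    det = _detectable(de)
    members = set(det.index.intersection(pd.Index(sig.members)))
    m = len(members)
    n = len(det)
    if m == 0:
        raise ValueError(f"signature {sig.name!r} has no expressed members")
    if m == n:
        raise ValueError("signature equals the detectable universe; area undefined")
    ranked = det.assign(_gene=det.index).sort_values(
        ["log2fc", "_gene"], ascending=[False, True], kind="mergesort"
    )
    hits = np.fromiter((g in members for g in ranked.index), dtype=float, count=n)
    running = np.cumsum(hits) / m - np.arange(1, n + 1) / n
    area = float(running.mean())
    member_fc = det.loc[det.index.isin(members), "log2fc"].to_numpy()
    other_fc = det.loc[~det.index.isin(members), "log2fc"].to_numpy()
    p = float(stats.mannwhitneyu(member_fc, other_fc, alternative="two-sided").pvalue)
    return AreaStatResult(sig.name, area, p, m)


def annotation_enrichment(
    deg_set: list[str],
    universe: list[str],
    term_to_genes: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of annotation terms in a DEG set.

    Terms with zero overlap are skipped; BH adjustment across tested terms.
    """
    uni = set(universe)
    degs = set(deg_set)
    if not degs <= uni:
        raise ValueError("deg_set must be a subset of the universe")
    n_uni, n_deg = len(uni), len(degs)
    rows = []
    for term, genes in term_to_genes.items():
        in_uni = uni.intersection(genes)
        if not in_uni:
            warnings.warn(f"term {term!r} disjoint from the universe; skipped")
            continue
        overlap = degs.intersection(in_uni)
        if not overlap:
            continue
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(in_uni), n_deg))
        rows.append(
            {
                "term": term,
                "term_size": len(in_uni),
                "overlap": k,
                "p": p,
                "example_genes": ",".join(sorted(overlap)[:5]),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("term")
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p")
    return out


def aggregate_disease_sources(source_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Union disease-gene table with per-gene source membership and tier.

    Tier = number of sources claiming the gene. Filter with
    ``table[table.tier >= 4]`` etc.
    """
    if not source_sets:
        raise ValueError("need at least one source")
    all_genes = sorted(set().union(*source_sets.values()))
    data = {s: [g in members for g in all_genes] for s, members in source_sets.items()}
    table = pd.DataFrame(data, index=pd.Index(all_genes, name="gene"))
    table["tier"] = table.sum(axis=1).astype(int)
    return table


def random_set_fc_null(
    de: pd.DataFrame,
    target_genes: list[str],
    n_trials: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Mean |log2FC| of a target set against equal-size random draws.

    Each trial samples, without replacement, ``len(target)`` detectable
    genes; the empirical p is (1 + #{trial mean >= observed})/(n_trials+1).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    det = _detectable(de)
    target = det.index.intersection(pd.Index(target_genes))
    k = len(target)
    if k == 0:
        raise ValueError("target set has no detectable genes")
    abs_fc = det["log2fc"].abs().to_numpy()
    observed = float(det.loc[target, "log2fc"].abs().mean())
    rng = np.random.default_rng(seed)
    n = len(det)
    null = np.empty(n_trials)
    # chunked vectorized sampling without replacement via random-key argpartition
    chunk = max(1, min(n_trials, int(5e7 // max(n, 1))))
    done = 0
    while done < n_trials:
        b = min(chunk, n_trials - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[done : done + b] = abs_fc[idx].mean(axis=1)
        done += b
    p = (1.0 + float((null >= observed).sum())) / (n_trials + 1.0)
    return observed, null, p


def fc_vector_correlation(
    deA: pd.DataFrame, deB: pd.DataFrame, method: str = "pearson"
) -> dict[str, float]:
    """Correlation of two log2FC vectors over shared detectable genes.

    Also reports quadrant fractions (up/up, up/down, down/up, down/down)
    for directional-overabundance summaries.
    """
    detA, detB = _detectable(deA), _detectable(deB)
    shared = detA.index.intersection(detB.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared detectable genes")
    x = detA.loc[shared, "log2fc"].to_numpy()
    y = detB.loc[shared, "log2fc"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) fold-change vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    n = len(shared)
    return {
        "r": float(r),
        "p": float(p),
        "n": n,
        "frac_up_up": float(((x > 0) & (y > 0)).sum() / n),
        "frac_up_down": float(((x > 0) & (y < 0)).sum() / n),
        "frac_down_up": float(((x < 0) & (y > 0)).sum() / n),
        "frac_down_down": float(((x < 0) & (y < 0)).sum() / n),
    }


def top_k_overlap(
    deA: pd.DataFrame,
    deB: pd.DataFrame,
    k: int = 100,
    direction: str = "up",
) -> dict[str, float]:
    """One-sided Fisher test of top-k gene overlap between two rankings.

    Top-k by signed log2FC (descending for ``up``, ascending for ``down``)
    over the shared universe.
    """
    detA, detB = _detectable(deA), _detectable(deB)
    shared = detA.index.intersection(detB.index)
    n = len(shared)
    if n < 2 * k:
        raise ValueError(f"shared universe ({n}) smaller than 2k ({2 * k})")
    ascending = direction == "down"
    topA = set(
        detA.loc[shared, "log2fc"].sort_values(ascending=ascending, kind="mergesort").index[:k]
    )
    topB = set(
        detB.loc[shared, "log2fc"].sort_values(ascending=ascending, kind="mergesort").index[:k]
    )
    ov = len(topA & topB)
    table = [[ov, k - ov], [k - ov, n - 2 * k + ov]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return {"overlap": ov, "k": k, "n": n, "p": float(p)}
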