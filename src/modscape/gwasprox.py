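"""Proximity statistics between DEG lists and GWAS loci.

Distance is gene-body to locus: 0 when the locus falls inside the gene's
interval, otherwise base pairs to the nearer interval edge; genes with no
same-chromosome locus get infinite distance (excluded from means, but
counted). The window-overlap scan tests, per distance window, whether the
top-ranked DEGs are over-represented among near-locus genes (one-sided
Fisher), and the mean-distance null resamples equal-size random gene sets
to score how much closer the top DEGs sit to loci than expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BedInterval


@dataclass
class LocusMap:
    """Gene intervals plus GWAS locus points."""

    genes: dict[str, BedInterval]
    loci: list[BedInterval]

    @classmethod
    def from_bed(cls, gene_records: list[BedInterval], locus_records: list[BedInterval]) -> "LocusMap":
        return cls({g.name: g for g in gene_records}, list(locus_records))

    def locus_positions(self) -> dict[str, np.ndarray]:
        by_chrom: dict[str, list[int]] = {}
        for locus in self.loci:
            by_chrom.setdefault(locus.chrom, []).append(locus.start)
        return {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}


@dataclass
class ProximityParams:
    top_n: int = 30
    windows: tuple[int, ...] = (0, 10_000, 50_000, 100_000, 500_000, 1_000_000)
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if any(b <= a for a, b in zip(self.windows, self.windows[1:])):
            raise ValueError("windows must be strictly increasing")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def nearest_locus_distance(locus_map: LocusMap, gene: str) -> float:
    """Distance in bp from a gene's body to the nearest same-chromosome locus."""
    if gene not in locus_map.genes:
        raise KeyError(f"unknown gene {gene!r}")
    if not locus_map.loci:
        raise ValueError("locus map contains no loci")
    return _distances(locus_map, [gene])[0]


def _distances(locus_map: LocusMap, genes: list[str]) -> np.ndarray:
    """Vector of nearest-locus distances; inf where no same-chromosome locus."""
    positions = locus_map.locus_positions()
    out = np.empty(len(genes))
    for i, name in enumerate(genes):
        g = locus_map.genes[name]
        pos = positions.get(g.chrom)
        if pos is None or pos.size == 0:
            out[i] = np.inf
            continue
        inside = (pos >= g.start) & (pos < g.end)
        if inside.any():
            out[i] = 0.0
        else:
            d = np.minimum(np.abs(pos - g.start), np.abs(pos - (g.end - 1)))
            out[i] = float(d.min())
    return out


def window_overlap_scan(
    deg_top: list[str],
    universe: list[str],
    locus_map: LocusMap,
    params: ProximityParams | None = None,
) -> pd.DataFrame:
    """Per-window overlap between top DEGs and genes near loci.

    For each window d: near-set = genes with nearest-locus distance <= d;
    one-sided Fisher's exact test on (top DEG vs rest) x (near vs not).
    The background column reports the near fraction among non-top genes.
    """
    params = params or ProximityParams()
    top = set(deg_top)
    if not top <= set(universe):
        raise ValueError("deg_top must be a subset of the universe")
    dist = _distances(locus_map, list(universe))
    is_top = np.array([g in top for g in universe])
    rows = []
    for w in params.windows:
        near = dist <= w
        a = int((is_top & near).sum())
        b = int((is_top & ~near).sum())
        c = int((~is_top & near).sum())
        d = int((~is_top & ~near).sum())
        if a + c == 0:
            p = 1.0
        else:
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "window": w,
                "top_near": a,
                "top_total": a + b,
                "frac_top_near": a / max(a + b, 1),
                "frac_background_near": c / max(c + d, 1),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("window")


def mean_distance_null(
    deg_top: list[str],
    universe: list[str],
    locus_map: LocusMap,
    params: ProximityParams | None = None,
) -> dict:
    """Observed mean nearest-locus distance vs random same-size gene sets.

    Infinite-distance genes are excluded from each mean (their count is
    reported). Empirical p is lower-tail with the add-one estimator:
    (1 + #{trial mean <= observed})/(n_trials + 1).
    """
    params = params or ProximityParams()
    if len(universe) < len(deg_top):
        raise ValueError("universe smaller than the top gene list")
    dist_all = _distances(locus_map, list(universe))
    index = {g: i for i, g in enumerate(universe)}
    try:
        top_idx = np.array([index[g] for g in deg_top])
    except KeyError as exc:
        raise ValueError(f"top gene {exc} not in universe") from None
    top_d = dist_all[top_idx]
    finite = np.isfinite(top_d)
    if not finite.any():
        raise ValueError("no top gene has a finite nearest-locus distance")
    observed = float(top_d[finite].mean())

    rng = np.random.default_rng(params.seed)
    k = len(deg_top)
    n = len(universe)
    null = np.empty(params.n_trials)
    chunk = max(1, min(params.n_trials, int(5e7 // max(n, 1))))
    done = 0
    while done < params.n_trials:
        b = min(chunk, params.n_trials - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        draws = dist_all[idx]
        with np.errstate(invalid="ignore"):
            masked = np.where(np.isfinite(draws), draws, np.nan)
            null[done : done + b] = np.nanmean(masked, axis=1)
        done += b
    p = (1.0 + float((null <= observed).sum())) / (params.n_trials + 1.0)
    return {
        "observed_mean": observed,
        "n_finite": int(finite.sum()),
        "n_infinite": int((~finite).sum()),
        "null": null,
        "p": p,
        "marginal": p < 0.10,
    }
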