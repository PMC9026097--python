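"""Probe collapse, gene filters, and sample-level outlier screening.

These steps precede differential expression: probes are collapsed to one
per gene (highest mean expression), genes must be detectable (above the
per-array 20th percentile in enough samples of a comparison), variable
(across-sample SD at or above the 5th percentile of all gene SDs), and not
driven by a single designated outlier sample (|z| > 2.50 while being the
strict extremum). Sample-level screening uses PCA plus a two-sided Grubbs
(maximum normalized residual) test on PC1 scores, and average-linkage
hierarchical clustering of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .io import ExpressionMatrix


@dataclass
class FilterParams:
    detect_percentile: float = 20.0
    min_detect_samples: int = 2
    sd_percentile_floor: float = 5.0
    outlier_z: float = 2.50
    outlier_sample: str | None = None

    def __post_init__(self) -> None:
        for pct in (self.detect_percentile, self.sd_percentile_floor):
            if not 0.0 < pct < 100.0:
                raise ValueError("percentiles must lie in (0,100)")
        if self.outlier_z <= 0:
            raise ValueError("outlier_z must be positive")
        if self.min_detect_samples < 1:
            raise ValueError("min_detect_samples must be >= 1")


@dataclass
class FilterReport:
    """Per-gene flags and the counts they imply.

    ``retained`` is detected AND variable AND NOT outlier-excluded.
    """

    detected: pd.Series
    variable: pd.Series
    outlier_excluded: pd.Series
    collapse_ties: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def retained(self) -> pd.Series:
        return self.detected & self.variable & ~self.outlier_excluded

    def counts(self) -> dict[str, int]:
        return {
            "n_genes": int(len(self.detected)),
            "n_detected": int(self.detected.sum()),
            "n_variable": int(self.variable.sum()),
            "n_outlier_excluded": int(self.outlier_excluded.sum()),
            "n_retained": int(self.retained.sum()),
        }


def collapse_probes(
    probe_matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> tuple[ExpressionMatrix, list[tuple[str, str, str]]]:
    """Keep, per gene, the single probe with the highest mean expression.

    Ties in mean are broken toward the lexicographically smaller probe ID;
    tied pairs are returned for the report. Probes with no gene mapping are
    dropped.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    df = probe_matrix.data
    means = df.mean(axis=1)
    best: dict[str, str] = {}
    ties: list[tuple[str, str, str]] = []
    for probe in sorted(df.index):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        cur = best.get(gene)
        if cur is None or means[probe] > means[cur]:
            best[gene] = probe
        elif means[probe] == means[cur]:
            ties.append((gene, cur, probe))  # cur < probe lexicographically
    genes = sorted(best)
    out = df.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(out, probe_matrix.groups), ties


def detection_filter(
    matrix: ExpressionMatrix,
    comparison_samples: Sequence[str],
    params: FilterParams | None = None,
) -> pd.Series:
    """Flag genes detectable in a two-group comparison.

    A gene is detected on an array when its value is strictly above that
    array's own ``detect_percentile`` quantile (computed over all genes,
    linear-interpolation quantile); detection requires at least
    ``min_detect_samples`` such arrays among the comparison's samples.
    """
    params = params or FilterParams()
    missing = set(comparison_samples) - set(matrix.samples)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)}")
    if len(comparison_samples) < params.min_detect_samples:
        raise ValueError("fewer comparison samples than min_detect_samples")
    sub = matrix.data.loc[:, list(comparison_samples)]
    thresholds = sub.quantile(params.detect_percentile / 100.0, axis=0)
    above = sub.gt(thresholds, axis=1)
    return above.sum(axis=1) >= params.min_detect_samples


def variability_filter(
    matrix: ExpressionMatrix, params: FilterParams | None = None
) -> pd.Series:
    """Flag genes whose across-sample SD is at or above the percentile floor."""
    params = params or FilterParams()
    if matrix.data.shape[1] < 2:
        raise ValueError("variability filter needs at least 2 samples")
    sds = matrix.data.std(axis=1, ddof=1)
    floor = np.quantile(sds.to_numpy(), params.sd_percentile_floor / 100.0)
    return sds >= floor


def outlier_gene_filter(
    matrix: ExpressionMatrix, params: FilterParams | None = None
) -> pd.Series:
    """Flag genes driven by the designated outlier sample.

    Excluded iff the designated sample's z-score (against the gene's
    across-sample mean/SD) exceeds ``outlier_z`` in absolute value AND that
    sample is the strict minimum or maximum for the gene. With no sample
    designated this is a no-op (all False) with a warning.
    """
    params = params or FilterParams()
    df = matrix.data
    if params.outlier_sample is None:
        warnings.warn("no outlier sample designated; outlier filter is a no-op")
        return pd.Series(False, index=df.index)
    if params.outlier_sample not in df.columns:
        raise ValueError(f"outlier sample {params.outlier_sample!r} not in matrix")
    vals = df[params.outlier_sample]
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean) / sd
    others = df.drop(columns=[params.outlier_sample])
    strict_max = vals > others.max(axis=1)
    strict_min = vals < others.min(axis=1)
    return (z.abs() > params.outlier_z) & (strict_max | strict_min)


def grubbs_test(values: np.ndarray) -> tuple[int, float, float]:
    """Two-sided Grubbs (maximum normalized residual) test.

    Returns (index of the most extreme value, G statistic, p-value) using
    the t-based closed form: with t^2 = n (n-2) G^2 / ((n-1)^2 - n G^2),
    p = min(1, 2 n P(T_{n-2} > t)).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return 0, 0.0, 1.0
    resid = np.abs(x - mean)
    idx = int(np.argmax(resid))
    g = resid[idx] / sd
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        return idx, float(g), 0.0
    t = np.sqrt(n * (n - 2) * g * g / denom)
    p = min(1.0, 2 * n * stats.t.sf(t, n - 2))
    return idx, float(g), float(p)


def sample_pca_outlier_test(
    matrix: ExpressionMatrix,
) -> tuple[pd.DataFrame, str, float, float]:
    """PCA on the gene-standardized matrix + Grubbs test on PC1 scores.

    Samples are the observations. Returns (PC score table with PC1/PC2
    columns, most extreme sample, G statistic, p).
    """
    df = matrix.data
    if df.shape[1] < 3:
        raise ValueError("PCA outlier test needs at least 3 samples")
    scores = _pca_scores(df)
    idx, g, p = grubbs_test(scores["PC1"].to_numpy())
    return scores, str(scores.index[idx]), g, p


def _pca_scores(df: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PC scores of samples; genes standardized to mean 0, SD 1 first."""
    vals = df.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    x = z.T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=df.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )


def cluster_samples(matrix: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage Euclidean dendrogram of samples.

    Returns (scipy linkage matrix, sample labels in input order).
    """
    df = matrix.data
    if df.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    z = linkage(df.to_numpy().T, method="average", metric="euclidean")
    return z, list(df.columns)


def filter_report(
    matrix: ExpressionMatrix,
    comparison_samples: Sequence[str],
    params: FilterParams | None = None,
) -> FilterReport:
    """Run the three gene filters for one two-group comparison."""
    params = params or FilterParams()
    detected = detection_filter(matrix, comparison_samples, params)
    variable = variability_filter(matrix, params)
    if params.outlier_sample is not None:
        excluded = outlier_gene_filter(matrix, params)
    else:
        excluded = pd.Series(False, index=matrix.data.index)
    return FilterReport(detected, variable, excluded)
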