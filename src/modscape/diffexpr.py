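"""Two-group differential expression with empirical-Bayes moderated t.

Per gene, the treatment effect is the difference of group means on the log2
scale. Residual variances are shrunk toward a scaled inverse-chi-square
prior whose hyperparameters (d0, s0^2) are estimated by moment matching on
log variances (the standard empirical-Bayes approach for microarray linear
models); the moderated t then has d + d0 degrees of freedom. Raw p-values
are adjusted with Benjamini-Hochberg, and DEGs are called with strict
p/fold-change thresholds (lenient: p < 0.05, FC > 1.25 or FC < 0.80;
stringent: FDR < 0.10 with the same FC gates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .io import ExpressionMatrix

D0_CAP = 1e6  # treat prior df above this as infinite


@dataclass
class EBayesParams:
    """Hyperparameters of the inverse-chi-square variance prior."""

    d0: float
    s0_sq: float
    residual_df: int

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df must be nonnegative")
        if self.s0_sq <= 0 and self.d0 > 0:
            raise ValueError("prior variance must be positive")


@dataclass
class DEGCriteria:
    p_max: float = 0.05
    fc_up: float = 1.25
    fc_down: float = 0.80
    stringent_fdr: float = 0.10

    def __post_init__(self) -> None:
        if not self.fc_up > 1 > self.fc_down > 0:
            raise ValueError("need fc_up > 1 > fc_down > 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton's method."""
    if x <= 0:
        raise ValueError("trigamma inverse needs positive input")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the sample variances on the log scale.

    Uses e_g = log s2_g - digamma(d/2) + log(d/2), whose mean and excess
    variance over trigamma(d/2) identify the prior; d0 is capped at
    ``D0_CAP`` (effectively infinite) when the excess variance is
    nonpositive.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; prior unidentifiable")
    z = np.log(s2[pos])
    e = z - digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if evar <= 0:
        # no excess dispersion: variances look constant; use their mean
        return D0_CAP, float(s2[pos].mean())
    half_d0 = _trigamma_inverse(evar)
    d0 = min(2.0 * half_d0, D0_CAP)
    s0_sq = math.exp(emean + digamma(half_d0) - math.log(half_d0))
    return d0, s0_sq


def fit_moderated_t(
    matrix: ExpressionMatrix,
    group_a_samples: list[str],
    group_b_samples: list[str],
    prior: EBayesParams | None = None,
) -> tuple[pd.DataFrame, EBayesParams]:
    """Moderated-t differential expression of group a (treatment) vs b (control).

    Returns a per-gene table (log2fc, fc, t, p, fdr, mean_expr, detected)
    and the estimated (or supplied) prior. log2fc = mean(a) - mean(b).
    """
    na, nb = len(group_a_samples), len(group_b_samples)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per group")
    df = matrix.data
    a = df.loc[:, group_a_samples].to_numpy(dtype=float)
    b = df.loc[:, group_b_samples].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    d = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / d

    if prior is None:
        d0, s0_sq = estimate_prior(s2, d)
        prior = EBayesParams(d0, s0_sq, d)
    d0, s0_sq = prior.d0, prior.s0_sq

    if d0 >= D0_CAP:
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
            "mean_expr": np.concatenate([a, b], axis=1).mean(axis=1),
            "detected": True,
        },
        index=df.index,
    )
    return out, prior


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with enforced monotonicity."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_degs(
    de: pd.DataFrame, criteria: DEGCriteria | None = None, mode: str = "lenient"
) -> tuple[list[str], list[str]]:
    """Call (up, down) DEG lists with strict threshold inequalities."""
    criteria = criteria or DEGCriteria()
    if mode == "lenient":
        sig = de["p"] < criteria.p_max
    elif mode == "stringent":
        sig = de["fdr"] < criteria.stringent_fdr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if "detected" in de:
        sig &= de["detected"].astype(bool)
    up = de.index[sig & (de["fc"] > criteria.fc_up)]
    down = de.index[sig & (de["fc"] < criteria.fc_down)]
    return list(up), list(down)


def max_abs_fc(de_list: list[pd.DataFrame]) -> pd.Series:
    """Per-gene max |log2FC| across comparisons (for ranking display genes)."""
    if not de_list:
        raise ValueError("need at least one DE table")
    index = de_list[0].index
    for de in de_list[1:]:
        if not de.index.equals(index):
            raise ValueError("DE tables cover different gene universes")
    stacked = np.column_stack([de["log2fc"].abs().to_numpy() for de in de_list])
    return pd.Series(stacked.max(axis=1), index=index, name="max_abs_log2fc")


def pc_treatment_vectors(
    matrix: ExpressionMatrix, control: str = "CTL"
) -> dict[str, dict[str, np.ndarray | float]]:
    """Treatment-effect arrows in PC1/PC2 space.

    Each arrow runs from the control-group centroid to a treatment-group
    centroid of sample PC scores (PCA on the gene-standardized matrix);
    longer arrows indicate a stronger treatment effect.
    """
    from .preprocess import _pca_scores

    if matrix.groups is None:
        raise ValueError("matrix has no group labels")
    scores = _pca_scores(matrix.data, n_components=2)
    groups = sorted(set(matrix.groups.values()))
    if control not in groups:
        raise ValueError(f"control group {control!r} absent")
    centroids = {
        g: scores.loc[matrix.samples_in_group(g)].mean(axis=0).to_numpy()
        for g in groups
    }
    origin = centroids[control]
    arrows: dict[str, dict[str, np.ndarray | float]] = {}
    for g in groups:
        if g == control:
            continue
        tip = centroids[g]
        arrows[g] = {
            "origin": origin,
            "tip": tip,
            "length": float(np.linalg.norm(tip - origin)),
        }
    return arrows


def fc_scatter_stats(
    deA: pd.DataFrame, deB: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation of log2FC vectors over shared detectable genes."""
    shared = deA.index.intersection(deB.index)
    if "detected" in deA and "detected" in deB:
        det = deA.loc[shared, "detected"].astype(bool) & deB.loc[
            shared, "detected"
        ].astype(bool)
        shared = shared[det.to_numpy()]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared detectable genes")
    r, p = stats.spearmanr(
        deA.loc[shared, "log2fc"].to_numpy(), deB.loc[shared, "log2fc"].to_numpy()
    )
    return float(r), float(p)


def write_de_tsv(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene", float_format="%.15g")


def read_de_tsv(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", index_col="gene", comment="#")
    if "detected" in de:
        de["detected"] = de["detected"].astype(bool)
    return de
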