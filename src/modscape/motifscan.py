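"""PWM scanning of upstream sequences and motif enrichment among DEGs.

Promoters (5 kb upstream regions) are scanned on both strands with
log-odds position weight matrices; per-gene hit counts (or max scores)
then enter a semiparametric logistic model

    logit P(gene is DEG) = beta * motif_feature + s(GC) [+ s(length)]

where s() is an unpenalized cubic B-spline with 4 interior knots at
covariate quintiles — the spline absorbs sequence-composition confounding
so that beta isolates the motif effect. Significance is a likelihood-ratio
test of beta = 0, BH-adjusted across the PWM collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

from .diffexpr import bh_adjust
from .io import PWMRecord

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PWM:
    """Log-odds position weight matrix over {A,C,G,T}.

    Probabilities get a pseudocount then are renormalized; N in a sequence
    contributes log-odds 0 (background).
    """

    id: str
    matrix: np.ndarray  # positions x 4 probabilities
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        probs = self.matrix + self.pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1 after pseudocount")
        # 5th column: N scores as background (log-odds 0)
        lo = np.log2(probs / self.background)
        self.log_odds = np.column_stack([lo, np.zeros(self.width)])

    @classmethod
    def from_record(cls, rec: PWMRecord, **kwargs) -> "PWM":
        return cls(rec.id, rec.matrix, **kwargs)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.matrix, axis=1))


@dataclass
class ScanResult:
    max_score: float
    hits: list[tuple[int, str, float]]  # (0-based forward position, strand, score)

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq.upper()), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN character {exc}") from None


_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def _window_scores(encoded: np.ndarray, pwm: PWM) -> np.ndarray:
    w = pwm.width
    n_pos = len(encoded) - w + 1
    scores = np.zeros(n_pos)
    for i in range(w):
        scores += pwm.log_odds[i, encoded[i : i + n_pos]]
    return scores


def pwm_scan(
    sequence: str | np.ndarray, pwm: PWM, threshold_fraction: float = 0.8
) -> ScanResult:
    """Scan both strands; hits are windows scoring above a fraction of the max.

    Hit positions are 0-based starts on the forward strand (a reverse-strand
    hit is reported at the forward coordinate of its leftmost base).
    Sequences shorter than the PWM width give max score -inf and no hits.
    """
    encoded = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    w = pwm.width
    if len(encoded) < w:
        return ScanResult(float("-inf"), [])
    threshold = threshold_fraction * pwm.max_score
    fwd = _window_scores(encoded, pwm)
    rc = _COMPLEMENT[encoded][::-1]
    rev = _window_scores(rc, pwm)
    L = len(encoded)
    hits: list[tuple[int, str, float]] = []
    for j in np.nonzero(fwd > threshold)[0]:
        hits.append((int(j), "+", float(fwd[j])))
    for j in np.nonzero(rev > threshold)[0]:
        hits.append((int(L - w - j), "-", float(rev[j])))
    hits.sort()
    max_score = float(max(fwd.max(), rev.max()))
    return ScanResult(max_score, hits)


def motif_features(
    promoters: dict[str, str],
    pwm: PWM,
    mode: str = "count",
    threshold_fraction: float = 0.8,
) -> pd.Series:
    """Per-gene motif feature: hit count (default) or max log-odds score."""
    if mode not in ("count", "score"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for gene, seq in promoters.items():
        res = pwm_scan(seq, pwm, threshold_fraction)
        out[gene] = res.n_hits if mode == "count" else res.max_score
    return pd.Series(out, name=pwm.id, dtype=float)


# ---------------------------------------------------------------------------
# Semiparametric logistic enrichment


def _bspline_basis(x: np.ndarray, n_interior: int = 4, degree: int = 3) -> np.ndarray:
    """Unpenalized cubic B-spline basis, interior knots at quantiles.

    The basis spans constants (partition of unity), so designs built from it
    need no separate intercept.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.ones((x.size, 1))
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs)
    interior = interior[(interior > lo) & (interior < hi)]
    t = np.concatenate([[lo] * (degree + 1), np.unique(interior), [hi] * (degree + 1)])
    return BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()


def _ridge_logit_loglik(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Ridge-penalized logistic IRLS; returns (coefficients, unpenalized loglik)."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X + alpha * np.eye(X.shape[1]), XtW @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll


def gam_motif_enrichment(
    deg_flags: pd.Series,
    motif_feature: pd.Series,
    covariates: pd.DataFrame,
    pwm_id: str | None = None,
) -> dict:
    """Spline-adjusted logistic test of motif association with DEG status.

    ``covariates`` must have a ``gc_fraction`` column and may have a
    ``length`` column (splined only if it varies). Returns beta, the LRT p
    for beta = 0, the effect direction, and a separation flag (separated
    fits are re-estimated with a small ridge penalty).
    """
    name = pwm_id or (motif_feature.name or "motif")
    genes = deg_flags.index.intersection(motif_feature.index).intersection(covariates.index)
    y = deg_flags.loc[genes].astype(float).to_numpy()
    if (y == 1).sum() < 20 or (y == 0).sum() < 20:
        raise ValueError("need at least 20 genes per class")
    feat = motif_feature.loc[genes].to_numpy(dtype=float)
    if np.all(feat == feat[0]):
        raise ValueError(f"constant motif feature for PWM {name!r}; beta inestimable")

    basis = _bspline_basis(covariates.loc[genes, "gc_fraction"].to_numpy())
    blocks = [basis]
    if "length" in covariates:
        length = covariates.loc[genes, "length"].to_numpy(dtype=float)
        if np.unique(length).size > 1:
            blocks.append(_bspline_basis(length)[:, 1:])  # drop one col: constants already spanned
    X0 = np.column_stack(blocks)
    X1 = np.column_stack([feat, X0])

    separated = False
    try:
        with np.errstate(all="ignore"):
            fit1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit(maxiter=200)
            fit0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit(maxiter=200)
        beta = float(fit1.params[0])
        lrt = fit0.deviance - fit1.deviance
        if not np.isfinite(lrt) or abs(beta) > 15:
            separated = True
    except Exception:
        separated = True
    if separated:
        b1, ll1 = _ridge_logit_loglik(X1, y, alpha=1e-4)
        _, ll0 = _ridge_logit_loglik(X0, y, alpha=1e-4)
        beta = float(b1[0])
        lrt = 2.0 * (ll1 - ll0)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return {
        "pwm": name,
        "beta": beta,
        "p": p,
        "direction": "enriched" if beta > 0 else "depleted",
        "separated": separated,
    }


def motif_enrichment_table(
    deg_flags: pd.Series,
    features_by_pwm: dict[str, pd.Series],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Run the spline-logistic test per PWM and BH-adjust across PWMs."""
    rows = []
    for pwm_id, feature in features_by_pwm.items():
        rows.append(gam_motif_enrichment(deg_flags, feature, covariates, pwm_id))
    out = pd.DataFrame(rows).set_index("pwm")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


def sequence_covariates(promoters: dict[str, str]) -> pd.DataFrame:
    gc = {
        g: (s.count("G") + s.count("C")) / max(len(s), 1) for g, s in promoters.items()
    }
    length = {g: len(s) for g, s in promoters.items()}
    return pd.DataFrame({"gc_fraction": pd.Series(gc), "length": pd.Series(length)})


def irf_profile(
    deg_sets: dict[str, list[str]],
    irf_pwms: list[PWM],
    promoters: dict[str, str],
    fdr_threshold: float = 0.05,
    bin_size: int = 250,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """IRF-family motif enrichment per DEG set, plus positional histograms.

    Returns a long-format enrichment table (one row per DEG set x PWM) and,
    for each (DEG set, PWM) pair significant at the FDR threshold, a
    histogram of hit positions in that set's promoters (bins of
    ``bin_size`` bp).
    """
    covariates = sequence_covariates(promoters)
    universe = list(promoters)
    encoded = {g: encode_sequence(s) for g, s in promoters.items()}
    features: dict[str, pd.Series] = {}
    hit_positions: dict[str, dict[str, list[int]]] = {}
    for pwm in irf_pwms:
        counts = {}
        positions: dict[str, list[int]] = {}
        for gene in universe:
            res = pwm_scan(encoded[gene], pwm)
            counts[gene] = res.n_hits
            positions[gene] = [pos for pos, _, _ in res.hits]
        features[pwm.id] = pd.Series(counts, dtype=float)
        hit_positions[pwm.id] = positions

    tables = []
    histograms: dict[tuple[str, str], np.ndarray] = {}
    max_len = max(len(s) for s in promoters.values())
    edges = np.arange(0, max_len + bin_size, bin_size)
    usable = {k: f for k, f in features.items() if f.nunique() > 1}
    dropped = sorted(set(features) - set(usable))
    if dropped:
        import warnings

        warnings.warn(f"PWMs with constant hit counts skipped: {dropped}")
    for set_name, genes in deg_sets.items():
        flags = pd.Series(
            {g: 1.0 if g in set(genes) else 0.0 for g in universe}, dtype=float
        )
        table = motif_enrichment_table(flags, usable, covariates)
        table = table.assign(deg_set=set_name)
        tables.append(table.reset_index())
        for pwm_id in table.index[table["fdr"] < fdr_threshold]:
            pos = [
                p
                for g in genes
                if g in hit_positions[pwm_id]
                for p in hit_positions[pwm_id][g]
            ]
            histograms[(set_name, pwm_id)], _ = np.histogram(pos, bins=edges)
    return pd.concat(tables, ignore_index=True), histograms
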