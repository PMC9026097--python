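"""Reference-guided co-expression modules and the differential-module test.

Genes are standardized across the reference samples, clustered with average
linkage on Euclidean distance, and the dendrogram is pruned with a
variable-height rule: a module is a maximal subtree whose own merge height
drops by at least a ``prune_depth`` fraction below the height at which it
joins its parent (tight branches stand out against the locally flat merge
profile of unstructured genes). Branches with fewer than ``min_module_size``
leaves, and everything outside accepted branches, remain unassigned
(module 0). Modules are labeled ``GENE-size`` using the member with the
most annotation terms, summarized by their medoid profile, connected into a
network where medoid profiles have Spearman r >= 0.80, and tested for
differential expression (DEM) by rank-summing member fold changes against
all other detectable genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .diffexpr import bh_adjust
from .io import ExpressionMatrix


@dataclass
class ModuleParams:
    min_module_size: int = 25
    prune_depth: float = 0.08
    rs_edge_threshold: float = 0.80
    linkage_method: str = "average"
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0.0 < self.rs_edge_threshold <= 1.0:
            raise ValueError("rs_edge_threshold must be in (0,1]")
        if not 0.0 < self.prune_depth < 1.0:
            raise ValueError("prune_depth must be in (0,1)")


@dataclass
class ModuleSet:
    """Gene -> module assignment (0 = unassigned) with labels and medoids."""

    assignment: pd.Series
    labels: dict[int, str] = field(default_factory=dict)
    medoids: dict[int, str] = field(default_factory=dict)
    params: ModuleParams | None = None

    @property
    def module_ids(self) -> list[int]:
        ids = sorted(set(self.assignment) - {0})
        return ids

    def members(self, module_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.assignment == m).sum()) for m in self.module_ids}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": {g: int(m) for g, m in self.assignment.items()},
            "labels": {str(k): v for k, v in self.labels.items()},
            "medoids": {str(k): v for k, v in self.medoids.items()},
            "params": None
            if self.params is None
            else {
                "min_module_size": self.params.min_module_size,
                "prune_depth": self.params.prune_depth,
                "rs_edge_threshold": self.params.rs_edge_threshold,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "ModuleSet":
        with open(path) as fh:
            payload = json.load(fh)
        assignment = pd.Series(payload["assignment"], dtype=int)
        params = ModuleParams(**payload["params"]) if payload["params"] else None
        return cls(
            assignment,
            {int(k): v for k, v in payload["labels"].items()},
            {int(k): v for k, v in payload["medoids"].items()},
            params,
        )


def standardize_reference(ref_matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Center and scale each gene to mean 0, SD 1 across reference samples.

    Returns the z-matrix (constant genes dropped) and the list of flagged
    constant genes.
    """
    df = ref_matrix.data
    if df.shape[1] < 2:
        raise ValueError("need at least 2 reference samples")
    sd = df.std(axis=1, ddof=1)
    constant = list(df.index[sd == 0])
    if len(constant) == len(df):
        raise ValueError("all genes constant; nothing to standardize")
    kept = df.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, constant


def detect_modules(z_matrix: pd.DataFrame, params: ModuleParams | None = None) -> ModuleSet:
    """Variable-height dendrogram pruning into co-expression modules.

    Top-down over the average-linkage tree: a node is accepted as one
    module when its merge height is at most ``(1 - prune_depth)`` times the
    height at which it joins its parent, it has at least
    ``min_module_size`` leaves, and it does not itself split into two such
    tight sub-branches (in which case the split is taken instead). Leaves
    outside accepted branches get module 0.
    """
    params = params or ModuleParams()
    n = z_matrix.shape[0]
    assignment = pd.Series(0, index=z_matrix.index, dtype=int)
    if n < params.min_module_size:
        return ModuleSet(assignment, params=params)

    Z = linkage(z_matrix.to_numpy(), method=params.linkage_method, metric=params.distance)
    heights = Z[:, 2]
    counts = Z[:, 3].astype(int)
    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)

    def node_height(node: int) -> float:
        return 0.0 if node < n else float(heights[node - n])

    def node_count(node: int) -> int:
        return 1 if node < n else counts[node - n]

    def leaves(node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:
            k = stack.pop()
            if k < n:
                out.append(k)
            else:
                stack.extend((left[k - n], right[k - n]))
        return out

    shrink = 1.0 - params.prune_depth

    def is_tight(node: int, parent_height: float) -> bool:
        return (
            node >= n
            and node_count(node) >= params.min_module_size
            and node_height(node) <= shrink * parent_height
        )

    accepted: list[int] = []
    root = n + len(heights) - 1
    stack: list[tuple[int, float | None]] = [(root, None)]
    while stack:
        node, parent_h = stack.pop()
        if node < n or node_count(node) < params.min_module_size:
            continue
        h = node_height(node)
        l, r = left[node - n], right[node - n]
        if parent_h is not None and node_height(node) <= shrink * parent_h:
            # tight branch: accept unless it cleanly splits into two tight
            # sub-branches of sufficient size
            if is_tight(l, h) and is_tight(r, h):
                stack.append((l, h))
                stack.append((r, h))
            else:
                accepted.append(node)
        else:
            stack.append((l, h))
            stack.append((r, h))

    # deterministic module numbering: by smallest leaf index
    accepted.sort(key=lambda nd: min(leaves(nd)))
    for m, node in enumerate(accepted, start=1):
        assignment.iloc[leaves(node)] = m
    return ModuleSet(assignment, params=params)


def label_modules(
    module_set: ModuleSet, go_term_counts: Mapping[str, int]
) -> dict[int, str]:
    """Label each module ``GENE-size`` by the member with most GO terms.

    Count ties break lexicographically; duplicate labels across modules get
    a disambiguating ``.k`` suffix.
    """
    labels: dict[int, str] = {}
    seen: dict[str, int] = {}
    for m in module_set.module_ids:
        members = module_set.members(m)
        top = max(sorted(members), key=lambda g: (go_term_counts.get(g, 0), ), default=None)
        # max with key keeps the first of equal keys; sorted() gives lexicographic tie-break
        label = f"{top}-{len(members)}"
        if label in seen:
            seen[label] += 1
            label = f"{label}.{seen[label]}"
        else:
            seen[label] = 0
        labels[m] = label
    module_set.labels = labels
    return labels


def module_medoids(z_matrix: pd.DataFrame, module_set: ModuleSet) -> dict[int, str]:
    """Member gene minimizing summed Euclidean distance to all other members."""
    medoids: dict[int, str] = {}
    for m in module_set.module_ids:
        members = module_set.members(m)
        profiles = z_matrix.loc[members].to_numpy()
        diff = profiles[:, None, :] - profiles[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        sums = dist.sum(axis=1)
        medoids[m] = members[int(np.argmin(sums))]
    module_set.medoids = medoids
    return medoids


def module_network(
    medoid_profiles: pd.DataFrame,
    mean_fc_per_module: Mapping[int, float],
    params: ModuleParams | None = None,
) -> nx.Graph:
    """Module network: edges where medoid profiles have Spearman r >= threshold.

    ``medoid_profiles`` is modules x samples. Vertex attribute ``mean_fc``
    is the average member log2FC; edge ``mean_fc`` averages its endpoints.
    The threshold applies to signed r (anti-correlated medoids get no edge).
    """
    params = params or ModuleParams()
    if medoid_profiles.shape[0] < 2:
        raise ValueError("need at least 2 modules for a network")
    g = nx.Graph()
    mods = list(medoid_profiles.index)
    for m in mods:
        g.add_node(m, mean_fc=float(mean_fc_per_module.get(m, 0.0)))
    rho = stats.spearmanr(medoid_profiles.to_numpy().T).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    for i, mi in enumerate(mods):
        for j in range(i + 1, len(mods)):
            if rho[i, j] >= params.rs_edge_threshold - 1e-12:  # ">=" incl. boundary
                mj = mods[j]
                g.add_edge(
                    mi,
                    mj,
                    rs=float(rho[i, j]),
                    mean_fc=(g.nodes[mi]["mean_fc"] + g.nodes[mj]["mean_fc"]) / 2.0,
                )
    return g


def dem_test(
    de: pd.DataFrame,
    module_set: ModuleSet,
    alpha_fdr: float = 0.05,
    exact_max_members: int = 10,
) -> pd.DataFrame:
    """Differential expression module (DEM) test.

    Per module, a two-sided two-sample Wilcoxon rank-sum test compares
    member log2FCs against all other detectable genes (exact enumeration
    for very small modules, otherwise the tie-corrected normal
    approximation), followed by BH across modules. The shift statistic is
    median(member FC) - median(other FC).
    """
    detectable = de.index[de["detected"].astype(bool)] if "detected" in de else de.index
    fc = de.loc[detectable, "log2fc"]
    common = fc.index.intersection(module_set.assignment.index)
    fc = fc.loc[common]
    assign = module_set.assignment.loc[common]
    n_total = len(fc)

    # rank once; per-module rank sums give the normal-approximation test
    fc_vals = fc.to_numpy()
    codes = assign.to_numpy()
    ranks = stats.rankdata(fc_vals)
    _, tie_counts = np.unique(fc_vals, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())

    rows = []
    for m in module_set.module_ids:
        mask = codes == m
        n1 = int(mask.sum())
        n2 = n_total - n1
        if n1 < 2:
            warnings.warn(f"module {m} has <2 detectable members; skipped")
            continue
        if n2 < 1:
            raise ValueError("module covers the whole universe; DEM test undefined")
        member_fc = fc_vals[mask]
        other_fc = fc_vals[~mask]
        shift = float(np.median(member_fc) - np.median(other_fc))
        w = float(ranks[mask].sum())
        if n1 <= exact_max_members:
            res = stats.mannwhitneyu(member_fc, other_fc, alternative="two-sided", method="exact")
            p = float(res.pvalue)
        else:
            mean_w = n1 * (n_total + 1) / 2.0
            var_w = (
                n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
            )
            if var_w <= 0:
                p = 1.0
            else:
                z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
                p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "module": m,
                "label": module_set.labels.get(m, str(m)),
                "n_members": n1,
                "shift": shift,
                "W": w,
                "p": min(p, 1.0),
                "direction": "up" if shift > 0 else ("down" if shift < 0 else "none"),
            }
        )
    columns = ["label", "n_members", "shift", "W", "p", "direction", "fdr", "significant"]
    if not rows:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="module"))
    out = pd.DataFrame(rows).set_index("module")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < alpha_fdr
    return out
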