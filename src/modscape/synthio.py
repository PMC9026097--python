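"""Synthetic data with planted ground truth.

Every generator here emulates one input of the astrocyte fumarate study
design: a 4-group x 3-replicate treatment matrix with group-specific planted
log2 fold changes of differing breadth (the IDMF-like group perturbs the
most genes), a 24-sample reference matrix carrying latent-factor
co-expression modules, directional signature gene sets, a multi-source
disease-gene table, synthetic chromosomes with genes planted near loci, and
5 kb promoter sequences with planted motif instances.

All generators draw from an explicitly seeded ``numpy.random.Generator``
(one stream per operation, derived from ``SimParams.seed``) so identical
parameters give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    BedInterval,
    ExpressionMatrix,
    PWMRecord,
    SignatureSet,
    read_bed,
    read_expression_tsv,
    read_fasta,
    read_gmt,
    read_groups_tsv,
    read_pwms,
    write_bed,
    write_expression_tsv,
    write_fasta,
    write_gmt,
    write_groups_tsv,
    write_pwms,
)

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_experiment",
    "simulate_reference",
    "simulate_genome_and_loci",
    "simulate_promoters",
    "simulate_signature",
    "simulate_disease_sources",
    "synthetic_irf_pwms",
    "load_builtin_signatures",
    "gene_ids",
    # re-exported format I/O (same module surface as the simulators)
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "write_groups_tsv",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_pwms",
    "write_pwms",
]

DEFAULT_GROUPS = ("CTL", "MMF", "DRF", "IDMF")

# Fraction of genes perturbed per treatment. Mirrors the relative DEG burden
# of the three compounds (the IDMF-like group alters several-fold more genes
# than the MMF/DRF-like groups).
DEFAULT_EFFECT_FRACTIONS = {"MMF": 0.03, "DRF": 0.025, "IDMF": 0.10}


@dataclass
class SimParams:
    """Conditions for the synthetic treatment and reference experiments.

    Defaults reproduce the study design being emulated: four treatment
    groups with three replicates each, planted mean |log2FC| of 1.0 against
    per-gene residual SD 0.25, and a 24-sample reference set carrying
    co-expression modules of 25-196 genes.
    """

    n_genes: int = 5000
    n_reps_per_group: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    effect_fraction_per_group: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_FRACTIONS)
    )
    effect_size_log2: float = 1.0
    noise_sd: float = 0.25
    n_ref_samples: int = 24
    n_modules: int = 8
    module_size_range: tuple[int, int] = (25, 196)
    module_signal: float = 0.6
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    gc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_reps_per_group <= 0:
            raise ValueError("counts must be positive")
        if self.n_ref_samples <= 0 or self.n_modules <= 0:
            raise ValueError("counts must be positive")
        if len(self.groups) < 2 or self.groups[0] != "CTL":
            raise ValueError("groups must start with the control label 'CTL'")
        for g, f in self.effect_fraction_per_group.items():
            if g not in self.groups:
                raise ValueError(f"effect fraction given for unknown group {g!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"effect fraction for {g!r} outside [0,1]")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError("module_size_range must satisfy 2 <= min <= max")
        if self.noise_sd < 0 or self.module_signal < 0:
            raise ValueError("noise_sd and module_signal must be nonnegative")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0,1)")


@dataclass
class GroundTruth:
    """What the generators planted, for parameter-recovery tests."""

    planted_deg_sets: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_modules: dict[str, int] = field(default_factory=dict)
    planted_signature_overlaps: dict[str, dict] = field(default_factory=dict)
    planted_proximal_genes: list[str] = field(default_factory=list)
    planted_motif_genes: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def gene_ids(n_genes: int) -> list[str]:
    """Canonical synthetic gene universe: G00000, G00001, ..."""
    return [f"G{i:05d}" for i in range(n_genes)]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


# ---------------------------------------------------------------------------
# Treatment experiment


def simulate_experiment(params: SimParams) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the 4-group treatment matrix with planted group effects.

    Planted genes in treatment group g carry a constant signed mean shift of
    ``effect_size_log2`` relative to CTL, on top of a shared per-gene
    baseline and i.i.d. Gaussian residuals with SD ``noise_sd``.
    """
    import pandas as pd

    rng = _rng(params.seed, 1)
    genes = gene_ids(params.n_genes)
    n = params.n_genes
    reps = params.n_reps_per_group

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n)
    samples: list[str] = []
    groups_map: dict[str, str] = {}
    for g in params.groups:
        for r in range(1, reps + 1):
            name = f"{g}-{r}"
            samples.append(name)
            groups_map[name] = g

    shift = np.zeros((n, len(params.groups)))
    truth = GroundTruth()
    for gi, g in enumerate(params.groups):
        frac = params.effect_fraction_per_group.get(g, 0.0)
        if g == "CTL" or frac == 0.0:
            truth.planted_deg_sets.setdefault(g, {}) if g != "CTL" else None
            if g != "CTL":
                truth.planted_deg_sets[g] = {}
            continue
        k = int(round(frac * n))
        chosen = rng.choice(n, size=k, replace=False)
        signs = rng.choice([-1, 1], size=k)
        shift[chosen, gi] = signs * params.effect_size_log2
        truth.planted_deg_sets[g] = {
            genes[idx]: int(s) for idx, s in zip(chosen, signs)
        }

    values = (
        baseline[:, None]
        + np.repeat(shift, reps, axis=1)
        + rng.normal(0.0, params.noise_sd, size=(n, len(samples)))
    )
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(data, groups_map), truth


# ---------------------------------------------------------------------------
# Reference matrix with latent-factor modules


def simulate_reference(
    params: SimParams, genes: Sequence[str] | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the reference expression matrix carrying planted modules.

    Genes of module m share a latent factor z_m (one draw per reference
    sample) with loading ``module_signal`` plus residual noise; background
    genes are pure noise with matched marginal variance, so modules are
    distinguishable only through correlation, not variance.
    """
    import pandas as pd

    if params.n_ref_samples < 4:
        raise ValueError("need at least 4 reference samples")
    rng = _rng(params.seed, 2)
    if genes is None:
        genes = gene_ids(params.n_genes)
    n = len(genes)

    lo, hi = params.module_size_range
    sizes = rng.integers(lo, hi + 1, size=params.n_modules)
    if sizes.sum() > n:
        raise ValueError(
            f"planted module sizes total {sizes.sum()} but only {n} genes available"
        )
    order = rng.permutation(n)
    assignment = np.zeros(n, dtype=int)
    pos = 0
    for m, size in enumerate(sizes, start=1):
        assignment[order[pos : pos + size]] = m
        pos += size

    a, sd = params.module_signal, params.noise_sd
    total_sd = float(np.hypot(a, sd))
    values = np.empty((n, params.n_ref_samples))
    factors = rng.normal(size=(params.n_modules + 1, params.n_ref_samples))
    # standardize each factor across samples so the factor-model correlation
    # a^2/(a^2 + sd^2) holds realization-by-realization, not just in expectation
    factors = (factors - factors.mean(axis=1, keepdims=True)) / factors.std(
        axis=1, ddof=0, keepdims=True
    )
    noise = rng.normal(size=(n, params.n_ref_samples))
    for i in range(n):
        m = assignment[i]
        if m == 0:
            values[i] = total_sd * noise[i]
        else:
            values[i] = a * factors[m] + sd * noise[i]
    values += rng.normal(params.baseline_mean, params.baseline_sd, size=n)[:, None]

    samples = [f"REF-{j + 1}" for j in range(params.n_ref_samples)]
    data = pd.DataFrame(values, index=pd.Index(list(genes), name="gene"), columns=samples)
    truth = GroundTruth(
        planted_modules={g: int(m) for g, m in zip(genes, assignment)}
    )
    return ExpressionMatrix(data), truth


# ---------------------------------------------------------------------------
# Synthetic genome, GWAS-like loci


def simulate_genome_and_loci(
    n_genes: int,
    n_loci: int,
    planted_fraction: float,
    seed: int = 0,
    designated: Sequence[str] | None = None,
    window: int = 100_000,
    genes_per_chrom: int = 500,
    chrom_length: int | None = None,
) -> tuple[list[BedInterval], list[BedInterval], GroundTruth]:
    """Lay out non-overlapping genes on synthetic chromosomes and drop loci.

    A ``planted_fraction`` of the designated gene list gets a locus placed
    within ``window`` bp; the remaining loci land uniformly. Coordinates are
    0-based half-open; loci are single-base intervals.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_loci < 0:
        raise ValueError("n_loci must be nonnegative")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0,1]")
    rng = _rng(seed, 3)
    names = gene_ids(n_genes)

    genes: list[BedInterval] = []
    chrom_spans: dict[str, int] = {}
    idx = 0
    chrom_no = 0
    while idx < n_genes:
        chrom_no += 1
        chrom = f"chr{chrom_no}"
        cursor = 0
        for _ in range(min(genes_per_chrom, n_genes - idx)):
            cursor += int(rng.integers(5_000, 50_001))  # intergenic gap
            length = int(rng.integers(2_000, 20_001))
            if chrom_length is not None and cursor + length > chrom_length:
                raise ValueError(
                    f"chromosome capacity {chrom_length} exceeded on {chrom}"
                )
            genes.append(BedInterval(chrom, cursor, cursor + length, names[idx]))
            cursor += length
            idx += 1
        chrom_spans[chrom] = cursor + 50_000

    by_name = {g.name: g for g in genes}
    if designated is None:
        designated = list(rng.choice(names, size=min(30, n_genes), replace=False))
    else:
        missing = set(designated) - set(names)
        if missing:
            raise ValueError(f"designated genes not in universe: {sorted(missing)[:5]}")
        designated = list(designated)

    n_planted = int(round(planted_fraction * len(designated)))
    if n_planted > n_loci:
        raise ValueError(
            f"{n_planted} planted loci requested but only n_loci={n_loci} available"
        )
    planted_genes = (
        list(rng.choice(designated, size=n_planted, replace=False)) if n_planted else []
    )

    loci: list[BedInterval] = []
    for gname in planted_genes:
        g = by_name[gname]
        lo = max(0, g.start - window)
        hi = g.end - 1 + window
        pos = int(rng.integers(lo, hi + 1))
        loci.append(BedInterval(g.chrom, pos, pos + 1, f"locus_{gname}"))
    chroms = list(chrom_spans)
    weights = np.array([chrom_spans[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for j in range(n_loci - n_planted):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(0, chrom_spans[chrom]))
        loci.append(BedInterval(chrom, pos, pos + 1, f"locus_bg{j}"))

    truth = GroundTruth(planted_proximal_genes=sorted(planted_genes))
    return genes, loci, truth


# ---------------------------------------------------------------------------
# Promoters with planted motif instances


def pwm_consensus(pwm: PWMRecord) -> str:
    return "".join("ACGT"[b] for b in np.argmax(pwm.matrix, axis=1))


def simulate_promoters(
    gene_list: Sequence[str],
    pwm: PWMRecord,
    plant_in: Sequence[str],
    length: int = 5000,
    seed: int = 0,
    gc_fraction: float = 0.5,
) -> tuple[dict[str, str], GroundTruth]:
    """I.i.d.-background promoter sequences with planted consensus sites.

    Each planted gene receives one exact PWM-consensus instance at a
    position recorded in the returned ground truth (0-based, forward
    strand).
    """
    plant_set = set(plant_in)
    if not plant_set <= set(gene_list):
        raise ValueError("plant_in must be a subset of gene_list")
    consensus = pwm_consensus(pwm)
    if len(consensus) > length:
        raise ValueError("PWM consensus longer than promoter length")
    rng = _rng(seed, 4)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    truth = GroundTruth()
    w = len(consensus)
    for gene in gene_list:
        arr = rng.choice(4, size=length, p=p)
        seq = "".join(bases[arr])
        if gene in plant_set:
            pos = int(rng.integers(0, length - w + 1))
            seq = seq[:pos] + consensus + seq[pos + w :]
            truth.planted_motif_genes[gene] = pos
        seqs[gene] = seq
    return seqs, truth


# ---------------------------------------------------------------------------
# Directional signatures and disease-gene sources


def simulate_signature(
    truth: GroundTruth,
    group: str,
    direction: str,
    n_members: int,
    concordant_fraction: float,
    universe: Sequence[str],
    seed: int = 0,
    name: str | None = None,
) -> SignatureSet:
    """Build a directional signature overlapping the planted DEGs of a group.

    ``concordant_fraction`` of the members are drawn from genes planted in
    the requested direction; the rest are unperturbed background genes, so
    the planted concordance of the set is known exactly.
    """
    if direction not in ("up", "down", "activated", "suppressed"):
        raise ValueError(f"bad direction {direction!r}")
    sign = 1 if direction in ("up", "activated") else -1
    rng = _rng(seed, 5)
    planted = truth.planted_deg_sets.get(group, {})
    pool = sorted(g for g, s in planted.items() if s == sign)
    any_planted = set(planted)
    background = sorted(set(universe) - any_planted)
    k = int(round(concordant_fraction * n_members))
    if k > len(pool):
        raise ValueError(f"only {len(pool)} planted {direction} genes available, need {k}")
    if n_members - k > len(background):
        raise ValueError("not enough background genes")
    members = list(rng.choice(pool, size=k, replace=False)) + list(
        rng.choice(background, size=n_members - k, replace=False)
    )
    rng.shuffle(members)
    name = name or f"{group}_{direction.upper()}_SIG"
    truth.planted_signature_overlaps[name] = {
        "group": group,
        "direction": direction,
        "concordant_fraction": k / n_members,
    }
    return SignatureSet(name, members, direction, note=f"synthetic; direction={direction}")


def simulate_disease_sources(
    universe: Sequence[str],
    n_sources: int = 7,
    n_disease_genes: int = 500,
    seed: int = 0,
    source_names: Sequence[str] | None = None,
) -> dict[str, set[str]]:
    """Multi-source disease-gene table emulating aggregative curation.

    Per-gene source counts follow a truncated geometric distribution, so
    most genes are claimed by a single source and only a handful by all of
    them (mirroring real gene-disease databases).
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    rng = _rng(seed, 6)
    if source_names is None:
        source_names = [f"SOURCE{j + 1}" for j in range(n_sources)]
    if len(source_names) != n_sources:
        raise ValueError("source_names length must equal n_sources")
    n_disease_genes = min(n_disease_genes, len(universe))
    disease_genes = rng.choice(list(universe), size=n_disease_genes, replace=False)
    tiers = np.minimum(rng.geometric(0.55, size=n_disease_genes), n_sources)
    sources: dict[str, set[str]] = {s: set() for s in source_names}
    for gene, tier in zip(disease_genes, tiers):
        for s in rng.choice(source_names, size=int(tier), replace=False):
            sources[s].add(str(gene))
    return {s: members for s, members in sources.items() if members}


# ---------------------------------------------------------------------------
# Synthetic IRF-family PWMs


_IRF_CORE = "TTTCACTTTC"  # interferon-stimulated response element core


def synthetic_irf_pwms(n: int = 19, seed: int = 0) -> list[PWMRecord]:
    """Deterministic family of IRF-like PWMs built around the ISRE core.

    Stand-ins for a curated IRF motif collection (which is not shipped):
    each matrix is a flank-extended, mildly perturbed variant of the
    TTTC-repeat consensus, with dominant-base probability ~0.85.
    """
    rng = _rng(seed, 7)
    base_index = {b: i for i, b in enumerate("ACGT")}
    records: list[PWMRecord] = []
    irf_members = [1, 2, 3, 4, 5, 6, 7, 8, 9]
    for j in range(n):
        flank = rng.integers(0, 3)
        cons = (
            "".join(rng.choice(list("ACGT"), size=flank))
            + _IRF_CORE
            + "".join(rng.choice(list("ACGT"), size=flank))
        )
        w = len(cons)
        mat = np.full((w, 4), 0.05)
        for i, b in enumerate(cons):
            mat[i, base_index[b]] = 0.85
        jitter = rng.uniform(-0.02, 0.02, size=(w, 4))
        mat = np.clip(mat + jitter, 0.01, None)
        mat /= mat.sum(axis=1, keepdims=True)
        irf = irf_members[j % len(irf_members)]
        records.append(PWMRecord(f"IRF{irf}_M{j + 1}", mat))
    return records


# ---------------------------------------------------------------------------
# Packaged signature fixtures


def load_builtin_signatures() -> dict[str, SignatureSet]:
    """Packaged synthetic NRF2 and RELA signature fixtures.

    The NRF2 signature has 68 up- plus 75 down-regulated members (143
    total) and the RELA signature 304 activated plus 85 suppressed members
    (389 total), matching the sizes of the published reference signatures;
    member IDs are synthetic stand-ins from the simulator's gene universe.
    """
    out: dict[str, SignatureSet] = {}
    for fname in ("nrf2_signature_synthetic.gmt", "rela_signature_synthetic.gmt"):
        ref = resources.files("modscape.data").joinpath(fname)
        with resources.as_file(ref) as path:
            for sig in read_gmt(path):
                out[sig.name] = sig
    return out
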