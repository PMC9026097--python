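"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices are tab-delimited gene x sample tables (first column =
gene IDs, header row = sample IDs). Gene sets travel as GMT, genomic
intervals as BED (0-based, half-open), promoter sequences as FASTA, and
position weight matrices as a simple 4-row text format (A/C/G/T rows under
an ``>ID`` header line).

All writers emit a leading ``#`` comment recording the package version and,
where applicable, the seed that generated the data; readers skip such lines.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


class FormatError(ValueError):
    """Malformed input file; message names the offending line or record."""


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples table of log2-scale expression with group labels.

    Parameters
    ----------
    data:
        DataFrame indexed by gene ID with one column per sample.
    groups:
        Optional mapping sample ID -> treatment group label.
    """

    data: pd.DataFrame
    groups: dict[str, str] | None = None

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("no group labels attached to this matrix")
        return [s for s in self.data.columns if self.groups.get(s) == group]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        groups = None
        if self.groups is not None:
            groups = {s: self.groups[s] for s in samples if s in self.groups}
        return ExpressionMatrix(self.data.loc[:, list(samples)], groups)


def _comment(seed: int | None = None) -> str:
    tail = "" if seed is None else f" seed={seed}"
    return f"# modscape {__version__}{tail}\n"


def write_expression_tsv(
    matrix: ExpressionMatrix | pd.DataFrame, path: str | Path, seed: int | None = None
) -> None:
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    with open(path, "w") as fh:
        fh.write(_comment(seed))
        df.to_csv(fh, sep="\t", index_label="gene", float_format="%.15g")


def read_expression_tsv(
    path: str | Path, groups: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Parse a tab-delimited gene x sample matrix.

    Raises :class:`FormatError` naming the offending line for ragged rows,
    duplicate gene IDs, or non-numeric cells.
    """
    header: list[str] | None = None
    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise FormatError(
                    f"line {lineno}: expected {len(header) + 1} fields, got {len(parts)}"
                )
            gene = parts[0]
            if gene in seen:
                raise FormatError(f"line {lineno}: duplicate gene ID {gene!r}")
            seen.add(gene)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric cell ({exc})") from None
            genes.append(gene)
    if header is None:
        raise FormatError("empty expression file")
    data = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=header)
    return ExpressionMatrix(data, dict(groups) if groups is not None else None)


def write_groups_tsv(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment())
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "sample":
                continue
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 fields")
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# Gene sets (GMT)

_DIRECTIONS = ("up", "down", "activated", "suppressed", "none")


@dataclass
class SignatureSet:
    """Named, optionally directional gene set (one GMT line)."""

    name: str
    members: list[str]
    direction: str = "none"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"signature {self.name!r} has duplicate members")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


def _infer_direction(name: str, desc: str) -> str:
    for token in desc.split(";"):
        token = token.strip()
        if token.startswith("direction="):
            return token.split("=", 1)[1]
    lowered = name.lower()
    for suffix, direction in (
        ("_up", "up"),
        ("_down", "down"),
        ("_activated", "activated"),
        ("_suppressed", "suppressed"),
    ):
        if lowered.endswith(suffix):
            return direction
    return "none"


def read_gmt(path: str | Path) -> list[SignatureSet]:
    sets: list[SignatureSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: GMT line needs name, description, members")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"line {lineno}: gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"line {lineno}: duplicate members in {name!r}")
            sets.append(SignatureSet(name, members, _infer_direction(name, desc), desc))
    return sets


def write_gmt(sets: Iterable[SignatureSet], path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(seed))
        for s in sets:
            desc = s.note or f"direction={s.direction}"
            fh.write("\t".join([s.name, desc, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# BED intervals


@dataclass
class BedInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"interval {self.name} [{self.start},{self.end}) is not 0-based half-open"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: BED needs at least 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            if strand not in "+-":
                raise FormatError(f"line {lineno}: bad strand {strand!r}")
            try:
                out.append(BedInterval(parts[0], start, end, name, score, strand))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    return out


def write_bed(
    intervals: Iterable[BedInterval],
    path: str | Path,
    columns: int = 6,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(seed))
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, f"{iv.score:g}", iv.strand]
            fh.write("\t".join(fields[:columns]) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {header: sequence}; duplicate headers rejected."""
    out: dict[str, str] = {}
    with open(path) as fh:
        text = "".join(l for l in fh if not l.startswith((";", "#")))
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, seed: int | None = None) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        fh.write(_comment(seed).replace("#", ";", 1))
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# PWM text format

_BASES = "ACGT"


def read_pwms(path: str | Path) -> list["PWMRecord"]:
    """Parse the whitespace-delimited 4-row PWM format.

    Each record is an ``>ID`` line followed by four rows giving per-position
    probabilities for A, C, G, T in that order.
    """
    records: list[PWMRecord] = []
    current_id: str | None = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal rows, current_id
        if current_id is None:
            return
        if len(rows) != 4:
            raise FormatError(
                f"line {lineno}: PWM {current_id!r} has {len(rows)} rows, expected 4"
            )
        mat = np.asarray(rows, dtype=float).T  # positions x 4
        records.append(PWMRecord(current_id, mat))
        rows = []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno)
                current_id = line[1:].strip()
                continue
            if current_id is None:
                raise FormatError(f"line {lineno}: matrix row before any >ID header")
            try:
                rows.append([float(v) for v in line.split()])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric PWM entry") from None
        flush(lineno)
    return records


def write_pwms(records: Iterable["PWMRecord"], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment())
        for rec in records:
            fh.write(f">{rec.id}\n")
            for b in range(4):
                fh.write(" ".join(f"{v:.6f}" for v in rec.matrix[:, b]) + "\n")


@dataclass
class PWMRecord:
    """Raw probability matrix as read from disk (positions x ACGT)."""

    id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.id!r}: matrix must be positions x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id!r}: columns must sum to 1")
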