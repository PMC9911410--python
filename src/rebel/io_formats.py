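"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are 0-based half-open (BED convention) everywhere inside
the package; dialects that use other conventions are converted here and never
leak inward.  Readers validate records against the domain-type invariants and
reject (or, where documented, warn and drop) anything that violates them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("rebel")

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "Pwm",
    "DeRecord",
    "InteractionRecord",
    "read_fasta",
    "write_fasta",
    "read_peaks",
    "write_peaks",
    "read_motif_library",
    "write_motif_library",
    "read_de_table",
    "write_de_table",
    "read_interactions",
    "write_interactions",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named contig."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakRecord:
    """An accessibility peak with the offset of its apex (summit) from start."""

    interval: GenomicInterval
    summit_offset: int
    name: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def summit(self) -> int:
        """Absolute coordinate of the peak apex."""
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix with a log-odds detection threshold.

    ``matrix`` holds per-position base probabilities in A, C, G, T column
    order; each row sums to 1 (tolerance 1e-6).  ``detection_threshold`` is the
    minimum log-odds score (natural log against ``background``) at which a
    window position counts as a binding site.
    """

    motif_id: str
    matrix: np.ndarray
    detection_threshold: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(
            self, "background", np.asarray(self.background, dtype=float)
        )
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if mat.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        sums = mat.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1 (±1e-6)")
        if self.detection_threshold > self.max_score + 1e-9:
            raise ValueError(
                f"{self.motif_id}: threshold {self.detection_threshold} exceeds "
                f"maximum achievable score {self.max_score}"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log-odds matrix; zero probabilities floored at 1e-4."""
        p = np.maximum(self.matrix, 1e-4)
        return np.log(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression outcome."""

    gene_id: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"{self.gene_id}: adj_p {self.adj_p} outside [0, 1]")


@dataclass(frozen=True)
class InteractionRecord:
    """A bait/other-end fragment pair with per-replicate read counts.

    ``distance`` is |bait midpoint - other-end midpoint| for cis pairs and -1
    for trans pairs (different contigs).
    """

    bait: GenomicInterval
    bait_gene: str
    other_end: GenomicInterval
    counts_control: tuple[int, ...]
    counts_induced: tuple[int, ...]
    distance: int = -2  # sentinel: computed in __post_init__ unless supplied

    def __post_init__(self) -> None:
        ctrl = tuple(int(c) for c in self.counts_control)
        ind = tuple(int(c) for c in self.counts_induced)
        object.__setattr__(self, "counts_control", ctrl)
        object.__setattr__(self, "counts_induced", ind)
        if any(c < 0 for c in ctrl + ind):
            raise ValueError("read counts must be >= 0")
        if len(ctrl) != len(ind):
            raise ValueError("replicate vectors must have equal length")
        if self.distance == -2:
            object.__setattr__(self, "distance", self._computed_distance())

    def _computed_distance(self) -> int:
        if self.bait.chrom != self.other_end.chrom:
            return -1
        return abs(self.bait.midpoint - self.other_end.midpoint)

    @property
    def n_replicates(self) -> int:
        return len(self.counts_control)

    @property
    def key(self) -> tuple:
        """Identity of the fragment pair, ignoring counts."""
        return (
            self.bait.chrom,
            self.bait.start,
            self.bait.end,
            self.other_end.chrom,
            self.other_end.start,
            self.other_end.end,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered mapping contig -> uppercase sequence.

    Contig names are the header up to the first whitespace; descriptions are
    dropped.  A file whose first non-blank line is not a header raises
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header, got "
                        f"{line.strip()[:40]!r}"
                    )
                break
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    logger.info("read_fasta: %d contigs from %s", len(out), path)
    return out


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# peaks (BED6 / narrowPeak)
# ---------------------------------------------------------------------------


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[PeakRecord]:
    """Read peak calls in BED6 or narrowPeak dialect.

    narrowPeak column 10 carries the summit offset from peak start; the BED6
    dialect has no summit, so the midpoint floor((end-start)/2) is used.
    Records with start >= end are dropped with a logged warning; non-integer
    coordinate fields raise :class:`ParseError`.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    min_cols = 10 if dialect == "narrowPeak" else 4
    peaks: list[PeakRecord] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {min_cols} columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end or start < 0:
                logger.warning(
                    "%s: line %d: dropping record with invalid interval %d-%d",
                    path, lineno, start, end,
                )
                n_dropped += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else (
                f"peak_{lineno}"
            )
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                score = float(fields[4])
            if dialect == "narrowPeak":
                try:
                    summit = int(fields[9])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer summit column"
                    ) from exc
                if summit < 0:  # narrowPeak uses -1 for "no summit"
                    summit = (end - start) // 2
            else:
                summit = (end - start) // 2
            peaks.append(
                PeakRecord(
                    interval=GenomicInterval(fields[0], start, end),
                    summit_offset=summit,
                    name=name,
                    score=score,
                )
            )
    logger.info(
        "read_peaks: %d records (%d dropped) from %s", len(peaks), n_dropped, path
    )
    return peaks


def write_peaks(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    """Write peaks in narrowPeak format (summit preserved in column 10)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = p.score if p.score is not None else 0
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name,
                        str(int(score)),
                        p.interval.strand,
                        "0", "-1", "-1",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# motif libraries (HOMER text / MEME minimal)
# ---------------------------------------------------------------------------

#: MEME-dialect motifs carry no per-motif threshold; this fraction of the
#: maximum achievable log-odds score is used instead (HOMER-like stringency).
DEFAULT_THRESHOLD_FRACTION = 0.8


def _finish_pwm(
    motif_id: str,
    rows: list[list[float]],
    threshold: float | None,
    threshold_fraction: float,
    path: Path,
    lineno: int,
) -> Pwm:
    mat = np.asarray(rows, dtype=float)
    sums = mat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ParseError(
            f"{path}: motif {motif_id!r} row {bad} sums to {sums[bad]:.5f} "
            "(deviates from 1 by > 1e-3)"
        )
    mat = mat / sums[:, None]  # renormalize small drift
    if threshold is None:
        probe = Pwm(motif_id, mat, detection_threshold=-math.inf)
        threshold = threshold_fraction * probe.max_score
    try:
        return Pwm(motif_id, mat, detection_threshold=threshold)
    except ValueError as exc:
        raise ParseError(f"{path}: near line {lineno}: {exc}") from exc


def read_motif_library(
    path: str | Path,
    dialect: str = "homer",
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list[Pwm]:
    """Read a PWM library in HOMER text or MEME minimal format.

    HOMER headers (``>CONSENSUS<TAB>name<TAB>threshold``) carry a per-motif
    log-odds detection threshold which is passed through unchanged.  The MEME
    minimal dialect has no threshold, so ``threshold_fraction`` times the
    motif's maximum achievable log-odds score is assigned.
    """
    path = Path(path)
    if dialect not in ("homer", "meme_minimal"):
        raise ValueError(f"unknown motif dialect {dialect!r}")
    pwms: list[Pwm] = []
    if dialect == "homer":
        motif_id: str | None = None
        threshold: float | None = None
        rows: list[list[float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if motif_id is not None:
                        pwms.append(
                            _finish_pwm(motif_id, rows, threshold,
                                        threshold_fraction, path, lineno)
                        )
                    fields = line[1:].split("\t")
                    if len(fields) < 3:
                        raise ParseError(
                            f"{path}: line {lineno}: HOMER header needs "
                            "consensus, name and threshold columns"
                        )
                    motif_id = fields[1]
                    threshold = float(fields[2])
                    rows = []
                else:
                    vals = [float(x) for x in line.split()]
                    if len(vals) != 4:
                        raise ParseError(
                            f"{path}: line {lineno}: expected 4 probabilities"
                        )
                    rows.append(vals)
        if motif_id is not None:
            pwms.append(
                _finish_pwm(motif_id, rows, threshold, threshold_fraction,
                            path, lineno)
            )
    else:  # meme_minimal
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines):
            line = lines[i].strip()
            if line.startswith("MOTIF"):
                motif_id = line.split()[1]
                # advance to the letter-probability header
                j = i + 1
                while j < len(lines) and not lines[j].strip().startswith(
                    "letter-probability"
                ):
                    if lines[j].strip().startswith("MOTIF"):
                        raise ParseError(
                            f"{path}: line {i + 1}: motif {motif_id!r} has no "
                            "letter-probability matrix"
                        )
                    j += 1
                if j == len(lines):
                    raise ParseError(
                        f"{path}: line {i + 1}: motif {motif_id!r} has no "
                        "letter-probability matrix"
                    )
                rows = []
                j += 1
                while j < len(lines):
                    stripped = lines[j].strip()
                    if not stripped or not stripped[0].isdigit() and not (
                        stripped[0] in "0.+-"
                    ):
                        break
                    rows.append([float(x) for x in stripped.split()])
                    j += 1
                pwms.append(
                    _finish_pwm(motif_id, rows, None, threshold_fraction,
                                path, j)
                )
                i = j
            else:
                i += 1
    ids = [p.motif_id for p in pwms]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate motif ids in library")
    logger.info("read_motif_library: %d motifs from %s", len(pwms), path)
    return pwms


def write_motif_library(pwms: Sequence[Pwm], path: str | Path) -> None:
    """Write a PWM library in HOMER text format (threshold in header)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.consensus}\t{p.motif_id}\t{p.detection_threshold:.6f}\n")
            for row in p.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# differential-expression table
# ---------------------------------------------------------------------------


def read_de_table(path: str | Path) -> list[DeRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "adj_p"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: DE table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    recs = [
        DeRecord(str(r.gene_id), float(r.log2fc), float(r.adj_p))
        for r in df.itertuples()
    ]
    logger.info("read_de_table: %d genes from %s", len(recs), path)
    return recs


def write_de_table(records: Sequence[DeRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "adj_p": [r.adj_p for r in records],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

_INTERACTION_FIXED = [
    "bait_chrom", "bait_start", "bait_end", "bait_gene",
    "oe_chrom", "oe_start", "oe_end",
]


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read a promoter-interaction table with per-replicate count columns.

    Count columns are ``ctrl_rep1..n`` and ``ind_rep1..n``; the two conditions
    must have the same number of replicates.  Distances are recomputed from
    fragment midpoints (cis) or set to -1 (trans).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_INTERACTION_FIXED) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    ctrl_cols = sorted(
        (c for c in df.columns if c.startswith("ctrl_rep")),
        key=lambda c: int(c.removeprefix("ctrl_rep")),
    )
    ind_cols = sorted(
        (c for c in df.columns if c.startswith("ind_rep")),
        key=lambda c: int(c.removeprefix("ind_rep")),
    )
    if not ctrl_cols or len(ctrl_cols) != len(ind_cols):
        raise ParseError(
            f"{path}: unequal replicate columns "
            f"({len(ctrl_cols)} control vs {len(ind_cols)} induced)"
        )
    recs = []
    for r in df.itertuples():
        recs.append(
            InteractionRecord(
                bait=GenomicInterval(str(r.bait_chrom), int(r.bait_start),
                                     int(r.bait_end)),
                bait_gene=str(r.bait_gene),
                other_end=GenomicInterval(str(r.oe_chrom), int(r.oe_start),
                                          int(r.oe_end)),
                counts_control=tuple(int(getattr(r, c)) for c in ctrl_cols),
                counts_induced=tuple(int(getattr(r, c)) for c in ind_cols),
            )
        )
    logger.info(
        "read_interactions: %d pairs, %d replicates, from %s",
        len(recs), len(ctrl_cols), path,
    )
    return recs


def interactions_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=_INTERACTION_FIXED)
    n_rep = records[0].n_replicates
    data: dict[str, list] = {c: [] for c in _INTERACTION_FIXED}
    for i in range(n_rep):
        data[f"ctrl_rep{i + 1}"] = []
    for i in range(n_rep):
        data[f"ind_rep{i + 1}"] = []
    for r in records:
        if r.n_replicates != n_rep:
            raise ValueError("replicate vectors differ in length across records")
        data["bait_chrom"].append(r.bait.chrom)
        data["bait_start"].append(r.bait.start)
        data["bait_end"].append(r.bait.end)
        data["bait_gene"].append(r.bait_gene)
        data["oe_chrom"].append(r.other_end.chrom)
        data["oe_start"].append(r.other_end.start)
        data["oe_end"].append(r.other_end.end)
        for i in range(n_rep):
            data[f"ctrl_rep{i + 1}"].append(r.counts_control[i])
        for i in range(n_rep):
            data[f"ind_rep{i + 1}"].append(r.counts_induced[i])
    return pd.DataFrame(data)


def write_interactions(
    records: Sequence[InteractionRecord], path: str | Path
) -> None:
    interactions_to_frame(records).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Uniform TSV writer for all tabular outputs (header, UTF-8, LF)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
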