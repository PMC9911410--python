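"""Assignment of regulatory elements to interaction/expression categories.

Elements are ATAC peaks that overlap a fragment of a fusion-protein-associated
differential interaction.  Each element inherits the interaction direction
(gained or lost) and the expression outcome of the interaction's bait gene
(up, down or no change), yielding six possible categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import (
    DeRecord,
    GenomicInterval,
    InteractionRecord,
    PeakRecord,
)

logger = logging.getLogger("rebel")

INTERACTION_STATES = ("gained", "lost")
EXPRESSION_STATES = ("up", "down", "no_change")


@dataclass(frozen=True, order=True)
class CategoryLabel:
    """One of the six interaction-change x expression-change categories."""

    interaction: str
    expression: str

    def __post_init__(self) -> None:
        if self.interaction not in INTERACTION_STATES:
            raise ValueError(f"interaction must be one of {INTERACTION_STATES}")
        if self.expression not in EXPRESSION_STATES:
            raise ValueError(f"expression must be one of {EXPRESSION_STATES}")

    @property
    def code(self) -> str:
        return f"{self.interaction}_{self.expression}"

    @classmethod
    def from_code(cls, code: str) -> "CategoryLabel":
        inter, _, expr = code.partition("_")
        return cls(inter, expr)

    @classmethod
    def all_labels(cls) -> tuple["CategoryLabel", ...]:
        return tuple(
            cls(i, e) for i in INTERACTION_STATES for e in EXPRESSION_STATES
        )


@dataclass(frozen=True)
class ElementRecord:
    """A categorized analysis window centered on a peak summit."""

    peak: PeakRecord
    window: GenomicInterval
    category: CategoryLabel
    gene_id: str
    end_type: str  # "promoter" (bait side) or "distal" (other-end side)
    fusion_bound: bool = True

    def __post_init__(self) -> None:
        if self.end_type not in ("promoter", "distal"):
            raise ValueError(f"invalid end_type {self.end_type!r}")

    @property
    def element_id(self) -> str:
        return f"{self.peak.name}|{self.category.code}|{self.end_type}"


def label_expression(
    de: Sequence[DeRecord], alpha: float = 0.05
) -> dict[str, str]:
    """Map each gene to up / down / no_change at adjusted-p threshold alpha.

    A gene is up when adj_p <= alpha and log2fc > 0, down when adj_p <= alpha
    and log2fc < 0, and no_change otherwise (including the degenerate
    significant-but-zero-fold case).  Duplicate gene ids are an error.
    """
    labels: dict[str, str] = {}
    for rec in de:
        if rec.gene_id in labels:
            raise ValueError(f"duplicate gene id {rec.gene_id!r} in DE table")
        if rec.adj_p <= alpha and rec.log2fc > 0:
            labels[rec.gene_id] = "up"
        elif rec.adj_p <= alpha and rec.log2fc < 0:
            labels[rec.gene_id] = "down"
        else:
            labels[rec.gene_id] = "no_change"
    return labels


def flag_fusion_association(
    interactions: Sequence[InteractionRecord],
    fusion_peaks: Sequence[PeakRecord],
    mode: str = "either",
) -> list[bool]:
    """Flag interactions whose bait and/or other-end overlaps a fusion peak.

    ``mode`` selects which fragment must carry the binding site: "either"
    (default, most inclusive), "bait" or "oe".  Overlap is >= 1 bp.
    """
    if mode not in ("either", "bait", "oe"):
        raise ValueError(f"invalid mode {mode!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in fusion_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )

    def _hit(iv: GenomicInterval) -> bool:
        return any(
            iv.start < e and s < iv.end for s, e in by_chrom.get(iv.chrom, ())
        )

    flags = []
    for rec in interactions:
        bait_hit = _hit(rec.bait)
        oe_hit = _hit(rec.other_end)
        if mode == "bait":
            flags.append(bait_hit)
        elif mode == "oe":
            flags.append(oe_hit)
        else:
            flags.append(bait_hit or oe_hit)
    logger.info(
        "flag_fusion_association: %d / %d interactions flagged",
        sum(flags), len(flags),
    )
    return flags


def assign_categories(
    atac_peaks: Sequence[PeakRecord],
    consensus_diffs: Sequence,  # DifferentialInteraction from .diffint
    expr_labels: Mapping[str, str],
    fusion_flags: Sequence[bool] | None = None,
    window: int = 400,
    genome_lengths: Mapping[str, int] | None = None,
    unique_elements: bool = False,
) -> list[ElementRecord]:
    """Build categorized element windows from differential interactions.

    For each fusion-associated differential interaction, ATAC peaks overlapping
    the bait fragment become promoter elements and peaks overlapping the
    other-end fragment become distal elements; the category combines the
    interaction direction with the bait gene's expression label.  The analysis
    window is [summit - window//2, summit + window//2), so odd window sizes are
    right-heavy by one base.  Windows that would extend beyond their contig
    (when ``genome_lengths`` is supplied) are dropped with a warning rather
    than truncated.  With ``unique_elements`` peaks appearing in more than one
    category are dropped entirely (strict mode); by default a peak may appear
    once per category.
    """
    if fusion_flags is None:
        fusion_flags = [True] * len(consensus_diffs)
    if len(fusion_flags) != len(consensus_diffs):
        raise ValueError("fusion_flags length must match consensus_diffs")

    peaks_by_chrom: dict[str, list[PeakRecord]] = {}
    for p in atac_peaks:
        peaks_by_chrom.setdefault(p.interval.chrom, []).append(p)

    seen: set[tuple[str, str, str]] = set()  # (peak name, category, end_type)
    elements: list[ElementRecord] = []
    half = window // 2
    n_unlabeled = 0
    n_clipped = 0

    for diff, flagged in zip(consensus_diffs, fusion_flags):
        if not flagged:
            continue
        rec: InteractionRecord = diff.record
        expr = expr_labels.get(rec.bait_gene)
        if expr is None:
            n_unlabeled += 1
            continue
        category = CategoryLabel(diff.direction, expr)
        for frag, end_type in ((rec.bait, "promoter"), (rec.other_end, "distal")):
            for peak in peaks_by_chrom.get(frag.chrom, ()):
                if not peak.interval.overlaps(frag):
                    continue
                key = (peak.name, category.code, end_type)
                if key in seen:
                    continue
                seen.add(key)
                start = peak.summit - half
                end = peak.summit + (window - half)
                contig_len = (
                    genome_lengths.get(frag.chrom) if genome_lengths else None
                )
                if start < 0 or (contig_len is not None and end > contig_len):
                    logger.warning(
                        "assign_categories: window for peak %s clipped by "
                        "contig bounds; element dropped", peak.name,
                    )
                    n_clipped += 1
                    continue
                elements.append(
                    ElementRecord(
                        peak=peak,
                        window=GenomicInterval(frag.chrom, start, end),
                        category=category,
                        gene_id=rec.bait_gene,
                        end_type=end_type,
                    )
                )

    if unique_elements:
        cats_per_peak: dict[str, set[str]] = {}
        for el in elements:
            cats_per_peak.setdefault(el.peak.name, set()).add(el.category.code)
        before = len(elements)
        elements = [
            el for el in elements if len(cats_per_peak[el.peak.name]) == 1
        ]
        logger.info(
            "assign_categories: strict mode dropped %d multi-category elements",
            before - len(elements),
        )

    elements.sort(key=lambda e: (e.category, e.peak.name, e.end_type))
    logger.info(
        "assign_categories: %d elements (%d interactions without expression "
        "label, %d windows clipped)", len(elements), n_unlabeled, n_clipped,
    )
    return elements
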