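"""Planted-signature synthetic benchmark bundles.

The generator emulates the full input surface of the pipeline — a genome, ATAC
peaks with summits, fusion-protein binding peaks, a motif library,
per-replicate promoter-interaction counts and a differential-expression table
— with known ground truth.  Each category of elements can carry a planted
combinatorial motif signature: required motif consensi inserted at controlled
penetrance over a Poisson background of other motifs, with forbidden motifs
never inserted, so both presence and absence of a binding site can be made
predictive.

Every quantity is a pure function of the master seed: each stage draws from a
child generator at a fixed offset from the master seed, so stages are
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categorize import CategoryLabel, ElementRecord
from .diffint import DifferentialInteraction
from .io_formats import (
    DeRecord,
    GenomicInterval,
    InteractionRecord,
    PeakRecord,
    Pwm,
    write_de_table,
    write_fasta,
    write_interactions,
    write_motif_library,
    write_peaks,
    write_table,
)

logger = logging.getLogger("rebel")

# fixed offsets from the master seed, one child generator per stage
_STAGE_OFFSETS = {
    "library": 1_001,
    "elements": 2_001,
    "interactions": 3_001,
    "expression": 4_001,
    "permute": 5_001,
}


@dataclass(frozen=True)
class PlantedSignature:
    """Category-specific combinatorial motif signature.

    Each required motif's consensus is inserted into an element of the
    category independently with probability ``penetrance``; forbidden motifs
    are never inserted there (their absence becomes informative).  All other
    motifs arrive as background insertions at rate ``background_rate``
    (expected insertions per motif per element).
    """

    category: CategoryLabel
    required_motifs: frozenset[str]
    forbidden_motifs: frozenset[str] = frozenset()
    penetrance: float = 0.6
    background_rate: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_motifs",
                           frozenset(self.required_motifs))
        object.__setattr__(self, "forbidden_motifs",
                           frozenset(self.forbidden_motifs))
        if self.required_motifs & self.forbidden_motifs:
            raise ValueError("required and forbidden motif sets overlap")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance outside [0, 1]")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic bundle."""

    n_motifs: int = 436
    elements_per_category: int = 300
    window: int = 400
    seed: int = 1
    signatures: tuple[PlantedSignature, ...] = ()
    background_rate: float = 0.05  # for categories without a signature
    read_depth: int = 50
    n_replicates: int = 3
    effect_fold: float = 4.0
    effect_fraction: float = 1.0
    motif_min_len: int = 8
    motif_max_len: int = 12
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "signatures", tuple(self.signatures))
        if self.window % 2:
            raise ValueError("window must be even")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.effect_fold <= 0:
            raise ValueError("fold change must be > 0")
        cats = [s.category for s in self.signatures]
        if len(set(cats)) != len(cats):
            raise ValueError("at most one signature per category")

    def signature_for(self, category: CategoryLabel) -> PlantedSignature:
        for s in self.signatures:
            if s.category == category:
                return s
        return PlantedSignature(
            category=category,
            required_motifs=frozenset(),
            penetrance=0.0,
            background_rate=self.background_rate,
        )


def _rng(config: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(config.seed + _STAGE_OFFSETS[stage])


# ---------------------------------------------------------------------------
# motif library
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_motif_library(
    config: SyntheticConfig,
    min_len: int | None = None,
    max_len: int | None = None,
    threshold_fraction: float | None = None,
) -> list[Pwm]:
    """Information-rich PWMs with distinct consensus strings.

    Consensus bases carry probability 0.82-0.95 (per-position information
    content >= 1 bit), the remainder split evenly.  Detection threshold is
    ``threshold_fraction`` of the maximum achievable log-odds score, which the
    consensus itself always exceeds.
    """
    if config.n_motifs < 2:
        raise ValueError("need at least 2 motifs")
    min_len = min_len if min_len is not None else config.motif_min_len
    max_len = max_len if max_len is not None else config.motif_max_len
    if threshold_fraction is None:
        threshold_fraction = config.threshold_fraction
    rng = _rng(config, "library")
    seen: set[str] = set()
    pwms: list[Pwm] = []
    while len(pwms) < config.n_motifs:
        L = int(rng.integers(min_len, max_len + 1))
        cons_idx = rng.integers(0, 4, size=L)
        consensus = "".join(_BASES[cons_idx])
        if consensus in seen:
            continue
        seen.add(consensus)
        p_major = rng.uniform(0.82, 0.95, size=L)
        mat = np.full((L, 4), 0.0)
        mat[:] = ((1.0 - p_major) / 3.0)[:, None]
        mat[np.arange(L), cons_idx] = p_major
        probe = Pwm(f"M{len(pwms):04d}", mat, detection_threshold=-np.inf)
        pwms.append(
            Pwm(
                motif_id=f"M{len(pwms):04d}",
                matrix=mat,
                detection_threshold=threshold_fraction * probe.max_score,
            )
        )
    return pwms


# ---------------------------------------------------------------------------
# elements: genome, peaks, labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementTruth:
    """Ground truth for one synthetic element."""

    element: str        # contig name
    peak_name: str
    gene_id: str
    category: CategoryLabel
    planted_motifs: tuple[str, ...]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_COMP = np.array([3, 2, 1, 0], dtype=np.int8)


def _place_insertions(
    window_codes: np.ndarray,
    insertions: list[np.ndarray],
    rng: np.random.Generator,
    required_upto: int,
) -> list[int]:
    """Overwrite window positions with motif consensi, non-overlapping.

    Returns indices of insertions actually placed.  The first
    ``required_upto`` insertions must fit (error otherwise); later
    (background) insertions that no longer fit are skipped.
    """
    W = window_codes.shape[0]
    occupied = np.zeros(W, dtype=bool)
    placed: list[int] = []
    for k, codes in enumerate(insertions):
        L = codes.shape[0]
        if L > W:
            valid = np.empty(0, dtype=int)
        else:
            blocked = np.convolve(occupied.astype(int), np.ones(L, dtype=int),
                                  mode="valid")
            valid = np.flatnonzero(blocked == 0)
        if valid.size == 0:
            if k < required_upto:
                raise ValueError(
                    "window too small to host required motifs without overlap"
                )
            continue
        start = int(rng.choice(valid))
        window_codes[start : start + L] = codes
        occupied[start : start + L] = True
        placed.append(k)
    return placed


def generate_elements(
    config: SyntheticConfig, library: Sequence[Pwm]
) -> tuple[dict[str, str], list[PeakRecord], list[PeakRecord],
           list[ElementTruth]]:
    """Generate the genome, ATAC peaks, fusion peaks and element truth.

    One contig per element, 5x the window long: the other-end fragment
    occupies the first 2 windows (the ATAC peak and its planted-signature
    window sit in its middle, the fusion-binding peak at the window edge) and
    the bait fragment the last 2 windows.  Signature and background motif
    consensi are written into the analysis window on a random strand at
    uniform non-overlapping positions.
    """
    by_id = {p.motif_id: p for p in library}
    for sig in config.signatures:
        missing = (sig.required_motifs | sig.forbidden_motifs) - set(by_id)
        if missing:
            raise ValueError(f"signature references unknown motifs {missing}")
    rng = _rng(config, "elements")
    W = config.window
    contig_len = 5 * W
    win_start = W // 2          # window is contig[W/2 : W/2 + W]
    genome: dict[str, str] = {}
    atac: list[PeakRecord] = []
    fusion: list[PeakRecord] = []
    truth: list[ElementTruth] = []
    motif_ids = [p.motif_id for p in library]

    for category in CategoryLabel.all_labels():
        sig = config.signature_for(category)
        required = sorted(sig.required_motifs)
        req_len = sum(len(by_id[m]) for m in required)
        if req_len > W:
            raise ValueError(
                "window too small to host required motifs without overlap"
            )
        background_ids = [
            m for m in motif_ids if m not in sig.forbidden_motifs
        ]
        for i in range(config.elements_per_category):
            name = f"elem_{category.code}_{i:04d}"
            codes = _random_seq(rng, contig_len)
            insertions: list[np.ndarray] = []
            planted: list[str] = []
            for m in required:
                if rng.random() < sig.penetrance:
                    cons = by_id[m].matrix.argmax(axis=1).astype(np.int8)
                    if rng.random() < 0.5:
                        cons = _COMP[cons[::-1]]
                    insertions.append(cons)
                    planted.append(m)
            required_upto = len(insertions)
            if sig.background_rate > 0:
                n_bg = rng.poisson(sig.background_rate, size=len(background_ids))
                for m, k in zip(background_ids, n_bg):
                    for _ in range(int(k)):
                        cons = by_id[m].matrix.argmax(axis=1).astype(np.int8)
                        if rng.random() < 0.5:
                            cons = _COMP[cons[::-1]]
                        insertions.append(cons)
            window_codes = codes[win_start : win_start + W]
            _place_insertions(window_codes, insertions, rng, required_upto)
            genome[name] = "".join(_BASES[codes])
            atac.append(
                PeakRecord(
                    interval=GenomicInterval(name, win_start, win_start + W),
                    summit_offset=W // 2,
                    name=f"peak_{category.code}_{i:04d}",
                    score=100.0,
                )
            )
            fusion.append(
                PeakRecord(
                    interval=GenomicInterval(name, W - 20, W + 20),
                    summit_offset=20,
                    name=f"fusion_{category.code}_{i:04d}",
                )
            )
            truth.append(
                ElementTruth(
                    element=name,
                    peak_name=atac[-1].name,
                    gene_id=f"gene_{category.code}_{i:04d}",
                    category=category,
                    planted_motifs=tuple(planted),
                )
            )
    logger.info(
        "generate_elements: %d elements across %d categories",
        len(truth), len(CategoryLabel.all_labels()),
    )
    return genome, atac, fusion, truth


# ---------------------------------------------------------------------------
# interactions and expression
# ---------------------------------------------------------------------------


def generate_interaction_tables(
    config: SyntheticConfig, truth: Sequence[ElementTruth]
) -> tuple[list[InteractionRecord], pd.DataFrame]:
    """Per-replicate interaction counts with planted direction effects.

    Control counts are Poisson(read_depth) per replicate.  With probability
    ``effect_fraction`` a pair carries a true effect: induced counts are
    Poisson(depth x fold) for gained labels and Poisson(depth / fold) for
    lost labels; otherwise induced counts follow the control law.  The truth
    frame records which pairs carry effects.
    """
    if config.effect_fold <= 0:
        raise ValueError("fold change must be > 0")
    rng = _rng(config, "interactions")
    W = config.window
    records: list[InteractionRecord] = []
    rows = []
    for t in truth:
        is_effect = (config.effect_fold != 1.0
                     and rng.random() < config.effect_fraction)
        depth = config.read_depth
        if not is_effect:
            mean_ind = depth
        elif t.category.interaction == "gained":
            mean_ind = depth * config.effect_fold
        else:
            mean_ind = depth / config.effect_fold
        records.append(
            InteractionRecord(
                bait=GenomicInterval(t.element, 3 * W, 5 * W),
                bait_gene=t.gene_id,
                other_end=GenomicInterval(t.element, 0, 2 * W),
                counts_control=tuple(
                    rng.poisson(depth) for _ in range(config.n_replicates)
                ),
                counts_induced=tuple(
                    rng.poisson(mean_ind) for _ in range(config.n_replicates)
                ),
            )
        )
        rows.append(
            {
                "element": t.element,
                "gene_id": t.gene_id,
                "direction": t.category.interaction,
                "is_effect": bool(is_effect),
            }
        )
    return records, pd.DataFrame(rows)


def generate_expression_table(
    config: SyntheticConfig, truth: Sequence[ElementTruth]
) -> list[DeRecord]:
    """A DE table consistent with the planted expression labels."""
    rng = _rng(config, "expression")
    out = []
    for t in truth:
        expr = t.category.expression
        if expr == "up":
            rec = DeRecord(t.gene_id, float(rng.uniform(1.0, 3.0)),
                           float(rng.uniform(0.0, 0.05)))
        elif expr == "down":
            rec = DeRecord(t.gene_id, float(-rng.uniform(1.0, 3.0)),
                           float(rng.uniform(0.0, 0.05)))
        else:
            rec = DeRecord(t.gene_id, float(rng.uniform(-0.3, 0.3)),
                           float(rng.uniform(0.051, 1.0)))
        out.append(rec)
    return out


def truth_differentials(
    records: Sequence[InteractionRecord], truth: Sequence[ElementTruth]
) -> list[DifferentialInteraction]:
    """Oracle consensus differentials straight from the planted directions."""
    by_gene = {t.gene_id: t for t in truth}
    return [
        DifferentialInteraction(
            record=r,
            replicate_pvalues=(0.0,) * r.n_replicates,
            adj_p=0.0,
            direction=by_gene[r.bait_gene].category.interaction,
            n_supporting_replicates=r.n_replicates,
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticBundle:
    config: SyntheticConfig
    library: tuple[Pwm, ...]
    genome: Mapping[str, str]
    atac_peaks: tuple[PeakRecord, ...]
    fusion_peaks: tuple[PeakRecord, ...]
    truth: tuple[ElementTruth, ...]
    interactions: tuple[InteractionRecord, ...]
    interaction_truth: pd.DataFrame
    de_records: tuple[DeRecord, ...]

    @property
    def truth_diffs(self) -> list[DifferentialInteraction]:
        return truth_differentials(self.interactions, self.truth)

    def category_of_element_id(self) -> dict[str, CategoryLabel]:
        """Map categorize-style element ids to their planted category."""
        return {
            f"{t.peak_name}|{t.category.code}|distal": t.category
            for t in self.truth
        }


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    library = generate_motif_library(config)
    genome, atac, fusion, truth = generate_elements(config, library)
    interactions, itruth = generate_interaction_tables(config, truth)
    de = generate_expression_table(config, truth)
    return SyntheticBundle(
        config=config,
        library=tuple(library),
        genome=genome,
        atac_peaks=tuple(atac),
        fusion_peaks=tuple(fusion),
        truth=tuple(truth),
        interactions=tuple(interactions),
        interaction_truth=itruth,
        de_records=tuple(de),
    )


def default_signatures(
    library: Sequence[Pwm],
    n_required: int = 3,
    penetrance: float = 0.6,
    background_rate: float = 0.05,
    forbid_cross: bool = True,
) -> tuple[PlantedSignature, ...]:
    """Disjoint per-category signatures over the first motifs of a library.

    Category k receives motifs [k*n_required, (k+1)*n_required) as required;
    with ``forbid_cross`` every other category's required motifs are forbidden
    in k, making absence as well as presence informative.
    """
    cats = CategoryLabel.all_labels()
    ids = [p.motif_id for p in library]
    if len(ids) < n_required * len(cats):
        raise ValueError("library too small for disjoint signatures")
    blocks = [
        frozenset(ids[k * n_required : (k + 1) * n_required])
        for k in range(len(cats))
    ]
    sigs = []
    for k, cat in enumerate(cats):
        forbidden = frozenset()
        if forbid_cross:
            forbidden = frozenset().union(
                *(b for j, b in enumerate(blocks) if j != k)
            )
        sigs.append(
            PlantedSignature(
                category=cat,
                required_motifs=blocks[k],
                forbidden_motifs=forbidden,
                penetrance=penetrance,
                background_rate=background_rate,
            )
        )
    return tuple(sigs)


def standard_config(
    seed: int = 1,
    planted: bool = False,
    n_motifs: int = 436,
    elements_per_category: int = 300,
    penetrance: float = 0.6,
    background_rate: float = 0.05,
) -> SyntheticConfig:
    """The bundle configurations the benchmark results are reported on.

    ``planted=False`` gives the null bundle (background insertions only, no
    signatures); ``planted=True`` adds disjoint three-motif signatures per
    category at the given penetrance.
    """
    config = SyntheticConfig(
        n_motifs=n_motifs,
        elements_per_category=elements_per_category,
        seed=seed,
        background_rate=background_rate,
    )
    if planted:
        library = generate_motif_library(config)
        config = replace(
            config,
            signatures=default_signatures(
                library, penetrance=penetrance,
                background_rate=background_rate,
            ),
        )
    return config


def permute_element_categories(
    elements: Sequence[ElementRecord], seed: int
) -> list[ElementRecord]:
    """Randomly permute category labels across elements (null protocol)."""
    rng = np.random.default_rng(seed + _STAGE_OFFSETS["permute"])
    cats = [e.category for e in elements]
    perm = rng.permutation(len(cats))
    return [
        replace(e, category=cats[perm[i]]) for i, e in enumerate(elements)
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict:
    """Write the bundle in the formats the io module reads, plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_peaks(bundle.atac_peaks, outdir / "atac_peaks.narrowPeak")
    write_peaks(bundle.fusion_peaks, outdir / "fusion_peaks.narrowPeak")
    write_motif_library(bundle.library, outdir / "motifs.homer")
    write_de_table(bundle.de_records, outdir / "expression.tsv")
    write_interactions(bundle.interactions, outdir / "interactions.tsv")
    truth_df = pd.DataFrame(
        {
            "element": [t.element for t in bundle.truth],
            "peak_name": [t.peak_name for t in bundle.truth],
            "gene_id": [t.gene_id for t in bundle.truth],
            "category": [t.category.code for t in bundle.truth],
            "planted_motifs": [
                ",".join(t.planted_motifs) for t in bundle.truth
            ],
        }
    )
    write_table(truth_df, outdir / "truth_elements.tsv")
    write_table(bundle.interaction_truth, outdir / "truth_interactions.tsv")
    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": {
            "n_motifs": bundle.config.n_motifs,
            "elements_per_category": bundle.config.elements_per_category,
            "window": bundle.config.window,
            "seed": bundle.config.seed,
            "background_rate": bundle.config.background_rate,
            "read_depth": bundle.config.read_depth,
            "n_replicates": bundle.config.n_replicates,
            "effect_fold": bundle.config.effect_fold,
            "effect_fraction": bundle.config.effect_fraction,
            "n_signatures": len(bundle.config.signatures),
        },
        "files": {name: _sha256(outdir / name) for name in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
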