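"""PWM scanning of element windows and motif count-matrix construction.

The scanner counts, per window, the start positions whose best log-odds score
over the two strands reaches the motif's detection threshold.  Unknown bases
(N) contribute zero log-odds at their position, i.e. they score as background.
The count matrix is motifs x elements with a column-wise log10(x + 1)
transformed view, the classifier's feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .categorize import ElementRecord
from .io_formats import Pwm

logger = logging.getLogger("rebel")

_BASE_INDEX = np.full(256, 4, dtype=np.int8)  # everything unknown -> 4 (N)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _lodds_with_n(pwm: Pwm) -> np.ndarray:
    """L x 5 log-odds table; column 4 (N) contributes 0."""
    lo = np.zeros((len(pwm), 5))
    lo[:, :4] = pwm.log_odds
    return lo


def _scan_encoded(codes: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Per-window hit counts for an (n_windows, W) encoded sequence block."""
    L = len(pwm)
    W = codes.shape[1]
    if W < L:
        return np.zeros(codes.shape[0], dtype=int)
    lo = _lodds_with_n(pwm)
    # reverse-strand hit at start p == reverse-complemented matrix scored
    # forward at p; complement maps base b -> 3 - b, N stays N
    lo_rc = np.zeros((L, 5))
    lo_rc[:, :4] = pwm.log_odds[::-1, ::-1]
    windows = sliding_window_view(codes, L, axis=1)  # (n, P, L)
    pos = np.arange(L)
    fwd = lo[pos, windows].sum(axis=2)
    rev = lo_rc[pos, windows].sum(axis=2)
    best = np.maximum(fwd, rev)
    return (best >= pwm.detection_threshold - 1e-9).sum(axis=1)


def scan_window(sequence: str, pwm: Pwm) -> int:
    """Count binding sites of one motif in one window (both strands).

    A position is counted once even when both strands score above threshold
    (max over strands), avoiding palindromic double counting.  Sequences
    shorter than the motif yield 0.
    """
    codes = encode_sequence(sequence)[None, :]
    return int(_scan_encoded(codes, pwm)[0])


@dataclass(frozen=True)
class MotifMatrix:
    """Motifs x elements count matrix with its log10(x + 1) view."""

    element_ids: tuple[str, ...]
    motif_ids: tuple[str, ...]
    counts: np.ndarray  # (M, n) integers

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.motif_ids), len(self.element_ids)):
            raise ValueError("counts shape does not match id lists")
        if (c < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def transformed(self) -> np.ndarray:
        return np.log10(self.counts + 1.0)

    @property
    def features(self) -> np.ndarray:
        """Elements x motifs transformed matrix (model orientation)."""
        return self.transformed.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.motif_ids),
            columns=list(self.element_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotifMatrix":
        return cls(
            element_ids=tuple(str(c) for c in df.columns),
            motif_ids=tuple(str(i) for i in df.index),
            counts=df.to_numpy(dtype=int),
        )

    def subset_elements(self, ids: Sequence[str]) -> "MotifMatrix":
        pos = {e: i for i, e in enumerate(self.element_ids)}
        idx = [pos[e] for e in ids]
        return MotifMatrix(tuple(ids), self.motif_ids, self.counts[:, idx])


def extract_window(genome: Mapping[str, str], element: ElementRecord) -> str:
    contig = genome.get(element.window.chrom)
    if contig is None:
        raise KeyError(
            f"element {element.element_id}: contig {element.window.chrom!r} "
            "missing from genome"
        )
    if element.window.end > len(contig):
        raise ValueError(
            f"element {element.element_id}: window extends past contig end"
        )
    return contig[element.window.start : element.window.end]


def build_matrix(
    elements: Sequence[ElementRecord],
    genome: Mapping[str, str],
    library: Sequence[Pwm],
) -> MotifMatrix:
    """Scan every element window with every motif in the library."""
    element_ids = tuple(e.element_id for e in elements)
    seqs = [extract_window(genome, e) for e in elements]
    return build_matrix_from_sequences(element_ids, seqs, library)


def build_matrix_from_sequences(
    element_ids: Sequence[str],
    sequences: Sequence[str],
    library: Sequence[Pwm],
) -> MotifMatrix:
    n = len(sequences)
    counts = np.zeros((len(library), n), dtype=int)
    if n:
        lengths = {len(s) for s in sequences}
        if len(lengths) == 1:
            codes = np.stack([encode_sequence(s) for s in sequences])
            for m, pwm in enumerate(library):
                counts[m] = _scan_encoded(codes, pwm)
        else:  # ragged windows: per-sequence scan
            for m, pwm in enumerate(library):
                counts[m] = [scan_window(s, pwm) for s in sequences]
    logger.info(
        "build_matrix: %d motifs x %d elements, %.2f mean sites/element",
        len(library), n, counts.sum() / n if n else 0.0,
    )
    return MotifMatrix(tuple(element_ids), tuple(p.motif_id for p in library),
                       counts)


def motif_presence_enrichment(
    fg_elements: Sequence[str],
    bg_elements: Sequence[str],
    matrix: MotifMatrix,
) -> pd.DataFrame:
    """Per-motif Fisher-exact test of presence in foreground vs background.

    Presence means count > 0.  Returns a frame with odds ratio, raw p and
    BH-adjusted p per motif, sorted by descending odds ratio then ascending p.
    Foreground and background must be disjoint and non-empty.
    """
    fg, bg = set(fg_elements), set(bg_elements)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if fg & bg:
        raise ValueError("foreground and background overlap")
    pos = {e: i for i, e in enumerate(matrix.element_ids)}
    fg_idx = [pos[e] for e in fg_elements]
    bg_idx = [pos[e] for e in bg_elements]
    present = matrix.counts > 0
    rows = []
    for m, motif in enumerate(matrix.motif_ids):
        a = int(present[m, fg_idx].sum())      # fg present
        b = len(fg_idx) - a                    # fg absent
        c = int(present[m, bg_idx].sum())      # bg present
        d = len(bg_idx) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"motif_id": motif, "fg_present": a, "bg_present": c,
             "odds_ratio": odds, "p": p}
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = stats.false_discovery_control(df["p"], method="bh")
    return df.sort_values(
        ["odds_ratio", "p"], ascending=[False, True]
    ).reset_index(drop=True)
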