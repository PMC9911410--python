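"""Differential promoter-interaction statistics.

Each induced replicate is compared directly against its paired control
replicate: the induced read count of a fragment pair is tested against a
binomial null whose expected proportion comes from the control condition.
Per-comparison p-values are FDR-adjusted within distance strata (a
covariate-weighted surrogate for independent hypothesis weighting), and a
consensus set keeps pairs significant in the same direction in at least two
replicate comparisons.  A 4-kb fragment matcher and a Monte-Carlo overlap
test support cross-dataset comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import InteractionRecord

logger = logging.getLogger("rebel")

#: pseudo-count added to control reads when forming the expected proportion,
#: avoiding a degenerate p-hat of zero for pairs unobserved in the control.
CONTROL_PSEUDOCOUNT = 0.5

#: two interactions with the same bait gene match when their other-end
#: midpoints lie within this many bp on the same contig.
MATCH_WINDOW_BP = 4000


@dataclass(frozen=True)
class LibraryStats:
    """Total read counts of the two conditions (normalizing denominators)."""

    total_control: int
    total_induced: int

    def __post_init__(self) -> None:
        if self.total_control <= 0 or self.total_induced <= 0:
            raise ValueError("library totals must be > 0")


@dataclass(frozen=True)
class DifferentialInteraction:
    """A consensus differential fragment pair with its supporting evidence."""

    record: InteractionRecord
    replicate_pvalues: tuple[float, ...]
    adj_p: float
    direction: str  # "gained" | "lost"
    n_supporting_replicates: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError("adj_p outside [0, 1]")
        if self.direction not in ("gained", "lost"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.n_supporting_replicates < 0:
            raise ValueError("n_supporting_replicates must be >= 0")


def binomial_diff_test(
    o_ind: int, o_ctrl: int, stats_: LibraryStats
) -> tuple[float, float]:
    """Exact binomial tail probabilities for one fragment pair.

    The expected proportion is p-hat = (o_ctrl + 0.5) / N_ctrl; with
    X ~ Binomial(N_ind, p-hat), p_gain = P[X >= o_ind] and
    p_loss = P[X <= o_ind].  Both tails share the atom at o_ind, so
    p_gain + p_loss >= 1 always.
    """
    if o_ind < 0 or o_ctrl < 0:
        raise ValueError("counts must be >= 0")
    if o_ind > stats_.total_induced:
        raise ValueError("o_ind exceeds induced library total")
    p_hat = min(1.0, (o_ctrl + CONTROL_PSEUDOCOUNT) / stats_.total_control)
    n = stats_.total_induced
    # sf(k-1) = P[X >= k]; cdf(k) = P[X <= k]
    p_gain = float(stats.binom.sf(o_ind - 1, n, p_hat))
    p_loss = float(stats.binom.cdf(o_ind, n, p_hat))
    return min(p_gain, 1.0), min(p_loss, 1.0)


def adjust_fdr_distance_weighted(
    pvalues: Sequence[float],
    distances: Sequence[int],
    n_strata: int = 5,
) -> np.ndarray:
    """Benjamini-Hochberg within distance-quantile strata.

    This is a dependency-light surrogate for independent hypothesis weighting
    with interaction distance as the informative covariate: p-values are
    binned into ``n_strata`` distance quantiles and BH is applied within each
    bin.  Trans pairs (distance -1) form their own stratum.  With one stratum
    the result is plain BH.  Adjusted values are never below the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    d = np.asarray(distances, dtype=float)
    if p.shape != d.shape:
        raise ValueError("pvalues and distances must have equal length")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    if p.size == 0:
        return np.empty(0)

    adjusted = np.empty_like(p)
    cis = d >= 0
    strata: list[np.ndarray] = []
    if (~cis).any():
        strata.append(np.flatnonzero(~cis))
    if cis.any():
        cis_idx = np.flatnonzero(cis)
        if n_strata == 1 or cis_idx.size <= n_strata:
            strata.append(cis_idx)
        else:
            # quantile bins over cis distances; duplicate edges merged, and
            # fully degenerate (constant-distance) input collapses to one bin
            ranks = np.asarray(
                pd.qcut(d[cis_idx], q=n_strata, labels=False,
                        duplicates="drop"),
                dtype=float,
            )
            ranks[np.isnan(ranks)] = 0
            for b in np.unique(ranks):
                strata.append(cis_idx[ranks == b])
    for idx in strata:
        bh = stats.false_discovery_control(p[idx], method="bh")
        adjusted[idx] = np.minimum(np.maximum(bh, p[idx]), 1.0)
    return adjusted


@dataclass(frozen=True)
class ReplicateCall:
    """Per-replicate-comparison test results for a set of fragment pairs."""

    records: tuple[InteractionRecord, ...]
    p_gain: np.ndarray
    p_loss: np.ndarray
    adj_p_gain: np.ndarray
    adj_p_loss: np.ndarray


def test_replicate_pair(
    records: Sequence[InteractionRecord],
    replicate: int,
    n_strata: int = 5,
) -> ReplicateCall:
    """Run the binomial test for one induced-vs-control replicate pairing."""
    o_ctrl = np.array([r.counts_control[replicate] for r in records])
    o_ind = np.array([r.counts_induced[replicate] for r in records])
    lib = LibraryStats(
        total_control=int(o_ctrl.sum()) or 1,
        total_induced=int(o_ind.sum()) or 1,
    )
    pg = np.empty(len(records))
    pl = np.empty(len(records))
    for i, (oi, oc) in enumerate(zip(o_ind, o_ctrl)):
        pg[i], pl[i] = binomial_diff_test(int(oi), int(oc), lib)
    dists = np.array([r.distance for r in records])
    return ReplicateCall(
        records=tuple(records),
        p_gain=pg,
        p_loss=pl,
        adj_p_gain=adjust_fdr_distance_weighted(pg, dists, n_strata),
        adj_p_loss=adjust_fdr_distance_weighted(pl, dists, n_strata),
    )


def call_consensus_differentials(
    replicate_calls: Sequence[ReplicateCall],
    min_replicates: int = 2,
    fdr: float = 0.01,
) -> list[DifferentialInteraction]:
    """Combine per-replicate calls into a consensus differential set.

    A fragment pair is a consensus differential iff its adjusted p-value is
    <= ``fdr`` with the SAME direction in at least ``min_replicates``
    replicate comparisons.  Pairs significant in opposite directions across
    replicates (without a same-direction majority reaching the threshold) are
    excluded.
    """
    if len(replicate_calls) < 2:
        raise ValueError("need >= 2 replicate comparisons for a consensus")
    n = len(replicate_calls[0].records)
    if any(len(c.records) != n for c in replicate_calls):
        raise ValueError("replicate calls cover different record sets")

    out: list[DifferentialInteraction] = []
    for i in range(n):
        gains = [c.adj_p_gain[i] for c in replicate_calls]
        losses = [c.adj_p_loss[i] for c in replicate_calls]
        n_gain = sum(p <= fdr for p in gains)
        n_loss = sum(p <= fdr for p in losses)
        if n_gain >= min_replicates and n_gain >= n_loss:
            direction, support, adj = "gained", n_gain, gains
        elif n_loss >= min_replicates and n_loss > n_gain:
            direction, support, adj = "lost", n_loss, losses
        else:
            continue
        out.append(
            DifferentialInteraction(
                record=replicate_calls[0].records[i],
                replicate_pvalues=tuple(float(p) for p in adj),
                adj_p=float(min(adj)),
                direction=direction,
                n_supporting_replicates=int(support),
            )
        )
    logger.info(
        "call_consensus_differentials: %d / %d pairs pass (fdr %.3g, "
        ">= %d replicates)", len(out), n, fdr, min_replicates,
    )
    return out


def differential_interactions(
    records: Sequence[InteractionRecord],
    min_replicates: int = 2,
    fdr: float = 0.01,
    n_strata: int = 5,
) -> list[DifferentialInteraction]:
    """Full pipeline: per-replicate tests, stratified FDR, consensus."""
    if not records:
        return []
    n_rep = records[0].n_replicates
    calls = [
        test_replicate_pair(records, r, n_strata) for r in range(n_rep)
    ]
    return call_consensus_differentials(calls, min_replicates, fdr)


def _oe_mid(diff) -> int:
    rec = diff.record if hasattr(diff, "record") else diff
    return rec.other_end.midpoint


def _as_record(x) -> InteractionRecord:
    return x.record if hasattr(x, "record") else x


def match_interactions_4kb(
    set_a: Sequence, set_b: Sequence, window: int = MATCH_WINDOW_BP
) -> list[tuple[int, int, int]]:
    """Match interactions across two sets by bait gene and other-end position.

    Two interactions match when their baits carry the same gene and their
    other-end midpoints lie within ``window`` bp on the same contig.  Each
    a-interaction is paired with at most its nearest b-interaction (ties
    broken by smaller other-end start).  Returns (index_a, index_b, distance)
    triples.
    """
    by_gene: dict[str, list[int]] = {}
    for j, b in enumerate(set_b):
        by_gene.setdefault(_as_record(b).bait_gene, []).append(j)

    pairs: list[tuple[int, int, int]] = []
    for i, a in enumerate(set_a):
        ra = _as_record(a)
        best: tuple[int, int, int] | None = None  # (dist, start, j)
        for j in by_gene.get(ra.bait_gene, ()):
            rb = _as_record(set_b[j])
            if rb.other_end.chrom != ra.other_end.chrom:
                continue
            dist = abs(ra.other_end.midpoint - rb.other_end.midpoint)
            if dist > window:
                continue
            cand = (dist, rb.other_end.start, j)
            if best is None or cand < best:
                best = cand
        if best is not None:
            pairs.append((i, best[2], best[0]))
    return pairs


def overlap_mc_test(
    query_set: Sequence,
    target_set: Sequence,
    universe: Sequence | None = None,
    n_sims: int = 20_000,
    seed: int = 0,
    window: int = MATCH_WINDOW_BP,
) -> dict:
    """Monte-Carlo test of the overlap between two interaction sets.

    ``observed`` is the number of query interactions with a 4-kb match in
    ``target_set``.  The null resamples ``n_sims`` uniform subsets of
    ``universe`` (default: the target set itself) of size |query| and matches
    each against the target set; the empirical p-value uses the
    add-one convention (1 + #{null >= observed}) / (n_sims + 1).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if universe is None:
        universe = target_set
    if len(query_set) > len(universe):
        raise ValueError("query larger than sampling universe")
    observed = len(match_interactions_4kb(query_set, target_set, window))
    rng = np.random.default_rng(seed)
    universe = list(universe)
    nulls = np.empty(n_sims, dtype=int)
    for s in range(n_sims):
        idx = rng.choice(len(universe), size=len(query_set), replace=False)
        subset = [universe[i] for i in idx]
        nulls[s] = len(match_interactions_4kb(subset, target_set, window))
    return {
        "observed": observed,
        "null_mean": float(nulls.mean()),
        "null_range": (int(nulls.min()), int(nulls.max())),
        "empirical_p": float((1 + (nulls >= observed).sum()) / (n_sims + 1)),
    }


def differentials_to_frame(
    diffs: Sequence[DifferentialInteraction],
) -> pd.DataFrame:
    rows = []
    for d in diffs:
        r = d.record
        rows.append(
            {
                "bait_chrom": r.bait.chrom,
                "bait_start": r.bait.start,
                "bait_end": r.bait.end,
                "bait_gene": r.bait_gene,
                "oe_chrom": r.other_end.chrom,
                "oe_start": r.other_end.start,
                "oe_end": r.other_end.end,
                "distance": r.distance,
                "direction": d.direction,
                "adj_p": d.adj_p,
                "n_supporting_replicates": d.n_supporting_replicates,
            }
        )
    return pd.DataFrame(rows)
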