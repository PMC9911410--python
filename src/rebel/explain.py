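"""Shapley attribution, embedding and density clustering of elements.

For each comparison's five models, elements the model predicted correctly are
kept; exact tree-path Shapley values are computed for every kept element from
the model that held it out, so interpretation never sees a training
prediction.  Attributions are embedded in 2-D with t-SNE, clustered with
DBSCAN (noise points excluded from reports), and each cluster's driver motifs
are ranked by mean absolute attribution, with a presence-mode call saying
whether having or lacking the site is what drives the prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from ._treeshap import parse_booster, shap_values
from .model import TrainedModelBundle

logger = logging.getLogger("rebel")


@dataclass(frozen=True)
class AttributionMatrix:
    """Signed per-element, per-motif Shapley contributions."""

    element_ids: tuple[str, ...]
    motif_ids: tuple[str, ...]
    values: np.ndarray        # (n, M)
    base_values: np.ndarray   # (n,) expected margin per element's model
    source_model: np.ndarray  # (n,) subset index

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.element_ids), len(self.motif_ids)):
            raise ValueError("values shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.element_ids),
            columns=list(self.motif_ids),
        )


@dataclass(frozen=True)
class ClusterDrivers:
    """Ranked driver motifs of one density cluster."""

    cluster_id: int
    members: tuple[str, ...]
    # (motif_id, mean attribution, presence_mode, contribution_fraction)
    top_motifs: tuple[tuple[str, float, str, float], ...]


def filter_correct_predictions(bundle: TrainedModelBundle) -> np.ndarray:
    """Indices of elements whose held-out prediction matches their label.

    A positive call requires predicted probability strictly above 0.5, so an
    exactly-0.5 prediction is correct only for a negative element.
    """
    pred_pos = bundle.heldout_predictions > 0.5
    return np.flatnonzero(pred_pos == (bundle.labels == 1))


def compute_attributions(
    bundle: TrainedModelBundle,
    features: np.ndarray,
    keep: Sequence[int] | None = None,
    motif_ids: Sequence[str] | None = None,
) -> AttributionMatrix:
    """Exact tree-path Shapley values from each element's held-out model.

    ``features`` is the full elements-x-motifs matrix aligned to
    ``bundle.element_ids``; ``keep`` indexes into it (defaults to the
    correctly predicted elements).  Attributions come from a float64 TreeSHAP
    over the parsed ensembles, so local accuracy — attributions plus the base
    value equal the model's margin (log-odds output) — holds to near machine
    precision on every element.
    """
    if keep is None:
        keep = filter_correct_predictions(bundle)
    keep = np.asarray(keep, dtype=int)
    X = np.asarray(features, dtype=float)
    n, M = len(keep), X.shape[1]
    values = np.empty((n, M))
    bases = np.empty(n)
    source = bundle.source_model[keep]
    if (source < 0).any():
        raise ValueError("element without a source model")
    for s in np.unique(source):
        rows = np.flatnonzero(source == s)
        trees = parse_booster(bundle.models[s])
        phi, base = shap_values(trees, X[keep[rows]])
        values[rows] = phi
        bases[rows] = base
    ids = tuple(bundle.element_ids[i] for i in keep)
    mids = tuple(motif_ids) if motif_ids is not None else tuple(
        f"f{j}" for j in range(M)
    )
    return AttributionMatrix(
        element_ids=ids, motif_ids=mids, values=values,
        base_values=bases, source_model=source,
    )


def embed_2d(
    matrix: np.ndarray, perplexity: float = 30.0, seed: int = 1
) -> np.ndarray:
    """Deterministic 2-D t-SNE embedding (PCA initialization, fixed seed)."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    min_n = int(3 * perplexity) + 1
    if n <= 3 * perplexity:
        raise ValueError(
            f"embedding needs more than 3 x perplexity = {min_n - 1} points, "
            f"got {n}"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, init="pca",
        learning_rate="auto", random_state=seed, n_jobs=1,
    )
    return tsne.fit_transform(X)


def estimate_eps(coords: np.ndarray, k: int = 4) -> float:
    """DBSCAN eps from the elbow of the sorted k-NN distance curve.

    The elbow is the point of the sorted k-th neighbour distances farthest
    from the chord joining the curve's endpoints (Kneedle-style, deterministic).
    """
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dists = np.sort(nn.kneighbors(coords)[0][:, -1])
    n = len(dists)
    if n < 3 or dists[-1] == dists[0]:
        return float(dists[-1]) or 1.0
    x = np.arange(n) / (n - 1)
    y = (dists - dists[0]) / (dists[-1] - dists[0])
    elbow = int(np.argmax(x - y)) if (x - y).max() > 0 else int(
        np.argmax(y - x)
    )
    return float(max(dists[elbow], np.finfo(float).tiny))


def cluster_density(
    coords: np.ndarray, eps: float | None = None, min_pts: int = 10
) -> np.ndarray:
    """DBSCAN labels; -1 marks noise points (excluded from driver reports)."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    if eps is None:
        eps = estimate_eps(coords)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    n_clusters = len(set(labels)) - (1 if -1 in labels else 0)
    logger.info(
        "cluster_density: %d clusters, %d noise points (eps %.4g)",
        n_clusters, int((labels == -1).sum()), eps,
    )
    return labels


def rank_cluster_drivers(
    attribs: AttributionMatrix,
    clusters: Sequence[int],
    counts: np.ndarray,
    k: int | None = 15,
    present_only: bool = False,
) -> list[ClusterDrivers]:
    """Per-cluster motif ranking by mean absolute attribution.

    ``counts`` is the raw site-count matrix aligned to ``attribs`` (n x M).
    A motif is present-predictive when the mean attribution among members
    carrying the site exceeds that among members lacking it (a missing group
    contributes a neutral 0); otherwise absent-predictive.  The contribution
    fraction normalizes mean |attribution| over all motifs, so fractions sum
    to 1 within a cluster.  With ``present_only`` the ranking is filtered to
    present-predictive motifs before truncation to the top k.
    """
    clusters = np.asarray(clusters, dtype=int)
    counts = np.asarray(counts)
    if counts.shape != attribs.values.shape:
        raise ValueError("counts must align with the attribution matrix")
    out: list[ClusterDrivers] = []
    for cid in sorted(set(clusters) - {-1}):
        members = np.flatnonzero(clusters == cid)
        if members.size == 0:
            logger.warning("rank_cluster_drivers: empty cluster %d skipped", cid)
            continue
        vals = attribs.values[members]            # (m, M)
        has = counts[members] > 0
        mean_abs = np.abs(vals).mean(axis=0)
        total = mean_abs.sum()
        fractions = mean_abs / total if total > 0 else mean_abs
        order = np.argsort(-mean_abs, kind="stable")
        rows = []
        for j in order:
            with_site = vals[has[:, j], j]
            without = vals[~has[:, j], j]
            m_pres = float(with_site.mean()) if with_site.size else 0.0
            m_abs = float(without.mean()) if without.size else 0.0
            mode = "present-predictive" if m_pres > m_abs else "absent-predictive"
            if present_only and mode != "present-predictive":
                continue
            rows.append(
                (
                    attribs.motif_ids[j],
                    float(vals[:, j].mean()),
                    mode,
                    float(fractions[j]),
                )
            )
            if k is not None and len(rows) == k:
                break
        out.append(
            ClusterDrivers(
                cluster_id=int(cid),
                members=tuple(attribs.element_ids[i] for i in members),
                top_motifs=tuple(rows),
            )
        )
    return out


def category_silhouette(
    coords: np.ndarray, category_codes: Sequence[str]
) -> float:
    """Mean silhouette of category labels in an embedding."""
    return float(silhouette_score(coords, np.asarray(category_codes)))


def drivers_to_frame(drivers: Sequence[ClusterDrivers]) -> pd.DataFrame:
    rows = []
    for d in drivers:
        for rank, (motif, mean_attr, mode, frac) in enumerate(d.top_motifs, 1):
            rows.append(
                {
                    "cluster_id": d.cluster_id,
                    "n_members": len(d.members),
                    "rank": rank,
                    "motif_id": motif,
                    "mean_attribution": mean_attr,
                    "presence_mode": mode,
                    "contribution_fraction": frac,
                }
            )
    return pd.DataFrame(rows)
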