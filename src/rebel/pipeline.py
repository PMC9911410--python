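"""End-to-end orchestration: differentials -> categories -> matrix -> models
-> attributions, with per-stage manifests, plus the in-memory benchmark
protocol used on synthetic bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import categorize as cat
from . import diffint, explain, motif_matrix, synthetic
from .categorize import CategoryLabel, ElementRecord
from .io_formats import (
    read_de_table,
    read_fasta,
    read_interactions,
    read_motif_library,
    read_peaks,
    write_table,
)
from .model import ModelConfig, TrainedModelBundle, train_one_vs_all

logger = logging.getLogger("rebel")


@dataclass(frozen=True)
class RunConfig:
    genome_fasta: Path
    atac_peaks: Path
    fusion_peaks: Path
    motifs: Path
    de_table: Path
    interactions: Path
    outdir: Path
    peaks_dialect: str = "narrowPeak"
    fusion_dialect: str = "narrowPeak"
    motif_dialect: str = "homer"
    window: int = 400
    fdr: float = 0.01
    min_replicates: int = 2
    n_strata: int = 5
    model: ModelConfig = field(default_factory=ModelConfig)
    perplexity: float = 30.0
    eps: float | None = None
    min_pts: int = 10
    topk: int = 15
    seed: int = 1

    def validate(self) -> None:
        for name in ("genome_fasta", "atac_peaks", "fusion_peaks", "motifs",
                     "de_table", "interactions"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _elements_frame(elements: Sequence[ElementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [e.element_id for e in elements],
            "peak_name": [e.peak.name for e in elements],
            "chrom": [e.window.chrom for e in elements],
            "window_start": [e.window.start for e in elements],
            "window_end": [e.window.end for e in elements],
            "category": [e.category.code for e in elements],
            "gene_id": [e.gene_id for e in elements],
            "end_type": [e.end_type for e in elements],
        }
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order, persisting outputs and a run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    manifest_path = outdir / "run_manifest.json"

    def _record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    try:
        # 1. differential interactions
        interactions = read_interactions(config.interactions)
        diffs = diffint.differential_interactions(
            interactions, config.min_replicates, config.fdr, config.n_strata
        )
        diffs_path = outdir / "differential_interactions.tsv"
        write_table(diffint.differentials_to_frame(diffs), diffs_path)
        _record("diffint", n_pairs=len(interactions), n_differential=len(diffs),
                output=str(diffs_path))

        # 2. categorize
        genome = read_fasta(config.genome_fasta)
        peaks = read_peaks(config.atac_peaks, config.peaks_dialect)
        fusion = read_peaks(config.fusion_peaks, config.fusion_dialect)
        expr = cat.label_expression(read_de_table(config.de_table))
        flags = cat.flag_fusion_association(
            [d.record for d in diffs], fusion
        )
        elements = cat.assign_categories(
            peaks, diffs, expr, flags, window=config.window,
            genome_lengths={c: len(s) for c, s in genome.items()},
        )
        elements_path = outdir / "elements.tsv"
        write_table(_elements_frame(elements), elements_path)
        _record("categorize", n_elements=len(elements),
                output=str(elements_path))

        # 3. motif matrix
        library = read_motif_library(config.motifs, config.motif_dialect)
        matrix = motif_matrix.build_matrix(elements, genome, library)
        matrix_path = outdir / "matrix.tsv"
        matrix.to_frame().to_csv(matrix_path, sep="\t",
                                 index_label="motif_id", lineterminator="\n")
        with open(outdir / "matrix_params.json", "w") as fh:
            json.dump({"n_motifs": len(matrix.motif_ids),
                       "n_elements": len(matrix.element_ids),
                       "window": config.window, "transform": "log10(x+1)"},
                      fh, indent=2)
            fh.write("\n")
        _record("matrix", shape=[len(matrix.motif_ids),
                                 len(matrix.element_ids)],
                output=str(matrix_path))

        # 4 + 5. models and attributions
        bundles, summary = run_models_and_explain(
            elements, matrix, config.model, outdir,
            perplexity=config.perplexity, eps=config.eps,
            min_pts=config.min_pts, topk=config.topk,
        )
        _record("train", categories={
            b.comparison: {"best_params": list(b.best_params),
                           "mean_auc": b.mean_auc}
            for b in bundles.values()
        })
        _record("explain", **summary)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        raise
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# shared protocol pieces (used by run_all and the synthetic benchmark)
# ---------------------------------------------------------------------------


def elements_by_category(
    elements: Sequence[ElementRecord],
) -> dict[CategoryLabel, list[str]]:
    out: dict[CategoryLabel, list[str]] = {}
    for e in elements:
        out.setdefault(e.category, []).append(e.element_id)
    return out


def train_all_categories(
    elements: Sequence[ElementRecord],
    matrix: motif_matrix.MotifMatrix,
    config: ModelConfig,
    min_size: int | None = None,
) -> dict[CategoryLabel, TrainedModelBundle]:
    """One-vs-all protocol for every sufficiently large category."""
    by_cat = elements_by_category(elements)
    feats = {
        e: row for e, row in zip(matrix.element_ids, matrix.features)
    }
    min_size = min_size if min_size is not None else config.n_subsets * 2
    bundles = {}
    for category in sorted(by_cat):
        if len(by_cat[category]) < min_size:
            logger.warning(
                "train_all_categories: category %s has %d elements "
                "(< %d), skipped", category.code, len(by_cat[category]),
                min_size,
            )
            continue
        bundles[category] = train_one_vs_all(category, by_cat, feats, config)
    return bundles


def save_model_bundles(
    bundles: Mapping[CategoryLabel, TrainedModelBundle], outdir: Path
) -> None:
    """Persist trained bundles: predictions TSV, params JSON, model files."""
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    pred_rows = []
    params = {}
    for b in bundles.values():
        for i, bst in enumerate(b.models):
            bst.save_model(outdir / "models" / f"{b.comparison}_s{i}.json")
        for eid, y, p, s in zip(b.element_ids, b.labels,
                                b.heldout_predictions, b.source_model):
            pred_rows.append(
                {"comparison": b.comparison, "element_id": eid,
                 "label": int(y), "heldout_probability": float(p),
                 "subset": int(s)}
            )
        params[b.comparison] = {
            "min_child_weight": b.best_params[0],
            "max_depth": b.best_params[1],
            "n_rounds": b.n_rounds,
            "auc_per_subset": list(b.auc_per_subset),
            "mean_auc": b.mean_auc,
        }
    write_table(pd.DataFrame(pred_rows), outdir / "predictions.tsv")
    with open(outdir / "model_params.json", "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model_bundles(indir: Path) -> dict[str, TrainedModelBundle]:
    """Reload bundles persisted by :func:`save_model_bundles`, by comparison."""
    import xgboost as xgb

    indir = Path(indir)
    preds = pd.read_csv(indir / "predictions.tsv", sep="\t")
    with open(indir / "model_params.json") as fh:
        params = json.load(fh)
    bundles: dict[str, TrainedModelBundle] = {}
    for comparison, p in params.items():
        sub = preds[preds["comparison"] == comparison]
        models = []
        for i in range(len(p["auc_per_subset"])):
            bst = xgb.Booster()
            bst.load_model(indir / "models" / f"{comparison}_s{i}.json")
            models.append(bst)
        bundles[comparison] = TrainedModelBundle(
            comparison=comparison,
            best_params=(p["min_child_weight"], p["max_depth"]),
            n_rounds=p["n_rounds"],
            models=tuple(models),
            element_ids=tuple(sub["element_id"]),
            labels=sub["label"].to_numpy(),
            heldout_predictions=sub["heldout_probability"].to_numpy(),
            source_model=sub["subset"].to_numpy(),
            auc_per_subset=tuple(p["auc_per_subset"]),
        )
    return bundles


def explain_bundles(
    bundles: Mapping[str, TrainedModelBundle],
    matrix: motif_matrix.MotifMatrix,
    outdir: Path,
    perplexity: float = 30.0,
    eps: float | None = None,
    min_pts: int = 10,
    topk: int = 15,
    seed: int = 1,
) -> dict:
    """Attribution, embedding, clustering and driver reports per comparison."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = matrix.features
    pos_of = {e: i for i, e in enumerate(matrix.element_ids)}
    summary: dict = {"clusters_per_category": {}, "mean_auc": {}}
    driver_frames, coord_rows, attrib_frames = [], [], []
    for comparison, b in bundles.items():
        summary["mean_auc"][comparison] = b.mean_auc
        kept = explain.filter_correct_predictions(b)
        kept_pos = kept[b.labels[kept] == 1]
        if kept_pos.size == 0:
            continue
        X_full = np.stack([feats[pos_of[e]] for e in b.element_ids])
        attribs = explain.compute_attributions(
            b, X_full, keep=kept_pos, motif_ids=matrix.motif_ids
        )
        perp = min(perplexity, max(2.0, (len(kept_pos) - 2) / 3.0))
        if perp < perplexity:
            logger.warning(
                "explain: %s has %d kept elements; perplexity reduced "
                "to %.1f", comparison, len(kept_pos), perp,
            )
        coords = explain.embed_2d(attribs.values, perplexity=perp, seed=seed)
        labels = explain.cluster_density(coords, eps=eps, min_pts=min_pts)
        counts = np.stack(
            [matrix.counts[:, pos_of[e]] for e in attribs.element_ids]
        )
        drivers = explain.rank_cluster_drivers(attribs, labels, counts,
                                               k=topk)
        df = explain.drivers_to_frame(drivers)
        df.insert(0, "category", comparison)
        driver_frames.append(df)
        adf = attribs.to_frame().reset_index(names="element_id")
        adf.insert(0, "category", comparison)
        attrib_frames.append(adf)
        for eid, (x, y), lab in zip(attribs.element_ids, coords, labels):
            coord_rows.append(
                {"category": comparison, "element_id": eid,
                 "tsne_1": x, "tsne_2": y, "cluster": lab}
            )
        summary["clusters_per_category"][comparison] = len(drivers)
    if driver_frames:
        write_table(pd.concat(driver_frames, ignore_index=True),
                    outdir / "cluster_drivers.tsv")
        write_table(pd.concat(attrib_frames, ignore_index=True),
                    outdir / "attributions.tsv")
    write_table(pd.DataFrame(coord_rows), outdir / "embedding.tsv")
    summary["n_clusters_total"] = int(
        sum(summary["clusters_per_category"].values())
    )
    with open(outdir / "explain_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_models_and_explain(
    elements: Sequence[ElementRecord],
    matrix: motif_matrix.MotifMatrix,
    model_config: ModelConfig,
    outdir: Path,
    perplexity: float = 30.0,
    eps: float | None = None,
    min_pts: int = 10,
    topk: int = 15,
) -> tuple[dict[CategoryLabel, TrainedModelBundle], dict]:
    """Training plus per-category attribution clustering, persisted to disk."""
    outdir = Path(outdir)
    bundles = train_all_categories(elements, matrix, model_config)
    save_model_bundles(bundles, outdir)
    summary = explain_bundles(
        {b.comparison: b for b in bundles.values()}, matrix, outdir,
        perplexity=perplexity, eps=eps, min_pts=min_pts, topk=topk,
        seed=model_config.seed,
    )
    return bundles, summary


# ---------------------------------------------------------------------------
# synthetic benchmark protocol (in memory)
# ---------------------------------------------------------------------------


def elements_from_truth(
    bundle: synthetic.SyntheticBundle,
) -> list[ElementRecord]:
    """Categorized elements straight from the generator's truth tables.

    Runs the categorize stage against the oracle differential set, so element
    categories equal the planted labels exactly; the differential-calling
    statistics are benchmarked separately.
    """
    expr = cat.label_expression(list(bundle.de_records))
    flags = cat.flag_fusion_association(
        list(bundle.interactions), list(bundle.fusion_peaks)
    )
    return cat.assign_categories(
        list(bundle.atac_peaks), bundle.truth_diffs, expr, flags,
        window=bundle.config.window,
        genome_lengths={c: len(s) for c, s in bundle.genome.items()},
    )


def benchmark_protocol(
    bundle: synthetic.SyntheticBundle,
    model_config: ModelConfig,
    permute_seed: int | None = None,
) -> tuple[list[ElementRecord], motif_matrix.MotifMatrix,
           dict[CategoryLabel, TrainedModelBundle]]:
    """Categorize, scan and train one-vs-all models on a synthetic bundle.

    With ``permute_seed`` the category labels are randomly permuted across
    elements before training (the null protocol).
    """
    elements = elements_from_truth(bundle)
    if permute_seed is not None:
        elements = synthetic.permute_element_categories(elements, permute_seed)
    matrix = motif_matrix.build_matrix(
        elements, bundle.genome, list(bundle.library)
    )
    bundles = train_all_categories(elements, matrix, model_config)
    return elements, matrix, bundles


#: reduced (min_child_weight, max_depth) grid used by the desk-scale
#: benchmark runs; the full 400-point grid remains the protocol default
BENCHMARK_GRID = tuple(
    (mcw, depth) for mcw in (1, 5, 10, 20) for depth in (2, 5, 10, 21)
)


def null_calibration(
    seed: int,
    model_config: ModelConfig | None = None,
    elements_per_category: int = 300,
    n_motifs: int = 436,
) -> dict:
    """Chance-level calibration of the one-vs-all protocol.

    Generates the standard no-signal bundle (background insertions only),
    permutes category labels across elements, runs the full one-vs-all
    protocol for all six categories and reports the mean held-out AUC over
    every (category, subset) pair — the quantity that must sit at the 0.5
    chance line.
    """
    config = synthetic.standard_config(
        seed=seed, planted=False, n_motifs=n_motifs,
        elements_per_category=elements_per_category,
    )
    bundle = synthetic.generate_bundle(config)
    if model_config is None:
        model_config = ModelConfig(seed=seed)
    elements, matrix, bundles = benchmark_protocol(
        bundle, model_config, permute_seed=seed
    )
    subset_aucs = [a for b in bundles.values() for a in b.auc_per_subset]
    return {
        "mean_auc": float(np.mean(subset_aucs)),
        "auc_per_category": {
            c.code: b.mean_auc for c, b in bundles.items()
        },
        "n_elements": len(elements),
    }


def recovery_benchmark(
    seed: int,
    model_config: ModelConfig | None = None,
    elements_per_category: int = 300,
    n_motifs: int = 436,
    penetrance: float = 0.6,
    background_rate: float = 0.05,
    perplexity: float = 30.0,
    combined_perplexity: float = 50.0,
    min_pts: int = 10,
    top_k: int = 5,
) -> dict:
    """Planted-signature recovery through the full pipeline.

    Trains one-vs-all models on the standard planted bundle, clusters each
    category's correctly predicted positives in Shapley space, and reports
    per-category AUC, the union of top-``top_k`` driver motifs over that
    category's clusters, and the silhouette of category labels in the
    attribution embedding versus the raw log-count embedding.

    ``perplexity`` governs the per-category embeddings (a few hundred
    points); the combined six-category embedding holds ~5x more points and
    uses ``combined_perplexity`` so that within-category substructure stays
    attached to its category rather than fragmenting across the plane.
    Full-space silhouettes are reported alongside the embedded ones.
    """
    config = synthetic.standard_config(
        seed=seed, planted=True, n_motifs=n_motifs,
        elements_per_category=elements_per_category,
        penetrance=penetrance, background_rate=background_rate,
    )
    bundle = synthetic.generate_bundle(config)
    if model_config is None:
        model_config = ModelConfig(seed=seed, grid=BENCHMARK_GRID)
    elements, matrix, bundles = benchmark_protocol(bundle, model_config)
    feats = matrix.features
    pos_of = {e: i for i, e in enumerate(matrix.element_ids)}
    required = {
        s.category.code: sorted(s.required_motifs)
        for s in config.signatures
    }
    result: dict = {
        "auc_per_category": {},
        "top_driver_union": {},
        "required_motifs": required,
        "clusters_per_category": {},
    }
    all_attr, all_raw, all_codes = [], [], []
    for category, b in bundles.items():
        result["auc_per_category"][category.code] = b.mean_auc
        kept = explain.filter_correct_predictions(b)
        kept_pos = kept[b.labels[kept] == 1]
        X_full = np.stack([feats[pos_of[e]] for e in b.element_ids])
        attribs = explain.compute_attributions(
            b, X_full, keep=kept_pos, motif_ids=matrix.motif_ids
        )
        coords = explain.embed_2d(
            attribs.values, perplexity=perplexity, seed=model_config.seed
        )
        labels = explain.cluster_density(coords, min_pts=min_pts)
        counts = np.stack(
            [matrix.counts[:, pos_of[e]] for e in attribs.element_ids]
        )
        drivers = explain.rank_cluster_drivers(
            attribs, labels, counts, k=top_k
        )
        result["clusters_per_category"][category.code] = len(drivers)
        result["top_driver_union"][category.code] = sorted(
            {m for d in drivers for m, *_ in d.top_motifs}
        )
        all_attr.append(attribs.values)
        all_raw.append(X_full[kept_pos])
        all_codes.extend([category.code] * len(kept_pos))
    A, R = np.vstack(all_attr), np.vstack(all_raw)
    attr_coords = explain.embed_2d(
        A, perplexity=combined_perplexity, seed=model_config.seed
    )
    raw_coords = explain.embed_2d(
        R, perplexity=combined_perplexity, seed=model_config.seed
    )
    result["silhouette_attribution"] = explain.category_silhouette(
        attr_coords, all_codes
    )
    result["silhouette_raw"] = explain.category_silhouette(
        raw_coords, all_codes
    )
    result["silhouette_attribution_fullspace"] = explain.category_silhouette(
        A, all_codes
    )
    result["silhouette_raw_fullspace"] = explain.category_silhouette(
        R, all_codes
    )
    return result


def make_demo(seed: int, outdir: str | Path,
              elements_per_category: int = 60,
              n_motifs: int = 60) -> dict:
    """Write a small planted-signature fixture bundle with its manifest."""
    config = synthetic.SyntheticConfig(
        n_motifs=n_motifs,
        elements_per_category=elements_per_category,
        seed=seed,
    )
    library = synthetic.generate_motif_library(config)
    config = replace(
        config,
        signatures=synthetic.default_signatures(library),
    )
    bundle = synthetic.generate_bundle(config)
    return synthetic.write_bundle(bundle, outdir)
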