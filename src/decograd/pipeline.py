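"""End-to-end orchestration: configuration, pipeline runs, strategy grids.

``run_pipeline`` drives the full chain on one (segmentation method, map
source) choice: connectome -> gradients -> segmentations over a k range ->
pseudo-activation maps -> meta-analytic maps -> spin-permutation decoding,
writing stage artifacts and a machine-readable manifest.

``evaluate_grid`` scores every registered decoding strategy (segmentation
approach x map source x database) across the k range with the benchmark
metrics: mean top correlation, mean information content, mean TFIDF and
normalised SNR, alongside per-(method, k) clustering quality; top
performers are marked by configurable percentile thresholds and summed
into an overall score.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .connectome import DenseConnectome, GradientSet, cosine_affinity, diffusion_embedding, inverse_fisher, row_sparsify
from .decoder import SphereMesh, correlation_profile, decode, spin_nulls
from .meta_maps import MetaAnalyticMap, build_term_maps, build_topic_maps, fit_topics
from .pseudo_maps import build_map_set
from .segmentation import Segmentation, cluster_quality, segment_kde, segment_kmeans, segment_pct
from .semantics import category_model, classify_topic, classify_word, ic_topic, ic_word, snr, tfidf_topic, tfidf_word
from .synthetic import SyntheticWorld, synth_world

logger = logging.getLogger("decograd")

SEGMENTATION_METHODS = ("PCT", "KMeans", "KDE")
MAP_SOURCES = ("term", "topic", "external")


@dataclass
class RunConfig:
    """Pipeline configuration; file values can be overridden by CLI flags."""

    out_dir: str = "decograd_out"
    segmentation: str = "KMeans"
    map_source: str = "topic"
    k_min: int = 2
    k_max: int = 32
    n_perm: int = 1000
    alpha: float = 0.05
    term_threshold: float = 0.001
    topic_threshold: float = 0.05
    n_topics: int = 20
    density: float = 0.10
    n_components: int = 9
    seed: int = 0
    sigma_mode: str = "to_peak"
    quiet: bool = False
    # synthetic-world sizes (used when no external inputs are given)
    n_vertices: int = 2000
    n_studies: int = 500
    vocab_size: int = 400

    def __post_init__(self) -> None:
        for name in ("term_threshold", "topic_threshold", "alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.segmentation not in SEGMENTATION_METHODS:
            raise ValueError(f"segmentation must be one of {SEGMENTATION_METHODS}")
        if self.map_source not in MAP_SOURCES:
            raise ValueError(f"map_source must be one of {MAP_SOURCES}")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from one root seed (< 2**31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def gradients_from_connectome(
    connectome: DenseConnectome,
    density: float = 0.10,
    n_components: int = 9,
    alpha: float = 0.5,
    seed: int | None = None,
) -> GradientSet:
    """Convenience chain: (inverse Fisher ->) sparsify -> affinity -> embed."""
    if connectome.value_kind == "z":
        connectome = inverse_fisher(connectome)
    sparse = row_sparsify(connectome, density=density)
    affinity = cosine_affinity(sparse)
    return diffusion_embedding(affinity, n_components=n_components, alpha=alpha, seed=seed)


def segment_gradient(values: np.ndarray, method: str, k: int, seed: int | None = None) -> Segmentation:
    if method == "PCT":
        return segment_pct(values, k)
    if method == "KMeans":
        return segment_kmeans(values, k, seed=seed)
    if method == "KDE":
        return segment_kde(values, k)
    raise ValueError(f"unknown segmentation method {method!r}")


def _build_meta_maps(
    world: SyntheticWorld,
    map_source: str,
    config: RunConfig,
    external_maps: list[MetaAnalyticMap] | None = None,
):
    if map_source == "term":
        maps, _ = build_term_maps(world.database, world.study_maps, threshold=config.term_threshold)
        return maps, None
    if map_source == "topic":
        model = fit_topics(world.corpus, n_topics=config.n_topics, seed=stage_seed(config.seed, "lda"))
        maps, _ = build_topic_maps(model, world.study_maps, threshold=config.topic_threshold)
        return maps, model
    if map_source == "external":
        if external_maps is None:
            raise ValueError("map_source='external' requires a supplied map set")
        return external_maps, None
    raise ValueError(f"unknown map_source {map_source!r}")


def run_pipeline(
    config: RunConfig,
    world: SyntheticWorld | None = None,
    external_maps: list[MetaAnalyticMap] | None = None,
) -> Path:
    """Run the full chain and write stage artifacts plus a manifest.

    When ``world`` is None a synthetic world is generated from the config
    sizes and seed, so two runs with the same config are identical.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if world is None:
        world = synth_world(
            n_vertices=config.n_vertices,
            n_studies=config.n_studies,
            n_topics=config.n_topics,
            vocab_size=config.vocab_size,
            seed=stage_seed(config.seed, "world"),
        )
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": [],
    }

    def log(stage: str, msg: str) -> None:
        if not config.quiet:
            logger.info("[%s] seed=%d t=%.1fs %s", stage, config.seed, time.time() - t0, msg)

    gradients = gradients_from_connectome(
        world.connectome, density=config.density, n_components=config.n_components,
        seed=stage_seed(config.seed, "embedding"),
    )
    dio.write_gradients(out / "gradients", gradients)
    manifest["files"].append("gradients/gradient_eigenvalues.tsv")
    log("gradient", f"{gradients.n_components} components")

    g1 = gradients.components[:, 0]
    mesh = world.mesh
    nulls = spin_nulls(mesh, n_perm=config.n_perm, seed=stage_seed(config.seed, "spin"))
    meta_maps, _model = _build_meta_maps(world, config.map_source, config, external_maps)
    meta_maps = [m for m in meta_maps if np.std(m.values[mesh.cortex_mask]) > 0]
    log("maps", f"{len(meta_maps)} meta-analytic maps ({config.map_source})")

    quality_rows, table_paths = [], []
    seg_dir = out / "segmentations"
    for k in range(config.k_min, config.k_max + 1):
        seg = segment_gradient(g1, config.segmentation, k, seed=stage_seed(config.seed, f"seg{k}"))
        dio.write_segmentation(seg_dir, seg)
        q = cluster_quality(g1, seg.labels)
        quality_rows.append(
            {"method": seg.method, "k": k, "mean_silhouette": q.mean_silhouette,
             "variance_ratio": q.variance_ratio, "cluster_separation": q.cluster_separation}
        )
        pseudo = build_map_set(seg, sigma_mode=config.sigma_mode)
        # lift per-cortex maps onto the full mesh for decoding
        full = []
        for pm in pseudo:
            vals = np.zeros(mesh.n_vertices)
            vals[mesh.cortex_mask] = pm.values
            pm.values = vals
            full.append(pm)
        table = decode(full, meta_maps, mesh, seed=config.seed, alpha=config.alpha, nulls=nulls)
        path = out / f"decoding_{config.segmentation.lower()}_{config.map_source}_k{k:02d}.tsv"
        table.to_csv(path, sep="\t", index=False)
        table_paths.append(path.name)
        log("decode", f"k={k} table={path.name}")

    pd.DataFrame(quality_rows).to_csv(out / "cluster_quality.tsv", sep="\t", index=False)
    manifest["files"] += ["cluster_quality.tsv", *table_paths]
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


@dataclass
class StrategyGrid:
    """Cartesian product of segmentation approaches, map sources and databases."""

    segmentations: tuple[str, ...] = SEGMENTATION_METHODS
    map_sources: tuple[str, ...] = ("term", "topic")
    databases: tuple[str, ...] = ("db1",)

    def entries(self) -> list[tuple[str, str, str]]:
        out = [
            (seg, src, db)
            for db in self.databases
            for src in self.map_sources
            for seg in self.segmentations
        ]
        if len(set(out)) != len(out):
            raise ValueError("grid entries must be unique")
        return out


def _top_labels_with_scores(
    table: pd.DataFrame, meta_maps: list[MetaAnalyticMap]
) -> list[tuple[MetaAnalyticMap, float]]:
    by_name = {m.name: m for m in meta_maps}
    out = []
    for _, row in correlation_profile(table).iterrows():
        out.append((by_name[row["top_label"]], float(row["top_r"])))
    return out


def evaluate_grid(
    worlds: dict[str, SyntheticWorld],
    config: RunConfig,
    grid: StrategyGrid | None = None,
    corr_percentile: float = 90.0,
    snr_percentile: float = 90.0,
    ic_percentile: float = 70.0,
    tfidf_percentile: float = 70.0,
    silhouette_percentile: float = 90.0,
) -> dict[str, pd.DataFrame]:
    """Benchmark every strategy in the grid across the k range.

    Per (strategy, k): the mean top correlation across segments, the mean
    IC and TFIDF of the top labels, and the normalised SNR of their
    categories; per (method, k, database): clustering quality. Binary
    indicator matrices mark cells at or above the metric's percentile
    threshold (correlation/SNR default 90th, IC/TFIDF 70th, silhouette
    90th) and their sum is the overall score (max 5).
    """
    if grid is None:
        grid = StrategyGrid(databases=tuple(worlds))
    rows, quality_rows = [], []
    cache: dict[tuple, object] = {}
    for db_name in grid.databases:
        world = worlds[db_name]
        mesh = world.mesh
        cat_model = category_model(world.annotations)
        gradients = cache.setdefault(
            ("grad", db_name),
            gradients_from_connectome(
                world.connectome, density=config.density,
                n_components=config.n_components, seed=stage_seed(config.seed, f"emb:{db_name}"),
            ),
        )
        g1 = gradients.components[:, 0]
        for src in grid.map_sources:
            key = ("maps", db_name, src)
            if key not in cache:
                cache[key] = _build_meta_maps(world, src, config)[0]
            meta_maps = cache[key]
            for seg_method in grid.segmentations:
                strategy = f"{db_name}-{src}-{seg_method}"
                for k in range(config.k_min, config.k_max + 1):
                    skey = ("seg", db_name, seg_method, k)
                    if skey not in cache:
                        try:
                            cache[skey] = segment_gradient(
                                g1, seg_method, k, seed=stage_seed(config.seed, f"seg{k}")
                            )
                        except ValueError:
                            cache[skey] = None
                    seg = cache[skey]
                    if seg is None:
                        continue
                    qkey = ("q", db_name, seg_method, k)
                    if qkey not in cache:
                        q = cluster_quality(g1, seg.labels)
                        cache[qkey] = q
                        quality_rows.append(
                            {"database": db_name, "method": seg_method, "k": k,
                             "mean_silhouette": q.mean_silhouette,
                             "variance_ratio": q.variance_ratio,
                             "cluster_separation": q.cluster_separation}
                        )
                    pseudo = build_map_set(seg, sigma_mode=config.sigma_mode)
                    full = []
                    for pm in pseudo:
                        vals = np.zeros(mesh.n_vertices)
                        vals[mesh.cortex_mask] = pm.values
                        pm.values = vals
                        full.append(pm)
                    # evaluation metrics need ranks only: decode without nulls
                    table = _rank_only_table(full, meta_maps, mesh)
                    tops = _top_labels_with_scores(table, meta_maps)
                    ics, tfidfs, cats = [], [], []
                    for m, _r in tops:
                        sample = m.selected_ids or world.database.study_ids
                        try:
                            if len(m.labels) == 1:
                                ics.append(ic_word(world.corpus, m.labels[0], sample))
                                tfidfs.append(tfidf_word(world.corpus, m.labels[0], sample))
                                cats.append(classify_word(cat_model, m.labels[0]))
                            else:
                                ics.append(ic_topic(world.corpus, m.labels, sample))
                                tfidfs.append(tfidf_topic(world.corpus, m.labels, sample))
                                probs = m.word_probs or dict.fromkeys(m.labels, 1.0 / len(m.labels))
                                cats.append(classify_topic(cat_model, probs))
                        except (KeyError, ValueError):
                            continue
                    _, norm_snr = snr(cats) if cats else (np.nan, np.nan)
                    rows.append(
                        {"strategy": strategy, "database": db_name, "map_source": src,
                         "segmentation": seg_method, "k": k,
                         "mean_top_r": float(np.mean([r for _m, r in tops])),
                         "mean_ic": float(np.mean(ics)) if ics else np.nan,
                         "mean_tfidf": float(np.mean(tfidfs)) if tfidfs else np.nan,
                         "normalized_snr": norm_snr,
                         "mean_silhouette": cache[qkey].mean_silhouette}
                    )
    summary = pd.DataFrame(rows)
    quality = pd.DataFrame(quality_rows)

    def indicator(col: str, pct: float) -> pd.Series:
        threshold = np.nanpercentile(summary[col], pct)
        return (summary[col] >= threshold).astype(int)

    summary["pass_corr"] = indicator("mean_top_r", corr_percentile)
    summary["pass_snr"] = indicator("normalized_snr", snr_percentile)
    summary["pass_ic"] = indicator("mean_ic", ic_percentile)
    summary["pass_tfidf"] = indicator("mean_tfidf", tfidf_percentile)
    summary["pass_silhouette"] = indicator("mean_silhouette", silhouette_percentile)
    summary["overall_score"] = summary[
        ["pass_corr", "pass_snr", "pass_ic", "pass_tfidf", "pass_silhouette"]
    ].sum(axis=1)
    return {"summary": summary, "quality": quality}


def _rank_only_table(pseudo_maps, meta_maps, mesh: SphereMesh) -> pd.DataFrame:
    """Correlation table without permutation inference (for benchmarking)."""
    cortex = mesh.cortex_mask
    n_cx = int(cortex.sum())
    T = np.array([t.values[cortex] for t in pseudo_maps], dtype=float)
    meta_maps = [m for m in meta_maps if np.std(m.values[cortex]) > 0]
    M = np.array([m.values[cortex] for m in meta_maps], dtype=float)
    Zt = (T - T.mean(1, keepdims=True)) / T.std(1, keepdims=True)
    Zm = (M - M.mean(1, keepdims=True)) / M.std(1, keepdims=True)
    r = Zt @ Zm.T / n_cx
    rows = []
    for i, t in enumerate(pseudo_maps):
        for j, m in enumerate(meta_maps):
            rows.append({"segment_id": t.segment_id, "label": m.name, "r": r[i, j],
                         "p": np.nan, "q": np.nan, "significant": False})
    return pd.DataFrame(rows)
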