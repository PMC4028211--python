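"""End-to-end orchestration: split, standardize, pool, profile, cluster, select.

The pipeline is deterministic given its master seed: every stage derives its
own seed from (master seed, stage name), so a run manifest with the config and
seed reproduces any result bit-for-bit. Repeated-selection frequency analysis
fixes the deterministic front end (split through second-level pool) and
re-seeds only the swarm, mirroring how selection frequencies are ranked over
one shared pool.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import elm, gcs, gene_pools, mbpso
from .core_data import (
    ExpressionDataset,
    Standardizer,
    ValidationError,
    split_train_test,
)

logger = logging.getLogger("gcselect")


def _derive_seed(master: int, *key) -> int:
    spawn = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return int(
        np.random.SeedSequence(entropy=int(master), spawn_key=spawn).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    standardize: bool = True
    train_fraction: float = 0.6
    pool_size: int = gene_pools.DEFAULT_POOL_SIZE
    n_clusters: int | None = None  # None -> select via cluster_method
    cluster_candidates: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10)
    cluster_method: str = "cv"  # "cv" or "elbow"
    elbow_gain_threshold: float = 0.05
    theta_c: float = 0.5
    gcs_repeats: int = 50
    n_hidden: int | None = None  # classifier hidden size (CV evaluation)
    gcs_n_hidden: int | None = None  # sensitivity-profiling hidden size
    swarm: mbpso.SwarmConfig = field(default_factory=mbpso.SwarmConfig)
    n_runs: int = 50  # frequency-analysis repetitions
    top_k: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        swarm = d.pop("swarm", {})
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if swarm:
            cfg.swarm = mbpso.SwarmConfig(**swarm)
        if "cluster_candidates" in d:
            cfg.cluster_candidates = tuple(d["cluster_candidates"])
        return cfg


@dataclass
class PoolStage:
    """Deterministic front end: everything up to the second-level pool."""

    train: ExpressionDataset
    test: ExpressionDataset
    iic: gene_pools.IICScores
    pool_indices: np.ndarray  # into the full gene list
    pool_ids: list[str]
    profile: gcs.GCSProfile
    clustering: gene_pools.GeneClustering
    n_clusters: int
    second_level_indices: np.ndarray  # into the full gene list
    second_level_ids: list[str]
    X_pool2: np.ndarray  # training samples x N_gn2, standardized
    gcs_pool2: np.ndarray


@dataclass
class PipelineResult:
    stage: PoolStage
    swarm: mbpso.SwarmResult
    selected_ids: list[str]
    config: PipelineConfig

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "n_genes": self.stage.train.n_genes,
            "first_level_pool": len(self.stage.pool_ids),
            "n_clusters": self.stage.n_clusters,
            "second_level_pool": len(self.stage.second_level_ids),
            "selected": self.selected_ids,
            "gbest_fitness": self.swarm.gbest_fit,
            "n_evaluations": self.swarm.n_evaluations,
        }


@dataclass
class SelectionReport:
    """Selection frequencies over the second-level pool from repeated runs."""

    pool_ids: list[str]
    counts: np.ndarray  # selections per pooled gene, in [0, n_runs]
    n_runs: int
    runs: list[list[str]]  # selected ids per run

    @property
    def ranks(self) -> np.ndarray:
        """1 = most frequently selected; frequency ties broken by pool order."""
        order = np.argsort(-self.counts, kind="stable")
        ranks = np.empty(len(self.pool_ids), dtype=int)
        ranks[order] = np.arange(1, len(self.pool_ids) + 1)
        return ranks

    def top_table(self, k: int = 10) -> pd.DataFrame:
        order = np.argsort(-self.counts, kind="stable")[:k]
        return pd.DataFrame(
            {
                "gene_id": [self.pool_ids[i] for i in order],
                "frequency": self.counts[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def build_pools(ds: ExpressionDataset, config: PipelineConfig) -> PoolStage:
    """Run the deterministic stages: split, standardize, IIC, GCS, cluster, filter."""
    t0 = time.perf_counter()
    train, test = split_train_test(
        ds, config.train_fraction, _derive_seed(config.seed, "split"), stratified=True
    )
    if config.standardize:
        scaler = Standardizer().fit(train)
        train, test = scaler.transform(train), scaler.transform(test)
    logger.info("split: %d train / %d test samples", train.n_samples, test.n_samples)

    scores = gene_pools.iic_scores(train)
    pool_size = min(config.pool_size, train.n_genes)
    pool_idx = gene_pools.first_level_pool(scores, pool_size)
    pooled = train.subset_genes(pool_idx)
    logger.info("first-level pool: %d of %d genes", pool_size, train.n_genes)

    profile = gcs.gcs_profile(
        pooled,
        n_hidden=config.gcs_n_hidden,
        repeats=config.gcs_repeats,
        seed=_derive_seed(config.seed, "gcs"),
    )

    km_seed = _derive_seed(config.seed, "kmeans")
    if config.n_clusters is not None:
        n_clusters = config.n_clusters
    elif config.cluster_method == "elbow":
        n_clusters = gene_pools.select_num_clusters(
            pooled.X, config.cluster_candidates, "elbow", km_seed,
            gain_threshold=config.elbow_gain_threshold,
        )
    else:
        n_clusters = _select_n_clusters_cv(pooled, profile, config, km_seed)
    clustering = gene_pools.kmeans_genes(pooled.X, n_clusters, km_seed)
    clustering = gene_pools.filter_clusters(clustering, profile, config.theta_c)
    clustering = gene_pools.filter_genes_within_clusters(clustering, profile)

    kept_local = clustering.kept_gene_indices()
    second_idx = pool_idx[kept_local]
    logger.info(
        "clusters: %d (%d kept); second-level pool: %d genes",
        n_clusters, int(clustering.cluster_kept.sum()), kept_local.size,
    )
    stage = PoolStage(
        train=train,
        test=test,
        iic=scores,
        pool_indices=pool_idx,
        pool_ids=[ds.gene_ids[i] for i in pool_idx],
        profile=profile,
        clustering=clustering,
        n_clusters=n_clusters,
        second_level_indices=second_idx,
        second_level_ids=[ds.gene_ids[i] for i in second_idx],
        X_pool2=train.X[second_idx].T,
        gcs_pool2=profile.gcs[kept_local],
    )
    logger.debug("pool stages took %.2fs", time.perf_counter() - t0)
    return stage


def _select_n_clusters_cv(
    pooled: ExpressionDataset, profile: gcs.GCSProfile, config: PipelineConfig, seed: int
) -> int:
    """Score candidate cluster counts by a reduced-budget selection run."""

    small = dataclasses.replace(
        config.swarm, ns=max(10, config.swarm.ns // 4),
        max_iter=max(5, config.swarm.max_iter // 4), seed=_derive_seed(seed, "nc"),
    )

    def evaluate(nc: int) -> float:
        clustering = gene_pools.kmeans_genes(pooled.X, nc, seed)
        clustering = gene_pools.filter_clusters(clustering, profile, config.theta_c)
        clustering = gene_pools.filter_genes_within_clusters(clustering, profile)
        kept = clustering.kept_gene_indices()
        result = mbpso.run(
            pooled.X[kept].T, pooled.y, clustering, profile.gcs[kept], small
        )
        return elm.kfold_cv_accuracy(
            pooled.X[kept].T, pooled.y, result.selected,
            n_hidden=config.n_hidden, k=small.k_folds, seed=small.cv_seed,
        )

    return gene_pools.select_num_clusters(
        pooled.X, config.cluster_candidates, "cv", seed, cv_evaluator=evaluate
    )


def run_pipeline(ds: ExpressionDataset, config: PipelineConfig) -> PipelineResult:
    """Full selection run; deterministic given ``config.seed``."""
    stage = build_pools(ds, config)
    swarm_cfg = dataclasses.replace(
        config.swarm,
        seed=_derive_seed(config.seed, "swarm"),
        cv_seed=_derive_seed(config.seed, "cv"),
        n_hidden=config.n_hidden if config.swarm.n_hidden is None else config.swarm.n_hidden,
    )
    result = mbpso.run(stage.X_pool2, stage.train.y, stage.clustering, stage.gcs_pool2, swarm_cfg)
    selected_ids = [stage.second_level_ids[i] for i in result.selected]
    logger.info("selected %d genes, gbest fitness %.4f", len(selected_ids), result.gbest_fit)
    return PipelineResult(stage=stage, swarm=result, selected_ids=selected_ids, config=config)


def frequency_analysis(
    ds: ExpressionDataset,
    config: PipelineConfig,
    n_runs: int | None = None,
    selection_seed: int | None = None,
) -> SelectionReport:
    """Repeat the swarm search ``n_runs`` times over one shared second-level pool.

    The front end uses ``config.seed``; only the swarm (and its CV folds) is
    re-seeded per run from ``selection_seed``, so two analyses with different
    selection seeds are independent repetitions over the same pool.
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    if selection_seed is None:
        selection_seed = _derive_seed(config.seed, "freq")
    stage = build_pools(ds, config)
    counts = np.zeros(len(stage.second_level_ids))
    runs = []
    for r in range(n_runs):
        cfg = dataclasses.replace(
            config.swarm,
            seed=_derive_seed(selection_seed, "swarm", r),
            cv_seed=_derive_seed(selection_seed, "cv", r),
        )
        result = mbpso.run(stage.X_pool2, stage.train.y, stage.clustering, stage.gcs_pool2, cfg)
        counts[result.selected] += 1
        runs.append([stage.second_level_ids[i] for i in result.selected])
    return SelectionReport(
        pool_ids=list(stage.second_level_ids), counts=counts, n_runs=n_runs, runs=runs
    )


def reproducibility_correlation(a: SelectionReport, b: SelectionReport) -> float:
    """Spearman rank correlation between two frequency rankings (average ties)."""
    if a.pool_ids != b.pool_ids:
        raise ValidationError("reports cover different second-level pools")
    rho = spearmanr(a.counts, b.counts).statistic
    return float(rho)


def write_artifacts(result: PipelineResult, outdir) -> None:
    """Write intermediate tables (TSV) and the run manifest (JSON)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = result.stage
    pd.DataFrame({"gene_id": s.iic.gene_ids, "iic": s.iic.d}).to_csv(
        outdir / "iic_scores.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene_id": s.pool_ids, "gcs": s.profile.gcs}).to_csv(
        outdir / "gcs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        s.profile.S,
        index=pd.Index(s.pool_ids, name="gene_id"),
        columns=[f"class{j}" for j in range(s.profile.n_classes)],
    ).to_csv(outdir / "sensitivities.tsv", sep="\t")
    pd.DataFrame(
        {
            "gene_id": s.pool_ids,
            "cluster": s.clustering.assignment,
            "cluster_kept": s.clustering.cluster_kept[s.clustering.assignment],
            "gene_kept": s.clustering.gene_kept,
        }
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": result.selected_ids}).to_csv(
        outdir / "selected.tsv", sep="\t", index=False
    )
    pd.DataFrame({"iteration": range(len(result.swarm.trace)), "gbest_fitness": result.swarm.trace}).to_csv(
        outdir / "fitness_trace.tsv", sep="\t", index=False
    )
    (outdir / "manifest.json").write_text(json.dumps(result.manifest(), indent=2))
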