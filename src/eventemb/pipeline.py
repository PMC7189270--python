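"""End-to-end orchestration: network -> event graph -> environments ->
embedding -> SI sizes -> prediction report, plus parameter sweeps.

Every artifact a run writes is regenerable from its manifest alone: the
manifest echoes all parameters and named seeds, and contains no volatile
fields (timings go to the log, not the manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from eventemb.dim_select import entropy_curve, pairwise_distance_tensor
from eventemb.embedding import EventEmbedding, SkipGramParams, train_embedding
from eventemb.event_graph import build_event_graph
from eventemb.prediction import build_features, fit_and_score
from eventemb.sampling import SamplingConfig, sample_environments, write_corpus
from eventemb.spreading import epidemic_sizes_all_seeds, write_sizes
from eventemb.temporal_io import TemporalNetwork, read_event_list

logger = logging.getLogger("eventemb")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "sweep"]


@dataclass
class PipelineConfig:
    alpha: float = 0.5
    nb: int = 10
    s: int = 10
    d: Union[int, str] = "auto"  # "auto" triggers entropy-based selection
    mode: str = "combined"
    delta_t: Union[int, str] = "full"
    sampling_seed: int = 0
    training_seed: int = 0
    cv_seed: int = 0
    folds: int = 10
    skipgram: SkipGramParams = field(default_factory=SkipGramParams)
    # entropy-based dimension selection (used only when d == "auto")
    auto_dims: Sequence[int] = tuple(range(2, 101, 2))
    auto_realisations: int = 10
    auto_sample_size: int = 1000
    auto_n_samples: int = 10

    def manifest(self) -> Dict:
        out = asdict(self)
        out["auto_dims"] = list(self.auto_dims)
        return out


@dataclass
class PipelineResult:
    config: PipelineConfig
    dimension: int
    embedding: EventEmbedding
    sizes: Dict
    report: object
    n_skipped: int


def run_pipeline(
    tn: TemporalNetwork, cfg: PipelineConfig, out_dir: Optional[Path] = None
) -> PipelineResult:
    """Run the full prediction pipeline on ``tn``; optionally write artifacts."""
    t0 = time.perf_counter()
    graph = build_event_graph(tn, cfg.delta_t)
    logger.info("event graph: %d events, %d edges (%.2fs)",
                len(graph.events), graph.n_edges, time.perf_counter() - t0)

    if cfg.d == "auto":
        distances = pairwise_distance_tensor(
            tn,
            dims=cfg.auto_dims,
            realisations=cfg.auto_realisations,
            sample_size=cfg.auto_sample_size,
            n_samples=cfg.auto_n_samples,
            sampling_cfg=SamplingConfig(cfg.alpha, cfg.nb, cfg.s, cfg.mode),
            train_params=cfg.skipgram,
            base_seed=cfg.sampling_seed,
            delta_t=cfg.delta_t,
        )
        curve = entropy_curve(distances)
        dimension = curve.optimal_d
        if out_dir is not None:
            curve.write_tsv(Path(out_dir) / "entropy_curve.tsv")
        logger.info("entropy-selected dimension: d=%d", dimension)
    else:
        dimension = int(cfg.d)

    scfg = SamplingConfig(cfg.alpha, cfg.nb, cfg.s, cfg.mode, seed=cfg.sampling_seed)
    envs, skipped = sample_environments(graph, scfg)
    if skipped:
        logger.info("%d events had empty neighborhoods and were skipped", len(skipped))
    emb = train_embedding(envs, dimension, replace(cfg.skipgram, seed=cfg.training_seed))
    sizes = epidemic_sizes_all_seeds(tn)
    table = build_features(emb, sizes)
    report = fit_and_score(table, folds=cfg.folds, seed=cfg.cv_seed)
    logger.info("held-out r2 = %.4f +/- %.4f (%.2fs total)",
                report.r2_mean, report.r2_std, time.perf_counter() - t0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        graph.write_edge_list(out / "event_graph.tsv")
        write_corpus(envs, out / "corpus.txt")
        emb.save_word2vec_text(out / "embedding.txt")
        write_sizes(sizes, out / "sizes.tsv")
        manifest = {
            "config": cfg.manifest(),
            "dimension": dimension,
            "n_events": len(tn.events),
            "n_skipped": len(skipped),
            "r2_mean": report.r2_mean,
            "r2_std": report.r2_std,
            "per_fold_r2": report.per_fold_r2,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return PipelineResult(cfg, dimension, emb, sizes, report, len(skipped))


def sweep(
    tn: TemporalNetwork,
    cfg: PipelineConfig,
    grid: str,
    values_a: Sequence,
    values_b: Sequence,
    realisations: int = 3,
) -> List[Tuple[float, float, float, float]]:
    """Mean +/- std held-out r² over a 2-D parameter grid.

    ``grid`` is ``"nb_s"`` (vary nb and s) or ``"d_alpha"`` (vary d and
    alpha).  Each cell is averaged over ``realisations`` sampling/training
    seed pairs derived deterministically from the config seeds.

    Returns rows (value_a, value_b, r2_mean, r2_std).
    """
    if grid not in ("nb_s", "d_alpha"):
        raise ValueError(f"unknown grid {grid!r}")
    rows = []
    for va in values_a:
        for vb in values_b:
            if grid == "nb_s":
                cell = replace(cfg, nb=int(va), s=int(vb))
            else:
                cell = replace(cfg, d=int(va), alpha=float(vb))
            scores = []
            for k in range(realisations):
                run = replace(
                    cell,
                    sampling_seed=cfg.sampling_seed + 1000 * k,
                    training_seed=cfg.training_seed + 1000 * k,
                )
                scores.append(run_pipeline(tn, run).report.r2_mean)
            rows.append((float(va), float(vb), float(np.mean(scores)), float(np.std(scores))))
    return rows


def write_sweep_tsv(rows, grid: str, path) -> None:
    names = {"nb_s": ("nb", "s"), "d_alpha": ("d", "alpha")}[grid]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{names[0]}\t{names[1]}\tr2_mean\tr2_std\n")
        for va, vb, mean, std in rows:
            fh.write(f"{va:g}\t{vb:g}\t{mean:.6g}\t{std:.6g}\n")
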