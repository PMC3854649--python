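"""End-to-end pipeline: normalize → test/fold-change → collapse → enrich → rank.

These functions are the package's operational surface: they tie the
modules together for in-memory objects (:func:`run_enrichment`) and for
the standard on-disk formats (:func:`run_enrichment_files`,
:func:`meta_from_files`, :func:`simulate_to_files`), writing
deterministic TSVs plus a provenance record of the configuration used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import enrichment as enr
from .expression_prep import (
    SampleDesign,
    gene_stats,
    quantile_normalize,
    read_design_tsv,
    read_expression_tsv,
)
from .geneset_io import GeneSetCollection, collapse_probes, read_gmt, read_probe_map
from .meta import consistency_score, cross_tabulate, top_k_table
from .simulate import SimulationSpec, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "prepare_gene_stats",
    "run_enrichment",
    "run_enrichment_files",
    "meta_from_files",
    "simulate_to_files",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one enrichment run.

    Defaults follow the reference analysis: power 1 for the weighted
    tests, alpha 0.01 for the significance call, top-10 reporting.
    """

    method: str = "all"  # one of enrichment.METHODS or "all"
    power: float = 1.0
    alpha: float = 0.01
    top_k: int = 10

    def methods(self) -> tuple[str, ...]:
        if self.method == "all":
            return enr.METHODS
        if self.method not in enr.METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected 'all' or one of {enr.METHODS}"
            )
        return (self.method,)


def prepare_gene_stats(
    matrix: pd.DataFrame,
    design: SampleDesign,
    alpha: float = 0.01,
    probe_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Quantile-normalize, t-test, and (optionally) collapse probes to genes."""
    design.validate_against(matrix.columns)
    normalized = quantile_normalize(matrix)
    stats = gene_stats(normalized, design, alpha=alpha)
    if probe_map is not None:
        stats = collapse_probes(stats[["fold_change", "p_value"]], probe_map)
        stats["is_significant"] = stats["p_value"] < alpha
    return stats


def run_enrichment(
    matrix: pd.DataFrame,
    design: SampleDesign,
    sets: GeneSetCollection,
    config: RunConfig = RunConfig(),
    probe_map: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the configured enrichment method(s) on an in-memory dataset.

    Returns one ranked result table per method name.
    """
    stats = prepare_gene_stats(matrix, design, alpha=config.alpha, probe_map=probe_map)
    results = {
        method: enr.enrich(sets, stats, method, a=config.power, alpha=config.alpha)
        for method in config.methods()
    }
    n_sig = int(stats["is_significant"].sum())
    for method, res in results.items():
        n_flagged = int((res["flag"] != "").sum())
        logger.info(
            "%s: N=%d genes, m=%d significant, %d pathways (%d flagged)",
            method, len(stats), n_sig, len(res), n_flagged,
        )
    return results


def run_enrichment_files(
    expression_path: str | Path,
    design_path: str | Path,
    gmt_path: str | Path,
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
    probe_map_path: str | Path | None = None,
) -> dict[str, Path]:
    """File-based pipeline: read the standard TSV/GMT trio, write result TSVs.

    Writes one ``results_<method>.tsv`` per method plus ``run_config.json``
    echoing the configuration; returns the output manifest.
    """
    matrix = read_expression_tsv(expression_path)
    design = read_design_tsv(design_path)
    sets = read_gmt(gmt_path)
    probe_map = read_probe_map(probe_map_path) if probe_map_path else None
    results = run_enrichment(matrix, design, sets, config=config, probe_map=probe_map)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for method, res in results.items():
        path = out / f"results_{method}.tsv"
        res.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest[method] = path
    config_path = out / "run_config.json"
    config_path.write_text(json.dumps(asdict(config), indent=2) + "\n")
    manifest["config"] = config_path
    return manifest


def meta_from_files(
    result_paths: Mapping[str, str | Path] | Sequence[str | Path],
    out_path: str | Path | None = None,
    min_datasets: int = 2,
    top_k: int = 10,
    p_cutoff: float | None = None,
) -> pd.DataFrame:
    """Cross-tabulate top-k pathways across per-dataset result TSVs.

    ``result_paths`` maps dataset labels to result files (a plain list
    uses file stems as labels).  Writes the recurrence TSV when
    ``out_path`` is given and returns it; the pairwise-overlap summary
    is logged.
    """
    if not isinstance(result_paths, Mapping):
        result_paths = {Path(p).stem: p for p in result_paths}
    if len(result_paths) < 2:
        raise ValueError("meta-analysis needs at least 2 result files")
    results = {ds: pd.read_csv(p, sep="\t") for ds, p in result_paths.items()}
    table = top_k_table(results, k=top_k, p_cutoff=p_cutoff)
    recurrence = cross_tabulate(table, min_datasets=min_datasets)
    summary = consistency_score(table)
    logger.info(
        "mean pairwise top-%d overlap: %.3f; recurrence histogram: %s",
        top_k, summary.mean_pairwise_overlap, summary.recurrence_counts,
    )
    if out_path is not None:
        recurrence.to_csv(out_path, sep="\t", index=False)
    return recurrence


def simulate_to_files(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic dataset and write the standard file trio."""
    matrix, design, collection = simulate_dataset(spec)
    paths = write_dataset(matrix, design, collection, out_dir)
    logger.info("wrote synthetic dataset (seed=%d) to %s", spec.seed, out_dir)
    return paths
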