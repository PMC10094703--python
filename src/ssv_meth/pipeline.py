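"""End-to-end orchestration: preprocess → subgroup → DMR → SSV call.

A `PipelineConfig` collects the file paths, thresholds and the master
seed; `run_pipeline` executes the stages, writes every output next to a
run manifest (config echo, seed, per-stage counts) and is deterministic:
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .io import (
    check_sample_overlap,
    load_methylation_dataset,
    read_drop_list,
    read_expression,
    read_tss,
    write_candidates,
    write_dmr_details,
    write_dmrs_bed,
    write_solution,
)
from .nmf_subgroup import consensus_stability, select_solution
from .preprocess import beta_to_m, filter_probes, select_most_variable
from .ssv_call import call_candidates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run."""

    beta_path: str
    manifest_path: str
    expression_path: str
    tss_path: str
    out_dir: str
    seed: int
    drop_list_path: Optional[str] = None
    top_n: int = 10_000
    r_range: tuple[int, int] = (2, 10)
    k_range: tuple[int, int] = (2, 10)
    n_boot: int = 250
    subsample_fraction: float = 0.8
    lambda_bp: int = 1000
    delta_threshold: float = 0.2
    max_change_threshold: float = 0.3
    tss_max_distance: int = 20_000
    epsilon: float = 0.001
    target_subgroup: Optional[int] = None  # None → auto-select
    max_iter: int = 200

    def __post_init__(self) -> None:
        for name in ("lambda_bp", "delta_threshold", "max_change_threshold",
                     "tss_max_distance", "epsilon", "top_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for lo, hi in (self.r_range, self.k_range):
            if not (2 <= lo <= hi <= 10):
                raise ValueError("r_range and k_range must lie within 2..10")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("r_range", "k_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _auto_target(dataset, assignment, config) -> int:
    """Pick the subgroup with the most subgroup-specific differential
    regions (either direction, passing max-change and persistence)."""
    from .dmr import (
        GroupContrast,
        call_dmrs,
        max_change_subregion,
        persistence_filter,
        probe_deltas,
    )

    counts = {}
    for g in sorted(assignment.unique()):
        contrast = GroupContrast(
            target_samples=tuple(assignment.index[assignment == g]),
            reference_samples=tuple(assignment.index[assignment != g]),
            name=f"subgroup_{g}_vs_rest",
        )
        deltas = probe_deltas(dataset, contrast)
        dmrs = call_dmrs(
            deltas,
            dataset.probes,
            lambda_bp=config.lambda_bp,
            delta_threshold=config.delta_threshold,
        )
        n = 0
        for d in dmrs:
            upd = max_change_subregion(
                d, deltas, dataset.probes, threshold=config.max_change_threshold
            )
            if upd is None:
                continue
            ok, _ = persistence_filter(
                upd, dataset, assignment, g, threshold=config.max_change_threshold
            )
            n += ok
        counts[int(g)] = n
    # ties → smallest label, for determinism
    return min(counts, key=lambda g: (-counts[g], g))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full discovery pipeline and write all outputs.

    Returns a summary dict (also written as run_manifest.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = load_methylation_dataset(config.beta_path, config.manifest_path)
    expression = read_expression(config.expression_path)
    annotation = read_tss(config.tss_path)
    shared = check_sample_overlap(dataset, expression)
    n_probes_in = dataset.n_probes

    drop_ids = read_drop_list(config.drop_list_path) if config.drop_list_path else []
    filtered, n_removed, _unknown = filter_probes(dataset, drop_ids)

    m = beta_to_m(filtered, epsilon=config.epsilon)
    m_top = select_most_variable(m, config.top_n)

    surface = consensus_stability(
        m_top,
        r_range=range(config.r_range[0], config.r_range[1] + 1),
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        n_boot=config.n_boot,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed,
        max_iter=config.max_iter,
    )
    solution = select_solution(surface, m_top, seed=config.seed,
                               max_iter=config.max_iter)
    write_solution(solution, out / "solution.json")
    surface.to_frame().to_csv(out / "stability_surface.tsv", sep="\t")
    solution.consensus.to_csv(out / "consensus_matrix.tsv", sep="\t")

    target = (
        config.target_subgroup
        if config.target_subgroup is not None
        else _auto_target(filtered, solution.assignment, config)
    )

    candidates, traces = call_candidates(
        filtered,
        expression,
        annotation,
        solution.assignment,
        target_subgroup=target,
        lambda_bp=config.lambda_bp,
        delta_threshold=config.delta_threshold,
        max_change_threshold=config.max_change_threshold,
        tss_max_distance=config.tss_max_distance,
    )
    write_candidates(
        candidates,
        out / "candidates.tsv",
        trace_path=out / "filter_trace.json",
        traces=traces,
    )
    dmr_records = [c.dmr for c in candidates]
    write_dmrs_bed(dmr_records, out / "candidate_dmrs.bed")
    write_dmr_details(dmr_records, out / "candidate_dmrs.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_samples": dataset.n_samples,
        "n_samples_with_expression": len(shared),
        "n_probes_input": n_probes_in,
        "n_probes_removed": int(n_removed),
        "n_probes_clustered": m_top.m.shape[1],
        "chosen_r": solution.r,
        "chosen_k": solution.k,
        "target_subgroup": int(target),
        "n_dmrs_tested": len(traces),
        "n_candidates": len(candidates),
        "candidates": [c.gene_id for c in candidates],
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
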