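"""Subgroup-specific-vulnerability (SSV) candidate gene calling.

SSV (synthetic-lethal-like) genes are genes that selectively retain
normal, low promoter methylation — and expression — in exactly one
molecular subgroup, suggesting that subgroup depends on them for
survival.  Starting from called DMRs for a target-vs-rest contrast the
filters are, in order:

1. direction — keep regions hypomethylated in the target subgroup
   (candidate vulnerabilities, not tumour-suppressor-style gains);
2. max-change — a sub-window of ≥ 2 CpGs with mean Δβ beyond 0.3;
3. persistence — hypomethylation holds in every pairwise comparison
   against each other subgroup individually;
4. TSS distance — regions farther than 20 kb from every transcription
   start site are considered not gene-associated;
5. expression — the mapped gene's expression must be higher in the
   target subgroup than in every other subgroup (strict, on medians).

Every input DMR keeps a full trace of which filters it passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dmr import (
    DMRecord,
    GroupContrast,
    call_dmrs,
    max_change_subregion,
    persistence_filter,
    probe_deltas,
)
from .preprocess import MethylationDataset

__all__ = [
    "CandidateSSV",
    "direction_filter",
    "nearest_tss",
    "expression_filter",
    "call_candidates",
    "validate_annotation",
]


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a TSS table (gene_id, chrom, tss_pos, strand)."""
    required = {"gene_id", "chrom", "tss_pos", "strand"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annotation["gene_id"].duplicated().any():
        raise ValueError("duplicate gene IDs in annotation")
    bad = ~annotation["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("strand must be '+' or '-'")
    return annotation


@dataclass
class CandidateSSV:
    """A gene surviving every filter, with full provenance."""

    gene_id: str
    dmr: DMRecord
    tss_distance: int
    target_subgroup: int
    expression_summary: dict[int, float]
    filter_trace: list[dict]

    def __post_init__(self) -> None:
        if self.tss_distance > 20_000:
            raise ValueError("candidate TSS distance exceeds 20 kb")
        failed = [t for t in self.filter_trace if not t["passed"]]
        if failed:
            raise ValueError(f"candidate carries failed filters: {failed}")


def direction_filter(dmrs: Sequence[DMRecord]) -> list[DMRecord]:
    """Keep only regions hypomethylated in the target subgroup."""
    return [d for d in dmrs if d.direction == "hypo"]


def nearest_tss(
    dmr: DMRecord,
    annotation: pd.DataFrame,
    max_distance: int = 20_000,
) -> Optional[tuple[str, int]]:
    """Map a region to the nearest gene TSS on its chromosome.

    Distance is 0 when the TSS falls inside the region, otherwise the
    smaller of |tss − start| and |tss − end|.  Strand is ignored (a TSS
    is a point).  Returns (gene_id, distance) or None when the nearest
    TSS is beyond ``max_distance`` (a region exactly at the limit is
    still considered gene-associated) or the chromosome is absent.
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    here = annotation[annotation["chrom"] == dmr.chrom]
    if here.empty:
        return None
    tss = here["tss_pos"].to_numpy(dtype=np.int64)
    inside = (tss >= dmr.start) & (tss <= dmr.end)
    dist = np.where(
        inside, 0, np.minimum(np.abs(tss - dmr.start), np.abs(tss - dmr.end))
    )
    here = here.assign(distance=dist).sort_values(
        ["distance", "gene_id"], kind="stable"
    )
    best = here.iloc[0]
    if best["distance"] > max_distance:
        return None
    return str(best["gene_id"]), int(best["distance"])


def expression_filter(
    gene_id: str,
    expression: pd.DataFrame,
    assignment: pd.Series,
    target_subgroup: int,
    center: str = "median",
) -> tuple[bool, dict[int, float], str]:
    """Test whether a gene's expression is elevated in the target.

    ``expression`` is genes × samples (log2 scale).  Passes iff the
    target subgroup's central value (median by default, configurable to
    mean) strictly exceeds every other subgroup's.  Returns
    (passed, per-subgroup central values, reason).
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    if gene_id not in expression.index:
        return False, {}, "unmeasured"
    row = expression.loc[gene_id]
    summary: dict[int, float] = {}
    for g in sorted(assignment.unique()):
        samples = assignment.index[assignment == g]
        vals = row.loc[samples.intersection(row.index)]
        if vals.empty:
            raise ValueError(f"subgroup {g} has no expression samples")
        summary[int(g)] = float(vals.median() if center == "median" else vals.mean())
    target_val = summary[int(target_subgroup)]
    others = [v for g, v in summary.items() if g != int(target_subgroup)]
    passed = all(target_val > v for v in others)
    return passed, summary, "" if passed else "not highest in target"


def call_candidates(
    dataset: MethylationDataset,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    assignment: pd.Series,
    target_subgroup: int,
    lambda_bp: int = 1000,
    min_probes: int = 2,
    delta_threshold: float = 0.2,
    max_change_threshold: float = 0.3,
    tss_max_distance: int = 20_000,
    expression_center: str = "median",
) -> tuple[list[CandidateSSV], list[dict]]:
    """Run the full SSV filter cascade for one target subgroup.

    Compares the target subgroup against all other subgroups pooled,
    calls DMRs, then applies direction, max-change, persistence, TSS
    and expression filters.  A gene with several qualifying DMRs is
    reported once, with its closest DMR.  Returns the candidate list
    and the complete per-DMR filter trace (including failures).
    """
    if expression is None:
        raise ValueError("expression matrix is required")
    validate_annotation(annotation)
    missing = set(assignment.index) - set(dataset.beta.index)
    if missing:
        raise ValueError(f"assignment samples absent from dataset: {sorted(missing)[:3]}")
    shared_expr = set(assignment.index) & set(expression.columns)
    if not shared_expr:
        raise ValueError("no shared samples between assignment and expression")

    target_samples = tuple(assignment.index[assignment == target_subgroup])
    ref_samples = tuple(assignment.index[assignment != target_subgroup])
    if not target_samples:
        raise ValueError(f"target subgroup {target_subgroup} is empty")
    contrast = GroupContrast(
        target_samples=target_samples,
        reference_samples=ref_samples,
        name=f"subgroup_{target_subgroup}_vs_rest",
    )
    deltas = probe_deltas(dataset, contrast)
    dmrs = call_dmrs(
        deltas,
        dataset.probes,
        lambda_bp=lambda_bp,
        min_probes=min_probes,
        delta_threshold=delta_threshold,
    )

    traces: list[dict] = []
    survivors: list[tuple] = []
    for idx, dmr in enumerate(dmrs):
        trace: list[dict] = []
        rec = {
            "dmr_id": f"DMR_{idx + 1:04d}",
            "chrom": dmr.chrom,
            "start": dmr.start,
            "end": dmr.end,
            "n_probes": dmr.n_probes,
            "mean_delta": dmr.mean_delta,
            "direction": dmr.direction,
            "filters": trace,
        }
        traces.append(rec)

        is_hypo = dmr.direction == "hypo"
        trace.append({"filter": "direction", "passed": is_hypo})
        if not is_hypo:
            continue

        updated = max_change_subregion(
            dmr, deltas, dataset.probes, threshold=max_change_threshold
        )
        trace.append(
            {
                "filter": "max_change",
                "passed": updated is not None,
                "threshold": max_change_threshold,
            }
        )
        if updated is None:
            continue
        dmr = updated
        rec["max_subregion"] = {
            "start": dmr.max_subregion.start,
            "end": dmr.max_subregion.end,
            "mean_delta": dmr.max_subregion.mean_delta,
        }

        persisted, table = persistence_filter(
            dmr, dataset, assignment, target_subgroup, threshold=max_change_threshold
        )
        trace.append(
            {
                "filter": "persistence",
                "passed": persisted,
                "comparisons": table.to_dict(orient="records"),
            }
        )
        if not persisted:
            continue

        hit = nearest_tss(dmr, annotation, max_distance=tss_max_distance)
        trace.append(
            {
                "filter": "tss_distance",
                "passed": hit is not None,
                "gene_id": hit[0] if hit else None,
                "distance": hit[1] if hit else None,
            }
        )
        if hit is None:
            continue
        gene_id, distance = hit

        passed, summary, reason = expression_filter(
            gene_id,
            expression,
            assignment,
            target_subgroup,
            center=expression_center,
        )
        trace.append(
            {
                "filter": "expression",
                "passed": passed,
                "reason": reason,
                "medians": summary,
            }
        )
        if not passed:
            continue
        survivors.append((dmr, gene_id, distance, summary, list(trace)))

    # collapse multiple DMRs per gene to the closest (ties → leftmost)
    by_gene: dict[str, tuple] = {}
    for dmr, gene_id, distance, summary, trace in survivors:
        prev = by_gene.get(gene_id)
        if prev is None or (distance, dmr.chrom, dmr.start) < (
            prev[2],
            prev[0].chrom,
            prev[0].start,
        ):
            by_gene[gene_id] = (dmr, gene_id, distance, summary, trace)

    candidates = [
        CandidateSSV(
            gene_id=gene_id,
            dmr=dmr,
            tss_distance=distance,
            target_subgroup=int(target_subgroup),
            expression_summary=summary,
            filter_trace=trace,
        )
        for dmr, gene_id, distance, summary, trace in sorted(
            by_gene.values(), key=lambda t: t[1]
        )
    ]
    return candidates, traces
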