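"""Readers and writers for the pipeline's plain-text formats.

Formats:
  β matrix       TSV, rows = probe IDs, columns = sample IDs
  probe manifest TSV, columns probe_id, chrom, pos (1-based)
  expression     TSV, rows = gene IDs, columns = sample IDs (log2)
  TSS annotation TSV, columns chrom, tss_pos (1-based), gene_id, strand
  drop list      plain text, one probe ID per line
  DMRs           BED6 (0-based half-open) plus a detail TSV
  solution/trace JSON

Every reader validates loudly: malformed numbers, out-of-range β and
cross-file ID mismatches are reported with the offending probe/sample
named, never silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dmr import DMRecord
from .nmf_subgroup import StabilitySurface, SubgroupSolution
from .preprocess import MethylationDataset
from .ssv_call import CandidateSSV, validate_annotation

__all__ = [
    "read_beta",
    "read_manifest",
    "load_methylation_dataset",
    "read_expression",
    "read_tss",
    "read_drop_list",
    "check_sample_overlap",
    "write_solution",
    "read_solution",
    "write_dmrs_bed",
    "write_dmr_details",
    "write_candidates",
]


def _read_numeric_matrix(path: str | Path, index_label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            # astype(float) parses correctly rounded, so written values
            # round-trip exactly; to_numeric's fast path does not
            out[col] = df[col].astype(float)
        except (ValueError, TypeError):
            probe = pd.to_numeric(df[col], errors="coerce")
            bad = probe.isna() & df[col].notna()
            row = df.index[bad][0] if bad.any() else df.index[0]
            raise ValueError(
                f"{path}: malformed numeric value {df.loc[row, col]!r} "
                f"at {index_label}={row!r}, sample={col!r}"
            ) from None
    out.index.name = df.index.name
    return out


def read_beta(path: str | Path) -> pd.DataFrame:
    """β TSV (probes × samples) → samples × probes DataFrame."""
    df = _read_numeric_matrix(path, "probe")
    vals = df.to_numpy()
    bad = np.argwhere((vals < 0) | (vals > 1))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"{path}: β value {vals[i, j]} outside [0, 1] at "
            f"probe={df.index[i]!r}, sample={df.columns[j]!r}"
        )
    return df.T


def read_manifest(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    man["pos"] = pd.to_numeric(man["pos"], errors="raise").astype(int)
    return man.set_index("probe_id")[["chrom", "pos"]]


def load_methylation_dataset(
    beta_path: str | Path, manifest_path: str | Path
) -> MethylationDataset:
    beta = read_beta(beta_path)
    manifest = read_manifest(manifest_path)
    missing = beta.columns.difference(manifest.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} β probes absent from manifest "
            f"(first: {missing[0]!r})"
        )
    return MethylationDataset(beta=beta, probes=manifest)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV (genes × samples), log2 scale."""
    return _read_numeric_matrix(path, "gene")


def read_tss(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    ann["tss_pos"] = pd.to_numeric(ann["tss_pos"], errors="raise").astype(int)
    return validate_annotation(ann)


def read_drop_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def check_sample_overlap(
    dataset: MethylationDataset, expression: pd.DataFrame
) -> list[str]:
    """Samples present in both β and expression; error when empty."""
    shared = [s for s in dataset.samples if s in expression.columns]
    if not shared:
        raise ValueError("no samples shared between β and expression matrices")
    return shared


# ---------------------------------------------------------------- output


def write_solution(solution: SubgroupSolution, path: str | Path) -> None:
    payload = {
        "k": solution.k,
        "r": solution.r,
        "assignment": {s: int(g) for s, g in solution.assignment.items()},
    }
    if solution.stability is not None:
        payload["stability"] = {
            "n_boot": solution.stability.n_boot,
            "subsample_fraction": solution.stability.subsample_fraction,
            "scores": [
                {"r": r, "k": k, "score": s}
                for (r, k), s in sorted(solution.stability.scores.items())
            ],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_solution(path: str | Path) -> SubgroupSolution:
    with open(path) as fh:
        payload = json.load(fh)
    stability = None
    if "stability" in payload:
        st = payload["stability"]
        stability = StabilitySurface(
            scores={(e["r"], e["k"]): e["score"] for e in st["scores"]},
            n_boot=st["n_boot"],
            subsample_fraction=st["subsample_fraction"],
        )
    return SubgroupSolution(
        assignment=pd.Series(
            {s: int(g) for s, g in payload["assignment"].items()}, name="subgroup"
        ),
        k=payload["k"],
        r=payload["r"],
        stability=stability,
    )


def write_dmrs_bed(dmrs: Sequence[DMRecord], path: str | Path) -> None:
    """BED6: 1-based inclusive coordinates become 0-based half-open;
    score = 1000·|mean Δβ| capped at 1000."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs):
            score = min(int(round(1000 * abs(d.mean_delta))), 1000)
            fh.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\tDMR_{i + 1:04d}\t{score}\t.\n"
            )


def write_dmr_details(dmrs: Sequence[DMRecord], path: str | Path) -> None:
    rows = []
    for i, d in enumerate(dmrs):
        rows.append(
            {
                "dmr_id": f"DMR_{i + 1:04d}",
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "n_probes": d.n_probes,
                "probe_ids": ",".join(d.probe_ids),
                "mean_delta": d.mean_delta,
                "direction": d.direction,
                "max_subregion_start": d.max_subregion.start if d.max_subregion else "",
                "max_subregion_end": d.max_subregion.end if d.max_subregion else "",
                "max_subregion_delta": (
                    d.max_subregion.mean_delta if d.max_subregion else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_candidates(
    candidates: Sequence[CandidateSSV],
    path: str | Path,
    trace_path: Optional[str | Path] = None,
    traces: Optional[list[dict]] = None,
) -> None:
    rows = []
    for c in candidates:
        row = {
            "gene_id": c.gene_id,
            "chrom": c.dmr.chrom,
            "dmr_start": c.dmr.start,
            "dmr_end": c.dmr.end,
            "n_probes": c.dmr.n_probes,
            "mean_delta": c.dmr.mean_delta,
            "max_subregion_delta": (
                c.dmr.max_subregion.mean_delta if c.dmr.max_subregion else ""
            ),
            "tss_distance": c.tss_distance,
            "target_subgroup": c.target_subgroup,
        }
        for g, v in sorted(c.expression_summary.items()):
            row[f"expr_median_subgroup_{g}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if trace_path is not None and traces is not None:
        with open(trace_path, "w") as fh:
            json.dump(traces, fh, indent=2, default=float)
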