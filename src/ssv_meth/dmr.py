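"""Differentially methylated region (DMR) calling.

A deliberately transparent, threshold-based caller: per-probe β-value
differences between a target sample group and a reference group are
computed, probes whose absolute difference exceeds a threshold are
chained (same sign, neighbouring qualifying CpGs ≤ lambda bp apart),
and maximal chains of at least two CpGs become regions.  Regions are
then screened by their maximal-difference sub-window ("region of
biggest change") and, optionally, by persistence of the difference in
every pairwise subgroup comparison.  Defaults: |Δβ| > 0.2 per probe and
per region, lambda = 1000 bp, ≥ 2 CpGs, max-change window > 0.3.

No smoothing and no per-CpG test statistics are applied: the rules are
explicit so that the caller is checkable against exhaustive window
enumeration on small fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import MethylationDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GroupContrast",
    "SubRegion",
    "DMRecord",
    "probe_deltas",
    "call_dmrs",
    "max_change_subregion",
    "persistence_filter",
]


@dataclass(frozen=True)
class GroupContrast:
    """Two disjoint, non-empty sample sets to compare (target − reference)."""

    target_samples: tuple[str, ...]
    reference_samples: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        t, r = set(self.target_samples), set(self.reference_samples)
        if not t or not r:
            raise ValueError("both contrast groups must be non-empty")
        if t & r:
            raise ValueError("contrast groups must be disjoint")


@dataclass(frozen=True)
class SubRegion:
    start: int
    end: int
    probe_ids: tuple[str, ...]
    mean_delta: float


@dataclass
class DMRecord:
    """A called region: consecutive qualifying CpGs on one chromosome.

    ``start``/``end`` are the 1-based positions of the first/last member
    CpG (inclusive).  ``mean_delta`` is the mean over member probes of
    (mean β in target − mean β in reference); negative = hypomethylated
    in the target.  ``max_subregion`` is filled by
    :func:`max_change_subregion`.
    """

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    mean_delta: float
    direction: str
    max_subregion: Optional[SubRegion] = None
    group_means: Optional[dict] = None

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 2:
            raise ValueError("a DMR needs at least 2 member CpGs")
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def probe_deltas(
    dataset: MethylationDataset,
    contrast: GroupContrast,
    max_missing_fraction: float = 0.2,
) -> pd.Series:
    """Per-probe mean β difference, target − reference.

    Probes missing in more than ``max_missing_fraction`` of all samples,
    or with no observed value in either group, are dropped (logged).
    Within a group, missing values are simply excluded from that
    group's mean.
    """
    for s in contrast.target_samples + contrast.reference_samples:
        if s not in dataset.beta.index:
            raise KeyError(f"sample {s!r} not in dataset")
    beta = dataset.beta
    frac_missing = beta.isna().mean(axis=0)
    keep = frac_missing <= max_missing_fraction
    if (~keep).any():
        logger.info("dropping %d probes missing in >%d%% of samples",
                    int((~keep).sum()), int(100 * max_missing_fraction))
    beta = beta.loc[:, keep]
    t_mean = beta.loc[list(contrast.target_samples)].mean(axis=0)
    r_mean = beta.loc[list(contrast.reference_samples)].mean(axis=0)
    delta = t_mean - r_mean
    bad = delta.isna()
    if bad.any():
        logger.info("dropping %d probes with an empty group mean", int(bad.sum()))
        delta = delta[~bad]
    return delta


def call_dmrs(
    deltas: pd.Series,
    manifest: pd.DataFrame,
    lambda_bp: int = 1000,
    min_probes: int = 2,
    delta_threshold: float = 0.2,
) -> list[DMRecord]:
    """Chain qualifying probes into maximal regions.

    A probe qualifies when |Δβ| > ``delta_threshold``.  Walking each
    chromosome in coordinate order over qualifying probes only,
    successive probes join one chain while they share the sign of Δβ
    and are ≤ ``lambda_bp`` apart.  Chains with ≥ ``min_probes`` members
    and |mean Δβ| > ``delta_threshold`` are emitted, sorted by
    coordinate.  Chains are maximal by construction and cannot overlap.
    """
    manifest = manifest.loc[manifest.index.intersection(deltas.index)]
    for chrom, sub in manifest.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError(f"manifest not sorted by position on {chrom}")

    records: list[DMRecord] = []
    for chrom, sub in manifest.groupby("chrom", sort=True):
        d = deltas.loc[sub.index]
        qual = sub.index[np.abs(d) > delta_threshold]
        chain: list[str] = []

        def flush(chain: list[str]) -> None:
            if len(chain) < min_probes:
                return
            mean_delta = float(deltas.loc[chain].mean())
            if abs(mean_delta) <= delta_threshold:
                return
            records.append(
                DMRecord(
                    chrom=str(chrom),
                    start=int(sub.loc[chain[0], "pos"]),
                    end=int(sub.loc[chain[-1], "pos"]),
                    probe_ids=tuple(chain),
                    mean_delta=mean_delta,
                    direction="hypo" if mean_delta < 0 else "hyper",
                )
            )

        for pid in qual:
            if chain:
                prev = chain[-1]
                gap = int(sub.loc[pid, "pos"]) - int(sub.loc[prev, "pos"])
                same_sign = np.sign(deltas.loc[pid]) == np.sign(deltas.loc[prev])
                if gap <= lambda_bp and same_sign:
                    chain.append(pid)
                    continue
                flush(chain)
            chain = [pid]
        flush(chain)
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def max_change_subregion(
    dmr: DMRecord,
    deltas: pd.Series,
    manifest: pd.DataFrame,
    threshold: float = 0.3,
) -> Optional[DMRecord]:
    """Apply the "region of biggest change" rule.

    Scans every contiguous window of ≥ 2 member probes, keeps the window
    maximising |mean Δβ| (ties → leftmost, then shortest), and passes
    the DMR iff that maximum exceeds ``threshold``.  Returns the record
    with ``max_subregion`` filled, or None when rejected.
    """
    probes = list(dmr.probe_ids)
    d = deltas.loc[probes].to_numpy(dtype=float)
    best: tuple[float, int, int] | None = None  # (|mean|, i, j)
    for i in range(len(probes) - 1):
        csum = 0.0
        for j in range(i, len(probes)):
            csum += d[j]
            if j - i + 1 < 2:
                continue
            mean = csum / (j - i + 1)
            key = abs(mean)
            if best is None or key > best[0] + 1e-15:
                best = (key, i, j)
    assert best is not None
    _, i, j = best
    window = probes[i : j + 1]
    sub = SubRegion(
        start=int(manifest.loc[window[0], "pos"]),
        end=int(manifest.loc[window[-1], "pos"]),
        probe_ids=tuple(window),
        mean_delta=float(d[i : j + 1].mean()),
    )
    if abs(sub.mean_delta) <= threshold:
        return None
    return replace(dmr, max_subregion=sub)


def persistence_filter(
    dmr: DMRecord,
    dataset: MethylationDataset,
    assignment: pd.Series,
    target_subgroup: int,
    threshold: float = 0.3,
) -> tuple[bool, pd.DataFrame]:
    """Require the differential signal in every pairwise comparison.

    For each non-target subgroup the target-vs-that-subgroup Δβ is
    recomputed over the DMR's member probes and the best ≥2-probe
    window mean must exceed ``threshold`` with the DMR's direction
    (e.g. < −0.3 everywhere for a hypomethylated region).  Returns the
    overall verdict and a per-comparison table.
    """
    others = sorted(set(assignment.unique()) - {target_subgroup})
    if not others:
        raise ValueError("need at least one non-target subgroup")
    target_samples = tuple(assignment.index[assignment == target_subgroup])
    sign = -1.0 if dmr.direction == "hypo" else 1.0
    rows = []
    all_pass = True
    for g in others:
        contrast = GroupContrast(
            target_samples=target_samples,
            reference_samples=tuple(assignment.index[assignment == g]),
            name=f"vs_subgroup_{g}",
        )
        d = probe_deltas(dataset, contrast).loc[list(dmr.probe_ids)].to_numpy()
        best = -np.inf
        n = len(d)
        for i in range(n - 1):
            csum = 0.0
            for j in range(i, n):
                csum += d[j]
                if j - i + 1 >= 2:
                    best = max(best, sign * csum / (j - i + 1))
        ok = best > threshold
        all_pass &= ok
        rows.append(
            {
                "comparison": contrast.name,
                "other_subgroup": g,
                "best_window_delta": sign * best,
                "passed": ok,
            }
        )
    return all_pass, pd.DataFrame(rows)
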