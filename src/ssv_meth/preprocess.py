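"""Probe-level preprocessing for methylation array data.

The pipeline consumes already-normalised β values (fraction methylated,
in [0, 1]) together with a probe manifest giving each CpG's genomic
coordinate.  This module provides the container types, the β↔M logit
transform used before clustering, user-supplied probe filtering, and
most-variable-probe selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "MScoreMatrix",
    "FilterResult",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "select_most_variable",
]


@dataclass
class MethylationDataset:
    """A sample × probe β-value matrix with its probe manifest.

    Parameters
    ----------
    beta
        DataFrame of β values in [0, 1]; index = sample IDs,
        columns = probe IDs, column order matching ``probes``.
    probes
        Manifest DataFrame indexed by probe ID with columns
        ``chrom`` and ``pos`` (1-based CpG position), sorted by
        (chrom, pos).
    """

    beta: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.columns.duplicated().any():
            raise ValueError("duplicate probe IDs in beta matrix")
        if self.beta.index.duplicated().any():
            raise ValueError("duplicate sample IDs in beta matrix")
        if self.probes.index.duplicated().any():
            raise ValueError("duplicate probe IDs in manifest")
        missing = self.beta.columns.difference(self.probes.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} beta columns absent from manifest "
                f"(first: {missing[0]!r})"
            )
        # keep manifest restricted to, and aligned with, the matrix
        sortable = self.probes.loc[list(self.beta.columns)]
        order = sortable.sort_values(["chrom", "pos"], kind="stable").index
        self.probes = sortable.loc[order]
        self.beta = self.beta.loc[:, order]
        vals = self.beta.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("β values must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]


@dataclass
class MScoreMatrix:
    """M-scores (logit-2 of β) with the clamping constant used."""

    m: pd.DataFrame
    epsilon: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.m.to_numpy()).all():
            raise ValueError("M-score matrix contains non-finite values")


def beta_to_m(dataset: MethylationDataset, epsilon: float = 0.001) -> MScoreMatrix:
    """Transform β to M-scores, M = log2(β'/(1−β')), β' clamped to
    [epsilon, 1−epsilon] so the logit stays finite at β ∈ {0, 1}.

    Strictly monotone in β; invertible on (epsilon, 1−epsilon) via
    :func:`m_to_beta`.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = dataset.beta.clip(lower=epsilon, upper=1 - epsilon)
    m = np.log2(b / (1 - b))
    return MScoreMatrix(m=m, epsilon=epsilon)


def m_to_beta(m: MScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m`: β = 2^M / (1 + 2^M)."""
    mat = m.m if isinstance(m, MScoreMatrix) else m
    p = np.exp2(mat)
    return p / (1 + p)


class FilterResult(NamedTuple):
    dataset: MethylationDataset
    n_removed: int
    unknown_ids: list[str]


def filter_probes(
    dataset: MethylationDataset,
    drop_ids: Iterable[str] = (),
    detection_fail: Optional[pd.Series] = None,
) -> FilterResult:
    """Remove listed and detection-flagged probes.

    ``drop_ids`` is typically a published blacklist (cross-reactive or
    SNP-confounded probes); ``detection_fail`` a boolean per-probe flag
    (True = poorly performing).  Unknown IDs in ``drop_ids`` warn but do
    not fail.  Survivor order is preserved.
    """
    drop = set(drop_ids)
    unknown = sorted(drop.difference(dataset.beta.columns))
    if unknown:
        warnings.warn(
            f"{len(unknown)} probe IDs in drop list not present in dataset",
            stacklevel=2,
        )
        drop -= set(unknown)
    if detection_fail is not None:
        flagged = set(detection_fail.index[detection_fail.astype(bool)])
        drop |= flagged & set(dataset.beta.columns)
    keep = [p for p in dataset.beta.columns if p not in drop]
    filtered = MethylationDataset(
        beta=dataset.beta.loc[:, keep].copy(),
        probes=dataset.probes.loc[keep].copy(),
    )
    return FilterResult(filtered, dataset.n_probes - len(keep), unknown)


def select_most_variable(m: MScoreMatrix, n_top: int) -> MScoreMatrix:
    """Keep the ``n_top`` probes with largest across-sample standard
    deviation (sample SD, n−1 denominator).

    Ties break lexicographically on probe ID for reproducibility.  If
    ``n_top`` ≥ probe count the matrix is returned unchanged.  Surviving
    probes keep their original (genomic) column order.
    """
    if n_top < 2:
        raise ValueError(f"n_top must be ≥ 2, got {n_top}")
    if n_top >= m.m.shape[1]:
        return MScoreMatrix(m=m.m.copy(), epsilon=m.epsilon)
    sds = m.m.std(axis=0, ddof=1)
    ranked = sorted(m.m.columns, key=lambda p: (-sds[p], p))
    chosen = set(ranked[:n_top])
    keep = [p for p in m.m.columns if p in chosen]
    return MScoreMatrix(m=m.m.loc[:, keep].copy(), epsilon=m.epsilon)
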