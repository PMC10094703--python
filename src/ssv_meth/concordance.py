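"""Concordance of candidate model samples with a subgroup's methylation.

Used to judge whether e.g. a cell line is a plausible model for a
methylation subgroup: (i) the average methylation over a region
(reported as a percentage, as methylation percentages are conventionally
printed), and (ii) the Pearson correlation between two sample sets'
per-probe mean β profiles across a window, reported as r² with a
two-sided p-value from the t distribution on n − 2 degrees of freedom.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MethylationDataset

__all__ = ["region_probes", "region_mean_methylation", "profile_correlation"]


def region_probes(
    dataset: MethylationDataset, chrom: str, start: int, end: int
) -> list[str]:
    """Manifest probes falling inside [start, end] on ``chrom`` (1-based,
    inclusive)."""
    man = dataset.probes
    mask = (man["chrom"] == chrom) & (man["pos"] >= start) & (man["pos"] <= end)
    return list(man.index[mask])


def region_mean_methylation(
    dataset: MethylationDataset,
    region: tuple[str, int, int],
    sample_set: Sequence[str],
) -> float:
    """Mean β over (region probes × samples), as a percentage."""
    probes = region_probes(dataset, *region)
    if not probes:
        raise ValueError(f"no probes overlap region {region}")
    samples = list(sample_set)
    if not samples:
        raise ValueError("empty sample set")
    vals = dataset.beta.loc[samples, probes].to_numpy(dtype=float)
    return float(np.nanmean(vals) * 100.0)


def profile_correlation(
    dataset: MethylationDataset,
    region: tuple[str, int, int],
    sample_set_a: Sequence[str],
    sample_set_b: Sequence[str],
) -> tuple[float, float]:
    """Correlate two groups' mean methylation profiles across a window.

    Each group is reduced to its per-probe mean β over the window's
    probes; Pearson correlation between the two profiles gives
    (r², two-sided p).  Symmetric in the two sets; needs ≥ 3 shared
    probes and nonzero variance in both profiles.
    """
    probes = region_probes(dataset, *region)
    if len(probes) < 3:
        raise ValueError(f"need ≥ 3 probes in region, found {len(probes)}")
    a = dataset.beta.loc[list(sample_set_a), probes].mean(axis=0).to_numpy()
    b = dataset.beta.loc[list(sample_set_b), probes].mean(axis=0).to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic**2), float(res.pvalue)
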