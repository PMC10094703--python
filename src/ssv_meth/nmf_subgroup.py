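"""Consensus bootstrapped NMF subgroup discovery.

Samples are clustered by factorising the (shifted, nonnegative) M-score
matrix into r metagenes, X ≈ W·H, and running K-means on the rows of the
sample-weight matrix W.  Every (r, k) combination in a grid is scored
for reproducibility: the full-data reference clustering is compared,
via best-permutation label matching, against re-fits on repeated random
subsamples of the cohort.  The (r, k) with the highest mean agreement
wins; the paper-scale defaults are r, k ∈ 2..10, 250 resamples of 80%
of the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

__all__ = [
    "FactorizationResult",
    "StabilitySurface",
    "SubgroupSolution",
    "nonnegative_shift",
    "run_nmf",
    "cluster_metagenes",
    "match_labels",
    "consensus_stability",
    "select_solution",
]


@dataclass
class FactorizationResult:
    """One NMF fit: X ≈ W·H with W (samples × r), H (r × probes)."""

    W: np.ndarray
    H: np.ndarray
    r: int
    reconstruction_error: float
    seed: int

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be nonnegative")
        if self.W.shape[1] != self.r or self.H.shape[0] != self.r:
            raise ValueError("factor shapes inconsistent with r")


@dataclass
class StabilitySurface:
    """Mean subgrouping reproducibility over the (r, k) grid."""

    scores: dict[tuple[int, int], float]
    n_boot: int
    subsample_fraction: float

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be ≥ 1")
        for (r, k), s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score at (r={r}, k={k}) outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = sorted({r for r, _ in self.scores})
        cols = sorted({k for _, k in self.scores})
        df = pd.DataFrame(index=rows, columns=cols, dtype=float)
        for (r, k), s in self.scores.items():
            df.loc[r, k] = s
        df.index.name = "r_metagenes"
        df.columns.name = "k_clusters"
        return df


@dataclass
class SubgroupSolution:
    """Final subgrouping: per-sample labels in 1..k plus provenance."""

    assignment: pd.Series
    k: int
    r: int
    stability: StabilitySurface | None = None
    consensus: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        labels = set(self.assignment.unique())
        if not labels.issubset(set(range(1, self.k + 1))):
            raise ValueError("labels must lie in 1..k")
        if len(labels) < self.k:
            raise ValueError("empty subgroup in assignment")

    def samples_in(self, subgroup: int) -> list[str]:
        return list(self.assignment.index[self.assignment == subgroup])


def nonnegative_shift(m: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, float]:
    """Shift a signed matrix so its minimum is exactly 0.

    NMF needs nonnegative input but M-scores are signed; a global
    affine shift preserves all between-sample structure.  Returns the
    shifted array and the shift applied.
    """
    arr = np.asarray(m, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite values")
    shift = float(arr.min())
    return arr - shift, -shift


def run_nmf(
    x: np.ndarray,
    r: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> FactorizationResult:
    """Multiplicative-update (Frobenius) NMF with random init.

    Deterministic for a fixed seed; reconstruction error is
    non-increasing over multiplicative updates.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    if (x < 0).any():
        raise ValueError("input must be nonnegative")
    if not 2 <= r <= min(x.shape):
        raise ValueError(f"r must be in [2, {min(x.shape)}], got {r}")
    model = NMF(
        n_components=r,
        solver="mu",
        beta_loss="frobenius",
        init="random",
        random_state=int(seed),
        max_iter=max_iter,
        tol=tol,
    )
    import warnings

    with warnings.catch_warnings():
        # max_iter acts as the stopping rule when tol is not reached
        warnings.filterwarnings("ignore", message=".*Maximum number of iterations.*")
        W = model.fit_transform(x)
    return FactorizationResult(
        W=W,
        H=model.components_,
        r=r,
        reconstruction_error=float(model.reconstruction_err_),
        seed=int(seed),
    )


def cluster_metagenes(
    W: np.ndarray, k: int, seed: int, n_init: int = 10
) -> np.ndarray:
    """K-means (k-means++ init, ``n_init`` restarts) on the rows of the
    metagene-weight matrix W.  Returns labels in 1..k."""
    W = np.asarray(W, dtype=float)
    if k > W.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {W.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=int(seed))
    return km.fit_predict(W) + 1


def match_labels(
    reference: pd.Series, candidate: pd.Series
) -> tuple[pd.Series, float]:
    """Optimally relabel ``candidate`` to match ``reference`` and score
    the agreement.

    The candidate may cover a subset of the reference's samples.  The
    optimal one-to-one label permutation is found by solving the
    assignment problem on the label contingency table (Hungarian
    algorithm), maximising the number of agreeing samples.  Returns the
    relabelled candidate and the agreement fraction in [0, 1].
    """
    shared = candidate.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("candidate and reference share no samples")
    if len(shared) < len(candidate):
        raise ValueError("candidate contains samples absent from reference")
    ref = reference.loc[shared]
    cand = candidate.loc[shared]
    ref_labels = sorted(ref.unique())
    cand_labels = sorted(cand.unique())
    table = np.zeros((len(cand_labels), len(ref_labels)), dtype=int)
    for i, cl in enumerate(cand_labels):
        for j, rl in enumerate(ref_labels):
            table[i, j] = int(((cand == cl) & (ref == rl)).sum())
    rows, cols = linear_sum_assignment(-table)
    mapping = {cand_labels[i]: ref_labels[j] for i, j in zip(rows, cols)}
    # labels with no partner (more candidate labels than reference) keep
    # a fresh label beyond the reference's range
    spare = [l for l in cand_labels if l not in mapping]
    next_free = max(ref_labels, default=0)
    for l in spare:
        next_free += 1
        mapping[l] = next_free
    relabelled = candidate.map(mapping)
    agreement = float((relabelled.loc[shared] == ref).mean())
    return relabelled, agreement


def _spawn_seed(master: int, *key: int) -> int:
    """Derive an independent 31-bit seed from the master seed and a
    spawn key, reproducibly."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _reference_fit(
    x: np.ndarray, r: int, k: int, seed: int, max_iter: int, tol: float
) -> np.ndarray:
    fac = run_nmf(x, r=r, seed=_spawn_seed(seed, r, 0), max_iter=max_iter, tol=tol)
    return cluster_metagenes(fac.W, k=k, seed=_spawn_seed(seed, r, k, 1))


def consensus_stability(
    m,
    r_range: Sequence[int] = range(2, 11),
    k_range: Sequence[int] = range(2, 11),
    n_boot: int = 250,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> StabilitySurface:
    """Score every (r, k) for subgrouping reproducibility.

    For each r the matrix is factorised once on the full cohort and once
    per subsample (``n_boot`` draws of ⌈fraction·n⌉ samples without
    replacement); for each k, K-means labels from each subsample fit are
    matched (best permutation) against the full-data reference
    restricted to the subsample, and the score is the mean agreement.

    ``m`` may be an MScoreMatrix, DataFrame or array (samples × probes);
    the nonnegative shift is applied internally.
    """
    mat = m.m if hasattr(m, "m") else m
    samples = (
        list(mat.index) if isinstance(mat, pd.DataFrame) else list(range(len(mat)))
    )
    x, _ = nonnegative_shift(mat)
    n = x.shape[0]
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if n_boot < 1:
        raise ValueError("n_boot must be ≥ 1")
    sub_n = int(np.ceil(subsample_fraction * n))
    if sub_n < max(k_range):
        raise ValueError(
            f"subsample of {sub_n} samples smaller than largest k {max(k_range)}"
        )
    rng = np.random.default_rng(_spawn_seed(seed, 999_999))
    # fixed subsample indices shared across the whole grid
    subsets = [rng.choice(n, size=sub_n, replace=False) for _ in range(n_boot)]

    scores: dict[tuple[int, int], float] = {}
    for r in r_range:
        ref_fac = run_nmf(
            x, r=r, seed=_spawn_seed(seed, r, 0), max_iter=max_iter, tol=tol
        )
        boot_facs = []
        for b, idx in enumerate(subsets):
            if sub_n == n:
                # degenerate resample: identical data, reproduce the
                # reference fit exactly
                boot_facs.append((idx, ref_fac))
            else:
                fac = run_nmf(
                    x[idx],
                    r=r,
                    seed=_spawn_seed(seed, r, 0, b + 1),
                    max_iter=max_iter,
                    tol=tol,
                )
                boot_facs.append((idx, fac))
        for k in k_range:
            ref_labels = cluster_metagenes(
                ref_fac.W, k=k, seed=_spawn_seed(seed, r, k, 1)
            )
            reference = pd.Series(ref_labels, index=samples)
            agreements = []
            for b, (idx, fac) in enumerate(boot_facs):
                if sub_n == n:
                    boot_seed = _spawn_seed(seed, r, k, 1)
                else:
                    boot_seed = _spawn_seed(seed, r, k, 1, b + 1)
                labels = cluster_metagenes(fac.W, k=k, seed=boot_seed)
                # rows of W follow the fit's input order: the original
                # order for the degenerate full resample, idx otherwise
                order = samples if sub_n == n else [samples[i] for i in idx]
                cand = pd.Series(labels, index=order)
                _, agr = match_labels(reference, cand)
                agreements.append(agr)
            scores[(int(r), int(k))] = float(np.mean(agreements))
    return StabilitySurface(
        scores=scores, n_boot=n_boot, subsample_fraction=subsample_fraction
    )


def select_solution(
    surface: StabilitySurface,
    m,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    consensus_boot: int | None = None,
) -> SubgroupSolution:
    """Pick the most reproducible (r, k) and refit on the full cohort.

    Ties break towards the smallest k, then the smallest r.  The
    consensus matrix is the co-clustering frequency over
    ``consensus_boot`` subsample re-fits at the chosen (r, k)
    (default: the surface's own n_boot).
    """
    if not surface.scores:
        raise ValueError("empty stability surface")
    best_rk = min(surface.scores, key=lambda rk: (-surface.scores[rk], rk[1], rk[0]))
    r, k = best_rk
    mat = m.m if hasattr(m, "m") else m
    samples = (
        list(mat.index) if isinstance(mat, pd.DataFrame) else list(range(len(mat)))
    )
    x, _ = nonnegative_shift(mat)
    n = x.shape[0]
    ref_fac = run_nmf(x, r=r, seed=_spawn_seed(seed, r, 0), max_iter=max_iter, tol=tol)
    labels = cluster_metagenes(ref_fac.W, k=k, seed=_spawn_seed(seed, r, k, 1))
    assignment = pd.Series(labels, index=samples, name="subgroup")

    n_boot = surface.n_boot if consensus_boot is None else consensus_boot
    sub_n = int(np.ceil(surface.subsample_fraction * n))
    rng = np.random.default_rng(_spawn_seed(seed, 888_888))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for b in range(n_boot):
        idx = rng.choice(n, size=sub_n, replace=False)
        if sub_n == n:
            boot_labels = labels[idx]
        else:
            fac = run_nmf(
                x[idx],
                r=r,
                seed=_spawn_seed(seed, r, 0, b + 1),
                max_iter=max_iter,
                tol=tol,
            )
            boot_labels = cluster_metagenes(
                fac.W, k=k, seed=_spawn_seed(seed, r, k, 1, b + 1)
            )
        same = boot_labels[:, None] == boot_labels[None, :]
        ix = np.ix_(idx, idx)
        sampled[ix] += 1
        together[ix] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus_df = pd.DataFrame(consensus, index=samples, columns=samples)
    return SubgroupSolution(
        assignment=assignment,
        k=k,
        r=r,
        stability=surface,
        consensus=consensus_df,
    )
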