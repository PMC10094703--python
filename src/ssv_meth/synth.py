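"""Synthetic methylation + expression datasets with planted structure.

Emulates the statistical shape of 450K-style array data that the
analysis assumes: sparse, irregularly spaced CpG probes on a handful of
chromosomes, a bimodal β distribution (unmethylated mode near 0.1,
methylated mode near 0.85), k latent sample subgroups separated by
subgroup-differential "background" regions, and planted SSV loci —
promoter regions that stay unmethylated, with elevated gene expression,
in exactly one subgroup and are methylated everywhere else.

The ground truth (sample labels, SSV gene coordinates, background
region coordinates) is returned alongside the data so that recovery of
subgroups and candidates can be checked exactly.

Placement rules (deliberate, see docs/methods.md): SSV loci live on the
first chromosome, which carries no background regions; background
regions are distal — decoy gene TSSs are kept ≥ 25 kb away from every
planted region, so only SSV loci are promoter DMRs.  Within a planted
region consecutive probes are < 1 kb apart and the flanking gaps exceed
1 kb, so every planted region is recoverable (and maximal) under the
caller's chaining rule.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import MethylationDataset

__all__ = ["SynthConfig", "SynthTruth", "generate_dataset", "write_fixture", "read_fixture"]

# β modes of the bimodal baseline mixture
LOW_MODE = 0.10
HIGH_MODE = 0.85


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the generator; defaults mimic a small array cohort."""

    n_samples: int = 120
    k_true: int = 5
    n_probes: int = 4000
    n_chromosomes: int = 4
    probe_spacing: float = 1500.0
    n_background_dmrs: int = 20
    n_ssv_loci: int = 2
    ssv_subgroup: int = 2
    n_decoy_genes: int = 200
    beta_noise_sd: float = 0.05
    expression_effect: float = 2.0
    expression_noise_sd: float = 0.5
    n_control_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.k_true <= 10:
            raise ValueError("k_true must be in [2, 10]")
        if not 1 <= self.ssv_subgroup <= self.k_true:
            raise ValueError("ssv_subgroup must be in 1..k_true")
        if not 0 <= self.beta_noise_sd <= 0.2:
            raise ValueError("beta_noise_sd must be in [0, 0.2]")
        for name in ("n_samples", "n_probes", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_background_dmrs", "n_ssv_loci", "n_decoy_genes",
                     "n_control_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")


@dataclass
class SynthTruth:
    """What was planted: the oracle for recovery tests.

    ``sample_subgroup`` maps sample ID → subgroup label in 1..k_true
    (control samples, if any, get label 0).  ``ssv_genes`` lists
    (gene_id, chrom, start, end, ssv_subgroup) for each planted locus;
    ``background_dmr_coords`` lists
    (subgroup, chrom, start, end, direction).
    """

    sample_subgroup: dict[str, int]
    ssv_genes: list[tuple[str, str, int, int, int]]
    background_dmr_coords: list[tuple[int, str, int, int, str]]


@dataclass
class _Run:
    """A planted run of consecutive probes on one chromosome."""

    chrom: int
    start_idx: int  # index within the chromosome's probes
    length: int
    kind: str  # "ssv" | "background"
    subgroup: int
    direction: str  # "hypo" | "hyper" (in the differential subgroup)


def _plan_runs(config: SynthConfig, rng: np.random.Generator) -> list[_Run]:
    """Lay planted runs out in probe-index space with wide margins.

    SSV runs go on chromosome 0; background runs on the remaining
    chromosomes (or chromosome 0 too when there is only one and no SSV
    loci).  Raises when the probe grid cannot host all runs.
    """
    per_chrom = np.full(config.n_chromosomes, config.n_probes // config.n_chromosomes)
    per_chrom[: config.n_probes % config.n_chromosomes] += 1

    n_background = config.k_true * config.n_background_dmrs
    if config.n_ssv_loci > 0 and n_background > 0 and config.n_chromosomes < 2:
        raise ValueError(
            "need ≥ 2 chromosomes to separate SSV loci from background regions"
        )
    background_chroms = (
        list(range(1, config.n_chromosomes))
        if config.n_ssv_loci > 0 and config.n_chromosomes > 1
        else list(range(config.n_chromosomes))
    )

    # flanking probes between planted runs; inter-run genomic separation
    # is guaranteed by the >1 kb boundary gaps drawn at run edges
    margin = 3
    runs: list[_Run] = []

    def place(chrom: int, specs: list[tuple[str, int, str, int]]) -> None:
        # specs: (kind, subgroup, direction, length)
        n_here = int(per_chrom[chrom])
        n_runs = len(specs)
        if n_runs == 0:
            return
        block = n_here // n_runs
        for i, (kind, subgroup, direction, length) in enumerate(specs):
            slack = block - length - 2 * margin
            if slack < 1:
                raise ValueError(
                    f"planted regions do not fit: chromosome {chrom} holds "
                    f"{n_here} probes for {n_runs} regions"
                )
            start = block * i + margin + int(rng.integers(0, slack))
            runs.append(_Run(chrom, start, length, kind, subgroup, direction))

    ssv_specs = [
        ("ssv", config.ssv_subgroup, "hypo", int(rng.integers(3, 6)))
        for _ in range(config.n_ssv_loci)
    ]
    bg_specs = []
    for g in range(1, config.k_true + 1):
        for j in range(config.n_background_dmrs):
            direction = "hypo" if (j % 2 == 0 and g != config.ssv_subgroup) else "hyper"
            # the target subgroup's background regions are hyper-only:
            # a distal hypo region in the target would be
            # methylation-identical to an SSV locus
            bg_specs.append(("background", g, direction, int(rng.integers(3, 7))))
    rng.shuffle(bg_specs)

    if config.n_ssv_loci > 0:
        place(0, ssv_specs)
    # round-robin background runs over their chromosomes
    buckets: dict[int, list] = {c: [] for c in background_chroms}
    for i, spec in enumerate(bg_specs):
        buckets[background_chroms[i % len(background_chroms)]].append(spec)
    for c, specs in buckets.items():
        place(c, specs)
    return runs


def generate_dataset(
    config: SynthConfig,
) -> tuple[MethylationDataset, pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Generate (methylation, expression, gene annotation, truth).

    Identical config (including seed) gives bit-identical output.
    Expression is genes × samples on a log2 scale; annotation has
    columns gene_id, chrom, tss_pos, strand.
    """
    rng = np.random.default_rng(config.seed)

    # ---- samples -----------------------------------------------------
    labels = np.array(
        [(i % config.k_true) + 1 for i in range(config.n_samples)], dtype=int
    )
    rng.shuffle(labels)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    control_ids = [f"N{i + 1:03d}" for i in range(config.n_control_samples)]
    all_ids = sample_ids + control_ids
    n_total = len(all_ids)

    # ---- probe layout ------------------------------------------------
    runs = _plan_runs(config, rng)
    per_chrom = np.full(config.n_chromosomes, config.n_probes // config.n_chromosomes)
    per_chrom[: config.n_probes % config.n_chromosomes] += 1

    chroms: list[str] = []
    positions: list[int] = []
    probe_ids: list[str] = []
    run_of_probe: dict[int, _Run] = {}  # global probe index -> run
    global_idx = 0
    for c in range(config.n_chromosomes):
        runs_here = [r for r in runs if r.chrom == c]
        in_run = {}
        boundary = set()
        for r in runs_here:
            for j in range(r.length):
                in_run[r.start_idx + j] = r
            boundary.add(r.start_idx)  # gap *into* the run
            boundary.add(r.start_idx + r.length)  # gap *out of* the run
        pos = 10_000
        for i in range(int(per_chrom[c])):
            if i > 0:
                if i in in_run and (i - 1) in in_run and in_run[i] is in_run[i - 1]:
                    gap = int(rng.integers(150, 851))  # inside a planted run
                elif i in boundary:
                    gap = 1300 + int(rng.exponential(config.probe_spacing))
                else:
                    gap = 100 + int(rng.exponential(config.probe_spacing))
                pos += gap
            chroms.append(f"chr{c + 1}")
            positions.append(pos)
            probe_ids.append(f"cg{global_idx:07d}")
            if i in in_run:
                run_of_probe[global_idx] = in_run[i]
            global_idx += 1

    manifest = pd.DataFrame(
        {"chrom": chroms, "pos": positions}, index=pd.Index(probe_ids, name="probe_id")
    )

    # ---- β means -----------------------------------------------------
    n_probes = len(probe_ids)
    base_low = rng.random(n_probes) < 0.5
    baseline = np.where(
        base_low,
        rng.normal(LOW_MODE, 0.03, n_probes),
        rng.normal(HIGH_MODE, 0.03, n_probes),
    ).clip(0.02, 0.98)

    mu = np.tile(baseline, (n_total, 1))  # samples × probes
    label_of_row = np.concatenate([labels, np.zeros(config.n_control_samples, int)])

    for p_idx, run in run_of_probe.items():
        jitter = float(rng.normal(0, 0.02))
        in_group = label_of_row == run.subgroup
        if run.kind == "ssv":
            hi = np.clip(HIGH_MODE + jitter, 0.02, 0.98)
            lo = np.clip(LOW_MODE + jitter, 0.02, 0.98)
            mu[:, p_idx] = hi
            mu[in_group, p_idx] = lo
            if config.n_control_samples:
                # normal-like controls share the low, unmethylated profile
                mu[label_of_row == 0, p_idx] = lo
        elif run.direction == "hypo":
            mu[:, p_idx] = np.clip(0.85 + jitter, 0.02, 0.98)
            mu[in_group, p_idx] = np.clip(0.25 + jitter, 0.02, 0.98)
        else:
            mu[:, p_idx] = np.clip(0.15 + jitter, 0.02, 0.98)
            mu[in_group, p_idx] = np.clip(0.75 + jitter, 0.02, 0.98)

    beta = mu + rng.normal(0, config.beta_noise_sd, mu.shape)
    beta = beta.clip(0.001, 0.999)
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=all_ids, columns=probe_ids),
        probes=manifest,
    )

    # ---- genes -------------------------------------------------------
    run_intervals: dict[str, list[tuple[int, int]]] = {}
    run_coords: dict[int, tuple[str, int, int]] = {}
    for rid, run in enumerate(runs):
        member_pos = [
            positions[g]
            for g, rn in run_of_probe.items()
            if rn is run
        ]
        coord = (f"chr{run.chrom + 1}", min(member_pos), max(member_pos))
        run_coords[id(run)] = coord
        run_intervals.setdefault(coord[0], []).append((coord[1], coord[2]))

    genes: list[dict] = []
    ssv_truth: list[tuple[str, str, int, int, int]] = []
    ssv_runs = [r for r in runs if r.kind == "ssv"]
    for i, run in enumerate(ssv_runs):
        chrom, start, end = run_coords[id(run)]
        tss = start - int(rng.integers(200, 2001))
        genes.append(
            {
                "gene_id": f"SSVG{i + 1}",
                "chrom": chrom,
                "tss_pos": max(tss, 1),
                "strand": str(rng.choice(["+", "-"])),
            }
        )
        ssv_truth.append((f"SSVG{i + 1}", chrom, start, end, run.subgroup))

    chrom_span = {
        f"chr{c + 1}": (10_000, max(p for ch, p in zip(chroms, positions) if ch == f"chr{c + 1}"))
        for c in range(config.n_chromosomes)
    }
    exclusion = 25_000
    for i in range(config.n_decoy_genes):
        for _ in range(1000):
            c = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
            lo, hi = chrom_span[c]
            pos = int(rng.integers(lo, hi + 1))
            clash = any(
                s - exclusion <= pos <= e + exclusion
                for s, e in run_intervals.get(c, [])
            )
            if not clash:
                break
        else:
            raise ValueError("could not place decoy genes clear of planted regions")
        genes.append(
            {
                "gene_id": f"GENE{i + 1:04d}",
                "chrom": c,
                "tss_pos": pos,
                "strand": str(rng.choice(["+", "-"])),
            }
        )
    annotation = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss_pos", "strand"])

    # ---- expression --------------------------------------------------
    gene_ids = list(annotation["gene_id"])
    baseline_expr = rng.uniform(3.0, 8.0, len(gene_ids))
    expr = baseline_expr[:, None] + rng.normal(
        0, config.expression_noise_sd, (len(gene_ids), n_total)
    )
    expression = pd.DataFrame(expr, index=gene_ids, columns=all_ids)
    in_target = label_of_row == config.ssv_subgroup
    for gid, *_ in ssv_truth:
        expression.loc[gid, in_target] += config.expression_effect
        if config.n_control_samples:
            expression.loc[gid, label_of_row == 0] += config.expression_effect

    truth = SynthTruth(
        sample_subgroup={
            sid: int(lab) for sid, lab in zip(all_ids, label_of_row)
        },
        ssv_genes=ssv_truth,
        background_dmr_coords=[
            (r.subgroup, *run_coords[id(r)], r.direction)
            for r in runs
            if r.kind == "background"
        ],
    )
    return dataset, expression, annotation, truth


def write_fixture(
    dataset: MethylationDataset,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    truth: SynthTruth,
    dir_path: str | Path,
) -> dict[str, Path]:
    """Write the dataset bundle as plain-text files that round-trip.

    Emits beta.tsv (probes × samples), manifest.tsv, expression.tsv,
    tss.tsv and truth.json under ``dir_path``.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": d / "beta.tsv",
        "manifest": d / "manifest.tsv",
        "expression": d / "expression.tsv",
        "tss": d / "tss.tsv",
        "truth": d / "truth.json",
    }
    # %.17g prints enough digits that float64 values round-trip exactly
    dataset.beta.T.to_csv(
        paths["beta"], sep="\t", index_label="probe_id", float_format="%.17g"
    )
    dataset.probes.to_csv(paths["manifest"], sep="\t", index_label="probe_id")
    expression.to_csv(
        paths["expression"], sep="\t", index_label="gene_id", float_format="%.17g"
    )
    annotation.to_csv(paths["tss"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "sample_subgroup": truth.sample_subgroup,
                "ssv_genes": [list(t) for t in truth.ssv_genes],
                "background_dmr_coords": [list(t) for t in truth.background_dmr_coords],
            },
            fh,
            indent=2,
        )
    return paths


def read_fixture(dir_path: str | Path):
    """Read back a bundle written by :func:`write_fixture`."""
    from .io import load_methylation_dataset, read_expression, read_tss

    d = Path(dir_path)
    dataset = load_methylation_dataset(d / "beta.tsv", d / "manifest.tsv")
    expression = read_expression(d / "expression.tsv")
    annotation = read_tss(d / "tss.tsv")
    with open(d / "truth.json") as fh:
        raw = json.load(fh)
    truth = SynthTruth(
        sample_subgroup={k: int(v) for k, v in raw["sample_subgroup"].items()},
        ssv_genes=[tuple(t) for t in raw["ssv_genes"]],
        background_dmr_coords=[tuple(t) for t in raw["background_dmr_coords"]],
    )
    return dataset, expression, annotation, truth
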