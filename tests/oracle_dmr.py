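"""Brute-force oracle for the DMR caller.

Independent of the package's chaining implementation: enumerates every
contiguous window of the sign-consistent qualifying-probe subsequence
per chromosome and keeps windows that satisfy all rules and cannot be
extended.  Used to verify call_dmrs/max_change_subregion exactly on
small fixtures.
"""

import numpy as np


def oracle_regions(deltas, manifest, lambda_bp=1000, min_probes=2,
                   delta_threshold=0.2):
    """Return maximal qualifying regions as a list of
    (chrom, probe_id tuple, mean_delta) sorted by coordinate."""

    def qualifies(chrom_probes, positions, window):
        ids = chrom_probes[window[0]: window[1] + 1]
        d = np.array([deltas[p] for p in ids])
        if len(ids) < min_probes:
            return False
        if not (np.all(d > delta_threshold) or np.all(d < -delta_threshold)):
            return False
        pos = [positions[p] for p in ids]
        if any(b - a > lambda_bp for a, b in zip(pos, pos[1:])):
            return False
        return abs(d.mean()) > delta_threshold

    out = []
    positions = dict(zip(manifest.index, manifest["pos"]))
    for chrom in manifest["chrom"].unique():
        sub = manifest[manifest["chrom"] == chrom]
        qual = [p for p in sub.index
                if p in deltas.index and abs(deltas[p]) > delta_threshold]
        n = len(qual)
        for i in range(n):
            for j in range(i, n):
                if not qualifies(qual, positions, (i, j)):
                    continue
                # maximal: no qualifying extension on either side
                if i > 0 and qualifies(qual, positions, (i - 1, j)):
                    continue
                if j < n - 1 and qualifies(qual, positions, (i, j + 1)):
                    continue
                ids = tuple(qual[i: j + 1])
                mean = float(np.mean([deltas[p] for p in ids]))
                out.append((str(chrom), ids, mean))
    out.sort(key=lambda t: (t[0], min(positions[p] for p in t[1])))
    return out


def oracle_max_window(deltas, probe_ids):
    """Exhaustive best ≥2-probe contiguous window by |mean delta|."""
    d = [deltas[p] for p in probe_ids]
    best = None
    for i in range(len(d)):
        for j in range(i + 1, len(d)):
            mean = float(np.mean(d[i: j + 1]))
            if best is None or abs(mean) > abs(best):
                best = mean
    return best


def random_fixture(rng, max_probes=50):
    """A random single-chromosome delta/manifest pair for oracle checks."""
    import pandas as pd

    n = int(rng.integers(2, max_probes + 1))
    gaps = rng.integers(50, 2200, size=n - 1)
    pos = 1000 + np.concatenate([[0], np.cumsum(gaps)])
    probe_ids = [f"cg{i:04d}" for i in range(n)]
    manifest = pd.DataFrame(
        {"chrom": "chr1", "pos": pos.astype(int)},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    deltas = pd.Series(rng.uniform(-0.6, 0.6, size=n), index=probe_ids)
    return deltas, manifest
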