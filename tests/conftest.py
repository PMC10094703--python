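import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ssv_meth import MethylationDataset, SynthConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_dataset(beta_rows, positions, chrom="chr1", samples=None, chroms=None):
    """Build a MethylationDataset from a list of per-sample β rows and
    probe positions (single chromosome unless ``chroms`` is given)."""
    beta = np.asarray(beta_rows, dtype=float)
    n_samples, n_probes = beta.shape
    probe_ids = [f"cg{i:04d}" for i in range(n_probes)]
    samples = samples or [f"S{i + 1}" for i in range(n_samples)]
    manifest = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else [chrom] * n_probes,
            "pos": list(positions),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return MethylationDataset(
        beta=pd.DataFrame(beta, index=samples, columns=probe_ids),
        probes=manifest,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted dataset shared across tests: 3 subgroups,
    2 SSV loci for subgroup 2, modest noise."""
    config = SynthConfig(
        n_samples=60,
        k_true=3,
        n_probes=1500,
        n_chromosomes=3,
        n_background_dmrs=8,
        n_ssv_loci=2,
        ssv_subgroup=2,
        n_decoy_genes=60,
        beta_noise_sd=0.04,
        seed=11,
    )
    dataset, expression, annotation, truth = generate_dataset(config)
    assignment = pd.Series(truth.sample_subgroup, name="subgroup")
    return {
        "config": config,
        "dataset": dataset,
        "expression": expression,
        "annotation": annotation,
        "truth": truth,
        "assignment": assignment[assignment > 0],
    }
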