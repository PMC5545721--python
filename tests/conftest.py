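"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexpci.network import module_eigengene
from coexpci.prep import residualize
from coexpci.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-regime cohort with a small background (fast eigengene work)."""
    return simulate_cohort(CohortConfig(seed=0, n_background_genes=15))


@pytest.fixture(scope="session")
def small_me(small_cohort):
    resid = residualize(small_cohort.expression, small_cohort.covariates)
    return module_eigengene(
        resid, small_cohort.truth.module_gene_ids, small_cohort.truth.seed_gene_id
    )


@pytest.fixture(scope="session")
def full_cohort():
    """Full default cohort (915 background genes) for network-scale tests."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_snp_meta(mafs, chrom="1", start_pos=1000, spacing=1_000_000):
    """SNP metadata frame helper with evenly spaced positions."""
    ids = [f"t{i + 1:03d}" for i in range(len(mafs))]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [start_pos + i * spacing for i in range(len(mafs))],
            "minor": "A",
            "major": "G",
            "maf": list(mafs),
        },
        index=ids,
    )
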