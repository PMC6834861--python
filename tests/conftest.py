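"""Shared fixtures: seeded synthetic cohorts and a tiny hand-built dataset helper."""

from __future__ import annotations

import numpy as np
import pytest

from repliqc import (
    CohortDataset,
    ReplicateMap,
    VariantSite,
    gatk_pass_prefilter,
    partition_by_allele_count,
    remove_monomorphic,
)
from repliqc.synthetic_cohort import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Seed-1 fixture cohort: 2,000 sites, 20 samples, 4 replicate pairs."""
    params = SimulationParams(
        n_sites=2000,
        n_samples=20,
        n_replicate_pairs=4,
        discordance_prob=0.05,
        seed=1,
    )
    dataset, truth = generate_cohort(params)
    return params, dataset, truth


@pytest.fixture(scope="session")
def biallelic_indices(cohort):
    """Pre-QC'd biallelic site indices of the seed-1 cohort."""
    _, dataset, _ = cohort
    idx = gatk_pass_prefilter(dataset)
    idx = remove_monomorphic(dataset, idx)
    parts = partition_by_allele_count([dataset.sites[i] for i in idx])
    return idx[parts["biallelic"]]


def make_dataset(sites, gt, samples=None, dp=None, gq=None, pairs=(), singletons=None):
    """Small hand-built CohortDataset; gt rows are per-site lists of (a, b)."""
    gt = np.asarray(gt, dtype=np.int16)
    n_sites, n_samples = gt.shape[:2]
    if samples is None:
        samples = [f"P{j}" for j in range(n_samples)]
    paired = {s for p in pairs for s in p}
    rmap = ReplicateMap(
        pairs=list(pairs),
        singletons=[s for s in samples if s not in paired] if singletons is None else singletons,
    )
    return CohortDataset(
        sites=list(sites),
        samples=list(samples),
        gt=gt,
        dp=np.full((n_sites, n_samples), 30, dtype=np.int32) if dp is None else np.asarray(dp, dtype=np.int32),
        gq=np.full((n_sites, n_samples), 80, dtype=np.int32) if gq is None else np.asarray(gq, dtype=np.int32),
        replicate_map=rmap,
    )


def snv(pos=100, chrom="1", ref="A", alt="G", **kw):
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alts=(alt,), **kw)
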