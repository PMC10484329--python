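"""Shared fixtures: hand-built toy genotype panels and seeded synthetic
panels reused across recovery tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apiscan.matrix import SNPMatrix


def make_matrix(
    genotypes,
    populations,
    ploidy=None,
    chrom=None,
    pos=None,
    samples=None,
):
    """Build an SNPMatrix from a nested list of (a, b) genotype pairs.

    ``genotypes`` is sites x samples of 2-tuples (use (-1, -1) for missing,
    (a, -1) for haploid calls).
    """
    g = np.array(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape[0], g.shape[1]
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if ploidy is None:
        ploidy = [2] * n_samples
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    return SNPMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        genotypes=g,
        samples=list(samples),
        populations=np.array(populations, dtype=object),
        ploidy=np.array(ploidy, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def default_panels():
    """Twenty seeded default-configuration synthetic panels (config,
    frequencies, genotype matrix, truth), shared by the recovery tests."""
    from apiscan import simdata

    panels = []
    for seed in range(1, 21):
        cfg = simdata.SimConfig(seed=seed)
        anc, freqs = simdata.generate_lineage_frequencies(cfg)
        mat, truth = simdata.generate_admixed_genotypes(freqs, cfg, ancestral=anc)
        panels.append((cfg, freqs, mat, truth))
    return panels
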