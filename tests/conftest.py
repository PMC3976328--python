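"""Shared fixtures: small hand-built panels and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from haplofine.genotypes import MISSING, CohortPanel, Sample, Variant
from haplofine.simulate import default_scenario, simulate_panel


def make_panel(
    genotypes,
    phenotypes=None,
    populations=None,
    sexes=None,
    positions=None,
    chrom="3",
):
    """Build a CohortPanel from a genotype matrix with sensible defaults.

    Variants are named snp1..snpM with alleles A (major) / G (minor).
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    phenotypes = phenotypes or ["case" if i < n // 2 else "control" for i in range(n)]
    populations = populations or ["pop1"] * n
    sexes = sexes or ["female" if i % 2 else "male" for i in range(n)]
    positions = positions or [1000 * (j + 1) for j in range(m)]
    variants = [
        Variant(f"snp{j + 1}", chrom, positions[j], "A", "G") for j in range(m)
    ]
    samples = [
        Sample(f"s{i + 1}", populations[i], sexes[i], phenotypes[i]) for i in range(n)
    ]
    return CohortPanel(variants, samples, g)


def hw_genotypes(rng, n, freqs):
    """Independent Hardy-Weinberg genotypes, one column per allele freq."""
    return np.column_stack(
        [rng.binomial(2, f, size=n) for f in np.atleast_1d(freqs)]
    ).astype(np.int8)


@pytest.fixture(scope="session")
def scenario_small():
    """Six-cohort scenario at scale 0.1 (about 2 500 samples), seed 1."""
    cfg = default_scenario(scale=0.1, seed=1)
    panel, truth = simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def scenario_small_pops(scenario_small):
    _cfg, panel, _truth = scenario_small
    return panel.split_by_population()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
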