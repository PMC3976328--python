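"""LD statistics, EM phasing against an exhaustive oracle, block building."""

import itertools

import numpy as np
import pytest

from haplofine.genotypes import MISSING, CohortPanel, Sample, Variant
from haplofine.ld_phase import (
    LDError,
    build_blocks,
    dprime_ci,
    ld_pair,
    phase_em,
)
from haplofine.simulate import (
    PROTECTIVE_HAPLOTYPE,
    SimConfig,
    default_scenario,
    simulate_panel,
)

from conftest import hw_genotypes, make_panel


def exhaustive_em_oracle(G, max_iter=2000, tol=1e-12):
    """Dense EM over all 2^L haplotypes and all ordered pairs per
    individual; written independently of the package implementation."""
    G = np.asarray(G)
    n, L = G.shape
    haps = np.array(list(itertools.product([0, 1], repeat=L)))  # (2^L, L)
    K = len(haps)
    p = G.astype(float)
    p[p == MISSING] = np.nan
    allele = np.nanmean(p / 2, axis=0)
    freqs = np.prod(np.where(haps == 1, allele, 1 - allele), axis=1)
    freqs /= freqs.sum()
    # compatibility of ordered pair (k1, k2) with each row
    compat = np.zeros((n, K, K), dtype=bool)
    for i in range(n):
        g = G[i]
        obs = g != MISSING
        s = haps[:, None, :] + haps[None, :, :]
        compat[i] = (s[:, :, obs] == g[obs]).all(axis=2)
    for _ in range(max_iter):
        w = freqs[None, :, None] * freqs[None, None, :] * compat
        norm = w.sum(axis=(1, 2), keepdims=True)
        ok = norm[:, 0, 0] > 0
        w = np.where(norm > 0, w / np.maximum(norm, 1e-300), 0.0)
        counts = w[ok].sum(axis=(0, 2)) + w[ok].sum(axis=(0, 1))
        new = counts / counts.sum()
        if np.abs(new - freqs).max() < tol:
            freqs = new
            break
        freqs = new
    strings = ["".join("G" if b else "A" for b in h) for h in haps]
    return dict(zip(strings, freqs))


def random_genotype_fixture(rng, n, L, missing_rate=0.0):
    """Random LD-structured genotypes: 3 random haplotypes plus noise."""
    pool = rng.integers(0, 2, size=(3, L))
    probs = rng.dirichlet(np.ones(3))
    idx = rng.choice(3, size=(n, 2), p=probs)
    g = pool[idx[:, 0]] + pool[idx[:, 1]]
    flip = rng.random((n, L)) < 0.05
    g = np.clip(g + flip * rng.choice([-1, 1], size=(n, L)), 0, 2)
    if missing_rate:
        g[rng.random((n, L)) < missing_rate] = MISSING
    return g.astype(np.int8)


class TestLdPair:
    def test_self_ld_is_complete(self):
        g = np.array([[0], [1], [2], [1], [0], [2]], dtype=np.int8)
        panel = CohortPanel(
            [Variant("a", "3", 100, "A", "G"), Variant("b", "3", 200, "A", "G")],
            [Sample(f"s{i}", "p") for i in range(6)],
            np.hstack([g, g]),
        )
        stats = ld_pair(panel, "a", "b")
        assert stats.r2 == pytest.approx(1.0, abs=1e-6)
        assert stats.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_near_zero_r2(self, rng):
        panel = make_panel(hw_genotypes(rng, 50_000, [0.3, 0.4]))
        assert ld_pair(panel, "snp1", "snp2").r2 < 0.001

    def test_known_phase_fixture_matches_direct_counting(self):
        # six individuals, no double heterozygotes -> phase is unambiguous
        g = np.array(
            [[2, 2], [2, 1], [0, 0], [0, 1], [1, 2], [0, 0]], dtype=np.int8
        )
        panel = make_panel(g)
        # direct haplotype counting (12 haplotypes)
        haps = [(1, 1), (1, 1), (1, 1), (1, 0), (0, 0), (0, 0), (0, 0), (0, 1),
                (1, 1), (0, 1), (0, 0), (0, 0)]
        pAB = sum(1 for a, b in haps if a and b) / 12
        pA = sum(a for a, _ in haps) / 12
        pB = sum(b for _, b in haps) / 12
        d = pAB - pA * pB
        stats = ld_pair(panel, "snp1", "snp2")
        assert stats.d == pytest.approx(d, abs=1e-9)
        r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
        assert stats.r2 == pytest.approx(r2, abs=1e-9)

    def test_monomorphic_input_errors(self):
        panel = make_panel([[0, 1], [0, 1], [0, 0], [0, 2]])
        with pytest.raises(LDError):
            ld_pair(panel, "snp1", "snp2")

    def test_r2_dprime_d_identity(self, rng):
        """r2 * (pA pa pB pb) = d^2 regardless of sign relations."""
        for _ in range(5):
            g = random_genotype_fixture(rng, 200, 2)
            panel = make_panel(g)
            try:
                s = ld_pair(panel, "snp1", "snp2")
            except LDError:
                continue
            col = panel.genotypes
            pA = col[:, 0].mean() / 2
            pB = col[:, 1].mean() / 2
            assert s.r2 * pA * (1 - pA) * pB * (1 - pB) == pytest.approx(
                s.d**2, abs=1e-12
            )


class TestPhaseEm:
    def test_fully_homozygous_panel_is_exact(self):
        g = np.array([[0, 0, 2], [2, 2, 2], [0, 0, 0], [2, 0, 2]], dtype=np.int8)
        panel = make_panel(g)
        haps = phase_em(panel, ["snp1", "snp2", "snp3"], freq_floor=0.0)
        assert all(len(p) == 1 and probs[0] == 1.0
                   for p, probs in zip(haps.posterior_pairs, haps.posterior_probs))
        assert sum(f for _, f in haps.haplotypes) == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_small_fixture(self, rng):
        g = random_genotype_fixture(rng, 30, 3)
        panel = make_panel(g)
        haps = phase_em(panel, ["snp1", "snp2", "snp3"], freq_floor=0.0)
        oracle = exhaustive_em_oracle(g)
        for h, f in haps.haplotypes:
            assert f == pytest.approx(oracle[h], abs=1e-8)

    def test_missing_data_fixture_matches_oracle(self, rng):
        g = random_genotype_fixture(rng, 40, 4, missing_rate=0.1)
        # ensure nobody is fully missing (those are excluded by phase_em)
        g[(g == MISSING).all(axis=1), 0] = 1
        panel = make_panel(g)
        haps = phase_em(panel, [f"snp{j+1}" for j in range(4)], freq_floor=0.0)
        oracle = exhaustive_em_oracle(g)
        for h, f in haps.haplotypes:
            assert f == pytest.approx(oracle[h], abs=1e-6)

    def test_loglik_nondecreasing_every_iteration(self, rng):
        g = random_genotype_fixture(rng, 60, 4)
        panel = make_panel(g)
        haps = phase_em(panel, [f"snp{j+1}" for j in range(4)], freq_floor=0.0)
        trace = np.array(haps.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_scenario_recovers_protective_frequency(self):
        cfg = default_scenario(scale=0.25, seed=5)
        cfg.populations = [("UK", 2500, 2500)]
        panel, truth = simulate_panel(cfg)
        haps = phase_em(panel, [v.id for v in panel.variants], freq_floor=0.01)
        est = haps.frequency_of(PROTECTIVE_HAPLOTYPE)
        assert abs(est - truth.haplotype_frequency(0)) < 0.01

    def test_all_missing_individual_excluded(self):
        g = np.array([[1, 1], [MISSING, MISSING], [0, 2]], dtype=np.int8)
        panel = make_panel(g)
        haps = phase_em(panel, ["snp1", "snp2"], freq_floor=0.0)
        assert haps.excluded_sample_ids == ["s2"]
        assert len(haps.sample_ids) == 2

    def test_window_guard(self, rng):
        g = hw_genotypes(rng, 10, [0.5] * 26)
        panel = make_panel(g)
        with pytest.raises(LDError, match="split"):
            phase_em(panel, [v.id for v in panel.variants])

    def test_dosage_rows_sum_to_two(self, scenario_small):
        _cfg, panel, _ = scenario_small
        sub = panel.subset_samples(panel.stratum_mask("controls"))
        haps = phase_em(sub, [v.id for v in sub.variants][:6], freq_floor=0.01)
        sums = haps.dosage_matrix().sum(axis=1)
        assert np.allclose(sums[sums > 0], 2.0, atol=1e-9)


class TestBlocks:
    def test_single_pool_simulation_yields_one_block(self, scenario_small):
        _cfg, panel, _ = scenario_small
        uk = panel.subset_samples(
            np.array([s.population == "UK" for s in panel.samples])
        )
        blocks = build_blocks(uk, window_bp=250_000, anchor="rs2030519")
        assert len(blocks) == 1
        assert blocks[0].nsnp == 14
        assert blocks[0].interval.start_bp == 188116907
        assert blocks[0].interval.end_bp == 188121019

    def test_two_separated_blocks_recovered(self, rng):
        n = 800

        def block(freq, L, start):
            pool = np.array([[0] * L, [1] * L])
            idx = rng.choice(2, size=(n, 2), p=[freq, 1 - freq])
            return (pool[idx[:, 0]] + pool[idx[:, 1]]).astype(np.int8)

        a = block(0.4, 3, 0)
        sep = hw_genotypes(rng, n, [0.5])  # unlinked spacer
        b = block(0.3, 3, 0)
        g = np.hstack([a, sep, b])
        panel = make_panel(g, positions=[100, 200, 300, 5000, 9000, 9100, 9200])
        blocks = build_blocks(panel)
        spans = sorted(tuple(b.snp_ids) for b in blocks)
        assert (("snp1", "snp2", "snp3") in spans)
        assert (("snp5", "snp6", "snp7") in spans)
        assert all("snp4" not in b.snp_ids for b in blocks)

    def test_two_snp_perfect_ld_block(self, rng):
        pool = np.array([[0, 0], [1, 1]])
        idx = rng.choice(2, size=(500, 2))
        g = (pool[idx[:, 0]] + pool[idx[:, 1]]).astype(np.int8)
        panel = make_panel(g)
        blocks = build_blocks(panel)
        assert len(blocks) == 1 and blocks[0].nsnp == 2

    def test_dprime_ci_tight_for_perfect_ld(self, rng):
        pool = np.array([[0, 0], [1, 1]])
        idx = rng.choice(2, size=(2000, 2))
        g = (pool[idx[:, 0]] + pool[idx[:, 1]]).astype(np.int8)
        panel = make_panel(g)
        low, high = dprime_ci(panel, "snp1", "snp2")
        assert low >= 0.9 and high == 1.0

    def test_empty_window_returns_no_blocks(self, rng):
        panel = make_panel(hw_genotypes(rng, 50, [0.4]))
        assert build_blocks(panel, window_bp=10, anchor="snp1") == []
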