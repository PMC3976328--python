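"""QC and association: exact HWE, crude OR, logistic fits, joint and
conditional analysis."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplofine.assoc import (
    AssocError,
    CollinearityError,
    UndefinedValueError,
    conditional_scan,
    crude_or,
    hwe_exact,
    hwe_exact_from_counts,
    joint_meta,
    logistic_assoc,
    maf,
    meta_inverse_variance,
    qc_filter,
)
from haplofine.genotypes import CohortPanel, Sample

from conftest import hw_genotypes, make_panel


def hwe_enumeration_oracle(hom_major: int, het: int, hom_minor: int) -> float:
    """Exact-rational enumeration over all heterozygote counts compatible
    with the allele counts; p = total probability of outcomes no more
    likely than the observed one."""
    n = hom_major + het + hom_minor
    n_minor = 2 * hom_minor + het
    if n_minor == 0 or 2 * n - n_minor == 0:
        return 1.0
    rare = min(n_minor, 2 * n - n_minor)
    common = 2 * n - rare

    def ways(h: int) -> int:
        a, b = (rare - h) // 2, (common - h) // 2
        return (
            math.factorial(n)
            // (math.factorial(a) * math.factorial(h) * math.factorial(b))
            * 2**h
        )

    total = sum(ways(h) for h in range(rare % 2, rare + 1, 2))
    probs = {h: Fraction(ways(h), total) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestMaf:
    def test_simple_counts(self):
        panel = make_panel([[0], [1], [2]])
        assert maf(panel, "snp1") == 0.5

    def test_all_reference_is_zero(self):
        panel = make_panel([[0], [0], [0], [0]])
        assert maf(panel, "snp1") == 0.0

    def test_missing_excluded_pairwise(self):
        panel = make_panel([[2], [-1], [0], [2]])
        assert maf(panel, "snp1") == pytest.approx(4 / 6)

    def test_empty_stratum_raises(self):
        panel = make_panel([[1], [1]], phenotypes=["case", "case"])
        with pytest.raises(UndefinedValueError):
            maf(panel, "snp1", "controls")

    def test_scenario_control_maf_matches_configured_frequency(self, scenario_small):
        _cfg, panel, _truth = scenario_small
        uk = np.array([s.population == "UK" for s in panel.samples])
        ctrl = uk & (panel.phenotype_vector == 0)
        f = maf(panel.subset_samples(ctrl), "rs2030519")
        assert abs(f - 0.4818) < 0.04  # 827 controls at scale 0.1


class TestHweExact:
    def test_perfect_hwe_gives_p_one(self):
        assert hwe_exact_from_counts(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_het_deficit_matches_enumeration(self):
        p = hwe_exact_from_counts(50, 0, 50)
        oracle = hwe_enumeration_oracle(50, 0, 50)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-25

    def test_tiny_table_matches_enumeration(self):
        assert hwe_exact_from_counts(3, 1, 0) == pytest.approx(
            hwe_enumeration_oracle(3, 1, 0), rel=1e-12
        )

    def test_monomorphic_is_one_by_convention(self):
        assert hwe_exact_from_counts(10, 0, 0) == 1.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.integers(0, 80), st.integers(0, 80), st.integers(0, 40)
    )
    def test_matches_full_enumeration_up_to_n200(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_from_counts(a, h, b) == pytest.approx(
            hwe_enumeration_oracle(a, h, b), abs=1e-12, rel=1e-9
        )

    def test_panel_interface_uses_stratum(self):
        g = [[0]] * 5 + [[2]] * 5
        panel = make_panel(g, phenotypes=["case"] * 5 + ["control"] * 5)
        assert hwe_exact(panel, "snp1", "controls") == 1.0  # monomorphic stratum
        assert hwe_exact(panel, "snp1", "all") < 0.01  # no hets at MAF 0.5


class TestQcFilter:
    def test_monomorphic_removed_at_default_floor(self):
        panel = make_panel([[0, 1], [0, 1], [0, 0], [0, 2]])
        kept = qc_filter(panel, maf_min=0.01, hwe_min_p=0.0)
        assert [v.id for v in kept.variants] == ["snp2"]

    def test_known_violations_filtered(self, rng):
        n = 120
        good = hw_genotypes(rng, n, [0.3, 0.4, 0.2])
        mono = np.zeros((n, 1), dtype=np.int8)  # MAF 0
        # total heterozygote deficit, interleaved so the control stratum
        # (second half of the samples) keeps both homozygote classes
        bad_hwe = np.array([[0, 2] * (n // 2)], dtype=np.int8).T
        panel = make_panel(np.hstack([good, mono, bad_hwe]))
        kept = qc_filter(panel, maf_min=0.01, hwe_min_p=1e-4)
        assert [v.id for v in kept.variants] == ["snp1", "snp2", "snp3"]

    def test_vacuous_thresholds_keep_everything(self, rng):
        panel = make_panel(hw_genotypes(rng, 50, [0.1, 0.5]))
        kept = qc_filter(panel, maf_min=0.0, hwe_min_p=0.0)
        assert [v.id for v in kept.variants] == [v.id for v in panel.variants]


class TestCrudeOr:
    def test_published_frequency_pairs(self):
        assert round(crude_or(0.41, 0.48), 2) == 0.75
        assert round(crude_or(0.16, 0.12), 1) == 1.4

    def test_equal_frequencies_give_unity(self):
        for x in (0.01, 0.25, 0.5, 0.9):
            assert crude_or(x, x) == pytest.approx(1.0)

    def test_boundary_frequency_flagged(self):
        with pytest.raises(AssocError, match="boundary"):
            crude_or(0.0, 0.3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 0.99), st.floats(0.01, 0.99)
    )
    def test_reciprocal_symmetry(self, a, b):
        assert crude_or(a, b) * crude_or(b, a) == pytest.approx(1.0, rel=1e-9)


class TestLogisticAssoc:
    def test_additive_fit_reproduces_two_by_two_table_or(self, rng):
        """On a panel of homozygotes only, the additive model is saturated:
        exp(2*beta) equals the closed-form 2x2 genotype odds ratio."""
        for _ in range(5):
            n = 400
            g = (2 * rng.binomial(1, rng.uniform(0.2, 0.8), size=n)).astype(np.int8)
            y = rng.binomial(1, np.where(g == 2, 0.55, 0.4))
            if len({(gi, yi) for gi, yi in zip(g, y)}) < 4:
                continue
            panel = make_panel(
                g[:, None], phenotypes=["case" if v else "control" for v in y]
            )
            res = logistic_assoc(panel, "snp1", covariates=())
            n2c = np.sum((g == 2) & (y == 1))
            n2t = np.sum((g == 2) & (y == 0))
            n0c = np.sum((g == 0) & (y == 1))
            n0t = np.sum((g == 0) & (y == 0))
            cell_or = (n2c * n0t) / (n2t * n0c)
            assert math.exp(2 * res.beta) == pytest.approx(cell_or, rel=1e-6)
            # and the same number via the crude allele-frequency OR
            assert math.exp(2 * res.beta) == pytest.approx(
                crude_or(res.maf_cases, res.maf_controls), rel=1e-6
            )

    def test_null_calibration_beta_within_three_se(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            g = hw_genotypes(rng, 300, 0.3)
            y = rng.binomial(1, 0.5, size=300)
            panel = make_panel(g, phenotypes=["case" if v else "control" for v in y])
            res = logistic_assoc(panel, "snp1", covariates=())
            if abs(res.beta) < 3 * res.se:
                hits += 1
        assert hits >= 95

    def test_ci_covers_generating_or(self, rng):
        """Wald 95% CI covers the true protective OR in about 95% of
        replicates."""
        beta_true = math.log(0.75)
        covered = 0
        reps = 60
        for _ in range(reps):
            g = hw_genotypes(rng, 2000, 0.45)
            p = 1 / (1 + np.exp(-(0.0 + beta_true * g[:, 0])))
            y = rng.binomial(1, p)
            panel = make_panel(g, phenotypes=["case" if v else "control" for v in y])
            res = logistic_assoc(panel, "snp1", covariates=())
            lo, hi = res.ci95
            covered += lo <= 0.75 <= hi
        assert covered >= 50  # >= ~83% at 95% nominal coverage

    def test_separated_data_flagged_not_crashed(self):
        g = np.array([[2]] * 20 + [[0]] * 20, dtype=np.int8)
        panel = make_panel(g, phenotypes=["case"] * 20 + ["control"] * 20)
        res = logistic_assoc(panel, "snp1", covariates=())
        assert not res.converged
        assert math.isnan(res.p)

    def test_collinear_covariates_error_names_offenders(self, rng):
        g = hw_genotypes(rng, 200, 0.3)
        y = rng.binomial(1, 0.5, 200)
        sexes = ["male" if i % 2 else "female" for i in range(200)]
        # conditioning SNP identical to the sex covariate -> rank deficient
        sex_col = np.array([1 if s == "male" else 0 for s in sexes], dtype=np.int8)
        panel = make_panel(
            np.column_stack([g[:, 0], sex_col]),
            phenotypes=["case" if v else "control" for v in y],
            sexes=sexes,
        )
        with pytest.raises(CollinearityError, match=r"sex|cond\[snp2\]"):
            logistic_assoc(panel, "snp1", covariates=("sex",), condition_on=["snp2"])

    def test_p_invariant_under_label_swap_with_sign_flip(self, rng):
        g = hw_genotypes(rng, 400, 0.35)
        y = rng.binomial(1, 0.35 + 0.1 * (g[:, 0] > 0))
        panel = make_panel(g, phenotypes=["case" if v else "control" for v in y])
        swapped = make_panel(g, phenotypes=["control" if v else "case" for v in y])
        a = logistic_assoc(panel, "snp1", covariates=())
        b = logistic_assoc(swapped, "snp1", covariates=())
        assert a.beta == pytest.approx(-b.beta, abs=1e-8)
        assert a.p == pytest.approx(b.p, abs=1e-10)


class TestJointAndConditional:
    def _panel_pair(self, rng, flip_effect=False):
        def one(pop, flip):
            g = hw_genotypes(rng, 600, 0.4)
            shift = -0.35 if flip else 0.35
            y = rng.binomial(1, 1 / (1 + np.exp(-(0.0 + shift * g[:, 0]))))
            return make_panel(
                g,
                phenotypes=["case" if v else "control" for v in y],
                populations=[pop] * 600,
            )

        a = one("alpha", False)
        b = one("beta", flip_effect)
        for i, s in enumerate(b.samples):
            object.__setattr__(s, "id", f"b{i}")
        return a, b

    def test_identical_populations_match_single_fit(self, rng):
        a, _ = self._panel_pair(rng)
        b = CohortPanel(
            a.variants,
            [Sample(f"dup_{s.id}", "zeta", s.sex, s.phenotype) for s in a.samples],
            a.genotypes.copy(),
        )
        joint = joint_meta([a, b], covariates=("population",))
        single = logistic_assoc(a, "snp1", covariates=())
        assert joint["snp1"].beta == pytest.approx(single.beta, abs=1e-6)

    def test_opposite_effects_cancel(self, rng):
        a, b = self._panel_pair(rng, flip_effect=True)
        joint = joint_meta([a, b], covariates=("population",))
        assert abs(joint["snp1"].beta) < 3 * joint["snp1"].se

    def test_inverse_variance_combiner_close_to_pooled_fit(self, rng):
        a, b = self._panel_pair(rng)
        per_pop = [logistic_assoc(p, "snp1", covariates=()) for p in (a, b)]
        beta_iv, se_iv, _p = meta_inverse_variance(per_pop)
        joint = joint_meta([a, b], covariates=("population",))
        assert beta_iv == pytest.approx(joint["snp1"].beta, abs=3 * se_iv / 10)

    def test_conditioning_on_monomorphic_snp_changes_nothing(self, rng):
        g = hw_genotypes(rng, 300, [0.3, 0.4])
        g = np.hstack([g, np.zeros((300, 1), dtype=np.int8)])  # snp3 monomorphic
        y = rng.binomial(1, 0.5, 300)
        panel = make_panel(g, phenotypes=["case" if v else "control" for v in y])
        plain = joint_meta([panel], covariates=())
        cond = conditional_scan([panel], "snp3", covariates=())
        for vid in ("snp1", "snp2"):
            assert cond[vid].beta == pytest.approx(plain[vid].beta, abs=1e-10)
            assert cond[vid].p == pytest.approx(plain[vid].p, abs=1e-10)

    def test_second_independent_signal_survives_conditioning(self, rng):
        g = hw_genotypes(rng, 3000, [0.4, 0.4])
        eta = -0.1 + 0.35 * g[:, 0] + 0.35 * g[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        panel = make_panel(g, phenotypes=["case" if v else "control" for v in y])
        cond = conditional_scan([panel], "snp1", covariates=())
        assert cond["snp2"].p < 1e-4

    def test_scenario_top_snp_tags_causal_haplotype(self):
        """Joint analysis of the simulated six cohorts puts the strongest
        signal on a perfect proxy of the causal tag SNP."""
        from haplofine.ld_phase import ld_pair
        from haplofine.simulate import default_scenario, simulate_panel

        cfg = default_scenario(scale=0.25, seed=11)
        panel, _ = simulate_panel(cfg)
        pops = panel.split_by_population()
        res = joint_meta(list(pops.values()))
        finite = {v: r for v, r in res.items() if math.isfinite(r.p)}
        top = min(finite, key=lambda v: finite[v].p)
        assert ld_pair(panel, top, "rs2030519").r2 > 0.99
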