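"""Per-SNP quality control and case/control association tests.

Association is additive-coding logistic regression (0/1/2 copies of the
minor allele) with Wald tests, fitted by iteratively reweighted maximum
likelihood via statsmodels.  The joint analysis across cohorts pools all
samples into one regression with sex and population-indicator covariates
(a "mega-analysis"); a fixed-effect inverse-variance combiner over the
per-population fits is provided as an independent cross-check.

QC follows the conventional pre-imputation filters: pooled MAF above a
floor and an exact Hardy-Weinberg test in controls above a p-value floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .genotypes import MISSING, CohortPanel, Variant

#: 97.5% normal quantile used for 95% confidence intervals.
CI_MULTIPLIER = 1.959964

#: Logistic fit convergence: log-likelihood change tolerance and iteration cap.
LOGIT_TOL = 1e-8
LOGIT_MAXITER = 50

#: |log OR| beyond which a non-converged fit is declared separated.
SEPARATION_BETA = 15.0


class AssocError(Exception):
    pass


class CollinearityError(AssocError):
    """Covariate design matrix is rank deficient (names offending columns)."""


class UndefinedValueError(AssocError):
    """Requested statistic has an empty denominator."""


@dataclass
class AssocResult:
    """Per-variant association summary (one row of an association table)."""

    variant: Variant
    n_cases: int
    n_controls: int
    maf_all: float
    maf_cases: float
    maf_controls: float
    beta: float
    se: float
    p: float
    converged: bool = True
    note: str = ""

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.beta - CI_MULTIPLIER * self.se),
            math.exp(self.beta + CI_MULTIPLIER * self.se),
        )


# ---------------------------------------------------------------------------
# Allele frequency and HWE
# ---------------------------------------------------------------------------

def maf(panel: CohortPanel, variant: Variant | str, stratum: str = "all") -> float:
    """Minor-allele frequency in a stratum, missing genotypes excluded.

    Defined against the panel's stored minor allele, so a population-split
    panel whose own minor allele differs may legitimately return > 0.5.
    """
    j = panel.variant_index(variant if isinstance(variant, str) else variant.id)
    col = panel.genotypes[panel.stratum_mask(stratum), j]
    obs = col != MISSING
    n = int(obs.sum())
    if n == 0:
        raise UndefinedValueError(
            f"{panel.variants[j].id}: no non-missing genotypes in stratum {stratum!r}"
        )
    return float(col[obs].sum() / (2 * n))


def genotype_counts(
    panel: CohortPanel, variant: Variant | str, stratum: str = "all"
) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts in a stratum."""
    j = panel.variant_index(variant if isinstance(variant, str) else variant.id)
    col = panel.genotypes[panel.stratum_mask(stratum), j]
    return tuple(int((col == g).sum()) for g in (0, 1, 2))


def hwe_exact_from_counts(hom_major: int, het: int, hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Sums, conditional on the allele counts, the probabilities of all
    heterozygote counts no more likely than the observed one.  Monomorphic
    input returns 1 by convention.
    """
    n = hom_major + het + hom_minor
    if n == 0:
        raise UndefinedValueError("no genotypes for HWE test")
    n_minor = 2 * hom_minor + het
    n_major = 2 * hom_major + het
    if n_minor == 0 or n_major == 0:
        return 1.0
    rare = min(n_minor, n_major)
    obs_het = het
    # log P(het = h | allele counts): multinomial genotype probabilities
    # conditional on allele counts; h runs over the parity class of `rare`.
    log_const = (
        gammaln(n + 1) + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1)
    )

    def log_prob(h: int) -> float:
        rr = (min(n_minor, n_major) - h) // 2
        cc = (max(n_minor, n_major) - h) // 2
        return log_const + h * math.log(2.0) - (
            gammaln(rr + 1) + gammaln(h + 1) + gammaln(cc + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets == obs_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact(panel: CohortPanel, variant: Variant | str, stratum: str = "all") -> float:
    return hwe_exact_from_counts(*genotype_counts(panel, variant, stratum))


def qc_filter(panel: CohortPanel, maf_min: float = 0.01, hwe_min_p: float = 1e-4) -> CohortPanel:
    """Retain variants with pooled MAF > maf_min and control-stratum HWE
    p > hwe_min_p; variant order is preserved.

    If the panel has no controls the HWE filter falls back to all samples.
    """
    stratum = "controls" if (panel.phenotype_vector == 0).any() else "all"
    keep = [
        v.id
        for v in panel.variants
        if maf(panel, v) > maf_min and hwe_exact(panel, v, stratum) > hwe_min_p
    ]
    return panel.subset_variants(keep)


# ---------------------------------------------------------------------------
# Odds ratios and logistic association
# ---------------------------------------------------------------------------

def crude_or(maf_cases: float, maf_controls: float) -> float:
    """Allelic odds ratio from case and control allele frequencies."""
    for name, f in (("maf_cases", maf_cases), ("maf_controls", maf_controls)):
        if not (0 < f < 1):
            raise AssocError(f"{name}={f} is on the boundary; odds ratio degenerate")
    return (maf_cases / (1 - maf_cases)) / (maf_controls / (1 - maf_controls))


def _population_indicators(
    populations: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """Indicator columns for all but the alphabetically first label."""
    levels = sorted(set(populations))
    cols = [
        (np.array([p == lev for p in populations], dtype=float), f"pop[{lev}]")
        for lev in levels[1:]
    ]
    if not cols:
        return np.zeros((len(populations), 0)), []
    return np.column_stack([c for c, _ in cols]), [n for _, n in cols]


def wald_fit(
    y: np.ndarray, X: np.ndarray, names: list[str]
) -> tuple[float, float, float, bool, str]:
    """Newton-IRLS logistic fit of y ~ X; column 1 of X is the tested dosage.

    Returns (beta, se, p, converged, note).  Nuisance-column collinearity
    raises; a dosage collinear with a conditioning covariate (r^2 = 1) is
    flagged with p = NaN instead, since that is an expected outcome of a
    conditional scan.
    """
    import statsmodels.api as sm

    if len(np.unique(y)) < 2:
        raise AssocError("phenotype has a single class after missing-data deletion")

    nuisance = np.delete(X, 1, axis=1)
    rank_nuis = np.linalg.matrix_rank(nuisance)
    if rank_nuis < nuisance.shape[1]:
        bad = _deficient_columns(nuisance, [n for i, n in enumerate(names) if i != 1])
        raise CollinearityError(f"collinear covariate columns: {bad}")
    if np.linalg.matrix_rank(X) == rank_nuis:
        return 0.0, float("inf"), float("nan"), False, "dosage collinear with covariates"

    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and flagged below; the fit-time warning
            # is redundant noise
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(
                method="newton", maxiter=LOGIT_MAXITER, tol=LOGIT_TOL, disp=0,
                warn_convergence=False,
            )
        beta, se = float(fit.params[1]), float(fit.bse[1])
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        beta, se, converged = float("nan"), float("nan"), False

    if not converged and (not math.isfinite(beta) or abs(beta) > SEPARATION_BETA):
        return float("nan"), float("nan"), float("nan"), False, "separation"

    p = float(2 * norm.sf(abs(beta / se)))
    return beta, se, p, converged, ""


def _fit_logit(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    result_skeleton: AssocResult,
) -> AssocResult:
    res = result_skeleton
    beta, se, p, converged, note = wald_fit(y, X, names)
    res.beta, res.se, res.p, res.converged = beta, se, p, converged
    if note:
        res.note = note
    return res


def _deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def _assemble_design(
    dosage: np.ndarray,
    samples,
    covariates: Sequence[str],
    condition_dosages: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Returns (y, X, names, keep_mask) with pairwise deletion of missing
    genotype/sex values.  Column order: const, dosage, covariates."""
    n = len(samples)
    keep = dosage != MISSING
    cols: list[np.ndarray] = []
    names = ["const", "dosage"]
    if "sex" in covariates:
        sex = np.array(
            [{"male": 1.0, "female": 0.0}.get(s.sex, np.nan) for s in samples]
        )
        keep &= ~np.isnan(sex)
        cols.append(sex)
        names.append("sex")
    pops = [s.population for s in samples]
    if "population" in covariates and len(set(pops)) > 1:
        ind, ind_names = _population_indicators(pops)
        cols.extend(ind.T)
        names.extend(ind_names)
    if condition_dosages:
        for cid, cd in condition_dosages.items():
            keep &= cd != MISSING
            cols.append(np.asarray(cd, dtype=float))
            names.append(f"cond[{cid}]")
    y = np.array([1.0 if s.is_case else 0.0 for s in samples])
    X = np.column_stack(
        [np.ones(n), dosage.astype(float)] + [np.asarray(c, dtype=float) for c in cols]
    )
    # drop conditioning columns that are constant after deletion (e.g. a
    # monomorphic conditioning SNP): they carry no information
    X, y = X[keep], y[keep]
    const_cond = [
        j for j, nm in enumerate(names)
        if nm.startswith("cond[") and np.ptp(X[:, j]) == 0
    ]
    if const_cond:
        X = np.delete(X, const_cond, axis=1)
        names = [nm for j, nm in enumerate(names) if j not in const_cond]
    return y, X, names, keep


def _skeleton(variant: Variant, samples, dosage: np.ndarray, keep: np.ndarray) -> AssocResult:
    y = np.array([s.is_case for s in samples])[keep]
    d = dosage[keep]

    def _freq(mask: np.ndarray) -> float:
        sub = d[mask]
        return float(sub.sum() / (2 * len(sub))) if len(sub) else float("nan")

    return AssocResult(
        variant=variant,
        n_cases=int(y.sum()),
        n_controls=int((~y).sum()),
        maf_all=_freq(np.ones(len(d), dtype=bool)),
        maf_cases=_freq(y),
        maf_controls=_freq(~y),
        beta=float("nan"),
        se=float("nan"),
        p=float("nan"),
    )


def logistic_assoc(
    panel: CohortPanel,
    variant: Variant | str,
    covariates: Sequence[str] = ("sex",),
    condition_on: Sequence[Variant | str] = (),
) -> AssocResult:
    """Additive logistic regression of case/control status on one SNP.

    ``covariates`` may contain "sex" and/or "population"; ``condition_on``
    adds other variants' dosages as covariates (conditional analysis).
    Samples missing the tested genotype, a conditioning genotype, or sex
    (when adjusted for) are dropped.
    """
    vid = variant if isinstance(variant, str) else variant.id
    j = panel.variant_index(vid)
    dosage = panel.genotypes[:, j].astype(np.int16)
    cond = {
        (c if isinstance(c, str) else c.id): panel.genotypes[
            :, panel.variant_index(c if isinstance(c, str) else c.id)
        ].astype(np.int16)
        for c in condition_on
    }
    y, X, names, keep = _assemble_design(dosage, panel.samples, covariates, cond)
    skel = _skeleton(panel.variants[j], panel.samples, dosage, keep)
    return _fit_logit(y, X, names, skel)


def joint_meta(
    panels: Sequence[CohortPanel] | Mapping[str, CohortPanel],
    covariates: Sequence[str] = ("sex", "population"),
    condition_on: Sequence[str] = (),
) -> dict[str, AssocResult]:
    """Joint (pooled) association across cohorts for every shared variant.

    All samples enter a single logistic fit with sex and population
    indicators.  A variant absent from some cohort is analysed over the
    cohorts that carry it, noted on the result.
    """
    panel_list = list(panels.values()) if isinstance(panels, Mapping) else list(panels)
    if not panel_list:
        raise AssocError("no panels given")
    out: dict[str, AssocResult] = {}
    vids: list[str] = []
    for p in panel_list:
        for v in p.variants:
            if v.id not in vids:
                vids.append(v.id)
    for vid in vids:
        carrying = [p for p in panel_list if any(v.id == vid for v in p.variants)]
        omitted = len(panel_list) - len(carrying)
        dosages, samples, cond_cols = [], [], {c: [] for c in condition_on}
        variant = carrying[0].variant(vid)
        for p in carrying:
            j = p.variant_index(vid)
            v = p.variants[j]
            col = p.genotypes[:, j].astype(np.int16)
            if v.allele_minor != variant.allele_minor:  # harmonise orientation
                obs = col != MISSING
                col[obs] = 2 - col[obs]
            dosages.append(col)
            samples.extend(p.samples)
            for c in condition_on:
                cj = p.variant_index(c)
                cc = p.genotypes[:, cj].astype(np.int16)
                if p.variants[cj].allele_minor != panel_list[0].variant(c).allele_minor:
                    obs = cc != MISSING
                    cc[obs] = 2 - cc[obs]
                cond_cols[c].append(cc)
        dosage = np.concatenate(dosages)
        cond = {c: np.concatenate(v) for c, v in cond_cols.items()}
        y, X, names, keep = _assemble_design(dosage, samples, covariates, cond)
        skel = _skeleton(variant, samples, dosage, keep)
        if omitted:
            skel.note = f"{omitted} cohort(s) without this variant omitted"
        out[vid] = _fit_logit(y, X, names, skel)
    return out


def conditional_scan(
    panels: Sequence[CohortPanel] | Mapping[str, CohortPanel],
    condition_on: str | Sequence[str],
    covariates: Sequence[str] = ("sex", "population"),
) -> dict[str, AssocResult]:
    """Joint association of every variant conditional on one or more lead
    SNPs (their dosages added as covariates).  Iterating with a growing
    ``condition_on`` list gives a stepwise conditional analysis."""
    cond = [condition_on] if isinstance(condition_on, str) else list(condition_on)
    results = joint_meta(panels, covariates=covariates, condition_on=cond)
    return {vid: r for vid, r in results.items() if vid not in cond}


def stepwise_conditional(
    panels: Sequence[CohortPanel] | Mapping[str, CohortPanel],
    p_threshold: float = 5e-2,
    max_steps: int = 5,
    covariates: Sequence[str] = ("sex", "population"),
) -> list[tuple[str, dict[str, AssocResult]]]:
    """Repeatedly condition on the accumulated top SNPs until no residual
    test clears ``p_threshold``.  Returns [(added_snp, scan_results), ...]."""
    added: list[str] = []
    trail = []
    current = joint_meta(panels, covariates=covariates)
    for _ in range(max_steps):
        valid = {v: r for v, r in current.items() if math.isfinite(r.p)}
        if not valid:
            break
        top = min(valid, key=lambda v: valid[v].p)
        if valid[top].p >= p_threshold:
            break
        added.append(top)
        current = conditional_scan(panels, added, covariates=covariates)
        trail.append((top, current))
    return trail


def meta_inverse_variance(results: Iterable[AssocResult]) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance combination of per-cohort estimates.

    Returns (beta, se, p).  Secondary cross-check for :func:`joint_meta`.
    """
    betas, ws = [], []
    for r in results:
        if math.isfinite(r.beta) and math.isfinite(r.se) and r.se > 0:
            betas.append(r.beta)
            ws.append(1.0 / r.se**2)
    if not betas:
        raise AssocError("no finite estimates to combine")
    w = np.asarray(ws)
    beta = float(np.average(betas, weights=w))
    se = float(1.0 / math.sqrt(w.sum()))
    p = float(2 * norm.sf(abs(beta / se)))
    return beta, se, p


def association_table(results: Iterable[AssocResult]) -> "pd.DataFrame":
    """Tab-separated-ready table with the conventional columns."""
    import pandas as pd

    rows = []
    for r in results:
        lo, hi = r.ci95
        rows.append(
            {
                "SNP": r.variant.id,
                "CHR": r.variant.chrom,
                "BP": r.variant.pos,
                "minor": r.variant.allele_minor,
                "major": r.variant.allele_major,
                "MAF": r.maf_all,
                "MAF_cases": r.maf_cases,
                "MAF_controls": r.maf_controls,
                "OR": r.or_,
                "CI_low": lo,
                "CI_high": hi,
                "P": r.p,
            }
        )
    return pd.DataFrame(rows)
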