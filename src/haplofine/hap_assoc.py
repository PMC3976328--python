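"""Haplotype logistic association on EM-phased windows.

Each haplotype above the frequency floor is tested one-vs-rest by logistic
regression with covariates, using its expected copy count per individual
(posterior dosage) as the predictor.  Dosage coding is standard practice
for haplotype association because it stays stable under phase uncertainty;
the per-individual dosages over all haplotypes always sum to 2.

Case- and control-stratum haplotype frequencies are obtained by rerunning
the EM within each stratum, so the reported stratified frequencies are
maximum-likelihood within-stratum estimates rather than dosage averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .assoc import CI_MULTIPLIER, AssocError, _population_indicators, wald_fit
from .genotypes import CohortPanel, Sample, Variant
from .ld_phase import HaplotypeBlock, HaplotypeSet, phase_em

#: Haplotypes below this pooled frequency are not tested.
DEFAULT_FREQ_FLOOR = 0.01


@dataclass
class HapAssocResult:
    haplotype: str
    freq_all: float
    freq_cases: float
    freq_controls: float
    beta: float
    se: float
    p: float
    population: str = "joint"
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


def hap_logistic(
    haps: HaplotypeSet,
    samples: Sequence[Sample],
    covariates: Sequence[str] = ("sex",),
    freq_floor: float = DEFAULT_FREQ_FLOOR,
    stratified: Mapping[str, HaplotypeSet] | None = None,
    population: str = "joint",
) -> list[HapAssocResult]:
    """One-vs-rest logistic regression for each haplotype above the floor.

    ``samples`` must cover ``haps.sample_ids``.  ``stratified`` optionally
    supplies within-stratum EM fits keyed "cases"/"controls" for the
    stratified frequency columns; otherwise dosage-average frequencies are
    reported.  Results are sorted by p-value ascending.
    """
    by_id = {s.id: s for s in samples}
    try:
        kept = [by_id[sid] for sid in haps.sample_ids]
    except KeyError as exc:
        raise AssocError(f"sample {exc} missing from metadata") from exc
    dosages = haps.dosage_matrix()
    y_all = np.array([1.0 if s.is_case else 0.0 for s in kept])

    sex = np.array([{"male": 1.0, "female": 0.0}.get(s.sex, np.nan) for s in kept])
    keep = np.ones(len(kept), dtype=bool)
    cov_cols: list[np.ndarray] = []
    names = ["const", "dosage"]
    if "sex" in covariates:
        keep &= ~np.isnan(sex)
        cov_cols.append(sex)
        names.append("sex")
    pops = [s.population for s in kept]
    if "population" in covariates and len(set(pops)) > 1:
        ind, ind_names = _population_indicators(pops)
        cov_cols.extend(ind.T)
        names.extend(ind_names)

    results: list[HapAssocResult] = []
    for k, (hap, freq) in enumerate(haps.haplotypes):
        if freq < freq_floor:
            continue
        d = dosages[:, k]
        X = np.column_stack(
            [np.ones(len(kept)), d] + [c for c in cov_cols]
        )[keep]
        beta, se, p, converged, note = wald_fit(y_all[keep], X, names)
        case_mask = y_all == 1
        if stratified is not None:
            f_cases = stratified["cases"].frequency_of(hap)
            f_controls = stratified["controls"].frequency_of(hap)
        else:
            f_cases = float(d[case_mask].mean() / 2) if case_mask.any() else float("nan")
            f_controls = (
                float(d[~case_mask].mean() / 2) if (~case_mask).any() else float("nan")
            )
        results.append(
            HapAssocResult(
                haplotype=hap,
                freq_all=freq,
                freq_cases=f_cases,
                freq_controls=f_controls,
                beta=beta,
                se=se,
                p=p,
                population=population,
                converged=converged,
                note=note,
            )
        )
    results.sort(key=lambda r: (math.isnan(r.p), r.p, r.haplotype))
    return results


def haplotype_association(
    panel: CohortPanel,
    snp_window: Sequence[Variant | str],
    covariates: Sequence[str] = ("sex",),
    freq_floor: float = DEFAULT_FREQ_FLOOR,
    population: str = "joint",
) -> tuple[HaplotypeSet, list[HapAssocResult]]:
    """Phase a window (pooled plus per-stratum EMs) and test every common
    haplotype; convenience wrapper over :func:`phase_em` + :func:`hap_logistic`."""
    haps = phase_em(panel, snp_window, freq_floor=freq_floor)
    stratified = {}
    for stratum in ("cases", "controls"):
        mask = panel.stratum_mask(stratum)
        if mask.any():
            stratified[stratum] = phase_em(
                panel.subset_samples(mask), snp_window, freq_floor=freq_floor
            )
    results = hap_logistic(
        haps,
        panel.samples,
        covariates=covariates,
        freq_floor=freq_floor,
        stratified=stratified if len(stratified) == 2 else None,
        population=population,
    )
    return haps, results


def select_top(results: Sequence[HapAssocResult]) -> HapAssocResult:
    """Most-associated haplotype: minimum p, ties broken by larger |log OR|
    then lexicographically smaller allele string."""
    if not results:
        raise AssocError("no haplotype results to select from")
    finite = [r for r in results if math.isfinite(r.p)] or list(results)
    return min(finite, key=lambda r: (r.p, -abs(r.beta), r.haplotype))


def top_haplotype(
    per_population: Mapping[str, tuple[HaplotypeBlock, Sequence[HapAssocResult]]],
) -> dict[str, tuple[HaplotypeBlock, HapAssocResult]]:
    """Per population, the most-associated haplotype and its block."""
    return {
        pop: (block, select_top(results))
        for pop, (block, results) in per_population.items()
    }


def haplotype_table(results: Sequence[HapAssocResult]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "population": r.population,
                "HAPLOTYPE": r.haplotype,
                "Freq": r.freq_all,
                "Freq_cases": r.freq_cases,
                "Freq_controls": r.freq_controls,
                "OR": r.or_,
                "P": r.p,
            }
        )
    return pd.DataFrame(rows)
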