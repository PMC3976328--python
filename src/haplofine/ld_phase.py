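"""Two-locus LD, EM haplotype phasing, and haplotype-block construction.

All phase inference here is expectation-maximisation over unphased
genotypes.  For a window of L SNPs the hidden variable per individual is the
ordered haplotype pair; the E-step distributes each individual over the
pairs compatible with its genotype in proportion to the current haplotype
frequency products (Hardy-Weinberg at the haplotype level), and the M-step
re-estimates pool frequencies from the expected counts.  Initialisation is
deterministic: the product of single-SNP allele frequencies.  Haplotypes
falling below a frequency floor are pruned between iterations and the
remaining mass renormalised, as in the classic PLINK/haplo.stats EMs.

Blocks use the Gabriel confidence-interval rule on D': a pair is in strong
LD when the likelihood-based 90% CI of |D'| has lower bound >= 0.70 and
upper bound >= 0.98; strong recombination when the upper bound < 0.90; a
candidate block is accepted when its end pair is strong and >= 95% of its
informative pairs are strong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import MISSING, CohortPanel, GenomicInterval, Variant

EM_TOL = 1e-10
EM_MAX_ITER = 1000
MAX_WINDOW_SNPS = 25

# Gabriel-rule thresholds on the |D'| 90% CI
STRONG_LD_LOW = 0.70
STRONG_LD_HIGH = 0.98
RECOMB_HIGH = 0.90
BLOCK_STRONG_FRACTION = 0.95


class LDError(Exception):
    pass


@dataclass(frozen=True)
class LDStats:
    """Two-locus LD summary for the minor alleles of a SNP pair."""

    r2: float
    d_prime: float
    d: float


@dataclass(frozen=True)
class HaplotypeBlock:
    interval: GenomicInterval
    snp_ids: tuple[str, ...]

    @property
    def nsnp(self) -> int:
        return len(self.snp_ids)


@dataclass
class HaplotypeSet:
    """EM phasing output over an ordered SNP window.

    ``haplotypes`` is sorted by frequency (descending, ties by allele
    string).  ``posterior_pairs``/``posterior_probs`` hold, per retained
    individual, the ordered-haplotype-pair support and probabilities
    (indices into ``haplotypes``).
    """

    snps: list[Variant]
    haplotypes: list[tuple[str, float]]
    sample_ids: list[str]
    posterior_pairs: list[np.ndarray]  # (k, 2) int arrays
    posterior_probs: list[np.ndarray]
    log_likelihood: float
    excluded_sample_ids: list[str] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.haplotypes])

    def frequency_of(self, hap: str) -> float:
        for h, f in self.haplotypes:
            if h == hap:
                return f
        return 0.0

    def dosage_matrix(self) -> np.ndarray:
        """Expected copy count of each haplotype per retained individual;
        rows sum to 2 (posterior mass conservation)."""
        K = len(self.haplotypes)
        out = np.zeros((len(self.sample_ids), K))
        for i, (pairs, probs) in enumerate(zip(self.posterior_pairs, self.posterior_probs)):
            np.add.at(out[i], pairs[:, 0], probs)
            np.add.at(out[i], pairs[:, 1], probs)
        return out


# ---------------------------------------------------------------------------
# Two-locus EM and LD statistics
# ---------------------------------------------------------------------------

def _two_locus_counts(panel: CohortPanel, va: str, vb: str) -> np.ndarray:
    ja, jb = panel.variant_index(va), panel.variant_index(vb)
    ga, gb = panel.genotypes[:, ja], panel.genotypes[:, jb]
    keep = (ga != MISSING) & (gb != MISSING)
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga[keep] == i) & (gb[keep] == j))
    return counts


def _em_two_locus(counts: np.ndarray, tol: float = EM_TOL) -> np.ndarray:
    """Haplotype frequencies (pAB, pAb, paB, pab) for minor alleles A/B by
    EM over the 3x3 genotype table; only the double heterozygote is
    phase-ambiguous."""
    n = counts.sum()
    if n == 0:
        raise LDError("no jointly observed genotypes")
    # known haplotype counts from the eight unambiguous cells
    kAB = kAb = kaB = kab = 0.0
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # i copies of A split over two haplotypes; unambiguous unless both het
            a_alleles = [1] * i + [0] * (2 - i)
            b_alleles = [1] * j + [0] * (2 - j)
            if i == 1:
                # pair with the determined b alleles (j is 0 or 2 here)
                pairs = [(1, b_alleles[0]), (0, b_alleles[1])]
            elif j == 1:
                pairs = [(a_alleles[0], 1), (a_alleles[1], 0)]
            else:
                pairs = list(zip(a_alleles, b_alleles))
            for a, b in pairs:
                if a and b:
                    kAB += c
                elif a:
                    kAb += c
                elif b:
                    kaB += c
                else:
                    kab += c
    n11 = counts[1, 1]
    pA = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise LDError("monomorphic site in LD computation")
    pAB = pA * pB  # product (linkage-equilibrium) initialisation
    for _ in range(EM_MAX_ITER):
        pAb, paB = pA - pAB, pB - pAB
        pab = 1 - pA - pB + pAB
        cis = pAB * pab
        trans = pAb * paB
        frac = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = (kAB + n11 * frac) / (2 * n)
        if abs(new - pAB) < tol:
            pAB = new
            break
        pAB = new
    pAb, paB = pA - pAB, pB - pAB
    pab = 1 - pA - pB + pAB
    return np.array([pAB, pAb, paB, pab]), pA, pB


def ld_pair(panel: CohortPanel, variant_a: Variant | str, variant_b: Variant | str) -> LDStats:
    """r^2, D' and D between two SNPs, phased by two-locus EM.

    Individuals missing either genotype are excluded pairwise.
    """
    va = variant_a if isinstance(variant_a, str) else variant_a.id
    vb = variant_b if isinstance(variant_b, str) else variant_b.id
    counts = _two_locus_counts(panel, va, vb)
    (pAB, pAb, paB, pab), pA, pB = _em_two_locus(counts)
    d = pAB - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = d / dmax if dmax > 0 else 0.0
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    return LDStats(r2=float(r2), d_prime=float(d_prime), d=float(d))


def dprime_ci(
    panel: CohortPanel, variant_a: Variant | str, variant_b: Variant | str,
    grid: int = 101,
) -> tuple[float, float]:
    """Likelihood-profile 90% CI (0.05/0.95 brackets) for |D'|.

    Profiles the genotype-table likelihood over |D'| in [0, 1] with allele
    frequencies fixed at their MLEs, treating the normalised likelihood as a
    distribution over the grid (the Haploview convention).
    """
    va = variant_a if isinstance(variant_a, str) else variant_a.id
    vb = variant_b if isinstance(variant_b, str) else variant_b.id
    counts = _two_locus_counts(panel, va, vb)
    _, pA, pB = _em_two_locus(counts)
    stats = ld_pair(panel, va, vb)
    sign = 1.0 if stats.d >= 0 else -1.0
    if sign >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dps = np.linspace(0.0, 1.0, grid)
    eps = 1e-12
    loglik = np.empty(grid)
    cells = [(i, j, counts[i, j]) for i in range(3) for j in range(3) if counts[i, j] > 0]
    for g, dp in enumerate(dps):
        d = sign * dp * dmax
        q = np.array(
            [pA * pB + d, pA * (1 - pB) - d, (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d]
        )
        q = np.clip(q, eps, None)
        q = q / q.sum()
        # P(genotype cell) = sum over ordered compatible haplotype pairs
        hap_a = np.array([1, 1, 0, 0])
        hap_b = np.array([1, 0, 1, 0])
        ll = 0.0
        for i, j, c in cells:
            p_cell = 0.0
            for h1 in range(4):
                for h2 in range(4):
                    if hap_a[h1] + hap_a[h2] == i and hap_b[h1] + hap_b[h2] == j:
                        p_cell += q[h1] * q[h2]
            ll += c * math.log(max(p_cell, eps))
        loglik[g] = ll
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    low = float(dps[np.searchsorted(cdf, 0.05)])
    high = float(dps[np.searchsorted(cdf, 0.95)])
    return low, high


# ---------------------------------------------------------------------------
# Multi-locus EM phasing
# ---------------------------------------------------------------------------

def _pattern_masks(pattern: tuple[int, ...]) -> tuple[int, int, int, int]:
    """(known1, known0, het, miss) bitmasks; bit j = SNP j of the window."""
    known1 = known0 = het = miss = 0
    for j, g in enumerate(pattern):
        bit = 1 << j
        if g == 2:
            known1 |= bit
        elif g == 0:
            known0 |= bit
        elif g == 1:
            het |= bit
        else:
            miss |= bit
    return known1, known0, het, miss


def _subsets(mask: int):
    """All submasks of ``mask`` (including 0 and mask)."""
    sub = mask
    while True:
        yield sub
        if sub == 0:
            return
        sub = (sub - 1) & mask


def _expand_pattern(pattern: tuple[int, ...]) -> list[int]:
    """All haplotype bitmasks compatible with a genotype pattern."""
    known1, _known0, het, miss = _pattern_masks(pattern)
    free = het | miss
    return [known1 | sub for sub in _subsets(free)]


def phase_em(
    panel: CohortPanel,
    snp_window: Sequence[Variant | str],
    freq_floor: float = 0.01,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeSet:
    """EM haplotype-frequency estimation over an SNP window (L <= 25).

    Individuals with every window genotype missing are excluded from the
    estimate (reported in ``excluded_sample_ids``).  With ``freq_floor`` 0
    this is the exhaustive EM over every compatible haplotype.
    """
    ids = [v if isinstance(v, str) else v.id for v in snp_window]
    L = len(ids)
    if L == 0:
        raise LDError("empty SNP window")
    if L > MAX_WINDOW_SNPS:
        raise LDError(
            f"window of {L} SNPs exceeds the {MAX_WINDOW_SNPS}-SNP enumeration "
            "guard; split the window"
        )
    idx = [panel.variant_index(i) for i in ids]
    variants = [panel.variants[j] for j in idx]
    G = panel.genotypes[:, idx]

    all_missing = (G == MISSING).all(axis=1)
    excluded = [s.id for s, m in zip(panel.samples, all_missing) if m]
    kept_samples = [s.id for s, m in zip(panel.samples, all_missing) if not m]
    G = G[~all_missing]
    n = G.shape[0]
    if n == 0:
        raise LDError("no individuals with any observed genotype in window")

    # group individuals by genotype pattern
    pattern_rows: dict[tuple[int, ...], list[int]] = {}
    for i, row in enumerate(map(tuple, G.tolist())):
        pattern_rows.setdefault(row, []).append(i)
    patterns = list(pattern_rows)

    # initial candidate set and product-of-allele-frequency initialisation
    cand: list[int] = sorted({h for pat in patterns for h in _expand_pattern(pat)})
    p_allele = np.empty(L)
    for j in range(L):
        col = G[:, j]
        obs = col != MISSING
        p_allele[j] = col[obs].sum() / (2 * obs.sum()) if obs.any() else 0.5
    p_allele = np.clip(p_allele, 1e-12, 1 - 1e-12)

    def product_freq(h: int) -> float:
        lf = 0.0
        for j in range(L):
            lf += math.log(p_allele[j] if (h >> j) & 1 else 1 - p_allele[j])
        return math.exp(lf)

    freqs = np.array([product_freq(h) for h in cand])
    freqs /= freqs.sum()

    pattern_count = np.array([len(pattern_rows[p]) for p in patterns], dtype=float)

    def build_pairs(cand_list: list[int]):
        index = {h: k for k, h in enumerate(cand_list)}
        out = []
        for pat in patterns:
            known1, known0, het, miss = _pattern_masks(pat)
            compat = [
                h for h in cand_list
                if (h & known0) == 0 and (h & known1) == known1
            ]
            i1, i2 = [], []
            for h1 in compat:
                base = known1 | (het & ~h1)
                for sub in _subsets(miss):
                    h2 = base | sub
                    k2 = index.get(h2)
                    if k2 is not None:
                        i1.append(index[h1])
                        i2.append(k2)
            out.append((np.array(i1, dtype=np.int64), np.array(i2, dtype=np.int64)))
        return out

    pairs = build_pairs(cand)
    loglik = -np.inf
    # pruning starts only after a short burn-in: under the product
    # initialisation the first E-steps spread mass over many spurious
    # haplotypes, and pruning immediately could discard genuine rare ones
    burn_in = 5
    trace: list[float] = []
    for it in range(max_iter):
        counts = np.zeros(len(cand))
        loglik = 0.0
        for pi, (i1, i2) in enumerate(pairs):
            if len(i1) == 0:
                continue
            w = freqs[i1] * freqs[i2]
            norm = w.sum()
            if norm <= 0:
                continue
            loglik += pattern_count[pi] * math.log(norm)
            w = w * (pattern_count[pi] / norm)
            np.add.at(counts, i1, w)
            np.add.at(counts, i2, w)
        trace.append(loglik)
        total = counts.sum()  # equals 2n unless a pattern lost all support
        new = counts / total if total > 0 else counts
        delta = float(np.abs(new - freqs).max())
        freqs = new
        if freq_floor > 0 and it >= burn_in:
            keep = freqs >= freq_floor
            if not keep.all() and keep.any():
                cand = [h for h, k in zip(cand, keep) if k]
                freqs = freqs[keep]
                freqs = freqs / freqs.sum()
                pairs = build_pairs(cand)
                continue
        if delta < tol:
            break

    # posteriors per individual under the final frequencies
    order = sorted(
        range(len(cand)),
        key=lambda k: (-freqs[k], _hap_string(cand[k], variants)),
    )
    rank = {k: r for r, k in enumerate(order)}
    haplotypes = [
        (_hap_string(cand[k], variants), float(freqs[k])) for k in order
    ]
    post_pairs: list[np.ndarray] = [None] * n
    post_probs: list[np.ndarray] = [None] * n
    for pi, pat in enumerate(patterns):
        i1, i2 = pairs[pi]
        if len(i1):
            w = freqs[i1] * freqs[i2]
            norm = w.sum()
        else:
            norm = 0.0
        if norm > 0:
            probs = w / norm
            pp = np.column_stack(
                [[rank[k] for k in i1], [rank[k] for k in i2]]
            ).astype(np.int64)
        else:  # all explanations pruned; degenerate uniform over nothing
            probs = np.array([])
            pp = np.zeros((0, 2), dtype=np.int64)
        for row in pattern_rows[pat]:
            post_pairs[row] = pp
            post_probs[row] = probs
    return HaplotypeSet(
        snps=variants,
        haplotypes=haplotypes,
        sample_ids=kept_samples,
        posterior_pairs=post_pairs,
        posterior_probs=post_probs,
        log_likelihood=float(loglik),
        excluded_sample_ids=excluded,
        loglik_trace=trace,
    )


def _hap_string(h: int, variants: Sequence[Variant]) -> str:
    return "".join(
        v.allele_minor if (h >> j) & 1 else v.allele_major
        for j, v in enumerate(variants)
    )


# ---------------------------------------------------------------------------
# Haplotype blocks (Gabriel CI rule)
# ---------------------------------------------------------------------------

def build_blocks(
    panel: CohortPanel,
    window_bp: int = 250_000,
    anchor: Variant | str | None = None,
) -> list[HaplotypeBlock]:
    """Partition the SNPs within ``window_bp`` centred on ``anchor`` into
    haplotype blocks by the D'-confidence-interval rule.

    Blocks are chosen greedily, longest bp span first, non-overlapping, and
    returned sorted by position.  Monomorphic SNPs are ignored.
    """
    if anchor is None:
        in_window = list(panel.variants)
    else:
        a = panel.variant(anchor if isinstance(anchor, str) else anchor.id)
        half = window_bp / 2
        in_window = [
            v for v in panel.variants
            if v.chrom == a.chrom and abs(v.pos - a.pos) <= half
        ]
    poly = []
    for v in in_window:
        col = panel.genotypes[:, panel.variant_index(v.id)]
        obs = col[col != MISSING]
        if len(obs) and 0 < obs.sum() < 2 * len(obs):
            poly.append(v)
    poly.sort(key=lambda v: v.pos)
    m = len(poly)
    if m < 2:
        return []

    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            low, high = dprime_ci(panel, poly[i], poly[j])
            s = low >= STRONG_LD_LOW and high >= STRONG_LD_HIGH
            r = high < RECOMB_HIGH
            strong[i, j] = strong[j, i] = s
            informative[i, j] = informative[j, i] = s or r

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if not strong[i, j]:
                continue
            sub_inf = informative[i : j + 1, i : j + 1]
            sub_str = strong[i : j + 1, i : j + 1]
            n_inf = np.triu(sub_inf, 1).sum()
            n_str = np.triu(sub_str, 1).sum()
            if n_inf > 0 and n_str / n_inf >= BLOCK_STRONG_FRACTION:
                candidates.append((poly[j].pos - poly[i].pos, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    used = np.zeros(m, dtype=bool)
    blocks: list[HaplotypeBlock] = []
    for _, i, j in candidates:
        if used[i : j + 1].any():
            continue
        used[i : j + 1] = True
        blocks.append(
            HaplotypeBlock(
                interval=GenomicInterval(poly[i].chrom, poly[i].pos, poly[j].pos),
                snp_ids=tuple(v.id for v in poly[i : j + 1]),
            )
        )
    blocks.sort(key=lambda b: b.interval.start_bp)
    return blocks
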