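"""Cross-population fine-mapping: Bonferroni gating, core-haplotype
intersection, and risk/protective differentiating-SNP detection.

The fine-mapping logic narrows an associated LD region in three moves:

1. keep only populations whose anchor-SNP p-value clears a Bonferroni
   threshold (alpha over the number of populations tested);
2. intersect the retained populations' most-associated haplotype blocks
   into a shared "core" region;
3. within the core, flag the SNPs whose minor allele sits on the protective
   haplotype but not on the risk haplotype — the span of those flagged SNPs
   is the refined candidate region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genotypes import GenomicInterval, ValidationError, Variant
from .hap_assoc import HapAssocResult
from .ld_phase import HaplotypeBlock


class FinemapError(Exception):
    pass


@dataclass
class CoreRegion:
    """Shared haplotype region across populations."""

    interval: GenomicInterval
    snp_ids: tuple[str, ...]
    mode: str
    member_populations: tuple[str, ...]
    core_haplotypes: dict[str, str] = field(default_factory=dict)
    differentiating_flags: tuple[bool, ...] | None = None
    differentiating_ids: tuple[str, ...] | None = None
    refined_interval: GenomicInterval | None = None


def gate_populations(
    per_pop_p_at_anchor: Mapping[str, float], k: int, alpha: float = 0.05
) -> tuple[list[str], float]:
    """Bonferroni gate: include a population iff its anchor-SNP p-value is
    below round(alpha/k, 3).  Returns (included labels, threshold)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    threshold = round(alpha / k, 3)
    included = [
        label for label, p in per_pop_p_at_anchor.items() if p < threshold
    ]
    return included, threshold


def core_intersection(
    top_blocks: Mapping[str, HaplotypeBlock],
    mode: str = "strict",
    snp_positions: Mapping[str, int] | None = None,
    top_haplotypes: Mapping[str, str] | None = None,
) -> CoreRegion:
    """Intersect per-population top blocks into a core region.

    strict: interval [max of block starts, min of block ends]; member SNPs
    are those inside it carried by every population's block.

    consensus: the strict core extended outward SNP by SNP for as long as
    every population's top haplotype that covers the flanking SNP carries
    the same allele there; requires ``snp_positions`` (id -> bp) and
    ``top_haplotypes`` (population -> allele string aligned to its block's
    SNP list).
    """
    if len(top_blocks) < 2:
        raise FinemapError("core intersection needs blocks from >= 2 populations")
    if mode not in ("strict", "consensus"):
        raise ValueError(f"mode must be strict/consensus, got {mode!r}")
    blocks = dict(top_blocks)
    chroms = {b.interval.chrom for b in blocks.values()}
    if len(chroms) > 1:
        raise FinemapError(f"blocks span multiple chromosomes: {sorted(chroms)}")
    start = max(b.interval.start_bp for b in blocks.values())
    end = min(b.interval.end_bp for b in blocks.values())
    if end < start:
        pairs = []
        labels = sorted(blocks)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                ov = min(
                    blocks[a].interval.end_bp, blocks[b].interval.end_bp
                ) - max(blocks[a].interval.start_bp, blocks[b].interval.start_bp)
                pairs.append(f"{a}/{b}: {max(0, ov + 1)} bp")
        raise FinemapError(
            "blocks have an empty common intersection; pairwise overlaps: "
            + "; ".join(pairs)
        )

    positions = dict(snp_positions or {})
    for b in blocks.values():
        # block endpoints anchor first/last SNP when positions not supplied
        if b.snp_ids and b.snp_ids[0] not in positions:
            positions.setdefault(b.snp_ids[0], b.interval.start_bp)
            positions.setdefault(b.snp_ids[-1], b.interval.end_bp)

    def snps_in(lo: int, hi: int) -> list[str]:
        shared = None
        for b in blocks.values():
            ids = set(b.snp_ids)
            shared = ids if shared is None else shared & ids
        shared = shared or set()
        inside = [s for s in shared if s in positions and lo <= positions[s] <= hi]
        return sorted(inside, key=lambda s: positions[s])

    core_ids = snps_in(start, end)
    chrom = next(iter(chroms))
    if mode == "strict":
        region = CoreRegion(
            interval=GenomicInterval(chrom, start, end),
            snp_ids=tuple(core_ids),
            mode="strict",
            member_populations=tuple(sorted(blocks)),
        )
    else:
        if top_haplotypes is None:
            raise FinemapError("consensus mode requires top_haplotypes")
        allele_at = {}
        for pop, b in blocks.items():
            hap = top_haplotypes[pop]
            if len(hap) != len(b.snp_ids):
                raise FinemapError(
                    f"{pop}: haplotype length {len(hap)} != block SNPs {len(b.snp_ids)}"
                )
            for sid, allele in zip(b.snp_ids, hap):
                allele_at.setdefault(sid, {})[pop] = allele
        # candidate SNPs ordered by position over the union of blocks
        union = sorted(
            {s for b in blocks.values() for s in b.snp_ids if s in positions},
            key=lambda s: positions[s],
        )
        lo = next(i for i, s in enumerate(union) if positions[s] >= start)
        hi = max(i for i, s in enumerate(union) if positions[s] <= end)

        def consistent(sid: str) -> bool:
            alleles = set(allele_at.get(sid, {}).values())
            return len(alleles) == 1

        while lo > 0 and consistent(union[lo - 1]):
            lo -= 1
        while hi < len(union) - 1 and consistent(union[hi + 1]):
            hi += 1
        ids = tuple(union[lo : hi + 1])
        region = CoreRegion(
            interval=GenomicInterval(chrom, positions[ids[0]], positions[ids[-1]]),
            snp_ids=ids,
            mode="consensus",
            member_populations=tuple(sorted(blocks)),
        )
    return region


def designate_risk_protective(
    results: Sequence[HapAssocResult],
) -> tuple[HapAssocResult, HapAssocResult]:
    """(protective, risk) = the two most frequent haplotypes, which must
    have opposite odds-ratio directions (OR < 1 vs OR > 1); errors
    otherwise rather than guessing."""
    if len(results) < 2:
        raise FinemapError("need >= 2 haplotypes to designate risk/protective")
    top2 = sorted(results, key=lambda r: -r.freq_all)[:2]
    a, b = top2
    if not (math.isfinite(a.beta) and math.isfinite(b.beta)):
        raise FinemapError("top haplotypes lack finite effect estimates")
    if a.beta < 0 < b.beta:
        return a, b
    if b.beta < 0 < a.beta:
        return b, a
    raise FinemapError(
        "two most frequent haplotypes do not have opposite OR directions "
        f"(ORs {a.or_:.3f}, {b.or_:.3f})"
    )


def differentiating_snps(
    core_snps: Sequence[Variant],
    protective: str,
    risk: str,
) -> tuple[tuple[bool, ...], tuple[str, ...], GenomicInterval | None]:
    """Flag core SNPs whose minor allele is on the protective haplotype and
    whose major allele is on the risk haplotype.

    Returns (flags aligned to core_snps, flagged ids, refined interval
    spanning the flagged SNPs, or None when nothing is flagged).
    """
    if len(protective) != len(core_snps) or len(risk) != len(core_snps):
        raise ValidationError(
            f"haplotype strings (len {len(protective)}/{len(risk)}) do not align "
            f"to {len(core_snps)} core SNPs"
        )
    flags = []
    for v, p_allele, r_allele in zip(core_snps, protective, risk):
        valid = {v.allele_major, v.allele_minor}
        for allele, which in ((p_allele, "protective"), (r_allele, "risk")):
            if allele not in valid:
                raise ValidationError(
                    f"{v.id}: {which} haplotype allele {allele!r} matches neither "
                    f"declared allele {sorted(valid)}"
                )
        flags.append(p_allele == v.allele_minor and r_allele == v.allele_major)
    ids = tuple(v.id for v, f in zip(core_snps, flags) if f)
    refined = None
    if ids:
        flagged = [v for v, f in zip(core_snps, flags) if f]
        refined = GenomicInterval(
            flagged[0].chrom,
            min(v.pos for v in flagged),
            max(v.pos for v in flagged),
        )
    return tuple(flags), ids, refined


def interval_span_kb(interval: GenomicInterval) -> float:
    """Interval span in kb, truncated (floored) to one decimal, matching
    the reporting convention of the block tables."""
    return math.floor((interval.end_bp - interval.start_bp) / 100) / 10
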