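"""Regulatory prioritisation of fine-mapped SNPs.

Three ingredients: LD-proxy expansion from the study's own genotypes,
interval overlap against BED feature tracks (open chromatin, histone
marks, TF binding, conservation), and position-weight-matrix (PWM) motif
disruption scoring of the reference vs alternative allele.

Motif scores are log2 likelihood ratios against a background base
distribution, maximised over every motif placement covering the SNP on
both strands; ``delta`` is best-alt minus best-ref.  A pseudo-count is
applied when PWMs are loaded so no matrix entry is zero.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotypes import GenomicInterval, Variant
from .ld_phase import LDError, LDStats, ld_pair

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: pseudo-count fraction applied to PWM probabilities at load time
PWM_PSEUDOCOUNT = 1e-3

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class AnnotationError(Exception):
    pass


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background base frequencies.

    ``matrix`` is positions x 4 (A, C, G, T) probabilities; every row sums
    to 1 and, thanks to the load-time pseudo-count, has no zero entry.
    """

    motif_id: str
    matrix: np.ndarray
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise AnnotationError(f"{self.motif_id}: PWM must be positions x 4")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise AnnotationError(f"{self.motif_id}: PWM rows must be probabilities")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            tuple(self.background[::-1]),
        )

    def log_odds(self) -> np.ndarray:
        bg = np.asarray(self.background)
        return np.log2(self.matrix / bg)


def pwm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    pseudocount: float = PWM_PSEUDOCOUNT,
) -> PWM:
    counts = np.asarray(counts, dtype=float) + pseudocount
    return PWM(motif_id, counts / counts.sum(axis=1, keepdims=True), background)


def read_jaspar(path: str | os.PathLike, pseudocount: float = PWM_PSEUDOCOUNT) -> list[PWM]:
    """Load a JASPAR-format PWM file (count or frequency matrices)."""
    from Bio import motifs

    out = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
            out.append(pwm_from_counts(m.matrix_id or m.name, counts, pseudocount=pseudocount))
    return out


@dataclass(frozen=True)
class MotifDisruption:
    """Best-placement motif scores for the two alleles of one SNP."""

    motif_id: str
    best_ref_score: float
    best_alt_score: float
    ref_offset: int
    ref_strand: str
    alt_offset: int
    alt_strand: str

    @property
    def delta(self) -> float:
        return self.best_alt_score - self.best_ref_score


# ---------------------------------------------------------------------------
# LD proxies and feature overlap
# ---------------------------------------------------------------------------

def ld_proxies(
    panel, anchor: Variant | str, r2_min: float = 0.9
) -> list[tuple[Variant, LDStats]]:
    """All panel variants with r^2 >= r2_min to the anchor, sorted by r^2
    descending (the anchor itself comes first at r^2 = 1).  Monomorphic
    variants cannot be proxies and are skipped."""
    aid = anchor if isinstance(anchor, str) else anchor.id
    a = panel.variant(aid)
    out = []
    for v in panel.variants:
        try:
            stats = ld_pair(panel, a, v)
        except LDError:
            if v.id == aid:
                raise
            continue
        if stats.r2 >= r2_min:
            out.append((v, stats))
    out.sort(key=lambda t: (-t[1].r2, t[0].pos))
    return out


def overlap_features(
    snps: Sequence[Variant], features: Sequence[GenomicInterval]
) -> dict[str, list[GenomicInterval]]:
    """Per-SNP feature overlaps; a SNP hits a feature iff
    start <= pos <= end in the shared 1-based inclusive convention."""
    from intervaltree import IntervalTree

    snp_chroms = {v.chrom for v in snps}
    feat_chroms = {f.chrom for f in features}
    unmatched = sorted(snp_chroms ^ feat_chroms)
    if snps and features and snp_chroms.isdisjoint(feat_chroms):
        warnings.warn(
            f"no shared chromosome names between SNPs and features: {unmatched}",
            stacklevel=2,
        )
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start_bp, f.end_bp + 1, f)
    out: dict[str, list[GenomicInterval]] = {}
    for v in snps:
        hits = trees[v.chrom][v.pos] if v.chrom in trees else []
        out[v.id] = sorted(
            (h.data for h in hits), key=lambda f: (f.start_bp, f.end_bp, f.label)
        )
    return out


def feature_class(label: str) -> str:
    """Feature class = BED label prefix before the first colon
    ("DNase:GM12878" -> "DNase"); an empty label is its own class."""
    return label.split(":", 1)[0]


# ---------------------------------------------------------------------------
# Motif disruption
# ---------------------------------------------------------------------------

def _score_window(window: str, log_odds: np.ndarray) -> float | None:
    score = 0.0
    for pos, base in enumerate(window):
        k = BASES.find(base)
        if k < 0:  # ambiguous base: skip this placement
            return None
        score += log_odds[pos, k]
    return score


def _best_placement(
    seq: str, snp_index: int, pwm: PWM
) -> tuple[float, int, str]:
    L = len(pwm)
    fwd = pwm.log_odds()
    rev = pwm.reverse_complement().log_odds()
    best: tuple[float, int, str] | None = None
    for offset in range(max(0, snp_index - L + 1), min(len(seq) - L, snp_index) + 1):
        window = seq[offset : offset + L]
        for strand, lo in (("+", fwd), ("-", rev)):
            s = _score_window(window, lo)
            if s is None:
                continue
            if best is None or s > best[0] or (
                s == best[0] and (offset, strand) < (best[1], best[2])
            ):
                best = (s, offset, strand)
    if best is None:
        raise AnnotationError(
            f"{pwm.motif_id}: no valid motif placement covers the SNP"
        )
    return best


def motif_disruption(
    sequence_context: str,
    snp_index: int,
    ref: str,
    alt: str,
    pwm: PWM,
) -> MotifDisruption:
    """Score the best PWM placement covering the SNP for each allele.

    ``sequence_context`` must carry ``ref`` at ``snp_index``.  Placements
    containing ambiguous bases are skipped; the reverse strand scores the
    reverse-complemented matrix against the forward sequence, which equals
    scoring the motif on the reverse-complement strand.
    """
    seq = sequence_context.upper()
    if not (0 <= snp_index < len(seq)):
        raise AnnotationError("snp_index outside sequence context")
    if seq[snp_index] != ref.upper():
        raise AnnotationError(
            f"context base {seq[snp_index]!r} at index {snp_index} != ref {ref!r}"
        )
    if len(seq) < len(pwm):
        raise AnnotationError("sequence context shorter than the motif")
    ref_score, ref_off, ref_strand = _best_placement(seq, snp_index, pwm)
    alt_seq = seq[:snp_index] + alt.upper() + seq[snp_index + 1 :]
    alt_score, alt_off, alt_strand = _best_placement(alt_seq, snp_index, pwm)
    return MotifDisruption(
        motif_id=pwm.motif_id,
        best_ref_score=ref_score,
        best_alt_score=alt_score,
        ref_offset=ref_off,
        ref_strand=ref_strand,
        alt_offset=alt_off,
        alt_strand=alt_strand,
    )


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def prioritize(
    snps: Sequence[Variant],
    feature_hits: Mapping[str, Sequence[GenomicInterval]],
    disruptions: Mapping[str, Sequence[MotifDisruption]] | None = None,
) -> "pd.DataFrame":
    """Rank SNPs by (distinct feature classes hit, max |motif delta|,
    position); the ordering is total, so permuting the input never changes
    the output order."""
    import pandas as pd

    disruptions = disruptions or {}
    rows = []
    for v in snps:
        classes = sorted({feature_class(f.label) for f in feature_hits.get(v.id, [])})
        deltas = [abs(d.delta) for d in disruptions.get(v.id, [])]
        rows.append(
            {
                "SNP": v.id,
                "CHR": v.chrom,
                "BP": v.pos,
                "n_feature_classes": len(classes),
                "feature_classes": ",".join(classes),
                "max_abs_delta": max(deltas) if deltas else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            by=["n_feature_classes", "max_abs_delta", "BP"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
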