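"""Genotype, phenotype and interval data structures plus file I/O.

The in-memory model is a :class:`CohortPanel`: an ordered list of biallelic
SNPs, a list of samples with case/control phenotype, sex and population
labels, and a samples x variants matrix of minor-allele counts (0/1/2, with
-1 for missing).  All genomic coordinates inside the package are 1-based
inclusive; BED input is converted at the boundary.

Supported on-disk formats: VCF 4.x (GT field only), PLINK-style text PED/MAP,
BED3/BED4, and a tab-separated phenotype table with columns
``sample_id  population  sex  phenotype``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

VALID_BASES = frozenset("ACGT")
SEX_LABELS = ("male", "female", "unknown")
PHENOTYPE_LABELS = ("case", "control")


class PanelError(Exception):
    """Base class for panel I/O and validation failures."""


class ParseError(PanelError):
    """A file did not parse under the declared standard."""


class ValidationError(PanelError):
    """Parsed data violated a panel invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """One genotyped biallelic SNP.

    Positions are 1-based base pairs on the build recorded in
    :attr:`CohortPanel.build`.
    """

    id: str
    chrom: str
    pos: int
    allele_major: str
    allele_minor: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.id}: position must be >= 1, got {self.pos}")
        for allele in (self.allele_major, self.allele_minor):
            if allele not in VALID_BASES:
                raise ValidationError(f"{self.id}: invalid allele {allele!r}")
        if self.allele_major == self.allele_minor:
            raise ValidationError(f"{self.id}: major and minor alleles are identical")


@dataclass(frozen=True)
class Sample:
    id: str
    population: str
    sex: str = "unknown"
    phenotype: str = "control"

    def __post_init__(self) -> None:
        if self.sex not in SEX_LABELS:
            raise ValidationError(f"{self.id}: sex must be one of {SEX_LABELS}, got {self.sex!r}")
        if self.phenotype not in PHENOTYPE_LABELS:
            raise ValidationError(
                f"{self.id}: phenotype must be 'case' or 'control', got {self.phenotype!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.phenotype == "case"


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval [start_bp, end_bp], 1-based inclusive on both ends."""

    chrom: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValidationError(
                f"interval end {self.end_bp} < start {self.start_bp} on {self.chrom}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class CohortPanel:
    """Genotype matrix plus sample metadata for one cohort (or pooled cohorts).

    ``genotypes[i, j]`` is the minor-allele count of sample i at variant j,
    in {0, 1, 2} or ``MISSING`` (-1).
    """

    variants: list[Variant]
    samples: list[Sample]
    genotypes: np.ndarray
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.samples), len(self.variants)
        if self.genotypes.shape != (n, m):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} != (samples={n}, variants={m})"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype value {self.genotypes[i, j]} at sample {self.samples[i].id}, "
                f"variant {self.variants[j].id} not in {{0,1,2,missing}}"
            )
        for items, kind in ((self.variants, "variant"), (self.samples, "sample")):
            ids = [x.id for x in items]
            if len(set(ids)) != len(ids):
                dup = sorted({v for v in ids if ids.count(v) > 1})
                raise ValidationError(f"duplicate {kind} id(s): {dup}")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(f"variant {variant_id!r} not in panel")

    def variant(self, variant_id: str) -> Variant:
        return self.variants[self.variant_index(variant_id)]

    @property
    def phenotype_vector(self) -> np.ndarray:
        """1 for case, 0 for control."""
        return np.array([1 if s.is_case else 0 for s in self.samples], dtype=np.int8)

    @property
    def populations(self) -> list[str]:
        return sorted({s.population for s in self.samples})

    def stratum_mask(self, stratum: str) -> np.ndarray:
        if stratum == "all":
            return np.ones(self.n_samples, dtype=bool)
        if stratum == "cases":
            return self.phenotype_vector == 1
        if stratum == "controls":
            return self.phenotype_vector == 0
        raise ValueError(f"stratum must be all/cases/controls, got {stratum!r}")

    # -- subsetting ---------------------------------------------------------
    def subset_samples(self, mask: np.ndarray) -> "CohortPanel":
        mask = np.asarray(mask, dtype=bool)
        samples = [s for s, keep in zip(self.samples, mask) if keep]
        return CohortPanel(list(self.variants), samples, self.genotypes[mask], self.build)

    def subset_variants(self, ids: Sequence[str]) -> "CohortPanel":
        idx = [self.variant_index(i) for i in ids]
        return CohortPanel(
            [self.variants[j] for j in idx], list(self.samples),
            self.genotypes[:, idx], self.build,
        )

    def split_by_population(self, recode_minor: bool = True) -> dict[str, "CohortPanel"]:
        """Split into per-population panels, recomputing the minor allele
        within each population by default."""
        out = {}
        pops = np.array([s.population for s in self.samples])
        for pop in self.populations:
            sub = self.subset_samples(pops == pop)
            out[pop] = recode_minor_alleles(sub) if recode_minor else sub
        return out


def merge_panels(panels: Iterable[CohortPanel], recode_minor: bool = True) -> CohortPanel:
    """Concatenate panels sample-wise; variants must agree in id/position.

    Allele coding is harmonised to the first panel's major/minor orientation,
    then optionally re-oriented to the pooled minor allele.
    """
    panels = list(panels)
    if not panels:
        raise ValueError("no panels to merge")
    ref = panels[0]
    blocks = [ref.genotypes]
    samples = list(ref.samples)
    for p in panels[1:]:
        if [(v.id, v.chrom, v.pos) for v in p.variants] != [
            (v.id, v.chrom, v.pos) for v in ref.variants
        ]:
            raise ValidationError("panels to merge carry different variant lists")
        g = p.genotypes.copy()
        for j, (va, vb) in enumerate(zip(ref.variants, p.variants)):
            if {va.allele_major, va.allele_minor} != {vb.allele_major, vb.allele_minor}:
                raise ValidationError(f"allele mismatch at {va.id}")
            if va.allele_minor != vb.allele_minor:  # flip orientation
                col = g[:, j]
                obs = col != MISSING
                col[obs] = 2 - col[obs]
        blocks.append(g)
        samples.extend(p.samples)
    merged = CohortPanel(list(ref.variants), samples, np.vstack(blocks), ref.build)
    return recode_minor_alleles(merged) if recode_minor else merged


def recode_minor_alleles(panel: CohortPanel) -> CohortPanel:
    """Re-orient each variant so the stored counts refer to the less frequent
    allele in this panel's full sample; ties go to the alphabetically later
    allele."""
    g = panel.genotypes.copy()
    variants = []
    for j, v in enumerate(panel.variants):
        col = g[:, j]
        obs = col != MISSING
        n_obs = int(obs.sum())
        minor_count = int(col[obs].sum())
        freq = minor_count / (2 * n_obs) if n_obs else 0.0
        flip = freq > 0.5 or (
            freq == 0.5 and v.allele_minor < v.allele_major
        )
        if flip:
            col[obs] = 2 - col[obs]
            v = replace(v, allele_major=v.allele_minor, allele_minor=v.allele_major)
        variants.append(v)
    return CohortPanel(variants, list(panel.samples), g, panel.build)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | os.PathLike) -> dict[str, Sample]:
    """Read the tab-separated phenotype/covariate table.

    Columns: sample_id, population, sex (male/female/unknown or 1/2/0),
    phenotype (case/control or 2/1).
    """
    sex_map = {"male": "male", "female": "female", "unknown": "unknown",
               "1": "male", "2": "female", "0": "unknown"}
    phe_map = {"case": "case", "control": "control", "2": "case", "1": "control"}
    out: dict[str, Sample] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if ln == 1 and fields[0].lower() in ("sample_id", "sample", "iid"):
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}: line {ln}: expected 4 tab-separated columns")
            sid, pop, sex, phe = fields[:4]
            if sex.lower() not in sex_map:
                raise ParseError(f"{path}: line {ln}: bad sex value {sex!r}")
            if phe.lower() not in phe_map:
                raise ValidationError(
                    f"{path}: line {ln}: phenotype {phe!r} is not binary case/control"
                )
            if sid in out:
                raise ValidationError(f"{path}: duplicate sample id {sid!r} at line {ln}")
            out[sid] = Sample(sid, pop, sex_map[sex.lower()], phe_map[phe.lower()])
    return out


def write_phenotype_table(samples: Sequence[Sample], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\tsex\tphenotype\n")
        for s in samples:
            fh.write(f"{s.id}\t{s.population}\t{s.sex}\t{s.phenotype}\n")


# ---------------------------------------------------------------------------
# Panel readers / writers
# ---------------------------------------------------------------------------

def read_panel(
    genotype_path: str | os.PathLike,
    phenotype_path: str | os.PathLike,
    format: str = "vcf",
) -> CohortPanel:
    """Read genotypes plus the phenotype table into a validated panel.

    The minor allele per variant is recomputed as the less frequent allele in
    the full sample (ties to the alphabetically later allele) and variants
    are sorted by (chrom, pos).
    """
    pheno = read_phenotype_table(phenotype_path)
    if format == "vcf":
        variants, sample_ids, geno = _read_vcf(genotype_path)
    elif format == "plink_text":
        variants, sample_ids, geno = _read_ped_map(genotype_path)
    else:
        raise ValueError(f"format must be 'vcf' or 'plink_text', got {format!r}")

    missing_meta = [sid for sid in sample_ids if sid not in pheno]
    if missing_meta:
        raise ValidationError(
            f"samples absent from phenotype table: {missing_meta[:5]}"
            + ("..." if len(missing_meta) > 5 else "")
        )
    samples = [pheno[sid] for sid in sample_ids]

    order = sorted(range(len(variants)), key=lambda j: (variants[j].chrom, variants[j].pos))
    variants = [variants[j] for j in order]
    geno = geno[:, order]
    return recode_minor_alleles(CohortPanel(variants, samples, geno))


def _read_vcf(path: str | os.PathLike):
    from cyvcf2 import VCF

    try:
        vcf = VCF(os.fspath(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc
    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ParseError(
                f"{path}: variant {rec.ID or rec.POS} is not a biallelic SNP"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise ValidationError(f"{path}: duplicate variant id {vid!r}")
        seen.add(vid)
        variants.append(Variant(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # gt_types: 0=hom ref, 1=het, 2=hom alt (cyvcf2 UNKNOWN=3)
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt.copy())
    vcf.close()
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return variants, sample_ids, geno


def _read_ped_map(path: str | os.PathLike):
    """Read PLINK text PED/MAP.  ``path`` may be the prefix, the .ped or the
    .map file."""
    path = os.fspath(path)
    prefix = path[:-4] if path.endswith((".ped", ".map")) else path
    ped_path, map_path = prefix + ".ped", prefix + ".map"

    sites: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ParseError(f"{map_path}: line {ln}: expected 4 columns")
            chrom, vid, _cm, pos = fields[:4]
            sites.append((chrom, vid, int(pos)))

    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(sites):
                raise ParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * len(sites)} fields, "
                    f"got {len(fields)}"
                )
            sample_ids.append(fields[1])
            pairs = [(fields[6 + 2 * k], fields[7 + 2 * k]) for k in range(len(sites))]
            for a, b in pairs:
                if (a == "0") != (b == "0"):
                    raise ParseError(f"{ped_path}: line {ln}: half-missing genotype")
            allele_rows.append(pairs)

    variants: list[Variant] = []
    geno = np.full((len(sample_ids), len(sites)), MISSING, dtype=np.int8)
    for j, (chrom, vid, pos) in enumerate(sites):
        observed = sorted({a for row in allele_rows for a in row[j] if a != "0"})
        if len(observed) > 2:
            raise ParseError(f"{map_path}: {vid}: more than two alleles observed")
        if not observed:
            observed = ["A", "C"]  # fully missing site; placeholder coding
        if len(observed) == 1:
            # monomorphic: pick the complement-of-observed deterministically
            other = next(b for b in "ACGT" if b != observed[0])
            observed = sorted([observed[0], other])
        major, minor = observed[0], observed[1]
        for i, row in enumerate(allele_rows):
            a, b = row[j]
            if a == "0":
                continue
            geno[i, j] = (a == minor) + (b == minor)
        variants.append(Variant(vid, chrom, pos, major, minor))
    return variants, sample_ids, geno


def write_panel(panel: CohortPanel, path: str | os.PathLike, format: str = "vcf") -> None:
    """Write the panel so that ``read_panel`` reproduces it exactly.

    VCF output uses REF=major, ALT=minor and GT-only records; PLINK text
    output writes <path>.ped and <path>.map.
    """
    if format == "vcf":
        _write_vcf(panel, path)
    elif format == "plink_text":
        _write_ped_map(panel, path)
    else:
        raise ValueError(f"format must be 'vcf' or 'plink_text', got {format!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(panel: CohortPanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=haplofine\n##reference={panel.build}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chrom for v in panel.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        cols[7:7] = ["INFO"]
        fh.write("\t".join(cols + [s.id for s in panel.samples]) + "\n")
        for j, v in enumerate(panel.variants):
            gts = "\t".join(_GT_CODE[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.allele_major}\t{v.allele_minor}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def _write_ped_map(panel: CohortPanel, path: str | os.PathLike) -> None:
    prefix = os.fspath(path)
    if prefix.endswith((".ped", ".map")):
        prefix = prefix[:-4]
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    phe_code = {"control": "1", "case": "2"}
    with open(prefix + ".map", "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, s in enumerate(panel.samples):
            fields = [s.population, s.id, "0", "0", sex_code[s.sex], phe_code[s.phenotype]]
            for j, v in enumerate(panel.variants):
                g = int(panel.genotypes[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [v.allele_minor if k < g else v.allele_major for k in range(2)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file into 1-based inclusive intervals.

    BED is 0-based half-open, so a line ``chrom  s  e`` becomes the interval
    [s+1, e].  Column 4 (name) becomes the label when present.  Overlapping
    intervals are preserved, not merged.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {ln}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start > end:
                raise ValidationError(f"{path}: line {ln}: start {start} > end {end}")
            label = fields[3] if len(fields) > 3 else ""
            out.append(GenomicInterval(chrom, start + 1, end, label))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    """Inverse of :func:`read_bed` (internal 1-based inclusive -> BED)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start_bp - 1), str(iv.end_bp)]
            if iv.label:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")
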