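"""Config-driven end-to-end fine-mapping pipeline.

Stage order: QC -> per-population association -> joint (pooled) analysis ->
conditional scan on the top SNP -> block construction and EM phasing ->
haplotype association -> Bonferroni population gating -> core-haplotype
intersection -> differentiating-SNP detection -> optional regulatory
annotation.  ``run_analysis`` operates on in-memory panels and returns a
:class:`PipelineResult`; ``run_pipeline`` adds file I/O (reading panels per
the config, writing per-stage tab-separated reports, a JSON summary twin of
every summary number, and a simple -log10(p) SVG track).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import annotate as _annotate
from .assoc import (
    AssocResult,
    association_table,
    conditional_scan,
    joint_meta,
    logistic_assoc,
    qc_filter,
)
from .finemap import (
    CoreRegion,
    FinemapError,
    core_intersection,
    designate_risk_protective,
    differentiating_snps,
    gate_populations,
    interval_span_kb,
)
from .genotypes import (
    CohortPanel,
    GenomicInterval,
    merge_panels,
    read_bed,
    read_panel,
)
from .hap_assoc import (
    HapAssocResult,
    haplotype_association,
    haplotype_table,
    select_top,
)
from .ld_phase import MAX_WINDOW_SNPS, HaplotypeBlock, build_blocks


class PipelineError(Exception):
    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults mirror the package's reference analysis
    of a 70 kb LD region with six cohorts."""

    inputs: dict[str, dict[str, str]] = field(default_factory=dict)
    region_chrom: str = "3"
    region_start: int = 188_069_360
    region_end: int = 188_139_629
    window_bp: int = 250_000
    alpha: float = 0.05
    k_populations: int | None = None
    qc_maf_min: float = 0.01
    qc_hwe_min_p: float = 1e-4
    freq_floor: float = 0.01
    core_mode: str = "strict"
    seed: int = 0
    features_bed: str | None = None

    def __post_init__(self) -> None:
        if self.region_start >= self.region_end:
            raise ValueError("region start must be < end")
        for name, v in (
            ("alpha", self.alpha), ("qc_maf_min", self.qc_maf_min),
            ("qc_hwe_min_p", self.qc_hwe_min_p), ("freq_floor", self.freq_floor),
        ):
            if not (0 <= v < 1):
                raise ValueError(f"{name}={v} outside [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        region = raw.pop("region", None)
        if region:
            raw["region_chrom"] = str(region.get("chrom", "3"))
            raw["region_start"] = int(region["start"])
            raw["region_end"] = int(region["end"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    status: str
    per_pop_assoc: dict[str, dict[str, AssocResult]] = field(default_factory=dict)
    meta_assoc: dict[str, AssocResult] = field(default_factory=dict)
    top_snp: str | None = None
    conditional: dict[str, AssocResult] = field(default_factory=dict)
    bonferroni_threshold: float | None = None
    gated_populations: list[str] = field(default_factory=list)
    top_blocks: dict[str, HaplotypeBlock] = field(default_factory=dict)
    top_hap_results: dict[str, HapAssocResult] = field(default_factory=dict)
    hap_results: dict[str, list[HapAssocResult]] = field(default_factory=dict)
    core: CoreRegion | None = None
    core_hap_results: list[HapAssocResult] = field(default_factory=list)
    protective: HapAssocResult | None = None
    risk: HapAssocResult | None = None
    annotation: "object" = None
    notes: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        out: dict = {"status": self.status, "notes": list(self.notes)}
        if self.top_snp:
            r = self.meta_assoc[self.top_snp]
            out["top_snp"] = {
                "id": self.top_snp, "p": r.p, "or": r.or_,
                "maf_cases": r.maf_cases, "maf_controls": r.maf_controls,
            }
        if self.conditional:
            finite = [r.p for r in self.conditional.values() if math.isfinite(r.p)]
            out["conditional_min_p"] = min(finite) if finite else None
        if self.bonferroni_threshold is not None:
            out["bonferroni_threshold"] = self.bonferroni_threshold
            out["gated_populations"] = list(self.gated_populations)
        if self.core is not None:
            out["core"] = {
                "chrom": self.core.interval.chrom,
                "start_bp": self.core.interval.start_bp,
                "end_bp": self.core.interval.end_bp,
                "span_kb": interval_span_kb(self.core.interval),
                "n_snps": len(self.core.snp_ids),
                "mode": self.core.mode,
            }
        if self.protective is not None:
            out["protective_haplotype"] = {
                "haplotype": self.protective.haplotype,
                "or": self.protective.or_,
                "p": self.protective.p,
            }
            out["risk_haplotype"] = {
                "haplotype": self.risk.haplotype,
                "or": self.risk.or_,
                "p": self.risk.p,
            }
        if self.core is not None and self.core.refined_interval is not None:
            ri = self.core.refined_interval
            out["refined_interval"] = {
                "chrom": ri.chrom, "start_bp": ri.start_bp, "end_bp": ri.end_bp,
                "span_kb": interval_span_kb(ri),
                "n_differentiating_snps": len(self.core.differentiating_ids or ()),
                "differentiating_snps": list(self.core.differentiating_ids or ()),
            }
        if self.annotation is not None and len(self.annotation):
            out["prioritized_snp"] = str(self.annotation.iloc[0]["SNP"])
        return out


# ---------------------------------------------------------------------------
# In-memory pipeline
# ---------------------------------------------------------------------------

def run_analysis(
    panels: Mapping[str, CohortPanel],
    config: PipelineConfig | None = None,
    features: Sequence[GenomicInterval] | None = None,
) -> PipelineResult:
    """Run the full fine-mapping chain on per-population panels."""
    cfg = config or PipelineConfig()
    res = PipelineResult(status="ok")

    # --- QC and region restriction -----------------------------------
    region = GenomicInterval(cfg.region_chrom, cfg.region_start, cfg.region_end)
    clean: dict[str, CohortPanel] = {}
    for pop in sorted(panels):
        panel = panels[pop]
        keep = [v.id for v in panel.variants if region.contains(v.chrom, v.pos)]
        sub = panel.subset_variants(keep)
        try:
            sub = qc_filter(sub, cfg.qc_maf_min, cfg.qc_hwe_min_p)
        except Exception as exc:
            raise PipelineError("qc", f"{pop}: {exc}") from exc
        if sub.n_variants:
            clean[pop] = sub
        else:
            res.notes.append(f"{pop}: no variants after region/QC filters")
    if not clean:
        res.status = "no variants"
        return res

    # --- per-population association -----------------------------------
    for pop, panel in clean.items():
        res.per_pop_assoc[pop] = {
            v.id: logistic_assoc(panel, v, covariates=("sex",))
            for v in panel.variants
        }

    # --- joint analysis and conditional scan --------------------------
    try:
        res.meta_assoc = joint_meta(list(clean.values()))
    except Exception as exc:
        raise PipelineError("meta", str(exc)) from exc
    finite = {v: r for v, r in res.meta_assoc.items() if math.isfinite(r.p)}
    if not finite:
        res.status = "no testable variants"
        return res
    res.top_snp = min(finite, key=lambda v: finite[v].p)
    res.conditional = conditional_scan(list(clean.values()), res.top_snp)

    # --- Bonferroni gate on the anchor SNP ----------------------------
    k = cfg.k_populations or len(panels)
    anchor_p = {}
    for pop in clean:
        r = res.per_pop_assoc[pop].get(res.top_snp)
        anchor_p[pop] = r.p if r is not None and math.isfinite(r.p) else 1.0
    res.gated_populations, res.bonferroni_threshold = gate_populations(
        anchor_p, k=k, alpha=cfg.alpha
    )
    if not res.gated_populations:
        res.status = "no population passes the Bonferroni gate"
        return res

    # --- blocks, phasing and haplotype association per gated cohort ---
    for pop in res.gated_populations:
        panel = clean[pop]
        blocks = build_blocks(panel, cfg.window_bp, anchor=res.top_snp)
        if not blocks:
            res.notes.append(f"{pop}: no haplotype blocks; population skipped")
            continue
        best: tuple[HaplotypeBlock, HapAssocResult] | None = None
        for block in blocks:
            ids = _phasable_ids(block, panel, res.top_snp)
            _haps, results = haplotype_association(
                panel, ids, covariates=("sex",),
                freq_floor=cfg.freq_floor, population=pop,
            )
            if not results:
                continue
            res.hap_results.setdefault(pop, []).extend(results)
            top = select_top(results)
            if best is None or (math.isfinite(top.p) and top.p < best[1].p):
                best = (block, top)
        if best is not None:
            res.top_blocks[pop], res.top_hap_results[pop] = best

    if not res.top_blocks:
        res.status = "no blocks in any gated population"
        return res

    # --- core intersection ---------------------------------------------
    positions = {
        v.id: v.pos for panel in clean.values() for v in panel.variants
    }
    if len(res.top_blocks) == 1:
        ((pop, block),) = res.top_blocks.items()
        res.core = CoreRegion(
            interval=block.interval,
            snp_ids=block.snp_ids,
            mode=f"single-population ({pop})",
            member_populations=(pop,),
        )
        res.notes.append(
            "only one population passed the gate; its top block is the core"
        )
    else:
        try:
            res.core = core_intersection(
                res.top_blocks,
                mode=cfg.core_mode,
                snp_positions=positions,
                top_haplotypes={
                    p: r.haplotype for p, r in res.top_hap_results.items()
                },
            )
        except FinemapError as exc:
            raise PipelineError("core", str(exc), "inspect per-population blocks") from exc

    # --- haplotype association restricted to the core ------------------
    if not res.core.snp_ids:
        res.status = "core region carries no shared SNPs"
        return res
    merged = merge_panels(
        [clean[p] for p in res.gated_populations if p in clean]
    )
    core_ids = [sid for sid in res.core.snp_ids]
    _haps, res.core_hap_results = haplotype_association(
        merged, core_ids,
        covariates=("sex", "population") if len(res.gated_populations) > 1 else ("sex",),
        freq_floor=cfg.freq_floor, population="joint",
    )
    try:
        res.protective, res.risk = designate_risk_protective(res.core_hap_results)
    except FinemapError as exc:
        res.status = f"risk/protective designation failed: {exc}"
        return res
    core_variants = [merged.variant(sid) for sid in core_ids]
    flags, ids, refined = differentiating_snps(
        core_variants, res.protective.haplotype, res.risk.haplotype
    )
    res.core.differentiating_flags = flags
    res.core.differentiating_ids = ids
    res.core.refined_interval = refined
    res.core.core_haplotypes = {
        "protective": res.protective.haplotype, "risk": res.risk.haplotype
    }

    # --- optional annotation -------------------------------------------
    if features is not None and ids:
        flagged = [v for v in core_variants if v.id in ids]
        hits = _annotate.overlap_features(flagged, features)
        res.annotation = _annotate.prioritize(flagged, hits)
    return res


def _phasable_ids(block: HaplotypeBlock, panel: CohortPanel, anchor: str) -> list[str]:
    """Block SNPs, windowed to the enumeration guard around the anchor when
    the block is too wide to phase in one piece."""
    ids = list(block.snp_ids)
    if len(ids) <= MAX_WINDOW_SNPS:
        return ids
    center = ids.index(anchor) if anchor in ids else len(ids) // 2
    half = MAX_WINDOW_SNPS // 2
    lo = max(0, min(center - half, len(ids) - MAX_WINDOW_SNPS))
    return ids[lo : lo + MAX_WINDOW_SNPS]


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike) -> PipelineResult:
    """Read panels per the config, run the analysis and write stage reports.

    Writes per-stage TSVs, ``summary.json`` (the machine-readable twin of
    every summary number) and ``assoc_track.svg`` under ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    panels = {}
    for pop, paths in config.inputs.items():
        try:
            panels[pop] = read_panel(
                paths["genotypes"], paths["phenotypes"],
                format=paths.get("format", "vcf"),
            )
        except Exception as exc:
            raise PipelineError(
                "input", f"{pop}: {exc}", "check the paths in the config"
            ) from exc
    features = read_bed(config.features_bed) if config.features_bed else None
    result = run_analysis(panels, config, features=features)
    write_reports(result, out_dir)
    return result


def write_reports(result: PipelineResult, out_dir: str | os.PathLike) -> None:
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    for pop, table in result.per_pop_assoc.items():
        association_table(table.values()).to_csv(
            os.path.join(out, f"assoc_{pop}.tsv"), sep="\t", index=False
        )
    if result.meta_assoc:
        association_table(result.meta_assoc.values()).to_csv(
            os.path.join(out, "assoc_joint.tsv"), sep="\t", index=False
        )
    if result.conditional:
        association_table(result.conditional.values()).to_csv(
            os.path.join(out, "assoc_conditional.tsv"), sep="\t", index=False
        )
    for pop, hlist in result.hap_results.items():
        haplotype_table(hlist).to_csv(
            os.path.join(out, f"haplotypes_{pop}.tsv"), sep="\t", index=False
        )
    if result.core_hap_results:
        haplotype_table(result.core_hap_results).to_csv(
            os.path.join(out, "haplotypes_core_joint.tsv"), sep="\t", index=False
        )
    if result.annotation is not None:
        result.annotation.to_csv(
            os.path.join(out, "annotation.tsv"), sep="\t", index=False
        )
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if result.meta_assoc:
        _plot_track(result, os.path.join(out, "assoc_track.svg"))


def _plot_track(result: PipelineResult, path: str) -> None:
    import matplotlib

    matplotlib.use("svg", force=False)
    import matplotlib.pyplot as plt

    pos, logp = [], []
    for r in result.meta_assoc.values():
        if math.isfinite(r.p) and r.p > 0:
            pos.append(r.variant.pos)
            logp.append(-math.log10(r.p))
    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.scatter(pos, logp, s=12, c="0.2")
    if result.core is not None and result.core.refined_interval is not None:
        ri = result.core.refined_interval
        ax.axvspan(ri.start_bp, ri.end_bp, color="tab:orange", alpha=0.3)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
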