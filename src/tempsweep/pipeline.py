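"""End-to-end orchestration: simulate (or load) -> filter -> PCA ->
dAF enrichment, Fst/XP-EHH scan, mixed-model GWAS, region overlap, LD
refinement and the CNV screen, with every intermediate persisted as a
standard text format (VCF/TSV/BED/JSON) so stages can be re-run alone.

The overlap logic mirrors the published design: top-1% Fst windows
intersected with top-1% |XP-EHH| windows give candidate regions; regions
holding a Bonferroni-significant GWAS SNP survive; survivors are narrowed
to the LD envelope (r^2 > 0.4) around the lead SNP.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import afdiff, cnv, io, ld, mlm, scanstats, sim
from .containers import GenotypeMatrix, Region

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """One reproducible run: either a simulation block or input paths."""

    simulate: dict | None = None  # SimConfig overrides; None -> load from paths
    vcf: str | None = None
    meta: str | None = None
    pheno: str | None = None
    annot: str | None = None
    cn_matrix: str | None = None
    cohorts: tuple[int, int] = (1, 10)
    window: int = 10_000
    step: int = 5_000
    scan_tail: float = 0.01
    cnv_tail: float = 0.05
    gwas_alpha: float = 0.01
    r2_threshold: float = 0.4
    filter_profile: str = "discovery"
    n_pcs: int = 3
    n_cnvr: int = 80
    seed: int = 0

    def __post_init__(self):
        for name in ("scan_tail", "cnv_tail", "gwas_alpha", "r2_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.simulate is None and self.vcf is None:
            raise ValueError("config needs either a simulation block or input paths")
        if self.simulate is not None and self.vcf is not None:
            raise ValueError("give a simulation block or input paths, not both")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohorts" in raw:
            raw["cohorts"] = tuple(raw["cohorts"])
        return cls(**raw)


def _cohort_split(gm: GenotypeMatrix, meta: pd.DataFrame, gen: int) -> GenotypeMatrix:
    ids = list(meta.loc[meta["generation"] == gen, "sample_id"])
    if not ids:
        raise ValueError(f"no samples in generation {gen}")
    return gm.take_samples(ids)


def _region_list(regions: list[Region]) -> list[dict]:
    return [
        {
            "chrom": r.chrom,
            "start": int(r.start),
            "end": int(r.end),
            "span": int(r.span),
            "provenance": list(r.provenance),
            "snps": [int(p) for p in r.snps],
        }
        for r in regions
    ]


def _write_regions_bed(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{'+'.join(r.provenance)}\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the machine-readable run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # ---- data stage ------------------------------------------------------
    chrom_lengths = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        scfg = sim.SimConfig(**sim_kwargs)
        pops = sim.run_simulation(scfg)
        gm, meta, pheno = sim.sample_cohorts(pops, scfg.sample_schedule)
        truth, registry = sim.export_truth(pops)
        track = sim.make_annotation_track(scfg.n_chromosomes, scfg.chrom_length_bp)
        cn_values, cn_coords, cn_truth = sim.simulate_cnv_matrix(
            meta,
            n_cnvr=config.n_cnvr,
            n_generations=scfg.n_generations,
            chrom_length_bp=scfg.chrom_length_bp,
            seed=scfg.seed + 1,
        )
        chrom_lengths = {f"chr{i + 1}": scfg.chrom_length_bp for i in range(scfg.n_chromosomes)}
        io.write_vcf(gm, outdir / "genotypes.vcf")
        io.write_metadata(meta, outdir / "meta.tsv")
        io.write_phenotypes(pheno, outdir / "pheno.tsv")
        io.write_annotation_bed(track, outdir / "annotation.bed")
        cn_out = cn_coords.join(cn_values.reset_index(drop=True))
        cn_out.to_csv(outdir / "cn_matrix.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "truth_trajectories.tsv", sep="\t", index=False)
        registry.to_csv(outdir / "truth_causal.tsv", sep="\t", index=False)
        report["stages"]["simulate"] = {
            "n_samples": int(len(meta)),
            "n_sites": int(gm.n_sites),
            "n_causal": int(len(registry)),
        }
    else:
        gm = io.read_vcf(config.vcf)
        meta = io.read_metadata(config.meta)
        pheno = io.read_phenotypes(config.pheno) if config.pheno else None
        track = io.read_annotation_bed(config.annot) if config.annot else None
        cn_values = cn_coords = None
        if config.cn_matrix:
            raw = pd.read_csv(config.cn_matrix, sep="\t")
            cn_coords = raw[["cnvr_id", "chrom", "start", "end"]]
            cn_values = raw.drop(columns=["chrom", "start", "end"]).set_index("cnvr_id")
        report["stages"]["load"] = {"n_samples": int(len(meta)), "n_sites": int(gm.n_sites)}

    # ---- filter ----------------------------------------------------------
    fr = io.filter_variants(gm, config.filter_profile)
    gm_f = fr.table
    report["stages"]["filter"] = {
        "profile": config.filter_profile,
        "n_input": fr.n_input,
        "n_kept": fr.n_kept,
        "rejections": fr.rejections,
    }

    # ---- PCA -------------------------------------------------------------
    coords, eigvals, explained = scanstats.genotype_pca(gm_f, k=config.n_pcs)
    pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(config.n_pcs)]
    ).assign(sample_id=gm_f.samples).to_csv(outdir / "pca.tsv", sep="\t", index=False)
    report["stages"]["pca"] = {"explained": [float(x) for x in explained]}

    gen_a, gen_b = config.cohorts

    # ---- dAF enrichment branch ------------------------------------------
    fa = afdiff.cohort_ref_freq(gm_f, meta, gen_a)
    fb = afdiff.cohort_ref_freq(gm_f, meta, gen_b)
    af_table = afdiff.delta_af(fa, fb)
    af_table.insert(0, "chrom", gm_f.chrom)
    af_table.insert(1, "pos", gm_f.pos)
    bins = afdiff.bin_delta_af(af_table["delta_af"].to_numpy())
    af_table["bin"] = bins
    enrichment = None
    if track is not None:
        cats = io.intersect_with_annotation(gm_f, track)
        af_table["category"] = cats
        # sites fixed for the same allele in both cohorts carry no information
        poly = ~((fa == fb) & ((fa == 0.0) | (fa == 1.0)))
        enrichment = afdiff.category_enrichment(bins[poly], cats[poly])
        enrichment.to_csv(outdir / "afd_enrichment.tsv", sep="\t", index=False)
    af_table.to_csv(outdir / "afd.tsv", sep="\t", index=False)
    report["stages"]["afd"] = {
        "max_delta_af": float(np.nanmax(af_table["delta_af"])),
        "n_high_shift": int((af_table["delta_af"] > 0.3).sum()),
    }

    # ---- selection scan --------------------------------------------------
    gm_a = _cohort_split(gm_f, meta, gen_a)
    gm_b = _cohort_split(gm_f, meta, gen_b)
    comp = scanstats.wc_fst_site(gm_a.dosage, gm_b.dosage)
    fst_w = scanstats.fst_windows(
        comp, gm_f.chrom, gm_f.pos, config.window, config.step, chrom_lengths
    )
    xp = scanstats.xpehh_scan(gm_a, gm_b)
    xp_w = scanstats.xpehh_windows(xp, config.window, config.step, chrom_lengths)
    fst_cut = scanstats.empirical_threshold(
        [w.value for w in fst_w], config.scan_tail, "upper"
    )
    xp_lo, xp_hi = scanstats.empirical_threshold(
        [w.value for w in xp_w], config.scan_tail, "both"
    )
    fst_above = [w for w in fst_w if w.value >= fst_cut]
    xp_above = [w for w in xp_w if w.value >= xp_hi or w.value <= xp_lo]
    regions = scanstats.intersect_candidate_windows(fst_above, xp_above)
    pd.DataFrame(
        [(w.chrom, w.start, w.end, w.stat, w.value, w.n_snps) for w in fst_w + xp_w],
        columns=["chrom", "start", "end", "stat", "value", "n_snps"],
    ).to_csv(outdir / "windows.tsv", sep="\t", index=False)
    _write_regions_bed(regions, outdir / "candidate_regions.bed")
    report["stages"]["scan"] = {
        "fst_threshold": float(fst_cut),
        "xpehh_thresholds": [float(xp_lo), float(xp_hi)],
        "n_fst_windows_above": len(fst_above),
        "n_xpehh_windows_above": len(xp_above),
        "n_candidate_regions": len(regions),
        "candidate_span_bp": ld.region_span(regions) if regions else 0,
    }

    # ---- GWAS ------------------------------------------------------------
    overlapped: list[Region] = []
    refined: list[Region] = []
    if pheno is not None:
        joined = meta.merge(pheno[["sample_id", "BMW"]], on="sample_id")
        joined = joined.set_index("sample_id").loc[gm_f.samples].reset_index()
        y = joined["BMW"].to_numpy(dtype=float)
        sex_num = (joined["sex"] == "M").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y)), sex_num, coords[:, : config.n_pcs]])
        K = mlm.kinship_matrix(gm_f)
        sg2, se2, ll, transform = mlm.reml_null(y, X, K)
        assoc = mlm.emmax_scan(y, X, K, gm_f, transform)
        n_tested = int(np.isfinite(assoc["p"]).sum())
        cutoff = mlm.bonferroni_threshold(n_tested, config.gwas_alpha)
        assoc.to_csv(outdir / "assoc.tsv", sep="\t", index=False)
        overlapped = mlm.overlap_assoc_with_regions(assoc, regions, cutoff)
        _write_regions_bed(overlapped, outdir / "overlap_regions.bed")
        report["stages"]["gwas"] = {
            "sigma_g2": float(sg2),
            "sigma_e2": float(se2),
            "pseudo_h2": float(sg2 / (sg2 + se2)),
            "n_tested": n_tested,
            "bonferroni_mlog10p": float(cutoff),
            "n_significant": int((assoc["mlog10p"] >= cutoff).sum()),
            "n_overlapped_regions": len(overlapped),
        }

        # ---- LD refinement ----------------------------------------------
        for r in overlapped:
            lead = ld.lead_snp(r, gm_f.chrom, gm_f.pos, assoc["mlog10p"].to_numpy())
            refined.append(
                ld.refine_region(r, lead, gm_f, config.r2_threshold)
            )
        _write_regions_bed(refined, outdir / "refined_regions.bed")
        refine_info = {
            "n_refined": len(refined),
            "refined_span_bp": ld.region_span(refined) if refined else 0,
            "overlap_span_bp": ld.region_span(overlapped) if overlapped else 0,
        }
        if track is not None and refined:
            in_refined = np.zeros(gm_f.n_sites, dtype=bool)
            for r in refined:
                in_refined |= (
                    (gm_f.chrom == r.chrom)
                    & (gm_f.pos - 1 >= r.start)
                    & (gm_f.pos - 1 < r.end)
                )
            if in_refined.any():
                cats_r = io.intersect_with_annotation(gm_f.take_sites(np.flatnonzero(in_refined)), track)
                nonc, total, pct = ld.noncoding_fraction(cats_r)
                refine_info["noncoding"] = {"n": nonc, "total": total, "percent": pct}
        report["stages"]["refine"] = refine_info

        # per-generation trajectories of significant SNPs
        sig_idx = np.flatnonzero(assoc["mlog10p"].to_numpy() >= cutoff)
        if len(sig_idx):
            scanstats.frequency_trajectory(gm_f, meta, sig_idx).to_csv(
                outdir / "sig_snp_trajectories.tsv", sep="\t", index=False
            )

    # ---- CNV branch ------------------------------------------------------
    if cn_values is not None:
        ids_a = set(meta.loc[meta["generation"] == gen_a, "sample_id"])
        ids_b = set(meta.loc[meta["generation"] == gen_b, "sample_id"])
        rows = []
        for cnvr_id, row in cn_values.iterrows():
            keep, sil, reason = cnv.silhouette_filter(row.to_numpy())
            if not keep:
                rows.append((cnvr_id, sil, reason, np.nan, np.nan, np.nan))
                continue
            cls = cnv.classify_copy_number(row.to_numpy())
            sa = cls[[c in ids_a for c in cn_values.columns]]
            sb = cls[[c in ids_b for c in cn_values.columns]]
            fa_c = cnv.carrier_frequency(sa)
            fb_c = cnv.carrier_frequency(sb)
            stat = cnv.rfd(fa_c, fb_c, len(sa), len(sb))
            rows.append((cnvr_id, sil, "pass", fa_c, fb_c, stat))
        screen = pd.DataFrame(
            rows, columns=["cnvr_id", "silhouette", "status", "carrier_g1", "carrier_g10", "rfd"]
        )
        passing = screen[screen["status"] == "pass"]
        if len(passing):
            selected_mask, cut = cnv.screen_cnvrs(passing["rfd"], config.cnv_tail)
            screen["selected"] = False
            screen.loc[passing.index, "selected"] = selected_mask.to_numpy()
            traj = cnv.cnv_frequency_trajectory(cn_values.loc[passing["cnvr_id"]], meta)
            traj.to_csv(outdir / "cnv_trajectories.tsv", sep="\t")
            r2_top = np.nan
            if pheno is not None and screen["selected"].any():
                sel = screen[screen["selected"]].sort_values("rfd", key=np.abs, ascending=False)
                top_id = sel.iloc[0]["cnvr_id"]
                cls_top = cnv.classify_copy_number(cn_values.loc[top_id].to_numpy())
                bmw = (
                    pheno.set_index("sample_id").loc[list(cn_values.columns), "BMW"].to_numpy()
                )
                r2_top = cnv.cnv_variance_explained(cls_top, bmw)
            report["stages"]["cnv"] = {
                "n_cnvr_input": int(len(screen)),
                "n_pass_filter": int(len(passing)),
                "rfd_cutoff": float(cut),
                "n_selected": int(screen["selected"].sum()),
                "top_cnvr_variance_explained": None if np.isnan(r2_top) else float(r2_top),
            }
        screen.to_csv(outdir / "cnv_screen.tsv", sep="\t", index=False)
    else:
        report["stages"]["cnv"] = {"skipped": True}

    report["regions"] = {
        "candidate": _region_list(regions),
        "overlapped": _region_list(overlapped),
        "refined": _region_list(refined),
    }
    make_report(report, outdir)
    return report


def make_report(report: dict, outdir) -> None:
    """Persist the run report as JSON + Markdown."""
    outdir = Path(outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    lines = ["# tempsweep run report", ""]
    for stage, info in report.get("stages", {}).items():
        lines.append(f"## {stage}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    for kind in ("candidate", "overlapped", "refined"):
        rs = report.get("regions", {}).get(kind, [])
        lines.append(f"## {kind} regions ({len(rs)})")
        for r in rs:
            lines.append(
                f"- {r['chrom']}:{r['start']}-{r['end']} ({r['span']} bp; {','.join(r['provenance'])})"
            )
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
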