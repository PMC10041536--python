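"""Replicated simulation experiments: drift calibration, joint-scan
parameter recovery, and CNV screen power.

These are the package's self-checks on its own study design: each runs the
breeding simulator under controlled conditions and measures how well the
downstream statistics recover what was put in. They are used both by the
test suite and by the acceptance script.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import cnv, io, mlm, scanstats, sim

__all__ = [
    "effective_size",
    "drift_calibration",
    "joint_scan_recovery",
    "cnv_selection_power",
    "cnv_variance_recovery",
]


def effective_size(config: sim.SimConfig) -> float:
    """Ne = 4 Nm Nf / (Nm + Nf) for the retained-parent scheme."""
    n_m = config.pop_size // 2
    n_f = config.pop_size - n_m
    nm = math.ceil(config.male_retention * n_m)
    nf = math.ceil(config.female_retention * n_f)
    return 4.0 * nm * nf / (nm + nf)


def drift_calibration(
    n_loci: int = 100,
    config: sim.SimConfig | None = None,
    seed: int = 0,
    freq_bounds: tuple[float, float] = (0.05, 0.95),
) -> dict:
    """Neutral per-generation frequency-change variance vs p(1-p)/(2Ne).

    Simulates ``n_loci`` unlinked neutral loci (one per chromosome, no
    causal effects, independent founders) through the default breeding
    scheme and pools Var(dp)/(p(1-p)) over all generation transitions whose
    starting frequency lies inside ``freq_bounds``. Returns the
    observed/expected variance ratio, where expected = 1/(2 Ne) with
    Ne = 4 Nm Nf/(Nm + Nf).
    """
    if config is None:
        config = sim.SimConfig()
    config = dataclasses.replace(
        config,
        n_chromosomes=n_loci,
        n_snps=n_loci,
        n_causal=0,
        founder_maf_law={"law": "uniform", "low": 0.2, "high": 0.8},
        seed=seed,
    )
    pops = sim.run_simulation(config)
    traj, _ = sim.export_truth(pops)
    freqs = traj.filter(like="gen").to_numpy()  # (loci, generations)
    p0 = freqs[:, :-1]
    dp = np.diff(freqs, axis=1)
    ok = (p0 >= freq_bounds[0]) & (p0 <= freq_bounds[1])
    scaled = dp[ok] ** 2 / (p0[ok] * (1 - p0[ok]))
    ne = effective_size(config)
    ratio = float(np.mean(scaled) * 2.0 * ne)
    return {
        "ne": ne,
        "n_transitions": int(ok.sum()),
        "observed_over_expected": ratio,
    }


def _window_percentiles(windows: list, values: np.ndarray) -> np.ndarray:
    """Percentile rank (0..1, 1 = most extreme) of each window value."""
    order = values.argsort()
    ranks = np.empty(len(values))
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks / len(values)


def joint_scan_recovery(
    n_replicates: int = 20,
    seed: int = 0,
    n_causal: int = 10,
    n_snps: int = 1000,
    n_chromosomes: int = 4,
    chrom_length_bp: int = 500_000,
    recomb_rate: float = 2e-6,
    scan_tail: float = 0.01,
    gwas_alpha: float = 0.01,
    near_bp: int = 25_000,
    **config_overrides,
) -> pd.DataFrame:
    """Replicated causal-locus recovery under the default breeding design.

    Per replicate: simulate with ``n_causal`` causal loci, sample the
    default cohorts, then (i) rank 10-kb joint Fst x |XP-EHH| windows by
    the smaller of the two percentile ranks and record the best joint
    percentile of windows containing causal loci, and (ii) run the
    EMMAX GWAS with sex + top-3 PCs and test whether any Bonferroni-
    significant SNP lies within ``near_bp`` of a causal locus inside a
    scan candidate region (the overlap-stage recovery event).
    """
    rows = []
    for rep in range(n_replicates):
        cfg = sim.SimConfig(
            n_causal=n_causal,
            n_snps=n_snps,
            n_chromosomes=n_chromosomes,
            chrom_length_bp=chrom_length_bp,
            recomb_rate=recomb_rate,
            seed=seed + 1000 * rep,
            **config_overrides,
        )
        pops = sim.run_simulation(cfg)
        gm, meta, pheno = sim.sample_cohorts(pops, cfg.sample_schedule)
        _, registry = sim.export_truth(pops)
        gmf = io.filter_variants(gm, "discovery").table
        chrom_lengths = {f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chromosomes)}

        gen_a, gen_b = cfg.sample_schedule[0][0], cfg.sample_schedule[-1][0]
        ids_a = list(meta.loc[meta["generation"] == gen_a, "sample_id"])
        ids_b = list(meta.loc[meta["generation"] == gen_b, "sample_id"])
        gm_a, gm_b = gmf.take_samples(ids_a), gmf.take_samples(ids_b)

        comp = scanstats.wc_fst_site(gm_a.dosage, gm_b.dosage)
        fst_w = scanstats.fst_windows(comp, gmf.chrom, gmf.pos, chrom_lengths=chrom_lengths)
        xp = scanstats.xpehh_scan(gm_a, gm_b)
        xp_w = scanstats.xpehh_windows(xp, chrom_lengths=chrom_lengths)

        # joint percentile per window present in both scans
        fkey = {(w.chrom, w.start): w.value for w in fst_w}
        xkey = {(w.chrom, w.start): abs(w.value) for w in xp_w}
        shared = sorted(set(fkey) & set(xkey))
        fvals = np.array([fkey[k] for k in shared])
        xvals = np.array([xkey[k] for k in shared])
        fpct = _window_percentiles(shared, fvals)
        xpct = _window_percentiles(shared, xvals)
        joint = np.minimum(fpct, xpct)

        causal_pct = []
        for _, row in registry.iterrows():
            hit = [
                joint[i]
                for i, (c, s) in enumerate(shared)
                if c == row["chrom"] and s <= row["pos"] - 1 < s + 10_000
            ]
            if hit:
                causal_pct.append(max(hit))
        median_causal_pct = float(np.median(causal_pct)) if causal_pct else np.nan

        # overlap stage: scan candidate regions + Bonferroni GWAS SNPs
        fst_cut = scanstats.empirical_threshold(fvals, scan_tail, "upper")
        xlo, xhi = scanstats.empirical_threshold(
            [w.value for w in xp_w], scan_tail, "both"
        )
        regions = scanstats.intersect_candidate_windows(
            [w for w in fst_w if w.value >= fst_cut],
            [w for w in xp_w if w.value >= xhi or w.value <= xlo],
        )
        coords, _, _ = scanstats.genotype_pca(gmf, 3)
        y = pheno.set_index("sample_id").loc[gmf.samples, "BMW"].to_numpy(float)
        sex = (meta.set_index("sample_id").loc[gmf.samples, "sex"] == "M").to_numpy(float)
        X = np.column_stack([np.ones(len(y)), sex, coords])
        K = mlm.kinship_matrix(gmf)
        assoc = mlm.emmax_scan(y, X, K, gmf)
        cutoff = mlm.bonferroni_threshold(int(np.isfinite(assoc["p"]).sum()), gwas_alpha)
        overlapped = mlm.overlap_assoc_with_regions(assoc, regions, cutoff)

        recovered = False
        for r in overlapped:
            near = registry[
                (registry["chrom"] == r.chrom)
                & (registry["pos"] - 1 >= r.start - near_bp)
                & (registry["pos"] - 1 < r.end + near_bp)
            ]
            if len(near):
                recovered = True
        rows.append(
            {
                "replicate": rep,
                "median_causal_joint_pct": median_causal_pct,
                "n_candidate_regions": len(regions),
                "n_bonferroni_snps": int((assoc["mlog10p"] >= cutoff).sum()),
                "n_overlapped_regions": len(overlapped),
                "recovered_causal_region": recovered,
            }
        )
    return pd.DataFrame(rows)


def cnv_selection_power(
    n_replicates: int = 20,
    seed: int = 0,
    n_cnvr: int = 80,
    shift: tuple[float, float] = (0.1, 0.7),
    tail: float = 0.05,
) -> float:
    """Fraction of replicates in which the frequency-shifted CNVR survives
    the top-|RFD| screen among neutral CNVRs."""
    schedule = sim.DEFAULT_SCHEDULE
    meta_rows = []
    for gen, n_m, n_f in schedule:
        for sex, n in (("M", n_m), ("F", n_f)):
            meta_rows += [(f"G{gen:02d}{sex}{k:02d}", gen, sex) for k in range(n)]
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "generation", "sex"])
    gen_a, gen_b = schedule[0][0], schedule[-1][0]
    ids_a = set(meta.loc[meta["generation"] == gen_a, "sample_id"])
    ids_b = set(meta.loc[meta["generation"] == gen_b, "sample_id"])
    hits = 0
    for rep in range(n_replicates):
        values, coords, truth = sim.simulate_cnv_matrix(
            meta, n_cnvr=n_cnvr, selected_shift=shift, seed=seed + rep
        )
        stats = []
        for cnvr_id, row in values.iterrows():
            cls = cnv.classify_copy_number(row.to_numpy())
            sa = cls[[c in ids_a for c in values.columns]]
            sb = cls[[c in ids_b for c in values.columns]]
            stats.append(
                cnv.rfd(cnv.carrier_frequency(sa), cnv.carrier_frequency(sb), len(sa), len(sb))
            )
        sel, _ = cnv.screen_cnvrs(pd.Series(stats, index=values.index), tail)
        target = truth.index[truth["selected"]][0]
        if sel.loc[target]:
            hits += 1
    return hits / n_replicates


def cnv_variance_recovery(
    n_replicates: int = 50,
    n: int = 500,
    target_r2: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Estimated R^2 of phenotype on CNV class when the truth is ``target_r2``.

    Copy-number classes are drawn for a deletion-type CNVR segregating at
    intermediate frequency; the phenotype adds a class effect sized to the
    target variance share plus unit-variance noise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        nvar = rng.binomial(2, 0.3, size=n)
        cls = 1.0 - 0.5 * nvar  # 1, 0.5, 0 classes
        var_c = np.var(cls)
        beta = math.sqrt(target_r2 / (var_c * (1 - target_r2)))
        y = beta * cls + rng.normal(0, 1, n)
        out.append(cnv.cnv_variance_explained(cls, y))
    return np.array(out)
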