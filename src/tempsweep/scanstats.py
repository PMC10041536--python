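"""Population-genetic scan statistics.

Implements the two-population Weir–Cockerham (1984) Fst estimator at site
and window level, extended haplotype homozygosity (EHH), iHH and
cross-population EHH (XP-EHH), windowed nucleotide diversity, genotype PCA
with Patterson normalisation, per-generation allele-frequency trajectories,
the dN/dS count proportion, empirical tail thresholds, and the intersection
of above-threshold Fst and XP-EHH windows into candidate regions.

Window convention: 10-kb windows advanced in 5-kb steps (defaults),
[start, start + window) half-open, clipped at chromosome ends.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Region, WindowStat, intersect_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "wc_fst_site",
    "fst_windows",
    "EhhCurve",
    "ehh",
    "xpehh",
    "xpehh_scan",
    "xpehh_windows",
    "empirical_threshold",
    "intersect_candidate_windows",
    "nucleotide_diversity",
    "genotype_pca",
    "frequency_trajectory",
    "dnds_proportion",
    "make_windows",
]


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst


def _cohort_site_summaries(dosage: np.ndarray):
    """(n, p, h) per site for one cohort's dosage block (missing = -1)."""
    miss = dosage == MISSING
    n = (~miss).sum(axis=0).astype(float)
    d = np.where(miss, 0, dosage).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=0) / (2.0 * n)
        h = ((dosage == 1) & ~miss).sum(axis=0) / n
    return n, p, h


def wc_fst_site(dosage_a: np.ndarray, dosage_b: np.ndarray) -> pd.DataFrame:
    """Per-site Weir–Cockerham (1984) variance components for two cohorts.

    Parameters are (n_samples, n_sites) dosage blocks. Returns a frame with
    columns ``a`` (between-population component), ``denom`` (a + b + c) and
    ``fst`` = a / (a + b + c); sites monomorphic across both cohorts get
    (0, 0) and NaN Fst with ``informative = False``.
    """
    n1, p1, h1 = _cohort_site_summaries(np.atleast_2d(dosage_a))
    n2, p2, h2 = _cohort_site_summaries(np.atleast_2d(dosage_b))
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("each cohort needs >= 1 non-missing genotype per site")
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = a / denom
    mono = (pbar <= 0) | (pbar >= 1)
    a = np.where(mono, 0.0, a)
    denom = np.where(mono, 0.0, denom)
    fst = np.where(mono | (denom == 0), np.nan, fst)
    return pd.DataFrame(
        {"a": a, "denom": denom, "fst": fst, "informative": ~(mono | (denom == 0))}
    )


def make_windows(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """[start, end) sliding windows covering [0, length)."""
    if step > window:
        raise ValueError("step larger than window leaves coverage gaps")
    if length <= window:
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    return [(s, min(s + window, length)) for s in starts]


def fst_windows(
    components: pd.DataFrame,
    chrom: np.ndarray,
    pos: np.ndarray,
    window: int = 10_000,
    step: int = 5_000,
    chrom_lengths: dict | None = None,
    mode: str = "ratio_of_sums",
) -> list[WindowStat]:
    """Windowed Fst from per-site WC84 components.

    ``ratio_of_sums`` (default): sum(a) / sum(a+b+c) over informative sites
    in the window; ``mean_of_sites`` averages per-site Fst. Windows with no
    informative site are omitted.
    """
    if mode not in ("ratio_of_sums", "mean_of_sites"):
        raise ValueError(f"unknown window mode {mode!r}")
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    out: list[WindowStat] = []
    for c in pd.unique(chrom):
        mask = chrom == c
        cpos = pos[mask]
        ca = components["a"].to_numpy()[mask]
        cd = components["denom"].to_numpy()[mask]
        cf = components["fst"].to_numpy()[mask]
        inf = components["informative"].to_numpy()[mask]
        length = int(chrom_lengths[c]) if chrom_lengths else int(cpos.max())
        for start, end in make_windows(length, window, step):
            in_w = (cpos - 1 >= start) & (cpos - 1 < end) & inf
            k = int(in_w.sum())
            if k == 0:
                continue
            if mode == "ratio_of_sums":
                denom = cd[in_w].sum()
                if denom == 0:
                    continue
                val = float(ca[in_w].sum() / denom)
            else:
                val = float(np.nanmean(cf[in_w]))
            out.append(WindowStat(str(c), start, end, "fst", val, k))
    return out


# ---------------------------------------------------------------------------
# EHH / XP-EHH


@dataclass
class EhhCurve:
    """EHH decay away from a core site (one side)."""

    core_index: int
    side: str  # 'upstream' (left) or 'downstream' (right)
    positions: np.ndarray  # bp, starting at the core
    ehh: np.ndarray  # values in [0, 1]; ehh[0] == 1 at the core


def _homozygosity(groups: np.ndarray) -> float:
    """sum_g C(e_g, 2) / C(n, 2) for group labels of n haplotypes."""
    n = len(groups)
    if n < 2:
        return 0.0
    _, counts = np.unique(groups, return_counts=True)
    num = float((counts * (counts - 1) // 2).sum())
    return num / (n * (n - 1) / 2)


def _ehh_one_side(hap: np.ndarray, pos: np.ndarray, carriers: np.ndarray, core: int, step: int, cutoff: float):
    """Walk outward from core; returns (positions, ehh) including the core."""
    idxs = [core]
    vals = [1.0]
    groups = np.zeros(len(carriers), dtype=np.int64)
    j = core + step
    m = hap.shape[1]
    while 0 <= j < m:
        alleles = hap[carriers, j]
        # refine partition: new group id from (old group, allele)
        groups = groups * 2 + alleles
        _, groups = np.unique(groups, return_inverse=True)
        v = _homozygosity(groups)
        idxs.append(j)
        vals.append(v)
        if v < cutoff:
            break
        j += step
    return pos[np.array(idxs)], np.array(vals)


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_site: int,
    core_allele: int | None = None,
    cutoff: float = 0.05,
) -> tuple[EhhCurve, EhhCurve]:
    """EHH decay curves on both sides of a core site.

    ``core_allele`` selects the carrier set (0/1); ``None`` pools all
    haplotypes (the combined-allele curve used by XP-EHH's iHH). The walk
    stops once EHH drops below ``cutoff`` or the chromosome ends.
    """
    hap = np.asarray(haplotypes)
    if hap.ndim != 2:
        raise ValueError("need a (n_haplotypes, n_sites) phased matrix")
    if core_allele is None:
        carriers = np.arange(hap.shape[0])
    else:
        carriers = np.flatnonzero(hap[:, core_site] == core_allele)
    if len(carriers) < 2:
        raise ValueError("need >= 2 carriers of the core allele")
    pos = np.asarray(positions)
    pl, vl = _ehh_one_side(hap, pos, carriers, core_site, -1, cutoff)
    pr, vr = _ehh_one_side(hap, pos, carriers, core_site, +1, cutoff)
    return (
        EhhCurve(core_site, "upstream", pl, vl),
        EhhCurve(core_site, "downstream", pr, vr),
    )


def _ihh_from_curves(up: EhhCurve, down: EhhCurve, cutoff: float) -> float:
    """Trapezoidal integral of the two-sided EHH curve over physical distance,
    truncated at the last point with EHH >= cutoff on each side."""
    total = 0.0
    for curve in (up, down):
        keep = curve.ehh >= cutoff
        # walk stops right after falling below cutoff; drop that last point
        k = int(np.flatnonzero(keep).max()) + 1 if keep.any() else 0
        if k >= 2:
            x = np.abs(curve.positions[:k] - curve.positions[0]).astype(float)
            total += float(np.trapezoid(curve.ehh[:k], x))
    return total


def xpehh(
    hap_ref: np.ndarray,
    hap_query: np.ndarray,
    positions: np.ndarray,
    core_site: int,
    cutoff: float = 0.05,
) -> float:
    """Unstandardised XP-EHH = ln(iHH_query / iHH_ref) at one core site.

    Both cohorts must be phased over the same site set. iHH integrates each
    cohort's combined-allele EHH curve (trapezoid over bp, both sides,
    truncated at ``cutoff``). Returns NaN when either iHH is zero.
    """
    up_r, dn_r = ehh(hap_ref, positions, core_site, None, cutoff)
    up_q, dn_q = ehh(hap_query, positions, core_site, None, cutoff)
    ihh_r = _ihh_from_curves(up_r, dn_r, cutoff)
    ihh_q = _ihh_from_curves(up_q, dn_q, cutoff)
    if ihh_r <= 0 or ihh_q <= 0:
        logger.debug("core %d skipped: iHH ref=%.3g query=%.3g", core_site, ihh_r, ihh_q)
        return np.nan
    return math.log(ihh_q / ihh_r)


def xpehh_scan(
    gm_ref: GenotypeMatrix,
    gm_query: GenotypeMatrix,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Genome-wide XP-EHH: unstandardised and genome-standardised values.

    The reference cohort is the earlier generation, the query the later one,
    so positive standardised values mark haplotype homozygosity gained in
    the later cohort. Refuses unphased input rather than pseudo-phasing.
    """
    for name, g in (("reference", gm_ref), ("query", gm_query)):
        if not g.is_phased:
            raise ValueError(f"{name} cohort is unphased; XP-EHH requires phased haplotypes")
    if not np.array_equal(gm_ref.pos, gm_query.pos):
        raise ValueError("cohorts must share one site set")
    raw = np.full(gm_ref.n_sites, np.nan)
    for c in pd.unique(gm_ref.chrom):
        idx = np.flatnonzero(gm_ref.chrom == c)
        hr = gm_ref.haplotypes[:, idx]
        hq = gm_query.haplotypes[:, idx]
        pos = gm_ref.pos[idx]
        pooled = np.concatenate([hr, hq])
        poly = (pooled.mean(axis=0) > 0) & (pooled.mean(axis=0) < 1)
        for k in np.flatnonzero(poly):
            raw[idx[k]] = xpehh(hr, hq, pos, int(k), cutoff)
    ok = np.isfinite(raw)
    mu = np.nanmean(raw[ok]) if ok.any() else np.nan
    sd = np.nanstd(raw[ok]) if ok.any() else np.nan
    std = (raw - mu) / sd if ok.any() and sd > 0 else np.full_like(raw, np.nan)
    return pd.DataFrame(
        {"chrom": gm_ref.chrom, "pos": gm_ref.pos, "xpehh_raw": raw, "xpehh_std": std}
    )


def xpehh_windows(
    scan: pd.DataFrame,
    window: int = 10_000,
    step: int = 5_000,
    chrom_lengths: dict | None = None,
) -> list[WindowStat]:
    """Window score = the site value of maximum |standardised XP-EHH|."""
    out: list[WindowStat] = []
    for c in pd.unique(scan["chrom"]):
        sub = scan[scan["chrom"] == c]
        pos = sub["pos"].to_numpy()
        val = sub["xpehh_std"].to_numpy()
        length = int(chrom_lengths[c]) if chrom_lengths else int(pos.max())
        for start, end in make_windows(length, window, step):
            in_w = (pos - 1 >= start) & (pos - 1 < end) & np.isfinite(val)
            k = int(in_w.sum())
            if k == 0:
                continue
            v = val[in_w]
            out.append(WindowStat(str(c), start, end, "xpehh", float(v[np.argmax(np.abs(v))]), k))
    return out


# ---------------------------------------------------------------------------
# Thresholds and regions


def empirical_threshold(values, tail_fraction: float = 0.01, side: str = "upper"):
    """Empirical tail cutoff(s) by linear-interpolation (type-7) quantile.

    ``side``: 'upper' -> (1 - f) quantile; 'lower' -> f quantile;
    'both' -> (lower, upper) tuple.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to threshold")
    if values.size < 100 / tail_fraction:
        warnings.warn(
            f"only {values.size} values for a {tail_fraction:.0%} tail; "
            "threshold will be noisy",
            stacklevel=2,
        )
    if side == "upper":
        return float(np.quantile(values, 1 - tail_fraction))
    if side == "lower":
        return float(np.quantile(values, tail_fraction))
    if side == "both":
        return (
            float(np.quantile(values, tail_fraction)),
            float(np.quantile(values, 1 - tail_fraction)),
        )
    raise ValueError(f"unknown side {side!r}")


def intersect_candidate_windows(
    fst_above: list[WindowStat], xpehh_above: list[WindowStat]
) -> list[Region]:
    """Merged genomic intersection of above-threshold Fst and XP-EHH windows."""
    fa = [(w.chrom, w.start, w.end) for w in fst_above]
    xa = [(w.chrom, w.start, w.end) for w in xpehh_above]
    inter = intersect_intervals(fa, xa)
    regions = []
    for chrom, start, end in inter:
        members = [
            w for w in list(fst_above) + list(xpehh_above)
            if w.chrom == chrom and w.start < end and w.end > start
        ]
        regions.append(
            Region(chrom, start, end, provenance=("fst", "xpehh"), member_windows=members)
        )
    return regions


# ---------------------------------------------------------------------------
# Diversity, PCA, trajectories, dN/dS


def nucleotide_diversity(
    gm: GenotypeMatrix,
    window: int = 10_000,
    step: int | None = None,
    chrom_lengths: dict | None = None,
) -> list[WindowStat]:
    """Windowed nucleotide diversity (pi): mean pairwise difference per bp.

    Uses haplotypes when present (n sequences), else allele counts from
    genotypes (2n alleles): per-site heterozygosity 2 c (n - c) / (n (n-1)),
    summed over window sites and divided by window length. Windows without
    sites get pi = 0 and n_snps = 0.
    """
    step = step or window
    if gm.haplotypes is not None:
        alt = gm.haplotypes.sum(axis=0).astype(float)
        n = float(gm.haplotypes.shape[0])
        nvec = np.full(gm.n_sites, n)
    else:
        miss = gm.dosage == MISSING
        nvec = 2.0 * (~miss).sum(axis=0)
        alt = np.where(miss, 0, gm.dosage).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = 2.0 * alt * (nvec - alt) / (nvec * (nvec - 1.0))
    per_site = np.where(nvec >= 2, per_site, np.nan)

    out: list[WindowStat] = []
    for c in pd.unique(gm.chrom):
        mask = gm.chrom == c
        pos = gm.pos[mask]
        ps = per_site[mask]
        length = int(chrom_lengths[c]) if chrom_lengths else int(pos.max())
        for start, end in make_windows(length, window, step):
            in_w = (pos - 1 >= start) & (pos - 1 < end) & np.isfinite(ps)
            k = int(in_w.sum())
            val = float(ps[in_w].sum() / (end - start)) if k else 0.0
            out.append(WindowStat(str(c), start, end, "pi", val, k))
    return out


def genotype_pca(gm: GenotypeMatrix, k: int = 3):
    """Patterson-normalised genotype PCA.

    Missing dosages are mean-imputed per site, sites are centred at 2p and
    scaled by sqrt(p(1-p)); monomorphic sites are dropped. Returns
    (coordinates (n, k), eigenvalues (k,), explained-variance fractions).
    """
    if gm.n_samples <= k:
        raise ValueError(f"need more than k={k} samples")
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    keep = (p > 0) & (p < 1) & np.isfinite(p)
    d = d[:, keep]
    p = p[keep]
    mu = 2.0 * p
    d = np.where(np.isnan(d), mu, d)
    z = (d - mu) / np.sqrt(p * (1 - p))
    z -= z.mean(axis=0)  # remove residual sample-mean offset
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    coords = u[:, :k] * s[:k]
    eigvals = s[:k] ** 2 / z.shape[1]
    explained = s[:k] ** 2 / (s**2).sum()
    return coords, eigvals, explained


def frequency_trajectory(
    gm: GenotypeMatrix, meta: pd.DataFrame, sites: np.ndarray | None = None
) -> pd.DataFrame:
    """ALT-allele frequency per site per sampled generation.

    Rows: sites (chrom, pos); columns ``gen<g>`` with frequencies over
    non-missing alleles, plus ``n_gen<g>`` non-missing allele counts.
    Generations with zero samples are simply absent (never reported as 0).
    """
    idx = np.arange(gm.n_sites) if sites is None else np.asarray(sites)
    sub = gm.take_sites(idx)
    out = {"chrom": sub.chrom, "pos": sub.pos}
    for g in sorted(meta["generation"].unique()):
        ids = list(meta.loc[meta["generation"] == g, "sample_id"])
        cg = sub.take_samples(ids)
        miss = cg.dosage == MISSING
        n_alleles = 2 * (~miss).sum(axis=0)
        alt = np.where(miss, 0, cg.dosage).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"gen{g}"] = np.where(n_alleles > 0, alt / n_alleles, np.nan)
        out[f"n_gen{g}"] = n_alleles
    return pd.DataFrame(out)


def dnds_proportion(effect_labels) -> tuple[float, dict]:
    """Count ratio of nonsynonymous to synonymous coding SNPs.

    Labels are 'nonsynonymous'/'synonymous' (or 'N'/'S'). Returns
    (ratio, counts); the ratio is NaN (flagged in counts) when S = 0.
    """
    labels = np.asarray(effect_labels, dtype=object)
    n = int(np.isin(labels, ("nonsynonymous", "N", "nonsyn")).sum())
    s = int(np.isin(labels, ("synonymous", "S", "syn")).sum())
    if n + s != len(labels):
        raise ValueError("labels must be nonsynonymous/synonymous (or N/S)")
    counts = {"N": n, "S": s, "undefined": s == 0}
    return (np.nan if s == 0 else n / s), counts
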