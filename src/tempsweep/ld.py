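"""Pairwise linkage disequilibrium (r^2), lead-SNP identification and
LD-based refinement of candidate regions.

Two r^2 estimators are provided: ``composite`` (squared Pearson correlation
of genotype dosages; the default, appropriate for unphased data) and
``haplotype_em`` (r^2 = D^2 / (pA pB (1-pA)(1-pB)) from haplotype
frequencies, counted directly on phased data or EM-estimated from unphased
two-locus genotype tables).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Region, merge_intervals

__all__ = [
    "r2_pair",
    "r2_from_haplotype_counts",
    "ld_table",
    "lead_snp",
    "refine_region",
    "region_span",
    "noncoding_fraction",
]


def r2_from_haplotype_counts(n_ab, n_aB, n_Ab, n_AB) -> float:
    """r^2 from two-locus haplotype counts (upper case = ALT)."""
    n = n_ab + n_aB + n_Ab + n_AB
    if n == 0:
        return np.nan
    p_a = (n_AB + n_Ab) / n  # ALT frequency at locus 1
    p_b = (n_AB + n_aB) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return np.nan
    d = n_AB / n - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def _em_r2(dos_a: np.ndarray, dos_b: np.ndarray, tol=1e-10, max_iter=200) -> float:
    """EM haplotype-frequency r^2 from unphased dosages (no missing)."""
    p_a = dos_a.mean() / 2.0
    p_b = dos_b.mean() / 2.0
    p_ab = p_a * p_b  # ALT-ALT haplotype frequency, start at equilibrium
    n = len(dos_a)
    dh = (dos_a == 1) & (dos_b == 1)  # double heterozygotes: phase-ambiguous
    n_dh = int(dh.sum())
    # unambiguous individuals contribute gA * gB / 2 ALT-ALT haplotypes
    base = float((dos_a[~dh] * dos_b[~dh]).sum()) / 2.0
    for _ in range(max_iter):
        # P(cis | double het) given current haplotype freqs
        p_Ab = p_a - p_ab
        p_aB = p_b - p_ab
        p_aabb = 1 - p_a - p_b + p_ab
        cis = p_ab * p_aabb
        trans = p_Ab * p_aB
        frac = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = (base + n_dh * frac) / (2 * n)
        if abs(new - p_ab) < tol:
            p_ab = new
            break
        p_ab = new
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    return float(d * d / denom) if denom > 0 else np.nan


def r2_pair(dos_a, dos_b, method: str = "composite", haplotypes=None) -> float:
    """r^2 between two SNPs.

    ``composite``: squared Pearson correlation of dosage vectors over
    samples non-missing at both SNPs. ``haplotype_em``: haplotype-frequency
    r^2; counted directly when a phased (2n, 2) haplotype pair is supplied
    via ``haplotypes``, else EM-estimated from the dosages. Monomorphic
    SNPs give NaN.
    """
    if method == "haplotype_em" and haplotypes is not None:
        h = np.asarray(haplotypes)
        n_AB = int(((h[:, 0] == 1) & (h[:, 1] == 1)).sum())
        n_Ab = int(((h[:, 0] == 1) & (h[:, 1] == 0)).sum())
        n_aB = int(((h[:, 0] == 0) & (h[:, 1] == 1)).sum())
        n_ab = int(((h[:, 0] == 0) & (h[:, 1] == 0)).sum())
        return r2_from_haplotype_counts(n_ab, n_aB, n_Ab, n_AB)
    a = np.asarray(dos_a, dtype=float)
    b = np.asarray(dos_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING) & np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    if method == "composite":
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    if method == "haplotype_em":
        return _em_r2(a.astype(int), b.astype(int))
    raise ValueError(f"unknown r2 method {method!r}")


def ld_table(
    gm: GenotypeMatrix, lead_index: int, method: str = "composite"
) -> pd.DataFrame:
    """r^2 of every site against one lead SNP (same chromosome)."""
    lead_chrom = gm.chrom[lead_index]
    idx = np.flatnonzero(gm.chrom == lead_chrom)
    rows = []
    for j in idx:
        hap = None
        if method == "haplotype_em" and gm.haplotypes is not None:
            hap = gm.haplotypes[:, [lead_index, j]]
        r2 = r2_pair(gm.dosage[:, lead_index], gm.dosage[:, j], method, haplotypes=hap)
        rows.append((str(lead_chrom), int(gm.pos[lead_index]), int(gm.pos[j]), r2))
    return pd.DataFrame(rows, columns=["chrom", "pos_lead", "pos", "r2"])


def lead_snp(region: Region, chrom: np.ndarray, pos: np.ndarray, scores: np.ndarray) -> int:
    """Index of the extreme-|score| SNP inside the region; position ties go
    to the smaller coordinate."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    scores = np.asarray(scores, dtype=float)
    inside = np.flatnonzero(
        (chrom == region.chrom) & (pos - 1 >= region.start) & (pos - 1 < region.end)
        & np.isfinite(scores)
    )
    if len(inside) == 0:
        raise ValueError(f"no scored SNP inside region {region.chrom}:{region.start}-{region.end}")
    vals = np.abs(scores[inside])
    best = vals.max()
    cands = inside[vals == best]
    return int(cands[np.argmin(pos[cands])])


def refine_region(
    region: Region,
    lead_index: int,
    gm: GenotypeMatrix,
    r2_threshold: float = 0.4,
    method: str = "composite",
) -> Region:
    """Shrink a region to the [min, max] envelope of SNPs in LD with the lead.

    Keeps SNPs inside the region with r^2(snp, lead) > threshold; the lead
    always qualifies. With no other qualifying SNP the result degenerates to
    the lead position (flagged via provenance).
    """
    if not region.contains(str(gm.chrom[lead_index]), int(gm.pos[lead_index]) - 1):
        raise ValueError("lead SNP lies outside the region")
    inside = np.flatnonzero(
        (gm.chrom == region.chrom)
        & (gm.pos - 1 >= region.start)
        & (gm.pos - 1 < region.end)
    )
    qual = [lead_index]
    for j in inside:
        if j == lead_index:
            continue
        hap = None
        if method == "haplotype_em" and gm.haplotypes is not None:
            hap = gm.haplotypes[:, [lead_index, j]]
        r2 = r2_pair(gm.dosage[:, lead_index], gm.dosage[:, j], method, haplotypes=hap)
        if np.isfinite(r2) and r2 > r2_threshold:
            qual.append(int(j))
    qpos0 = gm.pos[np.array(qual)] - 1
    prov = tuple(region.provenance) + (
        ("ld_refined",) if len(qual) > 1 else ("ld_refined", "degenerate")
    )
    return Region(
        region.chrom,
        int(qpos0.min()),
        int(qpos0.max()) + 1,
        provenance=prov,
        snps=[int(p) for p in sorted(gm.pos[np.array(qual)])],
    )


def region_span(regions: list[Region] | list[tuple]) -> int:
    """Total bp covered by a set of regions (merged first if overlapping)."""
    ivs = [
        (r.chrom, r.start, r.end) if isinstance(r, Region) else tuple(r) for r in regions
    ]
    merged = merge_intervals(ivs)
    if len(merged) != len(ivs):
        warnings.warn("overlapping regions merged before span accounting", stacklevel=2)
    return int(sum(e - s for _, s, e in merged))


def noncoding_fraction(categories) -> tuple[int, int, float]:
    """(noncoding count, total, percent) where noncoding = everything except
    'exon' (UTRs count as noncoding, matching a regulatory reading)."""
    cats = np.asarray(categories, dtype=object)
    total = len(cats)
    if total == 0:
        raise ValueError("no sites to classify")
    nonc = int((cats != "exon").sum())
    return nonc, total, 100.0 * nonc / total
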