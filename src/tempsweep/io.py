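"""Readers and writers for VCF, BED annotation, metadata/phenotype tables,
plus the resequencing-style variant filters.

VCF handling uses :mod:`cyvcf2` for parsing; writing emits minimal VCF v4.2
text (SNP records with GT and optional per-site DP) which cyvcf2/bcftools
read back unchanged. Coordinates are converted at this boundary only:
VCF positions are 1-based, BED intervals 0-based half-open.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, AnnotationTrack, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation_bed",
    "write_annotation_bed",
    "filter_variants",
    "FilterReport",
    "intersect_with_annotation",
]


def _opener(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_vcf(path, strict_biallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    ``./.`` genotypes become missing (-1), never zero. Phase is preserved:
    if every non-missing genotype on every record is phased, the haplotype
    matrix is populated. Multi-allelic records raise under
    ``strict_biallelic`` (default) and are skipped otherwise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, depths = [], [], [], [], []
    dosage_rows, hap_rows = [], []
    any_depth = False
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            if strict_biallelic:
                raise ValueError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                    f"(ALT={','.join(rec.ALT)}); split or filter first"
                )
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        dos = np.empty(len(samples), dtype=np.int8)
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                dos[i] = MISSING
                hap[2 * i] = hap[2 * i + 1] = 0
            else:
                dos[i] = a0 + a1
                hap[2 * i], hap[2 * i + 1] = a0, a1
                if not g[2]:
                    all_phased = False
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        dosage_rows.append(dos)
        hap_rows.append(hap)
        dp = rec.INFO.get("DP")
        if dp is not None:
            any_depth = True
            depths.append(float(dp) / max(len(samples), 1))
        else:
            depths.append(np.nan)
    n_sites = len(poss)
    dosage = (
        np.stack(dosage_rows, axis=1) if n_sites else np.zeros((len(samples), 0), np.int8)
    )
    haplotypes = None
    if all_phased and n_sites:
        haplotypes = np.stack(hap_rows, axis=1)
        # haplotypes at missing genotypes are meaningless; keep consistency check happy
        haplotypes[np.repeat(dosage == MISSING, 2, axis=0)] = 0
    mean_depth = np.array(depths) if any_depth else None
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
        samples=samples,
        haplotypes=haplotypes,
        mean_depth=mean_depth,
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write VCF v4.2; phased ``0|1`` genotypes when haplotypes are present."""
    with _opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.chrom):
            cmax = int(gm.pos[gm.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={cmax}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        phased = gm.haplotypes is not None
        for j in range(gm.n_sites):
            info = "."
            if gm.mean_depth is not None and np.isfinite(gm.mean_depth[j]):
                info = f"DP={int(round(gm.mean_depth[j] * gm.n_samples))}"
            cols = [
                str(gm.chrom[j]),
                str(int(gm.pos[j])),
                ".",
                str(gm.ref[j]),
                str(gm.alt[j]),
                ".",
                "PASS",
                info,
                "GT",
            ]
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                if d == MISSING:
                    cols.append("./.")
                elif phased:
                    cols.append(f"{gm.haplotypes[2 * i, j]}|{gm.haplotypes[2 * i + 1, j]}")
                else:
                    cols.append("0/1" if d == 1 else ("1/1" if d == 2 else "0/0"))
            fh.write("\t".join(cols) + "\n")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "generation", "sex"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_annotation_bed(path) -> AnnotationTrack:
    """Read BED3+1 (category in column 4) into an AnnotationTrack."""
    ivs = []
    with _opener(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: need 4 columns (chrom start end category)")
            ivs.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return AnnotationTrack(ivs)


def write_annotation_bed(track: AnnotationTrack, path) -> None:
    with _opener(path, "wt") as fh:
        for chrom, start, end, cat in track.to_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{cat}\n")


@dataclass
class FilterReport:
    """Survivors plus per-criterion rejection counts.

    A site failing several criteria is counted under each one, so counts can
    sum to more than the number of rejected sites.
    """

    table: GenotypeMatrix
    n_input: int
    n_kept: int
    rejections: dict


# profile -> (depth_lo, depth_hi, depth_strict, maf_min, maxaf_max, miss_max, miss_strict)
_PROFILES = {
    # resequencing discovery set: 3x < depth < 30x, MAF > 0.05, max AF < 0.99,
    # missing rate < 0.1
    "discovery": dict(depth=(3.0, 30.0, True), maf=0.05, maxaf=0.99, miss=(0.1, True)),
    # allele-frequency-difference set: 5 <= depth <= 30, MAF > 0.01,
    # missing rate <= 0.1 (vcftools --max-missing 0.9)
    "afd": dict(depth=(5.0, 30.0, False), maf=0.01, maxaf=None, miss=(0.1, False)),
}


def filter_variants(gm: GenotypeMatrix, profile: str = "discovery") -> FilterReport:
    """Apply one of the two variant-retention profiles.

    All allele-frequency quantities use non-missing alleles only, and every
    boundary is strict or inclusive exactly as documented in ``_PROFILES``.
    Depth criteria are skipped (with a warning) when the table carries no
    depth annotation, as is the case for simulated genotypes.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown filter profile {profile!r}; use 'discovery' or 'afd'")
    cfg = _PROFILES[profile]
    n = gm.n_sites
    keep = np.ones(n, dtype=bool)
    rejections: dict[str, int] = {}

    miss_rate = np.mean(gm.dosage == MISSING, axis=0) if gm.n_samples else np.zeros(n)
    af = gm.alt_freq()
    af = np.where(np.isnan(af), 0.0, af)
    maf = np.minimum(af, 1 - af)
    maxaf = np.maximum(af, 1 - af)

    lo, hi, strict = cfg["depth"]
    if gm.mean_depth is None:
        if n:
            warnings.warn(
                f"no depth annotation in input; '{profile}' depth filter skipped",
                stacklevel=2,
            )
        rejections["depth"] = 0
    else:
        d = gm.mean_depth
        ok = (d > lo) & (d < hi) if strict else (d >= lo) & (d <= hi)
        ok &= np.isfinite(d)
        rejections["depth"] = int((~ok).sum())
        keep &= ok

    ok = maf > cfg["maf"]
    rejections["maf"] = int((~ok).sum())
    keep &= ok

    if cfg["maxaf"] is not None:
        ok = maxaf < cfg["maxaf"]
        rejections["maxaf"] = int((~ok).sum())
        keep &= ok

    mlim, mstrict = cfg["miss"]
    ok = miss_rate < mlim if mstrict else miss_rate <= mlim
    rejections["missing"] = int((~ok).sum())
    keep &= ok

    out = gm.take_sites(np.flatnonzero(keep))
    return FilterReport(table=out, n_input=n, n_kept=out.n_sites, rejections=rejections)


def intersect_with_annotation(gm: GenotypeMatrix, track: AnnotationTrack) -> np.ndarray:
    """Assign exactly one annotation category per site (else 'intergenic')."""
    return track.category_at(gm.chrom, gm.pos)
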