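"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genotype dosages count ALT-allele copies: 0, 1, 2; missing is ``-1``.
* Haplotype matrices are ``(2 * n_samples, n_sites)`` int8 arrays of
  ALT-allele indicators; haplotypes ``2i`` and ``2i + 1`` belong to
  sample ``i``.
* Internal coordinates are 0-based half-open; VCF (1-based) and BED
  (0-based half-open) conversions happen only at the I/O boundary.
* Sample metadata is a :class:`pandas.DataFrame` with columns
  ``sample_id``, ``generation``, ``sex`` (``M``/``F``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AnnotationTrack",
    "WindowStat",
    "Region",
    "merge_intervals",
    "intersect_intervals",
]


@dataclass
class GenotypeMatrix:
    """Diploid genotypes (and optionally phased haplotypes) at biallelic SNPs.

    Attributes
    ----------
    chrom : array of str, per site
    pos : array of int, 1-based bp positions, strictly increasing per chrom
    ref, alt : arrays of single-base allele strings
    dosage : (n_samples, n_sites) int8, ALT-allele copies, -1 = missing
    samples : list of sample ids (column order of ``dosage`` rows)
    haplotypes : optional (2 * n_samples, n_sites) int8 of ALT indicators
    mean_depth : optional per-site mean sequencing depth
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    haplotypes: np.ndarray | None = None
    mean_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * len(self.samples), len(self.pos)):
                raise ValueError("haplotype matrix shape mismatch")
            derived = self.haplotypes[0::2] + self.haplotypes[1::2]
            obs = self.dosage
            ok = (obs == MISSING) | (derived == obs)
            if not np.all(ok):
                raise ValueError("dosage is not the sum of the two haplotypes")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            samples=list(self.samples),
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            mean_depth=None if self.mean_depth is None else self.mean_depth[idx],
        )

    def take_samples(self, which: list[str] | np.ndarray) -> "GenotypeMatrix":
        if np.asarray(which).dtype.kind in "US O":
            order = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([order[s] for s in which], dtype=int)
        else:
            idx = np.asarray(which, dtype=int)
        hap = None
        if self.haplotypes is not None:
            hidx = np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))
            hap = self.haplotypes[hidx]
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx],
            samples=[self.samples[i] for i in idx],
            haplotypes=hap,
            mean_depth=self.mean_depth,
        )

    def alt_freq(self) -> np.ndarray:
        """Per-site ALT-allele frequency over non-missing genotypes (NaN if all missing)."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def ref_freq(self) -> np.ndarray:
        return 1.0 - self.alt_freq()


class AnnotationTrack:
    """Non-overlapping categorised genomic intervals (exon / UTR / intron / ...).

    Stored 0-based half-open. Intervals of the same category that overlap or
    touch are merged on construction; overlapping intervals of *different*
    categories raise, because every site must map to exactly one category.
    """

    CATEGORIES = ("exon", "UTR", "intron", "intergenic")

    def __init__(self, intervals: list[tuple[str, int, int, str]]):
        for chrom, start, end, cat in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, cat in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), cat))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cats: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            merged: list[tuple[int, int, str]] = []
            for start, end, cat in sorted(ivs):
                if merged and start <= merged[-1][1]:
                    pstart, pend, pcat = merged[-1]
                    if cat != pcat and start < pend:
                        raise ValueError(
                            f"ambiguous annotation: {chrom}:{start}-{end} ({cat}) "
                            f"overlaps {chrom}:{pstart}-{pend} ({pcat})"
                        )
                    if cat == pcat:
                        merged[-1] = (pstart, max(pend, end), pcat)
                        continue
                merged.append((start, end, cat))
            self._starts[chrom] = np.array([m[0] for m in merged])
            self._ends[chrom] = np.array([m[1] for m in merged])
            self._cats[chrom] = np.array([m[2] for m in merged], dtype=object)

    def to_intervals(self) -> list[tuple[str, int, int, str]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e, c in zip(self._starts[chrom], self._ends[chrom], self._cats[chrom]):
                out.append((chrom, int(s), int(e), str(c)))
        return out

    def category_at(self, chrom: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Category per site; sites outside every interval are ``intergenic``.

        A 1-based position p falls in [start, end) iff start <= p-1 < end.
        """
        chrom = np.asarray(chrom, dtype=object)
        p0 = np.asarray(pos_1based, dtype=np.int64) - 1
        out = np.full(len(p0), "intergenic", dtype=object)
        for c in np.unique(chrom):
            mask = chrom == c
            if c not in self._starts:
                continue
            starts, ends, cats = self._starts[c], self._ends[c], self._cats[c]
            idx = np.searchsorted(starts, p0[mask], side="right") - 1
            inside = (idx >= 0) & (p0[mask] < ends[np.clip(idx, 0, None)])
            vals = out[mask]
            vals[inside] = cats[idx[inside]]
            out[mask] = vals
        return out


@dataclass
class WindowStat:
    """One sliding-window statistic value."""

    chrom: str
    start: int
    end: int
    stat: str
    value: float
    n_snps: int


@dataclass
class Region:
    """A merged above-threshold genomic interval with provenance."""

    chrom: str
    start: int
    end: int
    provenance: tuple[str, ...] = ()
    member_windows: list = field(default_factory=list)
    snps: list = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


def merge_intervals(
    intervals: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Merge overlapping or book-ended (chrom, start, end) intervals."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def intersect_intervals(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Genomic intersection of two merged interval lists."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[str, int, int]] = []
    for chrom in sorted({x[0] for x in a} & {x[0] for x in b}):
        ai = [x for x in a if x[0] == chrom]
        bi = [x for x in b if x[0] == chrom]
        i = j = 0
        while i < len(ai) and j < len(bi):
            lo = max(ai[i][1], bi[j][1])
            hi = min(ai[i][2], bi[j][2])
            if lo < hi:
                out.append((chrom, lo, hi))
            if ai[i][2] < bi[j][2]:
                i += 1
            else:
                j += 1
    return merge_intervals(out)
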