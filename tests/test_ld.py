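import numpy as np
import pytest

from tempsweep import ld
from tempsweep.containers import GenotypeMatrix, Region
from oracles import r2_dosage_oracle, r2_haplotype_oracle


class TestR2:
    def test_identical_dosages_give_one(self):
        d = np.array([0, 1, 2, 1, 0, 2])
        assert ld.r2_pair(d, d) == pytest.approx(1.0)

    def test_equilibrium_haplotypes_give_zero(self):
        # freqs 0.25 each of AB, Ab, aB, ab -> D = 0
        haps = np.array([[1, 1], [1, 0], [0, 1], [0, 0]] * 5)
        assert ld.r2_pair(None, None, "haplotype_em", haplotypes=haps) == pytest.approx(0.0)

    def test_worked_haplotype_example(self):
        # AB=40, Ab=10, aB=10, ab=40 -> D = 0.15, r2 = 0.36
        haps = np.array([[1, 1]] * 40 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 40)
        r2 = ld.r2_pair(None, None, "haplotype_em", haplotypes=haps)
        assert r2 == pytest.approx(0.36)
        assert r2 == pytest.approx(r2_haplotype_oracle(haps.tolist()))

    def test_composite_matches_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.integers(0, 3, 30).astype(float)
            b = rng.integers(0, 3, 30).astype(float)
            if a.std() == 0 or b.std() == 0:
                continue
            assert ld.r2_pair(a, b) == pytest.approx(
                r2_dosage_oracle(a.tolist(), b.tolist()), abs=1e-10
            )

    def test_em_agrees_with_phased_counting_at_exact_hwe(self):
        # deterministic exact-HWE construction: haplotype freqs in tenths
        # (AB, Ab, aB, ab) = (4, 1, 2, 3)/10; 100 individuals with pair
        # counts equal to the exact outer product
        alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        counts = [4, 1, 2, 3]
        h1_rows, h2_rows = [], []
        for i, ci in enumerate(counts):
            for j, cj in enumerate(counts):
                for _ in range(ci * cj):
                    h1_rows.append(alleles[i])
                    h2_rows.append(alleles[j])
        h1, h2 = np.array(h1_rows), np.array(h2_rows)
        dos_a, dos_b = h1[:, 0] + h2[:, 0], h1[:, 1] + h2[:, 1]
        haps = np.vstack([h1, h2])
        direct = ld.r2_pair(None, None, "haplotype_em", haplotypes=haps)
        em = ld.r2_pair(dos_a, dos_b, "haplotype_em")
        assert em == pytest.approx(direct, abs=1e-6)

    def test_monomorphic_undefined(self):
        assert np.isnan(ld.r2_pair(np.zeros(10), np.arange(10) % 3))


class TestLeadSnp:
    chrom = np.array(["chr1"] * 3, dtype=object)
    pos = np.array([100, 200, 300])

    def test_argmax_and_single(self):
        r = Region("chr1", 0, 1000)
        assert ld.lead_snp(r, self.chrom, self.pos, np.array([3.0, 9.0, 7.0])) == 1
        assert ld.lead_snp(Region("chr1", 150, 250), self.chrom, self.pos, np.array([3, 9, 7.0])) == 1

    def test_tie_goes_to_lower_position(self):
        r = Region("chr1", 0, 1000)
        assert ld.lead_snp(r, self.chrom, self.pos, np.array([5.0, 2.0, 5.0])) == 0

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="no scored SNP"):
            ld.lead_snp(Region("chr2", 0, 10), self.chrom, self.pos, np.array([1.0, 1, 1]))


def _ld_gm(dosage_cols, pos):
    dosage = np.array(dosage_cols, dtype=np.int8).T
    n = dosage.shape[0]
    return GenotypeMatrix(
        chrom=np.array(["chr1"] * len(pos), dtype=object),
        pos=np.array(pos),
        ref=np.array(["A"] * len(pos), dtype=object),
        alt=np.array(["G"] * len(pos), dtype=object),
        dosage=dosage,
        samples=[f"s{i}" for i in range(n)],
    )


class TestRefine:
    def _gm(self):
        rng = np.random.default_rng(2)
        lead = rng.integers(0, 3, 40)
        cols = [lead.copy()]  # site 0: the lead itself at pos 101
        cols.append(lead.copy())  # perfect LD at pos 251
        cols.append(rng.integers(0, 3, 40))  # unlinked at pos 601
        cols.append(lead.copy())  # perfect LD at pos 901
        return _ld_gm(cols, [101, 251, 601, 901])

    def test_envelope_of_qualifying_snps(self):
        gm = self._gm()
        region = Region("chr1", 0, 1000)
        out = ld.refine_region(region, 0, gm, r2_threshold=0.4)
        assert (out.start, out.end) == (100, 901)
        assert out.snps == [101, 251, 901]

    def test_no_qualifiers_degenerates_to_lead(self):
        gm = self._gm()
        out = ld.refine_region(Region("chr1", 0, 1000), 2, gm, r2_threshold=0.99)
        assert (out.start, out.end) == (600, 601)
        assert "degenerate" in out.provenance

    def test_monotone_in_threshold_and_contained(self):
        gm = self._gm()
        region = Region("chr1", 0, 1000)
        spans = []
        for thr in (0.1, 0.5, 0.9):
            out = ld.refine_region(region, 0, gm, thr)
            assert out.start >= region.start and out.end <= region.end
            spans.append(out.span)
        assert spans == sorted(spans, reverse=True)

    def test_lead_outside_region_raises(self):
        with pytest.raises(ValueError, match="outside"):
            ld.refine_region(Region("chr1", 0, 50), 2, self._gm())


class TestSpans:
    def test_printed_region_spans(self):
        combined = [("chr3", 180_000, 440_000), ("chr16", 3_400_000, 3_500_000)]
        assert ld.region_span(combined) == 360_000  # 0.36 Mb
        refined = [("chr3", 340_000, 430_000), ("chr16", 3_460_000, 3_490_000)]
        assert ld.region_span(refined) == 120_000  # 120 kb

    def test_empty_and_overlap_warning(self):
        assert ld.region_span([]) == 0
        with pytest.warns(UserWarning, match="merged"):
            span = ld.region_span([("chr1", 0, 100), ("chr1", 50, 150)])
        assert span == 150


class TestNoncoding:
    def test_printed_counts(self):
        cats = np.array(["exon"] * 127 + ["intron"] * 1000 + ["UTR"] * 500 + ["intergenic"] * 445)
        n, total, pct = ld.noncoding_fraction(cats)
        assert (n, total) == (1945, 2072)
        assert round(pct, 2) == 93.87

    def test_all_exonic_and_toy(self):
        assert ld.noncoding_fraction(["exon"] * 5)[2] == 0.0
        assert ld.noncoding_fraction(["exon"] * 4 + ["intron"] * 6)[2] == pytest.approx(60.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ld.noncoding_fraction([])
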