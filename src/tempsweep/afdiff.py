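"""Temporal allele-frequency differences between cohorts, 0.05-width
binning, and annotation-category enrichment (M-values and chi-square tests).

The per-SNP statistic is dAF = |RefAF_B - RefAF_A|, the absolute change in
*reference*-allele frequency between two cohorts (typically the first and
last sampled generations). SNPs are binned in steps of 0.05 and each
(bin, category) cell is scored with a log2 fold change
M = log2((n_bin_cat / n_bin) / (n_cat / n_total)) and a 2x2 chi-square
test of bin membership against category membership.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

__all__ = [
    "cohort_ref_freq",
    "delta_af",
    "bin_delta_af",
    "category_enrichment",
    "N_BINS_DEFAULT",
]

N_BINS_DEFAULT = 20


def cohort_ref_freq(gm: GenotypeMatrix, meta: pd.DataFrame, generation: int) -> np.ndarray:
    """Reference-allele frequency per site within one generation's cohort,
    computed over non-missing alleles only."""
    ids = meta.loc[meta["generation"] == generation, "sample_id"]
    if ids.empty:
        raise ValueError(f"no samples with generation == {generation}")
    sub = gm.take_samples(list(ids))
    return sub.ref_freq()


def delta_af(freq_a: np.ndarray, freq_b: np.ndarray, fold: bool = False) -> pd.DataFrame:
    """Per-site |RefAF_B - RefAF_A|.

    Both inputs must be frequencies of the *same* (reference) allele at the
    same ordered site set. ``fold=True`` instead differences minor-allele
    frequencies (optional convention).
    """
    freq_a = np.asarray(freq_a, dtype=float)
    freq_b = np.asarray(freq_b, dtype=float)
    if freq_a.shape != freq_b.shape:
        raise ValueError(
            f"site sets differ: {freq_a.shape} vs {freq_b.shape}; align cohorts first"
        )
    for name, f in (("A", freq_a), ("B", freq_b)):
        bad = (f < 0) | (f > 1)
        if np.any(bad & ~np.isnan(f)):
            raise ValueError(f"cohort {name} frequencies outside [0, 1]")
    fa, fb = (np.minimum(freq_a, 1 - freq_a), np.minimum(freq_b, 1 - freq_b)) if fold else (freq_a, freq_b)
    return pd.DataFrame(
        {"ref_af_a": freq_a, "ref_af_b": freq_b, "delta_af": np.abs(fb - fa)}
    )


def bin_delta_af(delta: np.ndarray, width: float = 0.05) -> np.ndarray:
    """1-based bin index per site; bins [0,w), [w,2w), ..., last bin closed.

    dAF = 0.00 -> bin 1; dAF = 0.05 -> bin 2; dAF = 1.00 -> bin 20.
    """
    if not 0 < width <= 1:
        raise ValueError("bin width must lie in (0, 1]")
    n_bins = round(1.0 / width)
    if abs(n_bins * width - 1.0) > 1e-9:
        raise ValueError("bin width must divide 1 evenly")
    delta = np.asarray(delta, dtype=float)
    if np.any((delta < 0) | (delta > 1)):
        raise ValueError("delta AF values must lie in [0, 1]")
    # guard against float fuzz at exact multiples of width
    idx = np.floor(delta / width + 1e-9).astype(int) + 1
    return np.minimum(idx, n_bins)


def category_enrichment(
    bins: np.ndarray,
    categories: np.ndarray,
    n_bins: int = N_BINS_DEFAULT,
    yates: bool = False,
    exclude_categories: tuple = (),
) -> pd.DataFrame:
    """M-value and chi-square p per (bin, category).

    The 2x2 table for cell (b, c) is {site in bin b?} x {site in category c?}
    over all sites. Chi-square is computed without continuity correction by
    default; Fisher's exact test replaces it when any expected count is
    below 5. Cells in empty bins get M = NaN (undefined, not zero).
    """
    bins = np.asarray(bins)
    categories = np.asarray(categories, dtype=object)
    if bins.shape != categories.shape:
        raise ValueError("bins and categories must align per site")
    keep = ~np.isin(categories, list(exclude_categories))
    bins, categories = bins[keep], categories[keep]
    n_total = len(bins)
    rows = []
    for cat in sorted(set(map(str, categories))):
        in_cat = categories == cat
        n_cat = int(in_cat.sum())
        for b in range(1, n_bins + 1):
            in_bin = bins == b
            n_bin = int(in_bin.sum())
            n_bc = int((in_bin & in_cat).sum())
            if n_bin == 0 or n_cat == 0 or n_bc == 0:
                m = np.nan
            else:
                m = float(np.log2((n_bc / n_bin) / (n_cat / n_total)))
            p = np.nan
            if n_bin and n_cat and n_total > n_bin and n_total > n_cat:
                tab = np.array(
                    [
                        [n_bc, n_bin - n_bc],
                        [n_cat - n_bc, n_total - n_bin - n_cat + n_bc],
                    ]
                )
                expected = stats.contingency.expected_freq(tab)
                if (expected < 5).any():
                    p = float(stats.fisher_exact(tab)[1])
                else:
                    p = float(stats.chi2_contingency(tab, correction=yates)[1])
            rows.append((b, cat, n_bin, n_cat, n_bc, m, p))
    return pd.DataFrame(
        rows, columns=["bin", "category", "n_bin", "n_cat", "n_bin_cat", "M", "p"]
    )
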