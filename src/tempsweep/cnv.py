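"""Copy-number-variation frequency screen between cohorts.

Normalized per-sample copy numbers are discretised to half-integer classes
(0 homozygous deletion, 0.5 heterozygous loss, 1 normal diploid,
1.5 heterozygous duplication, 2 homozygous duplication, >2 complex
multicopy). CNVRs are quality-filtered by 1-D silhouette (>0.7) and
minor-state frequency (>0.05); between-cohort change is scored by the
relative frequency difference (RFD) of carrier frequency and screened at
the empirical top-|RFD| quantile (default 5%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MULTICOPY",
    "classify_copy_number",
    "class_frequencies",
    "carrier_frequency",
    "silhouette_filter",
    "rfd",
    "screen_cnvrs",
    "cnv_variance_explained",
    "cnv_frequency_trajectory",
]

#: numeric stand-in for the ">2" complex multicopy class
MULTICOPY = 2.5


def classify_copy_number(values) -> np.ndarray:
    """Round normalized copy numbers to the nearest half-integer class.

    Midpoints round half-up (0.25 -> 0.5). Everything above 2.25 collapses
    into the multicopy class, encoded as :data:`MULTICOPY` (2.5). Negative
    input is a data error.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("copy-number values must be finite and >= 0")
    cls = np.floor(2.0 * v + 0.5) / 2.0
    return np.where(cls > 2.0, MULTICOPY, cls)


def class_frequencies(classes: np.ndarray) -> dict[float, float]:
    """Frequency of each copy-number class (sums to 1)."""
    cls = np.asarray(classes, dtype=float)
    if cls.size == 0:
        raise ValueError("no samples")
    uniq, counts = np.unique(cls, return_counts=True)
    return {float(u): float(c) / cls.size for u, c in zip(uniq, counts)}


def carrier_frequency(classes: np.ndarray) -> float:
    """Fraction of samples whose class deviates from normal diploid (1)."""
    cls = np.asarray(classes, dtype=float)
    return float((cls != 1.0).mean())


def silhouette_filter(
    values: np.ndarray, min_sil: float = 0.7, min_maf: float = 0.05
) -> tuple[bool, float, str]:
    """Quality filter for one CNVR: (keep, silhouette, reason).

    Silhouette is computed on the 1-D normalized values with the
    half-integer classes as clusters; the minor-state frequency is
    1 - (frequency of the most common class). A CNVR passes iff
    silhouette > ``min_sil`` and minor-state frequency > ``min_maf``.
    """
    from sklearn.metrics import silhouette_score

    v = np.asarray(values, dtype=float)
    cls = classify_copy_number(v)
    freqs = class_frequencies(cls)
    if len(freqs) < 2:
        return False, np.nan, "monomorphic"
    minor = 1.0 - max(freqs.values())
    if minor <= min_maf:
        return False, np.nan, "maf"
    sil = float(silhouette_score(v.reshape(-1, 1), cls.astype(str)))
    if sil <= min_sil:
        return False, sil, "silhouette"
    return True, sil, "pass"


def rfd(
    freq_a: float,
    freq_b: float,
    n_a: int | None = None,
    n_b: int | None = None,
    method: str = "zscore",
) -> float:
    """Relative frequency difference between cohort carrier frequencies.

    ``zscore`` (default): (fB - fA) / sqrt(fbar (1 - fbar) (1/nA + 1/nB))
    with fbar the pooled frequency — a two-proportion z statistic whose
    magnitude is unbounded, consistent with screens whose printed cutoffs
    exceed 1. ``relative``: 2 (fB - fA) / (fB + fA), bounded in [-2, 2].
    The sign convention is later-minus-earlier (G10 - G1).
    """
    fa, fb = float(freq_a), float(freq_b)
    for f in (fa, fb):
        if not 0 <= f <= 1:
            raise ValueError("carrier frequencies must lie in [0, 1]")
    if method == "zscore":
        if n_a is None or n_b is None:
            raise ValueError("zscore RFD needs both cohort sizes")
        fbar = (n_a * fa + n_b * fb) / (n_a + n_b)
        if fbar in (0.0, 1.0):
            return np.nan
        return (fb - fa) / np.sqrt(fbar * (1 - fbar) * (1 / n_a + 1 / n_b))
    if method == "relative":
        if fa + fb == 0:
            return 0.0
        return 2.0 * (fb - fa) / (fb + fa)
    raise ValueError(f"unknown RFD method {method!r}")


def screen_cnvrs(rfd_values: pd.Series | np.ndarray, tail_fraction: float = 0.05):
    """Select CNVRs whose |RFD| reaches the empirical (1 - tail) quantile.

    Returns (boolean selection aligned with input, realized cutoff). Ties
    at the cutoff are all kept. NaN RFDs are never selected and do not
    enter the quantile.
    """
    vals = pd.Series(rfd_values).astype(float)
    finite = vals[np.isfinite(vals)]
    if finite.empty:
        raise ValueError("no finite RFD values to screen")
    cutoff = float(np.quantile(np.abs(finite), 1 - tail_fraction))
    selected = (vals.abs() >= cutoff) & np.isfinite(vals)
    return selected, cutoff


def cnv_variance_explained(classes, phenotype, coding: str = "linear") -> float:
    """R^2 of phenotype on copy-number class.

    ``linear`` regresses on the numeric class value (multicopy coded 2.5);
    ``anova`` fits one mean per class. Undefined (NaN) with a single class.
    """
    cls = np.asarray(classes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(cls) != len(y):
        raise ValueError("classes and phenotype must align")
    if len(np.unique(cls)) < 2:
        return np.nan
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.nan
    if coding == "linear":
        x = np.column_stack([np.ones_like(cls), cls])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
    elif coding == "anova":
        resid = y.copy()
        for u in np.unique(cls):
            m = cls == u
            resid[m] = y[m] - y[m].mean()
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return 1.0 - float((resid**2).sum()) / ss_tot


def cnv_frequency_trajectory(
    values: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Carrier frequency per sampled generation per CNVR.

    ``values`` is the CNVR x sample normalized copy-number matrix; ``meta``
    supplies each sample's generation.
    """
    gens = sorted(meta["generation"].unique())
    out = {}
    for g in gens:
        ids = [s for s in values.columns if s in set(meta.loc[meta["generation"] == g, "sample_id"])]
        block = classify_copy_number(values[ids].to_numpy())
        out[f"gen{g}"] = (block != 1.0).mean(axis=1)
    return pd.DataFrame(out, index=values.index)
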