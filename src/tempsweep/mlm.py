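"""EMMAX-style mixed-linear-model association scan.

Model: y = X b + g a + u + e with u ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I). Variance components are estimated once by REML on
the null model (no SNP) through the spectral decomposition of K, then held
fixed while every SNP is tested by generalized least squares in the
rotated coordinates — the EMMAX approximation. Fixed effects default to
intercept + sex + the top genotype principal components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix, Region

__all__ = [
    "kinship_matrix",
    "reml_null",
    "emmax_scan",
    "bonferroni_threshold",
    "overlap_assoc_with_regions",
    "genomic_control_lambda",
]


def _imputed_dosage(gm_or_array) -> np.ndarray:
    if isinstance(gm_or_array, GenotypeMatrix):
        d = gm_or_array.dosage.astype(float)
        d[gm_or_array.dosage == MISSING] = np.nan
    else:
        d = np.array(gm_or_array, dtype=float)
        d[d == MISSING] = np.nan
    mu = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mu, inds[1])
    return d


def kinship_matrix(genotypes, method: str = "centered") -> np.ndarray:
    """Sample x sample kinship.

    ``centered``: K = Z Z' / m with Z per-site centred dosages, rescaled to
    mean diagonal 1 (VanRaden-style). ``ibs``: mean proportion of shared
    alleles, 1 - |d_i - d_j| / 2 averaged over sites.
    """
    d = _imputed_dosage(genotypes)
    n, m = d.shape
    if n < 2:
        raise ValueError("need >= 2 samples")
    if method == "centered":
        z = d - d.mean(axis=0)
        if not np.any(z.std(axis=0) > 0):
            raise ValueError("all sites monomorphic; kinship is degenerate")
        k = z @ z.T / m
        scale = np.mean(np.diag(k))
        if scale <= 0:
            raise ValueError("degenerate kinship (zero diagonal)")
        return k / scale
    if method == "ibs":
        k = np.empty((n, n))
        for i in range(n):
            k[i] = 1.0 - np.abs(d[i] - d).mean(axis=1) / 2.0
        return (k + k.T) / 2.0
    raise ValueError(f"unknown kinship method {method!r}")


def _reml_loglik(log_delta: float, eigvals, yt, xt) -> float:
    """Restricted log-likelihood at delta = sigma_e^2 / sigma_g^2 (profiled
    over sigma_g^2), in the rotated basis."""
    delta = np.exp(log_delta)
    w = eigvals + delta
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtx, xw.T @ yt)
    resid = yt - xt @ beta
    nq = len(yt) - xt.shape[1]
    rss = float(resid @ (resid / w))
    if rss <= 0:
        return -np.inf
    sg2 = rss / nq
    _, logdet_xx = np.linalg.slogdet(xt.T @ xt)
    return -0.5 * (
        nq * np.log(2 * np.pi * sg2)
        + nq
        + np.sum(np.log(w))
        + logdet_xtx
        - logdet_xx
    )


def reml_null(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """REML variance components of the null mixed model.

    Maximises the restricted likelihood over delta = sigma_e^2/sigma_g^2 on
    a log-spaced grid refined by bounded scalar optimisation. Returns
    (sigma_g^2, sigma_e^2, log-REML, transform) where ``transform`` carries
    the eigenvectors/eigenvalues needed by :func:`emmax_scan`.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n or K.shape != (n, n):
        raise ValueError("y, X, K dimensions disagree")
    if n <= np.linalg.matrix_rank(X) + 1:
        raise ValueError("too few samples for the fixed-effect design")
    eigvals, U = np.linalg.eigh((K + K.T) / 2.0)
    eigvals = np.clip(eigvals, 0.0, None)
    yt = U.T @ y
    xt = U.T @ X

    grid = np.linspace(np.log(1e-5), np.log(1e5), 61)
    lls = np.array([_reml_loglik(g, eigvals, yt, xt) for g in grid])
    if not np.any(np.isfinite(lls)):
        raise RuntimeError("restricted likelihood non-finite everywhere")
    i = int(np.nanargmax(np.where(np.isfinite(lls), lls, -np.inf)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, eigvals, yt, xt),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    best = res.x if -res.fun >= lls[i] else grid[i]
    delta = float(np.exp(best))
    w = eigvals + delta
    xw = xt / w[:, None]
    beta = np.linalg.solve(xt.T @ xw, xw.T @ yt)
    resid = yt - xt @ beta
    nq = n - X.shape[1]
    sg2 = float(resid @ (resid / w)) / nq
    se2 = sg2 * delta
    transform = {"U": U, "eigvals": eigvals, "delta": delta}
    return sg2, se2, float(_reml_loglik(best, eigvals, yt, xt)), transform


def emmax_scan(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    genotypes,
    transform: dict | None = None,
) -> pd.DataFrame:
    """Per-SNP GLS tests with variance components fixed from the null model.

    Each SNP's dosage joins the fixed design; the Wald t statistic on the
    SNP coefficient uses n - rank([X, snp]) degrees of freedom. Monomorphic
    or X-collinear SNPs get NaN results (flagged missing).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if transform is None:
        _, _, _, transform = reml_null(y, X, K)
    U, eigvals, delta = transform["U"], transform["eigvals"], transform["delta"]
    w = eigvals + delta
    sw = np.sqrt(w)
    yt = (U.T @ y) / sw
    xt = (U.T @ X) / sw[:, None]
    if isinstance(genotypes, GenotypeMatrix):
        chrom, pos = genotypes.chrom, genotypes.pos
    else:
        chrom = pos = None
    G = _imputed_dosage(genotypes)
    gt = (U.T @ G) / sw[:, None]

    # residualise y and every SNP against the (whitened) fixed effects
    q, _ = np.linalg.qr(xt)
    ry = yt - q @ (q.T @ yt)
    rg = gt - q @ (q.T @ gt)
    gg = np.einsum("ij,ij->j", rg, rg)
    gy = rg.T @ ry
    n, p = xt.shape
    df = n - p - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gg
        rss = float(ry @ ry) - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    poly = gg > 1e-10
    pvals = np.where(poly, 2.0 * stats.t.sf(np.abs(tstat), df), np.nan)
    beta = np.where(poly, beta, np.nan)
    se = np.where(poly, se, np.nan)
    out = {"beta": beta, "se": se, "p": pvals}
    with np.errstate(divide="ignore"):
        out["mlog10p"] = -np.log10(pvals)
    frame = pd.DataFrame(out)
    if chrom is not None:
        frame.insert(0, "chrom", chrom)
        frame.insert(1, "pos", pos)
    return frame


def bonferroni_threshold(n_tests: int, alpha: float = 0.01) -> float:
    """-log10 of the family-wise cutoff alpha / n_tests."""
    if n_tests < 1 or not 0 < alpha < 1:
        raise ValueError("need n_tests >= 1 and alpha in (0, 1)")
    return float(np.log10(n_tests / alpha))


def genomic_control_lambda(pvals: np.ndarray) -> float:
    """Median chi2(1) statistic over its null median (inflation factor)."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def overlap_assoc_with_regions(
    assoc: pd.DataFrame, regions: list[Region], cutoff: float
) -> list[Region]:
    """Regions containing >= 1 SNP with -log10 p >= cutoff, with those SNPs attached."""
    hits = assoc[assoc["mlog10p"] >= cutoff]
    out = []
    for r in regions:
        in_r = hits[
            (hits["chrom"] == r.chrom)
            & (hits["pos"] - 1 >= r.start)
            & (hits["pos"] - 1 < r.end)
        ]
        if len(in_r):
            out.append(
                Region(
                    r.chrom,
                    r.start,
                    r.end,
                    provenance=tuple(r.provenance) + ("gwas",),
                    member_windows=r.member_windows,
                    snps=list(in_r["pos"]),
                )
            )
    return out
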