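"""Kinship-corrected linear mixed model genome scan (GEMMA-style).

The model is ``y = Xb + u + e`` with ``u ~ N(0, sg^2 K)`` and
``e ~ N(0, se^2 I)``, where K is a centered SNP-derived kinship matrix,
optionally built leave-one-chromosome-out (LOCO).  The variance ratio
``lambda = sg^2/se^2`` is estimated once per kinship by maximising the
restricted likelihood on the eigenbasis of K (log-grid plus Brent
refinement), then each marker effect is tested by a Wald statistic
referred to F(1, n-2).  LOD is reported as -log10(Wald p) by default (the
GeneNetwork display convention), with a likelihood-ratio-style
``(n/2)·log10(RSS0/RSS1)`` alternative behind ``lod_scale="lrs"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scan_hk import ScanResult, align_trait_genotypes
from .simulate import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "LmmNull",
    "kinship_matrix",
    "fit_null_lmm",
    "lmm_scan",
    "lmm_permutation_maxima",
    "lmm_permutation_thresholds",
]

_LOG10_LAMBDA_BOUNDS = (-5.0, 5.0)
_GRID_POINTS = 100


@dataclass
class KinshipMatrix:
    """Symmetric PSD strains×strains genetic-similarity matrix."""

    strains: list[str]
    K: np.ndarray
    excluded_chromosome: int | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (len(self.strains),) * 2:
            raise ValueError("K shape inconsistent with strain list")
        if not np.allclose(self.K, self.K.T, atol=1e-12):
            raise ValueError("K not symmetric")


def _imputed_calls(geno: GenotypeMatrix, marker_mask: np.ndarray) -> np.ndarray:
    """Per-marker mean-imputed call matrix (uncentered)."""
    G = geno.calls[:, marker_mask].copy()
    col_mean = np.nanmean(G, axis=0)
    nan = ~np.isfinite(G)
    if nan.any():
        G[nan] = np.broadcast_to(col_mean, G.shape)[nan]
    return G


def _imputed_centered_calls(geno: GenotypeMatrix, marker_mask: np.ndarray) -> np.ndarray:
    """Per-marker mean-imputed then column-centered call matrix."""
    G = _imputed_calls(geno, marker_mask)
    return G - G.mean(axis=0)


def kinship_matrix(geno: GenotypeMatrix, loco_chromosome: int | None = None) -> KinshipMatrix:
    """Centered SNP kinship K = Gc Gc' / p over the included markers.

    With ``loco_chromosome`` set, markers on that chromosome are left out
    so the polygenic term never absorbs the tested locus itself.  Missing
    calls are mean-imputed per marker before centering.
    """
    # any marker with both alleles present contributes to relatedness
    mask = geno.polymorphic_mask(min_per_allele=1)
    if loco_chromosome is not None:
        mask = mask & (geno.markers["chromosome"].to_numpy() != loco_chromosome)
    p = int(mask.sum())
    if p < 1:
        raise ValueError("no polymorphic markers available for kinship")
    Gc = _imputed_centered_calls(geno, mask)
    K = (Gc @ Gc.T) / p
    return KinshipMatrix(strains=list(geno.strains), K=K, excluded_chromosome=loco_chromosome)


@dataclass
class LmmNull:
    """Null-model REML fit: variance ratio plus reusable eigen-rotation."""

    lambda_hat: float
    log_restricted_likelihood: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    yt: np.ndarray  # U' y
    ones_t: np.ndarray  # U' 1


def _reml_loglik(lam: float, s: np.ndarray, Xt: np.ndarray, yt: np.ndarray) -> float:
    """Restricted log-likelihood of lambda on the eigenbasis (up to a constant)."""
    n, q = Xt.shape
    w = 1.0 / (lam * s + 1.0)
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    b = XtW.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return -np.inf
    r = yt - Xt @ beta
    rwr = float(np.sum(w * r * r))
    if rwr <= 0:
        return -np.inf
    logdet_h = float(np.sum(np.log(lam * s + 1.0)))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return -0.5 * ((n - q) * np.log(rwr) + logdet_h + logdet_a)


def _optimize_lambda(s: np.ndarray, Xt: np.ndarray, yt: np.ndarray,
                     tol: float = 1e-6) -> tuple[float, float]:
    grid = np.logspace(*_LOG10_LAMBDA_BOUNDS, _GRID_POINTS)
    ll = np.array([_reml_loglik(lam, s, Xt, yt) for lam in grid])
    if not np.isfinite(ll).any():
        raise ValueError("restricted likelihood undefined everywhere on the grid")
    # flat likelihood (e.g. K = I): lambda unidentifiable, return 0 by convention
    finite = ll[np.isfinite(ll)]
    if finite.max() - finite.min() < 1e-8:
        return 0.0, float(_reml_loglik(0.0, s, Xt, yt))
    i = int(np.nanargmax(ll))
    lo = np.log10(grid[max(i - 1, 0)])
    hi = np.log10(grid[min(i + 1, len(grid) - 1)])
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(10.0 ** t, s, Xt, yt),
        bounds=(lo, hi), method="bounded", options={"xatol": tol},
    )
    lam = float(10.0 ** res.x)
    ll_hat = float(-res.fun)
    # the boundary lambda -> 0 can beat the interior grid optimum
    ll0 = _reml_loglik(0.0, s, Xt, yt)
    if ll0 >= ll_hat:
        return 0.0, float(ll0)
    return lam, ll_hat


def fit_null_lmm(y: np.ndarray | pd.Series, kinship: KinshipMatrix,
                 tol: float = 1e-6) -> LmmNull:
    """REML estimate of lambda = sg^2/se^2 under the intercept-only model.

    K is eigendecomposed once; the restricted likelihood of lambda is
    maximised on a 100-point log grid over [1e-5, 1e5] refined by bounded
    Brent search.  A flat likelihood (K = I up to scale) returns lambda = 0
    by convention.  The returned cache carries the rotation for reuse
    across markers and permutations.
    """
    yv = np.asarray(y, dtype=float)
    if yv.ndim != 1 or len(yv) != len(kinship.strains):
        raise ValueError("y length must match kinship order")
    if np.std(yv) == 0:
        raise ValueError("zero-variance phenotype")
    s, U = np.linalg.eigh(kinship.K)
    if s.min() < -1e-8 * max(1.0, abs(s.max())):
        raise ValueError("kinship matrix is not PSD within tolerance")
    s = np.maximum(s, 0.0)
    yt = U.T @ yv
    ones_t = U.T @ np.ones_like(yv)
    lam, ll = _optimize_lambda(s, ones_t[:, None], yt, tol=tol)
    return LmmNull(lambda_hat=lam, log_restricted_likelihood=ll,
                   eigenvalues=s, eigenvectors=U, yt=yt, ones_t=ones_t)


def _wald_scan_block(null: LmmNull, Xm: np.ndarray, lod_scale: str
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker GLS Wald tests given a fitted null rotation.

    ``Xm``: (n, m) marker codes (mean-imputed).  Returns (lod, beta, p).
    """
    s, yt, ot = null.eigenvalues, null.yt, null.ones_t
    n = len(yt)
    w = 1.0 / (null.lambda_hat * s + 1.0)
    Xt = null.eigenvectors.T @ Xm  # (n, m)
    a11 = float(np.sum(w * ot * ot))
    b1 = float(np.sum(w * ot * yt))
    syy = float(np.sum(w * yt * yt))
    a12 = (w * ot) @ Xt
    a22 = w @ (Xt * Xt)
    b2 = (w * yt) @ Xt
    det = a11 * a22 - a12 * a12
    with np.errstate(invalid="ignore", divide="ignore"):
        beta1 = (a22 * b1 - a12 * b2) / det
        beta2 = (a11 * b2 - a12 * b1) / det
        rss1 = syy - (beta1 * b1 + beta2 * b2)
        rss0 = syy - b1 * b1 / a11
        rss1 = np.maximum(rss1, 0.0)
        sigma2 = rss1 / (n - 2)
        var_beta = sigma2 * a11 / det
        F = beta2 * beta2 / var_beta
    bad = ~np.isfinite(F)
    F = np.where(bad, 0.0, F)
    p = stats.f.sf(F, 1, n - 2)
    p = np.where(bad, 1.0, p)
    if lod_scale == "lrs":
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = (n / 2.0) * np.log10(rss0 / np.maximum(rss1, 1e-300))
        lod = np.where(bad | ~np.isfinite(lod), 0.0, lod)
    else:
        with np.errstate(divide="ignore"):
            lod = -np.log10(np.maximum(p, 1e-300))
    return lod, beta2, p


def lmm_scan(
    trait: pd.Series,
    geno: GenotypeMatrix,
    loco: bool = False,
    kinship: KinshipMatrix | None = None,
    lod_scale: str = "neglog10p",
    trait_id: str | None = None,
) -> ScanResult:
    """Mixed-model association scan of one strain-mean trait.

    With ``loco`` the kinship (and lambda) is refit per chromosome from the
    complement marker set.  A pre-built ``kinship`` (e.g. the identity for
    an unstructured panel) overrides both and reduces the scan to GLS with
    that covariance; with K = I the p-values equal the single-marker OLS
    F test exactly.  Marker effects keep the ±1 coding sign convention
    (positive = D allele increases the trait).
    """
    if lod_scale not in ("neglog10p", "lrs"):
        raise ValueError("lod_scale must be 'neglog10p' or 'lrs'")
    y, g = align_trait_genotypes(trait, geno)
    poly = g.polymorphic_mask()
    markers = g.markers.loc[poly].reset_index(drop=True)
    Xall = _imputed_calls(g, poly)
    lod = np.empty(len(markers))
    beta = np.empty(len(markers))
    p = np.empty(len(markers))
    lambdas: dict[str, float] = {}

    if kinship is not None:
        if list(kinship.strains) != list(g.strains):
            raise ValueError("kinship strain order does not match trait/genotype strains")
        null = fit_null_lmm(y, kinship)
        lod[:], beta[:], p[:] = _wald_scan_block(null, Xall, lod_scale)
        lambdas["all"] = null.lambda_hat
    elif not loco:
        null = fit_null_lmm(y, kinship_matrix(g))
        lod[:], beta[:], p[:] = _wald_scan_block(null, Xall, lod_scale)
        lambdas["all"] = null.lambda_hat
    else:
        for chrom in markers["chromosome"].unique():
            null = fit_null_lmm(y, kinship_matrix(g, loco_chromosome=int(chrom)))
            sel = (markers["chromosome"] == chrom).to_numpy()
            lod[sel], beta[sel], p[sel] = _wald_scan_block(null, Xall[:, sel], lod_scale)
            lambdas[str(int(chrom))] = null.lambda_hat

    tab = markers[["marker_id", "chromosome", "position_mb"]].copy()
    tab["lod"] = lod
    tab["additive_effect"] = beta
    tab["p"] = p
    name = trait_id or (trait.name if trait.name is not None else "trait")
    res = ScanResult(trait_id=str(name), method="LMM", table=tab,
                     n_strains=len(y),
                     excluded=g.markers.loc[~poly, "marker_id"].tolist())
    res.lambdas = lambdas  # per-kinship-group variance ratios (JSON sidecar)
    return res


def lmm_permutation_maxima(
    trait: pd.Series,
    geno: GenotypeMatrix,
    n_perm: int,
    seed: int = 0,
    lod_scale: str = "neglog10p",
    refit_lambda: bool = True,
) -> np.ndarray:
    """Max-LOD null distribution: phenotypes shuffled, genotypes and K fixed.

    The kinship is computed once and reused for every permutation (its
    eigendecomposition is cached); lambda is refit per permuted phenotype
    unless ``refit_lambda`` is False.
    """
    y, g = align_trait_genotypes(trait, geno)
    poly = g.polymorphic_mask()
    Xall = _imputed_centered_calls(g, poly)
    kin = kinship_matrix(g)
    s, U = np.linalg.eigh(kin.K)
    s = np.maximum(s, 0.0)
    ones_t = U.T @ np.ones(len(y))
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    base = None
    for i in range(n_perm):
        yp = rng.permutation(y)
        yt = U.T @ yp
        if refit_lambda or base is None:
            lam, ll = _optimize_lambda(s, ones_t[:, None], yt)
        null = LmmNull(lambda_hat=lam, log_restricted_likelihood=ll,
                       eigenvalues=s, eigenvectors=U, yt=yt, ones_t=ones_t)
        lod, _, _ = _wald_scan_block(null, Xall, lod_scale)
        maxima[i] = lod.max()
        base = null
    return maxima


def lmm_permutation_thresholds(
    trait: pd.Series,
    geno: GenotypeMatrix,
    n_perm: int = 1000,
    quantiles: tuple[float, float] = (0.67, 0.95),
    seed: int = 0,
    lod_scale: str = "neglog10p",
):
    """Suggestive/significant LMM thresholds (67th/95th max-LOD percentiles)."""
    from .scan_hk import Thresholds, _nearest_rank

    maxima = np.sort(lmm_permutation_maxima(trait, geno, n_perm, seed=seed,
                                            lod_scale=lod_scale))
    return Thresholds(
        suggestive=_nearest_rank(maxima, quantiles[0]),
        significant=_nearest_rank(maxima, quantiles[1]),
        n_permutations=n_perm,
        seed=seed,
    )
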