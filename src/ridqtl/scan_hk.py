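"""Haley-Knott-style single-marker genome scan for RI strain means.

At each marker the strain-mean phenotype is regressed on the ±1 genotype
code; evidence is summarised as LOD = (n/2)·log10(RSS0/RSS1), the additive
effect is the OLS coefficient (half the D-minus-B class difference), and
the per-marker p-value comes from the equivalent F(1, n-2) test.
Genome-wide suggestive and significant thresholds are empirical quantiles
of the max-LOD distribution under phenotype permutation, and QTL support
intervals are defined by a 1.5-LOD drop from the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "ScanResult",
    "Thresholds",
    "hk_scan",
    "hk_lod_profile",
    "permutation_thresholds",
    "hk_permutation_thresholds",
    "lod_support_interval",
    "align_trait_genotypes",
    "LOD_CAP",
]

#: LOD assigned to perfect-fit markers (RSS1 == 0), which would otherwise
#: be infinite.
LOD_CAP = 50.0


@dataclass
class ScanResult:
    """Per-marker association statistics for one trait and one method.

    ``table`` columns: ``marker_id, chromosome, position_mb, lod,
    additive_effect, p`` (one row per tested marker; monomorphic and
    all-missing markers are excluded and listed in ``excluded``).
    """

    trait_id: str
    method: str
    table: pd.DataFrame
    n_strains: int
    excluded: list[str] = field(default_factory=list)

    def peak(self) -> pd.Series:
        """Genome-wide top marker; ties break to lowest chromosome, then Mb."""
        t = self.table.sort_values(["chromosome", "position_mb"], kind="stable")
        return t.loc[t["lod"].idxmax()]

    def chromosome_peaks(self) -> pd.DataFrame:
        t = self.table.sort_values(["chromosome", "position_mb"], kind="stable")
        idx = t.groupby("chromosome")["lod"].idxmax()
        return t.loc[idx]


@dataclass(frozen=True)
class Thresholds:
    """Permutation-derived genome-wide LOD thresholds.

    Both are nearest-rank quantiles of the same set of per-permutation
    max-LOD values: for the simple-regression convention the suggestive
    threshold is the 0.37 quantile (genome-wide adjusted p < 0.63) and the
    significant one the 0.95 quantile (adjusted p < 0.05); the LMM
    convention uses the 0.67 and 0.95 quantiles.
    """

    suggestive: float
    significant: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if self.significant < self.suggestive:
            raise ValueError("significant threshold below suggestive")


def align_trait_genotypes(trait: pd.Series, geno: GenotypeMatrix
                          ) -> tuple[np.ndarray, GenotypeMatrix]:
    """Match a strain-indexed phenotype to the genotype matrix by name."""
    shared = [s for s in geno.strains if s in trait.index and np.isfinite(trait[s])]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} strains shared between trait and genotypes")
    return trait.loc[shared].to_numpy(float), geno.subset_strains(shared)


def _hk_core(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized per-marker OLS of y on a ±1/NaN genotype matrix.

    Returns (lod, effect, p, n_used, perfect) arrays over markers; strains
    with a missing call are dropped marker-wise.
    """
    M = np.isfinite(G)
    Gz = np.where(M, G, 0.0)
    n = M.sum(axis=0).astype(float)
    sx = Gz.sum(axis=0)
    sy = M.T @ y
    sxy = Gz.T @ y
    syy = M.T @ (y * y)
    sxx = (Gz * Gz).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx, my = sx / n, sy / n
        Sxx = sxx - n * mx * mx
        Sxy = sxy - n * mx * my
        Syy = syy - n * my * my
        beta = Sxy / Sxx
        rss1 = Syy - Sxy * Sxy / Sxx
    rss1 = np.maximum(rss1, 0.0)
    lod = np.zeros_like(Sxx)
    p = np.ones_like(Sxx)
    perfect = np.zeros(Sxx.shape, dtype=bool)
    testable = (Sxx > 1e-12) & (n >= 3)
    const_y = Syy <= 1e-14
    ok = testable & ~const_y
    perfect[ok] = rss1[ok] <= 1e-12 * np.maximum(Syy[ok], 1.0)
    reg = ok & ~perfect
    with np.errstate(divide="ignore"):
        lod[reg] = (n[reg] / 2.0) * np.log10(Syy[reg] / rss1[reg])
        F = (Syy[reg] - rss1[reg]) / (rss1[reg] / (n[reg] - 2.0))
    p[reg] = stats.f.sf(F, 1, n[reg] - 2.0)
    lod[ok & perfect] = LOD_CAP
    p[ok & perfect] = 0.0
    beta = np.where(testable, beta, np.nan)
    lod = np.minimum(lod, LOD_CAP)
    return lod, beta, p, n, perfect, testable


def hk_lod_profile(y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """LOD vector only (fast path used by permutation machinery)."""
    return _hk_core(y, G)[0]


def hk_scan(trait: pd.Series, geno: GenotypeMatrix, trait_id: str | None = None) -> ScanResult:
    """Single-marker regression scan of one strain-mean trait.

    ``trait`` is a strain-indexed Series; strains are matched to the
    genotype matrix by name, and strains with a missing call at a marker
    are dropped for that marker only.  Monomorphic markers (fewer than two
    strains per allele among phenotyped strains) are excluded.
    """
    y, g = align_trait_genotypes(trait, geno)
    lod, beta, p, n, perfect, testable = _hk_core(y, g.calls)
    poly = g.polymorphic_mask() & testable
    tab = g.markers.loc[poly, ["marker_id", "chromosome", "position_mb"]].copy()
    tab["lod"] = lod[poly]
    tab["additive_effect"] = beta[poly]
    tab["p"] = p[poly]
    tab["n"] = n[poly].astype(int)
    tab["perfect_fit"] = perfect[poly]
    excluded = g.markers.loc[~poly, "marker_id"].tolist()
    name = trait_id or (trait.name if trait.name is not None else "trait")
    return ScanResult(trait_id=str(name), method="HK", table=tab.reset_index(drop=True),
                      n_strains=len(y), excluded=excluded)


def _nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile (no interpolation)."""
    n = len(sorted_values)
    k = int(np.ceil(q * n)) - 1
    return float(sorted_values[min(max(k, 0), n - 1)])


def _max_lod_of(result) -> float:
    if isinstance(result, ScanResult):
        return float(result.table["lod"].max())
    if isinstance(result, pd.DataFrame):
        return float(result["lod"].max())
    return float(np.max(result))


def permutation_thresholds(
    scan_fn: Callable[[np.ndarray], object],
    values: np.ndarray | pd.Series,
    n_perm: int = 1000,
    quantiles: tuple[float, float] = (0.37, 0.95),
    seed: int = 0,
) -> Thresholds:
    """Genome-wide thresholds from the max-LOD permutation distribution.

    The phenotype vector is shuffled across strains ``n_perm`` times with
    genotypes fixed; ``scan_fn`` maps a permuted vector to a scan (or a LOD
    array), and the genome-wide maximum of each permutation forms the
    empirical null.  ``quantiles`` = (suggestive, significant): (0.37,
    0.95) for the simple-regression convention (adjusted p < 0.63 / 0.05),
    (0.67, 0.95) for the LMM convention.
    """
    q_sugg, q_sig = quantiles
    for q in quantiles:
        if not 0.0 < q < 1.0:
            raise ValueError("quantiles must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        maxima[i] = _max_lod_of(scan_fn(rng.permutation(v)))
    maxima.sort()
    return Thresholds(
        suggestive=_nearest_rank(maxima, q_sugg),
        significant=_nearest_rank(maxima, q_sig),
        n_permutations=n_perm,
        seed=seed,
    )


def hk_permutation_thresholds(
    trait: pd.Series,
    geno: GenotypeMatrix,
    n_perm: int = 1000,
    quantiles: tuple[float, float] = (0.37, 0.95),
    seed: int = 0,
) -> Thresholds:
    """Permutation thresholds for :func:`hk_scan` using the fast LOD core."""
    y, g = align_trait_genotypes(trait, geno)
    G = g.calls[:, g.polymorphic_mask()]
    return permutation_thresholds(lambda v: hk_lod_profile(v, G), y,
                                  n_perm=n_perm, quantiles=quantiles, seed=seed)


def lod_support_interval(
    scan: ScanResult | pd.DataFrame,
    peak_marker: str,
    drop: float = 1.5,
) -> tuple[int, float, float]:
    """Support interval around a peak from a LOD drop on its chromosome.

    Walking outward from the peak, the interval ends at the first marker
    whose LOD falls below ``peak - drop`` on each side (that marker's Mb
    position is the reported bound); if the profile never crosses, the
    bound clamps to the chromosome end.  Returns ``(chromosome, left_mb,
    right_mb)``.
    """
    if drop <= 0:
        raise ValueError("drop must be > 0")
    tab = scan.table if isinstance(scan, ScanResult) else scan
    row = tab[tab["marker_id"] == peak_marker]
    if row.empty:
        raise KeyError(f"peak marker {peak_marker!r} not in scan")
    chrom = int(row["chromosome"].iloc[0])
    sub = tab[tab["chromosome"] == chrom].sort_values("position_mb", kind="stable")
    lods = sub["lod"].to_numpy(float)
    pos = sub["position_mb"].to_numpy(float)
    i = int(np.flatnonzero(sub["marker_id"].to_numpy() == peak_marker)[0])
    peak_lod = lods[i]
    if peak_lod < lods.max() - 1e-12:
        warnings.warn(f"{peak_marker} is not the chromosome-{chrom} maximum; "
                      "walking interval from the given marker")
    cut = peak_lod - drop
    left = pos[0]
    for j in range(i - 1, -1, -1):
        if lods[j] < cut:
            left = pos[j]
            break
    right = pos[-1]
    for j in range(i + 1, len(lods)):
        if lods[j] < cut:
            right = pos[j]
            break
    return chrom, float(left), float(right)
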