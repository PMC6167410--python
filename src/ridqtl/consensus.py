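"""Dual-method consensus QTL calling.

A locus enters the candidate set when the simple-regression (HK) scan
reaches the permutation-derived suggestive threshold at a chromosome peak,
and is confirmed when the kinship-corrected LMM scan also exceeds LOD > 3
at some marker inside the HK 1.5-LOD support interval on that chromosome.
Confirmed calls carry both methods' peaks and support intervals, their
intersection, and the direction of the trait-increasing founder allele
(B if the HK additive effect is negative, D if positive, under -1/+1
coding).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .scan_hk import ScanResult, Thresholds, lod_support_interval

__all__ = ["Locus", "QTLCall", "call_suggestive_loci", "consensus_qtls", "qtl_calls_table"]


@dataclass(frozen=True)
class Locus:
    """A chromosome-wise suggestive peak with its LOD-drop interval."""

    chromosome: int
    peak_marker: str
    peak_mb: float
    lod: float
    additive_effect: float
    ci_left_mb: float
    ci_right_mb: float


@dataclass(frozen=True)
class QTLCall:
    """A consensus QTL confirmed by both mapping methods."""

    trait_id: str
    chromosome: int
    peak_marker_hk: str
    peak_mb_hk: float
    lod_hk: float
    additive_effect: float
    peak_marker_lmm: str
    peak_mb_lmm: float
    lod_lmm: float
    ci_hk: tuple[float, float]
    ci_lmm: tuple[float, float]
    ci_intersection: tuple[float, float]
    increasing_allele: str


def call_suggestive_loci(
    scan: ScanResult,
    thresholds: Thresholds,
    drop: float = 1.5,
) -> list[Locus]:
    """Chromosome-wise peaks at or above the suggestive threshold.

    One locus per chromosome (the peak marker; position ties break to the
    lowest Mb), each with its LOD-drop support interval.
    """
    loci: list[Locus] = []
    peaks = scan.chromosome_peaks()
    for _, row in peaks.iterrows():
        if row["lod"] < thresholds.suggestive:
            continue
        chrom, left, right = lod_support_interval(scan, row["marker_id"], drop=drop)
        loci.append(Locus(
            chromosome=int(row["chromosome"]),
            peak_marker=str(row["marker_id"]),
            peak_mb=float(row["position_mb"]),
            lod=float(row["lod"]),
            additive_effect=float(row["additive_effect"]),
            ci_left_mb=left,
            ci_right_mb=right,
        ))
    return loci


def consensus_qtls(
    hk_loci: list[Locus],
    lmm_scan: ScanResult,
    lmm_lod_min: float = 3.0,
    drop: float = 1.5,
    trait_id: str | None = None,
) -> list[QTLCall]:
    """Confirm HK suggestive loci against the LMM scan.

    An HK locus is confirmed when the LMM LOD exceeds ``lmm_lod_min`` at
    some marker inside the HK support interval on the same chromosome.
    The reported LMM peak is the in-interval argmax (so the two intervals
    always intersect); its own LOD-drop interval is walked from there.
    """
    import warnings

    calls: list[QTLCall] = []
    tab = lmm_scan.table
    for locus in hk_loci:
        sub = tab[
            (tab["chromosome"] == locus.chromosome)
            & (tab["position_mb"] >= locus.ci_left_mb)
            & (tab["position_mb"] <= locus.ci_right_mb)
        ]
        if sub.empty:
            raise ValueError(
                f"no LMM markers on chromosome {locus.chromosome} inside the HK interval; "
                "scans must share a marker panel"
            )
        best = sub.loc[sub["lod"].idxmax()]
        if best["lod"] <= lmm_lod_min:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # in-interval peak need not be the chromosome max
            _, l2, r2 = lod_support_interval(lmm_scan, str(best["marker_id"]), drop=drop)
        inter = (max(locus.ci_left_mb, l2), min(locus.ci_right_mb, r2))
        calls.append(QTLCall(
            trait_id=trait_id or lmm_scan.trait_id,
            chromosome=locus.chromosome,
            peak_marker_hk=locus.peak_marker,
            peak_mb_hk=round(locus.peak_mb, 3),
            lod_hk=locus.lod,
            additive_effect=locus.additive_effect,
            peak_marker_lmm=str(best["marker_id"]),
            peak_mb_lmm=round(float(best["position_mb"]), 3),
            lod_lmm=float(best["lod"]),
            ci_hk=(round(locus.ci_left_mb, 3), round(locus.ci_right_mb, 3)),
            ci_lmm=(round(l2, 3), round(r2, 3)),
            ci_intersection=(round(inter[0], 3), round(inter[1], 3)),
            increasing_allele="D" if locus.additive_effect > 0 else "B",
        ))
    return calls


def qtl_calls_table(calls: list[QTLCall]) -> pd.DataFrame:
    """Flatten consensus calls into a two-rows-per-QTL report.

    Mirrors the published layout: one HK row (with additive effect) and
    one LMM row per locus, columns ``trait, method, chromosome, locus, mb,
    additive_effect, lod, ci_left_mb, ci_right_mb``.
    """
    rows = []
    for c in calls:
        rows.append((c.trait_id, "HK", c.chromosome, c.peak_marker_hk, c.peak_mb_hk,
                     round(c.additive_effect, 3), round(c.lod_hk, 2), *c.ci_hk))
        rows.append((c.trait_id, "LMM", c.chromosome, c.peak_marker_lmm, c.peak_mb_lmm,
                     np.nan, round(c.lod_lmm, 2), *c.ci_lmm))
    return pd.DataFrame(rows, columns=[
        "trait", "method", "chromosome", "locus", "mb",
        "additive_effect", "lod", "ci_left_mb", "ci_right_mb",
    ])
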