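"""Multi-evidence candidate-gene prioritization inside QTL intervals.

Genes under a QTL support interval are scored on three lines of evidence:
(1) presence of at least one potentially high-impact founder sequence
variant (VEP-style consequence in the shipped impact set), (2) cis
regulation of their expression (a genome scan of the probe peaking near
the gene above permutation thresholds), and (3) correlation of expression
with the mapped trait across strains.  Tier 1 candidates satisfy all
three, tier 2 the variant filter plus one of the other two, tier 3 the
variant filter alone; genes without a high-impact variant are excluded
outright (the variant filter runs first).  A companion screen correlates
the trait against a legacy strain-phenotype matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scan_hk import ScanResult, Thresholds, hk_scan
from .simulate import GenotypeMatrix, HIGH_IMPACT_CONSEQUENCES

__all__ = [
    "HIGH_IMPACT_CONSEQUENCES",
    "EXCLUDED_BIOTYPES",
    "genes_in_interval",
    "high_impact_filter",
    "cis_eqtl_test",
    "prioritize_candidates",
    "legacy_trait_correlations",
]

#: Gene biotypes dropped before prioritization (gene models, predicted
#: genes, non-coding and pseudo-genes).
EXCLUDED_BIOTYPES = frozenset({"pseudogene", "predicted_gene", "noncoding", "gene_model"})


def genes_in_interval(genes: pd.DataFrame, interval: tuple[int, float, float]) -> pd.DataFrame:
    """Genes whose span overlaps the half-open interval [left, right).

    ``interval`` is ``(chromosome, left_mb, right_mb)``; a gene overlapping
    either boundary is included.
    """
    chrom, left, right = interval
    if left > right:
        raise ValueError("malformed interval: left > right")
    if chrom not in set(genes["chromosome"].unique()):
        raise KeyError(f"chromosome {chrom} absent from gene table")
    sub = genes[genes["chromosome"] == chrom]
    if left == right:
        return sub.iloc[0:0].reset_index(drop=True)
    hit = (sub["start_mb"] < right) & (sub["end_mb"] > left)
    return sub[hit].reset_index(drop=True)


def high_impact_filter(
    genes: pd.DataFrame | list[str],
    variants: pd.DataFrame,
    impact_set: frozenset[str] | set[str] = HIGH_IMPACT_CONSEQUENCES,
) -> list[str]:
    """Genes retaining at least one variant with a high-impact consequence."""
    if not impact_set:
        raise ValueError("impact_set must be non-empty")
    symbols = genes["gene_symbol"] if isinstance(genes, pd.DataFrame) else pd.Series(genes)
    csq = variants["consequence"].str.lower().str.strip()
    hits = set(variants.loc[csq.isin({c.lower() for c in impact_set}), "gene_symbol"])
    return [g for g in symbols if g in hits]


def cis_eqtl_test(
    probe_values: pd.Series,
    gene_location: tuple[int, float],
    geno: GenotypeMatrix,
    thresholds: Thresholds,
    window_mb: float = 10.0,
) -> str:
    """Classify a probe as ``"none"``, ``"suggestive"`` or ``"significant"`` cis eQTL.

    The probe is scanned genome-wide exactly like a trait; the call is
    cis-significant (or cis-suggestive) only when the genome-wide peak
    exceeds the corresponding permutation threshold AND lies within
    ``window_mb`` of the gene on the same chromosome — a strong distal
    peak is trans regulation and returns ``"none"``.
    """
    vals = probe_values.dropna()
    if vals.std() == 0:
        raise ValueError("zero-variance probe")
    scan = hk_scan(vals, geno, trait_id=str(probe_values.name or "probe"))
    peak = scan.peak()
    chrom, pos = gene_location
    is_local = (int(peak["chromosome"]) == int(chrom)
                and abs(float(peak["position_mb"]) - float(pos)) <= window_mb)
    if not is_local:
        return "none"
    if peak["lod"] >= thresholds.significant:
        return "significant"
    if peak["lod"] >= thresholds.suggestive:
        return "suggestive"
    return "none"


def prioritize_candidates(
    interval: tuple[int, float, float],
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    expression: pd.DataFrame,
    trait: pd.Series,
    geno: GenotypeMatrix,
    thresholds: Thresholds,
    corr_p_cut: float = 0.05,
    window_mb: float = 10.0,
    impact_set: frozenset[str] | set[str] = HIGH_IMPACT_CONSEQUENCES,
) -> pd.DataFrame:
    """Rank genes in a QTL interval by variant, cis-eQTL and correlation evidence.

    The cascade mirrors the published filter order: restrict to genes in
    the interval, drop excluded biotypes, keep only genes overlapped by a
    potentially high-impact variant, then score the survivors on hippocampal
    -style expression evidence.  Within a tier, genes rank by |r| of the
    expression-trait correlation.

    ``expression`` is a gene-indexed frame with ``chromosome, position_mb``
    location columns followed by one column per strain.

    Returns a frame with ``gene_symbol, has_high_impact, mean_expression,
    cis_eqtl, trait_correlation_r, trait_correlation_p, priority_tier``.
    """
    in_iv = genes_in_interval(genes, interval)
    if "biotype" in in_iv.columns:
        in_iv = in_iv[~in_iv["biotype"].isin(EXCLUDED_BIOTYPES)]
    kept = high_impact_filter(in_iv, variants, impact_set=impact_set)
    strain_cols = [c for c in expression.columns if c not in ("chromosome", "position_mb")]
    rows = []
    for sym in kept:
        if sym not in expression.index:
            continue
        probe = expression.loc[sym, strain_cols].astype(float)
        probe.name = sym
        loc = (int(expression.loc[sym, "chromosome"]), float(expression.loc[sym, "position_mb"]))
        cis = cis_eqtl_test(probe, loc, geno, thresholds, window_mb=window_mb)
        shared = [s for s in probe.index if s in trait.index]
        if len(shared) >= 3 and probe[shared].std() > 0:
            r, p = stats.pearsonr(probe[shared], trait[shared])
        else:
            r, p = np.nan, np.nan
        correlated = np.isfinite(p) and p < corr_p_cut
        if cis != "none" and correlated:
            tier = 1
        elif cis != "none" or correlated:
            tier = 2
        else:
            tier = 3
        rows.append((sym, True, float(probe.mean()), cis, float(r), float(p), tier))
    out = pd.DataFrame(rows, columns=[
        "gene_symbol", "has_high_impact", "mean_expression", "cis_eqtl",
        "trait_correlation_r", "trait_correlation_p", "priority_tier",
    ])
    out["abs_r"] = out["trait_correlation_r"].abs()
    out = (out.sort_values(["priority_tier", "abs_r"], ascending=[True, False],
                           kind="stable")
              .drop(columns="abs_r").reset_index(drop=True))
    return out


def legacy_trait_correlations(
    trait: pd.Series,
    legacy: pd.DataFrame,
    p_cut: float = 0.005,
    method: str = "pearson",
) -> pd.DataFrame:
    """Screen a legacy traits×strains matrix for correlates of a phenotype.

    For each legacy trait (row) the correlation with ``trait`` is computed
    over shared strains (>=4 required); rows with two-sided p below
    ``p_cut`` are returned sorted by |r|.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    any_overlap = False
    for legacy_id, values in legacy.iterrows():
        v = values.astype(float).dropna()
        shared = [s for s in v.index if s in trait.index and np.isfinite(trait[s])]
        if len(shared) < 4:
            continue
        any_overlap = True
        a, b = v[shared].to_numpy(), trait[shared].to_numpy(float)
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        res = corr(a, b)
        r, p = float(res.statistic), float(res.pvalue)
        if p < p_cut:
            rows.append((legacy_id, r, p, len(shared)))
    if not any_overlap:
        raise ValueError("no legacy trait shares >=4 strains with the phenotype")
    out = pd.DataFrame(rows, columns=["trait_id", "r", "p", "n"])
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
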