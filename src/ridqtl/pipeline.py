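"""End-to-end orchestration: simulate -> phenotypes -> scans -> consensus -> candidates.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage; all
randomness derives from one master seed so a rerun with the same config
reproduces every artifact bit-exactly.  Each stage writes its outputs to
the configured directory and records row counts, seeds and timing in a
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gnio, phenotypes
from .candidates import prioritize_candidates
from .consensus import call_suggestive_loci, consensus_qtls, qtl_calls_table
from .scan_hk import hk_permutation_thresholds, hk_scan
from .scan_lmm import lmm_scan
from .simulate import (DidDesign, QtlSpec, default_map_spec,
                       simulate_did_phenotypes, simulate_omics,
                       simulate_ri_genotypes)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ridqtl.pipeline")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    QTLs are planted by chromosome + Mb position (the nearest marker is
    used); ``traits`` may name weekly traits (``W1D4``, ``W3avg``, ...) or
    the escalation traits ``Slope2h``/``Slope4h``.
    """

    out_dir: str = "ridqtl_out"
    seed: int = 1
    # simulation spec (used unless genotype_file/records_file given)
    n_strains: int = 39
    n_markers: int = 1000
    qtls: list[dict] = field(default_factory=list)
    design: dict = field(default_factory=dict)
    # or: load real inputs
    genotype_file: str | None = None
    records_file: str | None = None
    # analysis settings
    traits: list[str] = field(default_factory=lambda: ["W1D4", "W3avg", "Slope2h"])
    n_permutations: int = 1000
    hk_quantiles: tuple[float, float] = (0.37, 0.95)
    loco: bool = False
    winsorize_bounds: tuple[float, float] | None = None
    lmm_lod_min: float = 3.0
    lod_drop: float = 1.5
    # candidate stage
    run_candidates: bool = True
    n_genes: int = 300
    cis_fraction: float = 0.3
    impact_fraction: float = 0.3
    corr_p_cut: float = 0.05
    cis_window_mb: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.winsorize_bounds is not None:
            cfg.winsorize_bounds = tuple(cfg.winsorize_bounds)
        cfg.hk_quantiles = tuple(cfg.hk_quantiles)
        return cfg


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _nearest_marker(geno, chromosome: int, position_mb: float) -> str:
    sub = geno.markers[geno.markers["chromosome"] == chromosome]
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chromosome}")
    i = (sub["position_mb"] - position_mb).abs().idxmin()
    return str(sub.loc[i, "marker_id"])


def _trait_vector(cfg: PipelineConfig, traits_df: pd.DataFrame, trait_id: str) -> pd.Series:
    if trait_id in ("Slope2h", "Slope4h"):
        dur = "2h" if trait_id == "Slope2h" else "4h"
        fits = phenotypes.fit_strain_slopes(traits_df, duration=dur)
        s = fits.set_index("strain")["slope"]
        s.name = trait_id
        return s
    return phenotypes.trait_series(traits_df, trait_id)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config": dataclasses.asdict(config), "seeds": {
        "master": config.seed, "genotypes": seeds[0], "phenotypes": seeds[1],
        "omics": seeds[2], "permutations": seeds[3]},
        "stages": {}, "outputs": {}}

    def _done(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 2), **counts}
        log.info("stage %s done: %s", stage, counts)

    # --- inputs -----------------------------------------------------------
    if config.genotype_file:
        path = Path(config.genotype_file)
        geno = (gnio.read_genotypes_gn(path) if path.suffix in (".geno", ".txt")
                else gnio.read_genotypes_csv(path))
    else:
        spec = default_map_spec(config.n_markers)
        geno = simulate_ri_genotypes(config.n_strains, spec, seed=seeds[0])
    gnio.write_genotypes_csv(geno, out / "genotypes.csv")
    gnio.write_genotypes_gn(geno, out / "genotypes.geno")
    manifest["outputs"]["genotypes"] = str(out / "genotypes.csv")
    _done("genotypes", strains=geno.n_strains, markers=geno.n_markers)

    qtl_specs = [QtlSpec(_nearest_marker(geno, q["chromosome"], q["position_mb"]),
                         q["effect"], q.get("target", "level")) for q in config.qtls]
    manifest["planted_qtls"] = [dataclasses.asdict(q) for q in qtl_specs]

    if config.records_file:
        records = gnio.read_intake_csv(config.records_file)
    else:
        design = DidDesign(**config.design)
        records = simulate_did_phenotypes(geno, qtl_specs, design, seed=seeds[1])
    gnio.write_intake_csv(records, out / "intake_records.csv")
    manifest["outputs"]["intake_records"] = str(out / "intake_records.csv")
    _done("intake", records=len(records), animals=records["animal_id"].nunique())

    # --- phenotypes -------------------------------------------------------
    traits_df = phenotypes.weekly_strain_means(records)
    gnio.write_traits_csv(traits_df, out / "strain_traits.csv")
    fits2 = phenotypes.fit_strain_slopes(traits_df, "2h")
    fits4 = phenotypes.fit_strain_slopes(traits_df, "4h")
    gnio.write_slope_table_csv(fits2, fits4, out / "strain_slopes.csv")
    h2 = {}
    for tid in config.traits:
        if tid.startswith("Slope"):
            continue
        sub = records
        if tid.endswith("avg"):
            wk = int(tid[1])
            animal_vals = (sub[(sub["week"] == wk) & (sub["access_h"] == 2)]
                           .groupby(["strain", "animal_id"])["intake_gkg"].mean()
                           .reset_index().rename(columns={"intake_gkg": "value"}))
        else:
            wk, day = int(tid[1]), int(tid[3])
            animal_vals = (sub[(sub["week"] == wk) & (sub["day"] == day)]
                           .groupby(["strain", "animal_id"])["intake_gkg"].mean()
                           .reset_index().rename(columns={"intake_gkg": "value"}))
        h2[tid] = dataclasses.asdict(phenotypes.strain_anova(animal_vals))
    (out / "anova_h2.json").write_text(json.dumps(h2, indent=2))
    _done("phenotypes", traits=traits_df["trait_id"].nunique(), h2_traits=len(h2))

    # --- scans, thresholds, consensus ------------------------------------
    all_calls = []
    per_trait_counts = {}
    for k, tid in enumerate(config.traits):
        y = _trait_vector(config, traits_df, tid)
        if config.winsorize_bounds is not None:
            lo, hi = config.winsorize_bounds
            y = pd.Series(phenotypes.winsorize(y.to_numpy(), lo, hi),
                          index=y.index, name=y.name)
        hk = hk_scan(y, geno, trait_id=tid)
        hk.table.to_csv(out / f"scan_hk_{tid}.csv", index=False)
        thr = hk_permutation_thresholds(
            y, geno, n_perm=config.n_permutations,
            quantiles=config.hk_quantiles, seed=seeds[3] + k)
        (out / f"thresholds_{tid}.json").write_text(json.dumps({
            "suggestive": thr.suggestive, "significant": thr.significant,
            "n_permutations": thr.n_permutations, "seed": thr.seed}, indent=2))
        lmm = lmm_scan(y, geno, loco=config.loco, trait_id=tid)
        lmm.table.to_csv(out / f"scan_lmm_{tid}.csv", index=False)
        (out / f"lambda_{tid}.json").write_text(json.dumps(lmm.lambdas, indent=2))
        loci = call_suggestive_loci(hk, thr, drop=config.lod_drop)
        calls = consensus_qtls(loci, lmm, lmm_lod_min=config.lmm_lod_min,
                               drop=config.lod_drop, trait_id=tid)
        all_calls.extend(calls)
        per_trait_counts[tid] = {"hk_suggestive_loci": len(loci),
                                 "consensus_qtls": len(calls),
                                 "thresholds": [thr.suggestive, thr.significant]}
    qtl_calls_table(all_calls).to_csv(out / "qtl_calls.csv", index=False)
    (out / "qtl_calls.json").write_text(json.dumps(
        [dataclasses.asdict(c) for c in all_calls], indent=2))
    _done("mapping", **{t: c["consensus_qtls"] for t, c in per_trait_counts.items()})
    manifest["mapping"] = per_trait_counts

    # --- candidates -------------------------------------------------------
    n_candidate_tables = 0
    if config.run_candidates and all_calls:
        genes, variants, expression = simulate_omics(
            geno, n_genes=config.n_genes, cis_fraction=config.cis_fraction,
            impact_fraction=config.impact_fraction, seed=seeds[2])
        gnio.write_genes_bed(genes, out / "genes.bed")
        variants.to_csv(out / "variants.csv", index=False)
        gnio.write_expression_csv(expression, out / "expression.csv")
        for call in all_calls:
            y = _trait_vector(config, traits_df, call.trait_id)
            thr = hk_permutation_thresholds(
                y, geno, n_perm=max(100, config.n_permutations // 5),
                quantiles=config.hk_quantiles, seed=seeds[3])
            iv = (call.chromosome, *call.ci_intersection)
            table = prioritize_candidates(
                iv, genes, variants, expression, y, geno, thr,
                corr_p_cut=config.corr_p_cut, window_mb=config.cis_window_mb)
            table.to_csv(out / f"candidates_{call.trait_id}_chr{call.chromosome}.csv",
                         index=False)
            n_candidate_tables += 1
    _done("candidates", tables=n_candidate_tables)

    manifest["n_consensus_qtls"] = len(all_calls)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
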