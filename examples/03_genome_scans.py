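"""Dual genome scans of one trait with permutation thresholds.

Plants a QTL, maps the week-3 weekly 2 h trait with both Haley-Knott
regression and the kinship-corrected LMM, and reports the peaks with
their 1.5-LOD support intervals.
"""

from ridqtl import (DidDesign, QtlSpec, hk_permutation_thresholds, hk_scan,
                    lmm_scan, lod_support_interval, simulate_did_phenotypes,
                    simulate_ri_genotypes, trait_series, weekly_strain_means)

geno = simulate_ri_genotypes(39, {c: (30, 100.0) for c in range(1, 20)}, seed=6)
marker = geno.markers[geno.markers["chromosome"] == 12].iloc[15]
records = simulate_did_phenotypes(
    geno, [QtlSpec(marker["marker_id"], 0.5)],
    DidDesign(replicates=(1, 16)), seed=7)
y = trait_series(weekly_strain_means(records), "W3avg")

hk = hk_scan(y, geno, trait_id="W3avg")
thr = hk_permutation_thresholds(y, geno, n_perm=1000, seed=8)
peak = hk.peak()
chrom, left, right = lod_support_interval(hk, str(peak["marker_id"]))
print(f"planted QTL: chr 12 @ {marker['position_mb']:.1f} Mb, effect +0.5 g/kg")
print(f"HK peak: {peak['marker_id']} (chr {chrom}, {peak['position_mb']:.1f} Mb), "
      f"LOD {peak['lod']:.2f}, effect {peak['additive_effect']:+.3f}")
print(f"  thresholds from 1000 permutations: suggestive {thr.suggestive:.2f} "
      f"(adjusted p<0.63), significant {thr.significant:.2f} (p<0.05)")
print(f"  1.5-LOD support interval: {left:.1f}-{right:.1f} Mb")

lmm = lmm_scan(y, geno, loco=True, trait_id="W3avg")
lpeak = lmm.peak()
print(f"LMM (LOCO) peak: {lpeak['marker_id']} LOD {lpeak['lod']:.2f}; "
      f"variance ratios per chromosome span "
      f"{min(lmm.lambdas.values()):.2f}-{max(lmm.lambdas.values()):.2f}")
print("  -> agreement of both methods at the planted locus means the signal "
      "is not an artifact of kinship structure")
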