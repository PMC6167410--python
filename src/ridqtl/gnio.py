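"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as GeneNetwork-style genotype text (``@``-prefixed
header lines, then ``Chr  Locus  cM  Mb`` map columns followed by one
B/D/H/U call column per strain) or as a plain wide CSV; intake records,
trait tables, scans, gene/variant tables and expression matrices are CSV
(genes as BED-like TSV).  Parsers map ``H`` (residual heterozygous) and
``U`` (unknown) calls to missing — real RI panels retain both even though
the simulator never emits them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "write_genotypes_gn", "read_genotypes_gn",
    "write_genotypes_csv", "read_genotypes_csv",
    "write_intake_csv", "read_intake_csv",
    "write_traits_csv", "read_traits_csv",
    "write_slope_table_csv",
    "write_genes_bed", "read_genes_bed",
    "write_expression_csv", "read_expression_csv",
]

_CALL_TO_CHAR = {-1.0: "B", 1.0: "D"}
_CHAR_TO_CALL = {"B": -1.0, "D": 1.0, "H": np.nan, "U": np.nan}


def write_genotypes_gn(geno: GenotypeMatrix, path: str | Path, name: str = "synthetic") -> None:
    """Write GeneNetwork-style genotype text (tab-separated, B/D/U calls)."""
    lines = [f"@name:{name}", "@type:riset", "@mat:B", "@pat:D", "@het:H", "@unk:U"]
    header = ["Chr", "Locus", "cM", "Mb"] + list(geno.strains)
    lines.append("\t".join(header))
    for j, (_, m) in enumerate(geno.markers.iterrows()):
        calls = [
            _CALL_TO_CHAR.get(geno.calls[i, j], "U") for i in range(geno.n_strains)
        ]
        cm = m["position_mb"] * geno.cm_per_mb
        lines.append("\t".join(
            [str(int(m["chromosome"])), str(m["marker_id"]), f"{cm:.4f}",
             f"{m['position_mb']:.6f}"] + calls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_gn(path: str | Path) -> GenotypeMatrix:
    """Parse GeneNetwork genotype text; H/U calls become missing."""
    rows = []
    strains: list[str] | None = None
    cm_per_mb = 0.5
    calls_rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("@"):
            continue
        parts = line.split("\t")
        if strains is None:
            if parts[:4] != ["Chr", "Locus", "cM", "Mb"]:
                raise ValueError("expected header 'Chr Locus cM Mb <strains...>'")
            strains = parts[4:]
            continue
        chrom, locus, cm, mb = parts[:4]
        rows.append((locus, int(chrom), float(mb)))
        calls_rows.append([_CHAR_TO_CALL.get(c.strip().upper(), np.nan) for c in parts[4:]])
        if float(mb) > 0 and float(cm) > 0:
            cm_per_mb = float(cm) / float(mb)
    if strains is None:
        raise ValueError("no header line found")
    markers = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_mb"])
    calls = np.array(calls_rows, dtype=float).T  # markers-major file -> strains x markers
    return GenotypeMatrix(strains=strains, markers=markers, calls=calls, cm_per_mb=cm_per_mb)


def write_genotypes_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.to_frame().to_csv(path, index=False)


def read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    map_cols = ["marker_id", "chromosome", "position_mb"]
    strains = [c for c in df.columns if c not in map_cols]
    return GenotypeMatrix(
        strains=strains,
        markers=df[map_cols].copy(),
        calls=df[strains].to_numpy(float).T,
    )


def write_intake_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_intake_csv(path: str | Path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    required = {"animal_id", "strain", "week", "day", "access_h", "intake_gkg"}
    missing = required - set(rec.columns)
    if missing:
        raise ValueError(f"intake records missing columns {sorted(missing)}")
    bad = (rec["day"] == 4) != (rec["access_h"] == 4)
    if bad.any():
        raise ValueError("day-4 records must have 4 h access and days 1-3 must have 2 h")
    return rec


def write_traits_csv(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=False)


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_slope_table_csv(fits2h: pd.DataFrame, fits4h: pd.DataFrame, path: str | Path) -> None:
    """Merged per-strain slope/intercept report (2 h and 4 h columns)."""
    merged = fits2h.rename(columns={
        "slope": "slope_2h", "intercept": "intercept_2h", "se_slope": "se_2h",
        "p_slope": "p_2h"}).merge(
        fits4h.rename(columns={
            "slope": "slope_4h", "intercept": "intercept_4h", "se_slope": "se_4h",
            "p_slope": "p_4h"}), on="strain", how="outer")
    merged.to_csv(path, index=False)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chromosome", "start_mb", "end_mb", "gene_symbol", "biotype"]].to_csv(
        path, sep="\t", index=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_csv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, index=True, index_label="gene_symbol")


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="gene_symbol")
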