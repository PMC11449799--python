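"""DEG x GWAS-catalog intersection and three-way Venn partitions.

The GWAS catalog is consumed as a local TSV snapshot (gene_symbol,
n_studies) for reproducibility; ``n_studies`` counts studies reporting the
gene at p < 0.01 and is used as the display weight of each intersected
gene.  Down-regulated genes map to "blue", up-regulated to "red".
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InvalidParameterError

__all__ = ["standardize_symbols", "load_deg_table", "load_gwas_catalog",
           "intersect_degs_gwas", "venn3", "DEG_PADJ_CUTOFF"]

DEG_PADJ_CUTOFF = 0.05

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def standardize_symbols(symbols) -> list[str]:
    """Uppercase, strip whitespace and trailing version suffixes.

    Idempotent: applying it twice is the same as once.
    """
    out = []
    for s in symbols:
        s = str(s).strip().upper()
        s = _VERSION_SUFFIX.sub("", s)
        out.append(s)
    return out


def load_deg_table(path, padj_cutoff: float = DEG_PADJ_CUTOFF) -> pd.DataFrame:
    """Read a DEG TSV (gene_symbol, log2fc, padj) and derive direction."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_symbol", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"DEG table missing columns {sorted(missing)}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise InvalidParameterError("padj outside [0, 1]")
    df = df.copy()
    df["gene_symbol"] = standardize_symbols(df["gene_symbol"])
    df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
    df["significant"] = df["padj"] < padj_cutoff
    return df


def load_gwas_catalog(path) -> pd.DataFrame:
    """Read a GWAS catalog snapshot TSV (gene_symbol, n_studies)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_symbol", "n_studies"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(
            f"GWAS catalog missing columns {sorted(missing)}")
    if (df["n_studies"] < 1).any():
        raise InvalidParameterError("n_studies must be >= 1")
    df = df.copy()
    df["gene_symbol"] = standardize_symbols(df["gene_symbol"])
    return df.groupby("gene_symbol", as_index=False)["n_studies"].max()


def intersect_degs_gwas(degs: pd.DataFrame, gwas: pd.DataFrame,
                        padj_cutoff: float = DEG_PADJ_CUTOFF) -> pd.DataFrame:
    """Significant DEGs that also appear in the GWAS catalog.

    Returns one row per shared gene with direction, color (down -> blue,
    up -> red) and weight = catalog study count, sorted by weight
    descending (the word-cloud ordering).
    """
    d = degs.copy()
    d["gene_symbol"] = standardize_symbols(d["gene_symbol"])
    if "direction" not in d.columns:
        d["direction"] = np.where(d["log2fc"] >= 0, "up", "down")
    if "padj" in d.columns:
        d = d[d["padj"] < padj_cutoff]
    g = gwas.copy()
    g["gene_symbol"] = standardize_symbols(g["gene_symbol"])
    merged = d.merge(g[["gene_symbol", "n_studies"]], on="gene_symbol",
                     how="inner")
    merged["color"] = np.where(merged["direction"] == "down", "blue", "red")
    merged = merged.rename(columns={"n_studies": "weight"})
    cols = ["gene_symbol", "direction", "color", "weight"]
    extra = [c for c in ("log2fc", "padj") if c in merged.columns]
    return (merged[cols + extra]
            .sort_values(["weight", "gene_symbol"],
                         ascending=[False, True])
            .reset_index(drop=True))


def venn3(set_a, set_b, set_c) -> dict[str, int]:
    """Counts of the 7 regions of a three-set Venn diagram.

    Keys: '100', '010', '001', '110', '101', '011', '111' where each digit
    flags membership in (A, B, C).  Region counts sum to |A u B u C|.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "100": len(a - b - c),
        "010": len(b - a - c),
        "001": len(c - a - b),
        "110": len((a & b) - c),
        "101": len((a & c) - b),
        "011": len((b & c) - a),
        "111": len(a & b & c),
    }
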