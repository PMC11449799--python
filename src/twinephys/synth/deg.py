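"""Synthetic differential-expression tables (stand-in for a count-based DE
test's output consumed by the gene-set stage)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import InvalidParameterError

__all__ = ["generate_deg_table"]


def generate_deg_table(n_genes: int = 5000, n_dys: int = 305,
                       effect: float = 1.5, seed: int = 0,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Gene table with exactly ``n_dys`` rows at padj < ``alpha``.

    Columns: gene_symbol, log2fc, padj, direction (up/down from the sign of
    log2fc).  Deterministic for a fixed seed.
    """
    if n_dys > n_genes:
        raise InvalidParameterError("n_dys cannot exceed n_genes")
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    symbols = np.array([f"GENE{i:05d}" for i in range(1, n_genes + 1)])
    rng.shuffle(symbols)

    padj = np.empty(n_genes)
    log2fc = np.empty(n_genes)
    # dysregulated block: padj strictly below alpha, sizeable fold changes
    padj[:n_dys] = rng.uniform(1e-12, alpha * (1 - 1e-9), size=n_dys)
    signs = rng.choice([-1.0, 1.0], size=n_dys)
    log2fc[:n_dys] = signs * np.abs(rng.normal(effect, 0.3, size=n_dys))
    # null block: padj at or above alpha
    n_null = n_genes - n_dys
    padj[n_dys:] = rng.uniform(alpha, 1.0, size=n_null)
    log2fc[n_dys:] = rng.normal(0.0, 0.2, size=n_null)

    df = pd.DataFrame({"gene_symbol": symbols, "log2fc": log2fc, "padj": padj})
    df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
    return df.sort_values("padj", kind="stable").reset_index(drop=True)
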