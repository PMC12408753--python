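"""Local over-representation analysis against GMT gene sets.

One-sided hypergeometric (Fisher exact) enrichment of a query gene list
within each set, against the background of genes actually tested in the
scan. The combined score is -ln(p) * z with z the deterministic
hypergeometric z-score of the overlap, so results are fully reproducible
offline (service-based enrichment tools compute z from random-set rank
permutations instead, and their printed scores will differ).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .scan import bh_fdr


def fisher_enrichment(
    query: list[str] | set[str],
    gene_sets: dict[str, list[str]],
    background: list[str] | set[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set.

    Query genes outside the background are dropped with a warning; sets
    disjoint from the background are skipped. Columns: set, k (overlap),
    K (set within background), n (query), N (background), overlap_genes,
    fisher_p, adjusted_p, z, combined_score; sorted by fisher_p.
    """
    bg = set(background)
    if not bg:
        raise DataError("background gene universe is empty")
    q = set(query)
    outside = q - bg
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the background were dropped")
        q &= bg
    n, n_bg = len(q), len(bg)

    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & bg
        if not in_bg:
            continue
        big_k = len(in_bg)
        overlap = sorted(q & in_bg)
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n)) if n else 1.0
        mu = n * big_k / n_bg
        var = n * big_k / n_bg * (n_bg - big_k) / n_bg * (n_bg - n) / max(n_bg - 1, 1)
        z = 0.0 if var <= 0 else (k - mu) / np.sqrt(var)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            {
                "set": name, "k": k, "K": big_k, "n": n, "N": n_bg,
                "overlap_genes": ";".join(overlap),
                "fisher_p": p, "z": z,
                "combined_score": -np.log(p) * z,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set", "k", "K", "n", "N", "overlap_genes", "fisher_p", "z", "combined_score"],
    )
    if len(df):
        df["adjusted_p"] = bh_fdr(df["fisher_p"].to_numpy())
        df = df.sort_values("fisher_p", kind="stable").reset_index(drop=True)
    else:
        df["adjusted_p"] = pd.Series(dtype=float)
    return df


def export_for_network(genes: list[str] | set[str], path: str | Path) -> list[str]:
    """Write a deduplicated, sorted gene-symbol list (one per line).

    Suitable as input for external protein-interaction tools; returns the
    list written.
    """
    out = sorted(set(genes))
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))
    return out
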