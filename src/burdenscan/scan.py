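"""Extreme-percentile bootstrap association scan.

For each gene, participants are ranked by ascending burden score into
``n_bins`` near-equal percentile bins (default 100). Because most scores in
a sparse gene are exactly zero, assignment among tied scores is arbitrary;
the ranking is therefore repeated ``n_iterations`` times (default 1000) with
a fresh random tie-break each time. Each iteration compares the LDL-C of the
lowest bin against the highest bin (zero-score members removed from the top
bin) with a two-sided Mann-Whitney U test; the mean and SD of the p-values
are recorded, and Benjamini-Hochberg FDR is applied across genes within each
analysis family.

The per-iteration ranking is "shuffle then stable sort": equivalent to
sorting by the key (score, tie_break). The implementation resolves only the
membership of the two extreme bins - participants whose score is strictly
below/above the bin-boundary value are always members, and the boundary tie
block is filled by the smallest/largest tie-break keys - which is exactly
the sort's behaviour without materialising it.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .genepy import GenePyMatrix, split_by_chromosome
from .cohort import CohortTable

_DEFAULT_STRATA = ("combined", "under60", "over60_or_equal")


@dataclass
class ScanConfig:
    n_bins: int = 100
    n_iterations: int = 1000
    fdr_alpha: float = 0.01
    min_group_size: int = 2
    rng_seed: int = 0
    strata: tuple[str, ...] = _DEFAULT_STRATA

    def validate(self) -> None:
        if self.n_bins < 2:
            raise DataError("n_bins must be >= 2")
        if self.n_iterations < 1:
            raise DataError("n_iterations must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise DataError("fdr_alpha must be in (0,1)")


def bin_sizes(n: int, n_bins: int) -> tuple[int, int]:
    """(size of bin 0, size of bin n_bins-1) under floor(i*n_bins/n) assignment."""
    if n < n_bins:
        raise DataError(f"stratum of {n} participants is smaller than {n_bins} bins")
    k_low = int(np.ceil(n / n_bins))
    first_high = int(np.ceil((n_bins - 1) * n / n_bins))
    return k_low, n - first_high


def assign_bins(scores: np.ndarray, tie_break: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index per participant: stable rank by (score, tie_break), then
    the i-th of n sorted participants goes to bin floor(i*n_bins/n)."""
    n = len(scores)
    if n < n_bins:
        raise DataError(f"stratum of {n} participants is smaller than {n_bins} bins")
    order = np.lexsort((tie_break, scores))
    bins = np.empty(n, dtype=np.int32)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def extreme_groups(
    bins: np.ndarray, scores: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """(low indices, high indices); zero scores are removed from the top bin only."""
    low = np.flatnonzero(bins == 0)
    high = np.flatnonzero((bins == n_bins - 1) & (scores > 0))
    return low, high


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when both groups have <= 8 observations and no
    ties are present; otherwise the normal approximation with tie and
    continuity corrections. Identical multisets return p = 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("Mann-Whitney groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _batch_mwu(xmat: np.ndarray, ymat: np.ndarray) -> np.ndarray:
    """Row-wise two-sided MWU p (normal approximation, tie + continuity
    corrected); matches scipy's asymptotic method."""
    t_iter, n1 = xmat.shape
    n2 = ymat.shape[1]
    n = n1 + n2
    pooled = np.concatenate([xmat, ymat], axis=1)
    ranks = stats.rankdata(pooled, method="average", axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    tie_term = np.zeros(t_iter)
    s = np.sort(pooled, axis=1)
    has_tie = (s[:, 1:] == s[:, :-1]).any(axis=1)
    for i in np.flatnonzero(has_tie):
        _, counts = np.unique(s[i], return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    u_big = np.maximum(u1, n1 * n2 - u1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u_big - mu - 0.5) / sigma
    p = np.where(sigma > 0, 2.0 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


@dataclass
class GeneScanResult:
    gene: str
    mean_p: float
    sd_p: float
    n_valid_iterations: int
    n_low_group: int
    n_high_group: int
    fdr_adjusted_p: float = np.nan
    significant: bool = False


def _gene_rng(master_seed: int, gene: str) -> np.random.Generator:
    """Per-gene substream: reproducible and independent of gene order."""
    return np.random.default_rng([int(master_seed), zlib.crc32(gene.encode())])


def bootstrap_gene(
    scores: np.ndarray,
    phenotype: np.ndarray,
    config: ScanConfig,
    rng: np.random.Generator,
    gene: str = "",
    literal: bool = False,
) -> GeneScanResult:
    """Bootstrap the extreme-bin Mann-Whitney test for one gene.

    When no tied scores straddle either bin boundary the assignment is
    tie-break-invariant, so a single pass is computed and sd_p is 0; this
    equals the full loop. ``literal=True`` forces the explicit per-iteration
    assign_bins/extreme_groups path (same RNG stream, same result).
    """
    config.validate()
    n = len(scores)
    scores = np.asarray(scores, float)
    phenotype = np.asarray(phenotype, float)
    k_low, k_high = bin_sizes(n, config.n_bins)
    srt = np.sort(scores)
    v_low, v_high = srt[k_low - 1], srt[n - k_high]

    if literal:
        ps = []
        for _ in range(config.n_iterations):
            u = rng.random(n)
            bins = assign_bins(scores, u, config.n_bins)
            lo, hi = extreme_groups(bins, scores, config.n_bins)
            if len(lo) < config.min_group_size or len(hi) < config.min_group_size:
                continue
            ps.append(mann_whitney_u(phenotype[lo], phenotype[hi]))
        return _summarise(gene, ps, k_low, scores, v_high, k_high)

    low_fixed = np.flatnonzero(scores < v_low)
    low_block = np.flatnonzero(scores == v_low)
    r_low = k_low - len(low_fixed)
    high_fixed = np.flatnonzero(scores > v_high)
    high_block = np.flatnonzero(scores == v_high)
    r_high = k_high - len(high_fixed)

    # top-bin zero exclusion: a zero boundary value means the sampled block
    # members are dropped, leaving the (fixed) non-zero carriers
    high_random = v_high > 0 and r_high > 0 and r_high < len(high_block)
    low_random = r_low > 0 and r_low < len(low_block)
    n_high = k_high if v_high > 0 else len(high_fixed)
    n_low = k_low

    if n_low < config.min_group_size or n_high < config.min_group_size:
        return GeneScanResult(gene, np.nan, np.nan, 0, n_low, n_high)

    if not low_random and not high_random:
        lo = np.concatenate([low_fixed, low_block[:r_low] if r_low > 0 else low_block[:0]])
        hi = high_fixed if v_high <= 0 else np.concatenate(
            [high_fixed, high_block[:r_high] if r_high > 0 else high_block[:0]]
        )
        p = mann_whitney_u(phenotype[lo], phenotype[hi])
        return GeneScanResult(gene, p, 0.0, config.n_iterations, n_low, n_high)

    t_iter = config.n_iterations
    low_vals = np.empty((t_iter, n_low))
    low_vals[:, : len(low_fixed)] = phenotype[low_fixed]
    if v_high > 0:
        high_vals = np.empty((t_iter, n_high))
        high_vals[:, : len(high_fixed)] = phenotype[high_fixed]
    else:
        high_vals = np.broadcast_to(phenotype[high_fixed], (t_iter, n_high))

    ph_low_block = phenotype[low_block]
    ph_high_block = phenotype[high_block]
    for t in range(t_iter):
        u = rng.random(n)
        if r_low > 0:
            pick = np.argpartition(u[low_block], r_low - 1)[:r_low]
            low_vals[t, len(low_fixed):] = ph_low_block[pick]
        if v_high > 0 and r_high > 0:
            ub = u[high_block]
            pick = np.argpartition(ub, len(ub) - r_high)[len(ub) - r_high:]
            high_vals[t, len(high_fixed):] = ph_high_block[pick]

    if n_low <= 8 and n_high <= 8:
        # small groups may hit the exact MWU path; defer to the scalar test
        ps = np.array([mann_whitney_u(low_vals[t], high_vals[t]) for t in range(t_iter)])
    else:
        ps = _batch_mwu(low_vals, high_vals)
    return GeneScanResult(
        gene,
        float(ps.mean()),
        float(ps.std()),
        t_iter,
        n_low,
        n_high,
    )


def _summarise(gene, ps, k_low, scores, v_high, k_high) -> GeneScanResult:
    n_high = k_high if v_high > 0 else int((scores > v_high).sum())
    if not ps:
        return GeneScanResult(gene, np.nan, np.nan, 0, k_low, n_high)
    ps = np.asarray(ps)
    return GeneScanResult(gene, float(ps.mean()), float(ps.std()), len(ps), k_low, n_high)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _scan_family(
    matrix: GenePyMatrix,
    genes: list[str],
    col_idx: np.ndarray,
    ldl: np.ndarray,
    config: ScanConfig,
    label: dict,
) -> pd.DataFrame:
    rows = []
    g_pos = {g: i for i, g in enumerate(matrix.genes)}
    for gene in genes:
        rng = _gene_rng(config.rng_seed, gene)
        res = bootstrap_gene(matrix.scores[g_pos[gene], col_idx], ldl, config, rng, gene=gene)
        rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        testable = df["n_valid_iterations"] > 0
        if testable.any():
            df.loc[testable, "fdr_adjusted_p"] = bh_fdr(df.loc[testable, "mean_p"].to_numpy())
            df["significant"] = df["fdr_adjusted_p"] < config.fdr_alpha
        df = df.sort_values("mean_p", na_position="last", kind="stable").reset_index(drop=True)
    for k, v in label.items():
        df[k] = v
    return df


def run_scan(matrix: GenePyMatrix, cohort: CohortTable, config: ScanConfig) -> pd.DataFrame:
    """Scan all genes across the configured strata.

    Autosomal genes are tested in both-sexes strata; X genes separately per
    sex. FDR is controlled within each (stratum x chromosome-class x sex)
    family. Strata smaller than ``n_bins`` are skipped with a warning.
    """
    config.validate()
    autosomal, x_genes = split_by_chromosome(matrix.gene_meta, matrix.genes)
    col = {p: i for i, p in enumerate(matrix.participants)}
    t = cohort.table[cohort.table["participant_id"].isin(col)].copy()

    frames = []
    families = [(s, "autosomal", None, autosomal) for s in config.strata]
    families += [(s, "X", sx, x_genes) for s in config.strata for sx in ("female", "male")]
    for stratum, chrom_class, sex, genes in families:
        if not genes:
            continue
        sel = t if stratum == "combined" else t[t["stratum"] == stratum]
        if sex is not None:
            sel = sel[sel["sex"] == sex]
        if len(sel) < config.n_bins:
            warnings.warn(
                f"stratum {stratum}/{chrom_class}/{sex or 'both'} has {len(sel)} "
                f"participants (< {config.n_bins} bins); skipped"
            )
            continue
        idx = np.array([col[p] for p in sel["participant_id"]])
        frames.append(
            _scan_family(
                matrix, genes, idx, sel["ldl_mmol_l"].to_numpy(), config,
                {"stratum": stratum, "chrom_class": chrom_class, "sex_group": sex or "both"},
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene", "mean_p", "sd_p", "n_valid_iterations", "n_low_group",
                     "n_high_group", "fdr_adjusted_p", "significant", "stratum",
                     "chrom_class", "sex_group"]
        )
    return pd.concat(frames, ignore_index=True)
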