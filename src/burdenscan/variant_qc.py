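"""Genotype-, site- and deleteriousness-level quality control.

Call-level rules: heterozygous calls need read depth DP >= 8 and allelic
balance AB = alt_depth/DP >= 0.15; other alt-carrying calls need only the
depth rule; hom-ref calls are always retained. Site-level rules: missing
fraction (computed after call-level nulling) strictly below 0.12, exact
Hardy-Weinberg p above a Bonferroni-corrected 0.05, and CADD-Phred >= 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import DataError
from .ledger import Ledger
from .synthetic import HET, HOM_ALT, HOM_REF, MISSING


@dataclass
class QCThresholds:
    min_depth: int = 8
    min_ab: float = 0.15
    max_ab: float | None = None  # optional symmetric upper bound, off by default
    max_fmissing: float = 0.12
    hwe_alpha: float = 0.05
    min_cadd: float = 20.0


def filter_genotype(
    gt: str, depth: int, alt_depth: int, thresholds: QCThresholds | None = None
) -> str:
    """Apply call-level QC to a single genotype; returns the (possibly nulled) call.

    ``gt`` is one of hom_ref, het, hom_alt, hemi_ref, hemi_alt, missing.
    """
    t = thresholds or QCThresholds()
    if depth < 0:
        raise DataError(f"negative read depth {depth}")
    if gt in ("hom_ref", "hemi_ref", "missing"):
        return gt
    if depth < t.min_depth:
        return "missing"
    if gt == "het":
        ab = alt_depth / depth
        if ab < t.min_ab or (t.max_ab is not None and ab > t.max_ab):
            return "missing"
    return gt


def filter_genotype_matrix(
    genotypes: np.ndarray,
    depth: np.ndarray,
    alt_depth: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, int]:
    """Vectorised call-level QC; returns (filtered copy, number of nulled calls)."""
    t = thresholds or QCThresholds()
    if (depth < 0).any():
        raise DataError("negative read depth in DP matrix")
    g = genotypes.copy()
    alt = g > 0
    low_dp = alt & (depth < t.min_depth)
    with np.errstate(invalid="ignore"):
        ab = np.where(depth > 0, alt_depth / np.maximum(depth, 1), 0.0)
    het = g == HET
    bad_ab = het & (ab < t.min_ab)
    if t.max_ab is not None:
        bad_ab |= het & (ab > t.max_ab)
    nulled = (low_dp | bad_ab) & (g != MISSING)
    g[nulled] = MISSING
    return g, int(nulled.sum())


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the minor-allele count and the number of diploids, and sums
    the probabilities of all heterozygote counts no more probable than the
    observed one (the Wigginton-Cutler-Abecasis construction). Computed in
    log space for numerical range.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise DataError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise DataError("HWE test needs at least one genotype")
    m = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele copies
    if m == 0:
        return 1.0
    hs = np.arange(m % 2, m + 1, 2)
    lw = (
        hs * math.log(2.0)
        - gammaln(hs + 1)
        - gammaln((m - hs) / 2 + 1)
        - gammaln(n - (hs + m) / 2 + 1)
    )
    lw_obs = lw[hs == n_het]
    if lw_obs.size == 0:  # parity mismatch cannot happen with valid counts
        raise DataError("inconsistent genotype counts")
    keep = lw <= lw_obs[0] + 1e-9
    return float(min(1.0, math.exp(logsumexp(lw[keep]) - logsumexp(lw))))


def site_qc(
    genotypes_row: np.ndarray,
    cadd_phred: float,
    n_sites_tested: int,
    thresholds: QCThresholds | None = None,
    diploid_mask: np.ndarray | None = None,
) -> dict:
    """Site-level QC stats for one variant after call-level filtering.

    ``diploid_mask`` restricts the HWE test to diploid genotypes (females on
    chrX); missingness is computed over all samples. A site enters scoring
    iff all pass flags are true.
    """
    t = thresholds or QCThresholds()
    if n_sites_tested < 1:
        raise DataError("n_sites_tested must be >= 1")
    n = len(genotypes_row)
    f_missing = float((genotypes_row == MISSING).sum() / n) if n else 0.0
    dip = genotypes_row if diploid_mask is None else genotypes_row[diploid_mask]
    counts = [int((dip == c).sum()) for c in (HOM_REF, HET, HOM_ALT)]
    hwe_p = hwe_exact_test(*counts) if sum(counts) >= 1 else 1.0
    pass_missing = f_missing < t.max_fmissing
    pass_hwe = hwe_p > t.hwe_alpha / n_sites_tested
    pass_cadd = bool(not pd.isna(cadd_phred) and cadd_phred >= t.min_cadd)
    return {
        "f_missing": f_missing,
        "hwe_p": hwe_p,
        "pass_missing": pass_missing,
        "pass_hwe": pass_hwe,
        "pass_cadd": pass_cadd,
        "pass_all": pass_missing and pass_hwe and pass_cadd,
    }


def apply_qc(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    depth: np.ndarray,
    alt_depth: np.ndarray,
    sex: np.ndarray | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, Ledger]:
    """Run call-level then site-level QC over a variant set.

    Filter order: call-level nulling, then F_MISSING, then HWE (Bonferroni
    denominator = sites entering the HWE stage in this run), then CADD.
    Returns (filtered genotypes, per-site stats, retained-site mask, ledger).
    """
    t = thresholds or QCThresholds()
    n_var = len(variants)
    geno, n_nulled = filter_genotype_matrix(genotypes, depth, alt_depth, t)
    ledger = Ledger("variants", n_var)
    if n_var == 0:
        return geno, pd.DataFrame(), np.zeros(0, dtype=bool), ledger

    n_samp = geno.shape[1]
    f_missing = (geno == MISSING).sum(axis=1) / n_samp
    pass_missing = f_missing < t.max_fmissing
    ledger.exclude("F_MISSING >= %.2f" % t.max_fmissing, int((~pass_missing).sum()))

    on_x = variants["chrom"].astype(str).str.removeprefix("chr").eq("X").to_numpy()
    female = None if sex is None else (np.asarray(sex) == "female")
    n_tested = int(pass_missing.sum())
    hwe_p = np.ones(n_var)
    for i in np.flatnonzero(pass_missing):
        row = geno[i]
        if on_x[i] and female is not None:
            row = row[female]
        c = [int((row == c_).sum()) for c_ in (HOM_REF, HET, HOM_ALT)]
        hwe_p[i] = hwe_exact_test(*c) if sum(c) >= 1 else 1.0
    pass_hwe = hwe_p > t.hwe_alpha / max(n_tested, 1)
    ledger.exclude("HWE below Bonferroni threshold", int((pass_missing & ~pass_hwe).sum()))

    cadd = pd.to_numeric(variants["cadd_phred"], errors="coerce").to_numpy()
    pass_cadd = ~np.isnan(cadd) & (cadd >= t.min_cadd)
    keep = pass_missing & pass_hwe
    ledger.exclude("CADD-Phred < %g" % t.min_cadd, int((keep & ~pass_cadd).sum()))
    keep &= pass_cadd
    ledger.check()

    stats = pd.DataFrame(
        {
            "f_missing": f_missing,
            "hwe_p": hwe_p,
            "pass_missing": pass_missing,
            "pass_hwe": pass_hwe,
            "pass_cadd": pass_cadd,
            "pass_all": keep,
            "n_calls_nulled": (geno == MISSING).sum(axis=1) - (genotypes == MISSING).sum(axis=1),
        }
    )
    stats.attrs["n_genotypes_nulled"] = n_nulled
    stats.attrs["n_sites_tested_hwe"] = n_tested
    return geno, stats, keep.to_numpy() if hasattr(keep, "to_numpy") else keep, ledger


def qc_summary(ledger: Ledger) -> pd.DataFrame:
    """Accounting table of removed/retained variants per filter step."""
    ledger.check()
    return ledger.to_frame()
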