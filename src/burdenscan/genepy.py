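"""Per-gene, per-participant pathogenic burden (GenePy-style) scores.

Each QC-passing variant contributes, for a carrier, its deleteriousness
weight D times the negative log10 of the probability of the observed
alleles: het -> D*(-log10(f_ref*f_alt)), hom-alt -> D*(-log10(f_alt^2)),
hemizygous-alt -> D*(-log10(f_alt)). D is CADD-Phred divided by a
normaliser (default 100) and clipped to [0,1]. A gene's score for a
participant is the sum over that participant's qualifying variants, so
scores are non-negative, additive, and zero exactly for participants with
no QC-passing alternate allele in the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .ledger import Ledger
from .synthetic import HET, HOM_ALT, MISSING

_AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass
class ScoreParams:
    deleteriousness_normalizer: float = 100.0
    af_floor: float = 1e-6
    missing_af_policy: str = "cohort_af"  # or "floor"
    hwe_genotype_factor: bool = False  # include the 2 in 2*f_ref*f_alt for hets

    def validate(self) -> None:
        if not 0 < self.af_floor < 0.5:
            raise ConfigError(f"af_floor must be in (0, 0.5), got {self.af_floor}")
        if self.deleteriousness_normalizer <= 0:
            raise ConfigError("deleteriousness_normalizer must be > 0")
        if self.missing_af_policy not in ("cohort_af", "floor"):
            raise ConfigError(f"unknown missing_af_policy {self.missing_af_policy!r}")


@dataclass
class GenePyMatrix:
    genes: list[str]
    participants: list[str]
    scores: np.ndarray  # (n_genes, n_participants), non-negative
    gene_meta: pd.DataFrame  # gene, chrom, n_variants, n_nonzero

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.genes), len(self.participants)):
            raise DataError("score matrix shape does not match gene/participant lists")


def variant_score(
    d: float, f_alt: float, zygosity: str, params: ScoreParams | None = None
) -> float:
    """Score one variant call. ``d`` is deleteriousness already scaled to [0,1]."""
    p = params or ScoreParams()
    if zygosity in ("hom_ref", "hemi_ref", "missing"):
        return 0.0
    if not 0.0 < f_alt < 1.0:
        raise DataError(f"allele frequency {f_alt} outside (0,1) after flooring")
    if not 0.0 <= d <= 1.0:
        raise DataError(f"deleteriousness {d} outside [0,1]")
    if zygosity == "het":
        prod = (1.0 - f_alt) * f_alt
        if p.hwe_genotype_factor:
            prod *= 2.0
        return d * -math.log10(prod)
    if zygosity == "hom_alt":
        return d * -math.log10(f_alt * f_alt)
    if zygosity == "hemi_alt":
        return d * -math.log10(f_alt)
    raise DataError(f"unknown zygosity {zygosity!r}")


def gene_score(calls: list[tuple[float, float, str]], params: ScoreParams | None = None) -> float:
    """Sum of variant scores for one participant's calls in one gene.

    ``calls`` is a list of (d, f_alt, zygosity) triples; order-independent.
    """
    return float(sum(variant_score(d, f, z, params) for d, f, z in calls))


def effective_af(
    af: np.ndarray, genotypes: np.ndarray, hemi_mask: np.ndarray | None, params: ScoreParams
) -> np.ndarray:
    """Population AF with the missing-AF policy and floor applied.

    Missing frequencies fall back to the within-cohort alternate-allele
    frequency (policy ``cohort_af``) or to ``af_floor`` (policy ``floor``).
    """
    af = np.asarray(af, dtype=float).copy()
    missing = np.isnan(af)
    if missing.any():
        if params.missing_af_policy == "floor":
            af[missing] = params.af_floor
        else:
            g = genotypes[missing]
            called = g != MISSING
            if hemi_mask is not None:
                copies = np.where(hemi_mask[missing], np.clip(g, 0, 1), g)
                denom = (called * np.where(hemi_mask[missing], 1, 2)).sum(axis=1)
            else:
                copies = g
                denom = 2 * called.sum(axis=1)
            alt = np.where(called, np.clip(copies, 0, None), 0).sum(axis=1)
            af[missing] = np.divide(alt, denom, out=np.zeros_like(af[missing]), where=denom > 0)
    return np.clip(af, params.af_floor, 1.0 - params.af_floor)


def build_matrix(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    participants: list[str],
    sex: np.ndarray | None = None,
    params: ScoreParams | None = None,
) -> GenePyMatrix:
    """Aggregate QC-passing variant scores into a genes x participants matrix.

    ``variants`` must carry gene, chrom, cadd_phred and af columns and be
    row-aligned with ``genotypes``. Males on chrX are scored as hemizygous
    (single observed allele) whenever they carry any alternate call.
    """
    p = params or ScoreParams()
    p.validate()
    n_part = len(participants)
    genes = list(pd.unique(variants["gene"])) if len(variants) else []
    g_index = {g: i for i, g in enumerate(genes)}
    scores = np.zeros((len(genes), n_part))

    chrom = variants["chrom"].astype(str).str.removeprefix("chr").to_numpy() if len(variants) else np.array([])
    is_x = chrom == "X"
    male = (np.asarray(sex) == "male") if sex is not None else np.zeros(n_part, dtype=bool)

    if len(variants):
        d = np.clip(
            pd.to_numeric(variants["cadd_phred"], errors="coerce").to_numpy()
            / p.deleteriousness_normalizer,
            0.0,
            1.0,
        )
        af = effective_af(
            variants["af"].to_numpy(), genotypes, is_x[:, None] & male[None, :], p
        )
    else:
        d = af = np.array([])

    for v in range(len(variants)):
        g = genotypes[v]
        row = scores[g_index[variants["gene"].iat[v]]]
        f = af[v]
        s_het = d[v] * -math.log10(((1 - f) * f) * (2.0 if p.hwe_genotype_factor else 1.0))
        s_hom = d[v] * -math.log10(f * f)
        s_hemi = d[v] * -math.log10(f)
        if is_x[v]:
            alt = g > 0
            hemi = alt & male
            row += np.where(hemi, s_hemi, 0.0)
            row += np.where(alt & ~male & (g == HET), s_het, 0.0)
            row += np.where(alt & ~male & (g == HOM_ALT), s_hom, 0.0)
        else:
            row += np.where(g == HET, s_het, 0.0)
            row += np.where(g == HOM_ALT, s_hom, 0.0)

    gene_col = variants["gene"].to_numpy() if len(variants) else np.array([])
    meta = pd.DataFrame(
        {
            "gene": genes,
            "chrom": [chrom[gene_col == g][0] for g in genes],
            "n_variants": [int((gene_col == g).sum()) for g in genes],
            "n_nonzero": [int((scores[g_index[g]] > 0).sum()) for g in genes],
        },
        columns=["gene", "chrom", "n_variants", "n_nonzero"],
    )
    return GenePyMatrix(genes=genes, participants=list(participants), scores=scores, gene_meta=meta)


def refine_gene_set(
    gene_meta: pd.DataFrame,
    exclusion_lists: list[tuple[str, set[str]]] | None = None,
    min_nonzero: int = 5,
) -> tuple[list[str], Ledger]:
    """Drop under-powered and excluded genes; returns (retained, ledger).

    Genes are retained when ``n_nonzero > min_nonzero`` (strictly more) and
    they appear in no exclusion list. Removal accounting is non-overlapping:
    the sparsity cut is applied first, then each exclusion list in order, and
    a gene is counted against the first category that removes it.
    """
    exclusion_lists = exclusion_lists or []
    ledger = Ledger("genes", len(gene_meta))
    remaining = gene_meta.set_index("gene")["n_nonzero"].to_dict()
    sparse = {g for g, nz in remaining.items() if nz <= min_nonzero}
    ledger.exclude(f"<= {min_nonzero} non-zero scores", len(sparse))
    alive = set(remaining) - sparse
    for label, members in exclusion_lists:
        hit = alive & set(members)
        ledger.exclude(label, len(hit))
        alive -= hit
    ledger.check()
    retained = [g for g in gene_meta["gene"] if g in alive]
    return retained, ledger


def split_by_chromosome(gene_meta: pd.DataFrame, retained: list[str]) -> tuple[list[str], list[str]]:
    """Disjoint partition of retained genes into autosomal and X sets."""
    chrom = gene_meta.set_index("gene")["chrom"].astype(str).str.removeprefix("chr").to_dict()
    autosomal, x_genes = [], []
    for g in retained:
        c = chrom.get(g)
        if c in _AUTOSOMES:
            autosomal.append(g)
        elif c == "X":
            x_genes.append(g)
        else:
            raise DataError(f"gene {g!r} has unknown chromosome label {c!r}")
    return autosomal, x_genes
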