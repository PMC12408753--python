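"""Readers and writers for the pipeline's on-disk formats.

VCF parsing goes through :mod:`cyvcf2`; multi-allelic records are split into
one biallelic row per alternate allele with allele-specific AD. Tabular
formats (annotation, phenotype, kinship, gene lists, GMT gene sets, score
matrices) are plain TSV/text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class VariantCalls:
    """Per-variant site table plus aligned genotype/depth matrices.

    ``genotypes`` uses codes 0 = hom-ref, 1 = het, 2 = hom-alt (or
    hemizygous-alt for haploid calls), -1 = missing; rows follow ``sites``,
    columns follow ``samples``.
    """

    sites: pd.DataFrame  # chrom, pos, ref, alt
    samples: list[str]
    genotypes: np.ndarray  # int8, (n_sites, n_samples)
    depth: np.ndarray  # int32
    alt_depth: np.ndarray  # int32


def read_vcf(path: str | Path) -> VariantCalls:
    """Read a multi-sample VCF (GT/DP/AD), splitting multi-allelic sites."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows, genos, dps, ads = [], [], [], []
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1] if len(g) > 2 else g[0]] for g in gts], dtype=np.int16)
        dp = var.format("DP")
        dp = np.zeros(len(samples), dtype=np.int32) if dp is None else dp[:, 0].astype(np.int32)
        ad = var.format("AD")
        for k, alt in enumerate(var.ALT, start=1):
            code = (alleles == k).sum(axis=1).astype(np.int8)
            code[(alleles < 0).any(axis=1)] = -1
            alt_dp = (
                np.zeros(len(samples), dtype=np.int32)
                if ad is None
                else np.clip(ad[:, k], 0, None).astype(np.int32)
            )
            rows.append((var.CHROM, var.POS, var.REF, alt))
            genos.append(code)
            dps.append(np.clip(dp, 0, None))
            ads.append(alt_dp)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n = len(sites)
    shape = (n, len(samples))
    return VariantCalls(
        sites=sites,
        samples=samples,
        genotypes=np.vstack(genos) if n else np.empty(shape, dtype=np.int8),
        depth=np.vstack(dps) if n else np.empty(shape, dtype=np.int32),
        alt_depth=np.vstack(ads) if n else np.empty(shape, dtype=np.int32),
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Variant annotation TSV: chrom, pos, ref, alt, gene, cadd_phred, af.

    An empty ``af`` field means the variant has no population frequency.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "cadd_phred", "af"}
    missing = required - set(ann.columns)
    if missing:
        raise DataError(f"annotation table missing columns: {sorted(missing)}")
    ann["af"] = pd.to_numeric(ann["af"], errors="coerce")
    return ann


def annotate_calls(calls: VariantCalls, annotation: pd.DataFrame) -> pd.DataFrame:
    """Join the annotation onto the site table (left join on chrom,pos,ref,alt).

    Returns the merged per-variant table, row-aligned with the call matrices.
    Variants without an annotation row get NaN gene/cadd/af and are dropped
    by QC's CADD filter.
    """
    merged = calls.sites.merge(annotation, on=["chrom", "pos", "ref", "alt"], how="left")
    if len(merged) != len(calls.sites):
        raise DataError("annotation table has duplicate (chrom,pos,ref,alt) rows")
    return merged


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV; one row per LDL measurement, '.' marks missing fields."""
    ph = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "med_codes": str})
    ph["ldl_mmol_l"] = pd.to_numeric(ph["ldl_mmol_l"].replace(".", np.nan), errors="coerce")
    ph["assay_date"] = ph["assay_date"].replace(".", np.nan)
    if "reproducible" not in ph.columns:
        ph["reproducible"] = 1
    return ph


def read_kinship(path: str | Path) -> pd.DataFrame:
    k = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    if len(k) and (k["id1"] == k["id2"]).any():
        raise DataError("kinship pair with id1 == id2")
    return k


def read_gene_list(path: str | Path) -> set[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


read_drug_codes = read_gene_list  # same one-item-per-line format


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        name, members = parts[0], [g for g in parts[2:] if g]
        sets[name] = list(dict.fromkeys(members))  # dedupe, keep order
    return sets


def write_matrix_tsv(path: str | Path, genes: list[str], participants: list[str], scores: np.ndarray) -> None:
    pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=participants).to_csv(
        path, sep="\t", float_format="%.6g"
    )


def read_matrix_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), list(df.columns), df.to_numpy(dtype=float)
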