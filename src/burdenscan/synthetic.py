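"""Synthetic exome-cohort generator.

Emulates the statistical structure the burden pipeline assumes: multi-sample
variant calls drawn under Hardy–Weinberg equilibrium with realistic allele
frequency and CADD-Phred spectra, per-call read depths and allelic balances
(with a configurable fraction of heterozygous calls constructed to fail the
DP/AB filters), an age-dependent LDL-C phenotype with optional planted
gene–phenotype effects, medication flags, related participant pairs, and the
bookkeeping truth needed to validate every downstream exclusion step.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

# genotype codes used throughout the package
HOM_REF = 0
HET = 1
HOM_ALT = 2  # reinterpreted as hemizygous-alt for males on chrX
MISSING = -1

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedEffect:
    """A causal gene planted into the phenotype.

    ``effect_mmol_l`` is added to the LDL-C of every carrier, where a carrier
    by default is any participant with at least one alternate allele in a
    variant of the gene with CADD-Phred >= ``carrier_min_cadd``.
    """

    gene: str
    effect_mmol_l: float
    carrier_min_cadd: float = 20.0
    target_carrier_frac: float = 0.015  # generator aims carriers at ~1.5% of the cohort


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the cohort the pipeline was designed around: an adult
    biobank with LDL-C mean ~3.7 mmol/L (SD ~0.8), a mild positive age trend,
    roughly 16% of participants on LDL-altering medication (shifting LDL-C
    down ~0.9 mmol/L), 28% with no medication information, and allele
    frequencies log-uniform across five orders of magnitude.
    """

    n_participants: int = 2000
    n_genes: int = 100
    variants_per_gene: int | tuple = 4  # int, or ("poisson", lam) with a floor of 1
    af_spectrum: tuple = ("loguniform", 1e-5, 0.5)
    cadd_spectrum: tuple = ("uniform", 0.0, 50.0)
    frac_missing_af: float = 0.05
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    age_range: tuple[int, int] = (40, 70)
    age_slope: float = 0.02  # mmol/L per year
    baseline_ldl: float = 3.7  # mmol/L at age_ref
    age_ref: float = 57.0
    pheno_noise_sd: float = 0.8
    frac_on_drug: float = 0.16
    drug_effect: float = -0.9  # mmol/L shift for medicated participants
    frac_med_missing: float = 0.28  # no medication data at all
    frac_related_pairs: float = 0.03  # pairs per participant
    missing_pheno_rate: float = 0.05
    frac_nonreproducible: float = 0.01
    frac_multi_measure: float = 0.10
    frac_x_genes: float = 0.05
    mean_depth: float = 30.0
    het_fail_rate: float = 0.02  # het calls constructed to fail DP or AB
    frac_high_missing_sites: float = 0.01
    high_missing_rate: float = 0.20
    frac_hwe_violation: float = 0.0
    hwe_violation_f: float = 0.6  # inbreeding-style excess homozygosity
    af_noise_sd: float = 0.0  # lognormal sd on annotated AF
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name in (
            "frac_missing_af", "frac_on_drug", "frac_med_missing", "frac_related_pairs",
            "missing_pheno_rate", "frac_nonreproducible", "frac_multi_measure",
            "frac_x_genes", "het_fail_rate", "frac_high_missing_sites",
            "high_missing_rate", "frac_hwe_violation",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ConfigError("age_range must be (min, max) with 0 <= min <= max")
        if self.pheno_noise_sd < 0:
            raise ConfigError("pheno_noise_sd must be >= 0")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        kind = self.af_spectrum[0]
        if kind not in ("loguniform", "uniform", "fixed"):
            raise ConfigError(f"af_spectrum kind {kind!r} not recognised")
        if self.cadd_spectrum[0] not in ("uniform", "fixed"):
            raise ConfigError(f"cadd_spectrum kind {self.cadd_spectrum[0]!r} not recognised")


@dataclass
class SimResult:
    """In-memory synthetic cohort: everything the pipeline consumes plus truth."""

    config: SimConfig
    participants: list[str]
    sex: np.ndarray  # "female"/"male"
    variants: pd.DataFrame  # chrom,pos,ref,alt,gene,cadd_phred,af (annotated),af_true,...
    genotypes: np.ndarray  # (n_variants, n_participants) int8 codes
    depth: np.ndarray  # int16
    alt_depth: np.ndarray  # int16
    phenotypes: pd.DataFrame  # one row per LDL measurement
    kinship: pd.DataFrame  # id1,id2,degree
    truth: pd.DataFrame  # gene,effect,n_carriers for planted genes
    drug_codes: list[str]
    qc_truth: dict  # per-filter forced-failure bookkeeping
    ages: np.ndarray = None
    ldl: np.ndarray = None
    carrier_sets: dict = None  # gene -> boolean carrier vector


@dataclass
class SyntheticBundle:
    """Paths of a written bundle."""

    vcf_path: Path
    annotation_path: Path
    phenotype_path: Path
    kinship_path: Path
    truth_path: Path
    drug_codes_path: Path
    qc_truth_path: Path


def _draw(spectrum: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spectrum[0]
    if kind == "loguniform":
        lo, hi = spectrum[1], spectrum[2]
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))
    if kind == "uniform":
        return rng.uniform(spectrum[1], spectrum[2], size)
    if kind == "fixed":
        return np.full(size, float(spectrum[1]))
    raise ConfigError(f"unknown distribution spec {spectrum!r}")


def _variant_counts(spec, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, (int, np.integer)):
        if spec < 1:
            raise ConfigError("variants_per_gene must be >= 1")
        return np.full(n_genes, int(spec))
    if isinstance(spec, tuple) and spec[0] == "poisson":
        return np.maximum(1, rng.poisson(spec[1], n_genes))
    raise ConfigError(f"variants_per_gene spec {spec!r} not recognised")


def make_gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene symbols with chromosome assignments (autosomes 1..22 plus chrX)."""
    names = [f"G{i:04d}" for i in range(config.n_genes)]
    n_x = int(round(config.frac_x_genes * config.n_genes))
    chroms = [str(1 + i % 22) for i in range(config.n_genes - n_x)] + ["X"] * n_x
    return pd.DataFrame({"gene": names, "chrom": chroms})


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Draw per-variant genotype vectors under HWE with call-level noise.

    Returns ``(variants, genotypes, depth, alt_depth, sex, qc_truth)``.
    Genotype counts at a variant of frequency f are multinomial with
    probabilities ((1-f)^2, 2f(1-f), f^2); males on chrX carry a single
    allele (alt with probability f, encoded HOM_ALT and reinterpreted as
    hemizygous downstream).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    genes = make_gene_table(config, rng)
    counts = _variant_counts(config.variants_per_gene, config.n_genes, rng)
    v_gene = np.repeat(np.arange(config.n_genes), counts)
    n_var = len(v_gene)

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    is_male = sex == "male"

    af = _draw(config.af_spectrum, n_var, rng)
    af = np.clip(af, 1e-9, 0.5)
    cadd = np.clip(_draw(config.cadd_spectrum, n_var, rng), 0.0, 60.0)

    # planted genes are made detectable by construction: their variants pass
    # the deleteriousness filter and their joint HWE carrier probability
    # 1-(1-f)^(2k) is aimed at target_carrier_frac
    gene_names = genes["gene"].to_numpy()
    for eff in config.planted_effects:
        if eff.gene not in gene_names:
            raise ConfigError(f"planted gene {eff.gene!r} absent from gene map")
        rows = np.flatnonzero(gene_names[v_gene] == eff.gene)
        k = len(rows)
        cadd[rows] = rng.uniform(max(25.0, eff.carrier_min_cadd + 5.0), 45.0, k)
        af[rows] = 1.0 - (1.0 - eff.target_carrier_frac) ** (1.0 / (2.0 * k))

    # per-gene positions: genes sit on 1 Mb blocks of their chromosome
    chrom = genes["chrom"].to_numpy()[v_gene]
    blk = genes.groupby("chrom").cumcount().to_numpy()[v_gene]
    offset = np.concatenate([[0], np.cumsum(counts)])[:-1]
    pos = (blk + 1) * 1_000_000 + (np.arange(n_var) - offset[v_gene]) + 1
    ref_idx = rng.integers(0, 4, n_var)
    alt_idx = (ref_idx + rng.integers(1, 4, n_var)) % 4

    hwe_bad = rng.random(n_var) < config.frac_hwe_violation
    f_in = np.where(hwe_bad, config.hwe_violation_f, 0.0)
    p_hom_ref = (1 - af) ** 2 + f_in * af * (1 - af)
    p_het = 2 * af * (1 - af) * (1 - f_in)

    u = rng.random((n_var, n))
    geno = (
        (u >= p_hom_ref[:, None]).astype(np.int8)
        + (u >= (p_hom_ref + p_het)[:, None]).astype(np.int8)
    )
    # males on X: single allele, alt with probability f
    on_x = chrom == "X"
    if on_x.any():
        u_x = rng.random((int(on_x.sum()), int(is_male.sum())))
        hemi = np.where(u_x < af[on_x][:, None], HOM_ALT, HOM_REF).astype(np.int8)
        gx = geno[on_x]
        gx[:, is_male] = hemi
        geno[on_x] = gx

    depth = rng.poisson(config.mean_depth, (n_var, n)).astype(np.int16)
    frac_alt = np.where(geno == HET, 0.5, np.where(geno == HOM_ALT, 1.0, 0.0))
    alt_depth = rng.binomial(depth.astype(np.int64), frac_alt).astype(np.int16)

    # keep natural het calls clear of the DP/AB thresholds, then force a
    # designated fraction to fail so QC removal counts are exactly known
    het = geno == HET
    depth[het & (depth < 8)] = 8
    min_alt = np.ceil(0.15 * depth).astype(np.int16)
    lo = het & (alt_depth < min_alt)
    alt_depth[lo] = min_alt[lo]
    alt_depth = np.minimum(alt_depth, depth)

    fail = het & (rng.random((n_var, n)) < config.het_fail_rate)
    fail_mode = rng.random((n_var, n)) < 0.5  # True: low depth, False: low AB
    dp_fail = fail & fail_mode
    ab_fail = fail & ~fail_mode
    depth[dp_fail] = rng.integers(0, 8, int(dp_fail.sum())).astype(np.int16)
    alt_depth[dp_fail] = np.minimum(alt_depth[dp_fail], depth[dp_fail])
    alt_depth[ab_fail] = np.ceil(0.15 * depth[ab_fail]).astype(np.int16) - 1
    np.clip(alt_depth, 0, None, out=alt_depth)

    high_miss = rng.random(n_var) < config.frac_high_missing_sites
    forced_missing = np.zeros_like(geno, dtype=bool)
    if high_miss.any():
        forced_missing[high_miss] = rng.random((int(high_miss.sum()), n)) < config.high_missing_rate
        geno[forced_missing] = MISSING
        depth[forced_missing] = 0
        alt_depth[forced_missing] = 0

    af_annot = af.copy()
    if config.af_noise_sd > 0:
        af_annot = np.clip(af_annot * rng.lognormal(0.0, config.af_noise_sd, n_var), 1e-9, 0.999)
    missing_af = rng.random(n_var) < config.frac_missing_af
    af_annot[missing_af] = np.nan

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "gene": genes["gene"].to_numpy()[v_gene],
            "cadd_phred": np.round(cadd, 2),
            "af": af_annot,
            "af_true": af,
            "hwe_violator": hwe_bad,
            "high_missing_site": high_miss,
        }
    )
    qc_truth = {
        "n_hwe_violators": int(hwe_bad.sum()),
        "n_high_missing_sites": int(high_miss.sum()),
    }
    return variants, geno, depth, alt_depth, sex, qc_truth


def _count_failing_hets(geno: np.ndarray, depth: np.ndarray, alt_depth: np.ndarray) -> dict:
    """Recount genotype-level failures from the matrices themselves.

    Heterozygous calls are constructed to pass DP/AB unless deliberately
    failed, so hets below either threshold are exactly the planted failures.
    """
    het = geno == HET
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(depth > 0, alt_depth / np.maximum(depth, 1), 0.0)
    fail = het & ((depth < 8) | (ab < 0.15))
    return {
        "n_het_forced_fail": int(fail.sum()),
        "het_fail_per_variant": fail.sum(axis=1).tolist(),
        "forced_missing_per_variant": (geno == MISSING).sum(axis=1).tolist(),
    }


def carrier_vector(
    gene: str, variants: pd.DataFrame, genotypes: np.ndarray, min_cadd: float = 20.0
) -> np.ndarray:
    """Participants carrying >=1 alt allele of any variant of ``gene`` with CADD >= min_cadd."""
    rows = np.flatnonzero((variants["gene"] == gene) & (variants["cadd_phred"] >= min_cadd))
    if len(rows) == 0:
        return np.zeros(genotypes.shape[1], dtype=bool)
    return (genotypes[rows] > 0).any(axis=0)


def simulate_phenotype(
    config: SimConfig,
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    ages: np.ndarray,
    drug_flags: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """LDL-C per participant.

    LDL = baseline + age_slope*(age - age_ref) + sum(planted effects for
    carriers) + drug_effect*drug_flag + N(0, pheno_noise_sd), floored at
    0.3 mmol/L.
    """
    n = genotypes.shape[1]
    if len(ages) != n or len(drug_flags) != n:
        raise ConfigError("ages/drug_flags not conformable with genotype matrix")
    ldl = config.baseline_ldl + config.age_slope * (ages - config.age_ref)
    known_genes = set(variants["gene"])
    carriers = {}
    for eff in config.planted_effects:
        if eff.gene not in known_genes:
            raise ConfigError(f"planted gene {eff.gene!r} absent from gene map")
        c = carrier_vector(eff.gene, variants, genotypes, eff.carrier_min_cadd)
        carriers[eff.gene] = c
        ldl = ldl + eff.effect_mmol_l * c
    ldl = ldl + config.drug_effect * drug_flags
    if config.pheno_noise_sd > 0:
        ldl = ldl + rng.normal(0.0, config.pheno_noise_sd, n)
    return np.maximum(ldl, 0.3), carriers


DRUG_CODES = [f"drug{k:03d}" for k in range(8)]  # synthetic LDL-altering medication codes


def simulate_cohort(config: SimConfig) -> SimResult:
    """Run the full generator and return the in-memory cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants, geno, depth, alt_depth, sex, qc_truth = simulate_genotypes(config, rng)
    n = config.n_participants
    pids = [f"P{i:06d}" for i in range(n)]

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, n)
    assay_year = rng.integers(2006, 2011, n)
    birth_year = assay_year - ages
    month = rng.integers(1, 13, n)
    day = rng.integers(1, 29, n)

    med_missing = rng.random(n) < config.frac_med_missing
    on_drug = (~med_missing) & (rng.random(n) < config.frac_on_drug / max(1e-12, 1 - config.frac_med_missing))
    drug_pick = rng.integers(0, len(DRUG_CODES), n)

    # related pairs first, so phenotypes and QC truth see the final genotypes:
    # B duplicates A's calls (autosomes only when sexes differ) with a few
    # reversions to hom-ref; ages are forced to differ so "retain youngest"
    # is always decidable.
    n_pairs = int(round(config.frac_related_pairs * n))
    pair_ids = rng.permutation(n)[: 2 * n_pairs]
    autosomal_rows = (variants["chrom"] != "X").to_numpy()
    k_rows = []
    for a, b in zip(pair_ids[:n_pairs], pair_ids[n_pairs:]):
        rows = np.ones(len(variants), dtype=bool) if sex[a] == sex[b] else autosomal_rows
        geno[np.ix_(rows, [b])] = geno[np.ix_(rows, [a])]
        depth[np.ix_(rows, [b])] = depth[np.ix_(rows, [a])]
        alt_depth[np.ix_(rows, [b])] = alt_depth[np.ix_(rows, [a])]
        flip = rows & (rng.random(geno.shape[0]) < 0.02)
        geno[flip, b] = HOM_REF
        alt_depth[flip, b] = 0
        depth[flip, b] = np.maximum(depth[flip, b], 8)
        if ages[b] == ages[a]:
            ages[b] = min(ages[a] + 1, config.age_range[1] + 1)
            birth_year[b] = assay_year[b] - ages[b]
        k_rows.append((pids[min(a, b)], pids[max(a, b)], int(rng.integers(1, 4))))
    kinship = pd.DataFrame(k_rows, columns=["id1", "id2", "degree"])

    ldl, carriers = simulate_phenotype(config, geno, variants, ages, on_drug.astype(float), rng)

    # phenotype table: one row per measurement
    miss_pheno = rng.random(n) < config.missing_pheno_rate
    nonrepro = (~miss_pheno) & (rng.random(n) < config.frac_nonreproducible)
    multi = (~miss_pheno) & (~nonrepro) & (rng.random(n) < config.frac_multi_measure)
    med_str = np.where(med_missing, ".", np.where(on_drug, np.array(DRUG_CODES)[drug_pick], "NONE"))
    rows = []
    for i in range(n):
        base = dict(
            participant_id=pids[i], sex=sex[i], birth_year=int(birth_year[i]),
            med_codes=med_str[i],
        )
        if miss_pheno[i]:
            rows.append({**base, "ldl_mmol_l": np.nan, "assay_date": ".", "reproducible": 1})
            continue
        date = f"{assay_year[i]}-{month[i]:02d}-{day[i]:02d}"
        rows.append({
            **base, "ldl_mmol_l": round(float(ldl[i]), 4), "assay_date": date,
            "reproducible": 0 if nonrepro[i] else 1,
        })
        if multi[i]:
            rows.append({
                **base,
                "ldl_mmol_l": round(float(ldl[i] + rng.normal(0, 0.2)), 4),
                "assay_date": f"{assay_year[i] + int(rng.integers(1, 4))}-{month[i]:02d}-{day[i]:02d}",
                "reproducible": 1,
            })
    phenotypes = pd.DataFrame(rows)

    truth = pd.DataFrame(
        [
            {"gene": e.gene, "effect": e.effect_mmol_l, "n_carriers": int(carriers[e.gene].sum())}
            for e in config.planted_effects
        ],
        columns=["gene", "effect", "n_carriers"],
    )
    qc_truth = dict(qc_truth)
    qc_truth.update(_count_failing_hets(geno, depth, alt_depth))
    qc_truth.update(
        n_missing_pheno=int(miss_pheno.sum()),
        n_nonreproducible=int(nonrepro.sum()),
        n_related_pairs=n_pairs,
        n_on_drug=int(on_drug.sum()),
        n_med_missing=int(med_missing.sum()),
    )
    return SimResult(
        config=config, participants=pids, sex=sex, variants=variants, genotypes=geno,
        depth=depth, alt_depth=alt_depth, phenotypes=phenotypes, kinship=kinship,
        truth=truth, drug_codes=list(DRUG_CODES), qc_truth=qc_truth,
        ages=ages, ldl=ldl, carrier_sets=carriers,
    )


def _vcf_lines(sim: SimResult) -> list[str]:
    v = sim.variants
    out = ["##fileformat=VCFv4.2", "##source=burdenscan-synthetic"]
    for c in pd.unique(v["chrom"]):
        out.append(f"##contig=<ID={c}>")
    out += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sim.participants),
    ]
    gt_str = {MISSING: "./.", HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}
    for i in range(len(v)):
        g, d, a = sim.genotypes[i], sim.depth[i], sim.alt_depth[i]
        fields = [
            f"{gt_str[int(gi)]}:{int(di)}:{int(di) - int(ai)},{int(ai)}"
            for gi, di, ai in zip(g, d, a)
        ]
        out.append(
            f"{v['chrom'].iat[i]}\t{v['pos'].iat[i]}\t.\t{v['ref'].iat[i]}\t{v['alt'].iat[i]}"
            f"\t.\tPASS\t.\tGT:DP:AD\t" + "\t".join(fields)
        )
    return out


def write_bundle(config: SimConfig, out_dir: str | Path) -> SyntheticBundle:
    """Generate a cohort and serialise it as a plain-text bundle.

    Emits a multi-sample VCFv4.2 (FORMAT GT:DP:AD), annotation / phenotype /
    kinship / planted-truth TSVs, the LDL-altering drug-code list, and a JSON
    of genotype-level failure counts for bookkeeping tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(config)
    bundle = SyntheticBundle(
        vcf_path=out / "cohort.vcf",
        annotation_path=out / "annotation.tsv",
        phenotype_path=out / "phenotypes.tsv",
        kinship_path=out / "kinship.tsv",
        truth_path=out / "truth.tsv",
        drug_codes_path=out / "drug_codes.txt",
        qc_truth_path=out / "qc_truth.json",
    )
    bundle.vcf_path.write_text("\n".join(_vcf_lines(sim)) + "\n")
    ann = sim.variants[["chrom", "pos", "ref", "alt", "gene", "cadd_phred", "af"]].copy()
    ann["af"] = ann["af"].map(lambda x: "" if pd.isna(x) else f"{x:.8g}")
    ann.to_csv(bundle.annotation_path, sep="\t", index=False)
    ph = sim.phenotypes.copy()
    ph["ldl_mmol_l"] = ph["ldl_mmol_l"].map(lambda x: "." if pd.isna(x) else f"{x:.4f}")
    ph.to_csv(bundle.phenotype_path, sep="\t", index=False)
    sim.kinship.to_csv(bundle.kinship_path, sep="\t", index=False)
    sim.truth.to_csv(bundle.truth_path, sep="\t", index=False)
    bundle.drug_codes_path.write_text("\n".join(sim.drug_codes) + "\n")
    bundle.qc_truth_path.write_text(json.dumps(sim.qc_truth, indent=1, sort_keys=True))
    return bundle
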