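"""Worked accounting examples and calibration studies.

The cohort- and gene-set-accounting functions replay the published UK
Biobank-scale bookkeeping through the package's ledger machinery (the
printed step counts are inputs; the arithmetic and conservation checks are
computed). The calibration studies run the full synthetic pipeline: a null
cohort to measure the bootstrap statistic's type-I behaviour, and a
planted-effect cohort to measure recovery power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genepy import refine_gene_set
from .ledger import Ledger
from .pipeline import run_pipeline
from .scan import ScanConfig
from .synthetic import PlantedEffect, SimConfig, simulate_cohort

# published exclusion-cascade counts for the 200,620-exome cohort
COHORT_START = 200_620
COHORT_STEPS = (
    ("no sequencing data", 18),
    ("missing LDL-C", 10_008),
    ("related (degree <= 3)", 13_452),
)
NOT_ON_DRUG = 99_137
ON_DRUG = 28_104
MED_UNKNOWN = 49_901
STRATA_SPLIT = {"under60": 50_563, "over60_or_equal": 98_443, "missing_age": 32}

# published gene-set refinement counts
GENES_START = 24_625
GENE_REMOVALS = (
    ("<= 5 non-zero scores", 933),
    ("olfactory", 359),
    ("poorly annotated", 3_277),
    ("Y chromosome", 25),
)


def cohort_accounting() -> dict:
    """Replay the participant exclusion cascade and drug-group merge."""
    ledger = Ledger("participants", COHORT_START)
    for label, n in COHORT_STEPS:
        ledger.exclude(label, n)
    retained = ledger.retained
    ledger.exclude("on LDL-altering medication", ON_DRUG)
    ledger.exclude("unknown-medication group set aside", MED_UNKNOWN)
    ledger.add("unknown-medication group merged back (K-S compatible)", MED_UNKNOWN)
    ledger.check()
    analysis = ledger.retained
    assert analysis == NOT_ON_DRUG + MED_UNKNOWN
    strata_total = sum(STRATA_SPLIT.values())
    return {
        "retained_after_exclusions": retained,
        "analysis_cohort": analysis,
        "strata_total": strata_total,
        "strata_reconcile": strata_total == analysis,
        "ledger": ledger.to_frame(),
    }


def gene_refinement_accounting() -> dict:
    """Replay the gene-set refinement through refine_gene_set itself."""
    rng = np.random.default_rng(0)
    names = [f"GENE{i:05d}" for i in range(GENES_START)]
    n_nonzero = np.full(GENES_START, 100)
    idx = rng.permutation(GENES_START)
    lists, at = [], 0
    sparse_n = GENE_REMOVALS[0][1]
    n_nonzero[idx[:sparse_n]] = rng.integers(0, 6, sparse_n)  # <= 5 non-zero
    at = sparse_n
    for label, count in GENE_REMOVALS[1:]:
        lists.append((label, {names[i] for i in idx[at: at + count]}))
        at += count
    chrom = np.full(GENES_START, "1", dtype=object)
    chrom[[i for i in idx[at - GENE_REMOVALS[-1][1]: at]]] = "Y"
    meta = pd.DataFrame({"gene": names, "chrom": chrom, "n_variants": 1,
                         "n_nonzero": n_nonzero})
    retained, ledger = refine_gene_set(meta, lists, min_nonzero=5)
    return {"retained": len(retained), "ledger": ledger.to_frame()}


def null_calibration(
    seed: int,
    n_seeds: int = 20,
    n_participants: int = 2_000,
    n_genes: int = 500,
    n_iterations: int = 100,
) -> dict:
    """Null-cohort behaviour of the bootstrap statistic.

    Returns the fraction of tested genes with mean_p below 0.05/0.01 for the
    first seed, the 3-SE binomial bands around those levels, and the share
    of seeds with zero FDR-significant genes at 0.01.
    """
    frac = {}
    zero_sig_seeds = 0
    for i in range(n_seeds):
        s = (seed + 7919 * i) % (2**31)
        sim = simulate_cohort(SimConfig(n_participants=n_participants,
                                        n_genes=n_genes, seed=s))
        res = run_pipeline(
            sim,
            scan_config=ScanConfig(n_iterations=n_iterations, rng_seed=s,
                                   strata=("combined",)),
        )
        df = res.scan_results
        df = df[(df["chrom_class"] == "autosomal") & df["mean_p"].notna()]
        if int(df["significant"].sum()) == 0:
            zero_sig_seeds += 1
        if i == 0:
            n_tested = len(df)
            for alpha in (0.05, 0.01):
                frac[alpha] = float((df["mean_p"] < alpha).mean())
            se = {a: float(np.sqrt(a * (1 - a) / n_tested)) for a in (0.05, 0.01)}
    return {
        "n_tested": n_tested,
        "frac_below_005": frac[0.05],
        "frac_below_001": frac[0.01],
        "se_005": se[0.05],
        "se_001": se[0.01],
        "zero_fdr_seed_fraction": zero_sig_seeds / n_seeds,
        "n_seeds": n_seeds,
    }


PLANTED_GENE = "G0100"


def planted_recovery(
    seed: int,
    n_seeds: int = 20,
    n_participants: int = 10_000,
    n_genes: int = 200,
    effect_mmol_l: float = 1.5,
    n_iterations: int = 1_000,
) -> dict:
    """Recovery of one planted gene among null genes.

    The planted gene's carriers (~top percentile) have LDL-C shifted by
    ``effect_mmol_l``; success on a seed means the gene is both top-ranked
    by mean_p and FDR-significant at 0.01 in the combined analysis.
    """
    hits = top_ranked = 0
    for i in range(n_seeds):
        s = (seed + 104_729 * i) % (2**31)
        sim = simulate_cohort(
            SimConfig(
                n_participants=n_participants,
                n_genes=n_genes,
                seed=s,
                planted_effects=[PlantedEffect(PLANTED_GENE, effect_mmol_l)],
            )
        )
        res = run_pipeline(
            sim,
            scan_config=ScanConfig(n_iterations=n_iterations, rng_seed=s,
                                   strata=("combined",)),
        )
        df = res.scan_results
        df = df[(df["chrom_class"] == "autosomal") & df["mean_p"].notna()]
        df = df.reset_index(drop=True)
        row = df[df["gene"] == PLANTED_GENE]
        is_top = len(df) > 0 and df.iloc[0]["gene"] == PLANTED_GENE
        sig = bool(len(row) and row.iloc[0]["significant"])
        top_ranked += int(is_top)
        hits += int(is_top and sig)
    return {
        "n_seeds": n_seeds,
        "recovery_rate": hits / n_seeds,
        "top_ranked_rate": top_ranked / n_seeds,
    }


def score_property_sweep(seed: int = 0, n_cases: int = 1_000) -> dict:
    """Randomised sweep of the burden score's structural properties.

    Checks monotonicity in deleteriousness and rarity, zygosity ordering,
    additivity of the gene score, and zero-set correctness; returns
    violation counts (all zero for a correct implementation).
    """
    from .genepy import gene_score, variant_score
    from .synthetic import HET, HOM_ALT, HOM_REF

    rng = np.random.default_rng(seed)
    viol = {"monotone_d": 0, "monotone_rarity": 0, "zygosity": 0,
            "additivity": 0, "zero_set": 0}
    for _ in range(n_cases):
        d = rng.uniform(0.01, 1.0)
        f = rng.uniform(1e-6, 0.4999)
        s_het = variant_score(d, f, "het")
        if variant_score(min(d * 1.1, 1.0), f, "het") < s_het and d * 1.1 <= 1.0:
            viol["monotone_d"] += 1
        if variant_score(d, f * 0.9, "het") <= s_het:
            viol["monotone_rarity"] += 1
        if variant_score(d, f, "hom_alt") < s_het:  # f_alt <= f_ref here
            viol["zygosity"] += 1
        calls = [(rng.uniform(0.01, 1), rng.uniform(1e-6, 0.5), "het")
                 for _ in range(int(rng.integers(1, 5)))]
        total = gene_score(calls)
        parts = sum(variant_score(*c) for c in calls)
        if abs(total - parts) > 1e-10:
            viol["additivity"] += 1
        zyg = rng.choice([HOM_REF, HET, HOM_ALT])
        s = variant_score(d, f, {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}[zyg])
        if (s > 0) != (zyg != HOM_REF):
            viol["zero_set"] += 1
    viol["n_cases"] = n_cases
    return viol
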