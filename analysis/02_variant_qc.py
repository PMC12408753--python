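"""Variant quality control.

Reads the simulated bundle, applies call-level DP/AB filtering and
site-level F_MISSING / exact-HWE / CADD filters, and writes the per-site
stats and the removal ledger.
"""

from pathlib import Path

from burdenscan.pipeline import load_bundle
from burdenscan.variant_qc import apply_qc, qc_summary

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    inputs = load_bundle(SCRATCH / "bundle")
    _, stats, keep, ledger = apply_qc(
        inputs.variants, inputs.genotypes, inputs.depth, inputs.alt_depth,
        sex=inputs.sex,
    )
    sites = inputs.variants[["chrom", "pos", "ref", "alt", "gene"]].join(stats)
    sites.to_csv(ROOT / "qc_sites.tsv", sep="\t", index=False)
    qc_summary(ledger).to_csv(ROOT / "qc_ledger.tsv", sep="\t", index=False)
    print(qc_summary(ledger).to_string(index=False))
    print(f"\n{int(keep.sum())}/{len(inputs.variants)} variants enter scoring "
          f"({stats.attrs['n_genotypes_nulled']} genotype calls nulled).")


if __name__ == "__main__":
    main()
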