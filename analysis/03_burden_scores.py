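"""Per-gene burden scores and gene-set refinement.

Builds the genes x participants burden matrix from QC-passing variants,
drops genes with five or fewer non-zero scores, and writes the matrix,
per-gene metadata and the refinement ledger.
"""

from pathlib import Path

from burdenscan import io
from burdenscan.genepy import build_matrix, refine_gene_set
from burdenscan.pipeline import load_bundle, subset_matrix
from burdenscan.variant_qc import apply_qc

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    inputs = load_bundle(SCRATCH / "bundle")
    geno_f, _, keep, _ = apply_qc(
        inputs.variants, inputs.genotypes, inputs.depth, inputs.alt_depth,
        sex=inputs.sex,
    )
    matrix = build_matrix(
        inputs.variants.loc[keep].reset_index(drop=True), geno_f[keep],
        inputs.participants, sex=inputs.sex,
    )
    retained, ledger = refine_gene_set(matrix.gene_meta)
    matrix = subset_matrix(matrix, retained)
    io.write_matrix_tsv(SCRATCH / "genepy_matrix.tsv", matrix.genes,
                        matrix.participants, matrix.scores)
    matrix.gene_meta.to_csv(ROOT / "gene_meta.tsv", sep="\t", index=False)
    ledger.to_frame().to_csv(ROOT / "gene_refinement_ledger.tsv", sep="\t", index=False)
    print(ledger.to_frame().to_string(index=False))
    print(f"\nmatrix: {len(matrix.genes)} genes x {len(matrix.participants)} participants; "
          f"median non-zero per gene = {matrix.gene_meta['n_nonzero'].median():.0f}")


if __name__ == "__main__":
    main()
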