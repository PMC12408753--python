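"""End-to-end orchestration: inputs -> QC -> scores -> cohort -> scan.

Accepts either an in-memory :class:`~burdenscan.synthetic.SimResult` or a
bundle directory on disk; the analysis drivers, the test-suite and the
acceptance script all run through this module so every path exercises the
same code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cohort import CohortTable, build_cohort
from .genepy import GenePyMatrix, ScoreParams, build_matrix, refine_gene_set
from .ledger import Ledger
from .scan import ScanConfig, run_scan
from .synthetic import SimResult
from .variant_qc import QCThresholds, apply_qc


@dataclass
class PipelineInputs:
    participants: list[str]
    sex: np.ndarray
    variants: pd.DataFrame  # annotated, row-aligned with matrices
    genotypes: np.ndarray
    depth: np.ndarray
    alt_depth: np.ndarray
    phenotypes: pd.DataFrame
    kinship: pd.DataFrame
    drug_codes: set[str]


@dataclass
class PipelineResult:
    qc_ledger: Ledger
    site_stats: pd.DataFrame
    matrix: GenePyMatrix  # refined (tested genes only)
    full_matrix: GenePyMatrix
    refine_ledger: Ledger
    cohort: CohortTable
    scan_results: pd.DataFrame


def load_bundle(bundle_dir: str | Path) -> PipelineInputs:
    """Read a written bundle back into pipeline inputs."""
    d = Path(bundle_dir)
    calls = io.read_vcf(d / "cohort.vcf")
    ann = io.read_annotation(d / "annotation.tsv")
    variants = io.annotate_calls(calls, ann)
    phen = io.read_phenotypes(d / "phenotypes.tsv")
    sex_map = phen.drop_duplicates("participant_id").set_index("participant_id")["sex"]
    sex = np.array([sex_map.get(p, "female") for p in calls.samples])
    return PipelineInputs(
        participants=calls.samples,
        sex=sex,
        variants=variants,
        genotypes=calls.genotypes,
        depth=calls.depth,
        alt_depth=calls.alt_depth,
        phenotypes=phen,
        kinship=io.read_kinship(d / "kinship.tsv"),
        drug_codes=io.read_drug_codes(d / "drug_codes.txt"),
    )


def inputs_from_sim(sim: SimResult) -> PipelineInputs:
    return PipelineInputs(
        participants=sim.participants,
        sex=sim.sex,
        variants=sim.variants,
        genotypes=sim.genotypes,
        depth=sim.depth,
        alt_depth=sim.alt_depth,
        phenotypes=sim.phenotypes,
        kinship=sim.kinship,
        drug_codes=set(sim.drug_codes),
    )


def subset_matrix(matrix: GenePyMatrix, genes: list[str]) -> GenePyMatrix:
    keep = set(genes)
    idx = [i for i, g in enumerate(matrix.genes) if g in keep]
    return GenePyMatrix(
        genes=[matrix.genes[i] for i in idx],
        participants=matrix.participants,
        scores=matrix.scores[idx],
        gene_meta=matrix.gene_meta.iloc[idx].reset_index(drop=True),
    )


def run_pipeline(
    data: SimResult | PipelineInputs | str | Path,
    qc: QCThresholds | None = None,
    score_params: ScoreParams | None = None,
    scan_config: ScanConfig | None = None,
    exclusion_lists: list[tuple[str, set[str]]] | None = None,
    min_nonzero: int = 5,
    run_association: bool = True,
) -> PipelineResult:
    """Run QC, burden scoring, gene-set refinement, cohort assembly and
    (optionally) the association scan."""
    if isinstance(data, SimResult):
        inputs = inputs_from_sim(data)
    elif isinstance(data, (str, Path)):
        inputs = load_bundle(data)
    else:
        inputs = data

    geno_f, stats, keep, qc_ledger = apply_qc(
        inputs.variants, inputs.genotypes, inputs.depth, inputs.alt_depth,
        sex=inputs.sex, thresholds=qc,
    )
    variants_kept = inputs.variants.loc[keep].reset_index(drop=True)
    full_matrix = build_matrix(
        variants_kept, geno_f[keep], inputs.participants, sex=inputs.sex,
        params=score_params,
    )
    retained, refine_ledger = refine_gene_set(
        full_matrix.gene_meta, exclusion_lists, min_nonzero=min_nonzero
    )
    matrix = subset_matrix(full_matrix, retained)
    cohort = build_cohort(
        inputs.phenotypes, inputs.kinship, inputs.drug_codes,
        sequenced_ids=set(inputs.participants),
    )
    results = (
        run_scan(matrix, cohort, scan_config or ScanConfig())
        if run_association
        else pd.DataFrame()
    )
    return PipelineResult(
        qc_ledger=qc_ledger,
        site_stats=stats,
        matrix=matrix,
        full_matrix=full_matrix,
        refine_ledger=refine_ledger,
        cohort=cohort,
        scan_results=results,
    )
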