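"""Burden-score closed forms, matrix construction, gene-set refinement and
the score's monotonicity/additivity/zero-set properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from burdenscan import DataError, ScoreParams, gene_score, variant_score
from burdenscan.genepy import build_matrix, effective_af, refine_gene_set, split_by_chromosome
from burdenscan.synthetic import HET, HOM_ALT, HOM_REF, MISSING


def test_non_carrier_scores_zero():
    assert variant_score(0.9, 0.01, "hom_ref") == 0.0
    assert variant_score(0.9, 0.01, "missing") == 0.0


def test_closed_form_examples():
    # d=1 hom-alt at f=0.01: -log10(1e-4) = 4
    assert variant_score(1.0, 0.01, "hom_alt") == pytest.approx(4.0, abs=1e-12)
    # CADD 30 / 100 het at f=0.001
    expected = 0.30 * -math.log10(0.999 * 0.001)
    assert variant_score(0.30, 0.001, "het") == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.9001, abs=1e-4)
    # hemizygous single allele
    assert variant_score(1.0, 0.1, "hemi_alt") == pytest.approx(1.0, abs=1e-12)


def test_hwe_genotype_factor_switch():
    p = ScoreParams(hwe_genotype_factor=True)
    expected = 0.5 * -math.log10(2 * 0.9 * 0.1)
    assert variant_score(0.5, 0.1, "het", p) == pytest.approx(expected, abs=1e-12)


def test_frequency_out_of_range_raises():
    with pytest.raises(DataError):
        variant_score(0.5, 0.0, "het")
    with pytest.raises(DataError):
        variant_score(0.5, 1.0, "hom_alt")


def test_gene_score_additivity_and_empty():
    assert gene_score([]) == 0.0
    a = variant_score(0.4, 0.01, "het")
    b = variant_score(0.8, 0.001, "het")
    calls = [(0.4, 0.01, "het"), (0.8, 0.001, "het")]
    assert gene_score(calls) == pytest.approx(a + b, abs=1e-12)
    assert gene_score(calls[::-1]) == gene_score(calls)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    d=st.floats(0.01, 1.0),
    f=st.floats(1e-6, 0.4999),
    bump=st.floats(1e-4, 0.5),
)
def test_score_monotonicity_properties(d, f, bump):
    # rarer variants and higher deleteriousness both score higher
    s = variant_score(d, f, "het")
    rarer = max(f * (1 - bump), 1e-7)
    assert variant_score(d, rarer, "het") > s
    d_hi = min(d * (1 + bump), 1.0)
    if d_hi > d:
        assert variant_score(d_hi, f, "het") > s
    # zygosity ordering: hom-alt >= het when f_alt <= f_ref
    assert variant_score(d, f, "hom_alt") >= s


def _tiny_matrix_inputs(seed=0, n_genes=20, n_part=100):
    rng = np.random.default_rng(seed)
    rows = []
    genos = []
    for g in range(n_genes):
        for v in range(rng.integers(1, 4)):
            rows.append({
                "chrom": "1", "pos": g * 100 + v + 1, "ref": "A", "alt": "C",
                "gene": f"G{g}", "cadd_phred": float(rng.uniform(20, 50)),
                "af": float(rng.uniform(1e-4, 0.4)),
            })
            genos.append(rng.choice([HOM_REF, HET, HOM_ALT, MISSING],
                                    size=n_part, p=[0.7, 0.2, 0.05, 0.05]))
    return pd.DataFrame(rows), np.array(genos, dtype=np.int8)


def test_matrix_equals_per_cell_recomputation():
    variants, geno = _tiny_matrix_inputs()
    participants = [f"P{i}" for i in range(geno.shape[1])]
    m = build_matrix(variants, geno, participants)
    zyg = {HET: "het", HOM_ALT: "hom_alt"}
    for gi, gene in enumerate(m.genes):
        rows = np.flatnonzero(variants["gene"] == gene)
        for pj in range(len(participants)):
            calls = [
                (min(variants["cadd_phred"].iat[v] / 100, 1.0), variants["af"].iat[v],
                 zyg[geno[v, pj]])
                for v in rows if geno[v, pj] in zyg
            ]
            assert m.scores[gi, pj] == pytest.approx(gene_score(calls), abs=1e-10)


def test_matrix_zero_set_and_meta():
    variants, geno = _tiny_matrix_inputs(seed=3)
    participants = [f"P{i}" for i in range(geno.shape[1])]
    m = build_matrix(variants, geno, participants)
    assert (m.scores >= 0).all()
    for gi, gene in enumerate(m.genes):
        rows = np.flatnonzero(variants["gene"] == gene)
        carries = (geno[rows] > 0).any(axis=0)
        assert np.array_equal(m.scores[gi] > 0, carries)
        assert m.gene_meta["n_nonzero"].iat[gi] == int(carries.sum())


def test_matrix_participant_permutation_equivariance():
    variants, geno = _tiny_matrix_inputs(seed=5)
    n = geno.shape[1]
    participants = [f"P{i}" for i in range(n)]
    m1 = build_matrix(variants, geno, participants)
    perm = np.random.default_rng(1).permutation(n)
    m2 = build_matrix(variants, geno[:, perm], [participants[i] for i in perm])
    assert np.allclose(m1.scores[:, perm], m2.scores)


def test_single_variant_matrix():
    variants = pd.DataFrame({
        "chrom": ["1"], "pos": [1], "ref": ["A"], "alt": ["C"],
        "gene": ["G"], "cadd_phred": [30.0], "af": [0.01],
    })
    geno = np.array([[HET, HOM_REF]], dtype=np.int8)
    m = build_matrix(variants, geno, ["a", "b"])
    assert m.scores[0, 0] > 0 and m.scores[0, 1] == 0


def test_missing_af_policies():
    p_cohort = ScoreParams(missing_af_policy="cohort_af")
    p_floor = ScoreParams(missing_af_policy="floor")
    geno = np.array([[HET, HET, HOM_REF, HOM_REF]], dtype=np.int8)
    af = np.array([np.nan])
    got = effective_af(af, geno, None, p_cohort)
    assert got[0] == pytest.approx(2 / 8)
    assert effective_af(af, geno, None, p_floor)[0] == p_floor.af_floor


def test_hemizygous_male_x_scoring():
    variants = pd.DataFrame({
        "chrom": ["X"], "pos": [1], "ref": ["A"], "alt": ["C"],
        "gene": ["GX"], "cadd_phred": [100.0], "af": [0.1],
    })
    geno = np.array([[HOM_ALT, HOM_ALT]], dtype=np.int8)
    m = build_matrix(variants, geno, ["m1", "f1"], sex=np.array(["male", "female"]))
    assert m.scores[0, 0] == pytest.approx(-math.log10(0.1), abs=1e-12)  # one allele
    assert m.scores[0, 1] == pytest.approx(-math.log10(0.01), abs=1e-12)  # two alleles


def _meta(n_nonzero_by_gene, chrom="1"):
    return pd.DataFrame({
        "gene": list(n_nonzero_by_gene),
        "chrom": chrom if isinstance(chrom, list) else [chrom] * len(n_nonzero_by_gene),
        "n_variants": 1,
        "n_nonzero": list(n_nonzero_by_gene.values()),
    })


def test_refinement_cutoff_is_strictly_more_than_five():
    meta = _meta({"A": 5, "B": 6, "C": 100})
    retained, ledger = refine_gene_set(meta)
    assert retained == ["B", "C"]
    assert ledger.to_frame().iloc[1]["removed"] == 1


def test_refinement_all_dense_no_exclusions():
    meta = _meta({f"G{i}": 50 for i in range(10)})
    retained, _ = refine_gene_set(meta, [])
    assert len(retained) == 10


def test_refinement_first_category_accounting():
    meta = _meta({"A": 10, "B": 10, "C": 2})
    retained, ledger = refine_gene_set(
        meta, [("olfactory", {"A", "C"}), ("poor", {"A", "B"})]
    )
    df = ledger.to_frame().set_index("step")
    # C removed by the sparsity cut, A by olfactory (first list), B by poor
    assert df.loc["olfactory", "removed"] == 1
    assert df.loc["poor", "removed"] == 1
    assert retained == []


def test_split_by_chromosome():
    meta = _meta({"A": 9, "B": 9, "X1": 9}, chrom=["1", "22", "X"])
    auto, xs = split_by_chromosome(meta, ["A", "B", "X1"])
    assert auto == ["A", "B"] and xs == ["X1"]
    assert len(auto) + len(xs) == 3
    bad = _meta({"Z": 9}, chrom=["weird"])
    with pytest.raises(DataError):
        split_by_chromosome(bad, ["Z"])


def test_all_autosomal_gives_empty_x_set():
    meta = _meta({"A": 9, "B": 9})
    auto, xs = split_by_chromosome(meta, ["A", "B"])
    assert xs == []
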