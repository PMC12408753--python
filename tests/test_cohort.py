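"""LDL selection, age and medication rules, K-S merge decision, kinship
pruning, and the exclusion-cascade ledger."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenscan import (
    DataError,
    age_at_assay,
    build_cohort,
    classify_drug_status,
    ks_merge_check,
    prune_relatives,
    select_ldl,
    shapiro_diagnostic,
)
from oracles import ks_exact_oracle


def test_select_earliest_reproducible():
    assert select_ldl([(3.1, "2010-01-05", True), (4.0, "2012-03-01", True)]) == (3.1, "2010-01-05")
    assert select_ldl([(3.1, "2010-01-05", False)]) is None
    assert select_ldl([]) is None
    # non-reproducible earliest is skipped in favour of a later valid one
    assert select_ldl([(3.1, "2010-01-05", False), (4.0, "2012-03-01", True)])[0] == 4.0


def test_age_at_assay():
    assert age_at_assay(1950, "2010-06-01") == 60
    assert age_at_assay(1951, "2010-06-01") == 59
    with pytest.raises(DataError):
        age_at_assay(2011, "2010-06-01")


def test_drug_status_classification():
    drugs = {"statin_a", "statin_b"}
    assert classify_drug_status("NONE", drugs) == "not_on_drug"
    assert classify_drug_status(".", drugs) == "unknown"
    assert classify_drug_status(None, drugs) == "unknown"
    assert classify_drug_status("statin_a;aspirin", drugs) == "on_drug"
    assert classify_drug_status("aspirin", drugs) == "not_on_drug"
    assert classify_drug_status([], drugs) == "not_on_drug"


def test_ks_merge_identical_samples():
    x = np.linspace(1, 5, 100)
    p, merged = ks_merge_check(x, x)
    assert p > 0.999 and merged


def test_ks_merge_rejects_shifted_distributions():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 10_000)
    b = rng.normal(3, 1, 10_000)  # 3 SD shift
    p, merged = ks_merge_check(a, b)
    assert p < 1e-10 and not merged


def test_ks_small_sample_matches_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(5):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        p, _ = ks_merge_check(x, y)
        assert p == pytest.approx(ks_exact_oracle(x, y), abs=1e-9)


def test_ks_empty_sample_is_error():
    with pytest.raises(DataError):
        ks_merge_check(np.array([]), np.array([1.0]))


def test_shapiro_calibration_and_power():
    rng = np.random.default_rng(1)
    ps = [shapiro_diagnostic(rng.normal(size=500), seed=0)[1] for _ in range(40)]
    # roughly uniform under normality: KS against U(0,1) should not reject hard
    assert stats.kstest(ps, "uniform").pvalue > 1e-3
    w, p = shapiro_diagnostic(rng.exponential(size=500))
    assert p < 0.01
    with pytest.raises(DataError):
        shapiro_diagnostic(np.ones(10))
    with pytest.raises(DataError):
        shapiro_diagnostic(np.array([1.0, 2.0]))


def _pairs(*rows):
    return pd.DataFrame(rows, columns=["id1", "id2", "degree"])


def test_prune_no_pairs_keeps_everyone():
    assert prune_relatives({"a": 50, "b": 60}, _pairs()) == {"a", "b"}


def test_prune_triangle_keeps_youngest():
    ages = {"A": 50, "B": 45, "C": 60}
    pairs = _pairs(("A", "B", 1), ("B", "C", 2), ("A", "C", 3))
    assert prune_relatives(ages, pairs) == {"B"}


def test_prune_two_components():
    ages = {"A": 50, "B": 55, "C": 40, "D": 42, "E": 70}
    pairs = _pairs(("A", "B", 1), ("C", "D", 3))
    assert prune_relatives(ages, pairs) == {"A", "C", "E"}


def test_prune_missing_age_is_treated_as_oldest():
    ages = {"A": None, "B": 80}
    assert prune_relatives(ages, _pairs(("A", "B", 1))) == {"B"}


def test_prune_ties_broken_by_id():
    ages = {"B": 50, "A": 50}
    assert prune_relatives(ages, _pairs(("A", "B", 2))) == {"A"}


def test_prune_ignores_distant_pairs():
    ages = {"A": 50, "B": 45}
    assert prune_relatives(ages, _pairs(("A", "B", 4))) == {"A", "B"}


def test_no_retained_pair_remains_connected():
    rng = np.random.default_rng(2)
    ids = [f"P{i}" for i in range(60)]
    ages = {i: int(rng.integers(40, 70)) for i in ids}
    rows = [(ids[rng.integers(60)], ids[rng.integers(60)], int(rng.integers(1, 4)))
            for _ in range(40)]
    pairs = _pairs(*[(a, b, d) for a, b, d in rows if a != b])
    kept = prune_relatives(ages, pairs)
    for a, b, d in pairs.itertuples(index=False):
        assert not (a in kept and b in kept)


def _pheno_row(pid, sex="female", by=1950, ldl=3.5, date="2008-01-01", med="NONE", repro=1):
    return {"participant_id": pid, "sex": sex, "birth_year": by, "ldl_mmol_l": ldl,
            "assay_date": date, "med_codes": med, "reproducible": repro}


def test_build_cohort_cascade_and_ledger():
    rows = [
        _pheno_row("a"),                                  # kept, age 58 -> under60
        _pheno_row("b", by=1940),                         # kept, age 68 -> over60
        _pheno_row("c", ldl=np.nan, date=None),           # missing LDL
        _pheno_row("d", repro=0),                         # non-reproducible
        _pheno_row("e", med="drug001"),                   # on drug
        _pheno_row("f", med="."),                         # unknown, mergeable
        _pheno_row("g", by=1945),                         # related to a, older -> dropped
        _pheno_row("h"),                                  # not sequenced
    ]
    kin = pd.DataFrame([("a", "g", 2)], columns=["id1", "id2", "degree"])
    ct = build_cohort(pd.DataFrame(rows), kin, {"drug001"},
                      sequenced_ids={"a", "b", "c", "d", "e", "f", "g"})
    led = ct.ledger.to_frame().set_index("step")
    assert led.loc["no sequencing data", "removed"] == 1
    assert led.loc["missing or non-reproducible LDL-C", "removed"] == 2
    assert led.loc["related (degree <= 3, youngest kept)", "removed"] == 1
    assert led.loc["on LDL-altering medication", "removed"] == 1
    ct.ledger.check()
    got = ct.table.set_index("participant_id")
    assert set(got.index) == {"a", "b", "f"}
    assert got.loc["a", "stratum"] == "under60"
    assert got.loc["b", "stratum"] == "over60_or_equal"


def test_build_cohort_missing_birth_year_goes_to_missing_age():
    rows = [_pheno_row("a", by=np.nan), _pheno_row("b")]
    ct = build_cohort(pd.DataFrame(rows), pd.DataFrame(columns=["id1", "id2", "degree"]), set())
    got = ct.table.set_index("participant_id")
    assert got.loc["a", "stratum"] == "missing_age"
    assert set(ct.stratum_ids("combined")) == {"a", "b"}
    assert ct.stratum_ids("under60") == ["b"]


def test_build_cohort_on_synthetic_bundle(small_sim):
    sim = small_sim
    ct = build_cohort(sim.phenotypes, sim.kinship, set(sim.drug_codes),
                      sequenced_ids=set(sim.participants))
    ct.ledger.check()
    led = ct.ledger.to_frame().set_index("step")
    assert led.loc["missing or non-reproducible LDL-C", "removed"] == (
        sim.qc_truth["n_missing_pheno"] + sim.qc_truth["n_nonreproducible"]
    )
    assert (ct.table["drug_status"] != "on_drug").all()
    # strata partition the table
    assert set(ct.table["stratum"]) <= {"under60", "over60_or_equal", "missing_age"}
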