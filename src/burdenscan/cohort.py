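"""Analysis-cohort assembly from phenotype, medication and kinship data.

Exclusions are applied in a fixed order so ledgers are comparable across
runs: participants without sequencing data, then participants without a
usable LDL-C measurement (missing or non-reproducible), then one member of
every related group (degree <= 3; the youngest is kept), then medication
stratification. Participants with no medication information are merged into
the not-on-drug group only when a two-sample Kolmogorov-Smirnov test finds
their LDL-C distributions compatible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .ledger import Ledger


def select_ldl(measurements: list[tuple[float, str, bool]]) -> tuple[float, str] | None:
    """Earliest reproducible LDL-C measurement, or None if none qualifies.

    ``measurements`` is a list of (value, assay_date, reproducible) triples;
    dates are ISO strings so lexicographic order is chronological.
    """
    ok = [
        (date, value)
        for value, date, repro in measurements
        if repro and value is not None and not pd.isna(value) and date and not pd.isna(date)
    ]
    if not ok:
        return None
    date, value = min(ok)
    return value, date


def age_at_assay(birth_year: int, assay_date: str) -> int:
    """Whole years between birth year and the assay's calendar year."""
    year = int(str(assay_date)[:4])
    if year < birth_year:
        raise DataError(f"assay year {year} precedes birth year {birth_year}")
    return year - birth_year


def classify_drug_status(med_codes, drug_code_list: set[str]) -> str:
    """on_drug / not_on_drug / unknown from a participant's medication codes.

    ``med_codes`` may be None or "." (no medication data -> unknown), "NONE"
    or an empty container (data present, no medications), or an iterable /
    ";"-separated string of codes.
    """
    if med_codes is None or (isinstance(med_codes, float) and pd.isna(med_codes)):
        return "unknown"
    if isinstance(med_codes, str):
        s = med_codes.strip()
        if s == ".":
            return "unknown"
        codes = [] if s in ("", "NONE") else s.split(";")
    else:
        codes = list(med_codes)
    return "on_drug" if any(c in drug_code_list for c in codes) else "not_on_drug"


def ks_merge_check(
    ldl_not_on_drug: np.ndarray, ldl_unknown: np.ndarray, alpha: float = 0.05
) -> tuple[float, bool]:
    """Two-sample K-S comparison of the two LDL-C distributions.

    Returns (p, merged); the pipeline folds the unknown-medication group into
    the not-on-drug group when the distributions are compatible (p > alpha).
    """
    a, b = np.asarray(ldl_not_on_drug, float), np.asarray(ldl_unknown, float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("K-S merge check needs two non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue), bool(res.pvalue > alpha)


def shapiro_diagnostic(
    values: np.ndarray, max_n: int = 5000, seed: int = 0
) -> tuple[float, float]:
    """Shapiro-Wilk normality diagnostic (W, p); no filtering action is taken.

    Samples larger than ``max_n`` are subsampled with a seeded RNG, since the
    test statistic's null distribution is tabulated for moderate n.
    """
    v = np.asarray(values, float)
    if len(v) < 3:
        raise DataError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(v) == 0:
        raise DataError("Shapiro-Wilk is undefined for a constant sample")
    if len(v) > max_n:
        v = np.random.default_rng(seed).choice(v, max_n, replace=False)
    w, p = stats.shapiro(v)
    return float(w), float(p)


def prune_relatives(
    ages: dict[str, float | None], pairs: pd.DataFrame, max_degree: int = 3
) -> set[str]:
    """Keep the youngest member of every related group.

    A relatedness graph is built over pairs of degree <= ``max_degree``
    whose members are both in ``ages``; within each connected component
    exactly one participant is retained: the youngest, with missing ages
    treated as oldest and ties broken by lexicographically smallest id.
    """
    ids = set(ages)
    g = nx.Graph()
    if len(pairs):
        for id1, id2, deg in pairs[["id1", "id2", "degree"]].itertuples(index=False):
            if deg <= max_degree and id1 in ids and id2 in ids:
                g.add_edge(id1, id2)
    retained = set(ids)
    for comp in nx.connected_components(g):
        keep = min(comp, key=lambda i: (ages[i] if ages[i] is not None and not pd.isna(ages[i]) else np.inf, i))
        retained -= comp - {keep}
    return retained


@dataclass
class CohortTable:
    """Retained participants with strata labels plus the exclusion ledger."""

    table: pd.DataFrame  # participant_id, sex, ldl_mmol_l, age, stratum, drug_status
    ledger: Ledger
    ks_p: float | None
    merged_unknown: bool

    def stratum_ids(self, stratum: str, sex: str | None = None) -> list[str]:
        """Participant ids of one analysis stratum.

        ``stratum``: under60 / over60_or_equal / combined (combined includes
        the missing-age participants). ``sex`` optionally restricts to
        female or male.
        """
        t = self.table
        if stratum == "combined":
            sel = pd.Series(True, index=t.index)
        elif stratum in ("under60", "over60_or_equal", "missing_age"):
            sel = t["stratum"] == stratum
        else:
            raise DataError(f"unknown stratum {stratum!r}")
        if sex is not None:
            sel &= t["sex"] == sex
        return list(t.loc[sel, "participant_id"])


def build_cohort(
    phenotypes: pd.DataFrame,
    kinship: pd.DataFrame,
    drug_code_list: set[str],
    sequenced_ids: set[str] | None = None,
    ks_alpha: float = 0.05,
) -> CohortTable:
    """Apply the exclusion cascade and return the analysis cohort.

    ``phenotypes`` has one row per LDL measurement (participant_id, sex,
    birth_year, ldl_mmol_l, assay_date, med_codes, reproducible).
    """
    first = phenotypes.drop_duplicates("participant_id").set_index("participant_id")
    all_ids = list(first.index)
    ledger = Ledger("participants", len(all_ids))

    if sequenced_ids is not None:
        keep = [i for i in all_ids if i in sequenced_ids]
    else:
        keep = all_ids
    ledger.exclude("no sequencing data", len(all_ids) - len(keep))

    # earliest reproducible LDL per participant
    m = phenotypes[phenotypes["participant_id"].isin(keep)].copy()
    valid = (
        (m["reproducible"].astype(int) == 1)
        & m["ldl_mmol_l"].notna()
        & m["assay_date"].notna()
    )
    m = m[valid].sort_values(["participant_id", "assay_date"], kind="stable")
    sel = m.drop_duplicates("participant_id").set_index("participant_id")
    with_ldl = [i for i in keep if i in sel.index]
    ledger.exclude("missing or non-reproducible LDL-C", len(keep) - len(with_ldl))

    # age at assay (missing birth year -> missing age, kept for combined only)
    ages: dict[str, float | None] = {}
    for pid in with_ldl:
        by = first.at[pid, "birth_year"]
        if pd.isna(by):
            ages[pid] = None
        else:
            ages[pid] = age_at_assay(int(by), sel.at[pid, "assay_date"])

    retained_rel = prune_relatives(ages, kinship)
    unrelated = [i for i in with_ldl if i in retained_rel]
    ledger.exclude("related (degree <= 3, youngest kept)", len(with_ldl) - len(unrelated))

    status = {
        pid: classify_drug_status(first.at[pid, "med_codes"], drug_code_list)
        for pid in unrelated
    }
    on_drug = [i for i in unrelated if status[i] == "on_drug"]
    not_on = [i for i in unrelated if status[i] == "not_on_drug"]
    unknown = [i for i in unrelated if status[i] == "unknown"]
    ledger.exclude("on LDL-altering medication", len(on_drug))

    ks_p, merged = None, False
    if unknown and not_on:
        ks_p, merged = ks_merge_check(
            sel.loc[not_on, "ldl_mmol_l"].to_numpy(),
            sel.loc[unknown, "ldl_mmol_l"].to_numpy(),
            ks_alpha,
        )
    analysis = not_on + unknown if merged or not unknown else not_on
    if unknown and not merged:
        ledger.exclude("unknown medication status (K-S merge rejected)", len(unknown))
    ledger.check()

    rows = []
    for pid in analysis:
        age = ages[pid]
        stratum = (
            "missing_age" if age is None else ("under60" if age < 60 else "over60_or_equal")
        )
        rows.append(
            {
                "participant_id": pid,
                "sex": first.at[pid, "sex"],
                "ldl_mmol_l": float(sel.at[pid, "ldl_mmol_l"]),
                "age": np.nan if age is None else age,
                "stratum": stratum,
                "drug_status": status[pid],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["participant_id", "sex", "ldl_mmol_l", "age", "stratum", "drug_status"],
    )
    return CohortTable(table=table, ledger=ledger, ks_p=ks_p, merged_unknown=merged)
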