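"""Screening-cohort ingestion, validation, and restructuring.

A cohort is a pair of tables: one row per woman-visit (``visits``) carrying the
risk-factor profile recorded at that screen, and one row per woman
(``outcomes``) carrying the breast-cancer event indicator and the end of
follow-up on the study time axis (years since the woman's first mammogram).
Women without a diagnosis are censored two years after their last attended
mammogram, so every woman contributes person-time over her full screening
window.

The central restructuring is :func:`build_stacked`: each retained visit becomes
one record whose covariates are frozen at the visit (landmark) time and whose
outcome is the residual time from that landmark to the event or censoring.
These stacked records are the estimation units of the partly conditional Cox
model; all records of one woman share her identifier so that within-woman
correlation can be absorbed by a cluster-robust variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BBD_CATEGORIES",
    "FEATURE_CATEGORIES",
    "AGE_BANDS",
    "CohortTable",
    "CohortError",
    "SchemaError",
    "LinkageError",
    "DuplicationError",
    "load_cohort",
    "make_cohort",
    "apply_exclusions",
    "build_stacked",
    "describe_cohort",
    "age_band",
    "save_cohort",
]

#: Benign breast disease (Dupont-Page grouping, plus unknown-diagnosis biopsies).
BBD_CATEGORIES = ["none", "prior_biopsy_unknown", "non_proliferative", "proliferative"]

#: Mammographic features reported at screening interpretation.
FEATURE_CATEGORIES = [
    "none",
    "mass",
    "calcifications",
    "asymmetry",
    "architectural_distortion",
    "multiple",
]

#: Five-year age bands of the screening target population.
AGE_BANDS = ["50-54", "55-59", "60-64", "65-69"]

#: Censoring rule: follow-up ends this many years after the last mammogram.
CENSOR_LAG = 2.0

VISIT_COLUMNS = [
    "woman_id",
    "visit_time",
    "age_at_visit",
    "family_history",
    "bbd_category",
    "mammo_feature",
]
OUTCOME_COLUMNS = ["woman_id", "event", "end_time"]


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A cell violates the documented CSV schema (unknown label, bad type)."""


class LinkageError(CohortError):
    """Visits and outcomes disagree (missing outcome, visit after end_time)."""


class DuplicationError(CohortError):
    """Duplicate (woman_id, visit_time) pair."""


@dataclass
class CohortTable:
    """Validated screening cohort: visit rows, outcome rows, exclusion log."""

    visits: pd.DataFrame
    outcomes: pd.DataFrame
    exclusion_log: dict = field(default_factory=dict)

    @property
    def n_women(self) -> int:
        return len(self.outcomes)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def n_events(self) -> int:
        return int(self.outcomes["event"].sum())

    def baseline(self) -> pd.DataFrame:
        """One row per woman: her first visit merged with her outcome."""
        first = (
            self.visits.sort_values(["woman_id", "visit_time"])
            .groupby("woman_id", as_index=False, sort=False)
            .first()
        )
        return first.merge(self.outcomes, on="woman_id", validate="1:1")

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.visits.copy(), self.outcomes.copy(), dict(self.exclusion_log)
        )


def _check_enum(series: pd.Series, allowed: list[str], colname: str) -> None:
    # NaN is allowed here; missingness is handled by the exclusion rules
    # (family history / BBD) and is a schema error only for mammo_feature.
    bad = series.dropna()[~series.dropna().isin(allowed)]
    if len(bad):
        row = bad.index[0]
        raise SchemaError(
            f"{colname}: unknown label {bad.iloc[0]!r} at row {row}; "
            f"allowed: {allowed}"
        )


def _validate(visits: pd.DataFrame, outcomes: pd.DataFrame) -> None:
    for col in VISIT_COLUMNS:
        if col not in visits.columns:
            raise SchemaError(f"visits table missing column {col!r}")
    for col in OUTCOME_COLUMNS:
        if col not in outcomes.columns:
            raise SchemaError(f"outcomes table missing column {col!r}")

    _check_enum(visits["bbd_category"], BBD_CATEGORIES, "bbd_category")
    _check_enum(visits["mammo_feature"], FEATURE_CATEGORIES, "mammo_feature")
    if visits["mammo_feature"].isna().any():
        row = visits.index[visits["mammo_feature"].isna()][0]
        raise SchemaError(
            f"mammo_feature blank at row {row}: absence of findings must be "
            "coded 'none' explicitly"
        )
    fh = visits["family_history"].dropna()
    if not fh.isin([0, 1]).all():
        raise SchemaError("family_history must be 0, 1, or missing")
    if not outcomes["event"].isin([0, 1]).all():
        raise SchemaError("event must be 0 or 1")
    if (visits["visit_time"] < 0).any():
        raise SchemaError("visit_time must be >= 0")

    if outcomes["woman_id"].duplicated().any():
        dup = outcomes.loc[outcomes["woman_id"].duplicated(), "woman_id"].iloc[0]
        raise DuplicationError(f"multiple outcome rows for woman {dup!r}")
    dup_mask = visits.duplicated(subset=["woman_id", "visit_time"])
    if dup_mask.any():
        w = visits.loc[dup_mask, "woman_id"].iloc[0]
        raise DuplicationError(
            f"duplicate (woman_id, visit_time) for woman {w!r}; one "
            "interpretation per screen is required"
        )

    missing = set(visits["woman_id"]) - set(outcomes["woman_id"])
    if missing:
        raise LinkageError(f"visits without outcome row for women {sorted(missing)[:5]}")

    merged = visits.merge(outcomes, on="woman_id", how="left")
    late = merged["visit_time"] > merged["end_time"] + 1e-9
    if late.any():
        w = merged.loc[late, "woman_id"].iloc[0]
        raise LinkageError(f"woman {w!r} has a visit after her end_time")

    # Within-woman ordering: ages strictly increasing along visit order.
    srt = visits.sort_values(["woman_id", "visit_time"])
    same = srt["woman_id"] == srt["woman_id"].shift()
    if (srt["age_at_visit"].diff()[same] <= 0).any():
        raise SchemaError("age_at_visit must be strictly increasing within a woman")


def make_cohort(visits: pd.DataFrame, outcomes: pd.DataFrame) -> CohortTable:
    """Validate in-memory tables and assemble a :class:`CohortTable`."""
    visits = visits.reset_index(drop=True)
    outcomes = outcomes.reset_index(drop=True)
    _validate(visits, outcomes)
    return CohortTable(visits, outcomes)


def load_cohort(visits_path, outcomes_path) -> CohortTable:
    """Read and validate the two cohort CSVs.

    ``visits.csv`` columns: woman_id, visit_time, age_at_visit,
    family_history (0/1, may be blank), bbd_category, mammo_feature.
    ``outcomes.csv`` columns: woman_id, event (0/1), end_time.
    """
    visits = pd.read_csv(visits_path)
    outcomes = pd.read_csv(outcomes_path)
    return make_cohort(visits, outcomes)


def save_cohort(cohort: CohortTable, visits_path, outcomes_path) -> None:
    cohort.visits.to_csv(visits_path, index=False)
    cohort.outcomes.to_csv(outcomes_path, index=False)


def apply_exclusions(cohort: CohortTable) -> CohortTable:
    """Drop women per the cohort entry rules and log a per-rule breakdown.

    Rules (counts are disjoint, mirroring the four-way breakdown of the study
    population definition):

    * ``event_at_first_screen`` -- breast cancer detected at the first visit;
    * ``missing_family_history`` -- family history blank (only);
    * ``missing_bbd`` -- benign-breast-disease category blank (only);
    * ``missing_both`` -- both of the above blank.
    """
    visits, outcomes = cohort.visits, cohort.outcomes
    first = (
        visits.sort_values(["woman_id", "visit_time"])
        .groupby("woman_id")
        .first()[["visit_time"]]
        .rename(columns={"visit_time": "first_visit"})
    )
    out = outcomes.merge(first, left_on="woman_id", right_index=True, how="left")
    prevalent = set(
        out.loc[
            (out["event"] == 1) & (np.isclose(out["end_time"], out["first_visit"])),
            "woman_id",
        ]
    )

    by_woman = visits.groupby("woman_id")
    miss_fh = set(by_woman["family_history"].apply(lambda s: s.isna().any()).loc[lambda s: s].index)
    miss_bbd = set(by_woman["bbd_category"].apply(lambda s: s.isna().any()).loc[lambda s: s].index)
    # apply rules in order; a prevalent case is counted there even if also missing
    miss_fh -= prevalent
    miss_bbd -= prevalent
    both = miss_fh & miss_bbd

    log = {
        "event_at_first_screen": len(prevalent),
        "missing_family_history": len(miss_fh - both),
        "missing_bbd": len(miss_bbd - both),
        "missing_both": len(both),
    }
    drop = prevalent | miss_fh | miss_bbd
    kept_out = outcomes[~outcomes["woman_id"].isin(drop)].reset_index(drop=True)
    kept_vis = visits[~visits["woman_id"].isin(drop)].reset_index(drop=True)
    if len(kept_out) == 0:
        warnings.warn("all women excluded; empty cohort returned", stacklevel=2)
    new_log = dict(cohort.exclusion_log)
    for k, v in log.items():
        new_log[k] = new_log.get(k, 0) + v
    return CohortTable(kept_vis, kept_out, new_log)


def build_stacked(cohort: CohortTable) -> pd.DataFrame:
    """One record per retained visit, covariates frozen at the landmark.

    A visit at landmark time ``s`` is retained when ``s < end_time``; its
    record carries ``residual_time = end_time - s`` and the woman's event
    indicator (an observed event necessarily falls inside every retained
    record's residual window). Output is invariant to the input row order.
    """
    merged = cohort.visits.merge(cohort.outcomes, on="woman_id", validate="m:1")
    merged = merged[merged["visit_time"] < merged["end_time"] - 1e-12].copy()
    merged["landmark_time"] = merged["visit_time"]
    merged["residual_time"] = merged["end_time"] - merged["visit_time"]
    cols = [
        "woman_id",
        "landmark_time",
        "age_at_visit",
        "family_history",
        "bbd_category",
        "mammo_feature",
        "residual_time",
        "event",
    ]
    stacked = (
        merged[cols]
        .sort_values(["woman_id", "landmark_time"], kind="mergesort")
        .reset_index(drop=True)
    )
    stacked["family_history"] = stacked["family_history"].astype(int)
    stacked["event"] = stacked["event"].astype(int)
    return stacked


def age_band(age) -> pd.Series:
    """Map ages to the four screening age bands (clipped at the ends)."""
    age = pd.Series(np.asarray(age, dtype=float))
    edges = [-np.inf, 55, 60, 65, np.inf]
    return pd.cut(age, edges, right=False, labels=AGE_BANDS).astype(str)


def _two_prop_z(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test p-value (pooled variance)."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def describe_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Baseline characteristics split by eventual breast-cancer status.

    Categorical rows (entry age band, family history, BBD, mammographic
    feature at the first visit) report counts and percentages in each group
    with a two-proportion z-test, Bonferroni-corrected within each variable
    block; the follow-up row reports group means with a Mann-Whitney U test.
    """
    base = cohort.baseline()
    base["age_band"] = age_band(base["age_at_visit"]).values
    grp = base["event"] == 1
    n1, n0 = int(grp.sum()), int((~grp).sum())

    rows = []
    fu0 = base.loc[~grp, "end_time"]
    fu1 = base.loc[grp, "end_time"]
    if n0 and n1:
        p_fu = float(stats.mannwhitneyu(fu0, fu1, alternative="two-sided").pvalue)
    else:
        p_fu = np.nan
        warnings.warn("a group is empty; tests skipped", stacklevel=2)
    rows.append(
        {
            "variable": "follow_up",
            "level": "mean_years",
            "no_cancer": fu0.mean() if n0 else 0.0,
            "cancer": fu1.mean() if n1 else 0.0,
            "no_cancer_pct": np.nan,
            "cancer_pct": np.nan,
            "p_value": p_fu,
        }
    )

    blocks = {
        "age_band": AGE_BANDS,
        "family_history": [0, 1],
        "bbd_category": BBD_CATEGORIES,
        "mammo_feature": FEATURE_CATEGORIES,
    }
    for var, levels in blocks.items():
        m = len(levels)
        for lev in levels:
            k0 = int(((base[var] == lev) & ~grp).sum())
            k1 = int(((base[var] == lev) & grp).sum())
            if n0 and n1:
                p = min(1.0, _two_prop_z(k0, n0, k1, n1) * m)
            else:
                p = np.nan
            rows.append(
                {
                    "variable": var,
                    "level": lev,
                    "no_cancer": k0,
                    "cancer": k1,
                    "no_cancer_pct": 100 * k0 / n0 if n0 else 0.0,
                    "cancer_pct": 100 * k1 / n1 if n1 else 0.0,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
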