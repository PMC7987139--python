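"""Split-sample internal validation: calibration and discrimination.

The cohort is partitioned at the woman level into an estimation subcohort
(model fitting) and a validation subcohort. In the validation subcohort,
each woman's risk at horizon tau is predicted from her baseline (first
mammogram) profile, and

* calibration is the expected-to-observed (E/O) ratio: mean predicted risk
  over women, divided by the Kaplan-Meier cumulative incidence at tau, with
  a standardized-mortality-ratio-style confidence interval built on the
  observed event count (log-normal form by default, exact Poisson behind a
  flag);
* discrimination is the AUC among women observable at tau (cases: event by
  tau; controls: event-free with follow-up >= tau; women censored event-free
  before tau are excluded), with the Hanley-McNeil closed-form confidence
  interval.

Both expected and observed quantities are computed in the validation
subcohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import CohortTable, age_band
from .pc_cox import ModelFit
from .risk import DEFAULT_BIN_EDGES, predict_risk, risk_distribution

__all__ = [
    "SplitSpec",
    "CalibrationResult",
    "DiscriminationResult",
    "split_cohort",
    "observed_risk_km",
    "eo_ratio",
    "auc_at_horizon",
    "subgroup_calibration",
    "validation_report",
    "validate_model",
    "DEFAULT_HORIZONS",
]

DEFAULT_HORIZONS = [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]


@dataclass
class SplitSpec:
    """Woman-level random split: estimation fraction and seed."""

    estimation_fraction: float = 0.6
    seed: int = 0


@dataclass
class CalibrationResult:
    horizon: float
    subgroup: str
    O: int
    observed_rate: float
    expected: float
    eo_ratio: float
    ci_low: float
    ci_high: float
    note: str = ""


@dataclass
class DiscriminationResult:
    horizon: float
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    note: str = ""


def split_cohort(cohort: CohortTable, spec: SplitSpec) -> tuple[CohortTable, CohortTable]:
    """Disjoint, exhaustive woman-level partition, reproducible given seed."""
    if not 0 < spec.estimation_fraction < 1:
        raise ValueError("estimation_fraction must be in (0, 1)")
    women = np.sort(cohort.outcomes["woman_id"].to_numpy())
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(women))
    n_est = int(round(spec.estimation_fraction * len(women)))
    if n_est == 0 or n_est == len(women):
        raise ValueError("split fraction yields an empty subcohort")
    est_ids = set(women[perm[:n_est]])

    def _sub(ids):
        return CohortTable(
            cohort.visits[cohort.visits["woman_id"].isin(ids)].reset_index(drop=True),
            cohort.outcomes[cohort.outcomes["woman_id"].isin(ids)].reset_index(drop=True),
            dict(cohort.exclusion_log),
        )

    val_ids = set(women) - est_ids
    return _sub(est_ids), _sub(val_ids)


def observed_risk_km(outcomes: pd.DataFrame, tau: float) -> tuple[float, int]:
    """Kaplan-Meier cumulative incidence at tau and the observed event count.

    Uses woman-level (end_time, event) from the baseline landmark. If tau
    exceeds the last observed time the incidence at the last time is
    returned with a warning.
    """
    if len(outcomes) == 0:
        raise ValueError("empty subcohort")
    tmax = float(outcomes["end_time"].max())
    if tau > tmax:
        warnings.warn(
            f"horizon {tau} beyond last observed time {tmax:.2f}; "
            "reporting incidence at the last time",
            stacklevel=2,
        )
        tau = tmax
    km = KaplanMeierFitter()
    km.fit(outcomes["end_time"], outcomes["event"])
    surv = float(km.survival_function_at_times(tau).iloc[0])
    O = int(((outcomes["event"] == 1) & (outcomes["end_time"] <= tau)).sum())
    return 1.0 - surv, O


def eo_ratio(
    expected: float,
    observed_rate: float,
    O: int,
    *,
    horizon: float = np.nan,
    subgroup: str = "overall",
    method: str = "lognormal",
) -> CalibrationResult:
    """E/O ratio with an SMR-style 95% confidence interval.

    ``method='lognormal'`` uses ratio * exp(+-1.96/sqrt(O)), the classical
    log-normal form for a ratio whose denominator count is Poisson;
    ``method='poisson'`` inverts the exact Poisson interval for O.
    """
    if O == 0:
        # no observed events: ratio undefined; exact one-sided Poisson bound
        # on the observed count gives a one-sided lower bound on the ratio
        return CalibrationResult(
            horizon, subgroup, 0, observed_rate, expected,
            np.nan, np.nan, np.nan,
            note="no observed events; ratio undefined "
            "(one-sided: observed count <= 3.69 at 95%)",
        )
    ratio = expected / observed_rate
    if method == "lognormal":
        half = np.exp(1.96 / np.sqrt(O))
        lo, hi = ratio / half, ratio * half
    elif method == "poisson":
        o_lo = stats.chi2.ppf(0.025, 2 * O) / 2
        o_hi = stats.chi2.ppf(0.975, 2 * (O + 1)) / 2
        lo, hi = ratio * O / o_hi, ratio * O / o_lo
    else:
        raise ValueError("method must be 'lognormal' or 'poisson'")
    return CalibrationResult(
        horizon, subgroup, int(O), observed_rate, expected, ratio, lo, hi
    )


def eo_bootstrap_ci(
    risks: pd.Series,
    outcomes: pd.DataFrame,
    tau: float,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Woman-level bootstrap CI for the E/O ratio at horizon tau.

    Resamples validation women with replacement and recomputes both the mean
    predicted risk and the Kaplan-Meier incidence. Unlike the SMR-style
    interval, which models only Poisson noise in the observed count, this
    captures the full sampling noise of the ratio — in particular the heavy
    Kaplan-Meier tail variance at horizons near the end of follow-up support.
    """
    out = outcomes.reset_index(drop=True)
    r = risks.reindex(out["woman_id"]).to_numpy(dtype=float)
    t = out["end_time"].to_numpy()
    d = out["event"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(out)
    ratios = []
    km = KaplanMeierFitter()
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        km.fit(t[idx], d[idx])
        surv = float(km.survival_function_at_times(min(tau, t[idx].max())).iloc[0])
        obs = 1.0 - surv
        if obs > 0:
            ratios.append(float(r[idx].mean()) / obs)
    lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def eo_monte_carlo_ci(
    fit,
    est_stacked: pd.DataFrame,
    validation_cohort: CohortTable,
    taus,
    n_boot_val: int = 300,
    n_boot_fit: int = 25,
    seed: int = 0,
) -> dict:
    """Full Monte-Carlo CI for the overall E/O ratio at one or more horizons.

    The sampling noise of E/O has two comparably sized components: the
    validation subcohort (Kaplan-Meier incidence and the covariate mix the
    risks are averaged over) and the estimation subcohort (coefficients and
    Breslow baseline entering E). The first is estimated by a woman-level
    bootstrap of the validation side; the second by a cluster (woman-level)
    bootstrap of the stacked estimation records with refitting, shared
    across horizons. The two log-scale standard errors combine as
    independent. Returns {tau: (point, lo, hi)}.
    """
    from .pc_cox import fit_pc_cox
    from .risk import predict_risk

    taus = [float(t) for t in np.atleast_1d(taus)]
    rng = np.random.default_rng(seed)
    base = _baseline_profiles(validation_cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        risks = predict_risk(fit, base, taus)

    se_val, points = {}, {}
    for tau in taus:
        obs, _ = observed_risk_km(validation_cohort.outcomes, tau)
        points[tau] = float(risks[tau].mean()) / obs
        lo_v, hi_v = eo_bootstrap_ci(
            risks[tau], validation_cohort.outcomes, tau,
            n_boot=n_boot_val, seed=int(rng.integers(2**31)),
        )
        se_val[tau] = (np.log(hi_v) - np.log(lo_v)) / (2 * 1.96)

    est = est_stacked.reset_index(drop=True)
    codes, women = pd.factorize(est["woman_id"])
    order = np.argsort(codes, kind="mergesort")
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)])
    log_es = {tau: [] for tau in taus}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for _ in range(n_boot_fit):
            draw = rng.integers(0, len(women), size=len(women))
            rows = np.concatenate([order[starts[w]:starts[w + 1]] for w in draw])
            boot = est.iloc[rows].copy()
            boot["woman_id"] = np.repeat(np.arange(len(draw)), counts[draw])
            bfit = fit_pc_cox(boot, fit.spec, ties=fit.ties)
            bres = predict_risk(bfit, base, taus)
            for tau in taus:
                log_es[tau].append(np.log(float(bres[tau].mean())))

    out = {}
    for tau in taus:
        se_fit = float(np.std(log_es[tau], ddof=1))
        se = np.sqrt(se_val[tau] ** 2 + se_fit**2)
        p = points[tau]
        out[tau] = (p, float(p * np.exp(-1.96 * se)), float(p * np.exp(1.96 * se)))
    return out


def _hanley_mcneil_se(auc: float, n_cases: int, n_controls: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_cases - 1) * (q1 - auc**2)
        + (n_controls - 1) * (q2 - auc**2)
    ) / (n_cases * n_controls)
    return float(np.sqrt(max(var, 0.0)))


def auc_at_horizon(
    scores: pd.Series, outcomes: pd.DataFrame, tau: float
) -> DiscriminationResult:
    """Horizon-specific AUC of baseline risk scores with Hanley-McNeil CI.

    ``scores`` is indexed by woman_id. Eligibility at tau: cases have an
    event by tau; controls are event-free with follow-up >= tau; women
    censored event-free before tau are excluded.
    """
    out = outcomes.set_index("woman_id")
    s = scores.reindex(out.index)
    is_case = (out["event"] == 1) & (out["end_time"] <= tau)
    is_control = (out["end_time"] >= tau) & ~is_case
    eligible = is_case | is_control
    n_cases = int(is_case.sum())
    n_controls = int(is_control.sum())
    if n_cases == 0 or n_controls == 0:
        return DiscriminationResult(
            tau, np.nan, np.nan, np.nan, n_cases, n_controls,
            note="no eligible cases or controls at this horizon",
        )
    y = is_case[eligible].astype(int).to_numpy()
    x = s[eligible].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        auc = 0.5  # all scores tied: concordance credit 1/2 for every pair
    else:
        auc = float(roc_auc_score(y, x))
    se = _hanley_mcneil_se(auc, n_cases, n_controls)
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return DiscriminationResult(tau, auc, lo, hi, n_cases, n_controls)


def _baseline_profiles(cohort: CohortTable) -> pd.DataFrame:
    base = cohort.baseline()
    base = base.rename(columns={"age_at_visit": "age"})
    return base.set_index("woman_id")


def subgroup_calibration(
    cohort: CohortTable,
    fit: ModelFit,
    tau: float,
    grouping: str,
    *,
    method: str = "lognormal",
) -> list[CalibrationResult]:
    """E/O per level of a baseline covariate (age band, family history, BBD,
    mammographic feature). Levels with no observed events are retained as NA
    rows."""
    base = _baseline_profiles(cohort)
    if grouping == "age_band":
        groups = age_band(base["age"]).values
    elif grouping in ("family_history", "bbd_category", "mammo_feature"):
        groups = base[grouping].values
    else:
        raise ValueError(f"grouping must be a baseline covariate, got {grouping!r}")
    risks = predict_risk(fit, base, [tau]).iloc[:, 0]
    results = []
    for lev in pd.unique(groups):
        mask = groups == lev
        sub_out = base.loc[mask].reset_index()[["woman_id", "event", "end_time"]]
        expected = float(risks[mask].mean())
        obs, O = observed_risk_km(sub_out, tau)
        results.append(
            eo_ratio(expected, obs, O, horizon=tau, subgroup=str(lev), method=method)
        )
    return results


def validation_report(
    calibrations: list[CalibrationResult],
    discriminations: list[DiscriminationResult],
) -> pd.DataFrame:
    """One row per horizon: observed events, E/O (CI), AUC (CI)."""
    disc = {d.horizon: d for d in discriminations}
    rows = []
    for c in calibrations:
        d = disc.get(c.horizon)
        rows.append(
            {
                "horizon": c.horizon,
                "observed_events": c.O,
                "eo_ratio": c.eo_ratio,
                "eo_ci_low": c.ci_low,
                "eo_ci_high": c.ci_high,
                "auc": d.auc if d else np.nan,
                "auc_ci_low": d.ci_low if d else np.nan,
                "auc_ci_high": d.ci_high if d else np.nan,
            }
        )
    return pd.DataFrame(rows)


def validate_model(
    fit: ModelFit,
    validation_cohort: CohortTable,
    horizons=DEFAULT_HORIZONS,
    subgroup_tau: float = 10.0,
    *,
    smr_method: str = "lognormal",
) -> dict:
    """Full internal validation of a fitted model on a held-out subcohort.

    Returns a dict with the per-horizon table (E/O and AUC), the subgroup
    calibration block at ``subgroup_tau``, and the risk-distribution bins at
    the horizons for which default bins are defined.
    """
    base = _baseline_profiles(validation_cohort)
    outcomes = validation_cohort.outcomes
    risks = predict_risk(fit, base, horizons)

    calibs, discs = [], []
    for tau in horizons:
        r = risks[float(tau)]
        expected = float(r.mean())
        obs, O = observed_risk_km(outcomes, tau)
        calibs.append(eo_ratio(expected, obs, O, horizon=tau, method=smr_method))
        discs.append(auc_at_horizon(r, outcomes, tau))

    subgroups = []
    for grouping in ["family_history", "bbd_category", "mammo_feature", "age_band"]:
        subgroups += subgroup_calibration(
            validation_cohort, fit, subgroup_tau, grouping, method=smr_method
        )

    bins = {}
    for tau, edges in DEFAULT_BIN_EDGES.items():
        if float(tau) in risks.columns:
            bins[tau] = risk_distribution(risks[float(tau)], edges)

    return {
        "per_horizon": validation_report(calibs, discs),
        "calibrations": calibs,
        "discriminations": discs,
        "subgroup_tau": subgroup_tau,
        "subgroups": subgroups,
        "risk_bins": bins,
    }
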