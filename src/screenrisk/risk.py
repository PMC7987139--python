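"""Absolute cumulative breast-cancer risk from a fitted model.

A fitted partly conditional Cox model provides the Breslow baseline
cumulative hazard Lambda0 on the residual-time axis, so the absolute risk of
a woman with profile Z over the tau years following a landmark at which she
is cancer-free is

    risk(tau | Z) = 1 - exp(-Lambda0(tau) * exp(beta' Z)).

The exponential (cumulative-hazard) form is used rather than the
product-limit form; at screening-program event rates the two differ by less
than 1e-4 and the exponential form composes cleanly with the step-function
baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .pc_cox import ModelFit, build_design

__all__ = ["predict_risk", "risk_distribution", "DEFAULT_BIN_EDGES"]

#: Default risk-distribution bin edges (probabilities) per horizon in years.
DEFAULT_BIN_EDGES = {10: [0.015, 0.02], 20: [0.03, 0.05, 0.07]}


def predict_risk(
    fit: ModelFit, profiles: pd.DataFrame, horizons
) -> pd.DataFrame:
    """Absolute risk per profile at each horizon (years from the landmark).

    ``profiles`` needs the model's covariate columns (``age`` or
    ``age_at_visit``, ``family_history``, ``bbd_category``,
    ``mammo_feature``). Horizons beyond the support of the baseline hazard
    are evaluated at its last step and flagged with a warning (the step
    function is flat beyond the last observed event, so this is explicit
    non-extrapolation). Returns a DataFrame indexed like ``profiles`` with
    one column per horizon.
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if (horizons < 0).any():
        raise ValueError("horizons must be >= 0")
    beyond = horizons > fit.max_support
    if beyond.any():
        warnings.warn(
            f"horizons {horizons[beyond].tolist()} exceed the baseline-hazard "
            f"support ({fit.max_support:.2f} y); risks reported at the last "
            "observed step",
            stacklevel=2,
        )
    ages_ok = True
    age_col = "age" if "age" in profiles.columns else "age_at_visit"
    if fit.spec.include_age:
        a = np.asarray(profiles[age_col], dtype=float)
        ages_ok = bool(((a >= 50) & (a <= 69)).all())
    if not ages_ok:
        warnings.warn("profile ages outside the supported 50-69 range", stacklevel=2)

    X, _ = build_design(profiles, fit.spec)
    eta = X @ fit.beta.to_numpy()
    lam = fit.cumhaz_at(np.minimum(horizons, fit.max_support))
    risk = 1.0 - np.exp(-np.outer(np.exp(eta), lam))
    out = pd.DataFrame(risk, index=profiles.index, columns=[float(h) for h in horizons])
    out.attrs["extrapolated_horizons"] = horizons[beyond].tolist()
    return out


def risk_distribution(risks: pd.Series, bin_edges) -> pd.DataFrame:
    """Proportion of women per absolute-risk bin.

    ``bin_edges`` are interior cut points on the probability scale; bins are
    left-closed (``<e1``, ``[e1, e2)``, ..., ``>=e_last`` labelled
    ``>e_last``). Proportions sum to 1.
    """
    risks = pd.Series(risks).dropna()
    if len(risks) == 0:
        raise ValueError("no risks to bin")
    edges = list(np.asarray(bin_edges, dtype=float))
    if sorted(edges) != edges:
        raise ValueError("bin_edges must be increasing")
    full = [-np.inf] + edges + [np.inf]
    labels = (
        [f"<{100 * edges[0]:g}%"]
        + [f"{100 * a:g}-{100 * b:g}%" for a, b in zip(edges[:-1], edges[1:])]
        + [f">{100 * edges[-1]:g}%"]
    )
    counts = pd.cut(risks, full, right=False, labels=labels).value_counts(sort=False)
    return pd.DataFrame(
        {"bin": labels, "count": counts.values, "proportion": counts.values / len(risks)}
    )
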