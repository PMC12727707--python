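"""Downstream statistics for circadian clusters.

Covers the reference-cluster rule (the cluster whose metric means all lie
within one SD of the population mean, largest such cluster), multinomial
logistic associations of covariates with cluster membership, Cox
proportional-hazards models on PCA component scores, and Harrell's
C-index with a participant-level bootstrap for comparing the predictive
performance of metric sets (the full 36 metrics against the commonly
used 10-metric subset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .cluster import CircadianPca, MetricStandardizer  # noqa: used in _risk

__all__ = [
    "TEN_METRIC_SUBSET",
    "choose_reference",
    "fit_multinomial",
    "cox_component_model",
    "ConcordanceResult",
    "harrell_c",
    "compare_c",
    "metricset_comparison",
]

# The commonly used reduced metric set: rest-activity rhythm plus M10/L5
# timing and mean acceleration, excluding most daytime activity and sleep
# metrics.
TEN_METRIC_SUBSET: List[str] = [
    "IS",
    "IV",
    "relative_amplitude",
    "cosinor_mesor",
    "cosinor_amplitude",
    "acrotime",
    "M10_mean",
    "M10_start",
    "L5_mean",
    "L5_start",
]


def choose_reference(z_means: pd.DataFrame, sizes: pd.Series) -> Tuple[object, bool]:
    """Pick the reference cluster for the multinomial model.

    Among clusters whose standardized metric means all satisfy |z| < 1,
    the largest is chosen. If none qualifies, the cluster minimising the
    maximum |z-mean| is returned with a warning. Returns
    ``(cluster_id, rule_satisfied)``. A qualitative health-status
    preference can override the choice by passing the chosen id directly
    to :func:`fit_multinomial`.
    """
    max_abs = z_means.abs().max(axis=1)
    qualifying = max_abs.index[max_abs < 1.0]
    if len(qualifying):
        ref = sizes.loc[qualifying].idxmax()
        return ref, True
    warnings.warn("no cluster has all |z-means| < 1; using the min-max fallback")
    return max_abs.idxmin(), False


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: categorical columns become drop-first dummies."""
    cat = covariates.select_dtypes(include=["object", "category"]).columns
    X = pd.get_dummies(covariates, columns=list(cat), drop_first=True)
    return X.astype(float)


def fit_multinomial(
    covariates: pd.DataFrame,
    assignments: pd.Series,
    reference,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multinomial logistic regression of cluster membership on covariates.

    All covariates enter jointly (categoricals as drop-first dummies);
    the requested cluster is the baseline outcome. Returns a tidy table
    indexed by (cluster, covariate) with odds ratios, Wald 95% CIs,
    two-sided p-values and significance flags at 0.05 / 0.01.
    """
    joined = covariates.join(assignments.rename("_cluster"), how="inner").dropna()
    if joined.empty:
        raise ValueError("no complete-case rows shared by covariates and assignments")
    y_raw = joined.pop("_cluster")
    if reference not in set(y_raw):
        raise ValueError(f"reference cluster {reference!r} not present")
    # place the reference first so it is the MNLogit baseline
    levels = [reference] + sorted(set(y_raw) - {reference}, key=str)
    y = pd.Categorical(y_raw, categories=levels).codes
    X = sm.add_constant(_design_matrix(joined), has_constant="add")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.values[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        worst = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        cols = X.columns[1:]
        raise ValueError(
            f"rank-deficient design; most collinear pair: "
            f"{cols[worst[0]]!r} and {cols[worst[1]]!r}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(y, X).fit(method="newton", maxiter=200, disp=False)
    if not fit.mle_retvals.get("converged", True):
        warnings.warn("multinomial fit did not converge; possible separation "
                      "— affected contrasts have inflated CIs")
    params, bse, pvals = fit.params, fit.bse, fit.pvalues
    rows = []
    for j, level in enumerate(levels[1:]):
        for name in X.columns:
            if name == "const":
                continue
            beta = params.loc[name].iloc[j]
            se = bse.loc[name].iloc[j]
            or_ = np.exp(beta)
            rows.append(
                {
                    "cluster": level,
                    "covariate": name,
                    "odds_ratio": or_,
                    "ci_low": np.exp(beta - 1.959963984540054 * se),
                    "ci_high": np.exp(beta + 1.959963984540054 * se),
                    "p_value": pvals.loc[name].iloc[j],
                }
            )
    table = pd.DataFrame(rows).set_index(["cluster", "covariate"])
    table["sig_05"] = table["p_value"] < 0.05
    table["sig_01"] = table["p_value"] < 0.01
    table.attrs["reference"] = reference
    table.attrs["n"] = len(joined)
    return table


def cox_component_model(
    scores: pd.DataFrame, survival: pd.DataFrame
) -> Tuple[CoxPHFitter, np.ndarray]:
    """Cox proportional-hazards fit on retained PCA components.

    ``survival`` must carry ``time_years`` and ``event`` columns aligned
    with ``scores``. Ties are handled by the Efron approximation (the
    lifelines default). Returns the fitted model and the per-participant
    linear predictor (risk score).
    """
    t = survival["time_years"].to_numpy(float)
    e = survival["event"].to_numpy(int)
    if (t <= 0).any():
        raise ValueError("follow-up times must be positive")
    if e.sum() < 1:
        raise ValueError("need at least one event")
    frame = scores.reset_index(drop=True).copy()
    frame["time_years"] = t
    frame["event"] = e
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time_years", event_col="event")
    risk = cph.predict_partial_hazard(frame).to_numpy()
    return cph, np.log(risk)


@dataclass
class ConcordanceResult:
    """Harrell's C with a bootstrap confidence interval."""

    c_index: float
    ci_low: float
    ci_high: float
    n_events: int


def _cindex(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> float:
    """Harrell's C over comparable pairs (event vs longer survivor); ties
    in risk count one half."""
    ev = np.flatnonzero(event == 1)
    concordant = 0.0
    comparable = 0
    for i in ev:
        later = time > time[i]
        m = int(later.sum())
        if m == 0:
            continue
        comparable += m
        ri = risk[i]
        rj = risk[later]
        concordant += np.sum(ri > rj) + 0.5 * np.sum(ri == rj)
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return float(concordant / comparable)


def harrell_c(
    risk: np.ndarray,
    survival: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
) -> ConcordanceResult:
    """Harrell's concordance index with a participant-level bootstrap CI."""
    t = survival["time_years"].to_numpy(float)
    e = survival["event"].to_numpy(int)
    r = np.asarray(risk, float)
    c = _cindex(t, e, r)
    lo = hi = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = t.size
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                boots.append(_cindex(t[idx], e[idx], r[idx]))
            except ValueError:
                continue
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
    return ConcordanceResult(c, float(lo), float(hi), int(e.sum()))


def compare_c(
    risk_a: np.ndarray,
    risk_b: np.ndarray,
    survival: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> Dict[str, float]:
    """Paired bootstrap comparison of two risk scores' C-indices.

    Resamples participants, recomputes both C-indices on each replicate
    and returns the observed difference ``delta_c = C_a - C_b`` with a
    two-sided bootstrap p-value (identical models give delta 0 and p 1).
    """
    t = survival["time_years"].to_numpy(float)
    e = survival["event"].to_numpy(int)
    ra, rb = np.asarray(risk_a, float), np.asarray(risk_b, float)
    c_a = _cindex(t, e, ra)
    c_b = _cindex(t, e, rb)
    delta = c_a - c_b
    rng = np.random.default_rng(seed)
    n = t.size
    deltas = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            deltas.append(_cindex(t[idx], e[idx], ra[idx])
                          - _cindex(t[idx], e[idx], rb[idx]))
        except ValueError:
            continue
    deltas = np.asarray(deltas)
    if deltas.size == 0 or np.all(deltas == deltas[0]) and deltas[0] == 0.0:
        p = 1.0
    else:
        p_low = (np.sum(deltas <= 0) + 1) / (deltas.size + 1)
        p_high = (np.sum(deltas >= 0) + 1) / (deltas.size + 1)
        p = float(min(1.0, 2 * min(p_low, p_high)))
    return {"c_a": c_a, "c_b": c_b, "delta_c": delta, "p_value": p,
            "n_boot": int(deltas.size)}


def metricset_comparison(
    metrics: pd.DataFrame,
    survival: pd.DataFrame,
    subset: Sequence[str] = tuple(TEN_METRIC_SUBSET),
    eigen_min: float = 1.0,
    cumvar_min: float = 0.75,
    n_boot: int = 1000,
    seed: int = 0,
) -> Dict[str, object]:
    """Compare mortality prediction from the full metric set vs a subset.

    For each metric set: standardise, reduce by PCA with the joint
    retention rule, fit a Cox model on the retained components, compute
    Harrell's C; then compare the two C-indices by paired bootstrap.
    Complete-case rows shared by both sets are used.
    """
    complete = metrics.dropna(how="any")
    surv = survival.loc[complete.index] if survival.index.equals(metrics.index) \
        else survival.iloc[[metrics.index.get_loc(i) for i in complete.index]]

    def _risk(cols):
        Z = MetricStandardizer().fit_transform(complete[list(cols)])
        pca = CircadianPca(eigen_min, cumvar_min).fit(Z)
        scores = pca.transform(Z)
        _, risk = cox_component_model(scores, surv)
        return risk, pca

    risk_full, pca_full = _risk(metrics.columns)
    risk_sub, pca_sub = _risk(subset)
    comp = compare_c(risk_full, risk_sub, surv, n_boot=n_boot, seed=seed)
    return {
        "c_full": comp["c_a"],
        "c_subset": comp["c_b"],
        "delta_c": comp["delta_c"],
        "p_value": comp["p_value"],
        "n_components_full": pca_full.n_retained_,
        "n_components_subset": pca_sub.n_retained_,
        "cumvar_full": pca_full.cumvar_,
        "cumvar_subset": pca_sub.cumvar_,
        "n": len(complete),
    }
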