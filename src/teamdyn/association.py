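"""Questionnaire scoring, reliability, and marginal models.

Each participant rates two multi-item 7-point Likert subscales — quality of
participation and social support.  Participant scores are item means;
internal consistency is Cronbach's alpha.  The link between group-level
interaction dynamics and individual-level perception is estimated with
generalized estimating equations (GEE): outcome = subscale score, cluster =
group, predictors = the group's recurrence rate (stability), determinism
(predictability) and diagonal-line entropy (complexity), Gaussian family
with identity link, exchangeable working correlation, robust sandwich
standard errors, and Pan's QIC for model comparison.  GEE is the right tool
here because members of the same group share both the predictors and
unmeasured group context, so responses are correlated within clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

SCALE_PARTICIPATION = "quality of participation"
SCALE_SUPPORT = "social support"

PREDICTOR_LABELS = {"Intercept": "(Intercept)", "rr": "Stability",
                    "det": "Determinism", "ent": "Complexity"}


@dataclass(frozen=True)
class GEETerm:
    name: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    wald: float
    p: float


@dataclass(frozen=True)
class GEEFit:
    outcome: str
    terms: tuple[GEETerm, ...]
    qic: float
    rho: float
    n_clusters: int
    n_obs: int
    cov_struct: str

    def term(self, name: str) -> GEETerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def score_scale(responses: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score one subscale: participant means and group means of those.

    ``responses`` must hold columns participant, group, item, value (one
    row per answered item).  Raises if any listed participant has no items.
    """
    required = {"participant", "group", "item", "value"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")
    if responses.empty:
        raise ValueError("empty responses")
    participant = (
        responses.groupby(["group", "participant"], sort=True)["value"]
        .mean()
        .rename("score")
        .reset_index()
    )
    group = participant.groupby("group", sort=True)["score"].mean().rename("score").reset_index()
    return participant, group


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a participants x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with unbiased (n-1) sample variances.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 participants and >= 2 items")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of item sums: alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def item_matrix(responses: pd.DataFrame) -> np.ndarray:
    """Pivot long-format responses to a participants x items matrix."""
    wide = responses.pivot_table(index="participant", columns="item", values="value")
    if wide.isna().any().any():
        raise ValueError("incomplete item responses: cannot form item matrix")
    return wide.to_numpy(dtype=float)


def build_gee_data(
    measures: pd.DataFrame, participant_scores: pd.DataFrame
) -> pd.DataFrame:
    """One row per participant: subscale score plus the group's RQA measures."""
    data = participant_scores.merge(measures, on="group", how="inner", validate="many_to_one")
    if data["group"].nunique() < 2:
        raise ValueError("need at least 2 groups (clusters)")
    return data


def fit_gee(
    data: pd.DataFrame,
    outcome: str = "score",
    predictors: Sequence[str] = ("rr", "det", "ent"),
    cov_struct: Literal["exchangeable", "independence"] = "exchangeable",
    outcome_label: str = "",
) -> GEEFit:
    """Fit one marginal model of a subscale score on the RQA measures.

    Gaussian family, identity link; robust (sandwich) covariance throughout.
    Per-term Wald statistics are (B/SE)^2 against chi-square(1); 95%
    confidence intervals use the normal 1.96 quantile.
    """
    groups = data["group"]
    n_clusters = groups.nunique()
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    exog = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    exog = exog.rename(columns={"const": "Intercept"})
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if n_clusters <= exog.shape[1]:
        warnings.warn(
            f"only {n_clusters} clusters for {exog.shape[1]} parameters; "
            "sandwich standard errors may be unstable",
            stacklevel=2,
        )
    y = data[outcome].astype(float)
    if np.ptp(y.to_numpy()) == 0:
        # degenerate: constant outcome has an exact flat fit and no sampling
        # variability for the sandwich to estimate
        const = float(y.iloc[0])
        terms = tuple(
            GEETerm(
                name=PREDICTOR_LABELS.get(name, name),
                b=const if name == "Intercept" else 0.0,
                se=0.0,
                ci_low=const if name == "Intercept" else 0.0,
                ci_high=const if name == "Intercept" else 0.0,
                wald=float("inf") if name == "Intercept" and const != 0 else 0.0,
                p=0.0 if name == "Intercept" and const != 0 else 1.0,
            )
            for name in exog.columns
        )
        return GEEFit(outcome=outcome_label or outcome, terms=terms, qic=float("nan"),
                      rho=0.0, n_clusters=int(n_clusters), n_obs=int(len(data)),
                      cov_struct=cov_struct)
    cov = sm.cov_struct.Exchangeable() if cov_struct == "exchangeable" else sm.cov_struct.Independence()
    model = sm.GEE(
        y,
        exog,
        groups=groups,
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    res = model.fit(maxiter=100, ctol=1e-10)
    params, se = res.params, res.bse  # robust by default
    terms = []
    for name in exog.columns:
        b, s = float(params[name]), float(se[name])
        wald = (b / s) ** 2
        terms.append(
            GEETerm(
                name=PREDICTOR_LABELS.get(name, name),
                b=b,
                se=s,
                ci_low=b - 1.96 * s,
                ci_high=b + 1.96 * s,
                wald=wald,
                p=float(scipy.stats.chi2.sf(wald, df=1)),
            )
        )
    qic_value, _qicu = res.qic(scale=res.scale)
    rho = float(cov.dep_params) if cov_struct == "exchangeable" else 0.0
    max_size = data.groupby("group").size().max()
    lo = -1.0 / (max_size - 1) if max_size > 1 else -1.0
    if not lo < rho < 1:
        warnings.warn(f"exchangeable correlation {rho:.3f} outside ({lo:.3f}, 1); clamped",
                      stacklevel=2)
        rho = min(max(rho, lo + 1e-6), 1 - 1e-6)
    return GEEFit(
        outcome=outcome_label or outcome,
        terms=tuple(terms),
        qic=float(qic_value),
        rho=rho,
        n_clusters=int(n_clusters),
        n_obs=int(len(data)),
        cov_struct=cov_struct,
    )


def variance_inflation(data: pd.DataFrame, predictors: Sequence[str] = ("rr", "det", "ent")) -> dict[str, float]:
    """Variance inflation factors of the predictors (flag above 10)."""
    exog = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    arr = exog.to_numpy()
    return {
        name: float(variance_inflation_factor(arr, i))
        for i, name in enumerate(exog.columns)
        if name != "const"
    }


def run_association(
    measures: pd.DataFrame,
    responses: pd.DataFrame,
    cov_struct: Literal["exchangeable", "independence"] = "exchangeable",
) -> tuple[pd.DataFrame, dict]:
    """Fit both marginal models and lay the results out as a findings table.

    ``measures``: columns group, rr, det, ent (one row per group).
    ``responses``: long format participant, group, scale, item, value with
    both subscales present.  Returns the table (one row per coefficient:
    Outcome, QIC, Parameter, B, SE, ci_low, ci_high, Wald, p) and a details
    dict with the fits, VIFs and Cronbach's alphas.
    """
    rows = []
    details: dict = {"fits": {}, "vif": None, "alpha": {}}
    for scale in (SCALE_PARTICIPATION, SCALE_SUPPORT):
        sub = responses[responses["scale"] == scale]
        if sub.empty:
            raise ValueError(f"no responses for scale {scale!r}")
        participant_scores, _ = score_scale(sub)
        details["alpha"][scale] = cronbach_alpha(item_matrix(sub))
        data = build_gee_data(measures, participant_scores)
        if details["vif"] is None:
            details["vif"] = variance_inflation(data)
        fit = fit_gee(data, cov_struct=cov_struct, outcome_label=scale)
        details["fits"][scale] = fit
        for term in fit.terms:
            rows.append(
                {
                    "Outcome": scale,
                    "QIC": round(fit.qic, 3),
                    "Parameter": term.name,
                    "B": term.b,
                    "SE": term.se,
                    "ci_low": term.ci_low,
                    "ci_high": term.ci_high,
                    "Wald": term.wald,
                    "p": term.p,
                }
            )
    return pd.DataFrame(rows), details


def write_results_table(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), index=False, float_format="%.6g")
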