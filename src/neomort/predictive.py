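"""Multivariable prediction of 28-day death with QIC forward selection.

The predictive model is a log-link marginal model of the binary death
indicator with Poisson working variance, fitted by GEE with a robust
covariance clustered on study area; exponentiated coefficients are adjusted
relative risks.  Model choice uses the quasi-likelihood under the
independence model criterion (Pan, Biometrics 2001):

    QIC = -2 * QL(mu_hat; independence) + 2 * trace(Omega_I V_R)

where QL is the working-family quasi-likelihood evaluated at the fitted
means, Omega_I the model-based information under the independence working
model, and V_R the robust covariance.  Fit quality is summarised by the
marginal R^2 of the fitted mean (Zheng, Statistics in Medicine 2000):
1 - SSE/SST on the response scale.

Forward selection is greedy: starting from the intercept-only model, each
step adds the candidate that most lowers QIC, stopping when no addition
lowers it.  Ties break by candidate list order.  Newborn treatments and
essential-newborn-care indicators are deliberately absent from the default
candidate set: they are consequences of the infant's condition rather than
primary risk factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from sklearn.base import BaseEstimator

from .cohort import AnalysisCohort
from .risk import Z_95, RiskEstimate, RiskModelError
from .variables import add_derived, build_design, death_indicator

#: the shipped final-model preset: gestational age at delivery (per one-week
#: decrease), birth-weight band, and antenatal-care visit category
FINAL_MODEL_VARIABLES = ["ga_delivery_weeks", "birth_weight_band", "anc_visits_category"]

#: default forward-selection candidates (maternal + core neonatal factors;
#: treatments and newborn-care indicators are excluded by design)
DEFAULT_CANDIDATES = [
    "ga_delivery_weeks",
    "birth_weight_band",
    "anc_visits_category",
    "education",
    "parity_category",
    "age_category",
    "bmi_category",
]


def quasi_loglik(y: np.ndarray, mu: np.ndarray, family) -> float:
    """Independence quasi-likelihood of the working family at scale 1."""
    if isinstance(family, sm.families.Poisson):
        return float(np.sum(special.xlogy(y, mu) - mu))
    if isinstance(family, sm.families.Binomial):
        return float(np.sum(special.xlogy(y, mu) + special.xlogy(1 - y, 1 - mu)))
    raise ValueError(f"unsupported working family {type(family).__name__}")


def qic(result) -> float:
    """QIC of a fitted log-link GEE result.

    Uses the robust covariance the result was fitted with; the information
    matrix is recomputed under the independence working model at the fitted
    coefficients.  Raises :class:`RiskModelError` naming the offending term
    when that matrix is singular.
    """
    model = result.model
    y = np.asarray(model.endog, float)
    mu = np.asarray(result.fittedvalues, float)
    exog = np.asarray(model.exog, float)
    family = model.family

    ql = quasi_loglik(y, mu, family)
    # log link: dmu/deta = mu; weight = (dmu/deta)^2 / Var(mu)
    if isinstance(family, sm.families.Poisson):
        w = mu
    else:
        w = mu**2 / (mu * (1.0 - mu))
    omega = exog.T @ (exog * w[:, None])
    cond = np.linalg.cond(omega)
    if not np.isfinite(cond) or cond > 1e12:
        names = getattr(model, "exog_names", None) or [
            f"x{j}" for j in range(exog.shape[1])
        ]
        diag = np.diag(omega)
        worst = names[int(np.argmin(diag))]
        raise RiskModelError(
            f"independence information matrix is singular (term {worst!r})"
        )
    trace = float(np.trace(omega @ np.asarray(result.cov_params())))
    return -2.0 * ql + 2.0 * trace


def marginal_r2(result) -> float:
    """Squared-error R^2 of the fitted marginal mean on the response scale."""
    y = np.asarray(result.model.endog, float)
    mu = np.asarray(result.fittedvalues, float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("outcome has zero variance; marginal R^2 undefined", stacklevel=2)
        return np.nan
    return 1.0 - float(np.sum((y - mu) ** 2)) / sst


@dataclass
class ModelSummary:
    """Adjusted relative risks of a fitted multivariable model."""

    estimates: list  # RiskEstimate per non-intercept term
    marginal_r2: float
    qic: float
    n_obs: int
    n_clusters: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [e.label for e in self.estimates],
                "rr": [e.rr for e in self.estimates],
                "ci_low": [e.ci_low for e in self.estimates],
                "ci_high": [e.ci_high for e in self.estimates],
                "p_value": [e.p_value for e in self.estimates],
            }
        )


def _drop_aliased(exog: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    """Drop linearly dependent columns (intercept always kept), warning."""
    keep = [0]
    for j in range(1, exog.shape[1]):
        trial = exog[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(
                f"dropping aliased model column {names[j]!r}", stacklevel=3
            )
    return exog[:, keep], [names[j] for j in keep]


def fit_multivariable(
    cohort: Union[AnalysisCohort, pd.DataFrame],
    variables: Optional[list] = None,
    working_correlation: str = "independence",
    references: Optional[dict] = None,
):
    """Fit the multivariable marginal model; returns ``(result, summary)``.

    ``result`` is the statsmodels GEE results object (Poisson working
    variance, log link, robust clustered covariance); ``summary`` a
    :class:`ModelSummary` with adjusted relative risks, marginal R^2 and
    QIC.
    """
    variables = FINAL_MODEL_VARIABLES if variables is None else variables
    df = cohort.data if isinstance(cohort, AnalysisCohort) else cohort
    df = add_derived(df)
    y_all = death_indicator(df)
    design = build_design(df, variables, references=references)
    idx = design.index
    keep = y_all.loc[idx].notna() & df.loc[idx, "cluster_id"].notna()
    idx = idx[keep]
    exog = design.exog[np.asarray(keep)]
    names = list(design.names)
    y = y_all.loc[idx].to_numpy(float)
    groups = df.loc[idx, "cluster_id"].to_numpy()
    n_clusters = len(pd.unique(groups))
    if n_clusters < 2:
        raise RiskModelError("at least 2 clusters are required")

    exog, names = _drop_aliased(exog, names)
    # an indicator level with no observed events has a divergent log-RR and a
    # singular independence information matrix; drop it (reference-merged)
    keep = [0]
    for j in range(1, exog.shape[1]):
        col = exog[:, j]
        if set(np.unique(col)) <= {0.0, 1.0} and float(col @ y) == 0.0 and col.any():
            warnings.warn(
                f"no events observed for {names[j]!r}; term dropped", stacklevel=2
            )
        else:
            keep.append(j)
    exog, names = exog[:, keep], [names[j] for j in keep]
    cov_struct = {
        "independence": sm.cov_struct.Independence,
        "exchangeable": sm.cov_struct.Exchangeable,
    }[working_correlation]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y, exog, groups=groups, family=sm.families.Poisson(), cov_struct=cov_struct
        )
        model.exog_names[:] = names
        result = model.fit(maxiter=200)

    ses = np.sqrt(np.diag(result.cov_params()))
    estimates = [
        RiskEstimate(
            rr=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * se)),
            ci_high=float(np.exp(b + Z_95 * se)),
            p_value=float(2.0 * stats.norm.sf(abs(b / se))),
            method="cluster_gee_poisson",
            label=name,
            n=len(y),
        )
        for name, b, se in zip(names[1:], result.params[1:], ses[1:])
    ]
    summary = ModelSummary(
        estimates=estimates,
        marginal_r2=marginal_r2(result),
        qic=qic(result),
        n_obs=len(y),
        n_clusters=n_clusters,
    )
    return result, summary


@dataclass
class SelectionStep:
    """One forward-selection step: every candidate's QIC, and the winner."""

    qic_before: float
    candidate_qic: dict
    chosen: Optional[str]

    @property
    def qic_after(self) -> float:
        return self.candidate_qic[self.chosen] if self.chosen else self.qic_before


@dataclass
class SelectionPath:
    """The full greedy path and the final model."""

    steps: list = field(default_factory=list)
    selected: list = field(default_factory=list)
    final_result: object = None
    final_summary: Optional[ModelSummary] = None

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, step in enumerate(self.steps):
            for cand, q in step.candidate_qic.items():
                rows.append(
                    {
                        "step": i + 1,
                        "candidate": cand,
                        "qic": q,
                        "qic_before": step.qic_before,
                        "chosen": cand == step.chosen,
                    }
                )
        return pd.DataFrame(rows)


class ForwardQICSelector(BaseEstimator):
    """Greedy forward selection of risk factors by QIC (scikit-learn style).

    Parameters
    ----------
    candidates : list of str, optional
        Analysis variables to consider; defaults to the maternal and core
        neonatal factors (treatments excluded).
    working_correlation : {"independence", "exchangeable"}
    max_steps : int, optional
        Cap on the number of added variables (no cap by default).

    Attributes (after ``fit``)
    --------------------------
    path_ : :class:`SelectionPath`
    selected_ : list of chosen variable names, in selection order
    result_, summary_ : the final fitted model and its summary
    """

    def __init__(
        self,
        candidates: Optional[list] = None,
        working_correlation: str = "independence",
        max_steps: Optional[int] = None,
    ):
        self.candidates = candidates
        self.working_correlation = working_correlation
        self.max_steps = max_steps

    def fit(self, X: Union[AnalysisCohort, pd.DataFrame], y=None):
        candidates = list(
            DEFAULT_CANDIDATES if self.candidates is None else self.candidates
        )
        path = SelectionPath()
        selected: list = []
        _, cur_summary = fit_multivariable(
            X, [], working_correlation=self.working_correlation
        )
        cur_qic = cur_summary.qic
        remaining = list(candidates)
        while remaining:
            if self.max_steps is not None and len(selected) >= self.max_steps:
                break
            scores: dict = {}
            for cand in list(remaining):
                try:
                    _, summ = fit_multivariable(
                        X, selected + [cand], working_correlation=self.working_correlation
                    )
                    scores[cand] = summ.qic
                except (RiskModelError, np.linalg.LinAlgError, ValueError) as exc:
                    warnings.warn(
                        f"candidate {cand!r} disqualified: {exc}", stacklevel=2
                    )
                    remaining.remove(cand)
            if not scores:
                break
            # min QIC; ties break by candidate list order (dict preserves it)
            best = min(scores, key=scores.get)
            if scores[best] < cur_qic:
                path.steps.append(SelectionStep(cur_qic, scores, best))
                selected.append(best)
                remaining.remove(best)
                cur_qic = scores[best]
            else:
                path.steps.append(SelectionStep(cur_qic, scores, None))
                break
        result, summary = fit_multivariable(
            X, selected, working_correlation=self.working_correlation
        )
        path.selected = selected
        path.final_result = result
        path.final_summary = summary
        self.path_ = path
        self.selected_ = selected
        self.result_ = result
        self.summary_ = summary
        return self


def forward_select(
    cohort: Union[AnalysisCohort, pd.DataFrame],
    candidates: Optional[list] = None,
    working_correlation: str = "independence",
) -> SelectionPath:
    """Greedy QIC forward selection; see :class:`ForwardQICSelector`."""
    sel = ForwardQICSelector(
        candidates=candidates, working_correlation=working_correlation
    ).fit(cohort)
    return sel.path_
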