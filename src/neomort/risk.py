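"""Relative risks of 28-day neonatal death, crude and cluster-adjusted.

Crude risk ratios come from the closed form on a 2x2 table.  Cluster-aware
estimates come from a marginal log-link binary-outcome model (log-binomial
working model, falling back to a log-link model with Poisson variance when
the log-binomial fit fails to converge) fitted by generalized estimating
equations with a robust (sandwich) covariance clustered on the study-area
identifier.  Exponentiated coefficients are relative risks; confidence
intervals and p-values are Wald on the log scale.

Registry clusters are geographic study areas; outcomes within a cluster are
correlated, so naive binomial variances understate uncertainty.  The working
correlation defaults to independence — with a sandwich covariance the point
estimates stay consistent and the intervals are cluster-robust regardless of
the true correlation; exchangeable is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import AnalysisCohort
from .variables import add_derived, build_design, death_indicator, get_spec

#: 95% two-sided normal critical value, fixed to six decimals
Z_95 = 1.959964


class RiskModelError(RuntimeError):
    """The risk model cannot be fitted on the given data."""


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts: events/totals among exposed and unexposed."""

    a: int  # exposed events
    n1: int  # exposed total
    c: int  # unexposed events
    n0: int  # unexposed total

    def __post_init__(self):
        if min(self.a, self.n1, self.c, self.n0) < 0:
            raise ValueError("counts must be non-negative")
        if self.a > self.n1 or self.c > self.n0:
            raise ValueError("events cannot exceed totals")


@dataclass(frozen=True)
class RiskEstimate:
    """A relative risk with its 95% Wald interval and p-value."""

    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    label: str = ""
    reference: str = ""
    n: Optional[int] = None
    unbounded_ci: bool = False


def crude_rr(table: TwoByTwo, label: str = "", reference: str = "") -> RiskEstimate:
    """Closed-form risk ratio with the standard log-scale Wald interval.

    A zero event count in either arm leaves the ratio or interval undefined;
    the estimate is returned with ``unbounded_ci=True`` rather than raising.
    """
    if table.n1 == 0 or table.n0 == 0:
        raise ValueError("both exposure groups must be non-empty")
    n = table.n1 + table.n0
    if table.a == 0 or table.c == 0:
        rr = 0.0 if table.a == 0 and table.c > 0 else np.inf
        if table.a == 0 and table.c == 0:
            rr = np.nan
        return RiskEstimate(
            rr, 0.0, np.inf, np.nan, "crude", label, reference, n, unbounded_ci=True
        )
    log_rr = np.log((table.a / table.n1) / (table.c / table.n0))
    se = np.sqrt(1 / table.a - 1 / table.n1 + 1 / table.c - 1 / table.n0)
    z = log_rr / se
    p = 2.0 * stats.norm.sf(abs(z))
    return RiskEstimate(
        rr=float(np.exp(log_rr)),
        ci_low=float(np.exp(log_rr - Z_95 * se)),
        ci_high=float(np.exp(log_rr + Z_95 * se)),
        p_value=float(p),
        method="crude",
        label=label,
        reference=reference,
        n=n,
    )


def two_by_two(
    cohort: Union[AnalysisCohort, pd.DataFrame],
    variable: str,
    level: str,
    reference: str,
) -> TwoByTwo:
    """Count a 2x2 table of one exposure level against the reference level."""
    df = cohort.data if isinstance(cohort, AnalysisCohort) else cohort
    df = add_derived(df)
    y = death_indicator(df)
    keep = df[variable].notna() & y.notna()
    v, y = df.loc[keep, variable], y[keep]
    exposed = v == level
    ref = v == reference
    return TwoByTwo(
        a=int(y[exposed].sum()),
        n1=int(exposed.sum()),
        c=int(y[ref].sum()),
        n0=int(ref.sum()),
    )


# ---------------------------------------------------------------------------


class ClusterRelativeRisk(BaseEstimator):
    """Cluster-robust relative-risk estimator for a single exposure.

    Parameters
    ----------
    exposure : str
        Analysis variable name (schema column or derived band).
    reference : str, optional
        Reference level for a categorical exposure; defaults to the
        schema's conventional reference (e.g. ``">=2500"`` for birth-weight
        bands, ``"4+"`` for antenatal-care visits).
    per_unit_decrease : bool
        For a continuous exposure, report the relative risk per one-unit
        *decrease* (the convention for gestational age at delivery).
    working_correlation : {"independence", "exchangeable"}
        GEE working correlation structure.
    family : {"binomial", "poisson"}
        Working variance of the log-link marginal model.  ``"binomial"``
        (the log-binomial model) falls back automatically to Poisson
        variance if the fit does not converge; the fallback is tagged in
        ``method_``.
    cov_type : {"bias_reduced", "robust"}
        Sandwich covariance flavour for Wald inference.  The default is the
        Mancl-DeRouen bias-reduced sandwich, which corrects the downward
        bias of the plain robust covariance when the number of clusters is
        modest (registries typically have a few dozen study areas).

    Attributes (after ``fit``)
    --------------------------
    estimates_ : list of :class:`RiskEstimate`, one per non-reference level.
    overall_wald_p_ : float, joint Wald test across the exposure's terms.
    result_ : statsmodels GEE results object.
    n_clusters_, n_obs_, method_, converged_
    """

    def __init__(
        self,
        exposure: str = "birth_weight_band",
        reference: Optional[str] = None,
        per_unit_decrease: bool = True,
        working_correlation: str = "independence",
        family: str = "binomial",
        cov_type: str = "bias_reduced",
    ):
        self.exposure = exposure
        self.reference = reference
        self.per_unit_decrease = per_unit_decrease
        self.working_correlation = working_correlation
        self.family = family
        self.cov_type = cov_type

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None, groups=None):
        """Fit on cohort rows.

        ``y`` defaults to the 28-day death indicator derived from
        ``alive_at_28d``; ``groups`` defaults to ``cluster_id``.
        """
        df = X.data if isinstance(X, AnalysisCohort) else X
        df = add_derived(df)
        spec = get_spec(self.exposure, self.reference)
        y_all = death_indicator(df) if y is None else pd.Series(np.asarray(y, float), index=df.index)
        g_all = df["cluster_id"] if groups is None else pd.Series(groups, index=df.index)

        design = build_design(
            df,
            [self.exposure],
            references={self.exposure: spec.reference} if spec.reference else None,
        )
        idx = design.index
        keep = y_all.loc[idx].notna() & g_all.loc[idx].notna()
        idx = idx[keep]
        exog = design.exog[np.asarray(keep)]
        # build_design negates a per-decrease variable; undo if asked for the
        # per-increase parameterisation (the estimate is sign-symmetric)
        if spec.kind == "continuous" and spec.negate and not self.per_unit_decrease:
            exog = exog.copy()
            exog[:, 1] = -exog[:, 1]
            design.names[1] = spec.name
        yv = y_all.loc[idx].to_numpy(float)
        gv = g_all.loc[idx].to_numpy()

        if spec.kind == "continuous" and np.ptp(exog[:, 1]) == 0:
            raise RiskModelError(f"exposure {self.exposure!r} is constant")
        n_clusters = len(pd.unique(gv))
        if n_clusters < 2:
            raise RiskModelError(
                "robust variance is degenerate with a single cluster; "
                "at least 2 clusters are required"
            )

        result, method, converged = _fit_log_link_gee(
            yv, exog, gv, self.working_correlation, self.family
        )
        self.result_ = result
        self.method_ = method
        self.converged_ = converged
        self.n_obs_ = len(yv)
        self.n_clusters_ = n_clusters
        self.design_names_ = list(design.names)
        self.params_ = np.asarray(result.params)
        if self.cov_type == "bias_reduced" and result.cov_robust_bc is not None:
            self.cov_ = np.asarray(result.cov_robust_bc)
        else:
            self.cov_ = np.asarray(result.cov_robust)

        ses = np.sqrt(np.diag(self.cov_))
        estimates = []
        for j, name in enumerate(self.design_names_):
            if j == 0:
                continue
            b, se = self.params_[j], ses[j]
            estimates.append(
                RiskEstimate(
                    rr=float(np.exp(b)),
                    ci_low=float(np.exp(b - Z_95 * se)),
                    ci_high=float(np.exp(b + Z_95 * se)),
                    p_value=float(2.0 * stats.norm.sf(abs(b / se))),
                    method=method,
                    label=name,
                    reference=spec.reference or "",
                    n=self.n_obs_,
                )
            )
        self.estimates_ = estimates

        # joint Wald test across the exposure's terms, on the chosen covariance
        b = self.params_[1:]
        cov_b = self.cov_[1:, 1:]
        try:
            chi2 = float(b @ np.linalg.solve(cov_b, b))
            self.overall_wald_p_ = float(stats.chi2.sf(chi2, df=len(b)))
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
            self.overall_wald_p_ = np.nan
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted marginal death probability for new cohort rows."""
        df = X.data if isinstance(X, AnalysisCohort) else X
        df = add_derived(df)
        spec = get_spec(self.exposure, self.reference)
        design = build_design(
            df,
            [self.exposure],
            references={self.exposure: spec.reference} if spec.reference else None,
        )
        return np.exp(design.exog @ self.params_)


def _fit_log_link_gee(y, exog, groups, working_correlation, family):
    """Fit a log-link marginal model by GEE with robust covariance.

    Returns ``(results, method_tag, converged)``.  The log-binomial working
    model is started at the Poisson solution; if it fails (non-convergence,
    numerical error, or fitted means above 1) the Poisson-variance fit is
    returned, tagged as the documented fallback.
    """
    cov_struct = {
        "independence": sm.cov_struct.Independence,
        "exchangeable": sm.cov_struct.Exchangeable,
    }[working_correlation]()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        poisson = sm.GEE(
            y, exog, groups=groups, family=sm.families.Poisson(), cov_struct=cov_struct
        ).fit(maxiter=200, cov_type="bias_reduced")
    if family == "poisson":
        return poisson, "cluster_gee_poisson", True

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            binom = sm.GEE(
                y,
                exog,
                groups=groups,
                family=sm.families.Binomial(link=sm.families.links.Log()),
                cov_struct={
                    "independence": sm.cov_struct.Independence,
                    "exchangeable": sm.cov_struct.Exchangeable,
                }[working_correlation](),
            ).fit(maxiter=200, start_params=poisson.params, cov_type="bias_reduced")
        mu = np.asarray(binom.fittedvalues)
        ok = np.all(np.isfinite(binom.params)) and np.all(mu < 1.0) and np.all(mu > 0.0)
        if ok:
            return binom, "cluster_gee", True
    except (ValueError, np.linalg.LinAlgError, ZeroDivisionError):
        pass
    warnings.warn(
        "log-binomial GEE failed to converge; falling back to log-link "
        "Poisson-variance GEE with robust errors",
        stacklevel=3,
    )
    return poisson, "cluster_gee_poisson_fallback", False


# -- thin functional wrappers ------------------------------------------------


def cluster_rr(
    cohort: Union[AnalysisCohort, pd.DataFrame],
    variable: str,
    reference: Optional[str] = None,
    working_correlation: str = "independence",
    family: str = "binomial",
) -> tuple[list, float]:
    """Per-level cluster-robust relative risks plus the overall Wald p."""
    est = ClusterRelativeRisk(
        exposure=variable,
        reference=reference,
        working_correlation=working_correlation,
        family=family,
    ).fit(cohort)
    return est.estimates_, est.overall_wald_p_


def continuous_rr(
    cohort: Union[AnalysisCohort, pd.DataFrame],
    variable: str,
    per_unit_decrease: bool = True,
    working_correlation: str = "independence",
    family: str = "binomial",
) -> RiskEstimate:
    """Relative risk per one-unit change of a numeric variable."""
    est = ClusterRelativeRisk(
        exposure=variable,
        per_unit_decrease=per_unit_decrease,
        working_correlation=working_correlation,
        family=family,
    ).fit(cohort)
    return est.estimates_[0]
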