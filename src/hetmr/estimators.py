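"""Causal estimators for genetically driven effect heterogeneity.

Two families of quantities are estimated from an individual-level cohort:

* the genetically moderated exposure effect (GMEE) — the difference
  ``beta1 - beta0`` between the exposure effect in carriers and non-carriers
  of a moderator variant G — via the exposed-only contrast ``GMEE(1)``, the
  unexposed contrast ``GMEE(0)`` and their pleiotropy-robust difference
  ``RGMEE = GMEE(1) - GMEE(0)``;

* the group-specific causal effects ``beta1`` and ``beta0`` themselves, via
  two procedures that combine the moderator G with a conventional
  homogeneity-respecting instrument G2:

  - **Method 1** instruments the exposure with both variants jointly and
    fits the linear interaction model ``Y ~ S_hat*G + S_hat*(1-G)`` in a
    second stage.  Consistent when G satisfies independence and exclusion
    (it may affect the exposure).
  - **Method 2** first estimates the moderated effect by RGMEE, removes it
    from the outcome (``Y - diff_hat * S*`` with ``S* = G x S``), then runs a
    standard two-stage MR analysis with G2 alone on the adjusted outcome to
    recover ``beta0``; ``beta1`` follows by adding the RGMEE estimate.
    Consistent when G is independent of the exposure and the confounders,
    even if G affects the outcome directly (pleiotropy).

Standard errors are the stage-2 model-based errors throughout, with the
difference/sum combinations documented on :class:`GroupEffects`; no
first-stage variance correction is applied.  Confidence intervals are 95%
Wald intervals (``value +/- 1.96*se``) and p-values are two-sided normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import Cohort
from .errors import (
    CollinearityError,
    ConfigurationError,
    EstimabilityError,
    FitFailureError,
    GSAssociationWarning,
    WeakInstrumentWarning,
)

__all__ = [
    "FirstStageFit",
    "ScalarEstimate",
    "GroupEffects",
    "first_stage",
    "gmee_exposed",
    "gmee_unexposed",
    "rgmee",
    "method1",
    "method2",
    "standard_mr",
    "observational",
    "ace_identity",
    "estimates_to_frame",
]

_Z95 = 1.96


def _wald_p(value: float, se: float) -> float:
    if se == 0:
        return 0.0 if value != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(value) / se))


@dataclass(frozen=True)
class ScalarEstimate:
    """A single estimate with 95% Wald interval and two-sided p-value."""

    value: float
    se: float
    estimand_tag: str
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ConfigurationError(f"se must be non-negative, got {self.se!r}")
        object.__setattr__(self, "ci_low", self.value - _Z95 * self.se)
        object.__setattr__(self, "ci_high", self.value + _Z95 * self.se)
        object.__setattr__(self, "p_value", _wald_p(self.value, self.se))


@dataclass(frozen=True)
class GroupEffects:
    """Group-specific causal effect estimates (grams) from Method 1 or 2.

    For ``method1`` the difference is exactly ``beta1_hat - beta0_hat`` and
    its variance uses the stage-2 coefficient covariance:
    ``se_diff^2 = se_beta1^2 + se_beta0^2 - 2*cov_b1_b0``.

    For ``method2`` the two components are treated as independent, so
    ``se_beta1^2 = se_diff^2 + se_beta0^2`` exactly; ``cov_b1_b0`` is None.
    """

    beta1_hat: float
    beta0_hat: float
    diff_hat: float
    se_beta1: float
    se_beta0: float
    se_diff: float
    method_tag: str
    n_used: int
    cov_b1_b0: float | None = None

    _PARAMS = ("beta1", "beta0", "diff")

    def estimate(self, parameter: str) -> ScalarEstimate:
        """The named parameter (``beta1``/``beta0``/``diff``) as a ScalarEstimate."""
        if parameter not in self._PARAMS:
            raise KeyError(f"unknown parameter {parameter!r}; expected {self._PARAMS}")
        value = getattr(self, f"{parameter}_hat" if parameter != "diff" else "diff_hat")
        se = getattr(self, f"se_{parameter}" if parameter != "diff" else "se_diff")
        return ScalarEstimate(value=value, se=se, estimand_tag=f"{self.method_tag}:{parameter}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self._PARAMS:
            est = self.estimate(p)
            rows.append(
                dict(
                    method=self.method_tag,
                    parameter=p,
                    value=est.value,
                    se=est.se,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    p_value=est.p_value,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class FirstStageFit:
    """Fitted exposure model ``E[S | instruments, covariates]``.

    ``table`` has one row per instrument with the coefficient, its standard
    error, z statistic, p-value and a single-instrument F statistic (the
    squared z).
    """

    fitted_probs: np.ndarray
    table: pd.DataFrame
    instruments_used: list[str]
    link: str

    def f_statistic(self, instrument: str) -> float:
        return float(self.table.loc[instrument, "F"])


def _design(
    cohort: Cohort, columns: Sequence[str], add_const: bool = True
) -> pd.DataFrame:
    data = {name: cohort.column(name) for name in columns}
    X = pd.DataFrame(data, index=pd.RangeIndex(cohort.n))
    if add_const:
        X.insert(0, "const", np.ones(cohort.n))
    return X


def _check_collinearity(X: pd.DataFrame, skip: tuple[str, ...] = ("const",)) -> None:
    for col in X.columns:
        if col in skip:
            continue
        if np.ptp(X[col].to_numpy()) == 0.0:
            raise CollinearityError(f"design column {col!r} is constant")
    # rank via the k x k Gram matrix: cheap and stable for tall designs
    arr = X.to_numpy()
    gram = arr.T @ arr
    eigvals = np.linalg.eigvalsh(gram)
    if eigvals[0] < 1e-10 * max(eigvals[-1], 1.0):
        raise CollinearityError(
            f"design matrix with columns {list(X.columns)} is rank deficient"
        )


def first_stage(
    cohort: Cohort,
    instruments: Sequence[str],
    covariates: Sequence[str] = (),
    link: str = "logistic",
) -> FirstStageFit:
    """Fit the exposure model S ~ instruments + covariates.

    The default logistic link mirrors the applied-analysis convention for a
    binary exposure; a linear-probability backend is provided because the
    downstream ratio estimands are link-free.
    """
    instruments = list(instruments)
    if not instruments:
        raise ConfigurationError("instruments list must not be empty")
    X = _design(cohort, [*instruments, *covariates])
    _check_collinearity(X)
    s = cohort.s
    try:
        if link == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(s, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise FitFailureError("logistic first stage did not converge")
        elif link == "linear":
            res = sm.OLS(s, X).fit()
        else:
            raise ConfigurationError(
                f"link must be 'logistic' or 'linear', got {link!r}"
            )
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        np.linalg.LinAlgError,
    ) as err:
        raise FitFailureError(f"first-stage fit failed: {err}") from err
    z = res.params[instruments] / res.bse[instruments]
    table = pd.DataFrame(
        {
            "estimate": res.params[instruments],
            "se": res.bse[instruments],
            "z": z,
            "p_value": 2.0 * stats.norm.sf(np.abs(z)),
            "F": z**2,
        }
    )
    return FirstStageFit(
        fitted_probs=np.asarray(res.predict(X), dtype=float),
        table=table,
        instruments_used=instruments,
        link=link,
    )


# -- GMEE family ---------------------------------------------------------


def _cell_mean(cohort: Cohort, s_val: float, g_val: float) -> tuple[float, float, int]:
    mask = (cohort.s == s_val) & (cohort.g == g_val)
    n = int(mask.sum())
    if n == 0:
        raise EstimabilityError(f"cell (S={int(s_val)}, G={int(g_val)}) is empty")
    vals = cohort.y[mask]
    var = float(vals.var(ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), var, n


def _gmee(cohort: Cohort, s_val: float, tag: str) -> ScalarEstimate:
    m1, v1, n1 = _cell_mean(cohort, s_val, 1.0)
    m0, v0, n0 = _cell_mean(cohort, s_val, 0.0)
    return ScalarEstimate(
        value=m1 - m0, se=float(np.sqrt(v1 / n1 + v0 / n0)), estimand_tag=tag
    )


def gmee_exposed(cohort: Cohort) -> ScalarEstimate:
    """GMEE(1): between-genotype outcome contrast among the exposed.

    Estimates ``beta1 - beta0`` when the moderator is independent of the
    exposure and the confounders and has no direct outcome effect; any
    pleiotropic effect of G passes straight into this contrast.
    """
    return _gmee(cohort, 1.0, "gmee1")


def gmee_unexposed(cohort: Cohort) -> ScalarEstimate:
    """GMEE(0): between-genotype outcome contrast among the unexposed.

    Under no exposure the moderator can only reach the outcome through a
    direct (pleiotropic) path or via the confounder, so this contrast
    estimates exactly the bias afflicting GMEE(1).
    """
    return _gmee(cohort, 0.0, "gmee0")


def rgmee(cohort: Cohort) -> ScalarEstimate:
    """Robust GMEE: ``GMEE(1) - GMEE(0)``.

    Subtracting the unexposed contrast removes any direct moderator-outcome
    effect.  The estimator remains biased if the moderator is associated
    with the confounder or with the exposure itself, which is why a G-S
    association test is a prerequisite for its use.
    """
    e1 = gmee_exposed(cohort)
    e0 = gmee_unexposed(cohort)
    return ScalarEstimate(
        value=e1.value - e0.value,
        se=float(np.hypot(e1.se, e0.se)),
        estimand_tag="rgmee",
    )


# -- two-instrument group-effect procedures -------------------------------


def method1(
    cohort: Cohort,
    covariates_s: Sequence[str] = (),
    covariates_y: Sequence[str] = (),
    link: str = "logistic",
) -> GroupEffects:
    """Joint two-stage estimation of (beta1, beta0) using G and G2 together.

    Stage 1 fits ``E[S | G, G2, covariates_s]``; stage 2 regresses the
    outcome on ``S_hat*G`` and ``S_hat*(1-G)`` (plus ``covariates_y`` and an
    intercept).  Coefficient covariance from the stage-2 fit yields the
    standard error of the difference.
    """
    fs = first_stage(cohort, ["g", "g2"], covariates_s, link=link)
    shat = fs.fitted_probs
    X2 = _design(cohort, list(covariates_y))
    X2.insert(1, "shat_g", shat * cohort.g)
    X2.insert(2, "shat_1mg", shat * (1.0 - cohort.g))
    _check_collinearity(X2)
    res = sm.OLS(cohort.y, X2).fit()
    b1 = float(res.params["shat_g"])
    b0 = float(res.params["shat_1mg"])
    V = res.cov_params()
    v1 = float(V.loc["shat_g", "shat_g"])
    v0 = float(V.loc["shat_1mg", "shat_1mg"])
    c = float(V.loc["shat_g", "shat_1mg"])
    return GroupEffects(
        beta1_hat=b1,
        beta0_hat=b0,
        diff_hat=b1 - b0,
        se_beta1=float(np.sqrt(v1)),
        se_beta0=float(np.sqrt(v0)),
        se_diff=float(np.sqrt(v1 + v0 - 2.0 * c)),
        cov_b1_b0=c,
        method_tag="method1",
        n_used=cohort.n,
    )


def method2(
    cohort: Cohort,
    covariates_s: Sequence[str] = (),
    covariates_y: Sequence[str] = (),
    link: str = "logistic",
    gate_alpha: float = 0.05,
) -> GroupEffects:
    """RGMEE followed by MR on the moderation-free outcome.

    Step 1 estimates the moderated effect by RGMEE using G; step 2 fits
    ``E[S | G2, covariates_s]``; step 3 regresses the adjusted outcome
    ``Y - diff_hat * S*`` on the fitted exposure to recover ``beta0``.
    ``beta1 = beta0 + diff_hat`` with the independence approximation
    ``se_beta1 = sqrt(se_diff^2 + se_beta0^2)``.

    The G-S association prerequisite is tested and reported as a
    :class:`~hetmr.errors.GSAssociationWarning` (never silently enforced):
    Method 2 requires the moderator to be independent of the exposure.
    """
    step1 = rgmee(cohort)
    gate = first_stage(cohort, ["g"], covariates_s, link=link)
    gate_p = float(gate.table.loc["g", "p_value"])
    if gate_p < gate_alpha:
        warnings.warn(
            "moderator G is associated with exposure S "
            f"(F = {gate.f_statistic('g'):.2f}, p = {gate_p:.3g}); "
            "Method 2 assumes G is independent of S — interpret with caution",
            GSAssociationWarning,
            stacklevel=2,
        )
    fs = first_stage(cohort, ["g2"], covariates_s, link=link)
    y_adj = cohort.y - step1.value * cohort.s_star
    X3 = _design(cohort, list(covariates_y))
    X3.insert(1, "shat", fs.fitted_probs)
    _check_collinearity(X3)
    res = sm.OLS(y_adj, X3).fit()
    b0 = float(res.params["shat"])
    se_b0 = float(res.bse["shat"])
    return GroupEffects(
        beta1_hat=b0 + step1.value,
        beta0_hat=b0,
        diff_hat=step1.value,
        se_beta1=float(np.hypot(step1.se, se_b0)),
        se_beta0=se_b0,
        se_diff=step1.se,
        cov_b1_b0=None,
        method_tag="method2",
        n_used=cohort.n,
    )


def standard_mr(
    cohort: Cohort,
    instrument: str = "g2",
    covariates_s: Sequence[str] = (),
    covariates_y: Sequence[str] = (),
    link: str = "logistic",
    f_threshold: float = 10.0,
) -> ScalarEstimate:
    """Conventional two-stage MR estimate of the average causal effect.

    With a homogeneity-respecting instrument this targets the population
    ACE; with a homogeneity-violating one it targets the complier average
    causal effect under monotonicity.  A first-stage F statistic below
    ``f_threshold`` raises a :class:`WeakInstrumentWarning` (not an error).
    """
    fs = first_stage(cohort, [instrument], covariates_s, link=link)
    f_stat = fs.f_statistic(instrument)
    if f_stat < f_threshold:
        warnings.warn(
            f"first-stage F = {f_stat:.2f} for instrument {instrument!r} is below "
            f"{f_threshold:g}; estimate may suffer weak-instrument bias",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    X2 = _design(cohort, list(covariates_y))
    X2.insert(1, "shat", fs.fitted_probs)
    _check_collinearity(X2)
    res = sm.OLS(cohort.y, X2).fit()
    return ScalarEstimate(
        value=float(res.params["shat"]),
        se=float(res.bse["shat"]),
        estimand_tag="mr_ace",
    )


def observational(cohort: Cohort, covariates: Sequence[str] = ()) -> ScalarEstimate:
    """Covariate-adjusted linear regression of the outcome on the exposure.

    The confounded comparator: no instrument is used, so the coefficient
    reflects both the causal effect and any residual confounding.
    """
    X = _design(cohort, ["s", *covariates])
    _check_collinearity(X)
    res = sm.OLS(cohort.y, X).fit()
    return ScalarEstimate(
        value=float(res.params["s"]),
        se=float(res.bse["s"]),
        estimand_tag="observational",
    )


def ace_identity(beta0: float, diff: float, p_g_given_s1: float) -> float:
    """Average causal effect implied by the group effects.

    Under the linear interaction model the ACE targeted by a standard MR
    analysis with a homogeneity-respecting instrument equals
    ``beta0 + (beta1 - beta0) * E[G | S = 1]``.
    """
    if not (0.0 <= p_g_given_s1 <= 1.0):
        raise ConfigurationError(
            f"p_g_given_s1 must lie in [0, 1], got {p_g_given_s1!r}"
        )
    return beta0 + diff * p_g_given_s1


def estimates_to_frame(
    estimates: Sequence[ScalarEstimate | GroupEffects],
) -> pd.DataFrame:
    """Tidy table: one row per (estimand or method, parameter)."""
    frames = []
    for est in estimates:
        if isinstance(est, GroupEffects):
            frames.append(est.to_frame())
        else:
            frames.append(
                pd.DataFrame(
                    [
                        dict(
                            method=est.estimand_tag,
                            parameter="value",
                            value=est.value,
                            se=est.se,
                            ci_low=est.ci_low,
                            ci_high=est.ci_high,
                            p_value=est.p_value,
                        )
                    ]
                )
            )
    return pd.concat(frames, ignore_index=True)
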