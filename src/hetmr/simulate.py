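"""Synthetic-cohort generation and ground-truth estimands.

Cohorts are drawn from the linear-interaction structural model described in
:mod:`hetmr.config`.  Alongside the observed variables the simulator records
full latent truth — the confounder, potential exposures under each moderator
allele, and potential outcomes under each exposure level — by re-evaluating
the structural equations with the relevant variable forced while holding all
noise draws fixed (the "same person, different allele" counterfactual).  This
makes exact complier classification and oracle estimands available for every
simulated cohort.

:func:`wald_estimand` evaluates, under a known configuration, the population
quantity targeted by the Wald ratio ``Cov(G, Y) / Cov(G, S)``: a weighted
contrast of the group effects plus a bias term

.. math::

    B = \\frac{\\gamma_{YG} + \\gamma_{YU}\\,(E[U|G{=}1] - E[U|G{=}0])}
             {E[S|G{=}1] - E[S|G{=}0]},

which vanishes when the moderator satisfies independence and exclusion.
Under monotonicity the leading ratio term equals the complier average causal
effect (CACE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.special import roots_hermitenorm

from .cohort import Cohort
from .config import SimConfig
from .errors import (
    MonotonicityViolationError,
    UndefinedEstimandError,
    WeakInstrumentError,
)

__all__ = ["simulate_cohort", "true_cace", "wald_estimand", "WaldDecomposition"]

# Internal seed for the Monte-Carlo moment backend of wald_estimand.  Fixed so
# that the returned decomposition is a deterministic function of the
# configuration, independent of the cohort-level seed.
_MOMENT_SEED = 987_654_321
_MOMENT_DRAWS = 1_000_000


def simulate_cohort(cfg: SimConfig, n_covariates: int = 0) -> Cohort:
    """Draw a cohort from the structural model, with latent ground truth.

    Parameters
    ----------
    cfg
        Generating parameters; identical configurations (including the seed)
        yield bit-identical cohorts.
    n_covariates
        Number of independent standard-normal measured covariates to append
        (named ``z1..zk``).  They play no role in the structural model and
        exist purely to exercise covariate-adjustment code paths.

    Notes
    -----
    Potential exposures ``s_if_g1``/``s_if_g0`` re-evaluate the exposure
    linear predictor with the moderator forced to 1/0, propagating the
    moderator's contribution to the confounder, while reusing every noise
    draw (including the uniform that thresholds the exposure probability).
    Potential outcomes ``y_s1``/``y_s0`` share the outcome noise draw and
    keep the moderator at its factual value.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    # Fixed draw order; changing it would silently change every seeded study.
    g = (rng.random(n) < cfg.p_g).astype(float)
    g2 = (rng.random(n) < cfg.p_g2).astype(float)
    u_noise = rng.standard_normal(n)
    eta_noise = rng.normal(0.0, cfg.sd_eta, n)
    s_uniform = rng.random(n)
    y_noise = rng.normal(0.0, cfg.sd_y, n)

    u = cfg.gamma_ug * g + u_noise

    def exposure(g_forced: np.ndarray) -> np.ndarray:
        u_forced = cfg.gamma_ug * g_forced + u_noise
        eta = (
            cfg.eta0
            + cfg.gamma_sg * g_forced
            + cfg.gamma_sg2 * g2
            + cfg.gamma_su * u_forced
            + eta_noise
        )
        return (s_uniform < expit(eta)).astype(float)

    s = exposure(g)
    s_if_g1 = exposure(np.ones(n))
    s_if_g0 = exposure(np.zeros(n))

    baseline = cfg.y0 + cfg.gamma_yg * g + cfg.gamma_yu * u + y_noise
    y_s1 = baseline + cfg.beta1 * g + cfg.beta0 * (1.0 - g)
    y_s0 = baseline
    y = np.where(s == 1.0, y_s1, y_s0)

    z = None
    if n_covariates > 0:
        z = pd.DataFrame(
            rng.standard_normal((n, n_covariates)),
            columns=[f"z{k + 1}" for k in range(n_covariates)],
        )

    return Cohort(
        y=y,
        s=s,
        g=g,
        g2=g2,
        z=z,
        u=u,
        s_if_g1=s_if_g1,
        s_if_g0=s_if_g0,
        y_s1=y_s1,
        y_s0=y_s0,
        meta={"config": cfg.to_dict()},
    )


def true_cace(cohort: Cohort) -> float:
    """Complier average causal effect from the latent potential outcomes.

    Compliers are individuals whose exposure tracks the moderator allele
    (``s_if_g1 = 1`` and ``s_if_g0 = 0``).  Monotonicity is checked on the
    generated records, not assumed: any defier raises.
    """
    if not cohort.has_latent:
        raise UndefinedEstimandError(
            "true_cace requires latent potential exposures (simulated cohorts only)"
        )
    defiers = cohort.s_if_g1 < cohort.s_if_g0
    if defiers.any():
        raise MonotonicityViolationError(
            f"{int(defiers.sum())} defier(s) present: potential exposure is lower "
            "with the risk allele than without"
        )
    compliers = (cohort.s_if_g1 == 1.0) & (cohort.s_if_g0 == 0.0)
    if not compliers.any():
        raise UndefinedEstimandError("no compliers in cohort; CACE is undefined")
    return float(np.mean(cohort.y_s1[compliers] - cohort.y_s0[compliers]))


@dataclass(frozen=True)
class WaldDecomposition:
    """Population Wald estimand split into its effect and bias components.

    ``ratio_term`` is the weighted contrast of group effects that equals the
    CACE under monotonicity; ``bias_term`` collects the contributions of the
    moderator's direct outcome effect and its confounder association;
    ``estimand`` is their sum, the probability limit of the Wald ratio.
    """

    ratio_term: float
    bias_term: float
    estimand: float
    e_s_g1: float
    e_s_g0: float
    backend: str


def _conditional_exposure_mc(cfg: SimConfig, g_val: float) -> float:
    """E[S | G = g] by Monte-Carlo integration over U and the eta noise."""
    rng = np.random.default_rng(_MOMENT_SEED)
    u = cfg.gamma_ug * g_val + rng.standard_normal(_MOMENT_DRAWS)
    eta_noise = rng.normal(0.0, cfg.sd_eta, _MOMENT_DRAWS)
    total = 0.0
    for g2_val, w in ((0.0, 1.0 - cfg.p_g2), (1.0, cfg.p_g2)):
        eta = (
            cfg.eta0
            + cfg.gamma_sg * g_val
            + cfg.gamma_sg2 * g2_val
            + cfg.gamma_su * u
            + eta_noise
        )
        # averaging expit(eta) integrates out the Bernoulli draw exactly
        total += w * float(np.mean(expit(eta)))
    return total


def _conditional_exposure_gh(cfg: SimConfig, g_val: float, order: int = 80) -> float:
    """E[S | G = g] by Gauss-Hermite quadrature.

    The Gaussian parts of the linear predictor (the confounder noise scaled
    by ``gamma_su`` plus the eta noise) collapse to a single normal with SD
    ``sqrt(gamma_su^2 + sd_eta^2)``, leaving a one-dimensional integral per
    instrument genotype.
    """
    nodes, weights = roots_hermitenorm(order)
    weights = weights / np.sqrt(2.0 * np.pi)
    sigma = float(np.hypot(cfg.gamma_su, cfg.sd_eta))
    mean_u = cfg.gamma_ug * g_val
    total = 0.0
    for g2_val, w in ((0.0, 1.0 - cfg.p_g2), (1.0, cfg.p_g2)):
        loc = (
            cfg.eta0
            + cfg.gamma_sg * g_val
            + cfg.gamma_sg2 * g2_val
            + cfg.gamma_su * mean_u
        )
        total += w * float(np.sum(weights * expit(loc + sigma * nodes)))
    return total


def wald_estimand(
    cfg: SimConfig,
    backend: str = "mc",
    denominator_tol: float = 1e-6,
) -> WaldDecomposition:
    """Decompose the population Wald ratio ``Cov(G,Y)/Cov(G,S)`` under ``cfg``.

    Parameters
    ----------
    cfg
        Generating configuration.  The moderator must be relevant for the
        exposure under ``cfg`` (``E[S|G=1] != E[S|G=0]``).
    backend
        ``"mc"`` (default): Monte-Carlo integration of the conditional
        exposure moments with a fixed internal seed, making the result a
        deterministic function of ``cfg``.  ``"gh"``: Gauss-Hermite
        quadrature.  The two agree to Monte-Carlo accuracy.
    denominator_tol
        Minimum absolute exposure contrast between moderator groups before a
        weak-instrument error is raised.
    """
    if backend == "mc":
        moments = _conditional_exposure_mc
    elif backend == "gh":
        moments = _conditional_exposure_gh
    else:
        raise ValueError(f"unknown backend {backend!r}; expected 'mc' or 'gh'")
    e_s_g1 = moments(cfg, 1.0)
    e_s_g0 = moments(cfg, 0.0)
    denom = e_s_g1 - e_s_g0
    if abs(denom) < denominator_tol:
        raise WeakInstrumentError(
            f"exposure contrast E[S|G=1]-E[S|G=0] = {denom:.2e} is below "
            f"tolerance {denominator_tol:.0e}; Wald ratio undefined"
        )
    ratio = (cfg.beta1 * e_s_g1 - cfg.beta0 * e_s_g0) / denom
    # E[U|G=1] - E[U|G=0] = gamma_ug exactly under the structural model.
    bias = (cfg.gamma_yg + cfg.gamma_yu * cfg.gamma_ug) / denom
    return WaldDecomposition(
        ratio_term=float(ratio),
        bias_term=float(bias),
        estimand=float(ratio + bias),
        e_s_g1=float(e_s_g1),
        e_s_g0=float(e_s_g0),
        backend=backend,
    )
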