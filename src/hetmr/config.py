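"""Simulation configuration for the synthetic-cohort data-generating process.

The generator produces individual-level data for a Mendelian randomization
setting with genetically driven effect heterogeneity: a binary moderator
variant ``G`` that may alter the causal effect of a binary exposure ``S`` on a
continuous outcome ``Y`` (birth weight in grams), and a second variant ``G2``
acting as a conventional, homogeneity-respecting instrument for ``S``.

The structural model is

.. math::

    G \\sim \\mathrm{Bern}(p_G), \\qquad G_2 \\sim \\mathrm{Bern}(p_{G_2}),

    U = \\gamma_{UG} G + N(0, 1),

    \\eta = \\eta_0 + \\gamma_{SG} G + \\gamma_{SG_2} G_2 + \\gamma_{SU} U
           + N(0, \\sigma_\\eta),

    S \\sim \\mathrm{Bern}(\\mathrm{expit}(\\eta)),

    Y = y_0 + \\beta_1 S G + \\beta_0 S (1 - G) + \\gamma_{YG} G
        + \\gamma_{YU} U + N(0, \\sigma_Y).

``beta1`` and ``beta0`` are the causal effects of the exposure in the
``G = 1`` and ``G = 0`` groups; their difference is the genetically moderated
exposure effect (GMEE).  The coefficients ``gamma_ug``, ``gamma_sg`` and
``gamma_yg`` toggle violations of the instrumental-variable assumptions for
``G``: independence (IV2), relevance for S (IV1, required *absent* for
Method 2) and exclusion (IV3, pleiotropy) respectively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "method1_scenario",
    "method2_scenario",
    "shared_scenario",
]


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the synthetic-cohort data-generating process.

    Default values follow the generating model used throughout the package's
    simulation studies: a birth-weight-like outcome centred at 3500 g with
    residual SD 470 g, group effects ``beta1 = -200`` and ``beta0 = -100`` g,
    moderator allele frequency 0.55 and instrument allele frequency 0.4.
    The confounder and instrument-strength coefficients (``gamma_su``,
    ``gamma_sg2``, ``gamma_yu``) are calibrated so that the exposure
    prevalence (~24%), the total outcome SD (~481 g) and the large-sample
    power properties of the estimators are realistic for a cohort study of
    smoking and birth weight; see ``docs/methods.md``.

    All assumption-violation coefficients default to zero.
    """

    n: int = 10_000
    seed: int = 0
    p_g: float = 0.55
    p_g2: float = 0.4
    gamma_ug: float = 0.0
    eta0: float = -2.0
    gamma_sg: float = 0.0
    gamma_sg2: float = 1.5
    gamma_su: float = 0.5
    sd_eta: float = 0.5
    y0: float = 3500.0
    beta1: float = -200.0
    beta0: float = -100.0
    gamma_yg: float = 0.0
    gamma_yu: float = 100.0
    sd_y: float = 470.0

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int,)) or isinstance(self.n, bool) or self.n < 1:
            raise ConfigurationError(f"n must be a positive integer, got {self.n!r}")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")
        for name in ("p_g", "p_g2"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ConfigurationError(
                    f"{name} must lie strictly between 0 and 1, got {p!r}"
                )
        for name in ("sd_eta", "sd_y"):
            sd = getattr(self, name)
            if sd < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {sd!r}")

    @property
    def diff(self) -> float:
        """The genetically moderated exposure effect ``beta1 - beta0`` (grams)."""
        return self.beta1 - self.beta0

    def replace(self, **changes: Any) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Read a flat key:value YAML/JSON configuration file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"configuration file {path} is not a mapping")
        raw.pop("study", None)  # scenario files nest study settings separately
        return cls.from_dict(raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def method1_scenario(n: int, seed: int, **overrides: Any) -> SimConfig:
    """Generating conditions under which Method 1 is consistent.

    The moderator variant G predicts the exposure (``gamma_sg = 0.5``) but has
    no pleiotropic outcome effect and no confounder association.
    """
    base = dict(n=n, seed=seed, gamma_sg=0.5, gamma_yg=0.0, gamma_ug=0.0)
    base.update(overrides)
    return SimConfig(**base)


def method2_scenario(n: int, seed: int, **overrides: Any) -> SimConfig:
    """Generating conditions under which Method 2 is consistent.

    G is independent of the exposure (``gamma_sg = 0``) and of the confounder,
    but exerts a direct pleiotropic effect of 150 g on the outcome, which
    Method 2 tolerates and Method 1 does not.
    """
    base = dict(n=n, seed=seed, gamma_sg=0.0, gamma_yg=150.0, gamma_ug=0.0)
    base.update(overrides)
    return SimConfig(**base)


def shared_scenario(n: int, seed: int, **overrides: Any) -> SimConfig:
    """Generating conditions under which both methods are consistent.

    All violations off: no G-S effect, no pleiotropy, no G-confounder path.
    Used for head-to-head power and precision comparisons.
    """
    base = dict(n=n, seed=seed, gamma_sg=0.0, gamma_yg=0.0, gamma_ug=0.0)
    base.update(overrides)
    return SimConfig(**base)
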