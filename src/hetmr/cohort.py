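"""The Cohort container: observed variables plus optional latent ground truth.

A cohort is an analysis-ready individual-level table with a continuous
outcome ``y`` (grams), binary exposure ``s``, binary moderator variant ``g``,
an instrument ``g2`` (binary when simulated; a real-valued genetic risk score
is accepted on CSV input) and optional measured covariates.  Simulated
cohorts additionally carry the latent confounder, the potential exposures
under each moderator allele, and the potential outcomes under each exposure
level, which serve as ground truth for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["Cohort", "LATENT_COLUMNS"]

#: Latent-truth columns, present all together or not at all.
LATENT_COLUMNS = ("u", "s_if_g1", "s_if_g0", "y_s1", "y_s0")

_FLOAT_FMT = "%.17g"  # full round-trip precision for CSV serialisation


@dataclass
class Cohort:
    """Individual-level cohort data.

    Parameters
    ----------
    y, s, g, g2
        Observed outcome, exposure, moderator variant and instrument.
        ``s`` and ``g`` must be coded 0/1; ``g2`` may be a real-valued score.
    z
        Optional measured covariates, one column per covariate.
    u, s_if_g1, s_if_g0, y_s1, y_s0
        Latent ground truth (simulation only): confounder, potential
        exposures with the moderator allele forced present/absent, and
        potential outcomes with the exposure forced on/off.
    """

    y: np.ndarray
    s: np.ndarray
    g: np.ndarray
    g2: np.ndarray
    z: pd.DataFrame | None = None
    u: np.ndarray | None = None
    s_if_g1: np.ndarray | None = None
    s_if_g0: np.ndarray | None = None
    y_s1: np.ndarray | None = None
    y_s0: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("y", "s", "g", "g2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.y)
        for name in ("s", "g", "g2"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(
                    f"column {name} has length {len(getattr(self, name))}, expected {n}"
                )
        for name in ("s", "g"):
            vals = np.unique(getattr(self, name))
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ConfigurationError(
                    f"column {name} must be binary 0/1, found values {vals[:5]}"
                )
        if self.z is not None:
            self.z = pd.DataFrame(self.z)
            if len(self.z) != n:
                raise ConfigurationError(
                    f"covariate table has {len(self.z)} rows, expected {n}"
                )
        latent = [getattr(self, name) for name in LATENT_COLUMNS]
        present = [x is not None for x in latent]
        if any(present) and not all(present):
            missing = [c for c, p in zip(LATENT_COLUMNS, present) if not p]
            raise ConfigurationError(
                f"latent fields must be all-present or all-absent; missing {missing}"
            )
        if all(present):
            for name in LATENT_COLUMNS:
                arr = np.asarray(getattr(self, name), dtype=float)
                if len(arr) != n:
                    raise ConfigurationError(
                        f"latent column {name} has length {len(arr)}, expected {n}"
                    )
                setattr(self, name, arr)

    # -- basic structure ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def has_latent(self) -> bool:
        return self.u is not None

    @property
    def s_star(self) -> np.ndarray:
        """The moderated exposure ``S* = G x S``."""
        return self.g * self.s

    def column(self, name: str) -> np.ndarray:
        """Resolve a column by name: observed, latent, or a covariate."""
        if name in ("y", "s", "g", "g2", "s_star"):
            return getattr(self, name)
        if name in LATENT_COLUMNS:
            arr = getattr(self, name)
            if arr is None:
                raise KeyError(f"latent column {name!r} not present in this cohort")
            return arr
        if self.z is not None and name in self.z.columns:
            return self.z[name].to_numpy(dtype=float)
        raise KeyError(f"no column named {name!r} in cohort")

    @property
    def covariate_names(self) -> list[str]:
        return [] if self.z is None else list(self.z.columns)

    # -- serialisation -----------------------------------------------------

    def to_frame(self, latent: bool = True) -> pd.DataFrame:
        """Tabular view with header ``y,s,g,g2[,z...][,latent...]``."""
        data = {"y": self.y, "s": self.s, "g": self.g, "g2": self.g2}
        frame = pd.DataFrame(data)
        if self.z is not None:
            frame = pd.concat([frame, self.z.reset_index(drop=True)], axis=1)
        if latent and self.has_latent:
            for name in LATENT_COLUMNS:
                frame[name] = getattr(self, name)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        for req in ("y", "s", "g", "g2"):
            if req not in frame.columns:
                raise ConfigurationError(f"cohort table is missing column {req!r}")
        if frame[["y", "s", "g", "g2"]].isna().any().any():
            raise ConfigurationError(
                "missing values are not allowed in required columns y,s,g,g2"
            )
        latent_present = all(c in frame.columns for c in LATENT_COLUMNS)
        zcols = [
            c
            for c in frame.columns
            if c not in ("y", "s", "g", "g2") and c not in LATENT_COLUMNS
        ]
        return cls(
            y=frame["y"].to_numpy(float),
            s=frame["s"].to_numpy(float),
            g=frame["g"].to_numpy(float),
            g2=frame["g2"].to_numpy(float),
            z=frame[zcols].copy() if zcols else None,
            **{
                name: (frame[name].to_numpy(float) if latent_present else None)
                for name in LATENT_COLUMNS
            },
        )

    def write_csv(self, path: str | Path, latent: bool = True) -> None:
        """Write the cohort as CSV with full float round-trip precision."""
        self.to_frame(latent=latent).to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def read_csv(cls, path: str | Path, dichotomize_g: bool = False) -> "Cohort":
        """Read a cohort CSV.

        With ``dichotomize_g`` an allele-count moderator column is collapsed
        to carrier status ({1, 2} -> 1), the coding used for effect-modifying
        variants throughout the package.
        """
        frame = pd.read_csv(path)
        if dichotomize_g and "g" in frame.columns:
            frame["g"] = (frame["g"] >= 1).astype(float)
        return cls.from_frame(frame)
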