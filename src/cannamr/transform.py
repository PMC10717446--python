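"""Rescaling of per-log-unit MR estimates to an ever- vs never-user OR.

The MR estimate is expressed per 1-log-odds-unit increase in genetically
indexed liability to ever-use of cannabis, which is not directly comparable
with the observational ever- vs never-user contrast.  This module applies a
monotone log-scale rescaling theta_pop = c · theta, where the contrast
factor c (log-odds units of exposure separating ever- from never-users) is
either supplied directly or derived from the exposure prevalence P as
c = 1/(P(1−P)) — the probability-scale calibration of a binary exposure
instrumented on the liability log-odds scale.  The outcome-risk parameters
(population risk K, never-user risk K0) validate internal consistency and
yield the implied risk among ever-users.

All parameters are configuration inputs; nothing is hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .estimators import MrEstimate
from .sumstats import InputError


@dataclass(frozen=True)
class TransformParams:
    """Population parameters for the ever- vs never-user rescaling.

    ``disease_risk_population`` (K) and ``disease_risk_never_users`` (K0)
    are outcome risks; ``exposure_prevalence`` (P) is the fraction of
    ever-users.  ``exposure_contrast`` optionally fixes the log-odds
    contrast c directly (overriding the prevalence-based derivation).
    """

    disease_risk_population: float
    disease_risk_never_users: float
    exposure_prevalence: float
    exposure_contrast: float | None = None

    def __post_init__(self) -> None:
        for name in ("disease_risk_population", "disease_risk_never_users", "exposure_prevalence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.exposure_contrast is not None and self.exposure_contrast <= 0:
            raise ValueError("exposure_contrast must be positive")
        # implied risk among ever-users must be a valid probability
        k1 = self.implied_user_risk
        if not 0 < k1 < 1:
            raise ValueError(
                f"inconsistent params: implied ever-user risk {k1:.4f} outside (0, 1)"
            )

    @property
    def implied_user_risk(self) -> float:
        """Risk among ever-users from K = P·K1 + (1−P)·K0."""
        p = self.exposure_prevalence
        return (self.disease_risk_population - (1 - p) * self.disease_risk_never_users) / p

    @property
    def contrast(self) -> float:
        """Log-odds-unit contrast between ever- and never-users."""
        if self.exposure_contrast is not None:
            return self.exposure_contrast
        p = self.exposure_prevalence
        return 1.0 / (p * (1.0 - p))


def per_log_unit_to_ever_never(estimate: MrEstimate, params: TransformParams) -> MrEstimate:
    """Map a per-1-log-unit causal estimate to the ever- vs never-user scale.

    The log-OR, its SE and both CI bounds are multiplied by the contrast
    factor, so the transform is null-preserving (OR 1 maps to OR 1),
    strictly order-preserving, and scales the log-scale CI width by the
    same factor as the point estimate; the z-statistic and p-value are
    unchanged.
    """
    c = params.contrast
    if not math.isfinite(c) or c <= 0:
        raise InputError(f"invalid exposure contrast {c}")
    return replace(
        estimate,
        method=estimate.method + "_population",
        theta=c * estimate.theta,
        se=c * estimate.se,
        ci_low=c * estimate.ci_low,
        ci_high=c * estimate.ci_high,
    )
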