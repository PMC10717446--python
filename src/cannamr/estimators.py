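"""Per-SNP Wald ratios and their inverse-variance-weighted pooling.

The causal effect of the exposure on the outcome is estimated per SNP as
the Wald ratio theta_j = Gamma_j / gamma_j (SNP-outcome effect over
SNP-exposure effect, both on the log-odds scale) with a delta-method
standard error, and the per-SNP estimates are pooled by fixed-effects
(inverse-variance-weighted, IVW) or DerSimonian-Laird random-effects
meta-analysis.  Heterogeneity between per-SNP estimates is summarized by
Cochran's Q and I².

The exponentiated pooled estimate is an odds ratio per 1-log-unit increase
in the genetically indexed exposure.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedInstrument, InputError

Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal estimate Gamma_hat/gamma_hat with delta-method SE."""

    rsid: str
    ratio: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: Wald SE must be > 0")
        if not math.isfinite(self.ratio):
            raise ValueError(f"{self.rsid}: non-finite Wald ratio")


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal estimate on the log-odds scale.

    ``theta`` is the pooled log-OR per 1-log-unit increase in the exposure;
    ``intercept`` fields are populated by Egger-type methods only, ``tau2``
    by random-effects methods only.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    i2: float | None = None
    tau2: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    covariate_theta: float | None = None
    covariate_se: float | None = None
    covariate_p: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low < self.ci_high:
            raise ValueError("ci_low must be < ci_high")
        if self.i2 is not None and not 0 <= self.i2 <= 100:
            raise ValueError("i2 must lie in [0, 100]")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["odds_ratio"] = self.odds_ratio
        d["or_ci_low"], d["or_ci_high"] = self.or_ci
        return d


def wald_ratio(instrument: HarmonizedInstrument, second_order: bool = False) -> WaldEstimate:
    """Per-SNP causal estimate and its delta-method standard error.

    The first-order (default) SE is ``se_Γ/|γ|``, treating the exposure
    effect as known; with ``second_order=True`` the exposure-side term is
    added: ``se² = se_Γ²/γ² + Γ²·se_γ²/γ⁴``.  The first-order form is the
    standard choice for IVW weighting (it makes ratio-based pooling agree
    exactly with the weighted regression through the origin and avoids the
    extra weak-instrument bias that γ-dependent weights introduce).
    """
    g = instrument.beta_exposure
    if g == 0:
        raise InputError(f"{instrument.rsid}: zero exposure effect, Wald ratio undefined")
    G = instrument.beta_outcome
    var = instrument.se_outcome**2 / g**2
    if second_order:
        var += G**2 * instrument.se_exposure**2 / g**4
    return WaldEstimate(rsid=instrument.rsid, ratio=G / g, se=math.sqrt(var))


def wald_ratios(
    instruments: Iterable[HarmonizedInstrument], second_order: bool = False
) -> list[WaldEstimate]:
    return [wald_ratio(ins, second_order=second_order) for ins in instruments]


class _Pooled(NamedTuple):
    theta: float
    se: float
    q: float
    i2: float
    tau2: float


def _ivw_arrays(theta: np.ndarray, se: np.ndarray) -> _Pooled:
    """Fixed-effect inverse-variance pooling with heterogeneity statistics."""
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - pooled) ** 2))
    k = theta.size
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return _Pooled(pooled, pooled_se, q, i2, 0.0)


def _dl_arrays(theta: np.ndarray, se: np.ndarray) -> _Pooled:
    """DerSimonian-Laird random-effects pooling."""
    w = 1.0 / se**2
    fixed = _ivw_arrays(theta, se)
    k = theta.size
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (fixed.q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_star)))
    return _Pooled(pooled, pooled_se, fixed.q, fixed.i2, tau2)


def _finish(method: str, pooled: _Pooled, k: int, random_effects: bool) -> MrEstimate:
    z = pooled.theta / pooled.se
    return MrEstimate(
        method=method,
        theta=pooled.theta,
        se=pooled.se,
        ci_low=pooled.theta - Z95 * pooled.se,
        ci_high=pooled.theta + Z95 * pooled.se,
        pvalue=float(2 * stats.norm.sf(abs(z))),
        n_snps=k,
        q_stat=pooled.q,
        i2=pooled.i2,
        tau2=pooled.tau2 if random_effects else None,
    )


def _check_estimates(estimates: Sequence[WaldEstimate], minimum: int = 2) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) < minimum:
        raise InputError(f"need at least {minimum} per-SNP estimates, got {len(estimates)}")
    theta = np.array([e.ratio for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    return theta, se


def ivw_fixed(estimates: Sequence[WaldEstimate]) -> MrEstimate:
    """Fixed-effects IVW meta-analysis of per-SNP Wald ratios.

    Weights are 1/se_j²; the pooled estimate is the weighted mean with
    SE 1/sqrt(sum of weights); Cochran's Q and I² quantify between-SNP
    heterogeneity.
    """
    theta, se = _check_estimates(estimates)
    return _finish("ivw_fixed", _ivw_arrays(theta, se), theta.size, random_effects=False)


def ivw_random(estimates: Sequence[WaldEstimate]) -> MrEstimate:
    """DerSimonian-Laird random-effects meta-analysis of Wald ratios.

    The moment estimator tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) inflates
    the weights to 1/(se_j² + tau²); when Q ≤ k−1 the result coincides with
    the fixed-effects pooling.
    """
    theta, se = _check_estimates(estimates)
    return _finish("ivw_random", _dl_arrays(theta, se), theta.size, random_effects=True)


def ivw_regression(instruments: Sequence[HarmonizedInstrument]) -> MrEstimate:
    """Regression form of IVW: WLS of Gamma_hat on gamma_hat through the
    origin with weights 1/se_Γ².

    Equivalent to ratio-based IVW with simplified (outcome-only) Wald SEs;
    used as the no-intercept reference for the Egger and multivariable fits.
    """
    if len(instruments) < 2:
        raise InputError("need at least 2 instruments")
    x = np.array([i.beta_exposure for i in instruments])
    y = np.array([i.beta_outcome for i in instruments])
    w = np.array([1.0 / i.se_outcome**2 for i in instruments])
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y)) / sxx
    se = 1.0 / math.sqrt(sxx)
    z = slope / se
    return MrEstimate(
        method="ivw_regression",
        theta=slope,
        se=se,
        ci_low=slope - Z95 * se,
        ci_high=slope + Z95 * se,
        pvalue=float(2 * stats.norm.sf(abs(z))),
        n_snps=len(instruments),
    )


def write_estimates(estimates: Iterable[MrEstimate], path: str | Path, fmt: str = "tsv") -> None:
    """Serialize estimates one row (or object) per method, TSV or JSON."""
    rows = [e.to_dict() for e in estimates]
    path = Path(path)
    if fmt == "tsv":
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
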