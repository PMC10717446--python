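"""Pleiotropy-robust estimators and instrument diagnostics.

The IVW estimate is only consistent when every instrument affects the
outcome exclusively through the exposure.  This module implements the
standard battery of checks and robust alternatives:

* **MR-Egger** — weighted regression of outcome on exposure effects with a
  free intercept; a non-zero intercept estimates the average directional
  pleiotropic effect, and the slope remains consistent under the InSIDE
  assumption (pleiotropy independent of instrument strength).
* **I²_GX** — the share of variation in the SNP-exposure effects not
  attributable to their estimation error; values well below 100% signal
  violation of the no-measurement-error (NOME) assumption and consequent
  attenuation of the Egger slope.
* **SIMEX** — simulation-extrapolation correction of that attenuation:
  extra measurement error is injected at inflation factors lambda, the
  decay of the Egger slope is modelled as a quadratic in lambda, and the
  fit is extrapolated back to lambda = −1 (no measurement error).
* **Weighted median** — consistent when up to 50% of the pooled weight
  comes from invalid instruments.
* **Steiger filtering** — per-SNP check that the instrument explains more
  variance in the exposure than in the outcome, i.e. that causation runs in
  the assumed direction.
* **Multivariable MR** — joint weighted regression on two exposures'
  genetic effects, here used to adjust the cannabis effect for tobacco.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .estimators import Z95, MrEstimate, WaldEstimate, _check_estimates
from .sumstats import ConfigurationError, HarmonizedInstrument, InputError


class EstimationError(RuntimeError):
    """A model fit failed (e.g. rank-deficient design)."""


# ---------------------------------------------------------------------------
# shared helpers


def _oriented(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exposure/outcome effect arrays re-oriented so every gamma_hat >= 0.

    Egger-type fits are not invariant to which allele carries the effect;
    the convention is to flip each SNP so its exposure effect is positive
    (the outcome effect flips with it, the ratio is unchanged).
    """
    g = np.array([i.beta_exposure for i in instruments], dtype=float)
    G = np.array([i.beta_outcome for i in instruments], dtype=float)
    sg = np.array([i.se_exposure for i in instruments], dtype=float)
    sG = np.array([i.se_outcome for i in instruments], dtype=float)
    sign = np.where(g < 0, -1.0, 1.0)
    return g * sign, G * sign, sg, sG


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form weighted least squares line fit; broadcasts over leading
    axes (sums run over the last axis)."""
    sw = np.sum(w, axis=-1)
    sx = np.sum(w * x, axis=-1)
    sy = np.sum(w * y, axis=-1)
    sxx = np.sum(w * x * x, axis=-1)
    sxy = np.sum(w * x * y, axis=-1)
    denom = sw * sxx - sx**2
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / sw
    return slope, intercept


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _estimate(method: str, theta: float, se: float, k: int, **extra) -> MrEstimate:
    return MrEstimate(
        method=method,
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pvalue=_normal_p(theta / se),
        n_snps=k,
        **extra,
    )


# ---------------------------------------------------------------------------
# MR-Egger


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MrEstimate:
    """MR-Egger regression: slope = causal estimate, intercept = average
    directional pleiotropy.

    Outcome effects are regressed on exposure effects with weights
    1/se_outcome² and an unconstrained intercept, after re-orienting all
    exposure effects to be non-negative.  Standard errors come from
    resampling SNPs with replacement (``n_boot`` draws, default 10,000);
    ``n_boot=0`` falls back to analytic WLS standard errors.  A low
    intercept p-value suggests directional pleiotropy.
    """
    k = len(instruments)
    if k < 3:
        raise InputError(f"MR-Egger needs at least 3 instruments, got {k}")
    x, y, _, sG = _oriented(instruments)
    w = 1.0 / sG**2
    slope, intercept = _wls_line(x, y, w)
    slope, intercept = float(slope), float(intercept)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, k, size=(n_boot, k))
        bs, bi = _wls_line(x[idx], y[idx], w[idx])
        slope_se = float(np.std(bs, ddof=1))
        int_se = float(np.std(bi, ddof=1))
    else:
        sw, sx = np.sum(w), np.sum(w * x)
        sxx = np.sum(w * x * x)
        denom = sw * sxx - sx**2
        resid = y - intercept - slope * x
        # multiplicative overdispersion, floored at 1 (standard Egger practice)
        scale = max(1.0, float(np.sum(w * resid**2) / (k - 2)))
        slope_se = math.sqrt(scale * sw / denom)
        int_se = math.sqrt(scale * sxx / denom)

    return _estimate(
        "egger", slope, slope_se, k,
        intercept=intercept,
        intercept_se=int_se,
        intercept_p=_normal_p(intercept / int_se),
    )


def i2_gx(instruments: Sequence[HarmonizedInstrument]) -> float:
    """I²_GX: share of variance of the (oriented) SNP-exposure effects not
    due to estimation error, in percent.

    Values near 100% mean the NOME assumption underlying MR-Egger is
    near-satisfied; low values flag regression-dilution bias of the Egger
    slope (motivating the SIMEX correction).
    """
    if len(instruments) < 2:
        raise InputError("I²_GX needs at least 2 instruments")
    x, _, sg, _ = _oriented(instruments)
    w = 1.0 / sg**2
    xbar = np.sum(w * x) / np.sum(w)
    q = float(np.sum(w * (x - xbar) ** 2))
    k = x.size
    if q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q) * 100.0


def _simex_extrapolate(
    x: np.ndarray,
    y: np.ndarray,
    sg: np.ndarray,
    w: np.ndarray,
    lambdas: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean Egger slope/intercept on a lambda grid, extrapolated to -1."""
    mean_slopes = np.empty(lambdas.size)
    mean_ints = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        if lam == 0:
            s, a = _wls_line(x, y, w)
            mean_slopes[i], mean_ints[i] = float(s), float(a)
        else:
            noise = rng.normal(0.0, 1.0, size=(n_sim, x.size)) * np.sqrt(lam) * sg
            s, a = _wls_line(x + noise, y, w)
            mean_slopes[i], mean_ints[i] = float(s.mean()), float(a.mean())
    deg = min(2, lambdas.size - 1)
    slope_fit = np.polynomial.polynomial.polyfit(lambdas, mean_slopes, deg)
    int_fit = np.polynomial.polynomial.polyfit(lambdas, mean_ints, deg)
    return (
        float(np.polynomial.polynomial.polyval(-1.0, slope_fit)),
        float(np.polynomial.polynomial.polyval(-1.0, int_fit)),
    )


def egger_simex(
    instruments: Sequence[HarmonizedInstrument],
    lambdas: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
    n_sim: int = 1000,
    seed: int | None = None,
    n_boot: int = 200,
) -> MrEstimate:
    """SIMEX-corrected MR-Egger slope.

    For each inflation factor lambda in the grid, Normal(0, lambda·se_γ²)
    noise is added to the exposure effects and the Egger fit repeated
    ``n_sim`` times; a quadratic in lambda through the mean slopes is
    extrapolated to lambda = −1, undoing the NOME attenuation.  The SE is a
    bootstrap (``n_boot`` SNP resamples) over the whole procedure.
    Deterministic given ``seed``.
    """
    k = len(instruments)
    if k < 3:
        raise InputError(f"SIMEX needs at least 3 instruments, got {k}")
    lambdas = np.asarray(sorted(lambdas), dtype=float)
    if 0.0 not in lambdas:
        raise ConfigurationError("SIMEX lambda grid must contain 0")
    x, y, sg, sG = _oriented(instruments)
    w = 1.0 / sG**2
    rng = np.random.default_rng(seed)
    slope, intercept = _simex_extrapolate(x, y, sg, w, lambdas, n_sim, rng)

    if n_boot > 0:
        bs = np.empty(n_boot)
        bi = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, k, size=k)
            bs[b], bi[b] = _simex_extrapolate(
                x[idx], y[idx], sg[idx], w[idx], lambdas, n_sim, rng
            )
        slope_se = float(np.std(bs, ddof=1))
        int_se = float(np.std(bi, ddof=1))
    else:  # fall back on the naive Egger SE
        plain = mr_egger(instruments, n_boot=0)
        slope_se, int_se = plain.se, plain.intercept_se

    return _estimate(
        "egger_simex", slope, slope_se, k,
        intercept=intercept,
        intercept_se=int_se,
        intercept_p=_normal_p(intercept / int_se),
    )


# ---------------------------------------------------------------------------
# weighted median


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted-median of per-SNP ratios by cumulative-midpoint percentile
    interpolation.

    Ratios are sorted; each carries normalized weight w'_j and sits at
    percentile p_j = cum(w')_j − w'_j/2; the estimate interpolates the
    ratios linearly at p = 0.5.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    wn = w / w.sum()
    p = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, p, r))


def _weighted_median_rows(draws: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of ``draws`` (B, k) with fixed weights."""
    order = np.argsort(draws, axis=1)
    r = np.take_along_axis(draws, order, axis=1)
    w = weights[order]
    wn = w / w.sum(axis=1, keepdims=True)
    p = np.cumsum(wn, axis=1) - wn / 2
    # index of first percentile >= 0.5 in each row
    hi = np.minimum((p < 0.5).sum(axis=1), p.shape[1] - 1)
    lo = np.maximum(hi - 1, 0)
    rows = np.arange(p.shape[0])
    p_lo, p_hi = p[rows, lo], p[rows, hi]
    r_lo, r_hi = r[rows, lo], r[rows, hi]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / (p_hi - p_lo), 0.0)
    out = r_lo + np.clip(frac, 0.0, 1.0) * (r_hi - r_lo)
    out = np.where(p[rows, 0] >= 0.5, r[rows, 0], out)
    out = np.where(p[rows, -1] <= 0.5, r[rows, -1], out)
    return out


def weighted_median(
    estimates: Sequence[WaldEstimate],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-median causal estimate, consistent when up to half of the
    pooled weight comes from invalid instruments.

    Weights are inverse-variance (1/se_j²); the SE is a parametric
    bootstrap drawing theta*_j ~ Normal(theta_j, se_j²) ``n_boot`` times
    (default 10,000).
    """
    if len(estimates) < 3:
        raise InputError(f"weighted median needs at least 3 estimates, got {len(estimates)}")
    theta, se = _check_estimates(estimates, minimum=3)
    w = 1.0 / se**2
    point = weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(max(n_boot, 2), theta.size))
    boots = _weighted_median_rows(draws, w)
    boot_se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", point, boot_se, theta.size)


# ---------------------------------------------------------------------------
# Steiger directionality


@dataclass(frozen=True)
class SteigerResult:
    """Per-SNP directionality check: does the SNP explain more variance in
    the exposure than in the outcome?"""

    rsid: str
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    z_p: float

    def __post_init__(self) -> None:
        for v in (self.r2_exposure, self.r2_outcome):
            if not 0 <= v <= 1:
                raise ValueError("r² must lie in [0, 1]")


class SteigerSummary(NamedTuple):
    results: list[SteigerResult]
    overall_correct: bool
    overall_p: float


def _z_to_r2(z: float, n: float) -> float:
    """Squared correlation implied by a Wald z at sample size n."""
    return z**2 / (z**2 + n - 2)


def _fisher_diff_p(r_a: float, n_a: float, r_b: float, n_b: float) -> float:
    """Two-sided p for a difference of independent correlations via Fisher
    z-transforms."""
    z = (math.atanh(min(r_a, 0.999999)) - math.atanh(min(r_b, 0.999999))) / math.sqrt(
        1.0 / (n_a - 3) + 1.0 / (n_b - 3)
    )
    return _normal_p(z)


def steiger_filter(
    instruments: Sequence[HarmonizedInstrument],
    n_exposure: float | None = None,
    n_outcome: float | None = None,
) -> SteigerSummary:
    """Steiger directionality test per SNP and pooled across SNPs.

    Per-SNP variance explained is recovered from the Wald z and sample size
    as r² = z²/(z² + n − 2) on the observed (log-odds) scale for both
    traits; the difference of Fisher-transformed correlations gives a
    two-sided p-value.  The overall test applies the same comparison to the
    aggregate correlation sqrt(sum of per-SNP r²) on each side (instruments
    are assumed independent).
    """
    if not instruments:
        raise InputError("no instruments supplied")
    results = []
    sum_e = sum_o = 0.0
    for ins in instruments:
        ne = n_exposure if n_exposure is not None else ins.n_exposure
        no = n_outcome if n_outcome is not None else ins.n_outcome
        if not (ne > 3 and no > 3):
            raise InputError(f"{ins.rsid}: sample sizes must exceed 3")
        r2e = _z_to_r2(ins.beta_exposure / ins.se_exposure, ne)
        r2o = _z_to_r2(ins.beta_outcome / ins.se_outcome, no)
        sum_e += r2e
        sum_o += r2o
        results.append(
            SteigerResult(
                rsid=ins.rsid,
                r2_exposure=r2e,
                r2_outcome=r2o,
                correct_direction=r2e > r2o,
                z_p=_fisher_diff_p(math.sqrt(r2e), ne, math.sqrt(r2o), no),
            )
        )
    ne = n_exposure if n_exposure is not None else instruments[0].n_exposure
    no = n_outcome if n_outcome is not None else instruments[0].n_outcome
    overall_p = _fisher_diff_p(
        math.sqrt(min(sum_e, 0.999999)), ne, math.sqrt(min(sum_o, 0.999999)), no
    )
    return SteigerSummary(results, overall_correct=sum_e > sum_o, overall_p=overall_p)


# ---------------------------------------------------------------------------
# multivariable MR


def mvmr(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MrEstimate:
    """Multivariable MR: the exposure effect adjusted for a second exposure.

    Weighted least squares of the outcome effects on the exposure and
    covariate effect columns (weights 1/se_outcome², no intercept); the
    exposure coefficient is the adjusted causal estimate, the covariate
    coefficient is reported alongside.  Instruments with missing covariate
    effects are dropped and counted.  SEs come from resampling SNPs with
    replacement (default 10,000 draws).
    """
    usable = [i for i in instruments if i.beta_covariate is not None]
    n_dropped = len(instruments) - len(usable)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "mvmr: dropped %d instrument(s) without covariate effects", n_dropped
        )
    k = len(usable)
    if k < 3:
        raise InputError(f"multivariable MR needs at least 3 usable instruments, got {k}")
    g = np.array([i.beta_exposure for i in usable])
    d = np.array([i.beta_covariate for i in usable])
    y = np.array([i.beta_outcome for i in usable])
    w = np.array([1.0 / i.se_outcome**2 for i in usable])

    if np.all(d == 0.0):
        # degenerate but well-defined: the covariate column drops out and
        # the fit reduces to regression-form IVW through the origin
        slope = float(np.sum(w * g * y) / np.sum(w * g * g))
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, k, size=(max(n_boot, 2), k))
        gb, yb, wb = g[idx], y[idx], w[idx]
        boots = np.sum(wb * gb * yb, axis=1) / np.sum(wb * gb * gb, axis=1)
        return _estimate("mvmr", slope, float(np.std(boots, ddof=1)), k)

    def solve(g, d, y, w):
        a11 = np.sum(w * g * g, axis=-1)
        a12 = np.sum(w * g * d, axis=-1)
        a22 = np.sum(w * d * d, axis=-1)
        b1 = np.sum(w * g * y, axis=-1)
        b2 = np.sum(w * d * y, axis=-1)
        det = a11 * a22 - a12**2
        return (a22 * b1 - a12 * b2) / det, (a11 * b2 - a12 * b1) / det, det, a11 * a22

    beta1, beta2, det, norm = solve(g, d, y, w)
    if not np.isfinite(det) or det <= 1e-12 * norm:
        raise EstimationError("collinear exposure and covariate effects (rank-deficient design)")
    beta1, beta2 = float(beta1), float(beta2)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, k, size=(max(n_boot, 2), k))
    with np.errstate(invalid="ignore", divide="ignore"):
        bb1, bb2, bdet, _ = solve(g[idx], d[idx], y[idx], w[idx])
    ok = np.isfinite(bb1) & np.isfinite(bb2) & (bdet > 0)
    se1 = float(np.std(bb1[ok], ddof=1))
    se2 = float(np.std(bb2[ok], ddof=1))
    return _estimate(
        "mvmr", beta1, se1, k,
        covariate_theta=beta2,
        covariate_se=se2,
        covariate_p=_normal_p(beta2 / se2),
    )


def write_steiger(results: Iterable[SteigerResult], path) -> None:
    """Per-SNP Steiger results as TSV."""
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
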