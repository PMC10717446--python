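"""Random-effects meta-analysis of observational study estimates.

Study-level odds/hazard/risk ratios for cannabis ever-use versus never-use
are pooled on a common log scale with the DerSimonian-Laird random-effects
model, small-study (funnel-plot) asymmetry is tested by weighted regression
of effects on their standard errors, and pooled observational and causal
estimates are compared with a two-group heterogeneity Q test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import Z95, MrEstimate, _dl_arrays, _finish, _ivw_arrays
from .sumstats import InputError

OUTCOME_GROUPS = ("CAD", "IS", "ASCVD")


@dataclass(frozen=True)
class StudyEstimate:
    """One observational study's log-scale effect and standard error.

    ``effect`` is ln(OR/HR/RR); all ratio measures are pooled on the common
    log scale without conversion.  ``design`` distinguishes prospective from
    retrospective studies for sensitivity restrictions.
    """

    label: str
    outcome_group: str
    effect: float
    se: float
    design: str = "prospective"

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.label}: se must be > 0")


def study_from_ci(
    label: str,
    outcome_group: str,
    ratio: float,
    ci_low: float,
    ci_high: float,
    design: str = "prospective",
    rel_tol: float = 0.15,
) -> StudyEstimate:
    """Build a study record from a reported ratio and 95% CI.

    The SE is recovered as (ln(upper) − ln(lower)) / (2·1.96), assuming the
    interval is symmetric on the log scale; intervals whose log-asymmetry
    exceeds ``rel_tol`` (relative to the half-width) are rejected — they
    cannot come from a symmetric Wald interval and would corrupt pooling.
    """
    if not 0 < ci_low < ci_high:
        raise InputError(f"{label}: need 0 < ci_low < ci_high")
    lo, mid, hi = math.log(ci_low), math.log(ratio), math.log(ci_high)
    half = (hi - lo) / 2
    if half <= 0 or abs((hi - mid) - (mid - lo)) > rel_tol * 2 * half:
        raise InputError(
            f"{label}: CI ({ci_low}, {ci_high}) is asymmetric around {ratio} on the log scale"
        )
    return StudyEstimate(label, outcome_group, mid, half / Z95, design)


def read_study_table(path: str | Path) -> list[StudyEstimate]:
    """Read a TSV with columns label, outcome_group, estimate, ci_low,
    ci_high, design (ratio-scale estimate and CI)."""
    df = pd.read_csv(path, sep="\t")
    return [
        study_from_ci(
            str(r.label), str(r.outcome_group), float(r.estimate),
            float(r.ci_low), float(r.ci_high), str(getattr(r, "design", "prospective")),
        )
        for r in df.itertuples(index=False)
    ]


def dl_meta(studies: Sequence[StudyEstimate], random_effects: bool = True) -> MrEstimate:
    """DerSimonian-Laird random-effects pooling of study estimates.

    Returns the pooled log-effect with 95% CI, p-value, Cochran's Q, I² and
    tau²; with ``random_effects=False`` (tau² forced to zero) the result is
    the fixed-effect pooling.
    """
    if len(studies) < 2:
        raise InputError(f"meta-analysis needs at least 2 studies, got {len(studies)}")
    theta = np.array([s.effect for s in studies])
    se = np.array([s.se for s in studies])
    if random_effects:
        return _finish("dl_random", _dl_arrays(theta, se), theta.size, random_effects=True)
    return _finish("fixed", _ivw_arrays(theta, se), theta.size, random_effects=False)


class FunnelTest(NamedTuple):
    """Egger-type funnel-asymmetry test result (coefficient of SE)."""

    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_studies: int


def egger_funnel_test(
    studies: Sequence[StudyEstimate], precision_form: bool = False
) -> FunnelTest:
    """Small-study-effect test: weighted regression of effects on their
    standard errors.

    The log-effects are regressed on their SEs with inverse-variance
    weights and an intercept; a non-zero SE-coefficient indicates funnel
    asymmetry (possible publication bias).  ``precision_form=True`` uses
    the algebraically equivalent regression of standardized effects on
    precision, whose *intercept* is then the asymmetry coefficient.
    """
    if len(studies) < 3:
        raise InputError(f"funnel test needs at least 3 studies, got {len(studies)}")
    eff = np.array([s.effect for s in studies])
    se = np.array([s.se for s in studies])
    if precision_form:
        # standardized effect on precision: the intercept is the asymmetry term
        fit = sm.OLS(eff / se, sm.add_constant(1.0 / se)).fit()
        coef, coef_se = fit.params[0], fit.bse[0]
    else:
        fit = sm.WLS(eff, sm.add_constant(se), weights=1.0 / se**2).fit()
        coef, coef_se = fit.params[1], fit.bse[1]
    df = len(studies) - 2
    t = coef / coef_se
    tcrit = stats.t.ppf(0.975, df)
    return FunnelTest(
        coefficient=float(coef),
        se=float(coef_se),
        ci_low=float(coef - tcrit * coef_se),
        ci_high=float(coef + tcrit * coef_se),
        pvalue=float(2 * stats.t.sf(abs(t), df)),
        n_studies=len(studies),
    )


class BetweenGroupQ(NamedTuple):
    q_stat: float
    df: int
    pvalue: float


def between_group_q(estimate_a: MrEstimate, estimate_b: MrEstimate) -> BetweenGroupQ:
    """Heterogeneity test between two pooled estimates on the log scale.

    Q = sum of w_i (theta_i − theta_bar)² with inverse-variance weights;
    under homogeneity Q ~ chi²(1).
    """
    theta = np.array([estimate_a.theta, estimate_b.theta])
    se = np.array([estimate_a.se, estimate_b.se])
    w = 1.0 / se**2
    mean = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - mean) ** 2))
    return BetweenGroupQ(q_stat=q, df=1, pvalue=float(stats.chi2.sf(q, 1)))


def leave_one_out(studies: Sequence[StudyEstimate]) -> list[tuple[str, MrEstimate]]:
    """Re-pool with each study removed in turn (influence check)."""
    if len(studies) < 3:
        raise InputError("leave-one-out needs at least 3 studies")
    return [
        (studies[i].label, dl_meta([s for j, s in enumerate(studies) if j != i]))
        for i in range(len(studies))
    ]


def forest_data(studies: Sequence[StudyEstimate], pooled: MrEstimate) -> pd.DataFrame:
    """Tidy per-study + pooled table for external forest plotting."""
    rows = [
        {
            "label": s.label,
            "outcome_group": s.outcome_group,
            "ratio": math.exp(s.effect),
            "ci_low": math.exp(s.effect - Z95 * s.se),
            "ci_high": math.exp(s.effect + Z95 * s.se),
            "design": s.design,
            "kind": "study",
        }
        for s in studies
    ]
    rows.append(
        {
            "label": "pooled",
            "outcome_group": "",
            "ratio": pooled.odds_ratio,
            "ci_low": pooled.or_ci[0],
            "ci_high": pooled.or_ci[1],
            "design": "",
            "kind": "pooled",
        }
    )
    return pd.DataFrame(rows)
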