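"""Instrument-strength metrics and statistical power for binary outcomes.

Weak instruments bias two-sample MR toward the null; per-SNP and cumulative
F-statistics summarize the strength of the genetic instruments (F > 20 is
the conventional comfort zone), and a non-centrality approximation gives
the power of the design to detect a target odds ratio.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .sumstats import InputError, SnpAssociation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the binary-outcome MR power approximation.

    ``r2`` is the fraction of exposure variance jointly explained by the
    instruments; ``or_expected`` the odds ratio to detect (typically taken
    from the observational literature); the case fraction
    K = n_cases/(n_cases + n_controls) enters through its variance K(1−K).
    """

    n_cases: float
    n_controls: float
    r2: float
    or_expected: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not 0 < self.r2 < 1:
            raise ValueError(f"r2 must be in (0, 1), got {self.r2}")
        if self.or_expected <= 0:
            raise ValueError("or_expected must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def snp_r2(assoc: SnpAssociation, trait_variance: float = 1.0) -> float | None:
    """Fraction of trait variance explained by one SNP:
    r²_j = 2·beta_j²·p_j(1−p_j) / sigma².

    ``trait_variance`` defaults to 1 (standardized scale); pass K(1−K) for
    the observed-scale variance of a binary trait with case fraction K.
    Returns ``None`` with a warning when the allele frequency is missing.
    """
    if assoc.eaf is None:
        logger.warning("%s: missing eaf, r² skipped", assoc.rsid)
        return None
    return 2.0 * assoc.beta**2 * assoc.eaf * (1.0 - assoc.eaf) / trait_variance


def snp_f(r2: float, n: float) -> float:
    """Per-SNP F-statistic: F_j = r²_j (n − 2) / (1 − r²_j)."""
    return r2 * (n - 2) / (1.0 - r2)


def cumulative_f(r2_total: float, n: float, k: int) -> float:
    """Cumulative F-statistic of k instruments jointly explaining
    ``r2_total`` of the exposure variance in a sample of n:
    F = r²·(n − k − 1) / (k·(1 − r²)).
    """
    if not 0 < r2_total < 1:
        raise InputError(f"r2_total must be in (0, 1), got {r2_total}")
    if n <= k + 1:
        raise InputError(f"sample size {n} must exceed k + 1 = {k + 1}")
    return r2_total * (n - k - 1) / (k * (1.0 - r2_total))


def mr_power_binary(params: PowerParams, n_total_override: float | None = None) -> float:
    """Power of a two-sample MR design with a binary outcome.

    Non-centrality approximation: with case fraction K and total outcome
    sample N, power = Phi(|ln OR|·sqrt(N·r²·K(1−K)) − z_{1−alpha/2}).
    At OR = 1 the power equals alpha (returned with a warning).
    """
    K = params.n_cases / (params.n_cases + params.n_controls)
    N = n_total_override if n_total_override is not None else params.n_cases + params.n_controls
    z_crit = stats.norm.ppf(1.0 - params.alpha / 2)
    if params.or_expected == 1.0:
        warnings.warn("or_expected = 1: power equals alpha", stacklevel=2)
        return params.alpha
    ncp = abs(math.log(params.or_expected)) * math.sqrt(N * params.r2 * K * (1.0 - K))
    return float(stats.norm.cdf(ncp - z_crit))


def strength_table(
    assocs: list[SnpAssociation], trait_variance: float = 1.0
) -> pd.DataFrame:
    """Per-SNP r² and F diagnostics plus a cumulative summary row."""
    rows = []
    total_r2 = 0.0
    for a in assocs:
        r2 = snp_r2(a, trait_variance)
        if r2 is None:
            continue
        total_r2 += r2
        rows.append({"rsid": a.rsid, "r2": r2, "f_stat": snp_f(r2, a.n)})
    df = pd.DataFrame(rows)
    if rows and 0 < total_r2 < 1:
        n = assocs[0].n
        df.attrs["cumulative_r2"] = total_r2
        df.attrs["cumulative_f"] = cumulative_f(total_r2, n, len(rows))
    return df
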