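"""Reading, validation and allele harmonization of GWAS summary statistics.

Two-sample MR consumes per-SNP association records from an exposure GWAS
(e.g. ever use of cannabis) and an outcome GWAS (e.g. coronary artery
disease).  Before any causal estimate can be formed the two tables must be
joined on rsID and expressed with respect to the same effect allele; this
module owns that plumbing, together with the instrument-selection filters
(discordant-SNP exclusion, p-value thresholding, palindrome removal).

LD independence is an input-level assumption: tables are expected to be
pre-clumped and no reference panel is consulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names for summary-statistic tables
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}

GENOME_WIDE_P = 5e-8
LENIENT_P = 5e-5


class ConfigurationError(ValueError):
    """A user-supplied configuration value is invalid."""


class InputError(ValueError):
    """An input table or record set cannot support the requested operation."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait in one GWAS.

    ``beta`` is the additive per-allele effect of ``effect_allele`` on the
    trait, on the log-odds scale for binary traits.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not 0 < self.pvalue <= 1:
            raise ValueError(f"{self.rsid}: p-value must be in (0, 1], got {self.pvalue}")
        if not self.n > 0:
            raise ValueError(f"{self.rsid}: sample size must be > 0, got {self.n}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True when the allele pair is A/T or C/G (strand-ambiguous)."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's aligned exposure/outcome (and optional covariate) effects.

    All betas refer to the same effect allele after harmonization.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    pvalue_exposure: float
    beta_outcome: float
    se_outcome: float
    n_exposure: float
    n_outcome: float
    eaf: float | None = None
    beta_covariate: float | None = None
    se_covariate: float | None = None
    is_palindromic: bool = False
    gw_significant: bool = False


class ReadResult(NamedTuple):
    records: list[SnpAssociation]
    n_dropped: int


class HarmonizeResult(NamedTuple):
    instruments: list[HarmonizedInstrument]
    excluded: list[tuple[str, str]]  # (rsid, reason)


class PalindromeFilterResult(NamedTuple):
    kept: list[HarmonizedInstrument]
    removed: list[HarmonizedInstrument]


_REQUIRED = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue", "n")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ReadResult:
    """Read a TSV/CSV summary-statistic table into validated records.

    Rows violating the :class:`SnpAssociation` invariants (non-positive SE,
    out-of-range frequency, malformed alleles, ...) are dropped and counted;
    the drop count is logged and returned alongside the records.

    Parameters
    ----------
    path
        Tab- or comma-separated file with a header row.
    column_map
        Maps the canonical field names (keys of ``DEFAULT_COLUMN_MAP``) to
        the column names used in the file.  ``eaf`` may be absent.
    sep
        Field separator; inferred from the header line when ``None``.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: empty file")
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise InputError(f"{path}: no data rows")
    for field in _REQUIRED:
        if colmap[field] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {colmap[field]!r} (for {field}) not found"
            )
    has_eaf = colmap["eaf"] in df.columns

    records: list[SnpAssociation] = []
    dropped = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            eaf = row_d[colmap["eaf"]] if has_eaf else None
            if eaf is not None and pd.isna(eaf):
                eaf = None
            records.append(
                SnpAssociation(
                    rsid=str(row_d[colmap["rsid"]]),
                    effect_allele=str(row_d[colmap["effect_allele"]]),
                    other_allele=str(row_d[colmap["other_allele"]]),
                    beta=float(row_d[colmap["beta"]]),
                    se=float(row_d[colmap["se"]]),
                    pvalue=float(row_d[colmap["pvalue"]]),
                    n=float(row_d[colmap["n"]]),
                    eaf=None if eaf is None else float(eaf),
                )
            )
        except (ValueError, TypeError) as exc:
            dropped += 1
            logger.debug("dropping row: %s", exc)
    if dropped:
        logger.info("%s: dropped %d invalid row(s)", path, dropped)
    return ReadResult(records, dropped)


def write_summary_stats(records: Iterable[SnpAssociation], path: str | Path) -> None:
    """Write records in the same TSV dialect ``read_summary_stats`` reads."""
    rows = [
        {
            "rsid": r.rsid,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pvalue": r.pvalue,
            "n": r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _match_orientation(
    exp: SnpAssociation, out: SnpAssociation
) -> str | None:
    """How the outcome record's alleles relate to the exposure's.

    Returns ``"same"`` (betas already aligned), ``"flip"`` (outcome beta
    refers to the exposure's other allele) or ``None`` (irreconcilable even
    after strand complement).
    """
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    if o == e:
        return "same"
    if o == e[::-1]:
        return "flip"
    oc = (COMPLEMENT[o[0]], COMPLEMENT[o[1]])
    if oc == e:
        return "same"
    if oc == e[::-1]:
        return "flip"
    return None


def harmonize_pair(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    covariate: Sequence[SnpAssociation] | None = None,
) -> HarmonizeResult:
    """Align outcome (and optional covariate) effects to the exposure's
    effect allele.

    The rsID intersection of exposure and outcome is taken; when the outcome
    reports its beta with respect to the exposure's *other* allele (directly
    or after strand complement) the outcome beta sign is flipped and its
    frequency complemented.  SNPs absent from the outcome, or with
    irreconcilable alleles, are excluded with a reason — never silently kept.
    SNPs absent from the covariate set keep ``beta_covariate = None``.
    """
    out_by_rsid = {r.rsid: r for r in outcome}
    cov_by_rsid = {r.rsid: r for r in covariate} if covariate is not None else {}

    instruments: list[HarmonizedInstrument] = []
    excluded: list[tuple[str, str]] = []
    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            excluded.append((exp.rsid, "missing from outcome"))
            continue
        orient = _match_orientation(exp, out)
        if orient is None:
            excluded.append((exp.rsid, "allele mismatch"))
            continue
        sign = 1.0 if orient == "same" else -1.0
        beta_cov = se_cov = None
        cov = cov_by_rsid.get(exp.rsid)
        if cov is not None:
            cov_orient = _match_orientation(exp, cov)
            if cov_orient is not None:
                cov_sign = 1.0 if cov_orient == "same" else -1.0
                beta_cov = cov_sign * cov.beta
                se_cov = cov.se
        eaf = exp.eaf
        if eaf is None and out.eaf is not None:
            eaf = out.eaf if sign > 0 else 1.0 - out.eaf
        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                pvalue_exposure=exp.pvalue,
                beta_outcome=sign * out.beta,
                se_outcome=out.se,
                n_exposure=exp.n,
                n_outcome=out.n,
                eaf=eaf,
                beta_covariate=beta_cov,
                se_covariate=se_cov,
                is_palindromic=exp.is_palindromic,
                gw_significant=exp.pvalue < GENOME_WIDE_P,
            )
        )
    for rsid, reason in excluded:
        logger.info("harmonize: excluded %s (%s)", rsid, reason)
    return HarmonizeResult(instruments, excluded)


def filter_palindromic(
    instruments: Sequence[HarmonizedInstrument], maf_window: float = 0.08
) -> PalindromeFilterResult:
    """Remove strand-ambiguous palindromic SNPs with near-50% frequency.

    A/T and C/G SNPs cannot be strand-checked; when their effect-allele
    frequency lies within ``maf_window`` of 0.5 (default 0.08) the allele
    orientation is genuinely ambiguous and the SNP is removed.  Palindromic
    SNPs with missing frequency are treated as ambiguous and removed.
    Non-palindromic SNPs are always retained.
    """
    kept: list[HarmonizedInstrument] = []
    removed: list[HarmonizedInstrument] = []
    for ins in instruments:
        if ins.is_palindromic and (
            ins.eaf is None or abs(ins.eaf - 0.5) < maf_window
        ):
            removed.append(ins)
        else:
            kept.append(ins)
    if not kept:
        logger.warning("filter_palindromic: no instruments remain")
    return PalindromeFilterResult(kept, removed)


def select_instruments(
    instruments: Sequence[HarmonizedInstrument],
    pvalue_threshold: float = LENIENT_P,
    discordant_rsids: Iterable[str] = (),
) -> list[HarmonizedInstrument]:
    """Apply the instrument-selection rules to harmonized records.

    Removes SNPs on the exclusion list (e.g. discordant direction of effect
    between the source cohorts), then keeps SNPs whose exposure p-value is
    below ``pvalue_threshold``; the subset below 5e-8 is flagged
    ``gw_significant``.
    """
    if not 0 < pvalue_threshold <= 1:
        raise ConfigurationError(
            f"pvalue_threshold must be in (0, 1], got {pvalue_threshold}"
        )
    discordant = set(discordant_rsids)
    selected = [
        replace(ins, gw_significant=ins.pvalue_exposure < GENOME_WIDE_P)
        for ins in instruments
        if ins.rsid not in discordant and ins.pvalue_exposure < pvalue_threshold
    ]
    logger.info(
        "select_instruments: %d -> %d (threshold %.3g, %d excluded by list)",
        len(instruments), len(selected), pvalue_threshold,
        sum(1 for i in instruments if i.rsid in discordant),
    )
    return selected


_INSTRUMENT_COLUMNS = [
    "rsid", "effect_allele", "other_allele", "beta_exposure", "se_exposure",
    "pvalue_exposure", "beta_outcome", "se_outcome", "beta_covariate",
    "se_covariate", "eaf", "n_exposure", "n_outcome", "is_palindromic",
    "gw_significant",
]


def write_instruments(
    instruments: Iterable[HarmonizedInstrument], path: str | Path
) -> None:
    """Serialize harmonized instruments as TSV with fixed column order."""
    rows = [{c: getattr(ins, c) for c in _INSTRUMENT_COLUMNS} for ins in instruments]
    pd.DataFrame(rows, columns=_INSTRUMENT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_instruments(path: str | Path) -> list[HarmonizedInstrument]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: list[HarmonizedInstrument] = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        for opt in ("beta_covariate", "se_covariate", "eaf"):
            if pd.isna(d.get(opt)):
                d[opt] = None
        out.append(HarmonizedInstrument(**{c: d[c] for c in _INSTRUMENT_COLUMNS}))
    return out
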