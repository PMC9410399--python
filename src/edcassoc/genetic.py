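"""Hardy-Weinberg testing, genetic-model exposure coding, combined FLG genotype.

Genetic models follow the usual case-control conventions:

dominant
    risk-allele carriers (het + hom) vs wild-type homozygotes;
recessive
    risk-allele homozygotes vs everyone else;
genotype3
    0/1/2 count of risk alleles (the multiplicative-model coding);
allele
    each subject contributes two allele-level observations.

The combined FLG genotype is "null" for carriers of at least one of the four
screened loss-of-function filaggrin mutations (R501X, 2282del4, R2447X,
S3247X) and "normal" otherwise.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass

from scipy import stats

from ._util import UndefinedStatisticError, ValidationError
from .cohort import Cohort, Site, Subject
from .filters import resolve_population

__all__ = [
    "GenotypeCounts",
    "HweResult",
    "hwe_test",
    "genotype_counts",
    "code_genotype",
    "code_exposure",
    "combined_flg",
    "SiteExposure",
    "FlgNullExposure",
    "Conjunction",
    "resolve_exposure",
]

GENETIC_MODELS = ("dominant", "recessive", "genotype3", "allele")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one biallelic site (alt = risk allele)."""

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def alt_allele_count(self) -> int:
        return self.n_het + 2 * self.n_alt_hom

    @property
    def alt_allele_freq(self) -> float:
        if self.total == 0:
            raise UndefinedStatisticError("allele frequency of zero genotypes")
        return self.alt_allele_count / (2 * self.total)


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p: float
    expected: tuple[float, float, float]
    allele_freq: float
    degenerate: bool = False
    continuity_corrected: bool = False


def hwe_test(counts: GenotypeCounts, continuity_correction: bool = False) -> HweResult:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    The risk-allele frequency q is estimated from the sample; expected counts
    are ``n * ((1-q)^2, 2q(1-q), q^2)`` and the statistic has 1 degree of
    freedom (three classes, one estimated parameter). No continuity
    correction by default; Yates-style correction behind the flag.

    A monomorphic sample (q = 0 or 1) is degenerate: chi2 = 0, p = 1.
    """
    n = counts.total
    if n == 0:
        raise UndefinedStatisticError("HWE test on zero genotypes")
    q = counts.alt_allele_freq
    expected = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
    if q in (0.0, 1.0):
        return HweResult(0.0, 1, 1.0, expected, q, degenerate=True,
                         continuity_corrected=continuity_correction)
    observed = (counts.n_ref_hom, counts.n_het, counts.n_alt_hom)
    if continuity_correction:
        chi2 = sum(
            (max(abs(o - e) - 0.5, 0.0)) ** 2 / e for o, e in zip(observed, expected)
        )
    else:
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(float(chi2), 1, p, expected, q,
                     continuity_corrected=continuity_correction)


def genotype_counts(
    cohort: Cohort, site_id: str, population: "str | Callable[[Subject], bool]" = "controls"
) -> GenotypeCounts:
    """Tally genotype classes at a site, complete-case within a population.

    Defaults to controls, the group on which HWE is conventionally checked.
    """
    if site_id not in cohort.sites:
        raise ValidationError(f"undeclared site {site_id!r}")
    _, keep = resolve_population(population)
    risk = cohort.sites[site_id].risk_allele
    tally = [0, 0, 0]
    for s in cohort:
        if not keep(s):
            continue
        call = s.genotype(site_id)
        if call.missing:
            continue
        tally[call.risk_count(risk)] += 1
    return GenotypeCounts(*tally)


def code_genotype(risk_count: int, model: str) -> int:
    if model == "dominant":
        return int(risk_count >= 1)
    if model == "recessive":
        return int(risk_count == 2)
    if model == "genotype3":
        return risk_count
    raise ValidationError(f"unknown genetic model {model!r} (allele handled separately)")


def code_exposure(
    subject: Subject, site_id: str, model: str, risk_allele: str
) -> "int | tuple[int, int] | None":
    """Code one subject's genotype under a genetic model.

    Returns ``None`` when the call is missing (the subject must be excluded
    from the analysis, never silently treated as unexposed). Under the
    ``allele`` model the subject contributes two allele-level observations,
    returned as a pair of 0/1 indicators.
    """
    call = subject.genotype(site_id)
    if call.missing:
        return None
    if model == "allele":
        return (
            int(call.allele1 == risk_allele),
            int(call.allele2 == risk_allele),
        )
    return code_genotype(call.risk_count(risk_allele), model)


def combined_flg(subject: Subject) -> "str | None":
    """``"null"`` iff carrier of >= 1 of the four FLG mutations; None if unknown."""
    if subject.flg_null is None:
        return None
    return "null" if subject.flg_null else "normal"


# ---------------------------------------------------------------------------
# Exposure specs — the coded-exposure objects the table builders consume.


@dataclass(frozen=True)
class SiteExposure:
    """Genotype at a declared SNP site coded under a genetic model."""

    site_id: str
    model: str = "dominant"

    def __post_init__(self) -> None:
        if self.model not in ("dominant", "recessive", "genotype3"):
            raise ValidationError(
                f"SiteExposure model must be dominant/recessive/genotype3, "
                f"got {self.model!r} (use allele_model for allele-level analyses)"
            )

    @property
    def label(self) -> str:
        return f"{self.site_id}[{self.model}]"

    @property
    def binary(self) -> bool:
        return self.model in ("dominant", "recessive")

    def code(self, subject: Subject, sites: Mapping[str, Site]) -> "int | None":
        if self.site_id not in sites:
            raise ValidationError(f"undeclared site {self.site_id!r}")
        return code_exposure(
            subject, self.site_id, self.model, sites[self.site_id].risk_allele
        )


@dataclass(frozen=True)
class FlgNullExposure:
    """Carrier of any of the four FLG loss-of-function mutations."""

    label: str = "flg_null"
    binary: bool = True

    def code(self, subject: Subject, sites: Mapping[str, Site]) -> "int | None":
        status = combined_flg(subject)
        return None if status is None else int(status == "null")


@dataclass(frozen=True)
class Conjunction:
    """Positive iff positive under every (binary) component exposure."""

    parts: tuple

    def __post_init__(self) -> None:
        if len(self.parts) < 2:
            raise ValidationError("Conjunction needs at least two exposures")
        for p in self.parts:
            if not p.binary:
                raise ValidationError(f"Conjunction parts must be binary: {p.label}")

    @property
    def label(self) -> str:
        return " & ".join(p.label for p in self.parts)

    @property
    def binary(self) -> bool:
        return True

    def code(self, subject: Subject, sites: Mapping[str, Site]) -> "int | None":
        coded = [p.code(subject, sites) for p in self.parts]
        if any(c is None for c in coded):
            return None
        return int(all(coded))


def resolve_exposure(spec) -> "SiteExposure | FlgNullExposure | Conjunction":
    """Accept an exposure object, ``"flg_null"``, a site id (dominant), or a
    ``(site_id, model)`` pair."""
    if hasattr(spec, "code"):
        return spec
    if spec == "flg_null":
        return FlgNullExposure()
    if isinstance(spec, str):
        return SiteExposure(spec)
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        return SiteExposure(*spec)
    raise ValidationError(f"cannot interpret exposure spec {spec!r}")
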