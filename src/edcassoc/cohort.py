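"""Subject/cohort data model, delimited-table I/O, and cohort summaries.

The unit of data is one child from a case-control candidate-gene study of
atopic eczema: biallelic genotype calls at declared SNP sites, carrier status
for filaggrin (FLG) loss-of-function mutations, binary phenotypes (eczema,
eczema-associated asthma, allergic sensitization), SCORAD severity class,
and the covariates used for adjustment (age in months, sex, family history
of atopy).

Study-design invariants are enforced on load:

* polysensitized implies sensitized;
* a SCORAD class other than ``none`` implies eczema;
* asthma implies eczema (in this design every asthma case arose in a child
  with eczema, so "asthma" always means the composite asthma-plus-eczema
  phenotype);
* controls (no eczema, no asthma) have a negative family history of atopy,
  because that was a recruitment criterion for the control group.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Iterator, Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._util import SchemaError, ValidationError, round_half_up

__all__ = [
    "GenotypeCall",
    "Site",
    "Subject",
    "Cohort",
    "GroupSummary",
    "CohortSummary",
    "DEFAULT_SCHEMA",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "geometric_mean_ci",
]

SCORAD_CLASSES = ("none", "mild", "moderate", "severe")
SEXES = ("male", "female")

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}
_MISSING = {"", "na", "nan", "nn", ".", "none", "missing", "null"}


@dataclass(frozen=True)
class Site:
    """A biallelic SNP site: reference allele and declared risk allele.

    The risk allele is always configuration-declared (C for rs877776,
    T for rs12568784), never inferred from sample frequencies.
    """

    ref_allele: str
    risk_allele: str

    def __post_init__(self) -> None:
        for a in (self.ref_allele, self.risk_allele):
            if len(a) != 1 or not a.isalpha():
                raise ValidationError(f"allele must be a single letter, got {a!r}")
        if self.ref_allele == self.risk_allele:
            raise ValidationError("reference and risk allele must differ")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.ref_allele, self.risk_allele))


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered biallelic genotype call; ``GC`` and ``CG`` are identical."""

    site_id: str
    allele1: str | None = None
    allele2: str | None = None

    def __post_init__(self) -> None:
        a, b = self.allele1, self.allele2
        if (a is None) != (b is None):
            raise ValidationError(f"{self.site_id}: half-missing genotype call")
        if a is not None and b is not None and a > b:
            object.__setattr__(self, "allele1", b)
            object.__setattr__(self, "allele2", a)

    @property
    def missing(self) -> bool:
        return self.allele1 is None

    @classmethod
    def parse(cls, site_id: str, text: str) -> "GenotypeCall":
        """Parse ``"GC"``, ``"G/C"``, ``"g|c"`` or a missing marker."""
        raw = str(text).strip()
        if raw.lower() in _MISSING:
            return cls(site_id)
        compact = raw.replace("/", "").replace("|", "").replace(" ", "").upper()
        if len(compact) != 2 or not compact.isalpha():
            raise ValidationError(f"{site_id}: unparseable genotype {text!r}")
        return cls(site_id, compact[0], compact[1])

    def risk_count(self, risk_allele: str) -> int:
        """Number of copies of the risk allele (0, 1 or 2)."""
        if self.missing:
            raise ValidationError(f"{self.site_id}: risk count of a missing call")
        return int(self.allele1 == risk_allele) + int(self.allele2 == risk_allele)

    def __str__(self) -> str:
        return "" if self.missing else f"{self.allele1}{self.allele2}"


@dataclass(frozen=True)
class Subject:
    """One child: identifiers, phenotypes, covariates and genotype calls."""

    subject_id: str
    age_months: float
    sex: str
    family_atopy: bool
    eczema: bool
    scorad_class: str = "none"
    asthma: bool = False
    sensitized: bool = False
    polysensitized: bool = False
    total_ige_iu_ml: float | None = None
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)
    flg_null: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_months", float(self.age_months))
        if self.total_ige_iu_ml is not None:
            object.__setattr__(self, "total_ige_iu_ml", float(self.total_ige_iu_ml))
        errs = self.invariant_violations()
        if errs:
            raise ValidationError(f"subject {self.subject_id}: " + "; ".join(errs))

    def invariant_violations(self) -> list[str]:
        errs: list[str] = []
        if self.age_months < 0:
            errs.append(f"age_months must be non-negative, got {self.age_months}")
        if self.sex not in SEXES:
            errs.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.scorad_class not in SCORAD_CLASSES:
            errs.append(f"scorad_class must be one of {SCORAD_CLASSES}")
        if self.polysensitized and not self.sensitized:
            errs.append("polysensitized implies sensitized")
        if self.scorad_class != "none" and not self.eczema:
            errs.append("scorad_class != none implies eczema")
        if self.asthma and not self.eczema:
            errs.append("asthma implies eczema (all asthma arose in eczema cases)")
        if not self.eczema and not self.asthma and self.family_atopy:
            errs.append(
                "controls have family_atopy = false (control recruitment criterion)"
            )
        if self.total_ige_iu_ml is not None and self.total_ige_iu_ml <= 0:
            errs.append("total IgE must be positive when present")
        for sid, call in self.genotypes.items():
            if call.site_id != sid:
                errs.append(f"genotype keyed {sid} carries site_id {call.site_id}")
        return errs

    @property
    def is_control(self) -> bool:
        return not self.eczema and not self.asthma

    def genotype(self, site_id: str) -> GenotypeCall:
        return self.genotypes.get(site_id, GenotypeCall(site_id))


@dataclass(frozen=True)
class Cohort:
    """An ordered, validated collection of subjects plus site metadata."""

    subjects: tuple[Subject, ...]
    sites: Mapping[str, Site]
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "sites", dict(self.sites))
        seen: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise ValidationError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)
            for sid, call in s.genotypes.items():
                if sid not in self.sites:
                    raise ValidationError(
                        f"subject {s.subject_id}: genotype at undeclared site {sid!r}"
                    )
                if not call.missing:
                    declared = self.sites[sid].alleles
                    observed = {call.allele1, call.allele2}
                    if not observed <= declared:
                        raise ValidationError(
                            f"subject {s.subject_id}: alleles {''.join(sorted(observed))} "
                            f"not in declared pair for {sid}"
                        )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def subset(self, keep: Callable[[Subject], bool], note: str = "") -> "Cohort":
        prov = self.provenance + (f" | {note}" if note else "")
        return replace(
            self, subjects=tuple(s for s in self.subjects if keep(s)), provenance=prov
        )

    @property
    def cases(self) -> tuple[Subject, ...]:
        return tuple(s for s in self.subjects if s.eczema)

    @property
    def controls(self) -> tuple[Subject, ...]:
        return tuple(s for s in self.subjects if s.is_control)


# ---------------------------------------------------------------------------
# delimited I/O

#: logical field -> default column name; genotype columns default to the site id
DEFAULT_SCHEMA: dict[str, str] = {
    "subject_id": "subject_id",
    "age_months": "age_months",
    "sex": "sex",
    "family_atopy": "family_atopy",
    "eczema": "eczema",
    "scorad_class": "scorad_class",
    "asthma": "asthma",
    "sensitized": "sensitized",
    "polysensitized": "polysensitized",
    "total_ige_iu_ml": "total_ige_iu_ml",
    "flg_null": "flg_null",
}

_REQUIRED = ("subject_id", "age_months", "sex", "family_atopy", "eczema")
#: individual FLG loss-of-function mutation columns accepted in place of flg_null
FLG_MUTATION_COLUMNS = ("r501x", "del2282", "r2447x", "s3247x")


def _parse_bool(text: str, where: str) -> bool | None:
    t = str(text).strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    if t in _MISSING:
        return None
    raise ValidationError(f"{where}: unparseable boolean {text!r}")


def _parse_sex(text: str, where: str) -> str:
    t = str(text).strip().lower()
    if t in ("male", "m"):
        return "male"
    if t in ("female", "f"):
        return "female"
    raise ValidationError(f"{where}: unparseable sex {text!r}")


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_cohort(
    path: str,
    sites: Mapping[str, Site],
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    on_invalid: str = "raise",
    provenance: str | None = None,
) -> Cohort:
    """Read a delimited subject table into a validated :class:`Cohort`.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row (delimiter inferred from extension
        unless given).
    sites:
        Declared SNP sites with their reference and risk alleles; a genotype
        column is expected for every site id (remappable through ``schema``).
    schema:
        Optional mapping from logical field names (:data:`DEFAULT_SCHEMA`
        keys and site ids) to actual column names.
    on_invalid:
        ``"raise"`` (default) aborts with row-indexed diagnostics for every
        invalid row; ``"skip"`` drops invalid rows instead.

    FLG carrier status is read from a ``flg_null`` boolean column, or, if
    absent, as the OR of the four mutation columns
    ``r501x/del2282/r2447x/s3247x``.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValidationError("on_invalid must be 'raise' or 'skip'")
    colmap = dict(DEFAULT_SCHEMA)
    for sid in sites:
        colmap[sid] = sid
    if schema:
        colmap.update(schema)

    frame = pd.read_csv(
        path, sep=_delimiter_for(path, delimiter), dtype=str, keep_default_na=False
    )
    missing_cols = [colmap[f] for f in _REQUIRED if colmap[f] not in frame.columns]
    missing_cols += [colmap[sid] for sid in sites if colmap[sid] not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    have_flg = colmap["flg_null"] in frame.columns
    mut_cols = [c for c in FLG_MUTATION_COLUMNS if c in frame.columns]

    def cell(row: pd.Series, logical: str, default: str = "") -> str:
        col = colmap.get(logical, logical)
        return str(row[col]) if col in frame.columns else default

    subjects: list[Subject] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        where = f"row {idx + 2}"  # 1-based with header line
        try:
            genos = {
                sid: GenotypeCall.parse(sid, cell(row, sid)) for sid in sites
            }
            if have_flg:
                flg = _parse_bool(cell(row, "flg_null"), where)
            elif mut_cols:
                carried = [_parse_bool(row[c], where) for c in mut_cols]
                flg = None if any(v is None for v in carried) else any(carried)
            else:
                flg = None
            ige_txt = cell(row, "total_ige_iu_ml").strip()
            scorad = cell(row, "scorad_class", "none").strip().lower() or "none"
            subjects.append(
                Subject(
                    subject_id=cell(row, "subject_id").strip(),
                    age_months=float(cell(row, "age_months")),
                    sex=_parse_sex(cell(row, "sex"), where),
                    family_atopy=bool(_parse_bool(cell(row, "family_atopy"), where)),
                    eczema=bool(_parse_bool(cell(row, "eczema"), where)),
                    scorad_class=scorad,
                    asthma=bool(_parse_bool(cell(row, "asthma", "false"), where)),
                    sensitized=bool(_parse_bool(cell(row, "sensitized", "false"), where)),
                    polysensitized=bool(
                        _parse_bool(cell(row, "polysensitized", "false"), where)
                    ),
                    total_ige_iu_ml=float(ige_txt)
                    if ige_txt.lower() not in _MISSING
                    else None,
                    genotypes=genos,
                    flg_null=flg,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"{where}: {exc}")
    if errors and on_invalid == "raise":
        raise ValidationError(
            f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors)
        )
    return Cohort(
        subjects=tuple(subjects),
        sites=sites,
        provenance=provenance if provenance is not None else f"read from {path}",
    )


def write_cohort(cohort: Cohort, path: str, delimiter: str | None = None) -> None:
    """Write a cohort back to a delimited table; round-trips with ``read_cohort``."""

    def fmt_num(x: float) -> str:
        return repr(int(x)) if float(x).is_integer() else repr(float(x))

    rows = []
    for s in cohort:
        row = {
            "subject_id": s.subject_id,
            "age_months": fmt_num(s.age_months),
            "sex": s.sex,
            "family_atopy": str(s.family_atopy).lower(),
            "eczema": str(s.eczema).lower(),
            "scorad_class": s.scorad_class,
            "asthma": str(s.asthma).lower(),
            "sensitized": str(s.sensitized).lower(),
            "polysensitized": str(s.polysensitized).lower(),
            "total_ige_iu_ml": ""
            if s.total_ige_iu_ml is None
            else fmt_num(s.total_ige_iu_ml),
            "flg_null": "" if s.flg_null is None else str(s.flg_null).lower(),
        }
        for sid in cohort.sites:
            row[sid] = str(s.genotype(sid))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# summaries


def geometric_mean_ci(
    values: Iterable[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Geometric mean with a t-based CI computed on the log scale.

    Returns ``(gm, lower, upper)``; for n == 1 the CI is NaN, and a constant
    series yields the degenerate interval ``(gm, gm)``.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValidationError("geometric mean of an empty series")
    bad = np.nonzero(x <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"geometric mean requires positive values; offending index {bad[0]}"
            f" (value {x[bad[0]]})"
        )
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    if x.size < 2:
        return gm, math.nan, math.nan
    se = logs.std(ddof=1) / math.sqrt(x.size)
    t = float(stats.t.ppf(0.5 + level / 2.0, df=x.size - 1))
    return gm, float(np.exp(logs.mean() - t * se)), float(np.exp(logs.mean() + t * se))


def _count_pct(count: int, denom: int) -> tuple[int, float | None]:
    return count, (round_half_up(100.0 * count / denom, 1) if denom else None)


@dataclass
class GroupSummary:
    """Counts and display percentages for one outcome group (cases or controls)."""

    label: str
    n: int
    sex_counts: dict[str, tuple[int, float | None]]
    age_mean: float | None
    age_sd: float | None
    phenotypes: dict[str, tuple[int, float | None]]
    scorad: dict[str, tuple[int, float | None]]
    genotype_counts: dict[str, dict[str, tuple[int, float | None]]]
    genotype_denominators: dict[str, int]
    flg: dict[str, tuple[int, float | None]]
    flg_denominator: int
    ige_geometric_mean: tuple[float, float, float] | None
    flags: list[str]


@dataclass
class CohortSummary:
    """Per-group cohort characteristics in the shape of a study Table 1."""

    groups: dict[str, GroupSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups.values():
            for sid, classes in g.genotype_counts.items():
                for label, (n, pct) in classes.items():
                    rows.append(
                        {"group": g.label, "variable": f"{sid} {label}", "count": n,
                         "percent": pct}
                    )
            for name, (n, pct) in {**g.phenotypes, **g.flg}.items():
                rows.append(
                    {"group": g.label, "variable": name, "count": n, "percent": pct}
                )
        return pd.DataFrame(rows)


def _summarize_group(label: str, members: list[Subject], sites: Mapping[str, Site],
                     level: float) -> GroupSummary:
    n = len(members)
    flags: list[str] = []
    if n == 0:
        flags.append(f"empty group: {label}; percentages undefined")
    ages = np.array([s.age_months for s in members], dtype=float)
    sex_counts = {
        sx: _count_pct(sum(1 for s in members if s.sex == sx), n) for sx in SEXES
    }
    phen = {
        name: _count_pct(sum(1 for s in members if getattr(s, name)), n)
        for name in ("eczema", "asthma", "sensitized", "polysensitized", "family_atopy")
    }
    scorad = {
        cls: _count_pct(sum(1 for s in members if s.scorad_class == cls), n)
        for cls in SCORAD_CLASSES[1:]
    }
    geno: dict[str, dict[str, tuple[int, float | None]]] = {}
    geno_denoms: dict[str, int] = {}
    for sid, site in sites.items():
        calls = [s.genotype(sid) for s in members]
        typed = [c for c in calls if not c.missing]
        geno_denoms[sid] = len(typed)
        if len(typed) < len(calls):
            flags.append(f"{label}: {len(calls) - len(typed)} missing calls at {sid}")
        ref, risk = site.ref_allele, site.risk_allele
        classes = {
            f"{ref}{ref}": 0,
            f"{ref}{risk}": 1,
            f"{risk}{risk}": 2,
        }
        geno[sid] = {
            lab: _count_pct(
                sum(1 for c in typed if c.risk_count(risk) == k), len(typed)
            )
            for lab, k in classes.items()
        }
    known_flg = [s for s in members if s.flg_null is not None]
    flg = {
        "flg_normal": _count_pct(
            sum(1 for s in known_flg if not s.flg_null), len(known_flg)
        ),
        "flg_null": _count_pct(sum(1 for s in known_flg if s.flg_null), len(known_flg)),
    }
    ige_vals = [s.total_ige_iu_ml for s in members if s.total_ige_iu_ml is not None]
    ige = geometric_mean_ci(ige_vals, level) if len(ige_vals) >= 2 else None
    return GroupSummary(
        label=label,
        n=n,
        sex_counts=sex_counts,
        age_mean=float(ages.mean()) if n else None,
        age_sd=float(ages.std(ddof=1)) if n > 1 else None,
        phenotypes=phen,
        scorad=scorad,
        genotype_counts=geno,
        genotype_denominators=geno_denoms,
        flg=flg,
        flg_denominator=len(known_flg),
        ige_geometric_mean=ige,
        flags=flags,
    )


def summarize_cohort(cohort: Cohort, level: float = 0.95) -> CohortSummary:
    """Table-1-style summary: counts and percentages per outcome group.

    Percentages are display values rounded half-up to one decimal; every
    percentage is recomputable from the stored count and denominator.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    groups = {
        "cases": _summarize_group("cases", list(cohort.cases), cohort.sites, level),
        "controls": _summarize_group(
            "controls", list(cohort.controls), cohort.sites, level
        ),
    }
    return CohortSummary(groups=groups)
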