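"""Synthetic case-control cohorts with the structure the analysis assumes.

The generator draws a population of children — genotypes at each declared
SNP under Hardy-Weinberg proportions, FLG-null carrier status as an
independent Bernoulli — and pushes them through logistic disease models:
eczema for everyone, asthma only among eczema cases (the study observed no
asthma outside eczema), allergic sensitization for everyone (with eczema
itself allowed as a term). Case-control accrual is by rejection sampling:
children are drawn until the case quota (eczema) and the control quota
(no eczema, no asthma, family-history negative — the recruitment criteria)
are both met.

Defaults emulate the study population: risk-allele frequencies from the
control genotype counts (0.135 for rs877776[C], 0.106 for rs12568784[T]),
ages truncated-normal on 0-24 months, 103 cases vs 85 controls, eczema
severity mild/moderate only.

A second, "risk-table" mode (:func:`simulate_joint_counts`) specifies the
outcome probability per joint-exposure stratum directly and samples a plain
cohort-style table; a logistic model cannot hit arbitrary additive-scale
interaction (RERI) targets exactly, whereas the risk table can.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from ._util import SimulationError, ValidationError
from .cohort import Cohort, GenotypeCall, Site, Subject
from .interaction import JointExposureTable

__all__ = [
    "LogisticModel",
    "AgeModel",
    "CovariateModel",
    "IgeModel",
    "SimulationConfig",
    "RiskTableConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_joint_counts",
    "DEFAULT_SITES",
]

DEFAULT_SITES: dict[str, Site] = {
    "rs877776": Site("G", "C"),
    "rs12568784": Site("G", "T"),
}

_CODINGS = ("dominant", "recessive", "genotype3", "binary")


@dataclass(frozen=True)
class LogisticModel:
    """Log-odds model: intercept + per-term coded effects + pairwise products.

    ``effects`` maps a term (a site id, ``"flg_null"`` or ``"eczema"``) to a
    ``(coding, log_odds)`` pair; codings are dominant / recessive /
    genotype3 for sites and ``binary`` for the boolean terms.
    ``interactions`` maps term pairs to a product log-odds.
    """

    intercept: float
    effects: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    interactions: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", dict(self.effects))
        object.__setattr__(self, "interactions", dict(self.interactions))
        for term, (coding, _) in self.effects.items():
            if coding not in _CODINGS:
                raise ValidationError(f"unknown coding {coding!r} for term {term!r}")
        for pair in self.interactions:
            for term in pair:
                if term not in self.effects:
                    raise ValidationError(
                        f"interaction references unmodelled term {term!r}"
                    )


@dataclass(frozen=True)
class AgeModel:
    """Truncated-normal recruitment ages (months), per group."""

    case_mean: float = 13.6
    case_sd: float = 6.7
    control_mean: float = 15.9
    control_sd: float = 5.6
    low: float = 0.0
    high: float = 24.0


@dataclass(frozen=True)
class CovariateModel:
    age: AgeModel = field(default_factory=AgeModel)
    male_prob: float = 107 / 188
    family_atopy_prob: float = 57 / 103  # among eczema cases; controls are negative


@dataclass(frozen=True)
class IgeModel:
    """Log-normal total IgE (IU/mL) by group; geometric means and log-sd."""

    case_gm: float = 38.5
    control_gm: float = 17.7
    log_sd: float = 1.05


def _default_eczema_model() -> LogisticModel:
    return LogisticModel(
        intercept=-1.8,
        effects={
            "rs877776": ("dominant", math.log(2.2)),
            "rs12568784": ("dominant", math.log(2.2)),
            "flg_null": ("binary", math.log(6.0)),
        },
    )


def _default_asthma_model() -> LogisticModel:
    # baseline 18% among double-wild-type eczema cases
    return LogisticModel(
        intercept=-1.5,
        effects={
            "rs877776": ("dominant", math.log(2.9)),
            "rs12568784": ("dominant", math.log(5.0)),
        },
    )


def _default_sensitization_model() -> LogisticModel:
    return LogisticModel(
        intercept=-2.1,
        effects={
            "rs877776": ("dominant", math.log(2.1)),
            "rs12568784": ("dominant", math.log(3.8)),
            "eczema": ("binary", math.log(6.5)),
        },
    )


def _filter_model(model: LogisticModel, known: set[str]) -> LogisticModel:
    """Restrict a default model to the terms a config actually declares."""
    effects = {t: v for t, v in model.effects.items() if t in known}
    interactions = {
        pair: v for pair, v in model.interactions.items()
        if all(t in effects for t in pair)
    }
    return LogisticModel(model.intercept, effects, interactions)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_cases: int = 103
    n_controls: int = 85
    sites: Mapping[str, Site] = field(default_factory=lambda: dict(DEFAULT_SITES))
    allele_freq: Mapping[str, float] = field(
        default_factory=lambda: {"rs877776": 0.135, "rs12568784": 0.106}
    )
    flg_null_freq: float = 0.03
    eczema_model: "LogisticModel | None" = None
    asthma_model: "LogisticModel | None" = None
    sensitization_model: "LogisticModel | None" = None
    covariates: CovariateModel = field(default_factory=CovariateModel)
    moderate_prob: float = 24 / 103  # moderate (vs mild) SCORAD among cases
    poly_given_sensitized: float = 19 / 66
    ige: IgeModel = field(default_factory=IgeModel)
    max_draws: int = 10_000_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", dict(self.sites))
        object.__setattr__(self, "allele_freq", dict(self.allele_freq))
        # model defaults emulate the study, restricted to the declared sites
        known = set(self.sites) | {"flg_null", "eczema"}
        for attr, factory in (
            ("eczema_model", _default_eczema_model),
            ("asthma_model", _default_asthma_model),
            ("sensitization_model", _default_sensitization_model),
        ):
            if getattr(self, attr) is None:
                object.__setattr__(self, attr, _filter_model(factory(), known))
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("n_cases and n_controls must be positive")
        for sid, q in self.allele_freq.items():
            if sid not in self.sites:
                raise ValidationError(f"allele_freq for undeclared site {sid!r}")
            if not 0.0 <= q <= 1.0:
                raise ValidationError(f"allele frequency for {sid} outside [0, 1]")
        if set(self.sites) != set(self.allele_freq):
            raise ValidationError("every declared site needs an allele frequency")
        if not 0.0 <= self.flg_null_freq <= 1.0:
            raise ValidationError("flg_null_freq outside [0, 1]")
        for model in (self.eczema_model, self.asthma_model, self.sensitization_model):
            for term in model.effects:
                if term not in self.sites and term not in ("flg_null", "eczema"):
                    raise ValidationError(
                        f"model term {term!r} is neither a declared site nor "
                        "flg_null/eczema"
                    )


def simulate_genotypes(freq: float, n: int, seed) -> np.ndarray:
    """Risk-allele counts (0/1/2) for n subjects under Hardy-Weinberg.

    Genotype probabilities are ``((1-q)^2, 2q(1-q), q^2)`` — a Binomial(2, q)
    draw, which satisfies HWE by construction. ``seed`` may be an integer or
    a ``numpy.random.Generator``.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValidationError(f"allele frequency outside [0, 1]: {freq}")
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, freq, size=n)


def _code_array(counts: np.ndarray, coding: str) -> np.ndarray:
    if coding == "dominant":
        return (counts >= 1).astype(float)
    if coding == "recessive":
        return (counts == 2).astype(float)
    if coding == "genotype3":
        return counts.astype(float)
    return counts.astype(float)  # binary terms arrive already 0/1


def _eta(model: LogisticModel, columns: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    eta = np.full(n, model.intercept, dtype=float)
    coded: dict[str, np.ndarray] = {}
    for term, (coding, beta) in model.effects.items():
        coded[term] = _code_array(columns[term], coding)
        eta += beta * coded[term]
    for (ta, tb), beta in model.interactions.items():
        eta += beta * coded[ta] * coded[tb]
    return eta


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, low: float,
               high: float, n: int) -> np.ndarray:
    """Truncation by resampling; fine for the mild truncation used here."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < low) | (out > high)
    guard = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
        guard += 1
        if guard > 1000:
            raise SimulationError("age truncation never satisfied; check bounds")
    return out


_BATCH = 8192


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a case-control cohort under the configured disease models.

    Deterministic given the config (including seed). Raises
    :class:`~edcassoc._util.SimulationError` if the accrual quotas are not
    met within ``config.max_draws`` population draws.
    """
    rng = np.random.default_rng(config.seed)
    site_ids = list(config.sites)
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731

    case_rows: list[dict] = []
    control_rows: list[dict] = []
    drawn = 0
    while (
        len(case_rows) < config.n_cases or len(control_rows) < config.n_controls
    ):
        if drawn >= config.max_draws:
            raise SimulationError(
                f"accrual quotas unmet after {drawn} draws "
                f"(cases {len(case_rows)}/{config.n_cases}, "
                f"controls {len(control_rows)}/{config.n_controls}); "
                "check that the disease model makes both groups reachable"
            )
        m = min(_BATCH, config.max_draws - drawn)
        drawn += m
        cols: dict[str, np.ndarray] = {
            sid: simulate_genotypes(config.allele_freq[sid], m, rng)
            for sid in site_ids
        }
        cols["flg_null"] = (rng.random(m) < config.flg_null_freq).astype(float)
        eczema = rng.random(m) < expit(_eta(config.eczema_model, cols, m))
        asthma = np.zeros(m, dtype=bool)
        if eczema.any():
            p_asthma = expit(_eta(config.asthma_model, cols, m))
            asthma[eczema] = rng.random(int(eczema.sum())) < p_asthma[eczema]
        cols["eczema"] = eczema.astype(float)
        sensitized = rng.random(m) < expit(_eta(config.sensitization_model, cols, m))
        family = rng.random(m) < config.covariates.family_atopy_prob
        male = rng.random(m) < config.covariates.male_prob
        for i in range(m):
            row = {
                "genotypes": {sid: int(cols[sid][i]) for sid in site_ids},
                "flg_null": bool(cols["flg_null"][i]),
                "eczema": bool(eczema[i]),
                "asthma": bool(asthma[i]),
                "sensitized": bool(sensitized[i]),
                "male": bool(male[i]),
                "family_atopy": bool(family[i]),
            }
            if row["eczema"]:
                if len(case_rows) < config.n_cases:
                    case_rows.append(row)
            elif not row["family_atopy"]:
                if len(control_rows) < config.n_controls:
                    control_rows.append(row)

    ages_case = _truncnorm(
        rng, config.covariates.age.case_mean, config.covariates.age.case_sd,
        config.covariates.age.low, config.covariates.age.high, len(case_rows),
    )
    ages_ctrl = _truncnorm(
        rng, config.covariates.age.control_mean, config.covariates.age.control_sd,
        config.covariates.age.low, config.covariates.age.high, len(control_rows),
    )
    moderate = rng.random(len(case_rows)) < config.moderate_prob
    poly_case = rng.random(len(case_rows)) < config.poly_given_sensitized
    poly_ctrl = rng.random(len(control_rows)) < config.poly_given_sensitized
    ige_case = np.exp(
        rng.normal(math.log(config.ige.case_gm), config.ige.log_sd, len(case_rows))
    )
    ige_ctrl = np.exp(
        rng.normal(math.log(config.ige.control_gm), config.ige.log_sd,
                   len(control_rows))
    )

    def build(row: dict, idx: int, case: bool, age: float, scorad: str,
              poly: bool, ige: float) -> Subject:
        genos = {}
        for sid in site_ids:
            site = config.sites[sid]
            k = row["genotypes"][sid]
            alleles = (
                (site.ref_allele, site.ref_allele),
                (site.ref_allele, site.risk_allele),
                (site.risk_allele, site.risk_allele),
            )[k]
            genos[sid] = GenotypeCall(sid, *alleles)
        return Subject(
            subject_id=f"{'case' if case else 'ctrl'}-{idx:05d}",
            age_months=round(float(age), 1),
            sex="male" if row["male"] else "female",
            family_atopy=row["family_atopy"] if case else False,
            eczema=row["eczema"],
            scorad_class=scorad,
            asthma=row["asthma"],
            sensitized=row["sensitized"],
            polysensitized=bool(poly and row["sensitized"]),
            total_ige_iu_ml=round(float(ige), 2),
            genotypes=genos,
            flg_null=row["flg_null"],
        )

    subjects = [
        build(row, i + 1, True, ages_case[i],
              "moderate" if moderate[i] else "mild", poly_case[i], ige_case[i])
        for i, row in enumerate(case_rows)
    ] + [
        build(row, i + 1, False, ages_ctrl[i], "none", poly_ctrl[i], ige_ctrl[i])
        for i, row in enumerate(control_rows)
    ]
    return Cohort(
        subjects=tuple(subjects),
        sites=dict(config.sites),
        provenance=f"simulated (seed={config.seed})",
    )


# ---------------------------------------------------------------------------
# risk-table mode


@dataclass(frozen=True)
class RiskTableConfig:
    """Cohort-style sampling with explicit per-stratum outcome risks.

    Two independent binary exposures with carrier probabilities ``p_a`` and
    ``p_b``; ``risks`` maps the four joint strata (0,0)...(1,1) to outcome
    probabilities. Because risks are specified directly, any additive-scale
    interaction (RERI) target is exactly attainable.
    """

    seed: int
    n: int
    p_a: float
    p_b: float
    risks: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "risks", dict(self.risks))
        for p in (self.p_a, self.p_b, *self.risks.values()):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if set(self.risks) != {(0, 0), (1, 0), (0, 1), (1, 1)}:
            raise ValidationError("risks must cover exactly the four strata")
        if self.n <= 0:
            raise ValidationError("n must be positive")

    def true_rrs(self) -> tuple[float, float, float]:
        r = self.risks
        return (r[1, 0] / r[0, 0], r[0, 1] / r[0, 0], r[1, 1] / r[0, 0])


def simulate_joint_counts(config: RiskTableConfig) -> JointExposureTable:
    """Sample a joint-exposure outcome table under the risk-table model."""
    rng = np.random.default_rng(config.seed)
    a = rng.random(config.n) < config.p_a
    b = rng.random(config.n) < config.p_b
    p = np.empty(config.n)
    for (ia, ib), risk in config.risks.items():
        p[(a == bool(ia)) & (b == bool(ib))] = risk
    y = rng.random(config.n) < p
    cases, controls = [], []
    for ia, ib in ((0, 0), (1, 0), (0, 1), (1, 1)):
        mask = (a == bool(ia)) & (b == bool(ib))
        cases.append(int((mask & y).sum()))
        controls.append(int((mask & ~y).sum()))
    return JointExposureTable(
        cases=tuple(cases),
        controls=tuple(controls),
        label_a="A",
        label_b="B",
        outcome_label="outcome",
    )
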