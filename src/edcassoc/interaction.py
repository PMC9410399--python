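"""Gene-gene interaction on additive and multiplicative scales.

Subjects are cross-classified by two binary risk factors into four strata
(A-B-, A+B-, A-B+, A+B+). Within each stratum the "RR" is the ratio of the
within-stratum case proportion ``cases / (cases + controls)`` to the
reference (double-unexposed) stratum's proportion. In a case-control sample
this is a design artifact — the case proportion is fixed by the sampling
ratio, not a population risk — but it is the quantity the source tables
print, and the interaction contrasts built from it are computed exactly the
same way as from true risks:

* RERI = RR11 - RR10 - RR01 + 1 (> 0: superadditive)
* AP   = RERI / RR11
* S    = (RR11 - 1) / ((RR10 - 1) + (RR01 - 1)) (undefined at denominator 0)
* ratio of RRs = RR11 / (RR10 * RR01) (> 1: positive multiplicative interaction)

All measures are computed from unrounded RRs. Confidence intervals (not part
of the source analysis) are available by the Hosmer-Lemeshow delta method on
the log-RR covariance or by a stratified case/control bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import UndefinedStatisticError, ValidationError, z_quantile
from .association import EffectEstimate, ProductTerm, logistic_fit
from .cohort import Cohort
from .filters import resolve_phenotype, resolve_population
from .genetic import resolve_exposure

__all__ = [
    "JointExposureTable",
    "StratumRelativeRisks",
    "AdditiveMeasures",
    "InteractionMeasures",
    "joint_strata",
    "stratum_relative_risks",
    "additive_interaction",
    "multiplicative_interaction",
    "interaction_measures",
    "interaction_term_test",
    "interaction_cis",
]

STRATA = ((0, 0), (1, 0), (0, 1), (1, 1))


@dataclass(frozen=True)
class JointExposureTable:
    """Case/control counts for the four joint-exposure strata.

    ``cases`` and ``controls`` are 4-tuples ordered (A-B-, A+B-, A-B+, A+B+).
    """

    cases: tuple[int, int, int, int]
    controls: tuple[int, int, int, int]
    label_a: str = "A"
    label_b: str = "B"
    outcome_label: str = "case"
    n_excluded: int = field(default=0, compare=False)
    flags: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.cases) != 4 or len(self.controls) != 4:
            raise ValidationError("need exactly four strata")
        if min(self.cases) < 0 or min(self.controls) < 0:
            raise ValidationError("stratum counts must be non-negative")
        if self.cases[0] == 0 or self.controls[0] == 0:
            raise ValidationError(
                "reference stratum (A-B-) must contain cases and controls"
            )

    def stratum_total(self, i: int) -> int:
        return self.cases[i] + self.controls[i]

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)

    def risks(self) -> tuple[float, ...]:
        """Within-stratum case proportions; NaN for an empty stratum."""
        return tuple(
            self.cases[i] / t if (t := self.stratum_total(i)) else math.nan
            for i in range(4)
        )

    def swap_factors(self) -> "JointExposureTable":
        order = (0, 2, 1, 3)
        return JointExposureTable(
            cases=tuple(self.cases[i] for i in order),
            controls=tuple(self.controls[i] for i in order),
            label_a=self.label_b,
            label_b=self.label_a,
            outcome_label=self.outcome_label,
        )


@dataclass(frozen=True)
class StratumRelativeRisks:
    rr10: EffectEstimate
    rr01: EffectEstimate
    rr11: EffectEstimate

    def point(self) -> tuple[float, float, float]:
        return (self.rr10.estimate, self.rr01.estimate, self.rr11.estimate)


@dataclass(frozen=True)
class AdditiveMeasures:
    reri: float
    ap: float
    s: float | None  # None when the synergy-index denominator is 0
    s_note: str = ""


@dataclass(frozen=True)
class InteractionMeasures:
    risks: StratumRelativeRisks
    additive: AdditiveMeasures
    ratio_rr: float
    interaction_term_p: float | None = None
    cis: dict | None = None


def joint_strata(
    cohort: Cohort,
    exposure_a,
    exposure_b,
    outcome,
    population="all",
) -> JointExposureTable:
    """Cross-classify two binary exposures against an outcome.

    Complete-case within the population; subjects with a missing code at
    either factor (or an undefined outcome) are excluded and counted.
    """
    exp_a = resolve_exposure(exposure_a)
    exp_b = resolve_exposure(exposure_b)
    for e in (exp_a, exp_b):
        if not e.binary:
            raise ValidationError(f"joint strata need binary exposures: {e.label}")
    out_name, out_fn = resolve_phenotype(outcome)
    pop_name, keep = resolve_population(population)
    cases = [0, 0, 0, 0]
    controls = [0, 0, 0, 0]
    excluded = 0
    for s in cohort:
        if not keep(s):
            continue
        ca = exp_a.code(s, cohort.sites)
        cb = exp_b.code(s, cohort.sites)
        y = out_fn(s)
        if ca is None or cb is None or y is None:
            excluded += 1
            continue
        idx = STRATA.index((int(bool(ca)), int(bool(cb))))
        (cases if y else controls)[idx] += 1
    flags = tuple(
        f"empty stratum {STRATA[i]}" for i in range(4)
        if cases[i] + controls[i] == 0
    )
    return JointExposureTable(
        cases=tuple(cases),
        controls=tuple(controls),
        label_a=exp_a.label,
        label_b=exp_b.label,
        outcome_label=out_name,
        n_excluded=excluded,
        flags=flags,
    )


def _katz_ci(
    p_i: float, n_i: int, p0: float, n0: int, rr: float, level: float,
    haldane: bool = False,
) -> tuple[float, float]:
    """Log-RR (Katz) interval for a ratio of two proportions."""
    if haldane:
        # degenerate stratum (p = 0 or 1): 0.5-corrected variance term
        k_i = p_i * n_i
        p_i = (k_i + 0.5) / (n_i + 1)
    var = (1 - p_i) / (n_i * p_i) + (1 - p0) / (n0 * p0)
    z = z_quantile(level)
    half = z * math.sqrt(var)
    return rr * math.exp(-half), rr * math.exp(half)


def stratum_relative_risks(
    table: JointExposureTable, level: float = 0.95
) -> StratumRelativeRisks:
    """Per-stratum case-proportion ratios against the reference stratum.

    Point RRs are computed without any correction (a zero-control stratum
    yields RR = 1/p0 exactly, as printed in the source tables); the CI of
    such a degenerate stratum uses a Haldane-corrected variance and is
    flagged.
    """
    risks = table.risks()
    p0 = risks[0]
    if not (p0 > 0):
        raise UndefinedStatisticError("reference stratum risk is zero")
    out: dict[int, EffectEstimate] = {}
    for i in (1, 2, 3):
        n_i = table.stratum_total(i)
        if n_i == 0:
            raise UndefinedStatisticError(
                f"stratum {STRATA[i]} has zero total; RR not estimable"
            )
        p_i = risks[i]
        if p_i == 0:
            raise UndefinedStatisticError(
                f"stratum {STRATA[i]} has zero cases; RR is 0 and the interaction "
                "contrasts are degenerate"
            )
        rr = p_i / p0
        degenerate = p_i in (0.0, 1.0)
        lo, hi = _katz_ci(p_i, n_i, p0, table.stratum_total(0), rr, level,
                          haldane=degenerate)
        flags = ("degenerate CI (zero-control stratum)",) if degenerate else ()
        out[i] = EffectEstimate(
            measure="RR",
            estimate=rr,
            ci_lower=lo,
            ci_upper=hi,
            level=level,
            p=None,
            method="case-proportion ratio (katz CI)",
            n_used=n_i + table.stratum_total(0),
            flags=flags,
        )
    return StratumRelativeRisks(rr10=out[1], rr01=out[2], rr11=out[3])


def _as_rr_triple(rrs) -> tuple[float, float, float]:
    if isinstance(rrs, StratumRelativeRisks):
        return rrs.point()
    vals = tuple(float(v) for v in rrs)
    if len(vals) != 3:
        raise ValidationError("expected (rr10, rr01, rr11)")
    return vals


def additive_interaction(rrs) -> AdditiveMeasures:
    """RERI, AP and the synergy index S from (rr10, rr01, rr11)."""
    rr10, rr01, rr11 = _as_rr_triple(rrs)
    if not all(math.isfinite(v) and v > 0 for v in (rr10, rr01, rr11)):
        raise ValidationError("stratum RRs must be finite and positive")
    reri = rr11 - rr10 - rr01 + 1.0
    ap = reri / rr11
    denom = (rr10 - 1.0) + (rr01 - 1.0)
    if denom == 0:
        return AdditiveMeasures(reri, ap, None,
                                s_note="synergy index undefined: denominator 0")
    return AdditiveMeasures(reri, ap, (rr11 - 1.0) / denom)


def multiplicative_interaction(rrs) -> float:
    """Ratio of RRs (or ORs): eff11 / (eff10 * eff01)."""
    e10, e01, e11 = _as_rr_triple(rrs)
    if not all(math.isfinite(v) and v > 0 for v in (e10, e01, e11)):
        raise ValidationError("effect estimates must be finite and positive")
    return e11 / (e10 * e01)


def interaction_measures(
    table: JointExposureTable,
    level: float = 0.95,
    ci_method: "str | None" = None,
    reps: int = 2000,
    seed: "int | None" = None,
) -> InteractionMeasures:
    """All interaction measures for one joint-exposure table."""
    rrs = stratum_relative_risks(table, level=level)
    cis = (
        interaction_cis(table, method=ci_method, reps=reps, seed=seed, level=level)
        if ci_method
        else None
    )
    return InteractionMeasures(
        risks=rrs,
        additive=additive_interaction(rrs),
        ratio_rr=multiplicative_interaction(rrs),
        cis=cis,
    )


def interaction_term_test(
    cohort: Cohort,
    exposure_a,
    exposure_b,
    outcome,
    covariates: tuple = (),
    population="all",
    method: str = "auto",
):
    """Wald test of the logistic product term for two binary exposures.

    Fits ``outcome ~ A + B + A*B [+ covariates]`` via
    :func:`~edcassoc.association.logistic_fit` and returns
    ``(coefficient, fit)`` where ``coefficient`` carries the product-term
    estimate, SE and two-sided Wald p. Zero-cell strata commonly trigger
    separation; the fit's flag (and Firth refit under ``method="auto"``)
    reports it.
    """
    a = resolve_exposure(exposure_a)
    b = resolve_exposure(exposure_b)
    product = ProductTerm(a, b)
    fit = logistic_fit(
        cohort,
        outcome,
        [a, b, product, *covariates],
        population=population,
        method=method,
    )
    if product.label not in fit.coefficients:
        raise ValidationError(
            f"product term {product.label} dropped as degenerate: {fit.dropped}"
        )
    return fit[product.label], fit


# ---------------------------------------------------------------------------
# confidence intervals for the interaction measures


def _delta_cis(table: JointExposureTable, level: float) -> dict:
    risks = table.risks()
    if any((r <= 0 or r >= 1) for r in risks):
        raise UndefinedStatisticError("delta method needs 0 < risk < 1 in all strata")
    n = [table.stratum_total(i) for i in range(4)]
    v = [(1 - risks[i]) / (n[i] * risks[i]) for i in range(4)]
    rr = [risks[i] / risks[0] for i in range(4)]  # rr[0] == 1
    # log-RR covariance: var(l_i) = v_i + v_0, cov(l_i, l_j) = v_0
    cov = np.full((3, 3), v[0])
    for i in range(3):
        cov[i, i] = v[i + 1] + v[0]
    z = z_quantile(level)
    rr10, rr01, rr11 = rr[1], rr[2], rr[3]

    def wald(est: float, grad: np.ndarray) -> tuple[float, float]:
        se = math.sqrt(float(grad @ cov @ grad))
        return est - z * se, est + z * se

    reri = rr11 - rr10 - rr01 + 1
    out = {
        "reri": wald(reri, np.array([-rr10, -rr01, rr11])),
        "ap": wald(
            reri / rr11,
            np.array([-rr10 / rr11, -rr01 / rr11, (rr10 + rr01 - 1) / rr11]),
        ),
    }
    denom = (rr10 - 1) + (rr01 - 1)
    if denom > 0 and rr11 > 1:
        # CI on the log scale (Rothman), then exponentiate
        g = np.array([-rr10 / denom, -rr01 / denom, rr11 / (rr11 - 1)])
        lo, hi = wald(math.log((rr11 - 1) / denom), g)
        out["s"] = (math.exp(lo), math.exp(hi))
    else:
        out["s"] = None
    return out


def _bootstrap_cis(
    table: JointExposureTable, reps: int, seed: "int | None", level: float
) -> dict:
    if reps < 200:
        raise ValidationError("bootstrap needs at least 200 replicates")
    rng = np.random.default_rng(seed)
    case_p = np.array(table.cases) / table.n_cases
    ctrl_p = np.array(table.controls) / table.n_controls
    reri_s, ap_s, s_s = [], [], []
    draws = 0
    while len(reri_s) < reps:
        draws += 1
        if draws > 50 * reps:
            raise UndefinedStatisticError(
                "bootstrap: too many degenerate resamples; table too sparse"
            )
        cases = rng.multinomial(table.n_cases, case_p)
        controls = rng.multinomial(table.n_controls, ctrl_p)
        tot = cases + controls
        if cases[0] == 0 or controls[0] == 0 or (tot == 0).any() or (cases == 0).any():
            continue
        risks = cases / tot
        rr = risks / risks[0]
        reri_s.append(rr[3] - rr[1] - rr[2] + 1)
        ap_s.append((rr[3] - rr[1] - rr[2] + 1) / rr[3])
        denom = (rr[1] - 1) + (rr[2] - 1)
        if denom != 0:
            s_s.append((rr[3] - 1) / denom)
    alpha = (1 - level) / 2

    def pct(vals: list) -> tuple[float, float]:
        return (
            float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1 - alpha)),
        )

    return {
        "reri": pct(reri_s),
        "ap": pct(ap_s),
        "s": pct(s_s) if len(s_s) >= reps // 2 else None,
    }


def interaction_cis(
    table: JointExposureTable,
    method: str = "delta",
    reps: int = 2000,
    seed: "int | None" = None,
    level: float = 0.95,
) -> dict:
    """Confidence intervals for RERI, AP and S.

    ``method="delta"`` uses the Hosmer-Lemeshow construction on the log-RR
    covariance; it is invalid when any stratum has a zero cell, in which case
    it falls back to the stratified case/control bootstrap with a warning.
    Bootstrap results are reproducible given ``seed``.
    """
    if method == "delta":
        try:
            return _delta_cis(table, level)
        except UndefinedStatisticError:
            warnings.warn(
                "delta method undefined for zero-cell strata; "
                "falling back to bootstrap",
                stacklevel=2,
            )
            return _bootstrap_cis(table, reps, seed, level)
    if method == "bootstrap":
        return _bootstrap_cis(table, reps, seed, level)
    raise ValidationError(f"unknown CI method {method!r}")
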