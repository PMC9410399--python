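"""Genotype carrier status as a predictive biomarker for eczema-associated asthma.

The default evaluation population takes children who developed
eczema-associated asthma by age 6 as outcome-positives and healthy controls
as outcome-negatives; children with eczema but no asthma are excluded. This
is the population that makes sensitivity, specificity, PPV and NPV mutually
consistent with the study's joint-genotype counts. A "within-eczema"
alternative (positives = asthma, negatives = eczema without asthma) is
available through the ``negatives`` filter.

Sensitivity/specificity CIs are Clopper-Pearson exact binomial intervals.
PPV/NPV intervals are configurable (Clopper-Pearson or logit-Wald) because
predictive-value intervals have no single convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from ._util import UndefinedStatisticError, ValidationError, z_quantile
from .cohort import Cohort
from .filters import resolve_population
from .genetic import Conjunction, resolve_exposure

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "DiagnosticMetrics",
    "confusion_matrix",
    "clopper_pearson",
    "diagnostic_metrics",
    "combined_predictor",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int
    predictor: str = ""
    positives: str = "outcome-positive"
    negatives: str = "outcome-negative"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """One diagnostic metric as a percentage with its CI."""

    value: float  # percent
    ci_lower: float
    ci_upper: float
    numerator: int
    denominator: int
    ci_method: str


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: "MetricEstimate | None"
    specificity: "MetricEstimate | None"
    ppv: "MetricEstimate | None"
    npv: "MetricEstimate | None"
    level: float
    notes: tuple[str, ...] = ()


def confusion_matrix(
    cohort: Cohort,
    predictor,
    positives="asthma_or_control",
    negatives=None,
) -> ConfusionMatrix:
    """Tally the predictor against disjoint outcome populations.

    ``positives``/``negatives`` are population filters. The default takes
    positives = eczema-associated asthma cases and negatives = healthy
    controls. Subjects with a missing predictor code are excluded and
    counted.
    """
    pred = resolve_exposure(predictor)
    if not pred.binary:
        raise ValidationError(f"predictor must be binary, got {pred.label}")
    if negatives is None:
        pos_name, pos_fn = "asthma", lambda s: s.asthma
        neg_name, neg_fn = "controls", lambda s: s.is_control
    else:
        pos_name, pos_fn = resolve_population(positives)
        neg_name, neg_fn = resolve_population(negatives)
    overlap = [s.subject_id for s in cohort if pos_fn(s) and neg_fn(s)]
    if overlap:
        raise ValidationError(
            "positive and negative populations overlap: " + ", ".join(overlap[:10])
        )
    tp = fn = fp = tn = excluded = 0
    for s in cohort:
        is_pos, is_neg = pos_fn(s), neg_fn(s)
        if not (is_pos or is_neg):
            continue
        code = pred.code(s, cohort.sites)
        if code is None:
            excluded += 1
            continue
        if is_pos:
            tp += code
            fn += 1 - code
        else:
            fp += code
            tn += 1 - code
    if tp + fn == 0 or fp + tn == 0:
        raise ValidationError(
            f"empty outcome population (positives={pos_name!r}, negatives={neg_name!r})"
        )
    return ConfusionMatrix(
        tp, fn, fp, tn,
        predictor=pred.label, positives=pos_name, negatives=neg_name,
        n_excluded=excluded,
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) interval for k successes out of n."""
    if not 0 <= k <= n or n == 0:
        raise ValidationError(f"invalid binomial counts k={k}, n={n}")
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _logit_ci(k: int, n: int, level: float) -> tuple[float, float]:
    import math

    if k == 0 or k == n:  # logit interval degenerates; use exact
        return clopper_pearson(k, n, level)
    p = k / n
    se = math.sqrt(1 / k + 1 / (n - k))
    z = z_quantile(level)
    lo = math.log(p / (1 - p)) - z * se
    hi = math.log(p / (1 - p)) + z * se
    return 1 / (1 + math.exp(-lo)), 1 / (1 + math.exp(-hi))


def _metric(
    k: int, n: int, level: float, method: str
) -> "MetricEstimate | None":
    if n == 0:
        return None
    if method == "clopper-pearson":
        lo, hi = clopper_pearson(k, n, level)
    elif method == "logit":
        lo, hi = _logit_ci(k, n, level)
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    return MetricEstimate(
        value=100.0 * k / n,
        ci_lower=100.0 * lo,
        ci_upper=100.0 * hi,
        numerator=k,
        denominator=n,
        ci_method=method,
    )


def diagnostic_metrics(
    m: ConfusionMatrix,
    level: float = 0.95,
    ppv_ci_method: str = "clopper-pearson",
) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV (percent) with binomial CIs.

    A zero denominator leaves that metric ``None`` with an explanatory note
    rather than reporting a silent 0.
    """
    notes = []
    if m.tp + m.fp == 0:
        notes.append("PPV undefined: no predictor-positive subjects")
    if m.tn + m.fn == 0:
        notes.append("NPV undefined: no predictor-negative subjects")
    if m.n_positive == 0:
        notes.append("sensitivity undefined: no outcome-positive subjects")
    if m.n_negative == 0:
        notes.append("specificity undefined: no outcome-negative subjects")
    return DiagnosticMetrics(
        sensitivity=_metric(m.tp, m.n_positive, level, "clopper-pearson"),
        specificity=_metric(m.tn, m.n_negative, level, "clopper-pearson"),
        ppv=_metric(m.tp, m.tp + m.fp, level, ppv_ci_method),
        npv=_metric(m.tn, m.tn + m.fn, level, ppv_ci_method),
        level=level,
        notes=tuple(notes),
    )


def combined_predictor(spec_a, spec_b) -> Conjunction:
    """Conjunction predictor: positive iff positive under both components."""
    return Conjunction((resolve_exposure(spec_a), resolve_exposure(spec_b)))
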