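"""Contingency-table statistics, logistic regression, stratified analyses.

Crude effect measures come straight from 2x2 counts: OR = ad/bc with a Woolf
(log-OR Wald) confidence interval, Pearson chi-square without continuity
correction, and the two-sided Fisher exact test (sum of hypergeometric
probabilities no larger than the observed table's, margins fixed). Adjusted
odds ratios come from an in-package maximum-likelihood logistic regression
with explicit separation detection and an optional Firth penalized refit —
quasi-separation is endemic to this study design because controls are
family-history-negative by recruitment.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from ._util import UndefinedStatisticError, ValidationError, z_quantile
from .cohort import Cohort, Subject
from .filters import resolve_phenotype, resolve_population
from .genetic import SiteExposure, combined_flg, resolve_exposure

__all__ = [
    "ContingencyTable",
    "EffectEstimate",
    "ChiSquareResult",
    "build_table",
    "odds_ratio",
    "chi_square_test",
    "fisher_exact",
    "auto_p_value",
    "allele_model",
    "LogisticFit",
    "Coefficient",
    "ProductTerm",
    "fit_logistic_arrays",
    "logistic_fit",
    "stratified_association",
    "severity_association",
]

COVARIATES = ("age_months", "sex", "family_atopy")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-outcome counts.

    ``a`` exposed cases, ``b`` exposed non-cases, ``c`` unexposed cases,
    ``d`` unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int
    n_excluded: int = field(default=0, compare=False)
    flags: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValidationError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EffectEstimate:
    measure: str  # "OR" or "RR"
    estimate: float
    ci_lower: float
    ci_upper: float
    level: float
    p: float | None
    method: str
    n_used: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def build_table(
    cohort: Cohort,
    exposure,
    outcome,
    population="all",
) -> ContingencyTable:
    """Cross-classify a (binary-coded) exposure against an outcome.

    Complete-case within the population filter: subjects with a missing
    exposure code or undefined outcome are excluded and counted in
    ``n_excluded``. A constant outcome or constant exposure produces a valid
    table with an empty margin, flagged (most downstream statistics will then
    refuse it explicitly).
    """
    exp = resolve_exposure(exposure)
    if not exp.binary:
        raise ValidationError(f"build_table needs a binary exposure, got {exp.label}")
    out_name, out_fn = resolve_phenotype(outcome)
    pop_name, keep = resolve_population(population)
    members = [s for s in cohort if keep(s)]
    if not members:
        raise ValidationError(f"population filter {pop_name!r} selects no subjects")
    counts = [[0, 0], [0, 0]]  # [exposed?][case?]
    excluded = 0
    for s in members:
        e = exp.code(s, cohort.sites)
        y = out_fn(s)
        if e is None or y is None:
            excluded += 1
            continue
        counts[int(bool(e))][int(bool(y))] += 1
    a, b = counts[1][1], counts[1][0]
    c, d = counts[0][1], counts[0][0]
    flags = []
    if a + c == 0 or b + d == 0:
        flags.append(f"outcome {out_name!r} constant in population {pop_name!r}")
    if a + b == 0 or c + d == 0:
        flags.append(f"exposure {exp.label!r} constant in population {pop_name!r}")
    return ContingencyTable(a, b, c, d, n_excluded=excluded, flags=tuple(flags))


def odds_ratio(
    table: ContingencyTable,
    level: float = 0.95,
    p_value: "str | None" = "auto",
) -> EffectEstimate:
    """Crude odds ratio ad/bc with a Woolf log-OR confidence interval.

    A single zero cell triggers the Haldane–Anscombe correction (0.5 added to
    every cell) for both the estimate and the CI, flagged. Two zero cells on
    a diagonal leave the OR undefined and raise.

    ``p_value``: "auto" picks Fisher when any expected cell < 5 else the
    Pearson chi-square ("as appropriate"); also accepts "chi2", "fisher",
    or None.
    """
    cells = (table.a, table.b, table.c, table.d)
    zeros = sum(1 for x in cells if x == 0)
    flags: list[str] = []
    if (table.a == 0 and table.d == 0) or (table.b == 0 and table.c == 0):
        raise UndefinedStatisticError(
            f"odds ratio undefined: both cells of a diagonal are zero in "
            f"({table.a}, {table.b}, {table.c}, {table.d})"
        )
    if zeros:
        a, b, c, d = (x + 0.5 for x in cells)
        flags.append("haldane-anscombe 0.5 correction (zero cell)")
        method = "woolf+haldane"
    else:
        a, b, c, d = map(float, cells)
        method = "woolf"
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = z_quantile(level)
    lo, hi = est * math.exp(-z * se), est * math.exp(z * se)
    p = auto_p_value(table, p_value) if p_value else None
    return EffectEstimate(
        measure="OR",
        estimate=est,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
        p=p,
        method=method,
        n_used=table.total,
        flags=tuple(flags) + table.flags,
    )


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square without Yates correction; 2x2 or 2xk.

    Accepts a :class:`ContingencyTable` or an array-like of counts.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(
        table, dtype=float
    )
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("chi-square test undefined: zero margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table (fixed margins)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def expected_counts(table: ContingencyTable) -> np.ndarray:
    arr = table.as_array()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def auto_p_value(table: ContingencyTable, rule: str = "auto") -> float:
    """Two-sided p: chi-square, Fisher, or Fisher-when-sparse ("auto")."""
    if rule == "chi2":
        return chi_square_test(table).p
    if rule == "fisher":
        return fisher_exact(table)
    if rule == "auto":
        try:
            sparse = (expected_counts(table) < 5).any()
        except ZeroDivisionError:  # pragma: no cover - total>0 guaranteed
            sparse = True
        if sparse or table.flags:
            return fisher_exact(table)
        return chi_square_test(table).p
    raise ValidationError(f"unknown p-value rule {rule!r}")


def allele_model(
    cohort: Cohort,
    site_id: str,
    outcome,
    population="all",
    level: float = 0.95,
) -> EffectEstimate:
    """Per-allele (multiplicative-model) odds ratio.

    Each genotyped subject contributes two allele observations; the OR is
    computed on the resulting allele-by-outcome 2x2 table with a Woolf CI.
    """
    if site_id not in cohort.sites:
        raise ValidationError(f"undeclared site {site_id!r}")
    risk = cohort.sites[site_id].risk_allele
    out_name, out_fn = resolve_phenotype(outcome)
    _, keep = resolve_population(population)
    a = b = c = d = 0
    n_used = 0
    for s in cohort:
        if not keep(s):
            continue
        call = s.genotype(site_id)
        y = out_fn(s)
        if call.missing or y is None:
            continue
        n_used += 1
        r = call.risk_count(risk)
        if y:
            a += r
            c += 2 - r
        else:
            b += r
            d += 2 - r
    if a + b == 0 or c + d == 0:
        raise UndefinedStatisticError(
            f"allele model undefined: site {site_id} monomorphic in this population"
        )
    table = ContingencyTable(a, b, c, d)
    est = odds_ratio(table, level=level)
    return EffectEstimate(
        measure="OR",
        estimate=est.estimate,
        ci_lower=est.ci_lower,
        ci_upper=est.ci_upper,
        level=level,
        p=est.p,
        method="allele/" + est.method,
        n_used=n_used,
        flags=est.flags,
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    z: float
    p: float

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)

    def or_ci(self, level: float = 0.95) -> tuple[float, float]:
        zq = z_quantile(level)
        return (
            math.exp(self.estimate - zq * self.se),
            math.exp(self.estimate + zq * self.se),
        )


@dataclass(frozen=True)
class LogisticFit:
    coefficients: dict[str, Coefficient]
    converged: bool
    separation_flag: bool
    n_used: int
    method: str  # "mle" or "firth"
    loglike: float
    n_iter: int
    dropped: tuple[str, ...] = ()

    def __getitem__(self, term: str) -> Coefficient:
        return self.coefficients[term]


@dataclass(frozen=True)
class ProductTerm:
    """Interaction (product) of two binary exposures in a logistic design."""

    first: object
    second: object

    @property
    def label(self) -> str:
        a = resolve_exposure(self.first)
        b = resolve_exposure(self.second)
        return f"{a.label}*{b.label}"

    def code(self, subject: Subject, sites) -> "int | None":
        a = resolve_exposure(self.first).code(subject, sites)
        b = resolve_exposure(self.second).code(subject, sites)
        if a is None or b is None:
            return None
        return a * b


def _loglike(eta: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    # y*eta - log(1+exp(eta)), numerically stable
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _hat_diagonal(X: np.ndarray, W: np.ndarray, info_inv: np.ndarray) -> np.ndarray:
    XW = X * W[:, None]
    return np.einsum("ij,jk,ik->i", XW, info_inv, X)


def fit_logistic_arrays(
    X: np.ndarray,
    y: np.ndarray,
    weights: "np.ndarray | None" = None,
    method: str = "mle",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, bool, float, int]:
    """Newton-type logistic fit on a prepared design matrix.

    Returns ``(beta, se, converged, separation_flag, loglike, n_iter)``.
    Convergence is declared when the (penalized, for Firth) log-likelihood
    changes by less than ``tol``; step-halving guards each update.
    Separation is flagged when fitted probabilities sit within 1e-6 of 0/1
    together with a diverging coefficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    firth = method == "firth"
    ll_old = -np.inf
    converged = False
    it = 0
    info = np.eye(k)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        W = w * p * (1 - p)
        info = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "singular information matrix in logistic fit (rank-deficient design)"
            ) from exc
        if firth:
            h = _hat_diagonal(X, W, info_inv)
            score = X.T @ (w * (y - p) + h * (0.5 - p))
            sign, logdet = np.linalg.slogdet(info)
            ll = _loglike(eta, y, w) + 0.5 * (logdet if sign > 0 else -np.inf)
        else:
            score = X.T @ (w * (y - p))
            ll = _loglike(eta, y, w)
        step = info_inv @ score
        # step-halving: accept the largest step that does not decrease the objective
        new_beta = beta + step
        for _ in range(25):
            eta_new = X @ new_beta
            if firth:
                p_new = expit(eta_new)
                W_new = w * p_new * (1 - p_new)
                sign, logdet = np.linalg.slogdet(X.T @ (X * W_new[:, None]))
                ll_new = _loglike(eta_new, y, w) + 0.5 * (
                    logdet if sign > 0 else -np.inf
                )
            else:
                ll_new = _loglike(eta_new, y, w)
            if ll_new >= ll - 1e-12 or not np.isfinite(ll_new):
                if np.isfinite(ll_new):
                    break
            step = step / 2.0
            new_beta = beta + step
        beta = new_beta
        if abs(ll_new - ll_old) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = X @ beta
    p = expit(eta)
    W = w * p * (1 - p)
    info = X.T @ (X * W[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    extreme = bool(np.any((p < 1e-6) | (p > 1 - 1e-6)))
    separation = (not firth) and extreme and (
        bool(np.max(np.abs(beta)) > 10) or not converged
    )
    return beta, se, converged, separation, float(ll_old), it


def _design_from_cohort(
    cohort: Cohort, outcome, terms: Sequence, population
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    _, out_fn = resolve_phenotype(outcome)
    pop_name, keep = resolve_population(population)
    resolved: list[tuple[str, Callable[[Subject], "float | None"]]] = []
    for t in terms:
        if isinstance(t, str) and t in COVARIATES:
            if t == "age_months":
                resolved.append((t, lambda s: s.age_months))
            elif t == "sex":
                resolved.append((t, lambda s: float(s.sex == "male")))
            else:
                resolved.append((t, lambda s: float(s.family_atopy)))
        elif isinstance(t, ProductTerm):
            resolved.append((t.label, lambda s, t=t: t.code(s, cohort.sites)))
        else:
            exp = resolve_exposure(t)
            resolved.append(
                (exp.label, lambda s, exp=exp: exp.code(s, cohort.sites))
            )
    rows, ys = [], []
    excluded = 0
    for s in cohort:
        if not keep(s):
            continue
        y = out_fn(s)
        vals = [fn(s) for _, fn in resolved]
        if y is None or any(v is None for v in vals):
            excluded += 1
            continue
        rows.append([1.0] + [float(v) for v in vals])
        ys.append(float(bool(y)))
    if not rows:
        raise ValidationError(f"no usable subjects in population {pop_name!r}")
    X = np.asarray(rows)
    y = np.asarray(ys)
    names = ["intercept"] + [name for name, _ in resolved]
    return X, y, names, excluded


def _drop_degenerate_columns(
    X: np.ndarray, names: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    dropped: list[str] = []
    keep_idx = [0]
    for j in range(1, X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            dropped.append(names[j] + " (constant)")
        else:
            keep_idx.append(j)
    X = X[:, keep_idx]
    names = [names[j] for j in keep_idx]
    # exact collinearity: greedy QR-style rank check, keep earliest columns
    keep2 = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep2 + [j]]
        if np.linalg.matrix_rank(trial) == len(keep2) + 1:
            keep2.append(j)
        else:
            dropped.append(names[j] + " (collinear)")
    if len(keep2) < X.shape[1]:
        X = X[:, keep2]
        names = [names[j] for j in keep2]
    return X, names, dropped


def logistic_fit(
    cohort: Cohort,
    outcome,
    terms: Sequence,
    population="all",
    method: str = "auto",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Logistic regression of an outcome on exposures and covariates.

    ``terms`` mixes exposure specs (site/model, ``"flg_null"``,
    :class:`~edcassoc.genetic.Conjunction`, :class:`ProductTerm`) with the
    covariate names ``age_months``, ``sex`` (male = 1), ``family_atopy``.
    Complete-case; constant or collinear columns are dropped with a warning.

    ``method``: ``"mle"``, ``"firth"``, or ``"auto"`` (MLE, then a Firth
    penalized refit whenever separation is flagged).
    """
    if method not in ("mle", "firth", "auto"):
        raise ValidationError(f"unknown logistic method {method!r}")
    X, y, names, _ = _design_from_cohort(cohort, outcome, terms, population)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome is constant in the analysis population")
    X, names, dropped = _drop_degenerate_columns(X, names)
    for msg in dropped:
        warnings.warn(f"logistic_fit: dropped {msg}", stacklevel=2)
    fit_method = "firth" if method == "firth" else "mle"
    beta, se, converged, separation, ll, it = fit_logistic_arrays(
        X, y, method=fit_method, tol=tol, max_iter=max_iter
    )
    if method == "auto" and separation:
        warnings.warn(
            "logistic_fit: separation detected, refitting with Firth penalization",
            stacklevel=2,
        )
        beta, se, converged, _, ll, it = fit_logistic_arrays(
            X, y, method="firth", tol=tol, max_iter=max_iter
        )
        fit_method = "firth"
    if not converged and not separation:
        raise ValidationError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(last log-likelihood {ll:.6f})"
        )
    zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    coeffs = {
        name: Coefficient(float(b), float(s), float(z), float(p))
        for name, b, s, z, p in zip(names, beta, se, zvals, pvals)
    }
    return LogisticFit(
        coefficients=coeffs,
        converged=converged,
        separation_flag=separation,
        n_used=len(y),
        method=fit_method,
        loglike=ll,
        n_iter=it,
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# stratified and severity analyses


def stratified_association(
    cohort: Cohort,
    site_id: str,
    model: str,
    outcome,
    population="all",
    level: float = 0.95,
) -> dict[str, "EffectEstimate | None"]:
    """Run a genetic-model association separately inside each combined-FLG
    stratum (normal / null).

    Returns a mapping stratum -> crude estimate, with ``None`` for a stratum
    where the statistic is not estimable (empty stratum, empty margin).
    """
    results: dict[str, EffectEstimate | None] = {}
    for stratum in ("normal", "null"):
        sub = cohort.subset(lambda s, st=stratum: combined_flg(s) == st,
                            note=f"flg={stratum}")
        try:
            if model == "allele":
                results[stratum] = allele_model(sub, site_id, outcome, population, level)
            else:
                table = build_table(sub, SiteExposure(site_id, model), outcome, population)
                results[stratum] = odds_ratio(table, level=level)
        except (ValidationError, UndefinedStatisticError):
            results[stratum] = None
    return results


def severity_association(
    cohort: Cohort,
    site_id: str,
    model: str = "dominant",
    level: float = 0.95,
) -> EffectEstimate:
    """Carrier odds for moderate vs mild eczema (mild is the reference).

    Severe disease is absent from this cohort; any severe cases present are
    excluded from the comparison and flagged via the table's exclusion count.
    """
    table = build_table(
        cohort, SiteExposure(site_id, model), "moderate_eczema", "graded_eczema"
    )
    return odds_ratio(table, level=level)
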