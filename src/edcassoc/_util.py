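"""Shared error types and small numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

from scipy import stats


class EdcassocError(Exception):
    """Base class for all package errors."""


class ValidationError(EdcassocError):
    """Invalid input data or configuration."""


class SchemaError(ValidationError):
    """Input table does not match the declared column schema."""


class UndefinedStatisticError(EdcassocError):
    """The requested statistic is undefined for these counts (e.g. empty margin)."""


class SimulationError(EdcassocError):
    """Simulation could not satisfy its accrual quotas."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as report tables conventionally do.

    Python's builtin ``round`` is banker's rounding; display percentages use
    half-up so that e.g. 13.55 -> 13.6.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def z_quantile(level: float) -> float:
    """Two-sided normal quantile for a confidence level (0.95 -> 1.959964)."""
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def fmt_estimate_ci(est: float, lo: float, hi: float, nd: int = 2, sep: str = "-") -> str:
    return f"{est:.{nd}f} ({lo:.{nd}f} {sep} {hi:.{nd}f})"
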