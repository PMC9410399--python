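"""Named phenotype outcomes and analysis-population filters.

The study's tables shift denominators between analyses (whole population,
eczema cases only, asthma cases vs healthy controls), so population filters
are first-class: every statistic takes an explicit population spec, either a
registered name or an arbitrary ``Subject -> bool`` callable.

A phenotype callable may return ``None`` for "undefined for this subject"
(e.g. the moderate-vs-mild severity outcome for an ungraded child); such
subjects are excluded complete-case and counted.
"""

from __future__ import annotations

from collections.abc import Callable

from ._util import ValidationError
from .cohort import Subject

PhenotypeFn = Callable[[Subject], "bool | None"]
PopulationFn = Callable[[Subject], bool]


def _moderate_eczema(s: Subject) -> bool | None:
    if not s.eczema or s.scorad_class not in ("mild", "moderate"):
        return None
    return s.scorad_class == "moderate"


PHENOTYPES: dict[str, PhenotypeFn] = {
    "eczema": lambda s: s.eczema,
    "asthma": lambda s: s.asthma,  # always the composite asthma-plus-eczema phenotype
    "sensitized": lambda s: s.sensitized,
    "polysensitized": lambda s: s.polysensitized,
    "moderate_eczema": _moderate_eczema,
}

POPULATIONS: dict[str, PopulationFn] = {
    "all": lambda s: True,
    "eczema": lambda s: s.eczema,
    "controls": lambda s: s.is_control,
    # asthma cases against healthy controls; eczema-without-asthma excluded
    "asthma_or_control": lambda s: s.asthma or s.is_control,
    # eczema cases with a mild or moderate SCORAD grade (severity analyses)
    "graded_eczema": lambda s: s.eczema and s.scorad_class in ("mild", "moderate"),
}


def resolve_phenotype(spec: "str | PhenotypeFn") -> tuple[str, PhenotypeFn]:
    if callable(spec):
        return getattr(spec, "__name__", "custom"), spec
    try:
        return spec, PHENOTYPES[spec]
    except KeyError:
        raise ValidationError(
            f"unknown phenotype {spec!r}; known: {sorted(PHENOTYPES)}"
        ) from None


def resolve_population(spec: "str | PopulationFn | None") -> tuple[str, PopulationFn]:
    if spec is None:
        spec = "all"
    if callable(spec):
        return getattr(spec, "__name__", "custom"), spec
    try:
        return spec, POPULATIONS[spec]
    except KeyError:
        raise ValidationError(
            f"unknown population {spec!r}; known: {sorted(POPULATIONS)}"
        ) from None
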