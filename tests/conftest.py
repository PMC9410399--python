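"""Shared fixtures: cohorts reconstructed from the study's printed counts.

The study deposited no subject-level data, but its tables pin exact
marginal and joint counts; each fixture rebuilds a subject-level cohort
consistent with one table's counts so that table-level statistics can be
checked end-to-end through the cohort API. (The source tables are not all
mutually consistent — e.g. the HRNR carrier count among asthma cases is 17
in one table and 16 in the joint-genotype table — so each fixture follows
exactly one table family and says which.)
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest
from hypothesis import HealthCheck, settings

from edcassoc.cohort import Cohort, GenotypeCall, Site, Subject

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

HRNR = "rs877776"
FLG2 = "rs12568784"
SITES = {HRNR: Site("G", "C"), FLG2: Site("G", "T")}


def make_subject(
    subject_id: str,
    *,
    eczema: bool = False,
    asthma: bool = False,
    scorad: str | None = None,
    sensitized: bool = False,
    polysensitized: bool = False,
    family_atopy: bool = False,
    flg_null: bool | None = False,
    age: float = 14.0,
    sex: str = "male",
    ige: float | None = None,
    **genotypes: str,
) -> Subject:
    genos = {
        sid: GenotypeCall.parse(sid, text) for sid, text in genotypes.items()
    }
    if scorad is None:
        scorad = "mild" if eczema else "none"
    return Subject(
        subject_id=subject_id,
        age_months=age,
        sex=sex,
        family_atopy=family_atopy,
        eczema=eczema,
        scorad_class=scorad,
        asthma=asthma,
        sensitized=sensitized,
        polysensitized=polysensitized,
        total_ige_iu_ml=ige,
        genotypes=genos,
        flg_null=flg_null,
    )


def _cells_to_cohort(cells, sites, provenance) -> Cohort:
    """Each cell: (n, dict of per-subject kwargs, dict of count-limited flags).

    Count-limited flags assign True to the first k subjects of the cell,
    e.g. {"asthma": 11} marks the first 11 subjects of the cell asthmatic.
    """
    subjects = []
    i = 0
    for n, fixed, counted in cells:
        for j in range(n):
            i += 1
            kwargs = dict(fixed)
            for flag, k in counted.items():
                kwargs[flag] = j < k
            moderate = kwargs.pop("moderate", False)
            if kwargs.get("eczema"):
                kwargs["scorad"] = "moderate" if moderate else "mild"
            # deterministic age/sex variation so adjusted fits are well-posed
            kwargs.setdefault("age", 4.0 + (i * 7) % 20)
            kwargs.setdefault("sex", "male" if i % 2 else "female")
            subjects.append(make_subject(f"s{i:04d}", **kwargs))
    return Cohort(tuple(subjects), sites, provenance=provenance)


@pytest.fixture(scope="session")
def hrnr_cohort() -> Cohort:
    """HRNR rs877776 single-site cohort (study-group table + HRNR
    association table counts: genotype classes, asthma 11/17, sensitization,
    mild/moderate severity, 14/2 FLG-null carriers, 57 case family
    histories)."""
    sites = {HRNR: SITES[HRNR]}
    cases = [
        # (n, fixed kwargs, count-limited flags); first 57 of the 103 cases
        # get the positive family history via the flg/family counters below.
        (60, {"eczema": True, HRNR: "GG"},
         {"asthma": 11, "sensitized": 27, "moderate": 26}),
        (37, {"eczema": True, HRNR: "GC"},
         {"asthma": 17, "sensitized": 28, "moderate": 17}),
        (6, {"eczema": True, HRNR: "CC"}, {}),
    ]
    controls = [
        (66, {HRNR: "GG"}, {"sensitized": 10}),
        (15, {HRNR: "GC"}, {"sensitized": 1}),
        (4, {HRNR: "CC"}, {}),
    ]
    cohort = _cells_to_cohort(cases + controls, sites, "hrnr reconstruction")
    # family history for the first 57 cases; FLG null for first 14 cases / 2 controls
    import dataclasses

    reordered = []
    n_case = 0
    n_ctrl = 0
    for s in cohort:
        if s.eczema:
            n_case += 1
            s = dataclasses.replace(
                s, family_atopy=n_case <= 57, flg_null=n_case <= 14
            )
        else:
            n_ctrl += 1
            s = dataclasses.replace(s, flg_null=n_ctrl <= 2)
        reordered.append(s)
    return Cohort(tuple(reordered), sites, provenance="hrnr reconstruction")


@pytest.fixture(scope="session")
def flg2_cohort() -> Cohort:
    """FLG2 rs12568784 single-site cohort (study-group + FLG2 association
    table counts: asthma 13/15, sensitization 35+20 vs 6+5, severity
    50/24 vs 10/19)."""
    sites = {FLG2: SITES[FLG2]}
    cells = [
        (74, {"eczema": True, FLG2: "GG"},
         {"asthma": 13, "sensitized": 35, "moderate": 24}),
        (20, {"eczema": True, FLG2: "GT"},
         {"asthma": 15, "sensitized": 20, "moderate": 19}),
        (9, {"eczema": True, FLG2: "TT"}, {}),
        (72, {FLG2: "GG"}, {"sensitized": 6}),
        (8, {FLG2: "GT"}, {"sensitized": 5}),
        (5, {FLG2: "TT"}, {}),
    ]
    return _cells_to_cohort(cells, sites, "flg2 reconstruction")


@pytest.fixture(scope="session")
def hrnr_flg_cohort() -> Cohort:
    """HRNR-by-FLG joint-genotype cohort (interaction tables: eczema strata
    52/37/8/6 vs control 64/19/2/0, asthma 10/12/2/4)."""
    sites = {HRNR: SITES[HRNR]}
    cells = [
        (52, {"eczema": True, HRNR: "GG", "flg_null": False}, {"asthma": 10}),
        (37, {"eczema": True, HRNR: "GC", "flg_null": False}, {"asthma": 12}),
        (8, {"eczema": True, HRNR: "GG", "flg_null": True}, {"asthma": 2}),
        (6, {"eczema": True, HRNR: "GC", "flg_null": True}, {"asthma": 4}),
        (64, {HRNR: "GG", "flg_null": False}, {}),
        (19, {HRNR: "GC", "flg_null": False}, {}),
        (2, {HRNR: "GG", "flg_null": True}, {}),
    ]
    return _cells_to_cohort(cells, sites, "hrnr-flg joint reconstruction")


@pytest.fixture(scope="session")
def flg2_flg_cohort() -> Cohort:
    """FLG2-by-FLG joint-genotype cohort (interaction tables: eczema strata
    71/18/3/11 vs control 70/13/2/0, asthma 10/12/3/3)."""
    sites = {FLG2: SITES[FLG2]}
    cells = [
        (71, {"eczema": True, FLG2: "GG", "flg_null": False}, {"asthma": 10}),
        (18, {"eczema": True, FLG2: "GT", "flg_null": False}, {"asthma": 12}),
        (3, {"eczema": True, FLG2: "GG", "flg_null": True}, {"asthma": 3}),
        (11, {"eczema": True, FLG2: "GT", "flg_null": True}, {"asthma": 3}),
        (70, {FLG2: "GG", "flg_null": False}, {}),
        (13, {FLG2: "GT", "flg_null": False}, {}),
        (2, {FLG2: "GG", "flg_null": True}, {}),
    ]
    return _cells_to_cohort(cells, sites, "flg2-flg joint reconstruction")


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-rational enumeration over all tables with
    the observed margins; independent of any library routine."""
    n = a + b + c + d
    row = a + b
    col = a + c
    lo, hi = max(0, row + col - n), min(row, col)
    probs = {
        x: Fraction(comb(row, x) * comb(n - row, col - x), comb(n, col))
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))
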