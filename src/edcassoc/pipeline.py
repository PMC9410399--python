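"""Configuration-driven analysis pipeline and table rendering.

``run_pipeline`` executes every stage on a cohort (read from disk or
simulated): cohort summary, Hardy-Weinberg testing on controls, crude and
adjusted genetic-model associations, severity and FLG-stratified analyses,
gene-gene interaction blocks, and predictive-biomarker metrics. Each stage's
results are emitted as machine-readable JSON/TSV and a human-readable text
table; a manifest records the package version, seed and a config hash so a
run is reproducible byte-for-byte.

Stage errors are caught and recorded; independent stages still run. The
study's tables use shifting denominators, so every result row carries its
counts and exclusions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._util import EdcassocError, ValidationError
from .association import (
    allele_model,
    build_table,
    logistic_fit,
    odds_ratio,
    severity_association,
    stratified_association,
)
from .biomarker import combined_predictor, confusion_matrix, diagnostic_metrics
from .cohort import Cohort, Site, read_cohort, summarize_cohort, write_cohort
from .genetic import FlgNullExposure, SiteExposure, genotype_counts, hwe_test
from .interaction import interaction_measures, interaction_term_test, joint_strata
from .simulate import LogisticModel, SimulationConfig, simulate_cohort

__all__ = ["AnalysisConfig", "PipelineResult", "run_pipeline", "render_table"]

_ASSOC_OUTCOMES = (
    # (outcome, population)
    ("eczema", "all"),
    ("asthma", "all"),
    ("asthma", "eczema"),
    ("sensitized", "all"),
    ("polysensitized", "all"),
)


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration (YAML/JSON file or dict)."""

    seed: int
    sites: dict[str, Site]
    input: str | None = None
    simulate: SimulationConfig | None = None
    schema: dict[str, str] = field(default_factory=dict)
    ci_level: float = 0.95
    interaction_pairs: list[tuple[str, str]] = field(default_factory=list)
    predictors: list[list[str]] = field(default_factory=list)
    bootstrap_reps: int = 2000
    style: str = "paper"

    def __post_init__(self) -> None:
        if self.input is None and self.simulate is None:
            raise ValidationError("config needs either 'input' or 'simulate'")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        known = set(self.sites) | {"flg_null"}
        if not self.interaction_pairs:
            self.interaction_pairs = [(sid, "flg_null") for sid in self.sites]
            ids = list(self.sites)
            if len(ids) >= 2:
                self.interaction_pairs.append((ids[0], ids[1]))
        if not self.predictors:
            self.predictors = (
                [[sid] for sid in self.sites]
                + [["flg_null"]]
                + [[sid, "flg_null"] for sid in self.sites]
            )
        for pair in self.interaction_pairs:
            for name in pair:
                if name not in known:
                    raise ValidationError(
                        f"interaction pair references undeclared factor {name!r}"
                    )
        for pred in self.predictors:
            for name in pred:
                if name not in known:
                    raise ValidationError(
                        f"predictor references undeclared factor {name!r}"
                    )

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        sites = {
            sid: Site(spec["ref"], spec["risk"])
            for sid, spec in raw.pop("sites", {}).items()
        }
        if not sites:
            raise ValidationError("config must declare at least one site")
        sim = raw.pop("simulate", None)
        seed = raw.pop("seed", None)
        if seed is None:
            raise ValidationError("config must declare a seed")
        sim_cfg = None
        if sim is not None:
            sim = dict(sim)
            models = {}
            for key in ("eczema_model", "asthma_model", "sensitization_model"):
                if key in sim:
                    spec = dict(sim.pop(key))
                    models[key] = LogisticModel(
                        intercept=spec.get("intercept", 0.0),
                        effects={
                            t: (v[0], float(v[1]))
                            for t, v in spec.get("effects", {}).items()
                        },
                        interactions={
                            tuple(k.split(":")): float(v)
                            for k, v in spec.get("interactions", {}).items()
                        },
                    )
            sim_cfg = SimulationConfig(
                seed=sim.pop("seed", seed), sites=sites,
                **models, **sim,
            )
        pairs = [tuple(p) for p in raw.pop("interaction_pairs", [])]
        return cls(
            seed=int(seed),
            sites=sites,
            simulate=sim_cfg,
            interaction_pairs=pairs,
            **raw,
        )

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(raw)

    def canonical_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return {k: default_safe(v) for k, v in dataclasses.asdict(o).items()}
            return repr(o)

        def default_safe(v):
            return v

        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    tables: dict[str, list[dict]]
    manifest: dict
    errors: dict[str, str]


def _ee_row(est, extra: dict | None = None) -> dict:
    row = {
        "measure": est.measure,
        "estimate": est.estimate,
        "ci_lower": est.ci_lower,
        "ci_upper": est.ci_upper,
        "level": est.level,
        "p": est.p,
        "method": est.method,
        "n_used": est.n_used,
        "flags": list(est.flags),
    }
    if extra:
        row.update(extra)
    return row


def _exposure_for(name: str, sites) -> object:
    return FlgNullExposure() if name == "flg_null" else SiteExposure(name, "dominant")


def _stage_summary(cohort: Cohort, cfg: AnalysisConfig) -> list[dict]:
    summary = summarize_cohort(cohort, level=cfg.ci_level)
    rows = []
    for g in summary.groups.values():
        rows.append(
            {
                "group": g.label,
                "n": g.n,
                "age_mean": g.age_mean,
                "age_sd": g.age_sd,
                "male": g.sex_counts["male"][0],
                "phenotypes": {k: list(v) for k, v in g.phenotypes.items()},
                "scorad": {k: list(v) for k, v in g.scorad.items()},
                "genotypes": {
                    sid: {cls: list(v) for cls, v in classes.items()}
                    for sid, classes in g.genotype_counts.items()
                },
                "flg": {k: list(v) for k, v in g.flg.items()},
                "ige_geometric_mean": list(g.ige_geometric_mean)
                if g.ige_geometric_mean
                else None,
                "flags": g.flags,
            }
        )
    return rows


def _stage_hwe(cohort: Cohort, cfg: AnalysisConfig) -> list[dict]:
    rows = []
    for sid in cfg.sites:
        counts = genotype_counts(cohort, sid, population="controls")
        res = hwe_test(counts)
        rows.append(
            {
                "site": sid,
                "population": "controls",
                "counts": [counts.n_ref_hom, counts.n_het, counts.n_alt_hom],
                "allele_freq": res.allele_freq,
                "chi2": res.chi2,
                "df": res.df,
                "p": res.p,
                "expected": list(res.expected),
                "degenerate": res.degenerate,
            }
        )
    return rows


def _stage_association(cohort: Cohort, cfg: AnalysisConfig) -> list[dict]:
    rows = []
    covars = ["age_months", "sex", "family_atopy"]
    for sid in cfg.sites:
        for outcome, population in _ASSOC_OUTCOMES:
            base = {"site": sid, "outcome": outcome, "population": population}
            try:
                table = build_table(
                    cohort, SiteExposure(sid, "dominant"), outcome, population
                )
                crude = odds_ratio(table, level=cfg.ci_level)
                rows.append(
                    _ee_row(
                        crude,
                        {**base, "model": "dominant",
                         "counts": [table.a, table.b, table.c, table.d],
                         "n_excluded": table.n_excluded},
                    )
                )
            except EdcassocError as exc:
                rows.append({**base, "model": "dominant", "error": str(exc)})
                continue
            try:
                fit = logistic_fit(
                    cohort, outcome,
                    [SiteExposure(sid, "dominant"), *covars],
                    population=population, method="auto",
                )
                coef = fit[SiteExposure(sid, "dominant").label]
                lo, hi = coef.or_ci(cfg.ci_level)
                rows.append(
                    {**base, "model": "dominant-adjusted",
                     "estimate": coef.odds_ratio, "ci_lower": lo, "ci_upper": hi,
                     "p": coef.p, "method": f"logistic-{fit.method}",
                     "separation": fit.separation_flag, "n_used": fit.n_used,
                     "dropped": list(fit.dropped)}
                )
            except EdcassocError as exc:
                rows.append({**base, "model": "dominant-adjusted", "error": str(exc)})
            try:
                est = allele_model(cohort, sid, outcome, population, cfg.ci_level)
                rows.append(_ee_row(est, {**base, "model": "allele"}))
            except EdcassocError as exc:
                rows.append({**base, "model": "allele", "error": str(exc)})
    return rows


def _stage_severity(cohort: Cohort, cfg: AnalysisConfig) -> list[dict]:
    rows = []
    for sid in cfg.sites:
        try:
            est = severity_association(cohort, sid, "dominant", cfg.ci_level)
            rows.append(_ee_row(est, {"site": sid, "comparison": "moderate vs mild"}))
        except EdcassocError as exc:
            rows.append({"site": sid, "error": str(exc)})
    return rows


def _stage_stratified(cohort: Cohort, cfg: AnalysisConfig) -> list[dict]:
    rows = []
    for sid in cfg.sites:
        for model in ("dominant", "allele"):
            strata = stratified_association(
                cohort, sid, model, "eczema", "all", cfg.ci_level
            )
            for stratum, est in strata.items():
                base = {"site": sid, "model": model, "flg_stratum": stratum}
                rows.append(
                    _ee_row(est, base) if est is not None
                    else {**base, "error": "not estimable"}
                )
    return rows


def _stage_interaction(cohort: Cohort, cfg: AnalysisConfig) -> list[dict]:
    rows = []
    for name_a, name_b in cfg.interaction_pairs:
        exp_a = _exposure_for(name_a, cfg.sites)
        exp_b = _exposure_for(name_b, cfg.sites)
        for outcome, population in (("eczema", "all"), ("asthma", "asthma_or_control")):
            base = {"factor_a": name_a, "factor_b": name_b, "outcome": outcome}
            try:
                table = joint_strata(cohort, exp_a, exp_b, outcome, population)
                zero_cell = any(
                    c == 0 for c in (*table.cases, *table.controls)
                )
                meas = interaction_measures(
                    table, level=cfg.ci_level,
                    ci_method="bootstrap" if zero_cell else "delta",
                    reps=cfg.bootstrap_reps, seed=cfg.seed,
                )
                row = {
                    **base,
                    "cases": list(table.cases),
                    "controls": list(table.controls),
                    "n_excluded": table.n_excluded,
                    "rr10": _ee_row(meas.risks.rr10),
                    "rr01": _ee_row(meas.risks.rr01),
                    "rr11": _ee_row(meas.risks.rr11),
                    "reri": meas.additive.reri,
                    "ap": meas.additive.ap,
                    "s": meas.additive.s,
                    "ratio_rr": meas.ratio_rr,
                    "cis": {
                        k: (list(v) if v else None)
                        for k, v in (meas.cis or {}).items()
                    },
                }
                try:
                    coef, fit = interaction_term_test(
                        cohort, exp_a, exp_b, outcome, population=population
                    )
                    row["interaction_term_p"] = coef.p
                    row["interaction_term_coef"] = coef.estimate
                    row["separation"] = fit.separation_flag
                except EdcassocError as exc:
                    row["interaction_term_error"] = str(exc)
                rows.append(row)
            except EdcassocError as exc:
                rows.append({**base, "error": str(exc)})
    return rows


def _stage_prediction(cohort: Cohort, cfg: AnalysisConfig) -> list[dict]:
    rows = []
    for names in cfg.predictors:
        exps = [_exposure_for(n, cfg.sites) for n in names]
        pred = exps[0] if len(exps) == 1 else combined_predictor(*exps[:2])
        base = {"predictor": " & ".join(names)}
        try:
            m = confusion_matrix(cohort, pred)
            metrics = diagnostic_metrics(m, level=cfg.ci_level)
            row = {
                **base,
                "tp": m.tp, "fn": m.fn, "fp": m.fp, "tn": m.tn,
                "n_excluded": m.n_excluded,
                "notes": list(metrics.notes),
            }
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                est = getattr(metrics, name)
                row[name] = (
                    {"value": est.value, "ci_lower": est.ci_lower,
                     "ci_upper": est.ci_upper, "ci_method": est.ci_method}
                    if est else None
                )
            rows.append(row)
        except EdcassocError as exc:
            rows.append({**base, "error": str(exc)})
    return rows


_STAGES = {
    "summary": _stage_summary,
    "hwe": _stage_hwe,
    "association": _stage_association,
    "severity": _stage_severity,
    "stratified": _stage_stratified,
    "interaction": _stage_interaction,
    "prediction": _stage_prediction,
}


def run_pipeline(config: AnalysisConfig, outdir: "str | None" = None) -> PipelineResult:
    """Run every analysis stage; optionally write the report bundle.

    The bundle contains one ``<stage>.json`` + ``<stage>.tsv`` + ``<stage>.txt``
    per stage plus ``manifest.json`` and, for simulated input, the cohort
    itself as ``cohort.tsv``. Outputs are deterministic (no timestamps) so a
    rerun with the same config and seed is byte-identical.
    """
    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
    else:
        cohort = read_cohort(config.input, sites=config.sites,
                             schema=config.schema or None)
    tables: dict[str, list[dict]] = {}
    errors: dict[str, str] = {}
    for name, stage in _STAGES.items():
        try:
            tables[name] = stage(cohort, config)
        except EdcassocError as exc:
            errors[name] = str(exc)
            tables[name] = []
    manifest = {
        "package": "edcassoc",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.canonical_hash(),
        "n_subjects": len(cohort),
        "n_cases": len(cohort.cases),
        "n_controls": len(cohort.controls),
        "stages": {name: ("error" if name in errors else "ok") for name in _STAGES},
        "errors": errors,
    }
    result = PipelineResult(tables=tables, manifest=manifest, errors=errors)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if config.simulate is not None:
            write_cohort(cohort, str(out / "cohort.tsv"))
        for name, rows in tables.items():
            (out / f"{name}.json").write_text(
                json.dumps(rows, indent=2, sort_keys=True) + "\n"
            )
            _write_tsv(rows, out / f"{name}.tsv")
            (out / f"{name}.txt").write_text(render_table(rows, config.style) + "\n")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return result


def _flatten(row: dict) -> dict:
    flat = {}
    for k, v in row.items():
        if isinstance(v, dict):
            for k2, v2 in v.items():
                flat[f"{k}.{k2}"] = v2 if not isinstance(v2, (dict, list)) else json.dumps(v2)
        elif isinstance(v, list):
            flat[k] = json.dumps(v)
        else:
            flat[k] = v
    return flat


def _write_tsv(rows: list[dict], path: Path) -> None:
    flat = [_flatten(r) for r in rows]
    cols: list[str] = []
    for r in flat:
        for k in r:
            if k not in cols:
                cols.append(k)
    lines = ["\t".join(cols)]
    for r in flat:
        lines.append("\t".join("" if r.get(c) is None else str(r.get(c, "")) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def _fmt(value, style: str) -> str:
    if value is None:
        return "not estimable"
    if isinstance(value, float):
        if math.isnan(value):
            return "not estimable"
        if style == "paper":
            return f"{value:.2f}" if abs(value) >= 0.005 else f"{value:.3f}"
        return f"{value:.6g}"
    if isinstance(value, (dict, list)):
        return json.dumps(value)
    return str(value)


def render_table(rows: list[dict], style: str = "plain") -> str:
    """Render result rows as an aligned text table.

    ``paper`` style mirrors the source tables' rounding (2 decimals, CI
    separator "÷"); ``plain`` keeps 6 significant digits and a dash. Missing
    fields render as "not estimable", never blank.
    """
    if style not in ("paper", "plain"):
        raise ValidationError(f"unknown render style {style!r}")
    if not rows:
        return "(no rows)"
    sep = "÷" if style == "paper" else "-"
    display = []
    for row in rows:
        flat = _flatten(dict(row))
        if all(k in flat for k in ("estimate", "ci_lower", "ci_upper")) and isinstance(
            flat.get("estimate"), (int, float)
        ):
            spec = ".2f" if style == "paper" else ".6g"
            flat["estimate (CI)"] = (
                f"{flat.pop('estimate'):{spec}} "
                f"({flat.pop('ci_lower'):{spec}} {sep} {flat.pop('ci_upper'):{spec}})"
            )
        if isinstance(flat.get("p"), float) and style == "paper":
            flat["p"] = "<0.001" if flat["p"] < 0.001 else f"{flat['p']:.3f}"
        display.append(flat)
    cols: list[str] = []
    for r in display:
        for k in r:
            if k not in cols:
                cols.append(k)
    cells = [[_fmt(r.get(c), style) if c in r else "not estimable" for c in cols]
             for r in display]
    widths = [max(len(c), *(len(row[i]) for row in cells)) for i, c in enumerate(cols)]
    out = ["  ".join(c.ljust(w) for c, w in zip(cols, widths))]
    out.append("  ".join("-" * w for w in widths))
    for row in cells:
        out.append("  ".join(c.ljust(w) for c, w in zip(row, widths)))
    return "\n".join(out)
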