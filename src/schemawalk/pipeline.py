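"""End-to-end orchestration: schema files -> filtered tables -> mapping
evaluation -> coverage, consensus and gap reports.

A run is described by one YAML config (paths are resolved relative to the
config file).  ``run_forward`` produces the coverage table, the aggregate
statistics, the presence-absence matrix and the consensus report;
``run_backward`` produces per-model coverage means, standard-class rates
with the Kruskal-Wallis comparison, the unmapped-property list and the
information-gap complexes.  All machine outputs are full-precision and
byte-deterministic for identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import consensus as consensus_mod
from . import coverage as coverage_mod
from . import gaps as gaps_mod
from .crosswalk import read_sssom, validate_mapping_set, write_sssom
from .exceptions import ConfigError
from .rules_filter import FilterOutcome, apply_exclusion_rules, load_ruleset
from .schema_ingest import load_schema, write_canonical
from .synthetic import (
    SyntheticEnsemble,
    default_synthetic_ruleset,
    synthetic_standard_class_map,
)

log = logging.getLogger("schemawalk")


@dataclass
class RunConfig:
    """One crosswalk-analysis run."""

    source_model: str
    schemas: dict[str, dict[str, str]]  # model -> {path, dialect}
    rulesets: dict[str, str]  # model -> ruleset path
    forward_mappings: list[str] = field(default_factory=list)
    backward_mappings: list[str] = field(default_factory=list)
    cross_mapping: str | None = None
    standard_class_map: str | None = None
    consensus_threshold: int = 3
    rate_aggregation: str = "pooled"
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p):
            return str((base / p).resolve()) if p else p

        cfg = cls(
            source_model=doc.get("source_model", ""),
            schemas={
                m: {"path": resolve(s["path"]), "dialect": s.get("dialect", "canonical")}
                for m, s in (doc.get("schemas") or {}).items()
            },
            rulesets={m: resolve(p) for m, p in (doc.get("rulesets") or {}).items()},
            forward_mappings=[resolve(p) for p in doc.get("forward_mappings") or []],
            backward_mappings=[resolve(p) for p in doc.get("backward_mappings") or []],
            cross_mapping=resolve(doc.get("cross_mapping")),
            standard_class_map=resolve(doc.get("standard_class_map")),
            consensus_threshold=int(doc.get("consensus_threshold", 3)),
            rate_aggregation=doc.get("rate_aggregation", "pooled"),
            output_dir=str(base / doc.get("output_dir", "out")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.source_model:
            raise ConfigError("config: source_model missing")
        if self.source_model not in self.schemas:
            raise ConfigError(
                f"config: source model {self.source_model!r} has no schema entry"
            )
        paths = [s["path"] for s in self.schemas.values()]
        paths += list(self.rulesets.values())
        paths += self.forward_mappings + self.backward_mappings
        if self.cross_mapping:
            paths.append(self.cross_mapping)
        if self.standard_class_map:
            paths.append(self.standard_class_map)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise ConfigError(f"config references missing file(s): {missing}")


def _load_filters(config: RunConfig) -> dict[str, FilterOutcome]:
    filters = {}
    for model, entry in config.schemas.items():
        table = load_schema(entry["path"], entry["dialect"], model)
        rules = load_ruleset(config.rulesets[model]) if model in config.rulesets else []
        outcome = apply_exclusion_rules(table, rules)
        log.info(
            "filter[%s]: %d records -> %d included, %d excluded",
            model,
            len(table),
            len(outcome.included),
            len(outcome.excluded),
        )
        filters[model] = outcome
    return filters


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _test_result_dict(res: coverage_mod.TestResult) -> dict:
    return {
        "method": res.method,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "warnings": list(res.warnings),
        "group_medians": dict(sorted(res.group_medians.items())),
    }


@dataclass
class ForwardResult:
    coverage: coverage_mod.CoverageTable
    chi_squared: coverage_mod.TestResult
    matrix: consensus_mod.PresenceAbsenceMatrix
    consensus: consensus_mod.ConsensusReport
    classification: dict[str, list[tuple[str, str]]]


def run_forward(config: RunConfig) -> ForwardResult:
    """Forward analysis: source model -> target models."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    filters = _load_filters(config)
    src_filter = filters[config.source_model]

    sets = [read_sssom(p) for p in config.forward_mappings]
    for mset in sets:
        if mset.target_model in filters:
            report = validate_mapping_set(mset, src_filter, filters[mset.target_model])
            if not report.ok:
                log.warning(
                    "validate[%s->%s]: %d unknown subj, %d unknown obj, "
                    "%d excluded subj, %d excluded obj, %d uncovered, %d class-level",
                    mset.source_model,
                    mset.target_model,
                    len(report.unknown_subjects),
                    len(report.unknown_objects),
                    len(report.excluded_subjects),
                    len(report.excluded_objects),
                    len(report.uncovered_source_properties),
                    len(report.class_level_objects),
                )

    cells_by_model = {
        s.target_model: coverage_mod.class_coverage(s, src_filter) for s in sets
    }
    class_means = coverage_mod.forward_class_means(list(cells_by_model.values()))
    all_cells = tuple(c for cells in cells_by_model.values() for c in cells)
    table = coverage_mod.CoverageTable(cells=all_cells, class_means=class_means)
    table.write_tsv(outdir / "forward_coverage.tsv")
    log.info("coverage: %d cells across %d target models", len(all_cells), len(sets))

    chi = coverage_mod.chi_squared_mappability(
        coverage_mod.mappability_contingency(cells_by_model)
    )
    matrix = consensus_mod.build_presence_absence(sets, src_filter)
    matrix.write_tsv(outdir / "presence_absence.tsv")
    report = consensus_mod.find_consensus(matrix, config.consensus_threshold)
    classification = consensus_mod.classify_consensus(report)
    log.info(
        "consensus: %d of %d rows at threshold %d",
        report.n_consensus,
        matrix.n_rows,
        config.consensus_threshold,
    )

    _write_json(
        {
            "n_included_source_properties": matrix.n_rows,
            "matched_per_target": matrix.column_sums(),
            "class_means": class_means,
            "chi_squared": _test_result_dict(chi),
        },
        outdir / "forward_aggregate.json",
    )
    _write_json(
        {
            "threshold": report.threshold,
            "n_consensus": report.n_consensus,
            "n_in_all_targets": report.n_in_all_targets,
            "per_class": dict(sorted(report.per_class.items())),
            "per_model_missing": dict(sorted(report.per_model_missing.items())),
            "requirement_breakdown": dict(sorted(report.requirement_breakdown.items())),
            "n_controllable": len(classification["controllable"]),
            "n_descriptive": len(classification["descriptive"]),
            "n_range_unspecified": len(classification["unspecified"]),
            "controllable": sorted(map(list, classification["controllable"])),
            "descriptive": sorted(map(list, classification["descriptive"])),
            "range_unspecified": sorted(map(list, classification["unspecified"])),
        },
        outdir / "consensus.json",
    )
    return ForwardResult(
        coverage=table,
        chi_squared=chi,
        matrix=matrix,
        consensus=report,
        classification=classification,
    )


@dataclass
class BackwardResult:
    coverage: coverage_mod.CoverageTable
    chi_squared: coverage_mod.TestResult
    kruskal_wallis: coverage_mod.TestResult | None
    standard_class_rates: dict[str, dict[str, float]]
    unmapped: gaps_mod.UnmappedProperties
    complexes: list[gaps_mod.GapComplex]
    gap_report: gaps_mod.GapReport


def run_backward(config: RunConfig) -> BackwardResult:
    """Backward analysis: related models -> source model, plus gaps."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    filters = _load_filters(config)

    sets = [read_sssom(p) for p in config.backward_mappings]
    for mset in sets:
        if mset.source_model not in filters:
            raise ConfigError(
                f"backward set from unknown model {mset.source_model!r}"
            )
    cells_by_model = {
        s.source_model: coverage_mod.class_coverage(s, filters[s.source_model])
        for s in sets
    }
    model_means = coverage_mod.backward_model_means(cells_by_model)
    all_cells = tuple(c for cells in cells_by_model.values() for c in cells)
    table = coverage_mod.CoverageTable(cells=all_cells, model_means=model_means)
    table.write_tsv(outdir / "backward_coverage.tsv")

    chi = coverage_mod.chi_squared_mappability(
        coverage_mod.mappability_contingency(cells_by_model)
    )

    kw = None
    std_rates: dict[str, dict[str, float]] = {}
    if config.standard_class_map:
        scm = coverage_mod.load_standard_class_map(config.standard_class_map)
        std_rates = coverage_mod.standard_class_rates(
            cells_by_model, scm, aggregation=config.rate_aggregation
        )
        kw = coverage_mod.kruskal_wallis_classes(
            {m: list(r.values()) for m, r in std_rates.items()}
        )
        log.info("kruskal-wallis: H=%.4f p=%.4g", kw.statistic, kw.p_value)

    unmapped = gaps_mod.collect_unmapped(sets, filters)
    log.info(
        "unmapped: %d of %d analyzed related-model properties",
        len(unmapped),
        unmapped.n_analyzed,
    )
    if config.cross_mapping:
        cross = read_sssom(config.cross_mapping)
    else:
        from .crosswalk import MappingSet

        cross = MappingSet("*", "*", "cross", ())
    complexes = gaps_mod.build_complexes(unmapped, cross)
    gap_report = gaps_mod.summarize_gaps(complexes, n_related_models=len(sets))
    gap_report.write_tsv(outdir / "gap_membership.tsv")

    unmapped_frame = [
        {"model": r.model, "class": r.class_name, "property": r.property_name}
        for r in unmapped
    ]
    import pandas as pd

    pd.DataFrame(unmapped_frame, columns=["model", "class", "property"]).to_csv(
        outdir / "unmapped.tsv", sep="\t", index=False
    )
    _write_json(
        {
            "model_means": {
                m: {"mean_coverage": v[0], "n_classes": v[1]}
                for m, v in sorted(model_means.items())
            },
            "matched_per_model": {
                m: sum(c.m for c in cells) for m, cells in sorted(cells_by_model.items())
            },
            "n_analyzed": unmapped.n_analyzed,
            "n_unmapped": len(unmapped),
            "unmapped_per_model": dict(sorted(unmapped.by_model.items())),
            "standard_class_rates": {
                m: dict(sorted(r.items())) for m, r in sorted(std_rates.items())
            },
            "chi_squared": _test_result_dict(chi),
            "kruskal_wallis": _test_result_dict(kw) if kw else None,
        },
        outdir / "backward_aggregate.json",
    )
    _write_json(
        {
            "n_complexes": gap_report.n_complexes,
            "span_histogram": {str(k): v for k, v in sorted(gap_report.span_histogram.items())},
            "max_span": max(gap_report.span_histogram, default=0),
            "any_full_span_all_required": gap_report.any_full_span_all_required,
            "complexes": [
                {
                    "id": cx.id,
                    "label": cx.label,
                    "span": cx.span,
                    "all_required": cx.all_required,
                    "members": [
                        {
                            "model": ref.model,
                            "class": ref.class_name,
                            "property": ref.property_name,
                            "requirement": req,
                        }
                        for ref, req in cx.members
                    ],
                }
                for cx in complexes
            ],
        },
        outdir / "gap_complexes.json",
    )
    return BackwardResult(
        coverage=table,
        chi_squared=chi,
        kruskal_wallis=kw,
        standard_class_rates=std_rates,
        unmapped=unmapped,
        complexes=complexes,
        gap_report=gap_report,
    )


def write_ensemble(ensemble: SyntheticEnsemble, outdir) -> Path:
    """Materialize a synthetic ensemble as the canonical file formats the
    pipeline consumes, plus a ready-to-run config.  Returns the config path."""
    outdir = Path(outdir)
    (outdir / "schemas").mkdir(parents=True, exist_ok=True)
    (outdir / "mappings").mkdir(exist_ok=True)
    cfg = ensemble.config
    for model, table in ensemble.tables.items():
        write_canonical(table, outdir / "schemas" / f"{model}.tsv")
    for target, mset in ensemble.forward_sets.items():
        write_sssom(mset, outdir / "mappings" / f"forward_{target}.tsv")
    for model, mset in ensemble.backward_sets.items():
        write_sssom(mset, outdir / "mappings" / f"backward_{model}.tsv")
    write_sssom(ensemble.cross_set, outdir / "mappings" / "cross.tsv")

    ruleset = [
        {"category": r.category, "match": r.match, "scope": r.scope}
        for r in default_synthetic_ruleset()
    ]
    with open(outdir / "ruleset.yaml", "w") as fh:
        yaml.safe_dump(ruleset, fh, sort_keys=False)
    scm = synthetic_standard_class_map(ensemble.tables)
    with open(outdir / "standard_classes.yaml", "w") as fh:
        yaml.safe_dump(
            {s: [list(p) for p in pairs] for s, pairs in scm.assignments.items()},
            fh,
            sort_keys=True,
        )
    doc = {
        "source_model": cfg.source_model,
        "consensus_threshold": 3,
        "schemas": {
            m: {"path": f"schemas/{m}.tsv", "dialect": "canonical"} for m in cfg.models
        },
        "rulesets": {m: "ruleset.yaml" for m in cfg.models},
        "forward_mappings": [f"mappings/forward_{t}.tsv" for t in cfg.models[1:]],
        "backward_mappings": [f"mappings/backward_{m}.tsv" for m in cfg.models[1:]],
        "cross_mapping": "mappings/cross.tsv",
        "standard_class_map": "standard_classes.yaml",
        "output_dir": "out",
    }
    config_path = outdir / "run_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path
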