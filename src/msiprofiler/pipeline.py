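"""End-to-end pipeline: read or simulate a cohort, annotate indels, compute
burden profiles and rule evaluations, run the group statistics, and write
a plain TSV/JSON report bundle (no plotting dependency; histograms are
emitted as count-per-bin tables)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import burden as _burden
from .cohort import Cohort, read_mutation_table, write_cohort, write_cohort_summary
from .datasets import COMMON_CRC_GENES
from .errors import ConfigError, EvaluationError, MsiProfilerError
from .model import CohortComparison
from .simulate import (
    SimulationParams,
    generate_cohort,
    generate_reference_fixtures,
    load_reference_fixtures,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline configuration: either input paths or ``simulate=True``."""

    out_dir: str = "msiprofiler_out"
    simulate: bool = False
    seed: int = 0
    input_maf: str | None = None
    input_samples: str | None = None
    fasta_fixtures: str | None = None
    rule_total_k: int = 6
    rule_uncommon_k: int = 2
    rule_hp_indel_k: int = 2
    excluded_genes: Sequence[str] = field(default_factory=lambda: sorted(COMMON_CRC_GENES))
    histogram_max_bin: int = 10
    simulation: Mapping | None = None   # overrides for SimulationParams fields

    def __post_init__(self) -> None:
        if not self.simulate and self.input_maf is None:
            raise ConfigError("config needs either input_maf or simulate: true")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def histogram_counts(per_tumor_counts: Sequence[int], max_bin: int = 10) -> dict[str, int]:
    """Bin a burden vector into counts for bins 0..max_bin plus an overflow
    bin; bin counts always sum to the number of tumors."""
    if any(c < 0 for c in per_tumor_counts):
        raise ValueError("burden counts must be non-negative")
    bins = {str(b): 0 for b in range(max_bin + 1)}
    bins[f">{max_bin}"] = 0
    for c in per_tumor_counts:
        key = str(c) if c <= max_bin else f">{max_bin}"
        bins[key] += 1
    return bins


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MsiProfilerError as exc:
                raise MsiProfilerError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute read/simulate -> annotate -> burden -> rules -> statistics
    and write the report bundle to ``config.out_dir``.

    Returns a manifest dict of written files; raises with a stage-named
    message on any failure.  Byte-identical outputs for identical config
    and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    # ---- acquire cohort and references
    if config.simulate:
        overrides = dict(config.simulation or {})
        params = SimulationParams(seed=config.seed, **overrides)
        cohort, labels = generate_cohort(params)
        write_cohort(cohort, str(out / "cohort.tsv"), str(out / "samples.tsv"))
        with open(out / "truth_labels.tsv", "w") as fh:
            fh.write("tumor_id\ttrue_status\tis_hypermutator\n")
            for lab in labels:
                fh.write(
                    f"{lab.tumor_id}\t{lab.true_status.value}\t{int(lab.is_hypermutator)}\n"
                )
        manifest["cohort"] = "cohort.tsv"
        manifest["samples"] = "samples.tsv"
        manifest["truth_labels"] = "truth_labels.tsv"
    else:
        cohort = _stage("cohort_model")(read_mutation_table)(
            config.input_maf, config.input_samples
        )
    if len(cohort) == 0:
        raise MsiProfilerError("[cohort_model] cohort is empty")

    if config.fasta_fixtures:
        references = load_reference_fixtures(config.fasta_fixtures)
    else:
        references = generate_reference_fixtures(str(out / "reference_fixtures.fasta"))
        manifest["reference_fixtures"] = "reference_fixtures.fasta"

    # ---- fit the comparison model
    rules = [
        _burden.RuleSpec.total(config.rule_total_k),
        _burden.RuleSpec.uncommon(config.rule_uncommon_k, frozenset(config.excluded_genes)),
        _burden.RuleSpec.hp_indel(config.rule_hp_indel_k),
    ]
    model = CohortComparison(
        cohort,
        excluded_genes=config.excluded_genes,
        rules=rules,
        references=references,
    )
    try:
        results = model.fit()
    except EvaluationError as exc:
        raise MsiProfilerError(f"[burden_rules] {exc}") from exc

    # ---- write the bundle
    with open(out / "demography.tsv", "w") as fh:
        _stage("cohort_model")(write_cohort_summary)(cohort, fh)
    manifest["demography"] = "demography.tsv"

    results.gene_frequency_frame().to_csv(out / "gene_frequency.tsv", sep="\t", index=False)
    manifest["gene_frequency"] = "gene_frequency.tsv"
    results.indel_repeat_frame().to_csv(out / "indel_repeat.tsv", sep="\t", index=False)
    manifest["indel_repeat"] = "indel_repeat.tsv"
    results.profile_frame().to_csv(out / "tumor_profiles.tsv", sep="\t", index=False)
    manifest["tumor_profiles"] = "tumor_profiles.tsv"

    with open(out / "rule_evaluations.tsv", "w") as fh:
        fh.write("rule\tK\ttp\tfp\ttn\tfn\tsensitivity\tspecificity\n")
        for rule, ev in results.rule_evaluations.items():
            fh.write(
                f"{rule.name.value}\t{rule.threshold}\t{ev.tp}\t{ev.fp}\t{ev.tn}\t{ev.fn}"
                f"\t{ev.sensitivity:.6f}\t{ev.specificity:.6f}\n"
            )
    manifest["rule_evaluations"] = "rule_evaluations.tsv"

    with open(out / "burden_histograms.tsv", "w") as fh:
        fh.write("metric\tgroup\tbin\tcount\n")
        for metric, summaries in (
            ("total", results.burden),
            ("uncommon", results.uncommon_burden),
        ):
            for g, s in summaries.items():
                for b, c in histogram_counts(
                    s.per_tumor_counts, config.histogram_max_bin
                ).items():
                    fh.write(f"{metric}\t{g}\t{b}\t{c}\n")
    manifest["burden_histograms"] = "burden_histograms.tsv"

    bundle = {
        "burden": {
            g: {
                "n": s.n_tumors,
                "mean": s.mean,
                "sd": s.sd(),
                "totals_by_class": s.totals_by_class,
                "outlier_threshold_3sd": results.thresholds[g],
            }
            for g, s in results.burden.items()
        },
        "uncommon_burden": {
            g: {"mean": s.mean, "sd": s.sd()} for g, s in results.uncommon_burden.items()
        },
        "burden_t_test_p": results.burden_t_test.p_value,
        "gene_frequency": [
            {
                "set": r.name,
                "table": [r.table.a, r.table.b, r.table.c, r.table.d],
                "p_fisher": r.fisher.p_value,
                "p_chi2": r.chi2.p_value,
            }
            for r in results.gene_rows
        ],
        "rules": {
            f"{rule.name.value}_{rule.threshold}": {
                "tp": ev.tp, "fp": ev.fp, "tn": ev.tn, "fn": ev.fn,
                "sensitivity": ev.sensitivity, "specificity": ev.specificity,
            }
            for rule, ev in results.rule_evaluations.items()
        },
        "n_rejected_rows": len(cohort.rejected_rows),
    }
    with open(out / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["results"] = "results.json"

    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    manifest["summary"] = "summary.txt"
    return manifest
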