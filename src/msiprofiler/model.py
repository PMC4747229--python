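"""Model/Results interface over the MSS vs MSI-H comparison.

`CohortComparison` plays the role a model class plays in statsmodels: it
is constructed from data (a :class:`~msiprofiler.cohort.Cohort`, a pair of
DataFrames, or a MAF-like file), holds the analysis configuration (gene
exclusion set, gene sets to tabulate, prediction rules, reference
sequences), and ``fit()`` runs the full comparison, returning a
:class:`CohortComparisonResults` that carries the burden summaries,
outlier thresholds, gene-frequency table with p-values, repeat-indel
table, rule confusion matrices and a printable ``summary()``.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import burden as _burden
from . import repeats as _repeats
from . import stats as _stats
from .cohort import Cohort, read_mutation_table
from .datasets import COMMON_CRC_GENES
from .errors import EvaluationError


class CohortComparison:
    """MSS vs MSI-H mutational-profile comparison model.

    Parameters
    ----------
    cohort
        Labeled cohort; every tumor should carry an MSS or MSI_H label.
    excluded_genes
        Genes excluded from the "uncommon" burden (default: the nine genes
        most commonly mutated in colorectal cancer).
    gene_sets
        Named gene sets for the frequency table; default covers the eleven
        study genes plus the mTOR-pathway and RTK-family sets.
    rules
        MSI-H prediction rules to score; default: total burden >= 6,
        uncommon burden >= 2, homopolymer indels >= 2.
    references
        Gene symbol -> coding sequence, for repeat annotation of indels.
    """

    def __init__(
        self,
        cohort: Cohort,
        *,
        excluded_genes: Iterable[str] = COMMON_CRC_GENES,
        gene_sets: Mapping[str, Iterable[str]] | None = None,
        rules: Sequence[_burden.RuleSpec] | None = None,
        references: Mapping[str, str] | None = None,
    ) -> None:
        self.cohort = cohort
        self.excluded_genes = frozenset(excluded_genes)
        self.gene_sets = gene_sets
        self.rules = list(rules) if rules is not None else [
            _burden.RuleSpec.total(6),
            _burden.RuleSpec.uncommon(2, self.excluded_genes),
            _burden.RuleSpec.hp_indel(2),
        ]
        self.references = dict(references) if references else None

    @classmethod
    def from_dataframe(
        cls, mutations: pd.DataFrame, samples: pd.DataFrame | None = None, **kwargs
    ) -> "CohortComparison":
        """Build from in-memory mutation (and optional samples) tables in
        the MAF-like dialect."""
        mut_buf = io.StringIO(mutations.to_csv(sep="\t", index=False))
        smp_buf = (
            io.StringIO(samples.to_csv(sep="\t", index=False))
            if samples is not None
            else None
        )
        return cls(read_mutation_table(mut_buf, smp_buf), **kwargs)

    @classmethod
    def from_maf(
        cls, mutations_path: str, samples_path: str | None = None, **kwargs
    ) -> "CohortComparison":
        return cls(read_mutation_table(mutations_path, samples_path), **kwargs)

    def fit(self) -> "CohortComparisonResults":
        """Run annotation, burden, rules and statistics; return results."""
        if self.references:
            _repeats.annotate_cohort(self.cohort, self.references)

        total = _burden.cohort_burden(self.cohort)
        uncommon = _burden.cohort_burden(self.cohort, self.excluded_genes)
        thresholds = {
            g: _burden.outlier_threshold(s.mean, s.sd()) for g, s in total.items()
        }
        profiles = [
            _burden.tumor_profile(t, self.excluded_genes) for t in self.cohort
        ]
        truth = {t.id: t.msi_status for t in self.cohort}
        evaluations = {
            rule: _burden.evaluate_rule(profiles, truth, rule) for rule in self.rules
        }
        gene_rows = _stats.gene_frequency_table(self.cohort, self.gene_sets)
        indel_rows = _stats.indel_repeat_table(self.cohort)
        t_result = _stats.two_sample_t(
            total["MSS"].per_tumor_counts, total["MSI_H"].per_tumor_counts
        )
        return CohortComparisonResults(
            model=self,
            burden=total,
            uncommon_burden=uncommon,
            thresholds=thresholds,
            profiles=profiles,
            rule_evaluations=evaluations,
            gene_rows=gene_rows,
            indel_rows=indel_rows,
            burden_t_test=t_result,
        )


class CohortComparisonResults:
    """Fitted comparison: estimates, their tables, and ``summary()``."""

    def __init__(
        self,
        model: CohortComparison,
        burden: dict[str, _burden.BurdenSummary],
        uncommon_burden: dict[str, _burden.BurdenSummary],
        thresholds: dict[str, float],
        profiles: list[_burden.TumorProfile],
        rule_evaluations: dict[_burden.RuleSpec, _burden.RuleEvaluation],
        gene_rows: list[_stats.GeneFrequencyRow],
        indel_rows: list[_stats.IndelRepeatRow],
        burden_t_test: _stats.TestResult,
    ) -> None:
        self.model = model
        self.burden = burden
        self.uncommon_burden = uncommon_burden
        self.thresholds = thresholds
        self.profiles = profiles
        self.rule_evaluations = rule_evaluations
        self.gene_rows = gene_rows
        self.indel_rows = indel_rows
        self.burden_t_test = burden_t_test

    # ------------------------------------------------------------------ tables

    def gene_frequency_frame(self) -> pd.DataFrame:
        rows = [
            {
                "set": r.name,
                "mss_mutated": r.table.c,
                "mss_n": r.table.c + r.table.d,
                "mss_pct": round(100 * r.mss_fraction),
                "msih_mutated": r.table.a,
                "msih_n": r.table.a + r.table.b,
                "msih_pct": round(100 * r.msih_fraction),
                "p_fisher": r.fisher.p_value,
                "p_chi2": r.chi2.p_value,
            }
            for r in self.gene_rows
        ]
        return pd.DataFrame(rows)

    def indel_repeat_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "mss_repeat_indels": r.mss_repeat,
                "mss_indels": r.mss_indels,
                "msih_repeat_indels": r.msih_repeat,
                "msih_indels": r.msih_indels,
                "mss_per_tumor": round(r.mss_per_tumor, 2),
                "msih_per_tumor": round(r.msih_per_tumor, 2),
            }
            for r in self.indel_rows
        ]
        return pd.DataFrame(rows)

    def profile_frame(self) -> pd.DataFrame:
        truth = {t.id: t.msi_status.value for t in self.model.cohort}
        rules = {rule: ev for rule, ev in self.rule_evaluations.items()}
        rows = []
        for p in self.profiles:
            row = {
                "tumor_id": p.tumor_id,
                "total": p.total,
                "uncommon": p.uncommon,
                "hp_indels": p.hp_indels,
                "truth": truth[p.tumor_id],
            }
            for rule in rules:
                row[f"pred_{rule.name.value}_{rule.threshold}"] = int(
                    _burden.predict_msi(p, rule)
                )
            rows.append(row)
        return pd.DataFrame(rows)

    # ----------------------------------------------------------------- summary

    def summary(self) -> str:
        """Plain-text report mirroring the study's table layout."""
        out: list[str] = []
        out.append("MSS vs MSI-H mutational profile comparison")
        out.append("=" * 58)
        for g in ("MSS", "MSI_H"):
            s, u = self.burden[g], self.uncommon_burden[g]
            out.append(
                f"{g:6s} n={s.n_tumors:<4d} burden {s.display()}  "
                f"uncommon {u.display()}  mean+3SD {round(self.thresholds[g], 1):.1f}"
            )
        out.append(
            f"burden t-test (two-sided): p = {self.burden_t_test.p_value:.2g}"
        )
        out.append("")
        out.append("Gene / set      MSS          MSI-H        p (Fisher)  p (chi2)")
        for r in self.gene_rows:
            out.append(
                f"{r.name:15s} {r.table.c:3d} ({round(100 * r.mss_fraction):3d}%)"
                f"    {r.table.a:3d} ({round(100 * r.msih_fraction):3d}%)"
                f"    {r.fisher.p_value:<10.3g}  {r.chi2.p_value:.3g}"
            )
        out.append("")
        out.append("Repeat-context indels (per indel; per tumor)")
        for r in self.indel_rows:
            out.append(
                f"{r.gene:10s} MSS {r.mss_repeat}/{r.mss_indels}"
                f" ({r.mss_per_tumor:.2f}/tumor)   "
                f"MSI-H {r.msih_repeat}/{r.msih_indels}"
                f" ({r.msih_per_tumor:.2f}/tumor)"
            )
        out.append("")
        out.append("MSI-H prediction rules")
        for rule, ev in self.rule_evaluations.items():
            out.append(
                f"{rule.name.value} K={rule.threshold}: "
                f"tp={ev.tp} fp={ev.fp} tn={ev.tn} fn={ev.fn}  {ev.display()}"
            )
        return "\n".join(out)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = {g: s.n_tumors for g, s in self.burden.items()}
        return f"<CohortComparisonResults groups={sizes}>"
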