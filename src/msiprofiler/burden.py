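"""Per-tumor mutation burden, outlier thresholds, MSI-H prediction rules
and the PCR-panel MSI call.

Burden is mutations per tumor over the hotspot panel, counted over the
four variant classes (substitution, deletion, insertion/duplication,
splice).  The "uncommon" burden excludes the nine genes most commonly
mutated in colorectal cancer, which sharpens the MSS/MSI-H contrast: the
common drivers are mutated in both groups, while hypermutation with
defective mismatch repair spreads across the rest of the panel.

Three simple rules predict MSI-H from a tumor's mutation profile:

* ``TOTAL_GE_K``     — total burden >= K (the study used K = 6);
* ``UNCOMMON_GE_K``  — burden outside the 9 common genes >= K (K = 2);
* ``HP_INDEL_GE_K``  — indels in homopolymer/STR context >= K (K = 2,
  i.e. "more than 1").

Each rule is scored against the PCR-assay MSI label as a confusion matrix
with sensitivity and specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .cohort import Cohort, MsiStatus, Tumor, VariantClass
from .datasets import COMMON_CRC_GENES, MONONUCLEOTIDE_LOCI, PENTANUCLEOTIDE_LOCI
from .errors import EvaluationError

ALL_CLASSES = frozenset(VariantClass)


def tumor_burden(
    tumor: Tumor,
    excluded_genes: Iterable[str] = (),
    classes: Iterable[VariantClass] = ALL_CLASSES,
) -> int:
    """Count mutations with gene not excluded and class in ``classes``."""
    excluded = set(excluded_genes)
    classes = {VariantClass(c) for c in classes}
    return sum(
        1
        for m in tumor.mutations
        if m.gene not in excluded and m.variant_class in classes
    )


@dataclass
class BurdenSummary:
    """Per-group burden distribution with per-class totals."""

    group: str
    n_tumors: int
    per_tumor_counts: list[int]
    totals_by_class: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_tumor_counts)

    @property
    def mean(self) -> float:
        return self.total / self.n_tumors

    def sd(self, ddof: int = 1) -> float:
        """Standard deviation of the per-tumor counts (sample SD by default)."""
        n = self.n_tumors
        if n - ddof <= 0:
            return 0.0
        mu = self.mean
        return math.sqrt(sum((c - mu) ** 2 for c in self.per_tumor_counts) / (n - ddof))

    def display(self, ddof: int = 1) -> str:
        """One-decimal 'mean ± SD' as printed in burden tables."""
        return f"{round(self.mean, 1):.1f} ± {round(self.sd(ddof), 1):.1f}"


def cohort_burden(
    cohort: Cohort,
    excluded_genes: Iterable[str] = (),
    classes: Iterable[VariantClass] = ALL_CLASSES,
    groups: Sequence[str] = ("MSS", "MSI_H"),
) -> dict[str, BurdenSummary]:
    """Burden summaries per MSI group.  Raises if a requested group is empty."""
    excluded = set(excluded_genes)
    classes = {VariantClass(c) for c in classes}
    out: dict[str, BurdenSummary] = {}
    for g in groups:
        tumors = cohort.group(g)
        if not tumors:
            raise EvaluationError(f"group {g} has no tumors in cohort {cohort.name!r}")
        counts = [tumor_burden(t, excluded, classes) for t in tumors]
        totals = {c.value: 0 for c in VariantClass}
        for t in tumors:
            for m in t.mutations:
                if m.gene not in excluded and m.variant_class in classes:
                    totals[m.variant_class.value] += 1
        out[g] = BurdenSummary(
            group=g, n_tumors=len(tumors), per_tumor_counts=counts, totals_by_class=totals
        )
    return out


def outlier_threshold(mean: float, sd: float, k: float = 3.0) -> float:
    """Mean + k·SD burden threshold used to flag hypermutated outliers."""
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    return mean + k * sd


class RuleKind(str, Enum):
    TOTAL_GE_K = "TOTAL_GE_K"
    UNCOMMON_GE_K = "UNCOMMON_GE_K"
    HP_INDEL_GE_K = "HP_INDEL_GE_K"


@dataclass(frozen=True)
class RuleSpec:
    """An MSI-H prediction rule: a counted feature and a threshold K (>= K fires)."""

    name: RuleKind
    threshold: int
    excluded_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("rule threshold K must be >= 1")
        if self.name is not RuleKind.UNCOMMON_GE_K and self.excluded_genes:
            raise ValueError("excluded_genes only applies to UNCOMMON_GE_K")

    @classmethod
    def total(cls, k: int = 6) -> "RuleSpec":
        return cls(RuleKind.TOTAL_GE_K, k)

    @classmethod
    def uncommon(cls, k: int = 2, excluded_genes=COMMON_CRC_GENES) -> "RuleSpec":
        return cls(RuleKind.UNCOMMON_GE_K, k, frozenset(excluded_genes))

    @classmethod
    def hp_indel(cls, k: int = 2) -> "RuleSpec":
        return cls(RuleKind.HP_INDEL_GE_K, k)


@dataclass(frozen=True)
class TumorProfile:
    """The three per-tumor counts the rules consume."""

    tumor_id: str
    total: int
    uncommon: int
    hp_indels: int

    def __post_init__(self) -> None:
        if min(self.total, self.uncommon, self.hp_indels) < 0:
            raise ValueError("profile counts must be non-negative")


def tumor_profile(
    tumor: Tumor, excluded_genes: Iterable[str] = COMMON_CRC_GENES
) -> TumorProfile:
    """Profile a tumor; homopolymer indels require prior repeat annotation
    (mutations with ``in_repeat=None`` count as not flagged)."""
    hp = sum(1 for m in tumor.mutations if m.is_indel and m.in_repeat)
    return TumorProfile(
        tumor_id=tumor.id,
        total=tumor_burden(tumor),
        uncommon=tumor_burden(tumor, excluded_genes),
        hp_indels=hp,
    )


def predict_msi(profile: TumorProfile | Mapping[str, int], rule: RuleSpec) -> bool:
    """Apply one rule to one tumor profile."""
    if isinstance(profile, Mapping):
        profile = TumorProfile(
            tumor_id=str(profile.get("tumor_id", "?")),
            total=int(profile["total"]),
            uncommon=int(profile["uncommon"]),
            hp_indels=int(profile["hp_indels"]),
        )
    value = {
        RuleKind.TOTAL_GE_K: profile.total,
        RuleKind.UNCOMMON_GE_K: profile.uncommon,
        RuleKind.HP_INDEL_GE_K: profile.hp_indels,
    }[rule.name]
    return value >= rule.threshold


@dataclass(frozen=True)
class RuleEvaluation:
    """Confusion matrix of a rule against the assay MSI label."""

    rule: RuleSpec
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def display(self) -> str:
        """Two-decimal rendering as printed in the study-style reports."""
        return (
            f"sensitivity = {round(self.sensitivity, 2):.2f}, "
            f"specificity = {round(self.specificity, 2):.2f}"
        )


def evaluate_rule(
    profiles: Iterable[TumorProfile],
    truth: Mapping[str, str | MsiStatus],
    rule: RuleSpec,
) -> RuleEvaluation:
    """Score a rule over labeled tumor profiles.

    ``truth`` maps tumor_id to the assay label; every tumor must be labeled
    MSS or MSI_H and both groups must be present.
    """
    tp = fp = tn = fn = 0
    for p in profiles:
        label = MsiStatus(truth[p.tumor_id])
        if label is MsiStatus.UNKNOWN:
            raise EvaluationError(f"tumor {p.tumor_id} has unknown MSI status")
        positive = predict_msi(p, rule)
        if label is MsiStatus.MSI_H:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    if tp + fn == 0 or tn + fp == 0:
        raise EvaluationError("both MSS and MSI-H tumors are required to score a rule")
    return RuleEvaluation(rule=rule, tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_rule_on_cohort(cohort: Cohort, rule: RuleSpec) -> RuleEvaluation:
    excluded = rule.excluded_genes or COMMON_CRC_GENES
    profiles = [tumor_profile(t, excluded) for t in cohort]
    truth = {t.id: t.msi_status for t in cohort}
    return evaluate_rule(profiles, truth, rule)


@dataclass(frozen=True)
class MsiAssayResult:
    """Locus-level PCR-panel result and the derived MSS/MSI-H call."""

    locus_calls: Mapping[str, str]  # locus -> "stable" / "unstable"
    call: MsiStatus

    @property
    def n_unstable_mono(self) -> int:
        return sum(
            1 for l in MONONUCLEOTIDE_LOCI if self.locus_calls[l] == "unstable"
        )


def msi_assay_call(locus_calls: Mapping[str, str]) -> MsiAssayResult:
    """MSI-H iff >= 2 of the 5 mononucleotide loci show novel allele lengths.

    The two pentanucleotide identity-control loci are recorded when present
    but never counted.  A missing mononucleotide locus is an input error.
    """
    missing = [l for l in MONONUCLEOTIDE_LOCI if l not in locus_calls]
    if missing:
        raise EvaluationError(f"missing mononucleotide loci: {missing}")
    for locus, call in locus_calls.items():
        if call not in ("stable", "unstable"):
            raise EvaluationError(f"locus {locus}: call must be stable/unstable, got {call!r}")
    n_unstable = sum(
        1 for l in MONONUCLEOTIDE_LOCI if locus_calls[l] == "unstable"
    )
    call = MsiStatus.MSI_H if n_unstable >= 2 else MsiStatus.MSS
    kept = {
        l: locus_calls[l]
        for l in (*MONONUCLEOTIDE_LOCI, *PENTANUCLEOTIDE_LOCI)
        if l in locus_calls
    }
    return MsiAssayResult(locus_calls=kept, call=call)
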