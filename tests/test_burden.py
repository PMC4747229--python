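"""Burden computation, outlier thresholds, prediction rules, MSI assay call."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiprofiler.burden import (
    RuleSpec,
    TumorProfile,
    cohort_burden,
    evaluate_rule,
    msi_assay_call,
    outlier_threshold,
    predict_msi,
    tumor_burden,
    tumor_profile,
)
from msiprofiler.cohort import Cohort, MsiStatus, Mutation, Tumor, VariantClass
from msiprofiler.datasets import COMMON_CRC_GENES, MONONUCLEOTIDE_LOCI
from msiprofiler.errors import EvaluationError


def _tumor(tid, genes, status=MsiStatus.MSS, vclass=VariantClass.SUBSTITUTION):
    t = Tumor(id=tid, msi_status=status)
    for i, g in enumerate(genes):
        t.add_mutation(Mutation(tid, g, hgvs_c=f"c.{100 + i}A>T", variant_class=vclass))
    return t


def test_tumor_burden_counts_and_exclusion():
    t = _tumor("T1", [f"G{i}" for i in range(14)])
    assert tumor_burden(t) == 14
    t2 = _tumor("T2", ["KRAS", "TP53"])
    assert tumor_burden(t2, COMMON_CRC_GENES) == 0


def test_tumor_burden_partition_additivity():
    genes = ["APC", "KRAS", "PTEN", "EGFR", "MET", "TP53"]
    t = _tumor("T1", genes)
    half = set(genes[:3])
    rest = set(genes[3:])
    total = tumor_burden(t)
    assert total == len(genes)
    # excluding a gene set leaves exactly the complement's burden
    assert tumor_burden(t, half) == len(rest)
    assert tumor_burden(t, half) + tumor_burden(t, rest) == total


def test_cohort_burden_means_match_printed_arithmetic():
    # distribute the printed per-class totals over the printed group sizes
    def build(group, n, totals, start):
        tumors = [Tumor(id=f"{group}{i}", msi_status=MsiStatus(group)) for i in range(n)]
        i = start
        for vclass, count in totals.items():
            for j in range(count):
                t = tumors[j % n]
                t.add_mutation(
                    Mutation(t.id, f"G{i}", hgvs_c=f"c.{i}A>T",
                             variant_class=VariantClass(vclass))
                )
                i += 1
        return tumors

    mss_totals = {"substitution": 229, "deletion": 33,
                  "insertion_duplication": 3, "splice": 4}
    msih_totals = {"substitution": 92, "deletion": 12,
                   "insertion_duplication": 3, "splice": 1}
    cohort = Cohort(
        tumors=build("MSS", 113, mss_totals, 0) + build("MSI_H", 29, msih_totals, 10_000)
    )
    summaries = cohort_burden(cohort)
    assert summaries["MSS"].total == 269
    assert summaries["MSI_H"].total == 108
    assert round(summaries["MSS"].mean, 1) == 2.4
    assert round(summaries["MSI_H"].mean, 1) == 3.7
    assert summaries["MSS"].totals_by_class["deletion"] == 33
    assert summaries["MSI_H"].totals_by_class["substitution"] == 92


def test_cohort_burden_degenerate_and_missing_group():
    cohort = Cohort(tumors=[_tumor("A", ["X"], MsiStatus.MSS),
                            _tumor("B", ["X"], MsiStatus.MSS)])
    with pytest.raises(EvaluationError):
        cohort_burden(cohort)  # MSI_H group empty
    only = cohort_burden(cohort, groups=("MSS",))
    assert only["MSS"].mean == 1.0
    assert only["MSS"].sd() == 0.0


@pytest.mark.parametrize(
    "mean, sd, k, expected",
    [(2.4, 1.6, 3, 7.2), (3.7, 2.2, 3, 10.3), (5.0, 1.3, 0, 5.0)],
)
def test_outlier_threshold(mean, sd, k, expected):
    assert outlier_threshold(mean, sd, k) == pytest.approx(expected)


@pytest.mark.parametrize(
    "profile, rule, expected",
    [
        (TumorProfile("x", 14, 5, 0), RuleSpec.total(6), True),
        (TumorProfile("x", 5, 5, 0), RuleSpec.total(6), False),
        (TumorProfile("x", 6, 0, 0), RuleSpec.total(6), True),   # boundary
        (TumorProfile("x", 3, 2, 0), RuleSpec.uncommon(2), True),
        (TumorProfile("x", 3, 1, 0), RuleSpec.uncommon(2), False),
        (TumorProfile("x", 3, 0, 2), RuleSpec.hp_indel(2), True),
        (TumorProfile("x", 3, 0, 1), RuleSpec.hp_indel(2), False),
    ],
)
def test_predict_msi(profile, rule, expected):
    assert predict_msi(profile, rule) is expected


def _profiles(n_pos_msih, n_msih, n_pos_mss, n_mss, rule):
    """Profiles engineered so exactly the requested counts fire the rule."""
    key = {"TOTAL_GE_K": "total", "UNCOMMON_GE_K": "uncommon",
           "HP_INDEL_GE_K": "hp_indels"}[rule.name.value]
    profiles, truth = [], {}
    for i in range(n_msih):
        v = rule.threshold if i < n_pos_msih else rule.threshold - 1
        kw = {"total": v, "uncommon": 0, "hp_indels": 0}
        kw[key] = v
        kw["total"] = max(kw["total"], v)
        profiles.append(TumorProfile(f"H{i}", kw["total"], kw["uncommon"], kw["hp_indels"]))
        truth[f"H{i}"] = "MSI_H"
    for i in range(n_mss):
        v = rule.threshold if i < n_pos_mss else 0
        kw = {"total": v, "uncommon": 0, "hp_indels": 0}
        kw[key] = v
        kw["total"] = max(kw["total"], v)
        profiles.append(TumorProfile(f"S{i}", kw["total"], kw["uncommon"], kw["hp_indels"]))
        truth[f"S{i}"] = "MSS"
    return profiles, truth


def test_evaluate_rule_printed_confusion_fractions():
    rule = RuleSpec.uncommon(2)
    profiles, truth = _profiles(13, 29, 1, 113, rule)
    ev = evaluate_rule(profiles, truth, rule)
    assert (ev.tp, ev.fn, ev.fp, ev.tn) == (13, 16, 1, 112)
    assert ev.sensitivity == pytest.approx(13 / 29)
    assert ev.specificity == pytest.approx(112 / 113)
    assert ev.display() == "sensitivity = 0.45, specificity = 0.99"

    rule = RuleSpec.hp_indel(2)
    profiles, truth = _profiles(3, 29, 0, 113, rule)
    ev = evaluate_rule(profiles, truth, rule)
    assert ev.display() == "sensitivity = 0.10, specificity = 1.00"


def test_evaluate_rule_perfect_classifier():
    rule = RuleSpec.total(6)
    profiles, truth = _profiles(5, 5, 0, 7, rule)
    ev = evaluate_rule(profiles, truth, rule)
    assert (ev.sensitivity, ev.specificity) == (1.0, 1.0)
    assert ev.tp + ev.fp + ev.tn + ev.fn == 12


def test_evaluate_rule_requires_both_groups():
    rule = RuleSpec.total(6)
    profiles, truth = _profiles(2, 4, 0, 0, rule)
    with pytest.raises(EvaluationError):
        evaluate_rule(profiles, truth, rule)


@given(
    counts=st.lists(
        st.tuples(st.integers(0, 12), st.integers(0, 6), st.integers(0, 4),
                  st.booleans()),
        min_size=4, max_size=40,
    )
)
@settings(max_examples=60, deadline=None)
def test_rule_monotonicity_in_threshold(counts):
    """Raising K never increases sensitivity, never decreases specificity."""
    if not any(c[3] for c in counts) or all(c[3] for c in counts):
        counts = counts + [(0, 0, 0, True), (0, 0, 0, False)]
    profiles = [
        TumorProfile(f"T{i}", t + u, u, h) for i, (t, u, h, _) in enumerate(counts)
    ]
    truth = {f"T{i}": ("MSI_H" if pos else "MSS")
             for i, (_, _, _, pos) in enumerate(counts)}
    for maker in (RuleSpec.total, RuleSpec.uncommon, RuleSpec.hp_indel):
        evals = [evaluate_rule(profiles, truth, maker(k)) for k in range(1, 8)]
        for lo, hi in itertools.pairwise(evals):
            assert hi.sensitivity <= lo.sensitivity
            assert hi.specificity >= lo.specificity
        for ev in evals:
            assert 0.0 <= ev.sensitivity <= 1.0
            assert 0.0 <= ev.specificity <= 1.0
            assert ev.tp + ev.fp + ev.tn + ev.fn == len(profiles)


def test_tumor_profile_uses_annotation_flags():
    t = Tumor(id="T1", msi_status=MsiStatus.MSI_H)
    m1 = Mutation("T1", "PTEN", "c.800delA", variant_class=VariantClass.DELETION)
    m1.in_repeat = True
    m2 = Mutation("T1", "PTEN", "c.974T>G", variant_class=VariantClass.SUBSTITUTION)
    m3 = Mutation("T1", "APC", "c.50delG", variant_class=VariantClass.DELETION)  # unannotated
    for m in (m1, m2, m3):
        t.add_mutation(m)
    p = tumor_profile(t)
    assert (p.total, p.uncommon, p.hp_indels) == (3, 2, 1)


# ------------------------------------------------------------- MSI assay

def _calls(unstable=()):
    calls = {l: "stable" for l in MONONUCLEOTIDE_LOCI}
    calls.update({l: "unstable" for l in unstable})
    calls["Penta C"] = "stable"
    calls["Penta D"] = "stable"
    return calls


def test_msi_assay_call_two_or_more_loci():
    assert msi_assay_call(_calls(["BAT-25", "NR-21"])).call is MsiStatus.MSI_H
    assert msi_assay_call(_calls()).call is MsiStatus.MSS
    assert msi_assay_call(_calls(["BAT-26"])).call is MsiStatus.MSS


def test_msi_assay_pentanucleotide_loci_never_count():
    calls = _calls(["BAT-25"])
    calls["Penta C"] = "unstable"
    calls["Penta D"] = "unstable"
    result = msi_assay_call(calls)
    assert result.call is MsiStatus.MSS
    assert result.n_unstable_mono == 1


def test_msi_assay_missing_locus_is_error():
    calls = _calls()
    del calls["MONO-27"]
    with pytest.raises(EvaluationError, match="MONO-27"):
        msi_assay_call(calls)
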