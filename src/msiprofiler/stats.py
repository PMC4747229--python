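"""Exact and asymptotic 2x2 association tests and the cohort comparison tables.

The group comparisons of the analysis are 2x2 tables (MSI-H/MSS x feature
present/absent) tested with the two-sided Fisher exact test or the Pearson
chi-square test without continuity correction, plus a two-sample Student
t-test for burden vectors.  No multiple-testing correction is applied
anywhere; the analysis is explicitly exploratory.

The two-sided Fisher p-value follows the point-probability convention:
with margins fixed, sum the hypergeometric probabilities of every table
whose point probability does not exceed the observed one, allowing a
1 + 1e-7 relative slack to absorb floating-point ties.  The summation runs
in log space via the hypergeometric log-pmf.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

from .cohort import Cohort
from .datasets import COMMON_CRC_GENES, MTOR_GENES, RTK_GENES
from .errors import ConfigError, EvaluationError

logger = logging.getLogger(__name__)

#: relative slack when comparing point probabilities (absorbs float ties)
_FISHER_TIE_SLACK = 1e-7


class TestMethod(str, Enum):
    FISHER = "fisher_two_sided"
    CHI_SQUARE = "chi_square"
    T_STUDENT = "t_student"


@dataclass(frozen=True)
class TestResult:
    method: TestMethod
    p_value: float
    statistic: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups (MSI-H, MSS), columns = feature present/absent."""

    a: int  # group 1, present
    b: int  # group 1, absent
    c: int  # group 2, present
    d: int  # group 2, absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @classmethod
    def from_group_counts(cls, k1: int, n1: int, k2: int, n2: int) -> "ContingencyTable2x2":
        """Build from feature-positive counts k out of group sizes n."""
        return cls(k1, n1 - k1, k2, n2 - k2)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> np.ndarray:
        r1, r2, c1, c2 = self.margins
        n = self.n
        return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]], dtype=float) / n

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _degenerate(method: TestMethod, why: str) -> TestResult:
    warnings.warn(f"degenerate 2x2 table ({why}); returning p = 1", stacklevel=3)
    return TestResult(method=method, p_value=1.0, statistic=None, degenerate=True)


def fisher_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test (point-probability method).

    Conditions on all margins; p is the sum of hypergeometric point
    probabilities <= the observed one x (1 + 1e-7), accumulated in log
    space.  A zero margin makes every admissible table identical and
    returns the degenerate p = 1 with a warning.
    """
    r1, r2, c1, c2 = table.margins
    n = table.n
    if 0 in (r1, r2, c1, c2):
        return _degenerate(TestMethod.FISHER, "zero margin")
    support = np.arange(max(0, r1 - c2), min(r1, c1) + 1)
    logpmf = sps.hypergeom.logpmf(support, n, c1, r1)
    log_obs = sps.hypergeom.logpmf(table.a, n, c1, r1)
    keep = logpmf <= log_obs + np.log1p(_FISHER_TIE_SLACK)
    p = float(np.exp(logsumexp(logpmf[keep])))
    return TestResult(method=TestMethod.FISHER, p_value=min(p, 1.0))


def chi_square(table: ContingencyTable2x2, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, upper-tail p.

    No continuity correction by default.  Any zero expected cell makes the
    statistic undefined; a degenerate p = 1 is returned with a warning.
    """
    expected = table.expected()
    if np.any(expected == 0):
        return _degenerate(TestMethod.CHI_SQUARE, "zero expected cell")
    observed = table.as_array().astype(float)
    diff = np.abs(observed - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(method=TestMethod.CHI_SQUARE, p_value=p, statistic=stat)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sided two-sample Student t-test (pooled variance; Welch optional).

    Degenerate zero-variance input: equal means give p = 1; unequal means
    give p = 0 (the difference is then certain under the model), both with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise EvaluationError("each sample needs length >= 2 for a t-test")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return _degenerate(TestMethod.T_STUDENT, "zero variance, equal means")
        warnings.warn("zero variance with unequal means; p -> 0 convention")
        return TestResult(TestMethod.T_STUDENT, p_value=0.0, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        TestMethod.T_STUDENT, p_value=float(res.pvalue), statistic=float(res.statistic)
    )


DEFAULT_GENE_SETS: dict[str, frozenset[str]] = {
    **{g: frozenset({g}) for g in sorted(COMMON_CRC_GENES | {"AKT1", "PTEN"})},
    "mTOR": MTOR_GENES,
    "RTK": RTK_GENES,
}


@dataclass(frozen=True)
class GeneFrequencyRow:
    name: str
    table: ContingencyTable2x2     # rows MSI-H, MSS; columns mutated / not
    fisher: TestResult
    chi2: TestResult

    @property
    def msih_fraction(self) -> float:
        return self.table.a / (self.table.a + self.table.b)

    @property
    def mss_fraction(self) -> float:
        return self.table.c / (self.table.c + self.table.d)

    def display(self) -> str:
        """Counts with integer percentages, as printed in frequency tables."""
        return (
            f"{self.name}\t{self.table.c} ({round(100 * self.mss_fraction)}%)"
            f"\t{self.table.a} ({round(100 * self.msih_fraction)}%)"
            f"\t{self.fisher.p_value:.3g}"
        )


def gene_frequency_table(
    cohort: Cohort,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    known_genes: Iterable[str] | None = None,
) -> list[GeneFrequencyRow]:
    """Tumor-level mutation frequency per gene or gene set, MSI-H vs MSS.

    A tumor counts once per set regardless of how many of its mutations
    fall in the set (pathway membership, not mutation multiplicity).  Both
    Fisher and chi-square p-values are attached; no multiple-testing
    correction is applied.
    """
    gene_sets = dict(gene_sets) if gene_sets is not None else dict(DEFAULT_GENE_SETS)
    if known_genes is not None:
        known = set(known_genes)
        for name, genes in gene_sets.items():
            unknown = set(genes) - known
            if unknown:
                raise ConfigError(f"gene set {name!r} has unknown symbols: {sorted(unknown)}")

    msih = cohort.group("MSI_H")
    mss = cohort.group("MSS")
    if not msih or not mss:
        raise EvaluationError("gene_frequency_table needs both MSS and MSI-H tumors")

    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes)
        k1 = sum(1 for t in msih if t.mutated_genes() & genes)
        k2 = sum(1 for t in mss if t.mutated_genes() & genes)
        table = ContingencyTable2x2.from_group_counts(k1, len(msih), k2, len(mss))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                GeneFrequencyRow(
                    name=name, table=table, fisher=fisher_two_sided(table),
                    chi2=chi_square(table),
                )
            )
    return rows


@dataclass(frozen=True)
class IndelRepeatRow:
    gene: str
    # per group: (repeat-involving indels, total indels), mutation level
    mss_repeat: int
    mss_indels: int
    msih_repeat: int
    msih_indels: int
    mss_per_tumor: float
    msih_per_tumor: float


def indel_repeat_table(
    cohort: Cohort, genes: Sequence[str] | None = None
) -> list[IndelRepeatRow]:
    """Per-gene tallies of repeat-context indels, MSS vs MSI-H.

    Mutation-level ratio: repeat-involving indels / total indels.
    Per-tumor rate: repeat-involving indels / group size.  Requires repeat
    annotation (``in_repeat``) to have been computed; unannotated indels
    count toward the denominator only.  Ends with a Total row; genes not
    listed are pooled under "Others".
    """
    msih = cohort.group("MSI_H")
    mss = cohort.group("MSS")
    n_msih, n_mss = len(msih), len(mss)

    def tally(tumors, gene_filter):
        total = repeat = 0
        for t in tumors:
            for m in t.mutations:
                if m.is_indel and gene_filter(m.gene):
                    total += 1
                    repeat += bool(m.in_repeat)
        return repeat, total

    if genes is None:
        seen = {m.gene for m in cohort.mutations if m.is_indel}
        default = ["APC", "PIK3CA", "PTEN", "TP53"]
        genes = [g for g in default if g in seen] or sorted(seen)

    rows = []
    for g in genes:
        mr, mi = tally(mss, lambda x: x == g)
        hr, hi = tally(msih, lambda x: x == g)
        rows.append(
            IndelRepeatRow(
                g, mr, mi, hr, hi,
                mr / n_mss if n_mss else 0.0,
                hr / n_msih if n_msih else 0.0,
            )
        )
    named = set(genes)
    mr, mi = tally(mss, lambda x: x not in named)
    hr, hi = tally(msih, lambda x: x not in named)
    rows.append(
        IndelRepeatRow(
            "Others", mr, mi, hr, hi,
            mr / n_mss if n_mss else 0.0,
            hr / n_msih if n_msih else 0.0,
        )
    )
    mr, mi = tally(mss, lambda x: True)
    hr, hi = tally(msih, lambda x: True)
    rows.append(
        IndelRepeatRow(
            "Total", mr, mi, hr, hi,
            mr / n_mss if n_mss else 0.0,
            hr / n_msih if n_msih else 0.0,
        )
    )
    return rows
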