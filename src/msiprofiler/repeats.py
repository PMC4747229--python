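"""Homopolymer / short-tandem-repeat context annotation for coding indels.

Replication slippage in tumors with defective mismatch repair concentrates
insertion/deletion mutations in tandem repeats of 1–6 bp units.  Given a
parsed indel and the reference coding sequence, :func:`annotate_repeat`
decides whether the inserted/deleted bases are a whole number of copies of
some unit whose maximal tandem run in the reference has at least two
copies, and reports that run.

Conventions:

* The reported ``unit`` is the smallest repeating unit, written in the
  phase of the maximal run as it appears in the reference (so a
  ``TACTTACT`` block annotates as unit ``TACT`` x 2, and a ``TT``
  duplication as unit ``T`` x 2).  ``unit_canonical`` gives the
  lexicographically minimal rotation for phase-independent comparisons.
* ``copies`` counts unit copies in the *reference* run (deleted copies are
  part of the reference; inserted copies are not).
* Coordinates in :class:`RepeatAnnotation` are 1-based inclusive coding
  positions, matching HGVS; internally everything is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError, ReferenceMismatchError
from .hgvs import ChangeKind, CodingChange

MAX_UNIT = 6


def canonical_rotation(unit: str) -> str:
    """Lexicographically minimal rotation of a repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def smallest_period(s: str) -> int:
    """Length of the smallest unit u with s = u * k."""
    n = len(s)
    for L in range(1, n + 1):
        if n % L == 0 and s == s[:L] * (n // L):
            return L
    return n


@dataclass(frozen=True)
class RepeatAnnotation:
    in_repeat: bool
    unit: str = ""
    copies: int = 0
    run_start: int = 0   # 1-based inclusive, 0 when not in a repeat
    run_end: int = 0
    note: str = ""

    @property
    def unit_canonical(self) -> str:
        return canonical_rotation(self.unit) if self.unit else ""

    def label(self) -> str:
        """Human-readable context like ``(A)6`` / ``(TACT)2``."""
        if not self.in_repeat:
            return ""
        return f"({self.unit}){self.copies}"


def _extend_run(seq: str, lo: int, hi: int, unit: str) -> tuple[int, int]:
    """Extend the 0-based half-open window [lo, hi) by whole in-phase copies
    of ``unit`` on both sides; the window length must be a multiple of
    len(unit) on entry."""
    L = len(unit)
    while lo - L >= 0 and seq[lo - L : lo] == unit:
        lo -= L
    while hi + L <= len(seq) and seq[hi : hi + L] == unit:
        hi += L
    return lo, hi


def annotate_repeat(change: CodingChange, coding_sequence: str) -> RepeatAnnotation:
    """Annotate an indel for tandem-repeat context against a coding sequence.

    ``in_repeat`` is true iff the inserted/deleted sequence equals k >= 1
    copies of some unit u (1 <= |u| <= 6) and the maximal reference run of
    tandem u-copies containing (del/dup) or flanking (ins) the change has
    at least 2 copies.  Among qualifying unit lengths the smallest is
    reported, which makes the unit of a homopolymer-slippage event the
    single repeated base.

    Substitutions (and delins) are outside the contract and raise
    :class:`ContractError`; a deletion whose stated bases disagree with the
    reference raises :class:`ReferenceMismatchError`.
    """
    seq = coding_sequence.upper()
    if change.kind in (ChangeKind.SUB, ChangeKind.DELINS):
        raise ContractError(
            f"annotate_repeat expects del/dup/ins, got {change.kind.value}"
        )
    if change.end > len(seq):
        raise ContractError(
            f"change {change.start}_{change.end} outside coding sequence "
            f"of length {len(seq)}"
        )

    if change.kind in (ChangeKind.DEL, ChangeKind.DUP):
        lo, hi = change.start - 1, change.end  # 0-based half-open span
        ref = seq[lo:hi]
        if change.ref_seq and change.ref_seq != ref:
            raise ReferenceMismatchError(
                f"{change.kind.value} states {change.ref_seq!r} but reference "
                f"has {ref!r} at {change.start}_{change.end}"
            )
        affected = ref
    else:  # insertion between the two flanking positions
        lo = hi = change.start  # insertion point, 0-based
        affected = change.alt_seq

    best: RepeatAnnotation | None = None
    n = len(affected)
    for L in range(1, min(MAX_UNIT, n) + 1):
        if n % L != 0:
            continue
        unit = affected[:L]
        if affected != unit * (n // L):
            continue
        if change.kind is ChangeKind.INS:
            # run must be in phase with the insertion point on either side
            rlo, rhi = _extend_run(seq, lo, hi, unit)
        else:
            rlo, rhi = _extend_run(seq, lo, hi, unit)
        copies = (rhi - rlo) // L
        if copies >= 2:
            note = ""
            if n > L:
                note = (
                    f"change is {n // L} copies of unit {unit!r}; whole-change "
                    f"unit {affected!r} is an equally valid reading"
                )
            run_unit = seq[rlo : rlo + L] if rhi > rlo else unit
            return RepeatAnnotation(
                in_repeat=True,
                unit=run_unit,
                copies=copies,
                run_start=rlo + 1,
                run_end=rhi,
                note=note,
            )
        if best is None or copies > best.copies:
            best = RepeatAnnotation(
                in_repeat=False, unit="", copies=copies, run_start=0, run_end=0
            )
    if best is None:  # e.g. inserted sequence longer than 6 with no sub-unit
        best = RepeatAnnotation(in_repeat=False, copies=1)
    return best


def annotate_cohort(cohort, references: dict[str, str]) -> int:
    """Annotate every parseable indel of a cohort in place.

    ``references`` maps gene symbol to coding sequence.  Mutations in genes
    without a reference, or whose HGVS does not parse to an indel, keep
    ``in_repeat=None``.  Returns the number of mutations annotated.
    """
    from .hgvs import parse_hgvs_c

    n_done = 0
    for tumor in cohort:
        for m in tumor.mutations:
            if not m.is_indel or not m.hgvs_c or m.gene not in references:
                continue
            try:
                change = parse_hgvs_c(m.hgvs_c)
                ann = annotate_repeat(change, references[m.gene])
            except (ContractError, ReferenceMismatchError, ValueError):
                continue
            m.in_repeat = ann.in_repeat
            m.repeat_unit = ann.unit
            m.repeat_copies = ann.copies
            n_done += 1
    return n_done
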