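"""Parsing of the HGVS subset used in hotspot-panel reports.

Supported coding (c.) constructs: substitutions ``c.697C>T``, deletions
``c.800delA`` / ``c.954_957del``, duplications ``c.531_532dupTT``,
insertions ``c.100_101insTA`` and delins.  Intronic offsets (``c.88+1``),
UTR positions (``c.-12``, ``c.*34``) and inversions are rejected
explicitly — hotspot panels report coding changes only.

Protein (p.) strings are consulted for exactly one number: the ``fs*N``
frameshift annotation, read as the count of foreign amino acids translated
before the new reading frame hits a stop codon (a candidate neoepitope
length).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .errors import HgvsParseError

NUCLEOTIDES = "ACGT"


class ChangeKind(str, Enum):
    SUB = "sub"
    DEL = "del"
    DUP = "dup"
    INS = "ins"
    DELINS = "delins"


@dataclass(frozen=True)
class CodingChange:
    """A parsed HGVS c. change on 1-based inclusive coding coordinates."""

    kind: ChangeKind
    start: int
    end: int
    ref_seq: str = ""   # empty for ins, or when HGVS omits the deleted bases
    alt_seq: str = ""   # empty for del/dup

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise HgvsParseError(
                f"invalid coding range {self.start}_{self.end} (need 1 <= start <= end)"
            )
        span = self.end - self.start + 1
        if self.kind in (ChangeKind.DEL, ChangeKind.DUP) and self.ref_seq:
            if len(self.ref_seq) != span:
                raise HgvsParseError(
                    f"{self.kind.value} sequence {self.ref_seq!r} does not span "
                    f"{self.start}_{self.end}"
                )
        if self.kind is ChangeKind.SUB and (
            span != 1 or len(self.ref_seq) != 1 or len(self.alt_seq) != 1
        ):
            raise HgvsParseError("substitution must have length-1 ref and alt")
        if self.kind is ChangeKind.INS and span != 2:
            raise HgvsParseError(
                "insertion coordinates must be the two flanking positions"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


_POSITION = re.compile(r"^\d+$")
_BODY = re.compile(
    r"^(?P<start>[^_]+)(?:_(?P<end>[^_a-z]+))?"
    r"(?:(?P<op>delins|del|dup|ins|inv)(?P<seq>[A-Za-z]*)"
    r"|(?P<ref>[A-Za-z])>(?P<alt>[A-Za-z]))$"
)


def _parse_position(token: str, text: str) -> int:
    if not _POSITION.match(token):
        raise HgvsParseError(
            f"unsupported position token {token!r} in {text!r} "
            "(intronic/UTR offsets are not supported)"
        )
    return int(token)


def _check_seq(seq: str, text: str) -> str:
    seq = seq.upper()
    if any(b not in NUCLEOTIDES for b in seq):
        bad = next(b for b in seq if b not in NUCLEOTIDES)
        raise HgvsParseError(f"invalid nucleotide {bad!r} in {text!r}")
    return seq


def parse_hgvs_c(text: str) -> CodingChange:
    """Parse an HGVS coding-DNA string into a :class:`CodingChange`.

    Raises :class:`HgvsParseError` naming the offending token for anything
    outside the supported subset.
    """
    if not isinstance(text, str) or not text.startswith("c."):
        raise HgvsParseError(f"not an HGVS coding string (must start with 'c.'): {text!r}")
    body = text[2:].strip()
    m = _BODY.match(body)
    if m is None:
        raise HgvsParseError(f"cannot parse HGVS body {body!r} in {text!r}")

    start = _parse_position(m.group("start"), text)
    end = _parse_position(m.group("end"), text) if m.group("end") else start

    if m.group("op"):
        op = m.group("op")
        seq = _check_seq(m.group("seq") or "", text)
        if op == "inv":
            raise HgvsParseError(f"unsupported construct 'inv' in {text!r}")
        if op == "del":
            return CodingChange(ChangeKind.DEL, start, end, ref_seq=seq)
        if op == "dup":
            return CodingChange(ChangeKind.DUP, start, end, ref_seq=seq)
        if op == "ins":
            if not seq:
                raise HgvsParseError(f"insertion without sequence in {text!r}")
            return CodingChange(ChangeKind.INS, start, end, alt_seq=seq)
        if op == "delins":
            if not seq:
                raise HgvsParseError(f"delins without sequence in {text!r}")
            return CodingChange(ChangeKind.DELINS, start, end, alt_seq=seq)

    ref = _check_seq(m.group("ref"), text)
    alt = _check_seq(m.group("alt"), text)
    return CodingChange(ChangeKind.SUB, start, end, ref_seq=ref, alt_seq=alt)


_FRAMESHIFT = re.compile(r"fs(?:\*|Ter)(?P<n>\d+|\?)?$")
_PROTEIN = re.compile(r"^p\.\(?(?P<body>.+?)\)?$")


def foreign_peptide_length(hgvs_p: str) -> int | None:
    """Number of foreign amino acids encoded by a frameshift, from ``fs*N``.

    Returns ``N`` for ``fs*N`` annotations, 0 for nonsense (``Ter``/``*``)
    and missense changes (no foreign residues are translated), and ``None``
    when the string is a frameshift whose extent is unknown (``fs``,
    ``fs*?``) — unknown is distinct from zero.
    """
    if not isinstance(hgvs_p, str):
        raise HgvsParseError(f"not an HGVS protein string: {hgvs_p!r}")
    m = _PROTEIN.match(hgvs_p.strip())
    if m is None:
        raise HgvsParseError(
            f"not an HGVS protein string (must start with 'p.'): {hgvs_p!r}"
        )
    body = m.group("body")
    fs = _FRAMESHIFT.search(body)
    if fs is not None:
        n = fs.group("n")
        return int(n) if n and n != "?" else None
    if body.endswith("fs"):
        return None
    return 0


def expected_foreign_peptide_length(p_stop: float = 3.0 / 64.0) -> float:
    """Expected number of codons read in a shifted frame until (and
    including) the first stop codon, under i.i.d. random codons.

    The count of codons to the first stop is geometric with success
    probability ``p_stop``, whose mean is ``1/p_stop``; with the standard
    code's 3 stops in 64 codons this gives 64/3 ≈ 21.3 — the "about 21
    foreign amino acids" rule of thumb for frameshift neoepitopes.  The
    alternative convention ``(1 - p)/p`` counts only the residues *before*
    the stop (≈ 20.3); we use ``1/p`` because the fs*N annotation counts
    the position at which the stop appears.
    """
    if not 0.0 < p_stop <= 1.0:
        raise ValueError(f"p_stop must be in (0, 1], got {p_stop!r}")
    return 1.0 / p_stop
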