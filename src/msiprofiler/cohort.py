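"""Cohort data model and readers/writers for the tabular formats of the pipeline.

The observed unit is a tumor with its list of somatic coding mutations
(gene symbol, HGVS c./p. strings, variant class, optional VAF) and an MSI
label from the orthogonal PCR assay.  Tumors with zero panel mutations are
first-class members of a cohort — burden denominators are tumor counts —
so the tabular format carries an optional samples side-table listing every
tumor id even when it contributes no mutation rows.

Internal coordinates are 0-based half-open; HGVS text stays 1-based
inclusive at the API boundary.
"""

from __future__ import annotations

import io
import logging
import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ("tumor_id", "gene", "hgvs_c", "hgvs_p", "variant_class", "vaf")
ANNOTATION_COLUMNS = ["in_repeat", "repeat_unit", "repeat_copies"]


class VariantClass(str, Enum):
    """The four counted mutation classes of the hotspot-panel analysis."""

    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION_DUPLICATION = "insertion_duplication"
    SPLICE = "splice"


class MsiStatus(str, Enum):
    MSS = "MSS"
    MSI_H = "MSI_H"
    UNKNOWN = "unknown"


@dataclass
class Mutation:
    """One somatic coding mutation in one tumor.

    At least one of ``hgvs_c``/``hgvs_p`` must be present.  ``in_repeat``
    is filled by the repeat annotator; ``None`` means not yet annotated.
    """

    tumor_id: str
    gene: str
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    variant_class: VariantClass = VariantClass.SUBSTITUTION
    vaf: float | None = None
    in_repeat: bool | None = None
    repeat_unit: str = ""
    repeat_copies: int = 0

    def __post_init__(self) -> None:
        if not self.hgvs_c and not self.hgvs_p:
            raise ValidationError(
                f"mutation in {self.gene} ({self.tumor_id}): "
                "at least one of hgvs_c/hgvs_p is required"
            )
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf {self.vaf!r} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.gene, self.hgvs_c)

    @property
    def is_indel(self) -> bool:
        return self.variant_class in (
            VariantClass.DELETION,
            VariantClass.INSERTION_DUPLICATION,
        )


@dataclass
class Tumor:
    id: str
    msi_status: MsiStatus = MsiStatus.UNKNOWN
    site: str = "unknown"          # right / left / unknown
    stage: str = "unknown"         # I_III / IV / unknown
    specimen: str = "unknown"      # primary / metastasis / unknown
    age: float | None = None
    sex: str | None = None
    mutations: list[Mutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str | None]] = set()
        for m in self.mutations:
            if m.hgvs_c is not None and m.key in seen:
                raise ValidationError(
                    f"tumor {self.id}: duplicate mutation {m.gene} {m.hgvs_c}"
                )
            seen.add(m.key)

    def add_mutation(self, mutation: Mutation) -> None:
        if mutation.hgvs_c is not None and any(
            m.key == mutation.key for m in self.mutations
        ):
            raise ValidationError(
                f"tumor {self.id}: duplicate mutation {mutation.gene} {mutation.hgvs_c}"
            )
        self.mutations.append(mutation)

    @property
    def burden(self) -> int:
        return len(self.mutations)

    def mutated_genes(self) -> set[str]:
        return {m.gene for m in self.mutations}


@dataclass
class Cohort:
    tumors: list[Tumor] = field(default_factory=list)
    name: str = "cohort"
    #: rows that failed row-level parsing in non-strict reads: (row_number, reason)
    rejected_rows: list[tuple[int, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tumors]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate tumor ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.tumors)

    def __iter__(self):
        return iter(self.tumors)

    def group(self, status: MsiStatus | str) -> list[Tumor]:
        status = MsiStatus(status)
        return [t for t in self.tumors if t.msi_status is status]

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.tumors:
            out[t.msi_status.value] = out.get(t.msi_status.value, 0) + 1
        return out

    @property
    def mutations(self) -> list[Mutation]:
        return [m for t in self.tumors for m in t.mutations]

    def to_frame(self) -> pd.DataFrame:
        """Mutation-level table in the MAF-like dialect (one row per mutation).

        Repeat-annotation columns (``in_repeat``, ``repeat_unit``,
        ``repeat_copies``) are included so annotation survives a
        write/read round trip; blank ``in_repeat`` means unannotated.
        """
        rows = [
            {
                "tumor_id": m.tumor_id,
                "gene": m.gene,
                "hgvs_c": m.hgvs_c or "",
                "hgvs_p": m.hgvs_p or "",
                "variant_class": m.variant_class.value,
                "vaf": "" if m.vaf is None else m.vaf,
                "in_repeat": "" if m.in_repeat is None else str(int(m.in_repeat)),
                "repeat_unit": m.repeat_unit,
                "repeat_copies": m.repeat_copies if m.in_repeat is not None else "",
            }
            for m in self.mutations
        ]
        return pd.DataFrame(rows, columns=list(MUTATION_COLUMNS) + ANNOTATION_COLUMNS)

    def samples_frame(self) -> pd.DataFrame:
        """Per-tumor side-table (covers zero-mutation tumors)."""
        rows = [
            {
                "tumor_id": t.id,
                "msi_status": t.msi_status.value,
                "site": t.site,
                "stage": t.stage,
                "specimen": t.specimen,
                "age": "" if t.age is None else t.age,
                "sex": t.sex or "",
            }
            for t in self.tumors
        ]
        return pd.DataFrame(
            rows,
            columns=["tumor_id", "msi_status", "site", "stage", "specimen", "age", "sex"],
        )


def _coerce_variant_class(value: str, hgvs_c: str | None) -> VariantClass:
    value = (value or "").strip().lower()
    aliases = {
        "substitution": VariantClass.SUBSTITUTION,
        "snv": VariantClass.SUBSTITUTION,
        "missense": VariantClass.SUBSTITUTION,
        "nonsense": VariantClass.SUBSTITUTION,
        "deletion": VariantClass.DELETION,
        "del": VariantClass.DELETION,
        "insertion_duplication": VariantClass.INSERTION_DUPLICATION,
        "insertion": VariantClass.INSERTION_DUPLICATION,
        "duplication": VariantClass.INSERTION_DUPLICATION,
        "ins": VariantClass.INSERTION_DUPLICATION,
        "dup": VariantClass.INSERTION_DUPLICATION,
        "splice": VariantClass.SPLICE,
        "splicing": VariantClass.SPLICE,
    }
    if value in aliases:
        return aliases[value]
    if not value and hgvs_c:
        return infer_variant_class(hgvs_c)
    raise ValidationError(f"unknown variant_class {value!r}")


def infer_variant_class(hgvs_c: str) -> VariantClass:
    """Best-effort class from an HGVS c. string (used when the column is blank)."""
    if ">" in hgvs_c:
        return VariantClass.SUBSTITUTION
    if "dup" in hgvs_c or "ins" in hgvs_c:
        return VariantClass.INSERTION_DUPLICATION
    if "del" in hgvs_c:
        return VariantClass.DELETION
    return VariantClass.SUBSTITUTION


def read_mutation_table(
    source: str | TextIO,
    samples: str | TextIO | None = None,
    *,
    name: str = "cohort",
    strict: bool = True,
) -> Cohort:
    """Read a MAF-like tab-separated mutation table into a :class:`Cohort`.

    Required columns: ``tumor_id``, ``gene`` and at least one of
    ``hgvs_c``/``hgvs_p``.  ``samples`` is an optional per-tumor side-table
    (columns ``tumor_id`` and optionally ``msi_status``, ``site``, ``stage``,
    ``specimen``, ``age``, ``sex``) which also introduces tumors with zero
    mutation rows.

    With ``strict=True`` (default) any malformed row raises; with
    ``strict=False`` malformed rows are collected in
    ``Cohort.rejected_rows`` and logged, never silently dropped.
    Duplicate ``(tumor_id, gene, hgvs_c)`` rows always raise, listing the
    offenders.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = {"tumor_id", "gene"} - set(df.columns)
    if missing:
        raise FormatError(f"mutation table missing required columns: {sorted(missing)}")
    if "hgvs_c" not in df.columns and "hgvs_p" not in df.columns:
        raise FormatError("mutation table needs at least one of hgvs_c/hgvs_p columns")

    key_cols = [c for c in ("tumor_id", "gene", "hgvs_c") if c in df.columns]
    if "hgvs_c" in key_cols:
        keyed = df[df["hgvs_c"].astype(str).str.len() > 0]
        dup_mask = keyed.duplicated(subset=key_cols, keep=False)
        if dup_mask.any():
            offenders = (
                keyed.loc[dup_mask, key_cols].drop_duplicates().itertuples(index=False)
            )
            listing = "; ".join(" ".join(map(str, o)) for o in offenders)
            raise ValidationError(f"duplicate (tumor, gene, hgvs_c) rows: {listing}")

    tumors: dict[str, Tumor] = {}

    if samples is not None:
        sdf = pd.read_csv(samples, sep="\t", dtype=str, keep_default_na=False)
        if "tumor_id" not in sdf.columns:
            raise FormatError("samples table missing required column tumor_id")
        for row in sdf.itertuples(index=False):
            rec = row._asdict()
            tid = rec["tumor_id"]
            age_raw = rec.get("age", "")
            tumors[tid] = Tumor(
                id=tid,
                msi_status=MsiStatus(rec.get("msi_status", "unknown") or "unknown"),
                site=rec.get("site", "unknown") or "unknown",
                stage=rec.get("stage", "unknown") or "unknown",
                specimen=rec.get("specimen", "unknown") or "unknown",
                age=float(age_raw) if age_raw else None,
                sex=rec.get("sex") or None,
            )

    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rec = row._asdict()
        try:
            vaf_raw = rec.get("vaf", "")
            mutation = Mutation(
                tumor_id=rec["tumor_id"],
                gene=rec["gene"],
                hgvs_c=rec.get("hgvs_c") or None,
                hgvs_p=rec.get("hgvs_p") or None,
                variant_class=_coerce_variant_class(
                    rec.get("variant_class", ""), rec.get("hgvs_c") or None
                ),
                vaf=float(vaf_raw) if vaf_raw else None,
            )
        except (ValidationError, ValueError) as exc:
            if strict:
                raise ValidationError(f"row {i}: {exc}") from exc
            logger.warning("rejected row %d: %s", i, exc)
            rejected.append((i, str(exc)))
            continue
        if rec.get("in_repeat", "") != "":
            mutation.in_repeat = bool(int(rec["in_repeat"]))
            mutation.repeat_unit = rec.get("repeat_unit", "")
            copies_raw = rec.get("repeat_copies", "")
            mutation.repeat_copies = int(float(copies_raw)) if copies_raw else 0
        tumor = tumors.setdefault(mutation.tumor_id, Tumor(id=mutation.tumor_id))
        tumor.add_mutation(mutation)

    cohort = Cohort(tumors=list(tumors.values()), name=name)
    cohort.rejected_rows = rejected
    return cohort


def read_minimal_vcf(
    path: str,
    annotation_fields: Mapping[str, str] | None = None,
    *,
    name: str = "cohort",
) -> Cohort:
    """Read a minimal annotated VCF 4.x into a :class:`Cohort`.

    ``annotation_fields`` maps model fields to INFO keys, default
    ``{"gene": "GENE", "hgvs_c": "HGVSC", "hgvs_p": "HGVSP"}``.  Each record
    is assigned to every sample whose genotype carries an ALT allele (or to
    all samples when no GT is present).  A VCF with no samples yields an
    empty cohort; records with symbolic ALT alleles are skipped with a
    warning.
    """
    import pysam

    fields = {"gene": "GENE", "hgvs_c": "HGVSC", "hgvs_p": "HGVSP"}
    if annotation_fields:
        fields.update(annotation_fields)

    with pysam.VariantFile(path) as vcf:
        sample_names = list(vcf.header.samples)
        if fields["gene"] not in vcf.header.info:
            raise FormatError(f"VCF INFO lacks annotation field {fields['gene']!r}")
        tumors = {s: Tumor(id=s) for s in sample_names}
        for rec in vcf:
            alts = rec.alts or ()
            if any(a is None or a.startswith("<") for a in alts):
                logger.warning("skipping symbolic ALT at %s:%s", rec.chrom, rec.pos)
                continue

            def info_str(key: str) -> str | None:
                val = rec.info.get(key)
                if val is None:
                    return None
                if isinstance(val, tuple):
                    val = val[0]
                return str(val)

            gene = info_str(fields["gene"])
            if gene is None:
                raise FormatError(
                    f"record {rec.chrom}:{rec.pos} missing INFO/{fields['gene']}"
                )
            hgvs_c = info_str(fields["hgvs_c"])
            hgvs_p = info_str(fields["hgvs_p"])
            carriers = []
            for s in sample_names:
                gt = rec.samples[s].get("GT") if rec.samples[s] else None
                if gt is None or any(a not in (None, 0) for a in gt):
                    carriers.append(s)
            for s in carriers:
                tumors[s].add_mutation(
                    Mutation(
                        tumor_id=s,
                        gene=gene,
                        hgvs_c=hgvs_c,
                        hgvs_p=hgvs_p,
                        variant_class=infer_variant_class(hgvs_c or ""),
                    )
                )
    return Cohort(tumors=list(tumors.values()), name=name)


def write_cohort(cohort: Cohort, mutations_path: str, samples_path: str) -> None:
    """Write the MAF-like mutation table and the per-tumor samples table."""
    cohort.to_frame().to_csv(mutations_path, sep="\t", index=False)
    cohort.samples_frame().to_csv(samples_path, sep="\t", index=False)


def _categorical_block(
    label: str,
    values_by_group: dict[str, list[str]],
    categories: Sequence[str],
    out: list[str],
    groups: Sequence[str],
) -> tuple[list[int], list[int]] | None:
    """Append count rows for one covariate; return per-group known counts
    per category (2 groups x N categories) or None when not evaluable."""
    known = {
        g: [v for v in values_by_group[g] if v in categories] for g in groups
    }
    if all(len(known[g]) == 0 for g in groups):
        out.append(f"{label}\tnot-evaluable\t" + "\t".join("" for _ in groups))
        return None
    table = []
    for cat in categories:
        counts = [known[g].count(cat) for g in groups]
        cells = []
        for g, c in zip(groups, counts):
            denom = len(known[g])
            pct = f" ({round(100 * c / denom)}%)" if denom else ""
            cells.append(f"{c}{pct}")
        out.append(f"{label}:{cat}\t" + "\t".join(cells))
        table.append(counts)
    for g in groups:
        n_unknown = len(values_by_group[g]) - len(known[g])
        if n_unknown:
            out.append(f"{label}:unknown\t{g}={n_unknown}")
    return table  # type: ignore[return-value]


def write_cohort_summary(cohort: Cohort, stream: TextIO) -> None:
    """Write a demography summary: per-group n, age median/range and
    sex/site/stage/specimen counts, with a group-comparison p-value where
    both groups are evaluable.  Unknown categories are reported separately
    and excluded from the test denominators.
    """
    from .stats import ContingencyTable2x2, chi_square, fisher_two_sided, two_sample_t

    if len(cohort) == 0:
        raise ValidationError("cannot summarize an empty cohort")

    present = [s for s in ("MSI_H", "MSS") if cohort.group(s)]
    single = len(present) < 2
    groups = present if present else ["unknown"]
    out: list[str] = ["covariate\t" + "\t".join(groups) + ("\tp_value" if not single else "")]

    by_group = {g: cohort.group(g) if g != "unknown" else list(cohort) for g in groups}
    out.append("n\t" + "\t".join(str(len(by_group[g])) for g in groups))

    ages = {g: [t.age for t in by_group[g] if t.age is not None] for g in groups}
    age_cells = []
    for g in groups:
        if ages[g]:
            age_cells.append(
                f"{statistics.median(ages[g]):g} ({min(ages[g]):g}-{max(ages[g]):g})"
            )
        else:
            age_cells.append("not-evaluable")
    age_line = "median_age (range)\t" + "\t".join(age_cells)
    if not single and all(len(ages[g]) >= 2 for g in groups):
        age_line += f"\t{two_sample_t(ages[groups[0]], ages[groups[1]]).p_value:.2f}"
    out.append(age_line)

    covariates = [
        ("sex", lambda t: (t.sex or "unknown"), ("female", "male")),
        ("site", lambda t: t.site, ("right", "left")),
        ("stage", lambda t: t.stage, ("I_III", "IV")),
        ("specimen", lambda t: t.specimen, ("primary", "metastasis")),
    ]
    for label, getter, cats in covariates:
        values = {g: [getter(t) for t in by_group[g]] for g in groups}
        table = _categorical_block(label, values, cats, out, groups)
        if not single and table is not None and len(groups) == 2:
            a, b = table[0][0], table[1][0]
            c, d = table[0][1], table[1][1]
            tbl = ContingencyTable2x2(a, b, c, d)
            if tbl.n > 0 and tbl.expected().min() < 5.0:
                res = fisher_two_sided(tbl)
            else:
                res = chi_square(tbl)
            # p-value goes on the first category row of the block
            for i, line in enumerate(out):
                if line.startswith(f"{label}:{cats[0]}\t"):
                    out[i] += f"\t{res.p_value:.2g}"
                    break

    stream.write("\n".join(out) + "\n")
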