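"""Synthetic cohort generator and reference-sequence fixtures.

The study whose summary statistics parameterize this generator deposited
no per-tumor mutation lists, so every pipeline stage is exercised on
synthetic cohorts that reproduce the printed group-level structure:

* group sizes 113 MSS / 29 MSI-H;
* per-tumor total burden ~ negative binomial moment-matched to the printed
  mean +/- SD (MSS 2.4 +/- 1.6, MSI-H 3.7 +/- 2.2 mutations/tumor), with a
  Poisson fallback when SD^2 <= mean;
* tumor-level per-gene mutation probabilities from the printed
  mutated-tumor fractions, reconciled with the drawn total by filling the
  remainder from a background pool of panel genes outside the common nine;
* indel vs substitution per mutation from the printed class totals, and
  repeat-run placement of indels with run lengths 2-6 weighted by the
  ~1000x slippage-rate ratio between runs of 6 and runs of 2 (damped by a
  geometric site-abundance factor, since long runs are rare in coding
  sequence).

All randomness flows from one ``numpy`` SeedSequence; per-tumor substreams
make generation reproducible independent of iteration order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .burden import MsiAssayResult, msi_assay_call
from .cohort import Cohort, MsiStatus, Mutation, Tumor, VariantClass
from .datasets import (
    BURDEN_STATS,
    CLASS_TOTALS,
    COMMON_CRC_GENES,
    GENE_TUMOR_COUNTS,
    MONONUCLEOTIDE_LOCI,
    N_MSIH,
    N_MSS,
    PENTANUCLEOTIDE_LOCI,
    PTEN_MUTATIONS,
    RTK_GENES,
    SLIPPAGE_RATIO_6_VS_2,
    UNCOMMON_BURDEN_STATS,
)

logger = logging.getLogger(__name__)

_GROUPS = ("MSS", "MSI_H")

#: tumor-level gene mutation probabilities per group, from printed fractions
DEFAULT_GENE_FREQS = {
    "MSS": {g: c[0] / N_MSS for g, c in GENE_TUMOR_COUNTS.items()},
    "MSI_H": {g: c[1] / N_MSIH for g, c in GENE_TUMOR_COUNTS.items()},
}

#: fraction of mutations that are not substitutions, per group
DEFAULT_INDEL_FRACTION = {"MSS": 37 / 269, "MSI_H": 16 / 108}

#: fraction of indels that sit in a repeat run, per group (printed tallies)
DEFAULT_REPEAT_FRACTION = {"MSS": 22 / 34, "MSI_H": 13 / 15}

#: demography per group: (p_female, p_right_site, p_stage_IV, p_metastasis,
#: age median, age low, age high) from the printed demography table
_DEMOGRAPHY = {
    "MSS": (55 / 113, 35 / 108, 59 / 112, 29 / 113, 49, 25, 84),
    "MSI_H": (16 / 29, 18 / 28, 7 / 29, 1 / 29, 47, 26, 89),
}


@dataclass
class SimulationParams:
    """Every distributional constant of the synthetic generator.

    Defaults are the published study conditions; ``hypermutator_prob``
    defaults to 0 because the printed MSS mean/SD already include the one
    hypermutated outlier tumor — injecting more is an opt-in stress test.
    """

    n_mss: int = N_MSS
    n_msih: int = N_MSIH
    burden_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BURDEN_STATS)
    )
    uncommon_burden_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(UNCOMMON_BURDEN_STATS)
    )
    gene_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GENE_FREQS.items()}
    )
    indel_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_FRACTION)
    )
    repeat_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_FRACTION)
    )
    slippage_ratio_6_vs_2: float = SLIPPAGE_RATIO_6_VS_2
    hypermutator_prob: float = 0.0
    hypermutator_mean: float = 14.0
    n_background_genes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mss < 1 or self.n_msih < 1:
            raise ValueError("group sizes must be >= 1")
        for g in _GROUPS:
            mean, sd = self.burden_mean_sd[g]
            if mean < 0 or sd < 0:
                raise ValueError(f"{g}: burden mean/sd must be non-negative")
            for p in self.gene_freqs[g].values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("gene frequencies must be probabilities")
            for p in (self.indel_fraction[g], self.repeat_fraction[g]):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("fractions must be probabilities")
        if not 0.0 <= self.hypermutator_prob <= 1.0:
            raise ValueError("hypermutator_prob must be a probability")
        if self.slippage_ratio_6_vs_2 <= 0:
            raise ValueError("slippage ratio must be positive")


@dataclass(frozen=True)
class TruthLabel:
    tumor_id: str
    true_status: MsiStatus
    is_hypermutator: bool = False


def _negative_binomial_draw(rng: np.random.Generator, mean: float, sd: float) -> int:
    """One overdispersed count, moment-matched NB; Poisson when SD^2 <= mean."""
    var = sd * sd
    if var > mean > 0:
        r = mean * mean / (var - mean)
        p = mean / var
        return int(rng.negative_binomial(r, p))
    if mean == 0:
        return 0
    logger.debug("SD^2 <= mean; falling back to Poisson(%.3f)", mean)
    return int(rng.poisson(mean))


def run_length_weights(
    slippage_ratio: float = SLIPPAGE_RATIO_6_VS_2, lengths: Sequence[int] = (2, 3, 4, 5, 6)
) -> np.ndarray:
    """Relative probabilities of the reference run length behind a repeat indel.

    Per-site slippage rates grow log-linearly from run length 2 to 6 by the
    given ratio; the abundance of runs of length L in coding sequence
    shrinks roughly 4-fold per extra unit, so the effective weight is
    ``ratio**((L-2)/4) * 4**-(L-2)``, normalized.
    """
    w = np.array(
        [slippage_ratio ** ((L - 2) / 4.0) * 4.0 ** -(L - 2) for L in lengths]
    )
    return w / w.sum()


# the four distinct printed PTEN indel contexts, replayable against the fixture
_PTEN_INDEL_SITES = tuple(
    {
        c: (c, p)
        for _, grp, p, c, _ in PTEN_MUTATIONS
        if grp == "MSI_H" and (">" not in c)
    }.values()
)


def _synthesize_mutation(
    rng: np.random.Generator,
    tumor_id: str,
    gene: str,
    group: str,
    params: SimulationParams,
    used_hgvs: set[tuple[str, str]],
    pten_site_pool: list[tuple[str, str]],
) -> Mutation:
    totals = CLASS_TOTALS[group]
    is_indel = rng.random() < params.indel_fraction[group]
    if is_indel:
        # split the non-substitution mass by the printed class totals
        n_del = totals["deletion"]
        n_ins = totals["insertion_duplication"]
        n_spl = totals["splice"]
        kind = rng.choice(
            ["deletion", "insertion_duplication", "splice"],
            p=np.array([n_del, n_ins, n_spl]) / (n_del + n_ins + n_spl),
        )
    else:
        kind = "substitution"

    bases = "ACGT"
    if kind == "substitution":
        while True:
            pos = int(rng.integers(1, 1500))
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            hgvs_c = f"c.{pos}{ref}>{alt}"
            if (gene, hgvs_c) not in used_hgvs:
                break
        aa = int(math.ceil(pos / 3))
        hgvs_p = f"p.{rng.choice(list('ARNDCEQGHILKMFPSTWYV'))}{aa}{rng.choice(list('ARNDCEQGHILKMFPSTWYV'))}"
        return Mutation(tumor_id, gene, hgvs_c, hgvs_p, VariantClass.SUBSTITUTION,
                        vaf=round(float(rng.uniform(0.05, 0.9)), 3))

    if kind == "splice":
        while True:
            pos = int(rng.integers(1, 1500))
            hgvs_c = f"c.{pos}+1G>A"
            if (gene, hgvs_c) not in used_hgvs:
                break
        return Mutation(tumor_id, gene, hgvs_c, "p.?", VariantClass.SPLICE,
                        vaf=round(float(rng.uniform(0.05, 0.9)), 3))

    # indel: decide repeat context, then run length by slippage weighting
    in_repeat = bool(rng.random() < params.repeat_fraction[group])
    candidates = [s for s in pten_site_pool if (gene, s[0]) not in used_hgvs]
    if gene == "PTEN" and in_repeat and candidates:
        # replay a printed fixture context so annotation round-trips
        idx = int(rng.integers(len(candidates)))
        hgvs_c, hgvs_p = candidates[idx]
        pten_site_pool.remove(candidates[idx])
        vclass = (
            VariantClass.INSERTION_DUPLICATION if "dup" in hgvs_c else VariantClass.DELETION
        )
        run_len = 2 if ("dup" in hgvs_c or "954" in hgvs_c) else 6
        m = Mutation(tumor_id, gene, hgvs_c, hgvs_p, vclass,
                     vaf=round(float(rng.uniform(0.05, 0.9)), 3))
        m.in_repeat = True
        m.repeat_copies = run_len
        m.repeat_unit = "TACT" if "954" in hgvs_c else ("T" if "dup" in hgvs_c else "A")
        return m

    is_dup = kind == "insertion_duplication"
    base = rng.choice(list(bases))
    if in_repeat:
        lengths = (2, 3, 4, 5, 6)
        run_len = int(rng.choice(lengths, p=run_length_weights(params.slippage_ratio_6_vs_2)))
    else:
        run_len = 1
    while True:
        pos = int(rng.integers(1, 1500))
        if is_dup:
            hgvs_c = f"c.{pos}_{pos + 1}dup{base}{base}" if in_repeat else f"c.{pos}dup{base}"
        else:
            hgvs_c = f"c.{pos}del{base}"
        if (gene, hgvs_c) not in used_hgvs:
            break
    fs_n = int(rng.geometric(3.0 / 64.0))
    aa = int(math.ceil(pos / 3))
    hgvs_p = f"p.{rng.choice(list('ARNDCEQGHILKMFPSTWYV'))}{aa}{rng.choice(list('ARNDCEQGHILKMFPSTWYV'))}fs*{fs_n}"
    m = Mutation(
        tumor_id, gene, hgvs_c, hgvs_p,
        VariantClass.INSERTION_DUPLICATION if is_dup else VariantClass.DELETION,
        vaf=round(float(rng.uniform(0.05, 0.9)), 3),
    )
    m.in_repeat = in_repeat
    m.repeat_copies = run_len if in_repeat else 1
    m.repeat_unit = str(base) if in_repeat else ""
    return m


def _generate_tumor(
    rng: np.random.Generator, tumor_id: str, group: str, params: SimulationParams
) -> tuple[Tumor, TruthLabel]:
    p_female, p_right, p_iv, p_met, age_med, age_lo, age_hi = _DEMOGRAPHY[group]
    mean, sd = params.burden_mean_sd[group]
    is_hyper = group == "MSS" and rng.random() < params.hypermutator_prob
    if is_hyper:
        total = int(rng.poisson(params.hypermutator_mean))
    else:
        total = _negative_binomial_draw(rng, mean, sd)

    # split the total into common / uncommon burden: the uncommon burden is
    # itself a stated study condition, so it gets its own moment-matched draw
    u_mean, u_sd = params.uncommon_burden_mean_sd[group]
    uncommon_total = min(total, _negative_binomial_draw(rng, u_mean, u_sd))
    common_total = total - uncommon_total

    freqs = params.gene_freqs[group]
    common_hit = [g for g in sorted(freqs) if g in COMMON_CRC_GENES and rng.random() < freqs[g]]
    uncommon_hit = [g for g in sorted(freqs) if g not in COMMON_CRC_GENES and rng.random() < freqs[g]]
    rng.shuffle(common_hit)
    rng.shuffle(uncommon_hit)

    def reconcile(hit: list[str], target: int, pool: list[str]) -> list[str]:
        genes = hit[:target]
        while len(genes) < target:
            # extra burden: second hits in already-mutated genes, else the pool
            source = genes if genes and rng.random() < 0.5 else pool
            genes.append(source[int(rng.integers(len(source)))])
        return genes

    background = sorted(RTK_GENES) + [
        f"PANEL{j:02d}" for j in range(1, params.n_background_genes + 1)
    ]
    genes = reconcile(common_hit, common_total, sorted(COMMON_CRC_GENES)) + reconcile(
        uncommon_hit, uncommon_total, background
    )

    age = float(np.clip(rng.normal(age_med, 12.0), age_lo, age_hi))
    tumor = Tumor(
        id=tumor_id,
        msi_status=MsiStatus(group),
        site="right" if rng.random() < p_right else "left",
        stage="IV" if rng.random() < p_iv else "I_III",
        specimen="metastasis" if rng.random() < p_met else "primary",
        age=round(age, 0),
        sex="female" if rng.random() < p_female else "male",
    )
    used: set[tuple[str, str]] = set()
    pten_pool = list(_PTEN_INDEL_SITES)
    for gene in genes:
        m = _synthesize_mutation(rng, tumor_id, gene, group, params, used, pten_pool)
        used.add((m.gene, m.hgvs_c))
        tumor.add_mutation(m)
    return tumor, TruthLabel(tumor_id, MsiStatus(group), is_hyper)


def generate_cohort(
    params: SimulationParams | None = None, seed: int | None = None
) -> tuple[Cohort, list[TruthLabel]]:
    """Generate a labeled synthetic cohort.  Deterministic for fixed seed."""
    params = params or SimulationParams()
    seed = params.seed if seed is None else seed
    plan = [("MSS", params.n_mss), ("MSI_H", params.n_msih)]
    tumors: list[Tumor] = []
    labels: list[TruthLabel] = []
    index = 0
    for group, n in plan:
        for i in range(n):
            # per-tumor substream: reproducible under any generation order
            rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
            prefix = "CRC" if group == "MSS" else "MSIH"
            tumor, label = _generate_tumor(rng, f"{prefix}{index + 1:04d}", group, params)
            tumors.append(tumor)
            labels.append(label)
            index += 1
    return Cohort(tumors=tumors, name=f"synthetic-seed{seed}"), labels


#: per-locus instability probabilities per true status; the study printed
#: none, so these are placeholder defaults chosen to make the PCR call
#: nearly always agree with truth.
DEFAULT_INSTABILITY_PROBS = {"MSI_H": 0.9, "MSS": 0.02}


def simulate_msi_assay(
    truth: TruthLabel,
    instability_probs: Mapping[str, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MsiAssayResult:
    """Simulate the 7-locus PCR panel for one tumor.

    Each mononucleotide locus is independently unstable with the per-status
    probability; the two pentanucleotide identity-control loci are always
    recorded stable (they never count toward the call anyway).
    """
    probs = dict(DEFAULT_INSTABILITY_PROBS)
    if instability_probs:
        probs.update(instability_probs)
    p = probs[MsiStatus(truth.true_status).value]
    if not 0.0 <= p <= 1.0:
        raise ValueError("instability probability must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    calls = {
        locus: ("unstable" if rng.random() < p else "stable")
        for locus in MONONUCLEOTIDE_LOCI
    }
    calls.update({locus: "stable" for locus in PENTANUCLEOTIDE_LOCI})
    return msi_assay_call(calls)


# --------------------------------------------------------------------------
# reference-sequence fixtures

_CONTROL_BLOCK = "ACGACTAGCTGA"  # repeat-free by construction


def _build_pten_like_sequence(length: int = 1212) -> str:
    """Deterministic synthetic PTEN-like coding sequence.

    Reproduces the printed mutation contexts: (A)6 runs at c.795-800 and
    c.963-968 (so c.800delA and c.968delA are homopolymer slips), a
    (TACT)2 block at c.954-961 (c.954_957del deletes one unit), a TT
    dinucleotide at c.531-532 (c.531_532dupTT), the printed substitution
    reference bases, and a repeat-free control block around c.1090.
    This is a synthetic stand-in, not the real PTEN transcript.
    """
    rng = np.random.default_rng(20151016 % (2**31))
    seq = list(rng.choice(list("ACGT"), size=length))

    def put(pos1: int, s: str) -> None:
        seq[pos1 - 1 : pos1 - 1 + len(s)] = list(s)

    # substitution reference bases from the printed mutation table
    for pos1, base in ((29, "G"), (359, "G"), (365, "T"), (376, "G"),
                       (531, "T"), (532, "T"), (697, "C"), (700, "C"), (974, "T")):
        put(pos1, base)
    # repeat contexts
    put(795, "AAAAAA")
    put(954, "TACTTACT")
    put(963, "AAAAAA")   # directly follows the (TACT)2 block at 962? no: 963
    put(962, "G")        # breaks both the TACT extension and the A run
    put(1090, _CONTROL_BLOCK)
    # flanks that must not extend the runs
    put(530, "C"); put(533, "G")
    put(794, "C"); put(801, "C")
    put(969, "C")
    put(950, "CCTG")     # no in-phase TACT copy to the left of 954
    # a TT at 531-532 must be exactly two T's
    assert seq[529] != "T" and seq[532] != "T"
    return "".join(seq)


def generate_reference_fixtures(fasta_path: str | None = None) -> dict[str, str]:
    """Synthetic coding-sequence fixtures for repeat annotation.

    Returns a mapping gene symbol -> coding sequence and optionally writes
    it as FASTA.  Sequences are synthetic: they reproduce the printed
    repeat contexts at the printed coding coordinates but are otherwise
    random.
    """
    refs = {"PTEN": _build_pten_like_sequence(), "CONTROL": _CONTROL_BLOCK * 1}
    # self-check: the printed contexts must annotate as expected
    from .hgvs import parse_hgvs_c
    from .repeats import annotate_repeat

    checks = {
        "c.800delA": ("A", 6),
        "c.968delA": ("A", 6),
        "c.954_957del": ("TACT", 2),
        "c.531_532dupTT": ("T", 2),
    }
    for hgvs_c, (unit, copies) in checks.items():
        ann = annotate_repeat(parse_hgvs_c(hgvs_c), refs["PTEN"])
        if not (ann.in_repeat and ann.unit == unit and ann.copies == copies):
            raise AssertionError(f"fixture builder broke context {hgvs_c}: {ann}")

    if fasta_path is not None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=g, description="synthetic coding-sequence fixture")
            for g, s in refs.items()
        ]
        SeqIO.write(records, fasta_path, "fasta")
    return refs


def load_reference_fixtures(fasta_path: str) -> dict[str, str]:
    """Read coding-sequence fixtures back from FASTA."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
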