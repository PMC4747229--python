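# Methods

This note documents the models, conventions and numerical choices behind
`msiprofiler`, and what the synthetic-data tests do and do not establish
about real cohorts.

## Data model

A *cohort* is a list of tumors, each with an MSI label (MSS, MSI-H or
unknown), clinical covariates (site, stage, specimen type, age, sex) and
a list of somatic coding mutations (gene symbol, HGVS c. and p. strings,
variant class, optional variant allele fraction).  Four variant classes
are counted: substitution, deletion, insertion/duplication, splice.
Tumors with zero panel mutations are first-class members — burden
denominators are always tumor counts, so the tabular format carries a
per-tumor samples side-table that can introduce mutation-free tumors.
MSI-Low, when present in inputs, should be collapsed into MSS before
loading; the analysis contrasts MSS with MSI-H only.  Unknown clinical
covariates are excluded from that covariate's contingency table only,
never from the cohort.

Internally all coordinates are 0-based half-open; HGVS strings remain
1-based inclusive at every API boundary.

## HGVS subset

The parser covers the constructs hotspot-panel reports actually emit:
substitutions (`c.697C>T`), deletions with or without stated bases
(`c.800delA`, `c.954_957del`), duplications (`c.531_532dupTT`),
insertions and delins on coding positions.  Intronic offsets, UTR
positions and inversions are rejected explicitly with the offending token
named — silently misparsing a splice-site variant as coding would corrupt
the repeat annotation downstream.

`fs*N` protein annotations are read as the count N of foreign amino acids
translated before the shifted frame reaches a stop.  Nonsense and
missense changes contribute 0 foreign residues; a frameshift of unknown
extent (`fs`, `fs*?`) maps to "unknown", which is deliberately distinct
from 0.  The analytic expectation uses the geometric read length: with
stop probability p per codon the mean number of codons read up to and
including the first stop is 1/p, i.e. 64/3 ≈ 21.3 for the standard
code's 3 stops — matching the "about 21 residues" rule of thumb.  The
alternative convention (1−p)/p ≈ 20.3 counts only pre-stop residues; we
use 1/p because `fs*N` places the stop at position N of the new frame.

## Repeat annotation

An indel is *in repeat* when its inserted/deleted sequence equals k ≥ 1
copies of a unit u (|u| = 1–6) and the maximal tandem run of u in the
reference that contains the change (deletions, duplications) or abuts it
in phase (insertions) has ≥ 2 copies.  The ≥ 2-copy rule is the loosest
one consistent with scoring (A)₆, (TACT)₂ and a TT duplication all as
repeat events; a ≥ 3-copy rule would miss two of those three patterns.
"Homopolymer region" in the tally tables means any flagged repeat, mono-
through hexanucleotide.

Among qualifying unit lengths the smallest is reported, so a TT
duplication annotates as unit "T" × 2 copies rather than "TT" × 1; the
whole-change reading is recorded in a note.  The reported unit is written
in the phase of the run as it appears in the reference (unit "TACT" for a
`TACTTACT` block); `unit_canonical` exposes the lexicographically minimal
rotation ("ACTT") for phase-independent comparisons.  Because the run is
always extended maximally in both directions, the annotation is invariant
both to appending flanking sequence outside the run and to where within a
run an aligner happened to place the indel (left/right alignment).

Correctness is established against an independent brute-force scanner
(enumerate every maximal run of every unit length at every offset):
exhaustively for all 1–4 bp deletions and 1–2 bp duplications over every
{A,C} sequence of length ≤ 10, and on seeded random ACGT sequences up to
length 40 including insertions.

### Reference fixtures

No transcript database is required.  `generate_reference_fixtures()`
builds a deterministic *synthetic* PTEN-like coding sequence that
reproduces the published mutation contexts at their published coding
coordinates — (A)₆ runs ending at c.800 and c.968, a (TACT)₂ block at
c.954–961, a TT dinucleotide at c.531–532, the substitution reference
bases, and a repeat-free control block — plus a separate repeat-free
control sequence.  The builder self-checks by annotating the four printed
indel contexts before returning.  These fixtures are stand-ins with the
right local structure, not the real PTEN transcript.

## Burden rules and the MSI call

The "uncommon" burden excludes the nine genes most commonly mutated in
CRC (*APC, BRAF, CTNNB1, FBXW7, KRAS, NRAS, PIK3CA, SMAD4, TP53*).
Three prediction rules are scored, each firing at a configurable
threshold K (≥ K): total burden (study value K = 6), uncommon burden
(K = 2), and repeat-context indels (K = 2, i.e. "more than 1").  All four
variant classes count toward the totals by default (configurable).
Standard deviations are sample (n−1) SDs; display rounding is one decimal
for burdens and two for sensitivity/specificity, with full precision kept
internally.  The PCR-panel MSI call is MSI-H iff ≥ 2 of the 5
mononucleotide loci show novel allele lengths; the two pentanucleotide
loci are identity controls and never count.  Locus-level stable/unstable
is the modeling boundary — electropherograms are out of scope.

## Statistics

*Fisher exact (two-sided)*: point-probability convention — conditioning
on both margins, sum the hypergeometric probabilities of all tables whose
point probability is ≤ the observed one, with a 1 + 10⁻⁷ relative slack
to absorb floating-point ties.  The summation runs in log space
(`hypergeom.logpmf` + `logsumexp`) for stability.  The implementation is
verified against an exact-integer enumeration oracle for every 2×2 table
with n ≤ 40 (all point probabilities share the denominator C(n, c₁), so
the tie comparison is done exactly on integers) and against the standard
scipy reference on random tables.

*Chi-square*: Pearson statistic on the 2×2 table, no continuity
correction (configurable), df = 1, upper-tail p.  *t-test*:
pooled-variance Student by default, Welch optional.  Degenerate inputs
(zero margin, zero expected cell, zero variance) return p = 1 with a
warning rather than raising — except zero variance with unequal means,
which returns p = 0 by convention.  No multiple-testing correction is
applied anywhere, matching the exploratory design of the analysis.

The exact and asymptotic tests agree closely only in the small-p regime
at cohort-sized tables (within ~0.03 when p < 0.05); across the full p
range the discreteness of the hypergeometric keeps them up to ~0.15
apart, which is why the table reports both.

Gene-frequency tables count at tumor level: a tumor with two *PTEN*
mutations contributes once to the *PTEN* row and once to the mTOR row
(mTOR = *PIK3CA* ∪ *PTEN* ∪ *AKT1*; RTK = the twelve receptor tyrosine
kinase genes of the panel).  Repeat-indel tables report both
mutation-level ratios (repeat indels / all indels) and per-tumor rates
(repeat indels / group size).

## Synthetic cohort generator

The generator's defaults are the published study conditions: 113 MSS and
29 MSI-H tumors; total burden negative-binomial moment-matched to
2.4 ± 1.6 (MSS) and 3.7 ± 2.2 (MSI-H) mutations/tumor, with a Poisson
fallback when SD² ≤ mean; per-gene tumor-level mutation probabilities
from the published mutated-tumor fractions; substitution vs non-
substitution split 37/269 (MSS) and 16/108 (MSI-H); demography from the
published covariate table.

Reconciling a drawn total with tumor-level gene memberships is the one
genuinely open design point.  We draw the uncommon burden from its own
moment-matched negative binomial (0.2 ± 0.8 vs 1.6 ± 1.5, truncated at
the total), assign uncommon mutations first to Bernoulli-drawn *PTEN*/
*AKT1* memberships and then to a background pool (the RTK genes plus
generic panel genes), and fill the common-gene remainder as second hits
in already-mutated common genes or additional common genes.  At large n
this recovers the total-burden moments within ~2% and preserves the
MSS ≪ MSI-H uncommon contrast; tumor-level gene frequencies come out
somewhat shrunk relative to their inputs (e.g. *TP53* ~0.50 vs 0.63)
because membership draws are subsampled when the burden draw is small —
a documented compromise, not a target.

Indels are placed in repeat runs with per-group probability equal to the
published repeat fractions (22/34 MSS, 13/15 MSI-H).  Conditional on
repeat placement, the run length L ∈ {2..6} is drawn with weight
slippage^((L−2)/4) · 4^−(L−2): the first factor interpolates the ~1000×
slippage-rate ratio between runs of 6 and runs of 2 log-linearly; the
second damps by run abundance, since runs of length L are roughly 4-fold
rarer per extra unit in random coding sequence.  Pure slippage weighting
would put essentially all indels at L = 6, contradicting the published
repeat fractions.  This weighting is a modeling choice of this package.
MSI-H *PTEN* repeat indels reuse the four printed fixture contexts so
that re-annotating a simulated cohort against the FASTA reproduces the
generator's flags.

`hypermutator_prob` defaults to 0: the published MSS mean/SD already
include the study's one hypermutated outlier (a metastasis with 14
mutations, far above the mean + 3·SD thresholds of 7.2 and 10.3), so
layering additional outliers on a distribution matched to those numbers
would double-count.  Setting it > 0 injects Poisson(≈14)-burden MSS
tumors for classifier stress tests.  Frameshift lengths in simulated
`fs*N` annotations are geometric draws with p = 3/64.

Per-locus assay instability probabilities (default 0.9 for MSI-H, 0.02
for MSS per mononucleotide locus) are placeholders: the source analysis
printed none.  All randomness flows from one integer seed through numpy
`SeedSequence` substreams per tumor index, so generation is reproducible
and order-independent; identical parameters and seed give byte-identical
cohorts, labels and assay calls.

### What the synthetic tests do and do not show

Passing tests establish that the pipeline's arithmetic, annotation and
statistics are correct under the stated generative model, and that the
published group-level numbers are internally consistent.  They do not
establish classifier performance on real tumors: the generator draws
genes independently (no APC–KRAS co-occurrence structure, no mutual
exclusivity), models neither VAF/purity nor sequencing artifacts (real
homopolymer calls are error-prone), uses placeholder assay error rates,
and treats per-gene frequencies as fixed rather than uncertain.

## Test scales and numerical tolerances

Simulation-based checks use derandomized seeds and oracle-derived
expectations: moment recovery runs at 2 500 tumors per group (5%
relative tolerance); the t-test power check at the published effect size
runs 200 replicates (estimated power ≈ 0.59 at α = 0.001, asserted
> 0.45); the Fisher power check for a PTEN-sized frequency difference
(28% vs 3% at n = 113/29) runs 100 replicates (estimated power ≈ 0.90 at
α = 0.01, ≈ 0.72 at α = 0.001).  A single cohort of this size therefore
has a good — but not overwhelming — chance of reaching p < 0.001 for any
one such contrast, which is worth remembering when reading significance
claims from one observed cohort.  The exhaustive Fisher-oracle sweep
covers all 132 470 tables with n ≤ 40 in about half a minute.

## Known limitations

* HGVS coverage is the hotspot-panel subset only; no transcript mapping,
  no protein-consequence prediction from nucleotide changes.
* The minimal VCF reader takes gene/HGVS annotations from INFO fields and
  assigns records by genotype; it is not a general multi-sample VCF
  genotype engine.
* Repeat annotation requires a coding reference for the gene; mutations
  in genes without a shipped or supplied sequence stay unannotated and
  count only toward indel denominators.
* The rule thresholds are evaluated, not optimized; ROC analysis and any
  survival or treatment-response modeling are out of scope.
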