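"""Reference constants from a published 142-tumor colorectal cancer cohort.

A cohort of 113 microsatellite-stable (MSS) and 29 MSI-high (MSI-H)
colorectal cancers was profiled with a 50-gene hotspot amplicon panel.
The study itself deposited no per-tumor mutation lists; what it printed
were group-level summaries (per-class mutation totals, burden mean +/- SD,
per-gene mutated-tumor counts) and the full PTEN mutation table.  Those
printed values are inputs to this package: they parameterize the synthetic
cohort generator and anchor the desk-scale checks.
"""

from __future__ import annotations

from types import MappingProxyType

#: Group sizes of the reference cohort.
N_MSS = 113
N_MSIH = 29

#: The nine genes most commonly mutated in colorectal cancer, excluded when
#: computing the "uncommon" mutation burden.
COMMON_CRC_GENES = frozenset(
    {"APC", "BRAF", "CTNNB1", "FBXW7", "KRAS", "NRAS", "PIK3CA", "SMAD4", "TP53"}
)

#: mTOR-pathway membership: a tumor counts if PIK3CA, PTEN and/or AKT1 is mutated.
MTOR_GENES = frozenset({"PIK3CA", "PTEN", "AKT1"})

#: Receptor tyrosine kinase genes covered by the hotspot panel.
RTK_GENES = frozenset(
    {
        "EGFR", "ERBB2", "ERBB4",          # class I
        "CSF1R", "FLT3", "KIT", "PDGFRA",  # class II
        "FGFR1", "FGFR2", "FGFR3",         # class IV
        "MET",                             # class VI
        "RET",                             # class XIV
    }
)

#: Promega-style MSI panel: five mononucleotide loci counted toward the
#: MSI-H call and two pentanucleotide identity-control loci that never count.
MONONUCLEOTIDE_LOCI = ("BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27")
PENTANUCLEOTIDE_LOCI = ("Penta C", "Penta D")

#: Printed per-class mutation totals per group (mutation level).
CLASS_TOTALS = MappingProxyType(
    {
        "MSS": MappingProxyType(
            {"substitution": 229, "deletion": 33, "insertion_duplication": 3, "splice": 4}
        ),
        "MSI_H": MappingProxyType(
            {"substitution": 92, "deletion": 12, "insertion_duplication": 3, "splice": 1}
        ),
    }
)

#: Printed total-burden mean and sample SD (mutations per tumor).
BURDEN_STATS = MappingProxyType({"MSS": (2.4, 1.6), "MSI_H": (3.7, 2.2)})

#: Printed burden mean/SD after excluding the nine common CRC genes.
UNCOMMON_BURDEN_STATS = MappingProxyType({"MSS": (0.2, 0.8), "MSI_H": (1.6, 1.5)})

#: Tumor-level mutated-tumor counts per gene: (count in 113 MSS, count in 29 MSI-H).
GENE_TUMOR_COUNTS = MappingProxyType(
    {
        "APC": (53, 10),
        "BRAF": (6, 10),
        "CTNNB1": (6, 1),
        "FBXW7": (6, 4),
        "KRAS": (52, 9),
        "NRAS": (5, 3),
        "PIK3CA": (17, 10),
        "SMAD4": (12, 0),
        "TP53": (71, 9),
        "AKT1": (1, 1),
        "PTEN": (3, 8),
    }
)

#: Tumor-level counts for the derived gene sets (MSS, MSI-H).
SET_TUMOR_COUNTS = MappingProxyType(
    {"mTOR": (20, 17), "RTK": (2, 9), "PTEN_substitution_only": (3, 4)}
)

#: The complete printed PTEN mutation table: (case, group, hgvs_p, hgvs_c, exon).
#: Eight of the MSI-H entries are indels, every one in a homopolymer or short
#: tandem repeat context of the coding sequence.
PTEN_MUTATIONS = (
    ("131", "MSS", "p.Y177Ter", "c.531T>G", 6),
    ("133", "MSS", "p.R233Ter", "c.697C>T", 7),
    ("181", "MSS", "p.A126T", "c.376G>A", 5),
    ("48", "MSI_H", "p.T319Ter", "c.954_957del", 8),
    ("143", "MSI_H", "p.N323Mfs*21", "c.968delA", 8),
    ("218", "MSI_H", "p.L325R", "c.974T>G", 8),
    ("218", "MSI_H", "p.K267Rfs*9", "c.800delA", 7),
    ("240", "MSI_H", "p.R234W", "c.700C>T", 7),
    ("264", "MSI_H", "p.I122N", "c.365T>A", 5),
    ("264", "MSI_H", "p.R130Q", "c.359G>A", 5),
    ("264", "MSI_H", "p.N323Mfs*21", "c.968delA", 8),
    ("273", "MSI_H", "p.S10I", "c.29G>T", 1),
    ("MSIH22", "MSI_H", "p.Y178Ffs*6", "c.531_532dupTT", 6),
    ("MSIH22", "MSI_H", "p.K267Rfs*9", "c.800delA", 7),
    ("MSIH24", "MSI_H", "p.K267Rfs*9", "c.800delA", 7),
    ("MSIH24", "MSI_H", "p.N323Mfs*21", "c.968delA", 8),
)

#: Mononucleotide runs of six bases slip roughly 1000x more often than runs
#: of two during replication with defective mismatch repair.
SLIPPAGE_RATIO_6_VS_2 = 1000.0

#: Stop codons in the standard genetic code, out of 64 total codons.
P_STOP_PER_CODON = 3.0 / 64.0
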