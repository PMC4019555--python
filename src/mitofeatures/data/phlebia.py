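"""Published annotation summary of the *Phlebia radiata* 79 mitochondrial genome.

The deposited record is EMBL HE613568 / NCBI NC_020148: a single circular
dsDNA molecule of 156 348 bp with 31.1% GC.  The constants below transcribe
the published per-gene architecture (conserved protein/rRNA genes with their
spans, coding lengths, stop codons and intron lengths), the 28 tRNA loci
with anticodons, the homing-endonuclease (HE) domain summary, and the codons
reported as candidate unassigned codons.  They serve as fixed inputs for
replaying the genome's quantitative feature analysis without downloading the
record.
"""

from __future__ import annotations

GENOME_LENGTH = 156_348
GC_PERCENT = 31.1
ACCESSIONS = ("HE613568", "NC_020148")

#: Conserved protein-coding and rRNA genes.
#: name, start, end, strand, coding length (bp, incl. stop where annotated),
#: published protein length (aa, None for rRNA), published coding density (%),
#: published mean intron length (bp, None if intronless), stop codon,
#: feature class.
GENE_TABLE = [
    ("cox1", 1, 21743, "+", 1590, 529, 7.3, 1550, "TAA", "protein"),
    ("rnl", 23389, 34087, "+", 3624, None, 33.9, 1769, None, "rRNA"),
    ("atp6", 36924, 37700, "+", 777, 258, 100.0, None, "TAA", "protein"),
    ("cox2", 45480, 52022, "+", 756, 251, 11.6, 1929, "TAA", "protein"),
    ("cox3", 58610, 61439, "+", 813, 270, 28.7, 2017, "TAA", "protein"),
    ("nad4L", 64304, 66152, "+", 273, 90, 14.8, 1576, "TAA", "protein"),
    ("nad5", 66153, 76178, "+", 2007, 668, 20.0, 1604, "TAA", "protein"),
    ("atp8", 77128, 77286, "+", 159, 52, 100.0, None, "TAA", "protein"),
    ("nad2", 81572, 87656, "+", 1812, 603, 29.8, 2137, "TAA", "protein"),
    ("nad3", 87656, 88030, "+", 375, 124, 100.0, None, "TAA", "protein"),
    ("atp9", 103782, 104003, "-", 222, 73, 100.0, None, "TAA", "protein"),
    ("rns", 109435, 112341, "-", 1711, None, 58.9, 399, None, "rRNA"),
    ("cob", 119244, 126306, "-", 1272, 423, 18.0, 1930, "TAA", "protein"),
    ("nad4", 127498, 130848, "-", 1473, 490, 44.0, 1878, "TAA", "protein"),
    ("nad6", 133402, 134382, "-", 981, 326, 100.0, None, "TAA", "protein"),
    ("atp6-2", 139006, 139782, "-", 777, 258, 100.0, None, "TAA", "protein"),
    ("nad1", 140738, 143807, "-", 1017, 338, 33.1, 2053, "TAG", "protein"),
    ("rps3", 150069, 151403, "+", 1335, 444, 100.0, None, "TAA", "protein"),
]

#: Per-gene intron lengths (bp) with HE association labels
#: (G=GIY-YIG, L1/L2=LAGLIDADG 1/2, R=reverse-transcriptase ORF), plus the
#: published total and integer-rounded mean.
INTRON_TABLE = {
    "cox1": {
        "introns": [
            (1463, "G"), (1540, "L1"), (1680, "L1"), (1356, "L2"), (3420, None),
            (1447, "L1"), (432, None), (1144, "L2"), (1410, "L2"), (1649, "G"),
            (1076, "L1"), (2004, "G"), (1532, "G"),
        ],
        "total": 20153,
        "mean": 1550,
    },
    "nad5": {
        "introns": [(1413, "L1"), (2278, "L2"), (1405, "L1"), (1186, "L2"), (1737, "G")],
        "total": 8019,
        "mean": 1604,
    },
    "rnl": {
        "introns": [(1675, "L2"), (1912, "G"), (1756, "L2"), (1732, "G")],
        "total": 7075,
        "mean": 1769,
    },
    "cox2": {
        "introns": [(2849, "G"), (1152, "L2"), (1786, "G")],
        "total": 5787,
        "mean": 1929,
    },
    "rns": {"introns": [(704, None), (201, None), (291, None)], "total": 1196, "mean": 399},
    "cob": {
        "introns": [(1864, "L1"), (2452, "R"), (1475, "L2")],
        "total": 5791,
        "mean": 1930,
    },
    "nad2": {"introns": [(1306, "L2"), (2967, None)], "total": 4273, "mean": 2137},
    "cox3": {"introns": [(2017, "L2")], "total": 2017, "mean": 2017},
    "nad4L": {"introns": [(1576, "L1")], "total": 1576, "mean": 1576},
    "nad4": {"introns": [(1878, None)], "total": 1878, "mean": 1878},
    "nad1": {"introns": [(2053, "L1")], "total": 2053, "mean": 2053},
}

#: The 28 tRNA loci: amino acid, anticodon (RNA, 5'->3'), start, end, strand,
#: published locus length (bp).  The second CAU anticodon is the tRNA inferred
#: to decode Ile by comparative means.
TRNA_TABLE = [
    ("Ile", "GAU", 39443, 39514, "+", 72),
    ("Ala", "UGC", 55927, 55999, "+", 73),
    ("Trp", "CCA", 78296, 78369, "+", 74),
    ("Asp", "GUC", 79686, 79758, "+", 73),
    ("Phe", "GAA", 89697, 89767, "+", 71),
    ("Thr", "UGU", 91722, 91793, "+", 72),
    ("Gln", "UUG", 92238, 92311, "+", 74),
    ("Lys", "UUU", 93159, 93231, "+", 73),
    ("Tyr", "GUA", 95474, 95557, "+", 84),
    ("Phe", "GAA", 96533, 96603, "+", 71),
    ("Ile", "CAU", 96632, 96704, "+", 73),
    ("Ser", "UGA", 97243, 97328, "+", 86),
    ("Val", "UAC", 103081, 103151, "-", 71),
    ("Ser", "GCU", 107528, 107609, "-", 82),
    ("His", "GUG", 107979, 108050, "-", 72),
    ("Val", "UAC", 108850, 108920, "-", 71),
    ("Met", "CAU", 113144, 113216, "-", 73),
    ("Arg", "UCG", 114191, 114261, "-", 71),
    ("Leu", "UAG", 114743, 114816, "-", 74),
    ("Gly", "UCC", 117118, 117188, "-", 71),
    ("Ile", "GAU", 137192, 137263, "-", 72),
    ("Arg", "UCU", 146748, 146818, "-", 71),
    ("Cys", "GCA", 148390, 148461, "-", 72),
    ("Pro", "UGG", 153357, 153429, "+", 73),
    ("Asn", "GUU", 153900, 153972, "+", 73),
    ("Leu", "UAA", 154617, 154701, "+", 85),
    ("Met", "CAU", 154736, 154807, "+", 72),
    ("Glu", "UUC", 154832, 154902, "+", 71),
]

#: Inverted duplication ("mirror region"): ID1 spans 134346..140421 (given in
#: the record in descending orientation 140421->134346), ID2 spans
#: 36285..42360; the copies differ at three sites on the plus strand
#: (an extra A at 40066, a missing T at 41338, T instead of G at 42353).
INVERTED_DUPLICATION = {
    "id1": (134346, 140421),
    "id2": (36285, 42360),
    "caption_length": 6076,
    "n_differences": 3,
    "difference_positions": (40066, 41338, 42353),
    "difference_classes": ("insertion", "deletion", "substitution"),
}

#: HE core-domain summary: family -> (count, (len min, max, mean aa),
#: (similarity min, max, mean %), (locus distance min, max, mean bp)).
HE_SUMMARY = {
    "LAGLIDADG1": (28, (29, 115, 69), (3.2, 32, 11), (408, 141226, 56490)),
    "LAGLIDADG2": (19, (34, 181, 102), (0, 67, 16), (106, 114830, 34171)),
    "GIY-YIG": (10, (21, 112, 80), (12, 52, 26), (2214, 73172, 26106)),
}

#: Published headline correlations of HE similarity vs. circular locus
#: distance: family -> (method, transform, r, p).
HE_CORRELATIONS = {
    "LAGLIDADG1": ("pearson", "log", -0.166, 0.031),
    "GIY-YIG": ("pearson", "none", -0.256, 0.089),
    "LAGLIDADG2": ("spearman", "none", -0.040, 0.607),
}

#: Codons observed only outside conserved ORFs (candidate unassigned codons),
#: with their genome-wide counts in those regions.
UNASSIGNED_CODONS = {"UGA": 1, "AAG": 9, "CGC": 1, "AGG": 5, "CGG": 2}

#: ORF composition of the conserved coding sequences.
ORF_GC_PERCENT = {"overall": 26.83, "gc1": 34.14, "gc2": 33.33, "gc3": 13.00}

#: Replication landmark intervals inferred from G/C skew (bp).
ORI_REGION = (153_000, 7)
TER_REGION = (88_000, 109_000)
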