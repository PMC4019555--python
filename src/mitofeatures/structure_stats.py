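"""Gene-architecture accounting and genome composition.

Per-gene reports reproduce the printed precision of mitochondrial annotation
tables: coding density rounded half-up to one decimal, intron means rounded
half-up to the nearest integer, protein length excluding the annotated stop
codon.  Composition assigns every genomic position to exactly one primary
category with precedence conserved-coding > intronic > intergenic, so the
three categories always partition the genome even when genes overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import CircularGenome, FeatureInterval, GeneModel

__all__ = [
    "GeneStructureReport",
    "CompositionBreakdown",
    "TranslationResult",
    "GeneStructureError",
    "NoIntronsError",
    "gene_structure",
    "intron_summary",
    "genome_composition",
    "translate_cds",
    "round_half_up",
]


class GeneStructureError(ValueError):
    """Structurally invalid gene (e.g. protein coding length not divisible by 3)."""


class NoIntronsError(ValueError):
    """Intron summary requested for an intronless gene (undefined, not zero)."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (matches printed table precision; banker's
    rounding would disagree on exact .5 ties)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneStructureReport:
    gene: str
    feature_class: str
    span_bp: int
    coding_bp: int
    protein_aa: int | None
    intron_count: int
    intron_total_bp: int
    intron_mean_bp: int | None
    coding_density: float  # percent, one decimal, half-up


@dataclass(frozen=True)
class CompositionBreakdown:
    genome_bp: int
    conserved_coding_bp: int
    intronic_bp: int
    intergenic_bp: int
    significant_orf_bp: int | None = None

    @property
    def fractions(self) -> dict[str, float]:
        L = self.genome_bp
        return {
            "conserved_coding": self.conserved_coding_bp / L,
            "intronic": self.intronic_bp / L,
            "intergenic": self.intergenic_bp / L,
        }


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    internal_stop_codons: tuple[int, ...]  # 1-based codon ordinals

    @property
    def has_internal_stops(self) -> bool:
        return bool(self.internal_stop_codons)


def gene_structure(gene: GeneModel, genome_length: int | None = None) -> GeneStructureReport:
    """Derive the per-gene architecture row (span, coding, density, introns).

    ``coding_density = 100 * coding_bp / span_bp`` rounded half-up to one
    decimal; ``protein_aa = coding_bp/3 - 1`` when a stop codon is annotated
    (the stop is inside ``coding_bp`` but encodes no residue), ``coding_bp/3``
    otherwise.
    """
    coding = gene.coding_length(genome_length)
    intron_total = gene.intron_length(genome_length)
    span = coding + intron_total
    if gene.feature_class == "protein":
        if coding % 3:
            raise GeneStructureError(
                f"protein gene {gene.name}: coding length {coding} not divisible by 3"
            )
        protein_aa = coding // 3 - (1 if gene.stop_codon else 0)
    else:
        protein_aa = None
    n_introns = len(gene.introns)
    mean = int(round_half_up(intron_total / n_introns)) if n_introns else None
    density = round_half_up(100.0 * coding / span, 1)
    return GeneStructureReport(
        gene=gene.name,
        feature_class=gene.feature_class,
        span_bp=span,
        coding_bp=coding,
        protein_aa=protein_aa,
        intron_count=n_introns,
        intron_total_bp=intron_total,
        intron_mean_bp=mean,
        coding_density=density,
    )


def intron_summary(gene: GeneModel, genome_length: int | None = None) -> tuple[int, int]:
    """Total and half-up integer mean of a gene's intron lengths."""
    if not gene.introns:
        raise NoIntronsError(f"gene {gene.name} has no introns; summary undefined")
    total = gene.intron_length(genome_length)
    return total, int(round_half_up(total / len(gene.introns)))


def _paint(mask: np.ndarray, interval: FeatureInterval, L: int, value: int) -> None:
    s0, e0 = interval.unrolled(L)
    if e0 <= L:
        mask[s0:e0] = value
    else:
        mask[s0:L] = value
        mask[: e0 - L] = value


_INTERGENIC, _INTRONIC, _CODING = 0, 1, 2


def genome_composition(
    genome: CircularGenome,
    genes: Sequence[GeneModel],
    extra_orfs: Sequence[FeatureInterval] = (),
) -> CompositionBreakdown:
    """Partition the genome into conserved-coding / intronic / intergenic bp.

    Exons of every gene class (protein, rRNA, tRNA) count as conserved
    coding; precedence conserved-coding > intronic resolves overlaps.  The
    optional ``extra_orfs`` layer is reported without disturbing the
    partition.
    """
    L = len(genome)
    mask = composition_mask(genome, genes)
    orf_bp: int | None = None
    if extra_orfs:
        orf_mask = np.zeros(L, dtype=bool)
        for iv in extra_orfs:
            _paint(orf_mask, iv, L, 1)
        orf_bp = int(orf_mask.sum())
    counts = np.bincount(mask, minlength=3)
    return CompositionBreakdown(
        genome_bp=L,
        conserved_coding_bp=int(counts[_CODING]),
        intronic_bp=int(counts[_INTRONIC]),
        intergenic_bp=int(counts[_INTERGENIC]),
        significant_orf_bp=orf_bp,
    )


def composition_mask(genome: CircularGenome, genes: Sequence[GeneModel]) -> np.ndarray:
    """Per-position category array (0 intergenic, 1 intronic, 2 coding)."""
    L = len(genome)
    mask = np.zeros(L, dtype=np.uint8)
    for g in genes:
        for intron in g.introns:
            _paint(mask, intron.interval, L, _INTRONIC)
    for g in genes:
        for exon in g.exons:
            _paint(mask, exon, L, _CODING)
    return mask


def translate_cds(
    gene: GeneModel, genome: CircularGenome, code_table: int = 4
) -> TranslationResult:
    """Translate a gene's spliced coding sequence under an NCBI code table.

    Reverse-strand genes are translated from the reverse complement; the
    trailing stop is removed; internal stops are reported by codon ordinal
    rather than silently translated (their appearance under a candidate code
    is evidence against that code).
    """
    cds = "".join(genome.fetch(e) for e in gene.exons)
    if len(cds) % 3:
        raise GeneStructureError(
            f"gene {gene.name}: spliced CDS length {len(cds)} not divisible by 3"
        )
    table = CodonTable.unambiguous_dna_by_id[code_table]
    protein = str(Seq(cds).translate(table=code_table))
    if protein.endswith("*"):
        protein = protein[:-1]
    internal = tuple(i + 1 for i, aa in enumerate(protein) if aa == "*")
    protein = protein.replace("*", "X") if internal else protein
    _ = table  # table validated above; Seq.translate does the work
    return TranslationResult(protein=protein, internal_stop_codons=internal)
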