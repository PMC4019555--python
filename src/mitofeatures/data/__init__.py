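"""Reference data: the published *Phlebia radiata* mtDNA annotation summary."""

from __future__ import annotations

from .. import genome_io as gio
from . import phlebia

__all__ = ["phlebia", "phlebia_gene_models", "phlebia_anticodons"]


def phlebia_gene_models() -> list[gio.GeneModel]:
    """Gene models reconstructed from the published per-gene summaries.

    Exon/intron layout is rebuilt from each gene's span, coding length and
    intron lengths (introns in transcription order); the split of coding
    sequence across exons is not published, so coding bp are distributed
    evenly — every derived quantity used downstream (span, coding length,
    density, intron totals) is invariant to that split.
    """
    he_map = {"G": "GIY-YIG", "L1": "LAGLIDADG1", "L2": "LAGLIDADG2", "R": "RT", None: "none"}
    genes: list[gio.GeneModel] = []
    for name, start, end, strand, coding, _aa, _dens, _imean, stop, fclass in phlebia.GENE_TABLE:
        intron_info = phlebia.INTRON_TABLE.get(name, {"introns": []})["introns"]
        n_exons = len(intron_info) + 1
        base, extra = divmod(coding, n_exons)
        exon_sizes = [base + (1 if k < extra else 0) for k in range(n_exons)]
        # lay segments out in transcription order, then map to genome coords
        segments: list[tuple[str, int, str | None]] = []
        for k, size in enumerate(exon_sizes):
            segments.append(("exon", size, None))
            if k < len(intron_info):
                ilen, label = intron_info[k]
                segments.append(("intron", ilen, he_map[label]))
        exons: list[gio.FeatureInterval] = []
        introns: list[gio.IntronRecord] = []
        pos = start if strand == "+" else end
        ordinal = 0
        for kind, size, label in segments:
            if strand == "+":
                iv = gio.FeatureInterval(pos, pos + size - 1, strand)
                pos += size
            else:
                iv = gio.FeatureInterval(pos - size + 1, pos, strand)
                pos -= size
            if kind == "exon":
                exons.append(iv)
            else:
                ordinal += 1
                introns.append(
                    gio.IntronRecord(ordinal=ordinal, interval=iv, he_label=label or "none")
                )
        g = gio.GeneModel(
            name=name, feature_class=fclass, exons=exons, strand=strand, stop_codon=stop
        )
        g.introns = introns
        genes.append(g)
    return genes


def phlebia_anticodons() -> list[gio.AnticodonRecord]:
    """The 28 published tRNA loci as anticodon records."""
    return [
        gio.AnticodonRecord(aa, ac, gio.FeatureInterval(start, end, strand))
        for aa, ac, start, end, strand, _len in phlebia.TRNA_TABLE
    ]
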