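"""Synthetic circular mitochondrial genomes with fully known ground truth.

The generator emulates the architecture of a large fungal mtDNA: a circular
AT-rich molecule carrying a conserved protein/rRNA/tRNA gene set whose
coding sequences are split by long introns, a multi-kbp inverted duplication
differing at a small number of sites, AT-enriched intergenic spacers seeded
with short dispersed/inverted repeat families, and strand-asymmetric base
composition that flips sign at a planted replication origin and terminus so
a G-over-C cumulative-skew extremum is recoverable.

Everything planted is recorded as ground truth (gene models, repeat pairs,
duplication boundaries and edit list, ori/ter positions, the composition
partition), and output is fully determined by the spec's seed.

Two deliberate well-posedness guards: duplication edits and repeat-member
mutations are kept away from planted boundaries, and the bases flanking the
duplication copies are forced to break reverse-complement continuation.
Without these the planted boundary itself would be ambiguous (any
maximal-extension detector would legitimately disagree with the truth by a
base or two), and boundary/identity recovery would not be a meaningful
test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import genome_io as gio
from .codon_phylo import ALL_CODONS, stop_codons
from .genome_io import (
    AnticodonRecord,
    CircularGenome,
    FeatureInterval,
    GeneModel,
    IntronRecord,
)
from .repeats import InvertedDuplicationReport, MismatchRecord, RepeatPair
from .structure_stats import CompositionBreakdown

__all__ = [
    "SyntheticGeneSpec",
    "DuplicationSpec",
    "RepeatFamilySpec",
    "SkewSpec",
    "SyntheticGenomeSpec",
    "GroundTruth",
    "SpecError",
    "generate",
    "write_truth",
    "load_truth",
    "default_gene_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SpecError(ValueError):
    """Requested features cannot be packed into the requested length."""


@dataclass(frozen=True)
class SyntheticGeneSpec:
    name: str
    feature_class: Literal["protein", "rRNA", "tRNA"] = "protein"
    coding_length: int = 900  # bp, includes the terminal stop for proteins
    n_introns: int = 0
    anticodon: str | None = None  # tRNA only (RNA triplet)
    amino_acid: str | None = None


@dataclass(frozen=True)
class DuplicationSpec:
    length: int = 6076
    n_edits: int = 3
    edit_classes: tuple[str, ...] = ("insertion", "deletion", "substitution")
    across_origin: bool = False
    edge_guard: int = 100  # min bp between an edit and a copy boundary


@dataclass(frozen=True)
class RepeatFamilySpec:
    n_families: int = 4
    members_per_family: tuple[int, int] = (4, 6)
    member_length: tuple[int, int] = (60, 200)
    identity: float = 0.85  # member vs family founder
    edge_guard: int = 5  # mutations stay this far from member ends
    min_separation: int = 30  # bp between planted members in a spacer


@dataclass(frozen=True)
class SkewSpec:
    amplitude: float = 0.5  # G excess over C inside the leading arc
    ori_frac: float = 0.0  # desired ori position as a fraction of length
    ter_frac: float = 0.5


#: the published 28-anticodon repertoire, reused as the default tRNA set
_DEFAULT_ANTICODONS = [
    ("Ile", "GAU"), ("Ala", "UGC"), ("Trp", "CCA"), ("Asp", "GUC"),
    ("Phe", "GAA"), ("Thr", "UGU"), ("Gln", "UUG"), ("Lys", "UUU"),
    ("Tyr", "GUA"), ("Ile", "CAU"), ("Ser", "UGA"), ("Val", "UAC"),
]


def default_gene_set(rng: np.random.Generator) -> list[SyntheticGeneSpec]:
    """A conserved-style gene set scaled to a ~50 kbp molecule.

    Protein coding lengths mirror typical fungal mitochondrial subunit genes;
    intron counts are reduced so the default molecule stays ~40% intergenic.
    """
    proteins = [
        ("cox1", 1590, 4), ("cox2", 756, 2), ("cox3", 813, 0), ("cob", 1272, 2),
        ("nad1", 1017, 1), ("nad2", 1812, 0), ("atp6", 777, 0), ("atp9", 222, 0),
    ]
    genes = [
        SyntheticGeneSpec(name, "protein", coding, n_int)
        for name, coding, n_int in proteins
    ]
    genes.append(SyntheticGeneSpec("rnl", "rRNA", 2400, 1))
    genes.append(SyntheticGeneSpec("rns", "rRNA", 1400, 0))
    for k, (aa, ac) in enumerate(_DEFAULT_ANTICODONS, 1):
        genes.append(
            SyntheticGeneSpec(
                f"trn{aa}{k}", "tRNA", int(rng.integers(71, 87)), 0,
                anticodon=ac, amino_acid=aa,
            )
        )
    return genes


@dataclass
class SyntheticGenomeSpec:
    length: int = 60_000
    gc_fraction: float = 0.31
    genes: list[SyntheticGeneSpec] | None = None  # None -> default_gene_set
    intron_length_range: tuple[int, int] = (200, 3400)
    duplication: DuplicationSpec | None = field(default_factory=DuplicationSpec)
    repeats: RepeatFamilySpec | None = field(default_factory=RepeatFamilySpec)
    skew: SkewSpec | None = field(default_factory=SkewSpec)
    code_table: int = 4
    spacer_gc_factor: float = 0.8  # intergenic GC relative to genome GC
    min_spacer: int = 40
    seed: int = 0


@dataclass
class GroundTruth:
    genome: CircularGenome
    genes: list[GeneModel]
    anticodons: list[AnticodonRecord]
    repeat_pairs: list[RepeatPair]
    repeat_members: list[tuple[int, FeatureInterval, str]]  # family, locus, orientation
    duplication: InvertedDuplicationReport | None
    ori_position: int | None  # 1-based
    ter_position: int | None
    composition: CompositionBreakdown
    spec: SyntheticGenomeSpec


# ---------------------------------------------------------------------------
# sequence sampling helpers
# ---------------------------------------------------------------------------


def _codon_probs(code_table: int) -> tuple[list[str], np.ndarray]:
    """AT-rich codon distribution (W-ending codons preferred), stops removed."""
    p1 = {"A": 0.33, "T": 0.33, "G": 0.17, "C": 0.17}
    p3 = {"A": 0.435, "T": 0.435, "G": 0.065, "C": 0.065}
    stops = stop_codons(code_table)
    codons = [c for c in ALL_CODONS if c not in stops]
    w = np.array([p1[c[0]] * p1[c[1]] * p3[c[2]] for c in codons])
    return codons, w / w.sum()


def _sample_cds(rng: np.random.Generator, length: int, code_table: int) -> str:
    if length % 3:
        raise SpecError(f"coding length {length} not divisible by 3")
    codons, probs = _codon_probs(code_table)
    n = length // 3 - 1
    body = "".join(rng.choice(codons, size=n, p=probs)) if n > 0 else ""
    return body + "TAA"


class _ArcSampler:
    """Samples plus-strand bases with a G/C imbalance that flips at ori/ter."""

    def __init__(self, L: int, ori0: int | None, ter0: int | None, amplitude: float):
        self.L = L
        self.ori0 = ori0
        self.ter0 = ter0
        self.amp = amplitude if ori0 is not None else 0.0

    def sample(self, rng: np.random.Generator, s0: int, n: int, gc: float) -> np.ndarray:
        pos = (np.arange(s0, s0 + n)) % self.L
        if self.amp > 0 and self.ori0 is not None and self.ter0 is not None:
            arc_len = (self.ter0 - self.ori0) % self.L
            in_lead = ((pos - self.ori0) % self.L) < arc_len
            sign = np.where(in_lead, 1.0, -1.0)
        else:
            sign = np.zeros(n)
        pG = gc / 2.0 * (1.0 + self.amp * sign)
        pC = gc - pG
        pA = pT = (1.0 - gc) / 2.0
        probs = np.stack(
            [np.full(n, pA), np.full(n, pC), pG, np.full(n, pT)], axis=1
        )  # order A C G T
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        idx = (u[:, None] > cum).sum(axis=1)
        return np.array([ord("A"), ord("C"), ord("G"), ord("T")], dtype=np.uint8)[idx]


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    kind: str  # spacer | exon | intron | dupA | dupB | repeat
    length: int
    gene_idx: int | None = None
    meta: tuple | None = None  # repeat: (family, member, orientation, mut positions)
    start0: int = -1


def _split_coding(rng: np.random.Generator, total: int, pieces: int, min_piece: int = 30) -> list[int]:
    if pieces == 1:
        return [total]
    if total < pieces * min_piece:
        raise SpecError(f"cannot split {total} bp into {pieces} exons of >= {min_piece} bp")
    free = total - pieces * min_piece
    parts = rng.multinomial(free, np.ones(pieces) / pieces)
    return [min_piece + int(p) for p in parts]


def generate(spec: SyntheticGenomeSpec) -> GroundTruth:
    """Build a genome realizing the spec, with exhaustive ground truth.

    Deterministic under ``spec.seed``.  Raises :class:`SpecError` before any
    sequence is emitted when the requested features cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    gene_specs = spec.genes if spec.genes is not None else default_gene_set(rng)

    # --- phase 1: segment lengths ------------------------------------------
    gene_layouts: list[dict] = []
    for gi, gs in enumerate(gene_specs):
        if gs.feature_class == "protein":
            cds_len = gs.coding_length
            if cds_len % 3:
                raise SpecError(f"gene {gs.name}: coding length not divisible by 3")
        else:
            cds_len = gs.coding_length
        exon_sizes = _split_coding(rng, cds_len, gs.n_introns + 1)
        intron_sizes = [
            int(rng.integers(spec.intron_length_range[0], spec.intron_length_range[1] + 1))
            for _ in range(gs.n_introns)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_layouts.append(
            {"spec": gs, "exons": exon_sizes, "introns": intron_sizes, "strand": strand}
        )

    dup = spec.duplication
    dup_a_len = dup.length if dup else 0
    n_ins = n_del = 0
    if dup:
        classes = [dup.edit_classes[k % len(dup.edit_classes)] for k in range(dup.n_edits)]
        n_ins = classes.count("insertion")
        n_del = classes.count("deletion")
    dup_b_len = dup_a_len + n_ins - n_del

    items: list[_Segment | list[_Segment]] = []
    order = list(range(len(gene_layouts)))
    for gi in order:
        lay = gene_layouts[gi]
        segs: list[_Segment] = []
        tx_kinds = []  # transcription order
        for k, es in enumerate(lay["exons"]):
            tx_kinds.append(("exon", es))
            if k < len(lay["introns"]):
                tx_kinds.append(("intron", lay["introns"][k]))
        genomic = tx_kinds if lay["strand"] == "+" else tx_kinds[::-1]
        for kind, ln in genomic:
            segs.append(_Segment(kind=kind, length=ln, gene_idx=gi))
        items.append(segs)
    # repeat members are layout items of their own (always placeable, always
    # intergenic, separated by at least one minimum spacer)
    if spec.repeats and spec.repeats.n_families > 0:
        rs = spec.repeats
        for fam in range(rs.n_families):
            mlen = int(rng.integers(rs.member_length[0], rs.member_length[1] + 1))
            n_members = int(rng.integers(rs.members_per_family[0], rs.members_per_family[1] + 1))
            lo, hi = rs.edge_guard, mlen - rs.edge_guard
            n_mut = min(int(round((1 - rs.identity) * mlen)), hi - lo)
            for m in range(n_members):
                orient = "+" if (m == 0 or rng.random() < 0.5) else "-"
                # uniform placement, but dense clusters against either end
                # are rejected so planted boundaries stay score-maximal
                muts = (
                    _terminal_guarded_positions(
                        rng, lo, hi, n_mut, rs.identity, guard=rs.edge_guard)
                    if m > 0 else ()
                )
                seg = _Segment(kind="repeat", length=mlen, meta=(fam, m, orient, muts))
                items.insert(int(rng.integers(len(items) + 1)), [seg])

    if dup:
        # place the copies at the skew-arc midpoints, maximally clear of the
        # planted ori/ter flips: a multi-kbp skew-neutral block abutting a
        # flip would make the cumulative extremum ambiguous
        of = spec.skew.ori_frac if spec.skew else 0.0
        tf = spec.skew.ter_frac if spec.skew else 0.5
        target_a = ((of + (tf - of) % 1.0 / 2.0) % 1.0) * L
        target_b = ((tf + (of - tf) % 1.0 / 2.0) % 1.0) * L
        if target_a > target_b:
            target_a, target_b = target_b, target_a

        def slot_for(target: float) -> int:
            expected_spacer = spec.min_spacer + max(
                0, L - sum(sg.length for it in items for sg in it)
                - (len(items) + 3) * spec.min_spacer
            ) / (len(items) + 3)
            pos = expected_spacer
            for idx, it in enumerate(items):
                if pos >= target:
                    return idx
                pos += sum(sg.length for sg in it) + expected_spacer
            return len(items)

        kb = slot_for(target_b - dup_b_len / 2)
        ka = slot_for(target_a - dup_a_len / 2)
        items.insert(kb, [_Segment(kind="dupB", length=dup_b_len)])
        items.insert(ka, [_Segment(kind="dupA", length=dup_a_len)])

    fixed = sum(s.length for it in items for s in it)
    n_slots = len(items) + 1
    spare = L - fixed - n_slots * spec.min_spacer
    if spare < 0:
        raise SpecError(
            f"features need {fixed + n_slots * spec.min_spacer} bp but length is {L}"
        )
    extra = rng.multinomial(spare, np.ones(n_slots) / n_slots)
    spacer_lens = [spec.min_spacer + int(e) for e in extra]

    # interleave spacers and items; assign absolute offsets
    segments: list[_Segment] = []
    for si in range(len(items) + 1):
        segments.append(_Segment(kind="spacer", length=spacer_lens[si]))
        if si < len(items):
            segments.extend(items[si])
    pos = 0
    for seg in segments:
        seg.start0 = pos
        pos += seg.length
    assert pos == L

    # --- skew arcs (snapped to skew-eligible positions) --------------------
    # the duplication is not a skew carrier (see _balanced_sequence), so it
    # is not an eligible flip position either
    eligible = np.zeros(L, dtype=bool)
    for seg in segments:
        if seg.kind in ("spacer", "intron"):
            eligible[seg.start0 : seg.start0 + seg.length] = True
    if not eligible.any():
        eligible[:] = True  # degenerate all-coding layout: no snapping target
    ori0 = ter0 = None
    if spec.skew and spec.skew.amplitude > 0:
        ori0 = _snap(int(round(spec.skew.ori_frac * L)) % L, eligible, L)
        ter0 = _snap(int(round(spec.skew.ter_frac * L)) % L, eligible, L)
    sampler = _ArcSampler(L, ori0, ter0, spec.skew.amplitude if spec.skew else 0.0)

    # --- phase 2: sequence -------------------------------------------------
    seq = np.zeros(L, dtype=np.uint8)
    spacer_gc = spec.gc_fraction * spec.spacer_gc_factor
    dup_a_seg = next((s for s in segments if s.kind == "dupA"), None)
    dup_b_seg = next((s for s in segments if s.kind == "dupB"), None)

    cds_cache: dict[int, str] = {}
    for gi, lay in enumerate(gene_layouts):
        gs = lay["spec"]
        if gs.feature_class == "protein":
            cds_cache[gi] = _sample_cds(rng, gs.coding_length, spec.code_table)
        else:
            cds_cache[gi] = "".join(
                rng.choice(list("ACGT"), size=gs.coding_length,
                           p=[(1 - spec.gc_fraction) / 2, spec.gc_fraction / 2,
                              spec.gc_fraction / 2, (1 - spec.gc_fraction) / 2])
            )

    # family motifs, sampled once in family order for determinism
    motifs: dict[int, np.ndarray] = {}
    if spec.repeats:
        p = [(1 - spacer_gc) / 2, spacer_gc / 2, spacer_gc / 2, (1 - spacer_gc) / 2]
        fam_lens = {}
        for seg in segments:
            if seg.kind == "repeat":
                fam_lens.setdefault(seg.meta[0], seg.length)
        for fam in sorted(fam_lens):
            motifs[fam] = _BASES[rng.choice(4, size=fam_lens[fam], p=p)]

    exon_cursor: dict[int, int] = {gi: 0 for gi in range(len(gene_layouts))}
    for seg in segments:
        if seg.kind == "repeat":
            fam, m, orient, muts = seg.meta
            content = motifs[fam].copy()
            for pm in muts:
                old = int(content[pm])
                choices = [x for x in (65, 67, 71, 84) if x != old]
                content[pm] = int(rng.choice(choices))
            if orient == "-":
                comp = {65: 84, 67: 71, 71: 67, 84: 65}
                content = np.array([comp[int(x)] for x in content[::-1]], dtype=np.uint8)
            seq[seg.start0 : seg.start0 + seg.length] = content
        elif seg.kind in ("spacer", "intron"):
            gc = spacer_gc if seg.kind == "spacer" else spec.gc_fraction
            seq[seg.start0 : seg.start0 + seg.length] = sampler.sample(
                rng, seg.start0, seg.length, gc
            )
        elif seg.kind == "exon":
            gi = seg.gene_idx
            lay = gene_layouts[gi]
            # exon segments appear in genomic order; map back to the CDS chunk
            chunk_sizes = lay["exons"]
            gseq_sizes = chunk_sizes if lay["strand"] == "+" else chunk_sizes[::-1]
            k = exon_cursor[gi]
            exon_cursor[gi] += 1
            tx_index = k if lay["strand"] == "+" else len(chunk_sizes) - 1 - k
            cds = cds_cache[gi]
            off = sum(chunk_sizes[:tx_index])
            chunk = cds[off : off + chunk_sizes[tx_index]]
            if lay["strand"] == "-":
                chunk = gio.revcomp(chunk)
            seq[seg.start0 : seg.start0 + seg.length] = np.frombuffer(
                chunk.encode(), dtype=np.uint8
            )

    # --- duplication -------------------------------------------------------
    dup_truth: InvertedDuplicationReport | None = None
    if dup and dup_a_seg and dup_b_seg:
        a0, alen = dup_a_seg.start0, dup_a_seg.length
        a_seq = _balanced_sequence(rng, alen, spacer_gc)
        seq[a0 : a0 + alen] = a_seq
        b_plus, mismatches = _edit_copy(
            rng, a_seq, dup, dup_b_seg.start0, a0, L
        )
        seq[dup_b_seg.start0 : dup_b_seg.start0 + dup_b_seg.length] = b_plus
        _guard_flanks(seq, a0, alen, dup_b_seg.start0, dup_b_seg.length, rng)
        dup_truth = InvertedDuplicationReport(
            region_1=FeatureInterval(a0 + 1, a0 + alen, "+"),
            region_2=FeatureInterval(
                dup_b_seg.start0 + 1, dup_b_seg.start0 + dup_b_seg.length, "-"
            ),
            length=alen + n_ins,  # alignment columns: copy 1 plus its gaps
            identity=(alen + n_ins - dup.n_edits) / (alen + n_ins),
            mismatches=tuple(mismatches),
        )

    # --- repeat truth -------------------------------------------------------
    repeat_pairs: list[RepeatPair] = []
    repeat_members: list[tuple[int, FeatureInterval, str]] = []
    by_family: dict[int, list[_Segment]] = {}
    for seg in segments:
        if seg.kind == "repeat":
            by_family.setdefault(seg.meta[0], []).append(seg)
    for fam in sorted(by_family):
        members = sorted(by_family[fam], key=lambda s: s.meta[1])
        founder = members[0]
        founder_iv = FeatureInterval(founder.start0 + 1, founder.start0 + founder.length, "+")
        for seg in members:
            iv = FeatureInterval(seg.start0 + 1, seg.start0 + seg.length, "+")
            repeat_members.append((fam, iv, seg.meta[2]))
            if seg.meta[1] == 0:
                continue
            pairing = "direct" if seg.meta[2] == founder.meta[2] else "inverted"
            a, b = sorted((founder_iv, iv), key=lambda v: (v.start, v.end))
            repeat_pairs.append(
                RepeatPair(
                    interval_a=a,
                    interval_b=b,
                    orientation=pairing,  # type: ignore[arg-type]
                    identity=1.0 - len(seg.meta[3]) / seg.length,
                    length=seg.length,
                )
            )

    genome = CircularGenome("synthetic_mtDNA", seq.tobytes().decode())

    # --- gene models and truth ---------------------------------------------
    genes, anticodons = _gene_models(segments, gene_layouts, L)
    coding_bp = sum(g.coding_length(L) for g in genes)
    intronic_bp = sum(g.intron_length(L) for g in genes)
    composition = CompositionBreakdown(
        genome_bp=L,
        conserved_coding_bp=coding_bp,
        intronic_bp=intronic_bp,
        intergenic_bp=L - coding_bp - intronic_bp,
    )

    truth = GroundTruth(
        genome=genome,
        genes=genes,
        anticodons=anticodons,
        repeat_pairs=repeat_pairs,
        repeat_members=repeat_members,
        duplication=dup_truth,
        ori_position=ori0 + 1 if ori0 is not None else None,
        ter_position=ter0 + 1 if ter0 is not None else None,
        composition=composition,
        spec=spec,
    )
    if dup and dup.across_origin:
        truth = _rotate_truth(truth, (dup_b_seg.start0 + dup_b_seg.length // 2) % L)
    return truth


def _balanced_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random sequence with exactly balanced G/C (and A/T) counts.

    Used for the duplication copies: the reverse-complement copy carries the
    exact negation of the source's G-C imbalance, so a copy sampled with
    residual imbalance (or with arc-skewed composition) would plant a
    compositional dipole — or an outright counter-skew segment — that
    corrupts the genome's skew ground truth.  A balanced multiset makes the
    duplication strictly neutral for cumulative skew."""
    n_g = int(round(n * gc / 2))
    n_a = (n - 2 * n_g) // 2
    n_t = n - 2 * n_g - n_a
    pool = np.concatenate([
        np.full(n_a, ord("A"), dtype=np.uint8),
        np.full(n_g, ord("C"), dtype=np.uint8),
        np.full(n_g, ord("G"), dtype=np.uint8),
        np.full(n_t, ord("T"), dtype=np.uint8),
    ])
    return rng.permutation(pool)


def _terminal_guarded_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, identity: float,
    window: int = 50, max_tries: int = 500, guard: int = 5,
) -> tuple[int, ...]:
    """n distinct uniform positions in [lo, hi), resampled while a terminal
    mutation cluster would make the planted boundary score-suboptimal.

    A score-maximizing aligner (match +1, mismatch -2) trims any terminal
    stretch whose running score dips negative, so a draw that piles
    mutations against either end plants a boundary no detector can fairly
    be asked to recover.  The guard requires every prefix/suffix within
    ``window`` of either end to score >= 0; interior clusters are left
    alone — detectors must cross those on their own.
    """
    if n <= 0:
        return ()
    span = hi - lo + 2 * guard  # member span including the edge guards
    w = min(window, span)

    def terminal_ok(pos: np.ndarray) -> bool:
        is_mut = np.zeros(span, dtype=bool)
        is_mut[pos - lo + guard] = True
        for arr in (is_mut[-w:][::-1], is_mut[:w]):
            score = np.cumsum(np.where(arr, -2, 1))
            if score.min() < 1:  # strictly positive: ties truncate too
                return False
        return True

    pos = np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))
    for _ in range(max_tries):
        if terminal_ok(pos):
            break
        pos = np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))
    return tuple(int(x) for x in pos)


def _snap(desired0: int, eligible: np.ndarray, L: int, margin: int = 500) -> int:
    """Nearest position where the composition flip is actually expressed.

    A planted flip is only recoverable if skew-eligible sequence surrounds
    it; a flip at the edge of a long unskewed (coding) block would leave the
    cumulative curve flat on one side and the true extremum ill-defined.
    Require >= 80% eligible content within ``margin`` bp on each side.
    """
    ext = np.concatenate([eligible, eligible, eligible]).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(ext)])
    need = int(0.8 * margin)

    def qualifies(p0: int) -> bool:
        c = p0 + L  # center in the tripled array
        left = cum[c] - cum[c - margin]
        right = cum[c + margin] - cum[c]
        return eligible[p0] and left >= need and right >= need

    if qualifies(desired0):
        return desired0
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise SpecError("no skew-eligible positions (all coding)")
    order = np.argsort(np.minimum((idx - desired0) % L, (desired0 - idx) % L))
    for k in order:
        if qualifies(int(idx[k])):
            return int(idx[k])
    return int(idx[order[0]])  # fall back to nearest eligible position


def _edit_copy(
    rng: np.random.Generator,
    a_seq: np.ndarray,
    dup: DuplicationSpec,
    b_start0: int,
    a_start0: int,
    L: int,
) -> tuple[np.ndarray, list[MismatchRecord]]:
    """Reverse-complement copy with the requested edits; truth records are in
    copy-1 (region A) plus-strand coordinates, matching the detector."""
    comp = {65: 84, 67: 71, 71: 67, 84: 65}
    b = np.array([comp[int(x)] for x in a_seq[::-1]], dtype=np.uint8)
    alen = len(a_seq)
    guard = dup.edge_guard
    positions = np.sort(
        rng.choice(np.arange(guard, alen - guard), size=dup.n_edits, replace=False)
    )
    while np.any(np.diff(positions) < 2 * guard):  # keep edits apart
        positions = np.sort(
            rng.choice(np.arange(guard, alen - guard), size=dup.n_edits, replace=False)
        )
    classes = [dup.edit_classes[k % len(dup.edit_classes)] for k in range(dup.n_edits)]
    records: list[MismatchRecord] = []
    out = list(b)
    # apply edits from the right so earlier positions stay valid
    for pos_b, kind in sorted(zip(positions.tolist(), classes), reverse=True):
        # position in copy-1 coordinates: b index i aligns to a index alen-1-i
        a_idx = alen - 1 - pos_b
        a_pos = (a_start0 + a_idx) % L + 1
        if kind == "substitution":
            old = out[pos_b]
            choices = [x for x in (65, 67, 71, 84) if x != old]
            out[pos_b] = int(rng.choice(choices))
            records.append(
                MismatchRecord(a_pos, chr(a_seq[a_idx]), chr(comp[out[pos_b]]), "substitution")
            )
        elif kind == "insertion":
            out.insert(pos_b, int(rng.choice([65, 67, 71, 84])))
            records.append(MismatchRecord(a_pos, "-", chr(comp[out[pos_b]]), "insertion"))
        elif kind == "deletion":
            records.append(MismatchRecord(a_pos, chr(a_seq[a_idx]), "-", "deletion"))
            del out[pos_b]
        else:
            raise SpecError(f"unknown edit class {kind!r}")
    records.sort(key=lambda r: r.position)
    return np.array(out, dtype=np.uint8), records


def _guard_flanks(
    seq: np.ndarray, a0: int, alen: int, b0: int, blen: int, rng: np.random.Generator
) -> None:
    """Break reverse-complement continuation just outside both copies."""
    comp = {65: 84, 67: 71, 71: 67, 84: 65}
    L = len(seq)

    def fix(p: int, q: int) -> None:
        # ensure seq[p] != comp(seq[q])
        if seq[p % L] == comp[int(seq[q % L])]:
            choices = [x for x in (65, 67, 71, 84) if x != comp[int(seq[q % L])]]
            seq[p % L] = int(rng.choice(choices))

    fix(a0 + alen, b0 - 1)  # right of A vs left of B
    fix(a0 - 1, b0 + blen)  # left of A vs right of B


def _gene_models(
    segments: list[_Segment], gene_layouts: list[dict], L: int
) -> tuple[list[GeneModel], list[AnticodonRecord]]:
    by_gene: dict[int, list[_Segment]] = {}
    for seg in segments:
        if seg.gene_idx is not None:
            by_gene.setdefault(seg.gene_idx, []).append(seg)
    genes: list[GeneModel] = []
    anticodons: list[AnticodonRecord] = []
    intron_types = ["groupI", "groupII", "uncertain"]
    he_labels = ["GIY-YIG", "LAGLIDADG1", "LAGLIDADG2", "none", "none"]
    for gi, lay in enumerate(gene_layouts):
        gs = lay["spec"]
        segs = by_gene[gi]  # genomic order
        exon_ivs = [
            FeatureInterval(s.start0 + 1, s.start0 + s.length, lay["strand"])
            for s in segs if s.kind == "exon"
        ]
        intron_ivs = [
            FeatureInterval(s.start0 + 1, s.start0 + s.length, lay["strand"])
            for s in segs if s.kind == "intron"
        ]
        if lay["strand"] == "-":
            exon_ivs = exon_ivs[::-1]
            intron_ivs = intron_ivs[::-1]
        g = GeneModel(
            name=gs.name,
            feature_class=gs.feature_class,
            exons=exon_ivs,
            strand=lay["strand"],
            stop_codon="TAA" if gs.feature_class == "protein" else None,
        )
        # deterministic intron metadata derived from position, not the rng
        g.introns = [
            IntronRecord(
                ordinal=k + 1,
                interval=iv,
                intron_type=intron_types[iv.start % 3],
                he_label=he_labels[iv.start % 5],  # type: ignore[arg-type]
            )
            for k, iv in enumerate(intron_ivs)
        ]
        genes.append(g)
        if gs.feature_class == "tRNA" and gs.anticodon:
            anticodons.append(
                AnticodonRecord(gs.amino_acid or gs.name, gs.anticodon, g.span(L))
            )
    return genes, anticodons


def _rotate_truth(truth: GroundTruth, offset: int) -> GroundTruth:
    """Rotate the genome so previously interior features cross the origin."""
    L = len(truth.genome)
    g = truth.genome.rotate(offset)

    def sh(iv: FeatureInterval) -> FeatureInterval:
        return iv.shifted(offset, L)

    genes = []
    for gene in truth.genes:
        ng = GeneModel(
            name=gene.name,
            feature_class=gene.feature_class,
            exons=[sh(e) for e in gene.exons],
            strand=gene.strand,
            stop_codon=gene.stop_codon,
        )
        ng.introns = [
            IntronRecord(r.ordinal, sh(r.interval), r.intron_type, r.he_label)
            for r in gene.introns
        ]
        genes.append(ng)
    anticodons = [
        AnticodonRecord(a.amino_acid, a.anticodon, sh(a.locus)) for a in truth.anticodons
    ]
    pairs = [
        RepeatPair(sh(p.interval_a), sh(p.interval_b), p.orientation, p.identity,
                   p.length, p.score)
        for p in truth.repeat_pairs
    ]
    members = [(f, sh(iv), o) for f, iv, o in truth.repeat_members]
    dup = truth.duplication
    if dup is not None:
        shifted_mm = tuple(
            MismatchRecord((r.position - 1 - offset) % L + 1, r.base_1, r.base_2, r.kind)
            for r in dup.mismatches
        )
        dup = InvertedDuplicationReport(
            sh(dup.region_1), sh(dup.region_2), dup.length, dup.identity, shifted_mm
        )
    return GroundTruth(
        genome=g,
        genes=genes,
        anticodons=anticodons,
        repeat_pairs=pairs,
        repeat_members=members,
        duplication=dup,
        ori_position=((truth.ori_position - 1 - offset) % L + 1)
        if truth.ori_position else None,
        ter_position=((truth.ter_position - 1 - offset) % L + 1)
        if truth.ter_position else None,
        composition=truth.composition,
        spec=truth.spec,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Emit FASTA + GFF3 + truth tables; :func:`load_truth` reads them back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_genome_fasta(truth.genome, out / "genome.fasta")
    gio.write_annotation(
        truth.genes, out / "annotation.gff3", "gff3",
        genome=truth.genome, anticodons=truth.anticodons,
    )
    rows = ["family\tstart\tend\torientation"]
    for fam, iv, orient in truth.repeat_members:
        rows.append(f"{fam}\t{iv.start}\t{iv.end}\t{orient}")
    (out / "repeat_members.tsv").write_text("\n".join(rows) + "\n")
    rows = ["a_start\ta_end\tb_start\tb_end\torientation\tidentity\tlength"]
    for p in truth.repeat_pairs:
        rows.append(
            f"{p.interval_a.start}\t{p.interval_a.end}\t{p.interval_b.start}\t"
            f"{p.interval_b.end}\t{p.orientation}\t{p.identity:.6f}\t{p.length}"
        )
    (out / "repeat_pairs.tsv").write_text("\n".join(rows) + "\n")
    meta = {
        "ori_position": truth.ori_position,
        "ter_position": truth.ter_position,
        "composition": {
            "genome_bp": truth.composition.genome_bp,
            "conserved_coding_bp": truth.composition.conserved_coding_bp,
            "intronic_bp": truth.composition.intronic_bp,
            "intergenic_bp": truth.composition.intergenic_bp,
        },
        "duplication": None,
        "seed": truth.spec.seed,
    }
    if truth.duplication is not None:
        d = truth.duplication
        meta["duplication"] = {
            "region_1": [d.region_1.start, d.region_1.end, d.region_1.wraps_origin],
            "region_2": [d.region_2.start, d.region_2.end, d.region_2.wraps_origin],
            "length": d.length,
            "identity": d.identity,
            "mismatches": [
                [r.position, r.base_1, r.base_2, r.kind] for r in d.mismatches
            ],
        }
    (out / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_truth(out_dir: str | Path) -> dict:
    """Read back the persisted truth (genome, annotation, tables)."""
    out = Path(out_dir)
    genome, genes, anticodons = gio.read_annotated_genome(
        out / "annotation.gff3", "gff3+fasta", fasta_path=out / "genome.fasta"
    )
    meta = json.loads((out / "truth.json").read_text())
    members = []
    for line in (out / "repeat_members.tsv").read_text().splitlines()[1:]:
        fam, s, e, orient = line.split("\t")
        members.append((int(fam), FeatureInterval(int(s), int(e), "+"), orient))
    pairs = []
    for line in (out / "repeat_pairs.tsv").read_text().splitlines()[1:]:
        a_s, a_e, b_s, b_e, orient, ident, ln = line.split("\t")
        pairs.append(
            RepeatPair(
                FeatureInterval(int(a_s), int(a_e), "+"),
                FeatureInterval(int(b_s), int(b_e), "+"),
                orient,  # type: ignore[arg-type]
                float(ident),
                int(ln),
            )
        )
    return {
        "genome": genome,
        "genes": genes,
        "anticodons": anticodons,
        "repeat_members": members,
        "repeat_pairs": pairs,
        "meta": meta,
    }
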