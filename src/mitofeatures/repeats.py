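"""Repeat discovery by genome self-comparison, identity clustering, and
inverted-duplication detection.

Discovery seeds exact k-mer matches of the genome against itself (forward
strand for direct repeats, against the reverse complement for inverted
ones), merges co-diagonal seeds, extends them ungapped under an X-drop
criterion, and scores the resulting interval pairs with an edit-distance
alignment so small indels still count correctly toward identity.  Hits are
allowed to cross the origin of a circular molecule.  An E-value-like
Karlin-Altschul score is attached for reporting; filtering is purely by
length and identity.

Clustering is CD-HIT-style greedy incremental clustering: members sorted
longest first, each joining the first representative it matches at or above
the cutoff, cascaded over consecutive cutoffs (default 0.75, 0.80, 0.90).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import edlib
import numpy as np

from .genome_io import CircularGenome, FeatureInterval, GeneModel, revcomp
from .structure_stats import composition_mask

__all__ = [
    "RepeatPair",
    "RepeatCluster",
    "MismatchRecord",
    "InvertedDuplicationReport",
    "RepeatCoverage",
    "self_compare",
    "cluster_repeats",
    "find_inverted_duplication",
    "repeat_coverage",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

# Karlin-Altschul parameters for +1/-2 nucleotide scoring (reporting only)
_KA_LAMBDA, _KA_K = 1.33, 0.621


@dataclass(frozen=True)
class RepeatPair:
    interval_a: FeatureInterval
    interval_b: FeatureInterval
    orientation: Literal["direct", "inverted"]
    identity: float  # matches / alignment columns, in [0, 1]
    length: int  # alignment columns
    score: float | None = None  # E-value-like, smaller is more significant


@dataclass
class RepeatCluster:
    members: list[FeatureInterval]
    representative: FeatureInterval  # longest member (founder)
    cutoff_level: float


@dataclass(frozen=True)
class MismatchRecord:
    """One difference between duplication copies, in copy-1 coordinates.

    ``kind`` is relative to the second copy: an ``insertion`` is a base the
    second copy carries that the first lacks; ``base_1``/``base_2`` give the
    plus-strand base of copy 1 and the aligned (reverse-complemented) base of
    copy 2, '-' for a gap.
    """

    position: int
    base_1: str
    base_2: str
    kind: Literal["substitution", "insertion", "deletion"]


@dataclass(frozen=True)
class InvertedDuplicationReport:
    region_1: FeatureInterval
    region_2: FeatureInterval
    length: int  # alignment columns of the copy-vs-copy alignment
    identity: float
    mismatches: tuple[MismatchRecord, ...]


@dataclass(frozen=True)
class RepeatCoverage:
    total_bp: int
    total_fraction: float
    by_category: dict[str, int]  # coding / intronic / intergenic bp
    genome_bp: int


# ---------------------------------------------------------------------------
# seeding and extension
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int, max_occ: int = 1000) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return {km: ps for km, ps in index.items() if len(ps) <= max_occ}


def _merge_runs(starts: list[int], k: int, gap: int) -> list[tuple[int, int]]:
    """Merge sorted seed starts into covered runs [s, e) allowing gaps."""
    runs: list[tuple[int, int]] = []
    for i in starts:
        if runs and i <= runs[-1][1] + gap:
            runs[-1] = (runs[-1][0], max(runs[-1][1], i + k))
        else:
            runs.append((i, i + k))
    return runs


def _xdrop_extend(
    seq: str,
    a: tuple[int, int],
    b: tuple[int, int],
    inverted: bool,
    xdrop: int,
    exact: bool,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Ungapped X-drop extension of an anchored interval pair.

    For inverted pairs, extending copy a rightwards consumes copy b leftwards
    and vice versa.  In ``exact`` mode extension stops at the first mismatch
    (maximal exact match semantics).
    """
    n = len(seq)
    (as_, ae), (bs, be) = a, b

    def run(side: Literal["right", "left"]) -> int:
        nonlocal as_, ae, bs, be
        score = best = 0
        steps = best_t = 0
        t = 0
        while True:
            if side == "right":
                ia = ae + t
                ib = (bs - 1 - t) if inverted else (be + t)
            else:
                ia = as_ - 1 - t
                ib = (be + t) if inverted else (bs - 1 - t)
            if ia < 0 or ia >= n or ib < 0 or ib >= n:
                break
            ca, cb = seq[ia], seq[ib]
            if inverted:
                cb = cb.translate(_COMP)
            if ca == cb and ca != "N":
                score += 1
                if score > best:
                    best, best_t = score, t + 1
            else:
                if exact:
                    break
                score -= 2
                if best - score > xdrop:
                    break
            t += 1
        return best_t

    ext = run("right")
    ae += ext
    if inverted:
        bs -= ext
    else:
        be += ext
    ext = run("left")
    as_ -= ext
    if inverted:
        be += ext
    else:
        bs -= ext
    return (as_, ae), (bs, be)


def _interval_mod(s0: int, e0: int, L: int, strand: str = "+") -> FeatureInterval:
    """0-based half-open [s0, e0) on the extended axis -> genomic interval."""
    start = s0 % L + 1
    wraps = (s0 % L) + (e0 - s0) > L
    end = (e0 - 1) % L + 1
    return FeatureInterval(start, end, strand, wraps_origin=wraps)  # type: ignore[arg-type]


def _alignment_stats(qa: str, ta: str) -> tuple[float, int, str]:
    """Identity, alignment columns and cigar of an edit-distance alignment."""
    res = edlib.align(qa, ta, task="path", mode="NW")
    cigar = res["cigar"] or ""
    cols = matches = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ln = int(num)
            num = ""
            cols += ln
            if ch == "=":
                matches += ln
    return (matches / cols if cols else 0.0), cols, cigar


def _evalue(matches: int, cols: int, L: int) -> float:
    raw = matches - 2 * (cols - matches)
    return _KA_K * float(L) * float(L) * math.exp(-_KA_LAMBDA * max(raw, 0))


def self_compare(
    genome: CircularGenome,
    seed_k: int = 11,
    min_len: int = 30,
    min_identity: float = 0.75,
    orientation: Literal["direct", "inverted", "both"] = "both",
    max_gap: int = 40,
    xdrop: int = 25,
    wrap_overhang: int = 1000,
) -> list[RepeatPair]:
    """Find direct and/or inverted repeat pairs by genome self-comparison.

    The trivial full-length self-hit and symmetric (a,b)/(b,a) duplicates are
    removed; hits may cross the origin.  With ``min_identity=1.0`` the result
    is exactly the set of maximal exact repeat pairs of length >= min_len.
    """
    if seed_k < 8:
        raise ValueError("seed_k must be >= 8")
    if min_len < seed_k:
        raise ValueError("min_len must be >= seed_k")
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    L = len(genome)
    exact = min_identity >= 1.0
    gap = 0 if exact else max_gap
    W = min(L - 1, wrap_overhang) if genome.circular else 0
    seq = genome.residues + genome.residues[:W]
    index = _kmer_index(seq, seed_k)
    pairs: list[RepeatPair] = []
    seen: set[tuple] = set()

    def emit(a: tuple[int, int], b: tuple[int, int], inverted: bool) -> None:
        (as_, ae), (bs, be) = a, b
        if ae - as_ < min_len or be - bs < min_len:
            return
        iv_a = _interval_mod(as_, ae, L)
        iv_b = _interval_mod(bs, be, L)
        ka = (iv_a.start, iv_a.end, iv_a.wraps_origin)
        kb = (iv_b.start, iv_b.end, iv_b.wraps_origin)
        if ka == kb:
            return  # trivial self-hit
        key = (min(ka, kb), max(ka, kb), inverted)
        if key in seen:
            return
        sa = seq[as_:ae]
        sb = seq[bs:be]
        if inverted:
            sb = revcomp(sb)
        identity, cols, _ = _alignment_stats(sa, sb)
        if identity < min_identity or cols < min_len:
            return
        seen.add(key)
        matches = round(identity * cols)
        first, second = (iv_a, iv_b) if ka <= kb else (iv_b, iv_a)
        pairs.append(
            RepeatPair(
                interval_a=first,
                interval_b=second,
                orientation="inverted" if inverted else "direct",
                identity=identity,
                length=cols,
                score=_evalue(matches, cols, L),
            )
        )

    if orientation in ("direct", "both"):
        by_diagonal: dict[int, list[tuple[int, int]]] = {}
        for positions in index.values():
            for x in range(len(positions)):
                i = positions[x]
                if i >= L:
                    continue
                for y in range(x + 1, len(positions)):
                    j = positions[y]
                    d = j - i
                    if d == 0 or d % L == 0:
                        continue
                    by_diagonal.setdefault(d, []).append((i, j))
        for d, ij in by_diagonal.items():
            starts = sorted(i for i, _ in ij)
            for rs, re_ in _merge_runs(starts, seed_k, gap):
                a, b = _xdrop_extend(seq, (rs, re_), (rs + d, re_ + d), False, xdrop, exact)
                emit(a, b, False)

    if orientation in ("inverted", "both"):
        by_anti: dict[int, list[tuple[int, int]]] = {}
        for i in range(min(L, len(seq) - seed_k + 1)):
            kmer = seq[i : i + seed_k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            for j in index.get(rc, ()):
                if j <= i:
                    continue
                by_anti.setdefault(i + j, []).append((i, j))
        for c, ij in by_anti.items():
            starts = sorted(i for i, _ in ij)
            for rs, re_ in _merge_runs(starts, seed_k, gap):
                # b span mirrors the a span on the anti-diagonal
                bs, be = c - (re_ - seed_k), c - rs + seed_k
                a, b = _xdrop_extend(seq, (rs, re_), (bs, be), True, xdrop, exact)
                emit(a, b, True)

    pairs.sort(key=lambda p: (-p.length, p.interval_a.start, p.interval_b.start))
    return pairs


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _member_identity(seq_a: str, seq_b: str) -> float:
    """Best of direct and reverse-complement alignment identity."""
    ident_f, _, _ = _alignment_stats(seq_a, seq_b)
    ident_r, _, _ = _alignment_stats(seq_a, revcomp(seq_b))
    return max(ident_f, ident_r)


def _greedy_cluster(
    members: list[FeatureInterval], seqs: dict[tuple, str], cutoff: float
) -> list[RepeatCluster]:
    ordered = sorted(
        members,
        key=lambda iv: (-(len(seqs[_ikey(iv)])), iv.start, iv.end),
    )
    clusters: list[RepeatCluster] = []
    for iv in ordered:
        placed = False
        for cl in clusters:
            if _member_identity(seqs[_ikey(cl.representative)], seqs[_ikey(iv)]) >= cutoff:
                cl.members.append(iv)
                placed = True
                break
        if not placed:
            clusters.append(RepeatCluster(members=[iv], representative=iv, cutoff_level=cutoff))
    return clusters


def _ikey(iv: FeatureInterval) -> tuple:
    return (iv.start, iv.end, iv.wraps_origin)


def cluster_repeats(
    pairs: Sequence[RepeatPair],
    genome: CircularGenome,
    cutoffs: Sequence[float] = (0.75, 0.80, 0.90),
) -> dict[float, list[RepeatCluster]]:
    """Greedy longest-first clustering of repeat intervals, cascaded over
    ascending identity cutoffs; every member aligns to its cluster's
    representative at >= the level's cutoff.  Cluster counts are
    non-decreasing along the cascade (each level refines the previous)."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must ascend in cascade order")
    members_by_key: dict[tuple, FeatureInterval] = {}
    for p in pairs:
        for iv in (p.interval_a, p.interval_b):
            members_by_key.setdefault(_ikey(iv), iv)
    members = list(members_by_key.values())
    seqs = {k: genome.fetch(iv) for k, iv in members_by_key.items()}
    out: dict[float, list[RepeatCluster]] = {}
    if not members:
        return {c: [] for c in cutoffs}
    current = [RepeatCluster(members=list(members), representative=members[0], cutoff_level=0.0)]
    for cutoff in cutoffs:
        nxt: list[RepeatCluster] = []
        for cl in current:
            nxt.extend(_greedy_cluster(cl.members, seqs, cutoff))
        out[cutoff] = nxt
        current = nxt
    return out


# ---------------------------------------------------------------------------
# inverted duplication
# ---------------------------------------------------------------------------


def find_inverted_duplication(
    genome: CircularGenome,
    min_len: int = 1000,
    seed_k: int = 21,
    band: int = 30,
    max_gap: int = 800,
    identity_floor: float = 0.9,
) -> list[InvertedDuplicationReport]:
    """Locate long near-identical inverted region pairs and list their
    differences (substitutions and indels separately).

    Seeds exact ``seed_k``-mers against the reverse complement, chains
    co-anti-diagonal seeds (within ``band`` to absorb indel shifts), extends
    the chained ends while exact matching continues, and aligns copy 1
    against the reverse complement of copy 2 to produce the mismatch list.
    Wrap across the origin is handled by overhang extension.
    """
    L = len(genome)
    W = min(L - 1, max(min_len * 2, 8000)) if genome.circular else 0
    seq = genome.residues + genome.residues[:W]
    index = _kmer_index(seq, seed_k)
    seeds: list[tuple[int, int]] = []
    for i in range(min(L, len(seq) - seed_k + 1)):
        kmer = seq[i : i + seed_k]
        if "N" in kmer:
            continue
        for j in index.get(revcomp(kmer), ()):
            if j > i:
                seeds.append((i, j))
    seeds.sort()
    # chain seeds whose anti-diagonals agree within the band
    chains: list[dict] = []
    for i, j in seeds:
        c = i + j
        placed = False
        for ch in chains:
            if abs(c - ch["c"]) <= band and 0 <= i - ch["imax"] <= max_gap:
                ch["imax"] = max(ch["imax"], i)
                ch["imin"] = min(ch["imin"], i)
                ch["jmax"] = max(ch["jmax"], j)
                ch["jmin"] = min(ch["jmin"], j)
                ch["c"] = c
                placed = True
                break
        if not placed:
            chains.append({"imin": i, "imax": i, "jmin": j, "jmax": j, "c": c})
    reports: list[InvertedDuplicationReport] = []
    seen: set[tuple] = set()
    for ch in chains:
        as_, ae = ch["imin"], ch["imax"] + seed_k
        bs, be = ch["jmin"], ch["jmax"] + seed_k
        if ae - as_ < min_len // 2:
            continue
        (as_, ae), (bs, be) = _xdrop_extend(seq, (as_, ae), (bs, be), True, 0, True)
        if ae - as_ < min_len:
            continue
        if not (ae <= bs or be <= as_):
            continue  # overlapping copies: not a duplication pair
        sa = seq[as_:ae]
        sb_rc = revcomp(seq[bs:be])
        identity, cols, cigar = _alignment_stats(sa, sb_rc)
        if identity < identity_floor:
            continue
        iv_a = _interval_mod(as_, ae, L)
        iv_b = _interval_mod(bs, be, L, strand="-")
        key = (min(_ikey(iv_a), _ikey(iv_b)), max(_ikey(iv_a), _ikey(iv_b)))
        if key in seen:
            continue
        seen.add(key)
        mismatches = _mismatches_from_cigar(cigar, sa, sb_rc, as_, L)
        reports.append(
            InvertedDuplicationReport(
                region_1=iv_a,
                region_2=iv_b,
                length=cols,
                identity=identity,
                mismatches=tuple(mismatches),
            )
        )
    reports.sort(key=lambda r: -r.length)
    # drop reports fully contained in a longer one (circular-overhang echoes)
    kept: list[InvertedDuplicationReport] = []
    for rep in reports:
        cover = np.zeros(L, dtype=bool)
        contained = False
        for other in kept:
            cover[:] = False
            for iv in (other.region_1, other.region_2):
                s0, e0 = iv.unrolled(L)
                if e0 <= L:
                    cover[s0:e0] = True
                else:
                    cover[s0:L] = True
                    cover[: e0 - L] = True
            ok = True
            for iv in (rep.region_1, rep.region_2):
                s0, e0 = iv.unrolled(L)
                idx = np.arange(s0, e0) % L
                if not cover[idx].all():
                    ok = False
                    break
            if ok:
                contained = True
                break
        if not contained:
            kept.append(rep)
    return kept


def _mismatches_from_cigar(
    cigar: str, sa: str, sb: str, a_offset0: int, L: int
) -> list[MismatchRecord]:
    """Walk an edlib NW cigar into per-difference records.

    Query is copy 1, target is revcomp(copy 2): cigar 'I' means copy 1 has a
    base copy 2 lacks (a deletion in copy 2), 'D' the opposite.
    """
    records: list[MismatchRecord] = []
    qa = ta = 0  # cursors in sa (copy 1) and sb (rc of copy 2)
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch == "=":
            qa += ln
            ta += ln
        elif ch == "X":
            for t in range(ln):
                pos = (a_offset0 + qa + t) % L + 1
                records.append(MismatchRecord(pos, sa[qa + t], sb[ta + t], "substitution"))
            qa += ln
            ta += ln
        elif ch == "I":  # base only in copy 1
            for t in range(ln):
                pos = (a_offset0 + qa + t) % L + 1
                records.append(MismatchRecord(pos, sa[qa + t], "-", "deletion"))
            qa += ln
        elif ch == "D":  # base only in copy 2
            pos = (a_offset0 + qa - 1) % L + 1  # anchored after this copy-1 base
            for t in range(ln):
                records.append(MismatchRecord(pos, "-", sb[ta + t], "insertion"))
            ta += ln
    return records


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def repeat_coverage(
    pairs: Sequence[RepeatPair],
    genes: Sequence[GeneModel],
    genome: CircularGenome,
) -> RepeatCoverage:
    """Union repeat coverage projected onto the coding/intronic/intergenic
    partition (overlapping repeat intervals merged before counting)."""
    L = len(genome)
    covered = np.zeros(L, dtype=bool)
    for p in pairs:
        for iv in (p.interval_a, p.interval_b):
            s0, e0 = iv.unrolled(L)
            if e0 <= L:
                covered[s0:e0] = True
            else:
                covered[s0:L] = True
                covered[: e0 - L] = True
    mask = composition_mask(genome, genes)
    names = {0: "intergenic", 1: "intronic", 2: "coding"}
    by_cat = {name: int(np.sum(covered & (mask == code))) for code, name in names.items()}
    total = int(covered.sum())
    return RepeatCoverage(
        total_bp=total,
        total_fraction=total / L,
        by_category=by_cat,
        genome_bp=L,
    )
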