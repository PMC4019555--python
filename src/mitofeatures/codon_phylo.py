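"""Codon-usage tabulation, usage-distance phylogenetics, CAI, positional GC.

Distances between taxa are computed codon-on-codon from relative codon
frequencies: the root-mean-squared difference (RMSD) or the plain sum of
squared differences over a shared codon set (sense codons of the configured
genetic code by default, stop codons excluded).  Trees are reconstructed with
Saitou-Nei neighbor joining, deterministic under a lexicographic tie-break.
The Codon Adaptation Index follows Sharp & Li: geometric mean of relative
adaptiveness values w(c) = f(c)/max f within each synonymous family of a
reference usage table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "CodonUsageTable",
    "count_codons",
    "rmsd_distance",
    "sum_squared_distance",
    "usage_distance_matrix",
    "neighbor_joining",
    "compute_cai",
    "positional_gc",
    "codon_families",
    "EmptyUsageError",
]

BASES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))


class EmptyUsageError(ValueError):
    """A usage table without observed codons cannot enter a distance/CAI."""


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def stop_codons(code_table: int = 4) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[code_table].stop_codons)


def sense_codons(code_table: int = 4) -> tuple[str, ...]:
    stops = stop_codons(code_table)
    return tuple(c for c in ALL_CODONS if c not in stops)


def codon_families(code_table: int = 4) -> dict[str, tuple[str, ...]]:
    """Amino acid -> synonymous sense codons under the given NCBI code."""
    table = CodonTable.unambiguous_dna_by_id[code_table]
    fams: dict[str, list[str]] = {}
    for codon in sense_codons(code_table):
        fams.setdefault(table.forward_table[codon], []).append(codon)
    return {aa: tuple(cs) for aa, cs in fams.items()}


@dataclass
class CodonUsageTable:
    """Codon counts for a set of coding sequences from one taxon."""

    taxon: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    ambiguous: int = 0  # codons skipped for containing non-ACGT bases

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(
        self, code_table: int = 4, include_stops: bool = False
    ) -> dict[str, float]:
        """Counts normalized to sum 1 over the included codon set."""
        codons = ALL_CODONS if include_stops else sense_codons(code_table)
        total = sum(self.counts[c] for c in codons)
        if total == 0:
            raise EmptyUsageError(f"usage table {self.taxon!r} has no observed codons")
        return {c: self.counts[c] / total for c in codons}

    def family_fractions(self, code_table: int = 4) -> dict[str, dict[str, float]]:
        """Within-family synonymous codon percentages (RSCU-style shares)."""
        out: dict[str, dict[str, float]] = {}
        for aa, codons in codon_families(code_table).items():
            fam_total = sum(self.counts[c] for c in codons)
            if fam_total:
                out[aa] = {c: self.counts[c] / fam_total for c in codons}
        return out


def count_codons(cds_set: Iterable[str], taxon: str = "") -> CodonUsageTable:
    """Tabulate codons over concatenated CDSs (each length-divisible by 3).

    Codons containing ambiguous bases are skipped and tallied in
    ``ambiguous`` rather than counted.
    """
    table = CodonUsageTable(taxon=taxon)
    for cds in cds_set:
        s = _clean(cds)
        if len(s) % 3:
            raise ValueError(f"CDS length {len(s)} not divisible by 3")
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if codon in table.counts:
                table.counts[codon] += 1
            else:
                table.ambiguous += 1
    return table


def _freq_vectors(
    a: CodonUsageTable,
    b: CodonUsageTable,
    code_table: int,
    include_stops: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    codons = ALL_CODONS if include_stops else sense_codons(code_table)
    fa = a.frequencies(code_table, include_stops)
    fb = b.frequencies(code_table, include_stops)
    va = np.array([fa[c] for c in codons])
    vb = np.array([fb[c] for c in codons])
    return va, vb, len(codons)


def rmsd_distance(
    a: CodonUsageTable,
    b: CodonUsageTable,
    code_table: int = 4,
    include_stops: bool = False,
) -> float:
    """sqrt(mean over included codons of squared frequency difference)."""
    va, vb, n = _freq_vectors(a, b, code_table, include_stops)
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def sum_squared_distance(
    a: CodonUsageTable,
    b: CodonUsageTable,
    code_table: int = 4,
    include_stops: bool = False,
) -> float:
    """Sum of squared frequency differences (no mean, no root)."""
    va, vb, _ = _freq_vectors(a, b, code_table, include_stops)
    return float(np.sum((va - vb) ** 2))


def usage_distance_matrix(
    tables: Sequence[CodonUsageTable],
    metric: str = "rmsd",
    code_table: int = 4,
    include_stops: bool = False,
) -> DistanceMatrix:
    """Taxa-by-taxa codon-usage distance matrix."""
    fn = {"rmsd": rmsd_distance, "ssd": sum_squared_distance}[metric]
    n = len(tables)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = fn(tables[i], tables[j], code_table, include_stops)
    return DistanceMatrix(m, ids=[t.taxon for t in tables])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted (trifurcating) tree.

    At every step the pair minimizing Q(i,j) = (n-2)d(i,j) - r_i - r_j is
    joined; ties are broken on the lexicographically smallest pair of node
    labels, where a working node is labelled by the smallest leaf name in its
    subtree, so the result is deterministic.  Negative branch lengths are
    clamped to zero with the deficit transferred to the sister branch (raw
    values kept on the node as ``raw_length``).
    """
    d = np.asarray(dm.data, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    names = list(dm.ids)
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=nm) for nm in names]
    labels = list(names)  # smallest leaf name per working node

    active = list(range(n))
    dist = d.copy()

    def _join(i: int, j: int, li: float, lj: float) -> None:
        if clamp_negative:
            li, lj = _clamp_pair(nodes[i], nodes[j], li, lj)
        nodes[i].length = li
        nodes[j].length = lj

    def _clamp_pair(a: TreeNode, b: TreeNode, la: float, lb: float) -> tuple[float, float]:
        a.raw_length, b.raw_length = la, lb
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                la, lb = labels[active[ai]], labels[active[aj]]
                key = (q, min(la, lb), max(la, lb))
                if best is None or key < best[0:3]:
                    best = (*key, ai, aj)
        assert best is not None
        _, _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        _join(i, j, li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        # distances from the new node to the remaining active nodes
        new_row = np.zeros(len(nodes))
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row)] = new_row
        dist[: len(new_row), -1] = new_row
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # closed-form three-point resolution of the last three nodes
    i, j, k = active
    dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.raw_length = ln
        node.length = max(ln, 0.0) if clamp_negative else ln
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


# ---------------------------------------------------------------------------
# Codon Adaptation Index
# ---------------------------------------------------------------------------


def compute_cai(
    orf: str,
    reference: CodonUsageTable,
    code_table: int = 4,
) -> float:
    """Sharp-Li CAI of an ORF against a reference usage table.

    w(c) = count(c) / max count within c's synonymous family in the
    reference; codons unobserved in the reference receive the
    pseudo-adaptiveness 0.5 / (family max count) so a single missing codon
    does not collapse the index to zero.  Families with a single sense codon
    under the configured code, stop codons, and codons from reference
    families with zero total count are excluded from the geometric mean.
    """
    s = _clean(orf)
    if len(s) % 3:
        raise ValueError(f"ORF length {len(s)} not divisible by 3")
    fams = codon_families(code_table)
    w: dict[str, float] = {}
    for aa, codons in fams.items():
        if len(codons) < 2:
            continue  # single-codon family carries no usage information
        fam_max = max(reference.counts[c] for c in codons)
        if fam_max == 0:
            continue  # zero-count family: excluded (cannot define w)
        for c in codons:
            cnt = reference.counts[c]
            w[c] = (cnt if cnt > 0 else 0.5) / fam_max
    log_sum, n = 0.0, 0
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if codon in w:
            log_sum += math.log(w[codon])
            n += 1
    if n == 0:
        raise EmptyUsageError("no CAI-informative codons in the ORF")
    return math.exp(log_sum / n)


def positional_gc(cds_set: Iterable[str]) -> tuple[float, float, float, float]:
    """(overall, 1st, 2nd, 3rd codon position) GC percentages over CDSs."""
    counts = np.zeros(3)
    totals = np.zeros(3)
    for cds in cds_set:
        s = _clean(cds)
        if len(s) % 3:
            raise ValueError(f"CDS length {len(s)} not divisible by 3")
        for pos in range(3):
            sub = s[pos::3]
            counts[pos] += sub.count("G") + sub.count("C")
            totals[pos] += sum(sub.count(b) for b in "ACGT")
    if totals.sum() == 0:
        raise EmptyUsageError("no coding sequence provided")
    per_pos = 100.0 * counts / np.where(totals > 0, totals, 1)
    overall = 100.0 * counts.sum() / totals.sum()
    return float(overall), float(per_pos[0]), float(per_pos[1]), float(per_pos[2])
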