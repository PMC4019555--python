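"""tRNA wobble-decoding sufficiency and homing-endonuclease locus analysis.

Decoding follows Mycoplasma-style sparse-tRNA wobble rules: the anticodon
first (wobble) base U pairs with all four codon third-position bases, G
pairs with C or U, and A or C pair only Watson-Crick.  A codon used in the
conserved ORF set but decodable by no tRNA is flagged; codons used only
outside conserved ORFs are candidate unassigned codons.  One CAU-anticodon
tRNA may optionally be treated as an Ile isoacceptor (the anticodon is
presumed edited/modified), in which case it decodes AUA.

Homing-endonuclease core domains are compared by global pairwise alignment
identity and by circular genomic distance between locus midpoints; the two
matrices are correlated (Pearson or Spearman, optional log transform of
similarity) with both the classical p-value and a seeded Mantel permutation
p-value, since pairwise matrices violate the independence assumption of the
classical test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from scipy import stats

from .codon_phylo import CodonUsageTable, sense_codons
from .genome_io import AnticodonRecord, FeatureInterval

__all__ = [
    "DecodingReport",
    "HEDomainRecord",
    "CorrelationResult",
    "wobble_decodes",
    "decoding_check",
    "pairwise_identity",
    "circular_distance_matrix",
    "correlate_similarity_distance",
]

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"U": ("A", "G", "C", "U"), "G": ("C", "U"), "A": ("U",), "C": ("G",)}


def wobble_decodes(anticodon: str, ile_reassignment: bool = False) -> frozenset[str]:
    """Codons (RNA, 5'->3') readable by a tRNA with this anticodon.

    Positions 2 and 3 of the anticodon pair Watson-Crick with codon
    positions 2 and 1; the wobble expansion applies at the anticodon's first
    base against the codon third position.  With ``ile_reassignment`` a CAU
    anticodon is taken as an edited/modified Ile isoacceptor reading AUA.
    """
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or set(ac) - set("ACGU"):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    if ac == "CAU" and ile_reassignment:
        return frozenset({"AUA"})
    codon_12 = _RNA_COMP[ac[2]] + _RNA_COMP[ac[1]]
    return frozenset(codon_12 + third for third in _WOBBLE[ac[0]])


@dataclass
class DecodingReport:
    decodable: frozenset[str]  # RNA codons some tRNA can read
    undecodable: frozenset[str]  # sense codons no tRNA reads
    undecodable_used: dict[str, int]  # of those, used in conserved ORFs
    unassigned_candidates: dict[str, int]  # zero conserved use, used elsewhere
    notes: list[str] = field(default_factory=list)

    @property
    def sufficient(self) -> bool:
        """True when every conserved-ORF codon is readable by some tRNA."""
        return not self.undecodable_used


def _as_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def decoding_check(
    anticodons: Sequence[AnticodonRecord],
    conserved_usage: CodonUsageTable,
    other_usage: CodonUsageTable | None = None,
    code_table: int = 4,
    cau_as_ile: bool = True,
) -> DecodingReport:
    """Check whether a tRNA set can read every codon the conserved ORFs use.

    ``decodable`` and ``undecodable`` partition the sense codons of the
    configured code.  When ``cau_as_ile`` is set and an Ile-labelled CAU
    anticodon is present, that record decodes AUA (the reassignment is
    noted); all other CAU records keep Watson-Crick AUG reading.
    """
    notes: list[str] = []
    decodable: set[str] = set()
    reassigned = False
    for rec in anticodons:
        use_flag = (
            cau_as_ile
            and not reassigned
            and rec.anticodon == "CAU"
            and rec.amino_acid.lower().startswith("ile")
        )
        if use_flag:
            reassigned = True
            notes.append("CAU anticodon of an Ile-labelled tRNA treated as reading AUA")
        decodable |= wobble_decodes(rec.anticodon, ile_reassignment=use_flag)
    sense = {_as_rna(c) for c in sense_codons(code_table)}
    decodable &= sense
    undecodable = sense - decodable
    undecodable_used = {
        c: conserved_usage.counts[c.replace("U", "T")]
        for c in sorted(undecodable)
        if conserved_usage.counts[c.replace("U", "T")] > 0
    }
    unassigned: dict[str, int] = {}
    if other_usage is not None:
        for c in sorted(sense):
            dna = c.replace("U", "T")
            if conserved_usage.counts[dna] == 0 and other_usage.counts[dna] > 0:
                unassigned[c] = other_usage.counts[dna]
    return DecodingReport(
        decodable=frozenset(decodable),
        undecodable=frozenset(undecodable),
        undecodable_used=undecodable_used,
        unassigned_candidates=unassigned,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# homing endonucleases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HEDomainRecord:
    family: Literal["LAGLIDADG1", "LAGLIDADG2", "GIY-YIG"]
    aa_sequence: str
    locus: FeatureInterval

    def __post_init__(self) -> None:
        if not (10 <= len(self.aa_sequence) <= 600):
            raise ValueError(
                f"domain length {len(self.aa_sequence)} aa outside the plausible 10-600 band"
            )

    def midpoint(self, genome_length: int) -> float:
        s0, e0 = self.locus.unrolled(genome_length)
        return ((s0 + e0 - 1) / 2.0) % genome_length + 1


def _make_aligner() -> PairwiseAligner:
    # identity method must be fully specified for determinism: global
    # alignment, match +1 / mismatch -1, gap open -5 / extend -1, identity
    # denominator = all alignment columns including gaps
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def pairwise_identity(domains: Sequence[HEDomainRecord]) -> np.ndarray:
    """Symmetric percent-identity matrix from global pairwise alignments."""
    aligner = _make_aligner()
    n = len(domains)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(domains[i].aa_sequence, domains[j].aa_sequence)[0]
            c = aln.counts()
            columns = c.identities + c.mismatches + c.gaps
            m[i, j] = m[j, i] = 100.0 * c.identities / columns
    return m


def circular_distance_matrix(
    domains: Sequence[HEDomainRecord], genome_length: int
) -> np.ndarray:
    """Circular bp distances between locus midpoints:
    d(i,j) = min(|m_i - m_j|, L - |m_i - m_j|)."""
    mids = np.array([d.midpoint(genome_length) for d in domains])
    diff = np.abs(mids[:, None] - mids[None, :])
    return np.minimum(diff, genome_length - diff)


@dataclass(frozen=True)
class CorrelationResult:
    method: Literal["pearson", "spearman"]
    transform: Literal["none", "log"]
    r: float | None
    p_value: float | None
    n_pairs: int
    mantel_p: float | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None


def _upper(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def correlate_similarity_distance(
    similarity: np.ndarray,
    distance: np.ndarray,
    method: Literal["pearson", "spearman"] = "pearson",
    transform: Literal["none", "log"] = "none",
    n_permutations: int = 0,
    seed: int = 0,
) -> CorrelationResult:
    """Correlate pairwise similarity against pairwise locus distance.

    Vectorizes the n(n-1)/2 upper-triangle pairs; ``transform='log'``
    applies log(x+1) to similarity (admitting 0% identities).  The classical
    p-value (t-distribution for Pearson, large-sample for Spearman) is
    reported; with ``n_permutations`` > 0 a seeded Mantel permutation
    p-value is attached, which respects the matrix dependence structure.
    A constant vector yields an undefined (no-result) correlation rather
    than NaN propagation.
    """
    similarity = np.asarray(similarity, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if similarity.shape != distance.shape or similarity.ndim != 2:
        raise ValueError("matrices must be square and of identical shape")
    n = similarity.shape[0]
    n_pairs = n * (n - 1) // 2
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs to correlate")
    sim_t = np.log(similarity + 1.0) if transform == "log" else similarity
    x = _upper(sim_t)
    y = _upper(distance)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(method, transform, None, None, n_pairs)

    def corr(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if method == "pearson":
            res = stats.pearsonr(a, b)
        else:
            res = stats.spearmanr(a, b)
        return float(res.statistic), float(res.pvalue)

    r, p = corr(x, y)
    mantel_p: float | None = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            xp = _upper(sim_t[np.ix_(perm, perm)])
            rp, _ = corr(xp, y)
            if abs(rp) >= abs(r):
                hits += 1
        mantel_p = (hits + 1) / (n_permutations + 1)
    return CorrelationResult(method, transform, r, p, n_pairs, mantel_p)
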