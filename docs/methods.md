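# Methods

This note records the models, conventions and parameter choices behind each
module, what the synthetic-genome generator does and does not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and circular topology

External coordinates are 1-based inclusive throughout (the GenBank/EMBL
convention used by annotation tables); internal arithmetic is 0-based
half-open. A feature crossing the sequence origin of a circular molecule
is one interval with `wraps_origin=True`, never two sub-intervals, so
rotating the sequence start is lossless: rotating by *k* maps every
interval through `start' = ((start−1−k) mod L)+1` and preserves lengths and
circular pairwise distances. In GFF3 output a wrapping feature follows the
GFF3 circular-genome convention (`end` exceeds the landmark length by the
wrapped portion); BED cannot express wrapping and raises an error instead
of silently splitting. `N` residues are legal in sequence but excluded
from every composition denominator.

## Gene architecture and composition

For a gene with exons `e_1..e_m` (transcription order) and introns between
them: `coding_bp = Σ|e_i|`, `span_bp = coding_bp + Σ|introns|`,
`coding_density = 100·coding_bp/span_bp`. Protein length is
`coding_bp/3 − 1` when a stop codon is annotated: the stop is part of the
annotated CDS but encodes no residue. Rounding is decimal **half-up** — to
one decimal for densities, to integer for intron means — because published
tables round half-up and a replay must agree at printed precision
(banker's rounding differs on exact ties).

Composition partitions every position into exactly one of
conserved-coding / intronic / intergenic with precedence
coding > intronic > intergenic. Exons of all three gene classes (protein,
rRNA, tRNA) count as coding. The precedence rule makes the partition
well-defined under overlapping annotation (genes sharing a stop-codon
base, intron-nested genes); per-gene statistics still use each gene's own
span. Additional ORF layers are reported on top without disturbing the
partition.

Translation uses NCBI code tables via Biopython (default table 4, the
mold-mitochondrial code). Internal stops are never silently translated:
they are reported by codon ordinal, since the appearance of internal stops
under a candidate code is precisely the evidence used to reject that code
for a genome.

## Codon usage, distances, NJ, CAI

Codon frequencies are global relative frequencies over the sense codons of
the configured code (stops excluded by default; 62 sense codons under
code 4). The codon-on-codon distance between taxa is the RMSD of these
frequency vectors; a sum-of-squares variant (`ssd = n·rmsd²`) is provided
for matrices published on that scale. Family-normalized (RSCU-style)
shares are available separately; the raw-frequency form is the default
because "codon-on-codon difference" operates on the usage vector itself.

Neighbor joining is the Saitou–Nei algorithm: join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, branch lengths from the standard
formulas, three-point closed form at the end, unrooted (trifurcating root)
result. Determinism under ties: each working node is labelled by the
smallest leaf name in its subtree and equal-Q pairs are resolved by the
lexicographically smallest label pair. Negative branch lengths are clamped
to zero with the deficit transferred to the sister branch; raw values are
retained on the node (`raw_length`). On additive matrices the algorithm is
exact (verified to 1e−9 in tests, and cross-checked against an independent
NJ implementation for topology).

CAI follows Sharp & Li: relative adaptiveness `w(c) = f(c)/max f` within
each synonymous family of the reference table; CAI is the geometric mean
of `w` over the ORF's codons. Codons unobserved in the reference receive
`w = 0.5/(family max count)` so one missing codon does not collapse the
index to zero. Families with a single sense codon under the configured
code are excluded (under the standard code that is Met and Trp; under
code 4 Trp has two codons and is included) — this is computed from the
code table, not hard-coded. Families entirely absent from the reference
are excluded rather than invented.

## GC skew and replication landmarks

Windowed skew is `(first−second)/(first+second)` per window, zero when the
window contains neither base; windows wrap on circular genomes, so the
profile of a rotated genome is a circular shift of the original. The
cumulative series assigns +1/−1/0 per position and removes the linear
drift (the mean contribution): with zero-mean contributions the detrended
series of a rotated genome is an exact circular shift plus a constant,
which makes extremum positions rotation-equivariant — the property that
justifies reading ori (global minimum: entry into the G-rich arc) and ter
(global maximum) off the curve regardless of where the assembly happened
to linearize the circle. The curve is smoothed with the profile's window
(default 1000 bp, step 100 bp, matching the ~1 kbp precision at which
origins are typically quoted) before the extrema are taken, and calls are
reported as window-wide intervals.

No-call guard: the observed cumulative range must exceed the
`(1−alpha)`-quantile of ranges from `n_shuffles` random permutations of
the contribution series (seeded; defaults alpha = 0.01, n = 199). The
default is 0.01 rather than a conventional 0.05 because landmark calling
is typically run across whole panels of genomes: at alpha = 0.05 a
20-genome null panel has only ~74% probability of ≤1 false call
(binomial), while at 0.01 it has ~98%. Mono-nucleotide skew only is
implemented; k-mer ("up to hexamer") skew is a documented extension point,
not reimplemented, because no precise procedure for it is specified
anywhere we could follow.

## Repeat discovery and clustering

`self_compare` seeds exact k-mers (default k = 11) of the genome against
itself (forward for direct repeats, against the reverse complement for
inverted), merges co-(anti)diagonal seeds with gaps ≤ 40 bp, and extends
ungapped under an X-drop criterion (match +1, mismatch −2, X = 25). The
X-drop depth is set to survive the mismatch-run lengths implied by the
0.75 discovery identity floor — a shallow X-drop truncates legitimate
75–85% identity repeats at interior mismatch clusters. Reported identity
is matches/columns of an edit-distance alignment of the final interval
pair (edlib), so small indels count correctly. A Karlin–Altschul
E-value-like score (λ = 1.33, K = 0.621 for +1/−2) is attached for
reporting only; filtering is purely by length (default ≥ 30 bp) and
identity. With `min_identity = 1.0` seed merging becomes contiguous-only
and extension exact, and the output is precisely the set of maximal exact
repeat pairs — the regime in which a brute-force diagonal-scan oracle
verifies the implementation. Hits may cross the origin (the sequence is
extended by a bounded overhang and coordinates canonicalized mod L).

Clustering is greedy longest-first: members sorted by (length desc, start,
end), each joining the first representative it matches at ≥ cutoff
(identity is the better of direct and reverse-complement alignment,
since dispersed families occur in both orientations); the cascade
0.75 → 0.80 → 0.90 re-clusters each level's clusters at the next cutoff,
so counts are monotone along the cascade and the whole procedure is
deterministic.

The inverted-duplication detector reuses inverted seeding with k = 21,
chains seeds whose anti-diagonals agree within a band (±30, absorbing
indel shifts), extends the chain ends while exact matching continues, and
aligns copy 1 against the reverse complement of copy 2 to produce the
mismatch list with substitutions, insertions and deletions classified
relative to the second copy. Reports fully contained in a longer one
(circular-overhang echoes) are suppressed. Indel anchor positions inherit
the usual alignment ambiguity next to equal bases (±1–2 bp).

## Wobble decoding and HE correlation

The wobble model: anticodon positions 2–3 pair Watson–Crick with codon
positions 2–1; at the wobble position U reads all four third-position
bases, G reads C or U, A and C are Watson–Crick only. This is the sparse
mitochondrial tRNA-set model; it deliberately over-decodes two-codon boxes
(a wobble-U tRNA formally reads all four codons of its box), which is
harmless for sufficiency checking — coverage is a superset property. With
the reassignment flag, one CAU anticodon labelled Ile is treated as an
edited/modified isoacceptor reading AUA (and no longer AUG). A codon is
*undecodable* if no tRNA reads it; *unassigned candidates* are sense
codons with zero conserved-ORF usage but nonzero usage elsewhere.

HE domain identity uses global alignment with match +1, mismatch −1, gap
open −5, extend −1, and identity = matches / all alignment columns
including gaps. These constants are a convention fixed for determinism —
published identity percentages rarely state their gap treatment, so exact
agreement with any particular published matrix is not claimed. Locus of a
domain is its genomic midpoint; distances are circular
(`min(|Δ|, L−|Δ|)`, hence ≤ L/2). Correlation vectorizes the n(n−1)/2
upper-triangle pairs; the log transform is `log(x+1)` so 0% identities are
admissible. The classical Pearson/Spearman p-value is reported for
comparability, but pairwise matrices violate its independence assumption,
so a seeded Mantel permutation p-value (label permutations of the
similarity matrix) is reported alongside whenever requested.

## Synthetic genomes and what passing tests mean

The generator's defaults describe a mid-range large fungal mtDNA: 60 kbp
circular molecule at 31% GC; a conserved-style gene set (8 protein genes
with realistic coding lengths, two rRNAs, 12 tRNAs carrying a subset of
the published anticodon repertoire) with introns drawn uniformly from
200–3400 bp; AT-enriched spacers (GC × 0.8); a 6,076 bp inverted
duplication carrying exactly one substitution, one insertion and one
deletion; four dispersed repeat families (4–6 members of 60–200 bp at 85%
identity to their founder, mixed orientations); and a strand-composition
flip of amplitude 0.5 at a planted ori (position ~1) and ter (antipodal).
60 kbp (rather than the largest observed genomes) keeps every default
layout feasible across seeds once the duplication and repeat demands are
packed, while remaining mid-range for the genome family being emulated.
All randomness flows from one integer seed; identical seeds give
byte-identical FASTA/GFF3/truth files.

Truth well-posedness guards — these are deliberate design constraints,
each preventing the planted "truth" from being unrecoverable *in
principle* rather than merely hard:

- Duplication edits and repeat-member mutations stay ≥ a guard distance
  from planted boundaries, and the bases flanking both duplication copies
  are forced to break reverse-complement continuation. Otherwise a
  maximal-extension detector legitimately disagrees with the recorded
  boundary by a base or two.
- Repeat-member mutation draws are resampled until every terminal 50 bp
  prefix/suffix scores strictly positively under +1/−2 scoring. A draw
  that piles mutations against an end plants a tail that any
  score-maximizing aligner must trim; requiring strict positivity also
  excludes exact argmax ties. Interior mutation clusters are left alone —
  detectors must cross those unaided.
- The duplication copies are sampled with exactly balanced G/C (and A/T)
  counts and are excluded from skew-flip placement, and both copies are
  placed at the skew-arc midpoints. An inverted copy carries the exact
  negation of its source's G−C imbalance, so an unbalanced or arc-skewed
  copy plants a compositional dipole (or outright counter-skew segment)
  that corrupts the ori/ter ground truth; a multi-kbp skew-neutral block
  abutting a flip makes the detrended extremum ambiguous.
- The planted ori/ter are snapped to positions with ≥ 80% skew-eligible
  sequence (spacer/intron) within 500 bp on each side, since a
  composition flip inside a long coding block is simply not expressed in
  the sequence.

What the generator does **not** emulate: sequencing error and assembly
artifacts; realistic intron secondary structure or splice-site motifs
(intron types and HE labels are annotation metadata, not sequence
features); homology between genes; tandem microsatellites;
transcription-coupled or replication-timing composition gradients beyond
the single two-arc flip; gene-order evolution. Passing recovery tests
therefore demonstrates algorithmic correctness on clean planted signal
with known truth — not end-to-end performance on real assemblies, where
boundary ambiguity, partial degeneration of repeats and annotation error
all blur the targets.

Problem sizes used by the test suite and acceptance script — 60 kbp
default genomes, 20 + 20 genomes for skew recovery/null, 3 genomes for
repeat recovery, 2 kbp genomes for brute-force oracle equivalence, 10
random 4–8 leaf trees for NJ — are chosen so the planted-signal statistics
are meaningful (tens of planted pairs, binomially stable call rates) while
a full run stays in the minutes range on one core.

## Pipeline

`pipeline.run_all` executes structure, codon-usage, skew, repeat and
decoding stages independently after a single input load; a stage failure
is recorded in the JSON manifest and the rest continue (an annotation
without tRNAs marks the decoding stage `skipped`). The manifest lists
every artifact with its sha256 and the full parameter set, so identical
config + inputs yield identical manifests; no timestamps are embedded.

## Known limitations

- GenBank/EMBL location parsing handles the common forms (simple, join,
  complement, origin-spanning joins on circular records); exotic operators
  (`order`, remote references, fuzzy positions) are not supported.
- The repeat search is heuristic (seeded): repeats shorter than ~2 seed
  lengths at low identity can be missed; the brute-force oracle equality
  holds in the exact-match regime only.
- The published HE-domain similarity matrices cannot be reproduced without
  the underlying domain sequences, which the reference tables do not
  print; the correlation machinery is therefore validated on constructed
  and property-based inputs, and the published summary table ships as
  reference data only.
- Classical p-values for matrix correlations are reported as such; the
  Mantel permutation p is the statistically defensible one.
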