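"""Repeat discovery, identity clustering, inverted duplication, coverage."""

from __future__ import annotations

import numpy as np
import pytest

from mitofeatures import genome_io as gio
from mitofeatures import repeats, synthetic
from conftest import pair_matches
from oracles import brute_force_exact_pairs, pairwise_identity_brute


def _random_seq(rng, n, gc=0.3):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestSelfCompare:
    def test_planted_direct_repeat(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 100)
        genome = gio.CircularGenome(
            "g", _random_seq(rng, 300) + s + _random_seq(rng, 300) + s + _random_seq(rng, 300)
        )
        pairs = repeats.self_compare(genome, orientation="direct")
        hits = [p for p in pairs if p.length >= 100]
        assert len(hits) == 1
        p = hits[0]
        assert p.identity >= 0.99
        assert p.orientation == "direct"
        # random flanks may chance-match a base or two at the ends
        assert abs(p.interval_a.start - 301) <= 3 and abs(p.interval_a.end - 400) <= 3
        assert abs(p.interval_b.start - 701) <= 3 and abs(p.interval_b.end - 800) <= 3

    def test_planted_inverted_repeat(self):
        rng = np.random.default_rng(1)
        s = _random_seq(rng, 100)
        genome = gio.CircularGenome(
            "g",
            _random_seq(rng, 300) + s + _random_seq(rng, 300)
            + gio.revcomp(s) + _random_seq(rng, 300),
        )
        pairs = repeats.self_compare(genome, orientation="inverted")
        hits = [p for p in pairs if p.length >= 100]
        assert len(hits) == 1
        p = hits[0]
        assert p.orientation == "inverted"
        assert p.identity >= 0.99
        assert abs(p.interval_a.start - 301) <= 3 and abs(p.interval_a.end - 400) <= 3
        assert abs(p.interval_b.start - 701) <= 3 and abs(p.interval_b.end - 800) <= 3

    def test_parameter_validation(self):
        genome = gio.CircularGenome("g", "ACGT" * 100)
        with pytest.raises(ValueError):
            repeats.self_compare(genome, min_identity=1.5)
        with pytest.raises(ValueError):
            repeats.self_compare(genome, seed_k=4)

    def test_planted_families_recovered_with_accurate_identity(self, default_truth):
        pairs = repeats.self_compare(default_truth.genome)
        for tp in default_truth.repeat_pairs:
            match = [p for p in pairs if pair_matches(p, tp)]
            assert match, f"planted pair at {tp.interval_a} not recovered"
            best = max(
                match, key=lambda p: -abs(p.identity - tp.identity)
            )
            assert abs(match[0].identity - tp.identity) <= 0.02

    def test_brute_force_oracle_equivalence_small_genome(self):
        spec = synthetic.SyntheticGenomeSpec(
            length=2000,
            genes=[synthetic.SyntheticGeneSpec("g1", "protein", 300, 0)],
            duplication=None,
            repeats=synthetic.RepeatFamilySpec(
                n_families=2, members_per_family=(2, 3),
                member_length=(40, 80), identity=1.0,
            ),
            skew=None,
            seed=6,
        )
        truth = synthetic.generate(spec)
        g = truth.genome
        L = len(g)
        overhang = min(L - 1, 1000)
        seqx = g.residues + g.residues[:overhang]
        for inverted in (False, True):
            found = repeats.self_compare(
                g,
                min_len=20,
                min_identity=1.0,
                orientation="inverted" if inverted else "direct",
                wrap_overhang=overhang,
            )
            got = {
                (
                    min((p.interval_a.start, p.interval_a.end, p.interval_a.wraps_origin),
                        (p.interval_b.start, p.interval_b.end, p.interval_b.wraps_origin)),
                    max((p.interval_a.start, p.interval_a.end, p.interval_a.wraps_origin),
                        (p.interval_b.start, p.interval_b.end, p.interval_b.wraps_origin)),
                )
                for p in found
            }
            expected = brute_force_exact_pairs(seqx, 20, L, inverted=inverted)
            assert got == expected

    def test_inverted_pairs_mirror_on_reverse_complement(self):
        rng = np.random.default_rng(2)
        s = _random_seq(rng, 80)
        seq = _random_seq(rng, 200) + s + _random_seq(rng, 150) + gio.revcomp(s) + _random_seq(rng, 200)
        g = gio.CircularGenome("g", seq)
        rc = gio.CircularGenome("rc", gio.revcomp(seq))
        L = len(seq)

        def canon(pairs):
            out = set()
            for p in pairs:
                if p.length < 80:
                    continue
                a = (p.interval_a.start, p.interval_a.end)
                b = (p.interval_b.start, p.interval_b.end)
                out.add((min(a, b), max(a, b)))
            return out

        fwd = canon(repeats.self_compare(g, orientation="inverted"))
        mirrored = set()
        for p in repeats.self_compare(rc, orientation="inverted"):
            if p.length < 80:
                continue
            a = (L - p.interval_a.end + 1, L - p.interval_a.start + 1)
            b = (L - p.interval_b.end + 1, L - p.interval_b.start + 1)
            mirrored.add((min(a, b), max(a, b)))
        assert fwd == mirrored


class TestClustering:
    def _genome_with_members(self, members):
        rng = np.random.default_rng(3)
        parts, intervals, pos = [], [], 0
        for m in members:
            gap = _random_seq(rng, 100)
            parts += [gap, m]
            pos += 100
            intervals.append(gio.FeatureInterval(pos + 1, pos + len(m), "+"))
            pos += len(m)
        parts.append(_random_seq(rng, 100))
        genome = gio.CircularGenome("g", "".join(parts))
        pairs = [
            repeats.RepeatPair(intervals[0], iv, "direct", 0.9, len(members[0]))
            for iv in intervals[1:]
        ]
        return genome, intervals, pairs

    @staticmethod
    def _mutate(seq, positions, rng):
        out = list(seq)
        for p in positions:
            out[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[p]]
        return "".join(out)

    def test_identical_members_form_one_cluster_at_every_level(self):
        rng = np.random.default_rng(4)
        m = _random_seq(rng, 50)
        genome, intervals, pairs = self._genome_with_members([m, m, m])
        levels = repeats.cluster_repeats(pairs, genome)
        for cutoff, clusters in levels.items():
            assert len(clusters) == 1
            assert len(clusters[0].members) == 3

    def test_two_families_merge_at_075_split_at_080(self):
        rng = np.random.default_rng(5)
        m1 = _random_seq(rng, 100)
        cross_positions = list(rng.choice(100, size=22, replace=False))
        m2 = self._mutate(m1, cross_positions, rng)  # 78% vs m1
        a2 = self._mutate(m1, cross_positions[:3], rng)  # 97% vs m1, mutated
        b2 = self._mutate(m2, cross_positions[:3], rng)  # 97% vs m2
        # brute-force verification of the constructed identities
        assert pairwise_identity_brute(m1, m2) == pytest.approx(78.0)
        assert pairwise_identity_brute(m1, a2) >= 95.0
        assert pairwise_identity_brute(m2, b2) >= 95.0
        genome, intervals, pairs = self._genome_with_members([m1, a2, m2, b2])
        levels = repeats.cluster_repeats(pairs, genome, cutoffs=(0.75, 0.80))
        assert len(levels[0.75]) == 1
        assert len(levels[0.80]) == 2

    def test_cluster_count_monotone_in_cutoff(self, default_truth):
        pairs = repeats.self_compare(default_truth.genome)
        levels = repeats.cluster_repeats(pairs, default_truth.genome)
        counts = [len(levels[c]) for c in (0.75, 0.80, 0.90)]
        assert counts == sorted(counts)

    def test_empty_input_gives_empty_levels(self, default_truth):
        levels = repeats.cluster_repeats([], default_truth.genome)
        assert all(v == [] for v in levels.values())


class TestInvertedDuplication:
    def test_planted_duplication_recovered_exactly(self, default_truth):
        truth = default_truth.duplication
        reports = repeats.find_inverted_duplication(default_truth.genome)
        assert len(reports) == 1
        d = reports[0]
        assert (d.region_1.start, d.region_1.end) == (
            truth.region_1.start, truth.region_1.end,
        )
        assert (d.region_2.start, d.region_2.end) == (
            truth.region_2.start, truth.region_2.end,
        )
        assert len(d.mismatches) == len(truth.mismatches) == 3
        assert sorted(m.kind for m in d.mismatches) == sorted(
            m.kind for m in truth.mismatches
        )
        for got, exp in zip(d.mismatches, truth.mismatches):
            assert abs(got.position - exp.position) <= 2

    def test_duplication_across_origin_recovered(self):
        spec = synthetic.SyntheticGenomeSpec(
            seed=4, duplication=synthetic.DuplicationSpec(across_origin=True)
        )
        truth = synthetic.generate(spec)
        reports = repeats.find_inverted_duplication(truth.genome)
        assert len(reports) == 1
        d = reports[0]
        t = truth.duplication
        regions = {(iv.start, iv.end, iv.wraps_origin)
                   for iv in (d.region_1, d.region_2)}
        assert regions == {
            (t.region_1.start, t.region_1.end, t.region_1.wraps_origin),
            (t.region_2.start, t.region_2.end, t.region_2.wraps_origin),
        }
        assert len(d.mismatches) == 3

    def test_random_sequence_yields_no_report(self):
        rng = np.random.default_rng(6)
        g = gio.CircularGenome("g", _random_seq(rng, 20000, gc=0.5))
        assert repeats.find_inverted_duplication(g) == []


class TestRepeatCoverage:
    def test_union_arithmetic(self):
        genome = gio.CircularGenome("g", "A" * 1000)
        pairs = [
            repeats.RepeatPair(
                gio.FeatureInterval(1, 100), gio.FeatureInterval(51, 150),
                "direct", 1.0, 100,
            )
        ]
        cov = repeats.repeat_coverage(pairs, [], genome)
        assert cov.total_bp == 150
        assert cov.total_fraction == pytest.approx(0.15)

    def test_coverage_invariant_to_pair_order(self, default_truth):
        pairs = repeats.self_compare(default_truth.genome)
        cov1 = repeats.repeat_coverage(pairs, default_truth.genes, default_truth.genome)
        cov2 = repeats.repeat_coverage(pairs[::-1], default_truth.genes, default_truth.genome)
        assert cov1 == cov2

    def test_intergenic_planted_repeats_do_not_touch_coding(self, default_truth):
        truth_pairs = default_truth.repeat_pairs
        cov = repeats.repeat_coverage(
            truth_pairs, default_truth.genes, default_truth.genome
        )
        assert cov.by_category["coding"] == 0

    def test_coverage_invariant_under_rotation(self, default_truth):
        g = default_truth.genome
        L = len(g)
        offset = L // 4
        pairs = default_truth.repeat_pairs
        shifted_pairs = [
            repeats.RepeatPair(
                p.interval_a.shifted(offset, L), p.interval_b.shifted(offset, L),
                p.orientation, p.identity, p.length,
            )
            for p in pairs
        ]
        genes_shifted = []
        for gene in default_truth.genes:
            ng = gio.GeneModel(
                gene.name, gene.feature_class,
                [e.shifted(offset, L) for e in gene.exons], gene.strand,
                gene.stop_codon,
            )
            ng.introns = [
                gio.IntronRecord(r.ordinal, r.interval.shifted(offset, L),
                                 r.intron_type, r.he_label)
                for r in gene.introns
            ]
            genes_shifted.append(ng)
        cov = repeats.repeat_coverage(pairs, default_truth.genes, g)
        cov_rot = repeats.repeat_coverage(shifted_pairs, genes_shifted, g.rotate(offset))
        assert cov.total_bp == cov_rot.total_bp
        assert cov.by_category == cov_rot.by_category
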