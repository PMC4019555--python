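"""Wobble decoding, HE domain identity/distance matrices, correlations."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mitofeatures import genome_io as gio
from mitofeatures import trna_he
from mitofeatures.codon_phylo import CodonUsageTable, sense_codons
from mitofeatures.data import phlebia, phlebia_anticodons


def usage(counts: dict[str, int], taxon="t") -> CodonUsageTable:
    t = CodonUsageTable(taxon=taxon)
    for c, n in counts.items():
        t.counts[c.replace("U", "T")] = n
    return t


class TestWobbleRules:
    def test_wobble_u_reads_all_four(self):
        assert trna_he.wobble_decodes("UGC") == frozenset(
            {"GCA", "GCU", "GCG", "GCC"}
        )

    def test_wobble_g_reads_c_or_u(self):
        assert trna_he.wobble_decodes("GAA") == frozenset({"UUC", "UUU"})

    def test_a_and_c_pair_watson_crick_only(self):
        assert trna_he.wobble_decodes("CCA") == frozenset({"UGG"})
        assert trna_he.wobble_decodes("CAU") == frozenset({"AUG"})
        assert trna_he.wobble_decodes("ACG") == frozenset({"CGU"})

    def test_ile_reassignment_flag(self):
        assert trna_he.wobble_decodes("CAU", ile_reassignment=True) == frozenset({"AUA"})

    def test_invalid_anticodon_rejected(self):
        with pytest.raises(ValueError):
            trna_he.wobble_decodes("CAT" + "U")
        with pytest.raises(ValueError):
            trna_he.wobble_decodes("CAX")


class TestDecodingCheck:
    def _conserved_usage_all_but(self, missing=()):
        u = usage({})
        for c in sense_codons(4):
            u.counts[c] = 10
        for c in missing:
            u.counts[c.replace("U", "T")] = 0
        return u

    def test_published_trna_set_decodes_conserved_proteome(self):
        conserved = self._conserved_usage_all_but(
            missing=("UGA", "AAG", "CGC", "AGG", "CGG")
        )
        report = trna_he.decoding_check(
            phlebia_anticodons(), conserved, code_table=4, cau_as_ile=True
        )
        assert report.sufficient
        assert report.undecodable_used == {}
        # without the Ile reassignment AUA remains unreadable
        report_no_flag = trna_he.decoding_check(
            phlebia_anticodons(), conserved, code_table=4, cau_as_ile=False
        )
        assert "AUA" in report_no_flag.undecodable_used

    def test_decodable_and_undecodable_partition_sense_codons(self):
        conserved = self._conserved_usage_all_but()
        report = trna_he.decoding_check(phlebia_anticodons(), conserved)
        sense = {c.replace("T", "U") for c in sense_codons(4)}
        assert report.decodable | report.undecodable == sense
        assert not (report.decodable & report.undecodable)

    def test_missing_gln_trna_flags_its_codons(self):
        # CAA/CAG are read only by the Gln wobble-U tRNA (His GAU+G covers
        # just CAC/CAU), so dropping it must surface both codons
        records = [a for a in phlebia_anticodons() if a.amino_acid != "Gln"]
        conserved = self._conserved_usage_all_but()
        report = trna_he.decoding_check(records, conserved)
        assert {"CAA", "CAG"} <= set(report.undecodable_used)

    def test_unassigned_candidates_from_nonconserved_usage(self):
        conserved = self._conserved_usage_all_but(missing=("AAG",))
        other = usage({"AAG": 9})
        report = trna_he.decoding_check(phlebia_anticodons(), conserved, other)
        assert report.unassigned_candidates == {"AAG": 9}


def _domain(seq, start, end, family="LAGLIDADG1"):
    return trna_he.HEDomainRecord(family, seq, gio.FeatureInterval(start, end, "+"))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        d = [_domain("MLKTEST" * 3, 1, 63), _domain("MLKTEST" * 3, 100, 162)]
        m = trna_he.pairwise_identity(d)
        assert m[0, 1] == 100.0

    def test_single_substitution_no_gaps(self):
        d = [_domain("AAAAAAAAAAAA", 1, 36), _domain("AAAAATAAAAAA", 100, 136)]
        m = trna_he.pairwise_identity(d)
        assert m[0, 1] == pytest.approx(100 * 11 / 12)

    def test_summary_matches_brute_recomputation(self):
        rng = np.random.default_rng(0)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(alphabet, size=40)) for _ in range(5)]
        domains = [_domain(s, 10 * i + 1, 10 * i + 120) for i, s in enumerate(seqs)]
        m = trna_he.pairwise_identity(domains)
        vals = [m[i, j] for i, j in itertools.combinations(range(5), 2)]
        # recompute each entry pairwise and compare the summary statistics
        singles = [
            trna_he.pairwise_identity([domains[i], domains[j]])[0, 1]
            for i, j in itertools.combinations(range(5), 2)
        ]
        assert min(vals) == pytest.approx(min(singles))
        assert max(vals) == pytest.approx(max(singles))
        assert np.mean(vals) == pytest.approx(np.mean(singles))

    def test_domain_length_band_enforced(self):
        with pytest.raises(ValueError):
            _domain("MLK", 1, 9)


class TestCircularDistance:
    def test_wraparound_minimum(self):
        d = [_domain("A" * 20, 1, 1), _domain("A" * 20, 1000, 1000)]
        m = trna_he.circular_distance_matrix(d, 1000)
        assert m[0, 1] == 1.0

    def test_interior_distance(self):
        d = [_domain("A" * 20, 5, 15), _domain("A" * 20, 105, 115)]
        m = trna_he.circular_distance_matrix(d, 1000)
        assert m[0, 1] == 100.0

    def test_bounded_by_half_genome_and_rotation_invariant(self):
        rng = np.random.default_rng(1)
        L = 10000
        starts = sorted(int(x) for x in rng.integers(1, L - 50, size=8))
        domains = [_domain("A" * 20, s, s + 30) for s in starts]
        m = trna_he.circular_distance_matrix(domains, L)
        assert np.all(m <= L / 2)
        offset = 3333
        shifted = [
            trna_he.HEDomainRecord(
                d.family, d.aa_sequence, d.locus.shifted(offset, L)
            )
            for d in domains
        ]
        m2 = trna_he.circular_distance_matrix(shifted, L)
        assert np.allclose(m, m2)


class TestCorrelation:
    def _matrices(self, n, rng, noise=0.0):
        mids = rng.uniform(0, 1000, size=n)
        diff = np.abs(mids[:, None] - mids[None, :])
        sim = 100 - diff / 10 + rng.normal(0, noise, size=diff.shape)
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 100)
        return sim, diff

    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(2)
        sim, dist = self._matrices(8, rng)
        res = trna_he.correlate_similarity_distance(sim, dist, "pearson")
        assert res.r == pytest.approx(-1.0)
        assert res.p_value < 1e-10
        assert res.n_pairs == 28

    def test_constant_similarity_is_no_result(self):
        sim = np.full((5, 5), 50.0)
        dist = np.abs(np.arange(5)[:, None] - np.arange(5)[None, :]).astype(float)
        res = trna_he.correlate_similarity_distance(sim, dist)
        assert not res.defined
        assert res.r is None and res.p_value is None

    def test_pearson_matches_textbook_formula_on_hand_data(self):
        # 4 domains -> 6 pairs; verify against the closed-form computation
        sim = np.zeros((4, 4))
        dist = np.zeros((4, 4))
        vals_s = [10.0, 20.0, 5.0, 40.0, 15.0, 30.0]
        vals_d = [100.0, 80.0, 120.0, 30.0, 95.0, 60.0]
        iu = np.triu_indices(4, k=1)
        sim[iu] = vals_s
        dist[iu] = vals_d
        sim += sim.T
        dist += dist.T
        res = trna_he.correlate_similarity_distance(sim, dist, "pearson")
        x, y = np.array(vals_s), np.array(vals_d)
        r_hand = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.r == pytest.approx(r_hand)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        sim, dist = self._matrices(7, rng, noise=5.0)
        r1 = trna_he.correlate_similarity_distance(sim, dist, "spearman").r
        r2 = trna_he.correlate_similarity_distance(
            np.exp(sim / 30.0), dist, "spearman"
        ).r
        assert r1 == pytest.approx(r2)

    def test_log_transform_handles_zero_similarity(self):
        rng = np.random.default_rng(4)
        sim, dist = self._matrices(6, rng, noise=3.0)
        sim = sim - sim.min()  # introduce exact zeros
        res = trna_he.correlate_similarity_distance(sim, dist, "pearson", "log")
        assert res.defined and np.isfinite(res.r)

    def test_mantel_p_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        sim, dist = self._matrices(7, rng, noise=20.0)
        res1 = trna_he.correlate_similarity_distance(
            sim, dist, n_permutations=199, seed=42
        )
        res2 = trna_he.correlate_similarity_distance(
            sim, dist, n_permutations=199, seed=42
        )
        assert res1.mantel_p == res2.mantel_p
        assert 0 < res1.mantel_p <= 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            trna_he.correlate_similarity_distance(np.zeros((2, 2)), np.zeros((2, 2)))
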