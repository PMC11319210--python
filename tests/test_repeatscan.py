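"""Tandem arrays, monomer clusters, centromere and telomere detection."""

import numpy as np
import pytest

from panscape import (call_centromere, cluster_monomers, detect_telomeres,
                      find_tandem_repeats, reverse_complement,
                      simulate_chromosome, top_clusters)
from panscape.io_formats import (GeneModel, GenomeAnnotationBundle,
                                 RepeatFeature)
from panscape.repeatscan import TandemArray


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def shifted_identity(seq: str, lo: int, hi: int, p: int) -> float:
    """Brute-force shifted-self identity of seq[lo:hi] at period p."""
    region = seq[lo:hi]
    pairs = [(a, b) for a, b in zip(region, region[p:])]
    return sum(a == b for a, b in pairs) / len(pairs)


class TestFindTandemRepeats:
    def test_telomere_motif_array(self):
        arrays = find_tandem_repeats("CCCTAAA" * 10, min_copies=5)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 7
        assert a.copy_number == pytest.approx(10, abs=0.5)
        assert a.mean_identity == 1.0
        assert a.consensus_monomer in "CCCTAAACCCTAAA"

    def test_smallest_period_reported(self):
        (a,) = find_tandem_repeats("ACGT" * 3, min_period=2, min_copies=3)
        assert a.period == 4            # not 8: divisors collapsed
        assert a.copy_number == pytest.approx(3, abs=0.5)

    def test_repeat_free_sequence_empty(self):
        rng = np.random.default_rng(41)
        assert find_tandem_repeats(_random_seq(rng, 5_000)) == []

    def test_mutated_monomer_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        monomer = _random_seq(rng, 100)
        copies = []
        for _ in range(50):
            c = list(monomer)
            for i in np.flatnonzero(rng.random(100) < 0.02):
                c[i] = "ACGT"[("ACGT".index(c[i]) + 1) % 4]
            copies.append("".join(c))
        left, right = _random_seq(rng, 3_000), _random_seq(rng, 3_000)
        seq = left + "".join(copies) + right
        true_span = (3_000, 3_000 + 50 * 100)

        arrays = find_tandem_repeats(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert abs(a.period - 100) <= 2
        assert abs(a.span[0] - true_span[0]) <= 100
        assert abs(a.span[1] - true_span[1]) <= 100
        # oracle: among all periods 5..200, the smallest with an
        # above-threshold shifted-self identity on the true region is the
        # true monomer length (multiples score equally well)
        idents = {p: shifted_identity(seq, *true_span, p)
                  for p in range(5, 201)}
        assert min(p for p, v in idents.items() if v >= 0.8) == 100
        assert a.mean_identity == pytest.approx(idents[100], abs=0.02)

    def test_zero_divergence_period_exact(self):
        seq, _, manifest = simulate_chromosome(
            length=100_000, centromere_span=(40_000, 60_000),
            monomer_divergence=0.0, telomere_copies=20, seed=43)
        arrays = find_tandem_repeats(seq)
        m = manifest.generator_params["monomer_length"]
        best = max(arrays, key=lambda a: a.length)
        assert best.period == m

    def test_strand_consistency(self, simulated_chromosome):
        seq, _, manifest = simulated_chromosome
        n = len(seq)
        fwd = find_tandem_repeats(seq, chromosome="f")
        rev = find_tandem_repeats(reverse_complement(seq), chromosome="r")
        big_f = max(fwd, key=lambda a: a.length)
        big_r = max(rev, key=lambda a: a.length)
        assert big_r.period == big_f.period
        assert big_r.span == (n - big_f.span[1], n - big_f.span[0])

    def test_no_overlaps_after_merging(self, detected_arrays):
        arrays, _ = detected_arrays
        spans = sorted(a.span for a in arrays)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestClusterMonomers:
    def _array(self, i, mono, copies=10.0):
        return TandemArray(id=f"arr{i}", chromosome="c", span=(0, 1),
                           period=len(mono), copy_number=copies,
                           consensus_monomer=mono, mean_identity=1.0)

    def test_identical_monomers_single_cluster(self):
        rng = np.random.default_rng(51)
        mono = _random_seq(rng, 100)
        arrays = [self._array(i, mono, copies=5.0) for i in range(4)]
        (cl,) = cluster_monomers(arrays)
        assert cl.abundance == 20.0
        assert len(cl.members) == 4

    def test_threshold_splits_and_joins_families(self):
        rng = np.random.default_rng(52)
        a = _random_seq(rng, 100)
        b = list(a)
        for i in rng.choice(100, 35, replace=False):
            b[i] = "ACGT"[("ACGT".index(b[i]) + 1) % 4]
        b = "".join(b)                  # ~65% identity to a
        arrays = [self._array(0, a), self._array(1, b)]
        assert len(cluster_monomers(arrays, identity_threshold=0.8)) == 2
        assert len(cluster_monomers(arrays, identity_threshold=0.6)) == 1

    def test_reverse_complement_joins_cluster(self):
        rng = np.random.default_rng(53)
        mono = _random_seq(rng, 80)
        arrays = [self._array(0, mono), self._array(1,
                                                    reverse_complement(mono))]
        assert len(cluster_monomers(arrays)) == 1

    def test_abundance_conservation_and_top_k(self, detected_arrays):
        arrays, clusters = detected_arrays
        assert sum(c.abundance for c in clusters) \
            == pytest.approx(sum(a.copy_number for a in arrays))
        assert [c.rank for c in clusters] == list(range(1, len(clusters) + 1))
        top = top_clusters(clusters, 8)
        assert len(top) <= 8
        assert all(c.rank <= 8 for c in top)


class TestCallCentromere:
    def test_recovers_simulated_span(self, simulated_chromosome,
                                     detected_arrays):
        _, bundle, manifest = simulated_chromosome
        arrays, clusters = detected_arrays
        call = call_centromere(bundle, "chr01", arrays, clusters)
        ts, te = manifest.true_centromeres["chr01"]
        cs, ce = call.span
        inter = max(0, min(ce, te) - max(cs, ts))
        union = max(ce, te) - min(cs, ts)
        assert inter / union >= 0.8

    def test_repeat_free_chromosome_none(self):
        rng = np.random.default_rng(61)
        seq = _random_seq(rng, 300_000)
        bundle = GenomeAnnotationBundle(assembly={"c": seq})
        assert call_centromere(bundle, "c", [], []) is None

    def test_gene_dense_array_loses_to_gypsy_rich_array(self):
        rng = np.random.default_rng(62)
        mono_a, mono_b = _random_seq(rng, 100), _random_seq(rng, 120)
        seq = (_random_seq(rng, 50_000) + mono_a * 300 +
               _random_seq(rng, 70_000) + mono_b * 250 +
               _random_seq(rng, 50_000))
        a_span = (50_000, 80_000)
        b_span = (150_000, 180_000)
        genes = [GeneModel(f"g{i}", "c", (s, s + 2_000), "+")
                 for i, s in enumerate(range(a_span[0], a_span[1], 3_000))]
        repeats = [RepeatFeature("c", (s, s + 2_000), "LTR/Gypsy")
                   for s in range(b_span[0], b_span[1], 3_000)]
        bundle = GenomeAnnotationBundle(assembly={"c": seq}, genes=genes,
                                        repeats=repeats)
        arrays = find_tandem_repeats(seq, chromosome="c")
        clusters = cluster_monomers(arrays)
        call = call_centromere(bundle, "c", arrays, clusters,
                               window=30_000, step=15_000)
        mid = (call.span[0] + call.span[1]) / 2
        assert b_span[0] <= mid <= b_span[1]


class TestDetectTelomeres:
    def test_both_ends_present_on_simulated_chromosome(
            self, simulated_chromosome):
        seq, _, _ = simulated_chromosome
        calls = detect_telomeres(seq, "chr01")
        assert [c.present for c in calls] == [True, True]
        assert all(c.motif_copies >= 100 for c in calls)

    def test_motif_free_sequence_absent(self):
        assert sum(c.present
                   for c in detect_telomeres("ACGG" * 10_000)) == 0

    def test_five_prime_only(self):
        rng = np.random.default_rng(71)
        seq = "CCCTAAA" * 50 + _random_seq(rng, 40_000)
        calls = {c.end: c for c in detect_telomeres(seq)}
        assert calls["5prime"].present
        assert not calls["3prime"].present

    def test_reverse_complement_swaps_ends(self, simulated_chromosome):
        seq, _, _ = simulated_chromosome
        fwd = {c.end: c.motif_copies for c in detect_telomeres(seq)}
        rev = {c.end: c.motif_copies
               for c in detect_telomeres(reverse_complement(seq))}
        assert fwd["5prime"] == rev["3prime"]
        assert fwd["3prime"] == rev["5prime"]
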