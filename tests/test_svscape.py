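"""SV merging, summaries, annotation, enrichment, hotspots, ancestry."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from panscape import (InputError, ParameterError, SvRecord,
                      ancestry_partition, annotate_svs, bonferroni_threshold,
                      core_svs, inversion_hotspots, merge_svs, mergeable,
                      repeat_enrichment, summarize_types)
from panscape.io_formats import GeneModel, RepeatFeature
from panscape.svscape import fisher_test


def hypergeom_two_sided(table) -> float:
    """Exhaustive two-sided Fisher p over all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


def random_records(rng, n, accessions, chrom="chr1", types=("DEL", "INS")):
    recs = []
    for _ in range(n):
        t = types[int(rng.integers(len(types)))]
        length = int(rng.integers(30, 400))
        start = int(rng.integers(0, 50_000))
        span = (start, start) if t == "INS" else (start, start + length)
        recs.append(SvRecord(accession=accessions[int(rng.integers(
            len(accessions)))], chromosome=chrom, span=span, type=t,
            length=length))
    return recs


def oracle_components(records, **kwargs):
    """All-pairs connected components of the pairwise merge criterion."""
    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    for i, j in itertools.combinations(range(len(records)), 2):
        if mergeable(records[i], records[j], **kwargs):
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestMergeSvs:
    def test_single_accession_identity(self):
        recs = [SvRecord("a1", "chr1", (100, 300), "DEL", 200),
                SvRecord("a1", "chr1", (900, 900), "INS", 50)]
        merged = merge_svs(recs)
        assert len(merged) == 2
        assert all(m.presence == {"a1": True} for m in merged)

    def test_identical_dels_merge_across_accessions(self):
        recs = [SvRecord("a1", "chr1", (100, 300), "DEL", 200),
                SvRecord("a2", "chr1", (100, 300), "DEL", 200)]
        (m,) = merge_svs(recs)
        assert m.presence == {"a1": True, "a2": True}

    def test_insufficient_reciprocal_overlap_stays_split(self):
        # 40% reciprocal overlap at threshold 0.5 -> two records
        recs = [SvRecord("a1", "chr1", (0, 100), "DEL", 100),
                SvRecord("a2", "chr1", (60, 160), "DEL", 100)]
        assert len(merge_svs(recs)) == 2
        assert len(merge_svs(recs, reciprocal_overlap=0.3)) == 1

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(81)
        recs = random_records(rng, 200, ["a1", "a2", "a3"],
                              types=("DEL", "INS", "DUP", "INV", "TRA"))
        merged = merge_svs(recs)
        expected = oracle_components(recs)
        idx = {id(r): i for i, r in enumerate(recs)}
        got = {frozenset(idx[id(r)] for r in comp.members)
               for comp in merged}
        assert got == expected
        # presence vectors union member accessions
        for comp in merged:
            assert set(comp.carriers()) == {r.accession
                                            for r in comp.members}

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(82)
        recs = random_records(rng, 100, ["a1", "a2"])
        merged = merge_svs(recs)
        remerged = merge_svs(
            [SvRecord("x", m.chromosome, m.span, m.type,
                      m.representative_length) for m in merged])
        assert len(remerged) == len(merged)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert [(m.span, m.type) for m in merge_svs(shuffled)] \
            == [(m.span, m.type) for m in merge_svs(recs)]


class TestSummarizeTypes:
    def test_single_record(self):
        summary = summarize_types([SvRecord("a", "c", (0, 30), "DEL", 30)])
        assert summary.percentages["DEL"] == 100.0
        assert summary.total == 1

    def test_empty_set(self):
        summary = summarize_types([])
        assert summary.total == 0
        assert all(v == 0.0 for v in summary.percentages.values())

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(83)
        types = ["DEL", "INS", "DUP", "INV", "TRA"]
        recs = random_records(rng, 500, ["a"], types=tuple(types))
        summary = summarize_types(recs)
        for t in types:
            cnt = sum(r.type == t for r in recs)
            assert summary.counts[t] == cnt
            assert summary.percentages[t] == pytest.approx(
                round(100 * cnt / 500, 2), abs=0.005)


class TestAnnotateSvs:
    GENE = GeneModel("g1", "chr1", (10_000, 13_000), "+",
                     ((10_200, 10_800), (11_500, 12_400)))
    REPEATS = [RepeatFeature("chr1", (40_000, 45_000), "LTR/Gypsy")]

    def _annotate(self, svs):
        return annotate_svs(svs, [self.GENE], self.REPEATS)

    def _sv(self, span, type_="DEL", length=None):
        from panscape.svscape import NonredundantSv

        length = length or max(21, span[1] - span[0])
        return NonredundantSv(id="s", chromosome="chr1", span=span,
                              type=type_, representative_length=length,
                              presence={"a": True})

    def test_deletion_in_cds_is_frameshift(self):
        (a,), _ = self._annotate([self._sv((10_300, 10_323), length=23)])
        assert a.context == "cds"
        assert a.coding_effect == "frameshift"
        (a,), _ = self._annotate([self._sv((10_300, 10_324), length=24)])
        assert a.coding_effect == "inframe"

    def test_inversion_over_cds_is_structural(self):
        (a,), _ = self._annotate([self._sv((10_000, 13_000), "INV")])
        assert a.coding_effect == "structural"

    def test_ins_upstream_is_flank(self):
        (a,), _ = self._annotate([self._sv((8_500, 8_500), "INS", 60)])
        assert a.context == "flank2kb"
        assert a.coding_effect == "none"

    def test_far_sv_is_intergenic_nonrepeat(self):
        (a,), _ = self._annotate([self._sv((60_000, 60_100))])
        assert a.context == "intergenic"
        assert not a.in_repeat

    def test_repeat_overlap_flagging(self):
        (a,), _ = self._annotate([self._sv((44_900, 45_200))])
        assert a.in_repeat

    def test_unknown_chromosome_excluded(self):
        sv = self._sv((100, 200))
        object.__setattr__(sv, "chromosome", "chrX")
        annotated, summary = self._annotate([sv])
        assert annotated == []
        assert summary["n_flagged"] == 1

    def test_context_fractions_partition(self, sv_world):
        bundle, _, _, _, merged = sv_world
        _, summary = annotate_svs(merged, bundle.genes, bundle.repeats)
        assert sum(summary["context_fractions"].values()) \
            == pytest.approx(1.0, abs=1e-9)


class TestFisherAndEnrichment:
    def test_symmetric_table(self):
        odds, p = fisher_test([[10, 10], [10, 10]])
        assert odds == 1.0
        assert p == 1.0

    def test_matches_exhaustive_enumeration(self):
        _, p = fisher_test([[12, 3], [5, 10]])
        assert p == pytest.approx(hypergeom_two_sided([[12, 3], [5, 10]]),
                                  rel=1e-9)

    def test_enrichment_detected_on_enriched_landscape(self, sv_world):
        bundle, _, _, _, merged = sv_world
        res = repeat_enrichment(merged, bundle.repeats,
                                bundle.chromosome_lengths())
        assert res.odds_ratio > 1
        assert res.p_value < 1e-6
        assert np.mean(res.repeat_density) > np.mean(res.nonrepeat_density)

    def test_zero_marginal_flagged(self):
        res = repeat_enrichment([], [], {"chr1": 1_000})
        assert res.flagged
        assert math.isnan(res.p_value)


class TestAncestry:
    def test_printed_partition_arithmetic(self):
        # a 362-SV core set split 33 / 68 / 200 across two ancestors
        def dels(indices, acc):
            return [SvRecord(acc, "chr1", (i * 1_000, i * 1_000 + 100),
                             "DEL", 100) for i in indices]

        target = dels(range(362), "t")
        set_a = dels(range(0, 33), "A") + dels(range(101, 301), "A")
        set_b = dels(range(33, 101), "B") + dels(range(101, 301), "B")
        part = ancestry_partition(target, set_a, set_b)
        assert part.counts == {"onlyA": 33, "onlyB": 68, "both": 200,
                               "neither": 61}
        assert part.total == 362

    def test_disjoint_sets(self):
        target = [SvRecord("t", "chr1", (0, 100), "DEL", 100)]
        part = ancestry_partition(target, [], [])
        assert part.counts == {"onlyA": 0, "onlyB": 0, "both": 0,
                               "neither": 1}

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(84)
        target = random_records(rng, 50, ["t"])
        set_a = random_records(rng, 50, ["A"])
        set_b = random_records(rng, 50, ["B"])
        part = ancestry_partition(target, set_a, set_b)
        counts = {"onlyA": 0, "onlyB": 0, "both": 0, "neither": 0}
        for sv in target:
            a = any(mergeable(sv, r) for r in set_a)
            b = any(mergeable(sv, r) for r in set_b)
            counts["both" if a and b else "onlyA" if a
                   else "onlyB" if b else "neither"] += 1
        assert part.counts == counts

    def test_core_sv_selection(self, sv_world):
        _, design, _, _, merged = sv_world
        core = core_svs(merged, list(design.target_group))
        for m in core:
            assert all(m.presence[a] for a in design.target_group)


class TestHotspots:
    def _inv(self, pos, chrom="chr1"):
        return SvRecord("a", chrom, (pos, pos + 5_000), "INV", 5_000)

    def test_cluster_yields_single_hotspot(self):
        svs = [self._inv(p) for p in (2_000_000, 2_100_000, 2_300_000,
                                      2_500_000, 2_700_000)]
        spots = inversion_hotspots(svs, min_count=3)
        assert len(spots) == 1
        chrom, lo, hi = spots[0]
        mids = [s.midpoint for s in svs]
        assert lo <= min(mids) and hi >= max(mids)

    def test_no_inversions_empty(self):
        assert inversion_hotspots([]) == []

    def test_sparse_inversions_no_hotspot(self):
        svs = [self._inv(p) for p in (1_000_000, 3_000_000, 5_000_000)]
        assert inversion_hotspots(svs, min_count=2) == []

    def test_matches_sliding_count_oracle(self):
        rng = np.random.default_rng(85)
        svs = [self._inv(int(p)) for p in rng.integers(0, 10_000_000, 40)]
        spots = inversion_hotspots(svs, min_count=3)
        mids = sorted(s.midpoint for s in svs)
        for _, lo, hi in spots:
            # every merged hotspot contains >= min_count midpoints
            assert sum(lo <= m < hi for m in mids) >= 3


class TestBonferroni:
    def test_printed_snp_count(self):
        thr = bonferroni_threshold(0.05, 9_618_384)
        assert thr == pytest.approx(5.19e-9, rel=0.01)

    def test_trivial_values(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ParameterError):
            bonferroni_threshold(0.05, 0)


def test_sv_record_validation():
    with pytest.raises(InputError):
        SvRecord("a", "c", (0, 15), "DEL", 15)       # below the >20 bp floor
    with pytest.raises(InputError):
        SvRecord("a", "c", (0, 100), "INS", 100)     # INS must be anchored
    with pytest.raises(InputError):
        SvRecord("a", "c", (0, 100), "CNV", 100)
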