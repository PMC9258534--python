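"""Hit finding, E-values, clustering, and the two-condition specificity rule."""

import pytest

from repeatfish._utils import revcomp
from repeatfish.locus_mapper import (
    Hit,
    MappingParams,
    check_specificity,
    classify_specificity,
    cluster_hits,
    estimate_evalue,
    find_hits,
)
from repeatfish.sequence_io import GenomeAssembly, GenomicInterval

from conftest import make_seedless_background, naive_find_hits, random_seq


def _clean_probe(rng, length=25):
    """A random probe with no internal duplicate seed word, so each planted
    copy produces exactly one seed diagonal."""
    while True:
        probe = random_seq(rng, length)
        words = [probe[i : i + 11] for i in range(length - 10)]
        if len(set(words)) == len(words):
            return probe


# seeds of 5 make the search exhaustive at unit-test genome sizes: any hit
# passing E <= 10 there must contain a contiguous 5-match and is found
_EXHAUSTIVE = MappingParams(word_size=5)


class TestFindHits:
    def test_exact_plants_found_on_both_strands(self, rng):
        probe = _clean_probe(rng)
        # background shares no seed word with the probe on either strand,
        # so the only reported hits can be the planted copies
        bg = make_seedless_background(rng, 50_000, probe)
        s = (bg[:5000] + probe + bg[5000:20000] + revcomp(probe)
             + bg[20000:40000] + probe + bg[40000:])
        hits = find_hits(GenomeAssembly({"c1": s}), probe)
        assert [(h.interval.start, h.interval.strand) for h in hits] == [
            (5001, "+"), (20026, "-"), (40051, "+"),
        ]
        assert all(h.raw_score == 25 and h.percent_identity == 100.0 for h in hits)

    def test_imperfect_hit_matches_naive_oracle(self, rng):
        probe = _clean_probe(rng)
        mutated = list(probe)
        mutated[12] = {"A": "C", "C": "G", "G": "A", "T": "G"}[mutated[12]]
        mutated = "".join(mutated)
        records = {"c1": random_seq(rng, 20_000)}
        records["c1"] = records["c1"][:8000] + mutated + records["c1"][8000 + 25:]
        hits = find_hits(GenomeAssembly(dict(records)), probe, _EXHAUSTIVE)
        got = {(h.interval.chrom, h.interval.start, h.interval.end,
                h.interval.strand, h.raw_score) for h in hits}
        assert got == naive_find_hits(records, probe)
        planted = [h for h in hits if h.interval.start <= 8025 and h.interval.end >= 8001]
        assert planted and all(h.percent_identity < 100.0 for h in planted)
        assert all(h.evalue <= 10.0 for h in hits)

    def test_equivalence_with_naive_scan_on_random_genome(self, rng):
        """Seeded search equals the brute-force per-offset scan, including
        any chance hits, on an unconstrained random genome."""
        genome = {"a": random_seq(rng, 15_000), "b": random_seq(rng, 15_000)}
        probe = random_seq(rng, 25)
        # plant one perfect and one 1-substitution copy
        genome["a"] = genome["a"][:4000] + probe + genome["a"][4000 + 25:]
        probe2 = "C" + probe[1:] if probe[0] != "C" else "G" + probe[1:]
        genome["b"] = genome["b"][:9000] + probe2 + genome["b"][9000 + 25:]
        g = GenomeAssembly(dict(genome))
        got = {(h.interval.chrom, h.interval.start, h.interval.end,
                h.interval.strand, h.raw_score) for h in find_hits(g, probe, _EXHAUSTIVE)}
        assert got == naive_find_hits(genome, probe)

    def test_query_far_from_everything_yields_nothing(self, rng):
        probe = _clean_probe(rng, 20)
        bg = make_seedless_background(rng, 30_000, probe)
        assert find_hits(GenomeAssembly({"c": bg}), probe) == []

    def test_strand_symmetry(self, rng):
        genome = {"a": random_seq(rng, 10_000)}
        probe = random_seq(rng, 22)
        genome["a"] = genome["a"][:3000] + probe + genome["a"][3022:]
        g = GenomeAssembly(genome)
        fwd = find_hits(g, probe)
        rev = find_hits(g, revcomp(probe))
        flip = {"+": "-", "-": "+"}
        assert {(h.interval.start, h.interval.end, h.interval.strand) for h in fwd} == {
            (h.interval.start, h.interval.end, flip[h.interval.strand]) for h in rev
        }

    def test_ambiguous_query_rejected(self):
        g = GenomeAssembly({"c": "ACGT" * 100})
        with pytest.raises(ValueError, match="unambiguous"):
            find_hits(g, "ACGTNACGTNACGT")

    def test_query_shorter_than_word_rejected(self):
        g = GenomeAssembly({"c": "ACGT" * 100})
        with pytest.raises(ValueError, match="word size"):
            find_hits(g, "ACGTACGT")


class TestEvalue:
    def test_linear_in_search_space(self):
        assert estimate_evalue(10, 20, 2_000_000) == pytest.approx(
            2 * estimate_evalue(10, 20, 1_000_000)
        )

    def test_zero_score_gives_kmn(self):
        from repeatfish.locus_mapper import KA_K

        assert estimate_evalue(0, 20, 1000) == pytest.approx(KA_K * 20 * 1000)

    def test_monotone_decreasing_in_score(self):
        evs = [estimate_evalue(s, 25, 10**8) for s in range(0, 26)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_perfect_20mer_vs_large_genome_passes(self):
        assert estimate_evalue(20, 20, 100_000_000) < 0.01


def _fake_hits(chrom, starts, width=24):
    return [
        Hit(GenomicInterval(chrom, s, s + width), 25, 100.0, 1e-6)
        for s in starts
    ]


class TestClustering:
    def test_dense_hits_form_one_cluster(self):
        clusters, singles = cluster_hits(_fake_hits("I", range(1000, 16000, 1500)))
        assert len(clusters) == 1 and not singles
        assert clusters[0].hit_count == 10

    def test_distant_pair_stays_singletons(self):
        clusters, singles = cluster_hits(_fake_hits("I", [1000, 201_000]))
        assert clusters == [] and len(singles) == 2

    def test_single_linkage_chains(self):
        clusters, singles = cluster_hits(_fake_hits("I", [1000, 40_000, 80_000]))
        assert len(clusters) == 1 and clusters[0].hit_count == 3 and not singles


class TestClassify:
    def test_single_major_cluster_passes(self):
        c, s = cluster_hits(_fake_hits("I", range(1000, 201_000, 1000)))
        assert classify_specificity(c, s).verdict == "PASS"

    def test_secondary_cluster_on_other_chromosome_fails(self):
        hits = _fake_hits("I", range(1000, 151_000, 1000)) + _fake_hits(
            "X", range(5000, 65_000, 1000)
        )
        rep = classify_specificity(*cluster_hits(hits))
        assert rep.verdict == "FAIL"
        assert rep.failed_condition == "clustered_offtarget_hits"

    def test_offchromosome_singletons_tolerated(self):
        hits = (_fake_hits("I", range(1000, 201_000, 1000))
                + _fake_hits("II", [5000]) + _fake_hits("II", [700_000])
                + _fake_hits("IV", [9000]))
        rep = classify_specificity(*cluster_hits(hits))
        assert rep.verdict == "PASS"
        assert rep.failed_condition == "none"

    def test_split_majority_same_chromosome_fails_condition_one(self):
        hits = _fake_hits("I", range(1000, 61_000, 1000)) + _fake_hits(
            "I", range(900_000, 940_000, 1000)
        )
        rep = classify_specificity(*cluster_hits(hits))
        assert rep.verdict == "FAIL"
        assert rep.failed_condition == "multiple_major_loci"

    def test_zero_hits_fail_with_diagnostic(self):
        rep = classify_specificity([], [])
        assert rep.verdict == "FAIL"
        assert rep.failed_condition == "no_hits"
        assert "hybridize" in rep.diagnostic

    def test_hit_fractions_sum_to_one(self):
        hits = _fake_hits("I", range(1000, 91_000, 1000)) + _fake_hits("II", [5000])
        clusters, singles = cluster_hits(hits)
        total = sum(c.hit_fraction for c in clusters) + len(singles) / len(hits)
        assert total == pytest.approx(1.0)


class TestSpecificityFlips:
    """Adding copies elsewhere can only make the verdict worse."""

    def _base_genome(self, rng, probe):
        bg1 = make_seedless_background(rng, 30_000, probe)
        bg2 = make_seedless_background(rng, 30_000, probe)
        # tandem block of 20 copies on chromosome I is the target locus
        chr1 = bg1[:10_000] + probe * 20 + bg1[10_000:]
        return chr1, bg2

    def test_clustered_copies_on_other_chromosome_flip_pass_to_fail(self, rng):
        probe = _clean_probe(rng, 25)
        chr1, bg2 = self._base_genome(rng, probe)
        params = MappingParams(cluster_gap=5000)
        rep, _ = check_specificity(
            GenomeAssembly({"I": chr1, "II": bg2}), probe, params
        )
        assert rep.verdict == "PASS"
        chr2 = bg2[:15_000] + probe * 3 + bg2[15_000:]
        rep2, _ = check_specificity(
            GenomeAssembly({"I": chr1, "II": chr2}), probe, params
        )
        assert rep2.verdict == "FAIL"
        assert rep2.failed_condition == "clustered_offtarget_hits"

    def test_single_copy_on_other_chromosome_does_not_flip_fail_to_pass(self, rng):
        probe = _clean_probe(rng, 25)
        chr1, bg2 = self._base_genome(rng, probe)
        params = MappingParams(cluster_gap=5000)
        chr2 = bg2[:15_000] + probe * 3 + bg2[15_000:]
        g_fail = GenomeAssembly({"I": chr1, "II": chr2})
        rep, _ = check_specificity(g_fail, probe, params)
        assert rep.verdict == "FAIL"
        chr2b = chr2[:25_000] + probe + chr2[25_000:]
        rep2, _ = check_specificity(
            GenomeAssembly({"I": chr1, "II": chr2b}), probe, params
        )
        assert rep2.verdict == "FAIL"
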