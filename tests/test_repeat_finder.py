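"""Wraparound scoring kernel, tandem array detection, locus merging, spans."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repeatfish.repeat_finder import (
    DetectorParams,
    compute_locus_span,
    filter_by_span,
    find_tandem_repeats,
    merge_arrays_to_loci,
    RepeatLocus,
    score_wraparound,
    TandemRepeatArray,
)
from repeatfish.sequence_io import GenomeAssembly, GenomicInterval
from repeatfish._utils import revcomp

from conftest import oracle_has_array, random_seq, sw_tandem_score, to_seq


class TestScoreWraparound:
    def test_perfect_repeat(self):
        assert score_wraparound("ACGTACGTACGT", "ACGT") == 24

    def test_one_substitution(self):
        # 11 matches and 1 substitution: 22 - 7 = 15, confirmed by the
        # independent Smith-Waterman oracle
        assert sw_tandem_score("ACGTACCTACGT", "ACGT") == 15
        assert score_wraparound("ACGTACCTACGT", "ACGT") == 15

    def test_all_mismatch_floors_at_zero(self):
        assert score_wraparound("AAAA", "C") == 0

    def test_empty_segment(self):
        assert score_wraparound("", "ACGT") == 0

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            score_wraparound("ACGT", "")

    @settings(max_examples=150, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=0, max_size=28),
        st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    def test_matches_smith_waterman_oracle(self, segment, motif):
        assert score_wraparound(segment, motif) == sw_tandem_score(segment, motif)

    def test_extra_substitution_never_increases_score(self, rng):
        for _ in range(20):
            p = int(rng.integers(2, 9))
            copies = int(rng.integers(3, 8))
            motif = random_seq(rng, p)
            seg = list(motif * copies)
            pos = int(rng.integers(0, len(seg)))
            orig = seg[pos]
            seg[pos] = "ACGT"[("ACGT".index(orig) + 1) % 4]
            assert score_wraparound("".join(seg), motif) <= score_wraparound(
                motif * copies, motif
            )


class TestFindTandemRepeats:
    def test_perfect_chromosome_wide_array(self):
        g = GenomeAssembly({"chr1": "ACGT" * 1500})
        arrays = find_tandem_repeats(g)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.interval.start, a.interval.end) == (1, 6000)
        assert a.period == 4  # smallest period wins for perfect arrays
        assert a.consensus_motif == "ACGT"
        assert a.alignment_score == 12000

    def test_random_sequence_yields_no_spanning_locus(self):
        rng = np.random.default_rng(42)
        g = GenomeAssembly({"c": to_seq(rng.integers(0, 4, 10_000))})
        loci = filter_by_span(merge_arrays_to_loci(find_tandem_repeats(g)))
        assert loci == []

    def test_planted_diverged_array_recovered(self):
        rng = np.random.default_rng(7)
        bg = rng.integers(0, 4, 20_000)
        motif = rng.integers(0, 4, 96)
        arr = np.tile(motif, 150)
        subs = rng.random(len(arr)) < 0.02
        arr = np.where(subs, (arr + rng.integers(1, 4, len(arr))) % 4, arr)
        bg[2000 : 2000 + len(arr)] = arr
        arrays = find_tandem_repeats(GenomeAssembly({"c": to_seq(bg)}))
        assert len(arrays) == 1
        a = arrays[0]
        assert abs(a.period - 96) <= 2
        planted = set(range(2001, 2001 + len(arr)))
        reported = set(range(a.interval.start, a.interval.end + 1))
        assert len(planted & reported) >= 0.95 * len(planted)
        assert a.copy_number == pytest.approx(150, rel=0.05)
        assert a.percent_identity > 95

    def test_short_chromosome_skipped(self):
        g = GenomeAssembly({"tiny": "A", "ok": "ACGT" * 20})
        arrays = find_tandem_repeats(g)
        assert all(a.interval.chrom == "ok" for a in arrays)

    def test_interval_never_contains_n(self):
        core = "ACGTT" * 30
        g = GenomeAssembly({"c": core + "NN" + core})
        for a in find_tandem_repeats(g):
            seq = g.records["c"][a.interval.start - 1 : a.interval.end]
            assert "N" not in seq

    def test_oracle_equivalence_small_instances(self, rng):
        """Detector reports an array iff brute-force enumeration over
        (offset, period <= 20, extent >= 2 copies) reaches score 50."""
        cases = []
        for _ in range(10):  # pure background
            cases.append(random_seq(rng, 200))
        for _ in range(10):  # planted perfect arrays straddling the threshold
            p = int(rng.integers(3, 13))
            ncopy = int(rng.integers(2, 8))
            plant = (random_seq(rng, p) * (ncopy + 2))[: p * ncopy]
            bg = random_seq(rng, 200)
            pos = int(rng.integers(0, 200 - len(plant)))
            cases.append(bg[:pos] + plant + bg[pos + len(plant):])
        agree = 0
        for seq in cases:
            detected = bool(find_tandem_repeats(GenomeAssembly({"c": seq})))
            expected = oracle_has_array(seq)
            assert detected == expected, f"disagreement on {seq}"
            agree += 1
        assert agree == len(cases)


class TestLoci:
    def _arr(self, chrom, start, end, motif, period=None, score=500):
        return TandemRepeatArray(
            interval=GenomicInterval(chrom, start, end),
            period=period or len(motif),
            copy_number=(end - start + 1) / len(motif),
            consensus_motif=motif,
            alignment_score=score,
            percent_identity=100.0,
        )

    def test_published_multi_interval_span(self):
        ivs = [
            GenomicInterval("I", 15772551, 15784070),
            GenomicInterval("I", 15789511, 15807243),
            GenomicInterval("I", 15847728, 15890937),
        ]
        assert compute_locus_span(ivs) == 72.46

    def test_published_single_interval_span(self):
        assert compute_locus_span([GenomicInterval("II", 6603736, 6620597)]) == 16.86

    def test_nearby_same_motif_arrays_merge(self):
        m = "ACGTTGCA" * 2
        arrays = [
            self._arr("I", 1000, 2000, m),
            self._arr("I", 10_000, 12_000, m),
        ]
        loci = merge_arrays_to_loci(arrays, max_gap=50_000)
        assert len(loci) == 1
        assert len(loci[0].intervals) == 2

    def test_rotated_and_revcomp_motifs_merge(self):
        m = "AACCGGTTACGTACCA"
        rot = m[5:] + m[:5]
        rc = revcomp(m)
        arrays = [
            self._arr("I", 1000, 2000, m),
            self._arr("I", 5000, 6000, rot),
            self._arr("I", 9000, 9900, rc),
        ]
        assert len(merge_arrays_to_loci(arrays)) == 1

    def test_unrelated_adjacent_motifs_stay_separate(self):
        arrays = [
            self._arr("I", 1000, 2000, "ACGTTGCAAC"),
            self._arr("I", 2100, 3000, "GGATCCAGTA"),
        ]
        assert len(merge_arrays_to_loci(arrays)) == 2

    def test_distant_same_motif_arrays_split(self):
        m = "ACGTTGCAGG"
        arrays = [self._arr("I", 1000, 2000, m), self._arr("I", 90_000, 92_000, m)]
        assert len(merge_arrays_to_loci(arrays, max_gap=50_000)) == 2

    def test_span_filter_is_strict(self):
        mk = lambda span: RepeatLocus(
            "ACGT", (GenomicInterval("I", 1, 1 + int(span * 1000)),), span
        )
        kept = filter_by_span([mk(5.05), mk(4.99), mk(5.00)], 5.0)
        assert [l.span_kb for l in kept] == [5.05]
        assert filter_by_span([], 5.0) == []


class TestDetectorParams:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            DetectorParams(match_score=0)
        with pytest.raises(ValueError):
            DetectorParams(max_period=0)
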