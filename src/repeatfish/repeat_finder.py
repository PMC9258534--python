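"""Tandem repeat array detection, locus merging, and span filtering.

Detection proposes candidate periods from recurring k-mers (k = 5): two
occurrences of the same 5-mer at distance d <= max_period vote for period d
at that position. Dense vote runs become candidate regions; each candidate
is verified by wraparound dynamic programming of the region against a
majority-vote consensus of length d, scored with +match per aligned match,
-mismatch per substitution and -indel per inserted/deleted base, with local
(score floor 0) semantics. An array is reported when its alignment score
reaches the report threshold and it contains at least two motif copies.

Nearby arrays whose consensus motifs are equivalent up to rotation or
reverse complement are merged into a repeat locus whose span statistic
(total kb covered, summed over sub-arrays) drives the > 5 kb selection
filter used to nominate FISH targets.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np

from ._utils import canonical_motif, encode, round_half_up
from .sequence_io import GenomeAssembly, GenomicInterval

logger = logging.getLogger(__name__)

KMER_SIZE = 5
# stop DP extension once the running row maximum falls this far below the
# best score seen (X-drop style termination)
XDROP = 50


@dataclass(frozen=True)
class DetectorParams:
    """Scoring and reporting parameters of the repeat detector."""

    match_score: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    min_report_score: int = 50
    max_period: int = 200

    def __post_init__(self) -> None:
        if min(
            self.match_score,
            self.mismatch_penalty,
            self.indel_penalty,
            self.min_report_score,
            self.max_period,
        ) < 1:
            raise ValueError("all detector parameters must be positive")


@dataclass(frozen=True)
class TandemRepeatArray:
    """One detected tandem array: where, what motif, how well it repeats."""

    interval: GenomicInterval
    period: int
    copy_number: float
    consensus_motif: str
    alignment_score: int
    percent_identity: float


@dataclass(frozen=True)
class RepeatLocus:
    """One or more nearby arrays of one motif with a total-span statistic."""

    motif: str
    intervals: tuple[GenomicInterval, ...]
    span_kb: float
    period: int = 0
    copy_number: float = 0.0
    score: int = 0

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom


def compute_locus_span(intervals) -> float:
    """Total span in kb: sum of (end - start) per interval, half-up to 2 dp.

    The difference of the genomic indices (not the +1 inclusive length) is
    what reproduces published span columns.
    """
    total = sum(iv.end - iv.start for iv in intervals)
    return round_half_up(total / 1000.0, 2)


# ---------------------------------------------------------------------------
# wraparound dynamic programming kernel


def _wdp_scan(seg: np.ndarray, motif: np.ndarray, params: DetectorParams):
    """Forward local wraparound DP; returns (best score, best end row).

    Row i holds the best local alignment score ending at segment position i
    for each motif phase. The within-row wrap (gaps consuming motif bases
    across the motif boundary) is resolved with a doubled-array running-max
    scan. Extension stops early once the row maximum X-drops.
    """
    p = len(motif)
    m, mm, ind = params.match_score, params.mismatch_penalty, params.indel_penalty
    prev = np.zeros(p, dtype=np.int64)
    idx2 = np.arange(2 * p, dtype=np.int64)
    best = 0
    best_row = -1
    for i in range(len(seg)):
        sub = np.where(motif == seg[i], m, -mm)
        cand = np.maximum(np.roll(prev, 1) + sub, prev - ind)
        d = np.concatenate((cand, cand))
        run = np.maximum.accumulate(d + ind * idx2)
        h = np.maximum(d[p:], run[p:] - ind * idx2[p:])
        np.maximum(h, 0, out=h)
        prev = h
        rm = int(h.max())
        if rm > best:
            best, best_row = rm, i
        elif best - rm > XDROP:
            break
    return best, best_row


def score_wraparound(segment: str, motif: str, params: DetectorParams | None = None) -> int:
    """Best local alignment score of ``segment`` against tandem motif copies.

    The alignment may wrap across motif boundaries any number of times;
    flanking segment bases may be left unaligned (local semantics).
    An empty segment scores 0.
    """
    if params is None:
        params = DetectorParams()
    if not motif:
        raise ValueError("motif must be non-empty")
    if not segment:
        return 0
    best, _ = _wdp_scan(encode(segment), encode(motif), params)
    return best


def _align_bounds(seg: np.ndarray, motif: np.ndarray, params: DetectorParams):
    """(score, start, end) of the best local wraparound alignment (0-based)."""
    best, end = _wdp_scan(seg, motif, params)
    if end < 0:
        return 0, 0, -1
    rbest, rend = _wdp_scan(seg[: end + 1][::-1], motif[::-1], params)
    start = end - rend
    return max(best, rbest), start, end


# ---------------------------------------------------------------------------
# candidate proposal

_MIN_RUN_VOTES = 4
_MAX_SEED_PARTNERS = 64


def _kmer_positions(arr: np.ndarray, k: int) -> dict[int, np.ndarray]:
    n = len(arr)
    if n < k:
        return {}
    codes = arr.astype(np.int64)
    val = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        w = codes[j : j + n - k + 1]
        val = val * 4 + np.where(w == 255, 0, w)
        ok &= w != 255
    pos_all = np.flatnonzero(ok)
    vals = val[pos_all]
    order = np.argsort(vals, kind="stable")
    vals, pos_all = vals[order], pos_all[order]
    bounds = np.flatnonzero(np.diff(vals)) + 1
    out = {}
    for s, e in zip(np.concatenate(([0], bounds)), np.concatenate((bounds, [len(vals)]))):
        if e - s > 1:
            out[int(vals[s])] = np.sort(pos_all[s:e])
    return out


def _vote_runs(seq_arr: np.ndarray, params: DetectorParams):
    """Yield (period, region_start, region_end) candidates from k-mer votes."""
    votes: dict[int, list[int]] = defaultdict(list)
    for pos in _kmer_positions(seq_arr, KMER_SIZE).values():
        pl = pos.tolist()
        for i, a in enumerate(pl):
            for b in pl[i + 1 : i + 1 + _MAX_SEED_PARTNERS]:
                d = b - a
                if d > params.max_period:
                    break
                votes[d].append(a)
    # a genuine array votes at nearly every position (density ~1 for perfect
    # repeats, ~(1-q)^2k at substitution rate q), so runs are chained with a
    # short constant gap and must be reasonably dense; sparse chance votes in
    # background sequence fail one or the other
    gap_thresh = 50
    for d, positions in sorted(votes.items()):
        positions.sort()
        run_start = positions[0]
        run_prev = positions[0]
        count = 1
        runs = []
        for pnt in positions[1:]:
            if pnt - run_prev <= gap_thresh:
                run_prev = pnt
                count += 1
            else:
                runs.append((run_start, run_prev, count))
                run_start = run_prev = pnt
                count = 1
        runs.append((run_start, run_prev, count))
        for a, b, cnt in runs:
            if cnt >= _MIN_RUN_VOTES and 4 * cnt >= b - a:
                # the votes support [a, b + d + k); margins beyond that are
                # for boundary refinement only and must not dilute consensus
                tight_lo, tight_hi = a, min(len(seq_arr), b + d + KMER_SIZE)
                lo = max(0, a - d - 10)
                hi = min(len(seq_arr), b + 2 * d + KMER_SIZE + 10)
                yield d, lo, hi, tight_lo, tight_hi


def _split_at_n(arr: np.ndarray, lo: int, hi: int):
    """Split [lo, hi) at N positions; N can never sit inside a reported array."""
    block = arr[lo:hi]
    n_pos = np.flatnonzero(block == 255)
    if len(n_pos) == 0:
        yield lo, hi
        return
    prev = 0
    for np_ in n_pos.tolist() + [hi - lo]:
        if np_ > prev:
            yield lo + prev, lo + np_
        prev = np_ + 1


def _consensus(arr: np.ndarray, start: int, end: int, period: int) -> np.ndarray | None:
    """Majority-vote consensus over phases (pos - start) mod period.

    Ties resolve to the smallest base code, so the result is deterministic.
    """
    region = arr[start:end]
    valid = region != 255
    phases = np.arange(len(region), dtype=np.int64) % period
    counts = np.bincount(
        phases[valid] * 4 + region[valid].astype(np.int64), minlength=period * 4
    ).reshape(period, 4)
    if (counts.sum(axis=1) == 0).any():
        return None
    return counts.argmax(axis=1).astype(np.uint8)


def _kadane(vals: np.ndarray):
    """Best-scoring contiguous run: (score, start, end), leftmost on ties."""
    cs = np.concatenate(([0], np.cumsum(vals)))
    run_min = np.minimum.accumulate(cs[:-1])
    gains = cs[1:] - run_min
    end = int(np.argmax(gains))
    score = int(gains[end])
    start = int(np.flatnonzero(cs[: end + 1] == run_min[end])[0])
    return score, start, end


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def find_tandem_repeats(
    genome: GenomeAssembly, params: DetectorParams | None = None
) -> list[TandemRepeatArray]:
    """Detect tandem repeat arrays on every chromosome.

    Deterministic for a fixed input: candidates are verified in sorted order
    and overlapping candidates are resolved by (higher score, then smaller
    period, then leftmost).
    """
    if params is None:
        params = DetectorParams()
    out: list[TandemRepeatArray] = []
    for chrom, seq in genome.records.items():
        if len(seq) < 2:
            logger.info("skipping chromosome %s: shorter than 2 bases", chrom)
            continue
        arr = genome.encoded(chrom)
        verified: list[TandemRepeatArray] = []
        seen: set[tuple[int, int, int]] = set()
        for d, lo0, hi0, tlo, thi in _vote_runs(arr, params):
            for lo, hi in _split_at_n(arr, lo0, hi0):
                if hi - lo < 2 * d or (d, lo, hi) in seen:
                    continue
                seen.add((d, lo, hi))
                if _already_explained(verified, lo, hi, params):
                    continue
                _verify_region(chrom, arr, lo, hi, d, params, verified,
                               cons_bounds=(max(lo, tlo), min(hi, thi)))
        out.extend(_resolve_overlaps(verified))
    out.sort(key=lambda a: (list(genome.records).index(a.interval.chrom), a.interval.start))
    return out


def _already_explained(accepted, lo, hi, params) -> bool:
    """True when a previously verified array already accounts for a region.

    Candidate periods are examined smallest first, so once an array explains
    most of a region with a score near the ceiling for its length, the
    larger-period (or slightly off-period) re-readings of the same bases are
    redundant; the overlap-resolution tie rules would discard them anyway.
    """
    span = hi - lo
    for a in accepted:
        s, e = a.interval.start - 1, a.interval.end - 1
        ov = min(e, hi - 1) - max(s, lo) + 1
        if ov >= 0.9 * span and a.alignment_score >= 1.2 * span:
            return True
    return False


def _verify_region(chrom, arr, lo, hi, period, params, out, depth=0,
                   cons_bounds=None):
    """Verify one candidate region against its phase-locked consensus.

    Verification uses the ungapped restriction of the wraparound alignment
    (substitutions only): the best contiguous run against the tiled
    consensus, re-anchored once so the reported motif starts in phase with
    the array start. Arrays interrupted by indels shift phase; the flanks of
    an accepted run are re-examined recursively with a freshly derived
    consensus, so each phase-coherent sub-run is reported as its own array
    (the locus merger later reunites them). If a mixed-phase consensus hides
    every run, the region is bisected and retried.
    """
    if hi - lo < 2 * period or depth > 40:
        return
    c_lo, c_hi = (lo, hi) if cons_bounds is None else cons_bounds
    if c_hi - c_lo < period:
        c_lo, c_hi = lo, hi
    cons = _consensus(arr, c_lo, c_hi, period)
    if cons is None:
        cons = _consensus(arr, lo, hi, period)
        c_lo = lo
        if cons is None:
            return
    region = arr[lo:hi]
    phases = (np.arange(lo, hi, dtype=np.int64) - c_lo) % period
    vals = np.where(region == cons[phases], params.match_score,
                    -params.mismatch_penalty)
    score, s0, e0 = _kadane(vals)
    if score < params.min_report_score or e0 - s0 + 1 < 2 * period:
        # a phase mixture can wash out the consensus; bisect and retry, but
        # not where an accepted array already explains the bases
        if hi - lo >= 4 * period and not _already_explained(out, lo, hi, params):
            mid = (lo + hi) // 2
            if mid + 2 * period < hi and mid - 2 * period > lo:
                _verify_region(chrom, arr, lo, mid + 2 * period, period, params,
                               out, depth + 1)
                _verify_region(chrom, arr, mid - 2 * period, hi, period, params,
                               out, depth + 1)
        return
    start, end = lo + s0, lo + e0
    cons2 = _consensus(arr, start, end + 1, period)
    seg = arr[start : end + 1]
    vals2 = np.where(seg == np.resize(cons2, len(seg)), params.match_score,
                     -params.mismatch_penalty)
    score2, s1, e1 = _kadane(vals2)
    if score2 >= params.min_report_score and e1 - s1 + 1 >= 2 * period:
        fstart, fend = start + s1, start + e1
        motif = np.roll(cons2, -(s1 % period)) if s1 % period else cons2
        length = fend - fstart + 1
        tiled = np.resize(motif, length)
        fseg = arr[fstart : fend + 1]
        identity = round_half_up(100.0 * float(np.mean(fseg == tiled)), 1)
        out.append(
            TandemRepeatArray(
                interval=GenomicInterval(chrom, fstart + 1, fend + 1),
                period=period,
                copy_number=round_half_up(length / period, 1),
                consensus_motif=_decode(motif),
                alignment_score=int(score2),
                percent_identity=identity,
            )
        )
    # flanks may hold further (phase-shifted) runs
    _verify_region(chrom, arr, lo, start, period, params, out, depth + 1)
    _verify_region(chrom, arr, end + 1, hi, period, params, out, depth + 1)


def _resolve_overlaps(arrays: list[TandemRepeatArray]) -> list[TandemRepeatArray]:
    """Keep the higher-scoring of overlapping candidates; ties favor the
    smaller period, then the leftmost start."""
    ranked = sorted(
        arrays,
        key=lambda a: (-a.alignment_score, a.period, a.interval.start, a.interval.end),
    )
    accepted: list[TandemRepeatArray] = []
    for a in ranked:
        clash = False
        for b in accepted:
            lo = max(a.interval.start, b.interval.start)
            hi = min(a.interval.end, b.interval.end)
            if hi >= lo:
                ov = hi - lo + 1
                if ov > 0.5 * min(len(a.interval), len(b.interval)):
                    clash = True
                    break
        if not clash:
            accepted.append(a)
    accepted.sort(key=lambda a: a.interval.start)
    return accepted


# ---------------------------------------------------------------------------
# locus assembly


def merge_arrays_to_loci(
    arrays: list[TandemRepeatArray], max_gap: int = 50_000
) -> list[RepeatLocus]:
    """Combine same-chromosome arrays of equivalent motifs into loci.

    Motifs are equivalent when identical up to rotation or reverse
    complement of a rotation. Arrays within ``max_gap`` chain into one
    locus; overlapping intervals are unioned so locus intervals are sorted
    and non-overlapping.
    """
    groups: dict[tuple[str, str], list[TandemRepeatArray]] = defaultdict(list)
    for a in arrays:
        groups[(a.interval.chrom, canonical_motif(a.consensus_motif))].append(a)
    loci: list[RepeatLocus] = []
    for (_chrom, _canon), members in groups.items():
        members.sort(key=lambda a: a.interval.start)
        chains: list[list[TandemRepeatArray]] = [[members[0]]]
        for a in members[1:]:
            if a.interval.start - chains[-1][-1].interval.end <= max_gap:
                chains[-1].append(a)
            else:
                chains.append([a])
        for chain in chains:
            intervals: list[GenomicInterval] = []
            for a in chain:
                iv = a.interval
                if intervals and iv.start <= intervals[-1].end + 1:
                    prev = intervals[-1]
                    intervals[-1] = GenomicInterval(
                        prev.chrom, prev.start, max(prev.end, iv.end)
                    )
                else:
                    intervals.append(replace(iv))
            rep = max(chain, key=lambda a: a.alignment_score)
            loci.append(
                RepeatLocus(
                    motif=rep.consensus_motif,
                    intervals=tuple(intervals),
                    span_kb=compute_locus_span(intervals),
                    period=rep.period,
                    copy_number=round_half_up(sum(a.copy_number for a in chain), 1),
                    score=max(a.alignment_score for a in chain),
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.intervals[0].start))
    return loci


def filter_by_span(loci: list[RepeatLocus], min_span_kb: float = 5.0) -> list[RepeatLocus]:
    """Keep loci spanning strictly more than ``min_span_kb``; order preserved."""
    return [l for l in loci if l.span_kb > min_span_kb]
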