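"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately written with different algorithms from
the package (plain Smith-Waterman over an unrolled reference, per-offset
full scans) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings as _hsettings

from repeatfish._utils import revcomp

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

BASES = "ACGT"


def to_seq(codes) -> str:
    return "".join(BASES[int(c)] for c in codes)


def random_seq(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), n))


# ---------------------------------------------------------------------------
# oracle 1: plain Smith-Waterman of a segment against unrolled tandem copies


def sw_tandem_score(segment: str, motif: str, match=2, mismatch=7, indel=7) -> int:
    """Local alignment score of segment vs enough tandem copies of motif.

    Quadratic full-matrix Smith-Waterman; the reference is the motif
    unrolled to more than twice the segment length, which (by periodicity)
    is equivalent to an unbounded tandem reference.
    """
    if not segment:
        return 0
    copies = (2 * len(segment)) // len(motif) + 2
    ref = motif * copies
    prev = [0] * (len(ref) + 1)
    best = 0
    for i in range(1, len(segment) + 1):
        cur = [0] * (len(ref) + 1)
        for j in range(1, len(ref) + 1):
            sub = match if segment[i - 1] == ref[j - 1] else -mismatch
            cur[j] = max(0, prev[j - 1] + sub, prev[j] - indel, cur[j - 1] - indel)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


# ---------------------------------------------------------------------------
# oracle 2: brute-force tandem-array existence by (offset, period, extent)


def oracle_has_array(seq: str, max_period: int = 20, min_score: int = 50,
                     match=2, mismatch=7) -> bool:
    """Does any (offset, period <= max_period, extent >= 2*period) achieve a
    wraparound score >= min_score against its own leading motif copy?

    The motif is the first ``period`` bases at the offset; the score is the
    running ungapped sum of +match/-mismatch over the tiled comparison,
    maximized over extents of at least two full copies.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    for p in range(1, min(max_period, n // 2) + 1):
        for i in range(n - 2 * p + 1):
            t_max = n - i
            idx = i + (np.arange(t_max) % p)
            vals = np.where(arr[i : i + t_max] == arr[idx], match, -mismatch)
            prefix = np.cumsum(vals)
            if prefix[2 * p - 1 :].max() >= min_score:
                return True
    return False


# ---------------------------------------------------------------------------
# oracle 3: naive per-offset hit scan on both strands

KA_LAMBDA = 1.374
KA_K = 0.711


def naive_find_hits(records: dict[str, str], query: str, evalue_max=10.0):
    """Full scan over every offset and both strands; best contiguous +1/-3
    run per offset, kept when its E-value passes.

    Returns a set of (chrom, start, end, strand, score) with 1-based
    inclusive coordinates.
    """
    genome_len = sum(len(s) for s in records.values())
    m = len(query)
    out = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for chrom, seq in records.items():
            n = len(seq)
            for off in range(-(m - 1), n):
                g_lo, g_hi = max(0, off), min(n, off + m)
                if g_hi - g_lo <= 0:
                    continue
                best = 0
                run = 0
                best_end = -1
                run_start = g_lo
                best_start = g_lo
                for g in range(g_lo, g_hi):
                    sc = 1 if seq[g] == q[g - off] and seq[g] != "N" else -3
                    if run <= 0:
                        run = sc
                        run_start = g
                    else:
                        run += sc
                    if run > best:
                        best = run
                        best_end = g
                        best_start = run_start
                if best <= 0:
                    continue
                ev = KA_K * m * genome_len * math.exp(-KA_LAMBDA * best)
                if ev <= evalue_max:
                    out.add((chrom, best_start + 1, best_end + 1, strand, best))
    return out


# ---------------------------------------------------------------------------
# genome constructions that provably exclude chance seed matches


def make_seedless_background(rng: np.random.Generator, n: int, query: str,
                             word_size: int = 11) -> str:
    """Random background guaranteed to share no seed word with ``query``.

    Built in chunks; any chunk sharing a ``word_size``-mer with the query
    (either strand) is resampled. Deterministic for a fixed generator state.
    """
    bad_words = set()
    for q in (query, revcomp(query)):
        for i in range(len(q) - word_size + 1):
            bad_words.add(q[i : i + word_size])
    chunk = 997
    parts: list[str] = []
    tail = ""
    while sum(len(p) for p in parts) < n:
        cand = random_seq(rng, chunk)
        joined = tail + cand
        if any(w in joined for w in bad_words):
            continue
        parts.append(cand)
        tail = cand[-(word_size - 1):]
    return "".join(parts)[:n]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
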