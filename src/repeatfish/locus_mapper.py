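"""Genome-wide approximate matching of motifs/oligos and the two-condition
locus-specificity rule.

A query is mapped on both strands by exact-word seeding followed by ungapped
local extension along each seed diagonal, scored +1 per match / -3 per
mismatch. Hits are kept when their Karlin-Altschul E-value passes the
threshold (default 10). Hits are then single-linkage clustered per
chromosome and a candidate passes when (1) one cluster holds at least
``major_cluster_min_fraction`` of all hits and (2) no cluster exists on any
other chromosome; scattered singleton hits elsewhere are tolerated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._utils import encode, revcomp, round_half_up
from .sequence_io import GenomeAssembly, GenomicInterval

# Karlin-Altschul constants for the ungapped +1/-3 nucleotide scoring system
KA_LAMBDA = 1.374
KA_K = 0.711


@dataclass(frozen=True)
class MappingParams:
    """BLASTN-style mapping and clustering parameters.

    ``gap_open``/``gap_extend`` mirror the conventional gap penalties of the
    scoring system; hit extension itself is ungapped, so for substitution-
    level divergence the two scoring systems retain the same hit set.
    """

    match_reward: int = 1
    mismatch_penalty: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    evalue_max: float = 10.0
    word_size: int = 11
    cluster_gap: int = 50_000
    major_cluster_min_fraction: float = 0.9
    min_cluster_hits: int = 3

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not (0 < self.major_cluster_min_fraction <= 1):
            raise ValueError("major_cluster_min_fraction must be in (0, 1]")
        if self.min_cluster_hits < 2:
            raise ValueError("min_cluster_hits must be >= 2")


@dataclass(frozen=True)
class Hit:
    interval: GenomicInterval
    raw_score: int
    percent_identity: float
    evalue: float
    # aligned run in query coordinates (0-based inclusive, plus-orientation)
    q_start: int = 0
    q_end: int = 0


@dataclass(frozen=True)
class HitCluster:
    chrom: str
    start: int
    end: int
    hit_count: int
    hit_fraction: float


@dataclass(frozen=True)
class HitClusterReport:
    clusters: tuple[HitCluster, ...]
    singletons: int
    total_hits: int
    verdict: str  # PASS | FAIL
    failed_condition: str  # none | multiple_major_loci | clustered_offtarget_hits | no_hits
    diagnostic: str = ""


def estimate_evalue(raw_score: int, query_len: int, genome_len: int) -> float:
    """Expected number of chance alignments scoring >= raw_score.

    Karlin-Altschul E = K*m*n*exp(-lambda*S) with the ungapped +1/-3
    constants; decreasing in score, linear in the search space m*n.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return KA_K * query_len * genome_len * math.exp(-KA_LAMBDA * raw_score)


def _query_words(q: np.ndarray, w: int) -> dict[int, list[int]]:
    words: dict[int, list[int]] = {}
    for i in range(len(q) - w + 1):
        window = q[i : i + w]
        if (window == 255).any():
            continue
        val = 0
        for b in window:
            val = val * 4 + int(b)
        words.setdefault(val, []).append(i)
    return words


def _best_run(vals: np.ndarray):
    """Kadane: best contiguous score run, leftmost on ties -> (score, s, e)."""
    cs = np.concatenate(([0], np.cumsum(vals)))
    run_min = np.minimum.accumulate(cs[:-1])
    gains = cs[1:] - run_min
    end = int(np.argmax(gains))
    score = int(gains[end])
    start = int(np.flatnonzero(cs[: end + 1] == run_min[end])[0])
    return score, start, end


def find_hits(
    genome: GenomeAssembly, query: str, params: MappingParams | None = None
) -> list[Hit]:
    """All genome-wide matches of ``query`` on either strand passing E-value.

    Minus-strand hits are occurrences of the reverse complement in the
    forward text, reported in plus-strand coordinates. One hit is reported
    per seed diagonal: the best-scoring ungapped run at that offset.
    """
    if params is None:
        params = MappingParams()
    query = query.upper()
    if "N" in query or not set(query) <= set("ACGT"):
        raise ValueError("query must be unambiguous A/C/G/T")
    if len(query) < params.word_size:
        raise ValueError(
            f"query shorter than word size ({len(query)} < {params.word_size})"
        )
    genome_len = sum(genome.lengths.values())
    index = genome.word_index(params.word_size)
    hits: list[Hit] = []
    m = len(query)
    for strand, q in (("+", query), ("-", revcomp(query))):
        qarr = encode(q)
        words = _query_words(qarr, params.word_size)
        for chrom in genome.records:
            garr = genome.encoded(chrom)
            n = len(garr)
            offsets: set[int] = set()
            for val, qpos_list in words.items():
                gpos = index.get((chrom, val))
                if gpos is None:
                    continue
                for qpos in qpos_list:
                    offsets.update((gpos - qpos).tolist())
            for off in sorted(offsets):
                g_lo = max(0, off)
                g_hi = min(n, off + m)
                if g_hi - g_lo < params.word_size:
                    continue
                window = garr[g_lo:g_hi]
                qwin = qarr[g_lo - off : g_hi - off]
                vals = np.where(
                    (window == qwin) & (window != 255),
                    params.match_reward,
                    -params.mismatch_penalty,
                )
                score, s, e = _best_run(vals)
                if score <= 0:
                    continue
                ev = estimate_evalue(score, m, genome_len)
                if ev > params.evalue_max:
                    continue
                sub = vals[s : e + 1]
                ident = round_half_up(
                    100.0 * float(np.sum(sub == params.match_reward)) / len(sub), 1
                )
                q_lo = g_lo + s - off
                q_hi = g_lo + e - off
                if strand == "-":
                    q_lo, q_hi = m - 1 - q_hi, m - 1 - q_lo
                hits.append(
                    Hit(
                        interval=GenomicInterval(
                            chrom, g_lo + s + 1, g_lo + e + 1, strand
                        ),
                        raw_score=score,
                        percent_identity=ident,
                        evalue=ev,
                        q_start=q_lo,
                        q_end=q_hi,
                    )
                )
    hits.sort(key=lambda h: (list(genome.records).index(h.interval.chrom),
                             h.interval.start, h.interval.end, h.interval.strand))
    return hits


def cluster_hits(hits: list[Hit], params: MappingParams | None = None):
    """Single-linkage chaining of hits within ``cluster_gap`` per chromosome.

    Returns (clusters, singletons): groups of >= min_cluster_hits become
    clusters, the rest stay singleton hits.
    """
    if params is None:
        params = MappingParams()
    by_chrom: dict[str, list[Hit]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    total = len(hits)
    clusters: list[HitCluster] = []
    singletons: list[Hit] = []
    for chrom, chrom_hits in by_chrom.items():
        chrom_hits.sort(key=lambda h: (h.interval.start, h.interval.end))
        group: list[Hit] = [chrom_hits[0]]
        groups: list[list[Hit]] = [group]
        for h in chrom_hits[1:]:
            if h.interval.start - group[-1].interval.end <= params.cluster_gap:
                group.append(h)
            else:
                group = [h]
                groups.append(group)
        for g in groups:
            if len(g) >= params.min_cluster_hits:
                clusters.append(
                    HitCluster(
                        chrom=chrom,
                        start=min(h.interval.start for h in g),
                        end=max(h.interval.end for h in g),
                        hit_count=len(g),
                        hit_fraction=len(g) / total,
                    )
                )
            else:
                singletons.extend(g)
    clusters.sort(key=lambda c: (-c.hit_count, c.chrom, c.start))
    return clusters, singletons


def classify_specificity(
    clusters: list[HitCluster],
    singletons: list[Hit],
    params: MappingParams | None = None,
) -> HitClusterReport:
    """Apply the two-condition locus-specificity rule.

    PASS requires (1) exactly one cluster holding at least
    ``major_cluster_min_fraction`` of all hits and (2) no cluster on any
    other chromosome. Unclustered singleton hits anywhere are tolerated.
    """
    if params is None:
        params = MappingParams()
    total = sum(c.hit_count for c in clusters) + len(singletons)
    if total == 0:
        return HitClusterReport(
            clusters=(), singletons=0, total_hits=0, verdict="FAIL",
            failed_condition="no_hits",
            diagnostic="query has no genomic hits; probe would not hybridize",
        )
    # condition 2 first (relative to the largest cluster's chromosome): a
    # clustered off-target locus is the more specific failure label
    if clusters:
        target_chrom = clusters[0].chrom
        offtarget = [c for c in clusters if c.chrom != target_chrom]
        if offtarget:
            worst = offtarget[0]
            return HitClusterReport(
                clusters=tuple(clusters), singletons=len(singletons),
                total_hits=total, verdict="FAIL",
                failed_condition="clustered_offtarget_hits",
                diagnostic=f"{worst.hit_count} clustered hits on {worst.chrom}",
            )
    majors = [c for c in clusters if c.hit_fraction >= params.major_cluster_min_fraction]
    if len(majors) != 1:
        return HitClusterReport(
            clusters=tuple(clusters), singletons=len(singletons), total_hits=total,
            verdict="FAIL", failed_condition="multiple_major_loci",
            diagnostic=f"{len(majors)} clusters hold >= "
            f"{params.major_cluster_min_fraction:.0%} of hits",
        )
    return HitClusterReport(
        clusters=tuple(clusters), singletons=len(singletons), total_hits=total,
        verdict="PASS", failed_condition="none",
    )


def check_specificity(
    genome: GenomeAssembly, query: str, params: MappingParams | None = None
) -> tuple[HitClusterReport, list[Hit]]:
    """Convenience wrapper: find hits, cluster, classify."""
    if params is None:
        params = MappingParams()
    hits = find_hits(genome, query, params)
    clusters, singletons = cluster_hits(hits, params)
    return classify_specificity(clusters, singletons, params), hits
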