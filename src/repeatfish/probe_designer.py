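"""Turn a specificity-passing repeat locus into 1-2 short oligo probes.

The design path follows the selection procedure used for repeat FISH
panels: a consensus motif that cross-hybridizes elsewhere is first trimmed
to its largest locus-specific core; motifs longer than the oligo ceiling
(30 b) are split into nonoverlapping pieces of roughly 20 b (skipping
homopolymer runs, which make poor probe sequence); every candidate oligo is
then re-mapped genome-wide and must itself pass the two-condition
specificity rule. Tm is annotated but never used to select probes —
repetitive targets hybridize robustly across a wide predicted-Tm range.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from ._utils import round_half_up
from .locus_mapper import Hit, HitClusterReport, MappingParams, check_specificity
from .oligo_thermo import DimerParams, DimerReport, ThermoParams, dimer_scan, melting_temperature
from .repeat_finder import RepeatLocus
from .sequence_io import GenomeAssembly

logger = logging.getLogger(__name__)

_HOMOPOLYMER_MIN = 6  # split pieces re-anchor across runs at least this long


@dataclass(frozen=True)
class DesignParams:
    max_oligo_len: int = 30
    target_oligo_len: int = 20
    min_oligo_len: int = 17
    max_oligos_per_locus: int = 2

    def __post_init__(self) -> None:
        if not (self.min_oligo_len <= self.target_oligo_len <= self.max_oligo_len):
            raise ValueError("need min_oligo_len <= target_oligo_len <= max_oligo_len")


@dataclass(frozen=True)
class OligoProbe:
    probe_id: str
    sequence: str
    offset_in_motif: int
    length: int
    gc_pct: float
    tm_c: float
    specificity: HitClusterReport
    dimer_warnings: tuple[DimerReport, ...] = ()
    target_hit_count: int = 0


@dataclass(frozen=True)
class RejectRecord:
    locus: RepeatLocus
    reason: str


@dataclass(frozen=True)
class DesignResult:
    locus: RepeatLocus
    probes: tuple[OligoProbe, ...]
    reject: RejectRecord | None = None


def gc_content(sequence: str) -> float:
    """GC percentage, 1 decimal, half-up. A/C/G/T only."""
    seq = sequence.upper()
    if not seq or not set(seq) <= set("ACGT"):
        raise ValueError("sequence must be non-empty unambiguous A/C/G/T")
    return round_half_up(100.0 * (seq.count("G") + seq.count("C")) / len(seq), 1)


def _equal_pieces(length: int, params: DesignParams) -> list[int] | None:
    """Piece lengths as equal as possible, each within [min, max] oligo length.

    The piece count targets ~target_oligo_len per piece; neighbouring counts
    are tried so a length like 48 yields 24+24 rather than an invalid 16x3.
    """
    if length <= params.max_oligo_len:
        return [length]
    base = max(1, round(length / params.target_oligo_len))
    for n in sorted(range(1, length // params.min_oligo_len + 1),
                    key=lambda n: (abs(n - base), n)):
        size, extra = divmod(length, n)
        if size < params.min_oligo_len or size + (1 if extra else 0) > params.max_oligo_len:
            continue
        return [size + 1 if i < extra else size for i in range(n)]
    return None


def split_motif(motif: str, params: DesignParams | None = None) -> list[tuple[str, int]]:
    """Split a motif into nonoverlapping candidate oligos (sequence, offset).

    Motifs within the oligo ceiling are returned whole. Longer motifs are
    cut into near-equal pieces of roughly the target length. Homopolymer
    runs of >= 6 b are skipped entirely: pieces re-anchor on the segments
    between runs (such runs are poor probe sequence and real panels avoid
    them).
    """
    if params is None:
        params = DesignParams()
    if len(motif) < params.min_oligo_len:
        raise ValueError(
            f"motif shorter than min_oligo_len ({len(motif)} < {params.min_oligo_len})"
        )
    if len(motif) <= params.max_oligo_len:
        return [(motif, 0)]
    segments: list[tuple[int, int]] = []  # (start, end) exclusive
    prev = 0
    for m in re.finditer(r"(A{6,}|C{6,}|G{6,}|T{6,})".replace("6", str(_HOMOPOLYMER_MIN)), motif):
        if m.start() > prev:
            segments.append((prev, m.start()))
        prev = m.end()
    if prev < len(motif):
        segments.append((prev, len(motif)))
    out: list[tuple[str, int]] = []
    for seg_start, seg_end in segments:
        seg_len = seg_end - seg_start
        if seg_len < params.min_oligo_len:
            continue
        lengths = _equal_pieces(seg_len, params)
        if lengths is None:
            # segment not evenly divisible into valid pieces: take as many
            # target-length pieces as fit
            lengths = [params.target_oligo_len] * (seg_len // params.target_oligo_len)
        pos = seg_start
        for ln in lengths:
            out.append((motif[pos : pos + ln], pos))
            pos += ln
    return out


def trim_cross_hybridizing(
    motif: str,
    genome: GenomeAssembly,
    params: MappingParams | None = None,
    window: int = 20,
) -> str:
    """Largest contiguous sub-motif free of cross-hybridizing sequence.

    A motif that already passes the two-condition rule is returned
    unchanged. Otherwise, the bases of the motif that align into hit
    clusters outside the target locus are marked conflicted, and the
    longest contiguous sub-motif is returned that (a) contains no
    conflicted base and (b) has every ``window``-length piece passing the
    specificity rule on its own. Empty string when no such sub-motif
    exists.
    """
    if params is None:
        params = MappingParams()
    report, full_hits = check_specificity(genome, motif, params)
    if report.verdict == "PASS":
        return motif
    conflicted = [False] * len(motif)
    if report.clusters:
        target_chrom = report.clusters[0].chrom
        off_clusters = [c for c in report.clusters if c.chrom != target_chrom]
        for h in full_hits:
            for c in off_clusters:
                if (h.interval.chrom == c.chrom
                        and h.interval.start <= c.end and h.interval.end >= c.start):
                    for i in range(h.q_start, h.q_end + 1):
                        conflicted[i] = True
                    break
    if len(motif) < window:
        return ""
    ok = []
    for i in range(len(motif) - window + 1):
        if any(conflicted[i : i + window]):
            ok.append(False)
            continue
        wrep, _ = check_specificity(genome, motif[i : i + window], params)
        ok.append(wrep.verdict == "PASS")
    best_len = 0
    best_start = 0
    run_start = None
    for i, flag in enumerate(ok + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            length = (i - 1) - run_start + window
            if length > best_len:
                best_len, best_start = length, run_start
            run_start = None
    if best_len == 0:
        logger.info("no specific probe available for motif %s...", motif[:20])
        return ""
    return motif[best_start : best_start + best_len]


def _target_hits(hits: list[Hit], locus: RepeatLocus) -> int:
    count = 0
    for h in hits:
        if h.interval.chrom != locus.chrom:
            continue
        for iv in locus.intervals:
            if h.interval.start <= iv.end and h.interval.end >= iv.start:
                count += 1
                break
    return count


def design_probes(
    locus: RepeatLocus,
    genome: GenomeAssembly,
    design: DesignParams | None = None,
    mapping: MappingParams | None = None,
    thermo: ThermoParams | None = None,
    dimer: DimerParams | None = None,
    probe_id: str = "probe",
) -> DesignResult:
    """End-to-end design for one locus: trim, split, re-validate, annotate.

    Emits at most ``max_oligos_per_locus`` oligos, preferring specificity
    PASS, then more hits at the target locus, then length closest to the
    target, breaking remaining ties by motif offset. A locus with no passing
    oligo yields a reject record instead.
    """
    design = design or DesignParams()
    mapping = mapping or MappingParams()
    thermo = thermo or ThermoParams()
    dimer = dimer or DimerParams()

    motif = locus.motif
    report, _ = check_specificity(genome, motif, mapping)
    if report.verdict != "PASS":
        motif = trim_cross_hybridizing(
            locus.motif, genome, mapping, design.target_oligo_len
        )
        if len(motif) < design.min_oligo_len:
            return DesignResult(
                locus, (), RejectRecord(locus, "no specific sub-motif after trimming")
            )
    try:
        candidates = split_motif(motif, design)
    except ValueError as exc:
        return DesignResult(locus, (), RejectRecord(locus, str(exc)))

    motif_shift = locus.motif.find(motif)
    evaluated = []
    for seq, offset in candidates:
        if len(seq) < design.min_oligo_len:
            continue
        rep, hits = check_specificity(genome, seq, mapping)
        evaluated.append(
            OligoProbe(
                probe_id=probe_id,
                sequence=seq,
                offset_in_motif=motif_shift + offset,
                length=len(seq),
                gc_pct=gc_content(seq),
                tm_c=melting_temperature(seq, thermo),
                specificity=rep,
                target_hit_count=_target_hits(hits, locus),
            )
        )
    passing = [p for p in evaluated if p.specificity.verdict == "PASS"]
    if not passing:
        reasons = sorted({p.specificity.failed_condition for p in evaluated})
        return DesignResult(
            locus, (),
            RejectRecord(locus, "no oligo passes specificity: "
                         + (",".join(reasons) if reasons else "no candidates")),
        )
    passing.sort(
        key=lambda p: (
            -p.target_hit_count,
            abs(p.length - design.target_oligo_len),
            p.offset_in_motif,
        )
    )
    chosen = passing[: design.max_oligos_per_locus]
    chosen.sort(key=lambda p: p.offset_in_motif)
    # annotate homo-/heterodimer warnings within the emitted set
    final = []
    for i, p in enumerate(chosen):
        warnings: list[DimerReport] = []
        self_reports = dimer_scan(p.sequence, None, dimer)
        if self_reports:
            warnings.append(self_reports[0])
        for j, q in enumerate(chosen):
            if i == j:
                continue
            cross = dimer_scan(p.sequence, q.sequence, dimer)
            if cross:
                warnings.append(cross[0])
        final.append(
            OligoProbe(
                probe_id=p.probe_id, sequence=p.sequence,
                offset_in_motif=p.offset_in_motif, length=p.length,
                gc_pct=p.gc_pct, tm_c=p.tm_c, specificity=p.specificity,
                dimer_warnings=tuple(warnings),
                target_hit_count=p.target_hit_count,
            )
        )
    return DesignResult(locus, tuple(final))
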