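"""Genome and interval I/O with explicit coordinate conventions.

Internally every interval is 1-based and inclusive on both ends, matching the
coordinate style of published probe tables. BED export converts to 0-based
half-open; GFF3 and TSV stay 1-based inclusive. Multi-interval records (a
repeat locus made of nearby sub-arrays) are written to TSV as a single row
with "/"-joined "start-end" blocks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO

from ._utils import encode

VALID_BASES = frozenset("ACGTN")


class SequenceIOError(ValueError):
    """Malformed FASTA or an interval inconsistent with its assembly."""


@dataclass
class GenomeAssembly:
    """Named chromosome sequences, upper-cased, in input order.

    ``records`` maps chromosome name to its nucleotide string; ``lengths``
    mirrors it with base counts. Word indexes built by the hit finder are
    cached on the instance (see :meth:`word_index`).
    """

    records: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {name: len(seq) for name, seq in self.records.items()}
        for name, seq in self.records.items():
            if not name:
                raise SequenceIOError("empty chromosome name")
            if self.lengths[name] != len(seq):
                raise SequenceIOError(f"length mismatch for {name!r}")
        self._word_index_cache: dict[int, dict] = {}
        self._encoded_cache: dict[str, object] = {}

    def encoded(self, chrom: str):
        """uint8 encoding of a chromosome, cached."""
        arr = self._encoded_cache.get(chrom)
        if arr is None:
            arr = encode(self.records[chrom])
            self._encoded_cache[chrom] = arr
        return arr

    def word_index(self, word_size: int) -> dict:
        """Exact-word seed index: (chrom, word) -> sorted positions (0-based).

        Built lazily once per word size; words containing N are skipped.
        """
        import numpy as np

        idx = self._word_index_cache.get(word_size)
        if idx is not None:
            return idx
        idx = {}
        for chrom in self.records:
            arr = self.encoded(chrom)
            n = len(arr)
            if n < word_size:
                continue
            codes = arr.astype(np.int64)
            val = np.zeros(n - word_size + 1, dtype=np.int64)
            ok = np.ones(n - word_size + 1, dtype=bool)
            for k in range(word_size):
                window = codes[k : k + n - word_size + 1]
                val = val * 4 + np.where(window == 255, 0, window)
                ok &= window != 255
            order = np.argsort(val[ok], kind="stable")
            pos = np.flatnonzero(ok)[order]
            vals = val[ok][order]
            bounds = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], bounds))
            ends = np.concatenate((bounds, [len(vals)]))
            for s, e in zip(starts, ends):
                idx[(chrom, int(vals[s]))] = np.sort(pos[s:e])
        self._word_index_cache[word_size] = idx
        return idx


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SequenceIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise SequenceIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def validate(self, genome: GenomeAssembly) -> None:
        if self.chrom not in genome.lengths:
            raise SequenceIOError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.lengths[self.chrom]:
            raise SequenceIOError(
                f"interval {self.chrom}:{self.start}-{self.end} off chromosome "
                f"end ({genome.lengths[self.chrom]})"
            )


@dataclass(frozen=True)
class IntervalRecord:
    """A named feature made of one or more intervals on one chromosome."""

    name: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise SequenceIOError("record with no intervals")
        chroms = {iv.chrom for iv in self.intervals}
        if len(chroms) != 1:
            raise SequenceIOError("record intervals span multiple chromosomes")

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    def positions_str(self) -> str:
        return "/".join(f"{iv.start}-{iv.end}" for iv in self.intervals)


def read_fasta(path) -> GenomeAssembly:
    """Load a FASTA assembly, case-folded to upper.

    Rejects duplicate headers, empty records, and any character outside
    A/C/G/T/N (reported with its 1-based position).
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in records:
            raise SequenceIOError(f"duplicate FASTA header {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise SequenceIOError(f"empty FASTA record {name!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq, 1) if c in bad)
            raise SequenceIOError(
                f"non-IUPAC character {sorted(bad)[0]!r} in record {name!r} "
                f"at position {pos}"
            )
        records[name] = seq
    if not records:
        raise SequenceIOError(f"no FASTA records in {path}")
    return GenomeAssembly(records)


def write_fasta(genome: GenomeAssembly, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_intervals(
    records: list[IntervalRecord], path, fmt: str, genome: GenomeAssembly | None = None
) -> None:
    """Write interval records as BED, GFF3 or TSV.

    BED is 0-based half-open, one line per interval; GFF3 is 1-based
    inclusive, one line per interval; TSV is 1-based inclusive with one row
    per record and "/"-joined positions.
    """
    if genome is not None:
        for rec in records:
            for iv in rec.intervals:
                iv.validate(genome)
    fmt = fmt.upper()
    buf = io.StringIO()
    if fmt == "BED":
        for rec in records:
            for iv in rec.intervals:
                buf.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{rec.name}\t0\t{iv.strand}\n"
                )
    elif fmt == "GFF3":
        buf.write("##gff-version 3\n")
        for rec in records:
            for iv in rec.intervals:
                buf.write(
                    f"{iv.chrom}\trepeatfish\ttandem_repeat\t{iv.start}\t{iv.end}"
                    f"\t.\t{iv.strand}\t.\tID={rec.name}\n"
                )
    elif fmt == "TSV":
        buf.write("name\tchrom\tpositions\tstrand\n")
        for rec in records:
            buf.write(
                f"{rec.name}\t{rec.chrom}\t{rec.positions_str()}"
                f"\t{rec.intervals[0].strand}\n"
            )
    else:
        raise ValueError(f"unknown interval format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_intervals(path, fmt: str) -> list[IntervalRecord]:
    """Inverse of :func:`write_intervals` (round-trip safe per format)."""
    fmt = fmt.upper()
    grouped: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if fmt == "BED":
        for ln in lines:
            chrom, start, end, name, _score, strand = ln.split("\t")[:6]
            iv = GenomicInterval(chrom, int(start) + 1, int(end), strand)
            grouped.setdefault(name, []).append(iv)
            if name not in order:
                order.append(name)
    elif fmt == "GFF3":
        for ln in lines:
            if ln.startswith("#"):
                continue
            cols = ln.split("\t")
            name = dict(kv.split("=", 1) for kv in cols[8].split(";"))["ID"]
            iv = GenomicInterval(cols[0], int(cols[3]), int(cols[4]), cols[6])
            grouped.setdefault(name, []).append(iv)
            if name not in order:
                order.append(name)
    elif fmt == "TSV":
        for ln in lines[1:]:
            name, chrom, positions, strand = ln.split("\t")
            ivs = []
            for block in positions.split("/"):
                s, e = block.split("-")
                ivs.append(GenomicInterval(chrom, int(s), int(e), strand))
            grouped[name] = ivs
            order.append(name)
    else:
        raise ValueError(f"unknown interval format {fmt!r}")
    return [IntervalRecord(name, tuple(grouped[name])) for name in order]
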