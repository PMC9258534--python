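"""Seeded synthetic assemblies with planted tandem arrays and truth records.

Backgrounds are i.i.d. uniform A/C/G/T. Planted arrays are tandem copies of
a motif with a per-base substitution rate (and an optional low-rate indel
mode), optionally split into sub-arrays separated by background gaps, which
mimics repeat loci interrupted by insertions. Dispersed decoys copy motif
fragments to other chromosomes to exercise the cross-hybridization rules,
and a per-array copy-number multiplier models strain-specific copy-number
variation (a probe validated in the reference strain can drop out of a
variant strain whose array has collapsed).

Every generator is deterministic for a fixed seed, so fixtures never need
to ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .repeat_finder import RepeatLocus, compute_locus_span
from .sequence_io import GenomeAssembly, GenomicInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedArray:
    """One tandem array to embed.

    ``motif`` may be a sequence or an integer length (drawn from the spec's
    RNG); ``position`` is the 1-based start on ``chrom``. ``gaps`` splits
    the copies into sub-arrays separated by that many background bases.
    """

    chrom: str
    position: int
    motif: str | int
    copy_number: int
    substitution_rate: float = 0.02
    indel_rate: float = 0.0
    gaps: tuple[int, ...] = ()  # background gap after each sub-array split
    split_copies: tuple[int, ...] = ()  # copies per sub-array; must sum to copy_number
    cnv_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 0.2):
            raise ValueError("substitution_rate must be in [0, 0.2]")
        if not (0 <= self.indel_rate <= 0.01):
            raise ValueError("indel_rate must be in [0, 0.01]")
        if self.split_copies and sum(self.split_copies) != self.copy_number:
            raise ValueError("split_copies must sum to copy_number")
        if self.split_copies and len(self.gaps) != len(self.split_copies) - 1:
            raise ValueError("need one gap per adjacent sub-array pair")


@dataclass(frozen=True)
class DispersedDecoy:
    """Scattered (non-tandem) copies of a motif fragment on other chromosomes."""

    source_motif: str
    n_copies: int
    target_chroms: tuple[str, ...]
    identity: float = 1.0  # fraction of bases left unmutated per copy


@dataclass
class SyntheticGenomeSpec:
    chromosomes: list[tuple[str, int]]
    planted_arrays: list[PlantedArray] = field(default_factory=list)
    dispersed_decoys: list[DispersedDecoy] = field(default_factory=list)
    seed: int = 0


@dataclass(frozen=True)
class GenomeTruth:
    loci: tuple[RepeatLocus, ...]
    decoys: tuple[GenomicInterval, ...]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray, sub_rate: float,
            indel_rate: float) -> np.ndarray:
    out = codes.copy()
    if sub_rate > 0:
        mask = rng.random(len(out)) < sub_rate
        shift = rng.integers(1, 4, len(out), dtype=np.uint8)
        out[mask] = (out[mask] + shift[mask]) % 4
    if indel_rate > 0:
        pieces = []
        rolls = rng.random(len(out))
        ins = rng.integers(0, 4, len(out), dtype=np.uint8)
        for i, b in enumerate(out):
            if rolls[i] < indel_rate / 2:
                continue  # deletion
            pieces.append(b)
            if rolls[i] > 1 - indel_rate / 2:
                pieces.append(ins[i])
        out = np.array(pieces, dtype=np.uint8)
    return out


def generate(spec: SyntheticGenomeSpec) -> tuple[GenomeAssembly, GenomeTruth]:
    """Build the assembly and its truth records. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    chrom_codes = {name: _random_seq(rng, length) for name, length in spec.chromosomes}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in spec.chromosomes}
    truth_loci: list[RepeatLocus] = []

    for plant in spec.planted_arrays:
        if plant.chrom not in chrom_codes:
            raise ValueError(f"unknown chromosome {plant.chrom!r}")
        if isinstance(plant.motif, int):
            motif_codes = _random_seq(rng, plant.motif)
        else:
            motif_str = plant.motif.upper()
            if not set(motif_str) <= set("ACGT"):
                raise ValueError("planted motif must be A/C/G/T")
            motif_codes = np.frombuffer(motif_str.encode(), dtype=np.uint8).copy()
            lut = np.zeros(256, dtype=np.uint8)
            for i, b in enumerate("ACGT"):
                lut[ord(b)] = i
            motif_codes = lut[motif_codes]
        copies = int(round(plant.copy_number * plant.cnv_multiplier))
        if copies <= 0:
            continue  # array absent in this (variant-strain) genome
        splits = list(plant.split_copies) if plant.split_copies else [copies]
        if plant.split_copies:
            total = sum(plant.split_copies)
            splits = [max(1, int(round(c * copies / total))) for c in plant.split_copies]
        gaps = list(plant.gaps) + [0]
        pos = plant.position - 1  # 0-based
        intervals: list[GenomicInterval] = []
        target = chrom_codes[plant.chrom]
        for n_copies, gap in zip(splits, gaps):
            block = _mutate(rng, np.tile(motif_codes, n_copies),
                            plant.substitution_rate, plant.indel_rate)
            if pos + len(block) > len(target):
                raise ValueError(
                    f"planted array on {plant.chrom} extends past chromosome end"
                )
            for s, e in occupied[plant.chrom]:
                if pos < e and pos + len(block) > s:
                    raise ValueError(f"planted arrays overlap on {plant.chrom}")
            target[pos : pos + len(block)] = block
            occupied[plant.chrom].append((pos, pos + len(block)))
            intervals.append(GenomicInterval(plant.chrom, pos + 1, pos + len(block)))
            pos += len(block) + gap
        truth_loci.append(
            RepeatLocus(
                motif=_to_str(motif_codes),
                intervals=tuple(intervals),
                span_kb=compute_locus_span(intervals),
                period=len(motif_codes),
                copy_number=float(copies),
            )
        )

    decoy_intervals: list[GenomicInterval] = []
    for decoy in spec.dispersed_decoys:
        frag = decoy.source_motif.upper()
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        frag_codes = lut[np.frombuffer(frag.encode(), dtype=np.uint8)]
        for _ in range(decoy.n_copies):
            chrom = decoy.target_chroms[int(rng.integers(0, len(decoy.target_chroms)))]
            target = chrom_codes[chrom]
            copy = _mutate(rng, frag_codes, 1.0 - decoy.identity, 0.0)
            # rejection-sample a free placement
            for _attempt in range(1000):
                p = int(rng.integers(0, len(target) - len(copy)))
                if all(not (p < e and p + len(copy) > s) for s, e in occupied[chrom]):
                    break
            else:
                raise ValueError(f"no free space for decoy on {chrom}")
            target[p : p + len(copy)] = copy
            occupied[chrom].append((p, p + len(copy)))
            decoy_intervals.append(GenomicInterval(chrom, p + 1, p + len(copy)))

    genome = GenomeAssembly({name: _to_str(chrom_codes[name]) for name, _ in spec.chromosomes})
    return genome, GenomeTruth(tuple(truth_loci), tuple(decoy_intervals))


def nematode_like_spec(seed: int = 0, chrom_length: int = 50_000) -> SyntheticGenomeSpec:
    """Standard validation scenario: a six-chromosome karyotype (five
    autosomes and an X) with one locus-specific tandem array per chromosome.

    Chromosomes are scaled to tens of kb so the whole pipeline runs in
    seconds; motif lengths span the short/long regimes seen in real
    satellite panels (25-120 b), copy numbers give spans comfortably above
    the 5 kb selection threshold, and arrays diverge at 2% per base.
    """
    lengths = {"I": 68, "II": 48, "III": 96, "IV": 25, "V": 120, "X": 68}
    copies = {"I": 100, "II": 150, "III": 80, "IV": 300, "V": 60, "X": 110}
    return SyntheticGenomeSpec(
        chromosomes=[(name, chrom_length) for name in lengths],
        planted_arrays=[
            PlantedArray(name, chrom_length // 5 + 1, lengths[name],
                         copies[name], 0.02)
            for name in lengths
        ],
        seed=seed,
    )


def make_conflict_genome(
    spec: SyntheticGenomeSpec,
    shared_fraction: float,
    conflict_chrom: str,
    array_index: int = 0,
    n_conflict_copies: int = 20,
    min_shared_len: int = 11,
) -> tuple[GenomeAssembly, GenomeTruth]:
    """Plant a cross-hybridization conflict for one designated array.

    The 5' ``shared_fraction`` of the designated motif is tandem-amplified
    on ``conflict_chrom``, producing a motif that fails the two-condition
    rule until trimmed. ``shared_fraction`` 0 plants nothing.
    """
    if not (0 <= shared_fraction <= 1):
        raise ValueError("shared_fraction must be in [0, 1]")
    genome, truth = generate(spec)
    plant = spec.planted_arrays[array_index]
    motif = truth.loci[array_index].motif
    shared_len = int(round(shared_fraction * len(motif)))
    if shared_fraction == 0:
        return genome, truth
    if shared_len < min_shared_len:
        raise ValueError(
            f"shared fragment of {shared_len} b is below the seed word size; "
            "the conflict would be invisible to the mapper"
        )
    fragment = motif[:shared_len]
    rng = np.random.default_rng(spec.seed + 1)
    records = dict(genome.records)
    target = records[conflict_chrom]
    block = fragment * n_conflict_copies
    # place in the middle of the conflict chromosome, away from any plant
    occupied = [
        (iv.start - 1, iv.end)
        for locus in truth.loci
        for iv in locus.intervals
        if iv.chrom == conflict_chrom
    ]
    for _attempt in range(1000):
        p = int(rng.integers(0, len(target) - len(block)))
        if all(not (p < e and p + len(block) > s) for s, e in occupied):
            break
    else:
        raise ValueError("no free space for conflict block")
    records[conflict_chrom] = target[:p] + block + target[p + len(block):]
    decoys = truth.decoys + (
        GenomicInterval(conflict_chrom, p + 1, p + len(block)),
    )
    return GenomeAssembly(records), GenomeTruth(truth.loci, decoys)
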