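"""Small shared helpers: rounding, complements, base encoding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A=0 C=1 G=2 T=3; N (and anything else) = 255 so it mismatches everything
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed reports conventionally do.

    Python's round() is banker's rounding; report columns (spans, GC%, Tm)
    use ordinary half-up rounding instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0..T=3, N=255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif under rotation and reverse complement.

    Tandem repeat consensus motifs are defined only up to cyclic rotation, and
    a probe hybridizes to either strand, so two motifs are considered the same
    repeat family when one is a rotation of the other or of its reverse
    complement. The canonical form is the lexicographically smallest rotation
    over both strands.
    """
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)
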