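"""Thermodynamic and physical QC for probe oligos.

Melting temperatures come from unified nearest-neighbor thermodynamics
(Allawi & SantaLucia 1997 dinucleotide ΔH/ΔS with terminal initiation
terms):

    Tm(K) = 1000·ΔH / (ΔS + ΔS_salt + R·ln C_eff)

with ΔH in kcal/mol, ΔS in cal/(mol·K), R = 1.987 cal/(mol·K),
ΔS_salt = 0.368·(N−1)·ln[Na+] (monovalent salt entropy correction) and
C_eff the effective duplex-formation concentration: c1 − c2/2 for a
non-self-complementary oligo, c1 for a self-complementary one (which also
gains the ΔS symmetry term). Formamide depresses Tm linearly
(−0.65 °C per volume %), which models hybridization stringency in
formamide-containing FISH buffers. Defaults reflect standard worm FISH
hybridization: 585 mM Na+, 48% formamide, 25 nM per strand.

Dimer screening slides two oligos against each other in every antiparallel
register and reports registers whose longest contiguous Watson-Crick run
reaches the sensitivity threshold; dimers are warnings, not filters.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._utils import revcomp, round_half_up

R_GAS = 1.987  # cal/(mol*K)

# Unified DNA nearest-neighbor parameters (ΔH kcal/mol, ΔS cal/mol/K),
# keyed by the 5'->3' top-strand dinucleotide; complementary stacks share
# one entry.
NN_TABLE: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)
SYMMETRY = (0.0, -1.4)


@dataclass(frozen=True)
class ThermoParams:
    """Hybridization conditions for Tm prediction."""

    monovalent_cation_mM: float = 585.0
    formamide_pct: float = 48.0
    strand_conc_nM: float = 25.0
    formamide_slope_c_per_pct: float = 0.65

    def __post_init__(self) -> None:
        if self.monovalent_cation_mM <= 0 or self.strand_conc_nM <= 0:
            raise ValueError("concentrations must be positive")
        if not (0 <= self.formamide_pct <= 100):
            raise ValueError("formamide_pct must be in [0, 100]")


@dataclass(frozen=True)
class DimerParams:
    sensitivity: int = 3  # minimum reportable complementary run

    def __post_init__(self) -> None:
        if self.sensitivity < 1:
            raise ValueError("sensitivity must be >= 1")


@dataclass(frozen=True)
class DimerReport:
    pair: tuple[str, str]
    offset: int
    max_complementary_run: int
    is_3prime_anchored: bool
    alignment_diagram: str


def melting_temperature(sequence: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex Tm under the given hybridization conditions (°C).

    Reported to 1 decimal, half-up. Sequences must be unambiguous A/C/G/T of
    length >= 2.
    """
    if params is None:
        params = ThermoParams()
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bases")
    if not set(seq) <= set("ACGT"):
        raise ValueError("sequence must be unambiguous A/C/G/T")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_AT if terminal in "AT" else INIT_GC
        dh += h
        ds += s
    selfcomp = seq == revcomp(seq)
    if selfcomp:
        dh += SYMMETRY[0]
        ds += SYMMETRY[1]
        c_eff = params.strand_conc_nM * 1e-9
    else:
        c_eff = (params.strand_conc_nM - params.strand_conc_nM / 2.0) * 1e-9
    import math

    ds_salt = 0.368 * (len(seq) - 1) * math.log(params.monovalent_cation_mM / 1000.0)
    tm = 1000.0 * dh / (ds + ds_salt + R_GAS * math.log(c_eff)) - 273.15
    tm -= params.formamide_slope_c_per_pct * params.formamide_pct
    return round_half_up(tm, 1)


def dimer_scan(
    oligo_a: str, oligo_b: str | None = None, params: DimerParams | None = None
) -> list[DimerReport]:
    """Report homo-/heterodimer registers between two oligos (or one with itself).

    ``oligo_a`` is slid against the reverse complement of ``oligo_b`` (self
    mode when ``oligo_b`` is None): a run of equal characters in that frame
    is a contiguous antiparallel Watson-Crick duplex. Registers whose
    longest run reaches the sensitivity are reported, flagged when the run
    reaches the 3' end of either oligo.
    """
    if params is None:
        params = DimerParams()
    a = oligo_a.upper()
    b = a if oligo_b is None else oligo_b.upper()
    for seq in (a, b):
        if not set(seq) <= set("ACGT"):
            raise ValueError("oligos must be unambiguous A/C/G/T")
    c = revcomp(b)  # c[j] pairs with b[len(b)-1-j]
    reports: list[DimerReport] = []
    for off in range(-(len(b) - 1), len(a)):
        best = 0
        run = 0
        best_end = -1
        for i in range(max(0, off), min(len(a), off + len(c))):
            if a[i] == c[i - off]:
                run += 1
                if run > best:
                    best = run
                    best_end = i
            else:
                run = 0
        if best < params.sensitivity:
            continue
        best_start = best_end - best + 1
        # a's 3' end is its last base; b's 3' end maps to c's first base
        anchored = best_end == len(a) - 1 or best_start - off == 0
        pad = max(0, -off)
        diagram = (
            " " * pad + "5'-" + a + "-3'\n"
            + " " * (3 + max(0, off)) + "".join(
                "|" if max(0, off) <= i < min(len(a), off + len(c))
                and a[i] == c[i - off] else " "
                for i in range(max(0, off), min(len(a), off + len(c)))
            ).rjust(min(len(a), off + len(c)) - max(0, off))
            + "\n" + " " * max(0, off) + "3'-" + b[::-1] + "-5'"
        )
        reports.append(
            DimerReport(
                pair=(a, b),
                offset=off,
                max_complementary_run=best,
                is_3prime_anchored=anchored,
                alignment_diagram=diagram,
            )
        )
    reports.sort(key=lambda r: (-r.max_complementary_run, r.offset))
    return reports


def max_dimer_run(oligo_a: str, oligo_b: str | None = None) -> int:
    """Longest contiguous complementary run over all registers (0 if none)."""
    reports = dimer_scan(oligo_a, oligo_b, DimerParams(sensitivity=1))
    return reports[0].max_complementary_run if reports else 0


def mass_to_molarity(conc_ng_per_ul: float, molecular_weight_g_per_mol: float) -> float:
    """Convert ng/µl to nM for a given molecular weight (1 decimal, half-up)."""
    if conc_ng_per_ul <= 0 or molecular_weight_g_per_mol <= 0:
        raise ValueError("concentration and molecular weight must be positive")
    return round_half_up(1e6 * conc_ng_per_ul / molecular_weight_g_per_mol, 1)
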