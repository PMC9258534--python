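"""Published reference probe panels for *C. elegans* and *P. pacificus*.

These are the validated chromosome-specific tandem-repeat FISH panels for
the *C. elegans* VC2010 and *P. pacificus* El Paco assemblies: per probe,
the repeat locus coordinates (1-based inclusive; multi-interval loci are
"/"-separated), the published span statistic, and the oligo sequence(s)
with their published GC% and Tm (predicted at 585 mM Na+, 48% formamide,
25 nM per strand). They serve as a reference surface for the QC functions
and as ready-to-order probe sets.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PanelEntry:
    chrom: str
    probe_name: str
    intervals: tuple[tuple[int, int], ...]
    span_kb: float  # published value
    oligos: tuple[str, ...]
    gc_pct: tuple[float, ...]  # published values
    tm_c: tuple[float, ...]  # published values
    motif: str


C_ELEGANS_PANEL: tuple[PanelEntry, ...] = (
    PanelEntry("I", "I-1", ((10374806, 10387363),), 12.58,
               ("TCTTTCTGAAATTCTAAGAA",), (25.0,), (22.2,),
               "TTTTGGTAAAAGAAAACCATTGTCAACTGAATAGGTTGATTTGTGTTTTCTTTCTGAAATTCTAAGAA"),
    PanelEntry("I", "I-2", ((14697045, 14704558),), 7.51,
               ("AATTTTCACTTTCGGTAAAT",), (25.0,), (24.2,),
               "TGCCGATTTGCCGGAAATTTTCACTTTCGGTAAAT"),
    PanelEntry("II", "II-1", ((6603736, 6620597),), 16.86,
               ("CGAGATGATCGGTCCAGAATACAGC",), (52.0,), (38.4,),
               "CAGTATTTTGGGGTCTCTCCCTAGTTGTTAGGTAACTTTATACTTTTCTTCTTCTATTTCTT"
               "CGAGATGATCGGTCCAGAATACAGC"),
    PanelEntry("III", "III-1", ((9125488, 9139755),), 14.27,
               ("CAGTTGAGACTACACCATATACCGG",), (48.0,), (35.9,),
               "AGGATCAACAGCTTCTCCACCAACTGGAACCACCGATGAGCCTGGATCTT"
               "CAGTTGAGACTACACCATATACCGGTGAGACTCCATCAGTACCTAC"),
    PanelEntry("IV", "IV-1", ((1966969, 1972014),), 5.05,
               ("CCGTAAATCTACAGTAATACC",), (38.1,), (26.1,),
               "CCGTAAATCTACAGTAATACC"),
    PanelEntry("IV", "IV-2", ((3243704, 3271880),), 28.18,
               ("TCACTCAAAATCCTGAGCC",), (47.4,), (30.0,),
               "TCACTCAAAATCCTGAGCC"),
    PanelEntry("IV", "IV-3", ((12787278, 12803238),), 15.96,
               ("CTTCTGGTAATGTTCCCATAATTGG", "CTCATAAGTAACTAGTATGGGAC"),
               (40.0, 39.1), (33.4, 28.5),
               "CTTCTGGTAATGTTCCCATAATTGGGTTAAATACCACTCATAAGTAACTAGTATGGGAC"
               "TGAAAAGATACTAAATGAGCTTATTCTAAGGGTGAAG"),
    PanelEntry("IV", "IV-4", ((14987799, 15001823),), 14.02,
               ("CAGTTCATAAGGGGGACCTT",), (50.0,), (31.9,),
               "ATCCTTTGGAGCTGAAGATTCAGTTCATAAGGGGGACCTTGTG"),
    PanelEntry("V", "V-1", ((6165504, 6179481),), 13.98,
               ("CCTCCTGTTTCAGTTTATCATCCT", "TCTCCTTTTTCAGTTTAGCATCAG"),
               (41.7, 37.5), (33.7, 32.6),
               "CCTCCTGTTTCAGTTTATCATCCTTCTCCTTTTTCAGTTTAGCATCAG"),
    PanelEntry("V", "V-2", ((8761483, 8777144),), 15.66,
               ("CTCGTTATGTCGGTTGAAGACACAATTGGA",), (43.3,), (40.9,),
               "GTGGTGCTTGAGGAGCTGGATTCAGTTGAGCTCGTTATGTCGGTTGAAGACACAATTGGA"),
    PanelEntry("V", "V-3", ((14861885, 14869289),), 7.40,
               ("GATATCGTAGCGTTTTTTGGTG",), (40.9,), (31.2,),
               "GATATCGTAGCGTTTTTTGGTGGAATATGGAAAAATAAAAAAGTGCTAC"),
    PanelEntry("X", "X-1", ((7586210, 7592860),), 6.65,
               ("CGCCGGTTTCGCTTTGAGCG",), (65.0,), (40.4,),
               "CGCCGGTTTCGCTTTGAGCGATTCCTTACCCTTAAATGGG"),
    PanelEntry("X", "X-2", ((17825386, 17836686),), 11.30,
               ("CACTTCGACTCCATCCACCAGC",), (59.9,), (38.5,),
               "CACTTCGACTCCATCCACCAGCACTGCTTCGAGTACGACAGAAAG"),
)

P_PACIFICUS_PANEL: tuple[PanelEntry, ...] = (
    PanelEntry("I", "I-1", ((8491799, 8511776), (8551777, 8558864)), 27.06,
               ("GCCTTGAGCTTCGCCTGTTCTTCGG",), (60.0,), (43.5,),
               "GGCCTTCTTCTCTTCTTCAGCCTTGAGCTTCGCCTGTTCTTCGGCGGTCTTCTTGGCATCCTT"),
    PanelEntry("I", "I-2",
               ((15772551, 15784070), (15789511, 15807243), (15847728, 15890937)),
               72.46,
               ("ACCTCGTGGAGTCCATT",), (52.9,), (29.6,),
               "ACCTCGTGGAGTCCATTCGATCATTGCTCTGCTCCACTTCAAGTCATAATCATTG"),
    PanelEntry("II", "II-1", ((5022684, 5059631),), 36.95,
               ("GGGAGGGTAGACAGTTTACCCACACCAGAA",), (53.3,), (44.4,),
               "GGGGAGGGAGGGTAGACAGTTTACCCACACCAGAAACCTCAAGATCTTCGACGAATGGG"
               "TTTCCTGGAAAGTTGGCTACATTGAG"),
    PanelEntry("III", "III-1", ((5716734, 5757229), (5760170, 5762654)), 43.32,
               ("CGTTGACATTGCACGATCGAATTCC",), (48.0,), (38.6,),
               "TTCGTTGACATTGCACGATCGAATTCCGCAAGGAGAGAC"),
    PanelEntry("IV", "IV-1", ((11295637, 11335802),), 40.17,
               ("TCATTGAAATGATCACAATCATTGA",), (28.0,), (31.3,),
               "ATGATCATTGAAATGATCACAATCATTGAG"),
    PanelEntry("IV", "IV-2", ((30637612, 30681023),), 43.41,
               ("CTGATGCGTTCTCTACATTTTCGCC",), (48.0,), (37.9,),
               "ACTCAAAATGTCAATGAAATTGGCTAAAAAAATGAAAAGTTGAACTTAGATTTCTCACG"
               "CAAAGGACATTGCTTTTCATTATTAAATTAATGATTACTGATGCGTTCTCTACATTTTCGCC"
               "TAGCCTATGGTTGTGCAAGTGCACTCGTTCACAGAGGAC"),
    PanelEntry("V", "V-1", ((18957565, 18980331),), 22.77,
               ("GACACTGGCGGTGTTCATTGAGAAC",), (52.0,), (39.8,),
               "TTTTTGATTGATTGTTAGATTGAGAATGTGAGGCCCATGCAGATAACTATAGATCCATGC"
               "ATGCAGGATCTTACGATGAGACACTGGCGGTGTTCATTGAGAAC"),
    PanelEntry("X", "X-1", ((1, 29285), (69286, 80443)), 40.44,
               ("GGTGGTCGACGGCTGCGTCG",), (75.0,), (43.4,),
               "GGTGGTCGACGGCTGCGTCGACTGAAGAGT"),
    PanelEntry("X", "X-2", ((9167758, 9180432), (9222015, 9236383)), 27.04,
               ("TCCGGGGCTTTAGATGAGTTAGA", "GGAGAAACGATCGAGTTGTATATC"),
               (47.8, 41.7), (36.2, 32.3),
               "AAAGAGATACTGAAATAATCATTCCGGGGCTTTAGATGAGTTAGAGGGGGGGGG"
               "GGAGAAACGATCGAGTTGTATATCTTT"),
    PanelEntry("X", "X-3", ((15501721, 15528787),), 27.07,
               ("TCCCTTTGTTCCGCAGTCCG",), (60.0,), (38.0,),
               "TCATCATGAATGGGATTACGGTATCCCTTTGTTCCGCAGTCCG"),
)


def all_oligos(panel) -> list[tuple[str, str, float, float]]:
    """Flatten a panel to (probe_name, oligo, published GC%, published Tm)."""
    out = []
    for entry in panel:
        for seq, gc, tm in zip(entry.oligos, entry.gc_pct, entry.tm_c):
            out.append((entry.probe_name, seq, gc, tm))
    return out
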