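# Methods

## Problem and scope

`repeatfish` selects tandem-repeat FISH targets from a chromosome-level
assembly and designs short labeled oligos against them. The guiding
criteria are the ones that have proven reliable for worm satellite
panels: a repeat locus must span more than 5 kb in total, its motif must
hybridize to exactly one major genomic locus, and the probes themselves
must be ≤ 30 b oligos that re-pass the same genome-wide specificity
check. Everything downstream of the assembly — detection, mapping,
trimming, splitting, thermodynamic annotation — is computed by this
package; wet-lab protocol steps are out of scope.

## Coordinate conventions

Internal coordinates are 1-based inclusive, matching the way probe
tables print repeat positions. BED export converts to 0-based half-open;
GFF3 and TSV stay 1-based. Multi-interval loci are serialized as
`start-end/start-end/...`. The span statistic of a locus is
Σ(end − start) over its intervals divided by 1000, rounded half-up to
2 decimals — the difference of the genomic indices, without the +1 of an
inclusive length, which is the convention that reproduces published span
columns. Soft-masked (lower-case) input is folded to upper and treated
as ordinary sequence. N is legal in input, is a universal mismatch in
every comparison, and can never fall inside a reported repeat interval
or probe.

## Tandem repeat detection

Candidate periods come from a k-mer recurrence scan (k = 5): two
occurrences of one 5-mer at distance d ≤ 200 vote for period d at that
position. A genuine array votes at nearly every position
(density ≈ (1−q)^2k at per-base divergence q), so votes are chained into
runs with a constant 50 b gap and a run must hold ≥ 4 votes at ≥ 1/4
density to become a candidate. Each candidate region is verified against
a majority-vote consensus of its period, phase-locked to the region
start (base-code ties resolve to the alphabetically first base, for
determinism). Verification scores +2 per match and −7 per substitution
and takes the best contiguous run (the ungapped restriction of
wraparound alignment — exact for substitution-only divergence, which is
the regime these parameters target); the consensus is then re-anchored
at the refined start and re-scored. The consensus is derived only from
the vote-supported core of the region, not the refinement margins, so
minimal two-copy arrays near the score-50 threshold are not diluted by
background bases.

An array is reported when its score reaches 50 **and** it contains at
least two full motif copies. The two-copy requirement matters: without
it, a brute-force reading of "any offset/period/extent scoring ≥ 50"
admits chance arrays at periods near 20 in random sequence, because the
first motif copy matches itself for free.

Arrays interrupted by indels shift phase; the flanks of an accepted run
are re-examined recursively with a freshly derived consensus, so each
phase-coherent sub-run becomes its own array, and the locus merger
(below) reunites them. If a phase mixture washes out the consensus
entirely, the region is bisected and retried. The full wraparound
dynamic program (with indel moves at −7, local score floor 0, X-drop 50
termination, within-row wrap resolved by a doubled-array running-max
scan) is exposed as `score_wraparound` and is the scoring kernel
verified against a plain Smith–Waterman oracle in the tests.

Overlapping candidates with different periods resolve to the higher
score, ties to the smaller period (so a perfect period-p array is
reported at p, not 2p), then to the leftmost start. Detection already
verified at a smaller period suppresses redundant re-readings of the
same bases at larger periods.

## Locus assembly and the span filter

Arrays whose consensus motifs are identical up to rotation, or up to
reverse complement of a rotation, are the same repeat family; same-
chromosome arrays of one family within 50 kb chain into a single locus
(sorted, overlap-unioned intervals). The 50 kb merge gap is a package
choice: published multi-interval loci join sub-arrays up to ~40 kb
apart. The selection filter keeps loci with span strictly greater than
5 kb.

## Genome-wide mapping and the two-condition rule

Queries are mapped on both strands by exact-seed lookup (default word
size 11, the classic nucleotide-BLAST default) followed by ungapped
local extension along each seed diagonal with reward +1 / penalty −3;
the best-scoring run per diagonal is a hit if its Karlin–Altschul
E-value (λ = 1.374, K = 0.711, the published ungapped constants for
+1/−3; E = K·m·n·e^(−λS)) is at most 10. Gap penalties (open 5,
extend 2) are carried in the configuration for interface parity with
the conventional scoring system, but extension is ungapped: for the
substitution-level divergence that matters here the hit sets coincide,
and ungapped scoring makes the mapper exactly equivalent to an
exhaustive per-offset scan, which the tests exploit. Hits are reported
in plus-strand coordinates with the aligned query range attached.

Hits are single-linkage clustered per chromosome (gap ≤ `cluster_gap`);
a group of ≥ 3 hits is a cluster, smaller groups are singletons. A
query passes when (1) exactly one cluster holds ≥ 90% of all hits and
(2) no cluster exists on any chromosome other than the major one.
Scattered singletons anywhere are tolerated — dispersed degenerate
copies of a satellite do not produce visible FISH signal. Zero hits is
a failure in its own right (the probe would not hybridize). The
"clustered ≥ 3 within 50 kb" and "major = 90%" operationalizations are
package choices for quantities the selection procedure leaves
qualitative; both are exposed in the configuration.

**Scale correspondence.** The 50 kb cluster gap and the E ≤ 10 cutoff
are calibrated to ~100 Mb genomes. On the tens-of-kb synthetic
chromosomes used for validation, 50 kb is half a chromosome and E ≤ 10
admits ~10 b chance words, so scattered chance hits would chain into
spurious "clusters". Synthetic-scale runs therefore use
`cluster_gap = 5000` — the same locus-scale proximity relative to a
~250× scaled-down chromosome — while the library default remains 50 kb.

## Probe design

A locus whose motif fails the two-condition rule is first trimmed: the
bases of the motif that align into off-target clusters are marked
conflicted, and the longest contiguous sub-motif is kept whose every
20 b window passes the rule on its own and which contains no conflicted
base. Motifs longer than 30 b are split into non-overlapping pieces of
near-equal length targeting 20 b (minimum 17 b, the shortest validated
panel oligo). Homopolymer runs ≥ 6 b are skipped entirely and pieces
re-anchor on the segments between them — such runs are poor probe
sequence, and validated panels route oligos around them. Every candidate
oligo is re-mapped and re-classified genome-wide; at most two passing
oligos are emitted per locus, preferring more hits at the target locus,
then length closest to 20 b, with remaining ties broken by motif offset.
Trimming precedes splitting. Probes are reported in the motif's as-found
plus-strand orientation (FISH targets dsDNA, so either strand is valid).
A single oligo per locus is experimentally sufficient; when both pieces
of a two-oligo design pass, both are emitted and the choice is left to
the user.

Predicted Tm is annotated but never used to select probes: repetitive
targets hybridize robustly at a standard annealing temperature even when
predicted Tm deviates widely in both directions.

## Thermodynamics

Tm uses unified nearest-neighbor thermodynamics — the Allawi–SantaLucia
1997 dinucleotide ΔH/ΔS set with terminal A·T (+2.3 kcal/mol, +4.1 cal/mol·K)
and G·C (+0.1, −2.8) initiation terms:

Tm(K) = 1000·ΔH / (ΔS + 0.368·(N−1)·ln[Na⁺] + R·ln C_eff),

then −0.65 °C per % formamide. C_eff is 25 − 25/2 = 12.5 nM for a
non-self-complementary oligo at 25 nM per strand; self-complementary
oligos use 25 nM plus the −1.4 cal/mol·K symmetry entropy. Defaults are
the standard worm-FISH hybridization buffer: 585 mM Na⁺, 48% formamide.
This parameter set reproduces the published panel Tm columns to the
printed decimal, which pins the edition of the table; the implementation
is additionally cross-checked against Biopython's independent NN code in
the tests. No Mg²⁺/dNTP correction and no secondary-structure folding
energies are computed.

Dimer screening slides one oligo against the reverse complement of the
other (or itself) through every antiparallel register and reports
registers whose longest contiguous Watson–Crick run reaches the
sensitivity threshold (default 3), flagging runs that reach either 3′
end. This mirrors the "sensitivity" knob of common primer-analysis
tools, whose exact algorithm is unpublished; a contiguous-run minimum is
the standard reading. Dimer reports are warnings only — panel probes
with predicted dimers perform fine in practice.

`mass_to_molarity` converts ng/µl to nM as 10⁶·c/MW; probe-panel
conversions agree with published figures within 0.5% (the published
values themselves carry a small internal rounding inconsistency).

## Synthetic genomes

The generator plants tandem arrays (motif given or drawn at the
requested length) on i.i.d. uniform A/C/G/T backgrounds, with a per-base
substitution rate (default 2%, a realistic satellite divergence;
allowed range 0–20%) and an optional indel mode (≤ 1%) that exists to
exercise the indel scoring path — substitution-only is the default so
truth intervals stay exact. Arrays can be split into sub-arrays with
background gaps (modeling interrupted loci), dispersed decoys copy
motif fragments elsewhere, a per-array copy-number multiplier models
strain copy-number variation (multiplier 0 reproduces the probe-dropout
phenotype in a variant strain), and `make_conflict_genome` tandem-
amplifies the 5′ fraction of a designated motif on another chromosome to
exercise the trimming rule. Everything is deterministic per seed.

The standard validation scenario (`nematode_like_spec`) is a
six-chromosome karyotype (I–V, X) of 50 kb chromosomes, one planted
array per chromosome with motif lengths 25–120 b, copy numbers giving
~6.8–7.7 kb spans, at 2% divergence. These sizes keep a full pipeline
run in the low seconds; they exercise every decision rule (span filter,
specificity, splitting, QC) but deliberately omit the GC skew,
repeat-background structure, and sequence families of real genomes —
passing on them demonstrates the selection logic, not detector
performance on genuine heterochromatin.

## Numerical choices and degenerate inputs

- Report rounding is half-up (spans 2 dp, GC/Tm/identity 1 dp); Python's
  default banker's rounding would disagree with printed tables on exact
  halves.
- All tie-breaks are deterministic (consensus base ties → alphabetical;
  overlapping arrays → score, then smaller period, then leftmost; probe
  ranking → target-hit count, length distance to 20, offset), and
  reports carry no timestamps, so identical inputs give byte-identical
  outputs.
- Chromosomes shorter than 2 bases are skipped with a log notice;
  queries containing N are rejected (probes must be unambiguous); a
  motif shorter than the minimum oligo length is a design error for
  that locus, reported in the rejects file.
- Pipeline exit status: 0 when at least one probe is emitted, 2 when no
  locus passes the span filter, 1 when loci exist but no oligo passes.

## Known limitations

- Detector verification is substitution-oriented; heavily indel-mutated
  arrays are reported as several phase-coherent sub-arrays (merged at
  the locus level) and their scores can under-report relative to a full
  gapped alignment.
- The mapper's word-size-11 seeding can miss alignments whose best run
  is shorter than the seed; at real genome scales such alignments fail
  the E-value cutoff anyway, and the test suite uses word size 5 where
  exhaustive sensitivity is asserted.
- Hit extension is ungapped; a probe whose only off-target similarity
  requires gapped alignment would be scored optimistically.
- The period ceiling (200 bp) and the 5 kb span threshold are selection
  criteria, not detector limits; both are configurable, and more relaxed
  criteria are expected to yield additional usable probes.
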