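# repeatfish

Design locus-specific oligonucleotide DNA FISH probes against tandem
repeats, starting from nothing but a chromosome-level genome assembly.

Satellite DNA and other tandem repeats are ideal FISH targets: a single
short labeled oligo hybridizes to hundreds of clustered copies, giving
bright, robust signals at a tiny fraction of the cost of single-copy
probe libraries. The catch is target selection — the repeat must be large
enough to light up (total span > 5 kb) and confined to one genomic locus,
or the probe paints more than the locus you meant to mark. `repeatfish`
automates that selection and the probe design that follows:

1. **scan** — detect tandem repeat arrays (period ≤ 200 bp) with a k-mer
   periodicity scan verified by wraparound alignment against a
   majority-vote consensus (match +2, mismatch −7, indel −7, report score
   ≥ 50); merge nearby arrays of one motif into loci and keep loci
   spanning **> 5 kb**.
2. **map** — find all genome-wide approximate matches of each candidate
   motif on both strands (exact-word seeding, +1/−3 ungapped extension,
   Karlin–Altschul E ≤ 10) and apply the two-condition specificity rule:
   *(1)* hits cluster at exactly one major locus and *(2)* no hit cluster
   exists on any other chromosome (scattered singletons are tolerated).
3. **design** — trim away cross-hybridizing portions of the motif, split
   motifs longer than 30 b into non-overlapping ~20 b oligos (skipping
   homopolymer runs), and re-validate every oligo genome-wide; emit 1–2
   passing oligos per locus.
4. **qc** — annotate GC%, nearest-neighbor Tm under FISH hybridization
   conditions (585 mM Na⁺, 48% formamide, 25 nM per strand;
   Tm = 1000·ΔH / (ΔS + 0.368·(N−1)·ln[Na⁺] + R·ln C_eff) − 273.15 −
   0.65·F), and homo-/heterodimer warnings (complementary-run
   sensitivity 3). Tm is reported but never used as a filter — repetitive
   probes hybridize robustly at a standard annealing temperature across a
   wide predicted-Tm range.

A seeded synthetic-genome module plants tandem arrays, dispersed decoys,
cross-hybridization conflicts, and strain copy-number variants with exact
truth records, so the whole pipeline is testable without downloading any
assembly. The validated *C. elegans* (VC2010) and *P. pacificus* (El Paco)
probe panels ship in `repeatfish.panels` as a reference surface.

## Worked example

Simulate a six-chromosome genome (50 kb per chromosome, one planted
locus-specific array each) and run the full pipeline:

```python
from repeatfish import PipelineConfig, MappingParams, run_pipeline
from repeatfish.synthetic_genome import generate, nematode_like_spec

genome, truth = generate(nematode_like_spec(seed=11))
# clustering gap scaled to the 50 kb synthetic chromosomes
config = PipelineConfig(mapping=MappingParams(cluster_gap=5000))
result = run_pipeline(genome, config, "out")
print(len(result.kept_loci), "loci kept,", len(result.probes), "oligos")
for d in result.designs:
    p = d.probes[0]
    print(d.locus.chrom, d.locus.span_kb, p.sequence, p.gc_pct, p.tm_c)
```

prints

```
6 loci kept, 11 oligos
I 6.8 GCGGGAGCCATTGAACCAGGGTC 65.2 43.3
II 7.2 ACTCATGCGAAGCCCTTAACGCCA 54.2 42.5
III 7.68 TCGCTGCTGCCCGAGCGAAC 70.0 43.3
IV 7.5 CTGAGAACAAATGACGTGCGGGTCG 56.0 41.6
V 7.2 TGGGCCGGGCCTAAACTGTT 60.0 39.8
X 7.48 TAGGCAATCCCCACTCCTAATTC 47.8 35.1
```

— one probe set per chromosome; each row is a detected locus (span in
kb), its first designed oligo, and the oligo's GC% and predicted Tm (°C)
under the hybridization conditions above. `out/probes.tsv` mirrors the
layout of published probe-panel tables; `out/rejects.tsv` explains every
locus that was dropped (sub-span or no specific oligo).

The same flow is available from the shell:

```sh
repeatfish simulate --spec sim.toml --out genome.fa --truth truth.bed
repeatfish run --genome genome.fa --config cfg.toml --outdir out
repeatfish scan --genome genome.fa --out loci.tsv --bed loci.bed
repeatfish qc --probes out/probes.fa --out qc.tsv
```

Quick single-oligo QC:

```python
>>> from repeatfish import gc_content, melting_temperature
>>> gc_content("TCTTTCTGAAATTCTAAGAA")
25.0
>>> melting_temperature("TCTTTCTGAAATTCTAAGAA")   # 585 mM Na+, 48% formamide
22.2
```

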