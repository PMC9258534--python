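"""End-to-end orchestration: scan -> map -> design -> qc with one config.

Every tunable of every stage lives in :class:`PipelineConfig`, whose
defaults are the published repeat-FISH selection parameters (period <= 200,
match/mismatch/indel = 2/7/7, report score 50, span > 5 kb, +1/-3 mapping
with E <= 10, oligos <= 30 b targeting ~20 b, 585 mM Na+ / 48% formamide,
dimer sensitivity 3). Outputs are plain TSV/FASTA, written in a fixed order
with no timestamps, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .locus_mapper import MappingParams, check_specificity
from .oligo_thermo import DimerParams, ThermoParams, max_dimer_run
from .probe_designer import DesignParams, DesignResult, design_probes
from .repeat_finder import (
    DetectorParams,
    RepeatLocus,
    filter_by_span,
    find_tandem_repeats,
    merge_arrays_to_loci,
)
from .sequence_io import GenomeAssembly, read_fasta

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_NO_PROBES = 1
EXIT_NO_LOCI = 2


@dataclass
class PipelineConfig:
    detector: DetectorParams = field(default_factory=DetectorParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    design: DesignParams = field(default_factory=DesignParams)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    dimer: DimerParams = field(default_factory=DimerParams)
    min_span_kb: float = 5.0
    locus_merge_gap: int = 50_000
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from a nested mapping (e.g. parsed TOML)."""
        kwargs = {}
        for name, params_cls in [
            ("detector", DetectorParams), ("mapping", MappingParams),
            ("design", DesignParams), ("thermo", ThermoParams),
            ("dimer", DimerParams),
        ]:
            if name in data:
                kwargs[name] = params_cls(**data[name])
        for scalar in ("min_span_kb", "locus_merge_gap", "seed"):
            if scalar in data:
                kwargs[scalar] = data[scalar]
        return cls(**kwargs)

    def echo(self) -> str:
        """Full parameter dump; enough to reproduce a run exactly."""
        lines = []
        for name in ("detector", "mapping", "design", "thermo", "dimer"):
            obj = getattr(self, name)
            for f in dataclasses.fields(obj):
                lines.append(f"{name}.{f.name} = {getattr(obj, f.name)!r}")
        for scalar in ("min_span_kb", "locus_merge_gap", "seed"):
            lines.append(f"{scalar} = {getattr(self, scalar)!r}")
        return "\n".join(lines)


@dataclass
class PipelineResult:
    loci: list[RepeatLocus]
    kept_loci: list[RepeatLocus]
    designs: list[DesignResult]
    exit_code: int

    @property
    def probes(self):
        return [p for d in self.designs for p in d.probes]


def _chrom_tag(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") and len(chrom) > 3 else chrom


def _fmt_interval_list(locus: RepeatLocus) -> str:
    return "/".join(f"{iv.start}-{iv.end}" for iv in locus.intervals)


def write_loci_tsv(loci, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tintervals\tspan_kb\tperiod\tcopy_number\tconsensus_motif\tscore\n")
        for l in loci:
            fh.write(
                f"{l.chrom}\t{_fmt_interval_list(l)}\t{l.span_kb:.2f}\t{l.period}"
                f"\t{l.copy_number}\t{l.motif}\t{l.score}\n"
            )


def read_loci_tsv(path) -> list[RepeatLocus]:
    from .repeat_finder import compute_locus_span
    from .sequence_io import GenomicInterval

    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("chrom\t"), "not a loci TSV"
        for ln in fh:
            chrom, ivs, _span, period, copies, motif, score = ln.rstrip("\n").split("\t")
            intervals = tuple(
                GenomicInterval(chrom, int(b.split("-")[0]), int(b.split("-")[1]))
                for b in ivs.split("/")
            )
            out.append(
                RepeatLocus(
                    motif=motif, intervals=intervals,
                    span_kb=compute_locus_span(intervals),
                    period=int(period), copy_number=float(copies), score=int(score),
                )
            )
    return out


def run_pipeline(
    genome: GenomeAssembly | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path = "repeatfish_out",
) -> PipelineResult:
    """Run the whole probe-design pipeline and write the report files.

    Writes loci.tsv, hits.tsv, probes.tsv, rejects.tsv, qc.tsv, probes.fa
    and run.log under ``outdir``. Exit code 0 means at least one probe was
    emitted; 2 means no locus passed the span filter.
    """
    if config is None:
        config = PipelineConfig()
    if not isinstance(genome, GenomeAssembly):
        genome = read_fasta(genome)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    arrays = find_tandem_repeats(genome, config.detector)
    loci = merge_arrays_to_loci(arrays, config.locus_merge_gap)
    chrom_order = {c: i for i, c in enumerate(genome.records)}
    loci.sort(key=lambda l: (chrom_order[l.chrom], l.intervals[0].start))
    kept = filter_by_span(loci, config.min_span_kb)
    write_loci_tsv(kept, outdir / "loci.tsv")

    rejects_rows: list[tuple[str, str, str]] = []  # (name, positions, reason)
    per_chrom_counter: dict[str, int] = {}
    names: dict[int, str] = {}
    for l in loci:
        per_chrom_counter[l.chrom] = per_chrom_counter.get(l.chrom, 0) + 1
        names[id(l)] = f"{_chrom_tag(l.chrom)}-{per_chrom_counter[l.chrom]}"
    for l in loci:
        if l not in kept:
            rejects_rows.append(
                (names[id(l)], _fmt_interval_list(l),
                 f"span {l.span_kb:.2f} kb <= {config.min_span_kb:g} kb")
            )

    designs: list[DesignResult] = []
    hit_rows: list[str] = []
    for l in kept:
        name = names[id(l)]
        result = design_probes(
            l, genome, config.design, config.mapping, config.thermo,
            config.dimer, probe_id=name,
        )
        designs.append(result)
        if result.reject is not None:
            rejects_rows.append((name, _fmt_interval_list(l), result.reject.reason))
        for k, probe in enumerate(result.probes):
            oligo_id = name if len(result.probes) == 1 else f"{name}{'ab'[k]}"
            _report, hits = check_specificity(genome, probe.sequence, config.mapping)
            for h in hits:
                hit_rows.append(
                    f"{oligo_id}\t{h.interval.chrom}\t{h.interval.start}"
                    f"\t{h.interval.end}\t{h.interval.strand}\t{h.raw_score}"
                    f"\t{h.percent_identity}\t{h.evalue:.3g}\n"
                )

    with open(outdir / "hits.tsv", "w") as fh:
        fh.write("oligo\tchrom\tstart\tend\tstrand\tscore\tpercent_identity\tevalue\n")
        fh.writelines(hit_rows)

    with open(outdir / "probes.tsv", "w") as fh:
        fh.write(
            "Chr\tProbe name\tRepeat position\tSpan (kb)\tOligo sequence(s)"
            "\tLength (b)\tGC%\tTm\tComplete tandem repeat motif\tMotif length (b)\n"
        )
        for d in designs:
            if not d.probes:
                continue
            l = d.locus
            name = d.probes[0].probe_id
            fh.write(
                f"{_chrom_tag(l.chrom)}\t{name}\t{_fmt_interval_list(l)}"
                f"\t{l.span_kb:.2f}"
                f"\t{','.join(p.sequence for p in d.probes)}"
                f"\t{','.join(str(p.length) for p in d.probes)}"
                f"\t{','.join(f'{p.gc_pct:g}' for p in d.probes)}"
                f"\t{','.join(f'{p.tm_c:g}' for p in d.probes)}"
                f"\t{l.motif}\t{len(l.motif)}\n"
            )

    with open(outdir / "probes.fa", "w") as fh:
        for d in designs:
            for k, p in enumerate(d.probes):
                oligo_id = p.probe_id if len(d.probes) == 1 else f"{p.probe_id}{'ab'[k]}"
                fh.write(f">{oligo_id}\n{p.sequence}\n")

    with open(outdir / "rejects.tsv", "w") as fh:
        fh.write("locus\tpositions\treason\n")
        for name, positions, reason in rejects_rows:
            fh.write(f"{name}\t{positions}\t{reason}\n")

    all_probes = [(p, d) for d in designs for p in d.probes]
    with open(outdir / "qc.tsv", "w") as fh:
        fh.write(
            "probe_id\tlength\tgc_pct\ttm_c\tself_dimer_max_run"
            "\tworst_pair_partner\tworst_pair_run\n"
        )
        for p, d in all_probes:
            self_run = max_dimer_run(p.sequence)
            worst_partner, worst_run = "", 0
            for q, _d2 in all_probes:
                if q is p:
                    continue
                r = max_dimer_run(p.sequence, q.sequence)
                if r > worst_run:
                    worst_partner, worst_run = q.probe_id, r
            fh.write(
                f"{p.probe_id}\t{p.length}\t{p.gc_pct:g}\t{p.tm_c:g}"
                f"\t{self_run}\t{worst_partner}\t{worst_run}\n"
            )

    n_probes = len(all_probes)
    if not kept:
        exit_code = EXIT_NO_LOCI
    elif n_probes == 0:
        exit_code = EXIT_NO_PROBES
    else:
        exit_code = EXIT_OK
    with open(outdir / "run.log", "w") as fh:
        fh.write("# repeatfish run configuration\n")
        fh.write(config.echo() + "\n")
        fh.write(f"# chromosomes = {len(genome.records)}\n")
        fh.write(f"# loci_detected = {len(loci)}\n")
        fh.write(f"# loci_kept = {len(kept)}\n")
        fh.write(f"# probes_emitted = {n_probes}\n")
        fh.write(f"# exit_code = {exit_code}\n")
    if not kept:
        logger.warning("no locus passed the %g kb span filter", config.min_span_kb)
    return PipelineResult(loci, kept, designs, exit_code)
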