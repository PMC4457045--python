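"""End-to-end orchestration: preprocess → map → phase → annotate →
triggers → targets → reports, with a machine-readable run manifest.

Every stage persists its outputs as plain text (TSV/FASTA/BED/GFF3) under
the run directory, so any stage can be re-run from the previous stage's
files; all thresholds come from one RunConfig and are logged as applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import io as pio
from .io import RunConfig, SequenceRecord
from .preprocess import (
    Alignment,
    CollapsedRead,
    GenomeIndex,
    assign_rpm,
    filter_rrna,
    map_reads,
)
from .phasing import PhasLocus, call_phas_loci, scan_windows, windows_table
from .annotate import (
    classify_locus,
    differential_table,
    library_profile,
    LibraryStatus,
    merge_by_gene,
    compare_libraries,
    summarize,
)
from .triggers import (
    classify_trigger_model,
    filter_triggers,
    find_triggers,
    phasirna_pool,
    predict_targets,
    tally_degradome,
)

log = logging.getLogger("phasekit")


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    inputs: dict = field(default_factory=dict)
    counters: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = ""
    seed: int = 0
    failed_stage: str | None = None

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# persisted intermediates
# ---------------------------------------------------------------------------

def save_alignments(alignments: list[Alignment], path: str) -> None:
    rows = [
        dict(seq=a.read.seq, count=a.read.count, rpm=a.read.rpm,
             ref_id=a.ref_id, strand=a.strand, start=a.start, hits=a.hits)
        for a in alignments
    ]
    pd.DataFrame(rows, columns=["seq", "count", "rpm", "ref_id", "strand", "start", "hits"]).to_csv(
        path, sep="\t", index=False
    )


def load_alignments(path: str) -> list[Alignment]:
    df = pd.read_csv(path, sep="\t")
    reads: dict[str, CollapsedRead] = {}
    out = []
    for row in df.itertuples(index=False):
        if row.seq not in reads:
            reads[row.seq] = CollapsedRead(seq=row.seq, count=int(row.count), rpm=float(row.rpm))
        out.append(
            Alignment(reads[row.seq], str(row.ref_id), str(row.strand), int(row.start), int(row.hits))
        )
    return out


def save_loci(loci: list[PhasLocus], prefix: str) -> dict[str, str]:
    paths = pio.write_locus_outputs(loci, prefix)
    rows, member_rows = [], []
    for loc in loci:
        rows.append(
            dict(locus_id=loc.locus_id, ref_id=loc.ref_id, start=loc.start, end=loc.end,
                 register_len=loc.register_len, phase_offset=loc.phase_offset,
                 pvalue=loc.best_pvalue, phasing_score=loc.best_phasing_score,
                 windows=loc.window_count, genomic_class=loc.genomic_class or "NA",
                 gene_id=loc.gene_id or "NA", n_member_reads=len(loc.member_reads),
                 total_rpm=loc.total_rpm())
        )
        for a in loc.inphase_alignments:
            member_rows.append(
                dict(locus_id=loc.locus_id, seq=a.read.seq, count=a.read.count,
                     rpm=a.read.rpm, ref_id=a.ref_id, strand=a.strand, start=a.start, hits=a.hits)
            )
    loci_cols = ["locus_id", "ref_id", "start", "end", "register_len", "phase_offset",
                 "pvalue", "phasing_score", "windows", "genomic_class", "gene_id",
                 "n_member_reads", "total_rpm"]
    pd.DataFrame(rows, columns=loci_cols).to_csv(prefix + ".loci.tsv", sep="\t", index=False)
    member_cols = ["locus_id", "seq", "count", "rpm", "ref_id", "strand", "start", "hits"]
    pd.DataFrame(member_rows, columns=member_cols).to_csv(
        prefix + ".members.tsv", sep="\t", index=False
    )
    paths["loci"] = prefix + ".loci.tsv"
    paths["members"] = prefix + ".members.tsv"
    return paths


def load_loci(prefix: str) -> list[PhasLocus]:
    df = pd.read_csv(prefix + ".loci.tsv", sep="\t")
    members = pd.read_csv(prefix + ".members.tsv", sep="\t")
    by_locus: dict[str, list[Alignment]] = {}
    reads: dict[str, CollapsedRead] = {}
    for row in members.itertuples(index=False):
        if row.seq not in reads:
            reads[row.seq] = CollapsedRead(seq=row.seq, count=int(row.count), rpm=float(row.rpm))
        by_locus.setdefault(row.locus_id, []).append(
            Alignment(reads[row.seq], str(row.ref_id), str(row.strand), int(row.start), int(row.hits))
        )
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            PhasLocus(
                ref_id=str(row.ref_id), start=int(row.start), end=int(row.end),
                register_len=int(row.register_len), phase_offset=int(row.phase_offset),
                best_pvalue=float(row.pvalue), best_phasing_score=float(row.phasing_score),
                window_count=int(row.windows),
                inphase_alignments=by_locus.get(row.locus_id, []),
                genomic_class=None if row.genomic_class == "NA" else str(row.genomic_class),
                gene_id=None if row.gene_id == "NA" else str(row.gene_id),
                locus_id=str(row.locus_id),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def derive_transcriptome(
    genome: list[SequenceRecord],
    models,
    loci: list[PhasLocus],
    flank: int = 100,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Unspliced gene-span transcripts plus noncoding precursors for
    intergenic loci; returns the records and a locus_id → record-id map."""
    refs = {r.id: r.seq for r in genome}
    records = [SequenceRecord(m.gene_id, refs[m.chrom][m.start : m.end]) for m in models]
    origins: dict[str, str] = {}
    for loc in loci:
        if loc.gene_id is None:
            rid = loc.locus_id or f"{loc.ref_id}:{loc.start}-{loc.end}"
            seq = refs[loc.ref_id][max(0, loc.start - flank) : loc.end + flank]
            records.append(SequenceRecord(rid, seq))
            origins[loc.locus_id or rid] = rid
    return records, origins


def run_pipeline(
    cfg: RunConfig,
    outdir: str,
    genome_path: str,
    reads_path: str,
    gff_path: str | None = None,
    rrna_path: str | None = None,
    mirna_path: str | None = None,
    degradome_path: str | None = None,
    coverage_path: str | None = None,
    transcriptome_path: str | None = None,
    run_24nt: bool = False,
) -> RunManifest:
    """Run every stage on the given inputs and persist all outputs.

    Raises before any stage runs if a named input is missing; on a stage
    failure, earlier outputs are preserved and the manifest records the
    failure point.
    """
    os.makedirs(outdir, exist_ok=True)
    named = dict(genome=genome_path, reads=reads_path, gff=gff_path, rrna=rrna_path,
                 mirnas=mirna_path, degradome=degradome_path, coverage=coverage_path,
                 transcriptome=transcriptome_path)
    for name, p in named.items():
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(f"input {name!r} not found: {p}")
    from . import __version__

    manifest = RunManifest(
        config=cfg.to_dict(),
        inputs={k: {"path": v, "md5": _md5(v)} for k, v in named.items() if v},
        version=__version__,
        seed=cfg.rng_seed,
    )
    mpath = os.path.join(outdir, "manifest.json")
    stage = "preprocess"
    try:
        t0 = time.time()
        genome = pio.read_fasta(genome_path)
        ref_lengths = {r.id: len(r.seq) for r in genome}
        reads = pio.read_collapsed_reads(reads_path)
        raw_total = sum(r.count for r in reads)
        rrna = pio.read_fasta(rrna_path) if rrna_path else []
        cleaned = filter_rrna(reads, rrna)
        cleaned_total = assign_rpm(cleaned)
        log.info("preprocess: %d raw reads, %d after rRNA filter", raw_total, cleaned_total)
        pio.write_collapsed_reads(cleaned, os.path.join(outdir, "cleaned_reads.fa"))
        manifest.counters["reads_raw"] = raw_total
        manifest.counters["reads_rrna_removed"] = raw_total - cleaned_total
        manifest.counters["reads_cleaned"] = cleaned_total
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "map"
        t0 = time.time()
        index = GenomeIndex(genome)
        alignments = map_reads(cleaned, genome, cfg.max_hits, index=index)
        mapped_seqs = {a.read.seq for a in alignments}
        manifest.counters["unique_reads_mapped"] = len(mapped_seqs)
        manifest.counters["unique_reads_unmapped_or_multihit"] = len(cleaned) - len(mapped_seqs)
        save_alignments(alignments, os.path.join(outdir, "alignments.tsv"))
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "phase"
        t0 = time.time()
        all_loci: list[PhasLocus] = []
        for reg in ([21, 24] if run_24nt else [21]):
            mode_cfg = cfg.replace(register_len=reg, window_step=None)
            log.info(
                "phase %d-nt mode: window %d nt, step %d, p<%g / score>=%g",
                reg, mode_cfg.window_span, mode_cfg.step,
                mode_cfg.pvalue_cutoff, mode_cfg.score_cutoff_24nt,
            )
            windows = scan_windows(alignments, ref_lengths, mode_cfg)
            windows_table(windows, mode_cfg).to_csv(
                os.path.join(outdir, f"windows_{reg}nt.tsv"), sep="\t", index=False
            )
            all_loci += call_phas_loci(windows, mode_cfg)
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "annotate"
        t0 = time.time()
        models = pio.read_gff3(gff_path) if gff_path else []
        for loc in all_loci:
            classify_locus(loc, models)
        loci = merge_by_gene(all_loci)
        paths = save_loci(loci, os.path.join(outdir, "phas"))
        manifest.outputs.update(paths)
        if coverage_path and models:
            from .annotate import intron_retention_support

            coverage = pio.read_bedgraph(coverage_path)
            by_id = {m.gene_id: m for m in models}
            calls = [
                intron_retention_support(
                    loc, by_id[loc.gene_id], coverage, cfg.low_coverage, cfg.high_coverage
                )
                for loc in loci
                if loc.genomic_class == "intron" and loc.gene_id in by_id
            ]
            pd.DataFrame(
                [dict(locus=c.locus_id, intron_start=c.intron[0], intron_end=c.intron[1],
                      mean_coverage=c.rnaseq_mean_coverage, call=c.call) for c in calls],
                columns=["locus", "intron_start", "intron_end", "mean_coverage", "call"],
            ).to_csv(os.path.join(outdir, "intron_calls.tsv"), sep="\t", index=False)
        profile = library_profile(loci)
        pd.DataFrame(
            [dict(key=k, rpm=v.rpm, phas=v.phas) for k, v in sorted(profile.items())],
            columns=["key", "rpm", "phas"],
        ).to_csv(os.path.join(outdir, "locus_profile.tsv"), sep="\t", index=False)
        manifest.counters["phas_loci"] = len(loci)
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "triggers"
        t0 = time.time()
        refs = {r.id: r.seq for r in genome}
        known = pio.read_fasta(mirna_path) if mirna_path else []
        degradome = None
        if degradome_path:
            deg_reads = pio.read_collapsed_reads(degradome_path)
            deg_aln = map_reads(deg_reads, genome, max_hits=20, index=index)
            degradome = tally_degradome(deg_aln)
        pool = [r for r in cleaned if r.seq in mapped_seqs]
        trig_rows = []
        for loc in loci:
            if loc.register_len != 21:
                continue
            cands = find_triggers(loc, pool, refs, cfg, known_mirnas=known, degradome=degradome)
            kept, _ = filter_triggers(cands, degradome_available=degradome is not None)
            model = classify_trigger_model(kept)
            for c in kept:
                trig_rows.append(
                    dict(locus=loc.locus_id, srna=c.alignment.srna, length=c.trigger_len,
                         score=c.alignment.score, end=c.end, site_start=c.genomic_site[0],
                         site_end=c.genomic_site[1], cleavage=c.genomic_cleavage,
                         phase_relation=c.phase_relation, model=model,
                         mirna_status=c.mirna_status, degradome=c.degradome)
                )
        trig_cols = ["locus", "srna", "length", "score", "end", "site_start", "site_end",
                     "cleavage", "phase_relation", "model", "mirna_status", "degradome"]
        pd.DataFrame(trig_rows, columns=trig_cols).to_csv(
            os.path.join(outdir, "triggers.tsv"), sep="\t", index=False
        )
        manifest.counters["trigger_candidates"] = len(trig_rows)
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "targets"
        t0 = time.time()
        if transcriptome_path:
            transcripts = pio.read_fasta(transcriptome_path)
            origins = {}
        else:
            transcripts, origins = derive_transcriptome(genome, models, loci)
        fams = dict(pd.read_csv(gff_path + ".families.tsv", sep="\t").values) \
            if gff_path and os.path.exists(gff_path + ".families.tsv") else None
        pool21 = phasirna_pool(
            [l for l in loci if l.register_len == 21], cfg.min_rpm, origins
        )
        preds = predict_targets(pool21, transcripts, cfg, families=fams)
        pd.DataFrame(
            [dict(phasirna=p.phasirna, origin=p.origin_id or "NA", target=p.target_id,
                  strand=p.target_strand, score=p.score, stringent=p.stringent,
                  relation=p.relation, cleavage=p.cleavage_pos) for p in preds],
            columns=["phasirna", "origin", "target", "strand", "score", "stringent",
                     "relation", "cleavage"],
        ).to_csv(os.path.join(outdir, "targets.tsv"), sep="\t", index=False)
        manifest.counters["target_predictions"] = len(preds)
        manifest.timings[stage] = round(time.time() - t0, 3)

        stage = "report"
        summarize(loci).to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(mpath)
        raise
    manifest.write(mpath)
    return manifest


def compare_runs(dir_a: str, dir_b: str, cfg: RunConfig, out_path: str | None = None):
    """Differential phasiRNA production between two finished runs.

    Refuses to compare runs made against different genomes (manifest input
    checksums must match).
    """
    for d in (dir_a, dir_b):
        if not os.path.exists(os.path.join(d, "manifest.json")):
            raise FileNotFoundError(f"no manifest.json under {d}")
    man_a = json.load(open(os.path.join(dir_a, "manifest.json")))
    man_b = json.load(open(os.path.join(dir_b, "manifest.json")))
    md5_a = man_a["inputs"].get("genome", {}).get("md5")
    md5_b = man_b["inputs"].get("genome", {}).get("md5")
    if md5_a != md5_b:
        raise ValueError("runs used different genomes; comparison refused")

    def load_profile(d):
        df = pd.read_csv(os.path.join(d, "locus_profile.tsv"), sep="\t")
        return {
            str(r.key): LibraryStatus(rpm=float(r.rpm), phas=bool(r.phas))
            for r in df.itertuples(index=False)
        }

    records = compare_libraries(load_profile(dir_a), load_profile(dir_b), cfg)
    table = differential_table(records)
    if out_path:
        table.to_csv(out_path, sep="\t", index=False)
        counts = table["verdict"].value_counts().to_dict()
        with open(os.path.splitext(out_path)[0] + ".summary.txt", "w") as fh:
            for verdict in ("induced", "suppressed", "gained_PHAS", "lost_PHAS", "stable"):
                fh.write(f"{verdict}\t{counts.get(verdict, 0)}\n")
    return records
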