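"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and SAM (1-based POS) are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import pysam
import gffutils
from Bio import SeqIO

log = logging.getLogger("phasekit")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (uppercase, U normalized to T)."""

    id: str
    seq: str


@dataclass
class GeneModel:
    """A gene with its exon structure on the genome.

    ``exons`` holds the primary isoform (the longest one); all isoforms are
    retained in ``isoform_exons`` for junction / intron-retention logic.
    Intervals are 0-based half-open, sorted, non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    isoform_exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive primary-isoform exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the published defaults.

    register_len
        Phase register length in nt: 21 for the canonical phasiRNAs, 24 for
        the reproductive-tissue class.
    cycles_per_window
        Number of register cycles per sliding window (9, i.e. a 189-nt
        window in 21-nt mode).
    window_step
        Sliding-window step; ``None`` derives the three-register break
        (63 nt in 21-nt mode, 72 nt in 24-nt mode).
    min_unique_reads / min_inphase_unique
        Window eligibility: at least 10 unique reads of any length, more
        than half of them register-length, and at least 3 register-length
        reads in the best phase.
    pvalue_cutoff
        Strict upper bound on the hypergeometric phasing P-value for a
        positive 21-nt window (0.001).
    score_cutoff_24nt
        Minimum phasing score for a positive 24-nt window (15).
    max_hits
        Reads with more placements than this are discarded entirely (6).
    trigger_flank / trigger_score_cutoff
        Trigger search: 200 nt on each side of a locus, duplex score <= 4.
    target_score_cutoff / stringent_target_cutoff
        phasiRNA target prediction: report score <= 3, flag <= 1.5.
    min_rpm
        Abundance gate (reads per million cleaned reads) for trigger and
        phasiRNA pools (10).
    fold_change_cutoff
        Differential phasiRNA production calls use a plain 5-fold rule.
    """

    register_len: int = 21
    cycles_per_window: int = 9
    window_step: int | None = None
    min_unique_reads: int = 10
    min_inphase_unique: int = 3
    pvalue_cutoff: float = 0.001
    score_cutoff_24nt: float = 15.0
    max_hits: int = 6
    trigger_flank: int = 200
    trigger_score_cutoff: float = 4.0
    target_score_cutoff: float = 3.0
    stringent_target_cutoff: float = 1.5
    min_rpm: float = 10.0
    fold_change_cutoff: float = 5.0
    trim_min_len: int = 18
    trim_max_len: int = 34
    low_coverage: float = 1.0
    high_coverage: float = 5.0
    min_degradome_reads: int = 2
    rpm_pseudocount: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.register_len not in (21, 24):
            raise ValueError("register_len must be 21 or 24")
        for name in (
            "cycles_per_window",
            "min_unique_reads",
            "min_inphase_unique",
            "max_hits",
            "trigger_flank",
            "min_degradome_reads",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.pvalue_cutoff < 1.0:
            raise ValueError("pvalue_cutoff must lie in (0, 1)")
        if self.window_step is not None and self.window_step < 1:
            raise ValueError("window_step must be >= 1")

    @property
    def step(self) -> int:
        return self.window_step if self.window_step is not None else 3 * self.register_len

    @property
    def window_span(self) -> int:
        return self.register_len * self.cycles_per_window

    def replace(self, **kw) -> "RunConfig":
        d = asdict(self)
        d.update(kw)
        return RunConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# FASTA / collapsed reads
# ---------------------------------------------------------------------------

def _norm(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords (U→T, uppercased).

    Raises FormatError on an empty file or a duplicated header id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = _norm(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id}")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_collapsed_reads(path: str | os.PathLike):
    """Read a collapsed small-RNA library.

    Two dialects are auto-detected: FASTA with headers ending in
    ``_<count>`` and two-column TSV ``sequence<TAB>count``. Duplicate
    sequences have their counts summed (with a warning); counts must be
    positive integers.

    Returns a list of :class:`phasekit.preprocess.CollapsedRead`.
    """
    from .preprocess import CollapsedRead

    with open(path) as fh:
        head = fh.read(1)
    counts: dict[str, int] = {}
    order: list[str] = []

    def add(seq: str, count: int) -> None:
        if seq in counts:
            log.warning("duplicate sequence %s...: counts summed", seq[:12])
        else:
            order.append(seq)
        counts[seq] = counts.get(seq, 0) + count

    if head == ">":  # dialect A: collapsed FASTA
        for rec in SeqIO.parse(str(path), "fasta"):
            tail = rec.id.rsplit("_", 1)
            if len(tail) != 2 or not tail[1].isdigit() or int(tail[1]) < 1:
                raise FormatError(f"header {rec.id!r} does not end in _<count>")
            add(_norm(rec.seq), int(tail[1]))
    else:  # dialect B: seq<TAB>count
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"line {ln}: expected seq<TAB>count")
                seq, cnt = parts
                try:
                    count = int(cnt)
                except ValueError:
                    raise FormatError(f"line {ln}: non-integer count {cnt!r}") from None
                if count < 1:
                    raise FormatError(f"line {ln}: count must be positive")
                add(_norm(seq), count)
    if not counts:
        raise FormatError(f"no reads in {path}")
    return [CollapsedRead(seq=s, count=counts[s]) for s in order]


def write_collapsed_reads(reads, path: str | os.PathLike, prefix: str = "read") -> None:
    """Write collapsed reads in dialect A (``>prefixN_count``)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f">{prefix}{i:06d}_{r.count}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon), 1-based → 0-based half-open.

    The longest isoform becomes the primary exon set; exons with no resolvable
    Parent are skipped with a warning; an exon outside its gene span is a
    FormatError.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    known_parents = {f.id for f in db.all_features() if f.featuretype in ("gene", "mRNA")}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or all(p not in known_parents for p in parents):
            log.warning("exon %s:%d-%d has no known Parent; skipped", exon.seqid, exon.start, exon.end)

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gspan = (gene.start - 1, gene.end)
        isoforms: dict[str, list[tuple[int, int]]] = {}
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            for mrna in mrnas:
                ex = sorted(
                    (e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")
                )
                if ex:
                    isoforms[mrna.id] = ex
        else:
            ex = sorted((e.start - 1, e.end) for e in db.children(gene, featuretype="exon"))
            if ex:
                isoforms[gene.id] = ex
        if not isoforms:
            log.warning("gene %s has no exons; skipped", gene.id)
            continue
        for iso, ex in isoforms.items():
            for s, e in ex:
                if s < gspan[0] or e > gspan[1]:
                    raise FormatError(
                        f"exon [{s},{e}) of isoform {iso} outside gene {gene.id} span {gspan}"
                    )
                if s >= e:
                    raise FormatError(f"empty exon interval in {iso}")
        primary = max(isoforms.values(), key=lambda ex: sum(e - s for s, e in ex))
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=primary,
                isoform_exons=isoforms,
            )
        )
    return models


def write_gff3_genes(models: list[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as gene/mRNA/exon GFF3 (0-based half-open → 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\tphasekit\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for iso, exons in m.isoform_exons.items():
                mid = iso if iso != m.gene_id else f"{m.gene_id}.t1"
                fh.write(
                    f"{m.chrom}\tphasekit\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t{m.strand}\t.\t"
                    f"ID={mid};Parent={m.gene_id}\n"
                )
                for i, (s, e) in enumerate(exons, 1):
                    fh.write(
                        f"{m.chrom}\tphasekit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"ID={mid}.exon{i};Parent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# SAM import
# ---------------------------------------------------------------------------

def import_alignments(path: str | os.PathLike, max_hits: int = 6):
    """Import ungapped, mismatch-free records from a SAM file.

    Hit multiplicity comes from the NH tag when present, otherwise from
    grouping records by read id. Records with more than ``max_hits``
    placements, gapped CIGARs, or mismatches (NM>0) are dropped; drop
    counters are logged.
    """
    from .preprocess import CollapsedRead, Alignment

    dropped = {"gapped": 0, "mismatch": 0, "multihit": 0, "unmapped": 0}
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if not sam.header.get("SQ"):
            raise FormatError("SAM header lists no reference sequences")
        for rec in sam:
            if rec.is_unmapped:
                dropped["unmapped"] += 1
                continue
            cig = rec.cigartuples or []
            if len(cig) != 1 or cig[0][0] != 0:  # anything but a single M run
                dropped["gapped"] += 1
                continue
            if rec.has_tag("NM") and rec.get_tag("NM") != 0:
                dropped["mismatch"] += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            seq = _norm(rec.query_sequence or "")
            if rec.is_reverse:
                seq = revcomp(seq)  # store the read in its own 5'->3' orientation
            rows.append(
                (rec.query_name, seq, rec.reference_name, rec.reference_start,
                 "-" if rec.is_reverse else "+", nh)
            )
    by_name: dict[str, int] = {}
    for name, *_ in rows:
        by_name[name] = by_name.get(name, 0) + 1
    alignments = []
    reads: dict[str, CollapsedRead] = {}
    for name, seq, ref, start, strand, nh in rows:
        hits = nh if nh is not None else by_name[name]
        if hits > max_hits:
            dropped["multihit"] += 1
            continue
        if seq not in reads:
            tail = name.rsplit("_", 1)
            count = int(tail[1]) if len(tail) == 2 and tail[1].isdigit() else 1
            reads[seq] = CollapsedRead(seq=seq, count=count)
        alignments.append(
            Alignment(read=reads[seq], ref_id=ref, strand=strand, start=start, hits=hits)
        )
    if any(dropped.values()):
        log.info("import_alignments dropped: %s", dropped)
    return alignments


# ---------------------------------------------------------------------------
# BedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    """Parse a BedGraph coverage track into (chrom, start, end, value) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, s, e, v = line.split()[:4]
            out.append((chrom, int(s), int(e), float(v)))
    return out


# ---------------------------------------------------------------------------
# Locus output
# ---------------------------------------------------------------------------

def write_locus_outputs(loci, prefix: str | os.PathLike) -> dict[str, str]:
    """Write BED6, GFF3 and a class-count summary TSV for the given loci.

    Returns a mapping of format name to path. Empty locus lists produce
    header-only files.
    """
    from .annotate import summarize

    prefix = str(prefix)
    paths = {"bed": prefix + ".bed", "gff3": prefix + ".gff3", "summary": prefix + ".summary.tsv"}
    with open(paths["bed"], "w") as bed:
        for i, loc in enumerate(loci, 1):
            score = int(round(min(max(loc.best_phasing_score, 0.0), 1000.0)))
            bed.write(
                f"{loc.ref_id}\t{loc.start}\t{loc.end}\tPHAS{i:04d}\t{score}\t+\n"
            )
    with open(paths["gff3"], "w") as gff:
        gff.write("##gff-version 3\n")
        for i, loc in enumerate(loci, 1):
            attrs = (
                f"ID=PHAS{i:04d};pvalue={loc.best_pvalue:.3g};"
                f"phasing_score={loc.best_phasing_score:.3f};"
                f"class={loc.genomic_class or 'unclassified'};"
                f"gene_id={loc.gene_id or 'NA'};register_len={loc.register_len}"
            )
            gff.write(
                f"{loc.ref_id}\tphasekit\tphasiRNA_locus\t{loc.start + 1}\t{loc.end}\t"
                f"{loc.best_phasing_score:.2f}\t+\t.\t{attrs}\n"
            )
    summarize(list(loci)).to_csv(paths["summary"], sep="\t", index=False)
    return paths
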