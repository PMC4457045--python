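"""Genomic classification of PHAS loci, gene-level consolidation,
intron-retention support, and differential phasiRNA production.

Classification uses the union of phased-read intervals (the footprint),
not the window extent: a merged window can overhang an annotation purely
because window starts sit on the scan grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import GeneModel, RunConfig
from .phasing import PhasLocus

log = logging.getLogger("phasekit")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_locus(locus: PhasLocus, models: list[GeneModel]) -> tuple[str, str | None]:
    """Assign a genomic class (exon / intron / exon_intron / intergenic).

    The locus is attached to the overlapping gene with the largest extent
    overlap (ties to the lexicographically smaller gene id, with a warning);
    its footprint is then compared against the primary isoform's exons and
    introns. Sets ``locus.genomic_class`` and ``locus.gene_id`` and returns
    them.
    """
    extent = (locus.start, locus.end)
    candidates = [
        (m, _overlap(extent, m.span))
        for m in models
        if m.chrom == locus.ref_id and _overlap(extent, m.span) > 0
    ]
    if not candidates:
        locus.genomic_class, locus.gene_id = "intergenic", None
        return "intergenic", None
    candidates.sort(key=lambda t: (-t[1], t[0].gene_id))
    if len(candidates) > 1 and candidates[0][1] == candidates[1][1]:
        log.warning(
            "locus %s overlaps genes %s and %s equally; assigned to %s",
            locus.locus_id, candidates[0][0].gene_id, candidates[1][0].gene_id,
            candidates[0][0].gene_id,
        )
    gene = candidates[0][0]
    footprint = locus.footprint() or [extent]
    exon_bp = sum(_overlap(iv, ex) for iv in footprint for ex in gene.exons)
    intron_bp = sum(_overlap(iv, intr) for iv in footprint for intr in gene.introns)
    if exon_bp and intron_bp:
        cls = "exon_intron"
    elif exon_bp:
        cls = "exon"
    elif intron_bp:
        cls = "intron"
    else:
        # footprint misses the gene entirely (extent-only overlap)
        cls = "intergenic"
        locus.genomic_class, locus.gene_id = cls, None
        return cls, None
    locus.genomic_class, locus.gene_id = cls, gene.gene_id
    return cls, gene.gene_id


def merge_by_gene(loci: list[PhasLocus]) -> list[PhasLocus]:
    """Collapse loci that map to the same gene into one record.

    The merged record keeps the union extent, the minimum P-value, the
    maximum phasing score, and the union of member reads; its class becomes
    ``exon_intron`` when the members' classes disagree. Intergenic loci pass
    through untouched. Idempotent.
    """
    by_gene: dict[str, list[PhasLocus]] = {}
    out: list[PhasLocus] = []
    for loc in loci:
        if loc.gene_id is None:
            out.append(loc)
        else:
            by_gene.setdefault(loc.gene_id, []).append(loc)
    for gene_id, group in by_gene.items():
        if len(group) == 1:
            out.append(group[0])
            continue
        group.sort(key=lambda l: l.start)
        base = group[0]
        merged = PhasLocus(
            ref_id=base.ref_id,
            start=min(l.start for l in group),
            end=max(l.end for l in group),
            register_len=base.register_len,
            phase_offset=base.phase_offset,
            best_pvalue=min(l.best_pvalue for l in group),
            best_phasing_score=max(l.best_phasing_score for l in group),
            window_count=sum(l.window_count for l in group),
            gene_id=gene_id,
        )
        seen = set()
        for l in group:
            for a in l.inphase_alignments:
                key = (a.read.seq, a.start, a.strand)
                if key not in seen:
                    seen.add(key)
                    merged.inphase_alignments.append(a)
        classes = {l.genomic_class for l in group}
        merged.genomic_class = classes.pop() if len(classes) == 1 else "exon_intron"
        merged.locus_id = f"{merged.ref_id}:{merged.start}-{merged.end}/{merged.register_len}"
        out.append(merged)
    out.sort(key=lambda l: (l.ref_id, l.start))
    return out


@dataclass
class IntronCall:
    """Intron-retention assessment of an intron-class locus."""

    locus_id: str
    intron: tuple[int, int]
    rnaseq_mean_coverage: float
    call: str  # bona_fide_intron | retained_intron | unknown


def intron_retention_support(
    locus: PhasLocus,
    model: GeneModel,
    coverage: list[tuple[str, int, int, float]] | None,
    low_cov: float = 1.0,
    high_cov: float = 5.0,
) -> IntronCall:
    """Classify the phasiRNA-producing intron by RNA-seq coverage.

    Mean per-base coverage below ``low_cov`` supports a spliced ("bona
    fide") intron; at or above ``high_cov`` it indicates retention; the band
    in between is left unknown, as is the case with no coverage track.
    """
    footprint = locus.footprint() or [(locus.start, locus.end)]
    introns = [
        intr for intr in model.introns if any(_overlap(iv, intr) > 0 for iv in footprint)
    ]
    intron = introns[0] if introns else (locus.start, locus.end)
    if coverage is None:
        return IntronCall(locus.locus_id or "", intron, float("nan"), "unknown")
    length = intron[1] - intron[0]
    total = sum(
        _overlap((s, e), intron) * v
        for chrom, s, e, v in coverage
        if chrom == locus.ref_id
    )
    mean = total / length if length else 0.0
    if mean < low_cov:
        call = "bona_fide_intron"
    elif mean >= high_cov:
        call = "retained_intron"
    else:
        call = "unknown"
    return IntronCall(locus.locus_id or "", intron, mean, call)


# ---------------------------------------------------------------------------
# Differential phasiRNA production between libraries
# ---------------------------------------------------------------------------

@dataclass
class LibraryStatus:
    """Per-locus-key state of one library: abundance and PHAS verdict."""

    rpm: float = 0.0
    phas: bool = False

    @property
    def status(self) -> str:
        if self.phas:
            return "PHAS"
        return "siRNA_only" if self.rpm > 0 else "silent"


@dataclass
class DifferentialRecord:
    key: str
    rpm_a: float
    rpm_b: float
    ratio: float
    status_a: str
    status_b: str
    verdict: str  # induced | suppressed | gained_PHAS | lost_PHAS | stable


def library_profile(loci: list[PhasLocus]) -> dict[str, LibraryStatus]:
    """Summarize one processed library as locus-key → (RPM, PHAS flag).

    Keys are gene ids where available, locus coordinates otherwise.
    """
    prof: dict[str, LibraryStatus] = {}
    for loc in loci:
        key = loc.gene_id or loc.locus_id or f"{loc.ref_id}:{loc.start}-{loc.end}"
        st = prof.setdefault(key, LibraryStatus())
        st.rpm += loc.total_rpm()
        st.phas = True
    return prof


def compare_libraries(
    profile_a: dict[str, LibraryStatus],
    profile_b: dict[str, LibraryStatus],
    cfg: RunConfig,
    cfg_b: RunConfig | None = None,
) -> list[DifferentialRecord]:
    """Fold-change comparison of register-length siRNA production per locus.

    ratio = (rpm_b + eps) / (rpm_a + eps) with a 0.1-RPM pseudocount.
    PHAS-status transitions take precedence (gained_PHAS / lost_PHAS); then
    the plain fold-change rule: induced above the cutoff, suppressed below
    its reciprocal, stable otherwise. Swapping the libraries maps ratio to
    1/ratio and exchanges induced/suppressed and gained/lost.
    """
    if cfg_b is not None and cfg_b.to_dict() != cfg.to_dict():
        raise ValueError("libraries were processed with different configurations")
    eps = cfg.rpm_pseudocount
    records = []
    for key in sorted(set(profile_a) | set(profile_b)):
        a = profile_a.get(key, LibraryStatus())
        b = profile_b.get(key, LibraryStatus())
        ratio = (b.rpm + eps) / (a.rpm + eps)
        if a.phas and not b.phas:
            verdict = "lost_PHAS"
        elif b.phas and not a.phas:
            verdict = "gained_PHAS"
        elif ratio > cfg.fold_change_cutoff:
            verdict = "induced"
        elif ratio < 1.0 / cfg.fold_change_cutoff:
            verdict = "suppressed"
        else:
            verdict = "stable"
        records.append(
            DifferentialRecord(key, a.rpm, b.rpm, ratio, a.status, b.status, verdict)
        )
    return records


def differential_table(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(locus=r.key, rpm_a=r.rpm_a, rpm_b=r.rpm_b, ratio=r.ratio,
                 status_a=r.status_a, status_b=r.status_b, verdict=r.verdict)
            for r in records
        ],
        columns=["locus", "rpm_a", "rpm_b", "ratio", "status_a", "status_b", "verdict"],
    )


def summarize(loci: list[PhasLocus]) -> pd.DataFrame:
    """Class counts per register length (exon / intron / exon-intron /
    genic subtotal / intergenic / total), one row per register length."""
    rows = []
    for reg in sorted({l.register_len for l in loci}) or []:
        sub = [l for l in loci if l.register_len == reg]
        counts = {c: sum(1 for l in sub if l.genomic_class == c)
                  for c in ("exon", "intron", "exon_intron", "intergenic")}
        unclassified = sum(1 for l in sub if l.genomic_class is None)
        genic = counts["exon"] + counts["intron"] + counts["exon_intron"]
        rows.append(
            dict(register_len=reg, exon=counts["exon"], intron=counts["intron"],
                 exon_intron=counts["exon_intron"], genic=genic,
                 intergenic=counts["intergenic"] + unclassified, total=len(sub))
        )
    return pd.DataFrame(
        rows,
        columns=["register_len", "exon", "intron", "exon_intron", "genic", "intergenic", "total"],
    )
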