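"""Synthetic genomes and small-RNA libraries with planted PHAS loci.

The generator emulates the statistical structure of real plant small-RNA
libraries at desk scale: a random genome with multi-exon gene models and
one duplicated gene family; phased duplex populations (sense read at the
cleavage register, antisense partner two nucleotides upstream, the 3'
overhang) with geometric abundance decay along the locus; a planted
21/22-nt trigger whose complementary site cleaves exactly at the first
phasiRNA 5' end (one-hit 22-nt or two-hit 21-nt model); off-phase
degradation noise (per-duplex position jitter), uniform background reads,
rRNA contamination and a degradome library with 5' ends at every true
cleavage site. Every planted feature is recorded in a truth table, and all
randomness flows from one seed, so outputs are byte-identical per seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    SequenceRecord,
    revcomp,
    write_fasta,
    write_gff3_genes,
    write_collapsed_reads,
)
from .preprocess import CollapsedRead
from .phasing import PhasLocus

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T


@dataclass
class SimConfig:
    """Study conditions for the synthetic libraries.

    Defaults: a 200-kb genome with 24 genes, 30 planted 21-nt loci spread
    over the four genomic classes plus two 24-nt loci, ten duplex cycles per
    locus with geometric decay 0.8, phasing fidelity 0.9 (one duplex in ten
    is jittered off phase), 400 background reads (~30% of the unique reads
    in the library) and 5% rRNA contamination.
    """

    genome_len: int = 200_000
    n_genes: int = 24
    n_phas_exonic: int = 8
    n_phas_intronic: int = 7
    n_phas_junction: int = 7
    n_phas_intergenic: int = 8
    n_phas_24nt: int = 2
    duplex_cycles: int = 10
    abundance_decay: float = 0.8
    base_count: int = 2000
    strand_balance: float = 0.5
    phasing_fidelity: float = 0.9
    noise_reads: int = 400
    rrna_fraction: float = 0.05
    trigger_len_mix: float = 0.5  # P(one-hit 22-nt model) vs two-hit
    trigger_count: int = 3000
    degradome_depth: int = 20
    library_depth: int | None = None
    family_identity: float = 0.88
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("abundance_decay", "strand_balance", "phasing_fidelity",
                     "rrna_fraction", "trigger_len_mix", "family_identity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_phas_exonic", "n_phas_intronic", "n_phas_junction",
                     "n_phas_intergenic", "n_phas_24nt", "noise_reads", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duplex_cycles < 1 or self.base_count < 1:
            raise ValueError("duplex_cycles and base_count must be >= 1")

    @property
    def n_genic(self) -> int:
        return self.n_phas_exonic + self.n_phas_intronic + self.n_phas_junction

    def replace(self, **kw) -> "SimConfig":
        d = asdict(self)
        d.update(kw)
        return SimConfig(**d)


@dataclass
class TruthRecord:
    """Ground truth for one planted locus."""

    locus_id: str
    genomic_class: str
    ref_id: str
    start: int
    end: int
    register_len: int
    phase_offset: int
    gene_id: str | None
    trigger_seq: str | None
    model: str  # one_hit_22 | two_hit | none
    cleavage_positions: list[int] = field(default_factory=list)
    trigger_sites: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SimResult:
    """Everything one synthetic run produced, plus the truth tables."""

    config: SimConfig
    genome: list[SequenceRecord]
    models: list[GeneModel]
    family_map: dict[str, str]
    reads: list[CollapsedRead]
    rrna_refs: list[SequenceRecord]
    degradome_reads: list[CollapsedRead]
    truth: list[TruthRecord]
    transcriptome: list[SequenceRecord]
    read_provenance: dict[str, str]

    @property
    def ref_lengths(self) -> dict[str, int]:
        return {r.id: len(r.seq) for r in self.genome}

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    locus_id=t.locus_id, genomic_class=t.genomic_class, ref_id=t.ref_id,
                    start=t.start, end=t.end, register_len=t.register_len,
                    phase_offset=t.phase_offset, gene_id=t.gene_id or "NA",
                    trigger_seq=t.trigger_seq or "NA", model=t.model,
                    cleavage_positions=",".join(map(str, t.cleavage_positions)),
                )
                for t in self.truth
            ]
        )

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "gff3": os.path.join(outdir, "annotation.gff3"),
            "reads": os.path.join(outdir, "reads.fa"),
            "rrna": os.path.join(outdir, "rrna.fa"),
            "degradome": os.path.join(outdir, "degradome.fa"),
            "truth": os.path.join(outdir, "truth_loci.tsv"),
            "families": os.path.join(outdir, "families.tsv"),
            "transcripts": os.path.join(outdir, "transcripts.fa"),
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3_genes(self.models, paths["gff3"])
        write_collapsed_reads(self.reads, paths["reads"], prefix="sim")
        write_fasta(self.rrna_refs, paths["rrna"])
        write_collapsed_reads(self.degradome_reads, paths["degradome"], prefix="deg")
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": g, "family": f} for g, f in sorted(self.family_map.items())]
        ).to_csv(paths["families"], sep="\t", index=False)
        write_fasta(self.transcriptome, paths["transcripts"])
        return paths


class _GenomeBuild:
    """Mutable genome under construction (trigger sites are written in
    before phasiRNA sequences are extracted)."""

    def __init__(self, arr: np.ndarray, models: list[GeneModel], family_map: dict[str, str]):
        self.arr = arr
        self.models = models
        self.family_map = family_map

    def slice(self, start: int, end: int) -> str:
        return self.arr[start:end].tobytes().decode()

    def write_seq(self, start: int, seq: str) -> None:
        self.arr[start : start + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)

    def record(self, ref_id: str = "chr1") -> SequenceRecord:
        return SequenceRecord(ref_id, self.arr.tobytes().decode())


def _mutate(arr: np.ndarray, identity: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute ~(1-identity) of the bases, two thirds of them transitions
    (the dominant substitution class between recent paralogs)."""
    out = arr.copy()
    hit = rng.random(len(arr)) > identity
    for i in np.nonzero(hit)[0]:
        if rng.random() < 2 / 3:
            out[i] = _TRANSITION[int(out[i])]
        else:
            choices = [b for b in _BASES if b != out[i] and b != _TRANSITION[int(out[i])]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return out


def make_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> _GenomeBuild:
    """Random genome with multi-exon genes and one duplicated gene family.

    The last gene is a structural copy of the first at ``family_identity``
    sequence identity; the two share family id FAM1.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cfg.n_genes == 0 and cfg.n_genic > 0:
        raise ValueError("genic PHAS loci requested but n_genes == 0")
    if cfg.n_genes > 0 and cfg.n_genes < cfg.n_genic + 1:
        raise ValueError(
            f"need at least {cfg.n_genic + 1} genes to host "
            f"{cfg.n_genic} genic loci plus the duplicated family member"
        )
    arr = _BASES[rng.integers(0, 4, cfg.genome_len)].copy()

    models: list[GeneModel] = []
    structures: list[list[tuple[int, int]]] = []  # exon intervals per gene
    cursor = 1200
    for g in range(cfg.n_genes):
        if g == cfg.n_genes - 1 and cfg.n_genes >= 2:
            exon_lens = [e - s for s, e in structures[0]]
            intron_lens = [
                structures[0][i + 1][0] - structures[0][i][1]
                for i in range(len(structures[0]) - 1)
            ]
        else:
            n_ex = int(rng.integers(2, 6))
            exon_lens = [int(rng.integers(280, 521)) for _ in range(n_ex)]
            if g == 0:
                exon_lens[0] = int(rng.integers(350, 521))
            intron_lens = [int(rng.integers(300, 601)) for _ in range(n_ex - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        if cursor + span + 1200 > cfg.genome_len:
            need = cursor + span + 1200
            raise ValueError(f"genome too small for {cfg.n_genes} genes; need >= {need} nt")
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        structures.append(exons)
        models.append(
            GeneModel(
                gene_id=f"gene{g + 1:03d}",
                chrom="chr1",
                strand="+",
                exons=exons,
                isoform_exons={f"gene{g + 1:03d}.t1": exons},
            )
        )
        cursor = pos + int(rng.integers(900, 1601))

    family_map: dict[str, str] = {}
    if cfg.n_genes >= 2:
        src, dup = models[0], models[-1]
        arr[dup.start : dup.end] = _mutate(
            arr[src.start : src.end], cfg.family_identity, rng
        )
        family_map[src.gene_id] = "FAM1"
        family_map[dup.gene_id] = "FAM1"
    return _GenomeBuild(arr, models, family_map)


def _random_srna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def plant_phas_locus(
    build: _GenomeBuild,
    start: int,
    register_len: int,
    genomic_class: str,
    model: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    locus_id: str,
    gene_id: str | None = None,
) -> tuple[list[tuple[str, int, str]], list[tuple[str, int]], TruthRecord]:
    """Plant one PHAS locus at ``start`` (the first cleavage register).

    Writes the trigger's complementary site(s) into the genome, then emits
    ``duplex_cycles`` sense/antisense duplexes at N x register_len spacing
    with geometric count decay; a fraction (1 - phasing_fidelity) of the
    duplexes is jittered 1-10 nt off phase. Returns the locus reads as
    (sequence, count, provenance) triples, the degradome reads, and the
    truth record.
    """
    reg, cycles = register_len, cfg.duplex_cycles
    end = start + cycles * reg
    if start < 30 or end + 30 > len(build.arr):
        raise ValueError("site too short: locus does not fit with its flanks")

    cleavages: list[int] = []
    sites: list[tuple[int, int]] = []
    trigger_seq: str | None = None
    if model in ("one_hit_22", "two_hit"):
        tlen = 22 if model == "one_hit_22" else 21
        trigger_seq = _random_srna(rng, tlen)
        cleavages = [start] if model == "one_hit_22" else [start, end]
        for cl in cleavages:
            site = (cl + 10 - tlen, cl + 10)
            sites.append(site)
            build.write_seq(site[0], revcomp(trigger_seq))

    reads: list[tuple[str, int, str]] = []
    for i in range(cycles):
        cyc = cfg.base_count * cfg.abundance_decay ** i
        anchor = start + i * reg
        for strand in ("+", "-"):
            if rng.random() < cfg.phasing_fidelity:
                jitter, prov = 0, "phased"
            else:
                jitter = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
                prov = "offphase"
            spos = anchor + jitter
            frac = cfg.strand_balance if strand == "+" else 1 - cfg.strand_balance
            n = max(1, round(cyc * 2 * frac * rng.uniform(0.7, 1.3)))
            if strand == "+":
                reads.append((build.slice(spos, spos + reg), n, prov))
            else:
                reads.append((revcomp(build.slice(spos - 2, spos - 2 + reg)), n, prov))
    if trigger_seq is not None:
        reads.append((trigger_seq, cfg.trigger_count, "trigger"))

    degradome = [(build.slice(cl, cl + 20), cfg.degradome_depth) for cl in cleavages]
    truth = TruthRecord(
        locus_id=locus_id,
        genomic_class=genomic_class,
        ref_id="chr1",
        start=start,
        end=end,
        register_len=reg,
        phase_offset=start % reg,
        gene_id=gene_id,
        trigger_seq=trigger_seq,
        model=model,
        cleavage_positions=cleavages,
        trigger_sites=sites,
    )
    return reads, degradome, truth


def _pick_exonic_site(gene: GeneModel, rng) -> int:
    exons = [e for e in gene.exons if e[1] - e[0] >= 260]
    if not exons:
        raise ValueError(f"gene {gene.gene_id} has no exon long enough for a locus")
    s, e = exons[int(rng.integers(len(exons)))]
    return int(rng.integers(s + 27, e - 225 + 1))


def _pick_intronic_site(gene: GeneModel, rng) -> int:
    introns = [iv for iv in gene.introns if iv[1] - iv[0] >= 260]
    if not introns:
        raise ValueError(f"gene {gene.gene_id} has no intron long enough for a locus")
    s, e = introns[int(rng.integers(len(introns)))]
    return int(rng.integers(s + 27, e - 225 + 1))


def _pick_junction_site(gene: GeneModel, rng) -> int:
    # locus straddles an exon -> intron boundary
    pairs = [
        (gene.exons[i], gene.introns[i])
        for i in range(len(gene.introns))
        if gene.exons[i][1] - gene.exons[i][0] >= 180 and gene.introns[i][1] - gene.introns[i][0] >= 250
    ]
    if not pairs:
        raise ValueError(f"gene {gene.gene_id} has no usable exon-intron boundary")
    exon, intron = pairs[int(rng.integers(len(pairs)))]
    offset = int(rng.integers(60, 141))  # exonic bases 5' of the boundary
    return exon[1] - offset


def make_library(cfg: SimConfig) -> SimResult:
    """Build the full synthetic dataset for one configuration and seed."""
    rng = np.random.default_rng(cfg.seed)
    build = make_genome(cfg, rng)
    models = build.models

    # assign distinct host genes; the first gene (family member) hosts an
    # exonic locus so that same-family targeting is exercised
    hosts = models[:-1] if len(models) >= 2 else models[:]
    host_iter = iter(hosts)
    plan: list[tuple[str, GeneModel | None]] = []
    for _ in range(cfg.n_phas_exonic):
        plan.append(("exon", next(host_iter)))
    for _ in range(cfg.n_phas_intronic):
        plan.append(("intron", next(host_iter)))
    for _ in range(cfg.n_phas_junction):
        plan.append(("exon_intron", next(host_iter)))

    # carve intergenic gaps into non-overlapping slots, one planted locus each
    gaps: list[tuple[int, int]] = []
    prev = 0
    for m in models:
        if m.start - prev >= 800:
            gaps.append((prev, m.start))
        prev = m.end
    if cfg.genome_len - prev >= 800:
        gaps.append((prev, cfg.genome_len))
    slots: list[tuple[int, int]] = []
    for lo, hi in gaps:
        pos = lo
        while hi - pos >= 800:
            slots.append((pos, pos + 800))
            pos += 800
    n_slots_needed = cfg.n_phas_intergenic + cfg.n_phas_24nt
    if len(slots) < n_slots_needed:
        raise ValueError(
            f"genome layout offers {len(slots)} intergenic slots; {n_slots_needed} needed"
        )
    order = rng.permutation(len(slots))

    reads: list[tuple[str, int, str]] = []
    degradome: list[tuple[str, int]] = []
    truth: list[TruthRecord] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"PHAS{idx:03d}"

    for cls, gene in plan:
        if cls == "exon":
            c = _pick_exonic_site(gene, rng)
        elif cls == "intron":
            c = _pick_intronic_site(gene, rng)
        else:
            c = _pick_junction_site(gene, rng)
        model = "one_hit_22" if rng.random() < cfg.trigger_len_mix else "two_hit"
        r, d, t = plant_phas_locus(
            build, c, 21, cls, model, cfg, rng, next_id(), gene_id=gene.gene_id
        )
        reads += r
        degradome += d
        truth.append(t)

    slot_i = 0
    for _ in range(cfg.n_phas_intergenic):
        lo, hi = slots[order[slot_i]]
        slot_i += 1
        c = int(rng.integers(lo + 280, hi - 280 + 1))
        model = "one_hit_22" if rng.random() < cfg.trigger_len_mix else "two_hit"
        r, d, t = plant_phas_locus(build, c, 21, "intergenic", model, cfg, rng, next_id())
        reads += r
        degradome += d
        truth.append(t)
    for _ in range(cfg.n_phas_24nt):
        lo, hi = slots[order[slot_i]]
        slot_i += 1
        c = int(rng.integers(lo + 280, hi - 310 + 1))
        r, d, t = plant_phas_locus(build, c, 24, "intergenic", "none", cfg, rng, next_id())
        reads += r
        degradome += d
        truth.append(t)

    # uniform background reads, 21-nt dominated as in real libraries
    lengths = np.array([18, 19, 20, 21, 22, 23, 24, 25, 26])
    weights = np.array([0.05, 0.05, 0.10, 0.35, 0.15, 0.08, 0.12, 0.05, 0.05])
    for _ in range(cfg.noise_reads):
        L = int(rng.choice(lengths, p=weights))
        pos = int(rng.integers(0, cfg.genome_len - L))
        s = build.slice(pos, pos + L)
        if rng.random() < 0.5:
            s = revcomp(s)
        reads.append((s, int(rng.integers(1, 6)), "noise"))

    # rRNA contamination from a stub reference outside the genome
    rrna_seq = _random_srna(rng, 2000)
    rrna_refs = [SequenceRecord("rRNA_stub", rrna_seq)]
    genome_total = sum(c for _, c, _ in reads)
    if cfg.rrna_fraction > 0:
        if cfg.library_depth is not None:
            n_rrna_total = int(rng.binomial(cfg.library_depth, cfg.rrna_fraction))
            scale = (cfg.library_depth - n_rrna_total) / max(1, genome_total)
            reads = [(s, max(1, round(c * scale)), p) for s, c, p in reads]
        else:
            n_rrna_total = round(cfg.rrna_fraction / (1 - cfg.rrna_fraction) * genome_total)
        n_distinct = 80
        if n_rrna_total > 0:
            split = rng.multinomial(n_rrna_total, np.full(n_distinct, 1 / n_distinct))
            for j, cnt in enumerate(split):
                if cnt == 0:
                    continue
                L = int(rng.integers(18, 27))
                pos = int(rng.integers(0, 2000 - L))
                reads.append((rrna_seq[pos : pos + L], int(cnt), "rrna"))
    elif cfg.library_depth is not None:
        scale = cfg.library_depth / max(1, genome_total)
        reads = [(s, max(1, round(c * scale)), p) for s, c, p in reads]

    collapsed: dict[str, int] = {}
    provenance: dict[str, str] = {}
    order_keys: list[str] = []
    for s, c, p in reads:
        if s not in collapsed:
            order_keys.append(s)
            provenance[s] = p
        collapsed[s] = collapsed.get(s, 0) + c
    library = [CollapsedRead(seq=s, count=collapsed[s]) for s in order_keys]

    deg_collapsed: dict[str, int] = {}
    deg_order: list[str] = []
    for s, c in degradome:
        if s not in deg_collapsed:
            deg_order.append(s)
        deg_collapsed[s] = deg_collapsed.get(s, 0) + c
    degradome_lib = [CollapsedRead(seq=s, count=deg_collapsed[s]) for s in deg_order]

    genome_rec = build.record("chr1")
    transcriptome = [
        SequenceRecord(m.gene_id, genome_rec.seq[m.start : m.end]) for m in models
    ] + [
        SequenceRecord(
            t.locus_id, genome_rec.seq[max(0, t.start - 100) : t.end + 100]
        )
        for t in truth
        if t.gene_id is None
    ]

    return SimResult(
        config=cfg,
        genome=[genome_rec],
        models=models,
        family_map=dict(build.family_map),
        reads=library,
        rrna_refs=rrna_refs,
        degradome_reads=degradome_lib,
        truth=truth,
        transcriptome=transcriptome,
        read_provenance=provenance,
    )


@dataclass
class RecoveryReport:
    sensitivity: float
    precision: float
    per_class: dict[str, tuple[int, int]]
    recovered: list[str]
    missed: list[str]
    false_positives: list[str]


def score_recovery(
    called: list[PhasLocus],
    truth: list[TruthRecord],
    min_overlap: float = 0.5,
    register_len: int | None = None,
) -> RecoveryReport:
    """Sensitivity and precision of locus calls against the truth table.

    A truth locus is recovered iff a called locus of the same register
    length overlaps it by >= ``min_overlap`` of the truth span; a called
    locus is a false positive when it covers no truth locus by >=
    ``min_overlap`` of the shorter of the two spans.
    """
    if register_len is not None:
        truth = [t for t in truth if t.register_len == register_len]
        called = [l for l in called if l.register_len == register_len]

    def ov(a, b) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    recovered, missed = [], []
    per_class: dict[str, list[int]] = {}
    for t in truth:
        hit = any(
            l.register_len == t.register_len
            and l.ref_id == t.ref_id
            and ov((l.start, l.end), (t.start, t.end)) >= min_overlap * (t.end - t.start)
            for l in called
        )
        (recovered if hit else missed).append(t.locus_id)
        tot = per_class.setdefault(t.genomic_class, [0, 0])
        tot[1] += 1
        tot[0] += int(hit)
    false_pos = [
        l.locus_id or f"{l.ref_id}:{l.start}"
        for l in called
        if not any(
            t.register_len == l.register_len
            and t.ref_id == l.ref_id
            and ov((l.start, l.end), (t.start, t.end))
            >= min_overlap * min(t.end - t.start, l.end - l.start)
            for t in truth
        )
    ]
    sens = len(recovered) / len(truth) if truth else 1.0
    prec = 1.0 - len(false_pos) / len(called) if called else 1.0
    return RecoveryReport(
        sensitivity=sens,
        precision=prec,
        per_class={k: (v[0], v[1]) for k, v in per_class.items()},
        recovered=recovered,
        missed=missed,
        false_positives=false_pos,
    )
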