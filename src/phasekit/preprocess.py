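"""Raw small-RNA reads → cleaned, collapsed, genome-placed sRNAs.

The placement step is exact-match only (no mismatches, no gaps) and drops
reads with more than ``max_hits`` placements, following the standard
phasiRNA-analysis convention. Abundance is expressed in reads per million
cleaned library reads (RPM), where "cleaned" means the reads surviving
adaptor trimming, length bounds and rRNA filtering, before the multi-hit
mapping filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .io import SequenceRecord, revcomp

log = logging.getLogger("phasekit")


@dataclass
class CollapsedRead:
    """A distinct small-RNA sequence with its observed read count."""

    seq: str
    count: int
    rpm: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.seq:
            raise ValueError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __hash__(self) -> int:  # identity by sequence
        return hash(self.seq)


@dataclass(frozen=True)
class Alignment:
    """An exact, full-length placement of a collapsed read on a reference.

    ``start`` is the 0-based leftmost genome coordinate regardless of strand;
    ``hits`` is the total number of placements of the read on the reference.
    """

    read: CollapsedRead
    ref_id: str
    strand: str
    start: int
    hits: int

    @property
    def end(self) -> int:
        return self.start + self.read.length

    @property
    def length(self) -> int:
        return self.read.length


def trim_adaptor(
    read: str,
    adaptor: str,
    min_len: int = 18,
    max_len: int = 34,
) -> str | None:
    """Strip the 3' adaptor from a raw read.

    The leftmost exact match of the adaptor's first 8 nt (or of the whole
    adaptor if shorter) marks the insert end. Returns the insert, or None
    when no adaptor is found or the insert length falls outside
    [min_len, max_len].
    """
    if len(adaptor) < 6:
        raise ValueError("adaptor must be at least 6 nt")
    read = read.upper().replace("U", "T")
    seed = adaptor.upper().replace("U", "T")[:8]
    idx = read.find(seed)
    if idx < 0:
        return None
    if not (min_len <= idx <= max_len):
        return None
    return read[:idx]


def collapse_reads(reads) -> list[CollapsedRead]:
    """Collapse a sequence multiset into unique reads with counts."""
    counts = Counter(r.upper().replace("U", "T") for r in reads)
    return [CollapsedRead(seq=s, count=c) for s, c in counts.items()]


def filter_rrna(
    reads: list[CollapsedRead],
    rrna_refs: list[SequenceRecord],
) -> list[CollapsedRead]:
    """Drop reads that exactly match any rRNA reference on either strand.

    A read is removed iff it occurs as a substring of a reference or of its
    reverse complement. Idempotent; with no references it is the identity.
    """
    if not rrna_refs:
        return list(reads)
    haystacks = [r.seq for r in rrna_refs] + [revcomp(r.seq) for r in rrna_refs]
    return [rd for rd in reads if not any(rd.seq in h for h in haystacks)]


def compute_rpm(count: int, cleaned_total: int) -> float:
    """Reads per million cleaned library reads."""
    if cleaned_total <= 0:
        raise ValueError("cleaned library total must be positive")
    return count * 1e6 / cleaned_total


def assign_rpm(reads: list[CollapsedRead], cleaned_total: int | None = None) -> int:
    """Fill the rpm field of every read; returns the library total used."""
    total = cleaned_total if cleaned_total is not None else sum(r.count for r in reads)
    for r in reads:
        r.rpm = compute_rpm(r.count, total)
    return total


class GenomeIndex:
    """Exact-match lookup of short reads on a small genome.

    A dictionary of fixed-length prefixes (k = 18 by default, the shortest
    read the pipeline keeps) maps to candidate positions; candidates are
    verified by direct comparison, so placements are exact and full-length.
    Reads shorter than k fall back to a string scan.
    """

    def __init__(self, genome: list[SequenceRecord], k: int = 18):
        self.k = k
        self.refs = {r.id: r.seq for r in genome}
        self._prefix: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.refs.items():
            for i in range(len(seq) - k + 1):
                self._prefix.setdefault(seq[i : i + k], []).append((rid, i))

    def placements(self, query: str) -> list[tuple[str, int]]:
        """All (ref_id, start) where ``query`` occurs verbatim on the + strand."""
        n = len(query)
        if n < self.k:
            out = []
            for rid, seq in self.refs.items():
                i = seq.find(query)
                while i >= 0:
                    out.append((rid, i))
                    i = seq.find(query, i + 1)
            return out
        return [
            (rid, i)
            for rid, i in self._prefix.get(query[: self.k], [])
            if self.refs[rid][i : i + n] == query
        ]


def map_reads(
    reads: list[CollapsedRead],
    genome: list[SequenceRecord],
    max_hits: int = 6,
    index: GenomeIndex | None = None,
) -> list[Alignment]:
    """Enumerate every exact full-length placement of each read, both strands.

    Reads with no placement are dropped; reads with more than ``max_hits``
    total placements are dropped entirely. The leftmost coordinate is
    reported for both strands.
    """
    idx = index or GenomeIndex(genome)
    alignments: list[Alignment] = []
    n_unmapped = n_multi = 0
    for read in reads:
        plus = idx.placements(read.seq)
        minus = idx.placements(revcomp(read.seq))
        hits = len(plus) + len(minus)
        if hits == 0:
            n_unmapped += 1
            continue
        if hits > max_hits:
            n_multi += 1
            continue
        for rid, pos in plus:
            alignments.append(Alignment(read, rid, "+", pos, hits))
        for rid, pos in minus:
            alignments.append(Alignment(read, rid, "-", pos, hits))
    if n_unmapped or n_multi:
        log.info("map_reads: %d unmapped, %d dropped for >%d hits", n_unmapped, n_multi, max_hits)
    return alignments


@dataclass
class PreprocessStats:
    """Read-conservation counters across the cleaning stages."""

    raw: int = 0
    no_adaptor: int = 0
    bad_length: int = 0
    trimmed: int = 0
    rrna: int = 0
    cleaned: int = 0
    counters: dict = field(default_factory=dict)


def preprocess_reads(
    raw_seqs,
    adaptor: str | None = None,
    rrna_refs: list[SequenceRecord] | None = None,
    min_len: int = 18,
    max_len: int = 34,
) -> tuple[list[CollapsedRead], PreprocessStats]:
    """Trim, length-filter, collapse and rRNA-clean a raw read iterable.

    Returns cleaned collapsed reads with RPM filled against the cleaned
    library total, plus conservation counters.
    """
    stats = PreprocessStats()
    kept: list[str] = []
    for seq in raw_seqs:
        stats.raw += 1
        if adaptor is not None:
            trimmed = trim_adaptor(seq, adaptor, min_len, max_len)
            if trimmed is None:
                idx = seq.upper().replace("U", "T").find(adaptor.upper().replace("U", "T")[:8])
                if idx < 0:
                    stats.no_adaptor += 1
                else:
                    stats.bad_length += 1
                continue
            seq = trimmed
        else:
            seq = seq.upper().replace("U", "T")
            if not (min_len <= len(seq) <= max_len):
                stats.bad_length += 1
                continue
        kept.append(seq)
    stats.trimmed = len(kept)
    collapsed = collapse_reads(kept)
    cleaned = filter_rrna(collapsed, rrna_refs or [])
    stats.rrna = sum(r.count for r in collapsed) - sum(r.count for r in cleaned)
    stats.cleaned = sum(r.count for r in cleaned)
    assign_rpm(cleaned, stats.cleaned if stats.cleaned else None)
    return cleaned, stats
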