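"""Phase-register window scan, phasing statistics and PHAS locus calling.

The model: a PHAS precursor is diced from a trigger cleavage site into
head-to-tail 21-nt (or 24-nt) duplexes, so the 5' ends of the resulting
siRNAs fall into a single residue class ("phase register") modulo the
register length. Antisense reads carry a +2 offset (the 2-nt 3' overhang of
the duplex) that places the partner of a sense read back into the sense
register. A sliding window of nine register cycles tallies how strongly
one register dominates; significance comes from a hypergeometric tail and,
for 24-nt loci, a log phasing score.

The hypergeometric statistic treats the window as 21*m positions of which
m belong to one register: with n occupied positions, the probability of k
or more of them landing in a single register is

    p(k) = sum_{X=k}^{min(n,m)} C(20m, n-X) C(m, X) / C(21m, n).

n counts the distinct register-length reads in the window and k the
register slots of the dominant phase occupied by at least one of them
(both strands collapse onto one slot through the +2 rule, so k is bounded
by the m cycles as the formula requires). The window-eligibility filter
is applied first: >= 10 unique reads of any length, more than half of them
register-length, >= 3 register-length reads in the best phase.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from functools import lru_cache

from .io import RunConfig
from .preprocess import Alignment


def register_position(a: Alignment, register_len: int = 21) -> int:
    """Phase coordinate of an alignment: plus-strand 5' end, or leftmost+2
    on the minus strand (the 2-nt 3'-overhang correction)."""
    return a.start + 2 if a.strand == "-" else a.start


def register_index(pos: int, window_start: int, register_len: int) -> int:
    """Residue class of a phase coordinate within a window."""
    if pos < window_start:
        raise ValueError("position precedes window")
    return (pos - window_start) % register_len


@lru_cache(maxsize=200_000)
def phas_pvalue(n: int, k: int, m: int, register_len: int = 21) -> float:
    """Hypergeometric tail probability of phasing by chance.

    Exact integer binomials throughout; the float conversion happens once at
    the end, so the result is correct to full double precision.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if k < 0 or k > min(n, m):
        raise ValueError(f"k={k} outside [0, min(n={n}, m={m})]")
    total = register_len * m
    if n > total:
        raise ValueError(f"n={n} exceeds the {total} window positions")
    black = (register_len - 1) * m
    denom = math.comb(total, n)
    num = sum(math.comb(black, n - x) * math.comb(m, x) for x in range(k, min(n, m) + 1))
    return num / denom


def phas_pmf(x: int, n: int, m: int, register_len: int = 21) -> float:
    """Point probability Pr(X = x) of the phasing hypergeometric."""
    total = register_len * m
    return math.comb((register_len - 1) * m, n - x) * math.comb(m, x) / math.comb(total, n)


def phasing_score(
    inphase_abundance: float,
    outphase_unique: int,
    occupied_registers: int,
) -> float:
    """Log phasing score: (occupied - 2) * ln(1 + 10*sum(P)/(1 + sum(U))).

    ``inphase_abundance`` is the total read count in the dominant register
    across the window's cycles, ``outphase_unique`` the number of unique
    register-length reads outside it, and ``occupied_registers`` the number
    of the window's cycle positions holding at least one in-phase read.
    Fewer than three occupied cycles scores zero.
    """
    if inphase_abundance < 0 or outphase_unique < 0:
        raise ValueError("abundances must be non-negative")
    if occupied_registers < 3:
        return 0.0
    return (occupied_registers - 2) * math.log1p(
        10.0 * inphase_abundance / (1.0 + outphase_unique)
    )


@dataclass
class PhaseWindow:
    """One sliding-window evaluation with its register tallies."""

    ref_id: str
    start: int
    register_len: int
    cycles: int
    phase_offset: int  # register index (relative to window start) maximizing k
    n_unique_all: int  # distinct reads of any length in the window
    n_unique_reg: int  # distinct register-length reads in the window
    n_positions: int  # distinct occupied register positions (register-length reads)
    k_inphase: int  # occupied positions in the best register
    occupied_registers: int  # cycle slots of the best register holding a read
    inphase_abundance: float  # total read count in the best register
    outphase_unique: int  # unique register-length reads outside it
    pvalue: float = 1.0
    score: float = 0.0
    inphase_alignments: list[Alignment] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.register_len * self.cycles

    @property
    def end(self) -> int:
        return self.start + self.span

    @property
    def abs_phase(self) -> int:
        """Absolute phase residue (mod register_len) on the reference."""
        return (self.start + self.phase_offset) % self.register_len


def window_filter(w: PhaseWindow, cfg: RunConfig) -> tuple[bool, str]:
    """Eligibility of a window for statistics.

    Requires >= min_unique_reads unique reads, strictly more than half of
    them register-length, and >= min_inphase_unique register-length reads in
    the best phase.
    """
    if w.n_unique_all < cfg.min_unique_reads:
        return False, f"unique<{cfg.min_unique_reads}"
    if not (w.n_unique_reg * 2 > w.n_unique_all):
        return False, "register-length reads not more than half"
    if w.k_inphase < cfg.min_inphase_unique:
        return False, f"inphase<{cfg.min_inphase_unique}"
    return True, "pass"


def _window_stats(
    ref_id: str,
    wstart: int,
    alns: list[tuple[int, Alignment]],
    cfg: RunConfig,
) -> PhaseWindow:
    """Tally one window from (adjusted position, alignment) pairs inside it."""
    reg = cfg.register_len
    m = cfg.cycles_per_window
    seqs_all = {a.read.seq for _, a in alns}
    reg_alns = [(p, a) for p, a in alns if a.length == reg]
    seqs_reg = {a.read.seq for _, a in reg_alns}
    positions = sorted({p for p, _ in reg_alns})

    per_offset: dict[int, set[int]] = {}
    for p in positions:
        per_offset.setdefault((p - wstart) % reg, set()).add(p)
    if per_offset:
        best = max(per_offset, key=lambda o: (len(per_offset[o]), -o))
        best_positions = per_offset[best]
    else:
        best, best_positions = 0, set()

    # de-duplicate identical placements before summing abundance
    inphase, seen = [], set()
    for p, a in reg_alns:
        if p in best_positions:
            key = (a.read.seq, a.start, a.strand)
            if key not in seen:
                seen.add(key)
                inphase.append((p, a))
    inphase_abund = sum(a.read.count for _, a in inphase)
    inphase_seqs = {a.read.seq for _, a in inphase}

    return PhaseWindow(
        ref_id=ref_id,
        start=wstart,
        register_len=reg,
        cycles=m,
        phase_offset=best,
        n_unique_all=len(seqs_all),
        n_unique_reg=len(seqs_reg),
        n_positions=len(positions),
        k_inphase=len(best_positions),
        occupied_registers=len(best_positions),
        inphase_abundance=inphase_abund,
        outphase_unique=len(seqs_reg - inphase_seqs),
        inphase_alignments=[a for _, a in inphase],
    )


def scan_windows(
    alignments: list[Alignment],
    ref_lengths: dict[str, int],
    cfg: RunConfig,
) -> list[PhaseWindow]:
    """Slide the phase window along every reference and score eligible windows.

    Windows of span register_len * cycles are placed at starts 0, step,
    2*step, ... (step = three registers). Windows failing the eligibility
    filter are discarded before statistics; the rest get their
    hypergeometric P-value and phasing score.
    """
    span, step = cfg.window_span, cfg.step
    by_ref: dict[str, list[tuple[int, Alignment]]] = {}
    for a in alignments:
        by_ref.setdefault(a.ref_id, []).append((register_position(a, cfg.register_len), a))
    out: list[PhaseWindow] = []
    for ref_id, pairs in by_ref.items():
        if ref_id not in ref_lengths:
            raise KeyError(f"no length known for reference {ref_id}")
        pairs.sort(key=lambda t: t[0])
        pos = [p for p, _ in pairs]
        for wstart in range(0, ref_lengths[ref_id] - span + 1, step):
            lo = bisect_left(pos, wstart)
            hi = bisect_right(pos, wstart + span - 1)
            if lo == hi:
                continue
            w = _window_stats(ref_id, wstart, pairs[lo:hi], cfg)
            ok, _ = window_filter(w, cfg)
            if not ok:
                continue
            # n is capped at the number of window positions so the
            # hypergeometric stays in domain in pathologically dense windows
            n_stat = min(w.n_unique_reg, cfg.register_len * cfg.cycles_per_window)
            w.pvalue = phas_pvalue(
                n_stat, min(w.k_inphase, n_stat), cfg.cycles_per_window, cfg.register_len
            )
            w.score = phasing_score(w.inphase_abundance, w.outphase_unique, w.occupied_registers)
            out.append(w)
    return out


@dataclass
class PhasLocus:
    """Merged positive windows sharing one phase register."""

    ref_id: str
    start: int
    end: int
    register_len: int
    phase_offset: int  # absolute residue class mod register_len
    best_pvalue: float
    best_phasing_score: float
    window_count: int
    inphase_alignments: list[Alignment] = field(default_factory=list)
    genomic_class: str | None = None
    gene_id: str | None = None
    locus_id: str | None = None

    @property
    def member_reads(self) -> dict[str, Alignment]:
        """One representative alignment per distinct member read sequence."""
        return {a.read.seq: a for a in self.inphase_alignments}

    def total_abundance(self) -> int:
        """Summed read count of the distinct in-phase member reads."""
        return sum(a.read.count for a in self.member_reads.values())

    def total_rpm(self) -> float:
        return sum(a.read.rpm for a in self.member_reads.values())

    def footprint(self) -> list[tuple[int, int]]:
        """Union of the genomic intervals covered by member reads."""
        ivs = sorted((a.start, a.end) for a in self.inphase_alignments)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


def merge_windows(positives: list[PhaseWindow]) -> list[PhasLocus]:
    """Combine contiguous positive windows that share a phase register.

    Windows on the same reference merge when their starts differ by a
    multiple of the register length, their chosen phases agree (same residue
    class), and their spans touch or overlap. The locus keeps the union
    extent, minimum P-value, maximum score and the union of member reads.
    """
    loci: list[PhasLocus] = []
    for w in sorted(positives, key=lambda w: (w.ref_id, w.start)):
        cur = loci[-1] if loci else None
        if (
            cur is not None
            and cur.ref_id == w.ref_id
            and cur.register_len == w.register_len
            and (w.start - cur.start) % w.register_len == 0
            and w.abs_phase == cur.phase_offset
            and w.start <= cur.end
        ):
            cur.end = max(cur.end, w.end)
            cur.best_pvalue = min(cur.best_pvalue, w.pvalue)
            cur.best_phasing_score = max(cur.best_phasing_score, w.score)
            cur.window_count += 1
            seen = {(a.read.seq, a.start, a.strand) for a in cur.inphase_alignments}
            cur.inphase_alignments.extend(
                a for a in w.inphase_alignments if (a.read.seq, a.start, a.strand) not in seen
            )
        else:
            loci.append(
                PhasLocus(
                    ref_id=w.ref_id,
                    start=w.start,
                    end=w.end,
                    register_len=w.register_len,
                    phase_offset=w.abs_phase,
                    best_pvalue=w.pvalue,
                    best_phasing_score=w.score,
                    window_count=1,
                    inphase_alignments=list(w.inphase_alignments),
                )
            )
    for i, loc in enumerate(loci, 1):
        loc.locus_id = f"{loc.ref_id}:{loc.start}-{loc.end}/{loc.register_len}"
    return loci


def call_phas_loci(windows: list[PhaseWindow], cfg: RunConfig) -> list[PhasLocus]:
    """Call PHAS loci from eligible windows.

    21-nt mode: positive iff P-value < pvalue_cutoff (strict).
    24-nt mode: positive iff phasing score >= score_cutoff_24nt.
    Positive windows are then merged by shared phase register.
    """
    if cfg.register_len == 24:
        positives = [w for w in windows if w.score >= cfg.score_cutoff_24nt]
    else:
        positives = [w for w in windows if w.pvalue < cfg.pvalue_cutoff]
    return merge_windows(positives)


def windows_table(windows: list[PhaseWindow], cfg: RunConfig):
    """Per-window audit table (one row per eligible window)."""
    import pandas as pd

    rows = []
    for w in windows:
        verdict = (
            w.score >= cfg.score_cutoff_24nt
            if cfg.register_len == 24
            else w.pvalue < cfg.pvalue_cutoff
        )
        rows.append(
            dict(
                ref=w.ref_id, start=w.start, offset=w.phase_offset,
                n_unique_all=w.n_unique_all, n_unique_reg=w.n_unique_reg,
                n_positions=w.n_positions, k=w.k_inphase, m=w.cycles,
                inphase_abundance=w.inphase_abundance, outphase_unique=w.outphase_unique,
                occupied=w.occupied_registers, pvalue=w.pvalue, score=w.score,
                positive=bool(verdict),
            )
        )
    cols = ["ref", "start", "offset", "n_unique_all", "n_unique_reg", "n_positions",
            "k", "m", "inphase_abundance", "outphase_unique", "occupied",
            "pvalue", "score", "positive"]
    return pd.DataFrame(rows, columns=cols)
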