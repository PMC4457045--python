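"""Trigger and target prediction for PHAS loci.

Small-RNA/target duplexes are scored with the plant-target penalty scheme:
mismatch 1.0, G:U wobble 0.5, bulge 2.0, every penalty doubled at sRNA
positions 2-13 (5'->3'), alignments ungapped or with a single one-base
bulge on either side. The guided cleavage site is the target base paired to
sRNA position 10, the canonical slicing register of plant AGO complexes; a
trigger whose cleavage falls N x register_len from the locus phase is
"in phase" and taken to set the phasing register.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .io import RunConfig, SequenceRecord, revcomp
from .preprocess import CollapsedRead
from .phasing import PhasLocus

log = logging.getLogger("phasekit")

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# penalty of sRNA base s against the revcomp-space target base t:
# equal bases are Watson-Crick pairs; (G,A) and (T,C) are G:U wobbles.
_PEN = np.ones((5, 5), dtype=np.float64)
for _b in range(4):
    _PEN[_b, _b] = 0.0
_PEN[_IDX["G"], _IDX["A"]] = 0.5
_PEN[_IDX["T"], _IDX["C"]] = 0.5
_PEN[4, :] = 1.0
_PEN[:, 4] = 1.0

_BULGE = 2.0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().replace("U", "T").encode().translate(
            bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
        ),
        dtype=np.uint8,
    ).copy()


def _weights(L: int) -> np.ndarray:
    w = np.ones(L)
    w[1:13] = 2.0  # sRNA positions 2-13 (1-based)
    return w


@dataclass
class TargetAlignment:
    """One sRNA/target duplex: score, site, pairing and cleavage position.

    Coordinates are 0-based on the supplied target sequence;
    ``target_strand`` is '-' when the sRNA was matched against the reverse
    complement of that sequence, in which case coordinates are already
    converted back to the forward sequence.
    """

    srna: str
    target_id: str
    target_start: int
    target_end: int
    target_strand: str
    score: float
    cleavage_pos: int
    pairing: str
    variant: str  # ungapped | target_bulge | srna_bulge


def _pairing_string(s: np.ndarray, t: np.ndarray, j: int, variant: str, p: int) -> str:
    """Human-readable duplex trace along the sRNA (5'->3')."""
    sym = {0.0: "|", 0.5: "o", 1.0: "x"}
    out = []
    for i in range(len(s)):
        if variant == "srna_bulge" and i == p:
            out.append("-")
            continue
        if variant == "ungapped":
            u = j + i
        elif variant == "target_bulge":
            u = j + i if i <= p - 1 else j + i + 1
        else:  # srna_bulge
            u = j + i if i < p else j + i - 1
        out.append(sym[_PEN[s[i], t[u]]])
    return "".join(out)


class EncodedTarget:
    """A target sequence pre-encoded for repeated duplex scans."""

    def __init__(self, target_id: str, seq: str):
        self.target_id = target_id
        self.seq = seq.upper().replace("U", "T")
        self.length = len(self.seq)
        self.rc = _encode(revcomp(self.seq))


def _scan(
    s_arr: np.ndarray,
    t: np.ndarray,
    max_score: float,
    allow_bulge: bool = True,
) -> list[tuple[float, int, str, int]]:
    """All duplex registrations of an encoded sRNA against an encoded
    revcomp-space target, as (score, t_offset, variant, bulge_pos) tuples."""
    L, Lt = len(s_arr), len(t)
    n_off = Lt - L + 1
    if n_off < 1:
        return []
    w = _weights(L)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    Mw = _PEN[s_arr[None, :], windows] * w[None, :]
    U = Mw.sum(axis=1)
    pre = np.concatenate([np.zeros((n_off, 1)), np.cumsum(Mw, axis=1)], axis=1)
    hits: list[tuple[float, int, str, int]] = []
    for j in np.nonzero(U <= max_score)[0]:
        hits.append((float(U[j]), int(j), "ungapped", -1))
    if not allow_bulge:
        return hits

    bw = _BULGE * w  # bulge penalty, doubled in the 2-13 core

    # one unpaired target base between sRNA positions p-1 and p (p = 1..L-1)
    if n_off >= 2:
        ps = np.arange(1, L)
        tb = pre[:-1, ps] + (U[1:, None] - pre[1:, ps]) + bw[ps][None, :]
        for j, pi in zip(*np.nonzero(tb <= max_score)):
            hits.append((float(tb[j, pi]), int(j), "target_bulge", int(ps[pi])))

    # one unpaired (bulged) sRNA base at internal position p (p = 1..L-2)
    ps = np.arange(1, L - 1)
    if n_off >= 2 and len(ps):
        sb = pre[1:, ps] + (U[:-1, None] - pre[:-1, ps + 1]) + bw[ps][None, :]
        for j0, pi in zip(*np.nonzero(sb <= max_score)):
            hits.append((float(sb[j0, pi]), int(j0 + 1), "srna_bulge", int(ps[pi])))
    # edge offsets of the sRNA-bulge variant (site consumes L-1 target bases)
    for j2 in (0, n_off):
        if j2 + L - 1 > Lt or j2 < 0:
            continue
        for p in range(1, L - 1):
            sc = 0.0
            for i in range(L):
                if i == p:
                    continue
                u = j2 + i if i < p else j2 + i - 1
                sc += _PEN[s_arr[i], t[u]] * w[i]
            sc += bw[p]
            if sc <= max_score:
                hits.append((float(sc), j2, "srna_bulge", p))
    return hits


def _cleavage_t_index(j: int, variant: str, p: int) -> int:
    """revcomp-space index of the target base paired to sRNA position 10."""
    i = 9  # 0-based sRNA index of position 10
    if variant == "ungapped":
        return j + i
    if variant == "target_bulge":
        return j + i if i <= p - 1 else j + i + 1
    # srna_bulge: position p unpaired; boundary convention when p == 9
    if i < p:
        return j + i
    if i > p:
        return j + i - 1
    return j + i


def scan_target(
    srna: str,
    target: EncodedTarget | SequenceRecord,
    max_score: float,
    orientation: str = "+",
    allow_bulge: bool = True,
) -> list[TargetAlignment]:
    """All duplexes of ``srna`` against one orientation of a target with
    score <= max_score, with coordinates on the forward target sequence."""
    enc = target if isinstance(target, EncodedTarget) else EncodedTarget(target.id, target.seq)
    s = srna.upper().replace("U", "T")
    s_arr = _encode(s)
    L, Lt = len(s_arr), enc.length
    if orientation == "+":
        t = enc.rc
    else:
        t = _encode(enc.seq)  # revcomp space of the reverse-complement target
    out = []
    for score, j, variant, p in _scan(s_arr, t, max_score, allow_bulge):
        slen = {"ungapped": L, "target_bulge": L + 1, "srna_bulge": L - 1}[variant]
        a, b = Lt - (j + slen), Lt - j  # site on the scanned orientation
        cl = Lt - 1 - _cleavage_t_index(j, variant, p)
        if orientation == "-":
            a, b = Lt - b, Lt - a
            cl = Lt - 1 - cl
        out.append(
            TargetAlignment(
                srna=s,
                target_id=enc.target_id,
                target_start=a,
                target_end=b,
                target_strand=orientation,
                score=score,
                cleavage_pos=cl,
                pairing=_pairing_string(s_arr, t, j, variant, p),
                variant=variant,
            )
        )
    out.sort(key=lambda h: (h.score, h.target_start))
    return out


def align_srna_target(srna: str, target_window: str) -> TargetAlignment | None:
    """Best duplex of an sRNA against a target window (forward orientation).

    Returns the minimal-score alignment, or None when the window is shorter
    than the sRNA.
    """
    if len(target_window) < len(srna):
        return None
    hits = scan_target(srna, EncodedTarget("window", target_window), max_score=float("inf"))
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# Triggers
# ---------------------------------------------------------------------------

@dataclass
class TriggerCandidate:
    """A candidate trigger sRNA for one PHAS locus."""

    alignment: TargetAlignment
    locus: PhasLocus
    end: str  # 5prime | 3prime
    trigger_len: int
    genomic_site: tuple[int, int]
    genomic_cleavage: int
    phase_relation: str = "out_of_phase"
    model: str = "unclassified"
    mirna_status: str = "putative"  # known | putative | siRNA
    matched_mirna: str | None = None
    degradome: str = "no_data"  # validated | unsupported | no_data


def phase_consistency(cleavage_pos: int, locus: PhasLocus) -> str:
    """in_phase iff the cleavage coordinate sits on the locus phase register."""
    return (
        "in_phase"
        if (cleavage_pos - locus.phase_offset) % locus.register_len == 0
        else "out_of_phase"
    )


def find_triggers(
    locus: PhasLocus,
    pool: list[CollapsedRead],
    reference: dict[str, str],
    cfg: RunConfig,
    known_mirnas: list[SequenceRecord] | None = None,
    degradome: dict[str, dict[int, int]] | None = None,
) -> list[TriggerCandidate]:
    """Scan the 200-nt flanks (plus the locus ends) for trigger duplexes.

    The pool is restricted to 21/22-nt reads above the RPM gate. Called
    locus boundaries sit on the window-scan grid and can overhang the true
    phased region, so the scan regions extend 150 nt into the locus from
    each boundary; both orientations are scanned because the precursor
    orientation is unknown. Alignments scoring <= trigger_score_cutoff are
    kept and annotated with flank, phase relation, miRNA status and
    degradome support.
    """
    seq = reference[locus.ref_id]
    inner = min(150, (locus.end - locus.start) // 2)
    regions = [
        (max(0, locus.start - cfg.trigger_flank), locus.start + inner),
        (locus.end - inner, min(len(seq), locus.end + cfg.trigger_flank)),
    ]
    if regions[0][1] < locus.start + inner or regions[1][0] < 0:
        log.info("locus %s at reference edge; flank truncated", locus.locus_id)
    pool = [
        r for r in pool if r.length in (21, 22) and r.rpm > cfg.min_rpm
    ]
    cands: list[TriggerCandidate] = []
    seen: set[tuple] = set()
    for lo, hi in regions:
        lo, hi = max(0, lo), min(len(seq), hi)
        if hi - lo < 21:
            continue
        enc = EncodedTarget(locus.ref_id, seq[lo:hi])
        for read in pool:
            for orient in "+-":
                for hit in scan_target(read.seq, enc, cfg.trigger_score_cutoff, orient):
                    site = (lo + hit.target_start, lo + hit.target_end)
                    key = (read.seq, site, orient)
                    if key in seen:
                        continue
                    seen.add(key)
                    cleav = lo + hit.cleavage_pos
                    cand = TriggerCandidate(
                        alignment=hit,
                        locus=locus,
                        end=(
                            "5prime"
                            if abs(cleav - locus.start) <= abs(cleav - locus.end)
                            else "3prime"
                        ),
                        trigger_len=read.length,
                        genomic_site=site,
                        genomic_cleavage=cleav,
                        phase_relation=phase_consistency(cleav, locus),
                    )
                    if known_mirnas:
                        status, match = annotate_mirna(read.seq, known_mirnas)
                        cand.mirna_status, cand.matched_mirna = status, match
                    cand.degradome = degradome_support(
                        locus.ref_id, cleav, degradome, cfg.min_degradome_reads
                    )
                    cands.append(cand)
    return cands


def _mirna_family(name: str) -> str | None:
    m = re.search(r"(miR\d+)", name, flags=re.IGNORECASE)
    return m.group(1).lower() if m else None


def load_trigger_whitelist(path: str | None = None) -> set[str]:
    """miRNA families established as phasiRNA triggers (editable text list)."""
    if path is not None:
        text = open(path).read()
    else:
        text = resources.files("phasekit.data").joinpath("known_trigger_families.txt").read_text()
    fams = set()
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if line:
            fams.add(line.lower())
    return fams


def filter_triggers(
    cands: list[TriggerCandidate],
    whitelist: set[str] | None = None,
    degradome_available: bool = False,
) -> tuple[list[TriggerCandidate], dict[str, int]]:
    """Keep in-phase candidates; out-of-phase ones survive only when they are
    known miRNAs that are whitelisted trigger families or degradome-validated."""
    wl = whitelist if whitelist is not None else load_trigger_whitelist()
    kept, dropped = [], {"out_of_phase_unknown": 0, "out_of_phase_unsupported": 0}
    for c in cands:
        if c.phase_relation == "in_phase":
            kept.append(c)
            continue
        if c.mirna_status != "known":
            dropped["out_of_phase_unknown"] += 1
            continue
        fam = _mirna_family(c.matched_mirna or "")
        if (fam and fam in wl) or c.degradome == "validated":
            kept.append(c)
        else:
            dropped["out_of_phase_unsupported"] += 1
    return kept, dropped


def _site_clusters(positions: list[int], tol: int = 2) -> int:
    """Number of distinct hit sites, collapsing alignment variants of one
    site (cleavage positions within ``tol`` nt of each other)."""
    n = 0
    prev: int | None = None
    for p in sorted(positions):
        if prev is None or p - prev > tol:
            n += 1
        prev = p
    return n


def classify_trigger_model(cands: list[TriggerCandidate]) -> str:
    """Trigger model of one locus from its retained candidates.

    Two distinct 21-nt hit sites (same or different sRNAs) indicate the
    two-hit model; a single 22-nt hit the one-hit model; a lone 21-nt hit is
    left unclassified. Sites are counted as cleavage-position clusters, so
    bulge/offset variants of one duplex do not masquerade as extra sites.
    """
    n21 = _site_clusters([c.genomic_cleavage for c in cands if c.trigger_len == 21])
    has22 = any(c.trigger_len == 22 for c in cands)
    if n21 >= 2:
        model = "two_hit"
    elif has22:
        model = "one_hit_22"
    else:
        model = "unclassified"
    for c in cands:
        c.model = model
    return model


def annotate_mirna(
    srna: str,
    known: list[SequenceRecord],
) -> tuple[str, str | None]:
    """Match an sRNA against mature miRNAs: 'known' iff some entry has the
    same length +/-1 and <=2 mismatches over the shared span."""
    srna = srna.upper().replace("U", "T")
    best: tuple[int, str] | None = None
    for entry in known or []:
        ref = entry.seq
        if abs(len(ref) - len(srna)) > 1:
            continue
        short, long_ = (srna, ref) if len(srna) <= len(ref) else (ref, srna)
        for off in range(len(long_) - len(short) + 1):
            mm = sum(1 for a, b in zip(short, long_[off : off + len(short)]) if a != b)
            if best is None or mm < best[0]:
                best = (mm, entry.id)
    if best is not None and best[0] <= 2:
        return "known", best[1]
    return "putative", None


def degradome_support(
    ref_id: str,
    cleavage_pos: int,
    degradome: dict[str, dict[int, int]] | None,
    min_reads: int = 2,
    tolerance: int = 1,
) -> str:
    """validated iff >= min_reads degradome 5' ends fall at cleavage +/-1."""
    if degradome is None:
        return "no_data"
    ends = degradome.get(ref_id, {})
    n = sum(ends.get(cleavage_pos + d, 0) for d in range(-tolerance, tolerance + 1))
    return "validated" if n >= min_reads else "unsupported"


def tally_degradome(alignments) -> dict[str, dict[int, int]]:
    """Per-reference 5'-end counts of mapped degradome reads (plus strand
    reads end at .start; minus strand 5' ends at .end - 1)."""
    out: dict[str, dict[int, int]] = {}
    for a in alignments:
        pos = a.start if a.strand == "+" else a.end - 1
        ref = out.setdefault(a.ref_id, {})
        ref[pos] = ref.get(pos, 0) + a.read.count
    return out


# ---------------------------------------------------------------------------
# Hairpin evaluation (optional ViennaRNA plugin)
# ---------------------------------------------------------------------------

def _rnafold(seq: str) -> str | None:
    exe = shutil.which("RNAfold")
    if exe is None:
        return None
    proc = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    for line in proc.stdout.splitlines():
        if line and line[0] in ".()":
            return line.split()[0]
    return None


def evaluate_hairpin(
    srna: str,
    reference: dict[str, str],
    placements,
    flank: int = 150,
) -> list[str]:
    """Fold +/-150 nt around each placement and ask whether the sRNA sits in
    one arm of a stem-loop: >=16 of its bases paired, all in one bracket
    direction, with no internal unpaired run of 4+ inside the sRNA region.

    Returns one verdict per placement: plausible_mirna, not_hairpin, or
    no_engine when no folding engine is installed.
    """
    if shutil.which("RNAfold") is None:
        return ["no_engine"] * len(list(placements))
    verdicts = []
    for a in placements:
        seq = reference[a.ref_id]
        lo, hi = max(0, a.start - flank), min(len(seq), a.end + flank)
        context = seq[lo:hi]
        if a.strand == "-":
            context = revcomp(context)
            s_lo = (hi - lo) - (a.end - lo)
        else:
            s_lo = a.start - lo
        struct = _rnafold(context)
        region = struct[s_lo : s_lo + a.length] if struct else ""
        paired = sum(1 for c in region if c in "()")
        one_arm = not ("(" in region and ")" in region)
        runs = re.findall(r"\.{4,}", region)
        if paired >= 16 and one_arm and len(runs) <= 1:
            verdicts.append("plausible_mirna")
        else:
            verdicts.append("not_hairpin")
    return verdicts


# ---------------------------------------------------------------------------
# phasiRNA targets
# ---------------------------------------------------------------------------

@dataclass
class TargetPrediction:
    """A predicted phasiRNA target transcript."""

    phasirna: str
    origin_id: str | None
    target_id: str
    target_strand: str
    score: float
    stringent: bool
    relation: str  # cis | same_family | trans
    cleavage_pos: int
    alignment: TargetAlignment = field(repr=False, default=None)


def classify_target(
    target_id: str,
    origin_id: str | None,
    families: dict[str, str] | None = None,
) -> str:
    """cis when the target is the originating transcript, same_family for a
    paralog (shared family-map entry), trans otherwise."""
    if origin_id is not None and target_id == origin_id:
        return "cis"
    fam = families or {}
    if (
        origin_id is not None
        and fam.get(target_id, f"__{target_id}") == fam.get(origin_id, f"__{origin_id}")
    ):
        return "same_family"
    return "trans"


def phasirna_pool(
    loci: list[PhasLocus],
    min_rpm: float = 10.0,
    origins: dict[str, str] | None = None,
) -> list[tuple[CollapsedRead, str | None]]:
    """Abundant register-length reads of positive loci, with their origin id
    (the locus gene id, or the locus id for intergenic loci)."""
    out, seen = [], set()
    for loc in loci:
        origin = loc.gene_id or (origins or {}).get(loc.locus_id or "", loc.locus_id)
        for aln in loc.member_reads.values():
            if aln.read.rpm >= min_rpm and aln.read.seq not in seen:
                seen.add(aln.read.seq)
                out.append((aln.read, origin))
    return out


def predict_targets(
    phasirnas: list[tuple[CollapsedRead, str | None]],
    transcriptome: list[SequenceRecord],
    cfg: RunConfig,
    families: dict[str, str] | None = None,
) -> list[TargetPrediction]:
    """Report every transcriptome duplex of an abundant phasiRNA with score
    <= target_score_cutoff; hits at or below the stringent cutoff are
    flagged. Both transcript orientations are scanned (phasiRNAs derive from
    both strands of the dsRNA precursor)."""
    encoded = [(EncodedTarget(t.id, t.seq)) for t in transcriptome]
    preds: list[TargetPrediction] = []
    for read, origin in phasirnas:
        if read.rpm < cfg.min_rpm:
            continue
        for enc in encoded:
            for orient in "+-":
                for hit in scan_target(read.seq, enc, cfg.target_score_cutoff, orient):
                    preds.append(
                        TargetPrediction(
                            phasirna=read.seq,
                            origin_id=origin,
                            target_id=enc.target_id,
                            target_strand=orient,
                            score=hit.score,
                            stringent=hit.score <= cfg.stringent_target_cutoff,
                            relation=classify_target(enc.target_id, origin, families),
                            cleavage_pos=hit.cleavage_pos,
                            alignment=hit,
                        )
                    )
    preds.sort(key=lambda p: (p.phasirna, p.score))
    return preds
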