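"""Splice-boundary resolution, exon stitching and genomic-context calls.

The 3' splice site is closely determined by the D5/D6 structural hit (the
built-in detector already extends it through the D6 helix to the terminal
residue); the 5' splice site is placed at a conserved GWYRG motif in the
upstream vicinity of the 5' structural hit. Stitching the flanking exons
back together reconstructs the host gene product, which can be validated
against user-provided intronless homolog proteins; the surrounding reading
frames and a rho-independent-terminator heuristic then classify the
genomic context of each candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from .candidate_scan import GWYRG_RE, MIN_LOOP, ScanConfig, ladder
from .core_io import GenomeRecord, Interval
from .hit_pairing import IntronCandidate

STOP_CODONS = {"TAA", "TAG", "TGA"}
CONTEXT_CLASSES = ("intragenic", "intergenic", "pseudogene", "truncated", "post_terminator")


@dataclass
class BoundaryCall:
    """Resolved intron extent on the genome (0-based half-open).

    start/end are genome coordinates of the intron's 5'/3' splice sites in
    plus-strand order; method_5/method_3 record how each end was resolved
    (gwyrg_motif, homolog_alignment, model_hit_end) or None if unresolved.
    """

    start: int | None
    end: int | None
    strand: str = "+"
    method_5: str | None = None
    method_3: str | None = None

    @property
    def confidence(self) -> str:
        n = (self.start is not None) + (self.end is not None)
        return {2: "exact", 1: "approximate", 0: "unresolved"}[n]

    @property
    def resolved(self) -> bool:
        return self.start is not None and self.end is not None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and not self.start < self.end:
            raise ValueError("boundary start must precede end")


def refine_boundaries(
    candidate: IntronCandidate, genome: GenomeRecord, cfg: ScanConfig | None = None
) -> BoundaryCall:
    """Resolve the candidate's splice boundaries from its hits.

    3' end = 3' extent of the D5/D6 hit (through the D6 helix). 5' end =
    the GWYRG occurrence nearest the 5' hit start within gwyrg_window.
    Unresolved ends stay None; they are flagged, never guessed.
    """
    cfg = cfg or ScanConfig()
    if not candidate.all_hits():
        raise ValueError(f"{candidate.candidate_id}: no hits to refine")
    strand = candidate.span.strand
    five = three = None
    m5 = m3 = None
    if candidate.d5d6_hit is not None:
        three = (
            candidate.d5d6_hit.interval.end
            if strand == "+"
            else candidate.d5d6_hit.interval.start
        )
        m3 = "model_hit_end"
    if candidate.d1d4_hits:
        # 5'-most D1-D4 hit in transcript orientation
        if strand == "+":
            anchor = min(h.interval.start for h in candidate.d1d4_hits)
            lo = max(0, anchor - cfg.gwyrg_window)
            hi = min(len(genome.seq) - 5, anchor + 10)
            best = None
            for m in GWYRG_RE.finditer(genome.seq, lo, hi + 5):
                pos = m.start()
                if best is None or abs(pos - anchor) < abs(best - anchor):
                    best = pos
            if best is not None:
                five, m5 = best, "gwyrg_motif"
        else:
            from .core_io import revcomp

            anchor = max(h.interval.end for h in candidate.d1d4_hits)
            lo = max(0, anchor - 10 - 5)
            hi = min(len(genome.seq), anchor + cfg.gwyrg_window)
            region = revcomp(genome.seq[lo:hi])
            best = None
            for m in GWYRG_RE.finditer(region):
                pos = hi - m.start()  # genome coordinate of motif end
                if best is None or abs(pos - anchor) < abs(best - anchor):
                    best = pos
            if best is not None:
                five, m5 = best, "gwyrg_motif"
    if strand == "+":
        return BoundaryCall(five, three, strand, m5, m3)
    return BoundaryCall(three, five, strand, m5, m3)


def stitch_exons(genome: GenomeRecord, boundary: BoundaryCall, orf_bounds: Interval) -> str:
    """Concatenate the flanking exons and translate in the host-ORF frame.

    orf_bounds is the host gene extent in with-intron genome coordinates
    (spanning the intron). A stitched length not divisible by 3 raises a
    frame-shift warning and falls back to the in-frame prefix. The trailing
    stop is removed.
    """
    if not boundary.resolved:
        raise ValueError("boundaries must be resolved before stitching")
    s, e = boundary.start, boundary.end
    if not (orf_bounds.start <= s and e <= orf_bounds.end):
        raise ValueError("host ORF does not span the intron")
    dna = genome.seq[orf_bounds.start : s] + genome.seq[e : orf_bounds.end]
    if len(dna) % 3 != 0:
        warnings.warn(
            f"stitched exons not in frame (len {len(dna)}); possible "
            "boundary frame shift",
            stacklevel=2,
        )
        dna = dna[: len(dna) - len(dna) % 3]
    prot = str(Seq(dna).translate())
    return prot[:-1] if prot.endswith("*") else prot


def polish_three_prime(
    boundary: BoundaryCall, genome: GenomeRecord, max_shift: int = 3
) -> BoundaryCall:
    """Nudge the 3' boundary (<= max_shift nt) to restore a spanning frame.

    The structural 3' call can slip a nucleotide or two past the D6 helix
    when exon bases happen to extend the terminal stem. Exon stitching
    exposes this: if no stop-free reading frame spans the junction as
    called but a small 3' shift produces one, the shifted boundary is taken
    (method homolog_alignment — the stitched host-gene evidence path).
    Intergenic candidates are unaffected: no shift creates a frame there.
    """
    if not boundary.resolved:
        return boundary
    s, e = boundary.start, boundary.end
    # 3' end in plus-order coordinates is `end` on +, `start` on -
    minus = boundary.strand == "-"
    if _stop_free_frame(_stitched(genome, s, e), s) is not None:
        return boundary
    for d in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
        if d == 0:
            continue
        ns, ne = (s + d, e) if minus else (s, e + d)
        if not (0 <= ns < ne <= len(genome.seq)):
            continue
        if _stop_free_frame(_stitched(genome, ns, ne), ns) is not None:
            return BoundaryCall(ns, ne, boundary.strand, boundary.method_5, "homolog_alignment")
    return boundary


# --- global affine protein alignment --------------------------------------


@dataclass
class ProteinAlignment:
    score: float
    identities: int
    pid: float  # 100 * identities / min(len a, len b)
    aligned_a: str
    aligned_b: str


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def align_proteins(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> ProteinAlignment:
    """Global affine-gap alignment; a gap of length L costs
    gap_open + (L-1)*gap_extend. Percent identity uses the shorter of the
    two unaligned sequence lengths as denominator."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    al = _aligner(match, mismatch, gap_open, gap_extend)
    best = al.align(a, b)[0]
    ident = 0
    for (xa, ya), (xb, yb) in zip(*best.aligned):
        for i, j in zip(range(xa, ya), range(xb, yb)):
            if a[i] == b[j]:
                ident += 1
    pid = 100.0 * ident / min(len(a), len(b))
    return ProteinAlignment(
        score=float(best.score),
        identities=ident,
        pid=pid,
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
    )


def percent_identity(a: str, b: str, **kwargs) -> float:
    """Pairwise percent identity with shorter-sequence denominator."""
    return align_proteins(a, b, **kwargs).pid


# --- rho-independent terminator -------------------------------------------


def detect_terminator(
    window: str,
    stem_min: int = 6,
    loop_range: tuple[int, int] = (3, 8),
    u_run_gap: int = 8,
    u_min: int = 4,
) -> tuple[bool, Interval | None]:
    """Detect a rho-independent-terminator signature in a sequence window.

    Fires iff a hairpin with >= stem_min pairs and a loop in loop_range is
    followed within u_run_gap nt by a 6-nt window containing >= u_min T.
    Returns (fired, hairpin interval) for the 5'-most qualifying hairpin.
    """
    n = len(window)
    if n > 300:
        raise ValueError("terminator window too long (> 300)")
    lo, hi = loop_range
    for a in range(0, n - (2 * stem_min + lo)):
        for span in range(2 * stem_min + lo, min(2 * 12 + hi, n - a) + 1):
            b = a + span - 1
            run = ladder(window, a, b)
            loop = (b - run) - (a + run) + 1
            if run >= stem_min and lo <= loop <= hi:
                end = b + 1
                tail = window[end : end + u_run_gap + 6]
                for off in range(0, min(u_run_gap, max(0, len(tail) - 5)) + 1):
                    if tail[off : off + 6].count("T") >= u_min:
                        return True, Interval(a, end)
    return False, None


# --- context classification ------------------------------------------------


def _frame_stops(seq: str, lo: int, hi: int, frame: int) -> list[int]:
    start = lo + ((frame - lo) % 3)
    return [c for c in range(start, hi - 2, 3) if seq[c : c + 3] in STOP_CODONS]


def _stitched(genome: GenomeRecord, s: int, e: int) -> str:
    return genome.seq[:s] + genome.seq[e:]


def _stop_free_frame(st: str, j: int, half: int = 150) -> int | None:
    """A reading frame with no stop within +-half nt of the junction."""
    lo = max(0, j - half)
    hi = min(len(st), j + half)
    if j - lo < 60 or hi - j < 60:
        return None
    for f in range(3):
        if not _frame_stops(st, lo, hi, f):
            return f
    return None


def _segment_protein(st: str, j: int, frame: int, reach: int = 2000) -> str:
    """Translate the maximal stop-free in-frame segment around the junction."""
    lo = max(0, j - reach)
    hi = min(len(st), j + reach)
    stops = _frame_stops(st, lo, hi, frame)
    left = max([c + 3 for c in stops if c < j - 2], default=lo + ((frame - lo) % 3))
    right = min([c for c in stops if c >= j - 2], default=hi)
    dna = st[left:right]
    dna = dna[: len(dna) - len(dna) % 3]
    return str(Seq(dna).translate()) if dna else ""


def _pseudogene_frame(st: str, j: int) -> bool:
    """A decayed-gene signature: an ATG-initiated in-frame stretch spanning
    the junction with a small number (2-4) of internal stops — far fewer
    than random sequence would show over the same extent — falling on both
    sides of the junction."""
    for f in range(3):
        lo = max(0, j - 650)
        start = lo + ((f - lo) % 3)
        for a in range(start, max(start, j - 250), 3):
            if st[a : a + 3] != "ATG" or a + 850 > len(st):
                continue
            stops = _frame_stops(st, a, a + 850, f)
            up = [c for c in stops if c < j - 2]
            dn = [c for c in stops if c >= j - 2]
            if 2 <= len(stops) <= 4 and up and dn:
                return True
    return False


@dataclass
class ContextCall:
    context: str
    homolog_pid: float | None = None
    homolog_id: str | None = None
    frame: int | None = None
    stitched_protein: str | None = None


def classify_context(
    candidate: IntronCandidate,
    boundary: BoundaryCall,
    genome: GenomeRecord,
    homologs: dict[str, str] | None = None,
    host_annotations: list | None = None,
    min_homolog_pid: float = 30.0,
    min_stitched_aa: int = 120,
    terminator_window: int = 200,
) -> ContextCall:
    """Assign exactly one genomic-context class to a candidate.

    Decision cascade: truncated (intron interval touches a contig end),
    intragenic (a stop-free reading frame spans the stitched junction, and
    when homolog proteins are supplied the stitched product aligns to one
    at >= min_homolog_pid), post_terminator (terminator signature within
    terminator_window nt 5' of the intron and no spanning frame),
    pseudogene (an ATG-initiated decayed frame with 2-4 internal stops
    spans the junction), else intergenic. The terminator signature (stem +
    U-run) is far more specific than the decayed-frame heuristic, so it is
    tested first.
    """
    n = len(genome.seq)
    s = boundary.start if boundary.start is not None else candidate.span.start
    e = boundary.end if boundary.end is not None else candidate.span.end
    if s <= 2 or e >= n - 2:
        return ContextCall("truncated")

    st = _stitched(genome, s, e)
    j = s
    frame = None
    if host_annotations:
        for feat in host_annotations:
            iv = feat.interval if hasattr(feat, "interval") else feat
            if iv.start <= s and e <= iv.end:
                frame = iv.start % 3
                break
    if frame is None:
        frame = _stop_free_frame(st, j)
    if frame is not None:
        if homologs:
            prot = _segment_protein(st, j, frame)
            # chance stop-free junction frames expand to short segments;
            # a real stitched host gene is much longer
            best_id, best_pid = None, 0.0
            for hid, hseq in homologs.items():
                if len(prot) < min_stitched_aa or not hseq:
                    continue
                pid = percent_identity(prot, hseq)
                if pid > best_pid:
                    best_id, best_pid = hid, pid
            if best_pid >= min_homolog_pid:
                return ContextCall(
                    "intragenic",
                    homolog_pid=best_pid,
                    homolog_id=best_id,
                    frame=frame,
                    stitched_protein=prot,
                )
        else:
            return ContextCall("intragenic", frame=frame)
    fired, _hp = detect_terminator(genome.seq[max(0, s - terminator_window) : s])
    if fired:
        return ContextCall("post_terminator")
    if _pseudogene_frame(st, j):
        return ContextCall("pseudogene")
    return ContextCall("intergenic")
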