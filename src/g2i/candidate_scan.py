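"""Structure-anchored detection of candidate group II intron hits.

Two detection paths exist: ingestion of external covariance-model hit tables
(core_io.parse_cmsearch_tblout) and the built-in lightweight detector in this
module. The built-in detector is a deliberately simplified stand-in for
profile-SCFG search: it anchors on the catalytic-triad-bearing D5 hairpin and
the branch-point-bearing D6 helix (the most conserved part of the group II
consensus), then anchors 5' candidates on the conserved GWYRG terminus motif
backed by a foldable D1 proxy helix. Its contract is calibrated on synthetic
data, not on reproducing Rfam model coordinates.

All stem searches use contiguous base-pair ladders (canonical AT/TA/GC/CG
plus GU/UG wobble on the transcribed sense, i.e. GT/TG on DNA), searched
directly rather than extracted from a global maximum-pairing fold: global
Nussinov-style folds are heavily tie-degenerate, and the anchored ladder is
the deterministic restriction of maximum pairing to helices anchored at the
motif of interest. fold_max_pairs below provides the exact global
maximum-pairing fold where one is genuinely needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core_io import GenomeRecord, Interval, ModelHit, revcomp

_PAIRS = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
}
_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

#: lookahead form so overlapping motif occurrences are all reported
GWYRG_RE = re.compile(r"(?=(G[AT][CT][AG]G))")
MIN_LOOP = 3  # minimum hairpin loop length in every fold/ladder


def pairs_ok(a: str, b: str, wobble: bool = True) -> bool:
    """True if bases a and b can pair. N never participates in a pair."""
    return (a, b) in (_PAIRS if wobble else _CANONICAL)


@dataclass
class ScanConfig:
    """Tunable parameters of the built-in detector.

    Defaults encode the consensus constraints: AGC/CGC catalytic triad at the
    D5 stem start, a D5 stem of >=9 pairs closing a 3-10 nt loop, a single
    bulged (branch-point) adenosine in the D6 helix 5-12 nt from its 3' base,
    and a GWYRG 5' terminus motif.
    """

    evalue_max: float = 0.01
    d5_stem_min: int = 9
    d5_loop_range: tuple[int, int] = (3, 10)
    triads: tuple[str, ...] = ("AGC", "CGC")
    branch_window: tuple[int, int] = (5, 12)
    gwyrg_window: int = 100
    min_score: float = 0.0
    d5_scan_window: int = 60  # window downstream of a triad match
    d6_stem_min: int = 6
    d6_gap_max: int = 12  # max linker between D5 hairpin end and D6 start
    d6_loop_max: int = 10
    five_prime_span: int = 3300  # how far upstream of D5/D6 to look for GWYRG
    d1_helix_min: int = 10  # contiguous canonical pairs for the D1 proxy
    d1_anchor_max: int = 20  # D1 helix must start within this of the motif
    d1_window: int = 200  # D1 proxy search span downstream of the motif
    triad_bonus: dict = field(default_factory=lambda: {"AGC": 3.0, "CGC": 2.0})

    def __post_init__(self) -> None:
        if not self.triads:
            raise ValueError("triads must be non-empty")
        for name, val in (
            ("d5_scan_window", self.d5_scan_window),
            ("gwyrg_window", self.gwyrg_window),
            ("d1_window", self.d1_window),
            ("five_prime_span", self.five_prime_span),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")


# --- exact maximum-pairing fold ------------------------------------------


def fold_max_pairs(window: str, wobble: bool = True) -> tuple[int, str]:
    """Maximum number of nested base pairs in `window`, with the structure.

    Exact O(n^3) dynamic programming (maximum pairing with minimum hairpin
    loop 3). Returns (pair count, dot-bracket string). Traceback is
    deterministic: at each position the 5'-most base pairs with its smallest
    admissible optimal partner, else is left unpaired.
    """
    n = len(window)
    if n > 200:
        raise ValueError(f"window too long for exact fold ({n} > 200)")
    if n == 0:
        return 0, ""
    s = window.upper()
    # M[i][j] = max pairs in s[i..j]
    M = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]
            row_i1 = M[i + 1]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if pairs_ok(s[i], s[k], wobble):
                    val = 1 + (row_i1[k - 1] if k - 1 >= i + 1 else 0) + (
                        M[k + 1][j] if k + 1 <= j else 0
                    )
                    if val > best:
                        best = val
            M[i][j] = best
    struct = ["."] * n

    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j - MIN_LOOP + 1 or j < 0 or i >= n:
            continue
        target = M[i][j]
        if target == 0:
            continue
        paired = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            if pairs_ok(s[i], s[k], wobble):
                inner = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                right = M[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == target:
                    struct[i], struct[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return M[0][n - 1], "".join(struct)


# --- ladder primitives ----------------------------------------------------


def ladder(s: str, i: int, j: int, wobble: bool = True) -> int:
    """Length of the contiguous pair ladder (i,j),(i+1,j-1),... respecting
    the minimum hairpin loop."""
    run = 0
    while i < j - MIN_LOOP and pairs_ok(s[i], s[j], wobble):
        run += 1
        i += 1
        j -= 1
    return run


def best_anchored_hairpin(
    s: str, t: int, stem_min: int, loop_range: tuple[int, int], window: int
) -> tuple[int, int, int] | None:
    """Best hairpin whose 5' stem arm starts exactly at t.

    Returns (run, close_j, loop_len) maximizing run (ties: smallest close_j),
    subject to run >= stem_min and loop within loop_range, or None.
    """
    lo, hi = loop_range
    best = None
    jmax = min(len(s) - 1, t + window - 1)
    for j in range(t + 2 * stem_min + lo - 1, jmax + 1):
        run = ladder(s, t, j)
        loop = (j - run) - (t + run) + 1
        if run >= stem_min and lo <= loop <= hi:
            if best is None or run > best[0]:
                best = (run, j, loop)
    return best


def bulged_a_helix(
    s: str,
    p_lo: int,
    p_hi: int,
    limit: int,
    stem_min: int,
    branch_window: tuple[int, int],
    loop_max: int,
) -> tuple[int, int, int, int] | None:
    """Search [p_lo, p_hi] for a helix with exactly one unpaired A bulged on
    its 3' side (the branch-point adenosine in D6).

    Returns (p, q, pairs, branch_pos) for the best-scoring helix (most pairs,
    ties 5'-most), or None. The bulged A must sit branch_window nucleotides
    from the helix 3' base and have at least one pair on each side.
    """
    b_lo, b_hi = branch_window
    best = None
    for p in range(p_lo, min(p_hi, limit - 1) + 1):
        qmax = min(limit - 1, p + 2 * stem_min + MIN_LOOP + 12)
        for q in range(p + 2 * stem_min + MIN_LOOP, qmax + 1):
            i, j = p, q
            pairs = 0
            bulge = None
            after = 0
            while i < j - MIN_LOOP:
                if pairs_ok(s[i], s[j]):
                    pairs += 1
                    if bulge is not None:
                        after += 1
                    i += 1
                    j -= 1
                elif bulge is None and s[j] == "A" and pairs > 0:
                    bulge = j
                    j -= 1
                else:
                    break
            loop = j - i + 1
            if (
                bulge is not None
                and after >= 1
                and pairs >= stem_min
                and loop <= loop_max
                and b_lo <= q - bulge <= b_hi
            ):
                if best is None or pairs > best[2]:
                    best = (p, q, pairs, bulge)
    return best


# --- D5/D6 detector -------------------------------------------------------


def _scan_d56_one_strand(seq: str, cfg: ScanConfig) -> list[dict]:
    """Detect D5/D6 signatures on one strand; coordinates are strand-local."""
    out = []
    n = len(seq)
    triad_re = re.compile("|".join(cfg.triads))
    pos = 0
    while True:
        m = triad_re.search(seq, pos)
        if m is None:
            break
        t = m.start()
        pos = t + 1
        hp = best_anchored_hairpin(
            seq, t, cfg.d5_stem_min, cfg.d5_loop_range, cfg.d5_scan_window
        )
        if hp is None:
            continue
        run, close_j, _loop = hp
        limit = min(n, t + cfg.d5_scan_window + 30)
        d6 = bulged_a_helix(
            seq,
            close_j + 1,
            close_j + 1 + cfg.d6_gap_max,
            limit,
            cfg.d6_stem_min,
            cfg.branch_window,
            cfg.d6_loop_max,
        )
        if d6 is None:
            continue
        p, q, d6_pairs, branch = d6
        score = run + d6_pairs + cfg.triad_bonus.get(m.group(), 0.0)
        if score < cfg.min_score:
            continue
        out.append(
            {
                "start": t,
                "end": q + 1,
                "score": score,
                "triad": m.group(),
                "d5_end_off": close_j - t,
                "d6_start_off": p - t,
                "branch_off": branch - t,
            }
        )
    return out


def resolve_overlaps(hits: list[ModelHit]) -> list[ModelHit]:
    """Among overlapping hits keep the best: higher score, then + strand,
    then 5'-most. Strand is ranked before position because the reverse
    complement of a D5 hairpin is itself a triad-opened hairpin, so a real
    hit can be shadowed by its own minus-strand mirror at equal score; the
    mirror lacks the bulged-A asymmetry only in its D6 evidence."""
    ranked = sorted(
        hits, key=lambda h: (-h.score, 0 if h.interval.strand == "+" else 1, h.interval.start)
    )
    kept: list[ModelHit] = []
    for h in ranked:
        if not any(
            h.genome_id == k.genome_id and h.interval.overlaps(k.interval) for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return kept


def scan_d56(genome: GenomeRecord, cfg: ScanConfig | None = None) -> list[ModelHit]:
    """Scan both strands of a genome for D5/D6 signatures.

    A hit requires a triad occurrence, a hairpin anchored at the triad with
    >= d5_stem_min pairs closing a loop in d5_loop_range, and a downstream
    helix carrying a single bulged A within branch_window of its 3' base.
    Hit score = paired-base count + triad bonus. Overlapping hits are
    resolved to the best-scoring one.
    """
    cfg = cfg or ScanConfig()
    n = len(genome.seq)
    hits: list[ModelHit] = []
    if n < 60:
        return hits
    for strand, seq in (("+", genome.seq), ("-", revcomp(genome.seq))):
        for raw in _scan_d56_one_strand(seq, cfg):
            if strand == "+":
                iv = Interval(raw["start"], raw["end"], "+")
            else:
                iv = Interval(n - raw["end"], n - raw["start"], "-")
            hits.append(
                ModelHit(
                    genome_id=genome.id,
                    model="builtin-D5D6",
                    model_class="D5D6",
                    interval=iv,
                    score=raw["score"],
                    evalue=0.0,
                    detail={
                        "triad": raw["triad"],
                        "d5_end_off": raw["d5_end_off"],
                        "d6_start_off": raw["d6_start_off"],
                        "branch_off": raw["branch_off"],
                    },
                )
            )
    return resolve_overlaps(hits)


# --- 5' (GWYRG / D1) detector ---------------------------------------------


def _d1_proxy_score(seq: str, m: int, cfg: ScanConfig) -> tuple[float, int] | None:
    """Best contiguous canonical helix ladder whose 5' arm starts within
    d1_anchor_max of the motif at m and closes within d1_window.

    Returns (ladder length, ladder close position) or None below threshold.
    """
    best_run, best_close, best_anchor = 0, m, m
    hi = min(len(seq) - 1, m + cfg.d1_window)
    for a in range(m, min(m + cfg.d1_anchor_max, hi) + 1):
        for b in range(hi, a + 2 * cfg.d1_helix_min + MIN_LOOP - 1, -1):
            if not pairs_ok(seq[a], seq[b], wobble=False):
                continue
            run = 0
            i, j = a, b
            while i < j - MIN_LOOP and pairs_ok(seq[i], seq[j], wobble=False):
                run += 1
                i += 1
                j -= 1
            if run > best_run:
                best_run, best_close, best_anchor = run, b, a
    if best_run >= cfg.d1_helix_min:
        return float(best_run), best_close
    return None


def scan_5prime(
    genome: GenomeRecord, d56_hits: list[ModelHit], cfg: ScanConfig | None = None
) -> list[ModelHit]:
    """Find candidate 5' intron termini upstream of D5/D6 hits.

    For each D5/D6 hit the region from five_prime_span upstream (in
    transcriptional orientation) to the hit start is searched for GWYRG
    motifs whose downstream context contains a foldable D1 proxy helix; one
    hit is emitted per retained motif, starting exactly at the motif.
    """
    cfg = cfg or ScanConfig()
    n = len(genome.seq)
    out: list[ModelHit] = []
    seen: set[tuple[int, str]] = set()
    for d56 in d56_hits:
        if d56.genome_id != genome.id:
            raise ValueError(
                f"hit genome {d56.genome_id!r} does not match {genome.id!r}"
            )
        if d56.model_class != "D5D6":
            continue
        strand = d56.interval.strand
        if strand == "+":
            lo = max(0, d56.interval.start - cfg.five_prime_span)
            region = genome.seq[lo : d56.interval.start]
            offset = lo
        else:
            hi = min(n, d56.interval.end + cfg.five_prime_span)
            region = revcomp(genome.seq[d56.interval.end : hi])
            offset = hi  # strand-local position p maps to offset-1-p
        for m in GWYRG_RE.finditer(region):
            proxy = _d1_proxy_score(region, m.start(), cfg)
            if proxy is None:
                continue
            score, close = proxy
            if strand == "+":
                iv = Interval(offset + m.start(), offset + close + 1, "+")
            else:
                iv = Interval(offset - close - 1, offset - m.start(), "-")
            key = (iv.start, strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ModelHit(
                    genome_id=genome.id,
                    model="builtin-D1D4",
                    model_class="D1D4",
                    interval=iv,
                    score=score,
                    evalue=0.0,
                )
            )
    out.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return out


def scan_genome(genome: GenomeRecord, cfg: ScanConfig | None = None) -> list[ModelHit]:
    """Run the full built-in detector (D5/D6 then anchored 5' search)."""
    cfg = cfg or ScanConfig()
    d56 = scan_d56(genome, cfg)
    d14 = scan_5prime(genome, d56, cfg)
    return sorted(d14 + d56, key=lambda h: (h.interval.start, h.model_class))
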