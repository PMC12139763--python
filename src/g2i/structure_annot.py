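"""EBS/IBS pseudoknots, tertiary interactions and subtype classification.

Exon recognition in group II introns runs through base-pairing between exon
binding sites (EBS1/EBS2) in D1 loops and intron binding sites (IBS1/IBS2)
at the 3' end of the 5' exon: IBS1 is the last 6 nt of the exon, IBS2 the
few nt immediately 5' of it (the EBS2:IBS2 duplex can be as short as 4 bp).
A further set of named pseudoknot and tertiary pairings (alpha..zeta)
connects the domains; here they are approximated as antiparallel
complementarity searches (GU allowed) between domain-anchored windows read
from a bundled, user-editable table. Subtype (IIA/IIB/IIC) is read from the
unpaired feature of the lambda/epsilon' region: an 11-nt loop with AGC for
IIA, a 4-nt bulge matching AARC for IIB, a 7-12-nt loop with AGG for IIC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .candidate_scan import MIN_LOOP, best_anchored_hairpin, ladder, pairs_ok
from .core_io import Interval
from .domains import DomainMap

INTERACTION_NAMES = (
    "EBS1:IBS1", "EBS2:IBS2", "alpha", "beta", "gamma", "delta", "epsilon",
    "lambda", "kappa", "zeta",
)

_AARC = re.compile("AA[AG]C")


@dataclass
class Interaction:
    name: str
    intron_interval: Interval
    partner_interval: Interval
    pairing: str  # one char per pair: '|' canonical, ':' GU wobble
    n_pairs: int
    partner_in_exon: bool = False

    def __post_init__(self) -> None:
        if self.n_pairs != len(self.pairing):
            raise ValueError("pairing string length must equal n_pairs")
        if not self.partner_in_exon and self.intron_interval.overlaps(
            self.partner_interval
        ):
            raise ValueError(f"{self.name}: interaction intervals overlap")


@dataclass
class SubtypeCall:
    subtype: str  # IIA | IIB | IIC | unclassified
    lambda_eps_region: Interval | None
    feature_kind: str  # loop | bulge | none
    feature_len: int
    feature_seq: str
    consensus_matched: bool
    db_support: str | None = None


# --- duplex search --------------------------------------------------------


def _pair_char(a: str, b: str) -> str:
    return ":" if (a, b) in (("G", "T"), ("T", "G")) else "|"


def _best_duplex(
    seq: str, w1: tuple[int, int], w2: tuple[int, int]
) -> tuple[int, int, int, str] | None:
    """Longest contiguous antiparallel duplex between two windows.

    Returns (start1, end2_exclusive_partner_start, run, pairing) as
    (a, b, run, pairing) where positions a..a+run-1 pair with b..b-run+1.
    Deterministic: best run, then 5'-most a, then 3'-most b.
    """
    lo1, hi1 = w1
    lo2, hi2 = w2
    best: tuple[int, int, int, str] | None = None
    for a in range(lo1, hi1):
        for b in range(hi2 - 1, lo2 - 1, -1):
            run = 0
            chars = []
            while (
                a + run < hi1
                and b - run >= lo2
                and abs((b - run) - (a + run)) > MIN_LOOP
                and pairs_ok(seq[a + run], seq[b - run])
            ):
                chars.append(_pair_char(seq[a + run], seq[b - run]))
                run += 1
            if best is None or run > best[2]:
                best = (a, b, run, "".join(chars))
    return best


def _clip(lo: int, hi: int, n: int) -> tuple[int, int] | None:
    lo, hi = max(0, lo), min(n, hi)
    return (lo, hi) if lo < hi else None


# --- EBS/IBS ---------------------------------------------------------------


def find_ebs_ibs(
    intron_seq: str,
    five_prime_exon: str,
    domain_map: DomainMap,
    min_ebs1: int = 5,
    min_ebs2: int = 4,
    ibs2_len: int = 5,
) -> tuple[list[Interaction], list[str]]:
    """Locate EBS1:IBS1 and EBS2:IBS2 duplexes.

    IBS1 is the last 6 nt of the 5' exon; IBS2 the ibs2_len nt immediately
    5' of IBS1. EBS candidates are searched as reverse-complement duplexes
    (GU allowed) within the D1 loop regions of the domain map (the whole D1
    when loops are not resolved). Returns (found, skipped_or_absent names).
    """
    found: list[Interaction] = []
    missing: list[str] = []
    n = len(intron_seq)
    loops = domain_map.d1_loops or ([domain_map.d1] if domain_map.d1 else [])
    if not loops:
        return [], ["EBS1:IBS1", "EBS2:IBS2"]
    specs = [("EBS1:IBS1", 6, 0, min_ebs1)]
    if len(five_prime_exon) < 20:
        missing.append("EBS2:IBS2:skipped_short_exon")
    else:
        specs.append(("EBS2:IBS2", ibs2_len, 6, min_ebs2))
    for name, blen, off_from_end, min_pairs in specs:
        ibs_hi = len(five_prime_exon) - off_from_end
        ibs_lo = ibs_hi - blen
        if ibs_lo < 0:
            missing.append(name)
            continue
        ibs = five_prime_exon[ibs_lo:ibs_hi]
        best = None
        for loop in loops:
            w = _clip(loop.start, loop.end, n)
            if w is None:
                continue
            # duplex between intron loop window and the IBS block: pair
            # intron position a+k with IBS position (blen-1-k)
            for a in range(w[0], w[1]):
                run = 0
                chars = []
                while (
                    a + run < w[1]
                    and run < blen
                    and pairs_ok(intron_seq[a + run], ibs[blen - 1 - run])
                ):
                    chars.append(_pair_char(intron_seq[a + run], ibs[blen - 1 - run]))
                    run += 1
                if best is None or run > best[2]:
                    best = (a, ibs_hi - run, run, "".join(chars))
        if best is not None and best[2] >= min_pairs:
            a, pstart, run, chars = best
            found.append(
                Interaction(
                    name=name,
                    intron_interval=Interval(a, a + run),
                    partner_interval=Interval(ibs_hi - run, ibs_hi),
                    pairing=chars,
                    n_pairs=run,
                    partner_in_exon=True,
                )
            )
        else:
            missing.append(name)
    return found, missing


# --- tertiary interactions --------------------------------------------------


def load_window_table(path: str | Path | None = None) -> list[dict]:
    """Load the tertiary-interaction window table (bundled by default)."""
    if path is None:
        text = (resources.files("g2i") / "data/tertiary_windows.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        for k in ("lo1", "hi1", "lo2", "hi2", "min_pairs"):
            row[k] = int(row[k])
        rows.append(row)
    return rows


def find_tertiary(
    intron_seq: str,
    domain_map: DomainMap,
    window_table: list[dict] | None = None,
) -> tuple[list[Interaction], list[str], list[str]]:
    """Search the domain-anchored window pairs for tertiary duplexes.

    Returns (found, absent, skipped): absent means the windows resolved but
    no duplex reached the minimum length; skipped means an anchoring domain
    is unresolved in the map. Interactions are never fabricated.
    """
    table = window_table if window_table is not None else load_window_table()
    n = len(intron_seq)
    found: list[Interaction] = []
    absent: list[str] = []
    skipped: list[str] = []
    for row in table:
        a1 = domain_map.anchor(row["anchor1"], n)
        a2 = domain_map.anchor(row["anchor2"], n)
        if a1 is None or a2 is None:
            skipped.append(row["name"])
            continue
        w1 = _clip(a1 + row["lo1"], a1 + row["hi1"], n)
        w2 = _clip(a2 + row["lo2"], a2 + row["hi2"], n)
        if w1 is None or w2 is None:
            skipped.append(row["name"])
            continue
        swap = w2[0] < w1[0]
        lo_w, hi_w = (w2, w1) if swap else (w1, w2)
        hit = _best_duplex(intron_seq, lo_w, hi_w)
        if hit is None or hit[2] < row["min_pairs"]:
            absent.append(row["name"])
            continue
        a, b, run, chars = hit
        iv_lo = Interval(a, a + run)
        iv_hi = Interval(b - run + 1, b + 1)
        iv1, iv2 = (iv_hi, iv_lo) if swap else (iv_lo, iv_hi)
        found.append(
            Interaction(
                name=row["name"],
                intron_interval=iv1,
                partner_interval=iv2,
                pairing=chars,
                n_pairs=run,
            )
        )
    return found, absent, skipped


# --- subtype classification -------------------------------------------------


def _ladder_decompose(region: str) -> tuple[int, str, int, int]:
    """Fold the lambda/epsilon' region by outside-in terminal ladder.

    Returns (outer_run, feature_kind, feat_lo, feat_hi): the unpaired
    feature is either the apex loop or a one-sided bulge whose skip lets
    the ladder continue for >= 3 further pairs.
    """
    i, j = 0, len(region) - 1
    run = 0
    while i < j - MIN_LOOP and pairs_ok(region[i], region[j]):
        i += 1
        j -= 1
        run += 1
    for b in range(1, 7):
        if i + b < j and ladder(region, i + b, j) >= 3:
            return run, "bulge", i, i + b
        if j - b > i and ladder(region, i, j - b) >= 3:
            return run, "bulge", j - b + 1, j + 1
    return run, "loop", i, j + 1


def classify_subtype(
    intron_seq: str,
    domain_map: DomainMap,
    db: dict[str, str] | None = None,
    min_outer_stem: int = 4,
) -> SubtypeCall:
    """Classify IIA/IIB/IIC from the lambda/epsilon' region feature.

    Rule precedence IIA -> IIB -> IIC, length test before consensus test:
    a length-only match yields the subtype with consensus_matched=False.
    """
    le = domain_map.lambda_eps
    if le is None:
        raise ValueError("lambda/epsilon' region not located in domain map")
    region = intron_seq[le.start : le.end]
    run, kind, lo, hi = _ladder_decompose(region)
    feat = region[lo:hi]
    flen = len(feat)
    if run < min_outer_stem:
        return SubtypeCall("unclassified", le, "none", 0, "", False)
    subtype, consensus = "unclassified", False
    if kind == "loop" and flen == 11:
        subtype, consensus = "IIA", "AGC" in feat
    elif kind == "bulge" and flen == 4:
        subtype, consensus = "IIB", bool(_AARC.fullmatch(feat))
    elif kind == "loop" and 7 <= flen <= 12:
        subtype, consensus = "IIC", "AGG" in feat
    call = SubtypeCall(subtype, le, kind, flen, feat, consensus)
    if db and subtype != "unclassified":
        from .boundary_context import percent_identity

        best_id, best_pid = None, 0.0
        for did, dseq in db.items():
            pid = percent_identity(intron_seq, dseq)
            if pid > best_pid:
                best_id, best_pid = did, pid
        if best_id is not None:
            call.db_support = f"{best_id}:{best_pid:.1f}"
    return call


def _classify_region_score(region: str) -> tuple[int, int, int]:
    run, kind, lo, hi = _ladder_decompose(region)
    feat = region[lo:hi]
    flen = len(feat)
    rule = consensus = 0
    if kind == "loop" and flen == 11:
        rule, consensus = 1, int("AGC" in feat)
    elif kind == "bulge" and flen == 4:
        rule, consensus = 1, int(bool(_AARC.fullmatch(feat)))
    elif kind == "loop" and 7 <= flen <= 12:
        rule, consensus = 1, int("AGG" in feat)
    return consensus, rule, run


def locate_lambda_eps(
    intron_seq: str, d1: Interval, max_scan: int = 90
) -> Interval | None:
    """Find the most lambda/epsilon'-like stem-loop/bulge window in
    proximal D1 (the region where the element sits architecturally).

    Scans candidate windows for a terminal ladder of >= 5 pairs, preferring
    windows whose unpaired feature matches a subtype rule (consensus first,
    then length-only), then longer ladders, then 5'-most position.
    """
    n = len(intron_seq)
    best: tuple[tuple[int, int, int, int], Interval] | None = None
    a_hi = min(d1.end - 19, d1.start + max_scan, n - 19)
    for a in range(d1.start, a_hi):
        for span in range(19, 41):
            if a + span > min(d1.end, n):
                break
            region = intron_seq[a : a + span]
            if not pairs_ok(region[0], region[-1]):
                continue
            consensus, rule, run = _classify_region_score(region)
            if run < 5:
                continue
            key = (consensus, rule, run, -a)
            if best is None or key > best[0]:
                best = (key, Interval(a, a + span))
    return best[1] if best else None


def infer_domain_map(
    intron_seq: str, d5_offset: int | None = None, detail: dict | None = None
) -> DomainMap:
    """Approximate DomainMap for a detected intron.

    d5_offset is the intron-relative position of the D5/D6 hit start (the
    triad); detail carries the detector's D5/D6 sub-offsets when available.
    D1 is taken as the region after the conserved 5' head up to the D5
    flank, used whole as the EBS search space; the lambda/epsilon' region
    is located by structural scan.
    """
    n = len(intron_seq)
    dm = DomainMap()
    if d5_offset is not None and 0 <= d5_offset < n:
        det = detail or {}
        d5_end = d5_offset + det.get("d5_end_off", 21) + 1
        dm.d5 = Interval(d5_offset, min(d5_end, n))
        dm.triad = d5_offset
        hp = best_anchored_hairpin(intron_seq, d5_offset, 5, (3, 12), 60)
        if hp is not None:
            run, close, _loop = hp
            dm.d5_loop = Interval(d5_offset + run, close - run + 1)
        if "d6_start_off" in det:
            dm.d6 = Interval(
                min(d5_offset + det["d6_start_off"], n - 1), n
            )
        if "branch_off" in det:
            dm.branch_a = d5_offset + det["branch_off"]
    d1_hi = (d5_offset - 12) if d5_offset is not None else n - 12
    d1 = Interval(9, max(30, min(d1_hi, 170)))
    dm.d1 = d1
    dm.d1_loops = [d1]
    dm.lambda_eps = locate_lambda_eps(intron_seq, d1)
    return dm


# --- dot-bracket export -----------------------------------------------------

_LAYERS = [("[", "]"), ("{", "}"), ("<", ">"), ("A", "a"), ("B", "b")]
_OPEN = {"(": ")"} | dict(_LAYERS)


def _helix_pairs(seq: str, dm: DomainMap) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    if dm.d5 is not None:
        i, j = dm.d5.start, dm.d5.end - 1
        while i < j - MIN_LOOP and pairs_ok(seq[i], seq[j]):
            pairs.append((i, j))
            i += 1
            j -= 1
    if dm.d6 is not None:
        i, j = dm.d6.start, dm.d6.end - 1
        skipped = False
        while i < j - MIN_LOOP:
            if pairs_ok(seq[i], seq[j]):
                pairs.append((i, j))
                i += 1
                j -= 1
            elif not skipped and seq[j] == "A":
                skipped = True
                j -= 1
            else:
                break
    if dm.lambda_eps is not None:
        i, j = dm.lambda_eps.start, dm.lambda_eps.end - 1
        while i < j - MIN_LOOP and pairs_ok(seq[i], seq[j]):
            pairs.append((i, j))
            i += 1
            j -= 1
    return pairs


def dotbracket(
    intron_seq: str,
    domain_map: DomainMap,
    interactions: list[Interaction] | None = None,
    on_conflict: str = "error",
) -> str:
    """Dot-bracket string: nested helices in '()', pseudoknot interactions
    in successive bracket layers. Conflicting pair assignments (one base in
    two pairs) raise an error listing the positions, or drop the later
    interaction with on_conflict="skip"."""
    if on_conflict not in ("error", "skip"):
        raise ValueError("on_conflict must be 'error' or 'skip'")
    n = len(intron_seq)
    struct = ["."] * n
    used: set[int] = set()

    def place(pairs: list[tuple[int, int]], op: str, cl: str) -> bool:
        conflicts = [p for ij in pairs for p in ij if p in used]
        if conflicts:
            if on_conflict == "skip":
                return False
            raise ValueError(
                f"conflicting pair assignments at positions {sorted(conflicts)}"
            )
        for i, j in pairs:
            struct[i], struct[j] = op, cl
            used.update((i, j))
        return True

    place(_helix_pairs(intron_seq, domain_map), "(", ")")
    layers: list[list[tuple[int, int]]] = [[] for _ in _LAYERS]
    for inter in interactions or []:
        if inter.partner_in_exon or inter.partner_interval.end > n:
            continue
        iv1, iv2 = sorted(
            [inter.intron_interval, inter.partner_interval], key=lambda iv: iv.start
        )
        pairs = [(iv1.start + k, iv2.end - 1 - k) for k in range(inter.n_pairs)]
        pairs = [(i, j) for i, j in pairs if i < j]
        for li, layer in enumerate(layers):
            crossing = any(
                (i < x < j) != (i < y < j)
                for i, j in pairs
                for x, y in layer
            )
            if not crossing:
                if place(pairs, *_LAYERS[li]):
                    layer.extend(pairs)
                break
    return "".join(struct)


def parse_dotbracket(struct: str) -> set[tuple[int, int]]:
    """Recover the pair set from a dot-bracket string (all layers)."""
    stacks: dict[str, list[int]] = {op: [] for op in _OPEN}
    closers = {cl: op for op, cl in _OPEN.items()}
    pairs: set[tuple[int, int]] = set()
    for k, ch in enumerate(struct):
        if ch in _OPEN:
            stacks[ch].append(k)
        elif ch in closers:
            pairs.add((stacks[closers[ch]].pop(), k))
    if any(st for st in stacks.values()):
        raise ValueError("unbalanced dot-bracket string")
    return pairs
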