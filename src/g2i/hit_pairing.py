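"""Pair 5' (D1-D4) and 3' (D5/D6) hits into intron candidates.

A complete group II intron shows one or two structural hits: a D1-D4 hit to
a 5'-end model and a D5/D6 hit a few hundred nt to ~1 kb downstream. Hits
are paired within a transcriptional-orientation span budget (default 3 kb;
observed real pairs sit within 2 kb), categorized by which ends are present,
deduplicated on byte-identical region sequence, and summarized as a
prevalence percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .core_io import GenomeRecord, Interval, ModelHit

CATEGORIES = ("both", "five_prime_only", "three_prime_only")


@dataclass
class IntronCandidate:
    candidate_id: str
    genome_id: str
    d1d4_hits: list[ModelHit] = field(default_factory=list)
    d5d6_hit: ModelHit | None = None
    category: str = ""
    span: Interval | None = None
    region_seq: str = ""
    flags: set[str] = field(default_factory=set)
    # downstream annotations (filled by later stages)
    subtype: str | None = None
    context: str | None = None
    boundary = None
    interactions: list = field(default_factory=list)
    orfs: list = field(default_factory=list)
    orf_category: str = "none"

    def all_hits(self) -> list[ModelHit]:
        hits = list(self.d1d4_hits)
        if self.d5d6_hit is not None:
            hits.append(self.d5d6_hit)
        return hits


def _merged_span(hits: list[ModelHit]) -> Interval:
    return Interval(
        min(h.interval.start for h in hits),
        max(h.interval.end for h in hits),
        hits[0].interval.strand,
    )


def pair_hits(
    hits: list[ModelHit],
    max_span: int = 3000,
    genomes: dict[str, GenomeRecord] | None = None,
    strategy: str = "best_score",
) -> list[IntronCandidate]:
    """Group model hits into intron candidates.

    Each D5/D6 hit (processed in descending score order) is paired with one
    unpaired upstream D1-D4 hit on the same genome/strand whose end lies
    within max_span of the D5/D6 start: the best-scoring one by default
    (ties broken by proximity), or the nearest with strategy="nearest".
    Additional D1-D4 hits lying between the chosen 5' hit and the D5/D6 hit
    are absorbed into the same candidate with flag tandem_d1d4. Unpaired
    hits become single-category candidates. Every input hit appears in
    exactly one candidate; pairing is stable under input permutation.
    """
    if strategy not in ("best_score", "nearest"):
        raise ValueError(f"unknown pairing strategy {strategy!r}")
    if genomes is not None:
        unknown = {h.genome_id for h in hits} - set(genomes)
        if unknown:
            raise ValueError(f"hits reference unknown genomes: {sorted(unknown)}")

    by_gs: dict[tuple[str, str], dict[str, list[ModelHit]]] = {}
    for h in hits:
        slot = by_gs.setdefault((h.genome_id, h.interval.strand), {"D1D4": [], "D5D6": []})
        slot[h.model_class].append(h)

    candidates: list[IntronCandidate] = []
    for (gid, strand), slot in sorted(by_gs.items()):
        d14 = sorted(slot["D1D4"], key=lambda h: h.interval.start)
        d56 = sorted(
            slot["D5D6"], key=lambda h: (-h.score, h.interval.start)
        )
        paired_d14: set[int] = set()
        for hit56 in d56:
            # transcriptional orientation: upstream means 5' of the intron
            def gap(h14: ModelHit) -> int:
                if strand == "+":
                    return hit56.interval.start - h14.interval.end
                return h14.interval.start - hit56.interval.end

            def upstream(h14: ModelHit) -> bool:
                if strand == "+":
                    return h14.interval.start < hit56.interval.start
                return h14.interval.end > hit56.interval.end

            avail = [
                (k, h)
                for k, h in enumerate(d14)
                if k not in paired_d14 and upstream(h) and -50 <= gap(h) <= max_span
            ]
            if not avail:
                candidates.append(
                    IntronCandidate(
                        candidate_id="",
                        genome_id=gid,
                        d5d6_hit=hit56,
                        category="three_prime_only",
                        span=hit56.interval,
                    )
                )
                continue
            if strategy == "best_score":
                k0, chosen = max(avail, key=lambda kh: (kh[1].score, -gap(kh[1])))
            else:
                k0, chosen = min(avail, key=lambda kh: gap(kh[1]))
            members = [chosen]
            paired_d14.add(k0)
            flags = set()
            # absorb tandem D1-D4 hits sitting between the 5' hit and D5/D6
            for k, h in enumerate(d14):
                if k in paired_d14:
                    continue
                between = (
                    chosen.interval.start < h.interval.start < hit56.interval.start
                    if strand == "+"
                    else hit56.interval.end < h.interval.end < chosen.interval.end
                )
                if between:
                    members.append(h)
                    paired_d14.add(k)
                    flags.add("tandem_d1d4")
            candidates.append(
                IntronCandidate(
                    candidate_id="",
                    genome_id=gid,
                    d1d4_hits=sorted(members, key=lambda h: h.interval.start),
                    d5d6_hit=hit56,
                    category="both",
                    span=_merged_span(members + [hit56]),
                    flags=flags,
                )
            )
        for k, h in enumerate(d14):
            if k not in paired_d14:
                candidates.append(
                    IntronCandidate(
                        candidate_id="",
                        genome_id=gid,
                        d1d4_hits=[h],
                        category="five_prime_only",
                        span=h.interval,
                    )
                )
    candidates.sort(key=lambda c: (c.genome_id, c.span.start, c.category))
    for i, c in enumerate(candidates, start=1):
        c.candidate_id = f"{c.genome_id}.c{i}"
        if genomes is not None:
            c.region_seq = genomes[c.genome_id].seq[c.span.start : c.span.end]
    return candidates


def dedup_candidates(
    candidates: list[IntronCandidate], keep_exceptions: set[str] | frozenset[str] = frozenset()
) -> list[IntronCandidate]:
    """Collapse candidates with byte-identical region sequence.

    Among identical regions the survivor is the lexicographically smallest
    genome_id; the others are flagged duplicate_removed and excluded —
    unless both genome ids are listed in keep_exceptions, in which case both
    are kept and flagged kept_exception. Idempotent.
    """
    groups: dict[str, list[IntronCandidate]] = {}
    for c in candidates:
        groups.setdefault(c.region_seq, []).append(c)
    out: list[IntronCandidate] = []
    for region, group in groups.items():
        if not region or len(group) == 1:
            out.extend(group)
            continue
        group = sorted(group, key=lambda c: (c.genome_id, c.candidate_id))
        if all(c.genome_id in keep_exceptions for c in group):
            for c in group:
                c.flags.add("kept_exception")
            out.extend(group)
            continue
        out.append(group[0])
        for c in group[1:]:
            c.flags.add("duplicate_removed")
    out.sort(key=lambda c: (c.genome_id, c.span.start if c.span else 0))
    return out


def categorize_and_count(candidates: list[IntronCandidate]) -> pd.Series:
    """Counts by hit category; always sums to the number of candidates."""
    counts = {cat: 0 for cat in CATEGORIES}
    for c in candidates:
        counts[c.category] += 1
    return pd.Series(counts, name="n")


def prevalence(n_intron_genomes: int, n_genomes: int) -> str:
    """Percentage of intron-carrying genomes, half-up rounded to 2 decimals
    and formatted with trailing zeros (e.g. 20/29015 -> '0.07')."""
    if n_genomes <= 0:
        raise ValueError("n_genomes must be > 0")
    if not 0 <= n_intron_genomes <= n_genomes:
        raise ValueError("need 0 <= n_intron_genomes <= n_genomes")
    pct = Decimal(100) * Decimal(n_intron_genomes) / Decimal(n_genomes)
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
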