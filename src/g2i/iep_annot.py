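"""Intron-encoded ORF discovery and classification (RVT IEP vs HEG).

ORFs are taken from three forward frames on the intron's coding strand
(intron-encoded proteins are sense-encoded; a reverse-strand scan is
available behind a flag). Classification uses protein-domain evidence:
external hmmscan hit tables when provided, otherwise bundled sequence
motifs matching the synthetic generator's sentinel tokens. An RVT IEP
requires reverse-transcriptase plus maturase evidence; a homing
endonuclease (HEG) call requires endonuclease evidence without RT. A
genome carrying an RVT IEP intron can mobilize its orfless introns in
trans; such introns are flagged possible_trans_iep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .core_io import DomainHit, Interval, MalformedRowError, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: built-in motif evidence (matches synthetic_data sentinels)
BUILTIN_MOTIFS = {
    "rt": ("GIRYADDMLV",),
    "maturase": ("WKQMAPGHLE",),
    "endonuclease": ("NLAGLIDADGYE",),
}

#: Pfam-style domain families accepted as evidence for each role
DOMAIN_FAMILIES = {
    "rt": {"RVT_1", "RVT_2", "RVT_3", "RVT_N", "RT_like"},
    "maturase": {"GIIM", "Intron_maturas2", "gpII_maturase"},
    "endonuclease": {
        "HNH", "HNH_3", "LAGLIDADG_1", "LAGLIDADG_2", "GIY-YIG", "Vsr",
        "EDxHD", "CapR",
    },
}


@dataclass
class OrfCall:
    intron_id: str
    frame: int
    coords: Interval  # intron-relative, includes the stop codon when present
    protein: str
    category: str = "none"  # rvt_iep | heg | other | none
    evidence: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


def scan_orfs(
    intron_seq: str, min_orf_aa: int = 100, both_strands: bool = False
) -> list[tuple[int, Interval, str]]:
    """Find ORFs in the three forward frames of the intron.

    An ORF is the longest stop-to-stop stretch containing an ATG, reported
    from that ATG; shorter same-frame ORFs inside it are suppressed.
    Returns (frame, coords, protein) tuples sorted by position.
    """
    out: list[tuple[int, Interval, str]] = []
    n = len(intron_seq)
    strands = [(intron_seq, False)] + ([(revcomp(intron_seq), True)] if both_strands else [])
    for seq, is_rc in strands:
        for frame in range(3):
            boundaries = [frame - 3]  # virtual stop before the first codon
            for c in range(frame, n - 2, 3):
                if seq[c : c + 3] in STOP_CODONS:
                    boundaries.append(c)
            boundaries.append(((n - frame) // 3) * 3 + frame)  # past-the-end
            for prev, stop in zip(boundaries, boundaries[1:]):
                seg_lo = prev + 3
                seg_hi = stop
                if seg_hi - seg_lo < 3 * min_orf_aa:
                    continue
                atg = None
                for c in range(seg_lo, seg_hi - 2, 3):
                    if seq[c : c + 3] == "ATG":
                        atg = c
                        break
                if atg is None or seg_hi - atg < 3 * min_orf_aa:
                    continue
                prot = str(Seq(seq[atg:seg_hi]).translate())
                hi = min(seg_hi + 3, n) if seg_hi < n - 2 else seg_hi
                iv = Interval(atg, hi) if not is_rc else Interval(n - hi, n - atg, "-")
                out.append((frame, iv, prot))
    out.sort(key=lambda t: (t[1].start, t[0]))
    return out


def _motif_evidence(protein: str) -> dict[str, bool]:
    return {
        role: any(m in protein for m in motifs)
        for role, motifs in BUILTIN_MOTIFS.items()
    }


def _domain_evidence(hits: list[DomainHit]) -> dict[str, bool]:
    names = {h.domain for h in hits}
    return {role: bool(names & fams) for role, fams in DOMAIN_FAMILIES.items()}


def classify_orf(
    protein: str, domain_hits: list[DomainHit] | None = None
) -> tuple[str, list[str], set[str]]:
    """Classify one intron ORF; returns (category, evidence, flags).

    RT + maturase evidence -> rvt_iep; endonuclease without RT -> heg;
    RT + endonuclease without maturase is conflicting -> other (flagged).
    """
    if not protein:
        raise ValueError("empty protein")
    ev = _domain_evidence(domain_hits) if domain_hits else _motif_evidence(protein)
    tags = [role for role, present in ev.items() if present]
    flags: set[str] = set()
    if ev["rt"] and ev["maturase"]:
        return "rvt_iep", tags, flags
    if ev["endonuclease"] and not ev["rt"]:
        return "heg", tags, flags
    if ev["rt"] and ev["endonuclease"]:
        flags.add("conflicting_evidence")
    return "other", tags, flags


def annotate_candidate_orfs(
    candidate,
    intron_seq: str,
    min_orf_aa: int = 100,
    domain_hits_by_protein: dict[str, list[DomainHit]] | None = None,
) -> list[OrfCall]:
    """Scan and classify ORFs for one candidate; sets candidate.orf_category
    to rvt_iep > heg > other by precedence, or none without ORFs."""
    calls: list[OrfCall] = []
    for k, (frame, iv, prot) in enumerate(scan_orfs(intron_seq, min_orf_aa)):
        pid = f"{candidate.candidate_id}.orf{k + 1}"
        hits = (domain_hits_by_protein or {}).get(pid)
        category, evidence, flags = classify_orf(prot, hits)
        calls.append(OrfCall(candidate.candidate_id, frame, iv, prot, category, evidence, flags))
    candidate.orfs = calls
    cats = {c.category for c in calls}
    for cat in ("rvt_iep", "heg", "other"):
        if cat in cats:
            candidate.orf_category = cat
            break
    else:
        candidate.orf_category = "none"
    return calls


def flag_trans_iep(candidates: list) -> int:
    """Flag orfless introns that share a genome with an RVT-IEP intron.

    Returns the number of possible_trans_iep flags applied. Never flags an
    intron in a genome lacking an rvt_iep intron.
    """
    by_genome: dict[str, list] = {}
    for c in candidates:
        by_genome.setdefault(c.genome_id, []).append(c)
    n = 0
    for group in by_genome.values():
        if not any(c.orf_category == "rvt_iep" for c in group):
            continue
        for c in group:
            if c.orf_category == "none":
                c.flags.add("possible_trans_iep")
                n += 1
    return n


def parse_hmmscan_table(
    path: str | Path, evalue_max: float = 1e-3
) -> list[DomainHit]:
    """Parse an hmmscan tabular file into DomainHits, dropping rows with
    full-sequence E-value above evalue_max.

    The per-domain (--domtblout) dialect is preferred since it carries
    alignment coordinates; the 18-column --tblout dialect is accepted with
    a whole-protein placeholder interval.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if len(parts) >= 22:  # domtblout
                    domain, protein = parts[0], parts[3]
                    evalue = float(parts[6])
                    ali = (int(parts[17]) - 1, int(parts[18]))
                elif len(parts) >= 18:  # tblout
                    domain, protein = parts[0], parts[2]
                    evalue = float(parts[4])
                    ali = (0, 0)
                else:
                    raise ValueError(f"expected >=18 columns, got {len(parts)}")
            except ValueError as exc:
                raise MalformedRowError(f"{path}:{lineno}: {exc}") from exc
            if evalue > evalue_max:
                continue
            hits.append(DomainHit(protein, domain, evalue, ali[0], ali[1]))
    return hits


def best_domain_per_protein(hits: list[DomainHit]) -> dict[str, DomainHit]:
    best: dict[str, DomainHit] = {}
    for h in hits:
        if h.protein_id not in best or h.evalue < best[h.protein_id].evalue:
            best[h.protein_id] = h
    return best
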