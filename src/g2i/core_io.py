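"""Shared sequence/coordinate types and readers/writers.

Internal coordinates are 0-based half-open throughout the package; emitted
GFF3 is 1-based inclusive. Minus-strand rows of cmsearch tables are
normalized at parse time so downstream stages never see start > end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_DNA = set("ACGTN")

#: Default model-name -> model-class mapping. The seven 5' end models form an
#: Rfam clan; the D5/D6 model is RF00029 (named Intron_gpII). Overridable by
#: the caller, and the built-in detector emits its own names.
DEFAULT_MODEL_CLASSES: dict[str, str] = {
    **{f"group-II-D1D4-{i}": "D1D4" for i in range(1, 8)},
    "RF00029": "D5D6",
    "Intron_gpII": "D5D6",
    "builtin-D1D4": "D1D4",
    "builtin-D5D6": "D5D6",
}


class DuplicateIdError(ValueError):
    pass


class MalformedRowError(ValueError):
    pass


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GenomeRecord:
    """One DNA sequence (uppercase, alphabet ACGTN after ingestion)."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id}: empty sequence")


@dataclass
class ModelHit:
    """One structural-model hit (external cmsearch or built-in detector)."""

    genome_id: str
    model: str
    model_class: str  # D1D4 | D5D6
    interval: Interval
    score: float
    evalue: float
    #: detector extras (D5 hairpin end, branch-point position), absent for
    #: external hits
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_class not in ("D1D4", "D5D6"):
            raise ValueError(f"bad model_class {self.model_class!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class DomainHit:
    """One protein-domain hit from an hmmscan table."""

    protein_id: str
    domain: str
    evalue: float
    ali_start: int  # 0-based half-open on the protein
    ali_end: int


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path, alphabet: set[str] | None = None) -> list[GenomeRecord]:
    """Read DNA FASTA. Uppercases, maps U->T, rejects other characters.

    Raises on an empty file and on duplicate ids (naming the id).
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    allowed = (alphabet or VALID_DNA) | {"U"}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - (allowed - {"U"})
        if bad:
            raise ValueError(
                f"sequence {rec.id}: invalid characters {sorted(bad)}"
            )
        records.append(GenomeRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper().rstrip("*")
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[GenomeRecord | tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, GenomeRecord) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_cmsearch_tblout(
    path: str | Path,
    evalue_max: float = 0.01,
    model_classes: dict[str, str] | None = None,
    clan_compete: bool = False,
) -> list[ModelHit]:
    """Parse a cmsearch --tblout hit table into ModelHits.

    Comment lines are skipped; minus-strand rows (seq start > end) are
    normalized to strand='-'; rows with E-value > evalue_max are dropped.
    Model class comes from a model-name lookup; unknown names raise unless
    the caller supplies a mapping. With clan_compete=True, overlapping hits
    on the same genome/strand are competed and only the best E-value is kept.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    classes = dict(DEFAULT_MODEL_CLASSES)
    if model_classes:
        classes.update(model_classes)
    hits: list[ModelHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 16:
                raise MalformedRowError(
                    f"{path}:{lineno}: expected >=16 columns, got {len(parts)}"
                )
            try:
                genome_id = parts[0]
                model = parts[2]
                seq_from = int(parts[7])
                seq_to = int(parts[8])
                score = float(parts[14])
                evalue = float(parts[15])
            except ValueError as exc:
                raise MalformedRowError(f"{path}:{lineno}: {exc}") from exc
            if evalue > evalue_max:
                continue
            if seq_from <= seq_to:
                iv = Interval(seq_from - 1, seq_to, "+")
            else:
                iv = Interval(seq_to - 1, seq_from, "-")
            if model not in classes:
                raise MalformedRowError(
                    f"{path}:{lineno}: model {model!r} has no class mapping; "
                    "pass model_classes={...}"
                )
            if model not in DEFAULT_MODEL_CLASSES:
                warnings.warn(
                    f"model {model!r} not in the bundled mapping; using "
                    f"caller-supplied class {classes[model]}",
                    stacklevel=2,
                )
            hits.append(
                ModelHit(
                    genome_id=genome_id,
                    model=model,
                    model_class=classes[model],
                    interval=iv,
                    score=score,
                    evalue=evalue,
                )
            )
    if clan_compete:
        hits = compete_overlapping(hits)
    return hits


def compete_overlapping(hits: Sequence[ModelHit]) -> list[ModelHit]:
    """Keep the best hit (lowest E-value, then highest score) among mutually
    overlapping same-genome/strand hits of the same model class."""
    kept: list[ModelHit] = []
    by_key: dict[tuple[str, str, str], list[ModelHit]] = {}
    for h in hits:
        by_key.setdefault((h.genome_id, h.interval.strand, h.model_class), []).append(h)
    for group in by_key.values():
        group.sort(key=lambda h: (h.evalue, -h.score, h.interval.start))
        chosen: list[ModelHit] = []
        for h in group:
            if not any(h.interval.overlaps(c.interval) for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.genome_id, h.interval.start))
    return kept


# --- GFF3 ---------------------------------------------------------------

GFF_HEADER = "##gff-version 3"


def _attr_str(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) or "."


@dataclass
class GffFeature:
    seqid: str
    ftype: str
    interval: Interval
    score: float | None = None
    attrs: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Sequence[GffFeature], path: str | Path, source: str = "g2i") -> None:
    """Write features as GFF3 (1-based inclusive). An empty feature list
    yields a valid header-only file."""
    with open(path, "w") as fh:
        fh.write(GFF_HEADER + "\n")
        for f in features:
            if not f.seqid:
                raise ValueError("feature with unresolved genome id")
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        source,
                        f.ftype,
                        str(f.interval.start + 1),
                        str(f.interval.end),
                        score,
                        f.interval.strand,
                        ".",
                        _attr_str(f.attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise MalformedRowError(f"bad GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for kv in cols[8].split(";"):
                    k, _, v = kv.partition("=")
                    attrs[k] = v
            feats.append(
                GffFeature(
                    seqid=cols[0],
                    ftype=cols[2],
                    interval=Interval(int(cols[3]) - 1, int(cols[4]), cols[6]),
                    score=None if cols[5] == "." else float(cols[5]),
                    attrs=attrs,
                )
            )
    return feats


def candidates_to_gff3(candidates, path: str | Path) -> None:
    """Emit curated intron candidates as GFF3 features.

    Feature types: group_II_intron, five_prime_hit, three_prime_hit,
    intron_ORF, interaction. Attributes carry subtype, context class and
    hit category when resolved.
    """
    feats: list[GffFeature] = []
    for c in candidates:
        attrs = {"ID": c.candidate_id, "category": c.category}
        if getattr(c, "subtype", None):
            attrs["subtype"] = c.subtype
        if getattr(c, "context", None):
            attrs["context"] = c.context
        if c.flags:
            attrs["flags"] = ",".join(sorted(c.flags))
        feats.append(GffFeature(c.genome_id, "group_II_intron", c.span, None, attrs))
        for h in c.d1d4_hits:
            feats.append(
                GffFeature(
                    c.genome_id,
                    "five_prime_hit",
                    h.interval,
                    h.score,
                    {"Parent": c.candidate_id, "model": h.model},
                )
            )
        if c.d5d6_hit is not None:
            h = c.d5d6_hit
            feats.append(
                GffFeature(
                    c.genome_id,
                    "three_prime_hit",
                    h.interval,
                    h.score,
                    {"Parent": c.candidate_id, "model": h.model},
                )
            )
        for orf in getattr(c, "orfs", []) or []:
            feats.append(
                GffFeature(
                    c.genome_id,
                    "intron_ORF",
                    Interval(
                        c.span.start + orf.coords.start,
                        c.span.start + orf.coords.end,
                        c.span.strand,
                    ),
                    None,
                    {"Parent": c.candidate_id, "orf_category": orf.category},
                )
            )
        for inter in getattr(c, "interactions", []) or []:
            feats.append(
                GffFeature(
                    c.genome_id,
                    "interaction",
                    Interval(
                        c.span.start + inter.intron_interval.start,
                        c.span.start + inter.intron_interval.end,
                        c.span.strand,
                    ),
                    None,
                    {"Parent": c.candidate_id, "name": inter.name},
                )
            )
    write_gff3(feats, path)
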