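"""End-to-end orchestration: scan -> pair -> boundaries -> structure -> ORFs.

run_pipeline executes the stages in order on a genome set, producing the
candidate table (TSV + GFF3), the interaction table, the intron-ORF protein
FASTA and a plain-text report with category/subtype/ORF-category counts and
prevalence. Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .boundary_context import classify_context, polish_three_prime, refine_boundaries
from .candidate_scan import ScanConfig, scan_genome
from .core_io import (
    GenomeRecord,
    Interval,
    ModelHit,
    candidates_to_gff3,
    parse_cmsearch_tblout,
    read_fasta,
    read_protein_fasta,
    revcomp,
    write_fasta,
)
from .hit_pairing import IntronCandidate, dedup_candidates, pair_hits, prevalence
from .iep_annot import annotate_candidate_orfs, flag_trans_iep
from .structure_annot import classify_subtype, find_ebs_ibs, find_tertiary, infer_domain_map

SUBTYPE_ORDER = {"IIA": 0, "IIB": 1, "IIC": 2, "unclassified": 3, None: 3}


@dataclass
class PipelineConfig:
    fasta: str | None = None
    tblout: str | None = None
    homologs: str | None = None
    out_dir: str = "g2i_out"
    seed: int = 0
    evalue_max: float = 0.01
    max_span: int = 3000
    pairing_strategy: str = "best_score"
    min_orf_aa: int = 100
    min_homolog_pid: float = 30.0
    exclude: list[str] = field(default_factory=list)
    keep_exceptions: list[str] = field(default_factory=list)
    do_boundaries: bool = True
    do_structure: bool = True
    do_orfs: bool = True
    scan: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Hash of the analysis parameters. File locations (inputs and
        output directory) are excluded so identical analyses of the same
        data in different places share a hash."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "fasta", "tblout", "homologs"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def scan_config(self) -> ScanConfig:
        return ScanConfig(evalue_max=self.evalue_max, **self.scan)


@dataclass
class PipelineResult:
    genomes: list[GenomeRecord]
    hits: list[ModelHit]
    candidates: list[IntronCandidate]
    tables: dict[str, pd.DataFrame]
    report: str


def _oriented_intron(genome: GenomeRecord, start: int, end: int, strand: str) -> str:
    seg = genome.seq[start:end]
    return seg if strand == "+" else revcomp(seg)


def _oriented_exon5(genome: GenomeRecord, start: int, end: int, strand: str, width: int = 30) -> str:
    if strand == "+":
        return genome.seq[max(0, start - width) : start]
    return revcomp(genome.seq[end : end + width])


def annotate_candidate(
    cand: IntronCandidate,
    genome: GenomeRecord,
    cfg: PipelineConfig,
    homologs: dict[str, str] | None,
) -> None:
    """Run boundary, context, structure and ORF annotation on one candidate."""
    scan_cfg = cfg.scan_config()
    bc = refine_boundaries(cand, genome, scan_cfg) if cfg.do_boundaries else None
    if bc is not None and bc.resolved:
        bc = polish_three_prime(bc, genome)
    cand.boundary = bc
    if cfg.do_boundaries:
        ctx = classify_context(
            cand, bc, genome, homologs=homologs, min_homolog_pid=cfg.min_homolog_pid
        )
        cand.context = ctx.context
        if ctx.homolog_pid is not None:
            cand.flags.add(f"homolog_pid={ctx.homolog_pid:.1f}")
    if bc is None or not bc.resolved:
        return
    strand = cand.span.strand
    iseq = _oriented_intron(genome, bc.start, bc.end, strand)
    if cfg.do_structure or cfg.do_orfs:
        hit56 = cand.d5d6_hit
        d5_off = None
        detail = {}
        if hit56 is not None:
            detail = hit56.detail
            d5_off = (
                hit56.interval.start - bc.start
                if strand == "+"
                else bc.end - hit56.interval.end
            )
        dm = infer_domain_map(iseq, d5_off, detail)
        if cfg.do_structure:
            if dm.lambda_eps is not None:
                sub = classify_subtype(iseq, dm)
                cand.subtype = sub.subtype
            else:
                cand.subtype = "unclassified"
            exon5 = _oriented_exon5(genome, bc.start, bc.end, strand)
            ebs, _missing = find_ebs_ibs(iseq, exon5, dm)
            tert, _absent, _skipped = find_tertiary(iseq, dm)
            cand.interactions = ebs + tert
        if cfg.do_orfs:
            annotate_candidate_orfs(cand, iseq, cfg.min_orf_aa)


def summarize(candidates: list[IntronCandidate]) -> pd.DataFrame:
    """One row per candidate, sorted by subtype (IIA < IIB < IIC <
    unclassified) then genome id."""
    rows = []
    for c in candidates:
        bc = c.boundary
        rows.append(
            {
                "candidate_id": c.candidate_id,
                "genome_id": c.genome_id,
                "start": bc.start if bc and bc.start is not None else c.span.start,
                "end": bc.end if bc and bc.end is not None else c.span.end,
                "strand": c.span.strand,
                "category": c.category,
                "subtype": c.subtype or "unclassified",
                "context": c.context or "",
                "orf_category": c.orf_category,
                "n_interactions": len(c.interactions),
                "boundary_confidence": bc.confidence if bc else "unresolved",
                "flags": ",".join(sorted(c.flags)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "candidate_id", "genome_id", "start", "end", "strand", "category",
            "subtype", "context", "orf_category", "n_interactions",
            "boundary_confidence", "flags",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["subtype", "genome_id", "start"],
            key=lambda col: col.map(SUBTYPE_ORDER) if col.name == "subtype" else col,
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def _interaction_table(candidates: list[IntronCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        for it in c.interactions:
            rows.append(
                {
                    "candidate_id": c.candidate_id,
                    "name": it.name,
                    "intron_start": it.intron_interval.start,
                    "intron_end": it.intron_interval.end,
                    "partner_start": it.partner_interval.start,
                    "partner_end": it.partner_interval.end,
                    "partner_in_exon": it.partner_in_exon,
                    "n_pairs": it.n_pairs,
                    "pairing": it.pairing,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_id", "name", "intron_start", "intron_end",
            "partner_start", "partner_end", "partner_in_exon", "n_pairs",
            "pairing",
        ],
    )


def _report(candidates: list[IntronCandidate], n_genomes: int, cfg: PipelineConfig) -> str:
    lines = ["# g2i pipeline report", f"config_hash: {cfg.digest()}", f"seed: {cfg.seed}", ""]
    cats = pd.Series([c.category for c in candidates]).value_counts().to_dict()
    subs = pd.Series([c.subtype or "unclassified" for c in candidates]).value_counts().to_dict()
    orfs = pd.Series([c.orf_category for c in candidates]).value_counts().to_dict()
    lines.append(f"candidates: {len(candidates)}")
    for name, counts in (("category", cats), ("subtype", subs), ("orf_category", orfs)):
        for key in sorted(counts):
            lines.append(f"{name}.{key}: {counts[key]}")
    carrier = len({c.genome_id for c in candidates})
    if n_genomes > 0:
        lines.append(f"intron_genomes: {carrier}/{n_genomes}")
        lines.append(f"prevalence_pct: {prevalence(carrier, n_genomes)}")
    else:
        lines.append("intron_genomes: 0/0")
        lines.append("prevalence_pct: n/a")
    return "\n".join(lines) + "\n"


def run_pipeline(
    cfg: PipelineConfig, genomes: list[GenomeRecord] | None = None
) -> PipelineResult:
    """Execute the full pipeline and write the result bundle to out_dir."""
    if genomes is None:
        if cfg.fasta is None:
            raise ValueError("either a genome list or cfg.fasta is required")
        genomes = read_fasta(cfg.fasta)
    genomes = [g for g in genomes if g.id not in set(cfg.exclude)]
    gmap = {g.id: g for g in genomes}
    homologs = read_protein_fasta(cfg.homologs) if cfg.homologs else None
    scan_cfg = cfg.scan_config()

    if cfg.tblout:
        hits = [h for h in parse_cmsearch_tblout(cfg.tblout, cfg.evalue_max) if h.genome_id in gmap]
    else:
        hits = []
        for g in genomes:
            hits.extend(scan_genome(g, scan_cfg))

    candidates = pair_hits(
        hits, max_span=cfg.max_span, genomes=gmap, strategy=cfg.pairing_strategy
    )
    candidates = dedup_candidates(candidates, set(cfg.keep_exceptions))
    for cand in candidates:
        annotate_candidate(cand, gmap[cand.genome_id], cfg, homologs)
    if cfg.do_orfs:
        flag_trans_iep(candidates)

    cand_df = summarize(candidates)
    inter_df = _interaction_table(candidates)
    hit_rows = pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "model": h.model,
                "class": h.model_class,
                "start": h.interval.start,
                "end": h.interval.end,
                "strand": h.interval.strand,
                "score": h.score,
                "evalue": h.evalue,
            }
            for h in hits
        ],
        columns=["genome_id", "model", "class", "start", "end", "strand", "score", "evalue"],
    )
    report = _report(candidates, len(genomes), cfg)
    tables = {"candidates": cand_df, "interactions": inter_df, "hits": hit_rows}

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False)
    inter_df.to_csv(out / "interactions.tsv", sep="\t", index=False)
    hit_rows.to_csv(out / "hits.tsv", sep="\t", index=False)
    candidates_to_gff3(candidates, out / "candidates.gff3")
    orf_records = [
        (f"{o.intron_id}.orf{k + 1}", o.protein.rstrip("*"))
        for c in candidates
        for k, o in enumerate(c.orfs)
    ]
    write_fasta(orf_records, out / "orfs.faa")
    (out / "report.txt").write_text(report)
    (out / "run.log").write_text(
        f"g2i run\nconfig_hash={cfg.digest()}\nseed={cfg.seed}\n"
        f"n_genomes={len(genomes)}\nn_hits={len(hits)}\nn_candidates={len(candidates)}\n"
    )
    return PipelineResult(genomes, hits, candidates, tables, report)
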