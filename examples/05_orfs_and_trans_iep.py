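"""Find and classify intron-encoded ORFs; flag trans-IEP borrowing.

An RVT IEP shows reverse-transcriptase plus maturase evidence; a homing
endonuclease (HEG) shows endonuclease evidence without RT. An orfless
intron sharing a genome with an RVT intron may be mobilized in trans.
"""

from g2i import GeneratorConfig, generate_dataset, generate_intron
from g2i.iep_annot import classify_orf, scan_orfs
from g2i.pipeline import PipelineConfig, run_pipeline
from g2i.synthetic_data import write_dataset

for mode in ("rvt", "heg", "orfless"):
    seq, dm = generate_intron("IIB", mode, 2)
    orfs = scan_orfs(seq)
    if not orfs:
        print(f"{mode}: no ORF >= 100 aa (intron {len(seq)} nt)")
        continue
    frame, iv, prot = max(orfs, key=lambda o: len(o[2]))
    category, evidence, _ = classify_orf(prot)
    print(f"{mode}: ORF {iv.start}-{iv.end} frame {frame}, {len(prot)} aa "
          f"-> {category} (evidence: {evidence})")

# run the full pipeline on a dataset containing the four-intron genome
ds = generate_dataset(GeneratorConfig(n_genomes=20, seed=7), "scratch/ex05")
res = run_pipeline(PipelineConfig(fasta="scratch/ex05/genomes.fa",
                                  out_dir="scratch/ex05/out"))
flagged = [c.candidate_id for c in res.candidates if "possible_trans_iep" in c.flags]
print(f"possible trans-IEP introns: {flagged}")

# The orfless introns of the multi-intron genome are flagged because a
# sibling intron in the same genome encodes an RVT IEP.
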