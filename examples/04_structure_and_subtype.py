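"""Annotate EBS/IBS pseudoknots, tertiary interactions and subtype.

Subtype comes from the unpaired feature of the lambda/epsilon' region:
an 11-nt loop with AGC is IIA, a 4-nt bulge matching AARC is IIB, a
7-12-nt loop with AGG is IIC.
"""

from g2i import generate_intron
from g2i.core_io import revcomp
from g2i.structure_annot import classify_subtype, dotbracket, find_ebs_ibs, find_tertiary

for subtype in ("IIA", "IIB", "IIC"):
    seq, dm = generate_intron(subtype, "orfless", 1)
    call = classify_subtype(seq, dm)
    print(f"{subtype} exemplar: called {call.subtype}, feature "
          f"{call.feature_kind} of {call.feature_len} nt "
          f"('{call.feature_seq}'), consensus matched: {call.consensus_matched}")

seq, dm = generate_intron("IIA", "orfless", 1)
exon = "ACGTACGTACGTACGTACG" + revcomp(seq[dm.ebs2.start:dm.ebs2.end]) + \
       revcomp(seq[dm.ebs1.start:dm.ebs1.end])
ebs, missing = find_ebs_ibs(seq, exon, dm)
for it in ebs:
    print(f"{it.name}: {it.n_pairs} bp duplex at intron "
          f"{it.intron_interval.start}-{it.intron_interval.end}")

tert, absent, skipped = find_tertiary(seq, dm)
print(f"tertiary interactions recovered: {sorted(i.name for i in tert)}")

struct = dotbracket(seq, dm, tert, on_conflict="skip")
print("dot-bracket around D5:", struct[dm.d5.start - 4 : dm.d6.end])

# EBS1:IBS1 (6 bp) and EBS2:IBS2 (>=4 bp) plus eight named tertiary duplexes
# are the pseudoknot evidence the covariance models cannot themselves see.
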