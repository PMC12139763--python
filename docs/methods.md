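# Methods

This note documents the models, heuristics and numerical choices behind
`g2i`, what the synthetic data does and does not emulate, and the known
limitations.

## Detection model

Group II introns conserve secondary structure, not sequence. The
high-fidelity detection path is ingestion of covariance-model search hits
(cmsearch `--tblout`, per-row E-value filter, default 0.01, with optional
clan competition that keeps the best of mutually overlapping hits). The
built-in detector is a deliberately simplified structural stand-in for
profile-SCFG search, anchored on the most conserved features:

- **D5/D6 (3′) detector.** Every AGC/CGC triad occurrence (both strands) is
  tested as a D5 stem start: the hairpin anchored exactly at the triad must
  ladder ≥ `d5_stem_min` (9) contiguous canonical/GU pairs around a loop of
  3–10 nt, all within a 60-nt window. Downstream (≤12 nt linker), a second
  helix must carry **exactly one** unpaired adenosine — the branch point —
  5–12 nt from its 3′ base, with ≥ `d6_stem_min` (6) pairs. The hit score is
  the paired-base count plus a triad bonus (AGC 3, CGC 2); the hit interval
  runs from the triad through the end of the D6 helix, which is why the 3′
  hit end approximates the 3′ splice site.
- **5′ (GWYRG/D1) detector.** Upstream of each D5/D6 hit (3.3 kb, the 3-kb
  pairing budget plus 10% margin), every GWYRG occurrence (overlapping
  matches included) is tested for a D1 proxy: a contiguous canonical helix
  ladder of ≥ `d1_helix_min` (10) pairs whose 5′ arm starts within 20 nt of
  the motif and closes within 200 nt. The ladder length is the hit score.

All stem searches are *anchored ladders* rather than extractions from a
global maximum-pairing fold: global Nussinov-style folds are massively
tie-degenerate, so "the hairpin found by the fold" is not a well-defined
object, while the anchored ladder is the deterministic restriction of
maximum pairing to helices anchored at the motif of interest. An exact
maximum-pairing fold (`fold_max_pairs`, O(n³) DP, minimum hairpin loop 3,
deterministic 5′-most traceback, window ≤ 200 nt) exists and is
oracle-tested; detection does not depend on it.

Overlapping hits are resolved to the best score, preferring the plus strand
on ties before position: the reverse complement of a D5 hairpin is itself a
triad-opened hairpin, so a genuine hit can tie its own minus-strand mirror;
the mirror is distinguished only by its weaker D6 (bulged-A) evidence and
would otherwise win a position-first tie-break by starting earlier.

Null calibration: on i.i.d. uniform random sequence the full D5/D6
signature fires at ≈0.3% per kb (asserted < 5%/kb over 1,000 kb in the
test suite).

## Pairing and curation

Each D5/D6 hit — processed in descending score order — is paired with one
unpaired upstream (transcription-sense) D1–D4 hit whose end lies within
`max_span` (default 3000 nt; real pairs are observed within 2 kb, the
allowance is deliberately looser). The default choice is the best-scoring
such hit with proximity as tie-break; `strategy="nearest"` gives plain
nearest-upstream greedy pairing. Best-score is the default because chance
GWYRG motifs inside ORF-containing introns occasionally pass the D1 proxy
and would capture a nearest-first pairing. D1–D4 hits lying between the
chosen 5′ hit and the D5/D6 hit are absorbed with flag `tandem_d1d4`.

Candidates with byte-identical region sequences are collapsed to the
lexicographically smallest genome id, unless all carriers appear in a
user-supplied keep-exception list (both kept, flagged `kept_exception`) —
mirroring manual curation in which a duplicated intron in two well-studied
genomes is deliberately retained. Prevalence is reported as
100·a/b rounded half-up to two decimals with trailing zeros.

## Boundaries and context

The 3′ splice site is taken from the D5/D6 hit end (through the D6 helix);
the 5′ site is the GWYRG occurrence nearest the 5′ hit start within a
100-nt window (the "upstream vicinity" is not sharply defined; 100 nt is a
configurable default). Because chance exon pairs can extend the D6 ladder
by a nucleotide or two, the 3′ call is polished: if no stop-free reading
frame spans the stitched junction as called but a shift of ≤3 nt restores
one, the shifted boundary is adopted and recorded with method
`homolog_alignment` (the stitched-host-gene evidence path). Unresolved ends
are flagged, never guessed.

Context classification is a cascade producing exactly one class:

1. **truncated** — the intron interval touches a contig end;
2. **intragenic** — a stop-free reading frame spans ±150 nt of the stitched
   junction; when intronless homolog proteins are provided, the stitched
   segment (expanded to the flanking in-frame stops, required ≥120 aa so
   short chance frames cannot qualify) must align to one at ≥30% identity;
3. **post_terminator** — a rho-independent-terminator signature (hairpin
   with ≥6 pairs, loop 3–8 nt, followed within 8 nt by ≥4 T in a 6-nt
   window) within 200 nt 5′ of the intron;
4. **pseudogene** — an ATG-initiated frame spanning the junction with 2–4
   internal stops distributed on both sides (far fewer than random sequence
   shows over the same 850-nt extent);
5. **intergenic** otherwise.

The terminator test precedes the pseudogene test because its signature is
far more specific; the decayed-frame heuristic can be imitated by random
flanks at the few-percent level. The pseudogene and intergenic classes are
intrinsically fuzzy without homology evidence and are best-effort calls.

Protein alignment is global affine-gap (match 2, mismatch −1, gap open −5,
extend −1; a gap of length L costs open + (L−1)·extend), delegated to
Biopython's `PairwiseAligner` and verified against a brute-force alignment
enumeration for short peptides. Percent identity always uses the shorter
of the two unaligned sequence lengths as denominator. Simple fixed scores
(not substitution matrices) keep the oracle exhaustive; a matrix hook can
be added at the aligner construction point.

## Structure annotation and subtype

IBS1 is the last 6 nt of the 5′ exon and IBS2 the (default 5, range 4–6) nt
immediately 5′ of it; EBS partners are searched as antiparallel
complementarity (GU allowed) within the D1 loop regions of the domain map,
reporting the longest duplex per interaction with minima of 5 (EBS1) and 4
(EBS2 — the duplex can genuinely be as short as 4 bp). The eight tertiary
pairings (α β γ δ ε λ κ ζ) are searched between two domain-anchored windows
read from a bundled editable table
(`src/g2i/data/tertiary_windows.tsv`). The exact windows are the largest
judgment call in the package and are therefore isolated in data, not code;
"non-canonical" pairings are approximated as standard complementarity.
Interactions not found are reported absent; unresolvable anchors are
skipped, never fabricated.

Subtype is read from the λ–ε′ region: the region is folded outside-in as a
terminal ladder; the unpaired feature is the apex loop, or a one-sided
bulge when skipping ≤6 nt on one side lets the ladder continue ≥3 further
pairs. Rules apply in order IIA → IIB → IIC with the length test first
(loop of exactly 11 → IIA; bulge of exactly 4 → IIB; loop of 7–12 → IIC) and
the consensus motif (AGC / AARC / AGG) recorded as `consensus_matched` —
a length-only match still yields the subtype, with the flag false. For
detected (non-generator) introns the λ–ε′ region is located by scanning
proximal D1 (first 90 nt) for the best terminal-ladder window, preferring
rule-matching features, then longer ladders, then 5′-most position.

Dot-bracket export writes the D5/D6/λ–ε′ helices as nested parentheses and
pseudoknot interactions in successive bracket layers; a position claimed by
two pairs raises an error listing the positions (or drops the later
interaction with `on_conflict="skip"`).

## Intron-encoded ORFs

Three forward frames on the intron's coding strand are scanned (IEPs are
sense-encoded; a reverse-strand scan exists behind a flag). An ORF is the
longest stop-to-stop stretch containing an ATG, reported from that ATG,
with `min_orf_aa` = 100 — below the smallest real IEP domains, above noise.
Classification requires reverse-transcriptase plus maturase evidence for
`rvt_iep`, endonuclease without RT for `heg`; RT plus endonuclease without
maturase is flagged conflicting and labelled `other`. Evidence comes from
hmmscan domain tables (the `--domtblout` dialect, which carries alignment
coordinates; the 18-column `--tblout` dialect is accepted with placeholder
intervals) or, absent external tables, from built-in peptide motifs that
match the generator's sentinel tokens. Orfless introns sharing a genome
with an `rvt_iep` intron are flagged `possible_trans_iep`.

## Phylogeny preparation

Single-linkage clusters are connected components of the PID ≥ threshold
graph (scipy connected components; a union-find oracle backs the tests).
The cluster count is a non-decreasing step function of the threshold with
breakpoints at the distinct off-diagonal PID values; `threshold_for_k`
probes one representative per interval and returns the feasible interval's
midpoint, or None when a count is skipped by a jump. Stratified sampling
takes min(cap, stratum size) uniformly without replacement per stratum,
deterministic under seed. Assembly prefixes ids with their group label and
emits a per-group manifest with the total.

## Synthetic data: what it emulates and what it does not

The generator's purpose is ground truth for the pipeline's statistical
contract, not biological realism. It emulates: the consensus intron
anatomy (GWYRG terminus; ε′ after the terminus; D1 with a 12-bp closing
helix, EBS1/EBS2 hairpin loops, the λ–ε′ subtype element and tertiary
partner loci; D2–D3 hairpins; D4 hosting the ORF; the 9-bp triad-opened D5
hairpin; the D6 helix with one bulged A 7–8 nt from the 3′ end), the two
length regimes (orfless ≈600 nt with ±10% uniform jitter — the sources give
"around 600" with no tolerance — and ORF-containing 2–3 kb), homing-site
complementarity (the 11 nt of exon 5′ of the insertion rewritten so
IBS1/IBS2 reverse-complement the intron's EBS1/EBS2), five genomic-context
classes, intronless homolog genes planted in non-carrier genomes, a
four-intron genome (one RVT + three orfless) for trans-IEP flagging, and an
identical-intron pair for deduplication. Default weights follow the
observed census at configurable scale: subtypes 0.15/0.80/0.05
(IIA/IIB/IIC), ORF modes 7:4:6 (rvt:heg:orfless), prevalence 0.1 at
n=100 genomes of ~12 kb (a desk-scale stand-in for the 0.07% seen across
tens of thousands of real genomes — at realistic prevalence a test dataset
would contain no introns at all).

It does **not** emulate: real phage nucleotide composition or codon usage
(background is i.i.d. with configurable GC; host genes are stop-free random
codons), sequencing error, retrohoming dynamics, minus-strand genes
(introns are planted on the plus strand; detector strand symmetry is tested
directly), or profile-SCFG score statistics. Passing round-trip tests
therefore demonstrates the pipeline's internal consistency and calibration
under the stated structural model — not discovery performance on real
genomes, for which the external cmsearch ingestion path exists.

Three generator choices deliberately trade realism for *well-posed truth*:
loop/linker filler is drawn from {A,G}, which admits no canonical or wobble
pair on either strand sense, so designed helices are the only ladders
detectors can find; the insertion junction is redrawn until it contains
exactly one GWYRG occurrence, so the planted 5′ boundary is unambiguous;
and long unpaired stretches are seeded with stop cassettes
(`TAAATAAATAA`, stopping all three frames) so orfless introns cannot
contain spurious ≥100-aa ORFs. Randomness is split per genome from the top
seed (`numpy` SeedSequence spawning), so one genome's content never depends
on another's insertion order.

## Determinism and numerical choices

All randomness flows from explicit seeds; the analysis pipeline itself is
deterministic (sorted iteration everywhere, fixed tie-breaks: detector
overlap resolution by score/strand/position, duplex search by run length
then 5′-most, alignment traceback delegated to a deterministic aligner).
Identical configuration and inputs give byte-identical output files; the
run log records a configuration hash that excludes file locations.

Problem sizes in the shipped tests — 100 genomes of ~12 kb for
parameter-recovery, 1,000 kb for null calibration, ≤18-nt windows for the
fold oracle, ≤7-aa peptides for the alignment oracle, ≤8-sequence matrices
for the clustering oracle — were chosen so the full suite completes in
well under a minute while keeping binomial noise on the 95% thresholds
small.

## Known limitations

- The built-in detector is calibrated on the synthetic model; its
  sensitivity on real, diverged introns is untested and expected to be far
  below profile-SCFG search. It is a fallback and a testing device.
- Boundary inference assumes the 5′ GWYRG is present; group II introns
  with degenerate termini will come back unresolved.
- Tertiary-interaction windows assume the consensus domain architecture;
  heavily rearranged introns will yield absent/skipped interactions.
- Pseudogene/intergenic discrimination without homologs is heuristic.
- Prophage/ICE exclusion is a user-supplied genome id list; no automated
  mobile-element boundary detection is attempted.
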