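# Methods

## Problem and scope

`vdjseq` annotates V(D)J recombination in long transcriptomic reads: given
a germline segment database (IMGT-style FASTA) and reads that each span a
full rearranged V(D)J–C transcript, it reports per-read segment calls,
CDR1/2/3, SHM status and repertoire summaries.  It does not perform genome
alignment itself — candidate extraction consumes an existing BAM (or takes
all raw reads), and spliced alignment is out of scope.

## Local alignment

The aligner is an exact affine-gap Smith–Waterman (gap of length k costs
`gap_open + k·gap_extend`), not a seeded heuristic.  Default scores are the
blastn convention (+2 match, −3 mismatch, open 5, extend 2), chosen so the
V-gene score threshold of 350 retains its published meaning of roughly 175
matched bases.  Percent identity is matches over alignment columns, gap
columns included (BLAST `pident`).  `N` and IUPAC ambiguity codes mismatch
everything, so ambiguous runs cannot inflate identity.  Ties are resolved
deterministically: the best cell with the smallest (query end, subject
end); traceback prefers diagonal over up over left; gap-open is preferred
over gap-extend at equal score.  The numba kernel is checked cell-for-cell
against an independent pure-Python dynamic program in the test suite.

## Call filtering

V/J/C candidates per read (both strands, best orientation per segment) are
filtered by identity ≥ 90% and, for V only, raw score ≥ 350; survivors are
ranked by score, identity, aligned length, segment name.  One guard is the
package's own: calls must span **≥ 25 aligned columns**.  A full DP scan
reports the ~10 bp perfect matches that arise by chance between any two
sequences (expected longest exact match between a 300 nt read and a 55 nt
segment is ~8–10 bp); a seeded aligner's word size and E-value would never
surface these, and without the floor they would fabricate J/C calls on
reads that lack those segments.  25 columns is far below any real J (≥ 45
nt) or C (≥ 300 nt) hit and far above chance-match length, so the setting
is not delicate.  D-gene search is exempt (D segments can be trimmed to
~6 nt in a real junction); D specificity comes instead from the >80%
identity filter applied inside the narrow padded V–J window.

Read orientation follows the V call's strand (then J, then C).  V/J calls
on opposite strands are flagged and excluded from D search and CDR3;
J-before-V reads are flagged and excluded from CDR3 only.

## CDR extraction

Frames are derived from the germline `frame_offset` propagated through the
alignment path, codon by codon; codons interrupted by alignment indels are
skipped rather than guessed.  CDR3 is anchor-inclusive (conserved C through
conserved W/F), the junction convention; when the junction is out of frame
(start and end anchors in different frames) the nucleotide CDR3 is still
reported and the amino-acid field is left empty.  When several `YYC`
motifs occur, the 3′-most within the V region wins; the 5′-most `[WF]GxG`
within the J region wins — anchors sit at the V end and J start.  The
position-104 fallback uses the germline's IMGT position map when the FASTA
is IMGT-gapped (dots), else sequential codon numbering from the frame
offset.  Stop codons inside a CDR appear as `*` and do not abort
annotation.

## Consensus error correction

Annotation combinations are clustered into greedy fixed-anchor 50-bp
windows of alignment start (genomic start when the input was a BAM;
otherwise the V hit's germline start position, which keeps the module
usable on raw FASTQ but makes the windows coarse — full-length transcripts
all start near germline position 0, so alignment-free correction behaves
close to dataset scope).  The dominant combination needs support ≥ 2 and
strictly more support than a deviant's own combination; only single-slot
deviations are corrected, and a missing slot is a distinct value (gaining
or losing a D counts as one deviation).  Correction relabels the call; the
underlying alignment (used for CDR lifting) is untouched.  Per-window
scope is the default; `--correction-scope dataset` treats the whole run as
one window.

## Simulator

The generator emulates the benchmark design, not any particular sequencer:

- **Germlines**: V = 106 codons (318 nt) with C planted at IMGT position
  23, W at 41, and Y-Y-C at 102–104 plus two trailing codons so the anchor
  survives 3′ trimming (the anchor layout itself forces ≥ 312 nt at frame
  offset 0); D = 12–30 nt random; J = 45–60 nt with a `[WF]GxG` motif at
  codon 2 under a random frame offset 0–2, early motif mimics excluded;
  C = 300–600 nt random.  Same-class segments are rejection-sampled to
  pairwise global (Needleman–Wunsch/edlib) identity < 80% — local-hit
  identity is unusable as a divergence measure since unrelated sequences
  share short perfect local matches.
- **Recombination**: V 3′ trim 0–5 nt, J 5′ trim 0–5 nt, D trims 0–3 nt
  per end, N-insertions 0–10 nt per junction, all uniform; the bounds are
  the package's own choice (the benchmark design leaves the junction model
  open) and make D detection non-trivial but solvable at the 80% identity
  bar.  Half the transcripts are stored reverse-complemented; germline
  point mutations at 1e-4 per base.  Junction frame compatibility is *not*
  enforced — as in real repertoires many junctions are out of frame, and
  truth records the nucleotide junction, which is what the annotator is
  scored on.
- **Reads**: PacBio-like lengths N(2000, 500) clamped to [1000, 3500] and
  the transcript (so sub-kilobase transcripts yield whole-transcript
  reads), per-read accuracy uniform in [0.98, 1.00], error mix
  sub:ins:del = 6:3:1.  Nanopore-like lengths N(40000, 20000) truncated at
  the transcript, flat 1% error with a heavier indel share (4:3:3): the
  two platforms then share the same mean error magnitude, and the
  Nanopore's indel bias — the component that actually breaks frames and
  depresses alignment identity — carries the platform ordering, which is
  the package's modelling interpretation of "higher error", not a claim of
  equivalence to any published error profile.
- Everything is deterministic under the config seed.

What passing simulated benchmarks does **not** show: tolerance to real
IMGT germline sets, where same-family alleles differ by a handful of bases
(the synthetic segments are < 80% identical, so call confusions between
near-identical alleles are not exercised); homopolymer-structured Nanopore
errors; chimeric or truncated reads; genome-alignment recall.

## Benchmark conditions

Desk-scale study sizes, fixed in `vdjseq.benchmark`: IGH 20V/20D/6J/4C
with 50 transcripts; light chain 20V/6J/2C with 50; TRA 15V/8J/2C with 40;
TRB 15V/3D/8J/2C with 40; all at 20× coverage, mutation 1e-4, PacBio-like
(IGH additionally Nanopore-like).  Scoring uses gene-set mode — the set of
called gene labels (or V/D/J tuples) against the set of true ones — which
is how single recall/precision numbers per class over a many-gene
simulation are most naturally read; per-read mode is available throughout.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `min_identity_pct` | 90 | identity floor for V/J/C calls (%) |
| `min_v_score` | 350 | raw-score floor, V only |
| `min_aligned_length` | 25 | alignment-span floor for V/J/C calls (bp) |
| `d_min_identity_pct` | 80 | D hits must be strictly above (%) |
| `vj_pad` | 20 | padding of the V–J window for D search (bp) |
| `window_bp` | 50 | consensus-correction window (bp) |
| `shm_identity_pct` | 85 | SHM / novelty bar, strict less-than (%) |
| `min_support` | 2 | reads required for a novel candidate |
| `min_frequency` | 0 | clonotype report floor |

All are CLI flags or YAML config keys; unknown keys are rejected.

## Known limitations

- Alignment is O(read × segment) full DP; large databases or very long
  reads cost proportionally (the benchmarks run minutes on one CPU).
- Correction in alignment-free mode cannot separate co-located clones
  (see above); with a BAM the genomic start restores locality.
- Only the best call per class is reported; no secondary-hit or allele
  phasing output.
- The 85% novelty bar deliberately conflates heavy SHM with genuinely
  novel alleles; candidates are labelled "putative novel" and not
  adjudicated.
- IMGT gap insertion for arbitrary novel V genes is consumed (gapped
  FASTA) but never computed.
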