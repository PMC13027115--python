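# Methods

## Germline reference model

A reference is a FASTA of V/D/J segments for the four TCR loci (TRA,
TRB, TRG, TRD). Each V segment carries the 0-based offset of its
2nd-CYS codon and each J segment the offset of its junction-closing
Phe/Trp codon; D segments carry sequence only (no anchor model).
Records whose anchor codon does not translate to the expected residue
are excluded and reported rather than silently kept, and a locus that
loses its last V or J fails loudly. When a J segment arrives without
an anchor, it is inferred as the first `[FW]-G-x-G` amino-acid motif,
scanning all three frames and preferring the frame with the longest
stop-free run — deterministic and consistent with how the motif is
used to close junctions. Degenerate bases are rejected in reference
records; in reads, k-mers containing N are simply skipped.

The k-mer index stores forward-strand segment words at k = 15 and is
queried with both strands of each read, giving a strict superset of
any later exact-alignment hit of ≥ k consecutive matches. k = 15 is
the usual read-screen compromise between sensitivity and index size
at desk scale.

## Read simulator

The simulator is first-class, tested code, not a fixture. It emulates
the study design the analytics modules target: `n_patients` patients
split into MSI and MSS groups (default six, three per group), each
sampled in blood, adjacent normal and tumor tissue at Pre and Post
timepoints. Per sample it draws `n_clonotypes_per_sample` (default
20) productive rearrangements:

* **Segment choice** is biased: per-(locus, segment-type) usage
  weights are drawn once per run from a skewed Dirichlet
  (`usage_bias_strength`, default 1.5) or supplied explicitly —
  real repertoires show strongly non-uniform V/J usage.
* **Junction formation** trims up to 3 nt from the 3' V and 5' J ends
  and inserts Poisson(4) random N-nucleotides (twice around the D
  fragment for TRB/TRD), then redraws until the junction is in-frame,
  stop-free and passes the chain-specific CDR3 filter — clones are
  productive by construction, matching what the truth table promises
  downstream.
* **Clone sizes** follow a geometric law (default p = 0.6), a zipf
  law, or a constant — the geometric default gives the skewed,
  singleton-dominated size spectrum typical of blood repertoires.
* **Sharing structure**: a configurable fraction (default 0.1) of
  clonotype draws comes from a cross-patient public pool whose members
  keep identical V/J and junction everywhere, creating controllable
  private / intra-group / inter-group sharing and convergent (public)
  clones.
* **Reads**: each cell's chain is tiled by `reads_per_cell_chain`
  evenly spaced `read_length`-mers with per-base substitution
  probability `error_rate`; mate 1 carries barcode+UMI, mate 2 the
  cDNA (a flag instead writes single-end FASTQ with the barcode
  already embedded in the ID, exercising the second demux path).
  Qualities are constant.

All randomness flows through one seeded generator; identical config
and seed give byte-identical output files (sample sheets reference
FASTQ files by relative name for exactly this reason).

What the simulator does **not** model: PCR duplication, 5'/3' coverage
bias, indel sequencing errors (substitution-only by default), quality
score realism, doublets, or chain pairing within cells (each clonotype
is one chain). Passing round-trip tests therefore demonstrates
correctness of the pipeline's bookkeeping and algorithms under clean
assumptions, not performance on real droplet data.

The bundled synthetic germline reference places the 2nd-CYS 15 nt
before each V end; TRB/TRD V segments encode C-A-S-S at the anchor
and TRB/TRD J segments close on Phe, so that productive-by-construction
junctions can satisfy the beta/delta motif filter. It is a synthetic
stand-in with realistic anchor structure, not a copy of any germline
database; real analyses should load their own reference FASTA.

## Reconstruction pipeline

The stages replace the external aligner/assembler/annotator of
industrial pipelines with small, dependency-free, testable internals;
fidelity to any specific external binary is not claimed.

* **Screen**: a read is kept iff some segment shares a k-mer with it
  and a local alignment (match +1, mismatch −1, gap −2, via
  Biopython's PairwiseAligner) on either strand scores ≥ `min_score`
  (default 25). Retained reads carry their best-locus hint.
* **Embedding / demux**: read IDs become `<barcode>:<umi>:<id>`; both
  mates of a pair receive the identical prefix; parsing splits on the
  first two colons only, so original IDs containing ':' survive a
  round trip. Reads with N in the barcode are dropped and counted.
  UMIs are carried but deliberately not used for consensus; exact
  duplicate reads are collapsed before assembly.
* **Assembly** is greedy overlap-consensus per barcode group: after
  deduplication the pair of sequences with the longest suffix–prefix
  overlap ≥ `min_overlap` (default 20) with ≤ `max_mismatch` (default
  2) mismatches is merged, both orientations considered, consensus
  taken from the higher-support sequence, until no merge remains.
  Reads are processed in lexicographic order, making results
  independent of input order. An exhaustive merge-order oracle
  (feasible to ≤ 8 reads) backs the unit tests.
* **Annotation**: best local V and J hits over both contig strands fix
  the orientation (V-forward); ties break by identity then segment id.
  When top V hits from different loci score within `locus_margin`
  (default 5) of each other the locus is taken from the J call and the
  record flagged ambiguous — germline V segments of the α and δ loci
  cross-align often enough that the J gene is the more reliable locus
  witness. CDR3 boundaries are projected from the germline anchor
  offsets through the alignment blocks, extrapolating colinearly when
  an anchor falls outside the aligned region (exact whenever the flank
  is gap-free).
* **Productive call**: V and J present, CDR3 length divisible by 3,
  stop-free, and motif-valid. This conjunction is a design choice of
  this package; the motif rules themselves are: TRA/TRG start `C`, end
  `F`/`W`; TRB/TRD start `CASS`, end `F`. The CASS requirement for TRD
  is biologically unusual (δ junctions frequently begin `CACD…`); it
  is kept as the strict default with an explicit `relaxed` mode
  (`C…F`) because which convention a given reference set needs is a
  property of the data, not the code.

## Clonotype analytics

Clonotype key = (locus, allele-stripped V gene, CDR3 amino acids).
Allele calls from short RNA reads are unreliable, so `TRBV27*01` and
`*02` collapse to `TRBV27`. α and β (and γ, δ) chains define
independent keys; a cell carrying two productive chains of one locus
contributes to both keys, once each. Sharing classes partition
clonotypes by carrier patients (private / intra-group / inter-group);
the classifier accepts any locus.

Descriptive summaries: CDR3 length histograms (modal length, ties to
the smaller length), position-specific residue frequencies with
information content `IC_j = log2 20 − H_j` bits and no small-sample
correction (the quantity a sequence logo displays; pseudocounts would
only obscure the small test sets used here), V–J pairing counts
restricted to the top-N V genes, and a top-shared-clonotype selection
(rank by patient count, then total cells, then CDR3) optionally
restricted to clones present in both normal and tumor tissue, with
per-(group, tissue) patient counts exported for Sankey-style plots.

## Repertoire statistics

* Clonality uses `k = max(1, ⌊0.1 n⌋)` — the floor reading of the
  bracket, configurable to round. The denominator is total cells, the
  reading consistent with "cumulative frequency".
* Diversity is unique clonotypes over total cells.
* CEI is the mean of per-clonotype frequencies. With frequencies as
  proportions this is algebraically 1/N regardless of skew; the
  collapse is a property of the definition and is documented and
  asserted, not "fixed". A count mode (mean clone size) is provided
  alongside.
* E and Δ are log2 ratios of abundances; the default pseudocount is 0
  with an explicit error on zero counts — silently shifting a printed
  formula is worse than refusing. Raw cell counts are the default
  abundance; proportions can be passed instead.
* The treatment-effect contrast (ΔTumor − ΔNormal) is exposed as a
  derived table and is antisymmetric under swapping tissue labels.
* Group comparisons delegate to scipy (Student's t, Mann–Whitney U;
  exact rank-sum null when both groups have ≤ 8 values) and
  Benjamini–Hochberg FDR to statsmodels.

## Benchmark harness

Matching is per cell barcode and locus; equality classes are disjoint,
so maximum bipartite matching reduces to pairing within classes with
each reference chain consumed at most once. Three modes of decreasing
strictness on the junction: exact CDR3 nucleotides, exact CDR3 amino
acids, amino acids + V/J genes; all three are reported because
published overlap counts rarely pin the mode down. Overlap is reported
against both sets (matched/reference and matched/query), recall as
identified/total reads, and precision as true positives over total
identified — positive predictive value. An "accuracy" variant with
true negatives in the denominator circulates in the literature but is
not a precision; this package implements only TP/identified and says
so. Percentages are rounded half-up to two decimals at the reporting
layer only.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline on a
two-patient, three-tissue, two-timepoint design with 20 clonotypes per
sample and six error-free tiling reads per chain (~240–400 cells,
~2000–2500 read pairs) — large enough to exercise sharing structure,
clone-size skew and every pipeline stage, small enough to finish in
seconds. Under these conditions the pipeline recovers 100% of truth
junctions; the round-trip test asserts ≥ 95% to leave room for
benign seed-to-seed variation in junction composition.

Tie-breaks are deterministic throughout: segment hits by (score,
identity, id), assembler merges by (overlap length, sequence order),
clonotype ids by sorted key, ranking by (patients, cells, CDR3).
Degenerate inputs raise (`ValueError`) rather than return silent
defaults: empty clone lists, zero denominators, mixed-length logo
input, desynchronized mate files.

## Known limitations

* The greedy assembler is exact for clean tiling reads but has no
  error-correction beyond majority consensus in overlaps; highly
  uneven coverage or indel errors will fragment contigs.
* Anchor projection extrapolates outside aligned blocks assuming no
  gaps in the flank; long indels between the anchor and the aligned
  region would misplace the CDR3 boundary.
* Constant-region sequence, BCR loci, somatic hypermutation and
  paired-chain (αβ) clonotype units are out of scope.
* Study-scale quantities (cohort clonotype totals, recall/precision on
  real droplet data, cohort p-values) depend on restricted raw data and
  are not reproduced here; the formulas that produce them are covered
  by the property and round-trip suites instead.
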