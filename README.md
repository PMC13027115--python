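# tcrkit

Reconstruction and analysis of T-cell receptor (TCR) repertoires from
barcoded single-cell sequencing reads.

T cells recognise antigens through receptors assembled by somatic
V(D)J recombination; the hypervariable CDR3 junction — spanning the
conserved V-segment cysteine to the conserved J-segment
phenylalanine/tryptophan — is the principal determinant of
specificity. `tcrkit` rebuilds these chains cell by cell from raw
reads and quantifies the clonal architecture of the resulting
repertoire: who shares which clones, how concentrated each sample's
repertoire is, and how clones redistribute between blood, normal and
tumor tissue before and after treatment. It is aimed at
immunogenomics analysts who need a transparent, fully testable
alternative to black-box reconstruction pipelines, and ships a
multi-patient V(D)J read simulator so every stage can be validated
offline against ground truth.

## What it computes

**Reconstruction.** Reads are screened for TCR origin against a
germline V/D/J reference (shared k-mers plus Smith–Waterman at
+1/−1/−2), the cell barcode and UMI are embedded into read IDs
(`<barcode>:<umi>:<id>`), reads are clustered per cell, each cell's
reads are assembled by greedy overlap-consensus, and contigs are
annotated by projecting the germline anchor codons through the best
V and J alignments:

    CDR3 = contig[2nd-CYS codon .. J-PHE/TRP codon]

A chain is productive when V and J are called, the junction is
in-frame and stop-free, and the chain-specific motif rule holds
(TRA/TRG: `C…F/W`; TRB/TRD: `CASS…F`).

**Clonotypes and sharing.** A clonotype is (locus, allele-stripped V
gene, CDR3 amino-acid sequence). Across patients, clonotypes are
private (one patient), intra-group shared (several patients, one
group) or inter-group shared.

**Repertoire statistics**, per sample with clone sizes
`Clones_i` ranked descending, `n` unique clonotypes and
`Total_Clones` total cells:

    clonality = Σ_{i≤k} Clones_i / Total_Clones,  k = max(1, ⌊0.1·n⌋)
    diversity = Unique_Clones / Total_Clones
    CEI       = (1/N) Σ R_i
    E         = log2(T_pre / N_pre)      (tissue enrichment)
    Δ         = log2(T_post / T_pre)     (tumor response)

**Benchmarking.** Reconstructed chains are matched per cell and locus
against a reference chain set (exact CDR3 nucleotides, CDR3 amino
acids, or amino acids + V/J genes), yielding overlap rates against
both sets, read-screen recall, and per-component (V / J / D / CDR3)
precision.

## Worked example

```python
from tcrkit import RunConfig, SimConfig, run_end_to_end

config = RunConfig(
    outdir="demo",
    seed=42,
    sim=SimConfig(seed=42, n_patients=2, n_clonotypes_per_sample=20,
                  error_rate=0.0),
)
run_end_to_end(config)
```

This simulates two patients (one MSI, one MSS) sampled in blood,
normal and tumor tissue pre- and post-treatment, reconstructs every
cell, and writes `demo/benchmark.tsv`:

```
 match_mode  n_reference  n_query  n_matched  overlap_vs_reference_pct  ...  precision_cdr3_pct
junction_nt          402      402        402                     100.0  ...               100.0
junction_aa          402      402        402                     100.0  ...               100.0
 gene_level          402      402        402                     100.0  ...               100.0
```

At error rate 0 with six tiling reads per chain all 402 simulated
chains are recovered with exact junctions, so every rate is 100%.
`demo/sample_metrics.tsv` then carries the per-sample statistics, e.g.

```
    sample_id  n_unique  total_clones  clonality  diversity      cei  k_used
 P1_blood_Pre        18            34   0.147059   0.529412 0.055556       1
P1_blood_Post        20            31   0.225806   0.645161 0.050000       2
```

— 18 unique clonotypes over 34 cells in the first sample: the largest
clone holds 5 of 34 cells (clonality ≈ 0.15), diversity 18/34 ≈ 0.53,
and CEI in proportion mode is 1/18 ≈ 0.056.

The same stages are exposed on the command line:

```
tcrkit simulate --outdir sim --seed 42
tcrkit embed --r1 sim/P1_blood_Pre_R1.fastq --r2 sim/P1_blood_Pre_R2.fastq --out emb.fastq
tcrkit assemble --fastq emb.fastq --out contigs.fasta
tcrkit annotate --contigs contigs.fasta --out chains.tsv --seed 42
tcrkit metrics --annotations chains.tsv --samples sim/samples.tsv
tcrkit benchmark --n-reference 6962 --n-query 1026 --n-matched 765
```

The last command prints the overlap arithmetic for a pre-matched
count table:

```
overlap_vs_reference_pct        10.99
overlap_vs_query_pct    74.56
```

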