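# ampliconcn

Copy-number estimation for highly similar multi-copy gene families from
whole-genome sequencing read depth — with a bundled simulator that makes the
whole method testable end to end on synthetic data.

## The problem

Ampliconic gene families on the human Y chromosome (*TSPY*, *RBMY*, *VCY*,
*DAZ*, …) consist of copies that are >99% identical to one another, arranged
in palindromes and tandem arrays. Standard variant callers cannot genotype
them: short reads map ambiguously among the copies, so per-copy evidence is
smeared across the family. Yet family-level copy number varies between men
and matters for spermatogenesis phenotypes. `ampliconcn` estimates the copy
number of each family from aggregate read depth, sidestepping the
read-assignment problem entirely.

## The method

Two stages, run once per reference and once per sample:

**Build** — decide where depth is interpretable.

* *Control positions*: positions on the target chromosome whose k-mer
  (k = 101, the shortest read length) occurs nowhere else in the genome
  within 2 substitutions on either strand, outside annotated repeats and
  outside annotated gene copies. Depth here calibrates copy number 1.
* *Informative positions*: positions inside an annotated gene copy whose
  k-mer (1) lies outside repeats, (2) matches only locations inside its own
  family (≤ 2 mismatches, at most 15 alignments kept per k-mer), and
  (3) matches exactly once per copy — the number of alignments equals the
  number of genes in the family. Depth here scales linearly with the
  family's true copy number even though individual reads are unassignable.

**Count** — turn depth into copy numbers. Alignments are kept only if they
are part of a properly mapping pair with ≥ 88 perfect matches in the first
90 read bases. The per-position statistic is the *start-depth* `D_i`, the
number of retained alignments starting at `i`. Depth is GC-corrected
against the control baseline: control depths are binned by the GC fraction
of the 501-bp window centred on each position (100 bins), and with bin
means `μ_b` and global control mean `μ`, the corrected depth is
`μ·D_i/μ_b`. Then

```
gene copy   = mean corrected depth over the gene's informative sites / μ
family copy = Σ gene copies
```

Samples with ≥ 2 families near zero, or several single-copy (X-degenerate)
genes well below 1, are flagged by QC.

**Simulator** — synthetic Y-like references (tandem arrays of >99%-identical
50-kb amplicon units between long unique flanks, repeat intervals,
single-copy genes), error-free 101-bp read pairs with 260-bp outer distance,
and a minimal exact-placement aligner, so the estimator can be validated
against known truth without any external data.

## Worked example

`examples/02_copy_number_from_reads.py` simulates a sample carrying **5**
copies of a family against a reference annotated with **3** copies, then runs
the full pipeline:

```
simulated 23,638 error-free 101-bp pairs at 25x

control mean depth (copy-number-1 baseline): 0.249
family  n_genes  n_genes_used  family_copy_count
   FAM        3             3           4.872727
  XDG1        1             1           1.027341
  XDG2        1             1           0.982084
  XDG3        1             1           0.915248
sample QC: PASS
```

The family estimate 4.87 rounds to the true 5: reads from all five sample
copies pile onto the three annotated reference copies, and informative-site
depth relative to the control baseline recovers the total. The single-copy
`XDG` genes print ≈ 1 (sampling noise of a few percent at this small scale)
and the sample passes QC. The other examples build site tables
(`01_build_site_tables.py`) and run a one-set validation experiment
(`03_validation_experiment.py`).

The same pipeline is available from the shell:

```
ampliconcn simulate --families TSPY:22,RBMY:7,VCY:4 --coverage 30 --out sim/
ampliconcn build  --fasta ref.fa --genes genes.bed --repeats repeats.bed \
                  --target-chrom chrY --out build/ref
ampliconcn count  --bam sample.bam --fasta ref.fa --genes genes.bed \
                  --build build/ref --out sample.cn.tsv
ampliconcn validate --sets 1,2,3 --coverage 30 --out report.tsv
```

`count` accepts any coordinate-sorted SAM/BAM with MD or NM tags (e.g. from
BWA-MEM), not only the bundled aligner's output.

## Limitations

Copies diverged enough to carry >2 substitutions per 101-mer lose
informative sites; an unannotated near-identical paralog elsewhere in the
genome (the *VCX*/*VCY* situation) suppresses informative sites and biases
the family's estimate low. Sub-gene deletions and duplications are not
resolved — the estimate is a family-level dosage. See `docs/methods.md` for
the model, parameter choices and what the synthetic validation does and does
not establish.
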