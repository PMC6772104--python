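# Methods

## Model

The estimator treats sequencing as uniform sampling of read start positions:
at genome-wide start rate `r`, a position present in `C` copies in the
sample but represented once in the reference receives, in expectation, `C·r`
alignment starts, because every read from every copy must align *somewhere*
among the reference copies of the family. Copy number is therefore a ratio
of depths:

* `μ` — mean start-depth over **control** positions (unique k-mer, outside
  repeats and outside annotated gene copies) estimates `r`, the depth of
  copy-number-1 sequence.
* For each gene, the mean GC-corrected start-depth over its **informative**
  positions, divided by `μ`, estimates the number of sample copies whose
  reads aggregate at that gene; summing over the family's genes gives the
  family copy number.

The estimate is conservation-based, not assignment-based: it never decides
which copy a read came from, only that family-specific k-mer positions
capture all of the family's reads and nothing else. This is what makes it
robust to the >99% copy identity that defeats per-copy genotyping. The two
site classes enforce the capture property:

* control uniqueness uses a substitution-only (Hamming) edit budget of 2 on
  k = 101-mers, both strands — within the mismatch tolerance of the
  alignment filter, so that reads over control positions cannot have a
  second placement;
* informative positions require that every ≤2-mismatch match of the k-mer
  falls inside the family's annotated copies (specificity) and that the
  number of matches equals the number of copies (exactly once per copy);
  hit lists are capped at 15 per k-mer, so families with more than 15
  reference copies cannot yield informative sites.

### Alignment filter and depth statistic

Only primary, non-duplicate alignments in properly mapping pairs with at
least 88 perfect matches among the first 90 *read* bases (read orientation;
soft-clips, insertions and mismatches count as non-matches, deletions
consume no read bases) are retained. Reads shorter than 90 bp are discarded
with a warning. The depth at `i` is the number of retained alignments whose
leftmost position is `i`; repeat-masked positions are undefined, not zero.

### GC correction

Depth is corrected multiplicatively per GC stratum: control positions are
binned by the GC percentage of the 501-bp window centred on them (100 bins,
bin index `min(floor(gc·100/100), 99)`; windows truncated at chromosome ends
use the available bases, all-N windows are undefined), and corrected depth
is `μ·D_i/μ_b`. Two degenerate cases need a rule the formula does not give:
bins with no control position borrow `μ_b` from the nearest populated bin
(ties resolve toward lower GC — deterministic and conservative for the
AT-rich windows it mostly affects), and populated bins with `μ_b = 0` make
their positions undefined rather than infinite, with a warning. By
construction the mean corrected depth over the control set equals `μ`
exactly; the test suite asserts this identity at 1e-9 relative tolerance.

### Copy calls and QC

Genes with no usable informative position produce a *missing* estimate and
are excluded from the family sum — a family that is genuinely deleted shows
near-zero depth at sites that exist, which is distinguishable from sites not
existing. Sample-level QC fails when ≥ 2 families fall below 0.5 copies or
≥ 3 single-copy genes fall below 0.75 copies; the rule's structure follows
the published sample-exclusion criterion, the numeric thresholds are this
package's defaults (the source gives none) and are configurable.

## k-mer engine

Uniqueness and hit enumeration reduce to one primitive: all genome locations
(either strand) whose k-mer lies within a Hamming budget of a query k-mer.
The engine splits each k-mer into `budget+1` contiguous chunks (34/34/33 for
k = 101, budget 2); any qualifying match shares at least one chunk exactly
(pigeonhole), so exact chunk matches — found via a position-normalised
rolling polynomial hash over the concatenated genome, sorted once per chunk
length — generate candidates that a vectorised full-width comparison then
verifies. The scan is exact: the test suite proves equality with a naive
all-pairs Hamming scan on small genomes, including reverse-complement hits,
N handling and the ≤2-vs-3-substitution boundary. Substitution-only
matching (no indels) is used consistently for uniqueness, informative-site
selection and the alignment filter; an indel near a site shifts every
subsequent comparison and would in practice remove the site, a known
limitation shared with the mismatch-counting semantics of the original
pipeline's tools.

Hash collisions cannot create false matches (verification is exact) and
cannot hide true matches (equal substrings hash equally); they only cost
time. Inter-chromosome gaps of ≥ k N's plus per-position chromosome ids
prevent windows from spanning sequence boundaries.

## Minimal aligner

The bundled aligner places error-free (or lightly mutated) simulator reads:
candidates from the same chunk-hash machinery, full-width verification, then
joint mate pairing — among forward/reverse combinations on one chromosome
within the expected outer distance, the pair with the fewest total
mismatches wins and ties break uniformly at random (seeded). It is
guaranteed to find every placement with ≤ 2 mismatches and finds
higher-mismatch placements whenever one chunk is exact. It emits full-length
match alignments with NM/MD and proper-pair flags, writable as
coordinate-sorted SAM via pysam. It is a simulation component, not a
general-purpose aligner: no indels, no soft-clipping, no quality awareness.

## Synthetic data: what it emulates, and what it does not

`build_synthetic_reference` assembles a Y-like target chromosome: a long
unique left flank containing annotated short-tandem-repeat blocks, one
tandem array per family (copies directly adjacent, as in real amplicon
arrays), unique inter-family spacers, single-copy "X-degenerate-like" genes
(truth = 1, used by QC), a unique right flank, and optionally a diverged
unannotated paralog on a decoy chromosome to model the *VCX*/*VCY*
confound. Copies are drawn by mutating a per-family ancestral sequence at a
divergence of 0.002 substitutions/bp, keeping pairwise copy identity
comfortably >99% while leaving each copy a few distinguishing positions —
the regime the method targets.

Every element is generated from a seed-keyed substream independent of
layout, so references built with the same seed but different copy numbers
share flanks, spacers and common copies byte-for-byte. Validation
references with extra copies *duplicate existing baseline copies*
(`template_copies`) rather than inventing new paralogs: this mirrors a
reference edited by inserting copies of its own genes, and it matters for
bias. If added copies were independent mutants of the ancestral, their
reads would be "generic" and minimum-mismatch placement would concentrate
them on the cleanest reference copies — exactly the copies whose positions
informative-site selection preferentially retains — inflating family
estimates by 1.5–2.5% (measured during development). With duplicated
copies, each read matches its source copy exactly and the estimator is
conservation-unbiased.

Read simulation follows the wgsim geometry: 101-bp pairs, outer distance
drawn per pair from N(260, 25²) (the outer-distance spread is this package's
choice; a tight spread keeps desk-scale genomes properly paired), uniform
fragment placement, error rate 0 by default, mate 2 reverse-complemented,
`n_pairs = round(coverage·genome_length/(2·read_len))`.

Not emulated: sequencing errors beyond a uniform substitution rate, quality
score structure, indels, coverage waviness beyond GC (the GC correction is
therefore exercised as a pass-through plus noise, not as a bias remover),
population polymorphism between sample and reference copies, and genome
scale (megabases, not the 57-Mb Y). Passing the validation shows the
estimator's arithmetic, site selection and conservation logic are correct
under the stated read model; it does not certify accuracy on real
GC-biased, polymorphic, repeat-rich data.

## Scale of the bundled validation

The published validation used 666 million read pairs against the full human
reference. This package replicates the design at desk scale, chosen by a
power analysis so that the claims being checked are statistically resolvable
single-run events:

* amplicon unit length 50 kb (real Y duplication units span ~20 kb–1.45 Mb),
  ~47,000 informative positions per copy;
* flanks 700 kb and spacers 100 kb → a 2.57-Mb baseline target with
  ~1.7 million control positions;
* coverages 30x and 6x as in the source analyses.

For a C-copy family with n informative sites per gene at start rate
`r = coverage/(2·read_len)`, the estimate's standard error is approximately
`√(2C/(n·r))` (the factor 2 from mate-pair clustering) plus a small
control-mean term. At these sizes the worst case (22 copies at 6x) has
SE ≈ 0.17 copies, so the "<0.5 copies" replicate and low-coverage
comparisons sit at ≈ 3σ, and 30x estimates (SE ≈ 0.03–0.09) round to the
truth with large margin. Measured across independent read seeds: 30x SD
0.03/0.01/0.02 copies for the 22/7/4-copy families, 6x SD 0.16/0.06/0.04.
One build-plus-count cycle takes ~50 s on one CPU; the full three-set
validation about five minutes.

## Numerical and tie-break conventions

* Coordinates are 0-based half-open everywhere internally; SAM converts on
  read/write.
* Hit lists order by (chromosome order, position) before the 15-hit cap;
  the self-hit is always retained.
* Aligner ties break uniformly with a generator seeded per run; build
  artifacts are byte-identical across reruns with identical inputs.
* k-mers containing N are non-unique, non-informative and never control;
  N in a candidate window mismatches everything.
* Sub-seeds derive from the user seed via `SeedSequence([seed, tags…])`,
  keeping streams independent and reproducible.

## Known limitations

* Family annotation is an input; the package does not discover
  high-identity pseudogene copies itself.
* Families with more than 15 reference copies yield no informative sites
  under the default hit cap (raise `max_hits` deliberately if needed).
* Substitution-only matching: indel polymorphism between copies or between
  sample and reference degrades site counts silently (warnings fire only
  when a family loses *all* sites).
* The X-degenerate control alternative is supported only as a user-supplied
  control set semantics-free; it is not modelled.
* Sub-gene CNVs are out of scope; the estimate is family-level dosage.
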