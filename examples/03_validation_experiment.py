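"""Run a scaled-down version of the simulation validation end to end.

Builds site tables once on a baseline reference, then for one copy
configuration simulates reads from an *edited* reference (extra copies of the
baseline genes), aligns them back to the baseline and compares the family
estimates to the simulated truth.  Uses small genomes so it finishes in
about a minute; the full-size run is `ampliconcn validate` or
scripts/acceptance.py.
"""
from ampliconcn import run_validation_experiment

report = run_validation_experiment(
    sets=(1,),
    coverage=15.0,
    seed=9,
    spec_overrides={"gene_length": 6_000},
    flank_length=80_000,
    spacer_length=15_000,
)
print(report.to_string(index=False))

n_exact = int(report["exact"].sum())
print(f"\n{n_exact}/{len(report)} family copy numbers recovered exactly after rounding")
# Each row compares one family's estimate against the copy number actually
# simulated: TSPY-like 22, RBMY-like 7, VCY-like 4, plus three single-copy
# (X-degenerate-like) genes whose truth is 1.  `abs_error` is in copies.
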