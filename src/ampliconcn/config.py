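"""Run configuration: every tunable with its default, serialised into manifests."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields


@dataclass
class RunConfig:
    """Tunables for the build and count stages.

    Defaults follow the published protocol for 101-bp Illumina reads:
    k-mer length equals the shortest read, the uniqueness/site edit budget is
    two substitutions, up to 15 alignments are kept per k-mer, alignments must
    carry >= 88 perfect matches in their first 90 read bases, and GC content
    is measured over a 501-bp centred window binned into 100 bins.  The QC
    thresholds make the published rule ("close to zero" family estimates,
    "less than one copy" for several single-copy genes) concrete and are
    deliberately configurable.
    """

    k: int = 101
    max_edits: int = 2
    max_mismatches: int = 2
    max_hits: int = 15
    min_matches: int = 88
    prefix_len: int = 90
    gc_window: int = 501
    gc_bins: int = 100
    near_zero_threshold: float = 0.5
    single_copy_floor: float = 0.75
    single_copy_floor_count: int = 3

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
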