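"""Rare-variant filter cascade for dominant-family exome candidates.

Four filters applied in fixed order, each recording per-individual counts
of surviving variants carried by that individual:

1. functional class — drop synonymous (configurable exclusion set);
2. rarity — keep variants with every panel MAF strictly below the cutoff
   AND fewer than ``min_observations`` allele observations in a matched
   control cohort;
3. IBD — keep variants inside the group consensus IBD segments;
4. sharing — keep variants carried (>= 1 alternate allele) by every case.

The final shared list is order-invariant; the counts trace the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

from .ibd import IBDSegment
from .relatedness import CohortSpec

__all__ = [
    "VariantRecord",
    "FilterThresholds",
    "CascadeReport",
    "FUNCTIONAL_VOCABULARY",
    "filter_functional",
    "filter_rare",
    "filter_ibd",
    "filter_shared",
    "run_cascade",
]

FUNCTIONAL_VOCABULARY = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "splice",
        "frameshift",
        "inframe_indel",
        "other",
    }
)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated exonic variant with per-individual genotypes.

    ``genotypes`` maps individual id to alternate-allele dosage 0/1/2, or
    None for missing; ``panel_mafs`` maps reference-panel name to minor
    allele frequency; ``cohort_count`` is the allele observation count in
    the matched control cohort.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    functional_class: str
    panel_mafs: dict[str, float] = field(default_factory=dict)
    cohort_count: int = 0
    genotypes: dict[str, int | None] = field(default_factory=dict)
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_VOCABULARY:
            raise ValueError(
                f"unknown functional class {self.functional_class!r}; "
                f"expected one of {sorted(FUNCTIONAL_VOCABULARY)}"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.panel_mafs.values()):
            raise ValueError("panel frequencies must lie in [0, 1]")
        if self.cohort_count < 0:
            raise ValueError("cohort_count must be non-negative")

    def carried_by(self, individual: str) -> bool:
        """True when the individual has >= 1 alt allele; missing = absent."""
        g = self.genotypes.get(individual)
        return g is not None and g >= 1


@dataclass(frozen=True)
class FilterThresholds:
    maf_cutoff: float = 0.001  # strict <
    cohort: CohortSpec = field(default_factory=CohortSpec)
    classes_excluded: frozenset[str] = frozenset({"synonymous"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_cutoff <= 1.0:
            raise ValueError("maf_cutoff must lie in [0, 1]")
        unknown = set(self.classes_excluded) - FUNCTIONAL_VOCABULARY
        if unknown:
            raise ValueError(f"unknown excluded classes {sorted(unknown)}")


@dataclass(frozen=True)
class CascadeReport:
    """Per-step per-individual survivor counts plus the final shared list."""

    steps: tuple[str, ...]
    counts: dict[str, dict[str, int]]  # step -> individual -> carried count
    shared: tuple[VariantRecord, ...]

    def to_json(self) -> str:
        payload = {
            "steps": list(self.steps),
            "counts": self.counts,
            "n_shared": len(self.shared),
            "shared": [
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "gene": v.gene,
                    "class": v.functional_class,
                    "id": v.variant_id,
                }
                for v in self.shared
            ],
        }
        return json.dumps(payload, indent=2)


def filter_functional(
    variants: list[VariantRecord], thresholds: FilterThresholds = FilterThresholds()
) -> list[VariantRecord]:
    """Drop variants whose functional class is excluded (synonymous by default)."""
    return [v for v in variants if v.functional_class not in thresholds.classes_excluded]


def filter_rare(
    variants: list[VariantRecord], thresholds: FilterThresholds = FilterThresholds()
) -> list[VariantRecord]:
    """Keep variants rare everywhere: every panel MAF strictly below the
    cutoff (absent panel counts as 0) and cohort count below the recurrence
    threshold ("seen at least twice" removes)."""
    out = []
    for v in variants:
        max_maf = max(v.panel_mafs.values(), default=0.0)
        if max_maf < thresholds.maf_cutoff and (
            v.cohort_count < thresholds.cohort.min_observations
        ):
            out.append(v)
    return out


def filter_ibd(
    variants: list[VariantRecord], segments: list[IBDSegment]
) -> list[VariantRecord]:
    """Keep variants inside any group IBD segment (0-based half-open).

    Segments must be sorted by (chrom, start); lookup is by binary search
    per chromosome.
    """
    by_chrom: dict[str, list[IBDSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    starts: dict[str, list[int]] = {}
    for chrom, segs in by_chrom.items():
        if any(b.start < a.start for a, b in zip(segs, segs[1:])):
            raise ValueError(f"segments not sorted by start on {chrom}")
        starts[chrom] = [s.start for s in segs]

    import bisect

    out = []
    for v in variants:
        segs = by_chrom.get(v.chrom)
        if not segs:
            continue
        pos0 = v.pos - 1
        i = bisect.bisect_right(starts[v.chrom], pos0) - 1
        if i >= 0 and pos0 < segs[i].end:
            out.append(v)
    return out


def filter_shared(variants: list[VariantRecord], cases: list[str]) -> list[VariantRecord]:
    """Keep variants carried by every case; missing genotypes count as absent."""
    for v in variants:
        for c in cases:
            if c not in v.genotypes:
                raise KeyError(f"case {c!r} absent from genotype map of {v.variant_id or v.pos}")
    return [v for v in variants if all(v.carried_by(c) for c in cases)]


def run_cascade(
    variants: list[VariantRecord],
    cases: list[str],
    segments: list[IBDSegment],
    thresholds: FilterThresholds = FilterThresholds(),
) -> CascadeReport:
    """Apply the four filters in order, tracing per-individual counts.

    A per-individual count at each step is the number of variants carried
    by that individual (>= 1 alt allele) surviving the cascade so far.
    """
    steps: list[tuple[str, list[VariantRecord]]] = []
    current = list(variants)
    steps.append(("exonic", current))
    current = filter_functional(current, thresholds)
    steps.append(("non_synonymous", current))
    current = filter_rare(current, thresholds)
    steps.append(("rare", current))
    current = filter_ibd(current, segments)
    steps.append(("in_ibd_segments", current))
    shared = filter_shared(current, cases)
    steps.append(("shared", shared))

    counts = {
        name: {c: sum(v.carried_by(c) for v in vs) for c in cases}
        for name, vs in steps
    }
    return CascadeReport(
        steps=tuple(name for name, _ in steps),
        counts=counts,
        shared=tuple(shared),
    )
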