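"""Candidate-gene prioritization inside a CNV interval.

Three prioritization sources are supported and combined by average rank:
comparative expression (affected-tissue / control-tissue ratios on
unit-range-normalized profiles), externally computed gene score tables
(e.g. dosage-sensitivity classifiers or guilt-by-association tools,
ingested as plain score tables), and any other rank table.  Ranks use
1 = best with average ranks on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionProfile",
    "RankTable",
    "normalize_unit_range",
    "collapse",
    "tissue_ratio_rank",
    "rank_scores",
    "aggregate_ranks",
]

RATIO_FLOOR = 1e-6  # floor on control expression after normalization


@dataclass(frozen=True)
class ExpressionProfile:
    """One subject's probe-level expression in one condition."""

    subject: str
    condition: str
    values: dict[str, float]  # probe -> value
    gene_probes: dict[str, tuple[str, ...]]  # gene -> probes

    def genes(self) -> list[str]:
        return list(self.gene_probes)


@dataclass(frozen=True)
class RankTable:
    """Ranked genes from one prioritization source (1 = best)."""

    source: str
    ranks: dict[str, float]
    scores: dict[str, float] | None = None
    imputed: frozenset[str] = frozenset()  # genes given worst-rank imputation

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("rank table is empty")

    @property
    def top_gene(self) -> str:
        return min(self.ranks, key=lambda g: (self.ranks[g], g))

    def ordered(self) -> list[str]:
        return sorted(self.ranks, key=lambda g: (self.ranks[g], g))


def normalize_unit_range(profile: ExpressionProfile) -> ExpressionProfile:
    """Rescale one subject's values to span [0, 1] exactly.

    (x - min) / (max - min); constant profiles are an error because the
    normalization is undefined.  Idempotent and shift/scale invariant.
    """
    vals = np.array(list(profile.values.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError(f"constant profile for subject {profile.subject!r}")
    scaled = {k: (v - lo) / (hi - lo) for k, v in profile.values.items()}
    return replace(profile, values=scaled)


def collapse(
    profiles: list[ExpressionProfile], condition: str
) -> dict[str, float]:
    """Collapse a condition to one value per gene.

    Averaging order matters and is fixed: first mean over subjects within
    the condition (per probe), then mean over a gene's probes.  Genes with
    no probe present in the data are omitted with a warning.
    """
    subset = [p for p in profiles if p.condition == condition]
    if not subset:
        raise ValueError(f"no subjects for condition {condition!r}")
    probe_means: dict[str, float] = {}
    all_probes = {probe for p in subset for probe in p.values}
    for probe in all_probes:
        vals = [p.values[probe] for p in subset if probe in p.values]
        probe_means[probe] = float(np.mean(vals))
    gene_probes = subset[0].gene_probes
    out: dict[str, float] = {}
    for gene, probes in gene_probes.items():
        present = [probe_means[pr] for pr in probes if pr in probe_means]
        if not present:
            warnings.warn(f"gene {gene!r} has no probe in condition {condition!r}",
                          stacklevel=2)
            continue
        out[gene] = float(np.mean(present))
    return out


def _average_ranks_desc(values: dict[str, float]) -> dict[str, float]:
    genes = list(values)
    # rankdata ranks ascending; negate for descending (largest = rank 1)
    ranks = rankdata([-values[g] for g in genes], method="average")
    return {g: float(r) for g, r in zip(genes, ranks)}


def tissue_ratio_rank(
    affected: dict[str, float],
    control: dict[str, float],
    source: str = "expression_ratio",
) -> RankTable:
    """Rank genes by affected/control expression ratio, descending.

    Both inputs are gene -> collapsed value maps on the same gene
    universe; genes missing from either side are dropped (platform
    restriction).  Control values are floored at a small epsilon so that
    zero expression in the control tissue yields a large but finite ratio.
    """
    genes = [g for g in affected if g in control]
    if not genes:
        raise ValueError("no shared genes between conditions")
    ratios = {g: affected[g] / max(control[g], RATIO_FLOOR) for g in genes}
    floored = frozenset(g for g in genes if control[g] < RATIO_FLOOR)
    return RankTable(
        source=source,
        ranks=_average_ranks_desc(ratios),
        scores=ratios,
        imputed=floored,
    )


def rank_scores(scores: dict[str, float], source: str = "scores") -> RankTable:
    """Rank a gene score table descending (ties get average ranks)."""
    if not scores:
        raise ValueError("need at least one scored gene")
    for g, s in scores.items():
        if not isinstance(s, (int, float)) or not np.isfinite(s):
            raise ValueError(f"non-numeric score for {g!r}: {s!r}")
    return RankTable(source=source, ranks=_average_ranks_desc(scores), scores=dict(scores))


def aggregate_ranks(tables: list[RankTable], source: str = "average_rank") -> RankTable:
    """Mean rank per gene across sources, re-ranked ascending.

    The gene universe is the union; a gene missing from a source is
    imputed that source's worst possible rank (its table size) and flagged
    in ``imputed``.
    """
    if not tables:
        raise ValueError("need at least one rank table")
    universe = sorted({g for t in tables for g in t.ranks})
    if not universe:
        raise ValueError("empty gene universe")
    imputed: set[str] = set()
    means: dict[str, float] = {}
    for g in universe:
        vals = []
        for t in tables:
            if g in t.ranks:
                vals.append(t.ranks[g])
            else:
                vals.append(float(len(t.ranks)))
                imputed.add(g)
        means[g] = float(np.mean(vals))
    ranks = rankdata([means[g] for g in universe], method="average")
    return RankTable(
        source=source,
        ranks={g: float(r) for g, r in zip(universe, ranks)},
        scores=means,
        imputed=frozenset(imputed),
    )
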