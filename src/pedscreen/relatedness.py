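"""Closed-form and enumerative pedigree statistics.

Implements exact Cotterman coefficients (k0, k1, k2), the expected fraction
of the autosome at which a *group* of relatives all carry a copy of the same
founder allele (single-allele consensus sharing), and the exact binomial
probability used to justify control-cohort frequency cutoffs.

Exact results come from enumerating meiotic transmission indicators: every
non-founder receives one paternal and one maternal gamete, each determined
by a single bit saying which of the parent's two homologs was transmitted.
A pedigree with m relevant meioses has 2**m equiprobable transmission
patterns; probabilities are counted over all of them.  Beyond
``max_exact_meioses`` the computation falls back to a seeded Monte Carlo
gene drop with a reported standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "RelationshipPrior",
    "CohortSpec",
    "ShareEstimate",
    "relationship_coefficients",
    "expected_all_share_fraction",
    "min_observation_probability",
]

_CHUNK_BITS = 20  # enumerate / simulate in chunks of 2**20 transmission vectors


@dataclass(frozen=True)
class RelationshipPrior:
    """Cotterman coefficients for a non-inbred pair, plus meiotic distance.

    k0, k1, k2 are the probabilities that the pair shares 0, 1 or 2 alleles
    identical by descent at a random autosomal locus; n_meioses is the
    length of the shortest up-then-down path connecting the pair through a
    common ancestor.
    """

    k0: float
    k1: float
    k2: float
    n_meioses: int

    def __post_init__(self) -> None:
        ks = (self.k0, self.k1, self.k2)
        if any(k < -1e-12 or k > 1 + 1e-12 for k in ks):
            raise ValueError("Cotterman coefficients must lie in [0, 1]")
        if abs(sum(ks) - 1.0) > 1e-12:
            raise ValueError("Cotterman coefficients must sum to 1")

    @property
    def kinship(self) -> float:
        return self.k1 / 4 + self.k2 / 2


@dataclass(frozen=True)
class CohortSpec:
    """A control cohort screened for recurrent alleles.

    The default matches a panel of 21 individuals (42 chromosomes) in which
    any allele seen at least twice is treated as too common to be causal.
    """

    n_individuals: int = 21
    min_observations: int = 2

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("cohort needs at least one individual")
        if self.min_observations < 1:
            raise ValueError("min_observations must be >= 1")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals


@dataclass(frozen=True)
class ShareEstimate:
    """Result of a group IBD-sharing computation.

    ``method`` is "enumeration" (exact) or "monte_carlo"; ``se`` is 0 for
    exact results.  ``n_meioses`` counts the transmission indicators that
    were enumerated or simulated.
    """

    value: float
    method: str
    n_meioses: int
    se: float = 0.0
    seed: int | None = None

    def __float__(self) -> float:
        return self.value


# -- transmission-indicator machinery -------------------------------------


def _relevant_closure(ped: Pedigree, ids: set[str]) -> tuple[list[str], list[str]]:
    """Group members plus all their ancestors, split founders/non-founders.

    Non-founders come back in topological (parents-first) order.
    """
    relevant = set(ids)
    for mid in ids:
        relevant |= ped.ancestors(mid)
    topo = [mid for mid in ped.topological_order() if mid in relevant]
    founders = [mid for mid in topo if ped.member(mid).is_founder]
    nonfounders = [mid for mid in topo if not ped.member(mid).is_founder]
    return founders, nonfounders


def _propagate_labels(
    ped: Pedigree,
    founders: list[str],
    nonfounders: list[str],
    bits: np.ndarray,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Follow founder allele-copy labels down the pedigree.

    ``bits`` has shape (n_vectors, 2 * len(nonfounders)); bit (i, 2j) picks
    which homolog non-founder j received from its father, bit (i, 2j+1)
    from its mother.  Returns per member the pair of founder-copy label
    arrays over all transmission vectors.
    """
    n = bits.shape[0]
    labels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for idx, fid in enumerate(founders):
        a = np.full(n, 2 * idx, dtype=np.int16)
        b = np.full(n, 2 * idx + 1, dtype=np.int16)
        labels[fid] = (a, b)
    for j, mid in enumerate(nonfounders):
        m = ped.member(mid)
        pat = _pick(labels[m.father], bits[:, 2 * j])
        mat = _pick(labels[m.mother], bits[:, 2 * j + 1])
        labels[mid] = (pat, mat)
    return labels


def _pick(parent: tuple[np.ndarray, np.ndarray], bit: np.ndarray) -> np.ndarray:
    return np.where(bit == 0, parent[0], parent[1])


def _enumerate_bits(m: int, start: int, stop: int) -> np.ndarray:
    idx = np.arange(start, stop, dtype=np.int64)
    return ((idx[:, None] >> np.arange(m, dtype=np.int64)[None, :]) & 1).astype(np.int8)


def _all_share_indicator(
    labels: dict[str, tuple[np.ndarray, np.ndarray]], group: list[str]
) -> np.ndarray:
    """True where some single founder copy is carried by every group member."""
    first = labels[group[0]]
    share = np.zeros(first[0].shape[0], dtype=bool)
    for cand in first:
        ok = np.ones_like(share)
        for mid in group[1:]:
            a, b = labels[mid]
            ok &= (a == cand) | (b == cand)
        share |= ok
    return share


# -- public operations -----------------------------------------------------


def relationship_coefficients(ped: Pedigree, a: str, b: str) -> RelationshipPrior:
    """Exact Cotterman coefficients for a non-inbred pair, by enumeration.

    Raises :class:`PedigreeError` for unknown ids and an
    ``UnsupportedPedigreeError``-style :class:`PedigreeError` when either
    member is inbred (its parental founder pools overlap) or the pair has
    no common ancestor.
    """
    if a == b:
        raise ValueError("relationship_coefficients needs two distinct members")
    ma, mb = ped.member(a), ped.member(b)
    for m in (ma, mb):
        if not m.is_founder:
            pat_founders = _founder_pool(ped, m.father)
            mat_founders = _founder_pool(ped, m.mother)
            if pat_founders & mat_founders:
                raise PedigreeError(
                    f"member {m.id!r} is inbred; only non-inbred pairs are supported"
                )
    n_meioses = _shortest_meiotic_path(ped, a, b)

    founders, nonfounders = _relevant_closure(ped, {a, b})
    m = 2 * len(nonfounders)
    counts = np.zeros(3, dtype=np.int64)
    for start in range(0, 2**m, 2**_CHUNK_BITS):
        stop = min(start + 2**_CHUNK_BITS, 2**m)
        bits = _enumerate_bits(m, start, stop)
        labels = _propagate_labels(ped, founders, nonfounders, bits)
        (a0, a1), (b0, b1) = labels[a], labels[b]
        n_shared = (
            ((a0 == b0) | (a0 == b1)).astype(np.int8)
            + ((a1 == b0) | (a1 == b1)).astype(np.int8)
        )
        counts += np.bincount(n_shared, minlength=3)
    total = counts.sum()
    return RelationshipPrior(
        k0=counts[0] / total, k1=counts[1] / total, k2=counts[2] / total,
        n_meioses=n_meioses,
    )


def _founder_pool(ped: Pedigree, mid: str) -> set[str]:
    anc = ped.ancestors(mid) | {mid}
    return {x for x in anc if ped.member(x).is_founder}


def _shortest_meiotic_path(ped: Pedigree, a: str, b: str) -> int:
    depths_a = _ancestor_depths(ped, a)
    depths_b = _ancestor_depths(ped, b)
    common = set(depths_a) & set(depths_b)
    if not common:
        raise PedigreeError(f"{a!r} and {b!r} have no common ancestor")
    return min(depths_a[c] + depths_b[c] for c in common)


def _ancestor_depths(ped: Pedigree, mid: str) -> dict[str, int]:
    """Minimal generation counts from *mid* up to each ancestor (self = 0)."""
    depths = {mid: 0}
    frontier = [mid]
    while frontier:
        nxt = []
        for x in frontier:
            m = ped.member(x)
            for parent in (m.father, m.mother):
                if parent is not None and (
                    parent not in depths or depths[x] + 1 < depths[parent]
                ):
                    depths[parent] = depths[x] + 1
                    nxt.append(parent)
        frontier = nxt
    return depths


def expected_all_share_fraction(
    ped: Pedigree,
    group,
    *,
    max_exact_meioses: int = 25,
    mc_draws: int = 1_000_000,
    seed: int | None = None,
) -> ShareEstimate:
    """Probability that all group members share one founder allele copy IBD.

    At a random autosomal locus, each member carries two founder allele
    copies determined by the meiotic transmission pattern; the group
    "shares" when a single founder copy is present in every member.  For a
    grandmother and two grandchildren through different children this is
    1/8; adding the grandmother's first cousin drops it to 1/64.

    Exact enumeration over 2**m transmission vectors is used up to
    ``max_exact_meioses`` relevant meioses; beyond that, a seeded Monte
    Carlo gene drop of ``mc_draws`` transmission vectors is used and the
    binomial standard error is reported.
    """
    group = list(dict.fromkeys(group))
    if not group:
        raise ValueError("group must be non-empty")
    for mid in group:
        ped.member(mid)  # raises for unknown ids
    founders, nonfounders = _relevant_closure(ped, set(group))
    m = 2 * len(nonfounders)
    if len(group) == 1 or m == 0:
        return ShareEstimate(1.0, "enumeration", m)

    if m <= max_exact_meioses:
        hits = 0
        total = 0
        for start in range(0, 2**m, 2**_CHUNK_BITS):
            stop = min(start + 2**_CHUNK_BITS, 2**m)
            bits = _enumerate_bits(m, start, stop)
            labels = _propagate_labels(ped, founders, nonfounders, bits)
            share = _all_share_indicator(labels, group)
            hits += int(share.sum())
            total += share.shape[0]
        return ShareEstimate(hits / total, "enumeration", m)

    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < mc_draws:
        n = min(2**_CHUNK_BITS, mc_draws - done)
        bits = rng.integers(0, 2, size=(n, m), dtype=np.int8)
        labels = _propagate_labels(ped, founders, nonfounders, bits)
        hits += int(_all_share_indicator(labels, group).sum())
        done += n
    p = hits / mc_draws
    se = float(np.sqrt(p * (1 - p) / mc_draws))
    return ShareEstimate(p, "monte_carlo", m, se=se, seed=seed)


def min_observation_probability(maf: float, cohort: CohortSpec) -> float:
    """Exact binomial tail P(X >= min_observations), X ~ Bin(2N, maf).

    The probability that an allele with true frequency ``maf`` is observed
    at least ``cohort.min_observations`` times among the cohort's
    chromosomes.  Used to show that removing alleles seen repeatedly in a
    small control panel carries negligible risk of discarding a rare causal
    variant (< 1e-3 for MAF 0.1% seen twice in 42 chromosomes).
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must lie in [0, 1]")
    n = cohort.n_chromosomes
    k = cohort.min_observations
    if k > n:
        warnings.warn(
            "min_observations exceeds cohort chromosomes; probability is 0",
            stacklevel=2,
        )
        return 0.0
    return float(stats.binom.sf(k - 1, n, maf))
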