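"""LD pruning, pairwise IBD inference by HMM, and consensus segments.

The pipeline mirrors the classic array-based workflow for dominant-family
segment mapping: prune markers to approximate linkage equilibrium with a
sliding-window r² rule, run a continuous-time pair HMM over the pruned
grid to get per-marker posteriors over {IBD0, IBD1, IBD2}, and call group
consensus segments where every case pair has P(IBD >= 1) above threshold,
extending segments to chromosome tips when sharing reaches the first or
last marker.

HMM construction.  Hidden states are the number of alleles a pair shares
IBD; the stationary distribution is the pair's Cotterman vector
(k0, k1, k2).  Transitions over a map distance of d Morgans use the rate
matrix Q = a(1·pi' - I) with a = n_meioses per Morgan, whose matrix
exponential has the closed form

    P(d) = e^(-a d) I + (1 - e^(-a d)) 1 pi',

so the stationary distribution is preserved exactly.  The global rate a
is set so the leave rate out of the one-allele-shared state, a(1 - k1),
equals n_meioses per Morgan, making the expected length of an IBD
segment along a path of m meioses 100/m cM, the first-order Markov
approximation to the true switching process.
Emissions are joint ordered-genotype probabilities given the shared-allele
count under Hardy-Weinberg founder haplotypes, with an epsilon-probability
uniform genotype-replacement error channel; missing genotypes emit 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import GeneticMap
from .relatedness import RelationshipPrior

__all__ = [
    "PruneConfig",
    "IbdHmmConfig",
    "ConsensusConfig",
    "IBDSegment",
    "pairwise_r2",
    "ld_prune",
    "pair_ibd_posterior",
    "consensus_segments",
]


@dataclass(frozen=True)
class PruneConfig:
    """Sliding-window LD pruning parameters (PLINK-style indep-pairwise)."""

    window_size: int = 50
    step: int = 5
    r2_threshold: float = 0.35
    maf_min: float = 0.1

    def __post_init__(self) -> None:
        if not self.window_size >= self.step >= 1:
            raise ValueError("need window_size >= step >= 1")
        if not (0 <= self.r2_threshold <= 1 and 0 <= self.maf_min <= 1):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class IbdHmmConfig:
    prior: RelationshipPrior
    map: GeneticMap
    epsilon: float = 0.01  # per-genotype uniform replacement error

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")


@dataclass(frozen=True)
class ConsensusConfig:
    threshold: float = 0.5  # strict > on P(IBD >= 1)
    tip_extension: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class IBDSegment:
    """A genomic interval shared IBD by a pair or group (0-based half-open)."""

    chrom: str
    start: int
    end: int
    members: tuple[str, ...] = ()
    mean_posterior: float = 1.0
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment needs start < end")
        if not 0.0 <= self.mean_posterior <= 1.0:
            raise ValueError("posterior must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


# -- LD pruning ------------------------------------------------------------


def pairwise_r2(dose_a: np.ndarray, dose_b: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1/2 dosages over shared non-missing samples.

    Missing genotypes are NaN.  Zero variance at either marker is defined
    as r² = 0 (with a warning) so monomorphic markers never block pruning.
    """
    a = np.asarray(dose_a, dtype=float)
    b = np.asarray(dose_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < 2:
        raise ValueError("need at least two non-missing genotype pairs")
    a, b = a[keep], b[keep]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        warnings.warn("zero variance at a marker; defining r^2 = 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: pd.DataFrame,
    markers: pd.DataFrame,
    config: PruneConfig = PruneConfig(),
) -> list[str]:
    """Greedy windowed r² pruning; returns retained marker ids in order.

    ``genotypes`` is markers x samples (dosage 0/1/2, NaN missing) indexed
    by marker id; ``markers`` has columns id, chrom, pos, freq and must be
    position-sorted within chromosome.  Markers with MAF <= maf_min are
    dropped first; then a window of ``window_size`` markers slides by
    ``step`` and the later member of any pair with r² > r2_threshold is
    removed, permanently.
    """
    for chrom, sub in markers.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError(f"markers not position-sorted on {chrom}")
    maf = np.minimum(markers["freq"].to_numpy(), 1 - markers["freq"].to_numpy())
    kept_ids: list[str] = []
    dose = genotypes.to_numpy(dtype=float)
    id_to_row = {mid: i for i, mid in enumerate(genotypes.index)}
    for chrom, sub in markers.groupby("chrom", sort=False):
        ids = [
            mid
            for mid, m in zip(sub["id"], maf[sub.index.to_numpy()])
            if m > config.maf_min
        ]
        alive = {mid: True for mid in ids}
        start = 0
        while start < len(ids):
            window = ids[start : start + config.window_size]
            live = [m for m in window if alive[m]]
            # greedy: for each ordered pair, drop the later marker
            i = 0
            while i < len(live):
                j = i + 1
                while j < len(live):
                    r2 = pairwise_r2(
                        dose[id_to_row[live[i]]], dose[id_to_row[live[j]]]
                    )
                    if r2 > config.r2_threshold:
                        alive[live[j]] = False
                        live.pop(j)
                    else:
                        j += 1
                i += 1
            if start + config.window_size >= len(ids):
                break
            start += config.step
        kept_ids.extend(m for m in ids if alive[m])
    return kept_ids


# -- pair HMM --------------------------------------------------------------


def _emission_tables(freqs: np.ndarray) -> np.ndarray:
    """Joint ordered-genotype probabilities per IBD state.

    Returns array (n_markers, 3 states, 3 geno_a, 3 geno_b).  Generative
    model per marker with alt-allele frequency p: under IBD0 the pair's
    four allele draws are independent Bernoulli(p); under IBD1 the pair is
    (x, y), (x, z); under IBD2 both are (x, y).
    """
    p = np.asarray(freqs, dtype=float)
    q = 1 - p
    hw = np.stack([q * q, 2 * p * q, p * p], axis=1)  # (n, 3)
    n = p.size
    tables = np.zeros((n, 3, 3, 3))
    # IBD0: independent HWE genotypes
    tables[:, 0] = hw[:, :, None] * hw[:, None, :]
    # IBD1/IBD2: enumerate shared/private allele draws
    for x in (0, 1):
        px = np.where(x, p, q)
        for y in (0, 1):
            py = np.where(y, p, q)
            ga = x + y
            tables[:, 2, ga, ga] += px * py
            for z in (0, 1):
                pz = np.where(z, p, q)
                gb = x + z
                tables[:, 1, ga, gb] += px * py * pz
    return tables


def _error_matrix(epsilon: float) -> np.ndarray:
    return (1 - epsilon) * np.eye(3) + epsilon / 3.0


def pair_ibd_posterior(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    markers: pd.DataFrame,
    config: IbdHmmConfig,
) -> pd.DataFrame:
    """Forward-backward posterior over shared-allele count at each marker.

    ``markers`` needs columns chrom, pos, freq (same grid for both
    members, position-sorted); genotypes are dosage 0/1/2 with NaN
    missing, which emits 1 (uninformative).  When the prior has k2 = 0 the
    two-allele state is removed from the chain.  Returns a DataFrame with
    columns ibd0, ibd1, ibd2 whose rows sum to 1.
    """
    if "freq" not in markers.columns:
        raise ValueError("markers need a 'freq' column")
    prior = config.prior
    ks = np.array([prior.k0, prior.k1, prior.k2])
    states = [0, 1, 2] if prior.k2 > 0 else [0, 1]
    pi = ks[states]
    pi = pi / pi.sum()
    # scale a so the leave rate out of IBD1, a * (1 - pi_1), equals
    # n_meioses per Morgan (IBD segment mean length 100/m cM); degenerate
    # priors (k0 = 0 or k0 = 1) never switch
    if 0.0 < prior.k0 < 1.0:
        a_rate = prior.n_meioses / prior.k0
    else:
        a_rate = 0.0

    ga = np.asarray(geno_a, dtype=float)
    gb = np.asarray(geno_b, dtype=float)
    n = len(markers)
    if ga.shape[0] != n or gb.shape[0] != n:
        raise ValueError("genotype vectors must match the marker grid")

    tables = _emission_tables(markers["freq"].to_numpy())  # (n, 3, 3, 3)
    err = _error_matrix(config.epsilon)
    # observed emission: sum over true genotypes through the error channel
    tables = np.einsum("nsab,ca,db->nscd", tables, err, err)

    emis = np.ones((n, len(states)))
    obs_a = np.where(np.isnan(ga), 0, ga).astype(int)
    obs_b = np.where(np.isnan(gb), 0, gb).astype(int)
    miss_a, miss_b = np.isnan(ga), np.isnan(gb)
    for si, s in enumerate(states):
        e = tables[np.arange(n), s, obs_a, obs_b]
        # marginalize missing genotypes: emission integrates to the
        # marginal of the observed one, or exactly 1 when both missing
        e_a = np.einsum("nb->n", tables[np.arange(n), s, obs_a, :])
        e_b = np.einsum("na->n", tables[np.arange(n), s, :, obs_b])
        e = np.where(miss_a & miss_b, 1.0, np.where(miss_a, e_b, np.where(miss_b, e_a, e)))
        emis[:, si] = e

    post = np.zeros((n, len(states)))
    chrom_col = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy(dtype=float)
    for chrom in pd.unique(chrom_col):
        idx = np.where(chrom_col == chrom)[0]
        d = np.diff(pos[idx]) * config.map.map_rate / 1e8  # Morgans
        post[idx] = _forward_backward(emis[idx], pi, a_rate, d)

    out = pd.DataFrame(0.0, index=markers.index, columns=["ibd0", "ibd1", "ibd2"])
    for si, s in enumerate(states):
        out.iloc[:, s] = post[:, si]
    return out


def _forward_backward(
    emis: np.ndarray, pi: np.ndarray, a_rate: float, d_morgans: np.ndarray
) -> np.ndarray:
    n, k = emis.shape
    stay = np.exp(-a_rate * d_morgans)  # (n-1,)
    alpha = np.zeros((n, k))
    scale = np.zeros(n)
    alpha[0] = pi * emis[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        s = stay[t - 1]
        pred = s * alpha[t - 1] + (1 - s) * pi  # rows of P(d) are s*I + (1-s)*pi
        alpha[t] = pred * emis[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.ones((n, k))
    for t in range(n - 2, -1, -1):
        s = stay[t]
        nxt = emis[t + 1] * beta[t + 1]
        beta[t] = s * nxt + (1 - s) * float(pi @ nxt)
        beta[t] /= beta[t].max()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


# -- consensus segments ----------------------------------------------------


def consensus_segments(
    posteriors: dict[tuple[str, str], pd.DataFrame],
    markers: pd.DataFrame,
    gmap: GeneticMap,
    config: ConsensusConfig = ConsensusConfig(),
    members: tuple[str, ...] | None = None,
) -> list[IBDSegment]:
    """Group segments where every pair's P(IBD >= 1) exceeds the threshold.

    A marker is shared iff P(IBD1) + P(IBD2) > threshold (strict) for
    every pair; maximal runs of shared markers become 0-based half-open
    segments spanning first to last shared marker.  With tip extension, a
    run touching the first (last) marker of a chromosome is extended to
    the chromosome start (end) taken from the genetic map.
    """
    if not posteriors:
        raise ValueError("need at least one pair posterior")
    n = len(markers)
    shared = np.ones(n, dtype=bool)
    mean_p = np.zeros(n)
    for pair, post in posteriors.items():
        if len(post) != n:
            raise ValueError(f"posterior for {pair} is not on the marker grid")
        p_ibd = post["ibd1"].to_numpy() + post["ibd2"].to_numpy()
        shared &= p_ibd > config.threshold
        mean_p += p_ibd
    mean_p /= len(posteriors)
    if members is None:
        members = tuple(sorted({m for pair in posteriors for m in pair}))

    segments: list[IBDSegment] = []
    chrom_col = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    for chrom in pd.unique(chrom_col):
        idx = np.where(chrom_col == chrom)[0]
        sh = shared[idx]
        runs = _runs(sh)
        for lo, hi in runs:  # half-open in marker indices
            first, last = idx[lo], idx[hi - 1]
            start = int(pos[first]) - 1  # 1-based marker -> 0-based start
            end = int(pos[last])
            if config.tip_extension:
                if lo == 0:
                    start = 0
                if hi == idx.size:
                    end = gmap.length_bp(chrom)
            segments.append(
                IBDSegment(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    members=members,
                    mean_posterior=float(mean_p[idx[lo:hi]].mean()),
                    n_markers=int(hi - lo),
                )
            )
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out
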