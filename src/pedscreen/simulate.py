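"""Synthetic-data generation: gene-drop simulation and downstream emitters.

The generator drops founder haplotypes through an arbitrary pedigree with
recombination under a Haldane (no-interference) model on a linear genetic
map, keeping full ancestry labels per homolog.  From one drop it can emit
every input the downstream analysis consumes — genotype matrices, annotated
exonic variant tables, SNP-array probe intensities, qPCR Ct replicate
plates, and tissue expression matrices — together with ground-truth IBD
segments and copy-number states for oracle testing.

Ancestry is tracked as piecewise-constant founder allele-copy labels: each
founder homolog gets a unique integer, and each meiosis produces a
recombinant mosaic of the parent's two label tracks.  Crossover counts are
Poisson with mean equal to the chromosome's genetic length in Morgans and
crossover positions are uniform, i.e. the Haldane map function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exome import VariantRecord
from .cnv import QpcrMeasurement
from .generank import ExpressionProfile
from .ibd import IBDSegment
from .pedigree import GeneticMap, Pedigree

__all__ = [
    "FounderPool",
    "SimConfig",
    "Haplotype",
    "GeneDropResult",
    "simulate_founder_pool",
    "gene_drop",
    "true_ibd_segments",
    "emit_variant_table",
    "emit_array_intensities",
    "emit_qpcr",
    "emit_expression",
]


@dataclass(frozen=True)
class FounderPool:
    """Marker grid with population allele frequencies for founder haplotypes."""

    markers: pd.DataFrame  # columns: chrom, pos (1-based), freq
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "freq"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"markers need columns {sorted(required)}")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
        freqs = self.markers["freq"].to_numpy()
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")


def simulate_founder_pool(
    gmap: GeneticMap,
    n_markers: int,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> FounderPool:
    """Uniformly spread ``n_markers`` across the map, MAFs uniform in range.

    The default MAF range (0.1, 0.5) emulates a post-"MAF > 0.1" array
    marker panel, the input the IBD stage expects.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in gmap.chromosomes], dtype=float)
    counts = np.maximum(1, np.round(n_markers * lengths / lengths.sum()).astype(int))
    frames = []
    for (chrom, length), k in zip(gmap.chromosomes, counts):
        k = min(k, length)
        uniq = np.unique(rng.integers(1, length + 1, size=2 * k))
        while uniq.size < k:  # collisions are rare at desk scale
            uniq = np.unique(
                np.concatenate([uniq, rng.integers(1, length + 1, size=k)])
            )
        pos = np.sort(rng.choice(uniq, size=k, replace=False))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "freq": rng.uniform(*maf_range, size=pos.size),
                }
            )
        )
    markers = pd.concat(frames, ignore_index=True)
    markers.insert(0, "id", [f"m{i}" for i in range(len(markers))])
    return FounderPool(markers, seed=seed)


@dataclass(frozen=True)
class SimConfig:
    """One stated synthetic world.

    Defaults emulate the study family: a five-generation pedigree, a
    1 cM/Mb map, an implanted ~1.3 Mb duplication carried by one founder
    homolog of the affected branch ancestor, penetrance 0.8 (five affected
    among six carriers in the source family), and mild instrument noise.
    """

    pedigree: Pedigree
    map: GeneticMap
    n_markers: int = 10_000
    causal_cnv: tuple[str, int, int, str, int] | None = None
    # (chrom, start_bp 0-based, end_bp half-open, founder id, homolog 0|1)
    causal_variant: str | None = None  # variant id, placed on the CNV carrier homolog
    cnv_carriers: tuple[str, ...] | None = None  # default: the pedigree's affecteds
    penetrance: float = 0.8
    intensity_noise_sd: float = 0.5
    ct_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.intensity_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.causal_cnv is not None:
            chrom, start, end, founder, hom = self.causal_cnv
            if not 0 <= start < end <= self.map.length_bp(chrom):
                raise ValueError("causal CNV interval outside chromosome bounds")
            if founder not in self.pedigree or hom not in (0, 1):
                raise ValueError("causal CNV carrier homolog is invalid")
            if not self.pedigree.member(founder).is_founder:
                raise ValueError("causal CNV must be planted on a founder homolog")


@dataclass(frozen=True)
class Haplotype:
    """Piecewise-constant founder-copy labels along one homolog.

    ``ends`` are 1-based inclusive segment end positions in bp, strictly
    increasing, the last equal to the chromosome length; ``labels[i]`` is
    the founder allele-copy carried on (ends[i-1], ends[i]].
    """

    ends: np.ndarray
    labels: np.ndarray

    def label_at(self, pos: int | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, pos, side="left")
        return self.labels[idx]


def _meiosis(
    pat: Haplotype, mat: Haplotype, length_bp: int, morgans: float, rng
) -> Haplotype:
    """One recombinant gamete under the Haldane model."""
    n_x = rng.poisson(morgans)
    cuts = np.sort(rng.integers(1, length_bp, size=n_x)) if n_x else np.array([], dtype=np.int64)
    cuts = np.unique(cuts)
    which = rng.integers(0, 2)  # homolog transmitted first
    sources = (pat, mat)
    bounds = np.concatenate([cuts, [length_bp]])
    ends: list[int] = []
    labels: list[int] = []
    prev = 0
    for i, b in enumerate(bounds):
        src = sources[(which + i) % 2]
        lo = np.searchsorted(src.ends, prev, side="right")
        hi = np.searchsorted(src.ends, b, side="left")
        for j in range(lo, hi + 1):
            end = min(int(src.ends[j]), int(b))
            if end > prev:
                if labels and labels[-1] == int(src.labels[j]):
                    ends[-1] = end
                else:
                    ends.append(end)
                    labels.append(int(src.labels[j]))
                prev = end
            if end == b:
                break
        prev = int(b)
    return Haplotype(np.array(ends, dtype=np.int64), np.array(labels, dtype=np.int64))


@dataclass
class GeneDropResult:
    """Genomes with ancestry labels plus derived genotypes and phenotypes."""

    config: SimConfig
    pool: FounderPool
    genomes: dict[str, dict[str, tuple[Haplotype, Haplotype]]]
    founder_copy_ids: dict[str, tuple[int, int]]
    founder_alleles: np.ndarray  # (n_copies, n_markers) 0/1
    affected: dict[str, bool]
    carriers: set[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genomes)

    def labels_at(self, sample: str, chrom: str, pos) -> tuple[np.ndarray, np.ndarray]:
        pat, mat = self.genomes[sample][chrom]
        return pat.label_at(pos), mat.label_at(pos)

    def genotypes(self, samples: list[str] | None = None) -> pd.DataFrame:
        """Dosage matrix (markers x samples) from founder alleles and labels."""
        samples = samples or self.sample_ids
        mk = self.pool.markers
        out = {}
        for s in samples:
            dose = np.zeros(len(mk), dtype=np.int8)
            for chrom, sub in mk.groupby("chrom", sort=False):
                pat_lab, mat_lab = self.labels_at(s, chrom, sub["pos"].to_numpy())
                idx = sub.index.to_numpy()
                dose[idx] = (
                    self.founder_alleles[pat_lab, idx]
                    + self.founder_alleles[mat_lab, idx]
                )
            out[s] = dose
        return pd.DataFrame(out, index=mk["id"] if "id" in mk else mk.index)

    def copy_number(self, sample: str, chrom: str, pos: int) -> int:
        """Integer copy number at a position (2 + duplication carrier status)."""
        cnv = self.config.causal_cnv
        if cnv is None:
            return 2
        c_chrom, start, end, founder, hom = cnv
        if chrom != c_chrom or not (start < pos <= end):
            return 2
        target = self.founder_copy_ids[founder][hom]
        pat, mat = self.labels_at(sample, chrom, np.array([pos]))
        return 2 + int(pat[0] == target) + int(mat[0] == target)


def _carrier_chain(ped: Pedigree, founder: str, required: set[str]) -> dict[str, str]:
    """Map each obligate-carrier non-founder to the parent it must inherit from.

    The family is ascertained on the duplication segregating to every
    required carrier, so each meiosis on a descent path from the planted
    founder homolog to a required carrier is conditioned to transmit it.
    """
    chain_parent: dict[str, str] = {}
    for r in required:
        mid = r
        while mid != founder:
            m = ped.member(mid)
            parent = None
            for cand in (m.father, m.mother):
                if cand is not None and (
                    cand == founder or founder in ped.ancestors(cand)
                ):
                    parent = cand
                    break
            if parent is None:
                raise ValueError(
                    f"required carrier {r!r} does not descend from founder {founder!r}"
                )
            chain_parent[mid] = parent
            mid = parent
    return chain_parent


def gene_drop(config: SimConfig, pool: FounderPool | None = None) -> GeneDropResult:
    """Drop founder haplotypes through the pedigree; deterministic per seed.

    When a causal CNV is configured, meioses on the descent paths from the
    planted founder homolog to the designated carriers (default: the
    pedigree's affected members) are conditioned to transmit it, mirroring
    ascertainment of a family in which the variant segregates.
    """
    rng = np.random.default_rng(config.seed)
    gmap = config.map
    ped = config.pedigree
    if pool is None:
        pool = simulate_founder_pool(gmap, config.n_markers, seed=config.seed)
    mk = pool.markers

    founder_copy_ids: dict[str, tuple[int, int]] = {}
    genomes: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
    next_copy = 0
    for fid in ped.founders:
        founder_copy_ids[fid] = (next_copy, next_copy + 1)
        genomes[fid] = {}
        for chrom, length in gmap.chromosomes:
            genomes[fid][chrom] = (
                Haplotype(np.array([length]), np.array([next_copy])),
                Haplotype(np.array([length]), np.array([next_copy + 1])),
            )
        next_copy += 2

    chain_parent: dict[str, str] = {}
    cnv_target: int | None = None
    cnv_chrom: str | None = None
    cnv_mid = np.array([0])
    if config.causal_cnv is not None:
        cnv_chrom, start, end, cnv_founder, hom = config.causal_cnv
        cnv_target = founder_copy_ids[cnv_founder][hom]
        cnv_mid = np.array([(start + end) // 2])
        required = (
            set(config.cnv_carriers)
            if config.cnv_carriers is not None
            else {m.id for m in ped if m.affected == "yes"}
        )
        required.discard(cnv_founder)
        chain_parent = _carrier_chain(ped, cnv_founder, required)

    for mid in ped.nonfounders:
        m = ped.member(mid)
        genomes[mid] = {}
        for chrom, length in gmap.chromosomes:
            morgans = gmap.length_morgans(chrom)
            gametes = []
            for parent in (m.father, m.mother):
                pat, mat = genomes[parent][chrom]
                gamete = _meiosis(pat, mat, length, morgans, rng)
                if chrom == cnv_chrom and chain_parent.get(mid) == parent:
                    for _ in range(10_000):  # conditioned meiosis; E[tries] = 2
                        if int(gamete.label_at(cnv_mid)[0]) == cnv_target:
                            break
                        gamete = _meiosis(pat, mat, length, morgans, rng)
                    else:
                        raise RuntimeError(
                            f"could not condition meiosis {parent}->{mid} on CNV transmission"
                        )
                gametes.append(gamete)
            genomes[mid][chrom] = (gametes[0], gametes[1])

    n_copies = next_copy
    freqs = mk["freq"].to_numpy()
    founder_alleles = (rng.random((n_copies, len(mk))) < freqs[None, :]).astype(np.int8)

    carriers: set[str] = set()
    affected: dict[str, bool] = {}
    if config.causal_cnv is not None:
        chrom, start, end, founder, hom = config.causal_cnv
        target = founder_copy_ids[founder][hom]
        mid_pos = np.array([(start + end) // 2])
        for sid in genomes:
            pat, mat = genomes[sid][chrom]
            if target in (int(pat.label_at(mid_pos)[0]), int(mat.label_at(mid_pos)[0])):
                carriers.add(sid)
    for sid in genomes:
        is_carrier = sid in carriers
        # no phenocopies: only carriers can be affected
        affected[sid] = bool(is_carrier and rng.random() < config.penetrance)

    return GeneDropResult(
        config=config,
        pool=pool,
        genomes=genomes,
        founder_copy_ids=founder_copy_ids,
        founder_alleles=founder_alleles,
        affected=affected,
        carriers=carriers,
    )


def true_ibd_segments(drop: GeneDropResult, group: list[str]) -> list[IBDSegment]:
    """Maximal intervals where all group members carry one founder copy.

    Ground-truth oracle for the inference stage: segments are 0-based
    half-open and merged when adjacent.
    """
    segments: list[IBDSegment] = []
    for chrom, length in drop.config.map.chromosomes:
        cuts = {0, length}
        for mid in group:
            for hap in drop.genomes[mid][chrom]:
                cuts.update(int(e) for e in hap.ends)
        bounds = sorted(cuts)
        run_start: int | None = None
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            probe = np.array([lo + 1])  # interval (lo, hi] constant per homolog
            shared = _group_shares(drop, group, chrom, probe)
            if shared and run_start is None:
                run_start = lo
            elif not shared and run_start is not None:
                segments.append(IBDSegment(chrom, run_start, lo, tuple(group)))
                run_start = None
        if run_start is not None:
            segments.append(IBDSegment(chrom, run_start, length, tuple(group)))
    return segments


def _group_shares(drop, group, chrom, probe) -> bool:
    first = drop.labels_at(group[0], chrom, probe)
    for cand in (int(first[0][0]), int(first[1][0])):
        if all(
            cand in (int(p[0]), int(m[0]))
            for p, m in (drop.labels_at(g, chrom, probe) for g in group[1:])
        ):
            return True
    return False


# -- emitters --------------------------------------------------------------

FUNCTIONAL_CLASSES = (
    "missense",
    "nonsense",
    "splice",
    "frameshift",
    "inframe_indel",
    "other",
)


def emit_variant_table(
    drop: GeneDropResult,
    *,
    n_variants: int = 2_000,
    synonymous_fraction: float = 0.5,
    rare_tail_weight: float = 0.1,
    panels: tuple[str, ...] = ("ESP", "KG1000"),
    cohort_chromosomes: int = 42,
    seed: int | None = None,
) -> list[VariantRecord]:
    """Annotated exonic variant table dropped on the simulated haplotypes.

    Each variant's derived allele is planted on one random founder allele
    copy, so genotypes segregate through the pedigree; its true frequency
    is drawn from a common/rare mixture (``rare_tail_weight`` of variants
    are rarer than 0.05%), per-panel MAFs jitter around the truth and
    cohort allele counts are Binomial(cohort_chromosomes, MAF).  When the
    config names a causal variant it is placed inside the causal CNV on the
    same carrier founder homolog, made non-synonymous, panel-absent and
    cohort-absent.
    """
    cfg = drop.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    gmap = cfg.map
    chroms = gmap.chromosomes
    lengths = np.array([l for _, l in chroms], dtype=float)
    records: list[VariantRecord] = []
    samples = drop.sample_ids

    n_plain = n_variants - (1 if cfg.causal_variant else 0)
    chrom_idx = rng.choice(len(chroms), size=n_plain, p=lengths / lengths.sum())
    for i in range(n_plain):
        chrom, length = chroms[chrom_idx[i]]
        pos = int(rng.integers(1, length + 1))
        if rng.random() < rare_tail_weight:
            maf_true = float(rng.uniform(0, 0.0005))
        else:
            maf_true = float(rng.uniform(0.01, 0.5))
        if rng.random() < synonymous_fraction:
            klass = "synonymous"
        else:
            klass = str(rng.choice(FUNCTIONAL_CLASSES, p=(0.7, 0.05, 0.05, 0.1, 0.05, 0.05)))
        copy = int(rng.integers(0, drop.founder_alleles.shape[0]))
        genotypes = {}
        for s in samples:
            pat, mat = drop.labels_at(s, chrom, np.array([pos]))
            genotypes[s] = int(pat[0] == copy) + int(mat[0] == copy)
        panel_mafs = {
            p: float(np.clip(maf_true * rng.uniform(0.5, 1.5), 0.0, 1.0)) for p in panels
        }
        cohort_count = int(rng.binomial(cohort_chromosomes, min(maf_true, 1.0)))
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="A",
                alt="G",
                gene=f"GENE{i % max(1, n_variants // 10)}",
                functional_class=klass,
                panel_mafs=panel_mafs,
                cohort_count=cohort_count,
                genotypes=genotypes,
                variant_id=f"v{i}",
            )
        )

    if cfg.causal_variant:
        if cfg.causal_cnv is None:
            raise ValueError(
                "causal variant placement requires a causal CNV carrier homolog"
            )
        chrom, start, end, founder, hom = cfg.causal_cnv
        target = drop.founder_copy_ids[founder][hom]
        pos = (start + end) // 2 + 1
        genotypes = {}
        for s in samples:
            pat, mat = drop.labels_at(s, chrom, np.array([pos]))
            genotypes[s] = int(pat[0] == target) + int(mat[0] == target)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos),
                ref="C",
                alt="T",
                gene="CAUSAL_GENE",
                functional_class="missense",
                panel_mafs={p: 0.0 for p in panels},
                cohort_count=0,
                genotypes=genotypes,
                variant_id=cfg.causal_variant,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def emit_array_intensities(
    drop: GeneDropResult,
    *,
    chrom: str | None = None,
    probe_spacing_bp: int = 2_000,
    gain: float = 2.0,
    n_controls: int = 16,
    seed: int | None = None,
) -> pd.DataFrame:
    """Raw array probe intensities for family samples plus diploid controls.

    Intensity = 0.5 x (CN - 2) x gain + Gaussian noise, so a duplication
    carrier sits ``gain/2`` units above the diploid baseline before
    standardization.  Controls are named ``CTRL{i}`` and are CN=2
    everywhere.  Columns: probe, chrom, pos, then one column per sample.
    """
    cfg = drop.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    if chrom is None:
        chrom = cfg.causal_cnv[0] if cfg.causal_cnv else cfg.map.chromosomes[0][0]
    length = cfg.map.length_bp(chrom)
    pos = np.arange(probe_spacing_bp, length + 1, probe_spacing_bp, dtype=np.int64)
    samples = drop.sample_ids + [f"CTRL{i}" for i in range(n_controls)]
    data = {"probe": [f"p{i}" for i in range(pos.size)], "chrom": chrom, "pos": pos}
    cn_cache: dict[str, np.ndarray] = {}
    for s in samples:
        if s.startswith("CTRL"):
            cn = np.full(pos.size, 2, dtype=np.int8)
        else:
            cn = cn_cache.get(s)
            if cn is None:
                cn = np.array([drop.copy_number(s, chrom, int(p)) for p in pos], dtype=np.int8)
                cn_cache[s] = cn
        data[s] = 0.5 * (cn - 2) * gain + rng.normal(0.0, cfg.intensity_noise_sd, pos.size)
    return pd.DataFrame(data)


def emit_qpcr(
    drop: GeneDropResult,
    *,
    samples: list[str] | None = None,
    target_positions: dict[str, tuple[str, int]] | None = None,
    n_replicates: int = 4,
    baseline_target: float = 26.0,
    baseline_reference: float = 24.0,
    n_calibrators: int = 2,
    seed: int | None = None,
) -> list[QpcrMeasurement]:
    """Taqman-style Ct replicate plates for copy-number confirmation.

    Target Ct = baseline - log2(CN/2) + noise; the reference assay and the
    diploid calibrator samples (named ``CAL{i}``) sit at their baselines.
    Default targets: three probes inside the causal CNV and one flanking
    probe on each side.
    """
    cfg = drop.config
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    if samples is None:
        samples = drop.sample_ids
    if target_positions is None:
        if cfg.causal_cnv is None:
            raise ValueError("no causal CNV: supply target_positions explicitly")
        chrom, start, end, _, _ = cfg.causal_cnv
        span = end - start
        target_positions = {
            "IN_A": (chrom, start + span // 4),
            "IN_B": (chrom, start + span // 2),
            "IN_C": (chrom, start + 3 * span // 4),
            "FLANK_L": (chrom, max(1, start - span)),
            "FLANK_R": (chrom, min(cfg.map.length_bp(chrom), end + span)),
        }
    calibrators = [f"CAL{i}" for i in range(n_calibrators)]
    out: list[QpcrMeasurement] = []
    for target, (chrom, pos) in target_positions.items():
        for s in list(samples) + calibrators:
            cn = 2 if s in calibrators else drop.copy_number(s, chrom, pos)
            ct_t = baseline_target - math.log2(cn / 2.0) + rng.normal(
                0.0, cfg.ct_noise_sd, n_replicates
            )
            ct_r = baseline_reference + rng.normal(0.0, cfg.ct_noise_sd, n_replicates)
            out.append(
                QpcrMeasurement(
                    sample=s,
                    target=target,
                    ct_target=ct_t,
                    ct_reference=ct_r,
                    is_calibrator=s in calibrators,
                )
            )
    return out


def emit_expression(
    *,
    genes: tuple[str, ...] = (
        "OTX2",
        "OTX2OS1",
        "EXOC5",
        "AP5M1",
        "NAA30",
        "C14orf105",
        "SLC35F4",
        "C14orf37",
    ),
    designated_gene: str = "OTX2",
    fold: float = 2.0,
    affected_conditions: tuple[str, ...] = ("pharyngeal_arch_E10.5", "head_E13.5"),
    control_conditions: tuple[str, ...] = (
        "heart_E10.5",
        "urogenital_E10.5",
        "liver_E13.5",
        "heart_E13.5",
        "lung_E13.5",
    ),
    subjects_per_condition: int = 3,
    noise_sd: float = 0.0,
    duplicate_probe_genes: tuple[str, ...] = ("OTX2", "NAA30"),
    seed: int = 0,
) -> list[ExpressionProfile]:
    """Gene-by-condition expression matrices emulating embryonic tissue panels.

    One designated gene is elevated ``fold``-fold in the affected-tissue
    conditions; some genes carry two probes so probe-collapsing has work to
    do.  Values are positive; noise is multiplicative log-normal-ish
    (Gaussian on top of base, clipped at a small positive floor).
    """
    if designated_gene not in genes:
        raise ValueError("designated gene must be in the gene universe")
    rng = np.random.default_rng(seed)
    gene_probes = {}
    for g in genes:
        gene_probes[g] = [f"{g}_at"]
        if g in duplicate_probe_genes:
            gene_probes[g].append(f"{g}_x_at")
    base = {g: float(rng.uniform(1.0, 4.0)) for g in genes}
    profiles: list[ExpressionProfile] = []
    for cond in affected_conditions + control_conditions:
        elevated = cond in affected_conditions
        for k in range(subjects_per_condition):
            values = {}
            for g in genes:
                level = base[g] * (fold if (elevated and g == designated_gene) else 1.0)
                for probe in gene_probes[g]:
                    v = level + rng.normal(0.0, noise_sd)
                    values[probe] = max(v, 1e-3)
            profiles.append(
                ExpressionProfile(
                    subject=f"{cond}_s{k}",
                    condition=cond,
                    values=values,
                    gene_probes={g: tuple(p) for g, p in gene_probes.items()},
                )
            )
    return profiles
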