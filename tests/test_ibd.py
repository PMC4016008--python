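import itertools

import numpy as np
import pandas as pd
import pytest

import pedscreen as ps
from pedscreen.ibd import ConsensusConfig, IbdHmmConfig, PruneConfig, _forward_backward
from pedscreen.relatedness import RelationshipPrior

from conftest import marker_truth_mask


class TestPairwiseR2:
    def test_identical_vectors(self):
        assert ps.pairwise_r2([0, 1, 2, 2], [0, 1, 2, 2]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert ps.pairwise_r2([0, 2, 0, 2], [0, 0, 2, 2]) == pytest.approx(0.0)

    def test_hand_computed_pearson(self):
        a, b = np.array([0, 1, 2, 2]), np.array([0, 1, 1, 2])
        # brute-force Pearson^2
        num = ((a - a.mean()) * (b - b.mean())).sum()
        oracle = num**2 / (((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert ps.pairwise_r2(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            assert ps.pairwise_r2([1, 1, 1, 1], [0, 1, 2, 0]) == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ps.pairwise_r2([1, np.nan, np.nan], [1, 2, 0])


def prune_oracle(dose, markers, config):
    """Exhaustive-pairs reimplementation of the greedy windowed rule."""
    maf = np.minimum(markers["freq"], 1 - markers["freq"]).to_numpy()
    kept = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        ids = [m for m, f in zip(sub["id"], maf[sub.index]) if f > config.maf_min]
        alive = dict.fromkeys(ids, True)
        start = 0
        while start < len(ids):
            window = ids[start : start + config.window_size]
            changed = True
            while changed:
                changed = False
                live = [m for m in window if alive[m]]
                for i, j in itertools.combinations(range(len(live)), 2):
                    r2 = ps.pairwise_r2(
                        dose.loc[live[i]].to_numpy(), dose.loc[live[j]].to_numpy()
                    )
                    if r2 > config.r2_threshold:
                        alive[live[j]] = False
                        changed = True
                        break
            if start + config.window_size >= len(ids):
                break
            start += config.step
        kept.extend(m for m in ids if alive[m])
    return kept


class TestLdPrune:
    def _table(self, dose_rows, freqs, chrom="chr1"):
        n = len(dose_rows)
        markers = pd.DataFrame(
            {
                "id": [f"m{i}" for i in range(n)],
                "chrom": chrom,
                "pos": np.arange(1, n + 1) * 1000,
                "freq": freqs,
            }
        )
        dose = pd.DataFrame(
            np.array(dose_rows, dtype=float), index=markers["id"]
        )
        return dose, markers

    def test_independent_markers_all_retained(self):
        rng = np.random.default_rng(1)
        dose_rows = rng.integers(0, 3, size=(30, 200))
        dose, markers = self._table(dose_rows, np.full(30, 0.4))
        cfg = PruneConfig(window_size=10, step=2, r2_threshold=0.35)
        kept = ps.ld_prune(dose, markers, cfg)
        assert len(kept) >= 28  # random dosage vectors are near-orthogonal

    def test_duplicated_marker_drops_the_later(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=100)
        rows = [base, base] + [rng.integers(0, 3, size=100) for _ in range(8)]
        dose, markers = self._table(rows, np.full(10, 0.4))
        kept = ps.ld_prune(dose, markers, PruneConfig(window_size=10, step=5))
        assert "m0" in kept and "m1" not in kept

    def test_matches_exhaustive_oracle_on_ld_blocks(self):
        """Seeded LD-block fixture: greedy windowed rule equals an
        independent exhaustive-pairs implementation."""
        rng = np.random.default_rng(3)
        rows = []
        block = None
        for i in range(200):
            if i % 10 == 0 or block is None:
                block = rng.integers(0, 3, size=60)
            noise = rng.integers(0, 3, size=60)
            mix = np.where(rng.random(60) < 0.8, block, noise)  # LD decay
            rows.append(mix)
        dose, markers = self._table(rows, rng.uniform(0.2, 0.5, size=200))
        cfg = PruneConfig(window_size=50, step=5, r2_threshold=0.35)
        assert ps.ld_prune(dose, markers, cfg) == prune_oracle(dose, markers, cfg)

    def test_unsorted_markers_rejected(self):
        dose, markers = self._table(np.zeros((3, 10)), [0.4, 0.4, 0.4])
        markers.loc[2, "pos"] = 1  # break sort order
        with pytest.raises(ValueError):
            ps.ld_prune(dose, markers, PruneConfig())


def _grid(n, freq=0.3, chrom="chr1", spacing=1_000_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "freq": freq,
        }
    )


class TestPairHmm:
    def test_all_missing_returns_prior(self, small_map):
        prior = RelationshipPrior(0.5, 0.5, 0.0, 2)
        cfg = IbdHmmConfig(prior=prior, map=small_map)
        mk = _grid(40)
        nan = np.full(40, np.nan)
        post = ps.pair_ibd_posterior(nan, nan, mk, cfg)
        assert np.allclose(post["ibd0"], 0.5) and np.allclose(post["ibd1"], 0.5)

    def test_parent_offspring_prior_is_degenerate(self, small_map):
        prior = RelationshipPrior(0.0, 1.0, 0.0, 1)
        cfg = IbdHmmConfig(prior=prior, map=small_map)
        mk = _grid(30)
        rng = np.random.default_rng(0)
        post = ps.pair_ibd_posterior(
            rng.integers(0, 3, 30).astype(float),
            rng.integers(0, 3, 30).astype(float),
            mk,
            cfg,
        )
        assert np.allclose(post["ibd1"], 1.0)

    def test_posterior_rows_sum_to_one(self, small_map, trio_priors):
        cfg = IbdHmmConfig(prior=trio_priors[("V.2", "V.3")], map=small_map)
        mk = _grid(200, freq=0.25)
        rng = np.random.default_rng(4)
        post = ps.pair_ibd_posterior(
            rng.integers(0, 3, 200).astype(float),
            rng.integers(0, 3, 200).astype(float),
            mk,
            cfg,
        )
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_transition_preserves_stationary_distribution(self):
        """Closed-form P(d) rows sum to 1 and leave pi invariant."""
        pi = np.array([0.75, 0.25])
        for d in (0.001, 0.01, 0.1, 1.0):
            s = np.exp(-16 / 3 * d)
            P = s * np.eye(2) + (1 - s) * np.ones((2, 1)) @ pi[None, :]
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(pi @ P, pi, atol=1e-8)

    def test_grandparent_pair_recovers_truth(self, ped, genome_map, trio_priors):
        """Simulated grandparent-grandchild pair at 10^4 markers: state
        calls agree with gene-drop truth on >= 90% of markers and the mean
        posterior P(IBD1) is close to 1/2."""
        cfg = ps.SimConfig(pedigree=ped, map=genome_map, n_markers=10_000, seed=7)
        drop = ps.gene_drop(cfg)
        g = drop.genotypes(["III.1", "V.3"])
        mk = drop.pool.markers
        hmm = IbdHmmConfig(prior=trio_priors[("III.1", "V.3")], map=genome_map)
        post = ps.pair_ibd_posterior(
            g["III.1"].to_numpy(float), g["V.3"].to_numpy(float), mk, hmm
        )
        truth = marker_truth_mask(drop, ["III.1", "V.3"])
        calls = (post["ibd1"] > post["ibd0"]).to_numpy()
        assert (calls == truth).mean() >= 0.90
        assert abs(post["ibd1"].mean() - truth.mean()) < 0.05

    def test_epsilon_validation(self, small_map):
        prior = RelationshipPrior(0.5, 0.5, 0.0, 2)
        with pytest.raises(ValueError):
            IbdHmmConfig(prior=prior, map=small_map, epsilon=0.6)

    def test_missing_frequency_rejected(self, small_map):
        prior = RelationshipPrior(0.5, 0.5, 0.0, 2)
        cfg = IbdHmmConfig(prior=prior, map=small_map)
        mk = _grid(10).drop(columns=["freq"])
        with pytest.raises(ValueError):
            ps.pair_ibd_posterior(np.zeros(10), np.zeros(10), mk, cfg)


def _uniform_posterior(mk, p1):
    return pd.DataFrame({"ibd0": 1 - p1, "ibd1": p1, "ibd2": 0.0}, index=mk.index)


class TestConsensusSegments:
    def test_certain_sharing_covers_chromosomes(self, small_map):
        mk = pd.concat(
            [_grid(10, chrom="chr1"), _grid(8, chrom="chr2")], ignore_index=True
        )
        posts = {("a", "b"): _uniform_posterior(mk, np.ones(18))}
        segs = ps.consensus_segments(posts, mk, small_map)
        assert [(s.chrom, s.start, s.end) for s in segs] == [
            ("chr1", 0, 100_000_000),
            ("chr2", 0, 80_000_000),
        ]

    def test_threshold_is_strict(self, small_map):
        mk = _grid(5)
        posts = {
            ("a", "b"): _uniform_posterior(mk, np.ones(5)),
            ("a", "c"): _uniform_posterior(mk, np.full(5, 0.5)),  # exactly 0.5
        }
        assert ps.consensus_segments(posts, mk, small_map) == []

    def test_tip_extension_toggle(self, small_map):
        mk = _grid(10)
        p1 = np.zeros(10)
        p1[:4] = 1.0  # shared run touching the first marker
        posts = {("a", "b"): _uniform_posterior(mk, p1)}
        ext = ps.consensus_segments(posts, mk, small_map, ConsensusConfig())
        raw = ps.consensus_segments(
            posts, mk, small_map, ConsensusConfig(tip_extension=False)
        )
        assert ext[0].start == 0
        assert raw[0].start == 1_000_000 - 1

    def test_invariant_to_chromosome_relabeling(self, small_map):
        mk = pd.concat(
            [_grid(10, chrom="chr1"), _grid(8, chrom="chr2")], ignore_index=True
        )
        rng = np.random.default_rng(5)
        p1 = rng.uniform(0, 1, 18)
        posts = {("a", "b"): _uniform_posterior(mk, p1)}
        segs = ps.consensus_segments(posts, mk, small_map)
        relabel = {"chr1": "k9", "chr2": "k7"}
        mk2 = mk.assign(chrom=mk["chrom"].map(relabel))
        gmap2 = ps.GeneticMap(tuple((relabel[c], l) for c, l in small_map.chromosomes))
        segs2 = ps.consensus_segments(posts, mk2, gmap2, members=("a", "b"))
        assert [(relabel[s.chrom], s.start, s.end) for s in segs] == [
            (s.chrom, s.start, s.end) for s in segs2
        ]

    def test_mismatched_grid_rejected(self, small_map):
        mk = _grid(10)
        posts = {("a", "b"): _uniform_posterior(_grid(9), np.ones(9))}
        with pytest.raises(ValueError):
            ps.consensus_segments(posts, mk, small_map)

    def test_truth_fed_consensus_brackets_expectation(self, ped, genome_map):
        """The consensus + summary machinery, fed exact pair-sharing
        indicators, reproduces the 12.5% trio expectation across
        replicates (tests discretization and interval arithmetic; HMM
        fidelity is covered by the Jaccard acceptance check)."""
        cases = ["III.1", "V.2", "V.3"]
        pairs = [("III.1", "V.2"), ("III.1", "V.3"), ("V.2", "V.3")]
        pcts = []
        for seed in range(200):
            cfg = ps.SimConfig(pedigree=ped, map=genome_map, n_markers=10_000, seed=seed)
            drop = ps.gene_drop(cfg)
            mk = drop.pool.markers
            posts = {
                p: _uniform_posterior(mk, marker_truth_mask(drop, list(p)).astype(float))
                for p in pairs
            }
            segs = ps.consensus_segments(posts, mk, genome_map, members=tuple(cases))
            pcts.append(ps.summarize_ibd(segs, genome_map)[2] if segs else 0.0)
        arr = np.array(pcts)
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert arr.mean() - 1.96 * se <= 12.5 <= arr.mean() + 1.96 * se
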