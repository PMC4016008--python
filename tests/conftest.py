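import numpy as np
import pytest

import pedscreen as ps


@pytest.fixture(scope="session")
def ped():
    return ps.hfm_pedigree()


@pytest.fixture(scope="session")
def small_map():
    return ps.GeneticMap((("chr1", 100_000_000), ("chr2", 80_000_000)))


@pytest.fixture(scope="session")
def genome_map():
    """Desk-scale stand-in for the autosome: 22 x 130 Mb at 1 cM/Mb."""
    return ps.GeneticMap(tuple((f"chr{i + 1}", 130_000_000) for i in range(22)))


@pytest.fixture(scope="session")
def trio_priors(ped):
    pairs = [("III.1", "V.2"), ("III.1", "V.3"), ("V.2", "V.3")]
    return {p: ps.relationship_coefficients(ped, *p) for p in pairs}


@pytest.fixture(scope="session")
def demo_drop(ped, small_map):
    cfg = ps.SimConfig(
        pedigree=ped,
        map=small_map,
        n_markers=1_000,
        causal_cnv=("chr2", 40_000_000, 41_300_000, "I.1", 0),
        causal_variant="causal",
        penetrance=1.0,
        seed=1,
    )
    return ps.gene_drop(cfg)


def marker_truth_mask(drop, group):
    """Boolean per-marker indicator of true group IBD sharing."""
    mk = drop.pool.markers
    mask = np.zeros(len(mk), dtype=bool)
    for s in ps.true_ibd_segments(drop, list(group)):
        sel = (mk["chrom"] == s.chrom) & (mk["pos"] > s.start) & (mk["pos"] <= s.end)
        mask |= sel.to_numpy()
    return mask
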