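import numpy as np
import pandas as pd
import pytest

import pedscreen as ps
from pedscreen.cnv import CnvCall, CnvConfig, QpcrMeasurement


def _table(values, samples, spacing=2_000, chrom="chr1"):
    n = len(values[samples[0]])
    df = pd.DataFrame(
        {
            "probe": [f"p{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
        }
    )
    for s in samples:
        df[s] = values[s]
    return df


class TestStandardize:
    def test_sample_at_reference_mean_is_zero(self):
        raw = _table(
            {"r1": [1.0, 2.0], "r2": [3.0, 4.0], "s": [2.0, 3.0]}, ["r1", "r2", "s"]
        )
        z = ps.standardize(raw, ["r1", "r2"])
        assert np.allclose(z["s"], 0.0)

    def test_sd_convention(self):
        """References {1,3} and sample 4: z = (4-2)/sqrt(2) with the
        sample-SD (ddof=1) convention."""
        raw = _table({"r1": [1.0], "r2": [3.0], "s": [4.0]}, ["r1", "r2", "s"])
        z = ps.standardize(raw, ["r1", "r2"])
        assert z["s"][0] == pytest.approx(2.0 / np.sqrt(2.0), abs=1e-12)

    def test_too_few_references(self):
        raw = _table({"r1": [1.0], "s": [4.0]}, ["r1", "s"])
        with pytest.raises(ValueError):
            ps.standardize(raw, ["r1"])

    def test_carrier_shows_elevation_only_inside_duplication(self, ped):
        gmap = ps.GeneticMap((("chr14", 20_000_000),))
        cfg = ps.SimConfig(
            pedigree=ped,
            map=gmap,
            n_markers=50,
            causal_cnv=("chr14", 9_000_000, 10_300_000, "I.1", 0),
            intensity_noise_sd=0.5,
            penetrance=1.0,
            seed=3,
        )
        drop = ps.gene_drop(cfg)
        raw = ps.emit_array_intensities(drop, probe_spacing_bp=20_000)
        ctrl = [c for c in raw.columns if c.startswith("CTRL")]
        z = ps.standardize(raw, ctrl)
        inside = (z["pos"] > 9_000_000) & (z["pos"] <= 10_300_000)
        assert z.loc[inside, "V.3"].mean() > 1.0
        assert abs(z.loc[~inside, "V.3"].mean()) < 0.3


class TestMovingAverage:
    def test_constant_signal_unchanged(self):
        assert np.allclose(ps.moving_average(np.full(11, 3.5), 5), 3.5)

    def test_window_one_is_identity(self):
        x = np.arange(8, dtype=float)
        assert np.array_equal(ps.moving_average(x, 1), x)

    def test_center_value(self):
        out = ps.moving_average(np.array([0.0, 0.0, 4.0, 0.0, 0.0]), 5)
        assert out[2] == pytest.approx(0.8)

    def test_empty_signal(self):
        assert ps.moving_average(np.array([]), 5).size == 0

    def test_output_length_preserved(self):
        rng = np.random.default_rng(0)
        for n in (1, 5, 19, 100):
            for w in (1, 4, 20):
                x = rng.normal(size=n)
                assert ps.moving_average(x, w).size == n

    def test_shift_invariance_with_standardize(self):
        """Adding a constant to every sample commutes with the
        standardize -> moving_average chain."""
        rng = np.random.default_rng(1)
        samples = ["r1", "r2", "r3", "s"]
        vals = {s: rng.normal(size=40) for s in samples}
        raw = _table(vals, samples)
        shifted = raw.copy()
        for s in samples:
            shifted[s] = shifted[s] + 7.5
        z1 = ps.standardize(raw, ["r1", "r2", "r3"])
        z2 = ps.standardize(shifted, ["r1", "r2", "r3"])
        m1 = ps.moving_average(z1["s"].to_numpy(), 5)
        m2 = ps.moving_average(z2["s"].to_numpy(), 5)
        assert np.allclose(m1, m2, atol=1e-9)


class TestCallSegments:
    def test_zero_signal_no_calls(self):
        raw = _table({"s": np.zeros(100)}, ["s"])
        assert ps.call_segments(raw, CnvConfig())["s"] == []

    def test_short_run_fails_min_length(self):
        """An above-threshold run spanning only 8 kb is not called."""
        sig = np.zeros(100)
        sig[50:54] = 5.0  # 4 probes at 2 kb spacing: 6-8 kb span
        raw = _table({"s": sig}, ["s"])
        cfg = CnvConfig(ma_window=1, min_probes=2)
        assert ps.call_segments(raw, cfg)["s"] == []

    def test_negated_signal_swaps_gain_and_loss(self):
        rng = np.random.default_rng(2)
        sig = rng.normal(size=400)
        sig[100:200] += 2.0
        sig[300:350] -= 2.0
        cfg = CnvConfig(ma_window=5, min_probes=5, min_length_bp=5_000)
        up = ps.call_segments(_table({"s": sig}, ["s"]), cfg)["s"]
        down = ps.call_segments(_table({"s": -sig}, ["s"]), cfg)["s"]
        flip = {"gain": "loss", "loss": "gain"}
        assert [(c.start, c.end, flip[c.state]) for c in up] == [
            (c.start, c.end, c.state) for c in down
        ]

    def test_implanted_duplication_called_with_high_overlap(self, ped):
        """1.3 Mb implanted gain at 2 kb probe spacing, noise 0.3: one gain
        call overlaps the truth interval with reciprocal overlap >= 0.9."""
        gmap = ps.GeneticMap((("chr14", 20_000_000),))
        cfg = ps.SimConfig(
            pedigree=ped,
            map=gmap,
            n_markers=50,
            causal_cnv=("chr14", 9_000_000, 10_300_000, "I.1", 0),
            intensity_noise_sd=0.3,
            penetrance=1.0,
            seed=5,
        )
        drop = ps.gene_drop(cfg)
        raw = ps.emit_array_intensities(drop, probe_spacing_bp=2_000)
        ctrl = [c for c in raw.columns if c.startswith("CTRL")]
        z = ps.standardize(raw, ctrl)
        calls = ps.call_segments(z, CnvConfig(), samples=["V.3"])["V.3"]
        hits = [
            c
            for c in calls
            if c.state == "gain"
            and ps.reciprocal_overlap(c.start, c.end, 9_000_000, 10_300_000) >= 0.9
        ]
        assert len(hits) == 1


class TestSegregation:
    call = CnvCall("chr1", 1_000_000, 2_000_000, "gain", "a")

    def _calls(self, *samples, start=1_000_000, end=2_000_000, state="gain"):
        return {s: [CnvCall("chr1", start, end, state, s)] for s in samples}

    def test_absent_from_one_case_removes(self):
        cases = self._calls("a", "b", "c")
        cases["d"] = []
        assert ps.segregating_cnvs(cases) == []

    def test_present_in_all_cases_survives(self):
        assert len(ps.segregating_cnvs(self._calls("a", "b", "c"))) == 1

    def test_control_overlap_removes(self):
        out = ps.segregating_cnvs(
            self._calls("a", "b"), control_calls=self._calls("ctrl")
        )
        assert out == []

    def test_known_cnv_interval_removes(self):
        """A call matching a catalogued polymorphic duplication is screened
        out, as the chr3 duplication was via the genomic-variants database."""
        out = ps.segregating_cnvs(
            self._calls("a", "b"),
            known_intervals=[("chr1", 950_000, 2_050_000)],
        )
        assert out == []

    def test_same_state_required_across_cases(self):
        calls = self._calls("a")
        calls.update(self._calls("b", state="loss"))
        assert ps.segregating_cnvs(calls) == []


class TestDdct:
    def _m(self, sample, dct, target="T1", calibrator=False):
        return QpcrMeasurement(
            sample=sample,
            target=target,
            ct_target=np.full(4, 25.0 + dct),
            ct_reference=np.full(4, 25.0),
            is_calibrator=calibrator,
        )

    def test_calibrator_identity(self):
        cal = self._m("cal", 0.0, calibrator=True)
        cn, state = ps.ddct_copy_number(self._m("s", 0.0), [cal])
        assert (cn, state) == (2.0, 2)

    def test_duplication_closed_form(self):
        """ddCt = -log2(1.5) = -0.585 -> CN 3."""
        cal = self._m("cal", 0.0, calibrator=True)
        cn, state = ps.ddct_copy_number(self._m("s", -np.log2(1.5)), [cal])
        assert cn == pytest.approx(3.0, abs=1e-12)
        assert state == 3

    def test_exp_linearity_in_ddct(self):
        cal = self._m("cal", 0.0, calibrator=True)
        cns = [
            ps.ddct_copy_number(self._m("s", d), [cal])[0]
            for d in (-1.0, 0.0, 1.0, 2.0)
        ]
        # halving per unit of ddCt (efficiency fixed at 2)
        ratios = [a / b for a, b in zip(cns, cns[1:])]
        assert np.allclose(ratios, 2.0)

    def test_state_clipped_to_plausible_range(self):
        cal = self._m("cal", 0.0, calibrator=True)
        _, state = ps.ddct_copy_number(self._m("s", -3.0), [cal])
        assert state == 4

    def test_missing_calibrator_raises(self):
        cal = self._m("cal", 0.0, target="OTHER", calibrator=True)
        with pytest.raises(ValueError):
            ps.ddct_copy_number(self._m("s", 0.0), [cal])

    def test_replicate_validation(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("s", "T1", np.array([25.0]), np.array([25.0, 25.0]))
        with pytest.raises(ValueError):
            QpcrMeasurement("s", "T1", np.array([25.0, -1.0]), np.array([25.0, 25.0]))
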