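"""Array-intensity CNV detection and qPCR copy-number confirmation.

Detection follows the visual convention of raw-intensity CNV plots:
standardize each probe against reference samples (units: SDs from the
reference mean), smooth with a centered moving average, and call maximal
runs of smoothed signal beyond a symmetric threshold as gain/loss
segments, subject to minimum length and probe-count rules.  Candidate
calls are then screened for segregation (present in all cases), absence
from controls, and absence from known polymorphic-CNV catalogs, all via
reciprocal-overlap matching.  qPCR confirmation uses the comparative
(delta-delta Ct) method against diploid calibrators with assay efficiency
fixed at 2: CN = 2 x 2^(-ddCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CnvConfig",
    "CnvCall",
    "QpcrMeasurement",
    "standardize",
    "moving_average",
    "call_segments",
    "reciprocal_overlap",
    "segregating_cnvs",
    "ddct_copy_number",
]

META_COLS = ("probe", "chrom", "pos")


@dataclass(frozen=True)
class CnvConfig:
    ma_window: int = 20
    call_threshold: float = 0.3  # symmetric: > +t gain, < -t loss
    min_length_bp: int = 10_000  # strict >
    min_probes: int = 10

    def __post_init__(self) -> None:
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if self.min_length_bp < 0:
            raise ValueError("min_length_bp must be >= 0")


@dataclass(frozen=True)
class CnvCall:
    """One gain/loss call, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    sample: str
    mean_signal: float = 0.0
    n_probes: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("call needs start < end")
        if self.state not in ("gain", "loss"):
            raise ValueError("state must be 'gain' or 'loss'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one sample x target assay pair."""

    sample: str
    target: str
    ct_target: np.ndarray
    ct_reference: np.ndarray
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        for arr in (self.ct_target, self.ct_reference):
            a = np.asarray(arr, dtype=float)
            if a.size < 2:
                raise ValueError("need >= 2 Ct replicates")
            if not np.all(np.isfinite(a)) or np.any(a <= 0):
                raise ValueError("Ct values must be finite and positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def standardize(
    raw: pd.DataFrame, reference_samples: list[str]
) -> pd.DataFrame:
    """Per-probe z-scores against the reference samples.

    ``raw`` columns: probe, chrom, pos, then sample intensity columns.
    z = (x - mean over references) / SD over references, with the sample
    SD convention (ddof=1).  A zero reference SD yields z = 0 with a
    warning.  Requires >= 2 reference samples.
    """
    if len(reference_samples) < 2:
        raise ValueError("need at least two reference samples")
    missing = [s for s in reference_samples if s not in raw.columns]
    if missing:
        raise ValueError(f"reference samples absent from table: {missing}")
    ref = raw[reference_samples].to_numpy(dtype=float)
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} probes have zero reference SD; z set to 0",
            stacklevel=2,
        )
    sd_safe = np.where(zero, 1.0, sd)
    out = raw[list(META_COLS)].copy()
    sample_cols = [c for c in raw.columns if c not in META_COLS]
    for c in sample_cols:
        z = (raw[c].to_numpy(dtype=float) - mu) / sd_safe
        out[c] = np.where(zero, 0.0, z)
    return out


def moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean, shrinking symmetrically at the edges.

    Interior points of an odd window use (window-1)/2 probes each side;
    even windows use one more on the right (standard centered convention).
    Near an edge the half-width shrinks to what is available on the short
    side, keeping the window symmetric.  Output length equals input.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    if window < 1:
        raise ValueError("window must be >= 1")
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(n)
    for i in range(n):
        if i < left or (n - 1 - i) < right:
            h = min(i, n - 1 - i, max(left, right))
            lo, hi = i - h, i + h
        else:
            lo, hi = i - left, i + right
        out[i] = (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
    return out


def call_segments(
    z: pd.DataFrame,
    config: CnvConfig = CnvConfig(),
    samples: list[str] | None = None,
    smooth: bool = True,
) -> dict[str, list[CnvCall]]:
    """Threshold the (smoothed) standardized signal into gain/loss calls.

    Runs of consecutive probes with smoothed z > +threshold (gain) or
    < -threshold (loss) become calls when they span more than
    ``min_length_bp`` and at least ``min_probes`` probes.  Call bounds are
    0-based half-open from first to last probe position.
    """
    samples = samples or [c for c in z.columns if c not in META_COLS]
    out: dict[str, list[CnvCall]] = {s: [] for s in samples}
    for chrom, sub in z.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        for s in samples:
            sig = sub[s].to_numpy(dtype=float)
            sm = moving_average(sig, config.ma_window) if smooth else sig
            found: list[CnvCall] = []
            for state, mask in (
                ("gain", sm > config.call_threshold),
                ("loss", sm < -config.call_threshold),
            ):
                for lo, hi in _runs(mask):
                    start = int(pos[lo]) - 1
                    end = int(pos[hi - 1])
                    if end - start > config.min_length_bp and hi - lo >= config.min_probes:
                        found.append(
                            CnvCall(
                                chrom=str(chrom),
                                start=start,
                                end=end,
                                state=state,
                                sample=s,
                                mean_signal=float(sm[lo:hi].mean()),
                                n_probes=int(hi - lo),
                            )
                        )
            out[s].extend(sorted(found, key=lambda c: c.start))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i, n = 0, mask.size
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


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Overlap length divided by the longer interval length (0 if disjoint)."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return ov / max(a_end - a_start, b_end - b_start)


def segregating_cnvs(
    case_calls: dict[str, list[CnvCall]],
    control_calls: dict[str, list[CnvCall]] | None = None,
    known_intervals: list[tuple[str, int, int]] | None = None,
    min_reciprocal: float = 0.5,
) -> list[CnvCall]:
    """Calls present in all cases, absent from controls and known catalogs.

    A call from the first case survives when every other case has a
    same-state call with reciprocal overlap >= ``min_reciprocal``, no
    control sample has any call with such overlap, and no known-CNV
    interval reciprocally overlaps it.
    """
    if not case_calls:
        return []
    cases = list(case_calls)
    control_calls = control_calls or {}
    known_intervals = known_intervals or []
    survivors = []
    for call in case_calls[cases[0]]:
        ok = all(
            any(
                other.chrom == call.chrom
                and other.state == call.state
                and reciprocal_overlap(call.start, call.end, other.start, other.end)
                >= min_reciprocal
                for other in case_calls[c]
            )
            for c in cases[1:]
        )
        if not ok:
            continue
        in_controls = any(
            ctrl.chrom == call.chrom
            and reciprocal_overlap(call.start, call.end, ctrl.start, ctrl.end)
            >= min_reciprocal
            for calls in control_calls.values()
            for ctrl in calls
        )
        if in_controls:
            continue
        in_known = any(
            chrom == call.chrom
            and reciprocal_overlap(call.start, call.end, ks, ke) >= min_reciprocal
            for chrom, ks, ke in known_intervals
        )
        if in_known:
            continue
        survivors.append(call)
    return survivors


def ddct_copy_number(
    m: QpcrMeasurement, calibrators: list[QpcrMeasurement]
) -> tuple[float, int]:
    """Comparative-Ct copy number against diploid calibrators.

    dCt = mean(target Ct) - mean(reference Ct) per sample; ddCt is the
    sample dCt minus the mean calibrator dCt (calibrator copy number
    assumed 2); CN = 2 x 2^(-ddCt) with assay efficiency fixed at 2.
    Returns (real copy number, integer state rounded and clipped to [0, 4]).
    """
    cals = [c for c in calibrators if c.target == m.target]
    if not cals:
        raise ValueError(f"no calibrator measurements for target {m.target!r}")
    ddct = m.delta_ct - float(np.mean([c.delta_ct for c in cals]))
    cn = 2.0 * 2.0 ** (-ddct)
    state = int(np.clip(round(cn), 0, 4))
    return cn, state
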