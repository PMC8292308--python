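"""Open-flow heliox respirometry trace processing.

Converts a raw trace of excurrent O2 fraction into summit metabolism
(M_sum): the highest VO2 averaged over a sliding window (default 5 min).
Baseline (animal-absent) segments recorded before and after the animal
segment anchor a linear drift correction of the incurrent reference; VO2
uses the steady-state equation for a dry, CO2-scrubbed excurrent stream
with flow metered downstream:

    VO2(t) = flow * (FiO2(t) - FeO2(t)) / (1 - FiO2(t))   [ml O2 min^-1]

QC discards runs with large baseline drift or inconsistent flow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RespTrace",
    "MetabolicSummary",
    "correct_baseline_drift",
    "compute_vo2",
    "extract_msum",
    "qc_trace",
    "process_trace",
    "read_trace",
    "write_trace",
]

#: default QC thresholds; the source protocols publish no numbers, so these
#: are explicit, configurable package defaults (O2 fraction / fractional CV)
DEFAULT_DRIFT_MAX = 0.005
DEFAULT_FLOW_CV_MAX = 0.05


class TraceError(ValueError):
    """Invalid respirometry trace or configuration."""


@dataclass
class RespTrace:
    """A respirometry run: time (s), excurrent O2 fraction, flow (ml/min).

    ``baseline_segments`` are (start, end) index ranges (end exclusive)
    flagged animal-absent; ``animal_segment`` brackets the measurement.
    ``flow`` may be a scalar or a per-sample array.
    """

    time: np.ndarray
    feo2: np.ndarray
    flow: np.ndarray | float
    fio2: float = 0.21
    baseline_segments: list[tuple[int, int]] = field(default_factory=list)
    animal_segment: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.feo2 = np.asarray(self.feo2, dtype=float)
        if np.isscalar(self.flow):
            self.flow = float(self.flow)
        else:
            self.flow = np.asarray(self.flow, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise TraceError("time must be a 1-d array with >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise TraceError("time must be strictly increasing")
        if self.feo2.shape != self.time.shape:
            raise TraceError("feo2 and time must have the same length")
        if np.any(np.atleast_1d(self.flow) <= 0):
            raise TraceError("flow must be positive")

    @property
    def flow_array(self) -> np.ndarray:
        if np.isscalar(self.flow):
            return np.full_like(self.time, float(self.flow))
        return np.asarray(self.flow)

    def pre_post_baselines(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Split baseline segments into those before/after the animal segment."""
        if self.animal_segment is None:
            raise TraceError("animal_segment not set")
        a0, a1 = self.animal_segment
        pre = [s for s in self.baseline_segments if s[1] <= a0]
        post = [s for s in self.baseline_segments if s[0] >= a1]
        return pre, post


@dataclass
class MetabolicSummary:
    """Processed M_sum with QC bookkeeping."""

    msum: float
    window_start: float
    window_end: float
    baseline_drift: float
    flow_cv: float
    qc_pass: bool = True
    qc_reasons: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = dict(
            msum=self.msum,
            window_start=self.window_start,
            window_end=self.window_end,
            baseline_drift=self.baseline_drift,
            flow_cv=self.flow_cv,
            qc_pass=self.qc_pass,
            qc_reasons=";".join(self.qc_reasons),
        )
        return d


def _segment_means(trace: RespTrace, segments: list[tuple[int, int]]) -> tuple[float, float]:
    """Mean FeO2 and mean time over a list of index segments."""
    idx = np.concatenate([np.arange(s, e) for s, e in segments])
    return float(trace.feo2[idx].mean()), float(trace.time[idx].mean())


def correct_baseline_drift(trace: RespTrace) -> tuple[np.ndarray, float, list[str]]:
    """Effective incurrent reference FiO2(t) from bracketing baselines.

    Linearly interpolates between the mean pre- and post-baseline FeO2
    (anchored at the segments' mean times); beyond the anchors the
    reference is held at the respective baseline mean. Returns the
    reference series, the absolute drift, and any QC reason codes.
    """
    reasons: list[str] = []
    pre, post = trace.pre_post_baselines()
    if not pre or not post:
        reasons.append("missing_baseline")
        ref = np.full_like(trace.time, trace.fio2)
        return ref, np.nan, reasons
    pre_mean, pre_t = _segment_means(trace, pre)
    post_mean, post_t = _segment_means(trace, post)
    drift = abs(post_mean - pre_mean)
    ref = np.interp(trace.time, [pre_t, post_t], [pre_mean, post_mean])
    return ref, drift, reasons


def compute_vo2(
    trace: RespTrace, reference: np.ndarray | None = None, tolerance: float = 1e-4
) -> np.ndarray:
    """Per-sample VO2 (ml O2 min^-1) against a drift-corrected reference.

    The depletion is measured against the interpolated baseline
    reference; the denominator uses the nominal incurrent fraction
    because analyzer drift offsets the reading, not the true gas
    composition (this also makes M_sum exactly invariant to a common
    offset on FeO2 and both baselines).  Samples where FeO2 exceeds the
    reference by more than ``tolerance`` are flagged NaN (excluded from
    window means downstream).
    """
    ref = np.full_like(trace.time, trace.fio2) if reference is None else reference
    vo2 = trace.flow_array * (ref - trace.feo2) / (1.0 - trace.fio2)
    vo2 = np.where(trace.feo2 > ref + tolerance, np.nan, vo2)
    return vo2


def extract_msum(
    vo2: np.ndarray,
    time: np.ndarray,
    window_s: float = 300.0,
) -> tuple[float, float, float]:
    """Highest window-mean VO2 over all contiguous windows of ``window_s``.

    Window length in samples is derived from the median sampling
    interval.  Returns (msum, window_start_time, window_end_time); ties
    between equal-mean windows break to the earliest start.
    """
    vo2 = np.asarray(vo2, float)
    time = np.asarray(time, float)
    dt = float(np.median(np.diff(time)))
    w = int(round(window_s / dt))
    if w < 1 or w > vo2.size:
        raise TraceError(
            f"window of {window_s}s ({w} samples) exceeds series length {vo2.size}"
        )
    # NaN samples (flagged by compute_vo2) invalidate their windows
    c = np.concatenate([[0.0], np.nancumsum(vo2)])
    nbad = np.concatenate([[0], np.cumsum(np.isnan(vo2))])
    means = (c[w:] - c[:-w]) / w
    means[(nbad[w:] - nbad[:-w]) > 0] = -np.inf
    if not np.isfinite(means).any():
        raise TraceError("no valid window (all windows contain flagged samples)")
    i = int(np.argmax(means))  # argmax keeps the earliest tie
    return float(means[i]), float(time[i]), float(time[i + w - 1])


def qc_trace(
    baseline_drift: float,
    flow_cv: float,
    drift_max: float = DEFAULT_DRIFT_MAX,
    flow_cv_max: float = DEFAULT_FLOW_CV_MAX,
) -> tuple[bool, list[str]]:
    """QC decision: drift within bound and flow consistent."""
    reasons = []
    if not np.isfinite(baseline_drift) or baseline_drift > drift_max:
        reasons.append("baseline_drift")
    if flow_cv > flow_cv_max:
        reasons.append("flow")
    return (not reasons), reasons


def process_trace(
    trace: RespTrace,
    window_s: float = 300.0,
    drift_max: float = DEFAULT_DRIFT_MAX,
    flow_cv_max: float = DEFAULT_FLOW_CV_MAX,
) -> MetabolicSummary:
    """Full trace pipeline: drift correction -> VO2 -> window max -> QC."""
    ref, drift, reasons = correct_baseline_drift(trace)
    a0, a1 = trace.animal_segment
    vo2 = compute_vo2(trace, ref)[a0:a1]
    t = trace.time[a0:a1]
    flow = trace.flow_array[a0:a1]
    flow_cv = float(flow.std(ddof=1) / flow.mean()) if flow.size > 1 else 0.0
    try:
        msum, w0, w1 = extract_msum(vo2, t, window_s)
    except TraceError:
        return MetabolicSummary(
            msum=np.nan, window_start=np.nan, window_end=np.nan,
            baseline_drift=drift, flow_cv=flow_cv,
            qc_pass=False, qc_reasons=reasons + ["short_trace"],
        )
    ok, qc_reasons = qc_trace(drift, flow_cv, drift_max, flow_cv_max)
    qc_reasons = reasons + qc_reasons
    return MetabolicSummary(
        msum=msum, window_start=w0, window_end=w1,
        baseline_drift=drift, flow_cv=flow_cv,
        qc_pass=ok and not reasons, qc_reasons=qc_reasons,
    )


# ---------------------------------------------------------------------------
# I/O: delimited time-series + JSON segment sidecar


def write_trace(trace: RespTrace, csv_path: str | Path, sidecar_path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": trace.time, "feo2": trace.feo2, "flow_ml_min": trace.flow_array}
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "fio2": trace.fio2,
        "baseline_segments": [list(s) for s in trace.baseline_segments],
        "animal_segment": list(trace.animal_segment) if trace.animal_segment else None,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_trace(csv_path: str | Path, sidecar_path: str | Path) -> RespTrace:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    return RespTrace(
        time=df["time_s"].to_numpy(),
        feo2=df["feo2"].to_numpy(),
        flow=df["flow_ml_min"].to_numpy(),
        fio2=meta["fio2"],
        baseline_segments=[tuple(s) for s in meta["baseline_segments"]],
        animal_segment=tuple(meta["animal_segment"]),
    )
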