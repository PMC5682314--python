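"""Tapping-event detection (TED), segment extraction, and the FDER metric.

Two detectors are implemented:

* **RMS**: a sliding-window root-mean-square envelope ``g_r[t]`` thresholded
  at ``alpha_r`` times its mean over a known rest (baseline) interval.
* **DTF** (difference-template filtering): convolution of the signal with the
  fixed antisymmetric template ``D = [-1]*8 + [0] + [+1]*8``, rectified by
  default, thresholded at ``alpha_d`` times the baseline mean response.

The rectified DTF response is smoothed with a short centred moving average
(default 200 ms) before thresholding.  Without it the response at rest is a
rectified noise process whose threshold (2x its mean, i.e. ~1.6 sigma) is
exceeded on ~11% of samples in dense, short runs, so no run-level
post-processing can separate taps from baseline; averaging turns the response
into a proper activity envelope while leaving the threshold of Eq.-style
``alpha * baseline mean`` unchanged in expectation.  Set ``smooth=0`` for the
literal unsmoothed response.

Above-threshold runs become events after merging runs separated by less than
``merge_gap`` and then dropping runs shorter than ``min_event_duration``.

Detection quality is summarised by the false-detection-events ratio

    FDER = (N_FP + N_FN) / N_all,

where ``N_all`` counts detected events, ``N_FP`` unmatched detections and
``N_FN`` missed ground-truth events.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .core import Event, EventTable, Recording

__all__ = [
    "DIFFERENCE_TEMPLATE",
    "DetectorSpec",
    "DetectionResult",
    "FderResult",
    "rms_envelope",
    "rms_threshold",
    "dtf_response",
    "dtf_threshold",
    "binarize_and_segment",
    "detect_events",
    "extract_segments",
    "compute_fder",
]

logger = logging.getLogger(__name__)

#: Fixed difference template for DTF detection; coefficients sum to zero.
DIFFERENCE_TEMPLATE = np.array([-1.0] * 8 + [0.0] + [1.0] * 8)

#: Index of the template's zero element; 'same' convolution is centred here.
_TEMPLATE_HALF = len(DIFFERENCE_TEMPLATE) // 2


@dataclass
class DetectorSpec:
    """Configuration of one TED run.

    ``window`` and the duration parameters are in samples (400 samples =
    400 ms at the 1 kHz MMG sampling rate).  ``alpha`` defaults to 2.15 for
    the RMS detector and 2.0 for DTF when left as ``None``.  ``recenter``
    shifts RMS event boundaries by half a window so that timestamps refer to
    the window centre rather than the forward-looking window start.

    ``refine_window`` re-localises each coarse event's boundaries with a
    fine-scale activity measure (short RMS envelope, or lightly smoothed DTF
    response) thresholded at the same ``alpha`` times its own baseline mean;
    the coarse 400 ms window is robust but dilates events by up to half a
    window per side.  0 disables refinement.  ``edge_guard`` ignores
    activation within that many samples of the recording edges, where the
    0.1 Hz high-pass stage of the band-pass filter leaves a multi-second
    settling transient.
    """

    algorithm: Literal["rms", "dtf"] = "rms"
    window: int = 400
    alpha: Optional[float] = None
    rectify: bool = True
    smooth: int = 200
    min_event_duration: int = 100
    merge_gap: int = 200
    channel_combination: Union[Literal["or", "and"], int] = "or"
    recenter: bool = True
    # one carrier-envelope coherence time (~1/bandwidth of the 10-22 Hz MMG
    # band), so a single amplitude fade cannot mimic a burst edge
    refine_window: int = 80
    edge_guard: int = 2000

    def __post_init__(self) -> None:
        if self.algorithm not in ("rms", "dtf"):
            raise ValueError(f"unknown detector algorithm {self.algorithm!r}")
        if self.alpha is None:
            self.alpha = 2.15 if self.algorithm == "rms" else 2.0
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.min_event_duration < 1:
            raise ValueError("min_event_duration must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")
        if self.refine_window < 0 or self.edge_guard < 0:
            raise ValueError("refine_window and edge_guard must be >= 0")


@dataclass
class DetectionResult:
    """Per-recording detector output: envelopes, thresholds, activation, events."""

    envelopes: list[np.ndarray]
    thresholds: list[float]
    activation: np.ndarray
    events: EventTable
    index_offset: int = 0
    spec: Optional[DetectorSpec] = None


@dataclass(frozen=True)
class FderResult:
    """False-detection-events ratio and its components.

    ``fder`` is ``None`` when no events were detected but ground truth is
    non-empty (the ratio is undefined; the miss count still reports).
    ``fder`` may exceed 1 when misses dominate detections.
    """

    fder: Optional[float]
    n_fp: int
    n_fn: int
    n_all: int
    matches: tuple[tuple[int, int], ...] = field(default=())


def rms_envelope(x: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window RMS: ``g[t] = sqrt(mean(x[t:t+W]**2))``.

    Output has length ``len(x) - window``; all values are >= 0.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if window >= n:
        raise ValueError(f"window {window} must be < signal length {n}")
    sq = np.concatenate(([0.0], np.cumsum(x * x)))
    sums = sq[window : n] - sq[: n - window]
    # cumsum cancellation can leave tiny negatives on near-zero signals
    return np.sqrt(np.maximum(sums, 0.0) / window)


def _baseline_mean(g: np.ndarray, baseline: tuple[int, int]) -> float:
    t1, t2 = int(baseline[0]), int(baseline[1])
    if not (0 <= t1 < t2 <= g.size):
        raise ValueError(
            f"baseline interval ({t1}, {t2}) outside envelope range [0, {g.size}]"
        )
    return float(np.mean(g[t1:t2]))


def rms_threshold(g: np.ndarray, baseline: tuple[int, int], alpha: float) -> float:
    """``TH_r = alpha * mean(g)`` over the rest interval ``[T_s1, T_s2)``."""
    return alpha * _baseline_mean(g, baseline)


def dtf_response(x: np.ndarray, rectify: bool = True) -> np.ndarray:
    """Convolution of ``x`` with the difference template, 'same' alignment.

    The output index corresponds to the template's central zero element, so
    event indices stay aligned with the raw signal.  With ``rectify`` the
    absolute response is returned (the signed response has near-zero baseline
    mean, which would make a mean-scaled threshold degenerate).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < DIFFERENCE_TEMPLATE.size:
        raise ValueError(
            f"signal length {x.size} shorter than template "
            f"({DIFFERENCE_TEMPLATE.size} samples)"
        )
    g = np.convolve(x, DIFFERENCE_TEMPLATE, mode="same")
    return np.abs(g) if rectify else g


def smooth_response(g: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average of width ``width`` samples (0/1 = no-op)."""
    if width <= 1:
        return np.asarray(g, dtype=np.float64)
    kernel = np.full(width, 1.0 / width)
    return np.convolve(np.asarray(g, dtype=np.float64), kernel, mode="same")


def dtf_threshold(g: np.ndarray, baseline: tuple[int, int], alpha: float) -> float:
    """``TH_d = alpha * mean(g)`` over the rest interval; warns when zero."""
    th = alpha * _baseline_mean(g, baseline)
    if th == 0.0:
        logger.warning(
            "DTF threshold is 0 (zero baseline response); detection degenerate"
        )
    return th


def _runs_of_ones(z: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs of 1s in a binary series."""
    z = np.asarray(z).astype(bool)
    if z.size == 0:
        return []
    padded = np.concatenate(([False], z, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def binarize_and_segment(
    g: np.ndarray, threshold: float, spec: DetectorSpec
) -> DetectionResult:
    """Threshold an envelope/response and return the surviving events.

    ``Z[t] = 1`` iff ``g[t] > threshold``.  Runs separated by less than
    ``merge_gap`` are merged, then runs shorter than ``min_event_duration``
    are dropped.  Event boundaries are the first above-threshold and first
    below-threshold samples (half-open).
    """
    if not math.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    g = np.asarray(g, dtype=np.float64)
    z = g > threshold
    runs = _runs_of_ones(z)
    runs = _merge_runs(runs, spec.merge_gap)
    runs = [(s, e) for s, e in runs if e - s >= spec.min_event_duration]
    events = EventTable([Event(s, e) for s, e in runs])
    return DetectionResult(
        envelopes=[g],
        thresholds=[float(threshold)],
        activation=z.astype(np.int8),
        events=events,
        spec=spec,
    )


def detect_events(
    rec: Recording,
    spec: DetectorSpec,
    baseline: Optional[tuple[int, int]] = None,
) -> DetectionResult:
    """Run one TED algorithm over all channels of a (filtered) recording.

    Thresholds are calibrated per channel on the rest interval.  Per-channel
    activations are combined ('or' by default) before run extraction, and
    event indices are mapped back to raw-signal sample indices.
    """
    if baseline is None:
        baseline = rec.baseline_interval
    if baseline is None:
        raise ValueError("a baseline (rest) interval is required for thresholding")
    t1, t2 = baseline
    if t2 - t1 < spec.window:
        raise ValueError(
            f"baseline interval length {t2 - t1} shorter than detector window "
            f"{spec.window}"
        )

    envelopes: list[np.ndarray] = []
    thresholds: list[float] = []
    activations: list[np.ndarray] = []
    if spec.algorithm == "rms":
        offset = spec.window // 2 if spec.recenter else 0
        env_baseline = (t1, t2 - spec.window)
    else:
        offset = 0
        env_baseline = (t1 + _TEMPLATE_HALF, t2 - _TEMPLATE_HALF)

    for ch in range(rec.n_channels):
        x = rec.samples[ch]
        if spec.algorithm == "rms":
            g = rms_envelope(x, spec.window)
            th = rms_threshold(g, env_baseline, spec.alpha)
        else:
            g = dtf_response(x, rectify=spec.rectify)
            if spec.rectify:
                g = smooth_response(g, spec.smooth)
            th = dtf_threshold(g, env_baseline, spec.alpha)
        envelopes.append(g)
        thresholds.append(th)
        activations.append(g > th)

    comb = spec.channel_combination
    if isinstance(comb, int):
        z = activations[comb].copy()
    elif comb == "or":
        z = np.logical_or.reduce(activations)
    elif comb == "and":
        z = np.logical_and.reduce(activations)
    else:
        raise ValueError(f"unknown channel combination {comb!r}")

    if spec.edge_guard > 0:
        # filter settling transients make the recording edges unreliable
        lo = max(0, spec.edge_guard - offset)
        hi = max(0, rec.n_samples - spec.edge_guard - offset)
        z[:lo] = False
        z[hi:] = False

    runs = _runs_of_ones(z)
    runs = _merge_runs(runs, spec.merge_gap)
    runs = [(s, e) for s, e in runs if e - s >= spec.min_event_duration]
    intervals = [
        (max(0, s + offset), min(rec.n_samples, e + offset))
        for s, e in runs
        if min(rec.n_samples, e + offset) > max(0, s + offset)
    ]
    if spec.refine_window > 0 and intervals:
        intervals = _refine_boundaries(rec, spec, (t1, t2), intervals)
        # a refined event shorter than the minimum plausible tap is noise
        intervals = [
            (s, e) for s, e in intervals if e - s >= spec.min_event_duration
        ]
    events = EventTable([Event(s, e) for s, e in intervals])
    return DetectionResult(
        envelopes=envelopes,
        thresholds=thresholds,
        activation=z.astype(np.int8),
        events=events,
        index_offset=offset,
        spec=spec,
    )


def _refine_boundaries(
    rec: Recording,
    spec: DetectorSpec,
    baseline: tuple[int, int],
    intervals: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Tighten coarse event boundaries with a fine-scale activation series.

    The fine series is the channel-pooled total energy of per-channel
    ``refine_window`` RMS envelopes (rms) or ``refine_window`` moving
    averages of the rectified template response (dtf): pooling
    ``sqrt(g_1^2 + g_2^2)`` averages channel-independent noise at the
    boundary instead of letting one channel's fluctuation decide it.  The
    pooled series is thresholded at ``alpha`` times its baseline mean.  Fine
    runs shorter than one ``refine_window`` are discarded (isolated noise
    blips must not stretch a boundary).  Each event shrinks to the span of
    its longest fine run, grown by any neighbouring fine runs within one
    ``refine_window`` (burst fringes fragment at low SNR), and is then
    delimited hysteresis-style: each boundary extends outward while the fine
    series stays above its rest level (the threshold at alpha = 1), which is
    where the sub-threshold onset/offset ramps sink into the noise floor.
    For the RMS envelope the rest level is scaled by sqrt(2): an RMS
    envelope reaches that value where burst power equals noise power.
    Events with no fine activity are kept as-is.
    """
    t1, t2 = baseline
    w = spec.refine_window
    per_channel = []
    for ch in range(rec.n_channels):
        x = rec.samples[ch]
        if spec.algorithm == "rms":
            g = rms_envelope(x, w)
            full = np.zeros(rec.n_samples)
            full[w // 2 : w // 2 + g.size] = g
        else:
            full = smooth_response(dtf_response(x, rectify=True), w)
        per_channel.append(full)
    pooled = np.sqrt(np.sum(np.square(per_channel), axis=0))
    if spec.algorithm == "rms":
        rest = float(np.mean(pooled[t1 : t2 - w]))
        low_level = math.sqrt(2.0) * rest
    else:
        rest = float(np.mean(pooled[t1 + _TEMPLATE_HALF : t2 - _TEMPLATE_HALF]))
        low_level = rest
    fine = pooled > spec.alpha * rest
    low = pooled > low_level
    refined = []
    for s, e in intervals:
        runs = [
            (rs + s, re + s)
            for rs, re in _runs_of_ones(fine[s:e])
            if re - rs >= w
        ]
        if not runs:
            refined.append((s, e))
            continue
        k = int(np.argmax([re - rs for rs, re in runs]))
        lo, hi = runs[k]
        # grow over adjacent fragmented fringes
        for rs, re in runs[k + 1 :]:
            if rs - hi <= w:
                hi = re
            else:
                break
        for rs, re in reversed(runs[:k]):
            if lo - re <= w:
                lo = rs
            else:
                break
        # the sub-threshold ramp is short; cap the extension so a chance
        # noise stretch above the rest level cannot drag a boundary away
        lo_cap, hi_cap = max(s, lo - w), min(e, hi + w)
        while lo > lo_cap and low[lo - 1]:
            lo -= 1
        while hi < hi_cap and low[hi]:
            hi += 1
        refined.append((lo, hi))
    return refined


def extract_segments(
    rec: Recording, events: EventTable, segment_length: int
) -> list[np.ndarray]:
    """Cut one fixed-length window per event, centred on the event midpoint.

    Each returned array has shape ``(n_channels, segment_length)``.  Windows
    are zero-padded where they run past the recording edges and truncated
    symmetrically when the event is longer than ``segment_length``.
    """
    if segment_length % 32 != 0:
        raise ValueError(f"segment_length {segment_length} must be a multiple of 32")
    segments: list[np.ndarray] = []
    n = rec.n_samples
    for ev in events:
        if ev.end <= 0 or ev.start >= n:
            raise ValueError(
                f"event [{ev.start},{ev.end}) lies entirely outside the recording"
            )
        center = (ev.start + ev.end) // 2
        lo = center - segment_length // 2
        hi = lo + segment_length
        seg = np.zeros((rec.n_channels, segment_length), dtype=np.float64)
        src_lo, src_hi = max(lo, 0), min(hi, n)
        seg[:, src_lo - lo : src_hi - lo] = rec.samples[:, src_lo:src_hi]
        segments.append(seg)
    return segments


def compute_fder(
    detected: EventTable, truth: EventTable, tol: int
) -> FderResult:
    """Score detections against ground truth by midpoint proximity.

    Detected and truth events are matched one-to-one greedily by increasing
    midpoint distance, considering only pairs within ``tol`` samples.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    det_mid = detected.midpoints()
    tru_mid = truth.midpoints()
    # greedy by increasing midpoint distance, one-to-one
    candidates = sorted(
        (abs(dm - tm), i, j)
        for i, dm in enumerate(det_mid)
        for j, tm in enumerate(tru_mid)
        if abs(dm - tm) <= tol
    )
    used_det: set[int] = set()
    used_tru: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i not in used_det and j not in used_tru:
            used_det.add(i)
            used_tru.add(j)
            matches.append((i, j))
    matches.sort()
    unmatched_truth = set(range(len(truth))) - used_tru
    n_all = len(detected)
    n_fp = n_all - len(matches)
    n_fn = len(unmatched_truth)
    if n_all == 0:
        fder = 0.0 if n_fn == 0 else None
    else:
        fder = (n_fp + n_fn) / n_all
    return FderResult(
        fder=fder, n_fp=n_fp, n_fn=n_fn, n_all=n_all, matches=tuple(matches)
    )
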