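"""On-line detection and segmentation from accumulated state probabilities.

As the sensor stream advances, the classifier labels the trailing
window of L samples.  Each new window overwrites the estimates of the
samples it covers, so a sample's *final* estimate is the one from the
last window that contained it; estimates of samples older than the
current window never change again.  The growing per-sample record is
the accumulated state sequence.

Detection scans the most recent frames of the discretized (argmax)
sequence for the motion model's boundary-state pattern, either exactly
in order or tolerantly via longest-common-subsequence matching.  On a
match, segmentation localizes every boundary state to a single frame by
maximizing the summed log-probability of the boundary states subject to
strictly increasing frame indices — a small dynamic program over
(frame, boundary) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import SequenceClassifier
from .features import ImuStream, extract_features
from .model import MotionModel, boundary_states

__all__ = [
    "Accumulator",
    "DetectionResult",
    "SegmentationResult",
    "PipelineConfig",
    "discretize",
    "detect",
    "segment",
    "run_stream",
    "evaluate",
    "lcss_length",
]

_TINY = 1e-300  # probability floor inside logs


@dataclass
class Accumulator:
    """Growing per-sample record of state probability vectors.

    Each classifier window overwrites the estimates of the samples it
    covers, so a sample's final estimate comes from the last window
    containing it, and estimates older than the current window are
    final.
    """

    window_len: int
    num_classes: int
    _buf: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    _len: int = 0

    def __len__(self) -> int:
        return self._len

    @property
    def buffer(self) -> np.ndarray:
        """(T, K) matrix of the current per-sample estimates."""
        return self._buf[: self._len]

    def update(self, window_probs: np.ndarray, advance: int = 1) -> "Accumulator":
        """Merge the classifier output for the newest trailing window.

        ``window_probs`` covers the last L consumed samples, of which
        ``advance`` (default 1) are new since the previous update.  The
        first call initializes the buffer with the whole window.
        """
        wp = np.asarray(window_probs, dtype=np.float64)
        if wp.shape != (self.window_len, self.num_classes):
            raise ValueError(
                f"expected ({self.window_len}, {self.num_classes}) window, got {wp.shape}"
            )
        if not 1 <= advance <= self.window_len:
            raise ValueError(f"advance must be in [1, {self.window_len}]")
        end = self.window_len if self._len == 0 else self._len + advance
        if self._buf.shape[0] < end:
            grown = np.zeros((max(2 * end, 256), self.num_classes))
            if self._len:
                grown[: self._len] = self._buf[: self._len]
            self._buf = grown
        self._buf[end - self.window_len: end] = wp
        self._len = end
        return self


def discretize(buffer: np.ndarray | Accumulator) -> np.ndarray:
    """Per-sample argmax class indices; ties break toward the lower index."""
    b = buffer.buffer if isinstance(buffer, Accumulator) else np.asarray(buffer)
    if b.shape[0] == 0:
        raise ValueError("empty accumulator")
    return b.argmax(axis=1)


def lcss_length(a, b) -> int:
    """Length of the longest common subsequence of two index sequences."""
    a = list(a)
    b = list(b)
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


@dataclass
class DetectionResult:
    detected: bool
    boundary_indices: np.ndarray | None = None
    detection_time: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.detected and self.boundary_indices is not None:
            b = np.asarray(self.boundary_indices)
            if not (np.diff(b) > 0).all():
                raise ValueError("boundary indices must be strictly increasing")


@dataclass
class SegmentationResult:
    """Per-boundary frame indices and the phase intervals they delimit."""

    boundary_indices: np.ndarray
    boundary_labels: list[str]
    phases: list[tuple[str, int, int]]  # (phase name, start frame, end frame)
    detection_time: int
    score: float

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary_indices)
        if not (np.diff(b) > 0).all():
            raise ValueError("boundary indices must be strictly increasing")


def detect(acc: Accumulator | np.ndarray, model: MotionModel, horizon: int | None = None,
           mode: str = "exact", min_ratio: float = 0.8,
           start_floor: int = 0) -> DetectionResult:
    """Search the recent discretized sequence for the boundary-state pattern.

    Scans the most recent ``horizon`` frames (default: whole buffer) of the
    argmax state sequence, from the most recent frame backward.  With
    ``mode='exact'`` every boundary state must appear in temporal order;
    with ``mode='lcss'`` a match requires
    LCSS(pattern, window) / len(pattern) >= ``min_ratio``.
    ``start_floor`` masks frames before a previously consumed match so a
    completed detection does not re-fire.
    """
    probs = acc.buffer if isinstance(acc, Accumulator) else np.asarray(acc)
    if probs.ndim == 2:
        seq = discretize(probs)
    else:  # already a discrete state sequence
        seq, probs = probs, None
    t_now = len(seq) - 1
    if horizon is None:
        horizon = len(seq)
    lo = max(len(seq) - horizon, start_floor)
    window = seq[lo:]
    pattern = boundary_states(model)
    if mode == "exact":
        # greedy subsequence check (equivalent to the reverse scan)
        pos = lo
        hits = []
        for state in pattern:
            found = np.nonzero(window[pos - lo:] == state)[0]
            if len(found) == 0:
                return DetectionResult(False)
            pos = pos + found[0]
            hits.append(pos)
            pos += 1
        score = (
            float(np.mean([probs[h, k] for h, k in zip(hits, pattern)]))
            if probs is not None else 1.0
        )
        return DetectionResult(True, np.asarray(hits), t_now, score)
    elif mode == "lcss":
        ratio = lcss_length(pattern, window.tolist()) / len(pattern)
        if ratio < min_ratio:
            return DetectionResult(False)
        return DetectionResult(True, None, t_now, ratio)
    raise ValueError(f"unknown detection mode {mode!r}")


def segment(acc: Accumulator | np.ndarray, model: MotionModel,
            search_range: tuple[int, int] | None = None,
            method: str = "dp") -> SegmentationResult:
    """Localize each boundary state to one frame within ``search_range``.

    The frame indices b_1 < b_2 < ... < b_{N+1} maximize the summed
    log-probability of the respective boundary states, found globally by
    dynamic programming over (frame, boundary) pairs.  Ties resolve to
    the lexicographically smallest index tuple.  ``method='greedy'``
    instead takes each state's unconstrained argmax left-to-right,
    restricted to frames after the previous boundary.
    """
    buffer = acc.buffer if isinstance(acc, Accumulator) else np.asarray(acc)
    pattern = boundary_states(model)
    nb = len(pattern)
    lo, hi = (0, buffer.shape[0]) if search_range is None else search_range
    probs = buffer[lo:hi][:, pattern]  # (F, nb)
    F = probs.shape[0]
    if F < nb:
        raise ValueError(f"search range of {F} frames cannot hold {nb} ordered boundaries")
    logp = np.log(np.maximum(probs, _TINY))

    if method == "greedy":
        idx = []
        prev = -1
        for k in range(nb):
            cand = int(np.argmax(logp[prev + 1:, k])) + prev + 1
            idx.append(cand)
            prev = cand
        b = np.asarray(idx)
    elif method == "dp":
        # g[k, f] = best score placing boundaries k..nb-1 with b_k = f
        g = np.full((nb, F), -np.inf)
        g[nb - 1] = logp[:, nb - 1]
        for k in range(nb - 2, -1, -1):
            # best over f' > f of g[k+1, f']  (suffix max, shifted by one)
            suff = np.maximum.accumulate(g[k + 1][::-1])[::-1]
            g[k, :F - 1] = logp[:F - 1, k] + suff[1:]
        b = np.empty(nb, dtype=np.int64)
        best = g[0].max()
        b[0] = int(np.flatnonzero(g[0] >= best - 1e-12)[0])
        for k in range(1, nb):
            # remaining score after fixing b[k-1]
            target = g[k - 1, b[k - 1]] - logp[b[k - 1], k - 1]
            cand = np.flatnonzero(g[k] >= target - 1e-12)
            cand = cand[cand > b[k - 1]]
            b[k] = int(cand[0])
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    b = b + lo
    labels = [model.label_of(k) for k in pattern]
    phases = [
        (sm.name, int(b[i]), int(b[i + 1]))
        for i, sm in enumerate(model.sub_motions)
    ]
    score = float(np.mean([buffer[f, k] for f, k in zip(b, pattern)]))
    return SegmentationResult(
        boundary_indices=b,
        boundary_labels=labels,
        phases=phases,
        detection_time=hi - 1,
        score=score,
    )


@dataclass
class PipelineConfig:
    """Streaming options: classifier stride, detection horizon and mode."""

    stride: int = 1            # frames between classifier invocations
    horizon: int | None = None  # detection horizon in frames; default 3 * L
    mode: str = "exact"
    min_ratio: float = 0.8
    segmentation_method: str = "dp"


def run_stream(stream: ImuStream, classifier: SequenceClassifier, model: MotionModel,
               config: PipelineConfig | None = None) -> list[SegmentationResult]:
    """Replay a recording as an on-line stream; return motions in order.

    Features are extracted once (each per-sample feature depends only on
    current and previous raw samples, so this matches incremental
    extraction), then the classifier labels the trailing window at each
    stride step, the accumulator merges estimates, and detection is
    attempted.  A completed match is segmented, emitted, and consumed so
    it cannot re-fire; the search then resumes after the matched span.
    """
    config = config or PipelineConfig()
    L = classifier.config.window_len
    T = len(stream)
    if T < L:
        raise ValueError(f"stream of {T} frames is shorter than the window ({L})")
    horizon = config.horizon if config.horizon is not None else 3 * L
    feats = classifier.standardizer.transform(extract_features(stream)).values

    # classifier outputs for every window position, computed in batches;
    # identical to per-sample invocation because the net is stateless
    starts = np.arange(0, T - L + 1, config.stride)
    all_probs = classifier.predict_batch(feats[starts[:, None] + np.arange(L)])

    acc = Accumulator(window_len=L, num_classes=classifier.config.num_classes)
    results: list[SegmentationResult] = []
    consumed = 0  # frames before this index belong to already-emitted motions
    for wi in range(len(starts)):
        acc.update(all_probs[wi], advance=config.stride)
        det = detect(acc, model, horizon=min(horizon, len(acc)),
                     mode=config.mode, min_ratio=config.min_ratio,
                     start_floor=consumed)
        if det.detected:
            t_now = len(acc) - 1
            lo = max(consumed, t_now - horizon + 1)
            seg = segment(acc, model, (lo, t_now + 1), method=config.segmentation_method)
            results.append(seg)
            consumed = int(seg.boundary_indices[-1]) + 1
    return results


def evaluate(results: dict[str, SegmentationResult | None],
             truth: dict[str, np.ndarray],
             boundary_labels: list[str] | None = None) -> dict:
    """Detection rate and per-boundary mean absolute error in frames.

    Errors are averaged over detected recordings only; undetected
    recordings lower the detection rate but do not enter the error
    means.
    """
    if set(results) != set(truth):
        raise ValueError("results and truth must cover the same recordings")
    total = len(truth)
    detected_ids = [rid for rid, r in results.items() if r is not None]
    rate = len(detected_ids) / total if total else 0.0
    per_boundary: dict[str, list[float]] = {}
    for rid in detected_ids:
        est = np.asarray(results[rid].boundary_indices, dtype=float)
        tru = np.asarray(truth[rid], dtype=float)
        if est.shape != tru.shape:
            raise ValueError(f"recording {rid}: boundary count mismatch")
        labels = boundary_labels or results[rid].boundary_labels
        for lab, e in zip(labels, np.abs(est - tru)):
            per_boundary.setdefault(lab, []).append(e)
    return {
        "n_recordings": total,
        "n_detected": len(detected_ids),
        "detection_rate": rate,
        "boundary_mae": {lab: float(np.mean(v)) for lab, v in per_boundary.items()},
    }
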