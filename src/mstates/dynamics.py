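"""Back-fitting, temporal smoothing, and the microstate parameter suite.

Templates are fitted back to *every* sample of the (band-filtered,
average-referenced) recording, not just GFP peaks: each sample takes the
class of the template with the highest absolute spatial correlation.
Short segments (< 30 ms by default) are then iteratively relabeled to
their next most likely class until none remain.  The first and last
microstates of each artifact-free segment may be truncated by the
boundary and are excluded from all per-class parameters; coverage is
renormalized over the remaining samples so the classes still sum to 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster import TemplateSet, _normalize
from .recording import EEGRecording, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class Run:
    cls: int
    start: int  # absolute sample index, half-open interval
    end: int
    truncated: bool


@dataclass
class MicrostateSequence:
    """Per-sample class labels with the correlation evidence behind them."""

    labels: np.ndarray              # (n_samples,) class index
    sc: np.ndarray                  # (k, n_samples) |spatial correlation|
    fs: float
    segments: list[tuple[int, int]]  # artifact-free intervals of the recording
    smoothed: bool = False
    class_labels: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.sc.shape[0]

    def runs(self) -> list[Run]:
        """Segment list: maximal constant-label runs, flagged if they touch a boundary."""
        out: list[Run] = []
        for a, b in self.segments:
            lab = self.labels[a:b]
            changes = np.flatnonzero(np.diff(lab)) + 1
            bounds = np.concatenate([[0], changes, [b - a]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                out.append(Run(int(lab[s]), a + int(s), a + int(e),
                               truncated=(s == 0 or e == b - a)))
        return out


def backfit(rec: EEGRecording, templates: TemplateSet) -> MicrostateSequence:
    """Assign every sample to the template with the highest |spatial correlation|.

    Processing is per artifact-free segment; labels never bridge a gap.
    Zero-variance samples carry the previous sample's class (correlations
    set to 0).
    """
    if templates.maps.shape[1] != rec.n_channels:
        raise ParameterError("templates and recording have different channel counts")
    tn = _normalize(templates.maps)
    n = rec.n_samples
    k = templates.k
    sc = np.zeros((k, n))
    labels = np.zeros(n, dtype=int)
    for a, b, seg in rec.iter_segments():
        maps = seg.T  # samples x channels
        centered = maps - maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        safe = norms.copy()
        degenerate = norms < 1e-12
        safe[degenerate] = 1.0
        corr = np.abs((centered / safe[:, None]) @ tn.T)  # samples x k
        corr[degenerate] = 0.0
        sc[:, a:b] = corr.T
        lab = np.argmax(corr, axis=1)
        if degenerate.any():
            logger.info("%d zero-variance samples labeled by carry-over", degenerate.sum())
            for i in np.flatnonzero(degenerate):
                lab[i] = lab[i - 1] if i > 0 else lab[~degenerate][0] if (~degenerate).any() else 0
        labels[a:b] = lab
    return MicrostateSequence(labels=labels, sc=sc, fs=rec.fs,
                              segments=list(rec.segments),
                              class_labels=list(templates.labels))


def min_samples(min_ms: float, fs: float) -> int:
    """Smallest run length (samples) whose duration is >= ``min_ms``."""
    return int(np.ceil(min_ms * fs / 1000.0))


def smooth_sequence(seq: MicrostateSequence, min_ms: float = 30.0,
                    max_passes: int = 50) -> MicrostateSequence:
    """Relabel sub-threshold segments to their next most likely class.

    Iteratively, each run shorter than ``min_ms`` has its samples moved to
    the class with the highest spatial correlation among the classes other
    than the rejected one; passes repeat until no short run remains.  If
    the pass cap is hit (relabeling can oscillate on noisy evidence),
    remaining short runs are merged into their longer neighbor.
    """
    need = min_samples(min_ms, seq.fs)
    labels = seq.labels.copy()
    out = replace(seq, labels=labels, smoothed=True)
    for _ in range(max_passes):
        short = sorted((r for r in out.runs() if r.end - r.start < need),
                       key=lambda r: r.end - r.start)
        if not short:
            return out
        for r in short:
            sc = out.sc[:, r.start:r.end].copy()
            sc[r.cls] = -np.inf
            labels[r.start:r.end] = np.argmax(sc, axis=0)
    logger.warning("smoothing iteration cap hit; force-merging remaining short runs")
    for _ in range(len(out.runs())):
        runs = out.runs()
        short = [r for r in runs if r.end - r.start < need]
        # runs spanning a whole artifact segment have no neighbor to merge into
        fixable = [r for r in short
                   if not (r.truncated and (r.start, r.end) in seq.segments)]
        if not fixable:
            break
        r = min(fixable, key=lambda q: q.end - q.start)
        left = next((q for q in runs if q.end == r.start), None)
        right = next((q for q in runs if q.start == r.end), None)
        pick = max((q for q in (left, right) if q is not None),
                   key=lambda q: q.end - q.start)
        labels[r.start:r.end] = pick.cls
    return out


@dataclass
class ParameterTable:
    """Per-class microstate parameters plus the SC and TP matrices."""

    table: pd.DataFrame       # index: class label; columns: gev, mean_duration, ...
    sc_matrix: pd.DataFrame   # k x k, SC[X, Y] = mean |corr(template X, maps of class Y)|
    tp_matrix: pd.DataFrame   # k x k, observed - expected transition probability

    def to_long(self, recording_id: str = "") -> pd.DataFrame:
        long = self.table.reset_index(names="class").melt(
            id_vars="class", var_name="parameter", value_name="value")
        long.insert(0, "recording", recording_id)
        return long


def spatial_correlation_matrix(seq: MicrostateSequence,
                               include_truncated: bool = False) -> np.ndarray:
    """SC[X, Y]: mean |corr| of template X with the maps labeled Y (not symmetric)."""
    keep = np.zeros(seq.labels.size, dtype=bool)
    for r in seq.runs():
        if include_truncated or not r.truncated:
            keep[r.start:r.end] = True
    k = seq.k
    out = np.full((k, k), np.nan)
    for y in range(k):
        idx = keep & (seq.labels == y)
        if idx.any():
            out[:, y] = seq.sc[:, idx].mean(axis=1)
    return out


def transition_probabilities(seq: MicrostateSequence) -> np.ndarray:
    """Observed minus expected transition probability between classes.

    Observed: row-normalized counts of transitions between consecutive
    non-truncated runs inside the same artifact-free segment.  Expected:
    the destination class's share of non-truncated run counts among all
    classes except the source.  Diagonal 0; rows of the difference sum
    to 0.  Classes with no outgoing transition give NaN rows.
    """
    runs = [r for r in seq.runs() if not r.truncated]
    if len(runs) < 2:
        raise ParameterError("need at least 2 non-truncated runs for transitions")
    k = seq.k
    counts = np.zeros((k, k))
    for prev, nxt in zip(runs[:-1], runs[1:]):
        if prev.end == nxt.start:  # adjacent within one segment
            counts[prev.cls, nxt.cls] += 1
    n_runs = np.array([sum(1 for r in runs if r.cls == c) for c in range(k)], dtype=float)
    observed = np.full((k, k), np.nan)
    expected = np.full((k, k), np.nan)
    for x in range(k):
        out_total = counts[x].sum()
        others = np.delete(np.arange(k), x)
        denom = n_runs[others].sum()
        if out_total > 0 and denom > 0:
            observed[x] = counts[x] / out_total
            expected[x, others] = n_runs[others] / denom
            expected[x, x] = 0.0
    tp = observed - expected
    np.fill_diagonal(tp, 0.0)
    return tp


def compute_parameters(seq: MicrostateSequence, gfp: np.ndarray,
                       fs: float | None = None) -> ParameterTable:
    """The full per-class parameter suite of a smoothed microstate sequence.

    Truncated runs are excluded from every per-class aggregate, and
    coverage/GEV are renormalized over the non-excluded samples.  Units:
    GEV and coverage in percent, duration and interval in ms, occurrence
    in 1/s, mean GFP in the amplitude unit of the recording.
    """
    if not seq.smoothed:
        logger.warning("computing parameters on an unsmoothed sequence")
    fs = fs or seq.fs
    k = seq.k
    names = seq.class_labels or [str(c) for c in range(k)]
    runs = [r for r in seq.runs() if not r.truncated]
    keep = np.zeros(seq.labels.size, dtype=bool)
    for r in runs:
        keep[r.start:r.end] = True
    total_samples = int(keep.sum())
    if total_samples == 0:
        raise ParameterError("no non-truncated samples to analyze")
    total_s = total_samples / fs
    gfp = np.asarray(gfp, dtype=float)
    gfp_denom = np.sum(gfp[keep] ** 2)

    rows = {}
    for c in range(k):
        c_runs = [r for r in runs if r.cls == c]
        c_idx = keep & (seq.labels == c)
        n_c = int(c_idx.sum())
        durations = [(r.end - r.start) * 1000.0 / fs for r in c_runs]
        intervals = []
        for a, b in seq.segments:
            seg_runs = [r for r in c_runs if a <= r.start and r.end <= b]
            for prev, nxt in zip(seg_runs[:-1], seg_runs[1:]):
                intervals.append((nxt.start - prev.end) * 1000.0 / fs)
        gev_c = 100.0 * np.sum((gfp[c_idx] * seq.sc[c, c_idx]) ** 2) / gfp_denom
        rows[names[c]] = {
            "gev": gev_c,
            "mean_duration": float(np.mean(durations)) if durations else np.nan,
            "occurrence": len(c_runs) / total_s,
            "coverage": 100.0 * n_c / total_samples,
            "mean_interval": float(np.mean(intervals)) if intervals else np.nan,
            "mean_gfp": float(gfp[c_idx].mean()) if n_c else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "class"

    sc = pd.DataFrame(spatial_correlation_matrix(seq), index=names, columns=names)
    try:
        tp = transition_probabilities(seq)
    except ParameterError:
        tp = np.full((k, k), np.nan)
    tp = pd.DataFrame(tp, index=names, columns=names)
    return ParameterTable(table=table, sc_matrix=sc, tp_matrix=tp)
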