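"""Shuffle-null classification of stimulus-responsive cells.

A cell is called responsive to a set of windows (shock, tones, opto
pulses) when its pooled event rate inside the windows exceeds the mean of
a timing-shuffle null by a configurable number of null standard
deviations (1 s.d. by default). The null redraws each event's time
uniformly over the session, preserving the cell's event count, and
recomputes the pooled in-window rate per iteration — so a cell is flagged
only if its events concentrate in the windows more than chance placement
of the same number of events would produce.

Also provides the peri-LED response heatmap used to summarise
optogenetic silencing: per-cell event-filtered activity averaged over
pulses in 200-ms bins across [-6 s, +6 s), min-max normalized, rows
sorted by ON-OFF change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import EventTrain, TraceMatrix

__all__ = [
    "ShuffleNull",
    "CellLabels",
    "WindowResponsiveClassifier",
    "classify_window_responsive",
    "opto_response_heatmap",
    "event_filtered_traces",
]


@dataclass
class ShuffleNull:
    """Null distribution of in-window event rates for one cell."""

    rates: np.ndarray  # events/min, one per shuffle iteration
    mean: float
    sd: float


@dataclass
class CellLabels:
    """Per-cell responsiveness flags with their provenance."""

    flags: dict[str, int]
    observed_rate: dict[str, float]  # events/min
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    windows: list[tuple[float, float]]
    sd_threshold: float
    n_shuffles: int
    seed: int | None


def _pooled_rate(times: np.ndarray, windows: np.ndarray, total: float) -> float:
    """Events/min pooled over all windows ([start, end) each)."""
    count = 0
    for start, end in windows:
        count += int(np.count_nonzero((times >= start) & (times < end)))
    return count * 60.0 / total


class WindowResponsiveClassifier(BaseEstimator):
    """Flag cells whose in-window rate beats a timing-shuffle null.

    Parameters
    ----------
    windows : list of (start, end)
        Response windows in seconds (pooled). For shock cells this is
        the shock window; for tone cells the tone periods; for opto-stim
        cells the first 6 s of each LED pulse.
    duration : float
        Session duration in seconds; shuffled times are uniform on
        ``[0, duration)``.
    n_shuffles : int
        Null iterations (1000).
    sd_threshold : float
        Flag iff observed > null mean + sd_threshold * null s.d.
    scheme : str
        ``"uniform"`` redraws each event time uniformly;
        ``"circular"`` applies one uniform circular shift per iteration.
    random_state : int or None
        Seed; identical train + seed give identical flags and nulls.

    Attributes (after ``fit``)
    --------------------------
    ``labels_`` : :class:`CellLabels`; ``nulls_`` : per-cell
    :class:`ShuffleNull`.
    """

    def __init__(
        self,
        windows: list[tuple[float, float]],
        duration: float,
        n_shuffles: int = 1000,
        sd_threshold: float = 1.0,
        scheme: str = "uniform",
        random_state: int | None = None,
    ) -> None:
        self.windows = windows
        self.duration = duration
        self.n_shuffles = n_shuffles
        self.sd_threshold = sd_threshold
        self.scheme = scheme
        self.random_state = random_state

    def _validate(self) -> np.ndarray:
        if not self.windows:
            raise ValueError("need at least one window")
        win = np.asarray(self.windows, dtype=float)
        for start, end in win:
            if not (0 <= start < end <= self.duration):
                raise ValueError(
                    f"window ({start}, {end}) outside [0, {self.duration}]"
                )
        if self.scheme not in ("uniform", "circular"):
            raise ValueError("scheme must be 'uniform' or 'circular'")
        return win

    def fit(self, trains: list[EventTrain], y=None) -> "WindowResponsiveClassifier":
        win = self._validate()
        total = float(np.sum(win[:, 1] - win[:, 0]))
        rng = np.random.default_rng(self.random_state)
        flags, obs, nmean, nsd = {}, {}, {}, {}
        nulls = {}
        for train in trains:
            times = train.times
            observed = _pooled_rate(times, win, total)
            n = times.size
            if n == 0:
                null_rates = np.zeros(self.n_shuffles)
            elif self.scheme == "uniform":
                shuf = rng.random((self.n_shuffles, n)) * self.duration
                inside = np.zeros(self.n_shuffles)
                for start, end in win:
                    inside += np.count_nonzero(
                        (shuf >= start) & (shuf < end), axis=1
                    )
                null_rates = inside * 60.0 / total
            else:
                shifts = rng.random(self.n_shuffles) * self.duration
                null_rates = np.empty(self.n_shuffles)
                for k, sh in enumerate(shifts):
                    shifted = np.mod(times + sh, self.duration)
                    null_rates[k] = _pooled_rate(shifted, win, total)
            mu = float(null_rates.mean())
            sd = float(null_rates.std())
            nulls[train.cell_id] = ShuffleNull(null_rates, mu, sd)
            flags[train.cell_id] = int(
                n > 0 and observed > mu + self.sd_threshold * sd
            )
            obs[train.cell_id] = observed
            nmean[train.cell_id] = mu
            nsd[train.cell_id] = sd
        self.nulls_ = nulls
        self.labels_ = CellLabels(
            flags=flags,
            observed_rate=obs,
            null_mean=nmean,
            null_sd=nsd,
            windows=[tuple(w) for w in win],
            sd_threshold=self.sd_threshold,
            n_shuffles=self.n_shuffles,
            seed=self.random_state,
        )
        self.n_features_in_ = len(trains)
        return self

    def predict(self, trains: list[EventTrain]) -> np.ndarray:
        """Flags for ``trains`` in order (fits if not already fitted)."""
        if not hasattr(self, "labels_") or set(
            t.cell_id for t in trains
        ) - set(self.labels_.flags):
            self.fit(trains)
        return np.array([self.labels_.flags[t.cell_id] for t in trains])


def classify_window_responsive(
    train: EventTrain,
    windows: list[tuple[float, float]],
    duration: float,
    n_shuffles: int = 1000,
    sd_threshold: float = 1.0,
    seed: int | None = None,
) -> tuple[int, ShuffleNull]:
    """Flag one cell against its timing-shuffle null (thin wrapper)."""
    clf = WindowResponsiveClassifier(
        windows=windows,
        duration=duration,
        n_shuffles=n_shuffles,
        sd_threshold=sd_threshold,
        random_state=seed,
    ).fit([train])
    return clf.labels_.flags[train.cell_id], clf.nulls_[train.cell_id]


def event_filtered_traces(
    traces: TraceMatrix, trains: list[EventTrain], pad: float = 1.0
) -> TraceMatrix:
    """Zero the trace outside detected-transient neighbourhoods.

    Keeps ``[peak - pad, peak + pad]`` s around each event and sets all
    other timepoints to zero baseline, the pre-filtering used before
    averaging peri-stimulus activity.
    """
    out = np.zeros_like(traces.values)
    t = traces.frame_times()
    by_id = {tr.cell_id: tr for tr in trains}
    for i, cid in enumerate(traces.cell_ids):
        tr = by_id.get(cid)
        if tr is None:
            continue
        keep = np.zeros(traces.n_frames, dtype=bool)
        for te in tr.times:
            keep |= (t >= te - pad) & (t <= te + pad)
        out[i, keep] = traces.values[i, keep]
    return TraceMatrix(out, traces.fps, list(traces.cell_ids), traces.session)


def opto_response_heatmap(
    traces: TraceMatrix,
    led_onsets: list[float],
    window: float = 6.0,
    bin_width: float = 0.2,
    normalize: str = "global",
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Peri-LED activity heatmap: cells x 60 bins, sorted by ON-OFF change.

    Per cell, activity (ideally event-filtered: see
    :func:`event_filtered_traces`) is averaged across LED onsets in
    ``bin_width`` bins over ``[-window, +window)`` s. The matrix is then
    min-max normalized — over the whole matrix by default
    (``normalize="global"``) or per row (``"row"``) — and rows are
    ordered by mean(ON bins) - mean(OFF bins), most suppressed last.

    Returns (sorted heatmap, row order as indices into ``traces``, the
    onsets actually used). Onsets without a full window on both sides
    are dropped with a warning.
    """
    import warnings

    if normalize not in ("global", "row"):
        raise ValueError("normalize must be 'global' or 'row'")
    n_bins = int(round(2 * window / bin_width))
    frames_per_bin = bin_width * traces.fps
    if abs(frames_per_bin - round(frames_per_bin)) > 1e-9:
        raise ValueError("bin_width must be a whole number of frames")
    fpb = int(round(frames_per_bin))
    used = []
    for onset in led_onsets:
        if onset - window < 0 or onset + window > traces.duration + 1e-9:
            warnings.warn(
                f"LED onset {onset} s too close to the recording edge; dropped"
            )
            continue
        used.append(onset)
    if not used:
        raise ValueError("no usable LED onsets")
    acc = np.zeros((traces.n_cells, n_bins))
    for onset in used:
        start = int(round((onset - window) * traces.fps))
        block = traces.values[:, start: start + n_bins * fpb]
        acc += block.reshape(traces.n_cells, n_bins, fpb).mean(axis=2)
    acc /= len(used)
    half = n_bins // 2
    change = acc[:, half:].mean(axis=1) - acc[:, :half].mean(axis=1)
    if normalize == "global":
        lo, hi = acc.min(), acc.max()
        norm = (acc - lo) / (hi - lo) if hi > lo else np.zeros_like(acc)
    else:
        lo = acc.min(axis=1, keepdims=True)
        hi = acc.max(axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        norm = (acc - lo) / span
    order = np.argsort(-change, kind="stable")
    return norm[order], order, used
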