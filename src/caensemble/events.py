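"""Ca2+ transient event detection from fluorescence traces.

The detector converts per-cell fluorescence into trains of transient peak
times and amplitudes. Traces are z-scored by subtracting a mean computed
over "silent" timepoints (frames whose fluorescence falls below the pooled
0.50 quantile of all values in the FOV) and dividing by an estimated
Gaussian noise level (robust 1.4826*MAD by default, so transients barely
inflate it). Candidate transients are then excursions above a 0.5 s.d.
baseline that reach at least 2 s.d. and last at least the indicator-limited
minimum duration for their amplitude. Large multi-peaked envelopes are
split into separate rising events using a peak-prominence rule
(prominence >= 1.5 s.d., separation >= 1 s), mirroring how GCaMP6f
recordings are conventionally processed after source extraction.

Noise is estimated at the native acquisition rate; block-averaging down to
the 5 fps analysis rate then suppresses analysis-rate noise (by ~sqrt of
the downsampling factor) while leaving transient amplitudes on the same
scale, so the 2 s.d. amplitude criterion stays meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EventTrain, TraceMatrix

__all__ = [
    "DetectionParams",
    "EventDetector",
    "downsample",
    "zscore_traces",
    "min_duration",
    "detect_events",
    "event_rate",
]


@dataclass
class DetectionParams:
    """Event-detection parameters, in noise-s.d. (z) units unless noted.

    Attributes
    ----------
    amp_threshold : float
        Minimum peak amplitude for an accepted transient (2 s.d.).
    baseline : float
        Baseline level that a transient must rise from and return to
        (0.5 s.d.).
    a0 : float
        Reference amplitude of the minimum-duration rule (0.5 s.d.).
    t_half : float
        Indicator decay half-time in seconds (0.2 s for GCaMP6f).
    peak_prominence : float
        Minimum prominence for secondary rising peaks inside one
        envelope (1.5 s.d.).
    min_peak_distance : float
        Minimum separation between peaks in seconds (1 s).
    silent_quantile : float
        Pooled quantile below which frames count as silent (0.50).
    target_fps : float
        Analysis frame rate after temporal downsampling (5 fps).
    noise_estimator : str
        How the per-cell noise s.d. is estimated: ``"mad"`` (robust
        1.4826*MAD about the median, default), ``"silent"`` (s.d. of the
        silent timepoints) or ``"full"`` (plain trace s.d.).
    truncation_correction : bool
        Silent timepoints are the sub-quantile tail of the baseline
        noise, so their raw mean under-estimates the baseline by
        ``sigma * phi(z_F) / F`` for Gaussian noise (``F`` = the cell's
        silent fraction). When True (default) the centre is corrected by
        that amount, which vanishes as the silent set approaches the
        whole baseline; when False the literal silent mean is used.
    amp_attenuation : float or None
        Peak attenuation incurred by block-averaging a transient down to
        ``target_fps``. When the detector downsamples, amplitudes are
        estimated on the native scale with a two-tap template derived
        from the reference indicator kernel (:func:`kernel_bin_profile`)
        and the amplitude threshold applied there; ``None`` (default)
        computes the template automatically. Setting a float uses that
        single-tap attenuation instead; 1.0 disables correction.
    gap_tolerance : float
        Sub-baseline dips up to this long (s) do not terminate a
        candidate envelope; a return to baseline is only confirmed
        after this much sub-baseline time, since single-frame dips are
        common at the analysis-rate noise level. Default 0.4 s (two
        analysis frames).
    """

    amp_threshold: float = 2.0
    baseline: float = 0.5
    a0: float = 0.5
    t_half: float = 0.2
    peak_prominence: float = 1.5
    min_peak_distance: float = 1.0
    silent_quantile: float = 0.50
    target_fps: float = 5.0
    noise_estimator: str = "mad"
    truncation_correction: bool = True
    amp_attenuation: float | None = None
    gap_tolerance: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "amp_threshold",
            "baseline",
            "a0",
            "t_half",
            "peak_prominence",
            "min_peak_distance",
            "silent_quantile",
            "target_fps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.amp_threshold <= self.baseline:
            raise ValueError("amp_threshold must exceed baseline")
        if self.noise_estimator not in ("mad", "silent", "full"):
            raise ValueError("noise_estimator must be 'mad', 'silent' or 'full'")
        if self.amp_attenuation is not None and not 0 < self.amp_attenuation <= 1:
            raise ValueError("amp_attenuation must be in (0, 1]")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")


def kernel_bin_profile(
    bin_width: float,
    t_half: float = 0.2,
    rise: float = 0.1,
    n_phase: int = 64,
) -> tuple[float, float]:
    """Peak-bin and following-bin values of a block-averaged transient.

    A unit-amplitude reference transient (linear rise over ``rise`` s,
    exponential decay with half-time ``t_half``) averaged into
    non-overlapping bins of ``bin_width`` s has its peak bin reduced below
    1 and a characteristic value in the next bin. Both depend on where the
    peak falls within a bin, so they are averaged over a uniform phase.
    They form the two-tap template used to estimate native-scale
    amplitudes from downsampled traces.
    """
    dt = bin_width / 400.0
    tt = np.arange(-rise, 12.0 * t_half, dt)
    kernel = np.where(tt < 0, 1.0 + tt / rise, np.power(2.0, -tt / t_half))
    kernel = np.maximum(kernel, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(kernel) * dt))
    first, second = [], []
    for phase in np.linspace(0.0, bin_width, n_phase, endpoint=False):
        # bin edges aligned so the peak (t=0) sits at `phase` inside a bin
        edges = np.arange(-rise - phase, tt[-1] + bin_width, bin_width)
        idx = np.clip(((edges - tt[0]) / dt).astype(int), 0, len(csum) - 1)
        areas = np.diff(csum[idx]) / bin_width
        if areas.size:
            j = int(np.argmax(areas))
            first.append(areas[j])
            second.append(areas[j + 1] if j + 1 < areas.size else 0.0)
    return float(np.mean(first)), float(np.mean(second))


def block_attenuation(
    bin_width: float,
    t_half: float = 0.2,
    rise: float = 0.1,
    n_phase: int = 64,
) -> float:
    """Expected peak attenuation of a transient under block averaging."""
    return kernel_bin_profile(bin_width, t_half, rise, n_phase)[0]


def downsample(traces: TraceMatrix, target_fps: float) -> TraceMatrix:
    """Average frames in non-overlapping blocks down to ``target_fps``.

    The native rate must be an integer multiple of the target rate.
    Trailing frames that do not fill a complete block are dropped.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    factor = traces.fps / target_fps
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fps {traces.fps} is not an integer multiple of target {target_fps}"
        )
    factor = int(round(factor))
    if factor == 1:
        return TraceMatrix(
            traces.values.copy(), target_fps, list(traces.cell_ids), traces.session
        )
    n_blocks = traces.n_frames // factor
    blocked = traces.values[:, : n_blocks * factor].reshape(
        traces.n_cells, n_blocks, factor
    )
    return TraceMatrix(
        blocked.mean(axis=2), target_fps, list(traces.cell_ids), traces.session
    )


def min_duration(amplitude: float, params: DetectionParams | None = None) -> float:
    """Minimum duration (s) a transient of peak ``amplitude`` must last.

    A transient decaying exponentially with half-time ``t_half`` from peak
    amplitude ``A`` takes ``t_half * log2(A / A0)`` seconds to return to the
    reference level ``A0``; smaller amplitudes get (floored) zero.
    """
    params = params or DetectionParams()
    if amplitude < params.baseline:
        raise ValueError(
            f"amplitude {amplitude} below baseline {params.baseline}"
        )
    return max(0.0, params.t_half * math.log2(amplitude / params.a0))


class EventDetector(BaseEstimator, TransformerMixin):
    """Transform fluorescence traces into per-cell event trains.

    ``fit`` estimates the FOV-pooled silent threshold, the per-cell silent
    mean and the per-cell noise s.d.; ``transform`` z-scores the traces,
    downsamples them to ``target_fps`` and extracts events. Cells with a
    degenerate noise estimate (zero) are flagged in ``excluded_cells_`` and
    yield empty trains so FOV denominators stay intact.

    Parameters mirror :class:`DetectionParams`.
    """

    def __init__(
        self,
        amp_threshold: float = 2.0,
        baseline: float = 0.5,
        a0: float = 0.5,
        t_half: float = 0.2,
        peak_prominence: float = 1.5,
        min_peak_distance: float = 1.0,
        silent_quantile: float = 0.50,
        target_fps: float = 5.0,
        noise_estimator: str = "mad",
        truncation_correction: bool = True,
        amp_attenuation: float | None = None,
        gap_tolerance: float = 0.4,
    ) -> None:
        self.amp_threshold = amp_threshold
        self.baseline = baseline
        self.a0 = a0
        self.t_half = t_half
        self.peak_prominence = peak_prominence
        self.min_peak_distance = min_peak_distance
        self.silent_quantile = silent_quantile
        self.target_fps = target_fps
        self.noise_estimator = noise_estimator
        self.truncation_correction = truncation_correction
        self.amp_attenuation = amp_attenuation
        self.gap_tolerance = gap_tolerance

    def _params(self) -> DetectionParams:
        return DetectionParams(
            amp_threshold=self.amp_threshold,
            baseline=self.baseline,
            a0=self.a0,
            t_half=self.t_half,
            peak_prominence=self.peak_prominence,
            min_peak_distance=self.min_peak_distance,
            silent_quantile=self.silent_quantile,
            target_fps=self.target_fps,
            noise_estimator=self.noise_estimator,
            truncation_correction=self.truncation_correction,
            amp_attenuation=self.amp_attenuation,
            gap_tolerance=self.gap_tolerance,
        )

    def fit(self, traces: TraceMatrix, y=None) -> "EventDetector":
        """Estimate silent-frame statistics from a (raw-rate) trace matrix."""
        params = self._params()
        values = traces.values
        if not np.isfinite(values).all():
            bad = [
                traces.cell_ids[i]
                for i in range(traces.n_cells)
                if not np.isfinite(values[i]).any()
            ]
            if bad:
                raise ValueError(f"all-NaN cells: {bad}")
            raise ValueError("traces contain non-finite values")
        if np.unique(values).size < 2:
            raise ValueError("need at least two distinct fluorescence values")
        # pooled across every cell and frame in the FOV
        self.silent_threshold_ = float(
            np.quantile(values, params.silent_quantile)
        )
        silent = values < self.silent_threshold_
        means = np.full(traces.n_cells, np.nan)
        sds = np.full(traces.n_cells, np.nan)
        excluded: list[str] = []
        for i in range(traces.n_cells):
            sel = values[i, silent[i]]
            if sel.size < 2:
                excluded.append(traces.cell_ids[i])
                continue
            sd = _noise_sd(values[i], sel, params.noise_estimator)
            if sd == 0 or not np.isfinite(sd):
                excluded.append(traces.cell_ids[i])
                continue
            centre = sel.mean()
            if params.truncation_correction:
                frac = sel.size / values.shape[1]
                centre += sd * norm.pdf(norm.ppf(frac)) / frac
            means[i] = centre
            sds[i] = sd
        self.silent_mean_ = means
        self.noise_sd_ = sds
        self.excluded_cells_ = excluded
        self.n_features_in_ = traces.n_frames
        return self

    def zscore(self, traces: TraceMatrix) -> TraceMatrix:
        """Return traces in z units using the fitted silent statistics."""
        z = (traces.values - self.silent_mean_[:, None]) / self.noise_sd_[:, None]
        return TraceMatrix(z, traces.fps, list(traces.cell_ids), traces.session)

    def transform(self, traces: TraceMatrix) -> list[EventTrain]:
        """Z-score, downsample to ``target_fps`` and detect events per cell.

        Excluded (degenerate) cells yield empty trains.
        """
        params = self._params()
        z = self.zscore(traces)
        profile = (1.0, 0.0)
        if z.fps != params.target_fps:
            z = downsample(z, params.target_fps)
            if params.amp_attenuation is None:
                profile = kernel_bin_profile(
                    1.0 / params.target_fps, params.t_half
                )
            else:
                profile = (params.amp_attenuation, 0.0)
        elif params.amp_attenuation is not None:
            profile = (params.amp_attenuation, 0.0)
        trains = []
        for i, cid in enumerate(z.cell_ids):
            if cid in self.excluded_cells_:
                trains.append(EventTrain(cid, np.array([]), np.array([])))
                continue
            times, amps = _detect_cell(z.values[i], z.fps, params, profile)
            trains.append(EventTrain(cid, times, amps))
        return trains

    def fit_transform(self, traces: TraceMatrix, y=None) -> list[EventTrain]:
        return self.fit(traces).transform(traces)


def _noise_sd(trace: np.ndarray, silent: np.ndarray, estimator: str) -> float:
    """Per-cell Gaussian noise level in trace units."""
    if estimator == "mad":
        med = np.median(trace)
        return 1.4826 * float(np.median(np.abs(trace - med)))
    if estimator == "silent":
        return float(np.std(silent))
    return float(np.std(trace))


def _envelope_duration(
    ztrace: np.ndarray, s: int, e: int, baseline: float, dt: float
) -> float:
    """Supra-baseline duration of run ``[s, e)`` in seconds.

    Crossing times are linearly interpolated between the frames flanking
    the run, so the duration is continuous rather than a frame count;
    runs touching the trace edge are clipped there.
    """
    t_start = s * dt
    if s > 0:
        v0, v1 = ztrace[s - 1], ztrace[s]
        t_start = (s - 1 + (baseline - v0) / (v1 - v0)) * dt + 0.5 * dt
    t_end = e * dt
    if e < ztrace.size:
        v0, v1 = ztrace[e - 1], ztrace[e]
        t_end = (e - 1 + (v0 - baseline) / (v0 - v1)) * dt + 0.5 * dt
    return t_end - t_start


def _detect_cell(
    ztrace: np.ndarray,
    fps: float,
    params: DetectionParams,
    profile: tuple[float, float] = (1.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Detect events on one z-scored trace; returns (times, amplitudes).

    ``profile`` = (g1, g2) maps the native amplitude scale onto this
    trace: g1 is the peak-bin attenuation from block averaging and g2 the
    following-bin value of the reference kernel. With g2 > 0 amplitudes
    are estimated by the two-tap least-squares template
    ``(g1*x_peak + g2*x_next) / (g1^2 + g2^2)``, which has better noise
    rejection than the raw peak; with (1, 0) the raw peak is used, as on
    traces already at the analysis rate. The baseline and the duration
    rule stay on the observed trace's own scale: envelope and peak
    attenuate together under averaging, so they are compared like with
    like.
    """
    if ztrace.size == 0:
        return np.array([]), np.array([])
    if np.isnan(ztrace).all():
        raise ValueError("all-NaN trace")
    above = ztrace > params.baseline
    if not above.any():
        return np.array([]), np.array([])
    g1, g2 = profile
    wnorm = g1 * g1 + g2 * g2

    def native_amp(j: int) -> float:
        if g2 <= 0:
            return float(ztrace[j]) / g1
        nxt = float(ztrace[j + 1]) if j + 1 < ztrace.size else 0.0
        return (g1 * float(ztrace[j]) + g2 * nxt) / wnorm

    # contiguous supra-baseline runs = candidate transient envelopes
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(ztrace.size)
    # a sub-baseline dip shorter than gap_tolerance does not end a transient
    max_gap = int(round(params.gap_tolerance * fps))
    if max_gap > 0 and len(starts) > 1:
        ms, me = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - me[-1] <= max_gap:
                me[-1] = e
            else:
                ms.append(s)
                me.append(e)
        starts, ends = ms, me
    dt = 1.0 / fps
    frame_times = (np.arange(ztrace.size) + 0.5) * dt
    dist = max(1, int(round(params.min_peak_distance * fps)))
    times: list[float] = []
    amps: list[float] = []
    for s, e in zip(starts, ends):
        seg = ztrace[s:e]
        j_peak = int(np.argmax(seg))
        if native_amp(s + j_peak) < params.amp_threshold:
            continue
        dur = _envelope_duration(ztrace, s, e, params.baseline, dt)
        if dur < min_duration(max(float(seg[j_peak]), params.a0), params):
            continue
        # pad with baseline so peaks at segment edges get full prominence
        padded = np.concatenate(([params.baseline], seg, [params.baseline]))
        idx, _ = find_peaks(
            padded, prominence=params.peak_prominence * g1, distance=dist
        )
        idx = idx - 1  # undo pad offset
        if idx.size == 0:
            idx = np.array([j_peak])
        for j in np.sort(idx):
            times.append(frame_times[s + j])
            amps.append(native_amp(s + j))
    return np.asarray(times), np.asarray(amps)


def zscore_traces(
    traces: TraceMatrix, params: DetectionParams | None = None
) -> TraceMatrix:
    """Z-score traces against silent timepoints (thin wrapper).

    Silent threshold is the pooled ``silent_quantile`` over all cells and
    frames; mean and s.d. are per cell over that cell's silent frames.
    """
    params = params or DetectionParams()
    det = EventDetector(**_kw(params)).fit(traces)
    return det.zscore(traces)


def detect_events(
    ztraces: TraceMatrix, params: DetectionParams | None = None
) -> list[EventTrain]:
    """Detect events on already z-scored traces (thin wrapper)."""
    params = params or DetectionParams()
    trains = []
    for i, cid in enumerate(ztraces.cell_ids):
        times, amps = _detect_cell(ztraces.values[i], ztraces.fps, params)
        trains.append(EventTrain(cid, times, amps))
    return trains


def event_rate(train: EventTrain, window: tuple[float, float]) -> float:
    """Event rate in events/min over the half-open window [start, end)."""
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    count = int(np.count_nonzero((train.times >= start) & (train.times < end)))
    return count * 60.0 / (end - start)


def _kw(params: DetectionParams) -> dict:
    return {
        "amp_threshold": params.amp_threshold,
        "baseline": params.baseline,
        "a0": params.a0,
        "t_half": params.t_half,
        "peak_prominence": params.peak_prominence,
        "min_peak_distance": params.min_peak_distance,
        "silent_quantile": params.silent_quantile,
        "target_fps": params.target_fps,
        "noise_estimator": params.noise_estimator,
        "truncation_correction": params.truncation_correction,
    }
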