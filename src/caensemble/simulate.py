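"""Ground-truthed synthetic calcium-imaging datasets.

The generator emulates the statistical structure that the downstream
analyses assume, without any biophysical neuron model:

* background activity as homogeneous Poisson event trains (events/min),
* correlated ensembles planted through shared latent events: each latent
  event of a module is copied into each member cell with a participation
  probability and a Gaussian timing jitter, producing co-active 1-s bins,
* shock-responsive cells whose event rate inside the shock window is a
  multiple of their background rate,
* opto-modulated cells whose rate is scaled inside LED epochs,
* session structure of a 3-day contextual fear paradigm (contexts A1 with
  an end-of-session foot shock, retrieval A2, novel context B, optional
  homecage LED-pulse session), and
* per-animal freezing bouts whose across-animal change co-varies with the
  planted ensemble strength, enabling recovery of a memory-strength
  regression.

Traces are rendered at an acquisition-like frame rate by convolving each
event with a linear-rise / exponential-decay kernel (GCaMP6f-like 200 ms
decay half-time) and adding white Gaussian noise; amplitudes are drawn in
noise-s.d. units so detection thresholds are exercised near 2 s.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EventTrain, SessionTimeline, TraceMatrix

__all__ = [
    "ModuleSpec",
    "SessionSpec",
    "SimConfig",
    "GroundTruth",
    "AnimalDataset",
    "default_config",
    "generate_event_trains",
    "render_traces",
    "generate_centroids",
    "generate_freezing",
    "simulate_animal",
    "simulate_cohort",
    "homecage_opto_session",
]


@dataclass
class SessionSpec:
    """Plan for one session: label, duration and stimulus windows."""

    label: str
    duration: float
    shock_window: tuple[float, float] | None = None
    tone_windows: list[tuple[float, float]] = field(default_factory=list)
    opto_epochs: list[tuple[float, float]] = field(default_factory=list)

    def timeline(self) -> SessionTimeline:
        return SessionTimeline(
            label=self.label,
            duration=self.duration,
            shock_window=self.shock_window,
            tone_windows=list(self.tone_windows),
            opto_epochs=list(self.opto_epochs),
        )


@dataclass
class ModuleSpec:
    """A planted correlated ensemble.

    Attributes
    ----------
    members : list of str
        Cell ids sharing the latent event source.
    rate : float
        Latent event rate in events/min.
    participation : float
        Probability that a member expresses each latent event.
    jitter : float
        Gaussian s.d. (s) of per-member timing jitter; 0.2 s keeps
        co-events in the same 1-s bin most of the time.
    sessions : list of str or None
        Session labels in which the module is active (None = all).
    scales_with_strength : bool
        Whether :func:`simulate_cohort` scales this module's
        participation with the animal's planted ensemble strength
        (True for the retrieval ensemble, False for stable background
        assemblies).
    """

    members: list[str]
    rate: float = 6.0
    participation: float = 0.8
    jitter: float = 0.2
    sessions: list[str] | None = None
    scales_with_strength: bool = False

    def active_in(self, label: str) -> bool:
        return self.sessions is None or label in self.sessions


@dataclass
class SimConfig:
    """Full simulation configuration for one animal/FOV."""

    n_cells: int = 40
    session_plan: list[SessionSpec] = field(default_factory=lambda: [
        SessionSpec("A1", 184.0, shock_window=(178.0, 184.0)),
        SessionSpec("A2", 180.0),
        SessionSpec("B", 180.0),
    ])
    background_rate: float = 2.0  # events/min per cell
    modules: list[ModuleSpec] = field(default_factory=list)
    shock_cell_ids: list[str] = field(default_factory=list)
    # a 0.7 mA footshock drives a reliable burst in responsive cells:
    # 15x over a 2/min background puts ~3 transients in a 6-s window
    shock_rate_multiplier: float = 15.0
    opto_cell_ids: list[str] = field(default_factory=list)
    opto_rate_multiplier: float = 1.0
    kernel_rise: float = 0.1  # s, linear rise to peak
    kernel_t_half: float = 0.2  # s, GCaMP6f-like decay half-time
    noise_sd: float = 1.0  # trace noise; amplitudes are in these units
    amplitude_mean: float = 4.0
    amplitude_sd: float = 1.0
    fps: float = 20.0  # acquisition-like render rate
    fov_size: float = 300.0  # centroid field side, um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.shock_rate_multiplier < 0 or self.opto_rate_multiplier < 0:
            raise ValueError("rate multipliers must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        labels = [s.label for s in self.session_plan]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate session labels")
        for spec in self.session_plan:
            spec.timeline()  # validates windows against duration
        ids = set(self.cell_ids)
        for mod in self.modules:
            if not 0 <= mod.participation <= 1:
                raise ValueError("participation must be in [0, 1]")
            if mod.rate < 0 or mod.jitter < 0:
                raise ValueError("module rate and jitter must be >= 0")
            if not set(mod.members) <= ids:
                raise ValueError("module members must be cell ids")
        if not set(self.shock_cell_ids) <= ids:
            raise ValueError("shock_cell_ids must be cell ids")
        if not set(self.opto_cell_ids) <= ids:
            raise ValueError("opto_cell_ids must be cell ids")

    @property
    def cell_ids(self) -> list[str]:
        return [f"c{i:03d}" for i in range(self.n_cells)]

    def session(self, label: str) -> SessionSpec:
        for spec in self.session_plan:
            if spec.label == label:
                return spec
        raise KeyError(f"unknown session label {label!r}")


@dataclass
class GroundTruth:
    """Planted truth for one simulated session."""

    session: str
    event_times: dict[str, np.ndarray]  # per cell, sorted
    module_of: dict[str, int]  # cell id -> module index, -1 = none
    shock_cells: list[str]
    opto_cells: list[str]


@dataclass
class AnimalDataset:
    """One simulated animal: traces, trains, truth and timelines."""

    config: SimConfig
    trains: dict[str, list[EventTrain]]  # per session
    traces: dict[str, TraceMatrix]
    truth: dict[str, GroundTruth]
    timelines: dict[str, SessionTimeline]
    centroids: dict[str, tuple[float, float]]
    freezing_change: float = 0.0  # planted, fraction of session time
    ensemble_strength: float = 0.0  # planted, graph-metric delta units


def default_config(seed: int = 0, retrieval_module: bool = True) -> SimConfig:
    """Study-condition defaults for one animal.

    40 cells, 2 events/min background, 8 shock cells. The planted
    retrieval ensemble (present unless ``retrieval_module=False``) has 12
    members (4 shock + 8 non-shock) sharing a 6 events/min latent source
    with participation 0.8 and 0.2 s jitter, active only in A2. In every
    session eight stable two-cell background assemblies (same latent
    parameters; their pairwise R sits near the 0.3 edge threshold, so
    pairs flicker between sessions, echoing the low persistence of
    correlated pairs in this preparation) provide the baseline
    co-activity structure real FOVs show; two of them involve shock
    cells, so partner-like cells exist even with no retrieval ensemble.
    """
    ids = [f"c{i:03d}" for i in range(40)]
    assemblies = [
        ModuleSpec(members=[a, b], jitter=0.2)
        for a, b in [
            (ids[2], ids[20]),
            (ids[3], ids[21]),
            (ids[22], ids[23]),
            (ids[24], ids[25]),
            (ids[26], ids[27]),
            (ids[28], ids[29]),
            (ids[30], ids[31]),
            (ids[32], ids[33]),
        ]
    ]
    modules = list(assemblies)
    if retrieval_module:
        modules.insert(
            0,
            ModuleSpec(
                members=ids[4:16],
                sessions=["A2"],
                scales_with_strength=True,
            ),
        )
    return SimConfig(
        n_cells=40,
        shock_cell_ids=ids[:8],
        modules=modules,
        seed=seed,
    )


def _poisson_times(
    rng: np.random.Generator, rate_per_min: float, start: float, end: float
) -> np.ndarray:
    """Homogeneous Poisson event times on [start, end) at rate/min."""
    lam = rate_per_min / 60.0 * (end - start)
    if lam <= 0:
        return np.array([])
    n = rng.poisson(lam)
    return start + rng.random(n) * (end - start)


def _background_times(
    rng: np.random.Generator,
    rate: float,
    duration: float,
    windows: list[tuple[float, float, float]],
) -> np.ndarray:
    """Background Poisson train with per-window rate multipliers.

    ``windows`` holds (start, end, multiplier); inside a window the rate is
    ``rate * multiplier`` (replacing, not adding to, the base rate).
    """
    cuts = [(0.0, duration, 1.0)]
    for ws, we, mult in windows:
        new = []
        for s, e, m in cuts:
            if we <= s or ws >= e:
                new.append((s, e, m))
                continue
            if s < ws:
                new.append((s, ws, m))
            new.append((max(s, ws), min(e, we), mult))
            if we < e:
                new.append((we, e, m))
        cuts = new
    parts = [_poisson_times(rng, rate * m, s, e) for s, e, m in cuts]
    return np.sort(np.concatenate(parts)) if parts else np.array([])


def generate_event_trains(
    config: SimConfig,
    session: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[EventTrain], GroundTruth]:
    """Simulate per-cell event trains for one session.

    Each cell's train is the union of its background Poisson events (with
    shock/opto rate scaling inside the respective windows) and the latent
    events of every module it belongs to, each expressed with probability
    ``participation`` and jittered by a Gaussian of s.d. ``jitter``;
    jittered events falling outside the session are dropped. Amplitudes
    are drawn per latent event (shared by all expressing members, so a
    participation-1, jitter-0 module yields identical trains) and per
    background event, from N(amplitude_mean, amplitude_sd) floored at 0.1.
    """
    spec = config.session(session)  # raises KeyError for unknown label
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    T = spec.duration
    times: dict[str, list[np.ndarray]] = {cid: [] for cid in config.cell_ids}
    amps: dict[str, list[np.ndarray]] = {cid: [] for cid in config.cell_ids}

    def draw_amps(n: int) -> np.ndarray:
        return np.maximum(
            0.1, rng.normal(config.amplitude_mean, config.amplitude_sd, n)
        )

    for cid in config.cell_ids:
        windows: list[tuple[float, float, float]] = []
        if spec.shock_window and cid in config.shock_cell_ids:
            s, e = spec.shock_window
            windows.append((s, e, config.shock_rate_multiplier))
        if cid in config.opto_cell_ids:
            for s, e in spec.opto_epochs:
                windows.append((s, e, config.opto_rate_multiplier))
        bg = _background_times(rng, config.background_rate, T, windows)
        times[cid].append(bg)
        amps[cid].append(draw_amps(bg.size))

    module_of = {cid: -1 for cid in config.cell_ids}
    for mi, mod in enumerate(config.modules):
        for cid in mod.members:
            module_of[cid] = mi
        if not mod.active_in(session):
            continue
        latent = _poisson_times(rng, mod.rate, 0.0, T)
        latent_amp = draw_amps(latent.size)
        for cid in mod.members:
            if mod.participation >= 1.0:
                keep = np.ones(latent.size, dtype=bool)
            else:
                keep = rng.random(latent.size) < mod.participation
            t = latent[keep]
            if mod.jitter > 0:
                t = t + rng.normal(0.0, mod.jitter, t.size)
            inside = (t >= 0) & (t < T)
            times[cid].append(t[inside])
            amps[cid].append(latent_amp[keep][inside])

    trains = []
    truth_times = {}
    for cid in config.cell_ids:
        t = np.concatenate(times[cid])
        a = np.concatenate(amps[cid])
        order = np.argsort(t, kind="stable")
        trains.append(EventTrain(cid, t[order], a[order]))
        truth_times[cid] = t[order].copy()
    truth = GroundTruth(
        session=session,
        event_times=truth_times,
        module_of=module_of,
        shock_cells=list(config.shock_cell_ids),
        opto_cells=list(config.opto_cell_ids),
    )
    return trains, truth


def render_traces(
    trains: list[EventTrain],
    config: SimConfig,
    duration: float,
    session: str = "",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TraceMatrix:
    """Render event trains into a noisy fluorescence trace matrix.

    Each event contributes a kernel rising linearly over ``kernel_rise``
    seconds to its amplitude at the event (peak) time, then decaying
    exponentially with half-time ``kernel_t_half``; overlapping kernels
    sum. White Gaussian noise of s.d. ``noise_sd`` is added.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n_frames = int(round(duration * config.fps))
    t_grid = (np.arange(n_frames) + 0.5) / config.fps
    values = np.zeros((len(trains), n_frames))
    # render until the kernel decays below 1% of a unit amplitude
    tail = config.kernel_t_half * np.log2(
        max(config.amplitude_mean + 4 * config.amplitude_sd, 2.0) / 0.01
    )
    for i, train in enumerate(trains):
        for te, a in zip(train.times, train.amplitudes):
            lo = np.searchsorted(t_grid, te - config.kernel_rise)
            hi = np.searchsorted(t_grid, te + tail)
            if hi <= lo:
                continue
            tt = t_grid[lo:hi]
            kernel = np.where(
                tt <= te,
                a * (tt - (te - config.kernel_rise)) / config.kernel_rise,
                a * np.power(2.0, -(tt - te) / config.kernel_t_half),
            )
            values[i, lo:hi] += np.maximum(kernel, 0.0)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, values.shape)
    return TraceMatrix(
        values, config.fps, [tr.cell_id for tr in trains], session
    )


def generate_centroids(
    config: SimConfig,
    rng: np.random.Generator,
    cluster_modules: bool = True,
) -> dict[str, tuple[float, float]]:
    """Random cell centroids; module members are spatially clustered.

    Non-module cells are uniform over a ``fov_size`` square; members of
    each module are drawn from a Gaussian patch (s.d. fov_size/8) around a
    random centre, emulating the spatial proximity of correlated pairs.
    """
    L = config.fov_size
    cents = {
        cid: (float(rng.random() * L), float(rng.random() * L))
        for cid in config.cell_ids
    }
    if cluster_modules:
        for mod in config.modules:
            cx, cy = rng.random(2) * L * 0.6 + L * 0.2
            for cid in mod.members:
                x, y = rng.normal([cx, cy], L / 8.0)
                cents[cid] = (float(np.clip(x, 0, L)), float(np.clip(y, 0, L)))
    return cents


def generate_freezing(
    duration: float,
    frac: float,
    rng: np.random.Generator,
    mean_bout: float = 8.0,
    min_bout: float = 1.0,
) -> list[tuple[float, float]]:
    """Alternating freezing bouts totalling ``frac`` of the session.

    Bout lengths are drawn around ``mean_bout`` s (never below
    ``min_bout``) and placed at random non-overlapping positions; the last
    bout is trimmed so total frozen time equals ``frac * duration``.
    """
    if not 0 <= frac <= 1:
        raise ValueError("frac must be in [0, 1]")
    target = frac * duration
    if target <= 0:
        return []
    if target >= duration:
        return [(0.0, duration)]
    bouts: list[float] = []
    remaining = target
    while remaining > 0:
        b = max(min_bout, rng.normal(mean_bout, mean_bout / 3))
        b = min(b, remaining) if remaining >= min_bout else remaining
        bouts.append(b)
        remaining -= b
    # spread gaps uniformly between bouts
    free = duration - target
    gaps = rng.dirichlet(np.ones(len(bouts) + 1)) * free
    intervals = []
    t = gaps[0]
    for b, g in zip(bouts, gaps[1:]):
        intervals.append((float(t), float(min(t + b, duration))))
        t += b + g
    return intervals


def simulate_animal(
    config: SimConfig,
    seed: int | None = None,
    freezing_frac: dict[str, float] | None = None,
    render: bool = True,
) -> AnimalDataset:
    """Simulate all sessions of one animal from a single seed."""
    root = np.random.default_rng(config.seed if seed is None else seed)
    trains: dict[str, list[EventTrain]] = {}
    traces: dict[str, TraceMatrix] = {}
    truths: dict[str, GroundTruth] = {}
    timelines: dict[str, SessionTimeline] = {}
    cents = generate_centroids(config, np.random.default_rng(root.integers(2**31)))
    for spec in config.session_plan:
        rng = np.random.default_rng(root.integers(2**31))
        tr, gt = generate_event_trains(config, spec.label, rng=rng)
        trains[spec.label] = tr
        truths[spec.label] = gt
        if render:
            traces[spec.label] = render_traces(
                tr, config, spec.duration, session=spec.label, rng=rng
            )
        tl = spec.timeline()
        if freezing_frac and spec.label in freezing_frac:
            tl.freezing_intervals = generate_freezing(
                spec.duration, freezing_frac[spec.label], rng
            )
        timelines[spec.label] = tl
    return AnimalDataset(
        config=config,
        trains=trains,
        traces=traces,
        truth=truths,
        timelines=timelines,
        centroids=cents,
    )


def simulate_cohort(
    n_animals: int = 12,
    config: SimConfig | None = None,
    effect_slope: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
    freeze_range: tuple[float, float] = (0.05, 0.5),
    base_freeze: float = 0.05,
    render: bool = False,
) -> tuple[list[AnimalDataset], float]:
    """Simulate a cohort linking ensemble strength to freezing change.

    Per-animal freezing changes (fraction of session time, A2 - A1) are
    spread evenly over ``freeze_range``; the planted ensemble strength is
    ``effect_slope * freezing_change + noise_sd * eps`` with standard
    normal ``eps``, so regressing strength (or a strength-proportional
    graph-metric delta) on freezing change recovers ``effect_slope``.
    Module participation is scaled with each animal's strength so the
    planted correlation structure co-varies with behaviour. Returns the
    datasets and the ground-truth slope.
    """
    if n_animals < 3:
        raise ValueError("need at least 3 animals")
    if config is None:
        config = default_config()
    root = np.random.default_rng(seed)
    f_lo, f_hi = freeze_range
    freeze_changes = np.linspace(f_lo, f_hi, n_animals)
    strengths = effect_slope * freeze_changes + noise_sd * root.standard_normal(
        n_animals
    )
    animals = []
    for i in range(n_animals):
        # participation tracks strength so correlation structure follows it;
        # the floor keeps weak-memory animals with a sparse but nonempty
        # retrieval ensemble rather than none at all
        ref = max(abs(effect_slope) * f_hi, 1e-9)
        p = float(np.clip(0.65 + 0.3 * strengths[i] / ref, 0.5, 0.95))
        mods = [
            replace(m, participation=p) if m.scales_with_strength else m
            for m in config.modules
        ]
        cfg = replace(config, modules=mods, seed=int(root.integers(2**31)))
        ds = simulate_animal(
            cfg,
            freezing_frac={
                "A1": base_freeze,
                "A2": float(np.clip(base_freeze + freeze_changes[i], 0, 1)),
                "B": base_freeze,
            },
            render=render,
        )
        ds.freezing_change = float(freeze_changes[i])
        ds.ensemble_strength = float(strengths[i])
        animals.append(ds)
    return animals, effect_slope


def homecage_opto_session(
    n_on: int = 6, on_len: float = 30.0, off_len: float = 60.0
) -> SessionSpec:
    """Homecage LED-pulse session: n_on 30-s ON epochs between 60-s OFFs."""
    epochs = []
    t = off_len
    for _ in range(n_on):
        epochs.append((t, t + on_len))
        t += on_len + off_len
    return SessionSpec("homecage", t, opto_epochs=epochs)
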