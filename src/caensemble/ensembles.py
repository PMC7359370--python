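"""Shock-partner partitioning, cross-session deltas and cohort statistics.

During retrieval (session A2), cells that share a significant correlation
edge with a shock-responsive cell form the "A2 shock-partner" class; the
remaining non-shock cells are "A2 non-shock-partners". Per-cell graph
metrics are differenced across sessions (A2 - A1, B - A1), summarised per
class and per FOV, screened with a size-matched resampling control for
the partner-selection bias, and related to behaviour (change in % time
freezing) with an ordinary least-squares regression across animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import statsmodels.api as sm

from .containers import SessionTimeline
from .graphs import CorrelationGraph, GraphMetrics

__all__ = [
    "PartitionLabels",
    "DeltaMetrics",
    "RegressionResult",
    "partition_partners",
    "session_deltas",
    "partner_bias_control",
    "percent_freezing",
    "state_masks",
    "regress_deltas_on_freezing",
    "CLASS_SHOCK",
    "CLASS_PARTNER",
    "CLASS_NON_PARTNER",
    "METRIC_NAMES",
]

CLASS_SHOCK = "shock"
CLASS_PARTNER = "A2_shock_partner"
CLASS_NON_PARTNER = "A2_non_shock_partner"
METRIC_NAMES = ("pair_ratio", "clustering", "component_member")


@dataclass
class PartitionLabels:
    """Disjoint, exhaustive cell classes for one FOV."""

    classes: dict[str, str]  # cell id -> class constant

    def cells_in(self, cls: str) -> list[str]:
        return [cid for cid, c in self.classes.items() if c == cls]


@dataclass
class DeltaMetrics:
    """Per-cell metric changes relative to the encoding session (A1)."""

    deltas: dict[str, dict[str, dict[str, float]]]
    # session -> metric -> cell id -> metric(session) - metric(A1)
    reference: str = "A1"
    missing: dict[str, list[str]] | None = None  # session -> untracked cells

    def class_mean(
        self, session: str, metric: str, cells: Iterable[str]
    ) -> float:
        vals = [
            self.deltas[session][metric][c]
            for c in cells
            if c in self.deltas[session][metric]
        ]
        return float(np.mean(vals)) if vals else np.nan


@dataclass
class RegressionResult:
    """OLS fit of per-FOV metric change on freezing change."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int
    conf_int: tuple[float, float]  # 95% CI for the slope


def partition_partners(
    graph_a2: CorrelationGraph, shock_flags: dict[str, int]
) -> PartitionLabels:
    """Partition cells into shock / A2 shock-partner / non-partner.

    Shock cells (flagged during A1 encoding) keep their class; a
    non-shock cell is a partner iff it has at least one significant A2
    edge to a shock cell; everything else is a non-partner. Shock cells
    are never partners, so the classes are disjoint and exhaustive.
    """
    shock = {cid for cid, f in shock_flags.items() if f}
    classes = {}
    for cid in graph_a2.cell_ids:
        if cid in shock:
            classes[cid] = CLASS_SHOCK
            continue
        partner = any(
            (cid in e) and (e[0] in shock or e[1] in shock)
            for e in graph_a2.edges
        )
        classes[cid] = CLASS_PARTNER if partner else CLASS_NON_PARTNER
    return PartitionLabels(classes)


def session_deltas(
    metrics: dict[str, GraphMetrics],
    reference: str = "A1",
    metric_names: tuple[str, ...] = METRIC_NAMES,
) -> DeltaMetrics:
    """Per-cell metric(session) - metric(reference) for tracked cells.

    Cells missing from a session are excluded from that session's deltas
    and recorded in ``missing``.
    """
    if reference not in metrics:
        raise ValueError(f"reference session {reference!r} not present")
    ref = metrics[reference]
    ref_cells = set(ref.cell_ids)
    deltas: dict[str, dict[str, dict[str, float]]] = {}
    missing: dict[str, list[str]] = {}
    for label, gm in metrics.items():
        if label == reference:
            continue
        shared = [c for c in gm.cell_ids if c in ref_cells]
        if not shared:
            raise ValueError(f"no cells tracked in both {reference} and {label}")
        missing[label] = sorted(
            (set(gm.cell_ids) | ref_cells) - set(shared)
        )
        deltas[label] = {}
        for name in metric_names:
            cur = getattr(gm, name)
            refv = getattr(ref, name)
            deltas[label][name] = {
                c: float(cur[c]) - float(refv[c]) for c in shared
            }
    return DeltaMetrics(deltas=deltas, reference=reference, missing=missing)


def partner_bias_control(
    labels: PartitionLabels,
    deltas: DeltaMetrics,
    graph_a2: CorrelationGraph,
    session: str = "A2",
    metric_names: tuple[str, ...] = METRIC_NAMES,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> dict[str, float]:
    """Empirical p for the partner effect vs size-matched random samples.

    Partners by definition have at least one A2 edge, so their deltas are
    compared against repeated samples (of the same size) drawn from
    non-partners that also have at least one A2 edge. The empirical p is
    the add-one estimator ``(1 + #{null >= observed}) / (1 + n_iter)``.
    Returns a p per metric; raises if there are no partners or no
    eligible non-partners.
    """
    partners = labels.cells_in(CLASS_PARTNER)
    if not partners:
        raise ValueError("no A2 shock-partners to test")
    eligible = [
        c
        for c in labels.cells_in(CLASS_NON_PARTNER)
        if graph_a2.degree(c) >= 1
    ]
    if not eligible:
        raise ValueError("no eligible non-partners (degree >= 1 in A2)")
    rng = np.random.default_rng(seed)
    m = min(len(partners), len(eligible))
    out = {}
    for name in metric_names:
        table = deltas.deltas[session][name]
        obs = np.mean([table[c] for c in partners if c in table])
        pool = np.array([table[c] for c in eligible if c in table])
        if pool.size == 0:
            out[name] = np.nan
            continue
        idx = rng.integers(0, pool.size, size=(n_iter, min(m, pool.size)))
        null_means = pool[idx].mean(axis=1)
        out[name] = float((1 + np.sum(null_means >= obs)) / (1 + n_iter))
    return out


def percent_freezing(
    timeline: SessionTimeline, window: tuple[float, float] | None = None
) -> float:
    """Percent of (window) time spent freezing; intervals merged first."""
    start, end = window if window else (0.0, timeline.duration)
    if end <= start:
        raise ValueError("window must have positive length")
    frozen = 0.0
    for s, e in timeline.merged_freezing():
        frozen += max(0.0, min(e, end) - max(s, start))
    return 100.0 * frozen / (end - start)


def state_masks(
    timeline: SessionTimeline, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (freeze, non-freeze) bin masks for state-restricted graphs.

    A bin counts as frozen iff more than half of it overlaps a freezing
    interval; the masks are complements and can be fed to
    :func:`caensemble.graphs.binarize_events`.
    """
    n_bins = int(np.floor(timeline.duration / bin_width))
    freeze = np.zeros(n_bins, dtype=bool)
    intervals = timeline.merged_freezing()
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        overlap = sum(
            max(0.0, min(e, hi) - max(s, lo)) for s, e in intervals
        )
        freeze[b] = overlap > 0.5 * bin_width
    return freeze, ~freeze


def regress_deltas_on_freezing(
    fov_deltas: np.ndarray | list[float],
    freezing_change: np.ndarray | list[float],
) -> RegressionResult:
    """OLS of per-FOV mean metric change on per-FOV freezing change.

    Reports slope, intercept, R^2, the F statistic on (1, n-2) degrees
    of freedom and its two-sided p, as used for relating ensemble
    reorganisation to memory-retrieval strength across animals.
    """
    y = np.asarray(fov_deltas, dtype=float)
    x = np.asarray(freezing_change, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if y.size < 3:
        raise ValueError("need at least 3 FOVs")
    if np.std(x) == 0:
        raise ValueError("freezing change has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)[1]
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(y.size),
        conf_int=(float(ci[0]), float(ci[1])),
    )
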