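"""Correlation graphs over binarized event rasters and their node metrics.

Each cell's event train is reduced to a binary 1-s-bin time series marking
bins that contain at least one transient peak; the Pearson correlation of
every cell pair over these series defines a similarity matrix. Edges are
either pairs with R above a fixed threshold (0.3) or pairs significant
against a per-pair shuffle null in which each cell's occupied bins are
redrawn uniformly (preserving event counts). Node metrics follow the
sparse-graph conventions used for one-photon population imaging: the
correlated pair ratio (degree over FOV size), the clustering coefficient,
and membership in a connected component of at least three cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .containers import BinnedRaster, EventTrain

__all__ = [
    "CorrelationGraph",
    "GraphMetrics",
    "CorrelationGraphBuilder",
    "binarize_events",
    "correlation_matrix",
    "shuffle_r_thresholds",
    "build_graph",
    "node_metrics",
    "pair_persistence",
    "pair_distances",
    "MIN_CELLS_PER_FOV",
]

#: FOV inclusion rule: correlated-activity analyses need at least this many
#: simultaneously imaged cells, else partner sampling is too sparse.
MIN_CELLS_PER_FOV = 20


@dataclass
class CorrelationGraph:
    """Symmetric R matrix plus the significant-edge set for one session."""

    cell_ids: list[str]
    r: np.ndarray
    edges: set[tuple[str, str]]
    mode: str = "fixed"  # fixed | shuffle | shuffle-bonferroni
    threshold: float | np.ndarray = 0.3
    session: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.cell_ids)
        if self.r.shape != (n, n):
            raise ValueError("R must be n_cells x n_cells")
        self.edges = {_key(a, b) for a, b in self.edges}

    def degree(self, cell_id: str) -> int:
        return sum(1 for e in self.edges if cell_id in e)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.cell_ids)
        g.add_edges_from(self.edges)
        return g


@dataclass
class GraphMetrics:
    """Per-cell graph metrics plus the FOV-level component probability."""

    cell_ids: list[str]
    pair_ratio: dict[str, float]
    clustering: dict[str, float]
    component_member: dict[str, int]
    component_probability: float = 0.0
    n_cells_fov: int = 0
    session: str = ""


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def binarize_events(
    trains: list[EventTrain],
    duration: float,
    bin_width: float = 1.0,
    mask: np.ndarray | None = None,
    session: str = "",
) -> BinnedRaster:
    """Binarize event trains into half-open 1-s bins.

    Bin ``b`` is 1 iff the cell has at least one peak in
    ``[b*w, (b+1)*w)``. If a boolean ``mask`` over bins is given (e.g. a
    non-freezing mask), masked-out columns are removed before any
    correlation is computed.
    """
    n_bins = int(np.floor(duration / bin_width))
    values = np.zeros((len(trains), n_bins), dtype=np.int8)
    for i, train in enumerate(trains):
        if train.times.size and train.times.max() >= duration:
            raise ValueError(
                f"cell {train.cell_id}: event at {train.times.max()} s "
                f"outside session of {duration} s"
            )
        if train.times.size and train.times.min() < 0:
            raise ValueError(f"cell {train.cell_id}: negative event time")
        idx = np.floor(train.times / bin_width).astype(int)
        idx = idx[idx < n_bins]  # events in a trailing partial bin dropped
        values[i, idx] = 1
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != n_bins:
            raise ValueError("mask length must equal number of bins")
        values = values[:, mask]
    return BinnedRaster(
        values,
        [t.cell_id for t in trains],
        bin_width=bin_width,
        session=session,
        bin_mask=mask,
    )


def correlation_matrix(raster: BinnedRaster) -> np.ndarray:
    """Pairwise Pearson R of the binary series; constant series give NaN.

    Silent (or saturated) cells have zero variance, so their correlations
    are undefined; they are reported as NaN and treated downstream as
    pairs for which no edge is possible.
    """
    x = raster.values.astype(float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 bins to correlate")
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.nan)
    return r


def _shuffled_rasters(
    raster: BinnedRaster, n_shuffles: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_shuffles, cells, bins) rasters with occupied bins redrawn.

    Each cell's number of occupied bins is preserved; the occupied set is
    redrawn uniformly among all bins, which is the raster-level analogue
    of shuffling transient timing.
    """
    n_cells, n_bins = raster.values.shape
    counts = raster.values.sum(axis=1)
    out = np.zeros((n_shuffles, n_cells, n_bins), dtype=np.int8)
    # rank a uniform matrix per cell/shuffle: the k smallest become events
    u = rng.random((n_shuffles, n_cells, n_bins))
    order = np.argsort(u, axis=2)
    for i, k in enumerate(counts):
        if k == 0:
            continue
        sel = order[:, i, :k]
        rows = np.repeat(np.arange(n_shuffles), k)
        out[rows, i, sel.ravel()] = 1
    return out


def _pearson_pairs(x: np.ndarray) -> np.ndarray:
    """Row-pair Pearson R for a (stack of) binary matrices.

    ``x`` has shape (..., cells, bins); returns (..., cells, cells) with
    NaN where a series is constant.
    """
    xf = x.astype(float)
    mean = xf.mean(axis=-1, keepdims=True)
    xc = xf - mean
    cov = xc @ xc.swapaxes(-1, -2)
    var = np.einsum("...ij,...ij->...i", xc, xc)
    denom = np.sqrt(var[..., :, None] * var[..., None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    return r


def _nanquantile(null_r: np.ndarray, q: float) -> np.ndarray:
    """nanquantile over the shuffle axis, quiet about all-NaN pairs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanquantile(null_r, q, axis=0)


def shuffle_r_thresholds(
    raster: BinnedRaster,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    bonferroni: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-pair R significance thresholds from a timing-shuffle null.

    For each pair, each cell's occupied bins are redrawn ``n_shuffles``
    times and R recomputed; the threshold is the empirical
    ``1 - alpha`` quantile of that null (``alpha / n_pairs`` under
    Bonferroni). Pairs with a constant series are untestable (NaN).
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = raster.n_cells
    n_pairs = n * (n - 1) // 2
    a = alpha / n_pairs if bonferroni else alpha
    null_r = _pearson_pairs(_shuffled_rasters(raster, n_shuffles, rng))
    thresholds = _nanquantile(null_r, 1.0 - a)
    sd = raster.values.std(axis=1)
    thresholds[sd == 0, :] = np.nan
    thresholds[:, sd == 0] = np.nan
    np.fill_diagonal(thresholds, np.nan)
    return thresholds


class CorrelationGraphBuilder(BaseEstimator):
    """Build a correlation graph from a binned raster (sklearn-style).

    Parameters
    ----------
    mode : str
        ``"fixed"`` draws an edge when R strictly exceeds ``r_threshold``
        (0.3). ``"shuffle"`` / ``"shuffle-bonferroni"`` test each pair
        against a timing-shuffle null at level ``alpha`` (divided by the
        number of pairs under Bonferroni).
    randomize_ties : bool
        The shuffle null of a binary raster is discrete, so comparing R
        to an empirical quantile is conservative. When True (default) the
        shuffle modes use the randomized permutation p-value
        ``(#{null > obs} + U*(1 + #{null = obs})) / (n + 1)`` (edge iff
        p <= alpha), which has exact size for discrete statistics; when
        False, the strict-quantile rule is used.
    random_state : int or None
        Seed for the shuffle null and tie randomization.

    Attributes (after ``fit``)
    --------------------------
    r_ : (n, n) Pearson matrix; ``edges_`` : set of significant pairs;
    ``thresholds_`` : per-pair thresholds (shuffle modes) or the fixed
    threshold; ``graph_`` : the resulting :class:`CorrelationGraph`.
    """

    def __init__(
        self,
        mode: str = "fixed",
        r_threshold: float = 0.3,
        n_shuffles: int = 1000,
        alpha: float = 0.05,
        randomize_ties: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.mode = mode
        self.r_threshold = r_threshold
        self.n_shuffles = n_shuffles
        self.alpha = alpha
        self.randomize_ties = randomize_ties
        self.random_state = random_state

    def fit(self, raster: BinnedRaster, y=None) -> "CorrelationGraphBuilder":
        if self.mode not in ("fixed", "shuffle", "shuffle-bonferroni"):
            raise ValueError(f"unknown mode {self.mode!r}")
        r = correlation_matrix(raster)
        ids = raster.cell_ids
        n = len(ids)
        edges: set[tuple[str, str]] = set()
        if self.mode == "fixed":
            thresholds: float | np.ndarray = self.r_threshold
            for i in range(n):
                for j in range(i + 1, n):
                    if np.isfinite(r[i, j]) and r[i, j] > self.r_threshold:
                        edges.add(_key(ids[i], ids[j]))
        else:
            rng = np.random.default_rng(self.random_state)
            bonf = self.mode == "shuffle-bonferroni"
            n_pairs = n * (n - 1) // 2
            a = self.alpha / n_pairs if bonf else self.alpha
            null_r = _pearson_pairs(
                _shuffled_rasters(raster, self.n_shuffles, rng)
            )
            thresholds = _nanquantile(null_r, 1.0 - a)
            np.fill_diagonal(thresholds, np.nan)
            for i in range(n):
                for j in range(i + 1, n):
                    obs = r[i, j]
                    if not np.isfinite(obs):
                        continue
                    null = null_r[:, i, j]
                    null = null[np.isfinite(null)]
                    if null.size == 0:
                        continue
                    if self.randomize_ties:
                        greater = int(np.sum(null > obs))
                        equal = int(np.sum(null == obs))
                        p = (greater + rng.random() * (1 + equal)) / (
                            null.size + 1
                        )
                        if p <= a:
                            edges.add(_key(ids[i], ids[j]))
                    elif obs > thresholds[i, j]:
                        edges.add(_key(ids[i], ids[j]))
        self.r_ = r
        self.thresholds_ = thresholds
        self.edges_ = edges
        self.graph_ = CorrelationGraph(
            cell_ids=list(ids),
            r=r,
            edges=edges,
            mode=self.mode,
            threshold=thresholds,
            session=raster.session,
        )
        self.n_features_in_ = raster.n_bins
        return self

    def fit_graph(self, raster: BinnedRaster) -> CorrelationGraph:
        return self.fit(raster).graph_


def build_graph(
    r: np.ndarray,
    cell_ids: list[str],
    mode: str = "fixed",
    threshold: float | np.ndarray = 0.3,
    session: str = "",
) -> CorrelationGraph:
    """Threshold an R matrix into a graph (edge iff R strictly > threshold).

    ``threshold`` may be a scalar (fixed mode) or a per-pair matrix from
    :func:`shuffle_r_thresholds`; NaN entries (undefined R or untestable
    pairs) never produce edges.
    """
    r = np.asarray(r, dtype=float)
    thr = np.asarray(threshold, dtype=float)
    if thr.ndim == 0:
        thr = np.full_like(r, float(thr))
    edges = set()
    n = len(cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(r[i, j]) and np.isfinite(thr[i, j]):
                if r[i, j] > thr[i, j]:
                    edges.add(_key(cell_ids[i], cell_ids[j]))
    return CorrelationGraph(
        cell_ids=list(cell_ids),
        r=r,
        edges=edges,
        mode=mode,
        threshold=threshold,
        session=session,
    )


def node_metrics(
    graph: CorrelationGraph, n_cells_fov: int | None = None
) -> GraphMetrics:
    """Correlated pair ratio, clustering coefficient, component membership.

    * pair ratio: degree / total cells in the FOV,
    * clustering: edges among neighbours / possible edges among
      neighbours (0 when degree < 2),
    * component member: 1 iff the cell's connected component holds at
      least two OTHER cells (size >= 3); the FOV-level component
      probability is the mean of this flag over all FOV cells.
    """
    if n_cells_fov is None:
        n_cells_fov = len(graph.cell_ids)
    if n_cells_fov < len(graph.cell_ids):
        raise ValueError("n_cells_fov smaller than the graph's node count")
    g = graph.to_networkx()
    if n_cells_fov == 0:
        return GraphMetrics([], {}, {}, {}, 0.0, 0, graph.session)
    clustering = nx.clustering(g)
    comp_member = {}
    for comp in nx.connected_components(g):
        flag = 1 if len(comp) >= 3 else 0
        for cid in comp:
            comp_member[cid] = flag
    pair_ratio = {cid: g.degree(cid) / n_cells_fov for cid in graph.cell_ids}
    members = {cid: comp_member.get(cid, 0) for cid in graph.cell_ids}
    # cells absent from the graph object still count in the denominator
    comp_prob = sum(members.values()) / n_cells_fov
    return GraphMetrics(
        cell_ids=list(graph.cell_ids),
        pair_ratio=pair_ratio,
        clustering={cid: float(clustering[cid]) for cid in graph.cell_ids},
        component_member=members,
        component_probability=comp_prob,
        n_cells_fov=n_cells_fov,
        session=graph.session,
    )


def pair_persistence(
    reference: CorrelationGraph, target: CorrelationGraph
) -> float | None:
    """Fraction of reference-session edges present in the target session.

    Returns None (undefined) when the reference session has no edges.
    """
    if not reference.edges:
        return None
    shared = reference.edges & target.edges
    return len(shared) / len(reference.edges)


def pair_distances(
    graph: CorrelationGraph,
    centroids: dict[str, tuple[float, float]],
) -> dict:
    """Centroid distances of correlated vs non-correlated pairs.

    Cells without a centroid are excluded (with a warning via the
    returned ``excluded`` list). Returns both distance distributions and
    their means.
    """
    ids = [cid for cid in graph.cell_ids if cid in centroids]
    excluded = [cid for cid in graph.cell_ids if cid not in centroids]
    corr, non = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            xa, ya = centroids[a]
            xb, yb = centroids[b]
            d = float(np.hypot(xa - xb, ya - yb))
            (corr if _key(a, b) in graph.edges else non).append(d)
    return {
        "correlated": np.asarray(corr),
        "non_correlated": np.asarray(non),
        "mean_correlated": float(np.mean(corr)) if corr else np.nan,
        "mean_non_correlated": float(np.mean(non)) if non else np.nan,
        "excluded": excluded,
    }
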