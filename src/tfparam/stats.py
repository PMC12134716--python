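"""TFCE permutation statistics over channel × frequency × frame maps.

Threshold-free cluster enhancement integrates ``extent(p, h)**E * h**H * dh``
over thresholds ``h`` at every map point ``p``, where the extent is the size
of the connected component containing ``p`` at threshold ``h``. Connectivity
combines a channel adjacency graph (from sensor positions) with ±1-bin
adjacency in the frequency and frame dimensions. Familywise error is
controlled with a max-statistic permutation null over the whole map: paired
condition tests permute via subject-level sign flips (exhaustively for small
n), across-subject correlation tests permute the behavioral vector.

The production enhancer is a numba union-find threshold sweep;
:func:`tfce_enhance_reference` is an independent scipy implementation kept
for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse, stats as sp_stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AdjacencyGraph",
    "TFCEResult",
    "build_adjacency",
    "tfce_enhance",
    "tfce_enhance_reference",
    "paired_tfce_test",
    "correlation_tfce_test",
    "fisher_z_compare",
    "fisher_z_compare_dependent",
    "paired_ttest_power",
]


@dataclass
class AdjacencyGraph:
    """Symmetric channel neighborhoods from sensor geometry."""

    neighbors: tuple[np.ndarray, ...]
    positions: np.ndarray
    distance_threshold: float

    @property
    def n_channels(self) -> int:
        return len(self.neighbors)


@dataclass
class TFCEResult:
    """Observed map, enhanced map, permutation null, and corrected p-values."""

    observed_stat: np.ndarray
    enhanced: np.ndarray
    null_max: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int | None = None
    kind: str = ""


def build_adjacency(channel_positions, distance_threshold: float = 0.6) -> AdjacencyGraph:
    """Channels are neighbors iff their Euclidean distance is below threshold."""
    pos = np.asarray(channel_positions, dtype=float)
    if pos.ndim != 2 or len(pos) < 2:
        raise ValueError("at least 2 channels with 3-D positions required")
    if len(np.unique(pos, axis=0)) != len(pos):
        raise ValueError("channel positions must be distinct")
    d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    neighbors = tuple(np.nonzero(row < distance_threshold)[0] for row in d)
    for ch, nb in enumerate(neighbors):
        if nb.size == 0:
            warnings.warn(f"channel {ch} has no neighbors below distance "
                          f"{distance_threshold}", stacklevel=2)
    return AdjacencyGraph(neighbors=neighbors, positions=pos,
                          distance_threshold=distance_threshold)


# ---------------------------------------------------------------------------
# TFCE graph over (channel, frequency, frame)
# ---------------------------------------------------------------------------

def _map_graph_csr(adjacency: AdjacencyGraph, n_freq: int, n_time: int):
    """CSR neighbor lists for the flattened (ch, freq, frame) lattice."""
    n_ch = adjacency.n_channels
    idx = np.arange(n_ch * n_freq * n_time).reshape(n_ch, n_freq, n_time)
    rows, cols = [], []

    def link(a, b):
        rows.append(a.ravel())
        cols.append(b.ravel())
        rows.append(b.ravel())
        cols.append(a.ravel())

    link(idx[:, :-1, :], idx[:, 1:, :])   # ±1 frequency bin
    link(idx[:, :, :-1], idx[:, :, 1:])   # ±1 frame
    for ch, nb in enumerate(adjacency.neighbors):
        for other in nb:
            if other > ch:
                link(idx[ch], idx[other])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    g = sparse.csr_matrix((np.ones(rows.size, dtype=np.uint8), (rows, cols)),
                          shape=(idx.size, idx.size))
    g.sum_duplicates()
    return g


class _TFCEngine:
    """Precomputed lattice graph for repeated enhancement of same-shape maps."""

    def __init__(self, adjacency: AdjacencyGraph, n_freq: int, n_time: int):
        self.shape = (adjacency.n_channels, n_freq, n_time)
        self.graph = _map_graph_csr(adjacency, n_freq, n_time)
        self.indptr = self.graph.indptr
        self.indices = self.graph.indices.astype(np.int64)

    def enhance_signed(self, stat_map: np.ndarray, e: float, h: float, dh: float,
                       n_steps: int | None = None) -> np.ndarray:
        """Enhance positive and negative parts separately; keep the sign."""
        flat = np.ascontiguousarray(stat_map, dtype=np.float64).ravel()
        out = np.zeros_like(flat)
        for sign in (1.0, -1.0):
            part = np.clip(sign * flat, 0.0, None)
            if part.max() <= 0 or dh <= 0:
                continue
            k = n_steps if n_steps is not None else int(np.floor(part.max() / dh + 1e-12))
            if k < 1:
                continue
            enh = np.zeros_like(part)
            order = np.argsort(-part, kind="stable").astype(np.int64)
            _tfce_sweep(part, order, self.indptr, self.indices, e, h, dh, k, enh)
            out += sign * enh
        return out.reshape(stat_map.shape)


@njit(cache=True)
def _tfce_sweep(values, order, indptr, indices, e, h_exp, dh, n_steps, enhanced):
    n = values.size
    parent = np.full(n, -1, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    pos = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        # activate nodes reaching this threshold and union with active neighbors
        while pos < n and values[order[pos]] >= h:
            v = order[pos]
            parent[v] = v
            for jj in range(indptr[v], indptr[v + 1]):
                u = indices[jj]
                if parent[u] != -1:
                    ru = u
                    while parent[ru] != ru:
                        ru = parent[ru]
                    rv = v
                    while parent[rv] != rv:
                        rv = parent[rv]
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
            pos += 1
        incr = h ** h_exp * dh
        for i in range(pos):
            p = order[i]
            r = p
            while parent[r] != r:
                r = parent[r]
            # path compression
            q = p
            while parent[q] != r:
                nxt = parent[q]
                parent[q] = r
                q = nxt
            enhanced[p] += size[r] ** e * incr


def tfce_enhance(stat_map, adjacency: AdjacencyGraph, E: float = 0.5, H: float = 2.0,
                 dh: float | None = None) -> np.ndarray:
    """TFCE-enhance a signed (channel × frequency × frame) map.

    Positive and negative excursions are enhanced separately and the output
    carries the original sign. ``dh`` defaults to ``max(|map|)/100``.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("stat map contains non-finite values")
    if E <= 0 or H <= 0 or (dh is not None and dh <= 0):
        raise ValueError("E, H, and dh must be positive")
    vmax = np.abs(stat_map).max()
    if vmax == 0:
        return np.zeros_like(stat_map)
    if dh is None:
        dh = vmax / 100.0
    engine = _TFCEngine(adjacency, stat_map.shape[1], stat_map.shape[2])
    return engine.enhance_signed(stat_map, E, H, dh)


def tfce_enhance_reference(stat_map, adjacency: AdjacencyGraph, E: float = 0.5,
                           H: float = 2.0, dh: float | None = None) -> np.ndarray:
    """Independent scipy connected-components TFCE (slow; for verification)."""
    stat_map = np.asarray(stat_map, dtype=float)
    vmax = np.abs(stat_map).max()
    if vmax == 0:
        return np.zeros_like(stat_map)
    if dh is None:
        dh = vmax / 100.0
    graph = _map_graph_csr(adjacency, stat_map.shape[1], stat_map.shape[2])
    out = np.zeros(stat_map.size)
    flat = stat_map.ravel()
    for sign in (1.0, -1.0):
        part = np.clip(sign * flat, 0.0, None)
        k_max = int(np.floor(part.max() / dh + 1e-12))
        for k in range(1, k_max + 1):
            h = k * dh
            mask = part >= h
            if not mask.any():
                break
            sub = graph[mask][:, mask]
            _, labels = connected_components(sub, directed=False)
            sizes = np.bincount(labels)
            out[mask] += sign * sizes[labels] ** E * h ** H * dh
    return out.reshape(stat_map.shape)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _paired_t(diff_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for sign-flip patterns; rows of ``signs`` are ±1 per subject.

    Because flipping signs leaves sum(d²) unchanged, only the mean varies.
    """
    n = diff_flat.shape[0]
    ssq = (diff_flat ** 2).sum(axis=0)
    mean = signs @ diff_flat / n
    var = (ssq - n * mean ** 2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _max_abs_enhanced(engine: _TFCEngine, stat: np.ndarray, E, H, dh) -> float:
    return float(np.abs(engine.enhance_signed(stat.reshape(engine.shape), E, H, dh)).max())


def paired_tfce_test(surfaces_a, surfaces_b, adjacency: AdjacencyGraph,
                     E: float = 0.5, H: float = 2.0, dh: float | None = None,
                     n_permutations: int = 1000, seed: int | None = None,
                     exhaustive_max_n: int = 12) -> TFCEResult:
    """Paired (within-subject) TFCE test on per-subject maps.

    The observed statistic is a one-sample t on per-subject difference maps;
    the null randomly flips each subject's difference sign. For
    ``n <= exhaustive_max_n`` all ``2**n`` sign patterns are enumerated
    instead of sampled. Corrected p at each point is the fraction of null
    global maxima of ``|enhanced|`` at or above the observed ``|enhanced|``.
    """
    a = np.asarray(surfaces_a, dtype=float)
    b = np.asarray(surfaces_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition A and B must hold the same subjects and shape")
    n = a.shape[0]
    if n < 4:
        raise ValueError("paired test requires n >= 4 subjects")
    diffs = (a - b).reshape(n, -1)
    map_shape = a.shape[1:]
    engine = _TFCEngine(adjacency, map_shape[1], map_shape[2])

    t_obs = _paired_t(diffs, np.ones((1, n)))[0]
    vmax = np.abs(t_obs).max()
    if dh is None:
        dh = vmax / 100.0 if vmax > 0 else 1.0
    enhanced = engine.enhance_signed(t_obs.reshape(map_shape), E, H, dh)

    exhaustive = n <= exhaustive_max_n
    if exhaustive:
        bits = np.arange(2 ** n, dtype=np.uint64)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n, dtype=np.uint64)[None]) & 1).astype(float)
        n_perm = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        n_perm = n_permutations
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        t_i = _paired_t(diffs, signs[i:i + 1])[0]
        null_max[i] = _max_abs_enhanced(engine, t_i, E, H, dh)

    abs_enh = np.abs(enhanced).ravel()
    ge = (null_max[None, :] >= abs_enh[:, None]).sum(axis=1)
    if exhaustive:
        p = ge / n_perm  # identity pattern is among the 2**n, so p >= 1/2**n
    else:
        p = (1.0 + ge) / (n_perm + 1.0)
    return TFCEResult(observed_stat=t_obs.reshape(map_shape), enhanced=enhanced,
                      null_max=null_max, p_values=p.reshape(map_shape),
                      n_permutations=n_perm, seed=seed, kind="paired")


def _pearson_maps(surf_flat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between ``y`` (n,) and each column of ``surf_flat`` (n, P)."""
    n = surf_flat.shape[0]
    xz = surf_flat - surf_flat.mean(axis=0)
    yz = y - y.mean()
    denom = np.sqrt((xz ** 2).sum(axis=0) * (yz ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yz @ xz) / denom
    return np.nan_to_num(r, nan=0.0)


def correlation_tfce_test(surfaces, behavior, adjacency: AdjacencyGraph,
                          E: float = 0.5, H: float = 2.0, dh: float | None = None,
                          n_permutations: int = 1000, seed: int | None = None) -> TFCEResult:
    """Across-subject correlation TFCE test.

    The observed statistic is the Pearson r between the behavioral score and
    the per-subject surface value at each map point; the null permutes the
    behavioral vector across subjects.
    """
    surf = np.asarray(surfaces, dtype=float)
    y = np.asarray(behavior, dtype=float)
    n = surf.shape[0]
    if y.shape != (n,):
        raise ValueError("one behavioral score per subject required")
    if n < 5:
        raise ValueError("correlation test requires n >= 5 subjects")
    if np.ptp(y) == 0:
        raise ValueError("behavior has zero variance")
    flat = surf.reshape(n, -1)
    map_shape = surf.shape[1:]
    engine = _TFCEngine(adjacency, map_shape[1], map_shape[2])

    r_obs = _pearson_maps(flat, y)
    vmax = np.abs(r_obs).max()
    if dh is None:
        dh = vmax / 100.0 if vmax > 0 else 1.0
    enhanced = engine.enhance_signed(r_obs.reshape(map_shape), E, H, dh)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        r_i = _pearson_maps(flat, y[rng.permutation(n)])
        null_max[i] = _max_abs_enhanced(engine, r_i, E, H, dh)
    abs_enh = np.abs(enhanced).ravel()
    ge = (null_max[None, :] >= abs_enh[:, None]).sum(axis=1)
    p = (1.0 + ge) / (n_permutations + 1.0)
    return TFCEResult(observed_stat=r_obs.reshape(map_shape), enhanced=enhanced,
                      null_max=null_max, p_values=p.reshape(map_shape),
                      n_permutations=n_permutations, seed=seed, kind="correlation")


def surface_pair_correlation_test(surfaces_x, surfaces_y, adjacency: AdjacencyGraph,
                                  E: float = 0.5, H: float = 2.0, dh: float | None = None,
                                  n_permutations: int = 1000, seed: int | None = None) -> TFCEResult:
    """Across-subject correlation between two surface stacks, per map point.

    The null permutes the subject pairing of the second stack, breaking any
    point-wise association while preserving both stacks' spatial structure.
    """
    x = np.asarray(surfaces_x, dtype=float)
    y = np.asarray(surfaces_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("surface stacks must share subjects and shape")
    n = x.shape[0]
    if n < 5:
        raise ValueError("correlation test requires n >= 5 subjects")
    xf = x.reshape(n, -1)
    yf = y.reshape(n, -1)
    map_shape = x.shape[1:]
    engine = _TFCEngine(adjacency, map_shape[1], map_shape[2])

    def r_of(perm):
        a = xf - xf.mean(axis=0)
        b = yf[perm] - yf.mean(axis=0)
        denom = np.sqrt((a ** 2).sum(axis=0) * (b ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nan_to_num((a * b).sum(axis=0) / denom, nan=0.0)

    r_obs = r_of(np.arange(n))
    vmax = np.abs(r_obs).max()
    if dh is None:
        dh = vmax / 100.0 if vmax > 0 else 1.0
    enhanced = engine.enhance_signed(r_obs.reshape(map_shape), E, H, dh)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        null_max[i] = _max_abs_enhanced(engine, r_of(rng.permutation(n)), E, H, dh)
    abs_enh = np.abs(enhanced).ravel()
    ge = (null_max[None, :] >= abs_enh[:, None]).sum(axis=1)
    p = (1.0 + ge) / (n_permutations + 1.0)
    return TFCEResult(observed_stat=r_obs.reshape(map_shape), enhanced=enhanced,
                      null_max=null_max, p_values=p.reshape(map_shape),
                      n_permutations=n_permutations, seed=seed, kind="surface_correlation")


# ---------------------------------------------------------------------------
# closed-form statistics
# ---------------------------------------------------------------------------

def fisher_z_compare(r1: float, r2: float, n1: int, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's z transform.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be below 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sp_stats.norm.sf(abs(z))
    return float(z), float(p)


def fisher_z_compare_dependent(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's test for two correlations sharing one variable.

    ``r1 = r(x, y1)`` and ``r2 = r(x, y2)`` measured on the same ``n``
    subjects, with ``r12 = r(y1, y2)``. Caveat: the package's default
    comparisons use the independent-samples formula (matching the study
    procedure) even though the compared correlations share total power; this
    dependent variant is the statistically stricter alternative.
    """
    for r in (r1, r2, r12):
        if abs(r) >= 1:
            raise ValueError("|r| must be below 1")
    if n <= 3:
        raise ValueError("n must exceed 3")
    rbar2 = (r1 ** 2 + r2 ** 2) / 2.0
    psi = r12 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r12 ** 2)
    sbar = psi / (1.0 - rbar2) ** 2
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n - 3) / (2.0 * (1.0 - sbar)))
    p = 2.0 * sp_stats.norm.sf(abs(z))
    return float(z), float(p)


def paired_ttest_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided paired t-test via the noncentral t distribution.

    ``df = n - 1``, noncentrality ``d * sqrt(n)``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = sp_stats.t.ppf(1.0 - alpha / 2.0, df)
    power = sp_stats.nct.sf(tcrit, df, nc) + sp_stats.nct.cdf(-tcrit, df, nc)
    if not np.isfinite(power):  # large-df numerical failure: normal limit
        power = sp_stats.norm.sf(tcrit - nc) + sp_stats.norm.cdf(-tcrit - nc)
    return float(power)
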