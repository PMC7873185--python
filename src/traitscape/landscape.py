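"""Landscape structure metrics for 1 km x 1 km landscape windows.

Two levels of description are used throughout:

* the *landscape* level — all land-use classes together — summarised by
  compositional heterogeneity (Shannon diversity of land-use proportions)
  and configurational heterogeneity (sign-reversed log mean patch area);
* the *habitat* level — one focal habitat at a time — summarised by habitat
  amount (grassland percentage, total hedgerow length) and habitat isolation
  (mean nearest edge-to-edge distance between grassland patches, number of
  disconnected hedgerow networks).

Land-use maps are rasters of class codes; hedgerows are additionally carried
as a polyline layer because their amount and isolation are line-native
quantities (length, network count), not patch areas.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely import STRtree
from shapely.geometry import LineString, box
from shapely.ops import unary_union
from skimage import measure

#: The seven land-use classes, in code order (raster values 0..6).
CLASS_NAMES: tuple[str, ...] = (
    "grassland",
    "hedgerow",
    "crop",
    "orchard",
    "artificial",
    "woodland",
    "water",
)
GRASSLAND, HEDGEROW, CROP, ORCHARD, ARTIFICIAL, WOODLAND, WATER = range(7)

#: Column names of the six landscape predictors, in reporting order.
PREDICTOR_NAMES: tuple[str, ...] = (
    "compositional_heterogeneity",
    "configurational_heterogeneity",
    "grassland_amount",
    "grassland_isolation",
    "hedgerow_amount",
    "hedgerow_isolation",
)


@dataclasses.dataclass(frozen=True)
class LandUseMap:
    """Gridded land-use class map of one window at one year.

    Parameters
    ----------
    grid
        2-D integer array of class codes in ``0..6`` (see :data:`CLASS_NAMES`).
        Rasterised hedgerow cells carry the ``hedgerow`` code and, by default,
        count as areal class like any other.
    cell_size
        Cell edge length in metres; cell area is ``cell_size ** 2``.
    window_id, year
        Identifiers of the sampling unit and the map year.
    """

    grid: np.ndarray
    cell_size: float
    window_id: str = "w"
    year: str = "current"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if not np.issubdtype(g.dtype, np.integer):
            raise ValueError("grid must hold integer class codes")
        if g.min() < 0 or g.max() >= len(CLASS_NAMES):
            raise ValueError("class codes must lie in 0..6")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "grid", g)

    @property
    def window_area(self) -> float:
        """Total window area in m^2 (constant across years by construction)."""
        return float(self.grid.size) * self.cell_size**2

    def class_proportions(self) -> pd.Series:
        """Areal proportion of each of the seven classes (sums to 1)."""
        counts = np.bincount(self.grid.ravel(), minlength=len(CLASS_NAMES))
        return pd.Series(counts / self.grid.size, index=list(CLASS_NAMES))


@dataclasses.dataclass(frozen=True)
class HedgerowNetwork:
    """Hedgerow line segments of one window at one year.

    ``segments`` has shape ``(n, 2, 2)``: n segments given by their two
    planar endpoints in metres. An empty network is a valid value (two of the
    study's twenty windows have no hedgerows at all).
    """

    segments: np.ndarray
    window_id: str = "w"
    year: str = "current"

    def __post_init__(self) -> None:
        s = np.asarray(self.segments, dtype=float).reshape(-1, 2, 2)
        lengths = np.hypot(*(s[:, 1] - s[:, 0]).T)
        if s.shape[0] and not (lengths > 0).all():
            raise ValueError("all segments must have positive length")
        object.__setattr__(self, "segments", s)

    def __len__(self) -> int:
        return int(self.segments.shape[0])

    def segment_lengths(self) -> np.ndarray:
        d = self.segments[:, 1] - self.segments[:, 0]
        return np.hypot(d[:, 0], d[:, 1])

    def to_linestrings(self) -> list[LineString]:
        return [LineString(seg) for seg in self.segments]


# ---------------------------------------------------------------------------
# landscape-level metrics


def shannon_diversity(lu_map: LandUseMap) -> float:
    """Shannon diversity H (nats) of land-use areal proportions.

    ``H = -sum_c p_c ln p_c`` over classes with ``p_c > 0``. 0 for a window
    made of a single land-use type; high values mean many and/or evenly
    distributed land uses (compositional heterogeneity).
    """
    p = lu_map.class_proportions().to_numpy()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return 0.0 if h == 0 else h  # normalise -0.0


def patch_count(lu_map: LandUseMap, connectivity: int = 2) -> int:
    """Number of patches (connected components within each class, all classes).

    ``connectivity`` follows scikit-image: 2 = 8-connectivity (the Fragstats
    default), 1 = 4-connectivity.
    """
    total = 0
    for code in np.unique(lu_map.grid):
        labels = measure.label(lu_map.grid == code, connectivity=connectivity)
        total += int(labels.max())
    return total


def mean_patch_area(lu_map: LandUseMap, connectivity: int = 2) -> tuple[float, float]:
    """Mean patch area (m^2) and configurational heterogeneity ``-ln(MPA)``.

    MPA is total window area divided by the total patch count, so
    ``MPA * patch count == window area`` exactly. The log transform reduces
    skewness and the sign reversal makes larger values mean *more*
    configurational heterogeneity (smaller patches, more complex pattern).
    """
    n = patch_count(lu_map, connectivity=connectivity)
    mpa = lu_map.window_area / n
    return mpa, -math.log(mpa)


# ---------------------------------------------------------------------------
# habitat-level metrics: grassland


def grassland_amount(lu_map: LandUseMap) -> float:
    """Percentage [0, 100] of the window occupied by grassland cells."""
    return float(100.0 * np.mean(lu_map.grid == GRASSLAND))


def _patch_boundary_geometries(
    mask: np.ndarray, cell_size: float, connectivity: int
) -> list:
    """One shapely geometry per patch, built from its boundary cells only.

    Edge-to-edge distances between patches depend only on boundary cells,
    so interior cells are dropped before the polygon union (raster windows
    are 100 x 100 cells; full unions would be needlessly slow).
    """
    labels = measure.label(mask, connectivity=connectivity)
    n = labels.max()
    geoms = []
    interior = np.zeros_like(mask, dtype=bool)
    # a cell is interior if its 4 axial neighbours share its label
    interior[1:-1, 1:-1] = (
        (labels[1:-1, 1:-1] == labels[:-2, 1:-1])
        & (labels[1:-1, 1:-1] == labels[2:, 1:-1])
        & (labels[1:-1, 1:-1] == labels[1:-1, :-2])
        & (labels[1:-1, 1:-1] == labels[1:-1, 2:])
    )
    for patch in range(1, n + 1):
        rows, cols = np.nonzero((labels == patch) & ~interior)
        cells = [
            box(c * cell_size, r * cell_size, (c + 1) * cell_size, (r + 1) * cell_size)
            for r, c in zip(rows, cols)
        ]
        geoms.append(unary_union(cells))
    return geoms


def grassland_isolation(
    lu_map: LandUseMap, connectivity: int = 2
) -> float:
    """Mean nearest edge-to-edge Euclidean distance (m) between grassland patches.

    For each grassland patch, the minimum edge-to-edge distance to any other
    grassland patch is found; the mean over patches is returned. Windows with
    fewer than two grassland patches return NaN (the missing-value marker:
    such windows are excluded from models that use this predictor, mirroring
    absent habitat).
    """
    geoms = _patch_boundary_geometries(
        lu_map.grid == GRASSLAND, lu_map.cell_size, connectivity
    )
    n = len(geoms)
    if n < 2:
        return float("nan")
    nearest = np.full(n, np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d = geoms[i].distance(geoms[j])
            if d < nearest[i]:
                nearest[i] = d
            if d < nearest[j]:
                nearest[j] = d
    return float(nearest.mean())


# ---------------------------------------------------------------------------
# habitat-level metrics: hedgerows


def hedgerow_amount(network: HedgerowNetwork) -> float:
    """Total hedgerow length (m); 0 for an empty network."""
    return float(network.segment_lengths().sum())


def hedgerow_isolation(network: HedgerowNetwork, snap_tol: float = 0.0) -> int:
    """Number of disconnected hedgerow networks.

    Segments are nodes of a graph; two segments are joined when they
    intersect or come within ``snap_tol`` metres of one another (digitised
    junctions rarely meet exactly). The count of connected components is
    returned; an empty network counts 0.
    """
    if snap_tol < 0:
        raise ValueError("snap_tol must be >= 0")
    n = len(network)
    if n == 0:
        return 0
    lines = network.to_linestrings()
    tree = STRtree(lines)
    if snap_tol > 0:
        i, j = tree.query(lines, predicate="dwithin", distance=snap_tol)
    else:
        i, j = tree.query(lines, predicate="intersects")
    adj = coo_matrix((np.ones_like(i), (i, j)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


# ---------------------------------------------------------------------------
# assembling the predictor table


def compute_landscape_variables(
    maps: Mapping[tuple[str, str], LandUseMap],
    networks: Mapping[tuple[str, str], HedgerowNetwork],
    snap_tol: float = 0.5,
    connectivity: int = 2,
) -> pd.DataFrame:
    """Tidy table of the six predictors per (window, year).

    ``maps`` and ``networks`` are keyed by ``(window_id, year)`` and must
    share keys. Isolation metrics of an absent habitat are NaN; amounts are 0.
    """
    if set(maps) != set(networks):
        raise ValueError("maps and networks must cover the same (window, year) keys")
    rows = []
    for (window, year), lu_map in sorted(maps.items()):
        net = networks[(window, year)]
        _, config_het = mean_patch_area(lu_map, connectivity=connectivity)
        amount = hedgerow_amount(net)
        rows.append(
            {
                "window": window,
                "year": year,
                "compositional_heterogeneity": shannon_diversity(lu_map),
                "configurational_heterogeneity": config_het,
                "grassland_amount": grassland_amount(lu_map),
                "grassland_isolation": grassland_isolation(
                    lu_map, connectivity=connectivity
                ),
                "hedgerow_amount": amount,
                "hedgerow_isolation": (
                    hedgerow_isolation(net, snap_tol=snap_tol)
                    if amount > 0
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def predictor_correlations(
    variables: pd.DataFrame,
    year: str | None = None,
    threshold: float = 0.87,
    columns: Sequence[str] = PREDICTOR_NAMES,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Spearman correlation matrix of the predictors, plus over-threshold flags.

    Used to screen collinearity across windows before regression (the study
    design keeps all pairwise |rho| below 0.87). Pairs involving a constant
    predictor are undefined and reported as NaN, never flagged.

    Returns
    -------
    (corr, flags)
        ``corr`` — predictors x predictors Spearman rho; ``flags`` — list of
        ``(var_a, var_b, rho)`` with ``|rho| > threshold``.
    """
    df = variables
    if year is not None:
        df = df[df["year"] == year]
    sub = df.loc[:, list(columns)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 windows with complete predictors")
    corr = sub.corr(method="spearman")
    # a constant column has zero rank variance: force NaN rather than pandas' 1.0 diag
    const = [c for c in columns if sub[c].nunique() <= 1]
    for c in const:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    flags = []
    cols = list(columns)
    for a_idx in range(len(cols)):
        for b_idx in range(a_idx + 1, len(cols)):
            rho = corr.iloc[a_idx, b_idx]
            if np.isfinite(rho) and abs(rho) > threshold:
                flags.append((cols[a_idx], cols[b_idx], float(rho)))
    return corr, flags
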