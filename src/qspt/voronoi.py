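"""Voronoï tessellation nanocluster analysis of localization maps.

A super-resolved localization map is tessellated into Voronoï cells (one per
localization); the cell area is inversely proportional to the local emitter
density, so thresholding areas at the per-series 50th percentile and keeping
connected components of at least 10 retained cells isolates nanoclusters in
a nearly parameter-free way.  Cluster radius is √(Area/π) and density is
reported per 100 nm².

Cells are clipped exactly to the field of view by tessellating the point set
together with its mirror images across the four FOV edges: every real cell's
region is then a finite polygon whose union tiles the FOV exactly, so cell
areas sum to the FOV area to machine precision.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi
from sklearn.base import BaseEstimator, ClusterMixin

from .types import Cluster, LocalizationMap, Tessellation

__all__ = [
    "build_tessellation",
    "find_clusters",
    "classify_detections",
    "voronoi_area_histogram",
    "VoronoiClusterFinder",
    "SIZE_CUT_NM",
]

#: radius (nm) separating "small" from "large" clusters; ties go to "large"
SIZE_CUT_NM = 50.0


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def build_tessellation(
    loc_map: LocalizationMap, dedupe: bool = True
) -> Tessellation:
    """Voronoï tessellation of a localization map, clipped to the FOV.

    Exact duplicate coordinates are collapsed to a single cell with their
    multiplicity retained (``dedupe=False`` raises if duplicates exist).
    Cells whose unclipped Voronoï region is unbounded are flagged
    ``boundary``; after clipping all cells are finite and together partition
    the FOV.

    Raises ``ValueError`` on fewer than 4 usable points or a collinear map.
    """
    pts = np.asarray(loc_map.points, dtype=np.float64)
    uniq, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if not dedupe and uniq.shape[0] != pts.shape[0]:
        raise ValueError("duplicate localizations present and dedupe=False")
    n = uniq.shape[0]
    if n < 4:
        raise ValueError("tessellation requires >= 4 distinct localizations")
    if np.linalg.matrix_rank(uniq - uniq.mean(axis=0)) < 2:
        raise ValueError("localizations are collinear; tessellation undefined")

    xmin, ymin, xmax, ymax = loc_map.fov_bounds
    mirrors = [
        np.column_stack([2 * xmin - uniq[:, 0], uniq[:, 1]]),
        np.column_stack([2 * xmax - uniq[:, 0], uniq[:, 1]]),
        np.column_stack([uniq[:, 0], 2 * ymin - uniq[:, 1]]),
        np.column_stack([uniq[:, 0], 2 * ymax - uniq[:, 1]]),
    ]
    vor_plain = Voronoi(uniq)
    vor = Voronoi(np.vstack([uniq] + mirrors))

    areas = np.empty(n)
    polygons: List[np.ndarray] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        polygons.append(verts)
        areas[i] = _polygon_area(verts)

    boundary = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor_plain.regions[vor_plain.point_region[i]]
        boundary[i] = (-1 in region) or len(region) == 0

    neighbors: List[set] = [set() for _ in range(n)]
    for (p, q) in vor_plain.ridge_points:
        if p < n and q < n:
            neighbors[p].add(int(q))
            neighbors[q].add(int(p))

    return Tessellation(
        points=uniq, areas=areas, neighbors=neighbors, boundary=boundary,
        multiplicity=counts.astype(np.int64), fov_bounds=loc_map.fov_bounds,
        polygons=polygons,
    )


def find_clusters(
    tess: Tessellation, area_percentile: float = 50.0, min_cells: int = 10
) -> List[Cluster]:
    """Density-threshold cluster search on one tessellated series.

    Cells with area at or below the series' ``area_percentile`` threshold
    (linear interpolation) are retained; connected components of the
    Voronoï-adjacency graph restricted to retained cells with at least
    ``min_cells`` members become clusters.  Localization counts honour
    duplicate-point multiplicity.  Zero clusters is a valid result.
    """
    n = tess.n_cells
    if n == 0:
        return []
    threshold = np.percentile(tess.areas, area_percentile)
    keep = tess.areas <= threshold
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        return []
    pos = -np.ones(n, dtype=int)
    pos[idx] = np.arange(idx.size)
    rows, cols = [], []
    for i in idx:
        for j in tess.neighbors[i]:
            if keep[j]:
                rows.append(pos[i])
                cols.append(pos[j])
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(idx.size, idx.size))
    n_comp, labels = connected_components(graph, directed=False)

    clusters: List[Cluster] = []
    for c in range(n_comp):
        members = idx[labels == c]
        if members.size < min_cells:
            continue
        area = float(tess.areas[members].sum())
        n_locs = int(tess.multiplicity[members].sum())
        clusters.append(
            Cluster(
                member_cells=members,
                n_locs=n_locs,
                area=area,
                radius=float(np.sqrt(area / np.pi)),
                density=100.0 * n_locs / area,
            )
        )
    clusters.sort(key=lambda cl: int(cl.member_cells.min()))
    return clusters


def classify_detections(
    clusters: Sequence[Cluster], tess: Tessellation, size_cut: float = SIZE_CUT_NM
) -> Dict[str, float]:
    """Fraction of localizations in small clusters, large clusters, or neither.

    A localization inherits its cluster's radius class: radius < ``size_cut``
    nm is *small*, radius ≥ ``size_cut`` is *large* (the tie goes to large so
    the two classes partition); cluster-free localizations are *unclustered*.
    Fractions are over localizations (with duplicate multiplicity) and sum
    to 1.
    """
    total = int(tess.multiplicity.sum())
    n_small = n_large = 0
    for cl in clusters:
        if cl.radius < size_cut:
            n_small += cl.n_locs
        else:
            n_large += cl.n_locs
    return {
        "frac_unclustered": (total - n_small - n_large) / total,
        "frac_small": n_small / total,
        "frac_large": n_large / total,
    }


def voronoi_area_histogram(
    tess_list: Sequence[Tessellation],
    other: Sequence[Tessellation] = (),
    bins: int = 50,
) -> Dict:
    """Pooled Voronoï cell-area distribution, median, and condition comparison.

    Pools cell areas over the given tessellations (one condition), returning
    the histogram, the pooled median, and — when a second condition ``other``
    is provided — the two-sample Kolmogorov–Smirnov comparison between the
    pooled area distributions.
    """
    if not tess_list:
        raise ValueError("voronoi_area_histogram needs >= 1 tessellation")
    pooled = np.concatenate([t.areas for t in tess_list])
    hist, edges = np.histogram(pooled, bins=bins)
    out = {
        "areas": pooled,
        "median_area": float(np.median(pooled)),
        "hist": hist,
        "bin_edges": edges,
    }
    if other:
        pooled_b = np.concatenate([t.areas for t in other])
        ks = stats.ks_2samp(pooled, pooled_b)
        out["median_area_other"] = float(np.median(pooled_b))
        out["ks_stat"] = float(ks.statistic)
        out["ks_p"] = float(ks.pvalue)
    return out


class VoronoiClusterFinder(ClusterMixin, BaseEstimator):
    """Voronoï-tessellation cluster detector with a scikit-learn surface.

    Parameters
    ----------
    area_percentile : float, default 50.0
        Per-series cell-area percentile above which cells are discarded.
    min_cells : int, default 10
        Minimum connected retained cells forming a cluster.
    size_cut : float, default 50.0
        Radius (nm) separating small from large clusters.
    fov_bounds : tuple or None
        (xmin, ymin, xmax, ymax) nm; inferred from the data extent when None.

    Attributes
    ----------
    labels_ : ndarray of int, one per input localization
        Cluster index, −1 for unclustered.
    clusters_ : list of Cluster
    tessellation_ : Tessellation
    fractions_ : dict
        Unclustered/small/large localization fractions.
    """

    def __init__(self, area_percentile: float = 50.0, min_cells: int = 10,
                 size_cut: float = SIZE_CUT_NM, fov_bounds: Tuple = None):
        self.area_percentile = area_percentile
        self.min_cells = min_cells
        self.size_cut = size_cut
        self.fov_bounds = fov_bounds

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if isinstance(X, LocalizationMap):  # pragma: no cover - convenience
            loc_map = X
        else:
            bounds = self.fov_bounds
            if bounds is None:
                bounds = (X[:, 0].min(), X[:, 1].min(), X[:, 0].max(), X[:, 1].max())
            loc_map = LocalizationMap(points=X, fov_bounds=bounds)
        tess = build_tessellation(loc_map)
        clusters = find_clusters(tess, self.area_percentile, self.min_cells)

        cell_label = -np.ones(tess.n_cells, dtype=int)
        for k, cl in enumerate(clusters):
            cell_label[cl.member_cells] = k
        # map back from deduplicated cells to the original point order
        _, inverse = np.unique(X, axis=0, return_inverse=True)
        self.labels_ = cell_label[inverse]
        self.clusters_ = clusters
        self.tessellation_ = tess
        self.fractions_ = classify_detections(clusters, tess, self.size_cut)
        return self
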