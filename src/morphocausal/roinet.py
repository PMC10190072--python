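"""Bidirectional ROI-to-ROI causal network and degree analysis.

ROIs are spheres (default radius 8 mm) centered on peak coordinates in
world space.  For every ordered ROI pair the signed-path GC coefficient is
estimated on the ROIs' pseudo-time series; the directed adjacency keeps
edges with |GC| above the same fixed cut used voxelwise (0.16), and each
node is scored by binary out-degree (edges emitted), in-degree (edges
received) and their sum.  High out-degree marks a causal source — the
putative driver of the morphological cascade; "transition" nodes have
balanced in- and out-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cascn import CascnConfig, PseudoTimeSeries, signed_path_gc


@dataclass
class RoiSpec:
    """A spherical region of interest in world (mm) coordinates."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        self.center_mm = tuple(float(c) for c in self.center_mm)


def make_sphere_roi(
    center_mm: Sequence[float],
    radius_mm: float,
    mask: np.ndarray,
    affine: np.ndarray,
) -> np.ndarray:
    """Boolean region of the mask voxels whose *center* lies within
    ``radius_mm`` (inclusive) of ``center_mm`` in world space."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    mask = np.asarray(mask, dtype=bool)
    affine = np.asarray(affine, dtype=float)
    ijk = np.indices(mask.shape).reshape(3, -1).T
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(xyz - np.asarray(center_mm, dtype=float), axis=1)
    region = (dist <= radius_mm).reshape(mask.shape) & mask
    if not region.any():
        raise ValueError(
            f"sphere at {tuple(center_mm)} mm (r={radius_mm} mm) does not "
            "intersect the mask"
        )
    return region


@dataclass
class CausalNetwork:
    """Signed directed GC matrix over named ROIs, its binarization at
    |GC| > gc_abs_min, and the node degrees."""

    rois: list[RoiSpec]
    weights: np.ndarray          # (k, k) signed GC, weights[i, j] = i -> j
    gc_abs_min: float
    binary: np.ndarray = field(init=False)
    in_degree: np.ndarray = field(init=False)
    out_degree: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.rois)
        if self.weights.shape != (k, k):
            raise ValueError("weights must be square over the ROI list")
        np.fill_diagonal(self.weights, 0.0)
        self.binary = (np.abs(self.weights) > self.gc_abs_min).astype(int)
        np.fill_diagonal(self.binary, 0)
        self.out_degree = self.binary.sum(axis=1)
        self.in_degree = self.binary.sum(axis=0)

    @property
    def degree(self) -> np.ndarray:
        return self.in_degree + self.out_degree

    @property
    def n_edges(self) -> int:
        return int(self.binary.sum())

    def degree_table(self) -> pd.DataFrame:
        """Per-node degrees plus a transition flag (|in - out| <= 1, an
        interpretive rule for 'balanced' nodes)."""
        return pd.DataFrame({
            "roi": [r.name for r in self.rois],
            "out_degree": self.out_degree,
            "in_degree": self.in_degree,
            "degree": self.degree,
            "transition": np.abs(self.in_degree - self.out_degree) <= 1,
        })

    def edge_list(self) -> pd.DataFrame:
        names = [r.name for r in self.rois]
        rows = [
            {"source": names[i], "target": names[j],
             "gc": float(self.weights[i, j])}
            for i, j in zip(*np.nonzero(self.binary))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "gc"])

    def to_networkx(self):
        """Directed graph with signed GC edge weights (thresholded edges)."""
        import networkx as nx

        g = nx.DiGraph()
        for r in self.rois:
            g.add_node(r.name, center_mm=r.center_mm, radius_mm=r.radius_mm)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["source"], row["target"], gc=row["gc"])
        return g


def roi_gc_matrix(
    pts: PseudoTimeSeries,
    rois: Sequence[RoiSpec],
    config: CascnConfig | None = None,
) -> CausalNetwork:
    """Pairwise signed-path GC among sphere ROIs on the shared
    pseudo-time ordering.

    Overlapping ROIs are allowed (their series simply share voxels); an
    ROI whose sphere misses the mask is rejected by ``make_sphere_roi``.
    """
    config = config or CascnConfig()
    rois = list(rois)
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    series = []
    for roi in rois:
        region = make_sphere_roi(roi.center_mm, roi.radius_mm, pts.mask, pts.affine)
        series.append(pts.roi_series(region))
    k = len(rois)
    weights = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            weights[i, j] = signed_path_gc(series[i], series[j], config.model_order)
    return CausalNetwork(rois=rois, weights=weights, gc_abs_min=config.gc_abs_min)


def read_roi_table(path) -> list[RoiSpec]:
    """Load ROIs from a TSV with columns name, x_mm, y_mm, z_mm[, radius_mm]."""
    frame = pd.read_csv(path, sep="\t")
    out = []
    for _, row in frame.iterrows():
        out.append(RoiSpec(
            name=str(row["name"]),
            center_mm=(row["x_mm"], row["y_mm"], row["z_mm"]),
            radius_mm=float(row.get("radius_mm", 8.0)) if "radius_mm" in frame.columns else 8.0,
        ))
    return out
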