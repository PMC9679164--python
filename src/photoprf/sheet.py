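"""Cortical sheet graphs: a flat-lattice stand-in for a reconstructed surface.

Vertices carry 2-D positions in millimetres, a symmetric adjacency, and a
region/hemisphere label.  Geodesic (graph) distances along the sheet are used
by the surface smoothing steps of the pRF pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


@dataclass(frozen=True)
class CorticalSheetGraph:
    """2-D vertex lattice with symmetric weighted adjacency.

    ``positions_mm`` is (N, 2); ``edges`` is (E, 2) int with each undirected
    edge listed once; ``region`` and ``hemisphere`` are per-vertex labels.
    """

    positions_mm: np.ndarray
    edges: np.ndarray
    region: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float)
        edges = np.asarray(self.edges, dtype=int)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions_mm must be (N, 2)")
        if edges.size and (edges.min() < 0 or edges.max() >= pos.shape[0]):
            raise ValueError("edge indices out of range")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "edges", edges.reshape(-1, 2))
        object.__setattr__(self, "region", np.asarray(self.region))
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere))

    @property
    def n_vertices(self) -> int:
        return self.positions_mm.shape[0]

    def adjacency(self) -> csr_matrix:
        """Symmetric sparse adjacency weighted by Euclidean edge length (mm)."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = np.linalg.norm(self.positions_mm[i] - self.positions_mm[j], axis=1)
        n = self.n_vertices
        return csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )

    def geodesic_distances(self, limit: float = np.inf) -> np.ndarray:
        """All-pairs graph distances in mm (np.inf beyond ``limit``)."""
        return dijkstra(self.adjacency(), directed=False, limit=limit)

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        pd.DataFrame(
            {
                "vertex": np.arange(self.n_vertices),
                "x_mm": self.positions_mm[:, 0],
                "y_mm": self.positions_mm[:, 1],
                "region": self.region,
                "hemisphere": self.hemisphere,
            }
        ).to_csv(stem.parent / f"{stem.name}_vertices.csv", index=False)
        pd.DataFrame(self.edges, columns=["v0", "v1"]).to_csv(
            stem.parent / f"{stem.name}_edges.csv", index=False
        )

    @classmethod
    def load(cls, stem: str | Path) -> "CorticalSheetGraph":
        stem = Path(stem)
        vert = pd.read_csv(stem.parent / f"{stem.name}_vertices.csv")
        edges = pd.read_csv(stem.parent / f"{stem.name}_edges.csv")
        return cls(
            vert[["x_mm", "y_mm"]].to_numpy(),
            edges.to_numpy(),
            vert["region"].to_numpy(),
            vert["hemisphere"].to_numpy(),
        )


def lattice_graph(
    n_rows: int,
    n_cols: int,
    spacing_mm: float = 1.0,
    region: str = "V1",
    hemisphere: str = "L",
    offset_mm: tuple = (0.0, 0.0),
) -> CorticalSheetGraph:
    """Rectangular 4-connected lattice patch."""
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    pos = np.column_stack([cc.ravel() * spacing_mm, rr.ravel() * spacing_mm])
    pos += np.asarray(offset_mm)
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    edges = np.concatenate(
        [
            np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()]),
            np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()]),
        ]
    )
    n = n_rows * n_cols
    return CorticalSheetGraph(
        pos, edges, np.full(n, region), np.full(n, hemisphere)
    )


def merge_graphs(a: CorticalSheetGraph, b: CorticalSheetGraph) -> CorticalSheetGraph:
    """Disjoint union (e.g. two hemispheres); no edges are added between parts."""
    offset = a.n_vertices
    return CorticalSheetGraph(
        np.vstack([a.positions_mm, b.positions_mm]),
        np.vstack([a.edges, b.edges + offset]),
        np.concatenate([a.region, b.region]),
        np.concatenate([a.hemisphere, b.hemisphere]),
    )
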