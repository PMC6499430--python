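"""Connectome container, file I/O, distances and weight normalization.

A connectome here is a weighted, directed graph of brain regions embedded in
3-D space: region labels, centroid coordinates in micrometres, and a
non-negative weight matrix.  The orientation convention throughout the
package is **rows = targets**: ``weights[i, j]`` is the connection strength
from source region ``j`` to target region ``i``, so that the input strength
of node *i* is ``weights[i, :].sum()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "Connectome",
    "compute_distance_matrix",
    "normalize_weights",
    "load_connectome",
    "save_connectome",
    "assemble_bilateral",
]


def compute_distance_matrix(positions: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between region centroids.

    Parameters
    ----------
    positions : (n, 3) array of centroid coordinates, micrometres.

    Returns
    -------
    (n, n) symmetric matrix with zero diagonal, micrometres.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError(f"positions must be (n, 3), got {positions.shape}")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions contain non-finite coordinates")
    if positions.shape[0] < 2:
        return np.zeros((positions.shape[0],) * 2)
    return squareform(pdist(positions))


def normalize_weights(weights: np.ndarray, zero_diagonal: bool = True) -> np.ndarray:
    """Rescale a non-negative weight matrix to the unit interval.

    The diagonal (self-connectivity) is zeroed first when requested, then the
    matrix is divided by its global maximum so all weights lie in [0, 1].
    """
    w = np.array(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weights must be square, got {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax == 0:
        raise ValueError("cannot normalize an all-zero weight matrix")
    return w / wmax


@dataclass
class Connectome:
    """A spatially embedded, weighted, directed region-level network.

    Attributes
    ----------
    labels : list of region identifiers, length n.
    positions : (n, 3) centroid coordinates, micrometres.
    weights : (n, n) non-negative matrix; ``weights[i, j]`` is the strength
        from source j to target i.
    distances : (n, n) Euclidean distance matrix, recomputed from positions.
    """

    labels: list[str]
    positions: np.ndarray
    weights: np.ndarray
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"{n} labels but positions of shape {self.positions.shape}"
            )
        if self.weights.shape != (n, n):
            raise ValueError(
                f"{n} labels but weight matrix of shape {self.weights.shape}"
            )
        if np.any(self.weights < 0):
            raise ValueError("negative weights are not allowed")
        if self.distances is None:
            # always derived from positions: guarantees metric consistency
            self.distances = compute_distance_matrix(self.positions)
        else:
            self.distances = np.asarray(self.distances, dtype=float)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n_regions, dtype=bool)

    def input_strengths(self) -> np.ndarray:
        """Per-node input strength k_i = sum_j W_ij."""
        return self.weights.sum(axis=1)

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        """Same embedding, different weight matrix."""
        return Connectome(self.labels, self.positions, weights, self.distances)


def load_connectome(weights_path, positions_path) -> Connectome:
    """Load a connectome from a weights CSV and a positions CSV.

    The weights CSV is a square matrix with a header row of region labels and
    the labels in the first column.  The positions CSV has columns
    ``label,x,y,z`` (micrometres).
    """
    weights_path, positions_path = Path(weights_path), Path(positions_path)
    wdf = pd.read_csv(weights_path, index_col=0)
    pdf = pd.read_csv(positions_path)
    missing = {"label", "x", "y", "z"} - set(pdf.columns)
    if missing:
        raise ValueError(f"positions file missing columns: {sorted(missing)}")
    if wdf.shape[0] != wdf.shape[1]:
        raise ValueError(f"weight matrix is {wdf.shape[0]}x{wdf.shape[1]}, not square")
    if len(pdf) != len(wdf):
        raise ValueError(
            f"weight matrix has {len(wdf)} regions but positions file has {len(pdf)}"
        )
    labels = [str(x) for x in wdf.index]
    if list(map(str, wdf.columns)) != labels:
        raise ValueError("weight matrix row and column labels disagree")
    pdf = pdf.set_index(pdf["label"].astype(str))
    if set(pdf.index) != set(labels):
        raise ValueError("label sets of weights and positions files disagree")
    positions = pdf.loc[labels, ["x", "y", "z"]].to_numpy(dtype=float)
    return Connectome(labels, positions, wdf.to_numpy(dtype=float))


def save_connectome(conn: Connectome, weights_path, positions_path,
                    sidecar: dict | None = None, sidecar_path=None) -> None:
    """Write a connectome as weights CSV + positions CSV (+ JSON sidecar)."""
    wdf = pd.DataFrame(conn.weights, index=conn.labels, columns=conn.labels)
    wdf.to_csv(weights_path, float_format="%.12g")
    pdf = pd.DataFrame(conn.positions, columns=["x", "y", "z"])
    pdf.insert(0, "label", conn.labels)
    pdf.to_csv(positions_path, index=False, float_format="%.12g")
    if sidecar is not None:
        if sidecar_path is None:
            sidecar_path = Path(weights_path).with_suffix(".json")
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def assemble_bilateral(ipsi: np.ndarray, contra: np.ndarray,
                       positions: np.ndarray, labels: list[str] | None = None,
                       mirror_axis: int = 0,
                       midline: float | None = None) -> Connectome:
    """Assemble a two-hemisphere connectome from single-hemisphere blocks.

    Given the n x n ipsilateral block (within-hemisphere) and the n x n
    contralateral block (between hemispheres), builds the 2n-node matrix

        [[ipsi,   contra],
         [contra, ipsi  ]]

    assuming hemispheric mirror symmetry.  Positions of the second hemisphere
    are the first hemisphere's reflected across the midline plane
    (perpendicular to ``mirror_axis``; default midline is the maximum
    coordinate along that axis, so the hemispheres touch).
    """
    ipsi = np.asarray(ipsi, dtype=float)
    contra = np.asarray(contra, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = ipsi.shape[0]
    if ipsi.shape != (n, n) or contra.shape != (n, n):
        raise ValueError(
            f"block size mismatch: ipsi {ipsi.shape}, contra {contra.shape}"
        )
    if positions.shape != (n, 3):
        raise ValueError(f"expected {n} positions, got {positions.shape}")
    if labels is None:
        labels = [f"R{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    if midline is None:
        midline = positions[:, mirror_axis].max()
    mirrored = positions.copy()
    mirrored[:, mirror_axis] = 2.0 * midline - mirrored[:, mirror_axis]
    pos2 = np.vstack([positions, mirrored])
    w2 = np.block([[ipsi, contra], [contra, ipsi]])
    labels2 = [f"{l}_L" for l in labels] + [f"{l}_R" for l in labels]
    return Connectome(labels2, pos2, w2)
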