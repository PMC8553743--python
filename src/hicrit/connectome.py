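"""Build subjects x edges Fisher-Z connectivity panels from ROI time series.

A connectome here is the matrix of Pearson correlations between the mean
time signals of m regions of interest (ROIs).  The strict upper triangle of
that matrix, read row-major, defines the canonical linearization of the
m(m-1)/2 edges ("connectivities") used by every downstream module; for the
default 212-node connectome that is 22,366 edges.  Correlations are mapped
to the Fisher-Z scale (atanh) so that across-subject edge distributions are
approximately normal before regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: correlations with |r| above this are clamped before atanh
CLAMP = 1.0 - 1e-7


def edge_count(m: int) -> int:
    """Number of distinct node pairs among ``m`` nodes: m(m-1)/2."""
    if m < 0:
        raise ValueError("node count must be non-negative")
    return m * (m - 1) // 2


@dataclass(frozen=True)
class EdgeIndex:
    """Bijection between node pairs (i, j), i < j, and linear edge ids.

    The ordering is row-major over the strict upper triangle:
    (0,1), (0,2), ..., (0,m-1), (1,2), ... — the single canonical ordering
    shared by all modules.
    """

    m: int
    node_i: np.ndarray = field(init=False, repr=False)
    node_j: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("EdgeIndex requires at least 2 nodes")
        iu = np.triu_indices(self.m, k=1)
        object.__setattr__(self, "node_i", iu[0].astype(np.int64))
        object.__setattr__(self, "node_j", iu[1].astype(np.int64))

    @property
    def n_edges(self) -> int:
        return edge_count(self.m)

    def edge_id(self, i, j):
        """Linear edge id for node pair(s) (i, j) with i < j (vectorized)."""
        i = np.asarray(i)
        j = np.asarray(j)
        if np.any(i >= j) or np.any(i < 0) or np.any(j >= self.m):
            raise ValueError("require 0 <= i < j < m")
        return (i * (2 * self.m - i - 1)) // 2 + (j - i - 1)

    def endpoints(self, edge_ids):
        """Node pair (i, j) arrays for linear edge id(s)."""
        e = np.asarray(edge_ids)
        if np.any(e < 0) or np.any(e >= self.n_edges):
            raise ValueError("edge id out of range")
        return self.node_i[e], self.node_j[e]

    def to_matrix(self, values: np.ndarray, diag: float = 0.0) -> np.ndarray:
        """Inverse of :func:`vectorize_upper`: rebuild the symmetric matrix."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_edges,):
            raise ValueError("value vector length does not match edge count")
        mat = np.full((self.m, self.m), diag, dtype=float)
        mat[self.node_i, self.node_j] = values
        mat[self.node_j, self.node_i] = values
        return mat

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_id": np.arange(self.n_edges, dtype=np.int64),
                "node_i": self.node_i,
                "node_j": self.node_j,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def roi_correlation_matrix(series: np.ndarray) -> np.ndarray:
    """Sample Pearson correlation matrix of a T x m ROI time-series matrix.

    Raises if fewer than 3 time points or if any node has zero variance
    (the offending node ids are named in the error).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a T x m matrix")
    T, m = series.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    sd = series.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant signal for node(s) {dead.tolist()}")
    corr = np.corrcoef(series, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(r):
    """Fisher Z-transform atanh(r), variance-stabilizing sample correlations.

    Values with |r| >= 1 - 1e-7 are clamped (and logged) so degenerate inputs
    degrade gracefully instead of producing infinities.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.isnan(r)):
        raise ValueError("NaN correlation passed to fisher_z")
    n_clamped = int(np.sum(np.abs(r) > CLAMP))
    if n_clamped:
        logger.warning("fisher_z: clamped %d correlation(s) with |r| > %g", n_clamped, CLAMP)
    z = np.arctanh(np.clip(r, -CLAMP, CLAMP))
    return z if z.ndim else float(z)


def vectorize_upper(mat: np.ndarray) -> tuple[np.ndarray, EdgeIndex]:
    """Strict-upper-triangle vector of a square symmetric matrix.

    Returns the length-m(m-1)/2 edge vector in canonical order together with
    the :class:`EdgeIndex` describing the ordering.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("input must be a square matrix")
    index = EdgeIndex(mat.shape[0])
    return mat[index.node_i, index.node_j].copy(), index


@dataclass
class ConnectivityPanel:
    """n_subjects x n_edges matrix of Fisher-Z connectivities."""

    values: np.ndarray
    subject_ids: list[str]
    edge_index: EdgeIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel must be 2-D (subjects x edges)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject ids")
        if self.values.shape[1] != self.edge_index.n_edges:
            raise ValueError("column count does not match edge index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"e{k}" for k in range(self.n_edges)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConnectivityPanel":
        df = pd.read_csv(path)
        subject_ids = df["subject_id"].astype(str).tolist()
        values = df.drop(columns=["subject_id"]).to_numpy(dtype=float)
        # recover m from E = m(m-1)/2
        E = values.shape[1]
        m = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
        if edge_count(m) != E:
            raise ValueError(f"{E} columns is not a valid m(m-1)/2 edge count")
        return cls(values, subject_ids, EdgeIndex(m))


def build_panel(timeseries_panel) -> ConnectivityPanel:
    """Correlate, vectorize and Fisher-Z each subject's ROI series.

    Row s of the result is fisher_z(vectorize_upper(corr(series_s))).
    """
    series = timeseries_panel.series
    n, _, m = series.shape
    index = EdgeIndex(m)
    rows = np.empty((n, index.n_edges))
    for s in range(n):
        try:
            corr = roi_correlation_matrix(series[s])
        except ValueError as err:
            raise ValueError(
                f"subject {timeseries_panel.subject_ids[s]!r}: {err}"
            ) from err
        vec, _ = vectorize_upper(corr)
        rows[s] = fisher_z(vec)
    return ConnectivityPanel(rows, list(timeseries_panel.subject_ids), index)
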