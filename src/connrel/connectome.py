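"""Session-wise connectivity matrices, edge vectors and network summaries.

Functional connectivity (FC) between two regions is the Pearson correlation
of their conditioned timeseries; a subject-session's connectome is the full
region-by-region FC matrix.  Edge vectors use the canonical upper-triangle
order (i < j, row-major), so a parcellation with R regions yields
R(R-1)/2 edges.  No Fisher transform is applied anywhere: thresholding and
averaging operate in raw r units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .preprocess import SessionTimeseries

__all__ = [
    "ConnectivityMatrix",
    "EdgePanel",
    "DEFAULT_NETWORK_NAMES",
    "edge_index",
    "correlation_matrix",
    "vectorize_upper",
    "unvectorize_upper",
    "network_average_fc",
    "node_average",
    "edge_strength",
    "build_edge_panel",
]

#: the 12 canonical resting-state networks used for within-network averages
DEFAULT_NETWORK_NAMES = [
    "default_mode",
    "parieto_occipital",
    "fronto_parietal",
    "salience",
    "cingulo_opercular",
    "medial_parietal",
    "dorsal_attention",
    "ventral_attention",
    "visual",
    "smhand",
    "smmouth",
    "auditory",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson matrix for one subject-session.

    Regions whose timeseries had zero variance carry NaN correlations;
    downstream operations treat NaN as missing (pairwise exclusion).
    """

    values: np.ndarray
    region_names: list[str]
    subject_id: str = ""
    session_id: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = self.values.shape[0]
        if self.values.shape != (r, r):
            raise ValueError("values must be square")
        if len(self.region_names) != r:
            raise ValueError("region_names length must match matrix size")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("values must be symmetric within 1e-12")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgePanel:
    """Subjects x edges value table for one session.

    ``edge_index`` is the (E, 2) array of region pairs (i, j), i < j, in
    row-major upper-triangle order.
    """

    values: np.ndarray
    edge_index: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.edge_index = np.asarray(self.edge_index, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x edges")
        if self.edge_index.shape != (self.values.shape[1], 2):
            raise ValueError("edge_index must align with the edge axis")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids must align with the subject axis")
        pairs = self.edge_index
        if np.any(pairs[:, 0] >= pairs[:, 1]):
            raise ValueError("edge_index requires i < j")
        if pairs.shape[0] > 1:
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            if not np.array_equal(order, np.arange(pairs.shape[0])):
                raise ValueError("edge_index must be strictly increasing in (i, j)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def edge_index(n_regions: int) -> np.ndarray:
    """Canonical (E, 2) upper-triangle pair listing for R regions."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


def correlation_matrix(
    session: SessionTimeseries, subject_id: str = "", session_id: int = 1
) -> ConnectivityMatrix:
    """Pearson FC matrix of a session's concatenated timeseries.

    Zero-variance regions get NaN rows/columns and a warning; the diagonal
    is 1 for well-defined regions.
    """
    x = session.signal
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = x.std(axis=0)
    bad = sd == 0
    if bad.any():
        names = [session.region_names[i] for i in np.flatnonzero(bad)]
        warnings.warn(
            f"zero-variance regions {names}: correlations undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    return ConnectivityMatrix(
        values=r,
        region_names=list(session.region_names),
        subject_id=subject_id,
        session_id=session_id,
    )


def vectorize_upper(matrix: ConnectivityMatrix | np.ndarray,
                    atol: float = 1e-8) -> np.ndarray:
    """Emit the upper-triangle edges in canonical (i < j) row-major order."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else matrix
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(
        np.nan_to_num(values), np.nan_to_num(values.T), atol=atol
    ):
        raise ValueError(f"matrix is asymmetric beyond tolerance {atol}")
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu].copy()


def unvectorize_upper(
    edges: np.ndarray, n_regions: int, diagonal: float = np.nan
) -> np.ndarray:
    """Reassemble a symmetric matrix from a canonical edge vector."""
    edges = np.asarray(edges)
    expected = n_regions * (n_regions - 1) // 2
    if edges.shape != (expected,):
        raise ValueError(f"expected {expected} edges for {n_regions} regions")
    out = np.full((n_regions, n_regions), diagonal, dtype=float)
    iu = np.triu_indices(n_regions, k=1)
    out[iu] = edges
    out[(iu[1], iu[0])] = edges
    return out


def network_average_fc(
    matrix: ConnectivityMatrix, labels: Mapping[str, str]
) -> dict[str, float]:
    """Mean FC over within-network edges, one value per network.

    ``labels`` maps region name -> network name; unlabeled regions are
    simply excluded.  A network with fewer than two member regions has no
    within-network edge and is reported as NaN with a warning.  Missing
    (NaN) edges are excluded pairwise.
    """
    known = set(matrix.region_names)
    unknown = [r for r in labels if r not in known]
    if unknown:
        raise KeyError(f"labeled regions absent from matrix: {sorted(unknown)}")
    pos = {name: i for i, name in enumerate(matrix.region_names)}
    members: dict[str, list[int]] = {}
    for region, network in labels.items():
        members.setdefault(network, []).append(pos[region])
    out: dict[str, float] = {}
    for network in sorted(members):
        idx = sorted(members[network])
        if len(idx) < 2:
            warnings.warn(
                f"network {network!r} has a single region; average undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            out[network] = float("nan")
            continue
        block = matrix.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = block[iu]
        out[network] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return out


def node_average(edge_stat: np.ndarray, eidx: np.ndarray,
                 n_regions: int | None = None) -> np.ndarray:
    """Per-node mean of an edge statistic over the node's incident edges.

    Missing (NaN) edges are excluded from both numerator and denominator; a
    node with all incident edges missing gets NaN.
    """
    edge_stat = np.asarray(edge_stat, dtype=float)
    eidx = np.asarray(eidx, dtype=int)
    if edge_stat.shape != (eidx.shape[0],):
        raise ValueError("edge_stat must align with edge_index")
    if n_regions is None:
        n_regions = int(eidx.max()) + 1
    sums = np.zeros(n_regions)
    counts = np.zeros(n_regions)
    ok = np.isfinite(edge_stat)
    for col in (0, 1):
        np.add.at(sums, eidx[ok, col], edge_stat[ok])
        np.add.at(counts, eidx[ok, col], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def edge_strength(panel_s1: EdgePanel, panel_s2: EdgePanel) -> np.ndarray:
    """Per-edge mean FC over all subjects and both sessions."""
    _check_aligned(panel_s1, panel_s2)
    stacked = np.vstack([panel_s1.values, panel_s2.values])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(stacked, axis=0)


def build_edge_panel(matrices: Sequence[ConnectivityMatrix]) -> EdgePanel:
    """Stack one session's connectomes (one subject per row) into a panel."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("at least one matrix is required")
    names = matrices[0].region_names
    for m in matrices[1:]:
        if m.region_names != names:
            raise ValueError("all matrices must share an identical region order")
    rows = [vectorize_upper(m) for m in matrices]
    return EdgePanel(
        values=np.vstack(rows),
        edge_index=edge_index(len(names)),
        subject_ids=[m.subject_id for m in matrices],
    )


def _check_aligned(a: EdgePanel, b: EdgePanel) -> None:
    if a.subject_ids != b.subject_ids:
        raise ValueError("panels must list the same subjects in the same order")
    if not np.array_equal(a.edge_index, b.edge_index):
        raise ValueError("panels must share an identical edge index")
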