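"""Functional connectome construction: Fisher-z matrices and density sweeps.

From ROI time series, ROI-to-ROI connectivity is the Fisher-transformed
(arctanh) bivariate Pearson correlation of the BOLD series of each ROI pair.
Graphs are analysed at the whole-brain level and per subnetwork; each
(sub)matrix is proportionally thresholded — keeping only the strongest
fraction d of possible edges — at the nine densities 10%..50% in 5% steps,
then binarized. Thresholding operates on each network's own submatrix so
density is controlled per network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import ROIAtlas
from .errors import ContractError, DegenerateInputError, DomainError

#: The nine analysis densities: 10% to 50% of possible edges in 5% steps.
DENSITY_GRID = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))

#: Correlations are clamped to +/-(1 - CLAMP_EPS) before the Fisher transform
#: so duplicated series stay finite.
CLAMP_EPS = 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-z ROI-by-ROI matrix with zero diagonal."""

    values: np.ndarray
    roi_ids: tuple
    network: str = "global"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContractError("connectivity matrix must be square")
        if len(self.roi_ids) != v.shape[0]:
            raise ContractError("roi_ids length does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ContractError("connectivity matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ContractError("connectivity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ContractError("connectivity matrix must have a zero diagonal")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ThresholdedGraph:
    """Binary, undirected, self-loop-free graph at a fixed edge density."""

    adjacency: np.ndarray
    density: float
    network: str = "global"
    roi_ids: tuple = ()

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ContractError("adjacency must be square")
        a = a.astype(bool)
        if not np.array_equal(a, a.T):
            raise ContractError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(a)):
            raise ContractError("adjacency must have no self-loops")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def fisher_connectivity(timeseries: np.ndarray, roi_ids=None,
                        network: str = "global") -> ConnectivityMatrix:
    """Fisher-z connectivity from an (n_rois, n_timepoints) series.

    Entry (i, j) is arctanh(r_ij) of the Pearson correlation r_ij, clamped
    to +/-(1 - 1e-7) first so duplicated series give a large finite value
    rather than infinity. The diagonal is forced to zero. A zero-variance
    ROI is a degenerate input and is reported by name.
    """
    ts = np.asarray(timeseries, float)
    if ts.ndim != 2:
        raise ContractError("timeseries must be a 2-D (ROI x time) array")
    n_rois, n_t = ts.shape
    if n_t < 3:
        raise ContractError(f"need at least 3 time points, got {n_t}")
    if roi_ids is None:
        roi_ids = tuple(f"ROI{i + 1:03d}" for i in range(n_rois))
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if len(dead):
        names = ", ".join(str(roi_ids[i]) for i in dead[:5])
        raise DegenerateInputError(
            f"zero-variance time series for ROI(s): {names}"
        )
    r = np.corrcoef(ts)
    r = np.clip(r, -(1 - CLAMP_EPS), 1 - CLAMP_EPS)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, roi_ids=tuple(roi_ids), network=network)


def extract_subnetwork(matrix: ConnectivityMatrix, atlas: ROIAtlas,
                       network: str) -> ConnectivityMatrix:
    """Submatrix restricted to a subnetwork's ROIs, order preserved.

    ``"global"`` is the identity. The matrix must be atlas-sized (built on
    the full parcellation).
    """
    if network == "global":
        return matrix
    if matrix.n_rois != atlas.n_rois:
        raise ContractError(
            f"matrix has {matrix.n_rois} ROIs but atlas defines {atlas.n_rois}"
        )
    members = atlas.members(network)  # KeyError for unknown labels
    sub = matrix.values[np.ix_(members, members)]
    ids = tuple(matrix.roi_ids[i] for i in members)
    return ConnectivityMatrix(values=sub, roi_ids=ids, network=network)


def _edge_count(density: float, n: int) -> int:
    """Retained edges: round-half-up of density * possible edge count.

    A relative epsilon absorbs binary representation error in the density
    (0.35 * 44850 evaluates just below the half-way point in floats).
    """
    possible = n * (n - 1) // 2
    x = density * possible
    return int(np.floor(x + 0.5 + 1e-9 * max(1.0, x)))


def proportional_threshold(matrix: ConnectivityMatrix, density: float,
                           rank: str = "signed") -> ThresholdedGraph:
    """Keep the strongest ``density`` fraction of edges and binarize.

    Exactly ``round(density * n(n-1)/2)`` upper-triangular entries are
    retained — the k largest by signed weight (the toolbox convention for
    proportional thresholding; ``rank="abs"`` ranks by magnitude instead).
    Ties at the cut are broken by ascending (row, column) index, making the
    selection deterministic.
    """
    if not 0.0 < density <= 1.0:
        raise DomainError(f"density must lie in (0, 1], got {density}")
    if rank not in ("signed", "abs"):
        raise DomainError(f"unknown ranking mode {rank!r}")
    n = matrix.n_rois
    rows, cols = np.triu_indices(n, 1)
    w = matrix.values[rows, cols]
    if rank == "abs":
        w = np.abs(w)
    k = _edge_count(density, n)
    # lexsort: last key is primary -> descending weight, then (row, col) asc.
    order = np.lexsort((cols, rows, -w))
    keep = order[:k]
    adj = np.zeros((n, n), bool)
    adj[rows[keep], cols[keep]] = True
    adj |= adj.T
    return ThresholdedGraph(adjacency=adj, density=float(density),
                            network=matrix.network, roi_ids=matrix.roi_ids)


def density_sweep(matrix: ConnectivityMatrix, densities=DENSITY_GRID,
                  rank: str = "signed") -> list:
    """Thresholded, binarized graphs across the density grid (9 by default)."""
    return [proportional_threshold(matrix, d, rank=rank) for d in densities]


@dataclass(frozen=True)
class TSNRResult:
    """Per-ROI temporal signal-to-noise ratios and the scan-level summary."""

    per_roi: np.ndarray
    scan_mean: float
    n_undefined: int = 0


def temporal_snr(timeseries: np.ndarray) -> TSNRResult:
    """Temporal SNR per ROI: temporal mean over temporal SD.

    The scan-level summary is the mean over ROIs; ROIs with zero temporal
    SD are undefined (reported as +/-inf) and excluded from the summary
    with a warning.
    """
    ts = np.asarray(timeseries, float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ContractError("timeseries must be 2-D with at least 2 time points")
    mean = ts.mean(axis=1)
    sd = ts.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = mean / sd
    undefined = ~np.isfinite(tsnr)
    n_bad = int(undefined.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} ROI(s) have zero temporal SD; excluded from tSNR summary",
            stacklevel=2,
        )
    finite = tsnr[~undefined]
    scan_mean = float(finite.mean()) if len(finite) else float("nan")
    return TSNRResult(per_roi=tsnr, scan_mean=scan_mean, n_undefined=n_bad)
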