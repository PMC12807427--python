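"""Cartesian principal component analysis of trajectories.

The covariance of the fitted Cartesian coordinates,

    sigma_mn = < (r_m - <r_m>) (r_n - <r_n>) >,

is built over a chosen atom selection (conventionally the protein Calpha
trace) after rigid-fitting every frame to a common reference, then
diagonalised.  The large-eigenvalue modes (the essential subspace) carry the
collective motions; trajectories from other systems can be cross-projected
onto the same subspace to compare their sampling.  Rigid fitting removes six
degrees of freedom, so at least six eigenvalues are numerically zero.

Conventions: population covariance (divide by the number of frames); each
eigenvector's sign is fixed so its largest-magnitude component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import Selection, Structure, Trajectory, superpose

__all__ = [
    "CovarianceModel",
    "PCAResult",
    "ProjectionSet",
    "build_covariance",
    "eigendecompose",
    "contribution_fraction",
    "project",
    "extreme_conformations",
    "mode_arrows",
    "sorted_eigh",
]


@dataclass
class CovarianceModel:
    """Mean coordinates and 3N x 3N coordinate covariance (Angstrom^2)."""

    mean: np.ndarray
    matrix: np.ndarray
    selection: Selection
    n_frames: int
    fit_mode: str = "reference"

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")


@dataclass
class PCAResult:
    """Eigenvalues (descending, Angstrom^2) and orthonormal mode vectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray     # columns are modes
    mean: np.ndarray
    selection: Selection

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ProjectionSet:
    """Frame projections (Angstrom) onto selected modes."""

    values: np.ndarray           # F x k
    modes: tuple[int, ...]
    source: str = ""


def _fitted_selected_coords(
    trajs: Sequence[Trajectory],
    selection: Selection,
    reference: Structure,
) -> np.ndarray:
    """Concatenate frames from all replicas, rigid-fitted to the reference
    over the selection, and return the flattened selected coordinates."""
    idx = selection.indices
    ref = reference.coords[idx]
    rows = []
    for traj in trajs:
        if traj.frames.shape[1] <= idx.max():
            raise ValueError("selection exceeds trajectory atom count")
        for f in range(traj.n_frames):
            mob = traj.frames[f, idx]
            R, t, _ = superpose(mob, ref)
            rows.append((mob @ R.T + t).ravel())
    return np.asarray(rows)


def build_covariance(
    trajs: Sequence[Trajectory] | Trajectory,
    selection: Selection,
    reference: Structure,
    fit_mode: str = "reference",
) -> CovarianceModel:
    """Coordinate covariance of rigid-fitted frames about their combined mean.

    Replicas are concatenated before averaging, so one covariance describes
    the combined ensemble.  ``fit_mode="reference"`` fits every frame to the
    starting structure; ``"mean"`` adds one refit to the ensemble-average
    structure, the common alternative convention.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if fit_mode not in ("reference", "mean"):
        raise ValueError("fit_mode must be 'reference' or 'mean'")
    X = _fitted_selected_coords(trajs, selection, reference)
    if len(X) < 2:
        raise ValueError("need at least two frames for a covariance")
    if fit_mode == "mean":
        mean_structure = reference.with_coords(reference.coords.copy())
        mean_coords = mean_structure.coords.copy()
        mean_coords[selection.indices] = X.mean(axis=0).reshape(-1, 3)
        X = _fitted_selected_coords(trajs, selection,
                                    reference.with_coords(mean_coords))
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / len(X)   # population convention
    cov = 0.5 * (cov + cov.T)
    return CovarianceModel(mean=mean, matrix=cov, selection=selection,
                           n_frames=len(X), fit_mode=fit_mode)


def sorted_eigh(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalues descending, signs fixed so
    each eigenvector's largest-magnitude component is positive.

    Shared by Cartesian PCA and contact PCA so both report identical spectra
    on identical matrices.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-8 * max(1.0, np.abs(matrix).max())):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(matrix)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def eigendecompose(cov: CovarianceModel) -> PCAResult:
    """Full spectrum of the coordinate covariance, descending."""
    vals, vecs = sorted_eigh(cov.matrix)
    trace = np.trace(cov.matrix)
    if trace > 0 and vals.min() < -1e-8 * trace:
        raise ValueError("covariance is not positive semidefinite")
    return PCAResult(eigenvalues=vals, eigenvectors=vecs, mean=cov.mean,
                     selection=cov.selection)


def contribution_fraction(pca: PCAResult, mode: int) -> float:
    """Fraction of total fluctuation carried by one mode (0-based index;
    mode 0 is PC1).  Tiny negative eigenvalues are clipped to zero."""
    vals = np.clip(pca.eigenvalues, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    return float(vals[mode] / total)


def project(
    traj: Trajectory,
    pca: PCAResult,
    modes: Sequence[int] = (0, 1),
    reference: Structure | None = None,
    source: str = "",
) -> ProjectionSet:
    """Project a trajectory onto PCA modes (cross-projection supported).

    Frames are rigid-fitted to ``reference`` over the PCA selection, exactly
    as during the covariance build, then projected as
    ``(coords - mean) . eigenvector``.  Pass the same reference that defined
    the subspace; omit it only for pre-fitted coordinates.
    """
    idx = pca.selection.indices
    if traj.frames.shape[1] <= idx.max():
        raise ValueError("trajectory incompatible with PCA selection")
    if reference is not None:
        X = _fitted_selected_coords([traj], pca.selection, reference)
    else:
        X = traj.frames[:, idx].reshape(traj.n_frames, -1)
    if X.shape[1] != len(pca.mean):
        raise ValueError("dimension mismatch between trajectory and PCA model")
    modes = tuple(int(m) for m in modes)
    vecs = pca.eigenvectors[:, list(modes)]
    values = (X - pca.mean) @ vecs
    return ProjectionSet(values=values, modes=modes, source=source)


def extreme_conformations(proj: ProjectionSet, mode: int = 0) -> tuple[int, int]:
    """Frame indices with the most negative and most positive projection on
    one mode; ties resolve to the lowest frame index."""
    if proj.values.size == 0:
        raise ValueError("empty projection set")
    col = list(proj.modes).index(mode) if mode in proj.modes else mode
    values = proj.values[:, col]
    return int(np.argmin(values)), int(np.argmax(values))


def mode_arrows(pca: PCAResult, mode: int, scale: float = 1.0) -> np.ndarray:
    """Per-atom displacement field of a mode (selected atoms x 3), scaled;
    suitable for drawing arrows between conformations in a viewer."""
    vec = pca.eigenvectors[:, mode]
    return scale * vec.reshape(-1, 3)
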