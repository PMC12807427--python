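"""Contact-based PCA (conPCA).

Instead of Cartesian coordinates, the covariance

    sigma_ij = < (D_i - <D_i>) (D_j - <D_j>) >

is built over the per-frame minimum heavy-atom distances D of the native
contact pairs and diagonalised with the same eigensolver and sign convention
as the Cartesian PCA.  A mode's components weight the contacts by their
contribution to the collective contact dynamics; contacts that form or break
together carry same-signed components of comparable magnitude.  Raw distances
enter the covariance untransformed (no switching function, no
standardisation); an optional correlation variant is available for scale-free
comparisons but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactDistanceSeries, ContactPair
from .pca import sorted_eigh

__all__ = [
    "ContactCovariance",
    "ConPCAModes",
    "contact_covariance",
    "conpca_modes",
    "rank_components",
    "sign_coherent",
    "representative_frames",
    "conpca_projections",
]


@dataclass
class ContactCovariance:
    """Mean contact distances and their P x P covariance (Angstrom^2)."""

    mean: np.ndarray
    matrix: np.ndarray
    pairs: list[ContactPair]

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("contact covariance must be symmetric")
        if np.any(np.diag(self.matrix) < -1e-12):
            raise ValueError("contact covariance diagonal must be non-negative")


@dataclass
class ConPCAModes:
    """Contact-PCA spectrum; eigenvector components are indexed by contact."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean: np.ndarray
    pairs: list[ContactPair]


def contact_covariance(
    series: ContactDistanceSeries,
    correlation: bool = False,
) -> ContactCovariance:
    """Population covariance of the contact-distance columns.

    ``correlation=True`` normalises to unit variances (constant columns keep
    zero rows/columns); the default keeps raw Angstrom^2 covariances, so a
    contact's weight scales with the square of its distance fluctuation.
    """
    D = series.distances
    if D.shape[0] < 2:
        raise ValueError("need at least two frames for a covariance")
    mean = D.mean(axis=0)
    Dc = D - mean
    cov = (Dc.T @ Dc) / D.shape[0]
    if correlation:
        sd = np.sqrt(np.diag(cov))
        scale = np.where(sd > 0, sd, 1.0)
        cov = cov / np.outer(scale, scale)
        np.fill_diagonal(cov, np.where(sd > 0, 1.0, 0.0))
    cov = 0.5 * (cov + cov.T)
    return ContactCovariance(mean=mean, matrix=cov, pairs=list(series.contacts.pairs))


def conpca_modes(cov: ContactCovariance) -> ConPCAModes:
    """Eigendecomposition sharing the Cartesian-PCA solver and sign rule."""
    vals, vecs = sorted_eigh(cov.matrix)
    return ConPCAModes(eigenvalues=vals, eigenvectors=vecs, mean=cov.mean,
                       pairs=cov.pairs)


def rank_components(
    modes: ConPCAModes,
    mode: int = 0,
) -> list[tuple[ContactPair, float]]:
    """Contacts ordered by descending |component| of one mode.

    Ties keep native contact order; signed components are preserved in the
    output so form/break coherence remains visible.
    """
    comp = modes.eigenvectors[:, mode]
    order = sorted(range(len(comp)), key=lambda i: (-abs(comp[i]), i))
    return [(modes.pairs[i], float(comp[i])) for i in order]


def sign_coherent(modes: ConPCAModes, mode: int = 0, top_k: int | None = None) -> bool:
    """True when the top-k ranked components of a mode share one sign
    (zero components are sign-neutral)."""
    ranked = rank_components(modes, mode)
    if top_k is not None:
        ranked = ranked[:top_k]
    signs = {np.sign(c) for _, c in ranked if c != 0.0}
    return len(signs) <= 1


def conpca_projections(
    series: ContactDistanceSeries,
    modes: ConPCAModes,
    mode: int = 0,
) -> np.ndarray:
    """Per-frame projection (D - <D>) . eigenvector for one mode."""
    return (series.distances - modes.mean) @ modes.eigenvectors[:, mode]


def representative_frames(
    series: ContactDistanceSeries,
    modes: ConPCAModes,
    mode: int = 0,
) -> tuple[int, int]:
    """Frames with the most negative / most positive projection on a mode
    (lowest frame index on ties), the convention used to pick representative
    structures on either side of a contact transition."""
    if series.n_frames == 0:
        raise ValueError("empty distance series")
    proj = conpca_projections(series, modes, mode)
    return int(np.argmin(proj)), int(np.argmax(proj))
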