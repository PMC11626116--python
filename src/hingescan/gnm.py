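"""Gaussian Network Model: Kirchhoff matrix, slow modes, mode selection.

The GNM represents a protein as a network of Calpha nodes connected by
identical springs whenever two nodes are within a distance cutoff.  The
dynamics follow from the eigendecomposition of the Kirchhoff (graph
Laplacian) matrix: low-eigenvalue modes describe the most cooperative
motions, and each mode's share of the total fluctuation variance scales as
1/lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .errors import DisconnectedStructureError
from .structio import Structure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 10.0     # Angstrom, Calpha-Calpha
DEFAULT_SIGMA_MIN = 1.0 / 3.0
DEFAULT_K_MAX = 3


@dataclass
class KirchhoffMatrix:
    matrix: np.ndarray
    cutoff: float
    gamma: float = 1.0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModeSet:
    """Nonzero GNM modes sorted by ascending eigenvalue.

    ``eigenvectors`` is (N, n_modes); ``variance_fractions[k]`` is the mode's
    share of total variance, (1/lambda_k) / sum_j (1/lambda_j).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fractions: np.ndarray
    selected_k: int = 0
    sigma: float = 0.0

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def profile(self, mode_index: int) -> "ModeProfile":
        """1-based mode index -> per-residue profile."""
        return ModeProfile(mode_index=mode_index,
                           values=self.eigenvectors[:, mode_index - 1].copy())


@dataclass
class ModeProfile:
    """Per-residue signed displacement along one mode axis (unit norm)."""

    mode_index: int
    values: np.ndarray


def build_kirchhoff(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                    gamma: float = 1.0) -> KirchhoffMatrix:
    """Kirchhoff matrix from Calpha coordinates: -gamma for pairs within
    cutoff, diagonal = contact count, every row summing to zero."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = structure.ca_coords
    if len(coords) < 10:
        raise ValueError(f"need >= 10 residues for GNM, got {len(coords)}")
    dist = squareform(pdist(coords))
    adj = (dist <= cutoff).astype(float)
    np.fill_diagonal(adj, 0.0)
    k = -gamma * adj
    np.fill_diagonal(k, gamma * adj.sum(axis=1))
    return KirchhoffMatrix(matrix=k, cutoff=cutoff, gamma=gamma)


def _flip_sign(vec: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(vec)))
    return -vec if vec[i] < 0 else vec


def gnm_modes(kirchhoff: KirchhoffMatrix) -> ModeSet:
    """Eigendecompose the Kirchhoff matrix and drop the single zero mode.

    More than one numerically zero eigenvalue means the contact graph is
    disconnected; the error lists the components.
    """
    vals, vecs = eigh(kirchhoff.matrix)
    tol = 1e-8 * max(vals[-1], 1.0)
    n_zero = int(np.sum(np.abs(vals) <= tol))
    if n_zero > 1:
        adj = (kirchhoff.matrix < 0).astype(int)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise DisconnectedStructureError(comps)
    vals = vals[n_zero:]
    vecs = vecs[:, n_zero:]
    vecs = np.column_stack([_flip_sign(vecs[:, j]) for j in range(vecs.shape[1])])
    inv = 1.0 / vals
    fractions = inv / inv.sum()
    return ModeSet(eigenvalues=vals, eigenvectors=vecs,
                   variance_fractions=fractions)


def select_modes(modeset: ModeSet, sigma_min: float = DEFAULT_SIGMA_MIN,
                 k_max: int = DEFAULT_K_MAX) -> int:
    """Smallest k with cumulative variance >= sigma_min, capped at k_max.

    The chosen k and the cumulative variance sigma are stored on the
    ModeSet.  When the cap binds, k = k_max is used (with a warning) even if
    sigma stays below sigma_min.
    """
    if modeset.n_modes == 0:
        raise ValueError("empty mode set")
    cum = np.cumsum(modeset.variance_fractions)
    reached = np.flatnonzero(cum >= sigma_min)
    k = int(reached[0]) + 1 if len(reached) else modeset.n_modes
    if k >= k_max:
        if cum[min(k_max, modeset.n_modes) - 1] < sigma_min:
            logger.warning(
                "mode cap k_max=%d binds: cumulative variance %.3f < %.3f",
                k_max, cum[min(k_max, modeset.n_modes) - 1], sigma_min)
        else:
            logger.warning("using the maximum of %d modes", k_max)
        k = min(k_max, modeset.n_modes)
    modeset.selected_k = k
    modeset.sigma = float(cum[k - 1])
    return k


def modes_for_structure(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                        sigma_min: float = DEFAULT_SIGMA_MIN,
                        k_max: int = DEFAULT_K_MAX) -> ModeSet:
    """Convenience wrapper: Kirchhoff -> modes -> mode selection."""
    ms = gnm_modes(build_kirchhoff(structure, cutoff))
    select_modes(ms, sigma_min=sigma_min, k_max=k_max)
    return ms
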