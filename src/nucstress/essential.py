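"""Essential dynamics: superposition, displacement covariance, eigenanalysis,
per-mode RMSF, principal-plane projections, and essential-subspace overlap.

The covariance matrix C = <(x - <x>)(x - <x>)^T> of atomic displacements
(plain, not mass-weighted; units nm^2) is diagonalized to obtain the
collective modes of motion.  The leading eigenvectors describe the
large-scale, anharmonic movements (bending, torsion) that dominate the
dynamics; their eigenvalue fractions quantify how much of the total
fluctuation each mode carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structures import Selection, Trajectory

__all__ = [
    "CovarianceModel",
    "EDResult",
    "ProjectionSeries",
    "superpose",
    "covariance",
    "diagonalize",
    "mode_rmsf",
    "project",
    "subspace_overlap",
]


@dataclass
class CovarianceModel:
    """Displacement covariance of a selected atom set.

    ``covariance`` is the 3N x 3N matrix in nm^2 with population (1/F)
    normalization by default; ``mean_coords`` is the trajectory mean of the
    selection (N x 3 nm), ``reference_coords`` the superposition target.
    """

    selection: Selection
    reference_coords: np.ndarray
    mean_coords: np.ndarray
    covariance: np.ndarray
    n_frames: int

    def __post_init__(self):
        C = np.asarray(self.covariance, dtype=float)
        if not np.allclose(C, C.T, atol=1e-10 * max(np.abs(C).max(), 1.0)):
            raise ValueError("covariance must be symmetric")
        self.covariance = C

    @property
    def n_atoms(self) -> int:
        return len(self.selection)


@dataclass
class EDResult:
    """Eigensystem of a displacement covariance matrix.

    Eigenvalues descend (nm^2); ``fractions`` are eigenvalue/trace and sum to
    one; eigenvectors are orthonormal columns of ``eigenvectors``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # 3N x 3N, column k = mode k
    fractions: np.ndarray
    cumulative_fractions: np.ndarray
    mean_coords: np.ndarray
    selection: Selection

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


@dataclass
class ProjectionSeries:
    """Per-frame projections (A) of a trajectory on selected modes."""

    modes: tuple[int, ...]
    times: np.ndarray
    coordinates: np.ndarray  # F x len(modes)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ps": self.times}
        for j, m in enumerate(self.modes):
            cols[f"p{m}_A"] = self.coordinates[:, j]
        return pd.DataFrame(cols)


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation/translation of ``mobile`` onto ``reference``."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot, mc, rc


def superpose(trajectory: Trajectory, selection: Selection,
              reference: np.ndarray) -> Trajectory:
    """Least-squares rigid-body fit of every frame onto ``reference``.

    The fit minimizes the RMSD of the selection; the transform is applied to
    all atoms of the frame.  Requires at least 3 non-collinear selected atoms.
    """
    reference = np.asarray(reference, dtype=float)
    if len(selection) < 3:
        raise ValueError("superposition needs >= 3 selected atoms")
    sv = np.linalg.svd(reference - reference.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-30):
        raise ValueError("superposition reference atoms are collinear")
    frames = np.empty_like(trajectory.frames)
    for f in range(trajectory.n_frames):
        rot, mc, rc = _kabsch(trajectory.frames[f, selection.indices], reference)
        frames[f] = rot.apply(trajectory.frames[f] - mc) + rc
    return Trajectory(trajectory.structure, frames, trajectory.times)


def covariance(aligned: Trajectory, selection: Selection,
               ddof: int = 0) -> CovarianceModel:
    """Displacement covariance C = <dx dx^T> of the selected atoms (nm^2).

    ``ddof=0`` (default) is the population normalization 1/F; pass ``ddof=1``
    for the 1/(F-1) sample convention.
    """
    F = aligned.n_frames
    if F < 2:
        raise ValueError("covariance requires at least 2 frames")
    X = aligned.frames[:, selection.indices, :].reshape(F, -1)
    mean = X.mean(axis=0)
    dX = X - mean
    C = dX.T @ dX / (F - ddof)
    C = 0.5 * (C + C.T)
    return CovarianceModel(
        selection=selection,
        reference_coords=aligned.frames[0, selection.indices].copy(),
        mean_coords=mean.reshape(-1, 3),
        covariance=C,
        n_frames=F,
    )


def diagonalize(model: CovarianceModel) -> EDResult:
    """Eigen-decomposition of the covariance, eigenvalues descending.

    Negative numerical eigenvalues are clamped to zero before fractions are
    formed; the smallest eigenvalue must exceed -1e-10 times the largest
    (numerical positive semidefiniteness).
    """
    C = model.covariance
    if not np.allclose(C, C.T, atol=1e-8 * max(np.abs(C).max(), 1.0)):
        raise ValueError("covariance matrix is not symmetric")
    w, V = np.linalg.eigh(C)
    if w.size and w[0] < -1e-10 * max(w[-1], 1e-30):
        raise ValueError(f"covariance not PSD: min eigenvalue {w[0]:.3e}")
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    total = w.sum()
    fractions = w / total if total > 0 else np.zeros_like(w)
    return EDResult(
        eigenvalues=w,
        eigenvectors=V,
        fractions=fractions,
        cumulative_fractions=np.cumsum(fractions),
        mean_coords=model.mean_coords,
        selection=model.selection,
    )


def mode_rmsf(ed: EDResult, mode: int) -> np.ndarray:
    """Per-atom RMSF of mode ``mode`` (1-based), numerically in Angstrom.

    RMSF_i = sqrt(lambda_k) * ||v_k restricted to atom i||.  These are not
    true atomic displacements but per-atom weights of a collective mode; the
    units are arbitrary though numerically coincident with Angstrom, and the
    normalization makes sum_i RMSF_i^2 = lambda_k (in A^2).
    """
    if not 1 <= mode <= ed.n_modes:
        raise ValueError(f"mode {mode} out of range 1..{ed.n_modes}")
    v = ed.eigenvectors[:, mode - 1].reshape(-1, 3)
    lam_A2 = ed.eigenvalues[mode - 1] * 100.0  # nm^2 -> A^2
    return np.sqrt(lam_A2) * np.linalg.norm(v, axis=1)


def project(aligned: Trajectory, ed: EDResult,
            modes: tuple[int, ...] = (1, 2)) -> ProjectionSeries:
    """Project each frame onto the given modes: p_k = v_k . (x - <x>), in A."""
    for m in modes:
        if not 1 <= m <= ed.n_modes:
            raise ValueError(f"mode {m} out of range 1..{ed.n_modes}")
    X = aligned.frames[:, ed.selection.indices, :].reshape(aligned.n_frames, -1)
    if X.shape[1] != ed.eigenvectors.shape[0]:
        raise ValueError("trajectory selection does not match eigenvector size")
    dX = X - ed.mean_coords.reshape(-1)
    V = ed.eigenvectors[:, [m - 1 for m in modes]]
    return ProjectionSeries(tuple(modes), aligned.times, (dX @ V) * 10.0)


def subspace_overlap(ed_a: EDResult, ed_b: EDResult, d: int = 2) -> float:
    """Root-mean-square inner product (RMSIP) of the first ``d`` modes.

    RMSIP = sqrt( (1/d) sum_{i,j<=d} (v_i . u_j)^2 ), in [0, 1]; 1 for
    identical subspaces, 0 for mutually orthogonal ones.
    """
    if ed_a.eigenvectors.shape[0] != ed_b.eigenvectors.shape[0]:
        raise ValueError("eigenvector dimensions differ")
    if not 1 <= d <= ed_a.n_modes:
        raise ValueError(f"d={d} out of range")
    A = ed_a.eigenvectors[:, :d]
    B = ed_b.eigenvectors[:, :d]
    return float(np.sqrt(np.sum((A.T @ B) ** 2) / d))
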