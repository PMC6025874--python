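"""Schlitter configurational entropy and DSB excess entropy.

The Schlitter formula gives an upper bound on the configurational entropy of
a fluctuating molecular fragment from its positional covariance C:

    S = (1/2) k_B ln det[ I + (k_B T e^2 / hbar^2) M C ]

with M the diagonal mass matrix (each atom's mass repeated for x, y, z) and
e Euler's number (~2.71828) -- NOT the elementary charge.  The excess entropy
of a damaged fragment relative to the intact reference is

    T dS = T ( <S_damaged> - <S_reference> )

with <...> time averages of S over trajectory windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (AMU_KG, AVOGADRO, CAL_J, E_EULER, HBAR_J_S, KB_J,
                        NM2_M2)
from .essential import CovarianceModel, covariance
from .structures import Selection, Trajectory

__all__ = [
    "EntropyResult",
    "ExcessEntropyResult",
    "schlitter_entropy",
    "excess_entropy",
    "windowed_entropies",
    "schlitter_alpha",
]


@dataclass
class EntropyResult:
    """Absolute Schlitter entropy S (kcal mol^-1 K^-1) at temperature T (K)."""

    S: float
    T: float
    n_atoms: int
    n_frames: int

    def __post_init__(self):
        if self.S < 0:
            raise ValueError("Schlitter entropy cannot be negative")


@dataclass
class ExcessEntropyResult:
    """T*dS (kcal/mol) of a damaged fragment relative to the intact one."""

    TdS: float
    T: float
    mean_damaged: float
    mean_reference: float
    component: str = ""


def schlitter_alpha(temperature: float) -> float:
    """The dimensionless-group prefactor k_B T e^2 / hbar^2 in SI (J^-1 s^-2).

    Multiplying by mass (kg) and covariance (m^2) yields the dimensionless
    argument of the Schlitter determinant.
    """
    return KB_J * temperature * E_EULER**2 / HBAR_J_S**2


def schlitter_entropy(model: CovarianceModel, masses: np.ndarray,
                      temperature: float) -> EntropyResult:
    """Schlitter upper-bound entropy of a covariance model.

    ``masses`` are per-atom (amu, one entry per selected atom); the covariance
    is in nm^2.  Computed via the symmetrized product
    I + alpha * M^(1/2) C M^(1/2), which shares its spectrum with I + alpha*MC
    but is symmetric positive definite, so the log-determinant is evaluated
    stably from its eigenvalues.  Result in kcal mol^-1 K^-1.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    C = np.asarray(model.covariance, dtype=float)
    if masses.size * 3 != C.shape[0]:
        raise ValueError("need one mass per selected atom")

    alpha = schlitter_alpha(temperature)
    m_si = np.repeat(masses * AMU_KG, 3)
    sqrt_m = np.sqrt(m_si)
    A = alpha * (sqrt_m[:, None] * (C * NM2_M2) * sqrt_m[None, :])
    A = 0.5 * (A + A.T)
    w = np.linalg.eigvalsh(A)
    tol = 1e-10 * max(w[-1], 1.0) if w.size else 0.0
    if w.size and w[0] < -tol:
        raise ValueError(f"covariance has negative eigenvalues ({w[0]:.3e})")
    w = np.clip(w, 0.0, None)
    logdet = float(np.sum(np.log1p(w)))
    if not np.isfinite(logdet):
        raise ValueError("non-finite Schlitter determinant")
    S_si = 0.5 * KB_J * logdet  # J/K per fragment
    S = S_si * AVOGADRO / (1000.0 * CAL_J)  # kcal mol^-1 K^-1
    return EntropyResult(S=S, T=temperature, n_atoms=masses.size,
                         n_frames=model.n_frames)


def windowed_entropies(trajectory: Trajectory, selection: Selection,
                       masses: np.ndarray, temperature: float,
                       window: int = 100) -> list[EntropyResult]:
    """Schlitter entropy over disjoint ``window``-frame blocks.

    Forms the series whose mean enters the excess-entropy time average; the
    trailing partial block is dropped.
    """
    F = trajectory.n_frames
    out = []
    for start in range(0, F - window + 1, window):
        block = Trajectory(trajectory.structure,
                           trajectory.frames[start:start + window],
                           trajectory.times[start:start + window])
        model = covariance(block, selection)
        out.append(schlitter_entropy(model, masses, temperature))
    if not out:
        raise ValueError(f"trajectory shorter than one window ({window} frames)")
    return out


def excess_entropy(damaged_series: list[EntropyResult],
                   reference_series: list[EntropyResult],
                   temperature: float,
                   component: str = "") -> ExcessEntropyResult:
    """T*dS = T * (mean damaged S - mean reference S), in kcal/mol."""
    if not damaged_series or not reference_series:
        raise ValueError("both entropy series must be non-empty")
    for r in (*damaged_series, *reference_series):
        if not np.isclose(r.T, temperature):
            raise ValueError(
                f"temperature mismatch: series at {r.T} K, requested "
                f"{temperature} K")
    md = float(np.mean([r.S for r in damaged_series]))
    mr = float(np.mean([r.S for r in reference_series]))
    return ExcessEntropyResult(TdS=temperature * (md - mr), T=temperature,
                               mean_damaged=md, mean_reference=mr,
                               component=component)
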