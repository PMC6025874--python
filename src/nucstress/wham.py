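"""Umbrella-sampling free-energy reconstruction by the weighted-histogram
analysis method (WHAM), and barrier / Boltzmann-probability extraction.

Each umbrella window holds samples of the reaction coordinate zeta drawn
under a harmonic bias u_i(z) = (1/2) k_i (z - z0_i)^2.  The self-consistent
WHAM equations recombine the window histograms into the unbiased probability
P(z) and hence the potential of mean force A(z) = -k_B T ln P(z), min-shifted
to zero:

    P_l = sum_i n_il / sum_i N_i exp[(f_i - u_i(z_l)) / k_B T]
    exp(-f_i / k_B T) = sum_l P_l exp(-u_i(z_l) / k_B T)

iterated until the window free-energy constants f_i change by less than a
tolerance.  Barriers are read off the profile as dA = max A in a region minus
A at the region's left edge, and converted to a Boltzmann probability
p = 100 exp(-dA / k_B T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import CAL_J, kbt_kcal_mol

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "wham",
    "barrier_and_probability",
    "read_window_tsv",
    "write_window_tsv",
]

#: kJ/mol -> kcal/mol
KJ_TO_KCAL = 1.0 / CAL_J


@dataclass
class UmbrellaWindow:
    """Samples of zeta (nm) under a harmonic bias (1/2) k (z - z0)^2.

    ``spring_k`` is in kJ mol^-1 nm^-2 (the MD convention); temperature in K.
    """

    center: float
    spring_k: float
    samples: np.ndarray
    temperature: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.spring_k < 0:
            raise ValueError("spring constant must be >= 0")
        if self.samples.size == 0:
            raise ValueError("window has no samples")

    def bias_kcal(self, z: np.ndarray) -> np.ndarray:
        """Bias energy at z, kcal/mol."""
        return 0.5 * self.spring_k * KJ_TO_KCAL * (np.asarray(z) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free energy A(zeta) (kcal/mol, min-shifted to 0) on equal-width bins.

    Unpopulated bins carry NaN; ``window_free_energies`` are the converged
    WHAM constants f_i (kcal/mol, first window pinned at 0).
    """

    bin_centers: np.ndarray
    A: np.ndarray
    counts: np.ndarray
    temperature: float
    iterations: int
    residual: float
    window_free_energies: np.ndarray = field(default=None)

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        populated = np.isfinite(self.A)
        if populated.any() and not np.isclose(np.nanmin(self.A), 0.0, atol=1e-9):
            raise ValueError("profile must be min-shifted to zero")

    def to_frame(self) -> pd.DataFrame:
        # count-weighted statistical uncertainty per bin (Poisson, in kBT)
        kbt = kbt_kcal_mol(self.temperature)
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = np.where(self.counts > 0, kbt / np.sqrt(self.counts), np.nan)
        return pd.DataFrame({"zeta_nm": self.bin_centers, "A_kcal_mol": self.A,
                             "n": self.counts, "sigma_A_kcal_mol": sigma})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# T_K={self.temperature} iterations={self.iterations} "
                     f"residual_kcal_mol={self.residual:.3e}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def wham(windows: list[UmbrellaWindow], n_bins: int = 100,
         tol: float = 1e-8, temperature: float | None = None,
         max_iter: int = 100000) -> PMFProfile:
    """Self-consistent WHAM over harmonic umbrella windows.

    ``tol`` is the convergence threshold on the maximum change of the window
    free-energy constants per iteration, in kcal/mol.  Bins are equal-width
    over the pooled sample range.  A warning is emitted if adjacent windows
    (ordered by center) share no populated bin, in which case the profile may
    be disconnected.
    """
    if not windows:
        raise ValueError("wham requires at least one window")
    if temperature is None:
        temperature = windows[0].temperature
    for w in windows:
        if not np.isclose(w.temperature, temperature):
            raise ValueError("all windows must share the temperature")
    kbt = kbt_kcal_mol(temperature)

    pooled = np.concatenate([w.samples for w in windows])
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_win = len(windows)
    counts = np.zeros((n_win, n_bins))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
    N = counts.sum(axis=1)
    total = counts.sum(axis=0)

    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            warnings.warn(
                f"umbrella windows centered at {windows[a].center:.3f} and "
                f"{windows[b].center:.3f} nm share no populated bin; the "
                "reconstructed profile may be disconnected")

    # -beta * u_i(z_l)
    neg_bias = np.stack([-w.bias_kcal(centers) / kbt for w in windows])
    f = np.zeros(n_win)  # window free energies, kcal/mol
    logN = np.log(np.where(N > 0, N, 1.0))
    with np.errstate(divide="ignore"):
        log_total = np.where(total > 0, np.log(total), -np.inf)

    log_p = None
    for iteration in range(1, max_iter + 1):
        # log denominator_l = logsumexp_i [ ln N_i + (f_i - u_il)/kBT ]
        log_den = logsumexp(logN[:, None] + f[:, None] / kbt + neg_bias, axis=0)
        log_p = log_total - log_den
        # update f_i = -kBT ln sum_l P_l exp(-u_il/kBT)
        f_new = -kbt * logsumexp(log_p[None, :] + neg_bias, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kcal/mol)")

    with np.errstate(invalid="ignore"):
        A = np.where(total > 0, -kbt * log_p, np.nan)
    A = A - np.nanmin(A)
    return PMFProfile(centers, A, total.astype(int), temperature,
                      iterations=iteration, residual=residual,
                      window_free_energies=f)


def barrier_and_probability(profile: PMFProfile,
                            region: tuple[float, float],
                            temperature: float | None = None
                            ) -> tuple[float, float]:
    """Barrier height and Boltzmann escape probability over a zeta region.

    dA = max A within ``region`` minus A at the region's left edge (nearest
    populated bin); p = 100 * exp(-dA / k_B T) in percent.  E.g. a barrier of
    1.8 kcal/mol (3 k_B T) at 310 K gives p ~ 5%.
    """
    if temperature is None:
        temperature = profile.temperature
    lo, hi = region
    populated = np.isfinite(profile.A)
    in_region = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & populated
    if not np.any(in_region):
        raise ValueError(f"region {region} is outside the populated profile")
    idx = np.flatnonzero(in_region)
    A_left = profile.A[idx[0]]
    dA = float(np.max(profile.A[idx]) - A_left)
    p = 100.0 * float(np.exp(-dA / kbt_kcal_mol(temperature)))
    return dA, p


def write_window_tsv(window: UmbrellaWindow, path,
                     times: np.ndarray | None = None) -> None:
    """Window TSV: metadata header (# zeta0, k, T) then time/zeta columns."""
    if times is None:
        times = np.arange(window.samples.size, dtype=float) * 50.0  # ps
    with open(path, "w") as fh:
        fh.write(f"# zeta0_nm={window.center} k_kj_mol_nm2={window.spring_k} "
                 f"T_K={window.temperature}\n")
        pd.DataFrame({"time_ps": times, "zeta_nm": window.samples}
                     ).to_csv(fh, sep="\t", index=False)


def read_window_tsv(path) -> UmbrellaWindow:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    return UmbrellaWindow(center=float(meta["zeta0_nm"]),
                          spring_k=float(meta["k_kj_mol_nm2"]),
                          samples=df["zeta_nm"].to_numpy(),
                          temperature=float(meta["T_K"]))
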