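"""DNA tube geometry: base pairing, the neutral-axis centerline with local
frames, the DSB-detachment reaction coordinate zeta, contact distances, and
hydrogen-bond time series.

The nucleosomal duplex is treated as a curved elastic tube.  Its neutral axis
(centerline) is traced through the per-base-pair midpoints of the two backbone
phosphorus atoms; at every point a right-handed orthonormal frame {n, tau, b}
is carried, with tau the local tangent and b the binormal directed toward the
local center of curvature.  All downstream stress projections live in this
frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import Selection, Structure, Trajectory, normalize_atom_name

__all__ = [
    "BasePairTable",
    "Centerline",
    "DistanceSeries",
    "HBondSpec",
    "pair_bases",
    "compute_centerline",
    "zeta_coordinate",
    "min_distance_series",
    "hbond_series",
]


@dataclass
class BasePairTable:
    """Antiparallel pairing i <-> (L+1)-i between two chains of length L.

    Both chains are numbered 1..L in their own 5'->3' sense; the dyad of a
    187-bp nucleosomal duplex is then pair (94, 94) and every pair satisfies
    chain_a_residue + chain_b_residue = L + 1.
    """

    chain_a: str
    chain_b: str
    length: int
    entries: list[tuple[int, int, int]]  # (pair_index, resid_a, resid_b)

    def central_pair(self) -> tuple[int, int]:
        k = (self.length + 1) // 2
        return self.entries[k - 1][1], self.entries[k - 1][2]


def pair_bases(structure: Structure, chain_a: str, chain_b: str) -> BasePairTable:
    """Build the base-pair table for an antiparallel duplex.

    Residue i of ``chain_a`` pairs with residue L+1-i of ``chain_b`` (each
    chain numbered in its own 5'->3' sense).
    """
    resids_a = np.unique(structure.residue_numbers[structure.chain_ids == chain_a])
    resids_b = np.unique(structure.residue_numbers[structure.chain_ids == chain_b])
    if resids_a.size == 0 or resids_b.size == 0:
        raise ValueError(f"chains {chain_a!r}/{chain_b!r} not both present")
    if resids_a.size != resids_b.size:
        raise ValueError(
            f"chains {chain_a!r} and {chain_b!r} have unequal residue counts "
            f"({resids_a.size} vs {resids_b.size})")
    L = int(resids_a.size)
    set_b = set(int(r) for r in resids_b)
    entries = []
    for i, ra in enumerate(resids_a, start=1):
        rb = L + 1 - i
        if rb not in set_b:
            raise ValueError(f"chain {chain_b!r} missing residue {rb}")
        entries.append((i, int(ra), rb))
    return BasePairTable(chain_a, chain_b, L, entries)


@dataclass
class Centerline:
    """Neutral-axis points with orthonormal frames, arclength and curvature.

    Per point k: position ``points[k]`` (nm), unit tangent ``tangents[k]``,
    unit binormal ``binormals[k]`` toward the local curvature center, unit
    normal ``normals[k] = tau x b``, arclength ``arclength[k]`` (nm, strictly
    increasing) and curvature ``curvature[k]`` (nm^-1, >= 0).
    """

    points: np.ndarray
    tangents: np.ndarray
    binormals: np.ndarray
    normals: np.ndarray
    arclength: np.ndarray
    curvature: np.ndarray
    pair_indices: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        self.binormals = np.asarray(self.binormals, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        if self.pair_indices is None:
            self.pair_indices = np.arange(1, len(self.points) + 1)
        for name, v in (("tau", self.tangents), ("b", self.binormals),
                        ("n", self.normals)):
            norms = np.linalg.norm(v, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-8):
                raise ValueError(f"{name} vectors must be unit length")
        if np.any(np.abs(np.einsum("ij,ij->i", self.tangents,
                                   self.binormals)) > 1e-6):
            raise ValueError("tau and b must be orthogonal")
        if np.any(self.curvature < 0):
            raise ValueError("curvature must be >= 0")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        cols = {"pair_index": self.pair_indices, "s": self.arclength,
                "kappa": self.curvature}
        for tag, arr in (("c", self.points), ("tau", self.tangents),
                         ("b", self.binormals), ("n", self.normals)):
            for j, ax in enumerate("xyz"):
                cols[f"{tag}{ax}"] = arr[:, j]
        return pd.DataFrame(cols)

    def to_tsv(self, path, smoothing_window: int | None = None) -> None:
        with open(path, "w") as fh:
            if smoothing_window is not None:
                fh.write(f"# smoothing_window={smoothing_window}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the ends."""
    half = window // 2
    out = np.empty_like(points)
    n = len(points)
    for k in range(n):
        h = min(half, k, n - 1 - k)
        out[k] = points[k - h:k + h + 1].mean(axis=0)
    return out


def _orthonormalize(v: np.ndarray, tau: np.ndarray) -> np.ndarray:
    v = v - np.dot(v, tau) * tau
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        raise ValueError("degenerate frame vector")
    return v / nrm


def compute_centerline(structure: Structure, bp_table: BasePairTable,
                       coords: np.ndarray | None = None,
                       smoothing_window: int = 5,
                       kappa_min: float = 1e-3) -> Centerline:
    """Trace the duplex neutral axis from per-pair P-atom midpoints.

    Control points are the midpoints between the two backbone P atoms of each
    base pair (pairs whose 5'-terminal residue lacks a P are dropped with a
    warning), smoothed by a centered moving average of width
    ``smoothing_window``.  Tangents come from centered finite differences of
    the smoothed points; curvature and the curvature-center direction from
    second differences; b is the unit component of the second difference
    orthogonal to tau, and n = tau x b completes a right-handed frame.  Where
    curvature falls below ``kappa_min`` (nm^-1) the frame is parallel-
    transported from the nearest well-defined point.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    if coords is None:
        coords = structure.positions
    coords = np.asarray(coords, dtype=float)

    index = {}
    names = structure.names
    chains = structure.chain_ids
    resids = structure.residue_numbers
    p_mask = names == "P"
    for i in np.flatnonzero(p_mask):
        index[(chains[i], int(resids[i]))] = i

    controls, pair_idx = [], []
    for k, ra, rb in bp_table.entries:
        ia = index.get((bp_table.chain_a, ra))
        ib = index.get((bp_table.chain_b, rb))
        if ia is None or ib is None:
            warnings.warn(
                f"pair {k} ({bp_table.chain_a}{ra}/{bp_table.chain_b}{rb}) "
                "lacks a P atom; dropped from centerline")
            continue
        controls.append(0.5 * (coords[ia] + coords[ib]))
        pair_idx.append(k)
    controls = np.asarray(controls)
    if len(controls) < smoothing_window + 2:
        raise ValueError(
            f"need at least smoothing_window+2 = {smoothing_window + 2} pairs "
            f"with P atoms, got {len(controls)}")

    c = _moving_average(controls, smoothing_window)
    n_pts = len(c)

    # first differences -> tangents
    d1 = np.empty_like(c)
    d1[1:-1] = c[2:] - c[:-2]
    d1[0] = c[1] - c[0]
    d1[-1] = c[-1] - c[-2]
    tau = d1 / np.linalg.norm(d1, axis=1, keepdims=True)

    # second differences -> curvature vector
    a = np.zeros_like(c)
    a[1:-1] = c[2:] - 2.0 * c[1:-1] + c[:-2]
    a[0] = a[1]
    a[-1] = a[-2]

    steps = np.linalg.norm(np.diff(c, axis=0), axis=1)
    h = np.empty(n_pts)
    h[1:-1] = 0.5 * (steps[1:] + steps[:-1])
    h[0] = steps[0]
    h[-1] = steps[-1]

    a_perp = a - np.einsum("ij,ij->i", a, tau)[:, None] * tau
    kappa = np.linalg.norm(a_perp, axis=1) / h**2

    b = np.zeros_like(tau)
    defined = kappa >= kappa_min
    for k in np.flatnonzero(defined):
        b[k] = a_perp[k] / np.linalg.norm(a_perp[k])
    if not np.any(defined):
        # straight line: pick the axis least aligned with tau, same everywhere
        ref = np.eye(3)[np.argmin(np.abs(tau[0]))]
        for k in range(n_pts):
            b[k] = _orthonormalize(ref, tau[k])
    else:
        idx_def = np.flatnonzero(defined)
        for k in np.flatnonzero(~defined):
            nearest = idx_def[np.argmin(np.abs(idx_def - k))]
            b[k] = _orthonormalize(b[nearest], tau[k])

    n_vec = np.cross(tau, b)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    return Centerline(c, tau, b, n_vec, s, kappa,
                      pair_indices=np.asarray(pair_idx))


def zeta_coordinate(coords: np.ndarray, dsb_end: Selection,
                    histone_atoms: Selection,
                    superhelical_axis: np.ndarray) -> float:
    """Reaction coordinate zeta for DSB-end detachment (nm).

    The broken end's axis center is the unweighted mean position of the C4'
    and P atoms of the last two base pairs; zeta is its distance to the
    closest histone atom, measured in the plane perpendicular to the
    superhelical axis ("closest" minimizes that same in-plane distance).
    """
    if len(dsb_end) == 0 or len(histone_atoms) == 0:
        raise ValueError("zeta requires non-empty DSB-end and histone selections")
    axis = np.asarray(superhelical_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        axis = axis / nrm
    coords = np.asarray(coords, dtype=float)
    end_center = coords[dsb_end.indices].mean(axis=0)
    disp = end_center - coords[histone_atoms.indices]
    perp = disp - np.outer(disp @ axis, axis)
    return float(np.min(np.linalg.norm(perp, axis=1)))


@dataclass
class DistanceSeries:
    """A labelled per-frame distance trace, reported in Angstrom."""

    label: str
    times: np.ndarray
    values: np.ndarray
    cutoff: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be >= 0")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def rms_fluctuation(self) -> float:
        return float(self.values.std())

    def fraction_below(self, cutoff: float | None = None) -> float:
        cutoff = self.cutoff if cutoff is None else cutoff
        if cutoff is None:
            raise ValueError("no cutoff given")
        return float(np.mean(self.values <= cutoff))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label={self.label}")
            if self.cutoff is not None:
                fh.write(f" cutoff_A={self.cutoff}")
            fh.write("\n")
            pd.DataFrame({"time_ps": self.times, "distance_A": self.values}
                         ).to_csv(fh, sep="\t", index=False)


def min_distance_series(trajectory: Trajectory, probes: Selection,
                        target: Selection) -> list[DistanceSeries]:
    """Per probe atom, the per-frame minimum distance (A) to any target atom.

    Mirrors contact-detachment traces such as the distance of backbone P atoms
    from the histone core surface.
    """
    if len(probes) == 0:
        raise ValueError("empty probe selection")
    if len(target) == 0:
        raise ValueError("empty target selection")
    s = trajectory.structure
    F = trajectory.n_frames
    values = np.empty((F, len(probes)))
    for f in range(F):
        d = cdist(trajectory.frames[f, probes.indices],
                  trajectory.frames[f, target.indices])
        values[f] = d.min(axis=1)
    out = []
    for j, idx in enumerate(probes.indices):
        label = f"{s.chain_ids[idx]}:{s.names[idx]}{s.residue_numbers[idx]}"
        out.append(DistanceSeries(label, trajectory.times, values[:, j] * 10.0))
    return out


@dataclass
class HBondSpec:
    """Heavy-atom donor/acceptor pair addressed by (chain, resid, atom name)."""

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    label: str = ""

    def resolve(self, structure: Structure) -> tuple[int, int]:
        try:
            i = structure.find_atom(*self.donor)
            j = structure.find_atom(*self.acceptor)
        except KeyError as exc:
            raise ValueError(
                f"H-bond spec {self.label or self.donor}: {exc}") from exc
        return i, j


def hbond_series(trajectory: Trajectory, specs: list[HBondSpec],
                 cutoff: float = 2.1) -> list[DistanceSeries]:
    """Per-frame heavy-atom donor-acceptor distances (A) for each spec.

    No hydrogen geometry is used: the reported length is the donor-acceptor
    heavy-atom distance, with ``cutoff`` (A, default 2.1, the upper reference
    H-bond distance at 350 K) used for the bound fraction summary.
    """
    out = []
    for spec in specs:
        i, j = spec.resolve(trajectory.structure)
        d = np.linalg.norm(trajectory.frames[:, i] - trajectory.frames[:, j],
                           axis=1) * 10.0
        label = spec.label or (f"{spec.donor[0]}{spec.donor[1]}:{spec.donor[2]}"
                               f"-{spec.acceptor[0]}{spec.acceptor[1]}:"
                               f"{spec.acceptor[2]}")
        out.append(DistanceSeries(label, trajectory.times, d, cutoff=cutoff))
    return out
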