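"""Synthetic fixtures with analytic ground truth for every pipeline stage.

Generates (i) a coarse nucleosome-like 187-bp DNA duplex: 147 bp wrapped
left-handed on a superhelix (~8 nm diameter, nearly two turns) plus 20-bp
straight d(AGTC)-repeat linkers at each end, with a pseudo-histone core for
contact/zeta tests; (ii) double-strand-break (DSB) annotations at the four
canonical sites M1-M4 (cuts spaced 1 bp around a central A...T pair);
(iii) Gaussian positional ensembles with planted covariance modes;
(iv) analytic bent-rod stress fields with the compression-positive sign
convention; and (v) umbrella-window samples drawn exactly from a known PMF.

Every generator is seeded and reproducible; ground truth (centerline,
eigensystem, stress slope, PMF) is returned alongside the data so downstream
estimators can be validated against closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import ATOMIC_MASSES, kbt_kcal_mol
from .geometry import BasePairTable, Centerline, pair_bases
from .structures import Atom, GridTensorField, Structure, Trajectory
from .wham import KJ_TO_KCAL, UmbrellaWindow

__all__ = [
    "SuperhelixSpec",
    "DSBSite",
    "DSB_SITES",
    "PlantedModes",
    "BentRodFieldSpec",
    "UmbrellaTruthSpec",
    "build_superhelix",
    "insert_dsb",
    "gaussian_ensemble",
    "rigid_body_subspace",
    "planted_internal_modes",
    "bent_rod_field",
    "sample_umbrella",
    "double_well_potential",
    "harmonic_potential",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
PURINES = {"A", "G"}

# chain-a base identities printed for the cut sites (linkers fix the rest)
_SEQ_OVERRIDES = {21: "A", 22: "T", 67: "C", 68: "T", 69: "C",
                  73: "C", 74: "A", 75: "A", 94: "A", 95: "T"}


@dataclass
class SuperhelixSpec:
    """Geometry of the synthetic nucleosome-like duplex.

    Defaults: 147 bp wrapped at superhelix radius 4.18 nm / pitch 2.39 nm
    (diameter ~8 nm, ~1.9 turns), helical rise 0.34 nm/bp, 10.4 bp per
    double-helical turn, 20-bp d(AGTC) linkers on each end.
    """

    n_bp_total: int = 187
    wrapped_bp: int = 147
    linker_bp: int = 20
    linker_repeat: str = "AGTC"
    superhelix_radius: float = 4.18
    superhelix_pitch: float = 2.39
    rise: float = 0.34
    bp_per_turn: float = 10.4
    backbone_radius: float = 0.90
    core_radius: float = 3.0
    core_atoms: int = 200
    chain_a: str = "I"
    chain_b: str = "J"
    seed: int = 0

    def __post_init__(self):
        if self.n_bp_total != self.wrapped_bp + 2 * self.linker_bp:
            raise ValueError("n_bp_total must equal wrapped_bp + 2*linker_bp")
        for name in ("superhelix_radius", "superhelix_pitch", "rise",
                     "bp_per_turn", "backbone_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.superhelix_pitch >= 2 * math.pi * self.superhelix_radius:
            raise ValueError(
                "superhelix pitch exceeds the turn circumference: the wrapped "
                "path cannot close around the core at this rise")

    @property
    def curvature(self) -> float:
        """Analytic helix curvature R / (R^2 + (p/2pi)^2), nm^-1."""
        c = self.superhelix_pitch / (2 * math.pi)
        return self.superhelix_radius / (self.superhelix_radius**2 + c**2)

    @property
    def wrapped_turns(self) -> float:
        c = self.superhelix_pitch / (2 * math.pi)
        L = math.hypot(self.superhelix_radius, c)
        return (self.wrapped_bp - 1) * self.rise / L / (2 * math.pi)

    @property
    def helical_twists(self) -> float:
        """Double-helical twists of the wrapped region (~14 for defaults)."""
        return self.wrapped_bp / self.bp_per_turn


def _chain_a_sequence(spec: SuperhelixSpec) -> dict[int, str]:
    seq = {}
    rep = spec.linker_repeat
    for i in range(1, spec.n_bp_total + 1):
        if i <= spec.linker_bp or i > spec.n_bp_total - spec.linker_bp:
            seq[i] = rep[(i - 1) % len(rep)]
        else:
            seq[i] = "GATC"[(i - 1) % 4]
    seq.update({k: v for k, v in _SEQ_OVERRIDES.items()
                if spec.linker_bp < k <= spec.n_bp_total - spec.linker_bp})
    return seq


def _bp_frames(spec: SuperhelixSpec):
    """Analytic centerline point and {tau, b} frame at every bp position."""
    R = spec.superhelix_radius
    c = spec.superhelix_pitch / (2 * math.pi)
    L = math.hypot(R, c)
    n = spec.n_bp_total
    first_w = spec.linker_bp + 1
    last_w = n - spec.linker_bp

    points = np.empty((n, 3))
    taus = np.empty((n, 3))
    bs = np.empty((n, 3))
    kappas = np.zeros(n)

    def helix(phi):
        # left-handed: z decreases as phi advances
        p = np.array([R * math.cos(phi), R * math.sin(phi), -c * phi])
        t = np.array([-R * math.sin(phi), R * math.cos(phi), -c]) / L
        b = np.array([-math.cos(phi), -math.sin(phi), 0.0])
        return p, t, b

    for i in range(first_w, last_w + 1):
        s = (i - first_w) * spec.rise
        p, t, b = helix(s / L)
        points[i - 1], taus[i - 1], bs[i - 1] = p, t, b
        kappas[i - 1] = spec.curvature
    p0, t0, b0 = points[first_w - 1], taus[first_w - 1], bs[first_w - 1]
    for i in range(1, first_w):
        points[i - 1] = p0 - (first_w - i) * spec.rise * t0
        taus[i - 1], bs[i - 1] = t0, b0
    p1, t1, b1 = points[last_w - 1], taus[last_w - 1], bs[last_w - 1]
    for i in range(last_w + 1, n + 1):
        points[i - 1] = p1 + (i - last_w) * spec.rise * t1
        taus[i - 1], bs[i - 1] = t1, b1
    return points, taus, bs, kappas


def _base_atoms(base: str) -> list[tuple[str, str, float, float]]:
    """(name, element, radius nm, angular offset rad) of base pseudo-atoms."""
    if base in PURINES:
        return [("N1", "N", 0.15, -0.9)]
    return [("O1", "O", 0.14, -0.9), ("O2", "O", 0.25, -1.3)]


def build_superhelix(spec: SuperhelixSpec | None = None
                     ) -> tuple[Structure, BasePairTable, Centerline]:
    """Build the coarse superhelical duplex plus pseudo-histone core.

    Each nucleotide carries P (absent on the 5'-terminal residue of each
    chain), C4', C1' and base H-bond donor/acceptor pseudo-atoms; the two
    strands' P atoms sit diametrically opposite so the per-bp P midpoint lies
    exactly on the analytic centerline, which is returned as ground truth.
    """
    spec = spec or SuperhelixSpec()
    points, taus, bs, kappas = _bp_frames(spec)
    ns = np.cross(taus, bs)
    seq_a = _chain_a_sequence(spec)
    n = spec.n_bp_total

    atoms: list[Atom] = []
    serial = 0

    def add(name, element, chain, resid, resname, pos):
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial, name, element, resname, resid, chain,
                          ATOMIC_MASSES[element], pos))

    def u(i, offset):
        theta = 2 * math.pi * (i - 1) / spec.bp_per_turn + offset
        return math.cos(theta) * bs[i - 1] + math.sin(theta) * ns[i - 1]

    def place_strand(chain, mirror):
        """mirror=+1 for chain a, -1 for the antiparallel partner."""
        for resid in range(1, n + 1):
            i = resid if mirror > 0 else n + 1 - resid  # bp position
            base = seq_a[i] if mirror > 0 else COMPLEMENT[seq_a[i]]
            resname = RESNAME[base]
            c = points[i - 1]
            if resid > 1:  # 5'-terminal residue has no phosphate
                add("P", "P", chain, resid, resname,
                    c + mirror * spec.backbone_radius * u(i, 0.0))
            add("C4'", "C", chain, resid, resname,
                c + mirror * 0.75 * u(i, -0.25))
            add("C1'", "C", chain, resid, resname,
                c + mirror * 0.60 * u(i, -0.50))
            for name, element, radius, offset in _base_atoms(base):
                add(name, element, chain, resid, resname,
                    c + mirror * radius * u(i, offset))

    place_strand(spec.chain_a, +1)
    place_strand(spec.chain_b, -1)

    # pseudo-histone core: deterministic Fibonacci sphere shell inside the wrap
    first_w, last_w = spec.linker_bp + 1, n - spec.linker_bp
    center = np.array([0.0, 0.0,
                       0.5 * (points[first_w - 1, 2] + points[last_w - 1, 2])])
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for k in range(spec.core_atoms):
        z = 1.0 - 2.0 * (k + 0.5) / spec.core_atoms
        r = math.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * k
        pos = center + spec.core_radius * np.array(
            [r * math.cos(phi), r * math.sin(phi), z])
        add("CA", "C", "A", k + 1, "COR", pos)

    structure = Structure(atoms, title="synthetic superhelical nucleosome")
    for chain in (spec.chain_a, spec.chain_b):
        for resid in range(1, n):
            structure.backbone_bonds.append(
                ((chain, resid), (chain, resid + 1)))
    structure.metadata["superhelical_axis"] = np.array([0.0, 0.0, 1.0])
    structure.metadata["spec"] = spec

    # left-handedness check: axial advance opposes the angular sweep
    dz = points[last_w - 1, 2] - points[first_w - 1, 2]
    if dz >= 0:
        raise AssertionError("generated superhelix is not left-handed")

    bp_table = pair_bases(structure, spec.chain_a, spec.chain_b)
    s = np.arange(n, dtype=float) * spec.rise
    truth = Centerline(points, taus, bs, ns, s, kappas,
                       pair_indices=np.arange(1, n + 1))
    return structure, bp_table, truth


# ---------------------------------------------------------------------------
# DSB sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSBSite:
    """A double-strand break: two backbone cuts spaced 1 bp, A...T center.

    ``cut_a``/``cut_b`` give (chain key, resid i, resid i+1) meaning the
    backbone is severed between those residues.  ``ambiguous`` marks the
    dyad site whose printed central pair conflicts with the pairing rule.
    """

    label: str
    cut_a: tuple[str, int, int]
    cut_b: tuple[str, int, int]
    central_pair: tuple[int, int]
    ambiguous: bool = False


DSB_SITES = {
    "M1": DSBSite("M1", ("a", 68, 69), ("b", 120, 121), (68, 120)),
    "M2": DSBSite("M2", ("a", 73, 74), ("b", 113, 114), (74, 114)),
    "M3": DSBSite("M3", ("a", 94, 95), ("b", 94, 95), (94, 94), ambiguous=True),
    "M4": DSBSite("M4", ("a", 21, 22), ("b", 167, 168), (21, 167)),
}


def insert_dsb(structure: Structure, site: DSBSite | str,
               chain_a: str = "I", chain_b: str = "J") -> Structure:
    """Annotate a DSB: remove the two cut backbone bonds, record terminations.

    The backbone connectivity list loses exactly two entries; 5'-OH and
    3'-phosphate terminations and the central pair are recorded in metadata.
    """
    if isinstance(site, str):
        try:
            site = DSB_SITES[site]
        except KeyError:
            raise ValueError(f"unknown DSB site label {site!r}") from None
    chains = {"a": chain_a, "b": chain_b}
    out = structure.with_positions(structure.positions)
    for key, lo, hi in (site.cut_a, site.cut_b):
        chain = chains[key]
        bond = ((chain, lo), (chain, hi))
        if bond not in out.backbone_bonds:
            raise ValueError(f"cut site {bond} not present in backbone")
        out.backbone_bonds.remove(bond)
    out.metadata["dsb"] = {
        "label": site.label,
        "cuts": [(chains[site.cut_a[0]], site.cut_a[1], site.cut_a[2]),
                 (chains[site.cut_b[0]], site.cut_b[1], site.cut_b[2])],
        "central_pair": site.central_pair,
        "central_pair_ambiguous": site.ambiguous,
        "terminations": {"5prime": "OH", "3prime": "phosphate"},
    }
    return out


# ---------------------------------------------------------------------------
# Planted-covariance Gaussian ensembles
# ---------------------------------------------------------------------------

@dataclass
class PlantedModes:
    """Orthonormal 3N-vectors with planted eigenvalues (nm^2) plus a noise floor."""

    eigenvalues: np.ndarray
    vectors: np.ndarray  # k x 3N, rows orthonormal
    noise_floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != self.eigenvalues.size:
            raise ValueError("one vector per eigenvalue required")
        G = self.vectors @ self.vectors.T
        if not np.allclose(G, np.eye(len(G)), atol=1e-8):
            raise ValueError("planted mode vectors must be orthonormal")
        if self.noise_floor < 0 or np.any(self.eigenvalues < self.noise_floor):
            raise ValueError("eigenvalues must be >= noise floor >= 0")


def rigid_body_subspace(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3N) of rigid translations/rotations at ``reference``.

    Internal (vibrational) modes of a molecule are orthogonal to this
    subspace; planted modes meant to survive least-squares superposition
    should be drawn from its complement.
    """
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    centered = reference - reference.mean(axis=0)
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        vecs.append(t.ravel())
    for ax in np.eye(3):
        vecs.append(np.cross(ax, centered).ravel())
    basis, _ = np.linalg.qr(np.stack(vecs, axis=1))
    return basis.T


def planted_internal_modes(reference: np.ndarray, eigenvalues,
                           seed: int = 0, noise_floor: float = 0.0
                           ) -> PlantedModes:
    """Random orthonormal planted modes orthogonal to rigid-body motions."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    dim = 3 * np.asarray(reference).shape[0]
    rigid = rigid_body_subspace(reference)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((dim, eigenvalues.size))
    raw -= rigid.T @ (rigid @ raw)
    basis, _ = np.linalg.qr(raw)
    return PlantedModes(eigenvalues, basis.T, noise_floor=noise_floor,
                        seed=seed)


def gaussian_ensemble(reference: np.ndarray, modes: PlantedModes,
                      n_frames: int, seed: int | None = None,
                      structure: Structure | None = None,
                      dt: float = 40.0) -> Trajectory:
    """Draw frames = ref + sum_k sqrt(lambda_k) z_k v_k + isotropic noise.

    z_k are i.i.d. standard normals; reproducible by seed.  If no Structure
    is given, a minimal all-carbon one is synthesized for the N positions.
    """
    reference = np.asarray(reference, dtype=float)
    n_atoms = reference.shape[0]
    dim = 3 * n_atoms
    if modes.vectors.shape[1] != dim:
        raise ValueError("mode vectors must have length 3N")
    rng = np.random.default_rng(modes.seed if seed is None else seed)
    z = rng.standard_normal((n_frames, modes.eigenvalues.size))
    disp = (z * np.sqrt(modes.eigenvalues)) @ modes.vectors
    if modes.noise_floor > 0:
        disp = disp + math.sqrt(modes.noise_floor) * rng.standard_normal(
            (n_frames, dim))
    frames = reference[None, :, :] + disp.reshape(n_frames, n_atoms, 3)
    if structure is None:
        structure = Structure(
            [Atom(i + 1, "CA", "C", "GLY", i + 1, "A",
                  ATOMIC_MASSES["C"], reference[i]) for i in range(n_atoms)],
            title="planted Gaussian ensemble")
    times = np.arange(n_frames, dtype=float) * dt
    return Trajectory(structure, frames, times)


# ---------------------------------------------------------------------------
# Bent-rod stress fields
# ---------------------------------------------------------------------------

@dataclass
class BentRodFieldSpec:
    """Euler-Bernoulli bent-rod stress: axial A*d (compression-positive on the
    curvature-center side, d = (x-c).b) plus optional circumferential shear G."""

    bending_amplitude: float = 10.0  # MPa/nm
    torsion_amplitude: float = 0.0   # MPa
    tube_radius: float = 1.0
    sign_convention: str = "paper"

    def __post_init__(self):
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be > 0")
        if not np.isfinite([self.bending_amplitude, self.torsion_amplitude]).all():
            raise ValueError("amplitudes must be finite")


def bent_rod_field(spec: BentRodFieldSpec, centerline: Centerline,
                   origin, spacing, dims) -> GridTensorField:
    """Analytic bent-rod stress field on a regular grid.

    Inside the tube: sigma = A*d * (tau x tau outer) + G * (tau (x) theta_hat
    + theta_hat (x) tau), with d the signed distance toward the curvature
    center and theta_hat = tau x r_hat the circumferential direction; zero
    outside.  Tensors are symmetric by construction, and the paper-convention
    sign (compression on the inner half positive) is baked in.
    """
    from scipy.spatial import cKDTree

    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    dims = tuple(int(d) for d in dims)
    lo = origin - 0.5 * spacing
    hi = origin + spacing * (np.asarray(dims) - 0.5)
    if np.any(centerline.points < lo) or np.any(centerline.points > hi):
        raise ValueError("centerline exits the requested grid")

    axes = [origin[i] + spacing[i] * np.arange(dims[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    tree = cKDTree(centerline.points)
    _, nearest = tree.query(centers)
    c = centerline.points[nearest]
    tau = centerline.tangents[nearest]
    b = centerline.binormals[nearest]
    rel = centers - c
    axial = np.einsum("vi,vi->v", rel, tau)
    perp = rel - axial[:, None] * tau
    rperp = np.linalg.norm(perp, axis=1)
    inside = rperp <= spec.tube_radius

    comps = np.zeros((centers.shape[0], 3, 3))
    idx = np.flatnonzero(inside)
    if idx.size:
        d = np.einsum("vi,vi->v", perp[idx], b[idx])
        tt = np.einsum("vi,vj->vij", tau[idx], tau[idx])
        comps[idx] = spec.bending_amplitude * d[:, None, None] * tt
        if spec.torsion_amplitude != 0.0:
            safe = np.where(rperp[idx][:, None] > 1e-12, rperp[idx][:, None], 1.0)
            rhat = perp[idx] / safe
            theta = np.cross(tau[idx], rhat)
            shear = (np.einsum("vi,vj->vij", tau[idx], theta)
                     + np.einsum("vi,vj->vij", theta, tau[idx]))
            comps[idx] += spec.torsion_amplitude * shear
    return GridTensorField(origin, spacing, dims,
                           comps.reshape(*dims, 3, 3))


# ---------------------------------------------------------------------------
# Umbrella sampling from a known PMF
# ---------------------------------------------------------------------------

def harmonic_potential(kappa_kj: float) -> Callable[[np.ndarray], np.ndarray]:
    """A(z) = (1/2) kappa z^2, kappa in kJ mol^-1 nm^-2, returned in kcal/mol."""
    def A(z):
        return 0.5 * kappa_kj * KJ_TO_KCAL * np.asarray(z) ** 2
    return A


def double_well_potential(barrier_kcal: float, z_a: float, z_b: float
                          ) -> Callable[[np.ndarray], np.ndarray]:
    """Symmetric quartic double well: minima at z_a/z_b (A=0), barrier at the
    midpoint (A=barrier_kcal)."""
    m = 0.5 * (z_a + z_b)
    w = 0.5 * (z_b - z_a)

    def A(z):
        u = (np.asarray(z, dtype=float) - m) / w
        return barrier_kcal * (1.0 - u**2) ** 2
    return A


@dataclass
class UmbrellaTruthSpec:
    """A known PMF plus a ladder of harmonic windows to sample from it.

    ``potential`` maps zeta (nm) to kcal/mol; ``windows`` are (center nm,
    spring k in kJ mol^-1 nm^-2) pairs spanning ``support``.
    """

    potential: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]
    windows: Sequence[tuple[float, float]]
    samples_per_window: int = 10000
    temperature: float = 310.0
    seed: int = 0
    grid_points: int = 4001

    def __post_init__(self):
        if not self.windows:
            raise ValueError("at least one window required")
        if self.samples_per_window <= 0:
            raise ValueError("samples_per_window must be > 0")
        lo, hi = self.support
        centers = [c for c, _ in self.windows]
        if min(centers) < lo or max(centers) > hi:
            raise ValueError("window centers must lie within the support")


def sample_umbrella(truth: UmbrellaTruthSpec) -> list[UmbrellaWindow]:
    """Exact inverse-CDF sampling of each biased density on a fine grid.

    Window i draws from p_i(z) proportional to
    exp(-[A(z) + (1/2) k_i (z - z0_i)^2] / k_B T); seed-reproducible (window
    i uses seed + i).
    """
    kbt = kbt_kcal_mol(truth.temperature)
    z = np.linspace(*truth.support, truth.grid_points)
    A = np.asarray(truth.potential(z), dtype=float)
    out = []
    for i, (center, k) in enumerate(truth.windows):
        energy = A + 0.5 * k * KJ_TO_KCAL * (z - center) ** 2
        logp = -(energy - energy.min()) / kbt
        p = np.exp(logp)
        norm = np.trapezoid(p, z)
        if not np.isfinite(norm) or norm <= 0:
            raise ValueError(f"window {i}: unnormalizable biased density")
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (p[1:] + p[:-1]) * np.diff(z))]) / norm
        cdf[-1] = 1.0
        rng = np.random.default_rng(truth.seed + i)
        u = rng.random(truth.samples_per_window)
        samples = np.interp(u, cdf, z)
        out.append(UmbrellaWindow(center=center, spring_k=k, samples=samples,
                                  temperature=truth.temperature))
    return out
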