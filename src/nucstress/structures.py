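"""Molecular structures, trajectories, tensor fields and atom selection.

Containers are plain dataclasses holding numpy arrays; PDB parsing and writing
is delegated to biotite, XTC/DCD trajectory reading to mdtraj.  Internal length
unit is nm throughout (PDB files are read/written in Angstrom and converted at
the boundary).

Stress-tensor fields arrive as nine scalar Gaussian-cube files, one per tensor
component in row-major order (sigma_xx, sigma_xy, ..., sigma_zz), the dialect
emitted by local-stress MD post-processors.  The cube dialect used here is
documented in :func:`write_tensor_grid`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .constants import ATOMIC_MASSES, KJ_MOL_NM3_TO_MPA

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "GridTensorField",
    "AtomTensorField",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_tensor_grid",
    "write_tensor_grid",
    "average_tensor_fields",
    "read_atom_tensors",
    "write_atom_tensors",
    "select",
]

CUBE_COMPONENTS = ("xx", "xy", "xz", "yx", "yy", "yz", "zx", "zy", "zz")


def normalize_atom_name(name: str) -> str:
    """Normalize prime dialects: ``C4*`` and ``C4′`` both become ``C4'``."""
    return name.strip().replace("*", "'").replace("′", "'")


def _element_from_name(name: str) -> str:
    m = re.match(r"[A-Za-z]+", name.strip())
    if not m:
        return ""
    lead = m.group(0)
    # two-letter elements that actually occur; otherwise first letter
    if lead[:2].upper() in {"CL", "NA", "MG", "MN", "FE", "ZN"}:
        return lead[:2].upper()
    return lead[0].upper()


@dataclass
class Atom:
    """A single atom record (position in nm, mass in amu)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    mass: float
    position: np.ndarray

    def __post_init__(self):
        self.name = normalize_atom_name(self.name)
        self.position = np.asarray(self.position, dtype=float)
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be > 0")


class Structure:
    """An ordered collection of atoms with an optional orthogonal box (nm)."""

    def __init__(self, atoms: Sequence[Atom], box: np.ndarray | None = None,
                 title: str = ""):
        self.atoms = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in Structure")
        if box is not None:
            box = np.asarray(box, dtype=float)
            if np.any(box <= 0):
                raise ValueError("box lengths must be > 0")
        self.box = box
        self.title = title
        # connectivity annotations between consecutive backbone residues,
        # as ((chain, resid_i), (chain, resid_j)) tuples; populated by the
        # synthetic generator and edited by DSB insertion
        self.backbone_bonds: list[tuple[tuple[str, int], tuple[str, int]]] = []
        self.metadata: dict = {}
        self._cache: dict[str, np.ndarray] = {}

    # -- cached column views ------------------------------------------------
    def _col(self, key: str, fn) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.asarray([fn(a) for a in self.atoms])
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """N x 3 coordinates, nm."""
        if "pos" not in self._cache:
            self._cache["pos"] = np.array([a.position for a in self.atoms], dtype=float)
        return self._cache["pos"]

    @property
    def names(self) -> np.ndarray:
        return self._col("names", lambda a: a.name)

    @property
    def elements(self) -> np.ndarray:
        return self._col("elements", lambda a: a.element)

    @property
    def chain_ids(self) -> np.ndarray:
        return self._col("chains", lambda a: a.chain_id)

    @property
    def residue_numbers(self) -> np.ndarray:
        return self._col("resids", lambda a: a.residue_number)

    @property
    def residue_names(self) -> np.ndarray:
        return self._col("resnames", lambda a: a.residue_name)

    @property
    def masses(self) -> np.ndarray:
        return self._col("masses", lambda a: a.mass)

    def find_atom(self, chain_id: str, residue_number: int, name: str) -> int:
        """Index of a uniquely addressed atom; raises KeyError if absent."""
        name = normalize_atom_name(name)
        hits = np.flatnonzero(
            (self.chain_ids == chain_id)
            & (self.residue_numbers == residue_number)
            & (self.names == name)
        )
        if hits.size == 0:
            raise KeyError(f"no atom {chain_id}/{residue_number}/{name}")
        return int(hits[0])

    def with_positions(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        out = Structure(atoms, box=self.box, title=self.title)
        out.backbone_bonds = list(self.backbone_bonds)
        out.metadata = dict(self.metadata)
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames (F x N x 3, nm) over a fixed atom set."""

    structure: Structure
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be F x N x 3")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError("frame atom count does not match structure")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("one time per frame required")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Selection:
    """Ordered unique atom indices into a Structure."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size != np.unique(self.indices).size:
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return self.indices.size


# ---------------------------------------------------------------------------
# PDB structures and trajectories (via biotite / mdtraj)
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr, title: str = "") -> Structure:
    import biotite.structure as struc

    n = arr.array_length()
    try:
        serials = arr.get_annotation("atom_id")
    except (KeyError, ValueError):
        serials = np.arange(1, n + 1)
    atoms = []
    for i in range(n):
        name = normalize_atom_name(str(arr.atom_name[i]))
        element = str(arr.element[i]).strip().upper()
        if not element:
            element = _element_from_name(name)
            warnings.warn(
                f"atom serial {serials[i]}: missing element, inferred '{element}' "
                f"from name '{name}'"
            )
        mass = ATOMIC_MASSES.get(element)
        if mass is None:
            mass = 12.011
            warnings.warn(f"unknown element '{element}', using carbon mass")
        atoms.append(Atom(
            serial=int(serials[i]),
            name=name,
            element=element,
            residue_name=str(arr.res_name[i]).strip(),
            residue_number=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]).strip() or "A",
            mass=mass,
            position=arr.coord[i] / 10.0,  # A -> nm
        ))
    box = None
    if arr.box is not None:
        b = np.asarray(arr.box)
        diag = np.diag(b) / 10.0
        if np.all(diag > 0):
            box = diag
    return Structure(atoms, box=box, title=title)


def read_structure(path, fmt: str = "pdb") -> Structure:
    """Read a molecular structure from a PDB file (coordinates A -> nm)."""
    if fmt.lower() != "pdb":
        raise ValueError(f"unsupported structure format: {fmt}")
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises on malformed records
        raise ValueError(f"failed to parse PDB {path}: {exc}") from exc
    return _structure_from_atom_array(arr, title=path.stem)


def _atom_array_from_structure(structure: Structure):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.positions * 10.0  # nm -> A
    arr.chain_id = structure.chain_ids
    arr.res_id = structure.residue_numbers
    arr.res_name = structure.residue_names
    arr.atom_name = structure.names
    arr.element = structure.elements
    arr.set_annotation("atom_id", np.asarray([a.serial for a in structure.atoms]))
    arr.hetero = np.zeros(n, dtype=bool)
    if structure.box is not None:
        arr.box = np.diag(structure.box * 10.0)
    return arr


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as PDB (nm -> A)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(structure))
    pdb.write(str(path))


def read_trajectory(path, topology=None, dt: float = 40.0) -> Trajectory:
    """Read a trajectory.

    Multi-model PDB files are read with biotite; XTC/DCD files with mdtraj
    (``topology`` then names a PDB file).  ``dt`` (ps) sets the frame spacing
    when the format carries no time information.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(extra_fields=["atom_id"])
        first = stack[0] if stack.stack_depth() > 0 else None
        if first is None:
            raise ValueError(f"{path}: no models")
        structure = _structure_from_atom_array(first, title=path.stem)
        frames = np.asarray(stack.coord) / 10.0
        times = np.arange(frames.shape[0], dtype=float) * dt
        return Trajectory(structure, frames, times)
    if suffix in {".xtc", ".dcd"}:
        import mdtraj

        if topology is None:
            raise ValueError("XTC/DCD trajectories require a PDB topology file")
        traj = mdtraj.load(str(path), top=str(topology))
        structure = read_structure(topology)
        times = np.asarray(traj.time, dtype=float)
        if times.size > 1 and np.all(np.diff(times) <= 0):
            times = np.arange(traj.n_frames, dtype=float) * dt
        return Trajectory(structure, np.asarray(traj.xyz, dtype=float), times)
    raise ValueError(f"unsupported trajectory format: {suffix}")


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    template = _atom_array_from_structure(trajectory.structure)
    stack = struc.stack([template] * trajectory.n_frames)
    stack.coord = trajectory.frames * 10.0
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Tensor fields
# ---------------------------------------------------------------------------

class GridTensorField:
    """3x3 symmetric stress tensors (MPa) on a regular spatial grid (nm).

    ``components`` has shape (nx, ny, nz, 3, 3).
    """

    def __init__(self, origin, spacing, dims, components,
                 symmetry_tol: float = 1e-6):
        self.origin = np.asarray(origin, dtype=float)
        self.spacing = np.asarray(spacing, dtype=float)
        self.dims = tuple(int(d) for d in dims)
        self.components = np.asarray(components, dtype=float)
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must each be >= 1")
        if self.components.shape != (*self.dims, 3, 3):
            raise ValueError("components must have shape dims + (3, 3)")
        self._interp = None
        self.check_symmetry(symmetry_tol)

    def check_symmetry(self, tol_rel: float = 1e-6) -> float:
        """Warn if max |s_ij - s_ji| exceeds ``tol_rel`` * max |s|."""
        asym = np.max(np.abs(self.components - np.swapaxes(self.components, -1, -2)))
        scale = max(np.max(np.abs(self.components)), 1e-300)
        if asym > tol_rel * scale:
            warnings.warn(
                f"tensor field asymmetry: max |s_ij - s_ji| = {asym:.3e} "
                f"(tolerance {tol_rel:.1e} of max |s| = {scale:.3e})"
            )
        return float(asym)

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i])
            for i in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center coordinates, shape (nx*ny*nz, 3)."""
        ax, ay, az = self.axes
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def tensors_flat(self) -> np.ndarray:
        """Voxel tensors in the same order as :meth:`voxel_centers`."""
        return self.components.reshape(-1, 3, 3)

    def tensor_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated tensor(s) at ``points`` (nm).

        Raises ValueError for points outside the grid.
        """
        if self._interp is None:
            vals = self.components.reshape(*self.dims, 9)
            self._interp = RegularGridInterpolator(
                self.axes, vals, bounds_error=True)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        try:
            out = self._interp(pts).reshape(-1, 3, 3)
        except ValueError as exc:
            raise ValueError(f"point outside tensor grid: {exc}") from exc
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def same_grid(self, other: "GridTensorField") -> bool:
        return (self.dims == other.dims
                and np.array_equal(self.origin, other.origin)
                and np.array_equal(self.spacing, other.spacing))


@dataclass
class AtomTensorField:
    """Per-atom 3x3 stress tensors (MPa) with per-atom volumes (nm^3)."""

    serials: np.ndarray
    tensors: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        self.serials = np.asarray(self.serials, dtype=int)
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.volumes <= 0):
            raise ValueError("atomic volumes must be > 0")
        if self.tensors.shape != (self.serials.size, 3, 3):
            raise ValueError("tensors must be N x 3 x 3")


def _write_cube(path, comment1: str, comment2: str, origin, spacing, dims,
                values: np.ndarray) -> None:
    nx, ny, nz = dims
    with open(path, "w") as fh:
        fh.write(comment1.rstrip("\n") + "\n")
        fh.write(comment2.rstrip("\n") + "\n")
        fh.write(f"{0:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {spacing[0]:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {spacing[1]:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {spacing[2]:12.6f}\n")
        flat = values.reshape(nx, ny, nz)
        for ix in range(nx):
            for iy in range(ny):
                row = flat[ix, iy, :]
                for start in range(0, nz, 6):
                    chunk = row[start:start + 6]
                    fh.write(" ".join(f"{v: .6e}" for v in chunk) + "\n")


def _read_cube(path):
    with open(path) as fh:
        comment1 = fh.readline()
        comment2 = fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]])
        dims = []
        spacing = []
        for i in range(3):
            parts = fh.readline().split()
            dims.append(int(parts[0]))
            vec = np.array([float(x) for x in parts[1:4]])
            if abs(vec[i]) < max(abs(vec[(i + 1) % 3]), abs(vec[(i + 2) % 3])):
                raise ValueError(f"{path}: non-axis-aligned cube grid not supported")
            spacing.append(vec[i])
        for _ in range(abs(natoms)):
            fh.readline()
        data = np.array(fh.read().split(), dtype=float)
    nx, ny, nz = dims
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: expected {nx*ny*nz} values, got {data.size}")
    values = data.reshape(nx, ny, nz)
    header = comment1 + comment2
    return origin, np.array(spacing), tuple(dims), values, header


def write_tensor_grid(field: GridTensorField, directory, prefix: str = "stress",
                      units: str = "MPa") -> list[Path]:
    """Write nine scalar cube files, one per component sigma_xx .. sigma_zz.

    Dialect: lengths are nm, values are ``units`` (declared on the second
    comment line as ``units=<...> length=nm``); the atom count is zero; values
    are laid out x-slowest / z-fastest, six per line.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, comp in enumerate(CUBE_COMPONENTS):
        i, j = divmod(idx, 3)
        path = directory / f"{prefix}_s{comp}.cube"
        _write_cube(
            path,
            f"nucstress stress tensor component sigma_{comp}",
            f"units={units} length=nm",
            field.origin, field.spacing, field.dims,
            field.components[..., i, j],
        )
        paths.append(path)
    return paths


def read_tensor_grid(component_paths: Sequence, symmetry_tol: float = 1e-6
                     ) -> GridTensorField:
    """Assemble a GridTensorField from 9 cube files ordered sigma_xx..sigma_zz.

    All files must share origin/spacing/dims exactly; values declared as
    kJ mol^-1 nm^-3 in the header are converted to MPa.
    """
    if len(component_paths) != 9:
        raise ValueError("read_tensor_grid requires exactly 9 component files")
    grids = [_read_cube(p) for p in component_paths]
    origin, spacing, dims, _, _ = grids[0]
    comps = np.empty((*dims, 3, 3))
    for idx, (o, sp, d, vals, header) in enumerate(grids):
        if d != dims or not np.allclose(o, origin) or not np.allclose(sp, spacing):
            raise ValueError(
                f"grid mismatch in component file {component_paths[idx]}: all 9 "
                "components must share exactly the same grid (same box size and "
                "center)")
        if "kj" in header.lower():
            vals = vals * KJ_MOL_NM3_TO_MPA
        i, j = divmod(idx, 3)
        comps[..., i, j] = vals
    return GridTensorField(origin, spacing, dims, comps, symmetry_tol=symmetry_tol)


def average_tensor_fields(fields: Sequence[GridTensorField]) -> GridTensorField:
    """Voxelwise arithmetic mean of tensor fields on bit-identical grids.

    Time averaging of local-stress output (e.g. 100 frames spaced by 10 ps per
    1 ns segment) requires all fields on the same grid: frames from different
    boxes must not be mixed, since shifted grids produce spurious cancellation
    between large positive and negative values.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("no fields to average")
    first = fields[0]
    for f in fields[1:]:
        if not f.same_grid(first):
            raise ValueError(
                "cannot average tensor fields on different grids: stress fields "
                "are only comparable when they share exactly the same box size "
                "and center")
    mean = np.mean([f.components for f in fields], axis=0)
    return GridTensorField(first.origin, first.spacing, first.dims, mean)


def write_atom_tensors(field: AtomTensorField, path) -> None:
    import pandas as pd

    cols = {"serial": field.serials}
    for idx, comp in enumerate(CUBE_COMPONENTS):
        i, j = divmod(idx, 3)
        cols[f"s{comp}"] = field.tensors[:, i, j]
    cols["volume"] = field.volumes
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_atom_tensors(path) -> AtomTensorField:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    tensors = np.stack(
        [df[f"s{comp}"].to_numpy() for comp in CUBE_COMPONENTS], axis=1
    ).reshape(-1, 3, 3)
    return AtomTensorField(df["serial"].to_numpy(), tensors,
                           df["volume"].to_numpy())


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------

class SelectionError(ValueError):
    """Raised for malformed selection expressions."""


_KEYWORDS = {"name", "resname", "resid", "chain", "element", "serial",
             "all", "none", "heavy", "and", "or", "not", "(", ")"}


def _tokenize(expression: str):
    tokens = []  # (text, char offset)
    i = 0
    n = len(expression)
    while i < n:
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < n and not expression[j].isspace() and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser for the small selection grammar.

    expr    := term ('or' term)*
    term    := factor ('and' factor)*
    factor  := 'not' factor | '(' expr ')' | primitive
    primitive := 'all' | 'none' | 'heavy'
               | ('name'|'resname'|'chain'|'element') value+
               | ('resid'|'serial') intspec+      (intspec: 5 or 10:20)
    """

    def __init__(self, structure: Structure, expression: str):
        self.s = structure
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, message: str, offset: int | None = None):
        if offset is None:
            offset = (self.tokens[self.pos][1] if self.pos < len(self.tokens)
                      else len(self.expression))
        raise SelectionError(
            f"{message} at position {offset} in {self.expression!r}")

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self.fail("empty selection expression", 0)
        mask = self.expr()
        if self.pos != len(self.tokens):
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.take()
            return mask
        return self.primitive()

    def _values(self) -> list[tuple[str, int]]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            self.fail("expected at least one value")
        return vals

    def primitive(self) -> np.ndarray:
        if self.peek() is None:
            self.fail("unexpected end of expression")
        tok, off = self.take()
        n = self.s.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "heavy":
            return self.s.elements != "H"
        if tok == "name":
            vals = {normalize_atom_name(v) for v, _ in self._values()}
            return np.isin(self.s.names, list(vals))
        if tok == "resname":
            vals = {v for v, _ in self._values()}
            return np.isin(self.s.residue_names, list(vals))
        if tok == "chain":
            vals = {v for v, _ in self._values()}
            return np.isin(self.s.chain_ids, list(vals))
        if tok == "element":
            vals = {v.upper() for v, _ in self._values()}
            return np.isin(self.s.elements, list(vals))
        if tok in ("resid", "serial"):
            column = (self.s.residue_numbers if tok == "resid"
                      else np.asarray([a.serial for a in self.s.atoms]))
            mask = np.zeros(n, dtype=bool)
            for v, voff in self._values():
                m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", v)
                if not m:
                    self.fail(f"bad integer or range {v!r}", voff)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                mask |= (column >= lo) & (column <= hi)
            return mask
        self.fail(f"unknown token {tok!r}", off)


def select(structure: Structure, expression: str, label: str | None = None
           ) -> Selection:
    """Select atoms by a small expression grammar.

    Supported: ``name``, ``resname``, ``resid`` (ints or ``lo:hi`` ranges),
    ``chain``, ``element``, ``serial``, ``all``, ``none``, ``heavy``, combined
    with ``and``/``or``/``not`` and parentheses.  Example:
    ``"name P C4' and chain I and resid 160:167"``.
    """
    mask = _Parser(structure, expression).parse()
    indices = np.flatnonzero(mask)
    if indices.size == 0 and "none" not in expression:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return Selection(indices, label=label if label is not None else expression)
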