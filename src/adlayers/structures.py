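"""Atomistic configurations, file I/O, and van der Waals radius tables.

Slab convention: ``z`` is the surface normal; the box is rectangular with
lateral periodicity along ``x`` and ``y`` and an aperiodic (vacuum-padded)
``z`` for slab samples.  Monoclinic cells must be pre-orthogonalized by the
caller before they enter this package.  All positions are stored in Angstrom
regardless of the source format (GRO files in nm are converted on read).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import (
    BoxError,
    ConfigurationError,
    FormatError,
    TrajectoryError,
    ValidationError,
)

__all__ = [
    "AtomConfiguration",
    "RadiusTable",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "load_vdw_radii",
    "minimum_image_displacement",
]

_ELEMENT_RE = re.compile(r"[A-Z][a-z]?")


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from an atom name such as ``OW1`` or ``C12``."""
    m = _ELEMENT_RE.match(name.strip().capitalize())
    if not m:
        raise FormatError(f"cannot derive an element symbol from atom name {name!r}")
    return m.group(0)


@dataclass
class AtomConfiguration:
    """A set of atoms in a rectangular, laterally periodic box.

    Parameters
    ----------
    positions : (N, 3) array, Angstrom.
    elements : (N,) array of element symbols.
    box : (3,) array of box lengths (Lx, Ly, Lz), Angstrom.
    periodic : per-axis periodicity flags; slabs use (True, True, False).
    charges : optional (N,) array, units of e.
    chain_id, molecule_id : optional per-atom labels.
    """

    positions: np.ndarray
    elements: np.ndarray
    box: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, True, False)
    charges: np.ndarray | None = None
    chain_id: np.ndarray | None = None
    molecule_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions must be finite")
        self.elements = np.asarray(self.elements, dtype=object)
        n = len(self.positions)
        if len(self.elements) != n:
            raise ValidationError("elements must match positions in length")
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise BoxError(f"box lengths must be positive, got {self.box}")
        for name in ("charges", "chain_id", "molecule_id"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if len(val) != n:
                    raise ValidationError(f"{name} must match positions in length")
                setattr(self, name, val)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def lateral_area(self) -> float:
        """Area of the periodic surface cell, A^2."""
        return float(self.box[0] * self.box[1])

    def select(self, mask: np.ndarray) -> "AtomConfiguration":
        """Sub-configuration of the atoms where ``mask`` is True (box kept)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_atoms,):
            raise ValidationError("selection mask must be a length-N boolean array")
        pick = lambda a: None if a is None else a[mask]
        return AtomConfiguration(
            positions=self.positions[mask],
            elements=self.elements[mask],
            box=self.box.copy(),
            periodic=self.periodic,
            charges=pick(self.charges),
            chain_id=pick(self.chain_id),
            molecule_id=pick(self.molecule_id),
        )

    def translated(self, shift: Sequence[float]) -> "AtomConfiguration":
        return replace(self, positions=self.positions + np.asarray(shift, dtype=float))

    def permuted_axes(self, order: Sequence[int]) -> "AtomConfiguration":
        """Re-orient with an axis permutation, e.g. ``(1, 2, 0)``."""
        order = tuple(int(i) for i in order)
        if sorted(order) != [0, 1, 2]:
            raise ValidationError("axis order must be a permutation of (0, 1, 2)")
        return replace(
            self,
            positions=self.positions[:, order].copy(),
            box=self.box[list(order)].copy(),
            periodic=tuple(self.periodic[i] for i in order),
        )


def minimum_image_displacement(
    delta: np.ndarray, box: np.ndarray, periodic: Sequence[bool]
) -> np.ndarray:
    """Apply the minimum-image convention along the periodic axes.

    ``delta`` has shape (..., k) with k matching the length of ``box``.
    """
    delta = np.array(delta, dtype=float, copy=True)
    box = np.asarray(box, dtype=float)
    for ax, per in enumerate(periodic):
        if per:
            delta[..., ax] -= box[ax] * np.round(delta[..., ax] / box[ax])
    return delta


@dataclass(frozen=True)
class RadiusTable:
    """Immutable mapping element symbol -> van der Waals radius (Angstrom)."""

    radii: dict[str, float]
    default: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not r > 0:
                raise ValidationError(f"non-positive vdW radius for {el}: {r}")
        if self.default is not None and not self.default > 0:
            raise ValidationError("default radius must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            if self.default is not None:
                return self.default
            raise LookupError(
                f"element {element!r} not in radius table {self.name!r} "
                "and no default radius set"
            ) from None

    def lookup(self, elements: Iterable[str]) -> np.ndarray:
        return np.array([self.radius(e) for e in elements], dtype=float)

    def max_radius(self) -> float:
        vals = list(self.radii.values())
        if self.default is not None:
            vals.append(self.default)
        return max(vals)


def load_vdw_radii(table_name: str = "bondi", default: float | None = None) -> RadiusTable:
    """Load a bundled radius table by name, or a user file of element/radius pairs."""
    bundled = {"bondi": "vdw_radii_bondi.txt"}
    if table_name in bundled:
        text = (resources.files("adlayers.data") / bundled[table_name]).read_text()
        name = table_name
    else:
        path = Path(table_name)
        if not path.is_file():
            raise ConfigurationError(
                f"unknown radius table {table_name!r}: not bundled and not a file"
            )
        text = path.read_text()
        name = str(path)
    radii: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValidationError(f"{name}:{lineno}: expected 'element radius'")
        try:
            r = float(parts[1])
        except ValueError:
            raise ValidationError(f"{name}:{lineno}: radius {parts[1]!r} is not a number")
        if not r > 0:
            raise ValidationError(f"{name}:{lineno}: radius must be positive")
        radii[parts[0]] = r
    return RadiusTable(radii=radii, default=default, name=name)


# ---------------------------------------------------------------------------
# Structure file I/O.  XYZ uses an extended comment line "Lx Ly Lz" for the
# box; GRO goes through MDAnalysis (nm -> Angstrom on read); PDB through gemmi
# (CRYST1 cell, chain ids preserved).
# ---------------------------------------------------------------------------


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "gro", "xyz"):
        return suffix
    raise ConfigurationError(f"cannot infer structure format from {path!r}")


def _require_rectangular(angles: Sequence[float], path) -> None:
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise BoxError(
            f"{path}: cell angles {tuple(angles)} are not 90 degrees; "
            "pre-orthogonalize monoclinic cells before reading"
        )


def _parse_xyz_frame(lines: list[str], start: int, path) -> tuple[AtomConfiguration | None, int]:
    i = start
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines):
        return None, i
    try:
        n = int(lines[i].strip())
    except ValueError:
        raise FormatError(f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}")
    comment = lines[i + 1] if i + 1 < len(lines) else ""
    box = None
    fields = comment.split()
    if len(fields) >= 3:
        try:
            box = np.array([float(x) for x in fields[:3]])
        except ValueError:
            box = None
    elements, positions = [], []
    for j in range(n):
        lineno = i + 2 + j
        if lineno >= len(lines):
            raise FormatError(f"{path}:{lineno + 1}: truncated frame ({n} atoms expected)")
        parts = lines[lineno].split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno + 1}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            positions.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise FormatError(f"{path}:{lineno + 1}: non-numeric coordinate")
    config = None
    if n > 0:
        if box is None:
            config = ("noboX", elements, positions)  # resolved by caller via override
        else:
            config = AtomConfiguration(positions, elements, box)
    return config, i + 2 + n


def _read_xyz(path, box_override):
    lines = Path(path).read_text().splitlines()
    cfg, _ = _parse_xyz_frame(lines, 0, path)
    if cfg is None:
        raise FormatError(f"{path}: empty xyz file")
    if isinstance(cfg, tuple):
        if box_override is None:
            raise BoxError(f"{path}: no box on the xyz comment line and no override given")
        _, elements, positions = cfg
        cfg = AtomConfiguration(positions, elements, np.asarray(box_override, float))
    return cfg


def _read_gro(path, box_override):
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        _require_rectangular(u.dimensions[3:6], path)
        box = np.array(u.dimensions[:3], dtype=float)
    if box is None:
        if box_override is None:
            raise BoxError(f"{path}: no box line and no override given")
        box = np.asarray(box_override, dtype=float)
    elements = [_element_from_name(nm) for nm in u.atoms.names]
    return AtomConfiguration(
        positions=u.atoms.positions.astype(float),
        elements=elements,
        box=box,
        molecule_id=u.atoms.resids.copy(),
    )


def _read_pdb(path, box_override):
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: PDB file contains no model")
    cell = st.cell
    if cell.a > 1 and cell.b > 1 and cell.c > 1:
        _require_rectangular((cell.alpha, cell.beta, cell.gamma), path)
        box = np.array([cell.a, cell.b, cell.c], dtype=float)
    elif box_override is not None:
        box = np.asarray(box_override, dtype=float)
    else:
        raise BoxError(f"{path}: no CRYST1 record and no override given")
    positions, elements, chains, mols = [], [], [], []
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                el = atom.element.name if atom.element.name != "X" else None
                elements.append(el or _element_from_name(atom.name))
                chains.append(chain.name)
                mols.append(residue.seqid.num)
    if not positions:
        raise FormatError(f"{path}: PDB file contains no atoms")
    return AtomConfiguration(
        positions=positions,
        elements=elements,
        box=box,
        chain_id=np.array(chains, dtype=object),
        molecule_id=np.array(mols, dtype=int),
    )


def read_structure(
    path: str | Path,
    format: str | None = None,
    box: Sequence[float] | None = None,
    axis_order: Sequence[int] | None = None,
) -> AtomConfiguration:
    """Read a single-frame structure (pdb, gro or xyz) into Angstrom coordinates.

    ``box`` overrides missing box metadata; ``axis_order`` optionally permutes
    axes after reading so that z becomes the surface normal.
    """
    fmt = _infer_format(path, format)
    if not Path(path).is_file():
        raise FormatError(f"no such file: {path}")
    readers = {"xyz": _read_xyz, "gro": _read_gro, "pdb": _read_pdb}
    if fmt not in readers:
        raise ConfigurationError(f"unsupported structure format {fmt!r}")
    cfg = readers[fmt](path, box)
    if axis_order is not None:
        cfg = cfg.permuted_axes(axis_order)
    return cfg


def _write_xyz_frame(fh, config: AtomConfiguration) -> None:
    fh.write(f"{config.n_atoms}\n")
    fh.write("{:.6f} {:.6f} {:.6f}\n".format(*config.box))
    for el, (x, y, z) in zip(config.elements, config.positions):
        fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def _mda_universe(config: AtomConfiguration):
    import MDAnalysis as mda

    n = config.n_atoms
    if config.molecule_id is not None:
        resids = np.asarray(config.molecule_id, dtype=int)
    else:
        resids = np.ones(n, dtype=int)
    uniq, residx = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=residx, trajectory=True
    )
    u.add_TopologyAttr("names", [str(e) for e in config.elements])
    u.add_TopologyAttr("resids", uniq)
    u.add_TopologyAttr("resnames", ["MOL"] * len(uniq))
    u.atoms.positions = config.positions
    u.dimensions = np.array([*config.box, 90.0, 90.0, 90.0], dtype=np.float32)
    return u


def _write_pdb(path, config: AtomConfiguration) -> None:
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*config.box, 90.0, 90.0, 90.0)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain_ids = (
        config.chain_id
        if config.chain_id is not None
        else np.array(["A"] * config.n_atoms, dtype=object)
    )
    mol_ids = (
        np.asarray(config.molecule_id, dtype=int)
        if config.molecule_id is not None
        else np.ones(config.n_atoms, dtype=int)
    )
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for i in range(config.n_atoms):
        cid = str(chain_ids[i])
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        key = (cid, int(mol_ids[i]))
        if key not in residues:
            res = gemmi.Residue()
            res.name = "MOL"
            res.seqid = gemmi.SeqId(int(mol_ids[i]), " ")
            chains[cid].add_residue(res)
            residues[key] = chains[cid][-1]
        atom = gemmi.Atom()
        el = str(config.elements[i])
        atom.name = f"{el}{i % 100}"
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*config.positions[i])
        residues[key].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_structure(path: str | Path, config: AtomConfiguration, format: str | None = None) -> None:
    """Write a configuration to pdb, gro or xyz (format inferred from suffix)."""
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        with open(path, "w") as fh:
            _write_xyz_frame(fh, config)
    elif fmt == "gro":
        u = _mda_universe(config)
        u.atoms.write(str(path))
    elif fmt == "pdb":
        _write_pdb(path, config)
    else:
        raise ConfigurationError(f"unsupported structure format {fmt!r}")


def read_trajectory(
    path: str | Path,
    dt: float,
    format: str | None = None,
    box: Sequence[float] | None = None,
) -> tuple[list[AtomConfiguration], np.ndarray]:
    """Read a multi-frame gro/xyz trajectory; returns (frames, timestamps in ps)."""
    fmt = _infer_format(path, format)
    if dt <= 0:
        raise ValidationError("frame spacing dt must be positive")
    frames: list[AtomConfiguration] = []
    if fmt == "xyz":
        lines = Path(path).read_text().splitlines()
        i = 0
        while True:
            cfg, i = _parse_xyz_frame(lines, i, path)
            if cfg is None:
                break
            if isinstance(cfg, tuple):
                if box is None:
                    raise BoxError(f"{path}: frame without box and no override given")
                _, elements, positions = cfg
                cfg = AtomConfiguration(positions, elements, np.asarray(box, float))
            frames.append(cfg)
    elif fmt == "gro":
        import mdtraj

        traj = mdtraj.load(str(path))
        elements = [a.element.symbol if a.element else a.name for a in traj.topology.atoms]
        mol_ids = np.array([a.residue.resSeq for a in traj.topology.atoms], dtype=int)
        for k in range(traj.n_frames):
            if traj.unitcell_lengths is not None:
                fbox = traj.unitcell_lengths[k] * 10.0
            elif box is not None:
                fbox = np.asarray(box, float)
            else:
                raise BoxError(f"{path}: frame {k} has no box and no override given")
            frames.append(
                AtomConfiguration(
                    positions=traj.xyz[k] * 10.0,
                    elements=elements,
                    box=fbox,
                    molecule_id=mol_ids.copy(),
                )
            )
    else:
        raise ConfigurationError(f"unsupported trajectory format {fmt!r}")
    if not frames:
        raise FormatError(f"{path}: no frames found")
    n0 = frames[0].n_atoms
    for k, f in enumerate(frames):
        if f.n_atoms != n0:
            raise TrajectoryError(
                f"{path}: frame {k} has {f.n_atoms} atoms, frame 0 has {n0}"
            )
    times = np.arange(len(frames), dtype=float) * dt
    return frames, times


def write_trajectory(
    path: str | Path, frames: Sequence[AtomConfiguration], format: str | None = None
) -> None:
    """Write frames as a concatenated multi-frame xyz or gro file."""
    fmt = _infer_format(path, format)
    if not frames:
        raise ValidationError("cannot write an empty trajectory")
    if fmt == "xyz":
        with open(path, "w") as fh:
            for cfg in frames:
                _write_xyz_frame(fh, cfg)
    elif fmt == "gro":
        import mdtraj

        first = frames[0]
        top = mdtraj.Topology()
        ch = top.add_chain()
        mol_ids = (
            np.asarray(first.molecule_id, dtype=int)
            if first.molecule_id is not None
            else np.ones(first.n_atoms, dtype=int)
        )
        residues = {}
        for i in range(first.n_atoms):
            mid = int(mol_ids[i])
            if mid not in residues:
                residues[mid] = top.add_residue("MOL", ch, resSeq=mid)
            el = str(first.elements[i])
            try:
                md_el = mdtraj.element.get_by_symbol(el)
            except KeyError:
                md_el = mdtraj.element.virtual
            top.add_atom(f"{el}{i % 100}", md_el, residues[mid])
        xyz = np.stack([f.positions for f in frames]) / 10.0
        lengths = np.stack([f.box for f in frames]) / 10.0
        angles = np.full((len(frames), 3), 90.0)
        traj = mdtraj.Trajectory(xyz, top, unitcell_lengths=lengths, unitcell_angles=angles)
        traj.save_gro(str(path))
    else:
        raise ConfigurationError(f"unsupported trajectory format {fmt!r}")
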