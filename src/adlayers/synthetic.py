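"""Synthetic generators for every input the analyses consume.

These generators emulate the statistical and geometric structure of slab +
adlayer MD data at desk scale: crystalline slabs with sinusoidal corrugation,
rigid discoidal admolecules (flat monolayers, leaning stacked columns, or 3D
mounds), 2D Brownian walkers with optional long jumps, exponentially
decorrelating in-plane rotors, surface-energy-vs-temperature tables of known
functional form, water boxes at a prescribed density, and donor-H-acceptor
triplets at exact distance and angle.

All generators are pure functions of (spec, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, PackingError, TilingError, ValidationError
from .structures import AtomConfiguration, minimum_image_displacement
from .dynamics import OrientationSeries, Trajectory2D
from .thermo import ThermoSeries

__all__ = [
    "SlabSpec",
    "WalkSpec",
    "make_crystal_slab",
    "make_adlayer",
    "make_brownian_walk",
    "make_rotor_series",
    "make_us_table",
    "make_hbond_fixture",
    "make_water_box",
]

WATER_MOLAR_MASS = 18.01528       # g/mol
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class SlabSpec:
    """Crystalline slab: square lateral lattice stacked into planes, with the
    outermost plane(s) corrugated by h0 * sin(2 pi x / wavelength)."""

    box: tuple[float, float] = (20.0, 20.0)   # lateral lengths, A
    spacing: float = 2.0                      # lattice constant, A
    layers: int = 1
    h0: float = 0.0                           # corrugation amplitude, A
    wavelength: float = 10.0                  # corrugation wavelength, A
    element: str = "C"
    base_z: float = 10.0                      # z of the bottom plane, A
    vacuum: float = 20.0                      # vacuum padding above/below, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError("lattice spacing must be positive")
        if self.layers < 1:
            raise ValidationError("need at least one layer")
        if self.h0 < 0:
            raise ValidationError("corrugation amplitude must be non-negative")
        if self.wavelength <= 0:
            raise ValidationError("corrugation wavelength must be positive")


def make_crystal_slab(spec: SlabSpec) -> AtomConfiguration:
    """Deterministic lattice slab with sinusoidally corrugated outer planes."""
    nx = round(spec.box[0] / spec.spacing)
    ny = round(spec.box[1] / spec.spacing)
    for n, L, ax in ((nx, spec.box[0], "x"), (ny, spec.box[1], "y")):
        if n < 1 or abs(n * spec.spacing - L) > 1e-6 * max(L, 1.0):
            raise TilingError(
                f"box length {L} along {ax} is not an integer multiple of "
                f"spacing {spec.spacing}"
            )
    xs = np.arange(nx) * spec.spacing
    ys = np.arange(ny) * spec.spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    planes = []
    corr = spec.h0 * np.sin(2.0 * np.pi * X / spec.wavelength)
    for k in range(spec.layers):
        Z = np.full_like(X, spec.base_z + k * spec.spacing)
        if k == spec.layers - 1:
            Z = Z + corr
        if k == 0:
            Z = Z - (corr if spec.layers > 1 else 0.0)
        planes.append(np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1))
    positions = np.concatenate(planes)
    lz = spec.base_z + spec.layers * spec.spacing + 2.0 * spec.h0 + spec.vacuum
    return AtomConfiguration(
        positions=positions,
        elements=np.array([spec.element] * len(positions), dtype=object),
        box=np.array([spec.box[0], spec.box[1], lz]),
        chain_id=np.array(["S"] * len(positions), dtype=object),
        molecule_id=np.zeros(len(positions), dtype=int),
    )


def _disk_molecule(center: np.ndarray, radius: float, n_ring: int, element: str) -> np.ndarray:
    """Rigid flat disk: one central atom plus a ring of n_ring atoms."""
    ang = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang),
         np.full(n_ring, center[2])], axis=1,
    )
    return np.concatenate([center[None, :], ring])


def _place_without_overlap(rng, n, box_xy, min_dist, existing=None, max_attempts=10_000):
    placed = [] if existing is None else [np.asarray(p) for p in existing]
    new = []
    box = np.asarray(box_xy, dtype=float)
    for _ in range(n):
        for attempt in range(max_attempts):
            cand = rng.uniform(0.0, box, size=2)
            if placed:
                d = minimum_image_displacement(np.array(placed) - cand, box, (True, True))
                if np.min(np.hypot(d[:, 0], d[:, 1])) < min_dist:
                    continue
            placed.append(cand)
            new.append(cand)
            break
        else:
            raise PackingError(
                f"could not place molecule {len(new) + 1}/{n} without overlap "
                f"in {max_attempts} attempts"
            )
    return new


def make_adlayer(
    surface: AtomConfiguration,
    n_molecules: int,
    mode: str = "flat2d",
    disk_radius: float = 5.0,
    seed: int = 0,
    n_ring: int = 8,
    standoff: float = 3.4,
    layer_pitch: float = 3.4,
    lean_offset: float = 0.5,
    element: str = "N",
    base_fraction: float = 0.5,
) -> AtomConfiguration:
    """Deposit rigid disk admolecules on a surface.

    Modes: ``flat2d`` places one random non-overlapping monolayer; ``stacked``
    fills complete grid layers in sequence, each layer laterally shifted by
    ``lean_offset`` (leaning columns); ``cluster3d`` puts a fraction
    ``base_fraction`` of the molecules into one compact flat patch and piles
    the rest into a 3D mound on top of it.
    """
    if n_molecules < 0:
        raise ValidationError("n_molecules must be non-negative")
    if n_molecules == 0:
        return surface
    rng = np.random.default_rng(seed)
    box_xy = surface.box[:2]
    z0 = float(surface.positions[:, 2].max()) + standoff
    pitch = 2.0 * disk_radius
    centers: list[np.ndarray] = []   # (x, y, z)

    if mode == "flat2d":
        for xy in _place_without_overlap(rng, n_molecules, box_xy, pitch):
            centers.append(np.array([xy[0], xy[1], z0]))
    elif mode in ("stacked", "cluster3d"):
        nx = max(int(box_xy[0] // pitch), 1)
        ny = max(int(box_xy[1] // pitch), 1)
        grid = [
            np.array([(i + 0.5) * box_xy[0] / nx, (j + 0.5) * box_xy[1] / ny])
            for i in range(nx) for j in range(ny)
        ]
        mid = np.asarray(box_xy) / 2.0
        grid.sort(key=lambda p: float(np.hypot(*(p - mid))))
        per_layer = len(grid)
        if mode == "stacked":
            for k in range(n_molecules):
                layer, slot = divmod(k, per_layer)
                xy = (grid[slot] + layer * lean_offset) % box_xy
                centers.append(np.array([xy[0], xy[1], z0 + layer * layer_pitch]))
        else:  # cluster3d: partial compact base patch plus a mound above its center
            n_base = max(min(int(round(base_fraction * n_molecules)), per_layer), 1)
            n_base = min(n_base, n_molecules)
            for slot in range(n_base):
                xy = grid[slot]
                centers.append(np.array([xy[0], xy[1], z0]))
            n_mound_slots = max(n_base // 2, 1)
            for k in range(n_molecules - n_base):
                layer, slot = divmod(k, n_mound_slots)
                xy = (grid[slot] + (layer + 1) * lean_offset) % box_xy
                centers.append(np.array([xy[0], xy[1], z0 + (layer + 1) * layer_pitch]))
    else:
        raise ValidationError(f"unknown adlayer mode {mode!r}")

    mol0 = 0
    if surface.molecule_id is not None and len(surface.molecule_id):
        mol0 = int(np.max(surface.molecule_id))
    pos_parts, mol_ids = [], []
    for m, c in enumerate(centers):
        atoms = _disk_molecule(c, disk_radius, n_ring, element)
        pos_parts.append(atoms)
        mol_ids.extend([mol0 + 1 + m] * len(atoms))
    ad_pos = np.concatenate(pos_parts)
    n_ad = len(ad_pos)
    lz = max(surface.box[2], float(ad_pos[:, 2].max()) + 10.0)

    def _cat(surf_attr, ad_value):
        if surf_attr is None:
            return None
        return np.concatenate([np.asarray(surf_attr), np.array(ad_value, dtype=object)])

    surf_chain = (
        surface.chain_id
        if surface.chain_id is not None
        else np.array(["S"] * surface.n_atoms, dtype=object)
    )
    surf_mol = (
        np.asarray(surface.molecule_id, dtype=int)
        if surface.molecule_id is not None
        else np.zeros(surface.n_atoms, dtype=int)
    )
    return AtomConfiguration(
        positions=np.concatenate([surface.positions, ad_pos]),
        elements=np.concatenate(
            [surface.elements, np.array([element] * n_ad, dtype=object)]
        ),
        box=np.array([surface.box[0], surface.box[1], lz]),
        chain_id=np.concatenate([surf_chain, np.array(["A"] * n_ad, dtype=object)]),
        molecule_id=np.concatenate([surf_mol, np.array(mol_ids, dtype=int)]),
    )


@dataclass(frozen=True)
class WalkSpec:
    """2D Brownian walk with an optional fixed-length long-jump admixture."""

    D: float = 0.088              # A^2/ps (isotropic unless D_y given)
    dt: float = 1.0               # ps
    n_steps: int = 1000
    jump_probability: float = 0.0
    jump_length: float = 8.0      # A
    D_y: float | None = None      # anisotropic runs
    n_walkers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0 or (self.D_y is not None and self.D_y < 0):
            raise ValidationError("diffusion constant must be non-negative")
        if self.dt <= 0:
            raise ValidationError("timestep must be positive")
        if not 0.0 <= self.jump_probability <= 1.0:
            raise ValidationError("jump probability must be in [0, 1]")
        if self.n_steps < 1:
            raise ValidationError("need at least one step")


def make_brownian_walk(spec: WalkSpec) -> Trajectory2D:
    """Walk with per-axis increment variance 2 D dt plus Bernoulli long jumps."""
    rng = np.random.default_rng(spec.seed)
    dy = spec.D if spec.D_y is None else spec.D_y
    sd = np.sqrt(2.0 * spec.dt * np.array([spec.D, dy]))
    steps = rng.normal(0.0, 1.0, size=(spec.n_steps, spec.n_walkers, 2)) * sd
    if spec.jump_probability > 0:
        jump = rng.random((spec.n_steps, spec.n_walkers)) < spec.jump_probability
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_steps, spec.n_walkers))
        steps[..., 0] += jump * spec.jump_length * np.cos(theta)
        steps[..., 1] += jump * spec.jump_length * np.sin(theta)
    tracks = np.concatenate(
        [np.zeros((1, spec.n_walkers, 2)), np.cumsum(steps, axis=0)]
    )
    times = np.arange(spec.n_steps + 1, dtype=float) * spec.dt
    return Trajectory2D(times=times, tracks=tracks)


def make_rotor_series(tau: float, dt: float, n: int, seed: int = 0) -> OrientationSeries:
    """In-plane rotor whose vector autocorrelation decays as exp(-t / tau).

    The angle performs a random walk with per-step variance 2 dt / tau: for a
    2D unit vector, <u(t).u(0)> = <cos(d_theta)> = exp(-sigma^2(t)/2) with
    sigma^2(t) = (2/tau) t, giving the prescribed exponential decay.
    """
    if tau <= 0:
        raise ValidationError("relaxation time must be positive")
    if dt <= 0 or n < 1:
        raise ValidationError("need dt > 0 and n >= 1")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    increments = rng.normal(0.0, np.sqrt(2.0 * dt / tau), size=n - 1)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(increments)])
    vectors = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return OrientationSeries(times=np.arange(n, dtype=float) * dt, vectors=vectors)


def make_us_table(
    u0: float,
    alpha: float,
    high_T_slope: float,
    T_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ThermoSeries:
    """Surface-energy table u(T) = u0 + alpha T^2 / (1 + f T) plus Gaussian noise.

    The rational form has u(0) = u0, zero slope and quadratic behaviour at low
    T, and approaches the prescribed linear ``high_T_slope`` (= alpha / f) at
    high T; ``high_T_slope = 0`` leaves the pure quadratic (f = 0).
    """
    T = np.asarray(T_grid, dtype=float)
    if len(T) == 0 or T[0] != 0.0 or np.any(np.diff(T) <= 0):
        raise ValidationError("temperature grid must be ascending and start at 0 K")
    if noise_sd < 0:
        raise ValidationError("noise standard deviation must be non-negative")
    f = alpha / high_T_slope if high_T_slope != 0 else 0.0
    if f < 0 or (f > 0 and 1.0 + f * T[-1] <= 0):
        raise ValidationError("inconsistent alpha / high-T slope combination")
    u = u0 + alpha * T**2 / (1.0 + f * T)
    if noise_sd > 0:
        u = u + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(T))
    return ThermoSeries(T=T, u=u)


def make_hbond_fixture(dOO: float, angle: float, box: float = 20.0) -> AtomConfiguration:
    """Donor O, its H at 1.0 A, and an acceptor O at exact O-O distance and
    O-H...O angle (at the H), all in the z = box/2 plane."""
    if dOO <= 1.0:
        raise ValidationError("O-O distance must exceed the 1.0 A O-H bond")
    if not 0.0 < angle <= 180.0:
        raise ValidationError("angle must be in (0, 180] degrees")
    phi = np.pi - np.radians(angle)      # direction of H->acceptor from +x
    cosphi = np.cos(phi)
    disc = cosphi * cosphi - 1.0 + dOO * dOO
    if disc < 0:
        raise GeometryError(f"no acceptor position for dOO={dOO}, angle={angle}")
    L = -cosphi + np.sqrt(disc)
    if L <= 0:
        raise GeometryError(f"no acceptor position for dOO={dOO}, angle={angle}")
    z = box / 2.0
    donor = np.array([box / 2.0 - 2.0, box / 2.0, z])
    h = donor + np.array([1.0, 0.0, 0.0])
    acceptor = h + L * np.array([np.cos(phi), np.sin(phi), 0.0])
    return AtomConfiguration(
        positions=np.stack([donor, h, acceptor]),
        elements=np.array(["O", "H", "O"], dtype=object),
        box=np.array([box, box, box]),
        chain_id=np.array(["A", "A", "B"], dtype=object),
        molecule_id=np.array([1, 1, 2]),
    )


_WATER_GEOMETRY = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [0.9572 * np.cos(np.radians(104.52)), 0.9572 * np.sin(np.radians(104.52)), 0.0],
    ]
)
_WATER_CHARGES = np.array([-0.8476, 0.4238, 0.4238])  # SPC/E


def make_water_box(
    n_molecules: int,
    density: float = 1.0,
    seed: int = 0,
    min_oo_distance: float = 2.4,
    max_attempts: int = 10_000,
) -> AtomConfiguration:
    """Rigid 3-site waters at random orientations in a cube sized so that
    mass / volume equals ``density`` (g/cm^3).  Box edge is reported via the
    configuration box; the analytic volume is n M / (rho N_A)."""
    if n_molecules < 1:
        raise ValidationError("need at least one molecule")
    if density <= 0:
        raise ValidationError("density must be positive")
    volume_cm3 = n_molecules * WATER_MOLAR_MASS / (density * AVOGADRO)
    edge = (volume_cm3 * 1e24) ** (1.0 / 3.0)    # cm^3 -> A^3
    rng = np.random.default_rng(seed)
    box = np.array([edge, edge, edge])
    o_positions: list[np.ndarray] = []
    frames = []
    for m in range(n_molecules):
        for attempt in range(max_attempts):
            o = rng.uniform(0.0, edge, size=3)
            if o_positions:
                d = minimum_image_displacement(
                    np.array(o_positions) - o, box, (True, True, True)
                )
                if np.min(np.linalg.norm(d, axis=1)) < min_oo_distance:
                    continue
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(o + _WATER_GEOMETRY @ rot.T)
            o_positions.append(o)
            break
        else:
            raise PackingError(
                f"could not place water {m + 1}/{n_molecules} in {max_attempts} attempts"
            )
    positions = np.concatenate(frames)
    return AtomConfiguration(
        positions=positions,
        elements=np.array(["O", "H", "H"] * n_molecules, dtype=object),
        box=box,
        periodic=(True, True, True),
        charges=np.tile(_WATER_CHARGES, n_molecules),
        molecule_id=np.repeat(np.arange(1, n_molecules + 1), 3),
    )
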