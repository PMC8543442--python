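"""Virtual AFM: spherical-tip topography and Monte-Carlo volumetry.

A spherical tip of radius R is lowered along z onto the sample; the surface
height at a lateral point is the tip-center z at first van der Waals contact
with any atom (lateral minimum-image convention).  Probing N_p random lateral
points from above and below gives paired height maps z+ and z-, and the
sample volume follows as V = A <z+ - z->, a Monte-Carlo estimate whose
standard error is A sd(dz)/sqrt(n).

Recording the tip CENTER makes the thickness inflation symmetric
(approximately 2R + 2 r_vdw for a dense slab); the tip-apex convention is
available via ``contact="apex"``.  The closed-form ``analytic`` probe is the
default; the literal ``stepped`` descent (default dz = 0.001 A) is retained
and agrees with it to within one step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import EmptySurfaceError, SelectionError, ValidationError
from .structures import AtomConfiguration, RadiusTable, minimum_image_displacement

__all__ = [
    "ProbeSpec",
    "HeightMap",
    "VolumeResult",
    "AdlayerVolumeResult",
    "probe_height",
    "build_height_maps",
    "sample_volume",
    "adlayer_volume",
]


@dataclass(frozen=True)
class ProbeSpec:
    """Spherical probe parameters."""

    radius: float = 2.0        # tip radius R, A
    dz: float = 0.001          # stepped-descent increment, A
    n_points: int = 1024       # random lateral points N_p
    margin: float = 1.0        # extra start height above the highest possible contact, A
    seed: int = 0
    contact: str = "center"    # record tip "center" or "apex" z at contact

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("tip radius must be positive")
        if self.dz <= 0:
            raise ValidationError("descent step dz must be positive")
        if self.n_points < 1:
            raise ValidationError("need at least one probe point")
        if self.contact not in ("center", "apex"):
            raise ValidationError("contact must be 'center' or 'apex'")


@dataclass
class HeightMap:
    """Paired upper/lower surface samples at N_p random lateral points."""

    points: np.ndarray          # (N_p, 2) lateral coordinates, A
    z_upper: np.ndarray         # (N_p,) contact heights from above (nan: no contact)
    z_lower: np.ndarray         # (N_p,) contact heights from below
    area: float                 # lateral cell area, A^2
    probe: ProbeSpec
    radii_name: str = "custom"
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.z_upper = np.asarray(self.z_upper, dtype=float)
        self.z_lower = np.asarray(self.z_lower, dtype=float)
        n = len(self.points)
        if len(self.z_upper) != n or len(self.z_lower) != n:
            raise ValidationError("z_upper and z_lower must match points in length")
        if not self.area > 0:
            raise ValidationError("area must be positive")
        both = self.contact_mask
        if np.any(self.z_upper[both] < self.z_lower[both] - 1e-9):
            raise ValidationError("z_upper must be >= z_lower wherever both contact")

    @property
    def contact_mask(self) -> np.ndarray:
        """Points where both the upper and the lower probe made contact."""
        return np.isfinite(self.z_upper) & np.isfinite(self.z_lower)

    @property
    def thickness(self) -> np.ndarray:
        """dz = z+ - z- over the contacted points."""
        m = self.contact_mask
        return self.z_upper[m] - self.z_lower[m]

    @property
    def no_contact_fraction(self) -> float:
        return 1.0 - float(np.mean(self.contact_mask))


def _reach_radii(config: AtomConfiguration, probe: ProbeSpec, radii: RadiusTable):
    return probe.radius + radii.lookup(config.elements)


def _lateral_d2(config: AtomConfiguration, points: np.ndarray) -> np.ndarray:
    """Squared lateral minimum-image distances, shape (n_points, n_atoms)."""
    delta = points[:, None, :] - config.positions[None, :, :2]
    delta = minimum_image_displacement(delta, config.box[:2], config.periodic[:2])
    return delta[..., 0] ** 2 + delta[..., 1] ** 2


def _analytic_contact(
    z_atoms: np.ndarray, d2: np.ndarray, reach: np.ndarray, direction: str
) -> np.ndarray:
    """Closed-form tip-center contact height for each point (rows of d2)."""
    within = d2 <= reach[None, :] ** 2
    with np.errstate(invalid="ignore"):
        dz = np.sqrt(np.maximum(reach[None, :] ** 2 - d2, 0.0))
    if direction == "from_above":
        cand = np.where(within, z_atoms[None, :] + dz, -np.inf)
        out = cand.max(axis=1)
        out[~within.any(axis=1)] = np.nan
    else:
        cand = np.where(within, z_atoms[None, :] - dz, np.inf)
        out = cand.min(axis=1)
        out[~within.any(axis=1)] = np.nan
    return out


def _stepped_contact_single(
    z_atoms: np.ndarray, d2: np.ndarray, reach: np.ndarray,
    probe: ProbeSpec, direction: str,
) -> float:
    """Literal stepped descent for one lateral point (1D candidate arrays)."""
    within = d2 <= reach**2
    if not within.any():
        return float("nan")
    za, dd2, rr2 = z_atoms[within], d2[within], reach[within] ** 2
    sign = 1.0 if direction == "from_above" else -1.0
    start = (za * sign + np.sqrt(rr2)).max() * sign + sign * probe.margin
    # advance in blocks of dz steps; contact at the first step where the
    # tip-center-to-atom-center distance drops to the contact sphere
    block = 1024
    k0 = 0
    while True:
        ks = np.arange(k0 + 1, k0 + block + 1)
        z_grid = start - sign * probe.dz * ks
        hit = (dd2[None, :] + (z_grid[:, None] - za[None, :]) ** 2) <= rr2[None, :]
        rows = hit.any(axis=1)
        if rows.any():
            return float(z_grid[int(np.argmax(rows))])
        k0 += block
        if k0 * probe.dz > abs(start) + np.abs(za).max() + reach.max() + 10.0:
            return float("nan")  # safety: descended past every atom


def probe_height(
    config: AtomConfiguration,
    point: Sequence[float],
    direction: str = "from_above",
    probe: ProbeSpec = ProbeSpec(),
    radii: RadiusTable | None = None,
    method: str = "analytic",
) -> float:
    """Tip contact height at one lateral point; nan when nothing is in reach."""
    if config.n_atoms == 0:
        raise ValidationError("configuration has no atoms")
    if direction not in ("from_above", "from_below"):
        raise ValidationError("direction must be 'from_above' or 'from_below'")
    if radii is None:
        from .structures import load_vdw_radii

        radii = load_vdw_radii()
    reach = _reach_radii(config, probe, radii)
    pt = np.asarray(point, dtype=float).reshape(1, 2)
    d2 = _lateral_d2(config, pt)[0]
    z_atoms = config.positions[:, 2]
    if method == "analytic":
        z = float(_analytic_contact(z_atoms, d2[None, :], reach, direction)[0])
    elif method == "stepped":
        z = _stepped_contact_single(z_atoms, d2, reach, probe, direction)
    else:
        raise ValidationError("method must be 'analytic' or 'stepped'")
    if probe.contact == "apex" and np.isfinite(z):
        z += -probe.radius if direction == "from_above" else probe.radius
    return z


def probe_heights_at(
    config: AtomConfiguration,
    points: np.ndarray,
    probe: ProbeSpec,
    radii: RadiusTable | None = None,
    method: str = "analytic",
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Contact heights (z_upper, z_lower) at caller-supplied lateral points."""
    if config.n_atoms == 0:
        raise ValidationError("configuration has no atoms")
    if radii is None:
        from .structures import load_vdw_radii

        radii = load_vdw_radii()
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    reach = _reach_radii(config, probe, radii)
    z_atoms = config.positions[:, 2]
    z_up = np.empty(len(pts))
    z_lo = np.empty(len(pts))
    if method == "analytic":
        for s in range(0, len(pts), chunk):
            sl = slice(s, min(s + chunk, len(pts)))
            d2 = _lateral_d2(config, pts[sl])
            z_up[sl] = _analytic_contact(z_atoms, d2, reach, "from_above")
            z_lo[sl] = _analytic_contact(z_atoms, d2, reach, "from_below")
    elif method == "stepped":
        for i, p in enumerate(pts):
            d2 = _lateral_d2(config, p.reshape(1, 2))[0]
            z_up[i] = _stepped_contact_single(z_atoms, d2, reach, probe, "from_above")
            z_lo[i] = _stepped_contact_single(z_atoms, d2, reach, probe, "from_below")
    else:
        raise ValidationError("method must be 'analytic' or 'stepped'")
    if probe.contact == "apex":
        z_up -= probe.radius
        z_lo += probe.radius
    return z_up, z_lo


def build_height_maps(
    config: AtomConfiguration,
    probe: ProbeSpec,
    radii: RadiusTable | None = None,
    method: str = "analytic",
) -> HeightMap:
    """Probe N_p uniform random lateral points from above and below.

    The same point set is used for both surfaces; the map area is the lateral
    box area.  Raises EmptySurfaceError when no point makes contact.
    """
    if radii is None:
        from .structures import load_vdw_radii

        radii = load_vdw_radii()
    rng = np.random.default_rng(probe.seed)
    pts = rng.uniform(0.0, config.box[:2], size=(probe.n_points, 2))
    z_up, z_lo = probe_heights_at(config, pts, probe, radii, method)
    if not np.any(np.isfinite(z_up) | np.isfinite(z_lo)):
        raise EmptySurfaceError("no probe point made contact with the sample")
    return HeightMap(
        points=pts, z_upper=z_up, z_lower=z_lo,
        area=config.lateral_area, probe=probe,
        radii_name=radii.name, box=config.box.copy(),
    )


@dataclass
class VolumeResult:
    volume: float              # A^3
    standard_error: float      # A^3
    n_points_used: int
    no_contact_fraction: float

    def summary(self) -> str:
        return (
            f"V = {self.volume:.6g} +/- {self.standard_error:.3g} A^3 "
            f"({self.n_points_used} points, "
            f"{self.no_contact_fraction:.1%} without contact)"
        )


def sample_volume(hmap: HeightMap) -> VolumeResult:
    """Monte-Carlo volume V = A <z+ - z->, SE = A sd/sqrt(n)."""
    dz = hmap.thickness
    if len(dz) == 0:
        raise EmptySurfaceError("no point has both upper and lower contact")
    se = hmap.area * float(np.std(dz, ddof=1) / np.sqrt(len(dz))) if len(dz) > 1 else 0.0
    return VolumeResult(
        volume=hmap.area * float(np.mean(dz)),
        standard_error=se,
        n_points_used=len(dz),
        no_contact_fraction=hmap.no_contact_fraction,
    )


@dataclass
class AdlayerVolumeResult:
    adlayer_volume: float          # A^3
    volume_per_molecule: float | None
    n_molecules: int
    full: VolumeResult
    substrate: VolumeResult

    def summary(self) -> str:
        per = (
            f", {self.volume_per_molecule:.6g} A^3/molecule"
            if self.volume_per_molecule is not None
            else ""
        )
        return f"adlayer V = {self.adlayer_volume:.6g} A^3{per}"


def adlayer_volume(
    full: AtomConfiguration,
    substrate: np.ndarray | Callable[[AtomConfiguration], np.ndarray],
    probe: ProbeSpec,
    radii: RadiusTable | None = None,
    method: str = "analytic",
) -> AdlayerVolumeResult:
    """Adlayer volume by subtraction: V(full) - V(substrate alone).

    ``substrate`` is a boolean mask (or predicate) selecting substrate atoms;
    both probings use the same probe seed, hence the same lateral points.
    The per-molecule volume divides by the number of distinct adlayer
    molecule_id labels.
    """
    mask = np.asarray(substrate(full) if callable(substrate) else substrate, dtype=bool)
    if mask.shape != (full.n_atoms,):
        raise SelectionError("substrate selector must produce a length-N boolean mask")
    if not mask.any():
        raise SelectionError("substrate selection is empty")
    ad_mask = ~mask
    if not ad_mask.any():
        return AdlayerVolumeResult(
            adlayer_volume=0.0, volume_per_molecule=None, n_molecules=0,
            full=sample_volume(build_height_maps(full, probe, radii, method)),
            substrate=sample_volume(build_height_maps(full, probe, radii, method)),
        )
    v_full = sample_volume(build_height_maps(full, probe, radii, method))
    v_sub = sample_volume(build_height_maps(full.select(mask), probe, radii, method))
    diff = v_full.volume - v_sub.volume
    if full.molecule_id is not None:
        n_mol = len(np.unique(np.asarray(full.molecule_id)[ad_mask]))
    else:
        n_mol = 0
    return AdlayerVolumeResult(
        adlayer_volume=diff,
        volume_per_molecule=diff / n_mol if n_mol else None,
        n_molecules=n_mol,
        full=v_full,
        substrate=v_sub,
    )
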