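"""Adlayer dynamics estimators: diffusion, jumps, rotation, in-plane structure,
layer occupancy / growth mode, and dipole density.

Translational dynamics is analysed on unwrapped 2D center-of-mass tracks.
The mean square displacement uses all time origins (FFT evaluation) and the
diffusion constant comes from a straight-line fit of MSD(t) = 4 D t over an
intermediate lag window; its uncertainty is the scatter of block estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import constants

from .errors import FitError, SelectionError, ValidationError
from .structures import AtomConfiguration, minimum_image_displacement

__all__ = [
    "Trajectory2D",
    "MSDCurve",
    "OrientationSeries",
    "LayerProfile",
    "DipoleProfile",
    "com_tracks",
    "msd_and_diffusion",
    "displacement_anisotropy",
    "arrhenius_barrier",
    "detect_jumps",
    "rotational_relaxation",
    "orientation_histogram",
    "pair_distribution_2d",
    "layer_occupancy",
    "adlayer_dipole",
    "molecule_centers",
]

R_KJ_PER_MOL_K = constants.R / 1000.0  # gas constant, kJ/(mol K)
E_ANGSTROM_TO_DEBYE = 4.8032  # 1 e*Angstrom in debye
ANG2_PER_PS_TO_CM2_PER_S = 1.0e-4


@dataclass
class Trajectory2D:
    """Unwrapped lateral center-of-mass tracks.

    times : (n_frames,) ps, strictly increasing and uniformly spaced.
    tracks : (n_frames, n_molecules, 2) Angstrom, unwrapped across images.
    """

    times: np.ndarray
    tracks: np.ndarray
    box: np.ndarray | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tracks = np.asarray(self.tracks, dtype=float)
        if self.tracks.ndim == 2:  # single molecule convenience
            self.tracks = self.tracks[:, None, :]
        if self.tracks.ndim != 3 or self.tracks.shape[2] != 2:
            raise ValidationError("tracks must have shape (n_frames, n_molecules, 2)")
        if len(self.times) != len(self.tracks):
            raise ValidationError("times and tracks must have the same length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValidationError("timestamps must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_molecules(self) -> int:
        return self.tracks.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class OrientationSeries:
    """Time series of in-plane unit vectors (one molecule)."""

    times: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 2:
            raise ValidationError("vectors must have shape (n, 2)")
        if len(self.times) != len(self.vectors):
            raise ValidationError("times and vectors must have the same length")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("orientation vectors must have unit norm")

    @property
    def angles_deg(self) -> np.ndarray:
        """Angle from the first lateral axis, counterclockwise, in [0, 360)."""
        return np.degrees(np.arctan2(self.vectors[:, 1], self.vectors[:, 0])) % 360.0

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class MSDCurve:
    lags: np.ndarray          # ps
    msd: np.ndarray           # A^2
    counts: np.ndarray        # displacement pairs per lag
    diffusion: float          # A^2/ps
    diffusion_se: float       # A^2/ps
    fit_window: tuple[float, float]
    slope: float
    intercept: float

    @property
    def diffusion_cm2_s(self) -> float:
        return self.diffusion * ANG2_PER_PS_TO_CM2_PER_S

    @property
    def diffusion_se_cm2_s(self) -> float:
        return self.diffusion_se * ANG2_PER_PS_TO_CM2_PER_S

    def summary(self) -> str:
        return (
            f"D = {self.diffusion:.4g} A^2/ps "
            f"({self.diffusion_cm2_s:.4g} cm^2/s) "
            f"+/- {self.diffusion_se:.2g} A^2/ps, "
            f"fit window {self.fit_window[0]:.0%}-{self.fit_window[1]:.0%} of max lag"
        )


def com_tracks(
    frames: Sequence[AtomConfiguration], times: np.ndarray, temperature: float | None = None
) -> Trajectory2D:
    """Per-molecule lateral center-of-mass tracks from trajectory frames.

    Molecules are defined by molecule_id (each atom its own molecule when the
    label is absent).  Intra-molecular images are reassembled with the
    minimum-image convention and the track is unwrapped frame-to-frame.
    """
    first = frames[0]
    box = first.box
    periodic = first.periodic
    if first.molecule_id is not None:
        ids = np.asarray(first.molecule_id)
        uniq = np.unique(ids)
        groups = [np.flatnonzero(ids == m) for m in uniq]
    else:
        groups = [np.array([i]) for i in range(first.n_atoms)]
    coms = np.empty((len(frames), len(groups), 2))
    for t, cfg in enumerate(frames):
        pos = cfg.positions
        for g, idx in enumerate(groups):
            ref = pos[idx[0]]
            rel = minimum_image_displacement(pos[idx] - ref, box, periodic)
            coms[t, g] = (ref[:2] + rel[:, :2].mean(axis=0))
    # unwrap frame-to-frame
    steps = coms[1:] - coms[:-1]
    steps = minimum_image_displacement(steps, box[:2], periodic[:2])
    unwrapped = np.concatenate([coms[:1], coms[:1] + np.cumsum(steps, axis=0)])
    return Trajectory2D(times=times, tracks=unwrapped, box=box[:2], temperature=temperature)


def _msd_fft(track: np.ndarray) -> np.ndarray:
    """All-time-origin MSD of one track, shape (n, d) -> (n,). Lag 0 included."""
    n, d = track.shape
    nfft = 1 << (2 * n - 1).bit_length()
    acf = np.zeros(n)
    for k in range(d):
        f = np.fft.rfft(track[:, k], nfft)
        acf += np.fft.irfft(f * np.conj(f), nfft)[:n]
    sq = np.einsum("ij,ij->i", track, track)
    csum = np.cumsum(sq)
    total = csum[-1]
    m = np.arange(n)
    # sum of sq over [m, n-1] and over [0, n-1-m]
    tail = total - np.concatenate(([0.0], csum[:-1]))
    head = csum[::-1]
    return (tail + head - 2.0 * acf) / (n - m)


def _fit_diffusion(
    lags: np.ndarray, msd: np.ndarray, window: tuple[float, float], ndim: int
) -> tuple[float, float, float]:
    max_lag = lags[-1]
    lo, hi = window
    sel = (lags >= lo * max_lag) & (lags <= hi * max_lag) & (lags > 0)
    if sel.sum() < 5:
        raise FitError(
            f"MSD fit window [{lo}, {hi}] of max lag contains {int(sel.sum())} lags (< 5)"
        )
    slope, intercept = np.polyfit(lags[sel], msd[sel], 1)
    return slope / (2.0 * ndim), slope, intercept


def msd_and_diffusion(
    traj: Trajectory2D,
    fit_window: tuple[float, float] = (0.1, 0.5),
    max_lag_fraction: float = 0.1,
    n_blocks: int = 10,
    axes: Sequence[int] = (0, 1),
) -> MSDCurve:
    """MSD over all time origins and the 2D diffusion constant.

    D = slope / (2 d) with d = len(axes); the standard error comes from
    independent fits on ``n_blocks`` contiguous track segments.
    """
    if traj.n_frames < 100:
        raise ValidationError("need at least 100 frames for a diffusion estimate")
    axes = tuple(axes)
    n = traj.n_frames
    n_lag = max(int(n * max_lag_fraction), 2)
    msd = np.zeros(n_lag)
    for mol in range(traj.n_molecules):
        msd += _msd_fft(traj.tracks[:, mol, axes])[:n_lag]
    msd /= traj.n_molecules
    msd[0] = 0.0
    lags = traj.times[:n_lag] - traj.times[0]
    counts = traj.n_molecules * (n - np.arange(n_lag))
    D, slope, intercept = _fit_diffusion(lags, msd, fit_window, len(axes))

    block_Ds = []
    if n_blocks >= 2:
        seg = n // n_blocks
        for b in range(n_blocks):
            chunk = traj.tracks[b * seg : (b + 1) * seg, :, axes]
            if len(chunk) < 10:
                continue
            m = max(int(len(chunk) * max_lag_fraction), 2)
            bm = np.zeros(m)
            for mol in range(traj.n_molecules):
                bm += _msd_fft(chunk[:, mol, :])[:m]
            bm /= traj.n_molecules
            bl = (np.arange(m)) * traj.dt
            try:
                bD, _, _ = _fit_diffusion(bl, bm, fit_window, len(axes))
            except FitError:
                continue
            block_Ds.append(bD)
    if len(block_Ds) >= 2:
        # the block-averaged estimator is more efficient than one long-lag fit
        # and its scatter is an honest standard error
        D = float(np.mean(block_Ds))
        se = float(np.std(block_Ds, ddof=1) / np.sqrt(len(block_Ds)))
    else:
        se = float("nan")
    return MSDCurve(
        lags=lags, msd=msd, counts=counts, diffusion=float(D), diffusion_se=se,
        fit_window=fit_window, slope=float(slope), intercept=float(intercept),
    )


@dataclass
class AnisotropyResult:
    axis_curves: tuple[MSDCurve, MSDCurve]
    ratio: float          # D_axis0 / D_axis1
    ratio_se: float

    def summary(self) -> str:
        return (
            f"D_x/D_y = {self.ratio:.3f} +/- {self.ratio_se:.3f} "
            f"(D_x = {self.axis_curves[0].diffusion:.4g}, "
            f"D_y = {self.axis_curves[1].diffusion:.4g} A^2/ps)"
        )


def displacement_anisotropy(
    traj: Trajectory2D,
    axes: tuple[int, int] = (0, 1),
    fit_window: tuple[float, float] = (0.1, 0.5),
    n_blocks: int = 10,
) -> AnisotropyResult:
    """Per-axis MSD curves and the ratio of the two 1D diffusion constants."""
    curves = tuple(
        msd_and_diffusion(traj, fit_window=fit_window, n_blocks=n_blocks, axes=(ax,))
        for ax in axes
    )
    d0, d1 = curves[0].diffusion, curves[1].diffusion
    ratio = d0 / d1 if d1 != 0 else float("inf")
    if d1 != 0 and np.isfinite(curves[0].diffusion_se) and np.isfinite(curves[1].diffusion_se):
        rel = np.hypot(curves[0].diffusion_se / d0 if d0 else 0.0, curves[1].diffusion_se / d1)
        ratio_se = abs(ratio) * float(rel)
    else:
        ratio_se = float("nan")
    return AnisotropyResult(axis_curves=curves, ratio=float(ratio), ratio_se=ratio_se)


@dataclass
class ArrheniusResult:
    activation_energy: float  # kJ/mol
    note: str = "two-point estimate"

    def summary(self) -> str:
        return f"E_a = {self.activation_energy:.3g} kJ/mol ({self.note})"


def arrhenius_barrier(D1: float, T1: float, D2: float, T2: float) -> ArrheniusResult:
    """Activation energy from two diffusion constants.

    E_a = R ln(D2/D1) / (1/T1 - 1/T2), kJ/mol.  Two temperatures cannot
    establish Arrhenius behaviour, so the result is flagged as an estimate.
    """
    if D1 <= 0 or D2 <= 0:
        raise ValidationError("diffusion constants must be positive")
    if T1 <= 0 or T2 <= 0 or T1 == T2:
        raise ValidationError("temperatures must be positive and distinct")
    ea = R_KJ_PER_MOL_K * np.log(D2 / D1) / (1.0 / T1 - 1.0 / T2)
    return ArrheniusResult(activation_energy=float(ea))


@dataclass
class JumpEvents:
    times: np.ndarray          # arrival time of each jump step, ps
    displacements: np.ndarray  # step length, A
    molecule: np.ndarray       # molecule index per event
    n_steps: int
    threshold: float
    jump_fraction: float       # fraction of total path length carried by jumps

    @property
    def n_events(self) -> int:
        return len(self.times)


def detect_jumps(traj: Trajectory2D, threshold: float = 5.0) -> JumpEvents:
    """Flag single-frame displacements larger than ``threshold`` Angstrom."""
    if threshold < 0:
        raise ValidationError("jump threshold must be non-negative")
    steps = np.diff(traj.tracks, axis=0)           # (n-1, m, 2)
    lengths = np.linalg.norm(steps, axis=2)        # (n-1, m)
    mask = lengths > threshold
    t_idx, mols = np.nonzero(mask)
    total = lengths.sum()
    frac = float(lengths[mask].sum() / total) if total > 0 else 0.0
    return JumpEvents(
        times=traj.times[1:][t_idx],
        displacements=lengths[mask],
        molecule=mols,
        n_steps=int(lengths.size),
        threshold=threshold,
        jump_fraction=frac,
    )


@dataclass
class RotationResult:
    tau: float                 # ps
    bound: str | None          # None, "lower" (tau >= value) or "upper" (tau <= value)
    lags: np.ndarray
    autocorrelation: np.ndarray

    def summary(self) -> str:
        if self.bound == "lower":
            return f"tau >= {self.tau:.3g} ps (autocorrelation never decayed)"
        if self.bound == "upper":
            return f"tau <= {self.tau:.3g} ps (decorrelated within one frame)"
        return f"tau = {self.tau:.3g} ps"


def _vector_autocorrelation(vectors: np.ndarray) -> np.ndarray:
    n = len(vectors)
    nfft = 1 << (2 * n - 1).bit_length()
    acf = np.zeros(n)
    for k in range(vectors.shape[1]):
        f = np.fft.rfft(vectors[:, k], nfft)
        acf += np.fft.irfft(f * np.conj(f), nfft)[:n]
    return acf / (n - np.arange(n))


def rotational_relaxation(series: OrientationSeries, c_min: float = 0.05) -> RotationResult:
    """Relaxation time from C(t) = <u(t0 + t) . u(t0)>, exponential fit on C > c_min."""
    if len(series.vectors) < 1000:
        raise ValidationError("need at least 1000 frames for a relaxation estimate")
    C = _vector_autocorrelation(series.vectors)
    n_lag = len(C) // 2
    C = C[:n_lag]
    lags = series.times[:n_lag] - series.times[0]
    positive = C > c_min
    # use the contiguous initial run above the floor
    first_below = np.argmin(positive) if not positive.all() else n_lag
    sel = np.arange(n_lag) < first_below
    sel[0] = False  # C(0) = 1 carries no decay information
    if sel.sum() < 2:
        return RotationResult(tau=series.dt, bound="upper", lags=lags, autocorrelation=C)
    slope, _ = np.polyfit(lags[sel], np.log(C[sel]), 1)
    if slope >= 0:
        return RotationResult(tau=float(lags[-1]), bound="lower", lags=lags, autocorrelation=C)
    return RotationResult(tau=float(-1.0 / slope), bound=None, lags=lags, autocorrelation=C)


@dataclass
class OrientationHistogram:
    edges: np.ndarray       # degrees
    density: np.ndarray     # probability density per degree
    peaks: np.ndarray       # bin centers exceeding the excess factor
    excess_factor: float


def orientation_histogram(
    series: OrientationSeries, bin_width: float = 5.0, excess_factor: float = 1.5
) -> OrientationHistogram:
    """Normalized distribution of the in-plane angle phi in [0, 360) degrees.

    Peaks are contiguous runs of bins whose density exceeds ``excess_factor``
    times the uniform density; each run is reported by its densest bin.
    """
    nbins = max(int(round(360.0 / bin_width)), 1)
    edges = np.linspace(0.0, 360.0, nbins + 1)
    density, _ = np.histogram(series.angles_deg, bins=edges, density=True)
    uniform = 1.0 / 360.0
    hot = density > excess_factor * uniform
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = []
    i = 0
    while i < nbins:
        if hot[i]:
            j = i
            while j < nbins and hot[j]:
                j += 1
            run = slice(i, j)
            peaks.append(centers[run][np.argmax(density[run])])
            i = j
        else:
            i += 1
    return OrientationHistogram(
        edges=edges, density=density, peaks=np.array(peaks), excess_factor=excess_factor
    )


@dataclass
class GofRCurve:
    r: np.ndarray            # bin centers, A
    g: np.ndarray
    counts: np.ndarray
    first_peak: float | None  # position of the first local maximum with g > 1

    def summary(self) -> str:
        pk = "none" if self.first_peak is None else f"{self.first_peak:.2f} A"
        return f"g(r): first peak at {pk}"


def _annulus_arc_length(r: np.ndarray, Lx: float, Ly: float) -> np.ndarray:
    """Circumference of radius r inside the centered Lx x Ly minimum-image cell."""
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        ax = np.arccos(np.clip(Lx / (2.0 * r), -1.0, 1.0))
        ay = np.arccos(np.clip(Ly / (2.0 * r), -1.0, 1.0))
    quadrant = np.clip(np.pi / 2.0 - ax - ay, 0.0, None)
    return 4.0 * r * quadrant


def pair_distribution_2d(
    centers: np.ndarray,
    box: Sequence[float],
    bins: np.ndarray | int = 60,
    r_max: float | None = None,
) -> GofRCurve:
    """2D radial distribution function of molecular centers.

    ``centers`` has shape (n_frames, N, 2); distances use the lateral
    minimum-image convention and the normalization uses the exact annulus
    perimeter inside the rectangular minimum-image cell, so that the
    density-weighted integral of g recovers N - 1.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim == 2:
        centers = centers[None]
    n_frames, N = centers.shape[0], centers.shape[1]
    if N < 2:
        raise ValidationError("pair distribution requires at least 2 molecules")
    Lx, Ly = float(box[0]), float(box[1])
    area = Lx * Ly
    half_diag = 0.5 * np.hypot(Lx, Ly)
    if r_max is None:
        r_max = half_diag
    if np.isscalar(bins):
        edges = np.linspace(0.0, r_max, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts = np.zeros(len(edges) - 1)
    iu = np.triu_indices(N, k=1)
    for f in range(n_frames):
        d = centers[f][:, None, :] - centers[f][None, :, :]
        d = minimum_image_displacement(d, np.array([Lx, Ly]), (True, True))
        dist = np.hypot(d[..., 0], d[..., 1])[iu]
        counts += np.histogram(dist, bins=edges)[0]
    mid = 0.5 * (edges[:-1] + edges[1:])
    arc = _annulus_arc_length(mid, Lx, Ly)
    shell_area = arc * np.diff(edges)
    ideal = n_frames * (N * (N - 1) / 2.0) * shell_area / area
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    first_peak = None
    for i in range(1, len(g) - 1):
        if g[i] > 1.0 and g[i] >= g[i - 1] and g[i] >= g[i + 1]:
            first_peak = float(mid[i])
            break
    if first_peak is None and len(g) and g.max() > 1.0:
        first_peak = float(mid[int(np.argmax(g))])
    return GofRCurve(r=mid, g=g, counts=counts, first_peak=first_peak)


def molecule_centers(config: AtomConfiguration, mask: np.ndarray | None = None):
    """(ids, centers) of molecules; intra-molecular images reassembled."""
    if config.molecule_id is None:
        raise SelectionError("configuration has no molecule_id labels")
    ids = np.asarray(config.molecule_id)
    sel = np.ones(config.n_atoms, dtype=bool) if mask is None else np.asarray(mask, bool)
    uniq = np.unique(ids[sel])
    centers = np.empty((len(uniq), 3))
    for k, m in enumerate(uniq):
        idx = np.flatnonzero(sel & (ids == m))
        ref = config.positions[idx[0]]
        rel = minimum_image_displacement(
            config.positions[idx] - ref, config.box, config.periodic
        )
        centers[k] = ref + rel.mean(axis=0)
    return uniq, centers


@dataclass
class LayerProfile:
    boundaries: np.ndarray       # layer lower edges above the substrate top, A
    counts: np.ndarray           # molecules per layer
    coverages: np.ndarray        # counts * molecule_area / A
    verdict: str                 # layer_by_layer | stranski_krastanov | islands_3d

    def summary(self) -> str:
        occ = ", ".join(f"L{k}: {c}" for k, c in enumerate(self.counts))
        return f"layers [{occ}] -> {self.verdict}"


def layer_occupancy(
    config: AtomConfiguration,
    substrate_top_z: float,
    layer_thickness: float,
    molecule_area: float,
    adlayer: np.ndarray | Callable[[AtomConfiguration], np.ndarray] | None = None,
    area: float | None = None,
    full_fraction: float = 0.9,
    sk_lower: float = 0.3,
) -> LayerProfile:
    """Assign adlayer molecules to layers and classify the growth mode.

    A molecule with center-of-mass height z goes to layer
    floor((z - substrate_top_z) / layer_thickness), clipped at 0.  Growth is
    layer_by_layer when every layer below the topmost populated one is at
    least ``full_fraction`` covered; stranski_krastanov when upper layers
    populate over a partially covered (>= ``sk_lower``) first layer; and
    islands_3d otherwise.
    """
    if layer_thickness <= 0:
        raise ValidationError("layer thickness must be positive")
    if molecule_area <= 0:
        raise ValidationError("molecule footprint area must be positive")
    if callable(adlayer):
        mask = np.asarray(adlayer(config), dtype=bool)
    elif adlayer is not None:
        mask = np.asarray(adlayer, dtype=bool)
    else:
        mask = None
    try:
        _, centers = molecule_centers(config, mask)
    except SelectionError:
        centers = np.empty((0, 3))
    A = config.lateral_area if area is None else float(area)
    if len(centers) == 0:
        return LayerProfile(
            boundaries=np.array([]), counts=np.array([], dtype=int),
            coverages=np.array([]), verdict="empty",
        )
    layers = np.floor((centers[:, 2] - substrate_top_z) / layer_thickness).astype(int)
    layers = np.clip(layers, 0, None)
    n_layers = int(layers.max()) + 1
    counts = np.bincount(layers, minlength=n_layers)
    coverages = counts * molecule_area / A
    top = n_layers - 1
    if top == 0:
        verdict = "layer_by_layer"
    elif np.all(coverages[:top] >= full_fraction):
        verdict = "layer_by_layer"
    elif coverages[0] >= sk_lower:
        verdict = "stranski_krastanov"
    else:
        verdict = "islands_3d"
    return LayerProfile(
        boundaries=substrate_top_z + layer_thickness * np.arange(n_layers),
        counts=counts,
        coverages=coverages,
        verdict=verdict,
    )


@dataclass
class DipoleProfile:
    dipole_e_angstrom: float
    dipole_debye: float
    area_nm2: float
    dipole_per_area: float       # D/nm^2
    net_charge: float            # e
    origin_dependent: bool

    def summary(self) -> str:
        flag = " (non-neutral region: origin dependent)" if self.origin_dependent else ""
        return f"mu_z/A = {self.dipole_per_area:.3g} D/nm^2{flag}"


def adlayer_dipole(
    config: AtomConfiguration,
    region: np.ndarray | Callable[[AtomConfiguration], np.ndarray] | None = None,
    area_nm2: float | None = None,
    neutrality_tol: float = 1e-6,
) -> DipoleProfile:
    """Normal component of the region dipole per unit surface area.

    mu_z = sum_i q_i z_i in e*Angstrom, converted with 1 e*A = 4.8032 D and
    divided by the lateral area in nm^2.  The dipole of a net-neutral region
    is independent of the z origin; non-neutral regions are flagged.
    """
    if config.charges is None:
        raise ValidationError("configuration has no charges")
    if callable(region):
        mask = np.asarray(region(config), dtype=bool)
    elif region is not None:
        mask = np.asarray(region, dtype=bool)
    else:
        mask = np.ones(config.n_atoms, dtype=bool)
    q = np.asarray(config.charges, dtype=float)[mask]
    z = config.positions[mask, 2]
    mu = float(np.dot(q, z))
    net = float(q.sum())
    if area_nm2 is None:
        area_nm2 = config.lateral_area / 100.0
    mu_debye = mu * E_ANGSTROM_TO_DEBYE
    return DipoleProfile(
        dipole_e_angstrom=mu,
        dipole_debye=mu_debye,
        area_nm2=area_nm2,
        dipole_per_area=mu_debye / area_nm2,
        net_charge=net,
        origin_dependent=abs(net) > neutrality_tol,
    )
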