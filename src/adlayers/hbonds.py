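"""Geometric hydrogen-bond detection and intra/interchain classification.

An O-H...O triplet is hydrogen-bonded when the O-O distance is strictly
below 3.3 A and the angle at the hydrogen is at least 140 degrees; both
thresholds, the donor/acceptor element sets and the angle convention (at H
or at the donor O) are configurable.  Hydrogens are assigned to their donor
by a covalent-distance cutoff (default 1.2 A) since no bond topology is
read.  An oxygen may act as donor and acceptor at the same time; bonds are
counted directionally (donor -> acceptor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ClassificationError, ValidationError
from .structures import AtomConfiguration, minimum_image_displacement

__all__ = ["HBondCriterion", "HBond", "HBondSet", "HBondClassification",
           "find_hbonds", "classify_hbonds"]


@dataclass(frozen=True)
class HBondCriterion:
    max_oo_distance: float = 3.3         # A, strict upper bound
    min_angle: float = 140.0             # degrees, inclusive lower bound
    donor_elements: frozenset[str] = frozenset({"O"})
    acceptor_elements: frozenset[str] = frozenset({"O"})
    max_covalent_oh: float = 1.2         # A, donor-H assignment cutoff
    angle_at: str = "H"                  # "H" or "donor"

    def __post_init__(self) -> None:
        if self.max_oo_distance <= 0:
            raise ValidationError("distance cutoff must be positive")
        if not 0.0 < self.min_angle <= 180.0:
            raise ValidationError("angle cutoff must be in (0, 180]")
        if self.angle_at not in ("H", "donor"):
            raise ValidationError("angle_at must be 'H' or 'donor'")


@dataclass(frozen=True)
class HBond:
    donor: int        # donor O atom index
    hydrogen: int
    acceptor: int     # acceptor O atom index
    distance: float   # O-O, A
    angle: float      # degrees, at the configured vertex


@dataclass
class HBondSet:
    bonds: list[HBond]
    criterion: HBondCriterion

    def __len__(self) -> int:
        return len(self.bonds)

    def __iter__(self):
        return iter(self.bonds)

    def as_arrays(self):
        if not self.bonds:
            return np.empty((0, 3), dtype=int), np.empty(0), np.empty(0)
        idx = np.array([(b.donor, b.hydrogen, b.acceptor) for b in self.bonds])
        d = np.array([b.distance for b in self.bonds])
        a = np.array([b.angle for b in self.bonds])
        return idx, d, a


def _min_image(config: AtomConfiguration, delta: np.ndarray) -> np.ndarray:
    return minimum_image_displacement(delta, config.box, config.periodic)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def find_hbonds(
    config: AtomConfiguration, criterion: HBondCriterion = HBondCriterion()
) -> HBondSet:
    """Detect all donor-H...acceptor triplets satisfying the criterion.

    Distances use the minimum-image convention along the periodic axes.
    A configuration without hydrogens yields an empty set with a warning.
    """
    elements = np.asarray(config.elements, dtype=object)
    if elements.ndim != 1 or len(elements) != config.n_atoms:
        raise ValidationError("configuration must carry per-atom element labels")
    donors = np.flatnonzero(np.isin(elements, list(criterion.donor_elements)))
    acceptors = np.flatnonzero(np.isin(elements, list(criterion.acceptor_elements)))
    hydrogens = np.flatnonzero(elements == "H")
    if len(hydrogens) == 0:
        warnings.warn("configuration has no hydrogen atoms; no bonds detected",
                      stacklevel=2)
        return HBondSet(bonds=[], criterion=criterion)
    if len(donors) == 0 or len(acceptors) == 0:
        return HBondSet(bonds=[], criterion=criterion)
    pos = config.positions

    # assign each H to its nearest donor-element atom within the covalent cutoff
    dh = _min_image(config, pos[hydrogens][:, None, :] - pos[donors][None, :, :])
    dh_dist = np.linalg.norm(dh, axis=2)
    nearest = np.argmin(dh_dist, axis=1)
    covalent = dh_dist[np.arange(len(hydrogens)), nearest] <= criterion.max_covalent_oh
    h_of_donor: dict[int, list[int]] = {}
    for h_i, d_i, ok in zip(hydrogens, donors[nearest], covalent):
        if ok:
            h_of_donor.setdefault(int(d_i), []).append(int(h_i))

    # candidate O-O pairs within the distance cutoff
    dd = _min_image(config, pos[donors][:, None, :] - pos[acceptors][None, :, :])
    oo = np.linalg.norm(dd, axis=2)
    bonds: list[HBond] = []
    for di, donor in enumerate(donors):
        hs = h_of_donor.get(int(donor))
        if not hs:
            continue
        close = np.flatnonzero(oo[di] < criterion.max_oo_distance)
        for ai in close:
            acceptor = int(acceptors[ai])
            if acceptor == int(donor):
                continue
            for h in hs:
                if criterion.angle_at == "H":
                    v1 = _min_image(config, pos[donor] - pos[h])
                    v2 = _min_image(config, pos[acceptor] - pos[h])
                else:
                    v1 = _min_image(config, pos[h] - pos[donor])
                    v2 = _min_image(config, pos[acceptor] - pos[donor])
                ang = _angle_deg(np.atleast_1d(v1), np.atleast_1d(v2))
                if ang >= criterion.min_angle:
                    bonds.append(
                        HBond(int(donor), int(h), acceptor, float(oo[di, ai]), ang)
                    )
    return HBondSet(bonds=bonds, criterion=criterion)


@dataclass
class HBondClassification:
    intra: int
    inter: int
    intra_per_residue: float | None = None
    inter_per_residue: float | None = None

    @property
    def inter_to_intra_ratio(self) -> float:
        return self.inter / self.intra if self.intra else float("nan")

    def summary(self) -> str:
        return f"{self.intra} intrachain, {self.inter} interchain hydrogen bonds"


def classify_hbonds(
    bonds: HBondSet, config: AtomConfiguration, n_residues: int | None = None
) -> HBondClassification:
    """Split bonds into intra- and interchain by the chain_id of donor/acceptor."""
    if config.chain_id is None:
        raise ClassificationError("configuration has no chain_id labels")
    chains = np.asarray(config.chain_id, dtype=object)
    intra = sum(1 for b in bonds if chains[b.donor] == chains[b.acceptor])
    inter = len(bonds) - intra
    per_intra = intra / n_residues if n_residues else None
    per_inter = inter / n_residues if n_residues else None
    return HBondClassification(
        intra=intra, inter=inter,
        intra_per_residue=per_intra, inter_per_residue=per_inter,
    )
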