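"""Domain types for conformers and pharmacophore features, and the steric
descriptors (monopole volume, shape quadrupole, feature counts) plus the
conformer eligibility rules used to admit compounds into the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import gaussian_volume, kappa_from_radius, product_overlap_terms
from .config import DEFAULT_CONFIG, ScoringConfig

ORGANIC_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"})

FEATURE_TYPES = ("donor", "acceptor", "cation", "anion", "hydrophobe", "ring")

#: eligibility bounds: single covalent component, organic elements only,
#: at most 50 heavy atoms, 15 effective rotors, 5 undefined stereocenters
MAX_HEAVY_ATOMS = 50
MAX_ROTORS = 15
MAX_UNDEFINED_STEREO = 5


@dataclass(frozen=True)
class Atom:
    """One heavy atom: chemical symbol, position (A) and sphere radius (A)."""

    element: str
    position: np.ndarray
    radius: float = 1.70

    def __post_init__(self) -> None:
        if self.element not in ORGANIC_ELEMENTS:
            raise ValueError(f"element {self.element!r} outside the organic set")
        if self.radius <= 0:
            raise ValueError("atom radius must be positive")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))


@dataclass(frozen=True)
class FeaturePoint:
    """Typed pharmacophore point (color atom).

    ``member_atoms`` holds 1-based indices of the atoms the feature was
    derived from; when built from members the position is their centroid.
    """

    ftype: str
    position: np.ndarray
    member_atoms: tuple[int, ...] = ()
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(self, "member_atoms", tuple(int(i) for i in self.member_atoms))

    @classmethod
    def from_members(
        cls, ftype: str, atoms: list[Atom], member_atoms: tuple[int, ...], radius: float = 1.0
    ) -> "FeaturePoint":
        """Build a feature at the centroid of the given 1-based member atoms."""
        if not member_atoms:
            raise ValueError("feature needs at least one member atom")
        for i in member_atoms:
            if not 1 <= i <= len(atoms):
                raise ValueError(f"member atom index {i} out of range")
        centroid = np.mean([atoms[i - 1].position for i in member_atoms], axis=0)
        return cls(ftype=ftype, position=centroid, member_atoms=tuple(member_atoms), radius=radius)


@dataclass
class Conformer:
    """A single 3-D conformer: heavy atoms plus typed feature points.

    Hydrogens passed to the constructor are dropped; all scoring and all
    descriptors are heavy-atom only.
    """

    cid: int
    atoms: list[Atom]
    features: list[FeaturePoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atoms = [a for a in self.atoms if a.element != "H"]
        if not self.atoms:
            raise ValueError("no atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def feature_coords(self, ftype: str | None = None) -> np.ndarray:
        feats = self.features if ftype is None else [f for f in self.features if f.ftype == ftype]
        if not feats:
            return np.zeros((0, 3))
        return np.array([f.position for f in feats], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Copy with ``x -> R x + t`` applied to atoms and features."""
        atoms = [
            Atom(a.element, rotation @ a.position + translation, a.radius) for a in self.atoms
        ]
        feats = [
            FeaturePoint(f.ftype, rotation @ f.position + translation, f.member_atoms, f.radius)
            for f in self.features
        ]
        return Conformer(self.cid, atoms, feats)


@dataclass(frozen=True)
class DescriptorSet:
    """Per-conformer steric descriptor row."""

    cid: int
    heavy_atom_count: int
    volume: float
    q: tuple[float, float, float]
    feature_counts: dict[str, int]
    total_features: int


def monopole_volume(conf: Conformer, config: ScoringConfig = DEFAULT_CONFIG.scoring) -> float:
    """First-order inclusion-exclusion Gaussian volume (A^3).

    V = sum_i v_i - sum_{i<j} V^prod_ij, where v_i is the calibrated
    isolated-atom volume 4/3*pi*R_i^3 and V^prod_ij the two-Gaussian
    product integral.  Rigid-motion invariant; additive over far-separated
    fragments.
    """
    pos = conf.coords()
    radii = conf.radii()
    kappas = np.atleast_1d(kappa_from_radius(radii, config.amplitude))
    singles = float(np.sum(gaussian_volume(radii)))
    terms = product_overlap_terms(pos, kappas, pos, kappas, config.amplitude, config.skip_exponent)
    pairs = float(np.triu(terms, k=1).sum())
    return singles - pairs


def shape_quadrupole(
    conf: Conformer, config: ScoringConfig = DEFAULT_CONFIG.scoring
) -> tuple[float, float, float]:
    """Principal second moments (Qx >= Qy >= Qz, A^5) of the Gaussian density.

    The density is the plain sum of atom Gaussians; moments are taken about
    the density centroid and diagonalised, giving a sense of conformer
    length, width and height.  No mass weighting, no trace removal.
    """
    pos = conf.coords()
    radii = conf.radii()
    kappas = np.atleast_1d(kappa_from_radius(radii, config.amplitude))
    weights = np.atleast_1d(gaussian_volume(radii))  # per-atom density integral
    centroid = (weights[:, None] * pos).sum(axis=0) / weights.sum()
    d = pos - centroid
    m = np.einsum("i,ij,ik->jk", weights, d, d)
    # each atom Gaussian contributes an isotropic v_i/(2*kappa_i) about its centre
    m += np.diag(np.full(3, float(np.sum(weights / (2.0 * kappas)))))
    eig = np.linalg.eigvalsh(m)[::-1]
    return (float(eig[0]), float(eig[1]), float(eig[2]))


def feature_counts(conf: Conformer) -> dict[str, int]:
    """Per-type feature counts plus the total under key ``'total'``."""
    counts = {t: 0 for t in FEATURE_TYPES}
    for f in conf.features:
        counts[f.ftype] += 1
    counts["total"] = sum(counts[t] for t in FEATURE_TYPES)
    return counts


def eligibility_from_metadata(
    n_heavy: int,
    elements: list[str] | set[str],
    n_components: int = 1,
    rotor_count: int = 0,
    undefined_stereo: int = 0,
) -> tuple[bool, list[str]]:
    """Admission rules on raw molecule metadata: single covalent component,
    organic elements only, <= 50 heavy atoms, <= 15 effective rotors, <= 5
    undefined stereocenters.  Returns (passed, reasons) with one reason per
    violated rule.
    """
    reasons: list[str] = []
    if n_components > 1:
        reasons.append("multiple covalent components")
    bad = sorted(set(elements) - ORGANIC_ELEMENTS)
    if bad:
        reasons.append(f"non-organic element: {', '.join(bad)}")
    if n_heavy > MAX_HEAVY_ATOMS:
        reasons.append("too many heavy atoms")
    if rotor_count > MAX_ROTORS:
        reasons.append("too many effective rotors")
    if undefined_stereo > MAX_UNDEFINED_STEREO:
        reasons.append("too many undefined stereocenters")
    return (not reasons, reasons)


def eligibility_check(
    conf: Conformer,
    n_components: int = 1,
    rotor_count: int = 0,
    undefined_stereo: int = 0,
) -> tuple[bool, list[str]]:
    """`eligibility_from_metadata` applied to a built Conformer."""
    return eligibility_from_metadata(
        n_heavy=conf.n_atoms,
        elements={a.element for a in conf.atoms},
        n_components=n_components,
        rotor_count=rotor_count,
        undefined_stereo=undefined_stereo,
    )


def check_elements(elements: list[str]) -> bool:
    """True iff every symbol is in the organic element set."""
    return all(e in ORGANIC_ELEMENTS for e in elements)


def describe(conf: Conformer, config: ScoringConfig = DEFAULT_CONFIG.scoring) -> DescriptorSet:
    """Assemble the full descriptor row for one conformer."""
    counts = feature_counts(conf)
    total = counts.pop("total")
    return DescriptorSet(
        cid=conf.cid,
        heavy_atom_count=conf.n_atoms,
        volume=monopole_volume(conf, config),
        q=shape_quadrupole(conf, config),
        feature_counts=counts,
        total_features=total,
    )
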