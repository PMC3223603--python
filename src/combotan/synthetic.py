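"""Synthetic conformer populations and assay studies.

The generator stands in for a compound archive: it emits self-avoiding
3-D chains whose heavy-atom and pharmacophore-feature count distributions
match the archive-wide summary statistics (heavy atoms 24.6 +/- 6.4
truncated to [5, 50]; per-type feature rates below), and assay outcome
tables in two modes:

* ``null`` - tested compounds are an i.i.d. random draw from the
  population, so NN and NI pairs have identical score distributions;
* ``clustered`` - the noninactives are jittered copies of one or two
  template conformers (a compound-series structure), injecting a positive
  NN-NI similarity separation that downstream outlier detection should
  recover.

Every draw goes through one ``numpy.random.Generator`` in a fixed,
documented order, so a seed reproduces a study bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assays import AssayTable
from .molecules import FEATURE_TYPES, Atom, Conformer, FeaturePoint

#: per-type feature count rates (mean, sd) of the emulated archive
DEFAULT_FEATURE_RATES: dict[str, tuple[float, float]] = {
    "acceptor": (2.9, 1.6),
    "donor": (1.1, 1.0),
    "anion": (0.2, 0.4),
    "cation": (0.6, 0.8),
    "hydrophobe": (0.3, 0.6),
    "ring": (3.0, 1.2),
}


@dataclass(frozen=True)
class AssayPlan:
    """Recipe for one synthetic assay."""

    category: str = "screening"
    n_noninactive: int = 5
    n_inactive: int = 7
    mode: str = "null"                 # "null" or "clustered"
    sigma: float = 0.25                # clustered-mode perturbation SD, A
    feature_keep_prob: float = 0.9     # clustered-mode feature retention

    def __post_init__(self) -> None:
        if self.mode not in ("null", "clustered"):
            raise ValueError(f"unknown assay mode {self.mode!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_compounds: int = 200
    atom_count_mean: float = 24.6
    atom_count_sd: float = 6.4
    atom_count_range: tuple[int, int] = (5, 50)
    feature_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_RATES)
    )
    bond_length: float = 1.54
    bond_angle_deg: float = 109.5
    bond_angle_jitter_deg: float = 10.0
    min_nonbonded: float = 2.0
    hetero_prob: float = 0.25          # chance an atom is N or O instead of C
    assay_plan: tuple[AssayPlan, ...] = ()


@dataclass
class SyntheticStudy:
    conformers: list[Conformer]
    assays: list[AssayTable]
    truth: dict[int, dict]             # aid -> {"mode": ..., "sigma": ...}


def truncated_normal_int(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    """Rounded normal draw rejected until it lands in [lo, hi]."""
    for _ in range(10_000):
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated normal sampler failed to converge")


def _chain_positions(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    """Self-avoiding chain with fixed bond length and tetrahedral-ish angles."""
    length = config.bond_length
    for _ in range(50):  # whole-chain restarts
        pos = np.zeros((n, 3))
        if n > 1:
            pos[1] = [length, 0.0, 0.0]
        ok = True
        for k in range(2, n):
            placed = False
            for _ in range(60):
                prev = pos[k - 1] - pos[k - 2]
                prev /= np.linalg.norm(prev)
                # orthonormal frame around the previous bond
                helper = np.array([1.0, 0.0, 0.0])
                if abs(prev @ helper) > 0.9:
                    helper = np.array([0.0, 1.0, 0.0])
                e1 = np.cross(prev, helper)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(prev, e1)
                theta = math.radians(
                    config.bond_angle_deg + rng.normal(0.0, config.bond_angle_jitter_deg)
                )
                phi = rng.uniform(0.0, 2.0 * math.pi)
                # angle between successive bond vectors is pi - bond angle
                direction = -math.cos(theta) * prev + math.sin(theta) * (
                    math.cos(phi) * e1 + math.sin(phi) * e2
                )
                cand = pos[k - 1] + length * direction
                d = np.linalg.norm(pos[: k - 1] - cand, axis=1)
                if d.min() >= config.min_nonbonded:
                    pos[k] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise RuntimeError("self-avoiding chain placement failed")


def random_conformer(
    rng: np.random.Generator,
    n_atoms: int,
    cid: int = 0,
    config: GeneratorConfig = GeneratorConfig(),
) -> Conformer:
    """One synthetic conformer with explicit, generator-assigned features.

    Draw order: chain geometry, then elements, then per-type feature counts
    and member atoms in canonical feature-type order.
    """
    if not 1 <= n_atoms <= 50:
        raise ValueError("n_atoms must be in [1, 50]")
    pos = _chain_positions(rng, n_atoms, config)
    elements = []
    for _ in range(n_atoms):
        if rng.random() < config.hetero_prob:
            elements.append("N" if rng.random() < 0.5 else "O")
        else:
            elements.append("C")
    atoms = [Atom(e, p) for e, p in zip(elements, pos)]
    features: list[FeaturePoint] = []
    for ftype in FEATURE_TYPES:
        mean, sd = config.feature_rates.get(ftype, (0.0, 0.0))
        count = min(truncated_normal_int(rng, mean, sd, 0, 50), n_atoms)
        if count:
            members = rng.choice(n_atoms, size=count, replace=False)
            for m in sorted(int(i) for i in members):
                features.append(FeaturePoint.from_members(ftype, atoms, (m + 1,)))
    return Conformer(cid=cid, atoms=atoms, features=features)


def perturb_conformer(
    rng: np.random.Generator,
    conf: Conformer,
    sigma: float,
    feature_keep_prob: float = 1.0,
    cid: int | None = None,
) -> Conformer:
    """Jittered copy: i.i.d. Gaussian coordinate noise (SD sigma per axis);
    features follow their member atoms and are each kept with the given
    probability.  A fresh cid marks it as a distinct compound."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    noise = rng.normal(0.0, sigma, size=(conf.n_atoms, 3)) if sigma > 0 else np.zeros((conf.n_atoms, 3))
    atoms = [Atom(a.element, a.position + n, a.radius) for a, n in zip(conf.atoms, noise)]
    features = []
    for f in conf.features:
        if rng.random() < feature_keep_prob:
            features.append(FeaturePoint.from_members(f.ftype, atoms, f.member_atoms, f.radius))
    return Conformer(cid=conf.cid if cid is None else cid, atoms=atoms, features=features)


def sample_population(config: GeneratorConfig) -> list[Conformer]:
    """Population of conformers with cids 1..n_compounds."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.atom_count_range
    out = []
    for cid in range(1, config.n_compounds + 1):
        n = truncated_normal_int(rng, config.atom_count_mean, config.atom_count_sd, lo, hi)
        out.append(random_conformer(rng, n, cid=cid, config=config))
    return out


def synthesize_study(config: GeneratorConfig) -> SyntheticStudy:
    """Population plus assay outcome tables per the assay plan.

    Null assays draw their tested compounds i.i.d. from the population.
    Clustered assays add new compounds: jittered copies of one or two
    template conformers become the noninactives; inactives come from the
    background population.  Ground-truth modes are returned for recovery
    experiments.
    """
    conformers = sample_population(config)
    rng = np.random.default_rng([config.seed, 1])
    assays: list[AssayTable] = []
    truth: dict[int, dict] = {}
    next_cid = config.n_compounds + 1
    for i, plan in enumerate(config.assay_plan):
        aid = 1001 + i
        n_total = plan.n_noninactive + plan.n_inactive
        if n_total > config.n_compounds:
            raise ValueError(f"assay {aid} larger than population")
        rows: list[tuple[int, str]] = []
        if plan.mode == "null":
            chosen = rng.choice(config.n_compounds, size=n_total, replace=False) + 1
            for j, cid in enumerate(int(c) for c in chosen):
                rows.append((cid, "Active" if j < plan.n_noninactive else "Inactive"))
        else:
            n_templates = 1 if plan.n_noninactive < 4 else int(rng.integers(1, 3))
            template_idx = rng.choice(config.n_compounds, size=n_templates, replace=False) + 1
            templates = [conformers[t - 1] for t in template_idx]
            for j in range(plan.n_noninactive):
                child = perturb_conformer(
                    rng,
                    templates[j % n_templates],
                    plan.sigma,
                    plan.feature_keep_prob,
                    cid=next_cid,
                )
                conformers.append(child)
                rows.append((next_cid, "Active"))
                next_cid += 1
            background = rng.choice(config.n_compounds, size=plan.n_inactive, replace=False) + 1
            rows.extend((int(c), "Inactive") for c in background)
        assays.append(AssayTable.from_rows(aid, plan.category, rows))
        truth[aid] = {"mode": plan.mode, "sigma": plan.sigma if plan.mode == "clustered" else 0.0}
    return SyntheticStudy(conformers=conformers, assays=assays, truth=truth)
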