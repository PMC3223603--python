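"""Gaussian molecular shape overlap and the shape-Tanimoto (ST) score.

ST(A, B) = V_AB / (V_AA + V_BB - V_AB), where V_AB is the product-density
overlap integral between the atom-Gaussian representations of the two
conformers and V_AA, V_BB their self overlaps.  ST is 1 for identical
conformers in identical poses and tends to 0 as they separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import (
    bounding_grid,
    grid_density,
    kappa_from_radius,
    product_overlap,
)
from .config import DEFAULT_CONFIG, ScoringConfig
from .molecules import Conformer
from .transforms import RigidTransform


@dataclass(frozen=True)
class OverlapTerms:
    """Self and cross density-overlap integrals (A^3)."""

    v_aa: float
    v_bb: float
    v_ab: float

    def tanimoto(self) -> float:
        denom = self.v_aa + self.v_bb - self.v_ab
        assert denom > 0, "degenerate Tanimoto denominator"
        return self.v_ab / denom


def _shape_arrays(conf: Conformer, config: ScoringConfig):
    pos = conf.coords()
    kappas = np.atleast_1d(kappa_from_radius(conf.radii(), config.amplitude))
    return pos, kappas


def pair_overlap(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: RigidTransform,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> float:
    """Cross overlap V_AB (A^3) with ``transform`` applied to B."""
    transform.validate()
    pos_a, kap_a = _shape_arrays(conf_a, config)
    pos_b, kap_b = _shape_arrays(conf_b, config)
    return product_overlap(
        pos_a, kap_a, transform.apply(pos_b), kap_b, config.amplitude, config.skip_exponent
    )


def self_overlap(conf: Conformer, config: ScoringConfig = DEFAULT_CONFIG.scoring) -> float:
    """Self overlap V_AA (A^3); strictly positive for any nonempty conformer."""
    pos, kap = _shape_arrays(conf, config)
    v = product_overlap(pos, kap, pos, kap, config.amplitude, config.skip_exponent)
    assert v > 0
    return v


def overlap_terms(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: RigidTransform,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> OverlapTerms:
    return OverlapTerms(
        v_aa=self_overlap(conf_a, config),
        v_bb=self_overlap(conf_b, config),
        v_ab=pair_overlap(conf_a, conf_b, transform, config),
    )


def shape_tanimoto(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: RigidTransform,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> float:
    """Shape-Tanimoto score at the given relative pose; in [0, 1]."""
    st = overlap_terms(conf_a, conf_b, transform, config).tanimoto()
    # guard against roundoff excursions just outside [0, 1]
    return float(min(max(st, 0.0), 1.0))


def grid_overlap_oracle(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: RigidTransform,
    spacing: float = 0.1,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> float:
    """Numeric quadrature of the product density; test oracle only.

    Integrates rho_A * rho_B over a regular grid covering both conformers
    with 4 A padding.
    """
    if conf_a.n_atoms == 0 or conf_b.n_atoms == 0:
        return 0.0
    pos_a, kap_a = _shape_arrays(conf_a, config)
    pos_b, kap_b = _shape_arrays(conf_b, config)
    pos_b = transform.apply(pos_b)
    grid, cell = bounding_grid(np.vstack([pos_a, pos_b]), spacing)
    rho_a = grid_density(pos_a, kap_a, config.amplitude, grid)
    rho_b = grid_density(pos_b, kap_b, config.amplitude, grid)
    return float(np.sum(rho_a * rho_b) * cell)
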