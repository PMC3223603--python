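"""Feature ("color") overlap, the color-Tanimoto (CT) score and ComboT.

Each pharmacophore feature is a fictitious Gaussian sphere of one of six
independent types (donor, acceptor, cation, anion, hydrophobe, ring).
Only same-type features overlap.  CT is the Tanimoto of the type-summed
overlap volumes:

    CT = sum_f V_AB^f / (sum_f V_AA^f + sum_f V_BB^f - sum_f V_AB^f)

with CT := 0 when both conformers are featureless.  ComboT = ST + CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import bounding_grid, grid_density, kappa_from_radius, product_overlap
from .config import DEFAULT_CONFIG, ScoringConfig
from .molecules import FEATURE_TYPES, Conformer
from .transforms import RigidTransform


@dataclass(frozen=True)
class ColorOverlapTerms:
    """Per-feature-type self and cross overlap volumes (A^3)."""

    v_aa: dict[str, float]
    v_bb: dict[str, float]
    v_ab: dict[str, float]


def _color_arrays(conf: Conformer, ftype: str, config: ScoringConfig):
    pos = conf.feature_coords(ftype)
    kappa = kappa_from_radius(config.color_radius, config.amplitude)
    return pos, np.full(len(pos), kappa)


def color_overlap(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: RigidTransform,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> ColorOverlapTerms:
    """Per-type Gaussian feature overlaps with ``transform`` applied to B.

    Cross-type overlaps are identically zero (the six types are
    independent), so a type missing from either conformer contributes no
    cross term.
    """
    transform.validate()
    v_aa: dict[str, float] = {}
    v_bb: dict[str, float] = {}
    v_ab: dict[str, float] = {}
    for ftype in FEATURE_TYPES:
        pos_a, kap_a = _color_arrays(conf_a, ftype, config)
        pos_b, kap_b = _color_arrays(conf_b, ftype, config)
        pos_bt = transform.apply(pos_b) if len(pos_b) else pos_b
        v_aa[ftype] = product_overlap(
            pos_a, kap_a, pos_a, kap_a, config.amplitude, config.skip_exponent
        )
        v_bb[ftype] = product_overlap(
            pos_b, kap_b, pos_b, kap_b, config.amplitude, config.skip_exponent
        )
        v_ab[ftype] = product_overlap(
            pos_a, kap_a, pos_bt, kap_b, config.amplitude, config.skip_exponent
        )
    return ColorOverlapTerms(v_aa=v_aa, v_bb=v_bb, v_ab=v_ab)


def color_tanimoto(terms: ColorOverlapTerms) -> float:
    """CT from summed per-type overlaps; 0 when both sides are featureless."""
    s_aa = sum(terms.v_aa.values())
    s_bb = sum(terms.v_bb.values())
    s_ab = sum(terms.v_ab.values())
    if s_aa == 0.0 and s_bb == 0.0:
        return 0.0
    denom = s_aa + s_bb - s_ab
    assert denom > 0, "degenerate color-Tanimoto denominator"
    return float(min(max(s_ab / denom, 0.0), 1.0))


def color_tanimoto_at(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: RigidTransform,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> float:
    return color_tanimoto(color_overlap(conf_a, conf_b, transform, config))


def combo_tanimoto(st: float, ct: float) -> float:
    """ComboT = ST + CT, range [0, 2]."""
    if not (0.0 <= st <= 1.0):
        raise ValueError(f"ST out of range: {st}")
    if not (0.0 <= ct <= 1.0):
        raise ValueError(f"CT out of range: {ct}")
    return st + ct


def color_grid_oracle(
    conf_a: Conformer,
    conf_b: Conformer,
    transform: RigidTransform,
    spacing: float = 0.1,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> float:
    """Quadrature of the type-summed cross feature overlap; test oracle only."""
    total = 0.0
    for ftype in FEATURE_TYPES:
        pos_a, kap_a = _color_arrays(conf_a, ftype, config)
        pos_b, kap_b = _color_arrays(conf_b, ftype, config)
        if len(pos_a) == 0 or len(pos_b) == 0:
            continue
        pos_bt = transform.apply(pos_b)
        grid, cell = bounding_grid(np.vstack([pos_a, pos_bt]), spacing)
        rho_a = grid_density(pos_a, kap_a, config.amplitude, grid)
        rho_b = grid_density(pos_bt, kap_b, config.amplitude, grid)
        total += float(np.sum(rho_a * rho_b) * cell)
    return total
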