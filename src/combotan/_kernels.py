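"""Array-level Gaussian math shared by the shape and color scoring paths.

Every atom (or feature point) is a single spherical Gaussian

    rho_i(r) = p * exp(-kappa_i * |r - r_i|^2)

whose width ``kappa`` is calibrated from the sphere radius so that the
isolated-atom density integral p * (pi/kappa)^(3/2) equals the hard-sphere
volume 4/3*pi*R^3.  All overlap integrals here are density products
(first order, no triple terms), which keep the Tanimoto identity case at
exactly 1 and are analytic and differentiable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kappa_from_radius",
    "gaussian_volume",
    "product_overlap",
    "product_overlap_terms",
    "overlap_gradient_points",
    "grid_density",
]


def kappa_from_radius(radius: float | np.ndarray, amplitude: float) -> float | np.ndarray:
    """Gaussian decay constant (A^-2) for a sphere of the given radius."""
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise ValueError("radius must be positive")
    kappa = np.pi * (3.0 * amplitude / (4.0 * np.pi * radius**3)) ** (2.0 / 3.0)
    return float(kappa) if kappa.ndim == 0 else kappa


def gaussian_volume(radius: float | np.ndarray) -> float | np.ndarray:
    """Isolated-atom density integral; equals the hard-sphere volume by calibration."""
    radius = np.asarray(radius, dtype=float)
    vol = 4.0 / 3.0 * np.pi * radius**3
    return float(vol) if vol.ndim == 0 else vol


def _pair_constants(kappa_a: np.ndarray, kappa_b: np.ndarray, amplitude: float):
    """Prefactor c_ij and decay gamma_ij of the two-Gaussian product integral."""
    ksum = kappa_a[:, None] + kappa_b[None, :]
    gamma = kappa_a[:, None] * kappa_b[None, :] / ksum
    coeff = amplitude**2 * (np.pi / ksum) ** 1.5
    return coeff, gamma


def product_overlap_terms(
    pos_a: np.ndarray,
    kappa_a: np.ndarray,
    pos_b: np.ndarray,
    kappa_b: np.ndarray,
    amplitude: float,
    skip_exponent: float = 30.0,
) -> np.ndarray:
    """Matrix of pairwise product-density integrals c_ij * exp(-gamma_ij d_ij^2)."""
    if len(pos_a) == 0 or len(pos_b) == 0:
        return np.zeros((len(pos_a), len(pos_b)))
    coeff, gamma = _pair_constants(kappa_a, kappa_b, amplitude)
    d2 = np.sum((pos_a[:, None, :] - pos_b[None, :, :]) ** 2, axis=-1)
    arg = gamma * d2
    terms = np.where(arg < skip_exponent, coeff * np.exp(-np.minimum(arg, 700.0)), 0.0)
    return terms


def product_overlap(
    pos_a: np.ndarray,
    kappa_a: np.ndarray,
    pos_b: np.ndarray,
    kappa_b: np.ndarray,
    amplitude: float,
    skip_exponent: float = 30.0,
) -> float:
    """Total product-density overlap integral between two Gaussian point sets."""
    return float(
        product_overlap_terms(pos_a, kappa_a, pos_b, kappa_b, amplitude, skip_exponent).sum()
    )


def overlap_gradient_points(
    pos_a: np.ndarray,
    kappa_a: np.ndarray,
    pos_b: np.ndarray,
    kappa_b: np.ndarray,
    amplitude: float,
    skip_exponent: float = 30.0,
) -> tuple[float, np.ndarray]:
    """Overlap V and its gradient dV/d(pos_b), shape (nb, 3).

    dV/db_j = sum_i 2 * c_ij * gamma_ij * exp(.) * (a_i - b_j)
    """
    if len(pos_a) == 0 or len(pos_b) == 0:
        return 0.0, np.zeros((len(pos_b), 3))
    coeff, gamma = _pair_constants(kappa_a, kappa_b, amplitude)
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    d2 = np.sum(diff**2, axis=-1)
    arg = gamma * d2
    keep = arg < skip_exponent
    e = np.where(keep, coeff * np.exp(-np.minimum(arg, 700.0)), 0.0)
    grad = np.einsum("ij,ijk->jk", 2.0 * gamma * e, diff)
    return float(e.sum()), grad


def grid_density(
    points: np.ndarray,
    kappas: np.ndarray,
    amplitude: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Sum of atom Gaussians evaluated on an (m, 3) grid; returns (m,)."""
    rho = np.zeros(len(grid))
    for p, k in zip(points, kappas):
        d2 = np.sum((grid - p) ** 2, axis=1)
        rho += amplitude * np.exp(-k * d2)
    return rho


def bounding_grid(points: np.ndarray, spacing: float, pad: float = 4.0):
    """Regular grid covering the points with padding; returns (m,3) grid and cell volume."""
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)
    return grid, spacing**3
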