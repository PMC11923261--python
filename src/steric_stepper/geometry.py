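"""Confined free-end probability densities of the walker-foothold complex.

Four track designs are modelled by unnormalized densities for the position
``r = (x, y, z)`` of the free end, with the foothold tether at the origin and
``z`` the out-of-plane axis:

``baseline``
    ``z * exp(-beta_k/2 (|r| - L)^2)`` for ``z >= 0`` — a hemispherical
    harmonic shell with a Rayleigh-type ``z`` prefactor from surface
    tethering.
``tail``
    the harmonic shell multiplied by a damped Fourier sine series in ``z``
    that vanishes at ``z = 0`` and ``z = z_max`` (slit confinement by a
    stiff double-stranded tail; no ``z`` prefactor).
``trench``
    the baseline density multiplied by ``cos(pi y / h_max)`` on
    ``|y| <= h_max/2`` (single-mode lateral confinement by trench walls).
``trench_series``
    the full damped cosine series variant of the trench, with its own
    stiffness ``beta_k_dprime``.
``combined``
    tail density times the trench cosine factor (tail + trench, no ``z``
    prefactor).

All densities are hard zero outside their stated support, and negative
values produced by truncating the series are clipped to zero (the clipped
mass fraction is available as a diagnostic).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from .params import (
    SCENARIOS,
    TAIL_SCENARIOS,
    TRENCH_SCENARIOS,
    ConfinementParams,
    ParameterError,
)

__all__ = [
    "eval_density",
    "density_xyz",
    "bounding_box",
    "normalization_constant",
    "marginal_density",
    "clipped_mass_fraction",
]


class GridCoverageError(ValueError):
    """A grid or bounding box fails to cover the density support."""


# -- scenario factor functions -------------------------------------------------
#
# Every density factorizes as  radial(|r|) * zfac(z) * yfac(y); the radial
# reduction and the samplers reuse these factors so all code paths share one
# set of formulas.

def _slit_series(z: np.ndarray, z_max: float, beta_k: float,
                 beta_k_prime: float, n_terms: int,
                 clip: bool = True) -> np.ndarray:
    """Damped sine series sum_n sin(n pi z / z_max) c_n on [0, z_max]."""
    n = np.arange(1, n_terms + 1)
    coeff = np.exp(-0.5 * beta_k * (n * math.pi / (beta_k_prime * z_max)) ** 2)
    zz = np.asarray(z, dtype=float)
    out = np.sin(np.multiply.outer(zz, n) * (math.pi / z_max)) @ coeff
    # strict mask: exact zeros at the slit boundaries despite sin(n pi) noise
    out = np.where((zz > 0.0) & (zz < z_max), out, 0.0)
    if clip:
        out = np.maximum(out, 0.0)
    return out


def _trench_series(y: np.ndarray, h_max: float, beta_k: float,
                   beta_k_dprime: float, n_terms: int,
                   clip: bool = True) -> np.ndarray:
    """Damped cosine series sum_m cos(m pi y / h_max) c_m on |y| <= h_max/2."""
    m = np.arange(1, n_terms + 1)
    coeff = np.exp(-0.5 * beta_k * (m * math.pi / (beta_k_dprime * h_max)) ** 2)
    yy = np.asarray(y, dtype=float)
    out = np.cos(np.multiply.outer(yy, m) * (math.pi / h_max)) @ coeff
    out = np.where(np.abs(yy) < 0.5 * h_max, out, 0.0)
    if clip:
        out = np.maximum(out, 0.0)
    return out


def _z_factor(scenario: str, z: np.ndarray, params: ConfinementParams) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if scenario in TAIL_SCENARIOS:
        return _slit_series(z, params.z_max, params.beta_k,
                            params.beta_k_prime, params.n_terms)
    # baseline / trench / trench_series keep the Rayleigh-type prefactor z
    return np.where(z >= 0.0, z, 0.0)


def _y_factor(scenario: str, y: np.ndarray, params: ConfinementParams) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if scenario == "trench_series":
        return _trench_series(y, params.h_max, params.beta_k,
                              params.beta_k_dprime, params.n_terms)
    if scenario in ("trench", "combined"):
        inside = np.abs(y) < 0.5 * params.h_max  # exact zero at the walls
        return np.where(inside, np.cos(math.pi * y / params.h_max), 0.0)
    return np.ones_like(y)


def _radial_factor(norm_r: np.ndarray, params: ConfinementParams) -> np.ndarray:
    return np.exp(-0.5 * params.beta_k * (norm_r - params.L) ** 2)


def density_xyz(scenario: str, x: np.ndarray, y: np.ndarray, z: np.ndarray,
                params: ConfinementParams) -> np.ndarray:
    """Unnormalized density on broadcastable coordinate arrays (nm).

    The y- and z-factors are evaluated on the arrays as given (they are
    elementwise, so the final product broadcasts them); callers that pass
    low-dimensional coordinate axes pay for the series factors only once
    per distinct coordinate.
    """
    params.require_for(scenario)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    nr = np.sqrt(x * x + y * y + z * z)
    return _radial_factor(nr, params) * _z_factor(scenario, z, params) \
        * _y_factor(scenario, y, params)


def eval_density(scenario: str, r: Sequence[float],
                 params: ConfinementParams) -> float | np.ndarray:
    """Unnormalized scenario density at position(s) ``r``.

    ``r`` is a 3-vector in nm, or an array of shape (..., 3).  Values are
    non-negative, hard zero outside the scenario support, and raise on
    non-finite coordinates.
    """
    r = np.asarray(r, dtype=float)
    if r.shape[-1] != 3:
        raise ValueError(f"r must have a trailing axis of length 3, got {r.shape}")
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite coordinates in r")
    out = density_xyz(scenario, r[..., 0], r[..., 1], r[..., 2], params)
    return float(out) if out.ndim == 0 else out


# -- support / bounding box ----------------------------------------------------

def bounding_box(scenario: str, params: ConfinementParams,
                 a_max: float = 0.0) -> tuple[tuple[float, float], ...]:
    """Axis-aligned box covering all but < 1e-9 of the density mass.

    ``|x|, |y| <= a_max + L + 6/sqrt(beta_k)`` (six sigma beyond the shell)
    with ``y`` and ``z`` clipped to the steric support where a trench or
    tail applies.  ``a_max`` extends the box to cover targets out to that
    offset when the box is reused as a sampling/normalization envelope.
    """
    params.require_for(scenario)
    half = a_max + params.reach
    yhalf = half
    if scenario in TRENCH_SCENARIOS:
        yhalf = min(yhalf, 0.5 * params.h_max)
    ztop = params.reach
    if scenario in TAIL_SCENARIOS:
        ztop = min(ztop, params.z_max)
    return ((-half, half), (-yhalf, yhalf), (0.0, ztop))


# -- quadrature ----------------------------------------------------------------

def _gauss_nodes(lo: float, hi: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(n)
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    return mid + half * x, half * w


def normalization_constant(scenario: str, params: ConfinementParams,
                           box: tuple | None = None, method: str = "gauss",
                           n_nodes: int = 160) -> float:
    """Integral of the unnormalized density over its support.

    The default is a tensor Gauss-Legendre rule over the bounding box,
    vectorized over all nodes; ``method='nquad'`` uses adaptive quadrature
    (slow, kept for cross-checks).
    """
    params.require_for(scenario)
    if box is None:
        box = bounding_box(scenario, params)
    if method == "nquad":
        from scipy import integrate

        val, err = integrate.nquad(
            lambda z, y, x: density_xyz(scenario, x, y, z, params),
            [box[2], box[1], box[0]],
            opts={"epsabs": 1e-10, "epsrel": 1e-8},
        )
        if not np.isfinite(val) or val <= 0 or (val > 0 and err > 1e-3 * val):
            raise GridCoverageError(
                f"quadrature did not converge (value={val}, err={err})"
            )
        return float(val)
    if method != "gauss":
        raise ValueError(f"unknown method {method!r}")
    xs, wx = _gauss_nodes(*box[0], n_nodes)
    ys, wy = _gauss_nodes(*box[1], n_nodes)
    zs, wz = _gauss_nodes(*box[2], n_nodes)
    total = 0.0
    # chunk over x to bound memory at n_nodes^2 per slab
    for xi, wxi in zip(xs, wx):
        vals = density_xyz(scenario, xi, ys[:, None], zs[None, :], params)
        total += wxi * float(wy @ vals @ wz)
    if not (np.isfinite(total) and total > 0):
        raise GridCoverageError(f"normalization integral is {total}")
    return float(total)


_AXES = {"x": 0, "y": 1, "z": 2}


def marginal_density(scenario: str, axis: str, params: ConfinementParams,
                     grid: np.ndarray, n_nodes: int = 128) -> np.ndarray:
    """Normalized 1-D marginal of the scenario density on ``grid``.

    Integrates the density over the two remaining axes at each grid point
    (Gauss-Legendre over the bounding box), divides by the 3-D
    normalization constant, then renormalizes on the grid.  Raises
    :class:`GridCoverageError` if the grid misses more than 1% of the mass.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of x|y|z, got {axis!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 8 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    box = bounding_box(scenario, params)
    others = [i for i in range(3) if i != _AXES[axis]]
    u, wu = _gauss_nodes(*box[others[0]], n_nodes)
    v, wv = _gauss_nodes(*box[others[1]], n_nodes)
    m = np.empty_like(grid)
    chunk = max(1, 2_000_000 // (n_nodes * n_nodes))  # bound temporaries
    for lo in range(0, grid.size, chunk):
        coords: list[np.ndarray] = [None, None, None]  # type: ignore[list-item]
        coords[_AXES[axis]] = grid[lo:lo + chunk, None, None]
        coords[others[0]] = u[None, :, None]
        coords[others[1]] = v[None, None, :]
        vals = density_xyz(scenario, coords[0], coords[1], coords[2], params)
        m[lo:lo + chunk] = np.einsum("ijk,j,k->i", vals, wu, wv)
    z_const = normalization_constant(scenario, params, box=box, n_nodes=n_nodes)
    m = m / z_const
    mass = float(np.trapezoid(m, grid))
    if mass < 0.99:
        raise GridCoverageError(
            f"grid covers only {mass:.4f} of the {scenario} {axis}-marginal mass"
        )
    return m / mass


def clipped_mass_fraction(scenario: str, params: ConfinementParams,
                          n_grid: int = 201) -> float:
    """Fraction of series mass removed by clipping negative truncation ripple.

    Evaluates the truncated series factor of the scenario on a fine grid and
    returns |negative part| / (|negative| + positive).  Zero for scenarios
    without a series.
    """
    params.require_for(scenario)
    if scenario in TAIL_SCENARIOS:
        g = np.linspace(0.0, params.z_max, n_grid)
        s = _slit_series(g, params.z_max, params.beta_k,
                         params.beta_k_prime, params.n_terms, clip=False)
    elif scenario == "trench_series":
        g = np.linspace(-0.5 * params.h_max, 0.5 * params.h_max, n_grid)
        s = _trench_series(g, params.h_max, params.beta_k,
                           params.beta_k_dprime, params.n_terms, clip=False)
    else:
        return 0.0
    neg = max(-float(np.trapezoid(np.minimum(s, 0.0), g)), 0.0)
    pos = float(np.trapezoid(np.maximum(s, 0.0), g))
    return neg / (neg + pos) if (neg + pos) > 0 else 0.0
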