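"""Solvent-accessible surface area by Shrake-Rupley sphere sampling.

Each atom is inflated by the probe radius and sampled with a deterministic
Fibonacci (golden-angle) lattice; the accessible fraction of sample points
gives the atom's ASA.  The point set carries no randomness, so repeated runs
are bit-identical.  Accuracy is controlled solely by ``n_points``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError

__all__ = ["fibonacci_sphere", "shrake_rupley", "sphere_area"]


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Return ``n_points`` near-uniform unit vectors on the sphere.

    Golden-angle spiral: z descends in equal steps, azimuth advances by the
    golden angle.  Deterministic for fixed ``n_points``.
    """
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    azimuth = i * (np.pi * (3.0 - np.sqrt(5.0)))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(azimuth), rho * np.sin(azimuth), z))


def sphere_area(radius: float, probe: float) -> float:
    """Area of an isolated atom's solvent-accessible sphere, 4*pi*(r+p)^2."""
    return 4.0 * np.pi * (radius + probe) ** 2


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface areas (A^2).

    Parameters
    ----------
    coords : (n, 3) float array of atom centres.
    radii : (n,) van der Waals radii.
    probe_radius : solvent probe radius (1.4 A water).
    n_points : sample points per atom; must be >= 10.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if n_points < 10:
        raise ParameterError(f"n_points must be >= 10, got {n_points}")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ParameterError("coords must be an (n, 3) array")
    if not np.all(np.isfinite(coords)):
        raise ParameterError("coords must be finite")
    if np.any(radii <= 0):
        raise ParameterError("vdW radii must be positive")

    n = len(coords)
    unit = fibonacci_sphere(n_points)
    sas_radii = radii + probe_radius
    areas = np.empty(n, dtype=float)

    tree = cKDTree(coords)
    max_reach = 2.0 * sas_radii.max()
    neighbor_lists = tree.query_ball_point(coords, r=max_reach)

    for i in range(n):
        ri = sas_radii[i]
        nbrs = [j for j in neighbor_lists[i] if j != i]
        if nbrs:
            nbr_idx = np.array(nbrs, dtype=int)
            # keep only neighbours whose SAS sphere can intersect atom i's
            d = np.linalg.norm(coords[nbr_idx] - coords[i], axis=1)
            close = d < ri + sas_radii[nbr_idx]
            nbr_idx = nbr_idx[close]
        else:
            nbr_idx = np.empty(0, dtype=int)
        if nbr_idx.size == 0:
            areas[i] = 4.0 * np.pi * ri * ri
            continue
        pts = coords[i] + ri * unit  # (n_points, 3)
        # a point is buried if it lies inside any neighbour's SAS sphere
        diff = pts[:, None, :] - coords[nbr_idx][None, :, :]
        dist2 = np.einsum("pkd,pkd->pk", diff, diff)
        buried = (dist2 < (sas_radii[nbr_idx] ** 2)[None, :]).any(axis=1)
        frac = 1.0 - buried.mean()
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return areas
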