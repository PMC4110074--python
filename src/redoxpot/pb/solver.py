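"""Linear PB solves on the node lattice.

The discrete equation at interior node ``c`` is::

    sum_edges eps_edge * (phi_nb - phi_c) - kappa_sq * h^2 * phi_c
        = -4 pi k q_c / h

with Dirichlet values on the outermost node layer.  Two paths exist:

* heterogeneous dielectric -> Jacobi-preconditioned conjugate gradients
  (deterministic: fixed sweep order, no randomized components);
* uniform dielectric with zero screening -> exact direct solve by
  discrete sine transform, used for the vacuum reference legs.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

from ..constants import COULOMB, FOUR_PI
from .grids import ChargeGrid, DielectricMap, GridSpec, PBParams, PotentialMap

__all__ = ["solve_pb", "boundary_potential", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Iterative solve failed to reach tolerance within max_iter."""

    def __init__(self, iterations, residual, tol):
        self.iterations = iterations
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"PB solve did not converge in {iterations} iterations "
            f"(relative residual {residual:.3e}, tol {tol:.1e})")


def boundary_potential(grid: GridSpec, coords, charges, eps_boundary,
                       kappa=0.0, chunk=16384) -> np.ndarray:
    """Dirichlet boundary values from a Coulomb/Debye-Hueckel superposition.

    Returns a full-shape array whose interior is zero and whose outermost
    node layer holds ``sum_i k q_i exp(-kappa r_i) / (eps_b r_i)``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    charges = np.asarray(charges, dtype=float)
    nz = charges != 0
    coords, charges = coords[nz], charges[nz]
    phi = np.zeros(grid.dims)
    if len(charges) == 0:
        return phi
    mask = np.zeros(grid.dims, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    idx = np.argwhere(mask)
    pts = grid.origin + idx * grid.spacing
    out = np.empty(len(pts))
    for start in range(0, len(pts), chunk):
        block = pts[start:start + chunk]
        d = np.sqrt(((block[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        d = np.maximum(d, 1e-9)
        contrib = charges[None, :] / d
        if kappa > 0:
            contrib = contrib * np.exp(-kappa * d)
        out[start:start + chunk] = contrib.sum(axis=1)
    phi[mask] = COULOMB / eps_boundary * out
    return phi


def _apply_operator(x, eps, kappa_h2):
    """Apply the (negative-definite) PB operator to a full-shape array.

    Boundary entries of ``x`` participate as neighbours but the returned
    array is only meaningful on interior nodes.
    """
    ex, ey, ez = eps
    out = np.zeros_like(x)
    tx = ex * (x[1:, :, :] - x[:-1, :, :])
    out[1:-1, :, :] += tx[1:, :, :] - tx[:-1, :, :]
    ty = ey * (x[:, 1:, :] - x[:, :-1, :])
    out[:, 1:-1, :] += ty[:, 1:, :] - ty[:, :-1, :]
    tz = ez * (x[:, :, 1:] - x[:, :, :-1])
    out[:, :, 1:-1] += tz[:, :, 1:] - tz[:, :, :-1]
    if kappa_h2 is not None:
        out -= kappa_h2 * x
    _zero_boundary(out)
    return out


def _zero_boundary(a):
    a[0, :, :] = a[-1, :, :] = 0.0
    a[:, 0, :] = a[:, -1, :] = 0.0
    a[:, :, 0] = a[:, :, -1] = 0.0


def _diagonal(eps, kappa_h2, shape):
    ex, ey, ez = eps
    d = np.zeros(shape)
    d[1:-1, :, :] += ex[:-1, :, :] + ex[1:, :, :]
    d[:, 1:-1, :] += ey[:, :-1, :] + ey[:, 1:, :]
    d[:, :, 1:-1] += ez[:, :, :-1] + ez[:, :, 1:]
    if kappa_h2 is not None:
        d += kappa_h2
    # boundary entries never used; keep them nonzero for safe division
    d[d == 0] = 1.0
    return d


def _solve_cg(diel: DielectricMap, b, boundary, params: PBParams, x0=None):
    """Jacobi-preconditioned CG on the interior unknowns."""
    eps = diel.eps
    h = diel.grid.spacing
    kappa_h2 = None
    if diel.kappa_sq is not None:
        kappa_h2 = diel.kappa_sq * h * h
    rhs = b - _apply_operator(boundary, eps, kappa_h2)
    _zero_boundary(rhs)

    # solve (-A) x = (-rhs); -A is symmetric positive definite
    diag = _diagonal(eps, kappa_h2, b.shape)
    x = np.zeros_like(b)
    if x0 is not None:
        x[...] = x0
        _zero_boundary(x)
    r = -rhs + _apply_operator(x, eps, kappa_h2)  # r = (-rhs) - (-A)x
    _zero_boundary(r)
    z = r / diag
    p = z.copy()
    rz = float((r * z).sum())
    bnorm = float(np.linalg.norm(rhs))
    if bnorm == 0:
        return x, 0, 0.0
    rnorm = float(np.linalg.norm(r))
    it = 0
    while rnorm / bnorm > params.tol:
        if it >= params.max_iter:
            raise ConvergenceError(it, rnorm / bnorm, params.tol)
        Ap = -_apply_operator(p, eps, kappa_h2)
        alpha = rz / float((p * Ap).sum())
        x += alpha * p
        r -= alpha * Ap
        z = r / diag
        rz_new = float((r * z).sum())
        p = z + (rz_new / rz) * p
        rz = rz_new
        rnorm = float(np.linalg.norm(r))
        it += 1
    return x, it, rnorm / bnorm


def _solve_dst(eps0, b, boundary):
    """Exact solve of the uniform-dielectric Poisson problem via DST-I."""
    nx, ny, nz = b.shape
    eps = (np.full((nx - 1, ny, nz), eps0),
           np.full((nx, ny - 1, nz), eps0),
           np.full((nx, ny, nz - 1), eps0))
    rhs = b - _apply_operator(boundary, eps, None)
    interior = rhs[1:-1, 1:-1, 1:-1] / eps0
    n = interior.shape
    lam = []
    for axis in range(3):
        m = np.arange(1, n[axis] + 1)
        lam.append(2.0 * np.cos(np.pi * m / (n[axis] + 1)) - 2.0)
    denom = (lam[0][:, None, None] + lam[1][None, :, None]
             + lam[2][None, None, :])
    xhat = scipy.fft.dstn(interior, type=1)
    xhat /= denom
    x = np.zeros_like(b)
    x[1:-1, 1:-1, 1:-1] = scipy.fft.idstn(xhat, type=1)
    return x


def solve_pb(diel: DielectricMap, rho: ChargeGrid, params: PBParams,
             boundary: np.ndarray | None = None,
             x0: np.ndarray | None = None) -> PotentialMap:
    """Solve the discrete linear PB equation.

    Parameters
    ----------
    diel, rho
        Dielectric map and charge grid on the same :class:`GridSpec`.
    boundary : ndarray, optional
        Full-shape array with Dirichlet values on the outer node layer.
        When omitted it is computed by Debye-Hueckel superposition over
        the grid charges with the solvent (or uniform) dielectric.
    x0 : ndarray, optional
        Initial guess for the iterative path (interior warm start).

    Returns
    -------
    PotentialMap
        Potentials in kcal/(mol*e); ``meta`` records iterations and the
        final relative residual.
    """
    if diel.grid.dims != rho.grid.dims or \
            not np.allclose(diel.grid.origin, rho.grid.origin) or \
            diel.grid.spacing != rho.grid.spacing:
        raise ValueError("dielectric map and charge grid are on different grids")
    grid = diel.grid
    h = grid.spacing

    if boundary is None:
        nz = np.argwhere(rho.values != 0)
        coords = grid.origin + nz * h
        charges = rho.values[rho.values != 0]
        eps_b = diel.uniform_value if diel.is_uniform else params.eps_solvent
        kappa = 0.0
        if diel.kappa_sq is not None:
            kappa = float(np.sqrt(diel.kappa_sq.max() / params.eps_solvent))
        boundary = boundary_potential(grid, coords, charges, eps_b, kappa)

    b = -FOUR_PI * COULOMB * rho.values / h
    _zero_boundary(b)

    if diel.is_uniform and diel.kappa_sq is None:
        x = _solve_dst(diel.uniform_value, b, boundary)
        meta = {"method": "dst", "iterations": 0, "residual": 0.0}
    else:
        x, iters, res = _solve_cg(diel, b, boundary, params, x0=x0)
        meta = {"method": "cg", "iterations": iters, "residual": res}

    phi = x + boundary
    meta["spacing"] = h
    meta["dims"] = grid.dims
    return PotentialMap(grid=grid, values=phi, meta=meta)
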