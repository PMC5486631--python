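"""Cell-centered finite-volume assembly on tensor-product voxel grids.

Shared by the electrostatic and thermal solvers.  Fluxes between two active
cells use harmonic averaging of the coefficient over the two half-cells;
faces against a Dirichlet cell (an equipotential electrode) use the active
half-cell only, i.e. the boundary value is imposed on the shared face.
Faces with an inactive, non-Dirichlet neighbor carry no flux.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg

from .errors import SolverError
from .meshing import VoxelGrid

__all__ = ["assemble_diffusion", "solve_spd"]


def assemble_diffusion(grid: VoxelGrid, coeff: np.ndarray, active: np.ndarray,
                       dirichlet: np.ndarray | None = None,
                       dirichlet_gaps=None,
                       ) -> Tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Assemble the SPD operator K of -div(c grad u) over the active cells.

    Parameters
    ----------
    coeff : per-voxel coefficient (conductivity), used where active
    active : boolean mask of solved cells
    dirichlet : per-voxel boundary value, NaN where not prescribed
    dirichlet_gaps : optional per-axis ``(gap_minus, gap_plus)`` arrays of
        corrected active-cell-to-boundary distances (embedded-boundary
        treatment of non-face-aligned Dirichlet surfaces); NaN entries fall
        back to the half-cell distance

    Returns
    -------
    K : csr matrix (n_active x n_active); ``K u`` is the net outflux per cell
    b : right-hand side carrying the Dirichlet face fluxes
    index : int array mapping voxel -> row (or -1 where inactive)
    """
    shape = grid.shape
    active = np.asarray(active, bool)
    coeff = np.asarray(coeff, float)
    if dirichlet is None:
        dirichlet = np.full(shape, np.nan)

    index = np.full(shape, -1, dtype=np.int64)
    n = int(active.sum())
    index[active] = np.arange(n)

    dx, dy, dz = grid.spacings
    half = (np.broadcast_to(0.5 * dx[:, None, None], shape),
            np.broadcast_to(0.5 * dy[None, :, None], shape),
            np.broadcast_to(0.5 * dz[None, None, :], shape))
    vol = grid.volumes
    dmask = np.isfinite(dirichlet)

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    b = np.zeros(n)

    for ax in range(3):
        sl_l = [slice(None)] * 3
        sl_r = [slice(None)] * 3
        sl_l[ax] = slice(0, -1)
        sl_r[ax] = slice(1, None)
        sl_l, sl_r = tuple(sl_l), tuple(sl_r)

        area = (vol / (2.0 * half[ax]))[sl_l]  # cross-section, equal on both sides
        aL, aR = active[sl_l], active[sl_r]
        cL, cR = coeff[sl_l], coeff[sl_r]
        dL, dR = half[ax][sl_l], half[ax][sl_r]
        iL, iR = index[sl_l], index[sl_r]

        # active-active faces: harmonic average over the two half-cells
        m = aL & aR
        with np.errstate(divide="ignore"):
            tau = area[m] / (dL[m] / cL[m] + dR[m] / cR[m])
        i, j = iL[m], iR[m]
        rows.extend([i, j, i, j])
        cols.extend([j, i, i, j])
        vals.extend([-tau, -tau, tau, tau])

        # active cell against a Dirichlet face (value imposed on the face,
        # or on the true boundary surface when gap corrections are given)
        gap_minus = gap_plus = None
        if dirichlet_gaps is not None:
            gap_minus, gap_plus = dirichlet_gaps[ax]
        for a_side, d_vals, d_side, i_side, c_side, d_dist, gap_sl in (
                (aL, dirichlet[sl_r], dmask[sl_r], iL, cL, dL,
                 None if gap_plus is None else gap_plus[sl_l]),
                (aR, dirichlet[sl_l], dmask[sl_l], iR, cR, dR,
                 None if gap_minus is None else gap_minus[sl_r])):
            m = a_side & d_side
            if not m.any():
                continue
            dist = d_dist[m]
            if gap_sl is not None:
                corrected = gap_sl[m]
                dist = np.where(np.isfinite(corrected), corrected, dist)
            tau = area[m] * c_side[m] / dist
            i = i_side[m]
            rows.append(i)
            cols.append(i)
            vals.append(tau)
            np.add.at(b, i, tau * d_vals[m])

    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    return K, b, index


def solve_spd(K: sp.csr_matrix, b: np.ndarray, x0: np.ndarray | None = None,
              rtol: float = 1e-8, maxiter: int = 20000, name: str = "solve",
              diag: np.ndarray | None = None) -> Tuple[np.ndarray, int]:
    """Jacobi-preconditioned conjugate gradients on an SPD system.

    Returns the solution and the iteration count; raises :class:`SolverError`
    with a residual history sample on non-convergence.  ``diag`` may pass a
    precomputed matrix diagonal for repeated solves.
    """
    if b.size == 0:
        return np.zeros(0), 0
    if not np.any(b) and x0 is None:
        return np.zeros_like(b), 0
    if diag is None:
        diag = K.diagonal()
    if np.any(diag <= 0):
        raise SolverError(f"{name}: operator diagonal is not positive")
    M = sp.diags(1.0 / diag)

    count = 0
    history: List[float] = []
    b_norm = float(np.linalg.norm(b)) or 1.0

    def callback(xk: np.ndarray) -> None:
        nonlocal count
        count += 1
        if count % 200 == 0:
            history.append(float(np.linalg.norm(b - K @ xk)) / b_norm)

    x, info = cg(K, b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M,
                 callback=callback)
    if info != 0:
        final = float(np.linalg.norm(b - K @ x)) / b_norm
        raise SolverError(
            f"{name}: CG did not reach rtol={rtol:g} in {maxiter} iterations; "
            f"relative residual {final:.3e}, history (every 200 it) "
            f"{[f'{r:.2e}' for r in history[-8:]]}")
    return x, count
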