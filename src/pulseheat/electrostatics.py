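"""Quasi-static electric field with a stepped electroporation conductivity.

The potential solves -div(sigma grad phi) = 0 over the tissue voxels with
Dirichlet values on the electrode surfaces (one needle energized, the other
grounded) and zero normal current on every remaining boundary, including the
insulated needle sheath and the outer liver surface.  Tissue whose field
magnitude reaches the poration threshold switches irreversibly to its higher
post-electroporation conductivity; because that switch redistributes the
field, the mask is iterated to a fixed point.  Both conductivity states carry
a linear temperature multiplier 1 + alpha (T - t_ref).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import fv
from .errors import SolverError
from .meshing import (LAB_ELECTRODE_A, LAB_ELECTRODE_B, LABEL_TO_MATERIAL,
                      TISSUE_LABELS, VoxelGrid)
from .scenario import ConductivityModel, MaterialProperties, SolverSettings

__all__ = ["FieldSolution", "solve_potential", "field_and_joule",
           "porate_fixed_point", "electrode_current", "material_arrays"]


@dataclass
class FieldSolution:
    """Electric solution on the grid: potential, field magnitude, current
    density, Joule heating density, poration mask and the conductivity used."""

    potential: np.ndarray        # V, per voxel (0 outside the tissue solve)
    e_magnitude: np.ndarray      # V/m, per voxel
    current_density: np.ndarray  # A/m^2
    joule_density: np.ndarray    # W/m^3
    porated: np.ndarray          # bool, tissue voxels only
    sigma_effective: np.ndarray  # S/m used in the final solve
    n_iterations: int            # poration fixed-point passes (solves)
    cg_iterations: int           # total CG iterations across those passes


def material_arrays(grid: VoxelGrid, materials: Dict[str, MaterialProperties],
                    attr: str) -> np.ndarray:
    """Per-voxel array of one material property (zero on OUTSIDE voxels)."""
    out = np.zeros(grid.shape)
    for label, key in LABEL_TO_MATERIAL.items():
        mask = grid.material == label
        if mask.any():
            out[mask] = getattr(materials[key], attr)
    return out


def _tissue_mask(grid: VoxelGrid) -> np.ndarray:
    return np.isin(grid.material, TISSUE_LABELS)


def _dirichlet_array(grid: VoxelGrid, voltage: float) -> np.ndarray:
    d = np.full(grid.shape, np.nan)
    d[grid.material == LAB_ELECTRODE_A] = voltage
    d[grid.material == LAB_ELECTRODE_B] = 0.0
    return d


def electrode_gaps(grid: VoxelGrid):
    """Embedded-boundary distances from cells to the true needle surface.

    The voxelized electrode is a staircase whose re-entrant corners
    concentrate the discrete field artificially; measuring each
    electrode-adjacent flux over the distance to the *smooth* cylinder
    surface along the face direction (Shortley-Weller correction) restores
    convergence of the near-surface field.  Returns, per axis, a pair of 3-D
    arrays ``(gap_minus, gap_plus)``: the corrected distance when the
    Dirichlet neighbor sits on the -/+ side, NaN where the default half-cell
    distance applies.  ``None`` when the grid carries no needle layout
    (planar fixture electrodes are exactly face-aligned already).
    """
    layout = grid.needles
    if layout is None:
        return None
    cached = getattr(grid, "_electrode_gaps", None)
    if cached is not None:
        return cached

    xc, yc, zc = grid.centers
    X = xc[:, None, None]
    Y = yc[None, :, None]
    Z = zc[None, None, :]
    dx, dy, dz = grid.spacings
    half = (0.5 * dx[:, None, None] * np.ones(grid.shape),
            0.5 * dy[None, :, None] * np.ones(grid.shape),
            0.5 * dz[None, None, :] * np.ones(grid.shape))
    r = layout.radius
    z_lo, z_hi = layout.z_active

    gaps = {ax: (np.full(grid.shape, np.nan), np.full(grid.shape, np.nan))
            for ax in range(3)}
    for label, (ax_c, ay_c) in ((LAB_ELECTRODE_A, layout.axis_a),
                                (LAB_ELECTRODE_B, layout.axis_b)):
        elec = grid.material == label
        rho = np.sqrt((X - ax_c) ** 2 + (Y - ay_c) ** 2)
        radial_fallback = np.maximum(rho - r, 0.0)

        def neighbor_is(mask: np.ndarray, ax: int, side: int) -> np.ndarray:
            out = np.zeros(grid.shape, bool)
            take = [slice(None)] * 3
            put = [slice(None)] * 3
            if side == 1:
                put[ax], take[ax] = slice(0, -1), slice(1, None)
            else:
                put[ax], take[ax] = slice(1, None), slice(0, -1)
            out[tuple(put)] = mask[tuple(take)]
            return out

        for ax, coord, axis_pos, perp in ((0, X, ax_c, (Y - ay_c) ** 2),
                                          (1, Y, ay_c, (X - ax_c) ** 2)):
            disc = r ** 2 - perp
            root = np.sqrt(np.maximum(disc, 0.0))
            eps = 1e-3 * half[ax]
            for side, t in ((1, (axis_pos - coord) - root),
                            (0, (coord - axis_pos) - root)):
                nbr = neighbor_is(elec, ax, side)
                ok = (disc > 0) & (t > eps)
                val = np.where(ok, t, np.maximum(np.maximum(half[ax],
                                                            radial_fallback), eps))
                target = gaps[ax][side]
                target[nbr] = val[nbr]

        # axial faces: tissue below the flat electrode tip sees the tip disk
        eps = 1e-3 * half[2]
        t_tip = z_lo - Z
        inside = rho <= r
        diag = np.sqrt(radial_fallback ** 2 + np.maximum(t_tip, 0.0) ** 2)
        val = np.where(inside & (t_tip > eps), t_tip,
                       np.maximum(np.maximum(half[2], diag), eps))
        nbr_up = neighbor_is(elec, 2, 1)
        gaps[2][1][nbr_up] = val[nbr_up]
        # tissue above an exposed electrode top (normally sheathed): default
        # half-cell distance is kept (NaN)

    grid._electrode_gaps = gaps
    return gaps


def solve_potential(grid: VoxelGrid, sigma: np.ndarray, voltage: float,
                    settings: SolverSettings | None = None,
                    x0: Optional[np.ndarray] = None) -> tuple[np.ndarray, int]:
    """Solve the potential on the tissue voxels.

    ``sigma`` is the per-voxel effective conductivity (only tissue entries are
    used).  Returns the per-voxel potential (electrode voxels carry their
    Dirichlet values) and the CG iteration count.  ``x0`` warm-starts the
    solve with a previous tissue potential field.
    """
    settings = settings or SolverSettings()
    tissue = _tissue_mask(grid)
    phi = np.zeros(grid.shape)
    phi[grid.material == LAB_ELECTRODE_A] = voltage
    if voltage == 0.0:
        return phi, 0
    if np.any(sigma[tissue] <= 0):
        raise SolverError("solve_potential: sigma must be > 0 on tissue voxels")

    K, b, index = fv.assemble_diffusion(grid, sigma, tissue,
                                        _dirichlet_array(grid, voltage),
                                        dirichlet_gaps=electrode_gaps(grid))
    x0_vec = None if x0 is None else np.asarray(x0)[tissue]
    sol, n_iter = fv.solve_spd(K, b, x0=x0_vec, rtol=settings.cg_rtol,
                               maxiter=settings.cg_maxiter, name="potential")
    phi[tissue] = sol
    return phi, n_iter


def field_and_joule(potential: np.ndarray, grid: VoxelGrid, sigma: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel |E|, |J| = sigma |E| and Q = sigma |E|^2 from the potential.

    Cell values average the two face gradients per axis; faces against
    insulation or the domain boundary carry no normal field (zero-current
    boundary), and faces against an electrode use the half-cell gradient to
    the electrode surface.
    """
    tissue = _tissue_mask(grid)
    electrode = np.isin(grid.material, (LAB_ELECTRODE_A, LAB_ELECTRODE_B))
    dx, dy, dz = grid.spacings
    halves = (0.5 * dx[:, None, None], 0.5 * dy[None, :, None],
              0.5 * dz[None, None, :])
    gaps = electrode_gaps(grid)

    e2 = np.zeros(grid.shape)
    for ax in range(3):
        sl_l = [slice(None)] * 3
        sl_r = [slice(None)] * 3
        sl_l[ax] = slice(0, -1)
        sl_r[ax] = slice(1, None)
        sl_l, sl_r = tuple(sl_l), tuple(sl_r)
        hl = np.broadcast_to(halves[ax], grid.shape)

        dphi = potential[sl_r] - potential[sl_l]
        dist = np.where(electrode[sl_l], hl[sl_r],
                        np.where(electrode[sl_r], hl[sl_l], hl[sl_l] + hl[sl_r]))
        if gaps is not None:
            gap_minus, gap_plus = gaps[ax]
            dist = np.where(electrode[sl_l] & np.isfinite(gap_minus[sl_r]),
                            gap_minus[sl_r], dist)
            dist = np.where(electrode[sl_r] & np.isfinite(gap_plus[sl_l]),
                            gap_plus[sl_l], dist)
        conducting = ((tissue[sl_l] | electrode[sl_l])
                      & (tissue[sl_r] | electrode[sl_r])
                      & ~(electrode[sl_l] & electrode[sl_r]))
        g_face = np.where(conducting, dphi / dist, 0.0)

        # average the two adjacent face gradients; a missing face means
        # zero normal field there (insulated boundary)
        comp = np.zeros(grid.shape)
        comp[sl_l] += g_face
        comp[sl_r] += g_face
        e2 += (0.5 * comp) ** 2

    e_mag = np.where(tissue, np.sqrt(e2), 0.0)
    j_mag = sigma * e_mag * tissue
    q = sigma * e_mag**2 * tissue
    return e_mag, j_mag, q


def porate_fixed_point(grid: VoxelGrid, materials: Dict[str, MaterialProperties],
                       conductivity_model: ConductivityModel, voltage: float,
                       temperature, settings: SolverSettings | None = None,
                       porated0: Optional[np.ndarray] = None,
                       phi0: Optional[np.ndarray] = None) -> FieldSolution:
    """Self-consistent field solve with the irreversible poration switch.

    Alternates {solve potential, threshold |E|, rebuild sigma} until the
    porated set stops changing.  The set only ever grows (the switch is
    irreversible within a burst), so the iteration terminates; the cap guards
    against pathological inputs.  ``temperature`` (degC, scalar or per-voxel)
    enters through the linear conductivity multiplier.
    """
    settings = settings or SolverSettings()
    tissue = _tissue_mask(grid)
    sig_base = material_arrays(grid, materials, "sigma_base")
    sig_por = material_arrays(grid, materials, "sigma_porated")
    t_arr = np.broadcast_to(np.asarray(temperature, float), grid.shape)
    multiplier = 1.0 + conductivity_model.alpha * (t_arr - conductivity_model.t_ref)
    if np.any(multiplier[tissue] <= 0):
        raise SolverError("porate_fixed_point: temperature multiplier drove "
                          "sigma non-positive")

    porated = (np.zeros(grid.shape, bool) if porated0 is None
               else np.asarray(porated0, bool) & tissue)
    phi = phi0
    cg_total = 0
    for iteration in range(1, settings.porate_max_iter + 1):
        sigma = np.where(porated, sig_por, sig_base) * multiplier
        phi, n_cg = solve_potential(grid, sigma, voltage, settings, x0=phi)
        cg_total += n_cg
        e_mag, j_mag, q = field_and_joule(phi, grid, sigma)
        new_porated = porated | (tissue & (e_mag >= conductivity_model.e_threshold))
        if np.array_equal(new_porated, porated):
            return FieldSolution(potential=phi, e_magnitude=e_mag,
                                 current_density=j_mag, joule_density=q,
                                 porated=porated, sigma_effective=sigma,
                                 n_iterations=iteration, cg_iterations=cg_total)
        porated = new_porated
    raise SolverError(
        f"porate_fixed_point: no fixed point within {settings.porate_max_iter} "
        f"iterations; porated count last changed to {int(porated.sum())}")


def electrode_current(grid: VoxelGrid, potential: np.ndarray, sigma: np.ndarray,
                      electrode_label: int) -> float:
    """Net current (A) flowing from an electrode into the tissue."""
    tissue = _tissue_mask(grid)
    elec = grid.material == electrode_label
    dx, dy, dz = grid.spacings
    halves = (0.5 * dx[:, None, None], 0.5 * dy[None, :, None],
              0.5 * dz[None, None, :])
    vol = grid.volumes
    gaps = electrode_gaps(grid)
    total = 0.0
    for ax in range(3):
        sl_l = [slice(None)] * 3
        sl_r = [slice(None)] * 3
        sl_l[ax] = slice(0, -1)
        sl_r[ax] = slice(1, None)
        sl_l, sl_r = tuple(sl_l), tuple(sl_r)
        hl = np.broadcast_to(halves[ax], grid.shape)
        area = (vol / (2.0 * np.broadcast_to(halves[ax], grid.shape)))[sl_l]
        gap_minus, gap_plus = gaps[ax] if gaps is not None else (None, None)

        for e_side, t_side, gap in ((sl_l, sl_r, gap_minus), (sl_r, sl_l, gap_plus)):
            m = elec[e_side] & tissue[t_side]
            if not m.any():
                continue
            dist = hl[t_side][m]
            if gap is not None:
                corrected = gap[t_side][m]
                dist = np.where(np.isfinite(corrected), corrected, dist)
            tau = area[m] * sigma[t_side][m] / dist
            total += float(np.sum(tau * (potential[e_side][m] - potential[t_side][m])))
    return total
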