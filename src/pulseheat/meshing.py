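"""Graded structured voxel grid over the liver cylinder with material labels.

The domain is discretized on a tensor-product grid whose spacing is fine in a
band around the two needles (where the field and temperature hot spots live)
and grows geometrically, with adjacent-cell ratio bounded by the grading
factor, to a coarse far-field spacing.  Every voxel carries exactly one
material label decided by containment of its center, tested in priority order
electrode/insulation cylinders, tumor sphere, liver cylinder, outside.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MeshError, ValidationError
from .scenario import (ELECTRODE, GridSpec, Geometry, INSULATION, LIVER,
                       Scenario, TUMOR)

__all__ = [
    "OUTSIDE", "LAB_LIVER", "LAB_TUMOR", "LAB_ELECTRODE_A", "LAB_ELECTRODE_B",
    "LAB_INSULATION", "LABEL_NAMES", "LABEL_TO_MATERIAL",
    "VoxelGrid", "NeedleLayout", "build_grid", "grid_convergence",
    "needle_axes", "active_z_range", "classify_points",
]

# Integer voxel labels.
OUTSIDE = 0
LAB_LIVER = 1
LAB_TUMOR = 2
LAB_ELECTRODE_A = 3
LAB_ELECTRODE_B = 4
LAB_INSULATION = 5

LABEL_NAMES = {OUTSIDE: "outside", LAB_LIVER: "liver", LAB_TUMOR: "tumor",
               LAB_ELECTRODE_A: "electrode_a", LAB_ELECTRODE_B: "electrode_b",
               LAB_INSULATION: "insulation"}

# Voxel label -> material key in Scenario.materials.
LABEL_TO_MATERIAL = {LAB_LIVER: LIVER, LAB_TUMOR: TUMOR,
                     LAB_ELECTRODE_A: ELECTRODE, LAB_ELECTRODE_B: ELECTRODE,
                     LAB_INSULATION: INSULATION}

TISSUE_LABELS = (LAB_LIVER, LAB_TUMOR)


def needle_axes(geometry: Geometry) -> List[Tuple[float, float]]:
    """(x, y) axis positions of needles A and B, symmetric about the tumor."""
    cx, cy, _ = geometry.tumor_center
    half = geometry.electrode_spacing / 2.0
    return [(cx - half, cy), (cx + half, cy)]


def active_z_range(geometry: Geometry) -> Tuple[float, float]:
    """Axial extent of the energized electrode segment.

    The active segment is centered on the tumor's equatorial plane; the
    needle above it is insulated sheath up to the liver surface.  This
    placement convention is isolated here so alternatives are one-line edits.
    """
    _, _, cz = geometry.tumor_center
    half = geometry.active_length / 2.0
    return (cz - half, cz + half)


def classify_points(geometry: Geometry, x, y, z) -> np.ndarray:
    """Material label for arbitrary points (broadcastable arrays, meters)."""
    x, y, z = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float),
                                  np.asarray(z, float))
    label = np.full(x.shape, OUTSIDE, dtype=np.int8)

    r_liver = geometry.liver_diameter / 2.0
    cx, cy, cz = geometry.tumor_center
    in_liver = (x**2 + y**2 <= r_liver**2) & (z >= 0.0) & (z <= geometry.liver_height)
    label[in_liver] = LAB_LIVER

    r_t = geometry.tumor_diameter / 2.0
    in_tumor = (x - cx)**2 + (y - cy)**2 + (z - cz)**2 <= r_t**2
    label[in_tumor & in_liver] = LAB_TUMOR

    r_n = geometry.needle_diameter / 2.0
    z_lo, z_hi = active_z_range(geometry)
    (ax_a, ay_a), (ax_b, ay_b) = needle_axes(geometry)
    in_a = (x - ax_a)**2 + (y - ay_a)**2 <= r_n**2
    in_b = (x - ax_b)**2 + (y - ay_b)**2 <= r_n**2
    in_needle = (in_a | in_b) & (z >= z_lo) & (z <= geometry.liver_height)
    active = (z <= z_hi)
    label[in_needle & ~active] = LAB_INSULATION
    label[in_a & (z >= z_lo) & active] = LAB_ELECTRODE_A
    label[in_b & (z >= z_lo) & active] = LAB_ELECTRODE_B
    return label


@dataclass(frozen=True)
class NeedleLayout:
    """Exact electrode-cylinder geometry carried alongside the voxelization,
    so solvers can measure distances to the true needle surface instead of
    the staircased voxel faces (embedded-boundary correction)."""

    axis_a: Tuple[float, float]
    axis_b: Tuple[float, float]
    radius: float
    z_active: Tuple[float, float]


@dataclass(eq=False)
class VoxelGrid:
    """Tensor-product voxel grid with per-voxel material labels."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    z_edges: np.ndarray
    material: np.ndarray  # int8, shape (nx, ny, nz)
    needles: "NeedleLayout | None" = None

    def __post_init__(self) -> None:
        for name in ("x_edges", "y_edges", "z_edges"):
            e = np.asarray(getattr(self, name), float)
            if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
                raise ValidationError(f"grid.{name}: must be strictly increasing 1-D")
            setattr(self, name, e)
        self.material = np.asarray(self.material, np.int8)
        if self.material.shape != self.shape:
            raise ValidationError("grid.material: shape must match the edge arrays")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.x_edges.size - 1, self.y_edges.size - 1, self.z_edges.size - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @functools.cached_property
    def spacings(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.diff(self.x_edges), np.diff(self.y_edges), np.diff(self.z_edges))

    @functools.cached_property
    def centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
                0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
                0.5 * (self.z_edges[:-1] + self.z_edges[1:]))

    @functools.cached_property
    def volumes(self) -> np.ndarray:
        dx, dy, dz = self.spacings
        return dx[:, None, None] * dy[None, :, None] * dz[None, None, :]

    def counts(self) -> dict:
        """Voxel count per material label name."""
        labels, n = np.unique(self.material, return_counts=True)
        return {LABEL_NAMES[int(l)]: int(c) for l, c in zip(labels, n)}

    def locate(self, x: float, y: float, z: float) -> Tuple[int, int, int]:
        """Index of the voxel containing a point."""
        i = int(np.searchsorted(self.x_edges, x, side="right") - 1)
        j = int(np.searchsorted(self.y_edges, y, side="right") - 1)
        k = int(np.searchsorted(self.z_edges, z, side="right") - 1)
        nx, ny, nz = self.shape
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise ValidationError("locate: point outside the grid bounding box")
        return (i, j, k)


# ---------------------------------------------------------------------------
# Graded 1-D edge construction


def _graded_run(length: float, h0: float, h_max: float, growth: float) -> List[float]:
    """Spacings marching away from a fine region across ``length``.

    Grows geometrically from ``h0`` (ratio ``growth``) up to ``h_max`` and is
    then rescaled (scale <= 1) to fit exactly, which preserves the ratio bound.
    """
    if length <= 1e-12:
        return []
    spacings: List[float] = []
    h, total = h0, 0.0
    while total < length:
        h = min(h * growth, h_max)
        spacings.append(h)
        total += h
    scale = length / total
    return [s * scale for s in spacings]


def _bridge_run(length: float, h_left: float, h_right: float, h_max: float,
                growth: float) -> List[float]:
    """Spacings across a gap between two fine regions, grown from both ends."""
    if length <= 1e-12:
        return []
    if length <= max(h_left, h_right) * growth:
        return [length]
    left: List[float] = []
    right: List[float] = []
    hl, hr, total = h_left, h_right, 0.0
    while total < length:
        if hl <= hr:
            hl = min(hl * growth, h_max)
            left.append(hl)
            total += hl
        else:
            hr = min(hr * growth, h_max)
            right.append(hr)
            total += hr
    scale = length / total
    return [s * scale for s in left] + [s * scale for s in reversed(right)]


def _merge_windows(windows: Sequence[Tuple[float, float]], lo: float, hi: float,
                   h_fine: float) -> List[Tuple[float, float]]:
    clipped = sorted((max(lo, a), min(hi, b)) for a, b in windows if b > lo and a < hi)
    merged: List[Tuple[float, float]] = []
    for a, b in clipped:
        if merged and a <= merged[-1][1] + h_fine:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def graded_edges(lo: float, hi: float, windows: Sequence[Tuple[float, float]],
                 spec: GridSpec) -> np.ndarray:
    """1-D edge coordinates: uniform ``h_fine`` inside the windows, graded
    toward ``h_coarse`` elsewhere with adjacent-cell ratio <= ``growth``."""
    merged = _merge_windows(windows, lo, hi, spec.h_fine)
    spacings: List[float] = []
    if not merged:
        spacings = _graded_run(hi - lo, spec.h_coarse, spec.h_coarse, spec.growth)
    else:
        first_a, _ = merged[0]
        spacings.extend(reversed(_graded_run(first_a - lo, spec.h_fine,
                                             spec.h_coarse, spec.growth)))
        for idx, (a, b) in enumerate(merged):
            n = max(1, int(round((b - a) / spec.h_fine)))
            spacings.extend([(b - a) / n] * n)
            if idx + 1 < len(merged):
                spacings.extend(_bridge_run(merged[idx + 1][0] - b, spec.h_fine,
                                            spec.h_fine, spec.h_coarse, spec.growth))
        spacings.extend(_graded_run(hi - merged[-1][1], spec.h_fine,
                                    spec.h_coarse, spec.growth))
    edges = lo + np.concatenate([[0.0], np.cumsum(spacings)])
    edges[-1] = hi
    # symmetric domains get exactly symmetric edges (label mirror symmetry)
    if abs(lo + hi) < 1e-12 * max(1.0, abs(hi - lo)):
        edges = 0.5 * (edges - edges[::-1])
    return edges


def _absorb_surface_slivers(material: np.ndarray, layout: NeedleLayout,
                            x_edges, y_edges, z_edges, centers) -> None:
    """Merge sliver cells into the electrode labels (cut-cell small-cell merging).

    A tissue cell whose center lies closer than half its own width to the
    true needle surface is so strongly coupled to the Dirichlet boundary that
    keeping it as an unknown produces near-singular conductances and a
    resolution-divergent local field; such cells are absorbed into the
    electrode.  The Dirichlet surface itself stays the exact cylinder via the
    embedded-boundary gap distances, so the absorbed slivers do not inflate
    the effective electrode radius.
    """
    xc, yc, zc = centers
    X = xc[:, None, None]
    Y = yc[None, :, None]
    Z = zc[None, None, :]
    shape = material.shape
    dx3 = np.broadcast_to(np.diff(x_edges)[:, None, None], shape)
    dy3 = np.broadcast_to(np.diff(y_edges)[None, :, None], shape)
    dz3 = np.broadcast_to(np.diff(z_edges)[None, None, :], shape)
    h_xy = np.minimum(dx3, dy3)
    z_lo, z_hi = layout.z_active
    tissue = np.isin(material, TISSUE_LABELS)
    for label, (ax_c, ay_c) in ((LAB_ELECTRODE_A, layout.axis_a),
                                (LAB_ELECTRODE_B, layout.axis_b)):
        rho = np.sqrt((X - ax_c) ** 2 + (Y - ay_c) ** 2)
        near_radial = (rho - layout.radius) < 0.5 * h_xy
        in_axial = (Z >= z_lo - 0.5 * dz3) & (Z <= z_hi)
        material[tissue & near_radial & in_axial] = label
        # the sheath above the active segment gets the same treatment, so the
        # tissue beside the electrode/insulation junction starts a half cell
        # from the needle wall like everywhere else
        material[tissue & near_radial & (Z > z_hi)] = LAB_INSULATION


def build_grid(geometry: Geometry, resolution: GridSpec) -> VoxelGrid:
    """Build the graded voxel grid over the liver bounding box and label it.

    Raises :class:`MeshError` if the fine spacing exceeds the needle radius
    (the needles would vanish from the staircased geometry).
    """
    r_n = geometry.needle_diameter / 2.0
    if resolution.h_fine > r_n:
        raise MeshError(
            f"fine spacing {resolution.h_fine:g} m exceeds the needle radius "
            f"{r_n:g} m; the electrodes would not be resolved")

    r_liver = geometry.liver_diameter / 2.0
    margin = r_n + resolution.fine_margin
    x_windows = [(ax - margin, ax + margin) for ax, _ in needle_axes(geometry)]
    y_windows = [(ay - margin, ay + margin) for _, ay in needle_axes(geometry)]
    z_lo, z_hi = active_z_range(geometry)
    z_windows = [(z_lo - resolution.z_margin, z_hi + resolution.z_margin)]

    x_edges = graded_edges(-r_liver, r_liver, x_windows, resolution)
    y_edges = graded_edges(-r_liver, r_liver, y_windows, resolution)
    z_edges = graded_edges(0.0, geometry.liver_height, z_windows, resolution)

    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    material = classify_points(geometry, xc[:, None, None], yc[None, :, None],
                               zc[None, None, :])
    (ax_a, ay_a), (ax_b, ay_b) = needle_axes(geometry)
    layout = NeedleLayout(axis_a=(ax_a, ay_a), axis_b=(ax_b, ay_b), radius=r_n,
                          z_active=active_z_range(geometry))
    _absorb_surface_slivers(material, layout, x_edges, y_edges, z_edges,
                            (xc, yc, zc))
    grid = VoxelGrid(x_edges, y_edges, z_edges, material, needles=layout)

    for lab, name in ((LAB_ELECTRODE_A, "A"), (LAB_ELECTRODE_B, "B")):
        if not np.any(material == lab):
            raise MeshError(f"electrode {name} captured no voxels; refine the grid")
    return grid


def grid_convergence(scenario: Scenario, resolutions: Sequence[GridSpec]) -> pd.DataFrame:
    """Peak tumor temperature at burst end versus grid resolution.

    Runs the single-burst pipeline (duty-cycle-averaged source, burst phase
    only) at each resolution and reports the peak alongside successive
    differences.  Requires at least two resolutions ordered fine-ward
    (non-increasing ``h_fine``).
    """
    from .bioheat import simulate_burst  # local import; bioheat depends on meshing

    if len(resolutions) < 2:
        raise ValidationError("grid_convergence: need at least two resolutions")
    h = [r.h_fine for r in resolutions]
    if any(b > a for a, b in zip(h, h[1:])):
        raise ValidationError("grid_convergence: resolutions must refine "
                              "(non-increasing h_fine)")

    rows = []
    for res in resolutions:
        grid = build_grid(scenario.geometry, res)
        result = simulate_burst(scenario, grid=grid, mode="averaged",
                                t_end=scenario.protocol.burst_length_s)
        rows.append({"h_fine": res.h_fine, "h_coarse": res.h_coarse,
                     "n_cells": grid.n_cells,
                     "peak_tumor_t_burst_end_c": result.peak_tumor_t_burst_end})
    table = pd.DataFrame(rows)
    table["successive_difference_c"] = table["peak_tumor_t_burst_end_c"].diff().abs()
    return table
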