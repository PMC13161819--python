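"""Spherical parcellation geometry.

Cortical parcellations are modelled as a set of region centroids on the unit
sphere, split into left/right hemispheres, plus an assignment of surface
vertices to regions.  Centroids are laid out on a deterministic quasi-uniform
(Fibonacci) lattice per hemisphere, with the right hemisphere mirrored from
the left so that mirrored spin rotations are meaningful.  This is the only
geometric substrate the pipeline needs: similarity networks consume vertex
clouds per region, and spin tests consume centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParcellationGeometry", "generate_parcellation"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ParcellationGeometry:
    """Region centroids on the unit sphere plus a total vertex assignment.

    Attributes
    ----------
    region_ids : array of str, shape (R,)
        Ordered region identifiers, e.g. ``L001 ... L030, R001 ... R030``.
    centroids : array, shape (R, 3)
        Unit vectors on each hemisphere's own spherical projection; the
        right hemisphere is the x-mirror of the left.
    hemisphere : array of str, shape (R,)
        ``"L"`` or ``"R"`` per region.
    vertex_positions : array, shape (V, 3)
        Unit vectors of surface vertices.
    vertex_region_idx : array of int, shape (V,)
        Index into ``region_ids`` for every vertex (total assignment).
    """

    region_ids: np.ndarray
    centroids: np.ndarray
    hemisphere: np.ndarray
    vertex_positions: np.ndarray
    vertex_region_idx: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the unit sphere")
        counts = np.bincount(self.vertex_region_idx, minlength=self.n_regions)
        if (counts == 0).any():
            empty = self.region_ids[counts == 0]
            raise ValueError(f"regions without vertices: {list(empty)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_region_idx)

    @property
    def vertices_per_region(self) -> np.ndarray:
        return np.bincount(self.vertex_region_idx, minlength=self.n_regions)

    @property
    def left_mask(self) -> np.ndarray:
        return self.hemisphere == "L"

    def hemisphere_regions(self, hemi: str) -> np.ndarray:
        """Region indices belonging to one hemisphere, in atlas order."""
        return np.flatnonzero(self.hemisphere == hemi)


def _sphere_lattice(n: int, phase: float = 0.0) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice on the full unit sphere.

    Each hemisphere owns its own spherical projection (as cortical surface
    pipelines inflate each hemisphere to its own sphere), so its lattice
    covers the whole sphere; the other hemisphere uses the x-mirror.
    """
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    sin_phi = np.sqrt(1.0 - z**2)
    theta = _GOLDEN_ANGLE * i + phase
    pts = np.column_stack(
        [sin_phi * np.cos(theta), sin_phi * np.sin(theta), z]
    )
    return pts


def generate_parcellation(
    n_regions: int = 308, vertices_per_region: int = 100, seed: int = 0
) -> ParcellationGeometry:
    """Build a symmetric two-hemisphere parcellation with assigned vertices.

    ``n_regions`` must be even; half the regions go to each hemisphere and
    the right hemisphere is the x-mirror of the left.  ``vertices_per_region``
    sets the average vertex density: each hemisphere receives
    ``n_regions/2 * vertices_per_region`` lattice vertices, each assigned to
    its nearest centroid within the hemisphere.  The seed only randomizes the
    azimuthal phase of the vertex lattice; the layout is otherwise
    deterministic.
    """
    if n_regions < 2 or n_regions % 2 != 0:
        raise ValueError(f"n_regions must be even and >= 2, got {n_regions}")
    if vertices_per_region < 10:
        raise ValueError("vertices_per_region must be >= 10")

    n_half = n_regions // 2
    left = _sphere_lattice(n_half)
    right = left * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])

    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    vleft = _sphere_lattice(n_half * vertices_per_region, phase=phase)
    vright = vleft * np.array([-1.0, 1.0, 1.0])

    # nearest centroid within hemisphere (cosine distance == argmax dot)
    idx_left = np.argmax(vleft @ left.T, axis=1)
    idx_right = np.argmax(vright @ right.T, axis=1) + n_half

    region_ids = np.array(
        [f"L{i + 1:03d}" for i in range(n_half)]
        + [f"R{i + 1:03d}" for i in range(n_half)]
    )
    hemisphere = np.array(["L"] * n_half + ["R"] * n_half)
    return ParcellationGeometry(
        region_ids=region_ids,
        centroids=centroids,
        hemisphere=hemisphere,
        vertex_positions=np.vstack([vleft, vright]),
        vertex_region_idx=np.concatenate([idx_left, idx_right]),
        seed=seed,
    )
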