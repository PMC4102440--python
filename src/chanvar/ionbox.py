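"""Minimal bounding boxes and equivalent van der Waals radii of small ions.

An ion is modelled as a union of atom-centered van der Waals spheres.  The
minimal bounding box is found by scanning rigid orientations (a uniform
Euler-angle grid, then simplex refinement) and measuring the axis-aligned
box of the rotated spheres; the orientation of minimum volume wins.  Two
published conventions turn the box into a single "equivalent radius" for a
non-spherical ion: half of the second-largest box dimension, or the mean of
the two smaller half-dimensions (both reflect the minimal cross-section the
ion must squeeze through a pore).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

__all__ = [
    "IonModel",
    "BoundingBox",
    "minimal_bounding_box",
    "equivalent_radius",
    "bicarbonate_synthetic",
    "chloride",
    "BONDI_RADII",
]

#: Bondi van der Waals radii (Angstrom) for elements handled here.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75,
}

#: Effective radius of the mono-atomic chloride ion (Angstrom, Bondi-based
#: ionic value commonly used for permeation geometry).
CHLORIDE_RADIUS = 1.81


@dataclass
class IonModel:
    """Atom centers plus van der Waals radii describing one ion."""

    elements: np.ndarray
    coords: np.ndarray
    vdw_radii: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.vdw_radii = np.atleast_1d(np.asarray(self.vdw_radii, dtype=float))
        if self.coords.shape[0] < 1:
            raise ValueError("an ion needs at least one atom")
        if np.any(self.vdw_radii <= 0):
            raise ValueError("van der Waals radii must be positive")


@dataclass
class BoundingBox:
    """Box side lengths sorted ascending plus the rotation achieving them."""

    extents: tuple[float, float, float]
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.extents = tuple(sorted(float(e) for e in self.extents))

    @property
    def volume(self) -> float:
        e = self.extents
        return e[0] * e[1] * e[2]


def _extents_for(matrices: np.ndarray, coords: np.ndarray,
                 radii: np.ndarray) -> np.ndarray:
    """Axis-aligned extents of the sphere union under a stack of rotations."""
    rotated = np.einsum("kij,nj->kni", matrices, coords)
    upper = (rotated + radii[None, :, None]).max(axis=1)
    lower = (rotated - radii[None, :, None]).min(axis=1)
    return upper - lower


def minimal_bounding_box(
    ion: IonModel, grid_deg: float = 5.0, refine: bool = True
) -> BoundingBox:
    """Minimum-volume box over searched orientations containing all spheres.

    A uniform Euler-angle grid with spacing ``grid_deg`` (degrees, in
    (0, 30]) seeds a Nelder-Mead refinement.  The search is deterministic
    for a fixed grid.
    """
    if not 0 < grid_deg <= 30:
        raise ValueError("grid_deg must be in (0, 30]")
    coords = ion.coords - ion.coords.mean(axis=0)
    radii = ion.vdw_radii
    angles = np.arange(0.0, 180.0, grid_deg)
    grid = np.stack(np.meshgrid(angles, angles, angles, indexing="ij"),
                    axis=-1).reshape(-1, 3)
    best_vol = np.inf
    best_angles = np.zeros(3)
    # chunk the grid to bound memory for fine grids
    for chunk in np.array_split(grid, max(1, grid.shape[0] // 20000)):
        mats = Rotation.from_euler("xyz", chunk, degrees=True).as_matrix()
        ext = _extents_for(mats, coords, radii)
        vols = ext.prod(axis=1)
        k = int(np.argmin(vols))
        if vols[k] < best_vol:
            best_vol = float(vols[k])
            best_angles = chunk[k]

    if refine:
        def volume_of(angles_deg: np.ndarray) -> float:
            mat = Rotation.from_euler("xyz", angles_deg, degrees=True
                                      ).as_matrix()[None]
            return float(_extents_for(mat, coords, radii).prod())

        res = minimize(
            volume_of, x0=best_angles, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if res.fun <= best_vol:
            best_angles = res.x
    mat = Rotation.from_euler("xyz", best_angles, degrees=True).as_matrix()
    ext = _extents_for(mat[None], coords, radii)[0]
    return BoundingBox(tuple(ext), mat)


def equivalent_radius(box: BoundingBox, rule: str) -> float:
    """Equivalent van der Waals radius of an ion from its bounding box.

    rule = "half_second_largest":       extents[1] / 2
    rule = "mean_two_smallest_halves":  (extents[0]/2 + extents[1]/2) / 2
    """
    e = box.extents
    if rule == "half_second_largest":
        return e[1] / 2.0
    if rule == "mean_two_smallest_halves":
        return (e[0] / 2.0 + e[1] / 2.0) / 2.0
    raise ValueError(f"unknown rule: {rule!r}")


def chloride() -> IonModel:
    """Mono-atomic chloride ion with its Bondi-based effective radius."""
    return IonModel(["CL"], [[0.0, 0.0, 0.0]], [CHLORIDE_RADIUS], name="Cl-")


def bicarbonate_synthetic() -> IonModel:
    """A synthetic planar bicarbonate (HCO3-) geometry for demonstrations.

    Bond lengths and angles are textbook equilibrium values (delocalized
    C-O ~1.25 A, C-OH 1.42 A, O-H 0.97 A, trigonal-planar carbon); this is
    a constructed stand-in, not an ab initio optimized geometry.
    """
    c = np.array([0.0, 0.0, 0.0])
    o1 = 1.25 * np.array([np.cos(np.deg2rad(0)), np.sin(np.deg2rad(0)), 0.0])
    o2 = 1.25 * np.array([np.cos(np.deg2rad(126)), np.sin(np.deg2rad(126)), 0.0])
    o3 = 1.42 * np.array([np.cos(np.deg2rad(-117)), np.sin(np.deg2rad(-117)), 0.0])
    h_dir = np.deg2rad(-117 + 75)
    h = o3 + 0.97 * np.array([np.cos(h_dir), np.sin(h_dir), 0.0])
    coords = np.stack([c, o1, o2, o3, h])
    elements = ["C", "O", "O", "O", "H"]
    radii = [BONDI_RADII[e] for e in elements]
    return IonModel(elements, coords, radii, name="HCO3- (synthetic)")
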