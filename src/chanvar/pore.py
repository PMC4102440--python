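"""Channel pore geometry: radius profiles, constriction diameters, RMSD.

The permeation pathway of a channel is profiled by sliding a plane along a
pore axis and, at each elevation, finding the maximal disc (centered by
local search near the axis) that avoids all atom van der Waals spheres --
the same geometric idea as the HOLE program.  The width of the pathway at a
specific residue pair (e.g. a mutation site against the residue across the
cavity) is instead measured as the closest interatomic center-to-center
distance between the two residues, tracked per frame across a trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "AtomicStructure",
    "Trajectory",
    "PoreProfile",
    "DiameterSeries",
    "ConstrictionStats",
    "superpose_rmsd",
    "pore_profile",
    "site_min_distance",
    "diameter_series",
    "constriction_stats",
]


@dataclass
class AtomicStructure:
    """Atoms with coordinates and van der Waals radii (all in Angstrom)."""

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    vdw_radii: np.ndarray

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.vdw_radii <= 0):
            raise ValueError("van der Waals radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def residue_mask(self, chain_id: str, res_id: int) -> np.ndarray:
        return (self.chain_ids == chain_id) & (self.res_ids == res_id)


@dataclass
class Trajectory:
    """Frames sharing one topology: coords (n_frames, n_atoms, 3), times in ps."""

    topology: AtomicStructure
    coords: np.ndarray
    times_ps: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count differs from topology")
        if self.times_ps.shape[0] != self.coords.shape[0]:
            raise ValueError("one time per frame required")
        if np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> AtomicStructure:
        top = self.topology
        return AtomicStructure(
            top.atom_names, top.elements, top.res_ids, top.chain_ids,
            self.coords[i], top.vdw_radii,
        )


@dataclass
class PoreProfile:
    """Pore radius per elevation along the axis; NaN where no atoms define it."""

    elevations: np.ndarray
    radii: np.ndarray
    axis_point: np.ndarray
    axis_direction: np.ndarray

    @property
    def min_radius(self) -> float:
        return float(np.nanmin(self.radii))

    @property
    def min_elevation(self) -> float:
        return float(self.elevations[np.nanargmin(self.radii)])


@dataclass
class DiameterSeries:
    """Per-frame closest-approach distance for a named residue pair."""

    times_ps: np.ndarray
    diameters: np.ndarray
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]


@dataclass
class ConstrictionStats:
    mean: float
    sd: float
    hist_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    frames_used: int = 0


def superpose_rmsd(
    mobile: AtomicStructure,
    reference: AtomicStructure,
    selection: np.ndarray | None = None,
) -> float:
    """RMSD after optimal least-squares rigid superposition (Kabsch).

    ``selection`` is a boolean mask or index array applied to both
    structures, which must match 1:1 in atom identity and count.
    """
    p = mobile.coords if selection is None else mobile.coords[selection]
    q = reference.coords if selection is None else reference.coords[selection]
    if p.shape != q.shape:
        raise ValueError("selections must map atoms 1:1")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    sv = np.linalg.svd(qc, compute_uv=False)
    if sv[1] < 1e-8 * sv[0]:
        raise ValueError("selection is collinear: superposition is degenerate")
    u, _, vt = np.linalg.svd(pc.T @ qc)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    residual = pc @ rotation.T - qc
    return float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))


def _orthonormal_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def pore_profile(
    structure: AtomicStructure,
    z_min: float,
    z_max: float,
    step: float,
    axis_point: np.ndarray | None = None,
    axis_direction: np.ndarray = (0.0, 0.0, 1.0),
    selection: np.ndarray | None = None,
    max_shift: float = 5.0,
) -> PoreProfile:
    """Maximal-inscribed-disc radius at each elevation along the pore axis.

    At elevation z the probe center starts on the axis and is moved in-plane
    (by Nelder-Mead, never further than ``max_shift`` from the axis) to
    maximize the clearance ``min_i(|center - atom_i| - vdw_i)``.  A negative
    optimum (occluded pore) is reported as radius 0; an elevation whose slab
    contains no atoms is reported as NaN.  The slab half-width is
    ``step/2 + max(vdw)`` so that no atom can fall between slices.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    coords = structure.coords if selection is None else structure.coords[selection]
    radii = structure.vdw_radii if selection is None else structure.vdw_radii[selection]
    if coords.shape[0] == 0:
        raise ValueError("probe selection is empty")
    direction = np.asarray(axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if axis_point is None:
        axis_point = coords.mean(axis=0)
    axis_point = np.asarray(axis_point, dtype=float)
    e1, e2 = _orthonormal_basis(direction)

    z_atoms = (coords - axis_point) @ direction
    half_width = step / 2.0 + float(np.max(radii))
    elevations = np.arange(z_min, z_max + 0.5 * step, step)
    out = np.full(elevations.shape, np.nan)
    for i, z in enumerate(elevations):
        slab = np.abs(z_atoms - z) <= half_width
        if not np.any(slab):
            continue
        slab_xyz = coords[slab]
        slab_r = radii[slab]
        seed = axis_point + z * direction

        def neg_clearance(uv: np.ndarray) -> float:
            if uv @ uv > max_shift**2:
                return np.inf
            center = seed + uv[0] * e1 + uv[1] * e2
            d = np.sqrt(np.sum((slab_xyz - center) ** 2, axis=1))
            return -float(np.min(d - slab_r))

        res = minimize(
            neg_clearance,
            x0=np.zeros(2),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 400},
        )
        out[i] = max(-res.fun, 0.0)
    return PoreProfile(elevations, out, axis_point, direction)


def site_min_distance(
    structure: AtomicStructure,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
) -> float:
    """Closest interatomic center-to-center distance between two residues."""
    mask_a = structure.residue_mask(*residue_a)
    mask_b = structure.residue_mask(*residue_b)
    for name, mask in ((residue_a, mask_a), (residue_b, mask_b)):
        if not np.any(mask):
            raise ValueError(f"residue {name[0]}:{name[1]} not found")
    if residue_a == residue_b:
        warnings.warn(
            "residue_a equals residue_b: distance is degenerately 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    return float(cdist(structure.coords[mask_a], structure.coords[mask_b]).min())


def diameter_series(
    trajectory: Trajectory,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
) -> DiameterSeries:
    """Per-frame closest-approach distance between two residues.

    Following common practice for mutation-site monitoring, the value is the
    center-to-center distance, not reduced by van der Waals radii.
    """
    top = trajectory.topology
    mask_a = top.residue_mask(*residue_a)
    mask_b = top.residue_mask(*residue_b)
    for name, mask in ((residue_a, mask_a), (residue_b, mask_b)):
        if not np.any(mask):
            raise ValueError(f"residue {name[0]}:{name[1]} not found")
    diameters = np.array([
        cdist(frame[mask_a], frame[mask_b]).min() for frame in trajectory.coords
    ])
    return DiameterSeries(trajectory.times_ps.copy(), diameters, residue_a, residue_b)


def constriction_stats(
    series: DiameterSeries,
    discard_initial_ps: float | None = None,
    bins: int = 30,
) -> ConstrictionStats:
    """Mean, sample SD and histogram of a diameter series after equilibration.

    ``discard_initial_ps`` drops the leading transient; the default discards
    the first 10% of the simulated span (production MD conventionally drops
    an initial equilibration window).
    """
    t = series.times_ps
    if discard_initial_ps is None:
        discard_initial_ps = 0.1 * (t[-1] - t[0])
    keep = t >= t[0] + discard_initial_ps
    values = series.diameters[keep]
    if values.size < 2:
        raise ValueError("fewer than 2 frames remain after discarding")
    counts, edges = np.histogram(values, bins=bins)
    return ConstrictionStats(
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        hist_counts=counts,
        hist_edges=edges,
        frames_used=int(values.size),
    )
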