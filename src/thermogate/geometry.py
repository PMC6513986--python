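"""Pore geometry: solvent accessibility, radius profiles, conductance.

Solvent-accessible surface area (SASA) follows Shrake & Rupley: each atom's
sphere is expanded by the probe radius and sampled with a deterministic
golden-spiral point lattice; a point is accessible iff it lies strictly
outside every other atom's expanded sphere.  Exact surface-point ties
(distance equal to the other sphere's radius, e.g. two coincident atoms)
are awarded to the lower-index atom, so a duplicated atom is fully buried
and total area is conserved.

The pore-radius profile r(z) is the radius of the largest sphere centred in
each z-slab that touches no atom — the same quantity the HOLE program
reports — found by seeded stochastic annealing warm-started slab to slab.
Conductance is the Ohmic estimate from the resistance integral
R = ρ ∫ dz / (π r(z)²), optionally with access-resistance end corrections
ρ/(4 r) at each mouth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import ChannelStructure, RadiiSet, assign_radii

__all__ = [
    "SasaResult",
    "PoreProfile",
    "ConductanceEstimate",
    "sasa",
    "sasa_residue",
    "delta_sasa",
    "grid_sasa",
    "pore_profile",
    "min_radius",
    "predict_conductance",
    "compare_profiles",
    "golden_spiral_points",
]

#: Default resistivity of physiological (~150 mM) saline, Ω·m.
DEFAULT_RESISTIVITY = 0.8


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-spiral lattice).

    Deterministic: no RNG involved, so SASA values are exactly reproducible
    for a given point count.
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas (Å²)."""

    atom_areas: np.ndarray
    residue_areas: dict  # (chain_id, res_id) -> Å²
    probe_radius: float
    point_count: int

    def residue_area(self, res_id: int, chain_id: str | None = None) -> float:
        """SASA of a residue; summed over all chains if chain unspecified."""
        if chain_id is not None:
            key = (chain_id, res_id)
            if key not in self.residue_areas:
                raise KeyError(f"residue {res_id} of chain {chain_id} not found")
            return self.residue_areas[key]
        hits = [a for (c, r), a in self.residue_areas.items() if r == res_id]
        if not hits:
            raise KeyError(f"residue {res_id} not found in any chain")
        return float(sum(hits))


_TIE_TOL = 1e-9


def _molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal frame attached to the molecule.

    Sphere sample points are expressed in this frame (principal axes with
    skewness-fixed signs), which rotates with the molecule — making the
    lattice-sampled SASA exactly invariant under rigid motion.
    """
    if len(coords) < 2:
        return np.eye(3)
    x = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(x.T @ x)
    v = vecs[:, ::-1].copy()
    for i in range(3):
        skew = float(np.sum((x @ v[:, i]) ** 3))
        if skew < 0:
            v[:, i] = -v[:, i]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def _accessible_fraction(
    coords: np.ndarray,
    radii_exp: np.ndarray,
    indices: np.ndarray,
    points: np.ndarray,
    tree: cKDTree,
) -> np.ndarray:
    """Fraction of surface points of each atom in ``indices`` that are not
    inside (strictly, with lower-index tie ownership) any other atom's
    expanded sphere."""
    r_max = float(radii_exp.max())
    frac = np.empty(len(indices))
    for out_i, i in enumerate(indices):
        pts = coords[i] + radii_exp[i] * points
        neigh = tree.query_ball_point(coords[i], radii_exp[i] + r_max)
        buried = np.zeros(len(points), dtype=bool)
        for j in neigh:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            rj2 = radii_exp[j] ** 2
            buried |= d2 < rj2 - _TIE_TOL
            if j < i:
                buried |= np.abs(d2 - rj2) <= _TIE_TOL
        frac[out_i] = 1.0 - buried.mean()
    return frac


def _require_radii(structure: ChannelStructure,
                   radii_set: RadiiSet | None) -> ChannelStructure:
    if structure.radii is None:
        return assign_radii(structure, radii_set)
    return structure


def sasa(
    structure: ChannelStructure,
    radii_set: RadiiSet | None = None,
    n_points: int = 960,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area of every atom.

    ``n_points`` golden-spiral points sample each expanded sphere
    (radius r_atom + probe).  Per-residue areas are the sums of their
    member-atom areas, keyed by ``(chain_id, res_id)``.
    """
    if structure.n_atoms == 0:
        raise ValueError("cannot compute SASA of an empty structure")
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    structure = _require_radii(structure, radii_set)
    probe = (radii_set or RadiiSet()).probe_radius
    radii_exp = structure.radii + probe
    points = golden_spiral_points(n_points) @ _molecular_frame(
        structure.coords).T
    tree = cKDTree(structure.coords)
    frac = _accessible_fraction(
        structure.coords, radii_exp, np.arange(structure.n_atoms), points, tree
    )
    areas = frac * 4.0 * np.pi * radii_exp**2
    residue_areas: dict = {}
    for (chain, rid), a in zip(
        zip(structure.chain_ids, structure.res_ids), areas
    ):
        key = (str(chain), int(rid))
        residue_areas[key] = residue_areas.get(key, 0.0) + float(a)
    return SasaResult(areas, residue_areas, probe, n_points)


def sasa_residue(
    structure: ChannelStructure,
    res_id: int,
    chain_id: str | None = None,
    radii_set: RadiiSet | None = None,
    n_points: int = 960,
) -> float:
    """SASA (Å²) of one residue, computed without touching other atoms'
    areas — identical to the corresponding entry of :func:`sasa` but much
    cheaper on large structures."""
    structure = _require_radii(structure, radii_set)
    probe = (radii_set or RadiiSet()).probe_radius
    mask = structure.residue_mask(res_id, chain_id)
    if not mask.any():
        where = f"chain {chain_id}" if chain_id else "any chain"
        raise KeyError(f"residue {res_id} not found in {where}")
    radii_exp = structure.radii + probe
    points = golden_spiral_points(n_points) @ _molecular_frame(
        structure.coords).T
    tree = cKDTree(structure.coords)
    idx = np.nonzero(mask)[0]
    frac = _accessible_fraction(structure.coords, radii_exp, idx, points, tree)
    return float(np.sum(frac * 4.0 * np.pi * radii_exp[idx] ** 2))


def delta_sasa(
    site: int,
    structure_a: ChannelStructure,
    structure_b: ChannelStructure,
    radii_set: RadiiSet | None = None,
    chain_id: str | None = None,
    n_points: int = 960,
) -> float:
    """Per-residue SASA difference of ``site``: SASA(a) − SASA(b), Å².

    Positive means the site is more exposed in ``a`` (equivalently, buried
    on going from a to b).  With ``chain_id`` unset the residue's area is
    summed over all chains carrying that residue number.
    """
    a = sasa_residue(structure_a, site, chain_id, radii_set, n_points)
    b = sasa_residue(structure_b, site, chain_id, radii_set, n_points)
    return a - b


def grid_sasa(
    structure: ChannelStructure,
    radii_set: RadiiSet | None = None,
    resolution: float = 0.1,
) -> np.ndarray:
    """Voxel-shell reference SASA (per atom, Å²); slow but independent.

    The accessible area of atom i is estimated as (volume of the voxelized
    shell of thickness ``resolution`` around its expanded sphere that lies
    outside all other expanded spheres) / ``resolution``.  Used as the
    cross-check oracle for :func:`sasa`; do not use on large structures.
    """
    structure = _require_radii(structure, radii_set)
    probe = (radii_set or RadiiSet()).probe_radius
    coords = structure.coords
    radii_exp = structure.radii + probe
    h = resolution
    areas = np.empty(structure.n_atoms)
    for i in range(structure.n_atoms):
        r = radii_exp[i]
        lo = coords[i] - (r + h)
        hi = coords[i] + (r + h)
        ax = [np.arange(lo[d] + h / 2, hi[d], h) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d = np.linalg.norm(pts - coords[i], axis=1)
        shell = np.abs(d - r) <= h / 2
        pts = pts[shell]
        free = np.ones(len(pts), dtype=bool)
        for j in range(structure.n_atoms):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            rj2 = radii_exp[j] ** 2
            free &= ~(d2 < rj2 - _TIE_TOL)
            if j < i:
                free &= ~(np.abs(d2 - rj2) <= _TIE_TOL)
        areas[i] = free.sum() * h**3 / h
    return areas


# ---------------------------------------------------------------------------
# Pore profile
# ---------------------------------------------------------------------------

@dataclass
class PoreProfile:
    """Pore radius r(z) along the permeation axis.

    ``z`` is a strictly increasing grid with constant step; ``radius`` the
    largest-sphere radius per slab; ``center_x``/``center_y`` the channel
    centre path; ``capped`` flags slabs where no atom bounded the search and
    the radius was clipped at ``max_radius``.  ``regions`` maps each z index
    to the sorted residue numbers lining the pore there.
    """

    z: np.ndarray
    radius: np.ndarray
    center_x: np.ndarray
    center_y: np.ndarray
    capped: np.ndarray
    seed: int | None = None
    regions: list = field(default_factory=list)

    @property
    def step(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0


def _slab_radius(point: np.ndarray, coords: np.ndarray,
                 radii: np.ndarray) -> float:
    d = np.linalg.norm(coords - point, axis=1) - radii
    return float(d.min())


def pore_profile(
    structure: ChannelStructure,
    z_min: float,
    z_max: float,
    step: float = 0.25,
    seed: int = 0,
    radii_set: RadiiSet | None = None,
    max_radius: float = 15.0,
    n_evals: int = 2000,
    initial_step: float = 2.0,
    cooling: float = 0.95,
    max_jump: float = 1.5,
    annotate: bool = True,
) -> PoreProfile:
    """Largest-sphere pore-radius profile of an axis-aligned structure.

    For each z-slab the sphere centre (x, y) maximising
    ``min_i (|p − c_i| − r_i)`` is found by stochastic annealing (Gaussian
    moves with geometrically cooled step size, greedy acceptance),
    warm-started from the previous slab's optimum and confined to within
    ``max_jump`` Å of it so the centre line is a connected path (the first
    slab starts on the axis); the search is deterministic for a fixed
    ``seed``.  Slabs where no atom lies within reach are capped at
    ``max_radius`` and flagged.
    """
    structure = _require_radii(structure, radii_set)
    coords = structure.coords
    radii = structure.radii
    if coords.shape[0] == 0:
        raise ValueError("empty structure")
    span_lo, span_hi = coords[:, 2].min(), coords[:, 2].max()
    if z_min < span_lo - 1e-9 or z_max > span_hi + 1e-9:
        raise ValueError(
            f"z range [{z_min}, {z_max}] outside atom span "
            f"[{span_lo:.2f}, {span_hi:.2f}]"
        )
    rng = np.random.default_rng(seed)
    z_grid = z_min + step * np.arange(int(np.floor((z_max - z_min) / step)) + 1)
    tree = cKDTree(coords)
    r_atom_max = float(radii.max())

    radius = np.empty(len(z_grid))
    cx = np.empty(len(z_grid))
    cy = np.empty(len(z_grid))
    capped = np.zeros(len(z_grid), dtype=bool)
    regions: list = []
    center = np.array([0.0, 0.0])

    # Lateral search bound: the channel centre cannot lie outside the
    # structure's own footprint (prevents the search escaping through an
    # open mouth, where the objective grows without bound).
    r_xy_max = float(np.max(np.linalg.norm(coords[:, :2], axis=1)))

    batch = 25
    n_batches = max(1, n_evals // batch)
    for k, z in enumerate(z_grid):
        idx = tree.query_ball_point(
            [0.0, 0.0, z], r_xy_max + max_radius + r_atom_max
        )
        if not idx:
            radius[k] = max_radius
            capped[k] = True
            cx[k], cy[k] = center
            regions.append([])
            continue
        local = coords[idx]
        local_r = radii[idx]

        def objective(xy_batch):
            pts = np.column_stack([xy_batch,
                                   np.full(len(xy_batch), z)])
            d = (
                np.linalg.norm(local[None, :, :] - pts[:, None, :], axis=2)
                - local_r[None, :]
            ).min(axis=1)
            return np.minimum(d, max_radius)

        anchor = center.copy()
        best, best_xy = float(objective(anchor[None, :])[0]), anchor.copy()
        sigma = min(initial_step, max_jump)
        for _ in range(n_batches):
            props = best_xy + sigma * rng.standard_normal((batch, 2))
            # connected path: stay within max_jump of the previous slab's
            # centre (prevents tunnelling through the pore wall), and
            # inside the structure's lateral footprint
            jump = np.linalg.norm(props - anchor, axis=1)
            over = jump > max_jump
            if over.any():
                props[over] = anchor + (props[over] - anchor) \
                    * (max_jump / jump[over])[:, None]
            norms = np.linalg.norm(props, axis=1)
            over = norms > r_xy_max
            if over.any():
                props[over] *= (r_xy_max / norms[over])[:, None]
            d = objective(props)
            j = int(np.argmax(d))
            if d[j] > best:
                best = float(d[j])
                best_xy = props[j]
            sigma *= cooling
        if best >= max_radius:
            best = max_radius
            capped[k] = True
        radius[k] = max(best, 0.0)
        cx[k], cy[k] = best_xy
        center = best_xy
        if annotate:
            p_best = np.array([best_xy[0], best_xy[1], z])
            lining = (
                np.linalg.norm(local - p_best, axis=1) - local_r
                <= max(best, 0.0) + 1.0
            )
            rids = structure.res_ids[idx] if isinstance(idx, list) else []
            regions.append(sorted(set(int(r) for r in
                                      np.asarray(rids)[lining])))
        else:
            regions.append([])
    return PoreProfile(z_grid, radius, cx, cy, capped, seed, regions)


def min_radius(
    profile: PoreProfile, z_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Global minimum pore radius over ``z_range`` and its z location.

    Ties are broken toward the smallest z.
    """
    if z_range is None:
        mask = np.ones(len(profile.z), dtype=bool)
    else:
        lo, hi = z_range
        mask = (profile.z >= lo) & (profile.z <= hi)
    if not mask.any():
        raise ValueError("z_range contains no profile grid points")
    r = profile.radius[mask]
    z = profile.z[mask]
    i = int(np.argmin(r))  # argmin returns first occurrence → smallest z
    return float(r[i]), float(z[i])


# ---------------------------------------------------------------------------
# Conductance
# ---------------------------------------------------------------------------

@dataclass
class ConductanceEstimate:
    """Ohmic conductance predicted from a pore profile."""

    conductance_pS: float
    resistivity: float        # Ω·m
    correction: float
    access_resistance: bool
    occluded: bool = False


def predict_conductance(
    profile: PoreProfile,
    resistivity: float = DEFAULT_RESISTIVITY,
    correction: float = 1.0,
    access_resistance: bool = False,
    probe_floor: float = 0.0,
) -> ConductanceEstimate:
    """Conductance G = correction / R with R the trapezoid-integrated
    resistance ρ ∫ dz / (π r(z)²) (SI units internally; result in pS).

    With ``access_resistance`` the bulk access term ρ/(4 r) is added at each
    mouth.  A profile whose minimum radius is ≤ ``probe_floor`` is reported
    as occluded with zero conductance.
    """
    r_m = profile.radius * 1e-10
    z_m = profile.z * 1e-10
    if np.any(profile.radius <= probe_floor) or np.any(r_m <= 0):
        return ConductanceEstimate(0.0, resistivity, correction,
                                   access_resistance, occluded=True)
    integrand = 1.0 / (np.pi * r_m**2)
    resistance = resistivity * np.trapezoid(integrand, z_m)
    if access_resistance:
        resistance += resistivity / (4.0 * r_m[0])
        resistance += resistivity / (4.0 * r_m[-1])
    g_pS = correction / resistance * 1e12
    return ConductanceEstimate(float(g_pS), resistivity, correction,
                               access_resistance)


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------

@dataclass
class ProfileComparison:
    """Aligned difference track between two pore profiles."""

    z: np.ndarray
    delta_r: np.ndarray            # r_a − r_b on the common grid
    flagged_regions: list          # [(z_start, z_end), ...] where |Δr| > thr
    threshold: float


def compare_profiles(
    profile_a: PoreProfile,
    profile_b: PoreProfile,
    threshold: float = 0.5,
) -> ProfileComparison:
    """Per-z radius differences r_a(z) − r_b(z), resampling b onto a's grid
    over the overlap, with contiguous regions where |Δr| > ``threshold``
    reported as (z_start, z_end) intervals."""
    lo = max(profile_a.z[0], profile_b.z[0])
    hi = min(profile_a.z[-1], profile_b.z[-1])
    if lo > hi:
        raise ValueError("profiles cover disjoint z ranges")
    mask = (profile_a.z >= lo - 1e-12) & (profile_a.z <= hi + 1e-12)
    z = profile_a.z[mask]
    rb = np.interp(z, profile_b.z, profile_b.radius)
    delta = profile_a.radius[mask] - rb
    over = np.abs(delta) > threshold
    regions = []
    start = None
    for i, flag in enumerate(over):
        if flag and start is None:
            start = z[i]
        elif not flag and start is not None:
            regions.append((float(start), float(z[i - 1])))
            start = None
    if start is not None:
        regions.append((float(start), float(z[-1])))
    return ProfileComparison(z, delta, regions, threshold)
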