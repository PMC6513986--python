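"""Channel structures: PDB I/O, radii assignment, axis alignment, C4 symmetry.

A :class:`ChannelStructure` is a light array-of-records container for a
(typically homotetrameric) ion-channel structure.  Coordinates are in
ångström, residue numbering is 1-based as in the PDB format, and after
:func:`align_pore_axis` the molecular symmetry axis coincides with +z with
the centroid at the origin.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

import biotite.structure as bst
import biotite.structure.io.pdb as bst_pdb

__all__ = [
    "ChannelStructure",
    "RadiiSet",
    "LoopSpec",
    "BONDI_RADII",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "assign_radii",
    "align_pore_axis",
    "symmetrize_c4",
]

#: Bondi van der Waals radii (Å).  The default radii set for SASA and
#: pore-profile calculations; configurable through :class:`RadiiSet`.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed; carries the line number."""


@dataclass
class RadiiSet:
    """Mapping from element symbol to van der Waals radius (Å).

    Parameters
    ----------
    radii
        Element symbol (upper case) → radius in Å.
    probe_radius
        Solvent probe radius in Å (1.4 Å ≈ water).
    default
        Fallback radius for elements absent from ``radii``; ``None`` means
        unknown elements are an error.
    """

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    probe_radius: float = 1.4
    default: float | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all van der Waals radii must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")

    def lookup(self, elements: np.ndarray) -> np.ndarray:
        """Resolve an array of element symbols to radii; raise on unknowns."""
        out = np.empty(len(elements), dtype=float)
        unknown = []
        for i, el in enumerate(elements):
            key = str(el).upper()
            if key in self.radii:
                out[i] = self.radii[key]
            elif self.default is not None:
                out[i] = self.default
            else:
                unknown.append((i, key))
        if unknown:
            shown = ", ".join(f"atom {i} ({el})" for i, el in unknown[:10])
            raise KeyError(
                f"{len(unknown)} atom(s) with unknown element and no default "
                f"radius: {shown}"
            )
        return out


@dataclass
class LoopSpec:
    """Segments to remodel, plus the marker residue carrying the burial
    constraint.

    ``segments`` is a list of ``(chain_id, start_residue, end_residue)``
    tuples (inclusive, 1-based).  ``marker_site`` is the residue number whose
    solvent accessibility is constrained during refinement.
    """

    segments: list[tuple[str, int, int]]
    marker_site: int

    def __post_init__(self) -> None:
        seen: list[tuple[str, int, int]] = []
        for chain, start, end in self.segments:
            if start > end:
                raise ValueError(f"segment {chain}:{start}-{end} has start > end")
            for c2, s2, e2 in seen:
                if c2 == chain and not (end < s2 or start > e2):
                    raise ValueError(
                        f"segments {chain}:{start}-{end} and {c2}:{s2}-{e2} overlap"
                    )
            seen.append((chain, start, end))


@dataclass
class ChannelStructure:
    """Atomic model of a channel with optional per-atom radii.

    Fields are parallel arrays over atoms.  ``hetero`` marks HETATM records
    (ligands, toxins); by default these are excluded from pore and SASA
    calculations (see :meth:`protein_only`).
    """

    ids: np.ndarray               # int, atom serial
    elements: np.ndarray          # str
    atom_names: np.ndarray        # str, e.g. "CA"
    res_ids: np.ndarray           # int, 1-based
    res_names: np.ndarray         # str, e.g. "ALA"
    chain_ids: np.ndarray         # str
    coords: np.ndarray            # (n, 3) float, Å
    hetero: np.ndarray            # bool
    radii: np.ndarray | None = None
    symmetry_order: int = 4
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.res_ids) and np.min(self.res_ids) < 1:
            raise ValueError("residue numbers must be >= 1 (PDB convention)")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def copy(self) -> "ChannelStructure":
        return ChannelStructure(
            ids=self.ids.copy(),
            elements=self.elements.copy(),
            atom_names=self.atom_names.copy(),
            res_ids=self.res_ids.copy(),
            res_names=self.res_names.copy(),
            chain_ids=self.chain_ids.copy(),
            coords=self.coords.copy(),
            hetero=self.hetero.copy(),
            radii=None if self.radii is None else self.radii.copy(),
            symmetry_order=self.symmetry_order,
            axis=self.axis.copy(),
        )

    def select(self, mask: np.ndarray) -> "ChannelStructure":
        """Sub-structure of the atoms where ``mask`` is True."""
        return ChannelStructure(
            ids=self.ids[mask],
            elements=self.elements[mask],
            atom_names=self.atom_names[mask],
            res_ids=self.res_ids[mask],
            res_names=self.res_names[mask],
            chain_ids=self.chain_ids[mask],
            coords=self.coords[mask],
            hetero=self.hetero[mask],
            radii=None if self.radii is None else self.radii[mask],
            symmetry_order=self.symmetry_order,
            axis=self.axis.copy(),
        )

    def protein_only(self) -> "ChannelStructure":
        """Drop HETATM records and non-standard residues."""
        std = np.isin(self.res_names, list(_STANDARD_AA))
        return self.select(~self.hetero & std)

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        _, idx = np.unique(self.chain_ids, return_index=True)
        return [self.chain_ids[i] for i in sorted(idx)]

    def residue_mask(self, res_id: int, chain_id: str | None = None) -> np.ndarray:
        mask = self.res_ids == res_id
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        return mask


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed, with a stricter pre-validation pass so that parse
# failures report the offending line)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(
                f"line {lineno}: truncated ATOM/HETATM record "
                f"({len(line)} < 54 columns)"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparsable {what} coordinate "
                    f"{line[lo:hi]!r}"
                ) from None


def read_pdb(path, symmetry_order: int = 4) -> ChannelStructure:
    """Read ATOM/HETATM records from a PDB file.

    Atoms are kept in file order with chain and residue labels preserved.
    Raises :class:`PDBParseError` (naming the line) on malformed records and
    :class:`ValueError` on a file with no atoms.
    """
    with open(path) as fh:
        text = fh.read()
    _validate_pdb_lines(text)
    pdb_file = bst_pdb.PDBFile.read(_io.StringIO(text))
    try:
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - biotite-internal failures
        raise PDBParseError(f"biotite failed to parse {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return ChannelStructure(
        ids=np.arange(1, arr.array_length() + 1),
        elements=arr.element.astype(str),
        atom_names=arr.atom_name.astype(str),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype(str),
        chain_ids=arr.chain_id.astype(str),
        coords=np.asarray(arr.coord, dtype=float),
        hetero=arr.hetero.astype(bool),
        symmetry_order=symmetry_order,
    )


def write_pdb(structure: ChannelStructure, path) -> None:
    """Write the structure as wwPDB v3.3 ATOM/HETATM records."""
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_ids.astype(int)
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.hetero = structure.hetero.astype(bool)
    pdb_file = bst_pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Radii
# ---------------------------------------------------------------------------

def assign_radii(
    structure: ChannelStructure, radii_set: RadiiSet | None = None
) -> ChannelStructure:
    """Return a copy with per-atom van der Waals radii attached.

    Every element must resolve through ``radii_set`` (Bondi table by
    default); unknown elements without a declared default raise ``KeyError``
    listing the offending atoms.
    """
    if radii_set is None:
        radii_set = RadiiSet()
    out = structure.copy()
    out.radii = radii_set.lookup(structure.elements)
    return out


# ---------------------------------------------------------------------------
# Rotations and axis alignment
# ---------------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (unit) axis through the origin."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    k = np.array(
        [[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]], dtype=float
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _symmetry_score(coords: np.ndarray, axis: np.ndarray, order: int) -> float:
    """RMS nearest-neighbour distance between the atom set and its 2π/order
    rotation about ``axis`` through the centroid; ~0 for a true C_n axis."""
    center = coords.mean(axis=0)
    rot = rotation_about_axis(axis, 2 * np.pi / order)
    rotated = (coords - center) @ rot.T + center
    tree = cKDTree(coords)
    d, _ = tree.query(rotated, k=1)
    return float(np.sqrt(np.mean(d**2)))


def _min_rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Smallest rotation carrying ``axis`` onto +z (identity if aligned)."""
    u = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(u @ z, -1.0, 1.0))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # antiparallel: rotate 180° about x
        return np.diag([1.0, -1.0, -1.0])
    k = np.cross(u, z)
    return rotation_about_axis(k, np.arccos(c))


def find_symmetry_axis(
    coords: np.ndarray, order: int
) -> tuple[np.ndarray, float]:
    """Best-fit C_``order`` symmetry axis through the centroid.

    Candidate axes are the principal axes of the gyration tensor (for a
    C_n-symmetric body the symmetry axis is the non-degenerate principal
    axis); the best candidate is polished by minimising the RMS
    self-rotation mismatch over small tilts.  Returns ``(unit_axis, score)``.
    """
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: atoms are collinear")
    gyr = centered.T @ centered
    _, vecs = np.linalg.eigh(gyr)
    candidates = [vecs[:, i] for i in range(3)]
    scores = [_symmetry_score(coords, a, order) for a in candidates]
    best = int(np.argmin(scores))
    axis = candidates[best]

    # Polish: parameterize small tilts of the axis by two angles.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def cost(p):
        a = axis + p[0] * e1 + p[1] * e2
        return _symmetry_score(coords, a / np.linalg.norm(a), order)

    res = minimize(cost, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 200})
    refined = axis + res.x[0] * e1 + res.x[1] * e2
    refined /= np.linalg.norm(refined)
    score = _symmetry_score(coords, refined, order)
    if score > scores[best]:          # polishing must never hurt
        refined, score = axis, scores[best]
    # Deterministic sign: prefer +z hemisphere, then +y, then +x.
    for i in (2, 1, 0):
        if abs(refined[i]) > 1e-9:
            if refined[i] < 0:
                refined = -refined
            break
    return refined, score


def align_pore_axis(
    structure: ChannelStructure, axis: np.ndarray | None = None
) -> ChannelStructure:
    """Rigidly transform the structure so the pore (symmetry) axis is +z.

    The symmetry axis is detected from the structure's C_n symmetry unless
    ``axis`` is supplied explicitly.  The centroid is moved to the origin,
    so the pore runs along x = y = 0.  Idempotent to numerical tolerance.
    """
    coords = structure.coords
    if axis is not None:
        u = np.asarray(axis, dtype=float)
        nrm = np.linalg.norm(u)
        if nrm == 0:
            raise ValueError("explicit axis must be non-zero")
        u = u / nrm
    else:
        if structure.symmetry_order < 2:
            raise ValueError(
                "symmetry_order < 2: supply an explicit axis for alignment"
            )
        u, _ = find_symmetry_axis(coords, structure.symmetry_order)
    rot = _min_rotation_to_z(u)
    center = coords.mean(axis=0)
    out = structure.copy()
    out.coords = (coords - center) @ rot.T
    out.axis = np.array([0.0, 0.0, 1.0])
    return out


def symmetrize_c4(
    structure: ChannelStructure, reference_chain: str
) -> ChannelStructure:
    """Replace all chains by symmetry copies of ``reference_chain``.

    Requires an axis-aligned structure whose chain count equals
    ``symmetry_order`` and whose chains have identical atom counts.  Each
    non-reference chain is replaced by the rotation (k·2π/order about +z,
    k chosen per chain to best match its current position) of the reference
    chain.  Idempotent.
    """
    order = structure.symmetry_order
    chains = structure.chains()
    if len(chains) != order:
        raise ValueError(
            f"structure has {len(chains)} chains but symmetry order {order}"
        )
    if reference_chain not in chains:
        raise ValueError(f"reference chain {reference_chain!r} not present")
    ref_mask = structure.chain_ids == reference_chain
    ref_coords = structure.coords[ref_mask]
    out = structure.copy()
    for chain in chains:
        if chain == reference_chain:
            continue
        mask = structure.chain_ids == chain
        if mask.sum() != ref_mask.sum():
            raise ValueError(
                f"chain {chain!r} has {mask.sum()} atoms but reference "
                f"has {ref_mask.sum()}; cannot symmetrize"
            )
        best_coords, best_rmsd = None, np.inf
        for k in range(1, order):
            rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]),
                                      2 * np.pi * k / order)
            cand = ref_coords @ rot.T
            rmsd = float(np.sqrt(np.mean(
                np.sum((cand - structure.coords[mask]) ** 2, axis=1))))
            if rmsd < best_rmsd:
                best_coords, best_rmsd = cand, rmsd
        out.coords[mask] = best_coords
    return out
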