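"""Metal-site geometry from macromolecular coordinate files.

Parses PDB/mmCIF files (via gemmi), finds Cu(II) sites and their donor
atoms, tabulates pairwise metal-metal distances in nm, counts disulfide
bridges, and computes minimum contacts to crystallographic symmetry images.

Conventions
-----------
* Distances between atoms are in angstrom; the pairwise metal table is in nm
  (1 A = 0.1 nm).
* Fractional <-> orthogonal conversion uses the standard crystallographic
  orthogonalisation with **a** along x and **b** in the x-y plane.
* Only the first model of a multi-model file is read; for alternate
  locations the highest-occupancy conformer is kept (ties resolve to 'A').
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

import gemmi

from cuepr.constants import NM_PER_ANGSTROM

__all__ = [
    "Atom",
    "Structure",
    "MetalSite",
    "DistanceTable",
    "parse_structure",
    "detect_metal_sites",
    "pairwise_distances",
    "count_disulfides",
    "symmetry_ops",
    "min_symmetry_contact",
    "orthogonalization_matrix",
    "CANONICAL_SITE_RESIDUES",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Atom:
    """A single atom record (first model, one altloc already chosen)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str | None = None

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("Atom element must be non-empty")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("Atom position must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Structure:
    """Atoms of one model plus (optional) cell and space group."""

    atoms: list[Atom]
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    title: str = ""

    def __post_init__(self) -> None:
        if self.unit_cell is not None:
            a, b, c, al, be, ga = self.unit_cell
            if min(a, b, c) <= 0:
                raise ValueError("unit cell lengths must be positive")
            if not all(0.0 < ang < 180.0 for ang in (al, be, ga)):
                raise ValueError("unit cell angles must lie in (0, 180) degrees")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique within a model")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class MetalSite:
    """A bound metal ion with its coordinating (donor) atoms.

    Donors are protein/water N, O or S atoms within the donor cutoff,
    sorted by increasing metal-donor distance.
    """

    label: str
    metal_atom: Atom
    donors: list[tuple[Atom, float]]
    site_index: int = 0

    @property
    def donor_residues(self) -> list[tuple[str, int]]:
        return [(a.residue_name, a.residue_number) for a, _ in self.donors]


@dataclass
class DistanceTable:
    """Symmetric pairwise metal-metal distance matrix in nm."""

    labels: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self.distances = d

    def get(self, label_a: str, label_b: str) -> float:
        i = self.labels.index(label_a)
        j = self.labels.index(label_b)
        return float(self.distances[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.distances):
                fh.write(lab + "\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceTable":
        with open(path) as fh:
            header = fh.readline().split("\t")
            labels = [h.strip() for h in header[1:]]
            rows = []
            for line in fh:
                parts = line.split("\t")
                rows.append([float(v) for v in parts[1:]])
        return cls(labels=labels, distances=np.array(rows))


# Canonical site labelling: donor residue numbers of each named Cu site on
# equine serum albumin.  ATCUN = N-terminal Asp1-Thr2-His3 motif; site B =
# His9/Asp13; site A = His67/His246/Asp248; the remaining sites are named by
# their histidine (His287/Glu152, His317/Asp211, His509/Glu564).
CANONICAL_SITE_RESIDUES: dict[str, frozenset[int]] = {
    "ATCUN": frozenset({1, 2, 3}),
    "siteB": frozenset({9, 13}),
    "siteA": frozenset({67, 246, 248}),
    "H287": frozenset({287, 152}),
    "H317": frozenset({317, 211}),
    "H509": frozenset({509, 564}),
}

DONOR_ELEMENTS = frozenset({"N", "O", "S"})


# ---------------------------------------------------------------------------
# parsing


def _select_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per (chain, residue, atom name): highest occupancy,
    ties broken by the alphabetically first altloc ('A' wins)."""
    best: dict[tuple[str, int, str, str], Atom] = {}
    order: list[tuple[str, int, str, str]] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if atom.occupancy > cur.occupancy or (
                atom.occupancy == cur.occupancy
                and (atom.altloc or "~") < (cur.altloc or "~")
            ):
                best[key] = atom
    return [best[k] for k in order]


def parse_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    Only the first model is kept; heteroatoms (metals, waters) are retained.
    ``format`` may be ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")

    atoms: list[Atom] = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                serial += 1
                atoms.append(
                    Atom(
                        serial=at.serial if at.serial else serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=at.b_iso,
                        altloc=at.altloc if at.altloc != "\0" else None,
                    )
                )
    atoms = _select_altlocs(atoms)
    # re-serialise in case duplicate serials survived altloc merging
    if len({a.serial for a in atoms}) != len(atoms):
        atoms = [
            Atom(
                serial=i + 1,
                name=a.name,
                element=a.element,
                residue_name=a.residue_name,
                residue_number=a.residue_number,
                chain_id=a.chain_id,
                position=a.position,
                occupancy=a.occupancy,
                b_factor=a.b_factor,
                altloc=a.altloc,
            )
            for i, a in enumerate(atoms)
        ]

    cell = None
    sg = None
    if st.cell and st.cell.a > 1.0:
        cell = (
            st.cell.a,
            st.cell.b,
            st.cell.c,
            st.cell.alpha,
            st.cell.beta,
            st.cell.gamma,
        )
    if st.spacegroup_hm:
        sg = st.spacegroup_hm
    return Structure(atoms=atoms, unit_cell=cell, space_group=sg, title=st.name)


# ---------------------------------------------------------------------------
# metal sites and distances


def _assign_label(donor_residue_numbers: Iterable[int], index: int) -> str:
    nums = set(donor_residue_numbers)
    for label, canon in CANONICAL_SITE_RESIDUES.items():
        if nums & canon:
            return label
    return f"site{index + 1}"


def detect_metal_sites(
    structure: Structure,
    element: str = "Cu",
    donor_cutoff: float = 3.0,
) -> list[MetalSite]:
    """Find all bound metal ions of ``element`` and their donor spheres.

    Donors are non-hydrogen N/O/S atoms (protein or water) within
    ``donor_cutoff`` angstrom of the metal.  Sites are returned ordered by
    their first (lowest) donor residue number, and labelled with canonical
    albumin site names where the donor residues identify one.
    """
    if donor_cutoff <= 0:
        raise ValueError("donor_cutoff must be positive")
    element = element.strip()
    if not element or gemmi.Element(element).atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")

    metals = [a for a in structure.atoms if a.element.capitalize() == element.capitalize()]
    if not metals:
        return []

    others = [
        a
        for a in structure.atoms
        if a.element.capitalize() in DONOR_ELEMENTS and a is not None
    ]
    other_xyz = np.array([a.position for a in others]).reshape(-1, 3)

    sites = []
    for metal in metals:
        if other_xyz.size:
            d = np.linalg.norm(other_xyz - metal.xyz, axis=1)
            idx = np.where(d <= donor_cutoff)[0]
            donors = sorted(
                ((others[i], float(d[i])) for i in idx), key=lambda t: t[1]
            )
        else:
            donors = []
        sites.append(MetalSite(label="", metal_atom=metal, donors=donors))

    def sort_key(s: MetalSite) -> tuple:
        if s.donors:
            return (min(a.residue_number for a, _ in s.donors), s.metal_atom.serial)
        return (10**9, s.metal_atom.serial)

    sites.sort(key=sort_key)
    for i, s in enumerate(sites):
        s.site_index = i
        s.label = _assign_label((a.residue_number for a, _ in s.donors), i)
    return sites


def pairwise_distances(sites: Sequence[MetalSite]) -> DistanceTable:
    """Euclidean metal-metal distance matrix, converted to nm."""
    if len(sites) < 2:
        raise ValueError("need at least two metal sites for a distance table")
    xyz = np.array([s.metal_atom.position for s in sites])
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist_nm = np.linalg.norm(diff, axis=-1) * NM_PER_ANGSTROM
    return DistanceTable(labels=[s.label for s in sites], distances=dist_nm)


def count_disulfides(structure: Structure, sg_cutoff: float = 2.5) -> int:
    """Number of disulfide bridges: CYS SG-SG pairs within ``sg_cutoff`` A.

    Greedy nearest-pair matching; each SG joins at most one bridge.
    """
    sg_atoms = [
        a
        for a in structure.atoms
        if a.residue_name.upper() == "CYS" and a.name.upper() == "SG"
    ]
    n = len(sg_atoms)
    if n < 2:
        return 0
    xyz = np.array([a.position for a in sg_atoms])
    dmat = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    pairs = [
        (dmat[i, j], i, j) for i in range(n) for j in range(i + 1, n) if dmat[i, j] <= sg_cutoff
    ]
    pairs.sort()
    used: set[int] = set()
    count = 0
    for _, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        count += 1
    return count


# ---------------------------------------------------------------------------
# crystallographic symmetry


def _normalize_sg(symbol: str) -> str:
    return symbol.replace(" ", "").upper()


# Operators as (3x3 rotation, translation) acting on fractional coordinates.
# Minimal embedded table; P61 operators are the standard sixfold screw along c.
_SG_TABLE: dict[str, list[tuple[tuple, tuple]]] = {
    "P1": [(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))],
    "P61": [
        (((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0)),
        (((0, -1, 0), (1, -1, 0), (0, 0, 1)), (0, 0, 1 / 3)),
        (((-1, 1, 0), (-1, 0, 0), (0, 0, 1)), (0, 0, 2 / 3)),
        (((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0, 0, 1 / 2)),
        (((0, 1, 0), (-1, 1, 0), (0, 0, 1)), (0, 0, 5 / 6)),
        (((1, -1, 0), (1, 0, 0), (0, 0, 1)), (0, 0, 1 / 6)),
    ],
    "P212121": [
        (((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0)),
        (((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (1 / 2, 0, 1 / 2)),
        (((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0, 1 / 2, 1 / 2)),
        (((1, 0, 0), (0, -1, 0), (0, 0, -1)), (1 / 2, 1 / 2, 0)),
    ],
}


def symmetry_ops(space_group: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Symmetry operators (rotation matrix, translation vector) in fractional
    coordinates for a supported space group.  Identity is first."""
    key = _normalize_sg(space_group)
    if key not in _SG_TABLE:
        raise ValueError(
            f"unsupported space group {space_group!r}; supported: "
            + ", ".join(sorted(_SG_TABLE))
        )
    ops = []
    for rot, tr in _SG_TABLE[key]:
        ops.append((np.array(rot, dtype=float), np.array(tr, dtype=float)))
    # identity first by construction; keep stable order otherwise
    return ops


def orthogonalization_matrix(
    cell: tuple[float, float, float, float, float, float]
) -> np.ndarray:
    """Fractional -> orthogonal (angstrom) matrix, a along x, b in x-y plane."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    cos_al, cos_be, cos_ga = np.cos([al, be, ga])
    sin_ga = np.sin(ga)
    v = math.sqrt(
        1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
    )
    return np.array(
        [
            [a, b * cos_ga, c * cos_be],
            [0.0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
            [0.0, 0.0, c * v / sin_ga],
        ]
    )


def min_symmetry_contact(
    structure: Structure,
    selection: Callable[[Atom], bool] | None = None,
    shell: int = 1,
) -> tuple[float, tuple[Atom, Atom]]:
    """Minimum distance from any selected atom to any atom of a non-identity
    crystallographic image (symmetry operators x lattice translations within
    ``[-shell, shell]^3``).

    Returns ``(distance_A, (selected_atom, partner_atom))`` where the partner
    is the *reference-cell* atom whose image realises the contact.
    """
    if structure.unit_cell is None or structure.space_group is None:
        raise ValueError("structure has no unit cell / space group; cannot "
                         "generate symmetry images")
    ops = symmetry_ops(structure.space_group)
    M = orthogonalization_matrix(structure.unit_cell)
    Minv = np.linalg.inv(M)

    atoms = structure.atoms
    xyz = structure.coords
    frac = xyz @ Minv.T

    if selection is None:
        sel_idx = np.arange(len(atoms))
    else:
        sel_idx = np.array([i for i, a in enumerate(atoms) if selection(a)], dtype=int)
    if sel_idx.size == 0:
        raise ValueError("selection matched no atoms")
    sel_xyz = xyz[sel_idx]

    shifts = np.array(
        [
            (i, j, k)
            for i in range(-shell, shell + 1)
            for j in range(-shell, shell + 1)
            for k in range(-shell, shell + 1)
        ],
        dtype=float,
    )

    best = (math.inf, -1, -1)
    from scipy.spatial import cKDTree

    tree = cKDTree(sel_xyz)
    for op_i, (rot, tr) in enumerate(ops):
        img_frac = frac @ rot.T + tr
        for shift in shifts:
            if op_i == 0 and not shift.any():
                continue  # the structure itself
            img_xyz = (img_frac + shift) @ M.T
            d, j = tree.query(img_xyz, k=1)
            k = int(np.argmin(d))
            if d[k] < best[0]:
                best = (float(d[k]), int(sel_idx[j[k]]), k)
    dist, sel_at, partner_at = best
    if not math.isfinite(dist):
        raise RuntimeError("no symmetry contact found")
    return dist, (atoms[sel_at], atoms[partner_at])


def write_site_report(sites: Sequence[MetalSite], path: str | Path) -> None:
    """TSV report: one row per donor atom of each site."""
    with open(path, "w") as fh:
        fh.write("site\tmetal_serial\tdonor_residue\tdonor_atom\tdistance_A\n")
        for s in sites:
            for atom, dist in s.donors:
                fh.write(
                    f"{s.label}\t{s.metal_atom.serial}\t"
                    f"{atom.residue_name}{atom.residue_number}\t{atom.name}\t"
                    f"{dist:.2f}\n"
                )
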