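"""Coordinate containers for toy monomers and dimer poses, plus PDB I/O.

A :class:`ToyStructure` is a heavy-atom pseudo-structure: residues with a
few atoms each, annotated with a region map (TM1-TM4, ECH, ECL1, ECL2,
C-terminal tail) in claudin-like topology.  A :class:`DimerPose` pairs two
copies related by a rigid transform, with the membrane normal along +z.

PDB reading and writing go through biotite; coordinates are stored in
Angstroms and quantised to the PDB precision (0.001 A) at generation time so
file round trips are exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "ToyStructure",
    "DimerPose",
    "read_structure_pdb",
    "read_dimer_pdb",
    "write_region_map",
    "read_region_map",
    "rotation_about_z",
    "rotation_about_axis",
]

#: minimum allowed inter-chain heavy-atom distance in a valid pose, Angstrom
CLASH_DISTANCE = 2.0

_BACKBONE_NAMES = frozenset({"CA", "N", "C", "O"})


def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(th) * k + (1.0 - np.cos(th)) * (k @ k)


def rotation_about_z(angle_deg: float) -> np.ndarray:
    return rotation_about_axis((0.0, 0.0, 1.0), angle_deg)


@dataclass
class ToyStructure:
    """Heavy-atom pseudo-structure of one chain.

    Flat per-atom arrays (length ``n_atoms``): ``res_ids`` (1-based,
    contiguous per residue), ``atom_names``, ``elements``, ``coords``
    (Angstrom).  ``regions`` maps region names to inclusive residue-number
    ranges; residues outside every range are unassigned (linkers).
    """

    res_ids: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.res_ids)
        if not (len(self.atom_names) == len(self.elements) == len(self.coords) == n):
            raise ValueError("per-atom arrays must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        spans = sorted(self.regions.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError("region residue ranges overlap")
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {name!r} has an empty range")

    # -- residue-level views ---------------------------------------------

    @property
    def residue_numbers(self) -> np.ndarray:
        """Sorted unique residue numbers."""
        return np.unique(self.res_ids)

    def atoms_of(self, res_id: int) -> np.ndarray:
        return np.flatnonzero(self.res_ids == res_id)

    def alpha_coords(self) -> np.ndarray:
        """CA coordinates per residue (residue-number order)."""
        mask = self.atom_names == "CA"
        if mask.sum() != len(self.residue_numbers):
            raise ValueError("every residue needs exactly one CA atom")
        order = np.argsort(self.res_ids[mask])
        return self.coords[mask][order]

    def sidechain_centroids(
        self, mass_weighted: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Side-chain centres of mass per residue.

        Returns ``(centroids, fallback)`` where ``fallback`` flags residues
        with no side-chain atoms, whose centroid falls back to the CA
        position (the glycine convention).  Uniform atom weights by
        default; ``mass_weighted`` uses atomic masses.
        """
        masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
        res = self.residue_numbers
        centroids = np.empty((len(res), 3))
        fallback = np.zeros(len(res), dtype=bool)
        for k, rid in enumerate(res):
            idx = self.atoms_of(rid)
            side = idx[~np.isin(self.atom_names[idx], list(_BACKBONE_NAMES))]
            if len(side) == 0:
                ca = idx[self.atom_names[idx] == "CA"]
                centroids[k] = self.coords[ca[0] if len(ca) else idx[0]]
                fallback[k] = True
            else:
                w = (
                    np.array([masses.get(e, 12.011) for e in self.elements[side]])
                    if mass_weighted
                    else np.ones(len(side))
                )
                centroids[k] = np.average(self.coords[side], axis=0, weights=w)
        return centroids, fallback

    def region_of(self, res_id: int) -> str | None:
        for name, (lo, hi) in self.regions.items():
            if lo <= res_id <= hi:
                return name
        return None

    # -- transforms and I/O ----------------------------------------------

    def transformed(
        self,
        rotation: np.ndarray | None = None,
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        about_centroid: bool = True,
        quantize: bool = True,
    ) -> "ToyStructure":
        """Rigidly transformed copy (rotation about the centroid by default)."""
        coords = self.coords
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            pivot = coords.mean(axis=0) if about_centroid else np.zeros(3)
            coords = (coords - pivot) @ rotation.T + pivot
        coords = coords + np.asarray(translation, dtype=float)
        if quantize:
            coords = np.round(coords, 3)
        return dataclasses.replace(self, coords=coords)

    def with_chain(self, chain_id: str) -> "ToyStructure":
        return dataclasses.replace(self, chain_id=chain_id)

    def to_atom_array(self) -> struc.AtomArray:
        n = len(self.res_ids)
        arr = struc.AtomArray(n)
        arr.coord = self.coords.astype(np.float32)
        arr.chain_id = np.full(n, self.chain_id)
        arr.res_id = self.res_ids
        arr.res_name = np.full(n, "TOY")
        arr.atom_name = self.atom_names.astype("U4")
        arr.element = self.elements.astype("U2")
        arr.hetero = np.zeros(n, dtype=bool)
        arr.set_annotation("occupancy", np.ones(n, dtype=np.float32))
        arr.set_annotation("b_factor", np.zeros(n, dtype=np.float32))
        return arr

    def write_pdb(self, path: str | Path) -> None:
        f = pdb.PDBFile()
        f.set_structure(self.to_atom_array())
        f.write(str(path))

    @classmethod
    def from_atom_array(
        cls,
        arr: struc.AtomArray,
        regions: Mapping[str, tuple[int, int]] | None = None,
    ) -> "ToyStructure":
        chains = np.unique(arr.chain_id)
        if len(chains) != 1:
            raise ValueError("expected a single chain")
        return cls(
            res_ids=arr.res_id.copy(),
            atom_names=arr.atom_name.astype(object),
            elements=arr.element.astype(object),
            # PDB stores 0.001 A precision; re-quantise to undo the float32
            # representation error biotite introduces
            coords=np.round(arr.coord.astype(float), 3),
            chain_id=str(chains[0]),
            regions=dict(regions or {}),
        )


@dataclass
class DimerPose:
    """Two chains plus the rigid transform that carries chain A onto chain B.

    ``rotation`` must be a proper rotation (orthonormal, det +1);
    ``membrane_normal`` defaults to +z.  Construction does not enforce the
    clash criterion; :meth:`check_clash` does.
    """

    chain_a: ToyStructure
    chain_b: ToyStructure
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    membrane_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    label: str = "pose"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.membrane_normal = np.asarray(self.membrane_normal, dtype=float)
        self.membrane_normal /= np.linalg.norm(self.membrane_normal)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation matrix must have determinant +1")

    def min_interchain_distance(self) -> tuple[float, tuple[int, int]]:
        """Smallest heavy-atom distance between chains and its residue pair."""
        from scipy.spatial import cKDTree

        tree = cKDTree(self.chain_b.coords)
        d, j = tree.query(self.chain_a.coords)
        i = int(np.argmin(d))
        return float(d[i]), (
            int(self.chain_a.res_ids[i]),
            int(self.chain_b.res_ids[j[i]]),
        )

    def check_clash(self, min_distance: float = CLASH_DISTANCE) -> None:
        d, (ra, rb) = self.min_interchain_distance()
        if d < min_distance:
            raise ValueError(
                f"inter-chain clash: A:{ra} and B:{rb} at {d:.2f} A "
                f"(< {min_distance} A)"
            )

    def write_pdb(self, path: str | Path) -> None:
        arr = self.chain_a.to_atom_array() + self.chain_b.to_atom_array()
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))


def read_structure_pdb(
    path: str | Path, regions: Mapping[str, tuple[int, int]] | None = None
) -> ToyStructure:
    """Read a single-chain PDB file."""
    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[~arr.hetero]
    return ToyStructure.from_atom_array(arr, regions)


def read_dimer_pdb(
    path: str | Path,
    regions: Mapping[str, tuple[int, int]] | None = None,
    label: str | None = None,
) -> DimerPose:
    """Read a two-chain PDB file as a pose (identity transform recorded)."""
    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[~arr.hetero]
    chains = list(np.unique(arr.chain_id))
    if len(chains) != 2:
        raise ValueError(f"expected two chains, found {chains}")
    a = ToyStructure.from_atom_array(arr[arr.chain_id == chains[0]], regions)
    b = ToyStructure.from_atom_array(arr[arr.chain_id == chains[1]], regions)
    return DimerPose(a, b, label=label or Path(path).stem)


# -- region maps ----------------------------------------------------------


def write_region_map(regions: Mapping[str, tuple[int, int]], path: str | Path) -> None:
    data = {name: [int(lo), int(hi)] for name, (lo, hi) in regions.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_region_map(path: str | Path) -> dict[str, tuple[int, int]]:
    data = yaml.safe_load(Path(path).read_text())
    return {name: (int(lo), int(hi)) for name, (lo, hi) in data.items()}
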