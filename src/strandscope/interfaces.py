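"""Interface and pose-geometry analytics for claudin dimer triage.

Implements the docking-restraint and pose-filtering rules used to triage
cis dimer candidates: active/passive residue selection from SASA, the
side-chain contact map, 3 A interface residues, buried surface area
(delta-SASA), protomer tilt against the membrane normal, the in-plane
rotation between two poses, and per-region conservation of interface
residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .sasa import SASAResult, sasa_per_residue
from .structures import DimerPose, ToyStructure

__all__ = [
    "select_active_passive",
    "contact_map",
    "sidechain_com_distances",
    "interface_residues",
    "delta_sasa",
    "tilt_angle",
    "inplane_rotation",
    "interface_conservation",
    "InterfaceReport",
]

#: default spatial neighbourhood (A) defining passive residues around actives
PASSIVE_NEIGHBOR_CUTOFF = 6.5
#: heavy-atom cutoff (A) defining interfacial residues of a pose
INTERFACE_CUTOFF = 3.0
#: side-chain centre-of-mass cutoff (A) of the monomer contact map
CONTACT_CUTOFF = 10.0
#: maximum protomer tilt (deg) compatible with a planar lipid bilayer
TILT_LIMIT = 30.0


# -- restraint selection --------------------------------------------------


def select_active_passive(
    sasa: SASAResult,
    structure: ToyStructure,
    neighbor_cutoff: float = PASSIVE_NEIGHBOR_CUTOFF,
    residue_range: tuple[int, int] | None = None,
) -> tuple[set[int], set[int]]:
    """Active (exposed) and passive (neighbouring) docking-restraint residues.

    Active residues have SASA strictly above the median over the considered
    residue range; passive residues are the remaining ones whose side-chain
    centroid lies within ``neighbor_cutoff`` of an active residue's
    side-chain centroid.  The two sets are disjoint.
    """
    res = structure.residue_numbers
    if residue_range is not None:
        lo, hi = residue_range
        res = res[(res >= lo) & (res <= hi)]
    if len(res) == 0:
        raise ValueError("empty residue range")
    values = sasa.per_residue_array(structure.chain_id, res)
    median = float(np.median(values))
    active = {int(r) for r, v in zip(res, values) if v > median}
    centroids, _ = structure.sidechain_centroids()
    all_res = structure.residue_numbers
    pos = {int(r): centroids[k] for k, r in enumerate(all_res)}
    passive: set[int] = set()
    if active:
        act_xyz = np.array([pos[r] for r in sorted(active)])
        tree = cKDTree(act_xyz)
        for r in res:
            r = int(r)
            if r in active:
                continue
            if tree.query(pos[r])[0] <= neighbor_cutoff:
                passive.add(r)
    return active, passive


# -- contact map ----------------------------------------------------------


def sidechain_com_distances(
    structure: ToyStructure,
    pairs: Sequence[tuple[int, int]],
    mass_weighted: bool = False,
) -> np.ndarray:
    """Side-chain centre-of-mass distances (A) for given residue pairs."""
    centroids, _ = structure.sidechain_centroids(mass_weighted)
    index = {int(r): k for k, r in enumerate(structure.residue_numbers)}
    missing = sorted(
        {r for pair in pairs for r in pair if r not in index}
    )
    if missing:
        raise KeyError(f"residues without coordinates: {missing}")
    out = np.empty(len(pairs))
    for n, (i, j) in enumerate(pairs):
        out[n] = np.linalg.norm(centroids[index[i]] - centroids[index[j]])
    return out


def contact_map(
    structure: ToyStructure,
    cutoff: float = CONTACT_CUTOFF,
    min_seq_sep: int = 2,
    mass_weighted: bool = False,
) -> set[tuple[int, int]]:
    """Residue pairs whose side-chain centres of mass are closer than ``cutoff``.

    Pairs with sequence separation below ``min_seq_sep`` (adjacent residues)
    are excluded; pairs are returned with i < j.  Residues without
    side-chain atoms contribute their CA position.
    """
    centroids, _ = structure.sidechain_centroids(mass_weighted)
    res = structure.residue_numbers
    tree = cKDTree(centroids)
    out: set[tuple[int, int]] = set()
    for k, l in tree.query_pairs(cutoff):
        # pair queries are inclusive at the radius; the rule is strict
        if np.linalg.norm(centroids[k] - centroids[l]) >= cutoff:
            continue
        i, j = int(res[k]), int(res[l])
        if abs(i - j) >= min_seq_sep:
            out.add((min(i, j), max(i, j)))
    return out


# -- interface geometry ---------------------------------------------------


def interface_residues(
    pose: DimerPose, cutoff: float = INTERFACE_CUTOFF
) -> tuple[set[int], set[int]]:
    """Residues of each chain with any heavy atom within ``cutoff`` of the other."""
    a, b = pose.chain_a, pose.chain_b
    tree_b = cKDTree(b.coords)
    pairs = tree_b.query_ball_point(a.coords, cutoff)
    res_a: set[int] = set()
    res_b: set[int] = set()
    for i, hits in enumerate(pairs):
        # ball queries are inclusive; the rule is strictly below the cutoff
        close = [
            j for j in hits
            if np.linalg.norm(a.coords[i] - b.coords[j]) < cutoff
        ]
        if close:
            res_a.add(int(a.res_ids[i]))
            res_b.update(int(b.res_ids[j]) for j in close)
    return res_a, res_b


def delta_sasa(
    pose: DimerPose,
    probe_radius: float = 1.4,
    n_points: int = 960,
    per_side: bool = False,
) -> float:
    """Buried surface area on dimerisation (A^2).

    delta-SASA = SASA(A alone) + SASA(B alone) - SASA(complex); the total
    buried area over both chains.  ``per_side`` halves it.
    """
    free_a = sasa_per_residue(pose.chain_a, probe_radius, n_points).total
    free_b = sasa_per_residue(pose.chain_b, probe_radius, n_points).total
    complex_ = sasa_per_residue(pose, probe_radius, n_points).total
    value = free_a + free_b - complex_
    return value / 2.0 if per_side else value


# -- pose geometry --------------------------------------------------------


def _principal_axis(coords: np.ndarray, normal: np.ndarray, label: str) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-9 or (evals[-1] - evals[-2]) / evals[-1] < 1e-6:
        raise ValueError(f"chain {label}: degenerate (isotropic) atom cloud")
    axis = evecs[:, -1]
    if np.dot(axis, normal) < 0:
        axis = -axis
    return axis


def tilt_angle(pose: DimerPose, axis_mode: str = "principal") -> float:
    """Angle (deg) between the two protomer axes, in [0, 90].

    Each protomer axis is the dominant principal axis of its CA positions,
    sign-aligned with the membrane normal.  ``axis_mode='span'`` instead
    uses the vector from the lowest to the highest CA along the normal.
    """
    axes = []
    for chain, label in ((pose.chain_a, "A"), (pose.chain_b, "B")):
        ca = chain.alpha_coords()
        if len(ca) < 3:
            raise ValueError(f"chain {label}: need at least 3 CA atoms")
        if axis_mode == "principal":
            axes.append(_principal_axis(ca, pose.membrane_normal, label))
        elif axis_mode == "span":
            proj = ca @ pose.membrane_normal
            v = ca[np.argmax(proj)] - ca[np.argmin(proj)]
            axes.append(v / np.linalg.norm(v))
        else:
            raise ValueError("axis_mode must be 'principal' or 'span'")
    cosang = float(np.clip(np.dot(axes[0], axes[1]), -1.0, 1.0))
    angle = np.degrees(np.arccos(abs(cosang)))
    return float(angle)


def _kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotation carrying centred ``moving`` onto centred ``target``, plus RMSD."""
    mc = moving - moving.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(tc, mc)
    rmsd = rssd / np.sqrt(len(mc))
    return rot.as_matrix(), float(rmsd)


def inplane_rotation(
    pose: DimerPose, reference: DimerPose, rmsd_tolerance: float = 0.5
) -> float:
    """In-plane rotation (deg) of a pose's chain B relative to a reference pose.

    Chain A of the pose is superposed onto chain A of the reference
    (least-squares rigid fit, which must agree to ``rmsd_tolerance`` A,
    otherwise the poses do not share a monomer and an error is raised).
    The residual rotation carrying the pose's chain B onto the reference's
    chain B is then decomposed about the membrane normal (swing-twist) and
    the magnitude of the twist component is returned, folded into [0, 180].
    """
    rot_a, rmsd_a = _kabsch(pose.chain_a.coords, reference.chain_a.coords)
    if rmsd_a > rmsd_tolerance:
        raise ValueError(
            f"chain A superposition RMSD {rmsd_a:.3f} A exceeds tolerance; "
            "poses do not share the same monomer"
        )
    # apply the chain-A alignment to the pose's chain B, then find the
    # residual rotation onto the reference chain B
    b = pose.chain_b.coords
    b_aligned = (b - pose.chain_a.coords.mean(axis=0)) @ rot_a.T
    b_ref = reference.chain_b.coords - reference.chain_a.coords.mean(axis=0)
    residual, _ = _kabsch(b_aligned, b_ref)
    quat = Rotation.from_matrix(residual).as_quat()  # x, y, z, w
    v, w = quat[:3], quat[3]
    n = reference.membrane_normal
    twist = 2.0 * np.degrees(np.arctan2(np.dot(v, n), w))
    twist = abs(((twist + 180.0) % 360.0) - 180.0)
    return float(twist)


# -- conservation ---------------------------------------------------------


def interface_conservation(
    pose: DimerPose,
    conservation: Mapping[int, float] | pd.Series,
    regions: Mapping[str, tuple[int, int]] | None = None,
    cutoff: float = INTERFACE_CUTOFF,
) -> dict[str, float]:
    """Mean conservation ratio of interfacial residues, per region.

    Interfacial residues (both chains, monomer numbering) are grouped by
    the region map (defaults to chain A's); regions with no interfacial
    residue are absent from the result, not zero.  Residues missing from
    the conservation table raise an error listing them.
    """
    if isinstance(conservation, pd.Series):
        conservation = conservation.to_dict()
    regions = dict(regions or pose.chain_a.regions)
    res_a, res_b = interface_residues(pose, cutoff)
    residues = sorted(res_a | res_b)
    missing = [r for r in residues if r not in conservation]
    if missing:
        raise KeyError(f"residues missing from conservation table: {missing}")
    out: dict[str, list[float]] = {}
    for r in residues:
        for name, (lo, hi) in regions.items():
            if lo <= r <= hi:
                out.setdefault(name, []).append(float(conservation[r]))
                break
    return {name: float(np.mean(vals)) for name, vals in out.items()}


# -- aggregated report ----------------------------------------------------


@dataclass
class InterfaceReport:
    """Per-pose triage summary assembled by the interface pipeline."""

    label: str
    interface_residues_a: list[int]
    interface_residues_b: list[int]
    delta_sasa_A2: float
    tilt_deg: float
    tilt_filtered: bool
    inplane_rotation_deg: float | None
    ec_support_count: int
    ec_supported_pairs: list[tuple[int, int]]
    region_conservation: dict[str, float]
    mean_interface_conservation: float | None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "interface_residues_a": self.interface_residues_a,
            "interface_residues_b": self.interface_residues_b,
            "delta_sasa_A2": self.delta_sasa_A2,
            "tilt_deg": self.tilt_deg,
            "tilt_filtered": self.tilt_filtered,
            "inplane_rotation_deg": self.inplane_rotation_deg,
            "ec_support_count": self.ec_support_count,
            "ec_supported_pairs": [list(p) for p in self.ec_supported_pairs],
            "region_conservation": self.region_conservation,
            "mean_interface_conservation": self.mean_interface_conservation,
        }
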