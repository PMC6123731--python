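"""Evolutionary-coupling pair triage for oligomer-contact inference.

Coupling servers emit residue-pair tables (i, j, score).  High-scoring
pairs that are close in the monomer reflect the fold; high-scoring pairs
that are distant in the monomer are candidate intermolecular contacts and
are mapped onto dimer poses: a pair supports a pose when its cross-chain
side-chain distance is short (< 10 A) and shorter than in the monomer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interfaces import interface_residues, sidechain_com_distances
from .structures import DimerPose, ToyStructure

__all__ = [
    "read_ec_table",
    "write_ec_table",
    "read_conservation_table",
    "write_conservation_table",
    "filter_ec_pairs",
    "classify_pairs",
    "map_pairs_to_dimer",
    "summarize_support",
]

#: EVcomplex-style score threshold (strict >) for retaining pairs
SCORE_THRESHOLD = 0.47
#: number of top-scoring pairs retained
TOP_N = 500
#: residue range absent from the structural model, excluded from triage
EXCLUDED_RANGE = (187, 227)
#: side-chain COM cutoff (A) below which a pair reflects the monomer fold
FOLD_CUTOFF = 10.0
#: side-chain COM distance (A) above which a pair is a candidate oligomer contact
FAR_CUTOFF = 20.0
#: cross-chain distance (A) below which a candidate pair supports a pose
INTER_CUTOFF = 10.0


# -- tables ---------------------------------------------------------------


def read_ec_table(path: str | Path) -> pd.DataFrame:
    """Read a coupling table (TSV with header columns i, j, score)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"i", "j", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"EC table missing columns: {sorted(missing)}")
    return df


def write_ec_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_conservation_table(path: str | Path) -> pd.Series:
    """Read a per-residue conservation table (TSV columns residue, ratio)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"residue", "ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"conservation table missing columns: {sorted(missing)}")
    return pd.Series(
        df["ratio"].to_numpy(float), index=df["residue"].to_numpy(int), name="ratio"
    )


def write_conservation_table(series: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {"residue": series.index.to_numpy(int), "ratio": series.to_numpy(float)}
    ).to_csv(path, sep="\t", index=False)


# -- filtering ------------------------------------------------------------


def filter_ec_pairs(
    table: pd.DataFrame,
    score_threshold: float = SCORE_THRESHOLD,
    top_n: int = TOP_N,
    excluded_range: tuple[int, int] | None = EXCLUDED_RANGE,
) -> pd.DataFrame:
    """Triage a raw coupling table into the retained pair set.

    Order of operations: normalise pairs to i < j and drop malformed rows
    (reported by row number); exclude pairs touching ``excluded_range``
    (residues absent from the structural model); keep scores strictly
    above ``score_threshold``; keep at most ``top_n`` pairs, ranked by
    score descending with ties broken by (i, j) ascending.  Idempotent.
    """
    if len(table) == 0:
        raise ValueError("EC table is empty")
    df = table.copy()
    i = pd.to_numeric(df["i"], errors="coerce")
    j = pd.to_numeric(df["j"], errors="coerce")
    s = pd.to_numeric(df["score"], errors="coerce")
    bad = (
        i.isna()
        | j.isna()
        | s.isna()
        | ~np.isfinite(s)
        | (i < 1)
        | (j < 1)
        | (i == j)
        | (i != i.round())
        | (j != j.round())
    )
    if bad.any():
        rows = [int(r) for r in df.index[bad]]
        raise ValueError(f"malformed EC rows (by index): {rows}")
    df["i"] = np.minimum(i, j).astype(int)
    df["j"] = np.maximum(i, j).astype(int)
    df["score"] = s.astype(float)
    if excluded_range is not None:
        lo, hi = excluded_range
        keep = ~(
            df["i"].between(lo, hi) | df["j"].between(lo, hi)
        )
        df = df[keep]
    df = df[df["score"] > score_threshold]
    df = df.sort_values(
        ["score", "i", "j"], ascending=[False, True, True], kind="mergesort"
    ).head(top_n)
    return df.reset_index(drop=True)


# -- classification -------------------------------------------------------


def classify_pairs(
    pairs: pd.DataFrame,
    monomer: ToyStructure,
    contact_cutoff: float = FOLD_CUTOFF,
    far_cutoff: float = FAR_CUTOFF,
    mass_weighted: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Partition retained pairs against the monomer geometry.

    A pair is ``monomer-fold`` when its side-chain COM distance in the
    monomer is below ``contact_cutoff``; ``candidate-oligomer`` when at or
    above ``far_cutoff``; pairs in between are ``ambiguous``.  Returns the
    annotated table and the overlap fraction (fold pairs / retained pairs).
    """
    plist = list(zip(pairs["i"].astype(int), pairs["j"].astype(int)))
    dist = sidechain_com_distances(monomer, plist, mass_weighted)
    cls = np.where(
        dist < contact_cutoff,
        "monomer-fold",
        np.where(dist >= far_cutoff, "candidate-oligomer", "ambiguous"),
    )
    out = pairs.copy()
    out["monomer_distance_A"] = dist
    out["class"] = cls
    overlap = float(np.mean(cls == "monomer-fold")) if len(cls) else 0.0
    return out, overlap


def map_pairs_to_dimer(
    candidates: pd.DataFrame,
    pose: DimerPose,
    inter_cutoff: float = INTER_CUTOFF,
    mass_weighted: bool = False,
) -> pd.DataFrame:
    """Test candidate intermolecular pairs against one dimer pose.

    The intermolecular distance of an unordered pair (i, j) is the minimum
    of d(A:i, B:j) and d(A:j, B:i) between side-chain centres of mass.  A
    pair supports the pose when that distance is below ``inter_cutoff``
    and strictly smaller than its monomer-context distance.
    """
    cen_a, _ = pose.chain_a.sidechain_centroids(mass_weighted)
    cen_b, _ = pose.chain_b.sidechain_centroids(mass_weighted)
    idx_a = {int(r): k for k, r in enumerate(pose.chain_a.residue_numbers)}
    idx_b = {int(r): k for k, r in enumerate(pose.chain_b.residue_numbers)}
    out = candidates.copy()
    if "monomer_distance_A" not in out.columns:
        plist = list(zip(out["i"].astype(int), out["j"].astype(int)))
        out["monomer_distance_A"] = sidechain_com_distances(
            pose.chain_a, plist, mass_weighted
        )
    inter = np.empty(len(out))
    for n, (i, j) in enumerate(zip(out["i"].astype(int), out["j"].astype(int))):
        missing = [r for r in (i, j) if r not in idx_a or r not in idx_b]
        if missing:
            raise KeyError(f"residues missing from pose chains: {missing}")
        d1 = np.linalg.norm(cen_a[idx_a[i]] - cen_b[idx_b[j]])
        d2 = np.linalg.norm(cen_a[idx_a[j]] - cen_b[idx_b[i]])
        inter[n] = min(d1, d2)
    out[f"inter_distance_A"] = inter
    out["supported"] = (inter < inter_cutoff) & (
        inter < out["monomer_distance_A"].to_numpy()
    )
    return out


def summarize_support(
    candidates: pd.DataFrame,
    poses: Sequence[DimerPose],
    inter_cutoff: float = INTER_CUTOFF,
    restrict_to_interface: bool = False,
    interface_cutoff: float = 3.0,
    margin: int = 0,
) -> pd.DataFrame:
    """Per-pose counts of supporting candidate pairs.

    With ``restrict_to_interface``, only pairs whose residues lie in the
    pose's interface-residue sets (3 A rule, padded by ``margin`` residues
    in sequence) are counted.
    """
    if len(poses) == 0:
        raise ValueError("need at least one pose")
    rows = []
    for pose in poses:
        mapped = map_pairs_to_dimer(candidates, pose, inter_cutoff)
        supported = mapped[mapped["supported"]]
        if restrict_to_interface:
            res_a, res_b = interface_residues(pose, interface_cutoff)
            allowed = set()
            for r in res_a | res_b:
                allowed.update(range(r - margin, r + margin + 1))
            keep = supported.apply(
                lambda row: int(row["i"]) in allowed and int(row["j"]) in allowed,
                axis=1,
            )
            supported = supported[keep] if len(supported) else supported
        pairs = sorted(
            (int(r["i"]), int(r["j"])) for _, r in supported.iterrows()
        )
        rows.append(
            {
                "pose": pose.label,
                "support_count": len(pairs),
                "supported_pairs": pairs,
            }
        )
    return pd.DataFrame(rows)
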