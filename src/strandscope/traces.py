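"""Strand trace container and CSV input/output.

A strand trace is an ordered list of 2-D points (nm) digitised from a
freeze-fracture micrograph of a tight-junction strand, optionally carrying a
per-point fracture-face label ("P" protoplasmic / "E" exoplasmic).  Traces are
the unit of all morphometry downstream: curvature profiles, branch angles,
segment lengths and face-discontinuity rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrandTrace",
    "read_traces_csv",
    "write_traces_csv",
]

#: default digitisation scale, nm per pixel
DEFAULT_PIXEL_NM = 1.2

_FACES = frozenset({"P", "E"})


@dataclass
class StrandTrace:
    """An ordered polyline of digitised strand coordinates.

    Parameters
    ----------
    points
        ``(n, 2)`` float array of x, y coordinates in nanometres, ordered
        along the strand.  At least two points; consecutive duplicates are
        rejected (they carry no geometry and break tangent estimates).
    pixel_size
        Digitisation scale in nm per pixel (> 0).
    strand_id
        Identifier carried through to output tables.
    face
        Optional length-``n`` array of per-point fracture-face labels,
        each ``"P"`` or ``"E"``.
    """

    points: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_NM
    strand_id: str = "strand"
    face: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(pts) < 2:
            raise ValueError("a trace needs at least two points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace contains non-finite coordinates")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError("consecutive duplicate points are not allowed")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "points", pts)
        if self.face is not None:
            face = np.asarray(self.face, dtype=object)
            if len(face) != len(pts):
                raise ValueError("face labels must match point count")
            bad = set(face) - _FACES
            if bad:
                raise ValueError(f"unknown face labels: {sorted(bad)}")
            object.__setattr__(self, "face", face)

    # -- geometry helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.points)

    @property
    def step_lengths(self) -> np.ndarray:
        """Chord length of each polyline step, nm."""
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_length(self) -> float:
        """Total polyline length, nm."""
        return float(self.step_lengths.sum())

    @property
    def cumulative_length(self) -> np.ndarray:
        """Cumulative polyline length at each point, nm (starts at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.step_lengths)])

    def resample(self, spacing: float | None = None) -> "StrandTrace":
        """Resample to uniform arc-length spacing (default: one pixel).

        Linear interpolation along the polyline.  Face labels, if present,
        are carried by nearest original point.
        """
        spacing = self.pixel_size if spacing is None else float(spacing)
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        s = self.cumulative_length
        n_out = max(int(np.floor(s[-1] / spacing)) + 1, 2)
        s_new = np.arange(n_out) * spacing
        x = np.interp(s_new, s, self.points[:, 0])
        y = np.interp(s_new, s, self.points[:, 1])
        pts = np.column_stack([x, y])
        # interpolation can collapse points if spacing << local step; dedupe
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0]
        )
        pts = pts[keep]
        face = None
        if self.face is not None:
            idx = np.searchsorted(s, s_new[keep])
            idx = np.clip(idx, 0, len(s) - 1)
            face = self.face[idx]
        return StrandTrace(pts, self.pixel_size, self.strand_id, face)

    def transformed(
        self, rotation_deg: float = 0.0, translation: Sequence[float] = (0.0, 0.0)
    ) -> "StrandTrace":
        """Return a rigidly transformed copy (rotation about origin, then shift)."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = self.points @ rot.T + np.asarray(translation, dtype=float)
        return dataclasses.replace(self, points=pts)


# -- file format ----------------------------------------------------------

_COLUMNS = ["strand_id", "point_index", "x_nm", "y_nm", "face"]


def write_traces_csv(
    traces: Iterable[StrandTrace], path: str | Path
) -> None:
    """Write traces to CSV (columns strand_id, point_index, x_nm, y_nm, face)."""
    rows = []
    for tr in traces:
        face = tr.face if tr.face is not None else [""] * len(tr)
        for k, (x, y) in enumerate(tr.points):
            rows.append((tr.strand_id, k, x, y, face[k]))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False)


def read_traces_csv(
    path: str | Path, pixel_size: float = DEFAULT_PIXEL_NM
) -> list[StrandTrace]:
    """Read traces from CSV written by :func:`write_traces_csv` (or FIJI export)."""
    df = pd.read_csv(path, dtype={"strand_id": str}, keep_default_na=False)
    missing = set(_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for sid, grp in df.groupby("strand_id", sort=False):
        grp = grp.sort_values("point_index")
        pts = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        face = None
        if "face" in grp.columns:
            labels = grp["face"].astype(str).str.strip().to_numpy()
            if np.all(np.isin(labels, list(_FACES))):
                face = labels.astype(object)
        traces.append(StrandTrace(pts, pixel_size, str(sid), face))
    if not traces:
        raise ValueError(f"no traces found in {path}")
    return traces
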