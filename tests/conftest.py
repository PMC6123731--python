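"""Shared fixtures: deterministic toy structures, poses and helpers."""

import numpy as np
import pytest

from strandscope import (
    DimerPose,
    ToyStructure,
    gen_dimer,
    gen_toy_structure,
)
from strandscope.synthetic import ToyStructureSpec


@pytest.fixture(scope="session")
def monomer() -> ToyStructure:
    """The default 186-residue toy monomer (seed 0)."""
    return gen_toy_structure(ToyStructureSpec(seed=0))


@pytest.fixture(scope="session")
def reference_pose(monomer) -> DimerPose:
    """Plain side-by-side dimer: no rotation, no tilt."""
    return gen_dimer(monomer, rotation_deg=0.0, tilt_deg=0.0, label="ref")


@pytest.fixture(scope="session")
def rotated_pose(monomer) -> DimerPose:
    """Dimer with chain B rotated 17 degrees in plane."""
    return gen_dimer(monomer, rotation_deg=17.0, tilt_deg=0.0, label="rot17")


def circle_points(
    radius_nm: float,
    n: int,
    phase: float = 0.0,
    center=(0.0, 0.0),
    spacing_nm: float = 1.2,
) -> np.ndarray:
    """Vertices exactly on a circle at uniform *chord* spacing ``spacing_nm``.

    Chord spacing equal to the resampling pixel guarantees the resampled
    polyline reproduces the original vertices, so three-point circle fits
    see exact circle geometry.
    """
    dphi = 2.0 * np.arcsin(spacing_nm / (2.0 * radius_nm))
    phi = phase + dphi * np.arange(n)
    return np.column_stack(
        [center[0] + radius_nm * np.cos(phi), center[1] + radius_nm * np.sin(phi)]
    )
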