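"""End-to-end analysis runs: strand morphometry and interface triage.

Two tracks:

* the strand track turns trace CSVs into curvature profiles, an
  angle-per-monomer summary, branch-angle and segment statistics and
  face-discontinuity rates;
* the interface track scores dimer poses (interface residues, buried
  area, tilt and in-plane rotation vs a reference pose, coupling-pair
  support, per-region interface conservation) and ranks them.

Every report embeds the configuration hash and seed, and reruns with the
same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import ec as eclib
from . import interfaces as iface
from .curvature import (
    AngleModel,
    arcfit_curvature,
    branch_angle,
    branch_angle_modes,
    curvature_summary,
    discontinuity_rate,
    segment_stats,
)
from .structures import read_dimer_pdb, read_region_map, read_structure_pdb
from .traces import read_traces_csv

__all__ = ["RunConfig", "InputError", "run_strand_pipeline", "run_interface_pipeline"]


class InputError(ValueError):
    """A required input file is missing or malformed (CLI exit code 1)."""


@dataclass
class RunConfig:
    """All tunable parameters of both tracks, with their standard defaults.

    The numeric defaults are the protocol constants of the underlying
    analysis: 1.2 nm/px digitisation, 10 px curvature window, 2.8 nm
    monomer spacing, 1.4 A probe, 10 A contact / 3 A interface cutoffs,
    30 degree tilt limit, 0.47 coupling-score threshold, top 500 pairs,
    187-227 C-terminal exclusion, 20 A distant-pair cutoff.
    """

    # inputs
    traces: str | None = None
    branch_pairs: list[tuple[str, str]] = field(default_factory=list)
    segments: str | None = None
    monomer: str | None = None
    poses: list[str] = field(default_factory=list)
    reference_pose: str | None = None
    ec_table: str | None = None
    conservation: str | None = None
    region_map: str | None = None
    # strand-track parameters
    pixel_size_nm: float = 1.2
    curvature_window_px: int = 10
    curvature_step_px: int = 1
    smooth_px: int = 0
    monomer_spacing_nm: float = 2.8
    angle_mode: str = "arc"
    angle_threshold_deg: float = 3.0
    histogram_bin_per_um: float = 4.0
    tangent_window_px: int = 120
    # interface-track parameters
    probe_radius_A: float = 1.4
    sasa_points: int = 960
    contact_cutoff_A: float = 10.0
    interface_cutoff_A: float = 3.0
    passive_cutoff_A: float = 6.5
    tilt_limit_deg: float = 30.0
    score_threshold: float = 0.47
    top_n_pairs: int = 500
    excluded_range: tuple[int, int] = (187, 227)
    far_cutoff_A: float = 20.0
    inter_cutoff_A: float = 10.0
    # run control
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_range" in data:
            data["excluded_range"] = tuple(data["excluded_range"])
        if "branch_pairs" in data:
            data["branch_pairs"] = [tuple(p) for p in data["branch_pairs"]]
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_range"] = list(d["excluded_range"])
        d["branch_pairs"] = [list(p) for p in d["branch_pairs"]]
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise InputError(f"config is missing the {what} input")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{what} input not found: {p}")
    return p


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=1, sort_keys=True))


# ----------------------------------------------------------------------


def run_strand_pipeline(config: RunConfig) -> dict:
    """Strand-morphometry track: traces -> curvature/angle/branch statistics.

    Writes per-strand curvature profiles (CSV), a summary JSON and a
    curvature histogram CSV into ``config.out_dir`` and returns the
    report dictionary.
    """
    traces_path = _require(config.traces, "traces")
    for parent, branch in config.branch_pairs:
        _require(parent, "branch parent traces")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    traces = read_traces_csv(traces_path, config.pixel_size_nm)
    model = AngleModel(config.monomer_spacing_nm, config.angle_mode)
    profiles = [
        arcfit_curvature(
            tr, config.curvature_window_px, config.curvature_step_px,
            config.smooth_px,
        )
        for tr in traces
    ]
    rows = []
    for p in profiles:
        for s, k in zip(p.positions, p.kappa):
            rows.append((p.strand_id, s, k))
    pd.DataFrame(rows, columns=["strand_id", "arc_position_nm", "kappa_per_um"]).to_csv(
        out / "curvature_profiles.csv", index=False
    )
    summary = curvature_summary(
        profiles, model, config.angle_threshold_deg, config.histogram_bin_per_um
    )
    pd.DataFrame(
        {
            "bin_left_per_um": summary["histogram_edges_per_um"][:-1],
            "bin_right_per_um": summary["histogram_edges_per_um"][1:],
            "count": summary["histogram_counts"],
        }
    ).to_csv(out / "curvature_histogram.csv", index=False)

    # optional branch angles
    branch_angles = []
    for parent_path, branch_path in config.branch_pairs:
        parents = read_traces_csv(parent_path, config.pixel_size_nm)
        branches = read_traces_csv(branch_path, config.pixel_size_nm)
        for par, bra in zip(parents, branches):
            m = branch_angle(par, bra, config.tangent_window_px, config.smooth_px)
            branch_angles.append(
                {"parent": par.strand_id, "branch": bra.strand_id,
                 "angle_deg": m.angle_deg}
            )

    branch_modes = None
    if len(branch_angles) >= 2:
        try:
            branch_modes = branch_angle_modes(
                [b["angle_deg"] for b in branch_angles]
            )
        except ValueError:
            branch_modes = None

    # optional segment statistics and break rates
    seg_report = None
    break_rates = None
    if config.segments is not None:
        segs = read_traces_csv(_require(config.segments, "segments"),
                               config.pixel_size_nm)
        seg_report = segment_stats(segs)
        seg_report = {k: v for k, v in seg_report.items() if k != "lengths_nm"}
    labelled = [t for t in traces if t.face is not None]
    if labelled:
        break_rates = {
            t.strand_id: discontinuity_rate(t) for t in labelled
        }

    report = {
        "track": "strands",
        "config_hash": config.config_hash,
        "seed": config.seed,
        "summary": summary,
        "branch_angles": branch_angles,
        "branch_angle_modes_deg": branch_modes,
        "segment_stats": seg_report,
        "break_rates_per_um": break_rates,
    }
    _write_json(report, out / "strand_report.json")
    return report


# ----------------------------------------------------------------------


def run_interface_pipeline(config: RunConfig) -> dict:
    """Interface-triage track: monomer + poses + tables -> ranked pose report.

    Per pose: interface residues (3 A rule), buried area, tilt (flagged
    against the 30 degree bilayer-compatibility limit, never dropped),
    in-plane rotation against the reference pose, count of supporting
    coupling pairs, and per-region interface conservation.  The ranking
    is lexicographic (support, mean interface conservation, buried area,
    all descending) -- a reporting convenience, not a single fused score.
    """
    monomer_path = _require(config.monomer, "monomer")
    if not config.poses:
        raise InputError("config lists no poses")
    pose_paths = [_require(p, "pose") for p in config.poses]
    ec_path = _require(config.ec_table, "EC table")
    cons_path = _require(config.conservation, "conservation table")
    regions = (
        read_region_map(_require(config.region_map, "region map"))
        if config.region_map
        else None
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    monomer = read_structure_pdb(monomer_path, regions)
    poses = [read_dimer_pdb(p, regions) for p in pose_paths]
    reference = (
        read_dimer_pdb(_require(config.reference_pose, "reference pose"), regions)
        if config.reference_pose
        else poses[0]
    )
    raw = eclib.read_ec_table(ec_path)
    conservation = eclib.read_conservation_table(cons_path)

    retained = eclib.filter_ec_pairs(
        raw, config.score_threshold, config.top_n_pairs, config.excluded_range
    )
    classified, overlap = eclib.classify_pairs(
        retained, monomer, config.contact_cutoff_A, config.far_cutoff_A
    )
    candidates = classified[classified["class"] == "candidate-oligomer"]
    eclib.write_ec_table(classified, out / "ec_classification.tsv")

    reports = []
    for pose in poses:
        mapped = eclib.map_pairs_to_dimer(candidates, pose, config.inter_cutoff_A)
        supported = mapped[mapped["supported"]]
        res_a, res_b = iface.interface_residues(pose, config.interface_cutoff_A)
        tilt = iface.tilt_angle(pose)
        try:
            rot = iface.inplane_rotation(pose, reference)
        except ValueError:
            rot = None
        cons_regions = iface.interface_conservation(
            pose, conservation, regions or pose.chain_a.regions,
            config.interface_cutoff_A,
        )
        all_iface = sorted(res_a | res_b)
        mean_cons = (
            float(np.mean([conservation[r] for r in all_iface]))
            if all_iface
            else None
        )
        reports.append(
            iface.InterfaceReport(
                label=pose.label,
                interface_residues_a=sorted(res_a),
                interface_residues_b=sorted(res_b),
                delta_sasa_A2=iface.delta_sasa(
                    pose, config.probe_radius_A, config.sasa_points
                ),
                tilt_deg=tilt,
                tilt_filtered=tilt >= config.tilt_limit_deg,
                inplane_rotation_deg=rot,
                ec_support_count=int(len(supported)),
                ec_supported_pairs=[
                    (int(r["i"]), int(r["j"])) for _, r in supported.iterrows()
                ],
                region_conservation=cons_regions,
                mean_interface_conservation=mean_cons,
            )
        )

    ranked = sorted(
        reports,
        key=lambda r: (
            -r.ec_support_count,
            -(r.mean_interface_conservation or 0.0),
            -r.delta_sasa_A2,
        ),
    )
    rank_table = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "pose": [r.label for r in ranked],
            "ec_support": [r.ec_support_count for r in ranked],
            "mean_interface_conservation": [
                r.mean_interface_conservation for r in ranked
            ],
            "delta_sasa_A2": [r.delta_sasa_A2 for r in ranked],
            "tilt_deg": [r.tilt_deg for r in ranked],
            "tilt_filtered": [r.tilt_filtered for r in ranked],
            "inplane_rotation_deg": [r.inplane_rotation_deg for r in ranked],
        }
    )
    rank_table.to_csv(out / "pose_ranking.tsv", sep="\t", index=False)

    report = {
        "track": "interfaces",
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_pairs_retained": int(len(retained)),
        "fold_overlap_fraction": overlap,
        "n_candidate_pairs": int(len(candidates)),
        "reference_pose": reference.label,
        "poses": [r.to_dict() for r in ranked],
    }
    _write_json(report, out / "interface_report.json")
    return report
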