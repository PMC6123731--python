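"""Generators: strands, toy structures, dimers, EC and conservation tables."""

import numpy as np
import pandas as pd
import pytest

from strandscope import (
    StrandSimSpec,
    arcfit_curvature,
    branch_angle,
    gen_conservation,
    gen_dimer,
    gen_ec_table,
    gen_strands,
    gen_toy_structure,
    find_planted_candidates,
    trace_from_arcs,
)
from strandscope.interfaces import sidechain_com_distances
from strandscope.structures import CLASH_DISTANCE
from strandscope.synthetic import (
    ToyStructureSpec,
    _pair_inter_distance,
    read_ground_truth,
    write_ground_truth,
)


class TestStrandGeneration:
    def test_deterministic_per_seed(self):
        spec = StrandSimSpec(seed=42)
        t1, g1 = gen_strands(spec, 4)
        t2, g2 = gen_strands(spec, 4)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.points, b.points)
        assert [g.arc_kappa_per_um for g in g1] == [g.arc_kappa_per_um for g in g2]

    def test_different_seeds_differ(self):
        a, _ = gen_strands(StrandSimSpec(seed=1), 2)
        b, _ = gen_strands(StrandSimSpec(seed=2), 2)
        assert not np.array_equal(a[0].points, b[0].points)

    def test_lengths_within_requested_range(self):
        traces, truths = gen_strands(
            StrandSimSpec(jitter_px=0, pixelate=False, seed=5), 8, (0.5, 1.3)
        )
        parents = [t for t in traces if "_b" not in t.strand_id]
        for tr in parents:
            # generation stops within one arc of the target length
            assert 400.0 < tr.arc_length < 1350.0

    def test_planted_kappa_recovered_noiselessly(self):
        spec = StrandSimSpec(
            bend_prob=0.0, jitter_px=0, pixelate=False, seed=7
        )
        traces, truths = gen_strands(spec, 3)
        for tr, gt in zip(traces, truths):
            prof = arcfit_curvature(tr, window=10)
            # check each sample against the planted kappa of its arc
            bounds = np.asarray(gt.arc_boundaries_nm)
            planted = np.asarray(gt.arc_kappa_per_um)
            idx = np.searchsorted(bounds, prof.positions)
            idx = np.clip(idx, 0, len(planted) - 1)
            # ignore samples whose window straddles an arc joint
            clear = np.ones(len(prof), dtype=bool)
            for b in bounds[:-1]:
                clear &= np.abs(prof.positions - b) > 15.0
            err = np.abs(prof.kappa[clear] - planted[idx[clear]])
            assert np.median(err) < 0.05
            assert np.percentile(err, 90) < 1.0

    def test_branch_ground_truth_consistent(self):
        # bends off: the planted angle is defined against the local parent
        # tangent, which a finite fit window cannot reproduce across a kink
        spec = StrandSimSpec(
            branch_rate_per_um=3.0, bend_prob=0.0,
            jitter_px=0, pixelate=False, seed=9,
        )
        traces, truths = gen_strands(spec, 8)
        by_id = {t.strand_id: t for t in traces}
        errors = []
        for gt in truths:
            assert len(gt.branch_ids) == len(gt.branch_angles_deg)
            for bid, ang in zip(gt.branch_ids, gt.branch_angles_deg):
                assert 0.0 < ang <= 90.0
                m = branch_angle(by_id[gt.strand_id], by_id[bid])
                errors.append(abs(m.angle_deg - ang))
        assert len(errors) >= 5
        # junctions near arc joints see a mixed-curvature fit window, so a
        # few degrees of spread is expected even without noise
        assert np.median(errors) < 1.5
        assert np.percentile(errors, 90) < 5.0

    def test_face_switches_planted(self):
        spec = StrandSimSpec(face_switch_rate_per_um=3.0, seed=3)
        traces, truths = gen_strands(spec, 5)
        labelled = [t for t in traces if t.face is not None]
        assert labelled
        for tr in labelled:
            assert set(tr.face) <= {"P", "E"}

    def test_kappa_distribution_median(self):
        # pooled planted arc kappas match the log-normal median
        spec = StrandSimSpec(jitter_px=0, pixelate=False, seed=21)
        _, truths = gen_strands(spec, 60)
        kappas = np.concatenate([g.arc_kappa_per_um for g in truths])
        assert np.median(kappas) == pytest.approx(8.0, rel=0.15)
        assert kappas.max() <= 123.0

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, truths = gen_strands(StrandSimSpec(seed=2), 3)
        path = tmp_path / "gt.json"
        write_ground_truth(truths, path)
        back = read_ground_truth(path)
        assert [t.strand_id for t in back] == [t.strand_id for t in truths]
        assert back[0].arc_kappa_per_um == truths[0].arc_kappa_per_um

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            StrandSimSpec(jitter_px=-1)
        with pytest.raises(ValueError):
            StrandSimSpec(bend_prob=1.5)
        with pytest.raises(ValueError):
            StrandSimSpec(branch_angle_modes=(67.0, 120.0))
        with pytest.raises(ValueError):
            gen_strands(StrandSimSpec(), 0)


class TestTraceFromArcs:
    def test_single_arc_matches_circle(self):
        kappa = 12.0  # 1/um
        tr = trace_from_arcs([(400.0, kappa)])
        prof = arcfit_curvature(tr)
        assert np.allclose(prof.kappa, kappa, rtol=1e-6)

    def test_bend_angle_turns_heading(self):
        tr = trace_from_arcs(
            [(120.0, 0.0), (120.0, 0.0)], bend_angles_deg=[30.0]
        )
        d0 = tr.points[10] - tr.points[0]
        d1 = tr.points[-1] - tr.points[-10]
        cos = (d0 @ d1) / (np.linalg.norm(d0) * np.linalg.norm(d1))
        assert np.degrees(np.arccos(cos)) == pytest.approx(30.0, abs=0.1)

    def test_bad_arguments(self):
        with pytest.raises(ValueError, match="bend"):
            trace_from_arcs([(100, 0), (100, 0)], bend_angles_deg=[10, 20])
        with pytest.raises(ValueError, match="positive"):
            trace_from_arcs([(0.0, 5.0)])


class TestToyStructure:
    def test_deterministic(self, monomer):
        again = gen_toy_structure(ToyStructureSpec(seed=0))
        assert np.array_equal(monomer.coords, again.coords)
        assert np.array_equal(monomer.elements, again.elements)

    def test_residue_and_atom_counts(self, monomer):
        assert len(monomer.residue_numbers) == 186
        assert len(monomer.res_ids) == 186 * 3
        assert np.all(np.sort(monomer.residue_numbers) == np.arange(1, 187))

    def test_regions_cover_claudin_topology(self, monomer):
        assert set(monomer.regions) == {
            "TM1", "ECL1", "ECH", "TM2", "TM3", "ECL2", "TM4",
        }
        assert monomer.region_of(10) == "TM1"
        assert monomer.region_of(105) is None  # linker
        assert monomer.region_of(150) == "ECL2"

    def test_tm_helices_span_membrane(self, monomer):
        ca = monomer.alpha_coords()
        for name in ("TM1", "TM2", "TM3", "TM4"):
            lo, hi = monomer.regions[name]
            z = ca[lo - 1 : hi, 2]
            assert z.min() < -15 and z.max() > 15

    def test_extracellular_loops_above_membrane(self, monomer):
        ca = monomer.alpha_coords()
        for name in ("ECL1", "ECH", "ECL2"):
            lo, hi = monomer.regions[name]
            assert ca[lo - 1 : hi, 2].mean() > 10.0

    def test_intra_residue_atoms_separated(self, monomer):
        for rid in (1, 50, 186):
            idx = monomer.atoms_of(rid)
            xyz = monomer.coords[idx]
            d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 1.0

    def test_coords_quantised_to_pdb_precision(self, monomer):
        assert np.array_equal(monomer.coords, np.round(monomer.coords, 3))


class TestDimerGeneration:
    def test_transform_recorded(self, monomer):
        pose = gen_dimer(monomer, rotation_deg=17.0, tilt_deg=5.0)
        # chain B equals monomer transformed by the recorded rotation
        pivot = monomer.coords.mean(axis=0)
        expected = (monomer.coords - pivot) @ pose.rotation.T + pivot
        expected = np.round(expected + pose.translation, 3)
        assert np.allclose(pose.chain_b.coords, expected, atol=1e-9)

    def test_no_clash_at_default_separation(self, monomer):
        pose = gen_dimer(monomer, 0.0, 0.0)
        d, _ = pose.min_interchain_distance()
        assert d >= CLASH_DISTANCE

    def test_clash_raises_with_residue_names(self, monomer):
        with pytest.raises(ValueError, match=r"clash: A:\d+ and B:\d+"):
            gen_dimer(monomer, 0.0, 0.0, translation=(2.0, 0.0, 0.0))


class TestEcTableGeneration:
    def test_planted_pairs_validated(self, reference_pose):
        eligible = find_planted_candidates(reference_pose)
        assert len(eligible) >= 5
        planted = eligible[:5]
        table = gen_ec_table(reference_pose, planted, seed=1)
        assert set(table["label"]) == {"planted"}
        assert len(table) == 5
        assert (table["score"] >= 0.60).all()
        # every planted pair is indeed distant intra, close inter
        mono_d = sidechain_com_distances(reference_pose.chain_a, planted)
        assert (mono_d >= 20.0).all()
        for i, j in planted:
            assert _pair_inter_distance(reference_pose, i, j) < 10.0

    def test_bad_planted_pair_rejected(self, reference_pose):
        with pytest.raises(ValueError, match="excluded range"):
            gen_ec_table(reference_pose, [(190, 50)])
        # a nearby pair (adjacent residues) is close intra and far inter
        with pytest.raises(ValueError, match="across the dimer"):
            gen_ec_table(reference_pose, [(100, 140)])

    def test_background_labels_and_scores(self, reference_pose):
        eligible = find_planted_candidates(reference_pose)
        table = gen_ec_table(
            reference_pose, eligible[:3],
            n_fold_background=20, n_noise_background=15,
            n_excluded_decoys=5, seed=3,
        )
        counts = table["label"].value_counts()
        assert counts["planted"] == 3
        assert counts["fold"] == 20
        assert counts["noise"] == 15
        assert counts["excluded-decoy"] == 5
        assert (table.loc[table["label"] == "noise", "score"] < 0.47).all()
        assert (table.loc[table["label"] == "fold", "score"] > 0.47).all()

    def test_deterministic(self, reference_pose):
        eligible = find_planted_candidates(reference_pose)
        t1 = gen_ec_table(reference_pose, eligible[:3], 10, 10, seed=5)
        t2 = gen_ec_table(reference_pose, eligible[:3], 10, 10, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestConservationGeneration:
    def test_patches_planted_exactly(self, monomer):
        cons = gen_conservation(monomer, [range(30, 41)], high_level=0.98, seed=0)
        assert (cons.loc[30:40] == 0.98).all()
        assert cons.between(0.0, 1.0).all()

    def test_background_beta_moments(self, monomer):
        cons = gen_conservation(monomer, seed=1, background=(2.0, 2.0))
        # Beta(2,2): mean 0.5, var 0.05; 186 samples -> loose bounds
        assert cons.mean() == pytest.approx(0.5, abs=0.06)
        assert cons.var() == pytest.approx(0.05, abs=0.02)

    def test_invalid_parameters(self, monomer):
        with pytest.raises(ValueError, match="high_level"):
            gen_conservation(monomer, high_level=1.5)
        with pytest.raises(ValueError, match="Beta"):
            gen_conservation(monomer, background=(0.0, 1.0))
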