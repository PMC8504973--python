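"""Pentamer geometry metrics on synthetic structures and PDB text."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from mwcgate.structure import (
    ATOM_COLUMNS,
    Frame,
    MetricSeries,
    RegionSpec,
    Trajectory,
    asymmetry_stats,
    build_synthetic_pentamer,
    load_trajectory,
    pair_distance,
    ring_radius,
    rmsd_to_reference,
    synthetic_region_spec,
    twist_angle,
    variability_declines,
)

REGIONS = synthetic_region_spec()


def dihedral_oracle(p0, p1, p2, p3):
    """Independent signed-dihedral formula (atan2 on normal vectors)."""
    b1, b2, b3 = np.asarray(p1) - p0, np.asarray(p2) - p1, np.asarray(p3) - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))


def random_rigid(seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    return rot, rng.normal(0, 50, 3)


def tiny_frame(points):
    """Frame from a list of (chain, resnum, resname, atom, x, y, z)."""
    rows = [
        (c, r, name, atom, atom[0], x, y, z, 1.0, "")
        for (c, r, name, atom, x, y, z) in points
    ]
    return Frame(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS))


class TestSyntheticPentamer:
    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_synthetic_pentamer(n_chains=2)

    def test_zero_twist_gives_zero_angles(self):
        frame = build_synthetic_pentamer(twist_deg=0.0)
        angles = twist_angle(frame, REGIONS)
        np.testing.assert_allclose(angles.to_numpy(), 0.0, atol=1e-9)

    def test_constructed_twist_recovered(self):
        frame = build_synthetic_pentamer(twist_deg=10.0)
        angles = twist_angle(frame, REGIONS)
        np.testing.assert_allclose(angles.to_numpy(), 10.0, atol=0.01)
        # oracle: direct dihedral on the four constructed centroids of chain A
        a = frame.atoms
        ecd = a[(a.chain == "A") & (a.resnum <= 5)][["x", "y", "z"]].to_numpy().mean(axis=0)
        tmd = a[(a.chain == "A") & (a.resnum >= 101)][["x", "y", "z"]].to_numpy().mean(axis=0)
        ecd_all = a[a.resnum <= 5][["x", "y", "z"]].to_numpy().mean(axis=0)
        tmd_all = a[a.resnum >= 101][["x", "y", "z"]].to_numpy().mean(axis=0)
        # counterclockwise-positive convention flips the raw dihedral sign
        assert -dihedral_oracle(ecd, ecd_all, tmd_all, tmd) == pytest.approx(
            angles["A"], abs=1e-9
        )

    def test_negative_twist_signed(self):
        frame = build_synthetic_pentamer(twist_deg=-7.5)
        np.testing.assert_allclose(twist_angle(frame, REGIONS).to_numpy(), -7.5, atol=0.01)

    def test_compaction_scales_ecd_distances_exactly(self):
        base = build_synthetic_pentamer(compaction_scale=1.0)
        tight = build_synthetic_pentamer(compaction_scale=0.9)
        d0 = pair_distance(Trajectory([base]), 3, 3, mode="CA", topology="inter")
        d1 = pair_distance(Trajectory([tight]), 3, 3, mode="CA", topology="inter")
        np.testing.assert_allclose(
            d1.values["value"].to_numpy(), 0.9 * d0.values["value"].to_numpy(), rtol=1e-12
        )


class TestTwistInvariance:
    def test_rigid_motion_leaves_twist_unchanged(self):
        frame = build_synthetic_pentamer(twist_deg=13.0)
        rot, trans = random_rigid(5)
        moved = frame.transformed(rot, trans)
        a = twist_angle(frame, REGIONS).to_numpy()
        b = twist_angle(moved, REGIONS).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_empty_region_selection_rejected(self):
        frame = build_synthetic_pentamer()
        bad = RegionSpec(ecd_range=(900, 950), tmd_range=(101, 105), chains=REGIONS.chains)
        with pytest.raises(ValueError, match="empty region"):
            twist_angle(frame, bad)


class TestPairDistance:
    def test_three_four_five_triangle(self):
        frame = tiny_frame([
            ("A", 1, "GLY", "CA", 0.0, 0.0, 0.0),
            ("A", 2, "GLY", "CA", 3.0, 4.0, 0.0),
            ("B", 1, "GLY", "CA", 1.0, 1.0, 1.0),
            ("B", 2, "GLY", "CA", 1.0, 1.0, 1.0),
            ("C", 1, "GLY", "CA", 2.0, 2.0, 2.0),
            ("C", 2, "GLY", "CA", 2.0, 2.0, 2.0),
        ])
        d = pair_distance(Trajectory([frame]), 1, 2, mode="CA", topology="intra")
        assert d.values.iloc[0]["value"] == pytest.approx(5.0)
        assert d.unit == "angstrom"

    def test_symmetric_pentamer_interfaces_identical(self):
        frame = build_synthetic_pentamer()
        d = pair_distance(Trajectory([frame]), 1, 2, mode="CA", topology="inter")
        assert len(d.values) == 5
        assert d.values["value"].std(ddof=1) == pytest.approx(0.0, abs=1e-9)

    def test_sidechain_centroid_uses_heavy_atoms_beyond_cb(self):
        frame = tiny_frame([
            ("A", 10, "TYR", "N", 0, 0, 0),
            ("A", 10, "TYR", "CA", 1, 0, 0),
            ("A", 10, "TYR", "CB", 2, 0, 0),
            ("A", 10, "TYR", "CG", 4, 0, 0),
            ("A", 10, "TYR", "OH", 6, 0, 0),
            # a placed bimane: non-standard residue, all heavy atoms count
            ("A", 500, "BIM", "C1", 4.0, 3.0, 0.0),
            ("A", 500, "BIM", "C2", 6.0, 3.0, 0.0),
            ("A", 500, "BIM", "C3", 5.0, 5.0, 0.0),
        ])
        d = pair_distance(
            Trajectory([frame]), 10, 500, mode="sidechain_centroid", topology="intra"
        )
        # TYR centroid (5,0,0) from CG/OH only; BIM centroid (5, 11/3, 0)
        assert d.values.iloc[0]["value"] == pytest.approx(11.0 / 3.0)

    def test_missing_atom_error_names_location(self):
        frame = build_synthetic_pentamer()
        with pytest.raises(KeyError, match="residue 77 in chain A"):
            pair_distance(Trajectory([frame]), 77, 1, mode="CA", topology="intra")

    def test_named_atom_mode(self):
        frame = tiny_frame([
            ("A", 1, "HIS", "NE2", 0, 0, 0),
            ("A", 2, "ILE", "O", 0, 0, 2.5),
            ("B", 1, "HIS", "NE2", 9, 9, 9),
            ("B", 2, "ILE", "O", 9, 9, 9),
            ("C", 1, "HIS", "NE2", 5, 5, 5),
            ("C", 2, "ILE", "O", 5, 5, 5),
        ])
        d = pair_distance(Trajectory([frame]), 1, 2, mode="named_atom",
                          topology="intra", atom_a="NE2", atom_b="O")
        assert d.values.iloc[0]["value"] == pytest.approx(2.5)


class TestRingRadius:
    def test_pentagon_radius_exact(self):
        frame = build_synthetic_pentamer(radius=5.0, layer_separation=40.0)
        # TMD residue 101 sits on a circle of radius exactly 5
        assert ring_radius(frame, 101, REGIONS) == pytest.approx(5.0, abs=1e-9)

    def test_vdw_subtraction_is_constant_offset(self):
        frame = build_synthetic_pentamer(radius=5.0)
        r = ring_radius(frame, 101, REGIONS)
        r_vdw = ring_radius(frame, 101, REGIONS, subtract_vdw=True)
        assert r - r_vdw == pytest.approx(1.7, abs=1e-12)
        assert r_vdw == pytest.approx(3.3, abs=1e-9)

    def test_rigid_motion_invariance(self):
        frame = build_synthetic_pentamer(radius=8.0)
        rot, trans = random_rigid(9)
        moved = frame.transformed(rot, trans)
        assert ring_radius(moved, 101, REGIONS) == pytest.approx(
            ring_radius(frame, 101, REGIONS), abs=1e-6
        )

    def test_collinear_ring_rejected(self):
        pts = []
        for i, c in enumerate("ABCDE"):
            pts.append((c, 1, "GLY", "CA", 0.0, 0.0, 30.0 + i))   # ECD stack
            pts.append((c, 101, "GLY", "CA", 0.0, 0.0, float(i)))  # collinear ring
        frame = tiny_frame(pts)
        regions = RegionSpec(ecd_range=(1, 1), tmd_range=(101, 101), chains=tuple("ABCDE"))
        with pytest.raises(ValueError, match="collinear"):
            ring_radius(frame, 101, regions)

    def test_missing_ring_atoms_rejected(self):
        frame = build_synthetic_pentamer()
        with pytest.raises(ValueError, match="need >= 3"):
            ring_radius(frame, 999, REGIONS)


class TestRmsd:
    def test_zero_against_itself(self):
        frame = build_synthetic_pentamer()
        out = rmsd_to_reference(Trajectory([frame]), frame)
        assert out.values.iloc[0]["value"] == pytest.approx(0.0, abs=1e-12)

    def test_superposition_removes_rigid_motion(self):
        frame = build_synthetic_pentamer(twist_deg=4.0)
        rot, trans = random_rigid(3)
        moved = frame.transformed(rot, trans)
        out = rmsd_to_reference(Trajectory([moved]), frame, superpose=True)
        assert out.values.iloc[0]["value"] == pytest.approx(0.0, abs=1e-6)

    def test_translation_without_superposition(self):
        frame = build_synthetic_pentamer()
        moved = frame.transformed(np.eye(3), np.array([3.0, 0.0, 0.0]))
        out = rmsd_to_reference(Trajectory([moved]), frame, superpose=False)
        assert out.values.iloc[0]["value"] == pytest.approx(3.0, abs=1e-12)

    def test_correspondence_mismatch_rejected(self):
        frame = build_synthetic_pentamer()
        smaller = Frame(atoms=frame.atoms.iloc[:-1].copy())
        with pytest.raises(ValueError, match="correspondence"):
            rmsd_to_reference(Trajectory([smaller]), frame)


class TestAsymmetryStats:
    @staticmethod
    def metric_from(values_by_frame):
        rows = [
            {"frame": f, "label": str(i), "value": v}
            for f, values in values_by_frame.items()
            for i, v in enumerate(values)
        ]
        return MetricSeries(name="test", unit="angstrom", values=pd.DataFrame(rows))

    def test_textbook_mean_and_sd(self):
        stats = asymmetry_stats(self.metric_from({1: [10, 10, 10, 10, 14]}))
        assert stats.loc[1, "mean"] == pytest.approx(10.8)
        assert stats.loc[1, "sd"] == pytest.approx(1.789, abs=1e-3)
        assert stats.loc[1, "range"] == pytest.approx(4.0)

    def test_equal_values_have_zero_sd(self):
        stats = asymmetry_stats(self.metric_from({1: [7, 7, 7, 7, 7]}))
        assert stats.loc[1, "sd"] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match=">= 2 values"):
            asymmetry_stats(self.metric_from({1: [5.0]}))

    def test_variability_decline_detector(self):
        declining = self.metric_from({1: [10, 12, 14, 9, 11], 2: [10.5, 10.6, 10.4, 10.5, 10.5]})
        assert variability_declines(declining)
        assert not variability_declines(self.metric_from({1: [10, 10.1], 2: [5, 9]}))


def write_pdb(path, frames):
    """Minimal multi-MODEL PDB text from synthetic frames."""
    lines = []
    for mi, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for _, row in frame.atoms.iterrows():
            lines.append(
                f"ATOM  {serial:5d}  {row['atom']:<3s}{row['resname']:>4s} "
                f"{row['chain']}{int(row['resnum']):4d}    "
                f"{row['x']:8.3f}{row['y']:8.3f}{row['z']:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}           {row['element']:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class TestLoadTrajectory:
    def test_single_model_file(self, tmp_path):
        path = tmp_path / "one.pdb"
        write_pdb(path, [build_synthetic_pentamer()])
        traj = load_trajectory(path)
        assert len(traj) == 1
        assert traj[0].chains == list("ABCDE")

    def test_twelve_model_trajectory(self, tmp_path):
        # a gating trajectory of 12 frames with growing twist
        path = tmp_path / "traj.pdb"
        frames = [build_synthetic_pentamer(twist_deg=t) for t in np.linspace(0, 11, 12)]
        write_pdb(path, frames)
        traj = load_trajectory(path)
        assert len(traj) == 12
        assert [f.model_index for f in traj] == list(range(1, 13))
        angles = [twist_angle(f, REGIONS).mean() for f in traj]
        np.testing.assert_allclose(angles, np.linspace(0, 11, 12), atol=0.01)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            load_trajectory(path)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        traj = load_trajectory(path)
        ca = traj[0].atom_xyz("A", 1, "CA")
        assert ca[0] == pytest.approx(9.0)  # the 0.60-occupancy altloc wins
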