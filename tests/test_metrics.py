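"""Superposition, RMSD/Rg/RMSF, Δ profiles, KDE and summary tables."""

import numpy as np
import pytest

from resdyn import (
    DegenerateGeometryError,
    GeneratorConfig,
    MetricSeries,
    ResidueLabel,
    ResidueProfile,
    TrajectoryError,
    delta_profile,
    generate,
    kabsch_superpose,
    kde_distribution,
    percent_difference,
    rg_series,
    rmsd_series,
    rmsf_profile,
    summary_from_means,
    summary_table,
)
from resdyn.metrics import round_half_up
from resdyn.trajectory import Trajectory

from .oracles import grid_search_rmsd

TETRA = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
)


class TestKabsch:
    def test_identity(self):
        _m, rmsd = kabsch_superpose(TETRA, TETRA)
        assert rmsd < 1e-12

    def test_translation_invariance(self):
        _m, rmsd = kabsch_superpose(TETRA + np.array([5.0, -2.0, 1.0]), TETRA)
        assert rmsd < 1e-12

    def test_common_rototranslation_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(0)
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        _m, r0 = kabsch_superpose(a, b)
        rot = Rotation.from_euler("zyx", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([2.0, -7.0, 0.5])
        _m, r1 = kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift)
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert kabsch_superpose(a, b)[1] == pytest.approx(kabsch_superpose(b, a)[1], abs=1e-10)

    def test_matches_rotation_grid_bruteforce(self):
        from scipy.spatial.transform import Rotation

        rot90 = Rotation.from_euler("z", np.pi / 2).as_matrix()
        mobile = TETRA @ rot90.T
        mobile[0] += np.array([1.0, 0.0, 0.0])  # 1 Å distortion on one vertex
        _m, rmsd = kabsch_superpose(mobile, TETRA)
        assert rmsd == pytest.approx(grid_search_rmsd(mobile, TETRA), abs=1e-3)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(TETRA[:2], TETRA[:2])

    def test_collinear_points_degenerate(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


def _static_trajectory(n_res=6, n_frames=4):
    cfg = GeneratorConfig(n_residues=n_res, n_frames=n_frames, seed=2, fluctuation_sigma=0.0)
    return generate(cfg)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        series = rmsd_series(_static_trajectory())
        assert np.all(series.values < 1e-12)

    def test_rigid_body_only_all_zero(self):
        cfg = GeneratorConfig(
            n_residues=15, n_frames=20, seed=4, fluctuation_sigma=0.0, rigid_body="random"
        )
        series = rmsd_series(generate(cfg))
        assert np.all(series.values < 1e-6)

    def test_uniform_displacement_removed(self):
        traj = _static_trajectory()
        coords = traj.coords.copy()
        coords[1] += np.array([1.0, 0.0, 0.0])
        shifted = Trajectory(traj.atom_sites, coords)
        assert rmsd_series(shifted).values[1] < 1e-12


def _bare_trajectory(points: np.ndarray) -> Trajectory:
    """Single-frame CA-only trajectory from raw points."""
    sites = [("CA", "ALA", 23 + i, "A") for i in range(points.shape[0])]
    return Trajectory(sites, points[None, :, :])


class TestRgSeries:
    def test_single_atom_zero(self):
        assert rg_series(_bare_trajectory(np.array([[1.0, 2.0, 3.0]]))).values[0] == 0.0

    def test_two_atoms_distance_2d_gives_d(self):
        d = 1.7
        traj = _bare_trajectory(np.array([[0.0, 0.0, 0.0], [2 * d, 0.0, 0.0]]))
        assert rg_series(traj).values[0] == pytest.approx(d, abs=1e-12)

    def test_unit_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
        )
        # every corner is sqrt(3)/2 from the centroid
        assert rg_series(_bare_trajectory(corners)).values[0] == pytest.approx(
            np.sqrt(3) / 2, abs=1e-12
        )

    def test_rotation_translation_invariance(self, jitter_trajectory):
        from scipy.spatial.transform import Rotation

        base = rg_series(jitter_trajectory).values
        rot = Rotation.from_euler("xyz", [0.4, 0.1, -0.9]).as_matrix()
        moved = Trajectory(
            jitter_trajectory.atom_sites,
            jitter_trajectory.coords @ rot.T + np.array([3.0, -1.0, 8.0]),
        )
        np.testing.assert_allclose(rg_series(moved).values, base, atol=1e-9)


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        prof = rmsf_profile(_static_trajectory())
        assert np.all(prof.values < 1e-12)

    def test_fewer_than_two_frames_rejected(self):
        traj = _bare_trajectory(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(TrajectoryError):
            rmsf_profile(traj)

    def test_doubling_sigma_doubles_rmsf(self):
        base = dict(n_residues=25, n_frames=1500, seed=9)
        r1 = rmsf_profile(generate(GeneratorConfig(fluctuation_sigma=0.3, **base)))
        r2 = rmsf_profile(generate(GeneratorConfig(fluctuation_sigma=0.6, **base)))
        ratio = np.mean(r2.values / r1.values)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_frame_order_invariance(self, jitter_trajectory):
        fwd = rmsf_profile(jitter_trajectory).values
        rev = rmsf_profile(
            Trajectory(jitter_trajectory.atom_sites, jitter_trajectory.coords[::-1])
        ).values
        np.testing.assert_allclose(fwd, rev, atol=1e-9)


def _profile(values, metric="RMSF", start=23):
    labels = [ResidueLabel("ALA", start + i) for i in range(len(values))]
    return ResidueProfile(labels=labels, values=np.asarray(values, float), metric=metric)


class TestDeltaProfile:
    def test_identical_profiles_zero(self):
        d = delta_profile(_profile([1.0, 2.0]), _profile([1.0, 2.0]))
        assert np.all(d.values == 0.0)
        assert d.metric == "deltaRMSF"

    def test_arithmetic(self):
        d = delta_profile(_profile([1.0, 2.0]), _profile([0.5, 2.5]))
        np.testing.assert_allclose(d.values, [0.5, -0.5])

    def test_more_flexible_variant_gives_negative_delta(self):
        # variant RMSF larger => WT − variant negative
        d = delta_profile(_profile([1.0]), _profile([1.5]))
        assert d.values[0] < 0

    def test_antisymmetry(self):
        a, b = _profile([1.0, 2.0, 0.3]), _profile([0.1, 2.4, 0.9])
        np.testing.assert_allclose(delta_profile(a, b).values, -delta_profile(b, a).values)

    def test_label_mismatch_names_residue(self):
        b = _profile([1.0, 2.0], start=24)
        with pytest.raises(TrajectoryError, match="Ala23"):
            delta_profile(_profile([1.0, 2.0]), b)


class TestKde:
    def test_integrates_to_one(self, jitter_trajectory):
        est = kde_distribution(rmsd_series(jitter_trajectory))
        assert est.integral() == pytest.approx(1.0, abs=1e-3)

    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(123)
        est = kde_distribution(rng.normal(size=10_000))
        at_zero = np.interp(0.0, est.grid, est.density)
        assert at_zero == pytest.approx(1 / np.sqrt(2 * np.pi), abs=0.02)

    def test_constant_series_rejected(self):
        with pytest.raises(TrajectoryError, match="static"):
            kde_distribution(np.ones(50))

    def test_bandwidth_override(self):
        rng = np.random.default_rng(5)
        est = kde_distribution(rng.normal(size=500), bandwidth=0.25)
        assert est.bandwidth == pytest.approx(0.25)


PRINTED_MEANS = {
    "RMSD": {
        "WT": 2.507, "S100A": 2.465, "S100L": 2.002, "S100P": 2.251,
        "E109D": 2.222, "G162R": 2.862, "R237Q": 2.248,
    },
    "Rg": {
        "WT": 18.120, "S100A": 17.961, "S100L": 17.926, "S100P": 18.024,
        "E109D": 17.865, "G162R": 18.113, "R237Q": 17.944,
    },
}
PRINTED_PCT = {
    "RMSD": {
        "WT": 0.00, "S100A": 1.68, "S100L": 20.14, "S100P": 10.21,
        "E109D": 11.37, "G162R": -14.16, "R237Q": 10.33,
    },
    "Rg": {
        "WT": 0.00, "S100A": 0.88, "S100L": 1.07, "S100P": 0.53,
        "E109D": 1.41, "G162R": 0.04, "R237Q": 0.97,
    },
}


class TestSummary:
    @pytest.mark.parametrize("metric", ["RMSD", "Rg"])
    def test_reproduces_published_percent_cells(self, metric):
        rows = summary_from_means(PRINTED_MEANS[metric], "WT", metric=metric)
        for row in rows:
            expected = PRINTED_PCT[metric][row.label]
            assert abs(row.percent_difference_from_wt - expected) <= 0.005
            assert round_half_up(row.percent_difference_from_wt, 2) == expected

    def test_wt_row_is_zero_and_first(self):
        rows = summary_from_means({"WT": 2.0, "V": 1.0}, "WT")
        assert rows[0].label == "WT"
        assert rows[0].percent_difference_from_wt == 0.0

    def test_equal_means_give_zero(self):
        assert percent_difference(3.2, 3.2) == 0.0

    def test_missing_wt_rejected(self):
        with pytest.raises(TrajectoryError):
            summary_from_means({"A": 1.0}, "WT")

    def test_summary_table_from_series(self):
        series = [
            MetricSeries("WT", "RMSD", np.array([2.0, 3.0])),
            MetricSeries("V", "RMSD", np.array([1.0, 1.5])),
        ]
        rows = summary_table(series, "WT")
        by_label = {r.label: r for r in rows}
        assert by_label["WT"].mean == 2.5
        assert by_label["V"].percent_difference_from_wt == pytest.approx(50.0)

    def test_frame_range_filter(self):
        series = [
            MetricSeries("WT", "RMSD", np.array([10.0, 2.0, 2.0])),
            MetricSeries("V", "RMSD", np.array([10.0, 1.0, 1.0])),
        ]
        rows = summary_table(series, "WT", frame_range=(1, 3))
        assert {r.label: r.mean for r in rows} == {"WT": 2.0, "V": 1.0}
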