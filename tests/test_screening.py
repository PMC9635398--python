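import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import fvdesign as fd
from fvdesign.fixtures import toy_coordinates
from fvdesign.fv import DesignRegion
from fvdesign.screening import (
    MockBinder,
    MockFolder,
    ScreeningThresholds,
    design_region_rmsd,
    kabsch_superpose,
    run_pipeline,
    screen_binding,
    screen_folding,
)


def region_for(n, design):
    return DesignRegion(tuple(design), tuple(i for i in range(n) if i not in design))


@pytest.fixture(scope="module")
def target_coords():
    return toy_coordinates(14, np.random.default_rng(20))


@pytest.fixture(scope="module")
def region14():
    return region_for(14, (5, 6, 7))


class TestKabsch:
    def test_identity_on_identical_points(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        rot, tran, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_rotation_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        R = Rotation.random(random_state=2).as_matrix()
        moved = pts @ R.T + np.array([1.0, -2.0, 3.0])
        rot, tran, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(moved @ rot.T + tran, pts, atol=1e-6)

    def test_matches_scipy_align_vectors(self):
        """Independent oracle: scipy's least-squares rotation on centered sets."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        rot, tran, rmsd = kabsch_superpose(a, b)
        Ra, _ = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        moved = (a - a.mean(0)) @ Ra.as_matrix().T + b.mean(0)
        rmsd_scipy = float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))
        assert rmsd == pytest.approx(rmsd_scipy, abs=1e-9)

    def test_single_displaced_point_toy(self):
        # 4 points; align is dominated by 3 identical ones, one atom off by ~1 A
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        moved = base.copy()
        moved[3, 2] += 1.0
        _, _, rmsd = kabsch_superpose(moved, base)
        # closed form: optimal superposition of this toy computed independently
        Ra, _ = Rotation.align_vectors(base - base.mean(0), moved - moved.mean(0))
        aligned = (moved - moved.mean(0)) @ Ra.as_matrix().T + base.mean(0)
        expected = float(np.sqrt(((aligned - base) ** 2).sum(axis=1).mean()))
        assert rmsd == pytest.approx(expected, abs=1e-9)

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestDesignRegionRMSD:
    def test_identical_structures_zero(self, target_coords, region14):
        rmsd, per_res = design_region_rmsd(target_coords, target_coords, region14)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(per_res, 0.0, atol=1e-9)

    def test_rigidly_transformed_copy_zero(self, target_coords, region14):
        R = Rotation.random(random_state=5).as_matrix()
        moved = target_coords.transformed(R, np.array([4.0, 4.0, -1.0]))
        rmsd, _ = design_region_rmsd(moved, target_coords, region14)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_constant_displacement_equals_shift(self, target_coords, region14):
        shift = np.array([0.0, 0.0, 3.0])
        atoms = {k: v.copy() for k, v in target_coords.atoms.items()}
        for name in atoms:
            atoms[name][list(region14.design_positions)] += shift
        moved = fd.StructureCoordinates(atoms, target_coords.has_cb.copy())
        rmsd, per_res = design_region_rmsd(moved, target_coords, region14)
        assert rmsd == pytest.approx(3.0, abs=1e-6)
        assert np.allclose(per_res, 3.0, atol=1e-6)

    def test_matches_independent_two_stage_recomputation(self, target_coords, region14):
        rng = np.random.default_rng(6)
        atoms = {k: v + rng.normal(scale=0.4, size=v.shape)
                 for k, v in target_coords.atoms.items()}
        moved = fd.StructureCoordinates(atoms, target_coords.has_cb.copy())
        rmsd, _ = design_region_rmsd(moved, target_coords, region14)

        # independent: scipy rotation on framework N/CA/C, then rmsd on design N/CA/C
        fw = sorted(region14.fixed_positions)
        d = list(region14.design_positions)
        def stack(c, idx):
            return np.concatenate([c.atoms[a][idx] for a in ("N", "CA", "C")], axis=0)
        A, B = stack(moved, fw), stack(target_coords, fw)
        Ra, _ = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        def apply(x):
            return (x - A.mean(0)) @ Ra.as_matrix().T + B.mean(0)
        diff = apply(stack(moved, d)) - stack(target_coords, d)
        expected = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
        assert rmsd == pytest.approx(expected, abs=1e-9)


class TestGates:
    def designs(self, n=20):
        rng = np.random.default_rng(9)
        return {f"d{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=14))
                for i in range(n)}

    def test_perfect_folder_all_pass(self, target_coords, region14):
        folder = MockFolder(target_coords, region14)
        passed, results = screen_folding(
            self.designs(), folder, target_coords, region14, ScreeningThresholds()
        )
        assert len(passed) == 20
        assert all(not r.failed for r in results.values())

    def test_half_displaced_half_fail(self, target_coords, region14):
        designs = self.designs()
        far = set(list(designs)[:10])

        class HalfFolder(MockFolder):
            def __call__(self, seq):
                coords = super().__call__(seq)
                did = [k for k, v in designs.items() if v == seq][0]
                if did in far:
                    atoms = {k: v.copy() for k, v in coords.atoms.items()}
                    for name in atoms:
                        atoms[name][list(region14.design_positions)] += [0, 0, 5.0]
                    return fd.StructureCoordinates(atoms, coords.has_cb)
                return coords

        passed, _ = screen_folding(
            designs, HalfFolder(target_coords, region14), target_coords, region14,
            ScreeningThresholds(rmsd_max=2.0),
        )
        assert passed == set(designs) - far

    def test_raising_threshold_never_shrinks_pass_set(self, target_coords, region14):
        folder = MockFolder(
            target_coords, region14, seed=3,
            displacement_sampler=lambda rng: rng.uniform(0.0, 4.0),
        )
        designs = self.designs(30)
        prev = set()
        for rmsd_max in (0.5, 1.0, 2.0, 3.0, 5.0):
            passed, _ = screen_folding(
                designs, folder, target_coords, region14,
                ScreeningThresholds(rmsd_max=rmsd_max),
            )
            assert prev <= passed
            prev = passed

    def test_decoy_min_rule(self):
        class FixedBinder:
            def __call__(self, seq, n):
                return [-10.0, -12.0, -11.0][:n]

        passed, results = screen_binding(
            {"a": "SEQ"}, FixedBinder(), ScreeningThresholds(dG_reference=-11.5),
            n_decoys=3,
        )
        assert results["a"].dG == -12.0
        assert passed == {"a"}

    def test_constant_dg_at_reference_all_pass(self):
        binder = lambda seq, n: [-30.0] * n
        passed, _ = screen_binding(
            {f"d{i}": "S" * 5 for i in range(10)}, binder,
            ScreeningThresholds(dG_reference=-30.0, dG_margin=0.0),
        )
        assert len(passed) == 10

    def test_adapter_failure_marks_design_and_continues(self, target_coords, region14):
        def bad_folder(seq):
            raise RuntimeError("boom")

        passed, results = screen_folding(
            {"a": "X" * 14, "b": "Y" * 14}, bad_folder, target_coords, region14,
            ScreeningThresholds(),
        )
        assert passed == set()
        assert all(r.failed for r in results.values())


class TestPipeline:
    def test_screened_is_intersection(self, target_coords, region14):
        rng = np.random.default_rng(13)
        designs = {f"d{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=14))
                   for i in range(50)}
        folder = MockFolder(
            target_coords, region14, seed=1,
            displacement_sampler=lambda r: r.uniform(0.0, 4.0),
        )
        binder = MockBinder(seed=2)
        thresholds = ScreeningThresholds(rmsd_max=2.0, dG_reference=-30.0)
        report = run_pipeline(designs, folder, binder, target_coords, region14, thresholds)

        # independent recomputation of both gates
        fold_expected = {
            did for did, seq in designs.items()
            if design_region_rmsd(folder(seq), target_coords, region14)[0] <= 2.0
        }
        bind_expected = {
            did for did, seq in designs.items() if min(binder(seq, 5)) <= -30.0
        }
        assert report.fold_pass == fold_expected
        assert report.bind_pass == bind_expected
        assert report.screened == fold_expected & bind_expected
        assert report.screened <= report.fold_pass
        assert report.screened <= report.bind_pass
        assert report.counts["designs"] == 50

    def test_empty_design_list_ok(self, target_coords, region14):
        report = run_pipeline(
            {}, MockFolder(target_coords, region14), MockBinder(),
            target_coords, region14, ScreeningThresholds(),
        )
        assert report.screened == set()
        assert report.screened_profile is None
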