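"""Centerline extraction, ray casting, scoring and planner feasibility."""

import math

import numpy as np
import pytest

from punctforce.path_planner import (
    PlannerConfig,
    cast_ray,
    extract_centerline,
    plan_all,
    score_path,
    skin_voxels,
)
from punctforce.phantom import PhantomSpec, layered_phantom
from punctforce.tissue_model import (
    AIR,
    BILE,
    BONE,
    SKIN,
    SOFT_TISSUE,
    VESSEL,
    HapticParams,
    PatientModel,
    Role,
    TissueEntry,
    TissueTable,
)
from punctforce.volumes import Volume3D

CFG = PlannerConfig()
RISK = (BONE, VESSEL)
TARGET = (BILE,)


def small_spec(**kwargs) -> PhantomSpec:
    defaults = dict(
        shape=(48, 48, 96),
        spacing=(1.0, 1.0, 1.0),
        liver_range=(30.0, 85.0),
        tube_x_range=(10.0, 38.0),
        vessel_y_offsets=(-12.0, 12.0),
        rib_window_halfwidth=8.0,
        seed=3,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestCenterline:
    def test_one_voxel_tube_is_its_own_centerline(self):
        m = np.zeros((12, 7, 7), dtype=np.uint8)
        m[2:10, 3, 3] = 1
        cl = extract_centerline(Volume3D(m, (1, 1, 1)))
        assert {tuple(v) for v in cl} == {(i, 3, 3) for i in range(2, 10)}

    def test_thick_tube_thins_to_axis(self):
        m = np.zeros((20, 9, 9), dtype=np.uint8)
        m[2:18, 3:6, 3:6] = 1  # 3x3 beam, odd cross-section
        cl = extract_centerline(Volume3D(m, (1, 1, 1)))
        assert len(cl) >= 3
        assert all(j == 4 and k == 4 for _, j, k in cl)

    def test_sphere_thins_to_point_like_skeleton(self):
        m = np.zeros((15, 15, 15), dtype=np.uint8)
        x, y, z = np.ogrid[:15, :15, :15]
        m[(x - 7) ** 2 + (y - 7) ** 2 + (z - 7) ** 2 <= 16] = 1
        cl = extract_centerline(Volume3D(m, (1, 1, 1)))
        assert len(cl) <= 7

    def test_even_diameter_tube_still_yields_an_axis(self):
        # perfectly symmetric even cross-section: topological thinning can
        # collapse this entirely; the distance-ridge fallback must not.
        m = np.zeros((30, 20, 20), dtype=np.uint8)
        yy, zz = np.meshgrid(np.arange(20) + 0.5, np.arange(20) + 0.5, indexing="ij")
        m[5:25, (yy - 10) ** 2 + (zz - 10) ** 2 <= 9] = 1
        cl = extract_centerline(Volume3D(m, (1, 1, 1)))
        assert 15 <= len(cl) <= 25
        # away from the tube ends the chain hugs the axis
        core = [(i, j, k) for i, j, k in cl if 8 <= i <= 21]
        assert len(core) >= 10
        assert all(9 <= j <= 10 and 9 <= k <= 10 for _, j, k in core)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            extract_centerline(Volume3D(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1)))


class TestCastRay:
    def _labels(self):
        v = np.full((20, 20, 20), AIR, dtype=np.int16)
        v[:, :, 10:] = SOFT_TISSUE
        v[5:15, 5:15, 12:14] = BONE
        return Volume3D(v, (1, 1, 1))

    def test_air_only_ray(self):
        labels = self._labels()
        crossings, length = cast_ray((0, 0, 0), (8, 0, 0), labels)
        assert crossings == [(AIR, 0.0)]
        assert length == 8.0

    def test_ray_through_rib_contains_bone(self):
        labels = self._labels()
        crossings, _ = cast_ray((10, 10, 0), (10, 10, 18), labels)
        assert [c for c, _ in crossings] == [AIR, SOFT_TISSUE, BONE, SOFT_TISSUE]

    def test_length_is_euclidean(self):
        labels = self._labels()
        _, length = cast_ray((0, 0, 0), (3, 4, 12), labels)
        assert length == pytest.approx(math.sqrt(9 + 16 + 144))


class TestScorePath:
    def test_blocked_by_bone_is_dismissed(self):
        crossings = [(AIR, 0.0), (BONE, 5.0), (BILE, 9.0)]
        s = score_path(crossings, 9.0, CFG, risk_codes=RISK, target_codes=TARGET)
        assert math.isinf(s.q) and not s.feasible

    def test_too_long_is_dismissed(self):
        crossings = [(AIR, 0.0), (BILE, 95.0)]
        s = score_path(crossings, 95.0, CFG, risk_codes=RISK, target_codes=TARGET)
        assert math.isinf(s.q)

    def test_fully_scored_feasible_path(self):
        crossings = [(SKIN, 0.0), (SOFT_TISSUE, 2.0), (BILE, 50.0)]
        s = score_path(
            crossings, 50.0, CFG,
            risk_codes=RISK, target_codes=TARGET,
            min_risk_dist_mm=15.0, n_target_voxels=12,
        )
        assert (s.c1, s.c2, s.c3, s.c4) == (0.0, 0.0, 1.0, 1.0)
        assert s.q == 1.0

    def test_low_quality_falls_under_filter(self):
        crossings = [(SKIN, 0.0), (BILE, 50.0)]
        s = score_path(
            crossings, 50.0, CFG,
            risk_codes=RISK, target_codes=TARGET,
            min_risk_dist_mm=3.0, n_target_voxels=3,
        )
        assert s.q == pytest.approx(0.3)
        assert s.q < CFG.quality_threshold

    def test_q_monotone_in_soft_criteria(self):
        crossings = [(SKIN, 0.0), (BILE, 50.0)]
        qs = [
            score_path(
                crossings, 50.0, CFG,
                risk_codes=RISK, target_codes=TARGET,
                min_risk_dist_mm=d, n_target_voxels=n,
            ).q
            for d, n in [(1, 1), (4, 4), (8, 8), (20, 20)]
        ]
        assert qs == sorted(qs)


@pytest.fixture(scope="module")
def phantom_paths():
    models = layered_phantom(small_spec())
    cfg = PlannerConfig(skin_stride=4)
    return models, cfg, plan_all(models.gold, cfg)


class TestPlanAll:
    def test_unobstructed_window_gives_paths(self, phantom_paths):
        _, _, paths = phantom_paths
        assert len(paths) > 10

    def test_accepted_paths_satisfy_constraints_by_voxel_walk(self, phantom_paths):
        """Independent oracle: walk each accepted path at quarter-voxel steps
        and verify target hit, length bound and absence of risk crossings."""
        models, cfg, paths = phantom_paths
        labels = models.gold.labels
        risk = set(models.gold.table.risk_codes())
        target = set(models.gold.table.target_codes())
        for p in paths:
            t = p.trajectory
            assert t.length <= cfg.max_length
            assert p.score.q >= cfg.quality_threshold
            depths = np.arange(0.0, t.length + 1e-9, 0.25 * min(labels.spacing))
            seen = set(int(v) for v in labels.values_at(t.points(depths)))
            assert seen & target
            assert not (seen & risk)

    def test_planner_is_deterministic(self, phantom_paths):
        models, cfg, paths = phantom_paths
        again = plan_all(models.gold, cfg)
        assert len(again) == len(paths)
        for a, b in zip(paths, again):
            assert np.array_equal(a.trajectory.entry, b.trajectory.entry)
            assert a.target_voxel == b.target_voxel and a.score == b.score

    def test_target_enclosed_in_bone_shell_yields_empty_set(self):
        v = np.full((24, 24, 28), AIR, dtype=np.int16)
        v[:, :, 4:6] = SKIN
        v[:, :, 6:] = SOFT_TISSUE
        x, y, z = np.ogrid[:24, :24, :28]
        r2 = (x - 12) ** 2 + (y - 12) ** 2 + (z - 16) ** 2
        v[r2 <= 25] = BONE
        v[r2 <= 4] = BILE
        model = PatientModel(labels=Volume3D(v, (1, 1, 1)))
        with pytest.warns(UserWarning, match="no feasible path"):
            paths = plan_all(model, PlannerConfig())
        assert paths == []

    def test_tie_broken_by_smallest_zyx_target(self):
        v = np.full((21, 21, 21), AIR, dtype=np.int16)
        v[:, :, 3:5] = SKIN
        v[:, :, 5:] = SOFT_TISSUE
        v[10, 8, 12] = BILE
        v[10, 12, 12] = BILE  # mirror-symmetric twin, same z, larger y
        model = PatientModel(labels=Volume3D(v, (1, 1, 1)))
        paths = plan_all(model, PlannerConfig(quality_threshold=0.1))
        by_skin = {p.skin_voxel: p for p in paths}
        assert by_skin[(10, 10, 3)].target_voxel == (10, 8, 12)

    def test_invariant_under_role_preserving_relabeling(self):
        spec = small_spec()
        models = layered_phantom(spec)
        values = models.gold.labels.values.copy()
        remap = {VESSEL: 11, BILE: 12}
        for old, new in remap.items():
            values[values == old] = new
        entries = []
        for e in models.gold.table:
            code = remap.get(e.code, e.code)
            entries.append(TissueEntry(code, e.name, e.role, e.params))
        model2 = PatientModel(
            labels=Volume3D(values, models.gold.labels.spacing),
            intensity=models.gold.intensity,
            thresholds=models.gold.thresholds,
            table=TissueTable(entries),
        )
        cfg = PlannerConfig(skin_stride=8)
        a = plan_all(models.gold, cfg)
        b = plan_all(model2, cfg)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.trajectory.entry, pb.trajectory.entry)
            assert pa.target_voxel == pb.target_voxel
            assert pa.score == pb.score
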