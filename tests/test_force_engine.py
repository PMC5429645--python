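"""Four-phase force rendering: springs, phase cycle, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctforce.force_engine import (
    EngineConfig,
    NeedleInsertion,
    render_insertion,
    render_retraction,
    spring_coeffs,
    spring_force,
)
from punctforce.tissue_model import (
    AIR,
    BILE,
    BONE,
    FASCIA,
    LIVER,
    SKIN,
    SOFT_TISSUE,
    VESSEL,
    default_table,
)

from conftest import column_trajectory, make_column_model

TABLE = default_table()


class TestSpringCoeffs:
    def test_a1_equals_k_degenerates_to_linear(self):
        c = spring_coeffs(t_n=0.7, a0=0.0, k=0.8, a1=0.8)
        assert c.a2 == 0.0
        d = np.linspace(0, 1, 7)
        assert np.allclose([c(x) for x in d], 0.8 * d)  # Hooke

    def test_skin_entered_from_air(self):
        # T_N=0.7, a0=0, k=0.8, a1=0: a2 = 0.8*0.8/0.7 and puncture at
        # d* = 0.7/0.8 = 0.875 mm where the polynomial reaches T_N exactly.
        c = spring_coeffs(t_n=0.7, a0=0.0, k=0.8, a1=0.0)
        assert c.a2 == pytest.approx(0.8 * 0.8 / 0.7)
        assert c(0.875) == pytest.approx(0.7)

    def test_fascia_entered_from_soft_tissue(self):
        c = spring_coeffs(t_n=2.5, a0=0.7, k=1.0, a1=0.5)
        assert c.a2 == pytest.approx(0.5 / 1.8)

    def test_design_slope_outside_range_rejected(self):
        with pytest.raises(ValueError, match="a1"):
            spring_coeffs(t_n=1.0, a0=0.0, k=1.0, a1=1.5)

    def test_spring_force_basics(self):
        c = spring_coeffs(t_n=2.5, a0=0.7, k=1.0, a1=0.5)
        assert spring_force(0.0, c) == 0.7
        assert spring_force(100.0, c, device_max=22.0) == 22.0
        with pytest.raises(ValueError):
            spring_force(-0.1, c)

    @given(
        t_n=st.floats(0.1, 5.0),
        a0_frac=st.floats(0.0, 0.95),
        k=st.floats(0.1, 3.0),
        a1_frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_puncture_displacement_equivalence(self, t_n, a0_frac, k, a1_frac):
        """The non-linear spring crosses T_N at exactly the linear spring's
        displacement (T_N - a0)/k, for any design slope a1 in [0, k]."""
        a0 = a0_frac * t_n
        c = spring_coeffs(t_n=t_n, a0=a0, k=k, a1=a1_frac * k)
        d_star = (t_n - a0) / k
        assert c(d_star) == pytest.approx(t_n, rel=1e-9)
        if d_star > 1e-6:
            assert c(0.99 * d_star) < t_n


# ---------------------------------------------------------------------------
# Independent closed-form oracle: piecewise-analytic four-phase force law
# built directly from the layer stack, never from the engine's state machine.
# ---------------------------------------------------------------------------

def analytic_oracle(layers, depths, table=TABLE, a1_fraction=0.5):
    """(force function, cut depths, surface depths) for a column stack.

    ``layers`` are (code, voxel count) at unit spacing; surfaces snap to the
    first sample of the new tissue on the given depth grid (nearest-voxel
    boundary at k0 - 0.5).
    """
    pieces = []  # (start_depth, force callable)
    cuts, surfaces = [], []
    cur = table.params(layers[0][0])
    pieces.append((0.0, lambda d, R=cur.R: R))
    k0 = 0
    for code, n in layers:
        if k0 > 0:
            b = k0 - 0.5
            s = float(depths[np.searchsorted(depths, b)])
            surfaces.append(s)
            new = table.params(code)
            if new.T_N <= cur.R:
                cuts.append(s)
                pieces.append((s, lambda d, R=new.R: R))
            else:
                a0, kk = cur.R, new.k
                a1 = a1_fraction * kk
                a2 = kk * (kk - a1) / (new.T_N - a0)
                cut = s + (new.T_N - a0) / kk
                cuts.append(cut)
                pieces.append(
                    (s, lambda d, a0=a0, a1=a1, a2=a2, s=s, T=new.T_N: min(
                        a2 * (d - s) ** 2 + a1 * (d - s) + a0, T))
                )
                pieces.append((cut, lambda d, R=new.R: R))
            cur = new
        k0 += n

    def force(d):
        fn = pieces[0][1]
        for start, f in pieces:
            if d >= start - 1e-12:
                fn = f
        return fn(d)

    return force, cuts, surfaces


def _random_stack(rng):
    codes = [SKIN, SOFT_TISSUE, FASCIA, LIVER, VESSEL, BILE]
    layers = [(AIR, rng.integers(4, 8))]
    prev = AIR
    for _ in range(rng.integers(3, 6)):
        code = int(rng.choice([c for c in codes if c != prev]))
        layers.append((code, int(rng.integers(6, 12))))
        prev = code
    return [(c, int(n)) for c, n in layers]


class TestEngineOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_piecewise_analytic_solution(self, seed):
        """Engine output equals the closed-form four-phase force law within
        0.05 N away from events, and cut positions align within one step."""
        rng = np.random.default_rng(seed)
        layers = _random_stack(rng)
        model = make_column_model(layers)
        traj = column_trajectory(model, n_samples=1000)
        sig = render_insertion(traj, model)
        force, cuts, surfaces = analytic_oracle(layers, sig.depth_mm)
        events = np.array(cuts + surfaces)
        step = traj.sample_spacing
        away = np.min(np.abs(sig.depth_mm[:, None] - events[None, :]), axis=1) > 1.5 * step
        expected = np.array([force(d) for d in sig.depth_mm])
        assert np.max(np.abs(sig.force_n[away] - expected[away])) <= 0.05
        engine_cuts = np.sort(sig.depth_mm[sig.event_indices("cut")])
        assert len(engine_cuts) == len(cuts)
        assert np.max(np.abs(engine_cuts - np.sort(cuts))) <= 1.5 * step

    @pytest.mark.parametrize("seed", range(8))
    def test_forces_bounded_and_deterministic(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = make_column_model(_random_stack(rng))
        traj = column_trajectory(model)
        a = render_insertion(traj, model)
        b = render_insertion(traj, model)
        assert np.all((a.force_n >= 0) & (a.force_n <= 22.0))
        assert np.array_equal(a.force_n, b.force_n)  # bit-identical
        assert np.array_equal(a.tissue, b.tissue)
        assert a.events == b.events


class TestPhases:
    def test_air_only_path_renders_zero_force(self):
        model = make_column_model([(AIR, 40)])
        sig = render_insertion(column_trajectory(model), model)
        assert np.all(sig.force_n == 0.0)

    def test_skin_puncture_has_no_force_drop(self):
        # R = T_N = 0.7 for skin: the sustain level equals the cut level.
        model = make_column_model([(AIR, 6), (SKIN, 30)])
        sig = render_insertion(column_trajectory(model), model)
        assert sig.peak == 0.7
        i_cut = sig.event_indices("cut")[0]
        assert np.all(sig.force_n[i_cut:] == 0.7)
        assert np.all(np.diff(sig.force_n[: i_cut + 1]) >= 0)  # monotone ramp

    def test_fascia_peak_equals_cut_threshold(self):
        model = make_column_model([(AIR, 6), (SKIN, 6), (SOFT_TISSUE, 20), (FASCIA, 8), (SOFT_TISSUE, 10)])
        sig = render_insertion(column_trajectory(model), model)
        assert sig.peak == 2.5
        i_peak = int(np.argmax(sig.force_n))
        assert i_peak in sig.event_indices("cut")

    def test_liver_entered_by_immediate_cut(self):
        # fascia sustain 1.0 > liver T_N 0.3: no ramp, force declines to 0.9
        model = make_column_model(
            [(AIR, 6), (SKIN, 6), (SOFT_TISSUE, 14), (FASCIA, 8), (LIVER, 20)]
        )
        sig = render_insertion(column_trajectory(model), model)
        liver = sig.tissue == LIVER
        assert np.all(sig.force_n[liver] == 0.9)

    def test_exiting_the_body_declines_to_zero(self):
        model = make_column_model([(AIR, 6), (SKIN, 6), (SOFT_TISSUE, 14), (AIR, 14)])
        sig = render_insertion(column_trajectory(model), model)
        exit_region = np.flatnonzero(sig.tissue == AIR)
        tail = exit_region[exit_region > 200]
        assert np.all(sig.force_n[tail] == 0.0)

    def test_bone_clamps_at_device_maximum_and_blocks(self):
        # bone ramps with its full stiffness, clamps at 22 N, and is never
        # punctured: tissue beyond the rib is never entered.
        model = make_column_model(
            [(AIR, 4), (SKIN, 4), (SOFT_TISSUE, 8), (BONE, 20), (SOFT_TISSUE, 20)]
        )
        sig = render_insertion(column_trajectory(model, n_samples=3000), model)
        assert sig.peak == 22.0
        assert sig.event_indices("bone_clamp")
        assert np.all(sig.force_n[sig.force_n > 3.0] <= 22.0)
        # the soft tissue behind the rib never takes over
        i_bone = int(np.argmax(sig.tissue == BONE))
        assert np.all(sig.tissue[i_bone:] == BONE)
        # the ramp never cuts: monotone rise to the clamp, no drop to a
        # sustain level of the tissue behind the rib
        assert np.all(np.diff(sig.force_n[i_bone:]) >= 0)
        assert sig.force_n[-1] == 22.0
        # slope before the clamp is the bone stiffness (linear, k = 2 N/mm)
        ramp = (sig.tissue == BONE) & (sig.force_n > 4.0) & (sig.force_n < 21.0)
        slopes = np.diff(sig.force_n[ramp]) / np.diff(sig.depth_mm[ramp])
        assert np.allclose(slopes, 2.0, atol=1e-6)

    def test_risk_event_on_vessel_surface(self):
        model = make_column_model(
            [(AIR, 6), (SKIN, 6), (SOFT_TISSUE, 10), (FASCIA, 8), (LIVER, 10), (VESSEL, 8), (LIVER, 10)]
        )
        sig = render_insertion(column_trajectory(model), model)
        risk_idx = sig.event_indices("risk")
        assert risk_idx and sig.tissue[risk_idx[0]] == VESSEL


class TestStepApi:
    def test_homogeneous_steady_advance_sustains_r(self):
        model = make_column_model([(SOFT_TISSUE, 40)])
        needle = NeedleInsertion(column_trajectory(model), model)
        forces = [needle.step(d)[0] for d in np.linspace(0, 30, 200)]
        assert forces == [0.7] * 200

    def test_tip_cannot_move_backwards(self):
        model = make_column_model([(SOFT_TISSUE, 40)])
        needle = NeedleInsertion(column_trajectory(model), model)
        needle.step(5.0)
        with pytest.raises(RuntimeError, match="retraction"):
            needle.step(4.0)

    def test_state_reports_proxy_behind_tip_in_pass_phase(self):
        model = make_column_model([(SOFT_TISSUE, 40)])
        needle = NeedleInsertion(column_trajectory(model), model)
        _, state = needle.step(10.0)
        assert state.proxy_depth == pytest.approx(10.0 - 0.7 / 1.0)  # l_max = R/k


class TestRetraction:
    def test_homogeneous_retraction_constant_friction(self):
        model = make_column_model([(SOFT_TISSUE, 40)])
        sig = render_retraction(column_trajectory(model), model)
        assert np.all(sig.force_n == 0.7)

    def test_no_puncture_peak_across_cut_fascia(self):
        model = make_column_model([(AIR, 6), (SKIN, 6), (SOFT_TISSUE, 14), (FASCIA, 8), (LIVER, 10)])
        traj = column_trajectory(model)
        sig = render_retraction(traj, model)
        assert sig.peak <= 1.0  # fascia sustain, never its 2.5 N cut level
        fascia = sig.tissue == FASCIA
        assert np.all(sig.force_n[fascia] == 1.0)

    def test_zero_length_retraction_is_empty(self):
        model = make_column_model([(SOFT_TISSUE, 40)])
        sig = render_retraction(column_trajectory(model), model, from_depth=-1.0)
        assert len(sig) == 0
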