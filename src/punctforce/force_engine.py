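"""Four-phase proxy/spring axial force rendering along straight trajectories.

The needle tip ``x`` is connected to a proxy point ``p`` by a spring. The
rendering cycles through four phases as the tip advances:

1. **Pre-puncture** — the proxy is pinned to a just-encountered tissue
   surface while the tip advances; the spring force follows a non-linear
   (second-degree) characteristic ``f(d) = a2 d^2 + a1 d + a0`` in the
   proxy-tip displacement ``d``, rising until it exceeds the tissue's cut
   threshold ``T_N``.
2. **Post-puncture** — an instantaneous cut event: the proxy is released and
   jumps to ``l_max = R/k`` behind the tip, dropping the force to the sustain
   level ``R`` (the salient "membrane pop").
3. **Pass** — the proxy trails the tip at the constant distance ``l_max``;
   a linear Hookean spring then sustains the friction force ``k * l_max = R``.
4. **Transition** — a new tissue surface is met. If its threshold exceeds the
   current sustain force a new pre-puncture ramp starts from ``a0 = R``;
   otherwise the surface is cut immediately and the force drops to the new
   sustain level (e.g. entering the liver, whose threshold 0.3 N is below any
   sustain level that can reach it; or piercing out into air, force -> 0).

The quadratic coefficient ``a2 = k (k - a1) / |T_N - a0|`` is chosen so the
non-linear spring reaches ``T_N`` at exactly the displacement
``(T_N - a0)/k`` of the plain linear spring — the puncture position is
independent of the design slope ``a1 in [0, k]``.

Bone is impenetrable (``T_N = inf``): the ramp never cuts, the force clamps
at the device maximum (22 N axial), and the tip cannot meaningfully advance,
so any tissue sampled beyond bone is never entered.

Retraction uses phase 3 only (all membranes along the path are already cut):
pure sustain forces, no puncture peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .tissue_model import (
    AIR,
    UNSEGMENTED,
    ClassifierState,
    HapticParams,
    PatientModel,
    Role,
    classify_intensity,
)
from .volumes import Trajectory, sample_labels_along

__all__ = [
    "SpringCoeffs",
    "EngineConfig",
    "NeedleState",
    "ForceSignal",
    "NeedleInsertion",
    "spring_coeffs",
    "spring_force",
    "render_insertion",
    "render_retraction",
]

#: Phase codes recorded per sample.
PH_PRE, PH_CUT, PH_PASS, PH_TRANSITION = 1, 2, 3, 4


@dataclass(frozen=True)
class SpringCoeffs:
    """Coefficients of the pre-puncture spring ``f(d) = a2 d^2 + a1 d + a0``.

    ``a0`` is the start force level (the sustain force of the tissue just
    passed, 0 when coming from air), ``a1 in [0, k]`` the design slope and
    ``a2 >= 0`` the quadratic term fixed by the puncture-displacement
    equivalence with the linear spring.
    """

    a0: float
    a1: float
    a2: float
    t_n: float = math.inf

    def __call__(self, d: float) -> float:
        return self.a2 * d * d + self.a1 * d + self.a0


def spring_coeffs(t_n: float, a0: float, k: float, a1: float) -> SpringCoeffs:
    """Build the non-linear pre-puncture spring for a tissue surface.

    Parameters
    ----------
    t_n : float
        Cut threshold of the new tissue in N (may be ``inf`` for bone).
    a0 : float
        Start force level in N (sustain level of the previous tissue).
    k : float
        Stiffness of the new tissue in N/mm.
    a1 : float
        Design slope in N/mm; must lie in ``[0, k]``. ``a1 = k`` degenerates
        to the linear spring (``a2 = 0``).

    The returned polynomial satisfies ``f((t_n - a0)/k) == t_n`` exactly.
    """
    if not (0.0 <= a1 <= k):
        raise ValueError(f"design slope a1 must lie in [0, k]=[0, {k}], got {a1}")
    if t_n < a0:
        raise ValueError(
            f"pre-puncture phase requires T_N >= a0, got T_N={t_n}, a0={a0}"
        )
    if math.isinf(t_n) or t_n == a0:
        a2 = 0.0
    else:
        a2 = k * (k - a1) / abs(t_n - a0)
    return SpringCoeffs(a0=a0, a1=a1, a2=a2, t_n=t_n)


def spring_force(d: float, c: SpringCoeffs, device_max: float | None = None) -> float:
    """Evaluate the spring polynomial at displacement ``d >= 0`` mm.

    Clamped to ``device_max`` when given (the haptic device force ceiling).
    """
    if d < 0:
        raise ValueError("displacement must be non-negative")
    f = c(d)
    if device_max is not None:
        f = min(f, device_max)
    return f


@dataclass(frozen=True)
class EngineConfig:
    """Force engine settings.

    ``a1_fraction`` sets the pre-puncture design slope as a fraction of the
    tissue stiffness (``a1 = a1_fraction * k``); any value in [0, 1] leaves
    the puncture displacement unchanged. For impenetrable tissue
    (``T_N = inf``) the linear spring ``a1 = k`` is used so the ramp carries
    the tissue's full stiffness. ``device_max`` is the axial force ceiling of
    the haptic device in N. ``identical_tol`` is the float tolerance under
    which two emitted forces count as exactly identical.
    """

    a1_fraction: float = 0.5
    device_max: float = 22.0
    n_samples: int = 1000
    identical_tol: float = 1e-9

    def __post_init__(self):
        if not (0.0 <= self.a1_fraction <= 1.0):
            raise ValueError("a1_fraction must lie in [0, 1]")
        if self.device_max <= 0:
            raise ValueError("device_max must be positive")


@dataclass
class NeedleState:
    """Snapshot of the phase machine after a step.

    ``proxy_depth`` is the proxy position along the trajectory: pinned at
    ``surface_depth`` during pre-puncture, trailing the tip at ``l_max = R/k``
    during pass.
    """

    phase: int
    tip_depth: float
    proxy_depth: float
    surface_depth: float | None
    tissue: int
    params: HapticParams
    classifier: ClassifierState


@dataclass(frozen=True)
class ForceSignal:
    """Sampled axial force signal along one trajectory.

    Samples are ordered by strictly increasing depth. ``events`` maps sample
    indices to event names (``surface``, ``cut``, ``risk``, ``bone_clamp``).
    """

    depth_mm: np.ndarray
    force_n: np.ndarray
    tissue: np.ndarray
    phase: np.ndarray
    events: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        n = len(self.depth_mm)
        if not (len(self.force_n) == len(self.tissue) == len(self.phase) == n):
            raise ValueError("signal arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.depth_mm) > 0):
            raise ValueError("depths must be strictly increasing")
        if n and (np.min(self.force_n) < 0):
            raise ValueError("forces must be non-negative")

    def __len__(self) -> int:
        return len(self.depth_mm)

    @property
    def peak(self) -> float:
        return float(np.max(self.force_n)) if len(self) else 0.0

    def event_indices(self, name: str) -> list[int]:
        return [i for i, n in self.events if n == name]

    def to_frame(self):
        import pandas as pd

        ev = np.full(len(self), "", dtype=object)
        for i, name in self.events:
            ev[i] = name if not ev[i] else f"{ev[i]}+{name}"
        return pd.DataFrame(
            {
                "depth_mm": self.depth_mm,
                "force_N": self.force_n,
                "tissue": self.tissue,
                "phase": self.phase,
                "event": ev,
            }
        )

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)


class _PhaseMachine:
    """The four-phase cycle over a per-sample (depth, tissue) stream.

    While a pre-puncture ramp is active, tissue changes at the tip are
    ignored: the pinned membrane has not been cut yet, so its parameters keep
    governing the spring until the cut occurs. Because bone never cuts, this
    also freezes the engine on bone for the rest of the path (the physical
    tip cannot advance past it).
    """

    def __init__(self, table, cfg: EngineConfig):
        self.table = table
        self.cfg = cfg
        self.cur: HapticParams | None = None
        self.cur_code: int | None = None
        self.mode = PH_PASS
        self.coeffs: SpringCoeffs | None = None
        self.pending: HapticParams | None = None
        self.pending_code: int | None = None
        self.surface_depth: float | None = None
        self.last_depth: float | None = None
        self._risk_active = False
        self._clamped = False

    # -- helpers ----------------------------------------------------------
    def _start_pre_puncture(self, depth: float, code: int, params: HapticParams):
        a1 = params.k if math.isinf(params.T_N) else self.cfg.a1_fraction * params.k
        self.coeffs = spring_coeffs(params.T_N, self.cur.R, params.k, a1)
        self.pending = params
        self.pending_code = code
        self.surface_depth = depth
        self.mode = PH_PRE
        self._clamped = False

    def _finish_cut(self):
        self.cur = self.pending
        self.cur_code = self.pending_code
        self.pending = self.pending_code = None
        self.coeffs = None
        self.surface_depth = None
        self.mode = PH_PASS

    # -- main step --------------------------------------------------------
    def advance(self, depth: float, code: int, risk_flag: bool):
        """One tip sample; returns (force, phase, events)."""
        if self.last_depth is not None and depth < self.last_depth:
            raise RuntimeError(
                "tip depth decreased during insertion (proxy would lead the tip); "
                "use render_retraction for withdrawal"
            )
        self.last_depth = depth
        events: list[str] = []

        if risk_flag and not self._risk_active:
            events.append("risk")
        self._risk_active = risk_flag

        if self.cur is None:  # first sample: adopt the starting tissue
            self.cur_code = code
            self.cur = self.table.params(code)
            if self.table.role(code) == Role.RISK:
                events.append("risk")
            return min(self.cur.R, self.cfg.device_max), PH_PASS, events

        if self.mode == PH_PASS:
            if code != self.cur_code:
                events.append("surface")
                entry = self.table.entry(code)
                if entry.role == Role.RISK and "risk" not in events:
                    events.append("risk")
                if entry.params.T_N <= self.cur.R:
                    # Immediate cut: no cutting force is due, drop to the new
                    # sustain level (includes piercing out into air, R = 0).
                    events.append("cut")
                    self.cur = entry.params
                    self.cur_code = code
                    return min(self.cur.R, self.cfg.device_max), PH_CUT, events
                self._start_pre_puncture(depth, code, entry.params)
                return min(self.coeffs.a0, self.cfg.device_max), PH_PRE, events
            return min(self.cur.R, self.cfg.device_max), PH_PASS, events

        # PH_PRE: ramp against the pinned membrane.
        d = depth - self.surface_depth
        f = self.coeffs(d)
        if f >= self.pending.T_N:
            # Cut sample: the spring reaches the threshold exactly (the
            # emitted peak equals T_N); phase 2 is instantaneous and the next
            # sample already carries the dropped sustain force.
            t_n = self.pending.T_N
            events.append("cut")
            self._finish_cut()
            return min(t_n, self.cfg.device_max), PH_CUT, events
        if f >= self.cfg.device_max and not self._clamped:
            events.append("bone_clamp" if math.isinf(self.pending.T_N) else "clamp")
            self._clamped = True
        return min(f, self.cfg.device_max), PH_PRE, events

    def state(self, tip_depth: float, classifier: ClassifierState) -> NeedleState:
        if self.mode == PH_PRE:
            proxy = self.surface_depth
            code, params = self.pending_code, self.pending
            surface = self.surface_depth
        else:
            params = self.cur if self.cur is not None else HapticParams(0, 0, 0)
            code = self.cur_code if self.cur_code is not None else AIR
            l_max = params.R / params.k if params.k > 0 else 0.0
            proxy = tip_depth - l_max
            surface = None
        return NeedleState(
            phase=self.mode,
            tip_depth=tip_depth,
            proxy_depth=proxy,
            surface_depth=surface,
            tissue=code,
            params=params,
            classifier=replace(classifier),
        )


def _tissue_sequence(
    traj: Trajectory, model: PatientModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (depths, tissue codes, air-cavity risk flags) along a path.

    Labels take precedence; unsegmented voxels go through the transfer
    function with the classifier state evolving as the tip advances.
    """
    depths, labels = sample_labels_along(traj, model.labels)
    n = len(depths)
    hu = None
    if np.any(labels == UNSEGMENTED):
        if model.intensity is None:
            raise ValueError(
                "trajectory crosses unsegmented voxels but the model has no "
                "intensity volume"
            )
        hu = model.intensity.values_at(traj.points(depths))
    codes = np.empty(n, dtype=np.int64)
    risk = np.zeros(n, dtype=bool)
    state = ClassifierState()
    for i in range(n):
        lab = int(labels[i])
        if lab != UNSEGMENTED:
            code = lab
        else:
            code = classify_intensity(float(hu[i]), state, model.thresholds)
            if code == AIR and state.inside_body:
                risk[i] = True
        codes[i] = code
        state.observe(code)
    # A labeled air pocket inside the body is equally a risk structure.
    inside = np.cumsum(codes != AIR) > 0
    risk |= (codes == AIR) & inside & (np.arange(n) > 0)
    return depths, codes, risk


class NeedleInsertion:
    """Incremental stepper: feed monotonically increasing tip depths.

    Mirrors :func:`render_insertion` one sample at a time; useful for
    driving the engine from an interactive loop.
    """

    def __init__(self, traj: Trajectory, model: PatientModel, cfg: EngineConfig | None = None):
        self.traj = traj
        self.model = model
        self.cfg = cfg or EngineConfig()
        self.classifier = ClassifierState()
        self._machine = _PhaseMachine(model.table, self.cfg)

    def step(self, tip_depth: float) -> tuple[float, NeedleState]:
        """Advance the tip to ``tip_depth`` (mm); returns (force N, state)."""
        if tip_depth < 0:
            raise ValueError("tip depth must be non-negative")
        pos = self.traj.point_at(tip_depth)
        from .tissue_model import haptic_params_at

        if self._machine.mode == PH_PRE:
            # Membrane not yet cut: tissue changes at the tip are ignored.
            code, risk_flag = self._machine.pending_code, False
        else:
            _, code, event = haptic_params_at(pos, self.model, self.classifier)
            risk_flag = event == "risk"
            self.classifier.observe(code)
        force, phase, _ = self._machine.advance(tip_depth, code, risk_flag)
        state = self._machine.state(tip_depth, self.classifier)
        state.phase = phase
        return force, state


def render_insertion(
    traj: Trajectory, model: PatientModel, cfg: EngineConfig | None = None
) -> ForceSignal:
    """Render the axial force signal of a full insertion along ``traj``.

    One force sample per trajectory sample; surface, cut, risk and clamp
    events are annotated at the samples where they occur. Deterministic:
    identical inputs give a bit-identical signal.
    """
    cfg = cfg or EngineConfig()
    depths, codes, risk = _tissue_sequence(traj, model)
    machine = _PhaseMachine(model.table, cfg)
    n = len(depths)
    forces = np.empty(n, dtype=float)
    phases = np.empty(n, dtype=np.int8)
    tissues = np.empty(n, dtype=np.int64)
    events: list[tuple[int, str]] = []
    for i in range(n):
        f, ph, evs = machine.advance(float(depths[i]), int(codes[i]), bool(risk[i]))
        forces[i] = f
        phases[i] = ph
        # Report the tissue governing the emitted force (the pinned membrane
        # during pre-puncture, the passed tissue otherwise).
        tissues[i] = machine.pending_code if machine.mode == PH_PRE else machine.cur_code
        for name in evs:
            events.append((i, name))
    return ForceSignal(
        depth_mm=depths,
        force_n=forces,
        tissue=tissues,
        phase=phases,
        events=tuple(events),
    )


def render_retraction(
    traj: Trajectory,
    model: PatientModel,
    cfg: EngineConfig | None = None,
    from_depth: float | None = None,
) -> ForceSignal:
    """Force profile while withdrawing along an already-punctured path.

    Only the pass phase applies — every membrane on the path has been cut —
    so the force at each depth is the sustain level of the local tissue
    (magnitude <= R, no puncture peaks). ``from_depth`` limits the profile
    to the depth actually reached during insertion; 0 gives an empty signal.
    """
    cfg = cfg or EngineConfig()
    depths, codes, _ = _tissue_sequence(traj, model)
    if from_depth is not None:
        keep = depths <= from_depth
        depths, codes = depths[keep], codes[keep]
    forces = np.array(
        [min(model.table.params(int(c)).R, cfg.device_max) for c in codes], dtype=float
    )
    return ForceSignal(
        depth_mm=depths,
        force_n=forces,
        tissue=codes.astype(np.int64),
        phase=np.full(len(depths), PH_PASS, dtype=np.int8),
        events=(),
    )
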