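"""Tissue haptic parameters and the position-state-dependent transfer function.

Every tissue carries a haptic tuple ``(T_N, R, k)``:

* ``T_N`` — cut-force threshold in N the pre-puncture spring must exceed
  before the tissue surface is pierced (infinite for bone: impenetrable);
* ``R``  — friction/sustain force in N while advancing inside the tissue;
* ``k``  — stiffness in N/mm of the proxy-tip spring.

For voxels without an explicit segmentation label, a threshold transfer
function maps the HU intensity to one of four bulk classes (air, skin,
fat/soft tissue, bone). The mapping depends on where the needle tip has been:
before the fascia is crossed, the *sensitive* bone threshold applies; after
it, the *specific* (higher) one — so slightly calcified voxels near the ribs
count as bone only where puncturing them would matter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np
import yaml

from .volumes import Volume3D, world_to_voxel

__all__ = [
    "AIR",
    "SKIN",
    "SOFT_TISSUE",
    "BONE",
    "BONE_SPECIFIC",
    "FASCIA",
    "LIVER",
    "VESSEL",
    "BILE",
    "UNSEGMENTED",
    "Role",
    "HapticParams",
    "TissueEntry",
    "TissueTable",
    "ThresholdSet",
    "ClassifierState",
    "PatientModel",
    "TissueConfigError",
    "classify_intensity",
    "haptic_params_at",
    "default_table",
    "load_tissue_config",
    "save_tissue_config",
]

# Label codes. 0 is reserved for "unsegmented".
UNSEGMENTED = 0
AIR = 1
SKIN = 2
SOFT_TISSUE = 3
BONE = 4            # sensitive-threshold bone (generic bone code)
BONE_SPECIFIC = 5   # specific-threshold bone; identical haptics to BONE
FASCIA = 6
LIVER = 7
VESSEL = 8          # hepatic blood vessels (risk)
BILE = 9            # hepatic bile ducts (target)

#: Rank of the bulk transfer-function classes, used by the monotonicity
#: property of the classifier: air < skin < soft < bone.
CLASS_RANK = {AIR: 0, SKIN: 1, SOFT_TISSUE: 2, BONE: 3}


class Role(str, Enum):
    PASS = "pass"
    RISK = "risk"
    TARGET = "target"


class HapticParams(NamedTuple):
    """Per-tissue haptic tuple (cut threshold N, sustain N, stiffness N/mm)."""

    T_N: float
    R: float
    k: float


class TissueConfigError(ValueError):
    """Invalid tissue table, thresholds, or unknown label code."""


@dataclass(frozen=True)
class TissueEntry:
    code: int
    name: str
    role: Role
    params: HapticParams

    def __post_init__(self):
        t_n, r, k = self.params
        if r < 0 or k < 0 or (t_n < 0):
            raise TissueConfigError(f"{self.name}: haptic parameters must be >= 0")
        if math.isfinite(t_n) and k == 0 and t_n > 0:
            raise TissueConfigError(
                f"{self.name}: penetrable tissue with T_N > 0 needs k > 0"
            )


class TissueTable:
    """Map from tissue code to name, role and haptic parameters."""

    def __init__(self, entries: list[TissueEntry]):
        self._entries: dict[int, TissueEntry] = {}
        for e in entries:
            if e.code in self._entries:
                raise TissueConfigError(f"duplicate tissue code {e.code}")
            if e.code == UNSEGMENTED:
                raise TissueConfigError("code 0 is reserved for unsegmented voxels")
            self._entries[e.code] = e

    def __contains__(self, code: int) -> bool:
        return int(code) in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def entry(self, code: int) -> TissueEntry:
        try:
            return self._entries[int(code)]
        except KeyError:
            raise TissueConfigError(
                f"label code {int(code)} is not registered in the tissue table"
            ) from None

    def params(self, code: int) -> HapticParams:
        return self.entry(code).params

    def role(self, code: int) -> Role:
        return self.entry(code).role

    def codes(self) -> list[int]:
        return sorted(self._entries)

    def codes_with_role(self, role: Role) -> list[int]:
        return sorted(c for c, e in self._entries.items() if e.role == role)

    def risk_codes(self) -> list[int]:
        return self.codes_with_role(Role.RISK)

    def target_codes(self) -> list[int]:
        return self.codes_with_role(Role.TARGET)


def default_table() -> TissueTable:
    """The default per-tissue haptic table.

    Air is nominally a pass tissue; an air reading *inside* the body marks an
    air cavity, which is a risk structure (handled by the classifier event,
    not by the role column). Liver has the lowest finite cut threshold of all
    tissues and a sustain force above it — the liver surface is always cut
    immediately when entered from fascia or soft tissue, so its pre-puncture
    phase never runs in practice.
    """
    inf = math.inf
    return TissueTable(
        [
            TissueEntry(AIR, "air", Role.PASS, HapticParams(0.0, 0.0, 0.0)),
            TissueEntry(SKIN, "skin", Role.PASS, HapticParams(0.7, 0.7, 0.8)),
            TissueEntry(SOFT_TISSUE, "fat/soft tissue", Role.PASS, HapticParams(0.7, 0.7, 1.0)),
            TissueEntry(BONE, "bone (sensitive)", Role.RISK, HapticParams(inf, 3.0, 2.0)),
            TissueEntry(BONE_SPECIFIC, "bone (specific)", Role.RISK, HapticParams(inf, 3.0, 2.0)),
            TissueEntry(FASCIA, "fascia", Role.PASS, HapticParams(2.5, 1.0, 1.0)),
            TissueEntry(LIVER, "liver", Role.PASS, HapticParams(0.3, 0.9, 1.2)),
            TissueEntry(VESSEL, "hepatic blood", Role.RISK, HapticParams(1.05, 0.75, 1.1)),
            TissueEntry(BILE, "hepatic bile", Role.TARGET, HapticParams(1.2, 0.5, 1.0)),
        ]
    )


@dataclass(frozen=True)
class ThresholdSet:
    """Lower HU interval bounds of the bulk classes (half-open intervals).

    ``[t0, t1)`` is skin, ``[t1, bone)`` fat/soft tissue, where the bone
    threshold is ``t2_minus`` before the fascia has been crossed and
    ``t2_plus`` after; anything below ``t0`` is air. The defaults are
    patient-specific in origin and freely configurable; the phantom generator
    draws intensities relative to whatever set is configured.
    """

    t0: float = -500.0
    t1: float = 50.0
    t2_minus: float = 200.0
    t2_plus: float = 400.0

    def __post_init__(self):
        if not (self.t0 < self.t1 < self.t2_minus <= self.t2_plus):
            raise TissueConfigError(
                "thresholds must satisfy t0 < t1 < t2_minus <= t2_plus, got "
                f"{(self.t0, self.t1, self.t2_minus, self.t2_plus)}"
            )


@dataclass
class ClassifierState:
    """Needle-tip position state of the transfer function.

    ``inside_body`` is set once the tip first crosses skin (first non-air
    class or label on the path); ``passed_fascia`` once the fascia label is
    first crossed. ``passed_fascia`` implies ``inside_body``.
    """

    inside_body: bool = False
    passed_fascia: bool = False

    def __post_init__(self):
        if self.passed_fascia and not self.inside_body:
            raise ValueError("passed_fascia implies inside_body")

    def observe(self, code: int) -> None:
        """Update the flags after the tip visited a voxel of class ``code``."""
        if code != AIR and code != UNSEGMENTED:
            self.inside_body = True
        if code == FASCIA:
            self.passed_fascia = True


@dataclass(frozen=True)
class PatientModel:
    """Intensity + (full or partial) label volume + thresholds + haptic table."""

    labels: Volume3D
    intensity: Volume3D | None = None
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    table: TissueTable = field(default_factory=default_table)

    def __post_init__(self):
        if not np.issubdtype(self.labels.values.dtype, np.integer):
            raise TissueConfigError("label volume must have an integer dtype")
        present = np.unique(self.labels.values)
        for code in present:
            if code != UNSEGMENTED and int(code) not in self.table:
                raise TissueConfigError(
                    f"label code {int(code)} present in volume but not in table"
                )
        if self.intensity is not None and self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and label volumes must share a grid")


def classify_intensity(hu: float, state: ClassifierState, thr: ThresholdSet) -> int:
    """Threshold transfer function: HU -> bulk tissue code.

    Total function over HU. Intervals are half-open ``[lower, next)``; the
    bone lower bound is ``t2_minus`` outside the fascia and ``t2_plus`` once
    it has been passed.
    """
    bone_thr = thr.t2_plus if state.passed_fascia else thr.t2_minus
    if hu < thr.t0:
        return AIR
    if hu < thr.t1:
        return SKIN
    if hu < bone_thr:
        return SOFT_TISSUE
    return BONE


def haptic_params_at(
    pos, model: PatientModel, state: ClassifierState
) -> tuple[HapticParams, int, str | None]:
    """Haptic parameters at a world position of a partially segmented patient.

    A segmented (nonzero) label takes precedence; otherwise the intensity is
    classified through the transfer function. Returns
    ``(params, tissue_code, event)`` where ``event`` is ``"risk"`` when an
    unsegmented voxel reads as air while the tip is inside the body (an air
    cavity — a risk structure), else ``None``.
    """
    idx = world_to_voxel(pos, model.labels)
    code = int(model.labels.values[idx])
    event = None
    if code == UNSEGMENTED:
        if model.intensity is None:
            raise TissueConfigError(
                "unsegmented voxel encountered but model has no intensity volume"
            )
        hu = float(model.intensity.values[idx])
        code = classify_intensity(hu, state, model.thresholds)
        if code == AIR and state.inside_body:
            event = "risk"
    return model.table.params(code), code, event


# ---------------------------------------------------------------------------
# Config I/O: haptic table + thresholds as YAML/JSON mirroring the table
# columns (tissue, role, T_N, R, k) plus the interval thresholds.
# ---------------------------------------------------------------------------

def _table_to_dict(table: TissueTable, thresholds: ThresholdSet) -> dict:
    return {
        "thresholds": {
            "t0": thresholds.t0,
            "t1": thresholds.t1,
            "t2_minus": thresholds.t2_minus,
            "t2_plus": thresholds.t2_plus,
        },
        "tissues": [
            {
                "code": e.code,
                "tissue": e.name,
                "role": e.role.value,
                "T_N": "inf" if math.isinf(e.params.T_N) else e.params.T_N,
                "R": e.params.R,
                "k": e.params.k,
            }
            for e in table
        ],
    }


def _table_from_dict(data: dict) -> tuple[TissueTable, ThresholdSet]:
    try:
        thr = ThresholdSet(**{k: float(v) for k, v in data["thresholds"].items()})
        entries = []
        for row in data["tissues"]:
            t_n = row["T_N"]
            t_n = math.inf if (isinstance(t_n, str) and t_n.lower() == "inf") else float(t_n)
            entries.append(
                TissueEntry(
                    code=int(row["code"]),
                    name=str(row["tissue"]),
                    role=Role(row["role"]),
                    params=HapticParams(t_n, float(row["R"]), float(row["k"])),
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, TissueConfigError):
            raise
        raise TissueConfigError(f"malformed tissue config: {exc}") from exc
    return TissueTable(entries), thr


def save_tissue_config(table: TissueTable, thresholds: ThresholdSet, path) -> None:
    """Write table + thresholds to YAML or JSON (by extension)."""
    data = _table_to_dict(table, thresholds)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_tissue_config(path) -> tuple[TissueTable, ThresholdSet]:
    """Read table + thresholds from YAML or JSON; accepts ``"inf"`` for T_N."""
    path = str(path)
    with open(path) as fh:
        data = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return _table_from_dict(data)
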