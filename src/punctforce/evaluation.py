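"""Force-error and border-lag evaluation of rendered needle force signals.

Metrics, all per planned path:

* RMSE — root mean squared force difference between a reference signal
  (gold-standard segmentation) and a test signal (partial segmentation).
* MAE — the *maximum* absolute force difference along the path (the field's
  convention; note this is a max, not a mean, hence ``rmse <= mae``).
* %Fc — percentage of samples with exactly identical emitted forces (up to a
  configurable float tolerance, default 1e-9 N).
* MSD / HSD — mean and Hausdorff (maximum) absolute depth difference of
  structure border crossings between the two segmentations, per structure
  and pooled per path. Depth lags of 2 mm / 3 mm serve as low/standard just
  noticeable spatial error lines for salient force events.
* Weber-fraction JNDs relate force and distance errors to what the hand-arm
  system can perceive.
* Top outliers are values above ``mean + 2.7 sigma`` (one-sided).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .force_engine import ForceSignal
from .tissue_model import PatientModel
from .volumes import Trajectory, Volume3D, sample_labels_along

__all__ = [
    "PathErrorReport",
    "JndSpec",
    "OutlierStats",
    "compare_signals",
    "border_crossings",
    "msd_hsd",
    "weber_jnd",
    "jnd_threshold",
    "outlier_stats",
    "summarize",
    "evaluate_path",
]

#: Interpretation lines for border lags (mm): low / standard just noticeable
#: spatial error for salient needle force events.
JND_DEPTH_LOW_MM = 2.0
JND_DEPTH_MM = 3.0


@dataclass(frozen=True)
class JndSpec:
    """A Weber just-noticeable-difference: threshold = S * fraction / 100."""

    reference: float
    fraction_pct: float

    @property
    def threshold(self) -> float:
        return jnd_threshold(self.reference, self.fraction_pct)


def weber_jnd(stimulus: float, delta: float) -> float:
    """Weber fraction in % of a stimulus change: 100 * ((S+dS) - S) / S."""
    if stimulus <= 0:
        raise ValueError("reference stimulus must be positive")
    return ((stimulus + delta) - stimulus) / stimulus * 100.0


def jnd_threshold(stimulus: float, fraction_pct: float) -> float:
    """Inverse Weber fraction: the just noticeable change dS = S * % / 100."""
    if stimulus <= 0:
        raise ValueError("reference stimulus must be positive")
    return stimulus * fraction_pct / 100.0


def compare_signals(
    ref: ForceSignal, test: ForceSignal, tol: float = 1e-9
) -> tuple[float, float, float]:
    """(rmse, mae, pct_identical) between two force signals on one grid.

    ``mae`` is the maximum absolute difference. ``pct_identical`` counts
    samples whose forces agree within ``tol`` (%Fc). The depth grids must
    match exactly; no resampling is applied silently.
    """
    if len(ref) != len(test):
        raise ValueError(
            f"sample counts differ ({len(ref)} vs {len(test)}); "
            "signals must share one depth grid"
        )
    if not np.array_equal(ref.depth_mm, test.depth_mm):
        raise ValueError("depth grids differ; resample explicitly before comparing")
    diff = np.abs(ref.force_n - test.force_n)
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.max(diff))
    pct = float(100.0 * np.count_nonzero(diff <= tol) / len(diff))
    return rmse, mae, pct


def border_crossings(
    traj: Trajectory, labels: Volume3D, structures: list[int] | None = None
) -> dict[int, list[float]]:
    """Entry-crossing depths per structure along a trajectory.

    A crossing into structure ``s`` is a sample whose label is ``s`` while
    the previous sample's label is not; its depth is recorded. Re-entrant
    structures (e.g. two fascia sheets) yield one depth per entry. Structures
    absent on the path map to empty lists.
    """
    depths, labs = sample_labels_along(traj, labels)
    if structures is None:
        structures = sorted(int(c) for c in np.unique(labs))
    out: dict[int, list[float]] = {int(s): [] for s in structures}
    change = np.flatnonzero(np.diff(labs) != 0) + 1
    for i in change:
        code = int(labs[i])
        if code in out:
            out[code].append(float(depths[i]))
    return out


def msd_hsd(
    ref_crossings: dict[int, list[float]],
    test_crossings: dict[int, list[float]],
) -> tuple[dict[int, tuple[float, float]], tuple[float, float], int]:
    """Mean and Hausdorff surface distance of border crossings, per path.

    Crossings of the same structure are matched in order; ``msd`` is the mean
    and ``hsd`` the maximum absolute depth difference over matched pairs.
    Unmatched crossings (a structure border present under one segmentation
    only) are excluded from the distances and returned as a count.

    Returns
    -------
    (per_structure, pooled, n_unmatched)
        ``per_structure`` maps code -> (msd, hsd) over that structure's
        matched pairs (NaN, NaN if none); ``pooled`` is (msd, hsd) over all
        matched pairs of the path.
    """
    codes = sorted(set(ref_crossings) | set(test_crossings))
    per_structure: dict[int, tuple[float, float]] = {}
    pooled: list[float] = []
    unmatched = 0
    for code in codes:
        r = ref_crossings.get(code, [])
        t = test_crossings.get(code, [])
        m = min(len(r), len(t))
        unmatched += abs(len(r) - len(t))
        diffs = [abs(a - b) for a, b in zip(r[:m], t[:m])]
        if diffs:
            per_structure[code] = (float(np.mean(diffs)), float(np.max(diffs)))
            pooled.extend(diffs)
        else:
            per_structure[code] = (math.nan, math.nan)
    pooled_stats = (
        (float(np.mean(pooled)), float(np.max(pooled))) if pooled else (math.nan, math.nan)
    )
    return per_structure, pooled_stats, unmatched


@dataclass(frozen=True)
class OutlierStats:
    mean: float
    sd: float
    outlier_pct: float
    flags: np.ndarray


def outlier_stats(values, factor: float = 2.7) -> OutlierStats:
    """Flag top outliers above ``mean + factor * sigma`` (one-sided).

    ``sigma`` is the sample standard deviation (n-1 denominator). Constant
    input has sd 0 and no outliers. Requires at least two values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("outlier statistics need at least two values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    flags = values > mean + factor * sd
    pct = float(100.0 * np.count_nonzero(flags) / values.size)
    return OutlierStats(mean=mean, sd=sd, outlier_pct=pct, flags=flags)


@dataclass(frozen=True)
class PathErrorReport:
    """Per-path force and border-lag errors."""

    rmse: float
    mae: float
    pct_identical: float
    n_samples: int
    msd_per_structure: dict[int, float] = field(default_factory=dict)
    hsd_per_structure: dict[int, float] = field(default_factory=dict)
    msd: float = math.nan
    hsd: float = math.nan
    n_unmatched_crossings: int = 0
    outlier: bool = False

    def to_dict(self) -> dict:
        d = {
            "rmse_N": self.rmse,
            "mae_N": self.mae,
            "pct_identical": self.pct_identical,
            "n_samples": self.n_samples,
            "msd_mm": self.msd,
            "hsd_mm": self.hsd,
            "n_unmatched_crossings": self.n_unmatched_crossings,
            "outlier": self.outlier,
        }
        for code, v in self.msd_per_structure.items():
            d[f"msd_mm_{code}"] = v
        for code, v in self.hsd_per_structure.items():
            d[f"hsd_mm_{code}"] = v
        return d


def evaluate_path(
    traj: Trajectory,
    ref_signal: ForceSignal,
    test_signal: ForceSignal,
    ref_model: PatientModel,
    test_model: PatientModel,
    tol: float = 1e-9,
) -> PathErrorReport:
    """Full per-path evaluation: force errors plus border-lag distances."""
    rmse, mae, pct = compare_signals(ref_signal, test_signal, tol=tol)
    ref_cross = border_crossings(traj, ref_model.labels)
    test_cross = border_crossings(traj, test_model.labels)
    # Only borders both segmentations can express are comparable: in a
    # partial model the bulk classes are unlabeled, so restrict to the
    # structures labeled on the test side.
    common = sorted(set(c for c, v in test_cross.items() if v))
    ref_cross = {c: ref_cross.get(c, []) for c in common}
    test_cross = {c: test_cross[c] for c in common}
    per_structure, (msd, hsd), unmatched = msd_hsd(ref_cross, test_cross)
    return PathErrorReport(
        rmse=rmse,
        mae=mae,
        pct_identical=pct,
        n_samples=len(ref_signal),
        msd_per_structure={c: v[0] for c, v in per_structure.items()},
        hsd_per_structure={c: v[1] for c, v in per_structure.items()},
        msd=msd,
        hsd=hsd,
        n_unmatched_crossings=unmatched,
    )


def summarize(reports: list[PathErrorReport], outlier_factor: float = 2.7) -> dict:
    """Cohort summary over per-path reports.

    Means and sample standard deviations of RMSE and MAE, the pooled
    percentage of identical forces (sample-weighted, not path-averaged), and
    the one-sided top-outlier percentages of both error metrics.
    """
    if not reports:
        raise ValueError("at least one report is required")
    rmse = np.array([r.rmse for r in reports])
    mae = np.array([r.mae for r in reports])
    n = np.array([r.n_samples for r in reports], dtype=float)
    pooled_pct = float(np.sum([r.pct_identical * r.n_samples for r in reports]) / n.sum())
    if len(reports) >= 2:
        rmse_out = outlier_stats(rmse, outlier_factor).outlier_pct
        mae_out = outlier_stats(mae, outlier_factor).outlier_pct
        rmse_sd = float(np.std(rmse, ddof=1))
        mae_sd = float(np.std(mae, ddof=1))
    else:
        rmse_out = mae_out = 0.0
        rmse_sd = mae_sd = 0.0
    return {
        "n_paths": len(reports),
        "rmse_mean_N": float(np.mean(rmse)),
        "rmse_sd_N": rmse_sd,
        "rmse_outlier_pct": rmse_out,
        "mae_mean_N": float(np.mean(mae)),
        "mae_sd_N": mae_sd,
        "mae_outlier_pct": mae_out,
        "pct_identical_pooled": pooled_pct,
    }


def reports_to_csv(reports: list[PathErrorReport], path, header_lines=None) -> None:
    import pandas as pd

    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame([r.to_dict() for r in reports]).to_csv(fh, index=False)


def summary_to_json(summary: dict, path, extra: dict | None = None) -> None:
    data = dict(summary)
    if extra:
        data.update(extra)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
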