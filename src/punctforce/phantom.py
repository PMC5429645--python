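"""Synthetic layered thorax/abdomen phantoms with controlled discrepancies.

The generator replaces clinical CT data: it builds a desk-scale virtual
patient with the layer order air | skin | fat/soft tissue | fascia | liver
(with embedded bile-duct and vessel tubes) along the insertion (z) axis,
plus two rib-like bone slabs flanking an intercostal window.

Each phantom yields a *gold* model (every voxel labeled — the stand-in for a
full manual expert segmentation) and a *test* model (by default only the key
structures fascia, liver, vessels and bile ducts keep their labels; skin,
fat, bone and air are left to the threshold transfer function, as in the
partial-segmentation patient modeling workflow). Controlled perturbations —
per-structure surface offsets and misclassified voxel bands — are applied to
the test model only, so every force discrepancy between the two models is
injected deliberately.

Intensities are drawn per class around means placed strictly inside the
configured threshold intervals, with noise small enough (default 5 sigma of
margin) that spontaneous misclassification is negligible; results therefore
do not depend on HU realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue_model import (
    AIR,
    BILE,
    BONE,
    FASCIA,
    LIVER,
    SKIN,
    SOFT_TISSUE,
    UNSEGMENTED,
    VESSEL,
    PatientModel,
    ThresholdSet,
    TissueTable,
    default_table,
)
from .volumes import Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomModels",
    "PhantomGeometryError",
    "STRUCTURE_CODES",
    "KEY_STRUCTURES",
    "layered_phantom",
    "two_fascia_phantom",
    "misclassify_band",
]

#: Structure names accepted in offsets / misclassification bands.
STRUCTURE_CODES = {
    "air": AIR,
    "skin": SKIN,
    "soft": SOFT_TISSUE,
    "bone": BONE,
    "fascia": FASCIA,
    "liver": LIVER,
    "vessel": VESSEL,
    "bile": BILE,
}

#: Structures that keep their labels in a partial (test) model; everything
#: else is handled by the transfer function.
KEY_STRUCTURES = (FASCIA, LIVER, VESSEL, BILE)


class PhantomGeometryError(ValueError):
    """The requested phantom geometry does not fit the volume."""


def _default_means() -> dict[int, float]:
    # Bulk classes sit strictly inside their default threshold intervals;
    # labeled key structures get soft-tissue-range values.
    return {
        AIR: -800.0,
        SKIN: -200.0,
        SOFT_TISSUE: 100.0,
        BONE: 500.0,
        FASCIA: 80.0,
        LIVER: 90.0,
        VESSEL: 110.0,
        BILE: 60.0,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity model and perturbations of a layered phantom.

    Depths are mm from the z = 0 volume face; the insertion axis is +z.
    ``surface_offsets`` shift the *proximal* (entry-side) surface of a
    structure deeper in the test model by the given amount (quantized to
    whole voxels); the distal boundary stays fixed. ``misclassify_bands``
    relabel a band of given thickness immediately proximal to a structure's
    surface as another tissue, again in the test model only.
    """

    shape: tuple[int, int, int] = (128, 128, 160)
    spacing: tuple[float, float, float] = (0.9, 0.9, 0.9)
    # layer geometry (mm depths)
    skin_depth: float = 5.0
    skin_thickness: float = 3.0
    fascia_depth: float = 25.0
    fascia_thickness: float = 4.0
    second_fascia_depth: float | None = None
    liver_range: tuple[float, float] | None = (30.0, 110.0)
    bile_depth: float = 60.0
    bile_radius: float = 3.0
    vessel_depths: tuple[float, ...] = (45.0, 75.0)
    vessel_y_offsets: tuple[float, ...] = (-15.0, 15.0)
    vessel_radius: float = 2.5
    tube_x_range: tuple[float, float] = (20.0, 95.0)
    ribs: bool = True
    rib_depth_range: tuple[float, float] = (10.0, 18.0)
    rib_window_halfwidth: float = 10.0
    # intensity model
    intensity_means: dict[int, float] = field(default_factory=_default_means)
    noise_sd: float = 10.0
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    seed: int = 0
    # perturbations (test model only)
    surface_offsets: dict[str, float] = field(default_factory=dict)
    misclassify_bands: tuple[tuple[str, float, str], ...] = ()
    test_partial: bool = True

    # -- derived ----------------------------------------------------------
    @property
    def extent(self) -> tuple[float, float, float]:
        """World extent spanned by voxel centers, per axis (mm)."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def validate(self) -> None:
        thr = self.thresholds
        means = self.intensity_means
        if not (means[AIR] < thr.t0):
            raise PhantomGeometryError("air mean must lie below t0")
        if not (thr.t0 <= means[SKIN] < thr.t1):
            raise PhantomGeometryError("skin mean must lie in [t0, t1)")
        if not (thr.t1 <= means[SOFT_TISSUE] < thr.t2_minus):
            raise PhantomGeometryError("soft-tissue mean must lie in [t1, t2_minus)")
        if not (means[BONE] >= thr.t2_plus):
            raise PhantomGeometryError("bone mean must lie at or above t2_plus")
        zmax = self.extent[2]
        off = self.surface_offsets
        skin_top = self.skin_depth + off.get("skin", 0.0)
        skin_end = self.skin_depth + self.skin_thickness
        if not (0 < self.skin_depth and skin_top < skin_end):
            raise PhantomGeometryError("skin offset exceeds skin thickness")
        f0 = self.fascia_depth + off.get("fascia", 0.0)
        f1 = self.fascia_depth + self.fascia_thickness
        if not (skin_end < self.fascia_depth and f0 < f1):
            raise PhantomGeometryError("fascia must lie below skin; offset too large")
        if self.second_fascia_depth is not None:
            if self.second_fascia_depth < f1:
                raise PhantomGeometryError("fascia sheets overlap")
            if self.second_fascia_depth + self.fascia_thickness > zmax:
                raise PhantomGeometryError("second fascia sheet exceeds the volume")
        if self.liver_range is not None:
            l0, l1 = self.liver_range
            if not (f1 <= l0 < l1 <= zmax):
                raise PhantomGeometryError(
                    f"liver range {self.liver_range} does not fit below the fascia "
                    f"inside the {zmax:.1f} mm volume"
                )
            for depth, radius in [(self.bile_depth, self.bile_radius)] + [
                (d, self.vessel_radius) for d in self.vessel_depths
            ]:
                if not (l0 <= depth - radius and depth + radius <= l1):
                    raise PhantomGeometryError(
                        f"tube at depth {depth} mm leaves the liver"
                    )
        if self.ribs:
            r0, r1 = self.rib_depth_range
            if not (skin_end <= r0 < r1 <= self.fascia_depth):
                raise PhantomGeometryError(
                    "ribs must lie in the soft tissue between skin and fascia"
                )
        if self.noise_sd < 0:
            raise PhantomGeometryError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PhantomModels:
    """Gold (fully labeled) and test (perturbed/partial) patient models."""

    gold: PatientModel
    test: PatientModel
    spec: PhantomSpec

    @property
    def gold_labels(self) -> Volume3D:
        return self.gold.labels

    @property
    def test_labels(self) -> Volume3D:
        return self.test.labels

    @property
    def intensity(self) -> Volume3D:
        return self.gold.intensity


def _grids(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    x = (np.arange(nx) * sx)[:, None, None]
    y = (np.arange(ny) * sy)[None, :, None]
    z = (np.arange(nz) * sz)[None, None, :]
    return x, y, z


def _build_labels(spec: PhantomSpec, offsets: dict[str, float]) -> np.ndarray:
    x, y, z = _grids(spec)
    yc = spec.extent[1] / 2.0
    labels = np.full(spec.shape, AIR, dtype=np.int16)

    skin_top = spec.skin_depth + offsets.get("skin", 0.0)
    skin_end = spec.skin_depth + spec.skin_thickness
    labels[np.broadcast_to(z >= skin_end, spec.shape)] = SOFT_TISSUE
    labels[np.broadcast_to((z >= skin_top) & (z < skin_end), spec.shape)] = SKIN

    fascia_starts = [spec.fascia_depth + offsets.get("fascia", 0.0)]
    fascia_ends = [spec.fascia_depth + spec.fascia_thickness]
    if spec.second_fascia_depth is not None:
        fascia_starts.append(spec.second_fascia_depth)
        fascia_ends.append(spec.second_fascia_depth + spec.fascia_thickness)
    for f0, f1 in zip(fascia_starts, fascia_ends):
        labels[np.broadcast_to((z >= f0) & (z < f1), spec.shape)] = FASCIA

    if spec.liver_range is not None:
        l0, l1 = spec.liver_range
        l0 = l0 + offsets.get("liver", 0.0)
        labels[np.broadcast_to((z >= l0) & (z < l1), spec.shape)] = LIVER
        x0, x1 = spec.tube_x_range
        in_x = np.broadcast_to((x >= x0) & (x <= x1), spec.shape)
        liver_mask = labels == LIVER
        for depth, y_off in zip(spec.vessel_depths, spec.vessel_y_offsets):
            tube = (z - depth) ** 2 + (y - (yc + y_off)) ** 2 <= spec.vessel_radius**2
            labels[np.broadcast_to(tube, spec.shape) & in_x & liver_mask] = VESSEL
        tube = (z - spec.bile_depth) ** 2 + (y - yc) ** 2 <= spec.bile_radius**2
        labels[np.broadcast_to(tube, spec.shape) & in_x & liver_mask] = BILE

    if spec.ribs:
        r0, r1 = spec.rib_depth_range
        rib = np.broadcast_to(
            (z >= r0) & (z < r1) & (np.abs(y - yc) >= spec.rib_window_halfwidth),
            spec.shape,
        )
        labels[rib] = BONE
    return labels


def _make_intensity(spec: PhantomSpec, gold_labels: np.ndarray) -> np.ndarray:
    means = np.zeros(max(spec.intensity_means) + 1, dtype=float)
    for code, mean in spec.intensity_means.items():
        means[code] = mean
    rng = np.random.default_rng(spec.seed)
    values = means[gold_labels]
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=gold_labels.shape)
    return values.astype(np.float32)


def _partialize(labels: np.ndarray) -> np.ndarray:
    out = np.where(np.isin(labels, KEY_STRUCTURES), labels, UNSEGMENTED)
    return out.astype(labels.dtype)


def _resolve_code(name: str) -> int:
    try:
        return STRUCTURE_CODES[name]
    except KeyError:
        raise ValueError(
            f"unknown structure {name!r}; known: {sorted(STRUCTURE_CODES)}"
        ) from None


def misclassify_band(
    labels: Volume3D, structure, thickness_mm: float, as_tissue
) -> Volume3D:
    """Relabel the band proximal to a structure's entry surface.

    For every (x, y) column containing the structure, the ``thickness_mm``
    band of voxels immediately above (smaller z than) the structure's first
    voxel is set to ``as_tissue``. Thickness 0 is the identity. Labels
    outside the band are untouched.
    """
    code = _resolve_code(structure) if isinstance(structure, str) else int(structure)
    as_code = _resolve_code(as_tissue) if isinstance(as_tissue, str) else int(as_tissue)
    if thickness_mm < 0:
        raise ValueError("band thickness must be non-negative")
    values = labels.values.copy()
    if thickness_mm == 0:
        return Volume3D(values, labels.spacing, labels.origin)
    mask = values == code
    if not mask.any():
        raise ValueError(f"structure {structure!r} not present in label volume")
    dz = labels.spacing[2]
    n_band = max(1, int(round(thickness_mm / dz)))
    has = mask.any(axis=2)
    first_k = np.argmax(mask, axis=2)
    ii, jj = np.nonzero(has)
    if np.any(first_k[ii, jj] - n_band < 0):
        raise ValueError("misclassification band would leave the volume")
    for o in range(1, n_band + 1):
        values[ii, jj, first_k[ii, jj] - o] = as_code
    return Volume3D(values, labels.spacing, labels.origin)


def layered_phantom(
    spec: PhantomSpec | None = None, table: TissueTable | None = None
) -> PhantomModels:
    """Build gold and test models of the layered phantom.

    The gold model is fully labeled and unperturbed. The test model carries
    the spec's surface offsets and misclassification bands and, when
    ``spec.test_partial`` is set, keeps labels only for the key structures.
    Identical inputs (including the seed) give bit-identical volumes.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    table = table or default_table()

    gold_labels = _build_labels(spec, {})
    test_labels = _build_labels(spec, dict(spec.surface_offsets))
    spacing, origin = spec.spacing, (0.0, 0.0, 0.0)
    test_vol = Volume3D(test_labels, spacing, origin)
    for structure, thickness, as_tissue in spec.misclassify_bands:
        test_vol = misclassify_band(test_vol, structure, thickness, as_tissue)
    if spec.test_partial:
        test_vol = Volume3D(_partialize(test_vol.values), spacing, origin)

    intensity = Volume3D(_make_intensity(spec, gold_labels), spacing, origin)
    gold = PatientModel(
        labels=Volume3D(gold_labels, spacing, origin),
        intensity=intensity,
        thresholds=spec.thresholds,
        table=table,
    )
    test = PatientModel(
        labels=test_vol,
        intensity=intensity,
        thresholds=spec.thresholds,
        table=table,
    )
    return PhantomModels(gold=gold, test=test, spec=spec)


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain-dict form of a phantom spec (YAML/JSON serializable)."""
    d = {
        "shape": list(spec.shape),
        "spacing": list(spec.spacing),
        "skin_depth": spec.skin_depth,
        "skin_thickness": spec.skin_thickness,
        "fascia_depth": spec.fascia_depth,
        "fascia_thickness": spec.fascia_thickness,
        "second_fascia_depth": spec.second_fascia_depth,
        "liver_range": list(spec.liver_range) if spec.liver_range else None,
        "bile_depth": spec.bile_depth,
        "bile_radius": spec.bile_radius,
        "vessel_depths": list(spec.vessel_depths),
        "vessel_y_offsets": list(spec.vessel_y_offsets),
        "vessel_radius": spec.vessel_radius,
        "tube_x_range": list(spec.tube_x_range),
        "ribs": spec.ribs,
        "rib_depth_range": list(spec.rib_depth_range),
        "rib_window_halfwidth": spec.rib_window_halfwidth,
        "intensity_means": {int(k): float(v) for k, v in spec.intensity_means.items()},
        "noise_sd": spec.noise_sd,
        "thresholds": {
            "t0": spec.thresholds.t0,
            "t1": spec.thresholds.t1,
            "t2_minus": spec.thresholds.t2_minus,
            "t2_plus": spec.thresholds.t2_plus,
        },
        "seed": spec.seed,
        "surface_offsets": dict(spec.surface_offsets),
        "misclassify_bands": [list(b) for b in spec.misclassify_bands],
        "test_partial": spec.test_partial,
    }
    return d


def spec_from_dict(data: dict) -> PhantomSpec:
    """Rebuild a phantom spec from its plain-dict form."""
    d = dict(data)
    kwargs = {}
    for key in ("shape", "spacing", "vessel_depths", "vessel_y_offsets"):
        if key in d:
            kwargs[key] = tuple(d.pop(key))
    for key in ("liver_range", "tube_x_range", "rib_depth_range"):
        if key in d:
            v = d.pop(key)
            kwargs[key] = tuple(v) if v is not None else None
    if "thresholds" in d:
        kwargs["thresholds"] = ThresholdSet(**d.pop("thresholds"))
    if "intensity_means" in d:
        kwargs["intensity_means"] = {int(k): float(v) for k, v in d.pop("intensity_means").items()}
    if "misclassify_bands" in d:
        kwargs["misclassify_bands"] = tuple(tuple(b) for b in d.pop("misclassify_bands"))
    if "surface_offsets" in d:
        kwargs["surface_offsets"] = {str(k): float(v) for k, v in d.pop("surface_offsets").items()}
    kwargs.update(d)
    return PhantomSpec(**kwargs)


def two_fascia_phantom(
    spec: PhantomSpec | None = None, table: TissueTable | None = None
) -> PhantomModels:
    """Phantom with two parallel fascia sheets separated by soft tissue.

    Reproduces the double-peak force curve of a two-membrane phantom: with
    aligned segmentations both models emit identical double peaks; a
    misclassified band or surface offset at the first sheet misaligns the
    pre-puncture ramps. Surface offsets apply to the first sheet only.
    """
    if spec is None:
        spec = PhantomSpec(second_fascia_depth=45.0, liver_range=None)
    if spec.second_fascia_depth is None:
        raise PhantomGeometryError("two-fascia phantom needs second_fascia_depth")
    return layered_phantom(spec, table=table)
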