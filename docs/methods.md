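# Methods

## Scope and assumptions

The package simulates the **axial** force at the handle of a rigid needle
inserted along a **straight** trajectory into an undeformed CT volume. It is
an offline evaluation tool, not a real-time device loop: tissue deformation
fields, breathing motion, needle bending, non-axial force components and
imaging (US/X-ray) rendering are out of scope. Forces are sampled on a fixed
depth grid rather than in device time; the model is quasi-static, so the
signal depends only on the sequence of tissues met along the path, not on
insertion speed.

The virtual patient is an intensity volume (HU) plus a label volume that may
be *partial*: only key structures (fascia, liver, hepatic vessels, bile
ducts) need explicit labels, everything else is classified on the fly by a
threshold transfer function. The evaluation framework compares the force
output of such a partial model against the output from a fully labeled
gold-standard model of the same anatomy.

## Tissue model

Each tissue code maps to a name, a planning role (`pass`, `risk`, `target`)
and a haptic tuple (T_N, R, k):

| tissue          | role   | T_N [N] | R [N] | k [N/mm] |
|-----------------|--------|---------|-------|----------|
| air             | pass*  | 0       | 0     | 0        |
| skin            | pass   | 0.7     | 0.7   | 0.8      |
| fat/soft tissue | pass   | 0.7     | 0.7   | 1.0      |
| bone (sensitive/specific) | risk | ∞ | 3.0   | 2.0      |
| fascia          | pass   | 2.5     | 1.0   | 1.0      |
| liver           | pass   | 0.3     | 0.9   | 1.2      |
| hepatic blood   | risk   | 1.05    | 0.75  | 1.1      |
| hepatic bile    | target | 1.2     | 0.5   | 1.0      |

*Air read inside the body marks an air cavity and raises a risk event.

Note the liver row has R > T_N. A global R ≤ T_N constraint would be natural
for the post-puncture force drop, but the table is the authority here and
the liver case is benign: its cut threshold (the lowest of all tissues) is
always below the sustain force of whatever tissue precedes it, so the liver
surface is cut immediately and its pre-puncture phase never runs. The table
is therefore validated for non-negativity only.

The transfer function classifies unlabeled voxels by half-open HU intervals
`[t0, t1)` skin, `[t1, bone)` fat/soft, below `t0` air, with the bone lower
bound switching from `t2_minus` (200 HU) to `t2_plus` (400 HU) once the
needle has passed the fascia. The numeric defaults (t0 = −500, t1 = 50) are
arbitrary-but-fixed stand-ins for patient-specific values obtained from
intensity-distribution intersections; the phantom generator draws its
intensities relative to the *configured* set, so no result depends on HU
realism. Half-open intervals give deterministic boundary behaviour;
classification is monotone in HU for a fixed needle state. The two bone rows
share one haptic tuple and differ only by threshold; the classifier emits
the generic bone code.

## Four-phase force rendering

Within one tissue cycle:

1. **Pre-puncture.** The proxy is pinned at the surface; with displacement
   d = tip − surface the force is f(d) = a₂d² + a₁d + a₀, where a₀ is the
   sustain force of the tissue just left (0 from air), a₁ = a₁_fraction·k
   (default a₁ = k/2) and a₂ = k(k − a₁)/|T_N − a₀|. This quadratic reaches
   T_N at exactly d* = (T_N − a₀)/k — the linear spring's puncture
   displacement — for every admissible a₁, which is the property all
   downstream error numbers rely on; a₁ only shapes the ramp.
2. **Post-puncture** is instantaneous at the sampling resolution. The sample
   at which f first reaches T_N emits exactly T_N (the puncture peak); the
   next sample already carries the dropped sustain force R. No intermediate
   decaying samples are emitted. Emitting the exact threshold at the cut
   sample makes the rendered peak equal T_N regardless of grid phase, so
   peak-based checks (fascia 2.5 N) and peak-mismatch errors are exact.
3. **Pass.** The proxy trails at l_max = R/k and the linear spring emits the
   constant friction force k·l_max = R while advancing.
4. **Transition.** At a label/class change between consecutive samples
   (the surface is the first sample of the new tissue): if T_N(new) > R(cur)
   a new ramp starts from a₀ = R(cur); if T_N(new) ≤ R(cur) the surface is
   cut immediately and the force drops to R(new) in the same sample. Exits
   (into soft tissue or out of the body) are the T_N ≤ R case.

Special rules:

- **Bone** never cuts (T_N = ∞). The quadratic coefficient degenerates to 0;
  the engine uses the linear spring a₁ = k there so the ramp carries the
  bone's full 2 N/mm stiffness, and the force clamps at the 22 N device
  maximum. Because the membrane is never cut, the engine stays in the bone
  ramp for the rest of the path — the physical tip cannot advance past bone,
  so tissue sampled beyond it is never entered.
- **During a ramp, tissue changes at the tip are ignored**: the pinned
  membrane has not been cut, so its parameters keep governing the spring.
  Layers thinner than the puncture displacement of the membrane above them
  are therefore skipped; with the default table and layer thicknesses this
  does not occur (largest d* ≈ 2.5 mm).
- **Retraction** renders the pass phase only (all membranes already cut):
  the profile over depth is the local sustain force, with no peaks.
- **Risk events** (vessel surface, air cavity inside the body, bone) are
  annotated on the signal but do not alter the force.

Determinism: rendering is pure arithmetic on the sampled tissue sequence;
identical inputs give bit-identical signals.

## Trajectories and sampling

Voxel convention: world = origin + index·spacing (voxel centers, 0-based).
Label and intensity lookups are nearest-neighbour — labels are categorical
and the classifier thresholds a single voxel at the tip, so interpolation
would be meaningless. Paths carry 1,000 uniform depth samples by default
regardless of length; at the 90 mm maximum insertion length this is a
0.09 mm worst-case spacing, ≥10× oversampling of sub-millimetre voxels. A
warning (with a 2% grace so the canonical 1,000-sample/90 mm grid on 0.9 mm
voxels conforms) is raised when a path is sampled coarser than a tenth of
the smallest voxel axis. Experiment runs extend each planned path backwards
into the air (default 5 mm, clipped at the volume bounds) so the skin
puncture is part of the rendered signal, and scale the sample count to keep
the planned-path spacing.

## Path planning

Candidates run from every exposed skin voxel (skin label with a 6-connected
air neighbour) to every voxel of the target centerline. The centerline is
the 3D topological thinning of the target mask; if thinning collapses a
non-empty mask entirely (observed for perfectly symmetric even-diameter
tubes), a deterministic distance-ridge fallback keeps one maximum-clearance
voxel per slab along the component's principal axis. Rays are marched at
half-voxel steps with nearest-voxel lookups.

Scores: C1 = ∞ if a risk structure is crossed before the target (else 0);
C2 = ∞ if the Euclidean length exceeds 90 mm (else 0); C3 = min Euclidean
clearance of the shaft from any risk structure (from a distance transform of
the risk mask, sampled along the ray), normalized by d_cap = 10 mm and
clipped to 1; C4 = number of distinct target voxels traversed, normalized by
n_cap = 10 and clipped to 1. Quality Q = ½(C1+C2+C3+C4), infinity flagging
infeasibility; higher is better. Per skin voxel the best finite-Q candidate
is kept (ties: smallest (z, y, x) target voxel), and accepted paths must
reach Q ≥ 0.4. The caps make the soft scores bounded, monotone and
data-independent; the intercostal-window preference of accepted paths is an
emergent property of the constraints, not coded anatomy.

## Evaluation metrics

- **RMSE** and **MAE** per path; MAE is the field's *maximum* absolute
  error, hence RMSE ≤ MAE.
- **%Fc**: percentage of samples with identical forces, tolerance 1e-9 N by
  default — the comparison is same-engine/different-labels, so anything
  beyond bit-level float noise is a real difference.
- **MSD/HSD**: border crossings of each structure are matched in order
  between the two segmentations; mean and maximum absolute depth difference
  per structure and pooled per path. Unmatched crossings are excluded from
  the distances and reported as a count, keeping the discrepancy visible
  without inventing pairings. Interpretation lines: 2 mm (low) and 3 mm
  (standard) just-noticeable depth lags for salient force events.
- **Weber JND**: JND% = 100·((S+ΔS)−S)/S and its inverse ΔS = S·%/100.
  The working force threshold is 18.1% of the 0.8 N average counter force
  inside the body, i.e. 0.145 N.
- **Outliers**: one-sided, values above mean + 2.7σ with σ the sample
  standard deviation (n−1).
- Cohort summaries report mean ± sd of RMSE/MAE, outlier percentages, and a
  *sample-weighted* pooled %Fc (not a path average).

## Synthetic phantoms

The layered phantom emulates a lower-thorax/upper-abdomen block along the
insertion (+z) axis: air (0–5 mm), skin (5–8 mm), fat/soft tissue, fascia
sheet (25–29 mm), liver (30–110 mm) containing a 6 mm bile tube (the target,
at 60 mm) and two 5 mm vessel tubes, plus two rib slabs (10–18 mm depth)
flanking a 20 mm intercostal window. Default grid 128×128×160 voxels at
0.9 mm isotropic — desk-scale, supports full 90 mm paths. The two-fascia
variant replaces the liver with a second fascia sheet at 45 mm for the
double-peak success/failure experiments.

Fascia sheets are 4 mm thick. This keeps the reference model inside the
fascia (≥ 0.9 N) wherever a test model's delayed puncture peak can fall
under perturbations up to 2 mm, so the worst peak-misalignment error is
bounded by 2.5 − 0.9 = 1.6 N; with a thin sheet the reference could already
be back at the 0.7 N soft-tissue level, inflating the failure mode beyond
what it is meant to isolate.

Intensities are drawn per class (seeded) around means placed strictly inside
their threshold intervals; the default 10 HU noise leaves ≥ 5σ margins, so
spontaneous misclassification (≈3·10⁻⁷ per voxel) is negligible and every
reference/test discrepancy is an injected perturbation. Perturbations are
applied to the test model only: per-structure proximal **surface offsets**
(quantized to whole voxels — on the default 0.9 mm grid a requested 2 mm
offset realizes as 1.8 mm) and **misclassification bands** (a band of given
thickness immediately above a structure's surface relabeled as another
tissue). The test model is partial by default (key-structure labels only);
`test_partial=False` yields a fully labeled perturbed model for
label-vs-label experiments.

What the phantoms do *not* emulate: real CT texture and partial-volume
effects, curved organ boundaries, segmentation errors that change topology,
and patient-to-patient anatomical variation. Passing tests therefore show
the force engine and metrics behave correctly under controlled geometric
discrepancies; they do not certify accuracy on clinical segmentations.

## Numerical choices

- Nearest-voxel rounding uses floor(x + 0.5) (half always rounds up) for a
  deterministic, direction-independent boundary convention.
- Cut detection triggers at f ≥ T_N on the sample grid; the crossing is
  exact in exact arithmetic (the quadratic is constructed to pass through
  T_N at d*), so grid placement shifts the cut sample by at most one step.
- Surface positions are quantized to the first sample of the new tissue;
  event positions are therefore accurate to one sample step (0.09 mm at
  default settings).
- Planner determinism: skin voxels and centerline voxels are processed in
  sorted (z, y, x) order; score ties resolve to the first (smallest) target.
- Degenerate inputs: empty target masks, non-unit directions, paths leaving
  the volume, unregistered label codes and ill-ordered thresholds all raise
  typed errors rather than degrading silently.

## Problem sizes

Default experiment scale, chosen as a desk-scale stand-in for one patient:
2,236 accepted paths on the default phantom (~16k skin voxels × ~160
centerline targets screened), 1,000 force samples per path; a full planned
cohort with rendering and evaluation completes in well under a minute on one
CPU core. The test suite uses smaller phantoms (48×48×96 at 1 mm) and
strided skin sets for speed.

## Known limitations

- Phase 3 friction is constant per tissue; no depth- or velocity-dependent
  component, no micro-events, no bevel-tip subphases.
- A ramp spanning a thin intermediate layer attributes the whole ramp to the
  pinned membrane (see above); sub-sample-thickness layers can be missed
  entirely by nearest-voxel sampling.
- MSD/HSD matching is positional (i-th crossing to i-th crossing); a missed
  or spurious structure detection shifts subsequent pairings of that
  structure.
- The planner scores straight rays only and treats visibility binarily; no
  margin-aware curved planning.
- Bone blocking refuses further advance physically but the signal keeps
  emitting the clamped force for the remaining (unreachable) samples rather
  than truncating the path.
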