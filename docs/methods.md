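# Methods

This document defines the estimators, their parameters, and the
reasoning behind the non-obvious choices. Units: strand coordinates in
nanometres, curvature in μm⁻¹, structure coordinates in Ångströms,
angles in degrees.

## Strand traces

A trace is an ordered polyline of digitised strand coordinates with a
pixel size (default 1.2 nm), optionally labelled per point with the
fracture face (`P`/`E`). Traces must have ≥ 2 points, finite
coordinates and no consecutive duplicates. Before analysis every trace
is resampled to uniform arc spacing equal to the pixel size, which
decouples estimator behaviour from the tracing density.

## Curvature by osculating-circle fitting

Local curvature at a resampled point is estimated from the circle
through three points — the point itself and its neighbours `w` pixels
(default 10) to either side along the polyline:

κ = 2 |cross(p₂−p₁, p₃−p₁)| / (|p₂−p₁| |p₃−p₁| |p₃−p₂|)

reported in μm⁻¹, with a signed variant for turn direction. The window
trades locality against noise; 10 px ≈ 12 nm, comfortably below the
50 nm minimum planted arc length, so constant-curvature stretches are
measured without cross-arc mixing. Samples with a three-point turn
above 45° are flagged as kinks so discrete bends can be separated from
smooth arching.

On exact circles of radius 8.13 nm – 1 μm the estimator matches 1/R to
better than 10⁻⁶ relative error at every sampling phase (see the test
suite), so all practical error comes from digitisation noise.

**Jitter smoothing.** One pixel of tracing jitter dominates the
three-point estimate (second differences amplify noise). For jittered
data the trace is pre-smoothed with a moving average of 35 px
(`JITTER_SMOOTH_PX`). This length was chosen from the noise model, not
fitted: the three-point curvature noise scales as σ/ℓ² for half-window
ℓ while the bias for the median planted curvature (radius 125 nm)
scales as the smoothed fraction of the arc; 35 px ≈ 42 nm keeps that
bias a few percent at the distribution's median while suppressing the
noise floor below it. With this setting the pooled curvature median of
a 16-strand replicate lands within 10 % of the planted arc-length-
weighted median in ≥ 95 of 100 replicates.

**Truth definition for recovery tests.** The planted curvature of a
replicate is summarised by the arc-length-weighted median of its
per-arc curvatures (interpolated weighted median), because the pooled
estimator samples curvature per unit arc length — an unweighted median
over arcs would measure a different quantity.

## Angle per monomer

Curvature is converted into the in-plane rotation between adjacent
protomers using the monomer centroid spacing d = 2.8 nm:

* arc mode (default): θ = d·κ (radians → degrees), the rotation of the
  tangent over one monomer step along the osculating circle;
* chord mode: θ = 2·arcsin(d·κ/2), treating d as a chord.

The two agree to < 0.11° over the observed curvature range (κ = 8 μm⁻¹
→ 1.28°; κ = 123 μm⁻¹ → 19.73° arc / 19.83° chord). The summary reports
the fraction of samples strictly above a 3° threshold.

## Branch angles

The acute angle between a parent strand and a branch at their junction.

* **Junction.** The branch endpoint nearest the parent polyline (the
  branch grows from the parent, so one of its two endpoints is the
  junction); the gap must be ≤ 2 px. A globally-closest-point rule
  fails here: strands curl at a median radius of ~125 nm, so a branch
  frequently re-approaches its parent far from the true junction.
* **Tangents.** An algebraic circle fit (Pratt normalisation,
  A(x²+y²)+Bx+Cy+D=0 with B²+C²−4AD=1, solved as a generalised
  eigenproblem) over a window of 120 px on each side of the junction;
  the parent window spans the junction, the branch window runs one-
  sided into the branch. Because the fitted model is exact for circular
  arcs, a long window does not bias constant-curvature geometry — it
  only averages jitter — and the fitted tangent can be evaluated at the
  junction itself by rotating along the fitted circle, so smoothing-
  induced endpoint trimming does not displace the evaluation point.
  The fit degrades gracefully to a straight line as A → 0.
* **Folding.** The angle between the two tangents is folded into
  [0°, 90°].

Under 1 px jitter the per-measurement spread is ≈ 4° IQR; ~4 % of
branches fail the 2 px junction gap check and are reported as errors
rather than silently skipped.

**Mode recovery.** Populations of branch angles are summarised by a
Gaussian kernel density estimate with a fixed 2° bandwidth. The data
are reflected about both domain boundaries (0° and 90°) before
density estimation; without reflection the fold at 90° halves the
density of a boundary mode and drags the estimate of a nearby interior
mode downward. Planted 67°/90° mixtures (σ = 3°) are recovered within
2° on ~1000-branch samples.

## Segments and fracture-face breaks

Segment statistics (count, mean, SD of lengths) summarise uninterrupted
strand stretches. Face-labelled traces yield a discontinuity rate:
P↔E label transitions per μm of strand; a warning (not an error) flags
traces outside the 0.8–1.5 μm length window where such counts are
customarily reported.

## Toy structures and dimer poses

A claudin-like pseudo-structure: 186 residues in four membrane-spanning
helices (TM1–TM4) with the extracellular helix (ECH) and loops
(ECL1, ECL2) arched above the membrane, 3 pseudo-atoms per residue (CA
plus radially-pointing side-chain atoms). It is a geometric stand-in
for surface, contact and pose arithmetic — not a homology model.
Coordinates are quantised to 0.001 Å so PDB round trips are exact, and
the finished scaffold is rotated so its dominant CA principal axis lies
exactly along the membrane normal (+z): the canonical orientation for a
membrane protein, and a prerequisite for tilt estimates that do not
inherit an arbitrary scaffold offset.

Dimer poses place a second copy at a known in-plane rotation about +z,
tilt about a membrane-plane axis, and translation; construction rejects
inter-chain heavy-atom clashes (< 2 Å), naming the offending residues.

## SASA

Shrake–Rupley with a deterministic golden-spiral point set (960
points/atom), probe 1.4 Å, van der Waals radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å. Exact for isolated atoms; within 1 % of the
closed-form two-sphere result; cross-checked against an independent
implementation in the tests. ΔSASA of a pose is
SASA(A) + SASA(B) − SASA(AB), the total buried area over both chains
(a per-side variant halves it).

## Pose geometry

* **Tilt** — angle between the protomers' dominant CA principal axes
  (sign-aligned with the membrane normal), in [0°, 90°]. Poses at or
  above the 30° bilayer-compatibility limit are flagged, never dropped.
* **In-plane rotation** — chain A of the pose is superposed onto chain
  A of the reference (least-squares rigid fit; RMSD must be ≤ 0.5 Å,
  otherwise the poses do not share a monomer and an error is raised);
  the residual rotation carrying chain B onto the reference's chain B
  is decomposed about the membrane normal (swing–twist), and the twist
  magnitude is reported folded into [0°, 180°].

Planted rotations {5°, 17°, 30°} and tilts {0°, 15°, 30°} are both
recovered to < 0.001° across 100 scaffold seeds.

## Coupling-pair triage

Filtering a raw (i, j, score) table, in order: normalise to i < j and
reject malformed rows (reported by row index); drop pairs touching the
excluded C-terminal range 187–227 (absent from the structural model);
keep scores strictly above 0.47; keep the top 500 by score with
deterministic (i, j)-ascending tie-breaking. The filter is idempotent.

Retained pairs are classified against the monomer: side-chain
centre-of-mass distance strictly below 10 Å → `monomer-fold`; at or
above 20 Å → `candidate-oligomer`; between → `ambiguous`. The fold
overlap fraction (fold pairs / retained pairs) measures how much of the
signal the monomer structure already explains.

A candidate pair supports a dimer pose when its cross-chain side-chain
distance — min of d(A:i, B:j) and d(A:j, B:i), since couplings are
unordered — is below 10 Å **and** strictly smaller than its
monomer-context distance.

All rule boundaries are pinned by constructed test cases: strictly
above 0.47, strictly below 10 Å (contact), strictly below 3 Å
(interface residues), flagged at ≥ 30° (tilt), strictly above the
median (active-residue selection).

## Restraint selection and conservation

Active residues have per-residue SASA strictly above the median over
the considered range; passive residues are the remaining ones whose
side-chain centroid lies within 6.5 Å of an active centroid. Interface
conservation averages per-residue conservation ratios of interfacial
residues per region; regions without interfacial residues are absent
from the result rather than zero.

## Pose ranking

The interface pipeline orders poses lexicographically by coupling
support, then mean interface conservation, then ΔSASA (all descending).
This is a reporting convenience for humans reading the table — not a
fused score with tuned weights — and no pose is ever removed by it.

## Limitations

* The toy structure supports geometric arithmetic only; its SASA,
  contacts and conservation have no biochemical meaning.
* Branch-angle measurement assumes the branch's own trace begins at the
  junction; detached branch traces (> 2 px gap) are rejected.
* The jitter-smoothing length (35 px) is tied to the 1.2 nm / 1 px
  digitisation model; other noise regimes need their own setting.
* Molecular-dynamics-scale quantities (binding energies, secondary-
  structure changes) are out of scope.
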