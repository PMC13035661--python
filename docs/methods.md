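# Methods

This note records the models, algorithms and numerical choices behind
`aortamorph`, in the spirit of a statistical/methodological appendix.
Units are fixed package-wide: millimetres, millilitres, days.

## Input model

The pipeline starts at a 3D integer label map of the dissected aorta
(aortic valve to aorto-iliac bifurcation, branches excluded, wall
included in the labels): background 0, true lumen (TL) 1, circulating
false lumen (CFL) 2, thrombus (TH) 3. Codes are remappable; any other
voxel value is a validation error. Geometry comes from the NIfTI affine;
all volumes are voxel counts × |det(affine₃ₓ₃)| / 1000, never raw voxel
counts, so anisotropic spacing needs no special casing. `Ao_Glo` and
`FL_Glo` are formed by summing the per-label float volumes, which makes
the conservation identities `Ao_Glo = V_TL + V_CFL + V_Th` and
`FL_Glo = V_CFL + V_Th` exact to machine identity.

## Centerline

The centerline is extracted from the union mask TL ∪ CFL ∪ TH:

1. **Component check.** The mask must contain exactly one 6-connected
   component of ≥ 27 voxels; smaller specks are treated as segmentation
   debris and ignored, a second large component is an error that reports
   the component sizes.
2. **Thinning.** 3D medial-axis thinning (Lee). Parallel thinning has a
   genuine degenerate case: a mask whose axis lies exactly on a
   half-voxel symmetry plane in two transverse axes is annihilated
   wholesale (every boundary voxel is simple on the same pass). When the
   skeleton of a substantial mask comes back (near-)empty, the mask is
   re-thinned after a one-sided single-voxel erosion, which shifts one
   boundary by one voxel and the medial axis by at most half a voxel;
   all measurements still use the untouched mask.
3. **Longest geodesic path.** Skeleton voxels form a graph
   (26-neighbour edges weighted by their mm separation); a double
   farthest-point sweep (Dijkstra from the lexicographically first
   voxel, then from the farthest voxel found) selects the longest
   geodesic path, pruning side branches by construction. Distance ties
   resolve to the lexicographically smallest voxel, so the result is
   deterministic.
4. **Smoothing.** Moving average over 5 samples (edge-replicated): wide
   enough to suppress the voxel staircase, narrow enough (~5 mm) not to
   shorten curvature features at the 30-mm scale used by FL_Loc.
5. **End extension.** Thinning skeletons retract roughly one vessel
   radius from blunt ends, which would bias Ao_length by 20–30% on
   aorta-calibre vessels. Each end is therefore extended along its
   (5-sample-averaged) end tangent in quarter-voxel steps until the
   walk leaves the mask.
6. **Resampling.** Chord-length parameterisation, uniform resampling at
   `step` (default 1 mm), tangents by central differences. `arclen` is
   the cumulative chord length of the resampled polyline; its last
   entry is Ao_length.

The centerline's orientation (which anatomical end is first) is
reported as metadata only: every downstream quantity uses absolute arc
distances and window sums, so the pipeline is direction-agnostic. On
phantoms this shows up as peak positions occasionally reported from the
opposite end.

Accuracy on phantoms: straight-tube length within 0.2%, quarter-arc and
candy-cane within ~1%, and refinement from 1.0 to 0.5 mm voxels moves
the length toward the analytic value.

## Diameter profile and D_max

At every centerline sample the union mask is resampled on a square
plane orthogonal to the local tangent (parallel-transported in-plane
frames avoid frame flips at bends). Sampling is bilinear interpolation
of the binary mask on a 0.5-mm in-plane grid, thresholded at 0.5 —
deterministic and sub-voxel consistent. The connected component
containing the centerline point is kept (a component touching the plane
border raises an error advising a larger `plane_extent`, default
100 mm), and its maximal Feret diameter is the local diameter; this
matches the clinical "double-oblique maximal diameter" convention of
measuring the outer contour across both lumina and thrombus.

Samples within `end_guard` (default 10 mm) of either end are flagged
invalid for peak search — an orthogonal plane near an open end cuts
obliquely through the cap and inflates the Feret diameter — but are
never dropped, and volumes are unaffected. D_max is the profile maximum
over valid samples; ties break toward the smaller arc length.

Binary voxelization plus contour extraction dilates diameters by about
one voxel (e.g. ~+0.7 mm at 0.5-mm voxels); phantom checks therefore
compare D_max at a tolerance of two in-plane resolutions, and the
dilation shrinks with spacing refinement.

## FL_Loc

Every CFL/TH voxel is assigned to its nearest resampled centerline
point (Euclidean distance, k-d tree), partitioning the false lumen
along arc length. This nearest-point rule, rather than normal-plane
slabs, avoids double counting at high curvature; on straight segments
the two coincide. A window `[c − h, c + h]` (half-width h = 15 mm by
default) is clipped to `[0, Ao_length]` and keeps its reduced span — no
re-centering — preserving "the volume around this position" semantics
at the ends.

The window sum weights each sample by the overlap between the window
and the sample's arc-length slab (the interval between midpoints to its
neighbours): interior samples count fully, edge samples fractionally.
Two consequences are used as invariants: a window spanning `w` of a
uniform vessel captures exactly `w/L` of the false lumen, and disjoint
windows tiling `[0, L]` reproduce FL_Glo exactly. The remaining
uncertainty is the ±1 voxel-plane quantisation of window content
(~3% of a 30-mm window at 1-mm voxels, halved at 0.5 mm).

Candidate positions: `s1` is the global valid-profile maximum; `s2` the
largest diameter among valid samples at least `min_separation` (10 mm)
from `s1` — the second-largest diameter outside the exclusion zone, not
necessarily a local maximum. FL_Loc is the larger of the windowed
false-lumen volumes at `s1` and `s2` (the `s1` window alone is a lower
bound, so the two-candidate rule can only help). Section lengths
10/15/30/50 mm form the standard sweep; FL_Loc is monotone
non-decreasing in section length and bounded by FL_Glo, reaching it
when the window covers the vessel.

## Evolution ("+") markers

`m⁺ = m_T1 + (m_T2 − m_T1) · Y/Δd` linearly extrapolates the observed
change to a fixed horizon of `Y` days (default 365; configurable
because day-count conventions differ). Negative growth is not floored:
the marker is an estimate, not a rate classification. Intervals shorter
than 30 days trigger a warning — the coefficient `Y/Δd` then exceeds
~12 and measurement noise dominates the extrapolation (clinical
inter-scan intervals are on the order of 194 ± 77 days).

## Prognostic statistics

- **ROC/AUC.** Thresholds are the observed marker values; the rule is
  "positive if value ≥ threshold" (a direction flag handles markers
  where small is adverse). The trapezoid area over this curve equals
  the midrank Mann–Whitney statistic with ties counted ½; the suite
  verifies the equality against brute-force pair counting at 1e-12.
- **DeLong CI.** Variance from event/non-event placement values, Wald
  interval on the AUC scale clipped to [0, 1]; chosen over the
  bootstrap for determinism (a seeded stratified percentile bootstrap
  is available behind a flag). When no placement variation exists (all
  values tied, or perfect separation) the interval collapses to
  (AUC, AUC) with a warning.
- **Youden point.** Threshold maximising J = Se + Sp − 1; ties break
  toward the lowest threshold, which keeps sensitivity maximal at equal
  J — the screening-oriented choice. PPV/NPV come from the 2×2 table at
  that threshold on the same cohort (an apparent, not cross-validated,
  operating point). The NPV is labelled "PNV" in reports, keeping the
  field's column naming.
- **Group tests.** Student's t when both groups have n ≥ 30 or
  Shapiro–Wilk finds no evidence of non-normality; otherwise
  Wilcoxon/Mann–Whitney. The test actually used is part of the result.
- **Likelihood-ratio test.** Univariate logistic regression fitted by
  IRLS on the standardised marker (gradient norm < 1e-8), LR = 2Δll
  against the intercept-only model, p from χ²₁. Complete separation is
  detected up front (disjoint group ranges) and during iteration
  (diverging slope) and raised as an explicit error, since the
  statistic is then unbounded.
- **KS distance.** Two-sample Kolmogorov–Smirnov statistic (exact ECDF
  supremum); the suite checks it against pooled-point ECDF evaluation.

## Synthetic data

**Phantoms.** Parametric tubes with three centerline families —
straight (optionally tilted to the grid), quarter arc, and candy cane
(semicircular arch joined C¹ to a straight descending limb, the
simplest geometry exercising aorta-like curvature). Radius profile
`r(s) = r0 + A·exp(−(s−s0)²/2w²)`; default r0 = 15 mm and descending
length 100 mm are in the range of adult dissected aortas. A voxel is
foreground when its perpendicular distance to the finely sampled curve
is within `r(s_eff)` of it, with the projected arc length `s_eff`
clipped to `[0, L]` — i.e. flat end caps, so the analytic volume is
exactly `∫π r(s)² ds` (adaptive quadrature) with no cap correction.
The false lumen is the angular sector θ ∈ [0, 2π·fl_fraction) measured
in a continuous in-plane frame, thrombus a sub-sector of it: the label
partition is exact by construction. The analytic FL_Loc is the windowed
false-lumen integral maximised over clipped window centers — the
continuous counterpart of the two-candidate rule, which on a uniform
tube reduces to `FL_Glo · L_section/L`. The voxel grid is offset by a
quarter voxel from the curve frame to stay clear of the thinning
degeneracy described above. Phantoms emulate geometry only: no CT
intensities, no noise, no segmentation errors, no multi-channel
dissections — so phantom tests validate the measurement chain, not
robustness to imperfect segmentations.

**Cohorts.** Two-group Gaussian draws `N(μ_e, σ_e)` / `N(μ_n, σ_n)` at
the published group sizes; presets carry the published per-group
summaries of the two clinical cohorts (83 and 79 patients). Normality
is the minimal assumption available from means ± SDs, and it yields the
closed-form expected AUC `Φ(Δμ/√(σ_e² + σ_n²))` used as the simulation
oracle. Real volumetric markers are right-skewed, so simulated cohorts
reproduce group separation — AUC, KS, test behaviour — not distribution
shape or threshold locations. The paired simulator adds per-group
annual growth over a Gaussian inter-scan interval (194 ± 77 days,
truncated to > 30 by redrawing) to exercise the annualize → evaluate
chain end-to-end.

## Problem sizes and determinism

Default analyses run on phantoms of 1–2 million voxels (0.5–1 mm
isotropic), a few seconds each through the full chain; replicate
AUC averaging uses 2000–3000 cohorts. Every stochastic component takes
a single integer seed (NumPy `default_rng`; replicate seeds spawned via
`SeedSequence`), and identical inputs, configuration and seed produce
byte-identical outputs. The CLI embeds a SHA-256 hash of the effective
configuration in its outputs for provenance.

## Known limitations

- The centerline algorithm is validated against phantoms, not against
  an expert-traced anatomical centerline; heavily tortuous or
  near-self-touching anatomies may defeat the longest-path heuristic on
  skeleton graphs with cycles.
- D_max carries a systematic ~one-voxel dilation from binary
  resampling; comparisons across resolutions should use the stated
  tolerance of two in-plane resolutions.
- The Youden operating point is apparent (estimated and evaluated on
  the same cohort) and optimistic relative to an external threshold.
- Evaluation is univariate by design; no multivariable or
  time-to-event modelling is included.
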